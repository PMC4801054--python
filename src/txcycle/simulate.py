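"""Stochastic (Gillespie) generator of per-cell smFISH-like datasets.

One *locus* is simulated exactly as in the kinetic model: a single gene copy
that switches ON/OFF, initiates transcripts that reside at the site for a
deterministic time ``tres`` before maturing, replicates into two copies at
``trep`` (the daughter copy inherits the parent copy's state, activation
rate becomes ``alpha*kon``), and at ``tdiv`` binomially partitions its
mature mRNA while one post-division copy is retained.  A diploid cell is
two independent loci sharing the same cell-cycle clock, so it carries 2
transcription sites before locus replication and 4 after.

The simulator doubles as the brute-force oracle for the FSP solver: its
histograms at fixed cell-cycle ages must agree with the solved
distributions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from .params import (
    CellCycleParams,
    KineticParams,
    phase_boundary_ages,
    sample_ages,
)

__all__ = [
    "SimulatedCell",
    "simulate_lineage",
    "sample_population",
    "sample_at_ages",
    "sample_dna_mixture",
    "true_dna_content",
    "cells_to_frame",
    "frame_to_cells",
    "write_cells_table",
    "read_cells_table",
    "nascent_total",
    "BURNIN_DIVISIONS",
]

#: divisions discarded before any observation, so records are cyclostationary
BURNIN_DIVISIONS = 5

_BUF = 4096  # per-copy ring buffer of pending initiation times


@njit(cache=True)
def _signal(buf, head, cnt, t, tres, probes):
    """Signal of one copy: sum of elongated fractions of resident transcripts.

    With an explicit probe list the contribution of a transcript elongated a
    fraction f is the fraction of probe positions already transcribed;
    with no probes (uniform approximation) it is f itself.
    """
    s = 0.0
    np_probes = len(probes)
    for j in range(cnt):
        ti = buf[(head + j) % _BUF]
        f = (t - ti) / tres
        if f > 1.0:
            f = 1.0
        if np_probes > 0:
            k = 0
            for q in range(np_probes):
                if probes[q] <= f:
                    k += 1
            s += k / np_probes
        else:
            s += f
    return s


@njit(cache=True)
def _sim_locus(kon, koff, kini, tres, kd, trep, tdiv, alpha, probes,
               rec_times, seed,
               rec_m, rec_sig, rec_ncop, rec_s):
    """Exact simulation of one locus; records state at absolute times ``rec_times``.

    rec_times must be sorted ascending.  Outputs are written into the
    preallocated rec_* arrays (len(rec_times) rows).
    """
    np.random.seed(seed)
    s = np.zeros(2, dtype=np.int64)
    buf = np.zeros((2, _BUF), dtype=np.float64)
    head = np.zeros(2, dtype=np.int64)
    cnt = np.zeros(2, dtype=np.int64)
    m = 0
    ncop = 1
    t = 0.0
    cyc = 0
    replicated = False
    ri = 0
    n_rec = len(rec_times)
    INF = 1.0e300

    while ri < n_rec:
        t_rep = cyc * tdiv + trep if not replicated else INF
        t_div = (cyc + 1.0) * tdiv
        t_rec = rec_times[ri]
        t_mat = INF
        mat_c = -1
        for c in range(ncop):
            if cnt[c] > 0:
                tm = buf[c, head[c] % _BUF] + tres
                if tm < t_mat:
                    t_mat = tm
                    mat_c = c
        t_det = t_mat
        if t_rec < t_det:
            t_det = t_rec
        if t_rep < t_det:
            t_det = t_rep
        if t_div < t_det:
            t_det = t_div

        kon_eff = alpha * kon if replicated else kon
        rate = kd * m
        for c in range(ncop):
            if s[c] == 1:
                rate += koff + kini
            else:
                rate += kon_eff
        if rate > 0.0:
            t_sto = t + np.random.exponential(1.0 / rate)
        else:
            t_sto = INF

        if t_sto < t_det:
            t = t_sto
            u = np.random.random() * rate
            if u < kd * m:
                m -= 1
            else:
                u -= kd * m
                done = False
                for c in range(ncop):
                    if done:
                        break
                    if s[c] == 1:
                        if u < koff:
                            s[c] = 0
                            done = True
                        else:
                            u -= koff
                            if u < kini:
                                buf[c, (head[c] + cnt[c]) % _BUF] = t
                                cnt[c] += 1
                                done = True
                            else:
                                u -= kini
                    else:
                        if u < kon_eff:
                            s[c] = 1
                            done = True
                        else:
                            u -= kon_eff
        else:
            t = t_det
            if t_det == t_mat:
                head[mat_c] = (head[mat_c] + 1) % _BUF
                cnt[mat_c] -= 1
                m += 1
            elif t_det == t_rec:
                rec_m[ri] = m
                rec_ncop[ri] = ncop
                for c in range(2):
                    rec_s[ri, c] = s[c]
                    if c < ncop:
                        rec_sig[ri, c] = _signal(buf[c], head[c], cnt[c], t, tres, probes)
                    else:
                        rec_sig[ri, c] = np.nan
                ri += 1
            elif t_det == t_rep:
                s[1] = s[0]
                cnt[1] = 0
                head[1] = 0
                ncop = 2
                replicated = True
            else:  # division
                m = np.random.binomial(m, 0.5)
                s[1] = 0
                cnt[1] = 0
                head[1] = 0
                ncop = 1
                replicated = False
                cyc += 1


@njit(cache=True)
def _sample_cells(ages, seeds, kon, koff, kini, tres, kd, trep, tdiv, alpha,
                  probes, burn):
    """Two independent loci per cell, each observed at the cell's age."""
    n = len(ages)
    mature = np.zeros(n, dtype=np.int64)
    nsig = np.full((n, 4), np.nan)
    ncop = np.zeros(n, dtype=np.int64)
    rec_m = np.zeros(1, dtype=np.int64)
    rec_sig = np.zeros((1, 2), dtype=np.float64)
    rec_ncop = np.zeros(1, dtype=np.int64)
    rec_s = np.zeros((1, 2), dtype=np.int64)
    rec_times = np.zeros(1, dtype=np.float64)
    for i in range(n):
        rec_times[0] = burn * tdiv + ages[i]
        for locus in range(2):
            _sim_locus(kon, koff, kini, tres, kd, trep, tdiv, alpha, probes,
                       rec_times, seeds[i, locus],
                       rec_m, rec_sig, rec_ncop, rec_s)
            mature[i] += rec_m[0]
            nsig[i, locus] = rec_sig[0, 0]
            if rec_ncop[0] == 2:
                nsig[i, 2 + locus] = rec_sig[0, 1]
        ncop[i] = 2 * rec_ncop[0]
    return mature, nsig, ncop


@dataclass
class SimulatedCell:
    """One observed cell from the synthetic population."""

    age: float
    gene_copies: int
    mature: int
    nascent_signals: list
    dna_content: float

    def __post_init__(self) -> None:
        if self.mature < 0:
            raise ValueError(f"mature count must be nonnegative, got {self.mature}")
        if self.gene_copies not in (2, 4):
            raise ValueError(f"gene_copies must be 2 or 4, got {self.gene_copies}")
        if len(self.nascent_signals) != self.gene_copies:
            raise ValueError("nascent_signals must have one entry per gene copy")
        if any(s < 0 for s in self.nascent_signals):
            raise ValueError("nascent signals must be nonnegative")


def _probe_array(probe_positions) -> np.ndarray:
    if probe_positions is None:
        return np.empty(0, dtype=np.float64)
    arr = np.asarray(probe_positions, dtype=np.float64)
    if arr.ndim != 1 or np.any(arr < 0) or np.any(arr > 1):
        raise ValueError("probe positions must be fractions in [0, 1]")
    return np.sort(arr)


def simulate_lineage(params: KineticParams, n_divisions: int, seed: int,
                     record_times=None, n_records: int = 200,
                     burnin_divisions: int = BURNIN_DIVISIONS,
                     probe_positions=None) -> pd.DataFrame:
    """Simulate one locus through ``n_divisions`` cell cycles after burn-in.

    Returns a frame with one row per record time: absolute ``time``, cycle
    ``age``, ``mature`` count, per-copy nascent ``signal_1``/``signal_2``,
    gene states and copy number.  Records start after ``burnin_divisions``
    discarded cycles, so the trajectory is cyclostationary.
    """
    if n_divisions < 1:
        raise ValueError("n_divisions must be >= 1")
    t0 = burnin_divisions * params.tdiv
    t_end = (burnin_divisions + n_divisions) * params.tdiv
    if record_times is None:
        record_times = np.linspace(t0, t_end, n_records, endpoint=False)
    rec = np.asarray(record_times, dtype=np.float64)
    if np.any(rec < t0):
        raise ValueError("record times fall inside the burn-in window")
    rec = np.sort(rec)
    n = len(rec)
    rec_m = np.zeros(n, dtype=np.int64)
    rec_sig = np.zeros((n, 2), dtype=np.float64)
    rec_ncop = np.zeros(n, dtype=np.int64)
    rec_s = np.zeros((n, 2), dtype=np.int64)
    _sim_locus(params.kon, params.koff, params.kini, params.tres, params.kd,
               params.trep, params.tdiv, params.alpha,
               _probe_array(probe_positions), rec,
               int(seed) % (2**31 - 1),
               rec_m, rec_sig, rec_ncop, rec_s)
    return pd.DataFrame({
        "time": rec,
        "age": rec % params.tdiv,
        "mature": rec_m,
        "signal_1": rec_sig[:, 0],
        "signal_2": rec_sig[:, 1],
        "state_1": rec_s[:, 0],
        "state_2": rec_s[:, 1],
        "n_copies": rec_ncop,
    })


def sample_at_ages(params: KineticParams, ages, n_lineages: int, seed: int,
                   burnin_divisions: int = BURNIN_DIVISIONS,
                   probe_positions=None):
    """Observe ``n_lineages`` independent loci at fixed ages within one cycle.

    Returns (mature, signals, n_copies): mature is (n_lineages, n_ages)
    counts, signals is (n_lineages, n_ages, 2) per-copy nascent signal
    (NaN for the absent pre-replication copy), n_copies is (n_ages,).
    Used as the brute-force oracle for the FSP distributions.
    """
    ages = np.sort(np.asarray(ages, dtype=float))
    rec = burnin_divisions * params.tdiv + ages
    na = len(ages)
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, n_lineages)
    mature = np.zeros((n_lineages, na), dtype=np.int64)
    signals = np.zeros((n_lineages, na, 2))
    probes = _probe_array(probe_positions)
    rec_m = np.zeros(na, dtype=np.int64)
    rec_sig = np.zeros((na, 2))
    rec_ncop = np.zeros(na, dtype=np.int64)
    rec_s = np.zeros((na, 2), dtype=np.int64)
    for i in range(n_lineages):
        _sim_locus(params.kon, params.koff, params.kini, params.tres, params.kd,
                   params.trep, params.tdiv, params.alpha, probes, rec,
                   int(seeds[i]), rec_m, rec_sig, rec_ncop, rec_s)
        mature[i] = rec_m
        signals[i] = rec_sig
    n_copies = np.where(ages < params.trep, 1, 2)
    return mature, signals, n_copies


def true_dna_content(ages, cc: CellCycleParams) -> np.ndarray:
    """Noise-free DNA content: mu in G1, linear mu->2mu across S, 2mu in G2/M."""
    t1, t2 = phase_boundary_ages(cc.phase_fractions, cc.tdiv)
    a = np.asarray(ages, dtype=float)
    frac = np.clip((a - t1) / max(t2 - t1, 1e-12), 0.0, 1.0)
    return cc.mu * (1.0 + frac)


def sample_population(params: KineticParams, cc: CellCycleParams, n_cells: int,
                      seed: int, probe_positions=None) -> list:
    """Draw an asynchronous population of cells from the stochastic model.

    Ages follow the exponential-growth age density; each cell's counts come
    from two independent cyclostationary loci observed at that age; DNA
    content is the piecewise-deterministic whole-genome content times
    multiplicative Gaussian noise of coefficient of variation ``cc.cv``.
    """
    if n_cells < 0:
        raise ValueError("n_cells must be >= 0")
    if n_cells == 0:
        import warnings

        warnings.warn("empty population requested", stacklevel=2)
        return []
    if abs(cc.tdiv - params.tdiv) > 1e-9:
        raise ValueError("cell-cycle and kinetic tdiv disagree")
    rng = np.random.default_rng(seed)
    ages = sample_ages(n_cells, params.tdiv, rng)
    seeds = rng.integers(0, 2**31 - 1, size=(n_cells, 2), dtype=np.int64)
    mature, nsig, ncop = _sample_cells(
        ages, seeds, params.kon, params.koff, params.kini, params.tres,
        params.kd, params.trep, params.tdiv, params.alpha,
        _probe_array(probe_positions), BURNIN_DIVISIONS)
    dna = true_dna_content(ages, cc) * (1.0 + cc.cv * rng.standard_normal(n_cells))
    dna = np.maximum(dna, 1e-6 * cc.mu)
    cells = []
    for i in range(n_cells):
        k = int(ncop[i])
        sig = [float(x) for x in nsig[i, :k]]
        cells.append(SimulatedCell(age=float(ages[i]), gene_copies=k,
                                   mature=int(mature[i]),
                                   nascent_signals=sig,
                                   dna_content=float(dna[i])))
    return cells


def sample_dna_mixture(n: int, cc: CellCycleParams, seed: int) -> np.ndarray:
    """Sample DNA contents directly from the five-Gaussian cell-cycle mixture.

    Component means are (i+3)/4 * mu for i=1..5 with equal coefficients of
    variation; weights are (fG1, fS/3, fS/3, fS/3, fG2M).
    """
    rng = np.random.default_rng(seed)
    f_g1, f_s, f_g2m = cc.phase_fractions
    weights = np.array([f_g1, f_s / 3, f_s / 3, f_s / 3, f_g2m])
    comp = rng.choice(5, size=n, p=weights / weights.sum())
    alpha_i = (np.arange(1, 6) + 3) / 4.0
    means = alpha_i[comp] * cc.mu
    sds = alpha_i[comp] * cc.cv * cc.mu
    return means + sds * rng.standard_normal(n)


def nascent_total(cells) -> np.ndarray:
    """Total nascent signal per cell (sum over transcription sites)."""
    if isinstance(cells, pd.DataFrame):
        cols = [c for c in cells.columns if c.startswith("nascent_site_")]
        return cells[cols].sum(axis=1, skipna=True).to_numpy()
    return np.array([sum(c.nascent_signals) for c in cells])


# ---------------------------------------------------------------------------
# per-cell table IO

_SITE_COLS = [f"nascent_site_{i}" for i in range(1, 5)]


def cells_to_frame(cells) -> pd.DataFrame:
    """Per-cell table: cell_id, mature, n_ts, nascent_site_1..4, dna_content, age_min.

    ``n_ts`` is the number of active transcription sites by the counting
    rule used downstream (sites with more than one nascent-mRNA equivalent).
    Absent sites (cells before locus replication) are empty fields.
    """
    rows = []
    for i, c in enumerate(cells):
        sig = list(c.nascent_signals) + [np.nan] * (4 - len(c.nascent_signals))
        rows.append({
            "cell_id": i,
            "mature": c.mature,
            "n_ts": int(sum(1 for s in c.nascent_signals if s > 1.0)),
            **dict(zip(_SITE_COLS, sig)),
            "dna_content": c.dna_content,
            "age_min": c.age,
        })
    cols = ["cell_id", "mature", "n_ts", *_SITE_COLS, "dna_content", "age_min"]
    return pd.DataFrame(rows, columns=cols)


def frame_to_cells(df: pd.DataFrame) -> list:
    cells = []
    for _, row in df.iterrows():
        sig = [float(row[c]) for c in _SITE_COLS if c in df.columns
               and not pd.isna(row[c])]
        cells.append(SimulatedCell(
            age=float(row["age_min"]) if "age_min" in df.columns else np.nan,
            gene_copies=len(sig),
            mature=int(row["mature"]),
            nascent_signals=sig,
            dna_content=float(row["dna_content"]),
        ))
    return cells


def write_cells_table(cells, path) -> None:
    """Write the per-cell table as comma-delimited text (full float precision)."""
    df = cells if isinstance(cells, pd.DataFrame) else cells_to_frame(cells)
    df.to_csv(path, index=False, float_format="%.17g")


def read_cells_table(path):
    """Read a per-cell table and validate invariants; returns list of cells."""
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except (pd.errors.ParserError, ValueError) as exc:
        raise ValueError(f"malformed per-cell table {path}: {exc}") from exc
    required = {"cell_id", "mature", "dna_content"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"per-cell table {path} lacks columns {sorted(missing)}")
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        if row["mature"] < 0 or int(row["mature"]) != row["mature"]:
            raise ValueError(f"line {line}: mature count must be a nonnegative integer")
        if not row["dna_content"] > 0:
            raise ValueError(f"line {line}: dna_content must be positive")
        for c in _SITE_COLS:
            if c in df.columns and not pd.isna(row[c]) and row[c] < 0:
                raise ValueError(f"line {line}: negative nascent signal in {c}")
    return frame_to_cells(df)
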