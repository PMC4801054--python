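"""Spot- and allele-level statistics.

Covers the table-level analysis upstream and downstream of the kinetic
model: calibrating the integrated intensity of a single mRNA from the spot
histogram (sum of Gaussians at integer multiples of one intensity),
counting active transcription sites, testing allele independence
(binomial site counts, copy-copy correlation), and the phase-gated G2/G1
fold change in nascent signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "CalibrationFit",
    "calibrate_intensity",
    "count_transcription_sites",
    "binomial_independence_test",
    "copy_correlation",
    "phase_fold_change",
]


@dataclass
class CalibrationFit:
    """Single-mRNA intensity calibration from the spot histogram."""

    i1: float                  # integrated intensity of one mRNA
    scale: float               # per-molecule variance parameter s^2
    weights: np.ndarray        # mixture weights of the 1x..Kx components
    false_positive_threshold: float
    n_spots: int
    n_discarded: int

    def counts(self, intensities) -> np.ndarray:
        """mRNA molecules per spot: intensity / i1, rounded, floored at 1."""
        x = np.asarray(intensities, dtype=float)
        return np.maximum(np.floor(x / self.i1 + 0.5).astype(int), 1)


def calibrate_intensity(spot_intensities, control_intensities,
                        n_components: int = 4, threshold_quantile: float = 0.99,
                        max_overlap: float = 0.5) -> CalibrationFit:
    """Fit I ~ sum_k w_k Normal(k*I1, k*s^2) after false-positive filtering.

    The false-positive threshold is a quantile of the negative-control
    intensity distribution; if more than ``max_overlap`` of the positive
    sample falls below it the two populations are declared inseparable.
    """
    pos = np.asarray(spot_intensities, dtype=float)
    ctrl = np.asarray(control_intensities, dtype=float)
    if len(pos) < 10:
        raise ValueError("need at least 10 spots to calibrate")
    thr = float(np.quantile(ctrl, threshold_quantile)) if len(ctrl) else 0.0
    keep = pos > thr
    overlap = 1.0 - keep.mean()
    if overlap > max_overlap:
        raise ValueError(
            f"control and positive intensities are inseparable: "
            f"{overlap:.0%} of spots fall below the threshold")
    x = pos[keep]

    def nll(theta):
        i1 = np.exp(theta[0])
        s2 = np.exp(theta[1])
        w = np.exp(theta[2:])
        w = w / w.sum()
        k = np.arange(1, n_components + 1)
        comp = w * np.exp(-0.5 * (x[:, None] - k * i1) ** 2 / (k * s2)) \
            / np.sqrt(2 * np.pi * k * s2)
        return -np.sum(np.log(np.maximum(comp.sum(axis=1), 1e-300)))

    med = np.median(x)
    sols = []
    for i1_0 in (med, med / 2, med / 3):
        theta0 = np.concatenate([[np.log(i1_0), np.log((0.15 * i1_0) ** 2)],
                                 np.zeros(n_components)])
        sol = optimize.minimize(nll, theta0, method="Nelder-Mead",
                                options={"maxiter": 4000, "xatol": 1e-6, "fatol": 1e-8})
        sols.append(sol)
    best_fun = min(s.fun for s in sols)
    # a unit of i1/2 with even components is near-degenerate with the true
    # unit; among statistically equivalent optima take the coarsest one
    best = max((s for s in sols if s.fun <= best_fun + 2.0),
               key=lambda s: s.x[0])
    w = np.exp(best.x[2:])
    return CalibrationFit(i1=float(np.exp(best.x[0])),
                         scale=float(np.exp(best.x[1])),
                         weights=w / w.sum(),
                         false_positive_threshold=thr,
                         n_spots=int(keep.sum()),
                         n_discarded=int((~keep).sum()))


def count_transcription_sites(nascent_signals, copy_number,
                              colocalized=None, min_nascent: float = 1.0) -> np.ndarray:
    """Active transcription sites per cell.

    A site is active iff it is exon-intron colocalized and carries more
    than ``min_nascent`` nascent-mRNA equivalents.  Counts above the known
    copy number (unresolved sister chromatids) are clipped with a warning.

    ``nascent_signals``: sequence of per-cell site-signal sequences (NaN =
    absent site); ``copy_number``: scalar or per-cell array.
    """
    ncells = len(nascent_signals)
    copies = np.broadcast_to(np.asarray(copy_number), (ncells,))
    counts = np.zeros(ncells, dtype=int)
    clipped = 0
    for i, sig in enumerate(nascent_signals):
        sig = np.asarray(sig, dtype=float)
        ok = ~np.isnan(sig) & (sig > min_nascent)
        if colocalized is not None:
            ok &= np.asarray(colocalized[i], dtype=bool)
        c = int(ok.sum())
        if c > copies[i]:
            clipped += 1
            c = int(copies[i])
        counts[i] = c
    if clipped:
        warnings.warn(f"{clipped} cells had more active sites than gene copies; "
                      "clipped to the copy number", stacklevel=2)
    return counts


def binomial_independence_test(site_counts, n_copies: int = 2):
    """Chi-squared goodness of fit of site counts to Binomial(n_copies, p).

    p is fitted by matching the mean; with the three categories {0, 1, 2}
    and one fitted parameter the test has one degree of freedom.  Returns
    (p_hat, chi2, p_value).
    """
    counts = np.asarray(site_counts, dtype=int)
    if len(counts) == 0 or np.all(counts == 0) or np.all(counts == n_copies):
        # p_hat of 0 or 1 gives zero expected counts in all but one category
        raise ValueError("degenerate site counts: cannot fit a binomial")
    obs = np.bincount(counts, minlength=n_copies + 1)[: n_copies + 1]
    p_hat = counts.mean() / n_copies
    exp = stats.binom.pmf(np.arange(n_copies + 1), n_copies, p_hat) * len(counts)
    chi2 = float(np.sum((obs - exp) ** 2 / exp))
    df = (n_copies + 1) - 1 - 1
    p_value = float(stats.chi2.sf(chi2, df))
    return float(p_hat), chi2, p_value


def copy_correlation(nascent_pairs, n_reshuffles: int = 100, seed: int = 0):
    """Pearson correlation between the two gene copies, with a reshuffle control.

    The control re-pairs copy-1 signals with copy-2 signals from randomly
    chosen other cells.  Returns (r, p_value, reshuffled_r) where
    ``reshuffled_r`` holds one coefficient per reshuffle.
    """
    pairs = np.asarray(nascent_pairs, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2:
        raise ValueError("nascent_pairs must be (n_cells, 2)")
    a, b = pairs[:, 0], pairs[:, 1]
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("constant signal on one copy: correlation undefined")
    r, p = stats.pearsonr(a, b)
    rng = np.random.default_rng(seed)
    resh = np.empty(n_reshuffles)
    for k in range(n_reshuffles):
        resh[k] = stats.pearsonr(a, rng.permutation(b))[0]
    return float(r), float(p), resh


def phase_fold_change(phases, nascent_totals, n_boot: int = 200, seed: int = 0,
                      method: str = "bootstrap"):
    """Fold change of mean total nascent signal, G2/M over G1, with its SEM.

    SEM either by bootstrap over cells (default) or by first-order error
    propagation of the two phase means.
    """
    phases = np.asarray(phases)
    y = np.asarray(nascent_totals, dtype=float)
    g1 = y[phases == "G1"]
    g2 = y[phases == "G2M"]
    if len(g1) == 0 or len(g2) == 0:
        raise ValueError("need cells in both G1 and G2/M")
    if g1.mean() == 0:
        raise ValueError("zero mean G1 signal: fold change undefined")
    fold = g2.mean() / g1.mean()
    if method == "bootstrap":
        rng = np.random.default_rng(seed)
        boots = np.empty(n_boot)
        for k in range(n_boot):
            b1 = rng.choice(g1, len(g1))
            b2 = rng.choice(g2, len(g2))
            boots[k] = b2.mean() / max(b1.mean(), 1e-12)
        sem = float(boots.std(ddof=1))
    elif method == "propagation":
        rel = (g1.std(ddof=1) / g1.mean() / np.sqrt(len(g1))) ** 2 \
            + (g2.std(ddof=1) / g2.mean() / np.sqrt(len(g2))) ** 2
        sem = float(fold * np.sqrt(rel))
    else:
        raise ValueError(f"unknown SEM method {method!r}")
    return float(fold), sem
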