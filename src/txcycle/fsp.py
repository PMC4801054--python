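"""Finite-state-projection solver for the cell-cycle telegraph model.

The chemical master equation is truncated at ``mmax`` mature mRNA and
solved for one locus carrying two gene-copy slots: the joint state is
(s1, s2, m) with s_i in {OFF, ON}; the second slot stays OFF until the
replication time ``trep``, when it inherits the first slot's state
(operator R).  After ``trep`` the activation rate of both slots is
``alpha*kon``.  At division the mRNA are thinned binomially (operator B)
and the second slot is reset OFF (operator V); B and V commute.  Iterating
propagate -> R -> propagate -> B,V converges to the cyclostationary
solution, which is recorded at 20 evenly spaced cell-cycle times.

State ordering: index = 4*m + s with s = 0:(OFF,OFF), 1:(ON,OFF),
2:(OFF,ON), 3:(ON,ON); columns of the generator sum to zero except for the
truncation sink at m = mmax.

Distributions for a diploid cell (2 loci, hence 2 copies replicating to 4)
are obtained by autoconvolution of the single-locus solution.  The nascent
distribution is computed by a semi-analytic Monte Carlo over the
deterministic residence window (deterministic-delay species are
non-Markovian, so they are not part of the CME state).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy import sparse
from scipy.sparse.linalg import expm_multiply, spsolve
from scipy.special import gammaln

from .params import KineticParams

__all__ = [
    "GeneratorSpec",
    "DistributionGrid",
    "build_generator",
    "propagate",
    "apply_replication",
    "apply_division",
    "division_operator",
    "replication_operator",
    "state_collapse_operator",
    "solve_cyclostationary",
    "solve_stationary",
    "nascent_distribution",
    "nascent_mean",
    "convolve_copies",
    "suggest_mmax",
    "N_TIMEPOINTS",
]

N_TIMEPOINTS = 20
DEFAULT_DT = 0.001  # min


def _blocks(params: KineticParams, regime: str):
    kon, koff, kini, kd = params.kon, params.koff, params.kini, params.kd
    if regime == "pre":
        A = np.array([
            [-kon, koff, 0.0, 0.0],
            [kon, -koff, 0.0, 0.0],
            [0.0, 0.0, 0.0, 0.0],
            [0.0, 0.0, 0.0, 0.0],
        ])
    elif regime == "post":
        a = params.alpha * kon
        A = np.array([
            [-2 * a, koff, koff, 0.0],
            [a, -a - koff, 0.0, koff],
            [a, 0.0, -a - koff, koff],
            [0.0, a, a, -2 * koff],
        ])
    else:
        raise ValueError(f"regime must be 'pre' or 'post', got {regime!r}")
    T = np.diag([0.0, kini, kini, 2 * kini])
    D = kd * np.eye(4)
    return A, T, D


@dataclass
class GeneratorSpec:
    """Assembled CME generator for one time regime."""

    Q: sparse.csr_matrix
    A: np.ndarray
    T: np.ndarray
    D: np.ndarray
    mmax: int
    dt: float
    regime: str


def build_generator(params: KineticParams, regime: str, mmax: int,
                    dt: float = DEFAULT_DT) -> GeneratorSpec:
    """Assemble the block-tridiagonal generator Q for the given regime."""
    if mmax < 1:
        raise ValueError("mmax must be >= 1")
    if params.alpha <= 0:
        raise ValueError("alpha must be positive")
    A, T, D = _blocks(params, regime)
    M = mmax + 1
    mvec = np.arange(M, dtype=float)
    Q = (sparse.kron(sparse.eye(M), A - T, format="csr")
         - sparse.kron(sparse.diags(mvec), D, format="csr")
         + sparse.kron(sparse.diags(mvec[1:], 1), D, format="csr")
         + sparse.kron(sparse.diags(np.ones(M - 1), -1), T, format="csr"))
    return GeneratorSpec(Q=Q.tocsr(), A=A, T=T, D=D, mmax=mmax, dt=dt, regime=regime)


@njit(cache=True)
def _step_discrete(data, indices, indptr, P, dt, n_steps):
    N = P.shape[0]
    cur = P.copy()
    nxt = np.empty(N)
    for _ in range(n_steps):
        for i in range(N):
            acc = 0.0
            for k in range(indptr[i], indptr[i + 1]):
                acc += data[k] * cur[indices[k]]
            nxt[i] = cur[i] + dt * acc
        tmp = cur
        cur = nxt
        nxt = tmp
    return cur


def _expm_uniform(Q: sparse.csr_matrix, P: np.ndarray, t: float,
                  tol: float = 1e-12) -> np.ndarray:
    """exp(Q t) P by uniformization (Poissonization).

    With lam = max exit rate, A = I + Q/lam is substochastic and
    exp(Qt) P = sum_k Pois(lam t){k} A^k P.  Time is chunked so the Poisson
    weights never underflow; the result is nonnegative by construction.
    """
    lam = float(-Q.diagonal().min())
    if lam * t <= 0:
        return P.copy()
    A = sparse.eye(Q.shape[0], format="csr") + Q * (1.0 / lam)
    n_chunks = max(1, int(math.ceil(lam * t / 300.0)))
    dt = t / n_chunks
    mu = lam * dt
    v = np.asarray(P, dtype=np.float64)
    for _ in range(n_chunks):
        w = math.exp(-mu)
        term = v
        out = w * term
        acc = w
        k = 0
        while acc < 1.0 - tol and k < 100_000:
            k += 1
            term = A @ term
            w *= mu / k
            out += w * term
            acc += w
        v = out
    return v


def propagate(P: np.ndarray, gen: GeneratorSpec, t0: float, t1: float,
              backend: str = "discrete") -> np.ndarray:
    """Propagate the probability vector from t0 to t1 under constant Q.

    ``discrete`` applies the Euler propagator (I + Q*dt)^n with
    n = round((t1-t0)/dt); ``expm`` uses scipy's matrix-exponential action;
    ``uniform`` evaluates the same exponential by uniformization.
    """
    if t1 < t0:
        raise ValueError("t1 must be >= t0")
    if t1 == t0:
        return P.copy()
    if backend == "expm":
        out = expm_multiply(gen.Q * (t1 - t0), P)
    elif backend == "uniform":
        out = _expm_uniform(gen.Q, P, t1 - t0)
    elif backend == "discrete":
        n_steps = int(round((t1 - t0) / gen.dt))
        out = _step_discrete(gen.Q.data, gen.Q.indices, gen.Q.indptr,
                             np.asarray(P, dtype=np.float64), gen.dt, n_steps)
    else:
        raise ValueError(f"unknown backend {backend!r}")
    if out.min() < -1e-12:
        raise FloatingPointError(
            f"negative probability {out.min():.3e} during propagation; "
            "decrease dt or increase mmax")
    return out


def replication_operator(mmax: int) -> sparse.csr_matrix:
    """R: the replicated slot inherits slot 1's state, (s1, s2) -> (s1, s1)."""
    Rm = np.zeros((4, 4))
    Rm[0, 0] = Rm[0, 2] = 1.0  # OFF parent -> (OFF, OFF)
    Rm[3, 1] = Rm[3, 3] = 1.0  # ON parent  -> (ON, ON)
    return sparse.kron(sparse.eye(mmax + 1), Rm, format="csr")


def apply_replication(P: np.ndarray) -> np.ndarray:
    """Copy slot 1's gene state onto slot 2 at the replication time."""
    W = P.reshape(-1, 4).copy()
    out = np.zeros_like(W)
    out[:, 0] = W[:, 0] + W[:, 2]
    out[:, 3] = W[:, 1] + W[:, 3]
    return out.reshape(-1)


def state_collapse_operator(mmax: int) -> sparse.csr_matrix:
    """V: reset the second slot OFF at division, (s1, s2) -> (s1, OFF)."""
    Vm = np.zeros((4, 4))
    Vm[0, 0] = Vm[0, 2] = 1.0
    Vm[1, 1] = Vm[1, 3] = 1.0
    return sparse.kron(sparse.eye(mmax + 1), Vm, format="csr")


def division_operator(mmax: int) -> sparse.csr_matrix:
    """B: binomial thinning kernel B[m, k] = C(k, m) 2^-k acting on mRNA."""
    M = mmax + 1
    rows, cols, vals = [], [], []
    k = np.arange(M)
    for m in range(M):
        kk = k[m:]
        logp = gammaln(kk + 1) - gammaln(m + 1) - gammaln(kk - m + 1) - kk * math.log(2)
        rows.append(np.full(len(kk), m))
        cols.append(kk)
        vals.append(np.exp(logp))
    Bm = sparse.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(M, M))
    return sparse.kron(Bm, sparse.eye(4), format="csr")


def apply_division(P: np.ndarray, B: sparse.csr_matrix | None = None) -> np.ndarray:
    """Binomially partition the mRNA and reset slot 2 OFF (operators B then V)."""
    mmax = P.shape[0] // 4 - 1
    if B is None:
        B = division_operator(mmax)
    V = state_collapse_operator(mmax)
    return B @ (V @ P)


@dataclass
class DistributionGrid:
    """Cyclostationary single-locus solution recorded at evenly spaced times.

    ``locus_P[:, j]`` is the full FSP state vector at ``times[j]``;
    ``mature_locus[m, j]`` its mRNA marginal.  Cell-level distributions
    (two independent loci) come from autoconvolution.
    """

    times: np.ndarray
    locus_P: np.ndarray
    mmax: int
    trep: float
    tdiv: float
    residuals: list = field(default_factory=list)
    leak: float = 0.0

    @property
    def mature_locus(self) -> np.ndarray:
        return self.locus_P.reshape(self.mmax + 1, 4, -1).sum(axis=1)

    def mature_cell(self) -> np.ndarray:
        """P(total mature | t_j) for a diploid cell: one autoconvolution."""
        cols = [convolve_copies(self.mature_locus[:, j], 2)
                for j in range(len(self.times))]
        n = max(len(c) for c in cols)
        out = np.zeros((n, len(self.times)))
        for j, c in enumerate(cols):
            out[: len(c), j] = c
        return out

    def save(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as fh:
            fh["times"] = self.times
            fh["locus_P"] = self.locus_P
            fh.attrs["mmax"] = self.mmax
            fh.attrs["trep"] = self.trep
            fh.attrs["tdiv"] = self.tdiv

    @classmethod
    def load(cls, path) -> "DistributionGrid":
        import h5py

        with h5py.File(path, "r") as fh:
            return cls(times=fh["times"][:], locus_P=fh["locus_P"][:],
                       mmax=int(fh.attrs["mmax"]), trep=float(fh.attrs["trep"]),
                       tdiv=float(fh.attrs["tdiv"]))


def record_times(tdiv: float, n: int = N_TIMEPOINTS) -> np.ndarray:
    """The n evenly spaced recording times, at window midpoints (j+1/2)*tdiv/n."""
    return (np.arange(n) + 0.5) * tdiv / n


def suggest_mmax(params: KineticParams, cap: int = 1500) -> int:
    """Truncation keeping the terminal-state mass negligible.

    Uses the post-replication locus mean (two copies) with the telegraph
    Fano factor 1 + kini*koff/((kon+koff)(kon+koff+kd)) as variance margin:
    mmax = mean + 8*sd + 20.
    """
    duty = max(params.duty_pre, params.duty_post)
    mean = 2.0 * duty * params.kini / max(params.kd, 1e-12)
    s = params.kon + params.koff
    fano = 1.0 + params.kini * params.koff / max(s * (s + params.kd), 1e-12)
    m = mean + 10.0 * math.sqrt(max(mean, 1.0) * fano) + 20
    return int(min(max(m, 30), cap))


def solve_cyclostationary(params: KineticParams, mmax: int | None = None,
                          dt: float = DEFAULT_DT, backend: str = "discrete",
                          n_timepoints: int = N_TIMEPOINTS, tol: float = 1e-6,
                          max_cycles: int = 200) -> DistributionGrid:
    """Iterate whole cell cycles until the start-of-cycle vector is periodic.

    Each cycle: propagate to trep, apply R, propagate to tdiv, apply B and
    V.  Convergence: L1 difference between successive start vectors < tol.
    A final recorded pass samples P(t) at ``n_timepoints`` evenly spaced
    times.
    """
    if mmax is None:
        mmax = suggest_mmax(params)
    gen_pre = build_generator(params, "pre", mmax, dt)
    gen_post = build_generator(params, "post", mmax, dt)
    B = division_operator(mmax)
    N = 4 * (mmax + 1)
    P0 = np.zeros(N)
    P0[0] = 1.0
    residuals = []

    def segment(P, gen, t0, t1, rec, recorder, offset):
        """Propagate t0 -> t1 recording at rec (sorted, inside [t0, t1])."""
        if len(rec) == 0:
            return propagate(P, gen, t0, t1, backend)
        if backend == "expm" and len(rec) >= 2:
            steps = np.diff(rec)
            if np.allclose(steps, steps[0]):
                # one scaling pass for the whole evenly spaced record grid
                out = expm_multiply(gen.Q, P, start=rec[0] - t0,
                                    stop=rec[-1] - t0, num=len(rec),
                                    endpoint=True)
                for j in range(len(rec)):
                    recorder(offset + j, out[j])
                return propagate(out[-1], gen, rec[-1], t1, backend)
        t = t0
        for j, tr in enumerate(rec):
            P = propagate(P, gen, t, tr, backend)
            recorder(offset + j, P)
            t = tr
        return propagate(P, gen, t, t1, backend)

    def one_cycle(P, rec_ts=None, recorder=None):
        if rec_ts is None:
            rec_pre = rec_post = np.empty(0)
            n_pre = 0
        else:
            rec_pre = rec_ts[rec_ts < params.trep]
            rec_post = rec_ts[rec_ts >= params.trep]
            n_pre = len(rec_pre)
        P = segment(P, gen_pre, 0.0, params.trep, rec_pre, recorder, 0)
        P = apply_replication(P)
        P = segment(P, gen_post, params.trep, params.tdiv, rec_post, recorder, n_pre)
        return apply_division(P, B)

    converged = False
    for _ in range(max_cycles):
        P1 = one_cycle(P0)
        # renormalise between fixed-point iterations so that truncation
        # leakage does not mask convergence of the distribution itself
        P1 = P1 / P1.sum()
        res = np.abs(P1 - P0).sum()
        residuals.append(res)
        P0 = P1
        if res < tol:
            converged = True
            break
    if not converged:
        raise RuntimeError(
            f"no cyclostationary convergence in {max_cycles} cycles; "
            f"residual history tail: {residuals[-5:]}")

    ts = record_times(params.tdiv, n_timepoints)
    out = np.zeros((N, n_timepoints))

    def rec(j, P):
        out[:, j] = P

    one_cycle(P0, rec_ts=ts, recorder=rec)
    leak = float(np.max(1.0 - out.sum(axis=0)))
    if leak > 1e-6:
        warnings.warn(
            f"FSP leakage {leak:.2e} exceeds 1e-6; increase mmax", stacklevel=2)
    return DistributionGrid(times=ts, locus_P=out, mmax=mmax, trep=params.trep,
                            tdiv=params.tdiv, residuals=residuals, leak=leak)


def solve_stationary(params: KineticParams, mmax: int, regime: str = "pre") -> np.ndarray:
    """Stationary FSP solution with the cell cycle disabled (Q P = 0, sum P = 1)."""
    gen = build_generator(params, regime, mmax)
    Q = gen.Q.tolil()
    Q[0, :] = 1.0
    b = np.zeros(Q.shape[0])
    b[0] = 1.0
    P = spsolve(Q.tocsc(), b)
    P = np.maximum(P, 0.0)
    return P / P.sum()


# ---------------------------------------------------------------------------
# nascent mRNA distribution (deterministic residence window)


@njit(cache=True)
def _nascent_paths(kon, koff, kini, tres, probes, n_paths, seed, counts,
                   n_copies):
    """Monte Carlo over the trailing residence window of gene copies.

    The gene state of each copy at the window start is drawn from the
    stationary telegraph marginal for the regime's activation rate;
    initiations are an inhomogeneous (state-gated) Poisson process; a
    transcript initiated at u contributes its elongated fraction
    (tres-u)/tres (or the fraction of probe positions already
    transcribed); the signal summed over ``n_copies`` independent copies
    is rounded to the nearest integer, .5 up.
    """
    np.random.seed(seed)
    nmax = len(counts) - 1
    p_on = kon / (kon + koff) if kon + koff > 0 else 0.0
    n_pr = len(probes)
    for _ in range(n_paths):
        sig = 0.0
        for _c in range(n_copies):
            s = 1 if np.random.random() < p_on else 0
            t = 0.0
            while t < tres:
                rate = koff if s == 1 else kon
                if rate > 0.0:
                    t_next = t + np.random.exponential(1.0 / rate)
                else:
                    t_next = tres
                if t_next > tres:
                    t_next = tres
                if s == 1 and kini > 0.0:
                    n_ini = np.random.poisson(kini * (t_next - t))
                    for _k in range(n_ini):
                        u = t + np.random.random() * (t_next - t)
                        f = (tres - u) / tres
                        if n_pr > 0:
                            c = 0
                            for q in range(n_pr):
                                if probes[q] <= f:
                                    c += 1
                            sig += c / n_pr
                        else:
                            sig += f
                t = t_next
                if t < tres:
                    s = 1 - s
        k = int(math.floor(sig + 0.5))
        if k > nmax:
            k = nmax
        counts[k] += 1


def nascent_mean(params: KineticParams, regime: str = "pre") -> float:
    """Closed-form mean nascent signal per gene copy: lam*duty*kini*tres."""
    duty = params.duty_pre if regime == "pre" else params.duty_post
    return params.lam * duty * params.kini * params.tres


def _nascent_pmf(params: KineticParams, regime: str, n_paths: int, seed: int,
                 probe_positions=None, n_copies: int = 1) -> np.ndarray:
    """pmf of the integer-rounded nascent signal of ``n_copies`` copies.

    With n_copies > 1 the continuous signals are summed before rounding,
    matching per-cell observed totals; autoconvolution of the 1-copy pmf
    instead rounds each copy first.
    """
    kon = params.kon if regime == "pre" else params.alpha * params.kon
    lam_mean = n_copies * params.kini * params.tres
    nmax = int(lam_mean + 10 * math.sqrt(max(lam_mean, 1.0)) + 10)
    counts = np.zeros(nmax + 1, dtype=np.int64)
    probes = (np.sort(np.asarray(probe_positions, dtype=float))
              if probe_positions is not None else np.empty(0))
    _nascent_paths(kon, params.koff, params.kini, params.tres, probes,
                   n_paths, int(seed) % (2**31 - 1), counts, n_copies)
    return counts / counts.sum()


def nascent_distribution(params: KineticParams, t_grid=None,
                         n_paths: int = 200_000, seed: int = 0,
                         probe_positions=None) -> np.ndarray:
    """Per-copy integer nascent-signal distribution at each time of t_grid.

    The residence window is short compared to the cell cycle, so within a
    regime the nascent distribution is taken at its (regime-wise)
    steady state; only the activation rate differs before/after trep.
    Columns of the returned (nmax+1, len(t_grid)) array are pmfs.
    """
    if params.tres > 0.1 * params.tdiv:
        warnings.warn("tres is not small compared to tdiv; the steady-state "
                      "nascent approximation degrades", stacklevel=2)
    if t_grid is None:
        t_grid = record_times(params.tdiv)
    t_grid = np.atleast_1d(np.asarray(t_grid, dtype=float))
    pre = _nascent_pmf(params, "pre", n_paths, seed, probe_positions)
    post = _nascent_pmf(params, "post", n_paths, seed + 1, probe_positions)
    n = max(len(pre), len(post))
    out = np.zeros((n, len(t_grid)))
    for j, t in enumerate(t_grid):
        pmf = pre if t < params.trep else post
        out[: len(pmf), j] = pmf
    return out


def convolve_copies(dist: np.ndarray, n_fold: int, mmax: int | None = None) -> np.ndarray:
    """Distribution of a sum of independent copies by autoconvolution.

    One autoconvolution for 2 copies; two successive autoconvolutions for
    4.  If ``mmax`` truncates the support, lost mass > 1e-6 triggers a
    renormalisation warning.
    """
    if n_fold not in (2, 4):
        raise ValueError("n_fold must be 2 or 4")
    out = np.convolve(dist, dist)
    if n_fold == 4:
        out = np.convolve(out, out)
    if mmax is not None and len(out) > mmax + 1:
        lost = out[mmax + 1:].sum()
        out = out[: mmax + 1]
        if lost > 1e-6:
            warnings.warn(f"autoconvolution truncated {lost:.2e} mass; renormalising",
                          stacklevel=2)
            out = out / out.sum()
    return out
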