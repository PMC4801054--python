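"""Cell-cycle deconvolution from DNA content.

The DNA-content histogram of an asynchronous population is fitted with the
Fried/Baisch five-Gaussian mixture: component i has mean ``alpha_i * mu``
with ``alpha_i = (i+3)/4`` and standard deviation ``alpha_i * sigma``
(equal coefficients of variation).  Component 1 is G1, components 2-4 are
S, component 5 is G2/M.  The fitted mixture CDF F(x) is then turned into a
time within the cell cycle by ergodic rate analysis,

    t(x) = tdiv * log2(2 / (2 - F(x))),

valid for an exponentially growing population whose age density is
p(a) = (2 ln2 / tdiv) 2^(-a/tdiv).  Finally, the nascent signal versus time
is fitted with a two-level step, n(t) = 2*beta for t < trep and
4*eta*beta for t >= trep, yielding the locus replication time trep and the
per-copy dosage-compensation fold eta (total fold change 2*eta).
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator

__all__ = [
    "FriedBaischModel",
    "ReplicationStepModel",
    "FitConvergenceError",
    "fit_dna_histogram",
    "classify_phase",
    "era_transform",
    "fit_replication_step",
    "alpha_from_eta",
    "eta_from_alpha",
    "nascent_fold_change",
]

ALPHA_I = (np.arange(1, 6) + 3) / 4.0  # component mean multipliers
PHASES = np.array(["G1", "S", "G2M"])


class FitConvergenceError(RuntimeError):
    """Mixture fit failed; carries the best attempt found."""

    def __init__(self, message, best=None):
        super().__init__(message)
        self.best = best


def _freedman_diaconis_bins(x: np.ndarray) -> int:
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    if iqr <= 0:
        return 50
    width = 2.0 * iqr / len(x) ** (1.0 / 3.0)
    return max(10, int(np.ceil((x.max() - x.min()) / width)))


class FriedBaischModel(BaseEstimator):
    """Five-Gaussian cell-cycle mixture fitted to a DNA-content sample.

    Parameters
    ----------
    bins : int or None
        Histogram bins for the least-squares fit; Freedman-Diaconis if None.
    cv_init : float
        Initial guess for sigma/mu.
    n_starts : int
        Multi-start attempts (mu initialised at the histogram mode and at
        percentiles of the sample).

    Attributes (after fit)
    ----------------------
    mu_, sigma_ : G1 component mean and standard deviation.
    amplitudes_ : heights A1..A5 of the five components.
    weights_ : area fractions of the five components (sum to 1).
    phase_fractions_ : (G1, S, G2M) area fractions.
    gates_ : (mu_+sigma_, 2*mu_) phase gates.
    """

    def __init__(self, bins=None, cv_init: float = 0.05, n_starts: int = 6):
        self.bins = bins
        self.cv_init = cv_init
        self.n_starts = n_starts

    # -- mixture evaluation ------------------------------------------------
    @staticmethod
    def _heights(x, mu, sigma, amps):
        x = np.asarray(x, dtype=float)[..., None]
        means = ALPHA_I * mu
        sds = ALPHA_I * sigma
        return np.sum(amps * np.exp(-0.5 * ((x - means) / sds) ** 2), axis=-1)

    def pdf(self, x):
        """Fitted mixture density, normalised to unit area."""
        self._check_fitted()
        norm = np.sum(self.amplitudes_ * ALPHA_I * self.sigma_) * np.sqrt(2 * np.pi)
        return self._heights(x, self.mu_, self.sigma_, self.amplitudes_) / norm

    def cdf(self, x):
        """CDF of the fitted mixture (analytic sum of component CDFs)."""
        self._check_fitted()
        x = np.asarray(x, dtype=float)[..., None]
        z = (x - ALPHA_I * self.mu_) / (ALPHA_I * self.sigma_)
        return np.clip(np.sum(self.weights_ * stats.norm.cdf(z), axis=-1), 0.0, 1.0)

    # -- fitting -----------------------------------------------------------
    def fit(self, X, y=None):
        x = np.asarray(X, dtype=float).ravel()
        if np.any(x <= 0):
            raise ValueError("DNA contents must be positive")
        if len(x) < 100:
            warnings.warn(
                f"only {len(x)} cells; the mixture fit is unreliable below ~100",
                stacklevel=2)
        nbins = self.bins or _freedman_diaconis_bins(x)
        counts, edges = np.histogram(x, bins=nbins)
        # extend with empty bins so components up to 2*mu stay constrained
        # even when the sample does not reach them (e.g. a pure-G1 sample)
        width = edges[1] - edges[0]
        mode0 = 0.5 * (edges[np.argmax(counts)] + edges[np.argmax(counts) + 1])
        upper = 2.3 * mode0
        if edges[-1] < upper:
            extra = int(np.ceil((upper - edges[-1]) / width))
            edges = np.concatenate([edges, edges[-1] + width * np.arange(1, extra + 1)])
            counts = np.concatenate([counts, np.zeros(extra, dtype=counts.dtype)])
        centers = 0.5 * (edges[:-1] + edges[1:])
        w = 1.0 / np.sqrt(np.maximum(counts, 1.0))  # Poisson weighting

        def resid(theta):
            mu, sigma = theta[0], theta[1]
            amps = theta[2:]
            return (self._heights(centers, mu, sigma, amps) - counts) * w

        mode = centers[np.argmax(counts)]
        mu_starts = [mode] + list(np.percentile(x, np.linspace(20, 60, self.n_starts - 1)))
        best = None
        amax = counts.max() * 1.5
        for mu0 in mu_starts[: self.n_starts]:
            theta0 = np.concatenate(
                [[mu0, self.cv_init * mu0],
                 np.full(5, 0.3) * counts.max()])
            try:
                sol = optimize.least_squares(
                    resid, theta0,
                    bounds=([x.min() / 2, 1e-6 * mu0, 0, 0, 0, 0, 0],
                            [x.max(), x.max(), amax, amax, amax, amax, amax]),
                    max_nfev=2000)
            except ValueError:
                continue
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None or not np.isfinite(best.cost):
            raise FitConvergenceError("Fried/Baisch fit did not converge", best=best)
        self.mu_, self.sigma_ = float(best.x[0]), float(abs(best.x[1]))
        self.amplitudes_ = np.asarray(best.x[2:], dtype=float)
        areas = self.amplitudes_ * ALPHA_I  # * sigma*sqrt(2pi) cancels
        total = areas.sum()
        if total <= 0:
            raise FitConvergenceError("degenerate fit: all amplitudes zero", best=best)
        self.weights_ = areas / total
        self.phase_fractions_ = np.array([
            self.weights_[0], self.weights_[1:4].sum(), self.weights_[4]])
        self.gates_ = (self.mu_ + self.sigma_, 2.0 * self.mu_)
        self.n_cells_ = len(x)
        return self

    def _check_fitted(self):
        if not hasattr(self, "mu_"):
            raise RuntimeError("model is not fitted")

    # -- downstream --------------------------------------------------------
    def predict(self, X):
        """Phase labels by DNA-content gating: G1 below mu+sigma, G2M above 2mu."""
        self._check_fitted()
        x = np.asarray(X, dtype=float)
        idx = np.ones(x.shape, dtype=int)  # S
        idx[x < self.gates_[0]] = 0
        idx[x > self.gates_[1]] = 2
        return PHASES[idx]

    def era_time(self, X, tdiv: float):
        """Ergodic-rate-analysis time in the cycle for DNA contents X."""
        self._check_fitted()
        F = self.cdf(X)
        return tdiv * np.log2(2.0 / (2.0 - F))

    def report(self) -> dict:
        self._check_fitted()
        return {
            "mu": self.mu_,
            "sigma": self.sigma_,
            "amplitudes": self.amplitudes_.tolist(),
            "phase_fractions": dict(zip(PHASES.tolist(), self.phase_fractions_.round(6).tolist())),
            "gates": {"g1_upper": self.gates_[0], "g2_lower": self.gates_[1]},
            "n_cells": self.n_cells_,
        }


class ReplicationStepModel(BaseEstimator):
    """Two-level step fit of total nascent signal versus cell-cycle time.

    Nascent totals are smoothed with an ``n_neighbors``-nearest running mean
    in time, then fitted by least squares to n(t) = 2*beta (t < trep),
    4*eta*beta (t >= trep); trep is searched over the observed times, ties
    broken toward the earlier time.
    """

    def __init__(self, n_neighbors: int = 50):
        self.n_neighbors = n_neighbors

    @staticmethod
    def _smooth(t_sorted, y_sorted, k):
        n = len(t_sorted)
        k = min(k, n)
        if k <= 1:
            return y_sorted.copy()
        csum = np.concatenate([[0.0], np.cumsum(y_sorted)])
        out = np.empty(n)
        for i in range(n):
            lo = min(max(i - (k - 1) // 2, 0), n - k)
            # slide window toward the true k nearest neighbours in time
            while lo > 0 and t_sorted[i] - t_sorted[lo - 1] < t_sorted[lo + k - 1] - t_sorted[i]:
                lo -= 1
            while lo + k < n and t_sorted[lo + k] - t_sorted[i] < t_sorted[i] - t_sorted[lo]:
                lo += 1
            out[i] = (csum[lo + k] - csum[lo]) / k
        return out

    def fit(self, X, y):
        t = np.asarray(X, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        if len(t) != len(y):
            raise ValueError("times and nascent totals differ in length")
        if len(t) < 2:
            raise ValueError("need at least two cells for the step fit")
        if np.allclose(y, 0):
            raise ValueError("all nascent totals are zero; eta is undefined")
        order = np.argsort(t, kind="stable")
        ts, ys = t[order], y[order]
        sm = self._smooth(ts, ys, self.n_neighbors)
        csum = np.concatenate([[0.0], np.cumsum(sm)])
        csum2 = np.concatenate([[0.0], np.cumsum(sm**2)])
        n = len(sm)
        best = (np.inf, None)
        # candidate trep between each pair of consecutive observed times
        for i in range(1, n):
            m1 = csum[i] / i
            m2 = (csum[n] - csum[i]) / (n - i)
            sse = (csum2[n]
                   - 2 * (m1 * csum[i] + m2 * (csum[n] - csum[i]))
                   + i * m1**2 + (n - i) * m2**2)
            if sse < best[0] - 1e-12:
                best = (sse, i)
        i = best[1]
        pre_mean = csum[i] / i
        post_mean = (csum[n] - csum[i]) / (n - i)
        if pre_mean <= 0:
            raise ValueError("pre-replication mean signal is zero; eta is undefined")
        self.tau_rep_ = float(ts[i])
        self.beta_ = float(pre_mean / 2.0)
        self.eta_ = float(post_mean / (4.0 * self.beta_))
        self.fold_change_ = 2.0 * self.eta_
        self.sse_ = float(best[0])
        self.smoothed_ = sm
        self.times_ = ts
        return self

    def report(self) -> dict:
        return {"beta": self.beta_, "tau_rep": self.tau_rep_,
                "eta": self.eta_, "fold_change": self.fold_change_}


# ---------------------------------------------------------------------------
# functional wrappers


def fit_dna_histogram(dna_contents, **kwargs) -> FriedBaischModel:
    """Fit the five-Gaussian cell-cycle mixture to a DNA-content sample."""
    return FriedBaischModel(**kwargs).fit(dna_contents)


def classify_phase(x, fit: FriedBaischModel):
    """G1 if x < mu+sigma, G2M if x > 2mu, else S."""
    out = fit.predict(np.atleast_1d(x))
    return out[0] if np.isscalar(x) else out


def era_transform(x, fit: FriedBaischModel, tdiv: float):
    """Map DNA content to time within the cycle, t = tdiv*log2(2/(2-F(x)))."""
    out = fit.era_time(np.atleast_1d(x), tdiv)
    return float(out[0]) if np.isscalar(x) else out


def fit_replication_step(times, nascent_totals, n_neighbors: int = 50) -> ReplicationStepModel:
    """Smooth and step-fit nascent totals; returns the fitted model."""
    return ReplicationStepModel(n_neighbors=n_neighbors).fit(times, nascent_totals)


def alpha_from_eta(eta: float, kon: float, koff: float) -> float:
    """Activation-rate fold alpha producing a per-copy nascent fold eta.

    alpha = eta*koff / ((1-eta)*kon + koff); diverges as eta approaches
    (kon+koff)/kon, beyond which no finite alpha can produce the fold.
    """
    if kon <= 0 or koff <= 0:
        raise ValueError("kon and koff must be positive")
    denom = (1.0 - eta) * kon + koff
    if denom <= 0:
        raise ValueError(
            f"eta={eta} >= (kon+koff)/kon={(kon + koff) / kon:.4g}: alpha undefined")
    return eta * koff / denom


def eta_from_alpha(alpha: float, kon: float, koff: float) -> float:
    """Per-copy nascent fold eta for an activation-rate fold alpha."""
    if kon <= 0 or koff <= 0:
        raise ValueError("kon and koff must be positive")
    return alpha * (kon + koff) / (alpha * kon + koff)


def nascent_fold_change(alpha: float, kon: float, koff: float) -> float:
    """Total nascent fold change after replication, 2*eta (copy doubling x duty)."""
    return 2.0 * eta_from_alpha(alpha, kon, koff)
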