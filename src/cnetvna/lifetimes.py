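"""Per-molecule lifetime extraction from photon streams.

The chain is: bin the macro-times into an intensity trace, detect
photobleaching steps by Poisson changepoint segmentation, keep only molecules
with a single downward step, histogram the pre-bleach micro-times into a TCSPC
decay curve, and fit a monoexponential decay reconvolved with a Gaussian
instrument response (IRF) plus a flat background floor.

The decay model per TCSPC bin is the bin-integrated, periodically wrapped
exponentially-modified Gaussian (the analytic convolution of an exponential
with a Gaussian IRF), mixed with a uniform background:

    q_i = (1 - b) * P_i(tau, t0; sigma) / sum_j P_j  +  b / n_bins

The default estimator maximizes the Poisson/multinomial likelihood of the bin
counts over (tau, b, t0); a Neyman-weighted least-squares mode is provided as
a cross-check.  Standard errors come from the observed-information diagonal.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares, minimize
from scipy.special import log_ndtr, ndtr
from sklearn.base import BaseEstimator

from cnetvna.synthdata import PhotonStream

__all__ = [
    "IntensityTrace",
    "DecayCurve",
    "LifetimeFit",
    "MoleculeRecord",
    "BleachAnalysis",
    "bin_trace",
    "detect_bleach_steps",
    "classify_bleach",
    "build_decay",
    "fit_monoexponential",
    "MonoexponentialFitter",
    "analyze_stream",
    "analyze_cohort",
]

MIN_PHOTONS_DEFAULT = 100
TAU_BOUNDS_FACTOR = 2.0   # upper tau bound = 2 * TCSPC window
TAU_LOWER_BOUND = 0.02    # ns


@dataclass
class IntensityTrace:
    bin_edges: np.ndarray  # seconds, uniform
    counts: np.ndarray     # photons per bin

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts)
        if self.counts.size != self.bin_edges.size - 1:
            raise ValueError("need len(counts) == len(bin_edges) - 1")
        if self.counts.size and self.counts.min() < 0:
            raise ValueError("counts must be non-negative")

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])


@dataclass
class DecayCurve:
    bin_edges: np.ndarray  # ns over [0, tcspc_window)
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts)
        if self.counts.size != self.bin_edges.size - 1:
            raise ValueError("need len(counts) == len(bin_edges) - 1")
        widths = np.diff(self.bin_edges)
        if not np.allclose(widths, widths[0]):
            raise ValueError("decay bins must be uniform")

    @property
    def window(self) -> float:
        return float(self.bin_edges[-1] - self.bin_edges[0])

    @property
    def n_photons(self) -> int:
        return int(self.counts.sum())


@dataclass
class LifetimeFit:
    tau: float
    tau_se: float
    background_fraction: float
    irf_sigma: float
    log_likelihood: float
    n_photons: int
    converged: bool
    t0: float = 0.0
    pinned: bool = False


@dataclass
class MoleculeRecord:
    molecule_id: str
    n_steps: int
    accepted: bool
    fit: LifetimeFit | None = None
    reject_reason: str | None = None

    def __post_init__(self) -> None:
        if self.accepted and (
            self.n_steps != 1 or self.fit is None or not self.fit.converged
        ):
            raise ValueError(
                "accepted records require a single bleach step and a converged fit"
            )


@dataclass
class BleachAnalysis:
    changepoints: list[int]   # bin index of the first bin after each change
    n_steps: int              # number of downward changepoints
    bleach_time: float | None # seconds; time of the step down to background


def bin_trace(stream: PhotonStream, bin_width: float = 0.01) -> IntensityTrace:
    """Bin macro-times into an intensity trace; the last partial bin is dropped."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if stream.n_photons == 0:
        warnings.warn("empty photon stream: returning a single zero bin", stacklevel=2)
        return IntensityTrace(np.array([0.0, bin_width]), np.array([0]))
    t_max = stream.macro_times.max()
    n_bins = int(math.floor(t_max / bin_width))
    if n_bins < 1:
        warnings.warn(
            "bin_width exceeds the stream duration: returning a single zero bin",
            stacklevel=2,
        )
        return IntensityTrace(np.array([0.0, bin_width]), np.array([0]))
    edges = np.arange(n_bins + 1) * bin_width
    # half-open [lo, hi) bins: an event exactly at the last edge belongs to
    # the dropped partial bin
    counts, _ = np.histogram(stream.macro_times[stream.macro_times < edges[-1]],
                             bins=edges)
    return IntensityTrace(edges, counts)


def _poisson_segment_ll(cum: np.ndarray, lo: int, hi: int) -> float:
    # max Poisson log-likelihood of counts[lo:hi] under one rate (constants dropped)
    c = cum[hi] - cum[lo]
    n = hi - lo
    return float(c * math.log(c / n)) if c > 0 else 0.0


def detect_bleach_steps(trace: IntensityTrace, penalty: float | None = None) -> list[int]:
    """Changepoints in a Poisson count trace by recursive binary segmentation.

    At each stage the split maximizing the two-segment Poisson log-likelihood
    gain is accepted while the gain exceeds `penalty` (default 3 ln n_bins, a
    BIC-like cost).  Returns sorted bin indices: index i means the rate
    changes between bins i-1 and i.
    """
    counts = np.asarray(trace.counts, dtype=float)
    n = counts.size
    if n == 0:
        raise ValueError("trace must be non-empty")
    if penalty is None:
        penalty = 3.0 * math.log(max(n, 2))
    cum = np.concatenate([[0.0], np.cumsum(counts)])
    out: list[int] = []

    def best_split(lo: int, hi: int) -> tuple[float, int]:
        # vectorized scan of split points within [lo, hi)
        if hi - lo < 2:
            return -math.inf, -1
        ks = np.arange(lo + 1, hi)
        c1 = cum[ks] - cum[lo]
        c2 = cum[hi] - cum[ks]
        n1 = ks - lo
        n2 = hi - ks
        with np.errstate(divide="ignore", invalid="ignore"):
            ll1 = np.where(c1 > 0, c1 * np.log(c1 / n1), 0.0)
            ll2 = np.where(c2 > 0, c2 * np.log(c2 / n2), 0.0)
        gain = ll1 + ll2 - _poisson_segment_ll(cum, lo, hi)
        i = int(np.argmax(gain))
        return float(gain[i]), int(ks[i])

    def recurse(lo: int, hi: int) -> None:
        gain, k = best_split(lo, hi)
        if gain > penalty:
            out.append(k)
            recurse(lo, k)
            recurse(k, hi)

    recurse(0, n)
    return sorted(out)


def _merge_transition_bins(counts: np.ndarray, cps: list[int]) -> list[int]:
    # collapse a <=1-bin segment whose mean lies between its neighbours'
    # means (a bin-edge quantization artifact of a single step)
    n = counts.size
    changed = True
    while changed and len(cps) >= 2:
        changed = False
        for i in range(len(cps) - 1):
            k1, k2 = cps[i], cps[i + 1]
            if k2 - k1 > 1:
                continue
            lo = cps[i - 1] if i > 0 else 0
            hi = cps[i + 2] if i + 2 < len(cps) else n
            m_left = counts[lo:k1].mean()
            m_mid = counts[k1:k2].mean()
            m_right = counts[k2:hi].mean()
            if m_left >= m_mid >= m_right or m_left <= m_mid <= m_right:
                del cps[i + 1]
                changed = True
                break
    return cps


def classify_bleach(
    trace: IntensityTrace, changepoints: Sequence[int] | None = None,
    penalty: float | None = None,
) -> BleachAnalysis:
    """Count photobleaching steps and locate the bleach time.

    A step is a downward changepoint (post-segment mean below the pre-segment
    mean).  A rate change falling inside a time bin leaves one bin at an
    intermediate count, which binary segmentation brackets with two
    changepoints; such single-bin monotone transition segments are coalesced
    into one step before counting.  The bleach time is the first downward
    changepoint whose post-segment mean is statistically consistent with the
    background level estimated from the final segment.
    """
    if changepoints is None:
        changepoints = detect_bleach_steps(trace, penalty)
    counts = np.asarray(trace.counts, dtype=float)
    changepoints = _merge_transition_bins(counts, list(changepoints))
    bounds = [0, *changepoints, counts.size]
    seg_means = np.array(
        [counts[a:b].mean() for a, b in zip(bounds[:-1], bounds[1:])]
    )
    seg_lens = np.diff(bounds)
    down = [i for i in range(len(changepoints)) if seg_means[i + 1] < seg_means[i]]
    n_steps = len(down)
    bleach_time: float | None = None
    if down:
        bg_mean, bg_len = seg_means[-1], seg_lens[-1]
        for i in down:
            m, ln = seg_means[i + 1], seg_lens[i + 1]
            tol = 3.0 * math.sqrt(max(bg_mean, 1.0) / ln + max(bg_mean, 1.0) / bg_len)
            if m <= bg_mean + tol:
                bleach_time = float(trace.bin_edges[changepoints[i]])
                break
        if bleach_time is None:  # no step reaches background; use the last one
            bleach_time = float(trace.bin_edges[changepoints[down[-1]]])
    return BleachAnalysis(list(changepoints), n_steps, bleach_time)


def build_decay(
    stream: PhotonStream,
    n_bins: int = 256,
    post_bleach_exclusion: bool = True,
    bleach_time: float | None = None,
    trace_bin_width: float = 0.01,
    penalty: float | None = None,
) -> DecayCurve:
    """Histogram micro-times into a TCSPC decay curve.

    With `post_bleach_exclusion` only photons arriving before the detected (or
    supplied) bleach time are used.
    """
    if n_bins < 32:
        raise ValueError("n_bins must be >= 32")
    micro = stream.micro_times
    if post_bleach_exclusion:
        if bleach_time is None:
            analysis = classify_bleach(bin_trace(stream, trace_bin_width), penalty=penalty)
            bleach_time = analysis.bleach_time
        if bleach_time is not None:
            micro = micro[stream.macro_times < bleach_time]
    edges = np.linspace(0.0, stream.tcspc_window, n_bins + 1)
    counts, _ = np.histogram(micro, bins=edges)
    return DecayCurve(edges, counts)


# ---------------------------------------------------------------------------
# decay model: wrapped exponentially-modified Gaussian


def _emg_cdf(t: np.ndarray, t0: float, sigma: float, tau: float) -> np.ndarray:
    """CDF of the exponential(tau) + Gaussian(t0, sigma) convolution.

    Evaluated in log space where the standard closed form overflows.
    """
    t = np.asarray(t, dtype=float)
    if sigma < 1e-9:
        return np.where(t > t0, -np.expm1(-(t - t0) / tau), 0.0)
    u = (t - t0) / sigma
    a = 0.5 * (sigma / tau) ** 2 - (t - t0) / tau
    return ndtr(u) - np.exp(a + log_ndtr(u - sigma / tau))


def _wrapped_bin_probs(
    edges: np.ndarray, t0: float, sigma: float, tau: float, period: float
) -> np.ndarray:
    """Probability mass per TCSPC bin of the periodically wrapped decay."""
    n_wrap = min(40, max(6, int(math.ceil(8.0 * tau / period)) + 2))
    F = np.zeros_like(edges)
    for k in range(-1, n_wrap):
        F += _emg_cdf(edges + k * period, t0, sigma, tau)
    p = np.diff(F)
    return np.clip(p, 1e-300, None)


class MonoexponentialFitter(BaseEstimator):
    """Monoexponential TCSPC decay fit with Gaussian-IRF reconvolution.

    Scikit-learn style estimator.  ``fit(X)`` takes the photon micro-times (in
    ns, shape ``(n_photons,)`` or ``(n_photons, 1)``), bins them into
    `n_bins` over ``[0, tcspc_window)`` and fits (tau, background, t0);
    :meth:`fit_decay` fits a prebinned :class:`DecayCurve` directly.

    Parameters
    ----------
    irf_sigma : Gaussian IRF width in ns (held fixed during the fit).
    fit_mode : "mle" (Poisson/multinomial likelihood, default) or "lsq"
        (Neyman-weighted least squares).
    tcspc_window : TCSPC range in ns; inferred from the data when None.
    n_bins : number of decay bins.
    min_photons : molecules with fewer photons are refused.

    Fitted attributes: ``tau_``, ``tau_se_``, ``background_fraction_``,
    ``t0_``, ``log_likelihood_``, ``n_photons_``, ``converged_``, ``pinned_``.
    """

    def __init__(
        self,
        irf_sigma: float = 0.1,
        fit_mode: str = "mle",
        tcspc_window: float | None = None,
        n_bins: int = 256,
        min_photons: int = MIN_PHOTONS_DEFAULT,
    ):
        self.irf_sigma = irf_sigma
        self.fit_mode = fit_mode
        self.tcspc_window = tcspc_window
        self.n_bins = n_bins
        self.min_photons = min_photons

    # -- model ------------------------------------------------------------
    def _bin_fractions(self, edges: np.ndarray, theta: np.ndarray, period: float) -> np.ndarray:
        tau, b, t0 = theta
        p = _wrapped_bin_probs(edges, t0, self.irf_sigma, tau, period)
        p = p / p.sum()
        return (1.0 - b) * p + b / (edges.size - 1)

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim == 2 and X.shape[1] == 1:
            X = X[:, 0]
        if X.ndim != 1:
            raise ValueError("X must be a 1d array of micro-times (ns)")
        window = self.tcspc_window
        if window is None:
            window = float(np.ceil(X.max())) if X.size else 25.0
        edges = np.linspace(0.0, window, self.n_bins + 1)
        counts, _ = np.histogram(X, bins=edges)
        return self.fit_decay(DecayCurve(edges, counts))

    def fit_decay(self, decay: DecayCurve):
        if self.irf_sigma < 0:
            raise ValueError("irf_sigma must be >= 0")
        if self.fit_mode not in ("mle", "lsq"):
            raise ValueError("fit_mode must be 'mle' or 'lsq'")
        counts = np.asarray(decay.counts, dtype=float)
        N = counts.sum()
        if N < self.min_photons:
            raise ValueError(
                f"decay has {int(N)} photons, below the minimum of {self.min_photons}"
            )
        edges = decay.bin_edges
        window = decay.window
        period = window  # wrapping convention: window == excitation period
        centers = 0.5 * (edges[:-1] + edges[1:])

        # initial values: IRF position from the peak bin, tau from the mean
        # delay past the peak, background from the tail floor
        i_peak = int(np.argmax(counts))
        t0_init = float(np.clip(centers[i_peak] - self.irf_sigma, 0.0, window / 2))
        after = centers > t0_init
        if after.sum() > 2 and counts[after].sum() > 0:
            tau_init = float(
                np.average(centers[after] - t0_init, weights=counts[after])
            )
        else:
            tau_init = 1.0
        tau_init = float(np.clip(tau_init, 2 * TAU_LOWER_BOUND, window))
        b_init = 0.05

        bounds = [
            (TAU_LOWER_BOUND, TAU_BOUNDS_FACTOR * window),
            (1e-6, 1.0 - 1e-6),
            (0.0, window / 2),
        ]
        x0 = np.array([tau_init, b_init, t0_init])

        if self.fit_mode == "mle":
            def nll(theta):
                q = self._bin_fractions(edges, theta, period)
                return -float(np.dot(counts, np.log(q)))

            res = minimize(nll, x0, method="L-BFGS-B", bounds=bounds)
            theta_hat = res.x
            success = bool(res.success)
            loglik = -float(res.fun)
            tau_se = self._tau_se_from_hessian(nll, theta_hat, bounds)
        else:
            w = 1.0 / np.sqrt(np.maximum(counts, 1.0))

            def resid(theta):
                mu = N * self._bin_fractions(edges, theta, period)
                return (counts - mu) * w

            res = least_squares(
                resid, x0,
                bounds=([b[0] for b in bounds], [b[1] for b in bounds]),
            )
            theta_hat = res.x
            success = bool(res.success)
            q = self._bin_fractions(edges, theta_hat, period)
            loglik = float(np.dot(counts, np.log(q)))
            # Gauss-Newton covariance from the weighted Jacobian
            JTJ = res.jac.T @ res.jac
            try:
                cov = np.linalg.inv(JTJ)
                tau_se = float(math.sqrt(max(cov[0, 0], 0.0)))
            except np.linalg.LinAlgError:
                tau_se = math.inf

        tau_hat, b_hat, t0_hat = (float(v) for v in theta_hat)
        pinned = (
            tau_hat <= bounds[0][0] * (1 + 1e-6)
            or tau_hat >= bounds[0][1] * (1 - 1e-6)
        )
        degenerate = b_hat > 0.95 or not np.isfinite(tau_se) or tau_se <= 0
        self.tau_ = tau_hat
        self.tau_se_ = tau_se
        self.background_fraction_ = b_hat
        self.t0_ = t0_hat
        self.log_likelihood_ = loglik
        self.n_photons_ = int(N)
        self.pinned_ = bool(pinned)
        self.converged_ = bool(success and not pinned and not degenerate)
        return self

    @staticmethod
    def _tau_se_from_hessian(nll, theta, bounds) -> float:
        # central-difference observed information; steps scaled per parameter
        k = theta.size
        h = np.maximum(1e-4 * np.abs(theta), 1e-6)
        H = np.empty((k, k))
        f0 = nll(theta)
        for i in range(k):
            for j in range(i, k):
                if i == j:
                    tp = theta.copy(); tp[i] += h[i]
                    tm = theta.copy(); tm[i] -= h[i]
                    H[i, i] = (nll(tp) - 2 * f0 + nll(tm)) / h[i] ** 2
                else:
                    tpp = theta.copy(); tpp[[i, j]] += [h[i], h[j]]
                    tpm = theta.copy(); tpm[i] += h[i]; tpm[j] -= h[j]
                    tmp = theta.copy(); tmp[i] -= h[i]; tmp[j] += h[j]
                    tmm = theta.copy(); tmm[[i, j]] -= [h[i], h[j]]
                    H[i, j] = H[j, i] = (
                        nll(tpp) - nll(tpm) - nll(tmp) + nll(tmm)
                    ) / (4 * h[i] * h[j])
        try:
            cov = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            return math.inf
        v = cov[0, 0]
        return float(math.sqrt(v)) if v > 0 else math.inf

    def to_fit(self) -> LifetimeFit:
        return LifetimeFit(
            tau=self.tau_,
            tau_se=self.tau_se_,
            background_fraction=self.background_fraction_,
            irf_sigma=self.irf_sigma,
            log_likelihood=self.log_likelihood_,
            n_photons=self.n_photons_,
            converged=self.converged_,
            t0=self.t0_,
            pinned=self.pinned_,
        )


def fit_monoexponential(
    decay: DecayCurve,
    irf_sigma: float = 0.1,
    fit_mode: str = "mle",
    min_photons: int = MIN_PHOTONS_DEFAULT,
) -> LifetimeFit:
    """Fit a monoexponential decay; thin wrapper over MonoexponentialFitter."""
    est = MonoexponentialFitter(
        irf_sigma=irf_sigma, fit_mode=fit_mode, min_photons=min_photons
    )
    est.fit_decay(decay)
    return est.to_fit()


def analyze_stream(
    stream: PhotonStream,
    irf_sigma: float = 0.1,
    fit_mode: str = "mle",
    trace_bin_width: float = 0.01,
    n_decay_bins: int = 256,
    min_photons: int = MIN_PHOTONS_DEFAULT,
    penalty: float | None = None,
) -> MoleculeRecord:
    """Full per-molecule chain: trace -> step filter -> decay -> lifetime fit.

    A molecule is accepted only when it shows exactly one photobleaching step,
    carries at least `min_photons` pre-bleach photons, and the decay fit
    converges off the parameter bounds.
    """
    trace = bin_trace(stream, trace_bin_width)
    analysis = classify_bleach(trace, penalty=penalty)
    if analysis.n_steps != 1:
        return MoleculeRecord(
            stream.molecule_id, analysis.n_steps, False,
            reject_reason=f"{analysis.n_steps} bleach steps",
        )
    decay = build_decay(
        stream, n_bins=n_decay_bins, post_bleach_exclusion=True,
        bleach_time=analysis.bleach_time,
    )
    if decay.n_photons < min_photons:
        return MoleculeRecord(
            stream.molecule_id, 1, False,
            reject_reason=f"only {decay.n_photons} pre-bleach photons",
        )
    try:
        fit = fit_monoexponential(
            decay, irf_sigma=irf_sigma, fit_mode=fit_mode, min_photons=min_photons
        )
    except ValueError as exc:
        return MoleculeRecord(stream.molecule_id, 1, False, reject_reason=str(exc))
    if not fit.converged:
        return MoleculeRecord(
            stream.molecule_id, 1, False, fit=fit, reject_reason="fit did not converge"
        )
    return MoleculeRecord(stream.molecule_id, 1, True, fit=fit)


def analyze_cohort(streams: Sequence[PhotonStream], **kwargs) -> list[MoleculeRecord]:
    return [analyze_stream(s, **kwargs) for s in streams]
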