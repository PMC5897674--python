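"""Statistical core: Gamma MLE with confidence intervals, moments and NSR,
optimal-binning histograms, Gamma-plane power-law fits, and KS shift tests.

The platform treats each person's micro-movement (or inter-beat-interval)
samples as draws from a two-parameter Gamma law

    f(x | a, b) = x^(a-1) exp(-x / b) / (Gamma(a) b^a),  x > 0,

with shape ``a`` and scale ``b``. The mean is ``a b`` and the variance
``a b^2``, so the scale equals the noise-to-signal ratio (NSR =
variance / mean = b): the Gamma parameter plane (shape on x, scale on y)
separates regimes of high vs. low noise and of skewed (exponential-like,
a = 1) vs. symmetric (Gaussian-like, large a) fluctuations. Parameters
are estimated by maximum likelihood — Newton iteration on the profile
shape equation ``log a - psi(a) = log(mean) - mean(log)`` from a
method-of-moments start — and 95% Wald intervals are built from the
observed Fisher information on (log a, log b) so the intervals stay
positive after back-transformation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats
from scipy.special import gammaln, polygamma, psi
from statsmodels.stats.multitest import multipletests

from .signal_core import InputError, SpibaError

__all__ = [
    "GammaFit",
    "GammaMoments",
    "PlanePoint",
    "PowerLawFit",
    "fd_histogram",
    "fit_gamma_mle",
    "gamma_moments",
    "gamma_pdf",
    "loglog_power_fit",
    "ks_two_sample",
    "ks_vs_normal",
    "condition_shift_report",
    "compare_candidate_fits",
]

#: Hard floor on sample size for a fit.
MIN_FIT_N = 10
#: Below this many peaks the confidence intervals are considered loose.
TIGHT_CI_N = 100


@dataclass(frozen=True)
class GammaFit:
    """MLE of the Gamma shape/scale with Wald confidence intervals."""

    shape: float
    scale: float
    ci_shape: tuple[float, float]
    ci_scale: tuple[float, float]
    conf_level: float
    n: int
    loglik: float
    sample_label: str = "raw"

    def __post_init__(self) -> None:
        if not (self.shape > 0 and self.scale > 0):
            raise SpibaError("fitted shape and scale must be positive")


@dataclass(frozen=True)
class GammaMoments:
    """Closed-form moments of a fitted Gamma law; nsr == scale."""

    mean: float
    variance: float
    skewness: float
    kurtosis: float
    nsr: float


@dataclass(frozen=True)
class PlanePoint:
    """One participant x condition point on the Gamma parameter plane."""

    participant_id: str
    condition: str
    kind: str
    shape: float
    scale: float
    ci_shape: tuple[float, float]
    ci_scale: tuple[float, float]
    raw_median: float = float("nan")

    def __post_init__(self) -> None:
        if not (self.shape > 0 and self.scale > 0):
            raise SpibaError("plane points need positive shape and scale")


@dataclass(frozen=True)
class PowerLawFit:
    """Least-squares line through (log shape, log scale)."""

    slope: float
    intercept: float
    n_points: int
    log_base: str = "natural"


# ---------------------------------------------------------------------------
# histograms
# ---------------------------------------------------------------------------

def fd_histogram(samples: np.ndarray) -> dict[str, np.ndarray]:
    """Freedman-Diaconis histogram: bin width h = 2 IQR n^(-1/3).

    Quartiles use linear-interpolation quantiles. When the IQR is zero
    (near-constant sample) the histogram falls back to 2 equal bins with
    a warning. Counts always sum to n.
    """
    x = np.asarray(samples, dtype=float)
    if len(x) < 4:
        raise InputError("Freedman-Diaconis binning needs n >= 4")
    if not np.all(np.isfinite(x)):
        raise InputError("samples must be finite")
    q1, q3 = np.quantile(x, [0.25, 0.75])
    iqr = q3 - q1
    lo, hi = float(np.min(x)), float(np.max(x))
    if iqr <= 0 or hi == lo:
        warnings.warn("zero IQR: falling back to 2 equal bins", stacklevel=2)
        span = hi - lo if hi > lo else max(abs(hi), 1.0) * 1e-6
        edges = np.array([lo, lo + span / 2, lo + span])
    else:
        h = 2.0 * iqr * len(x) ** (-1.0 / 3.0)
        n_bins = max(int(np.ceil((hi - lo) / h)), 2)
        edges = lo + h * np.arange(n_bins + 1)
        edges[-1] = max(edges[-1], hi)
    counts, edges = np.histogram(x, bins=edges)
    return {"edges": edges, "counts": counts}


# ---------------------------------------------------------------------------
# Gamma MLE
# ---------------------------------------------------------------------------

def gamma_loglik(x: np.ndarray, a: float, b: float) -> float:
    """Gamma log-likelihood of samples ``x`` at shape ``a``, scale ``b``."""
    n = len(x)
    return float(
        (a - 1) * np.sum(np.log(x)) - np.sum(x) / b
        - n * gammaln(a) - n * a * np.log(b)
    )


def _solve_profile_shape(
    s: float, a0: float, max_iter: int = 100, tol: float = 1e-12
) -> float:
    """Newton solve of log(a) - psi(a) = s for the profile shape.

    ``s = log(mean) - mean(log)`` is strictly positive for non-constant
    positive samples (Jensen); the left-hand side is strictly decreasing
    in ``a``, so the root is unique. ``a0`` is the method-of-moments
    start, guarded into the valid range.
    """
    a = float(np.clip(a0, 1e-8, 1e8))
    for _ in range(max_iter):
        f = np.log(a) - psi(a) - s
        fp = 1.0 / a - polygamma(1, a)
        step = f / fp
        a_new = a - step
        if a_new <= 0:
            a_new = a / 2.0
        if abs(a_new - a) <= tol * a:
            return float(a_new)
        a = a_new
    raise SpibaError(
        f"profile shape equation did not converge in {max_iter} iterations "
        f"(s={s:.6g}, last a={a:.6g})"
    )


def fit_gamma_mle(
    samples: np.ndarray,
    conf_level: float = 0.95,
    sample_label: str = "raw",
) -> GammaFit:
    """Maximum-likelihood Gamma fit with Wald CIs on (log a, log b).

    The shape solves the profile likelihood equation by Newton iteration
    from a method-of-moments start; the scale is ``mean / shape``. The
    confidence intervals come from inverting the observed Fisher
    information in the log-parameterization and back-transforming, which
    keeps both interval ends positive. Samples must be strictly positive;
    fits on fewer than 100 samples warn that the intervals are loose.
    """
    x = np.asarray(samples, dtype=float)
    if len(x) < MIN_FIT_N:
        raise InputError(f"need at least {MIN_FIT_N} samples, got {len(x)}")
    if np.any(~np.isfinite(x)) or np.any(x <= 0):
        raise InputError("Gamma fitting requires finite, strictly positive samples")
    if len(x) < TIGHT_CI_N:
        warnings.warn(
            f"only {len(x)} samples; above {TIGHT_CI_N} are needed for tight "
            "confidence intervals", stacklevel=2,
        )
    n = len(x)
    mean = float(np.mean(x))
    s = float(np.log(mean) - np.mean(np.log(x)))
    if s <= 0:
        raise SpibaError("degenerate sample (zero spread): cannot fit a Gamma law")
    a0 = mean ** 2 / float(np.var(x))  # method-of-moments start
    a = _solve_profile_shape(s, a0)
    b = mean / a

    # observed Fisher information in (log a, log b); at the MLE the score
    # vanishes, so the chain rule leaves pure second-order terms
    info = np.array([
        [n * a * a * polygamma(1, a), n * a],
        [n * a, n * a],
    ])
    cov = np.linalg.inv(info)
    z = stats.norm.ppf(0.5 + conf_level / 2.0)
    se_la, se_lb = np.sqrt(np.diag(cov))
    ci_shape = (a * np.exp(-z * se_la), a * np.exp(z * se_la))
    ci_scale = (b * np.exp(-z * se_lb), b * np.exp(z * se_lb))
    return GammaFit(
        shape=a, scale=b,
        ci_shape=(float(ci_shape[0]), float(ci_shape[1])),
        ci_scale=(float(ci_scale[0]), float(ci_scale[1])),
        conf_level=conf_level, n=n,
        loglik=gamma_loglik(x, a, b),
        sample_label=sample_label,
    )


def gamma_moments(fit: GammaFit) -> GammaMoments:
    """Mean a·b, variance a·b², skewness 2/√a, kurtosis 3 + 6/a, NSR = b."""
    a, b = fit.shape, fit.scale
    return GammaMoments(
        mean=a * b,
        variance=a * b * b,
        skewness=2.0 / np.sqrt(a),
        kurtosis=3.0 + 6.0 / a,
        nsr=b,
    )


def gamma_pdf(x, a: float, b: float):
    """Gamma density evaluated in log-space for numerical stability."""
    if not (a > 0 and b > 0):
        raise ValueError("shape and scale must be positive")
    x = np.asarray(x, dtype=float)
    scalar = x.ndim == 0
    x = np.atleast_1d(x)
    if np.any(x < 0):
        raise ValueError("the Gamma density is supported on x >= 0")
    out = np.zeros_like(x)
    pos = x > 0
    out[pos] = np.exp(
        (a - 1) * np.log(x[pos]) - x[pos] / b - gammaln(a) - a * np.log(b)
    )
    zero = ~pos
    if zero.any():
        if a < 1:
            out[zero] = np.inf
        elif a == 1:
            out[zero] = 1.0 / b
        # a > 1: density is 0 at the origin (already set)
    return float(out[0]) if scalar else out


# ---------------------------------------------------------------------------
# Gamma-plane power law
# ---------------------------------------------------------------------------

def loglog_power_fit(
    points: list[PlanePoint] | np.ndarray,
    log_base: str = "natural",
) -> PowerLawFit:
    """Least-squares line through (log shape, log scale) of the scatter.

    A slope of -1 with intercept log(mu) arises exactly when all points
    share the same Gamma mean mu = a·b, since log b = log mu - log a.
    """
    if isinstance(points, np.ndarray):
        ab = np.asarray(points, dtype=float)
    else:
        ab = np.array([[p.shape, p.scale] for p in points], dtype=float)
    if len(ab) < 3:
        raise InputError("power-law fit needs at least 3 points")
    if np.any(ab <= 0):
        raise InputError("all shape/scale values must be positive")
    log = np.log if log_base == "natural" else np.log10
    if log_base not in ("natural", "base10"):
        raise ValueError(f"unknown log_base {log_base!r}")
    la, lb = log(ab[:, 0]), log(ab[:, 1])
    if np.ptp(la) < 1e-12:
        raise SpibaError("degenerate scatter: no spread along the shape axis")
    slope, intercept = np.polyfit(la, lb, 1)
    return PowerLawFit(slope=float(slope), intercept=float(intercept),
                       n_points=len(ab), log_base=log_base)


# ---------------------------------------------------------------------------
# Kolmogorov-Smirnov shift tests
# ---------------------------------------------------------------------------

def ks_two_sample(x: np.ndarray, y: np.ndarray) -> dict[str, float]:
    """Two-sided two-sample KS statistic with asymptotic p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 5 or len(y) < 5:
        raise InputError("two-sample KS needs n >= 5 in both samples")
    res = stats.ks_2samp(x, y, method="asymp")
    return {"D": float(res.statistic), "p": float(res.pvalue)}


def ks_vs_normal(
    x: np.ndarray,
    mode: str = "moment_matched",
    monte_carlo: bool = False,
    n_mc: int = 2000,
    rng: np.random.Generator | None = None,
) -> dict[str, float]:
    """One-sample KS against a normal with the sample's mean and SD.

    The default p comes from the asymptotic KS distribution and ignores
    that the normal's parameters were estimated from the same sample
    (which makes it conservative); ``monte_carlo=True`` recalibrates the
    p in the style of the Lilliefors test by simulating the null.
    """
    if mode != "moment_matched":
        raise ValueError(f"unknown mode {mode!r}")
    x = np.asarray(x, dtype=float)
    if len(x) < 20:
        raise InputError("normality KS needs n >= 20")
    sd = float(np.std(x, ddof=1))
    if sd == 0:
        raise InputError("zero variance sample")
    m = float(np.mean(x))
    res = stats.kstest(x, stats.norm(loc=m, scale=sd).cdf, method="asymp")
    out = {"D": float(res.statistic), "p": float(res.pvalue)}
    if monte_carlo:
        rng = rng or np.random.default_rng(0)
        n = len(x)
        null_d = np.empty(n_mc)
        for i in range(n_mc):
            z = rng.standard_normal(n)
            null_d[i] = stats.kstest(
                z, stats.norm(loc=z.mean(), scale=z.std(ddof=1)).cdf
            ).statistic
        out["p_mc"] = float((np.sum(null_d >= out["D"]) + 1) / (n_mc + 1))
    return out


# ---------------------------------------------------------------------------
# condition-shift report
# ---------------------------------------------------------------------------

def condition_shift_report(
    fits: dict[str, GammaFit],
    samples: dict[str, np.ndarray],
    participant_id: str = "",
    kind: str = "raw",
    raw_medians: dict[str, float] | None = None,
    condition_order: list[str] | None = None,
) -> dict:
    """All pairwise KS shifts plus per-condition signatures.

    Returns pairwise two-sample KS results (raw and Benjamini-Hochberg
    adjusted p-values), a per-condition normality KS, one PlanePoint and
    one GammaMoments per condition, and the ordered condition sequence
    used to draw transition arrows.
    """
    conditions = condition_order or list(fits)
    if len(conditions) < 2:
        raise InputError("need at least 2 conditions to compare")
    missing = [c for c in conditions if c not in fits or c not in samples]
    if missing:
        raise InputError(f"conditions without fits/samples: {missing}")

    pairwise = []
    for c1, c2 in combinations(conditions, 2):
        try:
            res = ks_two_sample(samples[c1], samples[c2])
        except InputError:
            continue
        pairwise.append({"a": c1, "b": c2, **res})
    if pairwise:
        adj = multipletests([p["p"] for p in pairwise], method="fdr_bh")[1]
        for row, p_adj in zip(pairwise, adj):
            row["p_bh"] = float(p_adj)

    normality = {}
    for c in conditions:
        try:
            normality[c] = ks_vs_normal(samples[c])
        except InputError:
            normality[c] = None  # too few samples for the normality check
    plane_points = {
        c: PlanePoint(
            participant_id=participant_id, condition=c, kind=kind,
            shape=fits[c].shape, scale=fits[c].scale,
            ci_shape=fits[c].ci_shape, ci_scale=fits[c].ci_scale,
            raw_median=(raw_medians or {}).get(c, float("nan")),
        )
        for c in conditions
    }
    moments = {c: gamma_moments(fits[c]) for c in conditions}
    return {
        "participant_id": participant_id,
        "kind": kind,
        "conditions": conditions,
        "pairwise_ks": pairwise,
        "normality_ks": normality,
        "plane_points": plane_points,
        "moments": moments,
        "arrows": list(zip(conditions[:-1], conditions[1:])),
    }


# ---------------------------------------------------------------------------
# candidate-family comparison (reported, never enforced)
# ---------------------------------------------------------------------------

def compare_candidate_fits(samples: np.ndarray) -> dict[str, float]:
    """Log-likelihoods of Gamma, exponential, lognormal and normal fits.

    A reporting utility for the model-selection step that precedes the
    Gamma choice; it does not alter which family the platform fits.
    """
    x = np.asarray(samples, dtype=float)
    if np.any(x <= 0):
        raise InputError("candidate comparison requires positive samples")
    fit = fit_gamma_mle(x)
    out = {"gamma": fit.loglik}
    out["exponential"] = float(np.sum(stats.expon.logpdf(x, scale=np.mean(x))))
    mu_l, sd_l = np.mean(np.log(x)), np.std(np.log(x))
    out["lognormal"] = float(np.sum(stats.lognorm.logpdf(x, sd_l, scale=np.exp(mu_l))))
    out["normal"] = float(
        np.sum(stats.norm.logpdf(x, loc=np.mean(x), scale=np.std(x)))
    )
    return out
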