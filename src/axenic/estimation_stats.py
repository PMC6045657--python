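"""Estimation statistics: effect sizes with bootstrap confidence intervals.

This module implements the quantitative core shared by every assay in the
package.  Following the estimation-statistics approach, group contrasts are
reported as point estimates (mean difference, Hedges' g, or a median
proportion) together with bootstrap 95% confidence intervals; p-values are
attached *pro forma* only and drive no decision anywhere in the pipeline.

Confidence intervals for two-sample contrasts use the bias-corrected and
accelerated (BCa) bootstrap:

* the bias term ``z0`` is the normal quantile of the proportion of bootstrap
  statistics strictly below the observed statistic (ties counted half);
* the acceleration ``a`` is estimated from the jackknife skewness of the
  statistic (leave-one-out within each group);
* percentile endpoints ``alpha/2`` and ``1 - alpha/2`` are mapped through

  ``alpha_adj = Phi( z0 + (z0 + z_alpha) / (1 - a * (z0 + z_alpha)) )``

  and the interval is read off the bootstrap distribution at the adjusted
  levels.  With ``z0 = 0`` and ``a = 0`` this reduces to the ordinary
  percentile interval.

Median confidence intervals use a smoothed bootstrap: resamples are perturbed
with zero-mean Gaussian kernel noise (Silverman's rule-of-thumb bandwidth by
default), which de-granularizes the otherwise lattice-valued distribution of
resampled medians.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats as _sps

__all__ = [
    "EstimationError",
    "EffectBands",
    "DEFAULT_BANDS",
    "EffectEstimate",
    "mean_difference",
    "hedges_g",
    "bca_ci",
    "smoothed_bootstrap_median",
    "classify_effect",
    "proforma_p",
    "two_sample_estimate",
]


class EstimationError(ValueError):
    """Raised for statistically undefined requests (empty samples, zero SD, ...)."""


@dataclass(frozen=True)
class EffectBands:
    """Descriptive bands for |g|: trivial / small / moderate / large.

    A value exactly on a threshold is assigned to the lower band.
    """

    trivial_upper: float = 0.2
    small_upper: float = 0.5
    moderate_upper: float = 0.8

    def __post_init__(self) -> None:
        t, s, m = self.trivial_upper, self.small_upper, self.moderate_upper
        if not (0 < t < s < m):
            raise ValueError("effect-size bands must be strictly increasing and positive")

    def classify(self, g: float) -> str:
        a = abs(float(g))
        if not np.isfinite(a):
            raise EstimationError("cannot classify a non-finite effect size")
        if a <= self.trivial_upper:
            return "trivial"
        if a <= self.small_upper:
            return "small"
        if a <= self.moderate_upper:
            return "moderate"
        return "large"


DEFAULT_BANDS = EffectBands()


@dataclass
class EffectEstimate:
    """A point estimate with bootstrap CI — the universal output record.

    ``orientation`` is experimental - control throughout the package
    (GF - CV, GF-C - CV), so a positive sign means the germ-free group is
    higher.  ``p_value`` is pro forma only.
    """

    kind: str  # mean_difference | hedges_g | median_proportion
    estimate: float
    ci_low: float
    ci_high: float
    ci_level: float = 0.95
    n1: int | None = None
    n2: int | None = None
    n_boot: int = 10_000
    p_value: float | None = None
    label: str | None = None
    orientation: str = "experimental-control"
    flags: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.kind not in ("mean_difference", "hedges_g", "median_proportion"):
            raise ValueError(f"unknown estimate kind {self.kind!r}")
        lo, est, hi = self.ci_low, self.estimate, self.ci_high
        if not (lo <= est <= hi or np.isclose(lo, est) or np.isclose(hi, est)):
            raise EstimationError(
                f"CI [{lo}, {hi}] does not contain the estimate {est}"
            )


def _clean(sample: Sequence[float], name: str) -> np.ndarray:
    x = np.asarray(sample, dtype=float).ravel()
    if x.size == 0:
        raise EstimationError(f"{name} sample is empty")
    if not np.all(np.isfinite(x)):
        raise EstimationError(f"{name} sample contains non-finite values")
    return x


def mean_difference(sample_exp: Sequence[float], sample_ctrl: Sequence[float]) -> float:
    """mean(experimental) - mean(control)."""
    x = _clean(sample_exp, "experimental")
    y = _clean(sample_ctrl, "control")
    return float(x.mean() - y.mean())


def _pooled_sd(x: np.ndarray, y: np.ndarray) -> float:
    n1, n2 = x.size, y.size
    v1 = x.var(ddof=1) if n1 > 1 else 0.0
    v2 = y.var(ddof=1) if n2 > 1 else 0.0
    return float(np.sqrt(((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)))


def hedges_g(sample_exp: Sequence[float], sample_ctrl: Sequence[float]) -> float:
    """Bias-corrected standardized mean difference.

    ``g = J * (mean_exp - mean_ctrl) / s_pooled`` with the df-weighted pooled
    standard deviation and Hedges' small-sample correction
    ``J = 1 - 3 / (4 * (n1 + n2 - 2) - 1)``.
    """
    x = _clean(sample_exp, "experimental")
    y = _clean(sample_ctrl, "control")
    n1, n2 = x.size, y.size
    if n1 + n2 < 3:
        raise EstimationError("Hedges' g needs at least 3 observations in total")
    sp = _pooled_sd(x, y)
    if sp == 0.0:
        raise EstimationError("pooled SD is zero; standardized effect undefined")
    j = 1.0 - 3.0 / (4.0 * (n1 + n2 - 2) - 1.0)
    return float(j * (x.mean() - y.mean()) / sp)


# ---------------------------------------------------------------------------
# bootstrap machinery

def _boot_indices(rng: np.random.Generator, n: int, n_boot: int) -> np.ndarray:
    return rng.integers(0, n, size=(n_boot, n))


def _bootstrap_two_sample(
    x: np.ndarray,
    y: np.ndarray,
    statistic: Callable[[np.ndarray, np.ndarray], float],
    n_boot: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Within-group resampling; vectorized fast paths for the common statistics."""
    i1 = _boot_indices(rng, x.size, n_boot)
    i2 = _boot_indices(rng, y.size, n_boot)
    if statistic is mean_difference:
        return x[i1].mean(axis=1) - y[i2].mean(axis=1)
    if statistic is hedges_g:
        return _vectorized_g(x[i1], y[i2])
    bx, by = x[i1], y[i2]
    return np.array([statistic(bx[b], by[b]) for b in range(n_boot)])


def _vectorized_g(bx: np.ndarray, by: np.ndarray) -> np.ndarray:
    n1, n2 = bx.shape[1], by.shape[1]
    v1 = bx.var(axis=1, ddof=1)
    v2 = by.var(axis=1, ddof=1)
    sp = np.sqrt(((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2))
    j = 1.0 - 3.0 / (4.0 * (n1 + n2 - 2) - 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        return j * (bx.mean(axis=1) - by.mean(axis=1)) / sp


def _jackknife_two_sample(
    x: np.ndarray,
    y: np.ndarray,
    statistic: Callable[[np.ndarray, np.ndarray], float],
) -> np.ndarray:
    """Leave-one-out values over both groups (n1 + n2 pseudo-values)."""
    vals = np.empty(x.size + y.size)
    for i in range(x.size):
        vals[i] = statistic(np.delete(x, i), y)
    for j in range(y.size):
        vals[x.size + j] = statistic(x, np.delete(y, j))
    return vals


def _acceleration(jack: np.ndarray) -> float:
    d = jack.mean() - jack
    denom = np.sum(d**2) ** 1.5
    if denom == 0.0:
        return 0.0
    return float(np.sum(d**3) / (6.0 * denom))


def _bca_adjusted_levels(z0: float, a: float, ci_level: float) -> tuple[float, float]:
    """Map nominal percentile levels through the BCa correction.

    With ``z0 == 0`` and ``a == 0`` this returns the plain percentile levels
    ``((1 - ci_level)/2, 1 - (1 - ci_level)/2)`` unchanged.
    """
    alpha = 1.0 - ci_level
    out = []
    for z_a in (_sps.norm.ppf(alpha / 2.0), _sps.norm.ppf(1.0 - alpha / 2.0)):
        denom = 1.0 - a * (z0 + z_a)
        if denom <= 0:
            # acceleration pathologically large: saturate toward the tail
            out.append(1.0 if (z0 + z_a) > 0 else 0.0)
            continue
        out.append(float(_sps.norm.cdf(z0 + (z0 + z_a) / denom)))
    return out[0], out[1]


def bca_ci(
    sample_exp: Sequence[float],
    sample_ctrl: Sequence[float],
    statistic: Callable[[np.ndarray, np.ndarray], float] = mean_difference,
    n_boot: int = 10_000,
    ci_level: float = 0.95,
    seed: int | np.random.Generator | None = None,
) -> tuple[float, float]:
    """Two-sided BCa bootstrap interval for a two-sample statistic.

    Resampling is within-group (the two samples are independent).  Degenerate
    data (the statistic constant across resamples) yields a zero-width
    interval at the estimate, with a warning; a bootstrap distribution lying
    entirely on one side of the estimate clamps the bias term, with a warning.
    """
    x = _clean(sample_exp, "experimental")
    y = _clean(sample_ctrl, "control")
    if n_boot < 1:
        raise EstimationError("n_boot must be >= 1")
    if not (0.0 < ci_level < 1.0):
        raise EstimationError("ci_level must be in (0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    theta = float(statistic(x, y))
    boots = _bootstrap_two_sample(x, y, statistic, n_boot, rng)
    boots = boots[np.isfinite(boots)]
    if boots.size == 0 or np.all(boots == theta):
        warnings.warn("degenerate bootstrap distribution; zero-width interval")
        return theta, theta

    prop = (np.sum(boots < theta) + 0.5 * np.sum(boots == theta)) / boots.size
    if prop <= 0.0 or prop >= 1.0:
        warnings.warn("all bootstrap statistics on one side; bias term clamped")
        prop = np.clip(prop, 1.0 / (boots.size + 1), 1.0 - 1.0 / (boots.size + 1))
    z0 = float(_sps.norm.ppf(prop))

    a = _acceleration(_jackknife_two_sample(x, y, statistic))

    lo_lvl, hi_lvl = _bca_adjusted_levels(z0, a, ci_level)
    low, high = np.quantile(boots, [lo_lvl, hi_lvl])
    low, high = float(low), float(high)
    tol = 1e-9 * max(1.0, abs(theta))
    if not (low - tol <= theta <= high + tol):
        raise EstimationError(
            f"BCa interval [{low}, {high}] excludes the estimate {theta}"
        )
    return min(low, theta), max(high, theta)


def silverman_bandwidth(sample: Sequence[float]) -> float:
    """Rule-of-thumb Gaussian kernel bandwidth 0.9 * A * n^(-1/5).

    ``A = min(SD, IQR/1.34)``, falling back to the SD when the IQR is zero.
    Zero for a constant sample.
    """
    x = _clean(sample, "sample")
    sd = float(x.std(ddof=1)) if x.size > 1 else 0.0
    iqr = float(np.subtract(*np.percentile(x, [75, 25])))
    a = min(sd, iqr / 1.34) if iqr > 0 else sd
    return 0.9 * a * x.size ** (-0.2)


def smoothed_bootstrap_median(
    sample: Sequence[float],
    n_boot: int = 10_000,
    ci_level: float = 0.95,
    seed: int | np.random.Generator | None = None,
    bandwidth: float | None = None,
) -> tuple[float, float, float]:
    """Sample median with a smoothed-bootstrap percentile interval.

    Each bootstrap resample is perturbed with N(0, bandwidth^2) kernel noise
    before taking its median.  ``bandwidth=None`` uses Silverman's rule;
    ``bandwidth=0`` recovers the ordinary bootstrap median distribution.
    The sample is sorted first, so the result depends only on the multiset of
    values, never on their order.
    """
    x = np.sort(_clean(sample, "sample"))
    if x.size < 2:
        raise EstimationError("smoothed bootstrap needs a sample of size >= 2")
    if not (0.0 < ci_level < 1.0):
        raise EstimationError("ci_level must be in (0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    med = float(np.median(x))
    bw = silverman_bandwidth(x) if bandwidth is None else float(bandwidth)
    if bw < 0:
        raise EstimationError("bandwidth must be non-negative")
    if np.all(x == x[0]):
        return med, med, med
    idx = _boot_indices(rng, x.size, n_boot)
    resamples = x[idx]
    if bw > 0:
        resamples = resamples + rng.standard_normal(idx.shape) * bw
    meds = np.median(resamples, axis=1)
    alpha = 1.0 - ci_level
    low, high = np.quantile(meds, [alpha / 2.0, 1.0 - alpha / 2.0])
    return med, float(low), float(high)


def classify_effect(g: float, bands: EffectBands = DEFAULT_BANDS) -> str:
    """Band label for |g|; threshold values fall into the lower band."""
    return bands.classify(g)


def proforma_p(
    sample_exp: Sequence[float],
    sample_ctrl: Sequence[float],
    method: str = "welch",
    n_perm: int = 10_000,
    seed: int | np.random.Generator | None = None,
) -> float:
    """Two-sided p-value, reported pro forma only.

    ``method="welch"`` uses the Welch two-sample t-test; ``method="permutation"``
    uses a mean-difference permutation test (exhaustive when feasible, else
    Monte-Carlo with ``n_perm`` resamples).
    """
    x = _clean(sample_exp, "experimental")
    y = _clean(sample_ctrl, "control")
    if x.size < 2 or y.size < 2:
        raise EstimationError("pro-forma p needs >= 2 observations per group")
    if method == "welch":
        return float(_sps.ttest_ind(x, y, equal_var=False).pvalue)
    if method == "permutation":
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        res = _sps.permutation_test(
            (x, y),
            lambda a, b, axis=-1: a.mean(axis=axis) - b.mean(axis=axis),
            permutation_type="independent",
            alternative="two-sided",
            n_resamples=n_perm,
            vectorized=True,
            rng=rng,
        )
        return float(res.pvalue)
    raise ValueError(f"unknown method {method!r}")


def two_sample_estimate(
    sample_exp: Sequence[float],
    sample_ctrl: Sequence[float],
    kind: str = "hedges_g",
    n_boot: int = 10_000,
    ci_level: float = 0.95,
    seed: int | np.random.Generator | None = None,
    bands: EffectBands = DEFAULT_BANDS,
    low_n_threshold: int = 5,
) -> EffectEstimate:
    """Convenience wrapper: estimate + BCa CI + pro-forma p in one record."""
    x = _clean(sample_exp, "experimental")
    y = _clean(sample_ctrl, "control")
    stat = {"mean_difference": mean_difference, "hedges_g": hedges_g}.get(kind)
    if stat is None:
        raise ValueError(f"two_sample_estimate supports mean_difference/hedges_g, not {kind!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    est = float(stat(x, y))
    flags: list[str] = []
    if min(x.size, y.size) < 2:
        flags.append("degenerate_ci")
        low = high = est
    else:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            low, high = bca_ci(x, y, stat, n_boot=n_boot, ci_level=ci_level, seed=rng)
        if caught:
            flags.append("bootstrap_flagged")
    if min(x.size, y.size) < low_n_threshold:
        flags.append("low_n")
    p = proforma_p(x, y) if min(x.size, y.size) >= 2 else None
    return EffectEstimate(
        kind=kind,
        estimate=est,
        ci_low=low,
        ci_high=high,
        ci_level=ci_level,
        n1=int(x.size),
        n2=int(y.size),
        n_boot=n_boot,
        p_value=p,
        label=classify_effect(est, bands) if kind == "hedges_g" else None,
        flags=tuple(flags),
    )
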