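"""Agreement and estimation statistics.

Between-system validation uses Bland-Altman analysis — the mean
difference (bias), the sample SD of the differences and the 95% limits
of agreement bias +- 1.96 SD — alongside the ordinary-least-squares
coefficient of determination.  Within-subject comparisons use paired
Cohen's d with a bias-corrected and accelerated (BCa) bootstrap
confidence interval and a sign-flip permutation p-value, the estimation
statistics typically presented on Gardner-Altman plots.

All SDs are sample SDs (N-1 denominator).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm


@dataclass
class AgreementResult:
    bias: float
    sd: float
    loa_lower: float
    loa_upper: float
    r_squared: float | None
    n: int
    flags: list[str] = field(default_factory=list)


@dataclass
class EffectSizeResult:
    d: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    n_boot: int
    n_perm: int
    interpretation: str
    denominator: str = "diff_sd"
    flags: list[str] = field(default_factory=list)


def _paired(a, b):
    a = np.asarray(a, float).ravel()
    b = np.asarray(b, float).ravel()
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    if np.isnan(a).any() or np.isnan(b).any():
        raise ValueError("missing values must be filtered by the caller")
    return a, b


def loa_from_bias_sd(bias: float, sd: float) -> tuple[float, float]:
    """95% limits of agreement from a printed bias and SD."""
    return bias - 1.96 * sd, bias + 1.96 * sd


def bland_altman(test, criterion) -> AgreementResult:
    """Bland-Altman agreement of a test method against a criterion.

    Differences are test - criterion; R^2 comes from OLS of test on
    criterion and is flagged undefined when the criterion has zero
    variance.
    """
    test, criterion = _paired(test, criterion)
    n = test.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    diff = test - criterion
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    lo, hi = loa_from_bias_sd(bias, sd)
    flags = []
    if criterion.std(ddof=1) < 1e-15:
        r2 = None
        flags.append("r_squared_undefined")
    else:
        r = np.corrcoef(test, criterion)[0, 1]
        r2 = float(r * r)
    return AgreementResult(bias=bias, sd=sd, loa_lower=lo, loa_upper=hi,
                           r_squared=r2, n=n, flags=flags)


def paired_cohens_d(a, b, denominator: str = "diff_sd") -> float:
    """Paired Cohen's d: mean difference scaled by a dispersion.

    ``diff_sd`` (default) divides by the SD of the paired differences;
    ``average_sd`` by the mean of the two samples' SDs.
    """
    a, b = _paired(a, b)
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    diff = a - b
    if denominator == "diff_sd":
        s = diff.std(ddof=1)
    elif denominator == "average_sd":
        s = (a.std(ddof=1) + b.std(ddof=1)) / 2.0
    else:
        raise ValueError(f"unknown denominator '{denominator}'")
    if s < 1e-15:
        if abs(diff.mean()) < 1e-15:
            return 0.0  # identical samples: no effect at all
        raise ZeroDivisionError("zero dispersion: effect size undefined")
    return float(diff.mean() / s)


def bootstrap_bca_ci(a, b, statistic=None, n_boot: int = 5000,
                     level: float = 0.95, seed: int | None = None):
    """BCa bootstrap CI for a paired statistic (default: paired Cohen's d).

    Pairs are resampled with replacement; the bias correction z0 comes
    from the fraction of resampled statistics below the observed value
    and the acceleration from jackknife skewness.  Degenerate resample
    distributions fall back to the percentile interval (flagged).
    Reproducible under ``seed``.
    """
    a, b = _paired(a, b)
    n = a.size
    if n < 3:
        raise ValueError("BCa needs at least 3 pairs")
    if statistic is None:
        statistic = paired_cohens_d
    rng = np.random.default_rng(seed)
    theta_hat = statistic(a, b)
    idx = rng.integers(0, n, size=(n_boot, n))
    boot = np.empty(n_boot)
    for i in range(n_boot):
        j = idx[i]
        try:
            boot[i] = statistic(a[j], b[j])
        except ZeroDivisionError:
            boot[i] = np.nan
    boot = boot[np.isfinite(boot)]
    flags = []
    alpha = (1.0 - level) / 2.0
    if boot.size == 0 or boot.std() < 1e-15:
        v = float(boot[0]) if boot.size else theta_hat
        return v, v, ["degenerate_bootstrap"]
    prop = np.mean(boot < theta_hat)
    if prop <= 0.0 or prop >= 1.0:
        flags.append("degenerate_bca_z0")
        lo, hi = np.quantile(boot, [alpha, 1 - alpha])
        return float(lo), float(hi), flags
    z0 = norm.ppf(prop)
    # jackknife acceleration
    jack = np.empty(n)
    for i in range(n):
        keep = np.arange(n) != i
        try:
            jack[i] = statistic(a[keep], b[keep])
        except ZeroDivisionError:
            jack[i] = np.nan
    jack = jack[np.isfinite(jack)]
    if jack.size < 3 or np.allclose(jack, jack.mean()):
        acc = 0.0
    else:
        u = jack.mean() - jack
        acc = (u**3).sum() / (6.0 * ((u**2).sum()) ** 1.5)
    zlo, zhi = norm.ppf(alpha), norm.ppf(1 - alpha)

    def adj(zq):
        num = z0 + zq
        return norm.cdf(z0 + num / (1 - acc * num))

    lo, hi = np.quantile(boot, [adj(zlo), adj(zhi)])
    return float(lo), float(hi), flags


def permutation_p(a, b, n_perm: int = 5000, seed: int | None = None,
                  exact: bool | None = None) -> float:
    """Sign-flip permutation p-value for a paired design.

    Each reshuffle randomly negates each within-pair difference; p is
    the proportion of permuted |mean difference| at or above the
    observed one, with a +1 continuity correction (the identity
    permutation counts).  ``exact=True`` (or automatically when
    2^N <= n_perm) enumerates all sign patterns instead.
    """
    a, b = _paired(a, b)
    diff = a - b
    n = diff.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    obs = abs(diff.mean())
    if obs < 1e-15:
        return 1.0
    if exact is None:
        exact = 2**n <= n_perm
    if exact:
        signs = np.array(np.meshgrid(*([[-1.0, 1.0]] * n))).T.reshape(-1, n)
        means = np.abs(signs @ diff) / n
        return float(np.mean(means >= obs - 1e-12))
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    means = np.abs(signs @ diff) / n
    hits = int(np.sum(means >= obs - 1e-12))
    return float((hits + 1) / (n_perm + 1))


def interpret_effect(d: float) -> str:
    """Qualitative effect-size band on |d|: none / small / moderate / large."""
    if not np.isfinite(d):
        raise ValueError("effect size must be finite")
    m = abs(d)
    if m >= 0.8:
        return "large"
    if m >= 0.5:
        return "moderate"
    if m >= 0.2:
        return "small"
    return "none"


def estimation_statistics(a, b, n_boot: int = 5000, n_perm: int = 5000,
                          seed: int | None = None,
                          denominator: str = "diff_sd") -> EffectSizeResult:
    """Paired Cohen's d with BCa CI, permutation p and interpretation."""
    a, b = _paired(a, b)
    d = paired_cohens_d(a, b, denominator=denominator)
    lo, hi, flags = bootstrap_bca_ci(
        a, b, statistic=lambda x, y: paired_cohens_d(x, y, denominator),
        n_boot=n_boot, seed=seed)
    p = permutation_p(a, b, n_perm=n_perm,
                      seed=None if seed is None else seed + 1)
    if not (lo <= d <= hi):
        flags = list(flags) + ["bca_degeneracy_d_outside_ci"]
    return EffectSizeResult(d=d, ci_low=lo, ci_high=hi, p=p, n=a.size,
                            n_boot=n_boot, n_perm=n_perm,
                            interpretation=interpret_effect(d),
                            denominator=denominator, flags=list(flags))


def gardner_altman_plot(a, b, result: EffectSizeResult | None = None,
                        labels=("inside", "outside"), ax=None):
    """Minimal Gardner-Altman-style estimation plot (requires matplotlib)."""
    import matplotlib.pyplot as plt

    a, b = _paired(a, b)
    if result is None:
        result = estimation_statistics(a, b, seed=0)
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    for ai, bi in zip(a, b):
        ax.plot([0, 1], [ai, bi], "o-", color="0.6", alpha=0.7, ms=4)
    ax.set_xticks([0, 1, 2])
    ax.set_xticklabels([*labels, "paired d"])
    ax2 = ax.twinx()
    ax2.errorbar([2], [result.d],
                 yerr=[[result.d - result.ci_low], [result.ci_high - result.d]],
                 fmt="ko", capsize=4)
    ax2.axhline(0.0, color="0.8", lw=0.8)
    ax2.set_ylabel("paired Cohen's d")
    return ax
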