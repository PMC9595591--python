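"""Estimation statistics and null-hypothesis tests for between-population
comparisons.

The estimation layer reports unpaired mean differences with 95%
bias-corrected and accelerated (BCa) bootstrap confidence intervals
(5000 resamples by default), in shared-control (every group vs a common
reference population) and two-group designs.  The NHST layer routes
between one-way ANOVA + Tukey HSD and Kruskal-Wallis + pairwise
Mann-Whitney with Bonferroni adjustment on a per-group Shapiro normality
screen, and provides the Tukey box-and-whisker summary used for display.

The resampling unit throughout is the well: samples passed in are
per-well summary values, never per-pixel or per-varicosity measurements.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .core import RESILIENT_POPULATIONS, VULNERABLE_POPULATIONS

DEFAULT_N_RESAMPLES = 5000


@dataclass
class EstimationResult:
    """Unpaired mean difference (b - a) with a BCa confidence interval."""

    group_a: str
    group_b: str
    n_a: int
    n_b: int
    difference: float
    ci_low: float
    ci_high: float
    n_resamples: int
    seed: int | None
    alpha: float = 0.05
    degenerate: bool = False


@dataclass
class TestResult:
    name: str  # kruskal_wallis | one_way_anova | tukey_hsd | pairwise_t | welch_t | mann_whitney_u
    statistic: float
    p_raw: float
    p_adjusted: float
    adjustment: str  # bonferroni | tukey | none
    groups: tuple[str, ...] = ()


@dataclass
class TukeyBoxStats:
    """Median, quartile hinges (linear-interpolation convention) and
    whiskers capped at 1.5 x IQR beyond the hinges; whiskers are data
    values."""

    median: float
    lower_hinge: float
    upper_hinge: float
    whisker_low: float
    whisker_high: float
    hinge_convention: str = "linear-interpolation"


def mean_difference_bca(
    a,
    b,
    n_resamples: int = DEFAULT_N_RESAMPLES,
    seed: int | None = None,
    alpha: float = 0.05,
    group_a: str = "a",
    group_b: str = "b",
) -> EstimationResult:
    """Unpaired mean difference mean(b) - mean(a) with a BCa interval.

    Bias correction z0 comes from the fraction of resampled differences
    below the observed difference; acceleration from the jackknife
    skewness of the statistic over both samples.  Identical
    (seed, n_resamples) reproduce the interval bit-exactly.  When both
    groups have zero variance the interval degenerates to [d, d] and is
    flagged.
    """
    a = np.asarray(a, float).ravel()
    b = np.asarray(b, float).ravel()
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs n >= 3")
    d_obs = b.mean() - a.mean()
    if a.std() == 0.0 and b.std() == 0.0:
        return EstimationResult(
            group_a, group_b, a.size, b.size, float(d_obs), float(d_obs),
            float(d_obs), n_resamples, seed, alpha, degenerate=True,
        )
    rng = np.random.default_rng(seed)
    ra = rng.integers(0, a.size, size=(n_resamples, a.size))
    rb = rng.integers(0, b.size, size=(n_resamples, b.size))
    boot = b[rb].mean(axis=1) - a[ra].mean(axis=1)
    # bias correction; ties with the observed value count half so that
    # lattice-valued statistics (heavily tied resamples) stay centred
    prop = float(np.mean(boot < d_obs) + 0.5 * np.mean(boot == d_obs))
    prop = min(max(prop, 1.0 / (n_resamples + 1)), n_resamples / (n_resamples + 1.0))
    z0 = sps.norm.ppf(prop)
    # acceleration from jackknife over both samples
    jack_a = (a.sum() - a) / (a.size - 1)  # mean of a with obs i removed
    jack_b = (b.sum() - b) / (b.size - 1)
    theta = np.concatenate([b.mean() - jack_a, jack_b - a.mean()])
    dev = theta.mean() - theta
    denom = 6.0 * (np.sum(dev**2)) ** 1.5
    accel = float(np.sum(dev**3) / denom) if denom > 0 else 0.0
    z_lo = sps.norm.ppf(alpha / 2.0)
    z_hi = sps.norm.ppf(1.0 - alpha / 2.0)
    a1 = sps.norm.cdf(z0 + (z0 + z_lo) / (1.0 - accel * (z0 + z_lo)))
    a2 = sps.norm.cdf(z0 + (z0 + z_hi) / (1.0 - accel * (z0 + z_hi)))
    lo, hi = np.quantile(boot, [a1, a2])
    return EstimationResult(
        group_a, group_b, a.size, b.size, float(d_obs), float(lo), float(hi),
        n_resamples, seed, alpha,
    )


def _pair_seed(master_seed: int | None, label: str) -> int:
    """Stable per-comparison seed: SHA-256 of "master:label", truncated to
    31 bits, so shared-control runs are order-invariant by group label."""
    digest = hashlib.sha256(f"{master_seed}:{label}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


def shared_control_design(
    groups: dict[str, np.ndarray],
    control_label: str,
    n_resamples: int = DEFAULT_N_RESAMPLES,
    master_seed: int | None = 0,
    include_control: bool = False,
) -> list[EstimationResult]:
    """One mean-difference estimate per non-control group vs the shared
    control, each with an independent label-derived seed."""
    if control_label not in groups:
        raise ValueError(f"control group {control_label!r} not present")
    control = np.asarray(groups[control_label], float)
    results = []
    for label in groups:
        if label == control_label and not include_control:
            continue
        results.append(
            mean_difference_bca(
                control,
                np.asarray(groups[label], float),
                n_resamples=n_resamples,
                seed=_pair_seed(master_seed, label),
                group_a=control_label,
                group_b=label,
            )
        )
    return results


def mann_whitney(
    a, b, exact_max_n: int = 20
) -> TestResult:
    """Two-sided Mann-Whitney U: exact when combined n <= ``exact_max_n``
    and tie-free, normal approximation with tie correction otherwise."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    if a.size + b.size <= exact_max_n and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return TestResult("mann_whitney_u", float(res.statistic), float(res.pvalue),
                      float(res.pvalue), "none")


def classify_population(label: str) -> str:
    """Map a population label onto its vulnerability class."""
    if label in VULNERABLE_POPULATIONS:
        return "vulnerable"
    if label in RESILIENT_POPULATIONS:
        return "resilient"
    raise ValueError(f"unknown population label {label!r}")


def class_comparison(
    values,
    labels,
    n_resamples: int = DEFAULT_N_RESAMPLES,
    seed: int | None = 0,
) -> tuple[TestResult, EstimationResult]:
    """Vulnerable-vs-resilient two-group comparison.

    ``labels`` may be population labels (mapped via the fixed class map:
    vulnerable = SNc, LC, R, DMV; resilient = VTA, XII, STR) or the class
    names themselves.  Returns the Mann-Whitney U test and the
    Gardner-Altman-style two-group mean-difference estimate
    (resilient minus vulnerable).
    """
    values = np.asarray(values, float)
    classes = np.array(
        [
            lab if lab in ("vulnerable", "resilient") else classify_population(lab)
            for lab in labels
        ]
    )
    vuln = values[classes == "vulnerable"]
    res = values[classes == "resilient"]
    if vuln.size == 0 or res.size == 0:
        raise ValueError("both classes must be non-empty")
    test = mann_whitney(vuln, res)
    test.groups = ("vulnerable", "resilient")
    est = mean_difference_bca(
        vuln, res, n_resamples=n_resamples, seed=seed,
        group_a="vulnerable", group_b="resilient",
    )
    return test, est


def bonferroni(p: float, m: int) -> float:
    """Bonferroni-adjusted p-value: min(1, m * p)."""
    return min(1.0, m * p)


def omnibus_and_posthoc(
    groups: dict[str, np.ndarray],
    route: str = "auto",
    alpha: float = 0.05,
) -> list[TestResult]:
    """Omnibus + post hoc comparisons across labeled groups.

    ``route='auto'`` screens each group with Shapiro-Wilk at ``alpha``;
    if every group is compatible with normality the parametric route
    (one-way ANOVA + Tukey HSD) is used, otherwise the nonparametric
    route (Kruskal-Wallis + pairwise Mann-Whitney, Bonferroni-adjusted).
    Both routes can be forced explicitly.
    """
    if route not in ("auto", "parametric", "nonparametric"):
        raise ValueError(f"unknown route {route!r}")
    labels = list(groups)
    samples = [np.asarray(groups[k], float) for k in labels]
    if len(samples) < 2:
        raise ValueError("need at least two groups")
    if any(s.size < 3 for s in samples):
        raise ValueError("every group needs n >= 3")
    if route == "auto":
        # zero-spread groups fail normality trivially (Shapiro undefined)
        if any(np.ptp(s) == 0 for s in samples):
            route = "nonparametric"
        else:
            normal = all(sps.shapiro(s).pvalue > alpha for s in samples)
            route = "parametric" if normal else "nonparametric"
    results: list[TestResult] = []
    pairs = [
        (i, j) for i in range(len(labels)) for j in range(i + 1, len(labels))
    ]
    if route == "parametric":
        f = sps.f_oneway(*samples)
        results.append(
            TestResult("one_way_anova", float(f.statistic), float(f.pvalue),
                       float(f.pvalue), "none", tuple(labels))
        )
        hsd = sps.tukey_hsd(*samples)
        for i, j in pairs:
            results.append(
                TestResult(
                    "tukey_hsd", float(hsd.statistic[i, j]),
                    float(hsd.pvalue[i, j]), float(hsd.pvalue[i, j]),
                    "tukey", (labels[i], labels[j]),
                )
            )
    else:
        kw = sps.kruskal(*samples)
        results.append(
            TestResult("kruskal_wallis", float(kw.statistic), float(kw.pvalue),
                       float(kw.pvalue), "none", tuple(labels))
        )
        m = len(pairs)
        for i, j in pairs:
            t = mann_whitney(samples[i], samples[j])
            results.append(
                TestResult(
                    "mann_whitney_u", t.statistic, t.p_raw,
                    bonferroni(t.p_raw, m), "bonferroni",
                    (labels[i], labels[j]),
                )
            )
    return results


def welch_t(a, b) -> TestResult:
    """Welch two-sample t test (unequal variances)."""
    res = sps.ttest_ind(np.asarray(a, float), np.asarray(b, float), equal_var=False)
    return TestResult("welch_t", float(res.statistic), float(res.pvalue),
                      float(res.pvalue), "none")


def tukey_box(sample) -> TukeyBoxStats:
    """Tukey box-and-whisker summary of one sample (n >= 5)."""
    x = np.sort(np.asarray(sample, float).ravel())
    if x.size < 5:
        raise ValueError("need n >= 5")
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    iqr = q3 - q1
    inliers_low = x[x >= q1 - 1.5 * iqr]
    inliers_high = x[x <= q3 + 1.5 * iqr]
    return TukeyBoxStats(
        median=float(med),
        lower_hinge=float(q1),
        upper_hinge=float(q3),
        whisker_low=float(inliers_low[0]),
        whisker_high=float(inliers_high[-1]),
    )
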