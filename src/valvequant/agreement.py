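"""Agreement and comparison statistics for paired tissue measurements.

Implements the statistics used to compare CT-derived and histological
valve composition, and one reader against another:

* Spearman rank correlation (average ranks, t-approximation p value);
* intraclass correlation from two-way ANOVA mean squares — the
  absolute-agreement single-measure form ICC(A,1) as primary, with the
  consistency form ICC(C,1) also available;
* Bland-Altman bias, 95% limits of agreement (bias +/- 1.96 SD of the
  paired differences) and the coefficient of repeatability, defined as
  1.96*SD of differences, i.e. exactly half the LoA width;
* the paired Wilcoxon signed-rank test (exact null for small samples);
* Kruskal-Wallis across groups with Bonferroni-corrected pairwise
  rank-sum post hoc tests.

Qualitative bands for correlation/agreement follow the conventional cut
points: < 0.5 poor, 0.5-0.74 moderate, 0.75-0.90 good, > 0.90 excellent
(a value sitting exactly on a cut belongs to the band below the cut,
e.g. 0.90 is "good").
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as _sps  # distribution quantiles only
from scipy.stats import rankdata

__all__ = [
    "PairedMeasurements",
    "SpearmanResult",
    "ICCResult",
    "BlandAltmanResult",
    "WilcoxonResult",
    "RankSumResult",
    "GroupComparisonResult",
    "spearman",
    "icc",
    "bland_altman",
    "wilcoxon_paired",
    "rank_sum",
    "kruskal_wallis_posthoc",
    "agreement_band",
]


def agreement_band(value: float) -> str:
    """Qualitative band of a correlation/agreement magnitude."""
    v = abs(value)
    if v < 0.5:
        return "poor"
    if v < 0.75:
        return "moderate"
    if v <= 0.90:
        return "good"
    return "excellent"


@dataclass(frozen=True)
class PairedMeasurements:
    """Two aligned measurement series of the same quantity.

    ``label_a``/``label_b`` name the modalities or readers; differences are
    always oriented as ``a - b``.
    """

    series_a: np.ndarray
    series_b: np.ndarray
    label_a: str = "a"
    label_b: str = "b"
    unit: str = ""

    def __post_init__(self) -> None:
        a = np.asarray(self.series_a, dtype=float).ravel()
        b = np.asarray(self.series_b, dtype=float).ravel()
        if a.size != b.size:
            raise ValueError(f"series lengths differ: {a.size} vs {b.size}")
        if a.size < 3:
            raise ValueError("paired analysis requires n >= 3")
        if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
            raise ValueError("series must be pairwise complete (finite)")
        object.__setattr__(self, "series_a", a)
        object.__setattr__(self, "series_b", b)

    @property
    def n(self) -> int:
        return int(self.series_a.size)


# ---------------------------------------------------------------------------
# Spearman


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    p_value: float
    n: int
    band: str
    defined: bool


def spearman(pairs: PairedMeasurements) -> SpearmanResult:
    """Spearman rank correlation with average ranks for ties.

    rho is the Pearson correlation of the rank vectors; the two-sided p
    value uses the t approximation with n-2 degrees of freedom.  A constant
    series leaves rho undefined (flagged, rho = nan).
    """
    ra = rankdata(pairs.series_a, method="average")
    rb = rankdata(pairs.series_b, method="average")
    if np.ptp(ra) == 0 or np.ptp(rb) == 0:
        return SpearmanResult(float("nan"), float("nan"), pairs.n, "undefined", False)
    ra = ra - ra.mean()
    rb = rb - rb.mean()
    rho = float(np.dot(ra, rb) / math.sqrt(np.dot(ra, ra) * np.dot(rb, rb)))
    rho = max(-1.0, min(1.0, rho))
    n = pairs.n
    if abs(rho) == 1.0:
        p = 0.0
    else:
        t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
        p = float(2.0 * _sps.t.sf(abs(t), df=n - 2))
    return SpearmanResult(rho, p, n, agreement_band(rho), True)


# ---------------------------------------------------------------------------
# ICC


@dataclass(frozen=True)
class ICCResult:
    form: str  # "ICC(A,1)" or "ICC(C,1)"
    estimate: float
    ci95: tuple[float, float]
    band: str
    n: int
    degenerate: bool
    mean_squares: dict[str, float] = field(default_factory=dict)


def _anova_mean_squares(a: np.ndarray, b: np.ndarray) -> dict[str, float]:
    """Two-way mean squares for an n-subject x 2-rater table."""
    data = np.column_stack([a, b])
    n, k = data.shape
    grand = data.mean()
    subj = data.mean(axis=1)
    rater = data.mean(axis=0)
    ss_subj = k * np.sum((subj - grand) ** 2)
    ss_rater = n * np.sum((rater - grand) ** 2)
    # residual SS from the interaction residuals directly (stable when the
    # two series are identical, where subtraction of totals leaves fp dust)
    resid = data - subj[:, None] - rater[None, :] + grand
    ss_err = float(np.sum(resid**2))
    msb = ss_subj / (n - 1)
    msc = ss_rater / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    if mse <= 1e-12 * max(msb, msc, 1.0):
        mse = 0.0
    if msc <= 1e-12 * max(msb, 1.0):
        msc = 0.0
    return {"MSB": msb, "MSC": msc, "MSE": mse, "n": n, "k": k}


def icc(pairs: PairedMeasurements, form: str = "absolute") -> ICCResult:
    """Intraclass correlation for two raters/modalities from two-way ANOVA.

    ``form`` is "absolute" (two-way random, absolute agreement, single
    measure — penalises systematic offsets) or "consistency" (two-way
    mixed, consistency, single measure).  The 95% CI uses the standard
    F-distribution bounds.  Zero between-subject variance, or a perfect
    fit with zero error mean square, is flagged degenerate.
    """
    if form not in ("absolute", "consistency"):
        raise ValueError("form must be 'absolute' or 'consistency'")
    ms = _anova_mean_squares(pairs.series_a, pairs.series_b)
    msb, msc, mse = ms["MSB"], ms["MSC"], ms["MSE"]
    n, k = int(ms["n"]), int(ms["k"])
    name = "ICC(A,1)" if form == "absolute" else "ICC(C,1)"

    if msb <= 0:
        return ICCResult(name, float("nan"), (float("nan"), float("nan")),
                         "undefined", n, True, ms)
    if mse == 0 and (form == "consistency" or msc == 0):
        return ICCResult(name, 1.0, (1.0, 1.0), "excellent", n, True, ms)

    alpha = 0.05
    if form == "consistency":
        est = (msb - mse) / (msb + (k - 1) * mse)
        f_obs = msb / mse
        df1, df2 = n - 1, (n - 1) * (k - 1)
        fl = f_obs / _sps.f.ppf(1 - alpha / 2, df1, df2)
        fu = f_obs * _sps.f.ppf(1 - alpha / 2, df2, df1)
        ci = ((fl - 1) / (fl + k - 1), (fu - 1) / (fu + k - 1))
    else:
        denom = msb + (k - 1) * mse + (k / n) * (msc - mse)
        est = (msb - mse) / denom
        # Satterthwaite df for the rater+error combination (McGraw & Wong)
        a_ = (k * est) / (n * (1 - est)) if est < 1 else float("inf")
        b_ = 1 + (k * est * (n - 1)) / (n * (1 - est)) if est < 1 else float("inf")
        if math.isfinite(a_) and (a_ * msc + b_ * mse) > 0:
            v = (a_ * msc + b_ * mse) ** 2 / (
                (a_ * msc) ** 2 / (k - 1) + (b_ * mse) ** 2 / ((n - 1) * (k - 1))
            )
            f1 = _sps.f.ppf(1 - alpha / 2, n - 1, v)
            f2 = _sps.f.ppf(1 - alpha / 2, v, n - 1)
            lo = n * (msb - f1 * mse) / (
                f1 * (k * msc + (k * n - k - n) * mse) + n * msb
            )
            hi = n * (f2 * msb - mse) / (
                k * msc + (k * n - k - n) * mse + n * f2 * msb
            )
            ci = (lo, hi)
        else:
            ci = (est, est)
    est = min(est, 1.0)
    ci = (min(ci[0], est), max(ci[1], est))
    return ICCResult(name, float(est), (float(ci[0]), float(ci[1])),
                     agreement_band(est), n, False, ms)


# ---------------------------------------------------------------------------
# Bland-Altman


@dataclass(frozen=True)
class BlandAltmanResult:
    """Bias, 95% limits of agreement, and coefficient of repeatability.

    Differences are oriented a - b.  ``cor`` (coefficient of repeatability)
    is 1.96*SD of the differences, identically half the LoA width, so
    (loa_lower + loa_upper)/2 == bias and loa_upper - loa_lower == 2*cor.
    """

    bias: float
    sd_diff: float
    loa_lower: float
    loa_upper: float
    cor: float
    n: int
    means: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    diffs: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    @classmethod
    def from_loa(cls, loa_lower: float, loa_upper: float, n: int = 0) -> "BlandAltmanResult":
        """Reconstruct bias and repeatability from printed limits of agreement."""
        if loa_upper < loa_lower:
            raise ValueError("loa_upper must be >= loa_lower")
        bias = (loa_lower + loa_upper) / 2.0
        cor = (loa_upper - loa_lower) / 2.0
        return cls(bias=bias, sd_diff=cor / 1.96, loa_lower=loa_lower,
                   loa_upper=loa_upper, cor=cor, n=n)


def bland_altman(pairs: PairedMeasurements) -> BlandAltmanResult:
    """Bland-Altman analysis of a - b with 1.96*SD limits of agreement."""
    a, b = pairs.series_a, pairs.series_b
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    cor = 1.96 * sd
    return BlandAltmanResult(
        bias=bias,
        sd_diff=sd,
        loa_lower=bias - cor,
        loa_upper=bias + cor,
        cor=cor,
        n=pairs.n,
        means=(a + b) / 2.0,
        diffs=d,
    )


def bland_altman_plot(result: BlandAltmanResult, path: str, title: str = "") -> None:
    """Write a Bland-Altman scatter with bias and LoA lines to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(result.means, result.diffs, s=18, alpha=0.8)
    for y, style in ((result.bias, "-"), (result.loa_lower, "--"), (result.loa_upper, "--")):
        ax.axhline(y, linestyle=style, color="k", linewidth=1)
    ax.set_xlabel("mean of pair")
    ax.set_ylabel("difference (a - b)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# Wilcoxon signed rank (paired)


@dataclass(frozen=True)
class WilcoxonResult:
    w_plus: float
    n_effective: int
    p_value: float
    method: str  # "exact" or "normal"
    alternative: str
    degenerate: bool


def _signed_rank_exact_p(ranks: np.ndarray, w_obs: float, alternative: str) -> float:
    """Exact signed-rank p by enumerating all sign assignments of the realized ranks."""
    n = ranks.size
    sums = np.zeros(1)
    for r in ranks:  # convolve the +0 / +r distribution, handles tied ranks
        sums = np.concatenate([sums, sums + r])
    ge = float(np.mean(sums >= w_obs - 1e-12))
    le = float(np.mean(sums <= w_obs + 1e-12))
    if alternative == "greater":
        return ge
    if alternative == "less":
        return le
    return min(1.0, 2.0 * min(ge, le))


def wilcoxon_paired(
    pairs: PairedMeasurements, alternative: str = "two-sided", exact_max_n: int = 15
) -> WilcoxonResult:
    """Paired Wilcoxon signed-rank test on a - b.

    Zero differences are dropped; tied absolute differences get average
    ranks.  The null distribution is enumerated exactly (all 2^n sign
    assignments of the realized ranks) for n <= ``exact_max_n``, and a
    tie-corrected normal approximation with continuity correction is used
    above.  All-zero differences yield a degenerate-flagged result.
    """
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError("alternative must be two-sided/greater/less")
    d = pairs.series_a - pairs.series_b
    d = d[d != 0]
    n = d.size
    if n == 0:
        return WilcoxonResult(0.0, 0, float("nan"), "degenerate", alternative, True)
    if n < 5:
        raise ValueError(f"need >= 5 informative (nonzero) pairs, got {n}")
    ranks = rankdata(np.abs(d), method="average")
    w_plus = float(ranks[d > 0].sum())
    if n <= exact_max_n:
        p = _signed_rank_exact_p(ranks, w_plus, alternative)
        method = "exact"
    else:
        mean = n * (n + 1) / 4.0
        _, counts = np.unique(ranks, return_counts=True)
        tie_corr = np.sum(counts**3 - counts) / 48.0
        var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_corr
        z_num = w_plus - mean
        cc = 0.5 * np.sign(z_num) if alternative == "two-sided" else 0.5
        if alternative == "greater":
            z = (w_plus - mean - cc) / math.sqrt(var)
            p = float(_sps.norm.sf(z))
        elif alternative == "less":
            z = (w_plus - mean + cc) / math.sqrt(var)
            p = float(_sps.norm.cdf(z))
        else:
            z = (z_num - cc) / math.sqrt(var) if z_num != 0 else 0.0
            p = float(min(1.0, 2.0 * _sps.norm.sf(abs(z))))
        method = "normal"
    return WilcoxonResult(w_plus, n, p, method, alternative, False)


# ---------------------------------------------------------------------------
# Rank sum (two independent groups) and Kruskal-Wallis with post hoc


@dataclass(frozen=True)
class RankSumResult:
    w: float  # rank sum of the first group
    n1: int
    n2: int
    p_value: float


def rank_sum(x: Sequence[float], y: Sequence[float]) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum test, tie-corrected normal approximation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be nonempty")
    allv = np.concatenate([x, y])
    ranks = rankdata(allv, method="average")
    w = float(ranks[:n1].sum())
    n = n1 + n2
    mean = n1 * (n + 1) / 2.0
    _, counts = np.unique(allv, return_counts=True)
    tie = np.sum(counts**3 - counts) / (n * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie)
    if var <= 0:
        return RankSumResult(w, n1, n2, 1.0)
    z_num = w - mean
    z = (z_num - 0.5 * np.sign(z_num)) / math.sqrt(var) if z_num != 0 else 0.0
    p = float(min(1.0, 2.0 * _sps.norm.sf(abs(z))))
    return RankSumResult(w, n1, n2, p)


@dataclass(frozen=True)
class GroupComparisonResult:
    h_statistic: float
    df: int
    p_value: float
    pairwise: dict[tuple[str, str], float]  # Bonferroni-adjusted p values
    group_sizes: dict[str, int]


def kruskal_wallis_posthoc(groups: Mapping[str, Sequence[float]]) -> GroupComparisonResult:
    """Kruskal-Wallis H across labeled groups plus Bonferroni pairwise rank-sum tests.

    H carries the standard tie correction; its p value is from the
    chi-square distribution with (groups - 1) degrees of freedom.  Each
    pairwise two-group rank-sum p value is multiplied by the number of
    pairs and capped at 1.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    arrays = {g: np.asarray(groups[g], dtype=float).ravel() for g in names}
    if any(a.size == 0 for a in arrays.values()):
        raise ValueError("groups must be nonempty")
    allv = np.concatenate([arrays[g] for g in names])
    n = allv.size
    ranks = rankdata(allv, method="average")
    h = 0.0
    start = 0
    for g in names:
        m = arrays[g].size
        r = ranks[start : start + m].sum()
        h += r * r / m
        start += m
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    _, counts = np.unique(allv, return_counts=True)
    denom = 1.0 - np.sum(counts**3 - counts) / (n**3 - n)
    h = h / denom if denom > 0 else 0.0
    df = len(names) - 1
    p = float(_sps.chi2.sf(h, df))
    pairs = list(itertools.combinations(names, 2))
    pairwise = {
        (g1, g2): min(1.0, rank_sum(arrays[g1], arrays[g2]).p_value * len(pairs))
        for g1, g2 in pairs
    }
    return GroupComparisonResult(
        float(h), df, p, pairwise, {g: int(arrays[g].size) for g in names}
    )
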