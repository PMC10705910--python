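"""Correlation chemometrics and classical test statistics for spectra.

Assignment of an unknown GC-EI spectrum to a library standard is scored by
the Pearson correlation of relative intensities over a shared ion-key set.
Because silylated carbohydrates produce near-identical fragmentation
patterns, a single |r| rarely settles an assignment; the protocol therefore
couples the correlation with a two-group one-way ANOVA of the intensity and
m/z datasets (with a Bonferroni simultaneous interval on the mean
difference), a normality screen (Shapiro-Wilk plus a numerical
probability-plot summary), Cochran's C for variance homogeneity and a
one-sample Kolmogorov-Smirnov goodness-of-fit test.  An ambiguity flag is
raised when the top two candidates' |r| differ by less than a configurable
gap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .spectra import IonKey, MassSpectrum, MatchedIonTable, SpectrumLibrary, match_ions

__all__ = [
    "GroupSummary",
    "AnovaResult",
    "BonferroniComparison",
    "AssignmentResult",
    "RankingResult",
    "pearson_match",
    "rank_candidates",
    "anova_from_summary",
    "anova_from_data",
    "bonferroni_compare",
    "shapiro_wilk",
    "probability_plot_stats",
    "cochran_c",
    "ks_gof",
    "intensity_ratio",
    "DEFAULT_AMBIGUITY_GAP",
]

#: Default |r| gap below which the top two candidates are flagged ambiguous.
#: An observed top-two gap of ~0.046 between deoxy-glucose standards was too
#: small to settle an assignment; 0.05 is the working threshold.
DEFAULT_AMBIGUITY_GAP = 0.05


@dataclass(frozen=True)
class GroupSummary:
    """Sample size, mean and sample standard deviation of one group."""

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("group summary requires n >= 2")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")

    @property
    def se(self) -> float:
        """Standard error of the mean, sd / sqrt(n)."""
        return self.sd / math.sqrt(self.n)

    @classmethod
    def from_data(cls, x) -> "GroupSummary":
        x = np.asarray(x, dtype=float)
        if x.size < 2:
            raise ValueError("need at least 2 observations")
        return cls(n=int(x.size), mean=float(x.mean()), sd=float(x.std(ddof=1)))


@dataclass(frozen=True)
class AnovaResult:
    """One-way ANOVA decomposition for the two-group comparison."""

    ss_model: float
    ss_error: float
    df_model: int
    df_error: int
    f_value: float
    p_value: float
    alpha: float
    grand_mean: float

    @property
    def ms_model(self) -> float:
        return self.ss_model / self.df_model

    @property
    def ms_error(self) -> float:
        return self.ss_error / self.df_error

    @property
    def verdict(self) -> bool:
        """True when the group means differ significantly at ``alpha``."""
        return self.p_value <= self.alpha

    def summary(self) -> str:
        lines = [
            "One-way ANOVA",
            f"{'Source':<8}{'DoF':>5}{'Sum of squares':>18}{'Mean square':>16}"
            f"{'F value':>12}{'P value':>12}",
            f"{'Model':<8}{self.df_model:>5}{self.ss_model:>18.6f}"
            f"{self.ms_model:>16.6f}{self.f_value:>12.5f}{self.p_value:>12.5f}",
            f"{'Error':<8}{self.df_error:>5}{self.ss_error:>18.3f}"
            f"{self.ms_error:>16.6f}",
            (
                f"At the {self.alpha} level, the population means are "
                + ("significantly different" if self.verdict else "not significantly different")
            ),
        ]
        return "\n".join(lines)


@dataclass(frozen=True)
class BonferroniComparison:
    """Simultaneous confidence interval on a difference of group means."""

    mean_difference: float
    ci_lower: float
    ci_upper: float
    alpha: float

    @property
    def significant(self) -> bool:
        return not (self.ci_lower <= 0.0 <= self.ci_upper)


@dataclass(frozen=True)
class AssignmentResult:
    """Correlation score of one query/candidate spectrum pair."""

    query_name: str
    candidate_name: str
    r: float
    n_ions: int
    ion_subset: tuple[IonKey, ...] = ()
    excluded_ions: tuple[IonKey, ...] = ()
    comparable: bool = True

    @property
    def abs_r(self) -> float:
        return abs(self.r)


@dataclass
class RankingResult:
    """Candidates ranked by |r|, with an ambiguity verdict on the top two."""

    query_name: str
    results: list[AssignmentResult]
    ambiguity_gap: float
    ambiguous: bool = field(init=False)
    top_gap: float | None = field(init=False)

    def __post_init__(self) -> None:
        comparable = [a for a in self.results if a.comparable]
        if len(comparable) >= 2:
            self.top_gap = comparable[0].abs_r - comparable[1].abs_r
            self.ambiguous = self.top_gap < self.ambiguity_gap
        else:
            self.top_gap = None
            self.ambiguous = False


# ---------------------------------------------------------------------------
# Pearson assignment
# ---------------------------------------------------------------------------

def pearson_match(
    table: MatchedIonTable,
    a: str,
    b: str,
    exclude: tuple[IonKey, ...] = (),
) -> AssignmentResult:
    """Pearson correlation of two spectra over pairwise-complete ions.

    Ions in ``exclude`` (matched by label) are dropped first; a cell missing
    in either spectrum removes that ion for this pair only.  At least three
    usable ions are required and neither intensity vector may be constant.
    The signed r is retained; callers report |r|.
    """
    excluded_labels = {k.label for k in exclude}
    keep = [i for i, key in enumerate(table.ions) if key.label not in excluded_labels]
    xa = table.column(a)[keep]
    xb = table.column(b)[keep]
    mask = ~(np.isnan(xa) | np.isnan(xb))
    used = [table.ions[keep[i]] for i in np.flatnonzero(mask)]
    xa, xb = xa[mask], xb[mask]
    if xa.size < 3:
        raise ValueError(
            f"pair ({a!r}, {b!r}): only {xa.size} pairwise-complete ions "
            "(need >= 3)"
        )
    for name, v in ((a, xa), (b, xb)):
        if np.ptp(v) == 0:
            raise ValueError(f"column {name!r} is constant over the usable ions")
    r = float(np.corrcoef(xa, xb)[0, 1])
    return AssignmentResult(
        query_name=a,
        candidate_name=b,
        r=r,
        n_ions=int(xa.size),
        ion_subset=tuple(used),
        excluded_ions=tuple(exclude),
    )


def rank_candidates(
    query: MassSpectrum,
    lib: SpectrumLibrary,
    ion_keys: tuple[IonKey, ...],
    tolerance: float = 0.5,
    exclude: tuple[IonKey, ...] = (),
    ambiguity_gap: float = DEFAULT_AMBIGUITY_GAP,
) -> RankingResult:
    """Score a query spectrum against every library entry and rank by |r|.

    Candidates sharing fewer than three usable ions with the query are kept
    in the result, marked not comparable (r = NaN), rather than silently
    dropped.  The ranking is flagged ambiguous when the top two |r| values
    differ by less than ``ambiguity_gap``.
    """
    if len(lib) == 0:
        raise ValueError("library is empty")
    spectra = [query] + [s for s in lib if s.name != query.name]
    table = match_ions(spectra, list(ion_keys), tolerance=tolerance)
    results: list[AssignmentResult] = []
    for cand in lib.names():
        if cand == query.name:
            results.append(
                AssignmentResult(query.name, cand, r=1.0, n_ions=len(ion_keys))
            )
            continue
        try:
            results.append(pearson_match(table, query.name, cand, exclude=exclude))
        except ValueError:
            results.append(
                AssignmentResult(
                    query.name, cand, r=math.nan, n_ions=0, comparable=False
                )
            )
    results.sort(
        key=lambda a: (a.comparable, a.abs_r if a.comparable else -1.0),
        reverse=True,
    )
    return RankingResult(
        query_name=query.name, results=results, ambiguity_gap=ambiguity_gap
    )


# ---------------------------------------------------------------------------
# ANOVA / Bonferroni
# ---------------------------------------------------------------------------

def anova_from_summary(
    g1: GroupSummary, g2: GroupSummary, alpha: float = 0.05
) -> AnovaResult:
    """Two-group one-way ANOVA from group summaries.

    SS_model = sum n_i (mean_i - grand_mean)^2, SS_error = sum (n_i-1) sd_i^2
    with df = (1, n1 + n2 - 2).  A zero error sum of squares with unequal
    means yields F = +inf, p = 0.
    """
    n = g1.n + g2.n
    grand = (g1.n * g1.mean + g2.n * g2.mean) / n
    ss_model = g1.n * (g1.mean - grand) ** 2 + g2.n * (g2.mean - grand) ** 2
    ss_error = (g1.n - 1) * g1.sd**2 + (g2.n - 1) * g2.sd**2
    df_model, df_error = 1, n - 2
    if ss_error == 0.0:
        f_value = math.inf if ss_model > 0 else 0.0
        p_value = 0.0 if ss_model > 0 else 1.0
    else:
        f_value = (ss_model / df_model) / (ss_error / df_error)
        p_value = float(stats.f.sf(f_value, df_model, df_error))
    return AnovaResult(
        ss_model=ss_model,
        ss_error=ss_error,
        df_model=df_model,
        df_error=df_error,
        f_value=f_value,
        p_value=p_value,
        alpha=alpha,
        grand_mean=grand,
    )


def anova_from_data(x1, x2, alpha: float = 0.05) -> AnovaResult:
    """One-way ANOVA from two raw vectors (identical to the summary form
    applied to their sample summaries)."""
    return anova_from_summary(
        GroupSummary.from_data(x1), GroupSummary.from_data(x2), alpha=alpha
    )


def bonferroni_compare(
    g1: GroupSummary,
    g2: GroupSummary,
    ms_error: float,
    df_error: int,
    alpha: float = 0.05,
) -> BonferroniComparison:
    """Bonferroni simultaneous confidence interval on mean1 - mean2.

    With exactly two groups there is a single comparison, so the Bonferroni
    factor is 1 and the interval is the plain t-interval on the pooled
    mean-square error:  diff +/- t(1 - alpha/2, df) * sqrt(MSE (1/n1 + 1/n2)).
    """
    if ms_error <= 0:
        raise ValueError("ms_error must be > 0")
    if df_error < 1:
        raise ValueError("df_error must be >= 1")
    diff = g1.mean - g2.mean
    half = float(
        stats.t.ppf(1 - alpha / 2, df_error)
        * math.sqrt(ms_error * (1 / g1.n + 1 / g2.n))
    )
    return BonferroniComparison(
        mean_difference=diff, ci_lower=diff - half, ci_upper=diff + half, alpha=alpha
    )


# ---------------------------------------------------------------------------
# Normality / homogeneity / goodness-of-fit screens
# ---------------------------------------------------------------------------

def shapiro_wilk(x) -> tuple[float, float]:
    """Shapiro-Wilk W and p (Royston's approximation), 3 <= n <= 5000."""
    x = np.asarray(x, dtype=float)
    if not 3 <= x.size <= 5000:
        raise ValueError(f"Shapiro-Wilk requires 3 <= n <= 5000, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("constant vector has zero variance")
    w, p = stats.shapiro(x)
    return float(w), float(p)


def probability_plot_stats(
    x, outlier_threshold: float = 2.0
) -> tuple[float, np.ndarray]:
    """Numerical summary of a normal probability plot.

    Returns the Pearson correlation between the order statistics and Blom
    plotting-position normal quantiles ((i - 3/8)/(n + 1/4)), plus indices
    (into the sorted sample) of points whose standardized residual from the
    fitted straight line exceeds ``outlier_threshold``.  A straight plot
    (r_plot near 1) indicates normally distributed measurands.
    """
    x = np.sort(np.asarray(x, dtype=float))
    n = x.size
    if n < 3:
        raise ValueError("need n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("constant vector")
    q = stats.norm.ppf((np.arange(1, n + 1) - 0.375) / (n + 0.25))
    r_plot = float(np.corrcoef(q, x)[0, 1])
    slope, intercept = np.polyfit(q, x, 1)
    resid = x - (slope * q + intercept)
    s = resid.std(ddof=2) if n > 2 else 0.0
    if s == 0:
        outliers = np.array([], dtype=int)
    else:
        outliers = np.flatnonzero(np.abs(resid / s) > outlier_threshold)
    return r_plot, outliers


def cochran_c(
    groups: list[GroupSummary], alpha: float = 0.05
) -> tuple[float, bool]:
    """Cochran's C test of variance homogeneity across groups.

    C = max(sd_i^2) / sum(sd_i^2), compared with the critical value
    C_crit = [1 + (k-1)/F_{1-alpha/k}(df, (k-1) df)]^{-1} at the groups'
    average degrees of freedom.  Returns (C, significant).
    """
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    variances = np.array([g.sd**2 for g in groups])
    total = variances.sum()
    if total == 0:
        raise ValueError("all group variances are zero")
    c = float(variances.max() / total)
    k = len(groups)
    df = np.mean([g.n - 1 for g in groups])
    f_crit = stats.f.ppf(1 - alpha / k, df, (k - 1) * df)
    c_crit = 1.0 / (1.0 + (k - 1) / f_crit)
    return c, c > c_crit


def ks_gof(x, cdf) -> tuple[float, float]:
    """One-sample Kolmogorov-Smirnov test against a fully specified CDF.

    ``cdf`` is either a frozen scipy distribution or a ``(name, *params)``
    tuple, e.g. ``("norm", 0.0, 1.0)``.  Returns (D, p).
    """
    x = np.asarray(x, dtype=float)
    if x.size < 1:
        raise ValueError("need n >= 1")
    if isinstance(cdf, tuple):
        name, *params = cdf
        if not params:
            raise ValueError(
                f"distribution {name!r} given without parameters; the KS "
                "goodness-of-fit test needs a fully specified distribution"
            )
        frozen = getattr(stats, name)(*params)
    else:
        frozen = cdf
    res = stats.kstest(x, frozen.cdf)
    return float(res.statistic), float(res.pvalue)


def intensity_ratio(
    spec: MassSpectrum, num: IonKey, den: IonKey, tolerance: float = 0.5
) -> float:
    """Ratio of two peak intensities, e.g. the I(191)/I(179) diagnostic that
    separates positional and cis/trans isomers of caffeoylquinic acid."""
    def lookup(key: IonKey) -> float:
        for target in (key.primary_mz, *key.alternates):
            ri = spec.intensity_at(target, tolerance)
            if ri is not None:
                return ri
        raise ValueError(f"spectrum {spec.name!r}: no peak matches ion {key.label}")

    numerator = lookup(num)
    denominator = lookup(den)
    if denominator == 0:
        raise ValueError(f"denominator ion {den.label} has zero intensity")
    return numerator / denominator
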