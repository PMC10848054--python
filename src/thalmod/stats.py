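"""Group-comparison and correlation statistics with Bonferroni correction.

The statistical battery mirrors a conventional clinical-neuroimaging
analysis: a one-sample Kolmogorov–Smirnov normality gate chooses between
parametric (pooled-variance t, one-way ANOVA) and rank-based tests
(Mann–Whitney U with tie-corrected normal approximation, Kruskal–Wallis H);
categorical variables use Pearson's chi-square without continuity
correction; cognitive screening scores below 26 denote impairment;
families of tests are Bonferroni-corrected at alpha = 0.05.

Summary-statistic entry points (means/SDs/n) are provided alongside the
raw-data ones with identical algebra, so published demographic tables can
be re-analysed without raw data.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

MOCA_CUTOFF = 26
ALPHA = 0.05


@dataclass
class StatResult:
    test_name: str
    statistic: float
    p_value: float
    df: float | tuple | None = None
    n: int | None = None
    corrected_p: float | None = None
    family_id: str | None = None
    extra: dict | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ValueError("p_value must lie in [0, 1]")


def classify_moca(score: int) -> str:
    """'CI' (cognitively impaired) iff the score is below 26, else 'CN'."""
    if not 0 <= score <= 30:
        raise ValueError(f"MoCA score {score} outside [0, 30]")
    return "CI" if score < MOCA_CUTOFF else "CN"


def ks_normality(sample: np.ndarray) -> tuple[StatResult, bool]:
    """One-sample KS test against a normal with the sample's mean/SD.

    ``is_normal`` is True when p >= 0.05. A constant sample is flagged
    non-normal outright.
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 5:
        raise ValueError("need at least 5 observations for the normality gate")
    sd = x.std(ddof=1)
    if sd == 0:
        # degenerate sample: maximal distance from any normal
        return StatResult("ks", 1.0, 0.0, n=x.size), False
    stat, p = sps.kstest(x, "norm", args=(x.mean(), sd))
    return StatResult("ks", float(stat), float(p), n=x.size), bool(p >= ALPHA)


# ---------------------------------------------------------------------------
# parametric tests


def student_t(group1: np.ndarray, group2: np.ndarray, welch: bool = False) -> StatResult:
    """Two-sided independent-samples t test (pooled variance by default)."""
    g1, g2 = np.asarray(group1, float), np.asarray(group2, float)
    if g1.size < 2 or g2.size < 2:
        raise ValueError("each group needs n >= 2")
    if g1.std(ddof=1) == 0 and g2.std(ddof=1) == 0:
        raise ValueError("both groups have zero variance")
    t, p = sps.ttest_ind(g1, g2, equal_var=not welch)
    df = g1.size + g2.size - 2 if not welch else None
    name = "welch_t" if welch else "student_t"
    return StatResult(name, float(t), float(p), df=df, n=g1.size + g2.size)


def student_t_from_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int,
    welch: bool = False,
) -> StatResult:
    """Pooled t from summary statistics; same algebra as :func:`student_t`."""
    t, p = sps.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2, equal_var=not welch)
    name = "welch_t" if welch else "student_t"
    return StatResult(name, float(t), float(p), df=None if welch else n1 + n2 - 2, n=n1 + n2)


def one_way_anova(*groups: np.ndarray) -> StatResult:
    """One-way ANOVA F over two or more groups."""
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    arrays = [np.asarray(g, float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs n >= 2")
    if all(a.std(ddof=1) == 0 for a in arrays):
        raise ValueError("within-group variance is zero; F undefined")
    f, p = sps.f_oneway(*arrays)
    k = len(arrays)
    n = sum(a.size for a in arrays)
    return StatResult("one_way_anova", float(f), float(p), df=(k - 1, n - k), n=n)


def anova_from_summary(summaries: list[tuple[float, float, int]]) -> StatResult:
    """One-way ANOVA reconstructed from per-group (mean, SD, n)."""
    if len(summaries) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    means = np.array([s[0] for s in summaries], float)
    sds = np.array([s[1] for s in summaries], float)
    ns = np.array([s[2] for s in summaries], int)
    n = ns.sum()
    k = len(summaries)
    grand = (ns * means).sum() / n
    ss_between = (ns * (means - grand) ** 2).sum()
    ss_within = ((ns - 1) * sds**2).sum()
    if ss_within == 0:
        raise ValueError("within-group variance is zero; F undefined")
    f = (ss_between / (k - 1)) / (ss_within / (n - k))
    p = sps.f.sf(f, k - 1, n - k)
    return StatResult("one_way_anova", float(f), float(p), df=(k - 1, int(n - k)), n=int(n))


# ---------------------------------------------------------------------------
# rank-based tests


def _tie_correction_terms(pooled: np.ndarray) -> float:
    _, counts = np.unique(pooled, return_counts=True)
    return float((counts**3 - counts).sum())


def mann_whitney_u(group1, group2, method: str = "auto") -> StatResult:
    """Two-sided Mann–Whitney U with a tie-corrected z statistic.

    ``method='exact'`` (automatic for total n <= 10 without ties) uses the
    exact null distribution of U; otherwise the p value comes from the
    normal approximation without continuity correction, consistent with the
    reported z.
    """
    g1, g2 = np.asarray(group1, float), np.asarray(group2, float)
    n1, n2 = g1.size, g2.size
    pooled = np.concatenate([g1, g2])
    has_ties = np.unique(pooled).size < pooled.size
    if method == "auto":
        method = "exact" if (n1 + n2 <= 10 and not has_ties) else "asymptotic"

    u1 = float(sps.mannwhitneyu(g1, g2, alternative="two-sided", method="exact"
                                if method == "exact" else "asymptotic").statistic)
    mu = n1 * n2 / 2.0
    nn = n1 + n2
    sigma2 = n1 * n2 / 12.0 * ((nn + 1) - _tie_correction_terms(pooled) / (nn * (nn - 1)))
    z = 0.0 if sigma2 == 0 else (u1 - mu) / np.sqrt(sigma2)
    if method == "exact":
        p = float(sps.mannwhitneyu(g1, g2, alternative="two-sided", method="exact").pvalue)
    else:
        p = float(2 * sps.norm.sf(abs(z)))
    return StatResult("mann_whitney_u", float(z), p, n=nn, extra={"U": u1, "z": float(z)})


def _kruskal_h(ranks_by_group: list[np.ndarray], n: int, tie_term: float) -> float:
    h = 12.0 / (n * (n + 1)) * sum(r.sum() ** 2 / r.size for r in ranks_by_group) - 3 * (n + 1)
    correction = 1.0 - tie_term / (n**3 - n)
    return h / correction if correction > 0 else 0.0


def kruskal_wallis(*groups, method: str = "auto") -> StatResult:
    """Kruskal–Wallis H with tie correction; exact p by enumeration for
    total n <= 10 (``method='exact'`` / automatic), chi-square reference
    otherwise."""
    arrays = [np.asarray(g, float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("Kruskal-Wallis needs at least 2 groups")
    if any(a.size == 0 for a in arrays):
        raise ValueError("Kruskal-Wallis groups must be non-empty")
    pooled = np.concatenate(arrays)
    n = pooled.size
    sizes = [a.size for a in arrays]
    if method == "auto":
        method = "exact" if n <= 10 else "asymptotic"
    ranks = sps.rankdata(pooled)
    tie_term = _tie_correction_terms(pooled)
    bounds = np.cumsum([0] + sizes)
    h_obs = _kruskal_h(
        [ranks[bounds[i]: bounds[i + 1]] for i in range(len(sizes))], n, tie_term
    )
    if method == "asymptotic":
        p = float(sps.chi2.sf(h_obs, len(arrays) - 1))
    else:
        # enumerate all assignments of rank positions to groups
        count = total = 0
        idx_all = range(n)

        def assignments(remaining: tuple, szs: list[int]):
            if not szs:
                yield []
                return
            for combo in itertools.combinations(remaining, szs[0]):
                rest = tuple(i for i in remaining if i not in combo)
                for tail in assignments(rest, szs[1:]):
                    yield [combo] + tail

        for assign in assignments(tuple(idx_all), sizes):
            h = _kruskal_h([ranks[list(c)] for c in assign], n, tie_term)
            total += 1
            if h >= h_obs - 1e-12:
                count += 1
        p = count / total
    return StatResult("kruskal_wallis_h", float(h_obs), float(p), df=len(arrays) - 1, n=n)


def chi_square(table: np.ndarray) -> StatResult:
    """Pearson chi-square on an r x c contingency table, no continuity
    correction."""
    table = np.asarray(table, dtype=float)
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("contingency table has a zero margin")
    chi2, p, df, _ = sps.chi2_contingency(table, correction=False)
    return StatResult("chi_square", float(chi2), float(p), df=int(df), n=int(table.sum()))


# ---------------------------------------------------------------------------
# multiple comparisons and correlations


def bonferroni(results: list[StatResult], family_id: str = "") -> list[StatResult]:
    """corrected_p = min(1, m * p) with m the family size."""
    m = len(results)
    if m < 1:
        raise ValueError("empty test family")
    return [
        replace(r, corrected_p=min(1.0, m * r.p_value), family_id=family_id or r.family_id)
        for r in results
    ]


def metric_moca_correlation(metric: np.ndarray, moca: np.ndarray) -> StatResult:
    """Correlation between a network metric and MoCA scores.

    Pearson when both variables pass the KS normality gate, Spearman
    otherwise; two-sided p.
    """
    metric = np.asarray(metric, float)
    moca = np.asarray(moca, float)
    if metric.size != moca.size:
        raise ValueError("metric and MoCA vectors differ in length")
    if metric.size < 5:
        raise ValueError("need n >= 5 per group for correlation")
    if metric.std(ddof=1) == 0:
        raise ValueError("metric is constant; correlation undefined")
    _, normal_metric = ks_normality(metric)
    _, normal_moca = ks_normality(moca)
    if normal_metric and normal_moca:
        r, p = sps.pearsonr(metric, moca)
        return StatResult("pearson_r", float(r), float(p), n=metric.size)
    rho, p = sps.spearmanr(metric, moca)
    return StatResult("spearman_rho", float(rho), float(p), n=metric.size)


def auto_two_sample(g1, g2) -> StatResult:
    """t test when both samples pass the normality gate, else Mann–Whitney."""
    g1, g2 = np.asarray(g1, float), np.asarray(g2, float)
    try:
        normal = ks_normality(g1)[1] and ks_normality(g2)[1]
    except ValueError:
        normal = False
    return student_t(g1, g2) if normal else mann_whitney_u(g1, g2)


def auto_k_sample(*groups) -> StatResult:
    """ANOVA when every sample passes the normality gate, else
    Kruskal–Wallis."""
    arrays = [np.asarray(g, float) for g in groups]
    try:
        normal = all(ks_normality(a)[1] for a in arrays)
    except ValueError:
        normal = False
    return one_way_anova(*arrays) if normal else kruskal_wallis(*arrays, method="asymptotic")


# ---------------------------------------------------------------------------
# the demographic/clinical battery

_REQUIRED_COLUMNS = (
    "subject_id", "group", "age", "sex", "education",
    "onset_age", "duration", "seizure_freq", "aed", "moca",
)


def run_table1(phenotypes: pd.DataFrame) -> pd.DataFrame:
    """Demographic/clinical test battery over the three study groups.

    For every variable: a three-group comparison (HC vs patients with
    normal cognition vs impaired patients; ANOVA or Kruskal–Wallis by the
    normality gate, chi-square for categoricals) and the matching pairwise
    comparison (patients-vs-controls, or impaired-vs-intact for clinical
    variables controls lack).
    """
    missing = [c for c in _REQUIRED_COLUMNS if c not in phenotypes.columns]
    if missing:
        raise ValueError(f"phenotype table is missing columns: {', '.join(missing)}")
    df = phenotypes
    hc = df[df.group == "HC"]
    cn = df[df.group == "TLE-CN"]
    ci = df[df.group == "TLE-CI"]
    tle = df[df.group.isin(["TLE-CN", "TLE-CI"])]

    rows = []

    def emit(variable: str, comparison: str, fn, *args) -> None:
        # comparisons a degenerate sample (empty/constant group) cannot
        # support are skipped rather than reported with an invalid p
        try:
            res = fn(*args)
        except ValueError:
            return
        rows.append(dict(variable=variable, comparison=comparison, test=res.test_name,
                         statistic=res.statistic, p_value=res.p_value, n=res.n))

    for var in ("age", "education", "moca"):
        emit(var, "3-group", auto_k_sample, ci[var], cn[var], hc[var])
        emit(var, "TLE-vs-HC", auto_two_sample, tle[var], hc[var])

    sex_3 = np.array([
        [(ci.sex == "M").sum(), (cn.sex == "M").sum(), (hc.sex == "M").sum()],
        [(ci.sex == "F").sum(), (cn.sex == "F").sum(), (hc.sex == "F").sum()],
    ])
    emit("sex", "3-group", chi_square, sex_3)
    sex_2 = np.array([
        [(tle.sex == "M").sum(), (hc.sex == "M").sum()],
        [(tle.sex == "F").sum(), (hc.sex == "F").sum()],
    ])
    emit("sex", "TLE-vs-HC", chi_square, sex_2)

    for var in ("onset_age", "duration", "seizure_freq"):
        emit(var, "CI-vs-CN", auto_two_sample, ci[var].dropna(), cn[var].dropna())

    aed = np.array([
        [(ci.aed == "mono").sum(), (cn.aed == "mono").sum()],
        [(ci.aed == "poly").sum(), (cn.aed == "poly").sum()],
    ])
    emit("aed", "CI-vs-CN", chi_square, aed)

    return pd.DataFrame(rows)
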