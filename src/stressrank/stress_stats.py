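"""Longitudinal statistics: change scores, split-plot ANOVA, post hocs, correlations.

The core inferential tool is the two-way mixed (split-plot) repeated-measures
ANOVA with time as the within-subjects factor and a grouping label (rank class,
dyad type, appearance stratum) as the between-subjects factor. Sphericity of
the within-subject covariance is assessed with Mauchly's test; when it is
rejected (p < 0.05) and the within factor has more than two levels, the
within and interaction degrees of freedom are scaled by the Greenhouse-Geisser
epsilon before computing p-values. Effect sizes are partial eta squared,
SS_effect / (SS_effect + SS_error).

Relative change between two sample points i and j is the signed proportion
(X_i - X_j) / X_j (0.10 means a 10% increase), undefined when X_j = 0.

Correlations with "social rank" use a rank-collapsed procedure that absorbs
colony-level differences: both variables are converted to within-group average
ranks, the groups are pooled, and a two-tailed Pearson correlation is computed
on the pooled ranks. First-order partial correlation controls one covariate
through the standard formula with n - 3 degrees of freedom.
"""

from __future__ import annotations

import enum
import logging
import re
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "UndefinedChangeError",
    "CorrelationMethod",
    "CorrelationResult",
    "MixedAnovaResult",
    "change_score",
    "change_table",
    "mixed_anova",
    "holm_adjust",
    "posthoc_time_contrasts",
    "rank_collapse_correlation",
    "partial_correlation",
]

logger = logging.getLogger(__name__)


class UndefinedChangeError(ValueError):
    """Relative change from a zero reference value is undefined."""


class CorrelationMethod(str, enum.Enum):
    PEARSON = "PEARSON"
    RANK_COLLAPSED = "RANK_COLLAPSED"
    PARTIAL = "PARTIAL"


@dataclass
class CorrelationResult:
    r: float
    p: float
    n: int
    method: CorrelationMethod

    def __iter__(self):
        return iter((self.r, self.p, self.n, self.method))


def _contrast_label(later: str, earlier: str) -> str:
    """``S2``/``S1`` -> ``S2vs1``; ``W2``/``W0`` -> ``W2vs0``; else ``AvsB``."""
    m_l = re.fullmatch(r"([A-Za-z])(\d+)", str(later))
    m_e = re.fullmatch(r"([A-Za-z])(\d+)", str(earlier))
    if m_l and m_e and m_l.group(1) == m_e.group(1):
        return f"{later}vs{m_e.group(2)}"
    return f"{later}vs{earlier}"


def change_score(x_i: float, x_j: float) -> float:
    """Relative change (x_i - x_j) / x_j between sample points i and j."""
    if x_j == 0:
        raise UndefinedChangeError("reference value is 0; relative change undefined")
    return (x_i - x_j) / x_j


def change_table(
    wide: pd.DataFrame, pairs: Sequence[tuple[str, str]] | None = None
) -> pd.DataFrame:
    """Per-unit relative changes for each (later, earlier) timepoint pair.

    ``wide`` is units x ordered timepoints. By default all C(T, 2) pairs are
    compared, labeled like ``"S2vs1"`` from columns S1..S3 (or ``"W2vs0"``).
    Undefined changes (reference 0) become NaN with a logged warning, never a
    silent 0.
    """
    cols = list(wide.columns)
    if pairs is None:
        pairs = [(cols[i], cols[j]) for j in range(len(cols)) for i in range(j + 1, len(cols))]
    out = {}
    for later, earlier in pairs:
        label = _contrast_label(later, earlier)
        ref = wide[earlier].to_numpy(dtype=float)
        val = wide[later].to_numpy(dtype=float)
        undefined = ref == 0
        if undefined.any():
            logger.warning(
                "%d unit(s) have a zero reference at %s; change set to missing",
                int(undefined.sum()),
                earlier,
            )
        with np.errstate(invalid="ignore", divide="ignore"):
            delta = np.where(undefined, np.nan, (val - ref) / np.where(undefined, 1.0, ref))
        out[label] = delta
    return pd.DataFrame(out, index=wide.index)


# ---------------------------------------------------------------------------
# Mixed (split-plot) repeated-measures ANOVA
# ---------------------------------------------------------------------------


@dataclass
class MixedAnovaResult:
    """Split-plot ANOVA summary: one row each for within, between, interaction.

    ``table`` has columns SS, df1, df2, MS, F, p_unc, p (GG-corrected when
    applied, otherwise equal to p_unc) and partial_eta_sq. Sphericity
    diagnostics apply to the within factor.
    """

    table: pd.DataFrame
    mauchly_w: float
    mauchly_p: float
    epsilon: float
    gg_applied: bool
    within: str
    between: str

    def summary(self) -> str:
        lines = [
            "Mixed repeated-measures ANOVA "
            f"(within: {self.within}, between: {self.between})",
            self.table.to_string(float_format=lambda v: f"{v:.4f}"),
            f"Mauchly W = {self.mauchly_w:.4f} (p = {self.mauchly_p:.4f}); "
            f"GG epsilon = {self.epsilon:.4f}; correction applied: {self.gg_applied}",
        ]
        return "\n".join(lines)


def _mauchly(pivot: np.ndarray) -> tuple[float, float]:
    """Mauchly's sphericity test on a subjects x levels matrix.

    Returns (W, p) using the chi-square approximation with the second-order
    correction term (as in ezANOVA). W and p are (nan, 1.0) for two levels,
    where sphericity holds trivially.
    """
    n, k = pivot.shape
    d = k - 1
    if k <= 2:
        return float("nan"), 1.0
    S = np.cov(pivot, rowvar=False, ddof=1)
    # population (double-centered) covariance; its d nonzero eigenvalues
    S_pop = S - S.mean(axis=0)[None, :] - S.mean(axis=1)[:, None] + S.mean()
    eig = np.linalg.eigvalsh(S_pop)[1:]
    if eig.max() <= 0:  # no within-subject variance at all
        return float("nan"), 1.0
    tol = np.finfo(float).eps * eig.max() * d
    eig = eig[eig > tol]
    W = float(np.prod(eig) / (eig.sum() / d) ** d)
    f = 1 - (2 * d**2 + d + 2) / (6 * d * (n - 1))
    w2 = (
        (d + 2) * (d - 1) * (d - 2) * (2 * d**3 + 6 * d**2 + 3 * k + 2)
        / (288 * ((n - 1) * d * f) ** 2)
    )
    chi_sq = -(n - 1) * f * np.log(W)
    ddof = d * (d + 1) / 2 - 1
    p1 = stats.chi2.sf(chi_sq, ddof)
    p2 = stats.chi2.sf(chi_sq, ddof + 4)
    return W, float(p1 + w2 * (p2 - p1))


def _gg_epsilon(pivot: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the sample covariance of the levels."""
    k = pivot.shape[1]
    if k <= 2:
        return 1.0
    S = np.cov(pivot, rowvar=False, ddof=1)
    mean_var = np.diag(S).mean()
    grand = S.mean()
    num = (k * (mean_var - grand)) ** 2
    den = (k - 1) * ((S**2).sum() - 2 * k * (S.mean(axis=1) ** 2).sum() + k**2 * grand**2)
    if den == 0:
        return 1.0
    return float(min(num / den, 1.0))


def mixed_anova(
    data: pd.DataFrame,
    dv: str = "value",
    within: str = "time",
    between: str = "group",
    subject: str = "unit",
    gg_alpha: float = 0.05,
) -> MixedAnovaResult:
    """Two-way mixed ANOVA: ``within`` repeated over units nested in ``between``.

    Requires a balanced within factor (every unit observed at every level)
    and at least two units per between level. Units with any missing value
    are dropped listwise with a logged warning.
    """
    data = data[[subject, within, between, dv]].copy()
    n_before = data[subject].nunique()
    piv = data.pivot_table(index=[subject, between], columns=within, values=dv, aggfunc="mean")
    complete = piv.dropna()
    if len(complete) < len(piv):
        logger.warning("dropped %d unit(s) with missing values (listwise)", len(piv) - len(complete))
    piv = complete
    if piv.index.get_level_values(0).nunique() < n_before and len(piv) == 0:
        raise ValueError("no complete units remain")
    counts = data.groupby(subject)[within].nunique()
    k = data[within].nunique()
    if piv.empty or piv.shape[1] != k:
        raise ValueError("unbalanced within factor: every unit must be observed at every level")
    groups = piv.index.get_level_values(1)
    group_sizes = pd.Series(groups).value_counts()
    if (group_sizes < 2).any():
        bad = group_sizes[group_sizes < 2].index.tolist()
        raise ValueError(f"between level(s) with fewer than 2 units: {bad}")

    Y = piv.to_numpy(dtype=float)  # N subjects x k levels
    N = Y.shape[0]
    G = group_sizes.size
    grand = Y.mean()

    ss_total = ((Y - grand) ** 2).sum()
    m_t = Y.mean(axis=0)  # level means
    ss_with = N * ((m_t - grand) ** 2).sum()
    m_s = Y.mean(axis=1)  # subject means
    ss_subj = k * ((m_s - grand) ** 2).sum()

    group_labels = np.asarray(groups)
    uniq = group_sizes.index.to_numpy()
    ss_betw = 0.0
    ss_cells = 0.0  # residual around (group, time) cell means
    for g in uniq:
        mask = group_labels == g
        ss_betw += mask.sum() * k * (Y[mask].mean() - grand) ** 2
        cell_means = Y[mask].mean(axis=0)
        ss_cells += ((Y[mask] - cell_means) ** 2).sum()
    ss_inter = ss_total - ss_cells - ss_with - ss_betw
    ss_resbetw = ss_subj - ss_betw
    ss_reswith = ss_total - ss_with - ss_subj - ss_inter

    df_with = k - 1
    df_betw = G - 1
    df_resbetw = N - G
    df_reswith = df_with * df_resbetw
    df_inter = df_with * df_betw

    ms = lambda ss, df: ss / df if df > 0 else np.nan
    ms_with, ms_betw, ms_inter = ms(ss_with, df_with), ms(ss_betw, df_betw), ms(ss_inter, df_inter)
    ms_resbetw, ms_reswith = ms(ss_resbetw, df_resbetw), ms(ss_reswith, df_reswith)

    def f_p(ms_eff, ms_err, df1, df2):
        if ms_err == 0:
            return 0.0, 1.0
        F = ms_eff / ms_err
        return float(F), float(stats.f.sf(F, df1, df2))

    f_with, p_with = f_p(ms_with, ms_reswith, df_with, df_reswith)
    f_betw, p_betw = f_p(ms_betw, ms_resbetw, df_betw, df_resbetw)
    f_inter, p_inter = f_p(ms_inter, ms_reswith, df_inter, df_reswith)

    def pes(ss_eff, ss_err):
        tot = ss_eff + ss_err
        return float(ss_eff / tot) if tot > 0 else 0.0

    mauchly_w, mauchly_p = _mauchly(Y)
    eps = _gg_epsilon(Y)
    gg_applied = bool(k > 2 and mauchly_p < gg_alpha)
    if gg_applied:
        p_with_corr = float(stats.f.sf(f_with, df_with * eps, df_reswith * eps)) if ms_reswith else 1.0
        p_inter_corr = (
            float(stats.f.sf(f_inter, df_inter * eps, df_reswith * eps)) if ms_reswith else 1.0
        )
    else:
        p_with_corr, p_inter_corr = p_with, p_inter

    table = pd.DataFrame(
        {
            "SS": [ss_with, ss_betw, ss_inter],
            "df1": [df_with, df_betw, df_inter],
            "df2": [df_reswith, df_resbetw, df_reswith],
            "MS": [ms_with, ms_betw, ms_inter],
            "F": [f_with, f_betw, f_inter],
            "p_unc": [p_with, p_betw, p_inter],
            "p": [p_with_corr, p_betw, p_inter_corr],
            "partial_eta_sq": [
                pes(ss_with, ss_reswith),
                pes(ss_betw, ss_resbetw),
                pes(ss_inter, ss_reswith),
            ],
        },
        index=pd.Index([within, between, "interaction"], name="effect"),
    )
    return MixedAnovaResult(
        table=table,
        mauchly_w=mauchly_w,
        mauchly_p=mauchly_p,
        epsilon=eps,
        gg_applied=gg_applied,
        within=within,
        between=between,
    )


# ---------------------------------------------------------------------------
# Multiple testing and post hoc contrasts
# ---------------------------------------------------------------------------


def holm_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Holm-Bonferroni step-down adjustment, returned in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-D sequence")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * (m - np.arange(m))
    adjusted_sorted = np.minimum(np.maximum.accumulate(scaled), 1.0)
    adjusted = np.empty(m)
    adjusted[order] = adjusted_sorted
    return adjusted


def posthoc_time_contrasts(
    wide: pd.DataFrame, family: Sequence[tuple[str, str]] | None = None
) -> pd.DataFrame:
    """Paired two-tailed t-tests between time levels, Holm-adjusted as a family.

    ``wide`` is units x ordered timepoints. By default every C(T, 2) pair is
    tested, labeled ``"<later>vs<earlier>"``. Units missing either level are
    dropped pairwise; a contrast with fewer than 2 paired units raises.
    """
    cols = list(wide.columns)
    if family is None:
        family = [(cols[j], cols[i]) for i in range(len(cols)) for j in range(i + 1, len(cols))]
    rows = []
    for later, earlier in family:
        pair = wide[[later, earlier]].dropna()
        if len(pair) < 2:
            raise ValueError(f"contrast {later} vs {earlier}: fewer than 2 paired units")
        a = pair[later].to_numpy(dtype=float)
        b = pair[earlier].to_numpy(dtype=float)
        if np.allclose(a, b):
            t, p = 0.0, 1.0
        else:
            res = stats.ttest_rel(a, b)
            t, p = float(res.statistic), float(res.pvalue)
        rows.append({"contrast": _contrast_label(later, earlier), "t": t, "p_raw": p, "n": len(pair)})
    out = pd.DataFrame(rows)
    out["p_holm"] = holm_adjust(out["p_raw"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# Correlations
# ---------------------------------------------------------------------------


def _pearson_from_pooled(x: np.ndarray, y: np.ndarray, method: CorrelationMethod) -> CorrelationResult:
    n = x.size
    if n < 4:
        raise ValueError(f"need at least 4 observations, got {n}")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(r=float(r), p=float(p), n=n, method=method)


def rank_collapse_correlation(
    groups: Mapping[str, tuple[Sequence[float], Sequence[float]]]
) -> CorrelationResult:
    """Rank within each group, pool the ranks, then Pearson-correlate.

    This compensates for colony-level differences in scale: only the ordering
    within each group carries information. With a single group and no ties
    this is exactly Spearman's rho. Pairs with a missing value are dropped
    (pairwise) before ranking.
    """
    xs, ys = [], []
    for name, (x, y) in groups.items():
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.shape != y.shape:
            raise ValueError(f"group {name!r}: x and y lengths differ")
        keep = ~(np.isnan(x) | np.isnan(y))
        if keep.sum() < x.size:
            logger.warning("group %s: dropped %d pair(s) with missing values", name, x.size - keep.sum())
        x, y = x[keep], y[keep]
        if x.size == 0:
            continue
        xs.append(stats.rankdata(x, method="average"))
        ys.append(stats.rankdata(y, method="average"))
    if not xs:
        raise ValueError("no data after dropping missing values")
    pooled_x = np.concatenate(xs)
    pooled_y = np.concatenate(ys)
    return _pearson_from_pooled(pooled_x, pooled_y, CorrelationMethod.RANK_COLLAPSED)


def partial_correlation(
    x: Sequence[float], y: Sequence[float], z: Sequence[float]
) -> CorrelationResult:
    """First-order partial correlation of x and y controlling for z.

    r_xy.z = (r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2)); the
    two-tailed p-value uses the t-transform with n - 3 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    if not (x.shape == y.shape == z.shape):
        raise ValueError("x, y, z must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y) | np.isnan(z))
    x, y, z = x[keep], y[keep], z[keep]
    n = x.size
    if n < 4:
        raise ValueError(f"need at least 4 complete observations, got {n}")
    for name, v in (("x", x), ("y", y), ("z", z)):
        if np.std(v) == 0:
            raise ValueError(f"correlation undefined: {name} is constant")
    r_xy = float(stats.pearsonr(x, y).statistic)
    r_xz = float(stats.pearsonr(x, z).statistic)
    r_yz = float(stats.pearsonr(y, z).statistic)
    if abs(abs(r_xz) - 1) < 1e-12 or abs(abs(r_yz) - 1) < 1e-12:
        raise ValueError("degenerate control: z is collinear with x or y")
    r = (r_xy - r_xz * r_yz) / np.sqrt((1 - r_xz**2) * (1 - r_yz**2))
    r = float(np.clip(r, -1.0, 1.0))
    df = n - 3
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1 - r**2))
        p = float(2 * stats.t.sf(abs(t), df))
    return CorrelationResult(r=r, p=p, n=n, method=CorrelationMethod.PARTIAL)


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Plain two-tailed Pearson correlation with pairwise missing-data removal."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    return _pearson_from_pooled(x[keep], y[keep], CorrelationMethod.PEARSON)
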