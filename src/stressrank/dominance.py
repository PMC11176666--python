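"""David's score dominance ranking and hierarchy stability.

A *win* of i over j is aggression initiated by i toward j plus submission
initiated by j toward i. From the win matrix each dyad gets a win proportion
P_ij = w_ij / n_ij, optionally chance-corrected to
D_ij = P_ij - (P_ij - 0.5) / (n_ij + 1), which shrinks sparse dyads toward
0.5 so that a single uncontested win does not read as total dominance.
David's score for individual i is

    DS_i = w_i + w2_i - l_i - l2_i

with w_i the row sum of the index matrix, w2_i the opponent-weighted row sum,
and l, l2 the column analogues. DS sums to zero over a group. Scores are
mapped onto [0, 1] by shifting by |DS_min| and dividing by the shifted
maximum, so the top individual scores 1 and the bottom individual 0;
individuals above 0.5 are classed high-ranking (HR), below 0.5 low-ranking
(LR), and exactly 0.5 BOUNDARY.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .behavior_io import Behavior, InteractionMatrix, Observation, ValidationError

__all__ = [
    "DyadicIndexVariant",
    "ZeroDyadPolicy",
    "RankClass",
    "DegenerateHierarchyError",
    "WinMatrix",
    "DominanceComponents",
    "DominanceResult",
    "StabilityReport",
    "build_win_matrix",
    "dyadic_index",
    "david_score",
    "normalize_ds",
    "partition_hr_lr",
    "compute_dominance",
    "hierarchy_stability",
    "dominance_table",
]

logger = logging.getLogger(__name__)


class DyadicIndexVariant(str, enum.Enum):
    RAW = "RAW"  # P_ij = w_ij / n_ij
    CHANCE_CORRECTED = "CHANCE_CORRECTED"  # D_ij = P_ij - (P_ij - 0.5)/(n_ij + 1)


class ZeroDyadPolicy(str, enum.Enum):
    """How a dyad with no decided interactions enters the index matrix."""

    ZERO = "ZERO"  # contributes 0 to both directions (no invented dominance)
    HALF = "HALF"  # contributes 0.5 to both directions


class RankClass(str, enum.Enum):
    HR = "HR"
    LR = "LR"
    BOUNDARY = "BOUNDARY"


class DegenerateHierarchyError(ValueError):
    """All David's scores equal: the normalization denominator is zero."""


@dataclass
class WinMatrix:
    """W[i, j] = wins of subject i over subject j in one observation period."""

    subjects: tuple[str, ...]
    W: np.ndarray
    observation_id: Observation | None = None

    def __post_init__(self) -> None:
        self.subjects = tuple(self.subjects)
        self.W = np.asarray(self.W, dtype=float)
        n = len(self.subjects)
        if self.W.shape != (n, n):
            raise ValidationError(f"win matrix shape {self.W.shape} != roster size {n}")
        if np.any(np.diag(self.W) != 0):
            raise ValidationError("win matrix must have a zero diagonal")
        if np.any(self.W < 0):
            raise ValidationError("win matrix entries must be >= 0")


@dataclass
class DominanceComponents:
    """Dyadic index matrix and the w/w2/l/l2 sums behind David's scores."""

    subjects: tuple[str, ...]
    index_matrix: np.ndarray
    variant: DyadicIndexVariant
    w: np.ndarray | None = None
    w2: np.ndarray | None = None
    l: np.ndarray | None = None
    l2: np.ndarray | None = None
    ds: np.ndarray | None = None


@dataclass
class DominanceResult:
    """Per-subject DS, normalized DS, ordinal rank and HR/LR class."""

    subjects: tuple[str, ...]
    ds: np.ndarray
    norm_ds: np.ndarray
    ds_min: float
    ds_prime_max: float
    ordinal_rank: np.ndarray | None = None  # 1 = highest normDS
    klass: list[RankClass] | None = None
    observation_id: Observation | None = None

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": self.subjects,
                "DS": self.ds,
                "normDS": self.norm_ds,
                "ordinal_rank": self.ordinal_rank,
                "class": [k.value for k in self.klass] if self.klass is not None else None,
            }
        )

    def classes(self) -> dict[str, RankClass]:
        if self.klass is None:
            raise ValueError("partition_hr_lr has not been applied")
        return dict(zip(self.subjects, self.klass))

    def rank_of(self) -> dict[str, int]:
        if self.ordinal_rank is None:
            raise ValueError("partition_hr_lr has not been applied")
        return {s: int(r) for s, r in zip(self.subjects, self.ordinal_rank)}


@dataclass
class StabilityReport:
    """Agreement between two rank orders on the same roster."""

    tau: float
    rho: float
    switched_pairs: list[tuple[str, str]] = field(default_factory=list)


def build_win_matrix(agg: InteractionMatrix, sub: InteractionMatrix) -> WinMatrix:
    """Compose wins: i's initiated aggression toward j plus j's submission toward i."""
    if agg.behavior is not Behavior.AGG or sub.behavior is not Behavior.SUB:
        raise ValidationError("expected an AGG matrix and a SUB matrix")
    if agg.subjects != sub.subjects:
        raise ValidationError("roster mismatch between aggression and submission matrices")
    if agg.observation_id is not sub.observation_id:
        raise ValidationError("observation mismatch between aggression and submission matrices")
    W = np.asarray(agg.M, dtype=float) + np.asarray(sub.M, dtype=float).T
    return WinMatrix(subjects=agg.subjects, W=W, observation_id=agg.observation_id)


def dyadic_index(
    win: WinMatrix,
    variant: DyadicIndexVariant | str = DyadicIndexVariant.CHANCE_CORRECTED,
    zero_dyad: ZeroDyadPolicy | str = ZeroDyadPolicy.ZERO,
) -> DominanceComponents:
    """Populate the dyadic win-proportion (or chance-corrected) index matrix."""
    variant = DyadicIndexVariant(variant)
    zero_dyad = ZeroDyadPolicy(zero_dyad)
    W = win.W
    n = len(win.subjects)
    N = W + W.T  # n_ij, interactions per dyad
    with np.errstate(invalid="ignore", divide="ignore"):
        P = np.where(N > 0, W / np.where(N > 0, N, 1), 0.0)
    if variant is DyadicIndexVariant.CHANCE_CORRECTED:
        index = np.where(N > 0, P - (P - 0.5) / (N + 1), 0.0)
    else:
        index = P
    if zero_dyad is ZeroDyadPolicy.HALF:
        index = np.where(N > 0, index, 0.5)
    np.fill_diagonal(index, 0.0)
    return DominanceComponents(subjects=win.subjects, index_matrix=index, variant=variant)


def david_score(components: DominanceComponents) -> DominanceComponents:
    """Fill w, w2, l, l2 and DS_i = w_i + w2_i - l_i - l2_i."""
    idx = components.index_matrix
    w = idx.sum(axis=1)
    l = idx.sum(axis=0)
    w2 = idx @ w
    l2 = idx.T @ l
    components.w, components.w2, components.l, components.l2 = w, w2, l, l2
    components.ds = w + w2 - l - l2
    return components


def normalize_ds(
    ds: Sequence[float] | np.ndarray,
    subjects: Sequence[str] | None = None,
    observation_id: Observation | None = None,
) -> DominanceResult:
    """Shift DS by |DS_min| and scale by the shifted maximum onto [0, 1].

    Genuine David's scores sum to zero, so DS_min <= 0 and the shift equals
    subtracting the minimum; subtraction is used so the [0, 1] bounds also
    hold for translated score vectors.
    """
    ds = np.asarray(ds, dtype=float)
    if ds.size < 2:
        raise ValueError("need at least two subjects to normalize")
    if subjects is None:
        subjects = tuple(f"s{i + 1}" for i in range(ds.size))
    ds_min = float(ds.min())
    shifted = ds - ds_min
    ds_prime_max = float(shifted.max())
    if ds_prime_max == 0.0:
        raise DegenerateHierarchyError("all David's scores equal; normalization undefined")
    norm = shifted / ds_prime_max
    return DominanceResult(
        subjects=tuple(subjects),
        ds=ds,
        norm_ds=norm,
        ds_min=ds_min,
        ds_prime_max=ds_prime_max,
        observation_id=observation_id,
    )


def partition_hr_lr(result: DominanceResult) -> DominanceResult:
    """Assign HR/LR/BOUNDARY classes and ordinal ranks (1 = highest normDS).

    Ties in normDS are broken by roster order with a logged warning;
    BOUNDARY individuals (normDS exactly 0.5) are flagged for downstream
    exclusion from HR/LR contrasts.
    """
    norm = result.norm_ds
    klass = []
    for s, v in zip(result.subjects, norm):
        if v > 0.5:
            klass.append(RankClass.HR)
        elif v < 0.5:
            klass.append(RankClass.LR)
        else:
            klass.append(RankClass.BOUNDARY)
            logger.warning("subject %s has normDS exactly 0.5 (BOUNDARY)", s)
    if len(np.unique(norm)) < norm.size:
        logger.warning("tied normDS values; ordinal ranks broken by roster order")
    # stable sort on descending normDS => roster order breaks ties
    order = np.argsort(-norm, kind="stable")
    ranks = np.empty(norm.size, dtype=int)
    ranks[order] = np.arange(1, norm.size + 1)
    result.ordinal_rank = ranks
    result.klass = klass
    return result


def compute_dominance(
    win: WinMatrix,
    variant: DyadicIndexVariant | str = DyadicIndexVariant.CHANCE_CORRECTED,
    zero_dyad: ZeroDyadPolicy | str = ZeroDyadPolicy.ZERO,
) -> DominanceResult:
    """Full chain: dyadic index -> David's score -> normalization -> classes."""
    comp = david_score(dyadic_index(win, variant=variant, zero_dyad=zero_dyad))
    result = normalize_ds(comp.ds, subjects=win.subjects, observation_id=win.observation_id)
    return partition_hr_lr(result)


def hierarchy_stability(result_a: DominanceResult, result_b: DominanceResult) -> StabilityReport:
    """Kendall tau / Spearman rho between two rank orders, plus switched pairs.

    Switched pairs are all subject pairs ordered oppositely in the two
    rankings (for a single adjacent swap this is exactly that pair).
    """
    if result_a.subjects != result_b.subjects:
        raise ValidationError("roster mismatch between dominance results")
    if result_a.ordinal_rank is None or result_b.ordinal_rank is None:
        raise ValueError("ordinal ranks missing; run partition_hr_lr first")
    ra, rb = result_a.ordinal_rank, result_b.ordinal_rank
    tau = float(stats.kendalltau(ra, rb).statistic)
    rho = float(stats.spearmanr(ra, rb).statistic)
    switched = []
    n = len(ra)
    for i in range(n):
        for j in range(i + 1, n):
            if (ra[i] - ra[j]) * (rb[i] - rb[j]) < 0:
                switched.append((result_a.subjects[i], result_a.subjects[j]))
    return StabilityReport(tau=tau, rho=rho, switched_pairs=switched)


def dominance_table(results: dict[tuple[str, Observation], DominanceResult]) -> pd.DataFrame:
    """Stack per-(group, observation) results into the ds_table layout."""
    frames = []
    for (group_id, obs), res in results.items():
        frame = res.as_frame()
        frame.insert(0, "observation_id", Observation(obs).value)
        frame.insert(0, "group_id", group_id)
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)
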