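"""Ordered-dyad analyses: interaction types, appearance strata, change correlations.

A dyad is *directed*: behavior initiated by one individual and received by
another, so a group of n yields n(n-1) dyads. Crossing the HR/LR classes of
initiator and receiver gives four interaction types — LL, HL, LH, HH (first
letter = initiator's class, second = receiver's). Dyads are further stratified
per behavior by their baseline (first observation) frequency into
Zero-Appearance (0), Low-Appearance (0 < f < t) and High-Appearance (f >= t);
the threshold t can be fixed (the study used 5 for aggression, 17 for
grooming) or chosen automatically to balance the Low/High subgroup sizes.
"""

from __future__ import annotations

import enum
import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .behavior_io import Behavior, InteractionMatrix, Observation
from .dominance import RankClass
from .stress_stats import CorrelationResult, pearson_correlation

__all__ = [
    "DyadType",
    "AppearanceClass",
    "classify_dyad_types",
    "stratify_appearance",
    "dyad_change_correlation",
    "dyad_summary",
]

logger = logging.getLogger(__name__)


class DyadType(str, enum.Enum):
    LL = "LL"
    HL = "HL"
    LH = "LH"
    HH = "HH"


class AppearanceClass(str, enum.Enum):
    ZERO = "ZERO"
    LOW = "LOW"
    HIGH = "HIGH"


def classify_dyad_types(
    classes_by_group: Mapping[str, Mapping[str, RankClass | str]]
) -> pd.DataFrame:
    """Emit every ordered dyad per group with its LL/HL/LH/HH type.

    ``classes_by_group`` maps group_id -> {subject -> HR/LR class}. BOUNDARY
    subjects are excluded with a logged warning. Per group of h HR and l LR
    subjects this yields h(h-1) HH, l(l-1) LL and h*l each of HL and LH dyads.
    """
    rows = []
    for group_id, classes in classes_by_group.items():
        kept: dict[str, RankClass] = {}
        for subject, klass in classes.items():
            klass = RankClass(klass)
            if klass is RankClass.BOUNDARY:
                logger.warning(
                    "group %s: subject %s is BOUNDARY and excluded from dyad typing",
                    group_id,
                    subject,
                )
                continue
            kept[subject] = klass
        for initiator, ki in kept.items():
            for receiver, kr in kept.items():
                if initiator == receiver:
                    continue
                dtype = DyadType(
                    ("H" if ki is RankClass.HR else "L") + ("H" if kr is RankClass.HR else "L")
                )
                rows.append(
                    {
                        "group_id": group_id,
                        "initiator": initiator,
                        "receiver": receiver,
                        "dtype": dtype.value,
                    }
                )
    return pd.DataFrame(rows, columns=["group_id", "initiator", "receiver", "dtype"])


def stratify_appearance(
    baseline_freqs: Mapping | pd.Series, threshold: int | str = "AUTO"
) -> tuple[pd.Series, int]:
    """Assign ZERO/LOW/HIGH appearance classes from baseline frequencies.

    ZERO iff f = 0; LOW iff 0 < f < t; HIGH iff f >= t. ``threshold="AUTO"``
    searches integer thresholds and picks the one minimizing the absolute
    size difference between LOW and HIGH among nonzero dyads (ties go to the
    smaller threshold). Returns (labels, threshold used).
    """
    freqs = pd.Series(baseline_freqs, dtype=float)
    if (freqs < 0).any():
        raise ValueError("frequencies must be >= 0")
    nonzero = np.sort(freqs[freqs > 0].to_numpy())
    if isinstance(threshold, str):
        if threshold.upper() != "AUTO":
            raise ValueError(f"threshold must be an integer or 'AUTO', got {threshold!r}")
        if nonzero.size == 0:
            raise ValueError("AUTO threshold undefined: all baseline frequencies are zero")
        # candidate cut points: one below the smallest (all HIGH) .. one above
        # the largest (all LOW); only distinct nonzero values can change the split
        candidates = sorted({1, *(int(v) for v in np.unique(nonzero)), int(nonzero.max()) + 1})
        best_t, best_gap = None, None
        for t in candidates:
            low = int(((nonzero > 0) & (nonzero < t)).sum())
            high = int((nonzero >= t).sum())
            gap = abs(low - high)
            if best_gap is None or gap < best_gap:
                best_t, best_gap = t, gap
        threshold = best_t
    threshold = int(threshold)
    labels = pd.Series(AppearanceClass.LOW.value, index=freqs.index, dtype=object)
    labels[freqs == 0] = AppearanceClass.ZERO.value
    labels[freqs >= threshold] = AppearanceClass.HIGH.value
    return labels, threshold


def dyad_change_correlation(
    baseline: Mapping | pd.Series, followup: Mapping | pd.Series
) -> CorrelationResult:
    """Pearson r between baseline frequency and relative change, existing dyads only.

    Dyads with baseline 0 ("non-existing pairs") are excluded before the
    relative change (followup - baseline) / baseline is formed; fewer than 4
    surviving dyads is an error, as is a constant change vector.
    """
    baseline = pd.Series(baseline, dtype=float)
    followup = pd.Series(followup, dtype=float).reindex(baseline.index)
    existing = baseline > 0
    excluded = int((~existing).sum())
    if excluded:
        logger.warning("excluded %d non-existing dyad(s) (baseline 0)", excluded)
    base = baseline[existing]
    if len(base) < 4:
        raise ValueError(f"insufficient data: only {len(base)} existing dyad(s)")
    delta = (followup[existing] - base) / base
    if np.std(delta.to_numpy()) == 0:
        raise ValueError("correlation undefined: change vector is constant")
    return pearson_correlation(base.to_numpy(), delta.to_numpy())


def dyad_summary(
    dyads: pd.DataFrame,
    matrices: Mapping[tuple[str, Behavior | str, Observation | str], InteractionMatrix],
    thresholds: Mapping[Behavior | str, int | str] | None = None,
) -> pd.DataFrame:
    """Per-dyad, per-behavior frequencies across observations with changes.

    ``dyads`` is the output of :func:`classify_dyad_types`; ``matrices`` maps
    (group_id, behavior, observation) to aggregated interaction matrices.
    Appearance strata use baseline (first-observation) frequencies; relative
    changes are NaN where the reference frequency is 0.
    """
    thresholds = {Behavior(k): v for k, v in (thresholds or {}).items()}
    obs_order = [Observation.OBS1, Observation.OBS3A, Observation.OBS3B]
    rows = []
    for behavior in Behavior:
        freq_cols: dict[Observation, list[float]] = {o: [] for o in obs_order}
        keys = []
        for dyad in dyads.itertuples(index=False):
            keys.append((dyad.group_id, dyad.initiator, dyad.receiver, dyad.dtype))
            for obs in obs_order:
                mat = matrices.get((dyad.group_id, Behavior(behavior), obs))
                if mat is None:
                    freq_cols[obs].append(np.nan)
                    continue
                i, j = mat.index_of(dyad.initiator), mat.index_of(dyad.receiver)
                freq_cols[obs].append(float(mat.M[i, j]))
        f1 = pd.Series(freq_cols[Observation.OBS1])
        labels, used_t = stratify_appearance(f1.fillna(0), thresholds.get(Behavior(behavior), "AUTO")) \
            if f1.notna().any() and (f1.fillna(0) > 0).any() else (
                pd.Series(AppearanceClass.ZERO.value, index=f1.index), 0)
        for idx, (group_id, initiator, receiver, dtype) in enumerate(keys):
            f_obs1 = freq_cols[Observation.OBS1][idx]
            f_3a = freq_cols[Observation.OBS3A][idx]
            f_3b = freq_cols[Observation.OBS3B][idx]

            def rel(a: float, b: float) -> float:
                if b == 0 or np.isnan(b) or np.isnan(a):
                    return np.nan
                return (a - b) / b

            rows.append(
                {
                    "group_id": group_id,
                    "initiator": initiator,
                    "receiver": receiver,
                    "behavior": Behavior(behavior).value,
                    "dtype": dtype,
                    "appearance": labels.iloc[idx],
                    "freq_obs1": f_obs1,
                    "freq_obs3a": f_3a,
                    "freq_obs3b": f_3b,
                    "delta_3avs1": rel(f_3a, f_obs1),
                    "delta_3bvs3a": rel(f_3b, f_3a),
                    "delta_3bvs1": rel(f_3b, f_obs1),
                }
            )
    return pd.DataFrame(rows)
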