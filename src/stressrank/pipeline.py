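"""End-to-end orchestration: event logs + physiology in, analysis tables out.

Stages mirror the study's analysis plan: (1) dominance hierarchies per group
and observation from agonistic behavior; (2) mixed time x rank ANOVAs on
physiology and on per-subject behavior totals, with Holm-adjusted post hoc
time contrasts; (3) rank-collapsed correlations of social rank with analyte
levels/changes and behavior totals/changes, plus dyad-level baseline-vs-change
Pearson correlations and OT/AVP-controlled partial correlations; (4) ordered
dyad typing (LL/HL/LH/HH) and appearance stratification. Every run emits a
machine-readable manifest (config hash, versions, seed) and is byte-for-byte
reproducible from the same config and inputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from . import __version__
from .behavior_io import (
    Analyte,
    Behavior,
    BehaviorEvent,
    InteractionMatrix,
    Observation,
    PhysioPanel,
    aggregate_interactions,
    read_event_log,
    read_physiology,
    roster_of,
    TRIPHASE_ANALYTES,
)
from .dominance import (
    DominanceResult,
    DyadicIndexVariant,
    RankClass,
    ZeroDyadPolicy,
    build_win_matrix,
    compute_dominance,
    dominance_table,
)
from .dyad_analysis import classify_dyad_types, dyad_change_correlation, dyad_summary
from .stress_stats import (
    change_table,
    mixed_anova,
    partial_correlation,
    pearson_correlation,
    posthoc_time_contrasts,
    rank_collapse_correlation,
)

__all__ = ["PipelineConfig", "RunReport", "PipelineError", "run_pipeline"]

logger = logging.getLogger(__name__)

OBS_ORDER = [Observation.OBS1, Observation.OBS3A, Observation.OBS3B]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    events_path: str
    physio_path: str | None = None
    out_dir: str = "results"
    ds_variant: str = DyadicIndexVariant.CHANCE_CORRECTED.value
    zero_dyad: str = ZeroDyadPolicy.ZERO.value
    appearance_thresholds: dict = field(default_factory=lambda: {"AGG": "AUTO", "GRO": "AUTO"})
    gg_alpha: float = 0.05
    seed: int | None = None

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class RunReport:
    tables: dict[str, Path]
    manifest: Path


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc

        return wrapper

    return deco


# ---------------------------------------------------------------------------
# Stage computations (also used by the CLI subcommands)
# ---------------------------------------------------------------------------


def interaction_matrices(
    events: Iterable[BehaviorEvent],
) -> dict[tuple[str, Behavior, Observation], InteractionMatrix]:
    """Aggregate all (group, behavior, observation) frequency matrices."""
    events = list(events)
    by_group: dict[str, list[BehaviorEvent]] = {}
    for e in events:
        by_group.setdefault(e.group_id, []).append(e)
    matrices = {}
    for gid in sorted(by_group):
        roster = roster_of(by_group[gid])
        for behavior in Behavior:
            for obs in OBS_ORDER:
                matrices[(gid, behavior, obs)] = aggregate_interactions(
                    by_group[gid], behavior, obs, roster=roster
                )
    return matrices


def dominance_results(
    matrices: Mapping[tuple[str, Behavior, Observation], InteractionMatrix],
    variant: str = DyadicIndexVariant.CHANCE_CORRECTED.value,
    zero_dyad: str = ZeroDyadPolicy.ZERO.value,
) -> dict[tuple[str, Observation], DominanceResult]:
    """Per-(group, observation) David's-score results from AGG + SUB matrices."""
    groups = sorted({gid for gid, _, _ in matrices})
    out = {}
    for gid in groups:
        for obs in OBS_ORDER:
            win = build_win_matrix(matrices[(gid, Behavior.AGG, obs)], matrices[(gid, Behavior.SUB, obs)])
            out[(gid, obs)] = compute_dominance(win, variant=variant, zero_dyad=zero_dyad)
    return out


def baseline_classes(
    results: Mapping[tuple[str, Observation], DominanceResult]
) -> dict[str, dict[str, RankClass]]:
    """Initial-observation HR/LR classes per group (used for all downstream splits)."""
    classes: dict[str, dict[str, RankClass]] = {}
    for (gid, obs), res in results.items():
        if obs is Observation.OBS1:
            classes[gid] = res.classes()
    return classes


def behavior_totals(
    matrices: Mapping[tuple[str, Behavior, Observation], InteractionMatrix]
) -> dict[str, pd.DataFrame]:
    """Per-subject initiated/received totals per behavior: measurement -> wide table.

    Measurements are named iAgg, rAgg, iSub, ... with columns OBS1/OBS3A/OBS3B.
    """
    behaviors = {Behavior.AGG: "Agg", Behavior.SUB: "Sub", Behavior.GRO: "Gro", Behavior.PRO: "Pro"}
    tables: dict[str, dict[str, dict[str, float]]] = {}
    for (gid, behavior, obs), mat in matrices.items():
        for direction, totals in (("i", mat.M.sum(axis=1)), ("r", mat.M.sum(axis=0))):
            name = direction + behaviors[behavior]
            col = tables.setdefault(name, {}).setdefault(obs.value, {})
            for subject, v in zip(mat.subjects, totals):
                col[subject] = float(v)
    out = {}
    for name, cols in tables.items():
        wide = pd.DataFrame(cols)
        wide = wide.reindex(columns=[o.value for o in OBS_ORDER]).sort_index()
        wide.index.name = "subject_id"
        out[name] = wide
    return out


def _long_from_wide(wide: pd.DataFrame, groups: Mapping[str, str]) -> pd.DataFrame:
    """units x timepoints -> long {unit, time, group, value}, dropping unlabeled units."""
    long = wide.reset_index().melt(id_vars=wide.index.name or "index", var_name="time", value_name="value")
    long = long.rename(columns={wide.index.name or "index": "unit"})
    long["group"] = long["unit"].map(groups)
    return long.dropna(subset=["group"])


def _classes_flat(classes: Mapping[str, Mapping[str, RankClass]]) -> dict[str, str]:
    flat = {}
    for per_group in classes.values():
        for subject, klass in per_group.items():
            if klass is not RankClass.BOUNDARY:
                flat[subject] = klass.value
    return flat


def run_anovas(
    measurements: Mapping[str, pd.DataFrame],
    between_labels: Mapping[str, str],
    between_name: str,
    gg_alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mixed time x <between> ANOVA and post hoc time contrasts per measurement."""
    anova_rows = []
    posthoc_frames = []
    for name in sorted(measurements):
        wide = measurements[name]
        long = _long_from_wide(wide, between_labels)
        res = mixed_anova(long, dv="value", within="time", between="group", subject="unit", gg_alpha=gg_alpha)
        tab = res.table.reset_index()
        tab.insert(0, "measurement", name)
        tab["effect"] = tab["effect"].replace({"time": "time", "group": between_name})
        tab["epsilon"] = res.epsilon
        tab["gg_applied"] = res.gg_applied
        tab["mauchly_w"] = res.mauchly_w
        tab["mauchly_p"] = res.mauchly_p
        anova_rows.append(tab)
        ph = posthoc_time_contrasts(wide.loc[wide.index.isin(between_labels)])
        ph.insert(0, "measurement", name)
        posthoc_frames.append(ph)
    return pd.concat(anova_rows, ignore_index=True), pd.concat(posthoc_frames, ignore_index=True)


def _rank_corr(
    name_x: str,
    name_y: str,
    x: Mapping[str, float],
    y: Mapping[str, float],
    group_of: Mapping[str, str],
) -> dict | None:
    groups: dict[str, tuple[list[float], list[float]]] = {}
    for subject, gx in x.items():
        if subject in y and subject in group_of:
            groups.setdefault(group_of[subject], ([], []))
            groups[group_of[subject]][0].append(gx)
            groups[group_of[subject]][1].append(y[subject])
    try:
        res = rank_collapse_correlation(groups)
    except ValueError as exc:
        logger.warning("correlation %s vs %s skipped: %s", name_x, name_y, exc)
        return None
    return {
        "method": res.method.value,
        "x": name_x,
        "y": name_y,
        "control": "",
        "r": res.r,
        "p": res.p,
        "n": res.n,
    }


def run_correlations(
    analyte_wide: Mapping[str, pd.DataFrame],
    behavior_wide: Mapping[str, pd.DataFrame],
    norm_ds: Mapping[str, float],
    group_of: Mapping[str, str],
    matrices: Mapping[tuple[str, Behavior, Observation], InteractionMatrix],
    dyads: pd.DataFrame,
) -> pd.DataFrame:
    """The correlation battery for correlations.tsv.

    Social rank is coded as baseline normDS (larger = higher status); the
    rank-collapsed procedure ranks it within each group before pooling.
    """
    rows: list[dict] = []

    def add_rank_block(name: str, wide: pd.DataFrame) -> None:
        for col in wide.columns:
            vals = wide[col].dropna().to_dict()
            row = _rank_corr("rank", f"{name}_{col}", norm_ds, vals, group_of)
            if row:
                rows.append(row)
        deltas = change_table(wide)
        for col in deltas.columns:
            vals = deltas[col].dropna().to_dict()
            row = _rank_corr("rank", f"{name}_d{col}", norm_ds, vals, group_of)
            if row:
                rows.append(row)

    for analyte, wide in analyte_wide.items():
        add_rank_block(analyte, wide)
    for name, wide in behavior_wide.items():
        add_rank_block(name, wide)

    # dyad-level baseline vs change, existing pairs only (pooled across groups)
    for behavior, label in ((Behavior.AGG, "Agg"), (Behavior.GRO, "Gro")):
        base, follow = {}, {}
        for dyad in dyads.itertuples(index=False):
            key = f"{dyad.group_id}:{dyad.initiator}->{dyad.receiver}"
            m1 = matrices[(dyad.group_id, behavior, Observation.OBS1)]
            m3a = matrices[(dyad.group_id, behavior, Observation.OBS3A)]
            i, j = m1.index_of(dyad.initiator), m1.index_of(dyad.receiver)
            base[key] = float(m1.M[i, j])
            follow[key] = float(m3a.M[i, j])
        try:
            res = dyad_change_correlation(pd.Series(base), pd.Series(follow))
            rows.append(
                {
                    "method": res.method.value,
                    "x": f"pair_{label}_OBS1",
                    "y": f"pair_{label}_dOBS3Avs1",
                    "control": "",
                    "r": res.r,
                    "p": res.p,
                    "n": res.n,
                }
            )
        except ValueError as exc:
            logger.warning("dyad change correlation for %s skipped: %s", label, exc)

    # initiated vs received prosocial changes, plain and hormone-controlled
    hormone_changes = {}
    for analyte in ("OT", "AVP"):
        if analyte in analyte_wide:
            hormone_changes[analyte] = change_table(analyte_wide[analyte])["S3vs2"]
    for label in ("Gro", "Pro"):
        iw, rw = behavior_wide.get("i" + label), behavior_wide.get("r" + label)
        if iw is None or rw is None:
            continue
        di = change_table(iw)["OBS3BvsOBS3A"]
        dr = change_table(rw)["OBS3BvsOBS3A"]
        joined = pd.concat({"x": di, "y": dr}, axis=1).dropna()
        try:
            res = pearson_correlation(joined["x"], joined["y"])
            rows.append({"method": res.method.value, "x": f"di{label}_3Bvs3A", "y": f"dr{label}_3Bvs3A",
                         "control": "", "r": res.r, "p": res.p, "n": res.n})
        except ValueError as exc:
            logger.warning("prosocial change correlation (%s) skipped: %s", label, exc)
            continue
        for analyte, dh in hormone_changes.items():
            triple = pd.concat({"x": di, "y": dr, "z": dh}, axis=1).dropna()
            try:
                res = partial_correlation(triple["x"], triple["y"], triple["z"])
                rows.append({"method": res.method.value, "x": f"di{label}_3Bvs3A",
                             "y": f"dr{label}_3Bvs3A", "control": f"d{analyte}_3vs2",
                             "r": res.r, "p": res.p, "n": res.n})
            except ValueError as exc:
                logger.warning("partial correlation (%s | %s) skipped: %s", label, analyte, exc)
    return pd.DataFrame(rows, columns=["method", "x", "y", "control", "r", "p", "n"])


# ---------------------------------------------------------------------------
# run_pipeline
# ---------------------------------------------------------------------------


def _write_tsv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, sep="\t", index=False)


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Run every analysis stage and write all output tables plus a manifest."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tables: dict[str, Path] = {}

    events = _stage("read_events")(read_event_log)(config.events_path)
    if not events:
        raise PipelineError("stage 'read_events' failed: event log is empty")
    logger.info("read_events: %d records", len(events))

    matrices = _stage("aggregate")(interaction_matrices)(events)
    results = _stage("dominance")(dominance_results)(matrices, config.ds_variant, config.zero_dyad)
    ds_frame = dominance_table({(g, o): r for (g, o), r in results.items()})
    tables["ds_table"] = out_dir / "ds_table.tsv"
    _write_tsv(ds_frame, tables["ds_table"])
    logger.info("dominance: %d rows", len(ds_frame))

    classes = baseline_classes(results)
    flat_classes = _classes_flat(classes)
    norm_ds = {
        s: float(v)
        for (gid, obs), res in results.items()
        if obs is Observation.OBS1
        for s, v in zip(res.subjects, res.norm_ds)
    }
    group_of = {s: gid for gid, per in classes.items() for s in per}

    behavior_wide = behavior_totals(matrices)
    analyte_wide: dict[str, pd.DataFrame] = {}
    if config.physio_path:
        panel = _stage("read_physiology")(read_physiology)(config.physio_path)
        for analyte in Analyte:
            wide = panel.values_wide(analyte)
            if not wide.empty:
                analyte_wide[analyte.value] = wide
        logger.info("read_physiology: %d rows", len(panel))

    # time x rank ANOVAs on subject-level measurements
    measurements = dict(behavior_wide)
    measurements.update(analyte_wide)
    anova_frame, posthoc_frame = _stage("anova")(run_anovas)(
        measurements, flat_classes, "rank", config.gg_alpha
    )

    # dyad typing, time x dtype and time x appearance ANOVAs
    dyads = _stage("dyads")(classify_dyad_types)(classes)
    summary = _stage("dyads")(dyad_summary)(dyads, matrices, config.appearance_thresholds)
    tables["dyad_summary"] = out_dir / "dyad_summary.tsv"
    _write_tsv(summary, tables["dyad_summary"])

    def dyad_measurements(label_col: str, behaviors: list[Behavior]) -> tuple[dict, dict]:
        meas, labels = {}, {}
        for behavior in behaviors:
            sub = summary[summary["behavior"] == behavior.value]
            key = sub["group_id"] + ":" + sub["initiator"] + "->" + sub["receiver"]
            wide = pd.DataFrame(
                {
                    "OBS1": sub["freq_obs1"].to_numpy(),
                    "OBS3A": sub["freq_obs3a"].to_numpy(),
                    "OBS3B": sub["freq_obs3b"].to_numpy(),
                },
                index=pd.Index(key, name="unit"),
            )
            name = {"dtype": "dyad_", "appearance": "pair_"}[label_col] + behavior.value.title()
            meas[name] = wide
            labels.update(dict(zip(key, sub[label_col])))
        return meas, labels

    try:
        type_meas, type_labels = dyad_measurements("dtype", list(Behavior))
        type_anova, type_posthoc = run_anovas(type_meas, type_labels, "dtype", config.gg_alpha)
        app_meas, app_labels = dyad_measurements("appearance", [Behavior.AGG, Behavior.GRO])
        app_anova, app_posthoc = run_anovas(app_meas, app_labels, "appearance", config.gg_alpha)
        anova_frame = pd.concat([anova_frame, type_anova, app_anova], ignore_index=True)
        posthoc_frame = pd.concat([posthoc_frame, type_posthoc, app_posthoc], ignore_index=True)
    except (ValueError, PipelineError) as exc:
        logger.warning("dyad-level ANOVAs skipped: %s", exc)

    tables["anova_table"] = out_dir / "anova_table.tsv"
    _write_tsv(anova_frame, tables["anova_table"])
    tables["posthoc"] = out_dir / "posthoc.tsv"
    _write_tsv(posthoc_frame, tables["posthoc"])
    logger.info("anova: %d effect rows, %d post hoc rows", len(anova_frame), len(posthoc_frame))

    corr_frame = _stage("correlate")(run_correlations)(
        analyte_wide, behavior_wide, norm_ds, group_of, matrices, dyads
    )
    tables["correlations"] = out_dir / "correlations.tsv"
    _write_tsv(corr_frame, tables["correlations"])
    logger.info("correlate: %d rows", len(corr_frame))

    manifest = {
        "package": "stressrank",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "tables": {k: str(v) for k, v in tables.items()},
        "rows": {
            "events": len(events),
            **{k: int(pd.read_csv(v, sep="\t").shape[0]) for k, v in tables.items()},
        },
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return RunReport(tables=tables, manifest=manifest_path)
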