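"""Synthetic colonies: planted hierarchies, event logs, rank-dependent physiology.

The generator emulates the design of a two-colony chronic-stress study on
adult female macaques: groups of 7 and 6 subjects, three behavioral
observation periods of six days each (baseline OBS1 and post-stress OBS3A /
OBS3B), three blood/hair/weight sample points and five weekly fecal samples.

Behavior. Each group carries a planted strict dominance order. Per unordered
dyad and observation, a Poisson number of decided agonistic interactions is
drawn; the higher-planted individual wins each with probability
``dominance_prob``. Every decided interaction emits one aggressive event
(winner -> loser) and one submissive event (loser -> winner), so the win
matrix is exercised from both behavior classes. Grooming and proximity are
Poisson per *directed* dyad. Post-stress observations apply multiplicative
shifts: aggression within LR-LR dyads scaled down, grooming within LR-LR
dyads scaled up, proximity scaled up in all dyad types.

Physiology. Hair cortisol rises after isolation with a slope proportional to
planted rank and partially recovers; oxytocin starts higher in high-ranking
subjects, rises globally under stress, and keeps rising after release with a
negative rank slope; vasopressin rises globally and falls back more in
high-ranking subjects; fecal immunoglobulins ramp up from a configurable
onset week with a negative rank slope and partly decline at week 4; weight
is flat through isolation and increases after release. All values carry
multiplicative Gaussian noise and a log-normal per-subject baseline spread.

A single global seed expands into independent named substreams for behavior
and physiology, so either half of a study can be regenerated byte-identically
without drawing from the other's stream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .behavior_io import (
    Analyte,
    Behavior,
    BehaviorEvent,
    Observation,
    PhysioPanel,
    PHYSIO_COLUMNS,
    TRIPHASE_TIMEPOINTS,
    WEEKLY_TIMEPOINTS,
    write_event_log,
)

__all__ = [
    "StressEffects",
    "PostStressShifts",
    "SimulationConfig",
    "SyntheticStudy",
    "planted_subjects",
    "planted_norm_ds",
    "planted_classes",
    "simulate_colony",
    "simulate_physiology",
    "simulate_study",
    "generate_fixture_study",
]

DAYS_PER_OBSERVATION = 6

#: baseline analyte levels in assay units (HC pg/mg, OT/AVP pg/mL,
#: IgG/IgA ug/g, weight kg)
BASELINES: dict[Analyte, float] = {
    Analyte.HC: 50.0,
    Analyte.OT: 100.0,
    Analyte.AVP: 50.0,
    Analyte.IGG: 6.0,
    Analyte.IGA: 4.0,
    Analyte.WEIGHT: 5.0,
}

_BEHAVIOR_STREAM = 11
_PHYSIO_STREAM = 22


@dataclass
class StressEffects:
    """Rank-dependent physiological responses (slopes are per unit of normDS)."""

    hc_rank_slope: float = 1.0  # extra proportional HC rise at S2 for the top rank
    hc_global_increase: float = 0.3  # proportional HC rise shared by all ranks
    hc_recovery_fraction: float = 0.5  # fraction of the S2 increment lost by S3
    ot_baseline_rank_slope: float = 0.5  # proportional OT elevation at S1 per normDS
    ot_global_increase: float = 0.2  # proportional OT rise at S2, all ranks
    ot_recovery_gain: float = 0.35  # proportional further OT rise S2 -> S3 at normDS 0
    ot_recovery_rank_slope: float = -0.30  # rank slope of the S2 -> S3 OT rise
    avp_shift: float = 0.4  # proportional AVP rise at S2, all ranks
    avp_recovery_base: float = 0.10  # proportional AVP fall S2 -> S3 at normDS 0
    avp_recovery_rank_slope: float = 0.30  # extra AVP fall per normDS
    igg_iga_ramp_onset_week: int = 2  # first elevated weekly sample
    igg_iga_ramp_gain: float = 0.5  # proportional Ig elevation at normDS 0
    igg_iga_rank_slope: float = -0.25  # rank slope of the Ig elevation
    weight_s3_gain: float = 0.04  # proportional weight gain at S3


@dataclass
class PostStressShifts:
    """Multiplicative behavior-rate shifts applied in OBS3A/OBS3B."""

    ll_agg_decrease: float = 0.4  # LR-LR agonistic rate multiplier (< 1)
    ll_gro_increase: float = 2.0  # LR-LR grooming rate multiplier (> 1)
    pro_increase_all_types: float = 1.5  # proximity multiplier, every dyad type


@dataclass
class SimulationConfig:
    """Study conditions for a synthetic two-colony experiment."""

    group_sizes: tuple[int, ...] = (7, 6)
    interactions_per_dyad: float = 25.0  # mean decided agonistic bouts / dyad / observation
    dominance_prob: float = 0.9  # P(higher-planted wins a decided bout)
    behavior_rates: dict = field(default_factory=lambda: {"GRO": 12.0, "PRO": 18.0})
    stress_effects: StressEffects = field(default_factory=StressEffects)
    post_stress_shifts: PostStressShifts = field(default_factory=PostStressShifts)
    noise_sd: dict = field(
        default_factory=lambda: {
            "HC": 0.05,
            "OT": 0.05,
            "AVP": 0.05,
            "IGG": 0.06,
            "IGA": 0.06,
            "WEIGHT": 0.01,
        }
    )
    subject_sd: float = 0.10  # log-normal sigma of per-subject baselines
    seed: int = 0

    def validate(self) -> None:
        if any(int(n) < 2 for n in self.group_sizes):
            raise ValueError("every group must have at least 2 subjects")
        if not 0.5 <= self.dominance_prob <= 1.0:
            raise ValueError("dominance_prob must lie in [0.5, 1]")
        if self.interactions_per_dyad < 0:
            raise ValueError("interactions_per_dyad must be >= 0")
        for key, rate in self.behavior_rates.items():
            if Behavior(key) not in (Behavior.GRO, Behavior.PRO):
                raise ValueError("behavior_rates configures GRO and PRO only")
            if rate < 0:
                raise ValueError(f"behavior rate {key} must be >= 0")
        for key, sd in self.noise_sd.items():
            Analyte(key)
            if sd < 0:
                raise ValueError(f"noise sd {key} must be >= 0")
        shifts = self.post_stress_shifts
        if min(shifts.ll_agg_decrease, shifts.ll_gro_increase, shifts.pro_increase_all_types) < 0:
            raise ValueError("post-stress multipliers must be >= 0")
        if not 0 <= self.stress_effects.igg_iga_ramp_onset_week <= 4:
            raise ValueError("igg_iga_ramp_onset_week must be in 0..4")

    def to_dict(self) -> dict:
        return asdict(self)


def _group_ids(config: SimulationConfig) -> list[str]:
    return [chr(ord("A") + i) for i in range(len(config.group_sizes))]


def planted_subjects(config: SimulationConfig) -> dict[str, list[str]]:
    """group_id -> subjects in planted rank order (index 0 = top rank)."""
    return {
        gid: [f"{gid}{i + 1}" for i in range(int(n))]
        for gid, n in zip(_group_ids(config), config.group_sizes)
    }


def planted_norm_ds(config: SimulationConfig) -> dict[str, float]:
    """Planted normalized dominance scores, evenly spaced from 1 down to 0."""
    scores = {}
    for subjects in planted_subjects(config).values():
        n = len(subjects)
        for rank0, s in enumerate(subjects):
            scores[s] = (n - 1 - rank0) / (n - 1)
    return scores


def planted_classes(config: SimulationConfig) -> dict[str, str]:
    """Planted HR/LR split: the top ceil(n/2) ranks of each group are HR."""
    classes = {}
    for subjects in planted_subjects(config).values():
        n_hr = math.ceil(len(subjects) / 2)
        for rank0, s in enumerate(subjects):
            classes[s] = "HR" if rank0 < n_hr else "LR"
    return classes


def _spread_over_days(rng: np.random.Generator, count: int) -> np.ndarray:
    if count == 0:
        return np.zeros(DAYS_PER_OBSERVATION, dtype=int)
    return rng.multinomial(count, np.full(DAYS_PER_OBSERVATION, 1 / DAYS_PER_OBSERVATION))


def simulate_colony(config: SimulationConfig) -> list[BehaviorEvent]:
    """Directed behavioral event logs for all groups and observation periods."""
    config.validate()
    rng = np.random.default_rng([int(config.seed), _BEHAVIOR_STREAM])
    shifts = config.post_stress_shifts
    classes = planted_classes(config)
    events: list[BehaviorEvent] = []

    def emit(gid, obs, initiator, receiver, behavior, per_day):
        for day, c in enumerate(per_day, start=1):
            if c > 0:
                events.append(
                    BehaviorEvent(
                        group_id=gid,
                        observation_id=obs,
                        day=day,
                        initiator=initiator,
                        receiver=receiver,
                        behavior=behavior,
                        count=int(c),
                    )
                )

    for gid, subjects in planted_subjects(config).items():
        n = len(subjects)
        for obs in Observation:
            post = obs is not Observation.OBS1
            # agonistic bouts per unordered dyad; higher-planted subject is `hi`
            for i in range(n):
                for j in range(i + 1, n):
                    hi, lo = subjects[i], subjects[j]
                    rate = config.interactions_per_dyad
                    if post and classes[hi] == "LR" and classes[lo] == "LR":
                        rate *= shifts.ll_agg_decrease
                    bouts = rng.poisson(rate)
                    wins_hi = rng.binomial(bouts, config.dominance_prob) if bouts else 0
                    wins_lo = bouts - wins_hi
                    emit(gid, obs, hi, lo, Behavior.AGG, _spread_over_days(rng, wins_hi))
                    emit(gid, obs, lo, hi, Behavior.SUB, _spread_over_days(rng, wins_hi))
                    emit(gid, obs, lo, hi, Behavior.AGG, _spread_over_days(rng, wins_lo))
                    emit(gid, obs, hi, lo, Behavior.SUB, _spread_over_days(rng, wins_lo))
            # prosocial behaviors per directed dyad
            for initiator in subjects:
                for receiver in subjects:
                    if initiator == receiver:
                        continue
                    both_lr = classes[initiator] == "LR" and classes[receiver] == "LR"
                    gro_rate = config.behavior_rates.get("GRO", 0.0)
                    pro_rate = config.behavior_rates.get("PRO", 0.0)
                    if post:
                        if both_lr:
                            gro_rate *= shifts.ll_gro_increase
                        pro_rate *= shifts.pro_increase_all_types
                    emit(gid, obs, initiator, receiver, Behavior.GRO,
                         _spread_over_days(rng, rng.poisson(gro_rate)))
                    emit(gid, obs, initiator, receiver, Behavior.PRO,
                         _spread_over_days(rng, rng.poisson(pro_rate)))
    return events


def _physio_trajectory(
    analyte: Analyte, base: float, nd: float, eff: StressEffects
) -> dict[str, float]:
    """Noise-free expected levels per timepoint for one subject."""
    if analyte is Analyte.HC:
        inc = eff.hc_global_increase + eff.hc_rank_slope * nd
        return {
            "S1": base,
            "S2": base * (1 + inc),
            "S3": base * (1 + (1 - eff.hc_recovery_fraction) * inc),
        }
    if analyte is Analyte.OT:
        s1 = base * (1 + eff.ot_baseline_rank_slope * nd)
        s2 = s1 + base * eff.ot_global_increase
        s3 = s2 + base * (eff.ot_recovery_gain + eff.ot_recovery_rank_slope * nd)
        return {"S1": s1, "S2": s2, "S3": s3}
    if analyte is Analyte.AVP:
        s2 = base * (1 + eff.avp_shift)
        s3 = s2 - base * (eff.avp_recovery_base + eff.avp_recovery_rank_slope * nd)
        return {"S1": base, "S2": s2, "S3": s3}
    if analyte is Analyte.WEIGHT:
        return {"S1": base, "S2": base, "S3": base * (1 + eff.weight_s3_gain)}
    # weekly immunoglobulins
    elevation = eff.igg_iga_ramp_gain + eff.igg_iga_rank_slope * nd
    levels = {}
    for week in range(5):
        tp = f"W{week}"
        if week < eff.igg_iga_ramp_onset_week:
            levels[tp] = base
        elif week < 4:
            levels[tp] = base * (1 + elevation)
        else:
            levels[tp] = base * (1 + 0.5 * elevation)  # partial decline at week 4
    return levels


def simulate_physiology(
    config: SimulationConfig, norm_ds: Mapping[str, float] | None = None
) -> PhysioPanel:
    """Longitudinal physiology panels with rank-dependent stress responses.

    ``norm_ds`` maps subject -> planted normalized dominance score; by default
    the evenly spaced planted scores of the config are used.
    """
    config.validate()
    if norm_ds is None:
        norm_ds = planted_norm_ds(config)
    rng = np.random.default_rng([int(config.seed), _PHYSIO_STREAM])
    eff = config.stress_effects
    rows = []
    for gid, subjects in planted_subjects(config).items():
        for subject in subjects:
            nd = float(norm_ds[subject])
            for analyte in Analyte:
                base = BASELINES[analyte] * float(
                    np.exp(rng.normal(0.0, config.subject_sd))
                )
                sd = float(config.noise_sd.get(analyte.value, 0.0))
                for tp, level in _physio_trajectory(analyte, base, nd, eff).items():
                    noisy = level * (1 + rng.normal(0.0, sd)) if sd > 0 else level
                    rows.append((gid, subject, analyte.value, tp, max(noisy, 1e-6)))
    frame = pd.DataFrame(rows, columns=PHYSIO_COLUMNS)
    return PhysioPanel(frame, require_complete=True)


@dataclass
class SyntheticStudy:
    """A complete simulated study plus its planted ground truth."""

    config: SimulationConfig
    events: list[BehaviorEvent]
    physiology: PhysioPanel
    planted_order: dict[str, list[str]]
    planted_norm_ds: dict[str, float]
    planted_classes: dict[str, str]


def simulate_study(config: SimulationConfig | None = None) -> SyntheticStudy:
    config = config or SimulationConfig()
    return SyntheticStudy(
        config=config,
        events=simulate_colony(config),
        physiology=simulate_physiology(config),
        planted_order=planted_subjects(config),
        planted_norm_ds=planted_norm_ds(config),
        planted_classes=planted_classes(config),
    )


def generate_fixture_study(config: SimulationConfig, out_dir) -> dict[str, Path]:
    """Write a complete synthetic study (events.csv, physiology.csv) to disk."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    study = simulate_study(config)
    events_path = out_dir / "events.csv"
    physio_path = out_dir / "physiology.csv"
    write_event_log(study.events, events_path)
    study.physiology.to_csv(physio_path)
    return {"events": events_path, "physiology": physio_path}
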