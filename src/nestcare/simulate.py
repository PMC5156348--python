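"""Two-parent behavioural simulator emitting ethogram event logs.

Each parent moves among three states — ``off`` (out of the nest box),
``inside`` and ``care`` — as a continuous-time jump process.  Transition
hazards are piecewise-constant on a 1-minute grid: the log-hazard of
entering care carries a diurnal polynomial, a stage-day shift, a per-parent
normal random intercept and a partner-coupling term (the entry hazard is
multiplied by ``joint_coupling`` while the other parent is in care); the
care-exit hazard carries the same shifts with opposite sign.  Between grid
updates the simulation is exact: competing exponential clocks over both
parents' transitions plus Poisson feeding bouts while a parent is in the
box (provisioning only).

Outside lights-on hours both parents roost on the nest, so every run
starts at 06:00 in ``care``; only the requested recording span is emitted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .ethogram import (FULL_DAY, MIDDAY_3H, PARENTS, FeedingEvent,
                       NestRecording, StateInterval)

HOUR = 3600.0
SIM_START = 6 * HOUR          # lights on; both parents on nest
GRID_S = 60.0                 # hazard-update grid

STATES3 = ("off", "inside", "care")
TRANSITIONS = (
    ("off", "inside"), ("off", "care"),
    ("inside", "off"), ("inside", "care"),
    ("care", "inside"), ("care", "off"),
)
CARE_ENTRY = {("off", "care"), ("inside", "care")}
CARE_EXIT = {("care", "inside"), ("care", "off")}


def _default_rates() -> Dict[str, Dict[Tuple[str, str], float]]:
    # per-hour baseline transition rates, per sex
    return {
        "male": {
            ("off", "inside"): 2.0, ("off", "care"): 4.0,
            ("inside", "off"): 5.0, ("inside", "care"): 7.0,
            ("care", "inside"): 1.5, ("care", "off"): 3.0,
        },
        "female": {
            ("off", "inside"): 2.0, ("off", "care"): 8.0,
            ("inside", "off"): 4.0, ("inside", "care"): 10.0,
            ("care", "inside"): 1.2, ("care", "off"): 1.2,
        },
    }


@dataclass
class SimulationConfig:
    """Full parameterization of the two-parent behavioural process."""

    n_nests: int = 10
    base_rates: Dict[str, Dict[Tuple[str, str], float]] = field(
        default_factory=_default_rates)
    #: polynomial coefficients (powers 1..len) on the care-entry log-hazard,
    #: evaluated in scaled daytime u = (hour - 13) / 6 (u in [-1, 1] over
    #: 07:00-19:00); keyed by stage
    diurnal_coefficients: Dict[str, Tuple[float, ...]] = field(
        default_factory=lambda: {"incubation": (), "provisioning": ()})
    #: additive log-hazard shift on care entry (and its negative on care
    #: exit) per (stage, stage_day, sex)
    stage_effects: Dict[Tuple[str, int, str], float] = field(default_factory=dict)
    sigma_individual: float = 0.0
    joint_coupling: float = 1.0
    feed_rate: float = 0.0      # bouts/hour while in the box (provisioning)
    seed: Optional[int] = None

    def validate(self) -> None:
        for sex in PARENTS:
            for tr in TRANSITIONS:
                if self.base_rates[sex][tr] <= 0:
                    raise ValueError(f"rate {sex} {tr} must be > 0")
        if self.sigma_individual < 0:
            raise ValueError("sigma_individual must be >= 0")
        if self.joint_coupling <= 0:
            raise ValueError("joint_coupling must be > 0")
        if self.feed_rate < 0:
            raise ValueError("feed_rate must be >= 0")


def preset_paperlike() -> SimulationConfig:
    """Default configuration mirroring the study's qualitative structure.

    Female-biased incubation, male effort rising over the incubation stage,
    brooding declining sharply over provisioning, a mid-day dip in care on
    early days, individual consistency yielding window repeatabilities
    roughly in the 0.2-0.8 band, and partner coupling producing excess
    joint care.
    """
    cfg = SimulationConfig(
        n_nests=10,
        diurnal_coefficients={
            "incubation": (0.25, -0.9),
            "provisioning": (-0.45,),
        },
        stage_effects={
            ("incubation", 3, "male"): -0.35,
            ("incubation", 8, "male"): 0.0,
            ("incubation", 13, "male"): 0.4,
            ("incubation", 3, "female"): 0.15,
            ("incubation", 8, "female"): 0.15,
            ("incubation", 13, "female"): 0.15,
            ("provisioning", 3, "male"): 0.1,
            ("provisioning", 10, "male"): -0.7,
            ("provisioning", 17, "male"): -1.5,
            ("provisioning", 3, "female"): -0.2,
            ("provisioning", 10, "female"): -1.0,
            ("provisioning", 17, "female"): -1.8,
        },
        sigma_individual=0.6,
        joint_coupling=1.6,
        feed_rate=6.0,
    )
    cfg.validate()
    return cfg


def config_to_dict(config: SimulationConfig) -> dict:
    """Plain-string representation suitable for YAML/JSON round-tripping."""
    return {
        "n_nests": config.n_nests,
        "base_rates": {sex: {f"{frm}->{to}": r for (frm, to), r in rates.items()}
                       for sex, rates in config.base_rates.items()},
        "diurnal_coefficients": {stage: list(c) for stage, c
                                 in config.diurnal_coefficients.items()},
        "stage_effects": {f"{stage}:{day}:{sex}": v for (stage, day, sex), v
                          in config.stage_effects.items()},
        "sigma_individual": config.sigma_individual,
        "joint_coupling": config.joint_coupling,
        "feed_rate": config.feed_rate,
        "seed": config.seed,
    }


def config_from_dict(d: dict) -> SimulationConfig:
    cfg = SimulationConfig(
        n_nests=int(d.get("n_nests", 10)),
        sigma_individual=float(d.get("sigma_individual", 0.0)),
        joint_coupling=float(d.get("joint_coupling", 1.0)),
        feed_rate=float(d.get("feed_rate", 0.0)),
        seed=d.get("seed"),
    )
    if "base_rates" in d:
        cfg.base_rates = {
            sex: {tuple(k.split("->")): float(v) for k, v in rates.items()}
            for sex, rates in d["base_rates"].items()}
    if "diurnal_coefficients" in d:
        cfg.diurnal_coefficients = {stage: tuple(c) for stage, c
                                    in d["diurnal_coefficients"].items()}
    if "stage_effects" in d:
        eff = {}
        for k, v in d["stage_effects"].items():
            stage, day, sex = k.split(":")
            eff[(stage, int(day), sex)] = float(v)
        cfg.stage_effects = eff
    cfg.validate()
    return cfg


def _log_hazard_shift(config: SimulationConfig, stage: str, stage_day: int,
                      sex: str, t_s: float, intercept: float) -> float:
    u = (t_s / HOUR - 13.0) / 6.0
    shift = intercept + config.stage_effects.get((stage, stage_day, sex), 0.0)
    for i, c in enumerate(config.diurnal_coefficients.get(stage, ()), start=1):
        shift += c * u ** i
    return shift


def simulate_nest(config: SimulationConfig, nest_id: str, stage: str,
                  stage_day: int, span: Tuple[float, float], *,
                  rng: Optional[np.random.Generator] = None,
                  individual_intercepts: Optional[Dict[str, float]] = None,
                  ) -> NestRecording:
    """Simulate one nest-day and return its clipped recording.

    ``individual_intercepts`` maps sex -> random intercept; pass the same
    values across days to give a parent consistent behaviour.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if individual_intercepts is None:
        if config.sigma_individual > 0:
            individual_intercepts = {
                s: rng.normal(0.0, config.sigma_individual) for s in PARENTS}
        else:
            individual_intercepts = {s: 0.0 for s in PARENTS}
    rec_start, rec_end = span
    state = {s: "care" for s in PARENTS}
    entered = {s: SIM_START for s in PARENTS}
    bouts: List[StateInterval] = []
    feeds: List[FeedingEvent] = []

    def close_bout(sex: str, until: float) -> None:
        st = state[sex]
        if st == "off":
            return
        s, e = max(entered[sex], rec_start), min(until, rec_end)
        if e > s:
            bouts.append(StateInterval(sex, "care" if st == "care" else "inside",
                                       s, e))

    feeding_on = stage == "provisioning" and config.feed_rate > 0
    t = SIM_START
    while t < rec_end:
        seg_end = min(math.floor(t / GRID_S) * GRID_S + GRID_S, rec_end)
        # competing clocks: (rate per hour, kind, sex, destination)
        clocks: List[Tuple[float, str, str, str]] = []
        for sex in PARENTS:
            st = state[sex]
            partner_in_care = state["male" if sex == "female" else "male"] == "care"
            for (frm, to), base in config.base_rates[sex].items():
                if frm != st:
                    continue
                logr = math.log(base)
                shift = _log_hazard_shift(config, stage, stage_day, sex, t,
                                          individual_intercepts[sex])
                if (frm, to) in CARE_ENTRY:
                    logr += shift
                    if partner_in_care:
                        logr += math.log(config.joint_coupling)
                elif (frm, to) in CARE_EXIT:
                    logr -= shift
                clocks.append((math.exp(logr), "move", sex, to))
            if feeding_on and st != "off":
                clocks.append((config.feed_rate, "feed", sex, st))
        total = sum(c[0] for c in clocks)
        if total <= 0:
            t = seg_end
            continue
        wait_s = rng.exponential(1.0 / total) * HOUR
        if t + wait_s >= seg_end:
            t = seg_end
            continue
        t += wait_s
        pick = rng.uniform(0.0, total)
        acc = 0.0
        for rate, kind, sex, dest in clocks:
            acc += rate
            if pick < acc:
                break
        if kind == "feed":
            if rec_start <= t < rec_end:
                feeds.append(FeedingEvent(sex, t))
        else:
            close_bout(sex, t)
            state[sex] = dest
            entered[sex] = t
    for sex in PARENTS:
        close_bout(sex, rec_end)
    feeds.sort(key=lambda f: f.time)
    return NestRecording(nest_id=nest_id, stage=stage, stage_day=stage_day,
                         record_start=rec_start, record_end=rec_end,
                         intervals=sorted(bouts, key=lambda b: (b.parent, b.start)),
                         feedings=feeds)


@dataclass(frozen=True)
class ScheduledRecording:
    nest_id: str
    stage: str
    stage_day: int
    span: Tuple[float, float]

    @property
    def hours(self) -> float:
        return (self.span[1] - self.span[0]) / HOUR


def schedule(config: SimulationConfig, *, all_full_day: bool = False
             ) -> List[ScheduledRecording]:
    """The study layout: per-nest recording sessions with spans.

    Incubation nests: full days 3 and 13 plus a mid-day 3h on day 8.
    Provisioning nests: full days 3 and 17 post-hatching, mid-day 3h on day
    10, plus a mid-day 3h on incubation day 8.  ``all_full_day`` switches
    every session to the 12h span (the counterfactual design).
    """
    three_h = FULL_DAY if all_full_day else MIDDAY_3H
    out: List[ScheduledRecording] = []
    for i in range(1, config.n_nests + 1):
        nid = f"I{i:02d}"
        out += [ScheduledRecording(nid, "incubation", 3, FULL_DAY),
                ScheduledRecording(nid, "incubation", 8, three_h),
                ScheduledRecording(nid, "incubation", 13, FULL_DAY)]
    for i in range(1, config.n_nests + 1):
        nid = f"P{i:02d}"
        out += [ScheduledRecording(nid, "incubation", 8, three_h),
                ScheduledRecording(nid, "provisioning", 3, FULL_DAY),
                ScheduledRecording(nid, "provisioning", 10, three_h),
                ScheduledRecording(nid, "provisioning", 17, FULL_DAY)]
    return out


def scheduled_hours(entries: Sequence[ScheduledRecording]) -> float:
    """Total footage the schedule commits to, in hours."""
    return sum(e.hours for e in entries)


def simulate_population(config: SimulationConfig, *,
                        all_full_day: bool = False) -> List[NestRecording]:
    """Simulate the full study corpus.

    Per-parent random intercepts are drawn once per nest so behaviour is
    consistent across that nest's recording days; the event stream of each
    session gets an independent child seed, so the corpus is deterministic
    given ``config.seed``.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    plan = schedule(config, all_full_day=all_full_day)
    nests = sorted({e.nest_id for e in plan})
    intercept_rng = np.random.default_rng(ss.spawn(1)[0])
    intercepts = {
        nid: {s: (intercept_rng.normal(0.0, config.sigma_individual)
                  if config.sigma_individual > 0 else 0.0)
              for s in PARENTS}
        for nid in nests
    }
    out = []
    for entry, child in zip(plan, ss.spawn(len(plan))):
        out.append(simulate_nest(
            config, entry.nest_id, entry.stage, entry.stage_day, entry.span,
            rng=np.random.default_rng(child),
            individual_intercepts=intercepts[entry.nest_id]))
    return out


def stationary_distribution(rates: Dict[Tuple[str, str], float]) -> Dict[str, float]:
    """Closed-form stationary distribution of the 3-state generator.

    Oracle for the homogeneous, uncoupled simulator: solve pi Q = 0 with
    the given per-hour rates.
    """
    idx = {s: i for i, s in enumerate(STATES3)}
    Q = np.zeros((3, 3))
    for (frm, to), r in rates.items():
        Q[idx[frm], idx[to]] = r
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    A = np.vstack([Q.T, np.ones(3)])
    b = np.array([0.0, 0.0, 0.0, 1.0])
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    return {s: float(pi[idx[s]]) for s in STATES3}
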