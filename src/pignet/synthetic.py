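"""Synthetic study generator with known ground-truth effects.

Generates pens of mixed-sex pigs housed with a small number of littermates,
go/no-go trial records with a learnable location preference, post-mixing
agonistic event streams, and lesion counts driven by received damaging
aggression.  Every draw flows from one seeded generator, so a study is
fully reproducible from its seed.

The defaults emulate the study conditions the pipeline assumes: pens of
12-16 pigs (about 14 on average), body weight 62.4 +/- 7.2 kg with reduced
within-pen spread, 6-14 non-littermates per pig (mean near 10.8), per-pig
agonistic involvement with median of roughly 600 s over the 5 h observation
window, and a dyadic aggression rate that decays exponentially from mixing.
All effects (sex, weight, cognition, dominance asymmetry, lesion rate) are
user-settable, including zero for a null world.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .cognition import PHASE_REVERSAL, PHASE_SDT, reversal_pass
from .ethogram import default_ethogram
from .events import OBSERVATION_WINDOW_S, BehaviourEvent, sort_events

#: pen floor dimensions, metres
PEN_LENGTH_M = 6.1
PEN_WIDTH_M = 2.35

MEAN_WEIGHT_KG = 62.4
WEIGHT_SD_KG = 7.2
# between-pen and within-pen components of the weight SD: weight variation
# within a pen is deliberately minimised at regrouping, so most of the
# overall 7.2 kg spread sits between pens
BETWEEN_PEN_WEIGHT_SD = 4.6
WITHIN_PEN_WEIGHT_SD = 5.5


def space_allowance_m2(
    n_pigs: float, length_m: float = PEN_LENGTH_M, width_m: float = PEN_WIDTH_M
) -> float:
    """Floor area per pig for a group of ``n_pigs`` in a standard pen."""
    if n_pigs <= 0:
        raise ValueError("n_pigs must be positive")
    return length_m * width_m / n_pigs


@dataclass(frozen=True)
class Pig:
    pig_id: str
    pen_id: str
    litter_id: str
    sex: str  # "M" | "F"
    weight_kg: float


@dataclass
class PenConfig:
    pen_id: str
    pigs: list[Pig]

    @property
    def n_pigs(self) -> int:
        return len(self.pigs)

    def littermate_count(self, pig: Pig) -> int:
        return sum(1 for p in self.pigs if p.litter_id == pig.litter_id) - 1

    def n_nonlittermates(self, pig: Pig) -> int:
        return self.n_pigs - 1 - self.littermate_count(pig)


@dataclass(frozen=True)
class EffectConfig:
    """Ground-truth effect sizes injected into the generator.

    Multiplicative effects equal to 1 and slopes equal to 0 mean "no
    effect"; :meth:`null` returns that configuration.
    """

    #: dyad/initiation rate multiplier for males
    male_rate_multiplier: float = 1.6
    #: log-linear slope of aggression propensity per kg above the mean
    weight_log_slope: float = 0.02
    #: damaging-aggression rate multiplier for dyads involving a
    #: reversal-learning passer; sized by power analysis so a 14-pen study
    #: detects it with >= 80% power
    reversal_uni_multiplier: float = 1.5
    #: probability that a fight ends with a clear retreat
    fight_decided_p: float = 0.55
    #: logistic slope (per kg weight difference) of the heavier pig winning
    retreat_weight_slope: float = 0.15
    #: expected fresh lesions per second of damaging aggression received
    lesion_rate_per_s: float = 0.2
    # dyadic interaction budget over the 5 h window (non-littermate dyads)
    nondamaging_rate: float = 4.0
    damaging_rate: float = 1.4
    fight_rate: float = 0.75
    littermate_rate: float = 0.3
    #: exponential decay constant of the aggression rate, seconds
    decay_tau_s: float = 5400.0

    @classmethod
    def null(cls) -> "EffectConfig":
        return cls(
            male_rate_multiplier=1.0,
            weight_log_slope=0.0,
            reversal_uni_multiplier=1.0,
            retreat_weight_slope=0.0,
        )


def generate_pen(
    pen_id: str,
    rng: np.random.Generator,
    n_pigs: Optional[int] = None,
    batch: str = "B1",
) -> PenConfig:
    """One pen roster: 12-16 pigs, balanced sexes, sibling groups of 1-4.

    Sibling group sizes mirror the typical regrouping pattern (mostly
    pairs, occasional singletons, triples and quads), which puts the
    per-pig non-littermate count in the 8-15 range with a mean near 11-12.
    """
    if n_pigs is None:
        n_pigs = int(rng.choice([12, 13, 14], p=[0.4, 0.4, 0.2]))
    if n_pigs < 2:
        raise ValueError("a pen needs at least 2 pigs to form dyads")
    sizes: list[int] = []
    remaining = n_pigs
    while remaining > 0:
        size = int(rng.choice([1, 2, 3, 4], p=[0.04, 0.78, 0.14, 0.04]))
        # keep every pig's non-littermate count within the 6-14 range
        size = max(size, n_pigs - 14)
        size = min(size, remaining)
        sizes.append(size)
        remaining -= size
    sexes = ["M"] * (n_pigs // 2) + ["F"] * (n_pigs - n_pigs // 2)
    rng.shuffle(sexes)
    pen_mean = rng.normal(MEAN_WEIGHT_KG, BETWEEN_PEN_WEIGHT_SD)
    pigs = []
    k = 0
    for litter_no, size in enumerate(sizes, start=1):
        litter_id = f"{pen_id}L{litter_no:02d}"
        for _ in range(size):
            k += 1
            weight = rng.normal(pen_mean, WITHIN_PEN_WEIGHT_SD)
            while weight <= 1.0:
                weight = rng.normal(pen_mean, WITHIN_PEN_WEIGHT_SD)
            pigs.append(
                Pig(
                    pig_id=f"{pen_id}P{k:02d}",
                    pen_id=pen_id,
                    litter_id=litter_id,
                    sex=sexes[k - 1],
                    weight_kg=round(float(weight), 1),
                )
            )
    return PenConfig(pen_id=pen_id, pigs=pigs)


def roster_frame(pens: Sequence[PenConfig]) -> pd.DataFrame:
    rows = []
    for pen in pens:
        for pig in pen.pigs:
            rows.append(
                {
                    "pig_id": pig.pig_id,
                    "pen_id": pig.pen_id,
                    "litter_id": pig.litter_id,
                    "sex": pig.sex,
                    "weight_kg": pig.weight_kg,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cognitive trials


def _sdt_locations(rng: np.random.Generator, n: int) -> list[str]:
    # pseudorandomised: never more than two negative trials in a row
    locations = []
    neg_run = 0
    for _ in range(n):
        if neg_run >= 2:
            loc = "positive"
        else:
            loc = "negative" if rng.random() < 0.5 else "positive"
        neg_run = neg_run + 1 if loc == "negative" else 0
        locations.append(loc)
    return locations


def generate_pig_trials(
    pig_id: str,
    rng: np.random.Generator,
    p_learn: float,
    onset_trial: int = 1,
    n_trials: int = 36,
    phase: str = PHASE_SDT,
    pre_onset_p: float = 0.5,
) -> list[dict]:
    """One phase of go/no-go trials for one pig.

    Decisions are correct with probability ``pre_onset_p`` before the
    learning-onset trial and ``p_learn`` from it onwards.
    """
    if not 0.0 < p_learn <= 1.0:
        raise ValueError("p_learn must be in (0, 1]")
    locations = _sdt_locations(rng, n_trials)
    rows = []
    for i, loc in enumerate(locations, start=1):
        p = p_learn if i >= onset_trial else pre_onset_p
        correct = rng.random() < p
        if loc == "positive":
            decision = "go" if correct else "no_go"
        else:
            decision = "no_go" if correct else "go"
        latency = float(
            np.round(rng.uniform(3, 12) if decision == "go" else rng.uniform(15, 30), 1)
        )
        rows.append(
            {
                "pig": pig_id,
                "phase": phase,
                "trial": i,
                "location": loc,
                "decision": decision,
                "latency_s": latency,
            }
        )
    return rows


def generate_trials(
    roster: pd.DataFrame,
    rng: np.random.Generator,
    sdt_inclusion_p: float = 0.71,
    reversal_inclusion_p: float = 0.85,
) -> pd.DataFrame:
    """Trial records for a study roster.

    Each pig carries a latent ability; ability raises the post-onset
    probability of a correct SDT decision and the probability of tracking
    the reversed cue.  Pigs enter the SDT with probability
    ``sdt_inclusion_p``; pigs that showed a location preference (proxied by
    SDT inclusion) enter reversal with probability ``reversal_inclusion_p``,
    mirroring the attrition between the two tests.  The defaults put the
    median trials-to-pass near the 17-trial fast/slow split.
    """
    rows: list[dict] = []
    for pig_id in roster["pig_id"]:
        ability = rng.normal()
        if rng.random() >= sdt_inclusion_p:
            continue
        p_learn = float(expit(1.8 + 0.9 * ability))
        onset = 1 + int(rng.geometric(0.15))
        rows += generate_pig_trials(
            str(pig_id), rng, p_learn=p_learn, onset_trial=onset, n_trials=36
        )
        if rng.random() < reversal_inclusion_p:
            p_rev = float(expit(1.2 + 0.9 * ability))
            onset_rev = 6 + int(rng.geometric(0.3))
            rows += generate_pig_trials(
                str(pig_id),
                rng,
                p_learn=p_rev,
                onset_trial=onset_rev,
                n_trials=20,
                phase=PHASE_REVERSAL,
                pre_onset_p=0.25,
            )
    return pd.DataFrame(
        rows, columns=["pig", "phase", "trial", "location", "decision", "latency_s"]
    )


# ---------------------------------------------------------------------------
# agonistic events


def _decayed_times(
    rng: np.random.Generator, n: int, duration_s: float, tau_s: float
) -> np.ndarray:
    """Event times from an exponentially decaying rate on [0, duration)."""
    u = rng.random(n)
    mass = 1.0 - math.exp(-duration_s / tau_s)
    return -tau_s * np.log(1.0 - u * mass)


def _propensity(pig: Pig, effects: EffectConfig) -> float:
    prop = effects.male_rate_multiplier if pig.sex == "M" else 1.0
    return prop * math.exp(effects.weight_log_slope * (pig.weight_kg - MEAN_WEIGHT_KG))


def _pick_actor(rng, a: Pig, b: Pig, effects: EffectConfig, power: float = 1.0):
    pa = _propensity(a, effects) ** power
    pb = _propensity(b, effects) ** power
    return (a, b) if rng.random() < pa / (pa + pb) else (b, a)


_NONDAMAGING_MENU = (
    ("heads_up", 0.10, (3.0, 10.0)),
    ("parallel_walk", 0.07, (4.0, 12.0)),
    ("head_knock", 0.30, None),
    ("lunge", 0.18, None),
    ("shove", 0.12, None),
    ("flick", 0.08, None),
    ("push", 0.15, (2.0, 6.0)),
)


def generate_events(
    pen: PenConfig,
    effects: EffectConfig,
    rng: np.random.Generator,
    duration_s: float = OBSERVATION_WINDOW_S,
    reversal_passers: Optional[set[str]] = None,
) -> list[BehaviourEvent]:
    """Post-mixing agonistic event stream for one pen.

    Each non-littermate dyad receives three independent streams of
    interactions (non-damaging, damaging, fights) with exponentially
    decaying onset times.  Actors are chosen in proportion to a propensity
    combining sex and body weight; fight outcomes follow a logistic
    function of the weight difference; dyads involving a reversal-learning
    passer get an elevated damaging-aggression rate.  Littermate dyads
    receive a small residual rate of mild behaviour only.
    """
    passers = reversal_passers or set()
    ethogram = default_ethogram()
    events: list[BehaviourEvent] = []
    pigs = pen.pigs

    for i in range(len(pigs)):
        for j in range(i + 1, len(pigs)):
            a, b = pigs[i], pigs[j]
            littermates = a.litter_id == b.litter_id
            gm = math.sqrt(_propensity(a, effects) * _propensity(b, effects))
            uni_mult = (
                effects.reversal_uni_multiplier
                if (a.pig_id in passers or b.pig_id in passers)
                else 1.0
            )
            if littermates:
                rates = {"nd": effects.littermate_rate, "dmg": 0.0, "fight": 0.0}
            else:
                rates = {
                    "nd": effects.nondamaging_rate * gm,
                    "dmg": effects.damaging_rate * gm * uni_mult,
                    "fight": effects.fight_rate * gm,
                }

            # non-damaging / display stream
            n_nd = rng.poisson(rates["nd"])
            codes, probs, durs = zip(*[(c, p, d) for c, p, d in _NONDAMAGING_MENU])
            probs = np.array(probs) / sum(probs)
            for t in _decayed_times(rng, n_nd, duration_s, effects.decay_tau_s):
                idx = rng.choice(len(codes), p=probs)
                code, dur_range = codes[idx], durs[idx]
                actor, receiver = _pick_actor(rng, a, b, effects)
                dur = 0.0 if dur_range is None else float(rng.uniform(*dur_range))
                t = min(t, duration_s - dur - 0.5)
                if t < 0:
                    continue
                events.append(
                    BehaviourEvent(float(t), actor.pig_id, receiver.pig_id, code, dur)
                )

            # damaging unilateral stream: bites and bullying
            n_dmg = rng.poisson(rates["dmg"])
            for t in _decayed_times(rng, n_dmg, duration_s, effects.decay_tau_s):
                actor, receiver = _pick_actor(rng, a, b, effects, power=2.0)
                if rng.random() < 0.7:
                    t = min(t, duration_s - 6.0)
                    events.append(
                        BehaviourEvent(float(t), actor.pig_id, receiver.pig_id, "single_bite")
                    )
                    if rng.random() < 0.15:  # reciprocated exchange
                        events.append(
                            BehaviourEvent(
                                float(t + 1.5), receiver.pig_id, actor.pig_id, "single_bite"
                            )
                        )
                else:
                    dur = float(rng.uniform(8, 30))
                    t = min(t, duration_s - dur - 0.5)
                    if t < 0:
                        continue
                    events.append(
                        BehaviourEvent(float(t), actor.pig_id, receiver.pig_id, "bully", dur)
                    )

            # fight stream
            n_fight = rng.poisson(rates["fight"])
            fight_times = np.sort(_decayed_times(rng, n_fight, duration_s, effects.decay_tau_s))
            last_end = -math.inf
            for t in fight_times:
                total = float(rng.lognormal(math.log(35.0), 0.7))
                total = min(total, 600.0)
                t = float(max(t, last_end + rng.uniform(65.0, 200.0)))
                if t + total + 5.0 > duration_s:
                    continue
                initiator, receiver = _pick_actor(rng, a, b, effects)
                if rng.random() < 0.25 and total > 20.0:
                    # fighting pauses: two fight segments around a rest
                    rest = float(rng.uniform(5.0, min(25.0, total - 10.0)))
                    seg = (total - rest) / 2.0
                    events.append(
                        BehaviourEvent(t, initiator.pig_id, receiver.pig_id, "fight", seg)
                    )
                    events.append(
                        BehaviourEvent(t + seg, initiator.pig_id, receiver.pig_id, "rest", rest)
                    )
                    events.append(
                        BehaviourEvent(
                            t + seg + rest, initiator.pig_id, receiver.pig_id, "fight", seg
                        )
                    )
                else:
                    events.append(
                        BehaviourEvent(t, initiator.pig_id, receiver.pig_id, "fight", total)
                    )
                t_end = t + total
                last_end = t_end
                if rng.random() < effects.fight_decided_p:
                    p_a_wins = expit(
                        effects.retreat_weight_slope * (a.weight_kg - b.weight_kg)
                    )
                    winner, loser = (a, b) if rng.random() < p_a_wins else (b, a)
                    events.append(
                        BehaviourEvent(
                            min(t_end + 1.0, duration_s), loser.pig_id, winner.pig_id, "retreat"
                        )
                    )
    return sort_events(events)


# ---------------------------------------------------------------------------
# lesions

REGION_SHARES = {"anterior": 0.78, "central": 0.13, "posterior": 0.09}
PRE_MIXING_MEANS = {"anterior": 1.5, "central": 0.5, "posterior": 0.3}
WEEKLY_BASELINES = {
    "1wk": {"anterior": 10.0, "central": 0.8, "posterior": 0.5},
    "2wk": {"anterior": 8.0, "central": 0.6, "posterior": 0.4},
}


def damaging_received_seconds(events: Sequence[BehaviourEvent]) -> dict[str, float]:
    """Seconds of damaging aggression received per pig.

    Bites count one second to the receiver, bullying its duration, and
    mutual fighting its duration to both participants.
    """
    ethogram = default_ethogram()
    received: dict[str, float] = {}
    for e in events:
        if e.receiver is None:
            continue
        cat = ethogram.category(e.code)
        if cat == "single_bite":
            received[e.receiver] = received.get(e.receiver, 0.0) + 1.0
        elif cat == "unilateral":
            received[e.receiver] = received.get(e.receiver, 0.0) + e.duration_s
        elif cat == "mutual_fight":
            for pig in (e.actor, e.receiver):
                received[pig] = received.get(pig, 0.0) + e.duration_s
    return received


def expected_lesion_mean(
    received_s: float, region: str, effects: EffectConfig, timepoint: str = "24h"
) -> float:
    """Expected fresh-lesion count for a region given received aggression.

    Linear in received seconds at 24 h; later timepoints carry a small
    residual dependence on the acute aggression received.
    """
    share = REGION_SHARES[region]
    if timepoint == "pre":
        return PRE_MIXING_MEANS[region]
    if timepoint == "24h":
        return PRE_MIXING_MEANS[region] + share * effects.lesion_rate_per_s * received_s
    return (
        WEEKLY_BASELINES[timepoint][region]
        + share * 0.05 * effects.lesion_rate_per_s * received_s
    )


def generate_lesions(
    roster: pd.DataFrame,
    events: Sequence[BehaviourEvent],
    effects: EffectConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Poisson lesion counts per pig, region and timepoint."""
    received = damaging_received_seconds(events)
    rows = []
    for pig_id in roster["pig_id"]:
        r = received.get(str(pig_id), 0.0)
        for region in REGION_SHARES:
            for tp in ("pre", "24h", "1wk", "2wk"):
                mean = expected_lesion_mean(r, region, effects, timepoint=tp)
                rows.append(
                    {
                        "pig": str(pig_id),
                        "timepoint": tp,
                        "region": region,
                        "count": int(rng.poisson(mean)),
                    }
                )
    return pd.DataFrame(rows, columns=["pig", "timepoint", "region", "count"])


# ---------------------------------------------------------------------------
# whole study


@dataclass
class SyntheticStudy:
    """A complete synthetic study: inputs for every pipeline stage."""

    roster: pd.DataFrame
    events: pd.DataFrame  # event CSV dialect, with a pen_id column
    trials: pd.DataFrame
    lesions: pd.DataFrame
    effects: EffectConfig
    seed: int
    reversal_passers: set[str] = field(default_factory=set)


def generate_study(
    n_pens: int = 14,
    effects: Optional[EffectConfig] = None,
    seed: int = 0,
    n_pigs_per_pen: Optional[int] = None,
    duration_s: float = OBSERVATION_WINDOW_S,
) -> SyntheticStudy:
    """Generate a full study: pens, trials, events and lesions.

    Deterministic given ``seed``; per-pen substreams are spawned from the
    master generator so pens are independent.
    """
    from .events import events_to_frame

    effects = effects or EffectConfig()
    master = np.random.default_rng(seed)
    pen_rngs = master.spawn(n_pens + 2)
    trial_rng, lesion_rng = pen_rngs[-2], pen_rngs[-1]

    pens = [
        generate_pen(f"pen{p + 1:02d}", pen_rngs[p], n_pigs=n_pigs_per_pen)
        for p in range(n_pens)
    ]
    roster = roster_frame(pens)
    trials = generate_trials(roster, trial_rng)

    # reversal outcome drives the injected cognition effect on events
    passers: set[str] = set()
    if len(trials):
        rev = trials[trials["phase"] == PHASE_REVERSAL]
        for pig, sub in rev.groupby("pig"):
            flags = [
                (r.decision == "go") == (r.location == "positive")
                for r in sub.sort_values("trial").itertuples(index=False)
            ]
            if reversal_pass(flags):
                passers.add(str(pig))

    event_frames = []
    for p, pen in enumerate(pens):
        evs = generate_events(
            pen, effects, pen_rngs[p], duration_s=duration_s, reversal_passers=passers
        )
        frame = events_to_frame(evs)
        frame.insert(0, "pen_id", pen.pen_id)
        event_frames.append(frame)
    events = (
        pd.concat(event_frames, ignore_index=True)
        if event_frames
        else pd.DataFrame()
    )

    lesions = generate_lesions(
        roster,
        _frame_to_event_list(events),
        effects,
        lesion_rng,
    )
    return SyntheticStudy(
        roster=roster,
        events=events,
        trials=trials,
        lesions=lesions,
        effects=effects,
        seed=seed,
        reversal_passers=passers,
    )


def _frame_to_event_list(events: pd.DataFrame) -> list[BehaviourEvent]:
    if events.empty:
        return []
    out = []
    for r in events.itertuples(index=False):
        receiver = r.receiver
        if receiver is None or (isinstance(receiver, float) and pd.isna(receiver)):
            receiver = None
        out.append(
            BehaviourEvent(
                float(r.time_s),
                str(r.actor),
                None if receiver is None else str(receiver),
                str(r.behaviour),
                float(r.duration_s),
            )
        )
    return out
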