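"""Scoring of the spatial discrimination and reversal learning tests.

Spatial discrimination test (SDT): up to 36 go/no-go trials in which one
location is positive (food reward) and the other negative.  The pass
criterion is 10/12 consecutive correct decisions, chosen so that chance
performance passes with probability below 0.05.  Learning speed counts
trials from the first trial on which the pig opened the goal box in the
negative location (first experience of both cue types) to the trial on
which the criterion was reached; pigs completing all trials without
passing are scored 36, so the trait is bounded at 12-36.  Pigs that never
opened the negative box with at least 12 trials remaining cannot in
principle pass afterwards and are excluded (not completed).

Reversal learning: positive and negative locations are swapped for 20
trials; a pass requires the new positive location as first choice for 6/6
or 10/12 consecutive trials.

Learning speed is categorised fast (pass in <= 17 trials, the cohort
median) versus slow (fail, or pass in > 17 trials).  For regrouping, pigs
are ranked within litter on summed points for (i) passing the SDT,
(ii) above-average learning speed and (iii) passing reversal; the top two
littermates form the "high test performance" group.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd
from scipy import stats

PHASE_SDT = "SDT"
PHASE_REVERSAL = "reversal"
SDT_MAX_TRIALS = 36
REVERSAL_MAX_TRIALS = 20
#: score assigned to pigs which completed the SDT but did not pass
SDT_FAIL_SCORE = 36
#: fast/slow split: pass in <= 17 trials is "fast" (the cohort median)
FAST_THRESHOLD = 17
PASS_WINDOW = 12
PASS_MIN_CORRECT = 10

TRIAL_COLUMNS = ["pig", "phase", "trial", "location", "decision", "latency_s"]


@dataclass(frozen=True)
class TrialOutcome:
    """One go/no-go trial."""

    pig: str
    phase: str
    index: int  # 1-based trial number within phase
    location: str  # "positive" | "negative"
    decision: str  # "go" | "no_go"
    latency_s: float = 0.0

    def __post_init__(self) -> None:
        if self.location not in ("positive", "negative"):
            raise ValueError(f"location must be positive/negative: {self.location!r}")
        if self.decision not in ("go", "no_go"):
            raise ValueError(f"decision must be go/no_go: {self.decision!r}")

    @property
    def correct(self) -> bool:
        return (self.decision == "go") == (self.location == "positive")


@dataclass
class CognitiveProfile:
    """Per-pig cognitive test outcomes."""

    pig: str
    sdt_completed: bool = False
    sdt_passed: bool = False
    trials_to_pass: Optional[int] = None  # in [12, 36] when completed
    learning_category: Optional[str] = None  # "fast" | "slow" | None
    reversal_completed: bool = False
    reversal_passed: Optional[bool] = None
    performance_points: Optional[int] = None


def detect_pass(
    correct_flags: Sequence[bool],
    window: int = PASS_WINDOW,
    min_correct: int = PASS_MIN_CORRECT,
) -> tuple[bool, Optional[int]]:
    """Earliest window of ``window`` consecutive trials with ``min_correct``
    correct decisions.

    Returns ``(passed, pass_trial)`` where ``pass_trial`` is the 1-based
    index of the last trial of the earliest qualifying window.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if min_correct > window:
        raise ValueError("min_correct cannot exceed window")
    flags = [bool(f) for f in correct_flags]
    if not flags:
        raise ValueError("empty trial sequence")
    running = sum(flags[:window])
    if len(flags) >= window and running >= min_correct:
        return True, window
    for end in range(window, len(flags)):
        running += flags[end] - flags[end - window]
        if running >= min_correct:
            return True, end + 1
    return False, None


def reversal_pass(correct_first_choice: Sequence[bool]) -> Optional[bool]:
    """Pass iff 6 consecutive correct first choices, or 10 correct within
    some 12-trial window.  An empty record (pig not tested) is ``None``."""
    flags = [bool(f) for f in correct_first_choice]
    if not flags:
        return None
    run = 0
    for f in flags:
        run = run + 1 if f else 0
        if run >= 6:
            return True
    if len(flags) >= 12:
        passed, _ = detect_pass(flags, window=12, min_correct=10)
        if passed:
            return True
    return False


def first_negative_go(trials: Sequence[TrialOutcome]) -> Optional[int]:
    """1-based index of the first trial where the pig opened the box in the
    negative location, or None if it never did."""
    for t in sorted(trials, key=lambda t: t.index):
        if t.location == "negative" and t.decision == "go":
            return t.index
    return None


def sdt_outcome(
    trials: Sequence[TrialOutcome],
    max_trials: int = SDT_MAX_TRIALS,
    window: int = PASS_WINDOW,
    min_correct: int = PASS_MIN_CORRECT,
) -> tuple[bool, bool, Optional[int]]:
    """Score one pig's SDT record.

    Returns ``(completed, passed, trials_to_pass)``.  A pig is *completed*
    only if it opened the negative-location box with at least ``window``
    trials remaining before reaching the criterion; ``trials_to_pass``
    counts from that first negative-box trial (inclusive) to the pass trial
    (inclusive), clamped to the 12-36 bound, and is 36 for completers that
    never passed.
    """
    trials = sorted(trials, key=lambda t: t.index)
    if not trials:
        return False, False, None
    flags = [t.correct for t in trials]
    passed, pass_trial = detect_pass(flags, window=window, min_correct=min_correct)
    fng = first_negative_go(trials)
    latest_start = max_trials - window + 1
    if fng is None or fng > latest_start or (passed and pass_trial < fng):
        return False, False, None
    if passed:
        speed = pass_trial - fng + 1
        speed = max(window, min(SDT_FAIL_SCORE, speed))
        return True, True, speed
    if len(trials) >= max_trials:
        return True, False, SDT_FAIL_SCORE
    return False, False, None  # record truncated without a pass


def learning_category(
    completed: bool, passed: bool, trials_to_pass: Optional[int]
) -> Optional[str]:
    if not completed:
        return None
    if passed and trials_to_pass is not None and trials_to_pass <= FAST_THRESHOLD:
        return "fast"
    return "slow"


def criterion_tail_probability(
    window: int, min_correct: int, p_correct: float
) -> float:
    """P(at least ``min_correct`` successes in ``window`` Bernoulli trials).

    The chance probability of meeting a consecutive-correct criterion within
    one window; for the 10/12 criterion at p = 0.5 this is 79/4096, below
    the 0.05 design threshold.
    """
    if not 0.0 <= p_correct <= 1.0:
        raise ValueError("p_correct must be in [0, 1]")
    if window < 1:
        raise ValueError("window must be >= 1")
    return float(stats.binom.sf(min_correct - 1, window, p_correct))


def profile_from_trials(
    pig: str, trials: Iterable[TrialOutcome]
) -> CognitiveProfile:
    trials = list(trials)
    sdt = [t for t in trials if t.phase == PHASE_SDT]
    rev = sorted(
        (t for t in trials if t.phase == PHASE_REVERSAL), key=lambda t: t.index
    )
    completed, passed, speed = sdt_outcome(sdt) if sdt else (False, False, None)
    rev_pass = reversal_pass([t.correct for t in rev])
    return CognitiveProfile(
        pig=pig,
        sdt_completed=completed,
        sdt_passed=passed,
        trials_to_pass=speed,
        learning_category=learning_category(completed, passed, speed),
        reversal_completed=bool(rev),
        reversal_passed=rev_pass,
    )


def load_trials(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"pig": str})
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing trial columns: {missing}")
    return df


def profiles_from_frame(df: pd.DataFrame) -> list[CognitiveProfile]:
    """Build per-pig profiles from a trial table
    (columns ``pig, phase, trial, location, decision, latency_s``)."""
    profiles = []
    for pig, sub in df.groupby("pig", sort=True):
        trials = [
            TrialOutcome(
                pig=str(pig),
                phase=str(r.phase),
                index=int(r.trial),
                location=str(r.location),
                decision=str(r.decision),
                latency_s=float(r.latency_s),
            )
            for r in sub.itertuples(index=False)
        ]
        profiles.append(profile_from_trials(str(pig), trials))
    return profiles


def profiles_to_frame(profiles: Sequence[CognitiveProfile]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "pig": [p.pig for p in profiles],
            "sdt_completed": [p.sdt_completed for p in profiles],
            "sdt_passed": [p.sdt_passed for p in profiles],
            "trials_to_pass": [p.trials_to_pass for p in profiles],
            "learning_category": [p.learning_category for p in profiles],
            "reversal_completed": [p.reversal_completed for p in profiles],
            "reversal_passed": [p.reversal_passed for p in profiles],
            "performance_points": [p.performance_points for p in profiles],
        }
    )


def performance_points(
    profile: CognitiveProfile, completer_mean_speed: float
) -> int:
    """Points for: passing the SDT, above-average learning speed (strictly
    fewer trials than the completer mean), and passing reversal learning."""
    points = 0
    if profile.sdt_passed:
        points += 1
    if (
        profile.trials_to_pass is not None
        and profile.trials_to_pass < completer_mean_speed
    ):
        points += 1
    if profile.reversal_passed is True:
        points += 1
    return points


def allocate_groups(
    profiles_by_litter: dict[str, Sequence[CognitiveProfile]],
    completer_mean_speed: Optional[float] = None,
) -> dict[str, str]:
    """Assign each profiled pig to the "high" or "low" test-performance group.

    Within each litter (at most 4 profiled pigs) the two highest point
    scorers go to "high"; ties are broken by faster ``trials_to_pass`` and
    then by pig ID.  Litters with fewer than two pigs are assigned by a
    points threshold at the litter median.  ``completer_mean_speed``
    defaults to the mean ``trials_to_pass`` of SDT completers across all
    supplied litters (the training cohort).
    """
    all_profiles = [p for ps in profiles_by_litter.values() for p in ps]
    if completer_mean_speed is None:
        speeds = [p.trials_to_pass for p in all_profiles if p.sdt_completed]
        completer_mean_speed = (
            sum(speeds) / len(speeds) if speeds else float(SDT_FAIL_SCORE)
        )

    assignment: dict[str, str] = {}
    for litter, profiles in profiles_by_litter.items():
        profiles = list(profiles)
        if len(profiles) > 4:
            raise ValueError(f"litter {litter!r} has more than 4 profiled pigs")
        scored = []
        for p in profiles:
            pts = performance_points(p, completer_mean_speed)
            p.performance_points = pts
            speed = p.trials_to_pass if p.trials_to_pass is not None else float("inf")
            scored.append((pts, speed, p.pig))
        if len(scored) < 2:
            pts_values = sorted(pts for pts, _, _ in scored)
            median = pts_values[len(pts_values) // 2] if pts_values else 0
            for pts, _, pig in scored:
                assignment[pig] = "high" if pts >= median else "low"
            continue
        ranked = sorted(scored, key=lambda s: (-s[0], s[1], s[2]))
        for rank, (_, _, pig) in enumerate(ranked):
            assignment[pig] = "high" if rank < 2 else "low"
    return assignment
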