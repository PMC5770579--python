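"""Synthetic cohorts: interviews hitting exact target scores, staging
answers realizing target stages, and Likert responses hitting target
item means.

Score targeting uses a deterministic lexicographic search over the
configured weight table (never sampling), honoring the skip logic so
every generated interview validates.  The four-patient pilot fixture
reproduces the published target-drug scores {21, 30} for opioids and
{27, 29} for cocaine, the stage mix (two contemplation, one action, one
maintenance) and the three-of-four polysubstance pattern; non-target
scores are synthetic and deliberately kept below the target score.
"""

from __future__ import annotations

import random
from datetime import date, timedelta
from typing import Optional, Sequence

from pydantic import BaseModel, Field

from .acceptability import LikertResponse
from .errors import UnachievableTargetError
from .screening import (
    AssistInterview,
    AssistItemResponse,
    ScoringWeights,
    validate_interview,
)
from .substances import CORE_SUBSTANCES, Substance
from .tailoring import IntentionWindow, Stage, StagingAnswers

#: Fixed reference date for deterministic staging answers.
DEFAULT_REFERENCE_DATE = date(2020, 6, 1)


class PatientProfile(BaseModel):
    name: str
    date_of_birth: date
    target_scores: dict[Substance, int]
    quit_stage: Stage
    treatment_stage: Optional[Stage] = None
    polysubstance: bool = False


class SimulatedPatient(BaseModel):
    profile: PatientProfile
    interview: AssistInterview
    quit_answers: StagingAnswers
    treatment_answers: Optional[StagingAnswers] = None


def _search_pattern(
    substance: Substance, target: int, weights: ScoringWeights
) -> dict[int, int]:
    """First lexicographic skip-consistent response pattern summing to target."""
    items = [
        i
        for i in weights.items_for(substance)
        if i in weights.contributing_items
    ]
    follow_up = [i for i in items if i in weights.recent_never_still_asked]

    def solve(remaining: Sequence[int], target: int) -> dict[int, int] | None:
        if not remaining:
            return {} if target == 0 else None
        idx, rest = remaining[0], remaining[1:]
        spec = weights.items[idx]
        cap = sum(max(weights.items[i].weights) for i in rest)
        for code, w in enumerate(spec.weights):
            if w > target or target - w > cap:
                continue
            sub = solve(rest, target - w)
            if sub is not None:
                return {idx: code, **sub}
        return None

    # Branch A: no use in the past 3 months (item 2 = never); only the
    # skip-table follow-up items can contribute.
    pattern = solve(follow_up, target)
    if pattern is not None:
        return {2: 0, **pattern}
    # Branch B: recent use; item 2 must be nonzero.
    first, rest = items[0], items[1:]
    assert first == 2
    spec = weights.items[first]
    cap = sum(max(weights.items[i].weights) for i in rest)
    for code in range(1, len(spec.weights)):
        w = spec.weights[code]
        if w > target or target - w > cap:
            continue
        sub = solve(rest, target - w)
        if sub is not None:
            return {first: code, **sub}
    raise UnachievableTargetError(
        f"{substance.value}: no response pattern yields score {target}"
    )


def simulate_interview(
    target_scores: dict[Substance, int], weights: ScoringWeights
) -> AssistInterview:
    """Interview whose per-substance scores hit the targets exactly.

    Substances absent from ``target_scores`` are coded as never used;
    an explicit target of 0 is realized with lifetime use but none in
    the past three months (low risk, not "none").
    """
    responses: list[AssistItemResponse] = []
    for substance in CORE_SUBSTANCES:
        if substance not in target_scores:
            responses.append(
                AssistItemResponse(substance=substance, item_index=1, response_code=0)
            )
            continue
        target = target_scores[substance]
        if not 0 <= target <= weights.max_score(substance):
            raise UnachievableTargetError(
                f"{substance.value}: target {target} outside "
                f"0..{weights.max_score(substance)}"
            )
        responses.append(
            AssistItemResponse(substance=substance, item_index=1, response_code=1)
        )
        pattern = _search_pattern(substance, target, weights)
        if pattern[2] == 0:
            # keep only items the skip table still administers
            pattern = {
                i: c
                for i, c in pattern.items()
                if i == 2 or i in weights.recent_never_still_asked
            }
        for idx in sorted(pattern):
            responses.append(
                AssistItemResponse(
                    substance=substance, item_index=idx, response_code=pattern[idx]
                )
            )
    interview = AssistInterview(responses=responses)
    validate_interview(interview, weights)
    return interview


def staging_for_stage(
    stage: Stage, seed: int, reference_date: date = DEFAULT_REFERENCE_DATE
) -> StagingAnswers:
    """Staging answers that realize the requested stage (seeded jitter)."""
    rng = random.Random(seed)
    if stage is Stage.ACTION:
        days_ago = rng.randrange(14, 183)
        return StagingAnswers(
            behavior_changed=True,
            change_date=reference_date - timedelta(days=days_ago),
            reference_date=reference_date,
        )
    if stage is Stage.MAINTENANCE:
        days_ago = rng.randrange(183, 720)
        return StagingAnswers(
            behavior_changed=True,
            change_date=reference_date - timedelta(days=days_ago),
            reference_date=reference_date,
        )
    window = {
        Stage.PRECONTEMPLATION: IntentionWindow.NONE_6MO,
        Stage.CONTEMPLATION: IntentionWindow.WITHIN_6MO,
        Stage.PREPARATION: IntentionWindow.WITHIN_30D,
    }[stage]
    return StagingAnswers(
        behavior_changed=False,
        intention_window=window,
        reference_date=reference_date,
    )


def simulate_patient(
    profile: PatientProfile,
    weights: ScoringWeights | None = None,
    seed: int = 0,
    reference_date: date = DEFAULT_REFERENCE_DATE,
) -> SimulatedPatient:
    """Deterministic synthetic patient realizing the profile exactly."""
    weights = weights or ScoringWeights.default()
    interview = simulate_interview(profile.target_scores, weights)
    quit_answers = staging_for_stage(profile.quit_stage, seed, reference_date)
    treatment_answers = (
        staging_for_stage(profile.treatment_stage, seed + 1, reference_date)
        if profile.treatment_stage is not None
        else None
    )
    return SimulatedPatient(
        profile=profile,
        interview=interview,
        quit_answers=quit_answers,
        treatment_answers=treatment_answers,
    )


# -- the four-patient pilot fixture --------------------------------------

PILOT_PROFILES: tuple[PatientProfile, ...] = (
    PatientProfile(
        name="Pilot Patient One",
        date_of_birth=date(1975, 3, 14),
        target_scores={Substance.OPIOIDS: 21, Substance.CANNABIS: 10},
        quit_stage=Stage.CONTEMPLATION,
        polysubstance=True,
    ),
    PatientProfile(
        name="Pilot Patient Two",
        date_of_birth=date(1981, 11, 2),
        target_scores={Substance.OPIOIDS: 30, Substance.SEDATIVES: 12},
        quit_stage=Stage.CONTEMPLATION,
        treatment_stage=Stage.CONTEMPLATION,
        polysubstance=True,
    ),
    PatientProfile(
        name="Pilot Patient Three",
        date_of_birth=date(1990, 7, 23),
        target_scores={Substance.COCAINE: 27, Substance.CANNABIS: 8},
        quit_stage=Stage.ACTION,
        treatment_stage=Stage.PREPARATION,
        polysubstance=True,
    ),
    PatientProfile(
        name="Pilot Patient Four",
        date_of_birth=date(1968, 1, 30),
        target_scores={Substance.COCAINE: 29},
        quit_stage=Stage.MAINTENANCE,
        treatment_stage=Stage.CONTEMPLATION,
        polysubstance=False,
    ),
)


def pilot_fixture(
    weights: ScoringWeights | None = None, seed: int = 7
) -> list[SimulatedPatient]:
    """The four synthetic pilot patients (scores 21/30 opioids, 27/29 cocaine)."""
    weights = weights or ScoringWeights.default()
    return [
        simulate_patient(profile, weights, seed=seed + i)
        for i, profile in enumerate(PILOT_PROFILES)
    ]


# -- Likert simulation ---------------------------------------------------


def simulate_likert(
    item_ids: Sequence[str],
    target_means: Sequence[float],
    n: int,
    seed: int = 0,
    instrument: str = "",
) -> list[LikertResponse]:
    """Integer 1–5 ratings whose item means sit within 1/(2n) of targets.

    Each item's rating total is the nearest integer to ``target * n``;
    the split between adjacent rating values is exact, and only the
    assignment of ratings to respondents is seeded.
    """
    if len(item_ids) != len(target_means):
        raise ValueError("item_ids and target_means differ in length")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = random.Random(seed)
    responses: list[LikertResponse] = []
    respondents = [f"r{i + 1}" for i in range(n)]
    for item, mean in zip(item_ids, target_means):
        if not 1.0 <= mean <= 5.0:
            raise UnachievableTargetError(
                f"{item}: target mean {mean} outside 1..5"
            )
        total = int(mean * n + 0.5)
        base, extra = divmod(total, n)
        if base == 5:  # mean exactly 5.0
            base, extra = 5, 0
        ratings = [base + 1] * extra + [base] * (n - extra)
        if any(not 1 <= r <= 5 for r in ratings):
            raise UnachievableTargetError(
                f"{item}: mean {mean} unachievable with n={n}"
            )
        assert abs(sum(ratings) / n - mean) <= 0.5 / n + 1e-9
        order = respondents[:]
        rng.shuffle(order)
        for respondent, rating in zip(order, ratings):
            responses.append(
                LikertResponse(
                    respondent=respondent,
                    instrument=instrument,
                    item=item,
                    rating=rating,
                )
            )
    return responses
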