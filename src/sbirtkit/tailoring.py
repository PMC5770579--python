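"""Session tailoring: target-drug selection, stage assessment, module choice.

The session flow runs five steps in order: score the screen and build
the risk chart; pick the most problematic eligible drug and assign the
intervention track (screening out low-risk patients); deliver risk
education for that drug; assess readiness to quit and select three
stage-matched change-process modules plus a goal menu; and, when the
target-drug score reaches the treatment cut point (>= 27), assess
readiness to seek treatment and select a second stage-matched module
set.

Stage assignment follows the usual readiness windows: change made less
than six months ago -> action; six months or more -> maintenance;
otherwise intention within 30 days -> preparation, within six months ->
contemplation, else precontemplation.  "Six months" is operationalized
as 183 days (strict less-than for action).
"""

from __future__ import annotations

from datetime import date
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional

import yaml
from pydantic import BaseModel, Field, model_validator

from .errors import ConfigError, GoalNotInMenuError, StagingError
from .screening import (
    HIGH_MIN,
    LOW_MAX,
    AssistInterview,
    RiskCategory,
    ScoringWeights,
    categorize_risk,
    score_substance,
)
from .substances import CORE_SUBSTANCES, Substance

SIX_MONTHS_DAYS = 183
TREATMENT_CUTOFF = HIGH_MIN  # treatment-readiness branch at score >= 27


class Stage(str, Enum):
    PRECONTEMPLATION = "precontemplation"
    CONTEMPLATION = "contemplation"
    PREPARATION = "preparation"
    ACTION = "action"
    MAINTENANCE = "maintenance"


class IntentionWindow(str, Enum):
    NONE_6MO = "none_6mo"
    WITHIN_6MO = "within_6mo"
    WITHIN_30D = "within_30d"


class Purpose(str, Enum):
    QUIT = "quit"
    SEEK_TREATMENT = "seek_treatment"


class Track(str, Enum):
    SCREENED_OUT = "screened_out"
    MODERATE = "moderate"
    HIGH = "high"


class StagingAnswers(BaseModel):
    behavior_changed: bool
    change_date: Optional[date] = None
    intention_window: Optional[IntentionWindow] = None
    reference_date: date

    @model_validator(mode="after")
    def _consistent(self) -> "StagingAnswers":
        if self.behavior_changed and self.change_date is None:
            raise ValueError("change_date required when behavior_changed")
        if not self.behavior_changed and self.change_date is not None:
            raise ValueError("change_date given without behavior_changed")
        if not self.behavior_changed and self.intention_window is None:
            raise ValueError("intention_window required when no change yet")
        return self


def stage_from_answers(answers: StagingAnswers) -> Stage:
    """Readiness stage from the staging questions (total and exclusive)."""
    if answers.behavior_changed:
        assert answers.change_date is not None
        days = (answers.reference_date - answers.change_date).days
        if days < 0:
            raise StagingError("change_date is after reference_date")
        return Stage.ACTION if days < SIX_MONTHS_DAYS else Stage.MAINTENANCE
    if answers.intention_window is IntentionWindow.WITHIN_30D:
        return Stage.PREPARATION
    if answers.intention_window is IntentionWindow.WITHIN_6MO:
        return Stage.CONTEMPLATION
    return Stage.PRECONTEMPLATION


class DrugRanking:
    """Total harm order over substances; earlier = more harmful."""

    def __init__(self, order: list[Substance]):
        if len(set(order)) != len(order):
            raise ConfigError("ranking contains duplicates")
        self.order = list(order)
        self._pos = {s: i for i, s in enumerate(order)}

    def position(self, substance: Substance) -> int:
        try:
            return self._pos[substance]
        except KeyError:
            raise ConfigError(f"{substance.value} missing from ranking") from None


class TailoringConfig:
    """Declarative tailoring rules loaded from YAML."""

    def __init__(self, doc: Mapping):
        try:
            self.ranking = DrugRanking([Substance(s) for s in doc["ranking"]])
            self.eligible = frozenset(Substance(s) for s in doc["eligible"])
            self.stage_modules = {
                Purpose(p): {
                    Stage(st): list(mods) for st, mods in stages.items()
                }
                for p, stages in doc["stage_modules"].items()
            }
            self.goal_menus = {
                Purpose(p): {
                    Stage(st): list(goals) for st, goals in stages.items()
                }
                for p, stages in doc["goal_menus"].items()
            }
            self.drug_risks = {
                Substance(s): list(risks) for s, risks in doc["drug_risks"].items()
            }
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigError(f"bad tailoring configuration: {exc}") from exc
        for purpose, stages in self.stage_modules.items():
            for stage, mods in stages.items():
                if len(mods) != 3:
                    raise ConfigError(
                        f"{purpose.value}/{stage.value}: need exactly 3 modules, "
                        f"got {len(mods)}"
                    )

    @classmethod
    def from_file(cls, path: str | Path) -> "TailoringConfig":
        with open(path) as fh:
            return cls(yaml.safe_load(fh))

    @classmethod
    def default(cls) -> "TailoringConfig":
        text = resources.files("sbirtkit.data").joinpath("tailoring.yaml").read_text()
        return cls(yaml.safe_load(text))


def select_target_drug(
    scores: Mapping[Substance, int],
    ranking: DrugRanking,
    eligible: frozenset[Substance] | set[Substance],
) -> Substance | None:
    """Eligible substance with the highest score; ties broken by harm rank.

    Returns None when no eligible substance reaches moderate risk
    (score > 3): those patients are screened out.
    """
    if not eligible:
        raise ValueError("eligible set is empty")
    best: Substance | None = None
    best_key: tuple[int, int] | None = None
    for substance in eligible:
        score = scores.get(substance, 0)
        if score <= LOW_MAX:
            continue
        key = (-score, ranking.position(substance))
        if best_key is None or key < best_key:
            best, best_key = substance, key
    return best


def assign_track(target_category: RiskCategory | None) -> Track:
    if target_category in (None, RiskCategory.NONE, RiskCategory.LOW):
        return Track.SCREENED_OUT
    if target_category is RiskCategory.MODERATE:
        return Track.MODERATE
    return Track.HIGH


class StageModuleSet(BaseModel):
    purpose: Purpose
    module_ids: list[str] = Field(min_length=3, max_length=3)


def select_stage_modules(
    stage: Stage, purpose: Purpose, config: TailoringConfig
) -> StageModuleSet:
    try:
        module_ids = config.stage_modules[purpose][stage]
    except KeyError:
        raise ConfigError(
            f"no module mapping for {purpose.value}/{stage.value}"
        ) from None
    return StageModuleSet(purpose=purpose, module_ids=list(module_ids))


class GoalPlan(BaseModel):
    chosen_goal: str
    when: str = ""
    where: str = ""
    how: str = ""


class SubstanceAssessment(BaseModel):
    substance: Substance
    score: int = Field(ge=0, le=39)
    category: RiskCategory


class AuditEntry(BaseModel):
    kind: str
    previous: dict
    payload: dict = Field(default_factory=dict)


class TailoredSession(BaseModel):
    """Central artifact of one tailored-intervention session."""

    patient_name: Optional[str] = None
    date_of_birth: Optional[date] = None
    interview: AssistInterview
    quit_answers: Optional[StagingAnswers] = None
    treatment_answers: Optional[StagingAnswers] = None
    assessments: list[SubstanceAssessment]
    target_drug: Optional[Substance] = None
    track: Track
    quit_stage: Optional[Stage] = None
    treatment_stage: Optional[Stage] = None
    quit_modules: Optional[StageModuleSet] = None
    treatment_modules: Optional[StageModuleSet] = None
    goal_menu: list[str] = Field(default_factory=list)
    goal_plan: Optional[GoalPlan] = None
    education: list[str] = Field(default_factory=list)
    treatment_needed: bool = False
    restage_requested: bool = False
    audit_trail: list[AuditEntry] = Field(default_factory=list)

    @model_validator(mode="after")
    def _consistent(self) -> "TailoredSession":
        if self.track is Track.SCREENED_OUT and self.target_drug is not None:
            raise ValueError("screened-out session cannot carry a target drug")
        if self.track is not Track.SCREENED_OUT and self.target_drug is None:
            raise ValueError("target drug required unless screened out")
        return self

    @property
    def target_score(self) -> int | None:
        if self.target_drug is None:
            return None
        for a in self.assessments:
            if a.substance == self.target_drug:
                return a.score
        return None

    def scores(self) -> dict[Substance, int]:
        return {a.substance: a.score for a in self.assessments}

    def to_json(self) -> str:
        return self.model_dump_json(indent=2)

    @classmethod
    def from_json(cls, text: str) -> "TailoredSession":
        return cls.model_validate_json(text)


def build_session(
    interview: AssistInterview,
    quit_answers: StagingAnswers | None,
    treatment_answers: StagingAnswers | None = None,
    *,
    weights: ScoringWeights | None = None,
    config: TailoringConfig | None = None,
    patient_name: str | None = None,
    date_of_birth: date | None = None,
    forced_target: Substance | None = None,
) -> TailoredSession:
    """Run the session flow end to end and return the tailored session.

    ``forced_target`` supports provider overrides; it must name a
    substance with lifetime use.
    """
    weights = weights or ScoringWeights.default()
    config = config or TailoringConfig.default()

    assessments = []
    scores: dict[Substance, int] = {}
    for substance in CORE_SUBSTANCES:
        score = score_substance(interview, substance, weights)
        scores[substance] = score
        assessments.append(
            SubstanceAssessment(
                substance=substance,
                score=score,
                category=categorize_risk(score, interview.lifetime_use(substance)),
            )
        )

    if forced_target is not None:
        target = forced_target
    else:
        target = select_target_drug(scores, config.ranking, config.eligible)

    if target is None:
        return TailoredSession(
            patient_name=patient_name,
            date_of_birth=date_of_birth,
            interview=interview,
            quit_answers=quit_answers,
            assessments=assessments,
            track=Track.SCREENED_OUT,
        )

    category = categorize_risk(scores[target], interview.lifetime_use(target))
    track = assign_track(category)
    if forced_target is not None and track is Track.SCREENED_OUT:
        # An overridden target below moderate risk still gets the
        # moderate-track intervention rather than a screen-out.
        track = Track.MODERATE

    if quit_answers is None:
        raise StagingError("quit staging answers required for an at-risk session")
    quit_stage = stage_from_answers(quit_answers)

    session = TailoredSession(
        patient_name=patient_name,
        date_of_birth=date_of_birth,
        interview=interview,
        quit_answers=quit_answers,
        treatment_answers=treatment_answers,
        assessments=assessments,
        target_drug=target,
        track=track,
        quit_stage=quit_stage,
        quit_modules=select_stage_modules(quit_stage, Purpose.QUIT, config),
        goal_menu=list(config.goal_menus[Purpose.QUIT][quit_stage]),
        education=list(config.drug_risks.get(target, [])),
    )

    if scores[target] >= TREATMENT_CUTOFF:
        if treatment_answers is None:
            raise StagingError(
                "treatment staging answers required: target score "
                f"{scores[target]} >= {TREATMENT_CUTOFF}"
            )
        treatment_stage = stage_from_answers(treatment_answers)
        session = session.model_copy(
            update={
                "treatment_needed": True,
                "treatment_stage": treatment_stage,
                "treatment_modules": select_stage_modules(
                    treatment_stage, Purpose.SEEK_TREATMENT, config
                ),
            }
        )
    return session


def record_goal_plan(
    session: TailoredSession,
    goal: str,
    when: str = "",
    where: str = "",
    how: str = "",
) -> TailoredSession:
    """Attach a goal from the stage-matched menu plus a simple plan."""
    if goal not in session.goal_menu:
        raise GoalNotInMenuError(
            f"goal {goal!r} not in menu {session.goal_menu}"
        )
    plan = GoalPlan(chosen_goal=goal, when=when, where=where, how=how)
    if session.goal_plan == plan:
        return session
    return session.model_copy(update={"goal_plan": plan})
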