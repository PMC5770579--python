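"""Provider-facing views: dashboard, printable summary, patient report,
session lookup and overrides.

Documents are emitted as a renderer-agnostic sectioned structure that
serializes to plain text; PDF generation is deliberately out of scope.
Session lookup is normalized exact match on (name, date of birth) —
safety over convenience.
"""

from __future__ import annotations

import json
from datetime import date
from enum import Enum
from pathlib import Path
from typing import Optional

from pydantic import BaseModel, Field

from .content import Channel, ContentLibrary
from .errors import (
    AmbiguousMatchError,
    MissingTemplateError,
    OverrideError,
    SessionNotFoundError,
)
from .scheduling import MessageSchedule, add_stage_assessment
from .screening import RiskCategory
from .substances import CORE_SUBSTANCES, Substance
from .tailoring import (
    AuditEntry,
    Purpose,
    Stage,
    StagingAnswers,
    TailoredSession,
    TailoringConfig,
    Track,
    build_session,
    select_stage_modules,
    stage_from_answers,
)


def normalize_name(name: str) -> str:
    return " ".join(name.split()).casefold()


class SessionStore:
    """Directory of session JSON documents with a lookup index."""

    INDEX = "index.json"

    def __init__(self, directory: str | Path):
        self.directory = Path(directory)
        self.directory.mkdir(parents=True, exist_ok=True)

    def _index_path(self) -> Path:
        return self.directory / self.INDEX

    def _read_index(self) -> list[dict]:
        if not self._index_path().exists():
            return []
        return json.loads(self._index_path().read_text())

    def save(self, session: TailoredSession) -> Path:
        if session.patient_name is None or session.date_of_birth is None:
            raise ValueError("stored sessions need patient_name and date_of_birth")
        index = self._read_index()
        filename = f"session-{len(index) + 1:04d}.json"
        (self.directory / filename).write_text(session.to_json())
        index.append(
            {
                "name": normalize_name(session.patient_name),
                "date_of_birth": session.date_of_birth.isoformat(),
                "file": filename,
            }
        )
        self._index_path().write_text(json.dumps(index, indent=2))
        return self.directory / filename


def lookup_session(
    store: SessionStore, name: str, date_of_birth: date
) -> TailoredSession:
    """Retrieve the stored session for (name, DOB); exact normalized match."""
    key = (normalize_name(name), date_of_birth.isoformat())
    hits = [
        e
        for e in store._read_index()
        if (e["name"], e["date_of_birth"]) == key
    ]
    if not hits:
        raise SessionNotFoundError(f"no session for {name!r} / {date_of_birth}")
    if len(hits) > 1:
        raise AmbiguousMatchError(
            f"{len(hits)} sessions match {name!r} / {date_of_birth}"
        )
    return TailoredSession.from_json(
        (store.directory / hits[0]["file"]).read_text()
    )


class ChartRow(BaseModel):
    substance: Substance
    score: int
    category: RiskCategory


class DashboardView(BaseModel):
    patient_name: Optional[str]
    chart: list[ChartRow]
    target_drug: Optional[Substance]
    track: Track
    quit_stage: Optional[Stage]
    treatment_stage: Optional[Stage]
    script: Optional[str] = None
    treatment_script: Optional[str] = None
    goal: Optional[str] = None
    plan: Optional[dict] = None


def _script_for(
    library: ContentLibrary, stage: Stage, purpose: Purpose, context: dict
) -> str:
    pool = library.matching(
        channel=Channel.PROVIDER_SCRIPT, stage=stage, purpose=purpose
    )
    if not pool:
        raise MissingTemplateError(
            f"no provider script for {purpose.value}/{stage.value}"
        )
    return pool[0].resolve(context)


def render_dashboard(
    session: TailoredSession, library: ContentLibrary
) -> DashboardView:
    """Chart for all nine substances plus stage-matched provider scripts."""
    chart = [
        ChartRow(substance=a.substance, score=a.score, category=a.category)
        for a in session.assessments
    ]
    assert len(chart) == len(CORE_SUBSTANCES)
    view = DashboardView(
        patient_name=session.patient_name,
        chart=chart,
        target_drug=session.target_drug,
        track=session.track,
        quit_stage=session.quit_stage,
        treatment_stage=session.treatment_stage,
        goal=session.goal_plan.chosen_goal if session.goal_plan else None,
        plan=(
            session.goal_plan.model_dump(exclude={"chosen_goal"})
            if session.goal_plan
            else None
        ),
    )
    if session.track is Track.SCREENED_OUT:
        return view
    context = {
        "drug": session.target_drug.display_name,
        "risk": "",
        "stage": session.quit_stage.value,
    }
    view.script = _script_for(library, session.quit_stage, Purpose.QUIT, context)
    if session.treatment_stage is not None:
        view.treatment_script = _script_for(
            library, session.treatment_stage, Purpose.SEEK_TREATMENT, context
        )
    return view


class DocumentMode(str, Enum):
    PROVIDER_SUMMARY = "provider_summary"
    PATIENT_REPORT = "patient_report"


class Section(BaseModel):
    heading: str
    lines: list[str]


class Document(BaseModel):
    title: str
    sections: list[Section] = Field(default_factory=list)

    def add(self, heading: str, lines: list[str]) -> None:
        self.sections.append(Section(heading=heading, lines=lines))

    def to_text(self) -> str:
        parts = [self.title, "=" * len(self.title), ""]
        for s in self.sections:
            parts += [s.heading, "-" * len(s.heading), *s.lines, ""]
        return "\n".join(parts)


EMPTY_RESOURCES_NOTICE = "No local referral resources are configured."


def _chart_lines(view: DashboardView) -> list[str]:
    return [
        f"{row.substance.display_name}: score {row.score} ({row.category.value} risk)"
        for row in view.chart
    ]


def render_documents(
    session: TailoredSession,
    mode: DocumentMode,
    library: ContentLibrary,
    referral_resources: list[str] | None = None,
) -> Document:
    """Printable provider summary or full patient report for a session."""
    resources_list = list(referral_resources or [])
    view = render_dashboard(session, library)

    if mode is DocumentMode.PROVIDER_SUMMARY:
        doc = Document(title="Session summary (provider copy)")
        doc.add("Patient", [view.patient_name or "(unnamed)"])
        doc.add("Risk chart", _chart_lines(view))
        doc.add(
            "Decisions",
            [
                f"Track: {view.track.value}",
                f"Target drug: {view.target_drug.display_name if view.target_drug else 'none'}",
                f"Stage (quit): {view.quit_stage.value if view.quit_stage else 'n/a'}",
                "Stage (treatment): "
                + (view.treatment_stage.value if view.treatment_stage else "n/a"),
            ],
        )
        if view.script:
            doc.add("Session script", [view.script])
        if view.treatment_script:
            doc.add("Treatment script", [view.treatment_script])
        doc.add(
            "Goal and plan",
            [f"Goal: {view.goal}", f"Plan: {view.plan}"]
            if view.goal
            else ["No goal recorded."],
        )
        doc.add("Referral resources", resources_list or [EMPTY_RESOURCES_NOTICE])
        return doc

    doc = Document(title="Your session report")
    doc.add("Your results", _chart_lines(view))
    if session.track is Track.SCREENED_OUT:
        doc.add(
            "What this means",
            ["Your answers show low risk. No follow-up program is needed."],
        )
        return doc
    assert session.target_drug is not None and session.quit_stage is not None
    risk = next(
        a.category
        for a in session.assessments
        if a.substance == session.target_drug
    )
    context = {
        "drug": session.target_drug.display_name,
        "risk": risk.value,
        "stage": session.quit_stage.value,
    }
    doc.add("About your drug of focus", list(session.education))
    feedback = library.matching(
        channel=Channel.CTI_FEEDBACK,
        drug=session.target_drug,
        risk=risk,
        stage=session.quit_stage,
        purpose=Purpose.QUIT,
    )
    doc.add("Your feedback", [t.resolve(context) for t in feedback])
    if session.treatment_stage is not None:
        treat = library.matching(
            channel=Channel.CTI_FEEDBACK,
            drug=session.target_drug,
            risk=risk,
            stage=session.treatment_stage,
            purpose=Purpose.SEEK_TREATMENT,
        )
        doc.add("About getting help", [t.resolve(context) for t in treat])
    if session.goal_plan:
        doc.add(
            "Your goal",
            [
                f"Goal: {session.goal_plan.chosen_goal}",
                f"When: {session.goal_plan.when}",
                f"Where: {session.goal_plan.where}",
                f"How: {session.goal_plan.how}",
            ],
        )
    else:
        doc.add("Your goal", ["Pick one goal from your menu: "
                              + ", ".join(session.goal_menu)])
    doc.add("Places that can help", resources_list or [EMPTY_RESOURCES_NOTICE])
    return doc


class OverrideKind(str, Enum):
    TARGET_DRUG = "target_drug"
    TREATMENT_NEEDED = "treatment_needed"
    RESTAGE_REQUEST = "restage_request"


class ProviderOverride(BaseModel):
    kind: OverrideKind
    target_drug: Optional[Substance] = None
    treatment_answers: Optional[StagingAnswers] = None


def _audit(session: TailoredSession, kind: OverrideKind, payload: dict) -> AuditEntry:
    return AuditEntry(
        kind=kind.value,
        previous={
            "target_drug": session.target_drug.value if session.target_drug else None,
            "track": session.track.value,
            "treatment_needed": session.treatment_needed,
            "treatment_stage": (
                session.treatment_stage.value if session.treatment_stage else None
            ),
        },
        payload=payload,
    )


def apply_override(
    session: TailoredSession,
    override: ProviderOverride,
    *,
    config: TailoringConfig | None = None,
    schedule: MessageSchedule | None = None,
) -> tuple[TailoredSession, MessageSchedule | None]:
    """Apply a provider override; the original decision stays in the audit trail.

    Returns the updated session and, when a schedule was passed, the
    updated schedule (restage requests append one stage-assessment
    message to it).
    """
    config = config or TailoringConfig.default()

    if override.kind is OverrideKind.TARGET_DRUG:
        if override.target_drug is None:
            raise OverrideError("target_drug override requires a substance")
        if not session.interview.lifetime_use(override.target_drug):
            raise OverrideError(
                f"{override.target_drug.value}: no lifetime use on record"
            )
        audit = _audit(
            session, override.kind, {"target_drug": override.target_drug.value}
        )
        rebuilt = build_session(
            session.interview,
            session.quit_answers,
            override.treatment_answers or session.treatment_answers,
            config=config,
            patient_name=session.patient_name,
            date_of_birth=session.date_of_birth,
            forced_target=override.target_drug,
        )
        rebuilt = rebuilt.model_copy(
            update={"audit_trail": [*session.audit_trail, audit]}
        )
        return rebuilt, schedule

    if override.kind is OverrideKind.TREATMENT_NEEDED:
        answers = override.treatment_answers or session.treatment_answers
        if answers is None:
            raise OverrideError(
                "treatment_needed override requires treatment staging answers"
            )
        if session.track is Track.SCREENED_OUT:
            raise OverrideError("cannot add a treatment branch to a screened-out session")
        audit = _audit(session, override.kind, {})
        treatment_stage = stage_from_answers(answers)
        updated = session.model_copy(
            update={
                "treatment_needed": True,
                "treatment_answers": answers,
                "treatment_stage": treatment_stage,
                "treatment_modules": select_stage_modules(
                    treatment_stage, Purpose.SEEK_TREATMENT, config
                ),
                "audit_trail": [*session.audit_trail, audit],
            }
        )
        return updated, schedule

    # restage request
    audit = _audit(session, override.kind, {})
    updated = session.model_copy(
        update={
            "restage_requested": True,
            "audit_trail": [*session.audit_trail, audit],
        }
    )
    if schedule is not None:
        schedule = add_stage_assessment(schedule)
    return updated, schedule
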