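"""Tagged template content: loading, validation, coverage, readability.

Templates are tagged by channel, target drug, risk level, stage and
purpose.  ``any`` tags act as wildcards during *selection*; *coverage*
checking, by contrast, demands an exactly-tagged template per required
cell so that the bundled library stays minimal and auditable (each
required cell is served by exactly one template).

Patient-facing channels (sms, cti_feedback, pac_activity) must grade at
or below the configured Flesch-Kincaid threshold (default 5.0).
Readability is computed on the raw body with placeholder markers
contributing their bare names as words.
"""

from __future__ import annotations

import string
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Optional, Union

import yaml
from pydantic import BaseModel, Field

from .errors import LibrarySchemaError
from .readability import fk_grade
from .screening import RiskCategory
from .substances import Substance
from .tailoring import Purpose, Stage

ANY = "any"

DEFAULT_FK_THRESHOLD = 5.0

#: Placeholder names a template body may use.
ALLOWED_PLACEHOLDERS = frozenset({"drug", "risk", "stage", "link", "goal"})


class Channel(str, Enum):
    CTI_FEEDBACK = "cti_feedback"
    SMS = "sms"
    PAC_ACTIVITY = "pac_activity"
    PROVIDER_SCRIPT = "provider_script"


PATIENT_FACING_CHANNELS = frozenset(
    {Channel.CTI_FEEDBACK, Channel.SMS, Channel.PAC_ACTIVITY}
)

DrugTag = Union[Substance, Literal["any"]]
RiskTag = Union[RiskCategory, Literal["any"]]
StageTag = Union[Stage, Literal["any"]]
PurposeTag = Union[Purpose, Literal["any"]]


class ContentTemplate(BaseModel):
    id: str
    channel: Channel
    drug: DrugTag = ANY
    risk: RiskTag = ANY
    stage: StageTag = ANY
    purpose: PurposeTag = ANY
    link_slot: bool = False
    body: str = Field(min_length=1)

    def placeholders(self) -> set[str]:
        return {
            field
            for _, field, _, _ in string.Formatter().parse(self.body)
            if field
        }

    def matches(
        self,
        *,
        channel: Channel,
        drug: Substance | None = None,
        risk: RiskCategory | None = None,
        stage: Stage | None = None,
        purpose: Purpose | None = None,
        link_slot: bool | None = None,
    ) -> bool:
        """Wildcard-aware selection match (``any`` tag matches everything)."""
        if self.channel is not channel:
            return False
        if link_slot is not None and self.link_slot != link_slot:
            return False
        for tag, value in (
            (self.drug, drug),
            (self.risk, risk),
            (self.stage, stage),
            (self.purpose, purpose),
        ):
            if value is not None and tag != ANY and tag != value:
                return False
        return True

    def resolve(self, context: dict[str, str]) -> str:
        try:
            return self.body.format(**context)
        except (KeyError, IndexError) as exc:
            raise LibrarySchemaError(
                f"unresolved placeholder {exc}", template_id=self.id
            ) from exc


class ContentLibrary:
    def __init__(self, templates: Iterable[ContentTemplate]):
        self.templates = list(templates)
        self.by_id: dict[str, ContentTemplate] = {}
        for t in self.templates:
            if t.id in self.by_id:
                raise LibrarySchemaError("duplicate id", template_id=t.id)
            self.by_id[t.id] = t

    def __len__(self) -> int:
        return len(self.templates)

    def matching(self, **criteria) -> list[ContentTemplate]:
        return [t for t in self.templates if t.matches(**criteria)]

    def without(self, template_id: str) -> "ContentLibrary":
        return ContentLibrary(
            [t for t in self.templates if t.id != template_id]
        )


def load_library(source: str | Path | dict | None = None) -> ContentLibrary:
    """Load and validate a template library (default: the bundled one)."""
    if source is None:
        doc = yaml.safe_load(
            resources.files("sbirtkit.data")
            .joinpath("default_library.yaml")
            .read_text()
        )
    elif isinstance(source, dict):
        doc = source
    else:
        with open(source) as fh:
            doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "templates" not in doc:
        raise LibrarySchemaError("document must contain a 'templates' list")
    templates = []
    for i, raw in enumerate(doc["templates"]):
        tid = raw.get("id", f"<template #{i}>") if isinstance(raw, dict) else f"<template #{i}>"
        try:
            template = ContentTemplate.model_validate(raw)
        except Exception as exc:
            raise LibrarySchemaError(str(exc), template_id=str(tid)) from exc
        unknown = template.placeholders() - ALLOWED_PLACEHOLDERS
        if unknown:
            raise LibrarySchemaError(
                f"unknown placeholders {sorted(unknown)}", template_id=template.id
            )
        templates.append(template)
    return ContentLibrary(templates)


# -- coverage ------------------------------------------------------------


class Cell(BaseModel):
    """One required content slot."""

    model_config = {"frozen": True}

    channel: Channel
    drug: DrugTag = ANY
    risk: RiskTag = ANY
    stage: StageTag = ANY
    purpose: PurposeTag = ANY
    link_slot: bool = False

    def describe(self) -> str:
        def plain(tag) -> str:
            return tag.value if isinstance(tag, Enum) else tag

        link = "+link" if self.link_slot else ""
        return (
            f"{self.channel.value}{link}/{plain(self.risk)}"
            f"/{plain(self.stage)}/{plain(self.purpose)}"
        )


PAC_SLOT_COUNT = 4  # weekly web activities over the 30-day horizon


def required_cells() -> list[Cell]:
    """Cells every complete library must fill (drug dimension wildcarded)."""
    cells: list[Cell] = []
    for stage in Stage:
        for risk in (RiskCategory.MODERATE, RiskCategory.HIGH):
            cells.append(
                Cell(channel=Channel.SMS, risk=risk, stage=stage, purpose=Purpose.QUIT)
            )
            cells.append(
                Cell(
                    channel=Channel.CTI_FEEDBACK,
                    risk=risk,
                    stage=stage,
                    purpose=Purpose.QUIT,
                )
            )
        cells.append(
            Cell(channel=Channel.SMS, stage=stage, purpose=Purpose.QUIT, link_slot=True)
        )
        cells.append(
            Cell(
                channel=Channel.CTI_FEEDBACK,
                risk=RiskCategory.HIGH,
                stage=stage,
                purpose=Purpose.SEEK_TREATMENT,
            )
        )
        cells.append(
            Cell(channel=Channel.PROVIDER_SCRIPT, stage=stage, purpose=Purpose.QUIT)
        )
        cells.append(
            Cell(
                channel=Channel.PROVIDER_SCRIPT,
                stage=stage,
                purpose=Purpose.SEEK_TREATMENT,
            )
        )
    return cells


def _covers(template: ContentTemplate, cell: Cell) -> bool:
    return (
        template.channel is cell.channel
        and template.link_slot == cell.link_slot
        and template.drug == cell.drug
        and template.risk == cell.risk
        and template.stage == cell.stage
        and template.purpose == cell.purpose
    )


class LibraryReport(BaseModel):
    gaps: list[str]
    readability: dict[str, float]
    threshold: float
    verdict: bool

    def over_threshold(self) -> list[str]:
        return [tid for tid, g in self.readability.items() if g > self.threshold]


def validate_library(
    library: ContentLibrary, threshold: float = DEFAULT_FK_THRESHOLD
) -> LibraryReport:
    """Report coverage gaps and patient-facing readability grades."""
    gaps = [
        cell.describe()
        for cell in required_cells()
        if not any(_covers(t, cell) for t in library.templates)
    ]
    pac_count = sum(
        1 for t in library.templates if t.channel is Channel.PAC_ACTIVITY
    )
    for slot in range(pac_count, PAC_SLOT_COUNT):
        gaps.append(f"pac_activity/slot-{slot + 1}")
    readability = {
        t.id: round(fk_grade(t.body), 2)
        for t in library.templates
        if t.channel in PATIENT_FACING_CHANNELS
    }
    verdict = not gaps and all(g <= threshold for g in readability.values())
    return LibraryReport(
        gaps=gaps, readability=readability, threshold=threshold, verdict=verdict
    )
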