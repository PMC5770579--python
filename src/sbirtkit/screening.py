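"""Substance-involvement screening: items, skip logic, scoring, risk bands.

Up to seven items are administered per substance.  Item 1 asks about
lifetime use; a "never" answer skips the rest of the branch.  Item 2 asks
about use in the past three months; a "never" answer skips ahead so that
only the items listed in the configured skip table are still asked.
Summing the configured weights of the contributing items yields a 0–39
involvement score per substance, which maps onto validated risk bands:
low (0–3), moderate (4–26) and high (27+).  A fourth display-only band,
``none``, is used when there is no lifetime use at all.

Item weights and the skip table are configuration, not code: see
``data/assist_v3.yaml``.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import yaml
from pydantic import BaseModel, Field, field_validator

from .errors import (
    ConfigError,
    IncompleteBranchError,
    InconsistentInterviewError,
    UnknownResponseCodeError,
)
from .substances import CORE_SUBSTANCES, Substance

MAX_SCORE = 39

#: Uniform risk-band cutoffs applied to every substance.
LOW_MAX = 3
MODERATE_MAX = 26
HIGH_MIN = 27


class RiskCategory(str, Enum):
    NONE = "none"  # display only: no lifetime use
    LOW = "low"
    MODERATE = "moderate"
    HIGH = "high"


@dataclass(frozen=True)
class ItemSpec:
    """One interview item: its labelled response codes and their weights."""

    index: int
    labels: tuple[str, ...]
    weights: tuple[int, ...]

    def code_for(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise UnknownResponseCodeError(
                f"item {self.index} has no response labelled {label!r}"
            ) from None


class ScoringWeights:
    """Versioned weight table + skip table driving all screening logic."""

    def __init__(
        self,
        version: str,
        items: Mapping[int, ItemSpec],
        contributing_items: Iterable[int],
        not_administered: Mapping[Substance, frozenset[int]],
        recent_never_still_asked: Iterable[int],
    ):
        self.version = version
        self.items = dict(items)
        self.contributing_items = tuple(contributing_items)
        self.not_administered = dict(not_administered)
        self.recent_never_still_asked = frozenset(recent_never_still_asked)
        for idx, spec in self.items.items():
            if len(spec.labels) != len(spec.weights):
                raise ConfigError(f"item {idx}: labels/weights length mismatch")
            if any(w < 0 for w in spec.weights):
                raise ConfigError(f"item {idx}: negative weight")

    # -- construction ---------------------------------------------------

    @classmethod
    def from_mapping(cls, doc: Mapping) -> "ScoringWeights":
        try:
            items = {
                int(idx): ItemSpec(int(idx), tuple(spec["labels"]), tuple(spec["weights"]))
                for idx, spec in doc["items"].items()
            }
            not_admin = {
                Substance(sub): frozenset(int(i) for i in idxs)
                for sub, idxs in doc.get("not_administered", {}).items()
            }
            return cls(
                version=str(doc["version"]),
                items=items,
                contributing_items=[int(i) for i in doc["contributing_items"]],
                not_administered=not_admin,
                recent_never_still_asked=[int(i) for i in doc["recent_never_still_asked"]],
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigError(f"bad weight configuration: {exc}") from exc

    @classmethod
    def from_file(cls, path: str | Path) -> "ScoringWeights":
        with open(path) as fh:
            return cls.from_mapping(yaml.safe_load(fh))

    @classmethod
    def default(cls) -> "ScoringWeights":
        text = resources.files("sbirtkit.data").joinpath("assist_v3.yaml").read_text()
        return cls.from_mapping(yaml.safe_load(text))

    # -- queries --------------------------------------------------------

    def allowed_codes(self, item_index: int) -> range:
        spec = self.items.get(item_index)
        if spec is None:
            raise ConfigError(f"no item {item_index} configured")
        return range(len(spec.weights))

    def items_for(self, substance: Substance) -> tuple[int, ...]:
        """Item indexes administered for a substance, in interview order."""
        skipped = self.not_administered.get(substance, frozenset())
        return tuple(i for i in sorted(self.items) if i not in skipped)

    def weight(self, substance: Substance, item_index: int, code: int) -> int:
        spec = self.items.get(item_index)
        if spec is None or item_index not in self.items_for(substance):
            raise UnknownResponseCodeError(
                f"item {item_index} is not administered for {substance.value}"
            )
        if not 0 <= code < len(spec.weights):
            raise UnknownResponseCodeError(
                f"item {item_index}: response code {code} not in "
                f"0..{len(spec.weights) - 1}"
            )
        return spec.weights[code]

    def max_score(self, substance: Substance) -> int:
        return sum(
            max(self.items[i].weights)
            for i in self.items_for(substance)
            if i in self.contributing_items
        )


class AssistItemResponse(BaseModel):
    substance: Substance
    item_index: int = Field(ge=1, le=7)
    response_code: int = Field(ge=0)


class AssistInterview(BaseModel):
    """A set of item responses, at most one per (substance, item)."""

    responses: list[AssistItemResponse] = Field(default_factory=list)

    @field_validator("responses")
    @classmethod
    def _no_duplicates(cls, v: list[AssistItemResponse]) -> list[AssistItemResponse]:
        seen = set()
        for r in v:
            key = (r.substance, r.item_index)
            if key in seen:
                raise ValueError(
                    f"duplicate response for {r.substance.value} item {r.item_index}"
                )
            seen.add(key)
        return v

    def response_map(self) -> dict[tuple[Substance, int], int]:
        return {(r.substance, r.item_index): r.response_code for r in self.responses}

    def get(self, substance: Substance, item_index: int) -> int | None:
        for r in self.responses:
            if r.substance == substance and r.item_index == item_index:
                return r.response_code
        return None

    def lifetime_use(self, substance: Substance) -> bool:
        return bool(self.get(substance, 1))

    def with_response(
        self, substance: Substance, item_index: int, response_code: int
    ) -> "AssistInterview":
        return AssistInterview(
            responses=[
                *self.responses,
                AssistItemResponse(
                    substance=substance,
                    item_index=item_index,
                    response_code=response_code,
                ),
            ]
        )

    # -- serialization --------------------------------------------------

    def to_json(self) -> str:
        return self.model_dump_json(indent=2)

    @classmethod
    def from_json(cls, text: str) -> "AssistInterview":
        return cls.model_validate_json(text)


DONE = None  # sentinel returned by next_question when a branch is exhausted


def _required_items(
    interview: AssistInterview, substance: Substance, weights: ScoringWeights
) -> tuple[int, ...] | None:
    """Items still required for the branch given answers so far.

    Returns None when the branch terminates at item 1 ("never used").
    Raises on answers that contradict the skip table.
    """
    administered = weights.items_for(substance)
    resp = {i: interview.get(substance, i) for i in range(1, 8)}
    for idx, code in resp.items():
        if code is None:
            continue
        if idx not in administered:
            raise InconsistentInterviewError(
                f"{substance.value}: item {idx} is never administered"
            )
        if code not in weights.allowed_codes(idx):
            raise UnknownResponseCodeError(
                f"{substance.value} item {idx}: code {code} out of range"
            )

    answered = [i for i in administered if resp[i] is not None]
    if resp[1] is None:
        if answered:
            raise InconsistentInterviewError(
                f"{substance.value}: items answered before lifetime-use item"
            )
        return (1,)
    if resp[1] == 0:  # never used in lifetime
        if len(answered) > 1:
            raise InconsistentInterviewError(
                f"{substance.value}: responses present after lifetime 'never'"
            )
        return None
    if resp[2] is None:
        extra = [i for i in answered if i > 2]
        if extra:
            raise InconsistentInterviewError(
                f"{substance.value}: item {extra[0]} answered before item 2"
            )
        return (1, 2)
    if resp[2] == 0:  # no use in past 3 months: restricted follow-up set
        required = (1, 2) + tuple(
            i for i in administered if i in weights.recent_never_still_asked
        )
        bad = [i for i in answered if i not in required]
        if bad:
            raise InconsistentInterviewError(
                f"{substance.value}: item {bad[0]} answered despite "
                "'not in past 3 months' skip"
            )
        return required
    return administered


def validate_interview(interview: AssistInterview, weights: ScoringWeights) -> None:
    """Raise if any branch violates codes or skip logic."""
    for substance in Substance:
        _required_items(interview, substance, weights)


def next_question(
    interview: AssistInterview, substance: Substance, weights: ScoringWeights
) -> int | None:
    """Next unanswered item index for the substance, or DONE (None)."""
    required = _required_items(interview, substance, weights)
    if required is None:
        return DONE
    for idx in required:
        if interview.get(substance, idx) is None:
            return idx
    return DONE


def branch_complete(
    interview: AssistInterview, substance: Substance, weights: ScoringWeights
) -> bool:
    return next_question(interview, substance, weights) is DONE


def score_substance(
    interview: AssistInterview, substance: Substance, weights: ScoringWeights
) -> int:
    """Involvement score 0–39: configured weights summed over contributing items.

    A branch fully skipped at item 1 scores 0.  Raises
    IncompleteBranchError when required items are unanswered.
    """
    if not branch_complete(interview, substance, weights):
        raise IncompleteBranchError(
            f"{substance.value}: branch incomplete "
            f"(next item {next_question(interview, substance, weights)})"
        )
    total = 0
    for idx in weights.contributing_items:
        if idx not in weights.items_for(substance):
            continue
        code = interview.get(substance, idx)
        if code is not None:
            total += weights.weight(substance, idx, code)
    return total


def categorize_risk(score: int, lifetime_use: bool = True) -> RiskCategory:
    """Map a 0–39 score to a risk band; ``none`` when never used at all."""
    if not 0 <= score <= MAX_SCORE:
        raise ValueError(f"score {score} outside 0..{MAX_SCORE}")
    if not lifetime_use:
        if score != 0:
            raise ValueError("nonzero score is inconsistent with no lifetime use")
        return RiskCategory.NONE
    if score >= HIGH_MIN:
        return RiskCategory.HIGH
    if score > LOW_MAX:
        return RiskCategory.MODERATE
    return RiskCategory.LOW


def score_all(
    interview: AssistInterview, weights: ScoringWeights
) -> dict[Substance, int]:
    """Scores for the nine named substances (requires complete branches)."""
    return {s: score_substance(interview, s, weights) for s in CORE_SUBSTANCES}


# -- batch CSV import ---------------------------------------------------

CSV_COLUMNS = ("patient_id", "substance", "item_index", "response_code")


def read_interviews_csv(path: str | Path) -> dict[str, AssistInterview]:
    """Read batch interviews from long-format CSV.

    Columns: patient_id, substance, item_index, response_code.  Errors
    are addressed by line and field.
    """
    rows: dict[str, list[AssistItemResponse]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or set(CSV_COLUMNS) - set(reader.fieldnames):
            missing = set(CSV_COLUMNS) - set(reader.fieldnames or [])
            raise InconsistentInterviewError(
                f"{path}: missing columns {sorted(missing)}"
            )
        for lineno, row in enumerate(reader, start=2):
            try:
                substance = Substance(row["substance"].strip())
            except ValueError:
                raise InconsistentInterviewError(
                    f"{path}:{lineno}: field 'substance': "
                    f"unknown substance {row['substance']!r}"
                ) from None
            try:
                item_index = int(row["item_index"])
                response_code = int(row["response_code"])
            except ValueError as exc:
                raise InconsistentInterviewError(
                    f"{path}:{lineno}: non-integer item/response: {exc}"
                ) from None
            rows.setdefault(row["patient_id"].strip(), []).append(
                AssistItemResponse(
                    substance=substance,
                    item_index=item_index,
                    response_code=response_code,
                )
            )
    out: dict[str, AssistInterview] = {}
    for patient_id, responses in rows.items():
        try:
            out[patient_id] = AssistInterview(responses=responses)
        except ValueError as exc:
            raise InconsistentInterviewError(f"{path}: {patient_id}: {exc}") from exc
    return out


def write_interview_json(interview: AssistInterview, path: str | Path) -> None:
    Path(path).write_text(interview.to_json())


def read_interview_json(path: str | Path) -> AssistInterview:
    return AssistInterview.from_json(Path(path).read_text())


def interview_summary(
    interview: AssistInterview, weights: ScoringWeights
) -> list[dict]:
    """Per-substance (score, display category) rows for the risk chart."""
    rows = []
    for substance in CORE_SUBSTANCES:
        score = score_substance(interview, substance, weights)
        category = categorize_risk(score, interview.lifetime_use(substance))
        rows.append(
            {
                "substance": substance.value,
                "score": score,
                "category": category.value,
            }
        )
    return rows


def dumps_scores(scores: Mapping[Substance, int]) -> str:
    return json.dumps({s.value: v for s, v in scores.items()}, indent=2)
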