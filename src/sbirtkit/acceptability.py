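"""Five-point acceptability survey scoring.

Item-level statistics are the mean and sample (n-1) standard deviation
of the 1–5 ratings.  The overall statistics are computed over the item
means (unweighted), not over pooled raw responses, and the benchmark
verdict compares the one-decimal rounded overall mean against the
configured benchmark (default 4.0).  Rounding is half-up; full precision
is retained internally.
"""

from __future__ import annotations

import csv
import statistics
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Sequence

from pydantic import BaseModel, Field

DEFAULT_BENCHMARK = 4.0


def round1(value: float) -> float:
    """Round half-up to one decimal (4.45 -> 4.5)."""
    return float(Decimal(repr(value)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


class LikertResponse(BaseModel):
    respondent: str
    instrument: str = ""
    item: str
    rating: int = Field(ge=1, le=5)


class ItemSummary(BaseModel):
    item: str
    n: int = Field(ge=1)
    mean: float = Field(ge=1.0, le=5.0)
    sd: float = Field(ge=0.0)
    sd_defined: bool = True  # False for n=1, where sd is reported as 0

    @property
    def mean_1dp(self) -> float:
        return round1(self.mean)

    @property
    def sd_1dp(self) -> float:
        return round1(self.sd)


class AcceptabilitySummary(BaseModel):
    overall_mean: float  # rounded to one decimal
    overall_sd: float  # rounded to one decimal
    raw_mean: float
    raw_sd: float
    benchmark: float
    verdict: bool
    n_items: int


def item_summaries(
    responses: Iterable[LikertResponse],
    item_order: Sequence[str] | None = None,
) -> list[ItemSummary]:
    """Per-item mean and sample SD, in declared (or first-seen) item order."""
    by_item: dict[str, list[int]] = {}
    seen: set[tuple[str, str]] = set()
    for r in responses:
        key = (r.respondent, r.instrument, r.item)
        if key in seen:
            raise ValueError(f"duplicate rating for {key}")
        seen.add(key)
        by_item.setdefault(r.item, []).append(r.rating)
    if not by_item:
        raise ValueError("no responses")
    order = list(item_order) if item_order is not None else list(by_item)
    missing = set(order) - set(by_item)
    if missing:
        raise ValueError(f"items with no responses: {sorted(missing)}")
    summaries = []
    for item in order:
        ratings = by_item[item]
        n = len(ratings)
        mean = statistics.fmean(ratings)
        if n == 1:
            summaries.append(
                ItemSummary(item=item, n=1, mean=mean, sd=0.0, sd_defined=False)
            )
        else:
            summaries.append(
                ItemSummary(
                    item=item, n=n, mean=mean, sd=statistics.stdev(ratings)
                )
            )
    return summaries


def overall_acceptability(
    items: Sequence[ItemSummary], benchmark: float = DEFAULT_BENCHMARK
) -> AcceptabilitySummary:
    """Unweighted mean and sample SD of the item means, with verdict."""
    if not items:
        raise ValueError("no items")
    means = [i.mean for i in items]
    raw_mean = statistics.fmean(means)
    raw_sd = statistics.stdev(means) if len(means) > 1 else 0.0
    overall_mean = round1(raw_mean)
    return AcceptabilitySummary(
        overall_mean=overall_mean,
        overall_sd=round1(raw_sd),
        raw_mean=raw_mean,
        raw_sd=raw_sd,
        benchmark=benchmark,
        verdict=overall_mean >= benchmark,
        n_items=len(items),
    )


def extreme_items(items: Sequence[ItemSummary]) -> tuple[ItemSummary, ItemSummary]:
    """(lowest-mean, highest-mean) items; ties go to the earlier item."""
    if not items:
        raise ValueError("no items")
    lowest = min(items, key=lambda i: i.mean)
    highest = max(items, key=lambda i: i.mean)
    return lowest, highest


def summaries_from_means(
    means: Sequence[tuple[str, float]], n: int
) -> list[ItemSummary]:
    """Build item summaries directly from already-aggregated item means."""
    return [
        ItemSummary(item=item, n=n, mean=mean, sd=0.0, sd_defined=False)
        for item, mean in means
    ]


# -- long-format CSV I/O -------------------------------------------------

CSV_COLUMNS = ("respondent", "instrument", "item", "rating")


def read_responses_csv(path: str | Path) -> list[LikertResponse]:
    responses = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or set(CSV_COLUMNS) - set(reader.fieldnames):
            missing = set(CSV_COLUMNS) - set(reader.fieldnames or [])
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                responses.append(
                    LikertResponse(
                        respondent=row["respondent"].strip(),
                        instrument=row["instrument"].strip(),
                        item=row["item"].strip(),
                        rating=int(row["rating"]),
                    )
                )
            except (ValueError, TypeError) as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    return responses


def write_responses_csv(responses: Iterable[LikertResponse], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for r in responses:
            writer.writerow([r.respondent, r.instrument, r.item, r.rating])
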