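"""Acceptability instrument definitions and pilot reference statistics."""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

from .acceptability import ItemSummary
from .errors import ConfigError


@dataclass(frozen=True)
class InstrumentItem:
    id: str
    text: str
    reference_mean: float


@dataclass(frozen=True)
class Instrument:
    id: str
    n: int
    items: tuple[InstrumentItem, ...]

    def item_ids(self) -> list[str]:
        return [i.id for i in self.items]

    def reference_means(self) -> list[float]:
        return [i.reference_mean for i in self.items]

    def reference_summaries(self) -> list[ItemSummary]:
        """Item summaries built from the published per-item means."""
        return [
            ItemSummary(
                item=i.id, n=self.n, mean=i.reference_mean, sd=0.0, sd_defined=False
            )
            for i in self.items
        ]


def load_instruments(path: str | Path | None = None) -> dict[str, Instrument]:
    if path is None:
        doc = yaml.safe_load(
            resources.files("sbirtkit.data").joinpath("instruments.yaml").read_text()
        )
    else:
        with open(path) as fh:
            doc = yaml.safe_load(fh)
    try:
        return {
            name: Instrument(
                id=name,
                n=int(spec["n"]),
                items=tuple(
                    InstrumentItem(
                        id=item["id"],
                        text=item["text"],
                        reference_mean=float(item["reference_mean"]),
                    )
                    for item in spec["items"]
                ),
            )
            for name, spec in doc["instruments"].items()
        }
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigError(f"bad instrument configuration: {exc}") from exc
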