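"""Substance classes covered by the screening instrument.

Nine named classes are screened, in a stable display order, plus an
``other`` bucket for write-ins.  The enum value is the canonical id used
in every document format.
"""

from __future__ import annotations

from enum import Enum


class Substance(str, Enum):
    TOBACCO = "tobacco"
    ALCOHOL = "alcohol"
    CANNABIS = "cannabis"
    COCAINE = "cocaine"
    STIMULANTS = "stimulants"  # amphetamine-type stimulants
    INHALANTS = "inhalants"
    SEDATIVES = "sedatives"
    HALLUCINOGENS = "hallucinogens"
    OPIOIDS = "opioids"
    OTHER = "other"

    @property
    def display_name(self) -> str:
        return _DISPLAY[self]


#: The nine named screening classes, in display order (``other`` excluded).
CORE_SUBSTANCES: tuple[Substance, ...] = (
    Substance.TOBACCO,
    Substance.ALCOHOL,
    Substance.CANNABIS,
    Substance.COCAINE,
    Substance.STIMULANTS,
    Substance.INHALANTS,
    Substance.SEDATIVES,
    Substance.HALLUCINOGENS,
    Substance.OPIOIDS,
)

_DISPLAY = {
    Substance.TOBACCO: "tobacco products",
    Substance.ALCOHOL: "alcoholic beverages",
    Substance.CANNABIS: "cannabis",
    Substance.COCAINE: "cocaine",
    Substance.STIMULANTS: "amphetamine-type stimulants",
    Substance.INHALANTS: "inhalants",
    Substance.SEDATIVES: "sedatives or sleeping pills",
    Substance.HALLUCINOGENS: "hallucinogens",
    Substance.OPIOIDS: "opioids",
    Substance.OTHER: "other drugs",
}
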