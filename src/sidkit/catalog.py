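"""Predictor catalog and prediction horizons.

The catalog order is fixed: it defines tie-breaking in the subset search and
the column order of every exported table.  The first 11 entries are the
bedside physical signs; the last is the derived shock-index predictor.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

#: The 11 physical signs, in canonical order.
SIGN_IDS: tuple[str, ...] = (
    "decreased_response_verbal",
    "decreased_response_visual",
    "peripheral_cyanosis",
    "mandibular_respiration",
    "death_rattle",
    "neck_hyperextension",
    "eyes_unable_to_close",
    "nasolabial_drooping",
    "cheyne_stokes",
    "radial_pulselessness",
    "apnea",
)

#: Identifier of the derived shock-index (> 1.0) predictor.
SI_PREDICTOR: str = "shock_index_gt1"

#: All 12 predictors: 11 signs plus the shock-index event.
PREDICTOR_IDS: tuple[str, ...] = SIGN_IDS + (SI_PREDICTOR,)

PREDICTOR_INDEX: dict[str, int] = {p: i for i, p in enumerate(PREDICTOR_IDS)}


def display_names() -> dict[str, str]:
    """Mapping from predictor identifier to its human-readable name."""
    text = resources.files("sidkit.data").joinpath("sign_names.json").read_text()
    return json.loads(text)


@dataclass(frozen=True)
class Horizon:
    """A prediction window counted backward from death."""

    label: str
    hours: float

    def __post_init__(self) -> None:
        if self.hours <= 0:
            raise ValueError(f"horizon duration must be > 0, got {self.hours}")


HORIZON_7D = Horizon("7d", 168.0)
HORIZON_72H = Horizon("72h", 72.0)
HORIZON_24H = Horizon("24h", 24.0)

HORIZONS: dict[str, Horizon] = {
    h.label: h for h in (HORIZON_7D, HORIZON_72H, HORIZON_24H)
}
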