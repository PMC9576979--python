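"""Cartridge panel definitions for i-STAT-style analyzers.

A *panel* is the ordered set of analytes one cartridge type reports.  Two
panels are bundled:

* ``CG4`` — arterial blood gas, 13 reported values.  Eight are the values a
  technician would copy from the printed strip (``hand_recorded``): the
  temperature-corrected pH/pCO2/pO2, lactate, bicarbonate, base excess,
  oxygen saturation and TCO2.  The other five are machine-only: sample
  temperature, the *measured* (37 °C) pH/pCO2/pO2 and barometric pressure.
  Each temperature-corrected blood-gas value is ``paired_with`` its measured
  counterpart — transcribing the measured value in place of the corrected one
  is the dominant manual-entry error this package quantifies.
* ``CHEM8`` — basic metabolic panel, 11 values, all hand-recorded.

Panels are plain data and can be loaded from a YAML/JSON mapping, so the
composition is configuration, not a hard-coded science claim.  Sampling
ranges are swine-plausible defaults for a hemorrhagic-shock critical-care
setting and exist to make simulated values look right; they carry no
diagnostic meaning.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal
from typing import Mapping, Optional, Sequence

__all__ = ["Analyte", "CartridgePanel", "DEFAULT_PANELS", "panels_from_mapping"]


@dataclass(frozen=True)
class Analyte:
    """One analyte slot on a cartridge panel.

    ``sampling_range`` bounds simulated draws; ``decimals`` is the display
    precision the device prints (values are rendered, stored and compared as
    decimal strings at exactly this precision).
    """

    observation_id: str
    units: str
    low: Decimal
    high: Decimal
    decimals: int
    hand_recorded: bool = False
    #: observation_id of the measured counterpart of a temperature-corrected
    #: value (or vice versa); None for unpaired analytes.
    paired_with: Optional[str] = None
    #: measured counterparts are derived from the corrected draw by a bounded
    #: perturbation of up to this many display quanta (never zero quanta, so
    #: the pair always differs at display precision and swaps are detectable)
    max_pair_delta_quanta: int = 0

    @property
    def quantum(self) -> Decimal:
        return Decimal(1).scaleb(-self.decimals)


@dataclass(frozen=True)
class CartridgePanel:
    name: str
    analytes: tuple[Analyte, ...]

    @property
    def analyte_ids(self) -> tuple[str, ...]:
        return tuple(a.observation_id for a in self.analytes)

    @property
    def hand_recorded_ids(self) -> tuple[str, ...]:
        return tuple(a.observation_id for a in self.analytes if a.hand_recorded)

    def analyte(self, observation_id: str) -> Analyte:
        for a in self.analytes:
            if a.observation_id == observation_id:
                return a
        raise KeyError(observation_id)

    def validate_values(self, values: Mapping[str, str]) -> None:
        """Check a result's value map against this panel (ids and ranges)."""
        ids = set(self.analyte_ids)
        got = set(values)
        if got != ids:
            raise ValueError(
                f"panel {self.name}: value keys {sorted(got ^ ids)} do not "
                "match the panel's analytes"
            )
        for a in self.analytes:
            v = Decimal(values[a.observation_id])
            # paired measured values may drift slightly past the sampling
            # range by construction; allow the perturbation margin
            margin = a.quantum * a.max_pair_delta_quanta
            if not (a.low - margin <= v <= a.high + margin):
                raise ValueError(
                    f"panel {self.name}: {a.observation_id}={v} outside "
                    f"[{a.low}, {a.high}]"
                )


def _a(
    oid: str,
    units: str,
    low: str,
    high: str,
    decimals: int,
    hand: bool = False,
    pair: Optional[str] = None,
    pair_quanta: int = 0,
) -> Analyte:
    return Analyte(
        observation_id=oid,
        units=units,
        low=Decimal(low),
        high=Decimal(high),
        decimals=decimals,
        hand_recorded=hand,
        paired_with=pair,
        max_pair_delta_quanta=pair_quanta,
    )


CG4 = CartridgePanel(
    name="CG4",
    analytes=(
        # hand-recorded (8)
        _a("pH_tc", "[pH]", "6.80", "7.60", 2, hand=True, pair="pH_m", pair_quanta=6),
        _a("pCO2_tc", "mm[Hg]", "20.0", "80.0", 1, hand=True, pair="pCO2_m", pair_quanta=40),
        _a("pO2_tc", "mm[Hg]", "30", "250", 0, hand=True, pair="pO2_m", pair_quanta=20),
        _a("lactate", "mmol/L", "0.30", "15.00", 2, hand=True),
        _a("HCO3", "mmol/L", "10.0", "35.0", 1, hand=True),
        _a("BE", "mmol/L", "-20", "10", 0, hand=True),
        _a("sO2", "%", "60", "100", 0, hand=True),
        _a("TCO2", "mmol/L", "10", "40", 0, hand=True),
        # machine-only (5)
        _a("temp", "Cel", "35.0", "41.0", 1),
        _a("pH_m", "[pH]", "6.80", "7.60", 2, pair="pH_tc", pair_quanta=6),
        _a("pCO2_m", "mm[Hg]", "20.0", "80.0", 1, pair="pCO2_tc", pair_quanta=40),
        _a("pO2_m", "mm[Hg]", "30", "250", 0, pair="pO2_tc", pair_quanta=20),
        _a("baro", "mm[Hg]", "720", "780", 0),
    ),
)

CHEM8 = CartridgePanel(
    name="CHEM8",
    analytes=(
        _a("Na", "mmol/L", "128", "152", 0, hand=True),
        _a("K", "mmol/L", "2.8", "7.2", 1, hand=True),
        _a("Cl", "mmol/L", "90", "115", 0, hand=True),
        _a("iCa", "mmol/L", "0.80", "1.60", 2, hand=True),
        _a("TCO2", "mmol/L", "10", "40", 0, hand=True),
        _a("Glu", "mg/dL", "40", "250", 0, hand=True),
        _a("BUN", "mg/dL", "4", "45", 0, hand=True),
        _a("Crea", "mg/dL", "0.4", "3.5", 1, hand=True),
        _a("Hct", "%", "12", "48", 0, hand=True),
        _a("Hgb", "g/dL", "4.0", "16.0", 1, hand=True),
        _a("AnGap", "mmol/L", "4", "28", 0, hand=True),
    ),
)

DEFAULT_PANELS: dict[str, CartridgePanel] = {"CG4": CG4, "CHEM8": CHEM8}


def panels_from_mapping(data: Mapping[str, Sequence[Mapping]]) -> dict[str, CartridgePanel]:
    """Build panels from a parsed YAML/JSON mapping.

    Shape: ``{panel_name: [{observation_id, units, low, high, decimals,
    hand_recorded?, paired_with?, max_pair_delta_quanta?}, ...]}``.
    """
    panels: dict[str, CartridgePanel] = {}
    for name, entries in data.items():
        analytes = tuple(
            Analyte(
                observation_id=e["observation_id"],
                units=e["units"],
                low=Decimal(str(e["low"])),
                high=Decimal(str(e["high"])),
                decimals=int(e["decimals"]),
                hand_recorded=bool(e.get("hand_recorded", False)),
                paired_with=e.get("paired_with"),
                max_pair_delta_quanta=int(e.get("max_pair_delta_quanta", 0)),
            )
            for e in entries
        )
        panels[name] = CartridgePanel(name=name, analytes=analytes)
    return panels
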