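"""Manual-transcription accounting: hand-entry simulation, mismatch
classification, and the arithmetic of error rates, capture gain and
personnel time.

Before automated logging, blood-gas strips were printed and copied into a
database by hand.  Three things go wrong with hand entry, and each is a
distinct class here:

``SWAP``
    The technician copies the *measured* (37 °C) blood-gas value instead of
    the temperature-corrected one (or vice versa).  Applies only to the
    paired pH/pCO2/pO2 triplet and, when it happens, typically affects the
    whole triplet of an entry — so the simulator swaps at the cartridge
    level with a per-technician probability.
``TYPO``
    A single-digit slip (one digit off by one), e.g. chloride 95 recorded
    as 94.
``OMIT``
    The value was never entered.

The comparator classifies each hand-recorded value of each cartridge against
device truth: ``MATCH`` if equal to the corrected value, ``SWAP`` if exactly
equal to the paired measured value, ``OMIT`` if absent, anything else
``TYPO``.  Rates are percentages of individual values, rounded half-up to
two decimals.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field, replace
from decimal import Decimal, ROUND_HALF_UP
from typing import Mapping, Optional, Sequence

from .panels import CartridgePanel, DEFAULT_PANELS
from .simulator import DeviceResult

__all__ = [
    "ErrorModel",
    "TranscriptionEntry",
    "TranscriptionLog",
    "ErrorReport",
    "RecoverySummary",
    "round_half_up",
    "values_per_study",
    "per_cartridge_entry_time",
    "error_rate_percent",
    "capture_gain_percent",
    "person_hours",
    "simulate_manual_transcription",
    "compare_transcripts",
    "recover_error_rates",
]


def round_half_up(x: float | Decimal, decimals: int) -> float:
    """Decimal half-up rounding (the convention of the reported figures)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(str(x)).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# accounting arithmetic
# ---------------------------------------------------------------------------


def values_per_study(
    n_cg4: int, n_chem8: int, vals_cg4: int = 8, vals_chem8: int = 11
) -> int:
    """Total hand-entered values in one study.

    Defaults reflect the hand-recorded slice of each panel: 8 of the 13 CG4
    values and all 11 CHEM8 values.
    """
    if min(n_cg4, n_chem8, vals_cg4, vals_chem8) < 0:
        raise ValueError("counts must be >= 0")
    return n_cg4 * vals_cg4 + n_chem8 * vals_chem8


def per_cartridge_entry_time(
    total_minutes: float,
    n_cg4: int,
    n_chem8: int,
    vals_cg4: int = 8,
    vals_chem8: int = 11,
) -> tuple[float, float]:
    """Apportion total curation time uniformly per value.

    Returns (minutes per CG4 cartridge, minutes per CHEM8 cartridge), each
    rounded half-up to one decimal.  With a 120-minute entry-and-QC session
    for 16 CG4 + 10 CHEM8 this yields the familiar 4.0 and 5.5 minutes.
    """
    if n_cg4 + n_chem8 <= 0:
        raise ValueError("at least one cartridge is required")
    total_values = values_per_study(n_cg4, n_chem8, vals_cg4, vals_chem8)
    if total_values == 0:
        return (0.0, 0.0)
    t = Decimal(str(total_minutes)) / total_values
    return (
        round_half_up(t * vals_cg4, 1),
        round_half_up(t * vals_chem8, 1),
    )


def error_rate_percent(n_errors: int, n_entries: int) -> float:
    """Percentage of erroneous values among ``n_entries`` checked values,
    rounded half-up to two decimals."""
    if n_entries <= 0:
        raise ValueError("n_entries must be > 0")
    if not 0 <= n_errors <= n_entries:
        raise ValueError("require 0 <= n_errors <= n_entries")
    return round_half_up(Decimal(100) * n_errors / n_entries, 2)


def capture_gain_percent(
    hand_recorded_per_result: int, machine_only_per_result: int
) -> float:
    """Share of per-result data that automation adds, as a percentage.

    The machine-only values (never copied by hand) become available once
    results download automatically: gain = machine / (hand + machine).
    """
    total = hand_recorded_per_result + machine_only_per_result
    if total <= 0:
        raise ValueError("at least one value per result is required")
    return round_half_up(Decimal(100) * machine_only_per_result / total, 1)


def person_hours(n_animals: int, hours_per_study: float) -> float:
    """Total personnel time for a cohort at a fixed per-study entry cost."""
    if n_animals < 0 or hours_per_study < 0:
        raise ValueError("counts must be >= 0")
    return n_animals * hours_per_study


# ---------------------------------------------------------------------------
# hand-entry simulation
# ---------------------------------------------------------------------------


@dataclass
class ErrorModel:
    """Stochastic model of a technician's hand entry.

    ``p_swap`` fires per cartridge entry and replaces the whole corrected
    blood-gas triplet by its measured counterpart; per-technician overrides
    in ``technicians`` emulate two operators with very different swap habits
    who alternate sporadically.  ``p_typo`` and ``p_omit`` fire per value,
    mutually exclusively, after any swap.  Defaults emulate the observed
    hand-entry behaviour of a two-technician team: a swap-value incidence
    near one value in ten and a rare digit slip.
    """

    p_swap: float = 0.26
    p_typo: float = 0.003
    p_omit: float = 0.0
    #: technician id -> that technician's own p_swap
    technicians: Mapping[str, float] = field(
        default_factory=lambda: {"A": 0.45, "B": 0.07}
    )
    #: entry index -> technician id; None alternates over ``technicians``
    technician_schedule: Optional[Sequence[str]] = None
    seed: int = 1

    def validate(self) -> None:
        probs = [self.p_swap, self.p_typo, self.p_omit, *self.technicians.values()]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if self.p_typo + self.p_omit > 1.0:
            raise ValueError("p_typo + p_omit must not exceed 1")

    def technician_for(self, entry_index: int) -> str:
        if self.technician_schedule is not None:
            return self.technician_schedule[entry_index % len(self.technician_schedule)]
        ids = list(self.technicians) or ["A"]
        return ids[entry_index % len(ids)]

    def swap_prob(self, technician_id: str) -> float:
        return self.technicians.get(technician_id, self.p_swap)


@dataclass(frozen=True)
class TranscriptionEntry:
    result_id: str
    technician_id: str
    #: hand-recorded analytes only; omitted values are absent from the map
    recorded: Mapping[str, str]


@dataclass(frozen=True)
class TranscriptionLog:
    entries: tuple[TranscriptionEntry, ...]


def _typo(value: str, rng: random.Random, forbidden: frozenset[str]) -> str:
    """Perturb exactly one digit of a decimal string by +/-1.

    Never returns the original value or anything in ``forbidden`` (the
    corrected/measured pair), so the error classes stay disjoint.
    """
    digit_positions = [i for i, c in enumerate(value) if c.isdigit()]
    candidates: list[str] = []
    for i in digit_positions:
        d = int(value[i])
        for delta in (-1, 1):
            if 0 <= d + delta <= 9:
                mutated = value[:i] + str(d + delta) + value[i + 1:]
                if mutated != value and mutated not in forbidden:
                    candidates.append(mutated)
    if not candidates:  # cannot happen for any nonempty decimal string
        return value
    return rng.choice(candidates)


def simulate_manual_transcription(
    truth: Sequence[DeviceResult],
    model: ErrorModel,
    panels: Optional[Mapping[str, CartridgePanel]] = None,
) -> TranscriptionLog:
    """Simulate technicians copying printed results into a database.

    For each entry, the assigned technician's swap probability decides
    whether the corrected blood-gas triplet is replaced by the measured
    triplet; independently, each recorded value then suffers a single-digit
    typo with ``p_typo`` or an omission with ``p_omit``.  Deterministic for
    a fixed model seed.
    """
    model.validate()
    if panels is None:
        panels = DEFAULT_PANELS
    rng = random.Random(model.seed)
    entries: list[TranscriptionEntry] = []
    for idx, res in enumerate(truth):
        panel = panels[res.cartridge_name]
        tech = model.technician_for(idx)
        has_pairs = any(
            a.hand_recorded and a.paired_with is not None for a in panel.analytes
        )
        swapped = has_pairs and rng.random() < model.swap_prob(tech)
        recorded: dict[str, str] = {}
        for a in panel.analytes:
            if not a.hand_recorded:
                continue
            value = res.values[a.observation_id]
            if swapped and a.paired_with is not None:
                value = res.values[a.paired_with]
            u = rng.random()
            if u < model.p_typo:
                forbidden = {res.values[a.observation_id]}
                if a.paired_with is not None:
                    forbidden.add(res.values[a.paired_with])
                value = _typo(value, rng, frozenset(forbidden))
            elif u < model.p_typo + model.p_omit:
                continue  # omitted: never written down
            recorded[a.observation_id] = value
        entries.append(
            TranscriptionEntry(result_id=res.result_id, technician_id=tech, recorded=recorded)
        )
    return TranscriptionLog(entries=tuple(entries))


# ---------------------------------------------------------------------------
# comparison and reporting
# ---------------------------------------------------------------------------

MATCH = "MATCH"
SWAP = "SWAP"
TYPO = "TYPO"
OMIT = "OMIT"


@dataclass
class ErrorReport:
    """Classified mismatch tallies for one truth/log comparison."""

    n_entries: int  # individual values checked
    n_errors: int
    class_counts: dict[str, int]
    per_analyte_counts: dict[str, int]
    rate_percent: float
    #: entries (cartridges) whose blood-gas triplet was recorded swapped
    swapped_cartridges: int = 0
    triplet_entries: int = 0

    def as_table(self) -> str:
        lines = [
            f"{'values checked':<22}{self.n_entries:>8}",
            f"{'values in error':<22}{self.n_errors:>8}",
            f"{'error rate (%)':<22}{self.rate_percent:>8.2f}",
        ]
        for cls in (SWAP, TYPO, OMIT):
            lines.append(f"{'  ' + cls:<22}{self.class_counts.get(cls, 0):>8}")
        if self.per_analyte_counts:
            lines.append("errors by analyte:")
            for oid, n in sorted(self.per_analyte_counts.items()):
                lines.append(f"{'  ' + oid:<22}{n:>8}")
        return "\n".join(lines)


class ComparisonError(ValueError):
    """A log references result ids that are not in the truth set."""


def classify_value(
    recorded: Optional[str], corrected: str, measured: Optional[str]
) -> str:
    """Classify one hand-recorded value against device truth."""
    if recorded is None:
        return OMIT
    if recorded == corrected:
        return MATCH
    if measured is not None and recorded == measured:
        return SWAP
    return TYPO


def compare_transcripts(
    truth: Sequence[DeviceResult],
    log: TranscriptionLog,
    panels: Optional[Mapping[str, CartridgePanel]] = None,
) -> ErrorReport:
    """Classify every hand-recorded value of ``log`` against ``truth``."""
    if panels is None:
        panels = DEFAULT_PANELS
    truth_by_id = {r.result_id: r for r in truth}
    unknown = [e.result_id for e in log.entries if e.result_id not in truth_by_id]
    if unknown:
        raise ComparisonError(f"log references unknown result ids: {unknown}")

    n_values = 0
    n_errors = 0
    class_counts = {SWAP: 0, TYPO: 0, OMIT: 0}
    per_analyte: dict[str, int] = {}
    swapped_cartridges = 0
    triplet_entries = 0

    for entry in log.entries:
        res = truth_by_id[entry.result_id]
        panel = panels[res.cartridge_name]
        entry_swaps = 0
        entry_triplets = 0
        for a in panel.analytes:
            if not a.hand_recorded:
                continue
            n_values += 1
            measured = res.values[a.paired_with] if a.paired_with else None
            cls = classify_value(
                entry.recorded.get(a.observation_id),
                res.values[a.observation_id],
                measured,
            )
            if a.paired_with is not None:
                entry_triplets += 1
                if cls == SWAP:
                    entry_swaps += 1
            if cls != MATCH:
                n_errors += 1
                class_counts[cls] += 1
                per_analyte[a.observation_id] = per_analyte.get(a.observation_id, 0) + 1
        if entry_triplets:
            triplet_entries += 1
            if entry_swaps > 0:
                swapped_cartridges += 1

    return ErrorReport(
        n_entries=n_values,
        n_errors=n_errors,
        class_counts=class_counts,
        per_analyte_counts=per_analyte,
        rate_percent=error_rate_percent(n_errors, n_values) if n_values else 0.0,
        swapped_cartridges=swapped_cartridges,
        triplet_entries=triplet_entries,
    )


# ---------------------------------------------------------------------------
# parameter-recovery harness
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RecoverySummary:
    """Observed class rates over simulation replicates, with binomial SEs.

    Swap incidence is estimated per cartridge (the independent unit the swap
    fires on); typo incidence per value.  Confidence intervals are normal
    approximations at 95%.
    """

    replicates: int
    values_per_replicate: int
    cartridges_per_replicate: int
    mean_swap_rate: float
    swap_se: float
    mean_typo_rate: float
    typo_se: float

    @property
    def swap_ci(self) -> tuple[float, float]:
        return (self.mean_swap_rate - 1.96 * self.swap_se,
                self.mean_swap_rate + 1.96 * self.swap_se)

    @property
    def typo_ci(self) -> tuple[float, float]:
        return (self.mean_typo_rate - 1.96 * self.typo_se,
                self.mean_typo_rate + 1.96 * self.typo_se)


def recover_error_rates(
    n_entries: int,
    model: ErrorModel,
    replicates: int,
    panels: Optional[Mapping[str, CartridgePanel]] = None,
) -> RecoverySummary:
    """Validation harness: simulate + compare, report observed class rates.

    ``n_entries`` is the number of hand-recorded blood-gas values per
    replicate (rounded up to whole cartridges).  Each replicate draws a
    fresh truth set and a fresh transcription from sub-seeds of
    ``model.seed``.
    """
    from .simulator import GeneratorConfig, build_study_queue

    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if panels is None:
        panels = DEFAULT_PANELS
    vals_per_cart = len(panels["CG4"].hand_recorded_ids)
    n_cg4 = math.ceil(n_entries / vals_per_cart)

    total_values = 0
    total_typos = 0
    total_cartridges = 0
    total_swapped = 0
    for r in range(replicates):
        sub = (model.seed * 100003 + r) % (2**31 - 1)
        truth = build_study_queue(
            GeneratorConfig(seed=sub, n_cg4=n_cg4, n_chem8=0), panels=dict(panels)
        )
        log = simulate_manual_transcription(truth, replace(model, seed=sub + 1), panels)
        report = compare_transcripts(truth, log, panels)
        total_values += report.n_entries
        total_typos += report.class_counts[TYPO]
        total_cartridges += report.triplet_entries
        total_swapped += report.swapped_cartridges

    swap_rate = total_swapped / total_cartridges if total_cartridges else 0.0
    typo_rate = total_typos / total_values if total_values else 0.0
    swap_se = math.sqrt(max(swap_rate * (1 - swap_rate), 1e-12) / max(total_cartridges, 1))
    typo_se = math.sqrt(max(typo_rate * (1 - typo_rate), 1e-12) / max(total_values, 1))
    return RecoverySummary(
        replicates=replicates,
        values_per_replicate=n_cg4 * vals_per_cart,
        cartridges_per_replicate=n_cg4,
        mean_swap_rate=swap_rate,
        swap_se=swap_se,
        mean_typo_rate=typo_rate,
        typo_se=typo_se,
    )
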