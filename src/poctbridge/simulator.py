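"""Device simulator: physiologically plausible CG4/CHEM8 results and an
analyzer emulation with an unsent-record queue and scripted faults.

This is the synthetic stand-in for a docked blood analyzer in every
end-to-end test: it draws panel values, queues them as a study worth of
cartridge runs, and speaks the device side of the conversation, optionally
injecting transport faults (dropped connections, a device never docked, an
absent manager).

Study-scale defaults mirror a real critical-care experiment day: 16 blood-gas
(CG4) and 10 electrolyte (CHEM8) cartridges, interleaved chronologically.
Each analyte is drawn uniformly within its panel's sampling range and
rendered at the device's display precision.  The temperature-corrected and
measured blood-gas triplets are linked: the measured variant is derived from
the corrected draw by a bounded nonzero perturbation, so a transcription
that confuses the two is always detectable downstream.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta
from decimal import Decimal, ROUND_HALF_UP
from typing import Optional, Sequence

from . import conversation
from .conversation import DeviceState, SessionConfig, Transport
from .messages import Observation, ObservationsPayload, ObservationStatus
from .panels import Analyte, CartridgePanel, DEFAULT_PANELS

__all__ = [
    "DeviceResult",
    "GeneratorConfig",
    "FailurePlan",
    "generate_result",
    "build_study_queue",
    "simulate_device",
    "FaultyTransport",
    "result_to_dict",
    "result_from_dict",
]


@dataclass(frozen=True)
class DeviceResult:
    """One cartridge run as held in the device's unsent queue."""

    result_id: str
    timestamp: datetime
    device_serial: str
    vendor_name: str
    cartridge_name: str
    lot_number: str
    expiration_date: date
    #: observation_id -> decimal string at display precision
    values: dict[str, str]

    def to_payload(
        self, panels: Optional[dict[str, CartridgePanel]] = None
    ) -> ObservationsPayload:
        panel = (panels or DEFAULT_PANELS).get(self.cartridge_name)
        return ObservationsPayload(
            result_id=self.result_id,
            observation_time=self.timestamp,
            cartridge_name=self.cartridge_name,
            lot_number=self.lot_number,
            expiration_date=self.expiration_date,
            device_serial=self.device_serial,
            observations=tuple(
                Observation(
                    observation_id=oid,
                    value=val,
                    units=panel.analyte(oid).units if panel is not None else "",
                    status=ObservationStatus.NORMAL,
                )
                for oid, val in self.values.items()
            ),
        )


@dataclass
class GeneratorConfig:
    """Study composition and identity templates for the simulator."""

    seed: int = 1
    n_cg4: int = 16
    n_chem8: int = 10
    device_serial: str = "SIM-000001"
    vendor_name: str = "Abbott Point of Care (simulated)"
    lot_template: str = "LOT{panel}{n:03d}"
    start_time: datetime = field(
        default_factory=lambda: datetime(2026, 1, 5, 8, 0, 0)
    )

    def validate(self) -> None:
        if self.n_cg4 < 0 or self.n_chem8 < 0:
            raise ValueError("cartridge counts must be >= 0")


def _quantize(value: Decimal, decimals: int) -> str:
    q = Decimal(1).scaleb(-decimals)
    return str(value.quantize(q, rounding=ROUND_HALF_UP))


def _draw(analyte: Analyte, rng: random.Random) -> Decimal:
    u = Decimal(str(rng.random()))
    return analyte.low + u * (analyte.high - analyte.low)


def generate_result(
    panel: CartridgePanel,
    rng: random.Random,
    *,
    result_id: str = "R-0001",
    timestamp: Optional[datetime] = None,
    device_serial: str = "SIM-000001",
    vendor_name: str = "Abbott Point of Care (simulated)",
    lot_number: str = "LOT000",
) -> DeviceResult:
    """Draw one cartridge result with values uniform within sampling ranges.

    For paired analytes (temperature-corrected vs. measured pH/pCO2/pO2) the
    measured variant is the corrected draw shifted by 1 to
    ``max_pair_delta_quanta`` display quanta in a random direction — never
    zero, so the pair always differs at display precision.
    """
    values: dict[str, str] = {}
    base: dict[str, Decimal] = {}
    for a in panel.analytes:
        if a.paired_with is not None and a.paired_with in base:
            # derive from the already-drawn partner
            partner = base[a.paired_with]
            quanta = rng.randint(1, max(1, a.max_pair_delta_quanta))
            sign = rng.choice((-1, 1))
            val = partner + a.quantum * quanta * sign
            base[a.observation_id] = val
        else:
            val = _draw(a, rng)
            base[a.observation_id] = val
        values[a.observation_id] = _quantize(base[a.observation_id], a.decimals)
    if timestamp is None:
        timestamp = datetime(2026, 1, 5, 8, 0, 0)
    return DeviceResult(
        result_id=result_id,
        timestamp=timestamp,
        device_serial=device_serial,
        vendor_name=vendor_name,
        cartridge_name=panel.name,
        lot_number=lot_number,
        expiration_date=timestamp.date() + timedelta(days=180),
        values=values,
    )


def build_study_queue(
    cfg: GeneratorConfig,
    panels: Optional[dict[str, CartridgePanel]] = None,
) -> list[DeviceResult]:
    """Build one study's worth of results, interleaved chronologically.

    Returns ``n_cg4 + n_chem8`` results with strictly increasing timestamps
    (5–15 minutes apart) in a seeded random cartridge order.  The result id
    is ``serial-YYYYmmddHHMMSS-seq``, which doubles as the sink's
    idempotency key.
    """
    cfg.validate()
    if panels is None:
        panels = DEFAULT_PANELS
    rng = random.Random(cfg.seed)
    order = ["CG4"] * cfg.n_cg4 + ["CHEM8"] * cfg.n_chem8
    rng.shuffle(order)
    t = cfg.start_time
    results: list[DeviceResult] = []
    for seq, panel_name in enumerate(order, start=1):
        t = t + timedelta(minutes=rng.randint(5, 15))
        results.append(
            generate_result(
                panels[panel_name],
                rng,
                result_id=f"{cfg.device_serial}-{t:%Y%m%d%H%M%S}-{seq:04d}",
                timestamp=t,
                device_serial=cfg.device_serial,
                vendor_name=cfg.vendor_name,
                lot_number=cfg.lot_template.format(panel=panel_name, n=seq),
            )
        )
    return results


def result_to_dict(result: DeviceResult) -> dict:
    """JSON-ready form of a result (used by the queue state file and fixtures)."""
    d = dict(result.__dict__)
    d["timestamp"] = result.timestamp.isoformat(timespec="seconds")
    d["expiration_date"] = result.expiration_date.isoformat()
    d["values"] = dict(result.values)
    return d


def result_from_dict(d: dict) -> DeviceResult:
    d = dict(d)
    d["timestamp"] = datetime.fromisoformat(d["timestamp"])
    d["expiration_date"] = date.fromisoformat(d["expiration_date"])
    return DeviceResult(**d)


# ---------------------------------------------------------------------------
# fault injection
# ---------------------------------------------------------------------------


@dataclass
class FailurePlan:
    """Scripted faults for an emulated transmission attempt."""

    #: drop the connection after this many sent messages (None = never)
    disconnect_after_sends: Optional[int] = None
    #: the device is never placed in the dock: no connection is attempted
    withhold_dock: bool = False


class FaultyTransport:
    """Transport wrapper that severs the link after N sends."""

    def __init__(self, inner: Transport, disconnect_after_sends: int) -> None:
        self._inner = inner
        self._remaining = disconnect_after_sends
        self._dead = False

    def sendall(self, data: bytes) -> None:
        if self._dead:
            raise ConnectionResetError("scripted disconnect")
        if self._remaining <= 0:
            self._dead = True
            self._inner.close()
            raise ConnectionResetError("scripted disconnect")
        self._remaining -= 1
        self._inner.sendall(data)

    def recv(self, bufsize: int) -> bytes:
        if self._dead:
            raise ConnectionResetError("scripted disconnect")
        return self._inner.recv(bufsize)

    def settimeout(self, value: Optional[float]) -> None:
        self._inner.settimeout(value)

    def close(self) -> None:
        self._inner.close()


def simulate_device(
    queue: Sequence[DeviceResult],
    transport_factory,
    failure_plan: Optional[FailurePlan] = None,
    config: Optional[SessionConfig] = None,
    device_serial: str = "SIM-000001",
) -> DeviceState:
    """Emulate one dock-and-transmit attempt for a queue of results.

    ``transport_factory`` is a zero-argument callable returning a connected
    :class:`~poctbridge.conversation.Transport` (or raising ``OSError`` when
    the manager is unreachable).  Faults from ``failure_plan`` are applied on
    top; the returned state carries the retained queue and the UI log.
    """
    if failure_plan is None:
        failure_plan = FailurePlan()
    if config is None:
        config = SessionConfig(panels=DEFAULT_PANELS)
    state = DeviceState(queue=tuple(queue), device_serial=device_serial)
    if failure_plan.withhold_dock:
        return state.logged("device not docked: no transmission attempted")
    try:
        transport = transport_factory()
    except OSError as exc:
        return state.logged(f"connection failed: {exc}")
    if failure_plan.disconnect_after_sends is not None:
        transport = FaultyTransport(transport, failure_plan.disconnect_after_sends)
    return conversation.run_device_session(transport, state, config)
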