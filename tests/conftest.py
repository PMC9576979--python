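"""Shared fixtures: fixed clocks, sample messages, and a threaded listener."""

from __future__ import annotations

import threading
from contextlib import contextmanager
from datetime import date, datetime

import pytest
from hypothesis import settings

from poctbridge.conversation import SessionConfig, serve

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")
from poctbridge.messages import (
    AckPayload,
    AckType,
    Message,
    MessageHeader,
    MessageType,
    Observation,
    ObservationsPayload,
)
from poctbridge.panels import DEFAULT_PANELS

FIXED_NOW = datetime(2026, 1, 5, 8, 0, 0)


@pytest.fixture
def fixed_now() -> datetime:
    return FIXED_NOW


@pytest.fixture
def session_config() -> SessionConfig:
    return SessionConfig(panels=DEFAULT_PANELS, ack_timeout_s=2.0)


def make_ack(control_id: int, ref: int, ack_type: AckType = AckType.ACCEPT) -> Message:
    return Message(
        MessageHeader(MessageType.ACK, control_id, FIXED_NOW),
        AckPayload(ack_control_id=ref, ack_type=ack_type),
    )


def make_cg4_payload(result_id: str = "R-0001", n_obs: int = 13) -> ObservationsPayload:
    panel = DEFAULT_PANELS["CG4"]
    observations = tuple(
        Observation(a.observation_id, str(a.low), a.units)
        for a in panel.analytes[:n_obs]
    )
    return ObservationsPayload(
        result_id=result_id,
        observation_time=FIXED_NOW,
        cartridge_name="CG4",
        lot_number="LOT001",
        expiration_date=date(2026, 7, 1),
        device_serial="SIM-000001",
        observations=observations,
    )


@contextmanager
def listener(sink, config: SessionConfig, max_sessions: int = 1):
    """Run the data-manager listener on an ephemeral port in a thread.

    Yields the bound port; joins the thread (collecting reports) on exit.
    """
    holder: dict = {}
    ready = threading.Event()

    def _ready(port: int) -> None:
        holder["port"] = port
        ready.set()

    def _serve() -> None:
        holder["reports"] = serve(
            "127.0.0.1", 0, sink, config,
            max_sessions=max_sessions, ready_callback=_ready,
        )

    thread = threading.Thread(target=_serve, daemon=True)
    thread.start()
    assert ready.wait(5.0), "listener did not start"
    try:
        yield holder
    finally:
        thread.join(timeout=30.0)
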