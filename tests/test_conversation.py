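"""Pure-transition tests for both conversation roles."""

from __future__ import annotations

from datetime import datetime

import pytest

from poctbridge.conversation import (
    Close,
    DevicePhase,
    DeviceState,
    Docked,
    Log,
    ManagerPhase,
    ManagerState,
    Persist,
    PersistResult,
    Send,
    Timeout,
    device_transition,
    manager_transition,
)
from poctbridge.messages import (
    AckType,
    DeviceCondition,
    DeviceStatusPayload,
    HelloPayload,
    Message,
    MessageHeader,
    MessageType,
    SimplePayload,
)
from poctbridge.simulator import GeneratorConfig, build_study_queue
from conftest import FIXED_NOW, make_ack, make_cg4_payload


def _hello(control_id: int = 1) -> Message:
    return Message(
        MessageHeader(MessageType.HELLO, control_id, FIXED_NOW),
        HelloPayload(device_serial="SIM-000001", vendor_name="ACME"),
    )


def _status(qty: int, control_id: int = 2) -> Message:
    return Message(
        MessageHeader(MessageType.DEVICE_STATUS, control_id, FIXED_NOW),
        DeviceStatusPayload(condition=DeviceCondition.READY, new_observations_qty=qty),
    )


def _obs(control_id: int = 3, result_id: str = "R-0001") -> Message:
    return Message(
        MessageHeader(MessageType.OBSERVATIONS, control_id, FIXED_NOW),
        make_cg4_payload(result_id=result_id),
    )


def _sends(outcome) -> list[Message]:
    return [a.message for a in outcome.actions if isinstance(a, Send)]


# --- manager role ----------------------------------------------------------


def test_hello_from_idle_is_accepted_and_acked():
    out = manager_transition(ManagerState(), _hello(), now=FIXED_NOW)
    assert out.new_state.phase is ManagerPhase.AWAIT_STATUS
    assert out.new_state.peer_serial == "SIM-000001"
    (ack,) = _sends(out)
    assert ack.payload.ack_type is AckType.ACCEPT
    assert ack.payload.ack_control_id == 1


def test_device_status_records_expected_quantity():
    state = manager_transition(ManagerState(), _hello(), now=FIXED_NOW).new_state
    out = manager_transition(state, _status(5), now=FIXED_NOW)
    assert out.new_state.phase is ManagerPhase.RECEIVING
    assert out.new_state.expected_qty == 5
    assert _sends(out)[0].payload.ack_type is AckType.ACCEPT


def _receiving_state() -> ManagerState:
    s = manager_transition(ManagerState(), _hello(), now=FIXED_NOW).new_state
    return manager_transition(s, _status(3), now=FIXED_NOW).new_state


def test_observations_emit_persist_then_success_acks_aa():
    state = _receiving_state()
    out = manager_transition(state, _obs(control_id=9), now=FIXED_NOW)
    assert [type(a) for a in out.actions] == [Persist]
    assert out.actions[0].control_id == 9

    done = manager_transition(out.new_state, PersistResult(True), now=FIXED_NOW)
    (ack,) = _sends(done)
    assert ack.payload.ack_type is AckType.ACCEPT
    assert ack.payload.ack_control_id == 9
    assert done.new_state.received_count == 1
    assert done.new_state.pending is None


def test_persist_failure_acks_ae_and_does_not_count():
    state = _receiving_state()
    pending = manager_transition(state, _obs(control_id=9), now=FIXED_NOW).new_state
    done = manager_transition(pending, PersistResult(False, "disk full"), now=FIXED_NOW)
    (ack,) = _sends(done)
    assert ack.payload.ack_type is AckType.ERROR
    assert ack.payload.ack_control_id == 9
    assert done.new_state.received_count == 0


def test_out_of_order_message_rejected_with_ar_and_phase_kept():
    out = manager_transition(ManagerState(), _obs(control_id=4), now=FIXED_NOW)
    assert out.new_state.phase is ManagerPhase.IDLE
    (ack,) = _sends(out)
    assert ack.payload.ack_type is AckType.REJECT
    assert ack.payload.ack_control_id == 4


def test_timeout_terminates_manager_from_any_phase():
    for state in (ManagerState(), _receiving_state()):
        out = manager_transition(state, Timeout(), now=FIXED_NOW)
        assert out.new_state.phase is ManagerPhase.TERMINATED
        assert any(isinstance(a, Close) for a in out.actions)


def test_end_of_topic_closes_the_session():
    state = _receiving_state()
    eot = Message(
        MessageHeader(MessageType.END_OF_TOPIC, 10, FIXED_NOW), SimplePayload()
    )
    out = manager_transition(state, eot, now=FIXED_NOW)
    assert out.new_state.phase is ManagerPhase.TERMINATED
    assert any(isinstance(a, Close) for a in out.actions)


def test_manager_transitions_are_deterministic():
    events = [_hello(), _status(2), _obs(control_id=3), PersistResult(True)]

    def run():
        state, trace = ManagerState(), []
        for e in events:
            out = manager_transition(state, e, now=FIXED_NOW)
            state = out.new_state
            trace.append(out)
        return trace

    assert run() == run()


# --- device role -----------------------------------------------------------


def _queued_device(n: int) -> DeviceState:
    queue = build_study_queue(GeneratorConfig(seed=1, n_cg4=n, n_chem8=0))
    return DeviceState(queue=tuple(queue))


def _drive_happy_path(state: DeviceState) -> DeviceState:
    """Play the manager's side with immediate AA acks, purely."""
    out = device_transition(state, Docked(), now=FIXED_NOW)
    state = out.new_state
    mgr_cid = 0
    while True:
        sends = _sends(out)
        if any(
            m.header.message_type in (MessageType.END_OF_TOPIC, MessageType.TERMINATE)
            for m in sends
        ) or any(isinstance(a, Close) for a in out.actions):
            return state
        assert len(sends) == 1
        mgr_cid += 1
        ack = make_ack(mgr_cid, sends[0].header.control_id)
        out = device_transition(state, ack, now=FIXED_NOW)
        state = out.new_state


def test_docked_device_says_hello():
    out = device_transition(_queued_device(1), Docked(), now=FIXED_NOW)
    assert out.new_state.phase is DevicePhase.HELLO_SENT
    (hello,) = _sends(out)
    assert hello.header.message_type is MessageType.HELLO


def test_status_reports_queue_depth():
    state = device_transition(_queued_device(3), Docked(), now=FIXED_NOW).new_state
    out = device_transition(state, make_ack(1, 1), now=FIXED_NOW)
    (status,) = _sends(out)
    assert status.header.message_type is MessageType.DEVICE_STATUS
    assert status.payload.new_observations_qty == 3


def test_happy_path_drains_queue_with_three_success_notifications():
    final = _drive_happy_path(_queued_device(3))
    assert final.phase is DevicePhase.DRAINED
    assert final.queue == ()
    assert final.ui_log.count("Successful Transmit") == 3


def test_empty_queue_reports_zero_and_ends_immediately():
    state = device_transition(_queued_device(0), Docked(), now=FIXED_NOW).new_state
    out = device_transition(state, make_ack(1, 1), now=FIXED_NOW)
    assert _sends(out)[0].payload.new_observations_qty == 0
    out2 = device_transition(out.new_state, make_ack(2, 2), now=FIXED_NOW)
    types = [m.header.message_type for m in _sends(out2)]
    assert types == [MessageType.END_OF_TOPIC, MessageType.TERMINATE]
    assert out2.new_state.phase is DevicePhase.DRAINED
    assert "Successful Transmit" not in out2.new_state.ui_log
    assert "Failed Transmit" not in out2.new_state.ui_log


def test_ack_timeout_retains_record_and_logs_failed_transmit():
    state = _queued_device(1)
    state = device_transition(state, Docked(), now=FIXED_NOW).new_state
    state = device_transition(state, make_ack(1, 1), now=FIXED_NOW).new_state
    out = device_transition(state, make_ack(2, 2), now=FIXED_NOW)  # starts sending
    sending = out.new_state
    assert sending.phase is DevicePhase.SENDING
    timed_out = device_transition(sending, Timeout(), now=FIXED_NOW)
    final = timed_out.new_state
    assert final.phase is DevicePhase.TERMINATED
    assert len(final.queue) == 1
    assert "Failed Transmit" in final.ui_log


def test_error_ack_retains_record_in_fifo_order():
    state = _queued_device(2)
    state = device_transition(state, Docked(), now=FIXED_NOW).new_state
    state = device_transition(state, make_ack(1, 1), now=FIXED_NOW).new_state
    out = device_transition(state, make_ack(2, 2), now=FIXED_NOW)
    obs = _sends(out)[0]
    first_id = obs.payload.result_id
    rejected = device_transition(
        out.new_state, make_ack(3, obs.header.control_id, AckType.ERROR), now=FIXED_NOW
    )
    final = rejected.new_state
    assert [r.result_id for r in final.queue][0] == first_id
    assert len(final.queue) == 2
    assert "Failed Transmit" in final.ui_log


def test_ack_with_unknown_control_id_is_ignored_with_warning():
    state = _queued_device(1)
    state = device_transition(state, Docked(), now=FIXED_NOW).new_state
    state = device_transition(state, make_ack(1, 1), now=FIXED_NOW).new_state
    sending = device_transition(state, make_ack(2, 2), now=FIXED_NOW).new_state
    out = device_transition(sending, make_ack(3, 999), now=FIXED_NOW)
    assert out.new_state == sending
    assert any(isinstance(a, Log) for a in out.actions)
    assert not _sends(out)


def test_device_transitions_are_deterministic():
    def run():
        state = _queued_device(2)
        trace = []
        out = device_transition(state, Docked(), now=FIXED_NOW)
        trace.append(out)
        out = device_transition(out.new_state, make_ack(1, 1), now=FIXED_NOW)
        trace.append(out)
        return trace

    assert run() == run()
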