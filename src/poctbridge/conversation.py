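"""Conversation state machines for both roles, plus session runners.

The protocol is a device-initiated push: after docking, the device opens with
Hello, reports its unsent-queue depth, then volunteers each queued result in
FIFO order.  The data manager acknowledges every message; a result is
acknowledged ``AA`` (accept) only after the sink reports a durable write, so
the device removes a record from its queue exactly when the record is safely
persisted.  A persist failure is acknowledged ``AE`` so the device can log
"Failed Transmit" promptly and retain the record for the next session;
silence (no acknowledgment at all) is reserved for transport loss and has the
same retain-and-notify effect via the acknowledgment timeout.

Both state machines are *pure*: ``manager_transition`` and
``device_transition`` map (state, event) to a :class:`TransitionOutcome`
holding the successor state and an ordered action list, with the wall clock
passed in explicitly.  The session runners at the bottom of the module are
thin interpreters of those actions over a socket-like transport, which is why
every protocol rule can be unit-tested without opening a socket.
"""

from __future__ import annotations

import logging
import socket
from dataclasses import dataclass, field, replace
from datetime import datetime, timezone
from enum import Enum
from typing import Mapping, Optional, Protocol, Sequence, Union

from .messages import (
    AckPayload,
    AckType,
    DeviceCondition,
    DeviceStatusPayload,
    FramingError,
    HelloPayload,
    Message,
    MessageHeader,
    MessageType,
    ObservationsPayload,
    ParseError,
    SimplePayload,
    StreamSplitter,
    parse_message,
    serialize_message,
)
from .panels import CartridgePanel
from .sink import ResultSink, flatten_result

logger = logging.getLogger("poctbridge.conversation")

__all__ = [
    "Docked",
    "Timeout",
    "PersistResult",
    "Send",
    "Persist",
    "Log",
    "Close",
    "TransitionOutcome",
    "ManagerPhase",
    "ManagerState",
    "manager_transition",
    "DevicePhase",
    "DeviceState",
    "device_transition",
    "SessionConfig",
    "SessionReport",
    "run_manager_session",
    "run_device_session",
    "serve",
    "connect_and_run_device",
]

SUCCESSFUL_TRANSMIT = "Successful Transmit"
FAILED_TRANSMIT = "Failed Transmit"


# ---------------------------------------------------------------------------
# events and actions
# ---------------------------------------------------------------------------


class Docked:
    """Device-side event: the analyzer was placed in its dock."""


class Timeout:
    """No message arrived within the acknowledgment timeout."""


@dataclass(frozen=True)
class PersistResult:
    """Manager-side event: outcome of persisting the pending result."""

    success: bool
    detail: str = ""


Event = Union[Message, Docked, Timeout, PersistResult]


@dataclass(frozen=True)
class Send:
    message: Message


@dataclass(frozen=True)
class Persist:
    payload: ObservationsPayload
    control_id: int  # of the OBS message, for the eventual acknowledgment


@dataclass(frozen=True)
class Log:
    text: str


@dataclass(frozen=True)
class Close:
    pass


Action = Union[Send, Persist, Log, Close]


@dataclass(frozen=True)
class TransitionOutcome:
    new_state: "ManagerState | DeviceState"
    actions: tuple[Action, ...] = ()


def _now(now: Optional[datetime]) -> datetime:
    if now is not None:
        return now
    return datetime.now(timezone.utc).replace(tzinfo=None, microsecond=0)


# ---------------------------------------------------------------------------
# data manager (receiver / logger) role
# ---------------------------------------------------------------------------


class ManagerPhase(str, Enum):
    IDLE = "IDLE"
    AWAIT_STATUS = "AWAIT_STATUS"
    RECEIVING = "RECEIVING"
    TERMINATED = "TERMINATED"


@dataclass(frozen=True)
class ManagerState:
    phase: ManagerPhase = ManagerPhase.IDLE
    peer_serial: Optional[str] = None
    peer_vendor: str = ""
    expected_qty: Optional[int] = None
    received_count: int = 0
    #: observations message awaiting a persist outcome
    pending: Optional[tuple[ObservationsPayload, int]] = None
    #: this sender's control-id counter (last id used)
    control_counter: int = 0


def _ack(
    state_counter: int, ref_control_id: int, ack_type: AckType, now: datetime,
    note: Optional[str] = None,
) -> tuple[Message, int]:
    cid = state_counter + 1
    msg = Message(
        header=MessageHeader(MessageType.ACK, cid, now),
        payload=AckPayload(ack_control_id=ref_control_id, ack_type=ack_type, note=note),
    )
    return msg, cid


def manager_transition(
    state: ManagerState, event: Event, now: Optional[datetime] = None
) -> TransitionOutcome:
    """Advance the data-manager state machine by one event.

    Handshake: Hello is accepted from IDLE, the device status (queue depth)
    from AWAIT_STATUS, observations from RECEIVING.  An observations message
    first emits a ``Persist`` action; the follow-up :class:`PersistResult`
    event decides between ``AA`` (success — the device may dequeue) and
    ``AE`` (failure — the record is not counted and stays on the device).
    Out-of-order messages are rejected with ``AR`` without leaving the
    current phase; any timeout terminates the session.
    """
    now = _now(now)

    if isinstance(event, Timeout):
        return TransitionOutcome(
            replace(state, phase=ManagerPhase.TERMINATED),
            (Log("session timeout"), Close()),
        )

    if isinstance(event, PersistResult):
        if state.pending is None:
            return TransitionOutcome(state, (Log("persist outcome with no pending record"),))
        payload, obs_cid = state.pending
        if event.success:
            msg, cid = _ack(state.control_counter, obs_cid, AckType.ACCEPT, now)
            return TransitionOutcome(
                replace(
                    state,
                    pending=None,
                    received_count=state.received_count + 1,
                    control_counter=cid,
                ),
                (Send(msg),),
            )
        msg, cid = _ack(
            state.control_counter, obs_cid, AckType.ERROR, now,
            note=event.detail or "persist failed",
        )
        return TransitionOutcome(
            replace(state, pending=None, control_counter=cid),
            (Send(msg), Log(f"persist failed for {payload.result_id}: {event.detail}")),
        )

    if not isinstance(event, Message):
        return TransitionOutcome(state, (Log(f"ignoring event {event!r}"),))

    mtype = event.header.message_type
    in_cid = event.header.control_id

    # session teardown is legal from any live phase
    if mtype in (MessageType.END_OF_TOPIC, MessageType.TERMINATE):
        return TransitionOutcome(
            replace(state, phase=ManagerPhase.TERMINATED), (Close(),)
        )

    if mtype is MessageType.ACK:
        # the manager's own acks are never acknowledged; an inbound ack is
        # noise, not a protocol violation worth rejecting
        return TransitionOutcome(state, (Log(f"ignoring inbound ack {in_cid}"),))

    if state.phase is ManagerPhase.IDLE and mtype is MessageType.HELLO:
        assert isinstance(event.payload, HelloPayload)
        msg, cid = _ack(state.control_counter, in_cid, AckType.ACCEPT, now)
        return TransitionOutcome(
            replace(
                state,
                phase=ManagerPhase.AWAIT_STATUS,
                peer_serial=event.payload.device_serial,
                peer_vendor=event.payload.vendor_name,
                control_counter=cid,
            ),
            (Send(msg), Log(f"hello from {event.payload.device_serial}")),
        )

    if state.phase is ManagerPhase.AWAIT_STATUS and mtype is MessageType.DEVICE_STATUS:
        assert isinstance(event.payload, DeviceStatusPayload)
        msg, cid = _ack(state.control_counter, in_cid, AckType.ACCEPT, now)
        return TransitionOutcome(
            replace(
                state,
                phase=ManagerPhase.RECEIVING,
                expected_qty=event.payload.new_observations_qty,
                control_counter=cid,
            ),
            (Send(msg), Log(f"device reports {event.payload.new_observations_qty} unsent")),
        )

    if (
        state.phase is ManagerPhase.RECEIVING
        and mtype is MessageType.OBSERVATIONS
        and state.pending is None
    ):
        assert isinstance(event.payload, ObservationsPayload)
        return TransitionOutcome(
            replace(state, pending=(event.payload, in_cid)),
            (Persist(event.payload, in_cid),),
        )

    # anything else is out of order: reject, stay in phase
    msg, cid = _ack(
        state.control_counter, in_cid, AckType.REJECT, now,
        note=f"unexpected {mtype.value} in {state.phase.value}",
    )
    return TransitionOutcome(
        replace(state, control_counter=cid),
        (Send(msg), Log(f"rejected out-of-order {mtype.value} in {state.phase.value}")),
    )


# ---------------------------------------------------------------------------
# device (sender) role
# ---------------------------------------------------------------------------


class DevicePhase(str, Enum):
    UNDOCKED = "UNDOCKED"
    HELLO_SENT = "HELLO_SENT"
    STATUS_SENT = "STATUS_SENT"
    SENDING = "SENDING"
    DRAINED = "DRAINED"
    TERMINATED = "TERMINATED"


class ResultLike(Protocol):
    """Anything the device can hold in its unsent queue."""

    result_id: str

    def to_payload(self) -> ObservationsPayload: ...


@dataclass(frozen=True)
class DeviceState:
    """Sender-side session state: FIFO unsent queue plus UI notifications.

    A final phase of ``DRAINED`` means every queued record was acknowledged;
    ``TERMINATED`` means the session ended early and unacknowledged records
    were retained.
    """

    phase: DevicePhase = DevicePhase.UNDOCKED
    queue: tuple[ResultLike, ...] = ()
    in_flight: Optional[tuple[ResultLike, int]] = None
    ui_log: tuple[str, ...] = ()
    device_serial: str = "SIM-000001"
    vendor_name: str = "Abbott Point of Care (simulated)"
    model_name: str = "i-STAT Alinity (simulated)"
    control_counter: int = 0

    def logged(self, *lines: str) -> "DeviceState":
        return replace(self, ui_log=self.ui_log + lines)


def _device_msg(
    state: DeviceState, mtype: MessageType, payload, now: datetime
) -> tuple[Message, int]:
    cid = state.control_counter + 1
    return Message(MessageHeader(mtype, cid, now), payload), cid


def _send_next_or_finish(
    state: DeviceState, now: datetime, extra_actions: tuple[Action, ...] = ()
) -> TransitionOutcome:
    """Ship the queue head, or wind the session down if the queue is empty."""
    if state.queue:
        head, rest = state.queue[0], state.queue[1:]
        msg, cid = _device_msg(
            state, MessageType.OBSERVATIONS, head.to_payload(), now
        )
        return TransitionOutcome(
            replace(
                state,
                phase=DevicePhase.SENDING,
                queue=rest,
                in_flight=(head, cid),
                control_counter=cid,
            ),
            extra_actions + (Send(msg),),
        )
    eot, cid1 = _device_msg(state, MessageType.END_OF_TOPIC, SimplePayload(), now)
    state = replace(state, control_counter=cid1)
    end, cid2 = _device_msg(state, MessageType.TERMINATE, SimplePayload(), now)
    return TransitionOutcome(
        replace(state, phase=DevicePhase.DRAINED, in_flight=None, control_counter=cid2),
        extra_actions + (Send(eot), Send(end), Close()),
    )


def _fail_and_terminate(
    state: DeviceState, now: datetime, reason: str
) -> TransitionOutcome:
    """Retain the in-flight record (front of queue), notify, terminate."""
    queue = state.queue
    if state.in_flight is not None:
        queue = (state.in_flight[0],) + queue
    state = replace(state, queue=queue, in_flight=None)
    end, cid = _device_msg(state, MessageType.TERMINATE, SimplePayload(reason), now)
    return TransitionOutcome(
        replace(
            state,
            phase=DevicePhase.TERMINATED,
            control_counter=cid,
            ui_log=state.ui_log + (FAILED_TRANSMIT,),
        ),
        (Log(f"{FAILED_TRANSMIT}: {reason}"), Send(end), Close()),
    )


def device_transition(
    state: DeviceState, event: Event, now: Optional[datetime] = None
) -> TransitionOutcome:
    """Advance the device (sender) state machine by one event.

    The device always waits for an acknowledgment after each observations
    message: ``AA`` referencing the in-flight control id dequeues the record
    and raises a "Successful Transmit" notification; ``AE``/``AR`` or an
    acknowledgment timeout retains the record at the front of the queue,
    raises "Failed Transmit", and winds the session down.  An acknowledgment
    with an unknown control id is logged and ignored.
    """
    now = _now(now)

    if isinstance(event, Docked):
        if state.phase is not DevicePhase.UNDOCKED:
            return TransitionOutcome(state, (Log("already docked"),))
        hello = HelloPayload(
            device_serial=state.device_serial,
            vendor_name=state.vendor_name,
            model_name=state.model_name,
        )
        msg, cid = _device_msg(state, MessageType.HELLO, hello, now)
        return TransitionOutcome(
            replace(state, phase=DevicePhase.HELLO_SENT, control_counter=cid),
            (Send(msg),),
        )

    if isinstance(event, Timeout):
        if state.phase is DevicePhase.SENDING:
            return _fail_and_terminate(state, now, "acknowledgment timeout")
        return TransitionOutcome(
            replace(state, phase=DevicePhase.TERMINATED),
            (Log("session timeout"), Close()),
        )

    if not isinstance(event, Message):
        return TransitionOutcome(state, (Log(f"ignoring event {event!r}"),))

    mtype = event.header.message_type
    if mtype is MessageType.TERMINATE:
        outcome_phase = (
            DevicePhase.DRAINED if state.phase is DevicePhase.DRAINED
            else DevicePhase.TERMINATED
        )
        return TransitionOutcome(replace(state, phase=outcome_phase), (Close(),))

    if mtype is not MessageType.ACK:
        return TransitionOutcome(
            state, (Log(f"ignoring unexpected {mtype.value} from manager"),)
        )

    assert isinstance(event.payload, AckPayload)
    ack = event.payload

    if state.phase is DevicePhase.HELLO_SENT:
        if ack.ack_type is AckType.ACCEPT:
            status = DeviceStatusPayload(
                condition=DeviceCondition.READY,
                new_observations_qty=len(state.queue),
            )
            msg, cid = _device_msg(state, MessageType.DEVICE_STATUS, status, now)
            return TransitionOutcome(
                replace(state, phase=DevicePhase.STATUS_SENT, control_counter=cid),
                (Send(msg),),
            )
        return _fail_and_terminate(state, now, "hello rejected")

    if state.phase is DevicePhase.STATUS_SENT:
        if ack.ack_type is AckType.ACCEPT:
            return _send_next_or_finish(state, now)
        return _fail_and_terminate(state, now, "status rejected")

    if state.phase is DevicePhase.SENDING:
        if state.in_flight is None or ack.ack_control_id != state.in_flight[1]:
            return TransitionOutcome(
                state,
                (Log(f"ignoring ack with unknown control id {ack.ack_control_id}"),),
            )
        record, _ = state.in_flight
        if ack.ack_type is AckType.ACCEPT:
            state = replace(
                state,
                in_flight=None,
                ui_log=state.ui_log + (SUCCESSFUL_TRANSMIT,),
            )
            return _send_next_or_finish(
                state, now,
                extra_actions=(Log(f"{SUCCESSFUL_TRANSMIT}: {record.result_id}"),),
            )
        return _fail_and_terminate(
            state, now, f"record {record.result_id} acknowledged {ack.ack_type.value}"
        )

    return TransitionOutcome(state, (Log(f"ignoring ack in phase {state.phase.value}"),))


# ---------------------------------------------------------------------------
# session runners over a transport
# ---------------------------------------------------------------------------


class Transport(Protocol):
    """Ordered reliable byte stream (satisfied by ``socket.socket``)."""

    def recv(self, bufsize: int) -> bytes: ...
    def sendall(self, data: bytes) -> None: ...
    def settimeout(self, value: Optional[float]) -> None: ...
    def close(self) -> None: ...


@dataclass
class SessionConfig:
    panels: Mapping[str, CartridgePanel]
    ack_timeout_s: float = 10.0
    max_message_bytes: int = 1 << 20
    recv_bufsize: int = 4096


@dataclass
class SessionReport:
    records_persisted: int = 0
    records_acked: int = 0
    errors: list[str] = field(default_factory=list)
    final_phase: Optional[str] = None


class _SessionEnd(Exception):
    pass


def run_manager_session(
    transport: Transport, sink: ResultSink, config: SessionConfig
) -> SessionReport:
    """Serve one inbound device conversation to completion.

    Frames the byte stream, drives :func:`manager_transition`, persists each
    observations message through ``sink`` and acknowledges according to the
    receipt.  ``records_acked`` equals the number of results that were
    durably persisted; on a framing/parse error the session is aborted and
    the partial report returned.
    """
    report = SessionReport()
    state = ManagerState()
    splitter = StreamSplitter(config.max_message_bytes)
    transport.settimeout(config.ack_timeout_s)

    def execute(outcome: TransitionOutcome) -> None:
        # commit the successor state before side effects so a Close (which
        # unwinds via _SessionEnd) cannot discard the final transition
        nonlocal state
        assert isinstance(outcome.new_state, ManagerState)
        state = outcome.new_state
        for action in outcome.actions:
            if isinstance(action, Send):
                transport.sendall(serialize_message(action.message))
            elif isinstance(action, Persist):
                try:
                    meta, row = flatten_result(
                        action.payload, config.panels, vendor_name=state.peer_vendor
                    )
                    receipt = sink.persist(meta, row)
                    success, detail = receipt.ok, receipt.detail
                except Exception as exc:  # mapping errors etc.
                    success, detail = False, str(exc)
                if success:
                    report.records_persisted += 1
                    report.records_acked += 1
                else:
                    report.errors.append(
                        f"persist failed for {action.payload.result_id}: {detail}"
                    )
                execute(manager_transition(state, PersistResult(success, detail)))
            elif isinstance(action, Log):
                logger.info("%s", action.text)
            elif isinstance(action, Close):
                try:
                    transport.close()
                finally:
                    raise _SessionEnd

    try:
        while True:
            try:
                data = transport.recv(config.recv_bufsize)
            except TimeoutError:
                execute(manager_transition(state, Timeout()))
                continue
            if not data:
                break
            try:
                docs = splitter.feed(data)
            except FramingError as exc:
                report.errors.append(f"framing error: {exc}")
                break
            for doc in docs:
                try:
                    msg = parse_message(doc)
                except ParseError as exc:
                    report.errors.append(f"parse error: {exc}")
                    raise _SessionEnd
                execute(manager_transition(state, msg))
    except _SessionEnd:
        pass
    finally:
        try:
            transport.close()
        except OSError:
            pass
    report.final_phase = state.phase.value
    return report


def run_device_session(
    transport: Transport, device_state: DeviceState, config: SessionConfig
) -> DeviceState:
    """Run one device-side conversation; returns the post-session state.

    Retained records (acknowledgment withheld, rejected, or transport loss)
    remain in the returned state's queue, and the UI log carries the
    "Successful Transmit" / "Failed Transmit" notifications.
    """
    state = device_state
    splitter = StreamSplitter(config.max_message_bytes)
    transport.settimeout(config.ack_timeout_s)

    def execute(outcome: TransitionOutcome) -> None:
        nonlocal state
        assert isinstance(outcome.new_state, DeviceState)
        state = outcome.new_state
        for action in outcome.actions:
            if isinstance(action, Send):
                transport.sendall(serialize_message(action.message))
            elif isinstance(action, Log):
                logger.info("%s", action.text)
            elif isinstance(action, Close):
                try:
                    transport.close()
                finally:
                    raise _SessionEnd

    try:
        execute(device_transition(state, Docked()))
        while state.phase not in (DevicePhase.DRAINED, DevicePhase.TERMINATED):
            try:
                data = transport.recv(config.recv_bufsize)
            except TimeoutError:
                execute(device_transition(state, Timeout()))
                continue
            if not data:
                # transport loss: same consequence as a missing ack
                execute(device_transition(state, Timeout()))
                break
            for doc in splitter.feed(data):
                execute(device_transition(state, parse_message(doc)))
    except _SessionEnd:
        pass
    except (ConnectionError, OSError) as exc:
        state = device_transition(state, Timeout()).new_state  # type: ignore[assignment]
        logger.info("transport error: %s", exc)
    finally:
        try:
            transport.close()
        except OSError:
            pass
    return state


def serve(
    host: str,
    port: int,
    sink: ResultSink,
    config: SessionConfig,
    max_sessions: Optional[int] = None,
    ready_callback=None,
    accept_timeout_s: Optional[float] = None,
) -> list[SessionReport]:
    """Listen for device connections and serve sessions one at a time.

    ``max_sessions`` bounds the number of accepted connections (None = until
    interrupted); accepting stops after ``accept_timeout_s`` idle seconds
    (defaults to the session acknowledgment timeout).  ``ready_callback``
    fires with the bound port once listening, which tests use to learn an
    ephemeral port.
    """
    reports: list[SessionReport] = []
    with socket.create_server((host, port)) as server:
        server.settimeout(
            config.ack_timeout_s if accept_timeout_s is None else accept_timeout_s
        )
        if ready_callback is not None:
            ready_callback(server.getsockname()[1])
        n = 0
        while max_sessions is None or n < max_sessions:
            try:
                conn, addr = server.accept()
            except TimeoutError:
                break
            logger.info("connection from %s", addr)
            reports.append(run_manager_session(conn, sink, config))
            n += 1
    return reports


def connect_and_run_device(
    host: str, port: int, state: DeviceState, config: SessionConfig
) -> DeviceState:
    """Dial the data manager and run one device session.

    An unreachable manager leaves the queue intact and logs the failure.
    """
    try:
        sock = socket.create_connection((host, port), timeout=config.ack_timeout_s)
    except OSError as exc:
        logger.info("connection failed: %s", exc)
        return state.logged(f"connection failed: {exc}")
    return run_device_session(sock, state, config)
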