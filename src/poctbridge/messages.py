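"""POCT1-A-style XML message dialect: typed messages, serialization, parsing, framing.

The conversation between a point-of-care analyzer and a data manager is a
stream of small XML documents over one TCP connection.  Six message types are
exchanged:

========  =======================  =========================================
Code      Name                     Direction / purpose
========  =======================  =========================================
HEL.R01   Hello                    device -> manager, opens the conversation
ACK.R01   Acknowledgment           either direction, references control_id
DST.R01   Device status            device -> manager, unsent-queue depth
OBS.R01   Observations             device -> manager, one cartridge result
EOT.R01   End of topic             device -> manager, no more observations
END.R01   Terminate                either direction, closes the session
========  =======================  =========================================

Every document's root element is the message-type code.  A ``HDR`` child
carries the header fields; payload fields are leaf elements whose value is in
a ``V`` attribute (the convention used by POCT1-A device dialects).  Analyte
values travel as decimal *strings* end to end so that what the sink stores is
byte-identical to what the device measured.

See ``docs/protocol.md`` for one annotated example per message type.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from datetime import date, datetime, timezone
from decimal import Decimal, InvalidOperation
from enum import Enum
from typing import Iterable, Iterator, Optional, Sequence, Union

from lxml import etree

__all__ = [
    "MessageType",
    "AckType",
    "DeviceCondition",
    "ObservationStatus",
    "MessageHeader",
    "HelloPayload",
    "AckPayload",
    "DeviceStatusPayload",
    "Observation",
    "ObservationsPayload",
    "SimplePayload",
    "Message",
    "SerializationError",
    "ParseError",
    "UnsupportedMessageError",
    "ValidationError",
    "FramingError",
    "SenderCounter",
    "next_control_id",
    "serialize_message",
    "parse_message",
    "StreamSplitter",
    "split_stream",
    "MAX_MESSAGE_BYTES",
    "TIMESTAMP_FORMAT",
    "PROTOCOL_VERSION",
]

PROTOCOL_VERSION = "POCT1"
TIMESTAMP_FORMAT = "%Y-%m-%dT%H:%M:%S"
#: Framing aborts the session if a single document exceeds this many bytes.
MAX_MESSAGE_BYTES = 1 << 20


class MessageType(str, Enum):
    HELLO = "HEL.R01"
    ACK = "ACK.R01"
    DEVICE_STATUS = "DST.R01"
    OBSERVATIONS = "OBS.R01"
    END_OF_TOPIC = "EOT.R01"
    TERMINATE = "END.R01"


class AckType(str, Enum):
    ACCEPT = "AA"
    ERROR = "AE"
    REJECT = "AR"


class DeviceCondition(str, Enum):
    READY = "READY"
    BUSY = "BUSY"
    FAULT = "FAULT"


class ObservationStatus(str, Enum):
    NORMAL = "NORMAL"
    OUT_OF_RANGE = "OUT_OF_RANGE"
    SUPPRESSED = "SUPPRESSED"


class SerializationError(ValueError):
    """A message violates an invariant and cannot be serialized."""


class ParseError(ValueError):
    """Input is not a well-formed document of this dialect."""


class UnsupportedMessageError(ParseError):
    """Well-formed XML whose root element is not a known message code."""


class ValidationError(ParseError):
    """A known message missing a required element or carrying a bad value."""


class FramingError(RuntimeError):
    """The byte stream cannot be split into documents (session abort)."""


# ---------------------------------------------------------------------------
# header and payload types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MessageHeader:
    """Common header: type code, per-sender sequence number, timestamp."""

    message_type: MessageType
    control_id: int
    creation_time: datetime
    version_id: str = PROTOCOL_VERSION

    def validate(self) -> None:
        if self.control_id < 1:
            raise SerializationError("control_id must be >= 1")
        if not isinstance(self.creation_time, datetime):
            raise SerializationError("creation_time must be a datetime")


@dataclass(frozen=True)
class HelloPayload:
    device_serial: str
    vendor_name: str = ""
    model_name: str = ""
    application_version: Optional[str] = None
    supported_topics: tuple[str, ...] = ("OBSERVATIONS",)

    def validate(self) -> None:
        if not self.device_serial:
            raise SerializationError("device_serial must be non-empty")


@dataclass(frozen=True)
class AckPayload:
    ack_control_id: int
    ack_type: AckType
    note: Optional[str] = None

    def validate(self) -> None:
        if self.ack_control_id < 1:
            raise SerializationError("ack_control_id must be >= 1")


@dataclass(frozen=True)
class DeviceStatusPayload:
    condition: DeviceCondition
    new_observations_qty: int

    def validate(self) -> None:
        if self.new_observations_qty < 0:
            raise SerializationError("new_observations_qty must be >= 0")


@dataclass(frozen=True)
class Observation:
    """One analyte measurement within a cartridge result."""

    observation_id: str
    value: str
    units: str
    status: ObservationStatus = ObservationStatus.NORMAL

    def validate(self) -> None:
        try:
            dec = Decimal(self.value)
        except InvalidOperation:
            raise SerializationError(
                f"observation {self.observation_id!r}: value {self.value!r} "
                "is not a decimal"
            ) from None
        if not dec.is_finite():
            raise SerializationError(
                f"observation {self.observation_id!r}: value must be finite"
            )


@dataclass(frozen=True)
class ObservationsPayload:
    """One cartridge run: identity, cartridge metadata, analyte observations."""

    result_id: str
    observation_time: datetime
    cartridge_name: str
    lot_number: str
    expiration_date: date
    device_serial: str
    observations: tuple[Observation, ...]
    operator_id: Optional[str] = None
    patient_or_subject_id: Optional[str] = None

    def validate(self) -> None:
        if not self.result_id:
            raise SerializationError("result_id must be non-empty")
        if not self.observations:
            raise SerializationError("observations must be non-empty")
        for obs in self.observations:
            obs.validate()


@dataclass(frozen=True)
class SimplePayload:
    """Payload of EOT.R01 and END.R01: an optional free-text reason."""

    reason: Optional[str] = None

    def validate(self) -> None:  # nothing to check
        return


Payload = Union[
    HelloPayload, AckPayload, DeviceStatusPayload, ObservationsPayload, SimplePayload
]

_PAYLOAD_KIND: dict[MessageType, type] = {
    MessageType.HELLO: HelloPayload,
    MessageType.ACK: AckPayload,
    MessageType.DEVICE_STATUS: DeviceStatusPayload,
    MessageType.OBSERVATIONS: ObservationsPayload,
    MessageType.END_OF_TOPIC: SimplePayload,
    MessageType.TERMINATE: SimplePayload,
}


@dataclass(frozen=True)
class Message:
    header: MessageHeader
    payload: Payload

    def validate(self) -> None:
        self.header.validate()
        expected = _PAYLOAD_KIND[self.header.message_type]
        if type(self.payload) is not expected:
            raise SerializationError(
                f"payload kind {type(self.payload).__name__} does not match "
                f"message_type {self.header.message_type.value}"
            )
        self.payload.validate()


# ---------------------------------------------------------------------------
# control-id sequencing
# ---------------------------------------------------------------------------


@dataclass
class SenderCounter:
    """Per-session monotone counter for one sender's control ids."""

    value: int = 0


def next_control_id(counter: SenderCounter) -> int:
    """Advance ``counter`` and return the next control id (strictly increasing)."""
    counter.value += 1
    return counter.value


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def _leaf(parent: etree._Element, name: str, value: str) -> None:
    etree.SubElement(parent, name).set("V", value)


def _format_dt(dt: datetime) -> str:
    if dt.tzinfo is not None:
        dt = dt.astimezone(timezone.utc).replace(tzinfo=None)
    return dt.strftime(TIMESTAMP_FORMAT)


def serialize_message(msg: Message) -> bytes:
    """Render ``msg`` as one complete UTF-8 XML document.

    The root element name is the message-type code; output is deterministic
    for a fixed message.  Raises :class:`SerializationError` naming the
    offending field if an invariant is violated.
    """
    msg.validate()
    root = etree.Element(msg.header.message_type.value)
    hdr = etree.SubElement(root, "HDR")
    _leaf(hdr, "control_id", str(msg.header.control_id))
    _leaf(hdr, "version_id", msg.header.version_id)
    _leaf(hdr, "creation_time", _format_dt(msg.header.creation_time))

    p = msg.payload
    if isinstance(p, HelloPayload):
        dev = etree.SubElement(root, "DEV")
        _leaf(dev, "device_serial", p.device_serial)
        _leaf(dev, "vendor_name", p.vendor_name)
        _leaf(dev, "model_name", p.model_name)
        if p.application_version is not None:
            _leaf(dev, "application_version", p.application_version)
        topics = etree.SubElement(dev, "TOPICS")
        for t in p.supported_topics:
            _leaf(topics, "topic", t)
    elif isinstance(p, AckPayload):
        ack = etree.SubElement(root, "ACK")
        _leaf(ack, "ack_control_id", str(p.ack_control_id))
        _leaf(ack, "ack_type", p.ack_type.value)
        if p.note is not None:
            _leaf(ack, "note", p.note)
    elif isinstance(p, DeviceStatusPayload):
        st = etree.SubElement(root, "STATUS")
        _leaf(st, "condition", p.condition.value)
        _leaf(st, "new_observations_qty", str(p.new_observations_qty))
    elif isinstance(p, ObservationsPayload):
        svc = etree.SubElement(root, "SVC")
        _leaf(svc, "result_id", p.result_id)
        _leaf(svc, "observation_time", _format_dt(p.observation_time))
        if p.operator_id is not None:
            _leaf(svc, "operator_id", p.operator_id)
        if p.patient_or_subject_id is not None:
            _leaf(svc, "patient_or_subject_id", p.patient_or_subject_id)
        cart = etree.SubElement(svc, "CART")
        _leaf(cart, "cartridge_name", p.cartridge_name)
        _leaf(cart, "lot_number", p.lot_number)
        _leaf(cart, "expiration_date", p.expiration_date.isoformat())
        _leaf(cart, "device_serial", p.device_serial)
        for obs in p.observations:
            el = etree.SubElement(svc, "OBS")
            _leaf(el, "observation_id", obs.observation_id)
            _leaf(el, "value", obs.value)
            _leaf(el, "units", obs.units)
            _leaf(el, "status", obs.status.value)
    elif isinstance(p, SimplePayload):
        if p.reason is not None:
            _leaf(root, "NOTE", p.reason)

    return etree.tostring(
        root, xml_declaration=True, encoding="UTF-8", pretty_print=False
    )


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------


def _get_leaf(parent: etree._Element, name: str, required: bool = True) -> Optional[str]:
    el = parent.find(name)
    if el is None:
        if required:
            raise ValidationError(f"missing required element {name!r}")
        return None
    v = el.get("V")
    if v is None:
        raise ValidationError(f"element {name!r} has no V attribute")
    return v


def _child(parent: etree._Element, name: str) -> etree._Element:
    el = parent.find(name)
    if el is None:
        raise ValidationError(f"missing required element {name!r}")
    return el


def _parse_dt(text: str, what: str) -> datetime:
    try:
        return datetime.strptime(text, TIMESTAMP_FORMAT)
    except ValueError:
        raise ValidationError(f"{what}: bad timestamp {text!r}") from None


def _parse_int(text: str, what: str) -> int:
    try:
        return int(text)
    except ValueError:
        raise ValidationError(f"{what}: not an integer: {text!r}") from None


def _parse_enum(enum_cls, text: str, what: str):
    try:
        return enum_cls(text)
    except ValueError:
        raise ValidationError(f"{what}: unknown code {text!r}") from None


def parse_message(xml_text: Union[str, bytes]) -> Message:
    """Parse one complete XML document into a typed :class:`Message`.

    Unknown optional elements are ignored; missing required elements raise a
    :class:`ValidationError` naming the element.
    """
    if isinstance(xml_text, str):
        xml_text = xml_text.encode("utf-8")
    try:
        root = etree.fromstring(xml_text)
    except etree.XMLSyntaxError as exc:
        raise ParseError(f"malformed XML: {exc}") from None

    try:
        mtype = MessageType(root.tag)
    except ValueError:
        raise UnsupportedMessageError(f"unknown root element {root.tag!r}") from None

    hdr = _child(root, "HDR")
    header = MessageHeader(
        message_type=mtype,
        control_id=_parse_int(_get_leaf(hdr, "control_id"), "HDR/control_id"),
        version_id=_get_leaf(hdr, "version_id"),
        creation_time=_parse_dt(_get_leaf(hdr, "creation_time"), "HDR/creation_time"),
    )

    payload: Payload
    if mtype is MessageType.HELLO:
        dev = _child(root, "DEV")
        topics_el = dev.find("TOPICS")
        topics: tuple[str, ...] = ()
        if topics_el is not None:
            topics = tuple(
                t.get("V", "") for t in topics_el.findall("topic")
            )
        payload = HelloPayload(
            device_serial=_get_leaf(dev, "device_serial"),
            vendor_name=_get_leaf(dev, "vendor_name", required=False) or "",
            model_name=_get_leaf(dev, "model_name", required=False) or "",
            application_version=_get_leaf(dev, "application_version", required=False),
            supported_topics=topics,
        )
    elif mtype is MessageType.ACK:
        ack = _child(root, "ACK")
        payload = AckPayload(
            ack_control_id=_parse_int(
                _get_leaf(ack, "ack_control_id"), "ACK/ack_control_id"
            ),
            ack_type=_parse_enum(AckType, _get_leaf(ack, "ack_type"), "ACK/ack_type"),
            note=_get_leaf(ack, "note", required=False),
        )
    elif mtype is MessageType.DEVICE_STATUS:
        st = _child(root, "STATUS")
        payload = DeviceStatusPayload(
            condition=_parse_enum(
                DeviceCondition, _get_leaf(st, "condition"), "STATUS/condition"
            ),
            new_observations_qty=_parse_int(
                _get_leaf(st, "new_observations_qty"), "STATUS/new_observations_qty"
            ),
        )
    elif mtype is MessageType.OBSERVATIONS:
        svc = _child(root, "SVC")
        cart = _child(svc, "CART")
        obs_list = []
        for el in svc.findall("OBS"):
            obs_list.append(
                Observation(
                    observation_id=_get_leaf(el, "observation_id"),
                    value=_get_leaf(el, "value"),
                    units=_get_leaf(el, "units"),
                    status=_parse_enum(
                        ObservationStatus, _get_leaf(el, "status"), "OBS/status"
                    ),
                )
            )
        try:
            exp = date.fromisoformat(_get_leaf(cart, "expiration_date"))
        except ValueError:
            raise ValidationError("CART/expiration_date: bad date") from None
        payload = ObservationsPayload(
            result_id=_get_leaf(svc, "result_id"),
            observation_time=_parse_dt(
                _get_leaf(svc, "observation_time"), "SVC/observation_time"
            ),
            operator_id=_get_leaf(svc, "operator_id", required=False),
            patient_or_subject_id=_get_leaf(
                svc, "patient_or_subject_id", required=False
            ),
            cartridge_name=_get_leaf(cart, "cartridge_name"),
            lot_number=_get_leaf(cart, "lot_number"),
            expiration_date=exp,
            device_serial=_get_leaf(cart, "device_serial"),
            observations=tuple(obs_list),
        )
    else:  # EOT.R01 / END.R01
        note = root.find("NOTE")
        payload = SimplePayload(reason=note.get("V") if note is not None else None)

    msg = Message(header=header, payload=payload)
    try:
        msg.validate()
    except SerializationError as exc:
        raise ValidationError(str(exc)) from None
    return msg


# ---------------------------------------------------------------------------
# stream framing
# ---------------------------------------------------------------------------

_WS = b" \t\r\n"
# structural characters inside an unquoted start tag
_TAG_STRUCTURAL = re.compile(rb"[>\"'/]")


class StreamSplitter:
    """Incrementally split a byte stream into complete top-level XML documents.

    Documents are delimited by root-element completion (tag-depth tracking),
    not length prefixes; inter-document whitespace is tolerated.  Output is
    independent of how the byte stream is chunked: feed bytes in any pieces
    and each complete document is emitted exactly once, in order, as soon as
    its root element closes.

    Only the constructs this dialect can emit plus comments, CDATA sections
    and processing instructions are recognized; anything else outside a
    document raises :class:`FramingError`.
    """

    # scanner modes
    _OUT = 0        # between documents
    _TEXT = 1       # inside a document, between tags
    _LT = 2         # just saw '<', kind unknown
    _START_TAG = 3  # inside a start/empty-element tag
    _END_TAG = 4    # inside an end tag
    _BANG = 5       # saw '<!', disambiguating comment / CDATA / doctype
    _COMMENT = 6
    _CDATA = 7
    _PI = 8
    _DOCTYPE = 9
    _OUT_DECL = 10  # after a depth-0 XML declaration, awaiting the root tag

    def __init__(self, max_message_bytes: int = MAX_MESSAGE_BYTES) -> None:
        self.max_message_bytes = max_message_bytes
        self._buf = bytearray()
        self._mode = self._OUT
        self._depth = 0
        self._quote: Optional[int] = None  # active quote byte inside a tag
        self._lookback = bytearray()       # partial marker bytes for _BANG etc.
        self._tail = bytearray()           # recent bytes to detect -->, ]]>, ?>
        self._empty_tag = False            # '/' seen just before '>' in a tag

    def feed(self, chunk: bytes) -> list[bytes]:
        """Consume a chunk; return any documents completed by it.

        Runs of non-structural bytes (text content, attribute names, quoted
        attribute values) are consumed in bulk; only structural characters
        go through the per-byte state machine.
        """
        out: list[bytes] = []
        i, n = 0, len(chunk)
        while i < n:
            m = self._mode
            if m == self._TEXT or m == self._OUT:
                j = chunk.find(b"<", i)
                seg = chunk[i:j] if j >= 0 else chunk[i:]
                if m == self._OUT:
                    if seg.strip(_WS):
                        raise FramingError("unexpected bytes between documents")
                    if j >= 0:
                        self._buf = bytearray(b"<")
                else:
                    self._append_bulk(seg)
                    if j >= 0:
                        self._buf += b"<"
                if j < 0:
                    break
                self._mode = self._LT
                i = j + 1
            elif m == self._LT:
                # disambiguate the tag kind directly
                b = chunk[i]
                self._buf.append(b)
                i += 1
                if b == 0x2F:
                    self._mode = self._END_TAG
                elif b == 0x3F:
                    self._mode = self._PI
                    self._tail.clear()
                elif b == 0x21:
                    self._mode = self._BANG
                    self._lookback.clear()
                else:
                    self._mode = self._START_TAG
                    self._quote = None
                    self._empty_tag = False
            elif m == self._START_TAG:
                if self._quote is not None:
                    j = chunk.find(bytes((self._quote,)), i)
                    if j < 0:
                        self._append_bulk(chunk[i:])
                        break
                    self._append_bulk(chunk[i : j + 1])
                    self._quote = None
                    i = j + 1
                    continue
                match = _TAG_STRUCTURAL.search(chunk, i)
                if match is None:
                    self._append_bulk(chunk[i:])
                    break
                j = match.start()
                b = chunk[j]
                self._append_bulk(chunk[i:j])
                i = j + 1
                if b == 0x3E:  # >
                    doc = self._step(b)
                    if doc is not None:
                        out.append(doc)
                elif b == 0x2F:  # /
                    self._buf.append(b)
                    self._empty_tag = True
                else:  # opening quote
                    self._buf.append(b)
                    self._quote = b
            elif m == self._END_TAG:
                j = chunk.find(b">", i)
                if j < 0:
                    self._append_bulk(chunk[i:])
                    break
                self._append_bulk(chunk[i:j])
                doc = self._step(0x3E)
                if doc is not None:
                    out.append(doc)
                i = j + 1
            else:
                # rare modes (comments, CDATA, PIs, declarations): per byte
                doc = self._step(chunk[i])
                if doc is not None:
                    out.append(doc)
                i += 1
        return out

    def _append_bulk(self, seg: bytes) -> None:
        if not seg:
            return
        self._buf += seg
        if len(self._buf) > self.max_message_bytes:
            raise FramingError(f"message exceeds {self.max_message_bytes} bytes")
        # a '/' only marks an empty-element tag when immediately before '>';
        # any other byte after it cancels that reading
        if self._empty_tag and seg.strip(_WS):
            self._empty_tag = False

    def close(self) -> None:
        """Signal end of stream; raises if a document is left incomplete."""
        if self._mode != self._OUT or self._buf.strip(_WS):
            raise FramingError("stream ended mid-document")

    # -- internals ----------------------------------------------------------

    def _step(self, b: int) -> Optional[bytes]:
        self._buf.append(b)
        if len(self._buf) > self.max_message_bytes:
            raise FramingError(
                f"message exceeds {self.max_message_bytes} bytes"
            )
        m = self._mode

        if m == self._OUT:
            if b == 0x3C:  # <
                # discard inter-document whitespace already buffered
                self._buf = bytearray(b"<")
                self._mode = self._LT
            elif b not in _WS:
                raise FramingError(
                    f"unexpected byte {bytes([b])!r} between documents"
                )
            else:
                self._buf.clear()
            return None

        if m == self._OUT_DECL:
            # like _OUT, but the buffered '<?xml ...?>' bytes are retained
            # so they stay attached to the document that follows
            if b == 0x3C:
                self._mode = self._LT
            elif b not in _WS:
                raise FramingError(
                    f"unexpected byte {bytes([b])!r} after XML declaration"
                )
            return None

        if m == self._TEXT:
            if b == 0x3C:
                self._mode = self._LT
            return None

        if m == self._LT:
            if b == 0x2F:  # /
                self._mode = self._END_TAG
            elif b == 0x3F:  # ?
                self._mode = self._PI
                self._tail.clear()
            elif b == 0x21:  # !
                self._mode = self._BANG
                self._lookback.clear()
            else:
                self._mode = self._START_TAG
                self._quote = None
                self._empty_tag = False
            return None

        if m == self._START_TAG:
            if self._quote is not None:
                if b == self._quote:
                    self._quote = None
                return None
            if b in (0x22, 0x27):  # " '
                self._quote = b
            elif b == 0x2F:
                self._empty_tag = True
            elif b == 0x3E:  # >
                if not self._empty_tag:
                    self._depth += 1
                    self._mode = self._TEXT
                    return None
                # self-closing: depth unchanged
                self._empty_tag = False
                return self._tag_closed()
            elif self._empty_tag and b not in _WS:
                self._empty_tag = False
            return None

        if m == self._END_TAG:
            if b == 0x3E:
                self._depth -= 1
                if self._depth < 0:
                    raise FramingError("unbalanced end tag")
                return self._tag_closed()
            return None

        if m == self._BANG:
            self._lookback.append(b)
            lb = bytes(self._lookback)
            if lb == b"--":
                self._mode = self._COMMENT
                self._tail.clear()
            elif lb == b"[CDATA[":
                self._mode = self._CDATA
                self._tail.clear()
            elif not (b"--".startswith(lb) or b"[CDATA[".startswith(lb)):
                self._mode = self._DOCTYPE
            return None

        if m == self._COMMENT:
            self._tail.append(b)
            del self._tail[:-3]
            if bytes(self._tail) == b"-->":
                self._mode = self._TEXT if self._depth > 0 else self._OUT
            return None

        if m == self._CDATA:
            self._tail.append(b)
            del self._tail[:-3]
            if bytes(self._tail) == b"]]>":
                self._mode = self._TEXT
            return None

        if m == self._PI:
            self._tail.append(b)
            del self._tail[:-2]
            if bytes(self._tail) == b"?>":
                # a depth-0 declaration/PI belongs to the coming document
                self._mode = self._TEXT if self._depth > 0 else self._OUT_DECL
            return None

        if m == self._DOCTYPE:
            if b == 0x3E:
                self._mode = self._TEXT if self._depth > 0 else self._OUT
            return None

        raise AssertionError(f"bad mode {m}")

    def _tag_closed(self) -> Optional[bytes]:
        if self._depth == 0:
            doc = bytes(self._buf)
            self._buf.clear()
            self._mode = self._OUT
            return doc
        self._mode = self._TEXT
        return None


def split_stream(byte_chunks: Iterable[bytes]) -> list[bytes]:
    """Split chunked bytes into complete XML documents (chunk-invariant).

    Convenience wrapper over :class:`StreamSplitter` for fully-buffered input.
    """
    splitter = StreamSplitter()
    docs: list[bytes] = []
    for chunk in byte_chunks:
        docs.extend(splitter.feed(chunk))
    return docs
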