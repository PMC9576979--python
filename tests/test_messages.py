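"""Message dialect: round-trips, determinism, framing, sequencing."""

from __future__ import annotations

from datetime import date, datetime
from decimal import Decimal

import pytest
from hypothesis import given, settings, strategies as st
from lxml import etree

from poctbridge.messages import (
    AckPayload,
    AckType,
    DeviceCondition,
    DeviceStatusPayload,
    FramingError,
    HelloPayload,
    Message,
    MessageHeader,
    MessageType,
    Observation,
    ObservationsPayload,
    ObservationStatus,
    ParseError,
    SenderCounter,
    SerializationError,
    SimplePayload,
    StreamSplitter,
    UnsupportedMessageError,
    ValidationError,
    next_control_id,
    parse_message,
    serialize_message,
    split_stream,
)
from conftest import FIXED_NOW, make_ack, make_cg4_payload

# --- hypothesis strategies -------------------------------------------------

# XML 1.0 cannot carry most control characters; surrogates are not unicode text
_text = st.text(
    alphabet=st.characters(blacklist_categories=("Cs", "Cc")),
    min_size=0, max_size=12,
)
_ident = st.text(
    alphabet=st.characters(whitelist_categories=("Lu", "Ll", "Nd")),
    min_size=1, max_size=12,
)
_dt = st.datetimes(
    min_value=datetime(2000, 1, 1), max_value=datetime(2099, 12, 31)
).map(lambda d: d.replace(microsecond=0))
_decimal_str = st.decimals(
    allow_nan=False, allow_infinity=False, places=2,
    min_value=Decimal("-10000"), max_value=Decimal("10000"),
).map(str)

_headers = st.builds(
    MessageHeader,
    message_type=st.just(MessageType.ACK),  # overwritten per payload below
    control_id=st.integers(min_value=1, max_value=10**6),
    creation_time=_dt,
)

_observations = st.builds(
    Observation,
    observation_id=_ident,
    value=_decimal_str,
    units=_text,
    status=st.sampled_from(ObservationStatus),
)

_payloads = st.one_of(
    st.builds(
        HelloPayload,
        device_serial=_ident,
        vendor_name=_text,
        model_name=_text,
        application_version=st.none() | _text,
        supported_topics=st.lists(_ident, max_size=3).map(tuple),
    ),
    st.builds(
        AckPayload,
        ack_control_id=st.integers(min_value=1, max_value=10**6),
        ack_type=st.sampled_from(AckType),
        note=st.none() | _text,
    ),
    st.builds(
        DeviceStatusPayload,
        condition=st.sampled_from(DeviceCondition),
        new_observations_qty=st.integers(min_value=0, max_value=500),
    ),
    st.builds(
        ObservationsPayload,
        result_id=_ident,
        observation_time=_dt,
        cartridge_name=st.sampled_from(["CG4", "CHEM8"]),
        lot_number=_ident,
        expiration_date=st.dates(date(2020, 1, 1), date(2099, 1, 1)),
        device_serial=_ident,
        observations=st.lists(_observations, min_size=1, max_size=5).map(tuple),
        operator_id=st.none() | _ident,
        patient_or_subject_id=st.none() | _ident,
    ),
    st.builds(SimplePayload, reason=st.none() | _text),
)

_PAYLOAD_TYPES = {
    HelloPayload: [MessageType.HELLO],
    AckPayload: [MessageType.ACK],
    DeviceStatusPayload: [MessageType.DEVICE_STATUS],
    ObservationsPayload: [MessageType.OBSERVATIONS],
    SimplePayload: [MessageType.END_OF_TOPIC, MessageType.TERMINATE],
}


@st.composite
def messages(draw) -> Message:
    payload = draw(_payloads)
    mtype = draw(st.sampled_from(_PAYLOAD_TYPES[type(payload)]))
    header = draw(_headers)
    return Message(
        header=MessageHeader(
            message_type=mtype,
            control_id=header.control_id,
            creation_time=header.creation_time,
        ),
        payload=payload,
    )


# --- round trips -----------------------------------------------------------


@settings(deadline=None, max_examples=200)
@given(messages())
def test_parse_serialize_round_trip(msg: Message):
    """parse(serialize(m)) structurally equals m for any valid message."""
    assert parse_message(serialize_message(msg)) == msg


@settings(deadline=None, max_examples=50)
@given(messages())
def test_serialization_is_deterministic(msg: Message):
    assert serialize_message(msg) == serialize_message(msg)


def test_ack_round_trip_carries_reference():
    doc = serialize_message(make_ack(control_id=1, ref=7))
    parsed = parse_message(doc)
    assert parsed.payload.ack_control_id == 7
    assert parsed.payload.ack_type is AckType.ACCEPT


def test_cg4_observations_document_has_13_observation_elements():
    payload = make_cg4_payload(n_obs=13)
    msg = Message(MessageHeader(MessageType.OBSERVATIONS, 3, FIXED_NOW), payload)
    root = etree.fromstring(serialize_message(msg))
    assert len(root.findall("SVC/OBS")) == 13
    obs = parse_message(serialize_message(msg)).payload.observations
    assert [o.observation_id for o in obs] == [
        o.observation_id for o in payload.observations
    ]


def test_observation_value_survives_as_exact_string():
    payload = make_cg4_payload(n_obs=4)
    lactate = payload.observations[3]
    assert lactate.observation_id == "lactate"
    msg = Message(MessageHeader(MessageType.OBSERVATIONS, 1, FIXED_NOW), payload)
    parsed = parse_message(serialize_message(msg))
    got = {o.observation_id: o.value for o in parsed.payload.observations}
    assert got["lactate"] == lactate.value  # byte-exact decimal string


# --- error handling --------------------------------------------------------


def test_malformed_xml_raises_parse_error():
    with pytest.raises(ParseError):
        parse_message(b"<ACK.R01><HDR>")


def test_unknown_root_element_raises_unsupported():
    with pytest.raises(UnsupportedMessageError):
        parse_message(b"<UNKNOWN.R01/>")


def test_missing_required_field_names_the_element():
    doc = (
        b"<ACK.R01><HDR><control_id V='1'/><version_id V='POCT1'/>"
        b"<creation_time V='2026-01-05T08:00:00'/></HDR>"
        b"<ACK><ack_type V='AA'/></ACK></ACK.R01>"
    )
    with pytest.raises(ValidationError, match="ack_control_id"):
        parse_message(doc)


def test_unknown_optional_elements_are_ignored():
    doc = (
        b"<ACK.R01><HDR><control_id V='1'/><version_id V='POCT1'/>"
        b"<creation_time V='2026-01-05T08:00:00'/><vendor_extra V='x'/></HDR>"
        b"<ACK><ack_control_id V='7'/><ack_type V='AA'/></ACK>"
        b"<TRAILER V='ignored'/></ACK.R01>"
    )
    assert parse_message(doc).payload.ack_control_id == 7


@pytest.mark.parametrize(
    "bad_msg, field",
    [
        (Message(MessageHeader(MessageType.ACK, 0, FIXED_NOW),
                 AckPayload(1, AckType.ACCEPT)), "control_id"),
        (Message(MessageHeader(MessageType.ACK, 1, FIXED_NOW),
                 AckPayload(0, AckType.ACCEPT)), "ack_control_id"),
        (Message(MessageHeader(MessageType.HELLO, 1, FIXED_NOW),
                 HelloPayload(device_serial="")), "device_serial"),
        (Message(MessageHeader(MessageType.ACK, 1, FIXED_NOW),
                 SimplePayload()), "payload kind"),
    ],
)
def test_serialization_errors_name_the_field(bad_msg, field):
    with pytest.raises(SerializationError, match=field):
        serialize_message(bad_msg)


def test_non_decimal_observation_value_rejected():
    obs = Observation("lactate", "not-a-number", "mmol/L")
    with pytest.raises(SerializationError, match="lactate"):
        obs.validate()


# --- stream framing --------------------------------------------------------


def _two_message_stream() -> tuple[bytes, bytes, bytes]:
    doc1 = serialize_message(make_ack(1, 7))
    doc2 = serialize_message(
        Message(MessageHeader(MessageType.OBSERVATIONS, 2, FIXED_NOW),
                make_cg4_payload())
    )
    return doc1, doc2, doc1 + b"\n" + doc2


def test_two_concatenated_documents_in_one_chunk():
    doc1, doc2, stream = _two_message_stream()
    assert split_stream([stream]) == [doc1, doc2]


def test_framing_is_invariant_under_every_chunking():
    """Splitting the byte stream at every possible boundary yields the same
    two documents."""
    doc1, doc2, stream = _two_message_stream()
    for cut in range(len(stream) + 1):
        assert split_stream([stream[:cut], stream[cut:]]) == [doc1, doc2]


def test_empty_input_yields_no_documents():
    assert split_stream([]) == []
    assert split_stream([b""]) == []


def test_interdocument_whitespace_tolerated_but_text_rejected():
    doc1, doc2, _ = _two_message_stream()
    assert split_stream([b"  \r\n", doc1, b"\t\n", doc2, b"\n"]) == [doc1, doc2]
    with pytest.raises(FramingError):
        split_stream([b"garbage", doc1])


def test_oversize_document_aborts_framing():
    doc1, _, _ = _two_message_stream()
    splitter = StreamSplitter(max_message_bytes=32)
    with pytest.raises(FramingError):
        splitter.feed(doc1)


def test_incomplete_document_detected_at_close():
    doc1, _, _ = _two_message_stream()
    splitter = StreamSplitter()
    splitter.feed(doc1[:-5])
    with pytest.raises(FramingError):
        splitter.close()


def test_splitter_handles_comments_and_self_closing_roots():
    docs = split_stream([b"<!-- liaison noise --><A.R01/>\n<B.R01><c/></B.R01>"])
    assert docs == [b"<A.R01/>", b"<B.R01><c/></B.R01>"]


# --- control-id sequencing -------------------------------------------------


def test_next_control_id_strictly_increasing():
    counter = SenderCounter()
    assert [next_control_id(counter) for _ in range(5)] == [1, 2, 3, 4, 5]
    counter = SenderCounter(41)
    assert next_control_id(counter) == 42
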