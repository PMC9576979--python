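"""Record sinks: flatten observation messages into database-shaped rows and
deliver them with idempotent, transactional semantics.

The storage model mirrors a small research database: one *metadata* table
(who/what/when of each cartridge run) plus one *analyte* table per cartridge
type, with a column per analyte.  ``result_id`` is both the foreign key and
the idempotency key — a retransmitted record is recognized and dropped, which
is what turns at-least-once retransmission on the device side into
exactly-once storage.

Two concrete sinks are provided: an append-only file sink (JSONL or CSV) and
an HTTP sink that POSTs token-authenticated flat records in the style of a
REDCap API import (form fields ``token``, ``content=record``, ``format=json``,
``data=<JSON array of rows>``).  A sink returns a :class:`DeliveryReceipt`;
``OK`` is only returned after a durable write, and the conversation layer
acknowledges a record to the device only on ``OK``.
"""

from __future__ import annotations

import csv
import io
import json
import os
import urllib.error
import urllib.parse
import urllib.request
from dataclasses import dataclass, field
from datetime import datetime, timezone
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Protocol, Sequence

from .messages import ObservationsPayload
from .panels import CartridgePanel

__all__ = [
    "DeliveryStatus",
    "DeliveryReceipt",
    "MetadataRow",
    "AnalyteRow",
    "flatten_result",
    "dedupe_filter",
    "deliver_file",
    "deliver_http",
    "ResultSink",
    "MemorySink",
    "FileSink",
    "HttpSink",
    "FlakySink",
]


class DeliveryStatus(str, Enum):
    OK = "OK"
    RETRYABLE_FAILURE = "RETRYABLE_FAILURE"
    PERMANENT_FAILURE = "PERMANENT_FAILURE"


@dataclass(frozen=True)
class DeliveryReceipt:
    status: DeliveryStatus
    detail: str = ""

    @property
    def ok(self) -> bool:
        return self.status is DeliveryStatus.OK


@dataclass(frozen=True)
class MetadataRow:
    """One row of the metadata table (all values pre-rendered as strings)."""

    result_id: str
    device_serial: str
    vendor_name: str
    cartridge_name: str
    lot_number: str
    expiration_date: str
    observation_time: str
    received_time: str

    def as_dict(self) -> dict[str, str]:
        return {"table": "metadata", **self.__dict__}


@dataclass(frozen=True)
class AnalyteRow:
    """One row of a per-cartridge analyte table.

    ``values`` holds a decimal string per panel analyte, in panel order;
    analytes absent from the transmitted payload are ``None`` (null column).
    """

    result_id: str
    cartridge_name: str
    values: Mapping[str, Optional[str]]

    def as_dict(self) -> dict[str, Optional[str]]:
        return {
            "table": self.cartridge_name.lower(),
            "result_id": self.result_id,
            **dict(self.values),
        }


class MappingError(ValueError):
    """The payload references a cartridge panel the sink does not know."""


def flatten_result(
    payload: ObservationsPayload,
    panels: Mapping[str, CartridgePanel],
    received_time: Optional[datetime] = None,
    vendor_name: str = "",
) -> tuple[MetadataRow, AnalyteRow]:
    """Flatten one observations payload into (metadata row, analyte row).

    The mapping is lossless: observation values are carried over as the exact
    decimal strings that were transmitted.  Panel analytes missing from the
    payload become null columns; observations not in the panel raise.
    """
    panel = panels.get(payload.cartridge_name)
    if panel is None:
        raise MappingError(f"unknown cartridge panel {payload.cartridge_name!r}")
    if received_time is None:
        received_time = datetime.now(timezone.utc).replace(tzinfo=None, microsecond=0)
    meta = MetadataRow(
        result_id=payload.result_id,
        device_serial=payload.device_serial,
        vendor_name=vendor_name,
        cartridge_name=payload.cartridge_name,
        lot_number=payload.lot_number,
        expiration_date=payload.expiration_date.isoformat(),
        observation_time=payload.observation_time.isoformat(timespec="seconds"),
        received_time=received_time.isoformat(timespec="seconds"),
    )
    by_id = {o.observation_id: o.value for o in payload.observations}
    unknown = set(by_id) - set(panel.analyte_ids)
    if unknown:
        raise MappingError(
            f"panel {panel.name}: unknown observation ids {sorted(unknown)}"
        )
    values = {oid: by_id.get(oid) for oid in panel.analyte_ids}
    return meta, AnalyteRow(
        result_id=payload.result_id, cartridge_name=panel.name, values=values
    )


def dedupe_filter(row: MetadataRow, seen_ids: set[str]) -> bool:
    """Return True (keep) for a fresh result_id, False (drop) for a repeat.

    ``seen_ids`` is the sink's persisted id set and is updated in place when
    the row is kept, making the filter idempotent.
    """
    if row.result_id in seen_ids:
        return False
    seen_ids.add(row.result_id)
    return True


# ---------------------------------------------------------------------------
# delivery functions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FileSinkConfig:
    directory: Path
    format: str = "jsonl"  # "jsonl" or "csv"


def _table_path(cfg: FileSinkConfig, table: str) -> Path:
    ext = "jsonl" if cfg.format == "jsonl" else "csv"
    return Path(cfg.directory) / f"{table}.{ext}"


def deliver_file(
    rows: Sequence[MetadataRow | AnalyteRow], cfg: FileSinkConfig
) -> DeliveryReceipt:
    """Append rows to per-table files, durably flushed before OK is returned.

    JSONL is the canonical format (append-safe during live sessions); CSV
    writes a header line on first use with columns in panel order.
    """
    try:
        Path(cfg.directory).mkdir(parents=True, exist_ok=True)
        for row in rows:
            d = row.as_dict()
            table = d.pop("table")
            path = _table_path(cfg, table)
            if cfg.format == "jsonl":
                line = json.dumps(d, separators=(",", ":")) + "\n"
                with open(path, "a", encoding="utf-8") as fh:
                    fh.write(line)
                    fh.flush()
                    os.fsync(fh.fileno())
            elif cfg.format == "csv":
                new = not path.exists() or path.stat().st_size == 0
                with open(path, "a", newline="", encoding="utf-8") as fh:
                    w = csv.DictWriter(fh, fieldnames=list(d))
                    if new:
                        w.writeheader()
                    w.writerow(d)
                    fh.flush()
                    os.fsync(fh.fileno())
            else:
                return DeliveryReceipt(
                    DeliveryStatus.PERMANENT_FAILURE,
                    f"unknown file format {cfg.format!r}",
                )
    except OSError as exc:
        return DeliveryReceipt(DeliveryStatus.RETRYABLE_FAILURE, str(exc))
    return DeliveryReceipt(DeliveryStatus.OK)


@dataclass(frozen=True)
class HttpEndpointConfig:
    url: str
    token: str
    timeout_s: float = 10.0


def deliver_http(
    rows: Sequence[MetadataRow | AnalyteRow], cfg: HttpEndpointConfig
) -> DeliveryReceipt:
    """POST rows to a REDCap-style record-import endpoint.

    2xx maps to OK, 5xx/timeouts to RETRYABLE_FAILURE, other 4xx to
    PERMANENT_FAILURE.  Never raises past the receipt; the token is never
    included in receipt details or logs.
    """
    body = urllib.parse.urlencode(
        {
            "token": cfg.token,
            "content": "record",
            "format": "json",
            "data": json.dumps([r.as_dict() for r in rows]),
        }
    ).encode("ascii")
    req = urllib.request.Request(
        cfg.url,
        data=body,
        headers={"Content-Type": "application/x-www-form-urlencoded"},
        method="POST",
    )
    try:
        with urllib.request.urlopen(req, timeout=cfg.timeout_s) as resp:
            status = resp.status
    except urllib.error.HTTPError as exc:
        status = exc.code
    except (urllib.error.URLError, TimeoutError, OSError) as exc:
        return DeliveryReceipt(DeliveryStatus.RETRYABLE_FAILURE, f"transport: {exc}")
    if 200 <= status < 300:
        return DeliveryReceipt(DeliveryStatus.OK, f"HTTP {status}")
    if status >= 500:
        return DeliveryReceipt(DeliveryStatus.RETRYABLE_FAILURE, f"HTTP {status}")
    return DeliveryReceipt(DeliveryStatus.PERMANENT_FAILURE, f"HTTP {status}")


# ---------------------------------------------------------------------------
# sink objects (what a conversation session persists into)
# ---------------------------------------------------------------------------


class ResultSink(Protocol):
    def persist(self, meta: MetadataRow, row: AnalyteRow) -> DeliveryReceipt: ...


class MemorySink:
    """In-memory sink with exactly-once semantics; handy for tests and state
    inspection."""

    def __init__(self) -> None:
        self.metadata: list[MetadataRow] = []
        self.analytes: list[AnalyteRow] = []
        self.seen_ids: set[str] = set()

    def persist(self, meta: MetadataRow, row: AnalyteRow) -> DeliveryReceipt:
        if not dedupe_filter(meta, self.seen_ids):
            return DeliveryReceipt(DeliveryStatus.OK, "duplicate dropped")
        self.metadata.append(meta)
        self.analytes.append(row)
        return DeliveryReceipt(DeliveryStatus.OK)


class FileSink:
    """Durable append-only sink over per-table JSONL/CSV files.

    Previously stored result ids are reloaded on construction so dedupe
    survives restarts.
    """

    def __init__(self, directory: str | Path, format: str = "jsonl") -> None:
        self.cfg = FileSinkConfig(directory=Path(directory), format=format)
        self.seen_ids: set[str] = set()
        self._load_seen_ids()

    def _load_seen_ids(self) -> None:
        path = _table_path(self.cfg, "metadata")
        if not path.exists():
            return
        if self.cfg.format == "jsonl":
            with open(path, encoding="utf-8") as fh:
                for line in fh:
                    line = line.strip()
                    if line:
                        self.seen_ids.add(json.loads(line)["result_id"])
        else:
            with open(path, newline="", encoding="utf-8") as fh:
                for rec in csv.DictReader(fh):
                    self.seen_ids.add(rec["result_id"])

    def persist(self, meta: MetadataRow, row: AnalyteRow) -> DeliveryReceipt:
        if not dedupe_filter(meta, self.seen_ids):
            return DeliveryReceipt(DeliveryStatus.OK, "duplicate dropped")
        receipt = deliver_file([meta, row], self.cfg)
        if not receipt.ok:
            # the write did not land; allow a future retry to keep it
            self.seen_ids.discard(meta.result_id)
        return receipt


class HttpSink:
    """Sink over a REDCap-style HTTP endpoint with in-process dedupe."""

    def __init__(self, cfg: HttpEndpointConfig) -> None:
        self.cfg = cfg
        self.seen_ids: set[str] = set()

    def persist(self, meta: MetadataRow, row: AnalyteRow) -> DeliveryReceipt:
        if not dedupe_filter(meta, self.seen_ids):
            return DeliveryReceipt(DeliveryStatus.OK, "duplicate dropped")
        receipt = deliver_http([meta, row], self.cfg)
        if not receipt.ok:
            self.seen_ids.discard(meta.result_id)
        return receipt


class FlakySink:
    """Wrapper that fails the first ``fail_first`` persist attempts per
    result_id, then delegates — a scripted fault for retransmission tests."""

    def __init__(self, inner: ResultSink, fail_first: int = 1) -> None:
        self.inner = inner
        self.fail_first = fail_first
        self.attempts: dict[str, int] = {}

    def persist(self, meta: MetadataRow, row: AnalyteRow) -> DeliveryReceipt:
        n = self.attempts.get(meta.result_id, 0) + 1
        self.attempts[meta.result_id] = n
        if n <= self.fail_first:
            return DeliveryReceipt(
                DeliveryStatus.RETRYABLE_FAILURE, f"scripted failure {n}"
            )
        return self.inner.persist(meta, row)
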