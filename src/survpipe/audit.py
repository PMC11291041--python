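"""Structured event log used for provenance and leakage audits.

Every operation that touches data records a JSON-serialisable event through
:func:`record`.  By default events go to an in-memory buffer; the CLI attaches
a JSON-lines file sink.  Tests (and the leakage audit) parse these events to
assert, e.g., that validation rows only ever pass through single-patient
imputation and frozen encoders.
"""

from __future__ import annotations

import json
import threading
from contextlib import contextmanager
from typing import Any, Iterator

_lock = threading.Lock()
_events: list[dict[str, Any]] = []
_sink = None  # optional open file handle


def record(event: str, **fields: Any) -> None:
    """Append a structured event to the audit log."""
    entry = {"event": event, **fields}
    with _lock:
        _events.append(entry)
        if _sink is not None:
            _sink.write(json.dumps(entry, default=str) + "\n")
            _sink.flush()


def events() -> list[dict[str, Any]]:
    """Snapshot of all recorded events."""
    with _lock:
        return list(_events)


def clear() -> None:
    with _lock:
        _events.clear()


@contextmanager
def sink(path: str) -> Iterator[None]:
    """Also mirror events to a JSON-lines file while the context is active."""
    global _sink
    with open(path, "w") as fh:
        with _lock:
            _sink = fh
        try:
            yield
        finally:
            with _lock:
                _sink = None


@contextmanager
def capture() -> Iterator[list[dict[str, Any]]]:
    """Capture events emitted inside the context (appended to the returned list)."""
    start = len(events())
    out: list[dict[str, Any]] = []
    try:
        yield out
    finally:
        out.extend(events()[start:])
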