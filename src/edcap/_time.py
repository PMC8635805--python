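"""Timestamp helpers.

All timestamps in the system are ISO-8601 with timezone offset and (by
default) millisecond precision, so reaction times survive a round trip
through text storage.  Comparisons are always done in UTC; the original
offset is preserved in the stored string.
"""

from __future__ import annotations

from datetime import datetime, timezone

ISO_TIMESPEC = "milliseconds"


def now_utc() -> datetime:
    return datetime.now(timezone.utc)


def format_iso(dt: datetime) -> str:
    """Render an aware datetime as ISO-8601 with 1 ms precision."""
    if dt.tzinfo is None:
        raise ValueError("naive datetime: timestamps must carry a timezone")
    return dt.isoformat(timespec=ISO_TIMESPEC)


def parse_iso(text: str) -> datetime:
    dt = datetime.fromisoformat(text)
    if dt.tzinfo is None:
        raise ValueError(f"timestamp lacks timezone: {text!r}")
    return dt


def to_utc(dt: datetime) -> datetime:
    return dt.astimezone(timezone.utc)
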