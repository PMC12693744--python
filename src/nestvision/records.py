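"""Append-only "position-quantity" record store.

Every inspection writes one row: auto-incremented id, the 8-digit nest Uid,
the fused egg count (zero counts are recorded too) and the capture time.
The backing store is a single-file SQLite database (or in-memory), and rows
export losslessly to CSV with the Uid kept as zero-padded text.
Re-inspection appends a new row; nothing is ever updated in place.
"""

from __future__ import annotations

import csv
import sqlite3
from dataclasses import dataclass
from datetime import datetime
from pathlib import Path

from .codes import parse_position

__all__ = ["EggRecord", "RecordStore", "add_record", "query_by_uid", "export_csv", "import_csv"]

DISPLAY_FMT = "%m-%d %H:%M:%S"


@dataclass(frozen=True)
class EggRecord:
    id: int
    uid: str
    number: int
    time: str  # display form "MM-DD HH:MM:SS"
    time_iso: str = ""


class RecordStore:
    """SQLite-backed, append-only store of egg records."""

    def __init__(self, path: str | Path = ":memory:") -> None:
        self._conn = sqlite3.connect(str(path))
        self._conn.execute(
            "CREATE TABLE IF NOT EXISTS records ("
            "id INTEGER PRIMARY KEY AUTOINCREMENT,"
            "uid TEXT NOT NULL,"
            "number INTEGER NOT NULL,"
            "time TEXT NOT NULL,"
            "time_iso TEXT NOT NULL)"
        )
        self._conn.commit()

    def close(self) -> None:
        self._conn.close()

    def __enter__(self) -> "RecordStore":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    def add_record(self, uid: str, number: int, time: datetime | str | None = None) -> EggRecord:
        """Append one row; the uid must parse as a valid position code."""
        parse_position(uid)  # raises on format/range violations
        if not isinstance(number, int) or isinstance(number, bool) or number < 0:
            raise ValueError(f"number must be a non-negative integer, got {number!r}")
        if time is None:
            time = datetime.now()
        if isinstance(time, datetime):
            display, iso = time.strftime(DISPLAY_FMT), time.isoformat(timespec="seconds")
        else:
            display, iso = str(time), ""
        cur = self._conn.execute(
            "INSERT INTO records (uid, number, time, time_iso) VALUES (?, ?, ?, ?)",
            (uid, number, display, iso),
        )
        self._conn.commit()
        return EggRecord(cur.lastrowid, uid, number, display, iso)

    def query_by_uid(self, uid: str) -> list[EggRecord]:
        """All records of one nest, ascending id."""
        parse_position(uid)
        rows = self._conn.execute(
            "SELECT id, uid, number, time, time_iso FROM records WHERE uid = ? ORDER BY id",
            (uid,),
        ).fetchall()
        return [EggRecord(*r) for r in rows]

    def all_records(self) -> list[EggRecord]:
        rows = self._conn.execute(
            "SELECT id, uid, number, time, time_iso FROM records ORDER BY id"
        ).fetchall()
        return [EggRecord(*r) for r in rows]

    def export_csv(self, path: str | Path) -> int:
        """Write Id,Uid,Number,Time rows; returns the number of data rows."""
        records = self.all_records()
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["Id", "Uid", "Number", "Time"])
            for r in records:
                writer.writerow([r.id, r.uid, r.number, r.time])
        return len(records)


def add_record(store: RecordStore, uid: str, number: int, time=None) -> EggRecord:
    return store.add_record(uid, number, time)


def query_by_uid(store: RecordStore, uid: str) -> list[EggRecord]:
    return store.query_by_uid(uid)


def export_csv(store: RecordStore, path: str | Path) -> int:
    return store.export_csv(path)


def import_csv(path: str | Path) -> list[EggRecord]:
    """Read an exported CSV back; Uid stays a zero-padded string."""
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(EggRecord(int(row["Id"]), row["Uid"], int(row["Number"]), row["Time"]))
    return out
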