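"""Unblind a session and write the consolidated results table.

Unblinding joins every annotation, keyed by its opaque blind ID, back to the
label and source file it came from.  Rows are ordered by label (row letter,
then column number) for readability; the 1-based presentation rank is kept
as the ``blind_position`` column so the randomized order remains auditable.

Tables are written as XLSX (single sheet "results") or CSV (UTF-8,
RFC-4180 quoting).  Partial sessions export their annotated rows only; the
annotated/total status goes into a sidecar summary file, never into the
table itself, so the table stays rectangular.
"""

from __future__ import annotations

import csv
import json
import os
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

from openpyxl import Workbook

from .errors import InvalidInput, IOFailure, NoAnnotations
from .session import Session

FIXED_COLUMNS = ("label", "source_file", "blind_position")


@dataclass(frozen=True)
class ResultRow:
    """One unblinded record: label, source file, presentation rank, and one
    note per analysis stage."""

    label: str
    source_file: str
    blind_position: int  # 1-based rank in the randomized presentation
    notes: dict[str, str]


def unblind(session: Session) -> list[ResultRow]:
    """Join each annotation to its original label and source file.

    Partial sessions yield only their annotated rows; a session with no
    annotations raises ``NoAnnotations``.
    """
    if not session.annotations:
        raise NoAnnotations("session has no annotations to unblind")
    position_of = {bid: k for k, bid in enumerate(session.blind_ids)}
    rows = []
    for bid, notes in session.annotations.items():
        k = position_of[bid]
        seg = session.manifest.segments[session.order[k]]
        source = session.manifest.source_by_id(seg.media_id)
        rows.append(ResultRow(
            label=seg.label.render(),
            source_file=Path(source.path).name,
            blind_position=k + 1,
            notes=dict(notes),
        ))
    rows.sort(key=lambda r: (r.label[0], int(r.label[1:])))
    return rows


def write_results(
    rows: Sequence[ResultRow],
    path: Union[str, os.PathLike],
    stages: Sequence[str],
    fmt: Optional[str] = None,
) -> Path:
    """Write the results table; header is [label, source_file,
    blind_position, <stage names...>].

    ``fmt`` is "csv" or "xlsx"; inferred from the path suffix when omitted.
    A sidecar ``<path>.summary.json`` records how many rows were exported.
    Byte-identical CSV output for identical rows (export is pure).
    """
    if not rows:
        raise NoAnnotations("no rows to export")
    p = Path(path)
    if fmt is None:
        fmt = p.suffix.lstrip(".").lower()
    if fmt not in ("csv", "xlsx"):
        raise InvalidInput(f"unknown results format {fmt!r}; use csv or xlsx")
    header = list(FIXED_COLUMNS) + list(stages)
    table = [
        [r.label, r.source_file, r.blind_position] + [r.notes.get(s, "") for s in stages]
        for r in rows
    ]
    try:
        if fmt == "csv":
            with open(p, "w", newline="", encoding="utf-8") as fh:
                writer = csv.writer(fh)
                writer.writerow(header)
                writer.writerows(table)
        else:
            wb = Workbook()
            ws = wb.active
            ws.title = "results"
            ws.append(header)
            for row in table:
                ws.append(row)
            wb.save(p)
        summary = {"rows_exported": len(rows)}
        p.with_name(p.name + ".summary.json").write_text(
            json.dumps(summary, indent=2) + "\n", encoding="utf-8")
    except OSError as exc:
        raise IOFailure(f"cannot write results to {p}: {exc}") from exc
    return p


def export_session(
    session: Session,
    path: Union[str, os.PathLike],
    fmt: Optional[str] = None,
) -> Path:
    """Unblind and write in one step; the sidecar summary additionally
    records the session's annotated/total counts and status."""
    rows = unblind(session)
    p = write_results(rows, path, stages=session.manifest.stages, fmt=fmt)
    summary = {
        "rows_exported": len(rows),
        "annotated": session.n_annotated,
        "total_segments": session.n_segments,
        "status": session.status,
    }
    p.with_name(p.name + ".summary.json").write_text(
        json.dumps(summary, indent=2) + "\n", encoding="utf-8")
    return p
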