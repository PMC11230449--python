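"""Blinded annotation sessions: seeded shuffle, opaque IDs, pause/resume.

The segment order is produced by an explicit Fisher-Yates shuffle driven by
NumPy's PCG64 generator.  The generator identity is recorded in the session
file as ``"pcg64-fisher-yates-v1"`` so a session is reproducible from its
manifest and seed alone, on any machine, independent of the Python release
(PCG64's bit stream is covered by NumPy's random-stream compatibility
policy).

Blind IDs are positional ("S001" for the first presented segment), which
makes them provably independent of labels, rectangles and source files.  At
session creation every extracted segment file is copied into a ``blinded/``
folder under its blind-position name; this copy is the only path the blinded
interface ever exposes, so neither the annotator nor anyone browsing the
folder mid-analysis can recover a label.  The label <-> blind-ID key is
written to a separate key file next to the session file and is consumed by
the export step.

Session files are JSON with a schema version; saves are atomic (temp file +
rename), so an interrupted save never corrupts the recorded random order.
"""

from __future__ import annotations

import json
import logging
import os
import secrets
import shutil
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import NamedTuple, Optional, Union

import numpy as np

from .errors import (
    AlreadyAnnotated,
    CorruptSession,
    InvalidInput,
    IOFailure,
    NoSegments,
    StageMismatch,
    UnknownSegment,
)
from .segmentation import (
    SegmentManifest,
    manifest_from_dict,
    manifest_to_dict,
)

log = logging.getLogger(__name__)

SESSION_SCHEMA_VERSION = 1

#: named, versioned PRNG + shuffle algorithm recorded in every session file
PRNG_ID = "pcg64-fisher-yates-v1"

#: ceiling for seeds drawn from system entropy (fits in a signed 32-bit int)
_MAX_AUTO_SEED = 2**31 - 1

STATUS_IN_PROGRESS = "in_progress"
STATUS_COMPLETE = "complete"


def fisher_yates(n: int, seed: int) -> list[int]:
    """Uniform permutation of ``range(n)`` via Fisher-Yates over PCG64."""
    if n < 1:
        raise InvalidInput("cannot shuffle an empty sequence")
    rng = np.random.Generator(np.random.PCG64(seed))
    order = list(range(n))
    for i in range(n - 1, 0, -1):
        j = int(rng.integers(0, i + 1))
        order[i], order[j] = order[j], order[i]
    return order


def blind_id_for_position(position: int, n: int) -> str:
    """Opaque ID for shuffled position ``position`` (0-based): "S001"...
    Zero-padded to at least 3 digits so names sort in presentation order."""
    width = max(3, len(str(n)))
    return f"S{position + 1:0{width}d}"


class BlindItem(NamedTuple):
    """What the blinded interface exposes: an opaque ID and the path of the
    blind-named segment copy.  Never a label, rectangle or source file."""

    blind_id: str
    segment_path: str


def _now() -> str:
    return datetime.now(timezone.utc).isoformat(timespec="seconds")


@dataclass(eq=False)
class Session:
    """Persisted blinded state: seed, shuffled order, blind IDs, annotations.

    ``order[k]`` is the manifest segment index presented at shuffled
    position ``k``.  ``annotations`` maps blind_id -> {stage: note}.
    ``path`` is the file the session autosaves to (set by save/load); it is
    not part of the session's identity.
    """

    manifest: SegmentManifest
    seed: int
    order: list[int]
    blind_ids: list[str]
    blinded_paths: list[str]
    annotations: dict[str, dict[str, str]] = field(default_factory=dict)
    prng: str = PRNG_ID
    status: str = STATUS_IN_PROGRESS
    created: str = field(default_factory=_now)
    updated: str = field(default_factory=_now)
    path: Optional[str] = None

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Session):
            return NotImplemented
        return session_to_dict(self) == session_to_dict(other)

    @property
    def n_segments(self) -> int:
        return len(self.order)

    @property
    def n_annotated(self) -> int:
        return len(self.annotations)

    def key_map(self) -> dict[str, str]:
        """blind_id -> rendered label (the unblinding key)."""
        return {
            self.blind_ids[k]: self.manifest.segments[self.order[k]].label.render()
            for k in range(self.n_segments)
        }


def create_session(
    manifest: SegmentManifest,
    seed: Optional[int] = None,
    blind_dir: Union[str, os.PathLike, None] = None,
) -> Session:
    """Shuffle the manifest's segments and open a blinded session.

    If ``seed`` is omitted one is drawn from system entropy and recorded, so
    every session is reproducible after the fact.  Extracted segment files
    are copied to ``blind_dir`` (default ``<results_folder>/blinded``) under
    their blind-position names.
    """
    if not manifest.segments:
        raise NoSegments("cannot create a session for a manifest with no segments")
    for seg in manifest.segments:
        if not seg.segment_path or not Path(seg.segment_path).is_file():
            raise InvalidInput(
                f"segment {seg.label.render()} has no extracted file; "
                "run extract_segments first"
            )
    if seed is None:
        seed = secrets.randbelow(_MAX_AUTO_SEED + 1)
        log.info("no seed given; drew and recorded seed from system entropy")
    n = len(manifest.segments)
    order = fisher_yates(n, seed)
    blind_ids = [blind_id_for_position(k, n) for k in range(n)]

    bdir = Path(blind_dir) if blind_dir is not None else (
        Path(manifest.results_folder) / "blinded")
    try:
        bdir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise IOFailure(f"cannot create {bdir}: {exc}") from exc
    blinded_paths = []
    for k in range(n):
        src = Path(manifest.segments[order[k]].segment_path)
        dst = bdir / f"{blind_ids[k]}{src.suffix}"
        try:
            shutil.copyfile(src, dst)
        except OSError as exc:
            raise IOFailure(f"cannot write blinded copy {dst}: {exc}") from exc
        blinded_paths.append(str(dst))
    log.info("session created: %d segments shuffled (prng=%s)", n, PRNG_ID)
    return Session(manifest=manifest, seed=int(seed), order=order,
                   blind_ids=blind_ids, blinded_paths=blinded_paths)


def next_pending(session: Session) -> Optional[BlindItem]:
    """Earliest shuffled position without an annotation, as a
    :class:`BlindItem`; ``None`` (the done-signal) when every segment is
    annotated, at which point the session status flips to complete."""
    for k in range(session.n_segments):
        bid = session.blind_ids[k]
        if bid not in session.annotations:
            return BlindItem(blind_id=bid, segment_path=session.blinded_paths[k])
    session.status = STATUS_COMPLETE
    return None


def record_annotation(
    session: Session,
    blind_id: str,
    notes: dict[str, str],
    overwrite: bool = False,
) -> Session:
    """Store one annotation: a note (free text, possibly empty) for every
    declared stage, keyed by blind ID.

    Notes must cover exactly the declared stages.  Re-annotating requires
    ``overwrite=True``.  If the session has a save path (set by
    ``save_session``/``load_session``) it is persisted atomically before
    returning; a purely in-memory session is left to the caller to save.
    """
    if blind_id not in session.blind_ids:
        raise UnknownSegment(f"blind ID {blind_id!r} is not part of this session")
    declared = list(session.manifest.stages)
    missing = [s for s in declared if s not in notes]
    extra = [s for s in notes if s not in declared]
    if missing or extra:
        raise StageMismatch(
            f"notes for {blind_id} must cover exactly the stages {declared}; "
            f"missing={missing} extra={extra}"
        )
    if blind_id in session.annotations and not overwrite:
        raise AlreadyAnnotated(
            f"{blind_id} already annotated; pass overwrite=True to replace"
        )
    session.annotations[blind_id] = {s: str(notes[s]) for s in declared}
    session.updated = _now()
    if len(session.annotations) == session.n_segments:
        session.status = STATUS_COMPLETE
    if session.path:
        save_session(session, session.path)
    return session


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def session_to_dict(session: Session) -> dict:
    return {
        "version": SESSION_SCHEMA_VERSION,
        "prng": session.prng,
        "seed": session.seed,
        "manifest": manifest_to_dict(session.manifest),
        "order": list(session.order),
        "blind_ids": list(session.blind_ids),
        "blinded_paths": list(session.blinded_paths),
        "annotations": {k: dict(v) for k, v in session.annotations.items()},
        "status": session.status,
        "created": session.created,
        "updated": session.updated,
    }


def _validate_session_dict(data: dict) -> None:
    if data.get("version") != SESSION_SCHEMA_VERSION:
        raise CorruptSession(f"unknown session schema version {data.get('version')!r}")
    if data.get("prng") != PRNG_ID:
        raise CorruptSession(
            f"session was produced by PRNG {data.get('prng')!r}; "
            f"this build implements {PRNG_ID!r}"
        )
    order = data["order"]
    n = len(data["manifest"]["segments"])
    if sorted(order) != list(range(n)):
        raise CorruptSession(
            "order is not a permutation of the manifest's segment indices"
        )
    blind_ids = data["blind_ids"]
    if len(blind_ids) != n or len(set(blind_ids)) != n:
        raise CorruptSession("blind_ids must be unique, one per segment")
    if len(data["blinded_paths"]) != n:
        raise CorruptSession("one blinded path per segment required")
    stages = set(data["manifest"]["stages"])
    for bid, notes in data["annotations"].items():
        if bid not in blind_ids:
            raise CorruptSession(f"annotation for unknown blind ID {bid!r}")
        if set(notes) != stages:
            raise CorruptSession(f"annotation {bid!r} does not cover the stages")
    if data["status"] not in (STATUS_IN_PROGRESS, STATUS_COMPLETE):
        raise CorruptSession(f"unknown status {data['status']!r}")


def session_from_dict(data: dict) -> Session:
    try:
        _validate_session_dict(data)
        return Session(
            manifest=manifest_from_dict(data["manifest"]),
            seed=int(data["seed"]),
            order=[int(i) for i in data["order"]],
            blind_ids=list(data["blind_ids"]),
            blinded_paths=list(data["blinded_paths"]),
            annotations={k: dict(v) for k, v in data["annotations"].items()},
            prng=data["prng"],
            status=data["status"],
            created=data["created"],
            updated=data["updated"],
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise CorruptSession(f"malformed session file: {exc}") from exc


def key_file_path(session_path: Union[str, os.PathLike]) -> Path:
    p = Path(session_path)
    return p.with_name(p.stem + ".key.json")


def save_session(session: Session, path: Union[str, os.PathLike]) -> Path:
    """Atomically write the session (temp file + rename) and the unblinding
    key file next to it; records ``path`` on the session for autosave."""
    p = Path(path)
    payload = json.dumps(session_to_dict(session), indent=2) + "\n"
    key_payload = json.dumps(session.key_map(), indent=2) + "\n"
    try:
        p.parent.mkdir(parents=True, exist_ok=True)
        tmp = p.with_name(p.name + ".tmp")
        tmp.write_text(payload, encoding="utf-8")
        os.replace(tmp, p)
        ktmp = key_file_path(p).with_suffix(".tmp")
        ktmp.write_text(key_payload, encoding="utf-8")
        os.replace(ktmp, key_file_path(p))
    except OSError as exc:
        raise IOFailure(f"cannot write session to {p}: {exc}") from exc
    session.path = str(p)
    return p


def load_session(path: Union[str, os.PathLike]) -> Session:
    """Load and validate a session file; schema violations and corrupt
    permutations raise ``CorruptSession``."""
    p = Path(path)
    try:
        data = json.loads(p.read_text(encoding="utf-8"))
    except OSError as exc:
        raise IOFailure(f"cannot read {p}: {exc}") from exc
    except json.JSONDecodeError as exc:
        raise CorruptSession(f"{p.name}: not valid JSON ({exc})") from exc
    session = session_from_dict(data)
    session.path = str(p)
    return session
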