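"""Error taxonomy for the blinded-analysis workflow.

Each error family carries a distinct process exit code (used by the CLI) so
scripted callers can distinguish media problems from definition problems from
session-state problems without parsing messages.
"""

from __future__ import annotations


class BlindcutError(Exception):
    """Base class for all blindcut errors."""

    exit_code = 1


# --- media family -----------------------------------------------------------

class UnsupportedFormat(BlindcutError):
    """File extension is not one of the accepted media formats."""

    exit_code = 3


class CorruptMedia(BlindcutError):
    """File could not be decoded, or its header contradicts its extension."""

    exit_code = 3


class UnsupportedCodec(CorruptMedia):
    """Container was parsed but no decoder exists for its video codec."""

    exit_code = 3


class KindMismatch(BlindcutError):
    """Operation requires a different media kind (image vs video)."""

    exit_code = 3


class IOFailure(BlindcutError):
    """Filesystem read/write failed."""

    exit_code = 6


class InvalidInput(BlindcutError):
    """Degenerate input such as an empty frame stream."""

    exit_code = 4


# --- segmentation family ----------------------------------------------------

class InvalidLabel(BlindcutError):
    """Segment label outside the A1..Z36 scheme."""

    exit_code = 4


class DuplicateLabel(BlindcutError):
    """Label already used elsewhere in the manifest."""

    exit_code = 4


class EmptyRegion(BlindcutError):
    """Rectangle is empty, or empty after clamping to the frame."""

    exit_code = 4


class ParseError(BlindcutError):
    """Malformed row in a segment-definition or annotation file."""

    exit_code = 4


class InvalidSpec(BlindcutError):
    """Synthetic plate specification is inconsistent (grid overflow etc.)."""

    exit_code = 4


class NoSegments(BlindcutError):
    """Manifest holds no segments."""

    exit_code = 5


# --- session / export family ------------------------------------------------

class UnknownSegment(BlindcutError):
    """Blind ID does not belong to this session."""

    exit_code = 5


class StageMismatch(BlindcutError):
    """Annotation notes do not cover exactly the declared stages."""

    exit_code = 5


class AlreadyAnnotated(BlindcutError):
    """Blind ID already has an annotation and overwrite was not requested."""

    exit_code = 5


class CorruptSession(BlindcutError):
    """Session file violates the schema or holds a corrupt permutation."""

    exit_code = 5


class NoAnnotations(BlindcutError):
    """Export requested on a session with no annotations."""

    exit_code = 5
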