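"""Segment-anchored generic residue numbering for class C GPCRs.

Cross-receptor residue labels of the form ``<segment>x<index>`` (e.g. ``6x50``,
``45x52``): the segment code is the transmembrane helix number (1-7) or a
two-digit loop code (ECL2 = 45), and the index counts relative to the most
conserved position of the segment, which is defined to be 50.  A residue three
positions C-terminal of the TM6 anchor is therefore 6x53, and the conserved
ECL2 cysteine that bridges to 3x29 is 45x50.

Numbering is consumed from a per-receptor annotation table (segment spans plus
one anchor residue per segment), not derived from structure: positions before
the anchor count backwards with the same arithmetic (anchor - 1 -> x49).
All sequence indices are 1-based inclusive.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from functools import total_ordering
from pathlib import Path
from typing import Iterable, Mapping, Optional

from .errors import AnnotationError, FormatError, RangeError

#: Segment name -> numeric code used in generic labels.  Helices are 1-7,
#: loops use the two-digit convention (code of flanking helices), H8 is 8.
SEGMENT_CODES: dict[str, int] = {
    "TM1": 1, "TM2": 2, "TM3": 3, "TM4": 4, "TM5": 5, "TM6": 6, "TM7": 7,
    "H8": 8,
    "ICL1": 12, "ECL1": 23, "ICL2": 34, "ECL2": 45, "ICL3": 56, "ECL3": 67,
}

_CODE_TO_NAME = {v: k for k, v in SEGMENT_CODES.items()}

_GENERIC_RE = re.compile(r"^(\d{1,2})x(\d{1,2})$")


def segment_code(segment: int | str) -> int:
    """Normalise a segment given by name (``"TM6"``) or code (``6``)."""
    if isinstance(segment, str):
        name = segment.strip().upper()
        if name in SEGMENT_CODES:
            return SEGMENT_CODES[name]
        if name.isdigit():
            return int(name)
        raise AnnotationError(f"unknown segment {segment!r}")
    return int(segment)


@total_ordering
@dataclass(frozen=True)
class GenericPosition:
    """A segment-anchored generic residue label such as 6x50 or 45x52."""

    segment: int
    index: int

    def __post_init__(self) -> None:
        if not 1 <= self.index <= 99:
            raise AnnotationError(
                f"generic index {self.index} outside the 1-99 range"
            )
        if self.segment not in _CODE_TO_NAME:
            raise AnnotationError(f"unknown segment code {self.segment}")

    @classmethod
    def parse(cls, label: str) -> "GenericPosition":
        m = _GENERIC_RE.match(label.strip())
        if not m:
            raise AnnotationError(f"cannot parse generic position {label!r}")
        return cls(int(m.group(1)), int(m.group(2)))

    @property
    def segment_name(self) -> str:
        return _CODE_TO_NAME[self.segment]

    def __str__(self) -> str:
        return f"{self.segment}x{self.index:02d}"

    def __lt__(self, other: "GenericPosition") -> bool:
        return (self.segment, self.index) < (other.segment, other.index)


@dataclass(frozen=True)
class SegmentSpan:
    """One annotated segment of a receptor sequence.

    ``anchor_seq_index`` is the 1-based sequence position whose generic index
    is 50 (e.g. the conserved Trp of TM6, the ECL2 Cys).
    """

    segment: int
    seq_start: int
    seq_end: int
    anchor_seq_index: int

    def __post_init__(self) -> None:
        if not self.seq_start <= self.seq_end:
            raise AnnotationError(
                f"segment {self.segment}: start {self.seq_start} > end {self.seq_end}"
            )
        if not self.seq_start <= self.anchor_seq_index <= self.seq_end:
            raise AnnotationError(
                f"segment {self.segment}: anchor {self.anchor_seq_index} outside "
                f"[{self.seq_start}, {self.seq_end}]"
            )

    def __contains__(self, seq_index: int) -> bool:
        return self.seq_start <= seq_index <= self.seq_end


@dataclass
class ReceptorAnnotation:
    """Per-receptor segment spans, anchors and sequence."""

    receptor_id: str
    segments: list[SegmentSpan]
    sequence: str = ""

    def __post_init__(self) -> None:
        spans = sorted(self.segments, key=lambda s: s.seq_start)
        for a, b in zip(spans, spans[1:]):
            if b.seq_start <= a.seq_end:
                raise AnnotationError(
                    f"{self.receptor_id}: segments {a.segment} and {b.segment} overlap"
                )
        seen = set()
        for s in spans:
            if s.segment in seen:
                raise AnnotationError(
                    f"{self.receptor_id}: segment {s.segment} annotated twice"
                )
            seen.add(s.segment)
        self.segments = spans

    def segment_span(self, segment: int | str) -> Optional[SegmentSpan]:
        code = segment_code(segment)
        for s in self.segments:
            if s.segment == code:
                return s
        return None


def assign_generic(ann: ReceptorAnnotation, seq_index: int) -> Optional[GenericPosition]:
    """Map a 1-based sequence position to its generic label, or ``None`` if it
    falls in no annotated segment.

    The index is ``50 + (seq_index - anchor)``; positions N-terminal of the
    anchor count backwards (anchor - 1 -> x49).
    """
    if ann.sequence and not 1 <= seq_index <= len(ann.sequence):
        raise RangeError(
            f"{ann.receptor_id}: sequence index {seq_index} outside 1..{len(ann.sequence)}"
        )
    if seq_index < 1:
        raise RangeError(f"sequence index {seq_index} must be >= 1")
    for span in ann.segments:
        if seq_index in span:
            index = 50 + (seq_index - span.anchor_seq_index)
            if not 1 <= index <= 99:
                raise AnnotationError(
                    f"{ann.receptor_id}: seq {seq_index} in segment {span.segment} "
                    f"yields generic index {index} outside 1-99"
                )
            return GenericPosition(span.segment, index)
    return None


def generic_to_seq(ann: ReceptorAnnotation, pos: GenericPosition) -> Optional[int]:
    """Inverse of :func:`assign_generic`; ``None`` when the receptor's segment
    does not extend to that generic index (or is not annotated at all)."""
    span = ann.segment_span(pos.segment)
    if span is None:
        return None
    seq_index = span.anchor_seq_index + (pos.index - 50)
    if seq_index in span:
        return seq_index
    return None


# ---------------------------------------------------------------------------
# I/O: annotation CSV + FASTA sequences

_ANNOTATION_COLUMNS = ["receptor_id", "segment", "seq_start", "seq_end", "anchor_seq_index"]


def read_annotation_table(
    path: str | Path,
    sequences: Optional[Mapping[str, str]] = None,
) -> dict[str, ReceptorAnnotation]:
    """Read the segment-annotation CSV (one row per receptor segment).

    ``sequences`` (receptor_id -> amino-acid string, e.g. from
    :func:`read_fasta`) attaches sequences so out-of-range queries error.
    """
    rows: dict[str, list[SegmentSpan]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(_ANNOTATION_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise FormatError(f"annotation table missing columns: {sorted(missing)}")
        for row in reader:
            rows.setdefault(row["receptor_id"], []).append(
                SegmentSpan(
                    segment=segment_code(row["segment"]),
                    seq_start=int(row["seq_start"]),
                    seq_end=int(row["seq_end"]),
                    anchor_seq_index=int(row["anchor_seq_index"]),
                )
            )
    out = {}
    for rid, spans in rows.items():
        seq = (sequences or {}).get(rid, "")
        out[rid] = ReceptorAnnotation(receptor_id=rid, segments=spans, sequence=seq)
    return out


def write_annotation_table(path: str | Path, annotations: Iterable[ReceptorAnnotation]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_ANNOTATION_COLUMNS)
        for ann in annotations:
            for s in ann.segments:
                writer.writerow(
                    [ann.receptor_id, _CODE_TO_NAME.get(s.segment, s.segment),
                     s.seq_start, s.seq_end, s.anchor_seq_index]
                )
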