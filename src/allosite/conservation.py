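"""Physicochemical conservation of site positions across receptors.

For every generic position of interest the aligned residues are gathered via
the per-receptor numbering (receptors whose segment does not reach the
position contribute a gap) and the share of receptors carrying a residue of a
given physicochemical class is reported.  Two denominators are emitted: over
receptors that have the position (gaps excluded) and over all receptors (a
gap counts as non-matching); displayed figures are rounded half-up, the
unrounded values are retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from .errors import InputError, LookupError_
from .integration import round_half_up
from .numbering import GenericPosition, ReceptorAnnotation, generic_to_seq

GAP = "-"

#: Default physicochemical classes.  A residue may belong to several classes
#: (His is both aromatic and positive); the scheme is configurable.
DEFAULT_SCHEME: dict[str, frozenset[str]] = {
    "aromatic": frozenset("FYWH"),
    "aliphatic": frozenset("AVLIMC"),
    "polar": frozenset("STNQYHKRDE"),
    "positive": frozenset("KRH"),
    "negative": frozenset("DE"),
    "small": frozenset("AGSTC"),
    "glycine": frozenset("G"),
    "proline": frozenset("P"),
}


@dataclass
class PropertyScheme:
    classes: dict[str, frozenset[str]] = field(
        default_factory=lambda: dict(DEFAULT_SCHEME)
    )

    def classes_of(self, aa: str) -> set[str]:
        aa = aa.upper()
        return {name for name, members in self.classes.items() if aa in members}


@dataclass
class ColumnProfile:
    """Residues at one generic position across receptors, with class fractions."""

    generic: GenericPosition
    residues: dict[str, str]           # receptor_id -> 1-letter code or '-'
    class_fractions: dict[str, float] = field(default_factory=dict)

    @property
    def non_gap(self) -> dict[str, str]:
        return {r: aa for r, aa in self.residues.items() if aa != GAP}


def column_for_position(
    alignment: Mapping[str, str],
    annotations: Mapping[str, ReceptorAnnotation],
    pos: GenericPosition,
    scheme: Optional[PropertyScheme] = None,
) -> ColumnProfile:
    """Gather the residue at ``pos`` for every receptor of the alignment.

    Receptors whose annotated segment does not extend to the position are
    recorded as gaps.  Residues are read off the ungapped sequence, so the
    alignment may contain gap columns.
    """
    scheme = scheme or PropertyScheme()
    residues: dict[str, str] = {}
    found = False
    for rid, aligned in alignment.items():
        ann = annotations.get(rid)
        if ann is None:
            raise InputError(f"receptor {rid} has no annotation")
        seq_index = generic_to_seq(ann, pos)
        if seq_index is None:
            residues[rid] = GAP
            continue
        ungapped = aligned.replace("-", "").replace(".", "")
        if seq_index > len(ungapped):
            residues[rid] = GAP
            continue
        residues[rid] = ungapped[seq_index - 1].upper()
        found = True
    if not found:
        raise LookupError_(f"position {pos} is mappable in no receptor")
    col = ColumnProfile(generic=pos, residues=residues)
    present = list(col.non_gap.values())
    for cls in scheme.classes:
        col.class_fractions[cls] = (
            sum(1 for aa in present if cls in scheme.classes_of(aa)) / len(present)
        )
    return col


def property_conservation(
    col: ColumnProfile,
    cls: str,
    scheme: Optional[PropertyScheme] = None,
    denominator: str = "non_gap",
) -> tuple[int, float]:
    """Percentage of receptors whose residue at this column belongs to ``cls``.

    Returns ``(displayed, raw)``: the half-up rounded figure and the
    unrounded percentage.  ``denominator`` is ``"non_gap"`` (receptors that
    have the position) or ``"all"`` (gaps count as non-matching).
    """
    scheme = scheme or PropertyScheme()
    present = list(col.non_gap.values())
    if not present:
        raise InputError(f"column {col.generic} is all-gap")
    hits = sum(1 for aa in present if cls in scheme.classes_of(aa))
    denom = len(present) if denominator == "non_gap" else len(col.residues)
    raw = 100.0 * hits / denom
    return round_half_up(raw), raw


def site_similarity(
    seq_a: Mapping[GenericPosition, str] | Sequence[str],
    seq_b: Mapping[GenericPosition, str] | Sequence[str],
) -> float:
    """Percentage identity between two receptors over the same site columns.

    Inputs are equal-length residue sequences (or position->residue maps over
    the same positions); columns gapped in either receptor are skipped.
    """
    if hasattr(seq_a, "keys"):
        keys = set(seq_a.keys())
        if keys != set(seq_b.keys()):
            raise InputError("site-column sets differ between the two receptors")
        pairs = [(seq_a[k], seq_b[k]) for k in sorted(keys)]
    else:
        if len(seq_a) != len(seq_b):
            raise InputError("site-column sequences differ in length")
        pairs = list(zip(seq_a, seq_b))
    if not pairs:
        raise InputError("empty site-column set")
    compared = [(a, b) for a, b in pairs if a != GAP and b != GAP]
    if not compared:
        raise InputError("no columns present in both receptors")
    ident = sum(1 for a, b in compared if a.upper() == b.upper())
    return 100.0 * ident / len(compared)


def conservation_report(
    alignment: Mapping[str, str],
    annotations: Mapping[str, ReceptorAnnotation],
    positions: Iterable[GenericPosition],
    scheme: Optional[PropertyScheme] = None,
) -> list[dict]:
    """One row per position x class with both denominator variants."""
    scheme = scheme or PropertyScheme()
    rows = []
    for pos in sorted(positions):
        try:
            col = column_for_position(alignment, annotations, pos, scheme)
        except LookupError_:
            continue
        for cls in scheme.classes:
            disp_ng, raw_ng = property_conservation(col, cls, scheme, "non_gap")
            disp_all, raw_all = property_conservation(col, cls, scheme, "all")
            rows.append({
                "generic_position": str(pos),
                "class": cls,
                "pct_non_gap": disp_ng,
                "pct_non_gap_raw": raw_ng,
                "pct_all_receptors": disp_all,
                "pct_all_receptors_raw": raw_all,
                "n_non_gap": len(col.non_gap),
                "n_receptors": len(col.residues),
            })
    return rows


def write_conservation_csv(path: str | Path, rows: Sequence[dict]) -> None:
    import csv

    if not rows:
        Path(path).write_text("")
        return
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0]))
        writer.writeheader()
        writer.writerows(rows)
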