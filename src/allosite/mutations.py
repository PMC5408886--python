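"""Curated single-point mutagenesis records and the >5-fold effect rule.

Each record is one mutant x one modulator measurement.  The fold effect is a
direction-agnostic magnitude (>= 1): a potency loss and a potency gain of the
same size count equally.  A position is considered a potential modulator
contact when at least one measurement shows a strictly greater than 5-fold
effect on binding or function, or when the measurement abolished binding or
activity outright.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from .errors import FormatError
from .numbering import GenericPosition


class Modality(str, Enum):
    PAM = "PAM"
    NAM = "NAM"
    AGONIST = "agonist"   # allosteric agonists: effect-called, but excluded
    OTHER = "other"       # from the PAM/NAM dual-involvement statistic


class Assay(str, Enum):
    BINDING = "binding"
    FUNCTION = "function"


class Qualitative(str, Enum):
    NONE = "none"
    ABOLISHED = "abolished"
    NO_EFFECT = "no_effect"


class Reason(str, Enum):
    FOLD_GT_THRESHOLD = "fold_gt_threshold"
    ABOLISHED = "abolished"
    BELOW_THRESHOLD = "below_threshold"
    NO_EFFECT = "no_effect"


@dataclass(frozen=True)
class MutationRecord:
    receptor_id: str
    family: str
    seq_index: int
    generic: Optional[GenericPosition]
    wt_aa: str
    mut_aa: str
    ligand_id: str
    modality: Modality
    assay: Assay
    fold_effect: Optional[float] = None
    qualitative: Qualitative = Qualitative.NONE
    reference: str = ""

    def validate(self) -> Optional[str]:
        """Return a human-readable problem, or ``None`` if the record is valid."""
        if self.wt_aa == self.mut_aa:
            return f"wild-type equals mutant ({self.wt_aa})"
        if self.fold_effect is not None:
            if not math.isfinite(self.fold_effect) or self.fold_effect < 1.0:
                return f"fold effect {self.fold_effect} must be a finite magnitude >= 1"
        informative_fold = self.fold_effect is not None
        informative_qual = self.qualitative in (Qualitative.ABOLISHED, Qualitative.NO_EFFECT)
        if informative_fold == informative_qual:
            return "exactly one of fold_effect / qualitative must be informative"
        return None


@dataclass(frozen=True)
class EffectCall:
    record: MutationRecord
    passes: bool
    reason: Reason


def call_effect(rec: MutationRecord, threshold: float = 5.0) -> EffectCall:
    """Apply the inclusion rule: strictly more than ``threshold``-fold effect,
    or outright abolition, marks the position as a potential ligand contact."""
    if rec.qualitative is Qualitative.ABOLISHED:
        return EffectCall(rec, True, Reason.ABOLISHED)
    if rec.qualitative is Qualitative.NO_EFFECT:
        return EffectCall(rec, False, Reason.NO_EFFECT)
    assert rec.fold_effect is not None
    if rec.fold_effect > threshold:
        return EffectCall(rec, True, Reason.FOLD_GT_THRESHOLD)
    return EffectCall(rec, False, Reason.BELOW_THRESHOLD)


@dataclass
class EvidenceSummary:
    """Distinct-entity evidence behind one generic position (passing calls only)."""

    receptors: set[str] = field(default_factory=set)
    families: set[str] = field(default_factory=set)
    ligands_affected: set[str] = field(default_factory=set)
    modalities: set[Modality] = field(default_factory=set)
    records: list[MutationRecord] = field(default_factory=list)


def effect_positions(
    records: Iterable[MutationRecord],
    threshold: float = 5.0,
) -> dict[GenericPosition, EvidenceSummary]:
    """Summarise passing mutational evidence per generic position.

    Counting is by distinct entity: two assays of the same ligand contribute
    one ligand; duplicate records never inflate any count.  Records without a
    generic label are skipped (they cannot be compared across receptors).
    """
    out: dict[GenericPosition, EvidenceSummary] = {}
    for rec in records:
        if rec.generic is None:
            continue
        if not call_effect(rec, threshold).passes:
            continue
        summary = out.setdefault(rec.generic, EvidenceSummary())
        summary.receptors.add(rec.receptor_id)
        summary.families.add(rec.family)
        summary.ligands_affected.add(rec.ligand_id)
        summary.modalities.add(rec.modality)
        summary.records.append(rec)
    return out


# ---------------------------------------------------------------------------
# CSV I/O

CSV_HEADER = [
    "receptor_id", "family", "seq_index", "generic", "wt_aa", "mut_aa",
    "ligand_id", "modality", "assay", "fold_effect", "qualitative", "reference",
]


def _parse_row(row: Mapping[str, str]) -> MutationRecord:
    fold = row.get("fold_effect", "").strip()
    generic = row.get("generic", "").strip()
    return MutationRecord(
        receptor_id=row["receptor_id"].strip(),
        family=row["family"].strip(),
        seq_index=int(row["seq_index"]),
        generic=GenericPosition.parse(generic) if generic else None,
        wt_aa=row["wt_aa"].strip(),
        mut_aa=row["mut_aa"].strip(),
        ligand_id=row["ligand_id"].strip(),
        modality=Modality(row["modality"].strip()),
        assay=Assay(row["assay"].strip()),
        fold_effect=float(fold) if fold else None,
        qualitative=Qualitative(row.get("qualitative", "").strip() or "none"),
        reference=row.get("reference", "").strip(),
    )


def read_mutation_table(
    path: str | Path,
) -> tuple[list[MutationRecord], list[tuple[int, str]]]:
    """Read the mutation CSV.

    Returns ``(valid_records, rejections)`` where each rejection is a
    ``(1-based data row number, problem)`` pair; malformed rows are collected,
    not fatal.  A missing mandatory column is fatal.
    """
    records: list[MutationRecord] = []
    rejections: list[tuple[int, str]] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(CSV_HEADER) - set(reader.fieldnames or [])
        if missing:
            raise FormatError(f"mutation table missing columns: {sorted(missing)}")
        for i, row in enumerate(reader, start=1):
            try:
                rec = _parse_row(row)
            except (ValueError, KeyError) as exc:
                rejections.append((i, f"unparseable row: {exc}"))
                continue
            problem = rec.validate()
            if problem is not None:
                rejections.append((i, problem))
            else:
                records.append(rec)
    return records, rejections


def write_mutation_table(path: str | Path, records: Sequence[MutationRecord]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_HEADER)
        for r in records:
            writer.writerow([
                r.receptor_id, r.family, r.seq_index,
                str(r.generic) if r.generic else "",
                r.wt_aa, r.mut_aa, r.ligand_id, r.modality.value, r.assay.value,
                f"{r.fold_effect:g}" if r.fold_effect is not None else "",
                r.qualitative.value if r.qualitative is not Qualitative.NONE else "",
                r.reference,
            ])


def conflicting_duplicates(
    records: Iterable[MutationRecord],
    threshold: float = 5.0,
) -> list[tuple[MutationRecord, MutationRecord]]:
    """Pairs of records for the same mutant x ligand whose effect calls
    disagree.  The pipeline keeps all records and reports conflicts rather
    than resolving them."""
    by_key: dict[tuple, list[MutationRecord]] = {}
    for rec in records:
        key = (rec.receptor_id, rec.seq_index, rec.wt_aa, rec.mut_aa, rec.ligand_id)
        by_key.setdefault(key, []).append(rec)
    conflicts = []
    for recs in by_key.values():
        passing = [r for r in recs if call_effect(r, threshold).passes]
        failing = [r for r in recs if not call_effect(r, threshold).passes]
        if passing and failing:
            conflicts.append((passing[0], failing[0]))
    return conflicts
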