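"""Merging structural contacts with mutagenesis evidence.

The common allosteric site is the union of (a) positions within the distance
cutoff of a co-crystallized modulator in at least one structure and (b)
positions with passing mutational evidence.  On top of the merged profile the
module computes the structure/mutation Venn partition, multi-family binding
hotspots, the family-overlap and PAM/NAM dual-involvement statistics, and a
rule-based classification of effect positions that fall outside the site.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from .errors import InputError, ParameterError
from .mutations import EvidenceSummary, Modality, MutationRecord, call_effect
from .numbering import GenericPosition


def round_half_up(x: float) -> int:
    """Round to the nearest integer, halves away from zero (presentation rule)."""
    import math

    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass
class PositionEvidence:
    """All evidence behind one profiled position."""

    in_structure: bool = False
    in_mutation: bool = False
    families: set[str] = field(default_factory=set)            # structural + mutational
    mutation_families: set[str] = field(default_factory=set)
    receptors: set[str] = field(default_factory=set)
    ligands_affected: int = 0
    modalities: set[Modality] = field(default_factory=set)
    supporting_structures: set[str] = field(default_factory=set)

    @property
    def receptor_unique(self) -> bool:
        """Evidence confined to a single receptor (selectivity column)."""
        return len(self.receptors) == 1


@dataclass
class SiteProfile:
    positions: dict[GenericPosition, PositionEvidence]

    def __len__(self) -> int:
        return len(self.positions)

    def __iter__(self):
        return iter(self.positions)

    @property
    def site_set(self) -> set[GenericPosition]:
        return set(self.positions)

    @property
    def structural(self) -> set[GenericPosition]:
        return {p for p, e in self.positions.items() if e.in_structure}

    @property
    def mutational(self) -> set[GenericPosition]:
        return {p for p, e in self.positions.items() if e.in_mutation}


def build_site_profile(
    contact_union: Mapping[GenericPosition, set[str]],
    effect_map: Mapping[GenericPosition, EvidenceSummary],
    structure_families: Optional[Mapping[str, str]] = None,
    structure_receptors: Optional[Mapping[str, str]] = None,
) -> SiteProfile:
    """Merge the structural contact union with the mutational effect map.

    ``structure_families`` / ``structure_receptors`` map a structure id to the
    family / receptor of its crystallized receptor, so that a structure
    contributes family evidence exactly like a mutated receptor does.
    """
    positions: dict[GenericPosition, PositionEvidence] = {}
    for pos, structures in contact_union.items():
        ev = positions.setdefault(pos, PositionEvidence())
        ev.in_structure = True
        ev.supporting_structures |= set(structures)
        for sid in structures:
            if structure_families and sid in structure_families:
                ev.families.add(structure_families[sid])
            if structure_receptors and sid in structure_receptors:
                ev.receptors.add(structure_receptors[sid])
    for pos, summary in effect_map.items():
        ev = positions.setdefault(pos, PositionEvidence())
        ev.in_mutation = True
        ev.mutation_families |= summary.families
        ev.families |= summary.families
        ev.receptors |= summary.receptors
        ev.ligands_affected = len(summary.ligands_affected)
        ev.modalities |= summary.modalities
    return SiteProfile(positions)


@dataclass
class VennPartition:
    structure_only: set[GenericPosition]
    mutation_only: set[GenericPosition]
    both: set[GenericPosition]

    def sizes(self) -> dict[str, int]:
        return {
            "structure_only": len(self.structure_only),
            "mutation_only": len(self.mutation_only),
            "both": len(self.both),
        }


def venn_partition(profile: SiteProfile) -> VennPartition:
    """Partition profiled positions by evidence type (a true partition)."""
    s, m = profile.structural, profile.mutational
    return VennPartition(structure_only=s - m, mutation_only=m - s, both=s & m)


def hotspot_positions(
    profile: SiteProfile, min_families: int = 3
) -> set[GenericPosition]:
    """Positions whose passing mutational evidence spans >= ``min_families``
    distinct receptor families.  Structural support is not required."""
    if min_families < 1:
        raise ParameterError(f"min_families must be >= 1, got {min_families}")
    return {
        pos for pos, ev in profile.positions.items()
        if len(ev.mutation_families) >= min_families
    }


#: Modalities counted in the dual-involvement statistic.
_DUAL_MODALITIES = frozenset({Modality.PAM, Modality.NAM})


def overlap_statistics(profile: SiteProfile) -> dict[str, float]:
    """Family-overlap and PAM/NAM dual-involvement percentages.

    ``pct_multi_family``: share of all profiled positions whose combined
    (structural + mutational) family evidence spans >= 2 families.  A variant
    restricted to mutation-supported positions is emitted alongside, because
    structure-only positions cannot show multi-family mutational overlap.
    ``pct_dual_modality``: share of mutation-supported positions with passing
    evidence for both a PAM and a NAM (allosteric agonists do not count).
    Percentages are rounded half-up; the unrounded values are kept under
    ``*_raw`` keys.
    """
    if len(profile) == 0:
        raise InputError("overlap statistics are undefined on an empty profile")
    multi = [p for p, ev in profile.positions.items() if len(ev.families) >= 2]
    mutated = profile.mutational
    dual = [
        p for p in mutated
        if _DUAL_MODALITIES <= profile.positions[p].modalities
    ]
    stats: dict[str, float] = {}
    frac = 100.0 * len(multi) / len(profile)
    stats["pct_multi_family"] = round_half_up(frac)
    stats["pct_multi_family_raw"] = frac
    if mutated:
        frac_m = 100.0 * len([p for p in multi if p in mutated]) / len(mutated)
        stats["pct_multi_family_mutated_denominator"] = round_half_up(frac_m)
        frac_d = 100.0 * len(dual) / len(mutated)
        stats["pct_dual_modality"] = round_half_up(frac_d)
        stats["pct_dual_modality_raw"] = frac_d
    return stats


class PeripheralFlag(str, Enum):
    SINGLE_LIGAND_SINGLE_RECEPTOR = "single_ligand_single_receptor"
    WILDTYPE_GLYCINE = "wildtype_glycine"
    ADJACENT_TO_SITE = "adjacency_to_site"
    MEMBRANE_FACING = "membrane_facing"


@dataclass
class PeripheralClassification:
    """Rule-based flags for effect positions outside the common site."""

    flags: dict[GenericPosition, set[PeripheralFlag]]


def classify_outside_site(
    effect_map: Mapping[GenericPosition, EvidenceSummary],
    site_set: set[GenericPosition],
    mutation_records: Iterable[MutationRecord],
    threshold: float = 5.0,
    neighbor_map: Optional[Mapping[GenericPosition, set[GenericPosition]]] = None,
    membrane_facing: Optional[set[GenericPosition]] = None,
) -> PeripheralClassification:
    """Flag effect positions that are not part of the common site.

    ``wildtype_glycine`` requires a *passing* record whose wild-type residue
    is Gly at that position -- a non-Gly wild type at the same generic
    position in another receptor does not earn the flag.  Spatial flags are
    computed only when the corresponding annotation (``neighbor_map`` from a
    structure, ``membrane_facing`` orientation set) is supplied.
    """
    passing_by_pos: dict[GenericPosition, list[MutationRecord]] = {}
    for rec in mutation_records:
        if rec.generic is None:
            continue
        if call_effect(rec, threshold).passes:
            passing_by_pos.setdefault(rec.generic, []).append(rec)

    flags: dict[GenericPosition, set[PeripheralFlag]] = {}
    for pos, summary in effect_map.items():
        if pos in site_set:
            continue
        fl: set[PeripheralFlag] = set()
        if len(summary.ligands_affected) == 1 and len(summary.receptors) == 1:
            fl.add(PeripheralFlag.SINGLE_LIGAND_SINGLE_RECEPTOR)
        if any(rec.wt_aa == "G" for rec in passing_by_pos.get(pos, [])):
            fl.add(PeripheralFlag.WILDTYPE_GLYCINE)
        if neighbor_map is not None and neighbor_map.get(pos, set()) & site_set:
            fl.add(PeripheralFlag.ADJACENT_TO_SITE)
        if membrane_facing is not None and pos in membrane_facing:
            fl.add(PeripheralFlag.MEMBRANE_FACING)
        flags[pos] = fl
    return PeripheralClassification(flags)


# ---------------------------------------------------------------------------
# Report output

def write_profile_csv(path: str | Path, profile: SiteProfile) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow([
            "generic_position", "in_structure", "in_mutation", "families",
            "mutation_families", "receptors", "ligands_affected", "modalities",
            "supporting_structures", "receptor_unique",
        ])
        for pos in sorted(profile.positions):
            ev = profile.positions[pos]
            writer.writerow([
                str(pos), int(ev.in_structure), int(ev.in_mutation),
                ";".join(sorted(ev.families)),
                ";".join(sorted(ev.mutation_families)),
                ";".join(sorted(ev.receptors)),
                ev.ligands_affected,
                ";".join(sorted(m.value for m in ev.modalities)),
                ";".join(sorted(ev.supporting_structures)),
                int(ev.receptor_unique),
            ])


def summary_json(
    profile: SiteProfile,
    hotspots: set[GenericPosition],
    peripheral: Optional[PeripheralClassification] = None,
) -> dict:
    venn = venn_partition(profile)
    out = {
        "n_positions": len(profile),
        "n_structural": len(profile.structural),
        "n_mutational": len(profile.mutational),
        "venn": venn.sizes(),
        "hotspots": sorted(str(p) for p in hotspots),
        "n_hotspots": len(hotspots),
        "statistics": overlap_statistics(profile),
    }
    if peripheral is not None:
        out["outside_site"] = {
            str(pos): sorted(f.value for f in fl)
            for pos, fl in peripheral.flags.items()
        }
    return out
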