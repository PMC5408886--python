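"""Study-scale synthetic conditions.

This module pins down one concrete synthetic dataset sized like the curated
class C GPCR corpus the pipeline is meant for: 22 receptors in five families
(eight mGlu-like, two GABA-B-like, three taste-like, two calcium-sensing-like
and seven orphan-like), four receptor-modulator complexes from two mGlu-like
receptors, a 70-modulator ligand panel and a curated-style mutation table in
which eight receptors carry measurements.

The planted common site has 28 positions: 26 with structural contact
evidence, 23 with passing mutational evidence (21 with both).  Nine
positions -- 2x56, 3x32, 3x36, 5x43, 6x50, 6x53, 6x57, 7x37 and 7x40 -- are
planted as hotspots spanning three receptor families, with the central TM6
pair 6x50/6x53 affected through 37 and 24 distinct ligands across six
receptors.  Nineteen of the 28 positions carry evidence from at least two
families and 20 of the 23 mutated positions from both PAM and NAM ligands.
A handful of effect positions outside the site are planted too (a wild-type
glycine pair at 4x42/7x43, a membrane-facing TM1 position, secondary-effect
TM6 positions and several weak single-ligand single-receptor effects), and
the 6x53 column of the alignment is forced to hold an aromatic residue in 19
of the 22 receptors.
"""

from __future__ import annotations

from .mutations import Assay, Modality, Qualitative
from .numbering import GenericPosition
from .synthetic_data import ExtraRecord, PlannedPosition, SyntheticSpec

P = GenericPosition.parse

# receptor blocks (family_sizes below): R01-R08 mGlu-like (FAM1),
# R09-R10 GABA-B-like (FAM2), R11-R13 taste-like (FAM3),
# R14-R15 CaS-like (FAM4), R16-R22 orphan-like (FAM5)
FAMILY_SIZES = (8, 2, 3, 2, 7)

#: Receptors carrying mutagenesis measurements (eight, as in the curated set).
MUTATED_RECEPTORS = ("R01", "R02", "R04", "R05", "R10", "R13", "R14", "R15")

#: The planted common allosteric site (28 positions).
STUDY_SITE = tuple(sorted(P(s) for s in [
    "2x49", "2x52", "2x56",
    "3x32", "3x33", "3x35", "3x36", "3x40", "3x44",
    "5x40", "5x43", "5x44", "5x47",
    "6x46", "6x48", "6x50", "6x53", "6x57", "6x61",
    "7x33", "7x36", "7x37", "7x40", "7x41", "7x45",
    "45x49", "45x52", "45x53",
]))

MUTATION_ONLY = frozenset({P("45x49"), P("45x53")})
STRUCTURE_ONLY = frozenset({P("2x52"), P("3x44"), P("5x47"), P("6x61"), P("7x45")})

STRUCTURAL_POSITIONS = tuple(sorted(set(STUDY_SITE) - MUTATION_ONLY))     # 26
MUTATIONAL_POSITIONS = tuple(sorted(set(STUDY_SITE) - STRUCTURE_ONLY))    # 23

HOTSPOTS = frozenset(
    P(s) for s in ["2x56", "3x32", "3x36", "5x43", "6x50", "6x53", "6x57", "7x37", "7x40"]
)

#: Orientation annotation consumed by the outside-site classification.
MEMBRANE_FACING = frozenset({P("1x46"), P("4x42")})

# three families for every hotspot: mGlu-like + taste-like + CaS-like
_H3 = {
    "6x50": (("R01", "R02", "R04", "R05", "R13", "R14"), 37),
    "6x53": (("R01", "R02", "R04", "R05", "R13", "R14"), 24),
    "6x57": (("R05", "R13", "R14"), 15),
    "5x43": (("R02", "R13", "R15"), 12),
    "7x37": (("R04", "R13", "R14"), 11),
    "7x40": (("R05", "R13", "R15"), 10),
    "3x36": (("R04", "R13", "R14"), 8),
    "2x56": (("R01", "R13", "R14"), 6),
    "3x32": (("R02", "R13", "R15"), 5),
}

# two families (mGlu-like + one other) for ten further positions
_H2 = {
    "2x49": ("R01", "R10"), "3x33": ("R02", "R14"), "3x35": ("R05", "R13"),
    "5x40": ("R04", "R10"), "5x44": ("R05", "R14"), "6x46": ("R01", "R15"),
    "6x48": ("R05", "R13"), "7x33": ("R02", "R10"), "7x36": ("R04", "R15"),
    "45x52": ("R05", "R13"),
}


def study_plan() -> tuple[PlannedPosition, ...]:
    plan = []
    for label, (receptors, n_ligands) in _H3.items():
        plan.append(PlannedPosition(P(label), receptors, n_ligands))
    for label, receptors in _H2.items():
        plan.append(PlannedPosition(P(label), receptors, n_ligands=3))
    # receptor-unique positions (the mGlu5-like site extension flavour)
    plan.append(PlannedPosition(P("3x40"), ("R05",), 3, (Modality.NAM,)))
    plan.append(PlannedPosition(P("7x41"), ("R05",), 2))
    # mutation-only loop positions, each a single modality
    plan.append(PlannedPosition(P("45x49"), ("R05",), 2, (Modality.PAM,)))
    plan.append(PlannedPosition(P("45x53"), ("R04",), 2, (Modality.NAM,)))
    return tuple(plan)


def outside_effects() -> tuple[ExtraRecord, ...]:
    return (
        # membrane-facing TM1 position, one PAM abolished on one receptor
        ExtraRecord(P("1x46"), "R01", "LX01", Modality.PAM,
                    qualitative=Qualitative.ABOLISHED),
        # wild-type glycine pair; the non-Gly receptor shows no effect
        ExtraRecord(P("4x42"), "R02", "LX02", Modality.PAM, fold_effect=56.0,
                    mut_aa="V"),
        ExtraRecord(P("4x42"), "R01", "LX02", Modality.PAM,
                    qualitative=Qualitative.NO_EFFECT, mut_aa="I"),
        ExtraRecord(P("7x43"), "R13", "LX03", Modality.AGONIST,
                    qualitative=Qualitative.ABOLISHED, mut_aa="A"),
        # secondary effects through neighbours of site residues
        ExtraRecord(P("6x54"), "R05", "LX04", Modality.NAM, fold_effect=66.0),
        ExtraRecord(P("6x58"), "R05", "LX05", Modality.NAM, fold_effect=10.0),
        ExtraRecord(P("5x48"), "R05", "LX06", Modality.NAM, fold_effect=7.2),
        ExtraRecord(P("7x44"), "R14", "LX07", Modality.PAM, fold_effect=6.7,
                    assay=Assay.BINDING),
        # weak and rare effects: one ligand, one receptor each
        ExtraRecord(P("3x41"), "R04", "LX08", Modality.NAM, fold_effect=6.1),
        ExtraRecord(P("4x50"), "R05", "LX09", Modality.PAM, fold_effect=6.5),
        ExtraRecord(P("4x51"), "R02", "LX10", Modality.NAM, fold_effect=5.6),
        ExtraRecord(P("5x37"), "R01", "LX11", Modality.PAM, fold_effect=7.0),
        ExtraRecord(P("7x38"), "R05", "LX12", Modality.NAM, fold_effect=5.8),
        ExtraRecord(P("7x47"), "R13", "LX13", Modality.PAM, fold_effect=6.3),
    )


def forced_residues() -> tuple[tuple[str, str, str], ...]:
    forced = [
        ("R02", "4x42", "G"), ("R01", "4x42", "V"), ("R04", "4x42", "L"),
        ("R13", "7x43", "G"), ("R05", "3x40", "P"), ("R05", "5x48", "G"),
    ]
    # 6x53 aromatic in 19 of 22 receptors (planted conservation column)
    aromatics = "FYW"
    for i in range(1, 23):
        rid = f"R{i:02d}"
        aa = aromatics[i % 3] if i <= 19 else "L"
        forced.append((rid, "6x53", aa))
    return tuple(forced)


def study_structures() -> tuple[tuple[str, str, tuple[GenericPosition, ...]], ...]:
    """Four complexes: three of the mGlu5-like receptor, one mGlu1-like.
    The union of their planted contacts is the 26 structural positions."""
    s_all = STRUCTURAL_POSITIONS
    drop2 = {P("2x49"), P("2x52"), P("3x44")}
    drop3 = {P("5x47"), P("6x61"), P("7x36")}
    syn4 = tuple(sorted(set(s_all) - {P("3x40"), P("7x41"), P("2x52"),
                                      P("3x35"), P("6x48"), P("7x33"),
                                      P("5x44"), P("6x46")}))
    return (
        ("SYN1", "R05", s_all),
        ("SYN2", "R05", tuple(sorted(set(s_all) - drop2))),
        ("SYN3", "R05", tuple(sorted(set(s_all) - drop3))),
        ("SYN4", "R01", syn4),
    )


def study_spec(seed: int = 0) -> SyntheticSpec:
    """The full study-scale spec (pure function of the seed)."""
    return SyntheticSpec(
        seed=seed,
        n_receptors=22,
        n_families=5,
        family_sizes=FAMILY_SIZES,
        site_positions=STUDY_SITE,
        structural_positions=STRUCTURAL_POSITIONS,
        mutational_positions=MUTATIONAL_POSITIONS,
        structures=study_structures(),
        plan=study_plan(),
        extra_records=outside_effects(),
        forced_residues=forced_residues(),
        background_records=40,
    )
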