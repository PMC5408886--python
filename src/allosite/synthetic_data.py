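"""Synthetic pipeline inputs with planted ground truth.

Every input the pipeline consumes -- receptor sequences and segment
annotations, receptor-modulator complex coordinates, curated mutation tables,
family assignments -- can be generated here with a known answer planted, so
each stage is testable end to end without any external download.

Receptors share one segment layout: seven transmembrane helices of 37
residues (generic x32..x68, anchor at x50) and a nine-residue second
extracellular loop (45x46..45x54) anchored at a conserved Cys (45x50), joined
by short unannotated linkers.  Sequences follow a family-block process: one
root sequence, per-family ancestors mutated from it with the between-family
probability, members mutated from their ancestor with the within-family
probability, so within-family distances stay below between-family distances.

Complex geometry is an idealized bundle (3.6 residues/turn, 1.5 A rise, one
vertical stack per segment on a wide circle) with a pseudo C-beta per
non-glycine residue.  Realism is not a goal -- controllable distances are:
one ligand atom is placed radially outward of each planted site residue at
cutoff - margin, and the stack spacing guarantees every other residue stays
beyond cutoff + margin, so the distance rule recovers exactly the planted
site.  All generators are pure functions of their spec and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .errors import GenerationError
from .mutations import Assay, Modality, MutationRecord, Qualitative
from .numbering import (
    GenericPosition,
    ReceptorAnnotation,
    SegmentSpan,
    generic_to_seq,
)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# ---------------------------------------------------------------------------
# Segment layout (shared by every synthetic receptor)

TM_LENGTH = 37          # generic x32..x68
ECL2_LENGTH = 9         # generic 45x46..45x54
LINKER = 4
NTERM = 3

#: Segment order along the sequence; ECL2 sits between TM4 and TM5.
SEGMENT_ORDER: tuple[tuple[int, int], ...] = (
    (1, TM_LENGTH), (2, TM_LENGTH), (3, TM_LENGTH), (4, TM_LENGTH),
    (45, ECL2_LENGTH), (5, TM_LENGTH), (6, TM_LENGTH), (7, TM_LENGTH),
)


def default_layout() -> list[SegmentSpan]:
    """The shared segment spans, anchors at the segment centre (index 50)."""
    spans = []
    pos = NTERM + 1
    for seg, length in SEGMENT_ORDER:
        anchor = pos + length // 2
        spans.append(SegmentSpan(seg, pos, pos + length - 1, anchor))
        pos += length + LINKER
    return spans


def sequence_length() -> int:
    spans = default_layout()
    return spans[-1].seq_end + NTERM


def mappable_positions() -> list[GenericPosition]:
    """Every generic position representable under the shared layout."""
    out = []
    for span in default_layout():
        half = (span.seq_end - span.seq_start) // 2
        for idx in range(50 - half, 50 + (span.seq_end - span.anchor_seq_index) + 1):
            out.append(GenericPosition(span.segment, idx))
    return out


# ---------------------------------------------------------------------------
# Spec

@dataclass(frozen=True)
class PlannedPosition:
    """Mutational ground truth for one planted site position."""

    position: GenericPosition
    receptors: tuple[str, ...]
    n_ligands: int = 2
    modalities: tuple[Modality, ...] = (Modality.PAM, Modality.NAM)


@dataclass(frozen=True)
class ExtraRecord:
    """One hand-specified mutation measurement (used to plant effect
    positions outside the common site)."""

    position: GenericPosition
    receptor_id: str
    ligand_id: str
    modality: Modality
    fold_effect: Optional[float] = None
    qualitative: Qualitative = Qualitative.NONE
    mut_aa: Optional[str] = None
    assay: Assay = Assay.FUNCTION


@dataclass(frozen=True)
class SyntheticSpec:
    """All knobs of the generator; defaults are the study-scale conditions."""

    seed: int = 0
    n_receptors: int = 22
    n_families: int = 5
    family_sizes: tuple[int, ...] = ()   # optional explicit block sizes
    within_family_mismatch: float = 0.05
    between_family_mismatch: float = 0.45
    site_positions: tuple[GenericPosition, ...] = ()
    structural_positions: tuple[GenericPosition, ...] = ()
    mutational_positions: tuple[GenericPosition, ...] = ()
    structures: tuple[tuple[str, str, tuple[GenericPosition, ...]], ...] = ()
    # (structure_id, receptor_id, planted contact positions)
    cutoff: float = 5.0
    margin: float = 0.5
    jitter_sigma: float = 0.1
    fold_threshold: float = 5.0
    effect_mu_log: float = math.log(15.0)
    effect_sigma_log: float = 0.8
    pass_probability: float = 1.0
    background_records: int = 40
    pam_fraction: float = 0.5
    n_ligands: int = 70
    plan: tuple[PlannedPosition, ...] = ()
    extra_records: tuple[ExtraRecord, ...] = ()
    forced_residues: tuple[tuple[str, str, str], ...] = ()
    # (receptor_id, generic label, amino acid) forced into the sequence
    author_offset: int = 10   # PDB author numbering = seq_index + offset

    def validate(self) -> None:
        probs = (
            self.within_family_mismatch, self.between_family_mismatch,
            self.pass_probability, self.pam_fraction,
        )
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise GenerationError("probabilities must lie in [0, 1]")
        if self.jitter_sigma < 0 or self.margin < 0 or self.cutoff <= 0:
            raise GenerationError("cutoff must be positive, margin/jitter nonnegative")
        if self.margin == 0 and self.jitter_sigma > 0:
            raise GenerationError("jitter requires a positive margin")
        mappable = set(mappable_positions())
        unknown = set(self.site_positions) - mappable
        if unknown:
            raise GenerationError(
                f"site positions not mappable in the shared layout: "
                f"{sorted(str(p) for p in unknown)}"
            )


def receptor_ids(spec: SyntheticSpec) -> list[str]:
    return [f"R{i + 1:02d}" for i in range(spec.n_receptors)]


def family_assignment(spec: SyntheticSpec) -> dict[str, str]:
    """Receptors split into contiguous family blocks of near-equal size."""
    rids = receptor_ids(spec)
    fams = [f"FAM{i + 1}" for i in range(spec.n_families)]
    if spec.family_sizes:
        if len(spec.family_sizes) != spec.n_families or sum(spec.family_sizes) != len(rids):
            raise GenerationError("family_sizes must cover every receptor once")
        sizes = list(spec.family_sizes)
    else:
        sizes = [len(rids) // spec.n_families] * spec.n_families
        for i in range(len(rids) % spec.n_families):
            sizes[i] += 1
    out, k = {}, 0
    for fam, size in zip(fams, sizes):
        for _ in range(size):
            out[rids[k]] = fam
            k += 1
    return out


# ---------------------------------------------------------------------------
# Receptor set: alignment + annotations + family map

def _mutate(seq: list[str], p: float, rng: np.random.Generator) -> list[str]:
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < p:
            choices = [a for a in AMINO_ACIDS if a != out[i]]
            out[i] = choices[rng.integers(len(choices))]
    return out


def make_receptor_set(
    spec: SyntheticSpec,
) -> tuple[dict[str, str], dict[str, ReceptorAnnotation], dict[str, str]]:
    """Generate ``(alignment, annotations, family_map)``.

    The alignment is gapless (all receptors share the layout), the ECL2
    anchor carries the conserved Cys in every receptor, and any forced
    residues from the spec are written last so planted columns are exact.
    """
    spec.validate()
    rng = np.random.default_rng([spec.seed, 1])
    layout = default_layout()
    n = sequence_length()
    root = [AMINO_ACIDS[rng.integers(20)] for _ in range(n)]
    families = family_assignment(spec)
    ancestors: dict[str, list[str]] = {}
    sequences: dict[str, str] = {}
    annotations: dict[str, ReceptorAnnotation] = {}
    ecl2_anchor = next(s.anchor_seq_index for s in layout if s.segment == 45)

    forced: dict[tuple[str, str], str] = {
        (rid, label): aa for rid, label, aa in spec.forced_residues
    }
    for rid in receptor_ids(spec):
        fam = families[rid]
        if fam not in ancestors:
            # halve so the *pairwise* mismatch between two family members
            # approaches the configured probability
            ancestors[fam] = _mutate(root, spec.between_family_mismatch / 2, rng)
        seq = _mutate(ancestors[fam], spec.within_family_mismatch / 2, rng)
        seq[ecl2_anchor - 1] = "C"   # conserved ECL2 cysteine (45x50)
        ann = ReceptorAnnotation(rid, list(layout), "")
        for (rid2, label), aa in forced.items():
            if rid2 != rid:
                continue
            idx = generic_to_seq(ann, GenericPosition.parse(label))
            if idx is None:
                raise GenerationError(f"forced residue {label} not mappable")
            seq[idx - 1] = aa
        sequences[rid] = "".join(seq)
        annotations[rid] = replace_sequence(ann, sequences[rid])
    return sequences, annotations, families


def replace_sequence(ann: ReceptorAnnotation, seq: str) -> ReceptorAnnotation:
    return ReceptorAnnotation(ann.receptor_id, list(ann.segments), seq)


# ---------------------------------------------------------------------------
# Complex geometry

BUNDLE_RADIUS = 24.0     # stack-centre circle; spacing guarantees clearance
HELIX_RADIUS = 2.3       # C-alpha distance from the stack axis
CB_EXTENSION = 1.5       # pseudo side chain beyond C-alpha, radially outward
RISE = 1.5               # A per residue
TWIST = math.radians(100.0)   # 3.6 residues/turn

_THREE = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR",
}


def _residue_geometry(ann: ReceptorAnnotation) -> dict[int, dict[str, np.ndarray]]:
    """Coordinates for every annotated residue: CA, N, C, O and (non-Gly) CB.

    Each segment is one vertical helical stack on the bundle circle; the
    pseudo C-beta points radially away from the stack axis.
    """
    coords: dict[int, dict[str, np.ndarray]] = {}
    n_slots = len(ann.segments)
    for slot, span in enumerate(ann.segments):
        theta = 2.0 * math.pi * slot / n_slots
        centre = np.array([
            BUNDLE_RADIUS * math.cos(theta), BUNDLE_RADIUS * math.sin(theta), 0.0
        ])
        for j, seq_index in enumerate(range(span.seq_start, span.seq_end + 1)):
            phi = theta + TWIST * j
            radial = np.array([math.cos(phi), math.sin(phi), 0.0])
            ca = centre + HELIX_RADIUS * radial + np.array([0.0, 0.0, RISE * j])
            atoms = {
                "CA": ca,
                "N": ca + np.array([-0.5, 0.0, 0.6]),
                "C": ca + np.array([0.5, 0.0, -0.6]),
                "O": ca + np.array([0.9, 0.5, -0.6]),
            }
            aa = ann.sequence[seq_index - 1] if ann.sequence else "A"
            if aa != "G":
                atoms["CB"] = ca + CB_EXTENSION * radial
            coords[seq_index] = atoms
    return coords


def _round3(x: np.ndarray) -> np.ndarray:
    return np.round(np.asarray(x, dtype=float), 3)


def _place_ligand_atom(
    target: np.ndarray,
    direction: np.ndarray,
    cutoff: float,
    margin: float,
    jitter_sigma: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One ligand atom at ``cutoff - margin`` from the target test atom.

    Gaussian jitter is clipped to 0.9 * margin so the contact guarantee
    survives it.  Coordinates are quantized to the PDB's three decimals; at
    margin zero the atom is nudged inward by thousandths until the quantized
    distance is at (or immediately below) the cutoff.
    """
    u = direction / np.linalg.norm(direction)
    jitter = np.zeros(3)
    if jitter_sigma > 0:
        jitter = rng.normal(0.0, jitter_sigma, 3)
        norm = np.linalg.norm(jitter)
        cap = 0.9 * margin
        if norm > cap:
            jitter *= cap / norm
    t = _round3(target)
    for shrink in (0.0, 0.002, 0.004, 0.006):
        cand = _round3(target + (cutoff - margin - shrink) * u + jitter)
        if np.linalg.norm(cand - t) <= cutoff:
            return cand
    raise GenerationError("could not quantize ligand atom inside the cutoff")


def make_complex(
    spec: SyntheticSpec,
    receptor_id: str,
    annotation: ReceptorAnnotation,
    site_positions: Sequence[GenericPosition],
    structure_id: str = "SYN",
) -> str:
    """PDB text for one receptor-modulator complex.

    One ligand atom is planted within ``cutoff - margin`` of each planted
    position's side chain (C-alpha for glycine) and the construction is then
    verified: every ligand atom must stay beyond ``cutoff + margin - jitter``
    of every other residue's test atoms, else generation fails.
    """
    spec.validate()
    rng = np.random.default_rng([spec.seed, 3, _stable_hash(structure_id)])
    coords = _residue_geometry(annotation)
    targets: dict[GenericPosition, tuple[int, np.ndarray, np.ndarray]] = {}
    for pos in site_positions:
        seq_index = generic_to_seq(annotation, pos)
        if seq_index is None or seq_index not in coords:
            raise GenerationError(f"{receptor_id}: {pos} not in the structure")
        atoms = coords[seq_index]
        target = atoms.get("CB", atoms["CA"])
        # radial direction away from the owning stack axis
        span = next(s for s in annotation.segments if seq_index in s)
        slot = annotation.segments.index(span)
        theta = 2.0 * math.pi * slot / len(annotation.segments)
        centre = np.array([
            BUNDLE_RADIUS * math.cos(theta), BUNDLE_RADIUS * math.sin(theta), 0.0
        ])
        direction = np.array(atoms["CA"]) - centre
        direction[2] = 0.0
        targets[pos] = (seq_index, target, direction)

    ligand_atoms: list[np.ndarray] = []
    for pos in sorted(targets):
        seq_index, target, direction = targets[pos]
        ligand_atoms.append(
            _place_ligand_atom(
                target, direction, spec.cutoff, spec.margin, spec.jitter_sigma, rng
            )
        )

    # verification scan against quantized coordinates
    planted_seq = {targets[p][0] for p in targets}
    clearance = spec.cutoff + spec.margin - 0.9 * spec.margin if spec.margin > 0 else spec.cutoff
    for seq_index, atoms in coords.items():
        test = [v for k, v in atoms.items() if k in ("CA", "CB")]
        for lig in ligand_atoms:
            dmin = min(float(np.linalg.norm(_round3(a) - lig)) for a in test)
            if seq_index not in planted_seq and dmin < clearance - 0.01:
                raise GenerationError(
                    f"{structure_id}: ligand atom violates clearance at residue "
                    f"{seq_index} ({dmin:.2f} A)"
                )

    lines = [
        f"HEADER    SYNTHETIC COMPLEX {structure_id:<39s}",
        f"REMARK 250 SYNTHETIC BUNDLE receptor={receptor_id} seed={spec.seed}",
    ]
    serial = 1
    for seq_index in sorted(coords):
        atoms = coords[seq_index]
        aa = annotation.sequence[seq_index - 1] if annotation.sequence else "A"
        resname = _THREE.get(aa, "ALA")
        author = seq_index + spec.author_offset
        for name in ("N", "CA", "C", "O", "CB"):
            if name not in atoms:
                continue
            x, y, z = _round3(atoms[name])
            lines.append(
                f"ATOM  {serial:5d}  {name:<3s} {resname:>3s} A{author:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}          "
                f"{name[0]:>2s}"
            )
            serial += 1
    lines.append(f"TER   {serial:5d}      {'ALA':>3s} A{0:4d}")
    serial += 1
    for i, lig in enumerate(ligand_atoms, start=1):
        x, y, z = lig
        name = f"C{i}"
        lines.append(
            f"HETATM{serial:5d}  {name:<3s} LIG X 900    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}          "
            f"{'C':>2s}"
        )
        serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


def _stable_hash(text: str) -> int:
    h = 0
    for ch in text:
        h = (h * 131 + ord(ch)) % (2**31 - 1)
    return h


# ---------------------------------------------------------------------------
# Mutation table

def _ligand_pool(spec: SyntheticSpec) -> dict[str, Modality]:
    n_pam = int(round(spec.n_ligands * spec.pam_fraction))
    pool = {}
    for i in range(spec.n_ligands):
        modality = Modality.PAM if i < n_pam else Modality.NAM
        pool[f"L{i + 1:02d}"] = modality
    return pool


def _sample_passing_fold(spec: SyntheticSpec, rng: np.random.Generator) -> float:
    for _ in range(1000):
        fold = float(np.exp(rng.normal(spec.effect_mu_log, spec.effect_sigma_log)))
        if fold > spec.fold_threshold:
            return round(fold, 2)
    # lognormal mass below threshold is tiny for the defaults; shift as last resort
    return round(spec.fold_threshold * 1.5, 2)


def _mutant_aa(wt: str, rng: np.random.Generator) -> str:
    choices = [a for a in AMINO_ACIDS if a != wt]
    return choices[rng.integers(len(choices))]


def make_mutation_table(
    spec: SyntheticSpec,
    annotations: Mapping[str, ReceptorAnnotation],
    family_map: Mapping[str, str],
) -> tuple[list[MutationRecord], dict[GenericPosition, set[str]]]:
    """Generate the curated-style mutation table.

    Planted positions receive passing folds (sampled above the threshold,
    subject to ``pass_probability``) across their planned receptors, ligands
    and modalities; background records at non-site positions stay at or below
    the threshold or report no effect.  Returns ``(records, truth)`` where
    ``truth`` maps each planted position to the families planned for it.
    """
    spec.validate()
    rng = np.random.default_rng([spec.seed, 2])
    pool = _ligand_pool(spec)
    by_modality: dict[Modality, list[str]] = {}
    for lig, m in pool.items():
        by_modality.setdefault(m, []).append(lig)

    plan = spec.plan or _default_plan(spec, family_map, rng)
    records: list[MutationRecord] = []
    truth: dict[GenericPosition, set[str]] = {}

    for planned in plan:
        pos = planned.position
        ligands: list[str] = []
        # cycle the planned modalities so each contributes ligands
        mods = list(planned.modalities)
        k = 0
        while len(ligands) < planned.n_ligands:
            src = by_modality.get(mods[k % len(mods)], [])
            pick = src[int(rng.integers(len(src)))]
            if pick not in ligands:
                ligands.append(pick)
            k += 1
        truth.setdefault(pos, set())
        for i, lig in enumerate(ligands):
            rid = planned.receptors[i % len(planned.receptors)]
            ann = annotations[rid]
            seq_index = generic_to_seq(ann, pos)
            if seq_index is None:
                raise GenerationError(f"{rid}: planted position {pos} unmappable")
            wt = ann.sequence[seq_index - 1]
            passing = rng.random() < spec.pass_probability
            fold = (
                _sample_passing_fold(spec, rng)
                if passing
                else round(1.0 + float(rng.random()) * (spec.fold_threshold - 1.0), 2)
            )
            records.append(MutationRecord(
                receptor_id=rid,
                family=family_map[rid],
                seq_index=seq_index,
                generic=pos,
                wt_aa=wt,
                mut_aa=_mutant_aa(wt, rng),
                ligand_id=lig,
                modality=pool[lig],
                assay=Assay.BINDING if rng.random() < 0.5 else Assay.FUNCTION,
                fold_effect=fold,
                reference="synthetic",
            ))
            if passing:
                truth[pos].add(family_map[rid])

    # background: below-threshold or no-effect records away from the site
    site = set(spec.site_positions) | {e.position for e in spec.extra_records}
    background = [p for p in mappable_positions() if p not in site]
    rids = [r for r in receptor_ids(spec) if r in annotations]
    for _ in range(spec.background_records):
        pos = background[int(rng.integers(len(background)))]
        rid = rids[int(rng.integers(len(rids)))]
        ann = annotations[rid]
        seq_index = generic_to_seq(ann, pos)
        if seq_index is None:
            continue
        wt = ann.sequence[seq_index - 1]
        lig = list(pool)[int(rng.integers(len(pool)))]
        if rng.random() < 0.3:
            fold, qual = None, Qualitative.NO_EFFECT
        else:
            fold, qual = round(1.0 + float(rng.random()) * 3.5, 2), Qualitative.NONE
        records.append(MutationRecord(
            receptor_id=rid, family=family_map[rid], seq_index=seq_index,
            generic=pos, wt_aa=wt, mut_aa=_mutant_aa(wt, rng), ligand_id=lig,
            modality=pool[lig],
            assay=Assay.FUNCTION, fold_effect=fold, qualitative=qual,
            reference="synthetic-background",
        ))

    for extra in spec.extra_records:
        ann = annotations[extra.receptor_id]
        seq_index = generic_to_seq(ann, extra.position)
        if seq_index is None:
            raise GenerationError(
                f"{extra.receptor_id}: extra position {extra.position} unmappable"
            )
        wt = ann.sequence[seq_index - 1]
        records.append(MutationRecord(
            receptor_id=extra.receptor_id,
            family=family_map[extra.receptor_id],
            seq_index=seq_index,
            generic=extra.position,
            wt_aa=wt,
            mut_aa=extra.mut_aa or _mutant_aa(wt, rng),
            ligand_id=extra.ligand_id,
            modality=extra.modality,
            assay=extra.assay,
            fold_effect=extra.fold_effect,
            qualitative=extra.qualitative,
            reference="synthetic-extra",
        ))
    return records, truth


def _default_plan(
    spec: SyntheticSpec,
    family_map: Mapping[str, str],
    rng: np.random.Generator,
) -> tuple[PlannedPosition, ...]:
    """Spread the mutational site positions over 1-3 families at random."""
    by_family: dict[str, list[str]] = {}
    for rid, fam in family_map.items():
        by_family.setdefault(fam, []).append(rid)
    fams = sorted(by_family)
    positions = spec.mutational_positions or spec.site_positions
    plan = []
    for pos in positions:
        k = int(rng.integers(1, min(3, len(fams)) + 1))
        chosen = list(rng.choice(fams, size=k, replace=False))
        receptors = tuple(by_family[f][int(rng.integers(len(by_family[f])))] for f in chosen)
        plan.append(PlannedPosition(
            position=pos, receptors=receptors,
            n_ligands=max(2, k),
            modalities=(Modality.PAM, Modality.NAM),
        ))
    return tuple(plan)


# ---------------------------------------------------------------------------
# Random specs for property testing and the full bundle writer

def random_spec(
    seed: int,
    n_receptors: int = 8,
    n_families: int = 3,
    site_size: int = 10,
    n_structures: int = 2,
) -> SyntheticSpec:
    """A randomized closed-loop spec: random planted site, random split into
    structural / mutational evidence (every position keeps at least one)."""
    rng = np.random.default_rng([seed, 7])
    candidates = mappable_positions()
    idx = rng.choice(len(candidates), size=site_size, replace=False)
    site = tuple(sorted(candidates[i] for i in idx))
    structural, mutational = [], []
    for pos in site:
        r = rng.random()
        if r < 0.4:
            structural.append(pos)
        elif r < 0.7:
            mutational.append(pos)
        else:
            structural.append(pos)
            mutational.append(pos)
    if not structural:
        structural.append(site[0])
    if not mutational:
        mutational.append(site[-1])
    rids = [f"R{i + 1:02d}" for i in range(n_receptors)]
    structures = tuple(
        (f"SYN{i + 1}", rids[i % min(2, n_receptors)], tuple(structural))
        for i in range(n_structures)
    )
    return SyntheticSpec(
        seed=seed,
        n_receptors=n_receptors,
        n_families=n_families,
        site_positions=site,
        structural_positions=tuple(structural),
        mutational_positions=tuple(mutational),
        structures=structures,
        background_records=20,
    )


@dataclass
class Bundle:
    """All generated inputs of one run, in memory and (optionally) on disk."""

    spec: SyntheticSpec
    alignment: dict[str, str]
    annotations: dict[str, ReceptorAnnotation]
    family_map: dict[str, str]
    structures: dict[str, tuple[str, str]]     # structure_id -> (receptor, pdb text)
    records: list[MutationRecord]
    truth_families: dict[GenericPosition, set[str]]


def make_bundle(spec: SyntheticSpec) -> Bundle:
    alignment, annotations, family_map = make_receptor_set(spec)
    structures = {}
    for sid, rid, positions in spec.structures:
        structures[sid] = (
            rid, make_complex(spec, rid, annotations[rid], positions, sid)
        )
    records, truth = make_mutation_table(spec, annotations, family_map)
    return Bundle(spec, alignment, annotations, family_map, structures, records, truth)


def write_bundle(bundle: Bundle, outdir: str | Path) -> dict[str, Path]:
    """Write every artifact in the exact formats the pipeline reads."""
    import csv

    from .fastaio import write_fasta
    from .mutations import write_mutation_table
    from .numbering import write_annotation_table

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["alignment"] = out / "alignment.fasta"
    write_fasta(paths["alignment"], bundle.alignment)
    paths["annotations"] = out / "annotations.csv"
    write_annotation_table(paths["annotations"], bundle.annotations.values())
    paths["families"] = out / "families.csv"
    with open(paths["families"], "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["receptor_id", "family"])
        for rid, fam in bundle.family_map.items():
            writer.writerow([rid, fam])
    paths["mutations"] = out / "mutations.csv"
    write_mutation_table(paths["mutations"], bundle.records)

    structure_rows = []
    for sid, (rid, text) in bundle.structures.items():
        pdb_path = out / f"{sid}.pdb"
        pdb_path.write_text(text)
        structure_rows.append({
            "structure_id": sid, "path": pdb_path.name, "receptor_id": rid,
            "chain": "A", "chain_offset": -bundle.spec.author_offset,
            "ligand": "LIG", "cutoff": bundle.spec.cutoff,
        })
    paths["structures"] = out / "structures.csv"
    with open(paths["structures"], "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(structure_rows[0]) if structure_rows
                                else ["structure_id", "path", "receptor_id", "chain",
                                      "chain_offset", "ligand", "cutoff"])
        writer.writeheader()
        writer.writerows(structure_rows)

    paths["site"] = out / "site_positions.txt"
    paths["site"].write_text(
        "\n".join(str(p) for p in sorted(bundle.spec.site_positions)) + "\n"
    )
    return paths
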