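"""PDB parsing and distance-rule extraction of allosteric-site residues.

A residue is part of the modulator contact set when its C-alpha atom or any
side-chain heavy atom lies within the cutoff (default 5.0 A, inclusive) of any
atom of the co-crystallized modulator.  Backbone N, C, O (and OXT) are never
tested; glycine is testable through its C-alpha only.  Author residue
numbering in the PDB file is reconciled to 1-based sequence numbering by a
constant per-chain offset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionWarning
from scipy.spatial.distance import cdist

from .errors import ConfigurationError, ParseError, SelectionError
from .numbering import GenericPosition, ReceptorAnnotation, assign_generic

#: Mainchain atoms excluded from the distance test (C-alpha IS tested).
BACKBONE_ATOMS = frozenset({"N", "C", "O", "OXT"})


@dataclass(frozen=True)
class AtomRecord:
    """One heavy atom of the parsed structure, offset-corrected."""

    chain: str
    residue_seq: int          # author numbering as written in the file
    seq_index: int            # residue_seq + per-chain offset (sequence numbering)
    residue_name: str
    atom_name: str
    element: str
    coords: tuple[float, float, float]
    altloc: str
    occupancy: float
    is_hetero: bool


@dataclass(frozen=True)
class LigandSelection:
    """The co-crystallized modulator, selected by HET code (optionally chain)."""

    het_code: str
    chain: Optional[str] = None


@dataclass
class ContactSet:
    """Generic positions within ``cutoff`` of the ligand in one structure."""

    structure_id: str
    receptor_id: str
    positions: set[GenericPosition]
    cutoff: float
    min_distance: dict[GenericPosition, float] = field(default_factory=dict)
    supporting_atom: dict[GenericPosition, str] = field(default_factory=dict)
    unmapped: list[tuple[str, int, float]] = field(default_factory=list)
    # (chain, seq_index, min_distance) of in-contact residues without a generic label


def read_structure(
    path: str | Path,
    chain_offset_table: Optional[Mapping[str, int]] = None,
) -> list[AtomRecord]:
    """Parse a PDB file into heavy-atom records.

    Hydrogen (and deuterium) atoms are dropped.  For alternate locations only
    the highest-occupancy conformer is kept (ties resolved towards altloc
    'A').  Insertion codes are not supported.  ``chain_offset_table`` maps a
    chain id to the constant added to author numbering to obtain sequence
    numbering; chains absent from the table keep author numbering.
    """
    parser = PDBParser(QUIET=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", PDBConstructionWarning)
            structure = parser.get_structure("s", str(path))
    except Exception as exc:  # Bio.PDB raises assorted exceptions on bad input
        raise ParseError(f"cannot parse PDB file {path}: {exc}") from exc

    model = next(iter(structure))
    file_chains = {chain.id for chain in model}
    if chain_offset_table:
        unknown = set(chain_offset_table) - file_chains
        if unknown:
            raise ConfigurationError(
                f"offset table names chains absent from {path}: {sorted(unknown)}"
            )

    records: list[AtomRecord] = []
    for chain in model:
        offset = (chain_offset_table or {}).get(chain.id, 0)
        for residue in chain:
            hetflag, resseq, icode = residue.id
            if icode.strip():
                raise ParseError(
                    f"insertion code {icode!r} at {chain.id}{resseq} is unsupported"
                )
            is_hetero = bool(hetflag.strip())
            # Group altlocs by atom name; keep highest occupancy, ties -> 'A'.
            by_name: dict[str, list] = {}
            for atom in residue.get_unpacked_list():
                by_name.setdefault(atom.get_name(), []).append(atom)
            for name, atoms in by_name.items():
                atom = min(
                    atoms,
                    key=lambda a: (-(a.get_occupancy() or 0.0), a.get_altloc() or "A"),
                )
                element = (atom.element or "").upper()
                if element in ("H", "D"):
                    continue
                records.append(
                    AtomRecord(
                        chain=chain.id,
                        residue_seq=resseq,
                        seq_index=resseq + offset,
                        residue_name=residue.get_resname().strip(),
                        atom_name=name,
                        element=element,
                        coords=tuple(float(x) for x in atom.get_coord()),
                        altloc=atom.get_altloc() or " ",
                        occupancy=float(atom.get_occupancy() or 1.0),
                        is_hetero=is_hetero,
                    )
                )
    return records


def _is_contact_test_atom(atom: AtomRecord) -> bool:
    """C-alpha or a side-chain heavy atom; backbone N/C/O/OXT never tested."""
    if atom.atom_name == "CA":
        return True
    return atom.atom_name not in BACKBONE_ATOMS


def contact_positions(
    atoms: Sequence[AtomRecord],
    ligand: LigandSelection,
    ann: ReceptorAnnotation,
    cutoff: float = 5.0,
    structure_id: str = "",
    receptor_chains: Optional[Iterable[str]] = None,
) -> ContactSet:
    """Residues with C-alpha or side-chain atoms within ``cutoff`` of any
    ligand atom (inclusive), as generic positions.

    When the structure holds several receptor chains (protomers) the per-chain
    contact sets are unioned.  In-contact residues that carry no generic label
    are reported in ``ContactSet.unmapped`` rather than silently dropped.
    """
    lig = [
        a for a in atoms
        if a.is_hetero and a.residue_name == ligand.het_code
        and (ligand.chain is None or a.chain == ligand.chain)
    ]
    if not lig:
        raise SelectionError(
            f"ligand {ligand.het_code!r} (chain={ligand.chain}) matches no atom"
        )
    lig_xyz = np.array([a.coords for a in lig], dtype=float)

    allowed_chains = set(receptor_chains) if receptor_chains is not None else None
    residues: dict[tuple[str, int], list[AtomRecord]] = {}
    for a in atoms:
        if a.is_hetero:
            continue
        if allowed_chains is not None and a.chain not in allowed_chains:
            continue
        residues.setdefault((a.chain, a.seq_index), []).append(a)

    cset = ContactSet(
        structure_id=structure_id,
        receptor_id=ann.receptor_id,
        positions=set(),
        cutoff=cutoff,
    )
    for (chain, seq_index), res_atoms in sorted(residues.items()):
        test = [a for a in res_atoms if _is_contact_test_atom(a)]
        if not test:
            continue
        xyz = np.array([a.coords for a in test], dtype=float)
        dists = cdist(xyz, lig_xyz)
        dmin = float(dists.min())
        if dmin > cutoff:
            continue
        i = int(np.unravel_index(np.argmin(dists), dists.shape)[0])
        pos = assign_generic(ann, seq_index)
        if pos is None:
            warnings.warn(
                f"in-contact residue {chain}{seq_index} has no generic label",
                stacklevel=2,
            )
            cset.unmapped.append((chain, seq_index, dmin))
            continue
        cset.positions.add(pos)
        if pos not in cset.min_distance or dmin < cset.min_distance[pos]:
            cset.min_distance[pos] = dmin
            cset.supporting_atom[pos] = test[i].atom_name
    return cset


def union_contacts(contact_sets: Sequence[ContactSet]) -> dict[GenericPosition, set[str]]:
    """Union of contact positions across structures.

    Returns ``{position: {structure ids supporting it}}`` so that both
    per-receptor and pooled readings of the union remain available.
    """
    cutoffs = {cs.cutoff for cs in contact_sets}
    if len(cutoffs) > 1:
        raise ConfigurationError(f"mixed cutoffs in union: {sorted(cutoffs)}")
    union: dict[GenericPosition, set[str]] = {}
    for cs in contact_sets:
        for pos in cs.positions:
            union.setdefault(pos, set()).add(cs.structure_id)
    return union


def write_contact_csv(path: str | Path, contact_sets: Sequence[ContactSet]) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["structure_id", "receptor_id", "generic_position",
                         "min_distance_A", "supporting_atom"])
        for cs in contact_sets:
            for pos in sorted(cs.positions):
                writer.writerow([
                    cs.structure_id, cs.receptor_id, str(pos),
                    f"{cs.min_distance.get(pos, float('nan')):.3f}",
                    cs.supporting_atom.get(pos, ""),
                ])
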