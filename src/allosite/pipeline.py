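"""End-to-end orchestration: from input files to the consolidated report.

The run reads receptor annotations, structures, the mutation table, the
alignment and the family map; computes per-structure contact sets, effect
calls, the merged site profile with Venn partition / hotspots / overlap
statistics, the outside-site classification, conservation of the site
columns and the two UPGMA trees (whole TMD and site columns only); and
writes every stage result plus a machine-readable run log into the output
directory.  Outputs are deterministic for fixed inputs.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import yaml

from . import __version__
from .conservation import conservation_report, write_conservation_csv
from .errors import AllositeError, ConfigurationError
from .fastaio import read_fasta
from .integration import (
    PeripheralClassification,
    SiteProfile,
    build_site_profile,
    classify_outside_site,
    hotspot_positions,
    summary_json,
    venn_partition,
    write_profile_csv,
)
from .mutations import (
    MutationRecord,
    conflicting_duplicates,
    effect_positions,
    read_mutation_table,
)
from .numbering import GenericPosition, ReceptorAnnotation, read_annotation_table
from .phylogeny import (
    Tree,
    distance_matrix,
    family_coherence,
    upgma,
    write_distance_csv,
    write_newick,
)
from .structures import (
    ContactSet,
    LigandSelection,
    contact_positions,
    read_structure,
    union_contacts,
    write_contact_csv,
)


@dataclass
class RunConfig:
    """Paths and thresholds of one pipeline run (YAML-loadable)."""

    structures: Optional[Path] = None     # structures table CSV
    mutations: Optional[Path] = None
    alignment: Optional[Path] = None
    annotations: Optional[Path] = None
    families: Optional[Path] = None
    site_positions: Optional[Path] = None  # optional site definition (one label/line)
    membrane_facing: tuple[str, ...] = ()
    cutoff: float = 5.0
    fold_threshold: float = 5.0
    hotspot_min_families: int = 3
    distance_model: str = "poisson"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cutoff <= 0 or self.fold_threshold <= 0:
            raise ConfigurationError("cutoff and fold threshold must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        base = Path(path).parent
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        for key in ("structures", "mutations", "alignment", "annotations",
                    "families", "site_positions"):
            if raw.get(key):
                kwargs[key] = base / raw[key]
        for key in ("cutoff", "fold_threshold", "hotspot_min_families",
                    "distance_model", "seed"):
            if key in raw:
                kwargs[key] = raw[key]
        if raw.get("membrane_facing"):
            kwargs["membrane_facing"] = tuple(str(x) for x in raw["membrane_facing"])
        return cls(**kwargs)


def read_family_map(path: str | Path) -> dict[str, str]:
    with open(path, newline="") as fh:
        return {row["receptor_id"]: row["family"] for row in csv.DictReader(fh)}


def read_structure_table(path: str | Path) -> list[dict]:
    base = Path(path).parent
    rows = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            rows.append({
                "structure_id": row["structure_id"],
                "path": base / row["path"],
                "receptor_id": row["receptor_id"],
                "chain": row["chain"],
                "chain_offset": int(row["chain_offset"]),
                "ligand": row["ligand"],
                "cutoff": float(row.get("cutoff") or 5.0),
            })
    return rows


def read_site_list(path: str | Path) -> set[GenericPosition]:
    return {
        GenericPosition.parse(line)
        for line in Path(path).read_text().splitlines()
        if line.strip()
    }


def compute_contacts(
    structure_rows: Sequence[dict],
    annotations: Mapping[str, ReceptorAnnotation],
    cutoff: float,
) -> list[ContactSet]:
    sets = []
    for row in structure_rows:
        atoms = read_structure(row["path"], {row["chain"]: row["chain_offset"]})
        ann = annotations[row["receptor_id"]]
        sets.append(contact_positions(
            atoms, LigandSelection(row["ligand"]), ann,
            cutoff=cutoff, structure_id=row["structure_id"],
            receptor_chains=[row["chain"]],
        ))
    return sets


def tmd_subsequence(ann: ReceptorAnnotation) -> str:
    """Concatenated residues of the seven helices (tree input)."""
    parts = [
        ann.sequence[s.seq_start - 1:s.seq_end]
        for s in ann.segments if 1 <= s.segment <= 7
    ]
    return "".join(parts)


def site_subsequence(
    ann: ReceptorAnnotation, positions: Sequence[GenericPosition]
) -> str:
    """Residues at the site columns; '-' where the receptor lacks a position."""
    from .numbering import generic_to_seq

    out = []
    for pos in sorted(positions):
        idx = generic_to_seq(ann, pos)
        out.append(ann.sequence[idx - 1] if idx else "-")
    return "".join(out)


@dataclass
class ReportBundle:
    contact_sets: list[ContactSet]
    records: list[MutationRecord]
    profile: SiteProfile
    hotspots: set[GenericPosition]
    peripheral: Optional[PeripheralClassification]
    summary: dict
    trees: dict[str, Tree] = field(default_factory=dict)
    coherence: dict[str, dict[str, bool]] = field(default_factory=dict)


def run_pipeline(cfg: RunConfig, outdir: str | Path) -> ReportBundle:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    warnings_log: list[str] = []

    def _stage(name: str):
        class _Ctx:
            def __enter__(self):
                return None

            def __exit__(self, exc_type, exc, tb):
                if exc is not None and isinstance(exc, AllositeError):
                    raise AllositeError(f"[{name}] {exc}") from exc
                return False

        return _Ctx()

    with _stage("inputs"):
        sequences = read_fasta(cfg.alignment) if cfg.alignment else {}
        ungapped = {k: v.replace("-", "") for k, v in sequences.items()}
        annotations = (
            read_annotation_table(cfg.annotations, ungapped) if cfg.annotations else {}
        )
        family_map = read_family_map(cfg.families) if cfg.families else {}
        site_def = read_site_list(cfg.site_positions) if cfg.site_positions else None

    with _stage("contacts"):
        contact_sets: list[ContactSet] = []
        if cfg.structures:
            rows = read_structure_table(cfg.structures)
            contact_sets = compute_contacts(rows, annotations, cfg.cutoff)
            write_contact_csv(out / "contacts.csv", contact_sets)
            for cs in contact_sets:
                for chain, seq_index, dmin in cs.unmapped:
                    warnings_log.append(
                        f"unmapped contact residue {cs.structure_id}:{chain}{seq_index}"
                        f" at {dmin:.2f} A"
                    )
        contact_union = union_contacts(contact_sets)

    with _stage("effects"):
        records: list[MutationRecord] = []
        if cfg.mutations:
            records, rejections = read_mutation_table(cfg.mutations)
            for rownum, problem in rejections:
                warnings_log.append(f"mutation row {rownum} rejected: {problem}")
            for a, b in conflicting_duplicates(records, cfg.fold_threshold):
                warnings_log.append(
                    f"conflicting duplicate: {a.receptor_id} {a.wt_aa}{a.seq_index}"
                    f"{a.mut_aa} x {a.ligand_id}"
                )
        effect_map = effect_positions(records, cfg.fold_threshold)

    with _stage("integrate"):
        structure_families = {}
        structure_receptors = {}
        if cfg.structures:
            for row in rows:
                structure_receptors[row["structure_id"]] = row["receptor_id"]
                fam = family_map.get(row["receptor_id"])
                if fam:
                    structure_families[row["structure_id"]] = fam
        if site_def is not None:
            in_site_effects = {p: s for p, s in effect_map.items() if p in site_def}
        else:
            in_site_effects = dict(effect_map)
        profile = build_site_profile(
            contact_union, in_site_effects, structure_families, structure_receptors
        )
        hotspots = hotspot_positions(profile, cfg.hotspot_min_families)
        membrane = {GenericPosition.parse(s) for s in cfg.membrane_facing} or None
        peripheral = classify_outside_site(
            effect_map, profile.site_set, records,
            threshold=cfg.fold_threshold, membrane_facing=membrane,
        )
        summary = summary_json(profile, hotspots, peripheral)
        write_profile_csv(out / "site_profile.csv", profile)

    with _stage("conserve"):
        if sequences and annotations and len(profile) > 0:
            rows_c = conservation_report(sequences, annotations, profile.site_set)
            write_conservation_csv(out / "conservation.csv", rows_c)

    trees: dict[str, Tree] = {}
    coherence: dict[str, dict[str, bool]] = {}
    with _stage("tree"):
        if annotations and family_map and len(annotations) >= 2:
            tmd_aln = {rid: tmd_subsequence(a) for rid, a in annotations.items()}
            dm = distance_matrix(tmd_aln, cfg.distance_model)
            write_distance_csv(dm, out / "tmd_distances.csv")
            trees["tmd"] = upgma(dm)
            write_newick(trees["tmd"], out / "tmd_tree.nwk")
            coherence["tmd"] = family_coherence(trees["tmd"], family_map)
            if len(profile) > 0:
                site_aln = {
                    rid: site_subsequence(a, sorted(profile.site_set))
                    for rid, a in annotations.items()
                }
                dm_site = distance_matrix(site_aln, cfg.distance_model)
                trees["site"] = upgma(dm_site)
                write_newick(trees["site"], out / "site_tree.nwk")
                coherence["site"] = family_coherence(trees["site"], family_map)
            (out / "family_coherence.json").write_text(
                json.dumps(coherence, indent=2) + "\n"
            )

    summary["parameters"] = {
        "cutoff": cfg.cutoff,
        "fold_threshold": cfg.fold_threshold,
        "hotspot_min_families": cfg.hotspot_min_families,
        "distance_model": cfg.distance_model,
        "seed": cfg.seed,
        "version": __version__,
    }
    summary["warnings"] = warnings_log
    (out / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    (out / "run.log").write_text("\n".join(warnings_log) + "\n")

    return ReportBundle(
        contact_sets=contact_sets,
        records=records,
        profile=profile,
        hotspots=hotspots,
        peripheral=peripheral,
        summary=summary,
        trees=trees,
        coherence=coherence,
    )
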