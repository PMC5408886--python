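# Methods

## Generic residue numbering

Cross-receptor comparison rests on segment-anchored generic labels
`<segment>x<index>`: transmembrane helices are segments 1–7, loops carry the
two-digit code of their flanking helices (second extracellular loop, ECL2,
is 45), and the index counts from each segment's most conserved position,
fixed at 50. The package *consumes* this numbering from a per-receptor
annotation table (segment spans plus one anchor residue each) rather than
deriving it from structure; structure-based corrections for helix bulges
and constrictions are a separate problem and out of scope. Indices below
50 count backwards from the anchor with the same arithmetic (anchor − 1 →
x49), which also fixes the behaviour of ECL2 positions before the conserved
Cys at 45x50. All sequence indices are 1-based; PDB author numbering is
reconciled by one constant offset per chain, and insertion codes are
rejected rather than guessed at.

## Structural contact rule

A residue belongs to a structure's contact set iff the minimum distance
from {its Cα} ∪ {its side-chain heavy atoms} to any ligand atom is ≤ the
cutoff (default 5.0 Å, inclusive at the boundary; distances computed on
unrounded parsed coordinates). Backbone N, C, O and OXT are never tested —
a backbone approach is not a side-chain interaction — while Cα is always
tested, so glycine remains detectable. Hydrogens are dropped; for alternate
locations the highest-occupancy conformer is kept with ties resolved toward
altloc A. When a file holds several receptor chains the per-chain sets are
unioned. In-contact residues with no generic label are *reported*, not
silently dropped, because they usually indicate an annotation gap rather
than noise. Unions across structures keep per-position provenance (the
supporting structure ids), so pooled and per-receptor readings of the union
stay available downstream.

## Effect calling

Each curated record is one mutant × one modulator measurement with either a
direction-agnostic fold-change magnitude (≥ 1) or a qualitative call. A
record passes iff fold > threshold (default 5, strict) or the effect is
"abolished"; "no effect" fails at every threshold. Binding and functional
assays are interchangeable — any single passing measurement marks the
position. Per-position summaries count distinct receptors, families and
ligand ids (two assays of one ligand count once), which makes every derived
statistic invariant under record duplication. Conflicting duplicate reports
for the same mutant × ligand are kept and surfaced in the run log; the
pipeline does not adjudicate between laboratories. Allosteric agonists are
effect-called like any modulator but excluded from the PAM/NAM
dual-involvement statistic, which is a statement about modulators.

## Integration

The site profile is the union of contact and effect positions (optionally
restricted to an externally supplied site definition, mirroring how the
common site is a structural judgement in practice; effect positions outside
it are routed to the peripheral classification). On the profile:

- **Venn partition** — structure-only / mutation-only / both; a true
  partition by construction, checked by the property tests.
- **Hotspots** — positions whose *mutational* families number ≥ 3
  (default). Structural support is deliberately not required: the hotspot
  notion is about independent experimental recurrence across families.
  A structure contributes its receptor's family to the combined family
  evidence used by the overlap statistic, since structure-only positions
  can still recur across families that way.
- **Overlap statistics** — percentage of positions with combined family
  evidence in ≥ 2 families (reported over all profiled positions, with a
  mutation-only-denominator variant alongside, since the natural
  denominator is genuinely ambiguous), and percentage of mutation-supported
  positions with both PAM and NAM passing evidence. Displayed figures are
  rounded half-up; raw values are retained in the JSON.
- **Outside-site flags** — single-ligand/single-receptor (weak, rare),
  wild-type glycine (the effect needs the native Gly: a non-Gly wild type
  at the same generic position never earns the flag), and membrane-facing /
  site-adjacency flags that are computed only when the corresponding
  orientation or neighbour annotation is supplied — they cannot be inferred
  from the inputs alone.

## Distance models and trees

Pairwise distances on aligned sequences exclude columns gapped in either
partner; p is the mismatch fraction and the Poisson correction −ln(1 − p)
is applied on request, with p capped at 0.95 (flagged) to keep distances
finite. A likelihood model under an empirical substitution matrix would
give better branch lengths, but the only claim the trees support here is
qualitative — do families form coherent clades? — which is robust to the
distance model; this is a deliberate simplification. UPGMA merges the
closest cluster pair (ties broken toward the lexicographically smallest
pair of cluster labels, each cluster labelled by its smallest member, so
output is independent of input order), places the merge node at half the
merge distance and updates distances as size-weighted means; the result is
ultrametric to ~1e-12 and verified against a naive definitional
re-implementation. Trees serialize to Newick with branch length = parent
height − child height; reading goes through dendropy. A family is coherent
iff some clade's leaf set equals the family's member set exactly — a
singleton family is trivially coherent.

## Conservation

For each site position the per-receptor residues are gathered through the
numbering (receptors whose segment does not reach the position contribute a
gap) and the fraction carrying each physicochemical class is reported. The
default scheme is multi-class (His is both aromatic and positive; aromatic
= {F, Y, W, H}) and configurable. Both denominators are emitted — receptors
that have the position, and all receptors with gaps counting as
non-matching — because published percentages use either convention without
saying so. Displayed values are rounded half-up; raw values retained.

## Synthetic data

The generator emulates the shape of the real inputs, not their physics:

- **Sequences** — one random root, per-family ancestors mutated from it
  with the between-family probability (halved per branch so the *pairwise*
  mismatch matches the configured value), members mutated from ancestors
  likewise. Defaults 0.05 within / 0.45 between give family blocks whose
  UPGMA trees are coherent with a wide margin. The ECL2 anchor Cys is held
  fixed in every receptor; specific residues (planted conservation columns,
  wild-type glycines) can be forced per receptor after the block process.
- **Complexes** — every segment is a vertical helical stack (1.5 Å rise,
  100° twist, Cα 2.3 Å off the axis, pseudo-Cβ 1.5 Å further out, radially)
  on a circle of radius 24 Å. That radius is deliberately far from a real
  receptor's: with eight stacks it guarantees ≥ 6 Å clearance between any
  ligand atom (placed at cutoff − margin, default 4.5 Å, radially outward
  of its target side chain) and every non-planted residue's test atoms, so
  the contact rule provably recovers exactly the planted site. Gaussian
  placement jitter is clipped to 0.9 × margin to preserve the guarantee,
  and a full distance scan re-verifies it at generation time. PDB
  coordinates quantize to three decimals; at margin 0 the boundary atom is
  nudged inward by ≤ 0.006 Å so the quantized distance stays at or
  immediately below the cutoff.
- **Mutation tables** — planted positions receive folds sampled from a
  log-normal (μ = ln 15, σ = 0.8) conditioned above the threshold, spread
  over planned receptors, ligands and modalities; a pass-probability below
  1 turns planting into a Bernoulli per record (used for calibration
  tests). Background records at non-site positions stay at or below the
  threshold or report no effect. Hand-specified extra records plant
  outside-site effect positions.

What the generator does **not** emulate: real side-chain geometry and
rotamers, loop flexibility, indel-containing alignments, assay noise and
inter-laboratory disagreement, or literature curation bias. Passing the
closed-loop tests therefore shows the pipeline's logic is correct under its
own assumptions, not that the distance or fold thresholds are optimal for
real data.

## Study-scale conditions

`allosite.study` pins one dataset sized like the curated corpus this kind
of analysis runs on: 22 receptors in five families (8/2/3/2/7), eight of
them mutated, four complexes from two mGlu-like receptors, 70 ligands, a
28-position planted site with a 26/23 structural/mutational split (21
both), nine hotspots spanning three families, the central TM6 pair 6x50 /
6x53 affected through 37 and 24 ligands in six receptors, a single ECL2
structural contact at 45x52, an aromatic residue at 6x53 in 19 of 22
receptors, and a dozen planted outside-site effects (membrane-facing TM1,
wild-type glycine pair 4x42/7x43, secondary TM6 effects, weak single-ligand
effects). `scripts/acceptance.py` regenerates this dataset from a seed and
recomputes all of these quantities by running the pipeline; nothing in the
report is hard-coded.

## Numerical choices and limitations

- Cutoff comparisons are inclusive (≤), on unrounded parsed coordinates.
- Fold-threshold comparisons are strict (>); "abolished" passes at any
  threshold, "no effect" at none.
- Percentages are rounded half-up for display only.
- UPGMA ties: lexicographic smallest label pair; deterministic everywhere.
- All randomness flows through explicit integer seeds into
  `numpy.random.default_rng`; no global RNG state.
- mmCIF, insertion codes, symmetry mates and biological assemblies are
  unsupported; structures must be single-model PDB files.
- The site/outside split for mutation-only positions requires an external
  site definition; without one the profile is simply the evidence union.
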