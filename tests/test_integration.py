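import pytest
from hypothesis import given, settings, strategies as st

from allosite.errors import InputError, ParameterError
from allosite.integration import (
    PeripheralFlag,
    build_site_profile,
    classify_outside_site,
    hotspot_positions,
    overlap_statistics,
    round_half_up,
    venn_partition,
)
from allosite.mutations import (
    Assay,
    EvidenceSummary,
    Modality,
    MutationRecord,
    Qualitative,
)
from allosite.numbering import GenericPosition


def P(label):
    return GenericPosition.parse(label)


def _summary(families=("F1",), receptors=("R1",), ligands=("L1",),
             modalities=(Modality.NAM,)):
    return EvidenceSummary(
        receptors=set(receptors), families=set(families),
        ligands_affected=set(ligands), modalities=set(modalities),
    )


class TestBuildProfile:
    def test_union_of_evidence(self):
        contacts = {P("2x56"): {"S1"}, P("6x50"): {"S1", "S2"}}
        effects = {P("6x50"): _summary(), P("7x40"): _summary()}
        profile = build_site_profile(contacts, effects)
        assert profile.site_set == {P("2x56"), P("6x50"), P("7x40")}
        ev = profile.positions[P("6x50")]
        assert ev.in_structure and ev.in_mutation
        assert ev.supporting_structures == {"S1", "S2"}

    def test_empty_effects_gives_structure_profile(self):
        contacts = {P("2x56"): {"S1"}}
        profile = build_site_profile(contacts, {})
        assert profile.site_set == {P("2x56")}
        ev = profile.positions[P("2x56")]
        assert ev.in_structure and not ev.in_mutation and ev.ligands_affected == 0

    def test_structures_contribute_family_evidence(self):
        contacts = {P("2x56"): {"S1"}}
        profile = build_site_profile(
            contacts, {P("2x56"): _summary(families=("F2",))},
            structure_families={"S1": "F1"},
        )
        assert profile.positions[P("2x56")].families == {"F1", "F2"}

    def test_study_profile_cardinality(self, study_bundle):
        """Study-scale merge: 26 structural + 23 mutational -> 28 overall."""
        import tempfile
        from pathlib import Path

        from allosite.mutations import effect_positions
        from allosite.structures import (
            LigandSelection, contact_positions, read_structure, union_contacts,
        )

        spec = study_bundle.spec
        csets = []
        with tempfile.TemporaryDirectory() as td:
            for sid, (rid, text) in study_bundle.structures.items():
                p = Path(td) / f"{sid}.pdb"
                p.write_text(text)
                atoms = read_structure(p, {"A": -spec.author_offset})
                csets.append(contact_positions(
                    atoms, LigandSelection("LIG"), study_bundle.annotations[rid],
                    structure_id=sid,
                ))
        union = union_contacts(csets)
        effects = {
            pos: s for pos, s in effect_positions(study_bundle.records).items()
            if pos in set(spec.site_positions)
        }
        profile = build_site_profile(union, effects)
        assert len(profile) == 28
        assert len(profile.structural) == 26
        assert len(profile.mutational) == 23
        assert venn_partition(profile).sizes()["both"] == 21


class TestVennPartition:
    def test_disjoint_inputs(self):
        profile = build_site_profile({P("2x56"): {"S"}}, {P("7x40"): _summary()})
        venn = venn_partition(profile)
        assert venn.both == set()
        assert venn.structure_only == {P("2x56")}

    def test_identical_inputs(self):
        profile = build_site_profile({P("6x50"): {"S"}}, {P("6x50"): _summary()})
        venn = venn_partition(profile)
        assert venn.structure_only == venn.mutation_only == set()
        assert venn.both == {P("6x50")}

    def test_inclusion_exclusion_with_printed_totals(self):
        # |S| 26 and |M| 23 over a 28-position union force |both| = 21
        assert 26 + 23 - 28 == 21

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.sets(st.integers(32, 68), max_size=20),
           st.sets(st.integers(32, 68), max_size=20))
    def test_true_partition_on_fuzzed_inputs(self, s_idx, m_idx):
        contacts = {P(f"6x{i}"): {"S"} for i in s_idx}
        effects = {P(f"6x{i}"): _summary() for i in m_idx}
        profile = build_site_profile(contacts, effects)
        venn = venn_partition(profile)
        parts = [venn.structure_only, venn.mutation_only, venn.both]
        for i, a in enumerate(parts):
            for b in parts[i + 1:]:
                assert not (a & b)
        assert venn.structure_only | venn.mutation_only | venn.both == profile.site_set
        sizes = venn.sizes()
        assert sizes["both"] == len(s_idx) + len(m_idx) - len(s_idx | m_idx)
        assert sizes["structure_only"] + sizes["both"] == len(profile.structural)
        assert sizes["mutation_only"] + sizes["both"] == len(profile.mutational)


class TestHotspots:
    def _profile(self):
        effects = {
            P("6x50"): _summary(families=("F1", "F2", "F3")),
            P("6x53"): _summary(families=("F1", "F2")),
            P("7x40"): _summary(families=("F1",)),
        }
        return build_site_profile({}, effects)

    def test_planted_three_family_position(self):
        assert hotspot_positions(self._profile()) == {P("6x50")}

    def test_degenerate_threshold_returns_all_mutational(self):
        profile = self._profile()
        assert hotspot_positions(profile, 1) == profile.mutational

    def test_nesting_in_min_families(self):
        profile = self._profile()
        for k in (1, 2, 3):
            assert hotspot_positions(profile, k + 1) <= hotspot_positions(profile, k)

    def test_invalid_threshold(self):
        with pytest.raises(ParameterError):
            hotspot_positions(self._profile(), 0)

    def test_study_hotspots(self, study_bundle):
        from allosite.mutations import effect_positions
        from allosite.study import HOTSPOTS

        effects = {
            pos: s for pos, s in effect_positions(study_bundle.records).items()
            if pos in set(study_bundle.spec.site_positions)
        }
        profile = build_site_profile({}, effects)
        assert hotspot_positions(profile) == set(HOTSPOTS)


class TestOverlapStatistics:
    def test_rounding_reproduces_printed_figure(self):
        # 19 multi-family of 28: 67.86 -> 68 displayed
        effects = {}
        for i in range(19):
            effects[P(f"6x{32 + i}")] = _summary(families=("F1", "F2"))
        for i in range(9):
            effects[P(f"7x{32 + i}")] = _summary(families=("F1",))
        stats = overlap_statistics(build_site_profile({}, effects))
        assert stats["pct_multi_family"] == 68
        assert abs(stats["pct_multi_family_raw"] - 100 * 19 / 28) < 1e-12

    def test_all_single_family_is_zero(self):
        effects = {P("6x50"): _summary(), P("6x53"): _summary()}
        stats = overlap_statistics(build_site_profile({}, effects))
        assert stats["pct_multi_family"] == 0

    def test_all_dual_modality_is_hundred(self):
        effects = {
            P("6x50"): _summary(modalities=(Modality.PAM, Modality.NAM)),
        }
        stats = overlap_statistics(build_site_profile({}, effects))
        assert stats["pct_dual_modality"] == 100

    def test_agonists_do_not_count_as_dual(self):
        effects = {
            P("6x50"): _summary(modalities=(Modality.PAM, Modality.AGONIST)),
        }
        stats = overlap_statistics(build_site_profile({}, effects))
        assert stats["pct_dual_modality"] == 0

    def test_duplication_invariance(self):
        effects = {
            P("6x50"): _summary(families=("F1", "F2"), ligands=("L1", "L1")),
            P("7x40"): _summary(),
        }
        base = overlap_statistics(build_site_profile({}, effects))
        # merging the same evidence twice changes nothing (sets deduplicate)
        again = overlap_statistics(build_site_profile({}, dict(effects)))
        assert base == again

    def test_empty_profile_rejected(self):
        with pytest.raises(InputError):
            overlap_statistics(build_site_profile({}, {}))

    @pytest.mark.parametrize("x,expected", [(0.5, 1), (67.86, 68), (86.5, 87), (86.36, 86)])
    def test_round_half_up(self, x, expected):
        assert round_half_up(x) == expected


class TestOutsideSiteClassification:
    def _gly_record(self, receptor="R2", wt="G", fold=56.0, qual=Qualitative.NONE):
        return MutationRecord(
            receptor_id=receptor, family="F1", seq_index=120,
            generic=P("4x42"), wt_aa=wt, mut_aa="V", ligand_id="LX",
            modality=Modality.PAM, assay=Assay.FUNCTION,
            fold_effect=fold, qualitative=qual,
        )

    def test_wildtype_glycine_flag(self):
        rec = self._gly_record()
        effects = {P("4x42"): _summary(receptors=("R2",), ligands=("LX",))}
        cls = classify_outside_site(effects, {P("6x50")}, [rec])
        flags = cls.flags[P("4x42")]
        assert PeripheralFlag.WILDTYPE_GLYCINE in flags
        assert PeripheralFlag.SINGLE_LIGAND_SINGLE_RECEPTOR in flags

    def test_non_gly_wildtype_earns_no_flag(self):
        rec = self._gly_record(receptor="R1", wt="V", fold=None,
                               qual=Qualitative.NO_EFFECT)
        effects = {P("4x42"): _summary(receptors=("R1",), ligands=("LX",))}
        cls = classify_outside_site(effects, set(), [rec])
        assert PeripheralFlag.WILDTYPE_GLYCINE not in cls.flags[P("4x42")]

    def test_multi_ligand_multi_receptor_not_flagged_rare(self):
        effects = {P("4x42"): _summary(receptors=("R1", "R2"),
                                       ligands=("L1", "L2", "L3"))}
        cls = classify_outside_site(effects, set(), [])
        assert PeripheralFlag.SINGLE_LIGAND_SINGLE_RECEPTOR not in cls.flags[P("4x42")]

    def test_site_positions_excluded(self):
        effects = {P("6x50"): _summary()}
        cls = classify_outside_site(effects, {P("6x50")}, [])
        assert P("6x50") not in cls.flags

    def test_membrane_facing_only_with_annotation(self):
        effects = {P("1x46"): _summary()}
        with_ann = classify_outside_site(effects, set(), [],
                                         membrane_facing={P("1x46")})
        without = classify_outside_site(effects, set(), [])
        assert PeripheralFlag.MEMBRANE_FACING in with_ann.flags[P("1x46")]
        assert PeripheralFlag.MEMBRANE_FACING not in without.flags[P("1x46")]
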