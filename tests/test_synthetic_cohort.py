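"""The synthetic cohort generator: trees, mutations, reads, file bundles."""

import numpy as np
import pandas as pd
import pytest

from relapsetrace.contexts import CONTEXT_INDEX
from relapsetrace.synthetic_cohort import (
    SCENARIOS,
    CloneNode,
    CloneTree,
    ScenarioSpec,
    emit_cohort,
    file_checksum,
    make_fusion_marker,
    sample_reads,
    simulate_clone_tree,
    simulate_mutations,
    true_seeding_pattern,
)


def relapse_fractions(tree):
    rel = tree.days[-1]
    return {n.id: n.fraction(rel) for n in tree.non_root()}


class TestCloneTree:
    def test_multiclonal_scenario_keeps_multiple_diagnostic_clones_at_relapse(self):
        tree = simulate_clone_tree(
            ScenarioSpec("very_early_multiclonal", n_clones=3, seed=1)
        )
        diag = tree.days[0]
        survivors = [
            n for n in tree.non_root()
            if n.fraction(diag) > 0 and relapse_fractions(tree)[n.id] > 0
        ]
        assert len(survivors) >= 2

    def test_sweep_scenario_has_exactly_one_dominant_relapse_clone(self):
        tree = simulate_clone_tree(ScenarioSpec("early_sweep_chemo", n_clones=2, seed=1))
        dominant = [c for c, f in relapse_fractions(tree).items() if f > 0.5]
        assert dominant == ["c2"]
        # the relapse clone's private mutations carry chemotherapy weight >= 0.5
        exposures = tree.nodes["c2"].signature_exposures
        assert exposures.get("SBS_SYN_THIO", 0.0) >= 0.5

    def test_sweep_diagnostic_fraction_is_configurable_around_detection(self):
        hi = simulate_clone_tree(
            ScenarioSpec("early_sweep_chemo", seed=1, sweep_diag_fraction=0.008)
        )
        lo = simulate_clone_tree(
            ScenarioSpec("early_sweep_chemo", seed=1, sweep_diag_fraction=0.0004)
        )
        assert hi.nodes["c2"].fraction(0) / 2 >= 0.002
        assert lo.nodes["c2"].fraction(0) / 2 < 0.002
        assert true_seeding_pattern(hi)[0] == "sweep_detected"
        assert true_seeding_pattern(lo)[0] == "sweep_not_detected"

    def test_dormant_scenario_relapse_clone_mirrors_diagnostic_exposures(self):
        tree = simulate_clone_tree(ScenarioSpec("aml_dormant", seed=1))
        relapse_clone = max(
            tree.non_root(), key=lambda n: n.fraction(tree.days[-1])
        )
        assert relapse_clone.fraction(tree.days[0]) > 0
        assert (
            relapse_clone.signature_exposures
            == tree.nodes["c1"].signature_exposures
        )

    def test_single_clone_rejected(self):
        with pytest.raises(ValueError, match="n_clones"):
            ScenarioSpec("early_sweep_chemo", n_clones=1, seed=1)

    def test_invalid_scenario_lists_valid_ones(self):
        with pytest.raises(ValueError, match="very_early_multiclonal"):
            ScenarioSpec("late_mystery", seed=1)

    @pytest.mark.parametrize("scenario", SCENARIOS)
    @pytest.mark.parametrize("n_clones", [2, 3, 4, 6])
    def test_nesting_invariants_hold_for_every_tree(self, scenario, n_clones):
        tree = simulate_clone_tree(ScenarioSpec(scenario, n_clones=n_clones, seed=3))
        tree.validate()  # child <= parent, sibling sums <= parent
        assert all(
            n.fraction(d) <= 1.0 for n in tree.nodes.values() for d in tree.days
        )

    def test_interpolation_onto_custom_days_preserves_nesting(self):
        spec = ScenarioSpec("very_early_multiclonal", seed=1, days=(0, 50, 120))
        tree = simulate_clone_tree(spec)
        assert tree.days == (0, 50, 120)
        tree.validate()

    def test_remission_zeroes_fractions_after_induction(self):
        tree = simulate_clone_tree(ScenarioSpec("early_sweep_chemo", seed=1, remission=True))
        for n in tree.nodes.values():
            for d in tree.days:
                if d > 29:
                    assert n.fraction(d) == 0.0

    def test_nesting_violation_detected(self):
        with pytest.raises(ValueError, match="exceeds parent"):
            CloneTree(
                [
                    CloneNode("r", None, 0, {"s": 1.0}, {0: 0.5}),
                    CloneNode("k", "r", 0, {"s": 1.0}, {0: 0.6}),
                ]
            )


class TestSimulateMutations:
    @pytest.mark.parametrize("n", [1_000, 10_000])
    def test_spectrum_converges_to_exposure_mixture(self, n, catalog, reference, locus_index):
        tree = CloneTree(
            [
                CloneNode(
                    "r", None, n,
                    {"SBS_SYN_THIO": 0.7, "SBS_SYN_CLOCK": 0.3},
                    {0: 1.0},
                )
            ]
        )
        muts = simulate_mutations(tree, catalog, reference, seed=2, index=locus_index)
        counts = np.zeros(96)
        for m in muts:
            counts[CONTEXT_INDEX[m.context]] += 1
        mix = 0.7 * catalog.column("SBS_SYN_THIO") + 0.3 * catalog.column("SBS_SYN_CLOCK")
        tv = 0.5 * np.abs(counts / n - mix).sum()
        assert tv < 3 / np.sqrt(n) + 0.02

    def test_pure_signature_spectrum_within_tv_005_at_10k(self, catalog, reference, locus_index):
        tree = CloneTree(
            [CloneNode("r", None, 10_000, {"SBS_SYN_CLOCK": 1.0}, {0: 1.0})]
        )
        muts = simulate_mutations(tree, catalog, reference, seed=7, index=locus_index)
        counts = np.zeros(96)
        for m in muts:
            counts[CONTEXT_INDEX[m.context]] += 1
        tv = 0.5 * np.abs(counts / 10_000 - catalog.column("SBS_SYN_CLOCK")).sum()
        assert tv < 0.05

    def test_zero_mutation_clone_emits_nothing(self, catalog, reference, locus_index):
        tree = CloneTree([CloneNode("r", None, 0, {"SBS_SYN_CLOCK": 1.0}, {0: 1.0})])
        assert simulate_mutations(tree, catalog, reference, seed=1, index=locus_index) == []

    def test_unknown_exposure_name_rejected(self, catalog, reference, locus_index):
        tree = CloneTree([CloneNode("r", None, 5, {"SBS_NOPE": 1.0}, {0: 1.0})])
        with pytest.raises(ValueError, match="SBS_NOPE"):
            simulate_mutations(tree, catalog, reference, seed=1, index=locus_index)

    def test_placed_alleles_match_reference_context(self, catalog, reference, locus_index):
        tree = simulate_clone_tree(ScenarioSpec("aml_dormant", seed=5))
        muts = simulate_mutations(tree, catalog, reference, seed=5, index=locus_index)
        ids = [m.id for m in muts]
        assert len(set(ids)) == len(ids)  # unique loci
        for m in muts[:200]:
            assert reference.base(m.variant.pos) == m.variant.ref
            assert m.variant.ref != m.variant.alt


class TestSampleReads:
    def _single_clone_tree(self, fraction):
        return CloneTree(
            [CloneNode("r", None, 1, {"SBS_SYN_CLOCK": 1.0}, {0: fraction})]
        )

    def _variants(self, tree, catalog, reference, locus_index, seed=3):
        return simulate_mutations(tree, catalog, reference, seed=seed, index=locus_index)

    def test_heterozygous_diploid_full_clone_expects_vaf_half(
        self, catalog, reference, locus_index
    ):
        tree = self._single_clone_tree(1.0)
        v = self._variants(tree, catalog, reference, locus_index)
        (ro,) = sample_reads(v, tree, 0, depth=5000, error_rate=0.0, purity=1.0, seed=1)
        assert ro.expected_vaf == 0.5
        assert abs(ro.observation.vaf - 0.5) < 0.05

    def test_detection_limit_fraction_yields_six_point_five_alt_reads(
        self, catalog, reference, locus_index
    ):
        # clone fraction 0.004 -> VAF 0.002 -> 6.5 expected alt reads at 3250x
        tree = self._single_clone_tree(0.004)
        v = self._variants(tree, catalog, reference, locus_index)
        tree_many = CloneTree(
            [CloneNode("r", None, 0, {"SBS_SYN_CLOCK": 1.0}, {0: 0.004})]
        )
        alts = []
        for s in range(400):
            (ro,) = sample_reads(
                v, tree, 0, depth=3250, error_rate=0.0, purity=1.0, seed=s
            )
            alts.append(ro.observation.alt_reads)
        assert ro.expected_vaf == pytest.approx(0.002)
        assert np.mean(alts) == pytest.approx(6.5, abs=3 * np.std(alts) / 20)

    def test_zero_depth_flagged_uninformative(self, catalog, reference, locus_index):
        tree = self._single_clone_tree(1.0)
        v = self._variants(tree, catalog, reference, locus_index)
        (ro,) = sample_reads(v, tree, 0, depth=1e-9, error_rate=0.0, seed=1)
        assert ro.uninformative
        assert ro.observation.depth == 0

    def test_mean_unbiased_across_replicate_sites(self, catalog, reference, locus_index):
        tree = self._single_clone_tree(0.3)  # expected VAF 0.15
        v = self._variants(tree, catalog, reference, locus_index) * 1
        n_rep, depth = 10_000, 100
        readouts = sample_reads(v * n_rep, tree, 0, depth=depth, error_rate=0.0, seed=9)
        vafs = np.array(
            [r.observation.vaf for r in readouts if r.observation.depth > 0]
        )
        se = np.sqrt(0.15 * 0.85 / depth / len(vafs))
        assert abs(vafs.mean() - 0.15) < 3 * se + 1e-3

    def test_fusion_marker_immune_to_substitution_error(self, reference):
        fus = make_fusion_marker(reference)
        tree = CloneTree(
            [CloneNode("trunk", None, 0, {"SBS_SYN_CLOCK": 1.0}, {0: 0.0})]
        )
        readouts = sample_reads([fus] * 200, tree, 0, depth=3000, error_rate=0.005, seed=4)
        assert sum(r.observation.alt_reads for r in readouts) == 0


class TestEmitCohort:
    def test_rerun_with_same_seed_is_byte_identical(
        self, tmp_path, reference, locus_index, catalog
    ):
        spec = ScenarioSpec("early_sweep_chemo", seed=11)
        b1 = emit_cohort(spec, tmp_path / "a", reference=reference,
                         index=locus_index, catalog=catalog)
        b2 = emit_cohort(spec, tmp_path / "b", reference=reference,
                         index=locus_index, catalog=catalog)
        for key in ("vcf", "observations", "cn", "meta", "truth"):
            assert file_checksum(b1.paths[key]) == file_checksum(b2.paths[key])

    def test_two_timepoint_spec_emits_two_timepoints_per_variant(
        self, tmp_path, reference, locus_index, catalog
    ):
        spec = ScenarioSpec("aml_dormant", seed=2, days=(0, 400), mutation_scale=0.1)
        b = emit_cohort(spec, tmp_path, reference=reference,
                        index=locus_index, catalog=catalog)
        obs = pd.read_csv(b.paths["observations"], sep="\t")
        per_variant = obs.groupby("variant_id")["day"].nunique()
        assert (per_variant == 2).all()

    def test_truth_seeding_pattern_matches_scenario_definition(
        self, tmp_path, reference, locus_index, catalog
    ):
        for scenario, expected in [
            ("very_early_multiclonal", "multiple_clones"),
            ("early_sweep_chemo", "sweep_detected"),
            ("aml_dormant", "sweep_detected"),
        ]:
            spec = ScenarioSpec(scenario, seed=3, mutation_scale=0.05)
            b = emit_cohort(spec, tmp_path / scenario, reference=reference,
                            index=locus_index, catalog=catalog)
            assert b.truth.seeding_pattern == expected
            assert set(b.truth.panel["variants"]) <= set(b.truth.variant_clone)
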