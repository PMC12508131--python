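"""Spectrum building, NNLS refitting, etiology attribution, profile comparison."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from relapsetrace.catalog import SignatureCatalog
from relapsetrace.contexts import CONTEXTS_96, CONTEXT_INDEX
from relapsetrace.signature_analysis import (
    ContextSpectrum,
    average_vaf_per_signature,
    build_spectrum,
    classify_etiology,
    compare_profiles,
    motif_signature_map,
    motif_signature_ties,
    primary_signature,
    refit_exposures,
    relapse_specific_ids,
)
from relapsetrace.synthetic_cohort import (
    CloneNode,
    CloneTree,
    sample_reads,
    simulate_mutations,
)
from relapsetrace.variant_filters import Variant


def spectrum_from(counts_by_context):
    counts = np.zeros(96, dtype=np.int64)
    for ctx, n in counts_by_context.items():
        counts[CONTEXT_INDEX[ctx]] = n
    return ContextSpectrum(counts)


class TestBuildSpectrum:
    def test_purine_reference_uses_reverse_complement_class(self, reference):
        # find a G position whose trinucleotide is TGC, call G>A there
        pos = next(
            p for p in range(2, len(reference) - 1)
            if reference.trinucleotide(p) == "TGC"
        )
        v = Variant("chrS", pos, "G", "A", region_class="nonrepeat")
        spec = build_spectrum([v], reference)
        assert spec.n == 1
        assert spec.counts[CONTEXT_INDEX["G[C>T]A"]] == 1

    def test_empty_input_gives_zero_spectrum(self, reference):
        spec = build_spectrum([], reference)
        assert spec.n == 0 and spec.counts.sum() == 0

    def test_repeat_region_variants_excluded_by_default(self, reference):
        pos = next(
            p for p in range(2, len(reference) - 1)
            if reference.trinucleotide(p) == "ACA"
        )
        v = Variant("chrS", pos, "C", "T", region_class="repeat")
        assert build_spectrum([v], reference).n == 0
        assert build_spectrum([v], reference, include_repeats=True).n == 1

    def test_round_trip_with_simulator(self, catalog, reference, locus_index):
        tree = CloneTree(
            [CloneNode("r", None, 1000, {"SBS_SYN_MMR": 1.0}, {0: 1.0})]
        )
        muts = simulate_mutations(tree, catalog, reference, seed=4, index=locus_index)
        spec = build_spectrum([m.variant for m in muts], reference)
        assert spec.n == 1000
        tv = 0.5 * np.abs(spec.frequencies() - catalog.column("SBS_SYN_MMR")).sum()
        assert tv < 3 / np.sqrt(1000) + 0.02


class TestRefitExposures:
    def test_exact_single_column_recovers_fully(self, catalog):
        counts = np.round(500 * catalog.column("SBS_SYN_THIO")).astype(int)
        profile = refit_exposures(ContextSpectrum(counts), catalog)
        assert profile.contributions["SBS_SYN_THIO"] > 0.99

    def test_two_signature_mixture_recovered_within_005(self, catalog, rng):
        mix = 0.7 * catalog.column("SBS_SYN_THIO") + 0.3 * catalog.column("SBS_SYN_CLOCK")
        counts = rng.multinomial(20_000, mix)
        profile = refit_exposures(ContextSpectrum(counts), catalog)
        assert profile.contributions["SBS_SYN_THIO"] == pytest.approx(0.7, abs=0.05)
        assert profile.contributions["SBS_SYN_CLOCK"] == pytest.approx(0.3, abs=0.05)
        # independent oracle: grid search over the 2-signature simplex
        grid = np.arange(0.0, 1.0001, 0.01)
        m = np.column_stack(
            [catalog.column("SBS_SYN_THIO"), catalog.column("SBS_SYN_CLOCK")]
        )
        errs = [
            np.linalg.norm(counts - counts.sum() * (m @ np.array([w, 1 - w])))
            for w in grid
        ]
        w_best = grid[int(np.argmin(errs))]
        assert profile.contributions["SBS_SYN_THIO"] == pytest.approx(w_best, abs=0.02)

    def test_orthogonal_support_signatures_recover_exactly(self):
        m = np.zeros((96, 2))
        m[:48, 0] = 1 / 48
        m[48:, 1] = 1 / 48
        cat = SignatureCatalog(
            names=("a", "b"), matrix=m,
            etiology={"a": "Unknown", "b": "Unknown"},
        )
        counts = np.zeros(96, dtype=int)
        counts[:48] = 30  # 1440 mutations from a
        counts[48:] = 10  # 480 from b
        profile = refit_exposures(ContextSpectrum(counts), cat)
        assert profile.contributions["a"] == pytest.approx(0.75, abs=1e-9)
        assert profile.contributions["b"] == pytest.approx(0.25, abs=1e-9)

    def test_empty_spectrum_gives_defined_empty_profile(self, catalog):
        profile = refit_exposures(ContextSpectrum(np.zeros(96, int)), catalog)
        assert profile.contributions == {} and profile.n == 0

    def test_scale_invariance(self, catalog, rng):
        mix = 0.5 * catalog.column("SBS_SYN_UV") + 0.5 * catalog.column("SBS_SYN_APOBEC")
        counts = rng.multinomial(5_000, mix)
        p1 = refit_exposures(ContextSpectrum(counts), catalog)
        p2 = refit_exposures(ContextSpectrum(counts * 7), catalog)
        for name in catalog.names:
            assert p1.contributions[name] == pytest.approx(
                p2.contributions[name], abs=1e-9
            )

    def test_random_three_signature_mixtures_mean_error_below_003(self, catalog, rng):
        errs = []
        for _ in range(50):
            sig_idx = rng.choice(catalog.n_signatures, 3, replace=False)
            w = rng.dirichlet(np.ones(3))
            true = np.zeros(catalog.n_signatures)
            true[sig_idx] = w
            counts = rng.multinomial(10_000, catalog.matrix @ true)
            profile = refit_exposures(ContextSpectrum(counts), catalog)
            got = np.array([profile.contributions[n] for n in catalog.names])
            errs.append(np.abs(got - true).mean())
        assert np.mean(errs) < 0.03


class TestEtiology:
    def test_class_sums_conserve_mass(self, catalog):
        profile = refit_exposures(
            ContextSpectrum(np.round(1000 * catalog.matrix.mean(axis=1)).astype(int)),
            catalog,
        )
        sums = classify_etiology(profile, catalog)
        assert sum(sums.values()) == pytest.approx(
            sum(profile.contributions.values()), abs=1e-9
        )

    def test_simple_profiles(self, catalog):
        from relapsetrace.signature_analysis import ExposureProfile

        p = ExposureProfile(
            {"SBS_SYN_THIO": 0.6, "SBS_SYN_CLOCK": 0.4}, residual=0.0, n=10
        )
        assert classify_etiology(p, catalog) == {
            "Chemotherapy": 0.6, "Clock_like": 0.4,
        }
        p = ExposureProfile({"SBS_SYN_UNKNOWN": 1.0}, residual=0.0, n=10)
        assert classify_etiology(p, catalog) == {"Unknown": 1.0}

    def test_unmapped_signature_is_an_error(self, catalog):
        from relapsetrace.signature_analysis import ExposureProfile

        p = ExposureProfile({"SBS_MYSTERY": 1.0}, residual=0.0, n=10)
        with pytest.raises(ValueError, match="SBS_MYSTERY"):
            classify_etiology(p, catalog)


class TestPrimarySignature:
    def test_unknown_can_be_primary_with_separate_known_primary(self):
        call = primary_signature(
            {"Unknown": 0.5, "Chemotherapy": 0.3, "Clock_like": 0.2}
        )
        assert call.primary == "Unknown"
        assert call.primary_known == "Chemotherapy"

    def test_single_class(self):
        call = primary_signature({"Chemotherapy": 1.0})
        assert (call.primary, call.primary_known) == ("Chemotherapy", "Chemotherapy")

    def test_exact_tie_breaks_alphabetically_and_flags(self):
        call = primary_signature({"MMR": 0.5, "Chemotherapy": 0.5})
        assert call.primary == "Chemotherapy"
        assert call.tie

    def test_empty_input_is_an_error(self):
        with pytest.raises(ValueError):
            primary_signature({})

    def test_all_unknown_has_no_known_primary(self):
        call = primary_signature({"Unknown": 1.0})
        assert call.primary == "Unknown" and call.primary_known is None


class TestMotifMap:
    def test_single_signature_catalog_maps_everything_to_it(self):
        m = np.full((96, 1), 1.0 / 96)
        cat = SignatureCatalog(names=("only",), matrix=m, etiology={"only": "Unknown"})
        assert set(motif_signature_map(cat).values()) == {"only"}

    def test_disjoint_support_maps_each_context_to_its_signature(self):
        m = np.zeros((96, 2))
        m[:48, 0] = 1 / 48
        m[48:, 1] = 1 / 48
        cat = SignatureCatalog(
            names=("a", "b"), matrix=m, etiology={"a": "Unknown", "b": "Unknown"}
        )
        mapping = motif_signature_map(cat)
        assert all(mapping[CONTEXTS_96[i]] == "a" for i in range(48))
        assert all(mapping[CONTEXTS_96[i]] == "b" for i in range(48, 96))

    def test_bundled_catalog_matches_brute_force_argmax(self, catalog):
        mapping = motif_signature_map(catalog)
        for i, ctx in enumerate(CONTEXTS_96):
            best = max(
                range(catalog.n_signatures), key=lambda j: catalog.matrix[i, j]
            )
            assert mapping[ctx] == catalog.names[best]

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1), st.integers(2, 5))
    def test_random_catalogs_match_brute_force(self, seed, s):
        rng = np.random.default_rng(seed)
        m = rng.dirichlet(np.ones(96), size=s).T
        cat = SignatureCatalog(
            names=tuple(f"S{i}" for i in range(s)),
            matrix=m,
            etiology={f"S{i}": "Unknown" for i in range(s)},
        )
        mapping = motif_signature_map(cat)
        for i, ctx in enumerate(CONTEXTS_96):
            row = m[i]
            assert row[cat.names.index(mapping[ctx])] == row.max()

    def test_exposure_weighted_mode(self, catalog):
        # with all weight on one signature, every motif maps to it
        mapping = motif_signature_map(
            catalog, exposure_weights={"SBS_SYN_UV": 1.0}
        )
        assert set(mapping.values()) == {"SBS_SYN_UV"}

    def test_tie_detection(self):
        m = np.full((96, 2), 1.0 / 96)
        cat = SignatureCatalog(
            names=("a", "b"), matrix=m, etiology={"a": "Unknown", "b": "Unknown"}
        )
        assert motif_signature_ties(cat) == set(CONTEXTS_96)


class TestAverageVaf:
    def test_mean_within_signature(self):
        mapping = {c: "sigA" for c in CONTEXTS_96}
        out = average_vaf_per_signature(
            [("A[C>A]A", 0.2), ("A[C>A]C", 0.4)], mapping
        )
        assert out == {"sigA": pytest.approx(0.3)}

    def test_empty_input(self):
        assert average_vaf_per_signature([], {}) == {}

    def test_chemo_attributed_mutations_at_elevated_vaf(
        self, catalog, reference, locus_index
    ):
        # chemo-signature mutations generated in a higher-CCF clone than
        # clock mutations -> higher mean VAF for the chemo signature
        tree = CloneTree(
            [
                CloneNode("r", None, 0, {"SBS_SYN_CLOCK": 1.0}, {0: 0.9}),
                CloneNode("hi", "r", 600, {"SBS_SYN_THIO": 1.0}, {0: 0.8}),
                CloneNode("lo", "r", 600, {"SBS_SYN_CLOCK": 1.0}, {0: 0.1}),
            ]
        )
        muts = simulate_mutations(tree, catalog, reference, seed=6, index=locus_index)
        readouts = sample_reads(muts, tree, 0, depth=800, error_rate=0.0, seed=6)
        vaf_by_id = {r.variant_id: r.observation.vaf for r in readouts}
        mapping = motif_signature_map(catalog)
        pairs = [(m.context, vaf_by_id[m.id]) for m in muts]
        means = average_vaf_per_signature(pairs, mapping)
        assert means["SBS_SYN_THIO"] > means["SBS_SYN_CLOCK"]


class TestCompareProfiles:
    def test_identical_spectra_give_one(self, catalog, rng):
        counts = rng.multinomial(2000, catalog.column("SBS_SYN_CLOCK"))
        s = ContextSpectrum(counts)
        assert compare_profiles(s, s) == pytest.approx(1.0)

    def test_rank_reversal_also_gives_one_after_squaring(self):
        a = ContextSpectrum(np.arange(96, dtype=np.int64))
        b = ContextSpectrum(np.arange(96, dtype=np.int64)[::-1].copy())
        assert compare_profiles(a, b) == pytest.approx(1.0)

    def test_constant_spectrum_returns_nan_not_zero(self):
        a = ContextSpectrum(np.full(96, 5, dtype=np.int64))
        b = ContextSpectrum(np.arange(96, dtype=np.int64))
        assert np.isnan(compare_profiles(a, b))

    def test_dormant_relapse_mirrors_diagnosis_more_than_chemo_sweep(
        self, catalog, reference, locus_index
    ):
        # AML-like: relapse-specific exposures identical to diagnosis ->
        # high r2; ALL-like chemo sweep -> low r2.
        def r2_for(diag_exp, rel_exp, seed):
            n = 5000
            tree = CloneTree(
                [
                    CloneNode("r", None, 0, diag_exp, {0: 1.0}),
                    CloneNode("d", "r", n, diag_exp, {0: 0.5}),
                    CloneNode("g", "r", n, rel_exp, {0: 0.4}),
                ]
            )
            muts = simulate_mutations(
                tree, catalog, reference, seed=seed, index=locus_index
            )
            diag = ContextSpectrum.from_contexts(
                [m.context for m in muts if m.clone == "d"]
            )
            rel = ContextSpectrum.from_contexts(
                [m.context for m in muts if m.clone == "g"]
            )
            return compare_profiles(diag, rel)

        clock = {"SBS_SYN_CLOCK": 0.8, "SBS_SYN_UNKNOWN": 0.2}
        chemo = {"SBS_SYN_THIO": 0.7, "SBS_SYN_CLOCK": 0.3}
        r2_aml = r2_for(clock, clock, seed=8)
        r2_all = r2_for(clock, chemo, seed=9)
        assert r2_aml > r2_all


class TestRelapseSpecific:
    def test_selection_requires_absence_at_diagnosis_after_gate(self):
        diag = {"a": 0.0, "b": 0.2, "c": None}
        rel = {"a": 0.3, "b": 0.3, "c": 0.3, "d": 0.1}
        assert relapse_specific_ids(diag, rel) == {"a"}
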