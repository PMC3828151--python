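import itertools
import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from admixkit.data_model_io import HaplotypePanel, VariantTable
from admixkit.local_ancestry import (
    AncestryPath,
    Window,
    WindowModel,
    calls_to_tracts,
    deconvolve_within_tracts,
    fit_window_model,
    optimize_generations,
    paint_panel,
    posterior_decode,
    subancestry_fraction_by_block_size,
    tracts_to_site_labels,
    transition_matrix,
    viterbi_decode,
    window_distances,
    window_loglikelihoods,
)
from admixkit.simulate import (
    MigrationModel,
    default_frequency_model,
    simulate_admixed_cohort,
)

from conftest import build_reference_panel


def enumerate_posteriors(loglik, g, q, d):
    """Brute-force path enumeration oracle for forward-backward/Viterbi."""
    n, K = loglik.shape
    Ps = [transition_matrix(g, di, q) for di in d]
    probs = np.zeros((n, K))
    total = 0.0
    best_path, best_lp = None, -np.inf
    for path in itertools.product(range(K), repeat=n):
        lp = np.log(q[path[0]]) + loglik[0, path[0]]
        for t in range(1, n):
            lp += np.log(Ps[t - 1][path[t - 1], path[t]]) + loglik[t, path[t]]
        p = np.exp(lp)
        total += p
        for t in range(n):
            probs[t, path[t]] += p
        if lp > best_lp:
            best_lp, best_path = lp, path
    return probs / total, best_path, np.log(total)


class TestTransitionMatrix:
    def test_zero_distance_is_identity(self):
        np.testing.assert_allclose(
            transition_matrix(10, 0.0, np.array([0.3, 0.7])), np.eye(2))

    def test_hand_computed_entries(self):
        P = transition_matrix(10, 0.05, np.array([0.2, 0.8]))
        stay = np.exp(-0.5)
        assert P[0, 0] == pytest.approx(stay + (1 - stay) * 0.2, abs=1e-4)
        assert P[0, 1] == pytest.approx((1 - stay) * 0.8, abs=1e-4)
        assert P[0, 0] == pytest.approx(0.6852, abs=1e-4)
        assert P[0, 1] == pytest.approx(0.3148, abs=1e-4)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.floats(0.1, 100), st.floats(0.0, 2.0),
           st.floats(0.01, 0.99))
    def test_q_is_stationary_and_rows_sum_to_one(self, g, d, q0):
        q = np.array([q0, 1 - q0])
        P = transition_matrix(g, d, q)
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-12)
        np.testing.assert_allclose(q @ P, q, atol=1e-12)


class TestDecoding:
    def test_single_window_closed_form(self):
        loglik = np.array([[0.3, -1.2, 0.8]])
        q = np.array([0.5, 0.2, 0.3])
        post = posterior_decode(loglik, 5.0, q, np.array([]))
        expect = q * np.exp(loglik[0])
        expect /= expect.sum()
        np.testing.assert_allclose(post.probs[0], expect, atol=1e-12)

    def test_posteriors_match_enumeration(self):
        rng = np.random.default_rng(0)
        loglik = rng.normal(size=(4, 3))
        q = np.array([0.2, 0.5, 0.3])
        d = rng.uniform(0.01, 0.2, size=3)
        post = posterior_decode(loglik, 6.0, q, d)
        probs, _, logz = enumerate_posteriors(loglik, 6.0, q, d)
        assert np.abs(post.probs - probs).max() < 1e-10
        assert post.loglik == pytest.approx(logz, abs=1e-10)

    def test_large_distance_decouples_windows(self):
        rng = np.random.default_rng(1)
        loglik = rng.normal(size=(5, 2))
        q = np.array([0.4, 0.6])
        post = posterior_decode(loglik, 10.0, q, np.full(4, 1e6))
        for t in range(5):
            expect = q * np.exp(loglik[t] - loglik[t].max())
            np.testing.assert_allclose(post.probs[t], expect / expect.sum(),
                                       atol=1e-9)

    def test_posterior_rows_sum_to_one(self):
        rng = np.random.default_rng(2)
        loglik = rng.normal(scale=5, size=(30, 3))
        post = posterior_decode(loglik, 8.0, np.array([0.1, 0.4, 0.5]),
                                rng.uniform(0, 0.1, 29))
        np.testing.assert_allclose(post.probs.sum(axis=1), 1.0, atol=1e-9)

    def test_viterbi_matches_enumeration(self):
        rng = np.random.default_rng(3)
        loglik = rng.normal(size=(5, 2))
        q = np.array([0.35, 0.65])
        d = rng.uniform(0.01, 0.3, size=4)
        path = viterbi_decode(loglik, 4.0, q, d)
        _, best, _ = enumerate_posteriors(loglik, 4.0, q, d)
        assert tuple(path.viterbi) == best

    def test_uniform_likelihood_ties_break_low(self):
        loglik = np.zeros((6, 3))
        q = np.array([0.2, 0.6, 0.2])
        path = viterbi_decode(loglik, 5.0, q, np.full(5, 0.05))
        assert all(p == 1 for p in path.viterbi)   # argmax q
        # exact tie in q: lowest index wins
        path2 = viterbi_decode(loglik, 5.0, np.array([0.4, 0.4, 0.2]),
                               np.full(5, 0.05))
        assert all(p == 0 for p in path2.viterbi)

    def test_constant_shift_leaves_path_unchanged(self):
        rng = np.random.default_rng(4)
        loglik = rng.normal(size=(8, 3))
        q = np.array([0.3, 0.3, 0.4])
        d = rng.uniform(0.01, 0.2, size=7)
        p1 = viterbi_decode(loglik, 6.0, q, d)
        p2 = viterbi_decode(loglik + 17.3, 6.0, q, d)
        assert tuple(p1.viterbi) == tuple(p2.viterbi)

    def test_viterbi_likelihood_dominates_other_paths(self):
        rng = np.random.default_rng(5)
        loglik = rng.normal(size=(6, 3))
        q = np.array([0.2, 0.5, 0.3])
        d = rng.uniform(0.01, 0.2, size=5)
        Ps = [transition_matrix(7.0, di, q) for di in d]

        def path_lp(path):
            lp = np.log(q[path[0]]) + loglik[0, path[0]]
            for t in range(1, 6):
                lp += np.log(Ps[t - 1][path[t - 1], path[t]]) + loglik[t, path[t]]
            return lp

        vit = tuple(viterbi_decode(loglik, 7.0, q, d).viterbi)
        lp_vit = path_lp(vit)
        for path in itertools.islice(itertools.product(range(3), repeat=6), 200):
            assert lp_vit >= path_lp(path) - 1e-12

    def test_impossible_window_rejected(self):
        loglik = np.zeros((3, 2))
        loglik[1] = -np.inf
        with pytest.raises(ValueError):
            posterior_decode(loglik, 5.0, np.array([0.5, 0.5]),
                             np.array([0.1, 0.1]))


def toy_panel(alleles, pops, cm_span=10.0):
    alleles = np.asarray(alleles)
    n_var = alleles.shape[1]
    variants = VariantTable(pd.DataFrame({
        "chrom": "c1", "pos_bp": np.arange(1, n_var + 1) * 1000,
        "pos_cM": np.linspace(0, cm_span, n_var),
        "ref": "A", "alt": "G", "id": [f"v{i}" for i in range(n_var)]}))
    samples = [f"s{i}" for i in range(alleles.shape[0] // 2)]
    labels = {f"s{i}": pops[i] for i in range(len(samples))}
    return HaplotypePanel(alleles, samples, variants, labels)


class TestWindowModel:
    def test_disjoint_fixed_alleles_separate_clusters(self):
        # pop P fixed 0, pop Q fixed 1 across a 10-SNP window
        alleles = np.vstack([np.zeros((6, 10)), np.ones((6, 10))]).astype(int)
        panel = toy_panel(alleles, ["P"] * 3 + ["Q"] * 3)
        wm = fit_window_model(panel, window_size=10)
        d = np.linalg.norm(wm.means[0, 0] - wm.means[0, 1])
        spread = max(np.sqrt(np.trace(wm.covs[0, k])) for k in range(2))
        assert d > 5 * spread

    def test_identical_populations_have_close_means(self):
        rng = np.random.default_rng(6)
        alleles = rng.integers(0, 2, size=(40, 20))
        panel = toy_panel(alleles, ["P"] * 10 + ["Q"] * 10)
        wm = fit_window_model(panel, window_size=20)
        sd = np.sqrt(max(np.trace(wm.covs[0, 0]), np.trace(wm.covs[0, 1])))
        assert np.linalg.norm(wm.means[0, 0] - wm.means[0, 1]) < 1.2 * sd

    def test_remainder_snps_merged_into_last_window(self):
        rng = np.random.default_rng(7)
        alleles = rng.integers(0, 2, size=(12, 25))
        panel = toy_panel(alleles, ["P"] * 3 + ["Q"] * 3)
        wm = fit_window_model(panel, window_size=10)
        spans = [(w.start, w.stop) for w in wm.windows]
        assert spans == [(0, 10), (10, 25)]   # 5-SNP remainder merged

    def test_monomorphic_window_flagged_uninformative(self):
        alleles = np.zeros((12, 10), dtype=int)
        alleles[:, 5:] = np.random.default_rng(8).integers(0, 2, (12, 5))
        panel = toy_panel(alleles, ["P"] * 3 + ["Q"] * 3)
        wm = fit_window_model(panel, window_size=5)
        assert not wm.informative[0]
        assert wm.informative[1]
        ll = window_loglikelihoods(alleles[0].astype(np.int8), wm)
        assert np.allclose(ll[0], ll[0, 0])   # flat across populations

    def test_hand_computed_bivariate_density(self):
        # score (0,0), mean (0,0), identity covariance: log phi = -log(2 pi)
        win = Window("c1", 0, 2, 0.0, 0.0, 0.0, 1, 2)
        wm = WindowModel([win], ["P", "Q"], [np.zeros(2)], [np.eye(2)],
                         np.zeros((1, 2, 2)),
                         np.broadcast_to(np.eye(2), (1, 2, 2, 2)).copy(),
                         np.array([True]))
        ll = window_loglikelihoods(np.zeros(2, dtype=np.int8), wm)
        assert ll[0, 0] == pytest.approx(-np.log(2 * np.pi), abs=1e-12)


class TestGenerationsParameter:
    def test_recovered_g_in_plausible_band(self):
        # two-way admixture 8 generations ago: the effective HMM g is a
        # biased but informative estimate, expected within [4, 16]
        anc = default_frequency_model(2100, seed=50, ancestries=("EUR", "NAT"),
                                      divergence=0.1)
        model = MigrationModel(8, {"EUR": 0.5, "NAT": 0.5}, [], N=300)
        cohort = simulate_admixed_cohort(model, anc, {"c1": 1.5}, 8, seed=51,
                                         n_variants=2000)
        refs = build_reference_panel(anc, cohort.panel.variants, seed0=700)
        wm = fit_window_model(refs)
        q = np.array([0.5, 0.5])
        wi = wm.chrom_window_indices("c1")
        lls, dists = [], []
        for r in range(cohort.panel.n_haplotypes):
            ll = window_loglikelihoods(cohort.panel.alleles[r], wm)
            lls.append(ll[wi])
            dists.append(window_distances(wm, wi))
        g = optimize_generations(lls, q, dists)
        assert 4 <= g <= 16

    def test_local_optimality(self, study_scenario):
        from admixkit.local_ancestry import _forward
        wm = study_scenario["window_model"]
        cohort = study_scenario["cohort"]
        q = study_scenario["q"]
        wi = wm.chrom_window_indices("c1")
        lls = [window_loglikelihoods(cohort.panel.alleles[r], wm)[wi]
               for r in range(6)]
        dists = [window_distances(wm, wi)] * 6

        def total(g):
            return sum(_forward(ll, g, q, d)[2] for ll, d in zip(lls, dists))

        g = optimize_generations(lls, q, dists)
        assert total(g) >= total(g / 2)
        assert total(g) >= total(2 * g)

    def test_flat_likelihood_hits_bound_with_warning(self, caplog):
        lls = [np.zeros((10, 2))]
        dists = [np.full(9, 0.05)]
        with caplog.at_level(logging.WARNING, logger="admixkit"):
            optimize_generations(lls, np.array([0.5, 0.5]), dists)
        assert any("bound" in rec.message for rec in caplog.records)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            optimize_generations([], np.array([0.5, 0.5]), [])


class TestCallsToTracts:
    def make_path_model(self, labels):
        n = len(labels)
        wins = [Window("c1", 10 * i, 10 * (i + 1), 5.0 + 10 * i,
                       10.0 * i, 10.0 * i + 9, 1000 * i + 1, 1000 * i + 900)
                for i in range(n)]
        wm = WindowModel(wins, ["A", "B"], [np.zeros(10)] * n,
                         [np.eye(2, 10)] * n, np.zeros((n, 2, 2)),
                         np.broadcast_to(np.eye(2), (n, 2, 2, 2)).copy(),
                         np.ones(n, dtype=bool))
        path = AncestryPath(np.array(labels, dtype=object),
                            np.array(labels, dtype=object), ["A", "B"], 5.0)
        return path, wm

    def test_merge_rule_and_boundary_midpoint(self):
        path, wm = self.make_path_model(["A", "A", "B", "B", "B"])
        tracts = calls_to_tracts(path, wm)
        assert len(tracts) == 2
        first, second = tracts.df.iloc[0], tracts.df.iloc[1]
        assert first["ancestry"] == "A" and second["ancestry"] == "B"
        # boundary at midpoint between window 2's last and window 3's first cM
        assert first["end_cM"] == pytest.approx((19.0 + 20.0) / 2)
        assert second["start_cM"] == pytest.approx((19.0 + 20.0) / 2)
        assert not first["is_whole_chromosome"]

    def test_single_label_is_whole_chromosome(self):
        path, wm = self.make_path_model(["B"] * 4)
        tracts = calls_to_tracts(path, wm)
        assert len(tracts) == 1
        assert bool(tracts.df["is_whole_chromosome"].iloc[0])

    def test_painting_accuracy_on_simulated_cohort(self, study_scenario):
        # per-population divergence 0.1: at least 90% of sites painted true
        cohort = study_scenario["cohort"]
        tracts = study_scenario["tracts"]
        vt = cohort.panel.variants
        acc = [np.mean(tracts_to_site_labels(cohort.truth, vt, hap)
                       == tracts_to_site_labels(tracts, vt, hap))
               for hap in cohort.panel.haplotype_ids]
        assert np.mean(acc) >= 0.90

    def test_accuracy_increases_with_divergence(self):
        chrom_lengths = {"c1": 1.5}
        accs = []
        for F in (0.02, 0.05, 0.1, 0.2):
            anc = default_frequency_model(1600, seed=31, divergence=F)
            model = MigrationModel(8, {"EUR": 0.5, "NAT": 0.5},
                                   [(5, "AFR", 0.25)], N=200)
            cohort = simulate_admixed_cohort(model, anc, chrom_lengths,
                                             n_samples=6, seed=32,
                                             n_variants=1500)
            refs = build_reference_panel(anc, cohort.panel.variants,
                                         n_per_pop=20, seed0=800)
            from admixkit.local_ancestry import fit_window_model as fwm
            wm = fwm(refs)
            _, tracts = paint_panel(cohort.panel, wm, g=6.0,
                                    q=np.array([0.45, 0.3, 0.25]))
            vt = cohort.panel.variants
            acc = [np.mean(tracts_to_site_labels(cohort.truth, vt, hap)
                           == tracts_to_site_labels(tracts, vt, hap))
                   for hap in cohort.panel.haplotype_ids]
            accs.append(np.mean(acc))
        assert all(b > a for a, b in zip(accs, accs[1:]))


class TestDisjointDeconvolution:
    def make_sub_scenario(self, seed=40):
        from admixkit.simulate import (AncestralPopulationModel,
                                       draw_subpopulation_frequencies,
                                       simulate_reference_haplotypes)
        rng = np.random.default_rng(seed)
        base = rng.uniform(0.05, 0.95, 1300)
        freqs = {"A": draw_subpopulation_frequencies(base, 0.05, seed + 1),
                 "B": draw_subpopulation_frequencies(base, 0.05, seed + 2)}
        anc = AncestralPopulationModel(freqs)
        from admixkit.data_model_io import uniform_variant_table
        vt = uniform_variant_table(1200, {"c1": 1.2})
        refA = simulate_reference_haplotypes(freqs["A"][:len(vt)], 30,
                                             seed + 3, variants=vt,
                                             population="A")
        refB = simulate_reference_haplotypes(freqs["B"][:len(vt)], 30,
                                             seed + 4, variants=vt,
                                             population="B")
        refs = HaplotypePanel(np.vstack([refA.alleles, refB.alleles]),
                              refA.samples + refB.samples, vt,
                              {**refA.labels, **refB.labels})
        # admixed haplotype truly from A everywhere
        hap = (rng.random(len(vt)) < freqs["A"][:len(vt)]).astype(np.int8)
        return refs, hap, vt

    def test_true_source_recovered_in_blocks(self):
        refs, hap, vt = self.make_sub_scenario()
        blocks = [("c1", 0, 600), ("c1", 600, 1200)]
        res = deconvolve_within_tracts(hap, blocks, refs, g=2.0,
                                       window_size=40)
        for blk in res:
            k = blk.posterior.ancestries.index("A")
            assert blk.posterior.probs[:, k].mean() > 0.9

    def test_identical_subreferences_give_uniform_posterior(self):
        refs, hap, vt = self.make_sub_scenario()
        # make B's haplotypes a copy of A's: indistinguishable panels
        half = refs.alleles.shape[0] // 2
        alleles = np.vstack([refs.alleles[:half], refs.alleles[:half]])
        twin = HaplotypePanel(alleles, refs.samples, vt, refs.labels)
        res = deconvolve_within_tracts(hap, [("c1", 0, 600)], twin, g=2.0,
                                       window_size=40)
        assert np.abs(res[0].posterior.probs - 0.5).max() < 0.2
        assert np.abs(res[0].posterior.probs.mean(axis=0) - 0.5).max() < 0.05

    def test_short_block_skipped_with_warning(self, caplog):
        refs, hap, vt = self.make_sub_scenario()
        with caplog.at_level(logging.WARNING, logger="admixkit"):
            res = deconvolve_within_tracts(hap, [("c1", 0, 10)], refs, g=8.0,
                                           window_size=40)
        assert res == []
        assert any("skipped" in rec.message for rec in caplog.records)

    def test_disjoint_differs_from_joint_run(self):
        refs, hap, vt = self.make_sub_scenario()
        disjoint = deconvolve_within_tracts(hap, [("c1", 0, 400),
                                                  ("c1", 400, 800)],
                                            refs, g=8.0, window_size=40)
        joint = deconvolve_within_tracts(hap, [("c1", 0, 800)], refs, g=8.0,
                                         window_size=40)
        stacked = np.vstack([b.posterior.probs for b in disjoint])
        assert stacked.shape == joint[0].posterior.probs.shape
        assert not np.allclose(stacked, joint[0].posterior.probs)


class TestSubancestryFractions:
    def make_block(self, size_cM, probs):
        from admixkit.local_ancestry import BlockResult, PosteriorMatrix
        pm = PosteriorMatrix(np.asarray(probs, dtype=float), ["A", "B"],
                             5.0, 0.0)
        return BlockResult("c1", 0, 10, size_cM, pm)

    def test_pure_blocks_give_unit_fraction(self):
        blocks = [self.make_block(s, [[0.99, 0.01]] * 5)
                  for s in (2.0, 12.0, 30.0)]
        out = subancestry_fraction_by_block_size(blocks, "A",
                                                 [0, 10, 20, 40])
        np.testing.assert_allclose(out["fraction"], 1.0)

    def test_unconfident_windows_excluded_and_empty_bins_missing(self):
        blocks = [self.make_block(2.0, [[0.6, 0.4]] * 5)]
        out = subancestry_fraction_by_block_size(blocks, "A", [0, 10, 20],
                                                 confidence=1.0)
        assert np.isnan(out["fraction"]).all()

    def test_mixed_confidence_counts_only_confident(self):
        blocks = [self.make_block(5.0, [[0.95, 0.05], [0.55, 0.45],
                                        [0.05, 0.95], [0.92, 0.08]])]
        out = subancestry_fraction_by_block_size(blocks, "A", [0, 10])
        assert out["n_windows"].iloc[0] == 3
        assert out["fraction"].iloc[0] == pytest.approx(2 / 3)
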