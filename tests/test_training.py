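import numpy as np
import pytest

from fragscore.annotation import ScoreWeights, collect_counts, consensus_score
from fragscore.binning import build_binning, discretize
from fragscore.fragmentation import fragment_candidate, ion_mass
from fragscore.spectra import Peak, Spectrum
from fragscore.synth import FixtureSpec, make_benchmark
from fragscore.training import (FragmentAnnotationModel, TrainingConfig,
                                _build_query_cache, finalize_model, grid_search,
                                phase1_collect, sample_weights,
                                split_by_inchikey)


def labelled_spectrum(block: str, sid: str) -> Spectrum:
    return Spectrum(peaks=(Peak(100.0, 1.0),), precursor_mz=150.0,
                    polarity="positive", id=sid,
                    inchikey=f"{block}-UHFFFAOYSA-N")


class TestSplit:
    def blocks(self, n):
        return [f"{chr(65 + i) * 14}" for i in range(n)]

    def test_seventy_thirty_by_block_count(self):
        spectra = [labelled_spectrum(b, f"s{i}")
                   for i, b in enumerate(self.blocks(10))]
        g1, g2 = split_by_inchikey(spectra, 0.7, seed=0)
        assert len(g1) == 7 and len(g2) == 3

    def test_same_seed_same_split(self):
        spectra = [labelled_spectrum(b, f"s{i}")
                   for i, b in enumerate(self.blocks(9))]
        a = split_by_inchikey(spectra, 0.7, seed=5)
        b = split_by_inchikey(spectra, 0.7, seed=5)
        assert [s.id for s in a[0]] == [s.id for s in b[0]]

    def test_no_molecule_leakage(self):
        # two spectra per block must land on the same side
        spectra = [labelled_spectrum(b, f"s{i}_{r}")
                   for i, b in enumerate(self.blocks(6)) for r in (0, 1)]
        g1, g2 = split_by_inchikey(spectra, 0.5, seed=3)
        b1 = {s.inchikey_block1 for s in g1}
        b2 = {s.inchikey_block1 for s in g2}
        assert not b1 & b2

    def test_missing_label_rejected(self):
        s = Spectrum(peaks=(Peak(100.0, 1.0),), precursor_mz=150.0,
                     polarity="positive", id="x")
        with pytest.raises(ValueError, match="InChIKey"):
            split_by_inchikey([s], 0.7, seed=0)


class TestSampleWeights:
    def test_sum_to_one(self):
        for w in sample_weights(100, seed=1):
            assert abs(w.w1 + w.w2 + w.w3 - 1.0) <= 1e-12

    def test_seed_reproducible(self):
        assert sample_weights(50, seed=9) == sample_weights(50, seed=9)

    def test_uniform_on_simplex_symmetric(self):
        ws = sample_weights(100_000, seed=2)
        arr = np.array([w.as_tuple() for w in ws])
        assert np.allclose(arr.mean(axis=0), 1 / 3, atol=0.01)


class TestPhase1:
    def test_mass_correction_to_theoretical_bins(self, ethanol):
        frags = fragment_candidate(ethanol, max_depth=2)
        theo = sorted({ion_mass(f.formula_mass, "positive") for f in frags})
        # observe every peak 3 mDa off; tolerance admits it
        s = Spectrum(peaks=tuple(Peak(m + 0.003, 1.0) for m in theo),
                     precursor_mz=ion_mass(ethanol.monoisotopic_mass, "positive"),
                     polarity="positive", id="q",
                     inchikey=f"{ethanol.inchikey_block1}-UHFFFAOYSA-N")
        binning = build_binning(10.0, 100.0, mzabs=0.0005, mzppm=5.0)
        peak_tab, _ = phase1_collect([(s, ethanol)], binning, "circular",
                                     mzabs=0.005, mzppm=10.0)
        allowed = {discretize(m, binning) for m in theo}
        assert peak_tab.entries  # something was explained
        assert {m for m, _ in peak_tab.entries} <= allowed
        # the observed (uncorrected) masses fall into different bins
        observed = {discretize(m + 0.003, binning) for m in theo}
        assert observed != allowed

    def test_unexplained_spectrum_contributes_nothing(self, ethanol):
        s = Spectrum(peaks=(Peak(500.0, 1.0),),
                     precursor_mz=ion_mass(ethanol.monoisotopic_mass, "positive"),
                     polarity="positive", id="q")
        binning = build_binning(10.0, 600.0, mzabs=0.001, mzppm=5.0)
        peak_tab, loss_tab = phase1_collect([(s, ethanol)], binning, "circular",
                                            mzabs=0.001, mzppm=5.0)
        assert peak_tab.entries == ()
        assert loss_tab.entries == ()

    def test_inconsistent_precursor_skipped_with_warning(self, ethanol):
        s = Spectrum(peaks=(Peak(29.0, 1.0),), precursor_mz=400.0,
                     polarity="positive", id="q")
        binning = build_binning(10.0, 600.0, mzabs=0.001, mzppm=5.0)
        with pytest.warns(UserWarning, match="precursor"):
            peak_tab, _ = phase1_collect([(s, ethanol)], binning, "circular",
                                         mzabs=0.001, mzppm=5.0)
        assert peak_tab.entries == ()


def tiny_phase2_setup():
    """Shared small real-data setup for grid-search equivalence tests."""
    bm = make_benchmark(FixtureSpec(n_molecules=6, n_replicates=2, n_queries=2,
                                    n_decoys_per_query=5, decoy_pool_size=30,
                                    seed=11))
    spectra = bm.train_spectra
    model = FragmentAnnotationModel(spectra, bm.train_candidates,
                                    mzabs=0.002, mzppm=10.0)
    g1, g2 = split_by_inchikey(spectra, 0.7, seed=4)
    items1 = [(s, model._correct_candidate(s)) for s in g1]
    binning = build_binning(5.0, 400.0, mzabs=0.002, mzppm=10.0)
    pt, lt = phase1_collect(items1, binning, "circular", 0.002, 10.0)
    peak_counts = collect_counts([pt], binning)
    loss_counts = collect_counts([lt], binning)
    caches, phase2 = [], []
    for s in g2:
        cands = [model._correct_candidate(s)] + [
            c for c in bm.train_candidates[s.id]
            if c.inchikey_block1 != s.inchikey_block1]
        phase2.append((s, cands))
        caches.append(_build_query_cache(s, cands, 0, peak_counts, loss_counts,
                                         binning, "circular", 0.002, 10.0, 2,
                                         False))
    return model, binning, peak_counts, loss_counts, caches, phase2


class TestGridSearch:
    def test_initial_grid_matches_sequential_scoring_oracle(self):
        """The vectorized grid evaluation must agree with scoring every
        (hyper, weight) combination through the sequential model path."""
        from fragscore.annotation import AnnotationModel, HyperParams

        (model, binning, peak_counts, loss_counts, caches,
         phase2) = tiny_phase2_setup()
        cfg = TrainingConfig(hyper_grid_init=(0.01, 0.0005), stop_improvement=1e9)
        weights = sample_weights(7, seed=13)
        _, _, best, log = grid_search(caches, cfg, weights)
        assert log["initial_hyper_sets"] == 2 ** 4
        assert log["initial_combinations"] == 2 ** 4 * 7

        import itertools

        brute_best = 0
        for combo in itertools.product((0.0005, 0.01), repeat=4):
            am = AnnotationModel(
                peak_counts=peak_counts, loss_counts=loss_counts,
                hyper=HyperParams(*combo), weights=ScoreWeights(1, 0, 0),
                binning=binning, fingerprint_function="circular",
                polarity="positive", mzabs=0.002, mzppm=10.0)
            per_query = []
            for s, cands in phase2:
                df = am.score_query(s, cands)
                per_query.append(df)
            for w in weights:
                top1 = 0
                for df in per_query:
                    fin = (w.w1 * df.s_metfrag + w.w2 * df.s_peak
                           + w.w3 * df.s_loss)
                    if fin.iloc[0] > fin.iloc[1:].max():
                        top1 += 1
                brute_best = max(brute_best, top1)
        assert log["rounds"][0]["best_top1"] == brute_best

    def test_search_returns_logged_optimum(self):
        """The returned Top1 count equals the best across all logged rounds
        and the returned weights are a valid simplex point."""
        (model, binning, peak_counts, loss_counts, caches,
         phase2) = tiny_phase2_setup()
        cfg = TrainingConfig(hyper_grid_init=(0.01, 0.0005))
        weights = sample_weights(25, seed=3)
        hyper, w, best, log = grid_search(caches, cfg, weights)
        # exhaustive re-check of the winning combination through the log
        assert best == max(r["best_top1"] for r in log["rounds"])
        assert best >= 1
        assert w.w1 >= 0 and abs(sum(w.as_tuple()) - 1) < 1e-9

    def test_empty_phase2_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            grid_search([], TrainingConfig(), sample_weights(3, seed=0))


class TestFinalize:
    def test_phase2_empty_equals_phase1(self, ethanol):
        frags = fragment_candidate(ethanol, max_depth=2)
        theo = sorted({ion_mass(f.formula_mass, "positive") for f in frags})
        s = Spectrum(peaks=tuple(Peak(m, 1.0) for m in theo),
                     precursor_mz=ion_mass(ethanol.monoisotopic_mass, "positive"),
                     polarity="positive", id="q")
        binning = build_binning(10.0, 100.0, mzabs=0.001, mzppm=5.0)
        items = [(s, ethanol)]
        pt, _ = phase1_collect(items, binning, "circular", 0.001, 5.0)
        phase1_counts = collect_counts([pt], binning)
        from fragscore.annotation import HyperParams

        m = finalize_model(items, binning, "circular",
                           HyperParams(0.1, 0.1, 0.1, 0.1),
                           ScoreWeights(0.3, 0.4, 0.3), 0.001, 5.0, "positive")
        assert m.peak_counts.counts == phase1_counts.counts

    def test_final_counts_dominate_phase1(self, benchmark, fitted):
        model = FragmentAnnotationModel(benchmark.train_spectra,
                                        benchmark.train_candidates,
                                        mzabs=0.002, mzppm=10.0)
        g1, _ = split_by_inchikey(benchmark.train_spectra, 0.7, seed=4)
        items1 = [(s, model._correct_candidate(s)) for s in g1]
        pt, _ = phase1_collect(items1, fitted.annotation_model.binning,
                               "circular", 0.002, 10.0)
        phase1_counts = collect_counts([pt], fitted.annotation_model.binning)
        final = fitted.annotation_model.peak_counts
        # final tables tally the full training set: totals can only grow
        assert sum(final.row_totals.values()) >= sum(
            phase1_counts.row_totals.values())


class TestEndToEndProperties:
    def test_fit_reproducible(self):
        bm = make_benchmark(FixtureSpec(n_molecules=6, n_replicates=2,
                                        n_queries=2, n_decoys_per_query=5,
                                        decoy_pool_size=30, seed=21))
        m = FragmentAnnotationModel(bm.train_spectra, bm.train_candidates,
                                    mzabs=0.002, mzppm=10.0,
                                    config=TrainingConfig(n_weight_samples=50))
        r1 = m.fit(seed=77)
        r2 = m.fit(seed=77)
        assert r1.hyper == r2.hyper
        assert r1.weights == r2.weights
        assert r1.top1_count == r2.top1_count
        assert r1.annotation_model.peak_counts.counts == \
            r2.annotation_model.peak_counts.counts

    def test_consensus_is_convex_combination(self, fitted, benchmark):
        s = benchmark.query_spectra[0]
        df = fitted.score_query(s, benchmark.query_candidates[s.id])
        w = fitted.weights
        for row in df.itertuples():
            assert row.s_fin == pytest.approx(
                consensus_score(row.s_metfrag, row.s_peak, row.s_loss, w),
                abs=1e-12)

    def test_mixed_polarity_rejected(self):
        a = labelled_spectrum("A" * 14, "s1")
        b = Spectrum(peaks=(Peak(100.0, 1.0),), precursor_mz=150.0,
                     polarity="negative", id="s2",
                     inchikey=f"{'B' * 14}-UHFFFAOYSA-N")
        with pytest.raises(ValueError, match="independently"):
            FragmentAnnotationModel([a, b], {"s1": [], "s2": []})
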