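import numpy as np
import pytest
from scipy import stats as sps

from nucsens import SimulationConfig, simulate_digest, simulate_truth
from nucsens.simulate import DIGESTS, PromoterTruth, write_dataset


class TestSimulateTruth:
    def test_deterministic_given_seed(self, small_cfg):
        t1, a1, e1, p1 = simulate_truth(small_cfg)
        t2, a2, e2, p2 = simulate_truth(small_cfg)
        assert a1.records.equals(a2.records)
        assert e1.values.equals(e2.values)
        assert p1.records.equals(p2.records)
        for x, y in zip(t1, t2):
            assert np.array_equal(x.occupancy, y.occupancy)
            assert np.array_equal(x.release_light, y.release_light)

    def test_effect_zero_means_identical_conditions(self):
        cfg = SimulationConfig(n_genes=8, seed=2, effect_size=0.0)
        truths, *_ = simulate_truth(cfg)
        for t in truths:
            for cond in cfg.conditions:
                r = t.effective_release("light", cond)
                assert np.array_equal(r, t.effective_release("light", cfg.conditions[0]))

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError, match="quartile"):
            SimulationConfig(n_genes=3).validate()

    def test_expression_tiers_strictly_ordered(self, small_truth):
        truths, _, expr, _ = small_truth
        by_tier = {}
        for t in truths:
            by_tier.setdefault(t.expression_tier, []).append(expr[t.gene_id])
        assert min(by_tier["Q1"]) > max(by_tier["Q2"])
        assert min(by_tier["Q2"]) > max(by_tier["Q3"])
        assert min(by_tier["Q3"]) > max(by_tier["Q4"])

    def test_promoter_windows_do_not_overlap(self, small_truth):
        _, ann, _, _ = small_truth
        w = ann.windows().sort_values("start")
        assert (w["start"].to_numpy()[1:] >= w["end"].to_numpy()[:-1]).all()

    def test_tf_peaks_sit_in_nfr_of_top_tier_genes(self, small_truth):
        truths, ann, _, peaks = small_truth
        by_id = {t.gene_id: t for t in truths}
        assert len(peaks) > 0
        for _, peak in peaks.records.iterrows():
            gene = peak["name"].split("_", 1)[1]
            t = by_id[gene]
            assert t.expression_tier == "Q1" and t.has_tf_peak
            center = (peak["start"] + peak["end"]) // 2
            assert abs(center - t.tss) <= 50  # inside the NFR

    def test_treated_effect_only_at_minus_one_of_top_tier(self, small_truth, small_cfg):
        truths, *_ = small_truth
        i_m1 = list(small_cfg.dyads).index(-100)
        for t in truths:
            eff = t.condition_effects[small_cfg.treated_condition]
            if t.expression_tier == "Q1":
                assert eff[i_m1] == small_cfg.effect_size
                assert (np.delete(eff, i_m1) == 1.0).all()
            else:
                assert (eff == 1.0).all()


class TestSimulateDigest:
    def test_byte_identical_dataset_reruns(self, small_cfg, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_dataset(small_cfg, d1)
        write_dataset(small_cfg, d2)
        for f1 in sorted(d1.iterdir()):
            assert f1.read_bytes() == (d2 / f1.name).read_bytes()

    def test_fragment_count_conserved_per_gene(self, small_cfg, small_truth):
        truths, ann, _, _ = small_truth
        frags = simulate_digest(truths, "light", "untreated", small_cfg)
        assert frags.total_count == small_cfg.n_genes * small_cfg.depth
        mids = frags.midpoints()
        for t in truths:
            near = np.abs(mids - t.tss) <= small_cfg.flank + 300
            assert near.sum() >= small_cfg.depth  # all of this gene's fragments

    def test_lengths_within_truncation_bounds(self, small_cfg, small_truth):
        truths, *_ = small_truth
        for digest in DIGESTS:
            frags = simulate_digest(truths, digest, "20min", small_cfg)
            assert frags.lengths.min() >= small_cfg.frag_len_min
            assert frags.lengths.max() <= small_cfg.frag_len_max

    def test_unknown_labels_rejected(self, small_cfg, small_truth):
        truths, *_ = small_truth
        with pytest.raises(ValueError, match="digest"):
            simulate_digest(truths, "medium", "untreated", small_cfg)
        with pytest.raises(ValueError, match="condition"):
            simulate_digest(truths, "light", "90min", small_cfg)

    def test_degenerate_single_dyad_puts_all_midpoints_on_it(self):
        cfg = SimulationConfig(
            n_genes=4, depth=10, seed=0, dyads=(-100,), jitter_sd=0.0,
            frag_len_sd=0.0, frag_len_mean=150, background_frac=0.0,
        )
        truths, *_ = simulate_truth(cfg)
        frags = simulate_digest(truths, "light", "untreated", cfg)
        mids = np.sort(frags.midpoints())
        expected = np.sort(np.repeat([t.tss - 100 for t in truths], 10))
        assert np.array_equal(mids, expected)

    def test_release_contrast_matches_multinomial_expectation(self):
        """A dyad with doubled light release gains light share exactly as
        the normalized sampling weights predict."""
        cfg = SimulationConfig(
            n_genes=4, depth=40_000, seed=3, dyads=(-100, 50),
            jitter_sd=0.0, background_frac=0.0, frag_len_sd=0.0,
        )
        dyads = np.array([-100, 50])
        occ = np.ones(2)
        rl = np.array([0.8, 0.4])
        rh = np.array([0.4, 0.4])
        truth = PromoterTruth(
            gene_id="g0", tss=5000, strand="+", dyads=dyads, occupancy=occ,
            release_light=rl, release_heavy=rh, expression_tier="Q2",
            has_tf_peak=False,
            condition_effects={c: np.ones(2) for c in cfg.conditions},
        )
        light = simulate_digest([truth], "light", "untreated", cfg)
        heavy = simulate_digest([truth], "heavy", "untreated", cfg)
        at_dyad = lambda fs: np.mean(fs.midpoints() == 5000 - 100)
        share_l, share_h = at_dyad(light), at_dyad(heavy)
        exp_l = rl[0] / rl.sum()     # exact multinomial expectation
        exp_h = rh[0] / rh.sum()
        assert share_l == pytest.approx(exp_l, abs=0.01)
        assert share_h == pytest.approx(exp_h, abs=0.01)
        assert share_l / share_h == pytest.approx(exp_l / exp_h, rel=0.03)

    def test_pure_background_is_uniform(self):
        """background fraction 1.0: midpoints pass a chi-square uniformity
        test over 20 bins at alpha=0.01."""
        cfg = SimulationConfig(
            n_genes=4, depth=10_000, seed=11, background_frac=1.0
        )
        truths, ann, _, _ = simulate_truth(cfg)
        t = truths[0]
        frags = simulate_digest(truths, "light", "untreated", cfg)
        mids = frags.midpoints()
        sel = mids[(mids >= t.tss - cfg.flank) & (mids < t.tss + cfg.flank)]
        counts, _ = np.histogram(sel, bins=20, range=(t.tss - cfg.flank, t.tss + cfg.flank))
        _, p = sps.chisquare(counts)
        assert p > 0.01

    def test_null_effect_light_heavy_densities_proportional(self):
        """With effect size 0 the light and heavy digests draw from the
        same per-dyad weights, so expected midpoint densities match."""
        cfg = SimulationConfig(n_genes=6, depth=20_000, seed=4, effect_size=0.0)
        truths, ann, _, _ = simulate_truth(cfg)
        light = simulate_digest(truths, "light", "untreated", cfg)
        heavy = simulate_digest(truths, "heavy", "untreated", cfg)
        t = truths[0]
        bins = np.arange(t.tss - 500, t.tss + 500, 100)
        hl, _ = np.histogram(light.midpoints(), bins=bins)
        hh, _ = np.histogram(heavy.midpoints(), bins=bins)
        # two multinomial samples of the same density: chi-square homogeneity
        table = np.array([hl, hh])
        _, p, _, _ = sps.chi2_contingency(table)
        assert p > 0.001
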