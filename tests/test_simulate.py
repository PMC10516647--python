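"""Forward simulator: bias sampling, Wright–Fisher dynamics, detection."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from pelement_er.genome import AnnotationSet, GenomicInterval, RegionSet
from pelement_er.simulate import (
    InsertionSampler,
    Population,
    SimulationConfig,
    evolve_phase2,
    poolseq_detect,
    simulate_experiment,
    simulate_phase1,
    toy_config,
    toy_genome,
)

GI = GenomicInterval


def flat_genome(length=100_000, hotspot_frac=0.1):
    """One chromosome, no gene models, single hotspot block."""
    ann = AnnotationSet({}, {"2L": length})
    hot = RegionSet("ORC", [GI("2L", 0, int(length * hotspot_frac))])
    return ann, hot


def small_config(**kw):
    ann, hot = flat_genome()
    defaults = dict(
        annotation=ann, hotspots=hot, n_lines=5, line_size=20,
        phase1_generations=10, founder_size=100, phase2_generations=5,
        n_replicates=2, insertion_rate=0.05, bias_weight=1.0,
        s_by_feature={"intergenic": 0.0},
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestInsertionSampler:
    def test_unbiased_sampling_matches_hotspot_fraction(self, rng):
        ann, hot = flat_genome(hotspot_frac=0.1)
        sampler = InsertionSampler(ann, hot, beta=1.0)
        sites = sampler.sample(20_000, rng)
        frac = np.mean([hot.contains_point(c, p) for c, p in sites])
        se = np.sqrt(0.1 * 0.9 / 20_000)
        assert frac == pytest.approx(0.10, abs=4 * se)

    def test_biased_sampling_matches_weighted_closed_form(self, rng):
        # beta=10, hotspot 10% -> 10*0.1/(10*0.1+0.9) = 0.526
        ann, hot = flat_genome(hotspot_frac=0.1)
        sampler = InsertionSampler(ann, hot, beta=10.0)
        sites = sampler.sample(20_000, rng)
        frac = np.mean([hot.contains_point(c, p) for c, p in sites])
        expected = 10 * 0.1 / (10 * 0.1 + 0.9)
        se = np.sqrt(expected * (1 - expected) / 20_000)
        assert frac == pytest.approx(expected, abs=4 * se)

    def test_insertion_density_proportional_to_feature_length(self, rng):
        """Under beta=1 and no selection, insertions are uniform, so
        per-feature counts follow feature lengths (chi-square GOF)."""
        annotation, hotspots, _ = toy_genome()
        sampler = InsertionSampler(annotation, hotspots, beta=1.0)
        sites = sampler.sample(20_000, rng)
        ft = annotation.feature_lengths()
        labels = annotation.labels
        codes = annotation.annotate_points("2L", np.array([p for _, p in sites]))
        obs = np.bincount(codes, minlength=len(labels)).astype(float)
        exp = np.array([ft.f_l[l] for l in labels], dtype=float)
        keep = exp > 0
        exp = exp[keep] / exp[keep].sum() * obs[keep].sum()
        from scipy.stats import chisquare

        p = chisquare(obs[keep], exp).pvalue
        assert p > 0.001


class TestPhase1:
    def test_zero_insertion_rate_gives_empty_lines(self):
        config = small_config(insertion_rate=0.0)
        lines = simulate_phase1(config, np.random.default_rng(0))
        assert all(len(line.sites) == 0 for line in lines)

    def test_deterministic_under_fixed_seed(self):
        config = small_config()
        a = simulate_phase1(config, np.random.default_rng(7))
        b = simulate_phase1(config, np.random.default_rng(7))
        assert [l.sites for l in a] == [l.sites for l in b]
        assert all(np.array_equal(x.freq, y.freq) for x, y in zip(a, b))


class TestPhase2:
    def _founders(self, n=1000, freq=0.1, s=0.0):
        sites = [("2L", 100 + 90 * i) for i in range(n)]
        return Population(
            sites=sites,
            freq=np.full(n, freq),
            s=np.full(n, s),
            origin_phase=np.ones(n, dtype=np.int64),
        )

    def test_neutral_mean_frequency_is_martingale(self):
        """Without selection or new insertions the expected frequency is
        conserved; 1000 independent loci give the Monte-Carlo average."""
        config = small_config(insertion_rate=0.0, founder_size=200)
        founders = self._founders(n=2000, freq=0.1)
        pop, _ = evolve_phase2(founders, config, np.random.default_rng(3))
        se = np.sqrt(0.1 * 0.9 / (2 * 200)) / np.sqrt(2000)  # per-locus sd / sqrt(loci)
        assert pop.freq.mean() == pytest.approx(0.1, abs=5 * se)

    def test_lethal_insertions_eliminated(self):
        """s=-1 with h=1 makes every carrier inviable: elimination is
        exact after one generation."""
        config = small_config(insertion_rate=0.0, dominance=1.0, phase2_generations=1)
        founders = self._founders(n=100, freq=0.3, s=-1.0)
        pop, _ = evolve_phase2(founders, config, np.random.default_rng(5))
        assert np.all(pop.freq == 0.0)

    def test_zero_generations_returns_founders(self):
        config = small_config(phase2_generations=0)
        founders = self._founders(n=50, freq=0.2)
        pop, founder_freq = evolve_phase2(founders, config, np.random.default_rng(1))
        assert np.array_equal(pop.freq, founders.freq)
        assert np.array_equal(founder_freq, founders.freq)


class TestPoolseqDetect:
    def test_fixed_site_always_detected_at_frequency_one(self, rng):
        cat = poolseq_detect([("2L", 100)], np.array([1.0]), 1, 0, rng)
        assert len(cat.frame) == 1
        assert cat.frame.loc[0, "frequency"] == 1.0

    def test_absent_site_never_detected(self, rng):
        cat = poolseq_detect([("2L", 100)], np.array([0.0]), 1, 0, rng)
        assert len(cat.frame) == 0

    def test_detection_probability_matches_closed_form(self, rng):
        """f=0.1 at C=50, min_count=1: P(detect) = 1 - 0.9^50 = 0.9948."""
        n = 20_000
        sites = [("2L", 1000 * i) for i in range(n)]
        cat = poolseq_detect(sites, np.full(n, 0.1), 1, 0, rng, coverage=50)
        p = 1 - 0.9**50
        se = np.sqrt(p * (1 - p) / n)
        assert len(cat.frame) / n == pytest.approx(p, abs=4 * se)

    def test_estimated_frequency_unbiased(self, rng):
        n = 10_000
        sites = [("2L", 1000 * i) for i in range(n)]
        cat = poolseq_detect(sites, np.full(n, 0.3), 1, 0, rng, coverage=50)
        se = np.sqrt(0.3 * 0.7 / 50 / n)
        assert cat.frame["frequency"].mean() == pytest.approx(0.3, abs=4 * se)

    def test_nearby_sites_merge_into_one_record(self, rng):
        cat = poolseq_detect(
            [("2L", 100), ("2L", 400)], np.array([1.0, 1.0]), 1, 0, rng
        )
        assert len(cat.frame) == 1
        assert cat.frame.loc[0, "pos"] == 100

    def test_detection_rate_uniform_across_features(self, rng):
        """Detection sensitivity depends only on frequency, not on the
        annotation feature of the site."""
        annotation, _, _ = toy_genome()
        offset_by_feature = {"CDS": 300, "intron": 1900, "intergenic": 4000}
        p = 1 - 0.9**50
        for feat, offset in offset_by_feature.items():
            assert annotation.annotate_point("2L", offset) == feat
            # 100 well-separated sites of this feature, 50 detection draws
            sites = [("2L", offset + 10_000 * i) for i in range(100)]
            freq = np.full(100, 0.1)
            detected = sum(
                len(poolseq_detect(sites, freq, 1, 0, rng, coverage=50).frame)
                for _ in range(50)
            )
            n = 100 * 50
            se = np.sqrt(p * (1 - p) / n)
            assert detected / n == pytest.approx(p, abs=4 * se), feat


class TestFullExperiment:
    def test_deterministic_catalogs_under_fixed_seed(self):
        config = small_config()
        a = simulate_experiment(config, 11)
        b = simulate_experiment(config, 11)
        for ca, cb in zip(a.catalogs, b.catalogs):
            pd.testing.assert_frame_equal(ca.frame, cb.frame)
        for rep in a.truth:
            pd.testing.assert_frame_equal(a.truth[rep], b.truth[rep])

    def test_six_samples_emitted(self):
        config = small_config(n_replicates=3)
        res = simulate_experiment(config, 2)
        keys = {c.key for c in res.catalogs}
        assert keys == {f"r{r}_g{g}" for r in (1, 2, 3) for g in (0, 10)}

    def test_truth_log_classes_cover_all_loci(self):
        res = simulate_experiment(toy_config(n_lines=5), 3)
        for truth in res.truth.values():
            assert set(truth["true_class"]).issubset(
                {"lost", "persistent", "phase-2", "none"}
            )
            p1 = truth[truth["founder_freq"] > 0]
            assert (
                (p1["true_class"] == "lost") | (p1["true_class"] == "persistent")
            ).all()
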