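"""Site matching, joint/separate classification, RFS."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from pelement_er.catalog import (
    SampleCatalog,
    classify_joint,
    classify_separate,
    match_sites,
    replicate_frequency_spectrum,
)
from pelement_er.genome import GenomicInterval, RegionSet

GI = GenomicInterval


def cat(rep, gen, positions, chrom="2L", freq=0.1):
    return SampleCatalog(
        replicate=rep, generation=gen,
        frame=pd.DataFrame(
            {"chrom": chrom, "pos": positions, "frequency": freq}
        ),
    )


def six_samples(gen0={1: [], 2: [], 3: []}, gen10={1: [], 2: [], 3: []}):
    return [cat(r, 0, gen0[r]) for r in (1, 2, 3)] + [
        cat(r, 10, gen10[r]) for r in (1, 2, 3)
    ]


class TestMatchSites:
    def test_sites_within_radius_merge_across_samples(self):
        m = match_sites([cat(1, 0, [1000]), cat(1, 10, [1300])], radius=500)
        assert len(m) == 1
        assert m.loc[0, "pos"] == 1000  # representative = cluster minimum
        assert m.loc[0, "in_r1_g0"] and m.loc[0, "in_r1_g10"]

    def test_distant_sites_stay_separate(self):
        m = match_sites([cat(1, 0, [1000]), cat(1, 10, [3000])], radius=500)
        assert len(m) == 2

    def test_chain_merges_transitively(self):
        m = match_sites([cat(1, 0, [0, 400, 800])], radius=500)
        assert len(m) == 1 and m.loc[0, "pos"] == 0

    def test_different_chromosomes_never_merge(self):
        m = match_sites([cat(1, 0, [100]), cat(1, 10, [100], chrom="3R")], radius=500)
        assert len(m) == 2


class TestClassifyJoint:
    def test_persistent_in_focal_lost_elsewhere(self):
        """Detected at generation 0 in one replicate only: persistent
        where re-detected, lost in replicates where it is gone."""
        cats = six_samples(
            gen0={1: [5000], 2: [], 3: []}, gen10={1: [5000], 2: [], 3: []}
        )
        cl = classify_joint(match_sites(cats))
        assert cl.loc[0, "class_r1"] == "persistent"
        assert cl.loc[0, "class_r2"] == "lost"
        assert cl.loc[0, "class_r3"] == "lost"

    def test_new_site_is_phase2_in_focal_absent_elsewhere(self):
        cats = six_samples(gen10={1: [], 2: [], 3: [7000]})
        cl = classify_joint(match_sites(cats))
        assert cl.loc[0, "class_r3"] == "phase-2"
        assert cl.loc[0, "class_r1"] == "absent"
        assert cl.loc[0, "class_r2"] == "absent"

    def test_everywhere_detected_is_persistent_everywhere(self):
        cats = six_samples(
            gen0={1: [], 2: [5000], 3: []},
            gen10={1: [5000], 2: [5000], 3: [5000]},
        )
        cl = classify_joint(match_sites(cats))
        assert (cl[[f"class_r{r}" for r in (1, 2, 3)]] == "persistent").all().all()

    def test_missing_sample_rejected(self):
        cats = six_samples()[:-1]
        matrix = match_sites([c for c in cats if len(c.frame)] or [cat(1, 0, [1])])
        with pytest.raises(ValueError, match="missing sample"):
            classify_joint(matrix)

    def test_classes_partition_phase1_sites(self, rng):
        """Per replicate, lost + persistent = number of sites detected
        at generation 0 in any replicate."""
        gen0 = {r: sorted(rng.choice(10**6, 40, replace=False)) for r in (1, 2, 3)}
        gen10 = {r: sorted(rng.choice(10**6, 40, replace=False)) for r in (1, 2, 3)}
        cl = classify_joint(match_sites(six_samples(gen0, gen10)))
        m = match_sites(six_samples(gen0, gen10))
        n_phase1 = (m[[f"in_r{r}_g0" for r in (1, 2, 3)]].any(axis=1)).sum()
        for r in (1, 2, 3):
            counts = cl[f"class_r{r}"].value_counts()
            assert counts.get("lost", 0) + counts.get("persistent", 0) == n_phase1


class TestClassifySeparate:
    @pytest.mark.parametrize(
        "g0, g10, expected",
        [([100], [], "lost"), ([], [100], "phase-2"), ([100], [150], "persistent")],
    )
    def test_within_replicate_rules(self, g0, g10, expected):
        cl = classify_separate(cat(2, 0, g0), cat(2, 10, g10))
        assert cl.loc[0, "class"] == expected

    def test_replicate_mismatch_rejected(self):
        with pytest.raises(ValueError):
            classify_separate(cat(1, 0, [100]), cat(2, 10, [100]))


class TestReplicateFrequencySpectrum:
    def _regions(self):
        orc = RegionSet("ORC", [GI("2L", 0, 2000)])
        shared = RegionSet("shared", [GI("2L", 1500, 2500), GI("2L", 9000, 9500)])
        return orc, shared

    def test_cross_replicate_match_within_1kb(self):
        orc, shared = self._regions()
        rfs = replicate_frequency_spectrum(
            {1: [("2L", 5000)], 2: [("2L", 5900)], 3: []}, orc, shared
        )
        row = rfs.set_index(["region_class", "n_replicates"])
        assert row.loc[("!ORC & !shared", 2), "count"] == 1

    def test_single_replicate_inside_orc_only(self):
        orc, shared = self._regions()
        rfs = replicate_frequency_spectrum({1: [("2L", 100)], 2: [], 3: []}, orc, shared)
        row = rfs.set_index(["region_class", "n_replicates"])
        assert row.loc[("ORC & !shared", 1), "count"] == 1

    def test_three_replicates_in_both_region_sets(self):
        orc, shared = self._regions()
        rfs = replicate_frequency_spectrum(
            {1: [("2L", 1600)], 2: [("2L", 1700)], 3: [("2L", 1800)]}, orc, shared
        )
        row = rfs.set_index(["region_class", "n_replicates"])
        assert row.loc[("ORC & shared", 3), "count"] == 1

    def test_proportions_sum_to_one_per_region_class(self, rng):
        orc, shared = self._regions()
        sites = {
            r: [("2L", int(p)) for p in rng.choice(10**5, 30, replace=False)]
            for r in (1, 2, 3)
        }
        rfs = replicate_frequency_spectrum(sites, orc, shared)
        grouped = rfs.groupby("region_class")
        occupied = grouped["count"].sum() > 0
        sums = grouped["proportion"].sum()[occupied]
        assert len(sums) > 0 and np.allclose(sums, 1.0)

    def test_counts_sum_to_distinct_persistent_sites(self):
        orc, shared = self._regions()
        rfs = replicate_frequency_spectrum(
            {1: [("2L", 5000), ("2L", 20000)], 2: [("2L", 5500)], 3: []},
            orc, shared,
        )
        assert rfs["count"].sum() == 2


class TestCatalogIO:
    def test_tsv_roundtrip(self, tmp_path):
        c = cat(2, 10, [100, 5000], freq=0.25)
        path = tmp_path / "c.tsv"
        c.write_tsv(path)
        back = SampleCatalog.read_tsv(path)
        assert back.replicate == 2 and back.generation == 10
        pd.testing.assert_frame_equal(
            back.frame, c.frame, check_dtype=False
        )
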