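from __future__ import annotations

import numpy as np
import pytest

from pelement_er.genome import AnnotationSet, GenomicInterval, RegionSet


@pytest.fixture
def small_annotation() -> AnnotationSet:
    """10 kb single-chromosome genome with deliberately overlapping
    tracks to exercise precedence resolution."""
    tracks = {
        "CDS": [GenomicInterval("4", 1000, 2000), GenomicInterval("4", 5000, 5500)],
        "five_prime_UTR": [GenomicInterval("4", 800, 1100)],
        "three_prime_UTR": [GenomicInterval("4", 2000, 2200)],
        "exon": [GenomicInterval("4", 800, 2500)],
        "intron": [GenomicInterval("4", 1500, 3500)],
    }
    return AnnotationSet(tracks, {"4": 10_000})


@pytest.fixture
def orc_regions() -> RegionSet:
    return RegionSet(
        "ORC",
        [GenomicInterval("4", 1200, 1400), GenomicInterval("4", 6000, 6500)],
    )


@pytest.fixture
def shared_regions() -> RegionSet:
    return RegionSet(
        "shared",
        [GenomicInterval("4", 1300, 1350), GenomicInterval("4", 8000, 8200)],
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
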