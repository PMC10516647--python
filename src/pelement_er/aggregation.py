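"""Rediscovery-rate-corrected aggregation estimator.

Aggregation of TE insertions into a focal region set (e.g. ORC binding
sites or shared sites) is the fraction of insertions falling inside it.
Comparing aggregation between phase 1 (weak selection, small lines) and
phase 2 (strong selection, large outbred populations) separates
insertion bias from spatially variable purifying selection: under
uniform selection the two phases show the same aggregation regardless
of bias.

The phase-2 estimate must correct for lost phase-1 insertions that were
restored by new insertions during phase 2. The rediscovery rate r —
the fraction of phase-1 insertions outside the hotspot union that are
re-detected after phase 2 — predicts how many phase-1 insertions inside
the focal region should persist absent re-insertion; the observed
excess estimates the number of re-insertions R, which is added to both
the numerator and denominator of the phase-2 aggregation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .enrichment import replicate_mean_sem


@dataclass
class AggregationInput:
    """Counts feeding the estimator for one replicate and one focal region.

    ``phase1_out`` and ``persistent_out`` are counted outside the union
    of all hotspot region sets (ORC plus shared), not merely outside the
    focal region, so that the rediscovery rate is estimated from regions
    without insertion bias.
    """

    phase1_in: int
    phase1_out: int
    persistent_in: int
    persistent_out: int
    phase2_new_in: int
    phase2_new_total: int
    phase1_total: int | None = None  # defaults to phase1_in + phase1_out
    replicate: int | None = None

    def __post_init__(self) -> None:
        counts = [
            self.phase1_in, self.phase1_out, self.persistent_in,
            self.persistent_out, self.phase2_new_in, self.phase2_new_total,
        ]
        if any(c < 0 for c in counts):
            raise ValueError("negative count")
        if self.persistent_out > self.phase1_out:
            raise ValueError("persistent_out exceeds phase1_out")
        if self.phase2_new_in > self.phase2_new_total:
            raise ValueError("phase2_new_in exceeds phase2_new_total")
        if self.phase1_total is None:
            self.phase1_total = self.phase1_in + self.phase1_out


@dataclass
class AggregationResult:
    a1: float
    a2: float
    rediscovery: float
    reinsertions: float
    pct_change: float
    replicate: int | None = None


def rediscovery_rate(persistent_out: int, phase1_out: int) -> float:
    """Fraction of phase-1 insertions outside hotspot regions that are
    re-detected after phase 2."""
    if phase1_out <= 0:
        raise ValueError("rediscovery rate undefined without phase-1 sites outside")
    r = persistent_out / phase1_out
    if not 0 <= r <= 1:
        raise ValueError("rediscovery rate outside [0, 1]")
    return r


def estimate_reinsertions(persistent_in: int, r: float, phase1_in: int) -> float:
    """Excess of observed over expected persistent insertions inside the
    focal region, floored at zero (a negative re-insertion count is a
    sampling artefact)."""
    if not 0 <= r <= 1:
        raise ValueError("rediscovery rate outside [0, 1]")
    return max(0.0, persistent_in - r * phase1_in)


def aggregation(inp: AggregationInput) -> AggregationResult:
    """Phase-1 and corrected phase-2 aggregation for one replicate.

    A1 = phase-1 insertions inside / all phase-1 insertions.
    A2 = (observed new phase-2 insertions inside + re-insertion
    correction X) / (all observed phase-2 insertions + X), where
    X = persistent_in - r * phase1_in is the raw observed-minus-expected
    excess of persistent insertions inside the focal region.

    The raw (possibly negative) excess is used inside A2 — flooring it
    at zero there would bias the corrected aggregation upward under the
    no-selection-difference null, because E[max(0, X)] > 0 even when
    E[X] = 0. The reported re-insertion count is floored (a negative
    count of events is meaningless).
    """
    if inp.phase1_total is None or inp.phase1_total <= 0:
        raise ValueError("no phase-1 insertions; aggregation undefined")
    r = rediscovery_rate(inp.persistent_out, inp.phase1_out)
    excess = inp.persistent_in - r * inp.phase1_in
    reins = estimate_reinsertions(inp.persistent_in, r, inp.phase1_in)
    a1 = inp.phase1_in / inp.phase1_total
    denom = inp.phase2_new_total + excess
    if denom <= 0:
        raise ValueError("no phase-2 insertions; aggregation undefined")
    a2 = (inp.phase2_new_in + excess) / denom
    if a1 <= 0:
        raise ValueError("zero phase-1 aggregation; percent change undefined")
    pct = 100.0 * (a2 - a1) / a1
    return AggregationResult(
        a1=a1, a2=a2, rediscovery=r, reinsertions=reins, pct_change=pct,
        replicate=inp.replicate,
    )


def summarize_replicates(results: list[AggregationResult]) -> dict[str, float]:
    """Mean and SEM of the per-replicate aggregation change."""
    mean, sem = replicate_mean_sem([res.pct_change for res in results])
    a1_mean, _ = replicate_mean_sem([res.a1 for res in results])
    a2_mean, _ = replicate_mean_sem([res.a2 for res in results])
    return {
        "pct_change_mean": mean,
        "pct_change_sem": sem,
        "a1_mean": a1_mean,
        "a2_mean": a2_mean,
        "n": len(results),
    }
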