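"""Read-depth CNV stage, dual-pipeline consensus, and gene annotation.

The depth caller is deliberately simple — a library-size-normalized
depth-ratio test with a robust dispersion z-score against a reference panel
and run merging over consecutive targets — documented as a stand-in for a
full statistical exome-depth model. The architecture under test is the
consensus: only calls detected by both the discordant-pair caller and the
depth caller survive, and consensus calls are annotated with the genes they
overlap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from intervaltree import IntervalTree

from .model import CnvCall, GenomicInterval


@dataclass(frozen=True)
class TargetCounts:
    """Per-target read counts: one case vector plus a reference matrix
    (targets x reference samples), rows aligned 1:1 with ``targets``."""

    targets: tuple
    case_counts: np.ndarray
    reference_matrix: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.targets)
        if self.case_counts.shape != (n,):
            raise ValueError("case_counts must align 1:1 with targets")
        if self.reference_matrix.ndim != 2 or self.reference_matrix.shape[0] != n:
            raise ValueError("reference_matrix rows must align 1:1 with targets")
        if (self.case_counts < 0).any() or (self.reference_matrix < 0).any():
            raise ValueError("counts must be >= 0")


@dataclass(frozen=True)
class ConsensusConfig:
    """Depth-caller and consensus parameters.

    reciprocal_overlap: minimum shared fraction of each interval's own span
        for a discordant and a depth call to agree.
    ratio_dup / ratio_del: normalized depth-ratio thresholds for calling a
        target duplicated (expected 1.5 for a heterozygous duplication) or
        deleted (expected 0.5).
    min_consecutive_targets: run length needed before a call is emitted.
    z_threshold: minimum |z| of the case against the reference dispersion.
    """

    reciprocal_overlap: float = 0.5
    ratio_dup: float = 1.3
    ratio_del: float = 0.7
    min_consecutive_targets: int = 2
    z_threshold: float = 3.0

    def __post_init__(self) -> None:
        if not 0 < self.reciprocal_overlap <= 1:
            raise ValueError("reciprocal_overlap must be in (0, 1]")
        if not self.ratio_del < 1 < self.ratio_dup:
            raise ValueError("need ratio_del < 1 < ratio_dup")


def call_cnv_depth(
    counts: TargetCounts, config: ConsensusConfig = ConsensusConfig()
) -> list:
    """Depth-ratio CNV calls from case counts against a reference panel.

    Case and reference columns are normalized by their total count over the
    targets; per target, ratio = normalized case / mean normalized reference
    and z = (normalized case - reference mean) / reference SD. Runs of at
    least ``min_consecutive_targets`` consecutive targets on one chromosome
    that clear both the ratio and |z| thresholds in the same direction merge
    into a single call with support = run length.
    """
    if counts.reference_matrix.shape[1] < 2:
        raise ValueError("need at least 2 reference samples")
    case = counts.case_counts.astype(float)
    ref = counts.reference_matrix.astype(float)
    case_n = case / case.sum()
    ref_n = ref / ref.sum(axis=0, keepdims=True)
    ref_mean = ref_n.mean(axis=1)
    usable = ref_mean > 0

    # Robust dispersion: a per-target SD from a handful of reference samples
    # is far too noisy, so pool leave-one-out reference residuals across all
    # targets under a variance-proportional-to-mean model and take a single
    # MAD-based scale. sd(target) = sigma0 * sqrt(ref_mean).
    n_ref = ref_n.shape[1]
    loo_mean = (ref_n.sum(axis=1, keepdims=True) - ref_n) / (n_ref - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        scaled = (ref_n - loo_mean)[usable] / np.sqrt(ref_mean[usable, None])
    sigma0 = 1.4826 * np.median(np.abs(scaled))
    sigma0 = max(float(sigma0), 1e-12)

    ratio = np.ones_like(case_n)
    ratio[usable] = case_n[usable] / ref_mean[usable]
    z = np.zeros_like(case_n)
    z[usable] = (case_n[usable] - ref_mean[usable]) / (
        sigma0 * np.sqrt(ref_mean[usable])
    )

    state = np.zeros(len(ratio), dtype=int)  # +1 dup, -1 del
    state[usable & (ratio >= config.ratio_dup) & (z >= config.z_threshold)] = 1
    state[usable & (ratio <= config.ratio_del) & (z <= -config.z_threshold)] = -1

    calls = []
    i = 0
    n = len(state)
    while i < n:
        if state[i] == 0:
            i += 1
            continue
        j = i
        chrom = counts.targets[i].chrom
        while (
            j + 1 < n
            and state[j + 1] == state[i]
            and counts.targets[j + 1].chrom == chrom
        ):
            j += 1
        run_len = j - i + 1
        if run_len >= config.min_consecutive_targets:
            calls.append(
                CnvCall(
                    interval=GenomicInterval(
                        chrom, counts.targets[i].start, counts.targets[j].end
                    ),
                    sv_type="dup" if state[i] == 1 else "del",
                    support=run_len,
                    source="depth",
                    rank=len(calls) + 1,
                )
            )
        i = j + 1
    return calls


def consensus_calls(
    discordant: Sequence[CnvCall],
    depth: Sequence[CnvCall],
    config: ConsensusConfig = ConsensusConfig(),
) -> list:
    """Calls detected by both pipelines.

    A consensus call is emitted for every (discordant, depth) pair on the
    same chromosome whose reciprocal overlap reaches the threshold; its
    interval is the intersection, its sv-type is kept when the parents
    agree and is ``unknown`` otherwise, and its support is the smaller
    parent support. Output is sorted by coordinate.
    """
    out = []
    for a in discordant:
        for b in depth:
            if a.interval.reciprocal_overlap(b.interval) >= config.reciprocal_overlap:
                inter = GenomicInterval(
                    a.interval.chrom,
                    max(a.interval.start, b.interval.start),
                    min(a.interval.end, b.interval.end),
                )
                out.append(
                    CnvCall(
                        interval=inter,
                        sv_type=a.sv_type if a.sv_type == b.sv_type else "unknown",
                        support=min(a.support, b.support),
                        source="consensus",
                    )
                )
    out.sort(key=lambda c: (c.interval.chrom, c.interval.start, c.interval.end))
    return [
        CnvCall(
            interval=c.interval,
            sv_type=c.sv_type,
            support=c.support,
            source=c.source,
            genes=c.genes,
            rank=i + 1,
        )
        for i, c in enumerate(out)
    ]


def annotate_genes(calls: Sequence[CnvCall], gene_intervals: Sequence[tuple]) -> list:
    """Attach every gene overlapping a call by >= 1 base, in genomic order."""
    trees: dict = {}
    for iv, symbol in gene_intervals:
        # half-open tree coordinates; +1 keeps the 1-based closed end inside
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end + 1, symbol)
    annotated = []
    for call in calls:
        tree = trees.get(call.interval.chrom)
        genes: tuple = ()
        if tree is not None:
            hits = sorted(
                tree.overlap(call.interval.start, call.interval.end + 1),
                key=lambda h: (h.begin, h.end),
            )
            genes = tuple(h.data for h in hits)
        annotated.append(
            CnvCall(
                interval=call.interval,
                sv_type=call.sv_type,
                support=call.support,
                source=call.source,
                genes=genes,
                rank=call.rank,
            )
        )
    return annotated
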