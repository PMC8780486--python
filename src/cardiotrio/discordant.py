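"""Discordant read-pair CNV calling.

The caller consumes alignment fields only: it keeps uniquely mapped pairs
(MAPQ equal to the aligner's unique-mapping cap, 60 by default) whose
absolute template length falls in a structural-variant window (2.5 kb to
350 kb by default), derives the genomic footprint each template implies,
single-linkage clusters footprints whose endpoints agree within a +/-5%
coordinate tolerance, and reports clusters ranked by the number of
supporting templates.

Support counts templates (physical pairs), not alignment lines: the two
mates of a pair are canonicalized to the leftmost one (positive TLEN)
before clustering.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .io import read_sam_pairs
from .model import CnvCall, DiscordantCluster, GenomicInterval, ReadPairRecord


@dataclass(frozen=True)
class DiscordantFilterConfig:
    """Parameters of the discordant-pair caller.

    mapq_required: exact mapping quality a read must carry (the unique-
        mapping cap; equality, not a lower bound).
    tlen_min / tlen_max: inclusive bounds on |TLEN| in bases.
    cluster_tolerance: endpoint agreement as a fraction of the mean span of
        the two footprints being compared.
    min_support: minimum templates for a cluster to become a call.
    """

    mapq_required: int = 60
    tlen_min: int = 2500
    tlen_max: int = 350_000
    cluster_tolerance: float = 0.05
    min_support: int = 3

    def __post_init__(self) -> None:
        if not 0 < self.tlen_min < self.tlen_max:
            raise ValueError("need 0 < tlen_min < tlen_max")
        if not 0 < self.cluster_tolerance < 1:
            raise ValueError("cluster_tolerance must be in (0, 1)")
        if self.min_support < 1:
            raise ValueError("min_support must be >= 1")


def filter_discordant_pairs(
    pairs: Iterable[ReadPairRecord],
    config: DiscordantFilterConfig = DiscordantFilterConfig(),
    stats: Optional[dict] = None,
) -> list:
    """Keep one record per discordant template.

    A record is retained iff mapq == mapq_required and
    tlen_min <= |tlen| <= tlen_max (bounds inclusive). Records with
    tlen == 0 (unpaired or unmapped mate) are silently excluded and
    tallied under ``stats['skipped_zero_tlen']`` when a dict is passed.
    Exactly one record per template is kept — the leftmost mate
    (tlen > 0) when both pass; a lone rightmost mate is kept as-is and
    canonicalized downstream.
    """
    retained: list = []
    chosen: dict = {}
    skipped_zero = 0
    for p in pairs:
        if p.tlen == 0:
            skipped_zero += 1
            continue
        if p.mapq != config.mapq_required:
            continue
        if not config.tlen_min <= abs(p.tlen) <= config.tlen_max:
            continue
        if p.read_id in chosen:
            i = chosen[p.read_id]
            if retained[i].tlen < 0 and p.tlen > 0:
                retained[i] = p  # prefer the leftmost mate of the template
            continue
        chosen[p.read_id] = len(retained)
        retained.append(p)
    if stats is not None:
        stats["skipped_zero_tlen"] = stats.get("skipped_zero_tlen", 0) + skipped_zero
        stats["retained"] = stats.get("retained", 0) + len(retained)
    return retained


def implied_interval(pair: ReadPairRecord) -> GenomicInterval:
    """Genomic footprint the template spans.

    For the canonical leftmost mate (tlen > 0): [pos, pos + tlen - 1].
    For a lone rightmost mate (tlen < 0) the leftmost start is estimated
    as pos + tlen + 1, which ignores the read length — an offset within
    the clustering tolerance for spans in the structural-variant window.
    A tlen of 0 violates the filter's contract.
    """
    if pair.tlen == 0:
        raise ValueError("implied_interval requires |tlen| >= 1, got tlen=0")
    if pair.tlen > 0:
        return GenomicInterval(pair.chrom, pair.pos, pair.pos + pair.tlen - 1)
    return GenomicInterval(pair.chrom, max(1, pair.pos + pair.tlen + 1), pair.pos)


def _orientation(pair: ReadPairRecord) -> str:
    """FR/RF of the template, expressed from its leftmost mate."""
    fwd, mate_fwd = not pair.is_reverse, not pair.mate_is_reverse
    if pair.tlen < 0:  # record is the rightmost mate: swap the roles
        fwd, mate_fwd = mate_fwd, fwd
    if fwd and not mate_fwd:
        return "FR"
    if not fwd and mate_fwd:
        return "RF"
    return "other"


def _linked(
    a: GenomicInterval, b: GenomicInterval, tolerance: float
) -> bool:
    """Endpoint-wise +/-tolerance linkage against the mean span of the two."""
    if a.chrom != b.chrom:
        return False
    allowed = tolerance * (a.span + b.span) / 2.0
    return abs(a.start - b.start) <= allowed and abs(a.end - b.end) <= allowed


def cluster_pairs(
    retained: Sequence[ReadPairRecord],
    config: DiscordantFilterConfig = DiscordantFilterConfig(),
) -> list:
    """Single-linkage clustering of implied intervals.

    Two footprints link iff both their starts and their ends agree within
    cluster_tolerance x mean(span_a, span_b); clusters are the transitive
    closure of that relation. The representative interval takes the median
    of member starts and the median of member ends. Every retained pair
    belongs to exactly one cluster (singletons allowed).
    """
    pairs = list(retained)
    intervals = [implied_interval(p) for p in pairs]
    n = len(pairs)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    # Discordant pairs are rare, so the quadratic sweep is cheap in practice.
    for i in range(n):
        for j in range(i + 1, n):
            if _linked(intervals[i], intervals[j], config.cluster_tolerance):
                union(i, j)

    groups: dict = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)

    clusters = []
    for members in groups.values():
        members.sort(key=lambda i: (intervals[i].start, intervals[i].end))
        start = int(statistics.median_low([intervals[i].start for i in members]))
        end = int(statistics.median_high([intervals[i].end for i in members]))
        end = max(end, start)
        profile = {"FR": 0, "RF": 0, "other": 0}
        for i in members:
            profile[_orientation(pairs[i])] += 1
        clusters.append(
            DiscordantCluster(
                interval=GenomicInterval(pairs[members[0]].chrom, start, end),
                member_ids=tuple(pairs[i].read_id for i in members),
                orientation_profile=profile,
            )
        )
    clusters.sort(key=lambda c: (c.interval.chrom, c.interval.start, c.interval.end))
    return clusters


def _cluster_sv_type(profile: dict) -> str:
    rf, fr = profile.get("RF", 0), profile.get("FR", 0)
    if rf > fr:
        return "dup"
    if fr > rf:
        return "del"
    return "unknown"


def prioritize_clusters(
    clusters: Sequence[DiscordantCluster],
    config: DiscordantFilterConfig = DiscordantFilterConfig(),
) -> list:
    """Threshold clusters at min_support and rank by read support.

    Calls are sorted by support descending, ties broken by span descending
    then by coordinate; rank is the 1-based position in that order. The
    sv-type comes from the dominant orientation (everted RF majority: dup;
    FR majority: del; tie: unknown).
    """
    kept = [c for c in clusters if c.support >= config.min_support]
    kept.sort(
        key=lambda c: (
            -c.support,
            -c.interval.span,
            c.interval.chrom,
            c.interval.start,
            c.interval.end,
        )
    )
    return [
        CnvCall(
            interval=c.interval,
            sv_type=_cluster_sv_type(c.orientation_profile),
            support=c.support,
            source="discordant",
            rank=i + 1,
        )
        for i, c in enumerate(kept)
    ]


def call_cnv_discordant(
    sam_path,
    config: DiscordantFilterConfig = DiscordantFilterConfig(),
    stats: Optional[dict] = None,
) -> list:
    """Full in-house pipeline: filter -> implied intervals -> cluster -> rank."""
    retained = filter_discordant_pairs(read_sam_pairs(sam_path), config, stats=stats)
    clusters = cluster_pairs(retained, config)
    return prioritize_clusters(clusters, config)
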