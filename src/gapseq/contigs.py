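"""Contig assembly, base-read-ratio and Rank scoring, candidate calling.

This is the heart of the caller.  Palindromic loci survive the
snap-back/S1 enrichment protocol and show up as read pileups, so the
pipeline is a pure coverage-enrichment scan:

1. assemble uniquely mapped reads into *contigs* -- maximal runs of
   overlapping (or abutting) reads -- and score each with the base read
   ratio ``B = sum(read lengths) / contig length`` (B = 1 for a lone
   read, B > 1 for pileups);
2. single-linkage cluster contigs with ``B >= 1.5`` lying within 7.5 kb
   of each other (edge-to-edge) into *joined contigs*, requiring at
   least two members per cluster;
3. score each joined contig with the Rank
   ``R = total read bp within the span / (span length - masked length)``;
4. call candidates as joined contigs with ``R > 0.75``, sorted by R.

All thresholds live in :class:`CallerParams` and default to the values
above.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .core import GenomicInterval, MappedRead, MaskTrack

logger = logging.getLogger("gapseq")

__all__ = [
    "CallerParams",
    "Contig",
    "JoinedContig",
    "build_contigs",
    "join_contigs",
    "compute_rank",
    "call_candidates",
]


@dataclass(frozen=True)
class CallerParams:
    """Thresholds of the candidate caller.

    min_b : base read ratio above which a contig is joinable.
    max_gap : maximum edge-to-edge gap (bp) between joinable contigs.
    min_r : Rank threshold; candidates must have R strictly above it.
    min_members : minimum contigs per cluster ("two or more contigs").
    mask_overlap_drop : reads overlapping the mask by more than this
        fraction of their length are dropped before assembly (uniquely
        mapped input should already exclude them; this is a guard).
    """

    min_b: float = 1.5
    max_gap: int = 7_500
    min_r: float = 0.75
    min_members: int = 2
    mask_overlap_drop: float = 0.5

    def __post_init__(self) -> None:
        if min(self.min_b, self.max_gap, self.min_r, self.min_members) <= 0:
            raise ValueError("caller thresholds must be strictly positive")


@dataclass(frozen=True)
class Contig:
    """Maximal run of overlapping/abutting reads with its base read ratio."""

    interval: GenomicInterval
    reads: tuple[MappedRead, ...]
    read_bp: int

    @property
    def n_reads(self) -> int:
        return len(self.reads)

    @property
    def b(self) -> float:
        """Base read ratio: sum of member read lengths / contig length."""
        return self.read_bp / self.interval.length


@dataclass(frozen=True)
class JoinedContig:
    """Cluster of >= 2 high-B contigs with its Rank score.

    ``read_bp`` sums *all* reads whose midpoint falls within the span,
    including low-B contigs and singletons between members.
    """

    span: GenomicInterval
    members: tuple[Contig, ...]
    all_reads: tuple[MappedRead, ...]
    read_bp: int
    masked_len: int
    rank: float

    @property
    def n_contigs(self) -> int:
        return len(self.members)

    @property
    def n_reads(self) -> int:
        return len(self.all_reads)


def build_contigs(reads: Iterable[MappedRead]) -> list[Contig]:
    """Assemble reads into contigs (maximal overlap-connected runs).

    Abutting reads (zero gap in half-open coordinates) merge: a zero-gap
    union is still one contiguous genomic region.  Input order is
    irrelevant; output is sorted by (chrom, start).
    """
    ordered = sorted(reads, key=lambda r: (r.interval.chrom, r.interval.start, r.interval.end, r.read_id))
    contigs: list[Contig] = []
    cur: list[MappedRead] = []
    cur_chrom, cur_start, cur_end = "", 0, 0

    def flush() -> None:
        if cur:
            contigs.append(
                Contig(
                    GenomicInterval(cur_chrom, cur_start, cur_end),
                    tuple(cur),
                    sum(r.length for r in cur),
                )
            )

    for r in ordered:
        iv = r.interval
        if cur and iv.chrom == cur_chrom and iv.start <= cur_end:
            cur.append(r)
            cur_end = max(cur_end, iv.end)
        else:
            flush()
            cur = [r]
            cur_chrom, cur_start, cur_end = iv.chrom, iv.start, iv.end
    flush()
    return contigs


def compute_rank(jc: JoinedContig, mask: MaskTrack | None = None) -> float:
    """Rank R = read_bp / (span length - masked length).

    Recomputes the masked length from ``mask`` when given, else uses the
    stored value.  Raises on a non-positive denominator (degenerate
    fully-masked span).
    """
    masked = jc.masked_len if mask is None else mask.masked_bp(jc.span)
    return _rank(jc.read_bp, jc.span.length, masked)


def _rank(read_bp: int, span_len: int, masked_len: int) -> float:
    denom = span_len - masked_len
    if denom <= 0:
        raise ValueError(
            f"joined-contig span is fully masked (span {span_len} bp, masked {masked_len} bp)"
        )
    return read_bp / denom


def join_contigs(
    contigs: Sequence[Contig],
    all_reads: Sequence[MappedRead],
    mask: MaskTrack | None = None,
    params: CallerParams = CallerParams(),
) -> list[JoinedContig]:
    """Single-linkage cluster high-B contigs into joined contigs.

    Contigs with ``B >= params.min_b`` whose edge-to-edge gap is
    ``<= params.max_gap`` cluster transitively; clusters with fewer than
    ``params.min_members`` contigs are discarded.  ``all_reads`` is the
    full read set -- every read whose midpoint lies inside a cluster
    span contributes its full length to that cluster's read_bp.
    Clusters whose span is entirely masked are dropped with a warning.
    """
    mask = mask if mask is not None else MaskTrack()
    high = [c for c in contigs if c.b >= params.min_b]
    high.sort(key=lambda c: (c.interval.chrom, c.interval.start, c.interval.end))

    # per-chromosome sorted read midpoints for fast span collection
    by_chrom: dict[str, tuple[np.ndarray, list[MappedRead]]] = {}
    for chrom in {c.interval.chrom for c in high}:
        rs = sorted(
            (r for r in all_reads if r.interval.chrom == chrom),
            key=lambda r: (r.interval.midpoint, r.interval.start, r.read_id),
        )
        by_chrom[chrom] = (np.array([r.interval.midpoint for r in rs]), rs)

    joined: list[JoinedContig] = []
    cluster: list[Contig] = []

    def flush() -> None:
        if len(cluster) < params.min_members:
            return
        chrom = cluster[0].interval.chrom
        span = GenomicInterval(
            chrom,
            min(c.interval.start for c in cluster),
            max(c.interval.end for c in cluster),
        )
        mids, rs = by_chrom[chrom]
        lo = int(np.searchsorted(mids, span.start, side="left"))
        hi = int(np.searchsorted(mids, span.end, side="left"))
        span_reads = tuple(rs[lo:hi])
        read_bp = sum(r.length for r in span_reads)
        masked_len = mask.masked_bp(span)
        try:
            r_score = _rank(read_bp, span.length, masked_len)
        except ValueError:
            logger.warning(
                "dropping fully-masked cluster %s:%d-%d", chrom, span.start, span.end
            )
            return
        joined.append(
            JoinedContig(span, tuple(cluster), span_reads, read_bp, masked_len, r_score)
        )

    for c in high:
        if (
            cluster
            and c.interval.chrom == cluster[-1].interval.chrom
            and c.interval.start - cluster[-1].interval.end <= params.max_gap
        ):
            cluster.append(c)
        else:
            flush()
            cluster = [c]
    flush()
    return joined


def _filter_masked_reads(
    reads: Sequence[MappedRead], mask: MaskTrack, max_frac: float
) -> list[MappedRead]:
    kept = [r for r in reads if mask.masked_bp(r.interval) <= max_frac * r.length]
    dropped = len(reads) - len(kept)
    if dropped:
        logger.warning(
            "dropped %d/%d reads overlapping the repeat mask by > %.0f%%",
            dropped,
            len(reads),
            100 * max_frac,
        )
    return kept


def call_candidates(
    reads: Sequence[MappedRead],
    mask: MaskTrack | None = None,
    params: CallerParams = CallerParams(),
) -> list[JoinedContig]:
    """Full caller: assemble -> join -> rank -> threshold.

    Returns joined contigs with ``R > params.min_r`` sorted by R
    descending, ties broken by (chrom, start) for determinism.  The
    result is a pure function of the input read *set* (input order is
    irrelevant).
    """
    mask = mask if mask is not None else MaskTrack()
    kept = _filter_masked_reads(reads, mask, params.mask_overlap_drop)
    contigs = build_contigs(kept)
    joined = join_contigs(contigs, kept, mask, params)
    hits = [jc for jc in joined if jc.rank > params.min_r]
    hits.sort(key=lambda jc: (-jc.rank, jc.span.chrom, jc.span.start))
    return hits
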