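"""Random-placement null model for the specificity of the B/R thresholds.

The observed read set is re-placed uniformly at random over the genome
(read count and read-length multiset preserved exactly; placements
touching any repeat-masked base are rejected and redrawn), the full
caller is run on the null reads, and the resulting contig/Rank
statistics describe what pure coverage noise produces.  The published
analysis used this to argue that ~4% of random reads land in contigs
with B > 1.5 and that random joined contigs stay below the R = 0.75
candidate threshold; see the methods note for a discussion of the
extreme-value behavior of the second claim.

The default configuration is a scaled stand-in for the original run:
one 50-Mb chromosome, 10% masked in 500-bp islands, 6% coverage with
fixed 279-bp reads (the observed mean read length).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core import GenomicInterval, MappedRead, MaskTrack
from .contigs import CallerParams, build_contigs, join_contigs

__all__ = [
    "NullConfig",
    "NullSummary",
    "default_null_mask",
    "place_random_reads",
    "null_summary",
    "run_replicates",
    "empirical_threshold",
]


def default_null_mask(
    genome_len: int = 50_000_000,
    masked_fraction: float = 0.10,
    island: int = 500,
    chrom: str = "sim1",
    seed: int = 0,
) -> MaskTrack:
    """Random non-overlapping mask islands covering ``masked_fraction``."""
    rng = np.random.default_rng(seed)
    n_islands = int(round(genome_len * masked_fraction / island))
    occupied: list[tuple[int, int]] = []
    starts: list[int] = []
    attempts = 0
    while len(starts) < n_islands:
        attempts += 1
        if attempts > 100 * n_islands:
            raise RuntimeError("could not place mask islands without overlap")
        s = int(rng.integers(0, genome_len - island))
        if all(s + island <= a or s >= b for a, b in occupied):
            occupied.append((s, s + island))
            starts.append(s)
    return MaskTrack(GenomicInterval(chrom, s, s + island) for s in starts)


@dataclass(frozen=True)
class NullConfig:
    """Inputs of one null replicate.

    read_lengths may be a single int (all reads that length) or a
    sequence giving the exact per-read length multiset to preserve.
    """

    chrom_sizes: dict[str, int] = field(
        default_factory=lambda: {"sim1": 50_000_000}
    )
    mask: MaskTrack | None = None
    n_reads: int = 10_753  # 6% coverage of 50 Mb at 279 bp
    read_lengths: int | Sequence[int] = 279
    seed: int = 0
    n_replicates: int = 1
    max_draw_factor: int = 1_000

    def __post_init__(self) -> None:
        if self.n_reads < 1:
            raise ValueError("n_reads must be >= 1")
        if min(self.length_array()) < 1:
            raise ValueError("read lengths must be >= 1")

    def length_array(self) -> np.ndarray:
        if isinstance(self.read_lengths, (int, np.integer)):
            return np.full(self.n_reads, int(self.read_lengths), dtype=np.int64)
        arr = np.asarray(self.read_lengths, dtype=np.int64)
        if len(arr) != self.n_reads:
            raise ValueError("read_lengths sequence must have n_reads entries")
        return arr

    @classmethod
    def from_coverage(
        cls,
        genome_len: int = 50_000_000,
        coverage: float = 0.06,
        read_length: int = 279,
        chrom: str = "sim1",
        **kwargs,
    ) -> "NullConfig":
        n_reads = int(round(genome_len * coverage / read_length))
        return cls(
            chrom_sizes={chrom: genome_len},
            n_reads=n_reads,
            read_lengths=read_length,
            **kwargs,
        )


def place_random_reads(
    config: NullConfig, rng: np.random.Generator | None = None
) -> list[MappedRead]:
    """Place the read multiset uniformly at random, avoiding the mask.

    Each read must fit entirely within its chromosome; any placement
    overlapping >= 1 masked base is rejected and redrawn (so null reads
    live entirely in unique sequence, like the real pipeline's input).
    Reproducible for a fixed seed.  Raises if the rejection loop
    exceeds ``max_draw_factor * n_reads`` draws (mask too dense).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    mask = config.mask if config.mask is not None else MaskTrack()
    chroms = sorted(config.chrom_sizes)
    sizes = np.array([config.chrom_sizes[c] for c in chroms], dtype=np.int64)
    weights = sizes / sizes.sum()
    lengths = config.length_array()
    if (sizes.max() < lengths).any():
        raise ValueError("some reads are longer than every chromosome")

    reads: list[MappedRead] = []
    draws = 0
    budget = config.max_draw_factor * config.n_reads
    for i, L in enumerate(lengths):
        L = int(L)
        while True:
            draws += 1
            if draws > budget:
                raise RuntimeError(
                    "rejection sampling exceeded the draw budget; mask too dense"
                )
            ci = int(rng.choice(len(chroms), p=weights))
            limit = int(sizes[ci]) - L
            if limit < 0:
                continue
            start = int(rng.integers(0, limit + 1))
            iv = GenomicInterval(chroms[ci], start, start + L)
            if mask.masked_bp(iv) == 0:
                reads.append(MappedRead(iv, f"null{i + 1}"))
                break
    return reads


@dataclass(frozen=True)
class NullSummary:
    """Caller statistics of one null replicate."""

    frac_reads_in_high_b: float
    top_k_ranks: tuple[float, ...]
    n_joined: int
    n_reads: int

    @property
    def max_rank(self) -> float:
        return max(self.top_k_ranks) if self.top_k_ranks else float("nan")


def null_summary(
    config: NullConfig,
    caller_params: CallerParams = CallerParams(),
    top_k: int = 50,
    high_b: float = 1.5,
    rank_by: str = "R",
    rng: np.random.Generator | None = None,
    reads: Sequence[MappedRead] | None = None,
) -> NullSummary:
    """Run the caller on one random placement and summarize it.

    frac_reads_in_high_b is the fraction of placed reads lying in
    contigs with B strictly above ``high_b``.  ``top_k_ranks`` holds
    the R values of the K top joined contigs; ``rank_by`` selects the
    ordering -- "R" (K largest Rank scores) or "reads" (the K most
    read-rich loci, whose R values are then reported).
    """
    if reads is None:
        reads = place_random_reads(config, rng)
    contigs = build_contigs(reads)
    in_high = sum(c.n_reads for c in contigs if c.b > high_b)
    joined = join_contigs(contigs, reads, config.mask, caller_params)
    if rank_by == "R":
        ordered = sorted((jc.rank for jc in joined), reverse=True)[:top_k]
    elif rank_by == "reads":
        top = sorted(joined, key=lambda jc: (-jc.n_reads, -jc.rank))[:top_k]
        ordered = sorted((jc.rank for jc in top), reverse=True)
    else:
        raise ValueError(f"unknown rank_by: {rank_by!r}")
    return NullSummary(in_high / len(reads), tuple(ordered), len(joined), len(reads))


def run_replicates(
    config: NullConfig,
    caller_params: CallerParams = CallerParams(),
    top_k: int = 50,
    high_b: float = 1.5,
    rank_by: str = "R",
) -> pd.DataFrame:
    """Run ``config.n_replicates`` null replicates with derived seeds.

    Per-replicate RNG streams are spawned deterministically from the
    single config seed.  Returns one row per replicate with the
    high-B read fraction, joined-contig count, and max/top-K ranks.
    """
    children = np.random.SeedSequence(config.seed).spawn(config.n_replicates)
    rows = []
    for rep, child in enumerate(children):
        s = null_summary(
            config,
            caller_params,
            top_k=top_k,
            high_b=high_b,
            rank_by=rank_by,
            rng=np.random.default_rng(child),
        )
        rows.append(
            {
                "replicate": rep,
                "n_reads": s.n_reads,
                "frac_reads_in_high_b": s.frac_reads_in_high_b,
                "n_joined": s.n_joined,
                "max_rank": s.max_rank,
                "top_k_ranks": ",".join(f"{r:.6g}" for r in s.top_k_ranks),
            }
        )
    return pd.DataFrame(rows)


def empirical_threshold(
    top_k_ranks: Sequence[float] | Sequence[Sequence[float]], quantile: float
) -> float:
    """Quantile of the pooled top-K null ranks across replicates.

    Generalizes the fixed R = 0.75 candidate cutoff into a data-driven
    one: call candidates above the chosen quantile of what random
    placement produces.
    """
    if top_k_ranks and isinstance(top_k_ranks[0], (list, tuple, np.ndarray)):
        pooled = [r for reps in top_k_ranks for r in reps]
    else:
        pooled = list(top_k_ranks)  # type: ignore[arg-type]
    if not pooled:
        raise ValueError("no null ranks supplied")
    return float(np.quantile(pooled, quantile))
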