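"""Synthetic-data generator emulating the snap-back/S1 (GAPF) protocol.

The wet protocol denatures genomic DNA, lets palindromes reanneal
intrastrand into hairpins, and digests everything single-stranded with
S1 nuclease.  Sequencing the survivors gives reads whose density over a
palindromic locus decays with distance from the palindrome center:
shearing limits fragments to < ~50 kb and intrastrand reannealing is
more efficient close to the center.  Both palindrome arms are
sequence-identical, so both map to the *same* reference arm interval --
enrichment appears as elevated depth at the original locus, not as a
new locus.

The generator plants palindromes on a random reference genome, emits
arm-derived reads with per-read retention weight ``exp(-d / decay_tau)``
(d = distance of the read midpoint from the center; the exponential is
a modeling choice -- only monotone decay is protocol-backed) plus
uniform background reads modeling incomplete S1 digestion, and records
the planted truth for end-to-end evaluation.  Reads are BED intervals;
the genome sequence is only needed by the junction tools.

Default configuration (the study conditions emulated): a 10-Mb
chromosome, 10% masked in 500-bp islands, 6% coverage of 279 +/- 30 bp
reads, 90% background, one palindrome with a 30-kb arm, 500-bp spacer
and decay_tau = 10 kb.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio.Seq import Seq

from .core import GenomicInterval, MappedRead, MaskTrack, write_bed, write_reads_bed

__all__ = [
    "PalindromeTruth",
    "GapfSimConfig",
    "SimulatedGenome",
    "build_palindrome_sequence",
    "make_genome",
    "simulate_gapf_reads",
]

_DNA = set("ACGTN")


def build_palindrome_sequence(arm_seq: str, spacer_seq: str = "") -> str:
    """arm + spacer + reverse complement of arm.

    With an empty spacer the result is a perfect palindrome: the output
    equals its own reverse complement for *any* arm.  Alphabet ACGTN
    (case-insensitive, uppercased on output).
    """
    arm = arm_seq.upper()
    spacer = spacer_seq.upper()
    if not arm:
        raise ValueError("arm sequence must be non-empty")
    bad = (set(arm) | set(spacer)) - _DNA
    if bad:
        raise ValueError(f"invalid DNA characters: {sorted(bad)}")
    return arm + spacer + str(Seq(arm).reverse_complement())


@dataclass(frozen=True)
class PalindromeTruth:
    """A planted palindrome on the reference.

    center : the arm/spacer boundary coordinate.
    orientation : which side of the center the arm occupies on the
        reference ("left" or "right").  Read density rises *toward*
        the center, i.e. toward the opposite side of the arm.
    insertion : optional foreign sequence at the junction, recorded as
        (donor label, length bp).
    deletion : optional (start, end) interval removed from the spacer
        region, reference coordinates.
    """

    center: int
    arm_len: int
    spacer_len: int = 0
    orientation: str = "left"
    insertion: tuple[str, int] | None = None
    deletion: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.arm_len < 1:
            raise ValueError("arm_len must be >= 1")
        if self.spacer_len < 0:
            raise ValueError("spacer_len must be >= 0")
        if self.orientation not in ("left", "right"):
            raise ValueError("orientation must be 'left' or 'right'")
        if self.deletion is not None:
            d0, d1 = self.deletion
            s0, s1 = self.spacer_span()
            if not (s0 <= d0 < d1 <= s1):
                raise ValueError("deletion must lie within the spacer region")

    def arm_span(self) -> tuple[int, int]:
        if self.orientation == "left":
            return (self.center - self.arm_len, self.center)
        return (self.center, self.center + self.arm_len)

    def spacer_span(self) -> tuple[int, int]:
        if self.orientation == "left":
            return (self.center, self.center + self.spacer_len)
        return (self.center - self.spacer_len, self.center)

    def footprint(self) -> tuple[int, int]:
        a0, a1 = self.arm_span()
        s0, s1 = self.spacer_span()
        return (min(a0, s0), max(a1, s1))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["arm_span"] = list(self.arm_span())
        d["spacer_span"] = list(self.spacer_span())
        return d


@dataclass(frozen=True)
class GapfSimConfig:
    """Generator parameters (units: bp unless noted).

    coverage is the target fraction of the genome covered by read bp;
    background_rate is the fraction of reads that are S1-surviving
    background (uniform over unmasked sequence); decay_tau is the
    length scale of snap-back recovery away from the palindrome center.
    """

    genome_len: int = 10_000_000
    chrom: str = "sim1"
    masked_fraction: float = 0.10
    mask_island: int = 500
    palindromes: tuple[PalindromeTruth, ...] = (
        PalindromeTruth(center=5_000_000, arm_len=30_000, spacer_len=500),
    )
    coverage: float = 0.06
    read_len_mean: float = 279.0
    read_len_sd: float = 30.0
    min_read_len: int = 40
    shear_max: int = 50_000
    decay_tau: float = 10_000.0
    background_rate: float = 0.90
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.coverage < 1):
            raise ValueError("coverage must be in (0, 1)")
        if self.decay_tau <= 0:
            raise ValueError("decay_tau must be > 0")
        if self.shear_max <= self.read_len_mean:
            raise ValueError("shear_max must exceed the mean read length")
        if not (0 <= self.background_rate <= 1):
            raise ValueError("background_rate must be in [0, 1]")

    def n_reads(self) -> int:
        return int(round(self.genome_len * self.coverage / self.read_len_mean))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["palindromes"] = [p.to_dict() for p in self.palindromes]
        return d


@dataclass(frozen=True)
class SimulatedGenome:
    """Reference produced by :func:`make_genome`."""

    config: GapfSimConfig
    mask: MaskTrack
    truths: tuple[PalindromeTruth, ...]
    sequence: str | None = None


def _streams(seed: int) -> tuple[np.random.Generator, np.random.Generator, np.random.Generator]:
    # independent child streams so skipping sequence generation does not
    # perturb mask placement or read sampling
    mask_ss, seq_ss, reads_ss = np.random.SeedSequence(seed).spawn(3)
    return (
        np.random.default_rng(mask_ss),
        np.random.default_rng(seq_ss),
        np.random.default_rng(reads_ss),
    )


def make_genome(
    config: GapfSimConfig,
    outdir: str | Path | None = None,
    with_sequence: bool = True,
) -> SimulatedGenome:
    """Build the reference: mask islands, planted palindromes, sequence.

    Mask islands are placed uniformly, never overlapping each other or
    any palindrome footprint.  Palindromes overlapping each other or
    falling outside the genome raise.  Deterministic per seed; when
    ``outdir`` is given, writes genome.fa, mask.bed and truth.json.
    """
    mask_rng, seq_rng, _ = _streams(config.seed)

    footprints = []
    for p in config.palindromes:
        f0, f1 = p.footprint()
        if f0 < 0 or f1 > config.genome_len:
            raise ValueError("palindrome footprint outside the genome")
        footprints.append((f0, f1))
    footprints.sort()
    for (a0, a1), (b0, b1) in zip(footprints, footprints[1:]):
        if b0 < a1:
            raise ValueError("planted palindromes overlap each other")

    island = config.mask_island
    n_islands = int(round(config.genome_len * config.masked_fraction / island))
    occupied = list(footprints)
    starts: list[int] = []
    attempts = 0
    while len(starts) < n_islands:
        attempts += 1
        if attempts > 100 * max(1, n_islands):
            raise RuntimeError("could not place mask islands without overlap")
        s = int(mask_rng.integers(0, config.genome_len - island))
        if all(s + island <= a or s >= b for a, b in occupied):
            occupied.append((s, s + island))
            starts.append(s)
    mask = MaskTrack(
        GenomicInterval(config.chrom, s, s + island) for s in sorted(starts)
    )

    sequence = None
    if with_sequence:
        sequence = "".join(
            np.array(list("ACGT"))[seq_rng.integers(0, 4, config.genome_len)]
        )

    sim = SimulatedGenome(config, mask, tuple(config.palindromes), sequence)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        if sequence is not None:
            with open(outdir / "genome.fa", "w") as fh:
                fh.write(f">{config.chrom}\n")
                for i in range(0, len(sequence), 80):
                    fh.write(sequence[i : i + 80] + "\n")
        write_bed(outdir / "mask.bed", mask.intervals())
        with open(outdir / "truth.json", "w") as fh:
            json.dump(
                {
                    "palindromes": [p.to_dict() for p in sim.truths],
                    "config": config.to_dict(),
                },
                fh,
                indent=2,
                sort_keys=True,
            )
            fh.write("\n")
    return sim


def _draw_length(config: GapfSimConfig, rng: np.random.Generator) -> int:
    while True:
        L = int(round(rng.normal(config.read_len_mean, config.read_len_sd)))
        if config.min_read_len <= L <= config.shear_max:
            return L


def _place_uniform(
    config: GapfSimConfig, mask: MaskTrack, rng: np.random.Generator
) -> GenomicInterval:
    for _ in range(10_000):
        L = _draw_length(config, rng)
        start = int(rng.integers(0, config.genome_len - L + 1))
        iv = GenomicInterval(config.chrom, start, start + L)
        if mask.masked_bp(iv) == 0:
            return iv
    raise RuntimeError("background placement rejection budget exceeded")


def _place_arm_read(
    config: GapfSimConfig,
    truth: PalindromeTruth,
    mask: MaskTrack,
    rng: np.random.Generator,
) -> GenomicInterval:
    sign = -1 if truth.orientation == "left" else +1
    for _ in range(10_000):
        d = rng.exponential(config.decay_tau)
        if d >= truth.arm_len:
            continue  # truncate the decay at the arm end
        L = _draw_length(config, rng)
        mid = truth.center + sign * d
        start = int(round(mid - L / 2))
        if start < 0 or start + L > config.genome_len:
            continue
        iv = GenomicInterval(config.chrom, start, start + L)
        if mask.masked_bp(iv) == 0:
            return iv
    raise RuntimeError("palindrome read placement rejection budget exceeded")


def simulate_gapf_reads(
    sim: SimulatedGenome, rng: np.random.Generator | None = None
) -> list[MappedRead]:
    """Emit protocol-surviving reads as mapped intervals.

    ``round(background_rate * n)`` reads are uniform background over
    unmasked sequence; the remainder are palindrome-derived, split
    between planted palindromes in proportion to their retained weight
    mass ``tau * (1 - exp(-arm_len / tau))``, with midpoints at
    truncated-exponential distances from each center.  Read lengths are
    Normal(mean, sd) truncated to [min_read_len, shear_max].  Every
    read lies within the chromosome and entirely off the mask.
    Deterministic for the config seed (or an explicit rng).
    """
    config = sim.config
    if rng is None:
        _, _, rng = _streams(config.seed)
    n_total = config.n_reads()
    n_bg = int(round(config.background_rate * n_total))

    reads: list[MappedRead] = []
    for i in range(n_bg):
        reads.append(MappedRead(_place_uniform(config, sim.mask, rng), f"bg{i + 1}"))

    n_pal_total = n_total - n_bg
    if sim.truths and n_pal_total > 0:
        tau = config.decay_tau
        weights = np.array(
            [tau * (1 - np.exp(-t.arm_len / tau)) for t in sim.truths]
        )
        shares = weights / weights.sum()
        counts = np.floor(shares * n_pal_total).astype(int)
        # distribute the rounding remainder deterministically
        for j in range(n_pal_total - counts.sum()):
            counts[j % len(counts)] += 1
        for t_idx, (truth, n_p) in enumerate(zip(sim.truths, counts)):
            for i in range(int(n_p)):
                iv = _place_arm_read(config, truth, sim.mask, rng)
                reads.append(MappedRead(iv, f"pal{t_idx + 1}_{i + 1}"))
    return reads


def simulate_dataset(
    config: GapfSimConfig,
    outdir: str | Path | None = None,
    with_sequence: bool = False,
) -> tuple[SimulatedGenome, list[MappedRead]]:
    """Convenience wrapper: reference plus reads, optionally written out."""
    sim = make_genome(config, outdir=outdir, with_sequence=with_sequence)
    reads = simulate_gapf_reads(sim)
    if outdir is not None:
        write_reads_bed(Path(outdir) / "reads.bed", reads)
    return sim, reads
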