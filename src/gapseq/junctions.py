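"""Junction-side utilities: inversion PCR, snap-back digests, microhomology.

A palindromic locus carries the reference arm twice, in opposite
orientations, around a (possibly empty) spacer.  That geometry has
three practical consequences exploited here:

* a single forward primer in the arm also acts as a reverse primer on
  the mirrored copy, so PCR with primers all designed from one
  reference strand amplifies products that *must* contain the novel
  center junction (inversion PCR);
* on a restriction digest, snap-back hairpin formation halves the
  palindromic fragment (the hairpin runs from the center to the
  arm-side site);
* the junction itself, once sequenced, shows 0-7 bp of microhomology
  between the two joined source sequences, the fingerprint of
  end-joining repair.

All product arithmetic below is validated against an exhaustive
string-level oracle on sequences built by
:func:`gapseq.simulate.build_palindrome_sequence`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .core import GenomicInterval

__all__ = [
    "Primer",
    "PalindromeLocus",
    "PcrProduct",
    "SnapbackFragments",
    "predict_inversion_pcr",
    "predict_snapback_fragments",
    "compute_microhomology",
    "spacer_length",
]

_DNA = set("ACGTN")


@dataclass(frozen=True)
class Primer:
    """A PCR primer on the reference top strand.

    start is the 5' position (0-based); all primers are designed from
    the same strand, the convention of the inversion-PCR strategy.
    """

    name: str
    start: int
    length: int

    def __post_init__(self) -> None:
        if self.length < 10:
            raise ValueError("primer length must be >= 10")

    @property
    def end(self) -> int:
        return self.start + self.length


@dataclass(frozen=True)
class PalindromeLocus:
    """Arm + spacer geometry of a palindrome on the reference.

    The spacer abuts the arm at the center (the arm/spacer boundary).
    orientation says which side of the center the arm occupies.
    """

    chrom: str
    arm: GenomicInterval
    spacer: GenomicInterval | None = None
    orientation: str = "left"

    def __post_init__(self) -> None:
        if self.orientation not in ("left", "right"):
            raise ValueError("orientation must be 'left' or 'right'")
        if self.spacer is not None:
            if self.orientation == "left" and self.spacer.start != self.arm.end:
                raise ValueError("spacer must start at the arm end (left-arm locus)")
            if self.orientation == "right" and self.spacer.end != self.arm.start:
                raise ValueError("spacer must end at the arm start (right-arm locus)")

    @property
    def center(self) -> int:
        return self.arm.end if self.orientation == "left" else self.arm.start

    @property
    def arm_len(self) -> int:
        return self.arm.length

    @property
    def spacer_len(self) -> int:
        return self.spacer.length if self.spacer is not None else 0


@dataclass(frozen=True)
class PcrProduct:
    """One predicted inversion-PCR amplicon (always spans the junction)."""

    forward_primer: str
    reverse_primer: str
    product_len: int
    kind: str  # "single-primer" | "arm-arm" | "spacer-arm"
    contains_junction: bool = True


def _canonical_primer_start(locus: PalindromeLocus, p: Primer) -> int:
    """5' start in the canonical frame (arm left of the spacer).

    A right-arm locus is the mirror image of a left-arm one; reflecting
    coordinates through the center maps its toward-center primers onto
    canonical forward primers and leaves every product length intact.
    """
    if locus.orientation == "left":
        return p.start
    return 2 * locus.center - p.end


def classify_primer(locus: PalindromeLocus, primer: Primer) -> str:
    """'arm', 'spacer', 'straddles_center', 'straddles_spacer_end' or 'outside'."""
    c = locus.center
    p0 = _canonical_primer_start(locus, primer)
    p1 = p0 + primer.length
    arm0 = c - locus.arm_len
    sp1 = c + locus.spacer_len
    if p0 < c < p1:
        return "straddles_center"
    if arm0 <= p0 and p1 <= c:
        return "arm"
    if c <= p0 and p1 <= sp1:
        return "spacer"
    if p0 < sp1 <= p1:
        return "straddles_spacer_end"
    return "outside"


def predict_inversion_pcr(
    locus: PalindromeLocus, primers: Sequence[Primer]
) -> tuple[list[PcrProduct], dict[str, str]]:
    """Predict every junction-spanning amplicon from same-strand primers.

    For an arm primer whose 5' start lies d bp from the center, the
    mirrored arm copy carries its reverse complement at the mirrored
    position, so the primer amplifies alone: product = 2*d + spacer.
    Two arm primers (d1, d2) give d1 + d2 + spacer; a spacer primer at
    offset u from the center-proximal spacer end pairs with an arm
    primer: (spacer - u) + d.  Primers outside arm + spacer yield
    nothing; a primer straddling the center is reported unusable.

    Returns (products, per-primer classification notes).
    """
    notes: dict[str, str] = {}
    arm_primers: list[tuple[Primer, int]] = []  # (primer, d from 5' start to center)
    spacer_primers: list[tuple[Primer, int]] = []  # (primer, u offset into spacer)
    c = locus.center
    for p in primers:
        cls = classify_primer(locus, p)
        if cls == "straddles_center":
            notes[p.name] = "unusable: primer spans the palindrome center"
        elif cls == "straddles_spacer_end":
            notes[p.name] = "unusable: primer extends beyond the spacer"
        elif cls == "outside":
            notes[p.name] = "outside the palindrome: no product"
        else:
            notes[p.name] = cls
            p0 = _canonical_primer_start(locus, p)
            if cls == "arm":
                arm_primers.append((p, c - p0))
            else:
                spacer_primers.append((p, p0 - c))

    S = locus.spacer_len
    products: list[PcrProduct] = []
    for i, (pi, di) in enumerate(arm_primers):
        for pj, dj in arm_primers[i:]:
            kind = "single-primer" if pi is pj else "arm-arm"
            products.append(PcrProduct(pi.name, pj.name, di + dj + S, kind))
    for ps, u in spacer_primers:
        for pa, d in arm_primers:
            products.append(PcrProduct(ps.name, pa.name, (S - u) + d, "spacer-arm"))
    products.sort(key=lambda pr: (pr.product_len, pr.forward_primer, pr.reverse_primer))
    return products, notes


@dataclass(frozen=True)
class SnapbackFragments:
    """Restriction-fragment sizes diagnostic of a palindrome."""

    native: float  # palindromic fragment between mirrored flanking sites
    snapback: float  # hairpin fragment after intrastrand reannealing
    arm_site_distance: int  # center to nearest arm-side site


def predict_snapback_fragments(
    locus: PalindromeLocus, sites: Sequence[int], max_scan: int = 100_000
) -> SnapbackFragments:
    """Fragment sizes of a digested palindromic locus, before/after snap-back.

    ``sites`` are cut positions on the reference.  The rearranged
    molecule mirrors the arm side about the spacer, so the nearest
    arm-side site at distance d from the center flanks the palindromic
    fragment on *both* sides: native = 2*d + spacer.  Folding at the
    center halves it: snap-back = d + spacer/2.  Sites lying only on
    the spacer-distal side do not exist on the rearranged molecule, so
    having no arm-side site within ``max_scan`` raises.
    """
    c = locus.center
    if locus.orientation == "left":
        arm_side = [c - s for s in sites if s < c]
    else:
        arm_side = [s - c for s in sites if s > c]
    arm_side = [d for d in arm_side if d <= max_scan]
    if not arm_side:
        raise ValueError(
            f"no restriction site on the arm side within {max_scan} bp of the center"
        )
    d = min(arm_side)
    S = locus.spacer_len
    return SnapbackFragments(2 * d + S, d + S / 2, d)


def compute_microhomology(left_context: str, right_context: str) -> int:
    """Length of exact microhomology at a rearrangement junction.

    Both arguments are the junction-flanking strings of the two source
    sequences, each ending at its breakpoint as read on the joined
    molecule.  Returns the longest k >= 0 such that the k terminal
    bases are identical (case-insensitive, exact match only; N gets no
    credit).  Alphabet beyond ACGTN raises.
    """
    a = left_context.upper()
    b = right_context.upper()
    bad = (set(a) | set(b)) - _DNA
    if bad:
        raise ValueError(f"invalid DNA characters: {sorted(bad)}")
    k = 0
    while (
        k < len(a)
        and k < len(b)
        and a[-1 - k] == b[-1 - k]
        and a[-1 - k] != "N"
    ):
        k += 1
    return k


def spacer_length(
    spacer: GenomicInterval | tuple[int, int],
    insertion_len: int = 0,
    deletion_len: int = 0,
) -> int:
    """Spacer size from its boundary coordinates, adjusted for indels.

    Boundary subtraction (end - start) plus any inserted foreign
    sequence minus any deleted segment.  Accepts a plain (start, end)
    boundary pair as well, since a spacer may be empty (a perfect
    palindrome) while :class:`GenomicInterval` requires length >= 1.
    Negative results raise.
    """
    if insertion_len < 0 or deletion_len < 0:
        raise ValueError("indel adjustments must be non-negative")
    if isinstance(spacer, GenomicInterval):
        base = spacer.length
    else:
        start, end = spacer
        if end < start:
            raise ValueError("spacer end precedes its start")
        base = end - start
    size = base + insertion_len - deletion_len
    if size < 0:
        raise ValueError("spacer size would be negative after the deletion")
    return size
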