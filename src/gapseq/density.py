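"""Binned read-density profiles, palindrome signature, center/orientation.

DNA shearing (fragments generally < ~50 kb) and the distance dependence
of intrastrand reannealing make palindrome-derived coverage decay with
distance from the palindrome center.  A genuine candidate therefore
shows a *signature*: read density in 1-kb bins over the candidate
(+/- 10 kb flanks) rising monotonically toward one edge (the center).

The original analysis judged this signature by eye; here it is made
quantitative.  ``signature_score`` -- the fraction of adjacent bin
pairs whose counts are non-increasing moving away from the maximum bin
(1.0 = perfect monotone decay on both sides) -- is this module's own
construction, not a published statistic, and is documented as such.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import GenomicInterval, MappedRead, MaskTrack
from .contigs import JoinedContig

__all__ = [
    "DensityProfile",
    "CenterCall",
    "bin_reads",
    "predict_center",
    "signature_sort",
    "plot_profile",
]


@dataclass(frozen=True)
class DensityProfile:
    """Reads-per-bin over a candidate region plus flanks.

    A read is counted in the bin containing its midpoint (half-open
    bins: a midpoint exactly on a boundary belongs to the right bin),
    so no read is ever counted twice.  ``masked_frac`` flags bins
    dominated by repeat-masked sequence, which can be over- or
    under-represented; they are reported, never excluded.
    """

    region: GenomicInterval
    flank: int
    bin_size: int
    counts: np.ndarray
    masked_frac: np.ndarray

    @property
    def window_start(self) -> int:
        return self.region.start - self.flank

    @property
    def n_bins(self) -> int:
        return len(self.counts)

    def bin_start(self, i: int) -> int:
        return self.window_start + i * self.bin_size

    def bin_mid(self, i: int) -> int:
        return self.bin_start(i) + self.bin_size // 2


@dataclass(frozen=True)
class CenterCall:
    """Predicted palindrome center and orientation for one candidate.

    orientation : side of the windowed region toward which density
        rises ("left", "right", or "ambiguous" when the half-window
        sums differ by less than the relative tolerance).  The
        palindrome center sits on the rising side.
    """

    center_estimate: int
    orientation: str
    signature_score: float
    max_bin: int


def bin_reads(
    reads: Sequence[MappedRead],
    region: GenomicInterval,
    flank: int = 10_000,
    bin_size: int = 1_000,
    mask: MaskTrack | None = None,
) -> DensityProfile:
    """Bin read midpoints over ``region`` extended by ``flank`` on each side."""
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    if flank < 0:
        raise ValueError("flank must be >= 0")
    window_start = region.start - flank
    window_len = region.length + 2 * flank
    n_bins = max(1, math.ceil(window_len / bin_size))
    counts = np.zeros(n_bins, dtype=np.int64)
    for r in reads:
        if r.interval.chrom != region.chrom:
            continue
        idx = math.floor((r.interval.midpoint - window_start) / bin_size)
        if 0 <= idx < n_bins:
            counts[idx] += 1
    masked_frac = np.zeros(n_bins, dtype=float)
    if mask is not None:
        for i in range(n_bins):
            b0 = window_start + i * bin_size
            b1 = min(b0 + bin_size, window_start + window_len)
            if b1 > max(b0, 0):
                bin_iv = GenomicInterval(region.chrom, max(b0, 0), b1)
                masked_frac[i] = mask.masked_bp(bin_iv) / bin_iv.length
    return DensityProfile(region, flank, bin_size, counts, masked_frac)


def predict_center(
    profile: DensityProfile, ambiguous_rel_diff: float = 0.2
) -> CenterCall:
    """Locate the palindrome center from the density signature.

    Orientation is the side whose half-window read sum is larger;
    halves within ``ambiguous_rel_diff`` (relative) are called
    "ambiguous".  The center lies where the densest region ends on the
    rising side, so the estimate is the rising-side edge of the run of
    bins statistically compatible with the maximum count (within two
    Poisson standard deviations, i.e. count >= max - 2*sqrt(max));
    under Poisson noise the single argmax bin wanders within that run,
    while its center-facing boundary stays put.  With no orientation
    ("ambiguous") the estimate falls back to the midpoint of the
    maximum-count bin (ties resolved toward the window middle).
    """
    counts = profile.counts
    n = len(counts)
    if n < 3:
        raise ValueError("need at least 3 bins to call a center")
    total = int(counts.sum())
    if total == 0:
        raise ValueError("all-zero density profile")

    half = n // 2
    left_sum = int(counts[:half].sum())
    right_sum = int(counts[n - half:].sum())
    peak = max(left_sum, right_sum)
    if peak == 0 or abs(left_sum - right_sum) / peak < ambiguous_rel_diff:
        orientation = "ambiguous"
    else:
        orientation = "right" if right_sum > left_sum else "left"

    tied = np.flatnonzero(counts == counts.max())
    if orientation == "right":
        max_bin = int(tied[-1])
    elif orientation == "left":
        max_bin = int(tied[0])
    else:  # ambiguous: tied bin closest to the window middle
        max_bin = int(tied[np.argmin(np.abs(tied - (n - 1) / 2))])

    threshold = counts.max() - 2 * math.sqrt(counts.max())
    if orientation == "right":
        edge = max_bin
        while edge + 1 < n and counts[edge + 1] >= threshold:
            edge += 1
        center_estimate = profile.bin_start(edge) + profile.bin_size
    elif orientation == "left":
        edge = max_bin
        while edge > 0 and counts[edge - 1] >= threshold:
            edge -= 1
        center_estimate = profile.bin_start(edge)
    else:
        center_estimate = profile.bin_mid(max_bin)

    up = sum(1 for i in range(1, max_bin + 1) if counts[i - 1] <= counts[i])
    down = sum(1 for i in range(max_bin, n - 1) if counts[i + 1] <= counts[i])
    score = (up + down) / (n - 1)

    return CenterCall(center_estimate, orientation, score, max_bin)


def signature_sort(
    candidates: Sequence[JoinedContig], profiles: Sequence[DensityProfile]
) -> list[tuple[JoinedContig, DensityProfile, CenterCall]]:
    """Order candidates by (signature_score, R) descending.

    Returns (candidate, profile, center call) triples -- a permutation
    of the input, nothing dropped.  Candidates whose profile cannot be
    scored (all-zero) sort last with score -1 and a null call.
    """
    if len(candidates) != len(profiles):
        raise ValueError("one profile per candidate required")
    triples = []
    for jc, prof in zip(candidates, profiles):
        try:
            call = predict_center(prof)
        except ValueError:
            call = None
        triples.append((jc, prof, call))
    triples.sort(
        key=lambda t: (
            -(t[2].signature_score if t[2] else -1.0),
            -t[0].rank,
            t[0].span.chrom,
            t[0].span.start,
        )
    )
    return triples


def plot_profile(profile: DensityProfile, call: CenterCall | None = None, ax=None):
    """Simple per-candidate density figure (requires matplotlib)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    xs = [profile.bin_mid(i) for i in range(profile.n_bins)]
    ax.bar(xs, profile.counts, width=profile.bin_size * 0.9, color="0.3")
    ax.axvspan(profile.region.start, profile.region.end, alpha=0.15, color="tab:blue")
    if call is not None:
        ax.axvline(call.center_estimate, color="tab:red", ls="--",
                   label=f"center ({call.orientation})")
        ax.legend(frameon=False)
    ax.set_xlabel(f"{profile.region.chrom} position (bp)")
    ax.set_ylabel(f"reads / {profile.bin_size} bp")
    return ax
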