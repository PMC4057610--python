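"""Orthogonal validation arithmetic: TaqMan qPCR and CNV-breakpoint proximity.

The snap-back/S1 protocol destroys non-palindromic DNA, so a TaqMan
target's threshold cycle (Ct) rises after treatment in proportion to
how much of it was lost.  With amplification efficiency E per cycle,
a Ct shift of dCt corresponds to a (1+E)^dCt fold depletion; comparing
a candidate target's depletion to a single-copy control's gives its
relative protection (enrichment).  A dCt of ~10 at perfect efficiency
is >1000-fold depletion; a 7-cycle difference between control and
target is >100-fold relative enrichment.

Palindrome formation doubles copy number, so true candidates should sit
near copy-number-variation breakpoints (CNVB): the distance from either
side of a candidate to its nearest breakpoint, with a 5-kb proximity
rule, is the second orthogonal check.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import GenomicInterval, read_bed

__all__ = [
    "CtRecord",
    "CnvBreakpointSet",
    "fold_depletion",
    "relative_enrichment",
    "cnvb_distance",
    "proximity_summary",
]


@dataclass(frozen=True)
class CtRecord:
    """Threshold cycles for one TaqMan target before/after the protocol.

    efficiency is the per-cycle amplification efficiency in (0, 1];
    1.0 (perfect doubling) reproduces the conventional 2^dCt arithmetic.
    """

    target: str
    ct_before: float
    ct_after: float
    efficiency: float = 1.0

    def __post_init__(self) -> None:
        if self.ct_before <= 0 or self.ct_after <= 0:
            raise ValueError("Ct values must be positive")
        if not (0 < self.efficiency <= 1):
            raise ValueError("efficiency must be in (0, 1]")

    @property
    def delta_ct(self) -> float:
        return self.ct_after - self.ct_before


def fold_depletion(rec: CtRecord) -> float:
    """(1 + E) ** dCt; values > 1 mean the target was depleted."""
    return (1 + rec.efficiency) ** rec.delta_ct


def relative_enrichment(target: CtRecord, reference: CtRecord) -> float:
    """How much better the target survived the protocol than the reference.

    fold_depletion(reference) / fold_depletion(target), i.e.
    (1+E) ** (dCt_ref - dCt_target) under a shared efficiency model.
    """
    return fold_depletion(reference) / fold_depletion(target)


class CnvBreakpointSet:
    """Sorted, deduplicated copy-number-segment boundary positions."""

    def __init__(self, positions: Mapping[str, Iterable[int]]) -> None:
        self._pos = {
            chrom: np.unique(np.asarray(list(pts), dtype=np.int64))
            for chrom, pts in positions.items()
        }

    @classmethod
    def from_bed(cls, path: str | Path) -> "CnvBreakpointSet":
        """Each BED record contributes both of its boundary coordinates."""
        by_chrom: dict[str, list[int]] = {}
        for iv in read_bed(path):
            by_chrom.setdefault(iv.chrom, []).extend((iv.start, iv.end))
        return cls(by_chrom)

    @classmethod
    def from_positions_tsv(cls, path: str | Path) -> "CnvBreakpointSet":
        """Two-column TSV: chrom <tab> position (header lines start '#')."""
        by_chrom: dict[str, list[int]] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                chrom, pos = line.split("\t")[:2]
                by_chrom.setdefault(chrom, []).append(int(pos))
        return cls(by_chrom)

    def positions(self, chrom: str) -> np.ndarray:
        return self._pos.get(chrom, np.empty(0, dtype=np.int64))

    @property
    def chroms(self) -> list[str]:
        return sorted(self._pos)


def cnvb_distance(candidate: GenomicInterval, cnvbs: CnvBreakpointSet) -> int | None:
    """Distance (bp) from either side of a candidate to its nearest breakpoint.

    0 when a breakpoint lies inside the candidate; None when the
    candidate's chromosome has no breakpoints at all.
    """
    pts = cnvbs.positions(candidate.chrom)
    if len(pts) == 0:
        return None
    if ((pts >= candidate.start) & (pts <= candidate.end)).any():
        return 0
    best = min(
        int(np.abs(pts - candidate.start).min()),
        int(np.abs(pts - candidate.end).min()),
    )
    return best


def proximity_summary(
    candidates: Sequence[GenomicInterval],
    cnvbs: CnvBreakpointSet,
    threshold: int = 5_000,
) -> tuple[int, pd.DataFrame]:
    """Per-candidate nearest-CNVB table plus the count within ``threshold``.

    Distances are strict-less-than the threshold ("less than 5 kb");
    candidates on breakpoint-free chromosomes get a null distance and
    never count as proximal.
    """
    rows = []
    n_close = 0
    for iv in candidates:
        d = cnvb_distance(iv, cnvbs)
        close = d is not None and d < threshold
        n_close += int(close)
        chrom, start1, end1 = iv.to_report_coords()
        rows.append(
            {
                "chrom": chrom,
                "start": start1,
                "end": end1,
                "nearest_cnvb_distance": d,
                "within_threshold": close,
            }
        )
    return n_close, pd.DataFrame(rows)
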