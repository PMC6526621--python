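"""Per-position dark classification and region assembly.

A genomic position is *dark by depth* when its (multi-sample averaged)
aligned-read depth is at most ``dark_depth_max`` (default 5), and *dark
by mapping quality* when at least ``dark_mass_min_pct`` percent (default
90%) of its aligned reads have MAPQ <= ``mapq_low_max`` (default 9,
i.e. MAPQ < 10).  Depth is checked first, so the two classes are
mutually exclusive.  Evidence is averaged across samples before the
thresholds are applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

from .formats import AlignedRead

__all__ = [
    "DarkScanConfig",
    "PositionSummary",
    "DarkRegion",
    "summarize_pileup",
    "average_samples",
    "classify_position",
    "classify_summaries",
    "build_dark_regions",
    "scan_sample_arrays",
]

NONE, DARK_BY_DEPTH, DARK_BY_MAPQ = "none", "dark_by_depth", "dark_by_mapq"


@dataclass(frozen=True)
class DarkScanConfig:
    dark_depth_max: int = 5
    mapq_low_max: int = 9
    dark_mass_min_pct: float = 90.0
    camo_mass_min_pct: float = 50.0
    min_region_size: int = 20

    def __post_init__(self) -> None:
        if not 0 <= self.mapq_low_max <= 60:
            raise ValueError("mapq_low_max must be in [0, 60]")
        if not 0 < self.dark_mass_min_pct <= 100:
            raise ValueError("dark_mass_min_pct must be in (0, 100]")
        if self.min_region_size < 1:
            raise ValueError("min_region_size must be >= 1")


@dataclass
class PositionSummary:
    """Depth and low-MAPQ evidence at one position, averaged over samples."""

    contig: str
    pos: int
    depth: float
    low_mapq_count: float

    @property
    def low_mapq_frac(self) -> float:
        return self.low_mapq_count / self.depth if self.depth > 0 else 0.0


@dataclass
class DarkRegion:
    contig: str
    start: int
    end: int
    klass: str
    mean_depth: float
    mean_low_mapq_pct: float

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


def scan_sample_arrays(
    reads: Iterable[AlignedRead],
    contig: str,
    interval: tuple[int, int],
    config: DarkScanConfig = DarkScanConfig(),
) -> tuple[np.ndarray, np.ndarray]:
    """Accumulate (depth, low_mapq_count) arrays over ``interval``.

    A read contributes depth only at positions where it has an aligned
    base: CIGAR deletions/skips over a position do not count toward its
    depth, nor do soft-clipped bases.
    """
    start, end = interval
    n = end - start
    depth = np.zeros(n, dtype=np.float64)
    low = np.zeros(n, dtype=np.float64)
    last_start = -1
    for read in reads:
        if read.contig != contig:
            continue
        if read.start < last_start:
            raise ValueError("reads must be coordinate-sorted")
        last_start = read.start
        if read.start >= end:
            break
        is_low = read.mapq <= config.mapq_low_max
        for bstart, bend, _ in read.reference_blocks():
            lo = max(bstart, start) - start
            hi = min(bend, end) - start
            if lo < hi:
                depth[lo:hi] += 1
                if is_low:
                    low[lo:hi] += 1
    return depth, low


def summarize_pileup(
    reads: Iterable[AlignedRead],
    contig: str,
    interval: tuple[int, int],
    config: DarkScanConfig = DarkScanConfig(),
) -> list[PositionSummary]:
    """Per-position depth / low-MAPQ summary for one sample."""
    depth, low = scan_sample_arrays(reads, contig, interval, config)
    start = interval[0]
    return [
        PositionSummary(contig, start + i, float(depth[i]), float(low[i]))
        for i in range(len(depth))
    ]


def average_samples(
    per_sample: Sequence[Sequence[PositionSummary]],
) -> list[PositionSummary]:
    """Arithmetic mean of depth and low-MAPQ count across samples.

    The low-MAPQ fraction is recomputed from the averaged values
    (mean-then-ratio), matching how multi-sample evidence is pooled
    before thresholding.
    """
    if not per_sample:
        raise ValueError("no samples given")
    first = per_sample[0]
    grid = [(s.contig, s.pos) for s in first]
    for other in per_sample[1:]:
        if [(s.contig, s.pos) for s in other] != grid:
            raise ValueError("samples cover mismatched position grids")
    n = len(per_sample)
    out = []
    for i, (contig, pos) in enumerate(grid):
        depth = sum(sample[i].depth for sample in per_sample) / n
        low = sum(sample[i].low_mapq_count for sample in per_sample) / n
        out.append(PositionSummary(contig, pos, depth, low))
    return out


def classify_position(s: PositionSummary, config: DarkScanConfig = DarkScanConfig()) -> str:
    """Classify one position; depth takes precedence over MAPQ mass."""
    if s.depth <= config.dark_depth_max:
        return DARK_BY_DEPTH
    if s.low_mapq_frac * 100.0 >= config.dark_mass_min_pct:
        return DARK_BY_MAPQ
    return NONE


def classify_summaries(
    summaries: Iterable[PositionSummary], config: DarkScanConfig = DarkScanConfig()
) -> Iterator[tuple[PositionSummary, str]]:
    for s in summaries:
        yield s, classify_position(s, config)


def build_dark_regions(
    classified: Iterable[tuple[PositionSummary, str]],
    config: DarkScanConfig = DarkScanConfig(),
) -> list[DarkRegion]:
    """Merge maximal runs of identically classified positions.

    Runs shorter than ``config.min_region_size`` are dropped (the
    analysis default keeps regions of >= 20 contiguous bases).  Runs
    break at contig changes and position jumps.
    """
    regions: list[DarkRegion] = []
    cur: list[PositionSummary] = []
    cur_klass = NONE

    def flush() -> None:
        nonlocal cur
        if cur_klass != NONE and len(cur) >= config.min_region_size:
            depths = [s.depth for s in cur]
            fracs = [s.low_mapq_frac for s in cur]
            regions.append(
                DarkRegion(
                    contig=cur[0].contig,
                    start=cur[0].pos,
                    end=cur[-1].pos + 1,
                    klass=cur_klass,
                    mean_depth=float(np.mean(depths)),
                    mean_low_mapq_pct=100.0 * float(np.mean(fracs)),
                )
            )
        cur = []

    for s, klass in classified:
        contiguous = (
            cur
            and s.contig == cur[-1].contig
            and s.pos == cur[-1].pos + 1
            and klass == cur_klass
        )
        if not contiguous:
            flush()
            cur_klass = klass
        cur.append(s)
    flush()
    return regions
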