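"""Windowed read-depth tracks and mean-depth queries.

Depth files are BED-like (chrom, start, end, mean_depth) with the usual BED
0-based half-open convention; internally everything is 1-based inclusive to
match the VCF records it screens. Positions not covered by any interval
have depth 0.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Tuple, Union

import numpy as np
import pandas as pd


@dataclass
class CoverageTrack:
    """Per-chromosome sorted depth intervals (1-based inclusive)."""

    sample_id: str
    intervals: Dict[str, List[Tuple[int, int, float]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, ivs in self.intervals.items():
            ivs.sort()
            prev_end = 0
            for start, end, depth in ivs:
                if start < 1 or end < start:
                    raise ValueError(f"bad interval {chrom}:{start}-{end}")
                if depth < 0:
                    raise ValueError(f"negative depth at {chrom}:{start}-{end}")
                if start <= prev_end:
                    raise ValueError(
                        f"overlapping coverage intervals on {chrom} at {start}"
                    )
                prev_end = end

    def mean_depth(self, chrom: str, start: int, end: int) -> float:
        """Mean per-base depth over [start, end], gaps counting as 0."""
        if end < start:
            raise ValueError("end < start")
        ivs = self.intervals.get(chrom)
        length = end - start + 1
        if not ivs:
            return 0.0
        total = 0.0
        # first interval that could overlap: rightmost with iv_start <= end
        idx = bisect.bisect_right(ivs, (start, float("inf"), float("inf"))) - 1
        idx = max(idx, 0)
        for iv_start, iv_end, depth in ivs[idx:]:
            if iv_start > end:
                break
            lo = max(start, iv_start)
            hi = min(end, iv_end)
            if hi >= lo:
                total += depth * (hi - lo + 1)
        return total / length


def read_coverage(path: Union[str, Path], sample_id: str) -> CoverageTrack:
    """Read a 4-column BED depth file (0-based half-open) into a track."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=["chrom", "start", "end", "depth"],
        dtype={"chrom": str},
    )
    intervals: Dict[str, List[Tuple[int, int, float]]] = {}
    for chrom, start, end, depth in df.itertuples(index=False):
        # BED 0-based half-open -> 1-based inclusive
        intervals.setdefault(chrom, []).append((int(start) + 1, int(end), float(depth)))
    return CoverageTrack(sample_id, intervals)


def write_coverage_bed(track: CoverageTrack, path: Union[str, Path]) -> None:
    rows = []
    for chrom in sorted(track.intervals):
        for start, end, depth in track.intervals[chrom]:
            rows.append((chrom, start - 1, end, depth))
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def constant_track(
    sample_id: str,
    genome: Dict[str, int],
    depth: float,
    holes: Dict[str, List[Tuple[int, int]]] = None,
) -> CoverageTrack:
    """Uniform-depth track over a genome, with optional zero-depth holes
    given as 1-based inclusive intervals per chromosome."""
    intervals: Dict[str, List[Tuple[int, int, float]]] = {}
    holes = holes or {}
    for chrom, length in genome.items():
        cuts = sorted(holes.get(chrom, []))
        pos = 1
        ivs: List[Tuple[int, int, float]] = []
        for h_start, h_end in cuts:
            if h_start > pos:
                ivs.append((pos, h_start - 1, depth))
            pos = max(pos, h_end + 1)
        if pos <= length:
            ivs.append((pos, length, depth))
        intervals[chrom] = ivs
    return CoverageTrack(sample_id, intervals)
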