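"""Sliding-window read counting, depth normalization and peak calling.

The scoring recipe: count reads in fixed-width overlapping windows
(default 100 bp, 50 bp step), scale the IP counts by the ratio of mapped
control to mapped IP reads, substitute 1 for zero counts so ratios are
always defined, and score each window as scaled-IP over control.
Windows at or above a score threshold seed peaks; overlapping or
abutting seeds merge, and the merged area is re-scored from the reads it
contains (each read counted once per area).

The scale factor is held unrounded internally; its two-decimal form is
for display only (21,612,138 / 13,369,042 = 1.6166... displays as 1.62).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np

from yy2scan.io_genomics import AlignedRead, GenomicInterval

ClassFilter = Literal["all", "unique_only", "repeated_only"]


def _round2(x: float) -> float:
    """Round-half-up to 2 decimals, matching printed-table conventions."""
    return math.floor(x * 100 + 0.5) / 100


@dataclass(frozen=True)
class MappingStats:
    """Read-mapping summary; percentages are relative to the initial count."""

    n_initial: int
    n_mapped: int
    n_unique: int
    n_repeated: int

    def __post_init__(self):
        if self.n_initial <= 0:
            raise ValueError("n_initial must be positive (percentages undefined otherwise)")
        if self.n_unique + self.n_repeated != self.n_mapped:
            raise ValueError("n_unique + n_repeated must equal n_mapped")
        if self.n_mapped > self.n_initial:
            raise ValueError("n_mapped cannot exceed n_initial")

    @property
    def pct_mapped(self) -> float:
        return _round2(100.0 * self.n_mapped / self.n_initial)

    @property
    def pct_unique(self) -> float:
        return _round2(100.0 * self.n_unique / self.n_initial)

    @property
    def pct_repeated(self) -> float:
        return _round2(100.0 * self.n_repeated / self.n_initial)


def mapping_stats(reads: Iterable[AlignedRead], n_initial: int) -> MappingStats:
    """Summarize a read collection against the initial (pre-mapping) count."""
    n_unique = n_repeated = 0
    for r in reads:
        if r.mapping_class == "unique":
            n_unique += 1
        else:
            n_repeated += 1
    n_mapped = n_unique + n_repeated
    if n_initial < n_mapped:
        raise ValueError("n_initial must be >= number of mapped reads")
    return MappingStats(n_initial, n_mapped, n_unique, n_repeated)


@dataclass(frozen=True)
class ScaleFactor:
    """Depth-normalization ratio control/IP; numerator and denominator retained."""

    n_mapped_control: int
    n_mapped_ip: int

    def __post_init__(self):
        if self.n_mapped_control <= 0 or self.n_mapped_ip <= 0:
            raise ValueError("mapped counts must be positive")

    @property
    def value(self) -> float:
        return self.n_mapped_control / self.n_mapped_ip

    @property
    def exact(self):
        """The ratio as an exact fraction (the float `value` is a convenience)."""
        from fractions import Fraction

        return Fraction(self.n_mapped_control, self.n_mapped_ip)

    @property
    def display(self) -> str:
        return f"{_round2(self.value):.2f}"


def compute_scale_factor(n_mapped_control: int, n_mapped_ip: int) -> ScaleFactor:
    return ScaleFactor(n_mapped_control, n_mapped_ip)


class WindowGrid:
    """Overlapping fixed-width windows per chromosome.

    Window starts are 0, step, 2*step, ...; each window is
    ``[s, min(s + width, L))``.  Generation stops once ``s + width > L``,
    except that a chromosome shorter than ``width`` still yields the
    single truncated window ``[0, L)``.
    """

    def __init__(self, chrom_lengths: Mapping[str, int], width: int = 100, step: int = 50):
        if width <= 0 or step <= 0:
            raise ValueError("width and step must be positive")
        if step > width:
            raise ValueError("step must not exceed width")
        self.width = width
        self.step = step
        self.chrom_lengths = dict(chrom_lengths)
        self._n_windows: dict[str, int] = {}
        for chrom, length in self.chrom_lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {chrom} has non-positive length")
            if length < width:
                self._n_windows[chrom] = 1
            else:
                # last valid start s satisfies s + width <= L
                self._n_windows[chrom] = (length - width) // step + 1

    def n_windows(self, chrom: str) -> int:
        return self._n_windows[chrom]

    def windows(self, chrom: str) -> list[GenomicInterval]:
        length = self.chrom_lengths[chrom]
        return [
            GenomicInterval(chrom, s, min(s + self.width, length))
            for s in (i * self.step for i in range(self._n_windows[chrom]))
        ]

    def window_interval(self, chrom: str, index: int) -> GenomicInterval:
        s = index * self.step
        return GenomicInterval(chrom, s, min(s + self.width, self.chrom_lengths[chrom]))

    def chromosomes(self) -> list[str]:
        return list(self.chrom_lengths)


def make_windows(chrom_lengths: Mapping[str, int], width: int = 100, step: int = 50) -> WindowGrid:
    return WindowGrid(chrom_lengths, width=width, step=step)


@dataclass
class WindowCounts:
    """Per-window read counts on a grid, plus a tally of off-grid reads."""

    grid: WindowGrid
    counts: dict[str, np.ndarray]
    n_skipped: int = 0

    def total(self) -> int:
        return int(sum(c.sum() for c in self.counts.values()))


def _class_mask(read: AlignedRead, class_filter: ClassFilter) -> bool:
    if class_filter == "all":
        return True
    if class_filter == "unique_only":
        return read.mapping_class == "unique"
    if class_filter == "repeated_only":
        return read.mapping_class == "repeated"
    raise ValueError(f"unknown class_filter {class_filter!r}")


def count_reads(
    grid: WindowGrid, reads: Iterable[AlignedRead], class_filter: ClassFilter = "all"
) -> WindowCounts:
    """Count reads per window; a read increments every window it overlaps by >= 1 bp.

    Reads on chromosomes absent from the grid are skipped and tallied.
    """
    counts = {chrom: np.zeros(grid.n_windows(chrom), dtype=np.int64) for chrom in grid.chromosomes()}
    step, width = grid.step, grid.width
    n_skipped = 0
    for r in reads:
        if not _class_mask(r, class_filter):
            continue
        iv = r.interval
        arr = counts.get(iv.chrom)
        if arr is None:
            n_skipped += 1
            continue
        # window [s, s+width) overlaps [a, b) iff a - width < s < b
        lo = max(0, -(-(iv.start - width + 1) // step))  # ceil((a - width + 1)/step)
        hi = min(len(arr) - 1, (iv.end - 1) // step)
        if lo <= hi:
            arr[lo : hi + 1] += 1
    return WindowCounts(grid, counts, n_skipped)


def window_scores(
    ip_counts: WindowCounts, control_counts: WindowCounts, scale: ScaleFactor
) -> dict[str, np.ndarray]:
    """Per-window enrichment score: scaled IP (zero -> 1) over control (zero -> 1)."""
    if ip_counts.grid is not control_counts.grid and (
        ip_counts.grid.chrom_lengths != control_counts.grid.chrom_lengths
        or ip_counts.grid.width != control_counts.grid.width
        or ip_counts.grid.step != control_counts.grid.step
    ):
        raise ValueError("IP and control counts are on different grids")
    scores: dict[str, np.ndarray] = {}
    for chrom, ip in ip_counts.counts.items():
        ctrl = control_counts.counts[chrom]
        if len(ip) != len(ctrl):
            raise ValueError(f"window count length mismatch on {chrom}")
        num = np.where(ip > 0, ip * scale.value, 1.0)
        den = np.where(ctrl > 0, ctrl, 1).astype(float)
        scores[chrom] = num / den
    return scores


@dataclass
class Peak:
    """A merged enriched region with its area score and read counts."""

    interval: GenomicInterval
    score: float
    reads_ip: int
    reads_control: int
    rank: int = 0
    code: str | None = None
    annotation: object = None

    def __eq__(self, other):
        if not isinstance(other, Peak):
            return NotImplemented
        return (
            self.interval == other.interval
            and self.score == other.score
            and self.reads_ip == other.reads_ip
            and self.reads_control == other.reads_control
            and self.rank == other.rank
            and self.code == other.code
        )


def _merge_seed_windows(seeds: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping-or-abutting intervals (assumed same chrom, sorted)."""
    merged: list[list[int]] = []
    for iv in seeds:
        if merged and iv.start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], iv.end)
        else:
            merged.append([iv.start, iv.end])
    return [GenomicInterval(seeds[0].chrom, s, e) for s, e in merged]


def _reads_in_area(reads: Iterable[AlignedRead], area: GenomicInterval, class_filter: ClassFilter) -> int:
    n = 0
    for r in reads:
        if _class_mask(r, class_filter) and r.interval.overlaps(area):
            n += 1
    return n


def call_peaks(
    grid: WindowGrid,
    ip_reads: Sequence[AlignedRead],
    control_reads: Sequence[AlignedRead],
    scale: ScaleFactor,
    threshold: float = 2.0,
    class_filter: ClassFilter = "all",
) -> list[Peak]:
    """Call peaks: threshold window scores, merge seed windows, re-score areas.

    The merged-area score counts each read once per area even when the
    read overlapped several seed windows.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    ip_counts = count_reads(grid, ip_reads, class_filter)
    ctrl_counts = count_reads(grid, control_reads, class_filter)
    scores = window_scores(ip_counts, ctrl_counts, scale)

    # reads bucketed per chromosome so area re-counting stays linear
    ip_by_chrom: dict[str, list[AlignedRead]] = {}
    for r in ip_reads:
        ip_by_chrom.setdefault(r.interval.chrom, []).append(r)
    ctrl_by_chrom: dict[str, list[AlignedRead]] = {}
    for r in control_reads:
        ctrl_by_chrom.setdefault(r.interval.chrom, []).append(r)

    peaks: list[Peak] = []
    for chrom in grid.chromosomes():
        seed_idx = np.nonzero(scores[chrom] >= threshold)[0]
        if len(seed_idx) == 0:
            continue
        seeds = [grid.window_interval(chrom, int(i)) for i in seed_idx]
        for area in _merge_seed_windows(seeds):
            n_ip = _reads_in_area(ip_by_chrom.get(chrom, ()), area, class_filter)
            n_ctrl = _reads_in_area(ctrl_by_chrom.get(chrom, ()), area, class_filter)
            num = n_ip * scale.value if n_ip > 0 else 1.0
            den = n_ctrl if n_ctrl > 0 else 1
            peaks.append(Peak(area, num / den, n_ip, n_ctrl))
    return peaks


def rank_peaks(peaks: Iterable[Peak]) -> list[Peak]:
    """Sort by descending score (ties: chrom lexicographic, then start) and assign ranks 1..N."""
    ordered = sorted(peaks, key=lambda p: (-p.score, p.interval.chrom, p.interval.start))
    for i, p in enumerate(ordered, start=1):
        p.rank = i
    return ordered


def write_bedgraph(scores: Mapping[str, np.ndarray], grid: WindowGrid, path) -> None:
    """Write per-window scores as bedGraph (windows overlap; one line per window)."""
    with open(path, "w") as fh:
        fh.write('track type=bedGraph name="window_scores"\n')
        for chrom in grid.chromosomes():
            for i, s in enumerate(scores[chrom]):
                iv = grid.window_interval(chrom, i)
                fh.write(f"{chrom}\t{iv.start}\t{iv.end}\t{s:.6g}\n")
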