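"""Coverage-corrected windowed heterozygosity, ROH calling and F_ROH.

Heterozygosity per window is the heterozygous bi-allelic SNP count divided
by the number of *callable* bases (depth strictly between the low and high
multiples of mean coverage); windows with too few callable bases are
excluded.  ROH are called on small windows with a relaxed-peak rule: runs of
low-het seed windows are greedily merged across intervening heterozygosity
peaks whenever the callable-weighted mean of the merged span stays below the
ceiling (a fixed fraction of the genome-wide mean heterozygosity), taking
the lowest-mean merge first.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .io_formats import DepthTrack, GenomeLayout, Interval, Region, iter_windows


# ---------------------------------------------------------------------------
# Callable mask
# ---------------------------------------------------------------------------

@dataclass
class CallableMask:
    """Per-window count of bases whose depth lies strictly inside the
    coverage band ``(low_factor * mean, high_factor * mean)``."""

    window_size: int
    windows: list[Region]
    callable_bp: np.ndarray
    partial: list[bool]


def callable_mask(
    tracks: Sequence[DepthTrack],
    mean_coverage: float,
    window: int,
    layout: GenomeLayout,
    low_factor: float = 1.0 / 3.0,
    high_factor: float = 2.5,
    keep_partial: bool = True,
) -> CallableMask:
    if window <= 0:
        raise ValueError("window size must be positive")
    if mean_coverage <= 0:
        raise ValueError("mean_coverage must be positive")
    lo = low_factor * mean_coverage
    hi = high_factor * mean_coverage
    track_by_chrom = {t.region.chrom: t for t in tracks}
    regions: list[Region] = []
    counts: list[float] = []
    partial: list[bool] = []
    for w, is_partial in iter_windows(layout, window, keep_partial=keep_partial):
        regions.append(w)
        partial.append(is_partial)
        t = track_by_chrom.get(w.chrom)
        if t is None:
            counts.append(0)
            continue
        # overlap of window with the track span, in track-array coordinates
        lo_pos = max(w.start, t.region.start)
        hi_pos = min(w.end, t.region.end)
        if lo_pos > hi_pos:
            counts.append(0)
            continue
        seg = t.depth[lo_pos - t.region.start : hi_pos - t.region.start + 1]
        counts.append(int(np.count_nonzero((seg > lo) & (seg < hi))))
    return CallableMask(
        window_size=window,
        windows=regions,
        callable_bp=np.asarray(counts, dtype=np.int64),
        partial=partial,
    )


# ---------------------------------------------------------------------------
# Windowed heterozygosity
# ---------------------------------------------------------------------------

@dataclass
class HetWindow:
    chrom: str
    start: int
    end: int
    n_het: float
    callable_bp: float
    excluded: bool

    @property
    def het(self) -> float:
        """Corrected heterozygosity: het sites per callable base."""
        if self.callable_bp <= 0:
            return math.nan
        return self.n_het / self.callable_bp

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def window_heterozygosity(
    het_sites: Iterable[tuple[str, int]],
    mask: CallableMask,
    min_callable_fraction: float = 0.60,
) -> list[HetWindow]:
    """Assign het sites to the mask's windows and apply the exclusion rule.

    A window is excluded when its callable fraction (relative to its actual
    span) falls below ``min_callable_fraction`` or it has no callable base.
    Sites on chromosomes absent from the mask are an error; sites past the
    last window (possible when partial windows were dropped) are ignored.
    """
    first_idx: dict[str, int] = {}
    n_windows: dict[str, int] = {}
    for i, w in enumerate(mask.windows):
        if w.chrom not in first_idx:
            first_idx[w.chrom] = i
        n_windows[w.chrom] = n_windows.get(w.chrom, 0) + 1
    n_het = np.zeros(len(mask.windows), dtype=np.int64)
    for chrom, pos in het_sites:
        if chrom not in first_idx:
            raise KeyError(f"het site on chromosome {chrom!r} absent from mask")
        wi = (pos - 1) // mask.window_size
        if wi >= n_windows[chrom]:
            continue
        n_het[first_idx[chrom] + wi] += 1
    out: list[HetWindow] = []
    for i, w in enumerate(mask.windows):
        c = float(mask.callable_bp[i])
        excluded = c <= 0 or (c / w.length) < min_callable_fraction
        out.append(
            HetWindow(
                chrom=w.chrom,
                start=w.start,
                end=w.end,
                n_het=float(n_het[i]),
                callable_bp=c,
                excluded=excluded,
            )
        )
    return out


def genome_mean_het(windows: Sequence[HetWindow]) -> float:
    """Total het sites / total callable bases over non-excluded windows."""
    tot_het = sum(w.n_het for w in windows if not w.excluded)
    tot_call = sum(w.callable_bp for w in windows if not w.excluded)
    if tot_call <= 0:
        return math.nan
    return tot_het / tot_call


# ---------------------------------------------------------------------------
# ROH calling
# ---------------------------------------------------------------------------

@dataclass
class RohSegment:
    chrom: str
    start: int
    end: int
    mean_het: float
    n_windows: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _runs_of_usable_windows(windows: Sequence[HetWindow]) -> list[list[int]]:
    """Maximal runs of coordinate-adjacent, non-excluded windows.

    Excluded windows and chromosome boundaries terminate runs.
    """
    runs: list[list[int]] = []
    current: list[int] = []
    prev: HetWindow | None = None
    for i, w in enumerate(windows):
        contiguous = (
            prev is not None
            and not prev.excluded
            and w.chrom == prev.chrom
            and w.start == prev.end + 1
        )
        if w.excluded:
            if current:
                runs.append(current)
                current = []
        elif contiguous and current:
            current.append(i)
        else:
            if current:
                runs.append(current)
            current = [i]
        prev = w
    if current:
        runs.append(current)
    return runs


def call_roh(
    windows: Sequence[HetWindow],
    mean_het: float,
    ceiling_factor: float = 0.25,
) -> list[RohSegment]:
    """Relaxed-peak ROH calling on small tumbling windows.

    Per run of contiguous usable windows: (1) windows with het at or below
    ``ceiling_factor * mean_het`` seed candidates; (2) candidates are the
    maximal seed runs; (3) adjacent candidates are merged across intervening
    peak windows when the callable-weighted mean het of the merged span
    stays strictly below the ceiling, lowest merged mean first, until no
    merge qualifies; (4) each candidate becomes a segment spanning its
    windows.
    """
    if not windows:
        return []
    if not (mean_het > 0):
        if all(w.n_het == 0 for w in windows if not w.excluded):
            return [
                _make_segment(windows, run, run[0], run[-1])
                for run in _runs_of_usable_windows(windows)
            ]
        raise ValueError("genome mean heterozygosity must be positive")
    ceiling = ceiling_factor * mean_het
    segments: list[RohSegment] = []
    for run in _runs_of_usable_windows(windows):
        het = np.array([windows[i].het for i in run])
        weight = np.array([windows[i].callable_bp for i in run])
        mass = het * weight  # equals n_het when het = n_het / callable
        cum_mass = np.concatenate([[0.0], np.cumsum(mass)])
        cum_w = np.concatenate([[0.0], np.cumsum(weight)])

        def span_mean(a: int, b: int) -> float:
            wsum = cum_w[b + 1] - cum_w[a]
            if wsum <= 0:
                return math.inf
            return (cum_mass[b + 1] - cum_mass[a]) / wsum

        # seed runs (local indices within this run)
        seeds = het <= ceiling
        cands: list[tuple[int, int]] = []
        j = 0
        while j < len(run):
            if seeds[j]:
                k = j
                while k + 1 < len(run) and seeds[k + 1]:
                    k += 1
                cands.append((j, k))
                j = k + 1
            else:
                j += 1
        # best-first merging of adjacent candidates across peaks
        while len(cands) > 1:
            best_i = -1
            best_mean = math.inf
            for k in range(len(cands) - 1):
                m = span_mean(cands[k][0], cands[k + 1][1])
                if m < ceiling and m < best_mean:
                    best_mean = m
                    best_i = k
            if best_i < 0:
                break
            a = (cands[best_i][0], cands[best_i + 1][1])
            cands[best_i : best_i + 2] = [a]
        for a, b in cands:
            segments.append(_make_segment(windows, run, run[a], run[b]))
    segments.sort(key=lambda s: (s.chrom, s.start))
    return segments


def _make_segment(
    windows: Sequence[HetWindow], run: Sequence[int], i0: int, i1: int
) -> RohSegment:
    span = [windows[i] for i in range(i0, i1 + 1)]
    wsum = sum(w.callable_bp for w in span)
    mass = sum(w.het * w.callable_bp for w in span if w.callable_bp > 0)
    return RohSegment(
        chrom=span[0].chrom,
        start=span[0].start,
        end=span[-1].end,
        mean_het=mass / wsum if wsum > 0 else 0.0,
        n_windows=len(span),
    )


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

@dataclass
class RohSummary:
    total_roh_bp: int
    n_segments: int
    n_long: int
    froh: float

    def to_dict(self) -> dict:
        return {
            "total_roh_bp": self.total_roh_bp,
            "n_segments": self.n_segments,
            "n_long": self.n_long,
            "froh": self.froh,
        }


def summarize_roh(
    segments: Sequence[RohSegment],
    autosome_length_L: int,
    min_roh_length: int = 100_000,
    long_roh_length: int = 2_000_000,
) -> RohSummary:
    """Genomic inbreeding from ROH: the summed length of segments at least
    ``min_roh_length`` long divided by the autosomal genome length; the long
    count uses a strict ``> long_roh_length``."""
    if autosome_length_L <= 0:
        raise ValueError("autosome_length_L must be positive")
    total = sum(s.length for s in segments)
    qualifying = sum(s.length for s in segments if s.length >= min_roh_length)
    n_long = sum(1 for s in segments if s.length > long_roh_length)
    return RohSummary(
        total_roh_bp=total,
        n_segments=len(segments),
        n_long=n_long,
        froh=qualifying / autosome_length_L,
    )


def roh_length_histogram(
    segments: Sequence[RohSegment], edges: Sequence[float]
) -> list[tuple[float, float, int]]:
    lengths = np.array([s.length for s in segments], dtype=float)
    counts, _ = np.histogram(lengths, bins=np.asarray(edges, dtype=float))
    return [
        (float(edges[i]), float(edges[i + 1]), int(counts[i]))
        for i in range(len(counts))
    ]


def interval_jaccard(a: Sequence[Interval], b: Sequence[Interval]) -> float:
    """Base-level Jaccard index between two sets of 1-based inclusive
    intervals (each set assumed non-overlapping within itself)."""

    def to_events(ivs: Sequence[Interval], which: int):
        for chrom, s, e in ivs:
            yield (chrom, s, 1 << which)
            yield (chrom, e + 1, -(1 << which))

    events = sorted(
        list(to_events(a, 0)) + list(to_events(b, 1)),
        key=lambda t: (t[0], t[1]),
    )
    inter = 0
    union = 0
    state_a = 0
    state_b = 0
    prev: tuple[str, int] | None = None
    for chrom, pos, delta in events:
        if prev is not None and prev[0] == chrom and pos > prev[1]:
            span = pos - prev[1]
            if state_a > 0 and state_b > 0:
                inter += span
            if state_a > 0 or state_b > 0:
                union += span
        elif prev is not None and prev[0] != chrom:
            state_a = state_b = 0
        if delta in (1, -1):
            state_a += delta
        else:
            state_b += delta // 2
        prev = (chrom, pos)
    if union == 0:
        return 1.0 if not a and not b else 0.0
    return inter / union
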