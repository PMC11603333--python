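"""Trio-binning quality along the genome.

Per-window tag counts, binnability (fraction of parentally assigned reads),
the parental bias ratio, and the count of heavily biased windows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .io_formats import (
    MATERNAL,
    PATERNAL,
    UNASSIGNED,
    GenomeLayout,
    Region,
    TaggedRead,
    iter_windows,
)

#: sentinel for a window where exactly one parental class has reads
INF_BIAS = math.inf


@dataclass
class PhaseWindow:
    chrom: str
    start: int
    end: int
    n_paternal: int = 0
    n_maternal: int = 0
    n_unassigned: int = 0

    @property
    def n_total(self) -> int:
        return self.n_paternal + self.n_maternal + self.n_unassigned

    @property
    def n_assigned(self) -> int:
        return self.n_paternal + self.n_maternal

    @property
    def binnability(self) -> float:
        """(pat + mat) / total; NaN when the window holds no reads."""
        if self.n_total == 0:
            return math.nan
        return self.n_assigned / self.n_total


@dataclass
class PhaseSummary:
    windows: list[PhaseWindow]
    genome_binnability: float
    n_biased_windows: int
    bias_fold: float

    @property
    def window_binnabilities(self) -> np.ndarray:
        return np.array([w.binnability for w in self.windows])

    @property
    def window_bias_ratios(self) -> np.ndarray:
        return np.array([bias_ratio(w) for w in self.windows])


def bin_tagged_reads(
    reads: Iterable[TaggedRead],
    layout: GenomeLayout,
    phase_window: int = 100_000,
    autosomes_only: bool = False,
) -> list[PhaseWindow]:
    """Count reads per tag in tumbling windows of ``phase_window`` bp.

    Every read is counted exactly once, in the window containing its start.
    All windows are emitted, including empty ones.  Reads on chromosomes not
    in the layout (or outside it when ``autosomes_only``) raise ``KeyError``.
    """
    windows: list[PhaseWindow] = []
    index: dict[str, tuple[int, int]] = {}  # chrom -> (first window idx, n windows)
    for w, _partial in iter_windows(
        layout, phase_window, keep_partial=True, autosomes_only=autosomes_only
    ):
        if w.chrom not in index:
            index[w.chrom] = (len(windows), 0)
        first, n = index[w.chrom]
        index[w.chrom] = (first, n + 1)
        windows.append(PhaseWindow(w.chrom, w.start, w.end))
    for r in reads:
        if r.chrom not in index:
            raise KeyError(f"read on unknown chromosome {r.chrom!r}")
        first, n = index[r.chrom]
        wi = (r.start - 1) // phase_window
        if wi >= n or r.start > layout.length_of(r.chrom):
            raise KeyError(f"read start {r.start} beyond chromosome {r.chrom}")
        w = windows[first + wi]
        if r.tag == PATERNAL:
            w.n_paternal += 1
        elif r.tag == MATERNAL:
            w.n_maternal += 1
        else:
            w.n_unassigned += 1
    return windows


def bias_ratio(window: PhaseWindow) -> float:
    """max(pat, mat) / min(pat, mat).

    Exactly one of the two zero -> inf sentinel; both zero -> NaN (undefined).
    """
    hi = max(window.n_paternal, window.n_maternal)
    lo = min(window.n_paternal, window.n_maternal)
    if hi == 0:
        return math.nan
    if lo == 0:
        return INF_BIAS
    return hi / lo


def genome_binnability(
    windows: Sequence[PhaseWindow], read_weighted: bool = True
) -> float:
    """Genome-wide assigned fraction.

    Read-weighted by default (total assigned / total reads); with
    ``read_weighted=False`` returns the unweighted mean of defined window
    fractions instead (sensitivity analysis).
    """
    if read_weighted:
        total = sum(w.n_total for w in windows)
        if total == 0:
            return math.nan
        return sum(w.n_assigned for w in windows) / total
    vals = [w.binnability for w in windows if w.n_total > 0]
    if not vals:
        return math.nan
    return float(np.mean(vals))


def count_biased_windows(
    windows: Sequence[PhaseWindow], bias_fold: float = 5.0
) -> int:
    """Windows whose parental ratio is strictly greater than ``bias_fold``.

    The infinite sentinel counts as biased; windows with no parental reads
    at all are undefined and excluded.
    """
    n = 0
    for w in windows:
        r = bias_ratio(w)
        if not math.isnan(r) and r > bias_fold:
            n += 1
    return n


def summarize_phasing(
    windows: Sequence[PhaseWindow],
    bias_fold: float = 5.0,
    read_weighted: bool = True,
) -> PhaseSummary:
    return PhaseSummary(
        windows=list(windows),
        genome_binnability=genome_binnability(windows, read_weighted=read_weighted),
        n_biased_windows=count_biased_windows(windows, bias_fold=bias_fold),
        bias_fold=bias_fold,
    )


def histogram_table(
    values: np.ndarray, edges: np.ndarray
) -> list[tuple[float, float, int]]:
    """Finite-value histogram rows ``(low, high, count)`` for TSV output."""
    finite = values[np.isfinite(values)]
    counts, _ = np.histogram(finite, bins=edges)
    return [
        (float(edges[i]), float(edges[i + 1]), int(counts[i]))
        for i in range(len(counts))
    ]
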