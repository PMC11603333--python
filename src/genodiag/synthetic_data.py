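"""Seeded generators for every input the analysis stages consume.

Each generator draws from its own deterministic sub-stream of a single
global seed (``numpy`` ``SeedSequence`` spawn keys with fixed offsets), so
outputs are byte-reproducible and independent across generators.  Ground
truth (planted homozygous intervals, deletion genotypes, the tree behind an
SV presence matrix) is returned alongside the data for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io_formats import (
    MATERNAL,
    PATERNAL,
    UNASSIGNED,
    DepthTrack,
    GenomeLayout,
    Interval,
    Region,
    TaggedRead,
    VariantRecord,
    VariantSet,
    iter_windows,
)

# fixed sub-stream offsets — one per generator
_STREAM_VARIANTS = 1
_STREAM_DEPTH = 2
_STREAM_TAGS = 3
_STREAM_SV = 4

_BASES = ("A", "C", "G", "T")

HOM_DELETION = "hom"
HET_DELETION = "het"
NO_DELETION = "absent"
_DELETION_SCALE = {HOM_DELETION: 0.0, HET_DELETION: 0.5, NO_DELETION: 1.0}


@dataclass(frozen=True)
class TreeNode:
    """Rooted tree node; ``branch_sv_count`` is the SV count on the branch above it."""

    name: str | None
    children: tuple["TreeNode", ...] = ()
    branch_sv_count: int = 0

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            if self.name is None:
                raise ValueError("leaf without a name")
            return [self.name]
        out: list[str] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def iter_nodes(self) -> Iterable["TreeNode"]:
        yield self
        for c in self.children:
            yield from c.iter_nodes()

    def to_newick(self) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                return node.name  # type: ignore[return-value]
            return "(" + ",".join(fmt(c) for c in node.children) + ")"

        return fmt(self) + ";"


Profile = float | Mapping[str, np.ndarray]


@dataclass
class SimSpec:
    """Parameters and ground truth for one synthetic dataset."""

    layout: GenomeLayout
    seed: int
    mean_het: float = 1.0e-3
    roh_segments: tuple[Interval, ...] = ()
    residual_het_in_roh: float = 0.0
    mean_depth: float = 30.0
    depth_dispersion: float = 0.1
    binnability_profile: Profile = 0.6
    parental_bias_profile: Profile = 0.5
    phase_window: int = 100_000
    deletion_events: tuple[tuple[Region, str], ...] = ()
    sv_tree: TreeNode | None = None
    sv_min_length: int = 50
    sv_max_length: int = 5_000

    def __post_init__(self) -> None:
        if self.mean_het < 0 or self.residual_het_in_roh < 0:
            raise ValueError("heterozygosity rates must be >= 0")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if self.depth_dispersion < 0:
            raise ValueError("depth_dispersion must be >= 0")
        for p in (self.binnability_profile, self.parental_bias_profile):
            if isinstance(p, float) and not (0.0 <= p <= 1.0):
                raise ValueError("profile probabilities must lie in [0, 1]")
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, s, e in self.roh_segments:
            if chrom not in self.layout:
                raise ValueError(f"truth ROH on unknown chromosome {chrom!r}")
            if not (1 <= s <= e <= self.layout.length_of(chrom)):
                raise ValueError(f"truth ROH {chrom}:{s}-{e} outside layout")
            by_chrom.setdefault(chrom, []).append((s, e))
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            for (s1, e1), (s2, _) in zip(ivs, ivs[1:]):
                if s2 <= e1:
                    raise ValueError(f"overlapping truth ROH on {chrom}")
        for region, gt in self.deletion_events:
            if gt not in _DELETION_SCALE:
                raise ValueError(f"bad deletion genotype {gt!r}")
            if region.chrom not in self.layout:
                raise ValueError(f"deletion event on unknown chromosome {region.chrom!r}")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), stream])

    def profile_for(self, profile: Profile, chrom: str, n_windows: int) -> np.ndarray:
        if isinstance(profile, Mapping):
            arr = np.asarray(profile[chrom], dtype=float)
            if len(arr) != n_windows:
                raise ValueError(
                    f"profile for {chrom} has {len(arr)} windows, expected {n_windows}"
                )
        else:
            arr = np.full(n_windows, float(profile))
        if np.any((arr < 0) | (arr > 1)):
            raise ValueError("profile probabilities must lie in [0, 1]")
        return arr


# ---------------------------------------------------------------------------
# Small variants with planted ROH
# ---------------------------------------------------------------------------

def _het_positions(
    rng: np.random.Generator, start: int, end: int, rate: float
) -> np.ndarray:
    """Poisson-process positions on the 1-based inclusive interval [start, end]."""
    length = end - start + 1
    if length <= 0 or rate <= 0:
        return np.empty(0, dtype=np.int64)
    n = rng.poisson(rate * length)
    if n == 0:
        return np.empty(0, dtype=np.int64)
    pos = np.unique(rng.integers(start, end + 1, size=n))
    return pos


def simulate_diploid_variants(
    spec: SimSpec, sample: str = "sim0"
) -> tuple[VariantSet, list[Interval]]:
    """Heterozygous SNPs as a Poisson process, thinned inside planted ROH.

    Site density is ``mean_het`` per bp outside the truth intervals and
    ``residual_het_in_roh`` inside.  Genotypes are 0/1, depth is the rounded
    simulation mean depth, site quality a constant high value.
    """
    rng = spec.rng(_STREAM_VARIANTS)
    records: list[VariantRecord] = []
    dp = int(round(spec.mean_depth))
    roh_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in spec.roh_segments:
        roh_by_chrom.setdefault(chrom, []).append((s, e))
    for c in spec.layout.chromosomes:
        segments: list[tuple[int, int, float]] = []
        cursor = 1
        for s, e in sorted(roh_by_chrom.get(c.name, [])):
            if cursor < s:
                segments.append((cursor, s - 1, spec.mean_het))
            segments.append((s, e, spec.residual_het_in_roh))
            cursor = e + 1
        if cursor <= c.length:
            segments.append((cursor, c.length, spec.mean_het))
        positions: list[np.ndarray] = []
        for s, e, rate in segments:
            positions.append(_het_positions(rng, s, e, rate))
        all_pos = np.concatenate(positions) if positions else np.empty(0, dtype=np.int64)
        all_pos.sort()
        for p in all_pos:
            ref_i = int(rng.integers(0, 4))
            alt_i = (ref_i + int(rng.integers(1, 4))) % 4
            records.append(
                VariantRecord(
                    chrom=c.name,
                    pos=int(p),
                    ref=_BASES[ref_i],
                    alts=(_BASES[alt_i],),
                    qual=100.0,
                    genotypes=[(0, 1)],
                    depths=[dp],
                    ac=1,
                )
            )
    truth = sorted(spec.roh_segments, key=lambda t: (t[0], t[1]))
    return VariantSet(samples=[sample], records=records), list(truth)


# ---------------------------------------------------------------------------
# Depth tracks
# ---------------------------------------------------------------------------

def simulate_depth(
    spec: SimSpec, region: Region | None = None, chunk: int = 5_000_000
) -> list[DepthTrack]:
    """Overdispersed per-base depth with deletion events embedded.

    Depth is negative-binomial with mean ``mean_depth`` and variance
    ``mu + dispersion * mu**2`` (gamma-Poisson mixture); ``dispersion == 0``
    degenerates to a constant track.  Inside each deletion event the mean is
    scaled by 0 / 0.5 / 1 for hom / het / absent genotypes.
    """
    rng = spec.rng(_STREAM_DEPTH)
    regions = (
        [region]
        if region is not None
        else [Region(c.name, 1, c.length) for c in spec.layout.chromosomes]
    )
    tracks: list[DepthTrack] = []
    for reg in regions:
        events = [
            (max(ev.start, reg.start), min(ev.end, reg.end), _DELETION_SCALE[gt])
            for ev, gt in spec.deletion_events
            if ev.chrom == reg.chrom and ev.start <= reg.end and ev.end >= reg.start
        ]
        depth = np.empty(reg.length, dtype=np.int32)
        # chunked so whole-chromosome tracks never hold >1 float array in RAM
        for off in range(0, reg.length, chunk):
            span = min(chunk, reg.length - off)
            m = np.full(span, spec.mean_depth)
            c_start = reg.start + off
            for lo, hi, s in events:
                a = max(lo - c_start, 0)
                b = min(hi - c_start + 1, span)
                if a < b:
                    m[a:b] = spec.mean_depth * s
            if spec.depth_dispersion <= 0:
                depth[off : off + span] = np.round(m).astype(np.int32)
            else:
                n = 1.0 / spec.depth_dispersion
                p = n / (n + m)
                depth[off : off + span] = rng.negative_binomial(n, p).astype(np.int32)
        tracks.append(DepthTrack(reg, depth))
    return tracks


# ---------------------------------------------------------------------------
# Trio read tags
# ---------------------------------------------------------------------------

def simulate_trio_tags(
    spec: SimSpec, reads_per_window: int
) -> tuple[list[TaggedRead], dict[str, dict[str, np.ndarray]]]:
    """Reads tagged parental with the window's binnability probability, then
    paternal with the window's bias probability; starts uniform in the window.

    Returns the reads plus the truth profiles actually used, keyed by
    chromosome: ``{"binnability": array, "paternal_bias": array}``.
    """
    if reads_per_window < 0:
        raise ValueError("reads_per_window must be >= 0")
    rng = spec.rng(_STREAM_TAGS)
    windows_by_chrom: dict[str, list[Region]] = {}
    for w, _partial in iter_windows(spec.layout, spec.phase_window, keep_partial=True):
        windows_by_chrom.setdefault(w.chrom, []).append(w)
    reads: list[TaggedRead] = []
    truth: dict[str, dict[str, np.ndarray]] = {}
    for chrom, wins in windows_by_chrom.items():
        p_assign = spec.profile_for(spec.binnability_profile, chrom, len(wins))
        p_pat = spec.profile_for(spec.parental_bias_profile, chrom, len(wins))
        truth[chrom] = {"binnability": p_assign, "paternal_bias": p_pat}
        for i, w in enumerate(wins):
            starts = np.sort(rng.integers(w.start, w.end + 1, size=reads_per_window))
            assigned = rng.random(reads_per_window) < p_assign[i]
            paternal = rng.random(reads_per_window) < p_pat[i]
            for s, a, p in zip(starts, assigned, paternal):
                tag = (PATERNAL if p else MATERNAL) if a else UNASSIGNED
                reads.append(TaggedRead(chrom, int(s), tag))
    return reads, truth


# ---------------------------------------------------------------------------
# SV presence matrices on a known tree
# ---------------------------------------------------------------------------

def simulate_sv_matrix(spec: SimSpec):
    """SV presence matrix generated on a known rooted tree.

    Each branch contributes ``branch_sv_count`` SVs present in exactly the
    leaves below it.  Positions are uniform on the layout (length-weighted),
    lengths uniform in ``[sv_min_length, sv_max_length]``, classes random.
    Returns ``(SvPresenceMatrix, truth TreeNode)``.
    """
    from .sv_pangenome import SvPresenceMatrix, SvRecord  # avoid import cycle

    tree = spec.sv_tree
    if tree is None:
        raise ValueError("SimSpec.sv_tree is not set")
    leaves = tree.leaves()
    if len(leaves) < 2:
        raise ValueError("sv_tree must have at least 2 leaves")
    if len(set(leaves)) != len(leaves):
        raise ValueError("duplicate leaf names in sv_tree")
    rng = spec.rng(_STREAM_SV)
    leaf_index = {name: i for i, name in enumerate(leaves)}
    chroms = list(spec.layout.chromosomes)
    chrom_w = np.array([c.length for c in chroms], dtype=float)
    chrom_w /= chrom_w.sum()
    records: list[SvRecord] = []
    for node in tree.iter_nodes():
        if node.branch_sv_count < 0:
            raise ValueError("branch SV counts must be >= 0")
        if node.branch_sv_count == 0:
            continue
        presence = np.zeros(len(leaves), dtype=bool)
        for leaf in node.leaves():
            presence[leaf_index[leaf]] = True
        for _ in range(node.branch_sv_count):
            ci = int(rng.choice(len(chroms), p=chrom_w))
            c = chroms[ci]
            pos = int(rng.integers(1, c.length + 1))
            length = int(rng.integers(spec.sv_min_length, spec.sv_max_length + 1))
            sv_class = "DEL" if rng.random() < 0.5 else "INS"
            records.append(
                SvRecord(
                    chrom=c.name,
                    pos=pos,
                    sv_class=sv_class,
                    length=length,
                    presence=tuple(bool(b) for b in presence),
                )
            )
    records.sort(key=lambda r: (spec.layout.names().index(r.chrom), r.pos))
    return SvPresenceMatrix(assemblies=tuple(leaves), records=records), tree
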