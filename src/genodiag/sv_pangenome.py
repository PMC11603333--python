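"""Structural-variant presence/absence analytics from a deconstructed
multi-assembly VCF: per-pattern intersections, private-SV hotspot scan,
pairwise shared-SV distances and UPGMA clustering with Newick output.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from cyvcf2 import VCF

from .io_formats import FormatError, GenomeLayout, Region, iter_windows

INSERTION = "INS"
DELETION = "DEL"


@dataclass(frozen=True)
class SvRecord:
    chrom: str
    pos: int
    sv_class: str  # INS or DEL
    length: int
    presence: tuple[bool, ...]

    def __post_init__(self) -> None:
        if self.sv_class not in (INSERTION, DELETION):
            raise ValueError(f"bad SV class {self.sv_class!r}")
        if not any(self.presence):
            raise ValueError("SV present in no assembly")


@dataclass
class SvPresenceMatrix:
    assemblies: tuple[str, ...]
    records: list[SvRecord]

    def __post_init__(self) -> None:
        for r in self.records:
            if len(r.presence) != len(self.assemblies):
                raise ValueError("presence vector arity mismatch")

    def presence_array(self) -> np.ndarray:
        return np.array([r.presence for r in self.records], dtype=bool).reshape(
            len(self.records), len(self.assemblies)
        )


def presence_from_deconstructed_vcf(
    path: str, min_sv_length: int = 50
) -> SvPresenceMatrix:
    """Build the presence matrix from a pangenome-deconstruction VCF.

    One genotype column per assembly; an assembly is *present* for an alt
    allele iff its genotype carries that allele (missing counts as absent).
    Multi-allelic records are split per alt; the class is the sign of
    ``len(alt) - len(ref)`` and records shorter than ``min_sv_length`` (or
    with no carrier) are dropped.
    """
    vcf = VCF(str(path))
    assemblies = tuple(vcf.samples)
    if not assemblies:
        raise FormatError(f"{path}: no genotype columns")
    records: list[SvRecord] = []
    n_missing = 0
    for v in vcf:
        if any(a.startswith("<") for a in v.ALT):
            raise FormatError(
                f"{path}: symbolic allele without length info at {v.CHROM}:{v.POS}"
            )
        gts = v.genotypes or []
        alleles_per_sample: list[set[int]] = []
        for g in gts:
            alleles = {int(a) for a in g[:-1]}
            if -1 in alleles:
                n_missing += 1
                alleles.discard(-1)
            alleles_per_sample.append(alleles)
        for ai, alt in enumerate(v.ALT, start=1):
            diff = len(alt) - len(v.REF)
            length = abs(diff)
            if length < min_sv_length:
                continue
            presence = tuple(ai in alleles for alleles in alleles_per_sample)
            if not any(presence):
                continue
            records.append(
                SvRecord(
                    chrom=v.CHROM,
                    pos=v.POS,
                    sv_class=INSERTION if diff > 0 else DELETION,
                    length=length,
                    presence=presence,
                )
            )
    vcf.close()
    if n_missing:
        import logging

        logging.getLogger("genodiag").warning(
            "%d missing genotypes treated as absent", n_missing
        )
    return SvPresenceMatrix(assemblies=assemblies, records=records)


def write_deconstructed_vcf(
    matrix: SvPresenceMatrix, path: str, layout: GenomeLayout | None = None
) -> None:
    """Write the matrix back as a haploid-genotype VCF (deletions become a
    long REF with 1-bp ALT, insertions the reverse) for round-trip tests."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if layout is not None:
            for c in layout.chromosomes:
                fh.write(f"##contig=<ID={c.name},length={c.length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.assemblies)
            + "\n"
        )
        for r in matrix.records:
            if r.sv_class == DELETION:
                ref = "A" * (r.length + 1)
                alt = "A"
            else:
                ref = "A"
                alt = "A" * (r.length + 1)
            gts = "\t".join("1" if p else "0" for p in r.presence)
            fh.write(
                f"{r.chrom}\t{r.pos}\t.\t{ref}\t{alt}\t60\t.\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# Intersections (UpSet semantics)
# ---------------------------------------------------------------------------

def subset_intersections(
    matrix: SvPresenceMatrix,
) -> tuple[dict[frozenset, int], dict[str, int]]:
    """Exact-pattern counts (each SV counted once under its full presence
    set) plus per-assembly totals."""
    patterns: Counter = Counter()
    totals = {a: 0 for a in matrix.assemblies}
    for r in matrix.records:
        present = frozenset(
            a for a, p in zip(matrix.assemblies, r.presence) if p
        )
        patterns[present] += 1
        for a in present:
            totals[a] += 1
    return dict(patterns), totals


def private_svs(matrix: SvPresenceMatrix, focal: str) -> list[SvRecord]:
    if focal not in matrix.assemblies:
        raise KeyError(f"unknown focal assembly {focal!r}")
    fi = matrix.assemblies.index(focal)
    return [
        r
        for r in matrix.records
        if r.presence[fi] and sum(r.presence) == 1
    ]


@dataclass
class HotspotWindow:
    region: Region
    n_private: int
    fold: float


def private_sv_hotspots(
    matrix: SvPresenceMatrix,
    focal: str,
    window: int,
    layout: GenomeLayout,
    fold_threshold: float = 1.0,
) -> list[HotspotWindow]:
    """Windows where the density of SVs private to ``focal`` exceeds the
    genome-wide private-SV rate by at least ``fold_threshold``.

    fold = (window count / window bp) / (genome count / genome bp).
    """
    privates = private_svs(matrix, focal)
    genome_bp = layout.total_length
    n_total = len(privates)
    if n_total == 0:
        return []
    genome_rate = n_total / genome_bp
    by_chrom: dict[str, list[int]] = {}
    for r in privates:
        by_chrom.setdefault(r.chrom, []).append(r.pos)
    out: list[HotspotWindow] = []
    for w, _partial in iter_windows(layout, window, keep_partial=True):
        positions = by_chrom.get(w.chrom, [])
        n = sum(1 for p in positions if w.start <= p <= w.end)
        if n == 0:
            continue
        fold = (n / w.length) / genome_rate
        if fold >= fold_threshold:
            out.append(HotspotWindow(region=w, n_private=n, fold=fold))
    return out


# ---------------------------------------------------------------------------
# Pairwise distances
# ---------------------------------------------------------------------------

def pairwise_sv_distance(
    matrix: SvPresenceMatrix, mode: str = "shared"
) -> tuple[tuple[str, ...], np.ndarray]:
    """Symmetric distance matrix between assemblies.

    ``shared`` (default): d = 1 / number of SVs present in both; pairs
    sharing nothing get a sentinel of twice the largest finite distance.
    ``discordant``: d = discordant SVs / total SVs (0 when no SVs).
    """
    n = len(matrix.assemblies)
    if n < 2:
        raise ValueError("need at least 2 assemblies")
    P = matrix.presence_array()
    D = np.zeros((n, n))
    if mode == "shared":
        shared = P.T.astype(np.int64) @ P.astype(np.int64)
        with np.errstate(divide="ignore"):
            D = np.where(shared > 0, 1.0 / np.maximum(shared, 1), np.inf)
        np.fill_diagonal(D, 0.0)
        finite = D[np.isfinite(D)]
        if np.any(~np.isfinite(D)):
            if finite.size == 0:
                raise ValueError("no pair of assemblies shares any SV")
            D[~np.isfinite(D)] = 2.0 * finite.max()
    elif mode == "discordant":
        total = len(matrix.records)
        for i in range(n):
            for j in range(i + 1, n):
                disc = int(np.count_nonzero(P[:, i] != P[:, j]))
                D[i, j] = D[j, i] = disc / total if total else 0.0
    else:
        raise ValueError(f"unknown distance mode {mode!r}")
    return matrix.assemblies, D


# ---------------------------------------------------------------------------
# UPGMA
# ---------------------------------------------------------------------------

@dataclass
class ClusterNode:
    """Node of an ultrametric dendrogram; ``height`` is the merge half-distance."""

    name: str | None
    height: float = 0.0
    children: tuple["ClusterNode", ...] = ()

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]  # type: ignore[list-item]
        out: list[str] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def to_newick(self, digits: int = 6) -> str:
        def fmt(node: ClusterNode, parent_height: float) -> str:
            bl = parent_height - node.height
            if node.is_leaf:
                return f"{node.name}:{bl:.{digits}f}"
            inner = ",".join(fmt(c, node.height) for c in node.children)
            return f"({inner}):{bl:.{digits}f}"

        if self.is_leaf:
            return f"{self.name};"
        inner = ",".join(fmt(c, self.height) for c in self.children)
        return f"({inner});"


@dataclass
class Dendrogram:
    root: ClusterNode
    merges: list[tuple[frozenset, frozenset, float]] = field(default_factory=list)
    """Merge sequence: (leafset A, leafset B, merge height = d/2)."""

    def to_newick(self, digits: int = 6) -> str:
        return self.root.to_newick(digits)

    def is_ultrametric(self, tol: float = 1e-9) -> bool:
        """Merge heights must be non-decreasing from leaves to root, which
        makes every leaf-to-root path length equal (heights are absolute)."""
        ok = True

        def walk(node: ClusterNode) -> None:
            nonlocal ok
            for c in node.children:
                if c.height > node.height + tol:
                    ok = False
                walk(c)

        walk(self.root)
        return ok

    def clades(self) -> set[frozenset]:
        out: set[frozenset] = set()

        def walk(node: ClusterNode) -> frozenset:
            if node.is_leaf:
                s = frozenset([node.name])
            else:
                s = frozenset().union(*(walk(c) for c in node.children))
            out.add(s)
            return s

        walk(self.root)
        return out


def upgma(labels: Sequence[str], distances: np.ndarray) -> Dendrogram:
    """Size-weighted average-linkage agglomeration (UPGMA).

    Repeatedly joins the closest pair; the new cluster's distance to the
    rest is the member-count-weighted average, the merge height is half the
    joined distance.  Ties break on the lexicographically smallest pair of
    cluster labels, a cluster's label being its smallest leaf name.
    """
    D = np.asarray(distances, dtype=float)
    n = len(labels)
    if D.shape != (n, n):
        raise ValueError("distance matrix shape does not match labels")
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix is not symmetric")
    if np.any(np.diag(D) != 0):
        raise ValueError("distance matrix diagonal must be zero")
    if np.any(D < 0):
        raise ValueError("distances must be non-negative")
    if n == 1:
        return Dendrogram(root=ClusterNode(name=labels[0]))
    nodes = {i: ClusterNode(name=labels[i]) for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    names = {i: labels[i] for i in range(n)}  # lexicographic tie-break label
    active = list(range(n))
    work = D.copy()
    merges: list[tuple[frozenset, frozenset, float]] = []
    next_id = n
    while len(active) > 1:
        best: tuple[float, str, str, int, int] | None = None
        for ii in range(len(active)):
            for jj in range(ii + 1, len(active)):
                a, b = active[ii], active[jj]
                d = work[a, b]
                la, lb = sorted((names[a], names[b]))
                key = (d, la, lb, a, b)
                if best is None or key < best:
                    best = key
        assert best is not None
        d, _, _, a, b = best
        height = d / 2.0
        if names[b] < names[a]:
            a, b = b, a
        node = ClusterNode(name=None, height=height, children=(nodes[a], nodes[b]))
        merges.append(
            (frozenset(nodes[a].leaves()), frozenset(nodes[b].leaves()), height)
        )
        new = next_id
        next_id += 1
        grown = np.zeros((new + 1, new + 1))
        grown[: work.shape[0], : work.shape[1]] = work
        work = grown
        for c in active:
            if c in (a, b):
                continue
            dc = (sizes[a] * work[a, c] + sizes[b] * work[b, c]) / (
                sizes[a] + sizes[b]
            )
            work[new, c] = work[c, new] = dc
        nodes[new] = node
        sizes[new] = sizes[a] + sizes[b]
        names[new] = min(names[a], names[b])
        active = [c for c in active if c not in (a, b)] + [new]
    return Dendrogram(root=nodes[active[0]], merges=merges)


def robinson_foulds(clades_a: set[frozenset], clades_b: set[frozenset]) -> int:
    """Symmetric difference of non-trivial clade sets of two rooted trees
    over the same leaves (0 iff identical rooted topologies)."""
    leaves_a = max(clades_a, key=len)
    leaves_b = max(clades_b, key=len)
    if leaves_a != leaves_b:
        raise ValueError("trees are over different leaf sets")

    def nontrivial(cl: set[frozenset], all_leaves: frozenset) -> set[frozenset]:
        return {c for c in cl if 1 < len(c) < len(all_leaves)}

    a = nontrivial(clades_a, leaves_a)
    b = nontrivial(clades_b, leaves_b)
    return len(a ^ b)
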