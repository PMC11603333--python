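"""Readers/writers for the on-disk formats, region parsing and configuration.

Coordinate conventions
----------------------
All in-memory positions are 1-based inclusive (VCF convention).  BED output
is converted to 0-based half-open on write and back on read.  Depth tables
must be dense (``samtools depth -aa`` style): every position of a covered
chromosome stretch present exactly once.  Readers reject malformed input
rather than repairing it silently.
"""

from __future__ import annotations

import dataclasses
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
import yaml
from cyvcf2 import VCF

logger = logging.getLogger("genodiag")

PATERNAL = "paternal"
MATERNAL = "maternal"
UNASSIGNED = "unassigned"
TAGS = (PATERNAL, MATERNAL, UNASSIGNED)


class FormatError(ValueError):
    """Raised when an input file or string violates its format contract."""


# ---------------------------------------------------------------------------
# Genome layout
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Chromosome:
    name: str
    length: int
    is_autosome: bool = True

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"chromosome {self.name!r} has non-positive length")


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosomes with lengths; the coordinate frame for windowing."""

    chromosomes: tuple[Chromosome, ...]

    def __post_init__(self) -> None:
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names in layout")

    @classmethod
    def from_pairs(
        cls,
        pairs: Iterable[tuple[str, int]],
        autosomes: set[str] | None = None,
    ) -> "GenomeLayout":
        chroms = tuple(
            Chromosome(str(n), int(l), autosomes is None or str(n) in autosomes)
            for n, l in pairs
        )
        return cls(chroms)

    def __contains__(self, name: str) -> bool:
        return any(c.name == name for c in self.chromosomes)

    def names(self) -> list[str]:
        return [c.name for c in self.chromosomes]

    def length_of(self, name: str) -> int:
        for c in self.chromosomes:
            if c.name == name:
                return c.length
        raise KeyError(f"unknown chromosome {name!r}")

    def autosomes(self) -> list[Chromosome]:
        return [c for c in self.chromosomes if c.is_autosome]

    @property
    def autosome_length(self) -> int:
        return sum(c.length for c in self.autosomes())

    @property
    def total_length(self) -> int:
        return sum(c.length for c in self.chromosomes)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GenomeLayout":
        """Read a layout TSV: ``name<TAB>length[<TAB>autosome-flag 0/1]``."""
        chroms = []
        for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}:{ln}: expected at least 2 columns")
            flag = bool(int(parts[2])) if len(parts) > 2 else True
            chroms.append(Chromosome(parts[0], int(parts[1]), flag))
        return cls(tuple(chroms))

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for c in self.chromosomes:
                fh.write(f"{c.name}\t{c.length}\t{int(c.is_autosome)}\n")


# ---------------------------------------------------------------------------
# Regions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Region:
    """1-based inclusive genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"region start {self.start} < 1")
        if self.start > self.end:
            raise ValueError(f"region start {self.start} > end {self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, other: "Region") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


_REGION_RE = re.compile(r"^([^:]+):(\d+)-(\d+)$")


def parse_region(text: str, layout: GenomeLayout | None = None) -> Region:
    """Parse ``chrom:start-end`` into a 1-based inclusive :class:`Region`."""
    m = _REGION_RE.match(text.strip())
    if m is None:
        raise FormatError(f"malformed region string {text!r}; expected chrom:start-end")
    chrom, start, end = m.group(1), int(m.group(2)), int(m.group(3))
    if start > end:
        raise FormatError(f"region {text!r} has start > end")
    if start < 1:
        raise FormatError(f"region {text!r} has start < 1")
    if layout is not None:
        if chrom not in layout:
            raise FormatError(f"unknown chromosome {chrom!r} in region {text!r}")
        if end > layout.length_of(chrom):
            raise FormatError(
                f"region {text!r} extends past chromosome end "
                f"({layout.length_of(chrom)})"
            )
    return Region(chrom, start, end)


def iter_windows(
    layout: GenomeLayout,
    size: int,
    keep_partial: bool = True,
    autosomes_only: bool = False,
) -> Iterator[tuple[Region, bool]]:
    """Tile each chromosome with tumbling windows of ``size`` bp.

    Yields ``(region, is_partial)``.  The trailing window is clipped to the
    chromosome end; with ``keep_partial=False`` it is dropped instead.
    """
    if size <= 0:
        raise ValueError("window size must be positive")
    chroms = layout.autosomes() if autosomes_only else list(layout.chromosomes)
    for c in chroms:
        start = 1
        while start <= c.length:
            end = min(start + size - 1, c.length)
            partial = (end - start + 1) < size
            if partial and not keep_partial:
                break
            yield Region(c.name, start, end), partial
            start = end + 1


# ---------------------------------------------------------------------------
# Pipeline parameters / config
# ---------------------------------------------------------------------------

@dataclass
class PipelineParams:
    """All tunable thresholds used by the analysis stages."""

    phase_window: int = 100_000
    het_window: int = 1_000_000
    roh_window: int = 10_000
    depth_low_factor: float = 1.0 / 3.0
    depth_high_factor: float = 2.5
    min_callable_fraction: float = 0.60
    roh_het_ceiling_factor: float = 0.25
    min_roh_length: int = 100_000
    long_roh_length: int = 2_000_000
    bias_fold: float = 5.0
    min_site_qual: float = 30.0
    min_allele_count: int = 2
    proximity_bp: int = 5
    min_sample_coverage: float = 5.0
    min_sv_length: int = 50
    autosome_length_L: int = 2_682_350_267
    keep_partial_windows: bool = True

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, bool):
                continue
            if v <= 0:
                raise ValueError(f"parameter {f.name} must be positive, got {v}")
        if self.depth_low_factor >= self.depth_high_factor:
            raise ValueError("depth_low_factor must be < depth_high_factor")
        if not (0 < self.roh_het_ceiling_factor < 1):
            raise ValueError("roh_het_ceiling_factor must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineParams":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise FormatError(f"config {path} must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        )


# ---------------------------------------------------------------------------
# Depth tracks
# ---------------------------------------------------------------------------

@dataclass
class DepthTrack:
    """Dense per-base depth over a region (one value per position)."""

    region: Region
    depth: np.ndarray

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth)
        if self.depth.ndim != 1 or len(self.depth) != self.region.length:
            raise ValueError(
                f"depth array length {len(self.depth)} != region length "
                f"{self.region.length}"
            )
        if np.any(self.depth < 0):
            raise ValueError("negative depth values")


def read_depth_table(path: str | Path, layout: GenomeLayout | None = None) -> list[DepthTrack]:
    """Read a dense ``chrom<TAB>pos<TAB>depth`` table into one track per chromosome run.

    The table must be complete-output style: for each chromosome, every
    position between the first and last row present exactly once.  Gaps,
    duplicates and negative depths are errors.
    """
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "pos", "depth"],
        dtype={"chrom": str, "pos": np.int64, "depth": np.int64},
        comment="#",
    )
    tracks: list[DepthTrack] = []
    if df.empty:
        return tracks
    if (df["depth"] < 0).any():
        raise FormatError(f"{path}: negative depth value")
    # contiguous chromosome blocks, in file order
    block = (df["chrom"] != df["chrom"].shift()).cumsum()
    for _, sub in df.groupby(block, sort=False):
        chrom = sub["chrom"].iloc[0]
        if layout is not None and chrom not in layout:
            raise FormatError(f"{path}: unknown chromosome {chrom!r}")
        pos = sub["pos"].to_numpy()
        diffs = np.diff(pos)
        if np.any(diffs == 0):
            raise FormatError(f"{path}: duplicate position on {chrom}")
        if np.any(diffs != 1):
            raise FormatError(f"{path}: gap or unsorted positions on {chrom}")
        region = Region(chrom, int(pos[0]), int(pos[-1]))
        tracks.append(DepthTrack(region, sub["depth"].to_numpy()))
    seen = [t.region.chrom for t in tracks]
    if len(set(seen)) != len(seen):
        raise FormatError(f"{path}: chromosome appears in non-contiguous blocks")
    return tracks


def write_depth_table(tracks: Sequence[DepthTrack], path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in tracks:
            chrom = t.region.chrom
            for i, d in enumerate(t.depth):
                fh.write(f"{chrom}\t{t.region.start + i}\t{int(d)}\n")


# ---------------------------------------------------------------------------
# Tagged reads
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TaggedRead:
    """Primary-alignment start plus parental tag."""

    chrom: str
    start: int
    tag: str

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError("read start must be >= 1")
        if self.tag not in TAGS:
            raise ValueError(f"bad tag {self.tag!r}; expected one of {TAGS}")


def read_tagged_reads(path: str | Path) -> Iterator[TaggedRead]:
    """Stream a 3-column ``chrom<TAB>start<TAB>tag`` table."""
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 3:
                raise FormatError(f"{path}:{ln}: expected 3 columns")
            try:
                yield TaggedRead(parts[0], int(parts[1]), parts[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{ln}: {exc}") from exc


def write_tagged_reads(reads: Iterable[TaggedRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"{r.chrom}\t{r.start}\t{r.tag}\n")


# ---------------------------------------------------------------------------
# Variants
# ---------------------------------------------------------------------------

SNP = "SNP"
INDEL = "InDel"

Genotype = tuple[int, ...] | None


@dataclass
class VariantRecord:
    """One VCF record with per-sample genotype and depth.

    ``genotypes`` holds one entry per sample: a tuple of allele indices
    (0 = ref) or ``None`` for missing.  ``depths`` holds per-sample read
    depth or ``None`` when absent.
    """

    chrom: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    qual: float | None
    genotypes: list[Genotype]
    depths: list[int | None]
    ac: int | None = None
    id: str = "."

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("POS must be >= 1")
        n_alleles = 1 + len(self.alts)
        for g in self.genotypes:
            if g is not None and any(a < 0 or a >= n_alleles for a in g):
                raise FormatError(
                    f"{self.chrom}:{self.pos}: genotype allele out of range"
                )

    @property
    def variant_class(self) -> str:
        if len(self.ref) == 1 and all(len(a) == 1 for a in self.alts):
            return SNP
        return INDEL

    @property
    def is_biallelic(self) -> bool:
        return len(self.alts) == 1

    def computed_ac(self) -> int:
        """Non-reference allele count over non-missing genotypes."""
        return sum(
            sum(1 for a in g if a > 0) for g in self.genotypes if g is not None
        )

    def effective_ac(self) -> int:
        return self.ac if self.ac is not None else self.computed_ac()

    def is_het(self, sample_index: int = 0) -> bool:
        g = self.genotypes[sample_index]
        return g is not None and len(g) == 2 and g[0] != g[1]


@dataclass
class VariantSet:
    samples: list[str]
    records: list[VariantRecord]


def _genotype_from_cyvcf2(raw: list) -> Genotype:
    # cyvcf2 genotype entry: [allele, allele, ..., phased_flag]
    alleles = tuple(int(a) for a in raw[:-1])
    if any(a < 0 for a in alleles):
        return None
    return alleles


def read_variants(path: str | Path) -> VariantSet:
    """Read a VCF (uncompressed or bgzipped) into memory.

    Per-sample depth is taken from FORMAT/DP when present.  The site allele
    count is taken from INFO/AC (summed over alts) when present, otherwise
    left unset and recomputed from genotypes on demand.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    records: list[VariantRecord] = []
    for v in vcf:
        if v.genotypes is None and samples:
            raise FormatError(f"{path}: record {v.CHROM}:{v.POS} lacks GT")
        genotypes = [_genotype_from_cyvcf2(g) for g in (v.genotypes or [])]
        depths: list[int | None]
        try:
            fmt_dp = v.format("DP")
        except KeyError:
            fmt_dp = None
        if fmt_dp is not None:
            depths = [
                None if int(d) < 0 else int(d) for d in np.ravel(fmt_dp)[: len(samples)]
            ]
        else:
            depths = [None] * len(samples)
        ac_info = v.INFO.get("AC")
        if ac_info is None:
            ac = None
        elif isinstance(ac_info, tuple):
            ac = int(sum(ac_info))
        else:
            ac = int(ac_info)
        records.append(
            VariantRecord(
                chrom=v.CHROM,
                pos=v.POS,
                ref=v.REF,
                alts=tuple(v.ALT),
                qual=v.QUAL,
                genotypes=genotypes,
                depths=depths,
                ac=ac,
                id=v.ID or ".",
            )
        )
    vcf.close()
    return VariantSet(samples=samples, records=records)


def _fmt_qual(q: float | None) -> str:
    if q is None:
        return "."
    if float(q) == int(q):
        return str(int(q))
    return f"{q:g}"


def write_variants(
    vs: VariantSet, path: str | Path, layout: GenomeLayout | None = None
) -> None:
    """Write a minimal VCF with INFO/AC and FORMAT GT:DP (only fields consumed here)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if layout is not None:
            for c in layout.chromosomes:
                fh.write(f"##contig=<ID={c.name},length={c.length}>\n")
        fh.write('##INFO=<ID=AC,Number=A,Type=Integer,Description="Allele count">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
        fh.write("\t".join(cols + list(vs.samples)) + "\n")
        for r in vs.records:
            info = f"AC={r.effective_ac()}"
            fields = [
                r.chrom,
                str(r.pos),
                r.id,
                r.ref,
                ",".join(r.alts) if r.alts else ".",
                _fmt_qual(r.qual),
                ".",
                info,
                "GT:DP",
            ]
            for g, d in zip(r.genotypes, r.depths):
                gt = "./." if g is None else "/".join(str(a) for a in g)
                dp = "." if d is None else str(d)
                fields.append(f"{gt}:{dp}")
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

Interval = tuple[str, int, int]  # chrom, start, end — 1-based inclusive


def _check_sorted_nonoverlapping(segments: Sequence[Interval]) -> None:
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in segments:
        if s > e:
            raise ValueError(f"segment {chrom}:{s}-{e} has start > end")
        by_chrom.setdefault(chrom, []).append((s, e))
    for chrom, ivs in by_chrom.items():
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            if s2 <= e1:
                if s2 < s1:
                    raise ValueError(f"segments on {chrom} are unsorted")
                raise ValueError(f"segments on {chrom} overlap: "
                                 f"{s1}-{e1} and {s2}-{e2}")


def write_bed(segments: Sequence[Interval], path: str | Path) -> None:
    """Write 1-based inclusive segments as 0-based half-open BED lines."""
    _check_sorted_nonoverlapping(segments)
    with open(path, "w") as fh:
        for chrom, s, e in segments:
            fh.write(f"{chrom}\t{s - 1}\t{e}\n")


def read_bed(path: str | Path) -> list[Interval]:
    """Read BED back into 1-based inclusive segments."""
    out: list[Interval] = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise FormatError(f"{path}:{ln}: expected >= 3 BED columns")
        start0, end = int(parts[1]), int(parts[2])
        if start0 < 0 or end <= start0:
            raise FormatError(f"{path}:{ln}: bad BED interval")
        out.append((parts[0], start0 + 1, end))
    return out


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(levelname)s %(name)s: %(message)s",
    )
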