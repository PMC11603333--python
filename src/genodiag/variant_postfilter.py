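"""Small-variant post-filtering chain.

Order is fixed: per-sample depth masking -> indel-proximity removal ->
site quality / allele-count removal -> bi-allelic autosomal SNP selection.
Each record is removed at most once and attributed to the first failing
rule, so the report partitions the input exactly.
"""

from __future__ import annotations

import bisect
import dataclasses
import logging
from dataclasses import dataclass
from typing import Sequence

from .io_formats import INDEL, SNP, GenomeLayout, VariantRecord

logger = logging.getLogger("genodiag")


@dataclass
class FilterReport:
    n_input: int = 0
    n_genotypes_masked: int = 0
    n_removed_proximity: int = 0
    n_removed_qual: int = 0
    n_removed_ac: int = 0
    n_removed_class: int = 0
    n_retained_final: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def mask_genotypes_by_depth(
    records: Sequence[VariantRecord],
    mean_coverage: float,
    low_factor: float = 1.0 / 3.0,
    high_factor: float = 2.5,
) -> tuple[list[VariantRecord], int]:
    """Set a sample's genotype to missing when its depth is outside
    ``(low_factor * mean, high_factor * mean)`` — both bounds strict.

    A missing depth field also masks the genotype (logged).  Records are
    retained; the site allele count is recomputed from the surviving
    genotypes so the later AC filter sees post-masking counts.
    """
    if mean_coverage <= 0:
        raise ValueError("mean_coverage must be positive")
    lo = low_factor * mean_coverage
    hi = high_factor * mean_coverage
    out: list[VariantRecord] = []
    n_masked = 0
    for r in records:
        genotypes = list(r.genotypes)
        for i, (g, d) in enumerate(zip(r.genotypes, r.depths)):
            if g is None:
                continue
            if d is None:
                logger.debug("missing DP at %s:%d sample %d; masking", r.chrom, r.pos, i)
                genotypes[i] = None
                n_masked += 1
            elif d < lo or d > hi:
                genotypes[i] = None
                n_masked += 1
        rec = dataclasses.replace(r, genotypes=genotypes)
        rec.ac = rec.computed_ac()
        out.append(rec)
    return out, n_masked


def _check_sorted(records: Sequence[VariantRecord]) -> None:
    last: dict[str, int] = {}
    order: list[str] = []
    for r in records:
        if r.chrom not in last:
            order.append(r.chrom)
        elif order[-1] != r.chrom:
            raise ValueError(f"records for {r.chrom} are not contiguous")
        if r.pos < last.get(r.chrom, 0):
            raise ValueError(f"records unsorted at {r.chrom}:{r.pos}")
        last[r.chrom] = r.pos


def proximity_filter(
    records: Sequence[VariantRecord], proximity_bp: int = 5
) -> tuple[list[VariantRecord], int]:
    """Drop SNPs closer than ``proximity_bp`` to any indel and indels closer
    than ``proximity_bp`` to another indel.

    Distance is ``|POS_a - POS_b|`` on the VCF anchor positions, strict
    ``< proximity_bp``.  Removal is evaluated against the full pre-filter
    record set, so an indel that a later rule removes still masks its
    neighbourhood.
    """
    _check_sorted(records)
    indel_pos: dict[str, list[int]] = {}
    for r in records:
        if r.variant_class == INDEL:
            indel_pos.setdefault(r.chrom, []).append(r.pos)
    kept: list[VariantRecord] = []
    n_removed = 0
    for r in records:
        positions = indel_pos.get(r.chrom, [])
        near = _min_distance(positions, r.pos, skip_self=r.variant_class == INDEL)
        if near is not None and near < proximity_bp:
            n_removed += 1
        else:
            kept.append(r)
    return kept, n_removed


def _min_distance(sorted_pos: list[int], pos: int, skip_self: bool) -> int | None:
    """Minimum |pos - p| over sorted positions, optionally ignoring one
    exact self-match (an indel is not 'close' to itself)."""
    if not sorted_pos:
        return None
    i = bisect.bisect_left(sorted_pos, pos)
    best: int | None = None
    skipped = not skip_self
    for j in (i - 1, i, i + 1):
        if 0 <= j < len(sorted_pos):
            d = abs(sorted_pos[j] - pos)
            if d == 0 and not skipped:
                skipped = True
                continue
            if best is None or d < best:
                best = d
    return best


def quality_ac_filter(
    records: Sequence[VariantRecord],
    min_site_qual: float = 30.0,
    min_allele_count: int = 2,
) -> tuple[list[VariantRecord], int, int]:
    """Remove records with site quality below ``min_site_qual`` or allele
    count below ``min_allele_count`` (both strict).  A missing quality fails
    the quality rule.  Returns (kept, n_removed_qual, n_removed_ac)."""
    kept: list[VariantRecord] = []
    n_qual = 0
    n_ac = 0
    for r in records:
        if r.qual is None or r.qual < min_site_qual:
            n_qual += 1
        elif r.effective_ac() < min_allele_count:
            n_ac += 1
        else:
            kept.append(r)
    return kept, n_qual, n_ac


def select_biallelic_autosomal_snps(
    records: Sequence[VariantRecord], layout: GenomeLayout
) -> tuple[list[VariantRecord], int]:
    """Keep bi-allelic SNPs on chromosomes flagged autosomal."""
    autosomes = {c.name for c in layout.autosomes()}
    kept = [
        r
        for r in records
        if r.is_biallelic and r.variant_class == SNP and r.chrom in autosomes
    ]
    return kept, len(records) - len(kept)


def apply_filter_chain(
    records: Sequence[VariantRecord],
    layout: GenomeLayout,
    mean_coverage: float,
    low_factor: float = 1.0 / 3.0,
    high_factor: float = 2.5,
    proximity_bp: int = 5,
    min_site_qual: float = 30.0,
    min_allele_count: int = 2,
) -> tuple[list[VariantRecord], FilterReport]:
    report = FilterReport(n_input=len(records))
    recs, report.n_genotypes_masked = mask_genotypes_by_depth(
        records, mean_coverage, low_factor, high_factor
    )
    recs, report.n_removed_proximity = proximity_filter(recs, proximity_bp)
    recs, report.n_removed_qual, report.n_removed_ac = quality_ac_filter(
        recs, min_site_qual, min_allele_count
    )
    recs, report.n_removed_class = select_biallelic_autosomal_snps(recs, layout)
    report.n_retained_final = len(recs)
    assert report.n_retained_final == report.n_input - (
        report.n_removed_proximity
        + report.n_removed_qual
        + report.n_removed_ac
        + report.n_removed_class
    )
    return recs, report
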