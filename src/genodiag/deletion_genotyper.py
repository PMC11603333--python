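"""Normalized read-depth genotyping of a candidate deletion.

Per-base depth over a scan window is divided by the mean depth over the
scan minus an exclusion window around the event, so the expected normalized
level is 1 outside the event and 0 / 0.5 inside for homozygous /
heterozygous deletion carriers.  Samples below a minimum raw coverage are
reported as low-confidence rather than genotyped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import yaml

from .io_formats import DepthTrack, Region, parse_region

HOM_DELETION = "hom_deletion"
HET_DELETION = "het_deletion"
NO_DELETION = "no_deletion"
LOW_CONFIDENCE = "low_confidence"


@dataclass(frozen=True)
class LocusSpec:
    """Scan window, exclusion window and putative event span (nested)."""

    scan_region: Region
    exclusion_region: Region
    event_region: Region

    def __post_init__(self) -> None:
        if not self.scan_region.contains(self.exclusion_region):
            raise ValueError("exclusion region must lie within the scan region")
        if not self.exclusion_region.contains(self.event_region):
            raise ValueError("event region must lie within the exclusion region")

    @classmethod
    def from_yaml(cls, path: str) -> "LocusSpec":
        data = yaml.safe_load(open(path))
        scan = parse_region(data["scan_region"])
        excl = parse_region(data["exclusion_region"])
        event = parse_region(data.get("event_region", data["exclusion_region"]))
        return cls(scan, excl, event)


@dataclass
class DeletionCall:
    sample: str
    raw_mean_depth: float
    normalized_event_coverage: float  # NaN when low-confidence
    genotype: str


def _mask_outside_exclusion(track: DepthTrack, locus: LocusSpec) -> np.ndarray:
    scan = locus.scan_region
    if track.region != scan:
        raise ValueError(
            f"track region {track.region} does not match scan region {scan}"
        )
    idx = np.arange(scan.start, scan.end + 1)
    excl = locus.exclusion_region
    return (idx < excl.start) | (idx > excl.end)


def normalize_coverage(
    track: DepthTrack, locus: LocusSpec
) -> tuple[np.ndarray, float]:
    """Divide every base by the mean depth over scan minus exclusion.

    Returns ``(normalized track, raw mean)``.  When the raw mean is zero no
    division is performed and the normalized track is all-NaN (the caller
    reports the sample as low-confidence).
    """
    outside = _mask_outside_exclusion(track, locus)
    raw_mean = float(np.mean(track.depth[outside]))
    if raw_mean <= 0:
        return np.full(track.region.length, np.nan), raw_mean
    return track.depth.astype(float) / raw_mean, raw_mean


def genotype_deletion(
    track: DepthTrack,
    locus: LocusSpec,
    sample: str = "",
    min_sample_coverage: float = 5.0,
    hom_max: float = 0.25,
    het_max: float = 0.75,
) -> DeletionCall:
    """Classify the event span from its mean normalized coverage ``m``:
    ``m < hom_max`` -> homozygous deletion, ``hom_max <= m <= het_max`` ->
    heterozygous, ``m > het_max`` -> no deletion.  Raw mean depth below
    ``min_sample_coverage`` yields a low-confidence call instead."""
    norm, raw_mean = normalize_coverage(track, locus)
    if raw_mean < min_sample_coverage:
        return DeletionCall(sample, raw_mean, math.nan, LOW_CONFIDENCE)
    ev = locus.event_region
    scan = locus.scan_region
    m = float(np.mean(norm[ev.start - scan.start : ev.end - scan.start + 1]))
    if m < hom_max:
        gt = HOM_DELETION
    elif m <= het_max:
        gt = HET_DELETION
    else:
        gt = NO_DELETION
    return DeletionCall(sample, raw_mean, m, gt)


@dataclass
class GroupSummary:
    group: str
    n_confident: int
    mean: float
    ci_low: float
    ci_high: float
    ci_degenerate: bool
    tallies: dict[str, int]

    def to_dict(self) -> dict:
        return {
            "group": self.group,
            "n_confident": self.n_confident,
            "mean": self.mean,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "ci_degenerate": self.ci_degenerate,
            "tallies": self.tallies,
        }


def cohort_summary(
    calls: Sequence[DeletionCall], groups: Mapping[str, str]
) -> dict[str, GroupSummary]:
    """Per-group mean normalized event coverage with a normal-approximation
    95% CI (mean +/- 1.96 * SD / sqrt(n)) over confident samples, plus
    genotype tallies.  A group with no confident sample is reported empty
    (NaN mean, zero-width CI)."""
    by_group: dict[str, list[DeletionCall]] = {}
    for c in calls:
        g = groups.get(c.sample, "ungrouped")
        by_group.setdefault(g, []).append(c)
    out: dict[str, GroupSummary] = {}
    for g in sorted(by_group):
        members = by_group[g]
        tallies = {k: 0 for k in (HOM_DELETION, HET_DELETION, NO_DELETION, LOW_CONFIDENCE)}
        for c in members:
            tallies[c.genotype] += 1
        confident = [c for c in members if c.genotype != LOW_CONFIDENCE]
        n = len(confident)
        if n == 0:
            out[g] = GroupSummary(g, 0, math.nan, math.nan, math.nan, True, tallies)
            continue
        vals = np.array([c.normalized_event_coverage for c in confident])
        mean = float(np.mean(vals))
        if n == 1:
            out[g] = GroupSummary(g, 1, mean, mean, mean, True, tallies)
            continue
        sd = float(np.std(vals, ddof=1))
        half = 1.96 * sd / math.sqrt(n)
        out[g] = GroupSummary(
            g, n, mean, mean - half, mean + half, sd == 0.0, tallies
        )
    return out
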