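"""Interval algebra on CNV calls.

Two operations carry the genomic logic of the analysis:

* :func:`merge_calls` — rejoin large calls that the HMM caller split.
  Within one (sample, chromosome, copy-number) group, two neighbouring
  calls both spanning more than ``min_call_bp`` are merged when the gap
  between them is smaller than ``max_gap_fraction`` of the span the
  merged call would have.  The scan repeats until a fixed point, so a
  deletion fragmented into three or more pieces is recovered too.

* :func:`select_locus_carriers` — a sample carries the target deletion
  when at least one of its (merged) deletion calls covers at least
  ``min_overlap_fraction`` of the target region.  The denominator is
  the region length, not a reciprocal overlap: the question is whether
  the region is spanned, however large the call.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from .model import CnvCall, TargetRegion


@dataclass(frozen=True)
class MergePolicy:
    """Split-call merging rule: both members of a candidate pair must
    span strictly more than ``min_call_bp``; the inter-call gap (bases
    strictly between the calls) must be strictly smaller than
    ``max_gap_fraction`` of the merged span."""

    min_call_bp: int = 100_000
    max_gap_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.min_call_bp <= 0:
            raise ValueError("min_call_bp must be positive")
        if not (0 < self.max_gap_fraction < 1):
            raise ValueError("max_gap_fraction must be in (0, 1)")


def _mergeable(a: CnvCall, b: CnvCall, policy: MergePolicy) -> bool:
    """Can sorted-adjacent calls a, b (a.start <= b.start) be joined?"""
    gap_bp = b.start - a.end - 1
    if gap_bp < 0:  # genuinely overlapping calls always coalesce
        return True
    if a.length_bp <= policy.min_call_bp or b.length_bp <= policy.min_call_bp:
        return False
    merged_length = max(a.end, b.end) - a.start + 1
    return gap_bp < policy.max_gap_fraction * merged_length


def _merge_pair(a: CnvCall, b: CnvCall) -> CnvCall:
    return replace(a, end=max(a.end, b.end), num_snps=a.num_snps + b.num_snps)


def merge_calls(calls: Iterable[CnvCall], policy: MergePolicy = MergePolicy()) -> list[CnvCall]:
    """Merge erroneously split calls; see module docstring for the rule.

    Calls are never merged across samples, chromosomes or copy-number
    states.  Within each group the result is sorted by start and
    pairwise non-overlapping; every base covered on input stays covered.
    The left-to-right scan is iterated to a fixed point.
    """
    groups: dict[tuple[str, str, int], list[CnvCall]] = {}
    order: list[tuple[str, str, int]] = []
    for c in calls:
        key = (c.sample_id, c.chrom, c.copy_number)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(c)

    out: list[CnvCall] = []
    for key in order:
        group = sorted(groups[key], key=lambda c: (c.start, c.end))
        changed = True
        while changed:
            changed = False
            merged: list[CnvCall] = []
            for c in group:
                if merged and _mergeable(merged[-1], c, policy):
                    merged[-1] = _merge_pair(merged[-1], c)
                    changed = True
                else:
                    merged.append(c)
            group = merged
        out.extend(group)
    return out


def overlap_fraction(call: CnvCall, region: TargetRegion) -> float:
    """Fraction of the target region covered by the call, in [0, 1].

    Both lengths use the 1-based inclusive convention; a call on a
    different chromosome contributes 0.
    """
    if call.chrom != region.chrom:
        return 0.0
    inter = min(call.end, region.end) - max(call.start, region.start) + 1
    if inter <= 0:
        return 0.0
    return inter / region.length_bp


@dataclass
class CarrierSet:
    """Samples qualifying as carriers of the target deletion, with the
    single best qualifying call and its overlap fraction per sample."""

    region: TargetRegion
    carriers: dict[str, CnvCall]
    overlap_fractions: dict[str, float]

    @property
    def sample_ids(self) -> set[str]:
        return set(self.carriers)

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self.carriers


def select_locus_carriers(
    calls: Sequence[CnvCall],
    region: TargetRegion,
    max_copy_number: int = 1,
) -> CarrierSet:
    """Identify carrier samples: those with at least one call of copy
    number <= ``max_copy_number`` (deletions, by default) covering at
    least ``region.min_overlap_fraction`` of the region.  Each sample is
    counted once; the qualifying call with the largest overlap is kept.
    Calls should already be merged.
    """
    carriers: dict[str, CnvCall] = {}
    fractions: dict[str, float] = {}
    for c in calls:
        if c.copy_number > max_copy_number:
            continue
        frac = overlap_fraction(c, region)
        if frac >= region.min_overlap_fraction and frac > fractions.get(c.sample_id, -1.0):
            carriers[c.sample_id] = c
            fractions[c.sample_id] = frac
    return CarrierSet(region=region, carriers=carriers, overlap_fractions=fractions)


def carriers_to_frame(carrier_set: CarrierSet, samples=None):
    """Tabulate a carrier set (sample_id, study, group, overlap_fraction)
    for export; study/group come from ``samples`` when given."""
    import pandas as pd

    by_id = {s.sample_id: s for s in samples} if samples is not None else {}
    rows = []
    for sid in sorted(carrier_set.carriers):
        s = by_id.get(sid)
        rows.append(
            {
                "sample_id": sid,
                "study": s.study if s else "",
                "group": s.group if s else "",
                "overlap_fraction": carrier_set.overlap_fractions[sid],
            }
        )
    return pd.DataFrame(rows, columns=["sample_id", "study", "group", "overlap_fraction"])
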