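"""Sample- and call-level quality control.

A sample is excluded when its array noise metrics exceed fixed
thresholds (LRR_SD > 0.30 or BAF_SD > 0.15) or when its CNV count lies
more than 3 standard deviations above the mean count of its own
(study, group) cell.  Inequalities are strict, and the cell mean/SD are
computed once on the pre-exclusion population (single pass, no
iteration).  Calls supported by fewer than 10 probes are dropped before
any interval work.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .model import CnvCall, SampleRecord


@dataclass(frozen=True)
class QcThresholds:
    """Exclusion thresholds; all strictly positive.

    ``cnv_count_sd_multiplier`` is the z-cutoff of the per-cell CNV-count
    rule; ``min_snps_per_cnv`` is the probe-support floor applied to
    calls, not samples.
    """

    max_lrr_sd: float = 0.30
    max_baf_sd: float = 0.15
    cnv_count_sd_multiplier: float = 3.0
    min_snps_per_cnv: int = 10

    def __post_init__(self) -> None:
        for name in ("max_lrr_sd", "max_baf_sd", "cnv_count_sd_multiplier", "min_snps_per_cnv"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass
class QcReport:
    """Outcome of sample QC: a partition of the input into kept and
    excluded ids, failing reasons, and the per-cell CNV-count statistics
    the count rule used."""

    kept: set[str]
    excluded: dict[str, list[str]]  # sample_id -> reasons (lrr_sd|baf_sd|cnv_count)
    group_stats: dict[tuple[str, str], tuple[float, float]]  # (study, group) -> (mean, sd)

    def to_frame(self) -> pd.DataFrame:
        """Audit table: one row per sample, kept flag and reasons."""
        rows = [{"sample_id": s, "status": "kept", "reasons": ""} for s in sorted(self.kept)]
        rows += [
            {"sample_id": s, "status": "excluded", "reasons": ";".join(r)}
            for s, r in sorted(self.excluded.items())
        ]
        return pd.DataFrame(rows, columns=["sample_id", "status", "reasons"])


def filter_calls_by_snps(
    calls: Iterable[CnvCall], thresholds: QcThresholds = QcThresholds()
) -> list[CnvCall]:
    """Keep only calls supported by at least ``min_snps_per_cnv`` probes
    (boundary inclusive); input order preserved."""
    return [c for c in calls if c.num_snps >= thresholds.min_snps_per_cnv]


def apply_sample_qc(
    samples: Sequence[SampleRecord],
    thresholds: QcThresholds = QcThresholds(),
    *,
    pool_studies: bool = False,
    group_stats: Mapping[tuple[str, str], tuple[float, float]] | None = None,
) -> QcReport:
    """Apply the three sample-level exclusion rules.

    CNV-count mean/SD are computed within each (study, group) cell over
    all samples in the cell before any exclusion (``pool_studies=True``
    pools across studies, keying cells by group alone).  SD is the
    sample standard deviation (n-1 denominator), defined as 0 for a
    single-sample cell.  Pass ``group_stats`` to reuse statistics frozen
    from an earlier pass instead of recomputing them.
    """
    if not samples:
        raise ValueError("apply_sample_qc requires a non-empty sample collection")

    def cell_of(s: SampleRecord) -> tuple[str, str]:
        return ("*", s.group) if pool_studies else (s.study, s.group)

    if group_stats is None:
        counts: dict[tuple[str, str], list[int]] = {}
        for s in samples:
            counts.setdefault(cell_of(s), []).append(s.cnv_count)
        stats = {
            cell: (
                statistics.fmean(v),
                statistics.stdev(v) if len(v) > 1 else 0.0,
            )
            for cell, v in counts.items()
        }
    else:
        stats = dict(group_stats)

    kept: set[str] = set()
    excluded: dict[str, list[str]] = {}
    for s in samples:
        reasons = []
        if s.lrr_sd > thresholds.max_lrr_sd:
            reasons.append("lrr_sd")
        if s.baf_sd > thresholds.max_baf_sd:
            reasons.append("baf_sd")
        mean, sd = stats[cell_of(s)]
        if s.cnv_count > mean + thresholds.cnv_count_sd_multiplier * sd:
            reasons.append("cnv_count")
        if reasons:
            excluded[s.sample_id] = reasons
        else:
            kept.add(s.sample_id)
    return QcReport(kept=kept, excluded=excluded, group_stats=stats)
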