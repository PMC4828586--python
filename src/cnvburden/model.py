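"""Core domain types for locus-specific rare-CNV burden analysis.

Coordinates are 1-based inclusive throughout (the PennCNV convention);
conversion to BED's 0-based half-open system happens only at the I/O
boundary.  Chromosome labels are normalized by stripping an optional
``chr`` prefix and lower-casing, so ``chr22``, ``Chr22`` and ``22``
compare equal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


def normalize_chrom(chrom: str) -> str:
    """Strip an optional ``chr`` prefix, case-insensitively."""
    c = str(chrom).strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    return c.lower()


@dataclass(frozen=True)
class CnvCall:
    """One copy-number variant call on one sample.

    Attributes
    ----------
    sample_id : str
        Opaque sample identifier.
    chrom : str
        Chromosome label, normalized (no ``chr`` prefix).
    start, end : int
        1-based inclusive base positions, ``end >= start``.
    copy_number : int
        Integer copy number (0 or 1 = deletion, 3+ = duplication).
    num_snps : int
        Number of array probes supporting the call.
    """

    sample_id: str
    chrom: str
    start: int
    end: int
    copy_number: int
    num_snps: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if self.end < self.start:
            raise ValueError(
                f"CnvCall end < start ({self.end} < {self.start}) for sample "
                f"{self.sample_id!r}"
            )
        if self.num_snps < 1:
            raise ValueError(f"CnvCall num_snps must be >= 1, got {self.num_snps}")
        if self.copy_number < 0:
            raise ValueError(f"CnvCall copy_number must be >= 0, got {self.copy_number}")

    @property
    def length_bp(self) -> int:
        """Span in bases, inclusive of both endpoints."""
        return self.end - self.start + 1


#: sentinel for an absent age at onset
MISSING_ONSET = None


@dataclass(frozen=True)
class SampleRecord:
    """One participant: stratum label, phenotype group, onset age, QC metrics.

    ``onset_age`` is ``None`` when unknown (controls, or cases without
    onset records).  ``lrr_sd`` / ``baf_sd`` are the per-sample noise
    metrics of the array intensity channels; ``cnv_count`` is the number
    of autosomal CNV calls made on the sample.
    """

    sample_id: str
    study: str
    group: str  # "case" | "control"
    onset_age: float | None
    lrr_sd: float
    baf_sd: float
    cnv_count: int

    def __post_init__(self) -> None:
        g = self.group.strip().lower()
        if g not in ("case", "control"):
            raise ValueError(f"group must be 'case' or 'control', got {self.group!r}")
        object.__setattr__(self, "group", g)
        if self.onset_age is not None:
            a = float(self.onset_age)
            if math.isnan(a):
                object.__setattr__(self, "onset_age", None)
            elif a < 0:
                raise ValueError(f"onset_age must be nonnegative, got {a}")
            else:
                object.__setattr__(self, "onset_age", a)
        if self.lrr_sd < 0 or self.baf_sd < 0:
            raise ValueError("lrr_sd and baf_sd must be nonnegative")
        if self.cnv_count < 0:
            raise ValueError("cnv_count must be nonnegative")

    @property
    def is_case(self) -> bool:
        return self.group == "case"


@dataclass(frozen=True)
class TargetRegion:
    """Genomic interval defining a deletion locus, plus the minimum
    fraction of it a call must span to qualify a sample as a carrier.

    Defaults describe the proximal 22q11.2 region between low-copy
    repeats A and B (hg19), the 1.5 Mb interval nested inside the common
    3 Mb A-D deletion.
    """

    chrom: str = "22"
    start: int = 18_900_000
    end: int = 20_400_000
    build_label: str = "hg19"
    min_overlap_fraction: float = 0.60

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if self.end <= self.start:
            raise ValueError("TargetRegion requires end > start")
        if not (0 < self.min_overlap_fraction <= 1):
            raise ValueError("min_overlap_fraction must be in (0, 1]")

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1


#: the common ~3 Mb deletion between low-copy repeats A and D (hg19)
REGION_3MB = TargetRegion(chrom="22", start=18_800_000, end=21_800_000)
#: the nested ~1.5 Mb A-B region used for carrier selection
REGION_1_5MB = TargetRegion(chrom="22", start=18_900_000, end=20_400_000)
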