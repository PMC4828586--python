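"""Synthetic cohort and CNV-call generation.

Emulates the statistical structure the analysis consumes: several
case-control studies, a rare recurrent deletion planted at a target
locus at configurable per-group frequencies, split-call artifacts that
only merging can repair, QC-failing samples, benign background CNVs
away from the locus, and onset ages drawn from group-specific truncated
normals (carriers younger than non-carriers).  All randomness flows
from a single seed; identical configurations yield byte-identical
fixture files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from . import io as cio
from .model import CnvCall, SampleRecord, TargetRegion, REGION_1_5MB
from .segments import MergePolicy, overlap_fraction

# hg19 autosome lengths, for placing background calls
_CHROM_LEN = {
    "1": 249_250_621, "2": 243_199_373, "3": 198_022_430, "4": 191_154_276,
    "5": 180_915_260, "6": 171_115_067, "7": 159_138_663, "8": 146_364_022,
    "9": 141_213_431, "10": 135_534_747, "11": 135_006_516, "12": 133_851_895,
    "13": 115_169_878, "14": 107_349_540, "15": 102_531_392, "16": 90_354_753,
    "17": 81_195_210, "18": 78_077_248, "19": 59_128_983, "20": 63_025_520,
    "21": 48_129_895, "22": 51_304_566,
}

#: the four studies of the combined screen, (label, n_cases, n_controls)
DEFAULT_STUDIES: tuple[tuple[str, int, int], ...] = (
    ("US_NIA", 593, 726),
    ("UK_WTCCC2", 1592, 4939),
    ("Dutch", 740, 1996),
    ("IPDGC_NeuroX", 6462, 6202),
)


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings.

    Defaults mirror the combined screen's conditions: the four study
    sizes, a case carrier frequency of 8/9387 with zero control
    carriers, onset ~ Normal(42.1, 11.9) years for carriers and
    Normal(60.3, 12.8) for non-carriers truncated to (18, 95), and 10%
    of cases lacking onset records.  The planted deletion spans the
    common ~3 Mb interval; split fragments are constructed so neither
    piece alone reaches the carrier-selection overlap threshold while
    the merged call does.
    """

    studies: tuple[tuple[str, int, int], ...] = DEFAULT_STUDIES
    locus: TargetRegion = REGION_1_5MB
    planted_span: tuple[int, int] = (18_800_000, 21_800_000)
    carrier_freq_cases: float = 8 / 9387
    carrier_freq_controls: float = 0.0
    onset_mean_carrier: float = 42.1
    onset_sd_carrier: float = 11.9
    onset_mean_noncarrier: float = 60.3
    onset_sd_noncarrier: float = 12.8
    onset_bounds: tuple[float, float] = (18.0, 95.0)
    onset_missing_rate: float = 0.10
    split_call_rate: float = 0.0
    qc_fail_rates: dict[str, float] = field(
        default_factory=lambda: {"lrr_sd": 0.02, "baf_sd": 0.01, "cnv_count": 0.005}
    )
    background_cnv_rate: float = 5.0
    merge_policy: MergePolicy = MergePolicy()
    seed: int = 0

    def __post_init__(self) -> None:
        for f in (self.carrier_freq_cases, self.carrier_freq_controls,
                  self.onset_missing_rate, self.split_call_rate):
            if not (0 <= f <= 1):
                raise ValueError("rates and frequencies must be in [0, 1]")
        if self.onset_sd_carrier <= 0 or self.onset_sd_noncarrier <= 0:
            raise ValueError("onset SDs must be positive")
        for _, n_cases, n_controls in self.studies:
            if n_cases <= 0 or n_controls <= 0:
                raise ValueError("study sizes must be positive")
        if not (self.planted_span[0] < self.locus.start
                and self.planted_span[1] > self.locus.end):
            raise ValueError("planted_span must strictly contain the locus region")


@dataclass
class SynthTruth:
    """Ground truth of a generated cohort, for oracle-style tests."""

    planted_carriers: set[str]
    planted_fragments: dict[str, list[tuple[int, int]]]
    qc_planted_failures: set[str]

    def to_json(self) -> str:
        return json.dumps(
            {
                "planted_carriers": sorted(self.planted_carriers),
                "fragments": {k: v for k, v in sorted(self.planted_fragments.items())},
                "qc_failures": sorted(self.qc_planted_failures),
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "SynthTruth":
        d = json.loads(text)
        return cls(
            planted_carriers=set(d["planted_carriers"]),
            planted_fragments={k: [tuple(p) for p in v] for k, v in d["fragments"].items()},
            qc_planted_failures=set(d["qc_failures"]),
        )


def split_fragments(config: SynthConfig) -> tuple[tuple[int, int], tuple[int, int]]:
    """Deterministic two-fragment geometry for a split planted deletion.

    Each fragment covers less than the carrier-selection threshold of
    the locus, both spans exceed the merge policy's size gate, and the
    gap satisfies the merge rule — so the carrier is recoverable only
    after merging.  Raises if the configuration admits no such geometry.
    """
    region = config.locus
    del_start, del_end = config.planted_span
    f, L = region.min_overlap_fraction, region.length_bp
    # left fragment covers ~half the allowed overlap; right covers ~0.55 of it
    q1 = region.start + int(0.50 * f * L) - 1
    q2 = region.end - int(0.55 * f * L) + 1
    left, right = (del_start, q1), (q2, del_end)
    gap = q2 - q1 - 1
    merged_length = del_end - del_start + 1
    policy = config.merge_policy
    ok = (
        q2 > q1 + 1
        and (q1 - del_start + 1) > policy.min_call_bp
        and (del_end - q2 + 1) > policy.min_call_bp
        and gap < policy.max_gap_fraction * merged_length
    )
    if ok:
        probe = CnvCall("_", region.chrom, left[0], left[1], 1, 10)
        ok = overlap_fraction(probe, region) < f and overlap_fraction(
            replace(probe, start=right[0], end=right[1]), region
        ) < f
    if not ok:
        raise ValueError("split fragments cannot satisfy the merge and overlap rules "
                         "for this locus/span/policy combination")
    return left, right


def generate_cohort(
    config: SynthConfig,
) -> tuple[list[SampleRecord], list[CnvCall], SynthTruth]:
    """Generate samples, calls and ground truth; deterministic per seed."""
    rng = np.random.default_rng(config.seed)
    lo, hi = config.onset_bounds
    frag_geometry = split_fragments(config) if config.split_call_rate > 0 else None

    samples: list[SampleRecord] = []
    calls: list[CnvCall] = []
    truth = SynthTruth(set(), {}, set())
    autosomes = list(_CHROM_LEN)

    def onset_draws(carrier: bool, size: int) -> np.ndarray:
        mu, sd = (
            (config.onset_mean_carrier, config.onset_sd_carrier)
            if carrier
            else (config.onset_mean_noncarrier, config.onset_sd_noncarrier)
        )
        a, b = (lo - mu) / sd, (hi - mu) / sd
        return stats.truncnorm.rvs(a, b, loc=mu, scale=sd, size=size, random_state=rng)

    def background_call(sid: str) -> CnvCall:
        while True:
            chrom = autosomes[rng.integers(len(autosomes))]
            length = int(rng.integers(25_000, 250_000))
            start = int(rng.integers(1, _CHROM_LEN[chrom] - length))
            cn = int(rng.choice([0, 1, 3, 4], p=[0.05, 0.45, 0.45, 0.05]))
            call = CnvCall(sid, chrom, start, start + length - 1, cn, max(10, length // 2500))
            if overlap_fraction(call, config.locus) == 0.0:
                return call

    for study, n_cases, n_controls in config.studies:
        for group, n in (("case", n_cases), ("control", n_controls)):
            freq = config.carrier_freq_cases if group == "case" else config.carrier_freq_controls
            is_carrier = rng.random(n) < freq
            n_bg = rng.poisson(config.background_cnv_rate, size=n)
            lrr = rng.uniform(0.05, 0.28, size=n)
            baf = rng.uniform(0.02, 0.14, size=n)
            fail_lrr = rng.random(n) < config.qc_fail_rates.get("lrr_sd", 0.0)
            fail_baf = rng.random(n) < config.qc_fail_rates.get("baf_sd", 0.0)
            fail_cnt = rng.random(n) < config.qc_fail_rates.get("cnv_count", 0.0)
            split = rng.random(n) < config.split_call_rate
            missing = rng.random(n) < config.onset_missing_rate
            onset_if_carrier = onset_draws(True, n)
            onset_if_not = onset_draws(False, n)

            for i in range(n):
                sid = f"{study}_{group}_{i:05d}"
                carrier = bool(is_carrier[i])
                n_calls = int(n_bg[i])
                for _ in range(n_calls):
                    calls.append(background_call(sid))
                if carrier:
                    truth.planted_carriers.add(sid)
                    snps = int(rng.integers(400, 700))
                    if split[i]:
                        (ls, le), (rs, re) = frag_geometry
                        frags = [(ls, le), (rs, re)]
                        truth.planted_fragments[sid] = frags
                        half = max(10, snps // 2)
                        calls.append(CnvCall(sid, config.locus.chrom, ls, le, 1, half))
                        calls.append(CnvCall(sid, config.locus.chrom, rs, re, 1, snps - half))
                        n_calls += 2
                    else:
                        calls.append(
                            CnvCall(sid, config.locus.chrom, *config.planted_span, 1, snps)
                        )
                        n_calls += 1

                lrr_sd = float(rng.uniform(0.31, 0.50)) if fail_lrr[i] else float(lrr[i])
                baf_sd = float(rng.uniform(0.16, 0.30)) if fail_baf[i] else float(baf[i])
                cnv_count = n_calls + (50 if fail_cnt[i] else 0)
                if fail_lrr[i] or fail_baf[i] or fail_cnt[i]:
                    truth.qc_planted_failures.add(sid)

                onset = None
                if group == "case" and not missing[i]:
                    onset = round(float(onset_if_carrier[i] if carrier else onset_if_not[i]), 1)
                samples.append(
                    SampleRecord(
                        sample_id=sid,
                        study=study,
                        group=group,
                        onset_age=onset,
                        lrr_sd=round(lrr_sd, 4),
                        baf_sd=round(baf_sd, 4),
                        cnv_count=cnv_count,
                    )
                )
    return samples, calls, truth


def write_fixture(
    out_dir: str | Path,
    samples: Sequence[SampleRecord],
    calls: Sequence[CnvCall],
    truth: SynthTruth,
) -> dict[str, Path]:
    """Write rawcnv + cohort TSV + truth JSON under ``out_dir``; the
    files read back (via :mod:`cnvburden.io`) equal the in-memory
    objects, and a fixed seed yields byte-identical files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "rawcnv": out / "calls.rawcnv",
        "cohort": out / "cohort.tsv",
        "truth": out / "truth.json",
    }
    cio.write_rawcnv(calls, paths["rawcnv"])
    cio.write_cohort(samples, paths["cohort"])
    paths["truth"].write_text(truth.to_json() + "\n", encoding="utf-8")
    return paths
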