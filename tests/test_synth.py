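"""Synthetic cohort generator: determinism, planted-truth geometry,
statistical recovery of the configured onset model and carrier rates."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats as sps

from cnvburden import (
    SynthConfig,
    SynthTruth,
    TargetRegion,
    generate_cohort,
    merge_calls,
    overlap_fraction,
    read_cohort,
    read_rawcnv,
    select_locus_carriers,
    split_fragments,
    write_fixture,
)

SMALL = SynthConfig(
    studies=(("A", 150, 200), ("B", 100, 120)),
    carrier_freq_cases=0.05,
    carrier_freq_controls=0.0,
    background_cnv_rate=2.0,
    seed=7,
)


def _bytes_of(dirpath):
    return {p.name: p.read_bytes() for p in sorted(dirpath.iterdir())}


def test_fixture_files_are_byte_deterministic(tmp_path):
    a, b = tmp_path / "a", tmp_path / "b"
    write_fixture(a, *generate_cohort(SMALL))
    write_fixture(b, *generate_cohort(SMALL))
    assert _bytes_of(a) == _bytes_of(b)
    import dataclasses

    other = dataclasses.replace(SMALL, seed=8)
    c = tmp_path / "c"
    write_fixture(c, *generate_cohort(other))
    assert _bytes_of(a) != _bytes_of(c)


def test_fixture_round_trips_through_readers(tmp_path):
    samples, calls, truth = generate_cohort(SMALL)
    paths = write_fixture(tmp_path, samples, calls, truth)
    assert read_rawcnv(paths["rawcnv"]) == calls
    assert read_cohort(paths["cohort"]) == samples
    assert SynthTruth.from_json(paths["truth"].read_text()) == truth


def test_empty_cohort_not_representable_but_zero_freq_is():
    import dataclasses

    cfg = dataclasses.replace(SMALL, carrier_freq_cases=0.0)
    _, _, truth = generate_cohort(cfg)
    assert truth.planted_carriers == set()


def test_split_fragments_geometry():
    """With splitting forced on, no single fragment qualifies a carrier,
    but the merged call does — merging is load-bearing by construction."""
    import dataclasses

    cfg = dataclasses.replace(SMALL, split_call_rate=1.0)
    samples, calls, truth = generate_cohort(cfg)
    assert truth.planted_carriers and set(truth.planted_fragments) == truth.planted_carriers
    region = cfg.locus
    premerge = select_locus_carriers(calls, region)
    assert premerge.sample_ids == set()  # every fragment is below threshold
    for sid, frags in truth.planted_fragments.items():
        for start, end in frags:
            probe = next(
                c for c in calls if c.sample_id == sid and (c.start, c.end) == (start, end)
            )
            assert overlap_fraction(probe, region) < region.min_overlap_fraction
    merged = merge_calls(calls, cfg.merge_policy)
    assert select_locus_carriers(merged, region).sample_ids == truth.planted_carriers


def test_impossible_split_geometry_raises():
    # the left fragment would need to stay under 5% locus overlap yet
    # span >100 kb: impossible when the span barely exceeds the region
    region = TargetRegion(chrom="22", start=20_000_000, end=20_200_000,
                          min_overlap_fraction=0.05)
    cfg = SynthConfig(
        studies=(("A", 10, 10),),
        locus=region,
        planted_span=(19_990_000, 20_210_000),
        split_call_rate=1.0,
        carrier_freq_cases=1.0,
    )
    with pytest.raises(ValueError, match="split fragments"):
        split_fragments(cfg)


def test_background_calls_avoid_the_locus():
    samples, calls, truth = generate_cohort(SMALL)
    for c in calls:
        if c.sample_id not in truth.planted_carriers:
            assert overlap_fraction(c, SMALL.locus) == 0.0


def test_qc_failures_exceed_thresholds():
    import dataclasses

    # low rates: the cnv-count rule is relative to its own cell, so
    # planted count outliers only stand out when failures are rare
    cfg = dataclasses.replace(
        SMALL, qc_fail_rates={"lrr_sd": 0.05, "baf_sd": 0.05, "cnv_count": 0.03}, seed=11
    )
    samples, _, truth = generate_cohort(cfg)
    assert truth.qc_planted_failures
    by_id = {s.sample_id: s for s in samples}
    from cnvburden import apply_sample_qc

    rep = apply_sample_qc(samples)
    # every planted failure is caught by at least one rule
    assert truth.qc_planted_failures <= set(rep.excluded)


def test_carrier_count_within_binomial_interval_across_seeds():
    """Planted-carrier totals across seeds behave like Binomial(n, f):
    the count lies in the central 99% interval in almost every run."""
    studies = (("US_NIA", 593, 726), ("UK_WTCCC2", 1592, 4939),
               ("Dutch", 740, 1996), ("IPDGC_NeuroX", 6462, 6202))
    n_cases = sum(s[1] for s in studies)
    f = 8 / 9387
    lo, hi = sps.binom.ppf([0.005, 0.995], n_cases, f)
    inside = 0
    n_seeds = 200
    for seed in range(n_seeds):
        cfg = SynthConfig(studies=studies, background_cnv_rate=0.0,
                          onset_missing_rate=0.0, qc_fail_rates={}, seed=seed)
        _, _, truth = generate_cohort(cfg)
        inside += lo <= len(truth.planted_carriers) <= hi
    # P(inside) >= 0.99 per seed; 188 allows ~6-sigma slack at n=200
    assert inside >= 188


def test_onset_model_recovery():
    """Group onset means from a large synthetic cohort sit within 3
    standard errors of the configured truncated-normal means."""
    cfg = SynthConfig(
        studies=(("BIG", 6000, 10),),
        carrier_freq_cases=0.25,
        onset_missing_rate=0.0,
        background_cnv_rate=0.0,
        qc_fail_rates={},
        seed=13,
    )
    samples, _, truth = generate_cohort(cfg)
    carrier_onsets = [s.onset_age for s in samples if s.sample_id in truth.planted_carriers
                      and s.onset_age is not None]
    other_onsets = [s.onset_age for s in samples if s.is_case
                    and s.sample_id not in truth.planted_carriers and s.onset_age is not None]
    lo, hi = cfg.onset_bounds
    for onsets, mu, sd in (
        (carrier_onsets, cfg.onset_mean_carrier, cfg.onset_sd_carrier),
        (other_onsets, cfg.onset_mean_noncarrier, cfg.onset_sd_noncarrier),
    ):
        a, b = (lo - mu) / sd, (hi - mu) / sd
        true_mean = sps.truncnorm.mean(a, b, loc=mu, scale=sd)
        true_sd = sps.truncnorm.std(a, b, loc=mu, scale=sd)
        se = true_sd / np.sqrt(len(onsets))
        assert abs(np.mean(onsets) - true_mean) < 3 * se
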