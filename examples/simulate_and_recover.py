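"""Generate a synthetic cohort with planted deletions and recover them
with the full pipeline (QC -> merge -> carrier selection -> association).

Half of the planted deletions are emitted as two sub-threshold fragments
that only the merge step can reassemble, so perfect recovery exercises
every stage.
"""

from cnvburden import QcThresholds, RunConfig, SynthConfig, generate_cohort, run_pipeline

config = SynthConfig(
    studies=(("StudyA", 800, 1000), ("StudyB", 600, 700)),
    carrier_freq_cases=0.01,
    carrier_freq_controls=0.0,
    split_call_rate=0.5,
    background_cnv_rate=3.0,
    qc_fail_rates={},
    seed=42,
)
samples, calls, truth = generate_cohort(config)
print(f"cohort: {len(samples)} samples, {len(calls)} CNV calls, "
      f"{len(truth.planted_carriers)} planted carriers "
      f"({len(truth.planted_fragments)} split into fragments)")

report = run_pipeline(
    RunConfig(synth=config, qc=QcThresholds(cnv_count_sd_multiplier=50))
)
recovered = set(report.carrier_ids)
print(f"recovered carriers: {len(recovered)} "
      f"(sensitivity {len(recovered & truth.planted_carriers) / len(truth.planted_carriers):.0%}, "
      f"false positives {len(recovered - truth.planted_carriers)})")
print(f"stratified exact test on the recovered carriers: "
      f"p = {report.overall.meta.p_two_sided:.2g} "
      f"({report.n_cases} cases vs {report.n_controls} controls)")
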