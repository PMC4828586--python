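"""End-to-end orchestration: QC -> merge -> carrier selection ->
association -> report.

Two entry modes:

* :func:`run_pipeline` consumes call-level inputs (rawcnv + cohort
  table, or a synthetic-cohort block) and runs every stage in fixed
  order, logging every exclusion.
* :func:`run_from_counts` consumes pre-tabulated per-stratum carrier
  tables (e.g. published counts) and runs only the association layer —
  the same statistics, bypassing the CNV stages.

Reports serialise to JSON and markdown; provenance records the config
hash, seed and package version so a rerun with the same configuration
is bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Mapping, Sequence

import yaml

from . import __version__ as _pkg_version
from . import io as cio
from .assoc import (
    CarrierTable,
    LooSensitivity,
    OnsetPolicy,
    PopulationPrior,
    StratifiedResult,
    exact_cmh,
    fisher_exact_2x2,
    fold_vs_population,
    loo_sensitivity,
    onset_stratify,
    population_binomial_test,
    population_expected_count,
)
from .model import SampleRecord, TargetRegion
from .qc import QcThresholds, apply_sample_qc, filter_calls_by_snps
from .segments import CarrierSet, MergePolicy, merge_calls, select_locus_carriers
from .synth import SynthConfig, generate_cohort


@dataclass
class RunConfig:
    """One pipeline run: exactly one of (rawcnv+cohort paths) or a
    synthetic-cohort block; regions (first = primary locus); policies;
    analysis toggles."""

    rawcnv_path: str | None = None
    cohort_path: str | None = None
    synth: SynthConfig | None = None
    regions: Sequence[TargetRegion] = field(default_factory=lambda: [TargetRegion()])
    qc: QcThresholds = field(default_factory=QcThresholds)
    merge: MergePolicy = field(default_factory=MergePolicy)
    onset: OnsetPolicy = field(default_factory=OnsetPolicy)
    prior: PopulationPrior = field(default_factory=PopulationPrior)
    study_of_stratum: Mapping[str, str] | None = None
    analyses: dict[str, bool] = field(
        default_factory=lambda: {
            "overall": True,
            "onset_stratified": True,
            "sensitivity": True,
            "population_comparison": True,
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        has_paths = self.rawcnv_path is not None and self.cohort_path is not None
        if has_paths == (self.synth is not None):
            raise ValueError("provide exactly one of input paths or a synth block")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "rt", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any]) -> "RunConfig":
        kw: dict[str, Any] = {}
        inputs = raw.get("inputs", {})
        kw["rawcnv_path"] = inputs.get("rawcnv")
        kw["cohort_path"] = inputs.get("cohort")
        if "synth" in raw:
            sy = dict(raw["synth"])
            if "studies" in sy:
                sy["studies"] = tuple(tuple(s) for s in sy["studies"])
            if "locus" in sy:
                sy["locus"] = TargetRegion(**sy["locus"])
            if "planted_span" in sy:
                sy["planted_span"] = tuple(sy["planted_span"])
            if "merge_policy" in sy:
                sy["merge_policy"] = MergePolicy(**sy["merge_policy"])
            kw["synth"] = SynthConfig(**sy)
        if "regions" in raw:
            kw["regions"] = [TargetRegion(**r) for r in raw["regions"]]
        for name, typ in (("qc", QcThresholds), ("merge", MergePolicy),
                          ("onset", OnsetPolicy), ("prior", PopulationPrior)):
            if name in raw:
                kw[name] = typ(**raw[name])
        for name in ("analyses", "seed", "study_of_stratum"):
            if name in raw:
                kw[name] = raw[name]
        return cls(**kw)

    def config_hash(self) -> str:
        def default(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            if isinstance(o, (set, tuple)):
                return sorted(o) if isinstance(o, set) else list(o)
            return str(o)

        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=default)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class AssociationBlock:
    """Per-stratum Fisher tests plus the stratified meta-analysis."""

    strata: list[CarrierTable]
    fisher_two_sided: dict[str, float]
    fisher_one_sided: dict[str, float]
    meta: StratifiedResult


@dataclass
class RunReport:
    """Everything one run computed, plus provenance."""

    overall: AssociationBlock | None = None
    onset_early_vs_control: AssociationBlock | None = None
    onset_late_vs_control: AssociationBlock | None = None
    onset_early_vs_late: AssociationBlock | None = None
    sensitivity: LooSensitivity | None = None
    population: dict[str, float] | None = None
    carrier_ids: list[str] = field(default_factory=list)
    n_cases: int = 0
    n_controls: int = 0
    excluded_samples: dict[str, list[str]] = field(default_factory=dict)
    provenance: dict[str, Any] = field(default_factory=dict)

    def to_json(self) -> str:
        def default(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            if isinstance(o, set):
                return sorted(o)
            if isinstance(o, Mapping):
                return dict(o)
            return str(o)

        d = dataclasses.asdict(self)
        # null_pmf integer keys -> strings for JSON
        return json.dumps(d, sort_keys=True, default=default, indent=1)

    def to_markdown(self) -> str:
        lines = ["# Association report", ""]
        for title, block in (
            ("Overall (cases vs controls)", self.overall),
            ("Early-onset vs controls", self.onset_early_vs_control),
            ("Late-onset vs controls", self.onset_late_vs_control),
            ("Early- vs late-onset", self.onset_early_vs_late),
        ):
            if block is None:
                continue
            lines += [f"## {title}", "",
                      "| stratum | n1 | carriers1 | n2 | carriers2 | Fisher p (2s) |",
                      "|---|---|---|---|---|---|"]
            for t in block.strata:
                lines.append(
                    f"| {t.stratum} | {t.n1} | {t.a} | {t.n2} | {t.c} | "
                    f"{block.fisher_two_sided[t.stratum]:.3g} |"
                )
            lines += ["",
                      f"Stratified exact test: two-sided p = {block.meta.p_two_sided:.3g}, "
                      f"one-sided p = {block.meta.p_one_sided:.3g} "
                      f"(observed carriers = {block.meta.s_observed})", ""]
        if self.sensitivity is not None:
            lines += ["## Leave-one-study-out sensitivity", ""]
            for study, res in sorted(self.sensitivity.results.items()):
                lines.append(f"- excluding {study}: two-sided p = {res.p_two_sided:.3g}")
            lines += [f"- maximum p = {self.sensitivity.max_p_two_sided:.3g}", ""]
        if self.population is not None:
            lines += ["## Population-frequency comparison", ""]
            for k, v in self.population.items():
                lines.append(f"- {k}: {v:.4g}")
            lines.append("")
        return "\n".join(lines)


def _association_block(strata: Sequence[CarrierTable]) -> AssociationBlock:
    return AssociationBlock(
        strata=list(strata),
        fisher_two_sided={t.stratum: fisher_exact_2x2(t, "two_sided_minlike") for t in strata},
        fisher_one_sided={t.stratum: fisher_exact_2x2(t, "one_greater") for t in strata},
        meta=exact_cmh(strata),
    )


def build_carrier_tables(
    samples: Sequence[SampleRecord], carriers: CarrierSet | Sequence[str]
) -> list[CarrierTable]:
    """Per-study cases-vs-controls tables from sample records and a
    carrier set."""
    carrier_ids = set(getattr(carriers, "sample_ids", carriers))
    cells: dict[str, dict[str, list[int]]] = {}
    for s in samples:
        cell = cells.setdefault(s.study, {"case": [0, 0], "control": [0, 0]})
        cell[s.group][0] += 1 if s.sample_id in carrier_ids else 0
        cell[s.group][1] += 1
    tables = []
    for study in sorted(cells):
        ca, ctrl = cells[study]["case"], cells[study]["control"]
        if ca[1] > 0 and ctrl[1] > 0:
            tables.append(CarrierTable(study, ca[0], ca[1] - ca[0], ctrl[0], ctrl[1] - ctrl[0]))
    return tables


def run_from_counts(
    overall: Sequence[CarrierTable],
    *,
    early_vs_control: Sequence[CarrierTable] | None = None,
    late_vs_control: Sequence[CarrierTable] | None = None,
    early_vs_late: Sequence[CarrierTable] | None = None,
    study_of_stratum: Mapping[str, str] | None = None,
    sensitivity_strata: Sequence[CarrierTable] | None = None,
    prior: PopulationPrior = PopulationPrior(),
) -> RunReport:
    """Counts-only analysis: association layer over pre-tabulated
    tables.  ``sensitivity_strata`` (default: ``overall``) defines the
    stratification used inside the leave-one-study-out analysis."""
    report = RunReport()
    report.overall = _association_block(overall)
    report.n_cases = sum(t.n1 for t in overall)
    report.n_controls = sum(t.n2 for t in overall)
    for name, strata in (
        ("onset_early_vs_control", early_vs_control),
        ("onset_late_vs_control", late_vs_control),
        ("onset_early_vs_late", early_vs_late),
    ):
        if strata:
            setattr(report, name, _association_block(strata))
    sens_base = sensitivity_strata if sensitivity_strata is not None else overall
    try:
        report.sensitivity = loo_sensitivity(list(sens_base), study_of_stratum)
    except ValueError:
        report.sensitivity = None  # fewer than two studies
    x_cases = sum(t.a for t in overall)
    pop: dict[str, float] = {
        "expected_control_carriers": population_expected_count(report.n_controls, prior),
        "binomial_p_cases_vs_population": population_binomial_test(
            x_cases, report.n_cases, prior
        ),
    }
    if x_cases >= 1:
        pop["fold_cases_vs_population"] = fold_vs_population(x_cases, report.n_cases, prior)
    if early_vs_control:
        x_e = sum(t.a for t in early_vs_control)
        n_e = sum(t.n1 for t in early_vs_control)
        pop["binomial_p_early_vs_population"] = population_binomial_test(x_e, n_e, prior)
        if x_e >= 1:
            pop["fold_early_vs_population"] = fold_vs_population(x_e, n_e, prior)
    report.population = pop
    report.provenance = {"mode": "counts", "version": _pkg_version}
    return report


def run_pipeline(config: RunConfig) -> RunReport:
    """Run all stages in fixed order on call-level input.

    Stages: probe-support filter -> sample QC -> split-call merging ->
    carrier selection at the primary region -> per-study and stratified
    association -> onset stratification -> sensitivity -> population
    comparison.  Raises if QC leaves an empty cohort.
    """
    if config.synth is not None:
        samples, calls, _truth = generate_cohort(config.synth)
    else:
        calls = cio.read_rawcnv(config.rawcnv_path)
        samples = cio.read_cohort(config.cohort_path)

    calls = filter_calls_by_snps(calls, config.qc)
    qc_report = apply_sample_qc(samples, config.qc)
    kept_samples = [s for s in samples if s.sample_id in qc_report.kept]
    if not kept_samples:
        raise RuntimeError("sample QC excluded the whole cohort")
    calls = [c for c in calls if c.sample_id in qc_report.kept]

    merged = merge_calls(calls, config.merge)
    primary = config.regions[0]
    carrier_set = select_locus_carriers(merged, primary)

    report = RunReport()
    report.excluded_samples = qc_report.excluded
    report.carrier_ids = sorted(carrier_set.sample_ids)
    report.n_cases = sum(1 for s in kept_samples if s.is_case)
    report.n_controls = len(kept_samples) - report.n_cases

    toggles = config.analyses
    overall = build_carrier_tables(kept_samples, carrier_set)
    if toggles.get("overall", True) and overall:
        report.overall = _association_block(overall)
    if toggles.get("onset_stratified", True):
        tabs = onset_stratify(kept_samples, carrier_set, config.onset)
        if tabs.early_vs_control:
            report.onset_early_vs_control = _association_block(tabs.early_vs_control)
        if tabs.late_vs_control:
            report.onset_late_vs_control = _association_block(tabs.late_vs_control)
        if tabs.early_vs_late:
            report.onset_early_vs_late = _association_block(tabs.early_vs_late)
    if toggles.get("sensitivity", True) and overall:
        try:
            report.sensitivity = loo_sensitivity(overall, config.study_of_stratum)
        except ValueError:
            report.sensitivity = None
    if toggles.get("population_comparison", True) and overall:
        x_cases = sum(t.a for t in overall)
        pop = {
            "expected_control_carriers": population_expected_count(
                report.n_controls, config.prior
            ),
            "binomial_p_cases_vs_population": population_binomial_test(
                x_cases, report.n_cases, config.prior
            ),
        }
        if x_cases >= 1:
            pop["fold_cases_vs_population"] = fold_vs_population(
                x_cases, report.n_cases, config.prior
            )
        report.population = pop

    report.provenance = {
        "mode": "synth" if config.synth is not None else "files",
        "config_hash": config.config_hash(),
        "seed": config.synth.seed if config.synth is not None else config.seed,
        "version": _pkg_version,
        "n_input_samples": len(samples),
        "n_excluded_samples": len(qc_report.excluded),
        "n_calls_after_merge": len(merged),
    }
    return report


def write_report(report: RunReport, out_dir: str | Path) -> dict[str, Path]:
    """Serialise a report as JSON + markdown + per-block TSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"json": out / "report.json", "markdown": out / "report.md"}
    paths["json"].write_text(report.to_json() + "\n", encoding="utf-8")
    paths["markdown"].write_text(report.to_markdown() + "\n", encoding="utf-8")
    import pandas as pd

    for name, block in (
        ("overall", report.overall),
        ("early_vs_control", report.onset_early_vs_control),
        ("late_vs_control", report.onset_late_vs_control),
        ("early_vs_late", report.onset_early_vs_late),
    ):
        if block is None:
            continue
        df = pd.DataFrame(
            [
                {
                    "stratum": t.stratum,
                    "n_group1": t.n1,
                    "carriers_group1": t.a,
                    "n_group2": t.n2,
                    "carriers_group2": t.c,
                    "fisher_p_two_sided": block.fisher_two_sided[t.stratum],
                    "fisher_p_one_sided": block.fisher_one_sided[t.stratum],
                }
                for t in block.strata
            ]
        )
        p = out / f"table_{name}.tsv"
        df.to_csv(p, sep="\t", index=False)
        paths[name] = p
    return paths
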