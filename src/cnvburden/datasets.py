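"""Bundled published counts from the combined 22q11.2-deletion screen in
Parkinson's disease case-control studies.

Four genotyping studies (UK WTCCC2, the Dutch consortium, US NIA, and
the multi-country NeuroX study) contributed 9387 cases and 13 863
controls.  Eight cases and no controls carried the ~3 Mb 22q11.2
deletion.  The NeuroX study splits into seven country subgroups, giving
the "ten-subgroup" stratification; treating NeuroX as one stratum gives
the "four-subgroup" stratification.  Onset-age data were available for
8451 cases; five of the 1014 early-onset cases (onset < 45 years) and
three of the 7437 late-onset cases were carriers.

These counts are first-class inputs for the counts-only analysis mode:
the published association results can be recomputed from them without
any call-level data.
"""

from __future__ import annotations

from dataclasses import dataclass

from .assoc import CarrierTable


@dataclass(frozen=True)
class StratumCounts:
    """Per-stratum sample sizes and deletion-carrier counts."""

    stratum: str
    study: str
    n_cases: int
    case_carriers: int
    n_controls: int
    control_carriers: int
    n_early: int  # cases with onset < 45 y
    early_carriers: int
    n_late: int  # cases with onset >= 45 y
    late_carriers: int


#: ten strata: NIA, WTCCC2, Dutch, and the seven NeuroX country subgroups
STRATA: tuple[StratumCounts, ...] = (
    StratumCounts("US_NIA", "US_NIA", 593, 0, 726, 0, 121, 0, 472, 0),
    StratumCounts("UK_WTCCC2", "UK_WTCCC2", 1592, 2, 4939, 0, 94, 1, 1451, 1),
    StratumCounts("Dutch", "Dutch", 740, 1, 1996, 0, 139, 0, 575, 1),
    StratumCounts("NeuroX_UK", "IPDGC_NeuroX", 804, 2, 684, 0, 131, 1, 320, 1),
    StratumCounts("NeuroX_USA", "IPDGC_NeuroX", 2069, 0, 2652, 0, 131, 0, 1858, 0),
    StratumCounts("NeuroX_France", "IPDGC_NeuroX", 564, 2, 479, 0, 108, 2, 455, 0),
    StratumCounts("NeuroX_Germany", "IPDGC_NeuroX", 1298, 1, 883, 0, 177, 1, 962, 0),
    StratumCounts("NeuroX_Greece", "IPDGC_NeuroX", 736, 0, 891, 0, 46, 0, 642, 0),
    StratumCounts("NeuroX_Netherlands", "IPDGC_NeuroX", 316, 0, 447, 0, 16, 0, 81, 0),
    StratumCounts("NeuroX_PPMI_other", "IPDGC_NeuroX", 675, 0, 166, 0, 51, 0, 621, 0),
)

#: stratum label -> independent study (the sensitivity-analysis unit)
STUDY_OF_STRATUM: dict[str, str] = {s.stratum: s.study for s in STRATA}

Granularity = str  # "ten" | "four"


def _pooled(strata: tuple[StratumCounts, ...]) -> list[StratumCounts]:
    """Pool strata study-by-study (the four-subgroup view)."""
    by_study: dict[str, list[StratumCounts]] = {}
    for s in strata:
        by_study.setdefault(s.study, []).append(s)
    out = []
    for study in by_study:
        parts = by_study[study]
        out.append(
            StratumCounts(
                study,
                study,
                sum(p.n_cases for p in parts),
                sum(p.case_carriers for p in parts),
                sum(p.n_controls for p in parts),
                sum(p.control_carriers for p in parts),
                sum(p.n_early for p in parts),
                sum(p.early_carriers for p in parts),
                sum(p.n_late for p in parts),
                sum(p.late_carriers for p in parts),
            )
        )
    return out


def _select(granularity: Granularity) -> list[StratumCounts]:
    if granularity == "ten":
        return list(STRATA)
    if granularity == "four":
        return _pooled(STRATA)
    raise ValueError(f"granularity must be 'ten' or 'four', got {granularity!r}")


def overall_strata(granularity: Granularity = "ten") -> list[CarrierTable]:
    """Cases-vs-controls tables, one per stratum."""
    return [
        CarrierTable(
            s.stratum,
            s.case_carriers,
            s.n_cases - s.case_carriers,
            s.control_carriers,
            s.n_controls - s.control_carriers,
        )
        for s in _select(granularity)
    ]


def early_vs_control_strata(granularity: Granularity = "ten") -> list[CarrierTable]:
    return [
        CarrierTable(
            s.stratum,
            s.early_carriers,
            s.n_early - s.early_carriers,
            s.control_carriers,
            s.n_controls - s.control_carriers,
        )
        for s in _select(granularity)
    ]


def late_vs_control_strata(granularity: Granularity = "ten") -> list[CarrierTable]:
    return [
        CarrierTable(
            s.stratum,
            s.late_carriers,
            s.n_late - s.late_carriers,
            s.control_carriers,
            s.n_controls - s.control_carriers,
        )
        for s in _select(granularity)
    ]


def early_vs_late_strata(granularity: Granularity = "ten") -> list[CarrierTable]:
    return [
        CarrierTable(
            s.stratum,
            s.early_carriers,
            s.n_early - s.early_carriers,
            s.late_carriers,
            s.n_late - s.late_carriers,
        )
        for s in _select(granularity)
    ]
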