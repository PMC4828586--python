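"""Exact association statistics for sparse stratified 2x2 tables.

The central object is the exact conditional stratified (Mantel-Haenszel)
test.  Conditioning each stratum's 2x2 table on its margins makes the
carrier count in group 1 of stratum k a hypergeometric variable S_k; the
strata are independent, so the null distribution of the total
S = sum_k S_k is the convolution of the per-stratum hypergeometric pmfs.
With rare carriers the support of S is tiny (at most the total carrier
count), so the convolution is computed exactly by direct summation over
integer support, with pmfs evaluated in log space for overflow safety.

Two p-value rules are applied to the null pmf of S (or of a single
table's S_k, which is Fisher's exact test):

* one-sided ("greater"): P(S >= s_obs);
* two-sided minimum-likelihood ("minlike"): the sum of P(S = s) over all
  s whose null probability does not exceed that of the observed count
  (a relative tolerance of 1e-7 guards floating-point ties).

The minlike rule is the classical two-sided definition for Fisher's
exact test and its stratified generalisation; when the observed total is
the most extreme supported value and the opposite extreme is likelier,
one- and two-sided p-values coincide.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
from scipy import stats

#: relative tolerance when comparing null densities under the minlike rule
MINLIKE_RTOL = 1e-7

Alternative = Literal["two_sided_minlike", "one_greater"]


@dataclass(frozen=True)
class CarrierTable:
    """A 2x2 carrier/non-carrier table for two groups in one stratum.

    ``a``/``b`` are carriers/non-carriers in group 1 (e.g. cases),
    ``c``/``d`` in group 2 (e.g. controls).
    """

    stratum: str
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("CarrierTable counts must be nonnegative")
        if self.n1 == 0 or self.n2 == 0:
            raise ValueError(f"CarrierTable stratum {self.stratum!r}: both groups must be non-empty")

    @property
    def n1(self) -> int:
        return self.a + self.b

    @property
    def n2(self) -> int:
        return self.c + self.d

    @property
    def m(self) -> int:
        """Total carriers (the conditioned margin)."""
        return self.a + self.c


@dataclass
class StratifiedResult:
    """Outcome of an exact (possibly stratified) conditional test."""

    p_two_sided: float
    p_one_sided: float
    s_observed: int
    null_pmf: dict[int, float]
    method: str = "exact-convolution-minlike"

    def p_value(self, alternative: Alternative = "two_sided_minlike") -> float:
        return self.p_two_sided if alternative == "two_sided_minlike" else self.p_one_sided


def hypergeom_pmf_2x2(table: CarrierTable) -> dict[int, float]:
    """Null pmf of S_k = carriers in group 1, margins fixed as observed.

    Support is [max(0, m - n2), min(m, n1)]; probabilities are computed
    via the hypergeometric log-pmf and renormalised to sum to 1.
    """
    m, n1, n2 = table.m, table.n1, table.n2
    lo, hi = max(0, m - n2), min(m, n1)
    support = np.arange(lo, hi + 1)
    logp = stats.hypergeom.logpmf(support, n1 + n2, m, n1)
    p = np.exp(logp - logp.max())
    p /= p.sum()
    return dict(zip(support.tolist(), p.tolist()))


def _convolve(pmfs: Iterable[Mapping[int, float]]) -> dict[int, float]:
    acc: dict[int, float] = {0: 1.0}
    for pmf in pmfs:
        nxt: dict[int, float] = {}
        for s1, p1 in acc.items():
            for s2, p2 in pmf.items():
                nxt[s1 + s2] = nxt.get(s1 + s2, 0.0) + p1 * p2
        acc = nxt
    total = sum(acc.values())
    return {s: p / total for s, p in acc.items()}


def _p_values(pmf: Mapping[int, float], s_obs: int) -> tuple[float, float]:
    p_obs = pmf[s_obs]
    p_two = sum(p for p in pmf.values() if p <= p_obs * (1 + MINLIKE_RTOL))
    p_one = sum(p for s, p in pmf.items() if s >= s_obs)
    return min(p_two, 1.0), min(p_one, 1.0)


def fisher_exact_2x2(table: CarrierTable, alternative: Alternative = "two_sided_minlike") -> float:
    """Fisher's exact test on one 2x2 table.

    ``two_sided_minlike`` is the classical two-sided rule (sum the null
    probabilities of all outcomes no likelier than the observed one);
    ``one_greater`` is the upper tail P(S >= a).
    """
    pmf = hypergeom_pmf_2x2(table)
    p_two, p_one = _p_values(pmf, table.a)
    return p_two if alternative == "two_sided_minlike" else p_one


def exact_cmh(
    strata: Sequence[CarrierTable], alternative: Alternative = "two_sided_minlike"
) -> StratifiedResult:
    """Exact conditional stratified (Mantel-Haenszel) test.

    The null pmf of S = sum of per-stratum group-1 carrier counts is the
    exact convolution of the per-stratum hypergeometric pmfs.  Both the
    minlike two-sided and upper-tail one-sided p-values are returned; a
    single stratum reduces exactly to :func:`fisher_exact_2x2`.
    """
    if not strata:
        raise ValueError("exact_cmh requires at least one stratum")
    pmf = _convolve(hypergeom_pmf_2x2(t) for t in strata)
    s_obs = sum(t.a for t in strata)
    p_two, p_one = _p_values(pmf, s_obs)
    return StratifiedResult(
        p_two_sided=p_two, p_one_sided=p_one, s_observed=s_obs, null_pmf=pmf
    )


@dataclass
class LooSensitivity:
    """Leave-one-study-out meta-analysis results."""

    results: dict[str, StratifiedResult]
    max_p_two_sided: float


def loo_sensitivity(
    strata: Sequence[CarrierTable],
    study_of: Mapping[str, str] | None = None,
) -> LooSensitivity:
    """Sequentially exclude each study and repeat the stratified test.

    ``study_of`` maps stratum labels to study labels so several strata
    can be dropped together (default: each stratum is its own study).
    A study whose exclusion leaves no strata is an error.
    """
    study_of = study_of or {}
    mapping = {t.stratum: study_of.get(t.stratum, t.stratum) for t in strata}
    studies = sorted(set(mapping.values()))
    if len(studies) < 2:
        raise ValueError("loo_sensitivity requires at least two distinct studies")
    results: dict[str, StratifiedResult] = {}
    for study in studies:
        remaining = [t for t in strata if mapping[t.stratum] != study]
        if not remaining:
            raise ValueError(f"excluding study {study!r} leaves no strata")
        results[study] = exact_cmh(remaining)
    return LooSensitivity(
        results=results, max_p_two_sided=max(r.p_two_sided for r in results.values())
    )


@dataclass(frozen=True)
class OnsetPolicy:
    """Early-onset definition: onset strictly younger than the cutoff
    (default 45 years; 50 is the usual post-hoc alternative)."""

    early_cutoff_years: float = 45.0

    def __post_init__(self) -> None:
        if self.early_cutoff_years <= 0:
            raise ValueError("early_cutoff_years must be positive")


@dataclass
class OnsetTables:
    """Per-stratum tables for the three onset-stratified comparisons."""

    early_vs_control: list[CarrierTable]
    late_vs_control: list[CarrierTable]
    early_vs_late: list[CarrierTable]


def onset_stratify(
    samples: Sequence["SampleRecord"],
    carriers: Iterable[str] | "CarrierSet",
    policy: OnsetPolicy = OnsetPolicy(),
) -> OnsetTables:
    """Build per-stratum tables for early-onset vs control, late-onset
    vs control and early- vs late-onset comparisons.

    Cases with missing onset age are dropped from the onset analyses
    only (they remain in the overall analysis); onset exactly at the
    cutoff is late-onset.  ``carriers`` may be a
    :class:`~cnvburden.segments.CarrierSet` or any iterable of carrier
    sample ids.  Strata where a comparison has an empty group are
    omitted from that comparison (they carry no information and the
    table would be degenerate).
    """
    carrier_ids = set(getattr(carriers, "sample_ids", carriers))
    cells: dict[str, dict[str, list[int]]] = {}
    for s in samples:
        cell = cells.setdefault(s.study, {"e": [0, 0], "l": [0, 0], "ctrl": [0, 0]})
        hit = 1 if s.sample_id in carrier_ids else 0
        if s.group == "control":
            key = "ctrl"
        elif s.onset_age is None:
            continue
        elif s.onset_age < policy.early_cutoff_years:
            key = "e"
        else:
            key = "l"
        cell[key][0] += hit
        cell[key][1] += 1

    out = OnsetTables([], [], [])
    for study in sorted(cells):
        e, l, ctrl = cells[study]["e"], cells[study]["l"], cells[study]["ctrl"]
        pairs = [
            (out.early_vs_control, e, ctrl),
            (out.late_vs_control, l, ctrl),
            (out.early_vs_late, e, l),
        ]
        for dest, g1, g2 in pairs:
            if g1[1] > 0 and g2[1] > 0:
                dest.append(
                    CarrierTable(study, g1[0], g1[1] - g1[0], g2[0], g2[1] - g2[0])
                )
    return out


def mann_whitney_onset(
    x: Sequence[float],
    y: Sequence[float],
    mode: Literal["exact", "normal_approx", "auto"] = "auto",
) -> float:
    """Two-sided Mann-Whitney U comparison of two onset-age samples.

    ``auto`` uses the exact U distribution when len(x)*len(y) <= 10000
    and the pooled sample has no ties, otherwise the normal
    approximation with tie correction and no continuity correction.
    The two-sided p is min(1, 2 * smaller tail).
    """
    x, y = list(x), list(y)
    if not x or not y:
        raise ValueError("both samples must be non-empty")
    if mode == "auto":
        ties = len(set(x) | set(y)) < len(x) + len(y)
        mode = "exact" if (len(x) * len(y) <= 10_000 and not ties) else "normal_approx"
    if mode == "exact":
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        res = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=False
        )
    return float(min(res.pvalue, 1.0))


@dataclass(frozen=True)
class PopulationPrior:
    """Assumed population frequency of carriers of the target deletion
    (default 0.024%, i.e. about 24 per 100 000)."""

    carrier_frequency: float = 0.00024

    def __post_init__(self) -> None:
        if not (0 < self.carrier_frequency < 1):
            raise ValueError("carrier_frequency must be in (0, 1)")


def population_expected_count(n: int, prior: PopulationPrior = PopulationPrior()) -> float:
    """Expected carriers in a group of size n at the assumed population
    carrier frequency."""
    if n < 0:
        raise ValueError("n must be nonnegative")
    return n * prior.carrier_frequency


def population_binomial_test(
    x: int, n: int, prior: PopulationPrior = PopulationPrior()
) -> float:
    """One-sided (upper) exact binomial p: P(X >= x) for X ~
    Binomial(n, carrier_frequency)."""
    if not (0 <= x <= n):
        raise ValueError("require 0 <= x <= n")
    if x == 0:
        return 1.0
    return float(stats.binom.sf(x - 1, n, prior.carrier_frequency))


def fold_vs_population(
    x: int,
    n: int,
    prior: PopulationPrior = PopulationPrior(),
    method: Literal["proportion_ratio", "odds_ratio"] = "proportion_ratio",
) -> float:
    """Fold enrichment of carriers relative to the assumed population
    frequency.  ``proportion_ratio`` is (x/n)/f; ``odds_ratio`` is the
    corresponding odds ratio (infinite — raised as an error — if x = n).
    """
    if x < 1:
        raise ValueError("fold_vs_population requires x >= 1")
    f = prior.carrier_frequency
    if method == "proportion_ratio":
        return (x / n) / f
    if x == n:
        raise ValueError("odds ratio is unbounded when every sample is a carrier")
    return (x / (n - x)) / (f / (1 - f))


def prevalence_estimate(
    disease_prevalence_per_100k: float, early_onset_share: float, deletion_share: float
) -> float:
    """Prevalence (per 100 000) of early-onset disease with the deletion:
    the product of the disease prevalence, the early-onset share among
    patients, and the deletion-carrier share among early-onset patients.
    """
    for v in (disease_prevalence_per_100k, early_onset_share, deletion_share):
        if v < 0:
            raise ValueError("all factors must be nonnegative")
    return disease_prevalence_per_100k * early_onset_share * deletion_share
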