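"""HLA case-control association: carrier contingency tables, exact
Hardy-Weinberg testing, two-sided Fisher tests, Sidak correction, Woolf odds
ratios with the Haldane correction, and sample-size standardized p-values
with the control-size rule (cases + 3 x cases).

Carrier (dominant) coding throughout: a subject counts once if it has at
least one copy of the allele.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from scipy.stats import hypergeom

from infiltra.errors import InputError, ResolutionError

#: Relative tolerance when comparing hypergeometric probabilities for the
#: two-sided tail sum (floating-point tie handling).
TIE_TOLERANCE = 1e-7


@dataclass(frozen=True)
class CarrierContingency:
    """2x2 carrier table: a/b = case carriers/non-carriers, c/d = controls."""

    allele: str
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise InputError("contingency cells must be non-negative")

    @property
    def cells(self):
        return (self.a, self.b, self.c, self.d)


@dataclass(frozen=True)
class AssociationResult:
    allele: str
    odds_ratio: float
    ci95: tuple
    p_raw: float
    p_sidak: float
    p_standardized: float
    n_tests: int
    n_control_standard: int
    table: CarrierContingency


# ---------------------------------------------------------------------------
# Carrier tables


def _resolution(allele: str) -> int:
    return allele.count(":")


def carrier_table(
    cases: pd.DataFrame, controls: pd.DataFrame, allele: str
) -> CarrierContingency:
    """Build the 2x2 carrier table for one allele from long genotype tables
    (columns: subject, locus, allele1, allele2)."""
    locus = allele.split("*")[0]
    a, b = _carrier_counts(cases, locus, allele)
    c, d = _carrier_counts(controls, locus, allele)
    return CarrierContingency(allele=allele, a=a, b=b, c=c, d=d)


def _carrier_counts(table: pd.DataFrame, locus: str, allele: str):
    sub = table[table["locus"] == locus]
    if sub.empty:
        raise InputError(f"no genotypes at locus {locus}")
    res = {_resolution(x) for x in pd.concat([sub["allele1"], sub["allele2"]]).unique()}
    if _resolution(allele) not in res:
        raise ResolutionError(
            f"allele {allele!r} resolution does not match table at locus {locus}"
        )
    carrier = (sub["allele1"] == allele) | (sub["allele2"] == allele)
    n_carrier = int(carrier.sum())
    return n_carrier, int(len(sub) - n_carrier)


def carrier_table_from_freq(
    cases: pd.DataFrame,
    allele: str,
    freq: float,
    n_controls: int,
    freq_type: str = "carrier",
) -> CarrierContingency:
    """Carrier table with the control arm derived from a population
    reference frequency (``freq_type`` "carrier" or "allele"; an allele
    frequency f implies a carrier fraction 1-(1-f)^2)."""
    if not 0.0 <= freq <= 1.0:
        raise InputError("frequency outside [0, 1]")
    if n_controls < 1:
        raise InputError("n_controls must be >= 1")
    if freq_type == "allele":
        freq = 1.0 - (1.0 - freq) ** 2
    elif freq_type != "carrier":
        raise InputError("freq_type must be 'carrier' or 'allele'")
    locus = allele.split("*")[0]
    a, b = _carrier_counts(cases, locus, allele)
    c = int(math.floor(freq * n_controls + 0.5))
    return CarrierContingency(allele=allele, a=a, b=b, c=c, d=n_controls - c)


# ---------------------------------------------------------------------------
# Exact tests


def hwe_exact_test(n_aa_hom: int, n_het: int, n_other_hom: int) -> float:
    """Exact conditional Hardy-Weinberg test for a biallelic collapse
    (allele vs rest).

    Sums, over all heterozygote counts attainable given the observed allele
    counts, the probabilities no larger than that of the observed
    configuration.
    """
    if min(n_aa_hom, n_het, n_other_hom) < 0:
        raise InputError("genotype counts must be non-negative")
    n = n_aa_hom + n_het + n_other_hom
    if n < 1:
        raise InputError("need at least one subject")
    n_a = 2 * n_aa_hom + n_het
    n_b = 2 * n_other_hom + n_het
    if n_a == 0 or n_b == 0:
        return 1.0  # monomorphic: single attainable configuration
    hets = np.arange(n_a % 2, min(n_a, n_b) + 1, 2)
    n_aa = (n_a - hets) // 2
    n_bb = (n_b - hets) // 2
    logw = hets * math.log(2.0) - gammaln(n_aa + 1) - gammaln(hets + 1) - gammaln(n_bb + 1)
    logp = logw - logsumexp(logw)
    probs = np.exp(logp)
    p_obs = probs[np.searchsorted(hets, n_het)]
    return float(min(1.0, probs[probs <= p_obs * (1.0 + 1e-12)].sum()))


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p: sum of hypergeometric probabilities over
    all tables with the observed margins that are no more probable than the
    observed table (relative tie tolerance 1e-7).

    An empty margin leaves only one attainable table, so p = 1.
    """
    if isinstance(table, CarrierContingency):
        a, b, c, d = table.cells
    else:
        (a, b), (c, d) = table
    for cell in (a, b, c, d):
        if cell < 0 or cell != int(cell):
            raise InputError("cells must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    n = r1 + r2
    if min(r1, r2, c1, c2) == 0:
        return 1.0
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, n, c1, r1)
    p_obs = pmf[a - lo]
    return float(min(1.0, pmf[pmf <= p_obs * (1.0 + TIE_TOLERANCE)].sum()))


# ---------------------------------------------------------------------------
# Corrections


def sidak_correct(p_raw: float, n_tests: int) -> float:
    """Family-wise adjustment p_adj = 1 - (1 - p)^n."""
    if not 0.0 <= p_raw <= 1.0:
        raise InputError("p_raw outside [0, 1]")
    if n_tests < 1:
        raise InputError("n_tests must be >= 1")
    if p_raw == 1.0:
        return 1.0
    return float(-math.expm1(n_tests * math.log1p(-p_raw)))


def woolf_haldane_or(table):
    """Odds ratio and Woolf 95% CI on Haldane-corrected cells (each +0.5),
    which keeps both finite for zero cells.

    Returns (odds_ratio, (ci_low, ci_high)).
    """
    if isinstance(table, CarrierContingency):
        a, b, c, d = table.cells
    else:
        (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise InputError("cells must be non-negative")
    a, b, c, d = (x + 0.5 for x in (a, b, c, d))
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo = math.exp(math.log(or_) - 1.96 * se)
    hi = math.exp(math.log(or_) + 1.96 * se)
    return float(or_), (float(lo), float(hi))


def standard_control_size(n_cases: int) -> int:
    """Maximum allowed control-group size: cases plus three times cases."""
    if n_cases < 1:
        raise InputError("n_cases must be >= 1")
    return 4 * n_cases


def good_standardized_p(p_raw: float, n_controls_actual: int, n_control_standard: int) -> float:
    """Standardize a p-value obtained with an oversized control group down
    to the standard control size: p * sqrt(n_actual / n_standard), capped at
    0.5. Control groups at or below the standard size are left unchanged.
    """
    if not 0.0 <= p_raw <= 1.0:
        raise InputError("p_raw outside [0, 1]")
    if n_controls_actual < 1 or n_control_standard < 1:
        raise InputError("sample sizes must be >= 1")
    if n_controls_actual <= n_control_standard:
        return float(p_raw)
    return float(min(0.5, p_raw * math.sqrt(n_controls_actual / n_control_standard)))


# ---------------------------------------------------------------------------
# Scan


def run_association_scan(
    cases: pd.DataFrame,
    controls: pd.DataFrame | None = None,
    freq_table: pd.DataFrame | None = None,
    n_controls: int | None = None,
) -> list:
    """One association result per allele with at least one carrier in cases
    or controls. Sidak families are per locus (n_tests = alleles tested at
    the locus). Results are sorted by standardized p.

    Controls come either from a genotype table or from a population
    reference table (columns: allele, freq, freq_type) with ``n_controls``.
    """
    if (controls is None) == (freq_table is None):
        raise InputError("supply exactly one of controls / freq_table")
    if freq_table is not None and n_controls is None:
        raise InputError("n_controls required with a frequency table")

    results = []
    if controls is not None:
        loci = sorted(set(cases["locus"]) & set(controls["locus"]))
        for locus in loci:
            tables = []
            for allele in _alleles_at(cases, locus) | _alleles_at(controls, locus):
                t = carrier_table(cases, controls, allele)
                if t.a + t.c > 0:
                    tables.append(t)
            results.extend(_score_locus(tables, int((cases["locus"] == locus).sum())))
    else:
        by_locus: dict = {}
        for _, row in freq_table.iterrows():
            by_locus.setdefault(row["allele"].split("*")[0], []).append(row)
        for locus, rows in sorted(by_locus.items()):
            tables = []
            for row in rows:
                t = carrier_table_from_freq(
                    cases,
                    row["allele"],
                    float(row["freq"]),
                    int(n_controls),
                    freq_type=str(row.get("freq_type", "carrier")),
                )
                if t.a + t.c > 0:
                    tables.append(t)
            results.extend(_score_locus(tables, int((cases["locus"] == locus).sum())))

    if not results:
        raise InputError("no testable alleles")
    results.sort(key=lambda r: (r.p_standardized, r.allele))
    return results


def _alleles_at(table: pd.DataFrame, locus: str) -> set:
    sub = table[table["locus"] == locus]
    return set(sub["allele1"]) | set(sub["allele2"])


def _score_locus(tables, n_cases_locus: int) -> list:
    n_tests = len(tables)
    out = []
    for t in tables:
        p_raw = fisher_exact_2x2(t)
        or_, ci = woolf_haldane_or(t)
        n_std = standard_control_size(n_cases_locus)
        p_std = good_standardized_p(p_raw, t.c + t.d, n_std)
        out.append(
            AssociationResult(
                allele=t.allele,
                odds_ratio=or_,
                ci95=ci,
                p_raw=p_raw,
                p_sidak=sidak_correct(p_raw, n_tests),
                p_standardized=p_std,
                n_tests=n_tests,
                n_control_standard=n_std,
                table=t,
            )
        )
    return out


def results_to_frame(results) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "allele": [r.allele for r in results],
            "a_case_carriers": [r.table.a for r in results],
            "b_case_noncarriers": [r.table.b for r in results],
            "c_control_carriers": [r.table.c for r in results],
            "d_control_noncarriers": [r.table.d for r in results],
            "odds_ratio": [r.odds_ratio for r in results],
            "ci95_low": [r.ci95[0] for r in results],
            "ci95_high": [r.ci95[1] for r in results],
            "p_raw": [r.p_raw for r in results],
            "p_sidak": [r.p_sidak for r in results],
            "p_standardized": [r.p_standardized for r in results],
            "n_tests": [r.n_tests for r in results],
            "n_control_standard": [r.n_control_standard for r in results],
        }
    )
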