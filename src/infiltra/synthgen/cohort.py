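"""Synthetic patient cohorts: mutation status, infiltration ratios, HLA
genotypes, and right-censored event times."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from infiltra.errors import ConfigurationError

_DEFAULT_ALLELE_FREQS = {
    "A*02:01": 0.270,
    "A*03:01": 0.128,
    "A*11:01": 0.055,
    "A*01:01": 0.160,
}


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic patient cohort.

    Group CD8 ratios are lognormal with the specified group medians and a
    common log-scale standard deviation. Event times are exponential with a
    hazard modulated by the (centered) log ratio and administratively
    censored at ``horizon_years``.
    """

    n_patients: int = 101
    braf_pos_fraction: float = 0.5
    median_ratio_brafpos: float = 0.0316
    median_ratio_brafwt: float = 0.0775
    ratio_log_sd: float = 1.2
    allele_freqs: dict = field(default_factory=lambda: dict(_DEFAULT_ALLELE_FREQS))
    event_rate: float = 0.04
    effect_of_ratio_on_hazard: float = 0.0
    counter_cv: float = 0.05
    horizon_years: float = 15.0
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 2:
            raise ConfigurationError("n_patients must be >= 2")
        if not 0.0 <= self.braf_pos_fraction <= 1.0:
            raise ConfigurationError("braf_pos_fraction must lie in [0, 1]")
        if self.median_ratio_brafpos <= 0 or self.median_ratio_brafwt <= 0:
            raise ConfigurationError("group medians must be > 0")
        if self.ratio_log_sd < 0:
            raise ConfigurationError("ratio_log_sd must be >= 0")
        if not self.allele_freqs:
            raise ConfigurationError("allele_freqs must not be empty")
        for allele, f in self.allele_freqs.items():
            if "*" not in allele:
                raise ConfigurationError(f"allele {allele!r} lacks a locus prefix")
            if not 0.0 <= f <= 1.0:
                raise ConfigurationError(f"frequency of {allele!r} outside [0, 1]")
        for locus, total in _locus_totals(self.allele_freqs).items():
            if total > 1.0 + 1e-9:
                raise ConfigurationError(f"frequencies at locus {locus} sum to > 1")
        if self.event_rate <= 0:
            raise ConfigurationError("event_rate must be > 0")


def _locus_totals(allele_freqs: dict) -> dict:
    totals: dict = {}
    for allele, f in allele_freqs.items():
        locus = allele.split("*")[0]
        totals[locus] = totals.get(locus, 0.0) + f
    return totals


def _draw_locus(rng, allele_freqs: dict, locus: str, n: int) -> np.ndarray:
    alleles = [a for a in allele_freqs if a.split("*")[0] == locus]
    probs = [allele_freqs[a] for a in alleles]
    residual = 1.0 - sum(probs)
    if residual > 1e-12:
        alleles = alleles + [f"{locus}*XX"]
        probs = probs + [residual]
    probs = np.asarray(probs) / np.sum(probs)
    return rng.choice(alleles, size=(n, 2), p=probs)


def generate_genotypes(
    allele_freqs: dict, n_subjects: int, seed: int = 0, prefix: str = "S"
) -> pd.DataFrame:
    """Draw two alleles per locus per subject (independent loci, with
    replacement) and return a long genotype table
    (subject, locus, allele1, allele2)."""
    if not allele_freqs:
        raise ConfigurationError("allele_freqs must not be empty")
    rng = np.random.default_rng(seed)
    loci = sorted(_locus_totals(allele_freqs))
    frames = []
    subjects = [f"{prefix}{i + 1:05d}" for i in range(n_subjects)]
    for locus in loci:
        draws = _draw_locus(rng, allele_freqs, locus, n_subjects)
        frames.append(
            pd.DataFrame(
                {
                    "subject": subjects,
                    "locus": locus,
                    "allele1": draws[:, 0],
                    "allele2": draws[:, 1],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Generate a per-patient table with clinical covariates, CD8/CD3 ratios,
    HLA alleles, and right-censored follow-up."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients

    braf_pos = rng.random(n) < spec.braf_pos_fraction
    log_median = np.where(
        braf_pos,
        math.log(spec.median_ratio_brafpos),
        math.log(spec.median_ratio_brafwt),
    )
    log_ratio = rng.normal(log_median, spec.ratio_log_sd)
    cd8_ratio = np.exp(log_ratio)
    # CD3 ratio strictly exceeds the CD8 ratio (CD3 = CD8+ plus CD8- cells).
    cd3_ratio = cd8_ratio * (1.0 + rng.lognormal(math.log(2.0), 0.5, size=n))

    cd1a = np.floor(rng.lognormal(math.log(1500.0), 0.6, size=n) + 0.5).astype(int)
    cd1a = np.maximum(cd1a, 50)
    cd3cd8pos = np.floor(cd8_ratio * cd1a + 0.5).astype(int)
    cd3cd8neg = np.floor((cd3_ratio - cd8_ratio) * cd1a + 0.5).astype(int)

    center = 0.5 * (
        math.log(spec.median_ratio_brafpos) + math.log(spec.median_ratio_brafwt)
    )
    hazard = spec.event_rate * np.exp(
        spec.effect_of_ratio_on_hazard * (log_ratio - center)
    )
    t_event = rng.exponential(1.0 / hazard)
    event = t_event <= spec.horizon_years
    followup = np.minimum(t_event, spec.horizon_years)

    quartile = pd.qcut(cd8_ratio, 4, labels=False, duplicates="drop")
    semiquant = np.asarray(quartile, dtype=float) + 1.0

    df = pd.DataFrame(
        {
            "patient_id": [f"P{i + 1:04d}" for i in range(n)],
            "age_group": np.where(rng.random(n) < 0.84, "pediatric", "adult"),
            "sex": np.where(rng.random(n) < 0.52, "male", "female"),
            "extent": rng.choice(
                ["SS", "MS RO-", "MS RO+"], size=n, p=[0.77, 0.12, 0.11]
            ),
            "biopsy_site": rng.choice(
                ["bone", "skin", "other"], size=n, p=[0.55, 0.30, 0.15]
            ),
            "braf": np.where(braf_pos, "V600E", "WT"),
            "chemo_fdo": rng.random(n) < 0.34,
            "cd8_ratio": cd8_ratio,
            "cd3_ratio": cd3_ratio,
            "cd1a_count": cd1a,
            "cd3cd8neg_count": cd3cd8neg,
            "cd3cd8pos_count": cd3cd8pos,
            "semiquant": semiquant,
            "followup_years": followup,
            "event": event,
        }
    )

    loci = sorted(_locus_totals(spec.allele_freqs))
    for locus in loci:
        draws = _draw_locus(rng, spec.allele_freqs, locus, n)
        df[f"hla_{locus}_1"] = draws[:, 0]
        df[f"hla_{locus}_2"] = draws[:, 1]
    return df


def cohort_genotypes(cohort: pd.DataFrame) -> pd.DataFrame:
    """Reshape the wide per-patient HLA columns into the long genotype-table
    format consumed by the association module."""
    frames = []
    loci = sorted(
        c[len("hla_") : -2] for c in cohort.columns if c.startswith("hla_") and c.endswith("_1")
    )
    for locus in loci:
        frames.append(
            pd.DataFrame(
                {
                    "subject": cohort["patient_id"],
                    "locus": locus,
                    "allele1": cohort[f"hla_{locus}_1"],
                    "allele2": cohort[f"hla_{locus}_2"],
                }
            )
        )
    if not frames:
        raise ConfigurationError("cohort table has no hla_* columns")
    return pd.concat(frames, ignore_index=True)
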