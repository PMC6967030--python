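"""Peptide-level computations: enumeration of mutation-spanning 8-12mers,
competition-binding IC50 fitting with reference-ratio interpretation, and
PRM light/heavy abundance quantitation with detection calls."""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import spearmanr

from infiltra.errors import (
    ConfigurationError,
    InputError,
    InternalStandardError,
    ReferenceBindingError,
)
from infiltra.synthgen.assays import four_parameter_logistic

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

#: IC50 class cut points (nM): <=50 strong, <=500 intermediate, else weak.
STRONG_CUTOFF_NM = 50.0
INTERMEDIATE_CUTOFF_NM = 500.0

#: Sentinel for "no measurable binding".
NO_BINDING = math.inf


@dataclass(frozen=True)
class ProteinVariant:
    """Single amino-acid substitution in a protein sequence (1-based)."""

    sequence: str
    position: int
    ref_aa: str
    alt_aa: str

    def __post_init__(self):
        if not 1 <= self.position <= len(self.sequence):
            raise InputError("variant position outside sequence")
        if self.sequence[self.position - 1] != self.ref_aa:
            raise InputError(
                f"sequence has {self.sequence[self.position - 1]!r} at position "
                f"{self.position}, not {self.ref_aa!r}"
            )
        if self.ref_aa == self.alt_aa:
            raise InputError("ref and alt amino acids are identical")
        if self.alt_aa not in AMINO_ACIDS:
            raise InputError(f"invalid amino acid {self.alt_aa!r}")

    @classmethod
    def from_hgvs(cls, spec: str, sequence: str) -> "ProteinVariant":
        """Parse an HGVS-protein-like spec such as ``"BRAF:p.V600E"``."""
        m = re.fullmatch(r"(?:[\w.-]+:)?p\.([A-Z])(\d+)([A-Z])", spec.strip())
        if not m:
            raise InputError(f"cannot parse variant spec {spec!r}")
        ref, pos, alt = m.group(1), int(m.group(2)), m.group(3)
        return cls(sequence=sequence, position=pos, ref_aa=ref, alt_aa=alt)

    @property
    def mutated_sequence(self) -> str:
        i = self.position - 1
        return self.sequence[:i] + self.alt_aa + self.sequence[i + 1 :]


@dataclass(frozen=True)
class PeptideWindow:
    sequence: str
    start: int  # 1-based in the protein
    length: int
    contains_variant: bool
    variant_offset: int  # 1-based within the peptide


def enumerate_mutation_spanning_peptides(
    variant: ProteinVariant, lengths=range(8, 13)
) -> list:
    """All windows of the requested lengths that lie fully inside the
    sequence and include the variant position, with the alternate residue
    substituted. Deduplicated on peptide sequence, sorted by (length, start).

    An interior variant yields exactly sum(lengths) windows; a variant close
    to a terminus yields fewer (possibly zero for long windows).
    """
    mutated = variant.mutated_sequence
    pos = variant.position
    seen = set()
    out = []
    for length in sorted(set(int(x) for x in lengths)):
        if length < 1:
            raise ConfigurationError("window length must be >= 1")
        start_lo = max(1, pos - length + 1)
        start_hi = min(pos, len(mutated) - length + 1)
        for start in range(start_lo, start_hi + 1):
            pep = mutated[start - 1 : start - 1 + length]
            if pep in seen:
                continue
            seen.add(pep)
            out.append(
                PeptideWindow(
                    sequence=pep,
                    start=start,
                    length=length,
                    contains_variant=True,
                    variant_offset=pos - start + 1,
                )
            )
    return out


# ---------------------------------------------------------------------------
# Binding


@dataclass(frozen=True)
class IC50Fit:
    ic50: float  # nM; math.inf when no measurable binding
    hill: float
    top: float
    bottom: float
    residual: float

    @property
    def no_binding(self) -> bool:
        return math.isinf(self.ic50)


def fit_ic50(titration: pd.DataFrame) -> IC50Fit:
    """Least-squares 4PL fit of signal vs concentration (fit parameterized
    in log10 IC50).

    Data whose fitted dynamic range does not clear the noise (3x residual
    scatter, with a 5%-of-signal floor) are reported as "no measurable
    binding" with an infinite IC50 sentinel rather than an extrapolated
    number.
    """
    conc = titration["concentration_nM"].to_numpy(dtype=float)
    sig = titration["signal"].to_numpy(dtype=float)
    if conc.size < 4:
        raise InputError("need at least 4 concentration points")
    if np.any(conc <= 0):
        raise InputError("concentrations must be positive")
    if math.log10(conc.max() / conc.min()) < 2.0:
        raise InputError("concentrations must span at least 2 decades")

    scale = float(np.median(np.abs(sig))) or 1.0

    def model(logc, top, bottom, log_ic50, hill):
        return four_parameter_logistic(10.0**logc, top, bottom, 10.0**log_ic50, hill)

    logc = np.log10(conc)
    p0 = (float(sig.max()), float(sig.min()), float(np.median(logc)), 1.0)
    try:
        popt, _ = curve_fit(
            model,
            logc,
            sig,
            p0=p0,
            bounds=(
                (-np.inf, -np.inf, logc.min() - 3, 0.05),
                (np.inf, np.inf, logc.max() + 3, 20.0),
            ),
            maxfev=20000,
        )
    except RuntimeError:
        return IC50Fit(NO_BINDING, math.nan, float(sig.max()), float(sig.min()), math.nan)
    top, bottom, log_ic50, hill = popt
    resid = float(np.sqrt(np.mean((model(logc, *popt) - sig) ** 2)))
    dynamic_range = abs(top - bottom)
    if dynamic_range < max(3.0 * resid, 0.05 * scale) or bottom > top:
        return IC50Fit(NO_BINDING, float(hill), float(top), float(bottom), resid)
    return IC50Fit(float(10.0**log_ic50), float(hill), float(top), float(bottom), resid)


def relative_binding(ic50_target: float, ic50_reference: float):
    """Ratio of target to reference IC50 plus a qualitative interpretation.

    A ratio near 1 indicates binding comparable to the strong reference even
    at a high absolute IC50 (e.g. 260 vs 250), while a large ratio flags a
    much weaker binder even at a low absolute IC50 (e.g. 100 vs 5).
    """
    if math.isinf(ic50_reference) or ic50_reference <= 0:
        raise ReferenceBindingError("reference peptide shows no measurable binding")
    if math.isinf(ic50_target):
        return math.inf, "target shows no measurable binding"
    if ic50_target <= 0:
        raise InputError("ic50_target must be > 0")
    ratio = ic50_target / ic50_reference
    if ratio <= 3.0:
        interp = "binding capacity comparable to the strong reference"
    elif ratio <= 20.0:
        interp = "markedly weaker binding than the reference"
    else:
        interp = "far weaker binding than the reference"
    return float(ratio), interp


def classify_binding(ic50: float, relative: float | None = None) -> str:
    """Binder class from absolute IC50 with the boundary inclusive at the cut
    points; 500-1000 nM with a reference ratio < 3 is flagged
    "intermediate-by-ratio" (absolute IC50 alone understates such binders).
    """
    if math.isinf(ic50):
        return "weak/non-binder"
    if ic50 <= 0:
        raise InputError("ic50 must be > 0")
    if ic50 <= STRONG_CUTOFF_NM:
        return "strong"
    if ic50 <= INTERMEDIATE_CUTOFF_NM:
        return "intermediate"
    if relative is not None and ic50 <= 1000.0 and relative < 3.0:
        return "intermediate-by-ratio"
    return "weak/non-binder"


# ---------------------------------------------------------------------------
# PRM quantitation


@dataclass(frozen=True)
class PRMQuant:
    peptide: str
    light_area: float  # summed over shared transitions
    heavy_area: float
    abundance_fmol: float
    n_transitions_detected: int
    detected: bool | None = None
    transitions: pd.DataFrame | None = None


def prm_abundance(
    report: pd.DataFrame,
    heavy_spike: float,
    peptide: str | None = None,
    rt_tolerance: float = 0.5,
) -> PRMQuant:
    """Abundance = heavy_spike x (sum of light areas / sum of heavy areas)
    over transitions shared by both labels.

    Linear in the summed light area, inversely linear in the summed heavy
    area, and invariant to permuting transitions.
    """
    df = report
    if peptide is not None:
        df = df[df["peptide"] == peptide]
    elif df["peptide"].nunique() != 1:
        raise InputError("report holds multiple peptides; pass peptide=")
    else:
        peptide = str(df["peptide"].iloc[0])
    light = df[df["label"] == "light"].set_index("transition")
    heavy = df[df["label"] == "heavy"].set_index("transition")
    shared = light.index.intersection(heavy.index)
    if shared.empty or float(heavy.loc[shared, "area"].sum()) <= 0:
        raise InternalStandardError(f"{peptide}: no heavy internal-standard signal")
    l_area = float(light.loc[shared, "area"].sum())
    h_area = float(heavy.loc[shared, "area"].sum())
    pairs = pd.DataFrame(
        {
            "light_area": light.loc[shared, "area"],
            "heavy_area": heavy.loc[shared, "area"],
            "delta_rt": (light.loc[shared, "rt_min"] - heavy.loc[shared, "rt_min"]).abs(),
        }
    )
    n_coelute = int(((pairs["delta_rt"] <= rt_tolerance) & (pairs["light_area"] > 0)).sum())
    return PRMQuant(
        peptide=peptide,
        light_area=l_area,
        heavy_area=h_area,
        abundance_fmol=heavy_spike * l_area / h_area,
        n_transitions_detected=n_coelute,
        transitions=pairs,
    )


def call_detection(
    quant: PRMQuant,
    min_transitions: int = 3,
    min_ratio: float = 0.001,
    rt_tolerance: float = 0.5,
    min_rank_correlation: float = 0.9,
) -> PRMQuant:
    """Detected iff (i) at least ``min_transitions`` light transitions
    co-elute with their heavy counterparts, (ii) the light/heavy
    transition-intensity rank correlation is >= ``min_rank_correlation``,
    and (iii) the summed light/heavy ratio is >= ``min_ratio``."""
    if quant.transitions is None:
        raise InputError("quant lacks per-transition data")
    pairs = quant.transitions
    coelute = (pairs["delta_rt"] <= rt_tolerance) & (pairs["light_area"] > 0)
    n_co = int(coelute.sum())
    if len(pairs) >= 2:
        import warnings

        with warnings.catch_warnings():
            # constant arrays (e.g. zero light signal) leave rho undefined
            warnings.simplefilter("ignore")
            rho = spearmanr(pairs["light_area"], pairs["heavy_area"]).statistic
        rho = 0.0 if np.isnan(rho) else float(rho)
    else:
        rho = 1.0
    ratio = quant.light_area / quant.heavy_area
    detected = (
        n_co >= min_transitions and rho >= min_rank_correlation and ratio >= min_ratio
    )
    return PRMQuant(
        peptide=quant.peptide,
        light_area=quant.light_area,
        heavy_area=quant.heavy_area,
        abundance_fmol=quant.abundance_fmol,
        n_transitions_detected=n_co,
        detected=detected,
        transitions=pairs,
    )
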