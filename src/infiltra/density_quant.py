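"""Manual-counting workflow: per-image counts, inter-counter adjudication,
patient-level density ratios, 1+-4+ semi-quantitative scoring with consensus
rules, and cross-method concordance."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from skimage.measure import label

from infiltra.errors import (
    AdjudicationNeededError,
    ConsensusNeededError,
    InputError,
    UndefinedRatioError,
)

CLASSES = ("CD1a", "CD3CD8neg", "CD3CD8pos")

#: Mapping from image-quant color masks to cell classes.
MASK_TO_CLASS = {"green": "CD1a", "red": "CD3CD8neg", "purple": "CD3CD8pos"}

#: Connected components smaller than this are treated as debris, not cells.
DEFAULT_MIN_CELL_AREA = 20

#: Counter totals differing by more than this fraction trigger adjudication.
DISCREPANCY_THRESHOLD = 0.10


def round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class CountRecord:
    patient_id: str
    image_id: str
    counter_id: str
    counts: dict  # class -> non-negative int

    def __post_init__(self):
        for cls in CLASSES:
            if self.counts.get(cls, 0) < 0:
                raise InputError("counts must be non-negative")


@dataclass(frozen=True)
class AdjudicatedCount:
    patient_id: str
    final_counts: dict
    adjudicated: bool
    relative_discrepancy: float


@dataclass(frozen=True)
class DensityRatios:
    cd3_ratio: float
    cd8_ratio: float
    cells_per_tcell: int | None


@dataclass(frozen=True)
class SemiQuantScore:
    patient_id: str
    scorer_id: str
    score: int

    def __post_init__(self):
        if self.score not in (1, 2, 3, 4):
            raise InputError("score must be an integer 1-4")


@dataclass(frozen=True)
class ConsensusScore:
    final_score: int
    consensus_required: bool
    method: str  # "rounded-average" or "consensus"


# ---------------------------------------------------------------------------


def count_cells_from_masks(masks: dict, min_cell_area: int = DEFAULT_MIN_CELL_AREA) -> dict:
    """Emulate a counter via connected-component labeling on class masks.

    A component split in two by an ROI boundary is counted twice when both
    halves reach ``min_cell_area``; that is a documented limitation of the
    component definition, not a bug.
    """
    for a in masks.values():
        for b in masks.values():
            if a is not b and np.any(a & b):
                raise InputError("class masks must be disjoint")
    out = {}
    for mask_name, cls in MASK_TO_CLASS.items():
        lab, n = label(masks[mask_name], connectivity=2, return_num=True)
        if n == 0:
            out[cls] = 0
            continue
        sizes = np.bincount(lab.ravel())[1:]
        out[cls] = int(np.sum(sizes >= min_cell_area))
    return out


def aggregate_counts(records) -> dict:
    """Sum the per-image counts of one counter for one patient."""
    records = list(records)
    if not records:
        raise InputError("no records to aggregate")
    patients = {r.patient_id for r in records}
    counters = {r.counter_id for r in records}
    if len(patients) != 1 or len(counters) != 1:
        raise InputError("records mix patients or counters")
    return {cls: sum(r.counts.get(cls, 0) for r in records) for cls in CLASSES}


def _pair_discrepancy(a: int, b: int) -> float:
    if a == 0 and b == 0:
        return 0.0
    return abs(a - b) / ((a + b) / 2.0)


def adjudicate_counts(
    counter_a: dict,
    counter_b: dict,
    referee: dict | None = None,
    patient_id: str = "",
) -> AdjudicatedCount:
    """Combine two counters' per-class totals.

    If every class discrepancy |A-B|/mean(A,B) is <= 10%, the final count is
    the rounded (half-up) mean. Otherwise a referee selection is required and
    must equal one of the two counters' values per class. The rule is
    symmetric in A and B.
    """
    disc = {cls: _pair_discrepancy(counter_a.get(cls, 0), counter_b.get(cls, 0)) for cls in CLASSES}
    worst = max(disc.values())
    if worst <= DISCREPANCY_THRESHOLD:
        final = {
            cls: round_half_up((counter_a.get(cls, 0) + counter_b.get(cls, 0)) / 2.0)
            for cls in CLASSES
        }
        return AdjudicatedCount(patient_id, final, False, worst)
    if referee is None:
        raise AdjudicationNeededError(
            f"patient {patient_id!r}: discrepancy {worst:.3f} > "
            f"{DISCREPANCY_THRESHOLD}; referee selection required"
        )
    final = {}
    for cls in CLASSES:
        sel = referee.get(cls)
        if sel not in (counter_a.get(cls, 0), counter_b.get(cls, 0)):
            raise InputError(
                f"referee value {sel!r} for {cls} matches neither counter"
            )
        final[cls] = sel
    return AdjudicatedCount(patient_id, final, True, worst)


def referee_from_truth(counter_a: dict, counter_b: dict, truth: dict) -> dict:
    """Synthetic-run referee: per class, pick the counter closer to ground
    truth (ties go to counter A)."""
    out = {}
    for cls in CLASSES:
        a, b, t = counter_a.get(cls, 0), counter_b.get(cls, 0), truth.get(cls, 0)
        out[cls] = a if abs(a - t) <= abs(b - t) else b
    return out


def compute_density_ratios(final_counts: dict) -> DensityRatios:
    """CD3:CD1a and CD8:CD1a count ratios plus the rounded reciprocal
    ("one CD8+ T cell per N CD1a+ cells")."""
    cd1a = final_counts.get("CD1a", 0)
    if cd1a <= 0:
        raise UndefinedRatioError("CD1a count is 0; density ratios undefined")
    neg = final_counts.get("CD3CD8neg", 0)
    pos = final_counts.get("CD3CD8pos", 0)
    cd8 = pos / cd1a
    cd3 = (neg + pos) / cd1a
    per = round_half_up(1.0 / cd8) if cd8 > 0 else None
    return DensityRatios(cd3_ratio=cd3, cd8_ratio=cd8, cells_per_tcell=per)


def consensus_score(scores, consensus: int | None = None) -> ConsensusScore:
    """Combine three semi-quantitative scores.

    If the maximum pairwise difference is <= 1, the final score is the
    rounded (half-up) average; otherwise a collectively attained consensus
    value must be supplied. Permutation-invariant in its three inputs.
    """
    vals = [s.score if isinstance(s, SemiQuantScore) else int(s) for s in scores]
    if len(vals) != 3:
        raise InputError("exactly three scores required")
    if any(v not in (1, 2, 3, 4) for v in vals):
        raise InputError("scores must be integers 1-4")
    if max(vals) - min(vals) <= 1:
        return ConsensusScore(round_half_up(sum(vals) / 3.0), False, "rounded-average")
    if consensus is None:
        raise ConsensusNeededError(
            f"scores {vals} differ by more than 1; consensus value required"
        )
    if consensus not in (1, 2, 3, 4):
        raise InputError("consensus value must be 1-4")
    return ConsensusScore(int(consensus), True, "consensus")


def method_concordance(per_patient: pd.DataFrame) -> dict:
    """Pairwise Spearman correlations between the three quantification
    methods plus a score-vs-ratio-quartile agreement table.

    ``per_patient`` needs columns count_ratio, area_ratio, semiquant with at
    least 10 complete patients.
    """
    needed = ["count_ratio", "area_ratio", "semiquant"]
    missing = [c for c in needed if c not in per_patient.columns]
    if missing:
        raise InputError(f"missing columns: {missing}")
    df = per_patient.dropna(subset=needed)
    if len(df) < 10:
        raise InputError("need >= 10 patients with all three methods")
    pairs = {}
    for a, b in (("count_ratio", "area_ratio"), ("count_ratio", "semiquant"), ("area_ratio", "semiquant")):
        rho, p = spearmanr(df[a], df[b])
        pairs[f"{a}|{b}"] = {"rho": float(rho), "p": float(p)}
    quartile = pd.qcut(df["count_ratio"], 4, labels=[1, 2, 3, 4], duplicates="drop")
    agreement = pd.crosstab(df["semiquant"], quartile)
    return {"n": int(len(df)), "spearman": pairs, "score_vs_quartile": agreement}
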