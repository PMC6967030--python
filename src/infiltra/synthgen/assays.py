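"""Synthetic assay outputs: competition-binding titrations and PRM
light/heavy transition reports."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from infiltra.errors import ConfigurationError

#: Arbitrary peak-area units per fmol of peptide on column.
_AREA_PER_FMOL = 1.0e4

#: Relative light signal level when a peptide is truly absent.
_NOISE_FLOOR = 1.0e-4


def four_parameter_logistic(conc, top, bottom, ic50, hill):
    """4PL competition curve: signal falls from ``top`` to ``bottom`` as the
    competitor concentration grows; at ``conc == ic50`` the signal is the
    midpoint (top + bottom) / 2."""
    conc = np.asarray(conc, dtype=float)
    return bottom + (top - bottom) / (1.0 + (conc / ic50) ** hill)


def _mult_noise(rng, cv, size):
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log1p(cv**2))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)


def generate_binding_curve(
    true_ic50: float,
    hill: float,
    concentrations,
    noise_cv: float = 0.0,
    seed: int = 0,
    top: float = 1.0,
    bottom: float = 0.0,
) -> pd.DataFrame:
    """Simulate one competition titration.

    Returns a table (concentration_nM, signal); the generating truth is
    recorded in ``DataFrame.attrs``.
    """
    conc = np.asarray(list(concentrations), dtype=float)
    if conc.size < 4:
        raise ConfigurationError("need at least 4 concentration points")
    if np.any(conc <= 0):
        raise ConfigurationError("concentrations must be positive")
    if true_ic50 <= 0:
        raise ConfigurationError("true_ic50 must be positive")
    rng = np.random.default_rng(seed)
    signal = four_parameter_logistic(conc, top, bottom, true_ic50, hill)
    signal = signal * _mult_noise(rng, noise_cv, conc.size)
    df = pd.DataFrame({"concentration_nM": conc, "signal": signal})
    df.attrs.update(
        true_ic50=true_ic50, hill=hill, top=top, bottom=bottom, noise_cv=noise_cv
    )
    return df


def generate_prm_report(
    peptides,
    true_amounts,
    heavy_spike: float = 40.0,
    n_transitions: int = 3,
    noise_cv: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a PRM transition report with paired light/heavy rows.

    Per peptide, each monitored transition yields a heavy (spiked internal
    standard) row and a light (endogenous) row whose areas are proportional
    to amount on column and share the transition's response factor. A truly
    absent peptide (``true_amount == 0``) produces light rows at the noise
    floor with a shifted retention time, so downstream detection calls it
    absent.

    Columns: peptide, label {light, heavy}, transition, area, rt_min.
    """
    if heavy_spike <= 0:
        raise ConfigurationError("heavy_spike must be > 0")
    if n_transitions < 1:
        raise ConfigurationError("n_transitions must be >= 1")
    peptides = list(peptides)
    amounts = list(true_amounts)
    if len(peptides) != len(amounts):
        raise ConfigurationError("peptides and true_amounts differ in length")
    rng = np.random.default_rng(seed)
    rows = []
    for pep, amount in zip(peptides, amounts):
        if amount < 0:
            raise ConfigurationError("true_amounts must be >= 0")
        rt0 = rng.uniform(20.0, 90.0)
        # Response factors differ per transition but are shared between the
        # light and heavy isotopologues (co-fragmentation behavior).
        weights = rng.uniform(0.5, 1.5, size=n_transitions)
        heavy_noise = _mult_noise(rng, noise_cv, n_transitions)
        light_noise = _mult_noise(rng, noise_cv, n_transitions)
        for k in range(n_transitions):
            tname = f"y{k + 3}"
            heavy_area = _AREA_PER_FMOL * heavy_spike * weights[k] * heavy_noise[k]
            rows.append((pep, "heavy", tname, heavy_area, rt0))
            if amount > 0:
                light_area = _AREA_PER_FMOL * amount * weights[k] * light_noise[k]
                light_rt = rt0 + rng.normal(0.0, 0.02)
            else:
                light_area = (
                    _AREA_PER_FMOL
                    * heavy_spike
                    * weights[k]
                    * _NOISE_FLOOR
                    * rng.uniform(0.2, 1.0)
                )
                light_rt = rt0 + rng.uniform(2.0, 5.0) * rng.choice([-1.0, 1.0])
            rows.append((pep, "light", tname, light_area, light_rt))
    df = pd.DataFrame(rows, columns=["peptide", "label", "transition", "area", "rt_min"])
    df.attrs.update(
        heavy_spike=heavy_spike,
        true_amounts=dict(zip(peptides, amounts)),
        noise_cv=noise_cv,
    )
    return df
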