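"""Synthetic study-shaped datasets with known ground truth.

Emulates the experimental design: two genotypes (WT and a pyrenoid-less
mutant, "pyr"), light acclimation at LL (10), SL (50) or HL
(100 µmol photons m⁻² s⁻¹), air (0.04%) or 5% CO₂, with replicated
light-response measurements at the eight-step actinic intensity grid and
independent homoscedastic normal noise around the deterministic curve.

All truth values except the genotype contrasts are synthetic defaults (no
per-treatment parameter table exists to copy); the WT-minus-mutant ETR_max
contrasts are placed at 12 (SL/air), 4 (LL/air) and 0 (5% CO₂), i.e. a
large CO₂-limitation effect under standard light that shrinks under light
limitation and vanishes when CO₂ is saturating.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import MEASUREMENT_INTENSITIES, evaluate_model

__all__ = ["TreatmentTruth", "Scenario", "default_scenario", "generate", "induction_lag_curve"]

GENOTYPES = ("WT", "pyr")
LIGHT_LEVELS = {"LL": 10.0, "SL": 50.0, "HL": 100.0}
CO2_LEVELS = ("air", "5pct")


def treatment_label(genotype: str, light: str, co2: str) -> str:
    return f"{genotype}_{light}_{co2}"


@dataclass(frozen=True)
class TreatmentTruth:
    """True parameters and noise SD for one treatment and one response kind."""

    kind: str
    params: tuple[float, ...]  # natural scale, ordered per MODEL_PARAM_NAMES
    sigma: float

    def __post_init__(self):
        # sigma == 0 is allowed as the degenerate noiseless limit
        if self.sigma < 0 or any(p <= 0 for p in self.params):
            raise ValueError("parameters must be positive and noise SD non-negative")


@dataclass
class Scenario:
    """Full description of a simulated experiment.

    treatments maps label -> {kind -> TreatmentTruth}.  Replicate defaults
    follow the study design: 6 biological replicates for colony fluorescence
    (phi_ii), 3 for the spectroscopic TEF and NPQ measurements.
    """

    treatments: dict[str, dict[str, TreatmentTruth]]
    replicates: dict[str, int] = field(
        default_factory=lambda: {"phi_ii": 6, "tef": 3, "npq": 3}
    )
    intensities: tuple[float, ...] = MEASUREMENT_INTENSITIES
    seed: int | None = None

    def validate(self) -> None:
        if not self.treatments:
            raise ValueError("scenario has no treatments")
        for label, kinds in self.treatments.items():
            for kind, truth in kinds.items():
                if truth.kind != kind:
                    raise ValueError(f"kind mismatch in treatment {label}")
        if any(r < 1 for r in self.replicates.values()):
            raise ValueError("replicate counts must be >= 1")
        if any(i <= 0 for i in self.intensities):
            raise ValueError("intensities must be positive")


def default_scenario(seed: int | None = None) -> Scenario:
    """The 2 genotypes x {LL, SL} x {air, 5% CO2} default experiment.

    phi_II truths use (ETR_max, I_k); the WT-pyr ETR_max contrasts are
    12 under SL/air, 4 under LL/air and exactly 0 under 5% CO₂ (both
    genotypes share identical truth there, a built-in null).  TEF and NPQ
    truths mirror the qualitative pattern (lower electron flow, higher NPQ
    in the air-grown mutant).  Noise SDs are calibrated so simulated
    standard errors resemble colony-fluorescence error-bar scale.
    """
    phi_sigma = 0.02
    tef_sigma = 1.0
    npq_sigma = 0.05

    # (etr_max, i_k) per (genotype, light, co2)
    phi_truth = {
        ("WT", "SL", "air"): (30.0, 150.0),
        ("pyr", "SL", "air"): (18.0, 130.0),
        ("WT", "LL", "air"): (16.0, 110.0),
        ("pyr", "LL", "air"): (12.0, 100.0),
        ("WT", "SL", "5pct"): (32.0, 160.0),
        ("pyr", "SL", "5pct"): (32.0, 160.0),
        ("WT", "LL", "5pct"): (18.0, 120.0),
        ("pyr", "LL", "5pct"): (18.0, 120.0),
    }
    npq_truth = {
        key: (1.8 if (g == "pyr" and c == "air") else 1.0, 250.0, 2.0)
        for key in phi_truth
        for g, _, c in [key]
    }

    treatments: dict[str, dict[str, TreatmentTruth]] = {}
    for (g, l, c), (etr_max, i_k) in phi_truth.items():
        label = treatment_label(g, l, c)
        treatments[label] = {
            "phi_ii": TreatmentTruth("phi_ii", (etr_max, i_k), phi_sigma),
            "tef": TreatmentTruth("tef", (1.15 * etr_max, i_k), tef_sigma),
            "npq": TreatmentTruth("npq", npq_truth[(g, l, c)], npq_sigma),
        }
    scenario = Scenario(treatments=treatments, seed=seed)
    scenario.validate()
    return scenario


def _draw_phi(rng: np.random.Generator, mu: np.ndarray, sigma: float) -> np.ndarray:
    """Normal draws reject-redrawn into [0, 1] (phi_II is a proportion)."""
    if np.any(mu < -5 * sigma) or np.any(mu > 1 + 5 * sigma):
        raise ValueError(
            "phi_II mean outside [0,1] by more than 5 sigma; scenario inconsistent"
        )
    out = rng.normal(mu, sigma)
    bad = (out < 0) | (out > 1)
    while np.any(bad):
        out[bad] = rng.normal(mu[bad], sigma)
        bad = (out < 0) | (out > 1)
    return out


def generate(
    scenario: Scenario,
    kinds: tuple[str, ...] = ("phi_ii",),
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate a dataset: one row per (treatment, replicate, intensity, kind).

    Responses are the deterministic curve plus independent N(0, sigma)
    noise; phi_II draws are redrawn until inside [0, 1].  Deterministic
    given the seed (argument overrides scenario.seed).
    """
    scenario.validate()
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    grid = np.asarray(scenario.intensities, dtype=float)
    rows = []
    for label, truths in scenario.treatments.items():
        for kind in kinds:
            truth = truths[kind]
            n_rep = scenario.replicates[kind]
            mu = np.tile(evaluate_model(kind, grid, np.asarray(truth.params)), n_rep)
            if kind == "phi_ii":
                resp = _draw_phi(rng, mu, truth.sigma)
            else:
                resp = rng.normal(mu, truth.sigma)
            rows.append(
                pd.DataFrame(
                    {
                        "treatment": label,
                        "replicate": np.repeat(np.arange(1, n_rep + 1), grid.size),
                        "intensity": np.tile(grid, n_rep),
                        "response": resp,
                        "response_kind": kind,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


def induction_lag_curve(t_grid, lag: float, plateau: float, tau: float = 5.0) -> np.ndarray:
    """Fluorescence-induction-shaped time course: flat, then rise to plateau.

    Zero until ``lag`` seconds, then a smooth saturating rise with time
    constant ``tau``.  A plotting fixture only — no inference is run on it.
    """
    if lag < 0:
        raise ValueError("lag must be >= 0")
    t = np.asarray(t_grid, dtype=float)
    return np.where(t <= lag, 0.0, plateau * -np.expm1(-(np.maximum(t - lag, 0)) / tau))
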