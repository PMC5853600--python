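"""Deterministic light-response models and unit transformations.

Three families of saturating response are covered:

* PSII operating efficiency (``phi_II``) as a function of actinic intensity,
  in two algebraically equivalent parameterisations: the classical
  exponential-saturation form in terms of the maximum efficiency ``phi_m``
  and the light-saturation intensity ``I_k``, and an electron-transport
  parameterisation in terms of ``ETR_max`` that is easier to interpret when
  the data are presented as electron transport rates.
* Total electron flow (TEF), the same exponential saturation expressed
  directly in rate units.
* Non-photochemical quenching (NPQ), a Hill-type sigmoid dose-response.

All functions are vectorised over intensity.  Intensities are photon flux
densities in µmol photons m⁻² s⁻¹ throughout; rates are µmol e⁻ m⁻² s⁻¹.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "AbsorptionConstant",
    "WebbParams",
    "PhotoParams",
    "TEFParams",
    "NPQParams",
    "phi_ii_webb",
    "phi_ii_model",
    "etr_from_phi",
    "tef_model",
    "npq_model",
    "MODEL_PARAM_NAMES",
    "evaluate_model",
]

#: Canonical measurement grid of the colony fluorescence protocol
#: (µmol photons m⁻² s⁻¹).
MEASUREMENT_INTENSITIES = (22.0, 46.0, 106.0, 170.0, 251.0, 356.0, 509.0, 679.0)


def _as_checked_array(x, name: str, *, minimum: float | None = None) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite")
    if minimum is not None and np.any(arr < minimum):
        raise ValueError(f"{name} must be >= {minimum}")
    return arr


@dataclass(frozen=True)
class AbsorptionConstant:
    """Fraction of incident photons absorbed and routed to PSII.

    The default assumes 0.84 of incident light is absorbed and half of the
    absorbed light is allocated to photosystem II, giving a_II = 0.42.
    Both components are assumptions, not measurements, and may be overridden.
    """

    absorbance: float = 0.84
    psii_fraction: float = 0.5

    @property
    def a_ii(self) -> float:
        return self.absorbance * self.psii_fraction


@dataclass(frozen=True)
class WebbParams:
    """Exponential-saturation curve in efficiency terms.

    phi_m: maximum PSII operating efficiency (dimensionless, 0 < phi_m <= 1).
    i_k: light-saturation intensity (µmol photons m⁻² s⁻¹, > 0).
    """

    phi_m: float
    i_k: float

    def __post_init__(self):
        if not (0 < self.phi_m <= 1):
            raise ValueError("phi_m must lie in (0, 1]")
        if not self.i_k > 0:
            raise ValueError("i_k must be > 0")


@dataclass(frozen=True)
class PhotoParams:
    """Exponential-saturation curve in electron-transport terms.

    etr_max: maximum electron transport rate (µmol e⁻ m⁻² s⁻¹, > 0).
    i_k: light-saturation intensity (µmol photons m⁻² s⁻¹, > 0).

    The effective PSII absorption cross-section is the derived quantity
    ``sigma_ii = etr_max / i_k``; it is not stored separately.
    """

    etr_max: float
    i_k: float

    def __post_init__(self):
        if not (self.etr_max > 0 and self.i_k > 0):
            raise ValueError("etr_max and i_k must be > 0")

    @property
    def sigma_ii(self) -> float:
        return self.etr_max / self.i_k


@dataclass(frozen=True)
class TEFParams:
    """Saturating total-electron-flow curve: tef_max (µmol e⁻ m⁻² s⁻¹), i_k."""

    tef_max: float
    i_k: float

    def __post_init__(self):
        if not (self.tef_max > 0 and self.i_k > 0):
            raise ValueError("tef_max and i_k must be > 0")


@dataclass(frozen=True)
class NPQParams:
    """Hill-type NPQ dose-response.

    npq_max: asymptotic NPQ level (dimensionless, > 0).
    i_50: intensity of half-maximal NPQ (µmol photons m⁻² s⁻¹, > 0).
    n: Hill coefficient controlling sigmoidicity; n > 1 gives a sigmoid
       onset suggestive of cooperative induction.
    """

    npq_max: float
    i_50: float
    n: float

    def __post_init__(self):
        if not (self.npq_max > 0 and self.i_50 > 0 and self.n > 0):
            raise ValueError("npq_max, i_50 and n must all be > 0")


def phi_ii_webb(i, p: WebbParams) -> np.ndarray:
    """PSII operating efficiency, efficiency parameterisation.

    phi_II(I) = phi_m * (I_k / I) * (1 - exp(-I / I_k)).

    The apparent singularity at I = 0 is removable: the Taylor expansion of
    (I_k/I)(1 - exp(-I/I_k)) tends to 1, so the limit phi_m is returned there.
    """
    i = _as_checked_array(i, "intensity", minimum=0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        x = i / p.i_k
        val = p.phi_m * np.where(x > 0, -np.expm1(-x) / np.where(x > 0, x, 1.0), 1.0)
    return val


def phi_ii_model(i, p: PhotoParams, a: AbsorptionConstant = AbsorptionConstant()) -> np.ndarray:
    """PSII operating efficiency, electron-transport parameterisation.

    phi_II(I) = ETR_max / (a_II * I) * (1 - exp(-I / I_k)).

    Undefined at I = 0 (phi_II diverges there in this parameterisation);
    callers needing the I -> 0 limit should use :func:`phi_ii_webb` with
    phi_m = etr_max / (a_ii * i_k).
    """
    i = _as_checked_array(i, "intensity", minimum=0.0)
    if np.any(i == 0):
        raise ValueError(
            "phi_ii_model is undefined at I=0; use phi_ii_webb for the limit"
        )
    return p.etr_max / (a.a_ii * i) * -np.expm1(-i / p.i_k)


def etr_from_phi(phi_ii, i, a: AbsorptionConstant = AbsorptionConstant()) -> np.ndarray:
    """Convert PSII operating efficiency to an electron transport rate.

    ETR = phi_II * I * a_II, in µmol e⁻ m⁻² s⁻¹.
    """
    phi_ii = _as_checked_array(phi_ii, "phi_ii", minimum=0.0)
    if np.any(phi_ii > 1):
        raise ValueError("phi_ii must lie in [0, 1]")
    i = _as_checked_array(i, "intensity", minimum=0.0)
    return phi_ii * i * a.a_ii


def tef_model(i, p: TEFParams) -> np.ndarray:
    """Total electron flow: TEF(I) = TEF_max * (1 - exp(-I / I_k))."""
    i = _as_checked_array(i, "intensity", minimum=0.0)
    return p.tef_max * -np.expm1(-i / p.i_k)


def npq_model(i, p: NPQParams, *, literal_printed_form: bool = False) -> np.ndarray:
    """Hill-type NPQ response.

    Default (symmetric Hill form):

        NPQ(I) = NPQ_max * I**n / (I_50**n + I**n)

    which satisfies NPQ(I_50) = NPQ_max / 2 for every n.  With
    ``literal_printed_form=True`` the denominator's second term is I rather
    than I**n — a dimensionally asymmetric variant retained only so the two
    conventions can be compared explicitly; it is never chosen silently.
    """
    i = _as_checked_array(i, "intensity", minimum=0.0)
    num = np.power(i, p.n, where=i > 0, out=np.zeros_like(i))
    denom = p.i_50 ** p.n + (i if literal_printed_form else num)
    return p.npq_max * num / denom


# ---------------------------------------------------------------------------
# Uniform evaluation surface for the sampler: natural-scale parameter vectors.

MODEL_PARAM_NAMES = {
    "phi_ii": ("etr_max", "i_k"),
    "tef": ("tef_max", "i_k"),
    "npq": ("npq_max", "i_50", "n"),
}


def evaluate_model(kind: str, i, theta, a_ii: float = 0.42) -> np.ndarray:
    """Evaluate a response model from a natural-scale parameter vector.

    theta follows MODEL_PARAM_NAMES[kind].  Used by the likelihood, the
    credible-band machinery and the synthetic-data generator; raises
    KeyError for an unknown kind.
    """
    i = np.asarray(i, dtype=float)
    if kind == "phi_ii":
        etr_max, i_k = theta
        return etr_max / (a_ii * i) * -np.expm1(-i / i_k)
    if kind == "tef":
        tef_max, i_k = theta
        return tef_max * -np.expm1(-i / i_k)
    if kind == "npq":
        npq_max, i_50, n = theta
        num = np.power(i, n, where=i > 0, out=np.zeros_like(i))
        return npq_max * num / (i_50 ** n + num)
    raise KeyError(f"unknown response kind: {kind!r}")
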