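"""Population PK model of piperacillin in febrile neutropenia.

The final population model is a one-compartment model whose clearance
scales with Cockcroft–Gault creatinine clearance through a power model,

    CL_i = theta_cl * (CrCL_i / crcl_ref) ** beta_crcl * exp(eta_CL + kappa_CL),
    V_i  = theta_v  * exp(eta_V),

with between-subject (eta) and between-occasion (kappa) variability as
log-normal (exponential) random effects, and a combined residual-error
model ``y = f + (a + b * f) * eps`` with ``eps ~ N(0, 1)`` (the "combined1"
convention of the estimation software the parameters were reported from).

The default parameter set is the published population estimate for
febrile-neutropenic hematological patients: CL 12.0 L/h at the reference
CrCL of 99.3 mL/min, Vd 29.8 L, CrCL exponent 0.64, BSV 36.2 / 57.3 CV%
on CL / Vd, BOV 16.4 CV% on CL, residual a = 5.5 mg/L, b = 0.20.
Printed variabilities are CV% of log-normal effects and are converted to
the standard deviation of the log via ``omega = sqrt(log(1 + cv^2))``
(toggleable to the plain ``omega = cv`` reading).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path
from typing import Literal

import numpy as np
import yaml

__all__ = [
    "PopulationParameters",
    "RandomEffects",
    "cv_percent_to_sd",
    "sd_to_cv_percent",
    "individual_cl",
    "individual_v",
    "sample_random_effects",
    "residual_observe",
]

CvConversion = Literal["lognormal", "direct"]


def cv_percent_to_sd(cv_percent: float, mode: CvConversion = "lognormal") -> float:
    """SD of the log effect from a printed CV%.

    ``lognormal``: exact back-transform ``sqrt(log(1 + cv^2))`` of a
    log-normal coefficient of variation; ``direct``: ``cv`` itself (some
    software prints ``100 * omega`` as "CV%").  For the magnitudes here the
    two differ by < 3%.
    """
    cv = cv_percent / 100.0
    if cv < 0:
        raise ValueError("CV% must be >= 0")
    if mode == "lognormal":
        return float(np.sqrt(np.log1p(cv * cv)))
    if mode == "direct":
        return float(cv)
    raise ValueError(f"unknown conversion mode {mode!r}")


def sd_to_cv_percent(sd: float, mode: CvConversion = "lognormal") -> float:
    """Inverse of :func:`cv_percent_to_sd`."""
    if sd < 0:
        raise ValueError("sd must be >= 0")
    if mode == "lognormal":
        return float(100.0 * np.sqrt(np.expm1(sd * sd)))
    if mode == "direct":
        return float(100.0 * sd)
    raise ValueError(f"unknown conversion mode {mode!r}")


@dataclass(frozen=True)
class PopulationParameters:
    """Fixed effects, variability terms and residual error of the final model.

    Defaults are the published population estimates (see module docstring);
    ``omega``/``gamma`` are SDs of the log-scale random effects.
    """

    theta_cl: float = 12.0  #: population clearance, L/h
    theta_v: float = 29.8  #: population volume, L
    beta_crcl: float = 0.64  #: CrCL exponent on CL
    crcl_ref: float = 99.3  #: reference (population median) CrCL, mL/min
    omega_cl: float = cv_percent_to_sd(36.2)  #: BSV SD of log CL
    omega_v: float = cv_percent_to_sd(57.3)  #: BSV SD of log V
    gamma_cl: float = cv_percent_to_sd(16.4)  #: BOV SD of log CL
    err_a: float = 5.5  #: constant residual SD, mg/L
    err_b: float = 0.20  #: proportional residual coefficient

    def __post_init__(self) -> None:
        for name in ("theta_cl", "theta_v", "crcl_ref"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("omega_cl", "omega_v", "gamma_cl", "err_a", "err_b"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @classmethod
    def from_cv_percent(
        cls,
        bsv_cl_cv: float = 36.2,
        bsv_v_cv: float = 57.3,
        bov_cl_cv: float = 16.4,
        cv_conversion: CvConversion = "lognormal",
        **kwargs,
    ) -> "PopulationParameters":
        """Build a parameter set from printed CV% variabilities."""
        return cls(
            omega_cl=cv_percent_to_sd(bsv_cl_cv, cv_conversion),
            omega_v=cv_percent_to_sd(bsv_v_cv, cv_conversion),
            gamma_cl=cv_percent_to_sd(bov_cl_cv, cv_conversion),
            **kwargs,
        )

    def without_variability(self) -> "PopulationParameters":
        """Copy with all random-effect and residual terms set to zero."""
        return replace(self, omega_cl=0.0, omega_v=0.0, gamma_cl=0.0, err_a=0.0, err_b=0.0)

    # -- plain-text config round trip ------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PopulationParameters":
        return cls(**d)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (
            json.dumps(self.to_dict(), indent=2)
            if path.suffix == ".json"
            else yaml.safe_dump(self.to_dict(), sort_keys=False)
        )
        path.write_text(text)

    @classmethod
    def load(cls, path: str | Path) -> "PopulationParameters":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data)


@dataclass
class RandomEffects:
    """Sampled log-scale random effects for a cohort.

    ``eta_cl``/``eta_v`` have shape (n_subjects,), ``kappa_cl`` has shape
    (n_subjects, n_occasions).
    """

    eta_cl: np.ndarray
    eta_v: np.ndarray
    kappa_cl: np.ndarray


def individual_cl(
    pop: PopulationParameters,
    crcl: np.ndarray | float,
    eta_cl: np.ndarray | float = 0.0,
    kappa_cl: np.ndarray | float = 0.0,
) -> np.ndarray | float:
    """Individual clearance (L/h) from the covariate power model."""
    crcl_arr = np.asarray(crcl, dtype=float)
    if np.any(crcl_arr <= 0):
        raise ValueError("CrCL must be > 0")
    out = (
        pop.theta_cl
        * (crcl_arr / pop.crcl_ref) ** pop.beta_crcl
        * np.exp(np.asarray(eta_cl) + np.asarray(kappa_cl))
    )
    return float(out) if out.ndim == 0 else out


def individual_v(pop: PopulationParameters, eta_v: np.ndarray | float = 0.0) -> np.ndarray | float:
    """Individual volume of distribution (L)."""
    out = pop.theta_v * np.exp(np.asarray(eta_v, dtype=float))
    return float(out) if out.ndim == 0 else out


def sample_random_effects(
    pop: PopulationParameters,
    n_subjects: int,
    n_occasions: int,
    seed: int | np.random.Generator,
) -> RandomEffects:
    """Draw i.i.d. log-normal random effects for a simulated cohort.

    Reproducible: the same seed yields the same realizations.
    """
    if n_subjects < 1 or n_occasions < 1:
        raise ValueError("n_subjects and n_occasions must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return RandomEffects(
        eta_cl=rng.normal(0.0, pop.omega_cl, size=n_subjects),
        eta_v=rng.normal(0.0, pop.omega_v, size=n_subjects),
        kappa_cl=rng.normal(0.0, pop.gamma_cl, size=(n_subjects, n_occasions)),
    )


def residual_observe(
    f: np.ndarray | float,
    err_a: float,
    err_b: float,
    eps: np.ndarray | float,
) -> np.ndarray | float:
    """Observed concentration under the combined residual model.

    ``y = f + (a + b f) * eps``; negative results are possible (the error is
    additive on the concentration scale) and are handled downstream.
    """
    f_arr = np.asarray(f, dtype=float)
    if np.any(f_arr < 0):
        raise ValueError("model prediction must be >= 0")
    out = f_arr + (err_a + err_b * f_arr) * np.asarray(eps, dtype=float)
    return float(out) if out.ndim == 0 else out
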