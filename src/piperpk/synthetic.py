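"""Synthetic observation datasets emulating the BEATLE sampling design.

No patient-level data are distributable, so estimation is exercised on
simulated cohorts built to match the study design: ~44 febrile-neutropenic
hematological patients on piperacillin-tazobactam 4 g q6h, randomized to a
3 h extended-infusion (EI) or 30 min short-infusion (SI) arm (first dose
as a 30 min infusion for everyone), sampled on three occasions during the
first five days of treatment.  Sparse occasions collect a pre-dose sample
(-10 min) and one at 180 min after infusion start; the third sparse
occasion adds 270 min.  A subgroup per arm undergoes intensive sampling on
one occasion (EI: -10, 180, 210, 240, 270 min; SI: -10, 30, 60, 90, 180,
270 min).

Covariates are drawn to match the published cohort summaries (age mean
55.4 SD 10.2 y; weight median 70, IQI 62.4-77.6 kg; Cockcroft-Gault CrCL
median 96.2, IQI 83.4-125.7 mL/min; 47.7% male; albumin mean 3.4 SD 0.4
g/dL).  Log-normal covariates are moment-matched to the printed
median/inter-quartile interval: mu = log(median) and
sigma = log(q75/q25) / (2 * z_0.75) with z_0.75 = 0.6745.  CrCL varies
mildly across occasions (multiplicative log-normal jitter with median 1,
scaled so the median relative change is ~6.6%).

True concentrations are simulated from the population model with BSV and
BOV, then corrupted with the combined residual-error model; observations
below the assay LLOQ (0.58 mg/L), including negative draws, are flagged
BLQ but retained.  The per-subject truth (random effects, realized CL and
V) is returned as a sidecar table for parameter-recovery scoring.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pk_core import conc_piecewise_cl, events_to_array
from .population import PopulationParameters, individual_cl, individual_v, sample_random_effects
from .regimen import RegimenSpec, build

__all__ = ["CohortSpec", "ObservationDataset", "sampling_schedule", "generate", "LLOQ"]

#: Assay lower limit of quantification, mg/L.
LLOQ = 0.58

Z75 = 0.6744897501960817  # standard normal 75th percentile


def lognormal_from_median_iqi(median: float, q25: float, q75: float) -> tuple[float, float]:
    """(mu, sigma) of a log-normal matched to a printed median and IQI."""
    if not (0 < q25 <= median <= q75):
        raise ValueError("need 0 < q25 <= median <= q75")
    return float(np.log(median)), float(np.log(q75 / q25) / (2.0 * Z75))


@dataclass(frozen=True)
class CohortSpec:
    """Design of a simulated cohort (defaults: the study cohort)."""

    n_subjects: int = 44
    frac_ei: float = 21 / 44  #: fraction randomized to extended infusion
    frac_intensive_ei: float = 10 / 21  #: intensive-sampling fraction, EI arm
    frac_intensive_si: float = 14 / 23  #: intensive-sampling fraction, SI arm
    n_occasions: int = 3
    occasion_days: tuple[int, ...] = (1, 3, 5)  #: treatment day of each occasion
    intensive_occasion: int = 2  #: occasion (1-based) sampled intensively
    age_mean: float = 55.4
    age_sd: float = 10.2
    weight_median: float = 70.0
    weight_iqi: tuple[float, float] = (62.4, 77.6)
    crcl_median: float = 96.2
    crcl_iqi: tuple[float, float] = (83.4, 125.7)
    p_male: float = 0.477
    albumin_mean: float = 3.4
    albumin_sd: float = 0.4
    crcl_bounds: tuple[float, float] = (30.0, 250.0)
    weight_bounds: tuple[float, float] = (35.0, 160.0)
    crcl_occasion_median_variation: float = 0.066  #: median |relative change| across occasions

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.n_occasions != len(self.occasion_days):
            raise ValueError("occasion_days must have n_occasions entries")
        if not (1 <= self.intensive_occasion <= self.n_occasions):
            raise ValueError("intensive_occasion out of range")


@dataclass
class ObservationDataset:
    """Long-format records plus the simulation truth.

    ``records`` uses the pharmacometric long format: one row per dose
    (EVID=1, AMT/DUR set, MDV=1) or observation (EVID=0, DV set), with
    columns ID, OCC, TIME (h), AMT, RATE, DUR, DV, MDV, EVID, CRCL, ARM,
    BLQ plus subject-level covariates (AGE, WT, SEX, ALB).  ``truth`` holds
    the generating random effects and realized parameters per subject.
    """

    records: pd.DataFrame
    truth: pd.DataFrame | None = None
    occasion_boundaries: tuple[float, ...] = ()

    @property
    def n_subjects(self) -> int:
        return self.records["ID"].nunique()

    @property
    def observations(self) -> pd.DataFrame:
        return self.records[self.records["EVID"] == 0]

    @property
    def doses(self) -> pd.DataFrame:
        return self.records[self.records["EVID"] == 1]


# sampling offsets in minutes relative to the start of the reference infusion
_SPARSE_EARLY = (-10.0, 180.0)
_SPARSE_THIRD = (-10.0, 180.0, 270.0)
_INTENSIVE_EI = (-10.0, 180.0, 210.0, 240.0, 270.0)
_INTENSIVE_SI = (-10.0, 30.0, 60.0, 90.0, 180.0, 270.0)


def sampling_schedule(arm: str, occasion_index: int, intensive: bool) -> tuple[float, ...]:
    """Sampling offsets (min, relative to infusion start) for one occasion.

    ``arm`` is "EI" or "SI"; ``occasion_index`` is 1-based.  The intensive
    schedule applies to the single intensively sampled occasion; sparse
    occasions 1-2 collect (-10, 180) and occasion 3 adds 270 min.
    """
    if arm not in ("EI", "SI"):
        raise ValueError(f"arm must be 'EI' or 'SI', got {arm!r}")
    if occasion_index not in (1, 2, 3):
        raise ValueError(f"occasion_index must be in 1..3, got {occasion_index}")
    if intensive:
        return _INTENSIVE_EI if arm == "EI" else _INTENSIVE_SI
    return _SPARSE_THIRD if occasion_index == 3 else _SPARSE_EARLY


def draw_covariates(spec: CohortSpec, n: int, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Draw baseline covariates for ``n`` subjects (see module docstring)."""
    mu_w, sd_w = lognormal_from_median_iqi(spec.weight_median, *spec.weight_iqi)
    mu_c, sd_c = lognormal_from_median_iqi(spec.crcl_median, *spec.crcl_iqi)
    return {
        "age": rng.normal(spec.age_mean, spec.age_sd, n),
        "weight": np.clip(rng.lognormal(mu_w, sd_w, n), *spec.weight_bounds),
        "crcl": np.clip(rng.lognormal(mu_c, sd_c, n), *spec.crcl_bounds),
        "sex": (rng.random(n) < spec.p_male).astype(int),  # 1 = male
        "albumin": rng.normal(spec.albumin_mean, spec.albumin_sd, n),
    }


def _subject_regimen(arm: str, horizon: float) -> RegimenSpec:
    dur = 3.0 if arm == "EI" else 0.5
    return RegimenSpec(
        label=f"study_{arm.lower()}",
        maintenance_dose=4000.0,
        interval=6.0,
        infusion_duration=dur,
        horizon=horizon,
        first_dose_short_infusion=True,
    )


def generate(
    cohort_spec: CohortSpec | None = None,
    pop: PopulationParameters | None = None,
    seed: int | np.random.Generator = 0,
) -> ObservationDataset:
    """Simulate one BEATLE-like observation dataset.

    Deterministic given the seed; the same seed reproduces the dataset.
    """
    spec = cohort_spec or CohortSpec()
    pop = pop or PopulationParameters()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = spec.n_subjects

    # --- arm and intensive-subgroup assignment (exact counts, shuffled) ---
    n_ei = int(round(spec.frac_ei * n))
    arms = np.array(["EI"] * n_ei + ["SI"] * (n - n_ei))
    rng.shuffle(arms)
    intensive = np.zeros(n, dtype=bool)
    for arm, frac in (("EI", spec.frac_intensive_ei), ("SI", spec.frac_intensive_si)):
        idx = np.flatnonzero(arms == arm)
        k = int(round(frac * idx.size))
        intensive[rng.choice(idx, size=k, replace=False)] = True

    # --- covariates ---
    cov = draw_covariates(spec, n, rng)
    age, weight, crcl_base = cov["age"], cov["weight"], cov["crcl"]
    sex, albumin = cov["sex"], cov["albumin"]

    # occasion-level CrCL jitter: median |exp(N(0,s)) - 1| ~ target variation
    s_jit = abs(np.log1p(spec.crcl_occasion_median_variation)) / Z75
    jitter = np.exp(rng.normal(0.0, s_jit, (n, spec.n_occasions)))
    jitter[:, 0] = 1.0  # occasion 1 is the baseline measurement
    crcl_occ = np.clip(crcl_base[:, None] * jitter, *spec.crcl_bounds)

    # --- occasion timing: sampling around a mid-day dose on days 1, 3, 5 ---
    # reference dose = the 12 h dose of the occasion's day (t = 24*(day-1)+12)
    ref_dose_time = np.array([24.0 * (d - 1) + 12.0 for d in spec.occasion_days])
    horizon = 24.0 * max(spec.occasion_days)
    boundaries = [0.0]
    for j in range(spec.n_occasions - 1):
        boundaries.append(24.0 * (spec.occasion_days[j + 1] - 1))
    boundaries.append(horizon)

    eff = sample_random_effects(pop, n, spec.n_occasions, rng)
    cl_occ = individual_cl(pop, crcl_occ, eff.eta_cl[:, None], eff.kappa_cl)
    v = individual_v(pop, eff.eta_v)

    rows = []
    truth_rows = []
    for i in range(n):
        arm = arms[i]
        reg = _subject_regimen(arm, horizon)
        events = events_to_array(build(reg))
        base = {
            "ID": i + 1,
            "ARM": arm,
            "AGE": age[i],
            "WT": weight[i],
            "SEX": sex[i],
            "ALB": albumin[i],
        }
        for start, amt, dur in events:
            occ = int(np.searchsorted(boundaries, start, side="right"))
            occ = min(occ, spec.n_occasions)
            rows.append(
                {
                    **base,
                    "OCC": occ,
                    "TIME": start,
                    "AMT": amt,
                    "RATE": amt / dur,
                    "DUR": dur,
                    "DV": np.nan,
                    "MDV": 1,
                    "EVID": 1,
                    "CRCL": crcl_occ[i, occ - 1],
                    "BLQ": 0,
                }
            )
        # observation times
        obs_times, obs_occ = [], []
        for j in range(spec.n_occasions):
            is_int = intensive[i] and (j + 1 == spec.intensive_occasion)
            offsets = sampling_schedule(arm, j + 1, is_int)
            for off in offsets:
                obs_times.append(ref_dose_time[j] + off / 60.0)
                obs_occ.append(j + 1)
        obs_times = np.asarray(obs_times)
        obs_occ = np.asarray(obs_occ, dtype=int)
        f = conc_piecewise_cl(cl_occ[i], v[i], events, boundaries, obs_times)
        eps = rng.normal(size=f.shape)
        y = f + (pop.err_a + pop.err_b * f) * eps
        for t, occ, fij, yij in zip(obs_times, obs_occ, f, y):
            rows.append(
                {
                    **base,
                    "OCC": int(occ),
                    "TIME": t,
                    "AMT": np.nan,
                    "RATE": np.nan,
                    "DUR": np.nan,
                    "DV": yij,
                    "MDV": 0,
                    "EVID": 0,
                    "CRCL": crcl_occ[i, occ - 1],
                    "BLQ": int(yij < LLOQ),
                }
            )
        truth_rows.append(
            {
                "ID": i + 1,
                "eta_cl": eff.eta_cl[i],
                "eta_v": eff.eta_v[i],
                **{f"kappa_cl_{j + 1}": eff.kappa_cl[i, j] for j in range(spec.n_occasions)},
                **{f"cl_occ_{j + 1}": cl_occ[i, j] for j in range(spec.n_occasions)},
                "v": v[i],
            }
        )

    records = pd.DataFrame(rows).sort_values(["ID", "TIME", "EVID"], kind="stable")
    records = records.reset_index(drop=True)
    return ObservationDataset(
        records=records,
        truth=pd.DataFrame(truth_rows),
        occasion_boundaries=tuple(boundaries),
    )
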