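"""Synthetic severe-TBI cohort generator.

Emulates the statistical structure the profiling method assumes: a small
cohort (default 27 patients with a 7/27 death fraction), low initial GCS
scores (survivors 6.0 vs non-survivors 5.6 on average), 13 CSF mediator
series of 4-13 reading rounds at roughly daily spacing, log-normal
concentrations with outcome-dependent linear/quadratic drifts on the log
scale, and independent missingness.

Concentrations are log-normal because cytokine panels are right-skewed and
non-negative; outcome effects act additively on the log scale, so
``effect_scale`` multiplies log-fold differences between non-survivors and
survivors.  At ``effect_scale = 0`` the two groups' mediator dynamics are
identical by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .cohort import MEDIATOR_PANEL, ClinicalProfile, Cohort, MediatorSeries, Patient


@dataclass(frozen=True)
class MediatorParams:
    """Generating parameters for one mediator.

    ``baseline_median`` (pg/mL) sets the log-scale intercept; ``sigma`` is
    the log-scale noise s.d.; ``death_linear`` / ``death_quad`` are the
    extra log-scale trend coefficients non-survivors receive, evaluated in
    the normalized round position u = (round−1)/(rounds_max−1) ∈ [0, 1].
    """

    baseline_median: float
    sigma: float = 0.5
    death_linear: float = 0.0
    death_quad: float = 0.0


#: Baselines are order-of-magnitude plausible for severe-TBI CSF panels;
#: non-survivor effects concentrate in the canonical pro-inflammatory
#: (TNF-α, IL-6, IL-8, MIP-1α/β, IL-1β) and anti-inflammatory (IL-10) axes.
DEFAULT_MEDIATOR_PARAMS: dict[str, MediatorParams] = {
    "IL1a": MediatorParams(5.0),
    "IL1b": MediatorParams(10.0, death_linear=0.8),
    "IL2": MediatorParams(5.0),
    "IL4": MediatorParams(3.0),
    "IL5": MediatorParams(2.0),
    "IL6": MediatorParams(2000.0, death_linear=1.5),
    "IL8": MediatorParams(1500.0, death_linear=1.0),
    "IL10": MediatorParams(20.0, death_linear=1.5, death_quad=-1.0),
    "IL13": MediatorParams(3.0),
    "MIP1a": MediatorParams(30.0, death_linear=1.0),
    "MIP1b": MediatorParams(100.0, death_linear=0.5),
    "TNFa": MediatorParams(10.0, death_linear=2.0),
    "VEGF": MediatorParams(50.0),
}


@dataclass
class SimulationConfig:
    n_patients: int = 27
    death_fraction: float = 7 / 27
    gcs_mean_surv: float = 6.0
    gcs_mean_death: float = 5.6
    gcs_sd: float = 1.0
    gcs_range: tuple[int, int] = (3, 8)  # severe-TBI admission range
    age_mean_surv: float = 34.0
    age_mean_death: float = 37.9
    age_sd: float = 14.0
    male_fraction: float = 0.9
    rounds_min: int = 4
    rounds_max: int = 13
    round_spacing_hours: float = 24.0
    missing_rate: float = 0.05
    effect_scale: float = 1.0
    mediator_params: dict[str, MediatorParams] = field(
        default_factory=lambda: dict(DEFAULT_MEDIATOR_PARAMS)
    )
    #: class-dependent Bernoulli rates (survivor, non-survivor) for the
    #: clinical flags — mildly informative so stage-0 clustering has signal.
    flag_rates: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "infection": (0.30, 0.45),
            "bleeding": (0.40, 0.60),
            "surgical_decompression": (0.50, 0.60),
            "subarachnoid_hemorrhage": (0.50, 0.70),
        }
    )
    gos_given_survival: tuple[int, ...] = (2, 3, 4, 5)  # uniform
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.death_fraction < 1:
            raise ValueError("death_fraction must lie in (0, 1)")
        if self.rounds_min < 2:
            raise ValueError("rounds_min must be >= 2")
        if self.rounds_min > self.rounds_max:
            raise ValueError("rounds_min must not exceed rounds_max")
        if self.effect_scale < 0:
            raise ValueError("effect_scale must be non-negative")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.n_patients < 1:
            raise ValueError("n_patients must be positive")


@dataclass
class GroundTruth:
    """Per-patient generating state, for generator-vs-estimator checks."""

    outcome_class: dict[str, str]  # patient id -> "death" | "survival"
    trend_coefficients: dict[str, dict[str, tuple[float, float]]]


def _truncated_normal_int(rng, mean, sd, lo, hi) -> int:
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo - 0.5 <= x <= hi + 0.5:
            return int(np.clip(round(x), lo, hi))
    return int(round(np.clip(mean, lo, hi)))


def _simulate_patient(
    rng: np.random.Generator,
    cfg: SimulationConfig,
    pid: str,
    is_death: bool,
    n_rounds: int | None = None,
    missing_rate: float | None = None,
) -> tuple[Patient, dict[str, tuple[float, float]]]:
    miss = cfg.missing_rate if missing_rate is None else missing_rate
    gcs = _truncated_normal_int(
        rng,
        cfg.gcs_mean_death if is_death else cfg.gcs_mean_surv,
        cfg.gcs_sd, *cfg.gcs_range,
    )
    age = float(np.clip(
        rng.normal(cfg.age_mean_death if is_death else cfg.age_mean_surv, cfg.age_sd),
        16.0, 89.0,
    ))
    flags = {
        name: bool(rng.random() < rates[1 if is_death else 0])
        for name, rates in cfg.flag_rates.items()
    }
    clinical = ClinicalProfile(
        age=age,
        sex="male" if rng.random() < cfg.male_fraction else "female",
        gcs=gcs,
        **flags,
    )
    if n_rounds is None:
        n_rounds = int(rng.integers(cfg.rounds_min, cfg.rounds_max + 1))
    denom = max(cfg.rounds_max - 1, 1)
    series: dict[str, MediatorSeries] = {}
    truth: dict[str, tuple[float, float]] = {}
    for m in MEDIATOR_PANEL:
        par = cfg.mediator_params[m]
        lin = cfg.effect_scale * par.death_linear * is_death
        quad = cfg.effect_scale * par.death_quad * is_death
        truth[m] = (lin, quad)
        times, values, rounds = [], [], []
        for j in range(1, n_rounds + 1):
            if rng.random() < miss:
                continue
            u = (j - 1) / denom
            logc = (
                np.log(par.baseline_median)
                + lin * u + quad * u**2
                + rng.normal(0.0, par.sigma)
            )
            t = cfg.round_spacing_hours * (j - 0.5) + rng.uniform(-4.0, 4.0)
            times.append(t)
            values.append(float(np.exp(logc)))
            rounds.append(j)
        series[m] = MediatorSeries(m, np.array(times), np.array(values),
                                   rounds=np.array(rounds, dtype=int))
    gos = 1 if is_death else int(rng.choice(cfg.gos_given_survival))
    patient = Patient(id=pid, clinical=clinical, series=series, gos12=gos)
    return patient, truth


def simulate_cohort(config: SimulationConfig) -> tuple[Cohort, GroundTruth]:
    """Draw a full synthetic cohort; bit-identical under the same config.

    Outcome class is Bernoulli(death_fraction) per patient; rounds per
    patient are uniform on [rounds_min, rounds_max]; readings are dropped
    independently at ``missing_rate``.  Reading rounds are emitted directly
    (they survive missingness, unlike ordinal re-indexing).
    """
    rng = np.random.default_rng(config.seed)
    patients: list[Patient] = []
    classes: dict[str, str] = {}
    truths: dict[str, dict[str, tuple[float, float]]] = {}
    for i in range(config.n_patients):
        pid = f"S{i + 1:03d}"
        is_death = bool(rng.random() < config.death_fraction)
        p, truth = _simulate_patient(rng, config, pid, is_death)
        patients.append(p)
        classes[pid] = "death" if is_death else "survival"
        truths[pid] = truth
    return Cohort(patients), GroundTruth(classes, truths)


def worked_example_cohort(seed: int = 20160) -> Cohort:
    """Deterministic 12-patient cohort with two focal patients.

    Patient ``P11`` — a 29-year-old with GCS 6 who recovers to GOS 4 — and
    patient ``P14`` — a 60-year-old with GCS 7 who dies (GOS 1) — each have
    exactly 12 complete reading rounds, so documentation and integration
    tests can walk a survivor and a non-survivor through all stages.
    """
    cfg = SimulationConfig(n_patients=12, seed=seed)
    rng = np.random.default_rng(seed)
    p11, _ = _simulate_patient(rng, cfg, "P11", is_death=False, n_rounds=12,
                               missing_rate=0.0)
    p11.clinical.age = 29.0
    p11.clinical.gcs = 6
    p11.gos12 = 4
    p14, _ = _simulate_patient(rng, cfg, "P14", is_death=True, n_rounds=12,
                               missing_rate=0.0)
    p14.clinical.age = 60.0
    p14.clinical.gcs = 7
    p14.gos12 = 1
    others = [
        _simulate_patient(rng, cfg, f"S{i:03d}", is_death=rng.random() < cfg.death_fraction)[0]
        for i in range(1, 11)
    ]
    return Cohort([p11, p14, *others])


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    payload = {
        "outcome_class": truth.outcome_class,
        "trend_coefficients": {
            pid: {m: list(c) for m, c in med.items()}
            for pid, med in truth.trend_coefficients.items()
        },
    }
    Path(path).write_text(json.dumps(payload, indent=2))
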