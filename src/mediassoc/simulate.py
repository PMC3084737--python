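"""Synthetic case-control cohorts under an indirect-effect generative model.

Genotypes are drawn at Hardy-Weinberg proportions; genotype shifts smokers'
mean CPD and extends their effective smoking duration; disease risk for
smokers follows the Doll-Peto dose-response in CPD and duration with no
direct genotype term unless configured. Case-control ascertainment is by
rejection sampling from a large source population (transparent, if wasteful,
outcome-dependent sampling). A single seed drives independent sub-streams
per generative stage, so adding a stage never perturbs earlier draws.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .types import GenotypeCountTable, SimulationConfig, StudySummary

__all__ = ["simulate_cohort", "simulate_study_set", "SimulationConfig"]

# reference exposure at which smoking_rr is calibrated
_REF_CPD = 20.0
_REF_DURATION = 30.0
_STAGES = (
    "pilot", "genotype", "smoking", "cpd", "age", "disease", "sampling", "demographics",
)


def _rngs(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STAGES))
    return {name: np.random.default_rng(c) for name, c in zip(_STAGES, children)}


def _smoker_risk(
    cfg: SimulationConfig, cpd: np.ndarray, eff_dur: np.ndarray, g: np.ndarray
) -> np.ndarray:
    dose = ((cpd + 6.0) / (_REF_CPD + 6.0)) ** 2 * (eff_dur / _REF_DURATION) ** 4.5
    risk = cfg.baseline_risk * cfg.smoking_rr * dose
    risk = risk * np.exp(cfg.direct_log_or_per_allele * g)
    return np.clip(risk, 0.0, 0.99)


def _draw_population(cfg: SimulationConfig, n: int, rngs) -> pd.DataFrame:
    g = rngs["genotype"].binomial(2, cfg.raf, size=n)
    smoker = rngs["smoking"].random(n) < (1.0 - cfg.never_smoker_fraction)
    age = rngs["age"].uniform(cfg.age_range[0], cfg.age_range[1], size=n)

    # lognormal CPD whose raw mean shifts by beta_cpd per allele
    mu0 = math.log(cfg.cpd_mean) - 0.5 * cfg.cpd_sd_log**2
    shift = np.log1p(cfg.beta_cpd_per_allele * g / cfg.cpd_mean)
    cpd = np.exp(rngs["cpd"].normal(mu0, cfg.cpd_sd_log, size=n) + shift)
    cpd = np.where(smoker, cpd, np.nan)

    eff_dur = np.clip(age - 22.5 + cfg.beta_duration_per_allele * g, 1.0, None)
    eff_dur = np.where(smoker, eff_dur, np.nan)

    risk = np.where(
        smoker,
        _smoker_risk(cfg, np.nan_to_num(cpd), np.nan_to_num(eff_dur, nan=1.0), g),
        np.clip(cfg.baseline_risk * np.exp(cfg.direct_log_or_per_allele * g), 0.0, 0.99),
    )
    disease = rngs["disease"].random(n) < risk
    return pd.DataFrame(
        {
            "dosage": g.astype(int),
            "smoker": smoker,
            "age": age,
            "cpd": cpd,
            "duration_years": eff_dur,
            "disease": disease,
        }
    )


def _estimated_prevalence(cfg: SimulationConfig, rngs) -> float:
    """Cheap pilot estimate of disease prevalence for sizing the source pool."""
    pilot = _draw_population(cfg, 20_000, rngs)
    prev = float(pilot["disease"].mean())
    return max(prev, 1e-5)


def simulate_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Simulate a case-control cohort; returns the canonical records frame.

    Raises ``RuntimeError`` when the source population yields too few cases
    (or controls); increase ``oversample`` or ``source_size``.
    """
    cfg = config
    rngs = _rngs(cfg.seed)
    if cfg.source_size is not None:
        n_src = int(cfg.source_size)
    else:
        prev = _estimated_prevalence(cfg, rngs)
        n_src = int(
            math.ceil(
                cfg.oversample
                * max(cfg.n_cases / prev, cfg.n_controls / (1.0 - prev))
            )
        )
    pop = _draw_population(cfg, n_src, rngs)

    diseased = np.flatnonzero(pop["disease"].to_numpy())
    healthy = np.flatnonzero(~pop["disease"].to_numpy())
    if len(diseased) < cfg.n_cases or len(healthy) < cfg.n_controls:
        raise RuntimeError(
            f"source population of {n_src} produced {len(diseased)} cases / "
            f"{len(healthy)} controls; need {cfg.n_cases}/{cfg.n_controls} — "
            "increase oversample or source_size"
        )
    samp = rngs["sampling"]
    case_idx = samp.choice(diseased, size=cfg.n_cases, replace=False)
    control_idx = samp.choice(healthy, size=cfg.n_controls, replace=False)

    rows = pop.iloc[np.concatenate([case_idx, control_idx])].reset_index(drop=True)
    n = len(rows)
    status = np.array(["case"] * cfg.n_cases + ["control"] * cfg.n_controls)

    demo = rngs["demographics"]
    sex = np.where(demo.random(n) < cfg.male_fraction, "male", "female")
    current = demo.random(n) < cfg.current_smoker_fraction
    smoking_status = np.where(
        rows["smoker"], np.where(current, "current", "former"), "never"
    )
    fh = demo.random(n) < cfg.family_history_rate
    family_history = [
        bool(f) if s == "case" else None for f, s in zip(fh, status)
    ]

    out = pd.DataFrame(
        {
            "id": [f"S{i:06d}" for i in range(1, n + 1)],
            "status": status,
            "dosage": rows["dosage"].to_numpy(),
            "age": np.round(rows["age"].to_numpy(), 2),
            "sex": sex,
            "smoking_status": smoking_status,
            "cpd": np.round(rows["cpd"].to_numpy(), 2),
            "duration_years": np.round(rows["duration_years"].to_numpy(), 2),
            "family_history": family_history,
        }
    )
    return out


def simulate_study_set(
    k: int,
    true_log_or: float,
    tau2: float,
    size_range: tuple[int, int],
    seed: int,
    raf: float = 0.35,
) -> list[StudySummary]:
    """Simulate per-study genotype counts for meta-analysis fixtures.

    Study-specific true allelic log ORs are N(true_log_or, tau2); case and
    control genotype counts are multinomial at Hardy-Weinberg proportions of
    the implied case/control risk-allele frequencies.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if tau2 < 0:
        raise ValueError("tau2 must be >= 0")
    lo, hi = int(size_range[0]), int(size_range[1])
    if lo < 2 or hi < lo:
        raise ValueError("size_range must satisfy 2 <= lo <= hi")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    studies = []
    p0 = raf
    for i in range(k):
        theta = rng.normal(true_log_or, math.sqrt(tau2))
        odds1 = p0 / (1 - p0) * math.exp(theta)
        p1 = odds1 / (1 + odds1)
        n_cases = int(rng.integers(lo, hi + 1))
        n_controls = int(rng.integers(lo, hi + 1))
        cases = rng.multinomial(n_cases, [(1 - p1) ** 2, 2 * p1 * (1 - p1), p1**2])
        controls = rng.multinomial(n_controls, [(1 - p0) ** 2, 2 * p0 * (1 - p0), p0**2])
        table = GenotypeCountTable(
            label=f"sim{i + 1:02d}", cases=tuple(cases), controls=tuple(controls),
            stratum="synthetic",
        )
        studies.append(
            StudySummary(
                label=table.label, ancestry="synthetic", counts=table,
                n_cases=n_cases, n_controls=n_controls,
            )
        )
    return studies
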