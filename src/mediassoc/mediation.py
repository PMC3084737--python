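"""Dose-response mediation: translate genotype-linked exposure shifts into risk.

The excess-risk model makes lung cancer incidence proportional to
(CPD + 6)^2 * d^4.5, where d is effective smoking duration in years (age
minus 22.5, the age by which regular smoking is typically established). Only
risk *ratios* are used, so the proportionality constant never appears. A
genotype that adds delta_c cigarettes/day and delta_d years of smoking per
allele therefore predicts a per-allele relative risk

    ((c + delta_c + 6) / (c + 6))^2 * ((d + delta_d) / d)^4.5

at baseline exposure (c, d), to be compared with the per-allele odds ratio
observed in a case-control study (rare-disease approximation: OR ~ RR).
"""

from __future__ import annotations

from .types import DollPetoModel, MediationScenario

__all__ = [
    "relative_risk",
    "mediated_or_per_allele",
    "fraction_explained",
    "DollPetoModel",
    "MediationScenario",
]


def relative_risk(
    model: DollPetoModel, cpd_a: float, dur_a: float, cpd_b: float, dur_b: float
) -> float:
    """Risk ratio of exposure (cpd_b, dur_b) relative to (cpd_a, dur_a).

    Durations are effective smoking durations (age - age_offset) and must be
    positive; the model is undefined below the age offset.
    """
    if min(cpd_a, cpd_b) < 0:
        raise ValueError("CPD must be non-negative")
    if min(dur_a, dur_b) <= 0:
        raise ValueError(
            f"duration must be positive (model undefined below age {model.age_offset})"
        )
    cpd_ratio = (cpd_b + model.cpd_offset) / (cpd_a + model.cpd_offset)
    dur_ratio = dur_b / dur_a
    return float(cpd_ratio**model.cpd_exponent * dur_ratio**model.duration_exponent)


def mediated_or_per_allele(model: DollPetoModel, scenario: MediationScenario) -> float:
    """Predicted per-allele relative risk from the scenario's exposure shifts."""
    return relative_risk(
        model,
        scenario.baseline_cpd,
        scenario.baseline_duration,
        scenario.baseline_cpd + scenario.delta_cpd_per_allele,
        scenario.baseline_duration + scenario.delta_duration_per_allele,
    )


def fraction_explained(predicted_rr: float, observed_or: float) -> float:
    """Share of the observed log odds ratio accounted for by the prediction.

    Returns ln(predicted) / ln(observed); values above 1 mean the exposure
    pathway fully accounts for (indeed over-predicts) the observed
    association. Undefined at observed OR = 1.
    """
    if predicted_rr <= 0 or observed_or <= 0:
        raise ValueError("risks must be positive")
    if observed_or == 1.0:
        raise ValueError("fraction undefined when the observed OR is exactly 1")
    import math

    return math.log(predicted_rr) / math.log(observed_or)
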