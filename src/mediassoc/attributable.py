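"""Population attributable risk and familial risk from a heritable exposure.

PAR per locus follows p(OR - 1) / (p(OR - 1) + 1) with p the control
risk-allele frequency; several loci combine multiplicatively assuming
independence. The familial relative risk attributable to a heritable binary
exposure (e.g. persistent smoking) is computed under a liability-threshold
model: exposure liabilities of two relatives are standard bivariate normal
with correlation r = relatedness * h2, the exposure threshold is set by
prevalence, and disease risk is b * rr in the exposed and b otherwise. The
familial RR, E[risk_1 * risk_2] / E[risk]^2, does not depend on b.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
from scipy import stats

from .types import HeritableExposureModel, ParInput

__all__ = [
    "par_locus",
    "par_combined",
    "familial_rr_exposure",
    "exposure_orthant_probs",
    "ParInput",
    "HeritableExposureModel",
]


def par_locus(inp: ParInput) -> float:
    """Population attributable risk of one locus: p(OR-1) / (p(OR-1) + 1)."""
    excess = inp.p * (inp.or_per_allele - 1.0)
    par = excess / (excess + 1.0)
    if inp.or_per_allele < 1.0:
        warnings.warn(
            f"{inp.label or 'locus'}: OR < 1 (protective allele) gives negative PAR",
            stacklevel=2,
        )
    return float(par)


def par_combined(inputs: Sequence[ParInput]) -> float:
    """Combined PAR over independent loci: 1 - prod(1 - PAR_k)."""
    if len(inputs) == 0:
        raise ValueError("need at least one locus")
    pars = np.array([par_locus(i) for i in inputs])
    return float(1.0 - np.prod(1.0 - pars))


def exposure_orthant_probs(model: HeritableExposureModel) -> dict[str, float]:
    """Joint exposure probabilities of a relative pair.

    Returns p11 (both exposed), p10/p01 (one exposed) and p00 under the
    bivariate-normal liability model; marginals equal the prevalence.
    """
    prev = model.prevalence
    r = model.relatedness * model.h2
    t = stats.norm.isf(prev)  # liability threshold
    if abs(r) < 1e-14:
        p11 = prev * prev
    else:
        mvn = stats.multivariate_normal(mean=[0.0, 0.0], cov=[[1.0, r], [r, 1.0]])
        # P(X > t, Y > t) = 1 - 2 Phi(t) + F(t, t)
        p11 = 1.0 - 2.0 * stats.norm.cdf(t) + float(mvn.cdf([t, t]))
    p11 = min(max(p11, 0.0), prev)
    p10 = prev - p11
    p00 = 1.0 - 2.0 * p10 - p11
    return {"p11": float(p11), "p10": float(p10), "p01": float(p10), "p00": float(p00)}


def familial_rr_exposure(model: HeritableExposureModel) -> float:
    """Familial relative risk of disease attributable to the heritable exposure.

    FRR = [p00 + (p10 + p01) rr + p11 rr^2] / ((1 - prev) + prev * rr)^2.
    Equals 1 exactly when h2 = 0 or rr_exposed = 1.
    """
    if model.h2 == 0.0 or model.rr_exposed == 1.0:
        return 1.0
    probs = exposure_orthant_probs(model)
    rr = model.rr_exposed
    prev = model.prevalence
    num = probs["p00"] + (probs["p10"] + probs["p01"]) * rr + probs["p11"] * rr * rr
    den = ((1.0 - prev) + prev * rr) ** 2
    return float(num / den)
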