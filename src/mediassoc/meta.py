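"""From-scratch meta-analysis: fixed effect, DerSimonian-Laird random effects,
Cochran's Q / I2 heterogeneity, Egger's regression test, leave-one-out.

Studies enter on the log-OR scale; from genotype counts the study effect is
the allelic 2x2 log OR (risk vs non-risk allele counts) with Woolf SE. ORs
are exponentiated only for display.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import GenotypeCountTable, MetaResult, StudySummary

__all__ = [
    "summarize_study",
    "pool_fixed",
    "pool_random_dl",
    "egger_test",
    "leave_one_out",
    "funnel_data",
    "EggerResult",
    "MetaAnalysis",
    "StudySummary",
    "MetaResult",
]

Z975 = stats.norm.ppf(0.975)


def _allele_counts_from_table(t: GenotypeCountTable) -> tuple[int, int, int, int]:
    ca = t.cases
    co = t.controls
    cases_risk = ca[1] + 2 * ca[2]
    cases_non = 2 * ca[0] + ca[1]
    controls_risk = co[1] + 2 * co[2]
    controls_non = 2 * co[0] + co[1]
    return cases_risk, cases_non, controls_risk, controls_non


def summarize_study(study: StudySummary) -> tuple[float, float, bool]:
    """Study-specific allelic log OR and SE; flag is True if 0.5-corrected.

    Precomputed (log_or, se_log) pairs pass through unchanged.
    """
    if study.log_or is not None and study.se_log is not None:
        return float(study.log_or), float(study.se_log), False
    if study.allele_counts is not None:
        cells = np.array(study.allele_counts, dtype=float)
    else:
        cells = np.array(_allele_counts_from_table(study.counts), dtype=float)
    corrected = False
    if np.any(cells == 0):
        cells = cells + 0.5
        corrected = True
    a, b, c, d = cells
    log_or = float(np.log(a * d / (b * c)))
    se = float(np.sqrt((1.0 / cells).sum()))
    return log_or, se, corrected


def _effects(studies: Sequence[StudySummary]) -> tuple[np.ndarray, np.ndarray]:
    pairs = [summarize_study(s) for s in studies]
    y = np.array([p[0] for p in pairs])
    se = np.array([p[1] for p in pairs])
    return y, se


def pool_fixed(studies: Sequence[StudySummary]) -> MetaResult:
    """Inverse-variance fixed-effect pooled log OR with Wald CI and Z p."""
    if len(studies) == 0:
        raise ValueError("no studies to pool")
    y, se = _effects(studies)
    w = 1.0 / se**2
    mu = float((w * y).sum() / w.sum())
    se_mu = float(np.sqrt(1.0 / w.sum()))
    z = mu / se_mu
    return MetaResult(
        k=len(studies),
        fixed_log_or=mu,
        fixed_se=se_mu,
        fixed_ci=(mu - Z975 * se_mu, mu + Z975 * se_mu),
        fixed_p=float(2 * stats.norm.sf(abs(z))),
    )


def pool_random_dl(studies: Sequence[StudySummary]) -> MetaResult:
    """DerSimonian-Laird random-effects pooling with Q, tau2 and I2.

    Q = sum w_i (y_i - y_fixed)^2; tau2 = max(0, (Q - (k-1)) / (sum w -
    sum w^2 / sum w)); random weights 1 / (se^2 + tau2); I2 = max(0,
    (Q - (k-1)) / Q); Q p-value from chi2(k-1).
    """
    k = len(studies)
    if k < 2:
        raise ValueError("random-effects tau2 needs k >= 2 studies")
    fixed = pool_fixed(studies)
    y, se = _effects(studies)
    w = 1.0 / se**2
    q = float((w * (y - fixed.fixed_log_or) ** 2).sum())
    c = float(w.sum() - (w**2).sum() / w.sum())
    tau2 = max(0.0, (q - (k - 1)) / c) if c > 0 else 0.0
    wr = 1.0 / (se**2 + tau2)
    mu = float((wr * y).sum() / wr.sum())
    se_mu = float(np.sqrt(1.0 / wr.sum()))
    z = mu / se_mu
    i2 = max(0.0, (q - (k - 1)) / q) if q > 0 else 0.0
    return replace(
        fixed,
        random_log_or=mu,
        random_se=se_mu,
        random_ci=(mu - Z975 * se_mu, mu + Z975 * se_mu),
        random_p=float(2 * stats.norm.sf(abs(z))),
        tau2=tau2,
        q=q,
        q_p=float(stats.chi2.sf(q, k - 1)),
        i2=float(i2),
    )


@dataclass(frozen=True)
class EggerResult:
    intercept: float
    se: float
    p_value: float
    slope: float


def egger_test(studies: Sequence[StudySummary]) -> EggerResult:
    """Egger's funnel-asymmetry test.

    Regresses the standardized effect y_i / se_i on precision 1 / se_i
    (inverse-variance weighted form); the intercept is tested against zero
    by a t-test with k - 2 df. When every study has the same SE the design
    is rank-deficient and the test degenerates to a one-sample t-test of
    the mean standardized deviation from the common effect (k - 1 df).
    """
    k = len(studies)
    if k < 3:
        raise ValueError("Egger's test needs k >= 3 studies")
    y, se = _effects(studies)
    z = y / se
    prec = 1.0 / se
    if np.ptp(prec) < 1e-12:
        fixed = pool_fixed(studies)
        dev = (y - fixed.fixed_log_or) / se
        mean = float(dev.mean())
        se_mean = float(dev.std(ddof=1) / np.sqrt(k))
        t = mean / se_mean if se_mean > 0 else 0.0
        return EggerResult(mean, se_mean, float(2 * stats.t.sf(abs(t), k - 1)), 0.0)
    X = np.column_stack([np.ones(k), prec])
    coef, res_ss, *_ = np.linalg.lstsq(X, z, rcond=None)
    resid = z - X @ coef
    s2 = float(resid @ resid) / (k - 2)
    cov = s2 * np.linalg.inv(X.T @ X)
    se_int = float(np.sqrt(cov[0, 0]))
    t = coef[0] / se_int
    p = float(2 * stats.t.sf(abs(t), k - 2))
    return EggerResult(float(coef[0]), se_int, p, float(coef[1]))


def leave_one_out(studies: Sequence[StudySummary]) -> list[tuple[str, MetaResult]]:
    """Re-pool k times, each excluding one study; labelled by the omitted study."""
    if len(studies) < 2:
        raise ValueError("leave-one-out needs k >= 2 studies")
    out = []
    for i, s in enumerate(studies):
        rest = [t for j, t in enumerate(studies) if j != i]
        pooled = pool_random_dl(rest) if len(rest) >= 2 else pool_fixed(rest)
        out.append((s.label, pooled))
    return out


def funnel_data(studies: Sequence[StudySummary]) -> pd.DataFrame:
    """Per-study log OR and SE for funnel plotting (SE on the y axis)."""
    y, se = _effects(studies)
    return pd.DataFrame(
        {"label": [s.label for s in studies], "log_or": y, "se": se}
    )


class MetaAnalysis:
    """Meta-analysis model built from a list of :class:`StudySummary`.

    ``fit()`` pools under both fixed and random effects (k >= 2) and runs
    Egger's test when k >= 3; the returned :class:`MetaResult` carries the
    pooled estimates, heterogeneity statistics and a ``summary()`` table.
    """

    def __init__(self, studies: Sequence[StudySummary]):
        if len(studies) == 0:
            raise ValueError("no studies")
        self.studies = list(studies)

    def fit(self) -> MetaResult:
        k = len(self.studies)
        result = pool_random_dl(self.studies) if k >= 2 else pool_fixed(self.studies)
        if k >= 3:
            egger = egger_test(self.studies)
            result = replace(
                result, egger_intercept=egger.intercept, egger_p=egger.p_value
            )
        return result

    def leave_one_out(self) -> list[tuple[str, MetaResult]]:
        return leave_one_out(self.studies)

    def funnel_data(self) -> pd.DataFrame:
        return funnel_data(self.studies)
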