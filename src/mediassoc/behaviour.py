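"""Genotype-exposure analyses: smoking intensity, heavy smoking, and trends.

These operate on individual-level records (the canonical records frame, see
``types.RECORD_COLUMNS``). Smokers are subjects with smoking_status former or
current; never-smokers carry no CPD and are excluded from intensity analyses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .types import RafPair, TrendResult, records_to_frame

__all__ = [
    "kruskal_wallis",
    "per_allele_cpd_effect",
    "heavy_smoking_trend",
    "mean_trend_by_genotype",
    "boxcox_lambda",
    "CpdEffect",
    "HeavySmokingResult",
    "MeanTrendResult",
]


def _smokers(records) -> pd.DataFrame:
    df = records_to_frame(records)
    status = df["smoking_status"].astype(str).str.lower()
    return df[status.isin(["former", "current"])]


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TrendResult:
    """Kruskal-Wallis H across genotype groups, tie-corrected, chi2(k-1) p."""
    groups = [np.asarray(g, dtype=float) for g in groups if len(g) > 0]
    if len(groups) < 2:
        raise ValueError("need >= 2 non-empty groups")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return TrendResult(0.0, len(groups) - 1, 1.0, 0, flags=("degenerate",))
    h, p = stats.kruskal(*groups)
    return TrendResult(float(h), len(groups) - 1, float(p), 0)


@dataclass(frozen=True)
class CpdEffect:
    """Per-risk-allele effect on cigarettes per day."""

    slope: float  # on the analysed (possibly log) scale
    se: float
    p_value: float
    cpd_per_allele: float  # back-transformed to raw CPD at the sample mean
    log_scale: bool
    n_used: int


def _ols_slope(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Least-squares slope of y on x with t-test p (2-sided)."""
    res = stats.linregress(x, y)
    return float(res.slope), float(res.stderr), float(res.pvalue)


def per_allele_cpd_effect(records, log_scale: bool = True) -> CpdEffect:
    """Linear trend of (log-)CPD on risk-allele dosage among smokers.

    When ``log_scale``, the trend is tested on log CPD and the slope is
    back-transformed to a raw CPD difference evaluated at the sample mean
    CPD: delta = mean_cpd * (exp(slope) - 1).
    """
    df = _smokers(records).dropna(subset=["cpd", "dosage"])
    if df["dosage"].nunique() < 2:
        raise ValueError("need >= 2 distinct dosage groups with CPD data")
    x = df["dosage"].to_numpy(dtype=float)
    cpd = df["cpd"].to_numpy(dtype=float)
    if np.any(cpd < 0):
        raise ValueError("negative CPD")
    if log_scale:
        if np.any(cpd <= 0):
            raise ValueError("log scale requires strictly positive CPD")
        y = np.log(cpd)
    else:
        y = cpd
    if np.all(y == y[0]):
        return CpdEffect(0.0, 0.0, 1.0, 0.0, log_scale, len(df))
    slope, se, p = _ols_slope(x, y)
    delta = float(cpd.mean() * (np.exp(slope) - 1.0)) if log_scale else slope
    return CpdEffect(slope, se, p, delta, log_scale, len(df))


@dataclass(frozen=True)
class HeavySmokingResult:
    threshold: float
    raf_light: float
    raf_heavy: float
    n_light: int
    n_heavy: int
    trend: TrendResult

    @property
    def raf(self) -> RafPair:
        """Light stratum in the 'controls' slot, heavy in 'cases'."""
        return RafPair(raf_cases=self.raf_heavy, raf_controls=self.raf_light)


def heavy_smoking_trend(records, threshold: float = 20.0) -> HeavySmokingResult:
    """Genotype trend between light (1..threshold) and heavy (>threshold) smokers.

    Dichotomizes CPD at ``threshold``, reports the risk-allele frequency per
    stratum and a Cochran-Armitage trend test of genotype across strata.
    """
    from .association import cochran_armitage_trend
    from .types import GenotypeCountTable

    df = _smokers(records).dropna(subset=["cpd", "dosage"])
    heavy = df["cpd"].to_numpy(dtype=float) > threshold
    if heavy.all() or (~heavy).all():
        raise ValueError(f"one smoking stratum is empty at threshold {threshold}")
    g = df["dosage"].to_numpy(dtype=int)

    def counts(mask: np.ndarray) -> tuple[int, int, int]:
        return tuple(int(np.sum(g[mask] == d)) for d in (0, 1, 2))

    def raf(c: tuple[int, int, int]) -> float:
        n = sum(c)
        return (c[1] + 2 * c[2]) / (2 * n)

    light_counts, heavy_counts = counts(~heavy), counts(heavy)
    table = GenotypeCountTable(
        label=f"heavy>{threshold:g}", cases=heavy_counts, controls=light_counts,
        stratum="heavy-vs-light",
    )
    return HeavySmokingResult(
        threshold=float(threshold),
        raf_light=float(raf(light_counts)),
        raf_heavy=float(raf(heavy_counts)),
        n_light=int((~heavy).sum()),
        n_heavy=int(heavy.sum()),
        trend=cochran_armitage_trend(table),
    )


@dataclass(frozen=True)
class MeanTrendResult:
    means: dict[int, float]
    ns: dict[int, int]
    slope: float  # response units per risk allele
    trend: TrendResult
    adjusted_for: tuple[str, ...] = ()


def mean_trend_by_genotype(
    records, response: str, adjust_for: Optional[Sequence[str]] = None
) -> MeanTrendResult:
    """1-df linear trend of a numeric response across genotype groups.

    With ``adjust_for``, the response is first residualized on the named
    covariates by a linear model (sex handled as an indicator), and the trend
    test runs on the residuals; reported group means stay on the raw scale.
    """
    df = records_to_frame(records)
    needed = ["dosage", response] + list(adjust_for or ())
    sub = df.dropna(subset=[c for c in needed if c in df.columns])
    for c in needed:
        if c not in df.columns:
            raise ValueError(f"unknown column {c!r}")
    x = sub["dosage"].to_numpy(dtype=float)
    y = sub[response].to_numpy(dtype=float)
    means = {int(g): float(y[x == g].mean()) for g in sorted(set(x.astype(int)))}
    ns = {int(g): int(np.sum(x == g)) for g in sorted(set(x.astype(int)))}
    if np.all(y == y[0]):
        return MeanTrendResult(means, ns, 0.0, TrendResult(0.0, 1, 1.0, 0, flags=("constant",)))
    y_test = y
    if adjust_for:
        cols = [np.ones_like(y)]
        for c in adjust_for:
            if c == "sex":
                cols.append((sub["sex"].astype(str).str.lower() == "male").to_numpy(dtype=float))
            else:
                cols.append(sub[c].to_numpy(dtype=float))
        A = np.column_stack(cols)
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        y_test = y - A @ coef
    slope, se, p = _ols_slope(x, y_test)
    tstat = (slope / se) ** 2 if se > 0 else 0.0
    return MeanTrendResult(
        means, ns, float(slope),
        TrendResult(float(tstat), 1, float(p), int(np.sign(slope))),
        adjusted_for=tuple(adjust_for or ()),
    )


def boxcox_lambda(values: Sequence[float]) -> tuple[float, np.ndarray]:
    """Profile-likelihood Box-Cox exponent on [-2, 2] and transformed values.

    Maximizes the Box-Cox log-likelihood over lambda in [-2, 2] (bounded
    scalar optimization, tolerance 1e-4); transform y -> (y^lambda - 1)/lambda,
    log y at lambda = 0.
    """
    y = np.asarray(values, dtype=float)
    if np.any(y <= 0):
        raise ValueError(
            "Box-Cox requires strictly positive values; add a shift constant first"
        )
    res = optimize.minimize_scalar(
        lambda lam: -stats.boxcox_llf(lam, y),
        bounds=(-2.0, 2.0), method="bounded", options={"xatol": 1e-4},
    )
    lam = float(res.x)
    transformed = np.log(y) if abs(lam) < 1e-12 else (y**lam - 1.0) / lam
    return lam, transformed
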