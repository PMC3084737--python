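"""Case-control association statistics from genotype counts or records.

Crude genotype odds ratios use Woolf (log-OR Wald) confidence intervals,
which is what reproduces printed per-genotype CIs from case-control tables.
Per-allele odds ratios come from an additive logistic model fitted to the
grouped counts by Newton/IRLS. The Cochran-Armitage trend test conditions on
the table margins. P-values are two-sided throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import (
    ConvergenceError,
    GenotypeCountTable,
    ORResult,
    RafPair,
    TrendResult,
    records_to_frame,
)

__all__ = [
    "crude_genotype_or",
    "per_allele_or",
    "cochran_armitage_trend",
    "hwe_chi2",
    "adjusted_logistic",
    "allele_frequencies",
    "study_power",
    "cpd_category",
    "GenotypeAssociation",
    "AssociationResults",
]

Z975 = stats.norm.ppf(0.975)

CPD_CATEGORIES = ("0-10", "11-20", "21-30", "31+")


def _wald_or_result(log_or: float, se: float, n_used: int, *, corrected: bool = False,
                    method: str = "", flags: tuple[str, ...] = ()) -> ORResult:
    z = log_or / se
    p = 2.0 * stats.norm.sf(abs(z))
    return ORResult(
        estimate=float(np.exp(log_or)),
        ci_low=float(np.exp(log_or - Z975 * se)),
        ci_high=float(np.exp(log_or + Z975 * se)),
        se_log=float(se),
        p_value=float(p),
        n_used=int(n_used),
        corrected=corrected,
        method=method,
        flags=flags,
    )


def crude_genotype_or(
    table: GenotypeCountTable,
    dosage: int,
    reference_dosage: int = 0,
    continuity_correction: bool = False,
) -> ORResult:
    """Crude odds ratio of one genotype versus a reference genotype.

    CI by Woolf's method: exp(ln OR +/- 1.96 * sqrt(sum of 1/cell)); p from
    the Wald z of ln OR. Zero cells are rejected unless
    ``continuity_correction`` adds 0.5 to all four cells (result flagged).
    """
    if dosage == reference_dosage:
        raise ValueError("dosage and reference_dosage must differ")
    for g in (dosage, reference_dosage):
        if g not in (0, 1, 2):
            raise ValueError("dosage must be 0, 1 or 2")
    a = table.cases[dosage]
    b = table.cases[reference_dosage]
    c = table.controls[dosage]
    d = table.controls[reference_dosage]
    cells = np.array([a, b, c, d], dtype=float)
    corrected = False
    if np.any(cells == 0):
        if not continuity_correction:
            raise ValueError(
                f"{table.label}: zero cell in {dosage} vs {reference_dosage} 2x2 "
                "(pass continuity_correction=True for Haldane 0.5 correction)"
            )
        cells = cells + 0.5
        corrected = True
    a, b, c, d = cells
    log_or = np.log(a * d / (b * c))
    se = np.sqrt((1.0 / cells).sum())
    return _wald_or_result(
        log_or, se, int(round(cells.sum() - (2.0 if corrected else 0.0))),
        corrected=corrected, method="woolf",
    )


def _grouped_logit_irls(
    y: np.ndarray, n: np.ndarray, x: np.ndarray, tol: float = 1e-10, max_iter: int = 100
) -> tuple[np.ndarray, np.ndarray]:
    """Binomial logistic MLE on grouped data; returns (beta, cov).

    Newton-Raphson (IRLS) initialized at beta = 0, intercept = overall
    log-odds; convergence when the log-likelihood change is < tol.
    """
    X = np.column_stack([np.ones_like(x, dtype=float), x.astype(float)])
    tot_y, tot_n = y.sum(), n.sum()
    beta = np.array([np.log(tot_y / (tot_n - tot_y)), 0.0])

    def loglik(b: np.ndarray) -> float:
        eta = X @ b
        return float(y @ eta - n @ np.log1p(np.exp(eta)))

    ll = loglik(beta)
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = n * mu * (1.0 - mu)
        score = X.T @ (y - n * mu)
        info = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - degenerate design
            raise ConvergenceError("singular information matrix") from exc
        beta = beta + step
        ll_new = loglik(beta)
        if not np.isfinite(ll_new) or abs(beta[1]) > 15:
            raise ConvergenceError(
                "logistic fit diverged (complete separation of dosage groups?)"
            )
        if abs(ll_new - ll) < tol:
            eta = X @ beta
            mu = 1.0 / (1.0 + np.exp(-eta))
            cov = np.linalg.inv((X * (n * mu * (1 - mu))[:, None]).T @ X)
            return beta, cov
        ll = ll_new
    raise ConvergenceError("IRLS did not converge in 100 iterations")


def per_allele_or(table: GenotypeCountTable) -> ORResult:
    """Per-allele (additive, log-additive on odds) OR from grouped counts.

    Fits logit P(case | g) = alpha + beta * g by maximum likelihood on the
    three dosage groups; returns exp(beta) with Wald CI and p.
    """
    table.require_nonempty()
    y = np.array(table.cases, dtype=float)
    n = y + np.array(table.controls, dtype=float)
    occupied = n > 0
    if occupied.sum() < 2:
        raise ValueError(f"{table.label}: need >= 2 occupied dosage groups")
    # separation: all cases (or all controls) concentrated at one dosage extreme
    g = np.arange(3, dtype=float)[occupied]
    beta, cov = _grouped_logit_irls(y[occupied], n[occupied], g)
    se = float(np.sqrt(cov[1, 1]))
    return _wald_or_result(beta[1], se, int(n.sum()), method="grouped-logit")


def _exact_trend_p(
    n: np.ndarray, R: int, w: np.ndarray, u_obs: float
) -> float:
    """Exact conditional two-sided p: P(|U| >= |u_obs|) under the
    multivariate hypergeometric null (all case-label assignments given the
    genotype margins, counted with multiplicity)."""
    from math import comb

    n0, n1, n2 = (int(v) for v in n)
    wn = float(w @ n)
    N = n0 + n1 + n2
    total = comb(N, R)
    hits = 0
    for r0 in range(min(n0, R) + 1):
        for r1 in range(min(n1, R - r0) + 1):
            r2 = R - r0 - r1
            if not 0 <= r2 <= n2:
                continue
            u = w[0] * r0 + w[1] * r1 + w[2] * r2 - R * wn / N
            if abs(u) >= abs(u_obs) - 1e-9:
                hits += comb(n0, r0) * comb(n1, r1) * comb(n2, r2)
    return hits / total


def cochran_armitage_trend(
    table: GenotypeCountTable,
    weights: Sequence[float] = (0.0, 1.0, 2.0),
    exact: Optional[bool] = None,
) -> TrendResult:
    """Cochran-Armitage trend chi-square (1 df), margins-conditional variance.

    Under the null, the case counts follow a multivariate hypergeometric
    distribution given the genotype and status margins; the variance of the
    weighted case total uses the finite-population (N - 1) divisor. For
    small tables the chi-square approximation is poor, so the two-sided p
    is computed exactly by enumerating the conditional distribution when
    N <= 30 (or on request via ``exact``); the statistic itself is always
    the asymptotic chi-square.
    """
    table.require_nonempty()
    w = np.asarray(weights, dtype=float)
    if np.allclose(w, w[0]):
        raise ValueError("weights must not all be equal")
    r = np.array(table.cases, dtype=float)
    s = np.array(table.controls, dtype=float)
    n = r + s
    N, R = n.sum(), r.sum()
    if R == 0 or R == N:
        raise ValueError(f"{table.label}: all subjects share one status")
    u = float(w @ r - R * (w @ n) / N)
    var = R * (N - R) / (N - 1.0) * float((w**2 @ n) / N - ((w @ n) / N) ** 2)
    if var <= 0:
        return TrendResult(0.0, 1, 1.0, 0, flags=("degenerate",))
    chi2 = u * u / var
    if exact is None:
        exact = N <= 30
    if exact:
        p = _exact_trend_p(n, int(R), w, u)
        flags = ("exact",)
    else:
        p = float(stats.chi2.sf(chi2, 1))
        flags = ()
    return TrendResult(
        statistic=float(chi2),
        df=1,
        p_value=float(p),
        direction=int(np.sign(u)),
        flags=flags,
    )


def hwe_chi2(controls: Sequence[int]) -> TrendResult:
    """1-df chi-square of genotype counts against Hardy-Weinberg proportions."""
    obs = np.asarray(controls, dtype=float)
    if obs.shape != (3,) or obs.min() < 0:
        raise ValueError("controls must be 3 non-negative counts")
    n = obs.sum()
    if n <= 0:
        raise ValueError("empty sample")
    q = (obs[1] + 2 * obs[2]) / (2 * n)  # risk-allele frequency
    if q in (0.0, 1.0):
        return TrendResult(0.0, 1, 1.0, 0, flags=("monomorphic",))
    exp = n * np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2])
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    return TrendResult(chi2, 1, float(stats.chi2.sf(chi2, 1)), 0)


def cpd_category(cpd: float) -> str:
    """Categorize smoking quantity: 0-10, 11-20, 21-30, 31+ cigarettes/day."""
    if cpd is None or not np.isfinite(cpd) or cpd < 0:
        raise ValueError(f"invalid cpd value {cpd!r}")
    if cpd <= 10:
        return "0-10"
    if cpd <= 20:
        return "11-20"
    if cpd <= 30:
        return "21-30"
    return "31+"


def adjusted_logistic(
    records, covariates: Sequence[str] = ("age", "sex", "cpd_category")
) -> ORResult:
    """Per-allele OR adjusted for covariates by multivariable logistic MLE.

    Dosage enters additively; the pseudo-covariate ``cpd_category`` expands
    CPD into the four indicator categories 0-10 (reference), 11-20, 21-30,
    31+. Rows with missing covariates are dropped listwise; the number
    dropped is recorded in the result flags.
    """
    import statsmodels.api as sm

    df = records_to_frame(records).copy()
    cols = {"dosage"}
    design_parts: list[pd.DataFrame] = []
    df["_case"] = (
        df["status"].astype(str).str.lower().map({"case": 1, "control": 0})
    )
    if df["_case"].isna().any():
        raise ValueError("status must be case/control")
    for cov in covariates:
        if cov == "cpd_category":
            cols.add("cpd")
        elif cov not in df.columns:
            raise ValueError(f"unknown covariate {cov!r}")
        else:
            cols.add(cov)
    work = df.dropna(subset=sorted(cols))
    n_dropped = len(df) - len(work)
    if work["dosage"].nunique() < 2:
        raise ValueError("dosage is constant in the analysed records")

    design_parts.append(work[["dosage"]].astype(float))
    for cov in covariates:
        if cov == "cpd_category":
            cats = work["cpd"].map(cpd_category).astype(
                pd.CategoricalDtype(list(CPD_CATEGORIES))
            )
            dummies = pd.get_dummies(cats, prefix="cpd", drop_first=True, dtype=float)
            design_parts.append(dummies)
        elif cov == "sex":
            design_parts.append(
                (work["sex"].astype(str).str.lower() == "male").astype(float).rename("sex_male").to_frame()
            )
        else:
            design_parts.append(work[[cov]].astype(float))
    X = pd.concat(design_parts, axis=1)
    X = sm.add_constant(X, has_constant="add")
    # empty categories / single-level covariates: drop, don't error
    constant = [
        c for c in X.columns
        if c not in ("const", "dosage") and X[c].nunique() <= 1
    ]
    extra_flags: tuple[str, ...] = ()
    if constant:
        X = X.drop(columns=constant)
        extra_flags = (f"dropped_constant_columns={constant}",)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # name offending columns via pivoted QR
        import scipy.linalg as sla

        _, rmat, piv = sla.qr(X.to_numpy(), pivoting=True)
        bad = [X.columns[i] for i in piv[rank:]]
        raise ValueError(f"singular design matrix; collinear columns: {bad}")
    model = sm.GLM(work["_case"].to_numpy(), X, family=sm.families.Binomial())
    res = model.fit()
    i = list(X.columns).index("dosage")
    flags = ((f"dropped_missing={n_dropped}",) if n_dropped else ()) + extra_flags
    return _wald_or_result(
        float(res.params.iloc[i]), float(res.bse.iloc[i]), len(work),
        method="adjusted-logit", flags=flags,
    )


def allele_frequencies(table: GenotypeCountTable) -> RafPair:
    """Risk-allele frequencies by allele counting: (n1 + 2 n2) / 2N per group."""
    table.require_nonempty()
    def raf(counts: tuple[int, int, int]) -> float:
        c = np.asarray(counts, dtype=float)
        return float((c[1] + 2 * c[2]) / (2 * c.sum()))
    return RafPair(raf(table.cases), raf(table.controls))


def study_power(
    n_cases: int, n_controls: int, raf: float, or_alt: float, alpha: float = 0.05
) -> float:
    """Power of the per-allele (allelic) trend test at significance ``alpha``.

    Non-central chi-square approximation: under the alternative the expected
    allelic log OR is log(or_alt) applied to the control RAF, with variance
    from the four allele cells at the expected frequencies.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if n_cases <= 0 or n_controls <= 0:
        raise ValueError("sample sizes must be positive")
    if not 0.0 < raf < 1.0:
        raise ValueError("raf must be in (0, 1)")
    if or_alt <= 0:
        raise ValueError("or_alt must be positive")
    p0 = raf
    p1 = p0 * or_alt / (1.0 - p0 + p0 * or_alt)
    theta = np.log(p1 / (1 - p1)) - np.log(p0 / (1 - p0))
    var = 1.0 / (2 * n_cases * p1 * (1 - p1)) + 1.0 / (2 * n_controls * p0 * (1 - p0))
    ncp = theta**2 / var
    crit = stats.chi2.isf(alpha, 1)
    return float(stats.ncx2.sf(crit, 1, ncp)) if ncp > 0 else float(alpha)


# ---------------------------------------------------------------------------
# Model-style wrapper


@dataclass(frozen=True)
class AssociationResults:
    """Fitted association results for one genotype count table."""

    table: GenotypeCountTable
    genotype_ors: dict[int, ORResult]
    per_allele: ORResult
    trend: TrendResult
    raf: RafPair
    hwe_controls: TrendResult
    flags: tuple[str, ...] = ()

    def summary(self) -> str:
        t = self.table
        lines = [f"{t.label} ({t.stratum or 'all'}; risk allele {t.risk_allele or '?'})"]
        lines.append(f"  cases {t.cases}  controls {t.controls}")
        for g, res in sorted(self.genotype_ors.items()):
            lines.append(f"  dosage {g} vs 0: {res.summary()}")
        lines.append(f"  per allele: {self.per_allele.summary()}")
        lines.append(
            f"  RAF cases {self.raf.raf_cases:.2f} / controls {self.raf.raf_controls:.2f}"
        )
        lines.append(
            f"  trend chi2 = {self.trend.statistic:.2f}, p = {self.trend.p_value:.3g}; "
            f"HWE (controls) p = {self.hwe_controls.p_value:.2g}"
        )
        if self.flags:
            lines.append("  flags: " + ", ".join(self.flags))
        return "\n".join(lines)


class GenotypeAssociation:
    """Association model for one variant built from a genotype count table.

    ``fit()`` returns an :class:`AssociationResults` bundling the crude
    per-genotype ORs, the additive per-allele OR, the Cochran-Armitage trend
    test, allele frequencies and the control HWE check — one printed table
    row block per call.
    """

    def __init__(self, table: GenotypeCountTable):
        table.require_nonempty()
        self.table = table

    def fit(self, continuity_correction: bool = False) -> AssociationResults:
        t = self.table
        genotype_ors = {
            g: crude_genotype_or(t, g, 0, continuity_correction=continuity_correction)
            for g in (1, 2)
            if (t.cases[g] or continuity_correction) and (t.controls[g] or continuity_correction)
        }
        per = per_allele_or(t)
        raf = allele_frequencies(t)
        flags: tuple[str, ...] = ()
        # direction consistency: a per-allele OR > 1 should come with case RAF
        # above control RAF (and vice versa); flag instead of silently inverting
        if (per.estimate - 1.0) * (raf.raf_cases - raf.raf_controls) < 0:
            flags = ("direction-inconsistent",)
        return AssociationResults(
            table=t,
            genotype_ors=genotype_ors,
            per_allele=per,
            trend=cochran_armitage_trend(t),
            raf=raf,
            hwe_controls=hwe_chi2(t.controls),
            flags=flags,
        )
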