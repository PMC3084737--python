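"""Core domain types shared across the package.

The unit of association analysis is a :class:`GenotypeCountTable` (case and
control counts by risk-allele dosage 0/1/2); exposure and adjusted analyses
operate on individual-level records carried in a :class:`pandas.DataFrame`
with the columns of :data:`RECORD_COLUMNS` (one row per subject, typed as
:class:`IndividualRecord`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeCountTable",
    "ORResult",
    "TrendResult",
    "RafPair",
    "IndividualRecord",
    "RECORD_COLUMNS",
    "records_to_frame",
    "DollPetoModel",
    "MediationScenario",
    "ParInput",
    "HeritableExposureModel",
    "StudySummary",
    "MetaResult",
    "SimulationConfig",
]

RECORD_COLUMNS = (
    "id",
    "status",
    "dosage",
    "age",
    "sex",
    "smoking_status",
    "cpd",
    "duration_years",
    "family_history",
)


class ConvergenceError(RuntimeError):
    """Maximum-likelihood fit failed to converge (e.g. complete separation)."""


@dataclass(frozen=True)
class GenotypeCountTable:
    """Case/control genotype counts indexed by risk-allele dosage 0, 1, 2."""

    label: str
    cases: tuple[int, int, int]
    controls: tuple[int, int, int]
    risk_allele: str = ""
    stratum: str = ""

    def __post_init__(self) -> None:
        cases = tuple(int(c) for c in self.cases)
        controls = tuple(int(c) for c in self.controls)
        if len(cases) != 3 or len(controls) != 3:
            raise ValueError("cases and controls must each hold 3 dosage counts")
        if min(cases) < 0 or min(controls) < 0:
            raise ValueError(f"{self.label}: negative genotype count")
        object.__setattr__(self, "cases", cases)
        object.__setattr__(self, "controls", controls)

    @property
    def n_cases(self) -> int:
        return sum(self.cases)

    @property
    def n_controls(self) -> int:
        return sum(self.controls)

    @property
    def n_total(self) -> int:
        return self.n_cases + self.n_controls

    def require_nonempty(self) -> None:
        if self.n_cases == 0 or self.n_controls == 0:
            raise ValueError(f"{self.label}: needs cases and controls (> 0 each)")

    def reversed_dosage(self) -> "GenotypeCountTable":
        """Swap allele labelling: dosage g becomes 2 - g."""
        return GenotypeCountTable(
            label=self.label,
            cases=self.cases[::-1],
            controls=self.controls[::-1],
            risk_allele=self.risk_allele,
            stratum=self.stratum,
        )


@dataclass(frozen=True)
class ORResult:
    """Odds ratio with Woolf/Wald 95% CI on the log scale."""

    estimate: float
    ci_low: float
    ci_high: float
    se_log: float
    p_value: float
    n_used: int
    corrected: bool = False
    method: str = ""
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.estimate <= self.ci_high):
            raise ValueError("CI must bracket the estimate")
        if min(self.estimate, self.ci_low, self.ci_high) <= 0:
            raise ValueError("odds ratios and CI bounds must be positive")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value outside [0, 1]")

    def summary(self) -> str:
        tag = " (continuity-corrected)" if self.corrected else ""
        s = (
            f"OR {self.estimate:.2f} (95% CI {self.ci_low:.2f}-{self.ci_high:.2f}), "
            f"p = {self.p_value:.3g}, n = {self.n_used}{tag}"
        )
        if self.flags:
            s += " [" + ", ".join(self.flags) + "]"
        return s

    def to_dict(self) -> dict:
        d = asdict(self)
        d["flags"] = list(self.flags)
        return d


@dataclass(frozen=True)
class TrendResult:
    """A 1-df (or k-1 df) trend / heterogeneity style test."""

    statistic: float
    df: int
    p_value: float
    direction: int = 0
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value outside [0, 1]")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["flags"] = list(self.flags)
        return d


@dataclass(frozen=True)
class RafPair:
    raf_cases: float
    raf_controls: float

    def __post_init__(self) -> None:
        for v in (self.raf_cases, self.raf_controls):
            if not 0.0 <= v <= 1.0:
                raise ValueError("risk-allele frequency outside [0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class IndividualRecord:
    """One subject of a case-control cohort.

    ``age`` is age at diagnosis for cases and at sampling for controls.
    Never-smokers carry no cpd / duration (a smoker is a lifetime exposure of
    more than 100 cigarettes). ``family_history`` is recorded for cases only.
    """

    id: str
    status: str  # "case" | "control"
    dosage: int  # 0/1/2 risk alleles
    age: float
    sex: str  # "male" | "female"
    smoking_status: str  # "never" | "former" | "current"
    cpd: Optional[float] = None
    duration_years: Optional[float] = None
    family_history: Optional[bool] = None


def records_to_frame(records: Sequence[IndividualRecord] | pd.DataFrame) -> pd.DataFrame:
    """Coerce a list of records (or an already-built frame) to the canonical frame."""
    if isinstance(records, pd.DataFrame):
        missing = set(RECORD_COLUMNS) - set(records.columns)
        if missing:
            raise ValueError(f"records frame missing columns: {sorted(missing)}")
        return records
    return pd.DataFrame([asdict(r) for r in records], columns=list(RECORD_COLUMNS))


@dataclass(frozen=True)
class DollPetoModel:
    """Power-law excess-risk model: risk proportional to
    (CPD + cpd_offset)^cpd_exponent * duration^duration_exponent,
    with duration measured as age - age_offset ("effective duration")."""

    cpd_offset: float = 6.0
    cpd_exponent: float = 2.0
    age_offset: float = 22.5
    duration_exponent: float = 4.5

    def __post_init__(self) -> None:
        if min(self.cpd_offset, self.cpd_exponent, self.age_offset) <= 0:
            raise ValueError("model parameters must be positive")
        if self.duration_exponent < 0:
            raise ValueError("duration_exponent must be non-negative")


@dataclass(frozen=True)
class MediationScenario:
    """Per-allele exposure shifts to translate into a predicted relative risk."""

    baseline_cpd: float
    baseline_duration: float  # effective smoking duration (age - age_offset), years
    delta_cpd_per_allele: float
    delta_duration_per_allele: float
    observed_or_per_allele: Optional[float] = None

    def __post_init__(self) -> None:
        if self.baseline_cpd < 0:
            raise ValueError("baseline_cpd must be >= 0")
        if self.baseline_duration <= 0:
            raise ValueError("baseline_duration must be > 0")
        if self.observed_or_per_allele is not None and self.observed_or_per_allele <= 0:
            raise ValueError("observed OR must be positive")


@dataclass(frozen=True)
class ParInput:
    """One locus for the population attributable risk formula."""

    p: float  # risk-allele frequency in controls
    or_per_allele: float
    label: str = ""

    def __post_init__(self) -> None:
        if not 0.0 < self.p < 1.0:
            raise ValueError("control risk-allele frequency must be in (0, 1)")
        if self.or_per_allele <= 0:
            raise ValueError("odds ratio must be positive")


@dataclass(frozen=True)
class HeritableExposureModel:
    """Liability-threshold model of a heritable binary exposure driving disease."""

    h2: float  # heritability of exposure liability
    prevalence: float  # exposure prevalence
    rr_exposed: float  # disease relative risk in exposed
    relatedness: float = 0.5  # additive kinship (0.5 = first degree)

    def __post_init__(self) -> None:
        if not 0.0 <= self.h2 <= 1.0:
            raise ValueError("h2 must be in [0, 1]")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must be in (0, 1)")
        if self.rr_exposed <= 0:
            raise ValueError("rr_exposed must be positive")
        if not 0.0 <= self.relatedness <= 1.0:
            raise ValueError("relatedness must be in [0, 1]")


@dataclass(frozen=True)
class StudySummary:
    """One study of a meta-analysis.

    Provide either allelic 2x2 counts (risk vs non-risk allele), a genotype
    count table (converted to allele counts), or a precomputed
    (log_or, se_log) pair.
    """

    label: str
    ancestry: str = ""
    counts: Optional[GenotypeCountTable] = None
    allele_counts: Optional[tuple[int, int, int, int]] = None  # cases_risk, cases_nonrisk, controls_risk, controls_nonrisk
    log_or: Optional[float] = None
    se_log: Optional[float] = None
    n_cases: Optional[int] = None
    n_controls: Optional[int] = None

    def __post_init__(self) -> None:
        has_effect = self.log_or is not None and self.se_log is not None
        if not (has_effect or self.counts is not None or self.allele_counts is not None):
            raise ValueError(f"{self.label}: provide counts or (log_or, se_log)")
        if self.se_log is not None and self.se_log <= 0:
            raise ValueError(f"{self.label}: se_log must be positive")
        if self.allele_counts is not None:
            ac = tuple(int(c) for c in self.allele_counts)
            if len(ac) != 4 or min(ac) < 0:
                raise ValueError(f"{self.label}: allele_counts must be 4 non-negative ints")
            object.__setattr__(self, "allele_counts", ac)


@dataclass(frozen=True)
class MetaResult:
    """Pooled meta-analysis result (log-OR scale internally)."""

    k: int
    fixed_log_or: float
    fixed_se: float
    fixed_ci: tuple[float, float]
    fixed_p: float
    random_log_or: Optional[float] = None
    random_se: Optional[float] = None
    random_ci: Optional[tuple[float, float]] = None
    random_p: Optional[float] = None
    tau2: Optional[float] = None
    q: Optional[float] = None
    q_p: Optional[float] = None
    i2: Optional[float] = None
    egger_intercept: Optional[float] = None
    egger_p: Optional[float] = None

    @property
    def fixed_or(self) -> float:
        return float(np.exp(self.fixed_log_or))

    @property
    def random_or(self) -> Optional[float]:
        return None if self.random_log_or is None else float(np.exp(self.random_log_or))

    def summary(self) -> str:
        lines = [f"Meta-analysis of k = {self.k} studies"]
        lo, hi = np.exp(self.fixed_ci)
        lines.append(
            f"  fixed:  OR {self.fixed_or:.3f} (95% CI {lo:.3f}-{hi:.3f}), p = {self.fixed_p:.3g}"
        )
        if self.random_log_or is not None:
            rlo, rhi = np.exp(self.random_ci)
            lines.append(
                f"  random: OR {self.random_or:.3f} (95% CI {rlo:.3f}-{rhi:.3f}), "
                f"p = {self.random_p:.3g}, tau2 = {self.tau2:.4f}"
            )
            lines.append(
                f"  heterogeneity: Q = {self.q:.3f} (p = {self.q_p:.3g}), I2 = {100 * self.i2:.1f}%"
            )
        if self.egger_intercept is not None:
            lines.append(
                f"  Egger: intercept {self.egger_intercept:.3f}, p = {self.egger_p:.3g}"
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["fixed_ci"] = list(self.fixed_ci)
        if self.random_ci is not None:
            d["random_ci"] = list(self.random_ci)
        return d


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters of a synthetic case-control cohort.

    Disease risk follows the Doll-Peto dose-response in CPD and effective
    smoking duration with no direct genotype term unless
    ``direct_log_or_per_allele`` is set; genotype shifts mean CPD by
    ``beta_cpd_per_allele`` (raw cigarettes/day) and extends effective
    duration by ``beta_duration_per_allele`` years per risk allele.
    """

    n_cases: int = 1000
    n_controls: int = 1000
    raf: float = 0.40
    beta_cpd_per_allele: float = 1.0
    beta_duration_per_allele: float = 1.0
    direct_log_or_per_allele: float = 0.0
    cpd_mean: float = 18.0  # mean CPD of dosage-0 smokers (control-like)
    cpd_sd_log: float = 0.45
    never_smoker_fraction: float = 0.37
    current_smoker_fraction: float = 0.37  # of smokers
    age_range: tuple[float, float] = (45.0, 75.0)
    baseline_risk: float = 4e-4  # never-smoker disease probability
    smoking_rr: float = 10.0  # smoker risk multiplier at baseline dose (20 CPD / 30 y)
    male_fraction: float = 0.5
    family_history_rate: float = 0.14
    oversample: float = 1.5
    source_size: Optional[int] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValueError("sample sizes must be positive")
        for name in ("raf", "never_smoker_fraction", "current_smoker_fraction", "male_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0.0 < self.raf < 1.0:
            raise ValueError("raf must be in (0, 1)")
        if self.age_range[0] >= self.age_range[1]:
            raise ValueError("age_range must be increasing")
        if self.baseline_risk <= 0 or self.baseline_risk >= 1:
            raise ValueError("baseline_risk must be in (0, 1)")
        if self.cpd_mean <= 0 or self.cpd_sd_log <= 0:
            raise ValueError("cpd parameters must be positive")
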