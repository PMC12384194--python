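"""Cohort-level inference on whole-brain complexity summaries.

Implements the statistical battery for a two-group (ASD vs Control)
cohort carrying age, three Wechsler IQ indices (FIQ, VIQ, PIQ) and three
whole-brain complexity summaries (Hurst H, fApEn, fSampEn):

* Pearson correlations with Fisher (arctanh) 95% confidence intervals
  and two-tailed t-based p-values;
* within-group correlation matrices over the 7 variables (21 pairs) with
  Benjamini-Hochberg FDR correction at q = 0.05;
* Fisher r-to-z comparison of a correlation between the two groups;
* independent (pooled-variance Student) t-tests of group mean
  differences;
* moderation (Group x mean-centred entropy) OLS models predicting PIQ,
  with the group coded ASD = 1, Control = 2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sst
from statsmodels.stats.multitest import multipletests

__all__ = [
    "COHORT_COLUMNS",
    "CohortTable",
    "CorrelationResult",
    "GroupComparison",
    "TTestResult",
    "InteractionModel",
    "read_cohort_csv",
    "write_cohort_csv",
    "pearson_with_ci",
    "fisher_compare",
    "correlation_matrix",
    "fdr_bh",
    "independent_ttest",
    "interaction_model",
]

COHORT_COLUMNS = (
    "id", "group", "age", "fiq", "viq", "piq", "hurst", "fapen", "fsampen",
)
ANALYSIS_VARS = ("age", "fiq", "viq", "piq", "hurst", "fapen", "fsampen")
GROUPS = ("ASD", "Control")
GROUP_CODES = {"ASD": 1.0, "Control": 2.0}

# exact normal quantile for 95% two-sided; reproduces printed CI bounds to
# 3 decimals (1.96 gives the same printed values)
_Z95 = sst.norm.ppf(0.975)


@dataclass(frozen=True)
class CohortTable:
    """Per-subject phenotypes plus whole-brain complexity summaries."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in COHORT_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"cohort table missing column(s): {missing}")
        bad_groups = set(df["group"]) - set(GROUPS)
        if bad_groups:
            raise ValueError(f"unknown group label(s): {sorted(bad_groups)}")
        num = df[list(ANALYSIS_VARS)]
        if num.isna().any().any():
            bad = num.columns[num.isna().any()].tolist()
            raise ValueError(f"missing values in column(s): {bad}")
        object.__setattr__(self, "frame", df.reset_index(drop=True))

    def group(self, label: str) -> pd.DataFrame:
        if label not in GROUPS:
            raise ValueError(f"unknown group {label!r}")
        return self.frame[self.frame["group"] == label]

    def group_sizes(self) -> dict:
        return {g: int((self.frame["group"] == g).sum()) for g in GROUPS}

    def require_inferential(self) -> None:
        sizes = self.group_sizes()
        small = {g: n for g, n in sizes.items() if n < 4}
        if small:
            raise ValueError(
                f"need >= 4 subjects per group for inference, got {small}"
            )


def read_cohort_csv(path) -> CohortTable:
    return CohortTable(pd.read_csv(path))


def write_cohort_csv(cohort: CohortTable, path) -> None:
    cohort.frame.to_csv(path, index=False, columns=list(COHORT_COLUMNS))


@dataclass(frozen=True)
class CorrelationResult:
    var_x: str
    var_y: str
    r: float
    n: int
    ci_low: float
    ci_high: float
    p: float

    def asdict(self) -> dict:
        return {
            "pair": f"{self.var_x}-{self.var_y}", "r": self.r, "n": self.n,
            "ci_low": self.ci_low, "ci_high": self.ci_high, "p": self.p,
        }


def pearson_with_ci(x, y, conf: float = 0.95,
                    var_x: str = "x", var_y: str = "y") -> CorrelationResult:
    """Pearson r with a Fisher-transform CI and two-tailed t-based p.

    CI = tanh(atanh(r) ± z_conf / sqrt(n-3)); p from
    t = r*sqrt((n-2)/(1-r^2)) on n-2 degrees of freedom.  Perfect
    correlation collapses the CI onto r itself.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    if n != y.size:
        raise ValueError("x and y must be paired")
    if n < 4:
        raise ValueError(f"need n >= 4 pairs, got {n}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in correlation input")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in a correlation input")
    r, p = sst.pearsonr(x, y)
    r = float(r)
    if abs(r) >= 1.0 - 1e-15:
        r = math.copysign(1.0, r)
        return CorrelationResult(var_x, var_y, r, n, r, r, 0.0)
    zc = sst.norm.ppf(0.5 + conf / 2.0)
    half = zc / math.sqrt(n - 3)
    zr = math.atanh(r)
    return CorrelationResult(
        var_x, var_y, r, n,
        math.tanh(zr - half), math.tanh(zr + half), float(p),
    )


def ci_from_r(r: float, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Fisher CI for a correlation given only (r, n)."""
    if not abs(r) < 1:
        raise ValueError("|r| must be < 1")
    if n < 4:
        raise ValueError("need n >= 4")
    zc = sst.norm.ppf(0.5 + conf / 2.0)
    half = zc / math.sqrt(n - 3)
    zr = math.atanh(r)
    return math.tanh(zr - half), math.tanh(zr + half)


def p_from_r(r: float, n: int) -> float:
    """Two-tailed p for a correlation given only (r, n), via the t map."""
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * sst.t.sf(abs(t), n - 2))


@dataclass(frozen=True)
class GroupComparison:
    z: float
    p: float
    r1: float
    n1: int
    r2: float
    n2: int

    def asdict(self) -> dict:
        return {"z": self.z, "p": self.p, "r1": self.r1, "n1": self.n1,
                "r2": self.r2, "n2": self.n2}


def fisher_compare(r1: float, n1: int, r2: float, n2: int) -> GroupComparison:
    """Fisher r-to-z test of whether two independent correlations differ.

    z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3)), two-tailed
    normal p.
    """
    for r, n in ((r1, n1), (r2, n2)):
        if n < 4:
            raise ValueError(f"need n >= 4, got {n}")
        if not abs(r) < 1:
            raise ValueError(f"|r| must be < 1 for the Fisher transform, got {r}")
    se = math.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    z = (math.atanh(r1) - math.atanh(r2)) / se
    p = float(2.0 * sst.norm.sf(abs(z)))
    return GroupComparison(float(z), p, float(r1), int(n1), float(r2), int(n2))


def correlation_matrix(cohort: CohortTable, group: str,
                       conf: float = 0.95) -> list[CorrelationResult]:
    """All 21 unordered pairs among age, FIQ, VIQ, PIQ, H, fApEn, fSampEn."""
    sub = cohort.group(group)
    if len(sub) < 4:
        raise ValueError(f"group {group!r} has n={len(sub)} < 4")
    out = []
    for i, a in enumerate(ANALYSIS_VARS):
        for b in ANALYSIS_VARS[i + 1:]:
            out.append(pearson_with_ci(sub[a], sub[b], conf, a, b))
    return out


def fdr_bh(pvalues, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: per-test reject flags and adjusted p."""
    p = np.asarray(pvalues, float)
    if p.size == 0:
        return np.zeros(0, bool), np.zeros(0)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float

    def asdict(self) -> dict:
        return {"t": self.t, "df": self.df, "p": self.p,
                "mean_asd": self.mean_a, "sd_asd": self.sd_a,
                "mean_control": self.mean_b, "sd_control": self.sd_b}


def independent_ttest(a, b) -> TTestResult:
    """Two-sided Student t-test with pooled variance, df = n1 + n2 - 2."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        raise ValueError("zero pooled variance")
    t, p = sst.ttest_ind(a, b, equal_var=True)
    return TTestResult(
        float(t), a.size + b.size - 2, float(p),
        float(a.mean()), float(np.std(a, ddof=1)),
        float(b.mean()), float(np.std(b, ddof=1)),
    )


@dataclass(frozen=True)
class InteractionModel:
    """Group x centred-entropy moderation model predicting PIQ.

    ``terms`` maps each predictor (const, group, entropy_c, interaction)
    to its unstandardised B, SE, standardised beta, t, p and 95% CI for
    B.  ``group_slopes`` are the implied per-group entropy slopes
    B_ent + code * B_int under the ASD = 1 / Control = 2 coding.
    """

    entropy_field: str
    terms: dict = field(default_factory=dict)
    r_squared: float = float("nan")
    df_resid: int = 0
    n: int = 0
    group_slopes: dict = field(default_factory=dict)

    def asdict(self) -> dict:
        return {
            "entropy": self.entropy_field, "terms": self.terms,
            "r_squared": self.r_squared, "df_resid": self.df_resid,
            "n": self.n, "group_slopes": self.group_slopes,
        }


def interaction_model(cohort: CohortTable, entropy_field: str,
                      conf: float = 0.95) -> InteractionModel:
    """OLS of PIQ on [1, group, centred entropy, group x centred entropy].

    The entropy is centred on the *full-sample* mean; the group is coded
    ASD = 1, Control = 2.  Standardised betas follow the SPSS convention
    B * SD(predictor) / SD(outcome).
    """
    if entropy_field not in ("fapen", "fsampen", "hurst"):
        raise ValueError(f"unknown entropy field {entropy_field!r}")
    df = cohort.frame
    sizes = cohort.group_sizes()
    if min(sizes.values()) == 0:
        raise ValueError("both groups must be present for the moderation model")
    cohort.require_inferential()
    piq = df["piq"].to_numpy(float)
    ent_c = df[entropy_field].to_numpy(float) - df[entropy_field].mean()
    grp = df["group"].map(GROUP_CODES).to_numpy(float)
    design = pd.DataFrame({
        "const": 1.0,
        "group": grp,
        "entropy_c": ent_c,
        "interaction": grp * ent_c,
    })
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        raise ValueError("singular moderation design (degenerate cohort)")
    fit = sm.OLS(piq, design).fit()
    ci = fit.conf_int(alpha=1 - conf)
    sd_y = float(np.std(piq, ddof=1))
    terms = {}
    for name in design.columns:
        sd_x = float(np.std(design[name], ddof=1))
        beta_std = float(fit.params[name] * sd_x / sd_y) if name != "const" else None
        terms[name] = {
            "B": float(fit.params[name]),
            "SE": float(fit.bse[name]),
            "beta": beta_std,
            "t": float(fit.tvalues[name]),
            "p": float(fit.pvalues[name]),
            "ci_low": float(ci.loc[name, 0]),
            "ci_high": float(ci.loc[name, 1]),
        }
    b_ent = terms["entropy_c"]["B"]
    b_int = terms["interaction"]["B"]
    slopes = {g: b_ent + GROUP_CODES[g] * b_int for g in GROUPS}
    return InteractionModel(
        entropy_field=entropy_field,
        terms=terms,
        r_squared=float(fit.rsquared),
        df_resid=int(fit.df_resid),
        n=len(df),
        group_slopes=slopes,
    )
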