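"""Subject-level predictions and the cohort statistical battery.

Covers: personalized stationary seeding predictions from subject PET scans,
Welch two-sample contrasts with Bonferroni adjustment across group pairs,
simple and covariate-adjusted least-squares regressions of empirical tau on
model-predicted seeding (raw and standardized coefficients), diagnosis-
stratified fits, marginal-effect lines, and a bootstrap power estimate.

Standardization convention: continuous terms (predicted seeding, age) and
the outcome are z-scored for the standardized coefficients; binary
indicators (sex, APOE4) stay on their 0/1 scale, so std_beta =
raw_beta * sd(x) / sd(y) holds for every continuous term.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .atlas import RegionAtlas, braak_regions
from .connectome import Connectome
from .pet import ScanRecord
from .transport import AnomalyField, TransportParams, TauTransportModel

__all__ = [
    "GroupComparisonResult",
    "TermEstimate",
    "RegressionResult",
    "predict_subject_seeding",
    "welch_test",
    "pairwise_group_tests",
    "fit_simple_regression",
    "fit_adjusted_regression",
    "stratified_fits",
    "marginal_effect_line",
    "resampling_power",
]

SIGNIFICANCE_LEVELS = (0.05, 0.01, 0.001)


@dataclass(frozen=True)
class GroupComparisonResult:
    group_a: str
    group_b: str
    t: float
    df: float
    p_raw: float
    p_adjusted: float
    m: int

    @property
    def stars(self) -> str:
        for n_star, level in ((3, 0.001), (2, 0.01), (1, 0.05)):
            if self.p_adjusted < level:
                return "*" * n_star
        return "n.s."


@dataclass(frozen=True)
class TermEstimate:
    name: str
    raw_beta: float
    std_beta: Optional[float]
    se: float
    t: float
    p: float
    ci95_low: float
    ci95_high: float


@dataclass(frozen=True)
class RegressionResult:
    n: int
    terms: tuple
    r: Optional[float]       # Pearson r, simple model only
    model_kind: str          # "simple" | "adjusted"

    def term(self, name: str) -> TermEstimate:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)

    def summary(self) -> str:
        head = f"{self.model_kind.capitalize()} least-squares regression (n={self.n})"
        if self.r is not None:
            head += f"   Pearson r = {self.r:.3f}"
        lines = [head, f"  {'term':<12s}{'beta':>10s}{'std':>8s}{'se':>10s}"
                       f"{'t':>8s}{'p':>10s}{'95% CI':>22s}"]
        for t in self.terms:
            std = f"{t.std_beta:.3f}" if t.std_beta is not None else "-"
            lines.append(
                f"  {t.name:<12s}{t.raw_beta:>10.4f}{std:>8s}{t.se:>10.4f}"
                f"{t.t:>8.2f}{t.p:>10.3g}"
                f"   [{t.ci95_low:.4f}, {t.ci95_high:.4f}]"
            )
        return "\n".join(lines)


def predict_subject_seeding(scan: ScanRecord, conn: Connectome,
                            params: TransportParams = None,
                            target: Sequence[str] = None) -> float:
    """Subject-level predicted seeding: stationary concentration with the
    subject's (corrected) SUVR pattern as the anomaly field, averaged over
    the target regions (default bilateral entorhinal cortex)."""
    if scan.modality not in ("FDG", "amyloid"):
        raise ValueError("seeding predictions use FDG or amyloid scans")
    atlas = conn.atlas
    if target is None:
        target = sorted(braak_regions(atlas, {1}))
    target = list(target)
    if not target:
        raise ValueError("empty target region set")
    field = AnomalyField(atlas=atlas, values=scan.suvr, modality=scan.modality,
                         provenance="subject")
    res = TauTransportModel(conn, field, params).fit()
    return res.concentration(target)


def welch_test(x: Sequence[float], y: Sequence[float]):
    """Two-sided Welch's t-test: (t, Welch-Satterthwaite df, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        raise ValueError("both samples degenerate (zero variance)")
    res = sps.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def pairwise_group_tests(groups: Mapping[str, Sequence[float]],
                         alpha_levels: Sequence[float] = SIGNIFICANCE_LEVELS) -> list:
    """Welch contrasts over all unordered group pairs with Bonferroni
    adjustment (m = number of pairs actually tested)."""
    usable = {}
    for label, sample in groups.items():
        sample = np.asarray(sample, dtype=float)
        if sample.size < 2:
            warnings.warn(f"group {label!r} has < 2 members; skipped")
            continue
        usable[label] = sample
    if len(usable) < 2:
        raise ValueError("need at least two groups with >= 2 members")
    pairs = list(combinations(sorted(usable), 2))
    m = len(pairs)
    out = []
    for a, b in pairs:
        t, df, p = welch_test(usable[a], usable[b])
        out.append(GroupComparisonResult(
            group_a=a, group_b=b, t=t, df=df, p_raw=p,
            p_adjusted=min(1.0, m * p), m=m,
        ))
    return out


def _terms_from_fit(fit, std_map: Mapping[str, Optional[float]]) -> tuple:
    ci = fit.conf_int(alpha=0.05)
    terms = []
    for name in fit.params.index:
        terms.append(TermEstimate(
            name=name,
            raw_beta=float(fit.params[name]),
            std_beta=std_map.get(name),
            se=float(fit.bse[name]),
            t=float(fit.tvalues[name]),
            p=float(fit.pvalues[name]),
            ci95_low=float(ci.loc[name, 0]),
            ci95_high=float(ci.loc[name, 1]),
        ))
    return tuple(terms)


def fit_simple_regression(x: Sequence[float], y: Sequence[float],
                          name: str = "seeding") -> RegressionResult:
    """OLS of y on x with intercept; slope test is a two-sided t-test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y lengths differ")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.var(x) == 0:
        raise ValueError("constant predictor")
    X = sm.add_constant(pd.DataFrame({name: x}))
    fit = sm.OLS(y, X).fit()
    sdx, sdy = x.std(ddof=1), y.std(ddof=1)
    std_map = {name: float(fit.params[name] * sdx / sdy) if sdy > 0 else None}
    r = float(np.corrcoef(x, y)[0, 1])
    return RegressionResult(n=int(x.size), terms=_terms_from_fit(fit, std_map),
                            r=r, model_kind="simple")


def _check_collinearity(X: pd.DataFrame) -> None:
    mat = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(mat)
    if rank < X.shape[1]:
        sds = mat.std(axis=0)
        offenders = [c for c, s in zip(X.columns, sds) if s == 0 and c != "const"]
        corr = pd.DataFrame(mat, columns=X.columns).corr().abs()
        for a, b in combinations([c for c in X.columns if c != "const"], 2):
            if corr.loc[a, b] > 1 - 1e-10:
                offenders += [a, b]
        raise ValueError(
            f"collinear design matrix (rank {rank} < {X.shape[1]}); "
            f"offending columns: {sorted(set(offenders)) or 'unknown'}"
        )


def fit_adjusted_regression(seeding: Sequence[float],
                            covariates: pd.DataFrame,
                            y: Sequence[float],
                            seeding_name: str = "seeding") -> RegressionResult:
    """OLS of y on predicted seeding plus covariates (age, sex, APOE4).

    Complete cases only.  Standardized coefficients are reported for the
    seeding term and any covariate with more than two distinct values
    (continuous); binary indicators are left raw.
    """
    df = covariates.copy()
    df.insert(0, seeding_name, np.asarray(seeding, dtype=float))
    df["_y"] = np.asarray(y, dtype=float)
    df = df.dropna()
    n = len(df)
    if n <= df.shape[1]:  # predictors + intercept
        raise ValueError(f"too few complete cases (n={n}) for the design")
    yv = df.pop("_y").to_numpy()
    X = df.astype(float)
    sdy = yv.std(ddof=1)
    std_map = {}
    for col in X.columns:
        xv = X[col].to_numpy()
        if np.unique(xv).size > 2:
            std_map[col] = xv.std(ddof=1)  # filled with betas below
        else:
            std_map[col] = None
    Xc = sm.add_constant(X)
    _check_collinearity(Xc)
    fit = sm.OLS(yv, Xc).fit()
    std_betas = {
        col: (float(fit.params[col] * sd / sdy) if sd is not None and sdy > 0 else None)
        for col, sd in std_map.items()
    }
    return RegressionResult(n=n, terms=_terms_from_fit(fit, std_betas),
                            r=None, model_kind="adjusted")


def stratified_fits(cohort: pd.DataFrame, outcome: str = "tau",
                    seeding: str = "seeding",
                    covariate_cols: Sequence[str] = ("age", "sex", "apoe4"),
                    strata: Sequence[str] = ("CN", "MCI", "AD")) -> dict:
    """Separate adjusted regressions within each diagnosis stratum.

    Strata with too few complete cases are reported as skipped (value is a
    string reason instead of a RegressionResult).
    """
    out: dict = {}
    for label in strata:
        sub = cohort[cohort["diagnosis"] == label]
        try:
            out[label] = fit_adjusted_regression(
                sub[seeding], sub[list(covariate_cols)], sub[outcome],
                seeding_name=seeding,
            )
        except ValueError as exc:
            out[label] = f"skipped: {exc}"
    return out


def marginal_effect_line(fit: RegressionResult,
                         covariate_means: Mapping[str, float],
                         seeding_name: str = "seeding"):
    """Outcome-vs-seeding line with covariates held at their means.

    Returns (intercept, slope); the slope equals the fitted raw seeding
    coefficient exactly.
    """
    if fit.model_kind != "adjusted":
        raise ValueError("marginal effects require an adjusted fit")
    intercept = fit.term("const").raw_beta
    for name, mean in covariate_means.items():
        intercept += fit.term(name).raw_beta * float(mean)
    return float(intercept), float(fit.term(seeding_name).raw_beta)


def resampling_power(cohort: pd.DataFrame, n_target: int, reps: int = 2000,
                     alpha: float = 0.05, rng_seed: int = 0,
                     outcome: str = "tau", seeding: str = "seeding",
                     covariate_cols: Sequence[str] = ("age", "sex", "apoe4")) -> float:
    """Bootstrap power of the adjusted seeding test at sample size n_target.

    Subjects are resampled with replacement; each replicate refits the
    adjusted regression and records whether the seeding coefficient is
    significant at ``alpha``.  Degenerate resamples are skipped.
    """
    if n_target > len(cohort):
        raise ValueError("n_target exceeds cohort size")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(rng_seed)
    hits, used = 0, 0
    for _ in range(reps):
        idx = rng.integers(0, len(cohort), size=n_target)
        sub = cohort.iloc[idx]
        try:
            fit = fit_adjusted_regression(
                sub[seeding], sub[list(covariate_cols)], sub[outcome],
                seeding_name=seeding,
            )
        except ValueError:
            continue
        used += 1
        if fit.term(seeding).p < alpha:
            hits += 1
    if used == 0:
        raise RuntimeError("all bootstrap resamples degenerate")
    return hits / used
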