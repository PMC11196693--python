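"""Mixed-model variance partitioning and order-dependent linear decompositions.

The linear mixed model (LMM) has the selected environmental variables as
fixed effects (z-scored, so coefficients are "normalized effects") and
species identity as a random intercept, fitted by REML.  From the fitted
variance components we report:

* marginal R^2  = var(fixed predictions) / (var_fixed + var_random + var_resid)
* adjusted ICC  = var_random / (var_random + var_resid)
* unadjusted ICC = var_random / (var_fixed + var_random + var_resid)

Because species occurrence and environment are correlated in observational
data, the attribution of their shared variance depends on the fitting order.
``anova_order`` exposes this via sequential (type-I) sums of squares with
species fitted before or after the environmental terms, and
``shared_effects`` computes the classic commonality partition of two factors
(individual site, individual species, shared, unexplained) from three
least-squares fits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps

from .dataset import Dataset, yeo_johnson


class LMMError(RuntimeError):
    """The mixed model failed to converge or could not be fitted."""


@dataclass
class VariancePartition:
    """REML variance components of a species-random-intercept model."""

    var_fixed: float
    var_random: float
    var_resid: float
    icc_flavor: str = "adjusted"
    singular: bool = False

    @property
    def _total(self) -> float:
        return self.var_fixed + self.var_random + self.var_resid

    @property
    def r2_marginal(self) -> float:
        return self.var_fixed / self._total

    @property
    def r2_conditional(self) -> float:
        return (self.var_fixed + self.var_random) / self._total

    @property
    def icc_adjusted(self) -> float:
        denom = self.var_random + self.var_resid
        return self.var_random / denom if denom > 0 else 0.0

    @property
    def icc_unadjusted(self) -> float:
        return self.var_random / self._total

    @property
    def icc(self) -> float:
        return self.icc_adjusted if self.icc_flavor == "adjusted" else self.icc_unadjusted


@dataclass
class NormalizedEffect:
    """Fixed-effect coefficient on the z-scored predictor scale."""

    predictor: str
    coefficient: float
    t_value: float
    p_value: float

    @property
    def significant_1pct(self) -> bool:
        return self.p_value < 0.01


def fit_lmm(
    ds: Dataset,
    predictors,
    trait: str,
    transform: str | None = "yeo-johnson",
    icc_flavor: str = "adjusted",
) -> tuple[VariancePartition, list[NormalizedEffect]]:
    """REML fit of trait ~ predictors + (1 | species).

    Predictors are z-scored before fitting; the target is Yeo-Johnson
    transformed by default (``transform`` may also be ``"log"`` or ``None``).
    A near-zero random-intercept variance is reported as ICC 0 with a warning
    rather than an error.  t-tests for the normalized effects use a
    residual-df approximation (df = n - p).
    """
    df = ds.df
    counts = df.groupby("species").size()
    if (counts >= 2).sum() < 2:
        raise LMMError("need >= 2 species with >= 2 records each")
    y = df[trait].to_numpy(float)
    if transform == "yeo-johnson":
        y = yeo_johnson(y).values
    elif transform == "log":
        if (y <= 0).any():
            raise ValueError("log transform undefined for non-positive trait values")
        y = np.log(y)
    elif transform is not None:
        raise ValueError(f"unknown transform {transform!r}")

    predictors = list(predictors)
    if predictors:
        X = df[predictors].to_numpy(float)
        sd = X.std(axis=0, ddof=0)
        if (sd == 0).any():
            bad = predictors[int(np.argwhere(sd == 0)[0][0])]
            raise ValueError(f"predictor {bad!r} is constant; cannot standardize")
        Xz = (X - X.mean(axis=0)) / sd
    else:
        Xz = np.empty((len(df), 0))
    exog = sm.add_constant(Xz, has_constant="add")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(endog=y, exog=exog, groups=df["species"].to_numpy())
        fit = None
        errors = []
        for method in (None, "powell", "cg"):
            try:
                fit = model.fit(reml=True) if method is None else model.fit(reml=True, method=method)
            except Exception as exc:  # statsmodels raises various optimizer errors
                errors.append(str(exc))
                continue
            if fit.converged:
                break
    if fit is None:
        raise LMMError(f"mixed-model fit failed: {errors}")

    var_random = float(np.asarray(fit.cov_re)[0, 0])
    var_resid = float(fit.scale)
    # a random-intercept variance pinned at the boundary shows up either as a
    # tiny estimate or as a non-converged profile; both are the singular case
    singular = var_random < 1e-2 * var_resid
    if not fit.converged and not singular:
        raise LMMError("mixed-model optimizer did not converge")
    if singular:
        warnings.warn("random-intercept variance is ~0; ICC reported as 0", stacklevel=2)
        var_random = 0.0
    fixed_pred = exog @ np.asarray(fit.fe_params)
    var_fixed = float(np.var(fixed_pred))

    part = VariancePartition(var_fixed, var_random, var_resid,
                             icc_flavor=icc_flavor, singular=singular)
    dof = len(df) - exog.shape[1]
    effects = []
    params = np.asarray(fit.fe_params)
    bse = np.asarray(fit.bse_fe)
    for i, name in enumerate(predictors, start=1):
        t = params[i] / bse[i]
        p = 2.0 * sps.t.sf(abs(t), dof)
        effects.append(NormalizedEffect(name, float(params[i]), float(t), float(p)))
    return part, effects


@dataclass
class AnovaDecomposition:
    """Sequential (type-I) sums of squares for one term order."""

    order: str  # "species_first" | "species_last"
    term_ss: dict[str, float]
    residual_ss: float

    @property
    def total_ss(self) -> float:
        return sum(self.term_ss.values()) + self.residual_ss


def _sequential_ss(y: np.ndarray, blocks: list[tuple[str, np.ndarray]]) -> tuple[dict, float]:
    """Type-I sums of squares by nested least-squares model comparison.

    Each block of columns is added in order; its SS is the drop in residual
    SS it produces.  lstsq handles rank-deficient (collinear) designs, in
    which case a later block that is spanned by earlier ones gets SS 0 — the
    order dependence this module is about.
    """
    n = len(y)
    X = np.ones((n, 1))
    resid = y - y.mean()
    sse_prev = float(resid @ resid)
    out: dict[str, float] = {}
    for name, block in blocks:
        X = np.column_stack([X, block])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        sse = float(r @ r)
        out[name] = sse_prev - sse
        sse_prev = sse
    return out, sse_prev


def anova_order(ds: Dataset, predictors, trait: str) -> tuple[AnovaDecomposition, AnovaDecomposition]:
    """Type-I ANOVA with species fitted before vs after the environment.

    The two tables share the same full model (identical residual SS); the SS
    credited to species differs between orders whenever species identity and
    the environmental predictors are correlated.
    """
    predictors = list(predictors)
    y = ds.df[trait].to_numpy(float)
    species_block = ("species", pd.get_dummies(ds.df["species"], dtype=float).to_numpy())
    env_blocks = [(p, ds.df[[p]].to_numpy(float)) for p in predictors]
    out = []
    for order, blocks in (
        ("species_first", [species_block] + env_blocks),
        ("species_last", env_blocks + [species_block]),
    ):
        term_ss, residual_ss = _sequential_ss(y, blocks)
        out.append(AnovaDecomposition(order, term_ss, residual_ss))
    return out[0], out[1]


@dataclass
class SharedEffectDecomposition:
    """Commonality partition of two categorical factors."""

    individual_a: float
    individual_b: float
    shared: float
    unexplained: float
    suppression: bool = False  # negative shared component (flagged, not an error)

    def as_dict(self) -> dict:
        return {
            "individual_site": self.individual_a,
            "individual_species": self.individual_b,
            "shared": self.shared,
            "unexplained": self.unexplained,
            "suppression": self.suppression,
        }


def _factor_r2(df: pd.DataFrame, trait: str, factors: list[str]) -> float:
    rhs = " + ".join(f"C({f})" for f in factors)
    fit = smf.ols(f"{trait} ~ {rhs}", data=df).fit()
    return float(fit.rsquared)


def shared_effects(
    ds: Dataset, trait: str, factor_a: str = "site_id", factor_b: str = "species"
) -> SharedEffectDecomposition:
    """Individual and shared variance of two factors from three least-squares fits.

    With R2(A), R2(B) and R2(A+B): individual_a = R2(A+B) - R2(B),
    individual_b = R2(A+B) - R2(A), shared = R2(A) + R2(B) - R2(A+B) and
    unexplained = 1 - R2(A+B).  The shared component is the variance that
    cannot be attributed to either factor alone (it goes negative only under
    statistical suppression, which is flagged).
    """
    df = ds.df[[factor_a, factor_b, trait]].copy()
    for f in (factor_a, factor_b):
        if df[f].nunique() < 2:
            raise ValueError(f"factor {f!r} has a single level")
    df = df.rename(columns={trait: "trait_value"})
    r2_a = _factor_r2(df, "trait_value", [factor_a])
    r2_b = _factor_r2(df, "trait_value", [factor_b])
    r2_ab = _factor_r2(df, "trait_value", [factor_a, factor_b])
    shared = r2_a + r2_b - r2_ab
    return SharedEffectDecomposition(
        individual_a=r2_ab - r2_b,
        individual_b=r2_ab - r2_a,
        shared=shared,
        unexplained=1.0 - r2_ab,
        suppression=shared < -1e-10,
    )
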