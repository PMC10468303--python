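"""Mixed-model trait statistics: BLUPs, broad-sense heritability, selection.

The per-trait model is

    Y_ijk = mu + G_i + B_j + L_k + e_ijk

with image group G and experimental batch B as fixed effects and line L as a
random effect, fitted by restricted maximum likelihood.  Broad-sense
heritability is H^2 = sigma2_line / (sigma2_line + sigma2_residual); its 95%
confidence interval comes from a parametric bootstrap (simulate from the
fitted model, refit, percentile interval).

The REML fit is computed by profiling the fixed effects and the residual
variance out of the restricted likelihood and optimising the single variance
ratio lambda = sigma2_line / sigma2_residual.  For one random intercept the
required inverses have closed forms, making a fit cheap enough for the
thousands of refits the bootstrap and the recovery experiments need.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from .metrics import CENTRAL_TRAITS, DISPERSION_TRAITS, METRIC_NAMES

__all__ = [
    "VarianceComponents",
    "HeritabilityEstimate",
    "TraitTaxonomy",
    "InteractionFit",
    "LineBLUPModel",
    "fit_line_model",
    "heritability",
    "correlate_with_human_scores",
    "select_traits",
    "fit_transgene_interaction",
]


@dataclass
class VarianceComponents:
    var_line: float
    var_residual: float
    mu_hat: float
    fixed_effects: dict[str, float]

    @property
    def var_total(self) -> float:
        return self.var_line + self.var_residual


@dataclass
class HeritabilityEstimate:
    h2: float
    ci_low: float
    ci_high: float
    n_boot: int


@dataclass
class TraitTaxonomy:
    central: list[str]
    dispersion: list[str]
    excluded: list[str]
    unclassified: list[str]  # retained but outside the fixed 5+9 taxonomy


@dataclass
class InteractionFit:
    beta_ab42: float
    beta_tau: float
    beta_interaction: float
    p_interaction: float


def _validate_trait_table(data: pd.DataFrame) -> pd.DataFrame:
    required = {"line", "value"}
    if not required.issubset(data.columns):
        raise ValueError("trait table needs 'line' and 'value' columns")
    df = data.copy()
    for col in ("group", "batch"):
        if col not in df.columns:
            df[col] = "_all"
    if df["value"].isna().any():
        raise ValueError("trait table contains missing values")
    if df["line"].nunique() < 2:
        raise ValueError("need at least 2 lines")
    return df


def _design(df: pd.DataFrame, include_fixed: bool) -> tuple[np.ndarray, list[str]]:
    """Intercept plus treatment-coded group/batch dummies."""
    n = len(df)
    cols = [np.ones(n)]
    names = ["intercept"]
    if include_fixed:
        for factor in ("group", "batch"):
            levels = sorted(df[factor].unique())
            for lev in levels[1:]:
                cols.append((df[factor] == lev).to_numpy(dtype=float))
                names.append(f"{factor}[{lev}]")
    return np.column_stack(cols), names


def _reml_profile(
    lam: float,
    y: np.ndarray,
    X: np.ndarray,
    line_idx: np.ndarray,
    counts: np.ndarray,
):
    """Profiled REML pieces at variance ratio lambda.

    With H = I + lam * Z Z', H^{-1} x = x - Z diag(w) Z' x where
    w_k = lam / (1 + lam * n_k), and log|H| = sum log(1 + lam * n_k).
    """
    w = lam / (1.0 + lam * counts)

    def hinv(M: np.ndarray) -> np.ndarray:
        sums = np.zeros((len(counts),) + M.shape[1:])
        np.add.at(sums, line_idx, M)
        return M - (w[:, None] * sums if M.ndim == 2 else w * sums)[line_idx]

    HiX = hinv(X)
    Hiy = hinv(y)
    A = X.T @ HiX
    beta = np.linalg.solve(A, X.T @ Hiy)
    r = y - X @ beta
    q = float(r @ hinv(r))
    n, p = X.shape
    logdet_h = float(np.log1p(lam * counts).sum())
    sign, logdet_a = np.linalg.slogdet(A)
    crit = (n - p) * math.log(max(q, 1e-300)) + logdet_h + logdet_a
    return crit, beta, r, q


def fit_line_model(
    data: pd.DataFrame,
    include_fixed: bool = True,
    tol: float = 1e-8,
) -> tuple[VarianceComponents, pd.DataFrame]:
    """REML fit of the random-intercept line model.

    Returns the variance components and a BLUP table (line, blup, se).
    Negative variance solutions are truncated at the lambda = 0 boundary.
    ``include_fixed=False`` fits the reduced model without group/batch
    fixed effects.
    """
    df = _validate_trait_table(data)
    y = df["value"].to_numpy(dtype=float)
    X, names = _design(df, include_fixed)
    lines, line_idx = np.unique(df["line"].to_numpy(), return_inverse=True)
    counts = np.bincount(line_idx).astype(float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("fixed-effect design is rank deficient")

    def crit_of_log_lambda(t: float) -> float:
        return _reml_profile(math.exp(t), y, X, line_idx, counts)[0]

    res = optimize.minimize_scalar(
        crit_of_log_lambda,
        bounds=(-30.0, 15.0),
        method="bounded",
        options={"xatol": tol},
    )
    if not res.success:
        raise RuntimeError(f"REML optimisation failed: {res.message}")
    lam = math.exp(res.x)
    # boundary check: a ratio this small is numerically zero line variance
    if crit_of_log_lambda(-30.0) <= res.fun + tol:
        lam = 0.0
    crit, beta, r, q = _reml_profile(lam, y, X, line_idx, counts)
    n, p = X.shape
    var_e = q / (n - p)
    var_l = lam * var_e

    # BLUPs: u_k = lam * s_k / (1 + lam * n_k), s_k = sum of GLS residuals
    s = np.bincount(line_idx, weights=r)
    blup = lam * s / (1.0 + lam * counts)
    se = np.sqrt(var_l / (1.0 + lam * counts)) if var_l > 0 else np.zeros_like(blup)
    blups = pd.DataFrame({"line": lines, "blup": blup, "se": se})
    vc = VarianceComponents(
        var_line=float(var_l),
        var_residual=float(var_e),
        mu_hat=float(beta[0]),
        fixed_effects=dict(zip(names[1:], map(float, beta[1:]))),
    )
    return vc, blups


class LineBLUPModel(BaseEstimator):
    """Scikit-learn style estimator for the line mixed model.

    ``fit`` takes a trait table (DataFrame with columns line, group, batch,
    value) and exposes ``var_line_``, ``var_residual_``, ``blups_`` and
    ``h2_``.  ``heritability`` adds a parametric-bootstrap CI.
    """

    def __init__(self, include_fixed: bool = True, tol: float = 1e-8):
        self.include_fixed = include_fixed
        self.tol = tol

    def fit(self, X: pd.DataFrame, y=None):
        df = _validate_trait_table(X)
        vc, blups = fit_line_model(df, self.include_fixed, self.tol)
        self.data_ = df
        self.variance_components_ = vc
        self.var_line_ = vc.var_line
        self.var_residual_ = vc.var_residual
        self.mu_hat_ = vc.mu_hat
        self.fixed_effects_ = vc.fixed_effects
        self.blups_ = blups
        if vc.var_total == 0:
            self.h2_ = float("nan")
        else:
            self.h2_ = vc.var_line / vc.var_total
        return self

    def heritability(
        self, n_boot: int = 1000, seed: int = 0
    ) -> HeritabilityEstimate:
        """Point estimate with a percentile parametric-bootstrap 95% CI."""
        if not hasattr(self, "variance_components_"):
            raise RuntimeError("fit the model before estimating heritability")
        vc = self.variance_components_
        if vc.var_total == 0:
            raise ValueError("total variance is zero; H2 undefined")
        df = self.data_
        X, _ = _design(df, self.include_fixed)
        beta = np.array(
            [vc.mu_hat] + [vc.fixed_effects[k] for k in vc.fixed_effects]
        )
        fixed_part = X @ beta
        lines, line_idx = np.unique(df["line"].to_numpy(), return_inverse=True)
        rng = np.random.default_rng(seed)
        h2s = np.empty(n_boot)
        sd_l = math.sqrt(vc.var_line)
        sd_e = math.sqrt(vc.var_residual)
        sim = df.copy()
        for b in range(n_boot):
            u = rng.normal(0.0, sd_l, len(lines))
            sim["value"] = fixed_part + u[line_idx] + rng.normal(0.0, sd_e, len(df))
            bvc, _ = fit_line_model(sim, self.include_fixed, self.tol)
            h2s[b] = bvc.var_line / bvc.var_total if bvc.var_total > 0 else 0.0
        lo, hi = np.percentile(h2s, [2.5, 97.5])
        return HeritabilityEstimate(
            h2=float(self.h2_), ci_low=float(lo), ci_high=float(hi), n_boot=n_boot
        )


def heritability(
    model: LineBLUPModel | pd.DataFrame,
    n_boot: int = 1000,
    seed: int = 0,
    include_fixed: bool = True,
) -> HeritabilityEstimate:
    """Broad-sense heritability with bootstrap CI.

    Accepts a fitted :class:`LineBLUPModel` or a raw trait table.
    """
    if isinstance(model, pd.DataFrame):
        model = LineBLUPModel(include_fixed=include_fixed).fit(model)
    return model.heritability(n_boot=n_boot, seed=seed)


def correlate_with_human_scores(
    blups_machine: pd.Series, blups_human: pd.Series
) -> tuple[float, float]:
    """Spearman rank correlation between machine and human per-line scores.

    Ties get average ranks; the two-sided large-sample P value is reported.
    Only lines present in both series are used; fewer than 3 matches is an
    error.
    """
    joined = pd.concat(
        [blups_machine.rename("m"), blups_human.rename("h")], axis=1, join="inner"
    ).dropna()
    if len(joined) < 3:
        raise ValueError("need at least 3 matched lines")
    rho, p = stats.spearmanr(joined["m"], joined["h"])
    return float(rho), float(p)


def select_traits(
    h2_by_trait: dict[str, float],
    rho_by_trait: dict[str, float],
    p_by_trait: dict[str, float],
    h2_threshold: float = 0.05,
    p_threshold: float = 0.05,
) -> TraitTaxonomy:
    """Retain traits with H2 > threshold and significant human correlation.

    Retained traits are labelled central or dispersion per the fixed
    taxonomy; retained traits outside it are flagged for review rather than
    silently classified.
    """
    missing = set(METRIC_NAMES) - set(h2_by_trait)
    if missing:
        raise ValueError(f"missing traits: {sorted(missing)}")
    retained = [
        t
        for t in METRIC_NAMES
        if h2_by_trait[t] > h2_threshold and p_by_trait.get(t, 1.0) < p_threshold
    ]
    central = [t for t in retained if t in CENTRAL_TRAITS]
    dispersion = [t for t in retained if t in DISPERSION_TRAITS]
    unclassified = [t for t in retained if t not in central and t not in dispersion]
    excluded = [t for t in METRIC_NAMES if t not in retained]
    if unclassified:
        warnings.warn(
            f"retained traits outside the fixed taxonomy: {unclassified}",
            stacklevel=2,
        )
    return TraitTaxonomy(
        central=central,
        dispersion=dispersion,
        excluded=excluded,
        unclassified=unclassified,
    )


def fit_transgene_interaction(data: pd.DataFrame) -> InteractionFit:
    """Two-way fixed-effect model with interaction for transgene effects.

    ``data`` needs columns ``ab42`` and ``tau`` (0/1 indicators) and
    ``value``; effects are reported relative to the double-negative control
    cell.  All four genotype cells must be represented.
    """
    import statsmodels.api as sm

    for col in ("ab42", "tau", "value"):
        if col not in data.columns:
            raise ValueError(f"missing column '{col}'")
    cells = data.groupby(["ab42", "tau"]).size()
    if len(cells) < 4:
        raise ValueError("all four genotype cells must be represented")
    a = data["ab42"].to_numpy(dtype=float)
    t = data["tau"].to_numpy(dtype=float)
    X = sm.add_constant(np.column_stack([a, t, a * t]))
    fit = sm.OLS(data["value"].to_numpy(dtype=float), X).fit()
    return InteractionFit(
        beta_ab42=float(fit.params[1]),
        beta_tau=float(fit.params[2]),
        beta_interaction=float(fit.params[3]),
        p_interaction=float(fit.pvalues[3]),
    )
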