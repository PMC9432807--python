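"""Mixed-effects modelling of per-cell sSNV density against donor age.

The base model is y_ij = beta * age_j + mu + theta_j + eps_ij with a random
donor intercept theta_j; the cell-type model adds per-type age slopes
(beta + gamma_k) with a random intercept per donor-cell-type pair.

Coefficient estimates come from the maximum-likelihood fit. Inference
(standard errors, confidence intervals, p-values) uses REML standard errors
with a t reference distribution on between-donor degrees of freedom
(n_donors - 2): with only ~10 donor clusters, the naive ML Wald/likelihood-
ratio machinery is markedly anticonservative, while the REML-t approximation
is calibrated (checked by simulation in the test-suite). The ML
likelihood-ratio p-value is still reported as the secondary field
``p_lrt``. When the donor variance component collapses to the boundary the
fit falls back to OLS with donor-clustered standard errors (the tau = 0
limit).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM


@dataclass
class ModelFit:
    params: pd.Series
    bse: pd.Series
    slope: float
    slope_se: float
    slope_ci: tuple[float, float]
    p_age: float
    p_lrt: float
    loglik: float
    df_inference: float
    n_cells: int
    n_donors: int
    per_type_slopes: pd.DataFrame | None = None
    pairwise: pd.DataFrame | None = None
    converged: bool = True


class _OLSAdapter:
    """Shim exposing the MixedLM result surface for the tau=0 boundary fit."""

    def __init__(self, fit, n_fe):
        self._fit = fit
        self.params = np.append(np.asarray(fit.params), 0.0)
        self.bse = np.append(np.asarray(fit.bse), np.nan)
        with np.errstate(divide="ignore"):  # ssr=0 on interpolating fits
            self.llf = float(fit.llf)
        self.converged = True
        self._n_fe = n_fe

    def cov_params(self):
        c = np.asarray(self._fit.cov_params())
        out = np.full((self._n_fe + 1, self._n_fe + 1), np.nan)
        out[: self._n_fe, : self._n_fe] = c
        return out


def _fit_ols(endog, exog, groups):
    import statsmodels.api as sm

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.OLS(endog, exog).fit(cov_type="cluster", cov_kwds={"groups": groups})
    return _OLSAdapter(fit, exog.shape[1])


def _fit_mixed(endog, exog, groups, reml, force_ols=False):
    if not force_ols:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = MixedLM(endog, exog, groups=groups)
                fit = model.fit(reml=reml, method=["lbfgs", "bfgs", "cg"], maxiter=500)
            if np.isfinite(np.asarray(fit.bse[: exog.shape[1]])).all():
                return fit
        except (np.linalg.LinAlgError, ValueError):
            pass
    return _fit_ols(endog, exog, groups)


def _lrt(endog, exog_full, exog_null, groups, df):
    """ML likelihood-ratio p on a consistent likelihood path."""
    full = _fit_mixed(endog, exog_full, groups, reml=False)
    null = _fit_mixed(
        endog, exog_null, groups, reml=False, force_ols=isinstance(full, _OLSAdapter)
    )
    if isinstance(null, _OLSAdapter) and not isinstance(full, _OLSAdapter):
        full = _fit_mixed(endog, exog_full, groups, reml=False, force_ols=True)
    lr = max(0.0, 2.0 * (full.llf - null.llf))
    return full, float(stats.chi2.sf(lr, df=df))


def _clean(densities, ages, donor_ids, cell_types=None, covariates=None):
    df = pd.DataFrame({
        "y": np.asarray(densities, dtype=float),
        "age": np.asarray(ages, dtype=float),
        "donor": np.asarray(donor_ids).astype(str),
    })
    if cell_types is not None:
        df["cell_type"] = np.asarray(cell_types).astype(str)
    if covariates is not None:
        cov = pd.DataFrame(covariates).reset_index(drop=True)
        df = pd.concat([df, cov], axis=1)
    n0 = len(df)
    df = df.dropna()
    if len(df) < n0:
        warnings.warn(f"dropped {n0 - len(df)} cells with missing values")
    return df.reset_index(drop=True)


def _covariate_block(df, covariate_names):
    cols = []
    for name in covariate_names:
        x = df[name].to_numpy(dtype=float)
        r = np.corrcoef(x, df["age"])[0, 1]
        if abs(r) > 0.99:
            warnings.warn(f"covariate {name} is collinear with age (|r|={abs(r):.3f})")
        cols.append(x)
    return np.column_stack(cols) if cols else np.empty((len(df), 0))


def _t_p(est, se, df):
    if se == 0 or not np.isfinite(se):
        return float("nan")
    return float(2.0 * stats.t.sf(abs(est / se), df))


def fit_age_model(densities, ages, donor_ids, covariates=None) -> ModelFit:
    """Random-donor-intercept regression of density on age.

    Optional ``covariates`` (DataFrame, one row per cell) enter as fixed
    effects; the age slope is reported after adjustment.
    """
    cov_df = pd.DataFrame(covariates) if covariates is not None else None
    df = _clean(densities, ages, donor_ids, covariates=cov_df)
    n_donors = df["donor"].nunique()
    if n_donors < 3:
        raise ValueError("need >= 3 donors")
    if np.ptp(df["age"].to_numpy()) == 0:
        raise ValueError("all donor ages equal: age effect unidentifiable")
    cov_names = list(cov_df.columns) if cov_df is not None else []
    Z = _covariate_block(df, cov_names)
    names = ["intercept", "age", *cov_names]
    y = df["y"].to_numpy()
    X = np.column_stack([np.ones(len(df)), df["age"].to_numpy(), Z])
    X0 = np.column_stack([np.ones(len(df)), Z])

    ml_fit, p_lrt = _lrt(y, X, X0, df["donor"], df=1)
    inf_fit = _fit_mixed(y, X, df["donor"], reml=True)

    k = len(names)
    params = pd.Series(np.asarray(ml_fit.params[:k]), index=names)
    bse = pd.Series(np.asarray(inf_fit.bse[:k]), index=names)
    dof = max(n_donors - 2, 1)
    beta, se = float(params["age"]), float(bse["age"])
    tcrit = stats.t.ppf(0.975, dof)
    return ModelFit(
        params=params, bse=bse, slope=beta, slope_se=se,
        slope_ci=(beta - tcrit * se, beta + tcrit * se),
        p_age=_t_p(beta, se, dof), p_lrt=p_lrt,
        loglik=float(ml_fit.llf), df_inference=dof, n_cells=len(df),
        n_donors=n_donors, converged=bool(ml_fit.converged),
    )


def fit_interaction_model(
    densities, ages, donor_ids, cell_types,
    reference_type: str | None = None, covariates=None,
) -> ModelFit:
    """Cell-type x age interaction model with donor-by-type random intercepts.

    Per-type slopes are beta + gamma_k (gamma of the reference type is 0)
    with delta-method intervals; pairwise slope differences are tested with
    the same REML-t inference on the contrast.
    """
    cov_df = pd.DataFrame(covariates) if covariates is not None else None
    df = _clean(densities, ages, donor_ids, cell_types, cov_df)
    types = sorted(df["cell_type"].unique())
    if len(types) < 2:
        raise ValueError("need >= 2 cell types")
    for t in types:
        if df.loc[df["cell_type"] == t, "donor"].nunique() < 2:
            warnings.warn(f"cell type {t} has a single donor")
    ref = reference_type if reference_type is not None else types[0]
    if ref not in types:
        raise ValueError(f"unknown reference type {ref}")
    cov_names = list(cov_df.columns) if cov_df is not None else []
    Zc = _covariate_block(df, cov_names)
    groups = df["donor"] + ":" + df["cell_type"]
    n_donors = df["donor"].nunique()
    dof = max(n_donors - 2, 1)
    y = df["y"].to_numpy()

    cols = [np.ones(len(df)), df["age"].to_numpy()]
    names = ["intercept", "age"]
    for t in types:
        if t == ref:
            continue
        cols.append(df["age"].to_numpy() * (df["cell_type"] == t).to_numpy())
        names.append(f"age:{t}")
    names += cov_names
    X = np.column_stack(cols + ([Zc] if Zc.size else []))
    X00 = np.column_stack([np.ones(len(df))] + ([Zc] if Zc.size else []))

    ml_fit, p_lrt = _lrt(y, X, X00, groups, df=len(types))
    inf_fit = _fit_mixed(y, X, groups, reml=True)

    k = len(names)
    params = pd.Series(np.asarray(ml_fit.params[:k]), index=names)
    bse = pd.Series(np.asarray(inf_fit.bse[:k]), index=names)
    covm = pd.DataFrame(
        np.asarray(inf_fit.cov_params())[:k, :k], index=names, columns=names
    )
    tcrit = stats.t.ppf(0.975, dof)

    def slope_of(t):
        if t == ref:
            return float(params["age"]), float(covm.loc["age", "age"])
        c = f"age:{t}"
        s = float(params["age"] + params[c])
        v = float(covm.loc["age", "age"] + covm.loc[c, c] + 2 * covm.loc["age", c])
        return s, v

    rows = []
    for t in types:
        s, v = slope_of(t)
        se = float(np.sqrt(max(v, 0.0)))
        rows.append({
            "cell_type": t, "slope": s, "se": se,
            "ci_low": s - tcrit * se, "ci_high": s + tcrit * se,
        })
    per_type = pd.DataFrame(rows)

    pair_rows = []
    for i in range(len(types)):
        for j in range(i + 1, len(types)):
            a, b = types[i], types[j]
            ca = f"age:{a}" if a != ref else None
            cb = f"age:{b}" if b != ref else None
            diff = (params[ca] if ca else 0.0) - (params[cb] if cb else 0.0)
            v = 0.0
            for x in (ca, cb):
                if x:
                    v += covm.loc[x, x]
            if ca and cb:
                v -= 2 * covm.loc[ca, cb]
            se = float(np.sqrt(max(v, 0.0)))
            pair_rows.append({
                "type_a": a, "type_b": b, "slope_diff": float(diff),
                "p": _t_p(float(diff), se, dof),
            })
    pairwise = pd.DataFrame(pair_rows)

    beta, se = float(params["age"]), float(bse["age"])
    return ModelFit(
        params=params, bse=bse, slope=beta, slope_se=se,
        slope_ci=(beta - tcrit * se, beta + tcrit * se),
        p_age=_t_p(beta, se, dof), p_lrt=p_lrt,
        loglik=float(ml_fit.llf), df_inference=dof, n_cells=len(df),
        n_donors=n_donors, per_type_slopes=per_type, pairwise=pairwise,
        converged=bool(ml_fit.converged),
    )


def fit_burden_age_model(
    densities, ages, donor_ids, sensitivity, genome_mb, n_iter: int = 3
) -> ModelFit:
    """Measurement-error-aware mixed regression for corrected burdens.

    Sensitivity-corrected densities carry a known, strongly age-dependent
    sampling variance: with raw calls Poisson(lambda) and density =
    raw/(s x G), Var = lambda/(s G)^2, which is ~100-fold larger in aged
    cells than infants at desk scale. A homoscedastic mixed model then
    underestimates the slope uncertainty (the noisiest cells carry the most
    leverage). This fit uses model-implied measurement variances — implied,
    not observed, so the weights stay independent of the realized counts
    and introduce no shrinkage bias — iterating:

    1. lambda_i = (mu + beta x age_j) x G_i x s_i (expected raw calls);
    2. precision-weighted donor means with variance 1/sum(1/V_i);
    3. donor-level weighted regression with a DerSimonian-Laird
       between-donor variance tau^2.

    Inference is t-based on n_donors - 2 degrees of freedom. The p_lrt
    field is not defined for this fit.
    """
    df = pd.DataFrame({
        "y": np.asarray(densities, dtype=float),
        "age": np.asarray(ages, dtype=float),
        "donor": np.asarray(donor_ids).astype(str),
        "s": np.asarray(sensitivity, dtype=float),
        "G": np.asarray(genome_mb, dtype=float),
    }).dropna().reset_index(drop=True)
    n_donors = df["donor"].nunique()
    if n_donors < 3:
        raise ValueError("need >= 3 donors")
    if np.ptp(df["age"].to_numpy()) == 0:
        raise ValueError("all donor ages equal: age effect unidentifiable")
    y = df["y"].to_numpy()
    age = df["age"].to_numpy()
    donors = df["donor"].to_numpy()
    s = df["s"].to_numpy()
    G = df["G"].to_numpy()

    b, mu = np.polyfit(age, y, 1)
    tau2 = 0.0
    a = yb = vb = None
    for _ in range(n_iter):
        lam = np.maximum(mu + b * age, 0.02) * G * s  # expected raw calls
        V = lam / (s**2) / (G**2)
        rows = []
        for d in pd.unique(donors):
            m = donors == d
            w = 1.0 / V[m]
            rows.append((age[m][0], (w * y[m]).sum() / w.sum(), 1.0 / w.sum()))
        a = np.array([r[0] for r in rows])
        yb = np.array([r[1] for r in rows])
        vb = np.array([r[2] for r in rows])
        for _ in range(2):
            w = 1.0 / (vb + tau2)
            W = w.sum()
            xb = (w * a).sum() / W
            Sxx = (w * (a - xb) ** 2).sum()
            b = (w * (a - xb) * yb).sum() / Sxx
            mu = ((w * yb).sum() - b * (w * a).sum()) / W
            resid = yb - b * a - mu
            Q = (w * resid**2).sum()
            c = W - (w**2).sum() / W
            tau2 = max((Q - (len(a) - 2)) / c, 0.0) if c > 0 else 0.0
    w = 1.0 / (vb + tau2)
    W = w.sum()
    xb = (w * a).sum() / W
    Sxx = (w * (a - xb) ** 2).sum()
    se = float(np.sqrt(1.0 / Sxx))
    se_mu = float(np.sqrt(1.0 / W + xb**2 / Sxx))
    dof = max(n_donors - 2, 1)
    tcrit = stats.t.ppf(0.975, dof)
    params = pd.Series({"intercept": float(mu), "age": float(b)})
    bse = pd.Series({"intercept": se_mu, "age": se})
    return ModelFit(
        params=params, bse=bse, slope=float(b), slope_se=se,
        slope_ci=(float(b) - tcrit * se, float(b) + tcrit * se),
        p_age=_t_p(float(b), se, dof), p_lrt=float("nan"),
        loglik=float("nan"), df_inference=dof, n_cells=len(df),
        n_donors=n_donors, converged=True,
    )
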