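"""Family-clustered association models for transmitted/non-transmitted scores.

Each analysis residualizes the outcome on covariates (sex, birth year and
their interaction for adult attainment, ancestry PCs, genotyping platform),
standardizes outcome and predictors within the analysis subset, and fits a
model with one random intercept per family by maximum likelihood:

* continuous outcomes: linear mixed model (``statsmodels`` MixedLM, ML);
* ordinal outcomes: a proportional-odds model with a normal family random
  intercept, integrated with Gauss-Hermite quadrature (implemented here;
  no installed Python package offers a mixed cumulative-logit model).

Reported per-predictor quantities are the standardized coefficient, its
Wald 95% CI and p-value, and the variance explained convention
``r2_pct = 100 * beta_std**2`` (for standardized predictor and outcome the
squared coefficient is the incremental variance share; for ordinal fits it
is applied on the liability scale).

Symptom counts are square-root transformed before residualization to tame
their L-shaped distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy import linalg, optimize, special
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.tools.numdiff import approx_hess1

DEFAULT_ALPHA = 0.01

CHILD_OUTCOMES = ("achievement", "adhd_home", "adhd_school")
SQRT_OUTCOMES = ("adhd_home", "adhd_school")

MODEL_PREDICTORS = {
    "model1": ["PGS_T_EA", "PGS_NT_EA"],
    "model2": ["PGS_T_ADHD", "PGS_NT_ADHD"],
    "model3": ["PGS_T_EA", "PGS_NT_EA", "PGS_T_ADHD", "PGS_NT_ADHD"],
}


@dataclass
class AnalysisSpec:
    outcome: str
    predictors: list[str]
    alpha: float = DEFAULT_ALPHA

    def __post_init__(self) -> None:
        if not self.predictors:
            raise ValueError("predictors must be non-empty")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class FitResult:
    """Per-predictor estimates from a random-intercept fit."""

    params: pd.DataFrame  # predictor, beta_std, ci_low, ci_high, p, r2_pct
    loglik: float
    n_used: int
    converged: bool
    sigma_family: float

    def significant(self, alpha: float = DEFAULT_ALPHA) -> pd.Series:
        return self.params["p"] < alpha


def impute_scale_items(items: pd.DataFrame,
                       max_missing_frac: float = 0.2) -> pd.Series:
    """Sum-score a symptom scale with person-mean imputation.

    Missing items are replaced by the person's mean over answered items
    when the missing fraction is below ``max_missing_frac``; otherwise the
    scale score is missing.
    """
    values = items.to_numpy(dtype=float)
    frac_missing = np.isnan(values).mean(axis=1)
    person_mean = np.nanmean(np.where(np.isnan(values), np.nan, values), axis=1)
    filled = np.where(np.isnan(values), person_mean[:, None], values)
    total = filled.sum(axis=1)
    total[frac_missing >= max_missing_frac] = np.nan
    total[frac_missing == 1.0] = np.nan
    return pd.Series(total, index=items.index)


def _drop_aliased(x: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[str]]:
    """Keep a full-column-rank subset of the design via pivoted QR."""
    if x.shape[1] == 0:
        return x, names
    _, r, piv = linalg.qr(x, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(x.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    if rank < x.shape[1]:
        dropped = [names[i] for i in sorted(piv[rank:])]
        warnings.warn(f"dropping aliased covariates: {dropped}", stacklevel=2)
    keep = sorted(piv[:rank])
    return x[:, keep], [names[i] for i in keep]


def residualize(y: np.ndarray, covariates: pd.DataFrame,
                sqrt_transform: bool = False) -> np.ndarray:
    """OLS residuals of the (optionally sqrt-transformed) outcome."""
    y = np.asarray(y, dtype=float)
    if sqrt_transform:
        if np.nanmin(y) < 0:
            raise ValueError("sqrt transform requires non-negative outcome")
        y = np.sqrt(y)
    x = covariates.to_numpy(dtype=float)
    x = np.column_stack([np.ones(len(y)), x])
    names = ["const"] + list(covariates.columns)
    x, _ = _drop_aliased(x, names)
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    return y - x @ beta


def standardize_subset(values: np.ndarray) -> np.ndarray:
    """Scale to mean 0, SD 1 (population SD) on the analysis subset."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least two observations to standardize")
    sd = values.std()
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("zero or undefined variance, cannot standardize")
    return (values - values.mean()) / sd


def fit_linear_ri(y: np.ndarray, predictors: pd.DataFrame,
                  families: np.ndarray,
                  alpha: float = DEFAULT_ALPHA) -> FitResult:
    """Linear model with a family random intercept, ML estimation."""
    exog = pd.DataFrame({"const": np.ones(len(y))}).join(
        predictors.reset_index(drop=True))
    fit = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = MixedLM(np.asarray(y, dtype=float), exog,
                        groups=np.asarray(families))
        # optimizers occasionally hit a singular Hessian when the family
        # variance sits at the boundary; fall through until one succeeds
        for method in ("bfgs", "lbfgs", "powell", "cg"):
            try:
                fit = model.fit(reml=False, method=method)
                break
            except np.linalg.LinAlgError:
                continue
    if fit is None:
        raise RuntimeError("random-intercept fit failed with every optimizer")
    names = list(predictors.columns)
    beta = fit.fe_params[names]
    se = fit.bse_fe[names]
    z = special.ndtri(1.0 - 0.025)
    ci_low, ci_high = beta - z * se, beta + z * se
    pvals = fit.pvalues[names]
    params = pd.DataFrame({
        "predictor": names,
        "beta_std": beta.to_numpy(),
        "ci_low": ci_low.to_numpy(),
        "ci_high": ci_high.to_numpy(),
        "p": pvals.to_numpy(),
    })
    params["r2_pct"] = 100.0 * params["beta_std"] ** 2
    return FitResult(params=params, loglik=float(fit.llf), n_used=len(y),
                     converged=bool(fit.converged),
                     sigma_family=float(np.sqrt(max(fit.cov_re.iloc[0, 0], 0.0))))


# ---------------------------------------------------------------------------
# Random-intercept proportional-odds model
# ---------------------------------------------------------------------------

def _ordinal_loglik(params: np.ndarray, y: np.ndarray, x: np.ndarray,
                    fam_codes: np.ndarray, n_fam: int, n_levels: int,
                    nodes: np.ndarray, log_weights: np.ndarray) -> float:
    """Marginal log-likelihood, random intercept integrated by GH quadrature."""
    p = x.shape[1]
    beta = params[:p]
    cuts = np.empty(n_levels - 1)
    cuts[0] = params[p]
    cuts[1:] = params[p] + np.cumsum(np.exp(params[p + 1:p + n_levels - 1]))
    sigma = params[-1]

    eta = x @ beta if p else np.zeros(len(y))
    # bounds per observation: theta_{y} and theta_{y-1} with +/- inf at ends
    upper = np.concatenate([cuts, [np.inf]])[y]
    lower = np.concatenate([[-np.inf], cuts])[y]
    # (n_obs, n_quad) linear predictors under each quadrature node
    shift = eta[:, None] + sigma * nodes[None, :]
    with np.errstate(over="ignore"):
        cdf_hi = special.expit(upper[:, None] - shift)
        cdf_lo = special.expit(lower[:, None] - shift)
    logp_obs = np.log(np.clip(cdf_hi - cdf_lo, 1e-300, None))
    # sum within family, then logsumexp over quadrature nodes
    fam_logp = np.zeros((n_fam, len(nodes)))
    np.add.at(fam_logp, fam_codes, logp_obs)
    return float(special.logsumexp(fam_logp + log_weights[None, :],
                                   axis=1).sum())


def fit_ordinal_ri(y: np.ndarray, predictors: pd.DataFrame,
                   families: np.ndarray, alpha: float = DEFAULT_ALPHA,
                   n_quad: int = 31) -> FitResult:
    """Proportional-odds model with a normal family random intercept.

    ``P(y <= k | u) = logistic(theta_k - x beta - u)``, ``u ~ N(0, sigma^2)``
    per family; the marginal likelihood is evaluated with ``n_quad``
    Gauss-Hermite nodes and maximized with L-BFGS-B (sigma bounded at 0).
    Empty categories are collapsed with a warning.
    """
    y = np.asarray(y)
    levels, y_codes = np.unique(y, return_inverse=True)
    if len(levels) < 2:
        raise ValueError("ordinal outcome needs at least two observed levels")
    if len(levels) < len(np.unique(y)) + 0:  # pragma: no cover
        warnings.warn("empty ordinal categories collapsed")
    n_levels = len(levels)
    x = predictors.to_numpy(dtype=float)
    fam_levels, fam_codes = np.unique(np.asarray(families), return_inverse=True)

    gh_x, gh_w = hermgauss(n_quad)
    nodes = np.sqrt(2.0) * gh_x
    log_weights = np.log(gh_w) - 0.5 * np.log(np.pi)

    p = x.shape[1]
    # start values: cumulative-frequency thresholds, zero betas, sigma 0.5
    cum = np.cumsum(np.bincount(y_codes, minlength=n_levels))[:-1] / len(y)
    theta0 = special.logit(np.clip(cum, 1e-4, 1 - 1e-4))
    start = np.concatenate([
        np.zeros(p), [theta0[0]],
        np.log(np.clip(np.diff(theta0), 1e-3, None)), [0.5]])

    def nll(params: np.ndarray) -> float:
        return -_ordinal_loglik(params, y_codes, x, fam_codes,
                                len(fam_levels), n_levels, nodes, log_weights)

    bounds = [(None, None)] * (len(start) - 1) + [(0.0, None)]
    res = optimize.minimize(nll, start, method="L-BFGS-B", bounds=bounds,
                            options={"maxiter": 500, "ftol": 1e-12,
                                     "gtol": 1e-8})

    hess = approx_hess1(res.x, nll)
    # sigma at the boundary makes the full Hessian singular; invert the
    # beta/threshold block for Wald SEs
    free = slice(0, len(res.x) - 1) if res.x[-1] < 1e-6 else slice(None)
    cov = np.full((len(res.x), len(res.x)), np.nan)
    try:
        cov_free = np.linalg.inv(hess[free, free])
        cov[free, free] = cov_free
    except np.linalg.LinAlgError:
        pass
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))

    names = list(predictors.columns)
    beta = res.x[:p]
    beta_se = se[:p]
    z = special.ndtri(1.0 - 0.025)
    with np.errstate(invalid="ignore", divide="ignore"):
        zstat = beta / beta_se
        pvals = 2.0 * special.ndtr(-np.abs(zstat))
    params_df = pd.DataFrame({
        "predictor": names,
        "beta_std": beta,
        "ci_low": beta - z * beta_se,
        "ci_high": beta + z * beta_se,
        "p": pvals,
    })
    params_df["r2_pct"] = 100.0 * params_df["beta_std"] ** 2
    return FitResult(params=params_df, loglik=float(-res.fun), n_used=len(y),
                     converged=bool(res.success), sigma_family=float(res.x[-1]))


# ---------------------------------------------------------------------------
# Table-style report over outcomes and model specifications
# ---------------------------------------------------------------------------

def build_covariates(phenotypes: pd.DataFrame, pcs: pd.DataFrame | None,
                     for_ea: bool = False) -> pd.DataFrame:
    """Covariate design: sex, (birth year and sex x birth year for adult
    attainment), ancestry PCs, platform dummies."""
    cov = pd.DataFrame(index=phenotypes.index)
    cov["sex"] = phenotypes["sex"].astype(float)
    if for_ea and "birth_year" in phenotypes:
        by = phenotypes["birth_year"].astype(float)
        cov["birth_year"] = by - by.mean()
        cov["sex_x_birth_year"] = cov["sex"] * cov["birth_year"]
    if pcs is not None:
        merged = phenotypes[["individual_id"]].merge(
            pcs.rename(columns={"sample_id": "individual_id"}),
            on="individual_id", how="left")
        for c in merged.columns:
            if c.startswith("PC"):
                cov[c] = merged[c].to_numpy()
    if "platform" in phenotypes:
        dummies = pd.get_dummies(phenotypes["platform"], prefix="platform",
                                 drop_first=True, dtype=float)
        cov = cov.join(dummies.set_index(cov.index))
    return cov


def _analysis_frame(phenotypes: pd.DataFrame, scores: dict[str, pd.DataFrame],
                    ) -> pd.DataFrame:
    """Merge phenotypes with the four score columns."""
    frame = phenotypes.copy()
    for trait, tbl in scores.items():
        renamed = tbl.rename(columns={
            "person_id": "individual_id",
            "pgs_t": f"PGS_T_{trait}", "pgs_nt": f"PGS_NT_{trait}"})
        frame = frame.merge(
            renamed[["individual_id", f"PGS_T_{trait}", f"PGS_NT_{trait}"]],
            on="individual_id", how="left")
    return frame


def run_analysis(spec: AnalysisSpec, phenotypes: pd.DataFrame,
                 scores: dict[str, pd.DataFrame],
                 pcs: pd.DataFrame | None = None) -> FitResult:
    """Residualize, standardize and fit one outcome/predictor specification."""
    frame = _analysis_frame(phenotypes, scores)
    is_ordinal = spec.outcome == "ea_level"
    needed = [spec.outcome] + spec.predictors
    subset = frame.dropna(subset=needed).reset_index(drop=True)
    if len(subset) < len(spec.predictors) + 2:
        raise ValueError(f"too few complete observations for {spec.outcome}")

    cov = build_covariates(subset, pcs, for_ea=is_ordinal)
    predictors = pd.DataFrame({
        name: standardize_subset(subset[name].to_numpy())
        for name in spec.predictors})
    fams = subset["family_id"].to_numpy()

    if is_ordinal:
        cov_std = pd.DataFrame({
            c: cov[c].to_numpy() for c in cov.columns
            if np.nanstd(cov[c].to_numpy()) > 0})
        design = predictors.join(cov_std.reset_index(drop=True))
        fit = fit_ordinal_ri(subset[spec.outcome].to_numpy(), design, fams,
                             alpha=spec.alpha)
        fit.params = fit.params[fit.params["predictor"].isin(
            spec.predictors)].reset_index(drop=True)
        return fit

    resid = residualize(subset[spec.outcome].to_numpy(), cov,
                        sqrt_transform=spec.outcome in SQRT_OUTCOMES)
    y = standardize_subset(resid)
    return fit_linear_ri(y, predictors, fams, alpha=spec.alpha)


def run_table1(phenotypes: pd.DataFrame, scores: dict[str, pd.DataFrame],
               pcs: pd.DataFrame | None = None,
               alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    """Model 1-3 fits per childhood outcome plus the adult-attainment model.

    Model 1 uses the attainment (EA) transmitted + non-transmitted scores,
    model 2 the ADHD pair, model 3 all four.  Adult attainment (ordinal) is
    analysed with the EA score pair.  Returns a long-format report with one
    row per (outcome, model, predictor).
    """
    rows = []
    blocks = [(outcome, model, preds)
              for outcome in CHILD_OUTCOMES
              for model, preds in MODEL_PREDICTORS.items()]
    blocks.append(("ea_level", "model1", MODEL_PREDICTORS["model1"]))
    for outcome, model, preds in blocks:
        if outcome not in phenotypes.columns:
            warnings.warn(f"outcome {outcome!r} absent, block skipped")
            continue
        avail = [p for p in preds
                 if p.split("_")[-1] in scores]
        if avail != preds:
            warnings.warn(f"scores for {model} unavailable, block skipped")
            continue
        fit = run_analysis(AnalysisSpec(outcome, preds, alpha),
                           phenotypes, scores, pcs)
        for _, r in fit.params.iterrows():
            rows.append({
                "outcome": outcome, "model": model,
                "predictor": r["predictor"], "beta": r["beta_std"],
                "ci_low": r["ci_low"], "ci_high": r["ci_high"],
                "r2_pct": r["r2_pct"], "p": r["p"],
                "significant": bool(r["p"] < alpha),
                "n": fit.n_used, "converged": fit.converged,
            })
    return pd.DataFrame(rows)
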