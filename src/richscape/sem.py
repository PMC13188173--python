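"""Composite-index path model of richness drivers.

The four covariate groups are collapsed to composite indices — terrain (T),
climate (C), soil (S), anthropogenic (A) — and the richness response (R)
enters a recursive system of standardized structural equations:

    R = b_t T + b_c C + b_s S + b_a A + e
    C = g_ca A + g_ct T + z1
    S = g_sa A + g_st T + z2

T and A are exogenous; C and S mediate their influence on R. On
standardized variables the least-squares estimates of each equation are the
standardized path coefficients; direct effects are the coefficients,
indirect effects are products along mediated paths
(e.g. T -> C -> R contributes g_ct * b_c), and total = direct + indirect.

Model fit is judged against the sample covariance of (T, A, C, S, R) with
the maximum-likelihood discrepancy chi-square of the model-implied
covariance, plus the usual comparative indices (CFI, NFI) against the
mutual-independence baseline and the goodness-of-fit index GFI.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm_api

from .grids import GROUPS, EnvStack

VARS = ("T", "A", "C", "S", "R")
GROUP_TO_VAR = {"terrain": "T", "anthropogenic": "A", "climate": "C", "soil": "S"}

#: structural equations: endogenous -> ordered predictors
EQUATIONS = {"C": ("A", "T"), "S": ("A", "T"), "R": ("T", "C", "S", "A")}


@dataclass
class CompositeIndices:
    """Standardized per-pixel group indices and response."""

    data: pd.DataFrame            # columns T, A, C, S, R; mean 0, sd 1
    method: str                   # "pc1" or "mean"
    loadings: dict[str, pd.Series]

    def __post_init__(self) -> None:
        for col in VARS:
            if col not in self.data.columns:
                raise ValueError(f"missing index column {col!r}")
            v = self.data[col].to_numpy()
            if abs(v.mean()) > 1e-8 or abs(v.std() - 1) > 1e-6:
                raise ValueError(f"index {col!r} is not standardized")


def _standardize(df: pd.DataFrame) -> pd.DataFrame:
    return (df - df.mean()) / df.std(ddof=0)


def build_indices(pixel_table: pd.DataFrame, groups: Mapping[str, str],
                  response: np.ndarray, method: str = "pc1",
                  anchors: Mapping[str, str] | None = None) -> CompositeIndices:
    """Collapse each covariate group to one standardized composite index.

    ``pc1`` takes the first principal component of the group's
    standardized variables, sign-aligned so the anchor variable (default:
    the group's first variable) loads positively; ``mean`` takes the
    standardized average of standardized variables. Loadings are stored
    for provenance. Constant variables cannot be standardized and are
    dropped with a warning.
    """
    if method not in ("pc1", "mean"):
        raise ValueError(f"unknown index method {method!r}")
    anchors = dict(anchors or {})
    cols: dict[str, np.ndarray] = {}
    loadings: dict[str, pd.Series] = {}
    for group in GROUPS:
        members = [n for n, g in groups.items() if g == group and n in pixel_table]
        if not members:
            raise ValueError(f"group {group!r} has no variables")
        sub = pixel_table[members]
        constant = [m for m in members if sub[m].nunique() <= 1]
        if constant:
            warnings.warn(f"constant variable(s) {constant} dropped from "
                          f"{group} index", UserWarning, stacklevel=2)
            members = [m for m in members if m not in constant]
            sub = pixel_table[members]
        Z = _standardize(sub).to_numpy()
        if method == "pc1" and len(members) > 1:
            # first right singular vector = first principal axis
            _, _, vt = np.linalg.svd(Z - Z.mean(axis=0), full_matrices=False)
            w = vt[0]
        else:
            w = np.full(len(members), 1.0 / len(members))
        anchor = anchors.get(group, members[0])
        if w[members.index(anchor)] < 0:
            w = -w
        idx = Z @ w
        cols[GROUP_TO_VAR[group]] = (idx - idx.mean()) / idx.std()
        loadings[group] = pd.Series(w, index=members)
    resp = np.asarray(response, dtype=float).ravel()
    if len(resp) != len(pixel_table):
        raise ValueError("response length does not match pixel table")
    cols["R"] = (resp - resp.mean()) / resp.std()
    data = pd.DataFrame(cols)[list(VARS)]
    return CompositeIndices(data=data, method=method, loadings=loadings)


def indices_from_table(data: pd.DataFrame) -> CompositeIndices:
    """Wrap an already-built table of T, A, C, S, R values as indices.

    Convenience for fitting the path model on tabular draws (each column
    is standardized here); composite construction is bypassed.
    """
    z = _standardize(data[list(VARS)])
    return CompositeIndices(data=z, method="raw", loadings={})


@dataclass
class PathModel:
    """Fitted recursive path model on standardized indices."""

    coefficients: dict[str, float]       # "C~A" -> g_ca, etc.
    se: dict[str, float]
    ci95: dict[str, tuple[float, float]]
    resid_var: dict[str, float]          # ML residual variance per equation
    n: int
    exog_cov: np.ndarray                 # sample cov of (T, A), ML denominator
    bootstrap_ci95: dict[str, tuple[float, float]] | None = None

    def path(self, endog: str, pred: str) -> float:
        return self.coefficients[f"{endog}~{pred}"]

    def path_matrix(self) -> np.ndarray:
        """M with M[i, j] = coefficient of var j in var i's equation."""
        M = np.zeros((len(VARS), len(VARS)))
        for endog, preds in EQUATIONS.items():
            for p in preds:
                M[VARS.index(endog), VARS.index(p)] = self.path(endog, p)
        return M


def fit_path_model(indices: CompositeIndices, bootstrap: int = 0,
                   seed: int = 0) -> PathModel:
    """Estimate the structural equations by equation-wise least squares.

    For a recursive system on standardized variables, OLS per equation is
    the ML estimator of the standardized path coefficients; analytic
    standard errors and 95% normal CIs come from each equation's OLS
    covariance. Optional nonparametric bootstrap CIs resample pixels.

    Note: pixels are treated as independent, as in a conventional
    all-pixel fit; spatial autocorrelation makes the analytic SEs
    optimistic, so a caveat is warranted whenever the indices come from a
    smooth landscape.
    """
    df = indices.data
    n = len(df)
    if n < 50:
        raise ValueError("need at least 50 pixels to fit the path model")
    coefficients, se, ci95, resid_var = {}, {}, {}, {}
    for endog, preds in EQUATIONS.items():
        X = df[list(preds)].to_numpy()
        rank = np.linalg.matrix_rank(np.corrcoef(X, rowvar=False))
        if rank < len(preds):
            raise ValueError(
                f"predictors {preds} of {endog} are collinear (rank {rank})")
        fit = sm_api.OLS(df[endog].to_numpy(), sm_api.add_constant(X)).fit()
        for j, p in enumerate(preds, start=1):
            key = f"{endog}~{p}"
            coefficients[key] = float(fit.params[j])
            se[key] = float(fit.bse[j])
            ci95[key] = (coefficients[key] - 1.96 * se[key],
                         coefficients[key] + 1.96 * se[key])
        resid_var[endog] = float(np.mean(fit.resid ** 2))
    exog = df[["T", "A"]].to_numpy()
    model = PathModel(coefficients=coefficients, se=se, ci95=ci95,
                      resid_var=resid_var, n=n,
                      exog_cov=np.cov(exog, rowvar=False, ddof=0))
    if bootstrap:
        rng = np.random.default_rng(seed)
        draws: dict[str, list[float]] = {k: [] for k in coefficients}
        arr = df.to_numpy()
        for _ in range(bootstrap):
            bs = pd.DataFrame(arr[rng.integers(0, n, n)], columns=df.columns)
            for endog, preds in EQUATIONS.items():
                Xb = sm_api.add_constant(bs[list(preds)].to_numpy())
                params = np.linalg.lstsq(Xb, bs[endog].to_numpy(), rcond=None)[0]
                for j, p in enumerate(preds, start=1):
                    draws[f"{endog}~{p}"].append(float(params[j]))
        model.bootstrap_ci95 = {
            k: (float(np.percentile(v, 2.5)), float(np.percentile(v, 97.5)))
            for k, v in draws.items()}
    return model


@dataclass
class EffectTable:
    """Direct / indirect / total standardized effects on the response."""

    direct: dict[str, float]
    indirect_paths: dict[str, dict[str, float]]   # predictor -> route -> effect
    indirect: dict[str, float]
    total: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        rows = {p: {"direct": self.direct[p], "indirect": self.indirect[p],
                    "total": self.total[p]} for p in self.direct}
        out = pd.DataFrame(rows).T
        out.index.name = "predictor"
        return out


def total_effects_matrix(model: PathModel) -> np.ndarray:
    """Reduced-form total effects (I - M)^-1 - I over all variables.

    Entry [i, j] is the total effect of variable j on variable i summed
    over every directed route; used as the algebraic cross-check of the
    path-product decomposition.
    """
    M = model.path_matrix()
    return np.linalg.inv(np.eye(len(VARS)) - M) - np.eye(len(VARS))


def effects_decomposition(model: PathModel) -> EffectTable:
    """Path-product effect decomposition on the response.

    Direct effects are the R-equation coefficients. Indirect effects run
    through the mediators C and S: for T the routes T->C->R and T->S->R,
    for A the routes A->C->R and A->S->R. The result is verified against
    the reduced-form matrix computation; a mismatch raises.
    """
    direct = {p: model.path("R", p) for p in EQUATIONS["R"]}
    indirect_paths = {p: {} for p in direct}
    for exo in ("T", "A"):
        for med in ("C", "S"):
            indirect_paths[exo][f"{exo}->{med}->R"] = (
                model.path(med, exo) * model.path("R", med))
    indirect = {p: float(sum(routes.values()))
                for p, routes in indirect_paths.items()}
    total = {p: direct[p] + indirect[p] for p in direct}
    TE = total_effects_matrix(model)
    r = VARS.index("R")
    for p in direct:
        ref = TE[r, VARS.index(p)]
        if abs(total[p] - ref) > 1e-9:
            raise AssertionError(
                f"path-product total effect of {p} ({total[p]}) disagrees "
                f"with reduced-form value ({ref})")
    return EffectTable(direct=direct, indirect_paths=indirect_paths,
                       indirect=indirect, total=total)


@dataclass
class FitIndices:
    chi_square: float
    df: int
    baseline_chi_square: float
    baseline_df: int
    cfi: float
    nfi: float
    gfi: float


def implied_covariance(model: PathModel) -> np.ndarray:
    """Model-implied covariance of (T, A, C, S, R).

    The recursive system x = M x + e gives Sigma = (I-M)^-1 Psi (I-M)^-T,
    where Psi holds the exogenous covariance block (T, A) and the
    equation residual variances.
    """
    M = model.path_matrix()
    psi = np.zeros_like(M)
    psi[:2, :2] = model.exog_cov
    for endog, var in model.resid_var.items():
        i = VARS.index(endog)
        psi[i, i] = var
    inv = np.linalg.inv(np.eye(len(VARS)) - M)
    return inv @ psi @ inv.T


def _ml_discrepancy(S: np.ndarray, sigma: np.ndarray) -> float:
    p = S.shape[0]
    sign, logdet_sigma = np.linalg.slogdet(sigma)
    if sign <= 0:
        raise np.linalg.LinAlgError("implied covariance is not positive definite")
    _, logdet_s = np.linalg.slogdet(S)
    return float(logdet_sigma - logdet_s + np.trace(S @ np.linalg.inv(sigma)) - p)


def fit_indices(indices: CompositeIndices, model: PathModel) -> FitIndices:
    """Covariance-based fit of the recursive system.

    chi^2 = (n-1) * F_ML against the sample covariance of (T, A, C, S, R);
    df = number of non-redundant moments (15) minus free parameters
    (8 paths + 3 residual variances + 3 exogenous moments = 14).
    The baseline is the mutual-independence model (diagonal covariance,
    df = 10). CFI and NFI compare the two chi-squares; GFI measures the
    implied-vs-sample covariance agreement directly.
    """
    df_data = indices.data[list(VARS)]
    n = len(df_data)
    S = np.cov(df_data.to_numpy(), rowvar=False, ddof=0)
    sigma = implied_covariance(model)
    p = len(VARS)
    n_moments = p * (p + 1) // 2
    n_free = sum(len(v) for v in EQUATIONS.values()) + len(EQUATIONS) + 3
    dof = n_moments - n_free
    chi2 = (n - 1) * _ml_discrepancy(S, sigma)
    sigma_b = np.diag(np.diag(S))
    chi2_b = (n - 1) * _ml_discrepancy(S, sigma_b)
    dof_b = n_moments - p
    num = max(chi2 - dof, 0.0)
    den = max(chi2_b - dof_b, chi2 - dof, 0.0)
    cfi = 1.0 if den == 0 else 1.0 - num / den
    nfi = 0.0 if chi2_b <= 0 else (chi2_b - chi2) / chi2_b
    inv_sigma_s = np.linalg.inv(sigma) @ S
    resid = inv_sigma_s - np.eye(p)
    gfi = 1.0 - np.trace(resid @ resid) / np.trace(inv_sigma_s @ inv_sigma_s)
    clip = lambda v: float(min(max(v, 0.0), 1.0))
    return FitIndices(chi_square=float(chi2), df=dof,
                      baseline_chi_square=float(chi2_b), baseline_df=dof_b,
                      cfi=clip(cfi), nfi=clip(nfi), gfi=clip(gfi))


def path_table(model: PathModel) -> pd.DataFrame:
    """Tidy coefficient table (path, estimate, se, ci_low, ci_high)."""
    rows = []
    labels = {"C~T": "climate<-terrain", "C~A": "climate<-anthropogenic",
              "S~T": "soil<-terrain", "S~A": "soil<-anthropogenic",
              "R~T": "richness<-terrain", "R~C": "richness<-climate",
              "R~S": "richness<-soil", "R~A": "richness<-anthropogenic"}
    for key, est in model.coefficients.items():
        lo, hi = model.ci95[key]
        rows.append({"path": labels.get(key, key), "estimate": est,
                     "se": model.se[key], "ci_low": lo, "ci_high": hi})
    return pd.DataFrame(rows)


def edge_list(model: PathModel) -> str:
    """Plain-text path-diagram edge list."""
    lines = [f"{p} -> {endog}: {model.path(endog, p):+.4f}"
             for endog, preds in EQUATIONS.items() for p in preds]
    return "\n".join(lines)
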