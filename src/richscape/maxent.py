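"""Maximum-entropy (Gibbs) habitat suitability model.

The model places a probability distribution over landscape (background)
cells,

    P(x) = exp(lambda . f(x)) / Z,    Z = sum_x exp(lambda . f(x)),

the maximum-entropy distribution whose feature expectations match the
presence sample's empirical feature means. The fit maximizes the mean
presence log-likelihood under this Gibbs law minus an L1 penalty
``beta * ||lambda||_1`` — the standard regularized dual of the constrained
entropy maximization, whose KKT conditions bound every active feature's
moment mismatch by ``beta``.

Features are linear / quadratic / pairwise-product transforms of the
covariates, min-max scaled to [0, 1] on the background so the penalty acts
on comparable scales.

The optimizer splits ``lambda = u - v`` with ``u, v >= 0``, turning the L1
term into a smooth bound-constrained problem solved by L-BFGS-B; accepted
iterations are monotone in the penalized objective.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import logsumexp
from scipy.stats import rankdata

from .grids import EnvStack, OccurrenceSet, RasterGrid

logger = logging.getLogger(__name__)

FEATURE_KINDS = ("linear", "quadratic", "product")


class DegenerateFeatureWarning(UserWarning):
    pass


class ConvergenceWarning(UserWarning):
    pass


@dataclass
class FeatureSet:
    """Feature construction recipe fitted on the background.

    Covariates are min-max scaled to [0, 1] with the background minima and
    maxima; the identical transform is applied to presence rows, and values
    outside the training range are clamped (clamp counts are logged).
    """

    kinds: tuple[str, ...]
    covariates: list[str]
    mins: np.ndarray
    maxs: np.ndarray
    feature_names: list[str] = field(default_factory=list)
    dropped: list[str] = field(default_factory=list)

    def scale(self, table: pd.DataFrame) -> np.ndarray:
        X = table[self.covariates].to_numpy(dtype=float)
        S = (X - self.mins) / (self.maxs - self.mins)
        n_clamped = int(np.sum((S < 0) | (S > 1)))
        if n_clamped:
            logger.info("clamped %d scaled values outside [0, 1]", n_clamped)
        return np.clip(S, 0.0, 1.0)

    def transform(self, table: pd.DataFrame) -> np.ndarray:
        """Feature matrix for any covariate table (presence or background)."""
        S = self.scale(table)
        cols: list[np.ndarray] = []
        for j in range(S.shape[1]):
            if "linear" in self.kinds:
                cols.append(S[:, j])
            if "quadratic" in self.kinds:
                cols.append(S[:, j] ** 2)
        if "product" in self.kinds:
            for j in range(S.shape[1]):
                for k in range(j + 1, S.shape[1]):
                    cols.append(S[:, j] * S[:, k])
        return np.column_stack(cols) if cols else np.empty((len(S), 0))


def build_features(pixel_table: pd.DataFrame,
                   kinds: Sequence[str] = ("linear", "quadratic"),
                   ) -> tuple[np.ndarray, FeatureSet]:
    """Build the background feature matrix and its reusable recipe.

    Column order is deterministic: for each covariate in table order, its
    linear then quadratic column; all pairwise products follow, ordered by
    covariate pair. Constant covariates cannot be scaled and are dropped
    with a warning.
    """
    kinds = tuple(k for k in FEATURE_KINDS if k in set(kinds))
    if not kinds:
        raise ValueError("kinds must include at least one of "
                         f"{FEATURE_KINDS}")
    if pixel_table.shape[1] < 1:
        raise ValueError("pixel table has no covariates")
    keep, dropped = [], []
    for name in pixel_table.columns:
        col = pixel_table[name].to_numpy(dtype=float)
        if not np.all(np.isfinite(col)):
            raise ValueError(f"covariate {name!r} contains non-finite values")
        if col.max() == col.min():
            dropped.append(name)
            warnings.warn(f"covariate {name!r} is constant; dropped",
                          DegenerateFeatureWarning, stacklevel=2)
        else:
            keep.append(name)
    if not keep:
        raise ValueError("all covariates are constant")
    sub = pixel_table[keep]
    fs = FeatureSet(
        kinds=kinds,
        covariates=keep,
        mins=sub.min().to_numpy(dtype=float),
        maxs=sub.max().to_numpy(dtype=float),
        dropped=dropped,
    )
    names: list[str] = []
    for name in keep:
        if "linear" in kinds:
            names.append(name)
        if "quadratic" in kinds:
            names.append(f"{name}^2")
    if "product" in kinds:
        for j, a in enumerate(keep):
            for b in keep[j + 1:]:
                names.append(f"{a}*{b}")
    fs.feature_names = names
    return fs.transform(sub), fs


@dataclass
class MaxentModel:
    """Fitted Gibbs suitability model."""

    weights: np.ndarray          # lambda, one per feature
    log_z: float                 # log normalizer over the training background
    beta: float                  # L1 regularization weight
    features: FeatureSet
    background_size: int
    converged: bool
    n_iter: int
    objective_history: list[float]
    stop_reason: str

    def log_density(self, F: np.ndarray) -> np.ndarray:
        """log P per row, normalized over the training background."""
        return F @ self.weights - self.log_z

    def scores(self, table: pd.DataFrame) -> np.ndarray:
        """Unnormalized log-suitability (monotone in P) for any table."""
        return self.features.transform(table) @ self.weights

    def gain(self, presence_F: np.ndarray) -> float:
        """Regularized training gain in nats above the uniform model."""
        return float(np.mean(self.log_density(presence_F))
                     + np.log(self.background_size))


def _objective_parts(lam: np.ndarray, F_pres: np.ndarray, F_bg: np.ndarray):
    scores_bg = F_bg @ lam
    log_z = logsumexp(scores_bg)
    nll = -float(np.mean(F_pres @ lam)) + log_z
    # gradient of nll: model moments minus presence moments
    p = np.exp(scores_bg - log_z)
    grad = F_bg.T @ p - F_pres.mean(axis=0)
    return nll, grad, log_z


def fit_maxent(presence_features: np.ndarray, background_features: np.ndarray,
               features: FeatureSet | None = None, beta: float = 0.05,
               tol: float = 1e-6, max_iter: int = 500) -> MaxentModel:
    """Fit the L1-regularized maximum-entropy model.

    Maximizes the mean presence log-likelihood of the Gibbs distribution
    over background cells minus ``beta * ||lambda||_1``. The split
    ``lambda = u - v`` (u, v >= 0) makes the problem smooth and bound
    constrained; L-BFGS-B guarantees monotone decrease over accepted
    iterations. Stops when the objective change drops below ``tol`` or at
    ``max_iter``, recording which.
    """
    F_pres = np.asarray(presence_features, dtype=float)
    F_bg = np.asarray(background_features, dtype=float)
    if F_pres.ndim != 2 or F_bg.ndim != 2 or F_pres.shape[1] != F_bg.shape[1]:
        raise ValueError("presence/background feature matrices misshapen")
    if not (np.all(np.isfinite(F_pres)) and np.all(np.isfinite(F_bg))):
        raise ValueError("features contain non-finite values")
    if len(F_pres) < 5:
        raise ValueError("need at least 5 presence records to fit")
    if beta < 0:
        raise ValueError("beta must be non-negative")
    m = F_pres.shape[1]

    history: list[float] = []

    def fun(uv: np.ndarray):
        lam = uv[:m] - uv[m:]
        nll, grad, _ = _objective_parts(lam, F_pres, F_bg)
        obj = nll + beta * np.sum(uv)
        g = np.concatenate([grad + beta, -grad + beta])
        return obj, g

    def cb(uv: np.ndarray) -> None:
        lam = uv[:m] - uv[m:]
        nll, _, _ = _objective_parts(lam, F_pres, F_bg)
        history.append(nll + beta * np.sum(np.abs(lam)))

    x0 = np.zeros(2 * m)
    cb(x0)
    # run the solver essentially to gradient convergence (the KKT moment
    # conditions need gradient-level accuracy); `tol` governs the reported
    # objective-change stopping criterion
    res = optimize.minimize(
        fun, x0, jac=True, method="L-BFGS-B",
        bounds=[(0.0, None)] * (2 * m),
        callback=cb,
        options={"maxiter": max_iter, "ftol": 1e-14, "gtol": 1e-8},
    )
    lam = res.x[:m] - res.x[m:]
    # kill split remnants: min(u, v) cancels and only inflates the penalty
    lam[np.abs(lam) < 1e-12] = 0.0
    nll, grad, log_z = _objective_parts(lam, F_pres, F_bg)
    small_change = (len(history) >= 2
                    and abs(history[-1] - history[-2]) < tol)
    converged = bool(res.success) or res.status == 0 or small_change
    stop_reason = "objective change below tol" if converged else (
        "max_iter reached" if res.nit >= max_iter else str(res.message))
    if not converged:
        warnings.warn(
            f"fit stopped without convergence ({stop_reason}); "
            f"final gradient norm {np.linalg.norm(grad, np.inf):.3e}",
            ConvergenceWarning, stacklevel=2)
    return MaxentModel(
        weights=lam, log_z=float(log_z), beta=beta,
        features=features if features is not None else FeatureSet(
            kinds=("linear",), covariates=[], mins=np.array([]),
            maxs=np.array([]), feature_names=[f"f{j}" for j in range(m)]),
        background_size=len(F_bg), converged=converged, n_iter=int(res.nit),
        objective_history=history, stop_reason=stop_reason,
    )


def kkt_residuals(model: MaxentModel, presence_features: np.ndarray,
                  background_features: np.ndarray) -> np.ndarray:
    """|E_model[f_j] - E_presence[f_j]| per feature.

    At the optimum these are <= beta for every feature, with equality on
    active (nonzero-weight) features.
    """
    scores = background_features @ model.weights
    p = np.exp(scores - logsumexp(scores))
    return np.abs(background_features.T @ p - presence_features.mean(axis=0))


def predict_suitability(model: MaxentModel, env: EnvStack,
                        ) -> tuple[RasterGrid, RasterGrid]:
    """Predict suitability over a stack.

    Returns the raw Gibbs density (renormalized to sum to 1 over the
    stack's valid cells) and a monotone [0, 1] rescaling,
    ``1 - exp(-raw * n_cells)``, which maps the uniform density to a
    mid-scale value and preserves the raw ordering.
    """
    table = env.pixel_table
    scores = model.scores(table)
    raw = np.exp(scores - logsumexp(scores))
    cloglog = 1.0 - np.exp(-raw * len(raw))
    flat = table.index.to_numpy()
    return (env.grid_from_flat(flat, raw, name="suitability_raw"),
            env.grid_from_flat(flat, cloglog, name="suitability"))


def auc_score(positive: np.ndarray, negative: np.ndarray) -> float:
    """Rank AUC: P(random positive outranks random negative), ties count 1/2."""
    pos = np.asarray(positive, dtype=float)
    neg = np.asarray(negative, dtype=float)
    ranks = rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[:len(pos)].sum()
    return float((r_pos - len(pos) * (len(pos) + 1) / 2) / (len(pos) * len(neg)))


def _presence_cells(occurrences: OccurrenceSet, env: EnvStack,
                    dedup: bool = True) -> np.ndarray:
    cells = occurrences.cell_indices(env.grid)
    if dedup and len(cells):
        cells = np.unique(cells, axis=0)
    return cells


@dataclass
class EvaluationReport:
    """Replicate train/test AUC summary (75/25 split, 10 repetitions)."""

    species: str
    auc_replicates: list[float]
    train_auc_replicates: list[float]
    split_fraction: float
    n_presences: int

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.auc_replicates))

    @property
    def sd_auc(self) -> float:
        return float(np.std(self.auc_replicates, ddof=1))

    @property
    def mean_train_auc(self) -> float:
        return float(np.mean(self.train_auc_replicates))


def evaluate_auc(occurrences: OccurrenceSet, env: EnvStack, beta: float = 0.05,
                 split: float = 0.75, reps: int = 10, seed: int = 0,
                 kinds: Sequence[str] = ("linear", "quadratic"),
                 ) -> EvaluationReport:
    """Replicate hold-out evaluation of the suitability model.

    Per replicate the presence cells are randomly split (default 75%
    train / 25% test), the model is refit on the training cells, and the
    test AUC scores test presences against all background cells.
    Duplicate records in one cell are collapsed first.
    """
    if not 0 < split < 1:
        raise ValueError("split must be in (0, 1)")
    cells = _presence_cells(occurrences, env)
    n = len(cells)
    n_train = int(round(split * n))
    if n_train < 5 or n - n_train < 1:
        raise ValueError(
            f"{occurrences.species}: {n} presence cells leave fewer than the "
            "5-presence floor after the split")
    F_bg, fs = build_features(env.pixel_table, kinds=kinds)
    F_all = fs.transform(env.cells_to_table(cells))
    rng = np.random.default_rng(seed)
    test_aucs, train_aucs = [], []
    for _ in range(reps):
        perm = rng.permutation(n)
        tr, te = perm[:n_train], perm[n_train:]
        model = fit_maxent(F_all[tr], F_bg, features=fs, beta=beta)
        bg_scores = F_bg @ model.weights
        test_aucs.append(auc_score(F_all[te] @ model.weights, bg_scores))
        train_aucs.append(auc_score(F_all[tr] @ model.weights, bg_scores))
    return EvaluationReport(species=occurrences.species,
                            auc_replicates=test_aucs,
                            train_auc_replicates=train_aucs,
                            split_fraction=split, n_presences=n)


def variable_contributions(model: MaxentModel, presence_table: pd.DataFrame,
                           background_table: pd.DataFrame, n_perm: int = 5,
                           seed: int = 0) -> pd.Series:
    """Permutation importance as percentage contributions.

    For each covariate, its column is permuted jointly across the
    presence+background evaluation rows, features rebuilt, and the AUC
    recomputed; the contribution is the mean AUC drop over ``n_perm``
    permutations, floored at 0 and normalized to sum to 100.
    """
    fs = model.features
    n_pres = len(presence_table)
    combined = pd.concat([presence_table, background_table], ignore_index=True)
    scores = fs.transform(combined) @ model.weights
    base = auc_score(scores[:n_pres], scores[n_pres:])
    rng = np.random.default_rng(seed)
    drops = {}
    for cov in fs.covariates:
        d = []
        for _ in range(n_perm):
            shuffled = combined.copy()
            shuffled[cov] = rng.permutation(shuffled[cov].to_numpy())
            s = fs.transform(shuffled) @ model.weights
            d.append(base - auc_score(s[:n_pres], s[n_pres:]))
        drops[cov] = max(float(np.mean(d)), 0.0)
    total = sum(drops.values())
    if total == 0:
        warnings.warn("all permutation importances are zero; "
                      "reporting uniform contributions", UserWarning,
                      stacklevel=2)
        return pd.Series({c: 100.0 / len(drops) for c in drops})
    return pd.Series({c: 100.0 * v / total for c, v in drops.items()})


def jackknife_gains(presence_table: pd.DataFrame, background_table: pd.DataFrame,
                    beta: float = 0.05, kinds: Sequence[str] = ("linear", "quadratic"),
                    ) -> pd.DataFrame:
    """Leave-one-in / leave-one-out training gains per covariate.

    ``alone_gain`` refits on that covariate only; ``without_gain`` refits
    with it excluded. Gain is the mean presence log-likelihood above the
    uniform (log 1/N) baseline, in nats.
    """
    covs = list(background_table.columns)
    if len(covs) < 2:
        raise ValueError("jackknife needs at least 2 covariates")

    def gain_for(subset: list[str]) -> float:
        F_bg, fs = build_features(background_table[subset], kinds=kinds)
        F_pr = fs.transform(presence_table[subset])
        model = fit_maxent(F_pr, F_bg, features=fs, beta=beta)
        return model.gain(F_pr)

    rows = {c: {"alone_gain": gain_for([c]),
                "without_gain": gain_for([o for o in covs if o != c])}
            for c in covs}
    out = pd.DataFrame(rows).T
    out.index.name = "covariate"
    out.attrs["full_gain"] = gain_for(covs)
    return out


def fit_species(occurrences: OccurrenceSet, env: EnvStack, beta: float = 0.05,
                kinds: Sequence[str] = ("linear", "quadratic"),
                ) -> tuple[MaxentModel, np.ndarray]:
    """Fit one species on the full stack; returns the model and its
    presence cells (deduplicated, off-grid/nodata records excluded)."""
    cells = _presence_cells(occurrences, env)
    if len(cells) < 5:
        raise ValueError(
            f"{occurrences.species}: only {len(cells)} usable presence cells "
            "(minimum 5)")
    F_bg, fs = build_features(env.pixel_table, kinds=kinds)
    F_pr = fs.transform(env.cells_to_table(cells))
    model = fit_maxent(F_pr, F_bg, features=fs, beta=beta)
    return model, cells
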