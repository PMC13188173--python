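"""Synthetic landscapes with known ground truth.

Every downstream stage (suitability modelling, thresholding, stacking,
stratified-heterogeneity attribution, path modelling) is exercised against
data generated here, where the generating suitability weights and structural
coefficients are known exactly.

The generating model mirrors the structure the pipeline is meant to recover:

* four covariate groups — climate, soil, terrain, anthropogenic — each
  driven by one latent group index field;
* terrain and anthropogenic indices are independent exogenous random
  fields; the climate index is ``g_ca * A + g_ct * T`` plus noise and the
  soil index is ``g_sa * A + g_st * T`` plus noise (standardized
  coefficients);
* a continuous richness response ``b_t*T + b_c*C + b_s*S + b_a*A`` plus
  noise, discretized to integer counts by rank binning;
* species occurrences drawn from a Gibbs suitability law
  ``P(cell) ∝ exp(w · f(cell))`` with known weights ``w``.

Spatial autocorrelation is produced by moving-average (Gaussian-kernel)
smoothing of white noise on a torus, followed by re-standardization;
``corr_range`` is the e-folding distance (in cells) of the resulting
spatial correlation, and ``corr_range = 0`` is exactly white noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .grids import GROUPS, EnvStack, OccurrenceSet, RasterGrid

# Default generating structural coefficients (standardized). The endogenous
# equations are C = g_ca*A + g_ct*T, S = g_sa*A + g_st*T and
# R = b_t*T + b_c*C + b_s*S + b_a*A, each plus noise.
DEFAULT_STRUCTURAL = {
    "g_ca": 0.1558,   # climate <- anthropogenic
    "g_ct": -0.3624,  # climate <- terrain
    "g_sa": -0.0319,  # soil <- anthropogenic
    "g_st": 0.1162,   # soil <- terrain
    "b_t": 0.2597,    # richness <- terrain
    "b_c": 0.0548,    # richness <- climate
    "b_s": -0.0986,   # richness <- soil
    "b_a": 0.3469,    # richness <- anthropogenic
}

DEFAULT_GROUP_SIZES = {"climate": 6, "soil": 4, "terrain": 2, "anthropogenic": 4}

STRUCTURAL_KEYS = tuple(DEFAULT_STRUCTURAL)


@dataclass
class SimulationTruth:
    """Ground truth of one synthetic dataset.

    Attributes
    ----------
    true_weights
        species -> feature-weight vector used to draw its occurrences.
    structural_coeffs
        The generating standardized coefficients (keys as in
        ``DEFAULT_STRUCTURAL``).
    field_range
        Spatial correlation length in cells.
    noise_sd
        Residual standard deviation per structural equation
        (keys ``climate``, ``soil``, ``richness``).
    index_fields
        The generating latent group-index fields (T, C, S, A), kept so
        recovery can be scored against the exact generating surfaces.
    """

    structural_coeffs: dict[str, float]
    field_range: float
    noise_sd: dict[str, float]
    seed: int
    true_weights: dict[str, np.ndarray] = field(default_factory=dict)
    index_fields: dict[str, RasterGrid] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for k, v in self.structural_coeffs.items():
            if not np.isfinite(v):
                raise ValueError(f"structural coefficient {k} is not finite")
        for k, v in self.noise_sd.items():
            if not v > 0:
                raise ValueError(f"noise_sd[{k!r}] must be positive")


@dataclass
class SyntheticDataset:
    env: EnvStack
    occurrences: list[OccurrenceSet]
    richness_true: RasterGrid
    truth: SimulationTruth


def _standardize(a: np.ndarray) -> np.ndarray:
    return (a - a.mean()) / a.std()


def gen_gaussian_field(shape: tuple[int, int], corr_range: float,
                       seed: int | None = None,
                       rng: np.random.Generator | None = None) -> RasterGrid:
    """Stationary Gaussian random field, mean 0, variance 1.

    White noise is smoothed with a Gaussian kernel (wrapped boundaries, so
    every quadrant has the same marginal behaviour) and re-standardized;
    ``corr_range = 0`` returns plain white noise. The kernel scale is
    ``corr_range / 2``: smoothing white noise with a Gaussian of scale
    ``s`` yields autocorrelation ``exp(-d^2 / (4 s^2))``, so
    ``corr_range`` is the e-folding distance of the spatial correlation.
    """
    nrows, ncols = shape
    if nrows < 2 or ncols < 2:
        raise ValueError("shape must be at least 2x2")
    if corr_range < 0:
        raise ValueError("corr_range must be non-negative")
    if rng is None:
        rng = np.random.default_rng(seed)
    z = rng.standard_normal((nrows, ncols))
    if corr_range > 0:
        z = ndimage.gaussian_filter(z, sigma=corr_range / 2.0, mode="wrap")
    return RasterGrid(values=_standardize(z), name="field")


@dataclass
class LandscapeConfig:
    """Generating conditions of the synthetic landscape."""

    shape: tuple[int, int] = (100, 100)
    group_sizes: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    structural: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_STRUCTURAL))
    corr_range: float = 5.0
    member_loading: float = 0.8  # corr between a covariate and its group index
    n_species: int = 14
    n_points: int = 300          # occurrence records per species
    richness_noise_sd: float | None = None  # default: complement of explained var
    seed: int = 0

    def __post_init__(self) -> None:
        for g in GROUPS:
            if self.group_sizes.get(g, 0) < 1:
                raise ValueError(f"group {g!r} needs at least one variable")
        unknown = set(self.structural) - set(STRUCTURAL_KEYS)
        if unknown:
            raise ValueError(f"unknown structural coefficients: {sorted(unknown)}")
        self.structural = {**DEFAULT_STRUCTURAL, **dict(self.structural)}
        if not 0 < self.member_loading <= 1:
            raise ValueError("member_loading must be in (0, 1]")


# covariate names follow the field's usual abbreviations per group
_NAME_POOL = {
    "climate": ["amt", "mdr", "isot", "ts", "pwm", "pse"],
    "soil": ["tbs", "tcc", "toc", "tph"],
    "terrain": ["slp", "asp"],
    "anthropogenic": ["gdp", "ntl", "pop", "rd"],
}


def _member_names(group: str, n: int) -> list[str]:
    pool = _NAME_POOL[group]
    return [pool[i] if i < len(pool) else f"{group[:4]}{i + 1}" for i in range(n)]


def gen_env_stack(config: LandscapeConfig) -> tuple[EnvStack, SimulationTruth]:
    """Generate the four-group covariate stack and its ground truth.

    Terrain and anthropogenic index fields are independent; climate and
    soil indices follow the standardized structural equations; each group
    member is ``loading * index + sqrt(1 - loading^2) * noise``,
    re-standardized.
    """
    rng = np.random.default_rng(config.seed)
    shape = tuple(config.shape)
    coef = config.structural

    def fld() -> np.ndarray:
        return gen_gaussian_field(shape, config.corr_range, rng=rng).values

    t_idx = fld()
    a_idx = fld()
    sd_c = float(np.sqrt(max(1.0 - coef["g_ca"] ** 2 - coef["g_ct"] ** 2, 0.05)))
    sd_s = float(np.sqrt(max(1.0 - coef["g_sa"] ** 2 - coef["g_st"] ** 2, 0.05)))
    c_idx = _standardize(coef["g_ca"] * a_idx + coef["g_ct"] * t_idx + sd_c * fld())
    s_idx = _standardize(coef["g_sa"] * a_idx + coef["g_st"] * t_idx + sd_s * fld())
    indices = {"terrain": t_idx, "anthropogenic": a_idx,
               "climate": c_idx, "soil": s_idx}

    lam = config.member_loading
    resid = float(np.sqrt(1.0 - lam ** 2))
    layers: dict[str, RasterGrid] = {}
    groups: dict[str, str] = {}
    for group in GROUPS:
        for name in _member_names(group, config.group_sizes[group]):
            v = lam * indices[group] + resid * fld() if resid > 0 else indices[group]
            layers[name] = RasterGrid(values=_standardize(v), name=name)
            groups[name] = group

    truth = SimulationTruth(
        structural_coeffs=dict(coef),
        field_range=config.corr_range,
        noise_sd={"climate": sd_c, "soil": sd_s,
                  "richness": config.richness_noise_sd or _richness_noise_sd(coef)},
        seed=config.seed,
        index_fields={g: RasterGrid(values=v, name=f"{g}_index")
                      for g, v in indices.items()},
    )
    return EnvStack(layers, groups), truth


def _implied_index_cov(coef: Mapping[str, float]) -> np.ndarray:
    """Model-implied covariance of (T, A, C, S) with unit variances."""
    cov = np.eye(4)
    # order T, A, C, S; T ⟂ A by construction
    cov[0, 2] = cov[2, 0] = coef["g_ct"]
    cov[1, 2] = cov[2, 1] = coef["g_ca"]
    cov[0, 3] = cov[3, 0] = coef["g_st"]
    cov[1, 3] = cov[3, 1] = coef["g_sa"]
    cov[2, 3] = cov[3, 2] = (coef["g_ct"] * coef["g_st"] + coef["g_ca"] * coef["g_sa"])
    return cov


def _richness_noise_sd(coef: Mapping[str, float]) -> float:
    """Residual sd that leaves the continuous response near unit variance."""
    b = np.array([coef["b_t"], coef["b_a"], coef["b_c"], coef["b_s"]])
    explained = float(b @ _implied_index_cov(coef) @ b)
    return float(np.sqrt(max(1.0 - explained, 0.05)))


def gen_richness_response(env: EnvStack, truth: SimulationTruth,
                          n_species: int = 14,
                          seed: int | None = None) -> RasterGrid:
    """Known-truth richness surface for the attribution stages.

    The continuous response is the structural linear combination of the
    generating group indices plus spatially correlated noise, then
    discretized to integer counts in [0, n_species] by equal-count rank
    binning (rank order preserved).
    """
    coef = truth.structural_coeffs
    idx = {g: truth.index_fields[g].values for g in GROUPS}
    rng = np.random.default_rng(truth.seed + 1 if seed is None else seed)
    noise = gen_gaussian_field(env.grid.shape, truth.field_range, rng=rng).values
    cont = (coef["b_t"] * idx["terrain"] + coef["b_c"] * idx["climate"]
            + coef["b_s"] * idx["soil"] + coef["b_a"] * idx["anthropogenic"]
            + truth.noise_sd["richness"] * noise)
    mask = env.mask
    vals = cont[~mask]
    # equal-count rank bins -> integers 0..n_species
    ranks = np.argsort(np.argsort(vals))
    counts = np.floor(ranks * (n_species + 1) / len(vals)).astype(float)
    out = np.full(env.grid.shape, np.nan)
    out[~mask] = counts
    grid = env.grid.with_values(out, name="richness_true", mask=mask)
    grid.continuous = np.where(mask, np.nan, cont)  # kept for diagnostics
    return grid


def gen_occurrences(env: EnvStack, weights: np.ndarray, n_points: int,
                    seed: int, species: str = "sp",
                    kinds: Sequence[str] = ("linear",)) -> OccurrenceSet:
    """Draw presence records from the Gibbs law P(cell) ∝ exp(w·f(cell)).

    Features are built exactly as the suitability model builds them
    (scaled to [0, 1] from the stack), so a fitted model's weights are
    directly comparable with ``weights``. Sampling is with replacement
    over non-nodata cells; records are placed at cell centres.
    """
    from .maxent import build_features

    if n_points < 1:
        raise ValueError("n_points must be at least 1")
    table = env.pixel_table
    if table.empty:
        raise ValueError("environment stack has no valid (non-nodata) cells")
    F, _ = build_features(table, kinds=kinds)
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (F.shape[1],):
        raise ValueError(
            f"weights length {weights.size} != feature count {F.shape[1]}")
    logit = F @ weights
    p = np.exp(logit - logit.max())
    p /= p.sum()
    rng = np.random.default_rng(seed)
    picks = rng.choice(len(table), size=n_points, replace=True, p=p)
    flat = table.index.to_numpy()[picks]
    rows, cols = np.divmod(flat, env.grid.ncols)
    x, y = env.grid.cell_center(rows, cols)
    return OccurrenceSet(species=species, points=np.column_stack([x, y]))


def gen_species_weights(n_features: int, n_species: int, seed: int,
                        n_active: int = 3, scale: float = 12.0) -> dict[str, np.ndarray]:
    """Sparse random Gibbs weights for a community of synthetic species.

    Each species responds strongly to ``n_active`` randomly chosen features
    with N(0, scale^2) weights; the rest are zero, emulating species with a
    few dominant environmental drivers. The default scale makes most — not
    all — species discriminable at test AUC above 0.8, the usual situation
    for a multi-species suitability ensemble.
    """
    rng = np.random.default_rng(seed)
    out: dict[str, np.ndarray] = {}
    for i in range(n_species):
        w = np.zeros(n_features)
        active = rng.choice(n_features, size=min(n_active, n_features), replace=False)
        w[active] = rng.normal(0.0, scale, size=len(active))
        out[f"species_{i + 1:02d}"] = w
    return out


def make_dataset(config: LandscapeConfig) -> SyntheticDataset:
    """Full synthetic study: covariates, occurrences, known-truth richness."""
    env, truth = gen_env_stack(config)
    n_feat = len(env.names)
    truth.true_weights = gen_species_weights(n_feat, config.n_species,
                                             seed=config.seed + 10_000)
    occurrences = [
        gen_occurrences(env, w, config.n_points, seed=config.seed + 20_000 + i,
                        species=name)
        for i, (name, w) in enumerate(truth.true_weights.items())
    ]
    richness = gen_richness_response(env, truth, n_species=config.n_species)
    return SyntheticDataset(env=env, occurrences=occurrences,
                            richness_true=richness, truth=truth)


def simulate_structural_data(coeffs: Mapping[str, float], n: int, seed: int,
                             noise_sd: Mapping[str, float] | None = None,
                             ) -> pd.DataFrame:
    """Plain tabular draw from the structural equations (no spatial field).

    Used to study the path-model estimator itself: T and A are iid standard
    normal, C, S and R follow the structural equations with independent
    Gaussian noise. Residual sds default to the values that give each
    endogenous variable unit variance.
    """
    coef = {**DEFAULT_STRUCTURAL, **dict(coeffs)}
    rng = np.random.default_rng(seed)
    t = rng.standard_normal(n)
    a = rng.standard_normal(n)
    sd = dict(noise_sd or {})
    sd.setdefault("climate", np.sqrt(max(1 - coef["g_ca"] ** 2 - coef["g_ct"] ** 2, 0.05)))
    sd.setdefault("soil", np.sqrt(max(1 - coef["g_sa"] ** 2 - coef["g_st"] ** 2, 0.05)))
    sd.setdefault("richness", _richness_noise_sd(coef))
    c = coef["g_ca"] * a + coef["g_ct"] * t + sd["climate"] * rng.standard_normal(n)
    s = coef["g_sa"] * a + coef["g_st"] * t + sd["soil"] * rng.standard_normal(n)
    r = (coef["b_t"] * t + coef["b_c"] * c + coef["b_s"] * s + coef["b_a"] * a
         + sd["richness"] * rng.standard_normal(n))
    return pd.DataFrame({"T": t, "A": a, "C": c, "S": s, "R": r})
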