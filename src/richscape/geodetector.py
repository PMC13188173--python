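"""Stratified-heterogeneity (q-statistic) attribution of a response surface.

The factor detector measures the share of response variance explained by a
discrete stratification of the landscape:

    q = 1 - SSW / SST = 1 - sum_h N_h sigma_h^2 / (N sigma^2),

with population variances — the classical definition; q is the ANOVA
between-strata share SSB/SST and lies in [0, 1].

The interaction detector overlays two stratifications (distinct label
pairs) and compares q(A∩B) with q(A), q(B) and q(A)+q(B) to classify how
two factors act together. Because the overlay refines both inputs,
q(A∩B) >= max(q(A), q(B)) always holds.

Group-level strata combine every member factor of a covariate group into
one overlay stratification, so whole driver groups (climate, soil,
terrain, anthropogenic) can be compared and crossed.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .grids import EnvStack, RasterGrid
from .stacking import jenks_breaks

logger = logging.getLogger(__name__)

INTERACTION_CLASSES = (
    "nonlinear-weaken",    # q(AB) < min(qA, qB)
    "uni-weaken",          # min <= q(AB) < max
    "bi-enhance",          # max <= q(AB) < qA + qB
    "independent",         # q(AB) = qA + qB
    "nonlinear-enhance",   # q(AB) > qA + qB
)

#: directional (compass) class edges in degrees for circular covariates
ASPECT_EDGES = {4: (45.0, 135.0, 225.0, 315.0),
                8: (22.5, 67.5, 112.5, 157.5, 202.5, 247.5, 292.5, 337.5)}


@dataclass
class StrataMap:
    """Integer stratification (labels 1..H) of the pixel table."""

    labels: np.ndarray       # per pixel-table row
    method: str
    k: int                   # requested classes
    source: tuple[str, ...]  # covariate name(s)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        # relabel to a dense 1..H range
        _, self.labels = np.unique(self.labels, return_inverse=True)
        self.labels += 1

    @property
    def n_strata(self) -> int:
        return int(self.labels.max())


@dataclass
class QResult:
    """Factor/interaction detector output."""

    q: float
    n: int
    strata_stats: pd.DataFrame   # per-stratum count, mean, variance
    p_value: float | None = None
    interaction_class: str | None = None

    def __post_init__(self) -> None:
        if not -1e-12 <= self.q <= 1 + 1e-12:
            raise ValueError(f"q={self.q} outside [0, 1]")
        self.q = float(min(max(self.q, 0.0), 1.0))


def discretize(values: np.ndarray, method: str = "jenks", k: int = 5,
               name: str = "") -> StrataMap:
    """Stratify a continuous covariate into k classes.

    ``jenks`` uses the natural-breaks partition; ``quantile`` uses
    equal-count classes; ``directional`` treats the values as compass
    degrees (circular covariates such as aspect) and uses fixed
    directional sectors (k in {4, 8}), not data-driven breaks. Classes
    that come out empty are merged into their neighbour and the final
    class count recorded.
    """
    v = np.asarray(values, dtype=float).ravel()
    if len(np.unique(v)) < 2:
        raise ValueError("covariate has fewer than 2 distinct values")
    if method == "jenks":
        kk = min(k, len(np.unique(v)))
        labels = jenks_breaks(v, kk).classify(v)
    elif method == "quantile":
        edges = np.quantile(v, np.linspace(0, 1, k + 1)[1:-1])
        labels = np.searchsorted(edges, v, side="right") + 1
    elif method == "directional":
        if k not in ASPECT_EDGES:
            raise ValueError("directional classes support k in {4, 8}")
        deg = np.mod(v, 360.0)
        labels = np.searchsorted(ASPECT_EDGES[k], deg) % k + 1
    else:
        raise ValueError(f"unknown discretization method {method!r}")
    return StrataMap(labels=labels, method=method, k=k, source=(name,))


def _group_stats(response: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    counts = np.bincount(labels)[1:]
    sums = np.bincount(labels, weights=response)[1:]
    sq = np.bincount(labels, weights=response ** 2)[1:]
    means = sums / counts
    var = sq / counts - means ** 2   # population variance per stratum
    return pd.DataFrame({"count": counts, "mean": means,
                         "variance": np.maximum(var, 0.0)},
                        index=pd.RangeIndex(1, len(counts) + 1, name="stratum"))


def factor_q(response: np.ndarray, strata: StrataMap) -> QResult:
    """Variance share explained by one stratification."""
    y = np.asarray(response, dtype=float).ravel()
    if len(y) != len(strata.labels):
        raise ValueError("response and strata lengths differ")
    n = len(y)
    total_var = float(np.var(y))
    if total_var == 0:
        raise ValueError("response has zero variance; q undefined")
    stats = _group_stats(y, strata.labels)
    ssw = float((stats["count"] * stats["variance"]).sum())
    q = 1.0 - ssw / (n * total_var)
    return QResult(q=q, n=n, strata_stats=stats)


def overlay(a: StrataMap, b: StrataMap) -> StrataMap:
    """Cartesian intersection of two stratifications."""
    pair = a.labels.astype(np.int64) * (b.labels.max() + 1) + b.labels
    return StrataMap(labels=pair, method=f"{a.method}x{b.method}",
                     k=a.n_strata * b.n_strata, source=a.source + b.source)


def classify_interaction(q_ab: float, q_a: float, q_b: float,
                         tol: float = 1e-9) -> str:
    """Standard interaction-detector taxonomy."""
    lo, hi = min(q_a, q_b), max(q_a, q_b)
    s = q_a + q_b
    if abs(q_ab - s) <= tol:
        return "independent"
    if q_ab > s:
        return "nonlinear-enhance"
    if q_ab >= hi:
        return "bi-enhance"
    if q_ab >= lo:
        return "uni-weaken"
    return "nonlinear-weaken"


def interaction_q(response: np.ndarray, strata_a: StrataMap,
                  strata_b: StrataMap) -> QResult:
    """q of the two-factor overlay, with its interaction class."""
    q_a = factor_q(response, strata_a).q
    q_b = factor_q(response, strata_b).q
    res = factor_q(response, overlay(strata_a, strata_b))
    res.interaction_class = classify_interaction(res.q, q_a, q_b)
    return res


def group_strata(env: EnvStack, members: Sequence[str], k: int = 3,
                 method: str = "jenks", min_count: int = 10,
                 directional: Sequence[str] = ("asp",)) -> StrataMap:
    """Joint stratification of all members of one covariate group.

    Labels are the distinct tuples of per-member class labels. Overlay
    strata smaller than ``min_count`` pixels are merged into the stratum
    with the nearest centroid in the members' standardized value space
    (tiny strata otherwise inflate q); merges are logged.
    """
    if not members:
        raise ValueError("group has no members")
    table = env.pixel_table
    cur: StrataMap | None = None
    for m in members:
        meth = "directional" if m in directional else method
        kk = 8 if (meth == "directional" and k > 4) else (4 if meth == "directional" else k)
        sm = discretize(table[m].to_numpy(), method=meth, k=kk, name=m)
        cur = sm if cur is None else overlay(cur, sm)
    if cur.n_strata < 2:
        raise ValueError("group overlay produced a single stratum")
    labels = cur.labels
    X = ((table[list(members)] - table[list(members)].mean())
         / table[list(members)].std()).to_numpy()
    counts = np.bincount(labels)
    small = [h for h in range(1, len(counts)) if 0 < counts[h] < min_count]
    if small:
        big = [h for h in range(1, len(counts)) if counts[h] >= min_count]
        if big:
            centroids = {h: X[labels == h].mean(axis=0) for h in big}
            for h in small:
                c = X[labels == h].mean(axis=0)
                target = min(big, key=lambda g: float(np.sum((centroids[g] - c) ** 2)))
                labels = np.where(labels == h, target, labels)
            logger.info("merged %d strata smaller than %d pixels", len(small),
                        min_count)
    out = StrataMap(labels=labels, method=cur.method, k=cur.k,
                    source=tuple(members))
    return out


def factor_q_table(response: np.ndarray, env: EnvStack, method: str = "jenks",
                   k: int = 5, directional: Sequence[str] = ("asp",)) -> pd.DataFrame:
    """Factor detector q for every covariate, sorted descending."""
    rows = {}
    table = env.pixel_table
    for name in env.names:
        meth = "directional" if name in directional else method
        kk = 8 if meth == "directional" else k
        strata = discretize(table[name].to_numpy(), method=meth, k=kk, name=name)
        rows[name] = factor_q(response, strata).q
    out = pd.DataFrame({"q": pd.Series(rows)}).sort_values("q", ascending=False)
    out.index.name = "covariate"
    return out


def pairwise_interaction_matrix(response: np.ndarray, env: EnvStack,
                                method: str = "jenks", k: int = 5,
                                directional: Sequence[str] = ("asp",),
                                ) -> pd.DataFrame:
    """Symmetric matrix of two-factor interaction q values."""
    table = env.pixel_table
    strata = {}
    for name in env.names:
        meth = "directional" if name in directional else method
        kk = 8 if meth == "directional" else k
        strata[name] = discretize(table[name].to_numpy(), method=meth, k=kk,
                                  name=name)
    names = env.names
    M = pd.DataFrame(np.nan, index=names, columns=names)
    for a, b in itertools.combinations(names, 2):
        q = factor_q(response, overlay(strata[a], strata[b])).q
        M.loc[a, b] = M.loc[b, a] = q
    for a in names:
        M.loc[a, a] = factor_q(response, strata[a]).q
    return M


def group_interaction_table(response: np.ndarray, env: EnvStack,
                            per_factor_k: int = 5, group_k: int = 3,
                            method: str = "jenks", min_count: int = 10,
                            directional: Sequence[str] = ("asp",),
                            ) -> dict[str, pd.DataFrame]:
    """Group-level interaction matrices under both readings.

    ``combined``: q of the overlay of the two groups' joint (combined)
    strata — the "factors jointly combined" reading. ``mean-pairwise``:
    the mean of two-factor interaction q over all cross-group member
    pairs (within-group: over member pairs inside the group). Both are
    returned, labelled; diagonal entries are the within-group values.
    """
    groups = {g: env.group_members(g) for g in set(env.groups.values())}
    groups = {g: m for g, m in groups.items() if m}
    gnames = sorted(groups)
    gstrata = {g: group_strata(env, groups[g], k=group_k, method=method,
                               min_count=min_count, directional=directional)
               for g in gnames}
    combined = pd.DataFrame(np.nan, index=gnames, columns=gnames)
    for a, b in itertools.combinations(gnames, 2):
        q = factor_q(response, overlay(gstrata[a], gstrata[b])).q
        combined.loc[a, b] = combined.loc[b, a] = q
    for g in gnames:
        combined.loc[g, g] = factor_q(response, gstrata[g]).q

    table = env.pixel_table
    fstrata = {}
    for name in env.names:
        meth = "directional" if name in directional else method
        kk = 8 if meth == "directional" else per_factor_k
        fstrata[name] = discretize(table[name].to_numpy(), method=meth, k=kk,
                                   name=name)
    mean_pw = pd.DataFrame(np.nan, index=gnames, columns=gnames)
    for a, b in itertools.combinations_with_replacement(gnames, 2):
        if a == b:
            pairs = list(itertools.combinations(groups[a], 2))
        else:
            pairs = list(itertools.product(groups[a], groups[b]))
        if not pairs:
            continue
        qs = [factor_q(response, overlay(fstrata[u], fstrata[v])).q
              for u, v in pairs]
        mean_pw.loc[a, b] = mean_pw.loc[b, a] = float(np.mean(qs))
    return {"combined": combined, "mean-pairwise": mean_pw}


def q_significance(response: np.ndarray, strata: StrataMap, n_perm: int = 199,
                   seed: int = 0) -> float:
    """Permutation p-value of the observed q under a shuffled response."""
    if n_perm < 99:
        raise ValueError("use at least 99 permutations")
    y = np.asarray(response, dtype=float).ravel()
    q_obs = factor_q(y, strata).q
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        q = factor_q(rng.permutation(y), strata).q
        if q >= q_obs:
            exceed += 1
    return (1 + exceed) / (1 + n_perm)
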