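"""Suitability thresholding and species-richness stacking.

Per species, the continuous suitability surface is binarized at its natural
(Fisher-Jenks) breakpoint:

    B_i(x) = 1  if P_i(x) > T_i,   else 0,

and richness is the per-pixel stack R(x) = sum_i B_i(x) over species.

``jenks_breaks`` implements the exact Fisher-Jenks dynamic programme:
the optimal partition of sorted values into k contiguous classes minimizing
the total within-class sum of squared deviations. For very large inputs the
programme runs on a deterministic equal-quantile subsample (the class
structure of a smooth empirical distribution is preserved; see docs).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import AlignmentError, EnvStack, RasterGrid

#: above this many values the DP runs on an equal-quantile subsample
JENKS_EXACT_LIMIT = 3000


@dataclass
class BreaksResult:
    """Natural-breaks classification of a 1-D sample."""

    breakpoints: np.ndarray   # k-1 ascending cut values (class boundaries)
    k: int
    gvf: float                # goodness of variance fit, 1 - SSW/SST
    sswd: float               # total within-class sum of squared deviations
    class_edges: list[tuple[float, float]] = field(default_factory=list)
    subsampled: bool = False

    def classify(self, values: np.ndarray) -> np.ndarray:
        """Class labels 1..k (breakpoints are upper-open boundaries)."""
        return np.searchsorted(self.breakpoints, values, side="left") + 1


def _prefix_sse(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    s1 = np.concatenate([[0.0], np.cumsum(x)])
    s2 = np.concatenate([[0.0], np.cumsum(x * x)])
    return s1, s2


def _segment_sse(s1: np.ndarray, s2: np.ndarray, j: np.ndarray, i: int) -> np.ndarray:
    """SSE of sorted segments x[j..i] inclusive, vectorized over j."""
    n = i - j + 1
    tot = s1[i + 1] - s1[j]
    return (s2[i + 1] - s2[j]) - tot * tot / n


def jenks_breaks(values: np.ndarray, k: int) -> BreaksResult:
    """Optimal k-class natural breaks of a 1-D sample.

    Dynamic programme over the sorted values: O(k n^2) time with
    vectorized inner minimization. Breakpoints are placed midway between
    the last value of one class and the first value of the next (the DP
    yields a boundary pair of values, not a point).
    """
    x = np.sort(np.asarray(values, dtype=float).ravel())
    x = x[np.isfinite(x)]
    if k < 2:
        raise ValueError("k must be at least 2")
    n_distinct = len(np.unique(x))
    if n_distinct < k:
        raise ValueError(f"need at least k={k} distinct values, "
                         f"got {n_distinct}")
    subsampled = False
    if len(x) > JENKS_EXACT_LIMIT:
        # deterministic equal-quantile thinning keeps the distribution shape
        q = np.linspace(0, 1, JENKS_EXACT_LIMIT)
        x = np.quantile(x, q, method="closest_observation")
        subsampled = True
    n = len(x)
    s1, s2 = _prefix_sse(x)
    # cost[i] = optimal SSW of x[0..i] with the current number of classes
    zeros = np.zeros(1, dtype=int)
    cost = np.array([_segment_sse(s1, s2, zeros, i)[0] for i in range(n)])
    # start[c][i] = first index of the last class in the optimal partition
    starts = np.zeros((k, n), dtype=int)
    for c in range(1, k):
        new_cost = np.full(n, np.inf)
        for i in range(c, n):
            j = np.arange(c, i + 1)           # last class starts at j
            cand = cost[j - 1] + _segment_sse(s1, s2, j, i)
            a = int(np.argmin(cand))
            new_cost[i] = cand[a]
            starts[c, i] = j[a]
        cost = new_cost
    # backtrack boundaries
    sswd = float(cost[n - 1])
    edges_idx = []
    i = n - 1
    for c in range(k - 1, 0, -1):
        j = starts[c, i]
        edges_idx.append(j)
        i = j - 1
    edges_idx.reverse()
    breakpoints = np.array([(x[j - 1] + x[j]) / 2.0 for j in edges_idx])
    sst = float(np.sum((x - x.mean()) ** 2))
    class_edges = []
    bounds = [0] + edges_idx + [n]
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        class_edges.append((float(x[lo]), float(x[hi - 1])))
    return BreaksResult(breakpoints=breakpoints, k=k,
                        gvf=1.0 - sswd / sst if sst > 0 else 1.0,
                        sswd=sswd, class_edges=class_edges,
                        subsampled=subsampled)


def species_threshold(suitability: RasterGrid, k: int = 2) -> tuple[float, dict]:
    """Natural-breaks binarization threshold for one suitability surface.

    With the default k=2 the threshold is the single Jenks breakpoint
    (midpoint of the boundary value pair). For k > 2 the highest
    breakpoint is used, separating the top class from the rest. The
    choice is recorded in the returned provenance metadata.
    """
    vals = suitability.unmasked()
    if len(np.unique(vals)) < 2:
        raise ValueError(
            "suitability surface is constant; no natural threshold exists — "
            "supply a manual threshold instead")
    br = jenks_breaks(vals, k=k)
    t = float(br.breakpoints[-1])
    meta = {"method": "jenks", "k": k, "break_index": k - 1,
            "breakpoints": br.breakpoints.tolist(), "gvf": br.gvf,
            "subsampled": br.subsampled}
    return t, meta


def binarize(suitability: RasterGrid, threshold: float) -> RasterGrid:
    """Suitable/unsuitable map: 1 where P > T (strictly), 0 where P <= T."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    vals = (suitability.values > threshold).astype(float)
    vals[suitability.mask] = np.nan
    return suitability.with_values(vals, name=f"{suitability.name}_binary")


@dataclass
class RichnessMap:
    grid: RasterGrid
    n_species: int

    def __post_init__(self) -> None:
        v = self.grid.unmasked()
        if len(v) and (v.min() < 0 or v.max() > self.n_species):
            raise ValueError("richness outside [0, n_species]")


def stack_richness(binary_maps: list[RasterGrid]) -> RichnessMap:
    """Per-pixel species count from binarized suitability maps.

    Nodata follows the union rule: a pixel masked in any species map is
    masked in the richness map.
    """
    if not binary_maps:
        raise ValueError("no maps to stack")
    ref = binary_maps[0]
    total = np.zeros(ref.shape)
    mask = np.zeros(ref.shape, dtype=bool)
    for g in binary_maps:
        if not g.same_geometry(ref):
            raise AlignmentError(f"map {g.name!r} not aligned with {ref.name!r}")
        ok = ~g.mask
        if not np.all(np.isin(g.values[ok], (0.0, 1.0))):
            raise ValueError(f"map {g.name!r} is not binary")
        mask |= g.mask
        total += np.where(ok, g.values, 0.0)
    total[mask] = np.nan
    return RichnessMap(grid=ref.with_values(total, name="richness", mask=mask),
                       n_species=len(binary_maps))


def richness_correlations(richness: RasterGrid, env: EnvStack) -> pd.Series:
    """Pixelwise Pearson correlation of richness with each covariate.

    Computed over pixels jointly unmasked in the richness map and every
    covariate layer, sorted descending. A constant richness surface has
    no defined correlation; NaNs are reported with a warning.
    """
    mask = env.mask | richness.mask
    keep = ~mask
    if keep.sum() < 3:
        raise ValueError("need at least 3 jointly unmasked pixels")
    r_vals = richness.values[keep]
    if np.all(r_vals == r_vals[0]):
        warnings.warn("richness is constant; correlations undefined",
                      UserWarning, stacklevel=2)
        return pd.Series({n: np.nan for n in env.names})
    out = {n: float(np.corrcoef(r_vals, g.values[keep])[0, 1])
           for n, g in env.layers.items()}
    return pd.Series(out).sort_values(ascending=False)
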