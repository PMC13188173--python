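"""Covariate screening for the multi-species suitability ensemble.

The screen runs in three steps, all driven by per-species percentage
contributions (each species row sums to ~100):

1. per species, keep the smallest set of top-ranked covariates whose
   cumulative contribution reaches 95%;
2. count, per covariate, how many species selected it (its occurrence
   frequency); covariates never selected are excluded;
3. among highly collinear pairs (|Pearson r| > 0.8 over the pixel table),
   keep the covariate with the higher occurrence frequency.

A separate summary statistic counts, per covariate, how often it ranks
among a species' top three contributors.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def cumulative95_select(contributions: Mapping[str, float] | pd.Series,
                        cum_pct: float = 95.0) -> list[str]:
    """Minimal descending-sorted prefix reaching the cumulative cutoff.

    Ties in contribution are broken lexicographically by covariate name so
    the selection is independent of input order. The cutoff is inclusive:
    a prefix summing to exactly ``cum_pct`` qualifies.
    """
    s = pd.Series(dict(contributions), dtype=float)
    if (s < 0).any():
        raise ValueError("contributions must be non-negative")
    if s.sum() == 0:
        warnings.warn("all contributions are zero; nothing selected",
                      UserWarning, stacklevel=2)
        return []
    order = sorted(s.index, key=lambda c: (-s[c], c))
    out, cum = [], 0.0
    for cov in order:
        out.append(cov)
        cum += s[cov]
        if cum >= cum_pct:
            break
    return out


def occurrence_frequency(selected_sets: Mapping[str, Sequence[str]]) -> pd.Series:
    """Per covariate, the number of species whose 95% set contains it.

    Covariates with zero frequency never appear in the result (they are
    excluded from all further analysis); exclusions are logged.
    """
    if not selected_sets:
        raise ValueError("need at least one species")
    counts: dict[str, int] = {}
    for covs in selected_sets.values():
        for c in covs:
            counts[c] = counts.get(c, 0) + 1
    freq = pd.Series(counts, dtype=int).sort_values(ascending=False)
    return freq


@dataclass
class PruneDecision:
    kept: str
    dropped: str
    r: float
    reason: str


def correlation_prune(pixel_table: pd.DataFrame, freq: Mapping[str, int] | pd.Series,
                      threshold: float = 0.8,
                      total_contribution: Mapping[str, float] | None = None,
                      ) -> tuple[list[str], list[PruneDecision]]:
    """Drop the lower-frequency member of each highly correlated pair.

    Pearson correlations are computed over the (already unmasked) pixel
    table. Offending pairs (strictly ``|r| > threshold``) are processed in
    descending |r|; within a pair the covariate with lower occurrence
    frequency is dropped (frequency tie -> lower total contribution;
    still tied -> lexicographically later name). A covariate already
    dropped cannot trigger further drops. Every decision is returned.
    """
    freq = pd.Series(dict(freq), dtype=float)
    covs = [c for c in pixel_table.columns if c in freq.index]
    if len(covs) < 2:
        return covs, []
    sub = pixel_table[covs]
    constant = [c for c in covs if sub[c].nunique() <= 1]
    decisions: list[PruneDecision] = []
    for c in constant:
        warnings.warn(f"covariate {c!r} is constant; correlation undefined, "
                      "dropped", UserWarning, stacklevel=2)
        decisions.append(PruneDecision(kept="", dropped=c, r=float("nan"),
                                       reason="constant covariate"))
    covs = [c for c in covs if c not in constant]
    corr = sub[covs].corr()
    total = pd.Series(dict(total_contribution or {}), dtype=float)

    def survival_rank(c: str):
        # sort ascending: first element survives (higher frequency, then
        # higher total contribution, then lexicographically earlier name)
        return (-freq.get(c, 0), -total.get(c, 0.0), c)

    pairs = [(abs(corr.loc[a, b]), a, b)
             for i, a in enumerate(covs) for b in covs[i + 1:]
             if abs(corr.loc[a, b]) > threshold]
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    dropped: set[str] = set()
    for r, a, b in pairs:
        if a in dropped or b in dropped:
            continue
        winner, loser = sorted((a, b), key=survival_rank)
        dropped.add(loser)
        decisions.append(PruneDecision(kept=winner, dropped=loser,
                                       r=float(corr.loc[a, b]),
                                       reason=f"|r|={r:.3f} > {threshold}"))
        logger.info("pruned %s (kept %s, |r|=%.3f)", loser, winner, r)
    retained = [c for c in covs if c not in dropped]
    return retained, decisions


def top3_frequency(contribution_table: pd.DataFrame, top_n: int = 3) -> pd.Series:
    """Count, per covariate, its appearances among species' top contributors.

    ``contribution_table`` is species (rows) x covariates (columns). Ties
    at the cut are broken lexicographically by name. Counts conserve:
    their sum equals ``top_n * n_species``.
    """
    if contribution_table.shape[1] < top_n:
        raise ValueError(f"need at least {top_n} covariates per species")
    counts = pd.Series(0, index=sorted(contribution_table.columns), dtype=int)
    for _, row in contribution_table.iterrows():
        order = sorted(row.index, key=lambda c: (-row[c], c))
        counts[order[:top_n]] += 1
    return counts.sort_values(ascending=False)


def select_covariates(contribution_table: pd.DataFrame,
                      pixel_table: pd.DataFrame,
                      cum_pct: float = 95.0, threshold: float = 0.8,
                      ) -> dict:
    """Full screening pipeline; returns all intermediate artifacts."""
    sets = {sp: cumulative95_select(row, cum_pct=cum_pct)
            for sp, row in contribution_table.iterrows()}
    freq = occurrence_frequency(sets)
    retained, decisions = correlation_prune(
        pixel_table, freq, threshold=threshold,
        total_contribution=contribution_table.sum(axis=0).to_dict())
    return {"selected_sets": sets, "frequency": freq, "retained": retained,
            "prune_log": decisions,
            "top3": top3_frequency(contribution_table)}
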