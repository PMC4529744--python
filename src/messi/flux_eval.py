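"""Flux-based evaluation of gene rankings from deletion simulations.

Consumes a precomputed gene-deletion x reaction flux matrix (e.g. FBA
single-deletion scans of a genome-scale model) plus the wild-type flux
vector.  Fluxes of each reaction across deletions are assumed normally
distributed around the wild-type flux; each flux becomes a Z-score

    Z[d, r] = (F[d, r] - wt[r]) / sd_r,
    sd_r = sqrt(mean over deletions of (F[., r] - wt[r])^2)

with a two-sided normal P value.  Reactions never perturbed in any
deletion are removed first.  Per (deletion, pathway) the proportion of
that pathway's reactions with P < 0.05 summarizes how broadly the
deletion disturbs the pathway; pathways with fewer than 6 retained
reactions are dropped.  Finally the proportions of deletions of
top-ranked genes are compared against all other deletions with a Welch
two-sample t-test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

FLUX_SIG_P = 0.05
MIN_REACTIONS = 6


@dataclass
class FluxTable:
    deletions: list[str]  # deleted-gene ids
    reactions: list[str]
    flux: np.ndarray  # deletions x reactions
    wild_type: np.ndarray  # per reaction
    reaction_pathways: dict[str, set[str]]  # reaction -> pathway ids

    def __post_init__(self) -> None:
        self.flux = np.asarray(self.flux, dtype=float)
        self.wild_type = np.asarray(self.wild_type, dtype=float)
        if self.flux.shape != (len(self.deletions), len(self.reactions)):
            raise ValueError("flux matrix shape mismatch")
        if self.wild_type.shape != (len(self.reactions),):
            raise ValueError("wild-type vector misaligned with reactions")


@dataclass
class FluxScores:
    deletions: list[str]
    reactions: list[str]
    z: np.ndarray
    p: np.ndarray


def flux_zscores(table: FluxTable) -> FluxScores:
    """Z-score every (deletion, reaction) flux against wild type.

    Needs >= 2 deletions.  Unperturbed reactions (identical to wild type
    in every deletion) are removed before scoring, which also guarantees
    a nonzero spread for every retained reaction.
    """
    if len(table.deletions) < 2:
        raise ValueError("need at least 2 deletion simulations")
    dev = table.flux - table.wild_type[None, :]
    perturbed = ~np.all(dev == 0, axis=0)
    if not perturbed.any():
        raise ValueError("no reaction is perturbed in any deletion")
    dev = dev[:, perturbed]
    reactions = [r for r, keep in zip(table.reactions, perturbed) if keep]
    sd = np.sqrt(np.mean(dev**2, axis=0))
    sd = np.where(sd == 0, np.nan, sd)  # cannot happen after the filter; guarded
    z = dev / sd[None, :]
    p = 2.0 * stats.norm.sf(np.abs(z))
    return FluxScores(deletions=list(table.deletions), reactions=reactions, z=z, p=p)


def pathway_flux_proportions(
    scores: FluxScores,
    reaction_pathways: dict[str, set[str]],
    min_reactions: int = MIN_REACTIONS,
    sig_p: float = FLUX_SIG_P,
    valid_pathways: set[str] | None = None,
) -> pd.DataFrame:
    """Fraction of significantly altered reactions per (deletion, pathway).

    ``valid_pathways`` optionally restricts to pathways with usable
    activity information.  Pathways with fewer than ``min_reactions``
    retained reactions are excluded.  Returns a deletions x pathways
    DataFrame of proportions.
    """
    pathway_members: dict[str, list[int]] = {}
    for j, r in enumerate(scores.reactions):
        for pid in reaction_pathways.get(r, set()):
            pathway_members.setdefault(pid, []).append(j)
    cols = {}
    for pid, idx in sorted(pathway_members.items()):
        if valid_pathways is not None and pid not in valid_pathways:
            continue
        if len(idx) < min_reactions:
            continue
        cols[pid] = (scores.p[:, idx] < sig_p).mean(axis=1)
    return pd.DataFrame(cols, index=scores.deletions)


@dataclass
class TopkComparison:
    mean_topk: float
    mean_rest: float
    t_statistic: float
    p_value: float
    n_topk: int
    n_rest: int


def topk_vs_rest(
    proportions: pd.DataFrame, topk_genes: dict[str, list[str]]
) -> TopkComparison:
    """Compare perturbation proportions of top-ranked genes vs the rest.

    ``topk_genes`` maps pathway id -> top-k deleted-gene ids for that
    pathway.  Per pathway, the deletions of its top genes contribute to
    one pooled sample and the remaining deletions to the other; the
    pools are compared with a Welch t-test.
    """
    top_vals: list[float] = []
    rest_vals: list[float] = []
    for pid in proportions.columns:
        top = set(topk_genes.get(pid, []))
        for gene in proportions.index:
            v = float(proportions.loc[gene, pid])
            (top_vals if gene in top else rest_vals).append(v)
    if not top_vals or not rest_vals:
        raise ValueError("both comparison groups must be non-empty")
    t, p = stats.ttest_ind(top_vals, rest_vals, equal_var=False)
    return TopkComparison(
        mean_topk=float(np.mean(top_vals)),
        mean_rest=float(np.mean(rest_vals)),
        t_statistic=float(t),
        p_value=float(p),
        n_topk=len(top_vals),
        n_rest=len(rest_vals),
    )
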