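"""Metabolomics-derived pathway activity scores.

Compound abundances are first normalized to ratios against each compound's
mean over strains, then summed per pathway with a coverage weight: for
strain ``s`` and pathway ``p``,

    PA[s, p] = (1 / K_p) * sum over detected compounds c in p of I[s, c]

where ``I`` is the normalized abundance and ``K_p`` the total number of
compounds annotated to the pathway.  A compound is *detected* when it is
measured (non-missing) in every strain; pathways with no detected compound
yield no activity column and are reported as unused.  Downstream per-pathway
min-max normalization makes any monotone affine per-pathway rescaling of
these scores equivalent, so the coverage factor cannot affect rankings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model_io import MetaboliteTable, PathwayDefinition, StrainSet

logger = logging.getLogger(__name__)


@dataclass
class ActivityMatrix:
    """Strain x pathway raw activity scores with detection provenance."""

    strains: StrainSet
    pathways: list[PathwayDefinition]
    PA: pd.DataFrame  # index = strains, columns = pathway ids
    detected_compounds: dict[str, int]  # pathway id -> n detected
    unused_pathways: list[str]

    def universal_flags(self) -> pd.Series:
        return pd.Series(
            {p.pathway_id: p.universal for p in self.pathways}, name="universal"
        ).reindex(self.PA.columns)

    def pathway_by_id(self, pathway_id: str) -> PathwayDefinition:
        for p in self.pathways:
            if p.pathway_id == pathway_id:
                return p
        raise KeyError(pathway_id)


def normalize_abundance(table: MetaboliteTable) -> MetaboliteTable:
    """Convert abundances to ratios against each compound's mean over
    strains (missing values excluded from the mean).

    Compounds whose mean is zero or that are entirely missing carry no
    usable signal and are dropped with a warning.
    """
    df = table.abundance
    means = df.mean(axis=0, skipna=True)
    keep = []
    for c in df.columns:
        m = means[c]
        if np.isnan(m):
            logger.warning("compound %s is entirely missing; dropped", c)
        elif m == 0:
            logger.warning("compound %s has zero mean abundance; dropped", c)
        else:
            keep.append(c)
    normed = df[keep] / means[keep]
    return MetaboliteTable(strains=table.strains, abundance=normed)


def compute_pa(
    normed: MetaboliteTable, pathways: list[PathwayDefinition], invert: bool = False
) -> ActivityMatrix:
    """Score every pathway in every strain from normalized abundances.

    ``invert`` negates the scores for users preferring the inverse-flux
    reading of pathway activity; ranking behavior under a matching flipped
    expectation is unchanged.
    """
    if not pathways:
        raise ValueError("empty pathway list")
    df = normed.abundance
    measured = set(df.columns[df.notna().all(axis=0)])
    cols: dict[str, np.ndarray] = {}
    detected: dict[str, int] = {}
    unused: list[str] = []
    kept: list[PathwayDefinition] = []
    for p in pathways:
        hits = sorted(p.compounds & measured)
        if not hits:
            unused.append(p.pathway_id)
            continue
        k_total = len(p.compounds)
        col = df[hits].to_numpy(dtype=float).sum(axis=1) / k_total
        cols[p.pathway_id] = -col if invert else col
        detected[p.pathway_id] = len(hits)
        kept.append(p)
    pa = pd.DataFrame(cols, index=list(normed.strains.strain_ids))
    return ActivityMatrix(
        strains=normed.strains,
        pathways=kept,
        PA=pa,
        detected_compounds=detected,
        unused_pathways=unused,
    )
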