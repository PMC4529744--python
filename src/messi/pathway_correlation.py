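"""Pairwise Pearson correlation of pathway activity profiles.

All unordered pairs of non-universal pathways are tested; two-sided P
values come from the t-distribution transform of r, and are Bonferroni
adjusted over the number of tested pairs (reported as Q = min(1, P * m),
following the source tool's terminology).  Significance is Q < 0.05.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .pathway_activity import ActivityMatrix

logger = logging.getLogger(__name__)

SIGNIFICANCE_Q = 0.05


@dataclass(frozen=True)
class CorrelationResult:
    pathway_a: str
    pathway_b: str
    r: float
    p_value: float
    q_value: float
    significant: bool

    @property
    def pair(self) -> frozenset[str]:
        return frozenset((self.pathway_a, self.pathway_b))


def correlate_pathways(
    activity: ActivityMatrix | pd.DataFrame,
    universal_flags: pd.Series | None = None,
    alpha: float = SIGNIFICANCE_Q,
) -> list[CorrelationResult]:
    """Test every unordered pair of non-universal pathway activity columns.

    Constant columns make r undefined; such pairs are skipped with a
    warning and do not enter the Bonferroni family.
    """
    if isinstance(activity, ActivityMatrix):
        pa = activity.PA
        if universal_flags is None:
            universal_flags = activity.universal_flags()
    else:
        pa = activity
    if universal_flags is None:
        universal_flags = pd.Series(False, index=pa.columns)
    cols = [c for c in pa.columns if not bool(universal_flags.get(c, False))]
    if len(pa.index) < 3:
        raise ValueError("Pearson P values need at least 3 strains")
    if len(cols) < 2:
        raise ValueError("need at least 2 non-universal pathways")

    raw: list[tuple[str, str, float, float]] = []
    for a, b in combinations(sorted(cols), 2):
        x = pa[a].to_numpy(dtype=float)
        y = pa[b].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            logger.warning("constant activity column in pair (%s, %s); skipped", a, b)
            continue
        res = stats.pearsonr(x, y)
        raw.append((a, b, float(res.statistic), float(res.pvalue)))

    m = len(raw)
    out = []
    for a, b, r, p in raw:
        q = min(1.0, p * m)
        out.append(
            CorrelationResult(
                pathway_a=a, pathway_b=b, r=r, p_value=p, q_value=q,
                significant=q < alpha,
            )
        )
    return out


def correlated_partners(
    results: list[CorrelationResult], target: str
) -> list[str]:
    """Pathways significantly correlated with ``target``, by ascending Q."""
    hits = [
        (res.q_value, res.pathway_b if res.pathway_a == target else res.pathway_a)
        for res in results
        if res.significant and target in res.pair
    ]
    return [p for _, p in sorted(hits)]


def correlation_table(results: list[CorrelationResult]) -> pd.DataFrame:
    df = pd.DataFrame(
        [
            {
                "pathway_a": r.pathway_a,
                "pathway_b": r.pathway_b,
                "r": r.r,
                "p_value": r.p_value,
                "q_value": r.q_value,
                "significant": int(r.significant),
            }
            for r in results
        ],
        columns=["pathway_a", "pathway_b", "r", "p_value", "q_value", "significant"],
    )
    if len(df):
        df = df.sort_values("q_value", kind="mergesort").reset_index(drop=True)
    return df
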