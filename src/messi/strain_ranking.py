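"""Strain ranking by weighted aggregation of pathway activities.

Raw activities are min-max normalized per pathway (PAN), folded against a
user expectation E (PAT = 1 - |E - PAN|), and fused across pathways with
non-negative weights by one of two algorithms:

* WASF (Weighted AddScore Fuse): FS_i = sum_j PAT[i, j] * W_j
* WBF  (Weighted Borda Fuse):    FS_i = sum_j B[i, j] * W_j, where
  B[i, j] counts strains with strictly lower PAT than strain i in
  pathway j (ties share the count).

Higher fused score is better; final ties break by strain ID ascending.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

EXPECTATION_LABELS = {"very_weak": 0.0, "medium": 0.5, "very_active": 1.0}
VALID_EXPECTATIONS = (0.0, 0.5, 1.0)


@dataclass
class RankingConfig:
    """Per-pathway expectation and weight plus the fusion algorithm.

    ``expectation`` maps pathway id -> E in {0, 0.5, 1} (labels Very Weak /
    Medium / Very Active); ``weight`` maps pathway id -> W >= 0.  Universal
    pathways default to weight 0 when built via :meth:`from_pathways`.
    ``allow_any_expectation`` lifts the closed-set check for power users;
    the transfer formula itself admits any E in [0, 1].
    """

    expectation: dict[str, float]
    weight: dict[str, float]
    algorithm: str = "WASF"
    allow_any_expectation: bool = False

    def __post_init__(self) -> None:
        self.algorithm = self.algorithm.upper()
        if self.algorithm not in ("WASF", "WBF"):
            raise ValueError(f"unknown aggregation algorithm {self.algorithm!r}")
        for pid, e in self.expectation.items():
            if not self.allow_any_expectation and e not in VALID_EXPECTATIONS:
                raise ValueError(
                    f"expectation for {pid} must be one of {VALID_EXPECTATIONS}"
                )
            if not 0.0 <= e <= 1.0:
                raise ValueError(f"expectation for {pid} outside [0, 1]")
        for pid, w in self.weight.items():
            if w < 0:
                raise ValueError(f"negative weight for {pid}")

    @classmethod
    def from_pathways(
        cls,
        pathway_ids: list[str],
        universal: dict[str, bool] | None = None,
        expectation: float | dict[str, float] = 1.0,
        weight: float | dict[str, float] = 1.0,
        algorithm: str = "WASF",
    ) -> "RankingConfig":
        universal = universal or {}
        exp = {
            pid: (expectation[pid] if isinstance(expectation, dict) else expectation)
            for pid in pathway_ids
        }
        wts = {}
        for pid in pathway_ids:
            if isinstance(weight, dict):
                wts[pid] = weight[pid]
            else:
                wts[pid] = 0.0 if universal.get(pid, False) else weight
        return cls(expectation=exp, weight=wts, algorithm=algorithm)


@dataclass
class FusedRanking:
    fused_score: pd.Series  # index = strain ids
    rank: pd.Series  # 1 = best
    PAT: pd.DataFrame

    def __post_init__(self) -> None:
        ranks = sorted(self.rank.to_list())
        if ranks != list(range(1, len(ranks) + 1)):
            raise ValueError("ranks must be a permutation of 1..n")

    def top(self, k: int = 5) -> list[str]:
        order = self.rank.sort_values().index
        return list(order[: min(k, len(order))])


def normalize_pan(PA: pd.DataFrame) -> pd.DataFrame:
    """Min-max normalize each pathway column to [0, 1].

    A degenerate column (max == min) carries no ranking information and is
    set to 0.5 everywhere, with a warning.
    """
    lo, hi = PA.min(axis=0), PA.max(axis=0)
    span = hi - lo
    pan = pd.DataFrame(0.5, index=PA.index, columns=PA.columns)
    for c in PA.columns:
        if span[c] == 0:
            logger.warning("pathway %s has constant activity; PAN set to 0.5", c)
        else:
            pan[c] = (PA[c] - lo[c]) / span[c]
    return pan


def transfer_pat(PAN: pd.DataFrame, expectation: dict[str, float]) -> pd.DataFrame:
    """Fold normalized activity against the expectation: PAT = 1 - |E - PAN|.

    PAT reaches 1 exactly where PAN equals E, so strains closest to the
    desired activity level score highest.
    """
    missing = set(PAN.columns) - set(expectation)
    if missing:
        raise ValueError(f"no expectation for pathways: {sorted(missing)}")
    e = np.array([expectation[c] for c in PAN.columns])
    vals = 1.0 - np.abs(e[None, :] - PAN.to_numpy(dtype=float))
    return pd.DataFrame(vals, index=PAN.index, columns=PAN.columns)


def _weights_vector(columns, weight: dict[str, float]) -> np.ndarray:
    missing = set(columns) - set(weight)
    if missing:
        raise ValueError(f"no weight for pathways: {sorted(missing)}")
    w = np.array([weight[c] for c in columns], dtype=float)
    if (w < 0).any():
        raise ValueError("negative weight")
    return w


def fuse_wasf(PAT: pd.DataFrame, weight: dict[str, float]) -> pd.Series:
    """Weighted AddScore Fuse: weighted sum of transferred scores."""
    w = _weights_vector(PAT.columns, weight)
    return pd.Series(PAT.to_numpy(dtype=float) @ w, index=PAT.index, name="FS")


def borda_counts(PAT: pd.DataFrame) -> pd.DataFrame:
    """Per pathway, count strains with strictly lower PAT (ties share)."""
    vals = PAT.to_numpy(dtype=float)
    counts = (vals[:, None, :] > vals[None, :, :]).sum(axis=1)
    return pd.DataFrame(counts, index=PAT.index, columns=PAT.columns)


def fuse_wbf(PAT: pd.DataFrame, weight: dict[str, float]) -> pd.Series:
    """Weighted Borda Fuse: weighted sum of strictly-lower counts, so only
    the within-pathway ordering of PAT matters."""
    w = _weights_vector(PAT.columns, weight)
    b = borda_counts(PAT).to_numpy(dtype=float)
    return pd.Series(b @ w, index=PAT.index, name="FS")


def rank_strains(FS: pd.Series, PAT: pd.DataFrame | None = None) -> FusedRanking:
    """Rank strains by descending fused score, ties broken by strain ID."""
    if not np.isfinite(FS.to_numpy(dtype=float)).all():
        raise ValueError("fused scores must be finite")
    order = sorted(FS.index, key=lambda s: (-FS[s], s))
    rank = pd.Series({s: i + 1 for i, s in enumerate(order)}, name="rank").reindex(FS.index)
    if PAT is None:
        PAT = pd.DataFrame(index=FS.index)
    return FusedRanking(fused_score=FS, rank=rank, PAT=PAT)


def rank_pipeline(PA: pd.DataFrame, config: RankingConfig) -> FusedRanking:
    """Full aggregation: PAN -> PAT -> fuse -> rank."""
    pan = normalize_pan(PA)
    pat = transfer_pat(pan, config.expectation)
    fuse = fuse_wasf if config.algorithm == "WASF" else fuse_wbf
    fs = fuse(pat, config.weight)
    return rank_strains(fs, pat)
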