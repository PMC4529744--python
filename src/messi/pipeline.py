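"""End-to-end orchestration: metabolites + genotypes -> ranking, GWAS and
gene-level targets.

This is the library counterpart of chaining the CLI subcommands; the CLI
and the test harness both call into it so a whole run stays a single
function call with one seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gene_prioritization import (
    GeneScore,
    TargetReportSection,
    four_gamete_blocks,
    score_genes,
    select_targets,
)
from .model_io import GeneAnnotation, GenotypeMatrix, MetaboliteTable, PathwayDefinition
from .pathway_activity import ActivityMatrix, compute_pa, normalize_abundance
from .pathway_correlation import CorrelationResult, correlate_pathways, correlated_partners
from .strain_ranking import FusedRanking, RankingConfig, rank_pipeline
from .variant_association import (
    AssociationResult,
    KinshipMatrix,
    filter_variants,
    kinship,
    mixed_model_scan,
    permutation_adjust,
)


@dataclass
class AnalysisResult:
    activity: ActivityMatrix
    ranking: FusedRanking
    correlations: list[CorrelationResult]
    associations: dict[str, list[AssociationResult]]  # phenotype pathway -> results
    gene_scores: dict[str, list[GeneScore]]
    targets: list[TargetReportSection]
    kinship: KinshipMatrix | None = None
    scanned_pathways: list[str] = field(default_factory=list)


def run_analysis(
    metabolites: MetaboliteTable,
    pathways: list[PathwayDefinition],
    genotypes: GenotypeMatrix | None,
    genes: list[GeneAnnotation] | None,
    target_pathways: list[str],
    config: RankingConfig | None = None,
    level: int = 0,
    min_af: float = 0.05,
    effect_classes: set[str] | None = None,
    n_permutations: int = 200,
    seed: int = 0,
    target_compounds: list[str] | None = None,
    compound_genes: dict[str, set[str]] | None = None,
    pathway_genes: dict[str, set[str]] | None = None,
    invert_activity: bool = False,
) -> AnalysisResult:
    """Run activity scoring, ranking, correlation and (level > 0) the
    association/prioritization stages.

    Phenotypes scanned are the recognized target pathways plus, at level
    3 and above, their significantly correlated partners.
    """
    normed = normalize_abundance(metabolites)
    activity = compute_pa(normed, pathways, invert=invert_activity)
    available = list(activity.PA.columns)
    recognized = [p for p in target_pathways if p in available]

    if config is None:
        config = RankingConfig.from_pathways(
            available,
            universal={p.pathway_id: p.universal for p in activity.pathways},
        )
    ranking = rank_pipeline(activity.PA, config)
    correlations = correlate_pathways(activity)

    associations: dict[str, list[AssociationResult]] = {}
    gene_scores: dict[str, list[GeneScore]] = {}
    targets: list[TargetReportSection] = []
    K = None
    scanned: list[str] = []
    if level > 0:
        if genotypes is None or genes is None:
            raise ValueError("levels above 0 need genotypes and gene annotations")
        gm = filter_variants(genotypes, min_af=min_af, effect_classes=effect_classes)
        K = kinship(gm)
        blocks = four_gamete_blocks(gm)
        scanned = list(recognized)
        if level >= 3:
            for pid in recognized:
                for partner in correlated_partners(correlations, pid):
                    if partner not in scanned and partner in available:
                        scanned.append(partner)
        for pid in scanned:
            y = activity.PA[pid].to_numpy(dtype=float)
            assoc = mixed_model_scan(y, gm, K, pathway_id=pid)
            adj = permutation_adjust(
                y, gm, K, n_permutations=n_permutations, seed=seed
            )
            adj_by_key = dict(zip(gm.variant_keys, adj))
            for a in assoc:
                a.adjusted_p = float(adj_by_key[a.variant_key])
            associations[pid] = assoc
            gene_scores[pid] = score_genes(blocks, assoc, genes, gm)
        targets = select_targets(
            level,
            gene_scores,
            recognized,
            corr=correlations,
            target_compounds=target_compounds,
            compound_genes=compound_genes,
            pathway_genes=pathway_genes,
        )
    return AnalysisResult(
        activity=activity,
        ranking=ranking,
        correlations=correlations,
        associations=associations,
        gene_scores=gene_scores,
        targets=targets,
        kinship=K,
        scanned_pathways=scanned,
    )


def association_table(associations: dict[str, list[AssociationResult]]) -> pd.DataFrame:
    rows = [
        {
            "pathway_id": pid,
            "variant_key": a.variant_key,
            "beta": a.beta,
            "p_value": a.p_value,
            "adjusted_p": a.adjusted_p if a.adjusted_p is not None else np.nan,
            "significant": int(a.significant),
        }
        for pid, lst in associations.items()
        for a in lst
    ]
    df = pd.DataFrame(
        rows,
        columns=["pathway_id", "variant_key", "beta", "p_value", "adjusted_p", "significant"],
    )
    if len(df):
        df = df.sort_values("p_value", kind="mergesort").reset_index(drop=True)
    return df


def ranking_table(ranking: FusedRanking) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "strain": ranking.fused_score.index,
            "fused_score": ranking.fused_score.to_numpy(dtype=float),
            "rank": ranking.rank.to_numpy(),
        }
    )
    return df.sort_values("rank", kind="mergesort").reset_index(drop=True)


def targets_table(targets: list[TargetReportSection]) -> pd.DataFrame:
    rows = [
        {
            "source_kind": t.source_kind,
            "source_id": t.source_id,
            "pathway_id": t.pathway_id,
            "top_by_p": ",".join(t.top_by_p),
            "top_by_as": ",".join(t.top_by_as),
        }
        for t in targets
    ]
    return pd.DataFrame(
        rows, columns=["source_kind", "source_id", "pathway_id", "top_by_p", "top_by_as"]
    )
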