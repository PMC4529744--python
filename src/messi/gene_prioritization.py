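"""Gene-level prioritization from variant associations.

Haplotype blocks are built with the four-gamete rule: for each pair of
adjacent variants on a chromosome, recombination is declared when all four
two-marker haplotypes (00, 01, 10, 11) occur at frequency >= 0.01 among
strains with complete calls; blocks are maximal runs of adjacent pairs
without such a signal.  A gene's P value is the minimum association P over
all variants in blocks overlapping its region (gene body plus an 800 bp
upstream regulatory window, strand-aware, truncated at position 1) —
block expansion lets a regulatory hit outside the body count for the gene.

The accumulated score summarizes significant hits per unit length:

    AS_i = sum over significant variants j in gene i of -log10(P_ij) / L_i

with L_i the extended region length and significance taken at adjusted
P < 0.05.  Target-selection levels 0-4 then scope which genes are
reported, from nothing through target-compound reactions, target
pathways, correlated pathways, and the whole genome, each with top-3
lists by gene P and by AS.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model_io import GeneAnnotation, GenotypeMatrix
from .pathway_correlation import CorrelationResult, correlated_partners
from .variant_association import AssociationResult

logger = logging.getLogger(__name__)

FGR_FREQ_THRESHOLD = 0.01
UPSTREAM_BP = 800
AS_SIG_THRESHOLD = 0.05


@dataclass(frozen=True)
class LDBlock:
    chromosome: str
    first: int  # global variant index, inclusive
    last: int

    def __post_init__(self) -> None:
        if self.first > self.last:
            raise ValueError("block first > last")


@dataclass
class GeneScore:
    gene_id: str
    gene_p: float
    accumulated_score: float
    region_length: int
    n_variants_total: int
    n_variants_significant: int
    effect_counts: dict[str, int] = field(default_factory=dict)


def four_gamete_blocks(
    gm: GenotypeMatrix, freq_threshold: float = FGR_FREQ_THRESHOLD
) -> list[LDBlock]:
    """Partition the variants of each chromosome into LD blocks.

    Requires variants sorted by (chromosome, position).  Singleton blocks
    are allowed; missing calls are excluded pairwise from haplotype
    frequencies.
    """
    keys = [(v.chromosome, v.position) for v in gm.variants]
    if keys != sorted(keys):
        raise ValueError("variants must be sorted by (chromosome, position)")
    blocks: list[LDBlock] = []
    i = 0
    n = gm.n_variants
    while i < n:
        chrom = gm.variants[i].chromosome
        j = i
        while (
            j + 1 < n
            and gm.variants[j + 1].chromosome == chrom
            and not _recombination(
                gm.presence[j], gm.presence[j + 1], freq_threshold
            )
        ):
            j += 1
        blocks.append(LDBlock(chromosome=chrom, first=i, last=j))
        i = j + 1
    return blocks


def _recombination(g1: np.ndarray, g2: np.ndarray, freq_threshold: float) -> bool:
    """Four-gamete test on one adjacent pair of haploid markers."""
    ok = (g1 >= 0) & (g2 >= 0)
    n = int(ok.sum())
    if n == 0:
        return False
    hap = g1[ok] * 2 + g2[ok]
    counts = np.bincount(hap, minlength=4)
    return bool(np.all(counts / n >= freq_threshold))


def _block_span(block: LDBlock, gm: GenotypeMatrix) -> tuple[int, int]:
    positions = [gm.variants[i].position for i in range(block.first, block.last + 1)]
    return min(positions), max(positions)


def _overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] <= b[1] and b[0] <= a[1]


def gene_pvalue(
    blocks: list[LDBlock],
    assoc: list[AssociationResult],
    genes: list[GeneAnnotation],
    gm: GenotypeMatrix,
    upstream: int = UPSTREAM_BP,
) -> dict[str, float]:
    """Block-minimum gene P: the most significant variant in LD blocks
    overlapping the gene's extended region.  Genes whose region overlaps
    no scored block are absent from the result."""
    p_by_key = {a.variant_key: a.p_value for a in assoc}
    spans = [(_block_span(b, gm), b) for b in blocks]
    out: dict[str, float] = {}
    for gene in genes:
        region = gene.extended_region(upstream)
        best = math.inf
        for span, block in spans:
            if block.chromosome != gene.chromosome or not _overlaps(span, region):
                continue
            for i in range(block.first, block.last + 1):
                p = p_by_key.get(gm.variants[i].key)
                if p is not None and p < best:
                    best = p
        if best < math.inf:
            out[gene.gene_id] = best
    return out


def accumulated_score(
    assoc: list[AssociationResult],
    genes: list[GeneAnnotation],
    gm: GenotypeMatrix,
    sig_threshold: float = AS_SIG_THRESHOLD,
    upstream: int = UPSTREAM_BP,
) -> dict[str, float]:
    """Per-gene accumulated significance per base pair.

    Uses the adjusted P when present (falling back to the model P), both
    for the significance cut and inside the -log10 sum.  P = 0 is clipped
    to the smallest positive float with a warning.
    """
    by_key = {a.variant_key: a for a in assoc}
    out: dict[str, float] = {}
    for gene in genes:
        region = gene.extended_region(upstream)
        length = gene.extended_length(upstream)
        total = 0.0
        for i, v in enumerate(gm.variants):
            if v.chromosome != gene.chromosome or not (region[0] <= v.position <= region[1]):
                continue
            a = by_key.get(v.key)
            if a is None:
                continue
            p = a.adjusted_p if a.adjusted_p is not None else a.p_value
            if not (p < sig_threshold):
                continue
            if p <= 0:
                logger.warning("variant %s has P = 0; clipped", v.key)
                p = np.finfo(float).tiny
            total += -math.log10(p)
        out[gene.gene_id] = total / length
    return out


def score_genes(
    blocks: list[LDBlock],
    assoc: list[AssociationResult],
    genes: list[GeneAnnotation],
    gm: GenotypeMatrix,
    sig_threshold: float = AS_SIG_THRESHOLD,
    upstream: int = UPSTREAM_BP,
) -> list[GeneScore]:
    """Full per-gene summary: block-minimum P, AS, variant and effect
    counts over the extended region."""
    gene_p = gene_pvalue(blocks, assoc, genes, gm, upstream)
    as_score = accumulated_score(assoc, genes, gm, sig_threshold, upstream)
    by_key = {a.variant_key: a for a in assoc}
    out = []
    for gene in genes:
        if gene.gene_id not in gene_p:
            continue
        region = gene.extended_region(upstream)
        n_total = 0
        n_sig = 0
        effects: dict[str, int] = {}
        for v in gm.variants:
            if v.chromosome != gene.chromosome or not (region[0] <= v.position <= region[1]):
                continue
            a = by_key.get(v.key)
            if a is None:
                continue
            n_total += 1
            effects[v.effect_class] = effects.get(v.effect_class, 0) + 1
            p = a.adjusted_p if a.adjusted_p is not None else a.p_value
            if p < sig_threshold:
                n_sig += 1
        out.append(
            GeneScore(
                gene_id=gene.gene_id,
                gene_p=gene_p[gene.gene_id],
                accumulated_score=as_score.get(gene.gene_id, 0.0),
                region_length=gene.extended_length(upstream),
                n_variants_total=n_total,
                n_variants_significant=n_sig,
                effect_counts=effects,
            )
        )
    out.sort(key=lambda s: (s.gene_p, s.gene_id))
    return out


# ---------------------------------------------------------------------------
# Target-selection levels
# ---------------------------------------------------------------------------


@dataclass
class TargetReportSection:
    source_kind: str  # compound | target_pathway | correlated_pathway | genome
    source_id: str
    pathway_id: str  # phenotype pathway whose scan produced the scores
    top_by_p: list[str]
    top_by_as: list[str]
    genes: list[GeneScore]


def _topk(scores: list[GeneScore], k: int, by_as: bool) -> list[str]:
    if by_as:
        ordered = sorted(scores, key=lambda s: (-s.accumulated_score, s.gene_id))
    else:
        ordered = sorted(scores, key=lambda s: (s.gene_p, s.gene_id))
    return [s.gene_id for s in ordered[:k]]


def select_targets(
    level: int,
    scores_by_pathway: dict[str, list[GeneScore]],
    target_pathways: list[str],
    corr: list[CorrelationResult] | None = None,
    target_compounds: list[str] | None = None,
    compound_genes: dict[str, set[str]] | None = None,
    pathway_genes: dict[str, set[str]] | None = None,
    k: int = 3,
) -> list[TargetReportSection]:
    """Assemble the target report for a biological reporting level.

    Levels are cumulative: 0 reports nothing; 1 adds genes of reactions
    involving target compounds (compound input only); 2 adds genes inside
    each target pathway; 3 adds genes of significantly correlated
    pathways (scored against the correlated pathway's own activity); 4
    adds genome-wide genes against each target pathway's activity.
    ``pathway_genes`` and ``compound_genes`` are local stand-ins for the
    pathway/reaction membership lookups of the online database.
    """
    if level not in (0, 1, 2, 3, 4):
        raise ValueError("level must be in 0..4")
    sections: list[TargetReportSection] = []
    if level == 0:
        return sections

    if level >= 1 and target_compounds:
        if compound_genes is None:
            raise ValueError("level 1 needs a compound -> gene map")
        for comp in target_compounds:
            members = compound_genes.get(comp, set())
            for pid in target_pathways:
                scores = [s for s in scores_by_pathway.get(pid, []) if s.gene_id in members]
                if scores:
                    sections.append(
                        TargetReportSection(
                            "compound", comp, pid,
                            _topk(scores, k, False), _topk(scores, k, True), scores,
                        )
                    )
    elif level == 1:
        raise ValueError("level 1 requires a compound list as input")

    if level >= 2:
        for pid in target_pathways:
            scores = scores_by_pathway.get(pid, [])
            if pathway_genes is not None:
                members = pathway_genes.get(pid, set())
                scores = [s for s in scores if s.gene_id in members]
            sections.append(
                TargetReportSection(
                    "target_pathway", pid, pid,
                    _topk(scores, k, False), _topk(scores, k, True), scores,
                )
            )
    if level >= 3:
        if corr is None:
            raise ValueError("level 3 needs correlation results")
        for pid in target_pathways:
            for partner in correlated_partners(corr, pid):
                scores = scores_by_pathway.get(partner, [])
                if pathway_genes is not None:
                    members = pathway_genes.get(partner, set())
                    scores = [s for s in scores if s.gene_id in members]
                if scores:
                    sections.append(
                        TargetReportSection(
                            "correlated_pathway", partner, partner,
                            _topk(scores, k, False), _topk(scores, k, True), scores,
                        )
                    )
    if level == 4:
        for pid in target_pathways:
            scores = scores_by_pathway.get(pid, [])
            sections.append(
                TargetReportSection(
                    "genome", "genome-wide", pid,
                    _topk(scores, k, False), _topk(scores, k, True), scores,
                )
            )
    return sections


def gene_score_table(scores: list[GeneScore]) -> pd.DataFrame:
    cols = [
        "gene_id", "gene_p", "accumulated_score", "region_length",
        "n_variants_total", "n_variants_significant",
    ]
    rows = [
        {
            "gene_id": s.gene_id,
            "gene_p": s.gene_p,
            "accumulated_score": s.accumulated_score,
            "region_length": s.region_length,
            "n_variants_total": s.n_variants_total,
            "n_variants_significant": s.n_variants_significant,
            **{f"n_{e}": c for e, c in sorted(s.effect_counts.items())},
        }
        for s in scores
    ]
    df = pd.DataFrame(rows)
    if len(df):
        df = df.sort_values(["gene_p", "gene_id"], kind="mergesort").reset_index(drop=True)
        ordered = cols + [c for c in df.columns if c not in cols]
        df = df[ordered]
    return df
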