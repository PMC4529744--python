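"""Seeded generator of pipeline inputs with known ground truth.

Emulates a small yeast strain panel with paired metabolome and genome
data (default 21 strains, the regime of published paired panels).  Every
output is deterministic under the spec's seed:

* Genotypes are haploid haplotypes.  Each chromosome is divided into LD
  segments by a list of recombination hotspots; within a segment every
  strain copies one of two complementary founder haplotypes (Bernoulli
  assignment, independent across segments) with a small per-site
  mutation rate.  Adjacent in-segment markers therefore show at most two
  ancestral gametes, while hotspot-flanking markers mix all four.
* Metabolite abundances are lognormal around per-compound baselines.  A
  planted association multiplies the target pathway's compounds by
  exp(eta * g) for carriers of the causal variant, with eta scaled so the
  induced shift in the pathway activity phenotype is approximately the
  requested effect size in phenotype standard deviations.
* The flux table perturbs each pathway's reactions with unit-scale noise
  around wild type, inflated by ``flux_boost`` for the planted strong
  genes, so top-ranked genes perturb their pathway more broadly.

The ground-truth manifest records every planted fact (causal variants,
hotspots, strong flux genes) so recovery can be scored mechanically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .flux_eval import FluxTable
from .model_io import (
    GeneAnnotation,
    GenotypeMatrix,
    MetaboliteTable,
    PathwayDefinition,
    StrainSet,
    VariantRecord,
    write_gene_annotations,
    write_genotype_flat8,
    write_metabolite_table,
    write_pathway_definitions,
)

EFFECT_CHOICES = (
    ("missense", 0.30),
    ("synonymous", 0.30),
    ("upstream", 0.15),
    ("intron", 0.05),
    ("nonsense", 0.05),
    ("frameshift", 0.05),
    ("codon_insertion_deletion", 0.05),
    ("splice_site", 0.02),
    ("other", 0.03),
)

VARIANT_SPACING_BP = 150
VARIANTS_PER_GENE = 10


@dataclass(frozen=True)
class PlantedAssociation:
    chromosome: str
    variant_index: int  # index within the chromosome, 0-based
    pathway_id: str
    effect_sd: float  # approximate shift in phenotype standard deviations


@dataclass
class FixtureSpec:
    """Parameters of the synthetic study.

    Defaults mirror a realistic small strain panel: 21 strains, modest
    lognormal measurement noise, LD segments of 5 markers.
    """

    seed: int
    n_strains: int = 21
    n_pathways: int = 6  # non-universal
    pathway_size: int = 8  # compounds per pathway
    n_extra_compounds: int = 12
    n_compounds: int | None = None  # total pool; default fits the pathways
    include_universal: bool = True
    chromosomes: dict[str, int] = field(default_factory=lambda: {"chr1": 60, "chr2": 40})
    hotspots: dict[str, list[int]] | None = None  # hotspot after local index i
    block_length: int = 5
    mutation_rate: float = 0.01
    noise_sd: float = 0.25  # lognormal sigma of abundance noise
    missing_rate: float = 0.0
    planted: list[PlantedAssociation] = field(default_factory=list)
    reactions_per_pathway: int = 8
    flux_noise: float = 1.0
    flux_boost: float = 3.0

    def __post_init__(self) -> None:
        if self.n_strains < 3:
            raise ValueError("need at least 3 strains")
        for pa in self.planted:
            if not np.isfinite(pa.effect_sd):
                raise ValueError("planted effect size must be finite")

    def resolved_hotspots(self) -> dict[str, list[int]]:
        if self.hotspots is not None:
            return self.hotspots
        out = {}
        for chrom, n in self.chromosomes.items():
            out[chrom] = list(range(self.block_length - 1, n - 1, self.block_length))
        return out


@dataclass
class Fixture:
    metabolites: MetaboliteTable
    pathways: list[PathwayDefinition]
    genotypes: GenotypeMatrix
    genes: list[GeneAnnotation]
    flux: FluxTable
    pathway_genes: dict[str, set[str]]  # pathway id -> member gene ids
    compound_genes: dict[str, set[str]]  # compound id -> reaction gene ids
    manifest: dict[str, Any]


def _draw_effect(rng: np.random.Generator) -> str:
    names = [n for n, _ in EFFECT_CHOICES]
    probs = np.array([p for _, p in EFFECT_CHOICES])
    return names[rng.choice(len(names), p=probs / probs.sum())]


def _generate_genotypes(
    spec: FixtureSpec, strains: StrainSet, rng: np.random.Generator
) -> tuple[GenotypeMatrix, dict[str, list[int]]]:
    hotspots = spec.resolved_hotspots()
    variants: list[VariantRecord] = []
    rows: list[np.ndarray] = []
    bases = np.array(list("ACGT"))
    for chrom in sorted(spec.chromosomes):
        n_var = spec.chromosomes[chrom]
        cuts = sorted(h for h in hotspots.get(chrom, []) if 0 <= h < n_var - 1)
        bounds = [0] + [h + 1 for h in cuts] + [n_var]
        geno = np.empty((n_var, spec.n_strains), dtype=np.int8)
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            founder = rng.integers(0, 2, size=hi - lo).astype(np.int8)
            assign = rng.integers(0, 2, size=spec.n_strains)
            seg = np.where(assign[None, :] == 0, founder[:, None], 1 - founder[:, None])
            flips = rng.random((hi - lo, spec.n_strains)) < spec.mutation_rate
            geno[lo:hi] = np.where(flips, 1 - seg, seg)
        rows.append(geno)
        for i in range(n_var):
            pos = 1000 + VARIANT_SPACING_BP * i
            gene_idx = i // VARIANTS_PER_GENE
            ref, alt = rng.choice(bases, size=2, replace=False)
            effect = _draw_effect(rng)
            vtype = "InDel" if effect in ("frameshift", "codon_insertion_deletion") else "SNP"
            variants.append(
                VariantRecord(
                    chromosome=chrom,
                    position=pos,
                    variant_type=vtype,
                    ref_allele=str(ref),
                    alt_allele=str(alt) if vtype == "SNP" else str(ref) + str(alt),
                    gene_id=f"{chrom}_g{gene_idx}",
                    effect_class=effect,
                )
            )
    gm = GenotypeMatrix(
        strains=strains, variants=variants, presence=np.vstack(rows)
    ).sort()
    return gm, hotspots


def _generate_genes(spec: FixtureSpec) -> list[GeneAnnotation]:
    genes = []
    for chrom in sorted(spec.chromosomes):
        n_var = spec.chromosomes[chrom]
        n_genes = (n_var + VARIANTS_PER_GENE - 1) // VARIANTS_PER_GENE
        for g in range(n_genes):
            first = 1000 + VARIANT_SPACING_BP * (g * VARIANTS_PER_GENE)
            last_i = min((g + 1) * VARIANTS_PER_GENE, n_var) - 1
            last = 1000 + VARIANT_SPACING_BP * last_i
            genes.append(
                GeneAnnotation(
                    gene_id=f"{chrom}_g{g}",
                    chromosome=chrom,
                    start=max(1, first - 50),
                    end=last + 50,
                    strand="+" if g % 2 == 0 else "-",
                )
            )
    return genes


def generate(spec: FixtureSpec) -> Fixture:
    """Generate the full coupled input set with a ground-truth manifest."""
    rng = np.random.default_rng(spec.seed)
    strains = StrainSet(tuple(f"S{i:02d}" for i in range(1, spec.n_strains + 1)))

    # pathway structure over a disjoint compound pool
    n_assigned = spec.n_pathways * spec.pathway_size
    n_compounds = spec.n_compounds if spec.n_compounds is not None else (
        n_assigned + spec.n_extra_compounds
    )
    if n_assigned > n_compounds:
        raise ValueError("pathway definitions larger than the compound pool")
    compounds = [f"C{i:05d}" for i in range(1, n_compounds + 1)]
    pathways: list[PathwayDefinition] = []
    for j in range(spec.n_pathways):
        members = compounds[j * spec.pathway_size : (j + 1) * spec.pathway_size]
        pathways.append(
            PathwayDefinition(
                pathway_id=f"PW{j + 1}",
                name=f"Synthetic pathway {j + 1}",
                compounds=frozenset(members),
                universal=False,
            )
        )
    if spec.include_universal:
        uni = rng.choice(compounds, size=min(n_compounds, 3 * spec.pathway_size), replace=False)
        pathways.append(
            PathwayDefinition(
                pathway_id="PW_UNIV",
                name="Metabolic pathways",
                compounds=frozenset(str(c) for c in uni),
                universal=True,
            )
        )

    gm, hotspots = _generate_genotypes(spec, strains, rng)
    genes = _generate_genes(spec)

    # metabolite abundances with planted genotype effects
    base = rng.lognormal(mean=np.log(100.0), sigma=0.5, size=n_compounds)
    log_a = spec.noise_sd * rng.standard_normal((spec.n_strains, n_compounds))
    planted_records = []
    by_chrom_idx = {}
    for i, v in enumerate(gm.variants):
        by_chrom_idx.setdefault(v.chromosome, []).append(i)
    pathway_by_id = {p.pathway_id: p for p in pathways}
    comp_index = {c: k for k, c in enumerate(compounds)}
    for pa in spec.planted:
        gi = by_chrom_idx[pa.chromosome][pa.variant_index]
        g = gm.presence[gi].astype(float)
        target = pathway_by_id[pa.pathway_id]
        k_p = len(target.compounds)
        eta = pa.effect_sd * spec.noise_sd / np.sqrt(k_p)
        for c in target.compounds:
            log_a[:, comp_index[c]] += eta * g
        planted_records.append(
            {
                "variant_key": gm.variants[gi].key,
                "variant_index": gi,
                "chromosome": pa.chromosome,
                "pathway_id": pa.pathway_id,
                "effect_sd": pa.effect_sd,
                "causal_gene": gm.variants[gi].gene_id,
            }
        )
    abundance = base[None, :] * np.exp(log_a)
    if spec.missing_rate > 0:
        mask = rng.random(abundance.shape) < spec.missing_rate
        abundance = np.where(mask, np.nan, abundance)
    metabolites = MetaboliteTable(
        strains=strains,
        abundance=pd.DataFrame(abundance, index=list(strains.strain_ids), columns=compounds),
    )

    # flux table: reactions tiled over non-universal pathways; strong genes
    # (those hosting planted causal variants, else the first gene per
    # pathway in round-robin) perturb their pathway's reactions more
    non_universal = [p for p in pathways if not p.universal]
    reactions = []
    reaction_pathways: dict[str, set[str]] = {}
    for p in non_universal:
        for r in range(spec.reactions_per_pathway):
            rid = f"R_{p.pathway_id}_{r}"
            reactions.append(rid)
            reaction_pathways[rid] = {p.pathway_id}
    gene_ids = [g.gene_id for g in genes]
    strong: dict[str, str] = {}  # pathway -> strong gene
    for rec in planted_records:
        strong[rec["pathway_id"]] = rec["causal_gene"]
    for j, p in enumerate(non_universal):
        strong.setdefault(p.pathway_id, gene_ids[j % len(gene_ids)])
    wt = rng.lognormal(mean=np.log(10.0), sigma=0.5, size=len(reactions))
    scale = 0.1 * wt  # per-reaction deviation scale
    eps = rng.standard_normal((len(gene_ids), len(reactions)))
    boost = np.ones((len(gene_ids), len(reactions)))
    for j, rid in enumerate(reactions):
        pid = next(iter(reaction_pathways[rid]))
        gi = gene_ids.index(strong[pid])
        boost[gi, j] = spec.flux_boost
    flux = wt[None, :] + spec.flux_noise * boost * eps * scale[None, :]
    flux_table = FluxTable(
        deletions=gene_ids,
        reactions=reactions,
        flux=flux,
        wild_type=wt,
        reaction_pathways=reaction_pathways,
    )

    # pathway membership of genes (round-robin, a local stand-in for a
    # pathway database) and compound -> reaction-gene lookups for level 1
    pathway_genes: dict[str, set[str]] = {p.pathway_id: set() for p in non_universal}
    for i, gid in enumerate(gene_ids):
        pathway_genes[non_universal[i % len(non_universal)].pathway_id].add(gid)
    compound_genes: dict[str, set[str]] = {}
    for p in non_universal:
        for c in p.compounds:
            compound_genes[c] = set(pathway_genes[p.pathway_id])

    manifest: dict[str, Any] = {
        "seed": spec.seed,
        "n_strains": spec.n_strains,
        "planted_associations": planted_records,
        "hotspots": {c: list(map(int, v)) for c, v in hotspots.items()},
        "strong_flux_genes": dict(strong),
        "pathways": [p.pathway_id for p in pathways],
        "pathway_genes": {pid: sorted(g) for pid, g in pathway_genes.items()},
    }
    return Fixture(
        metabolites=metabolites,
        pathways=pathways,
        genotypes=gm,
        genes=genes,
        flux=flux_table,
        pathway_genes=pathway_genes,
        compound_genes=compound_genes,
        manifest=manifest,
    )


def write_fixture(fixture: Fixture, out_dir: str | Path) -> dict[str, Path]:
    """Write every fixture table as TSV plus a JSON ground-truth manifest."""
    import json

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "metabolites": out_dir / "metabolites.tsv",
        "pathways": out_dir / "pathways.tsv",
        "variants": out_dir / "variants.tsv",
        "genes": out_dir / "genes.tsv",
        "flux": out_dir / "flux.tsv",
        "wild_type": out_dir / "wild_type.tsv",
        "reaction_pathways": out_dir / "reaction_pathways.tsv",
        "pathway_genes": out_dir / "pathway_genes.tsv",
        "compound_genes": out_dir / "compound_genes.tsv",
        "manifest": out_dir / "manifest.json",
    }
    write_metabolite_table(fixture.metabolites, paths["metabolites"])
    write_pathway_definitions(fixture.pathways, paths["pathways"])
    write_genotype_flat8(fixture.genotypes, paths["variants"])
    write_gene_annotations(fixture.genes, paths["genes"])
    flux_df = pd.DataFrame(
        fixture.flux.flux, index=fixture.flux.deletions, columns=fixture.flux.reactions
    )
    flux_df.index.name = "deletion"
    flux_df.to_csv(paths["flux"], sep="\t")
    pd.DataFrame(
        {"reaction": fixture.flux.reactions, "flux": fixture.flux.wild_type}
    ).to_csv(paths["wild_type"], sep="\t", index=False)
    rp_rows = [
        {"reaction": r, "pathway_id": pid}
        for r in fixture.flux.reactions
        for pid in sorted(fixture.flux.reaction_pathways[r])
    ]
    pd.DataFrame(rp_rows).to_csv(paths["reaction_pathways"], sep="\t", index=False)
    pg_rows = [
        {"pathway_id": pid, "gene_id": g}
        for pid in sorted(fixture.pathway_genes)
        for g in sorted(fixture.pathway_genes[pid])
    ]
    pd.DataFrame(pg_rows).to_csv(paths["pathway_genes"], sep="\t", index=False)
    cg_rows = [
        {"compound_id": c, "gene_id": g}
        for c in sorted(fixture.compound_genes)
        for g in sorted(fixture.compound_genes[c])
    ]
    pd.DataFrame(cg_rows).to_csv(paths["compound_genes"], sep="\t", index=False)
    paths["manifest"].write_text(json.dumps(fixture.manifest, indent=2, sort_keys=True))
    return paths
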