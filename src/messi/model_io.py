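"""Domain containers and flat-file I/O for the pipeline.

All tabular formats are tab-separated UTF-8 text; ``.`` marks a missing
value.  Coordinates are 1-based inclusive throughout (VCF/GFF convention).
Genotypes are haploid presence/absence: 1 = variant observed in the strain,
0 = not observed, -1 = missing call.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = "."

#: Broad KEGG pathways excluded from correlation analysis and zero-weighted
#: in rank aggregation by default.
UNIVERSAL_PATHWAY_NAMES = frozenset(
    {
        "Metabolic pathways",
        "Biosynthesis of secondary metabolites",
        "Microbial metabolism in diverse environments",
        "Carbon metabolism",
        "2-Oxocarboxylic acid metabolism",
        "Fatty acid metabolism",
        "Biosynthesis of amino acids",
        "Degradation of aromatic compounds",
        "ABC transporters",
        "Aminoacyl-tRNA biosynthesis",
    }
)

EFFECT_CLASSES = (
    "upstream",
    "synonymous",
    "missense",
    "nonsense",
    "frameshift",
    "codon_insertion_deletion",
    "intron",
    "splice_site",
    "other",
)

#: SnpEff (sequence-ontology) annotation terms -> closed effect vocabulary.
SNPEFF_EFFECT_MAP = {
    "upstream_gene_variant": "upstream",
    "UPSTREAM": "upstream",
    "synonymous_variant": "synonymous",
    "stop_retained_variant": "synonymous",
    "start_retained_variant": "synonymous",
    "SYNONYMOUS_CODING": "synonymous",
    "SYNONYMOUS_STOP": "synonymous",
    "missense_variant": "missense",
    "NON_SYNONYMOUS_CODING": "missense",
    "stop_gained": "nonsense",
    "stop_lost": "nonsense",
    "start_lost": "nonsense",
    "STOP_GAINED": "nonsense",
    "STOP_LOST": "nonsense",
    "START_LOST": "nonsense",
    "frameshift_variant": "frameshift",
    "FRAME_SHIFT": "frameshift",
    "inframe_insertion": "codon_insertion_deletion",
    "inframe_deletion": "codon_insertion_deletion",
    "conservative_inframe_insertion": "codon_insertion_deletion",
    "conservative_inframe_deletion": "codon_insertion_deletion",
    "disruptive_inframe_insertion": "codon_insertion_deletion",
    "disruptive_inframe_deletion": "codon_insertion_deletion",
    "CODON_INSERTION": "codon_insertion_deletion",
    "CODON_DELETION": "codon_insertion_deletion",
    "intron_variant": "intron",
    "INTRON": "intron",
    "splice_acceptor_variant": "splice_site",
    "splice_donor_variant": "splice_site",
    "splice_region_variant": "splice_site",
    "SPLICE_SITE_ACCEPTOR": "splice_site",
    "SPLICE_SITE_DONOR": "splice_site",
    "SPLICE_SITE_REGION": "splice_site",
}


def map_effect(term: str) -> str:
    """Map an annotation term to the closed effect vocabulary.

    Terms already in the vocabulary pass through; unknown terms map to
    ``other`` with a logged warning.
    """
    term = term.strip()
    if term in EFFECT_CLASSES:
        return term
    mapped = SNPEFF_EFFECT_MAP.get(term)
    if mapped is None:
        logger.warning("unknown variant effect %r mapped to 'other'", term)
        return "other"
    return mapped


@dataclass(frozen=True)
class StrainSet:
    """Ordered, unique strain identifiers; the canonical row index for
    every strain-indexed matrix in the pipeline."""

    strain_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.strain_ids) == 0:
            raise ValueError("StrainSet must be non-empty")
        if len(set(self.strain_ids)) != len(self.strain_ids):
            raise ValueError("duplicate strain identifiers")

    def __len__(self) -> int:
        return len(self.strain_ids)

    def __iter__(self):
        return iter(self.strain_ids)

    def index_of(self, strain: str) -> int:
        return self.strain_ids.index(strain)


@dataclass
class MetaboliteTable:
    """Strain x compound abundance matrix (NaN = missing, values >= 0)."""

    strains: StrainSet
    abundance: pd.DataFrame  # index = strain_ids, columns = compound ids

    def __post_init__(self) -> None:
        if list(self.abundance.index) != list(self.strains.strain_ids):
            raise ValueError("abundance index must equal the strain set")
        if self.abundance.columns.duplicated().any():
            raise ValueError("duplicate compound identifiers")
        vals = self.abundance.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0:
            raise ValueError("negative abundance value")

    @property
    def compounds(self) -> list[str]:
        return list(self.abundance.columns)


@dataclass(frozen=True)
class PathwayDefinition:
    pathway_id: str
    name: str
    compounds: frozenset[str]
    universal: bool = False

    def __post_init__(self) -> None:
        if not self.compounds:
            raise ValueError(f"pathway {self.pathway_id} has no compounds")


@dataclass(frozen=True)
class VariantRecord:
    chromosome: str
    position: int  # 1-based
    variant_type: str  # SNP | InDel
    ref_allele: str
    alt_allele: str
    gene_id: str | None = None
    effect_class: str = "other"
    aa_change: str | None = None

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("variant position must be >= 1")
        if self.effect_class not in EFFECT_CLASSES:
            raise ValueError(f"unknown effect class {self.effect_class!r}")

    @property
    def key(self) -> str:
        return f"{self.chromosome}:{self.position}:{self.ref_allele}:{self.alt_allele}"


@dataclass
class GenotypeMatrix:
    """Haploid presence/absence genotypes: variants x strains, int8.

    1 = variant observed, 0 = not observed, -1 = missing.  Variants are
    kept sorted by (chromosome, position).
    """

    strains: StrainSet
    variants: list[VariantRecord]
    presence: np.ndarray

    def __post_init__(self) -> None:
        self.presence = np.asarray(self.presence, dtype=np.int8)
        if self.presence.shape != (len(self.variants), len(self.strains)):
            raise ValueError("presence matrix shape mismatch")
        bad = ~np.isin(self.presence, (-1, 0, 1))
        if bad.any():
            raise ValueError("genotype values must be in {0, 1, missing}")

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def variant_keys(self) -> list[str]:
        return [v.key for v in self.variants]

    def allele_frequency(self) -> np.ndarray:
        """Presence frequency per variant over non-missing strains."""
        obs = self.presence != -1
        n_obs = obs.sum(axis=1)
        n_alt = ((self.presence == 1) & obs).sum(axis=1)
        with np.errstate(invalid="ignore"):
            return np.where(n_obs > 0, n_alt / np.maximum(n_obs, 1), np.nan)

    def subset_variants(self, mask: np.ndarray) -> "GenotypeMatrix":
        idx = np.flatnonzero(mask)
        return GenotypeMatrix(
            strains=self.strains,
            variants=[self.variants[i] for i in idx],
            presence=self.presence[idx],
        )

    def sort(self) -> "GenotypeMatrix":
        order = sorted(
            range(len(self.variants)),
            key=lambda i: (self.variants[i].chromosome, self.variants[i].position),
        )
        return GenotypeMatrix(
            strains=self.strains,
            variants=[self.variants[i] for i in order],
            presence=self.presence[order],
        )


@dataclass(frozen=True)
class GeneAnnotation:
    gene_id: str
    chromosome: str
    start: int  # 1-based inclusive
    end: int
    strand: str  # "+" or "-"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")

    def extended_region(self, upstream: int = 800) -> tuple[int, int]:
        """Gene body plus the upstream regulatory window, strand-aware and
        truncated at position 1."""
        if self.strand == "+":
            return max(1, self.start - upstream), self.end
        return self.start, self.end + upstream

    def extended_length(self, upstream: int = 800) -> int:
        lo, hi = self.extended_region(upstream)
        return hi - lo + 1


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def _check_unique(values: Sequence[str], what: str) -> None:
    seen = set()
    for v in values:
        if v in seen:
            raise ValueError(f"duplicate {what}: {v!r}")
        seen.add(v)


def read_metabolite_table(path: str | Path) -> MetaboliteTable:
    """Read a strain x compound abundance TSV.

    First row holds compound IDs, first column strain IDs.  Empty cells or
    ``.`` are recorded as missing, never as zero.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    _check_unique(list(df.index), "strain")
    _check_unique(list(df.columns), "compound")
    df = df.replace({MISSING: np.nan, "": np.nan}).astype(float)
    strains = StrainSet(tuple(str(s) for s in df.index))
    df.index = list(strains.strain_ids)
    return MetaboliteTable(strains=strains, abundance=df)


def write_metabolite_table(table: MetaboliteTable, path: str | Path) -> None:
    out = table.abundance.copy()
    out.index.name = "strain"
    out.to_csv(path, sep="\t", na_rep=MISSING)


def read_pathway_definitions(path: str | Path) -> list[PathwayDefinition]:
    """Read pathway definitions: pathway_id, name, universal, compounds
    (comma-separated).  The ``universal`` column overrides the built-in
    universal-name list."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"pathway_id", "name", "universal", "compounds"}
    if not required.issubset(df.columns):
        raise ValueError(f"pathway table must have columns {sorted(required)}")
    _check_unique(list(df["pathway_id"]), "pathway_id")
    out = []
    for _, row in df.iterrows():
        out.append(
            PathwayDefinition(
                pathway_id=row["pathway_id"],
                name=row["name"],
                compounds=frozenset(c for c in row["compounds"].split(",") if c),
                universal=str(row["universal"]).strip().lower() in ("1", "true", "yes"),
            )
        )
    return out


def write_pathway_definitions(pathways: Iterable[PathwayDefinition], path: str | Path) -> None:
    rows = [
        {
            "pathway_id": p.pathway_id,
            "name": p.name,
            "universal": int(p.universal),
            "compounds": ",".join(sorted(p.compounds)),
        }
        for p in pathways
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_gene_annotations(path: str | Path) -> list[GeneAnnotation]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"gene_id", "chromosome", "start", "end", "strand"}
    if not required.issubset(df.columns):
        raise ValueError(f"gene table must have columns {sorted(required)}")
    _check_unique(list(df["gene_id"]), "gene_id")
    return [
        GeneAnnotation(
            gene_id=row["gene_id"],
            chromosome=row["chromosome"],
            start=int(row["start"]),
            end=int(row["end"]),
            strand=row["strand"],
        )
        for _, row in df.iterrows()
    ]


def write_gene_annotations(genes: Iterable[GeneAnnotation], path: str | Path) -> None:
    rows = [
        {
            "gene_id": g.gene_id,
            "chromosome": g.chromosome,
            "start": g.start,
            "end": g.end,
            "strand": g.strand,
        }
        for g in genes
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


FLAT8_COLUMNS = [
    "chromosome",
    "position",
    "variant_type",
    "ref_allele",
    "alt_allele",
    "gene_id",
    "effect",
    "aa_change",
]


def read_variants(path: str | Path, dialect: str = "flat8") -> GenotypeMatrix:
    """Read annotated variants plus per-strain genotypes.

    ``flat8``: the 8 metadata columns followed by one 0/1 column per strain.
    ``vcf``: a standard VCF; heterozygous diploid calls collapse to 1 (any
    alt allele present) and the first SnpEff ANN/EFF annotation supplies
    gene and effect.
    """
    if dialect == "flat8":
        return _read_flat8(path)
    if dialect == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unknown variant dialect {dialect!r}")


def _read_flat8(path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if list(df.columns[:8]) != FLAT8_COLUMNS:
        raise ValueError(f"flat8 file must start with columns {FLAT8_COLUMNS}")
    strain_cols = list(df.columns[8:])
    if not strain_cols:
        raise ValueError("flat8 file has no strain genotype columns")
    _check_unique(strain_cols, "strain")
    strains = StrainSet(tuple(strain_cols))
    variants = []
    for _, row in df.iterrows():
        variants.append(
            VariantRecord(
                chromosome=row["chromosome"],
                position=int(row["position"]),
                variant_type=row["variant_type"],
                ref_allele=row["ref_allele"],
                alt_allele=row["alt_allele"],
                gene_id=row["gene_id"] or None if row["gene_id"] != MISSING else None,
                effect_class=map_effect(row["effect"]),
                aa_change=row["aa_change"] or None if row["aa_change"] != MISSING else None,
            )
        )
    geno = np.empty((len(variants), len(strains)), dtype=np.int8)
    for j, col in enumerate(strain_cols):
        for i, cell in enumerate(df[col]):
            cell = cell.strip()
            if cell in (MISSING, ""):
                geno[i, j] = -1
            elif cell in ("0", "1"):
                geno[i, j] = int(cell)
            else:
                raise ValueError(f"genotype value {cell!r} outside {{0,1,missing}}")
    return GenotypeMatrix(strains=strains, variants=variants, presence=geno).sort()


def _read_vcf(path: str | Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    strains = StrainSet(tuple(vcf.samples))
    variants: list[VariantRecord] = []
    rows: list[np.ndarray] = []
    for rec in vcf:
        alt = rec.ALT[0] if rec.ALT else "."
        vtype = "SNP" if len(rec.REF) == 1 and len(alt) == 1 else "InDel"
        gene_id, effect, aa = None, "other", None
        ann = rec.INFO.get("ANN") or rec.INFO.get("EFF")
        if ann:
            first = str(ann).split(",")[0].split("|")
            if len(first) > 3:
                effect = map_effect(first[1].split("&")[0])
                gene_id = first[3] or first[4] or None
                if len(first) > 10 and first[10]:
                    aa = first[10]
        variants.append(
            VariantRecord(
                chromosome=rec.CHROM,
                position=rec.POS,
                variant_type=vtype,
                ref_allele=rec.REF,
                alt_allele=alt,
                gene_id=gene_id,
                effect_class=effect,
                aa_change=aa,
            )
        )
        row = np.empty(len(strains), dtype=np.int8)
        for j, call in enumerate(rec.genotypes):
            alleles = [a for a in call[:-1] if a != -1]
            if not alleles:
                row[j] = -1
            else:
                row[j] = 1 if any(a > 0 for a in alleles) else 0
        rows.append(row)
    geno = np.vstack(rows) if rows else np.empty((0, len(strains)), dtype=np.int8)
    return GenotypeMatrix(strains=strains, variants=variants, presence=geno).sort()


def write_genotype_flat8(gm: GenotypeMatrix, path: str | Path) -> None:
    rows = []
    for v, g in zip(gm.variants, gm.presence):
        row = {
            "chromosome": v.chromosome,
            "position": v.position,
            "variant_type": v.variant_type,
            "ref_allele": v.ref_allele,
            "alt_allele": v.alt_allele,
            "gene_id": v.gene_id if v.gene_id is not None else MISSING,
            "effect": v.effect_class,
            "aa_change": v.aa_change if v.aa_change is not None else MISSING,
        }
        for s, val in zip(gm.strains.strain_ids, g):
            row[s] = MISSING if val == -1 else int(val)
        rows.append(row)
    pd.DataFrame(rows, columns=FLAT8_COLUMNS + list(gm.strains.strain_ids)).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Report output
# ---------------------------------------------------------------------------

REPORT_FILES = {
    "strain_ranking": "strain_ranking.tsv",
    "variant_associations": "variant_associations.tsv",
    "gene_scores": "gene_scores.tsv",
    "correlated_pathways": "correlated_pathways.tsv",
}


def write_report(tables: Mapping[str, pd.DataFrame], out_dir: str | Path) -> list[Path]:
    """Write the standard result tables as TSV.

    Variant associations are sorted by ascending P value so the most
    significant hits come first; column order is deterministic.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for key, fname in REPORT_FILES.items():
        if key not in tables:
            continue
        df = tables[key].copy()
        if key == "variant_associations" and "p_value" in df.columns and len(df):
            df = df.sort_values("p_value", kind="mergesort").reset_index(drop=True)
        path = out_dir / fname
        df.to_csv(path, sep="\t", index=False, na_rep=MISSING)
        written.append(path)
    return written
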