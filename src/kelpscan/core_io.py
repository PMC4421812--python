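"""Readers, writers and shared domain types.

All genomic intervals are 0-based half-open internally; conversion to the
1-based closed conventions of VCF/BED-adjacent formats happens only at the
file boundary.  Variant tables keep biallelic SNVs only: indels and
multiallelic records are dropped on read (with a logged count) because every
downstream statistic in the package is defined on biallelic sites.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np
import yaml

logger = logging.getLogger("kelpscan")

# genotype codes (per sample, per site)
HOM_REF = 0
HET = 1
HOM_ALT = 2
MISSING = -1

_GT_STRINGS = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}


@dataclass
class VariantTable:
    """Biallelic SNVs for a set of samples.

    ``pos`` is 0-based internally (VCF's 1-based POS minus one).
    ``genotypes`` has shape (n_samples, n_sites) with codes
    HOM_REF/HET/HOM_ALT/MISSING.
    """

    samples: list[str]
    chrom: np.ndarray  # str array, one per site
    pos: np.ndarray  # int array, 0-based
    ref: np.ndarray  # single-character str array
    alt: np.ndarray
    genotypes: np.ndarray  # int8 (n_samples, n_sites)

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        if self.genotypes.shape != (len(self.samples), len(self.pos)):
            raise ValueError(
                f"genotype matrix shape {self.genotypes.shape} does not match "
                f"{len(self.samples)} samples x {len(self.pos)} sites"
            )
        for c in np.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if len(p) > 1 and not np.all(np.diff(p) > 0):
                raise ValueError(f"positions not strictly increasing on {c}")

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def subset_samples(self, samples: Sequence[str]) -> "VariantTable":
        missing = [s for s in samples if s not in self.samples]
        if missing:
            raise KeyError(
                f"unknown sample(s) {missing}; available: {self.samples}"
            )
        idx = [self.samples.index(s) for s in samples]
        return VariantTable(
            samples=list(samples),
            chrom=self.chrom.copy(),
            pos=self.pos.copy(),
            ref=self.ref.copy(),
            alt=self.alt.copy(),
            genotypes=self.genotypes[idx, :].copy(),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, VariantTable):
            return NotImplemented
        return (
            self.samples == other.samples
            and np.array_equal(self.chrom, other.chrom)
            and np.array_equal(self.pos, other.pos)
            and np.array_equal(self.ref, other.ref)
            and np.array_equal(self.alt, other.alt)
            and np.array_equal(self.genotypes, other.genotypes)
        )


@dataclass
class HaplotypeMatrix:
    """Phased-by-convention haplotypes over {0, 1, MISSING}.

    Shape is (2 * n_individuals, n_sites) for diploid data.  Heterozygotes
    expand to (0, 1); phase is arbitrary, which leaves every per-site allele
    count — and therefore S, pi and Tajima's D — unchanged.
    """

    sample_ids: list[str]  # one id per haplotype row
    chrom: str
    positions: np.ndarray  # 0-based
    alleles: np.ndarray  # int8 (n_haplotypes, n_sites), values {0,1,MISSING}

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.shape[1] != len(self.positions):
            raise ValueError("column count must equal number of positions")

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @classmethod
    def from_variant_table(
        cls, table: VariantTable, chrom: str | None = None
    ) -> "HaplotypeMatrix":
        """Expand genotypes deterministically: 0/0->(0,0), 0/1->(0,1), 1/1->(1,1)."""
        if chrom is None:
            chroms = np.unique(table.chrom)
            if len(chroms) != 1:
                raise ValueError("table spans multiple chroms; pass chrom=")
            chrom = str(chroms[0])
        mask = table.chrom == chrom
        gt = table.genotypes[:, mask]
        n_samp, n_sites = gt.shape
        alleles = np.empty((2 * n_samp, n_sites), dtype=np.int8)
        first = np.where(gt == MISSING, MISSING, np.where(gt == HOM_ALT, 1, 0))
        second = np.where(gt == MISSING, MISSING, np.where(gt == HOM_REF, 0, 1))
        alleles[0::2] = first
        alleles[1::2] = second
        ids = [f"{s}_h{i}" for s in table.samples for i in (0, 1)]
        return cls(
            sample_ids=ids,
            chrom=chrom,
            positions=table.pos[mask].copy(),
            alleles=alleles,
        )


@dataclass(frozen=True)
class Gene:
    gene_id: str
    chrom: str
    start: int  # 0-based half-open
    end: int
    order: int = 0

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"gene {self.gene_id}: start must be < end")


@dataclass
class GeneAnnotation:
    genes: list[Gene] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [g.gene_id for g in self.genes]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate gene_id in annotation")

    def __iter__(self):
        return iter(self.genes)

    def __len__(self) -> int:
        return len(self.genes)


# ---------------------------------------------------------------------------
# VCF


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_vcf(path: str | Path, sample_subset: Sequence[str] | None = None) -> VariantTable:
    """Read a VCF (v4.x, optionally gzipped) keeping only biallelic SNVs.

    Indels, multiallelic records and non-SNV alleles are dropped; counts of
    dropped records are logged.  Raises ``KeyError`` listing available
    samples if ``sample_subset`` names an unknown sample.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    available = list(vcf.samples)
    if sample_subset is not None:
        missing = [s for s in sample_subset if s not in available]
        if missing:
            raise KeyError(
                f"unknown sample(s) {missing}; available samples: {available}"
            )
        vcf.close()
        vcf = VCF(str(path), gts012=True, samples=list(sample_subset))
        samples = list(vcf.samples)
    else:
        samples = available

    chroms: list[str] = []
    pos: list[int] = []
    ref: list[str] = []
    alt: list[str] = []
    gts: list[np.ndarray] = []
    dropped = {"indel": 0, "multiallelic": 0, "non_snv": 0}
    for rec in vcf:
        if len(rec.ALT) != 1:
            dropped["multiallelic"] += 1
            continue
        if len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            dropped["indel"] += 1
            continue
        if rec.REF not in "ACGT" or rec.ALT[0] not in "ACGT":
            dropped["non_snv"] += 1
            continue
        chroms.append(rec.CHROM)
        pos.append(rec.POS - 1)  # to 0-based
        ref.append(rec.REF)
        alt.append(rec.ALT[0])
        g = rec.gt_types.astype(np.int8)  # 0,1,2,3(unknown)
        g[g == 3] = MISSING
        gts.append(g)
    vcf.close()

    n_dropped = sum(dropped.values())
    if n_dropped:
        logger.info("read_vcf: dropped %d records (%s)", n_dropped, dropped)
    if not pos:
        logger.warning("read_vcf: no biallelic SNV records retained from %s", path)
        return VariantTable(
            samples=samples,
            chrom=np.array([], dtype=object),
            pos=np.array([], dtype=np.int64),
            ref=np.array([], dtype=object),
            alt=np.array([], dtype=object),
            genotypes=np.zeros((len(samples), 0), dtype=np.int8),
        )
    return VariantTable(
        samples=samples,
        chrom=np.array(chroms, dtype=object),
        pos=np.array(pos, dtype=np.int64),
        ref=np.array(ref, dtype=object),
        alt=np.array(alt, dtype=object),
        genotypes=np.stack(gts, axis=1),
    )


def write_vcf(table: VariantTable, path: str | Path) -> None:
    """Write a minimal GT-only VCF v4.2 such that read_vcf(write_vcf(t)) == t."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in dict.fromkeys(table.chrom.tolist()):  # preserve order, unique
            fh.write(f"##contig=<ID={c}>\n")
        header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "FORMAT"]
        fh.write("\t".join(header[:-1] + ["INFO", "FORMAT"] + table.samples) + "\n")
        for j in range(table.n_sites):
            fields = [
                str(table.chrom[j]),
                str(table.pos[j] + 1),  # back to 1-based
                ".",
                str(table.ref[j]),
                str(table.alt[j]),
                ".",
                ".",
                ".",
                "GT",
            ]
            fields += [_GT_STRINGS[int(g)] for g in table.genotypes[:, j]]
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Newick trees (dendropy-backed)


def read_newick(text_or_path: str | Path, rooted: bool = True) -> dendropy.Tree:
    """Parse Newick text (or a path to a file) into a dendropy Tree."""
    text = text_or_path
    if isinstance(text_or_path, Path) or (
        isinstance(text_or_path, str)
        and "(" not in text_or_path
        and Path(text_or_path).exists()
    ):
        text = Path(text_or_path).read_text()
    try:
        tree = dendropy.Tree.get(
            data=str(text),
            schema="newick",
            rooting="force-rooted" if rooted else "force-unrooted",
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises assorted parse errors
        raise ValueError(f"malformed Newick: {exc}") from exc
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate leaf labels in Newick tree")
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    """Serialize with branch lengths to 10 significant digits (round-trip safe)."""
    return (
        tree.as_string(
            schema="newick",
            suppress_rooting=True,
            real_value_format_specifier=".10g",
        ).strip()
        + "\n"
    )


# ---------------------------------------------------------------------------
# BED / gene annotation


def read_bed(path: str | Path) -> GeneAnnotation:
    """Read a 4-column BED (chrom, start, end, name); BED is already 0-based half-open."""
    genes = []
    with _open_text(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{i + 1}: expected >=4 BED columns")
            genes.append(
                Gene(
                    gene_id=parts[3],
                    chrom=parts[0],
                    start=int(parts[1]),
                    end=int(parts[2]),
                    order=len(genes),
                )
            )
    return GeneAnnotation(genes=genes)


def write_bed(annotation: GeneAnnotation, path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in annotation:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\n")


# ---------------------------------------------------------------------------
# Presence / count matrices


def read_matrix_tsv(path: str | Path) -> "pd.DataFrame":
    """Family x taxon matrix: header row = taxon ids, first column = family ids."""
    import pandas as pd

    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix_tsv(df: "pd.DataFrame", path: str | Path) -> None:
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Config


def read_config(path: str | Path) -> dict:
    """Flat key=value or YAML mapping."""
    text = Path(path).read_text()
    lines = [l for l in text.splitlines() if l.strip() and not l.lstrip().startswith("#")]
    if lines and all("=" in l for l in lines):
        out = {}
        for line in lines:
            k, _, v = line.partition("=")
            out[k.strip()] = yaml.safe_load(v.strip())
        return out
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError("config must be a flat mapping")
    return data


def setup_logging(verbose: bool = False, quiet: bool = False) -> None:
    level = logging.DEBUG if verbose else (logging.ERROR if quiet else logging.INFO)
    logging.basicConfig(
        level=level, format="%(levelname)s %(name)s: %(message)s", force=True
    )
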