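"""Sliding-window diversity statistics and empirical-tail sweep scanning.

Per window we compute the number of segregating sites S, nucleotide
diversity theta-pi (mean pairwise differences, window total), Watterson's
theta-W = S/a1, and Tajima's D = (pi - thetaW) / sqrt(e1*S + e2*S*(S-1)).
Windows in the extreme empirical tails of the per-population D distribution
are merged into candidate selective-sweep regions labelled CN/CP (cultivated
negative/positive) or WN/WP (wild), and overlapping genes are collected.

Missing data policy: pi uses the per-site called-allele count n_s
(sum over sites of 2*p*(1-p)*n_s/(n_s-1)); S counts any site segregating
among called alleles; the variance constants use the window-level allele
count n = number of haplotypes with <=20% missing calls in the window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .core_io import MISSING, GeneAnnotation, HaplotypeMatrix, VariantTable

logger = logging.getLogger("kelpscan")

REGION_LABELS = ("CN", "CP", "WN", "WP")


@dataclass(frozen=True)
class TajimaConstants:
    """The n-dependent constants of Tajima's D variance (functions of n only)."""

    n: int
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float


def tajima_constants(n_alleles: int) -> TajimaConstants:
    if n_alleles < 2:
        raise ValueError("n_alleles must be >= 2")
    n = n_alleles
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return TajimaConstants(n=n, a1=a1, a2=a2, b1=b1, b2=b2, c1=c1, c2=c2, e1=e1, e2=e2)


def window_pi(alleles: np.ndarray) -> float:
    """Nucleotide diversity of a haplotype-matrix slice (window total).

    Frequency form: sum over sites of 2*p*(1-p) * n_s/(n_s-1), with n_s the
    called alleles at the site.  Equals the mean pairwise difference count
    over all haplotype pairs when no data are missing.  Sites with fewer
    than 2 called alleles contribute nothing; if no site has >=2 called
    alleles and the window is non-empty, returns NaN.
    """
    alleles = np.asarray(alleles)
    if alleles.size == 0:
        return 0.0
    called = alleles != MISSING
    n_s = called.sum(axis=0).astype(float)
    k = np.where(called, alleles, 0).sum(axis=0).astype(float)
    ok = n_s >= 2
    if not ok.any():
        if alleles.shape[1] == 0:
            return 0.0
        return float("nan")
    n_ok = n_s[ok]
    k_ok = k[ok]
    terms = 2.0 * k_ok * (n_ok - k_ok) / (n_ok * (n_ok - 1.0))
    return float(terms.sum())


def window_pi_pairwise(alleles: np.ndarray) -> float:
    """Pairwise form of pi: mean per-pair difference count (no-missing oracle form)."""
    alleles = np.asarray(alleles)
    n = alleles.shape[0]
    if n < 2:
        return float("nan")
    total = 0.0
    pairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            both = (alleles[i] != MISSING) & (alleles[j] != MISSING)
            total += np.sum(alleles[i][both] != alleles[j][both])
            pairs += 1
    return total / pairs


def count_segregating(alleles: np.ndarray) -> int:
    """Sites with both alleles observed among called haplotypes."""
    alleles = np.asarray(alleles)
    if alleles.size == 0:
        return 0
    called = alleles != MISSING
    n_s = called.sum(axis=0)
    k = np.where(called, alleles, 0).sum(axis=0)
    return int(np.sum((k > 0) & (k < n_s)))


def window_theta_w(S: int, n_alleles: int) -> float:
    if S < 0:
        raise ValueError("S must be >= 0")
    if S == 0:
        return 0.0
    return S / tajima_constants(n_alleles).a1


def tajimas_d(pi: float, S: int, n_alleles: int) -> float:
    """Tajima's D; NaN when undefined (S=0 or n<3 or degenerate variance)."""
    if S == 0 or n_alleles < 3 or not np.isfinite(pi):
        return float("nan")
    c = tajima_constants(n_alleles)
    var = c.e1 * S + c.e2 * S * (S - 1)
    if var <= 0:
        return float("nan")
    return (pi - S / c.a1) / np.sqrt(var)


@dataclass(frozen=True)
class SweepRegion:
    chrom: str
    start: int
    end: int
    label: str  # CN / CP / WN / WP
    n_windows: int
    gene_ids: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.label not in REGION_LABELS:
            raise ValueError(f"label must be one of {REGION_LABELS}")
        if not self.end > self.start:
            raise ValueError("region end must be > start")


def _window_starts(length: int, window: int, step: int) -> list[int]:
    starts = list(range(0, length, step))
    # keep trailing partial windows, but never emit a zero-length window
    return [s for s in starts if s < length]


def sliding_scan(
    table: VariantTable,
    window_size: int,
    step: int,
    population_samples: list[str] | None = None,
    chrom_lengths: dict[str, int] | None = None,
    max_missing_frac: float = 0.2,
) -> pd.DataFrame:
    """Tile each chromosome into windows and compute per-window statistics.

    Returns a DataFrame with columns chrom, start, end, full, n_alleles, S,
    pi, theta_w, D — one row per window, including empty windows (S=0,
    D=NaN).  Window n for the variance constants is the number of haplotypes
    with <= ``max_missing_frac`` missing calls in the window.
    """
    if not (window_size >= step >= 1):
        raise ValueError("require window_size >= step >= 1")
    if population_samples is not None:
        table = table.subset_samples(population_samples)

    rows = []
    chroms = list(dict.fromkeys(table.chrom.tolist()))
    if chrom_lengths is not None:
        chroms = list(chrom_lengths)
    for chrom in chroms:
        mask = table.chrom == chrom
        if chrom_lengths is not None and chrom in chrom_lengths:
            length = chrom_lengths[chrom]
        else:
            length = int(table.pos[mask].max()) + 1 if mask.any() else 0
        if length <= 0:
            continue
        hap = HaplotypeMatrix.from_variant_table(table, chrom=chrom) if mask.any() else None
        for start in _window_starts(length, window_size, step):
            end = min(start + window_size, length)
            if hap is not None:
                in_win = (hap.positions >= start) & (hap.positions < end)
                win = hap.alleles[:, in_win]
            else:
                win = np.zeros((2 * table.n_samples, 0), dtype=np.int8)
            S = count_segregating(win)
            pi = window_pi(win)
            if win.shape[1] > 0:
                miss_frac = (win == MISSING).mean(axis=1)
                n_alleles = int(np.sum(miss_frac <= max_missing_frac))
            else:
                n_alleles = win.shape[0]
            theta_w = window_theta_w(S, n_alleles) if n_alleles >= 2 else 0.0
            D = tajimas_d(pi, S, n_alleles)
            rows.append(
                dict(
                    chrom=chrom,
                    start=start,
                    end=end,
                    full=(end - start) == window_size,
                    n_alleles=n_alleles,
                    S=S,
                    pi=pi,
                    theta_w=theta_w,
                    D=D,
                )
            )
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "full", "n_alleles", "S", "pi", "theta_w", "D"],
    )


def empirical_thresholds(
    d_values: np.ndarray, tail_fraction: float = 0.05
) -> tuple[float, float]:
    """Empirical-tail D cutoffs by linear interpolation between order statistics."""
    if not (0 < tail_fraction < 0.5):
        raise ValueError("tail_fraction must be in (0, 0.5)")
    d = np.asarray(d_values, dtype=float)
    d = d[np.isfinite(d)]
    if d.size == 0:
        raise ValueError("no finite D values")
    if d.size < 20:
        raise ValueError(f"need >= 20 finite D values, got {d.size}")
    low = float(np.quantile(d, tail_fraction, method="linear"))
    high = float(np.quantile(d, 1.0 - tail_fraction, method="linear"))
    return low, high


def candidate_regions(
    window_stats: pd.DataFrame,
    low: float,
    high: float,
    population_label: str,
) -> list[SweepRegion]:
    """Call and merge tail windows into sweep regions.

    ``population_label`` is "C" (cultivated) or "W" (wild); windows with
    D < low get the negative label (CN/WN), D > high the positive (CP/WP).
    Consecutive or overlapping same-label windows merge into one region.
    """
    if low >= high:
        raise ValueError("low threshold must be < high threshold")
    if population_label not in ("C", "W"):
        raise ValueError("population_label must be 'C' or 'W'")

    regions: list[SweepRegion] = []
    current: dict | None = None
    df = window_stats.sort_values(["chrom", "start"], kind="stable")
    for row in df.itertuples(index=False):
        d = row.D
        if not np.isfinite(d):
            label = None
        elif d < low:
            label = population_label + "N"
        elif d > high:
            label = population_label + "P"
        else:
            label = None
        if label is None:
            if current is not None:
                regions.append(SweepRegion(**current))
                current = None
            continue
        if (
            current is not None
            and current["label"] == label
            and current["chrom"] == row.chrom
            and row.start <= current["end"]
        ):
            current["end"] = max(current["end"], row.end)
            current["n_windows"] += 1
        else:
            if current is not None:
                regions.append(SweepRegion(**current))
            current = dict(
                chrom=row.chrom,
                start=int(row.start),
                end=int(row.end),
                label=label,
                n_windows=1,
            )
    if current is not None:
        regions.append(SweepRegion(**current))
    return regions


def genes_in_regions(
    regions: list[SweepRegion], annotation: GeneAnnotation
) -> tuple[list[SweepRegion], int]:
    """Attach overlapping gene ids (>=1 bp, half-open) to each region.

    Returns the annotated regions and the number of unique genes across all
    regions (a gene spanning several regions counts once).
    """
    trees: dict[str, IntervalTree] = {}
    for g in annotation:
        trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end, g.gene_id)

    out: list[SweepRegion] = []
    all_genes: set[str] = set()
    region_chroms_missing = set()
    for r in regions:
        tree = trees.get(r.chrom)
        if tree is None:
            region_chroms_missing.add(r.chrom)
            hits: tuple[str, ...] = ()
        else:
            found = sorted(
                (iv.begin, iv.data) for iv in tree.overlap(r.start, r.end)
            )
            hits = tuple(gid for _, gid in found)
        all_genes.update(hits)
        out.append(
            SweepRegion(
                chrom=r.chrom,
                start=r.start,
                end=r.end,
                label=r.label,
                n_windows=r.n_windows,
                gene_ids=hits,
            )
        )
    if region_chroms_missing:
        logger.warning(
            "genes_in_regions: no annotation for chrom(s) %s",
            sorted(region_chroms_missing),
        )
    return out, len(all_genes)


def regions_to_frame(regions: list[SweepRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                chrom=r.chrom,
                start=r.start,
                end=r.end,
                label=r.label,
                n_windows=r.n_windows,
                n_genes=len(r.gene_ids),
                gene_ids=",".join(r.gene_ids),
            )
            for r in regions
        ],
        columns=["chrom", "start", "end", "label", "n_windows", "n_genes", "gene_ids"],
    )
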