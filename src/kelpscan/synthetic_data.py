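"""Synthetic inputs with recorded ground truth for every pipeline stage.

The coalescent generator implements the standard Kingman process per
window under a piecewise-constant demography (no recombination within
windows, windows independent) with infinite-sites mutation, so classical
neutral expectations are exact: E[S] = theta * a1(n) and E[pi] = theta per
window.  A two-population variant models a cultivated lineage that split
recently from a wild population and collapsed to a small effective size,
reproducing the wild > cultivated diversity contrast at the level where it
is testable on simulated data.  Further generators emulate repeat copies
decayed from a consensus at known Jukes-Cantor ages, Dollo-compatible
gene-family evolution on a rooted species tree, host/bacterial contig
mixtures with contrasting GC and coding density, and codon-aligned paralog
pairs with known Ka/Ks.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .core_io import HET, HOM_ALT, HOM_REF, HaplotypeMatrix, VariantTable
from .mol_evolution import (
    RepeatCopyAlignment,
    _CODON_TO_AA,
    _STOPS,
    _codon_syn_sites,
    jc_p_from_d,
)
from .phylo_dollo import GainLossMap, clade_signature
from .seq_qc import ContigRecord

BASES = "ACGT"


@dataclass
class SimTruth:
    """Ground-truth record serialized alongside every generated dataset."""

    generator: str
    seed: int
    params: dict = field(default_factory=dict)
    truth: dict = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        def _default(o):
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, frozenset):
                return sorted(o)
            raise TypeError(f"not serializable: {type(o)}")

        text = json.dumps(
            dict(generator=self.generator, seed=self.seed, params=self.params,
                 truth=self.truth),
            indent=2,
            default=_default,
        )
        if path is not None:
            Path(path).write_text(text)
        return text


@dataclass(frozen=True)
class DemographyModel:
    """Piecewise-constant sizes: epochs of (time-ago, relative size).

    Times are in coalescent units of the reference size; the first epoch
    must start at 0, times strictly increase, sizes are positive.  The last
    epoch extends to infinity.
    """

    epochs: tuple[tuple[float, float], ...] = ((0.0, 1.0),)

    def __post_init__(self) -> None:
        times = [t for t, _ in self.epochs]
        sizes = [s for _, s in self.epochs]
        if not self.epochs or times[0] != 0.0:
            raise ValueError("first epoch must start at time 0")
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("epoch times must be strictly increasing")
        if any(s <= 0 for s in sizes):
            raise ValueError("epoch sizes must be > 0")

    def size_at(self, t: float) -> float:
        size = self.epochs[0][1]
        for start, s in self.epochs:
            if t >= start:
                size = s
        return size

    def next_change(self, t: float) -> float:
        for start, _ in self.epochs:
            if start > t:
                return start
        return float("inf")


@dataclass
class _Edge:
    leaves: tuple[int, ...]
    birth: float
    death: float = float("inf")

    @property
    def duration(self) -> float:
        return self.death - self.birth


def _coalesce_pool(
    lineages: list[_Edge],
    t0: float,
    t1: float,
    demography: DemographyModel,
    rng: np.random.Generator,
    edges: list[_Edge],
) -> tuple[list[_Edge], float]:
    """Run pairwise coalescence in one pool from t0 to t1 (possibly inf).

    Piecewise-constant rescaling: with k lineages and relative size sigma
    the coalescence rate is k(k-1)/(2 sigma).  Closes finished edges into
    ``edges`` and returns the surviving lineages and the reached time.
    """
    t = t0
    lineages = list(lineages)
    while len(lineages) > 1:
        k = len(lineages)
        base_rate = k * (k - 1) / 2.0
        e = rng.exponential(1.0)
        # walk epochs until the exponential budget is spent
        while True:
            sigma = demography.size_at(t)
            rate = base_rate / sigma
            boundary = min(demography.next_change(t), t1)
            dt = e / rate
            if t + dt <= boundary:
                t = t + dt
                break
            e -= (boundary - t) * rate
            t = boundary
            if t >= t1:
                return lineages, t
        if t >= t1:
            return lineages, min(t, t1)
        i, j = rng.choice(len(lineages), size=2, replace=False)
        i, j = (int(i), int(j)) if i < j else (int(j), int(i))
        a, b = lineages[j], lineages[i]
        a.death = t
        b.death = t
        edges.append(a)
        edges.append(b)
        merged = _Edge(leaves=tuple(sorted(a.leaves + b.leaves)), birth=t)
        lineages = [x for idx, x in enumerate(lineages) if idx not in (i, j)]
        lineages.append(merged)
    return lineages, t


def _simulate_window_tree(
    n_alleles: int, demography: DemographyModel, rng: np.random.Generator
) -> list[_Edge]:
    """One Kingman genealogy; returns all closed edges (branches below the MRCA)."""
    lineages = [_Edge(leaves=(i,), birth=0.0) for i in range(n_alleles)]
    edges: list[_Edge] = []
    remaining, _ = _coalesce_pool(
        lineages, 0.0, float("inf"), demography, rng, edges
    )
    assert len(remaining) == 1
    return edges


def _drop_mutations(
    edges: list[_Edge],
    n_alleles: int,
    theta: float,
    window_length: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Poisson(theta/2 * L) mutations, infinite sites; returns (positions, columns)."""
    durations = np.array([e.duration for e in edges])
    total = durations.sum()
    n_mut = rng.poisson(theta / 2.0 * total)
    if n_mut == 0:
        return np.array([], dtype=np.int64), np.zeros((n_alleles, 0), dtype=np.int8)
    if n_mut > window_length:
        raise ValueError(
            f"drew {n_mut} mutations but window holds only {window_length} "
            "infinite-sites positions"
        )
    positions = np.sort(rng.choice(window_length, size=n_mut, replace=False))
    which_edge = rng.choice(len(edges), size=n_mut, p=durations / total)
    cols = np.zeros((n_alleles, n_mut), dtype=np.int8)
    for m, ei in enumerate(which_edge):
        cols[list(edges[ei].leaves), m] = 1
    return positions, cols


def _haplotypes_to_table(
    alleles: np.ndarray,
    positions: np.ndarray,
    chrom: str,
    sample_prefix: str,
    rng: np.random.Generator,
    pairing: np.ndarray | None = None,
) -> tuple[VariantTable, np.ndarray]:
    """Random-pair haplotypes into diploids and emit a VariantTable.

    Returns the table and the pairing (haplotype indices, shape (n/2, 2)).
    """
    n_hap = alleles.shape[0]
    if n_hap % 2 != 0:
        raise ValueError("diploid pairing requires an even number of haplotypes")
    if pairing is None:
        order = rng.permutation(n_hap)
        pairing = order.reshape(-1, 2)
    n_ind = pairing.shape[0]
    gsum = alleles[pairing[:, 0]] + alleles[pairing[:, 1]]
    gt = np.full(gsum.shape, HET, dtype=np.int8)
    gt[gsum == 0] = HOM_REF
    gt[gsum == 2] = HOM_ALT
    samples = [f"{sample_prefix}{i + 1}" for i in range(n_ind)]
    n_sites = len(positions)
    ref = np.array(["A"] * n_sites, dtype=object)
    alt = np.array(["T"] * n_sites, dtype=object)
    table = VariantTable(
        samples=samples,
        chrom=np.array([chrom] * n_sites, dtype=object),
        pos=np.asarray(positions, dtype=np.int64),
        ref=ref,
        alt=alt,
        genotypes=gt,
    )
    return table, pairing


def simulate_coalescent(
    n_alleles: int,
    theta: float,
    demography: DemographyModel | None = None,
    n_windows: int = 1,
    window_length: int = 10_000,
    seed: int = 0,
    chrom: str = "chr1",
    sample_prefix: str = "ind",
) -> tuple[HaplotypeMatrix, VariantTable, SimTruth]:
    """Neutral coalescent windows tiling one chromosome.

    Windows are independent genealogies occupying consecutive
    ``window_length`` stretches.  ``n_alleles`` must be even so haplotypes
    pair into diploids.
    """
    if n_alleles < 2:
        raise ValueError("n_alleles must be >= 2")
    if n_alleles % 2 != 0:
        raise ValueError("n_alleles must be even (diploid pairing)")
    if theta <= 0:
        raise ValueError("theta must be > 0")
    demography = demography or DemographyModel()
    rng = np.random.default_rng(seed)

    all_pos: list[np.ndarray] = []
    all_cols: list[np.ndarray] = []
    per_window_s: list[int] = []
    for w in range(n_windows):
        edges = _simulate_window_tree(n_alleles, demography, rng)
        positions, cols = _drop_mutations(
            edges, n_alleles, theta, window_length, rng
        )
        all_pos.append(positions + w * window_length)
        all_cols.append(cols)
        per_window_s.append(cols.shape[1])
    positions = np.concatenate(all_pos)
    alleles = np.concatenate(all_cols, axis=1)
    hap = HaplotypeMatrix(
        sample_ids=[f"hap{i}" for i in range(n_alleles)],
        chrom=chrom,
        positions=positions,
        alleles=alleles,
    )
    table, pairing = _haplotypes_to_table(
        alleles, positions, chrom, sample_prefix, rng
    )
    truth = SimTruth(
        generator="simulate_coalescent",
        seed=seed,
        params=dict(
            n_alleles=n_alleles,
            theta=theta,
            demography=[list(e) for e in demography.epochs],
            n_windows=n_windows,
            window_length=window_length,
        ),
        truth=dict(per_window_S=per_window_s, pairing=pairing.tolist()),
    )
    return hap, table, truth


@dataclass
class TwoPopResult:
    wild: HaplotypeMatrix
    cultivated: HaplotypeMatrix
    table: VariantTable  # combined samples: wild_* then cult_*
    wild_samples: list[str]
    cultivated_samples: list[str]
    truth: SimTruth


def simulate_two_pop(
    n_wild: int,
    n_cultivated: int,
    theta: float = 10.0,
    bottleneck_severity: float = 0.05,
    split_time: float = 0.1,
    n_windows: int = 200,
    window_length: int = 10_000,
    seed: int = 0,
    chrom: str = "chr1",
) -> TwoPopResult:
    """Structured coalescent: a cultivated deme of relative size
    ``bottleneck_severity`` that split from the wild population
    ``split_time`` coalescent units ago.

    ``n_wild``/``n_cultivated`` are diploid individuals.  Backward in time,
    cultivated lineages coalesce among themselves at the bottleneck size
    until the split, then all surviving lineages join the wild (size 1)
    pool.  severity = 1.0 makes the demes exchangeable.
    """
    if not (0 < bottleneck_severity <= 1.0):
        raise ValueError("bottleneck_severity must be in (0, 1]")
    if split_time <= 0:
        raise ValueError("split_time must be > 0")
    if n_wild < 1 or n_cultivated < 1:
        raise ValueError("population sizes must be positive")
    rng = np.random.default_rng(seed)
    nw, nc = 2 * n_wild, 2 * n_cultivated
    n_total = nw + nc
    wild_demo = DemographyModel(((0.0, 1.0),))
    cult_demo = DemographyModel(((0.0, bottleneck_severity),))

    all_pos, all_cols, per_window_s = [], [], []
    for w in range(n_windows):
        edges: list[_Edge] = []
        wild_lin = [_Edge(leaves=(i,), birth=0.0) for i in range(nw)]
        cult_lin = [_Edge(leaves=(nw + i,), birth=0.0) for i in range(nc)]
        wild_rem, _ = _coalesce_pool(wild_lin, 0.0, split_time, wild_demo, rng, edges)
        cult_rem, _ = _coalesce_pool(cult_lin, 0.0, split_time, cult_demo, rng, edges)
        merged, _ = _coalesce_pool(
            wild_rem + cult_rem, split_time, float("inf"), wild_demo, rng, edges
        )
        assert len(merged) == 1
        positions, cols = _drop_mutations(edges, n_total, theta, window_length, rng)
        all_pos.append(positions + w * window_length)
        all_cols.append(cols)
        per_window_s.append(cols.shape[1])
    positions = np.concatenate(all_pos)
    alleles = np.concatenate(all_cols, axis=1)

    wild_hap = HaplotypeMatrix(
        sample_ids=[f"wild_hap{i}" for i in range(nw)],
        chrom=chrom,
        positions=positions,
        alleles=alleles[:nw],
    )
    cult_hap = HaplotypeMatrix(
        sample_ids=[f"cult_hap{i}" for i in range(nc)],
        chrom=chrom,
        positions=positions,
        alleles=alleles[nw:],
    )
    # pair within populations so sample labels track the demes
    wild_pairs = rng.permutation(nw).reshape(-1, 2)
    cult_pairs = nw + rng.permutation(nc).reshape(-1, 2)
    pairing = np.vstack([wild_pairs, cult_pairs])
    table, _ = _haplotypes_to_table(
        alleles, positions, chrom, "s", rng, pairing=pairing
    )
    wild_samples = [f"wild_{i + 1}" for i in range(n_wild)]
    cult_samples = [f"cult_{i + 1}" for i in range(n_cultivated)]
    table.samples = wild_samples + cult_samples
    truth = SimTruth(
        generator="simulate_two_pop",
        seed=seed,
        params=dict(
            n_wild=n_wild,
            n_cultivated=n_cultivated,
            theta=theta,
            bottleneck_severity=bottleneck_severity,
            split_time=split_time,
            n_windows=n_windows,
            window_length=window_length,
        ),
        truth=dict(per_window_S=per_window_s, pairing=pairing.tolist()),
    )
    return TwoPopResult(
        wild=wild_hap,
        cultivated=cult_hap,
        table=table,
        wild_samples=wild_samples,
        cultivated_samples=cult_samples,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Random trees


def random_tree(
    n_leaves: int,
    rng: np.random.Generator,
    rooted: bool = True,
    length_range: tuple[float, float] = (0.05, 0.3),
    prefix: str = "t",
) -> dendropy.Tree:
    """Random binary tree by successive joins, branch lengths uniform.

    Unrooted trees end in a basal trifurcation (three children at the seed
    node); rooted trees are strictly bifurcating.
    """
    if n_leaves < (3 if not rooted else 2):
        raise ValueError("too few leaves")
    lo, hi = length_range
    taxa = [f"{prefix}{i:02d}" for i in range(n_leaves)]
    ns = dendropy.TaxonNamespace(taxa)
    nodes = []
    for lab in taxa:
        nd = dendropy.Node()
        nd.taxon = ns.get_taxon(lab)
        nodes.append(nd)
    stop = 3 if not rooted else 1
    while len(nodes) > stop:
        if not rooted and len(nodes) == 3:
            break
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        parent = dendropy.Node()
        for idx in (int(j), int(i)):
            child = nodes.pop(idx)
            child.edge.length = float(rng.uniform(lo, hi))
            parent.add_child(child)
        nodes.append(parent)
    if rooted:
        seed_node = nodes[0]
    else:
        seed_node = dendropy.Node()
        for child in nodes:
            child.edge.length = float(rng.uniform(lo, hi))
            seed_node.add_child(child)
    tree = dendropy.Tree(taxon_namespace=ns)
    tree.seed_node = seed_node
    tree.is_rooted = rooted
    return tree


# ---------------------------------------------------------------------------
# Repeat decay


def simulate_te_decay(
    consensus_length: int,
    copy_ages: list[float],
    fragment_fraction: float = 1.0,
    seed: int = 0,
    family_id: str = "TEfam",
) -> tuple[list[RepeatCopyAlignment], SimTruth]:
    """Derive repeat copies from a random consensus at known JC ages.

    Each copy substitutes every site independently with probability
    p(d) = (3/4)(1 - exp(-4d/3)) to a uniformly chosen different base,
    then (optionally) truncates to a random contiguous fragment covering
    ``fragment_fraction`` of the consensus, gapping the rest.
    """
    if any(d < 0 for d in copy_ages):
        raise ValueError("ages must be >= 0")
    if not (0 < fragment_fraction <= 1.0):
        raise ValueError("fragment_fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    consensus = "".join(rng.choice(list(BASES), size=consensus_length))
    alignments = []
    for idx, d in enumerate(copy_ages):
        p = jc_p_from_d(d)
        seq = np.array(list(consensus))
        hit = rng.random(consensus_length) < p
        for i in np.where(hit)[0]:
            others = [b for b in BASES if b != seq[i]]
            seq[i] = others[rng.integers(0, 3)]
        copy = "".join(seq)
        if fragment_fraction < 1.0:
            frag_len = max(1, int(round(fragment_fraction * consensus_length)))
            start = int(rng.integers(0, consensus_length - frag_len + 1))
            copy = (
                "-" * start
                + copy[start : start + frag_len]
                + "-" * (consensus_length - start - frag_len)
            )
        alignments.append(
            RepeatCopyAlignment(
                copy_id=f"{family_id}_copy{idx}",
                family_id=family_id,
                aligned_copy=copy,
                aligned_consensus=consensus,
            )
        )
    truth = SimTruth(
        generator="simulate_te_decay",
        seed=seed,
        params=dict(
            consensus_length=consensus_length,
            fragment_fraction=fragment_fraction,
            family_id=family_id,
        ),
        truth=dict(copy_ages=list(copy_ages)),
    )
    return alignments, truth


# ---------------------------------------------------------------------------
# Dollo-compatible family evolution


def simulate_family_evolution(
    species_tree: dendropy.Tree,
    n_families: int,
    loss_rate: float = 0.02,
    seed: int = 0,
) -> tuple[pd.DataFrame, GainLossMap, SimTruth]:
    """Single-gain families with Poisson losses on branches below the gain.

    Each family gains on a uniformly chosen branch (the branch above a
    uniformly chosen node, the root included); losses occur on each branch
    below the gain with count Poisson(loss_rate x branch length), each
    silencing its whole subtree.  Redundant losses inside an already-lost
    subtree are not recorded, so the recorded loss set is the minimal Dollo
    explanation by construction.
    """
    if not species_tree.is_rooted:
        raise ValueError("Dollo simulation requires a rooted species tree")
    if loss_rate < 0:
        raise ValueError("loss_rate must be >= 0")
    rng = np.random.default_rng(seed)
    nodes = list(species_tree.preorder_node_iter())
    leaves = sorted(lf.taxon.label for lf in species_tree.leaf_node_iter())

    truth_map = GainLossMap()
    presence_rows = np.zeros((n_families, len(leaves)), dtype=int)
    leaf_index = {lab: i for i, lab in enumerate(leaves)}
    for f in range(n_families):
        fam = f"fam{f}"
        gain_node = nodes[int(rng.integers(0, len(nodes)))]
        gain_sig = clade_signature(gain_node)
        truth_map.gains.setdefault(gain_sig, set()).add(fam)
        truth_map.family_gain[fam] = gain_sig
        present = set(gain_sig)

        def descend(node: dendropy.Node) -> None:
            for child in node.child_nodes():
                blen = child.edge.length or 0.0
                if loss_rate > 0 and rng.poisson(loss_rate * blen) > 0:
                    sig = clade_signature(child)
                    truth_map.losses.setdefault(sig, set()).add(fam)
                    present.difference_update(sig)
                else:
                    descend(child)

        descend(gain_node)
        for lab in present:
            presence_rows[f, leaf_index[lab]] = 1
    presence = pd.DataFrame(
        presence_rows, index=[f"fam{f}" for f in range(n_families)], columns=leaves
    )
    truth = SimTruth(
        generator="simulate_family_evolution",
        seed=seed,
        params=dict(n_families=n_families, loss_rate=loss_rate),
        truth=dict(
            family_gain={k: sorted(v) for k, v in truth_map.family_gain.items()}
        ),
    )
    return presence, truth_map, truth


# ---------------------------------------------------------------------------
# Contig mixtures


def _random_bases(n: int, gc: float, rng: np.random.Generator) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    return "".join(rng.choice(list("ACGT"), size=n, p=probs))


_NONSTOP_CODONS = sorted(set(_CODON_TO_AA) - _STOPS)


def _random_orf(length: int, gc: float, rng: np.random.Generator) -> str:
    """ATG + GC-biased non-stop codons + TAA; ``length`` is rounded to a codon multiple."""
    n_codons = max(3, length // 3)
    base_p = {"A": (1 - gc) / 2, "C": gc / 2, "G": gc / 2, "T": (1 - gc) / 2}
    weights = np.array(
        [base_p[c[0]] * base_p[c[1]] * base_p[c[2]] for c in _NONSTOP_CODONS]
    )
    weights /= weights.sum()
    body = rng.choice(_NONSTOP_CODONS, size=n_codons - 2, p=weights)
    return "ATG" + "".join(body) + "TAA"


def simulate_contigs(
    n_host: int,
    n_bacterial: int,
    host_gc: float = 0.50,
    bacterial_gc: float = 0.65,
    coding_density: float = 0.80,
    length_range: tuple[int, int] = (2_000, 5_000),
    seed: int = 0,
) -> tuple[list[ContigRecord], pd.DataFrame, SimTruth]:
    """Host-like and bacteria-like contigs with contrasting GC/coding density.

    Host contigs are i.i.d. bases at ``host_gc`` (sparse incidental ORFs);
    bacterial contigs interleave stop-free GC-biased ORFs to the requested
    coding density.  Taxonomy hints mirror the true origin, emulating
    upstream homology assignment.  Returns (contigs, labels, truth).
    """
    if not (0 < host_gc < 1 and 0 < bacterial_gc < 1):
        raise ValueError("gc values must be in (0, 1)")
    if not (0 <= coding_density <= 1):
        raise ValueError("coding_density must be in [0, 1]")
    lo, hi = length_range
    if not (0 < lo < hi):
        raise ValueError("degenerate length_range")
    rng = np.random.default_rng(seed)
    contigs: list[ContigRecord] = []
    labels = []
    for i in range(n_host):
        length = int(rng.integers(lo, hi + 1))
        contigs.append(
            ContigRecord(
                contig_id=f"host_{i}",
                sequence=_random_bases(length, host_gc, rng),
                taxonomy_hint="authentic",
            )
        )
        labels.append(("host_" + str(i), "host", "authentic"))
    for i in range(n_bacterial):
        length = int(rng.integers(lo, hi + 1))
        if coding_density >= 1.0:
            seq = _random_orf(length - length % 3, bacterial_gc, rng)
        else:
            parts = []
            coding_left = coding_density * length
            pos = 0
            while pos < length:
                if coding_left > 0:
                    orf_len = int(min(3 * rng.integers(150, 400), coding_left // 3 * 3))
                    orf_len = max(orf_len, 309)
                    orf = _random_orf(orf_len, bacterial_gc, rng)
                    parts.append(orf)
                    coding_left -= len(orf)
                    pos += len(orf)
                spacer = int(
                    rng.integers(50, 200)
                    if coding_left > 0
                    else max(0, length - pos)
                )
                if spacer:
                    parts.append(_random_bases(spacer, bacterial_gc, rng))
                    pos += spacer
                if coding_left <= 0 and pos >= length:
                    break
            seq = "".join(parts)[:length]
        contigs.append(
            ContigRecord(
                contig_id=f"bact_{i}",
                sequence=seq,
                taxonomy_hint="candidate_bacterial",
            )
        )
        labels.append(("bact_" + str(i), "bacterial", "candidate_bacterial"))
    label_df = pd.DataFrame(labels, columns=["contig_id", "origin", "hint"])
    truth = SimTruth(
        generator="simulate_contigs",
        seed=seed,
        params=dict(
            n_host=n_host,
            n_bacterial=n_bacterial,
            host_gc=host_gc,
            bacterial_gc=bacterial_gc,
            coding_density=coding_density,
            length_range=list(length_range),
        ),
        truth=dict(origins={cid: origin for cid, origin, _ in labels}),
    )
    return contigs, label_df, truth


# ---------------------------------------------------------------------------
# Paralog pairs with known Ka/Ks


def _candidate_changes(codon: str, synonymous: bool) -> list[tuple[int, str]]:
    out = []
    aa = _CODON_TO_AA[codon]
    for pos in range(3):
        for alt in BASES:
            if alt == codon[pos]:
                continue
            mut = codon[:pos] + alt + codon[pos + 1 :]
            if mut in _STOPS:
                continue
            if (_CODON_TO_AA[mut] == aa) == synonymous:
                out.append((pos, alt))
    return out


def simulate_paralog_pairs(
    n_pairs: int,
    true_ks: float,
    true_ka: float,
    codon_count: int = 2_000,
    seed: int = 0,
) -> tuple[list[tuple[str, str]], SimTruth]:
    """Codon-aligned pairs carrying known synonymous/nonsynonymous divergence.

    From a random stop-free ancestor, the derived copy receives
    round(p_s x S_sites) synonymous and round(p_n x N_sites) nonsynonymous
    single-base changes (p = inverse-JC of the true rate), each applied at
    a distinct codon position and never creating a stop codon.
    """
    if codon_count < 100:
        raise ValueError("codon_count must be >= 100")
    if not (0 <= true_ks <= 1.0 and 0 <= true_ka <= 1.0):
        raise ValueError("rates must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    pairs = []
    for _ in range(n_pairs):
        codons = list(rng.choice(_NONSTOP_CODONS, size=codon_count))
        s_sites = sum(_codon_syn_sites(c) for c in codons)
        n_sites = 3 * codon_count - s_sites
        n_syn = int(round(jc_p_from_d(true_ks) * s_sites))
        n_non = int(round(jc_p_from_d(true_ka) * n_sites))
        derived = list(codons)
        used_pos: set[tuple[int, int]] = set()
        touched: set[int] = set()
        for synonymous, n_changes in ((True, n_syn), (False, n_non)):
            # one change per codon keeps NG86 pathway counting exact; codons
            # are revisited only if the demand exceeds the untouched supply
            queue = [ci for ci in rng.permutation(codon_count) if ci not in touched]
            applied = 0
            refilled = False
            while applied < n_changes:
                if not queue:
                    if refilled:
                        raise ValueError(
                            "could not place requested substitutions without stops"
                        )
                    queue = list(rng.permutation(codon_count))
                    refilled = True
                ci = int(queue.pop())
                cands = [
                    (pos, alt)
                    for pos, alt in _candidate_changes(derived[ci], synonymous)
                    if (ci, pos) not in used_pos
                ]
                if not cands:
                    continue
                pos, alt = cands[int(rng.integers(0, len(cands)))]
                derived[ci] = derived[ci][:pos] + alt + derived[ci][pos + 1 :]
                used_pos.add((ci, pos))
                touched.add(ci)
                applied += 1
        pairs.append(("".join(codons), "".join(derived)))
    truth = SimTruth(
        generator="simulate_paralog_pairs",
        seed=seed,
        params=dict(n_pairs=n_pairs, codon_count=codon_count),
        truth=dict(true_ks=true_ks, true_ka=true_ka),
    )
    return pairs, truth
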