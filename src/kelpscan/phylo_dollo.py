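"""Homozygous-SNP distance matrices, neighbour-joining with bootstrap,
and Dollo parsimony gain/loss reconstruction of gene families.

NJ is the classical Saitou-Nei algorithm: iteratively join the pair with
minimal Q = (r-2) d(i,j) - R_i - R_j, branch lengths from the three-point
formulas, ties broken toward the lexicographically smallest label pair so
output is independent of input order.  Dollo parsimony assumes each gene
family arises exactly once: the gain is placed on the branch above the MRCA
of the possessing taxa and the minimal losses are the roots of the maximal
wholly-absent subtrees below it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .core_io import HOM_ALT, HOM_REF, VariantTable

logger = logging.getLogger("kelpscan")


# ---------------------------------------------------------------------------
# Distances


def snp_distance_matrix(
    table: VariantTable, samples: list[str] | None = None
) -> tuple[list[str], np.ndarray]:
    """Pairwise p-distances over sites where BOTH samples are homozygous.

    A site contributes to a pair iff each sample is hom-ref or hom-alt
    there; the pair differs at the site iff one is hom-ref and the other
    hom-alt.  Raises ValueError naming the pair if it has zero comparable
    sites.
    """
    if samples is not None:
        table = table.subset_samples(samples)
    labels = list(table.samples)
    if len(labels) < 2:
        raise ValueError("need >= 2 samples")
    gt = table.genotypes
    hom = (gt == HOM_REF) | (gt == HOM_ALT)
    n = len(labels)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = hom[i] & hom[j]
            comparable = int(both.sum())
            if comparable == 0:
                raise ValueError(
                    f"samples {labels[i]!r} and {labels[j]!r} share no "
                    "comparable homozygous site"
                )
            diffs = int(np.sum(gt[i][both] != gt[j][both]))
            dist[i, j] = dist[j, i] = diffs / comparable
    return labels, dist


# ---------------------------------------------------------------------------
# Neighbour joining


def _check_distance_matrix(labels: list[str], dist: np.ndarray) -> np.ndarray:
    dist = np.asarray(dist, dtype=float)
    n = len(labels)
    if dist.shape != (n, n):
        raise ValueError("distance matrix shape does not match labels")
    if not np.all(np.isfinite(dist)):
        raise ValueError("distance matrix has non-finite entries")
    if not np.allclose(dist, dist.T, atol=1e-12):
        raise ValueError("distance matrix is not symmetric")
    if not np.allclose(np.diag(dist), 0.0, atol=1e-12):
        raise ValueError("distance matrix diagonal is not zero")
    return dist


def neighbor_joining(labels: list[str], dist: np.ndarray) -> dendropy.Tree:
    """Saitou-Nei NJ returning an unrooted dendropy tree.

    Negative branch lengths are clamped to zero with the deficit moved to
    the sister branch (standard practice).  Equal-Q ties join the
    lexicographically smallest (label, label) pair, so the topology is
    invariant under permutations of the input order.
    """
    dist = _check_distance_matrix(labels, dist)
    n = len(labels)
    if n < 3:
        raise ValueError("NJ needs >= 3 taxa")

    taxa = dendropy.TaxonNamespace(labels)
    nodes: list[dendropy.Node] = []
    for lab in labels:
        nd = dendropy.Node()
        nd.taxon = taxa.get_taxon(lab)
        nodes.append(nd)
    # sort key per cluster: smallest leaf label underneath (deterministic ties)
    keys = list(labels)
    d = dist.copy()
    active = list(range(n))

    def _join_lengths(di_j: float, ri: float, rj: float, r: int) -> tuple[float, float]:
        li = 0.5 * di_j + (ri - rj) / (2.0 * (r - 2))
        lj = di_j - li
        if li < 0:
            lj += li  # transfer deficit to sister
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
            li = max(li, 0.0)
        return li, lj

    while len(active) > 3:
        r = len(active)
        sub = d[np.ix_(active, active)]
        R = sub.sum(axis=1)
        q = (r - 2) * sub - R[:, None] - R[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        best = None
        for ai in range(r):
            for aj in range(ai + 1, r):
                if q[ai, aj] <= qmin + 1e-12:
                    pair_key = tuple(sorted((keys[active[ai]], keys[active[aj]])))
                    if best is None or pair_key < best[0]:
                        best = (pair_key, ai, aj)
        _, ai, aj = best
        i, j = active[ai], active[aj]
        li, lj = _join_lengths(sub[ai, aj], R[ai], R[aj], r)
        parent = dendropy.Node()
        nodes[i].edge.length = li
        nodes[j].edge.length = lj
        # deterministic child order
        if keys[i] <= keys[j]:
            parent.add_child(nodes[i])
            parent.add_child(nodes[j])
        else:
            parent.add_child(nodes[j])
            parent.add_child(nodes[i])
        new_idx = len(nodes)
        nodes.append(parent)
        keys.append(min(keys[i], keys[j]))
        newrow = np.zeros(new_idx + 1)
        d = np.pad(d, ((0, 1), (0, 1)))
        for k in active:
            if k in (i, j):
                continue
            d[new_idx, k] = d[k, new_idx] = 0.5 * (d[i, k] + d[j, k] - d[i, j])
        active = [k for k in active if k not in (i, j)] + [new_idx]

    # connect the final three clusters to a central node
    i, j, k = active
    dij, dik, djk = d[i, j], d[i, k], d[j, k]
    li = 0.5 * (dij + dik - djk)
    lj = 0.5 * (dij + djk - dik)
    lk = 0.5 * (dik + djk - dij)
    center = dendropy.Node()
    lens = {i: li, j: lj, k: lk}
    for idx in sorted((i, j, k), key=lambda t: keys[t]):
        nodes[idx].edge.length = max(lens[idx], 0.0)
        center.add_child(nodes[idx])
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = center
    tree.is_rooted = False
    return tree


def unrooted_splits(tree: dendropy.Tree) -> set[frozenset[frozenset[str]]]:
    """Non-trivial bipartitions of an unrooted tree as pairs of label sets."""
    all_labels = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    splits = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        other = all_labels - side
        if len(side) >= 2 and len(other) >= 2:
            splits.add(frozenset({side, other}))
    return splits


def tree_path_distances(tree: dendropy.Tree) -> tuple[list[str], np.ndarray]:
    """Leaf-to-leaf path-length matrix of a tree (labels sorted)."""
    pdm = tree.phylogenetic_distance_matrix()
    labels = sorted(t.label for t in tree.taxon_namespace)
    n = len(labels)
    out = np.zeros((n, n))
    tax = {t.label: t for t in tree.taxon_namespace}
    for a in range(n):
        for b in range(a + 1, n):
            out[a, b] = out[b, a] = pdm.distance(tax[labels[a]], tax[labels[b]])
    return labels, out


def bootstrap_support(
    table: VariantTable,
    samples: list[str] | None = None,
    n_replicates: int = 1000,
    seed: int = 0,
) -> dendropy.Tree:
    """NJ tree on all sites, with per-bipartition bootstrap support (0-100).

    SNP columns are resampled with replacement; replicates in which any
    sample pair has zero comparable homozygous sites are skipped (logged).
    Support values are written as internal node labels of the full-data
    tree.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if samples is not None:
        table = table.subset_samples(samples)
    labels, dist = snp_distance_matrix(table)
    main_tree = neighbor_joining(labels, dist)
    main_tree.encode_bipartitions()
    bip_counts = {
        int(b.split_bitmask): 0
        for b in main_tree.bipartition_encoding
    }

    rng = np.random.default_rng(seed)
    n_sites = table.n_sites
    used = 0
    skipped = 0
    for _ in range(n_replicates):
        cols = rng.integers(0, n_sites, size=n_sites)
        rep = VariantTable(
            samples=table.samples,
            chrom=np.array(["boot"] * n_sites, dtype=object),
            pos=np.arange(n_sites),
            ref=table.ref[cols],
            alt=table.alt[cols],
            genotypes=table.genotypes[:, cols],
        )
        try:
            rl, rd = snp_distance_matrix(rep)
        except ValueError:
            skipped += 1
            continue
        rep_tree = neighbor_joining(rl, rd)
        # map replicate bipartitions onto the main tree's namespace
        rep_tree.migrate_taxon_namespace(main_tree.taxon_namespace)
        rep_tree.encode_bipartitions()
        rep_masks = {int(b.split_bitmask) for b in rep_tree.bipartition_encoding}
        for mask in bip_counts:
            if mask in rep_masks:
                bip_counts[mask] += 1
        used += 1
    if skipped:
        logger.info("bootstrap_support: skipped %d degenerate replicates", skipped)
    if used == 0:
        raise ValueError("all bootstrap replicates were degenerate")
    for edge in main_tree.preorder_edge_iter():
        node = edge.head_node
        if node.is_leaf() or edge.bipartition is None:
            continue
        pct = 100.0 * bip_counts[int(edge.bipartition.split_bitmask)] / used
        node.label = f"{pct:g}"
    return main_tree


# ---------------------------------------------------------------------------
# Dollo parsimony


def clade_signature(node: dendropy.Node) -> frozenset[str]:
    """Stable branch identifier: the set of leaf labels below the node."""
    return frozenset(lf.taxon.label for lf in node.leaf_iter())


@dataclass
class GainLossMap:
    """Per-branch gain/loss sets; branches keyed by clade signature."""

    gains: dict[frozenset[str], set[str]] = field(default_factory=dict)
    losses: dict[frozenset[str], set[str]] = field(default_factory=dict)
    family_gain: dict[str, frozenset[str]] = field(default_factory=dict)

    def gain_counts(self) -> dict[frozenset[str], int]:
        return {k: len(v) for k, v in self.gains.items()}

    def loss_counts(self) -> dict[frozenset[str], int]:
        return {k: len(v) for k, v in self.losses.items()}

    @property
    def n_families(self) -> int:
        return len(self.family_gain)


def dollo_reconstruct(
    presence: pd.DataFrame, species_tree: dendropy.Tree
) -> GainLossMap:
    """Single-gain, minimal-loss reconstruction of family presence/absence.

    ``presence`` is a family x taxon boolean (or 0/1) matrix whose columns
    must exactly match the tree's leaf labels.  Per family the gain sits on
    the branch above the MRCA of the possessing taxa; the losses are the
    roots of the maximal subtrees below the gain in which the family is
    absent from every leaf.  Families absent everywhere are skipped with a
    warning.
    """
    if not species_tree.is_rooted:
        raise ValueError("Dollo reconstruction requires a rooted species tree")
    leaf_labels = {lf.taxon.label for lf in species_tree.leaf_node_iter()}
    cols = set(presence.columns)
    if cols != leaf_labels:
        raise ValueError(
            f"presence-matrix taxa {sorted(cols)} do not match tree leaves "
            f"{sorted(leaf_labels)}"
        )

    out = GainLossMap()
    skipped = 0
    # precompute leaf sets per node, postorder
    for family, row in presence.astype(bool).iterrows():
        possessing = frozenset(t for t in presence.columns if row[t])
        if not possessing:
            skipped += 1
            continue
        if len(possessing) == 1:
            (taxon,) = possessing
            mrca = next(
                lf
                for lf in species_tree.leaf_node_iter()
                if lf.taxon.label == taxon
            )
        else:
            mrca = species_tree.mrca(taxon_labels=sorted(possessing))
        gain_key = clade_signature(mrca)
        out.gains.setdefault(gain_key, set()).add(str(family))
        out.family_gain[str(family)] = gain_key

        # maximal wholly-absent subtrees strictly below the gain node
        def collect_losses(node: dendropy.Node) -> None:
            for child in node.child_nodes():
                sig = clade_signature(child)
                if sig.isdisjoint(possessing):
                    out.losses.setdefault(sig, set()).add(str(family))
                else:
                    collect_losses(child)

        collect_losses(mrca)
    if skipped:
        logger.warning("dollo_reconstruct: skipped %d all-absent families", skipped)
    return out


def dollo_brute_force(
    possessing: frozenset[str], species_tree: dendropy.Tree
) -> tuple[frozenset[str], frozenset[frozenset[str]]]:
    """Exhaustive single-gain minimal-loss search (test oracle for small trees).

    Tries every branch as the gain; the required losses under a candidate
    gain are the maximal wholly-absent subtrees below it.  Returns the
    (gain, losses) pair with fewest losses; gain eligibility requires the
    candidate clade to contain all possessing taxa.
    """
    best: tuple[int, frozenset[str], frozenset[frozenset[str]]] | None = None
    for node in species_tree.preorder_node_iter():
        sig = clade_signature(node)
        if not possessing <= sig:
            continue
        losses: list[frozenset[str]] = []
        stack = list(node.child_nodes())
        while stack:
            child = stack.pop()
            csig = clade_signature(child)
            if csig.isdisjoint(possessing):
                losses.append(csig)
            else:
                stack.extend(child.child_nodes())
        cand = (len(losses), sig, frozenset(losses))
        if best is None or cand[0] < best[0] or (
            cand[0] == best[0] and len(sig) < len(best[1])
        ):
            best = cand
    assert best is not None
    return best[1], best[2]
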