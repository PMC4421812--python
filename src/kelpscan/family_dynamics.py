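"""Gene-family expansion testing and tandem-duplication cluster detection.

The expansion test compares a family's gene count against the genome totals
of two species with a two-sided Fisher exact test (minimum-likelihood rule:
sum the probabilities of all tables no more likely than the observed one).
It is computed in exact integer arithmetic, so ties between table
probabilities are resolved exactly rather than within a floating-point
slop.  Multiple-testing correction defaults to Benjamini-Hochberg.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import comb

import networkx as nx
import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .core_io import GeneAnnotation


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Exact two-sided Fisher p for the 2x2 table [[a, b], [c, d]].

    Conditional on the margins, P(table) is hypergeometric with weight
    C(r1, a') * C(r2, m - a') where r1 = a+b, r2 = c+d, m = a+c; the
    two-sided p sums the weights of all a' whose weight is <= the observed
    weight, compared as exact integers.
    """
    for x in (a, b, c, d):
        if x < 0:
            raise ValueError("table entries must be non-negative")
    r1, r2, m = a + b, c + d, a + c
    lo = max(0, m - r2)
    hi = min(r1, m)
    obs = comb(r1, a) * comb(r2, m - a)
    num = sum(
        w
        for ap in range(lo, hi + 1)
        if (w := comb(r1, ap) * comb(r2, m - ap)) <= obs
    )
    denom = comb(r1 + r2, m)
    return float(Fraction(num, denom))


def expansion_test(count_a: int, total_a: int, count_b: int, total_b: int) -> float:
    """Two-sided Fisher p for family counts vs genome totals.

    The table is [[count_a, total_a - count_a], [count_b, total_b - count_b]].
    """
    if count_a > total_a or count_b > total_b:
        raise ValueError("family count cannot exceed genome total")
    return fisher_exact_two_sided(
        count_a, total_a - count_a, count_b, total_b - count_b
    )


def adjust_pvalues(p_list: list[float], method: str = "bh") -> list[float]:
    """Benjamini-Hochberg (default) or Bonferroni adjustment, input order preserved."""
    p = np.asarray(p_list, dtype=float)
    if p.size == 0:
        return []
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p values must lie in (0, 1]")
    method_map = {"bh": "fdr_bh", "bonferroni": "bonferroni"}
    if method not in method_map:
        raise ValueError(f"method must be one of {sorted(method_map)}")
    _, adjusted, _, _ = multipletests(p, method=method_map[method])
    return [float(x) for x in adjusted]


@dataclass(frozen=True)
class ExpansionResult:
    family_id: str
    count_a: int
    total_a: int
    count_b: int
    total_b: int
    direction: str  # "A" if proportionally larger in genome A, "B", or "="
    p_value: float
    adjusted_p: float
    significant: bool


def expansion_scan(
    counts: pd.DataFrame,
    total_a: int,
    total_b: int,
    min_family_size: int = 10,
    alpha: float = 0.05,
    method: str = "bh",
) -> list[ExpansionResult]:
    """Fisher expansion test across families with multiple-test correction.

    ``counts`` needs columns count_a, count_b indexed by family id.
    Families whose summed size across both genomes is below
    ``min_family_size`` are excluded before testing (and before
    correction).
    """
    kept = counts[(counts["count_a"] + counts["count_b"]) >= min_family_size]
    pvals = [
        expansion_test(int(r.count_a), total_a, int(r.count_b), total_b)
        for r in kept.itertuples()
    ]
    adjusted = adjust_pvalues(pvals, method=method) if pvals else []
    results = []
    for (fam, row), p, ap in zip(kept.iterrows(), pvals, adjusted):
        ca, cb = int(row["count_a"]), int(row["count_b"])
        prop_a, prop_b = ca / total_a, cb / total_b
        direction = "A" if prop_a > prop_b else ("B" if prop_b > prop_a else "=")
        results.append(
            ExpansionResult(
                family_id=str(fam),
                count_a=ca,
                total_a=total_a,
                count_b=cb,
                total_b=total_b,
                direction=direction,
                p_value=p,
                adjusted_p=ap,
                significant=ap < alpha,
            )
        )
    return results


@dataclass(frozen=True)
class TandemCluster:
    scaffold: str
    gene_ids: tuple[str, ...]  # in coordinate order
    min_identity: float

    def __post_init__(self) -> None:
        if len(self.gene_ids) < 2:
            raise ValueError("a tandem cluster needs >= 2 members")


def tandem_clusters(
    annotation: GeneAnnotation,
    identity: pd.DataFrame,
    identity_threshold: float = 0.85,
    max_intervening: int = 5,
) -> list[TandemCluster]:
    """Connected components of high-identity near-adjacent same-scaffold genes.

    An edge joins two genes on one scaffold when their pairwise identity is
    >= ``identity_threshold`` and at most ``max_intervening`` annotated
    genes lie between them.  Components of size >= 2 are reported in
    coordinate order; output is invariant to gene input order and to
    identity-matrix row permutations.
    """
    coords = {g.gene_id: g for g in annotation}
    for gid in identity.index:
        if gid not in coords:
            raise KeyError(f"gene {gid!r} in identity matrix missing from annotation")

    by_scaffold: dict[str, list] = {}
    for g in annotation:
        by_scaffold.setdefault(g.chrom, []).append(g)
    for genes in by_scaffold.values():
        genes.sort(key=lambda g: (g.start, g.gene_id))

    graph = nx.Graph()
    for scaffold, genes in by_scaffold.items():
        ids = [g.gene_id for g in genes]
        rank = {gid: i for i, gid in enumerate(ids)}
        present = [gid for gid in ids if gid in identity.index]
        for i, ga in enumerate(present):
            for gb in present[i + 1 :]:
                if abs(rank[ga] - rank[gb]) - 1 > max_intervening:
                    continue
                ident = float(identity.at[ga, gb])
                if ident >= identity_threshold:
                    graph.add_edge(ga, gb, identity=ident)

    clusters = []
    for comp in nx.connected_components(graph):
        if len(comp) < 2:
            continue
        members = sorted(comp, key=lambda gid: (coords[gid].start, gid))
        scaffold = coords[members[0]].chrom
        idents = [
            graph.edges[e]["identity"]
            for e in graph.subgraph(comp).edges
        ]
        clusters.append(
            TandemCluster(
                scaffold=scaffold,
                gene_ids=tuple(members),
                min_identity=min(idents),
            )
        )
    clusters.sort(key=lambda c: (c.scaffold, c.gene_ids))
    return clusters
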