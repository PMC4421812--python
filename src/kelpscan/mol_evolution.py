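"""Pairwise distances, Jukes-Cantor correction, TE insertion ages, NG86 Ka/Ks.

The Jukes-Cantor one-parameter correction d = -(3/4) ln(1 - (4/3) p) turns
the observed proportion of differing aligned columns p into an expected
number of substitutions per site; applied to repeat copies aligned against
their family consensus, d serves as a relative insertion age.  Ka/Ks uses
the classical Nei-Gojobori (1986) counting method under the universal code:
synonymous/nonsynonymous site counts averaged over the two sequences,
multi-position codon differences averaged over all substitution orderings
that avoid stop codons, and JC correction of the resulting proportions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

GAP_CHARS = set("-.")
VALID_BASES = set("ACGT")

_STOPS = set(standard_dna_table.stop_codons)
_CODON_TO_AA = dict(standard_dna_table.forward_table)

JC_SATURATION = 0.75


def p_distance(aligned_a: str, aligned_b: str) -> float:
    """Proportion of differing columns, excluding gap/ambiguity columns.

    Returns NaN when no comparable column exists.
    """
    if len(aligned_a) != len(aligned_b):
        raise ValueError("aligned sequences must have equal length")
    compared = 0
    diffs = 0
    for x, y in zip(aligned_a.upper(), aligned_b.upper()):
        if x not in VALID_BASES or y not in VALID_BASES:
            continue
        compared += 1
        if x != y:
            diffs += 1
    if compared == 0:
        return float("nan")
    return diffs / compared


def jc_distance(p: float) -> float:
    """Jukes-Cantor corrected distance -(3/4) ln(1 - (4/3) p)."""
    if p < 0:
        raise ValueError("p must be >= 0")
    if p >= JC_SATURATION:
        raise ValueError(f"saturated distance: p={p} >= {JC_SATURATION}")
    if p == 0:
        return 0.0
    return -0.75 * math.log1p(-p / 0.75)


def jc_p_from_d(d: float) -> float:
    """Inverse of jc_distance: expected p = (3/4)(1 - exp(-4d/3))."""
    if d < 0:
        raise ValueError("d must be >= 0")
    return 0.75 * (1.0 - math.exp(-4.0 * d / 3.0))


@dataclass
class RepeatCopyAlignment:
    """One repeat copy aligned to its family consensus."""

    copy_id: str
    family_id: str
    aligned_copy: str
    aligned_consensus: str

    def __post_init__(self) -> None:
        if len(self.aligned_copy) != len(self.aligned_consensus):
            raise ValueError("aligned copy and consensus lengths differ")

    @property
    def p(self) -> float:
        return p_distance(self.aligned_copy, self.aligned_consensus)

    @property
    def d(self) -> float:
        """JC distance; inf when saturated (p >= 3/4), NaN when p undefined."""
        p = self.p
        if math.isnan(p):
            return float("nan")
        if p >= JC_SATURATION:
            return float("inf")
        return jc_distance(p)


def te_age_distribution(
    copy_alignments: list[RepeatCopyAlignment], bin_width: float = 0.01
) -> pd.DataFrame:
    """Per-family histogram of JC ages: counts of copies with d in [k*w, (k+1)*w).

    Saturated copies (p >= 3/4) land in an overflow row with bin_low = inf.
    Copies with undefined p are ignored.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    rows: list[dict] = []
    by_family: dict[str, list[float]] = {}
    overflow: dict[str, int] = {}
    for aln in copy_alignments:
        d = aln.d
        if math.isnan(d):
            continue
        if math.isinf(d):
            overflow[aln.family_id] = overflow.get(aln.family_id, 0) + 1
            by_family.setdefault(aln.family_id, [])
            continue
        by_family.setdefault(aln.family_id, []).append(d)
    for family in sorted(by_family):
        ds = by_family[family]
        if ds:
            n_bins = int(max(ds) // bin_width) + 1
            counts = np.zeros(n_bins, dtype=int)
            for d in ds:
                counts[int(d // bin_width)] += 1
            for k, c in enumerate(counts):
                if c:
                    rows.append(
                        dict(
                            family=family,
                            bin_low=k * bin_width,
                            bin_high=(k + 1) * bin_width,
                            count=int(c),
                        )
                    )
    for family, c in sorted(overflow.items()):
        rows.append(
            dict(family=family, bin_low=float("inf"), bin_high=float("inf"), count=c)
        )
    return pd.DataFrame(rows, columns=["family", "bin_low", "bin_high", "count"])


# ---------------------------------------------------------------------------
# NG86 Ka/Ks


@dataclass(frozen=True)
class CodonAlignmentPair:
    """Two gapless, in-frame nucleotide sequences without internal stops."""

    seq_a: str
    seq_b: str

    def __post_init__(self) -> None:
        a, b = self.seq_a.upper(), self.seq_b.upper()
        object.__setattr__(self, "seq_a", a)
        object.__setattr__(self, "seq_b", b)
        if len(a) != len(b):
            raise ValueError("sequences must have equal length")
        if len(a) % 3 != 0:
            raise ValueError("length must be divisible by 3")
        for s in (a, b):
            if set(s) - VALID_BASES:
                raise ValueError("sequences must be gapless A/C/G/T")
            for i in range(0, len(s), 3):
                if s[i : i + 3] in _STOPS:
                    raise ValueError(f"internal stop codon at position {i}")

    @property
    def n_codons(self) -> int:
        return len(self.seq_a) // 3


def _codon_syn_sites(codon: str) -> float:
    """Synonymous site count of one codon (changes to stops count as nonsynonymous)."""
    aa = _CODON_TO_AA[codon]
    syn = 0
    for pos in range(3):
        for alt in "ACGT":
            if alt == codon[pos]:
                continue
            mutant = codon[:pos] + alt + codon[pos + 1 :]
            if mutant not in _STOPS and _CODON_TO_AA[mutant] == aa:
                syn += 1
    return syn / 3.0


def _codon_path_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Average (syn, nonsyn) difference counts over stop-free substitution orderings."""
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return 0.0, 0.0
    paths: list[tuple[int, int]] = []
    for order in permutations(diff_pos):
        current = codon_a
        sd = nd = 0
        valid = True
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if nxt in _STOPS:
                valid = False
                break
            if _CODON_TO_AA[current] == _CODON_TO_AA[nxt]:
                sd += 1
            else:
                nd += 1
            current = nxt
        if valid:
            paths.append((sd, nd))
    if not paths:
        # every ordering passes through a stop; count all changes as nonsynonymous
        return 0.0, float(len(diff_pos))
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


@dataclass(frozen=True)
class KaKsResult:
    ka: float
    ks: float
    s_sites: float
    n_sites: float
    sd: float
    nd: float


def ng86_ka_ks(pair: CodonAlignmentPair) -> KaKsResult:
    """Nei-Gojobori (1986) Ka/Ks with Jukes-Cantor correction.

    Raises ValueError when ps or pn reaches JC saturation (>= 3/4).
    """
    s_sites = 0.0
    sd = nd = 0.0
    for i in range(0, len(pair.seq_a), 3):
        ca = pair.seq_a[i : i + 3]
        cb = pair.seq_b[i : i + 3]
        s_sites += (_codon_syn_sites(ca) + _codon_syn_sites(cb)) / 2.0
        d_s, d_n = _codon_path_differences(ca, cb)
        sd += d_s
        nd += d_n
    total_sites = 3.0 * pair.n_codons
    n_sites = total_sites - s_sites
    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    if ps >= JC_SATURATION:
        raise ValueError(f"synonymous proportion saturated: ps={ps:.4f}")
    if pn >= JC_SATURATION:
        raise ValueError(f"nonsynonymous proportion saturated: pn={pn:.4f}")
    return KaKsResult(
        ka=jc_distance(pn),
        ks=jc_distance(ps),
        s_sites=s_sites,
        n_sites=n_sites,
        sd=sd,
        nd=nd,
    )


def percent_identity(aligned_a: str, aligned_b: str) -> float:
    """Matches / columns, excluding terminal gap columns; internal gaps mismatch."""
    if len(aligned_a) != len(aligned_b):
        raise ValueError("aligned sequences must have equal length")
    if len(aligned_a) == 0:
        raise ValueError("empty alignment")
    a, b = aligned_a.upper(), aligned_b.upper()

    def core(s: str) -> tuple[int, int]:
        i, j = 0, len(s)
        while i < j and s[i] in GAP_CHARS:
            i += 1
        while j > i and s[j - 1] in GAP_CHARS:
            j -= 1
        return i, j

    ia, ja = core(a)
    ib, jb = core(b)
    start, end = max(ia, ib), min(ja, jb)
    if start >= end:
        raise ValueError("no aligned core after trimming terminal gaps")
    matches = sum(
        1
        for x, y in zip(a[start:end], b[start:end])
        if x == y and x not in GAP_CHARS
    )
    return matches / (end - start)
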