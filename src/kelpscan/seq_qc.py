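"""GC content, six-frame ORF density and the bacterial-contamination filter.

Candidate bacterial contigs (assigned by upstream homology search, consumed
here as hints) are removed when their ORF density is >= 60% or their GC
content is biased (> 60% or < 40%); authentic and unknown contigs are never
removed.  ORF density is the unioned length of ATG-to-stop open reading
frames across all six frames divided by contig length, so it can never
exceed 1.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

logger = logging.getLogger("kelpscan")

_STOPS = {"TAA", "TAG", "TGA"}
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

HINTS = ("candidate_bacterial", "authentic", "unknown")


def gc_content(sequence: str) -> float:
    """(G+C) / (A+C+G+T); ambiguity characters excluded from the denominator."""
    seq = sequence.upper()
    gc = seq.count("G") + seq.count("C")
    at = seq.count("A") + seq.count("T")
    if gc + at == 0:
        return float("nan")
    return gc / (gc + at)


def _orf_spans_forward(seq: str, min_orf_len: int, stop_to_stop: bool) -> list[tuple[int, int]]:
    """ATG-to-stop (or stop-to-stop) spans on the forward strand, all 3 frames."""
    n = len(seq)
    spans = []
    for frame in range(3):
        segment_start = frame  # start of current inter-stop segment
        i = frame
        while i + 3 <= n:
            codon = seq[i : i + 3]
            if codon in _STOPS:
                stop_end = i + 3
                if stop_to_stop:
                    begin = segment_start
                else:
                    begin = _first_atg(seq, segment_start, i)
                if begin is not None and stop_end - begin >= min_orf_len:
                    spans.append((begin, stop_end))
                segment_start = stop_end
            i += 3
    return spans


def _first_atg(seq: str, start: int, limit: int) -> int | None:
    i = start
    while i < limit:  # codons between segment start and the stop codon
        if seq[i : i + 3] == "ATG":
            return i
        i += 3
    return None


def _union_length(spans: list[tuple[int, int]]) -> int:
    if not spans:
        return 0
    spans = sorted(spans)
    total = 0
    cur_start, cur_end = spans[0]
    for s, e in spans[1:]:
        if s <= cur_end:
            cur_end = max(cur_end, e)
        else:
            total += cur_end - cur_start
            cur_start, cur_end = s, e
    total += cur_end - cur_start
    return total


def orf_density(sequence: str, min_orf_len: int = 300, stop_to_stop: bool = False) -> float:
    """Unioned ORF length / contig length over all six reading frames.

    An ORF is an ATG..stop span (stop codon included) of length >=
    ``min_orf_len``; ``stop_to_stop=True`` instead takes whole inter-stop
    segments.  Reverse-strand spans are mapped back to contig coordinates
    before the union.
    """
    seq = sequence.upper()
    n = len(seq)
    if n < 3:
        raise ValueError("sequence must be at least 3 nt")
    spans = _orf_spans_forward(seq, min_orf_len, stop_to_stop)
    rc = seq.translate(_COMPLEMENT)[::-1]
    for s, e in _orf_spans_forward(rc, min_orf_len, stop_to_stop):
        spans.append((n - e, n - s))
    return _union_length(spans) / n


@dataclass
class ContigRecord:
    contig_id: str
    sequence: str
    taxonomy_hint: str = "unknown"
    gc: float = float("nan")
    orf_dens: float = float("nan")
    filtered: bool = False

    def __post_init__(self) -> None:
        if self.taxonomy_hint not in HINTS:
            raise ValueError(f"taxonomy_hint must be one of {HINTS}")


def filter_contigs(
    contigs: list[ContigRecord],
    orf_cut: float = 0.60,
    gc_low: float = 0.40,
    gc_high: float = 0.60,
    min_orf_len: int = 300,
) -> tuple[list[ContigRecord], list[ContigRecord]]:
    """Partition contigs into (kept, removed) under the contamination rule.

    A contig is removed iff its hint is candidate_bacterial AND
    (ORF density >= orf_cut  OR  gc > gc_high  OR  gc < gc_low).
    The ORF-density bound is inclusive and the GC bounds are strict,
    mirroring the ">= 60%" / "> 60 or < 40%" semantics.  Pure function of
    (hint, gc, orf_density): permutation-invariant and idempotent.
    """
    kept, removed = [], []
    for contig in contigs:
        contig.gc = gc_content(contig.sequence)
        contig.orf_dens = orf_density(contig.sequence, min_orf_len=min_orf_len)
        biased = (
            contig.orf_dens >= orf_cut
            or (not math.isnan(contig.gc) and (contig.gc > gc_high or contig.gc < gc_low))
        )
        contig.filtered = contig.taxonomy_hint == "candidate_bacterial" and biased
        (removed if contig.filtered else kept).append(contig)
    logger.info(
        "filter_contigs: kept %d, removed %d of %d contigs",
        len(kept), len(removed), len(contigs),
    )
    return kept, removed
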