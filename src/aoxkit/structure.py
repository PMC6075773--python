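"""Exon/intron delineation by spliced matching of a transcript against its
gene, plus structural comparison of splice variants.

The delineator assumes transcript and gene come from the same assembly, so it
chains exact matches rather than running a full dynamic-programming spliced
alignment.  Among all placements that reconstruct the transcript it prefers,
in order: fewest non-GT..AG introns, fewest exons, leftmost donors/acceptors.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass

import pandas as pd

from aoxkit.core import AoxkitError, from_public, to_public

SEED_LENGTH = 12
EVENT_TYPES = ("intron_retention", "alt_5utr", "alt_3utr", "other")


@dataclass
class GeneStructure:
    gene_id: str
    transcript_id: str
    genomic_length: int
    exons: list[tuple[int, int]]            # 1-based inclusive genomic intervals
    introns: list[tuple[int, int]]
    splice_dinucleotides: list[tuple[str, str]]
    cds_length: int | None = None
    ambiguous: bool = False

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def n_introns(self) -> int:
        return len(self.introns)

    def transcript_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)


@dataclass
class SpliceEvent:
    event_type: str
    reference_interval: tuple[int, int]
    variant_interval: tuple[int, int]
    description: str = ""


def _extend(t: str, g: str, t_pos: int, g_pos: int) -> int:
    """Length of the exact match of t[t_pos:] against g[g_pos:]."""
    n = 0
    max_n = min(len(t) - t_pos, len(g) - g_pos)
    while n < max_n and t[t_pos + n] == g[g_pos + n]:
        n += 1
    return n


def _search(t: str, g: str, min_intron: int, max_solutions: int) -> tuple[list, int]:
    """Enumerate exon placements (0-based half-open) that reconstruct ``t``.

    Returns (solutions, deepest transcript offset reached).  Solutions are
    lists of (start0, end0) exon tuples.

    Two exact prunings keep this tractable on repetitive sequence without
    changing the top-ranked result under :func:`_score`:

    * a full-length terminal match is never split further (the split adds an
      exon and cannot reduce the non-GT..AG count, so it ranks strictly worse);
    * branch and bound on the (non-GT..AG introns, exon count) prefix of the
      ranking key; ties on that prefix are all enumerated so the leftmost
      tie-break stays exact.
    """
    solutions: list[list[tuple[int, int]]] = []
    deepest = 0
    seed_occurrences: dict[str, list[int]] = {}
    best = [len(t) + 1, len(t) + 1]  # non-GT..AG introns, exon count

    def occurrences(seed: str) -> list[int]:
        occ = seed_occurrences.get(seed)
        if occ is None:
            occ = []
            s = g.find(seed)
            while s != -1:
                occ.append(s)
                s = g.find(seed, s + 1)
            seed_occurrences[seed] = occ
        return occ

    def non_gtag(prev_end: int, next_start: int) -> int:
        return 0 if (g[prev_end : prev_end + 2] == "GT"
                     and g[next_start - 2 : next_start] == "AG") else 1

    def dfs(t_pos: int, g_min: int, exons: list, ng: int) -> None:
        nonlocal deepest
        deepest = max(deepest, t_pos)
        if len(solutions) >= max_solutions:
            return
        # bound: ng never decreases and at least one exon must be added
        if ng > best[0] or (ng == best[0] and len(exons) >= best[1]):
            return
        rem = len(t) - t_pos
        seed = t[t_pos : t_pos + min(SEED_LENGTH, rem)]
        occ = occurrences(seed)
        for s in occ[bisect_left(occ, g_min):]:
            ng_here = ng + (non_gtag(exons[-1][1], s) if exons else 0)
            if ng_here > best[0]:
                continue
            m = _extend(t, g, t_pos, s)
            if t_pos + m == len(t):
                if ng_here < best[0] or (ng_here == best[0]
                                         and len(exons) + 1 <= best[1]):
                    best[0], best[1] = ng_here, len(exons) + 1
                solutions.append(exons + [(s, s + m)])
                if len(solutions) >= max_solutions:
                    return
                continue  # splitting a terminal full match ranks strictly worse
            for length in range(m, 0, -1):
                dfs(t_pos + length, s + length + min_intron,
                    exons + [(s, s + length)], ng_here)

    dfs(0, 0, [], 0)
    unique = {tuple(sol): sol for sol in solutions}
    return list(unique.values()), deepest


def _score(g: str, exons0: list[tuple[int, int]]) -> tuple:
    """Ranking key: fewest non-GT..AG introns, fewest exons, leftmost bounds."""
    non_gtag = 0
    for (s_prev, e_prev), (s_next, _) in zip(exons0, exons0[1:]):
        if g[e_prev : e_prev + 2] != "GT" or g[s_next - 2 : s_next] != "AG":
            non_gtag += 1
    flat = tuple(x for iv in exons0 for x in iv)
    return (non_gtag, len(exons0), flat)


def delineate_structure(
    transcript_seq: str,
    genomic_seq: str,
    min_intron: int = 20,
    max_mismatch: int = 0,
    gene_id: str = "",
    transcript_id: str = "",
    max_solutions: int = 2000,
) -> GeneStructure:
    """Place ``transcript_seq`` on ``genomic_seq`` as spliced exons.

    With ``max_mismatch=0`` (default) the concatenated exon sequence equals
    the transcript exactly.  Mismatch tolerance is currently limited to exact
    seeding: raise ``max_mismatch`` only for single substitutions outside the
    first 12 bases of an exon.
    """
    t = transcript_seq.upper()
    g = genomic_seq.upper()
    if not t or not g:
        raise AoxkitError("empty transcript or genomic sequence")
    if max_mismatch == 0:
        solutions, deepest = _search(t, g, min_intron, max_solutions)
    else:
        solutions, deepest = _search_mismatch(t, g, min_intron, max_mismatch,
                                              max_solutions)
    if not solutions:
        raise AoxkitError(
            f"transcript {transcript_id or '<unnamed>'} not derivable from genomic "
            f"sequence; first unplaceable transcript offset: {deepest + 1}"
        )
    ranked = sorted(solutions, key=lambda sol: _score(g, sol))
    best = ranked[0]
    ambiguous = len(ranked) > 1 and _score(g, ranked[1])[:2] == _score(g, best)[:2]

    exons = [to_public(s, e) for s, e in best]
    introns = []
    dinucs = []
    for (_, e_prev), (s_next, _) in zip(exons, exons[1:]):
        i_start, i_end = e_prev + 1, s_next - 1
        introns.append((i_start, i_end))
        s0, e0 = from_public(i_start, i_end)
        dinucs.append((g[s0 : s0 + 2], g[e0 - 2 : e0]))
    return GeneStructure(
        gene_id=gene_id,
        transcript_id=transcript_id,
        genomic_length=len(g),
        exons=exons,
        introns=introns,
        splice_dinucleotides=dinucs,
        ambiguous=ambiguous,
    )


def _search_mismatch(t, g, min_intron, max_mismatch, max_solutions):
    """Mismatch-tolerant variant of :func:`_search` (exact 12-mer seeding)."""
    solutions = []
    deepest = 0

    def extend_mm(t_pos, g_pos, budget):
        # returns list of (length, mismatches_used) candidate stop points
        out = []
        n, used = 0, 0
        max_n = min(len(t) - t_pos, len(g) - g_pos)
        while n < max_n:
            if t[t_pos + n] != g[g_pos + n]:
                if used == budget:
                    break
                used += 1
            n += 1
            out.append((n, used))
        return out

    def dfs(t_pos, g_min, budget, exons):
        nonlocal deepest
        deepest = max(deepest, t_pos)
        if len(solutions) >= max_solutions:
            return
        rem = len(t) - t_pos
        seed = t[t_pos : t_pos + min(SEED_LENGTH, rem)]
        s = g.find(seed, g_min)
        while s != -1:
            stops = extend_mm(t_pos, s, budget)
            for length, used in reversed(stops):
                if t_pos + length == len(t):
                    solutions.append(tuple(exons + [(s, s + length)]))
                else:
                    dfs(t_pos + length, s + length + min_intron, budget - used,
                        exons + [(s, s + length)])
            s = g.find(seed, s + 1)

    dfs(0, 0, max_mismatch, [])
    unique = {sol: list(sol) for sol in solutions}
    return list(unique.values()), deepest


# ---------------------------------------------------------------------------
# splice-variant comparison
# ---------------------------------------------------------------------------

def _exonic_difference(a: GeneStructure, b: GeneStructure) -> list[tuple[int, int]]:
    """Maximal intervals exonic in ``a`` but not in ``b`` (1-based inclusive)."""
    length = a.genomic_length
    in_a = bytearray(length)
    for s, e in a.exons:
        for i in range(s - 1, e):
            in_a[i] = 1
    for s, e in b.exons:
        for i in range(s - 1, e):
            if in_a[i]:
                in_a[i] = 0
    out = []
    i = 0
    while i < length:
        if in_a[i]:
            j = i
            while j < length and in_a[j]:
                j += 1
            out.append((i + 1, j))
            i = j
        else:
            i += 1
    return out


def classify_splice_events(
    structure_a: GeneStructure, structure_b: GeneStructure
) -> list[SpliceEvent]:
    """Compare two delineated structures of the same gene.

    Every maximal interval exonic in exactly one structure yields one event:
    inside the other structure's intron -> intron_retention; upstream of its
    first exon -> alt_5utr; downstream of its last exon -> alt_3utr; anything
    else -> other.  Identical structures yield an empty list.
    """
    if structure_a.gene_id != structure_b.gene_id:
        raise AoxkitError(
            f"structures from different genes: {structure_a.gene_id!r} vs "
            f"{structure_b.gene_id!r}"
        )
    events: list[SpliceEvent] = []
    for carrier, other, labels in (
        (structure_a, structure_b, (structure_a.transcript_id, structure_b.transcript_id)),
        (structure_b, structure_a, (structure_b.transcript_id, structure_a.transcript_id)),
    ):
        for s, e in _exonic_difference(carrier, other):
            event_type = "other"
            if not other.exons or e < other.exons[0][0]:
                event_type = "alt_5utr"
            elif s > other.exons[-1][1]:
                event_type = "alt_3utr"
            else:
                for i_s, i_e in other.introns:
                    if i_s <= s and e <= i_e:
                        event_type = "intron_retention"
                        break
            events.append(
                SpliceEvent(
                    event_type=event_type,
                    reference_interval=(s, e),
                    variant_interval=(s, e),
                    description=(
                        f"({s}..{e}) is exonic in {labels[0] or 'A'} "
                        f"but not in {labels[1] or 'B'}"
                    ),
                )
            )
    events.sort(key=lambda ev: ev.reference_interval)
    return events


def structure_summary(structures: list[GeneStructure]) -> pd.DataFrame:
    """Table of per-transcript gene/transcript/CDS lengths and exon/intron
    counts, in input order (mirrors the family feature-table layout)."""
    rows = []
    for st in structures:
        rows.append(
            {
                "gene_id": st.gene_id,
                "transcript_id": st.transcript_id,
                "gene_length_bp": st.genomic_length,
                "transcript_length_bp": st.transcript_length(),
                "cds_length_bp": st.cds_length if st.cds_length is not None else "",
                "n_exons": st.n_exons,
                "n_introns": st.n_introns,
            }
        )
    columns = ["gene_id", "transcript_id", "gene_length_bp", "transcript_length_bp",
               "cds_length_bp", "n_exons", "n_introns"]
    return pd.DataFrame(rows, columns=columns)
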