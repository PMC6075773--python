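"""Degenerate-motif scanning and CpG-island detection on promoters and gene
bodies.

Scanning semantics: a window matches an IUPAC pattern when every non-N pattern
position's base set contains the window base, allowing up to ``max_mismatch``
violations; N positions never count as mismatches.  Minus-strand hits are
found by matching the reverse complement of the pattern and are reported in
plus-strand coordinates of the scanned sequence.

CpG island semantics follow the classic windowed observed/expected method:
for every window of ``window`` bp (step 1), GC% and obs/exp CpG
``(#CG * window) / (#C * #G)`` are attributed to the window midpoint
(``start + window//2``); islands are maximal runs of at least ``min_len``
qualifying midpoints.  With the default window of 100 this puts the first
possible island base at position 51, matching the reporting convention of the
reference tool.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from aoxkit.core import AoxkitError
from aoxkit.catalogs import IUPAC_SETS, RegulatorMotif, validate_iupac

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass
class MotifHit:
    motif_name: str
    start: int            # 1-based position on the scanned (+) sequence
    strand: str           # "+" or "-"
    matched_text: str     # plus-strand text of the matched window
    mismatches: int


@dataclass
class CpGIsland:
    start: int
    end: int
    length: int
    mean_gc: float     # percent
    mean_oe: float


@dataclass
class ElementTally:
    category: str
    motif_names: list[str]
    count: int


def _window_mismatches(window: str, pattern: str, limit: int) -> int | None:
    """Mismatch count of window vs IUPAC pattern, or None if above limit."""
    n = 0
    for base, pat in zip(window, pattern):
        if pat == "N":
            continue
        if base not in IUPAC_SETS[pat]:
            n += 1
            if n > limit:
                return None
    return n


def scan_iupac(
    seq: str,
    pattern: str,
    max_mismatch: int = 0,
    strands: str = "+-",
    motif_name: str = "",
) -> list[MotifHit]:
    """All (overlapping) hits of an IUPAC pattern, sorted by start then strand."""
    validate_iupac(pattern, motif_name or pattern)
    if max_mismatch < 0:
        raise AoxkitError("max_mismatch must be >= 0")
    bad = set(strands) - {"+", "-"}
    if bad:
        raise AoxkitError(f"invalid strand(s) {sorted(bad)}")
    seq = seq.upper()
    pattern = pattern.upper()
    name = motif_name or pattern
    hits: list[MotifHit] = []
    plans = []
    if "+" in strands:
        plans.append(("+", pattern))
    if "-" in strands:
        plans.append(("-", revcomp(pattern)))
    for strand, pat in plans:
        for i in range(len(seq) - len(pat) + 1):
            window = seq[i : i + len(pat)]
            mm = _window_mismatches(window, pat, max_mismatch)
            if mm is not None:
                hits.append(MotifHit(name, i + 1, strand, window, mm))
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def classify_deviation(hit: MotifHit, stringent_pattern: str) -> dict:
    """Deviation of a hit from a stringent same-length pattern.

    Counts the non-N stringent positions whose IUPAC set excludes the matched
    base; flags single-deviation hits with the 1-based site index.  Minus
    strand hits are compared on the motif strand.
    """
    validate_iupac(stringent_pattern)
    stringent = stringent_pattern.upper()
    if len(hit.matched_text) != len(stringent):
        raise AoxkitError(
            f"pattern length mismatch: hit {len(hit.matched_text)} vs "
            f"stringent {len(stringent)}"
        )
    text = hit.matched_text if hit.strand == "+" else revcomp(hit.matched_text)
    sites = [
        i
        for i, (base, pat) in enumerate(zip(text, stringent), 1)
        if pat != "N" and base not in IUPAC_SETS[pat]
    ]
    return {
        "deviation": len(sites),
        "site": sites[0] if len(sites) == 1 else None,
    }


def tally_elements(
    promoter_seq: str,
    regulator_motifs: list[RegulatorMotif],
    categories: list[str] | None = None,
    strands: str = "+-",
) -> list[ElementTally]:
    """Per-category totals of regulator-motif hits at zero mismatches."""
    known = set(categories) if categories is not None else None
    by_category: dict[str, ElementTally] = {}
    for motif in regulator_motifs:
        n = len(scan_iupac(promoter_seq, motif.pattern, 0, strands, motif.name))
        for cat in motif.categories:
            if known is not None and cat not in known:
                raise AoxkitError(
                    f"motif {motif.name!r} references unknown category {cat!r}"
                )
            tally = by_category.setdefault(cat, ElementTally(cat, [], 0))
            tally.motif_names.append(motif.name)
            tally.count += n
    return [by_category[c] for c in sorted(by_category)]


def find_cpg_islands(
    seq: str,
    window: int = 100,
    min_len: int = 200,
    oe_threshold: float = 0.6,
    gc_threshold: float = 50.0,
) -> list[CpGIsland]:
    """Windowed CpG-island finder (see module docstring for conventions)."""
    seq = seq.upper()
    if len(seq) < window:
        warnings.warn(
            f"sequence ({len(seq)} bp) shorter than window ({window} bp); "
            "no islands can be reported",
            stacklevel=2,
        )
        return []
    n_windows = len(seq) - window + 1

    # rolling counts of C, G and CG dinucleotides per window
    is_c = [1 if b == "C" else 0 for b in seq]
    is_g = [1 if b == "G" else 0 for b in seq]
    is_cg = [1 if seq[i : i + 2] == "CG" else 0 for i in range(len(seq) - 1)]

    c = sum(is_c[:window])
    g = sum(is_g[:window])
    cg = sum(is_cg[: window - 1])  # CG dinucleotides fully inside the window

    qualifying: list[bool] = []
    stats: list[tuple[float, float]] = []
    for i in range(n_windows):
        if i > 0:
            c += is_c[i + window - 1] - is_c[i - 1]
            g += is_g[i + window - 1] - is_g[i - 1]
            cg += is_cg[i + window - 2] - is_cg[i - 1]
        gc_pct = 100.0 * (c + g) / window
        oe = (cg * window) / (c * g) if c and g else 0.0
        stats.append((gc_pct, oe))
        qualifying.append(gc_pct > gc_threshold and oe > oe_threshold)

    midpoint_offset = window // 2  # window starting at base i+1 -> position i+1+window//2
    islands: list[CpGIsland] = []
    i = 0
    while i < n_windows:
        if qualifying[i]:
            j = i
            while j < n_windows and qualifying[j]:
                j += 1
            run_len = j - i
            if run_len >= min_len:
                run_stats = stats[i:j]
                islands.append(
                    CpGIsland(
                        start=i + 1 + midpoint_offset,
                        end=j + midpoint_offset,
                        length=run_len,
                        mean_gc=sum(s[0] for s in run_stats) / run_len,
                        mean_oe=sum(s[1] for s in run_stats) / run_len,
                    )
                )
            i = j
        else:
            i += 1
    return islands
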