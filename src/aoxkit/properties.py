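"""Protein physical properties: length, average molecular weight, theoretical
isoelectric point and amino-acid composition.

The pI model is the standard Henderson-Hasselbalch net-charge sum over the
termini and the ionizable side chains (K, R, H, D, E, C, Y), solved by
bisection.  Three selectable pKa sets ship with the package (EMBOSS default,
Lehninger, Sillero); results are tagged with the set used because the choice
shifts pI by a bounded but visible amount.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from aoxkit.core import AoxkitError, AMINO_ACIDS

# average (not monoisotopic) residue masses, Da
AVERAGE_RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER_MASS = 18.01524

# pKa sets: N-terminus, C-terminus and ionizable side chains
PKA_SETS: dict[str, dict[str, float]] = {
    "emboss": {
        "Nterm": 8.6, "Cterm": 3.6,
        "K": 10.8, "R": 12.5, "H": 6.5, "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1,
    },
    "lehninger": {
        "Nterm": 9.69, "Cterm": 2.34,
        "K": 10.53, "R": 12.48, "H": 6.0, "D": 3.65, "E": 4.25, "C": 8.33,
        "Y": 10.07,
    },
    "sillero": {
        "Nterm": 8.2, "Cterm": 3.2,
        "K": 10.4, "R": 12.0, "H": 6.4, "D": 4.0, "E": 4.5, "C": 9.0, "Y": 10.0,
    },
}
POSITIVE_GROUPS = ("K", "R", "H")
NEGATIVE_GROUPS = ("D", "E", "C", "Y")


@dataclass
class ProteinProperties:
    isoform_id: str
    length: int
    mw_kda: float       # 1 decimal, round-half-even
    pi: float           # 2 decimals
    composition: dict[str, int]
    pka_set: str


def _check_sequence(protein_seq: str, allow_x: bool = False) -> str:
    seq = protein_seq.upper().rstrip("*")
    allowed = AMINO_ACIDS | ({"X"} if allow_x else set())
    bad = set(seq) - allowed
    if bad:
        raise AoxkitError(f"unknown residue letter(s) {sorted(bad)}")
    if not seq:
        raise AoxkitError("empty protein sequence")
    return seq


def compute_mw(protein_seq: str) -> float:
    """Average molecular weight in Da: sum of residue masses plus one water."""
    seq = _check_sequence(protein_seq)
    return sum(AVERAGE_RESIDUE_MASS[a] for a in seq) + WATER_MASS


def net_charge(protein_seq: str, pH: float, pka_set: str | dict = "emboss") -> float:
    """Signed net charge at a pH.

    Positive groups contribute ``1/(1+10^(pH-pKa))``, negative groups
    ``-1/(1+10^(pKa-pH))``, summed over the termini and ionizable side chains.
    """
    seq = _check_sequence(protein_seq, allow_x=True)
    pkas = PKA_SETS[pka_set] if isinstance(pka_set, str) else pka_set
    for key in ("Nterm", "Cterm"):
        if key not in pkas:
            raise AoxkitError(f"pKa set missing entry {key!r}")
    counts = Counter(seq)
    charge = 1.0 / (1.0 + 10 ** (pH - pkas["Nterm"]))
    charge -= 1.0 / (1.0 + 10 ** (pkas["Cterm"] - pH))
    for aa in POSITIVE_GROUPS + NEGATIVE_GROUPS:
        n = counts.get(aa, 0)
        if not n:
            continue
        if aa not in pkas:
            raise AoxkitError(f"pKa set missing entry {aa!r}")
        if aa in POSITIVE_GROUPS:
            charge += n / (1.0 + 10 ** (pH - pkas[aa]))
        else:
            charge -= n / (1.0 + 10 ** (pkas[aa] - pH))
    return charge


def compute_pi(protein_seq: str, pka_set: str | dict = "emboss",
               tol: float = 0.001) -> float:
    """Bisection on [0, 14] for the pH of zero net charge."""
    lo, hi = 0.0, 14.0
    f_lo = net_charge(protein_seq, lo, pka_set)
    f_hi = net_charge(protein_seq, hi, pka_set)
    if f_lo <= 0 or f_hi >= 0:  # charge is strictly decreasing in pH
        raise AoxkitError("net charge does not bracket zero on [0, 14]")
    while hi - lo > tol:
        mid = (lo + hi) / 2.0
        if net_charge(protein_seq, mid, pka_set) > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def compute_properties(
    isoform_id: str, protein_seq: str, pka_set: str = "emboss"
) -> ProteinProperties:
    seq = _check_sequence(protein_seq)
    mw = compute_mw(seq)
    pi = compute_pi(seq, pka_set)
    comp = dict(sorted(Counter(seq).items()))
    props = ProteinProperties(
        isoform_id=isoform_id,
        length=len(seq),
        mw_kda=round(mw / 1000.0, 1),  # python round = round-half-even
        pi=round(pi, 2),
        composition=comp,
        pka_set=pka_set if isinstance(pka_set, str) else "custom",
    )
    assert props.length == sum(props.composition.values())
    return props


def properties_table(records: list[tuple[str, str]], pka_set: str = "emboss"):
    """Rows mirroring the family property table: id, length, MW (kDa), pI."""
    return [
        {
            "isoform_id": iso_id,
            "length_aa": (p := compute_properties(iso_id, seq, pka_set)).length,
            "mw_kda": p.mw_kda,
            "pi": p.pi,
        }
        for iso_id, seq in records
    ]
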