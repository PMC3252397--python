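"""Physicochemical characterization of proteins: length, molecular weight,
theoretical pI, and pairwise identity/similarity.

Molecular weight uses average (not monoisotopic) residue masses, the
convention under which ~16 kDa small heat-shock proteins are reported.
The theoretical pI follows the ProtParam convention: net charge from
Henderson-Hasselbalch over the termini and the ionizable side chains
(D, E, C, Y, H, K, R) with the Bjellqvist pKa set, solved by bisection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .sequences import PROTEIN_ALPHABET

#: Average residue (amino-acid minus water) masses in Da.
AVERAGE_RESIDUE_MASS: dict[str, float] = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER_MASS = 18.0153

#: Bjellqvist pKa values (the ProtParam set). Terminal pKas depend on the
#: terminal residue; unlisted residues take the generic value.
PKA_SIDECHAIN_NEGATIVE: dict[str, float] = {"D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0}
PKA_SIDECHAIN_POSITIVE: dict[str, float] = {"H": 5.98, "K": 10.0, "R": 12.0}
PKA_NTERM_GENERIC = 7.5
PKA_NTERM_BY_RESIDUE: dict[str, float] = {
    "A": 7.59, "M": 7.0, "S": 6.93, "P": 8.36, "T": 6.82, "V": 7.44, "E": 7.7,
}
PKA_CTERM_GENERIC = 3.55
PKA_CTERM_BY_RESIDUE: dict[str, float] = {"D": 4.55, "E": 4.75}


@dataclass(frozen=True)
class ProteinProperties:
    locus: str
    length_aa: int
    mw_da: float
    pi: float


@dataclass(frozen=True)
class SimilarityResult:
    locus_a: str
    locus_b: str
    identity_pct: float
    similarity_pct: float
    alignment_length: int


def _check_protein(seq: str) -> str:
    seq = seq.upper()
    if not seq:
        raise ValueError("empty protein sequence")
    bad = set(seq) - PROTEIN_ALPHABET
    if bad:
        raise ValueError(f"unknown residue(s) {sorted(bad)}; ambiguity codes unsupported")
    return seq


def molecular_weight(protein: str) -> float:
    """Average-isotopic molecular weight in Da: sum of residue masses plus
    one water."""
    protein = _check_protein(protein)
    return sum(AVERAGE_RESIDUE_MASS[aa] for aa in protein) + WATER_MASS


def net_charge(protein: str, ph: float) -> float:
    """Model net charge at a given pH (Henderson-Hasselbalch, Bjellqvist
    pKas). Strictly decreasing in pH."""
    protein = _check_protein(protein)

    def frac_positive(pka: float) -> float:
        return 1.0 / (1.0 + 10 ** (ph - pka))

    def frac_negative(pka: float) -> float:
        return -1.0 / (1.0 + 10 ** (pka - ph))

    charge = frac_positive(PKA_NTERM_BY_RESIDUE.get(protein[0], PKA_NTERM_GENERIC))
    charge += frac_negative(PKA_CTERM_BY_RESIDUE.get(protein[-1], PKA_CTERM_GENERIC))
    for aa, pka in PKA_SIDECHAIN_POSITIVE.items():
        charge += protein.count(aa) * frac_positive(pka)
    for aa, pka in PKA_SIDECHAIN_NEGATIVE.items():
        charge += protein.count(aa) * frac_negative(pka)
    return charge


def isoelectric_point(protein: str, tol: float = 1e-4) -> float:
    """pH at which the modeled net charge is zero, by bisection on [0, 14].

    The charge function is strictly monotone decreasing in pH, so the root
    is unique; bisection converges to ``tol`` pH units.
    """
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = (lo + hi) / 2
        if net_charge(protein, mid) > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def characterize(locus: str, protein: str) -> ProteinProperties:
    protein = _check_protein(protein)
    return ProteinProperties(
        locus=locus,
        length_aa=len(protein),
        mw_da=molecular_weight(protein),
        pi=isoelectric_point(protein),
    )


# ---------------------------------------------------------------------------
# Pairwise identity / similarity

GAP_OPEN = 10.0
GAP_EXTEND = 0.5


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -GAP_OPEN
    aligner.extend_gap_score = -GAP_EXTEND
    return aligner


def pairwise_identity_similarity(
    a: str, b: str, locus_a: str = "a", locus_b: str = "b"
) -> SimilarityResult:
    """Global alignment (BLOSUM62, gap open 10 / extend 0.5); identity is
    the fraction of identical alignment columns, similarity the fraction of
    columns whose substitution score is positive (gap columns count in the
    denominator only). Percentages are rounded to integers, matching how
    such values are conventionally reported.
    """
    a, b = _check_protein(a), _check_protein(b)
    aligner = _aligner()
    # co-optimal alignments can differ with argument order; align a
    # canonical ordering so the result is symmetric in (a, b)
    first, second = sorted((a, b))
    alignment = aligner.align(first, second)[0]
    row_a, row_b = str(alignment[0]), str(alignment[1])
    matrix = aligner.substitution_matrix
    ncols = len(row_a)
    ident = simil = 0
    for ca, cb in zip(row_a, row_b):
        if ca == "-" or cb == "-":
            continue
        if ca == cb:
            ident += 1
        if matrix[ca, cb] > 0:
            simil += 1
    return SimilarityResult(
        locus_a=locus_a,
        locus_b=locus_b,
        identity_pct=round(100 * ident / ncols),
        similarity_pct=round(100 * simil / ncols),
        alignment_length=ncols,
    )


PROPERTIES_COLUMNS = ["locus", "length_aa", "mw_da", "pi"]
PAIRWISE_COLUMNS = ["locus_a", "locus_b", "identity_pct", "similarity_pct", "alignment_length"]


def properties_table(props: Sequence[ProteinProperties]) -> pd.DataFrame:
    """Tabulate with report formatting: MW to the nearest Da, pI to 2 dp."""
    return pd.DataFrame(
        [
            {"locus": p.locus, "length_aa": p.length_aa,
             "mw_da": round(p.mw_da), "pi": f"{p.pi:.2f}"}
            for p in props
        ],
        columns=PROPERTIES_COLUMNS,
    )


def pairwise_table(proteins: Mapping[str, str]) -> pd.DataFrame:
    loci = list(proteins)
    rows = []
    for i, la in enumerate(loci):
        for lb in loci[i + 1 :]:
            r = pairwise_identity_similarity(proteins[la], proteins[lb], la, lb)
            rows.append(
                {"locus_a": la, "locus_b": lb, "identity_pct": int(r.identity_pct),
                 "similarity_pct": int(r.similarity_pct),
                 "alignment_length": r.alignment_length}
            )
    return pd.DataFrame(rows, columns=PAIRWISE_COLUMNS)
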