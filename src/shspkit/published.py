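"""Published reference values for the three *A. ferrooxidans* ATCC 23270
small heat-shock-protein genes (loci Afe_1009, Afe_1437, Afe_2172).

These are inputs taken from the literature record for this system — the
qRT-PCR primer pairs with their amplicon lengths, the reported protein
parameters, per-gene GC content and the reported heat-shock response —
kept in one place so analyses and simulations can use them as study
conditions. The genome itself is not redistributed here; analyses that
need the full sequences load them from a user-supplied FASTA (see
``data/reference/README`` in the repository).
"""

from __future__ import annotations

from .sequences import PrimerPair

SHSP_LOCI = ("Afe_1009", "Afe_1437", "Afe_2172")
REFERENCE_GENE = "alaS"

#: qRT-PCR primer pairs with their genomic amplicon lengths (bp).
PRIMER_PAIRS: dict[str, PrimerPair] = {
    "Afe_1009": PrimerPair("Afe_1009", "CCGAAATACCTGAGGTCAA", "TCCCTTTCTCCTCCTTCTCC", 91),
    "Afe_1437": PrimerPair("Afe_1437", "GTATTGAAGGCGGAGATTGC", "TCTTCTTCCTTGACGCCACT", 118),
    "Afe_2172": PrimerPair("Afe_2172", "AGGTAATCTTCAGCGGCAAC", "TAGGGGATCTCCAGACGATG", 97),
}

#: Reported protein parameters: length (aa), MW (Da), theoretical pI.
PROTEIN_PARAMS: dict[str, tuple[int, int, float]] = {
    "Afe_1009": (145, 16934, 6.20),
    "Afe_1437": (148, 16680, 5.43),
    "Afe_2172": (134, 16401, 5.60),
}

#: Reported pairwise identity/similarity percentages between the proteins.
PAIRWISE_ID_SIM: dict[tuple[str, str], tuple[int, int]] = {
    ("Afe_1009", "Afe_1437"): (29, 58),
    ("Afe_1009", "Afe_2172"): (26, 47),
    ("Afe_1437", "Afe_2172"): (22, 53),
}

#: Reported per-gene GC percentage of the CDS.
GC_PERCENT: dict[str, float] = {
    "Afe_1009": 47.71,
    "Afe_1437": 46.53,
    "Afe_2172": 58.76,
}

#: CDS length in nt implied by the protein length (3*(aa+1), stop included).
CDS_LENGTH_NT: dict[str, int] = {
    locus: 3 * (aa + 1) for locus, (aa, _, _) in PROTEIN_PARAMS.items()
}

#: Genome-average coding GC fraction for *A. ferrooxidans*.
GENOME_AVG_GC = 0.59

#: Reported 60-min heat-shock outcome: all three genes up-regulated
#: (p < 0.05, fold >= 2.0); Afe_1437 responds 20x more strongly than
#: Afe_2172 and 11.5x more strongly than Afe_1009. Anchoring the weakest
#: responder at the fold floor of 2.0 gives these fold changes.
HEAT_SHOCK_60MIN_FOLDS: dict[str, float] = {
    "Afe_1437": 40.0,
    "Afe_1009": 40.0 / 11.5,
    "Afe_2172": 2.0,
}
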