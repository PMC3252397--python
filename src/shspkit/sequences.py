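"""Sequence I/O and manipulation: FASTA, upstream-region extraction, translation, in-silico PCR.

All genomic coordinates exposed here are 1-based inclusive (GenBank
convention). Internally Python slices are used, but every reported position
is 1-based.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.Data import CodonTable

logger = logging.getLogger(__name__)

DNA_ALPHABET = set("ACGTN")
PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")

#: NCBI translation table 11 (bacterial/archaeal), used for all CDS translation.
BACTERIAL_TABLE = CodonTable.unambiguous_dna_by_id[11]


class SequenceError(ValueError):
    """Raised on malformed sequence input."""


class AmbiguousAmpliconError(ValueError):
    """A primer pair produces more than one amplicon (non-specific primers)."""

    def __init__(self, sites):
        self.sites = sites
        super().__init__(
            "primer pair is non-specific: %d productive amplicons at %s"
            % (len(sites), ", ".join(f"{strand}:{pos}(len {ln})" for strand, pos, ln in sites))
        )


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide or protein sequence.

    Sequences are stored uppercase; the alphabet is validated at
    construction time ({A,C,G,T,N} for DNA, the 20 standard residues for
    protein).
    """

    id: str
    seq: str
    alphabet: str = "dna"

    def __post_init__(self):
        if not self.id:
            raise SequenceError("sequence id must be non-empty")
        seq = self.seq.upper()
        object.__setattr__(self, "seq", seq)
        if not seq:
            raise SequenceError(f"{self.id}: sequence must be non-empty")
        allowed = DNA_ALPHABET if self.alphabet == "dna" else PROTEIN_ALPHABET
        if self.alphabet not in ("dna", "protein"):
            raise SequenceError(f"unknown alphabet {self.alphabet!r}")
        for i, ch in enumerate(seq):
            if ch not in allowed:
                raise SequenceError(
                    f"{self.id}: illegal {self.alphabet} character {ch!r} at position {i + 1}"
                )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class GeneCoordinates:
    """Location of a gene on a replicon, 1-based inclusive."""

    locus: str
    replicon: str
    start: int
    end: int
    strand: str

    def __post_init__(self):
        if not (1 <= self.start <= self.end):
            raise ValueError(f"{self.locus}: need 1 <= start <= end, got {self.start}..{self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.locus}: strand must be '+' or '-', got {self.strand!r}")


@dataclass(frozen=True)
class PrimerPair:
    """A qPCR primer pair, both primers written 5'->3'."""

    gene: str
    forward: str
    reverse: str
    expected_amplicon_bp: int | None = None

    def __post_init__(self):
        for name, p in (("forward", self.forward), ("reverse", self.reverse)):
            p = p.upper()
            object.__setattr__(self, name, p)
            if len(p) < 10:
                raise ValueError(f"{self.gene}: {name} primer shorter than 10 nt")
            bad = set(p) - (DNA_ALPHABET - {"N"})
            if bad:
                raise ValueError(f"{self.gene}: {name} primer has non-ACGT characters {bad}")


@dataclass(frozen=True)
class UpstreamWindow:
    """An upstream region in coding orientation; ``truncated`` marks windows
    shorter than requested because the gene sits near the replicon edge."""

    locus: str
    seq: str
    truncated: bool = False

    def __len__(self) -> int:
        return len(self.seq)

    def as_record(self) -> SequenceRecord:
        return SequenceRecord(id=f"{self.locus}_upstream", seq=self.seq, alphabet="dna")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path, alphabet: str = "dna") -> list[SequenceRecord]:
    """Read a FASTA file into validated :class:`SequenceRecord` objects.

    Order is preserved; sequences are uppercased. Empty files, duplicate
    ids and out-of-alphabet characters raise :class:`SequenceError`.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise SequenceError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(SequenceRecord(id=rec.id, seq=str(rec.seq), alphabet=alphabet))
    if not records:
        raise SequenceError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    """Write records as multi-FASTA, wrapped at ``width`` columns."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Basic nucleic-acid operations

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement; N maps to N."""
    seq = seq.upper()
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise SequenceError(f"non-DNA characters in sequence: {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


def translate_cds(seq: str, check_start: bool = True) -> str:
    """Translate a CDS with the bacterial/archaeal genetic code (table 11).

    A single trailing stop codon is trimmed; an internal stop raises.
    Alternative start codons (GTG/TTG/...) are reported as M at position 1,
    with a log notice; a CDS not opening with a recognized start codon only
    warns, since annotation edge cases exist.
    """
    seq = seq.upper()
    if len(seq) % 3 != 0:
        raise SequenceError(f"CDS length {len(seq)} not divisible by 3")
    aa = str(Seq(seq).translate(table=11))
    if aa.endswith("*"):
        aa = aa[:-1]
    if "*" in aa:
        raise SequenceError(f"internal stop codon at codon {aa.index('*') + 1}")
    first = seq[:3]
    if first in BACTERIAL_TABLE.start_codons:
        if aa and aa[0] != "M":
            logger.info("alternative start codon %s reported as M", first)
            aa = "M" + aa[1:]
    elif check_start:
        logger.warning("CDS does not begin with a recognized start codon (%s)", first)
    return aa


# ---------------------------------------------------------------------------
# Upstream-region extraction


def extract_upstream(
    genome: SequenceRecord, coords: GeneCoordinates, n: int = 200
) -> UpstreamWindow:
    """Return the ``n`` bases immediately 5' of the start codon, in coding
    orientation (reverse-complemented for minus-strand genes).

    The window does not stop at neighbouring gene boundaries: a fixed
    region is taken regardless of annotation context. If fewer than ``n``
    bases exist before the replicon edge the truncated window is returned
    with ``truncated=True``.
    """
    if n < 1:
        raise ValueError("n must be positive")
    glen = len(genome.seq)
    if coords.end > glen:
        raise ValueError(
            f"{coords.locus}: coordinates {coords.start}..{coords.end} outside "
            f"genome of length {glen}"
        )
    if coords.strand == "+":
        # start codon begins at coords.start; upstream is [start-n, start-1]
        lo = max(coords.start - n, 1)
        seq = genome.seq[lo - 1 : coords.start - 1]
    else:
        # start codon begins at coords.end on the minus strand
        hi = min(coords.end + n, glen)
        seq = reverse_complement(genome.seq[coords.end : hi])
    truncated = len(seq) < n
    if truncated:
        logger.warning(
            "%s: only %d of %d upstream bases available", coords.locus, len(seq), n
        )
    if not seq:
        raise ValueError(f"{coords.locus}: no upstream bases available")
    return UpstreamWindow(locus=coords.locus, seq=seq, truncated=truncated)


def extract_cds(genome: SequenceRecord, coords: GeneCoordinates) -> SequenceRecord:
    """Slice the annotated CDS (start through stop codon inclusive) in coding
    orientation."""
    if coords.end > len(genome.seq):
        raise ValueError(f"{coords.locus}: coordinates outside genome")
    seq = genome.seq[coords.start - 1 : coords.end]
    if coords.strand == "-":
        seq = reverse_complement(seq)
    return SequenceRecord(id=coords.locus, seq=seq, alphabet="dna")


# ---------------------------------------------------------------------------
# In-silico PCR


def _find_all(haystack: str, needle: str) -> list[int]:
    hits, start = [], 0
    while True:
        i = haystack.find(needle, start)
        if i < 0:
            return hits
        hits.append(i)
        start = i + 1


def find_amplicon(template: SequenceRecord, primers: PrimerPair) -> int | None:
    """Exact-match in-silico PCR.

    Searches both strands for the forward primer and, downstream of each
    match, for the reverse complement of the reverse primer. The amplicon
    length includes both primer footprints. Returns ``None`` when the pair
    is unproductive; raises :class:`AmbiguousAmpliconError` when more than
    one amplicon would form (non-specific primers). Matching is exact — the
    primers were designed for perfect identity to their template.
    """
    if template.alphabet != "dna":
        raise SequenceError("PCR template must be DNA")
    fwd = primers.forward
    rev_rc = reverse_complement(primers.reverse)
    sites: list[tuple[str, int, int]] = []  # (strand, 1-based fwd pos on that strand, length)
    for strand, seq in (("+", template.seq), ("-", reverse_complement(template.seq))):
        for f_pos in _find_all(seq, fwd):
            for r_pos in _find_all(seq[f_pos + len(fwd) :], rev_rc):
                length = len(fwd) + r_pos + len(rev_rc)
                sites.append((strand, f_pos + 1, length))
    if not sites:
        return None
    if len(sites) > 1:
        raise AmbiguousAmpliconError(sites)
    return sites[0][2]


# ---------------------------------------------------------------------------
# Tables

COORDINATE_COLUMNS = ["locus", "replicon", "start", "end", "strand"]
PRIMER_COLUMNS = ["gene", "forward", "reverse", "amplicon_bp"]


def read_coordinates(path: str | Path) -> list[GeneCoordinates]:
    """Read a TSV with header ``locus replicon start end strand``."""
    df = pd.read_csv(path, sep="\t")
    missing = set(COORDINATE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"coordinate table missing columns {sorted(missing)}")
    return [
        GeneCoordinates(
            locus=str(r.locus),
            replicon=str(r.replicon),
            start=int(r.start),
            end=int(r.end),
            strand=str(r.strand),
        )
        for r in df.itertuples()
    ]


def read_primers(path: str | Path) -> list[PrimerPair]:
    """Read a primer TSV with header ``gene forward reverse amplicon_bp``."""
    df = pd.read_csv(path, sep="\t")
    missing = {"gene", "forward", "reverse"} - set(df.columns)
    if missing:
        raise ValueError(f"primer table missing columns {sorted(missing)}")
    out = []
    for r in df.itertuples():
        exp = getattr(r, "amplicon_bp", None)
        exp = None if exp is None or pd.isna(exp) else int(exp)
        out.append(
            PrimerPair(gene=str(r.gene), forward=str(r.forward), reverse=str(r.reverse),
                       expected_amplicon_bp=exp)
        )
    return out
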