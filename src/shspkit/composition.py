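"""GC-composition screening for horizontally transferred genes.

Genes acquired by horizontal transfer often retain the nucleotide
composition of their donor. This module compares each gene's GC content
with the genome-wide average coding GC by a one-proportion Pearson
chi-square test (1 df) on the observed [GC, AT] counts, and flags genes
whose composition departs significantly (default alpha = 0.01) as
candidate horizontal acquisitions. For *A. ferrooxidans* the coding-gene
average is ~59% GC, the shipped default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import pandas as pd
from scipy import stats

from .sequences import SequenceRecord

#: Average GC fraction of *A. ferrooxidans* ATCC 23270 coding genes.
DEFAULT_GENOME_GC = 0.59
DEFAULT_ALPHA = 0.01


@dataclass(frozen=True)
class CompositionResult:
    locus: str
    length_nt: int
    gc_count: int
    gc_percent: float
    expected_gc_fraction: float
    chi_square: float
    p_value: float
    hgt_flag: bool


def gc_content(seq: str) -> tuple[int, float]:
    """(GC count, GC fraction) of a DNA string; N bases are excluded from
    both numerator and denominator."""
    seq = seq.upper()
    n_total = len(seq) - seq.count("N")
    if n_total == 0:
        raise ValueError("empty or all-N sequence has no defined GC content")
    gc = seq.count("G") + seq.count("C")
    return gc, gc / n_total


def gc_chi_square(gc_count: int, length_nt: int, expected_p: float) -> tuple[float, float]:
    """Pearson chi-square (1 df) of observed [GC, AT] counts against the
    expected proportion ``expected_p``; p-value from the chi2(1) tail.

    Warns when an expected class count falls below 1 (test unreliable).
    """
    if not 0 < expected_p < 1:
        raise ValueError("expected_p must be in (0, 1)")
    if length_nt <= 0:
        raise ValueError("length_nt must be positive")
    if gc_count < 0 or gc_count > length_nt:
        raise ValueError("gc_count must be in [0, length_nt]")
    exp_gc = expected_p * length_nt
    exp_at = (1 - expected_p) * length_nt
    if min(exp_gc, exp_at) < 1:
        warnings.warn("expected class count < 1; chi-square approximation unreliable")
    chi2 = (gc_count - exp_gc) ** 2 / exp_gc + ((length_nt - gc_count) - exp_at) ** 2 / exp_at
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p


def screen_gene(
    record: SequenceRecord,
    genome_avg_gc: float = DEFAULT_GENOME_GC,
    alpha: float = DEFAULT_ALPHA,
) -> CompositionResult:
    gc, frac = gc_content(record.seq)
    n = len(record.seq) - record.seq.count("N")
    chi2, p = gc_chi_square(gc, n, genome_avg_gc)
    return CompositionResult(
        locus=record.id,
        length_nt=n,
        gc_count=gc,
        gc_percent=round(100 * frac, 2),
        expected_gc_fraction=genome_avg_gc,
        chi_square=chi2,
        p_value=p,
        hgt_flag=p < alpha,
    )


def hgt_screen(
    genes: Sequence[SequenceRecord],
    genome_avg_gc: float = DEFAULT_GENOME_GC,
    alpha: float = DEFAULT_ALPHA,
) -> list[CompositionResult]:
    """Screen each CDS against the genome-average coding GC; ``hgt_flag``
    marks genes whose GC differs at the given significance level."""
    return [screen_gene(g, genome_avg_gc, alpha) for g in genes]


def genome_average_gc(cds_records: Sequence[SequenceRecord]) -> float:
    """Recompute the genome-average coding GC fraction by pooling all CDS
    bases (N excluded)."""
    gc_total = 0
    n_total = 0
    for rec in cds_records:
        s = rec.seq
        gc_total += s.count("G") + s.count("C")
        n_total += len(s) - s.count("N")
    if n_total == 0:
        raise ValueError("no non-N bases in CDS set")
    return gc_total / n_total


COMPOSITION_COLUMNS = [
    "locus", "length_nt", "gc_count", "gc_percent", "chi_square", "p_value", "hgt_flag",
]


def composition_table(results: Sequence[CompositionResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "locus": r.locus,
                "length_nt": r.length_nt,
                "gc_count": r.gc_count,
                "gc_percent": f"{r.gc_percent:.2f}",
                "chi_square": round(r.chi_square, 4),
                "p_value": format(r.p_value, ".3g"),
                "hgt_flag": r.hgt_flag,
            }
            for r in results
        ],
        columns=COMPOSITION_COLUMNS,
    )
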