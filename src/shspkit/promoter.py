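"""Two-block sigma-32 promoter discovery.

Heat-shock promoters recognized by the alternative sigma factor sigma-32
are bipartite: a 6-nt -35 element and an 8-nt -10 element separated by a
spacer of variable length. This module builds one position weight matrix
(PWM) per block from an aligned training set of known promoters, scans
upstream windows by exhaustively enumerating every (-35 position, spacer
length) placement allowed by the training set, and scores each candidate
site by summed log-odds in bits. It also reports the information content
of the model (Rsequence) and of each individual site (Ri), following the
Schneider information-theoretic treatment of binding sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .sequences import SequenceRecord, UpstreamWindow

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

UNIFORM_BACKGROUND = {b: 0.25 for b in BASES}

WIDTH_35 = 6
WIDTH_10 = 8


def gc_background(gc: float) -> dict[str, float]:
    """Background base probabilities with the given GC fraction
    (p(G)=p(C)=gc/2, p(A)=p(T)=(1-gc)/2)."""
    if not 0 < gc < 1:
        raise ValueError("gc fraction must be in (0, 1)")
    return {"A": (1 - gc) / 2, "C": gc / 2, "G": gc / 2, "T": (1 - gc) / 2}


@dataclass(frozen=True)
class PromoterTrainingSet:
    """Aligned promoter sites: (-35 hexamer, spacer length, -10 octamer) triples."""

    records: tuple[tuple[str, int, str], ...]
    source_label: str = ""

    def __post_init__(self):
        if len(self.records) < 2:
            raise ValueError("training set needs at least 2 records")
        norm = []
        for s35, gap, s10 in self.records:
            s35, s10 = s35.upper(), s10.upper()
            if len(s35) != WIDTH_35:
                raise ValueError(f"-35 site {s35!r} is not {WIDTH_35} nt")
            if len(s10) != WIDTH_10:
                raise ValueError(f"-10 site {s10!r} is not {WIDTH_10} nt")
            if gap < 0:
                raise ValueError("spacer length must be non-negative")
            norm.append((s35, int(gap), s10))
        object.__setattr__(self, "records", tuple(norm))

    @property
    def sites35(self) -> list[str]:
        return [r[0] for r in self.records]

    @property
    def sites10(self) -> list[str]:
        return [r[2] for r in self.records]

    @property
    def spacers(self) -> list[int]:
        return [r[1] for r in self.records]

    @classmethod
    def from_tsv(cls, path: str | Path, source_label: str = "") -> "PromoterTrainingSet":
        """Load a TSV with header ``site35 spacer_len site10``."""
        df = pd.read_csv(path, sep="\t")
        missing = {"site35", "spacer_len", "site10"} - set(df.columns)
        if missing:
            raise ValueError(f"training set missing columns {sorted(missing)}")
        recs = tuple(
            (str(r.site35), int(r.spacer_len), str(r.site10)) for r in df.itertuples()
        )
        return cls(records=recs, source_label=source_label or str(path))

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.records, columns=["site35", "spacer_len", "site10"]).to_csv(
            path, sep="\t", index=False
        )


@dataclass(frozen=True)
class PositionWeightMatrix:
    """Per-position base probabilities for a fixed-width motif.

    ``probs[l, b]`` is the smoothed probability of base ``BASES[b]`` at
    position ``l``: (count + pseudocount) / (n + 4 * pseudocount).
    """

    probs: np.ndarray  # (width, 4)
    counts: np.ndarray  # (width, 4) raw counts
    pseudocount: float
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)

    def __post_init__(self):
        probs = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", probs)
        object.__setattr__(self, "counts", np.asarray(self.counts, dtype=float))
        bg = np.asarray(self.background, dtype=float)
        if probs.ndim != 2 or probs.shape[1] != 4:
            raise ValueError("probs must have shape (width, 4)")
        if np.any(probs < 0) or np.any(np.abs(probs.sum(axis=1) - 1) > 1e-9):
            raise ValueError("each PWM column must be a probability distribution")
        if abs(bg.sum() - 1) > 1e-9 or np.any(bg <= 0):
            raise ValueError("background must be a positive distribution summing to 1")
        object.__setattr__(self, "background", tuple(bg))

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    def log_odds(self) -> np.ndarray:
        """(width, 4) matrix of log2(p / background); -inf where p == 0."""
        bg = np.asarray(self.background)
        with np.errstate(divide="ignore"):
            return np.log2(self.probs) - np.log2(bg)[None, :]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in np.argmax(self.probs, axis=1))


def build_pwm(
    sites: Sequence[str],
    pseudocount: float = 0.5,
    background: Mapping[str, float] | None = None,
) -> PositionWeightMatrix:
    """Build a PWM from equal-length aligned sites.

    Probabilities are Laplace-smoothed: (count + pseudocount) / (n + 4p).
    """
    if not sites:
        raise ValueError("empty site list")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    width = len(sites[0])
    counts = np.zeros((width, 4))
    for s in sites:
        s = s.upper()
        if len(s) != width:
            raise ValueError(f"site {s!r} has width {len(s)}, expected {width}")
        for l, ch in enumerate(s):
            if ch not in _BASE_INDEX:
                raise ValueError(f"site {s!r}: base {ch!r} not in ACGT")
            counts[l, _BASE_INDEX[ch]] += 1
    n = len(sites)
    probs = (counts + pseudocount) / (n + 4 * pseudocount)
    bg = background or UNIFORM_BACKGROUND
    bg_vec = tuple(bg[b] for b in BASES)
    return PositionWeightMatrix(probs=probs, counts=counts, pseudocount=pseudocount,
                                background=bg_vec)


def pwm_information_content(pwm: PositionWeightMatrix) -> float:
    """Total model information Rsequence in bits.

    Rsequence = sum over positions of sum_b p log2(p / bg_b), with
    0*log(0) taken as 0. Against an equiprobable background this equals
    sum over positions of (2 - H(column)).
    """
    p = pwm.probs
    bg = np.asarray(pwm.background)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * (np.log2(p) - np.log2(bg)[None, :])
    terms = np.where(p == 0, 0.0, terms)
    return float(terms.sum())


def site_individual_information(pwm: PositionWeightMatrix, site: str) -> float:
    """Individual information Ri of one site in bits:
    sum_l log2(probs[l, site_l] / bg). Build the PWM with pseudocount > 0
    to avoid -inf on bases unseen in training."""
    site = site.upper()
    if len(site) != pwm.width:
        raise ValueError(f"site width {len(site)} != PWM width {pwm.width}")
    lo = pwm.log_odds()
    return float(sum(lo[l, _BASE_INDEX[ch]] for l, ch in enumerate(site)))


@dataclass(frozen=True)
class SigmaPromoterModel:
    """Paired -35/-10 PWMs plus the admissible spacer range observed in
    training."""

    pwm35: PositionWeightMatrix
    pwm10: PositionWeightMatrix
    spacer_min: int
    spacer_max: int

    def __post_init__(self):
        if self.pwm35.width != WIDTH_35 or self.pwm10.width != WIDTH_10:
            raise ValueError(f"block widths must be {WIDTH_35} and {WIDTH_10}")
        if not 0 <= self.spacer_min <= self.spacer_max:
            raise ValueError("need 0 <= spacer_min <= spacer_max")

    @property
    def min_footprint(self) -> int:
        return WIDTH_35 + self.spacer_min + WIDTH_10

    @property
    def consensus(self) -> tuple[str, str]:
        return self.pwm35.consensus, self.pwm10.consensus

    def information_content(self) -> float:
        """Combined Rsequence of both blocks, in bits."""
        return pwm_information_content(self.pwm35) + pwm_information_content(self.pwm10)


def fit_sigma32_model(
    ts: PromoterTrainingSet,
    pseudocount: float = 0.5,
    background: Mapping[str, float] | None = None,
) -> SigmaPromoterModel:
    """Fit the two-block model: one PWM per block, spacer range = observed
    min..max spacer length in the training set."""
    return SigmaPromoterModel(
        pwm35=build_pwm(ts.sites35, pseudocount, background),
        pwm10=build_pwm(ts.sites10, pseudocount, background),
        spacer_min=min(ts.spacers),
        spacer_max=max(ts.spacers),
    )


@dataclass(frozen=True)
class PromoterHit:
    """One candidate sigma-32 site inside a scanned window.

    Positions are 1-based within the window; ``dist_to_start`` counts the
    bases between the 3' end of the -10 block and the start codon (the
    window is assumed to abut the ATG).
    """

    pos35: int
    pos10: int
    spacer_len: int
    seq35: str
    seq10: str
    score35: float
    score10: float
    total_score: float
    bits35: float
    bits10: float
    total_bits: float
    dist_to_start: int


def _window_scores(lo: np.ndarray, window_codes: np.ndarray, width: int) -> np.ndarray:
    """Score every width-length subsequence of the coded window against a
    (width, 4) log-odds matrix; vectorized sliding window."""
    n = len(window_codes) - width + 1
    if n <= 0:
        return np.empty(0)
    idx = np.arange(width)[None, :] + np.arange(n)[:, None]
    return lo[np.arange(width)[None, :], window_codes[idx]].sum(axis=1)


def scan_upstream(
    model: SigmaPromoterModel, window: SequenceRecord | UpstreamWindow | str
) -> list[PromoterHit]:
    """Enumerate and score every admissible two-block placement in a window.

    Every (-35 start, spacer length) pair with the spacer inside the
    model's range and both blocks inside the window is scored;
    total_score = score35 + score10 with no spacer-length penalty. Hits are
    returned best-first; ties break toward the site closer to the start
    codon, then leftmost. The caller filters (e.g. keeps top-k).
    """
    seq = window if isinstance(window, str) else window.seq
    seq = seq.upper()
    L = len(seq)
    if L < model.min_footprint:
        raise ValueError(
            f"window of length {L} shorter than minimal promoter footprint "
            f"{model.min_footprint}"
        )
    # N is coded 4 and scored as the background-average (log-odds 0 is wrong
    # for info; use column-mean log-odds so Ns neither reward nor kill a site)
    codes = np.array([_BASE_INDEX.get(ch, 4) for ch in seq])

    def padded(lo: np.ndarray, bg) -> np.ndarray:
        # column 5 scores N as the background-expected log-odds
        bg = np.asarray(bg)
        return np.hstack([lo, (lo * bg).sum(axis=1, keepdims=True)])

    # log-odds against the model's configured background drive ranking;
    # Ri (bits) is always reported against the equiprobable background
    lo35 = padded(model.pwm35.log_odds(), model.pwm35.background)
    lo10 = padded(model.pwm10.log_odds(), model.pwm10.background)
    uni = (0.25,) * 4
    with np.errstate(divide="ignore"):
        ri35 = padded(np.log2(model.pwm35.probs) + 2.0, uni)
        ri10 = padded(np.log2(model.pwm10.probs) + 2.0, uni)
    s35 = _window_scores(lo35, codes, WIDTH_35)
    s10 = _window_scores(lo10, codes, WIDTH_10)
    b35 = _window_scores(ri35, codes, WIDTH_35)
    b10 = _window_scores(ri10, codes, WIDTH_10)
    hits: list[PromoterHit] = []
    for spacer in range(model.spacer_min, model.spacer_max + 1):
        footprint = WIDTH_35 + spacer + WIDTH_10
        for p35 in range(0, L - footprint + 1):
            p10 = p35 + WIDTH_35 + spacer
            sc35, sc10 = float(s35[p35]), float(s10[p10])
            hits.append(
                PromoterHit(
                    pos35=p35 + 1,
                    pos10=p10 + 1,
                    spacer_len=spacer,
                    seq35=seq[p35 : p35 + WIDTH_35],
                    seq10=seq[p10 : p10 + WIDTH_10],
                    score35=sc35,
                    score10=sc10,
                    total_score=sc35 + sc10,
                    bits35=float(b35[p35]),
                    bits10=float(b10[p10]),
                    total_bits=float(b35[p35] + b10[p10]),
                    dist_to_start=L - (p10 + WIDTH_10),
                )
            )
    # scores equal to 6 decimals are treated as exact ties so that the
    # proximity/leftmost tie-break is stable against summation order
    hits.sort(key=lambda h: (-round(h.total_score, 6), h.dist_to_start, h.pos35))
    return hits


HIT_REPORT_COLUMNS = [
    "locus", "pos35", "seq35", "score35", "spacer_len", "pos10", "seq10",
    "score10", "total_score", "total_bits", "offset_from_ATG",
]


def report_promoters(
    model: SigmaPromoterModel,
    genes: Mapping[str, SequenceRecord | UpstreamWindow | str],
    top_k: int = 1,
) -> pd.DataFrame:
    """Scan each gene's upstream window and tabulate the top-k hits.

    ``offset_from_ATG`` is the (negative) 1-based offset of the -35 block
    relative to the first base of the start codon at +1.
    """
    rows = []
    for locus, window in genes.items():
        seq = window if isinstance(window, str) else window.seq
        for hit in scan_upstream(model, window)[:top_k]:
            rows.append(
                {
                    "locus": locus,
                    "pos35": hit.pos35,
                    "seq35": hit.seq35,
                    "score35": round(hit.score35, 4),
                    "spacer_len": hit.spacer_len,
                    "pos10": hit.pos10,
                    "seq10": hit.seq10,
                    "score10": round(hit.score10, 4),
                    "total_score": round(hit.total_score, 4),
                    "total_bits": round(hit.total_bits, 4),
                    "offset_from_ATG": hit.pos35 - len(seq) - 1,
                }
            )
    return pd.DataFrame(rows, columns=HIT_REPORT_COLUMNS)
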