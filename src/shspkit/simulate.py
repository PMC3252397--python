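"""Synthetic-data generators with known ground truth.

Every pipeline stage can run self-contained on data from this module,
which emulates the heat-shock study design: an 18-site sigma-32 promoter
training set (6-nt -35 block, variable spacer, 8-nt -10 block), 200-nt
upstream windows with optionally planted consensus boxes, CDS-like genes
with a target GC fraction, and triplicate Ct tables for three target
genes plus an endogenous control across a 30 C control and heat-shock
time points, with configurable true fold changes and Gaussian Ct noise.

Reproducibility: one integer seed drives a named, independent PRNG
stream per generator (``SeedSequence(seed, spawn_key=(stream,))``), so
adding a generator never perturbs the draws of existing ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import published
from .promoter import PromoterTrainingSet, SigmaPromoterModel, WIDTH_10, WIDTH_35
from .sequences import SequenceRecord

BASES = "ACGT"

# stable stream ids; append only, never renumber
_STREAMS = {"training_set": 0, "upstream": 1, "gene": 2, "ct": 3}

#: Demonstration consensus boxes for sigma-32-style promoters (E. coli-like
#: -35 and extended -10 elements); configurable, not a claim about any genome.
DEFAULT_CONSENSUS_35 = "CTTGAA"
DEFAULT_CONSENSUS_10 = "CCCCATTT"


def stream_rng(seed: int, stream: str) -> np.random.Generator:
    """Independent generator for a named stream under one master seed."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAMS[stream],)))


def _default_folds() -> dict[tuple[str, str], float]:
    """Study-design default true fold changes.

    The 60-min folds encode the reported outcome (weakest responder at the
    2.0 floor; 20x and 11.5x between-gene ratios); the unreported 15/30-min
    folds ramp log-linearly toward the 60-min value. The endogenous control
    alaS is 1.0 everywhere by definition.
    """
    folds: dict[tuple[str, str], float] = {}
    for gene, f60 in published.HEAT_SHOCK_60MIN_FOLDS.items():
        folds[(gene, "hs_15min")] = f60 ** (1 / 3)
        folds[(gene, "hs_30min")] = f60 ** (2 / 3)
        folds[(gene, "hs_60min")] = f60
    for cond in ("hs_15min", "hs_30min", "hs_60min"):
        folds[(published.REFERENCE_GENE, cond)] = 1.0
    return folds


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of all generators; defaults mirror the heat-shock study design."""

    seed: int = 0
    n_training_sites: int = 18
    mutation_rate: float = 0.1
    spacer_range: tuple[int, int] = (11, 15)
    upstream_len: int = 200
    background_gc: float = 0.59
    gene_gc_targets: Mapping[str, float] = field(
        default_factory=lambda: dict(
            (k, v / 100) for k, v in published.GC_PERCENT.items()
        )
    )
    ct_true_folds: Mapping[tuple[str, str], float] = field(default_factory=_default_folds)
    ct_noise_sd: float = 0.2
    replicates: int = 3
    control_condition: str = "control_30C"
    reference_gene: str = published.REFERENCE_GENE
    base_ct: float = 22.0

    def __post_init__(self):
        if not 0 <= self.mutation_rate <= 1:
            raise ValueError("mutation_rate must be in [0, 1]")
        if self.ct_noise_sd < 0:
            raise ValueError("ct_noise_sd must be >= 0")
        if any(f <= 0 for f in self.ct_true_folds.values()):
            raise ValueError("all true folds must be positive")


def simulate_training_set(
    consensus35: str = DEFAULT_CONSENSUS_35,
    consensus10: str = DEFAULT_CONSENSUS_10,
    config: SimulationConfig = SimulationConfig(),
) -> PromoterTrainingSet:
    """Training sites as noisy copies of the consensus boxes.

    Each position mutates independently with probability ``mutation_rate``
    to one of the three other bases; spacer lengths are uniform over
    ``spacer_range``.
    """
    if len(consensus35) != WIDTH_35 or len(consensus10) != WIDTH_10:
        raise ValueError(f"consensus widths must be {WIDTH_35} and {WIDTH_10}")
    rng = stream_rng(config.seed, "training_set")

    def mutate(site: str) -> str:
        out = []
        for ch in site:
            if rng.random() < config.mutation_rate:
                out.append(rng.choice([b for b in BASES if b != ch]))
            else:
                out.append(ch)
        return "".join(out)

    lo, hi = config.spacer_range
    records = tuple(
        (mutate(consensus35), int(rng.integers(lo, hi + 1)), mutate(consensus10))
        for _ in range(config.n_training_sites)
    )
    return PromoterTrainingSet(records=records, source_label=f"synthetic(seed={config.seed})")


def _random_dna(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(list(BASES), size=length, p=p))


@dataclass(frozen=True)
class PlantedPromoter:
    """Ground truth for a planted two-block site (1-based positions)."""

    pos35: int
    pos10: int
    spacer_len: int
    seq35: str
    seq10: str


def simulate_upstream(
    model_or_consensus: SigmaPromoterModel | tuple[str, str],
    planted: bool,
    config: SimulationConfig = SimulationConfig(),
    locus: str = "synthetic_upstream",
    rng: np.random.Generator | None = None,
) -> tuple[SequenceRecord, PlantedPromoter | None]:
    """A random upstream window, optionally with consensus boxes planted at
    a recorded position and spacer; background is i.i.d. at
    ``background_gc``."""
    if isinstance(model_or_consensus, SigmaPromoterModel):
        c35, c10 = model_or_consensus.consensus
    else:
        c35, c10 = model_or_consensus
    rng = rng if rng is not None else stream_rng(config.seed, "upstream")
    L = config.upstream_len
    lo, hi = config.spacer_range
    if L < WIDTH_35 + lo + WIDTH_10:
        raise ValueError("upstream_len shorter than the minimal promoter footprint")
    seq = list(_random_dna(rng, L, config.background_gc))
    truth = None
    if planted:
        spacer = int(rng.integers(lo, hi + 1))
        footprint = WIDTH_35 + spacer + WIDTH_10
        pos35 = int(rng.integers(0, L - footprint + 1))  # 0-based
        pos10 = pos35 + WIDTH_35 + spacer
        seq[pos35 : pos35 + WIDTH_35] = c35
        seq[pos10 : pos10 + WIDTH_10] = c10
        truth = PlantedPromoter(
            pos35=pos35 + 1, pos10=pos10 + 1, spacer_len=spacer, seq35=c35, seq10=c10
        )
    return SequenceRecord(id=locus, seq="".join(seq), alphabet="dna"), truth


_STOP_CODONS = {"TAA", "TAG", "TGA"}


def simulate_gene(
    length_nt: int,
    gc_target: float,
    seed: int,
    locus: str = "synthetic_gene",
    cds_like: bool = False,
) -> SequenceRecord:
    """Random gene with i.i.d. bases at the target GC fraction.

    With ``cds_like=True`` the length must be divisible by 3; the gene
    starts with ATG, ends with TAA, and internal stop codons are resampled
    (slightly perturbing realized GC).
    """
    if not 0 < gc_target < 1:
        raise ValueError("gc_target must be in (0, 1)")
    rng = stream_rng(seed, "gene")
    if not cds_like:
        return SequenceRecord(id=locus, seq=_random_dna(rng, length_nt, gc_target),
                              alphabet="dna")
    if length_nt % 3 != 0:
        raise ValueError("CDS-like gene length must be divisible by 3")
    if length_nt < 9:
        raise ValueError("CDS-like gene needs at least 3 codons")
    n_internal = length_nt // 3 - 2
    codons = ["ATG"]
    for _ in range(n_internal):
        codon = _random_dna(rng, 3, gc_target)
        while codon in _STOP_CODONS:
            codon = _random_dna(rng, 3, gc_target)
        codons.append(codon)
    codons.append("TAA")
    return SequenceRecord(id=locus, seq="".join(codons), alphabet="dna")


def simulate_gene_batch(
    n_genes: int, length_nt: int, gc_target: float, seed: int
) -> np.ndarray:
    """GC counts of ``n_genes`` i.i.d. random genes, drawn directly as
    Binomial(length, gc_target); distributionally identical to counting
    G+C in ``simulate_gene`` output, but fast enough for 10k-gene
    calibration runs."""
    rng = stream_rng(seed, "gene")
    return rng.binomial(length_nt, gc_target, size=n_genes)


def simulate_ct_table(config: SimulationConfig = SimulationConfig()) -> pd.DataFrame:
    """Triplicate Ct table for the configured genes x conditions.

    Construction inverts the Livak model: Ct = base_ct - log2(true fold)
    + N(0, sd), with the reference gene at fold 1 in every condition and
    all genes at fold 1 in the control condition, so at sd = 0 the ddCt
    pipeline recovers every configured fold exactly.
    """
    rng = stream_rng(config.seed, "ct")
    genes = sorted({g for g, _ in config.ct_true_folds} | {config.reference_gene})
    conditions = [config.control_condition] + sorted({c for _, c in config.ct_true_folds})
    ref_fold = [
        f for (g, c), f in config.ct_true_folds.items() if g == config.reference_gene
    ]
    if any(f != 1.0 for f in ref_fold):
        raise ValueError("reference gene must have fold 1 in all conditions")
    rows = []
    for gene in genes:
        # distinct per-gene basal Ct keeps the table realistic (stable across
        # processes; str hash randomization would break byte-determinism)
        gene_base = config.base_ct + (sum(ord(c) for c in gene) % 5)
        for cond in conditions:
            if cond == config.control_condition:
                fold = 1.0
            else:
                fold = config.ct_true_folds.get((gene, cond), 1.0)
            for rep in range(1, config.replicates + 1):
                noise = rng.normal(0.0, config.ct_noise_sd) if config.ct_noise_sd > 0 else 0.0
                rows.append(
                    {
                        "gene": gene,
                        "condition": cond,
                        "replicate": rep,
                        "ct": gene_base - np.log2(fold) + noise,
                    }
                )
    return pd.DataFrame(rows, columns=["gene", "condition", "replicate", "ct"])


def write_synthetic_inputs(config: SimulationConfig, outdir) -> dict:
    """Write a full set of synthetic pipeline inputs plus ground truth.

    Produces ``training_set.tsv``, ``upstream.fasta`` (one planted window
    per target gene), ``cds.fasta`` (CDS-like genes at the configured GC
    targets), ``ct.tsv`` and ``ground_truth.json``; returns the ground
    truth as a dict.
    """
    import json
    from pathlib import Path

    from .sequences import write_fasta

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    truth: dict = {"seed": config.seed}

    ts = simulate_training_set(config=config)
    ts.to_tsv(out / "training_set.tsv")

    rng = stream_rng(config.seed, "upstream")
    windows, planted = [], {}
    for locus in config.gene_gc_targets:
        rec, gt = simulate_upstream(
            (DEFAULT_CONSENSUS_35, DEFAULT_CONSENSUS_10),
            planted=True, config=config, locus=f"{locus}", rng=rng,
        )
        windows.append(rec)
        planted[locus] = gt.__dict__
    write_fasta(windows, out / "upstream.fasta")
    truth["planted_promoters"] = planted

    genes = []
    for i, (locus, gc) in enumerate(config.gene_gc_targets.items()):
        length = 450
        genes.append(simulate_gene(length_nt=length, gc_target=gc,
                                   seed=config.seed + i + 1, locus=locus, cds_like=True))
    write_fasta(genes, out / "cds.fasta")
    truth["gene_gc_targets"] = dict(config.gene_gc_targets)

    ct = simulate_ct_table(config)
    ct.to_csv(out / "ct.tsv", sep="\t", index=False)
    truth["true_folds"] = {f"{g}|{c}": f for (g, c), f in config.ct_true_folds.items()}

    with open(out / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
    return truth
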