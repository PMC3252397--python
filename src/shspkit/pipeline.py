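"""End-to-end orchestration: upstream extraction -> promoter scan ->
composition -> protein properties -> in-silico PCR -> expression.

Each stage is optional and runs only when its inputs are configured; any
stage failure aborts the run naming the stage, with earlier outputs
retained. Given the same config (and seed, for synthetic inputs) two
runs produce byte-identical TSVs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import composition as comp
from . import expression as expr
from . import promoter as prom
from . import proteins as prot
from . import published
from . import sequences as seqs

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")


@dataclass
class PipelineConfig:
    """Paths (all optional; stages without inputs are skipped) and
    per-stage parameters."""

    outdir: str = "shspkit_out"
    genome_fasta: str | None = None
    coordinates: str | None = None
    cds_fasta: str | None = None
    protein_fasta: str | None = None
    upstream_fasta: str | None = None
    primer_table: str | None = None
    training_set: str | None = None
    ct_table: str | None = None

    upstream_len: int = 200
    pseudocount: float = 0.5
    background: str = "uniform"  # "uniform" or "gc:<fraction>"
    top_k: int = 3
    genome_avg_gc: float = published.GENOME_AVG_GC
    composition_alpha: float = 0.01
    reference_gene: str = published.REFERENCE_GENE
    control_condition: str = "control_30C"
    expression_alpha: float = 0.05
    fc_floor: float = 2.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _background_map(spec: str):
    if spec == "uniform":
        return None
    if spec.startswith("gc:"):
        return prom.gc_background(float(spec[3:]))
    raise ValueError(f"background must be 'uniform' or 'gc:<fraction>', got {spec!r}")


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False)
    logger.info("wrote %s (%d rows)", path, len(df))


def run_pipeline(config: PipelineConfig) -> dict[str, pd.DataFrame]:
    """Run all configured stages; returns the stage tables keyed by name
    and writes them as TSVs under ``config.outdir``."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict[str, pd.DataFrame] = {}
    log_lines: list[str] = []

    def log_stage(name: str, msg: str) -> None:
        logger.info("[%s] %s", name, msg)
        log_lines.append(f"{name}\t{msg}")

    genome = coords = None
    upstream: dict[str, seqs.UpstreamWindow | seqs.SequenceRecord] = {}
    cds_records: list[seqs.SequenceRecord] = []
    proteins: dict[str, str] = {}

    # --- extraction ---
    try:
        if config.genome_fasta and config.coordinates:
            genome_records = {r.id: r for r in seqs.read_fasta(config.genome_fasta)}
            coords = seqs.read_coordinates(config.coordinates)
            for c in coords:
                if c.replicon not in genome_records:
                    raise ValueError(f"replicon {c.replicon!r} not in genome FASTA")
                g = genome_records[c.replicon]
                upstream[c.locus] = seqs.extract_upstream(g, c, config.upstream_len)
                cds_records.append(seqs.extract_cds(g, c))
            seqs.write_fasta(
                [w.as_record() for w in upstream.values()], out / "upstream.fasta"
            )
            seqs.write_fasta(cds_records, out / "cds.fasta")
            log_stage("extract", f"{len(coords)} genes, upstream_len={config.upstream_len}")
        elif config.upstream_fasta:
            upstream = {r.id: r for r in seqs.read_fasta(config.upstream_fasta)}
            log_stage("extract", f"loaded {len(upstream)} upstream windows")
    except Exception as e:  # noqa: BLE001
        raise StageError("extract", e) from e

    if config.cds_fasta:
        cds_records = seqs.read_fasta(config.cds_fasta)

    # --- promoter scan ---
    try:
        if config.training_set and upstream:
            ts = prom.PromoterTrainingSet.from_tsv(config.training_set)
            model = prom.fit_sigma32_model(
                ts, config.pseudocount, _background_map(config.background)
            )
            table = prom.report_promoters(model, upstream, top_k=config.top_k)
            _write(table, out / "promoters.tsv")
            results["promoters"] = table
            log_stage(
                "promoter_scan",
                f"{len(ts.records)} training sites, model information "
                f"{model.information_content():.2f} bits, top_k={config.top_k}",
            )
        elif config.training_set or upstream:
            log_stage("promoter_scan", "skipped (needs both training set and upstream windows)")
    except StageError:
        raise
    except Exception as e:  # noqa: BLE001
        raise StageError("promoter_scan", e) from e

    # --- composition ---
    try:
        if cds_records:
            res = comp.hgt_screen(cds_records, config.genome_avg_gc, config.composition_alpha)
            table = comp.composition_table(res)
            _write(table, out / "composition.tsv")
            results["composition"] = table
            log_stage("composition", f"{len(res)} genes vs background GC {config.genome_avg_gc}")
        else:
            log_stage("composition", "skipped (no CDS input)")
    except Exception as e:  # noqa: BLE001
        raise StageError("composition", e) from e

    # --- protein properties ---
    try:
        if config.protein_fasta:
            proteins = {r.id: r.seq for r in seqs.read_fasta(config.protein_fasta, "protein")}
        elif cds_records:
            for r in cds_records:
                try:
                    proteins[r.id] = seqs.translate_cds(r.seq)
                except seqs.SequenceError as e:
                    log_stage("protein_props", f"{r.id} not translatable ({e}); skipped")
        if proteins:
            props = [prot.characterize(k, v) for k, v in proteins.items()]
            table = prot.properties_table(props)
            _write(table, out / "protein_props.tsv")
            results["protein_props"] = table
            if len(proteins) > 1:
                pw = prot.pairwise_table(proteins)
                _write(pw, out / "protein_pairwise.tsv")
                results["protein_pairwise"] = pw
            log_stage("protein_props", f"{len(props)} proteins")
        else:
            log_stage("protein_props", "skipped (no protein or CDS input)")
    except Exception as e:  # noqa: BLE001
        raise StageError("protein_props", e) from e

    # --- in-silico PCR ---
    try:
        if config.primer_table and (cds_records or genome):
            primers = seqs.read_primers(config.primer_table)
            templates = {r.id: r for r in cds_records}
            rows = []
            for p in primers:
                template = templates.get(p.gene)
                if template is None:
                    rows.append({"gene": p.gene, "amplicon_bp": "NA",
                                 "expected_bp": p.expected_amplicon_bp, "match": "no_template"})
                    continue
                length = seqs.find_amplicon(template, p)
                match = ("NA" if p.expected_amplicon_bp is None
                         else str(length == p.expected_amplicon_bp))
                rows.append({"gene": p.gene, "amplicon_bp": length if length else "none",
                             "expected_bp": p.expected_amplicon_bp, "match": match})
            table = pd.DataFrame(rows, columns=["gene", "amplicon_bp", "expected_bp", "match"])
            _write(table, out / "pcr.tsv")
            results["pcr"] = table
            log_stage("pcr", f"{len(primers)} primer pairs")
        elif config.primer_table:
            log_stage("pcr", "skipped (no template sequences)")
    except Exception as e:  # noqa: BLE001
        raise StageError("pcr", e) from e

    # --- expression ---
    try:
        if config.ct_table:
            ct = expr.read_ct_table(config.ct_table)
            res = expr.analyze_experiment(
                ct,
                reference=config.reference_gene,
                control_condition=config.control_condition,
                alpha=config.expression_alpha,
                fc_floor=config.fc_floor,
            )
            table = expr.expression_table(res)
            _write(table, out / "expression.tsv")
            results["expression"] = table
            ratios = expr.ratio_matrix(res)
            _write(ratios, out / "expression_ratios.tsv")
            results["expression_ratios"] = ratios
            log_stage("expression", f"{len(res)} gene x condition contrasts")
        else:
            log_stage("expression", "skipped (no Ct table)")
    except StageError:
        raise
    except Exception as e:  # noqa: BLE001
        raise StageError("expression", e) from e

    # --- summary vs published expectations ---
    summary = _summary_vs_published(results)
    if len(summary):
        _write(summary, out / "summary_vs_published.tsv")
        results["summary"] = summary

    (out / "run_log.tsv").write_text(
        "stage\tmessage\n" + "".join(line + "\n" for line in log_lines)
    )
    (out / "run_config.yaml").write_text(yaml.safe_dump(asdict(config), sort_keys=True))
    return results


def _summary_vs_published(results: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Juxtapose computed values with the published expectations for loci
    that match the reference study's gene set."""
    rows = []
    props = results.get("protein_props")
    if props is not None:
        for _, r in props.iterrows():
            if r.locus in published.PROTEIN_PARAMS:
                aa, mw, pi = published.PROTEIN_PARAMS[r.locus]
                rows += [
                    {"locus": r.locus, "quantity": "length_aa", "computed": r.length_aa, "published": aa},
                    {"locus": r.locus, "quantity": "mw_da", "computed": r.mw_da, "published": mw},
                    {"locus": r.locus, "quantity": "pi", "computed": r.pi, "published": pi},
                ]
    compo = results.get("composition")
    if compo is not None:
        for _, r in compo.iterrows():
            if r.locus in published.GC_PERCENT:
                rows.append({"locus": r.locus, "quantity": "gc_percent",
                             "computed": r.gc_percent, "published": published.GC_PERCENT[r.locus]})
    pcr = results.get("pcr")
    if pcr is not None:
        for _, r in pcr.iterrows():
            if r.gene in published.PRIMER_PAIRS:
                rows.append({"locus": r.gene, "quantity": "amplicon_bp",
                             "computed": r.amplicon_bp,
                             "published": published.PRIMER_PAIRS[r.gene].expected_amplicon_bp})
    return pd.DataFrame(rows, columns=["locus", "quantity", "computed", "published"])
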