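"""Relative qRT-PCR quantification by the comparative-Ct (Livak) method.

Per replicate, the target gene's Ct is normalized to an endogenous
control gene (dCt = Ct_target - Ct_reference); the treatment-vs-control
contrast ddCt = mean dCt(treat) - mean dCt(control) yields the fold
change 2^(-ddCt) under the assumption of perfect (2.0) amplification
efficiency. Significance combines a two-sided Student's t-test on the
replicate dCt sets with a fold-change floor: a gene is called
up-regulated when p < 0.05 and fold >= 2.0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_ALPHA = 0.05
DEFAULT_FC_FLOOR = 2.0

CT_COLUMNS = ["gene", "condition", "replicate", "ct"]


@dataclass(frozen=True)
class CtMeasurement:
    gene: str
    condition: str
    replicate: int
    ct: float

    def __post_init__(self):
        if self.ct <= 0:
            raise ValueError(f"Ct must be positive, got {self.ct}")
        if self.replicate < 1:
            raise ValueError("replicate index starts at 1")


@dataclass(frozen=True)
class ExpressionResult:
    gene: str
    condition: str
    mean_dct_treat: float
    mean_dct_control: float
    ddct: float
    fold_change: float
    p_value: float  # nan when undefined (< 2 replicates)
    significant: bool


def measurements_to_frame(measurements: Sequence[CtMeasurement]) -> pd.DataFrame:
    df = pd.DataFrame(
        [(m.gene, m.condition, m.replicate, m.ct) for m in measurements],
        columns=CT_COLUMNS,
    )
    return validate_ct_table(df)


def validate_ct_table(df: pd.DataFrame) -> pd.DataFrame:
    missing = set(CT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"Ct table missing columns {sorted(missing)}")
    if df.duplicated(subset=["gene", "condition", "replicate"]).any():
        dup = df[df.duplicated(subset=["gene", "condition", "replicate"])].iloc[0]
        raise ValueError(
            f"duplicate (gene, condition, replicate): "
            f"({dup.gene}, {dup.condition}, {dup.replicate})"
        )
    if (df["ct"] <= 0).any():
        raise ValueError("all Ct values must be positive")
    return df


def read_ct_table(path: str | Path) -> pd.DataFrame:
    """Read a Ct table (TSV or CSV by extension) with columns
    ``gene condition replicate ct``."""
    sep = "," if str(path).endswith(".csv") else "\t"
    return validate_ct_table(pd.read_csv(path, sep=sep))


def summarize_ct(values: Sequence[float]) -> tuple[float, float, int]:
    """Mean, sample SD (ddof=1; 0.0 for a single replicate) and n of a set
    of replicate Ct values."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("no Ct measurements to summarize")
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return float(arr.mean()), sd, int(arr.size)


def _replicate_dct(df: pd.DataFrame, target: str, reference: str, condition: str) -> np.ndarray:
    """Per-replicate dCt = Ct_target - Ct_reference, paired on replicate id."""
    sub = df[df["condition"] == condition]
    tgt = sub[sub["gene"] == target].set_index("replicate")["ct"]
    ref = sub[sub["gene"] == reference].set_index("replicate")["ct"]
    if tgt.empty:
        raise ValueError(f"no measurements for gene {target!r} in condition {condition!r}")
    if ref.empty:
        raise ValueError(f"no measurements for reference {reference!r} in condition {condition!r}")
    common = tgt.index.intersection(ref.index)
    if len(common) == 0:
        raise ValueError(f"no shared replicates for {target!r}/{reference!r} in {condition!r}")
    return (tgt.loc[common] - ref.loc[common]).to_numpy(dtype=float)


def relative_expression(
    ct: pd.DataFrame,
    target: str,
    reference: str,
    control_condition: str,
    treat_condition: str,
    alpha: float = DEFAULT_ALPHA,
    fc_floor: float = DEFAULT_FC_FLOOR,
    equal_var: bool = True,
) -> ExpressionResult:
    """Livak ddCt contrast of one target gene between two conditions.

    The p-value is a two-sided two-sample Student's t-test on the replicate
    dCt sets (equal-variance by default; set ``equal_var=False`` for the
    Welch variant). With fewer than 2 replicates in either condition the
    p-value is NaN and the gene cannot be called significant.
    """
    ct = validate_ct_table(ct)
    dct_treat = _replicate_dct(ct, target, reference, treat_condition)
    dct_control = _replicate_dct(ct, target, reference, control_condition)
    ddct = float(dct_treat.mean() - dct_control.mean())
    fold = 2.0 ** (-ddct)
    if len(dct_treat) < 2 or len(dct_control) < 2:
        p = float("nan")
    else:
        p = float(stats.ttest_ind(dct_treat, dct_control, equal_var=equal_var).pvalue)
    significant = (not math.isnan(p)) and p < alpha and fold >= fc_floor
    return ExpressionResult(
        gene=target,
        condition=treat_condition,
        mean_dct_treat=float(dct_treat.mean()),
        mean_dct_control=float(dct_control.mean()),
        ddct=ddct,
        fold_change=fold,
        p_value=p,
        significant=significant,
    )


def call_significance(
    result: ExpressionResult,
    alpha: float = DEFAULT_ALPHA,
    fc_floor: float = DEFAULT_FC_FLOOR,
) -> bool:
    """Up-regulation call: p strictly below alpha AND fold change at or
    above the floor (defaults p < 0.05, fold >= 2.0)."""
    if math.isnan(result.p_value):
        return False
    return result.p_value < alpha and result.fold_change >= fc_floor


def between_gene_ratio(a: ExpressionResult, b: ExpressionResult) -> float:
    """Ratio of two genes' fold changes in the same condition (how many
    times more strongly a responds than b)."""
    if a.condition != b.condition:
        raise ValueError(
            f"cannot compare fold changes across conditions {a.condition!r} vs {b.condition!r}"
        )
    return a.fold_change / b.fold_change


def pool_technical_replicates(df: pd.DataFrame, group_col: str = "biological_replicate") -> pd.DataFrame:
    """Collapse technical replicates by averaging Ct within each biological
    replicate. Expects an extra column naming the biological replicate;
    returns a standard Ct table with one row per biological replicate."""
    if group_col not in df.columns:
        raise ValueError(f"Ct table lacks a {group_col!r} column")
    out = (
        df.groupby(["gene", "condition", group_col], as_index=False)["ct"].mean()
        .rename(columns={group_col: "replicate"})
    )
    return out[CT_COLUMNS]


def analyze_experiment(
    ct: pd.DataFrame,
    reference: str,
    control_condition: str,
    targets: Sequence[str] | None = None,
    conditions: Sequence[str] | None = None,
    alpha: float = DEFAULT_ALPHA,
    fc_floor: float = DEFAULT_FC_FLOOR,
    equal_var: bool = True,
) -> list[ExpressionResult]:
    """Run the ddCt contrast for every target gene in every non-control
    condition (defaults: all genes except the reference; all conditions
    except the control)."""
    ct = validate_ct_table(ct)
    if targets is None:
        targets = [g for g in ct["gene"].unique() if g != reference]
    if conditions is None:
        conditions = [c for c in ct["condition"].unique() if c != control_condition]
    return [
        relative_expression(ct, t, reference, control_condition, c,
                            alpha=alpha, fc_floor=fc_floor, equal_var=equal_var)
        for t in targets
        for c in conditions
    ]


EXPRESSION_COLUMNS = [
    "gene", "condition", "mean_dct_treat", "mean_dct_control", "ddct",
    "fold_change", "p_value", "significant",
]


def expression_table(results: Sequence[ExpressionResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": r.gene,
                "condition": r.condition,
                "mean_dct_treat": round(r.mean_dct_treat, 4),
                "mean_dct_control": round(r.mean_dct_control, 4),
                "ddct": round(r.ddct, 4),
                "fold_change": round(r.fold_change, 4),
                "p_value": format(r.p_value, ".3g"),
                "significant": r.significant,
            }
            for r in results
        ],
        columns=EXPRESSION_COLUMNS,
    )


def ratio_matrix(results: Sequence[ExpressionResult]) -> pd.DataFrame:
    """Per condition, the matrix of between-gene fold-change ratios
    (rows / columns)."""
    rows = []
    by_cond: dict[str, list[ExpressionResult]] = {}
    for r in results:
        by_cond.setdefault(r.condition, []).append(r)
    for cond, rs in by_cond.items():
        for a in rs:
            for b in rs:
                if a.gene != b.gene:
                    rows.append(
                        {"condition": cond, "gene_a": a.gene, "gene_b": b.gene,
                         "ratio": round(between_gene_ratio(a, b), 4)}
                    )
    return pd.DataFrame(rows, columns=["condition", "gene_a", "gene_b", "ratio"])
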