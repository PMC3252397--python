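"""ddCt relative quantification and significance calling."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from shspkit.expression import (
    ExpressionResult,
    analyze_experiment,
    between_gene_ratio,
    call_significance,
    measurements_to_frame,
    pool_technical_replicates,
    read_ct_table,
    relative_expression,
    summarize_ct,
    validate_ct_table,
)
from shspkit.expression import CtMeasurement
from shspkit.simulate import SimulationConfig, simulate_ct_table


def _table(rows):
    return validate_ct_table(pd.DataFrame(rows, columns=["gene", "condition", "replicate", "ct"]))


def _simple_experiment(treat_shift=-1.0):
    """Target and reference in control/treat; the target's Ct drops by
    ``-treat_shift`` cycles more than the reference under treatment."""
    rows = []
    for rep in range(1, 4):
        rows += [
            ("tgt", "ctrl", rep, 25.0 + 0.1 * rep),
            ("ref", "ctrl", rep, 20.0 + 0.1 * rep),
            ("tgt", "heat", rep, 25.0 + treat_shift + 0.1 * rep),
            ("ref", "heat", rep, 20.0 + 0.1 * rep),
        ]
    return _table(rows)


# --- summaries ---


@pytest.mark.parametrize(
    "values,expected",
    [([21, 21, 21], (21.0, 0.0, 3)), ([20, 21, 22], (21.0, 1.0, 3)), ([19.5], (19.5, 0.0, 1))],
)
def test_summarize_ct_examples(values, expected):
    mean, sd, n = summarize_ct(values)
    assert (mean, sd, n) == (pytest.approx(expected[0]), pytest.approx(expected[1]), expected[2])


def test_summarize_matches_two_pass_oracle():
    rng = np.random.default_rng(2)
    vals = rng.uniform(15, 35, size=9)
    mean, sd, n = summarize_ct(vals)
    m = sum(vals) / len(vals)
    s = math.sqrt(sum((v - m) ** 2 for v in vals) / (len(vals) - 1))
    assert mean == pytest.approx(m, abs=1e-12)
    assert sd == pytest.approx(s, abs=1e-12)


def test_summarize_empty_errors():
    with pytest.raises(ValueError):
        summarize_ct([])


# --- ddCt ---


def test_equal_dct_gives_fold_one():
    res = relative_expression(_simple_experiment(0.0), "tgt", "ref", "ctrl", "heat")
    assert res.ddct == pytest.approx(0.0)
    assert res.fold_change == pytest.approx(1.0)


def test_one_cycle_drop_doubles_expression():
    res = relative_expression(_simple_experiment(-1.0), "tgt", "ref", "ctrl", "heat")
    assert res.fold_change == pytest.approx(2.0)


def test_zero_noise_generator_fold_recovered_exactly():
    config = SimulationConfig(seed=5, ct_noise_sd=0.0)
    ct = simulate_ct_table(config)
    for (gene, cond), true_fold in config.ct_true_folds.items():
        if gene == config.reference_gene:
            continue
        res = relative_expression(ct, gene, config.reference_gene,
                                  config.control_condition, cond)
        assert res.fold_change == pytest.approx(true_fold, rel=1e-9)


def test_plate_shift_invariance():
    base = _simple_experiment(-2.0)
    shifted = base.copy()
    shifted.loc[shifted.condition == "heat", "ct"] += 3.7  # constant plate effect
    a = relative_expression(base, "tgt", "ref", "ctrl", "heat")
    b = relative_expression(shifted, "tgt", "ref", "ctrl", "heat")
    assert b.ddct == pytest.approx(a.ddct)
    assert b.fold_change == pytest.approx(a.fold_change)


@settings(derandomize=True, max_examples=30)
@given(st.floats(min_value=-5, max_value=5))
def test_fold_of_opposite_contrasts_multiply_to_one(ddct):
    assert 2.0 ** (-ddct) * 2.0 ** (ddct) == pytest.approx(1.0)


def test_missing_gene_errors():
    with pytest.raises(ValueError, match="no measurements"):
        relative_expression(_simple_experiment(), "nope", "ref", "ctrl", "heat")


def test_single_replicate_p_undefined_and_not_significant():
    rows = [("tgt", "ctrl", 1, 25.0), ("ref", "ctrl", 1, 20.0),
            ("tgt", "heat", 1, 22.0), ("ref", "heat", 1, 20.0)]
    res = relative_expression(_table(rows), "tgt", "ref", "ctrl", "heat")
    assert math.isnan(res.p_value) and not res.significant
    assert res.fold_change == pytest.approx(8.0)


def test_duplicate_measurement_rejected():
    rows = [("tgt", "ctrl", 1, 25.0), ("tgt", "ctrl", 1, 25.2)]
    with pytest.raises(ValueError, match="duplicate"):
        _table(rows)


# --- significance rule ---


@pytest.mark.parametrize(
    "p,fold,expected",
    [(0.01, 3.0, True), (0.01, 1.5, False), (0.20, 5.0, False),
     (0.049, 2.0, True), (0.05, 3.0, False)],  # threshold is strict: p < 0.05
)
def test_call_significance_rule(p, fold, expected):
    res = ExpressionResult("g", "c", 0, 0, 0, fold, p, False)
    assert call_significance(res) is expected


# --- between-gene ratios ---


def test_between_gene_ratio_arithmetic():
    a = ExpressionResult("a", "hs", 0, 0, 0, 40.0, 0.01, True)
    b = ExpressionResult("b", "hs", 0, 0, 0, 2.0, 0.01, True)
    assert between_gene_ratio(a, b) == pytest.approx(20.0)
    assert between_gene_ratio(a, a) == pytest.approx(1.0)


def test_between_gene_ratio_requires_same_condition():
    a = ExpressionResult("a", "hs15", 0, 0, 0, 4.0, 0.01, True)
    b = ExpressionResult("b", "hs30", 0, 0, 0, 2.0, 0.01, True)
    with pytest.raises(ValueError, match="conditions"):
        between_gene_ratio(a, b)


def test_configured_ratios_recovered_at_zero_noise():
    folds = {("g1", "hs"): 23.0, ("g2", "hs"): 2.0, ("g3", "hs"): 1.15}
    config = SimulationConfig(seed=1, ct_noise_sd=0.0, ct_true_folds=folds)
    ct = simulate_ct_table(config)
    res = {r.gene: r for r in analyze_experiment(ct, "alaS", "control_30C")}
    assert between_gene_ratio(res["g1"], res["g2"]) == pytest.approx(11.5, rel=1e-9)
    assert between_gene_ratio(res["g1"], res["g3"]) == pytest.approx(20.0, rel=1e-9)


# --- tables and replicate pooling ---


def test_measurements_to_frame_and_io_roundtrip(tmp_path):
    ms = [CtMeasurement("g", "c", r, 20.0 + r) for r in (1, 2, 3)]
    df = measurements_to_frame(ms)
    path = tmp_path / "ct.tsv"
    df.to_csv(path, sep="\t", index=False)
    assert read_ct_table(path).equals(df)


def test_pool_technical_replicates_averages_within_biological():
    rows = []
    for bio in (1, 2, 3):
        for tech_offset in (-0.1, 0.0, 0.1):
            rows.append({"gene": "g", "condition": "c", "replicate": 0,
                         "biological_replicate": bio, "ct": 20.0 + bio + tech_offset})
    df = pd.DataFrame(rows)
    pooled = pool_technical_replicates(df)
    assert len(pooled) == 3
    assert sorted(pooled["ct"]) == pytest.approx([21.0, 22.0, 23.0])
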