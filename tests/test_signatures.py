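"""Signature construction: fold-change convention, t-test, filtering, collapse."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sigoverlap import (
    DifferentialResult,
    ExpressionDataset,
    build_signature,
    collapse_probes,
    differential_expression,
    signature_from_results,
    signed_fold_change,
    two_group_t_test,
)
from sigoverlap.signatures import normalize_gene_id

finite = st.floats(min_value=-30, max_value=30, allow_nan=False)


@pytest.mark.parametrize(
    "num, den, expected",
    [(4.0, 3.0, 2.0), (3.0, 4.0, -2.0), (3.0, 3.0, 1.0)],
)
def test_signed_fold_change_convention(num, den, expected):
    assert signed_fold_change(num, den) == pytest.approx(expected)


@pytest.mark.parametrize("bad", [float("nan"), float("inf"), -float("inf")])
def test_signed_fold_change_rejects_non_finite(bad):
    with pytest.raises(ValueError):
        signed_fold_change(bad, 0.0)
    with pytest.raises(ValueError):
        signed_fold_change(0.0, bad)


@given(a=finite, b=finite)
@settings(deadline=None)
def test_signed_fold_change_antisymmetric_and_bounded(a, b):
    fc = signed_fold_change(a, b)
    assert abs(fc) >= 1.0
    if a == b:
        assert fc == 1.0
    else:
        assert signed_fold_change(b, a) == pytest.approx(-fc)


def test_t_test_identical_groups_is_one():
    assert two_group_t_test([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)


def test_t_test_symmetric_under_group_swap():
    a, b = [0.3, 1.1, 0.7, 0.2], [1.9, 2.4, 2.2]
    assert two_group_t_test(a, b) == two_group_t_test(b, a)


def test_t_test_matches_incomplete_beta_oracle():
    # Welch df is exactly 6 for these groups; exact two-sided p computed
    # independently as the regularized incomplete beta I_{df/(df+t^2)}(3, 1/2)
    # to 20 digits with sympy
    p = two_group_t_test([0.0, 0.1, -0.1, 0.05], [2.0, 2.1, 1.9, 2.05])
    assert p == pytest.approx(5.0384423465763500324e-08, rel=1e-9)


def test_t_test_degenerate_and_invalid_inputs():
    assert two_group_t_test([2.0, 2.0, 2.0], [2.0, 2.0]) == 1.0
    p = two_group_t_test([1.0, 1.0], [2.0, 2.0])
    assert 0 < p < 1e-300
    with pytest.raises(ValueError):
        two_group_t_test([1.0], [1.0, 2.0])


def _result(fid, fc, p):
    return DifferentialResult(fid, 0.0, 0.0, fc, p)


@pytest.mark.parametrize(
    "fc, p, included",
    [
        (1.25, 0.01, True),   # passes both strict thresholds
        (-1.19, 0.001, False),  # |FC| below threshold
        (1.20, 0.01, False),  # boundary: threshold is strict
        (1.5, 0.05, False),   # boundary p: strict
    ],
)
def test_threshold_filter_is_strict(fc, p, included):
    sig = signature_from_results([_result("GENE1", fc, p)], 1.2, 0.05, "s")
    assert (len(sig) == 1) is included
    if included:
        assert sig.entries[0].direction == ("up" if fc > 0 else "down")


def test_ranking_rule_p_then_fc_then_id():
    results = [
        _result("B", 1.5, 0.01),
        _result("A", -3.0, 0.01),
        _result("C", 1.5, 0.001),
        _result("D", -3.0, 0.01),
    ]
    sig = signature_from_results(results, 1.0, 1.0, "s")
    assert sig.gene_ids == ("C", "A", "D", "B")
    assert [e.rank for e in sig.entries] == [1, 2, 3, 4]


@given(
    data=st.lists(
        st.tuples(
            st.floats(min_value=-4, max_value=4, allow_nan=False),
            st.floats(min_value=1e-6, max_value=1.0, exclude_max=True),
        ),
        min_size=0,
        max_size=30,
    ),
    fc_thr=st.floats(min_value=1.0, max_value=3.0),
    p_thr=st.floats(min_value=0.01, max_value=1.0),
)
@settings(deadline=None, max_examples=50)
def test_filtering_is_monotone_in_thresholds(data, fc_thr, p_thr):
    results = [
        _result(f"G{i}", signed_fold_change(x, 0.0), p) for i, (x, p) in enumerate(data)
    ]
    base = signature_from_results(results, 1.0, 1.0, "s")
    # the widest thresholds keep every feature with p < 1 that changed at all
    # (|FC| strictly above 1; a fold change of exactly 1 has no direction)
    assert base.gene_set == {
        normalize_gene_id(r.feature_id)
        for r in results
        if r.p_value < 1 and abs(r.signed_fold_change) > 1
    }
    tighter = signature_from_results(results, fc_thr, p_thr, "s")
    assert tighter.gene_set <= base.gene_set


def test_collapse_probes_rules():
    results = [
        _result("p1", 1.5, 0.01),
        _result("p2", 2.0, 0.04),
        _result("p3", -1.8, 0.02),
        _result("p4", 1.5, 0.01),
        _result("p5", 2.0, 0.01),
        _result("p6", 1.4, 0.5),
    ]
    mapping = {"p1": "GENE1", "p2": "GENE1", "p3": "gene2 ",
               "p4": "GENE3", "p5": "GENE3"}
    out = {r.feature_id: r for r in collapse_probes(results, mapping)}
    assert set(out) == {"GENE1", "GENE2", "GENE3"}  # size = distinct mapped genes
    assert out["GENE1"].p_value == 0.01 and out["GENE1"].signed_fold_change == 1.5
    assert out["GENE2"].signed_fold_change == -1.8  # single probe passthrough
    assert out["GENE3"].signed_fold_change == 2.0  # p tie -> larger |FC|


def test_collapse_probes_lexicographic_tiebreak():
    results = [_result("pB", 2.0, 0.01), _result("pA", -2.0, 0.01)]
    out = collapse_probes(results, {"pA": "G", "pB": "G"})
    assert out[0].signed_fold_change == -2.0  # pA wins the full tie


def _two_group_dataset(values, n1, n2, roles=("patient", "control")):
    values = np.asarray(values, dtype=float)
    samples = [f"s{i}" for i in range(n1 + n2)]
    groups = {s: (roles[0] if i < n1 else roles[1]) for i, s in enumerate(samples)}
    return ExpressionDataset(
        "ds", [f"G{i}" for i in range(values.shape[0])], values, samples, groups, roles
    )


def test_differential_expression_recovers_planted_shift():
    rng = np.random.default_rng(42)
    base = rng.normal(8, 0.1, size=(5, 12))
    base[0, :6] += 1.0  # planted up-shift in the numerator group
    ds = _two_group_dataset(base, 6, 6)
    res = differential_expression(ds)
    assert res[0].signed_fold_change == pytest.approx(
        2 ** (res[0].mean_log2_numerator - res[0].mean_log2_denominator)
    )
    sig = build_signature(ds, 1.2, 0.05)
    assert sig.gene_ids == ("G0",)
    assert sig.entries[0].direction == "up"


def test_dataset_validation():
    vals = np.zeros((2, 4))
    samples = ["a", "b", "c", "d"]
    groups = {s: ("x" if i < 2 else "y") for i, s in enumerate(samples)}
    with pytest.raises(ValueError):  # duplicate feature ids
        ExpressionDataset("d", ["G", "G"], vals, samples, groups, ("x", "y"))
    with pytest.raises(ValueError):  # non-finite values
        ExpressionDataset("d", ["G1", "G2"], vals * np.nan, samples, groups, ("x", "y"))
    with pytest.raises(ValueError):  # a group with < 2 samples
        g3 = {"a": "x", "b": "y", "c": "y", "d": "y"}
        ExpressionDataset("d", ["G1", "G2"], vals, samples, g3, ("x", "y"))
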