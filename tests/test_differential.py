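"""Differential calling: imputation, t-test, BH, classification, CV, Venn."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from radprot import differential as dm
from radprot.simulate import gen_quant

from _oracles import bh_oracle


@pytest.mark.parametrize(
    "r1,r2,expected",
    [(1.2, 1.8, (1.2, 1.8, 1.5)), (1.0, 1.0, (1.0, 1.0, 1.0)), (0.5, 1.5, (0.5, 1.5, 1.0))],
)
def test_impute_triplicate_is_arithmetic_mean(r1, r2, expected):
    assert dm.impute_triplicate(r1, r2) == pytest.approx(expected)


def test_impute_triplicate_rejects_nonpositive():
    with pytest.raises(ValueError):
        dm.impute_triplicate(0.0, 1.0)


def test_t_test_on_log2_triple_matches_hand_computation():
    # log2 of (1.2, 1.8, 1.5) = (0.263034, 0.847997, 0.584963);
    # mean 0.565331, sd 0.292968 -> t = 3.342, two-sided p from t(df=2).
    t_hand = 0.565331 / (0.292968 / math.sqrt(3))
    p_expected = 2 * stats.t.sf(abs(t_hand), df=2)
    p = dm.protein_t_test(dm.impute_triplicate(1.2, 1.8))
    assert t_hand == pytest.approx(3.342, abs=1e-3)
    assert p == pytest.approx(p_expected, rel=1e-4)


@pytest.mark.parametrize("a", [1.0, 0.7, 2.5])
def test_t_test_zero_variance_is_not_testable(a):
    assert math.isnan(dm.protein_t_test((a, a, a)))


def test_ks_accepts_normal_rejects_two_point():
    rng = np.random.default_rng(42)
    accepted = sum(dm.ks_normality(rng.normal(0, 1, 1000))[1] > 0.05 for _ in range(100))
    assert accepted >= 95
    two_point = rng.choice([-1.0, 1.0], size=1000)
    assert dm.ks_normality(two_point)[1] < 1e-3
    with pytest.raises(ValueError):
        dm.ks_normality([1.0, 1.0, 1.0])
    with pytest.raises(ValueError):
        dm.ks_normality([1.0, 2.0])


@pytest.mark.parametrize(
    "p_in,expected",
    [
        ([0.005, 0.01, 0.03, 0.04], [0.02, 0.02, 0.04, 0.04]),
        ([0.5], [0.5]),
        ([1.0, 1.0], [1.0, 1.0]),
    ],
)
def test_bh_known_values(p_in, expected):
    assert dm.bh_adjust(p_in) == pytest.approx(expected)


def test_bh_matches_bruteforce_and_statsmodels():
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(0)
    for _ in range(50):
        p = rng.uniform(0, 1, size=rng.integers(1, 40))
        ours = dm.bh_adjust(p)
        assert np.allclose(ours, bh_oracle(p))
        assert np.allclose(ours, multipletests(p, method="fdr_bh")[1])


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        dm.bh_adjust([0.5, 1.5])


@pytest.mark.parametrize(
    "fc,p_adj,expected",
    [(1.25, 0.05, "up"), (1.25, 0.20, "unchanged"), (0.80, 0.01, "down"),
     (1.2, 0.1, "up"), (0.83, 0.1, "down"), (1.19, 0.001, "unchanged")],
)
def test_classify_thresholds(fc, p_adj, expected):
    assert dm.classify(fc, p_adj) == expected


@settings(max_examples=200, derandomize=True)
@given(
    fc=st.floats(0.01, 10.0),
    p1=st.floats(0.0, 1.0),
    p2=st.floats(0.0, 1.0),
)
def test_classify_monotone_in_p(fc, p1, p2):
    """Raising the adjusted p never turns unchanged into a call."""
    lo, hi = sorted([p1, p2])
    if dm.classify(fc, lo) == "unchanged":
        assert dm.classify(fc, hi) == "unchanged"


@pytest.mark.parametrize(
    "reps,expected",
    [([10, 10], 0.0), ([8, 12], 28.284), ([1.2, 1.8], 28.284)],
)
def test_percent_cv(reps, expected):
    assert dm.percent_cv(reps) == pytest.approx(expected, abs=1e-3)


def test_percent_cv_rejects_single_value():
    with pytest.raises(ValueError):
        dm.percent_cv([5.0])


def test_venn_partition_enumeration():
    sets = {"A": {1, 2, 3}, "B": {2, 3, 4}, "C": {3}}
    regions = dm.venn_partition(sets)
    assert regions == {
        "A": 1, "B": 1, "C": 0, "A&B": 1, "A&C": 0, "B&C": 0, "A&B&C": 1,
    }
    union = len({1, 2, 3, 4})
    assert sum(regions.values()) == union


def test_venn_identical_and_disjoint_sets():
    same = {"A": {1, 2}, "B": {1, 2}, "C": {1, 2}}
    assert dm.venn_partition(same)["A&B&C"] == 2
    assert sum(dm.venn_partition(same).values()) == 2
    disjoint = {"A": {1}, "B": {2}, "C": {3}}
    regions = dm.venn_partition(disjoint)
    assert regions["A"] == regions["B"] == regions["C"] == 1
    assert all(v == 0 for k, v in regions.items() if "&" in k)


@settings(max_examples=50, derandomize=True)
@given(
    a=st.sets(st.integers(0, 20)),
    b=st.sets(st.integers(0, 20)),
    c=st.sets(st.integers(0, 20)),
)
def test_venn_regions_sum_to_union(a, b, c):
    regions = dm.venn_partition({"A": a, "B": b, "C": c})
    assert sum(regions.values()) == len(a | b | c)


def test_call_differential_roundtrip_and_degenerates():
    quant = pd.DataFrame(
        {
            "protein_id": ["p1", "p1", "p2", "p2", "p3", "p3"],
            "group": "II",
            "replicate": [1, 2, 1, 2, 1, 2],
            "ratio": [1.5, 1.7, 1.0, 1.0, 0.5, 0.6],
        }
    )
    calls, qc = dm.call_differential(quant)
    p2 = calls.set_index("protein_id").loc["p2"]
    assert not p2["testable"] and math.isnan(p2["p_raw"])
    assert p2["status"] == "unchanged"
    assert (calls["p_adj"].dropna() >= calls["p_raw"].dropna()).all()
    assert qc.loc[0, "n_not_testable"] == 1


def test_null_data_controls_false_discoveries():
    """Global null: fraction passing both the adjusted-P and fold-change
    gates stays below alpha plus 3 sampling errors (conservative: the
    pseudo-triplicate makes the test anti-conservative in p but the FC gate
    dominates)."""
    fractions = []
    for seed in range(200):
        quant, _ = gen_quant(300, 0.0, replicate_noise_sd=0.1,
                             groups=("II",), seed=seed)
        calls, _ = dm.call_differential(quant)
        hit = (calls["p_adj"] <= 0.1) & (calls["log2_fc"].abs() >= 0.263)
        fractions.append(hit.mean())
    fractions = np.array(fractions)
    se = fractions.std(ddof=1) / math.sqrt(len(fractions))
    assert fractions.mean() <= 0.1 + 3 * se
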