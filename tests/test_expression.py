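"""TPM normalization, tissue aggregation and bait-gene PCC."""
import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, settings, strategies as st

from baitrank.errors import InputError
from baitrank.expression import (
    CountMatrix,
    bait_pcc,
    compute_tpm,
    tissue_mean_tpm,
)

from .helpers import make_tpm, pearson_sigma_formula


def _cm(counts, lengths, tissues=None):
    counts = pd.DataFrame(counts).T
    counts.columns = [f"s{i+1}" for i in range(counts.shape[1])]
    tissues = tissues or {c: "t1" for c in counts.columns}
    return CountMatrix(
        counts=counts,
        lengths=pd.Series(lengths),
        sample_tissue=pd.Series(tissues),
    )


def test_tpm_two_gene_hand_example():
    # length-normalized rates 0.01 and 0.03 -> 250,000 / 750,000
    cm = _cm({"gA": [10], "gB": [90]}, {"gA": 1000, "gB": 3000})
    tm = compute_tpm(cm)
    assert tm.tpm.loc["gA", "s1"] == pytest.approx(250_000.0)
    assert tm.tpm.loc["gB", "s1"] == pytest.approx(750_000.0)


def test_tpm_single_gene_normalizes_to_million():
    cm = _cm({"gA": [7]}, {"gA": 1234})
    assert compute_tpm(cm).tpm.loc["gA", "s1"] == pytest.approx(1e6)


def test_tpm_all_zero_column_yields_zero_not_crash():
    cm = _cm({"gA": [0, 5], "gB": [0, 5]}, {"gA": 1000, "gB": 1000})
    tm = compute_tpm(cm)
    assert (tm.tpm["s1"] == 0).all()
    assert tm.tpm["s2"].sum() == pytest.approx(1e6)


def test_tpm_column_sums_are_one_million():
    rng = np.random.default_rng(5)
    counts = {f"g{i}": list(rng.integers(0, 500, size=6)) for i in range(40)}
    lengths = {f"g{i}": int(rng.integers(300, 5000)) for i in range(40)}
    tm = compute_tpm(_cm(counts, lengths))
    np.testing.assert_allclose(tm.tpm.sum(axis=0), 1e6, rtol=1e-6)


def test_nonpositive_length_rejected():
    with pytest.raises(InputError):
        _cm({"gA": [1]}, {"gA": 0})


def test_negative_counts_rejected():
    with pytest.raises(InputError):
        _cm({"gA": [-1]}, {"gA": 100})


def test_unmapped_sample_rejected():
    with pytest.raises(InputError):
        _cm({"gA": [1, 2]}, {"gA": 100}, tissues={"s1": "t1"})


@pytest.mark.parametrize(
    "values,expected",
    [((2000.0, 4000.0), 3000.0), ((3000.0,), 3000.0), ((0.0, 0.0, 3000.0), 1000.0)],
)
def test_tissue_mean_tpm(values, expected):
    tissues = {f"s{i+1}": "primordia" for i in range(len(values))}
    tm = make_tpm({"gA": list(values)}, tissue_of=tissues)
    assert tissue_mean_tpm(tm, "primordia")["gA"] == pytest.approx(expected)


def test_tissue_mean_unknown_tissue_errors():
    tm = make_tpm({"gA": [1.0, 2.0]})
    with pytest.raises(InputError, match="unknown tissue"):
        tissue_mean_tpm(tm, "petals")


def test_pcc_self_and_anticorrelation():
    bait = [10.0, 20.0, 30.0, 40.0]
    anti = [40.0, 30.0, 20.0, 10.0]
    tm = make_tpm({"bait": bait, "same": list(bait), "anti": anti})
    res = bait_pcc(tm, "bait")
    assert res.pcc["bait"] == pytest.approx(1.0, abs=1e-12)
    assert res.pcc["same"] == pytest.approx(1.0, abs=1e-12)
    assert res.pcc["anti"] == pytest.approx(-1.0, abs=1e-12)


def test_pcc_hand_example():
    tm = make_tpm({"bait": [1, 2, 3, 4], "g": [1, 2, 3, 5]})
    res = bait_pcc(tm, "bait")
    assert res.pcc["g"] == pytest.approx(0.98270763, abs=1e-8)


def test_pcc_zero_variance_gene_undefined():
    tm = make_tpm({"bait": [1.0, 2.0, 3.0], "flat": [5.0, 5.0, 5.0]})
    res = bait_pcc(tm, "bait")
    assert not res.defined["flat"]
    assert np.isnan(res.pcc["flat"])
    assert res.defined["bait"]


def test_pcc_zero_variance_bait_all_undefined():
    tm = make_tpm({"bait": [5.0, 5.0, 5.0], "g": [1.0, 2.0, 3.0]})
    res = bait_pcc(tm, "bait")
    assert not res.defined.any()
    assert res.pcc.isna().all()


def test_pcc_bait_absent_or_too_few_samples():
    tm = make_tpm({"gA": [1.0, 2.0, 3.0]})
    with pytest.raises(InputError, match="bait"):
        bait_pcc(tm, "missing")
    tm2 = make_tpm({"bait": [1.0, 2.0], "g": [2.0, 1.0]})
    with pytest.raises(InputError, match="3 samples"):
        bait_pcc(tm2, "bait")


def test_pcc_matches_sigma_formula_oracle_random_vectors():
    rng = np.random.default_rng(42)
    for _ in range(200):
        bait = rng.uniform(0, 1000, size=10)
        gene = rng.uniform(0, 1000, size=10)
        tm = make_tpm({"bait": list(bait), "g": list(gene)})
        res = bait_pcc(tm, "bait")
        expected = pearson_sigma_formula(list(bait), list(gene))
        assert res.pcc["g"] == pytest.approx(expected, abs=1e-12)
        # independent library cross-check
        assert res.pcc["g"] == pytest.approx(
            scipy.stats.pearsonr(bait, gene).statistic, abs=1e-12
        )


@given(
    scale=st.floats(min_value=0.01, max_value=100),
    offset=st.floats(min_value=-50, max_value=50),
)
@settings(derandomize=True, max_examples=60, deadline=None)
def test_pcc_affine_invariance_and_sign_flip(scale, offset):
    rng = np.random.default_rng(7)
    bait = rng.uniform(0, 100, size=8)
    gene = rng.uniform(0, 100, size=8)
    base = bait_pcc(make_tpm({"bait": list(bait), "g": list(gene)}), "bait").pcc["g"]
    pos = bait_pcc(
        make_tpm({"bait": list(bait), "g": list(scale * gene + offset)}), "bait"
    ).pcc["g"]
    neg = bait_pcc(
        make_tpm({"bait": list(bait), "g": list(-scale * gene + offset)}), "bait"
    ).pcc["g"]
    assert pos == pytest.approx(base, abs=1e-9)
    assert neg == pytest.approx(-base, abs=1e-9)


def test_pcc_tissue_means_switch():
    tissues = {"s1": "a", "s2": "a", "s3": "b", "s4": "b", "s5": "c", "s6": "c"}
    bait = [1.0, 3.0, 10.0, 12.0, 4.0, 6.0]
    gene = [2.0, 2.0, 11.0, 11.0, 5.0, 5.0]  # equals bait's tissue means
    tm = make_tpm({"bait": bait, "g": gene}, tissue_of=tissues)
    res = bait_pcc(tm, "bait", tissue_means=True)
    assert res.n_samples_used == 3
    assert res.pcc["g"] == pytest.approx(1.0, abs=1e-12)
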