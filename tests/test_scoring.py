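"""Sub-score ramps, composite summation and ranking rules."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from baitrank.errors import ConfigError, InputError
from baitrank.models import BgcStatus, CandidateScore
from baitrank.scoring import (
    ScoringConfig,
    abundance_subscore,
    bgc_subscore,
    coexpr_subscore,
    composite_score,
    rank_candidates,
    report_score,
)

CFG = ScoringConfig()


@pytest.mark.parametrize(
    "pcc,expected",
    [
        (0.9, 1.0),  # score saturates at the upper knot
        (0.95, 1.0),
        (0.85, 0.5),  # linear midpoint of the 0.8-0.9 ramp
        (0.8, 0.0),
        (0.79, 0.0),
        (-1.0, 0.0),
        (None, 0.0),  # undefined PCC maps to 0
        (float("nan"), 0.0),
    ],
)
def test_coexpr_subscore_ramp(pcc, expected):
    assert coexpr_subscore(pcc, CFG) == pytest.approx(expected, abs=1e-15)


@pytest.mark.parametrize(
    "tpm,expected",
    [
        (3000.0, 1.0),
        (5000.0, 1.0),
        (2000.0, 0.5),  # midpoint of the 1,000-3,000 ramp
        (1000.0, 0.0),
        (0.0, 0.0),
    ],
)
def test_abundance_subscore_ramp(tpm, expected):
    assert abundance_subscore(tpm, CFG) == pytest.approx(expected, abs=1e-15)


def test_bgc_subscore_mapping():
    assert bgc_subscore(BgcStatus.IN_CHARACTERIZED_CLUSTER, CFG) == 1.0
    assert bgc_subscore(BgcStatus.IN_OTHER_CLUSTER, CFG) == 0.5
    assert bgc_subscore(BgcStatus.UNCLUSTERED, CFG) == 0.0


def test_subscore_input_errors():
    with pytest.raises(InputError):
        coexpr_subscore(1.5, CFG)
    with pytest.raises(InputError):
        abundance_subscore(-1.0, CFG)


def test_config_invariants():
    with pytest.raises(ConfigError):
        ScoringConfig(pcc_lo=0.9, pcc_hi=0.8)
    with pytest.raises(ConfigError):
        ScoringConfig(tpm_lo=3000, tpm_hi=1000)
    with pytest.raises(ConfigError):
        ScoringConfig(bgc_char_bonus=1.5)


@pytest.mark.parametrize(
    "pcc,tpm,status,expected",
    [
        (0.95, 4000.0, BgcStatus.IN_CHARACTERIZED_CLUSTER, 3.0),
        (0.95, 4000.0, BgcStatus.IN_OTHER_CLUSTER, 2.5),
        (0.0, 0.0, BgcStatus.UNCLUSTERED, 0.0),
    ],
)
def test_composite_worked_values(pcc, tpm, status, expected):
    s = composite_score("g", pcc, tpm, status, CFG)
    assert s.composite == expected
    assert report_score(s.composite) == round(expected, 2)


def test_composite_is_exact_sum():
    rng = np.random.default_rng(0)
    for _ in range(200):
        pcc = float(rng.uniform(-1, 1))
        tpm = float(rng.uniform(0, 6000))
        status = [BgcStatus.UNCLUSTERED, BgcStatus.IN_OTHER_CLUSTER,
                  BgcStatus.IN_CHARACTERIZED_CLUSTER][int(rng.integers(0, 3))]
        s = composite_score("g", pcc, tpm, status, CFG)
        assert s.composite == s.c_coexpr + s.c_abund + s.c_bgc  # no re-rounding
        assert 0.0 <= s.composite <= 3.0


def test_ramps_continuous_at_knots():
    eps = 1e-9
    for f, lo, hi in [
        (lambda v: coexpr_subscore(v, CFG), CFG.pcc_lo, CFG.pcc_hi),
        (lambda v: abundance_subscore(v, CFG), CFG.tpm_lo, CFG.tpm_hi),
    ]:
        assert f(lo) == 0.0 and f(hi) == 1.0
        assert f(lo + eps * (hi - lo)) == pytest.approx(0.0, abs=1e-8)
        assert f(hi - eps * (hi - lo)) == pytest.approx(1.0, abs=1e-8)


@given(
    a=st.floats(min_value=-1, max_value=1),
    b=st.floats(min_value=-1, max_value=1),
)
@settings(derandomize=True, max_examples=100)
def test_coexpr_subscore_monotone(a, b):
    lo, hi = sorted((a, b))
    assert coexpr_subscore(lo, CFG) <= coexpr_subscore(hi, CFG)


@given(
    a=st.floats(min_value=0, max_value=10_000),
    b=st.floats(min_value=0, max_value=10_000),
)
@settings(derandomize=True, max_examples=100)
def test_abundance_subscore_monotone(a, b):
    lo, hi = sorted((a, b))
    assert abundance_subscore(lo, CFG) <= abundance_subscore(hi, CFG)


def test_subscore_monotone_on_grid():
    grid = np.linspace(-1, 1, 401)
    vals = [coexpr_subscore(float(v), CFG) for v in grid]
    assert all(b >= a for a, b in zip(vals, vals[1:]))
    assert all(0.0 <= v <= 1.0 for v in vals)
    tgrid = np.linspace(0, 6000, 601)
    tvals = [abundance_subscore(float(v), CFG) for v in tgrid]
    assert all(b >= a for a, b in zip(tvals, tvals[1:]))


def _cs(gene_id, composite, pcc, tpm, enzyme_class=None):
    return CandidateScore(
        gene_id=gene_id, c_coexpr=0, c_abund=0, c_bgc=0, composite=composite,
        pcc=pcc, primordium_tpm=tpm, bgc_status=BgcStatus.UNCLUSTERED,
        enzyme_class=enzyme_class,
    )


def test_rank_tiebreak_by_pcc():
    scores = [
        _cs("gA", 2.5, 0.92, 100.0),
        _cs("gB", 3.0, 0.99, 100.0),
        _cs("gC", 2.5, 0.99, 100.0),
    ]
    ranked = rank_candidates(scores, ScoringConfig(top_n=None))
    assert [s.gene_id for s in ranked] == ["gB", "gC", "gA"]
    assert [s.rank for s in ranked] == [1, 2, 3]


def test_rank_top_n_truncation():
    scores = [_cs(f"g{i}", float(i), 0.0, 0.0) for i in range(3)]
    ranked = rank_candidates(scores, ScoringConfig(top_n=1))
    assert len(ranked) == 1
    assert ranked[0].gene_id == "g2" and ranked[0].rank == 1


def test_rank_class_whitelist_before_topn():
    wl = frozenset({"SDR-reductase", "BAHD-acyltransferase", "glycosyltransferase"})
    scores = [
        _cs("g1", 3.0, 0.99, 100.0, "CYP"),
        _cs("g2", 2.5, 0.9, 100.0, "glycosyltransferase"),
        _cs("g3", 2.0, 0.8, 100.0, "SDR-reductase"),
    ]
    ranked = rank_candidates(
        scores, ScoringConfig(top_n=2, class_whitelist=wl)
    )
    assert [s.gene_id for s in ranked] == ["g2", "g3"]
    # after-topN order instead keeps only whitelisted genes within the raw top 2
    ranked_after = rank_candidates(
        scores,
        ScoringConfig(top_n=2, class_whitelist=wl, whitelist_before_topn=False),
    )
    assert [s.gene_id for s in ranked_after] == ["g2"]


def test_rank_deterministic_gene_id_tiebreak():
    scores = [_cs(g, 1.0, 0.5, 50.0) for g in ("gB", "gA", "gC")]
    ranked = rank_candidates(scores, ScoringConfig(top_n=None))
    assert [s.gene_id for s in ranked] == ["gA", "gB", "gC"]


def test_undefined_pcc_sorts_last_among_ties():
    scores = [_cs("gA", 1.0, None, 50.0), _cs("gB", 1.0, 0.1, 50.0)]
    ranked = rank_candidates(scores, ScoringConfig(top_n=None))
    assert [s.gene_id for s in ranked] == ["gB", "gA"]
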