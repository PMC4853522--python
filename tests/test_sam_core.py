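"""SAM engine: regression exactness, fudge factor, permutation null, FDR."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

import traitsam as ts
from traitsam.preprocess import WeightedResponse
from traitsam.sam_core import SamError, _slopes_and_errors

from conftest import make_matrix


def _response(y, trait="t", method="minmax"):
    y = np.asarray(y, dtype=float)
    return WeightedResponse(trait, method, [f"S{j}" for j in range(y.size)], y)


def lstsq_oracle(x, y):
    """Independent per-probe least squares via the normal equations."""
    A = np.column_stack([np.ones_like(y), y])
    coef, *_ = np.linalg.lstsq(A, x, rcond=None)
    resid = x - A @ coef
    dof = len(y) - 2
    sigma2 = (resid ** 2).sum() / dof
    syy = ((y - y.mean()) ** 2).sum()
    return coef[1], np.sqrt(sigma2 / syy)


# ---------------------------------------------------------------------------
# regression scores
# ---------------------------------------------------------------------------

def test_scores_match_least_squares_oracle():
    rng = np.random.default_rng(42)
    for _ in range(20):
        n = int(rng.integers(5, 11))
        m = int(rng.integers(2, 21))
        X = rng.normal(size=(m, n))
        y = np.linspace(0, 1, n)
        scores = ts.compute_regression_scores(make_matrix(X), _response(y),
                                              s0=0.3)
        for i in range(m):
            r_ref, s_ref = lstsq_oracle(X[i], y)
            assert scores.r[i] == pytest.approx(r_ref, abs=1e-10)
            assert scores.s[i] == pytest.approx(s_ref, abs=1e-10)
            assert scores.d[i] == scores.r[i] / (scores.s[i] + 0.3)


def test_perfect_fit_probe():
    """x == y exactly: slope 1, zero residual SE, d = 1/(0+s0)."""
    y = np.array([0.0, 0.25, 0.5, 1.0])
    scores = ts.compute_regression_scores(make_matrix(y[None, :]), _response(y),
                                          s0=1.0)
    assert scores.r[0] == pytest.approx(1.0)
    assert scores.s[0] == pytest.approx(0.0, abs=1e-12)
    assert scores.d[0] == pytest.approx(1.0)


def test_constant_probe_scores_zero():
    y = np.array([0.0, 0.5, 0.5, 1.0])
    scores = ts.compute_regression_scores(make_matrix(np.full((1, 4), 7.0)),
                                          _response(y), s0=0.0)
    assert scores.r[0] == 0.0 and scores.s[0] == 0.0 and scores.d[0] == 0.0


def test_scores_preconditions():
    y3 = np.array([0.0, 0.5, 1.0])
    with pytest.raises(SamError, match="4 samples"):
        ts.compute_regression_scores(make_matrix(np.ones((1, 3))),
                                     _response(y3), s0=0.0)
    with pytest.raises(SamError):
        ts.compute_regression_scores(make_matrix(np.ones((1, 4))),
                                     _response([0, 1, 0, 1]), s0=-1.0)


def test_scale_equivariance_and_sign_symmetry():
    rng = np.random.default_rng(5)
    X = rng.normal(size=(15, 8))
    y = rng.uniform(size=8)
    y[0], y[1] = 0.0, 1.0
    base = ts.compute_regression_scores(make_matrix(X), _response(y), s0=0.0)
    scaled = ts.compute_regression_scores(make_matrix(3.5 * X), _response(y),
                                          s0=0.0)
    np.testing.assert_allclose(scaled.r, 3.5 * base.r, rtol=1e-12)
    np.testing.assert_allclose(scaled.s, 3.5 * base.s, rtol=1e-12)
    np.testing.assert_allclose(scaled.d, base.d, rtol=1e-9)
    flipped = ts.compute_regression_scores(make_matrix(X), _response(1.0 - y),
                                           s0=0.0)
    np.testing.assert_allclose(flipped.r, -base.r, rtol=1e-10, atol=1e-12)
    np.testing.assert_allclose(flipped.d, -base.d, rtol=1e-9, atol=1e-12)


def test_column_permutation_invariance():
    """Reordering samples together with their responses leaves d unchanged."""
    rng = np.random.default_rng(6)
    X = rng.normal(size=(10, 8))
    y = np.linspace(0, 1, 8)
    base = ts.compute_regression_scores(make_matrix(X), _response(y), s0=0.1)
    perm = rng.permutation(8)
    other = ts.compute_regression_scores(make_matrix(X[:, perm]),
                                         _response(y[perm]), s0=0.1)
    np.testing.assert_allclose(other.d, base.d, rtol=0, atol=1e-12)


# ---------------------------------------------------------------------------
# fudge factor
# ---------------------------------------------------------------------------

def test_estimate_s0_constant_s():
    r = np.arange(10.0)
    s0, alpha = ts.estimate_s0(r, np.full(10, 0.7))
    assert s0 == pytest.approx(0.7)


def test_estimate_s0_is_a_percentile_of_s():
    rng = np.random.default_rng(7)
    r = rng.normal(size=300)
    s = np.abs(rng.normal(1.0, 0.3, size=300)) + 0.05
    s0, alpha = ts.estimate_s0(r, s)
    assert s0 == pytest.approx(np.percentile(s, alpha))


def test_estimate_s0_stabilizes_small_s_inflation():
    """With variance inflation at small s, the chosen s0 beats s0 = 0.

    Oracle: exhaustive evaluation of the same candidate grid with the same
    bin-spread criterion, written independently below.
    """
    rng = np.random.default_rng(8)
    m = 2000
    s = np.sort(np.abs(rng.normal(0.2, 0.15, size=m))) + 1e-3
    r = rng.normal(size=m) * (s + 0.02)  # small-s probes get inflated d at s0=0
    s0, alpha = ts.estimate_s0(r, s)

    def cv_for(s0c):
        d = r / (s + s0c)
        order = np.argsort(s, kind="stable")
        bins = np.array_split(order, 100)
        mads = np.array([1.4826 * np.median(np.abs(d[b] - np.median(d[b])))
                         for b in bins])
        return mads.std() / mads.mean()

    grid = {a: cv_for(np.percentile(s, a)) for a in range(0, 101, 5)}
    assert s0 > 0
    assert cv_for(s0) <= grid[0] + 1e-12
    best_alpha = min(grid, key=lambda a: (grid[a], a))
    assert alpha == best_alpha


def test_estimate_s0_fallback_warns(caplog):
    with caplog.at_level("WARNING", logger="traitsam"):
        s0, _ = ts.estimate_s0(np.array([1.0]), np.array([0.5]))
    assert s0 == 0.5
    assert any("falling back" in r.message for r in caplog.records)


# ---------------------------------------------------------------------------
# permutation null
# ---------------------------------------------------------------------------

def test_exact_enumeration_matches_brute_force():
    """n = 4 distinct responses: all 24 arrangements enumerated exactly."""
    rng = np.random.default_rng(9)
    X = rng.normal(size=(6, 4))
    y = np.array([0.0, 0.2, 0.7, 1.0])
    null = ts.permutation_null(make_matrix(X), _response(y), s0=0.1, B=24,
                               seed=1)
    assert null.exact and null.B == 24

    d_all = []
    for perm in itertools.permutations(y):
        scores = ts.compute_regression_scores(make_matrix(X),
                                              _response(np.array(perm)), s0=0.1)
        d_all.append(np.sort(scores.d))
    dbar_ref = np.mean(d_all, axis=0)
    np.testing.assert_allclose(null.dbar, dbar_ref, atol=1e-12)

    sampled = ts.permutation_null(make_matrix(X), _response(y), s0=0.1, B=100,
                                  seed=1)
    assert sampled.exact and sampled.B == 24  # still enumerated, B capped


def test_null_determinism_and_shape():
    rng = np.random.default_rng(10)
    X = rng.normal(size=(20, 12))
    y = np.repeat(np.linspace(0, 1, 4), 3)
    a = ts.permutation_null(make_matrix(X), _response(y), s0=0.2, B=50, seed=7)
    b = ts.permutation_null(make_matrix(X), _response(y), s0=0.2, B=50, seed=7)
    np.testing.assert_array_equal(a.d_star, b.d_star)
    assert a.d_star.shape == (20, 50)
    assert np.all(np.diff(a.dbar) >= -1e-12)
    c = ts.permutation_null(make_matrix(X), _response(y), s0=0.2, B=50, seed=8)
    assert not np.array_equal(a.d_star, c.d_star)


def test_null_centered_on_pure_noise():
    """Mean expected order statistic is ~0 for unstructured data."""
    rng = np.random.default_rng(11)
    X = rng.normal(size=(300, 12))
    y = np.repeat(np.linspace(0, 1, 4), 3)
    null = ts.permutation_null(make_matrix(X), _response(y), s0=0.1, B=100,
                               seed=1)
    se = null.d_star.std() / np.sqrt(null.d_star.shape[0])
    assert abs(null.dbar.mean()) < 3 * max(se, 0.05)


def test_genotype_block_permutation_keeps_replicate_structure():
    rng = np.random.default_rng(12)
    X = rng.normal(size=(10, 12))
    y = np.repeat([0.0, 0.3, 0.8, 1.0], 3)
    m = make_matrix(X, genotypes=[g for g in "AAABBBCCCDDD"])
    resp = WeightedResponse("t", "minmax", m.sample_ids, y)
    null = ts.permutation_null(m, resp, s0=0.1, B=24, seed=1, permute="genotype")
    # 4 genotype blocks with distinct weights: exactly 4! arrangements
    assert null.exact and null.B == 24
    # every column of d_star must equal a scoring of some block-constant
    # arrangement of the genotype weights
    refs = {}
    for perm in itertools.permutations([0.0, 0.3, 0.8, 1.0]):
        yp = np.repeat(perm, 3)
        sc = ts.compute_regression_scores(m, _response(yp), s0=0.1)
        refs[perm] = sc.d
    for b in range(null.B):
        assert any(np.allclose(null.d_star[:, b], ref, atol=1e-12)
                   for ref in refs.values())


# ---------------------------------------------------------------------------
# FDR and q-values
# ---------------------------------------------------------------------------

def _tiny_sam(seed=13, m=200, spikes=0):
    rng = np.random.default_rng(seed)
    y = np.repeat(np.linspace(0, 1, 8), 3)
    X = rng.normal(size=(m, 24)) * 0.5
    for i in range(spikes):
        sign = 1 if i % 2 == 0 else -1
        X[i] += sign * 3.0 * y
    matrix = make_matrix(X)
    resp = _response_for(matrix, y)
    base = ts.compute_regression_scores(matrix, resp, s0=0.0)
    s0, _ = ts.estimate_s0(base.r, base.s)
    scores = ts.compute_regression_scores(matrix, resp, s0=s0)
    null = ts.permutation_null(matrix, resp, s0=s0, B=100, seed=seed)
    return scores, null


def _response_for(matrix, y):
    return WeightedResponse("t", "minmax", matrix.sample_ids, y)


def test_fdr_infinite_delta_boundary():
    scores, null = _tiny_sam()
    table, q = ts.fdr_and_qvalues(scores, null, delta_grid=np.array([np.inf]))
    row = table.table.iloc[0]
    assert row["n_called"] == 0 and row["fdr_percent"] == 0.0
    assert np.all(q == 100.0)


def test_fdr_table_monotone_and_bounded():
    scores, null = _tiny_sam(spikes=20)
    table, q = ts.fdr_and_qvalues(scores, null)
    called = table.table["n_called"].to_numpy()
    assert np.all(np.diff(called) <= 0)
    assert table.table["fdr_percent"].between(0, 100).all()
    assert 0 < table.pi0 <= 1
    assert np.all((q >= 0) & (q <= 100))


def test_q_monotone_in_score_within_side():
    """On either side, a more extreme d never has a larger q."""
    scores, null = _tiny_sam(spikes=20)
    _, q = ts.fdr_and_qvalues(scores, null)
    d = scores.d
    for side in (d > 0, d < 0):
        ds, qs = d[side], q[side]
        order = np.argsort(np.abs(ds))
        assert np.all(np.diff(qs[order]) <= 1e-9)


def test_fdr_five_percent_row_calls_most_spikes():
    """20 strong spikes out of 200 probes: the 5%-FDR rule finds >= 15."""
    scores, null = _tiny_sam(spikes=20)
    _, q = ts.fdr_and_qvalues(scores, null)
    assert int((q <= 5.0).sum()) >= 15

    # independent recomputation of q for the top-scoring probe from the table
    table, _ = ts.fdr_and_qvalues(scores, null)
    t = table.table
    i_top = int(np.argmax(scores.d))
    called = (scores.d[i_top] >= t["cut_up"]) | (scores.d[i_top] <= t["cut_low"])
    assert q[i_top] == pytest.approx(t.loc[called, "fdr_percent"].min())


def test_fdr_empty_grid_errors():
    scores, null = _tiny_sam()
    with pytest.raises(SamError, match="delta grid"):
        ts.fdr_and_qvalues(scores, null, delta_grid=np.array([]))


# ---------------------------------------------------------------------------
# selection
# ---------------------------------------------------------------------------

def test_select_significant_threshold_logic():
    scores = ts.SamScores(["A", "B", "C"], r=[1, -1, 1], s=[0.1, 0.1, 0.1],
                          d=[2.25, -3.65, 1.5], s0=0.0)
    q = np.array([2.34, 0.71, 1.0])
    sig = ts.select_significant(scores, q)
    assert sig.positive == ["A"] and sig.negative == ["B"]
    assert "C" not in set(sig.table["probe_id"])  # |d| = 1.5 < 2 despite q = 1%
    row_a = sig.table.set_index("probe_id").loc["A"]
    assert (row_a["d"], row_a["q_percent"]) == (2.25, 2.34)


def test_select_significant_empty_is_valid():
    scores = ts.SamScores(["A"], r=[0.1], s=[0.1], d=[0.5], s0=0.0)
    sig = ts.select_significant(scores, np.array([80.0]))
    assert len(sig) == 0 and sig.positive == [] and sig.negative == []


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

def test_run_trait_sam_recovers_spikes(normalized_stressed, spiked_dataset):
    stressed, traits = normalized_stressed
    _, _, _, truth = spiked_dataset
    res = ts.run_trait_sam(stressed, traits, "shoot_Na", condition="stressed",
                           config=ts.SamConfig(permutations=100, seed=2))
    spikes = truth[truth["trait"] == "shoot_Na"]
    pos, neg = set(res.significant.positive), set(res.significant.negative)
    hits = sum(r.probe_id in (pos if r.direction == "positive" else neg)
               for r in spikes.itertuples())
    assert hits / len(spikes) >= 0.8
    assert res.scores.s0 >= 0 and res.fdr_table.pi0 <= 1


def test_run_trait_sam_null_data_selects_nothing():
    """Spike-free data yields (near-)zero selections for any trait."""
    cfg = ts.SimulationConfig(n_probes=400, seed=29, spike_fraction=0.0)
    matrix, traits, _ = ts.generate_dataset(cfg)
    stressed = ts.subset_condition(
        ts.log2_transform(ts.quantile_normalize(matrix)), "stressed")
    res = ts.run_trait_sam(stressed, traits, "biomass", condition="stressed",
                           config=ts.SamConfig(permutations=100, seed=2))
    assert len(res.significant) <= 2


def test_run_all_traits_bookkeeping(normalized_stressed, spiked_dataset):
    stressed, traits = normalized_stressed
    _, matrix, _, _ = spiked_dataset
    norm = ts.log2_transform(ts.quantile_normalize(matrix))
    small = ts.TraitTable(traits.data[["shoot_Na", "biomass"]])
    cfg = ts.SamConfig(permutations=20, seed=1)
    summary, results = ts.run_all_traits(
        norm, {"control": small, "stressed": small}, cfg)
    assert len(summary) == 4 and len(results) == 4
    assert set(summary.columns) == {"trait", "condition", "n_positive",
                                    "n_negative"}
    # control data carries no spikes by construction
    ctrl = summary[summary["condition"] == "control"]
    assert (ctrl["n_positive"] + ctrl["n_negative"]).sum() <= 2
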