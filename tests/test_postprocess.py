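"""Unit and property tests for the two docking post-processing filters."""
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from targetfish import (
    RunLog,
    ScoreMatrix,
    normalize_method1,
    run_method,
    select_best_targets,
    threshold_method1,
    ztransform_2d,
)

from conftest import random_negative_matrix


# ---------------------------------------------------------------------------
# independent brute-force oracles (plain loops; no shared code with the
# implementation)
# ---------------------------------------------------------------------------


def oracle_normalize(df: pd.DataFrame):
    cells = {}
    for lig in df.index:
        for tgt in df.columns:
            v0 = df.loc[lig, tgt]
            if pd.isna(v0):
                continue
            row = [x for x in df.loc[lig] if not pd.isna(x)]
            col = [df.loc[k, tgt] for k in df.index if not pd.isna(df.loc[k, tgt])]
            ml = sum(row) / len(row)
            mt = sum(col) / len(col)
            cells[(lig, tgt)] = v0 / ((ml + mt) / 2.0)
    mean = sum(cells.values()) / len(cells)
    sd = math.sqrt(sum((v - mean) ** 2 for v in cells.values()) / len(cells))
    return cells, mean, sd


def oracle_ztransform(df: pd.DataFrame, wt=0.7, wl=0.3):
    """Spreadsheet-style recomputation: ZT per target column, ZL per ligand row."""

    def standardize(values):
        mean = sum(values) / len(values)
        sd = math.sqrt(sum((x - mean) ** 2 for x in values) / len(values))
        return mean, sd

    zcomb = {}
    for lig in df.index:
        for tgt in df.columns:
            x = df.loc[lig, tgt]
            if pd.isna(x):
                continue
            col = [df.loc[k, tgt] for k in df.index if not pd.isna(df.loc[k, tgt])]
            row = [y for y in df.loc[lig] if not pd.isna(y)]
            cm, cs = standardize(col)
            rm, rs = standardize(row)
            zt = 0.0 if cs == 0 else (x - cm) / cs
            zl = 0.0 if rs == 0 else (x - rm) / rs
            zcomb[(lig, tgt)] = wt * zt + wl * zl
    return zcomb


# ---------------------------------------------------------------------------
# method I
# ---------------------------------------------------------------------------


def test_normalize_matches_hand_arithmetic(small_matrix):
    # hand-computed: ML(a)=-8, MT(T1)=-8 -> V(a,T1) = -10/-8 = 1.25, etc.
    nm = normalize_method1(small_matrix)
    expected = np.array([[1.25, 6.0 / 7.0], [6.0 / 7.0, 1.0]])
    np.testing.assert_allclose(nm.values.to_numpy(), expected, atol=1e-12)


def test_normalize_constant_matrix_gives_unit_v_and_zero_sigma():
    m = ScoreMatrix(pd.DataFrame(np.full((3, 4), -8.0),
                                 index=list("abc"), columns=list("wxyz")))
    nm = normalize_method1(m)
    np.testing.assert_allclose(nm.values.to_numpy(), 1.0)
    assert nm.matrix_sd == 0.0


def test_normalize_rejects_unvalidated_matrix():
    m = ScoreMatrix(pd.DataFrame([[-8.0, 2.0]], index=["a"], columns=["X", "Y"]))
    with pytest.raises(ValueError, match="validate"):
        normalize_method1(m)


def test_threshold_selects_single_planted_cell():
    rng = np.random.default_rng(3)
    vals = np.minimum(rng.normal(-8, 0.3, (20, 10)), -1e-6)
    vals[4, 7] = -14.0  # far below everything else
    m = ScoreMatrix(pd.DataFrame(vals, index=[f"l{i}" for i in range(20)],
                                 columns=[f"t{j}" for j in range(10)]))
    ps = threshold_method1(normalize_method1(m))
    assert ps.pairs == frozenset({("t7", "l4")})
    assert ps.method_label == "method1"


def test_threshold_constant_matrix_all_pass_inclusively():
    m = ScoreMatrix(pd.DataFrame(np.full((2, 3), -5.0),
                                 index=["a", "b"], columns=["x", "y", "z"]))
    log = RunLog()
    ps = threshold_method1(normalize_method1(m), log=log)
    assert len(ps) == 6  # V == M everywhere and the comparison is inclusive
    assert any("degenerate" in line for line in log)


def test_threshold_exclusive_variant_drops_boundary():
    m = ScoreMatrix(pd.DataFrame(np.full((2, 2), -5.0),
                                 index=["a", "b"], columns=["x", "y"]))
    assert len(threshold_method1(normalize_method1(m), inclusive=False)) == 0


@settings(max_examples=20, deadline=None, derandomize=True)
@given(
    scale=st.floats(min_value=0.05, max_value=50.0),
    seed=st.integers(min_value=0, max_value=2**16),
)
def test_method1_invariant_under_positive_scaling(scale, seed):
    """V, M, sigma and the selected set are unchanged by V0 -> c*V0, c > 0."""
    rng = np.random.default_rng(seed)
    m = random_negative_matrix(rng, 8, 5)
    scaled = ScoreMatrix(m.scores * scale)
    nm, nms = normalize_method1(m), normalize_method1(scaled)
    np.testing.assert_allclose(nm.values.to_numpy(), nms.values.to_numpy(), rtol=1e-9)
    assert math.isclose(nm.matrix_mean, nms.matrix_mean, rel_tol=1e-9)
    assert math.isclose(nm.matrix_sd, nms.matrix_sd, rel_tol=1e-9, abs_tol=1e-12)
    assert threshold_method1(nm).pairs == threshold_method1(nms).pairs


# ---------------------------------------------------------------------------
# method II
# ---------------------------------------------------------------------------


def test_ztransform_matches_spreadsheet_oracle(z_fixture_matrix):
    z = ztransform_2d(z_fixture_matrix)
    expected = oracle_ztransform(z_fixture_matrix.scores)
    for (lig, tgt), val in expected.items():
        assert z.zcomb.loc[lig, tgt] == pytest.approx(val, abs=1e-12)


def test_ztransform_cell_at_both_means_is_zero():
    # centre cell equals its row mean and its column mean -> all Z vanish
    df = pd.DataFrame(
        [[-9.0, -8.0, -7.0], [-8.0, -8.0, -8.0], [-7.0, -8.0, -9.0]],
        index=["a", "b", "c"], columns=["x", "y", "z"],
    )
    z = ztransform_2d(ScoreMatrix(df))
    assert z.zt.loc["b", "y"] == 0.0
    assert z.zl.loc["b", "y"] == 0.0
    assert z.zcomb.loc["b", "y"] == 0.0


def test_ztransform_axes_standardized_and_weights_checked():
    rng = np.random.default_rng(11)
    z = ztransform_2d(random_negative_matrix(rng, 12, 7))
    np.testing.assert_allclose(z.zt.mean(axis=0), 0.0, atol=1e-9)
    np.testing.assert_allclose(z.zt.std(axis=0, ddof=0), 1.0, atol=1e-9)
    np.testing.assert_allclose(z.zl.mean(axis=1), 0.0, atol=1e-9)
    np.testing.assert_allclose(z.zl.std(axis=1, ddof=0), 1.0, atol=1e-9)
    with pytest.raises(ValueError, match="sum to 1"):
        ztransform_2d(random_negative_matrix(rng, 4, 4), weights=(0.6, 0.3))


def test_ztransform_orientation_flip_transposes_roles():
    rng = np.random.default_rng(5)
    m = random_negative_matrix(rng, 6, 4)
    a = ztransform_2d(m, orientation="per_target")
    b = ztransform_2d(m, orientation="per_ligand")
    pd.testing.assert_frame_equal(a.zt, b.zl)
    pd.testing.assert_frame_equal(a.zl, b.zt)


def test_ztransform_drops_thin_rows_and_columns():
    df = pd.DataFrame(
        [[-8.0, -7.0, np.nan], [-6.0, -9.0, np.nan], [np.nan, np.nan, -5.0]],
        index=["a", "b", "c"], columns=["x", "y", "z"],
    )
    log = RunLog()
    z = ztransform_2d(ScoreMatrix(df), log=log)
    assert list(z.zcomb.index) == ["a", "b"]
    assert list(z.zcomb.columns) == ["x", "y"]
    assert any("<2" in line for line in log)


def test_select_best_targets_planted_and_one_per_ligand():
    rng = np.random.default_rng(9)
    m = random_negative_matrix(rng, 10, 6)
    m.scores.iloc[2, 3] = -20.0  # -5 sigma plant
    z = ztransform_2d(m)
    ps = select_best_targets(z)
    assert len(ps) == 10  # one pairing per ligand
    assert ("t3", "l2") in ps.pairs


def test_select_best_targets_tie_breaks_lexicographically():
    df = pd.DataFrame(
        [[-10.0, -10.0, -6.0], [-6.0, -6.0, -10.0], [-7.0, -7.0, -8.0]],
        index=["a", "b", "c"], columns=["tB", "tA", "tC"],
    )
    log = RunLog()
    ps = select_best_targets(ztransform_2d(ScoreMatrix(df)), log=log)
    # ligand 'a' ties exactly between tA and tB -> tA wins
    assert ("tA", "a") in ps.pairs
    assert any("tie" in line for line in log)


def test_select_best_targets_optional_cutoff_filters():
    rng = np.random.default_rng(4)
    m = random_negative_matrix(rng, 8, 5)
    z = ztransform_2d(m)
    all_pairs = select_best_targets(z)
    strict = select_best_targets(z, zcomb_cutoff=-10.0)
    assert len(strict) == 0
    assert len(all_pairs) == 8


@settings(max_examples=20, deadline=None, derandomize=True)
@given(
    scale=st.floats(min_value=0.05, max_value=20.0),
    shift=st.floats(min_value=-30.0, max_value=-0.1),
    seed=st.integers(min_value=0, max_value=2**16),
)
def test_method2_selection_invariant_under_global_affine_transform(scale, shift, seed):
    rng = np.random.default_rng(seed)
    m = random_negative_matrix(rng, 8, 5)
    transformed = ScoreMatrix(m.scores * scale + shift)
    a = select_best_targets(ztransform_2d(m)).pairs
    b = select_best_targets(ztransform_2d(transformed)).pairs
    assert a == b


def test_removing_a_target_column_preserves_other_columns_zt():
    """Per-target standardization depends only on its own column."""
    rng = np.random.default_rng(21)
    m = random_negative_matrix(rng, 10, 6)
    full = ztransform_2d(m)
    reduced = ztransform_2d(ScoreMatrix(m.scores.drop(columns=["t2"])))
    kept = [c for c in m.scores.columns if c != "t2"]
    pd.testing.assert_frame_equal(full.zt[kept], reduced.zt)
    # ZL changes only through the row statistics, which recomputation covers
    expected = oracle_ztransform(m.scores.drop(columns=["t2"]))
    for (lig, tgt), val in expected.items():
        assert reduced.zcomb.loc[lig, tgt] == pytest.approx(val, abs=1e-9)


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------


def test_run_method_dispatch_and_labels(small_matrix):
    ps1 = run_method(small_matrix, "method1", run_label="excl_promiscuous")
    ps2 = run_method(small_matrix, "method2")
    assert ps1.method_label == "method1" and ps1.run_label == "excl_promiscuous"
    assert ps2.method_label == "method2"
    assert len(ps2) <= len(small_matrix.ligand_ids)
    with pytest.raises(ValueError, match="unknown method"):
        run_method(small_matrix, "method3")
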