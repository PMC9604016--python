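"""Generators: determinism, planted structure, exact cardinalities, bias correction."""
import numpy as np
import pandas as pd
import pytest
from scipy.stats import chisquare

from targetfish import (
    LibrarySimConfig,
    SimulationConfig,
    build_consensus,
    interactions_from_frame,
    merge_libraries,
    plant_random_pairings,
    read_score_matrix,
    run_method,
    screen,
    simulate_pairing_sets,
    simulate_reference_sets,
    simulate_score_matrix,
    summarize_consensus,
    validate_scores,
    write_score_matrix,
)


def test_score_matrix_deterministic_and_strictly_negative():
    cfg = SimulationConfig(n_ligands=40, n_targets=10, seed=5)
    m1, t1 = simulate_score_matrix(cfg)
    m2, t2 = simulate_score_matrix(SimulationConfig(n_ligands=40, n_targets=10, seed=5))
    pd.testing.assert_frame_equal(m1.scores, m2.scores)
    pd.testing.assert_frame_equal(t1, t2)
    assert (m1.scores.to_numpy() < 0).all()


def test_degenerate_config_constant_matrix():
    cfg = SimulationConfig(
        n_ligands=3, n_targets=2, background_sd=0.0,
        ligand_offset_scale=0.0, target_offset_scale=0.0, seed=1,
    )
    m, _ = simulate_score_matrix(cfg)
    np.testing.assert_allclose(m.scores.to_numpy(), -8.0)


def test_invalid_configs_rejected():
    with pytest.raises(ValueError, match="negative"):
        SimulationConfig(background_mean=1.0)
    with pytest.raises(ValueError):
        SimulationConfig(missing_fraction=1.0)
    with pytest.raises(ValueError, match=">= 0 kcal/mol"):
        simulate_score_matrix(
            SimulationConfig(background_mean=-0.5, target_offset_scale=2.0, seed=0)
        )


def test_planted_cells_sit_below_their_background():
    rng = np.random.default_rng(2)
    cfg = SimulationConfig(n_ligands=50, n_targets=10, seed=2)
    cfg.planted = plant_random_pairings(cfg, 5, 4.0, rng)
    m, truth = simulate_score_matrix(cfg)
    assert len(truth) == 5
    assert truth["ligand_id"].is_unique  # planted on distinct ligand rows
    clean, _ = simulate_score_matrix(
        SimulationConfig(n_ligands=50, n_targets=10, seed=2, planted=[])
    )
    for _, row in truth.iterrows():
        delta = (
            m.scores.loc[row.ligand_id, row.target_id]
            - clean.scores.loc[row.ligand_id, row.target_id]
        )
        assert delta == pytest.approx(-4.0 * cfg.background_sd)


def test_score_matrix_round_trips_through_pipeline_format(tmp_path):
    cfg = SimulationConfig(n_ligands=10, n_targets=5, missing_fraction=0.1, seed=3)
    m, _ = simulate_score_matrix(cfg)
    write_score_matrix(m, tmp_path / "m.tsv")
    back = read_score_matrix(tmp_path / "m.tsv")
    pd.testing.assert_frame_equal(m.scores, back.scores)


def test_reference_sets_realize_exact_cardinalities():
    cfg = LibrarySimConfig(source_sizes=(120, 150), overlap=50, n_targets=6,
                           n_queries=20, seed=4)
    sources, queries, planted = simulate_reference_sets(cfg)
    assert [len(s) for s in sources] == [120, 150]
    lib = merge_libraries(
        [interactions_from_frame(s, s["source_label"].iloc[0]) for s in sources]
    )
    assert len(lib) == 120 + 150 - 50
    assert lib.merge_report["pairwise_overlaps"][(0, 1)] == 50
    assert len(queries) == 20


def test_reference_subset_source_unions_to_superset():
    cfg = LibrarySimConfig(source_sizes=(40, 100), overlap=40, n_targets=4,
                           n_queries=4, seed=0)
    sources, _, _ = simulate_reference_sets(cfg)
    lib = merge_libraries(
        [interactions_from_frame(s, s["source_label"].iloc[0]) for s in sources]
    )
    assert len(lib) == 100  # A subset of B -> union == |B|


def test_planted_queries_hit_their_targets_at_unity():
    cfg = LibrarySimConfig(source_sizes=(80, 90), overlap=30, n_targets=5,
                           n_queries=20, planted_fraction=0.5, seed=6)
    sources, queries, planted = simulate_reference_sets(cfg)
    lib = merge_libraries(
        [interactions_from_frame(s, s["source_label"].iloc[0]) for s in sources]
    )
    hits = screen(queries, lib, cutoff=0.75)
    hit_pairs = {(h.query_id, h.target_id) for h in hits}
    exact = {(h.query_id, h.target_id) for h in hits if h.tanimoto == 1.0}
    planted_pairs = set(zip(planted["query_id"], planted["target_id"]))
    assert planted_pairs <= exact
    # decoy (aliphatic-pool) queries never reach the cutoff
    assert {q for q, _ in hit_pairs} == set(planted["query_id"])


def test_inconsistent_library_cardinalities_rejected():
    with pytest.raises(ValueError):
        LibrarySimConfig(source_sizes=(10, 20), overlap=15)


def test_pairing_fixture_realizes_requested_histogram():
    counts = {5: 3, 2: 4, 1: 6}
    sets, hits = simulate_pairing_sets(counts, seed=8)
    table = build_consensus(sets, hits)
    assert summarize_consensus(table)["score_counts"].to_dict() == counts
    # score 5 requires all five approaches, hence similarity support
    assert len(sets) == 4
    empty_sets, empty_hits = simulate_pairing_sets({}, seed=0)
    assert len(build_consensus(empty_sets, empty_hits)) == 0
    with pytest.raises(ValueError):
        simulate_pairing_sets({6: 1}, seed=0)


def test_pairing_fixture_respects_family_plan():
    sets, hits = simulate_pairing_sets(
        {2: 5, 1: 7}, seed=9, family_plan={2: (3, 0, 2), 1: (4, 3, 0)}
    )
    table = build_consensus(sets, hits)
    overlap = summarize_consensus(table)["family_overlap"]
    assert overlap == {"structure_based": 9, "ligand_based": 5, "both": 2, "union": 12}


def test_normalizations_suppress_systematic_column_bias():
    """Selections stay near-uniform under the default +-1 kcal/mol target bias,
    and both filters are far less column-biased than raw-score selection."""
    n_targets = 35
    m1 = np.zeros(n_targets)
    m2 = np.zeros(n_targets)
    m1_raw = np.zeros(n_targets)
    m2_raw = np.zeros(n_targets)
    for seed in range(10):
        cfg = SimulationConfig(target_offset_scale=1.0, ligand_offset_scale=0.0, seed=seed)
        matrix, _ = simulate_score_matrix(cfg)
        v = validate_scores(matrix)
        idx = {t: i for i, t in enumerate(v.target_ids)}
        for t, _ in run_method(v, "method1").pairs:
            m1[idx[t]] += 1
        for t, _ in run_method(v, "method2").pairs:
            m2[idx[t]] += 1
        vals = v.scores.to_numpy()
        thr = np.nanmean(vals) - 3 * np.nanstd(vals)
        for _, j in np.argwhere(vals <= thr):  # raw analogue of method I
            m1_raw[j] += 1
        for j in np.argmin(vals, axis=1):  # raw analogue of method II
            m2_raw[j] += 1
    assert chisquare(m1)[1] > 0.01
    assert chisquare(m2)[1] > 0.01
    assert chisquare(m1)[0] < chisquare(m1_raw)[0]
    assert chisquare(m2)[0] < 0.5 * chisquare(m2_raw)[0]
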