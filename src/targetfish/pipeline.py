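"""End-to-end synthetic pipeline: simulate, post-process, screen, fuse, project.

Mirrors the study design: two docking programs' score matrices are
post-processed with both filtering methods, promiscuous targets are
excluded and the docking analysis rerun, a similarity screen runs
against a merged reference library, and everything is fused into a
consensus table and a protein-ligand network.  Ground truth planted by
the generators is carried through so recovery can be measured.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from . import consensus as cns
from . import library as lib
from . import matrixio, network, postprocess, synthetic
from .config import PipelineConfig
from .runlog import RunLog

PROGRAMS = ("progA", "progB")


def docking_pairing_sets(
    matrices: dict[str, matrixio.ScoreMatrix],
    config: PipelineConfig,
    log: RunLog,
) -> tuple[list[postprocess.PairingSet], list[str]]:
    """Run both methods on each program's matrix, with and without exclusions.

    Returns the pairing sets (4 approaches x up to 2 runs) and the
    excluded target list (empty when nothing is flagged, in which case
    only the all-targets run exists).
    """
    first_run = []
    for prog, matrix in matrices.items():
        validated = matrixio.validate_scores(matrix, log=log)
        for method in ("method1", "method2"):
            first_run.append(
                postprocess.run_method(
                    validated,
                    method,
                    run_label="all_targets",
                    weights=config.z_weights,
                    orientation=config.z_orientation,
                    inclusive=config.threshold_inclusive,
                    zcomb_cutoff=config.zcomb_cutoff,
                    log=log,
                )
            )
    excluded = cns.detect_promiscuous(
        first_run,
        policy=config.exclusion_policy,
        manual_list=config.exclusion_list,
        k=config.exclusion_k,
        log=log,
    )
    all_sets = list(first_run)
    if excluded:
        for prog, matrix in matrices.items():
            validated = matrixio.validate_scores(matrix, log=log)
            reduced = matrixio.exclude_targets(validated, excluded, log=log)
            for method in ("method1", "method2"):
                all_sets.append(
                    postprocess.run_method(
                        reduced,
                        method,
                        run_label="excl_promiscuous",
                        weights=config.z_weights,
                        orientation=config.z_orientation,
                        inclusive=config.threshold_inclusive,
                        zcomb_cutoff=config.zcomb_cutoff,
                        log=log,
                    )
                )
    return all_sets, excluded


def run_all(
    seed: int = 0,
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
    n_ligands: int = 300,
    n_targets: int = 35,
    n_planted: int = 30,
    planted_signal: float = 4.0,
) -> dict:
    """Synthetic end-to-end run; returns a report dict of computed quantities.

    When ``out_dir`` is given, all intermediate tables, the consensus
    table, the network exports and the run log are written there.
    """
    config = config or PipelineConfig()
    log = RunLog()
    rng = np.random.default_rng(seed)

    # --- docking stage: two programs share the planted ground truth
    base = synthetic.SimulationConfig(
        n_ligands=n_ligands, n_targets=n_targets, seed=int(rng.integers(2**31))
    )
    planted = synthetic.plant_random_pairings(base, n_planted, planted_signal, rng)
    matrices, truth = {}, None
    for prog in PROGRAMS:
        cfg = synthetic.SimulationConfig(
            n_ligands=n_ligands,
            n_targets=n_targets,
            planted=planted,
            seed=int(rng.integers(2**31)),
        )
        matrix, truth = synthetic.simulate_score_matrix(cfg)
        matrix.program_label = prog
        matrices[prog] = matrix
    pairing_sets, excluded = docking_pairing_sets(matrices, config, log)

    # --- ligand-based stage: modest library over the same target universe
    lib_cfg = synthetic.LibrarySimConfig(
        source_sizes=(400, 500),
        overlap=150,
        target_ids=list(matrices[PROGRAMS[0]].target_ids),
        query_ids=list(matrices[PROGRAMS[0]].ligand_ids)[: max(40, n_planted)],
        planted_fraction=0.25,
        seed=int(rng.integers(2**31)),
    )
    sources, queries, planted_hits = synthetic.simulate_reference_sets(lib_cfg)
    merged = lib.merge_libraries(
        [lib.interactions_from_frame(s, s["source_label"].iloc[0], log=log) for s in sources],
        log=log,
    )
    hits = lib.screen(
        queries,
        merged,
        cutoff=config.similarity_cutoff,
        radius=config.fingerprint_radius,
        n_bits=config.fingerprint_bits,
        log=log,
    )

    # --- fusion and network
    table = cns.build_consensus(pairing_sets, hits, fuse_runs=config.fuse_runs, log=log)
    summary = cns.summarize_consensus(table)
    graph = network.build_network(table, min_confidence=1, log=log)

    # --- planted-truth recovery (method I pooled over runs/programs)
    truth_pairs = set(zip(truth["target_id"], truth["ligand_id"]))
    m1_pairs = set().union(
        *(ps.pairs for ps in pairing_sets if ps.method_label == "method1")
    )
    m2_pairs = set().union(
        *(ps.pairs for ps in pairing_sets if ps.method_label == "method2")
    )
    report = {
        "seed": seed,
        "n_ligands": n_ligands,
        "n_targets": n_targets,
        "excluded_targets": excluded,
        "n_pairing_sets": len(pairing_sets),
        "library_union_size": len(merged),
        "n_similarity_hits": len(hits),
        "n_planted_query_hits_expected": len(planted_hits),
        "consensus_unique_pairings": len(table),
        "score_counts": {int(k): int(v) for k, v in summary["score_counts"].items()},
        "family_overlap": summary["family_overlap"],
        "method1_recall": (
            len(m1_pairs & truth_pairs) / len(truth_pairs) if truth_pairs else float("nan")
        ),
        "method2_planted_ligand_rate": (
            len(m2_pairs & truth_pairs) / len(truth_pairs) if truth_pairs else float("nan")
        ),
        "network_nodes": graph.number_of_nodes(),
        "network_edges": graph.number_of_edges(),
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for prog, matrix in matrices.items():
            matrixio.write_score_matrix(matrix, out / f"scores_{prog}.tsv")
        synthetic.write_ground_truth(truth, out / "ground_truth.tsv")
        for i, src in enumerate(sources):
            synthetic.write_interaction_table(src, out / f"interactions_source{i}.tsv")
        synthetic.write_query_table(queries, out / "queries.tsv")
        for ps in pairing_sets:
            postprocess.write_pairing_set(
                ps, out / f"pairings_{ps.method_label}_{ps.program_label}_{ps.run_label}.tsv"
            )
        lib.write_hits(hits, out / "similarity_hits.tsv")
        table.write(out / "consensus.tsv")
        network.export_network(graph, out / "pli_network.graphml", "graphml")
        network.export_network(graph, out / "pli_network_edges.tsv", "edge_table")
        log.write(out / "run_log.txt")
        (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report
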