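"""Synthetic inputs with planted ground truth for every pipeline stage.

Three generators emulate the statistical structure the analysis assumes,
so the whole pipeline is testable without docking runs or database
downloads:

- :func:`simulate_score_matrix` — Gaussian blind-docking energies with
  ligand-row and target-column systematic offsets (the biases the
  normalizations exist to cancel) and planted high-affinity pairings.
- :func:`simulate_reference_sets` — interaction-table sources with
  exact, configurable sizes and overlap (merge arithmetic fixtures),
  plus a query table in which a chosen fraction of compounds duplicate
  reference structures (guaranteed similarity hits at Tanimoto 1.0).
- :func:`simulate_pairing_sets` — pairing sets and similarity hits that
  realize a requested confidence-score histogram exactly.

All generators are deterministic in their seed and emit the same
delimited formats the other modules consume.

Synthetic molecules are enumerated from small aromatic scaffolds with
real substituents (validated by RDKit), so fingerprints behave like
real chemistry; background query compounds come from a disjoint
aliphatic pool that cannot reach the 0.75 similarity cutoff against the
aromatic references.
"""
from __future__ import annotations

import dataclasses
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem

from .library import SimilarityHit
from .matrixio import ScoreMatrix
from .postprocess import PairingSet

# --------------------------------------------------------------------------
# synthetic chemistry: enumerated scaffold pools
# --------------------------------------------------------------------------

_AROMATIC_TEMPLATES = (
    "{0}c1ccc({1})cc1",  # para-disubstituted benzene
    "{0}c1ccc({1})nc1",  # disubstituted pyridine
    "{0}c1ccc({1})o1",  # disubstituted furan
    "{0}c1ccc({1})s1",  # disubstituted thiophene
)
_ALIPHATIC_TEMPLATES = (
    "{0}C1CCC({1})CC1",  # disubstituted cyclohexane
    "{0}CCCC{1}",  # 1,4-disubstituted butane
    "{0}CC(O)C{1}",  # substituted butan-2-ol backbone
)
_SUBSTITUENTS = (
    "C", "CC", "CCC", "C(C)C", "O", "OC", "OCC", "N", "NC",
    "F", "Cl", "Br", "C#N", "C(F)(F)F", "CO", "CCO",
)


def _enumerate_pool(templates: tuple[str, ...]) -> list[str]:
    seen: dict[str, None] = {}
    for template in templates:
        for s1 in _SUBSTITUENTS:
            for s2 in _SUBSTITUENTS:
                mol = Chem.MolFromSmiles(template.format(s1, s2))
                if mol is None:
                    continue
                seen.setdefault(Chem.MolToSmiles(mol))
    return list(seen)


@lru_cache(maxsize=1)
def aromatic_pool() -> tuple[str, ...]:
    """Canonical SMILES pool for synthetic reference ligands."""
    return tuple(_enumerate_pool(_AROMATIC_TEMPLATES))


@lru_cache(maxsize=1)
def aliphatic_pool() -> tuple[str, ...]:
    """Disjoint pool for background (non-hit) query compounds."""
    return tuple(_enumerate_pool(_ALIPHATIC_TEMPLATES))


def _synthetic_key(index: int) -> str:
    """Deterministic InChIKey-shaped identifier for synthetic records."""
    return f"SYNLIG{index:08d}-SYNTHETIC-N"


# --------------------------------------------------------------------------
# docking-score matrices
# --------------------------------------------------------------------------


@dataclasses.dataclass
class SimulationConfig:
    """Conditions for one synthetic blind-docking score matrix.

    Defaults emulate a diverse-compound blind-docking campaign:
    background energies N(-8.0, 1.5^2) kcal/mol with per-ligand and
    per-target systematic offsets drawn uniformly on +-1 kcal/mol.
    ``planted`` lists (ligand index, target index, signal) triples; the
    planted cell is lowered by signal * background_sd below its
    systematic expectation.
    """

    n_ligands: int = 300
    n_targets: int = 35
    background_mean: float = -8.0  # kcal/mol; must be negative
    background_sd: float = 1.5  # kcal/mol
    ligand_offset_scale: float = 1.0  # kcal/mol, uniform on +- this
    target_offset_scale: float = 1.0
    planted: list = dataclasses.field(default_factory=list)
    missing_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.background_mean >= 0:
            raise ValueError("background mean binding energy must be negative")
        if not 0 <= self.missing_fraction < 1:
            raise ValueError("missing fraction must be in [0, 1)")
        if self.background_sd < 0:
            raise ValueError("background SD must be non-negative")


def plant_random_pairings(
    cfg: SimulationConfig, n_planted: int, signal: float, rng: np.random.Generator
) -> list[tuple[int, int, float]]:
    """Place ``n_planted`` high-affinity cells on distinct ligand rows."""
    if n_planted > cfg.n_ligands:
        raise ValueError("cannot plant more pairings than ligand rows")
    ligands = rng.choice(cfg.n_ligands, size=n_planted, replace=False)
    targets = rng.integers(0, cfg.n_targets, size=n_planted)
    return [(int(l), int(t), float(signal)) for l, t in zip(ligands, targets)]


def simulate_score_matrix(cfg: SimulationConfig) -> tuple[ScoreMatrix, pd.DataFrame]:
    """Draw one score matrix; returns (matrix, ground-truth table).

    cell = N(mean, sd) + ligand offset + target offset, minus
    signal * sd for planted cells; everything is clamped strictly
    negative (a configuration whose systematic part is already
    non-negative is rejected instead of silently clamped away).
    """
    rng = np.random.default_rng(cfg.seed)
    row_off = rng.uniform(-cfg.ligand_offset_scale, cfg.ligand_offset_scale, cfg.n_ligands)
    col_off = rng.uniform(-cfg.target_offset_scale, cfg.target_offset_scale, cfg.n_targets)
    systematic = cfg.background_mean + row_off[:, None] + col_off[None, :]
    if np.any(systematic >= 0):
        raise ValueError("offsets push the expected binding energy to >= 0 kcal/mol")
    scores = systematic + rng.normal(0.0, cfg.background_sd, (cfg.n_ligands, cfg.n_targets))
    for ligand, target, signal in cfg.planted:
        scores[ligand, target] -= signal * cfg.background_sd
    scores = np.minimum(scores, -1e-6)
    if cfg.missing_fraction > 0:
        mask = rng.random(scores.shape) < cfg.missing_fraction
        scores[mask] = np.nan
    ligand_ids = [f"L{i:04d}" for i in range(cfg.n_ligands)]
    target_ids = [f"T{j:03d}" for j in range(cfg.n_targets)]
    matrix = ScoreMatrix(
        pd.DataFrame(scores, index=ligand_ids, columns=target_ids),
        program_label=f"sim-seed{cfg.seed}",
    )
    truth = pd.DataFrame(
        {
            "ligand_id": [ligand_ids[l] for l, _, _ in cfg.planted],
            "target_id": [target_ids[t] for _, t, _ in cfg.planted],
            "signal_sd": [s for _, _, s in cfg.planted],
            "plant_type": "high_affinity",
        }
    )
    return matrix, truth


# --------------------------------------------------------------------------
# reference libraries and query sets
# --------------------------------------------------------------------------


@dataclasses.dataclass
class LibrarySimConfig:
    """Conditions for two interaction-table sources plus a query set.

    ``source_sizes`` and ``overlap`` are realized exactly (structure
    keys are synthesized deterministically), emulating two activity
    databases whose exports partially overlap.  ``planted_fraction`` of
    the queries copy a reference SMILES verbatim, guaranteeing a
    similarity hit at Tanimoto 1.0 on that reference's target(s); the
    remaining queries come from the disjoint aliphatic pool.
    """

    source_sizes: tuple[int, int] = (6787, 8536)
    overlap: int = 3631
    n_targets: int = 22
    n_queries: int = 40
    planted_fraction: float = 0.25
    target_ids: list | None = None  # defaults to REF_T000...
    query_ids: list | None = None  # defaults to Q0000...
    seed: int = 0

    def __post_init__(self):
        if self.overlap > min(self.source_sizes):
            raise ValueError("overlap cannot exceed the smaller source")
        if self.overlap < 0 or min(self.source_sizes) <= 0:
            raise ValueError("inconsistent cardinalities")
        if not 0 <= self.planted_fraction <= 1:
            raise ValueError("planted fraction must be in [0, 1]")


def simulate_reference_sets(
    cfg: LibrarySimConfig,
) -> tuple[list[pd.DataFrame], pd.DataFrame, pd.DataFrame]:
    """Build two interaction sources, a query table, and the planted hits.

    Returns ``(sources, queries, planted)`` where ``sources`` is a list
    of two interaction tables (columns target_id, ligand_key, smiles),
    ``queries`` has columns (query_id, smiles) and ``planted`` lists
    every (query_id, target_id) pair guaranteed to hit at Tanimoto 1.0.
    """
    rng = np.random.default_rng(cfg.seed)
    size_a, size_b = cfg.source_sizes
    union_n = size_a + size_b - cfg.overlap
    targets = (
        list(cfg.target_ids)
        if cfg.target_ids is not None
        else [f"REF_T{j:03d}" for j in range(cfg.n_targets)]
    )
    pool = aromatic_pool()
    universe = pd.DataFrame(
        {
            "target_id": [targets[i % len(targets)] for i in range(union_n)],
            "ligand_key": [_synthetic_key(i) for i in range(union_n)],
            "smiles": [pool[i % len(pool)] for i in range(union_n)],
        }
    )
    # first size_a rows belong to source A, last size_b to source B:
    # the middle size_a + size_b - union_n = overlap rows sit in both
    source_a = universe.iloc[:size_a].sample(frac=1.0, random_state=int(rng.integers(2**31)))
    source_b = universe.iloc[union_n - size_b :].sample(
        frac=1.0, random_state=int(rng.integers(2**31))
    )
    sources = [
        source_a.reset_index(drop=True).assign(source_label="synthetic_source_A"),
        source_b.reset_index(drop=True).assign(source_label="synthetic_source_B"),
    ]

    query_ids = (
        list(cfg.query_ids)
        if cfg.query_ids is not None
        else [f"Q{i:04d}" for i in range(cfg.n_queries)]
    )
    n_queries = len(query_ids)
    n_planted = int(round(cfg.planted_fraction * n_queries))
    planted_rows = []
    query_smiles = []
    if n_planted:
        picks = rng.choice(union_n, size=n_planted, replace=False)
        for qid, idx in zip(query_ids[:n_planted], picks):
            smiles = universe["smiles"].iloc[idx]
            query_smiles.append(smiles)
            # the copied structure may serve several targets as reference
            for target in sorted(set(universe.loc[universe["smiles"] == smiles, "target_id"])):
                planted_rows.append({"query_id": qid, "target_id": target})
    decoys = aliphatic_pool()
    decoy_picks = rng.choice(len(decoys), size=n_queries - n_planted, replace=False)
    query_smiles += [decoys[i] for i in decoy_picks]
    queries = pd.DataFrame({"query_id": query_ids, "smiles": query_smiles})
    planted = pd.DataFrame(planted_rows, columns=["query_id", "target_id"])
    return sources, queries, planted


# --------------------------------------------------------------------------
# consensus fixtures
# --------------------------------------------------------------------------


def simulate_pairing_sets(
    score_counts: dict[int, int],
    seed: int = 0,
    programs: tuple[str, str] = ("progA", "progB"),
    family_plan: dict[int, tuple[int, int, int]] | None = None,
) -> tuple[list[PairingSet], list[SimilarityHit]]:
    """Construct pairing sets + hits realizing an exact confidence histogram.

    ``score_counts`` maps confidence score (1-5) to the number of
    pairings that must end up with exactly that score.  The optional
    ``family_plan`` maps a score to a
    (structure_only, ligand_only, both_families) split of its count,
    controlling whether the supporting approaches include the
    similarity channel; by default the split is drawn at random.

    Returns four target-based :class:`PairingSet` objects (one per
    method x program, run label ``all_targets``) and the similarity
    hits; empty channels still appear as empty pairing sets.
    """
    rng = np.random.default_rng(seed)
    target_channels = [
        ("method1", programs[0]),
        ("method1", programs[1]),
        ("method2", programs[0]),
        ("method2", programs[1]),
    ]
    for score, count in score_counts.items():
        if not 1 <= score <= 5:
            raise ValueError(f"confidence score {score} outside the 1-5 approach universe")
        if count < 0:
            raise ValueError("pairing counts must be non-negative")
    if family_plan is not None:
        for score, (n_struct, n_lig, n_both) in family_plan.items():
            if n_struct + n_lig + n_both != score_counts.get(score, 0):
                raise ValueError(f"family plan for score {score} does not match its count")
            if n_lig and score != 1:
                raise ValueError("ligand-only pairings can only have score 1")
            if n_both and score < 2:
                raise ValueError("both-family pairings need score >= 2")

    channel_pairs: dict[tuple[str, str], set] = {ch: set() for ch in target_channels}
    hits: list[SimilarityHit] = []
    serial = 0
    for score in sorted(score_counts):
        count = score_counts[score]
        if family_plan is not None and score in family_plan:
            n_struct, n_lig, n_both = family_plan[score]
            memberships = ["struct"] * n_struct + ["lig"] * n_lig + ["both"] * n_both
        else:
            memberships = [None] * count
        for membership in memberships:
            target = f"T{serial % 97:03d}"
            ligand = f"L{serial:05d}"
            serial += 1
            pair = (target, ligand)
            if membership == "lig":
                use_similarity = True
                n_target_channels = 0
            elif membership == "both":
                use_similarity = True
                n_target_channels = score - 1
            elif membership == "struct":
                use_similarity = False
                n_target_channels = score
            else:  # random split over the full 5-approach universe
                choice = rng.choice(5, size=score, replace=False)
                use_similarity = 4 in choice
                n_target_channels = score - int(use_similarity)
            if n_target_channels > 4:
                raise ValueError("score exceeds the available target-based channels")
            for idx in rng.choice(4, size=n_target_channels, replace=False):
                channel_pairs[target_channels[idx]].add(pair)
            if use_similarity:
                hits.append(
                    SimilarityHit(
                        query_id=ligand,
                        target_id=target,
                        best_reference_key=_synthetic_key(serial),
                        tanimoto=1.0,
                    )
                )
    pairing_sets = [
        PairingSet(
            pairs=frozenset(channel_pairs[(method, prog)]),
            method_label=method,
            program_label=prog,
            run_label="all_targets",
        )
        for method, prog in target_channels
    ]
    return pairing_sets, hits


# --------------------------------------------------------------------------
# file emission (round-trips through the standard pipeline formats)
# --------------------------------------------------------------------------


def write_interaction_table(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t", index=False)


def write_query_table(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t", index=False)


def write_ground_truth(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t", index=False)
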