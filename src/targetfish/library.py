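"""Reference-interaction libraries and the ligand-based similarity screen.

Known target-ligand interactions exported from activity databases
(BindingDB/ChEMBL-style tables) are merged into one deduplicated
library keyed on (target id, structure key).  Structure keys are full
InChIKeys computed from SMILES, so two spellings of one molecule
deduplicate and stereoisomers stay distinct.

A query compound is screened against each target's reference ligands by
Morgan-fingerprint Tanimoto similarity; a maximum similarity >= 0.75
(inclusive, deliberately less restrictive than the common 0.85) flags
the query as a potential ligand of that target.
"""
from __future__ import annotations

import dataclasses
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem, DataStructs, RDLogger
from rdkit.Chem import rdFingerprintGenerator

from .runlog import RunLog, get_log

RDLogger.DisableLog("rdApp.*")  # unparsable rows are reported via the run log

#: screen defaults: ECFP4-like Morgan parameters and the similarity cutoff
DEFAULT_RADIUS = 2
DEFAULT_N_BITS = 2048
DEFAULT_CUTOFF = 0.75


@dataclasses.dataclass(frozen=True)
class ReferenceInteraction:
    """One known target-ligand interaction from one source database."""

    target_id: str
    ligand_key: str  # canonical structure key (InChIKey)
    smiles: str
    source_label: str = ""


@dataclasses.dataclass(frozen=True)
class SimilarityHit:
    """A query flagged as potential ligand of a target by the screen."""

    query_id: str
    target_id: str
    best_reference_key: str
    tanimoto: float


@lru_cache(maxsize=8)
def _generator(radius: int, n_bits: int):
    return rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)


def _mol(smiles: str):
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    return mol


def smiles_to_key(smiles: str) -> str:
    """Canonical structure key (full InChIKey) for a SMILES string."""
    key = Chem.MolToInchiKey(_mol(smiles))
    if not key:
        raise ValueError(f"could not derive a structure key for SMILES: {smiles!r}")
    return key


def fingerprint(smiles: str, radius: int = DEFAULT_RADIUS, n_bits: int = DEFAULT_N_BITS):
    """Morgan bit fingerprint (default radius 2, 2048 bits) of a molecule."""
    return _generator(radius, n_bits).GetFingerprint(_mol(smiles))


def tanimoto(a, b) -> float:
    """Tanimoto coefficient |a AND b| / |a OR b|; 0.0 when both are all-zero."""
    if a.GetNumBits() != b.GetNumBits():
        raise ValueError(f"fingerprint length mismatch: {a.GetNumBits()} vs {b.GetNumBits()}")
    if a.GetNumOnBits() == 0 and b.GetNumOnBits() == 0:
        return 0.0
    return float(DataStructs.TanimotoSimilarity(a, b))


class ReferenceLibrary:
    """Deduplicated set of reference interactions merged from >=1 sources."""

    def __init__(self, interactions: pd.DataFrame, merge_report: dict | None = None):
        required = {"target_id", "ligand_key", "smiles"}
        missing = required - set(interactions.columns)
        if missing:
            raise ValueError(f"interaction table lacks column(s): {sorted(missing)}")
        frame = interactions.drop_duplicates(subset=["target_id", "ligand_key"])
        self.frame = frame.reset_index(drop=True)
        self.merge_report = merge_report

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def per_target_counts(self) -> pd.Series:
        return self.frame.groupby("target_id").size().sort_index()

    def ligands_of(self, target_id: str) -> pd.DataFrame:
        return self.frame[self.frame["target_id"] == target_id]


def load_interactions(
    path: str | Path, source_label: str = "", log: RunLog | None = None
) -> pd.DataFrame:
    """Read a delimited interaction table (target_id, smiles[, ligand_key]).

    Structure keys are computed from SMILES where the table does not
    provide them; rows whose SMILES cannot be parsed are dropped and
    counted in the run log.
    """
    log = get_log(log)
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    return interactions_from_frame(df, source_label=source_label, log=log)


def interactions_from_frame(
    df: pd.DataFrame, source_label: str = "", log: RunLog | None = None
) -> pd.DataFrame:
    """Normalize an in-memory interaction table to the library schema."""
    log = get_log(log)
    if "target_id" not in df.columns or "smiles" not in df.columns:
        raise ValueError("interaction table needs 'target_id' and 'smiles' columns")
    df = df.copy()
    if "ligand_key" not in df.columns:
        df["ligand_key"] = pd.NA
    keys, keep = [], []
    for smiles, key in zip(df["smiles"], df["ligand_key"]):
        if isinstance(key, str) and key:
            keys.append(key)
            keep.append(True)
            continue
        try:
            keys.append(smiles_to_key(smiles))
            keep.append(True)
        except ValueError:
            keys.append("")
            keep.append(False)
    n_dropped = len(keep) - sum(keep)
    if n_dropped:
        log.record(f"load_interactions[{source_label}]: dropped {n_dropped} unparsable row(s)")
    df["ligand_key"] = keys
    df = df[np.asarray(keep)]
    if df.empty:
        raise ValueError("no parsable interaction rows")
    df["source_label"] = source_label
    return df[["target_id", "ligand_key", "smiles", "source_label"]].reset_index(drop=True)


def merge_libraries(
    sources: list[pd.DataFrame], log: RunLog | None = None
) -> ReferenceLibrary:
    """Union interaction sources keyed on (target_id, ligand_key).

    The merge report records per-source sizes, every pairwise overlap
    and the union size, e.g. two sources of 6787 and 8536 interactions
    sharing 3631 unite into 11,692 unique interactions.
    """
    log = get_log(log)
    if not sources:
        raise ValueError("merge_libraries needs at least one source")
    keysets = [
        set(zip(src["target_id"], src["ligand_key"]))
        for src in sources
    ]
    sizes = [len(k) for k in keysets]
    overlaps = {
        (i, j): len(keysets[i] & keysets[j])
        for i in range(len(keysets))
        for j in range(i + 1, len(keysets))
    }
    merged = pd.concat(sources, ignore_index=True)
    lib = ReferenceLibrary(
        merged,
        merge_report={
            "source_sizes": sizes,
            "pairwise_overlaps": overlaps,
            "union_size": None,  # filled below
        },
    )
    lib.merge_report["union_size"] = len(lib)
    log.record(
        "merge_libraries: sizes=%s overlaps=%s union=%d"
        % (sizes, {f"{i}-{j}": n for (i, j), n in overlaps.items()}, len(lib))
    )
    return lib


def screen(
    queries: pd.DataFrame,
    lib: ReferenceLibrary,
    cutoff: float = DEFAULT_CUTOFF,
    radius: int = DEFAULT_RADIUS,
    n_bits: int = DEFAULT_N_BITS,
    log: RunLog | None = None,
) -> list[SimilarityHit]:
    """Similarity-screen query compounds against each target's references.

    ``queries`` needs columns ``query_id`` and ``smiles``.  For every
    (query, target) the maximum Tanimoto over that target's reference
    ligands is taken; one hit is emitted when it reaches ``cutoff``
    (inclusive), recording only the best-matching reference.  A query
    may hit many targets.
    """
    log = get_log(log)
    if not 0 < cutoff <= 1:
        raise ValueError("cutoff must be in (0, 1]")
    if len(lib) == 0:
        log.record("screen: empty reference library; no hits possible")
        return []
    # fingerprint each distinct reference structure once
    ref_fps: dict[str, object] = {}
    for key, smiles in zip(lib.frame["ligand_key"], lib.frame["smiles"]):
        if key not in ref_fps:
            try:
                ref_fps[key] = fingerprint(smiles, radius, n_bits)
            except ValueError:
                log.record(f"screen: unparsable reference SMILES for key {key!r}; skipped")
    by_target: dict[str, tuple[list[str], list[object]]] = {}
    for target, key in zip(lib.frame["target_id"], lib.frame["ligand_key"]):
        if key in ref_fps:
            keys, fps = by_target.setdefault(target, ([], []))
            keys.append(key)
            fps.append(ref_fps[key])
    hits: list[SimilarityHit] = []
    for query_id, smiles in zip(queries["query_id"], queries["smiles"]):
        try:
            qfp = fingerprint(smiles, radius, n_bits)
        except ValueError:
            log.record(f"screen: unparsable query SMILES for {query_id!r}; skipped")
            continue
        for target in sorted(by_target):
            keys, fps = by_target[target]
            sims = DataStructs.BulkTanimotoSimilarity(qfp, fps)
            best = int(np.argmax(sims))
            if sims[best] >= cutoff:
                hits.append(
                    SimilarityHit(
                        query_id=str(query_id),
                        target_id=target,
                        best_reference_key=keys[best],
                        tanimoto=float(sims[best]),
                    )
                )
    return hits


def write_hits(hits: list[SimilarityHit], path: str | Path) -> None:
    pd.DataFrame(
        {
            "query_id": [h.query_id for h in hits],
            "target_id": [h.target_id for h in hits],
            "tanimoto": [h.tanimoto for h in hits],
            "best_reference_key": [h.best_reference_key for h in hits],
        }
    ).to_csv(path, sep="\t", index=False)


def mean_pairwise_similarity(
    smiles_list: list[str], radius: int = DEFAULT_RADIUS, n_bits: int = DEFAULT_N_BITS
) -> float:
    """Mean Tanimoto over all unordered pairs; NaN for fewer than 2 molecules.

    Used to check whether the ligands attributed to one target are a
    single structural family (high mean) or chemically diverse (low).
    """
    if len(smiles_list) < 2:
        return float("nan")
    fps = [fingerprint(s, radius, n_bits) for s in smiles_list]
    sims = [
        tanimoto(fps[i], fps[j])
        for i in range(len(fps))
        for j in range(i + 1, len(fps))
    ]
    return float(np.mean(sims))
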