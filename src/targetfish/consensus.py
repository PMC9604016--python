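"""Consensus fusion of the target-based and ligand-based screening results.

The evidence universe has five distinct approaches: the two
post-processing methods crossed with the two docking programs (four
target-based channels) plus the similarity screen.  A unique
(target, ligand) pairing receives a confidence score equal to the
number of distinct approaches that identified it — an integer from 1 to
5, with 5 meaning unanimous support.

An approach that fires in several runs (with and without the
promiscuous-target exclusion) still counts once by default: the score
measures independent lines of evidence, not repetitions.
"""
from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import median_abs_deviation

from .library import SimilarityHit
from .postprocess import PairingSet
from .runlog import RunLog, get_log

SIMILARITY_APPROACH = "similarity"


@dataclasses.dataclass(frozen=True)
class ApproachID:
    """One of the five evidence channels."""

    family: str  # "target_based" | "ligand_based"
    method: str  # "method1" | "method2" | "similarity"
    program_label: str = ""

    def __post_init__(self):
        if self.family == "ligand_based" and self.program_label:
            raise ValueError("ligand-based approaches carry no program label")
        if self.family == "target_based" and self.method == SIMILARITY_APPROACH:
            raise ValueError("similarity is not a target-based method")

    @property
    def name(self) -> str:
        if self.family == "ligand_based":
            return SIMILARITY_APPROACH
        return f"{self.method}:{self.program_label}"


def approach_universe(programs: tuple[str, str] = ("progA", "progB")) -> list[ApproachID]:
    """The canonical 5-member approach universe for two docking programs."""
    return [
        ApproachID("target_based", method, prog)
        for method in ("method1", "method2")
        for prog in programs
    ] + [ApproachID("ligand_based", SIMILARITY_APPROACH)]


class ConsensusTable:
    """Unique (target, ligand) pairings with confidence scores and provenance."""

    def __init__(self, frame: pd.DataFrame):
        required = {"target_id", "ligand_id", "confidence", "approaches", "runs"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"consensus table lacks column(s): {sorted(missing)}")
        if frame.duplicated(subset=["target_id", "ligand_id"]).any():
            raise ValueError("consensus rows must be unique on (target_id, ligand_id)")
        self.frame = frame.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    def filter(self, min_confidence: int) -> "ConsensusTable":
        return ConsensusTable(self.frame[self.frame["confidence"] >= min_confidence].copy())

    def write(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


def build_consensus(
    pairing_sets: list[PairingSet],
    hits: list[SimilarityHit],
    fuse_runs: bool = True,
    log: RunLog | None = None,
) -> ConsensusTable:
    """Fuse docking pairing sets and similarity hits into one scored table.

    Parameters
    ----------
    pairing_sets
        Target-based results carrying (method, program, run) labels; two
        sets with identical labels would double-count and are rejected.
    hits
        Ligand-based screen results (one evidence channel regardless of
        how many reference ligands matched).
    fuse_runs
        When True (default) an approach supports a pairing if it found
        it in ANY run; when False each (approach, run) combination
        counts separately.
    """
    log = get_log(log)
    seen_labels = set()
    for ps in pairing_sets:
        label = (ps.method_label, ps.program_label, ps.run_label)
        if label in seen_labels:
            raise ValueError(f"duplicate pairing set for (method, program, run) = {label}")
        seen_labels.add(label)

    support: dict[tuple[str, str], set] = {}
    runs: dict[tuple[str, str], set] = {}
    for ps in pairing_sets:
        approach = ApproachID("target_based", ps.method_label, ps.program_label)
        channel = approach.name if fuse_runs else f"{approach.name}@{ps.run_label}"
        for pair in ps.pairs:
            support.setdefault(pair, set()).add(channel)
            runs.setdefault(pair, set()).add(ps.run_label)
    for hit in hits:
        pair = (hit.target_id, hit.query_id)
        support.setdefault(pair, set()).add(SIMILARITY_APPROACH)
        runs.setdefault(pair, set()).add("all_targets")

    rows = [
        {
            "target_id": target,
            "ligand_id": ligand,
            "confidence": len(support[(target, ligand)]),
            "approaches": ";".join(sorted(support[(target, ligand)])),
            "runs": ";".join(sorted(runs[(target, ligand)])),
        }
        for target, ligand in support
    ]
    frame = pd.DataFrame(
        rows, columns=["target_id", "ligand_id", "confidence", "approaches", "runs"]
    )
    if not frame.empty:
        frame = frame.sort_values(
            ["confidence", "target_id", "ligand_id"], ascending=[False, True, True]
        )
    log.record(f"build_consensus: {len(frame)} unique pairings from "
               f"{len(pairing_sets)} pairing set(s) and {len(hits)} similarity hit(s)")
    return ConsensusTable(frame)


def summarize_consensus(t: ConsensusTable) -> dict:
    """Distribution summaries of a consensus table.

    Returns a dict with:

    - ``score_counts``: pairings per confidence score (Series);
    - ``ligands_per_target``: associated-ligand count per target;
    - ``targets_per_ligand_hist``: how many ligands have k targets;
    - ``family_overlap``: sizes of the structure-based and ligand-based
      pairing families, their intersection, and the union (= table size).
    """
    frame = t.frame
    if frame.empty:
        empty = pd.Series(dtype=int)
        return {
            "score_counts": empty,
            "ligands_per_target": empty,
            "targets_per_ligand_hist": empty,
            "family_overlap": {"structure_based": 0, "ligand_based": 0, "both": 0, "union": 0},
        }
    approaches = frame["approaches"].str.split(";")
    is_ligand = approaches.map(lambda a: SIMILARITY_APPROACH in a)
    is_structure = approaches.map(lambda a: any(x != SIMILARITY_APPROACH for x in a))
    return {
        "score_counts": frame["confidence"].value_counts().sort_index(),
        "ligands_per_target": frame.groupby("target_id").size().sort_index(),
        "targets_per_ligand_hist": (
            frame.groupby("ligand_id").size().value_counts().sort_index()
        ),
        "family_overlap": {
            "structure_based": int(is_structure.sum()),
            "ligand_based": int(is_ligand.sum()),
            "both": int((is_structure & is_ligand).sum()),
            "union": len(frame),
        },
    }


def detect_promiscuous(
    pairing_sets: list[PairingSet],
    policy: str = "manual",
    manual_list: list[str] | None = None,
    k: float = 5.0,
    log: RunLog | None = None,
) -> list[str]:
    """Name targets to exclude before rerunning the docking analysis.

    ``manual`` (default) passes through a curator-supplied list — the
    choice of promiscuous targets is ultimately a judgement call.  The
    ``automatic`` policy flags targets whose associated-ligand count
    (over the union of all pairings) exceeds median + k*MAD; the MAD is
    floored at one ligand so near-uniform count vectors (MAD = 0) do
    not flag everything a hair above the median.
    """
    log = get_log(log)
    if not pairing_sets:
        raise ValueError("detect_promiscuous needs at least one pairing set")
    if policy == "manual":
        return list(manual_list or [])
    if policy != "automatic":
        raise ValueError(f"unknown promiscuity policy: {policy!r}")
    pairs = set().union(*(ps.pairs for ps in pairing_sets))
    if not pairs:
        return []
    counts = pd.Series([t for t, _ in pairs]).value_counts()
    median = float(counts.median())
    mad = max(float(median_abs_deviation(counts.to_numpy())), 1.0)
    cutoff = median + k * mad
    flagged = sorted(counts.index[counts > cutoff])
    if flagged:
        log.record(
            f"detect_promiscuous: flagged {flagged} "
            f"(counts {[int(counts[t]) for t in flagged]}, cutoff {cutoff:.1f})"
        )
    return flagged
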