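"""Ligand x target docking-score matrices: container, I/O, validation, exclusion.

A :class:`ScoreMatrix` holds the blind-docking binding energies of every
query compound against every candidate target for ONE docking program,
in kcal/mol under the negative sign convention (more negative = stronger
predicted binding).  Matrices from different programs are never merged
numerically; each flows through post-processing on its own and the
programs are only compared at the pairing-set level.

Missing cells (failed dockings, masked non-binders) are NaN and are
excluded from every row/column/matrix statistic downstream.
"""
from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from .runlog import RunLog, get_log

LIGAND_COLUMN = "ligand_id"


@dataclasses.dataclass
class ScoreMatrix:
    """Dense ligand x target table of binding energies (kcal/mol).

    Parameters
    ----------
    scores
        DataFrame indexed by ligand id with one column per target id;
        float cells, NaN for missing.
    program_label
        Free text naming the docking program that produced the matrix.
    """

    scores: pd.DataFrame
    program_label: str = ""

    def __post_init__(self) -> None:
        if self.scores.size == 0:
            raise ValueError("score matrix is empty")
        if self.scores.index.duplicated().any():
            dupes = self.scores.index[self.scores.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate ligand ids: {dupes}")
        if self.scores.columns.duplicated().any():
            dupes = self.scores.columns[self.scores.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate target ids: {dupes}")
        self.scores = self.scores.astype(float)
        self.scores.index = self.scores.index.astype(str)
        self.scores.columns = self.scores.columns.astype(str)
        self.scores.index.name = LIGAND_COLUMN

    @property
    def ligand_ids(self) -> list[str]:
        return list(self.scores.index)

    @property
    def target_ids(self) -> list[str]:
        return list(self.scores.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.scores.shape

    def n_missing(self) -> int:
        return int(self.scores.isna().sum().sum())

    def is_validated(self) -> bool:
        """True when every defined cell is finite and strictly negative."""
        vals = self.scores.to_numpy()
        defined = ~np.isnan(vals)
        return bool(np.all(np.isfinite(vals[defined])) and np.all(vals[defined] < 0))


def read_score_matrix(path: str | Path, program_label: str = "") -> ScoreMatrix:
    """Read a delimited score table (comma or tab, auto-detected).

    The first column holds ligand ids; the header row holds target ids.
    Non-numeric or empty cells become missing.
    """
    with open(path) as fh:
        first = fh.readline()
    delimiter = "\t" if "\t" in first else ","
    header = [h.strip() for h in first.rstrip("\n").split(delimiter)][1:]
    if len(set(header)) != len(header):
        dupes = sorted({t for t in header if header.count(t) > 1})
        raise ValueError(f"duplicate target ids: {dupes}")
    df = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str)
    if df.size == 0:
        raise ValueError(f"empty score table: {path}")

    def _to_float(cell):  # float() is correctly rounded; pd.to_numeric is not
        try:
            return float(cell)
        except (TypeError, ValueError):
            return float("nan")

    return ScoreMatrix(df.map(_to_float), program_label=program_label)


def write_score_matrix(m: ScoreMatrix, path: str | Path) -> None:
    """Write tab-delimited; round-trips bit-identically for finite matrices."""
    # repr gives the shortest digit string that parses back to the same double
    formatted = m.scores.map(lambda v: "" if pd.isna(v) else repr(float(v)))
    formatted.to_csv(path, sep="\t", index_label=LIGAND_COLUMN)


def validate_scores(m: ScoreMatrix, log: RunLog | None = None) -> ScoreMatrix:
    """Mask non-negative cells and drop rows/columns left entirely missing.

    A docking score >= 0 kcal/mol means the pose search failed to find a
    favourable binding mode; such cells cannot participate in the
    quotient normalization (a mixed-sign matrix makes it non-monotone),
    so they are treated as missing rather than imputed.
    """
    log = get_log(log)
    scores = m.scores.copy()
    nonneg = scores >= 0
    n_masked = int(nonneg.sum().sum())
    if n_masked:
        scores = scores.mask(nonneg)
        log.record(f"validate_scores[{m.program_label}]: masked {n_masked} non-negative cell(s)")
    empty_rows = scores.index[scores.isna().all(axis=1)].tolist()
    if empty_rows:
        log.record(
            f"validate_scores[{m.program_label}]: dropped all-missing ligand row(s): {empty_rows}"
        )
        scores = scores.drop(index=empty_rows)
    empty_cols = scores.columns[scores.isna().all(axis=0)].tolist()
    if empty_cols:
        log.record(
            f"validate_scores[{m.program_label}]: dropped all-missing target column(s): {empty_cols}"
        )
        scores = scores.drop(columns=empty_cols)
    if scores.size == 0:
        raise ValueError("validation removed every cell; no negative binding energies present")
    return ScoreMatrix(scores, program_label=m.program_label)


def exclude_targets(
    m: ScoreMatrix, exclusion: list[str], log: RunLog | None = None
) -> ScoreMatrix:
    """Return a copy of ``m`` without the named target columns.

    Used to remove promiscuous targets (e.g. broadly binding kinases)
    whose rows of strong scores bias every ligand-wide mean, after which
    the whole docking analysis is rerun.  Unknown ids are ignored with a
    warning; removing all targets is an error.
    """
    log = get_log(log)
    known = [t for t in exclusion if t in m.scores.columns]
    unknown = [t for t in exclusion if t not in m.scores.columns]
    if unknown:
        log.record(f"exclude_targets[{m.program_label}]: ignoring unknown target id(s): {unknown}")
    if len(known) == len(m.scores.columns):
        raise ValueError("exclusion list removes every target")
    if known:
        log.record(f"exclude_targets[{m.program_label}]: removed {known}")
    return ScoreMatrix(m.scores.drop(columns=known), program_label=m.program_label)
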