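"""Docking score-matrix post-processing: the two inverse-screening filters.

Method I (quotient normalization).  Each binding energy V0 is rescaled by
the mean of its ligand-row mean ML and target-column mean MT::

    V = V0 / ((ML + MT) / 2)

Both V0 and the denominator are negative, so V is positive and larger V
means the cell is strong *relative to* both its ligand's and its
target's typical score, cancelling ligand- and target-wide systematic
shifts to first order.  Pairings with V >= M + 3*sigma (matrix-wide mean
and SD of V) are selected: the overall best-scoring pairings.

Method II (two-directional Z-transformation).  Each cell is standardized
twice: ZT within its target column (across ligands), making scores
comparable across receptors with different score scales, and ZL within
its ligand row (across targets).  The combination

    Zcomb = 0.7 * ZT + 0.3 * ZL

weights the receptor-corrected term more heavily; for every ligand the
receptor with the LOWEST Zcomb (most favourable standardized score) is
selected, naming the single most likely target per ligand.

All statistics are population statistics (divide by n) over defined
cells only; missing cells can never be selected.
"""
from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .matrixio import ScoreMatrix
from .runlog import RunLog, get_log

#: Zcomb weights (target-direction, ligand-direction)
DEFAULT_WEIGHTS = (0.7, 0.3)
#: number of matrix SDs above the matrix mean for the method-I threshold
SIGMA_MULTIPLIER = 3.0


@dataclasses.dataclass
class NormalizedMatrix:
    """Method-I normalized matrix with its selection statistics."""

    values: pd.DataFrame  # V per cell, same axes as the source matrix
    matrix_mean: float  # M: mean of all defined V
    matrix_sd: float  # sigma: population SD of all defined V
    program_label: str = ""

    @property
    def threshold(self) -> float:
        return self.matrix_mean + SIGMA_MULTIPLIER * self.matrix_sd


@dataclasses.dataclass
class ZMatrices:
    """Method-II Z-score matrices and their combination."""

    zt: pd.DataFrame  # target-direction Z
    zl: pd.DataFrame  # ligand-direction Z
    zcomb: pd.DataFrame  # weights[0]*zt + weights[1]*zl
    weights: tuple[float, float] = DEFAULT_WEIGHTS
    orientation: str = "per_target"
    program_label: str = ""


@dataclasses.dataclass(frozen=True)
class PairingSet:
    """A set of (target, ligand) pairings produced by one approach in one run."""

    pairs: frozenset  # of (target_id, ligand_id)
    method_label: str  # "method1" | "method2" | "similarity"
    program_label: str = ""
    run_label: str = "all_targets"  # or "excl_promiscuous"

    def __len__(self) -> int:
        return len(self.pairs)

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(self.pairs)
        return pd.DataFrame(
            {
                "target_id": [t for t, _ in rows],
                "ligand_id": [l for _, l in rows],
                "method": self.method_label,
                "program": self.program_label,
                "run": self.run_label,
            }
        )


def write_pairing_set(ps: PairingSet, path) -> None:
    ps.to_frame().to_csv(path, sep="\t", index=False)


def _require_validated(m: ScoreMatrix) -> None:
    if not m.is_validated():
        raise ValueError(
            "score matrix contains non-negative or non-finite cells; "
            "run matrixio.validate_scores first"
        )


def normalize_method1(m: ScoreMatrix, log: RunLog | None = None) -> NormalizedMatrix:
    """Apply the quotient normalization V = V0 / ((ML + MT)/2).

    ML and MT are means over defined cells only; a row or column with a
    single defined cell degenerates to that cell, which is allowed.
    """
    _require_validated(m)
    scores = m.scores
    row_means = scores.mean(axis=1)  # ML per ligand
    col_means = scores.mean(axis=0)  # MT per target
    denom = (row_means.to_numpy()[:, None] + col_means.to_numpy()[None, :]) / 2.0
    values = pd.DataFrame(
        scores.to_numpy() / denom, index=scores.index, columns=scores.columns
    )
    flat = values.to_numpy()
    defined = flat[~np.isnan(flat)]
    return NormalizedMatrix(
        values=values,
        matrix_mean=float(defined.mean()),
        matrix_sd=float(defined.std(ddof=0)),
        program_label=m.program_label,
    )


def threshold_method1(
    nm: NormalizedMatrix,
    run_label: str = "all_targets",
    inclusive: bool = True,
    log: RunLog | None = None,
) -> PairingSet:
    """Select all pairings with V >= M + 3*sigma (inclusive by default)."""
    log = get_log(log)
    if nm.matrix_sd == 0.0:
        log.record(
            f"threshold_method1[{nm.program_label}]: degenerate constant matrix "
            "(sigma = 0); threshold equals the matrix mean"
        )
    selected = nm.values >= nm.threshold if inclusive else nm.values > nm.threshold
    pairs = frozenset(
        (target, ligand)
        for ligand, row in selected.iterrows()
        for target, hit in row.items()
        if hit
    )
    return PairingSet(
        pairs=pairs, method_label="method1", program_label=nm.program_label, run_label=run_label
    )


def _standardize(values: np.ndarray, axis: int, log: RunLog, label: str) -> np.ndarray:
    """Population Z-score along ``axis``; zero-SD slices get Z = 0, logged."""
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(values, axis=axis, keepdims=True)
        sd = np.nanstd(values, axis=axis, ddof=0, keepdims=True)
    zero = sd == 0
    if np.any(zero):
        log.record(f"ztransform_2d: {int(zero.sum())} zero-SD slice(s) along {label}; Z set to 0")
    sd = np.where(zero, 1.0, sd)
    z = (values - mean) / sd
    # a zero-SD slice has every defined cell equal to its mean
    return np.where(np.broadcast_to(zero, z.shape), np.where(np.isnan(values), np.nan, 0.0), z)


def ztransform_2d(
    m: ScoreMatrix,
    weights: tuple[float, float] = DEFAULT_WEIGHTS,
    orientation: str = "per_target",
    log: RunLog | None = None,
) -> ZMatrices:
    """Two-directional Z-transformation of a validated score matrix.

    Parameters
    ----------
    weights
        (wT, wL) with wT + wL = 1; defaults to (0.7, 0.3).
    orientation
        ``"per_target"`` (default): ZT standardizes each target column
        across ligands and ZL each ligand row across targets.
        ``"per_ligand"``: the transposed convention.

    Rows and columns with fewer than two defined cells are dropped with
    a warning (their SD is undefined or degenerate).
    """
    _require_validated(m)
    log = get_log(log)
    if orientation not in ("per_target", "per_ligand"):
        raise ValueError(f"unknown orientation: {orientation!r}")
    if abs(weights[0] + weights[1] - 1.0) > 1e-12:
        raise ValueError("Zcomb weights must sum to 1")
    scores = m.scores.copy()
    # dropping a sparse row can impoverish a column, so iterate to a fixed point
    while True:
        thin_rows = scores.index[scores.notna().sum(axis=1) < 2]
        thin_cols = scores.columns[scores.notna().sum(axis=0) < 2]
        if len(thin_rows) == 0 and len(thin_cols) == 0:
            break
        if len(thin_rows):
            log.record(
                f"ztransform_2d[{m.program_label}]: dropped ligand row(s) with <2 "
                f"defined cells: {list(thin_rows)}"
            )
        if len(thin_cols):
            log.record(
                f"ztransform_2d[{m.program_label}]: dropped target column(s) with <2 "
                f"defined cells: {list(thin_cols)}"
            )
        scores = scores.drop(index=thin_rows, columns=thin_cols)
        if scores.size == 0:
            raise ValueError("no rows/columns with >=2 defined cells remain")
    vals = scores.to_numpy()
    if orientation == "per_target":
        zt = _standardize(vals, axis=0, log=log, label="target columns")
        zl = _standardize(vals, axis=1, log=log, label="ligand rows")
    else:
        zt = _standardize(vals, axis=1, log=log, label="ligand rows")
        zl = _standardize(vals, axis=0, log=log, label="target columns")
    zcomb = weights[0] * zt + weights[1] * zl
    wrap = lambda a: pd.DataFrame(a, index=scores.index, columns=scores.columns)
    return ZMatrices(
        zt=wrap(zt),
        zl=wrap(zl),
        zcomb=wrap(zcomb),
        weights=weights,
        orientation=orientation,
        program_label=m.program_label,
    )


def select_best_targets(
    z: ZMatrices,
    run_label: str = "all_targets",
    zcomb_cutoff: float | None = None,
    log: RunLog | None = None,
) -> PairingSet:
    """Pick, for every ligand, the receptor with the lowest Zcomb.

    Exact ties are broken toward the lexicographically smallest target
    id (logged); ligands with no defined Zcomb are omitted.  An optional
    ``zcomb_cutoff`` additionally requires the winning Zcomb to be at or
    below the cutoff (off by default: every ligand yields a pairing).
    """
    log = get_log(log)
    zcomb = z.zcomb[sorted(z.zcomb.columns)]
    pairs = set()
    for ligand, row in zcomb.iterrows():
        row = row.dropna()
        if row.empty:
            log.record(f"select_best_targets: ligand {ligand!r} has no defined Zcomb; omitted")
            continue
        best = row.min()
        if zcomb_cutoff is not None and best > zcomb_cutoff:
            continue
        winners = row.index[row == best]
        if len(winners) > 1:
            log.record(
                f"select_best_targets: tie for ligand {ligand!r} among {list(winners)}; "
                f"chose {winners[0]!r}"
            )
        pairs.add((winners[0], ligand))
    return PairingSet(
        pairs=frozenset(pairs),
        method_label="method2",
        program_label=z.program_label,
        run_label=run_label,
    )


def run_method(
    m: ScoreMatrix,
    method: str,
    run_label: str = "all_targets",
    weights: tuple[float, float] = DEFAULT_WEIGHTS,
    orientation: str = "per_target",
    inclusive: bool = True,
    zcomb_cutoff: float | None = None,
    log: RunLog | None = None,
) -> PairingSet:
    """Dispatch a validated matrix through method I or method II."""
    if method == "method1":
        nm = normalize_method1(m, log=log)
        return threshold_method1(nm, run_label=run_label, inclusive=inclusive, log=log)
    if method == "method2":
        z = ztransform_2d(m, weights=weights, orientation=orientation, log=log)
        return select_best_targets(z, run_label=run_label, zcomb_cutoff=zcomb_cutoff, log=log)
    raise ValueError(f"unknown method: {method!r} (expected 'method1' or 'method2')")
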