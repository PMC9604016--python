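import numpy as np
import pandas as pd
import pytest

from targetfish import ScoreMatrix


@pytest.fixture
def small_matrix() -> ScoreMatrix:
    """2x2 matrix whose method-I normalization was worked out by hand."""
    return ScoreMatrix(
        pd.DataFrame(
            [[-10.0, -6.0], [-6.0, -6.0]], index=["lig_a", "lig_b"], columns=["T1", "T2"]
        ),
        program_label="fixture",
    )


@pytest.fixture
def z_fixture_matrix() -> ScoreMatrix:
    """3x3 matrix used against the spreadsheet-style Z-transform oracle."""
    return ScoreMatrix(
        pd.DataFrame(
            [[-12.0, -7.0, -7.0], [-8.0, -8.0, -8.0], [-6.0, -9.0, -9.0]],
            index=["l1", "l2", "l3"],
            columns=["TA", "TB", "TC"],
        ),
        program_label="fixture",
    )


def random_negative_matrix(
    rng: np.random.Generator, n_rows: int, n_cols: int, missing: float = 0.0
) -> ScoreMatrix:
    vals = rng.normal(-8.0, 1.5, (n_rows, n_cols))
    vals = np.minimum(vals, -1e-6)
    if missing:
        mask = rng.random(vals.shape) < missing
        # keep at least 2 defined cells per row/column for the Z-transform
        vals = np.where(mask, np.nan, vals)
    return ScoreMatrix(
        pd.DataFrame(
            vals,
            index=[f"l{i}" for i in range(n_rows)],
            columns=[f"t{j}" for j in range(n_cols)],
        )
    )
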