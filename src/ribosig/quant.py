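"""Replicated protein quantification matrices and their preprocessing.

The container and the three preprocessing steps mirror the standard
label-free / SILAC workflow: log2 transformation of raw intensities,
removal of sparsely quantified proteins, and imputation of the remaining
missing values from a down-shifted normal distribution.  Missing values
model left-censoring: low-abundance proteins drop below the detection
limit, so imputed draws are centred *below* the observed column mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CONTROL = "control"
TREATMENT = "treatment"


class DataError(ValueError):
    """Raised when input data violate a precondition (bad value, sparse column)."""


@dataclass
class QuantMatrix:
    """Proteins x samples intensity table with per-sample condition labels.

    Parameters
    ----------
    values
        DataFrame indexed by protein id with one column per sample.
        ``NaN`` encodes a missing quantification (distinct from a zero
        intensity, which is a data error after log transform).
    conditions
        Series mapping each sample id to ``"control"`` or ``"treatment"``.
    log2_transformed
        Whether :func:`logarithmize` has been applied.  Differential
        testing requires ``True``.
    """

    values: pd.DataFrame
    conditions: pd.Series
    log2_transformed: bool = False

    def __post_init__(self) -> None:
        self.conditions = pd.Series(self.conditions)
        missing = set(self.values.columns) - set(self.conditions.index)
        if missing:
            raise DataError(f"samples without condition label: {sorted(missing)}")
        self.conditions = self.conditions.loc[list(self.values.columns)]
        bad = set(self.conditions.unique()) - {CONTROL, TREATMENT}
        if bad:
            raise DataError(f"unknown condition labels: {sorted(bad)}")
        for cond in (CONTROL, TREATMENT):
            if (self.conditions == cond).sum() < 2:
                raise DataError(f"need >=2 samples in condition {cond!r}")

    def samples(self, condition: str) -> list[str]:
        return list(self.conditions.index[self.conditions == condition])

    @property
    def n_proteins(self) -> int:
        return self.values.shape[0]

    def copy(self) -> "QuantMatrix":
        return QuantMatrix(self.values.copy(), self.conditions.copy(), self.log2_transformed)


@dataclass
class FilterParams:
    """Minimum-valid-value filter: keep proteins quantified in at least
    ``min_valid_frac`` of samples, either overall or within each condition."""

    min_valid_frac: float = 0.70
    scope: str = "overall"  # "overall" | "per_group"

    def __post_init__(self) -> None:
        if not (0 < self.min_valid_frac <= 1):
            raise ValueError("min_valid_frac must be in (0, 1]")
        if self.scope not in ("overall", "per_group"):
            raise ValueError("scope must be 'overall' or 'per_group'")


@dataclass
class ImputeParams:
    """Down-shifted normal imputation, per column, in units of the column SD.

    A missing cell in column *c* is drawn from
    ``Normal(mu_c - shift * sd_c, (width * sd_c)^2)`` where ``mu_c`` and
    ``sd_c`` are the mean and (ddof=1) SD of the observed values in *c*.
    """

    width: float = 0.3
    shift: float = 1.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("width must be > 0")
        if self.shift < 0:
            raise ValueError("shift must be >= 0")


def logarithmize(matrix: QuantMatrix) -> QuantMatrix:
    """Replace every present raw intensity by log2(x); missing stays missing."""
    if matrix.log2_transformed:
        raise DataError("matrix is already log2-transformed")
    vals = matrix.values
    bad = (vals <= 0).any(axis=None)
    if bad:
        rows, cols = np.nonzero((vals <= 0).to_numpy())
        pid, sid = vals.index[rows[0]], vals.columns[cols[0]]
        raise DataError(f"non-positive intensity at protein {pid!r}, sample {sid!r}")
    return QuantMatrix(np.log2(vals), matrix.conditions.copy(), log2_transformed=True)


def filter_valid(matrix: QuantMatrix, params: FilterParams | None = None) -> QuantMatrix:
    """Drop proteins with too few quantified values; row order is preserved."""
    params = params or FilterParams()
    if not matrix.log2_transformed:
        raise DataError("filter_valid expects a log2-transformed matrix")
    present = matrix.values.notna()
    if params.scope == "overall":
        keep = present.mean(axis=1) >= params.min_valid_frac
    else:
        keep = pd.Series(True, index=matrix.values.index)
        for cond in (CONTROL, TREATMENT):
            cols = matrix.samples(cond)
            keep &= present[cols].mean(axis=1) >= params.min_valid_frac
    n_removed = int((~keep).sum())
    logger.info("filter_valid: kept %d of %d proteins (removed %d)",
                int(keep.sum()), len(keep), n_removed)
    if not keep.any():
        logger.warning("filter_valid: no proteins survive the %.0f%% rule",
                       100 * params.min_valid_frac)
    return QuantMatrix(matrix.values.loc[keep], matrix.conditions.copy(), True)


def impute_downshifted_normal(
    matrix: QuantMatrix, params: ImputeParams | None = None
) -> QuantMatrix:
    """Fill missing cells column-wise from the down-shifted normal.

    Observed cells are never altered; output is deterministic under
    ``params.seed``.
    """
    params = params or ImputeParams()
    if not matrix.log2_transformed:
        raise DataError("imputation expects a log2-transformed matrix")
    vals = matrix.values.copy()
    if not vals.isna().any(axis=None):
        return QuantMatrix(vals, matrix.conditions.copy(), True)
    rng = np.random.default_rng(params.seed)
    for col in vals.columns:
        x = vals[col]
        observed = x.dropna()
        n_missing = int(x.isna().sum())
        if n_missing == 0:
            continue
        if len(observed) < 2:
            raise DataError(f"column {col!r} has <2 observed values; cannot impute")
        mu, sd = observed.mean(), observed.std(ddof=1)
        draws = rng.normal(mu - params.shift * sd, params.width * sd, size=n_missing)
        vals.loc[x.isna(), col] = draws
    return QuantMatrix(vals, matrix.conditions.copy(), True)
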