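"""Interannual changes and the population-dynamics distance matrix.

The pipeline measures synchrony between species as the Pearson
correlation r of their year-to-year changes in standardized log
abundance, computed over complete pairs of observations, and converts it
to the distance d = 1 - r: 0 means perfectly synchronous dynamics, 1
uncorrelated, 2 perfectly opposite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import AbundanceMatrix

__all__ = [
    "standardize",
    "interannual_changes",
    "correlation_matrix",
    "to_distance",
    "ChangeMatrix",
    "DynamicsDistanceMatrix",
    "dynamics_distance",
]


@dataclass
class ChangeMatrix:
    """Species x year matrix of interannual changes Delta_t = x_t - x_{t-1}.

    Columns are labelled by the later year t; a change is missing iff
    either source year is missing.
    """

    data: pd.DataFrame

    @property
    def species(self) -> list[str]:
        return list(self.data.index)

    @property
    def change_years(self) -> list[int]:
        return list(self.data.columns)


@dataclass
class DynamicsDistanceMatrix:
    """Symmetric d = 1 - r matrix with complete-pair counts.

    Entries lie in [0, 2] (NaN where too few overlapping years exist);
    the diagonal is 0.
    """

    d: pd.DataFrame
    n_pairs: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.d.to_numpy(float)
        if not np.allclose(vals, vals.T, equal_nan=True):
            raise ValueError("distance matrix is not symmetric")
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < -1e-9 or finite.max() > 2 + 1e-9):
            raise ValueError("distance entries outside [0, 2]")

    @property
    def species(self) -> list[str]:
        return list(self.d.index)

    def require_complete(self) -> pd.DataFrame:
        """Return d, erroring if any pair is undefined (too few overlaps)."""
        if self.d.isna().any().any():
            bad = [
                (i, j)
                for i in self.d.index
                for j in self.d.columns
                if i < j and pd.isna(self.d.loc[i, j])
            ]
            raise ValueError(
                "distance matrix has undefined pairs (too few overlapping "
                f"years): {bad[:10]}{'...' if len(bad) > 10 else ''}; raise "
                "data coverage or lower min_pairs"
            )
        return self.d


def standardize(abund: AbundanceMatrix) -> AbundanceMatrix:
    """Z-score each species' series over its non-missing years.

    Constant (zero-variance) series cannot be standardized and are
    excluded with a warning naming the species.  The subsequent Pearson
    correlations are invariant to any per-species affine rescaling, so
    the choice of z-scoring only fixes a convention.
    """
    df = abund.data
    sd = df.std(axis=1, ddof=1)
    constant = sd.index[(sd == 0) | sd.isna()].tolist()
    if constant:
        warnings.warn(f"excluding constant-series species: {constant}")
        df = df.drop(index=constant)
        sd = sd.drop(index=constant)
    mean = df.mean(axis=1)
    z = df.sub(mean, axis=0).div(sd, axis=0)
    return AbundanceMatrix(z)


def interannual_changes(abund: AbundanceMatrix) -> ChangeMatrix:
    """Difference each series: Delta_t = x_t - x_{t-1}, labelled by year t."""
    df = abund.data
    delta = df.diff(axis=1).iloc[:, 1:]
    return ChangeMatrix(delta)


def correlation_matrix(
    changes: ChangeMatrix, min_pairs: int = 10
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise complete-observations Pearson correlation of changes.

    Only years where both species have a defined change enter each
    pairwise correlation; pairs with fewer than ``min_pairs`` complete
    observations are left NaN rather than fabricated.  Returns
    ``(r, n_pairs)``.
    """
    if min_pairs < 3:
        raise ValueError("min_pairs must be >= 3")
    df = changes.data
    present = df.notna().to_numpy(float)
    n_pairs = present @ present.T
    r = df.T.corr(method="pearson", min_periods=min_pairs)
    np.fill_diagonal(r.values, 1.0)
    n_df = pd.DataFrame(
        n_pairs.astype(int), index=df.index, columns=df.index
    )
    low = (n_df < min_pairs).to_numpy()
    np.fill_diagonal(low, False)
    if low.any():
        k = int(low.sum() // 2)
        warnings.warn(
            f"{k} species pairs have fewer than {min_pairs} complete "
            "observations; their correlations are undefined"
        )
    return r, n_df


def to_distance(
    r: pd.DataFrame, n_pairs: pd.DataFrame | None = None
) -> DynamicsDistanceMatrix:
    """Map correlations to distances d = 1 - r (multiply by -1, add 1)."""
    vals = r.to_numpy(float)
    finite = vals[np.isfinite(vals)]
    if finite.size and (finite.min() < -1 - 1e-8 or finite.max() > 1 + 1e-8):
        raise ValueError("correlation entries outside [-1, 1]")
    d = (1.0 - r).clip(lower=0.0, upper=2.0)
    np.fill_diagonal(d.values, 0.0)
    if n_pairs is None:
        n_pairs = pd.DataFrame(0, index=r.index, columns=r.columns)
    return DynamicsDistanceMatrix(d=d, n_pairs=n_pairs)


def dynamics_distance(
    abund: AbundanceMatrix, min_pairs: int = 10
) -> DynamicsDistanceMatrix:
    """Full chain: standardize -> difference -> correlate -> d = 1 - r."""
    z = standardize(abund)
    changes = interannual_changes(z)
    r, n = correlation_matrix(changes, min_pairs=min_pairs)
    return to_distance(r, n)
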