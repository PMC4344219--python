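"""Preprocessing: filtering rules, standardization, and the feature matrix.

The pipeline applies, in this fixed order:

1. drop areas with zero households (they break ratio denominators),
2. reset MOEs on zero estimates to zero (published zero-estimate MOEs are a
   statewide placeholder, not a measurement),
3. z-score the attribute values so dollar-, count- and ratio-scale variables
   contribute comparably to the homogeneity objective,
4. principal components on the standardized attributes, keeping every
   component but down-weighting each by the share of variance it explains, so
   correlated inputs do not dominate the objective while 100% of the variance
   is retained.

The resulting :class:`FeatureMatrix` holds the weighted component scores fed
to the sum-of-squared-deviations objective.  Constraint feasibility also uses
the 5%-proportion exemption computed here: a proportion estimated below 5%
in a candidate region is released from its CV constraint, because CVs of tiny
proportions are unstable and misleadingly large.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError
from .survey import AreaTable, VariableSpec

#: proportions estimated below this are released from the CV constraint
PROPORTION_EXEMPTION_THRESHOLD = 0.05


@dataclass
class FeatureMatrix:
    """Weighted principal-component scores used by the SSD objective."""

    ids: list[str]
    scores: np.ndarray  # (n_areas, n_components), weighted
    weights: np.ndarray  # explained-variance shares, sum to 1
    explained_variance: np.ndarray  # eigenvalues of the standardized data

    def row_index(self) -> dict[str, int]:
        return {a: i for i, a in enumerate(self.ids)}


@dataclass
class PreprocessReport:
    dropped_zero_household: list[str] = field(default_factory=list)
    zero_moe_resets: int = 0
    component_weights: list[float] = field(default_factory=list)
    n_components_dropped: int = 0


def filter_zero_household(table: AreaTable) -> tuple[AreaTable, list[str]]:
    """Drop areas with zero households (parks, prisons, water, ...)."""
    hh = table.df[table.households_col]
    dropped = [str(a) for a in table.df.index[hh == 0]]
    if len(dropped) == table.n_areas:
        raise DataError("every area has zero households; nothing to regionalize")
    kept = table.df.loc[hh > 0].copy()
    return AreaTable(kept, table.households_col, table.pop_est_col, table.pop_moe_col), dropped


def reset_zero_moes(table: AreaTable, specs: Sequence[VariableSpec]) -> tuple[AreaTable, int]:
    """Reset MOEs of zero estimates to zero.

    Published MOEs on zero estimates are a statewide constant unrelated to the
    area's sample, so they are treated as exactly zero instead.
    """
    df = table.df.copy()
    count = 0
    pairs = [(table.pop_est_col, table.pop_moe_col)]
    for spec in specs:
        pairs.append((spec.num_est, spec.num_moe))
        if spec.den_est is not None:
            pairs.append((spec.den_est, spec.den_moe))
    for est_col, moe_col in dict.fromkeys(pairs):
        mask = (df[est_col] == 0) & (df[moe_col] > 0)
        count += int(mask.sum())
        df.loc[mask, moe_col] = 0.0
    return AreaTable(df, table.households_col, table.pop_est_col, table.pop_moe_col), count


def attribute_matrix(table: AreaTable, specs: Sequence[VariableSpec]) -> pd.DataFrame:
    """Per-area attribute values: the estimate for counts, the ratio for
    derived variables.  These are the values the objective compares."""
    cols = {}
    for spec in specs:
        if spec.kind == "count":
            cols[spec.name] = table.df[spec.num_est].astype(float)
        else:
            den = table.df[spec.den_est].astype(float)
            if (den <= 0).any():
                bad = table.df.index[den <= 0][0]
                raise DataError(
                    f"variable {spec.name!r}: nonpositive denominator in area {bad!r}; "
                    "exclude the area or fix the data before regionalizing"
                )
            cols[spec.name] = table.df[spec.num_est].astype(float) / den
    return pd.DataFrame(cols, index=table.df.index)


def zscore(matrix: pd.DataFrame) -> pd.DataFrame:
    """Standardize each column to mean 0, sample (n-1) standard deviation 1."""
    sd = matrix.std(ddof=1)
    zero = sd[sd == 0].index.tolist()
    if zero:
        raise DataError(
            f"zero-variance column(s): {', '.join(map(str, zero))}; "
            "constant attributes carry no clustering information"
        )
    return (matrix - matrix.mean()) / sd


def pca_features(standardized: pd.DataFrame, rank_tol: float = 1e-10) -> FeatureMatrix:
    """All-component PCA with explained-variance weighting.

    Component scores are whitened to unit variance and multiplied by the
    component's explained-variance share w_c = lambda_c / sum(lambda), so a
    component's maximum possible contribution to squared deviations is
    proportional to the variance it explains.  Rank-deficient inputs drop the
    numerically null components and renormalize the weights.
    """
    n, j = standardized.shape
    if n < j:
        raise DataError(f"need at least as many areas ({n}) as attributes ({j}) for PCA")
    Z = standardized.to_numpy(dtype=float)
    Z = Z - Z.mean(axis=0)
    U, S, _ = np.linalg.svd(Z, full_matrices=False)
    lam = S**2 / (n - 1)
    keep = lam > rank_tol
    n_dropped = int((~keep).sum())
    if n_dropped:
        warnings.warn(
            f"dropping {n_dropped} numerically null principal component(s)",
            stacklevel=2,
        )
    lam = lam[keep]
    weights = lam / lam.sum()
    # U*S are raw scores with variance lam; whiten then apply weights
    scores = U[:, keep] * S[keep]
    whitened = scores / np.sqrt(lam)
    weighted = whitened * weights
    return FeatureMatrix(
        ids=[str(i) for i in standardized.index],
        scores=weighted,
        weights=weights,
        explained_variance=lam,
    )


def exemption_mask(
    region_estimates: Mapping[str, float], specs: Sequence[VariableSpec]
) -> dict[str, bool]:
    """Which variables' CV constraints are waived for a candidate region.

    Only proportions with a region-level estimate strictly below 5% are
    exempt; counts and means never are.
    """
    mask = {}
    for spec in specs:
        mask[spec.name] = (
            spec.kind == "proportion"
            and region_estimates[spec.name] < PROPORTION_EXEMPTION_THRESHOLD
        )
    return mask


class Preprocessor:
    """Stage-ordered preprocessing pipeline.

    The order filter -> reset -> zscore -> pca is fixed; calling a stage out
    of order raises.  Use :meth:`run` for the common case.
    """

    _STAGES = ("filter", "reset", "zscore", "pca")

    def __init__(self, table: AreaTable, specs: Sequence[VariableSpec]) -> None:
        self.table = table
        self.specs = list(specs)
        self.report = PreprocessReport()
        self._done: list[str] = []

    def _enter(self, stage: str) -> None:
        expected = self._STAGES[len(self._done)]
        if stage != expected:
            raise DataError(
                f"preprocessing stage {stage!r} out of order; expected {expected!r} "
                f"(completed: {self._done or 'none'})"
            )
        self._done.append(stage)

    def filter(self) -> "Preprocessor":
        self._enter("filter")
        self.table, dropped = filter_zero_household(self.table)
        self.report.dropped_zero_household = dropped
        return self

    def reset(self) -> "Preprocessor":
        self._enter("reset")
        self.table, count = reset_zero_moes(self.table, self.specs)
        self.report.zero_moe_resets = count
        return self

    def zscore(self) -> "Preprocessor":
        self._enter("zscore")
        self._standardized = zscore(attribute_matrix(self.table, self.specs))
        return self

    def pca(self) -> "Preprocessor":
        self._enter("pca")
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            self.features = pca_features(self._standardized)
        self.report.n_components_dropped = len(
            self._standardized.columns
        ) - len(self.features.weights)
        self.report.component_weights = [float(w) for w in self.features.weights]
        return self

    def run(self) -> tuple[AreaTable, FeatureMatrix, PreprocessReport]:
        self.filter().reset().zscore().pca()
        return self.table, self.features, self.report


def preprocess(
    table: AreaTable, specs: Sequence[VariableSpec]
) -> tuple[AreaTable, FeatureMatrix, PreprocessReport]:
    """Run the full fixed-order preprocessing pipeline."""
    return Preprocessor(table, specs).run()
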