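"""Normalization and quantitative-response design construction.

The analysis regresses every probe's expression on a continuous per-sample
response derived from one morpho-physiological trait: trait values measured
per genotype are rescaled to [0, 1] (min-max by default, average-rank as an
alternative) and every replicate of a genotype inherits its genotype's
weight verbatim.  Expression is quantile-normalized across arrays and
log2-transformed before scoring; control and stressed samples are analyzed
separately.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import CONDITIONS, ExpressionMatrix, TraitTable

logger = logging.getLogger("traitsam")

#: fewest samples per condition for a non-vacuous permutation null
MIN_SAMPLES_PER_CONDITION = 4

WEIGHTING_METHODS = ("minmax", "rank")


class PreprocessError(ValueError):
    """Raised for degenerate traits, missing conditions or invalid designs."""


@dataclass
class WeightedResponse:
    """Per-sample quantitative response for one trait.

    ``y`` is aligned with ``sample_ids``; all replicates of a genotype share
    one value and, under min-max weighting over the represented genotypes,
    the responses span [0, 1].  ``n_dropped`` counts sample columns removed
    because their genotype lacked a trait measurement.
    """

    trait: str | None
    method: str
    sample_ids: list[str]
    y: np.ndarray
    condition: str | None = None
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        if self.y.shape != (len(self.sample_ids),):
            raise PreprocessError("response length does not match sample ids")
        if not np.isfinite(self.y).all():
            raise PreprocessError("non-finite response value")
        if self.y.min() < -1e-12 or self.y.max() > 1 + 1e-12:
            raise PreprocessError("responses must lie in [0, 1]")
        if np.unique(self.y).size < 2:
            raise PreprocessError("response needs >= 2 distinct values")

    @property
    def ybar(self) -> float:
        return float(self.y.mean())


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample column onto the common empirical distribution.

    The reference distribution is the row-wise mean of the column-wise
    sorted values; ties within a column receive the mean of the reference
    values at their tied ranks (deterministic).  On tie-free data the
    operation is idempotent and leaves every column with an identical
    sorted value vector; columns with ties keep averaged values, so their
    empirical distributions can differ at the tied ranks.
    """
    X = matrix.values
    if X.shape[1] < 2:
        raise PreprocessError("quantile normalization needs >= 2 samples")
    if not np.isfinite(X).all():
        raise PreprocessError("NaN/inf in expression values")
    reference = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        col = X[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty_like(reference)
        assigned[order] = reference
        # average the reference values over each block of tied input values
        uniq, inverse, counts = np.unique(col, return_inverse=True,
                                          return_counts=True)
        if uniq.size < col.size:
            sums = np.bincount(inverse, weights=assigned)
            assigned = (sums / counts)[inverse]
        out[:, j] = assigned
    return matrix.with_values(out)


def log2_transform(matrix: ExpressionMatrix, pseudocount: float = 0.0) -> ExpressionMatrix:
    """log2(value + pseudocount); no-op (with a warning) on log2-scale input."""
    if pseudocount < 0:
        raise PreprocessError("pseudocount must be >= 0")
    if matrix.scale == "log2":
        logger.warning("log2_transform: matrix already on log2 scale; no-op")
        return matrix.with_values(matrix.values.copy())
    shifted = matrix.values + pseudocount
    if (shifted <= 0).any():
        i, j = np.argwhere(shifted <= 0)[0]
        raise PreprocessError(
            f"non-positive value at probe {matrix.probe_ids[i]!r}, "
            f"sample {matrix.sample_ids[j]!r} with pseudocount {pseudocount}"
        )
    return matrix.with_values(np.log2(shifted), scale="log2")


def subset_condition(matrix: ExpressionMatrix, condition: str) -> ExpressionMatrix:
    """Columns of one condition, probe order preserved."""
    if condition not in CONDITIONS:
        raise PreprocessError(f"unknown condition {condition!r}")
    ids = [s for s, c in matrix.samples["condition"].items() if c == condition]
    if not ids:
        raise PreprocessError(f"no samples with condition {condition!r}")
    return matrix.select_samples(ids)


def split_by_condition(matrix: ExpressionMatrix) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Partition columns into (control, stressed); both conditions required.

    A condition with fewer than four samples is an error because its
    permutation null would be vacuous.
    """
    present = set(matrix.samples["condition"])
    missing = set(CONDITIONS) - present
    if missing:
        raise PreprocessError(f"condition(s) {sorted(missing)} absent from matrix")
    parts = []
    for cond in CONDITIONS:
        sub = subset_condition(matrix, cond)
        if sub.n_samples < MIN_SAMPLES_PER_CONDITION:
            raise PreprocessError(
                f"condition {cond!r} has only {sub.n_samples} samples "
                f"(< {MIN_SAMPLES_PER_CONDITION})"
            )
        parts.append(sub)
    return parts[0], parts[1]


# ---------------------------------------------------------------------------
# trait weighting and response design
# ---------------------------------------------------------------------------

def weight_trait(
    traits: TraitTable, trait: str, method: str = "minmax"
) -> tuple[pd.Series, list[str]]:
    """Rescale one trait's per-genotype values to [0, 1].

    ``minmax``: w = (v - min)/(max - min), so the extreme genotypes map
    exactly to 0 and 1 and the weights are invariant to positive affine
    transforms of the raw trait.  ``rank``: average ranks mapped to
    (rank - 1)/(G - 1).  Returns (weights over measured genotypes, list of
    genotypes excluded for missing values).
    """
    if method not in WEIGHTING_METHODS:
        raise PreprocessError(f"unknown weighting method {method!r}")
    if trait not in traits.data.columns:
        raise PreprocessError(f"trait {trait!r} not in trait table")
    col = traits.data[trait]
    excluded = list(col.index[col.isna()])
    v = col.dropna()
    if len(v) < 2:
        raise PreprocessError(f"trait {trait!r}: need >= 2 measured genotypes")
    vals = v.to_numpy(dtype=float)
    if np.ptp(vals) == 0:
        raise PreprocessError(f"trait {trait!r} is degenerate (all values equal)")
    if method == "minmax":
        w = (vals - vals.min()) / np.ptp(vals)
    else:
        ranks = stats.rankdata(vals, method="average")
        w = (ranks - 1.0) / (len(vals) - 1.0)
    if excluded:
        logger.info("weight_trait(%s): %d genotype(s) lack measurements: %s",
                    trait, len(excluded), excluded)
    return pd.Series(w, index=v.index, name=trait), excluded


def build_response_design(
    matrix: ExpressionMatrix,
    weights: pd.Series,
    trait: str | None = None,
    method: str = "minmax",
    condition: str | None = None,
) -> WeightedResponse:
    """Assign each sample column its genotype's trait weight.

    Columns whose genotype has no weight (trait not measured) are dropped
    with a logged count; probe values are never touched — downstream scoring
    aligns the matrix to ``sample_ids`` of the returned response.
    """
    genotype_of = matrix.samples["genotype"]
    keep: list[str] = []
    y: list[float] = []
    for sid in matrix.sample_ids:
        g = genotype_of[sid]
        if g in weights.index and not np.isnan(weights[g]):
            keep.append(sid)
            y.append(float(weights[g]))
    n_dropped = matrix.n_samples - len(keep)
    if not keep:
        raise PreprocessError("all genotypes excluded: no samples with a trait weight")
    if n_dropped:
        logger.info("build_response_design: dropped %d sample column(s) of "
                    "unmeasured genotypes", n_dropped)
    trait_name = trait if trait is not None else weights.name
    return WeightedResponse(trait_name, method, keep, np.array(y),
                            condition=condition, n_dropped=n_dropped)
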