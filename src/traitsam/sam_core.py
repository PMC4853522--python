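"""Quantitative-response SAM: scores, fudge factor, permutation FDR, selection.

For probe i with expression x_ij and per-sample response y_j in [0, 1] the
score is d_i = r_i / (s_i + s0), where r_i is the least-squares slope of
x_i on y, s_i the standard error of that slope and s0 a small "fudge
factor" that stabilizes scores of low-variance probes.  Significance is
assessed by permuting the response across sample columns: expected order
statistics of the permuted scores give, for each threshold Delta,
asymmetric score cut-offs, a median false-call count, a null-proportion
estimate pi0 and hence an FDR; a probe's q-value is the smallest FDR at
which it is called.  Selection combines an FDR ceiling (default 5%) with a
minimum absolute score (default 2).
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sympy.utilities.iterables import multiset_permutations

from .io_formats import ExpressionMatrix, TraitTable
from .preprocess import (
    WeightedResponse,
    build_response_design,
    subset_condition,
    weight_trait,
)

logger = logging.getLogger("traitsam")

DEFAULT_PERMUTATIONS = 100
DEFAULT_MAX_FDR_PERCENT = 5.0
DEFAULT_MIN_ABS_D = 2.0
DEFAULT_N_DELTA = 200
DEFAULT_FALSE_SUMMARY = "p90"
S0_CANDIDATE_PERCENTILES = np.arange(0, 101, 5)
MAD_SCALE = 1.4826  # consistency factor for a normal distribution


class SamError(ValueError):
    """Raised for designs the statistic is undefined on."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class SamScores:
    """Per-probe slope r, slope standard error s and score d = r/(s + s0)."""

    probe_ids: list[str]
    r: np.ndarray
    s: np.ndarray
    d: np.ndarray
    s0: float
    s0_percentile: float | None = None

    def __post_init__(self) -> None:
        m = len(self.probe_ids)
        for name in ("r", "s", "d"):
            v = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, v)
            if v.shape != (m,):
                raise SamError(f"{name} must have one entry per probe")
        if (self.s < 0).any() or self.s0 < 0:
            raise SamError("standard errors and s0 must be >= 0")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"probe_id": self.probe_ids, "r": self.r,
                             "s": self.s, "d": self.d})


@dataclass
class PermutationNull:
    """Permuted score matrix (probes x B) and expected order statistics.

    ``dbar[k]`` is the mean over permutations of the k-th smallest permuted
    score; ``exact`` records whether all distinct response permutations were
    enumerated instead of sampled.
    """

    d_star: np.ndarray
    dbar: np.ndarray
    B: int
    seed: int | None
    exact: bool = False

    def __post_init__(self) -> None:
        if self.d_star.shape != (self.dbar.size, self.B):
            raise SamError("permuted score matrix must be probes x B")
        if np.any(np.diff(self.dbar) < -1e-12):
            raise SamError("expected order statistics must be non-decreasing")


@dataclass
class FdrTable:
    """Delta grid with cut-offs, call counts, false-call summary and FDR (%)."""

    table: pd.DataFrame
    pi0: float
    false_summary: str = DEFAULT_FALSE_SUMMARY

    COLUMNS = ["delta", "cut_up", "cut_low", "n_called", "false_calls",
               "fdr_percent"]

    def __post_init__(self) -> None:
        if list(self.table.columns) != self.COLUMNS:
            raise SamError(f"FDR table must have columns {self.COLUMNS}")
        called = self.table["n_called"].to_numpy()
        if np.any(np.diff(called) > 0):
            raise SamError("number called must be non-increasing in delta")
        fdr = self.table["fdr_percent"].to_numpy()
        if (fdr < 0).any() or (fdr > 100).any():
            raise SamError("FDR must lie in [0, 100]")
        if not 0 < self.pi0 <= 1:
            raise SamError("pi0 must lie in (0, 1]")


@dataclass
class SignificantGeneSet:
    """Probes passing the combined FDR / absolute-score rule for one trait.

    ``table`` has columns probe_id, d, q_percent, direction; direction is
    ``positive`` for d > 0 and ``negative`` for d < 0.
    """

    table: pd.DataFrame
    trait: str | None = None
    condition: str | None = None
    max_fdr_percent: float = DEFAULT_MAX_FDR_PERCENT
    min_abs_d: float = DEFAULT_MIN_ABS_D

    def __post_init__(self) -> None:
        t = self.table
        if list(t.columns) != ["probe_id", "d", "q_percent", "direction"]:
            raise SamError("significant-set table has the wrong columns")
        if len(t):
            if (t["q_percent"] > self.max_fdr_percent).any():
                raise SamError("member exceeds the FDR threshold")
            if (t["d"].abs() < self.min_abs_d).any():
                raise SamError("member below the |d| threshold")
            expect = np.where(t["d"] > 0, "positive", "negative")
            if (t["direction"].to_numpy() != expect).any():
                raise SamError("direction inconsistent with sign of d")

    @property
    def positive(self) -> list[str]:
        return list(self.table.loc[self.table["d"] > 0, "probe_id"])

    @property
    def negative(self) -> list[str]:
        return list(self.table.loc[self.table["d"] < 0, "probe_id"])

    def __len__(self) -> int:
        return len(self.table)


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def _slopes_and_errors(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized per-probe simple linear regression of X rows on Y columns.

    X is probes x n; Y is n x B response vectors (columns are permutations
    of one another, so the response sum of squares is shared).  Returns
    (r, s): slopes and slope standard errors, each probes x B.
    """
    n = X.shape[1]
    Yc = Y - Y.mean(axis=0, keepdims=True)
    syy = float((Yc[:, 0] ** 2).sum())
    Xc = X - X.mean(axis=1, keepdims=True)
    sxx = (Xc ** 2).sum(axis=1)
    r = (Xc @ Yc) / syy
    ssr = np.maximum(sxx[:, None] - r ** 2 * syy, 0.0)
    s = np.sqrt(ssr / (n - 2)) / math.sqrt(syy)
    return r, s


def compute_regression_scores(
    matrix: ExpressionMatrix, response: WeightedResponse, s0: float
) -> SamScores:
    """Score every probe against the weighted trait response.

    r_i = sum_j x_ij (y_j - ybar) / sum_j (y_j - ybar)^2 (the least-squares
    slope), s_i = sqrt(residual SS / (n - 2)) / sqrt(sum_j (y_j - ybar)^2)
    (its standard error), d_i = r_i / (s_i + s0).  A zero-variance probe
    scores r = s = d = 0.  The matrix is aligned to the response's sample
    columns, so columns dropped during design construction are ignored here.
    """
    if s0 < 0:
        raise SamError("s0 must be >= 0")
    sub = matrix if matrix.sample_ids == response.sample_ids \
        else matrix.select_samples(response.sample_ids)
    n = sub.n_samples
    if n < 4:
        raise SamError(f"need >= 4 samples, got {n}")
    y = response.y
    if np.unique(y).size < 2:
        raise SamError("all responses equal")
    r, s = _slopes_and_errors(sub.values, y[:, None])
    r, s = r[:, 0], s[:, 0]
    d = _safe_score(r, s, s0)
    zero_var = (sub.values.var(axis=1) == 0)
    r[zero_var] = 0.0
    s[zero_var] = 0.0
    d[zero_var] = 0.0
    return SamScores(list(sub.probe_ids), r, s, d, float(s0))


def _safe_score(r: np.ndarray, s: np.ndarray, s0: float) -> np.ndarray:
    denom = s + s0
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(denom > 0, r / np.where(denom > 0, denom, 1.0), 0.0)
    return d


# ---------------------------------------------------------------------------
# fudge factor
# ---------------------------------------------------------------------------

def estimate_s0(r: np.ndarray, s: np.ndarray) -> tuple[float, float]:
    """Choose the fudge factor s0 as a percentile of the s distribution.

    Candidates are the 0th, 5th, ..., 100th percentiles of s.  For each
    candidate the probes are split into up to 100 equal-count bins by s and
    the spread of the candidate scores within each bin is measured by
    1.4826 x median absolute deviation; the candidate minimizing the
    coefficient of variation of these bin spreads wins (smallest percentile
    on ties).  With fewer than two distinct s values the median of s is
    returned with a warning.
    """
    r = np.asarray(r, dtype=float)
    s = np.asarray(s, dtype=float)
    if r.shape != s.shape or r.ndim != 1:
        raise SamError("r and s must be equal-length vectors")
    m = r.size
    if np.unique(s).size < 2:
        s0 = float(np.median(s))
        logger.warning("estimate_s0: s has < 2 distinct values; falling back "
                       "to median(s) = %g", s0)
        return s0, 50.0
    order = np.argsort(s, kind="stable")
    n_bins = max(1, min(100, m // 2))
    bins = np.array_split(order, n_bins)
    best: tuple[float, float, float] | None = None  # (cv, percentile, s0)
    for alpha in S0_CANDIDATE_PERCENTILES:
        s0c = float(np.percentile(s, alpha))
        d = _safe_score(r, s, s0c)
        spreads = np.array([
            MAD_SCALE * np.median(np.abs(d[b] - np.median(d[b]))) for b in bins
        ])
        mean_spread = spreads.mean()
        cv = float(spreads.std() / mean_spread) if mean_spread > 0 else np.inf
        if best is None or cv < best[0] - 1e-15:
            best = (cv, float(alpha), s0c)
    assert best is not None
    return best[2], best[1]


# ---------------------------------------------------------------------------
# permutation null
# ---------------------------------------------------------------------------

def _n_distinct_permutations(values: np.ndarray) -> float:
    counts = Counter(values.tolist())
    total = math.factorial(len(values))
    for c in counts.values():
        total //= math.factorial(c)
    return total


def permutation_null(
    matrix: ExpressionMatrix,
    response: WeightedResponse,
    s0: float,
    B: int = DEFAULT_PERMUTATIONS,
    seed: int | None = 1,
    permute: str = "samples",
) -> PermutationNull:
    """Null score distribution from random relabelings of the response.

    By default the response vector is permuted uniformly across sample
    columns (replicate ties in the permuted vectors are allowed);
    ``permute="genotype"`` instead permutes the genotype-level weights as
    blocks, keeping replicate structure intact.  s0 is fixed from the
    observed data, never re-estimated per permutation.  If the multiset of
    responses admits no more than B distinct arrangements, all of them are
    enumerated instead (an exact null, logged).
    """
    if B < 10:
        raise SamError("need at least 10 permutations")
    if permute not in ("samples", "genotype"):
        raise SamError(f"unknown permutation scheme {permute!r}")
    sub = matrix if matrix.sample_ids == response.sample_ids \
        else matrix.select_samples(response.sample_ids)
    y = response.y

    if permute == "genotype":
        genos = sub.samples["genotype"].to_numpy()
        uniq_g = list(dict.fromkeys(genos))
        gy = np.array([y[genos == g][0] for g in uniq_g])
        n_distinct = _n_distinct_permutations(gy)
        if n_distinct <= B:
            perms_g = [np.asarray(p, dtype=float)
                       for p in multiset_permutations(sorted(gy.tolist()))]
            logger.info("permutation_null: enumerating all %d distinct "
                        "genotype-block arrangements", len(perms_g))
            exact, B_eff = True, len(perms_g)
        else:
            rng = np.random.default_rng(seed)
            perms_g = [rng.permutation(gy) for _ in range(B)]
            exact, B_eff = False, B
        g_index = {g: i for i, g in enumerate(uniq_g)}
        cols = np.array([g_index[g] for g in genos])
        Y = np.stack([p[cols] for p in perms_g], axis=1)
    else:
        n_distinct = _n_distinct_permutations(y)
        if n_distinct <= B:
            perms = [np.asarray(p, dtype=float)
                     for p in multiset_permutations(sorted(y.tolist()))]
            logger.info("permutation_null: enumerating all %d distinct "
                        "response arrangements (exact null)", len(perms))
            Y = np.stack(perms, axis=1)
            exact, B_eff = True, len(perms)
        else:
            rng = np.random.default_rng(seed)
            Y = np.stack([rng.permutation(y) for _ in range(B)], axis=1)
            exact, B_eff = False, B

    r_star, s_star = _slopes_and_errors(sub.values, Y)
    d_star = _safe_score(r_star, s_star, s0)
    zero_var = (sub.values.var(axis=1) == 0)
    d_star[zero_var, :] = 0.0
    dbar = np.sort(d_star, axis=0).mean(axis=1)
    return PermutationNull(d_star, dbar, B_eff, seed, exact)


# ---------------------------------------------------------------------------
# FDR and q-values
# ---------------------------------------------------------------------------

def fdr_and_qvalues(
    scores: SamScores,
    null: PermutationNull,
    delta_grid: np.ndarray | None = None,
    false_summary: str = DEFAULT_FALSE_SUMMARY,
) -> tuple[FdrTable, np.ndarray]:
    """Walk the observed order statistics against the expected null ones.

    For each Delta the upper cut is the smallest sorted non-negative
    observed score d_(k) with d_(k) - dbar_(k) >= Delta, the lower cut the
    largest non-positive one with dbar_(k) - d_(k) >= Delta (walking
    outwards from the origin, as in the canonical procedure); probes
    outside the cuts are called.  The
    false-call count of each permutation is the number of permuted scores
    outside the same cuts, summarized by its 90th percentile (the median
    alternative is anti-conservative at small B: it collapses to zero
    whenever the observed extreme beats half the permutation extremes);
    pi0 = min(1, #{observed d inside the permuted interquartile band}/(m/2)).
    FDR(Delta) = 100 * pi0 * false_calls / max(1, called), capped at 100;
    q_i is the minimum FDR over the Deltas at which probe i is called, 100
    for probes never called.
    """
    if false_summary not in ("median", "p90"):
        raise SamError(f"unknown false-call summary {false_summary!r}")
    d = scores.d
    m = d.size
    if null.dbar.size != m:
        raise SamError("scores and null disagree on the number of probes")
    d_sorted = np.sort(d, kind="stable")
    diff = d_sorted - null.dbar
    # walk outwards from the origin: upper cuts live on the non-negative
    # scores, lower cuts on the non-positive ones, so the two sides never
    # cross and calling is monotone in the score on each side
    upper_ok = d_sorted >= 0
    lower_ok = d_sorted <= 0
    if delta_grid is None:
        delta_grid = np.linspace(0.0, float(np.abs(diff).max()), DEFAULT_N_DELTA)
    delta_grid = np.asarray(delta_grid, dtype=float)
    if delta_grid.size == 0:
        raise SamError("empty delta grid")

    q25, q75 = np.percentile(null.d_star, [25, 75])
    inside = np.count_nonzero((d >= q25) & (d <= q75))
    pi0 = min(1.0, inside / (0.5 * m))
    pi0 = max(pi0, 1.0 / m)  # keep pi0 in (0, 1] on pathological inputs

    summarize = (lambda v: float(np.median(v))) if false_summary == "median" \
        else (lambda v: float(np.percentile(v, 90)))

    rows = []
    q = np.full(m, 100.0)
    for delta in delta_grid:
        up = np.nonzero((diff >= delta) & upper_ok)[0]
        low = np.nonzero((-diff >= delta) & lower_ok)[0]
        cut_up = d_sorted[up[0]] if up.size else np.inf
        cut_low = d_sorted[low[-1]] if low.size else -np.inf
        called_mask = (d >= cut_up) | (d <= cut_low)
        n_called = int(called_mask.sum())
        if n_called:
            false_b = ((null.d_star >= cut_up) | (null.d_star <= cut_low)).sum(axis=0)
            false_calls = summarize(false_b)
        else:
            false_calls = 0.0
        fdr = min(100.0, 100.0 * pi0 * false_calls / max(1, n_called))
        rows.append((float(delta), float(cut_up), float(cut_low), n_called,
                     false_calls, fdr))
        if n_called:
            q[called_mask] = np.minimum(q[called_mask], fdr)

    table = pd.DataFrame(rows, columns=FdrTable.COLUMNS)
    return FdrTable(table, pi0, false_summary), q


def select_significant(
    scores: SamScores,
    q: np.ndarray,
    max_fdr_percent: float = DEFAULT_MAX_FDR_PERCENT,
    min_abs_d: float = DEFAULT_MIN_ABS_D,
    trait: str | None = None,
    condition: str | None = None,
) -> SignificantGeneSet:
    """Combined selection rule: q <= max FDR (%) and |d| >= min score."""
    q = np.asarray(q, dtype=float)
    if q.shape != scores.d.shape:
        raise SamError("q must have one entry per probe")
    keep = (q <= max_fdr_percent) & (np.abs(scores.d) >= min_abs_d)
    idx = np.nonzero(keep)[0]
    table = pd.DataFrame({
        "probe_id": [scores.probe_ids[i] for i in idx],
        "d": scores.d[idx],
        "q_percent": q[idx],
        "direction": np.where(scores.d[idx] > 0, "positive", "negative"),
    }, columns=["probe_id", "d", "q_percent", "direction"])
    table = table.iloc[np.lexsort((table["probe_id"], -table["d"].abs()))]
    table = table.reset_index(drop=True)
    return SignificantGeneSet(table, trait, condition, max_fdr_percent, min_abs_d)


# ---------------------------------------------------------------------------
# per-trait driver
# ---------------------------------------------------------------------------

@dataclass
class SamConfig:
    """Knobs of one trait-SAM run (defaults match the documented analysis)."""

    permutations: int = DEFAULT_PERMUTATIONS
    seed: int = 1
    s0: float | None = None  # None -> estimate from the observed data
    weighting: str = "minmax"
    max_fdr_percent: float = DEFAULT_MAX_FDR_PERCENT
    min_abs_d: float = DEFAULT_MIN_ABS_D
    delta_grid: np.ndarray | None = None
    permute: str = "samples"
    false_summary: str = DEFAULT_FALSE_SUMMARY


@dataclass
class TraitSamResult:
    significant: SignificantGeneSet
    fdr_table: FdrTable
    scores: SamScores
    q: np.ndarray
    null: PermutationNull
    response: WeightedResponse


def run_trait_sam(
    matrix: ExpressionMatrix,
    traits: TraitTable,
    trait: str,
    condition: str | None = None,
    config: SamConfig | None = None,
) -> TraitSamResult:
    """Full quantitative-SAM analysis of one trait in one condition.

    Composes trait weighting -> response design -> scoring (s0 estimated if
    not fixed) -> permutation null -> FDR/q-values -> combined selection.
    ``matrix`` should already be normalized and log2-scale; if it contains
    several conditions, ``condition`` selects one.
    """
    cfg = config or SamConfig()
    sub = matrix
    if condition is not None and set(sub.samples["condition"]) != {condition}:
        sub = subset_condition(matrix, condition)
    weights, _excluded = weight_trait(traits, trait, cfg.weighting)
    response = build_response_design(sub, weights, trait=trait,
                                     method=cfg.weighting, condition=condition)
    base = compute_regression_scores(sub, response, s0=0.0)
    if cfg.s0 is None:
        s0, _alpha = estimate_s0(base.r, base.s)
    else:
        s0 = float(cfg.s0)
    scores = SamScores(base.probe_ids, base.r, base.s,
                       _zeroed(base, s0), s0)
    null = permutation_null(sub, response, s0, B=cfg.permutations,
                            seed=cfg.seed, permute=cfg.permute)
    fdr_table, q = fdr_and_qvalues(scores, null, cfg.delta_grid, cfg.false_summary)
    significant = select_significant(scores, q, cfg.max_fdr_percent,
                                     cfg.min_abs_d, trait, condition)
    return TraitSamResult(significant, fdr_table, scores, q, null, response)


def _zeroed(base: SamScores, s0: float) -> np.ndarray:
    d = _safe_score(base.r, base.s, s0)
    d[(base.r == 0) & (base.s == 0)] = 0.0
    return d


def run_all_traits(
    matrix: ExpressionMatrix,
    traits_by_condition: dict[str, TraitTable],
    config: SamConfig | None = None,
) -> tuple[pd.DataFrame, dict[tuple[str, str], TraitSamResult]]:
    """Loop every trait x condition; returns a count summary and all results.

    ``traits_by_condition`` states explicitly which trait table pairs with
    which expression condition.  The summary has one row per (trait,
    condition) with the numbers of positively and negatively expressed
    probes at the combined thresholds.
    """
    rows = []
    results: dict[tuple[str, str], TraitSamResult] = {}
    for condition, traits in traits_by_condition.items():
        sub = subset_condition(matrix, condition)
        for trait in traits.traits:
            res = run_trait_sam(sub, traits, trait, condition=condition,
                                config=config)
            results[(trait, condition)] = res
            rows.append({"trait": trait, "condition": condition,
                         "n_positive": len(res.significant.positive),
                         "n_negative": len(res.significant.negative)})
    summary = pd.DataFrame(rows, columns=["trait", "condition",
                                          "n_positive", "n_negative"])
    return summary, results
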