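"""Genotype normalization, chunked covariance accumulation, and the
sample eigenvalue spectrum.

Each marker j is centered by its nan-aware mean count mu_j and scaled by
d_j = 1 / sqrt(mu_j (1 - mu_j / 2)), the inverse binomial standard
deviation implied by a minor-allele frequency of mu_j / 2. The normalized
matrix M feeds the n-by-n sample covariance S_p = M M^T / p, whose n - 1
non-zero ordered eigenvalues l_1 >= ... >= l_{n-1} > 0 and consecutive
ratios r_i = l_{i+1} / l_i are the estimator's raw material.

All accumulation is in double precision regardless of input storage type:
the ratio statistics are sensitive to cancellation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .exceptions import EmptySpectrumError, NumericError, ParameterError, RankDeficiencyError
from .genotype_io import ChunkPlan, GenotypeSource, iter_column_chunks, plan_chunks

logger = logging.getLogger(__name__)

#: eigenvalues at or below RANK_TOL * l_1 are treated as numerically zero
RANK_TOL = 1e-10

IMPUTE_MODES = ("raw_zero", "centered_zero")


@dataclass(frozen=True)
class ColumnStats:
    """Per-marker moments and keep/drop flags.

    ``keep`` is False for monomorphic markers (mu in {0, 2}), all-missing
    markers, and — when a MAF filter is active — markers whose estimated
    minor-allele frequency min(mu/2, 1 - mu/2) falls below the threshold.
    """

    mu_hat: np.ndarray
    d: np.ndarray
    keep: np.ndarray
    n_obs: np.ndarray

    @property
    def p_effective(self) -> int:
        return int(self.keep.sum())


@dataclass
class CovarianceAccumulator:
    """Partial sums of M M^T over kept markers."""

    gram: np.ndarray
    p_effective: int

    @property
    def S_p(self) -> np.ndarray:
        return self.gram / self.p_effective


@dataclass(frozen=True)
class SpectrumResult:
    """Ordered non-zero sample eigenvalues and their consecutive ratios."""

    eigenvalues: np.ndarray  # l_1 >= ... >= l_{n-1} > 0
    ratios: np.ndarray       # r_i = l_{i+1} / l_i, i = 1..n-2
    n: int
    p_effective: int


def column_stats(
    source: GenotypeSource,
    plan: ChunkPlan,
    maf_threshold: float | None = None,
) -> ColumnStats:
    """Nan-aware per-marker means, scales and keep flags, in one pass."""
    p = source.p
    mu = np.empty(p)
    n_obs = np.empty(p, dtype=np.int64)
    for (start, end), block in iter_column_chunks(source, plan):
        obs = np.isfinite(block)
        n_obs[start:end] = obs.sum(axis=0)
        with np.errstate(invalid="ignore"):
            mu[start:end] = np.nansum(block, axis=0) / np.maximum(n_obs[start:end], 1)
    keep = (n_obs > 0) & (mu > 0.0) & (mu < 2.0)
    n_monomorphic = int(((n_obs > 0) & ((mu == 0.0) | (mu == 2.0))).sum())
    if maf_threshold is not None:
        maf = np.minimum(mu / 2.0, 1.0 - mu / 2.0)
        keep &= maf >= maf_threshold
    d = np.full(p, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        d[keep] = 1.0 / np.sqrt(mu[keep] * (1.0 - mu[keep] / 2.0))
    if not keep.any():
        raise EmptySpectrumError(
            "every marker was dropped (monomorphic, all-missing, or below "
            "the MAF threshold); nothing to analyze"
        )
    logger.info("column_stats p=%d kept=%d dropped=%d monomorphic_or_missing=%d",
                p, int(keep.sum()), int(p - keep.sum()), n_monomorphic)
    return ColumnStats(mu_hat=mu, d=d, keep=keep, n_obs=n_obs)


def normalize_chunk(
    chunk: np.ndarray,
    stats: ColumnStats,
    cols: tuple[int, int],
    impute_mode: str = "raw_zero",
) -> np.ndarray:
    """Center and scale one column chunk; dropped columns are excluded.

    Missing cells are imputed per ``impute_mode``:

    - ``"raw_zero"`` (default): the raw count is taken as 0, then centered
      and scaled, giving (0 - mu_j) d_j;
    - ``"centered_zero"``: the normalized value is 0 (equivalent to mean
      imputation on the count scale).
    """
    if impute_mode not in IMPUTE_MODES:
        raise ParameterError(f"unknown impute_mode {impute_mode!r}; expected one of {IMPUTE_MODES}")
    start, end = cols
    keep = stats.keep[start:end]
    mu = stats.mu_hat[start:end][keep]
    d = stats.d[start:end][keep]
    block = np.asarray(chunk, dtype=np.float64)[:, keep]
    missing = ~np.isfinite(block)
    if impute_mode == "raw_zero":
        block = np.where(missing, 0.0, block)
        out = (block - mu) * d
    else:
        out = np.where(missing, 0.0, (block - mu) * d)
    return out


def accumulate_covariance(
    source: GenotypeSource,
    plan: ChunkPlan,
    stats: ColumnStats,
    impute_mode: str = "raw_zero",
) -> CovarianceAccumulator:
    """Accumulate gram = sum over chunks of M_chunk M_chunk^T.

    The result is independent of the chunk width up to round-off; the
    gram matrix is symmetrized on exit to remove accumulation asymmetry.
    """
    n = source.n
    gram = np.zeros((n, n))
    for (start, end), block in iter_column_chunks(source, plan):
        m = normalize_chunk(block, stats, (start, end), impute_mode)
        if m.shape[1] == 0:
            continue
        gram += m @ m.T
        if not np.isfinite(gram).all():
            raise NumericError(
                f"non-finite covariance accumulation in column chunk [{start}, {end})"
            )
    gram = (gram + gram.T) / 2.0
    return CovarianceAccumulator(gram=gram, p_effective=stats.p_effective)


def sample_spectrum(acc: CovarianceAccumulator) -> SpectrumResult:
    """Eigendecompose S_p and keep the n-1 largest eigenvalues and ratios.

    Centering consumes one rank, so at most n - 1 eigenvalues are
    non-zero; the discarded smallest must be numerically zero and every
    retained one strictly positive relative to l_1.
    """
    n = acc.gram.shape[0]
    if n < 3:
        raise ParameterError(f"need at least 3 individuals for one ratio, got n={n}")
    ev = np.linalg.eigvalsh(acc.S_p)[::-1]  # descending
    retained = ev[: n - 1]
    if retained[-1] <= RANK_TOL * retained[0]:
        raise RankDeficiencyError(
            "sample covariance is numerically rank deficient "
            f"(l_{n-1} <= {RANK_TOL:g} * l_1); remove highly correlated markers "
            "or duplicated individuals and re-run"
        )
    ratios = retained[1:] / retained[:-1]
    return SpectrumResult(eigenvalues=retained, ratios=ratios,
                          n=n, p_effective=acc.p_effective)


def spectrum_from_source(
    source: GenotypeSource,
    plan: ChunkPlan | None = None,
    memory_budget_bytes: int = 2 << 30,
    maf_threshold: float | None = None,
    impute_mode: str = "raw_zero",
) -> SpectrumResult:
    """Convenience pipeline: stats -> covariance -> spectrum."""
    if plan is None:
        plan = plan_chunks(source, memory_budget_bytes)
    stats = column_stats(source, plan, maf_threshold)
    acc = accumulate_covariance(source, plan, stats, impute_mode)
    return sample_spectrum(acc)
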