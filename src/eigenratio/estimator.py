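"""Sequential eigenvalue-ratio estimation of the number of top PCs.

For each candidate index k the trailing eigenvalues l_k ... l_{n-1}
define bulk coefficients

    a_k = mean(l_k, ..., l_{n-1}),
    b_k = p / (n - k)^2 * sum_i (l_i - a_k)^2,

which map the simulated GOE top eigenvalues (w1, w2) onto a Monte-Carlo
null sample for the ratio r_k:

    r_null = (w2 * s + a_k) / (w1 * s + a_k),    s = sqrt(b_k / p).

The critical value xi_{alpha,k} is the floor(alpha * rep)-th smallest null
ratio (a lower-alpha quantile). The estimate K_hat is the smallest k such
that r_j >= xi_{alpha,j} for every j from k up to the coarse bound K_c
(default floor(n / 10)): ratios at or above their critical values are
consistent with the bulk, so K_hat marks where the spike set ends.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import EstimationFailureError, NumericError, ParameterError
from .goe_null import GOEnsemble
from .spectrum import SpectrumResult

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.001
DEFAULT_REP = 5000


@dataclass(frozen=True)
class NullCoefficients:
    """Bulk location/dispersion coefficients for candidate index k."""

    k: int
    a_hat: float
    b_hat: float


@dataclass(frozen=True)
class CriticalValues:
    """Per-k lower-alpha critical values from a rep-sized null ensemble."""

    alpha: float
    xi: np.ndarray
    rep: int


@dataclass(frozen=True)
class EstimatorResult:
    """Estimate with the full per-k diagnostic table.

    ``per_k`` has columns (k, ratio, xi, passed); the pass flag is True for
    every k in [K_hat, K_c].
    """

    K_hat: int
    K_c: int
    per_k: pd.DataFrame
    alpha: float
    rep: int
    seed: int | None
    n: int = 0
    p_effective: int = 0
    params: dict = field(default_factory=dict)


def bulk_coefficients(spectrum: SpectrumResult, k: int) -> NullCoefficients:
    """Mean and p-scaled squared dispersion of l_k ... l_{n-1}."""
    n = spectrum.n
    if not 1 <= k <= n - 2:
        raise ParameterError(f"k must be in [1, n-2] = [1, {n - 2}], got {k}")
    tail = spectrum.eigenvalues[k - 1:]  # l_k ... l_{n-1}, n - k values
    a_hat = float(tail.mean())
    b_hat = float(spectrum.p_effective / (n - k) ** 2 * ((tail - a_hat) ** 2).sum())
    return NullCoefficients(k=k, a_hat=a_hat, b_hat=b_hat)


def null_ratio_sample(
    coeff: NullCoefficients, ensemble: GOEnsemble, p_effective: int
) -> np.ndarray:
    """Monte-Carlo null sample of the ratio at index k, sorted ascending."""
    if coeff.a_hat <= 0:
        raise ParameterError(f"a_hat must be positive, got {coeff.a_hat}")
    if p_effective < 1:
        raise ParameterError(f"p_effective must be >= 1, got {p_effective}")
    s = math.sqrt(coeff.b_hat / p_effective)
    denom = ensemble.w1 * s + coeff.a_hat
    if (denom <= 0).any():
        raise NumericError(
            f"non-positive denominator in the null sample at k={coeff.k}: "
            "the bulk dispersion is pathologically large relative to its mean"
        )
    ratios = (ensemble.w2 * s + coeff.a_hat) / denom
    return np.sort(ratios)


def critical_value(sorted_null: np.ndarray, alpha: float) -> float:
    """The floor(alpha * rep)-th smallest null ratio (1-based, floored at 1)."""
    rep = len(sorted_null)
    if not 0 < alpha < 1:
        raise ParameterError(f"alpha must be in (0, 1), got {alpha}")
    if rep * alpha < 1:
        raise ParameterError(
            f"rep={rep} is too small for alpha={alpha}: need rep >= 1/alpha; "
            f"recommended rep between {math.ceil(2 / alpha)} and {math.ceil(5 / alpha)}"
        )
    idx = max(1, math.floor(alpha * rep))
    return float(sorted_null[idx - 1])


def sequential_min_index(passes: np.ndarray) -> int:
    """Smallest k (1-based) such that every flag from k to K_c is True.

    ``passes[j - 1]`` is the pass flag for index j. Raises
    :class:`EstimationFailureError` when the final flag is False (no valid
    k exists).
    """
    passes = np.asarray(passes, dtype=bool)
    if not passes[-1]:
        raise EstimationFailureError(
            "no index satisfies the decision rule (the last ratio is below its "
            "critical value); the data may exhibit serious multicollinearity — "
            "pre-process the genetic data to remove highly correlated genetic markers"
        )
    k = len(passes)
    while k > 1 and passes[k - 2]:
        k -= 1
    return k


def estimate_K(
    spectrum: SpectrumResult,
    ensemble: GOEnsemble,
    alpha: float = DEFAULT_ALPHA,
    K_c: int | None = None,
) -> EstimatorResult:
    """Run the sequential ratio test over k = 1 .. K_c.

    All K_c indices are evaluated (no short-circuit) so the per-k table is
    always complete for diagnostics. Ties r_k == xi_{alpha,k} count as
    passing.
    """
    n = spectrum.n
    if K_c is None:
        K_c = n // 10
    if K_c > n - 2:
        logger.warning("K_c=%d exceeds n-2=%d; clamping", K_c, n - 2)
        K_c = n - 2
    if K_c < 1:
        raise ParameterError(f"K_c must be >= 1 (got {K_c}; n={n} is too small)")

    rows = []
    for k in range(1, K_c + 1):
        coeff = bulk_coefficients(spectrum, k)
        null = null_ratio_sample(coeff, ensemble, spectrum.p_effective)
        xi = critical_value(null, alpha)
        r_k = float(spectrum.ratios[k - 1])
        rows.append((k, r_k, xi, r_k >= xi))
    per_k = pd.DataFrame(rows, columns=["k", "ratio", "xi", "passed"])
    K_hat = sequential_min_index(per_k["passed"].to_numpy())
    logger.info("estimate_K K_hat=%d K_c=%d alpha=%g rep=%d n=%d p_effective=%d",
                K_hat, K_c, alpha, ensemble.rep, n, spectrum.p_effective)
    return EstimatorResult(
        K_hat=K_hat, K_c=K_c, per_k=per_k, alpha=alpha, rep=ensemble.rep,
        seed=ensemble.seed, n=n, p_effective=spectrum.p_effective,
    )
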