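"""Monte-Carlo simulation of the top two eigenvalues of GOE matrices.

A Gaussian Orthogonal Ensemble (GOE) matrix is symmetric with independent
N(0, 2) diagonal and N(0, 1) off-diagonal entries. Its two largest
eigenvalues (w1, w2) calibrate the null fluctuations of consecutive
sample-eigenvalue ratios in the estimator.

Replication m draws from an independent child stream deterministically
spawned from the master seed, so ensembles are bit-identical for any
worker count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from joblib import Parallel, delayed

from .exceptions import ParameterError

logger = logging.getLogger(__name__)

_SQRT2 = np.sqrt(2.0)


@dataclass(frozen=True)
class GOEnsemble:
    """rep replications of the top two GOE eigenvalues at dimension n."""

    n: int
    rep: int
    w1: np.ndarray
    w2: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        if len(self.w1) != self.rep or len(self.w2) != self.rep:
            raise ParameterError("w1/w2 length must equal rep")


def goe_matrix(n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw one n-by-n GOE matrix.

    Constructed as (G + G^T) / sqrt(2) from an i.i.d. standard normal
    square G, which gives exactly N(0, 2) diagonal and N(0, 1)
    off-diagonal entries.
    """
    g = rng.standard_normal((n, n))
    return (g + g.T) / _SQRT2


def sample_goe_top2(n: int, rng: np.random.Generator) -> tuple[float, float]:
    """Top two eigenvalues (w1 >= w2) of one GOE draw."""
    if n < 2:
        raise ParameterError(f"GOE dimension must be >= 2, got {n}")
    ev = np.linalg.eigvalsh(goe_matrix(n, rng))
    return float(ev[-1]), float(ev[-2])


def _replicate(n: int, child: np.random.SeedSequence) -> tuple[float, float]:
    return sample_goe_top2(n, np.random.default_rng(child))


def simulate_ensemble(
    n: int,
    rep: int,
    seed: int,
    workers: int = 1,
    cache_dir: str | Path | None = None,
) -> GOEnsemble:
    """Simulate rep independent (w1, w2) pairs, optionally in parallel.

    With ``cache_dir`` set, a TSV keyed by (n, rep, seed) is reused across
    runs and written after a fresh simulation.
    """
    if rep < 1:
        raise ParameterError(f"rep must be >= 1, got {rep}")
    if workers < 1:
        raise ParameterError(f"workers must be >= 1, got {workers}")
    if n < 2:
        raise ParameterError(f"GOE dimension must be >= 2, got {n}")

    cache_path = None
    if cache_dir is not None:
        cache_path = Path(cache_dir) / f"goe_n{n}_rep{rep}_seed{seed}.tsv"
        if cache_path.exists():
            logger.info("goe_cache_hit path=%s", cache_path)
            return load_ensemble(cache_path)

    children = np.random.SeedSequence(seed).spawn(rep)
    if workers == 1:
        pairs = [_replicate(n, child) for child in children]
    else:
        pairs = Parallel(n_jobs=workers)(
            delayed(_replicate)(n, child) for child in children
        )
    w1 = np.array([a for a, _ in pairs])
    w2 = np.array([b for _, b in pairs])
    ensemble = GOEnsemble(n=n, rep=rep, w1=w1, w2=w2, seed=seed)
    logger.info("goe_ensemble n=%d rep=%d seed=%d workers=%d", n, rep, seed, workers)
    if cache_path is not None:
        save_ensemble(ensemble, cache_path)
    return ensemble


def save_ensemble(ensemble: GOEnsemble, path: str | Path) -> None:
    """Write an ensemble as TSV (m, w1, w2) with a metadata header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = np.column_stack([np.arange(ensemble.rep), ensemble.w1, ensemble.w2])
    header = f"n={ensemble.n} rep={ensemble.rep} seed={ensemble.seed}\nm\tw1\tw2"
    # %.17g round-trips float64 exactly, so cached ensembles are bit-identical
    np.savetxt(path, data, fmt=("%d", "%.17g", "%.17g"),
               delimiter="\t", header=header)


def load_ensemble(path: str | Path) -> GOEnsemble:
    """Read an ensemble written by :func:`save_ensemble`."""
    path = Path(path)
    with open(path) as fh:
        meta = dict(kv.split("=") for kv in fh.readline().lstrip("# ").split())
    data = np.loadtxt(path, skiprows=2)
    data = np.atleast_2d(data)
    return GOEnsemble(n=int(meta["n"]), rep=int(meta["rep"]),
                      w1=data[:, 1], w2=data[:, 2], seed=int(meta["seed"]))
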