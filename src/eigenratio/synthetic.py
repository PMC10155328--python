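"""Synthetic genotype matrices under a latent-subpopulation model.

Each individual belongs to one of K subpopulations; their genotype row is
the subpopulation mean count vector mu_k = 2 * f_k plus independent
noise, realized by drawing minor-allele counts Binomial(2, f_{k,j}) per
marker. Between-group structure is controlled by a frequency-scale
``separation``: group k's frequency at marker j is the shared base
frequency shifted by +/- separation (independent symmetric signs per
group and marker), clamped away from 0 and 1.

An optional Gaussian-copula block correlation (``ld_rho``) induces
linkage-disequilibrium-like dependence between nearby markers before
thresholding to {0, 1, 2} by the binomial quantiles. The default is
independent markers (diagonal binomial covariance).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np
from scipy import stats as sps

from .exceptions import ParameterError

logger = logging.getLogger(__name__)

#: frequencies are clamped to [MARGIN, 1 - MARGIN] so monomorphic columns are rare
MARGIN = 0.02

#: marker-block size for the Gaussian-copula LD option
LD_BLOCK = 50

# reference illustration regime: 12 well-separated subpopulations at
# sequencing scale (n=2500 individuals, p=8e6 markers)
_PRESET_K = 12
_PRESET_N = 2500
_PRESET_P = 8_000_000
_PRESET_SEPARATION = 0.15


@dataclass(frozen=True)
class PopulationModel:
    """K latent subpopulations with per-group minor-allele frequencies."""

    K: int
    group_sizes: tuple[int, ...]
    freqs: np.ndarray  # K x p, entries in (0, 1)
    separation: float
    ld_rho: float = 0.0

    @property
    def n(self) -> int:
        return int(sum(self.group_sizes))

    @property
    def p(self) -> int:
        return self.freqs.shape[1]


@dataclass(frozen=True)
class SyntheticDataset:
    """Generated genotypes with ground-truth labels."""

    genotypes: np.ndarray  # n x p, {0,1,2} (+ NaN when missing)
    labels: np.ndarray     # n, subpopulation index in [0, K)
    truth_K: int
    seed: int


@dataclass(frozen=True)
class RunParams:
    """Estimator settings bundled with a preset model."""

    alpha: float = 0.001
    rep: int = 2000
    K_c: int | None = None  # None = floor(n / 10)


def balanced_partition(n: int, K: int) -> tuple[int, ...]:
    """Group sizes as equal as possible, larger groups first."""
    base, extra = divmod(n, K)
    return tuple(base + (1 if k < extra else 0) for k in range(K))


def ladder_partition(n: int, K: int, spread: float = 3.0) -> tuple[int, ...]:
    """Unbalanced group sizes with largest/smallest ~= ``spread``.

    Real multi-population panels are unbalanced, and unequal sizes give the
    K - 1 structure eigenvalues distinct strengths (a spike's magnitude
    scales with its group's size), so the spike ratios spread visibly
    below the bulk instead of collapsing onto each other.
    """
    weights = np.linspace(1.0, spread, K)
    raw = n * weights / weights.sum()
    sizes = np.maximum(1, np.floor(raw).astype(int))
    # largest-remainder rounding to hit n exactly
    order = np.argsort(raw - np.floor(raw))[::-1]
    for idx in order:
        if sizes.sum() == n:
            break
        sizes[idx] += 1
    sizes[-1] += n - sizes.sum()
    return tuple(int(s) for s in sizes)


def sample_model(
    K: int,
    n: int,
    p: int,
    separation: float,
    seed: int,
    base_freq_law: Callable[[np.random.Generator, int], np.ndarray] | None = None,
    ld_rho: float = 0.0,
    group_sizes: tuple[int, ...] | None = None,
) -> PopulationModel:
    """Draw a population model with K groups over p markers.

    Base frequencies default to Uniform[0.05, 0.5]; group k's frequency at
    marker j is clamp(base_j + separation * delta_{k,j}, MARGIN, 1-MARGIN)
    with delta_{k,j} independent random signs. ``separation=0`` makes all
    groups identical (the null model).
    """
    if K < 1 or n < K or p < 1:
        raise ParameterError(f"need K >= 1, n >= K, p >= 1; got K={K}, n={n}, p={p}")
    if separation < 0:
        raise ParameterError(f"separation must be >= 0, got {separation}")
    if not 0 <= ld_rho < 1:
        raise ParameterError(f"ld_rho must be in [0, 1), got {ld_rho}")
    rng = np.random.default_rng(seed)
    base = base_freq_law(rng, p) if base_freq_law else rng.uniform(0.05, 0.5, p)
    if separation == 0:
        freqs = np.tile(base, (K, 1))
    else:
        # Equal-magnitude symmetric shifts keep every group's binomial noise
        # variance balanced (f (1 - f) is insensitive to the sign of the
        # shift), so the shared-noise-covariance assumption holds to first
        # order; distinct spike strengths come from group sizes, not here.
        delta = rng.choice((-1.0, 1.0), size=(K, p))
        freqs = np.clip(base + separation * delta, MARGIN, 1.0 - MARGIN)
    if group_sizes is None:
        group_sizes = balanced_partition(n, K)
    elif len(group_sizes) != K or sum(group_sizes) != n or min(group_sizes) < 1:
        raise ParameterError(f"group_sizes must be {K} positive integers summing to {n}")
    return PopulationModel(K=K, group_sizes=tuple(int(g) for g in group_sizes),
                           freqs=freqs, separation=float(separation),
                           ld_rho=float(ld_rho))


def _binomial2(rng: np.random.Generator, freqs: np.ndarray) -> np.ndarray:
    # Binomial(2, f) as a sum of two Bernoulli draws: much faster than
    # rng.binomial with an array p at this scale.
    return ((rng.random(freqs.shape) < freqs).astype(np.int8)
            + (rng.random(freqs.shape) < freqs).astype(np.int8))


def _copula_counts(rng: np.random.Generator, freqs: np.ndarray, rho: float) -> np.ndarray:
    """Counts with within-block latent-Gaussian correlation rho."""
    n, p = freqs.shape
    out = np.empty((n, p), dtype=np.int8)
    for start in range(0, p, LD_BLOCK):
        end = min(start + LD_BLOCK, p)
        u = rng.standard_normal((n, 1))
        e = rng.standard_normal((n, end - start))
        z = np.sqrt(rho) * u + np.sqrt(1.0 - rho) * e
        # threshold the latent Gaussian by the Binomial(2, f) quantiles
        out[:, start:end] = sps.binom.ppf(sps.norm.cdf(z), 2, freqs[:, start:end])
    return out


def generate_genotypes(
    model: PopulationModel, seed: int, missing_rate: float = 0.0
) -> SyntheticDataset:
    """Draw an n x p genotype matrix from the model.

    Genotypes are Binomial(2, f_{k,j}) minor-allele counts, independent
    across markers when ``ld_rho == 0``. Missing cells are set uniformly at
    random at ``missing_rate`` and stored as NaN (forcing a float matrix);
    with no missingness the matrix is int8.
    """
    if not 0.0 <= missing_rate <= 0.5:
        raise ParameterError(f"missing_rate must be in [0, 0.5], got {missing_rate}")
    rng = np.random.default_rng(seed)
    labels = np.repeat(np.arange(model.K), model.group_sizes)
    freqs = model.freqs[labels]  # n x p
    if model.ld_rho > 0:
        counts = _copula_counts(rng, freqs, model.ld_rho)
    else:
        counts = _binomial2(rng, freqs)
    if missing_rate > 0:
        geno = counts.astype(np.float32)
        geno[rng.random(counts.shape) < missing_rate] = np.nan
    else:
        geno = counts
    logger.info("synthetic_dataset K=%d n=%d p=%d separation=%g missing_rate=%g seed=%d",
                model.K, model.n, model.p, model.separation, missing_rate, seed)
    return SyntheticDataset(genotypes=geno, labels=labels, truth_K=model.K, seed=seed)


def fig1_preset(
    scale: float, n_scale: float = 1.0, seed: int = 0
) -> tuple[PopulationModel, RunParams]:
    """The K=12 well-separated illustration regime, scaled to desk size.

    ``scale`` multiplies the marker dimension p (reference 8,000,000);
    ``n_scale`` optionally shrinks the sample size n (reference 2500) so
    the whole pipeline runs in minutes on one CPU. K=12 and the per-marker
    frequency separation 0.15 are kept. Group sizes follow an unbalanced
    3:1 ladder (see :func:`ladder_partition`) so the K - 1 spike ratios
    are distinct and sit visibly below the bulk. A warning is issued when
    the scaled p falls below 50 n, outside the many-more-markers-than-
    individuals regime the estimator targets.
    """
    if not 0 < scale <= 1:
        raise ParameterError(f"scale must be in (0, 1], got {scale}")
    if not 0 < n_scale <= 1:
        raise ParameterError(f"n_scale must be in (0, 1], got {n_scale}")
    p = max(1, round(_PRESET_P * scale))
    n = max(_PRESET_K, round(_PRESET_N * n_scale))
    if p < 50 * n:
        warnings.warn(
            f"scaled p={p} < 50*n={50 * n}: outside the n/p -> 0 regime, "
            "estimator quality degrades", stacklevel=2)
    model = sample_model(K=_PRESET_K, n=n, p=p,
                         separation=_PRESET_SEPARATION, seed=seed,
                         group_sizes=ladder_partition(n, _PRESET_K))
    return model, RunParams(alpha=0.001, rep=2000, K_c=None)


def write_dataset(dataset: SyntheticDataset, out_prefix: str | Path) -> dict:
    """Write genotypes (NPY), labels (TSV) and a truth manifest (JSON).

    Files use the same formats the genotype readers accept, so synthetic
    fixtures are self-hosting.
    """
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    geno_path = out_prefix.parent / (out_prefix.name + ".genotypes.npy")
    labels_path = out_prefix.parent / (out_prefix.name + ".labels.tsv")
    manifest_path = out_prefix.parent / (out_prefix.name + ".truth.json")
    np.save(geno_path, dataset.genotypes)
    np.savetxt(labels_path, dataset.labels[:, None], fmt="%d",
               delimiter="\t", header="label", comments="")
    n, p = dataset.genotypes.shape
    manifest = {"truth_K": dataset.truth_K, "n": n, "p": p, "seed": dataset.seed}
    manifest_path.write_text(json.dumps(manifest, indent=2) + "\n")
    return {"genotypes": str(geno_path), "labels": str(labels_path),
            "truth": str(manifest_path), **manifest}
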