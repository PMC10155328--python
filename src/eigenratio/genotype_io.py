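"""Genotype matrix input: validated multi-file sources, chunked column
access, and a minimal VCF-to-matrix converter.

Matrices are oriented individuals x markers. Non-missing entries are minor
allele counts in {0, 1, 2}. Missing genotypes are canonically ``NaN`` in
memory regardless of the on-disk dialect: NPY arrays use NaN, delimited
text files may use any negative integer or the tokens ``NA`` / ``.``.

Column ranges are 0-based and half-open throughout.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    DimensionError,
    DomainError,
    EmptyOutputError,
    GenotypeIOError,
    ResourceError,
)

logger = logging.getLogger(__name__)

#: canonical in-memory sentinel for a missing genotype
MISSING = np.nan

#: per-column working-memory overhead factor used by :func:`plan_chunks`:
#: read buffer + normalized copy + transpose workspace + slack.
C_OVERHEAD = 4

_TEXT_SUFFIXES = {".tsv", ".csv", ".txt"}
_NA_TOKENS = ["NA", "na", "."]


@dataclass(frozen=True)
class GenotypeSource:
    """Handle to one or more genotype matrices sharing the same individuals.

    Attributes
    ----------
    paths : tuple of str
        Ordered file identifiers ("<array>" for in-memory blocks).
    n : int
        Number of individuals (rows, identical across files).
    p : int
        Total marker count, summed over files.
    col_counts : tuple of int
        Per-file marker counts; ``sum(col_counts) == p``.
    """

    paths: tuple[str, ...]
    n: int
    p: int
    col_counts: tuple[int, ...]
    _arrays: tuple[np.ndarray, ...]


@dataclass(frozen=True)
class ChunkPlan:
    """Column tiling derived from a memory budget.

    ``ceil(p / chunk_width)`` half-open ranges ``[start, end)`` tile the
    columns exactly once.
    """

    chunk_width: int
    memory_budget_bytes: int

    def ranges(self, p: int) -> Iterator[tuple[int, int]]:
        for start in range(0, p, self.chunk_width):
            yield start, min(start + self.chunk_width, p)


def _load_text(path: Path) -> np.ndarray:
    sep = "," if path.suffix.lower() == ".csv" else r"\s+"
    try:
        frame = pd.read_csv(path, sep=sep, header=None, na_values=_NA_TOKENS,
                            dtype=np.float64, engine="python")
    except Exception as exc:  # noqa: BLE001 - rewrap with file context
        raise GenotypeIOError(f"cannot parse delimited text file {path}: {exc}") from exc
    arr = frame.to_numpy(dtype=np.float64)
    # negative integers are a text-dialect missing code
    arr[arr < 0] = MISSING
    return arr


def _load_file(path: Path) -> np.ndarray:
    if path.suffix.lower() == ".npy":
        try:
            arr = np.load(path, mmap_mode="r")
        except Exception as exc:  # noqa: BLE001
            raise GenotypeIOError(f"cannot read NPY file {path}: {exc}") from exc
        if arr.ndim != 2:
            raise GenotypeIOError(f"{path}: expected a 2-D matrix, got ndim={arr.ndim}")
        return arr
    if path.suffix.lower() in _TEXT_SUFFIXES:
        arr = _load_text(path)
        if arr.ndim != 2:
            raise GenotypeIOError(f"{path}: expected a 2-D matrix")
        return arr
    raise GenotypeIOError(
        f"{path}: unsupported genotype format (expected .npy, .tsv, .csv or .txt)"
    )


def _validate_entries(arr: np.ndarray, name: str, block: int = 4096) -> None:
    """Check every non-missing entry is in {0, 1, 2}; report the first offender."""
    n, p = arr.shape
    for start in range(0, p, block):
        sub = np.asarray(arr[:, start:start + block], dtype=np.float64)
        if np.issubdtype(arr.dtype, np.integer) and (sub < 0).any():
            # NPY dialect uses NaN for missing; a negative integer is a
            # domain violation, not a missing code.
            r, c = np.argwhere(sub < 0)[0]
            raise DomainError(
                f"{name}: entry {arr[r, start + c]} at row {r}, column {start + c} "
                "is outside {0, 1, 2}"
            )
        finite = np.isfinite(sub)
        bad = finite & ~np.isin(sub, (0.0, 1.0, 2.0))
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise DomainError(
                f"{name}: entry {sub[r, c]} at row {r}, column {start + c} "
                "is outside {0, 1, 2}"
            )


def open_sources(paths: Sequence[str | Path]) -> GenotypeSource:
    """Open and validate one or more genotype files as a single source.

    All files must have the same number of rows (individuals, in the same
    order); columns are concatenated left to right in the order given.

    Raises
    ------
    DimensionError
        If two files disagree on the row count.
    DomainError
        If any non-missing entry lies outside {0, 1, 2}.
    """
    if not paths:
        raise GenotypeIOError("no input paths given")
    arrays: list[np.ndarray] = []
    names: list[str] = []
    for p in paths:
        path = Path(p)
        if not path.exists():
            raise GenotypeIOError(f"input file not found: {path}")
        arr = _load_file(path)
        _validate_entries(arr, str(path))
        arrays.append(arr)
        names.append(str(path))
    return _assemble(arrays, names)


def source_from_arrays(
    arrays: Sequence[np.ndarray], names: Sequence[str] | None = None
) -> GenotypeSource:
    """Build a validated in-memory source (same contract as :func:`open_sources`).

    Negative entries in integer arrays are domain errors; ``NaN`` marks
    missing genotypes in float arrays.
    """
    names = list(names) if names is not None else [f"<array{i}>" for i in range(len(arrays))]
    arrs = []
    for arr, name in zip(arrays, names):
        a = np.asarray(arr)
        if a.ndim != 2:
            raise GenotypeIOError(f"{name}: expected a 2-D matrix")
        _validate_entries(a, name)
        arrs.append(a)
    return _assemble(arrs, names)


def _assemble(arrays: list[np.ndarray], names: list[str]) -> GenotypeSource:
    n = arrays[0].shape[0]
    for arr, name in zip(arrays[1:], names[1:]):
        if arr.shape[0] != n:
            raise DimensionError(
                f"row (individual) count mismatch: {names[0]} has {n} rows "
                f"but {name} has {arr.shape[0]}"
            )
    col_counts = tuple(a.shape[1] for a in arrays)
    p = int(sum(col_counts))
    if p > 0 and n > p:
        logger.warning("source has more individuals than markers n=%d p=%d; "
                       "the estimator targets the n << p regime", n, p)
    logger.info("genotype_source n=%d p=%d files=%d", n, p, len(arrays))
    return GenotypeSource(paths=tuple(names), n=n, p=p,
                          col_counts=col_counts, _arrays=tuple(arrays))


def plan_chunks(source: GenotypeSource, memory_budget_bytes: int) -> ChunkPlan:
    """Choose a column chunk width that keeps peak memory within budget.

    The budget must cover the n-by-n double-precision covariance
    accumulator plus ``C_OVERHEAD`` double-precision working copies of each
    column: ``chunk_width = (budget - 8 n^2) / (8 n C_OVERHEAD)``, floored,
    at least 1.
    """
    n = source.n
    minimum = 8 * n * n + 8 * n * C_OVERHEAD
    if memory_budget_bytes < minimum:
        raise ResourceError(
            f"memory budget {memory_budget_bytes} B is too small for one column "
            f"plus the n×n accumulator at n={n}; need at least {minimum} B"
        )
    width = max(1, (memory_budget_bytes - 8 * n * n) // (8 * n * C_OVERHEAD))
    plan = ChunkPlan(chunk_width=int(width), memory_budget_bytes=int(memory_budget_bytes))
    logger.info("chunk_plan chunk_width=%d n_chunks=%d budget_bytes=%d",
                plan.chunk_width, math.ceil(source.p / plan.chunk_width) if source.p else 0,
                memory_budget_bytes)
    return plan


def iter_column_chunks(
    source: GenotypeSource, plan: ChunkPlan
) -> Iterator[tuple[tuple[int, int], np.ndarray]]:
    """Yield ``((start, end), block)`` column chunks in ascending order.

    Blocks are dense ``float64`` with NaN for missing entries; concatenating
    them column-wise reconstructs the full matrix bit-exactly. Chunks may
    span file boundaries.
    """
    offsets = np.cumsum((0,) + source.col_counts)
    for start, end in plan.ranges(source.p):
        parts = []
        for fi, arr in enumerate(source._arrays):
            lo = max(start, offsets[fi])
            hi = min(end, offsets[fi + 1])
            if lo >= hi:
                continue
            try:
                piece = np.asarray(arr[:, lo - offsets[fi]:hi - offsets[fi]],
                                   dtype=np.float64)
            except (OSError, ValueError) as exc:
                raise GenotypeIOError(
                    f"truncated read from {source.paths[fi]} at columns "
                    f"[{lo - offsets[fi]}, {hi - offsets[fi]}): {exc}"
                ) from exc
            parts.append(piece)
        block = parts[0] if len(parts) == 1 else np.concatenate(parts, axis=1)
        yield (start, end), block


def vcf_to_matrix(
    vcf_path: str | Path,
    out_path: str | Path,
    manifest_path: str | Path | None = None,
) -> dict:
    """Convert a diploid VCF into a minor-allele count matrix (NPY).

    One output column per biallelic variant; the counted allele is the
    minor allele (the allele with the lower frequency among called
    genotypes; exact ties are counted toward ALT). Missing or half-called
    genotypes become NaN. Multi-allelic records are skipped and tallied in
    the manifest.

    Returns a summary dict with ``n``, ``p``, ``n_skipped_multiallelic``
    and the written paths.
    """
    from cyvcf2 import VCF

    out_path = Path(out_path)
    manifest_path = Path(manifest_path) if manifest_path is not None else (
        out_path.with_suffix(out_path.suffix + ".manifest.tsv")
    )
    columns: list[np.ndarray] = []
    manifest_rows: list[dict] = []
    n_skipped = 0

    vcf = VCF(str(vcf_path))
    n = len(vcf.samples)
    for variant in vcf:
        if len(variant.ALT) != 1:
            n_skipped += 1
            manifest_rows.append({
                "chrom": variant.CHROM, "pos": variant.POS, "ref": variant.REF,
                "alt": ",".join(variant.ALT) or ".", "minor_allele": ".",
                "skipped": 1,
            })
            continue
        alt_dose = np.full(n, MISSING)
        for i, gt in enumerate(variant.genotypes):
            a1, a2 = gt[0], gt[1]
            if a1 < 0 or a2 < 0:
                continue  # missing or half-called
            alt_dose[i] = (a1 == 1) + (a2 == 1)
        called = np.isfinite(alt_dose)
        if called.any():
            alt_freq = alt_dose[called].sum() / (2.0 * called.sum())
        else:
            alt_freq = 0.0  # all-missing site: orientation immaterial
        # minor allele = lower sample frequency; ties go to ALT
        if alt_freq <= 0.5:
            col, minor = alt_dose, variant.ALT[0]
        else:
            col, minor = np.where(called, 2.0 - alt_dose, MISSING), variant.REF
        columns.append(col)
        manifest_rows.append({
            "chrom": variant.CHROM, "pos": variant.POS, "ref": variant.REF,
            "alt": variant.ALT[0], "minor_allele": minor, "skipped": 0,
        })
    vcf.close()

    if not columns:
        raise EmptyOutputError(
            f"{vcf_path}: no biallelic variants found; nothing to convert"
        )
    matrix = np.column_stack(columns).astype(np.float32)
    np.save(out_path, matrix)
    pd.DataFrame(manifest_rows).to_csv(manifest_path, sep="\t", index=False)
    logger.info("vcf_to_matrix n=%d p=%d skipped_multiallelic=%d out=%s",
                n, matrix.shape[1], n_skipped, out_path)
    return {
        "n": n, "p": matrix.shape[1], "n_skipped_multiallelic": n_skipped,
        "matrix_path": str(out_path), "manifest_path": str(manifest_path),
    }
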