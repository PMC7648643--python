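"""Outgroup-f3 and f4 statistics with weighted block-jackknife errors.

Statistics operate on alt-allele frequencies.  A label is resolved first as a
sample id (a single pseudo-haploid sample contributes frequencies in {0, 1}),
then as a population label (frequency = mean alt-allele dose over non-missing
samples).  SNP usability is listwise over exactly the populations entering
the statistic.  No small-sample heterozygosity correction is applied anywhere:
these are relative drift-sharing measures, not absolute branch lengths.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import EmptyStatisticError, JackknifeError, SampleLookupError
from .genotype_io import MISSING, GenotypeMatrix

DEFAULT_MIN_SNPS = 10_000
Z_THRESHOLD = 3.0


@dataclass
class BlockSpec:
    """Per-SNP block assignment for the jackknife."""

    block_ids: np.ndarray
    scheme: str = "custom"

    def __post_init__(self) -> None:
        self.block_ids = np.asarray(self.block_ids, dtype=np.int64)
        if self.block_ids.ndim != 1:
            raise ValueError("block_ids must be one-dimensional")
        if self.block_ids.size and self.block_ids.min() < 0:
            raise ValueError("block ids must be non-negative")

    @property
    def n_blocks(self) -> int:
        return int(self.block_ids.max()) + 1 if self.block_ids.size else 0


def blocks_per_chromosome(matrix: GenotypeMatrix) -> BlockSpec:
    """One jackknife block per chromosome, in order of first appearance."""
    chroms = matrix.chromosomes()
    order: dict[str, int] = {}
    ids = np.empty(len(chroms), dtype=np.int64)
    for j, c in enumerate(chroms):
        ids[j] = order.setdefault(c, len(order))
    return BlockSpec(block_ids=ids, scheme="per_chromosome")


def blocks_fixed_snp_count(n_snps: int, block_size: int) -> BlockSpec:
    """Contiguous blocks of ``block_size`` SNPs (last block may be short)."""
    if block_size <= 0:
        raise ValueError("block_size must be positive")
    ids = np.arange(n_snps, dtype=np.int64) // block_size
    return BlockSpec(block_ids=ids, scheme=f"fixed_snp_count({block_size})")


@dataclass
class FStatResult:
    statistic_kind: str
    populations: tuple[str, ...]
    estimate: float
    std_error: float
    z_score: float
    n_snps_used: int
    n_blocks: int
    significant: bool
    valid: bool


# ---------------------------------------------------------------------------
# jackknife
# ---------------------------------------------------------------------------

def block_jackknife(
    per_block_sums: np.ndarray, per_block_counts: np.ndarray
) -> tuple[float, float]:
    """Weighted delete-one-block jackknife for a ratio-of-sums estimator.

    The overall estimate is sum(sums)/sum(counts); weights are proportional
    to block SNP counts.  With B equal blocks the variance reduces to
    (B-1)/B * sum((theta_j - mean)^2) over delete-one estimates theta_j.
    Zero-count blocks are dropped with a warning.
    """
    sums = np.asarray(per_block_sums, dtype=float)
    counts = np.asarray(per_block_counts, dtype=float)
    if sums.shape != counts.shape:
        raise ValueError("per_block_sums and per_block_counts differ in shape")
    if np.any(counts == 0):
        warnings.warn("dropping zero-count jackknife blocks", stacklevel=2)
        keep = counts > 0
        sums, counts = sums[keep], counts[keep]
    B = sums.size
    if B < 2:
        raise JackknifeError(f"need at least 2 non-empty blocks, got {B}")
    total_sum = sums.sum()
    total_count = counts.sum()
    estimate = total_sum / total_count
    theta_del = (total_sum - sums) / (total_count - counts)
    # Busing et al. weighted jackknife with h_j = n / m_j
    h = total_count / counts
    tau = h * estimate - (h - 1.0) * theta_del
    theta_jack = tau.mean()
    var = np.sum((tau - theta_jack) ** 2 / (h - 1.0)) / B
    return float(estimate), float(np.sqrt(var))


# ---------------------------------------------------------------------------
# frequency resolution
# ---------------------------------------------------------------------------

def allele_frequencies(matrix: GenotypeMatrix, label: str) -> np.ndarray:
    """Per-SNP alt-allele frequency for a sample id or population label.

    Missing frequencies are NaN.  For a single pseudo-haploid sample the
    frequency is the sampled-allele indicator (0 or 1).
    """
    ids = matrix.sample_ids
    if label in ids:
        rows = [matrix.sample_index(label)]
    else:
        rows = [i for i, s in enumerate(matrix.samples) if s.population_label == label]
        if not rows:
            raise SampleLookupError(label)
    calls = matrix.calls[rows].astype(float)
    calls[calls == MISSING] = np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        return np.nanmean(calls, axis=0) / 2.0


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def _finalize(
    kind: str,
    populations: tuple[str, ...],
    per_snp: np.ndarray,
    usable: np.ndarray,
    blocks: BlockSpec,
    min_snps: int,
) -> FStatResult:
    n_used = int(usable.sum())
    if n_used == 0:
        raise EmptyStatisticError(f"{kind}{populations}: no usable SNPs")
    block_ids = blocks.block_ids
    if block_ids.size != per_snp.size:
        raise ValueError("block assignment does not cover the SNP panel")
    n_blocks_total = int(block_ids.max()) + 1
    sums = np.bincount(block_ids[usable], weights=per_snp[usable], minlength=n_blocks_total)
    counts = np.bincount(block_ids[usable], minlength=n_blocks_total)
    nonempty = counts > 0
    estimate, se = block_jackknife(sums[nonempty], counts[nonempty])
    z = estimate / se if se > 0 else float("nan")
    return FStatResult(
        statistic_kind=kind,
        populations=populations,
        estimate=estimate,
        std_error=se,
        z_score=z,
        n_snps_used=n_used,
        n_blocks=int(nonempty.sum()),
        significant=bool(abs(z) >= Z_THRESHOLD) if np.isfinite(z) else False,
        valid=n_used >= min_snps,
    )


def compute_outgroup_f3(
    matrix: GenotypeMatrix,
    outgroup: str,
    a: str,
    b: str,
    blocks: BlockSpec | None = None,
    min_snps: int = DEFAULT_MIN_SNPS,
) -> FStatResult:
    """f3(outgroup; a, b): mean over usable SNPs of (o - pa)(o - pb)."""
    if len({outgroup, a, b}) != 3:
        raise ValueError("outgroup, a and b must be three distinct labels")
    o = allele_frequencies(matrix, outgroup)
    pa = allele_frequencies(matrix, a)
    pb = allele_frequencies(matrix, b)
    usable = np.isfinite(o) & np.isfinite(pa) & np.isfinite(pb)
    per_snp = np.where(usable, (o - pa) * (o - pb), 0.0)
    return _finalize(
        "outgroup_f3",
        (outgroup, a, b),
        per_snp,
        usable,
        blocks or blocks_per_chromosome(matrix),
        min_snps,
    )


def compute_f4(
    matrix: GenotypeMatrix,
    a: str,
    b: str,
    c: str,
    d: str,
    blocks: BlockSpec | None = None,
    min_snps: int = DEFAULT_MIN_SNPS,
) -> FStatResult:
    """f4(a, b; c, d): mean over usable SNPs of (pa - pb)(pc - pd)."""
    if len({a, b, c, d}) != 4:
        raise ValueError("a, b, c, d must be four distinct labels")
    pa = allele_frequencies(matrix, a)
    pb = allele_frequencies(matrix, b)
    pc = allele_frequencies(matrix, c)
    pd_ = allele_frequencies(matrix, d)
    usable = np.isfinite(pa) & np.isfinite(pb) & np.isfinite(pc) & np.isfinite(pd_)
    per_snp = np.where(usable, (pa - pb) * (pc - pd_), 0.0)
    return _finalize(
        "f4",
        (a, b, c, d),
        per_snp,
        usable,
        blocks or blocks_per_chromosome(matrix),
        min_snps,
    )
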