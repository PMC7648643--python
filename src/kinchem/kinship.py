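"""Mismatch-rate kinship: pairwise rates, relatedness coefficient, degree
classification, and read-count sex determination.

The relatedness coefficient r places a pair's mismatch rate on the line
between two baselines: the rate of unrelated individuals (r = 0) and the
rate of an identical pair (r = 1).  Under pseudo-haploid sampling of
Hardy-Weinberg genotypes the identical-pair rate is analytically half the
unrelated rate, which is the default identical endpoint; an observed
same-individual/twin rate can override it.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass

import numpy as np

from .errors import BaselineError, EmptyStatisticError, JackknifeError
from .fstats import BlockSpec, block_jackknife, blocks_per_chromosome
from .genotype_io import MISSING, PSEUDO_HAPLOID, GenotypeMatrix, overlap_mask
from .popsim import SamplingModel, pseudo_haploidize

DEFAULT_MIN_SNPS = 10_000

#: expected genome-sharing fraction per degree class, most related first
DEGREE_SHARES: list[tuple[str, float]] = [
    ("identical", 1.0),
    ("first", 0.5),
    ("second", 0.25),
    ("third", 0.125),
    ("fourth", 0.0625),
    ("unrelated", 0.0),
]

#: arithmetic midpoints of adjacent expected shares; ties go to the more
#: related class
DEGREE_BOUNDARIES: list[float] = [
    (DEGREE_SHARES[i][1] + DEGREE_SHARES[i + 1][1]) / 2.0
    for i in range(len(DEGREE_SHARES) - 1)
]  # 0.75, 0.375, 0.1875, 0.09375, 0.03125


@dataclass
class MismatchResult:
    pair: tuple[str, str]
    n_overlap: int
    n_mismatch: int
    rate: float
    std_error: float
    ci95: tuple[float, float]
    qc_pass: bool = True


@dataclass
class RelatednessCall:
    pair: tuple[str, str]
    r: float
    r_ci95: tuple[float, float]
    degree_label: str
    n_overlap: int
    qc_pass: bool


@dataclass
class SexCallResult:
    n_x_reads: int
    n_y_reads: int
    r_y: float
    call: str


# ---------------------------------------------------------------------------
# mismatch rates
# ---------------------------------------------------------------------------

def _haploid_calls(matrix: GenotypeMatrix, sample: str, seed: int) -> np.ndarray:
    """Sample calls on the pseudo-haploid scale (diploids are haploidised)."""
    i = matrix.sample_index(sample)
    calls = matrix.calls[i]
    if matrix.ploidy_modes[i] == PSEUDO_HAPLOID:
        return calls
    # deterministic per-sample substream so every pair sees the same draw
    # (process-stable hash; builtin hash() is salted per interpreter run)
    digest = zlib.crc32(sample.encode("utf-8"))
    sub = np.random.default_rng([seed, digest])
    return pseudo_haploidize(calls, SamplingModel(), rng=sub)


def pairwise_mismatch(
    matrix: GenotypeMatrix,
    a: str,
    b: str,
    blocks: BlockSpec | None = None,
    min_snps: int = DEFAULT_MIN_SNPS,
    seed: int = 0,
) -> MismatchResult:
    """Mismatch rate over SNPs covered in both samples, with jackknife CI."""
    ca = _haploid_calls(matrix, a, seed)
    cb = _haploid_calls(matrix, b, seed)
    ok = (ca != MISSING) & (cb != MISSING)
    n_overlap = int(ok.sum())
    if n_overlap == 0:
        raise EmptyStatisticError(f"samples {a!r} and {b!r} share no covered SNPs")
    mism = ok & (ca != cb)
    n_mismatch = int(mism.sum())
    rate = n_mismatch / n_overlap

    blocks = blocks or blocks_per_chromosome(matrix)
    ids = blocks.block_ids
    nb = int(ids.max()) + 1 if ids.size else 0
    sums = np.bincount(ids[ok], weights=mism[ok].astype(float), minlength=nb)
    counts = np.bincount(ids[ok], minlength=nb)
    nonempty = counts > 0
    if nonempty.sum() >= 2:
        _, se = block_jackknife(sums[nonempty], counts[nonempty])
    else:
        warnings.warn("fewer than 2 non-empty blocks; mismatch SE undefined", stacklevel=2)
        se = float("nan")
    lo = max(0.0, rate - 1.96 * se) if np.isfinite(se) else float("nan")
    hi = min(1.0, rate + 1.96 * se) if np.isfinite(se) else float("nan")
    return MismatchResult(
        pair=(a, b),
        n_overlap=n_overlap,
        n_mismatch=n_mismatch,
        rate=rate,
        std_error=se,
        ci95=(lo, hi),
        qc_pass=n_overlap >= min_snps,
    )


def estimate_baselines(
    matrix: GenotypeMatrix,
    unrelated_pairs: list[tuple[str, str]],
    observed_identical_rate: float | None = None,
    blocks: BlockSpec | None = None,
    min_snps: int = DEFAULT_MIN_SNPS,
    seed: int = 0,
) -> tuple[float, float]:
    """Mismatch-rate baselines (m_unrelated, m_identical).

    m_unrelated is the overlap-weighted mean rate over the given unrelated
    pairs.  m_identical defaults to m_unrelated / 2 (the analytic
    pseudo-haploid expectation under HWE) unless an observed identical-pair
    rate is supplied.
    """
    if not unrelated_pairs:
        raise BaselineError("at least one unrelated pair is required")
    total_mm = 0
    total_ov = 0
    for a, b in unrelated_pairs:
        res = pairwise_mismatch(matrix, a, b, blocks=blocks, min_snps=min_snps, seed=seed)
        total_mm += res.n_mismatch
        total_ov += res.n_overlap
    if total_ov == 0:
        raise BaselineError("unrelated pairs have no covered overlap")
    m_unrelated = total_mm / total_ov
    m_identical = (
        observed_identical_rate if observed_identical_rate is not None else m_unrelated / 2.0
    )
    return m_unrelated, m_identical


# ---------------------------------------------------------------------------
# relatedness coefficient and degree classification
# ---------------------------------------------------------------------------

def relatedness_coefficient(
    m_pair: float,
    m_unrelated: float,
    m_identical: float,
    pair_ci95: tuple[float, float] | None = None,
) -> tuple[float, tuple[float, float]]:
    """r = (m_un - m_pair)/(m_un - m_id), with the pair CI propagated.

    Baselines are treated as fixed constants; r is reported unclipped and may
    fall outside [0, 1].
    """
    if not m_unrelated > m_identical >= 0:
        raise BaselineError(
            f"degenerate baselines: m_unrelated={m_unrelated}, m_identical={m_identical}"
        )
    denom = m_unrelated - m_identical
    r = (m_unrelated - m_pair) / denom
    if pair_ci95 is None:
        return r, (r, r)
    lo, hi = pair_ci95
    return r, ((m_unrelated - hi) / denom, (m_unrelated - lo) / denom)


def classify_degree(
    r: float,
    r_ci95: tuple[float, float] | None = None,
    qc_pass: bool = True,
    n_overlap: int = 0,
    pair: tuple[str, str] = ("", ""),
    ci_rule: str = "point",
) -> RelatednessCall:
    """Degree label from r by arithmetic-midpoint bins on expected shares.

    ``ci_rule='span'`` additionally returns ``indeterminate`` when the 95% CI
    crosses a bin boundary; the default classifies the point estimate alone.
    """

    def _bin(value: float) -> str:
        for (label, _), boundary in zip(DEGREE_SHARES, DEGREE_BOUNDARIES):
            if value >= boundary:
                return label
        return DEGREE_SHARES[-1][0]

    if not qc_pass:
        label = "indeterminate"
    else:
        label = _bin(r)
        if ci_rule == "span" and r_ci95 is not None:
            lo, hi = r_ci95
            if np.isfinite(lo) and np.isfinite(hi) and _bin(lo) != _bin(hi):
                label = "indeterminate"
    return RelatednessCall(
        pair=pair,
        r=r,
        r_ci95=r_ci95 if r_ci95 is not None else (r, r),
        degree_label=label,
        n_overlap=n_overlap,
        qc_pass=qc_pass,
    )


def call_relatedness(
    matrix: GenotypeMatrix,
    pair: tuple[str, str],
    m_unrelated: float,
    m_identical: float,
    blocks: BlockSpec | None = None,
    min_snps: int = DEFAULT_MIN_SNPS,
    ci_rule: str = "point",
    seed: int = 0,
) -> RelatednessCall:
    """End-to-end: mismatch rate -> r with CI -> degree label for one pair."""
    mm = pairwise_mismatch(matrix, *pair, blocks=blocks, min_snps=min_snps, seed=seed)
    ci = mm.ci95 if np.isfinite(mm.std_error) else None
    r, r_ci = relatedness_coefficient(mm.rate, m_unrelated, m_identical, pair_ci95=ci)
    return classify_degree(
        r,
        r_ci95=r_ci,
        qc_pass=mm.qc_pass,
        n_overlap=mm.n_overlap,
        pair=pair,
        ci_rule=ci_rule,
    )


# ---------------------------------------------------------------------------
# sex determination
# ---------------------------------------------------------------------------

def sex_from_counts(
    n_x_reads: int,
    n_y_reads: int,
    xy_threshold: float = 0.075,
    xx_threshold: float = 0.016,
) -> SexCallResult:
    """Genetic sex from the fraction of sex-chromosome reads on Y.

    r_y = Y/(X+Y); XY when r_y >= ``xy_threshold``, XX when
    r_y <= ``xx_threshold``, indeterminate in between or with no reads.
    """
    if n_x_reads < 0 or n_y_reads < 0:
        raise ValueError("read counts must be non-negative")
    total = n_x_reads + n_y_reads
    if total == 0:
        warnings.warn("no reads on X or Y; sex indeterminate", stacklevel=2)
        return SexCallResult(n_x_reads, n_y_reads, float("nan"), "indeterminate")
    r_y = n_y_reads / total
    if r_y >= xy_threshold:
        call = "XY"
    elif r_y <= xx_threshold:
        call = "XX"
    else:
        call = "indeterminate"
    return SexCallResult(n_x_reads, n_y_reads, r_y, call)
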