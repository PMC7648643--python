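"""Genotype matrix data model and EIGENSTRAT ASCII I/O.

The on-disk representation is the plain-text EIGENSTRAT triplet: a ``.geno``
file with one row per SNP and one digit per sample (``0``/``1``/``2`` alt-allele
counts, ``9`` missing), a ``.snp`` file with six whitespace-separated columns
(snp id, chromosome, genetic position in Morgans, physical position, ref
allele, alt allele) and a ``.ind`` file with three columns (sample id, sex
code, population label).  Packed binary geno files are not supported.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, SampleLookupError

MISSING = 9
VALID_CALLS = frozenset({0, 1, 2, 9})
VALID_ALLELES = frozenset("ACGT")
VALID_CHROMOSOMES = tuple(str(i) for i in range(1, 23)) + ("X", "Y", "MT")

DIPLOID = "diploid"
PSEUDO_HAPLOID = "pseudo_haploid"

# numeric aliases used by common tooling for the sex chromosomes / mtDNA
_CHROM_ALIASES = {"23": "X", "24": "Y", "90": "MT", "M": "MT", "chrM": "MT"}


def normalize_chromosome(token: str) -> str:
    """Map a chromosome token onto the canonical label set {1..22, X, Y, MT}."""
    tok = str(token).strip()
    if tok.startswith("chr"):
        tok = tok[3:]
    tok = _CHROM_ALIASES.get(tok, tok)
    if tok not in VALID_CHROMOSOMES:
        raise FormatError(f"unrecognised chromosome label {token!r}")
    return tok


@dataclass(frozen=True)
class SNPRecord:
    """A single locus with its metadata."""

    snp_id: str
    chromosome: str
    position_bp: int
    ref_allele: str
    alt_allele: str
    genetic_position_morgans: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "chromosome", normalize_chromosome(self.chromosome))
        if self.position_bp < 0:
            raise FormatError(f"{self.snp_id}: negative position {self.position_bp}")
        if self.genetic_position_morgans < 0:
            raise FormatError(f"{self.snp_id}: negative genetic position")
        for allele in (self.ref_allele, self.alt_allele):
            if allele not in VALID_ALLELES:
                raise FormatError(f"{self.snp_id}: invalid allele {allele!r}")
        if self.ref_allele == self.alt_allele:
            raise FormatError(f"{self.snp_id}: ref and alt alleles are identical")


@dataclass(frozen=True)
class SampleRecord:
    """A sample with its population label and sex code."""

    sample_id: str
    population_label: str = "POP"
    sex_code: str = "U"

    def __post_init__(self) -> None:
        if self.sex_code not in {"M", "F", "U"}:
            raise FormatError(f"{self.sample_id}: invalid sex code {self.sex_code!r}")


@dataclass
class GenotypeMatrix:
    """Samples x SNPs call matrix with per-sample ploidy modes.

    ``calls`` holds alt-allele counts in {0, 1, 2} with 9 for missing, as an
    int8 array of shape (n_samples, n_snps).  Pseudo-haploid samples may only
    carry {0, 2, 9}.
    """

    samples: list[SampleRecord]
    snps: list[SNPRecord]
    calls: np.ndarray
    ploidy_modes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2:
            raise FormatError("calls must be a 2-D array (samples x snps)")
        if self.calls.shape != (len(self.samples), len(self.snps)):
            raise FormatError(
                f"calls shape {self.calls.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.snps)} snps"
            )
        if not self.ploidy_modes:
            self.ploidy_modes = [self._infer_ploidy(i) for i in range(self.n_samples)]
        if len(self.ploidy_modes) != self.n_samples:
            raise FormatError("ploidy_modes length does not match sample count")
        self.validate()

    # -- basic views ---------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise SampleLookupError(sample_id) from None

    def chromosomes(self) -> np.ndarray:
        return np.array([s.chromosome for s in self.snps])

    def _infer_ploidy(self, i: int) -> str:
        return DIPLOID if np.any(self.calls[i] == 1) else PSEUDO_HAPLOID

    # -- validation ----------------------------------------------------
    def validate(self) -> None:
        ids = self.sample_ids
        if len(set(ids)) != len(ids):
            dup = next(s for s in ids if ids.count(s) > 1)
            raise FormatError(f"duplicate sample id {dup!r}")
        bad = ~np.isin(self.calls, (0, 1, 2, 9))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise FormatError(
                f"illegal call code {self.calls[i, j]} for sample {ids[i]!r} at snp {j}"
            )
        for i, mode in enumerate(self.ploidy_modes):
            if mode not in {DIPLOID, PSEUDO_HAPLOID}:
                raise FormatError(f"unknown ploidy mode {mode!r}")
            if mode == PSEUDO_HAPLOID and np.any(self.calls[i] == 1):
                raise FormatError(
                    f"pseudo-haploid sample {ids[i]!r} carries heterozygous code 1"
                )
        # positions strictly increasing within each chromosome run
        prev_chrom, prev_pos = None, -1
        for k, snp in enumerate(self.snps):
            if snp.chromosome == prev_chrom and snp.position_bp <= prev_pos:
                raise FormatError(
                    f"positions not strictly increasing on chromosome "
                    f"{snp.chromosome} at snp row {k} ({snp.snp_id!r})"
                )
            prev_chrom, prev_pos = snp.chromosome, snp.position_bp

    # -- debugging export ----------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """SNP-per-row dataframe with one call column per sample."""
        df = pd.DataFrame(
            {
                "snp_id": [s.snp_id for s in self.snps],
                "chromosome": [s.chromosome for s in self.snps],
                "position_bp": [s.position_bp for s in self.snps],
            }
        )
        for i, sid in enumerate(self.sample_ids):
            df[sid] = self.calls[i]
        return df


# ---------------------------------------------------------------------------
# EIGENSTRAT ASCII triplet I/O
# ---------------------------------------------------------------------------

def _triplet_paths(prefix: str | Path) -> tuple[Path, Path, Path]:
    base = str(prefix)
    return Path(base + ".geno"), Path(base + ".snp"), Path(base + ".ind")


def read_eigenstrat(
    geno_path: str | Path,
    snp_path: str | Path,
    ind_path: str | Path,
    ploidy_modes: Sequence[str] | None = None,
) -> GenotypeMatrix:
    """Read an ASCII EIGENSTRAT triplet.

    The geno file carries one row per SNP and one digit column per sample.
    Ploidy is inferred per sample (pseudo-haploid iff no code-1 call) unless
    ``ploidy_modes`` is given explicitly.
    """
    samples: list[SampleRecord] = []
    for ln, line in enumerate(Path(ind_path).read_text().splitlines(), start=1):
        fields = line.split()
        if not fields:
            continue
        if len(fields) != 3:
            raise FormatError(f"{ind_path}: row {ln}: expected 3 columns, got {len(fields)}")
        sid, sex, pop = fields
        if sex not in {"M", "F", "U"}:
            raise FormatError(f"{ind_path}: row {ln}: invalid sex code {sex!r}")
        samples.append(SampleRecord(sample_id=sid, population_label=pop, sex_code=sex))

    snps: list[SNPRecord] = []
    for ln, line in enumerate(Path(snp_path).read_text().splitlines(), start=1):
        fields = line.split()
        if not fields:
            continue
        if len(fields) != 6:
            raise FormatError(f"{snp_path}: row {ln}: expected 6 columns, got {len(fields)}")
        sid, chrom, gpos, ppos, ref, alt = fields
        try:
            snps.append(
                SNPRecord(
                    snp_id=sid,
                    chromosome=chrom,
                    genetic_position_morgans=float(gpos),
                    position_bp=int(ppos),
                    ref_allele=ref,
                    alt_allele=alt,
                )
            )
        except FormatError as exc:
            raise FormatError(f"{snp_path}: row {ln}: {exc}") from None

    geno_lines = Path(geno_path).read_text().splitlines()
    geno_lines = [ln for ln in geno_lines if ln]
    if len(geno_lines) != len(snps):
        raise FormatError(
            f"{geno_path}: {len(geno_lines)} rows but {len(snps)} snp records"
        )
    n_samples = len(samples)
    calls = np.empty((n_samples, len(snps)), dtype=np.int8)
    for j, line in enumerate(geno_lines):
        if len(line) != n_samples:
            raise FormatError(
                f"{geno_path}: row {j + 1}: {len(line)} digits but {n_samples} samples"
            )
        row = np.frombuffer(line.encode("ascii"), dtype=np.uint8) - ord("0")
        bad = ~np.isin(row, (0, 1, 2, 9))
        if bad.any():
            col = int(np.argwhere(bad)[0][0])
            raise FormatError(
                f"{geno_path}: row {j + 1}, column {col + 1}: illegal digit {line[col]!r}"
            )
        calls[:, j] = row
    return GenotypeMatrix(
        samples=samples,
        snps=snps,
        calls=calls,
        ploidy_modes=list(ploidy_modes) if ploidy_modes else [],
    )


def read_eigenstrat_prefix(prefix: str | Path, **kwargs) -> GenotypeMatrix:
    """Read ``<prefix>.geno/.snp/.ind``."""
    geno, snp, ind = _triplet_paths(prefix)
    return read_eigenstrat(geno, snp, ind, **kwargs)


def write_eigenstrat(matrix: GenotypeMatrix, out_prefix: str | Path) -> tuple[Path, Path, Path]:
    """Write the matrix as ``<out_prefix>.geno/.snp/.ind``; returns the paths."""
    geno_path, snp_path, ind_path = _triplet_paths(out_prefix)
    geno_path.parent.mkdir(parents=True, exist_ok=True)

    digits = matrix.calls.T + ord("0")  # snp-major
    buf = io.StringIO()
    for row in digits.astype(np.uint8):
        buf.write(row.tobytes().decode("ascii"))
        buf.write("\n")
    geno_path.write_text(buf.getvalue())

    with snp_path.open("w") as fh:
        for s in matrix.snps:
            fh.write(
                f"{s.snp_id} {s.chromosome} {s.genetic_position_morgans} "
                f"{s.position_bp} {s.ref_allele} {s.alt_allele}\n"
            )
    with ind_path.open("w") as fh:
        for s in matrix.samples:
            fh.write(f"{s.sample_id} {s.sex_code} {s.population_label}\n")
    return geno_path, snp_path, ind_path


def overlap_mask(matrix: GenotypeMatrix, sample_a: str, sample_b: str) -> np.ndarray:
    """Ascending indices of SNPs where neither sample's call is missing."""
    ia = matrix.sample_index(sample_a)
    ib = matrix.sample_index(sample_b)
    ok = (matrix.calls[ia] != MISSING) & (matrix.calls[ib] != MISSING)
    return np.flatnonzero(ok)
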