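"""Synthetic genotype data: founder panels, pedigree gene-dropping, sampling.

Founders are drawn under Hardy-Weinberg equilibrium from per-SNP allele
frequencies.  Pedigrees for the canonical relationship templates are built
explicitly and founder haplotypes are dropped through meioses with crossovers
placed as a Poisson process on a sex-averaged genetic map (no interference).
Every haplotype carries the id of its founder haplotype of origin, so the
realized identity-by-descent share of a simulated pair is known exactly.

Pseudo-haploid sampling emulates the random-read representation of
low-coverage capture data: one allele per site, with optional missingness,
contaminant draws and symmetric call error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import ConfigurationError
from .genotype_io import (
    DIPLOID,
    PSEUDO_HAPLOID,
    GenotypeMatrix,
    SampleRecord,
    SNPRecord,
)

_BASES = ("A", "C", "G", "T")


# ---------------------------------------------------------------------------
# models
# ---------------------------------------------------------------------------

ChromosomeMap = list[tuple[str, float, int]]  # (label, length in Morgans, n snps)


def default_chromosome_map(
    n_snps: int, n_chromosomes: int = 22, morgans_each: float = 1.5
) -> ChromosomeMap:
    """22 equal autosomes with near-equal SNP counts summing to ``n_snps``."""
    if n_snps < n_chromosomes:
        n_chromosomes = max(1, n_snps)
    base, extra = divmod(n_snps, n_chromosomes)
    return [
        (str(i + 1), morgans_each, base + (1 if i < extra else 0))
        for i in range(n_chromosomes)
    ]


@dataclass
class FounderModel:
    """Founder-population model: SNP layout plus an allele-frequency law."""

    n_snps: int
    seed: int = 0
    chromosome_map: ChromosomeMap = field(default_factory=list)
    allele_freq_law: tuple = ("uniform", 0.05, 0.95)

    def __post_init__(self) -> None:
        if self.n_snps <= 0:
            raise ConfigurationError("n_snps must be positive")
        if not self.chromosome_map:
            self.chromosome_map = default_chromosome_map(self.n_snps)
        if sum(n for _, _, n in self.chromosome_map) != self.n_snps:
            raise ConfigurationError("chromosome_map SNP counts do not sum to n_snps")
        law = self.allele_freq_law
        if law[0] == "uniform":
            _, a, b = law
            if not (0.0 < a <= b < 1.0):
                raise ConfigurationError(
                    f"uniform({a}, {b}) must satisfy 0 < a <= b < 1"
                )
        elif law[0] == "beta":
            _, alpha, beta = law
            if alpha <= 0 or beta <= 0:
                raise ConfigurationError("beta law requires positive shape parameters")
        else:
            raise ConfigurationError(f"unknown allele frequency law {law[0]!r}")


@dataclass
class SamplingModel:
    """Pseudo-haploid sampling model (missingness, error, contamination)."""

    missing_rate: float = 0.0
    error_rate: float = 0.0
    contamination_rate: float = 0.0
    contaminant_freqs: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("missing_rate", "error_rate", "contamination_rate"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name}={p} outside [0, 1]")
        if self.contamination_rate > 0 and self.contaminant_freqs is None:
            raise ConfigurationError(
                "contamination_rate > 0 requires contaminant_freqs"
            )


@dataclass(frozen=True)
class PedigreeTemplate:
    name: str
    expected_share: float  # k2 + k1/2: expected genome-sharing fraction
    degree: int | None  # relationship degree, None for unrelated/distant

    def __post_init__(self) -> None:
        degree_share = {0: 1.0, 1: 0.5, 2: 0.25, 3: 0.125, 4: 0.0625}
        if self.degree in degree_share and degree_share[self.degree] != self.expected_share:
            raise ConfigurationError(
                f"{self.name}: expected_share {self.expected_share} inconsistent "
                f"with degree {self.degree}"
            )


#: Canonical relationship templates; degree bindings use unilineal pedigrees
#: (1st = parent/offspring, 2nd = avuncular, 3rd = first cousins,
#: 4th = first cousins once removed).
TEMPLATES: dict[str, PedigreeTemplate] = {
    "twin": PedigreeTemplate("twin", 1.0, 0),
    "parent_offspring": PedigreeTemplate("parent_offspring", 0.5, 1),
    "full_sib": PedigreeTemplate("full_sib", 0.5, 1),
    "half_sib": PedigreeTemplate("half_sib", 0.25, 2),
    "avuncular": PedigreeTemplate("avuncular", 0.25, 2),
    "first_cousin": PedigreeTemplate("first_cousin", 0.125, 3),
    "first_cousin_once_removed": PedigreeTemplate(
        "first_cousin_once_removed", 0.0625, 4
    ),
    "second_cousin": PedigreeTemplate("second_cousin", 0.03125, None),
    "unrelated": PedigreeTemplate("unrelated", 0.0, None),
}


@dataclass
class SimulatedPair:
    """Two diploid genotype vectors with their exact realized IBD share."""

    genotype_a: np.ndarray
    genotype_b: np.ndarray
    realized_ibd_share: float
    template: str = ""


# ---------------------------------------------------------------------------
# founder simulation
# ---------------------------------------------------------------------------

@dataclass
class FounderPanel:
    """Per-SNP allele frequencies plus the layout needed for gene dropping."""

    model: FounderModel
    allele_freqs: np.ndarray

    def draw_founder_genotypes(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """n diploid genotypes (alt-allele counts) as an (n, n_snps) array."""
        p = self.allele_freqs
        return (
            (rng.random((n, p.size)) < p).astype(np.int8)
            + (rng.random((n, p.size)) < p).astype(np.int8)
        )


def simulate_founders(model: FounderModel) -> FounderPanel:
    """Draw per-SNP allele frequencies from the model's frequency law."""
    rng = np.random.default_rng(model.seed)
    kind = model.allele_freq_law[0]
    if kind == "uniform":
        _, a, b = model.allele_freq_law
        freqs = rng.uniform(a, b, size=model.n_snps) if a < b else np.full(model.n_snps, a)
    else:
        _, alpha, beta = model.allele_freq_law
        freqs = np.clip(rng.beta(alpha, beta, size=model.n_snps), 1e-9, 1 - 1e-9)
    return FounderPanel(model=model, allele_freqs=freqs)


# ---------------------------------------------------------------------------
# gene dropping
# ---------------------------------------------------------------------------

class _GeneticMap:
    """Per-chromosome SNP slices and genetic positions (Morgans)."""

    def __init__(self, chromosome_map: ChromosomeMap):
        self.slices: list[slice] = []
        self.positions: list[np.ndarray] = []
        self.lengths: list[float] = []
        start = 0
        for _label, morgans, n in chromosome_map:
            stop = start + n
            self.slices.append(slice(start, stop))
            self.positions.append(np.linspace(0.0, morgans, n))
            self.lengths.append(float(morgans))
            start = stop
        self.n_snps = start


class _Haplotype:
    __slots__ = ("ids", "alleles")

    def __init__(self, ids: np.ndarray, alleles: np.ndarray):
        self.ids = ids
        self.alleles = alleles


class _Individual:
    __slots__ = ("h1", "h2")

    def __init__(self, h1: _Haplotype, h2: _Haplotype):
        self.h1 = h1
        self.h2 = h2

    def genotype(self) -> np.ndarray:
        return (self.h1.alleles + self.h2.alleles).astype(np.int8)


def _meiosis(rng: np.random.Generator, parent: _Individual, gmap: _GeneticMap) -> _Haplotype:
    ids = np.empty(gmap.n_snps, dtype=np.int32)
    alleles = np.empty(gmap.n_snps, dtype=np.int8)
    for sl, pos, length in zip(gmap.slices, gmap.positions, gmap.lengths):
        n_x = rng.poisson(length)
        cuts = np.sort(rng.uniform(0.0, length, size=n_x))
        phase = (np.searchsorted(cuts, pos, side="right") + rng.integers(2)) % 2
        from_h1 = phase == 0
        ids[sl] = np.where(from_h1, parent.h1.ids[sl], parent.h2.ids[sl])
        alleles[sl] = np.where(from_h1, parent.h1.alleles[sl], parent.h2.alleles[sl])
    return _Haplotype(ids, alleles)


def _realized_share(a: _Individual, b: _Individual) -> float:
    """Mean over SNPs of (IBD-shared haplotypes)/2, via founder-haplotype ids."""
    m11 = a.h1.ids == b.h1.ids
    m12 = a.h1.ids == b.h2.ids
    m21 = a.h2.ids == b.h1.ids
    m22 = a.h2.ids == b.h2.ids
    two = (m11 & m22) | (m12 & m21)
    one = m11 | m12 | m21 | m22
    k = two.astype(np.int8) + one.astype(np.int8)  # 0, 1 or 2 shared haplotypes
    return float(k.mean() / 2.0)


def gene_drop(
    template: PedigreeTemplate | str,
    founders: FounderPanel,
    chromosome_map: ChromosomeMap | None = None,
    seed: int = 0,
) -> SimulatedPair:
    """Simulate one pair of related individuals under the named pedigree.

    Founder haplotypes are drawn fresh (Bernoulli per SNP at the panel
    frequencies); the pedigree for the template is constructed explicitly and
    gametes are produced by :func:`_meiosis`.  Deterministic under ``seed``.
    """
    if isinstance(template, str):
        try:
            template = TEMPLATES[template]
        except KeyError:
            raise KeyError(f"unknown pedigree template {template!r}") from None
    gmap = _GeneticMap(chromosome_map or founders.model.chromosome_map)
    if gmap.n_snps != founders.allele_freqs.size:
        raise ConfigurationError("chromosome map does not cover the SNP panel")
    rng = np.random.default_rng(seed)
    freqs = founders.allele_freqs

    counter = iter(range(1, 10_000))

    def founder() -> _Individual:
        haps = []
        for _ in range(2):
            hid = next(counter)
            alleles = (rng.random(freqs.size) < freqs).astype(np.int8)
            haps.append(_Haplotype(np.full(freqs.size, hid, dtype=np.int32), alleles))
        return _Individual(*haps)

    def child(p: _Individual, q: _Individual) -> _Individual:
        return _Individual(_meiosis(rng, p, gmap), _meiosis(rng, q, gmap))

    name = template.name
    if name == "unrelated":
        a, b = founder(), founder()
    elif name == "twin":
        a = child(founder(), founder())
        b = a
    elif name == "parent_offspring":
        p = founder()
        a, b = p, child(p, founder())
    elif name == "full_sib":
        p, q = founder(), founder()
        a, b = child(p, q), child(p, q)
    elif name == "half_sib":
        p = founder()
        a, b = child(p, founder()), child(p, founder())
    elif name == "avuncular":
        p, q = founder(), founder()
        s1, s2 = child(p, q), child(p, q)
        a, b = s1, child(s2, founder())
    elif name in {"first_cousin", "first_cousin_once_removed", "second_cousin"}:
        p, q = founder(), founder()
        s1, s2 = child(p, q), child(p, q)
        c1, c2 = child(s1, founder()), child(s2, founder())
        if name == "first_cousin":
            a, b = c1, c2
        elif name == "first_cousin_once_removed":
            a, b = c1, child(c2, founder())
        else:
            a, b = child(c1, founder()), child(c2, founder())
    else:  # pragma: no cover - guarded by TEMPLATES lookup
        raise KeyError(f"unknown pedigree template {name!r}")

    return SimulatedPair(
        genotype_a=a.genotype(),
        genotype_b=b.genotype(),
        realized_ibd_share=_realized_share(a, b),
        template=name,
    )


# ---------------------------------------------------------------------------
# pseudo-haploid sampling
# ---------------------------------------------------------------------------

def pseudo_haploidize(
    diploid_vector: np.ndarray,
    sampling: SamplingModel | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Reduce a diploid call vector to pseudo-haploid codes {0, 2, 9}.

    Per SNP: with ``missing_rate`` emit 9; otherwise sample one of the two
    alleles uniformly, replace it by a contaminant draw with
    ``contamination_rate``, and flip it with ``error_rate``.
    """
    sampling = sampling or SamplingModel()
    if rng is None:
        rng = np.random.default_rng(sampling.seed)
    g = np.asarray(diploid_vector)
    n = g.size
    out = np.full(n, 9, dtype=np.int8)

    observed = (g != 9) & (rng.random(n) >= sampling.missing_rate)
    # sampled allele: hom sites deterministic, het sites a fair coin
    allele = np.where(g == 2, 1, 0).astype(np.int8)
    het = g == 1
    allele[het] = (rng.random(n)[het] < 0.5).astype(np.int8)
    if sampling.contamination_rate > 0:
        contam = rng.random(n) < sampling.contamination_rate
        contam_allele = (rng.random(n) < np.asarray(sampling.contaminant_freqs)).astype(np.int8)
        allele = np.where(contam, contam_allele, allele)
    if sampling.error_rate > 0:
        flip = rng.random(n) < sampling.error_rate
        allele = np.where(flip, 1 - allele, allele)
    out[observed] = allele[observed] * 2
    return out


# ---------------------------------------------------------------------------
# scenario assembly
# ---------------------------------------------------------------------------

def _make_snp_records(panel: FounderPanel) -> list[SNPRecord]:
    records = []
    j = 0
    for label, morgans, n in panel.model.chromosome_map:
        for k in range(n):
            records.append(
                SNPRecord(
                    snp_id=f"snp{j}",
                    chromosome=label,
                    position_bp=(k + 1) * 1000,
                    genetic_position_morgans=round(morgans * k / max(n - 1, 1), 8),
                    ref_allele="A",
                    alt_allele="G",
                )
            )
            j += 1
    return records


def simulate_pair_matrix(
    panel: FounderPanel,
    template_counts: dict[str, int],
    sampling: SamplingModel | None = None,
    seed: int = 0,
) -> tuple[GenotypeMatrix, list[dict]]:
    """Simulate pairs for each template and assemble a pseudo-haploid matrix.

    Returns the matrix plus a manifest of pair records
    (sample ids, template, realized IBD share).
    """
    rng = np.random.default_rng(seed)
    sampling = sampling or SamplingModel()
    snps = _make_snp_records(panel)
    samples: list[SampleRecord] = []
    rows: list[np.ndarray] = []
    manifest: list[dict] = []
    for name in sorted(template_counts):
        for rep in range(template_counts[name]):
            pair = gene_drop(name, panel, seed=int(rng.integers(2**63)))
            sid_a = f"{name}_{rep:04d}_a"
            sid_b = f"{name}_{rep:04d}_b"
            for sid, g in ((sid_a, pair.genotype_a), (sid_b, pair.genotype_b)):
                samples.append(SampleRecord(sample_id=sid, population_label=name))
                rows.append(
                    pseudo_haploidize(g, sampling, rng=np.random.default_rng(int(rng.integers(2**63))))
                )
            manifest.append(
                {
                    "template": name,
                    "sample_a": sid_a,
                    "sample_b": sid_b,
                    "realized_ibd_share": pair.realized_ibd_share,
                }
            )
    calls = np.vstack(rows) if rows else np.empty((0, len(snps)), dtype=np.int8)
    matrix = GenotypeMatrix(
        samples=samples,
        snps=snps,
        calls=calls,
        ploidy_modes=[PSEUDO_HAPLOID] * len(samples),
    )
    return matrix, manifest
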