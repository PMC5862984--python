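"""SNP-based, haplotype-based and whole-genome genomic relationship matrices.

The SNP-based regional estimator averages, over the S window SNPs, the
frequency-standardised cross-product of counted-allele dosages:

    IBS_ij = (1/S) sum_k (O_ik - 2P_k)(O_jk - 2P_k) / (2 P_k (1 - P_k))

The haplotype-based estimator applies the same form to diplotype counts
Q_ik (copies of haplotype allele k carried by individual i), averaging over
the H distinct haplotype alleles observed in the window.  Rare alleles get
large weights 1/(2P(1-P)), so individuals sharing rare alleles come out as
more closely related.

Allele and haplotype frequencies are estimated from the analysed
individuals themselves, which makes the grand sum of every matrix exactly
zero.  Monomorphic markers/windows are skipped (``WindowSkipped``) rather
than imputed: the denominators are undefined there.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import HaplotypePanel

__all__ = [
    "WindowSkipped",
    "GenotypeView",
    "HaplotypeAlleles",
    "RegionalGRM",
    "enumerate_haplotypes",
    "snp_regional_grm",
    "haplotype_regional_grm",
    "whole_genome_grm",
]


class WindowSkipped(Exception):
    """Raised when a window has no usable markers (monomorphic / H = 1)."""


def _window_slice(window) -> slice:
    if isinstance(window, slice):
        return window
    if hasattr(window, "abs_start"):
        return slice(window.abs_start, window.abs_stop)
    a, b = window
    return slice(int(a), int(b))


@dataclass
class GenotypeView:
    """Dosage matrix O (N x S, values 0/1/2) with counted-allele frequencies."""

    individual_ids: list[str]
    dosages: np.ndarray
    freqs: np.ndarray  # P_k estimated from these individuals

    @classmethod
    def from_panel(cls, panel: HaplotypePanel) -> "GenotypeView":
        dose = panel.dosages().astype(float)
        return cls(list(panel.individual_ids), dose, dose.mean(axis=0) / 2.0)

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]


@dataclass
class HaplotypeAlleles:
    """Distinct haplotype alleles of a window with frequencies and diplotype counts."""

    individual_ids: list[str]
    alleles: np.ndarray  # (H, s) binary strings
    freqs: np.ndarray  # (H,) from the 2N chromosomes
    diplotypes: np.ndarray  # (N, H) copies carried, rows sum to 2

    @property
    def n_alleles(self) -> int:
        return self.alleles.shape[0]


@dataclass
class RegionalGRM:
    """Symmetric N x N relationship matrix.

    ``loadings`` (optional, N x m) is a factor with
    ``matrix = loadings @ loadings.T``; variance-component fitting exploits
    it to stay low-rank.
    """

    individual_ids: list[str]
    matrix: np.ndarray
    n_markers: int
    kind: str  # snp | haplotype | whole_genome
    loadings: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.individual_ids)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-8):
            raise ValueError("relationship matrix must be symmetric")


def _standardized_loadings(counts: np.ndarray, freqs: np.ndarray, n_avg: int) -> np.ndarray:
    z = (counts - 2.0 * freqs) / np.sqrt(2.0 * freqs * (1.0 - freqs))
    return z / np.sqrt(n_avg)


def enumerate_haplotypes(panel: HaplotypePanel, window) -> HaplotypeAlleles:
    """Enumerate the distinct haplotype alleles among the 2N chromosomes of a window."""
    sl = _window_slice(window)
    hap = panel.haplotypes[:, :, sl]
    if hap.shape[2] == 0:
        raise ValueError("empty window")
    if (hap < 0).any():
        raise ValueError("window contains missing alleles")
    n = panel.n_individuals
    chroms = hap.reshape(2 * n, -1)  # rows: ind0 hapA, ind0 hapB, ind1 hapA, ...
    alleles, inverse, counts = np.unique(chroms, axis=0, return_inverse=True, return_counts=True)
    h = alleles.shape[0]
    q = np.zeros((n, h), dtype=np.int16)
    inv = inverse.reshape(n, 2)
    np.add.at(q, (np.repeat(np.arange(n), 2), inv.ravel()), 1)
    return HaplotypeAlleles(
        list(panel.individual_ids), alleles, counts / (2.0 * n), q
    )


def snp_regional_grm(genotypes: GenotypeView, window=None) -> RegionalGRM:
    """SNP-based regional GRM over a window (monomorphic SNPs dropped first)."""
    sl = _window_slice(window) if window is not None else slice(None)
    dose = genotypes.dosages[:, sl]
    freqs = genotypes.freqs[sl]
    poly = (freqs > 0.0) & (freqs < 1.0)
    s = int(poly.sum())
    if s == 0:
        raise WindowSkipped("all SNPs in window are monomorphic")
    z = _standardized_loadings(dose[:, poly], freqs[poly], s)
    return RegionalGRM(genotypes.individual_ids, z @ z.T, s, "snp", loadings=z)


def haplotype_regional_grm(alleles: HaplotypeAlleles) -> RegionalGRM:
    """Haplotype-based regional GRM from diplotype counts (requires H >= 2)."""
    h = alleles.n_alleles
    if h < 2:
        raise WindowSkipped("window is monomorphic (single haplotype allele)")
    z = _standardized_loadings(alleles.diplotypes.astype(float), alleles.freqs, h)
    return RegionalGRM(alleles.individual_ids, z @ z.T, h, "haplotype", loadings=z)


def whole_genome_loadings(genotypes: GenotypeView, exclude=None) -> np.ndarray:
    """Standardised loadings Z with whole-genome GRM = Z Z^T (no N x N product).

    ``exclude`` optionally lists SNP indices to leave out, e.g. the tested
    window.  Monomorphic SNPs are always dropped.
    """
    mask = np.ones(genotypes.dosages.shape[1], dtype=bool)
    if exclude is not None:
        mask[np.asarray(exclude)] = False
    if not mask.any():
        raise ValueError("no SNPs left for whole-genome GRM")
    poly = mask & (genotypes.freqs > 0.0) & (genotypes.freqs < 1.0)
    s = int(poly.sum())
    if s == 0:
        raise ValueError("no polymorphic SNPs for whole-genome GRM")
    return _standardized_loadings(genotypes.dosages[:, poly], genotypes.freqs[poly], s)


def whole_genome_grm(genotypes: GenotypeView, exclude=None) -> RegionalGRM:
    """Whole-genome SNP GRM, optionally excluding SNP indices (e.g. the tested window)."""
    z = whole_genome_loadings(genotypes, exclude)
    return RegionalGRM(
        genotypes.individual_ids, z @ z.T, z.shape[1], "whole_genome", loadings=z
    )
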