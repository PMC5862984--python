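"""Readers and writers for the standard formats the tool touches, plus the QC filter.

Conventions used throughout the package:

* VCF positions are 1-based and preserved; every internal window index is a
  0-based half-open range over SNP order.
* The counted allele is the VCF ALT allele; haplotype code 1 means "carries
  the counted allele".
* Missing alleles (code ``-1``) are tolerated only before :func:`qc_filter`;
  all analysis operations require complete data.
"""

from __future__ import annotations

import gzip
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1

__all__ = [
    "HaplotypePanel",
    "GeneticMap",
    "PhenotypeTable",
    "read_vcf_phased",
    "write_vcf",
    "qc_filter",
    "hwe_exact_pvalue",
    "write_grm",
    "read_grm",
    "read_genetic_map",
    "read_phenotypes",
    "write_phenotypes",
    "write_scan_results",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class HaplotypePanel:
    """Phased biallelic panel: N individuals x 2 chromosomes x S SNPs.

    ``haplotypes`` holds int8 allele codes (0 = REF, 1 = ALT/counted,
    -1 = missing, pre-QC only).  ``snp_table`` is a DataFrame with columns
    ``id, chrom, pos_bp, cM`` sorted by chromosome (order of first
    appearance) then position.
    """

    individual_ids: list[str]
    snp_table: pd.DataFrame
    haplotypes: np.ndarray  # (N, 2, S) int8

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        n, two, s = self.haplotypes.shape
        if two != 2:
            raise ValueError("haplotypes must have shape (N, 2, S)")
        if n != len(self.individual_ids):
            raise ValueError("individual_ids length does not match haplotypes")
        if s != len(self.snp_table):
            raise ValueError("snp_table length does not match haplotypes")
        codes = np.unique(self.haplotypes)
        if not np.isin(codes, [MISSING, 0, 1]).all():
            raise ValueError("allele codes must be in {-1, 0, 1}")
        if len(set(self.individual_ids)) != n:
            raise ValueError("duplicate individual ids")
        self.snp_table = self.snp_table.reset_index(drop=True)
        for chrom, sub in self.snp_table.groupby("chrom", sort=False):
            pos = sub["pos_bp"].to_numpy()
            if not (np.diff(pos) > 0).all():
                raise ValueError(
                    f"positions not strictly increasing on chromosome {chrom}"
                )

    # -- basic queries ------------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.haplotypes.shape[2]

    @property
    def chromosomes(self) -> list:
        seen: dict = {}
        for c in self.snp_table["chrom"]:
            seen.setdefault(c, None)
        return list(seen)

    @property
    def has_missing(self) -> bool:
        return bool((self.haplotypes == MISSING).any())

    def chrom_slice(self, chrom) -> slice:
        """Absolute [start, stop) slice of this chromosome's SNPs."""
        idx = np.flatnonzero((self.snp_table["chrom"] == chrom).to_numpy())
        if idx.size == 0:
            raise KeyError(f"chromosome {chrom!r} not in panel")
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def dosages(self, snp_slice=None) -> np.ndarray:
        """N x S matrix of counted-allele dosages (0/1/2); requires complete data."""
        hap = self.haplotypes if snp_slice is None else self.haplotypes[:, :, snp_slice]
        if (hap == MISSING).any():
            raise ValueError("dosages require complete data; run qc_filter first")
        return hap.sum(axis=1, dtype=np.int16)

    def subset(self, individuals=None, snps=None) -> "HaplotypePanel":
        ind = np.arange(self.n_individuals) if individuals is None else np.asarray(individuals)
        snp = np.arange(self.n_snps) if snps is None else np.asarray(snps)
        return HaplotypePanel(
            [self.individual_ids[i] for i in ind],
            self.snp_table.iloc[snp].reset_index(drop=True),
            self.haplotypes[np.ix_(ind, [0, 1], snp)],
        )


@dataclass
class GeneticMap:
    """Piecewise-constant recombination map, per chromosome.

    For each chromosome: breakpoint positions (bp), the rate (cM/Mb)
    applying from a breakpoint up to the next one, and the cumulative map
    position (cM) at each breakpoint.
    """

    chromosomes: dict = field(default_factory=dict)
    # chrom -> dict(pos=np.ndarray, rate=np.ndarray, cm=np.ndarray)

    def add_chromosome(self, chrom, pos_bp, rate_cm_mb, cum_cm) -> None:
        pos = np.asarray(pos_bp, dtype=np.int64)
        rate = np.asarray(rate_cm_mb, dtype=float)
        cm = np.asarray(cum_cm, dtype=float)
        if not (np.diff(pos) > 0).all():
            raise ValueError(f"map positions not strictly increasing on {chrom}")
        if (rate < 0).any():
            raise ValueError("recombination rates must be non-negative")
        if (np.diff(cm) < -1e-12).any():
            raise ValueError(f"cumulative cM decreasing on chromosome {chrom}")
        self.chromosomes[chrom] = {"pos": pos, "rate": rate, "cm": cm}

    def span(self, chrom) -> tuple[int, int]:
        c = self.chromosomes[chrom]
        return int(c["pos"][0]), int(c["pos"][-1])

    def interp_cm(self, chrom, positions) -> np.ndarray:
        """Cumulative cM at bp positions (linear within map segments)."""
        c = self.chromosomes[chrom]
        positions = np.asarray(positions)
        lo, hi = self.span(chrom)
        if positions.min() < lo or positions.max() > hi:
            raise ValueError(f"position outside map span on chromosome {chrom}")
        return np.interp(positions, c["pos"], c["cm"])

    def max_rate_between(self, chrom, bp_a: int, bp_b: int) -> float:
        """Maximum rate over the open bp interval (bp_a, bp_b).

        A rate segment [p_i, p_{i+1}) contributes iff it overlaps the open
        interval, so a hotspot ending exactly at ``bp_b`` still counts while
        one starting at ``bp_b`` does not (boundary-on-SNP rule).
        """
        if bp_b <= bp_a:
            raise ValueError("interval must satisfy bp_a < bp_b")
        c = self.chromosomes[chrom]
        pos = c["pos"]
        i0 = int(np.searchsorted(pos, bp_a, side="right")) - 1
        i0 = max(i0, 0)
        i1 = int(np.searchsorted(pos, bp_b, side="left")) - 1
        i1 = min(max(i1, i0), len(c["rate"]) - 1)
        return float(c["rate"][i0 : i1 + 1].max())


@dataclass
class PhenotypeTable:
    """Quantitative phenotype per individual id."""

    individual_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.individual_ids) != len(self.values):
            raise ValueError("ids/values length mismatch")
        if len(set(self.individual_ids)) != len(self.individual_ids):
            raise ValueError("duplicate phenotype ids")
        if not np.isfinite(self.values).all():
            raise ValueError("phenotype values must be finite")

    def aligned_to(self, ids: list[str]) -> np.ndarray:
        index = {s: i for i, s in enumerate(self.individual_ids)}
        try:
            order = [index[s] for s in ids]
        except KeyError as exc:
            raise KeyError(f"phenotype missing for individual {exc.args[0]!r}") from None
        return self.values[order]


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_BASES = {"A", "C", "G", "T"}


def read_vcf_phased(path) -> HaplotypePanel:
    """Read a phased biallelic-SNP VCF into a :class:`HaplotypePanel`.

    Multiallelic or non-SNP records are skipped (logged).  Any unphased or
    missing genotype raises, naming the first offending record.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows = []
    haps = []
    n_skipped = 0
    for v in vcf:
        if len(v.ALT) != 1 or v.REF not in _BASES or v.ALT[0] not in _BASES:
            n_skipped += 1
            continue
        label = f"{v.CHROM}:{v.POS}" + (f" ({v.ID})" if v.ID else "")
        gts = v.genotypes  # [[a0, a1, phased], ...]
        col = np.empty((len(samples), 2), dtype=np.int8)
        for i, g in enumerate(gts):
            if len(g) < 3 or not g[-1]:
                raise ValueError(f"unphased genotype at record {label}, sample {samples[i]}")
            a0, a1 = g[0], g[1]
            if a0 < 0 or a1 < 0:
                raise ValueError(f"missing genotype at record {label}, sample {samples[i]}")
            col[i, 0], col[i, 1] = a0, a1
        rows.append((v.ID or ".", v.CHROM, v.POS, np.nan))
        haps.append(col)
    if n_skipped:
        logger.info("read_vcf_phased: skipped %d multiallelic/non-SNP records", n_skipped)
    if not rows:
        raise ValueError("no biallelic SNP records in VCF")
    snp_table = pd.DataFrame(rows, columns=["id", "chrom", "pos_bp", "cM"])
    haplotypes = np.stack(haps, axis=2)  # (N, 2, S)
    return HaplotypePanel(samples, snp_table, haplotypes)


def write_vcf(panel: HaplotypePanel, path) -> None:
    """Write a minimal phased VCF 4.2 for the panel (complete data only)."""
    if panel.has_missing:
        raise ValueError("cannot write VCF with missing alleles")
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, sub in panel.snp_table.groupby("chrom", sort=False):
            fh.write(f"##contig=<ID={chrom},length={int(sub['pos_bp'].max()) + 1}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.individual_ids)
            + "\n"
        )
        hap = panel.haplotypes
        tbl = panel.snp_table
        for k in range(panel.n_snps):
            gts = "\t".join(f"{hap[i, 0, k]}|{hap[i, 1, k]}" for i in range(panel.n_individuals))
            fh.write(
                f"{tbl.at[k, 'chrom']}\t{int(tbl.at[k, 'pos_bp'])}\t{tbl.at[k, 'id']}"
                f"\tA\tG\t.\t.\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------


def hwe_exact_pvalue(n_het: int, n_hom1: int, n_hom2: int) -> float:
    """Exact Hardy-Weinberg test p-value (two-sided, probability ordering).

    Sums the probabilities of all heterozygote configurations no more likely
    than the observed one, conditional on the allele counts (the standard
    exact SNP-HWE recurrence).
    """
    n = n_het + n_hom1 + n_hom2
    if n == 0:
        return 1.0
    rare = 2 * min(n_hom1, n_hom2) + n_het
    # probabilities over n_het = rare, rare-2, ..., parity(rare)
    hets = list(range(rare % 2, rare + 1, 2))
    probs = np.zeros(len(hets))
    # start from mid-range het count for numerical stability
    mid = rare * (2 * n - rare) // (2 * n)
    if (mid - rare) % 2:
        mid += 1
    imid = hets.index(mid)
    probs[imid] = 1.0
    # downward recurrence: P(h-2)/P(h) = h(h-1) / ((r-h+2)/2 * (2n-r-h+2)/2) ... derived
    for i in range(imid, 0, -1):
        h = hets[i]
        hom_r = (rare - h) // 2
        hom_c = n - h - hom_r
        probs[i - 1] = probs[i] * h * (h - 1.0) / (4.0 * (hom_r + 1.0) * (hom_c + 1.0))
    for i in range(imid, len(hets) - 1):
        h = hets[i]
        hom_r = (rare - h) // 2
        hom_c = n - h - hom_r
        probs[i + 1] = probs[i] * 4.0 * hom_r * hom_c / ((h + 2.0) * (h + 1.0))
    probs /= probs.sum()
    p_obs = probs[hets.index(n_het)]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def qc_filter(
    panel: HaplotypePanel,
    maf_min: float = 0.01,
    hwe_p_min: float = 1e-8,
    snp_callrate_min: float = 0.95,
    ind_callrate_min: float = 0.95,
) -> HaplotypePanel:
    """Apply the marker/individual QC used before analysis.

    Removes individuals with genotype call rate below ``ind_callrate_min``,
    then SNPs with call rate below ``snp_callrate_min``, minor-allele
    frequency below ``maf_min`` or exact-test HWE p-value below
    ``hwe_p_min``.  Finally any SNP still carrying a missing call is dropped
    so the output is complete.  Idempotent on complete panels.
    """
    hap = panel.haplotypes
    miss = hap == MISSING
    # an individual's call is missing if either allele is missing
    ind_miss = miss.any(axis=1)  # (N, S)
    ind_call = 1.0 - ind_miss.mean(axis=1)
    keep_ind = np.flatnonzero(ind_call >= ind_callrate_min)
    if keep_ind.size == 0:
        raise ValueError("empty panel after QC: all individuals removed")
    hap = hap[keep_ind]
    ind_miss = ind_miss[keep_ind]

    snp_call = 1.0 - ind_miss.mean(axis=0)
    keep = snp_call >= snp_callrate_min

    n_called = (~ind_miss).sum(axis=0)
    dose = np.where(ind_miss, 0, hap.sum(axis=1)).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = dose / (2.0 * n_called)
    maf = np.minimum(p, 1.0 - p)
    keep &= ~(maf < maf_min) & (n_called > 0)

    for k in np.flatnonzero(keep):
        g = hap[:, :, k][~ind_miss[:, k]].sum(axis=1)
        n_het = int((g == 1).sum())
        n_hom1 = int((g == 0).sum())
        n_hom2 = int((g == 2).sum())
        if hwe_exact_pvalue(n_het, n_hom1, n_hom2) < hwe_p_min:
            keep[k] = False

    keep &= ~ind_miss.any(axis=0)  # completeness pass
    keep_idx = np.flatnonzero(keep)
    if keep_idx.size == 0:
        raise ValueError("empty panel after QC")
    n_drop = panel.n_snps - keep_idx.size
    if n_drop:
        logger.info("qc_filter: removed %d of %d SNPs", n_drop, panel.n_snps)
    return panel.subset(individuals=keep_ind, snps=keep_idx)


# ---------------------------------------------------------------------------
# GRM text files (GCTA-style)
# ---------------------------------------------------------------------------


def write_grm(matrix, prefix) -> None:
    """Write a relationship matrix as GCTA-style text: ``<prefix>.grm`` holds
    lower-triangle lines ``i j n_markers value`` (1-based), ``<prefix>.grm.id``
    the individual ids."""
    prefix = str(prefix)
    ids = matrix.individual_ids
    mat = matrix.matrix
    n_markers = matrix.n_markers
    with open(prefix + ".grm", "w") as fh:
        for i in range(len(ids)):
            for j in range(i + 1):
                fh.write(f"{i + 1}\t{j + 1}\t{n_markers}\t{mat[i, j]:.10g}\n")
    with open(prefix + ".grm.id", "w") as fh:
        for s in ids:
            fh.write(f"{s}\t{s}\n")


def read_grm(prefix, kind: str = "snp"):
    """Read a GCTA-style text GRM written by :func:`write_grm` (``.grm`` or
    ``.grm.gz``)."""
    from .grm import RegionalGRM

    prefix = str(prefix)
    idpath = prefix + ".grm.id"
    ids = [line.split()[1] for line in open(idpath) if line.strip()]
    n = len(ids)
    datapath = prefix + ".grm"
    opener = open
    if not Path(datapath).exists() and Path(datapath + ".gz").exists():
        datapath += ".gz"
        opener = gzip.open
    mat = np.zeros((n, n))
    n_markers = 0
    count = 0
    with opener(datapath, "rt") as fh:
        for line in fh:
            if not line.strip():
                continue
            i_s, j_s, m_s, v_s = line.split()
            i, j = int(i_s) - 1, int(j_s) - 1
            if i >= n or j >= n:
                raise ValueError("GRM id file does not match matrix size")
            mat[i, j] = mat[j, i] = float(v_s)
            n_markers = int(round(float(m_s)))
            count += 1
    if count != n * (n + 1) // 2:
        raise ValueError("GRM id file does not match matrix size")
    return RegionalGRM(ids, mat, n_markers, kind)


# ---------------------------------------------------------------------------
# genetic map / phenotypes / scan results
# ---------------------------------------------------------------------------


def read_genetic_map(path) -> GeneticMap:
    """Read a HapMap-style map TSV: chromosome, position bp, rate cM/Mb, map cM."""
    df = pd.read_csv(path, sep=r"\s+", header=None, comment="#", dtype=str)
    if df.shape[1] < 4:
        raise ValueError("genetic map needs 4 columns: chrom, bp, rate, cM")
    # tolerate a header row
    try:
        float(df.iloc[0, 1])
    except ValueError:
        df = df.iloc[1:]
    gmap = GeneticMap()
    df = df.rename(columns=dict(enumerate(["chrom", "pos", "rate", "cm"])))
    for chrom, sub in df.groupby("chrom", sort=False):
        pos = sub["pos"].astype(np.int64).to_numpy()
        rate = sub["rate"].astype(float).to_numpy()
        cm = sub["cm"].astype(float).to_numpy()
        if not (np.diff(pos) > 0).all():
            raise ValueError(f"unsorted map positions on chromosome {chrom}")
        gmap.add_chromosome(chrom, pos, rate, cm)
    return gmap


def write_genetic_map(gmap: GeneticMap, path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tposition_bp\trate_cM_Mb\tmap_cM\n")
        for chrom, c in gmap.chromosomes.items():
            for p, r, m in zip(c["pos"], c["rate"], c["cm"]):
                fh.write(f"{chrom}\t{p}\t{r:.8g}\t{m:.10g}\n")


def read_phenotypes(path) -> PhenotypeTable:
    """Read a header-less two-column (id, value) phenotype file."""
    df = pd.read_csv(path, sep=r"\s+", header=None, dtype=str)
    if df.shape[1] != 2:
        raise ValueError("phenotype file must have exactly two columns")
    return PhenotypeTable(df[0].tolist(), df[1].astype(float).to_numpy())


def write_phenotypes(table: PhenotypeTable, path) -> None:
    with open(path, "w") as fh:
        for s, v in zip(table.individual_ids, table.values):
            fh.write(f"{s}\t{v:.10g}\n")


def write_scan_results(table: pd.DataFrame, path) -> None:
    """Write a scan-result table as TSV with a fixed header."""
    table.to_csv(path, sep="\t", index=False, float_format="%.6g", na_rep="NA")
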