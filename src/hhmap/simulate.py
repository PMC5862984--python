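"""Synthetic phased panels, forward-in-time mating, and phenotype architectures.

The synthetic base panel stands in for the unavailable cohort: each
chromosome is a sequence of haplotype blocks separated by recombination
hotspots, each block carrying a small set of distinct haplotype alleles
whose frequencies are drawn from a symmetric Dirichlet (low concentration
=> most alleles rare).  The emitted genetic map places hotspot-level rates
exactly in the inter-block gaps, so block definition at the hotspot
threshold recovers the generating blocks.

Phenotypes are built as y = g_r + g_p + e with the three components
centred, mutually orthogonalised in-sample and rescaled so the realised
variance split is exact (defaults 0.05 / 0.25 / 0.70, total 1).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .blocks import BlockMap, Window, define_blocks
from .grm import enumerate_haplotypes
from .io_formats import GeneticMap, HaplotypePanel, PhenotypeTable

__all__ = [
    "PanelConfig",
    "SimConfig",
    "PhenotypeSet",
    "synth_base_panel",
    "forward_simulate",
    "simulate_phenotypes",
    "select_regions",
    "emulated_cohort_config",
]

ARCHITECTURES = ("1SNP", "AllSNP", "1Hap", "AllHap")


def substream(seed, name: str) -> np.random.Generator:
    """Named, independent RNG substream derived from a master seed.

    ``seed`` may be an int or a tuple of ints (e.g. (master, arch, region,
    replicate)); the stream for a given (seed, name) pair is stable.
    """
    entropy = [int(s) for s in seed] if isinstance(seed, (tuple, list)) else [int(seed)]
    return np.random.default_rng(np.random.SeedSequence(entropy + [zlib.crc32(name.encode())]))


@dataclass
class PanelConfig:
    """Generator settings for a synthetic block-structured phased panel.

    ``allele_structure`` controls how a block's haplotype alleles are built:

    * ``"dirichlet"`` -- every allele is an independent random binary string
      and all frequencies come from one symmetric Dirichlet draw;
    * ``"founder"`` -- a few common founder strings share most of the
      frequency mass (Dirichlet with unit concentration) while the remaining
      alleles are rare recombinants/mutants of the founders with base
      frequencies drawn log-uniformly from ``derived_freq_range``.  This
      mimics real LD blocks, where rare haplotypes are rare combinations of
      common SNP alleles and are therefore poorly tagged by single SNPs.
    """

    n_individuals: int
    n_blocks_per_chrom: tuple = (30,)
    snps_per_block: tuple = (1, 12)
    alleles_per_block: tuple = (2, 12)
    concentration: float = 0.3
    allele_structure: str = "dirichlet"
    founders_per_block: tuple = (2, 6)
    derived_freq_range: tuple = (0.002, 0.02)
    snp_spacing_bp: int = 5000
    hotspot_bp: int = 10000
    pad_bp: int = 5000
    base_rate: float = 1.0
    hotspot_rate: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 1 or min(self.n_blocks_per_chrom) < 1:
            raise ValueError("counts must be >= 1")
        if self.concentration <= 0:
            raise ValueError("Dirichlet concentration must be positive")
        if self.hotspot_rate <= self.base_rate:
            raise ValueError("hotspot rate must exceed baseline rate")
        if self.allele_structure not in ("dirichlet", "founder"):
            raise ValueError("allele_structure must be 'dirichlet' or 'founder'")


@dataclass
class SimConfig:
    """One phenotype-simulation scenario."""

    architecture: str
    h2_region: float = 0.05
    h2_polygenic: float = 0.25
    n_generations: int = 20
    seed: object = 0  # int or tuple of ints
    causal_snp: int | None = None  # per-window SNP offset for 1SNP

    def __post_init__(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"architecture must be one of {ARCHITECTURES}")
        if not (0 <= self.h2_region <= 1 and 0 <= self.h2_polygenic <= 1):
            raise ValueError("heritabilities must lie in [0, 1]")
        if self.h2_region + self.h2_polygenic >= 1:
            raise ValueError("h2_region + h2_polygenic must be < 1")


@dataclass
class PhenotypeSet:
    """Simulated phenotypes with the true component values and provenance."""

    individual_ids: list[str]
    y: np.ndarray
    g_r: np.ndarray
    g_p: np.ndarray
    e: np.ndarray
    causal: dict = field(default_factory=dict)
    realized: dict = field(default_factory=dict)

    def table(self) -> PhenotypeTable:
        return PhenotypeTable(self.individual_ids, self.y)


# ---------------------------------------------------------------------------
# base panel
# ---------------------------------------------------------------------------


def _distinct_strings(rng: np.random.Generator, h: int, s: int) -> np.ndarray:
    if s <= 20:
        codes = rng.choice(2**s, size=h, replace=False)
        return ((codes[:, None] >> np.arange(s)) & 1).astype(np.int8)
    seen: set = set()
    rows = []
    while len(rows) < h:
        cand = rng.integers(0, 2, size=s, dtype=np.int8)
        key = cand.tobytes()
        if key not in seen:
            seen.add(key)
            rows.append(cand)
    return np.array(rows, dtype=np.int8)


def _block_alleles(rng: np.random.Generator, config: PanelConfig, s: int):
    """Distinct allele strings and base frequencies for one block."""
    cap = 2**s if s <= 30 else 2**30
    if config.alleles_per_block[0] > cap:
        raise ValueError(
            f"block of {s} SNPs cannot host {config.alleles_per_block[0]} haplotypes"
        )
    h = int(rng.integers(config.alleles_per_block[0], config.alleles_per_block[1] + 1))
    h = min(h, cap)
    if config.allele_structure == "dirichlet":
        alleles = _distinct_strings(rng, h, s)
        freqs = rng.dirichlet(np.full(h, config.concentration))
        return alleles, freqs

    # founder mode: common founders + rare derived recombinants/mutants
    f = int(rng.integers(config.founders_per_block[0], config.founders_per_block[1] + 1))
    f = min(f, h, cap)
    strings = [row for row in _distinct_strings(rng, f, s)]
    seen = {c.tobytes() for c in strings}
    founders = np.array(strings)
    poly_sites = np.flatnonzero(founders.min(axis=0) != founders.max(axis=0))
    if poly_sites.size == 0:
        poly_sites = np.arange(s)
    tries = 0
    while len(strings) < h and tries < 60 * h:
        tries += 1
        if s > 1 and rng.random() < 0.5:  # recombinant of two founders
            a, b = rng.integers(f, size=2)
            bp = int(rng.integers(1, s))
            cand = np.concatenate([strings[a][:bp], strings[b][bp:]]).astype(np.int8)
        else:  # 1-2-site mutant of a founder at a founder-polymorphic site
            cand = strings[int(rng.integers(f))].copy()
            flips = rng.choice(poly_sites, size=min(int(rng.integers(1, 3)), poly_sites.size),
                               replace=False)
            cand[flips] ^= 1
        if cand.tobytes() not in seen:
            seen.add(cand.tobytes())
            strings.append(cand)
    h = len(strings)
    freqs = np.empty(h)
    lo, hi = config.derived_freq_range
    if h > f:
        freqs[f:] = np.exp(rng.uniform(np.log(lo), np.log(hi), size=h - f))
    rare_mass = freqs[f:].sum() if h > f else 0.0
    freqs[:f] = rng.dirichlet(np.full(f, 1.0)) * max(1.0 - rare_mass, 0.3)
    freqs /= freqs.sum()
    return np.array(strings, dtype=np.int8), freqs


def synth_base_panel(config: PanelConfig):
    """Generate a base panel, its genetic map and the generating block map.

    Returns ``(panel, gmap, blocks)``; ``define_blocks`` on the emitted map at
    the hotspot threshold reproduces ``blocks`` exactly.
    """
    rng = substream(config.seed, "panel")
    n = config.n_individuals
    ids = [f"ind{i:05d}" for i in range(n)]
    snp_rows = []
    hap_cols = []
    windows: list[Window] = []
    gmap = GeneticMap()
    abs_off = 0
    for ci, n_blocks in enumerate(config.n_blocks_per_chrom):
        chrom = f"chr{ci + 1}"
        bp_pos: list[int] = []
        map_pos: list[int] = [1]
        map_rate: list[float] = [config.base_rate]
        per_chrom_off = 0
        cur = 1 + config.pad_bp
        for b in range(n_blocks):
            s = int(rng.integers(config.snps_per_block[0], config.snps_per_block[1] + 1))
            alleles, freqs = _block_alleles(rng, config, s)
            h = len(alleles)
            labels = rng.choice(h, size=2 * n, p=freqs)
            block_haps = alleles[labels].reshape(n, 2, s)
            pos = cur + config.snp_spacing_bp * np.arange(s)
            for j in range(s):
                snp_rows.append((f"{chrom}_b{b}_s{j}", chrom, int(pos[j]), np.nan))
            bp_pos.extend(pos.tolist())
            hap_cols.append(block_haps)
            windows.append(
                Window(chrom, per_chrom_off, per_chrom_off + s, s, abs_off, abs_off + s)
            )
            per_chrom_off += s
            abs_off += s
            last = int(pos[-1])
            if b < n_blocks - 1:
                hot_start = last + config.pad_bp
                map_pos.extend([hot_start, hot_start + config.hotspot_bp])
                map_rate.extend([config.hotspot_rate, config.base_rate])
                cur = hot_start + config.hotspot_bp + config.pad_bp
        map_pos.append(bp_pos[-1] + config.pad_bp)
        map_rate.append(config.base_rate)
        cm = np.concatenate(
            [[0.0], np.cumsum(np.diff(map_pos) / 1e6 * np.array(map_rate[:-1]))]
        )
        gmap.add_chromosome(chrom, map_pos, map_rate, cm)

    import pandas as pd

    panel = HaplotypePanel(
        ids,
        pd.DataFrame(snp_rows, columns=["id", "chrom", "pos_bp", "cM"]),
        np.concatenate(hap_cols, axis=2),
    )
    blocks = BlockMap(windows, threshold_cm_mb=5.0)
    return panel, gmap, blocks


# ---------------------------------------------------------------------------
# forward-in-time simulation
# ---------------------------------------------------------------------------


def _transmit(rng, hap, parents, cm_snps, length_cm, sl, out, role):
    """Fill one gamete per offspring for one chromosome."""
    n = parents.size
    k = rng.poisson(length_cm / 100.0, size=n)
    start = rng.integers(0, 2, size=n)
    out[:, role, sl] = hap[parents, start, sl]
    cm0 = cm_snps[0] if cm_snps.size else 0.0
    for i in np.flatnonzero(k):
        points = np.sort(rng.uniform(cm0, cm0 + length_cm, size=k[i]))
        phase = (start[i] + np.searchsorted(points, cm_snps, side="right")) % 2
        block = hap[parents[i], :, sl]
        out[i, role, sl] = np.where(phase == 0, block[0], block[1])


def forward_simulate(
    panel: HaplotypePanel, gmap: GeneticMap, n_generations: int, seed: int
) -> HaplotypePanel:
    """Random mating with Poisson crossovers (no interference) on the cM scale.

    Each generation keeps the population size constant: sexes are assigned
    1:1 at birth, each offspring draws a father and a mother uniformly with
    replacement, and each transmitted gamete recombines the parent's two
    chromosomes.
    """
    if n_generations < 0:
        raise ValueError("n_generations must be >= 0")
    if panel.has_missing:
        raise ValueError("panel must be complete")
    if n_generations == 0:
        return panel
    rng = substream(seed, "mating")
    n = panel.n_individuals
    chrom_info = []
    for chrom in panel.chromosomes:
        sl = panel.chrom_slice(chrom)
        pos = panel.snp_table["pos_bp"].to_numpy()[sl]
        cm = gmap.interp_cm(chrom, pos)
        length = float(gmap.chromosomes[chrom]["cm"][-1] - gmap.chromosomes[chrom]["cm"][0])
        chrom_info.append((sl, cm, length))

    hap = panel.haplotypes
    for _ in range(n_generations):
        order = rng.permutation(n)
        males, females = order[: n // 2], order[n // 2 :]
        fathers = males[rng.integers(0, males.size, size=n)]
        mothers = females[rng.integers(0, females.size, size=n)]
        new = np.empty_like(hap)
        for sl, cm, length in chrom_info:
            _transmit(rng, hap, fathers, cm, length, sl, new, 0)
            _transmit(rng, hap, mothers, cm, length, sl, new, 1)
        hap = new
    return HaplotypePanel(list(panel.individual_ids), panel.snp_table.copy(), hap)


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------


def _center_scale(v: np.ndarray, target_var: float, what: str) -> np.ndarray:
    v = v - v.mean()
    s = float(v @ v) / v.size
    if s <= 0:
        raise ValueError(f"zero raw variance of {what}")
    if target_var == 0:
        return np.zeros_like(v)
    return v * np.sqrt(target_var / s)


def _project_out(v: np.ndarray, *others: np.ndarray) -> np.ndarray:
    for u in others:
        uu = float(u @ u)
        if uu > 0:
            v = v - (float(v @ u) / uu) * u
    return v


def simulate_phenotypes(
    panel: HaplotypePanel, blocks: BlockMap, region: Window, config: SimConfig
) -> PhenotypeSet:
    """Build phenotypes under one of the four regional architectures.

    The regional value uses the region's SNP dosages (1SNP, AllSNP with
    frequency-standardised equal-variance effects) or diplotype counts
    (1Hap: one allele drawn uniformly among the distinct alleles regardless
    of frequency; AllHap: i.i.d. standard-normal allele effects).  The
    polygenic value sums dosage x N(0,1) effects over all SNPs outside the
    region.  Components are centred, orthogonalised and scaled so the
    realised variances hit the targets exactly.
    """
    n = panel.n_individuals
    sl = slice(region.abs_start, region.abs_stop)
    dose = panel.dosages().astype(float)
    freqs = dose.mean(axis=0) / 2.0
    eff_rng = substream(config.seed, "effects")
    causal: dict = {"architecture": config.architecture, "region": list(region)}

    arch = config.architecture
    if arch == "1SNP":
        poly_idx = np.flatnonzero((freqs[sl] > 0) & (freqs[sl] < 1))
        if poly_idx.size == 0:
            raise ValueError("region monomorphic: no polymorphic SNP for 1SNP")
        if config.causal_snp is not None:
            k = int(config.causal_snp)
            if k not in poly_idx:
                raise ValueError("designated causal SNP is monomorphic or out of range")
        else:
            k = int(eff_rng.choice(poly_idx))
        causal["snp_index"] = region.abs_start + k
        raw = dose[:, region.abs_start + k].copy()
    elif arch == "AllSNP":
        o = dose[:, sl]
        p = freqs[sl]
        poly = (p > 0) & (p < 1)
        if not poly.any():
            raise ValueError("region monomorphic: no polymorphic SNPs for AllSNP")
        signs = eff_rng.choice([-1.0, 1.0], size=int(poly.sum()))
        a = signs / np.sqrt(2.0 * p[poly] * (1.0 - p[poly]))
        causal["snp_effects"] = a.tolist()
        raw = o[:, poly] @ a
    elif arch in ("1Hap", "AllHap"):
        alleles = enumerate_haplotypes(panel, region)
        if alleles.n_alleles < 2:
            raise ValueError("region monomorphic: single haplotype allele")
        if arch == "1Hap":
            k = int(eff_rng.integers(alleles.n_alleles))
            causal["haplotype"] = "".join(map(str, alleles.alleles[k]))
            causal["haplotype_freq"] = float(alleles.freqs[k])
            raw = alleles.diplotypes[:, k].astype(float)
        else:
            beta = eff_rng.standard_normal(alleles.n_alleles)
            causal["haplotype_effects"] = beta.tolist()
            raw = alleles.diplotypes @ beta
    else:  # pragma: no cover
        raise ValueError(arch)

    g_r = _center_scale(raw, config.h2_region, "regional component")

    poly_rng = substream(config.seed, "polygenic")
    outside = np.ones(panel.n_snps, dtype=bool)
    outside[sl] = False
    outside &= (freqs > 0) & (freqs < 1)
    g_p = dose[:, outside] @ poly_rng.standard_normal(int(outside.sum()))
    g_p = _project_out(g_p - g_p.mean(), g_r)
    g_p = _center_scale(g_p, config.h2_polygenic, "polygenic component")

    res_rng = substream(config.seed, "residual")
    e = res_rng.standard_normal(n)
    e = _project_out(e - e.mean(), g_r, g_p)
    e = _center_scale(e, 1.0 - config.h2_region - config.h2_polygenic, "residual")

    y = g_r + g_p + e
    realized = {
        "var_g_r": float(g_r @ g_r) / n,
        "var_g_p": float(g_p @ g_p) / n,
        "var_e": float(e @ e) / n,
        "var_y": float((y - y.mean()) @ (y - y.mean())) / n,
    }
    return PhenotypeSet(list(panel.individual_ids), y, g_r, g_p, e, causal, realized)


def emulated_cohort_config(
    n_individuals: int = 2186, n_blocks_per_chrom: tuple = (12, 12, 12), seed: int = 0
) -> PanelConfig:
    """Calibrated panel preset emulating a phased SNP-array cohort.

    Founder-structured blocks: a handful of common haplotypes plus rare
    recombinant/mutant alleles at base frequencies 0.002-0.02, so that after
    20 generations of random mating the majority of uniformly drawn causal
    haplotype alleles have frequency below 0.02 (rare-variant regime).
    """
    return PanelConfig(
        n_individuals=n_individuals,
        n_blocks_per_chrom=n_blocks_per_chrom,
        snps_per_block=(2, 24),
        alleles_per_block=(4, 16),
        allele_structure="founder",
        founders_per_block=(3, 6),
        derived_freq_range=(0.002, 0.02),
        base_rate=0.5,
        seed=seed,
    )


def select_regions(blocks: BlockMap, n_regions: int, seed: int) -> list[Window]:
    """Sample windows without replacement, stratified over size terciles."""
    wins = list(blocks)
    if n_regions > len(wins):
        raise ValueError("n_regions exceeds the number of blocks")
    rng = substream(seed, "regions")
    order = np.argsort([w.n_snps for w in wins], kind="stable")
    terciles = np.array_split(order, 3)
    pools = [list(t) for t in terciles if len(t)]
    for pool in pools:
        rng.shuffle(pool)
    chosen: list[int] = []
    t = 0
    while len(chosen) < n_regions:
        if pools[t % len(pools)]:
            chosen.append(pools[t % len(pools)].pop())
        t += 1
    return [wins[i] for i in chosen]
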