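"""Partition chromosomes into haplotype-block windows at recombination hotspots.

A boundary is placed in the interval between two adjacent SNPs whenever the
maximum recombination rate over that bp interval is at least the threshold
(inclusive, "at least X cM/Mb").  Chromosome ends are implicit boundaries.
A hotspot whose segment ends exactly on a SNP position splits the interval
preceding that SNP.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .io_formats import GeneticMap, HaplotypePanel

logger = logging.getLogger(__name__)

__all__ = ["Window", "BlockMap", "define_blocks", "window_for_region", "write_blocks_bed"]


class Window(NamedTuple):
    chrom: object
    start: int  # 0-based, per-chromosome SNP order
    stop: int  # half-open
    n_snps: int
    abs_start: int  # absolute SNP index in the panel
    abs_stop: int


@dataclass
class BlockMap:
    """Ordered, contiguous, non-overlapping windows covering all SNPs."""

    windows: list[Window]
    threshold_cm_mb: float

    def __len__(self) -> int:
        return len(self.windows)

    def __iter__(self):
        return iter(self.windows)

    def __getitem__(self, i) -> Window:
        return self.windows[i]

    def for_chromosome(self, chrom) -> list[Window]:
        return [w for w in self.windows if w.chrom == chrom]

    def sizes(self) -> np.ndarray:
        return np.array([w.n_snps for w in self.windows])


def define_blocks(panel: HaplotypePanel, gmap: GeneticMap, threshold: float) -> BlockMap:
    """Split each chromosome's SNPs into hotspot-delimited windows.

    The inter-SNP interval between consecutive SNPs is assigned the maximum
    map rate over that bp span; intervals with rate >= ``threshold`` become
    window boundaries.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    windows: list[Window] = []
    for chrom in panel.chromosomes:
        sl = panel.chrom_slice(chrom)
        pos = panel.snp_table["pos_bp"].to_numpy()[sl]
        if chrom not in gmap.chromosomes:
            raise ValueError(f"chromosome {chrom!r} missing from genetic map")
        lo, hi = gmap.span(chrom)
        bad = np.flatnonzero((pos < lo) | (pos > hi))
        if bad.size:
            snp_id = panel.snp_table["id"].iloc[sl.start + bad[0]]
            raise ValueError(
                f"SNP {snp_id!r} at {chrom}:{pos[bad[0]]} outside map span [{lo}, {hi}]"
            )
        if pos.size == 0:
            logger.info("define_blocks: chromosome %r has no SNPs, skipped", chrom)
            continue
        cut = [
            j + 1
            for j in range(pos.size - 1)
            if gmap.max_rate_between(chrom, int(pos[j]), int(pos[j + 1])) >= threshold
        ]
        edges = [0, *cut, pos.size]
        for a, b in zip(edges[:-1], edges[1:]):
            windows.append(Window(chrom, a, b, b - a, sl.start + a, sl.start + b))
    if not windows:
        raise ValueError("no windows defined (empty panel?)")
    return BlockMap(windows, float(threshold))


def window_for_region(blocks: BlockMap, chrom, snp_index: int) -> Window:
    """Return the unique window covering a per-chromosome SNP index."""
    for w in blocks.for_chromosome(chrom):
        if w.start <= snp_index < w.stop:
            return w
    raise IndexError(f"SNP index {snp_index} out of range on chromosome {chrom}")


def enclosing_window(blocks_coarse: BlockMap, window: Window) -> Window:
    """The window of a coarser (higher-threshold) BlockMap containing ``window``."""
    w = window_for_region(blocks_coarse, window.chrom, window.start)
    if not (w.start <= window.start and window.stop <= w.stop):
        raise ValueError("window is not nested within the coarser block map")
    return w


def write_blocks_bed(blocks: BlockMap, panel: HaplotypePanel, path) -> None:
    """BED-like TSV export (chrom, first/last SNP bp, indices, n_snps)."""
    pos = panel.snp_table["pos_bp"].to_numpy()
    with open(path, "w") as fh:
        fh.write("chrom\tstart_bp\tend_bp\tstart_index\tend_index\tn_snps\n")
        for w in blocks:
            fh.write(
                f"{w.chrom}\t{pos[w.abs_start]}\t{pos[w.abs_stop - 1]}\t"
                f"{w.start}\t{w.stop}\t{w.n_snps}\n"
            )
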