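"""Fragment-size summaries and the per-bin short/long fragmentation ratio.

Tumor-derived cfDNA is shorter than background cfDNA, and the enrichment of
short fragments varies along the genome.  The genome (minus chromosome Y)
is tiled into 1-Mb bins; within each bin we count short (90-150 bp) and
long (151-220 bp) fragments, assigned by midpoint, and report the
pseudocounted ratio (n_short + 0.5) / (n_long + 0.5).
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import FragmentSet

SHORT_RANGE = (90, 150)
LONG_RANGE = (151, 220)
PSEUDOCOUNT = 0.5
DEFAULT_BIN_SIZE = 1_000_000
EXCLUDED_CHROMS = ("chrY", "Y")


@dataclass
class BinScheme:
    """Disjoint half-open windows tiling every non-Y chromosome exactly once.

    The last bin of a chromosome may be shorter than ``bin_size``.
    """

    chrom: np.ndarray      # per-bin chromosome name
    start: np.ndarray
    end: np.ndarray
    bin_size: int

    def __len__(self) -> int:
        return len(self.start)

    @property
    def names(self) -> list[str]:
        return [f"{c}:{s}-{e}" for c, s, e in zip(self.chrom, self.start, self.end)]

    def chrom_offsets(self) -> dict[str, int]:
        """First bin index of each chromosome."""
        out: dict[str, int] = {}
        for i, c in enumerate(self.chrom):
            out.setdefault(str(c), i)
        return out

    def assign(self, chrom: np.ndarray, pos: np.ndarray) -> np.ndarray:
        """Bin index of each (chrom, pos); -1 where no bin contains it."""
        idx = np.full(len(pos), -1, dtype=np.int64)
        offsets = self.chrom_offsets()
        lengths = {}
        for c in offsets:
            mask = self.chrom == c
            lengths[c] = int(self.end[mask].max())
        for c, first in offsets.items():
            m = chrom == c
            if not m.any():
                continue
            p = pos[m]
            ok = (p >= 0) & (p < lengths[c])
            vals = np.where(ok, first + p // self.bin_size, -1)
            idx[m] = vals
        return idx


def make_bins(genome, bin_size: int = DEFAULT_BIN_SIZE) -> BinScheme:
    """Tile every non-Y chromosome with ceil(length / bin_size) windows."""
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    chroms, starts, ends = [], [], []
    for name in genome.chrom_names:
        if name in EXCLUDED_CHROMS:
            continue
        size = genome.lengths[name]
        for i in range(math.ceil(size / bin_size)):
            chroms.append(name)
            starts.append(i * bin_size)
            ends.append(min((i + 1) * bin_size, size))
    return BinScheme(
        np.array(chroms, dtype=object),
        np.array(starts, dtype=np.int64),
        np.array(ends, dtype=np.int64),
        bin_size,
    )


@dataclass
class FragmentationProfile:
    sample_id: str
    n_short: np.ndarray
    n_long: np.ndarray
    ratio: np.ndarray
    mean_insert_size: float
    bins: BinScheme


def fragmentation_profile(fragments: FragmentSet, bins: BinScheme) -> FragmentationProfile:
    """Per-bin short/long counts and ratios plus the sample mean insert size.

    A fragment belongs to the bin containing its midpoint
    ``floor((start + end) / 2)``; a midpoint outside every bin (unknown or
    excluded chromosome) is corrupt input and raises.  Lengths outside
    [90, 220] count toward neither class but do enter the mean insert size.
    """
    mid = (fragments.start + fragments.end) // 2
    idx = bins.assign(fragments.chrom, mid)
    if np.any(idx < 0):
        bad = int(np.flatnonzero(idx < 0)[0])
        raise ValueError(
            f"fragment midpoint outside all bins "
            f"({fragments.chrom[bad]}:{mid[bad]}) — corrupt input"
        )
    lengths = fragments.lengths
    short = (lengths >= SHORT_RANGE[0]) & (lengths <= SHORT_RANGE[1])
    long_ = (lengths >= LONG_RANGE[0]) & (lengths <= LONG_RANGE[1])
    n_short = np.bincount(idx[short], minlength=len(bins)).astype(np.int64)
    n_long = np.bincount(idx[long_], minlength=len(bins)).astype(np.int64)
    ratio = (n_short + PSEUDOCOUNT) / (n_long + PSEUDOCOUNT)
    mean_insert = float(lengths.mean()) if len(lengths) else float("nan")
    return FragmentationProfile(fragments.sample_id, n_short, n_long, ratio,
                                mean_insert, bins)
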