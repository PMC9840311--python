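"""Nucleosome-footprint (NF) scoring at transcription start sites.

Active promoters carry a nucleosome-depleted region (NDR) immediately
upstream of the TSS; cfDNA coverage there drops relative to the promoter's
flanks because unprotected DNA is degraded.  For each gene we compare mean
per-base fragment coverage in the NDR (TSS -150 to +50, strand-aware)
against the surrounding background (TSS +/-2000 minus the NDR):

    NF = (bg_depth - ndr_depth) / bg_depth        (0 if bg_depth == 0)

NF is depth-independent, 0 for uniform coverage and 1 when the NDR is fully
depleted while the background retains coverage.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import FragmentSet

logger = logging.getLogger(__name__)

NDR_UPSTREAM = 150
NDR_DOWNSTREAM = 50
BACKGROUND_FLANK = 2000


def ndr_interval(position: int, strand: str,
                 upstream: int = NDR_UPSTREAM,
                 downstream: int = NDR_DOWNSTREAM) -> tuple[int, int]:
    """Half-open genomic NDR window for a TSS, mirrored on the minus strand."""
    if strand == "+":
        return position - upstream, position + downstream
    # exact mirror of [-upstream, +downstream) around the TSS
    return position - downstream + 1, position + upstream + 1


def _overlap_sum(starts: np.ndarray, ends: np.ndarray, a: int, b: int) -> int:
    """Total overlapped bases between fragments and the window [a, b)."""
    return int(
        np.maximum(
            0, np.minimum(ends, b) - np.maximum(starts, a)
        ).sum()
    )


@dataclass
class NFProfile:
    """Per-gene NF scores with the raw NDR/background mean depths."""

    sample_id: str
    table: pd.DataFrame  # gene_id, nf, ndr_depth, bg_depth

    @property
    def scores(self) -> pd.Series:
        return self.table.set_index("gene_id")["nf"]


def nf_score(
    fragments: FragmentSet,
    genome,
    *,
    flank: int = BACKGROUND_FLANK,
    ndr_upstream: int = NDR_UPSTREAM,
    ndr_downstream: int = NDR_DOWNSTREAM,
) -> NFProfile:
    """Compute NF for every gene in ``genome.tss``.

    Genes whose +/-flank window extends past a chromosome end are skipped
    with a logged warning.  Depth is per-base fragment coverage (overlapped
    bases / region length); the background excludes the NDR interval.
    """
    tss = genome.tss
    # fragments sorted per chromosome for windowed candidate lookup
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, int]] = {}
    for chrom in np.unique(fragments.chrom):
        m = fragments.chrom == chrom
        s = fragments.start[m]
        order = np.argsort(s, kind="stable")
        starts = s[order]
        ends = fragments.end[m][order]
        max_len = int((ends - starts).max()) if len(starts) else 0
        by_chrom[str(chrom)] = (starts, ends, max_len)

    rows = []
    for gene, chrom, pos, strand in tss[["gene_id", "chrom", "position", "strand"]].itertuples(index=False):
        size = genome.lengths[chrom]
        w0, w1 = pos - flank, pos + flank
        if w0 < 0 or w1 > size:
            logger.warning("gene %s: TSS window off chromosome %s; skipped", gene, chrom)
            continue
        n0, n1 = ndr_interval(pos, strand, ndr_upstream, ndr_downstream)
        starts, ends, max_len = by_chrom.get(chrom, (np.empty(0), np.empty(0), 0))
        lo = np.searchsorted(starts, w0 - max_len)
        hi = np.searchsorted(starts, w1)
        s, e = starts[lo:hi], ends[lo:hi]
        bg_overlap = _overlap_sum(s, e, w0, w1)
        ndr_overlap = _overlap_sum(s, e, n0, n1)
        ndr_len = n1 - n0
        bg_len = (w1 - w0) - ndr_len
        ndr_depth = ndr_overlap / ndr_len
        bg_depth = (bg_overlap - ndr_overlap) / bg_len
        nf = (bg_depth - ndr_depth) / bg_depth if bg_depth > 0 else 0.0
        rows.append((gene, nf, ndr_depth, bg_depth))
    table = pd.DataFrame(rows, columns=["gene_id", "nf", "ndr_depth", "bg_depth"])
    return NFProfile(fragments.sample_id, table)
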