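"""5'-end 4-mer motif profiling.

Plasma cfDNA is cut by endogenous nucleases with sequence preferences, so
the first four reference bases at each fragment's 5' terminus carry a
tissue-of-origin signal.  Each double-stranded fragment contributes two 5'
ends: the plus-strand end (reference bases ``[start, start+4)``) and the
minus-strand end (reverse complement of ``[end-4, end)``).  The per-sample
profile is the frequency vector over the 256 possible 4-mers.
"""
from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np

from .core import FragmentSet

BASES = "ACGT"
MOTIF_K = 4


def enumerate_motifs(k: int = MOTIF_K) -> list[str]:
    """All 4**k k-mers over {A,C,G,T} in lexicographic order (stable)."""
    return ["".join(p) for p in itertools.product(BASES, repeat=k)]


MOTIFS: tuple[str, ...] = tuple(enumerate_motifs())
MOTIF_INDEX: dict[str, int] = {m: i for i, m in enumerate(MOTIFS)}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class MotifProfile:
    """256-dimensional 5'-end motif frequency vector for one sample."""

    sample_id: str
    frequencies: np.ndarray
    n_ends_counted: int

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if self.frequencies.shape != (len(MOTIFS),):
            raise ValueError("motif frequency vector must have length 256")

    @property
    def is_empty(self) -> bool:
        return self.n_ends_counted == 0


def _end_motif_indices(codes: np.ndarray, starts: np.ndarray,
                       ends: np.ndarray) -> np.ndarray:
    """Valid motif indices for both 5' ends of each fragment on one chromosome.

    Ends whose 4-mer window runs off the chromosome or touches a non-ACGT
    base are skipped.
    """
    n = len(codes)
    out = []
    ok5 = starts + MOTIF_K <= n
    s = starts[ok5]
    if len(s):
        c0, c1, c2, c3 = codes[s], codes[s + 1], codes[s + 2], codes[s + 3]
        good = (c0 < 4) & (c1 < 4) & (c2 < 4) & (c3 < 4)
        idx = ((c0.astype(np.int64) * 4 + c1) * 4 + c2) * 4 + c3
        out.append(idx[good])
    ok3 = ends - MOTIF_K >= 0
    e = ends[ok3]
    if len(e):
        c0, c1, c2, c3 = codes[e - 1], codes[e - 2], codes[e - 3], codes[e - 4]
        good = (c0 < 4) & (c1 < 4) & (c2 < 4) & (c3 < 4)
        # reverse complement read 3'->5' on the plus strand
        idx = (((3 - c0.astype(np.int64)) * 4 + (3 - c1)) * 4 + (3 - c2)) * 4 + (3 - c3)
        out.append(idx[good])
    if not out:
        return np.empty(0, dtype=np.int64)
    return np.concatenate(out)


def motif_profile(fragments: FragmentSet, genome) -> MotifProfile:
    """Count the 4-mer at both 5' termini of every fragment.

    An empty fragment set yields an all-zero, flagged profile
    (``n_ends_counted == 0``).
    """
    counts = np.zeros(len(MOTIFS), dtype=np.int64)
    if len(fragments) == 0:
        warnings.warn(f"empty fragment set for {fragments.sample_id}; "
                      "motif profile is all-zero", stacklevel=2)
        return MotifProfile(fragments.sample_id, counts.astype(float), 0)
    for chrom in np.unique(fragments.chrom):
        mask = fragments.chrom == chrom
        codes = genome.sequence[str(chrom)]
        idx = _end_motif_indices(codes, fragments.start[mask], fragments.end[mask])
        counts += np.bincount(idx, minlength=len(MOTIFS)).astype(np.int64)
    total = int(counts.sum())
    freq = counts / total if total else counts.astype(float)
    return MotifProfile(fragments.sample_id, freq, total)
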