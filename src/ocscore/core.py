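"""Shared containers: aligned cfDNA fragments and per-sample collections.

Coordinates are 0-based half-open throughout the package, matching BED.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

HEALTHY = "HC"
TUMOR = "OC"
LABELS = (HEALTHY, TUMOR)


class OcscoreError(Exception):
    """Base class for package errors."""


class ConfigurationError(OcscoreError):
    """A simulation or pipeline configuration is internally inconsistent."""


@dataclass
class FragmentSet:
    """One sample's aligned cfDNA fragment population.

    Parameters
    ----------
    sample_id : str
        Cohort-unique identifier.
    label : str
        Class label, ``"HC"`` (healthy control) or ``"OC"`` (ovarian cancer).
    chrom, start, end : ndarray
        Parallel per-fragment arrays; ``start < end``, 0-based half-open.
    """

    sample_id: str
    label: str
    chrom: np.ndarray
    start: np.ndarray
    end: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")
        self.chrom = np.asarray(self.chrom)
        self.start = np.asarray(self.start, dtype=np.int64)
        self.end = np.asarray(self.end, dtype=np.int64)
        if not (len(self.chrom) == len(self.start) == len(self.end)):
            raise ValueError("chrom/start/end arrays must have equal length")
        if len(self.start):
            if self.start.min() < 0:
                raise ValueError("negative fragment coordinate")
            if np.any(self.start >= self.end):
                raise ValueError("every fragment must satisfy start < end")

    def __len__(self) -> int:
        return len(self.start)

    @property
    def lengths(self) -> np.ndarray:
        return self.end - self.start

    def validate_against(self, genome) -> None:
        """Check every fragment lies inside a chromosome of *genome*."""
        for name in np.unique(self.chrom):
            if str(name) not in genome.lengths:
                raise ValueError(f"unknown chromosome {name!r}")
            mask = self.chrom == name
            if np.any(self.end[mask] > genome.lengths[str(name)]):
                raise ValueError(f"fragment extends past end of {name}")

    def sorted(self) -> "FragmentSet":
        order = np.lexsort((self.start, self.chrom))
        return FragmentSet(
            self.sample_id,
            self.label,
            self.chrom[order],
            self.start[order],
            self.end[order],
            dict(self.meta),
        )
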