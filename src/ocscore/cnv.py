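"""Copy-number calling against a healthy baseline panel.

Low-pass WGS depth is summarized in 2-kb windows, GC-corrected, and
normalized to mean 1 per sample.  A baseline panel records each window's
mean and standard deviation across healthy training samples; per-window
z-scores against the panel flag significant windows (|z| > 3), which are
merged into same-sign runs (tolerating short gaps) and reported as CNV
segments when they span more than 2 Mb.  The scalar burden score is

    cnv_score = sum over segments of |mean_z| * span_Mb / 100

which is 0 exactly when no segment is called and grows with both the
amplitude and the extent of the aberration.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import FragmentSet
from .fragmentation import BinScheme, make_bins
from .simulate import GC_WINDOW

Z_THRESHOLD = 3.0
GAP_TOLERANCE = 10         # non-significant windows bridged inside a run;
                           # matches the depth-smoothing correlation length
MIN_SEGMENT_SPAN = 2_000_000
SCORE_SCALE = 100.0
SIGMA_FLOOR_FRAC = 0.03    # relative sigma floor for the baseline panel
SIGMA_FLOOR_ABS = 1e-3
MIN_PANEL_SIZE = 5
MIN_DECILE_WINDOWS = 10


@dataclass
class DepthVector:
    """Per-2-kb-window fragment counts and normalized (mean-1) depth."""

    raw: np.ndarray
    corrected: np.ndarray
    scheme: BinScheme

    def __len__(self) -> int:
        return len(self.raw)


def depth_windows(genome) -> BinScheme:
    """The 2-kb window scheme shared with the genome's GC track."""
    return make_bins(genome, GC_WINDOW)


def window_depth(fragments: FragmentSet, genome) -> DepthVector:
    """Count fragments per 2-kb window (midpoint rule), normalized to mean 1."""
    scheme = depth_windows(genome)
    mid = (fragments.start + fragments.end) // 2
    idx = scheme.assign(fragments.chrom, mid)
    if np.any(idx < 0):
        raise ValueError("fragment midpoint outside the genome window scheme")
    raw = np.bincount(idx, minlength=len(scheme)).astype(float)
    mean = raw.mean()
    corrected = raw / mean if mean > 0 else raw.copy()
    return DepthVector(raw, corrected, scheme)


def gc_correct(depth: DepthVector, gc_track: np.ndarray) -> DepthVector:
    """Divide each window's depth by its GC-decile median, renormalize to mean 1.

    Windows are grouped into GC deciles; deciles holding fewer than 10
    windows are merged with a neighbor.  A decile whose median depth is 0
    (possible at very low coverage) falls back to its mean; if that is also
    0 the decile is left uncorrected.
    """
    gc = np.asarray(gc_track, dtype=float)
    if len(gc) != len(depth):
        raise ValueError("gc_track length does not match window count")
    d = depth.corrected
    if not np.any(d > 0):
        raise ValueError("all-zero depth vector; sample unusable")

    edges = np.quantile(gc, np.linspace(0, 1, 11))
    edges[0], edges[-1] = -np.inf, np.inf
    group = np.clip(np.searchsorted(edges, gc, side="right") - 1, 0, 9)
    # merge deciles with too few windows into their left (else right) neighbor
    labels = sorted(set(group))
    merged = {g: g for g in labels}
    counts = {g: int((group == g).sum()) for g in labels}
    for i, g in enumerate(labels):
        if counts[g] < MIN_DECILE_WINDOWS and len(labels) > 1:
            target = labels[i - 1] if i > 0 else labels[i + 1]
            merged[g] = merged.get(target, target)
            counts[target] = counts.get(target, 0) + counts[g]
    group = np.array([merged[g] for g in group])

    out = d.copy()
    for g in np.unique(group):
        m = group == g
        med = np.median(d[m])
        if med <= 0:
            med = d[m].mean()
        if med > 0:
            out[m] = d[m] / med
    out = out / out.mean()
    return DepthVector(depth.raw, out, depth.scheme)


SMOOTH_WINDOWS = 10


def smooth_depth(depth: DepthVector, k: int = SMOOTH_WINDOWS) -> DepthVector:
    """Rolling-mean smoothing of corrected depth over k windows per chromosome.

    Single-window counts at low-pass depth are Poisson-noisy; averaging k
    adjacent windows (20 kb by default) trades ~k/2 windows of segment
    boundary resolution for a sqrt(k) noise reduction.  Apply the same
    smoothing to panel samples and test samples.  ``k <= 1`` is a no-op.
    """
    if k <= 1:
        return depth
    out = depth.corrected.copy()
    kernel = np.ones(k) / k
    scheme = depth.scheme
    for chrom in dict.fromkeys(scheme.chrom):
        m = scheme.chrom == chrom
        d = depth.corrected[m]
        if len(d) >= k:
            out[m] = np.convolve(np.pad(d, (k // 2, k - 1 - k // 2), mode="edge"),
                                 kernel, mode="valid")
    out = out / out.mean()
    return DepthVector(depth.raw, out, scheme)


@dataclass
class BaselinePanel:
    """Per-window mean/sd of corrected depth across healthy samples."""

    mu: np.ndarray
    sigma: np.ndarray
    n_panel: int


def build_baseline(depth_matrix: np.ndarray) -> BaselinePanel:
    """Panel statistics from a (samples x windows) corrected-depth matrix.

    Requires at least 5 healthy samples.  Sigma is floored at
    ``max(observed sd, 0.03 * mu, 1e-3)`` so that z-scores stay bounded in
    windows where the panel happens to be near-constant.
    """
    mat = np.asarray(depth_matrix, dtype=float)
    if mat.ndim != 2 or mat.shape[0] < MIN_PANEL_SIZE:
        raise ValueError(f"baseline panel needs >= {MIN_PANEL_SIZE} healthy samples")
    mu = mat.mean(axis=0)
    sd = mat.std(axis=0, ddof=1)
    sigma = np.maximum.reduce([sd, SIGMA_FLOOR_FRAC * mu,
                               np.full_like(mu, SIGMA_FLOOR_ABS)])
    return BaselinePanel(mu, sigma, mat.shape[0])


@dataclass
class CNVCall:
    """Called segments (>2 Mb, disjoint) and the scalar burden score."""

    segments: list[tuple[str, int, int, float, str]]  # chrom, start, end, mean_z, direction
    cnv_score: float
    z: np.ndarray


def _runs_with_gaps(sig_idx: np.ndarray, opposite: np.ndarray,
                    gap: int) -> list[tuple[int, int]]:
    """Merge sorted significant indices into runs bridging <= gap windows,
    never bridging across an opposite-sign significant window."""
    runs = []
    start = prev = int(sig_idx[0])
    for i in sig_idx[1:]:
        i = int(i)
        bridged = i - prev - 1
        if bridged <= gap and not opposite[prev + 1:i].any():
            prev = i
        else:
            runs.append((start, prev))
            start = prev = i
    runs.append((start, prev))
    return runs


def call_cnv(
    sample: DepthVector,
    panel: BaselinePanel,
    *,
    z_threshold: float = Z_THRESHOLD,
    gap_tolerance: int = GAP_TOLERANCE,
    min_span: int = MIN_SEGMENT_SPAN,
) -> CNVCall:
    """Call CNV segments for one sample against the baseline panel."""
    if len(sample.corrected) != len(panel.mu):
        raise ValueError("sample and panel use different window schemes")
    z = (sample.corrected - panel.mu) / panel.sigma
    # robust re-centering: mean-1 depth normalization shifts copy-neutral
    # windows whenever an aberration occupies a non-trivial genome fraction;
    # the genome-wide median z restores the neutral baseline to 0
    z = z - np.median(z)
    scheme = sample.scheme
    segments = []
    score = 0.0
    offsets = scheme.chrom_offsets()
    for chrom, first in offsets.items():
        m = scheme.chrom == chrom
        zc = z[m]
        gain = zc > z_threshold
        loss = zc < -z_threshold
        for sig, opposite, direction in ((gain, loss, "gain"), (loss, gain, "loss")):
            idx = np.flatnonzero(sig)
            if len(idx) == 0:
                continue
            for a, b in _runs_with_gaps(idx, opposite, gap_tolerance):
                start = int(scheme.start[first + a])
                end = int(scheme.end[first + b])
                if end - start <= min_span:
                    continue
                mean_z = float(zc[a:b + 1].mean())
                segments.append((chrom, start, end, mean_z, direction))
                score += abs(mean_z) * ((end - start) / 1e6) / SCORE_SCALE
    segments.sort(key=lambda s: (s[0], s[1]))
    return CNVCall(segments, float(score), z)
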