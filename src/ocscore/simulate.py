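"""Synthetic cfDNA cohort generator.

Builds a toy reference genome — chromosome sequences with a drifting GC
composition, strand-annotated transcription start sites (TSSs), planted
multi-megabase copy-number segments, promoter nucleosome-depletion
alterations and class-specific 4-mer cleavage preferences — and draws
per-sample fragment populations with the statistical structure the feature
extractors assume of plasma cfDNA:

* a healthy fragment-length law peaked at 167 bp (chromatosome peak) with
  the ~10.4-bp sub-peak ladder and a di-nucleosome shoulder at 334 bp;
* a shorter tumor length law (mode 150 bp);
* fragment placement weighted by nucleosome occupancy around TSSs, with
  reduced protection over the nucleosome-depleted region (NDR) of altered
  genes in the tumor class;
* tumor-class cut sites re-weighted by the genomic 4-mer at each 5' end;
* tumor-class sampling rates multiplied by the planted copy ratio inside
  truth CNV segments.

A cancer sample is a mixture: a fraction ``f`` (the tumor fraction) of
fragments follows the tumor law, the rest the healthy law.  Everything is
deterministic for a fixed seed.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

from .core import HEALTHY, TUMOR, ConfigurationError, FragmentSet

GC_WINDOW = 2000  # bp; also the CNV depth window
_BASES = "ACGT"
_MIN_CNV_SPAN = 2_000_000


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class LengthLaw:
    """Discretized fragment-length distribution.

    Two Gaussian components (mono- and di-nucleosome) on integer lengths,
    with a cosine "ladder" modulation of period ~10.4 bp applied at and
    below the mono-nucleosome mode, reproducing the sub-peak ladder of real
    cfDNA and giving the law a sharply defined 1-bp mode.
    """

    mono_mode: int = 167
    mono_sd: float = 12.0
    di_mode: int = 334
    di_sd: float = 25.0
    di_weight: float = 0.15
    ladder_period: float = 10.4
    ladder_amplitude: float = 0.6
    min_length: int = 60
    max_length: int = 600

    def pmf(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (lengths, probabilities) over the integer support."""
        L = np.arange(self.min_length, self.max_length + 1)
        base = (1.0 - self.di_weight) * norm.pdf(L, self.mono_mode, self.mono_sd)
        base = base + self.di_weight * norm.pdf(L, self.di_mode, self.di_sd)
        ladder = np.where(
            L <= self.mono_mode,
            1.0 + self.ladder_amplitude
            * np.cos(2.0 * np.pi * (L - self.mono_mode) / self.ladder_period),
            1.0,
        )
        p = base * ladder
        return L, p / p.sum()


#: default healthy-class length law (mode 167 bp)
HEALTHY_LAW = LengthLaw()
#: default tumor-class length law (shorter; mode 150 bp)
TUMOR_LAW = LengthLaw(mono_mode=150, di_mode=300)

_DEFAULT_CHROMS = (("chr1", 30_000_000), ("chr2", 30_000_000), ("chr3", 30_000_000))
_DEFAULT_CNV = (
    ("chr1", 10_000_000, 15_000_000, 1.5),
    ("chr2", 5_000_000, 8_000_000, 0.6),
)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for a synthetic cohort.

    The defaults are the package's reference conditions: 100 healthy
    controls and 59 cancer cases on a 3 x 30 Mb toy genome at ~0.55x
    genome-equivalent depth (300k fragments/sample), tumor fraction 0.3.
    """

    n_healthy: int = 100
    n_tumor: int = 59
    fragments_per_sample: int = 300_000
    tumor_fraction: float = 0.3
    healthy_law: LengthLaw = HEALTHY_LAW
    tumor_law: LengthLaw = TUMOR_LAW
    # genome
    chrom_lengths: tuple[tuple[str, int], ...] = _DEFAULT_CHROMS
    tss_per_chrom: int = 100
    gc_mean: float = 0.41
    gc_sd: float = 0.05
    # nucleosome model
    nucleosome_period: float = 190.0
    nucleosome_amplitude: float = 0.25
    ndr_floor: float = 0.5
    ndr_upstream: int = 150
    ndr_downstream: int = 50
    tss_window: int = 2000
    n_ndr_altered: int = 40
    ndr_depletion: float = 0.9
    # motif bias (tumor class)
    n_motifs_up: int = 16
    n_motifs_down: int = 16
    motif_weight_up: float = 1.3
    motif_weight_down: float = 0.75
    # planted CNV truth: (chrom, start, end, copy_ratio)
    cnv_segments: tuple[tuple[str, int, int, float], ...] = _DEFAULT_CNV
    # cohort bookkeeping
    train_fraction_oc: float = 2.0 / 3.0
    train_fraction_hc: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_healthy <= 0 or self.n_tumor <= 0 or self.fragments_per_sample <= 0:
            raise ConfigurationError("sample and fragment counts must be positive")
        if not 0.0 <= self.tumor_fraction <= 1.0:
            raise ConfigurationError("tumor_fraction must lie in [0, 1]")
        lengths = dict(self.chrom_lengths)
        for name, size in lengths.items():
            if size < 2 * _MIN_CNV_SPAN:
                raise ConfigurationError(
                    f"chromosome {name} ({size} bp) is shorter than twice the "
                    f"minimum CNV span ({_MIN_CNV_SPAN} bp)"
                )
        seen: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end, ratio in self.cnv_segments:
            if chrom not in lengths:
                raise ConfigurationError(f"CNV segment on unknown chromosome {chrom}")
            if not 0 <= start < end <= lengths[chrom]:
                raise ConfigurationError("CNV segment outside chromosome")
            if end - start < _MIN_CNV_SPAN:
                raise ConfigurationError("planted CNV segments must span >= 2 Mb")
            if ratio <= 0:
                raise ConfigurationError("copy_ratio must be positive")
            for a, b in seen.setdefault(chrom, []):
                if start < b and a < end:
                    raise ConfigurationError("planted CNV segments must be disjoint")
            seen[chrom].append((start, end))

    def with_(self, **kw) -> "SimulationConfig":
        return replace(self, **kw)


# --------------------------------------------------------------------------
# genome
# --------------------------------------------------------------------------

@dataclass
class CNVSegment:
    chrom: str
    start: int
    end: int
    copy_ratio: float


@dataclass
class GenomeTruth:
    """Machine-readable record of everything planted in a toy genome."""

    cnv_segments: tuple[CNVSegment, ...]
    ndr_altered: dict[str, float]          # gene_id -> depletion depth in [0, 1]
    motif_bias: dict[str, dict[str, float]]  # class label -> {4-mer: weight}

    def to_dict(self) -> dict:
        return {
            "cnv_segments": [
                {"chrom": s.chrom, "start": s.start, "end": s.end,
                 "copy_ratio": s.copy_ratio}
                for s in self.cnv_segments
            ],
            "ndr_altered": dict(self.ndr_altered),
            "motif_bias": {k: dict(v) for k, v in self.motif_bias.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GenomeTruth":
        return cls(
            tuple(CNVSegment(**s) for s in d["cnv_segments"]),
            dict(d["ndr_altered"]),
            {k: dict(v) for k, v in d["motif_bias"].items()},
        )


@dataclass(eq=False)
class ToyGenome:
    """Synthetic reference genome.

    ``sequence`` holds per-chromosome base codes (A=0, C=1, G=2, T=3) as
    uint8 arrays; ``gc_track`` the realized GC fraction of each 2-kb window
    (last window of a chromosome may be shorter); ``tss`` a table with
    columns gene_id/chrom/position/strand; ``truth`` the planted signal
    (absent for genomes loaded from plain reference files).
    """

    chrom_names: tuple[str, ...]
    lengths: dict[str, int]
    sequence: dict[str, np.ndarray]
    tss: pd.DataFrame
    gc_track: dict[str, np.ndarray]
    truth: GenomeTruth | None = None

    @property
    def total_length(self) -> int:
        return sum(self.lengths.values())

    def offsets(self) -> np.ndarray:
        """Cumulative start offset of each chromosome in genome order."""
        sizes = [self.lengths[c] for c in self.chrom_names]
        return np.concatenate([[0], np.cumsum(sizes)])

    def sequence_str(self, chrom: str, start: int | None = None,
                     end: int | None = None) -> str:
        codes = self.sequence[chrom][start:end]
        return "".join(_BASES[c] if c < 4 else "N" for c in codes)

    def gc_concat(self) -> np.ndarray:
        return np.concatenate([self.gc_track[c] for c in self.chrom_names])

    def n_windows(self) -> int:
        return int(sum(math.ceil(self.lengths[c] / GC_WINDOW) for c in self.chrom_names))


def gc_fraction_by_window(codes: np.ndarray, window: int = GC_WINDOW) -> np.ndarray:
    """GC fraction per *window*-bp tile of a coded sequence (vectorized)."""
    n = len(codes)
    gc = ((codes == 1) | (codes == 2)).astype(np.int64)
    edges = np.arange(0, n, window)
    sums = np.add.reduceat(gc, edges)
    sizes = np.minimum(edges + window, n) - edges
    return sums / sizes


def _genome_rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0,)))


def _sample_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(1, index)))


def build_toy_genome(config: SimulationConfig) -> ToyGenome:
    """Generate a seeded toy genome satisfying the documented invariants.

    Deterministic for a fixed ``config.seed``: running twice yields
    byte-identical sequences and truth sets.
    """
    config.validate()
    rng = _genome_rng(config.seed)
    chrom_names = tuple(name for name, _ in config.chrom_lengths)
    lengths = dict(config.chrom_lengths)

    sequence: dict[str, np.ndarray] = {}
    gc_track: dict[str, np.ndarray] = {}
    for name in chrom_names:
        size = lengths[name]
        n_win = math.ceil(size / GC_WINDOW)
        # smooth window-level GC target, then iid bases within windows
        raw = rng.normal(config.gc_mean, config.gc_sd, n_win + 8)
        kernel = np.ones(9) / 9.0
        target = np.convolve(raw, kernel, mode="valid")[:n_win]
        target = np.clip(target, 0.25, 0.65)
        per_base_gc = np.repeat(target, GC_WINDOW)[:size]
        u = rng.random(size)
        c_a = (1.0 - per_base_gc) / 2.0       # cum at end of A
        c_g = 0.5 + per_base_gc / 2.0         # cum at end of G (C ends at 0.5)
        codes = ((u >= c_a).astype(np.uint8) + (u >= 0.5) + (u >= c_g)).astype(np.uint8)
        sequence[name] = codes
        gc_track[name] = gc_fraction_by_window(codes)

    # TSS table: evenly spaced with jitter, >= tss_window from both ends
    margin = config.tss_window
    rows = []
    gene_no = 0
    for name in chrom_names:
        size = lengths[name]
        n = config.tss_per_chrom
        spacing = (size - 2 * margin) / (n + 1)
        base_pos = margin + spacing * (np.arange(n) + 1)
        jitter = rng.uniform(-0.3 * spacing, 0.3 * spacing, n)
        pos = np.clip((base_pos + jitter).astype(np.int64), margin, size - margin - 1)
        pos = np.sort(pos)
        strands = rng.choice(["+", "-"], n)
        for p, s in zip(pos, strands):
            gene_no += 1
            rows.append((f"gene_{gene_no:04d}", name, int(p), s))
    tss = pd.DataFrame(rows, columns=["gene_id", "chrom", "position", "strand"])

    # planted truth
    segments = tuple(
        CNVSegment(chrom, int(start), int(end), float(ratio))
        for chrom, start, end, ratio in config.cnv_segments
    )
    n_alt = min(config.n_ndr_altered, len(tss))
    altered_idx = rng.choice(len(tss), size=n_alt, replace=False)
    ndr_altered = {
        tss.iloc[i]["gene_id"]: float(config.ndr_depletion)
        for i in sorted(altered_idx)
    }
    from .motifs import MOTIFS  # local import to avoid a cycle
    n_bias = config.n_motifs_up + config.n_motifs_down
    bias_idx = rng.choice(len(MOTIFS), size=n_bias, replace=False)
    oc_bias = {MOTIFS[i]: config.motif_weight_up for i in bias_idx[: config.n_motifs_up]}
    oc_bias.update(
        {MOTIFS[i]: config.motif_weight_down for i in bias_idx[config.n_motifs_up:]}
    )
    truth = GenomeTruth(segments, ndr_altered, {HEALTHY: {}, TUMOR: oc_bias})
    return ToyGenome(chrom_names, lengths, sequence, tss, gc_track, truth)


# --------------------------------------------------------------------------
# fragment sampling
# --------------------------------------------------------------------------

class FragmentSimulator:
    """Vectorized rejection sampler for per-sample fragment populations.

    Precomputes global (concatenated-genome) lookup arrays once; reuse one
    instance across a cohort.
    """

    def __init__(self, genome: ToyGenome, config: SimulationConfig):
        if genome.truth is None:
            raise ConfigurationError("simulation requires a genome with a truth set")
        self.genome = genome
        self.config = config
        self.offsets = genome.offsets()
        self.total_len = int(self.offsets[-1])
        self.seq = np.concatenate([genome.sequence[c] for c in genome.chrom_names])

        # TSS lookup (global coordinates, sorted)
        tss = genome.tss
        chrom_off = {c: int(o) for c, o in zip(genome.chrom_names, self.offsets[:-1])}
        gpos = tss["position"].to_numpy() + np.array(
            [chrom_off[c] for c in tss["chrom"]], dtype=np.int64
        )
        order = np.argsort(gpos)
        self.tss_gpos = gpos[order]
        self.tss_strand = np.where(tss["strand"].to_numpy()[order] == "+", 1, -1)
        depl = np.array(
            [genome.truth.ndr_altered.get(g, 0.0) for g in tss["gene_id"]],
            dtype=float,
        )
        self.tss_depl = depl[order]

        # per-2kb-window copy ratio (tumor law)
        win_sizes = [math.ceil(genome.lengths[c] / GC_WINDOW) for c in genome.chrom_names]
        self.win_offsets = np.concatenate([[0], np.cumsum(win_sizes)])
        ratio = np.ones(int(self.win_offsets[-1]))
        for seg in genome.truth.cnv_segments:
            ci = genome.chrom_names.index(seg.chrom)
            w0 = self.win_offsets[ci] + seg.start // GC_WINDOW
            w1 = self.win_offsets[ci] + math.ceil(seg.end / GC_WINDOW)
            ratio[w0:w1] = seg.copy_ratio
        self.win_ratio = ratio
        self.max_ratio = float(ratio.max())

        # 4-mer cleavage weights per class
        from .motifs import MOTIF_INDEX
        w = np.ones(256)
        for motif, weight in genome.truth.motif_bias.get(TUMOR, {}).items():
            w[MOTIF_INDEX[motif]] = weight
        self.motif_w = w
        self.max_motif_w = float(w.max())

        for law_name in ("healthy_law", "tumor_law"):
            law: LengthLaw = getattr(config, law_name)
            vals, p = law.pmf()
            setattr(self, "_" + law_name, (vals, np.cumsum(p)))

    # -- internals ---------------------------------------------------------

    def _draw_lengths(self, law, u: np.ndarray) -> np.ndarray:
        vals, cum = law
        return vals[np.minimum(np.searchsorted(cum, u), len(vals) - 1)]

    def _occupancy(self, gmid: np.ndarray, tumor: np.ndarray) -> np.ndarray:
        """Nucleosome occupancy (protection) at fragment midpoints."""
        cfg = self.config
        if len(self.tss_gpos) == 0:
            return np.ones(len(gmid))
        j = np.searchsorted(self.tss_gpos, gmid)
        left = np.clip(j - 1, 0, len(self.tss_gpos) - 1)
        right = np.clip(j, 0, len(self.tss_gpos) - 1)
        d_left = np.abs(gmid - self.tss_gpos[left])
        d_right = np.abs(gmid - self.tss_gpos[right])
        k = np.where(d_left <= d_right, left, right)
        d = gmid - self.tss_gpos[k]
        inside = np.abs(d) < cfg.tss_window
        x = self.tss_strand[k] * d  # TSS-relative, strand-aware
        occ = 1.0 + cfg.nucleosome_amplitude * np.cos(
            2.0 * np.pi * x / cfg.nucleosome_period
        )
        in_ndr = (x >= -cfg.ndr_upstream) & (x < cfg.ndr_downstream)
        occ = np.where(in_ndr, cfg.ndr_floor, occ)
        altered = in_ndr & tumor & (self.tss_depl[k] > 0)
        occ = np.where(altered, cfg.ndr_floor * (1.0 - self.tss_depl[k]), occ)
        return np.where(inside, occ, 1.0)

    def _window_index(self, gpos: np.ndarray, ci: np.ndarray) -> np.ndarray:
        local = gpos - self.offsets[ci]
        return self.win_offsets[ci] + local // GC_WINDOW

    def _motif_weight(self, gstart: np.ndarray, gend: np.ndarray) -> np.ndarray:
        seq = self.seq
        s = np.clip(gstart, 0, self.total_len - 4)
        e = np.clip(gend, 4, self.total_len)
        idx5 = (((seq[s] * 4 + seq[s + 1]) * 4 + seq[s + 2]) * 4 + seq[s + 3]).astype(int)
        idx3 = (
            ((3 - seq[e - 1]) * 4 + (3 - seq[e - 2])) * 4 + (3 - seq[e - 3])
        ) * 4 + (3 - seq[e - 4])
        return self.motif_w[idx5] * self.motif_w[idx3.astype(int)]

    # -- public ------------------------------------------------------------

    def sample(
        self,
        sample_id: str,
        label: str,
        rng: np.random.Generator,
        n_fragments: int | None = None,
        tumor_fraction: float | None = None,
    ) -> FragmentSet:
        """Draw one sample; OC samples mix tumor-law fragments at fraction f.

        Fragments that would extend past a chromosome end are resampled,
        never clipped.
        """
        cfg = self.config
        n = cfg.fragments_per_sample if n_fragments is None else int(n_fragments)
        f = cfg.tumor_fraction if tumor_fraction is None else float(tumor_fraction)
        if label not in (HEALTHY, TUMOR):
            raise ValueError(f"label must be HC or OC, got {label!r}")
        is_oc = label == TUMOR and f > 0.0

        wmax = 1.0 + cfg.nucleosome_amplitude
        if is_oc:
            wmax *= self.max_ratio * self.max_motif_w**2

        out_start = np.empty(n, dtype=np.int64)
        out_len = np.empty(n, dtype=np.int64)
        filled = 0
        while filled < n:
            m = min(int((n - filled) * 1.7) + 32, 4_000_000)
            tumor = rng.random(m) < f if is_oc else np.zeros(m, dtype=bool)
            u = rng.random(m)
            L = self._draw_lengths(self._healthy_law, u)
            if is_oc:
                L = np.where(tumor, self._draw_lengths(self._tumor_law, u), L)
            s = rng.integers(0, self.total_len, m)
            e = s + L
            ci = np.searchsorted(self.offsets, s, side="right") - 1
            valid = e <= self.offsets[ci + 1]
            mid = s + L // 2
            w = self._occupancy(np.where(valid, mid, 0), tumor)
            if is_oc:
                widx = self._window_index(np.where(valid, mid, 0), ci)
                w = w * np.where(tumor, self.win_ratio[widx], 1.0)
                mw = self._motif_weight(s, e)
                w = w * np.where(tumor, mw, 1.0)
            accept = valid & (rng.random(m) * wmax < w)
            n_acc = min(int(accept.sum()), n - filled)
            idx = np.flatnonzero(accept)[:n_acc]
            out_start[filled:filled + n_acc] = s[idx]
            out_len[filled:filled + n_acc] = L[idx]
            filled += n_acc

        order = np.argsort(out_start, kind="stable")
        gs = out_start[order]
        gl = out_len[order]
        ci = np.searchsorted(self.offsets, gs, side="right") - 1
        local = gs - self.offsets[ci]
        chrom = np.array(self.genome.chrom_names, dtype=object)[ci]
        return FragmentSet(sample_id, label, chrom, local, local + gl,
                           meta={"tumor_fraction": f if label == TUMOR else 0.0})


def simulate_sample(
    genome: ToyGenome,
    label: str,
    config: SimulationConfig,
    seed: int | np.random.Generator = 0,
    *,
    sample_id: str | None = None,
    n_fragments: int | None = None,
    tumor_fraction: float | None = None,
) -> FragmentSet:
    """Convenience wrapper drawing a single sample (see FragmentSimulator)."""
    sim = FragmentSimulator(genome, config)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if sample_id is None:
        sample_id = f"{label}_sample"
    return sim.sample(sample_id, label, rng, n_fragments, tumor_fraction)


# --------------------------------------------------------------------------
# cohorts
# --------------------------------------------------------------------------

@dataclass
class Cohort:
    """A simulated cohort: manifest plus (optionally) in-memory fragments."""

    genome: ToyGenome
    config: SimulationConfig
    manifest: pd.DataFrame                      # sample_id, label, split, tumor_fraction, seed_index
    fragment_sets: list[FragmentSet] | None = None

    def iter_fragments(self):
        """Yield FragmentSets in manifest order, simulating lazily if needed."""
        if self.fragment_sets is not None:
            yield from self.fragment_sets
            return
        sim = FragmentSimulator(self.genome, self.config)
        for row in self.manifest.itertuples():
            rng = _sample_rng(self.config.seed, int(row.seed_index))
            yield sim.sample(row.sample_id, row.label, rng,
                             tumor_fraction=float(row.tumor_fraction))


def cohort_manifest(config: SimulationConfig) -> pd.DataFrame:
    """Deterministic manifest: ids, labels, per-sample tumor fraction, split.

    The train split takes ``ceil(train_fraction_oc * n_tumor)`` cancer cases
    (2/3 by default) and ``round(train_fraction_hc * n_healthy)`` controls,
    assigned by a seeded random partition.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(2,)))
    ids, labels = [], []
    for i in range(config.n_healthy):
        ids.append(f"HC_{i + 1:04d}")
        labels.append(HEALTHY)
    for i in range(config.n_tumor):
        ids.append(f"OC_{i + 1:04d}")
        labels.append(TUMOR)
    n_oc_train = math.ceil(config.train_fraction_oc * config.n_tumor)
    n_hc_train = round(config.train_fraction_hc * config.n_healthy)
    split = np.array(["test"] * len(ids), dtype=object)
    hc_idx = rng.permutation(config.n_healthy)[:n_hc_train]
    oc_idx = config.n_healthy + rng.permutation(config.n_tumor)[:n_oc_train]
    split[hc_idx] = "train"
    split[oc_idx] = "train"
    tf = [0.0 if lab == HEALTHY else config.tumor_fraction for lab in labels]
    return pd.DataFrame(
        {
            "sample_id": ids,
            "label": labels,
            "split": split,
            "tumor_fraction": tf,
            "seed_index": np.arange(len(ids)),
        }
    )


def simulate_cohort(
    genome: ToyGenome,
    config: SimulationConfig,
    outdir=None,
    *,
    overwrite: bool = False,
    keep_fragments: bool = True,
) -> Cohort:
    """Simulate the full cohort; optionally write BEDs, manifest and truth.

    With ``outdir`` set, writes one BED per sample, ``manifest.tsv`` and
    ``truth.json``; refuses to overwrite an existing manifest unless
    *overwrite* is given.  Byte-identical outputs for a fixed seed.
    """
    manifest = cohort_manifest(config)
    writer = None
    if outdir is not None:
        from . import io as _io
        from pathlib import Path
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        manifest_path = outdir / "manifest.tsv"
        if manifest_path.exists() and not overwrite:
            raise FileExistsError(
                f"{manifest_path} exists; pass overwrite=True to replace it"
            )
        _io.write_manifest(manifest, manifest_path)
        truth = {
            "genome": genome.truth.to_dict() if genome.truth else None,
            "samples": {
                r.sample_id: {"label": r.label, "tumor_fraction": float(r.tumor_fraction)}
                for r in manifest.itertuples()
            },
        }
        _io.write_truth(truth, outdir / "truth.json")
        writer = lambda fs: _io.write_fragments(fs, outdir / f"{fs.sample_id}.bed")

    cohort = Cohort(genome, config, manifest, fragment_sets=None)
    if keep_fragments or writer is not None:
        sets = []
        for fs in cohort.iter_fragments():
            if writer is not None:
                writer(fs)
            if keep_fragments:
                sets.append(fs)
        cohort.fragment_sets = sets if keep_fragments else None
    return cohort
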