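"""Shared test utilities: hand-built genomes and brute-force oracles."""
from __future__ import annotations

import numpy as np
import pandas as pd

from ocscore.core import FragmentSet
from ocscore.simulate import GenomeTruth, ToyGenome, gc_fraction_by_window

CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
BASES = "ACGT"


def genome_from_strings(seqs: dict[str, str], tss_rows=(), truth: GenomeTruth | None = None) -> ToyGenome:
    """ToyGenome from literal chromosome strings (supports N)."""
    sequence = {c: np.array([CODE[b] for b in s], dtype=np.uint8)
                for c, s in seqs.items()}
    lengths = {c: len(s) for c, s in seqs.items()}
    gc = {c: gc_fraction_by_window(sequence[c]) for c in seqs}
    tss = pd.DataFrame(list(tss_rows),
                       columns=["gene_id", "chrom", "position", "strand"])
    return ToyGenome(tuple(seqs), lengths, sequence, tss, gc, truth)


def genome_stub(lengths: dict[str, int]) -> ToyGenome:
    """Coordinate-only genome (no sequence) for binning tests."""
    tss = pd.DataFrame(columns=["gene_id", "chrom", "position", "strand"])
    return ToyGenome(tuple(lengths), dict(lengths), {}, tss, {}, None)


def fragments(chrom, starts, ends, sample_id="s1", label="HC") -> FragmentSet:
    starts = np.asarray(starts, dtype=np.int64)
    if np.isscalar(chrom) or isinstance(chrom, str):
        chrom = np.array([chrom] * len(starts), dtype=object)
    else:
        chrom = np.asarray(chrom, dtype=object)
    return FragmentSet(sample_id, label, chrom, starts,
                       np.asarray(ends, dtype=np.int64))


def random_sequence(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, n))


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

_RC = str.maketrans("ACGT", "TGCA")


def oracle_motif_counts(genome: ToyGenome, frags: FragmentSet) -> dict[str, int]:
    """Per-fragment substring recount of both 5'-end 4-mers (pure Python)."""
    counts: dict[str, int] = {}
    for c, s, e in zip(frags.chrom, frags.start, frags.end):
        seq = genome.sequence_str(str(c))
        plus = seq[s:s + 4]
        if len(plus) == 4 and all(b in "ACGT" for b in plus):
            counts[plus] = counts.get(plus, 0) + 1
        if e - 4 >= 0:
            minus = seq[e - 4:e].translate(_RC)[::-1]
            if len(minus) == 4 and all(b in "ACGT" for b in minus):
                counts[minus] = counts.get(minus, 0) + 1
    return counts


def oracle_nf(frags: FragmentSet, tss_pos: int, strand: str,
              flank: int = 2000, up: int = 150, down: int = 50):
    """Per-base coverage NF oracle for a single gene on a single chromosome."""
    depth: dict[int, int] = {}
    for s, e in zip(frags.start, frags.end):
        for p in range(s, e):
            depth[p] = depth.get(p, 0) + 1
    if strand == "+":
        ndr = set(range(tss_pos - up, tss_pos + down))
    else:  # reflect p -> in-NDR iff -up <= -(p - tss) < down
        ndr = {p for p in range(tss_pos - flank, tss_pos + flank)
               if -up <= -(p - tss_pos) < down}
    window = set(range(tss_pos - flank, tss_pos + flank))
    bg = window - ndr
    ndr_depth = sum(depth.get(p, 0) for p in ndr) / len(ndr)
    bg_depth = sum(depth.get(p, 0) for p in bg) / len(bg)
    nf = (bg_depth - ndr_depth) / bg_depth if bg_depth > 0 else 0.0
    return nf, ndr_depth, bg_depth


def oracle_auc(scores, labels, positive="OC") -> float:
    """All-pairs concordance with ties counted 1/2."""
    scores = np.asarray(scores, dtype=float)
    pos = scores[np.asarray(labels) == positive]
    neg = scores[np.asarray(labels) != positive]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def oracle_exact_rank_p(x, y) -> float:
    """Two-sided exact Mann-Whitney p by exhaustive enumeration of all
    rank assignments under the null (no ties supported)."""
    import itertools
    x, y = list(x), list(y)
    pooled = sorted(x + y)
    nx = len(x)

    def u_stat(xs, ys):
        return sum(1 for a in xs for b in ys if a > b)

    u_obs = u_stat(x, y)
    mu = nx * len(y) / 2.0
    dev = abs(u_obs - mu)
    count = 0
    total = 0
    for combo in itertools.combinations(range(len(pooled)), nx):
        xs = [pooled[i] for i in combo]
        ys = [pooled[i] for i in range(len(pooled)) if i not in combo]
        total += 1
        if abs(u_stat(xs, ys) - mu) >= dev:
            count += 1
    return count / total


def perturb_test_rows(features, factor: float = 1.03):
    """Copy of CohortFeatures with test-split values scaled (zeros kept) and
    test labels shuffled — training data untouched."""
    import copy

    from ocscore.pipeline import CohortFeatures
    from ocscore.selection import FeatureMatrix

    rng = np.random.default_rng(999)
    out = {}
    for fam in ("motif", "fragment", "nf"):
        fm = getattr(features, fam)
        vals = fm.values.copy()
        test = (fm.split == "test").to_numpy()
        vals.loc[test] = vals.loc[test] * factor
        labels = fm.labels.copy()
        shuffled = labels[test].to_numpy().copy()
        rng.shuffle(shuffled)
        labels.loc[test] = shuffled
        out[fam] = FeatureMatrix(vals, labels, fm.split.copy(), fam)
    cnv = features.cnv_scores.copy()
    test = (features.motif.split == "test").to_numpy()
    cnv.loc[test] = cnv.loc[test] * factor
    return CohortFeatures(out["motif"], out["fragment"], out["nf"], cnv,
                          features.mean_insert.copy(), features.manifest.copy())
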