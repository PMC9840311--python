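"""File formats: BED3 fragments, FASTA genomes, TSV tables, JSON reports.

Every pipeline output carries the hash of the run configuration in a
``# config=<hash>`` header line (TSV) or a ``"config"`` key (JSON), so
artifacts from different configurations cannot be silently mixed.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, is_dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import FragmentSet
from .simulate import GenomeTruth, ToyGenome, gc_fraction_by_window

_BASES = "ACGT"
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(_BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


class FormatError(ValueError):
    """Malformed input file; carries the offending line number."""

    def __init__(self, path, line_no: int, message: str):
        super().__init__(f"{path}, line {line_no}: {message}")
        self.line_no = line_no


# --------------------------------------------------------------------------
# config hashing
# --------------------------------------------------------------------------

def _jsonable(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, Path):
        return str(obj)
    return obj


def config_hash(config) -> str:
    """Stable short hash of any (nested dataclass / dict) configuration."""
    blob = json.dumps(_jsonable(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def check_config_hash(path, expected: str) -> None:
    """Refuse an artifact written under a different configuration."""
    found = None
    with open(path) as fh:
        first = fh.readline().strip()
    if first.startswith("# config="):
        found = first.split("=", 1)[1]
    else:
        try:
            with open(path) as fh:
                found = json.load(fh).get("config")
        except (json.JSONDecodeError, UnicodeDecodeError, AttributeError):
            found = None
    if found != expected:
        raise ValueError(
            f"{path} was written under config {found!r}, expected {expected!r}; "
            "refusing to mix artifacts"
        )


# --------------------------------------------------------------------------
# fragments (BED3)
# --------------------------------------------------------------------------

def write_fragments(fragments: FragmentSet, path) -> None:
    """BED3: chrom <TAB> start <TAB> end, one record per fragment."""
    with open(path, "w") as fh:
        for c, s, e in zip(fragments.chrom, fragments.start, fragments.end):
            fh.write(f"{c}\t{s}\t{e}\n")


def read_fragments(path, sample_id: str | None = None, label: str = "HC",
                   genome: ToyGenome | None = None) -> FragmentSet:
    """Parse a BED file (>= 3 columns; track/browser/# lines ignored).

    Malformed records raise :class:`FormatError` naming the 1-based line.
    With *genome* given, coordinates are validated against chromosome
    lengths and unknown chromosomes are rejected.
    """
    path = Path(path)
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(path, line_no, "expected >= 3 tab-separated columns")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise FormatError(path, line_no, "non-integer coordinate") from None
            if start < 0:
                raise FormatError(path, line_no, "negative coordinate")
            if start >= end:
                raise FormatError(path, line_no, f"start >= end ({start} >= {end})")
            if genome is not None:
                if chrom not in genome.lengths:
                    raise FormatError(path, line_no, f"unknown chromosome {chrom!r}")
                if end > genome.lengths[chrom]:
                    raise FormatError(path, line_no, "fragment extends past chromosome end")
            chroms.append(chrom)
            starts.append(start)
            ends.append(end)
    return FragmentSet(
        sample_id or path.stem,
        label,
        np.array(chroms, dtype=object),
        np.array(starts, dtype=np.int64),
        np.array(ends, dtype=np.int64),
    )


# --------------------------------------------------------------------------
# genome (FASTA + TSS table)
# --------------------------------------------------------------------------

def write_genome_fasta(genome: ToyGenome, path, width: int = 80) -> None:
    base = np.frombuffer(_BASES.encode() + b"N", dtype=np.uint8)
    with open(path, "w") as fh:
        for name in genome.chrom_names:
            fh.write(f">{name}\n")
            seq = base[np.minimum(genome.sequence[name], 4)].tobytes().decode()
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_tss_table(genome: ToyGenome, path) -> None:
    genome.tss.to_csv(path, sep="\t", index=False)


def read_tss_table(path) -> pd.DataFrame:
    tss = pd.read_csv(path, sep="\t")
    required = {"gene_id", "chrom", "position", "strand"}
    if not required.issubset(tss.columns):
        raise ValueError(f"TSS table must have columns {sorted(required)}")
    return tss


def load_reference(fasta_path, tss_path=None) -> ToyGenome:
    """Build a ToyGenome (truth-free) from a FASTA and optional TSS table."""
    from pyfaidx import Fasta
    fa = Fasta(str(fasta_path), as_raw=True, sequence_always_upper=True)
    names, lengths, seqs, gc = [], {}, {}, {}
    for name in fa.keys():
        s = str(fa[name][:])
        codes = _CODE[np.frombuffer(s.encode(), dtype=np.uint8)]
        names.append(name)
        lengths[name] = len(codes)
        seqs[name] = codes
        gc[name] = gc_fraction_by_window(codes)
    tss = read_tss_table(tss_path) if tss_path else pd.DataFrame(
        columns=["gene_id", "chrom", "position", "strand"])
    return ToyGenome(tuple(names), lengths, seqs, tss, gc, truth=None)


# --------------------------------------------------------------------------
# manifest / truth / tables
# --------------------------------------------------------------------------

def write_manifest(manifest: pd.DataFrame, path) -> None:
    manifest.to_csv(path, sep="\t", index=False)


def read_manifest(path) -> pd.DataFrame:
    m = pd.read_csv(path, sep="\t")
    if not {"sample_id", "label", "split"}.issubset(m.columns):
        raise ValueError("manifest must have sample_id, label, split columns")
    return m


def write_truth(truth: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(_jsonable(truth), fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_truth(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def read_genome_truth(path) -> GenomeTruth:
    return GenomeTruth.from_dict(read_truth(path)["genome"])


def write_table(df: pd.DataFrame, path, cfg_hash: str, index: bool = True) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config={cfg_hash}\n")
        df.to_csv(fh, sep="\t", index=index)


def read_table(path, cfg_hash: str | None = None, index_col=0) -> pd.DataFrame:
    if cfg_hash is not None:
        check_config_hash(path, cfg_hash)
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


def write_json(obj: dict, path, cfg_hash: str) -> None:
    payload = {"config": cfg_hash, **_jsonable(obj)}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_json(path, cfg_hash: str | None = None) -> dict:
    with open(path) as fh:
        payload = json.load(fh)
    if cfg_hash is not None and payload.get("config") != cfg_hash:
        raise ValueError(f"{path} config hash mismatch")
    return payload
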