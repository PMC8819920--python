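"""Shared readers/writers and the pipeline configuration.

All sequence files are plain text (FASTA/FASTQ Phred+33, SAM, BED3+, TSV).
Coordinates follow the conventions of each format: BED and PSL are 0-based
half-open throughout.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class ReadRecord:
    """One long-read consensus sequence.

    ``subread_count`` is the number of raw subreads that produced this
    consensus (1 when unknown); ``accuracy`` is an optional per-read
    accuracy estimate in [0, 1].
    """

    read_id: str
    sequence: str
    quality: str | None = None
    subread_count: int = 1
    accuracy: float | None = None

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.sequence)


def _record_header(read: ReadRecord) -> str:
    parts = [read.read_id]
    if read.subread_count != 1:
        parts.append(f"subreads={read.subread_count}")
    if read.accuracy is not None:
        parts.append(f"accuracy={read.accuracy:.4f}")
    return " ".join(parts)


def _parse_header(record_id: str, description: str) -> tuple[str, int, float | None]:
    subreads, accuracy = 1, None
    for token in description.split()[1:]:
        if token.startswith("subreads="):
            subreads = int(token[len("subreads="):])
        elif token.startswith("accuracy="):
            accuracy = float(token[len("accuracy="):])
    return record_id, subreads, accuracy


def read_fastx(path: str | Path) -> list[ReadRecord]:
    """Read FASTQ or FASTA (by extension) into ReadRecords."""
    path = Path(path)
    fmt = "fastq" if path.suffix.lower() in {".fastq", ".fq"} else "fasta"
    reads = []
    for rec in SeqIO.parse(str(path), fmt):
        read_id, subreads, accuracy = _parse_header(rec.id, rec.description)
        qual = None
        if fmt == "fastq":
            qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        reads.append(ReadRecord(read_id, str(rec.seq), qual, subreads, accuracy))
    return reads


def write_fastq(reads: Iterable[ReadRecord], path: str | Path, default_qual: str = "I") -> None:
    with open(path, "w") as fh:
        for read in reads:
            qual = read.quality if read.quality is not None else default_qual * len(read.sequence)
            fh.write(f"@{_record_header(read)}\n{read.sequence}\n+\n{qual}\n")


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 80) -> None:
    """Write (name, sequence) pairs as wrapped FASTA."""
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    return [(rec.description, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


@dataclass(frozen=True)
class BedInterval:
    """A BED3+ interval: 0-based half-open [start, end)."""

    chrom: str
    start: int
    end: int
    name: str = "."

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        """≥1 base overlap with another half-open interval."""
        return chrom == self.chrom and start < self.end and self.start < end


def read_bed(path: str | Path) -> list[BedInterval]:
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: BED line has <3 columns")
            name = fields[3] if len(fields) > 3 else "."
            intervals.append(BedInterval(fields[0], int(fields[1]), int(fields[2]), name))
    return intervals


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Pipeline configuration
# ---------------------------------------------------------------------------

def _from_mapping(cls, data: dict, where: str):
    """Build a dataclass from a mapping, rejecting unknown keys."""
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown config keys under '{where}': {sorted(unknown)}")
    return cls(**data)


@dataclass
class PipelineConfig:
    """Everything one end-to-end run needs, serializable to YAML.

    Section objects are the parameter dataclasses of the stage modules;
    they are stored here as plain dicts until ``resolve`` is called so the
    config module stays import-light.
    """

    reads: str = ""
    out_dir: str = "run_out"
    seed: int = 1
    log_level: str = "INFO"
    chemistry: dict = field(default_factory=dict)
    whitelist: dict = field(default_factory=dict)
    umi: dict = field(default_factory=dict)
    merge: dict = field(default_factory=dict)
    diff: dict = field(default_factory=dict)
    vfilter: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return _from_mapping(cls, data, "root")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def config_hash(self) -> str:
        """Hash of the analysis parameters (paths excluded, so reruns into
        a different directory report the same hash)."""
        data = dataclasses.asdict(self)
        data.pop("out_dir", None)
        data.pop("reads", None)
        blob = json.dumps(data, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
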