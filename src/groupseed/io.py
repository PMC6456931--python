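"""Sequence input, PAF output, and pipeline configuration."""

from __future__ import annotations

import gzip
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Dict, Iterable, List

from Bio import SeqIO

from .chaining import OverlapCall
from .suffix import ReadSet

__all__ = ["PipelineConfig", "read_sequences", "write_paf", "read_paf"]


@dataclass(frozen=True)
class PipelineConfig:
    """All tunables of the overlap pipeline (flat, file-serializable).

    filter_k / filter_threshold govern the long-k-mer filtration stage;
    group_k, p, q, alpha calibrate the seeding thresholds (rho, delta);
    c is the sensitivity coefficient of the acceptance rule and
    size_similarity_tau the tolerated relative span difference.
    """

    filter_k: int = 15
    filter_threshold: int = 2
    group_k: int = 9
    p: float = 0.85
    q: float = 0.06
    alpha: float = 0.05
    c: float = 2.0
    size_similarity_tau: float = 0.3
    min_read_length: int = 0
    seed: int = 0

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for f in fields(self):
                fh.write(f"{f.name}={getattr(self, f.name)}\n")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        types = {f.name: f.type for f in fields(cls)}
        kwargs = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{lineno}: expected key=value, got {line!r}")
                key, value = line.split("=", 1)
                key = key.strip()
                if key not in types:
                    raise ValueError(f"{path}:{lineno}: unknown parameter {key!r}")
                caster = float if types[key] in ("float", float) else int
                kwargs[key] = caster(value.strip())
        return cls(**kwargs)


def _open_text(path):
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path)


def read_sequences(path) -> ReadSet:
    """Load a FASTA or FASTQ file (plain or gzip, auto-detected).

    Ids are the first whitespace-delimited header token; sequences are
    uppercased; FASTQ qualities are ignored.  Duplicate ids and malformed
    records raise.
    """
    with _open_text(path) as fh:
        first = fh.read(1)
        if first == ">":
            fmt = "fasta"
        elif first == "@":
            fmt = "fastq"
        else:
            raise ValueError(f"{path}: not FASTA or FASTQ (starts with {first!r})")
    read_set = ReadSet()
    with _open_text(path) as fh:
        for record in SeqIO.parse(fh, fmt):
            read_set.add(record.id, str(record.seq))
    return read_set


def write_paf(
    calls: Iterable[OverlapCall], read_lengths: Dict[str, int], path
) -> None:
    """Write accepted calls as standard 12-column PAF.

    Coordinates are 0-based half-open; on the '-' strand the target
    coordinates are already on the forward strand per PAF convention.
    Residue matches = n_matched, block length = l_o, mapq = 255.
    """
    with open(path, "w") as fh:
        for call in calls:
            la, lb = read_lengths[call.id_a], read_lengths[call.id_b]
            for start, end, length, label in (
                (call.a_start, call.a_end, la, "query"),
                (call.b_start, call.b_end, lb, "target"),
            ):
                if not 0 <= start <= end <= length:
                    raise ValueError(
                        f"{call.id_a}/{call.id_b}: {label} coordinates "
                        f"[{start},{end}) out of bounds for length {length}"
                    )
            fh.write(
                "\t".join(
                    map(
                        str,
                        (
                            call.id_a, la, call.a_start, call.a_end,
                            call.strand,
                            call.id_b, lb, call.b_start, call.b_end,
                            call.n_matched, call.l_o, 255,
                        ),
                    )
                )
                + "\n"
            )


def read_paf(path) -> List[OverlapCall]:
    calls: List[OverlapCall] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 12:
                raise ValueError(f"{path}:{lineno}: PAF needs >= 12 columns")
            calls.append(
                OverlapCall(
                    id_a=parts[0],
                    id_b=parts[5],
                    strand=parts[4],
                    a_start=int(parts[2]),
                    a_end=int(parts[3]),
                    b_start=int(parts[7]),
                    b_end=int(parts[8]),
                    n_matched=int(parts[9]),
                    l_o=int(parts[10]),
                    accepted=True,
                )
            )
    return calls
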