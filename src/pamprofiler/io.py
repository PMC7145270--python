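"""Shared file plumbing: FASTA/FASTQ (gzip-transparent), TSV tables, nested
JSON, run manifests and output-directory hygiene.

Tabular dialect: tab-separated, header row, no quoting, "." for absent
values. Nested structures (PAM wheel, manifests) are JSON. Every file this
package writes is re-readable by the readers here.
"""

from __future__ import annotations

import dataclasses
import gzip
import hashlib
import json
from pathlib import Path
from typing import IO, Iterable, Optional, Union

import pandas as pd
from Bio import SeqIO

from .synthetic_screen import FastqRecord

PathLike = Union[str, Path]


def _open_text(path: PathLike, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: PathLike) -> dict[str, str]:
    """Ordered id -> sequence mapping from a (possibly gzipped) FASTA file."""
    out: dict[str, str] = {}
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in out:
                raise ValueError(f"{path}: duplicate FASTA id {rec.id!r}")
            out[rec.id] = str(rec.seq).upper()
    return out


def read_fastq(path: PathLike) -> list[FastqRecord]:
    """FASTQ records from a (possibly gzipped) file.

    Malformed or truncated records raise ValueError identifying the record.
    """
    records: list[FastqRecord] = []
    with _open_text(path) as fh:
        parser = SeqIO.parse(fh, "fastq")
        index = 0
        while True:
            try:
                rec = next(parser)
            except StopIteration:
                break
            except ValueError as exc:
                raise ValueError(f"{path}: malformed FASTQ at record {index + 1}: {exc}") from exc
            records.append(
                FastqRecord(
                    id=rec.description or rec.id,
                    sequence=str(rec.seq).upper(),
                    quality="".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"]),
                )
            )
            index += 1
    return records


def write_fasta(path: PathLike, records: dict[str, str] | Iterable[tuple[str, str]]) -> None:
    items = records.items() if isinstance(records, dict) else records
    with _open_text(path, "wt") as fh:
        for name, seq in items:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def write_fastq(path: PathLike, records: Iterable[FastqRecord]) -> None:
    with _open_text(path, "wt") as fh:
        for rec in records:
            fh.write(str(rec))


def read_tsv(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["."], keep_default_na=False)


def write_tsv(path: PathLike, frame: pd.DataFrame) -> None:
    frame.to_csv(path, sep="\t", index=False, na_rep=".")


def write_json(path: PathLike, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_json(path: PathLike) -> dict:
    return json.loads(Path(path).read_text())


def sha256(path: PathLike) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def prepare_outdir(path: PathLike, force: bool = False) -> Path:
    """Create the output directory; refuse to reuse a nonempty one without
    ``force`` (outputs never silently overwrite)."""
    path = Path(path)
    if path.exists() and any(path.iterdir()) and not force:
        raise FileExistsError(f"output directory {path} is not empty (use force to overwrite)")
    path.mkdir(parents=True, exist_ok=True)
    return path


def write_manifest(
    outdir: PathLike,
    stage: str,
    params: dict,
    seed: Optional[int],
    inputs: Iterable[PathLike] = (),
    outputs: Iterable[PathLike] = (),
) -> dict:
    """Record what a stage ran on: parameters, seed and output checksums."""

    def _clean(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: _clean(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, dict):
            return {str(k): _clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_clean(v) for v in obj]
        if isinstance(obj, Path):
            return str(obj)
        return obj

    manifest = {
        "stage": stage,
        "seed": seed,
        "parameters": _clean(params),
        "inputs": [str(p) for p in inputs],
        "outputs": {Path(p).name: sha256(p) for p in outputs},
    }
    write_json(Path(outdir) / "manifest.json", manifest)
    return manifest
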