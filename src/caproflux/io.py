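"""Shared readers and writers: FASTA, GFF3, TSV tables, JSON reports.

Coordinates are 0-based half-open everywhere inside the package; GFF3's
1-based inclusive convention is converted only at the format boundary.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional

from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "Feature",
    "MalformedAnnotationError",
    "read_fasta",
    "write_fasta",
    "read_annotations",
    "write_annotations",
    "write_json_report",
]

__version__ = "0.1.0"


class MalformedAnnotationError(ValueError):
    pass


@dataclass(frozen=True)
class Feature:
    """A gene/CDS feature with internal 0-based half-open coordinates."""

    seqid: str
    type: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    strand: str
    gene_id: str
    attributes: Mapping[str, str] = field(default_factory=dict)


def read_fasta(path) -> Dict[str, str]:
    """Read FASTA into an ordered id -> uppercase sequence map.

    Wrapping-agnostic (delegated to Biopython); duplicate ids are an error
    and an empty file yields an empty map with a warning.
    """
    records: Dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        records[rec.id] = str(rec.seq).upper()
    if not records:
        warnings.warn(f"no sequences found in {path}", stacklevel=2)
    return records


def write_fasta(path, sequences: Mapping[str, str], width: int = 70) -> None:
    with open(path, "w") as fh:
        for sid, seq in sequences.items():
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _parse_attributes(text: str) -> Dict[str, str]:
    attrs: Dict[str, str] = {}
    for part in text.strip().split(";"):
        if part and "=" in part:
            k, v = part.split("=", 1)
            attrs[k.strip()] = v.strip()
    return attrs


def read_annotations(path, types: Iterable[str] = ("gene", "CDS")) -> List[Feature]:
    """Parse GFF3 features of the requested types, sorted by (seqid, start).

    Converts 1-based inclusive spans to 0-based half-open; malformed spans
    raise with the offending line number.  The gene id is taken from
    ``locus_tag``, ``gene``, ``ID`` or ``Parent`` in that order.
    """
    wanted = set(types)
    feats: List[Feature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise MalformedAnnotationError(
                    f"{path}:{lineno}: expected 9 tab-separated columns"
                )
            seqid, _source, ftype, start, end, _score, strand, _phase, attr = cols
            if ftype not in wanted:
                continue
            try:
                start1, end1 = int(start), int(end)
            except ValueError:
                raise MalformedAnnotationError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from None
            if end1 < start1 or start1 < 1:
                raise MalformedAnnotationError(
                    f"{path}:{lineno}: malformed span {start1}..{end1}"
                )
            attrs = _parse_attributes(attr)
            gene_id = (
                attrs.get("locus_tag")
                or attrs.get("gene")
                or attrs.get("ID")
                or attrs.get("Parent")
                or f"{ftype}_{lineno}"
            )
            feats.append(Feature(seqid, ftype, start1 - 1, end1, strand, gene_id, attrs))
    feats.sort(key=lambda f: (f.seqid, f.start, f.end))
    return feats


def write_annotations(path, features: Iterable[Feature], source: str = "caproflux") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = dict(f.attributes)
            attrs.setdefault("ID", f.gene_id)
            attrs.setdefault("locus_tag", f.gene_id)
            attr_text = ";".join(f"{k}={v}" for k, v in attrs.items())
            fh.write(
                f"{f.seqid}\t{source}\t{f.type}\t{f.start + 1}\t{f.end}\t.\t"
                f"{f.strand}\t.\t{attr_text}\n"
            )


def write_json_report(path, payload: Mapping, config: Optional[Mapping] = None) -> None:
    """Write a JSON report with a provenance block (tool version + config echo)."""
    doc = {
        "provenance": {"tool": "caproflux", "version": __version__, "config": dict(config or {})},
        **payload,
    }
    Path(path).write_text(json.dumps(doc, indent=2, default=str) + "\n")


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())
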