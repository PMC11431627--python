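"""File formats: FASTA/FASTQ (via Bio.SeqIO), GFF3, SAM, TSV, bedGraph.

FASTQ pairs follow the ``_1``/``_2`` suffix convention and are gzip
compressed when the path ends in ``.gz``.  GFF3 output is 1-based inclusive
with an ``Is_circular=true`` region line, mirroring how small circular
replicons are deposited in the public archives.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .circular import CircularSequence, GeneAnnotation


@dataclass
class FastqRead:
    read_id: str
    seq: str
    qual: str = ""

    def __post_init__(self):
        if not self.qual:
            self.qual = "F" * len(self.seq)  # Q37


ReadPair = tuple[FastqRead, FastqRead]


def _open_text(path, mode="rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------- FASTA


def read_fasta(path) -> dict[str, str]:
    with _open_text(path) as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(path, records: dict[str, str] | Iterable[CircularSequence]):
    if isinstance(records, dict):
        recs = [SeqRecord(Seq(s), id=n, description="") for n, s in records.items()]
    else:
        recs = [SeqRecord(Seq(c.seq), id=c.name, description="") for c in records]
    with _open_text(path, "wt") as fh:
        SeqIO.write(recs, fh, "fasta")


# ---------------------------------------------------------------- FASTQ


def write_fastq_pairs(prefix, pairs: Sequence[ReadPair], gz: bool = True):
    """Write paired reads as ``<prefix>_1.fastq[.gz]`` / ``<prefix>_2.fastq[.gz]``."""
    suffix = ".fastq.gz" if gz else ".fastq"
    p1 = Path(f"{prefix}_1{suffix}")
    p2 = Path(f"{prefix}_2{suffix}")
    for path, idx in ((p1, 0), (p2, 1)):
        with _open_text(path, "wt") as fh:
            for pair in pairs:
                r = pair[idx]
                fh.write(f"@{r.read_id}\n{r.seq}\n+\n{r.qual}\n")
    return p1, p2


def read_fastq(path) -> list[FastqRead]:
    reads = []
    with _open_text(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) % 4 != 0:
        raise ValueError(f"malformed FASTQ {path}: {len(lines)} lines (record {len(lines)//4})")
    for i in range(0, len(lines), 4):
        header, seq, plus, qual = lines[i : i + 4]
        if not header.startswith("@") or not plus.startswith("+") or len(seq) != len(qual):
            raise ValueError(f"malformed FASTQ {path} at record index {i // 4}")
        reads.append(FastqRead(header[1:].split()[0], seq.upper(), qual))
    return reads


def read_fastq_pairs(path1, path2) -> list[ReadPair]:
    r1, r2 = read_fastq(path1), read_fastq(path2)
    if len(r1) != len(r2):
        raise ValueError("unpaired FASTQ files: unequal record counts")
    return list(zip(r1, r2))


# ---------------------------------------------------------------- GFF3


def write_gff3(path, seq: CircularSequence, annotations: Sequence[GeneAnnotation]):
    L = len(seq)
    lines = ["##gff-version 3", f"##sequence-region {seq.name} 1 {L}"]
    lines.append(
        f"{seq.name}\tplasmidloom\tregion\t1\t{L}\t.\t+\t.\tID={seq.name};Is_circular=true"
    )
    for ann in sorted(annotations, key=lambda a: (a.start, a.end)):
        attrs = {"ID": ann.label, "label": ann.label, **ann.attributes}
        attr_s = ";".join(f"{k}={v}" for k, v in attrs.items())
        # 1-based inclusive; wrapped features keep end > L (positions mod L)
        lines.append(
            f"{seq.name}\tplasmidloom\t{ann.feature_type}\t{ann.start + 1}\t{ann.end}"
            f"\t.\t{ann.strand}\t0\t{attr_s}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3(path) -> list[GeneAnnotation]:
    annotations = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        seqid, _src, ftype, start, end, _score, strand, _phase, attr_s = line.split("\t")
        attrs = dict(kv.split("=", 1) for kv in attr_s.split(";") if "=" in kv)
        if ftype == "region":
            continue
        label = attrs.pop("label", attrs.get("ID", ftype))
        attrs.pop("ID", None)
        annotations.append(
            GeneAnnotation(seqid, label, int(start) - 1, int(end), strand, ftype, attrs)
        )
    return annotations


# ---------------------------------------------------------------- SAM / TSV / bedGraph


def write_sam(path, placements, references: dict[str, str]):
    """Minimal SAM: QNAME/FLAG/RNAME/POS/MAPQ/CIGAR/SEQ columns populated."""
    lines = ["@HD\tVN:1.6\tSO:unsorted"]
    for name, seq in references.items():
        lines.append(f"@SQ\tSN:{name}\tLN:{len(seq)}")
    for p in placements:
        flag = 16 if p.strand == "-" else 0
        cigar = p.cigar or f"{p.end - p.start}M"
        seq = p.read_seq or "*"
        lines.append(
            f"{p.read_id}\t{flag}\t{p.reference_id}\t{p.start + 1}\t60\t{cigar}\t*\t0\t0\t{seq}\t*"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_tsv(path, rows: Sequence[dict]):
    import pandas as pd

    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_bedgraph(path, name: str, values):
    lines = []
    start = 0
    for i in range(1, len(values) + 1):
        if i == len(values) or values[i] != values[start]:
            lines.append(f"{name}\t{start}\t{i}\t{values[start]:g}")
            start = i
    Path(path).write_text("\n".join(lines) + "\n")
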