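"""Small-RNA library ingest: FASTQ collapsing and collapsed-FASTA tags.

A *tag* is the set of identical reads collapsed to one sequence plus a
count.  Mapping tags instead of reads is what makes exhaustive stratified
alignment affordable.  ``library_size`` is the total number of individual
clean reads in the sample (after the length/N ingest rules only) — this is
the denominator CPM normalisation uses, deliberately NOT the sum of mapped
miRNA counts, which over-counts multi-locus miRNAs.
"""

from __future__ import annotations

import gzip
import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pandas as pd

logger = logging.getLogger(__name__)

MIN_INGEST_LENGTH = 15
_VALID = re.compile(r"^[ACGTN]+$")

# collapsed-FASTA header dialects: how the read count is encoded in the id
HEADER_DIALECTS = ("suffix_x", "dash_count")
_DIALECT_RE = {
    "suffix_x": re.compile(r"_x(\d+)$"),  # >t1_x120
    "dash_count": re.compile(r"-(\d+)$"),  # >seq1-42
}


@dataclass(frozen=True)
class Tag:
    """A unique read sequence and the number of reads collapsed into it."""

    sequence: str
    count: int

    def __post_init__(self) -> None:
        if self.count <= 0:
            raise ValueError("tag count must be positive")
        if not _VALID.match(self.sequence):
            raise ValueError(f"tag sequence has invalid characters: {self.sequence!r}")

    @property
    def has_n(self) -> bool:
        return "N" in self.sequence


@dataclass
class Library:
    """One sample's collapsed tag set plus its metadata."""

    sample_id: str
    tags: list[Tag]
    library_size: int
    tissue_type: str = ""
    patient_id: str = ""

    def mappable_tags(self) -> list[Tag]:
        """Tags eligible for alignment (N-free); N-tags still count in library_size."""
        return [t for t in self.tags if not t.has_n]


def _open_text(path: str | Path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def _finalize(sample_id: str, counts: dict[str, int], n_reads: int, **meta) -> Library:
    tags = [Tag(seq, c) for seq, c in counts.items()]
    tags.sort(key=lambda t: (-t.count, t.sequence))
    return Library(sample_id=sample_id, tags=tags, library_size=n_reads, **meta)


def collapse_fastq(fastq: str | Path, sample_id: Optional[str] = None, **meta) -> Library:
    """Collapse a (clean, adapter-trimmed) FASTQ into a tag library.

    Reads shorter than 15 nt are discarded (and logged) before counting;
    everything else, including N-containing reads, enters library_size.
    Output tags are sorted by descending count then sequence, so the result
    is deterministic.
    """
    if sample_id is None:
        sample_id = Path(str(fastq)).name.split(".")[0]
    counts: dict[str, int] = {}
    n_reads = 0
    n_short = 0
    with _open_text(fastq) as fh:
        lineno = 0
        while True:
            header = fh.readline()
            lineno += 1
            if not header:
                break
            if not header.startswith("@"):
                raise ValueError(f"{fastq}:{lineno}: malformed FASTQ header")
            seq = fh.readline().rstrip("\n").upper()
            plus = fh.readline()
            qual = fh.readline().rstrip("\n")
            lineno += 3
            if not plus.startswith("+") or len(qual) != len(seq):
                raise ValueError(f"{fastq}:{lineno}: malformed FASTQ record")
            if len(seq) < MIN_INGEST_LENGTH:
                n_short += 1
                continue
            if not _VALID.match(seq):
                raise ValueError(f"{fastq}:{lineno}: invalid base in read {seq!r}")
            counts[seq] = counts.get(seq, 0) + 1
            n_reads += 1
    if n_short:
        logger.info("%s: discarded %d reads shorter than %d nt", sample_id, n_short, MIN_INGEST_LENGTH)
    return _finalize(sample_id, counts, n_reads, **meta)


def read_collapsed_fasta(
    fasta: str | Path,
    header_dialect: str = "auto",
    sample_id: Optional[str] = None,
    **meta,
) -> Library:
    """Read a count-encoded collapsed FASTA (the GEO deposition format).

    Supported header dialects: ``suffix_x`` (``>t1_x120``) and
    ``dash_count`` (``>seq1-42``); ``auto`` tries them in that order on the
    first record and then sticks with the winner.
    """
    if sample_id is None:
        sample_id = Path(str(fasta)).name.split(".")[0]
    if header_dialect not in HEADER_DIALECTS + ("auto",):
        raise ValueError(f"unknown header dialect {header_dialect!r}")

    counts: dict[str, int] = {}
    n_reads = 0
    n_short = 0
    dialect = None if header_dialect == "auto" else header_dialect
    with _open_text(fasta) as fh:
        name = None
        chunks: list[str] = []

        def flush() -> None:
            nonlocal dialect, n_reads, n_short
            if name is None:
                return
            seq = "".join(chunks).upper()
            if dialect is None:
                for d in HEADER_DIALECTS:
                    if _DIALECT_RE[d].search(name):
                        dialect = d
                        break
                else:
                    raise ValueError(
                        f"{fasta}: cannot parse count from header {name!r} "
                        f"(tried dialects {', '.join(HEADER_DIALECTS)})"
                    )
            m = _DIALECT_RE[dialect].search(name)
            if m is None:
                raise ValueError(
                    f"{fasta}: header {name!r} does not match dialect {dialect!r}"
                )
            count = int(m.group(1))
            if len(seq) < MIN_INGEST_LENGTH:
                n_short += count
                return
            if not _VALID.match(seq):
                raise ValueError(f"{fasta}: invalid base in tag {seq!r}")
            counts[seq] = counts.get(seq, 0) + count
            n_reads += count

        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                flush()
                name = line[1:].split()[0]
                chunks = []
            else:
                chunks.append(line)
        flush()
    if n_short:
        logger.info("%s: discarded %d reads shorter than %d nt", sample_id, n_short, MIN_INGEST_LENGTH)
    return _finalize(sample_id, counts, n_reads, **meta)


def write_collapsed_fasta(lib: Library, fasta: str | Path, header_dialect: str = "suffix_x") -> None:
    """Write a library as collapsed FASTA (round-trip inverse of the reader)."""
    with open(fasta, "w") as fh:
        for i, tag in enumerate(lib.tags, 1):
            if header_dialect == "suffix_x":
                fh.write(f">t{i}_x{tag.count}\n")
            elif header_dialect == "dash_count":
                fh.write(f">t{i}-{tag.count}\n")
            else:
                raise ValueError(f"unknown header dialect {header_dialect!r}")
            fh.write(tag.sequence + "\n")


def read_sample_sheet(tsv: str | Path) -> pd.DataFrame:
    """Sample metadata TSV: sample_id, tissue_type, patient_id, path."""
    df = pd.read_csv(tsv, sep="\t", dtype=str)
    required = {"sample_id", "tissue_type", "patient_id", "path"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        raise ValueError("sample sheet has duplicate sample_ids")
    return df


def load_libraries(sheet: pd.DataFrame, base_dir: str | Path = ".") -> list[Library]:
    """Load every sample listed in a sample sheet (FASTA or FASTQ by suffix)."""
    libs = []
    for row in sheet.itertuples(index=False):
        path = Path(base_dir) / row.path
        meta = dict(tissue_type=row.tissue_type, patient_id=row.patient_id)
        stem = str(path).removesuffix(".gz")
        if stem.endswith((".fastq", ".fq")):
            libs.append(collapse_fastq(path, sample_id=row.sample_id, **meta))
        else:
            libs.append(read_collapsed_fasta(path, sample_id=row.sample_id, **meta))
    return libs
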