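"""Precursor / mature miRNA reference handling.

The reference consists of hairpin precursor sequences (FASTA) and the
coordinates of their canonical mature products (GFF3, precursor-relative,
1-based inclusive as per GFF convention).  Internally all coordinates are
0-based half-open, so ``precursor.sequence[m.start:m.end]`` is the canonical
mature sequence.  All sequences are normalised to the DNA alphabet (U -> T)
at load time so that downstream matching works in a single alphabet.

Mature ids follow miRBase naming: the locus suffix lives on the precursor
(``hsa-let-7a-1``), not on the mature (``hsa-let-7a-5p``), so one mature id
may be encoded by several precursor loci ("multi-locus" miRNAs).  Reads
matching all loci of one such group are legitimate multi-mappers, unlike
reads matching distinct family members; :func:`build_multilocus_groups`
makes that distinction explicit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def normalize_seq(seq: str) -> str:
    """Uppercase and convert RNA to DNA alphabet (U -> T)."""
    return seq.upper().replace("U", "T")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomeLocus:
    chrom: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    strand: str  # '+' or '-'

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.end <= self.start:
            raise ValueError("locus end must exceed start")


@dataclass(frozen=True)
class MatureAnnotation:
    """Canonical mature miRNA coordinates within its precursor."""

    mature_id: str
    arm: str  # '5p' or '3p'
    start: int  # 0-based half-open offsets within the precursor
    end: int
    canonical_sequence: str

    def __post_init__(self) -> None:
        if self.arm not in ("5p", "3p"):
            raise ValueError(f"{self.mature_id}: arm must be '5p' or '3p', got {self.arm!r}")
        length = self.end - self.start
        if not 18 <= length <= 28:
            raise ValueError(
                f"{self.mature_id}: mature length {length} outside the 18-28 nt range"
            )
        if len(self.canonical_sequence) != length:
            raise ValueError(f"{self.mature_id}: canonical sequence length mismatch")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class PrecursorRecord:
    """A hairpin precursor with its annotated mature arm(s)."""

    precursor_id: str
    sequence: str
    matures: tuple[MatureAnnotation, ...]
    genome_locus: Optional[GenomeLocus] = None

    def __post_init__(self) -> None:
        if len(self.sequence) < 40:
            raise ValueError(
                f"{self.precursor_id}: precursor length {len(self.sequence)} < 40 nt"
            )
        arms = [m.arm for m in self.matures]
        if len(arms) != len(set(arms)) or not 1 <= len(arms) <= 2:
            raise ValueError(
                f"{self.precursor_id}: need 1-2 matures with distinct arms, got {arms}"
            )
        for m in self.matures:
            if m.start < 0 or m.end > len(self.sequence):
                raise ValueError(
                    f"{self.precursor_id}: mature {m.mature_id} [{m.start},{m.end}) "
                    f"outside precursor of length {len(self.sequence)}"
                )
            if self.sequence[m.start : m.end] != m.canonical_sequence:
                raise ValueError(
                    f"{self.precursor_id}: mature {m.mature_id} sequence does not "
                    "match its precursor slice"
                )
        if self.genome_locus is not None:
            span = self.genome_locus.end - self.genome_locus.start
            if span != len(self.sequence):
                raise ValueError(
                    f"{self.precursor_id}: genome locus span {span} != "
                    f"precursor length {len(self.sequence)}"
                )

    def mature(self, arm: str) -> Optional[MatureAnnotation]:
        for m in self.matures:
            if m.arm == arm:
                return m
        return None


@dataclass(frozen=True)
class MultiLocusGroup:
    """All precursor loci encoding one identical mature sequence."""

    base_name: str  # the shared mature_id, e.g. 'hsa-let-7a-5p'
    member_precursors: tuple[str, ...]
    canonical_sequence: str = ""


def _parse_gff_attributes(text: str) -> dict[str, str]:
    attrs = {}
    for item in text.strip().split(";"):
        item = item.strip()
        if not item:
            continue
        if "=" in item:
            key, _, value = item.partition("=")
            attrs[key.strip()] = value.strip()
    return attrs


def _infer_arm(mature_id: str, attrs: dict[str, str]) -> str:
    if "arm" in attrs:
        return attrs["arm"]
    if mature_id.endswith("-5p"):
        return "5p"
    if mature_id.endswith("-3p"):
        return "3p"
    raise ValueError(
        f"mature {mature_id!r} has no explicit arm: expected a -5p/-3p name "
        "suffix or an 'arm=' GFF attribute; ambiguous annotations are rejected"
    )


def load_reference(precursor_fasta: str | Path, mature_gff: str | Path) -> list[PrecursorRecord]:
    """Load precursors (FASTA) plus mature coordinates (GFF3).

    GFF3 layout: ``miRNA`` features carry precursor-relative 1-based
    inclusive coordinates with ``seqid`` naming the precursor (or a
    ``Derives_from=``/``Parent=`` attribute).  Optional
    ``miRNA_primary_transcript`` features with a ``seqid`` different from
    their ``ID`` supply genomic loci (``seqid`` = chromosome).

    Raises ``ValueError`` naming the offending record for matures falling
    outside their precursor or duplicate mature ids with differing
    sequences.
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(precursor_fasta), "fasta"):
        seqs[rec.id] = normalize_seq(str(rec.seq))

    matures_by_prec: dict[str, list[MatureAnnotation]] = {p: [] for p in seqs}
    loci: dict[str, GenomeLocus] = {}

    with open(mature_gff) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{mature_gff}:{lineno}: expected 9 GFF columns")
            seqid, _source, ftype, start1, end1, _score, strand, _phase, attr_text = fields
            attrs = _parse_gff_attributes(attr_text)
            if ftype == "miRNA_primary_transcript":
                prec_id = attrs.get("ID", seqid)
                if seqid != prec_id:
                    loci[prec_id] = GenomeLocus(
                        chrom=seqid, start=int(start1) - 1, end=int(end1), strand=strand
                    )
                continue
            if ftype != "miRNA":
                continue
            prec_id = attrs.get("Derives_from") or attrs.get("Parent") or seqid
            if prec_id not in seqs:
                raise ValueError(
                    f"{mature_gff}:{lineno}: precursor {prec_id!r} not in FASTA"
                )
            mature_id = attrs.get("ID") or attrs.get("Name")
            if mature_id is None:
                raise ValueError(f"{mature_gff}:{lineno}: miRNA feature lacks ID/Name")
            start, end = int(start1) - 1, int(end1)  # GFF 1-based inclusive -> half-open
            prec_seq = seqs[prec_id]
            if start < 0 or end > len(prec_seq):
                raise ValueError(
                    f"mature {mature_id} [{start1},{end1}] outside precursor "
                    f"{prec_id} of length {len(prec_seq)}"
                )
            matures_by_prec[prec_id].append(
                MatureAnnotation(
                    mature_id=mature_id,
                    arm=_infer_arm(mature_id, attrs),
                    start=start,
                    end=end,
                    canonical_sequence=prec_seq[start:end],
                )
            )

    records = []
    for prec_id, seq in seqs.items():
        if not matures_by_prec[prec_id]:
            logger.warning("precursor %s has no mature annotation; skipped", prec_id)
            continue
        records.append(
            PrecursorRecord(
                precursor_id=prec_id,
                sequence=seq,
                matures=tuple(matures_by_prec[prec_id]),
                genome_locus=loci.get(prec_id),
            )
        )
    # duplicate mature_id with differing canonical sequence is a hard error
    seen: dict[str, tuple[str, str]] = {}
    for rec in records:
        for m in rec.matures:
            if m.mature_id in seen:
                prev_prec, prev_seq = seen[m.mature_id]
                if prev_seq != m.canonical_sequence:
                    raise ValueError(
                        f"mature id {m.mature_id} has differing sequences in "
                        f"{prev_prec} and {rec.precursor_id}"
                    )
            else:
                seen[m.mature_id] = (rec.precursor_id, m.canonical_sequence)
    return records


def write_reference(
    records: Iterable[PrecursorRecord],
    precursor_fasta: str | Path,
    mature_gff: str | Path,
) -> None:
    """Write precursors + mature annotations back to FASTA + GFF3.

    Inverse of :func:`load_reference` (round-trip safe).
    """
    records = list(records)
    SeqIO.write(
        [SeqRecord(Seq(r.sequence), id=r.precursor_id, description="") for r in records],
        str(precursor_fasta),
        "fasta",
    )
    with open(mature_gff, "w") as fh:
        fh.write("##gff-version 3\n")
        for r in records:
            if r.genome_locus is not None:
                g = r.genome_locus
                fh.write(
                    f"{g.chrom}\tmirnome\tmiRNA_primary_transcript\t{g.start + 1}\t"
                    f"{g.end}\t.\t{g.strand}\t.\tID={r.precursor_id}\n"
                )
            for m in r.matures:
                fh.write(
                    f"{r.precursor_id}\tmirnome\tmiRNA\t{m.start + 1}\t{m.end}\t.\t+\t.\t"
                    f"ID={m.mature_id};Derives_from={r.precursor_id};arm={m.arm}\n"
                )


def build_multilocus_groups(records: Iterable[PrecursorRecord]) -> list[MultiLocusGroup]:
    """Group precursor loci by shared mature id.

    The grouping key is the mature_id (miRBase puts locus suffixes on the
    precursor name); members of a group must carry an identical canonical
    mature sequence — the same id with different sequences is an error.
    Distinct mature ids never group, however similar their sequences
    (family members such as miR-548a-3p vs miR-548b-3p stay separate).
    """
    by_mature: dict[str, list[tuple[str, str]]] = {}
    order: list[str] = []
    for rec in records:
        for m in rec.matures:
            if m.mature_id not in by_mature:
                by_mature[m.mature_id] = []
                order.append(m.mature_id)
            by_mature[m.mature_id].append((rec.precursor_id, m.canonical_sequence))
    groups = []
    for mature_id in order:
        members = by_mature[mature_id]
        seqs = {s for _, s in members}
        if len(seqs) > 1:
            locs = ", ".join(p for p, _ in members)
            raise ValueError(
                f"mature id {mature_id} has non-identical sequences across loci: {locs}"
            )
        groups.append(
            MultiLocusGroup(
                base_name=mature_id,
                member_precursors=tuple(p for p, _ in members),
                canonical_sequence=next(iter(seqs)),
            )
        )
    return groups


def group_index(groups: Iterable[MultiLocusGroup]) -> dict[str, MultiLocusGroup]:
    """Map mature_id -> its multi-locus group."""
    return {g.base_name: g for g in groups}
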