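"""Stratified small-RNA tag alignment with iterative 3' trimming.

The central problem: non-templated 3' additions (NTA) look like mismatches
to a conventional short-read mapper, so NTA-carrying reads are either lost
or mapped with spurious mismatches, aggravating cross-mapping within
near-identical miRNA families.  The strategy used here separates the two
signals:

* alignment proceeds in *steps* with a gradually increasing mismatch
  allowance (default 0, 1, 2), so perfect matches are always preferred;
* within a step, a tag that fails to map is iteratively trimmed at its 3'
  end — one base per *iteration* — until it maps or hits the minimum
  length; the trimmed bases are reported as the NTA suffix, never as
  mismatches;
* when a tag moves to the next step it is restored to its original length,
  which guarantees that a read carrying both an NTA and a true inner
  variant is reported with the variant only (the NTA is trimmed at the
  higher mismatch allowance);
* a mapped tag must have both ends of its (trimmed) alignment within a
  fixed window (default +/-5 nt) of some canonical mature miRNA's
  coordinates — this captures isomiR variation while excluding artifacts;
* multi-mapping tags survive only when every hit belongs to loci of the
  same mature miRNA (let-7a-1/-2/-3 style multi-locus groups); hits spread
  over distinct family members (miR-548a vs miR-548b) are discarded as
  ambiguous, which is the cross-mapping guard.

Two reference modes exist: ``precursor`` (map against hairpin sequences;
antisense hits are rejected) and ``genome`` (map against chromosomes with
the stricter restrictions: at most 1 mismatch, at most 2 trimmed bases,
and the all-hits-same-miRNA repeat rule applied to every genomic hit).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .reference_io import (
    MultiLocusGroup,
    PrecursorRecord,
    group_index,
    revcomp,
)
from .tag_io import Library, Tag

logger = logging.getLogger(__name__)

UNMAPPED_REASONS = ("no_hit", "ambiguous", "antisense_only", "out_of_window")


@dataclass(frozen=True)
class AlignerConfig:
    mismatch_ladder: tuple[int, ...] = (0, 1, 2)
    min_length: int = 18
    max_trim: Optional[int] = None
    window: int = 5
    mode: str = "precursor"

    def __post_init__(self) -> None:
        if self.mode not in ("precursor", "genome"):
            raise ValueError(f"mode must be 'precursor' or 'genome', got {self.mode!r}")
        lad = self.mismatch_ladder
        if not lad or lad[0] != 0 or any(b <= a for a, b in zip(lad, lad[1:])):
            raise ValueError("mismatch_ladder must be strictly increasing from 0")
        if self.min_length < 15:
            raise ValueError("min_length must be >= 15")
        if self.window < 0:
            raise ValueError("window must be >= 0")

    @classmethod
    def precursor_default(cls) -> "AlignerConfig":
        return cls(mismatch_ladder=(0, 1, 2), min_length=18, max_trim=None,
                   window=5, mode="precursor")

    @classmethod
    def genome_default(cls) -> "AlignerConfig":
        # genome restrictions: <=1 mismatch, <=2 trimmed bases
        return cls(mismatch_ladder=(0, 1), min_length=18, max_trim=2,
                   window=5, mode="genome")


@dataclass(frozen=True)
class TagAssignment:
    """A tag mapped to one mature miRNA (possibly via several loci)."""

    tag: Tag
    mature_id: str
    group: MultiLocusGroup
    step: int  # index into the mismatch ladder
    iteration: int  # number of 3' bases trimmed
    mismatches: int  # inner mismatches in the trimmed alignment
    nta_suffix: str  # the trimmed 3' bases ('' if none)
    offset5: int  # mapped 5' end minus canonical 5' end (mature frame)
    offset3: int  # mapped (trimmed) 3' end minus canonical 3' end
    mismatch_positions: tuple[tuple[int, str, str], ...]  # (pos in mature, ref, read)

    @property
    def mapped_sequence(self) -> str:
        return self.tag.sequence[: len(self.tag.sequence) - self.iteration]


@dataclass(frozen=True)
class Unmapped:
    tag: Tag
    reason: str  # one of UNMAPPED_REASONS

    def __post_init__(self) -> None:
        if self.reason not in UNMAPPED_REASONS:
            raise ValueError(f"unknown unmapped reason {self.reason!r}")


@dataclass
class MappingStats:
    """Count-weighted (per individual read) mapping summary."""

    total_reads: int = 0
    mapped_reads_per_step: dict[int, int] = field(default_factory=dict)
    unmapped_reads_by_reason: dict[str, int] = field(default_factory=dict)
    total_tags: int = 0
    mapped_tags: int = 0

    @property
    def mapped_reads(self) -> int:
        return sum(self.mapped_reads_per_step.values())

    def step_fraction(self, step: int) -> float:
        if self.total_reads == 0:
            return 0.0
        return self.mapped_reads_per_step.get(step, 0) / self.total_reads

    @property
    def mapped_fraction(self) -> float:
        return self.mapped_reads / self.total_reads if self.total_reads else 0.0


# ---------------------------------------------------------------------------
# reference index


@dataclass(frozen=True)
class _MatureWindow:
    """A canonical mature's interval on an indexed sequence, plus strand."""

    mature_id: str
    start: int
    end: int
    strand: str  # mature orientation relative to the indexed sequence


class ReferenceIndex:
    """Pre-encoded reference sequences with canonical mature windows.

    In precursor mode each precursor is one indexed sequence and matures sit
    at their annotated offsets on the '+' strand.  In genome mode the
    chromosomes are indexed and mature coordinates are projected through
    each precursor's genomic locus (minus-strand loci get strand '-';
    offsets are always reported in the mature's 5'->3' frame, so isomiR
    classes are strand-invariant).
    """

    def __init__(
        self,
        records: Sequence[PrecursorRecord],
        groups: Sequence[MultiLocusGroup],
        mode: str = "precursor",
        genome: Optional[dict[str, str]] = None,
    ) -> None:
        if not records:
            raise ValueError("empty reference")
        self.mode = mode
        self.group_of: dict[str, MultiLocusGroup] = group_index(groups)
        self.mature_length: dict[str, int] = {}
        self.seqs: dict[str, str] = {}
        self.windows: dict[str, list[_MatureWindow]] = {}

        if mode == "precursor":
            for rec in records:
                self.seqs[rec.precursor_id] = rec.sequence
                self.windows[rec.precursor_id] = [
                    _MatureWindow(m.mature_id, m.start, m.end, "+") for m in rec.matures
                ]
                for m in rec.matures:
                    self.mature_length[m.mature_id] = len(m)
        elif mode == "genome":
            if genome is None:
                raise ValueError("genome mode requires genome sequences")
            self.seqs = dict(genome)
            self.windows = {c: [] for c in self.seqs}
            for rec in records:
                loc = rec.genome_locus
                if loc is None:
                    logger.warning(
                        "precursor %s has no genome locus; skipped in genome mode",
                        rec.precursor_id,
                    )
                    continue
                if loc.chrom not in self.seqs:
                    raise ValueError(f"chromosome {loc.chrom} absent from genome FASTA")
                for m in rec.matures:
                    if loc.strand == "+":
                        gs, ge = loc.start + m.start, loc.start + m.end
                    else:
                        gs, ge = loc.end - m.end, loc.end - m.start
                    self.windows[loc.chrom].append(
                        _MatureWindow(m.mature_id, gs, ge, loc.strand)
                    )
                    self.mature_length[m.mature_id] = len(m)
        else:
            raise ValueError(f"unknown mode {mode!r}")

        self._encoded = {
            name: np.frombuffer(seq.encode(), dtype=np.uint8)
            for name, seq in self.seqs.items()
        }

    # -- hit search ---------------------------------------------------------

    def find_hits(self, query: str, max_mm: int) -> list[tuple[str, int, str, tuple[int, ...]]]:
        """All placements of ``query`` with <= max_mm substitutions.

        Returns (seq_name, start, strand, mismatch query-indices).  Strand
        '-' means the reverse complement of the query matches the indexed
        forward sequence (the query itself lies on the reverse strand).
        """
        hits = []
        for strand, q in (("+", query), ("-", revcomp(query))):
            qarr = np.frombuffer(q.encode(), dtype=np.uint8)
            L = len(qarr)
            for name, ref in self._encoded.items():
                if L > ref.size:
                    continue
                if max_mm == 0:
                    seq = self.seqs[name]
                    pos = seq.find(q)
                    while pos != -1:
                        hits.append((name, pos, strand, ()))
                        pos = seq.find(q, pos + 1)
                    continue
                view = np.lib.stride_tricks.sliding_window_view(ref, L)
                mm = (view != qarr).sum(axis=1)
                for pos in np.nonzero(mm <= max_mm)[0]:
                    idx = np.nonzero(view[pos] != qarr)[0]
                    if strand == "-":
                        idx = tuple(sorted(L - 1 - int(i) for i in idx))
                    else:
                        idx = tuple(int(i) for i in idx)
                    hits.append((name, int(pos), strand, idx))
        return hits


@dataclass(frozen=True)
class _Candidate:
    mature_id: str
    offset5: int
    offset3: int
    mismatches: int
    mismatch_positions: tuple[tuple[int, str, str], ...]


def _candidates_for_hit(
    index: ReferenceIndex,
    query: str,
    name: str,
    start: int,
    strand: str,
    mm_idx: tuple[int, ...],
    window: int,
) -> list[_Candidate]:
    """Project a raw placement onto every canonical mature window it fits."""
    end = start + len(query)
    out = []
    for w in index.windows[name]:
        if strand != w.strand:
            continue
        if w.strand == "+":
            off5, off3 = start - w.start, end - w.end
        else:
            off5, off3 = w.end - end, w.start - start
        if abs(off5) > window or abs(off3) > window:
            continue
        positions = []
        for i in mm_idx:
            if strand == "+":
                ref_base = index.seqs[name][start + i]
            else:
                ref_base = revcomp(index.seqs[name][start + (len(query) - 1 - i)])
            positions.append((off5 + i, ref_base, query[i]))
        out.append(
            _Candidate(
                mature_id=w.mature_id,
                offset5=off5,
                offset3=off3,
                mismatches=len(mm_idx),
                mismatch_positions=tuple(sorted(positions)),
            )
        )
    return out


# ---------------------------------------------------------------------------
# the stratified search


def align_tag(
    tag: Tag,
    index: ReferenceIndex,
    cfg: AlignerConfig,
) -> TagAssignment | Unmapped:
    """Map one tag through the stratified step/iteration search.

    Steps are tried in ladder order; within a step, trimming iterations run
    0, 1, 2, ... (full length first) down to the minimum length or the trim
    cap.  The first (step, iteration) yielding at least one admissible hit
    decides the tag's fate: it is either assigned (all best hits in one
    multi-locus group) or discarded as ambiguous.  Failing every
    combination returns an :class:`Unmapped` whose reason records the best
    evidence seen (ambiguous > out_of_window > antisense_only > no_hit).
    """
    seq = tag.sequence
    if len(seq) < cfg.min_length:
        return Unmapped(tag, "no_hit")
    max_iter = len(seq) - cfg.min_length
    if cfg.max_trim is not None:
        max_iter = min(max_iter, cfg.max_trim)

    saw_sense_out_of_window = False
    saw_antisense = False

    for step, max_mm in enumerate(cfg.mismatch_ladder):
        for iteration in range(max_iter + 1):
            query = seq[: len(seq) - iteration]
            hits = index.find_hits(query, max_mm)
            if not hits:
                continue
            cands: list[_Candidate] = []
            n_sense = 0
            min_mm_all = min(len(h[3]) for h in hits)
            stray_min_mm_hit = False  # a minimal-mismatch hit outside every window
            for name, start, strand, mm_idx in hits:
                cs = _candidates_for_hit(index, query, name, start, strand, mm_idx, cfg.window)
                cands.extend(cs)
                if cfg.mode == "precursor":
                    if strand == "+":
                        n_sense += 1
                else:
                    n_sense += 1  # genome is double-stranded; both strands count
                if not cs and len(mm_idx) == min_mm_all:
                    stray_min_mm_hit = True
            if not cands:
                if n_sense:
                    saw_sense_out_of_window = True
                else:
                    saw_antisense = True
                continue
            # admissible hits exist -> this (step, iteration) decides
            best_mm = min(c.mismatches for c in cands)
            best = [c for c in cands if c.mismatches == best_mm]
            groups_hit = {index.group_of[c.mature_id].base_name for c in best}
            if len(groups_hit) > 1:
                return Unmapped(tag, "ambiguous")
            if cfg.mode == "genome" and (min_mm_all < best_mm or stray_min_mm_hit):
                # strict repeat rule: every minimal-mismatch genomic hit
                # must correspond to a locus of this same miRNA
                return Unmapped(tag, "ambiguous")
            chosen = sorted(best, key=lambda c: (abs(c.offset5) + abs(c.offset3), c.mature_id))[0]
            return TagAssignment(
                tag=tag,
                mature_id=chosen.mature_id,
                group=index.group_of[chosen.mature_id],
                step=step,
                iteration=iteration,
                mismatches=chosen.mismatches,
                nta_suffix=seq[len(seq) - iteration :],
                offset5=chosen.offset5,
                offset3=chosen.offset3,
                mismatch_positions=chosen.mismatch_positions,
            )

    if saw_sense_out_of_window:
        return Unmapped(tag, "out_of_window")
    if saw_antisense:
        return Unmapped(tag, "antisense_only")
    return Unmapped(tag, "no_hit")


def align_library(
    lib: Library,
    index: ReferenceIndex,
    cfg: AlignerConfig,
) -> tuple[list[TagAssignment], MappingStats]:
    """Align every mappable tag of a library; stats are read-weighted.

    The fraction-mapped statistics weight each tag by its read count, so
    they report fractions of *individual reads*, and they use the full
    library size (including N-containing and too-short tags) as the
    denominator.
    """
    stats = MappingStats(total_reads=lib.library_size)
    assignments: list[TagAssignment] = []
    cache: dict[str, TagAssignment | Unmapped] = {}
    for tag in lib.mappable_tags():
        res = cache.get(tag.sequence)
        if res is None:
            res = align_tag(tag, index, cfg)
            cache[tag.sequence] = res
        stats.total_tags += 1
        if isinstance(res, TagAssignment):
            if res.tag.count != tag.count:  # cache hit from a different count
                res = TagAssignment(**{**res.__dict__, "tag": tag})
            assignments.append(res)
            stats.mapped_tags += 1
            stats.mapped_reads_per_step[res.step] = (
                stats.mapped_reads_per_step.get(res.step, 0) + tag.count
            )
        else:
            stats.unmapped_reads_by_reason[res.reason] = (
                stats.unmapped_reads_by_reason.get(res.reason, 0) + tag.count
            )
    return assignments, stats


def rows_to_assignments(
    rows: Iterable[dict],
    groups: Iterable[MultiLocusGroup],
) -> dict[str, list[TagAssignment]]:
    """Rebuild per-sample assignments from exported TSV rows."""
    gidx = group_index(groups)
    out: dict[str, list[TagAssignment]] = {}
    for row in rows:
        positions = []
        text = row.get("mismatch_positions") or ""
        if isinstance(text, str) and text:
            for item in text.split(";"):
                pos, _, change = item.partition(":")
                ref, _, read = change.partition(">")
                positions.append((int(pos), ref, read))
        out.setdefault(str(row["sample_id"]), []).append(
            TagAssignment(
                tag=Tag(row["sequence"], int(row["count"])),
                mature_id=row["mature_id"],
                group=gidx[row["mature_id"]],
                step=int(row["step"]),
                iteration=int(row["iteration"]),
                mismatches=int(row["mismatches"]),
                nta_suffix="" if pd_isna(row.get("nta_suffix")) else str(row["nta_suffix"]),
                offset5=int(row["offset5"]),
                offset3=int(row["offset3"]),
                mismatch_positions=tuple(positions),
            )
        )
    return out


def pd_isna(value) -> bool:
    return value is None or value != value or value == ""


def assignments_to_rows(sample_id: str, assignments: Iterable[TagAssignment]) -> list[dict]:
    """Flatten assignments for TSV export (one row per tag x sample)."""
    rows = []
    for a in assignments:
        rows.append(
            {
                "sample_id": sample_id,
                "sequence": a.tag.sequence,
                "count": a.tag.count,
                "mature_id": a.mature_id,
                "step": a.step,
                "iteration": a.iteration,
                "mismatches": a.mismatches,
                "nta_suffix": a.nta_suffix,
                "offset5": a.offset5,
                "offset3": a.offset3,
                "mismatch_positions": ";".join(
                    f"{p}:{r}>{b}" for p, r, b in a.mismatch_positions
                ),
            }
        )
    return rows
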