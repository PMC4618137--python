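"""Synthetic miRNome generator with exact ground truth.

Emits a miRBase-like reference (precursor FASTA + mature GFF3 + a small
synthetic genome holding the precursor loci on both strands) and collapsed
small-RNA tag libraries with a fully known generative structure:

* per-mature expression drawn once from a log-normal and shared across
  samples, with planted tissue-type log2 fold-change effects;
* isomiR end offsets from a categorical distribution over (offset5,
  offset3) pairs (3'-variation dominant, as in real small-RNA data);
* 3' non-templated additions from per-suffix rates (A/U-composed, as the
  dominant additions are in vivo);
* A-to-I editing planted at configured mature positions with per-tissue
  frequencies (applied before sequencing error);
* uniform per-base substitution sequencing error, applied last.

Read generation order per read: draw mature -> draw end offsets -> apply
editing -> append NTA suffix -> apply sequencing error -> collapse.

Identifiability by construction: the last few mature bases and the
template bases following every mature 3' end are drawn from {C, G} while
NTA suffixes are {A, T}-composed, so an addition can never coincide with a
templated extension and the truth tables (isomiR fractions, NTA fractions,
editing frequencies) are exact rather than approximate.  Multi-locus
families share one identical mature across loci; near-paralog pairs are
distinct matures at Hamming distance 2, planted to exercise the aligner's
cross-mapping discard; all other mature pairs are kept at Hamming
distance >= 4 by rejection sampling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binom

from .reference_io import (
    GenomeLocus,
    MatureAnnotation,
    MultiLocusGroup,
    PrecursorRecord,
    build_multilocus_groups,
    revcomp,
    write_reference,
)
from .tag_io import Library, Tag, write_collapsed_fasta
from .aligner import AlignerConfig

_BASES = "ACGT"
_MATURE_LEN = 22
_CG_GUARD = 5  # mature tail bases and following template bases drawn from C/G


@dataclass(frozen=True)
class EditingSpec:
    """One planted editing site (assigned to a concrete mature at build time)."""

    position: int = 5
    alt: str = "G"
    freq_by_tissue: tuple[tuple[str, float], ...] = (
        ("normal", 0.30), ("tumor", 0.30), ("metastasis", 0.30),
    )


def _default_samples() -> tuple[tuple[str, str, str], ...]:
    # 3 patients x (normal, tumor, metastasis), the matched design the
    # pipeline is built around
    out = []
    for p in (1, 2, 3):
        for t in ("normal", "tumor", "metastasis"):
            out.append((f"P{p}_{t}", t, f"P{p}"))
    return tuple(out)


@dataclass(frozen=True)
class SimConfig:
    n_precursors: int = 36  # total loci, including family loci and paralogs
    n_multilocus_families: int = 2  # families of 2 identical-mature loci
    n_near_paralogs: int = 2  # pairs of matures at Hamming distance 2
    n_single_arm: int = 2  # regular precursors annotated with a 5p arm only
    samples: tuple[tuple[str, str, str], ...] = field(default_factory=_default_samples)
    expression_sigma: float = 1.0  # log-normal sd (natural log) of mature weights
    n_de_matures: int = 6  # matures given a tumor/metastasis expression effect
    de_log2fc: float = 1.5  # half the affected matures go up, half down
    isomir_offset_dist: tuple[tuple[tuple[int, int], float], ...] = (
        ((0, 0), 0.68), ((0, -1), 0.10), ((0, 1), 0.08), ((0, 2), 0.04),
        ((-1, 0), 0.03), ((1, 0), 0.03), ((0, -2), 0.02),
        ((-1, 1), 0.01), ((1, -1), 0.01),
    )
    nta_rates: tuple[tuple[str, float], ...] = (
        ("A", 0.06), ("AA", 0.025), ("AAA", 0.005),
        ("T", 0.04), ("TT", 0.015), ("TA", 0.005),
    )
    editing: tuple[EditingSpec, ...] = (EditingSpec(),)
    planted_isomir_shift: float = 0.0  # contribution moved (0,0)->(0,1) in tumors
    planted_adenylation_shift: float = 0.0  # 'A' rate in tumors for one mature
    seq_error_rate: float = 0.001
    depth: int = 200_000  # reads per sample
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(p for _, p in self.isomir_offset_dist)
        if abs(total - 1.0) > 1e-9:
            raise ValueError("isomir_offset_dist must sum to 1")
        if sum(r for _, r in self.nta_rates) >= 1.0:
            raise ValueError("nta rates must sum to < 1")
        if not 0 <= self.seq_error_rate < 0.5:
            raise ValueError("seq_error_rate out of range")
        max_abs = max(max(abs(o5), abs(o3)) for (o5, o3), _ in self.isomir_offset_dist)
        if max_abs > 5:
            raise ValueError("isomiR offsets exceed the +/-5 canonical window")
        for suffix, _ in self.nta_rates:
            if not set(suffix) <= {"A", "T"}:
                raise ValueError(
                    "default-model NTA suffixes must be A/T-composed so that "
                    "additions are unambiguously non-templated"
                )


@dataclass
class SimTruth:
    """Exact generative ground truth, aggregated from the emitted reads."""

    counts: pd.DataFrame  # sample_id, mature_id, count
    isomirs: pd.DataFrame  # sample_id, mature_id, offset5, offset3, count, fraction
    nta: pd.DataFrame  # sample_id, mature_id, nta_suffix, count ('' = no addition)
    editing: pd.DataFrame  # sample_id, mature_id, position, alt, alt_count, covering, frequency
    log2fc: pd.DataFrame  # mature_id, tissue log2 fold change vs normal
    planted: dict  # names of the matures carrying planted effects
    mature_weights: pd.Series  # baseline expression weights


@dataclass
class SimResult:
    config: SimConfig
    records: list[PrecursorRecord]
    groups: list[MultiLocusGroup]
    genome: dict[str, str]
    libraries: list[Library]
    truth: SimTruth


# ---------------------------------------------------------------------------
# reference construction


def _rand_seq(rng: np.random.Generator, n: int, alphabet: str = _BASES) -> str:
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), n))


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _draw_mature(rng: np.random.Generator, accepted: list[str], min_dist: int = 4,
                 max_tries: int = 1000) -> str:
    """A 22-mer whose last bases are C/G, far from all accepted matures."""
    for _ in range(max_tries):
        seq = _rand_seq(rng, _MATURE_LEN - _CG_GUARD) + _rand_seq(rng, _CG_GUARD, "CG")
        if all(_hamming(seq, other) >= min_dist for other in accepted):
            return seq
    raise RuntimeError("could not draw a sufficiently distinct mature sequence")


def _build_precursor(
    rng: np.random.Generator,
    prec_id: str,
    mature5: tuple[str, str],
    mature3: Optional[tuple[str, str]] = None,
) -> PrecursorRecord:
    """Assemble flank + 5p [+ loop + 3p] + tail with C/G guards after each arm."""
    flank5 = _rand_seq(rng, 12)
    parts = [flank5, mature5[1]]
    m5_start = len(flank5)
    matures = []
    if mature3 is not None:
        loop = _rand_seq(rng, _CG_GUARD, "CG") + _rand_seq(rng, 10)
        m3_start = m5_start + _MATURE_LEN + len(loop)
        parts += [loop, mature3[1], _rand_seq(rng, _CG_GUARD, "CG") + _rand_seq(rng, 7)]
        matures.append((mature3[0], "3p", m3_start))
    else:
        parts.append(_rand_seq(rng, _CG_GUARD, "CG") + _rand_seq(rng, 17))
    matures.insert(0, (mature5[0], "5p", m5_start))
    seq = "".join(parts)
    anns = tuple(
        MatureAnnotation(mid, arm, start, start + _MATURE_LEN, seq[start : start + _MATURE_LEN])
        for mid, arm, start in matures
    )
    return PrecursorRecord(precursor_id=prec_id, sequence=seq, matures=anns)


def build_reference(cfg: SimConfig, rng: np.random.Generator) -> tuple[list[PrecursorRecord], dict[str, str], dict]:
    """Precursor set + synthetic genome + bookkeeping of planted roles."""
    n_family_loci = 2 * cfg.n_multilocus_families
    n_paralog_loci = 2 * cfg.n_near_paralogs
    n_regular = cfg.n_precursors - n_family_loci - n_paralog_loci
    if n_regular < cfg.n_single_arm + 4:
        raise ValueError("n_precursors too small for the configured families/paralogs")

    accepted: list[str] = []
    records: list[PrecursorRecord] = []

    def new_mature() -> str:
        seq = _draw_mature(rng, accepted)
        accepted.append(seq)
        return seq

    # regular precursors: both arms except the last n_single_arm
    for i in range(n_regular):
        both = i < n_regular - cfg.n_single_arm
        m5 = (f"sim-miR-{i + 1}-5p", new_mature())
        m3 = (f"sim-miR-{i + 1}-3p", new_mature()) if both else None
        records.append(_build_precursor(rng, f"sim-mir-{i + 1}", m5, m3))

    # multi-locus families: one identical mature embedded in 2 loci
    for j in range(cfg.n_multilocus_families):
        seq = new_mature()
        for k in (1, 2):
            records.append(
                _build_precursor(rng, f"sim-mir-f{j + 1}-{k}", (f"sim-miR-f{j + 1}-5p", seq))
            )

    # near-paralog pairs: distinct matures at Hamming distance 2
    for j in range(cfg.n_near_paralogs):
        a = new_mature()
        b = list(a)
        pos = rng.choice(_MATURE_LEN - _CG_GUARD, size=2, replace=False)
        for p in pos:
            b[p] = rng.choice([c for c in _BASES if c != a[p]])
        b = "".join(b)
        accepted.append(b)
        records.append(_build_precursor(rng, f"sim-mir-p{j + 1}a", (f"sim-miR-p{j + 1}a-5p", a)))
        records.append(_build_precursor(rng, f"sim-mir-p{j + 1}b", (f"sim-miR-p{j + 1}b-5p", b)))

    # planted roles go to distinct regular both-arm matures
    roles = {
        "editing": [f"sim-miR-{i + 1}-5p" for i in range(len(cfg.editing))],
        "isomir_shift": "sim-miR-5-3p" if cfg.planted_isomir_shift else None,
        "adenylation_shift": "sim-miR-6-3p" if cfg.planted_adenylation_shift else None,
    }
    # force the reference base at each editing position to A (the substrate
    # of A-to-I deamination)
    for spec, mid in zip(cfg.editing, roles["editing"]):
        for idx, rec in enumerate(records):
            hit = [m for m in rec.matures if m.mature_id == mid]
            if not hit:
                continue
            m = hit[0]
            p = m.start + spec.position
            seq = rec.sequence[:p] + "A" + rec.sequence[p + 1 :]
            new_matures = tuple(
                MatureAnnotation(x.mature_id, x.arm, x.start, x.end, seq[x.start : x.end])
                for x in rec.matures
            )
            records[idx] = PrecursorRecord(rec.precursor_id, seq, new_matures)

    # synthetic genome: one chromosome, loci alternating strand with spacers
    chrom_parts: list[str] = []
    pos = 0
    placed: list[tuple[PrecursorRecord, GenomeLocus]] = []
    for i, rec in enumerate(records):
        spacer = _rand_seq(rng, 40)
        chrom_parts.append(spacer)
        pos += len(spacer)
        strand = "+" if i % 2 == 0 else "-"
        insert = rec.sequence if strand == "+" else revcomp(rec.sequence)
        locus = GenomeLocus("chrS", pos, pos + len(rec.sequence), strand)
        chrom_parts.append(insert)
        pos += len(insert)
        placed.append((rec, locus))
    chrom_parts.append(_rand_seq(rng, 40))
    genome = {"chrS": "".join(chrom_parts)}
    records = [
        PrecursorRecord(r.precursor_id, r.sequence, r.matures, genome_locus=loc)
        for r, loc in placed
    ]
    return records, genome, roles


# ---------------------------------------------------------------------------
# read generation


def _mature_universe(records: Sequence[PrecursorRecord]) -> list[tuple[str, str, str]]:
    """Unique matures as (mature_id, canonical context slice owner, precursor_id)."""
    seen = set()
    out = []
    for rec in records:
        for m in rec.matures:
            if m.mature_id in seen:
                continue  # multi-locus duplicates generate from one locus
            seen.add(m.mature_id)
            out.append((m.mature_id, rec.precursor_id, m))
    return out


def simulate(cfg: SimConfig) -> SimResult:
    """Generate reference + libraries + truth, fully determined by the seed."""
    rng = np.random.default_rng(cfg.seed)
    records, genome, roles = build_reference(cfg, rng)
    groups = build_multilocus_groups(records)
    rec_by_id = {r.precursor_id: r for r in records}

    matures = _mature_universe(records)
    mature_ids = [m[0] for m in matures]
    n = len(mature_ids)

    # baseline expression weights, shared across samples
    weights = np.exp(rng.normal(0.0, cfg.expression_sigma, n))
    # planted DE effects (tumor + metastasis vs normal), on matures free of
    # other planted roles
    reserved = {m for m in roles["editing"]}
    reserved |= {roles["isomir_shift"], roles["adenylation_shift"]} - {None}
    de_candidates = [
        i for i, mid in enumerate(mature_ids)
        if mid not in reserved and not mid.startswith(("sim-miR-f", "sim-miR-p"))
    ]
    de_idx = list(rng.choice(de_candidates, size=min(cfg.n_de_matures, len(de_candidates)), replace=False))
    log2fc = {mature_ids[i]: (cfg.de_log2fc if k % 2 == 0 else -cfg.de_log2fc)
              for k, i in enumerate(de_idx)}

    editing_by_mature: dict[str, EditingSpec] = {
        mid: spec for spec, mid in zip(cfg.editing, roles["editing"])
    }

    offset_keys = [k for k, _ in cfg.isomir_offset_dist]
    offset_probs = np.array([p for _, p in cfg.isomir_offset_dist])
    suffixes = [s for s, _ in cfg.nta_rates]

    libraries: list[Library] = []
    t_counts, t_iso, t_nta, t_edit = [], [], [], []

    for sample_id, tissue, patient in cfg.samples:
        w = weights.copy()
        for mid, fc in log2fc.items():
            if tissue in ("tumor", "metastasis"):
                w[mature_ids.index(mid)] *= 2.0 ** fc
        mature_counts = rng.multinomial(cfg.depth, w / w.sum())

        tag_counter: dict[str, int] = {}
        for (mid, prec_id, ann), total in zip(matures, mature_counts):
            if total == 0:
                continue
            t_counts.append({"sample_id": sample_id, "mature_id": mid, "count": int(total)})
            prec = rec_by_id[prec_id].sequence

            probs = offset_probs.copy()
            if mid == roles["isomir_shift"] and tissue == "tumor":
                i00 = offset_keys.index((0, 0))
                i01 = offset_keys.index((0, 1))
                probs[i00] -= cfg.planted_isomir_shift
                probs[i01] += cfg.planted_isomir_shift
            iso_counts = rng.multinomial(total, probs)

            nta_probs = np.array([r for _, r in cfg.nta_rates])
            if mid == roles["adenylation_shift"] and tissue == "tumor":
                nta_probs = nta_probs.copy()
                nta_probs[suffixes.index("A")] = cfg.planted_adenylation_shift
            nta_full = np.append(nta_probs, 1.0 - nta_probs.sum())

            spec = editing_by_mature.get(mid)
            freq = dict(spec.freq_by_tissue).get(tissue, 0.0) if spec else 0.0
            edit_alt = edit_cov = 0
            nta_tally: dict[str, int] = {}

            for (o5, o3), c in zip(offset_keys, iso_counts):
                if c == 0:
                    continue
                t_iso.append({"sample_id": sample_id, "mature_id": mid,
                              "offset5": o5, "offset3": o3, "count": int(c)})
                start, end = ann.start + o5, ann.end + o3
                base_seq = prec[start:end]
                covers = spec is not None and o5 <= spec.position < len(ann) + o3
                n_edited = int(rng.binomial(c, freq)) if covers and freq > 0 else 0
                if covers:
                    edit_cov += c
                    edit_alt += n_edited
                for edited, sub_c in ((True, n_edited), (False, c - n_edited)):
                    if sub_c == 0:
                        continue
                    if edited:
                        p = spec.position - o5
                        seq_t = base_seq[:p] + spec.alt + base_seq[p + 1 :]
                    else:
                        seq_t = base_seq
                    suffix_counts = rng.multinomial(sub_c, nta_full)
                    for sfx, sc in zip(suffixes + [""], suffix_counts):
                        if sc == 0:
                            continue
                        nta_tally[sfx] = nta_tally.get(sfx, 0) + int(sc)
                        read = seq_t + sfx
                        _emit(rng, tag_counter, read, int(sc), cfg.seq_error_rate,
                              edited_pos=(spec.position - o5 + 0) if edited else None,
                              ref_base=(base_seq[spec.position - o5] if edited else None))
            for sfx, sc in nta_tally.items():
                t_nta.append({"sample_id": sample_id, "mature_id": mid,
                              "nta_suffix": sfx, "count": sc})
            if spec is not None:
                t_edit.append({"sample_id": sample_id, "mature_id": mid,
                               "position": spec.position, "alt": spec.alt,
                               "alt_count": edit_alt, "covering": edit_cov,
                               "frequency": edit_alt / edit_cov if edit_cov else 0.0})

        tags = [Tag(s, c) for s, c in tag_counter.items()]
        tags.sort(key=lambda t: (-t.count, t.sequence))
        libraries.append(
            Library(sample_id=sample_id, tags=tags, library_size=cfg.depth,
                    tissue_type=tissue, patient_id=patient)
        )

    counts_df = pd.DataFrame(t_counts, columns=["sample_id", "mature_id", "count"])
    iso_df = pd.DataFrame(t_iso, columns=["sample_id", "mature_id", "offset5", "offset3", "count"])
    if len(iso_df):
        iso_df["fraction"] = iso_df["count"] / iso_df.groupby(["sample_id", "mature_id"])["count"].transform("sum")
    truth = SimTruth(
        counts=counts_df,
        isomirs=iso_df,
        nta=pd.DataFrame(t_nta, columns=["sample_id", "mature_id", "nta_suffix", "count"]),
        editing=pd.DataFrame(t_edit, columns=["sample_id", "mature_id", "position",
                                              "alt", "alt_count", "covering", "frequency"]),
        log2fc=pd.DataFrame(
            [{"mature_id": m, "log2fc_tumor_vs_normal": fc} for m, fc in sorted(log2fc.items())]
        ),
        planted=roles,
        mature_weights=pd.Series(weights, index=mature_ids),
    )
    return SimResult(config=cfg, records=records, groups=groups, genome=genome,
                     libraries=libraries, truth=truth)


def _emit(
    rng: np.random.Generator,
    counter: dict[str, int],
    read: str,
    count: int,
    error_rate: float,
    edited_pos: Optional[int],
    ref_base: Optional[str],
) -> None:
    """Add `count` copies of `read`, with per-base substitution errors.

    Only the (binomially drawn) errored reads are materialised one by one;
    error-free copies are added in bulk.  An error landing on an edited
    position never restores the pre-editing reference base, so planted
    editing frequencies are not diluted upward or downward by the error
    model.
    """
    if error_rate <= 0:
        counter[read] = counter.get(read, 0) + count
        return
    L = len(read)
    p_any = 1.0 - (1.0 - error_rate) ** L
    n_err = int(rng.binomial(count, p_any))
    if count - n_err:
        counter[read] = counter.get(read, 0) + (count - n_err)
    for _ in range(n_err):
        while True:
            flags = rng.random(L) < error_rate
            if flags.any():
                break
        chars = list(read)
        for p in np.nonzero(flags)[0]:
            p = int(p)
            options = [b for b in _BASES if b != chars[p]]
            if edited_pos is not None and p == edited_pos and ref_base in options:
                options.remove(ref_base)
            chars[p] = options[int(rng.integers(len(options)))]
        mutated = "".join(chars)
        counter[mutated] = counter.get(mutated, 0) + 1


# ---------------------------------------------------------------------------
# analytic mapping-fraction oracle


def expected_mapping_fractions(cfg: SimConfig, aligner_cfg: Optional[AlignerConfig] = None) -> dict:
    """Closed-form expected per-step mapped-read fractions for a config.

    For each generative cell (offset pair x NTA suffix x edited-or-not) the
    number of unavoidable mismatches after maximal admissible 3' trimming
    is a constant plus a Binomial(L_prefix, e) error count, where L_prefix
    is the non-trimmable read prefix; the read maps at the first step
    whose allowance covers that number.  Averaging over cell probabilities
    gives exact expectations under two simplifications: sequencing errors
    never create a better hit elsewhere, and suffix bases never match the
    template (guaranteed by the C/G guard design).
    """
    acfg = aligner_cfg or AlignerConfig.precursor_default()
    ladder = acfg.mismatch_ladder
    L_mat = _MATURE_LEN
    e = cfg.seq_error_rate

    # editing affects only its target matures; weight its cells by the
    # expected expression share of those matures (approximated as the mean
    # share, 1/n_matures each, which is exact in expectation over seeds)
    n_family = cfg.n_multilocus_families
    n_paralog = 2 * cfg.n_near_paralogs
    n_regular = cfg.n_precursors - 2 * n_family - n_paralog
    n_matures = (n_regular - cfg.n_single_arm) * 2 + cfg.n_single_arm + n_family + n_paralog
    edit_weight = len(cfg.editing) / n_matures
    mean_freq = (
        float(np.mean([f for _, f in cfg.editing[0].freq_by_tissue])) if cfg.editing else 0.0
    )

    nta = list(cfg.nta_rates) + [("", 1.0 - sum(r for _, r in cfg.nta_rates))]
    step_p = {s: 0.0 for s in range(len(ladder))}
    p_unmapped = 0.0
    for (o5, o3), p_off in cfg.isomir_offset_dist:
        L_t = L_mat + o3 - o5
        for sfx, p_sfx in nta:
            L = L_t + len(sfx)
            for edited, p_e in ((False, 1.0 - edit_weight * mean_freq),
                                (True, edit_weight * mean_freq)):
                p_cell = p_off * p_sfx * p_e
                t_lo = max(0, o3 + len(sfx) - acfg.window)
                t_hi = min(L - acfg.min_length, o3 + len(sfx) + acfg.window)
                if acfg.max_trim is not None:
                    t_hi = min(t_hi, acfg.max_trim)
                if t_hi < t_lo:
                    p_unmapped += p_cell
                    continue
                prefix = L - t_hi
                mand = max(0, len(sfx) - t_hi)  # suffix bases that cannot be trimmed
                edit_in_prefix = edited and cfg.editing and (
                    cfg.editing[0].position - o5
                ) < prefix
                base_mm = mand + (1 if edit_in_prefix else 0)
                n_err_pos = prefix - mand - (1 if edit_in_prefix else 0)
                for s, allow in enumerate(ladder):
                    k = allow - base_mm
                    prev = ladder[s - 1] - base_mm if s else -1
                    if k < 0:
                        continue
                    p_map = binom.cdf(k, n_err_pos, e) - (
                        binom.cdf(prev, n_err_pos, e) if prev >= 0 else 0.0
                    )
                    step_p[s] += p_cell * p_map
                if ladder[-1] >= base_mm:
                    p_unmapped += p_cell * (1.0 - binom.cdf(ladder[-1] - base_mm, n_err_pos, e))
                else:
                    p_unmapped += p_cell
    total = sum(step_p.values())
    return {"per_step": step_p, "mapped": total, "unmapped": 1.0 - total}


# ---------------------------------------------------------------------------
# file emission


def write_outputs(result: SimResult, outdir: str | Path) -> dict[str, Path]:
    """Write reference, genome, per-sample collapsed FASTA and truth TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "precursors": outdir / "precursors.fa",
        "matures": outdir / "matures.gff3",
        "genome": outdir / "genome.fa",
        "samples": outdir / "samples.tsv",
    }
    write_reference(result.records, paths["precursors"], paths["matures"])
    with open(paths["genome"], "w") as fh:
        for name, seq in result.genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
    rows = []
    for lib in result.libraries:
        fasta = outdir / f"{lib.sample_id}.collapsed.fa"
        write_collapsed_fasta(lib, fasta)
        rows.append({"sample_id": lib.sample_id, "tissue_type": lib.tissue_type,
                     "patient_id": lib.patient_id, "path": fasta.name})
    pd.DataFrame(rows).to_csv(paths["samples"], sep="\t", index=False)
    truth_dir = outdir / "truth"
    truth_dir.mkdir(exist_ok=True)
    t = result.truth
    for name, df in (("counts", t.counts), ("isomirs", t.isomirs), ("nta", t.nta),
                     ("editing", t.editing), ("log2fc", t.log2fc)):
        df.to_csv(truth_dir / f"{name}.tsv", sep="\t", index=False)
    with open(truth_dir / "planted.json", "w") as fh:
        json.dump(t.planted, fh, indent=2)
    return paths
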