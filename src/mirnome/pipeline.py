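"""End-to-end orchestration: map -> quantify -> isoforms -> arms -> editing.

``run_all`` drives every stage over a reference + sample sheet and writes
one TSV per stage plus a ``summary.json`` whose every number is
re-derivable from the stage TSVs.  All randomness in the pipeline proper
is nil (the simulator owns the only seed), so a re-run on identical inputs
is byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from . import aligner as al
from . import editing as ed
from . import isoforms as iso
from . import quantify as qt
from .reference_io import PrecursorRecord, build_multilocus_groups, load_reference
from .tag_io import Library, load_libraries, read_sample_sheet

logger = logging.getLogger(__name__)

_CANONICAL_ORDER = ("normal", "tumor", "metastasis")


@dataclass
class PipelineConfig:
    precursors: str
    matures: str
    samples: str
    outdir: str
    genome: Optional[str] = None
    mode: str = "precursor"
    mismatch_ladder: tuple[int, ...] = (0, 1, 2)
    min_length: int = 18
    window: int = 5
    max_trim: Optional[int] = None
    min_cpm: float = 1.0
    min_samples: int = 3
    min_isomir_fraction: float = 0.01
    min_reads: int = 100
    shift_threshold: float = 0.20
    arm_fc_hi: float = 1.5
    arm_fc_lo: float = 0.66
    edit_min_coverage: int = 100
    edit_min_frequency: float = 0.05
    edit_min_alt_count: int = 10
    edit_edge_exclusion: int = 2
    per_locus_rows: bool = False
    use_tmm: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "mismatch_ladder" in raw:
            raw["mismatch_ladder"] = tuple(raw["mismatch_ladder"])
        return cls(**raw)

    def aligner_config(self) -> al.AlignerConfig:
        return al.AlignerConfig(
            mismatch_ladder=tuple(self.mismatch_ladder),
            min_length=self.min_length,
            max_trim=self.max_trim,
            window=self.window,
            mode=self.mode,
        )


def default_contrasts(tissues: Sequence[str]) -> list[tuple[str, str]]:
    """Ordered tissue contrasts: (tumor, normal), (metastasis, normal), (metastasis, tumor)
    when those labels exist; otherwise all ordered pairs in sorted order."""
    present = set(tissues)
    if present <= set(_CANONICAL_ORDER):
        order = [t for t in _CANONICAL_ORDER if t in present]
        return [(b, a) for i, a in enumerate(order) for b in order[i + 1 :]]
    ts = sorted(present)
    return [(b, a) for i, a in enumerate(ts) for b in ts[i + 1 :]]


def run_all(
    cfg: PipelineConfig,
    records: Optional[list[PrecursorRecord]] = None,
    libraries: Optional[list[Library]] = None,
    genome: Optional[dict[str, str]] = None,
) -> dict:
    """Run the full miRNome analysis; returns the summary dict.

    Inputs may be passed in memory (as the simulator produces them) or
    loaded from the configured paths.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if records is None:
        records = load_reference(cfg.precursors, cfg.matures)
    if libraries is None:
        sheet = read_sample_sheet(cfg.samples)
        libraries = load_libraries(sheet, Path(cfg.samples).parent)
    if genome is None and cfg.genome:
        from Bio import SeqIO

        genome = {r.id: str(r.seq).upper() for r in SeqIO.parse(cfg.genome, "fasta")}
    if cfg.mode == "genome" and genome is None:
        raise ValueError("genome mode requires a genome FASTA")

    groups = build_multilocus_groups(records)
    acfg = cfg.aligner_config()
    index = al.ReferenceIndex(records, groups, mode=cfg.mode, genome=genome)

    sample_tissue = {lib.sample_id: lib.tissue_type for lib in libraries}
    metadata = pd.DataFrame(
        [{"sample_id": l.sample_id, "tissue_type": l.tissue_type, "patient_id": l.patient_id}
         for l in libraries]
    )
    contrasts = default_contrasts(list(sample_tissue.values()))

    # --- mapping ----------------------------------------------------------
    assignments_by_sample: dict[str, list[al.TagAssignment]] = {}
    stats_rows = []
    assign_rows = []
    for lib in libraries:
        assignments, stats = al.align_library(lib, index, acfg)
        assignments_by_sample[lib.sample_id] = assignments
        logger.info("%s: %d/%d tags mapped (%.1f%% of reads)", lib.sample_id,
                    stats.mapped_tags, stats.total_tags, 100 * stats.mapped_fraction)
        row = {"sample_id": lib.sample_id, "total_reads": stats.total_reads,
               "mapped_reads": stats.mapped_reads,
               "mapped_fraction": stats.mapped_fraction}
        for s in range(len(acfg.mismatch_ladder)):
            row[f"step{s}_reads"] = stats.mapped_reads_per_step.get(s, 0)
            row[f"step{s}_fraction"] = stats.step_fraction(s)
        for reason in al.UNMAPPED_REASONS:
            row[f"unmapped_{reason}"] = stats.unmapped_reads_by_reason.get(reason, 0)
        stats_rows.append(row)
        assign_rows.extend(al.assignments_to_rows(lib.sample_id, assignments))
    stats_df = pd.DataFrame(stats_rows)
    stats_df.to_csv(outdir / "mapping_stats.tsv", sep="\t", index=False)
    pd.DataFrame(assign_rows).sort_values(["sample_id", "sequence"]).to_csv(
        outdir / "assignments.tsv", sep="\t", index=False
    )

    # --- quantification ---------------------------------------------------
    matrix = qt.count_matrix(assignments_by_sample, libraries, per_locus_rows=cfg.per_locus_rows)
    if cfg.use_tmm:
        matrix = qt.apply_tmm(matrix)
    matrix.counts.rename_axis("mature_id").to_csv(outdir / "counts.tsv", sep="\t")
    matrix.cpm.rename_axis("mature_id").to_csv(outdir / "cpm.tsv", sep="\t", float_format="%.6f")
    filtered = qt.cpm_filter(matrix, cfg.min_cpm, min(cfg.min_samples, matrix.counts.shape[1]))
    filtered.counts.rename_axis("mature_id").to_csv(outdir / "counts.filtered.tsv", sep="\t")
    qt.export_de_inputs(filtered, metadata, str(outdir / "de_counts.tsv"),
                        str(outdir / "de_design.tsv"))
    fc_frames = []
    for a, b in contrasts:
        try:
            fcs = qt.paired_log2fc(filtered, metadata, (a, b))
        except ValueError:
            continue
        fc_frames.append(pd.DataFrame(
            [{"mature_id": f.base_name, "tissue_a": a, "tissue_b": b, "log2fc": f.fc}
             for f in fcs]
        ))
    fc_df = pd.concat(fc_frames, ignore_index=True) if fc_frames else pd.DataFrame(
        columns=["mature_id", "tissue_a", "tissue_b", "log2fc"]
    )
    fc_df.to_csv(outdir / "paired_log2fc.tsv", sep="\t", index=False, float_format="%.6f")

    # --- isomiRs ----------------------------------------------------------
    table = iso.isomir_table(assignments_by_sample)
    table.to_csv(outdir / "isomir_table.tsv", sep="\t", index=False, float_format="%.6g")
    hist, chi2 = iso.isomir_count_distribution(
        table, sample_tissue, cfg.min_isomir_fraction, cfg.min_reads
    )
    hist.to_csv(outdir / "isomir_histogram.tsv", sep="\t")
    classes = iso.classify_isomirs(table)
    classes.to_csv(outdir / "isomir_classes.tsv", sep="\t", index=False, float_format="%.6g")
    totals = table.groupby(["sample_id", "mature_id"])["count"].sum()
    summary_classes = iso.class_contribution_summary(classes, totals, cfg.min_reads)
    summary_classes.to_csv(outdir / "isomir_class_summary.tsv", sep="\t", float_format="%.6g")
    shifts = iso.isomir_shift_screen(table, sample_tissue, contrasts, cfg.shift_threshold)
    shifts.to_csv(outdir / "isomir_shifts.tsv", sep="\t", index=False, float_format="%.6g")

    # --- NTA --------------------------------------------------------------
    profiles, suffix_counts = iso.nta_tables(assignments_by_sample)
    profiles.to_csv(outdir / "nta_profiles.tsv", sep="\t", index=False, float_format="%.6g")
    suffix_counts.to_csv(outdir / "nta_suffixes.tsv", sep="\t", index=False, float_format="%.6g")
    nta_summary = iso.nta_contribution_summary(suffix_counts, profiles, cfg.min_reads,
                                               cfg.min_isomir_fraction)
    nta_screens = iso.nta_screens(profiles, sample_tissue, contrasts,
                                  delta=cfg.shift_threshold)
    nta_screens["shift_hits"].to_csv(outdir / "nta_shifts.tsv", sep="\t", index=False,
                                     float_format="%.6g")

    # --- arm ratios -------------------------------------------------------
    arm_results = {}
    for mode in ("all_isoforms", "canonical_only"):
        expr = iso.arm_expression(assignments_by_sample, libraries, records, mode)
        res = iso.arm_ratios(expr, sample_tissue, contrasts, mode,
                             cfg.arm_fc_hi, cfg.arm_fc_lo)
        pd.DataFrame(
            [{"precursor_id": r.precursor_id, "tissue_type": r.tissue_type,
              "ratio": r.ratio, "dominant_arm": r.dominant_arm, "mode": mode}
             for r in res["records"]]
        ).to_csv(outdir / f"arm_ratios.{mode}.tsv", sep="\t", index=False,
                 float_format="%.6g")
        res["screen_hits"].to_csv(outdir / f"arm_screen.{mode}.tsv", sep="\t",
                                  index=False, float_format="%.6g")
        res["inversions"].to_csv(outdir / f"arm_inversions.{mode}.tsv", sep="\t", index=False)
        arm_results[mode] = res

    # --- editing ----------------------------------------------------------
    canonical_seqs = {}
    mature_lengths = {}
    for rec in records:
        for m in rec.matures:
            canonical_seqs[m.mature_id] = m.canonical_sequence
            mature_lengths[m.mature_id] = len(m)
    pile = ed.pileup(assignments_by_sample, mature_lengths)
    sites = ed.call_sites(pile, canonical_seqs, cfg.edit_min_coverage,
                          cfg.edit_min_frequency, cfg.edit_min_alt_count,
                          cfg.edit_edge_exclusion)
    ed.sites_to_frame(sites).to_csv(outdir / "editing_sites.tsv", sep="\t",
                                    index=False, float_format="%.6g")
    comp = ed.compare_frequencies(sites, sample_tissue, contrasts)
    comp.to_csv(outdir / "editing_compare.tsv", sep="\t", index=False, float_format="%.6g")

    # --- summary ----------------------------------------------------------
    summary = {
        "n_samples": len(libraries),
        "n_precursors": len(records),
        "n_mature_groups": len(groups),
        "mapping": {
            "overall_mapped_fraction": float(stats_df["mapped_reads"].sum()
                                             / stats_df["total_reads"].sum()),
            "per_step_fraction": {
                f"step{s}": float(stats_df[f"step{s}_reads"].sum()
                                  / stats_df["total_reads"].sum())
                for s in range(len(acfg.mismatch_ladder))
            },
        },
        "n_expressed_after_cpm_filter": int(filtered.counts.shape[0]),
        "isomir_histogram": {t: {str(b): int(v) for b, v in row.items()}
                             for t, row in hist.iterrows()} if len(hist) else {},
        "isomir_chi2": {"statistic": chi2[0], "p_value": chi2[1], "dof": chi2[2]}
        if chi2 else None,
        "n_isomir_shift_hits": int(len(shifts)),
        "nta_global_contributions": {k: float(v) for k, v in nta_summary.items()},
        "n_nta_shift_hits": int(len(nta_screens["shift_hits"])),
        "arm_screen_hits": {m: int(len(arm_results[m]["screen_hits"])) for m in arm_results},
        "arm_inversions": {m: int(len(arm_results[m]["inversions"])) for m in arm_results},
        "n_editing_sites": len(sites),
        "n_editing_AtoI": sum(1 for s in sites if s.is_AtoI),
        "parameters": {
            "mode": cfg.mode, "mismatch_ladder": list(cfg.mismatch_ladder),
            "min_length": cfg.min_length, "window": cfg.window,
            "max_trim": cfg.max_trim, "min_cpm": cfg.min_cpm,
            "min_samples": cfg.min_samples,
            "min_isomir_fraction": cfg.min_isomir_fraction,
            "min_reads": cfg.min_reads, "shift_threshold": cfg.shift_threshold,
            "arm_fc_hi": cfg.arm_fc_hi, "arm_fc_lo": cfg.arm_fc_lo,
            "edit_min_coverage": cfg.edit_min_coverage,
            "edit_min_frequency": cfg.edit_min_frequency,
            "edit_min_alt_count": cfg.edit_min_alt_count,
            "edit_edge_exclusion": cfg.edit_edge_exclusion,
        },
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
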