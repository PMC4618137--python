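"""Count matrices, CPM normalisation, expression filter and paired fold changes.

Two accounting pitfalls drive the design here.  First, multi-locus miRNAs
(one mature encoded at several loci) must not be counted once per locus:
rows are keyed by the multi-locus group, so a tag contributes once however
many loci it matched.  A ``per_locus_rows`` switch reproduces per-locus
accounting for comparison with pipelines that suffer from the double
counting.  Second, library sizes are taken from the ingest step (total
individual clean reads per sample), never from column sums of the miRNA
count matrix — column sums both miss non-miRNA reads and, in per-locus
mode, inflate with the duplicated multi-locus mass.

CPM = count / library_size * 1e6.  The expression filter keeps miRNAs with
CPM >= min_cpm in >= min_samples samples (defaults 1 CPM / 3 samples).
Paired log2 fold changes are computed per patient with a pseudocount and
summarised as the mean over patients; the negative-binomial GLM testing
that typically follows is delegated to external DE tools via the exported
count matrix + design table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .aligner import TagAssignment
from .tag_io import Library

logger = logging.getLogger(__name__)


@dataclass
class ExpressionMatrix:
    """miRNA x sample counts with per-sample library sizes.

    ``counts`` rows are mature base names (one row per multi-locus group
    unless built with per_locus_rows); ``lib_sizes`` is indexed like the
    columns.  ``norm_factors`` default to 1 and rescale the effective
    library sizes when TMM normalisation is applied.
    """

    counts: pd.DataFrame  # int, rows = mature base_name, cols = sample_id
    lib_sizes: pd.Series  # int, index = sample_id
    norm_factors: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        if list(self.counts.columns) != list(self.lib_sizes.index):
            raise ValueError("lib_sizes index must match count matrix columns")
        if (self.lib_sizes <= 0).any():
            raise ValueError("library sizes must be positive")

    @property
    def effective_lib_sizes(self) -> pd.Series:
        if self.norm_factors is None:
            return self.lib_sizes.astype(float)
        return self.lib_sizes * self.norm_factors

    @property
    def cpm(self) -> pd.DataFrame:
        return self.counts / self.effective_lib_sizes * 1e6


def count_matrix(
    assignments_by_sample: dict[str, Sequence[TagAssignment]],
    libraries: Sequence[Library],
    per_locus_rows: bool = False,
) -> ExpressionMatrix:
    """Tally mapped reads into a miRNA x sample count matrix.

    Default rows are multi-locus groups (a tag matching the 3 let-7a loci
    adds its count once, to the shared hsa-let-7a-5p row).  With
    ``per_locus_rows`` the tag's count is replicated onto one row per
    member locus (suffix ``@precursor``), reproducing the double counting
    some pipelines exhibit.
    """
    lib_by_id = {lib.sample_id: lib for lib in libraries}
    missing = set(lib_by_id) - set(assignments_by_sample)
    for sample in sorted(missing):
        logger.warning("sample %s has no assignments; zero column emitted", sample)

    tallies: dict[str, dict[str, int]] = {}
    for sample, assignments in assignments_by_sample.items():
        if sample not in lib_by_id:
            raise ValueError(f"assignments for unknown sample {sample!r}")
        col = tallies.setdefault(sample, {})
        for a in assignments:
            if per_locus_rows:
                for prec in a.group.member_precursors:
                    key = f"{a.group.base_name}@{prec}"
                    col[key] = col.get(key, 0) + a.tag.count
            else:
                key = a.group.base_name
                col[key] = col.get(key, 0) + a.tag.count

    samples = [lib.sample_id for lib in libraries]
    rows = sorted({k for col in tallies.values() for k in col})
    counts = pd.DataFrame(0, index=rows, columns=samples, dtype=int)
    for sample, col in tallies.items():
        for key, n in col.items():
            counts.loc[key, sample] = n
    lib_sizes = pd.Series({lib.sample_id: lib.library_size for lib in libraries})[samples]
    return ExpressionMatrix(counts=counts, lib_sizes=lib_sizes)


def cpm_filter(m: ExpressionMatrix, min_cpm: float = 1.0, min_samples: int = 3) -> ExpressionMatrix:
    """Keep rows with CPM >= min_cpm in at least min_samples samples."""
    if min_samples > m.counts.shape[1]:
        raise ValueError("min_samples exceeds the number of samples")
    keep = (m.cpm >= min_cpm).sum(axis=1) >= min_samples
    return ExpressionMatrix(
        counts=m.counts.loc[keep],
        lib_sizes=m.lib_sizes,
        norm_factors=m.norm_factors,
    )


def tmm_norm_factors(
    m: ExpressionMatrix,
    logratio_trim: float = 0.30,
    abs_expr_trim: float = 0.05,
) -> pd.Series:
    """Trimmed-mean-of-M-values normalisation factors.

    The standard TMM recipe: pick as reference the sample whose upper
    quartile (of CPM) is closest to the mean upper quartile, then for each
    sample compute the weighted mean of gene-wise log2 ratios (M values)
    after trimming 30 % of the most extreme M values and 5 % of the most
    extreme average abundances (A values), with inverse-variance weights
    from the binomial delta method.  Factors are rescaled to multiply to 1.
    """
    counts = m.counts.to_numpy(dtype=float)
    lib = m.lib_sizes.to_numpy(dtype=float)
    frac = counts / lib  # relative abundances
    uq = np.array([np.quantile(frac[:, j][counts[:, j] > 0], 0.75) if (counts[:, j] > 0).any() else 0 for j in range(frac.shape[1])])
    ref_j = int(np.argmin(np.abs(uq - uq.mean())))
    ref = frac[:, ref_j]
    ref_lib = lib[ref_j]

    factors = np.ones(frac.shape[1])
    for j in range(frac.shape[1]):
        if j == ref_j:
            continue
        obs = frac[:, j]
        ok = (obs > 0) & (ref > 0)
        if ok.sum() < 5:
            continue
        M = np.log2(obs[ok] / ref[ok])
        A = 0.5 * np.log2(obs[ok] * ref[ok])
        w = 1.0 / (
            (1 - obs[ok]) / (obs[ok] * lib[j]) + (1 - ref[ok]) / (ref[ok] * ref_lib)
        )
        n = len(M)
        lo_m, hi_m = np.floor(n * logratio_trim) + 1, n + 1 - (np.floor(n * logratio_trim) + 1)
        lo_a, hi_a = np.floor(n * abs_expr_trim) + 1, n + 1 - (np.floor(n * abs_expr_trim) + 1)
        rank_m = pd.Series(M).rank().to_numpy()
        rank_a = pd.Series(A).rank().to_numpy()
        keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
        if keep.sum() == 0:
            continue
        factors[j] = 2 ** (np.sum(w[keep] * M[keep]) / np.sum(w[keep]))
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=m.counts.columns)


def apply_tmm(m: ExpressionMatrix) -> ExpressionMatrix:
    """Return a copy of the matrix with TMM normalisation factors attached."""
    return ExpressionMatrix(counts=m.counts, lib_sizes=m.lib_sizes,
                            norm_factors=tmm_norm_factors(m))


@dataclass(frozen=True)
class FoldChange:
    base_name: str
    contrast: tuple[str, str]  # (tissue_a, tissue_b): fc = log2(a / b)
    fc: float  # mean over patients
    per_patient_fc: tuple[tuple[str, float], ...]


def paired_log2fc(
    m: ExpressionMatrix,
    metadata: pd.DataFrame,
    contrast: tuple[str, str],
    pseudocount_cpm: float = 0.5,
) -> list[FoldChange]:
    """Per-patient paired log2 fold changes in CPM for one tissue contrast.

    For each patient with at least one sample of each contrast tissue,
    fc = log2((cpm_a + pc) / (cpm_b + pc)) using the patient's mean CPM per
    tissue; the summary fc is the mean over patients.  Patients missing a
    tissue are excluded (and logged).  Antisymmetric by construction:
    swapping the contrast negates every fc.
    """
    tissue_a, tissue_b = contrast
    cpm = m.cpm
    meta = metadata.set_index("sample_id")
    usable_patients: list[tuple[str, list[str], list[str]]] = []
    for patient, sub in meta.groupby("patient_id"):
        sa = [s for s in sub.index[sub["tissue_type"] == tissue_a] if s in cpm.columns]
        sb = [s for s in sub.index[sub["tissue_type"] == tissue_b] if s in cpm.columns]
        if sa and sb:
            usable_patients.append((str(patient), sa, sb))
        else:
            logger.info("patient %s lacks a %s/%s pair; excluded from contrast",
                        patient, tissue_a, tissue_b)
    if not usable_patients:
        raise ValueError(f"no patient has both {tissue_a} and {tissue_b} samples")

    out = []
    for base_name in cpm.index:
        per_patient = []
        for patient, sa, sb in usable_patients:
            a = cpm.loc[base_name, sa].mean() + pseudocount_cpm
            b = cpm.loc[base_name, sb].mean() + pseudocount_cpm
            per_patient.append((patient, float(np.log2(a / b))))
        out.append(
            FoldChange(
                base_name=base_name,
                contrast=contrast,
                fc=float(np.mean([f for _, f in per_patient])),
                per_patient_fc=tuple(per_patient),
            )
        )
    return out


def export_de_inputs(
    m: ExpressionMatrix,
    metadata: pd.DataFrame,
    counts_tsv: str,
    design_tsv: str,
) -> None:
    """Write the count matrix + design table consumed by external DE tools."""
    m.counts.rename_axis("mature_id").to_csv(counts_tsv, sep="\t")
    cols = ["sample_id", "tissue_type", "patient_id"]
    design = metadata[cols].copy()
    design["lib_size"] = design["sample_id"].map(m.lib_sizes)
    design.to_csv(design_tsv, sep="\t", index=False)
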