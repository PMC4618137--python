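"""Isoform-level analytics: isomiRs, 3' non-templated additions, arm ratios.

An *isomiR* here is a genome-templated end variant of a mature miRNA,
identified by its signed 5' and 3' end offsets from the canonical
coordinates.  The NTA suffix is deliberately NOT part of isomiR identity:
two reads with the same templated ends but different 3' additions are one
isomiR (the additions are analysed on their own axis).  An
``include_nta`` switch restores suffix-inclusive accounting for
comparison with pipelines that do not trim NTAs.

Thresholds used throughout (all configurable at call sites):

* an isomiR is *present* in a sample when it carries >= 1 % of its
  mature's mapped reads there — this separates real isoforms from
  sequencing/trimming noise;
* distribution statistics only consider matures covered by >= 100 mapped
  reads;
* contribution shifts of >= 20 percentage points between tissue-type
  means are flagged by the screens;
* arm-ratio screens flag 5p/3p ratio fold changes > 1.5 or < 0.66 between
  tissue types, and separately any inversion of the dominant arm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import pandas as pd
from scipy import stats as sps

from .aligner import TagAssignment
from .reference_io import PrecursorRecord
from .tag_io import Library

logger = logging.getLogger(__name__)

ISOMIR_CLASSES = ("canonical", "end_site_3p", "start_site_5p", "both_sites")
NTA_CLASSES = ("adenylated", "uridylated", "other_single", "mixed")


def classify_offsets(offset5: int, offset3: int) -> str:
    """IsomiR class from signed end offsets."""
    if offset5 == 0 and offset3 == 0:
        return "canonical"
    if offset5 == 0:
        return "end_site_3p"
    if offset3 == 0:
        return "start_site_5p"
    return "both_sites"


def classify_suffix(suffix: str) -> str:
    """NTA class of a non-empty 3' suffix (DNA alphabet; T encodes U)."""
    bases = set(suffix)
    if bases == {"A"}:
        return "adenylated"
    if bases == {"T"}:
        return "uridylated"
    if len(bases) == 1:
        return "other_single"
    return "mixed"


# ---------------------------------------------------------------------------
# isomiR tables


def isomir_table(
    assignments_by_sample: Mapping[str, Sequence[TagAssignment]],
    include_nta: bool = False,
) -> pd.DataFrame:
    """Aggregate assignments to per-sample isomiR counts.

    Columns: sample_id, mature_id (group base name), offset5, offset3,
    [nta_suffix,] count, fraction (of the mature's mapped reads in that
    sample).
    """
    rows = []
    for sample, assignments in assignments_by_sample.items():
        agg: dict[tuple, int] = {}
        for a in assignments:
            key = (a.group.base_name, a.offset5, a.offset3)
            if include_nta:
                key = key + (a.nta_suffix,)
            agg[key] = agg.get(key, 0) + a.tag.count
        for key, count in agg.items():
            row = {"sample_id": sample, "mature_id": key[0],
                   "offset5": key[1], "offset3": key[2], "count": count}
            if include_nta:
                row["nta_suffix"] = key[3]
            rows.append(row)
    cols = ["sample_id", "mature_id", "offset5", "offset3"]
    if include_nta:
        cols.append("nta_suffix")
    df = pd.DataFrame(rows, columns=cols + ["count"])
    if len(df):
        totals = df.groupby(["sample_id", "mature_id"])["count"].transform("sum")
        df["fraction"] = df["count"] / totals
        df = df.sort_values(cols).reset_index(drop=True)
    else:
        df["fraction"] = pd.Series(dtype=float)
    return df


def present_isomirs(
    table: pd.DataFrame, min_fraction: float = 0.01
) -> dict[str, dict[str, set[tuple[int, int]]]]:
    """Per sample, per mature: the set of isomiR keys present at >= min_fraction."""
    out: dict[str, dict[str, set[tuple[int, int]]]] = {}
    for row in table.itertuples(index=False):
        if row.fraction >= min_fraction:
            out.setdefault(row.sample_id, {}).setdefault(row.mature_id, set()).add(
                (row.offset5, row.offset3)
            )
    return out


def isomir_count_distribution(
    table: pd.DataFrame,
    sample_tissue: Mapping[str, str],
    min_fraction: float = 0.01,
    min_reads: int = 100,
) -> tuple[pd.DataFrame, Optional[tuple[float, float, int]]]:
    """Distribution of the number of isomiRs per mature miRNA, by tissue type.

    Matures are considered in a sample only when covered by >= min_reads
    mapped reads there.  Per-sample isomiR counts are averaged over the
    samples of each tissue type (rounded to the nearest bin for the
    histogram).  Returns the tissue x bin contingency table and, when
    several tissues are present, the chi-squared independence test as
    (statistic, p-value, dof); with one tissue the test is skipped (None).
    """
    present = present_isomirs(table, min_fraction)
    totals = table.groupby(["sample_id", "mature_id"])["count"].sum()
    counts = []  # (tissue, mature, n_isomirs per sample)
    for (sample, mature), total in totals.items():
        if total < min_reads:
            continue
        n = len(present.get(sample, {}).get(mature, set()))
        counts.append((sample_tissue[sample], mature, n))
    if not counts:
        return pd.DataFrame(), None
    df = pd.DataFrame(counts, columns=["tissue_type", "mature_id", "n_isomirs"])
    means = df.groupby(["tissue_type", "mature_id"])["n_isomirs"].mean()
    binned = means.round().astype(int).rename("bin").reset_index()
    hist = (
        binned.groupby(["tissue_type", "bin"]).size().unstack(fill_value=0).sort_index(axis=1)
    )
    test = None
    if hist.shape[0] > 1:
        # drop all-zero bins to keep the contingency table valid
        tab = hist.loc[:, hist.sum(axis=0) > 0]
        if tab.shape[1] > 1:
            chi2, p, dof, _ = sps.chi2_contingency(tab.to_numpy())
            test = (float(chi2), float(p), int(dof))
    return hist, test


# ---------------------------------------------------------------------------
# isomiR classes


def _dominant_isomirs(
    table: pd.DataFrame,
    sample_tissue: Mapping[str, str],
    normal_label: str = "normal",
) -> dict[str, tuple[int, int]]:
    """Per mature, the isomiR with the highest mean contribution in normal samples.

    Ties break toward the miRBase canonical (0, 0), then the smallest
    |offset5| + |offset3|, then lexicographically for determinism.
    """
    normals = {s for s, t in sample_tissue.items() if t == normal_label}
    if not normals:
        raise ValueError(f"no sample has tissue type {normal_label!r}")
    sub = table[table["sample_id"].isin(normals)]
    out: dict[str, tuple[int, int]] = {}
    for mature, grp in sub.groupby("mature_id"):
        mean_frac = grp.groupby(["offset5", "offset3"])["fraction"].mean()
        best = mean_frac.max()
        ties = [k for k, v in mean_frac.items() if v == best]
        ties.sort(key=lambda k: (k != (0, 0), abs(k[0]) + abs(k[1]), k))
        out[mature] = ties[0]
    return out


def classify_isomirs(
    table: pd.DataFrame,
    canonical_source: str = "mirbase",
    sample_tissue: Optional[Mapping[str, str]] = None,
    normal_label: str = "normal",
) -> pd.DataFrame:
    """Per mature x sample contribution of each isomiR class.

    ``canonical_source='mirbase'`` classes offsets against the annotated
    canonical coordinates.  ``'normal_dominant'`` first redefines the
    canonical of each mature as its most expressed isomiR across the
    normal samples and re-expresses all offsets relative to it before
    classing (so the dominant isoform becomes class 'canonical').
    Returns columns sample_id, mature_id, class, fraction; fractions sum
    to 1 per mature x sample.
    """
    if canonical_source not in ("mirbase", "normal_dominant"):
        raise ValueError(f"unknown canonical_source {canonical_source!r}")
    df = table.copy()
    if canonical_source == "normal_dominant":
        if sample_tissue is None:
            raise ValueError("normal_dominant mode requires sample_tissue")
        dom = _dominant_isomirs(df, sample_tissue, normal_label)
        d5 = df["mature_id"].map(lambda m: dom.get(m, (0, 0))[0])
        d3 = df["mature_id"].map(lambda m: dom.get(m, (0, 0))[1])
        df["offset5"] = df["offset5"] - d5
        df["offset3"] = df["offset3"] - d3
    df["isomir_class"] = [
        classify_offsets(o5, o3) for o5, o3 in zip(df["offset5"], df["offset3"])
    ]
    out = (
        df.groupby(["sample_id", "mature_id", "isomir_class"])["fraction"]
        .sum()
        .reset_index()
        .rename(columns={"isomir_class": "class"})
    )
    return out


def class_contribution_summary(
    class_table: pd.DataFrame,
    totals: pd.Series,
    min_reads: int = 100,
    per_sample_quantifier: str = "every",
) -> pd.DataFrame:
    """Average class contributions across samples for well-covered matures.

    ``totals`` is the (sample_id, mature_id) -> mapped-read MultiIndex
    series; a mature is *selected* when it has >= min_reads in every
    sample (``per_sample_quantifier='every'``) or in at least one
    (``'any'``).  Returns one row per selected mature with the mean
    fraction of each class and the dominant class.
    """
    cov = totals.unstack(0).fillna(0)  # mature x sample
    if per_sample_quantifier == "every":
        selected = cov.index[(cov >= min_reads).all(axis=1)]
    elif per_sample_quantifier == "any":
        selected = cov.index[(cov >= min_reads).any(axis=1)]
    else:
        raise ValueError("per_sample_quantifier must be 'every' or 'any'")
    sub = class_table[class_table["mature_id"].isin(selected)]
    mean = (
        sub.groupby(["mature_id", "class"])["fraction"].mean().unstack(fill_value=0.0)
    )
    for cls in ISOMIR_CLASSES:
        if cls not in mean.columns:
            mean[cls] = 0.0
    mean = mean[list(ISOMIR_CLASSES)]
    mean["dominant_class"] = mean.idxmax(axis=1)
    return mean


def isomir_shift_screen(
    table: pd.DataFrame,
    sample_tissue: Mapping[str, str],
    contrasts: Sequence[tuple[str, str]],
    threshold: float = 0.20,
) -> pd.DataFrame:
    """IsomiRs whose mean contribution shifts >= threshold between tissues.

    Contribution = fraction of the mature's mapped reads carried by the
    isomiR, averaged over the samples of each tissue type.  Returns one
    row per (mature, isomiR, contrast) exceeding the threshold.
    """
    df = table.copy()
    df["tissue_type"] = df["sample_id"].map(sample_tissue)
    # missing isomiR x sample combinations are true zeros, so average over
    # the full per-tissue sample count rather than the observed rows
    n_samples = (
        pd.Series(sample_tissue).rename("tissue_type").reset_index()
        .groupby("tissue_type")["index"].nunique()
    )
    sums = df.groupby(["tissue_type", "mature_id", "offset5", "offset3"])["fraction"].sum()
    mean = (sums / sums.index.get_level_values(0).map(n_samples)).rename("mean_contribution")
    wide = mean.unstack(0).fillna(0.0)
    hits = []
    for a, b in contrasts:
        if a not in wide.columns or b not in wide.columns:
            continue
        delta = wide[a] - wide[b]
        for key, d in delta.items():
            if abs(d) >= threshold:
                mature, o5, o3 = key
                hits.append(
                    {"mature_id": mature, "offset5": o5, "offset3": o3,
                     "tissue_a": a, "tissue_b": b, "delta": float(d)}
                )
    return pd.DataFrame(
        hits, columns=["mature_id", "offset5", "offset3", "tissue_a", "tissue_b", "delta"]
    )


# ---------------------------------------------------------------------------
# non-templated additions


def nta_tables(
    assignments_by_sample: Mapping[str, Sequence[TagAssignment]],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """NTA class fractions and per-suffix counts, per mature x sample.

    Returns (profiles, suffix_counts).  ``profiles`` has one row per
    mature x sample with total_mapped and the fraction of reads in each
    NTA class (remainder = reads without any addition).  ``suffix_counts``
    has one row per distinct non-empty suffix with its count and its
    fraction of the mature's mapped reads.
    """
    prof_rows = []
    suff_rows = []
    for sample, assignments in assignments_by_sample.items():
        totals: dict[str, int] = {}
        by_class: dict[tuple[str, str], int] = {}
        by_suffix: dict[tuple[str, str], int] = {}
        for a in assignments:
            m = a.group.base_name
            totals[m] = totals.get(m, 0) + a.tag.count
            if a.nta_suffix:
                cls = classify_suffix(a.nta_suffix)
                by_class[(m, cls)] = by_class.get((m, cls), 0) + a.tag.count
                by_suffix[(m, a.nta_suffix)] = by_suffix.get((m, a.nta_suffix), 0) + a.tag.count
        for m, total in totals.items():
            row = {"sample_id": sample, "mature_id": m, "total_mapped": total}
            for cls in NTA_CLASSES:
                row[cls] = by_class.get((m, cls), 0) / total
            prof_rows.append(row)
        for (m, suffix), count in by_suffix.items():
            suff_rows.append(
                {"sample_id": sample, "mature_id": m, "nta_suffix": suffix,
                 "count": count, "fraction": count / totals[m]}
            )
    profiles = pd.DataFrame(
        prof_rows, columns=["sample_id", "mature_id", "total_mapped", *NTA_CLASSES]
    )
    suffixes = pd.DataFrame(
        suff_rows, columns=["sample_id", "mature_id", "nta_suffix", "count", "fraction"]
    ).sort_values(["sample_id", "mature_id", "nta_suffix"]).reset_index(drop=True)
    return profiles, suffixes


def nta_contribution_summary(
    suffix_counts: pd.DataFrame,
    profiles: pd.DataFrame,
    min_reads: int = 100,
    min_fraction: float = 0.01,
) -> pd.Series:
    """Global per-addition contributions, averaged across covered matures.

    The contribution of each individual addition is first computed per
    mature x sample (fraction of that mature's mapped reads), then
    averaged across all mature x sample observations with >= min_reads
    mapped reads.  Additions averaging below min_fraction are pooled into
    'other' — the floor that separates relevant additions from
    sequencing/trimming errors.
    """
    covered = profiles[profiles["total_mapped"] >= min_reads]
    if covered.empty:
        return pd.Series(dtype=float)
    key = list(zip(covered["sample_id"], covered["mature_id"]))
    n_obs = len(key)
    sub = suffix_counts[
        pd.Series(list(zip(suffix_counts["sample_id"], suffix_counts["mature_id"]))).isin(set(key)).to_numpy()
    ]
    # zero-contribution observations count in the mean, hence / n_obs
    mean = sub.groupby("nta_suffix")["fraction"].sum() / n_obs
    major = mean[mean >= min_fraction].sort_values(ascending=False)
    other = float(mean[mean < min_fraction].sum())
    if other > 0:
        major["other"] = other
    return major


def nta_screens(
    profiles: pd.DataFrame,
    sample_tissue: Mapping[str, str],
    contrasts: Sequence[tuple[str, str]],
    delta: float = 0.20,
    level: float = 0.30,
    top_k: int = 10,
) -> dict:
    """Adenylation/uridylation level and shift screens.

    Reports per-mature maximum A- and U-fractions and which matures exceed
    ``level`` (the sanity check that most miRNAs sit below 30 %); the
    overlap of the top-k most adenylated and top-k most uridylated
    matures; and (mature, contrast) pairs whose tissue-mean A- or
    U-fraction shifts by >= ``delta``.
    """
    df = profiles.copy()
    df["tissue_type"] = df["sample_id"].map(sample_tissue)
    per_mature_max = df.groupby("mature_id")[["adenylated", "uridylated"]].max()
    above = {
        "adenylated": sorted(per_mature_max.index[per_mature_max["adenylated"] > level]),
        "uridylated": sorted(per_mature_max.index[per_mature_max["uridylated"] > level]),
    }
    top_a = per_mature_max["adenylated"].nlargest(top_k).index
    top_u = per_mature_max["uridylated"].nlargest(top_k).index
    tissue_mean = df.groupby(["tissue_type", "mature_id"])[["adenylated", "uridylated"]].mean()
    shift_hits = []
    for a, b in contrasts:
        try:
            da = tissue_mean.loc[a] - tissue_mean.loc[b]
        except KeyError:
            continue
        for mature, row in da.iterrows():
            for kind in ("adenylated", "uridylated"):
                if abs(row[kind]) >= delta:
                    shift_hits.append(
                        {"mature_id": mature, "kind": kind, "tissue_a": a,
                         "tissue_b": b, "delta": float(row[kind])}
                    )
    return {
        "per_mature_max": per_mature_max,
        "above_level": above,
        "top_overlap": sorted(set(top_a) & set(top_u)),
        "shift_hits": pd.DataFrame(
            shift_hits, columns=["mature_id", "kind", "tissue_a", "tissue_b", "delta"]
        ),
    }


# ---------------------------------------------------------------------------
# 5p-to-3p arm ratios


@dataclass(frozen=True)
class ArmRatioRecord:
    precursor_id: str
    tissue_type: str
    ratio: float  # expr(5p) / expr(3p), tissue-mean CPM
    mode: str  # 'all_isoforms' or 'canonical_only'

    @property
    def dominant_arm(self) -> str:
        return "5p" if self.ratio > 1 else "3p"


def arm_expression(
    assignments_by_sample: Mapping[str, Sequence[TagAssignment]],
    libraries: Sequence[Library],
    records: Sequence[PrecursorRecord],
    mode: str = "all_isoforms",
) -> pd.DataFrame:
    """Per-precursor 5p/3p CPM per sample (precursors with both arms only).

    ``all_isoforms`` counts every mapped read of each arm;
    ``canonical_only`` counts only reads with (0, 0) templated end offsets
    (NTA suffixes do not disqualify a read from being canonical).
    """
    if mode not in ("all_isoforms", "canonical_only"):
        raise ValueError(f"unknown arm expression mode {mode!r}")
    lib_size = {lib.sample_id: lib.library_size for lib in libraries}
    both_arms = [r for r in records if r.mature("5p") and r.mature("3p")]
    rows = []
    for sample, assignments in assignments_by_sample.items():
        counts: dict[str, int] = {}
        for a in assignments:
            if mode == "canonical_only" and (a.offset5 != 0 or a.offset3 != 0):
                continue
            counts[a.group.base_name] = counts.get(a.group.base_name, 0) + a.tag.count
        for rec in both_arms:
            m5, m3 = rec.mature("5p"), rec.mature("3p")
            scale = 1e6 / lib_size[sample]
            rows.append(
                {
                    "precursor_id": rec.precursor_id,
                    "sample_id": sample,
                    "cpm_5p": counts.get(m5.mature_id, 0) * scale,
                    "cpm_3p": counts.get(m3.mature_id, 0) * scale,
                }
            )
    return pd.DataFrame(rows, columns=["precursor_id", "sample_id", "cpm_5p", "cpm_3p"])


def arm_ratios(
    arm_expr: pd.DataFrame,
    sample_tissue: Mapping[str, str],
    contrasts: Sequence[tuple[str, str]],
    mode: str = "all_isoforms",
    fc_hi: float = 1.5,
    fc_lo: float = 0.66,
) -> dict:
    """Tissue-level 5p/3p ratios plus fold-change screen and inversion flags.

    The ratio is computed from tissue-mean CPMs; a precursor enters a
    contrast only when both arms are expressed (CPM > 0) in both tissues.
    A screen hit is ratio_a/ratio_b > fc_hi or < fc_lo; an inversion is a
    change of the dominant arm between the two tissues.
    """
    df = arm_expr.copy()
    df["tissue_type"] = df["sample_id"].map(sample_tissue)
    tissue_mean = df.groupby(["precursor_id", "tissue_type"])[["cpm_5p", "cpm_3p"]].mean()
    records: list[ArmRatioRecord] = []
    for (prec, tissue), row in tissue_mean.iterrows():
        if row["cpm_5p"] > 0 and row["cpm_3p"] > 0:
            records.append(
                ArmRatioRecord(prec, tissue, float(row["cpm_5p"] / row["cpm_3p"]), mode)
            )
    by_key = {(r.precursor_id, r.tissue_type): r for r in records}
    screen_hits, inversions = [], []
    for a, b in contrasts:
        for prec in tissue_mean.index.get_level_values(0).unique():
            ra, rb = by_key.get((prec, a)), by_key.get((prec, b))
            if ra is None or rb is None:
                continue
            fold = ra.ratio / rb.ratio
            if fold > fc_hi or fold < fc_lo:
                screen_hits.append(
                    {"precursor_id": prec, "tissue_a": a, "tissue_b": b,
                     "ratio_a": ra.ratio, "ratio_b": rb.ratio, "fold": float(fold)}
                )
                if ra.dominant_arm != rb.dominant_arm:
                    inversions.append(
                        {"precursor_id": prec, "tissue_a": a, "tissue_b": b,
                         "arm_a": ra.dominant_arm, "arm_b": rb.dominant_arm}
                    )
    return {
        "records": records,
        "screen_hits": pd.DataFrame(
            screen_hits,
            columns=["precursor_id", "tissue_a", "tissue_b", "ratio_a", "ratio_b", "fold"],
        ),
        "inversions": pd.DataFrame(
            inversions, columns=["precursor_id", "tissue_a", "tissue_b", "arm_a", "arm_b"]
        ),
    }
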