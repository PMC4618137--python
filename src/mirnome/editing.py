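"""Substitution calling on mature miRNA positions; A-to-I candidate flags.

Highly expressed miRNAs reach coverages far beyond what genome variant
callers are tuned for, so the calling here is a direct count-based pileup
over mature-miRNA coordinates.  The pileup is built from the aligner's
inner-mismatch records: non-templated 3' additions were trimmed before
mismatch counting and can never enter it, and a fixed number of positions
at the mature 3' end (default 2) is excluded from calling to guard
against residual trimming artifacts.

A-to-I editing deaminates adenosine to inosine, which sequencers read as
G, so sense-strand A->G substitutions are candidate editing sites; all
substitution types are reported (SNPs and sequencing artifacts show up in
the same pileup and are distinguished by frequency/coverage filters and,
optionally, a user-supplied list of known SNP positions).

Default thresholds — coverage >= 100, alt frequency >= 5 %, alt count
>= 10 — are this package's own pragmatic choices and are configurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportions_ztest

from .aligner import TagAssignment

logger = logging.getLogger(__name__)

BASES = ("A", "C", "G", "T")


def pileup(
    assignments_by_sample: Mapping[str, Sequence[TagAssignment]],
    mature_lengths: Mapping[str, int],
) -> pd.DataFrame:
    """Count-weighted base pileup over canonical mature positions.

    A read covers canonical position p (0-based from the mature 5' end)
    when its trimmed alignment spans it, i.e. offset5 <= p < L + offset3;
    short 3' isomiRs therefore drop out of coverage near the 3' end.  At
    each covered position the read contributes its count to the reference
    base unless the aligner recorded an inner mismatch there.  Base counts
    at a position always sum to its coverage.

    Returns a tidy frame: sample_id, mature_id, position, ref_base,
    A/C/G/T counts, coverage.
    """
    rows = []
    for sample, assignments in assignments_by_sample.items():
        # (mature, position) -> base -> count; ref base recorded on the fly
        counts: dict[tuple[str, int], dict[str, int]] = {}
        refs: dict[tuple[str, int], str] = {}
        for a in assignments:
            m = a.group.base_name
            L = mature_lengths[m]
            mm = {p: (r, b) for p, r, b in a.mismatch_positions}
            lo = max(a.offset5, 0)
            hi = min(L + a.offset3, L)
            for p in range(lo, hi):
                key = (m, p)
                slot = counts.setdefault(key, {b: 0 for b in BASES})
                if p in mm:
                    ref, read = mm[p]
                    refs[key] = ref
                    slot[read] += a.tag.count
                else:
                    slot["__ref__"] = slot.get("__ref__", 0) + a.tag.count
        # matching reads accumulate under a placeholder; the reference base
        # is merged in later (annotate_reference) from the canonical seqs
        for (m, p), slot in sorted(counts.items()):
            ref = refs.get((m, p))
            ref_count = slot.pop("__ref__", 0)
            row = {"sample_id": sample, "mature_id": m, "position": p,
                   "ref_base": ref if ref is not None else "", "ref_count": ref_count}
            for b in BASES:
                row[b] = slot[b]
            row["coverage"] = sum(slot.values()) + ref_count
            rows.append(row)
    return pd.DataFrame(
        rows,
        columns=["sample_id", "mature_id", "position", "ref_base", "ref_count",
                 *BASES, "coverage"],
    )


def annotate_reference(pile: pd.DataFrame, canonical_seqs: Mapping[str, str]) -> pd.DataFrame:
    """Fill in reference bases from the canonical mature sequences."""
    df = pile.copy()
    ref = [
        canonical_seqs[m][p] for m, p in zip(df["mature_id"], df["position"])
    ]
    df["ref_base"] = ref
    for b in BASES:
        df[b] = np.where(df["ref_base"] == b, df[b] + df["ref_count"], df[b])
    df = df.drop(columns="ref_count")
    return df


@dataclass(frozen=True)
class EditingSite:
    mature_id: str
    position: int  # 0-based within the canonical mature
    ref_base: str
    alt_base: str
    per_sample: tuple[tuple[str, int, int, float], ...]  # (sample, coverage, alt, freq)
    is_AtoI: bool
    in_seed: bool  # positions 1-7 (0-based) of the mature 5' end

    def frequency(self, sample_id: str) -> Optional[float]:
        for s, _, _, f in self.per_sample:
            if s == sample_id:
                return f
        return None


def call_sites(
    pile: pd.DataFrame,
    canonical_seqs: Mapping[str, str],
    min_coverage: int = 100,
    min_frequency: float = 0.05,
    min_alt_count: int = 10,
    edge_exclusion: int = 2,
    known_snps: Optional[set[tuple[str, int]]] = None,
) -> list[EditingSite]:
    """Call substitution sites passing the filters in at least one sample.

    A (mature, position, alt) is called when some sample reaches
    coverage >= min_coverage, alt frequency >= min_frequency and
    alt count >= min_alt_count, provided the position lies at least
    ``edge_exclusion`` nt away from the mature 3' end (residual
    NTA/trimming artifact guard).  Values for every sample are reported
    on each called site.  A->G on the mature sense strand flags the site
    as a candidate A-to-I editing event.
    """
    df = annotate_reference(pile, canonical_seqs)
    sites: list[EditingSite] = []
    for (mature, position), grp in df.groupby(["mature_id", "position"]):
        L = len(canonical_seqs[mature])
        if position >= L - edge_exclusion:
            continue
        if known_snps and (mature, position) in known_snps:
            continue
        ref = canonical_seqs[mature][position]
        for alt in BASES:
            if alt == ref:
                continue
            passed = False
            per_sample = []
            for row in grp.itertuples(index=False):
                cov = row.coverage
                alt_count = getattr(row, alt)
                freq = alt_count / cov if cov else 0.0
                per_sample.append((row.sample_id, int(cov), int(alt_count), float(freq)))
                if cov >= min_coverage and freq >= min_frequency and alt_count >= min_alt_count:
                    passed = True
            if passed:
                sites.append(
                    EditingSite(
                        mature_id=mature,
                        position=int(position),
                        ref_base=ref,
                        alt_base=alt,
                        per_sample=tuple(sorted(per_sample)),
                        is_AtoI=(ref == "A" and alt == "G"),
                        in_seed=(1 <= position <= 7),
                    )
                )
    sites.sort(key=lambda s: (s.mature_id, s.position, s.alt_base))
    return sites


def compare_frequencies(
    sites: Sequence[EditingSite],
    sample_tissue: Mapping[str, str],
    contrasts: Sequence[tuple[str, str]],
) -> pd.DataFrame:
    """Per-site tissue-pooled frequency deltas with a two-proportion z-test.

    Alt and total counts are pooled over the samples of each tissue type;
    the test is descriptive (no multiplicity correction).  Sites lacking
    coverage in one tissue are reported with the available delta and
    flagged low_coverage.
    """
    rows = []
    for site in sites:
        pooled: dict[str, list[int]] = {}
        for sample, cov, alt, _ in site.per_sample:
            t = sample_tissue[sample]
            acc = pooled.setdefault(t, [0, 0])
            acc[0] += alt
            acc[1] += cov
        for a, b in contrasts:
            alt_a, cov_a = pooled.get(a, (0, 0))
            alt_b, cov_b = pooled.get(b, (0, 0))
            fa = alt_a / cov_a if cov_a else 0.0
            fb = alt_b / cov_b if cov_b else 0.0
            low = cov_a == 0 or cov_b == 0
            if not low and 0 < alt_a + alt_b < cov_a + cov_b:
                _, p = proportions_ztest([alt_a, alt_b], [cov_a, cov_b])
            else:
                p = 1.0
            rows.append(
                {"mature_id": site.mature_id, "position": site.position,
                 "ref_base": site.ref_base, "alt_base": site.alt_base,
                 "tissue_a": a, "tissue_b": b,
                 "freq_a": fa, "freq_b": fb, "delta": fa - fb,
                 "p_value": float(p), "low_coverage": low}
            )
    return pd.DataFrame(
        rows,
        columns=["mature_id", "position", "ref_base", "alt_base", "tissue_a",
                 "tissue_b", "freq_a", "freq_b", "delta", "p_value", "low_coverage"],
    )


def sites_to_frame(sites: Sequence[EditingSite]) -> pd.DataFrame:
    """Flatten called sites for TSV export (one row per site x sample)."""
    rows = []
    for s in sites:
        for sample, cov, alt, freq in s.per_sample:
            rows.append(
                {"mature_id": s.mature_id, "position": s.position,
                 "ref_base": s.ref_base, "alt_base": s.alt_base,
                 "is_AtoI": s.is_AtoI, "in_seed": s.in_seed,
                 "sample_id": sample, "coverage": cov,
                 "alt_count": alt, "frequency": freq}
            )
    return pd.DataFrame(
        rows,
        columns=["mature_id", "position", "ref_base", "alt_base", "is_AtoI",
                 "in_seed", "sample_id", "coverage", "alt_count", "frequency"],
    )
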