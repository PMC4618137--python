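"""Independent brute-force oracle for the stratified tag aligner.

Enumerates every (step, iteration, reference placement) combination with
plain string comparison — no shared code with the package's aligner — and
applies the same decision contract: first (step, iteration) with an
admissible hit wins; within it, hits with the fewest mismatches are
preferred; the tag is kept only when all those hits fall in one
multi-locus group.  Quadratic and slow on purpose.
"""

from __future__ import annotations

COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(seq):
    return "".join(COMP[c] for c in reversed(seq))


def mismatch_count(a, b, limit):
    n = 0
    for x, y in zip(a, b):
        if x != y:
            n += 1
            if n > limit:
                return None
    return n


def oracle_align(tag_seq, records, mature_group, ladder=(0, 1, 2), min_length=18,
                 window=5, max_trim=None):
    """Return ('mapped', step, iteration, mismatches, frozenset of mature ids)
    or ('unmapped',).  Precursor mode, sense strand only admissible."""
    if len(tag_seq) < min_length:
        return ("unmapped",)
    max_iter = len(tag_seq) - min_length
    if max_trim is not None:
        max_iter = min(max_iter, max_trim)
    for step, allow in enumerate(ladder):
        for it in range(max_iter + 1):
            query = tag_seq[: len(tag_seq) - it]
            admissible = []  # (mismatches, mature_id)
            for rec in records:
                seq = rec.sequence
                for start in range(len(seq) - len(query) + 1):
                    mm = mismatch_count(query, seq[start : start + len(query)], allow)
                    if mm is None:
                        continue
                    end = start + len(query)
                    for m in rec.matures:
                        if abs(start - m.start) <= window and abs(end - m.end) <= window:
                            admissible.append((mm, m.mature_id))
            if not admissible:
                continue
            best = min(mm for mm, _ in admissible)
            winners = {mid for mm, mid in admissible if mm == best}
            groups = {mature_group[mid] for mid in winners}
            if len(groups) > 1:
                return ("unmapped",)
            return ("mapped", step, it, best, frozenset(winners))
    return ("unmapped",)
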