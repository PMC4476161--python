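"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the vectorized dynamic programs of the package:
the TSD oracle walks backward from every end-position pair; the Fisher
oracle enumerates every table with the observed margins via itertools.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def oracle_find_tsd(
    upstream: str,
    copy: str,
    downstream: str,
    downstream_extended: str | None = None,
    min_len: int = 10,
    slack: int = 10,
    anchor: int = 10,
    max_mm: int = 1,
):
    """Quadratic brute-force TSD search mirroring the staged contract.

    Returns (seq, length, stage) or None.
    """
    downstream_extended = (
        downstream_extended if downstream_extended is not None else downstream
    )
    s = min(slack, len(copy))
    region_a = upstream + copy[:s]
    copy5 = len(upstream)
    copy3 = s
    anchor_lo, anchor_hi = copy5 - anchor, copy5 + anchor

    def exact_candidates(region_b, required_min):
        cands = []  # (length, combined_distance, i, j)
        for i_end in range(len(region_a)):
            if not anchor_lo <= i_end + 1 <= anchor_hi:
                continue
            for j_end in range(len(region_b)):
                if region_a[i_end] != region_b[j_end]:
                    continue
                r = 0
                while (
                    i_end - r >= 0
                    and j_end - r >= 0
                    and region_a[i_end - r] == region_b[j_end - r]
                ):
                    r += 1
                if r < required_min:
                    continue
                i, j = i_end - r + 1, j_end - r + 1
                dist = abs((i + r) - copy5) + abs(j - copy3)
                cands.append((r, dist, i, j))
        return cands

    def mismatch_candidates(region_b, required_min):
        cands = []
        for i_end in range(len(region_a)):
            if not anchor_lo <= i_end + 1 <= anchor_hi:
                continue
            for j_end in range(len(region_b)):
                if region_a[i_end] != region_b[j_end]:
                    continue
                mm = 0
                best_len = 0
                p = 0
                while i_end - p >= 0 and j_end - p >= 0:
                    if region_a[i_end - p] == region_b[j_end - p]:
                        best_cand = p + 1
                        if best_cand >= required_min:
                            best_len = max(best_len, best_cand)
                    else:
                        mm += 1
                        if mm > max_mm:
                            break
                    p += 1
                if best_len:
                    i, j = i_end - best_len + 1, j_end - best_len + 1
                    dist = abs((i + best_len) - copy5) + abs(j - copy3)
                    cands.append((best_len, dist, i, j))
        return cands

    region_b_near = copy[-s:] + downstream if s else downstream
    region_b_ext = copy[-s:] + downstream_extended if s else downstream_extended

    for stage, cands in (
        ("exact_near", exact_candidates(region_b_near, min_len)),
        ("exact_extended", exact_candidates(region_b_ext, min_len)),
        ("mismatch_extended", mismatch_candidates(region_b_ext, min_len + 2)),
    ):
        if not cands:
            continue
        best_len = max(c[0] for c in cands)
        finalists = [c for c in cands if c[0] == best_len]
        _, _, i, j = min(finalists, key=lambda c: (c[1], c[2], c[3]))
        return region_a[i : i + best_len], best_len, stage
    return None


def oracle_fisher_p(table) -> float:
    """Two-sided Fisher p by full enumeration of all r x 2 tables with the
    observed margins under the fixed-margin hypergeometric."""
    T = np.asarray(table)
    rows = T.sum(axis=1)
    c1 = int(T[:, 0].sum())
    total = int(T.sum())
    if total == 0:
        return 1.0

    def prob(ks):
        num = math.prod(math.comb(int(r), int(k)) for r, k in zip(rows, ks))
        return num / math.comb(total, c1)

    obs = prob(T[:, 0])
    p = 0.0
    for ks in itertools.product(*[range(int(r) + 1) for r in rows]):
        if sum(ks) != c1:
            continue
        pr = prob(ks)
        if pr <= obs * (1 + 1e-12):
            p += pr
    return p
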