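"""Independent reference implementations used to cross-check the package.

These deliberately work by exhaustive enumeration over small inputs rather
than by seed-and-extend, closed forms, or library calls, so that agreement
with the package is informative.
"""

from __future__ import annotations

import math
from itertools import combinations

from ssrforge.scan import ScanParams, canonical_motif, primitive_period


def brute_scan(seq: str, params: ScanParams | None = None) -> set[tuple]:
    """Brute-force SSR finder: enumerate all (interval, motif, phase)
    candidates meeting the record-level rules, then resolve overlaps.

    Returns a set of (start, end, motif, mismatches, score) tuples with
    1-based inclusive coordinates. Quadratic in sequence length; intended
    for sequences of at most a couple hundred bp.
    """
    params = params or ScanParams()
    seq = seq.upper()
    n = len(seq)
    pen = params.mismatch_penalty
    # a reported record's score cannot exceed its length
    min_len = params.min_score
    # mismatches must be separated by enough matches that the running score
    # stays within one penalty of its running maximum during extension
    min_sep = pen - 1

    cands: dict[tuple[int, int, int], tuple[int, int, str]] = {}
    valid = [c != "N" for c in seq]
    n_prefix = [0]
    for v in valid:
        n_prefix.append(n_prefix[-1] + (0 if v else 1))

    for k in sorted(params.motif_lengths):
        seed_len = max(params.min_seed_repeats * k, params.min_seed_length)
        for i in range(n - k + 1):
            motif = seq[i : i + k]
            if "N" in motif or primitive_period(motif) != motif:
                continue
            row = [
                valid[p] and seq[p] == motif[(p - i) % k] for p in range(n)
            ]
            # maximal perfect runs w.r.t. this phase
            runs = []
            p = 0
            while p < n:
                if row[p]:
                    q = p
                    while q + 1 < n and row[q + 1]:
                        q += 1
                    if q - p + 1 >= seed_len:
                        runs.append((p, q))
                    p = q + 1
                else:
                    p += 1
            if not runs:
                continue
            mism = [p for p in range(n) if valid[p] and not row[p]]
            for s in range(n):
                if not row[s]:
                    continue
                for e in range(s + max(min_len, 2 * k) - 1, n):
                    if not row[e]:
                        continue
                    if n_prefix[e + 1] - n_prefix[s] > 0:
                        continue  # contains N
                    if not any(
                        min(b, e) - max(a, s) + 1 >= seed_len for a, b in runs
                    ):
                        continue
                    mm = [p for p in mism if s <= p <= e]
                    if any(q - p <= min_sep for p, q in zip(mm, mm[1:])):
                        continue
                    score = (e - s + 1) - pen * len(mm)
                    if score < params.min_score:
                        continue
                    key = (s, e, k)
                    prev = cands.get(key)
                    if prev is None or score > prev[0]:
                        cands[key] = (score, len(mm), motif)

    chosen: list[tuple] = []
    occupied: list[tuple[int, int]] = []
    for (s, e, k), (score, mm, motif) in sorted(
        cands.items(),
        key=lambda kv: (
            -kv[1][0],          # score desc
            kv[0][2],           # shorter motif
            kv[0][1] - kv[0][0],  # shorter record (trim-to-first-max)
            kv[0][0],           # leftmost
            canonical_motif(kv[1][2]),
        ),
    ):
        if any(not (e < a or s > b) for a, b in occupied):
            continue
        chosen.append((s + 1, e + 1, canonical_motif(motif), mm, score))
        occupied.append((s, e))
    return set(chosen)


def hwe_two_allele_exact(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact HWE p-value for a biallelic locus by direct enumeration of all
    heterozygote counts compatible with the allele counts."""
    m1 = 2 * n_aa + n_ab
    m2 = 2 * n_bb + n_ab
    n = n_aa + n_ab + n_bb

    def prob(h: int) -> float:
        if (m1 - h) % 2 or (m2 - h) % 2:
            return 0.0
        f11, f22 = (m1 - h) // 2, (m2 - h) // 2
        if f11 < 0 or f22 < 0:
            return 0.0
        lp = (
            math.lgamma(n + 1)
            - math.lgamma(f11 + 1)
            - math.lgamma(h + 1)
            - math.lgamma(f22 + 1)
            + h * math.log(2.0)
            + math.lgamma(m1 + 1)
            + math.lgamma(m2 + 1)
            - math.lgamma(2 * n + 1)
        )
        return math.exp(lp)

    p_obs = prob(n_ab)
    return min(
        1.0,
        sum(prob(h) for h in range(min(m1, m2) + 1) if prob(h) <= p_obs * (1 + 1e-12)),
    )


def mann_whitney_enumeration(x, y) -> tuple[float, float]:
    """Two-sided exact Mann-Whitney by full enumeration of rank splits.

    Assumes no ties. Returns (U of the first sample, two-sided p as twice
    the smaller tail probability, capped at 1)."""
    x, y = list(x), list(y)
    m, n = len(x), len(y)
    pooled = sorted(x + y)
    assert len(set(pooled)) == m + n, "enumeration oracle assumes no ties"
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    u_obs = sum(ranks[v] for v in x) - m * (m + 1) / 2

    us = []
    for idx in combinations(range(m + n), m):
        r = sum(i + 1 for i in idx)
        us.append(r - m * (m + 1) / 2)
    total = len(us)
    lo = sum(1 for u in us if u <= u_obs) / total
    hi = sum(1 for u in us if u >= u_obs) / total
    return u_obs, min(1.0, 2 * min(lo, hi))


def rarefaction_enumeration(counts: list[int], g: int) -> float:
    """Expected distinct alleles in a g-gene subsample, by enumerating all
    subsets of the gene pool."""
    pool = [a for a, c in enumerate(counts) for _ in range(c)]
    subsets = list(combinations(range(len(pool)), g))
    return sum(len({pool[i] for i in s}) for s in subsets) / len(subsets)
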