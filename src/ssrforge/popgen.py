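"""Per-locus and per-population genetic statistics for diploid SSR data.

Implements the classical marker-evaluation battery:

* allele counts, observed heterozygosity, and Nei's (1978) unbiased expected
  heterozygosity He = (2n/(2n-1)) (1 - sum p_i^2);
* allelic richness by rarefaction to a standardized number of genes g,
  AR = sum_a [1 - C(2n - c_a, g) / C(2n, g)];
* the exact Hardy-Weinberg test conditional on allele counts with the
  probability ordering (full enumeration of genotype arrays when the array
  space is small, seeded Monte Carlo otherwise);
* a permutation G-test for linkage disequilibrium between locus pairs;
* Weir & Cockerham (1984) variance-component estimators theta (Fst) and
  f (Fis), multi-locus values as ratios of summed components;
* an EM estimator of per-locus null-allele frequency (visible homozygotes
  may carry one null copy; whole-locus missing individuals are attributed
  to null homozygotes);
* Holm's sequential Bonferroni correction.

Missing data are handled by pairwise-complete deletion per statistic; no
imputation is performed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .io import MISSING, GenotypeMatrix

__all__ = [
    "PopLocusStats",
    "locus_summary",
    "allelic_richness",
    "standardized_gene_count",
    "hwe_exact_test",
    "ld_test",
    "wc_fstats",
    "FStats",
    "null_allele_em",
    "EMResult",
    "EMNonConvergenceError",
    "sequential_bonferroni",
    "allele_counts",
]


# ---------------------------------------------------------------- summaries


@dataclass(frozen=True)
class PopLocusStats:
    n: int  # genotyped individuals
    na: int  # distinct alleles
    ho: float  # observed heterozygosity
    he: float  # Nei's unbiased expected heterozygosity
    defined: bool = True


def allele_counts(genotypes: np.ndarray) -> dict[int, int]:
    """Allele -> gene count from an (n, 2) array of non-missing genotypes."""
    vals, counts = np.unique(np.asarray(genotypes).ravel(), return_counts=True)
    return {int(v): int(c) for v, c in zip(vals, counts)}


def _he_unbiased(counts: dict[int, int]) -> float:
    genes = sum(counts.values())
    if genes <= 1:
        return float("nan")
    p2 = sum((c / genes) ** 2 for c in counts.values())
    return (genes / (genes - 1)) * (1.0 - p2)


def locus_summary(gm: GenotypeMatrix, locus: str) -> dict[str, PopLocusStats]:
    """Per-population (n, Na, Ho, He) at one locus.

    A population with no non-missing genotype gets a flagged-undefined
    entry (NaN statistics) so downstream comparisons can exclude it.
    """
    out: dict[str, PopLocusStats] = {}
    for pop in gm.pop_names:
        g = gm.genotypes(locus, pop)
        if len(g) == 0:
            out[pop] = PopLocusStats(0, 0, float("nan"), float("nan"), defined=False)
            continue
        counts = allele_counts(g)
        ho = float(np.mean(g[:, 0] != g[:, 1]))
        he = 0.0 if len(counts) == 1 else _he_unbiased(counts)
        out[pop] = PopLocusStats(n=len(g), na=len(counts), ho=ho, he=he)
    return out


# ------------------------------------------------------------- rarefaction


def allelic_richness(counts: dict[int, int] | list[int], g: int) -> float:
    """Expected allele count in a random subsample of g genes (rarefaction)."""
    cvec = list(counts.values()) if isinstance(counts, dict) else list(counts)
    genes = sum(cvec)
    if g > genes:
        raise ValueError(f"g={g} exceeds the {genes} genes sampled at this locus")
    if g < 1:
        raise ValueError("g must be >= 1")
    denom = math.comb(genes, g)
    return float(sum(1.0 - math.comb(genes - c, g) / denom for c in cvec))


def standardized_gene_count(gm: GenotypeMatrix, locus: str) -> int:
    """FSTAT's convention: 2 x the smallest per-population complete sample."""
    ns = [len(gm.genotypes(locus, pop)) for pop in gm.pop_names]
    return 2 * min(ns)


# ----------------------------------------------------------- HWE exact test


def _log_array_prob(f: dict[tuple[int, int], int], m: dict[int, int]) -> float:
    """log P(genotype array | allele counts) under HWE (conditional law)."""
    n = sum(f.values())
    het = sum(c for (i, j), c in f.items() if i != j)
    lp = math.lgamma(n + 1) + het * math.log(2.0) - math.lgamma(2 * n + 1)
    lp += sum(math.lgamma(c + 1) for c in m.values())
    lp -= sum(math.lgamma(c + 1) for c in f.values())
    return lp


def _genotype_dict(genotypes: np.ndarray) -> dict[tuple[int, int], int]:
    f: dict[tuple[int, int], int] = {}
    for a, b in np.sort(np.asarray(genotypes), axis=1):
        key = (int(a), int(b))
        f[key] = f.get(key, 0) + 1
    return f


def _enumerate_arrays(m_list: list[int]):
    """Yield all genotype-count arrays consistent with allele counts m_list.

    Arrays are upper-triangular dicts over allele indices. Exponential in
    the number of alleles/genes; callers bound the array space first.
    """
    r = len(m_list)

    def rec(i: int, rem: list[int], acc: dict[tuple[int, int], int]):
        if i == r:
            if all(v == 0 for v in rem):
                yield dict(acc)
            return
        mi = rem[i]
        # f_ii homozygotes, then distribute the rest among j > i
        for fii in range(mi // 2, -1, -1):
            left = mi - 2 * fii
            js = list(range(i + 1, r))

            def dist(idx: int, left_: int, acc2: dict):
                if idx == len(js):
                    if left_ == 0:
                        rem2 = rem.copy()
                        rem2[i] = 0
                        for j in js:
                            rem2[j] -= acc2.get((i, j), 0)
                        if all(v >= 0 for v in rem2):
                            yield from rec(i + 1, rem2, {**acc, (i, i): fii, **acc2})
                    return
                j = js[idx]
                for fij in range(min(left_, rem[j]) + 1):
                    if fij:
                        yield from dist(idx + 1, left_ - fij, {**acc2, (i, j): fij})
                    else:
                        yield from dist(idx + 1, left_, acc2)

            yield from dist(0, left, {})

    yield from rec(0, list(m_list), {})


def _array_space_size(m_list: list[int], cap: int) -> int:
    """Number of consistent genotype arrays (early exit once above cap).

    Closed-form loops for 2-3 alleles; for more alleles the generic
    enumerator is sampled with early exit at a small bound, since the space
    is then almost always far beyond enumeration anyway.
    """
    r = len(m_list)
    if r == 2:
        m1, m2 = m_list
        return sum(
            1
            for f12 in range(min(m1, m2) + 1)
            if (m1 - f12) % 2 == 0 and (m2 - f12) % 2 == 0
        )
    if r == 3:
        m1, m2, m3 = m_list
        count = 0
        for f12 in range(min(m1, m2) + 1):
            for f13 in range(min(m1 - f12, m3) + 1):
                if (m1 - f12 - f13) % 2:
                    continue
                for f23 in range(min(m2 - f12, m3 - f13) + 1):
                    if (m2 - f12 - f23) % 2 == 0 and (m3 - f13 - f23) % 2 == 0:
                        count += 1
                        if count > cap:
                            return count
        return count
    bound = min(cap, 20_000)
    count = 0
    for _ in _enumerate_arrays(m_list):
        count += 1
        if count > bound:
            return cap + 1  # treat as beyond enumeration
    return count


def hwe_exact_test(
    genotypes: np.ndarray,
    method: str = "auto",
    reps: int = 100_000,
    seed: int | None = None,
    enumeration_cap: int = 1_000_000,
) -> float:
    """Exact conditional Hardy-Weinberg test (probability ordering).

    The p-value is the total conditional probability, given the observed
    allele counts, of genotype arrays no more probable than the observed
    one. Full enumeration is used when the array space is small enough
    (always checked exactly for 2-3 alleles; with more alleles enumeration
    is only attempted for very small spaces); otherwise the null is sampled
    by randomly pairing the observed genes (seeded Monte Carlo with
    ``reps`` draws, vectorized in batches).
    """
    g = np.asarray(genotypes)
    if len(g) == 0:
        raise ValueError("no genotypes")
    alleles = sorted({int(x) for x in g.ravel()})
    if len(alleles) < 2:
        return 1.0
    idx = {a: i for i, a in enumerate(alleles)}
    gi = np.vectorize(idx.get)(g)
    f_obs = _genotype_dict(gi)
    m = allele_counts(gi)
    lp_obs = _log_array_prob(f_obs, m)
    m_list = [m[i] for i in range(len(alleles))]

    if method == "auto":
        small = _array_space_size(m_list, enumeration_cap) <= enumeration_cap
        method = "enumeration" if small else "monte_carlo"

    if method == "enumeration":
        total = 0.0
        p = 0.0
        for arr in _enumerate_arrays(m_list):
            lp = _log_array_prob(arr, m)
            pr = math.exp(lp)
            total += pr
            if lp <= lp_obs + 1e-9:
                p += pr
        return min(1.0, p / total)  # total == 1 up to float error

    if method != "monte_carlo":
        raise ValueError(f"unknown method {method!r}")
    rng = np.random.default_rng(seed)
    K = len(alleles)
    genes = np.repeat(np.arange(K), m_list)
    # log-probability of an array differs across arrays only through
    # H*log(2) - sum(lgamma(f_ij + 1)); compare that reduced statistic
    from scipy.special import gammaln

    def reduced(h: float, lg_sum: float) -> float:
        return h * math.log(2.0) - lg_sum

    red_obs = reduced(
        sum(c for (i, j), c in f_obs.items() if i != j),
        sum(math.lgamma(c + 1) for c in f_obs.values()),
    )
    hits = 0
    batch = 5_000
    done = 0
    while done < reps:
        b = min(batch, reps - done)
        order = np.argsort(rng.random((b, len(genes))), axis=1)
        perm = genes[order]
        a = perm[:, ::2]
        bb = perm[:, 1::2]
        lo = np.minimum(a, bb)
        hi = np.maximum(a, bb)
        codes = lo * K + hi
        counts = np.zeros((b, K * K), dtype=np.int64)
        np.add.at(counts, (np.repeat(np.arange(b), codes.shape[1]), codes.ravel()), 1)
        h = (a != bb).sum(axis=1)
        lg = gammaln(counts + 1).sum(axis=1)
        red = h * math.log(2.0) - lg
        hits += int((red <= red_obs + 1e-9).sum())
        done += b
    return (1 + hits) / (reps + 1)


# ------------------------------------------------------------------ LD test


def _g_statistic(table: np.ndarray) -> float:
    t = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
    n = t.sum()
    row = t.sum(axis=1, keepdims=True)
    col = t.sum(axis=0, keepdims=True)
    expected = row * col / n
    mask = t > 0
    return float(2.0 * np.sum(t[mask] * np.log(t[mask] / expected[mask])))


def ld_test(
    gm: GenotypeMatrix,
    locus_a: str,
    locus_b: str,
    pop: str | None = None,
    reps: int = 10_000,
    seed: int | None = None,
) -> float:
    """Permutation G-test of genotypic association between two loci.

    Builds the genotype-by-genotype contingency table over individuals
    complete at both loci and permutes one locus's genotypes across
    individuals to generate the null. Returns a flagged-undefined NaN when
    fewer than 5 complete individuals are available.
    """
    ja, jb = gm.locus_index(locus_a), gm.locus_index(locus_b)
    mask = np.ones(len(gm.individual_ids), dtype=bool)
    if pop is not None:
        mask &= gm.pop_mask(pop)
    ga = gm.calls[mask, ja, :]
    gb = gm.calls[mask, jb, :]
    ok = (ga != MISSING).all(axis=1) & (gb != MISSING).all(axis=1)
    ga, gb = np.sort(ga[ok], axis=1), np.sort(gb[ok], axis=1)
    if len(ga) < 5:
        return float("nan")

    def encode(g: np.ndarray) -> tuple[np.ndarray, int]:
        pairs = [tuple(row) for row in g]
        labels = {p: i for i, p in enumerate(sorted(set(pairs)))}
        return np.array([labels[p] for p in pairs]), len(labels)

    ca, ka = encode(ga)
    cb, kb = encode(gb)
    obs = _g_statistic(np.bincount(ca * kb + cb, minlength=ka * kb).reshape(ka, kb))
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(reps):
        perm = rng.permutation(cb)
        g = _g_statistic(np.bincount(ca * kb + perm, minlength=ka * kb).reshape(ka, kb))
        if g >= obs - 1e-9:
            hits += 1
    return (1 + hits) / (reps + 1)


# --------------------------------------------------- Weir-Cockerham F-stats


@dataclass(frozen=True)
class FStats:
    fis: float
    fst: float
    per_locus: dict[str, tuple[float, float]] = field(default_factory=dict)


def _wc_components(gm: GenotypeMatrix, locus: str) -> tuple[float, float, float]:
    """Summed (a, b, c) variance components over alleles at one locus."""
    pops = gm.pop_names
    gs = {p: gm.genotypes(locus, p) for p in pops}
    gs = {p: g for p, g in gs.items() if len(g) > 0}
    if len(gs) < 2:
        return 0.0, 0.0, 0.0
    r = len(gs)
    n = np.array([len(g) for g in gs.values()], dtype=float)
    nbar = n.mean()
    if nbar <= 1:
        return 0.0, 0.0, 0.0
    nc = (n.sum() - (n**2).sum() / n.sum()) / (r - 1)
    alleles = sorted({int(x) for g in gs.values() for x in g.ravel()})
    A = B = C = 0.0
    for al in alleles:
        p_i = np.array([np.mean(g == al) for g in gs.values()])
        h_i = np.array(
            [np.mean((g[:, 0] == al) ^ (g[:, 1] == al)) for g in gs.values()]
        )
        pbar = (n * p_i).sum() / n.sum()
        s2 = (n * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar)
        hbar = (n * h_i).sum() / n.sum()
        inner = pbar * (1 - pbar) - ((r - 1) / r) * s2
        a = (nbar / nc) * (s2 - (inner - hbar / 4) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (inner - ((2 * nbar - 1) / (4 * nbar)) * hbar)
        c = hbar / 2
        A += a
        B += b
        C += c
    return A, B, C


def wc_fstats(gm: GenotypeMatrix, loci: list[str] | None = None) -> FStats:
    """Weir & Cockerham (1984) theta (Fst) and f (Fis).

    Multi-locus estimates are ratios of variance components summed over
    loci and alleles. Requires at least two populations.
    """
    if len(gm.pop_names) < 2:
        raise ValueError("Fst requires at least two populations")
    loci = loci if loci is not None else list(gm.locus_ids)
    per_locus: dict[str, tuple[float, float]] = {}
    At = Bt = Ct = 0.0
    for locus in loci:
        a, b, c = _wc_components(gm, locus)
        At, Bt, Ct = At + a, Bt + b, Ct + c
        tot = a + b + c
        theta = a / tot if tot > 0 else float("nan")
        f = 1 - c / (b + c) if (b + c) > 0 else float("nan")
        per_locus[locus] = (f, theta)
    tot = At + Bt + Ct
    return FStats(
        fis=1 - Ct / (Bt + Ct) if (Bt + Ct) > 0 else float("nan"),
        fst=At / tot if tot > 0 else float("nan"),
        per_locus=per_locus,
    )


# ------------------------------------------------------------ null alleles


class EMNonConvergenceError(RuntimeError):
    def __init__(self, result: "EMResult"):
        super().__init__(
            f"null-allele EM did not converge in {result.n_iter} iterations "
            f"(last r = {result.null_freq:.6f})"
        )
        self.result = result


@dataclass
class EMResult:
    allele_freqs: dict[int, float]
    null_freq: float
    n_iter: int
    converged: bool
    loglik: float
    saturated: bool = False  # visible-data pattern drives r to its bound


def null_allele_em(
    genotypes: np.ndarray,
    n_missing: int = 0,
    tol: float = 1e-6,
    max_iter: int = 10_000,
) -> EMResult:
    """EM estimate of the null-allele frequency r at one locus.

    Model: a visible homozygote ii arises with probability p_i^2 + 2 p_i r
    (true homozygote or heterozygote with a null copy); a visible
    heterozygote ij with 2 p_i p_j; an individual missing at the locus is
    attributed to the null homozygote rr. EM iterates until |dr| < tol;
    the observed-data log-likelihood is checked to be non-decreasing at
    every step.
    """
    g = np.sort(np.asarray(genotypes), axis=1)
    if len(g) == 0:
        raise ValueError("no visible genotypes")
    alleles = sorted({int(x) for x in g.ravel()})
    if len(alleles) < 2:
        raise ValueError("null-allele EM needs >= 2 visible alleles")
    hom = {a: 0 for a in alleles}
    het_pairs: dict[tuple[int, int], int] = {}
    for (i, j), c in _genotype_dict(g).items():
        if i == j:
            hom[int(i)] = hom.get(int(i), 0) + c
        else:
            het_pairs[(int(i), int(j))] = c
    n_total = len(g) + n_missing
    genes = 2 * n_total

    # init: visible frequencies, small r
    counts = allele_counts(g)
    p = {a: counts.get(a, 0) / (2 * len(g)) for a in alleles}
    r = 0.05 if n_missing == 0 else max(0.05, math.sqrt(n_missing / n_total))
    scale = sum(p.values()) + r
    p = {a: v / scale for a, v in p.items()}
    r /= scale

    def loglik(p: dict[int, float], r: float) -> float:
        ll = 0.0
        for (i, j), c in het_pairs.items():
            ll += c * math.log(max(2 * p[i] * p[j], 1e-300))
        for a, c in hom.items():
            if c:
                ll += c * math.log(max(p[a] ** 2 + 2 * p[a] * r, 1e-300))
        if n_missing:
            ll += n_missing * 2 * math.log(max(r, 1e-300))
        return ll

    ll_prev = loglik(p, r)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        exp_genes = {a: 0.0 for a in alleles}
        exp_null = 2.0 * n_missing
        for (i, j), c in het_pairs.items():
            exp_genes[i] += c
            exp_genes[j] += c
        for a, c in hom.items():
            if not c:
                continue
            denom = p[a] + 2 * r
            null_share = (2 * r) / denom if denom > 0 else 0.0
            exp_null += c * null_share
            exp_genes[a] += c * (2 - null_share)
        r_new = exp_null / genes
        p_new = {a: exp_genes[a] / genes for a in alleles}
        ll = loglik(p_new, r_new)
        if ll < ll_prev - 1e-8:
            raise AssertionError(
                f"EM decreased the log-likelihood at iteration {it}: {ll_prev} -> {ll}"
            )
        delta = abs(r_new - r)
        p, r, ll_prev = p_new, r_new, ll
        if delta < tol:
            converged = True
            break

    result = EMResult(
        allele_freqs=p, null_freq=r, n_iter=it, converged=converged,
        loglik=ll_prev, saturated=(sum(het_pairs.values()) == 0 or r > 0.5),
    )
    if not converged:
        raise EMNonConvergenceError(result)
    return result


# -------------------------------------------------------- multiple testing


def sequential_bonferroni(pvals: list[float] | np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Holm step-down flags: p_(i) is significant iff p_(j) <= alpha/(m-j+1)
    for every j <= i; the procedure stops at the first failure."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    flags = np.zeros(m, dtype=bool)
    for rank, i in enumerate(order):
        if p[i] <= alpha / (m - rank):
            flags[i] = True
        else:
            break
    return flags
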