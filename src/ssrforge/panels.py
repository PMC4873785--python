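"""Marker-panel construction and comparison.

Four panels are built from per-locus marker profiles:

* SNI  — loci whose alleles include off-ladder sizes (single-nucleotide
  insertions: allele sizes not all congruent modulo the motif length);
* MP   — the most polymorphic non-SNI loci, ranked by allele number, with
  all ties at the cut included;
* SS   — stringently selected loci: amplified in every individual, no SNI,
  not significantly HWE-deviant in every population, unambiguous peaks;
* ALL  — every developed marker.

Panels are compared by per-population allelic richness, expected
heterozygosity and Fis, pairwise Fst, two-sided Mann-Whitney rank tests per
statistic, leave-one-out likelihood assignment of individuals to their
population (a Q-like normalized membership probability with a 0.60
correctness threshold), and PCA of allele-count matrices.

The package bundles a reference table of 30 polymorphic SSR markers
characterized in two western flower thrips (Frankliniella occidentalis)
populations; ``load_reference_markers`` exposes it and the panel rules
reproduce its published panel labels.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from scipy.special import logsumexp

from .io import MISSING, GenotypeMatrix
from .popgen import (
    allele_counts,
    allelic_richness,
    locus_summary,
    standardized_gene_count,
    wc_fstats,
)

__all__ = [
    "MarkerProfile",
    "PanelSet",
    "PanelComparison",
    "detect_sni",
    "build_panels",
    "assign_individuals",
    "compare_panels",
    "mann_whitney",
    "pca_coordinates",
    "load_reference_markers",
    "profiles_from_table",
]


@dataclass(frozen=True)
class MarkerProfile:
    """Per-locus metadata driving panel construction.

    ambiguous_peaks is genotyping metadata (peak quality cannot be computed
    from allele calls); hwe_deviant_pops counts populations in which the
    locus deviates from HWE after sequential Bonferroni correction.
    """

    locus_id: str
    motif_length: int
    na: int
    n_genotyped: int
    cohort_size: int
    sni: bool = False
    ambiguous_peaks: bool = False
    hwe_deviant_pops: int = 0
    n_pops: int = 2

    @property
    def amplified_in_all(self) -> bool:
        return self.n_genotyped == self.cohort_size

    @property
    def hwe_deviant_everywhere(self) -> bool:
        """Deviant in every studied population (the stringent exclusion)."""
        return self.n_pops > 0 and self.hwe_deviant_pops >= self.n_pops


@dataclass
class PanelSet:
    mp: list[str]
    sni: list[str]
    ss: list[str]
    all: list[str]
    decisions: dict[str, dict[str, str]] = field(default_factory=dict)

    def as_dict(self) -> dict[str, list[str]]:
        return {"MP": self.mp, "SNI": self.sni, "SS": self.ss, "ALL": self.all}


def detect_sni(allele_sizes, motif_length: int) -> bool:
    """True iff allele sizes are not all congruent modulo the motif length.

    An off-ladder allele (e.g. +1 bp) indicates a single-nucleotide
    insertion in or near the repeat, which complicates allele binning.
    Invariant under adding a constant to all sizes.
    """
    if motif_length < 2:
        raise ValueError("SNI detection is undefined for mononucleotide loci")
    sizes = sorted(set(int(s) for s in allele_sizes))
    if len(sizes) < 2:
        return False
    return len({s % motif_length for s in sizes}) > 1


def build_panels(profiles: list[MarkerProfile], k: int = 8) -> PanelSet:
    """Construct the MP / SNI / SS / ALL panels, recording each decision.

    MP ranks non-SNI loci by allele number and takes the top k, including
    every locus tied with the k-th; deterministic and idempotent.
    """
    decisions: dict[str, dict[str, str]] = {p.locus_id: {} for p in profiles}

    sni = [p.locus_id for p in profiles if p.sni]
    for p in profiles:
        decisions[p.locus_id]["SNI"] = (
            "included: off-ladder alleles" if p.sni else "excluded: alleles on motif ladder"
        )

    non_sni = sorted((p for p in profiles if not p.sni), key=lambda p: (-p.na, p.locus_id))
    mp: list[str] = []
    if non_sni:
        cut = non_sni[min(k, len(non_sni)) - 1].na
        mp = [p.locus_id for p in non_sni if p.na >= cut]
    for p in profiles:
        if p.sni:
            decisions[p.locus_id]["MP"] = "excluded: SNI locus"
        elif p.locus_id in mp:
            decisions[p.locus_id]["MP"] = f"included: Na={p.na} within top-{k} (ties kept)"
        else:
            decisions[p.locus_id]["MP"] = f"excluded: Na={p.na} below rank-{k} cut"

    ss: list[str] = []
    for p in profiles:
        reasons = []
        if not p.amplified_in_all:
            reasons.append(f"amplified in {p.n_genotyped}/{p.cohort_size}")
        if p.sni:
            reasons.append("SNI locus")
        if p.hwe_deviant_everywhere:
            reasons.append("HWE-deviant in every population")
        if p.ambiguous_peaks:
            reasons.append("ambiguous peaks")
        if reasons:
            decisions[p.locus_id]["SS"] = "excluded: " + "; ".join(reasons)
        else:
            decisions[p.locus_id]["SS"] = "included: passes all stringent criteria"
            ss.append(p.locus_id)

    all_ids = [p.locus_id for p in profiles]
    for p in profiles:
        decisions[p.locus_id]["ALL"] = "included: developed marker"
    return PanelSet(mp=mp, sni=sni, ss=ss, all=all_ids, decisions=decisions)


# ----------------------------------------------------------- assignment


def assign_individuals(
    gm: GenotypeMatrix, panel: list[str], q_threshold: float = 0.60
) -> pd.DataFrame:
    """Leave-one-out likelihood assignment of individuals to populations.

    For each individual, per-population allele frequencies at the panel
    loci are recomputed excluding that individual; zero frequencies are
    smoothed to 1/(2n+1). The multilocus genotype log-likelihood under HWE
    gives normalized membership probabilities Q; an individual is counted
    correct iff the most likely population is its true one and Q reaches
    the threshold. Individuals missing at every panel locus are reported
    unassigned.
    """
    if len(gm.pop_names) < 2:
        raise ValueError("assignment requires at least two populations")
    if not panel:
        raise ValueError("empty panel")
    pops = gm.pop_names
    loci_idx = [gm.locus_index(l) for l in panel]
    rows = []
    for i, ind in enumerate(gm.individual_ids):
        true_pop = gm.populations[i]
        own = gm.calls[i, loci_idx, :]
        if (own == MISSING).all():
            rows.append(
                {"individual": ind, "true_pop": true_pop, "assigned": None, "correct": False,
                 "unassigned": True, **{f"q_{p}": float("nan") for p in pops}}
            )
            continue
        ll = {}
        for pop in pops:
            mask = gm.pop_mask(pop)
            mask_i = mask.copy()
            mask_i[i] = False  # leave-one-out (no-op for other populations)
            total = 0.0
            for j, locus in zip(loci_idx, panel):
                a, b = gm.calls[i, j, :]
                if a == MISSING or b == MISSING:
                    continue
                ref = gm.calls[mask_i, j, :]
                ref = ref[(ref != MISSING).all(axis=1)]
                genes = 2 * len(ref)
                if genes == 0:
                    continue
                counts = allele_counts(ref)
                smooth = 1.0 / (genes + 1)
                pa = counts.get(int(a), 0) / genes or smooth
                pb = counts.get(int(b), 0) / genes or smooth
                total += np.log(pa * pa) if a == b else np.log(2 * pa * pb)
            ll[pop] = total
        lls = np.array([ll[p] for p in pops])
        q = np.exp(lls - logsumexp(lls))
        assigned = pops[int(np.argmax(q))]
        rows.append(
            {
                "individual": ind,
                "true_pop": true_pop,
                "assigned": assigned,
                "correct": bool(assigned == true_pop and q.max() >= q_threshold),
                "unassigned": False,
                **{f"q_{p}": float(qi) for p, qi in zip(pops, q)},
            }
        )
    return pd.DataFrame(rows)


# ----------------------------------------------------------- comparison


def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney rank test.

    Returns (W, P) with W the U statistic of the first sample (the
    convention of R's wilcox.test); exact when both samples have <= 12
    observations and no ties, normal-approximate otherwise.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    exact = (
        len(x) <= 12 and len(y) <= 12 and len(np.unique(np.concatenate([x, y]))) == len(x) + len(y)
    )
    res = mannwhitneyu(x, y, alternative="two-sided", method="exact" if exact else "asymptotic")
    return float(res.statistic), float(res.pvalue)


def pca_coordinates(gm: GenotypeMatrix, panel: list[str], n_components: int = 2) -> pd.DataFrame:
    """PCA of individuals on centered allele-count indicators.

    Each (locus, allele) pair is a column holding 0/1/2 copies; missing
    genotypes are filled with the column mean before centering. The sign of
    each component is fixed by forcing its largest-magnitude loading
    positive.
    """
    cols = []
    names = []
    for locus in panel:
        j = gm.locus_index(locus)
        g = gm.calls[:, j, :]
        present = (g != MISSING).all(axis=1)
        for allele in sorted({int(x) for x in g[present].ravel()}):
            v = np.where(present, (g == allele).sum(axis=1), np.nan).astype(float)
            cols.append(v)
            names.append(f"{locus}:{allele}")
    X = np.column_stack(cols)
    col_mean = np.nanmean(X, axis=0)
    X = np.where(np.isnan(X), col_mean, X) - col_mean
    _, s, vt = np.linalg.svd(X, full_matrices=False)
    k = min(n_components, vt.shape[0])
    coords = X @ vt[:k].T
    for c in range(k):
        load = vt[c]
        if load[np.argmax(np.abs(load))] < 0:
            coords[:, c] *= -1
    out = pd.DataFrame(coords, columns=[f"PC{c + 1}" for c in range(k)])
    out.insert(0, "individual", gm.individual_ids)
    out.insert(1, "population", gm.populations)
    var = s**2 / max(len(gm.individual_ids) - 1, 1)
    out.attrs["explained_variance_ratio"] = (var / var.sum())[:k].tolist()
    return out


@dataclass
class PanelComparison:
    diversity: pd.DataFrame  # panel x population x locus: AR, Ho, He
    summary: pd.DataFrame  # panel x population means + Fis; plus per-panel Fst
    fst: dict[str, float]
    tests: pd.DataFrame  # panel pair x population x statistic: W, P
    assignment: dict[str, pd.DataFrame]
    pca: dict[str, pd.DataFrame]


def compare_panels(
    gm: GenotypeMatrix, panels: PanelSet, q_threshold: float = 0.60
) -> PanelComparison:
    """Evaluate the four panels on one genotype dataset.

    Per-locus AR (rarefied to the locus's standardized gene count) and He
    feed the per-population panel means and the pairwise Mann-Whitney
    tests; Fis is the multilocus 1 - sum(Ho)/sum(He) per population;
    Fst is the multilocus Weir-Cockerham theta per panel. Loci undefined
    in a population are excluded pairwise.
    """
    pops = gm.pop_names
    per_locus_rows = []
    for locus in panels.all:
        g_std = standardized_gene_count(gm, locus)
        summ = locus_summary(gm, locus)
        for pop in pops:
            st = summ[pop]
            if not st.defined or g_std < 1:
                continue
            ar = allelic_richness(allele_counts(gm.genotypes(locus, pop)), g_std)
            per_locus_rows.append(
                {"locus": locus, "population": pop, "n": st.n, "na": st.na,
                 "ho": st.ho, "he": st.he, "ar": ar}
            )
    per_locus = pd.DataFrame(per_locus_rows)

    summary_rows = []
    fst: dict[str, float] = {}
    tests_rows = []
    assignment: dict[str, pd.DataFrame] = {}
    pca: dict[str, pd.DataFrame] = {}
    panel_map = panels.as_dict()
    for name, loci in panel_map.items():
        if not loci:
            continue
        sub = per_locus[per_locus["locus"].isin(loci)]
        for pop in pops:
            sp = sub[sub["population"] == pop]
            he_sum = sp["he"].sum()
            summary_rows.append(
                {
                    "panel": name,
                    "population": pop,
                    "n_loci": len(sp),
                    "mean_ar": sp["ar"].mean(),
                    "mean_he": sp["he"].mean(),
                    "mean_ho": sp["ho"].mean(),
                    "fis": 1.0 - sp["ho"].sum() / he_sum if he_sum > 0 else float("nan"),
                }
            )
        fst[name] = wc_fstats(gm, loci=loci).fst
        assignment[name] = assign_individuals(gm, loci, q_threshold)
        pca[name] = pca_coordinates(gm, loci)

    names = [n for n, l in panel_map.items() if l]
    for a_idx in range(len(names)):
        for b_idx in range(a_idx + 1, len(names)):
            a, b = names[a_idx], names[b_idx]
            for pop in pops:
                for stat in ("ar", "he"):
                    xa = per_locus[(per_locus["locus"].isin(panel_map[a])) & (per_locus["population"] == pop)][stat]
                    xb = per_locus[(per_locus["locus"].isin(panel_map[b])) & (per_locus["population"] == pop)][stat]
                    if len(xa) == 0 or len(xb) == 0:
                        continue
                    w, p = mann_whitney(xa, xb)
                    tests_rows.append(
                        {"panel_a": a, "panel_b": b, "population": pop,
                         "statistic": stat.upper(), "W": w, "P": p}
                    )
    return PanelComparison(
        diversity=per_locus,
        summary=pd.DataFrame(summary_rows),
        fst=fst,
        tests=pd.DataFrame(tests_rows),
        assignment=assignment,
        pca=pca,
    )


# ------------------------------------------------------- bundled reference


def load_reference_markers() -> pd.DataFrame:
    """The bundled table of 30 characterized F. occidentalis SSR markers.

    Columns: locus, scaffold, motif, units, size range, allele number (na),
    individuals genotyped (n, cohort 47), populations deviating from HWE
    after correction (hwe_deviant_pops), ambiguous_peaks, sni, and the
    reference panel label(s).
    """
    with importlib.resources.files("ssrforge.data").joinpath("wft_markers.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    df["panel"] = df["panel"].fillna("")
    for col in ("ambiguous_peaks", "sni"):
        if df[col].dtype != bool:
            df[col] = df[col].astype(str).str.lower().eq("true")
    return df


def profiles_from_genotypes(
    gm: GenotypeMatrix,
    alpha: float = 0.05,
    hwe_reps: int = 20_000,
    seed: int | None = None,
    ambiguous: set[str] | None = None,
) -> list[MarkerProfile]:
    """Derive MarkerProfiles from genotype data.

    Computes Na and the genotyped count from the calls, flags SNI loci from
    the observed allele-size ladders (requires gm.motif_lengths), and tests
    HWE per locus/population with sequential Bonferroni correction over the
    whole family. Peak ambiguity is metadata and must be supplied.
    """
    from .popgen import hwe_exact_test, sequential_bonferroni

    ambiguous = ambiguous or set()
    pops = gm.pop_names
    pvals, keys = [], []
    for locus in gm.locus_ids:
        for pop in pops:
            g = gm.genotypes(locus, pop)
            if len(g) == 0:
                continue
            pvals.append(hwe_exact_test(g, reps=hwe_reps, seed=seed))
            keys.append((locus, pop))
    flags = dict(zip(keys, sequential_bonferroni(pvals, alpha)))
    profiles = []
    for locus in gm.locus_ids:
        g = gm.genotypes(locus)
        k = gm.motif_lengths.get(locus, 0)
        sizes = sorted({int(x) for x in g.ravel()})
        profiles.append(
            MarkerProfile(
                locus_id=locus,
                motif_length=k,
                na=len(sizes),
                n_genotyped=len(g),
                cohort_size=len(gm.individual_ids),
                sni=detect_sni(sizes, k) if k >= 2 and len(sizes) >= 2 else False,
                ambiguous_peaks=locus in ambiguous,
                hwe_deviant_pops=sum(
                    bool(flags.get((locus, pop), False)) for pop in pops
                ),
                n_pops=len(pops),
            )
        )
    return profiles


def profiles_from_table(df: pd.DataFrame, cohort_size: int = 47, n_pops: int = 2) -> list[MarkerProfile]:
    """MarkerProfiles from a marker table shaped like the bundled one."""
    return [
        MarkerProfile(
            locus_id=row.locus,
            motif_length=len(row.motif),
            na=int(row.na),
            n_genotyped=int(row.n),
            cohort_size=cohort_size,
            sni=bool(row.sni),
            ambiguous_peaks=bool(row.ambiguous_peaks),
            hwe_deviant_pops=int(row.hwe_deviant_pops),
            n_pops=n_pops,
        )
        for row in df.itertuples()
    ]
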