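"""Genome-level characterization of a set of detected microsatellites.

Two normalized summary statistics are central:

* relative abundance — SSR loci per Mb of genome,
* relative density — Kb of SSR sequence per Mb of genome,

with the genome length taken as the raw assembly total (scaffold lengths
including N runs). Tabulations by motif class and locus length mirror the
usual genome-survey figures: counts per 3-bp length bin, mean mismatches and
imperfect fraction per bin (restricted to 20-70 bp, where imperfect loci can
exist under default scan parameters), and a ranking of canonical motifs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .scan import SSRRecord

__all__ = ["ProfileStats", "profile_genome", "mismatch_length_table", "motif_ranking_frame"]


@dataclass
class ProfileStats:
    total_count: int
    perfect_count: int
    genome_length: int
    relative_abundance: float  # loci / Mb
    relative_density: float  # Kb of SSR / Mb of genome
    mean_length: float
    length_quantiles: dict[float, float]
    per_category_counts: dict[int, int]
    motif_ranking: list[tuple[str, int, float]]
    length_histogram: pd.DataFrame
    mismatch_by_length: pd.DataFrame

    def summary_frame(self) -> pd.DataFrame:
        rows = {
            "total_count": self.total_count,
            "perfect_count": self.perfect_count,
            "genome_length_bp": self.genome_length,
            "relative_abundance_loci_per_mb": self.relative_abundance,
            "relative_density_kb_per_mb": self.relative_density,
            "mean_length_bp": self.mean_length,
        }
        rows.update({f"length_q{int(q * 100)}": v for q, v in self.length_quantiles.items()})
        rows.update({f"count_motif_len_{k}": v for k, v in self.per_category_counts.items()})
        return pd.DataFrame({"statistic": list(rows), "value": list(rows.values())})


def _length_bins(max_len: int, bin_width: int = 3, lo: int = 12, hi: int = 70) -> np.ndarray:
    """Bin edges: 3-bp bins from 12 bp up to a final open-ended 70+ bin."""
    edges = list(range(lo, hi + 1, bin_width))
    top = max(hi, max_len) + bin_width
    edges.append(top)
    return np.array(edges)


def relative_abundance(count: int, genome_length: int) -> float:
    """Loci per Mb of genome."""
    return count / (genome_length / 1e6)

def relative_density(total_ssr_bp: int | float, genome_length: int) -> float:
    """Kb of SSR sequence per Mb of genome."""
    return (total_ssr_bp / 1e3) / (genome_length / 1e6)


def profile_genome(records: list[SSRRecord], genome_length: int, bin_width: int = 3) -> ProfileStats:
    """Summarize SSR records against a genome of the given total length."""
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    if not records:
        empty = pd.DataFrame(
            columns=["motif_length", "bin_start", "bin_end", "count"]
        )
        empty_mm = pd.DataFrame(
            columns=["motif_length", "bin_start", "bin_end", "count", "mean_mismatches", "imperfect_fraction"]
        )
        return ProfileStats(
            total_count=0,
            perfect_count=0,
            genome_length=genome_length,
            relative_abundance=0.0,
            relative_density=0.0,
            mean_length=float("nan"),
            length_quantiles={},
            per_category_counts={k: 0 for k in range(1, 7)},
            motif_ranking=[],
            length_histogram=empty,
            mismatch_by_length=empty_mm,
        )

    df = pd.DataFrame(
        {
            "motif": [r.motif for r in records],
            "motif_length": [len(r.motif) for r in records],
            "length": [r.length for r in records],
            "mismatches": [r.mismatches for r in records],
            "perfect": [r.perfect for r in records],
        }
    )
    total = len(df)
    total_bp = int(df["length"].sum())

    counts = df["motif"].value_counts()
    # ties in count broken alphabetically (value_counts is count-desc, then insertion order)
    ranking_df = counts.rename_axis("motif").reset_index(name="count")
    ranking_df = ranking_df.sort_values(["count", "motif"], ascending=[False, True])
    ranking = [(m, int(c), c / total) for m, c in ranking_df.itertuples(index=False)]

    edges = _length_bins(int(df["length"].max()), bin_width)
    df["bin"] = pd.cut(df["length"], bins=edges, right=False, include_lowest=True)
    hist = (
        df.groupby(["motif_length", "bin"], observed=False)
        .size()
        .reset_index(name="count")
    )
    hist["bin_start"] = hist["bin"].map(lambda b: int(b.left))
    hist["bin_end"] = hist["bin"].map(lambda b: int(b.right) - 1)
    hist = hist[["motif_length", "bin_start", "bin_end", "count"]]

    return ProfileStats(
        total_count=total,
        perfect_count=int(df["perfect"].sum()),
        genome_length=genome_length,
        relative_abundance=relative_abundance(total, genome_length),
        relative_density=relative_density(total_bp, genome_length),
        mean_length=float(df["length"].mean()),
        length_quantiles={
            q: float(df["length"].quantile(q)) for q in (0.25, 0.5, 0.75, 0.95)
        },
        per_category_counts={
            k: int((df["motif_length"] == k).sum()) for k in range(1, 7)
        },
        motif_ranking=ranking,
        length_histogram=hist,
        mismatch_by_length=mismatch_length_table(records, bin_width),
    )


def mismatch_length_table(
    records: list[SSRRecord], bin_width: int = 3, lo: int = 20, hi: int = 70
) -> pd.DataFrame:
    """Mean mismatches and imperfect fraction per (motif length, length bin).

    Restricted to loci of lo..hi bp (defaults 20-70): shorter loci are
    always perfect under default scan parameters, longer ones are sparse.
    """
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    df = pd.DataFrame(
        {
            "motif_length": [len(r.motif) for r in records],
            "length": [r.length for r in records],
            "mismatches": [r.mismatches for r in records],
            "imperfect": [not r.perfect for r in records],
        }
    )
    df = df[(df["length"] >= lo) & (df["length"] <= hi)]
    if df.empty:
        return pd.DataFrame(
            columns=["motif_length", "bin_start", "bin_end", "count", "mean_mismatches", "imperfect_fraction"]
        )
    edges = np.arange(lo, hi + bin_width + 1, bin_width)
    df = df.assign(bin=pd.cut(df["length"], bins=edges, right=False, include_lowest=True))
    g = df.groupby(["motif_length", "bin"], observed=True)
    out = g.agg(
        count=("length", "size"),
        mean_mismatches=("mismatches", "mean"),
        imperfect_fraction=("imperfect", "mean"),
    ).reset_index()
    out["bin_start"] = out["bin"].map(lambda b: int(b.left))
    out["bin_end"] = out["bin"].map(lambda b: int(b.right) - 1)
    return out[
        ["motif_length", "bin_start", "bin_end", "count", "mean_mismatches", "imperfect_fraction"]
    ]


def motif_ranking_frame(stats: ProfileStats, top: int | None = None) -> pd.DataFrame:
    rows = stats.motif_ranking if top is None else stats.motif_ranking[:top]
    return pd.DataFrame(rows, columns=["motif", "count", "fraction"])
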