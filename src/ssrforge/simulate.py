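"""Synthetic inputs with known ground truth.

Two generators cover the pipeline's input side:

* ``simulate_genome`` — scaffolds of random background DNA with planted
  perfect or imperfect SSRs at known coordinates. Background segments are
  rejection-sampled until they contain no locus passing the default scan
  parameters, so the planted truth table is exactly the set of detectable
  loci.

* ``simulate_genotypes`` — a two-population diploid genotype dataset on
  allele-size ladders. Ancestral allele frequencies are Dirichlet(1,...,1)
  over 4-17 alleles per locus; population frequencies follow the
  Balding-Nichols model at a target Fst (closed-form differentiation, no
  coalescent machinery needed); genotypes are drawn under HWE. Null
  alleles hide single copies (apparent homozygotes) or whole genotypes
  (two null copies), off-ladder +1 bp alleles model single-nucleotide
  insertions, and missing data are applied after the null-allele logic so
  the two causes of absence stay distinguishable in the truth record.

Both generators are bit-deterministic under their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .io import MISSING, GenotypeMatrix
from .scan import ScanParams, SSRRecord, canonical_motif, scan_sequence

__all__ = [
    "PlantedSSR",
    "GenomeSimParams",
    "GenotypeSimParams",
    "simulate_genome",
    "simulate_genotypes",
]


@dataclass(frozen=True)
class PlantedSSR:
    motif: str
    units: int
    mismatch_positions: tuple[int, ...] = ()  # 0-based bp offsets within the repeat

    def build(self) -> tuple[str, int]:
        """Repeat sequence with substitutions applied; returns (seq, mismatches)."""
        seq = list(self.motif * self.units)
        k = len(self.motif)
        for pos in self.mismatch_positions:
            if not (k <= pos < len(seq) - k):
                raise ValueError(
                    f"mismatch position {pos} too close to the repeat boundary"
                )
            expected = seq[pos]
            seq[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[expected]
        return "".join(seq), len(self.mismatch_positions)


@dataclass
class GenomeSimParams:
    n_scaffolds: int = 1
    scaffold_length: int = 10_000
    gc_content: float = 0.5
    planted_loci: list[PlantedSSR] = field(default_factory=list)
    min_spacing: int = 50
    seed: int = 0


class GenomeSizingError(ValueError):
    pass


def _clean_segment(rng: np.random.Generator, length: int, gc: float, params: ScanParams,
                   max_tries: int = 200) -> str:
    """Random background DNA of the given length with no detectable SSR."""
    if length == 0:
        return ""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = np.array(list("ACGT"))
    for _ in range(max_tries):
        seq = "".join(rng.choice(bases, size=length, p=p))
        if not scan_sequence(seq, "bg", params):
            return seq
    raise GenomeSizingError(f"could not draw a clean {length}-bp background segment")


def simulate_genome(
    params: GenomeSimParams, scan_params: ScanParams | None = None
) -> tuple[dict[str, str], list[SSRRecord]]:
    """Generate scaffolds with planted SSRs; returns (sequences, truth records).

    Planted loci are distributed round-robin across scaffolds with at least
    ``min_spacing`` bp of screened background between them; after assembly
    each scaffold is re-screened and rebuilt if the junctions created any
    unplanned detectable locus.
    """
    sp = scan_params or ScanParams()
    rng = np.random.default_rng(params.seed)
    per_scaffold: list[list[PlantedSSR]] = [[] for _ in range(params.n_scaffolds)]
    for i, locus in enumerate(params.planted_loci):
        per_scaffold[i % params.n_scaffolds].append(locus)

    seqs: dict[str, str] = {}
    truth: list[SSRRecord] = []
    for s in range(params.n_scaffolds):
        sid = f"scaffold_{s + 1}"
        loci = per_scaffold[s]
        repeat_seqs = [l.build() for l in loci]
        total_repeat = sum(len(r) for r, _ in repeat_seqs)
        n_gaps = len(loci) + 1
        free = params.scaffold_length - total_repeat
        if free < params.min_spacing * n_gaps:
            raise GenomeSizingError(
                f"scaffold {sid}: {total_repeat} bp of repeats + spacing exceeds "
                f"{params.scaffold_length} bp"
            )
        for attempt in range(50):
            gap_extra = rng.multinomial(free - params.min_spacing * n_gaps,
                                        np.ones(n_gaps) / n_gaps)
            gaps = [params.min_spacing + int(e) for e in gap_extra]
            parts: list[str] = []
            records: list[SSRRecord] = []
            pos = 0
            for gap, locus, (rep_seq, mm) in zip(gaps, loci, repeat_seqs):
                parts.append(_clean_segment(rng, gap, params.gc_content, sp))
                pos += gap
                parts.append(rep_seq)
                length = len(rep_seq)
                records.append(
                    SSRRecord(
                        sequence_id=sid,
                        start=pos + 1,
                        end=pos + length,
                        motif=canonical_motif(locus.motif),
                        length=length,
                        mismatches=mm,
                        score=length - sp.mismatch_penalty * mm,
                        perfect=(mm == 0),
                    )
                )
                pos += length
            parts.append(_clean_segment(rng, gaps[-1] if len(gaps) == len(loci) + 1 else 0,
                                        params.gc_content, sp))
            seq = "".join(parts)
            found = scan_sequence(seq, sid, sp)
            planted_iv = [(r.start, r.end) for r in records]
            extraneous = [
                f for f in found
                if not any(f.start <= e and f.end >= s0 for s0, e in planted_iv)
            ]
            # junction bases may accidentally continue a repeat's period;
            # demand boundary agreement within one motif unit so the truth
            # table matches what the scanner can recover
            sloppy = False
            for r in records:
                hits = [f for f in found if f.start <= r.end and f.end >= r.start]
                tol = len(r.motif) - 1
                if len(hits) != 1 or abs(hits[0].start - r.start) > tol or abs(
                    hits[0].end - r.end
                ) > tol:
                    sloppy = True
                    break
            if not extraneous and not sloppy:
                seqs[sid] = seq
                truth.extend(records)
                break
        else:
            raise GenomeSizingError(f"scaffold {sid}: junctions kept creating spurious loci")
    return seqs, truth


# ------------------------------------------------------------- genotypes


@dataclass
class GenotypeSimParams:
    """Two-population diploid genotype simulation settings.

    Defaults emulate a two-site survey of 23 + 24 individuals typed at 30
    tri-/tetra-nucleotide loci with moderate differentiation.
    """

    n_per_pop: tuple[int, ...] = (23, 24)
    n_loci: int = 30
    min_alleles: int = 4
    max_alleles: int = 17
    target_fst: float = 0.10
    null_rate: dict[int, float] | float = 0.0  # per-locus or global
    sni_loci: dict[int, float] = field(default_factory=dict)  # locus index -> +1bp allele freq
    missing_rate: float = 0.0
    motif_lengths: tuple[int, ...] = (3, 4)
    ladder_offset: int = 150
    seed: int = 0

    def null_rate_at(self, locus: int) -> float:
        if isinstance(self.null_rate, dict):
            return self.null_rate.get(locus, 0.0)
        return float(self.null_rate)


def _balding_nichols(rng: np.random.Generator, p: np.ndarray, fst: float) -> np.ndarray:
    if fst <= 0:
        return p.copy()
    return rng.dirichlet(p * (1 - fst) / fst)


def simulate_genotypes(params: GenotypeSimParams) -> tuple[GenotypeMatrix, dict[str, Any]]:
    """Simulate genotypes; returns (GenotypeMatrix, truth).

    Truth records population labels, per-population allele frequencies,
    the allele-size ladders, SNI allele sizes, and realized null/missing
    events per individual x locus.
    """
    rng = np.random.default_rng(params.seed)
    n_pops = len(params.n_per_pop)
    pops = [f"pop{i + 1}" for i in range(n_pops)]
    pop_labels = [p for p, n in zip(pops, params.n_per_pop) for _ in range(n)]
    n_ind = len(pop_labels)
    ids = [f"{pop}_ind{j + 1}" for pop in pops for j in range(dict(zip(pops, params.n_per_pop))[pop])]

    calls = np.zeros((n_ind, params.n_loci, 2), dtype=np.int64)
    loci = [f"L{l + 1:03d}" for l in range(params.n_loci)]
    motif_lengths: dict[str, int] = {}
    truth: dict[str, Any] = {
        "populations": pop_labels,
        "loci": {},
        "null_events": np.zeros((n_ind, params.n_loci), dtype=np.int64),
        "missing_events": np.zeros((n_ind, params.n_loci), dtype=bool),
    }

    for l, locus in enumerate(loci):
        k = int(rng.choice(params.motif_lengths))
        na = int(rng.integers(params.min_alleles, params.max_alleles + 1))
        start = params.ladder_offset + int(rng.integers(0, 20)) * k
        sizes = start + k * np.arange(na)
        anc = rng.dirichlet(np.ones(na))
        pop_freqs = [_balding_nichols(rng, anc, params.target_fst) for _ in range(n_pops)]
        sni_size = None
        if l in params.sni_loci:
            f_sni = params.sni_loci[l]
            sni_size = int(sizes[na // 2]) + 1
            sizes = np.append(sizes, sni_size)
            pop_freqs = [np.append(f * (1 - f_sni), f_sni) for f in pop_freqs]
        motif_lengths[locus] = k
        truth["loci"][locus] = {
            "motif_length": k,
            "sizes": sizes.tolist(),
            "sni_size": sni_size,
            "ancestral_freqs": anc.tolist(),
            "pop_freqs": {pop: f.tolist() for pop, f in zip(pops, pop_freqs)},
            "null_rate": params.null_rate_at(l),
        }

        nr = params.null_rate_at(l)
        row = 0
        for pi, n_in_pop in enumerate(params.n_per_pop):
            f = pop_freqs[pi]
            draws = rng.choice(len(sizes), size=(n_in_pop, 2), p=f)
            geno = sizes[draws]
            if nr > 0:
                nulls = rng.random((n_in_pop, 2)) < nr
                for ii in range(n_in_pop):
                    n_null = int(nulls[ii].sum())
                    truth["null_events"][row + ii, l] = n_null
                    if n_null == 2:
                        geno[ii] = (MISSING, MISSING)
                    elif n_null == 1:
                        visible = geno[ii, 1 - int(np.where(nulls[ii])[0][0])]
                        geno[ii] = (visible, visible)
            if params.missing_rate > 0:
                drop = rng.random(n_in_pop) < params.missing_rate
                truth["missing_events"][row : row + n_in_pop, l] |= drop
                geno[drop] = (MISSING, MISSING)
            calls[row : row + n_in_pop, l, :] = np.sort(geno, axis=1)
            row += n_in_pop

    gm = GenotypeMatrix(
        individual_ids=ids,
        populations=pop_labels,
        locus_ids=loci,
        calls=calls,
        motif_lengths=motif_lengths,
        title=f"simulated two-population SSR dataset (seed={params.seed})",
    )
    return gm, truth
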