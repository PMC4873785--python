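"""File formats: FASTA, GENEPOP, and the pipeline's TSV tables.

GENEPOP is the standard text exchange format for diploid co-dominant
genotypes: a title line, one locus name per line (or comma-separated), and
``Pop`` blocks of individuals, each line ``id ,`` followed by one 4- or
6-digit code per locus (two 2- or 3-digit allele calls; here a call is the
fragment size in bp). ``000``/``00`` encodes a missing allele. No reader for
the format ships with the scientific stack, so parsing lives here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .scan import SSRRecord

MISSING = 0  # allele-size sentinel for a missing call

__all__ = [
    "MISSING",
    "GenotypeMatrix",
    "read_fasta",
    "read_genepop",
    "write_genepop",
    "records_to_frame",
    "write_ssr_tsv",
    "read_ssr_tsv",
]


class GenepopParseError(ValueError):
    pass


@dataclass
class GenotypeMatrix:
    """Diploid allele-size calls, individuals x loci.

    calls has shape (n_individuals, n_loci, 2); entries are allele sizes in
    bp, with ``MISSING`` (0) marking an absent call. Both alleles of a
    genotype are missing together or present together on write.
    """

    individual_ids: list[str]
    populations: list[str]
    locus_ids: list[str]
    calls: np.ndarray
    motif_lengths: dict[str, int] = field(default_factory=dict)
    title: str = "ssrforge dataset"

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int64)
        n, m = len(self.individual_ids), len(self.locus_ids)
        if self.calls.shape != (n, m, 2):
            raise ValueError(f"calls shape {self.calls.shape} != {(n, m, 2)}")
        if len(self.populations) != n:
            raise ValueError("one population label per individual required")

    @property
    def pop_names(self) -> list[str]:
        seen: list[str] = []
        for p in self.populations:
            if p not in seen:
                seen.append(p)
        return seen

    def pop_mask(self, pop: str) -> np.ndarray:
        return np.array([p == pop for p in self.populations])

    def locus_index(self, locus: str) -> int:
        return self.locus_ids.index(locus)

    def genotypes(self, locus: str, pop: str | None = None) -> np.ndarray:
        """Non-missing genotype pairs (n x 2 allele sizes) at one locus."""
        j = self.locus_index(locus)
        g = self.calls[:, j, :]
        if pop is not None:
            g = g[self.pop_mask(pop)]
        return g[(g != MISSING).all(axis=1)]

    def subset_loci(self, loci: list[str]) -> "GenotypeMatrix":
        idx = [self.locus_index(l) for l in loci]
        return GenotypeMatrix(
            individual_ids=list(self.individual_ids),
            populations=list(self.populations),
            locus_ids=list(loci),
            calls=self.calls[:, idx, :].copy(),
            motif_lengths={l: self.motif_lengths[l] for l in loci if l in self.motif_lengths},
            title=self.title,
        )


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a (wrapped or unwrapped) FASTA file, uppercasing sequences.

    Order of records is preserved; N is accepted.
    """
    path = Path(path)
    seqs: dict[str, str] = {}
    with open(path) as fh:
        first = fh.read(1)
        if first == "":
            raise ValueError(f"{path}: empty FASTA file")
        if first != ">":
            raise ValueError(f"{path}: line 1: expected FASTA header starting with '>'")
    for rec in SeqIO.parse(str(path), "fasta"):
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for sid, seq in seqs.items():
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _parse_code(code: str, indiv: str) -> tuple[int, int]:
    if len(code) == 6:
        a, b = int(code[:3]), int(code[3:])
    elif len(code) == 4:
        a, b = int(code[:2]), int(code[2:])
    else:
        raise GenepopParseError(f"individual {indiv!r}: allele code {code!r} is not 4 or 6 digits")
    return a, b


def read_genepop(path: str | Path) -> GenotypeMatrix:
    """Parse a GENEPOP file into a GenotypeMatrix (allele size = code)."""
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise GenepopParseError("empty GENEPOP file")
    title = lines[0].strip()
    loci: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().lower() != "pop":
        for name in lines[i].replace(",", " ").split():
            loci.append(name)
        i += 1
    if i == len(lines):
        raise GenepopParseError("no 'Pop' separator found")

    ids: list[str] = []
    pops: list[str] = []
    rows: list[list[tuple[int, int]]] = []
    pop_no = 0
    while i < len(lines):
        line = lines[i].strip()
        i += 1
        if not line:
            continue
        if line.lower() == "pop":
            pop_no += 1
            continue
        if "," not in line:
            raise GenepopParseError(f"line {i}: expected 'id , codes': {line!r}")
        indiv, codes_s = line.split(",", 1)
        indiv = indiv.strip()
        codes = codes_s.split()
        if len(codes) != len(loci):
            raise GenepopParseError(
                f"individual {indiv!r}: {len(codes)} codes for {len(loci)} loci"
            )
        rows.append([_parse_code(c, indiv) for c in codes])
        ids.append(indiv)
        pops.append(f"pop{pop_no}")
    calls = np.array(rows, dtype=np.int64)
    return GenotypeMatrix(ids, pops, loci, calls, title=title)


def write_genepop(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write a GenotypeMatrix as GENEPOP with 3-digit codes; missing = 000000."""
    if int(gm.calls.max(initial=0)) > 999:
        raise ValueError("allele sizes above 999 bp cannot be encoded as 3-digit codes")
    out = [gm.title]
    out.extend(gm.locus_ids)
    current = None
    for i, pop in enumerate(gm.populations):
        if pop != current:
            out.append("Pop")
            current = pop
        codes = "".join(
            f" {a:03d}{b:03d}" for a, b in gm.calls[i]
        )
        out.append(f"{gm.individual_ids[i]} ,{codes}")
    Path(path).write_text("\n".join(out) + "\n")


_SSR_COLUMNS = ["sequence_id", "start", "end", "motif", "length", "mismatches", "score", "perfect"]


def records_to_frame(records: list[SSRRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.sequence_id, r.start, r.end, r.motif, r.length, r.mismatches, r.score, r.perfect)
            for r in records
        ],
        columns=_SSR_COLUMNS,
    )


def write_ssr_tsv(records: list[SSRRecord], path: str | Path, bed: bool = False) -> None:
    """Write records as TSV (1-based inclusive) or BED (0-based half-open)."""
    df = records_to_frame(records)
    if bed:
        bed_df = pd.DataFrame(
            {
                "chrom": df["sequence_id"],
                "chromStart": df["start"] - 1,
                "chromEnd": df["end"],
                "name": df["motif"],
                "score": df["score"],
            }
        )
        bed_df.to_csv(path, sep="\t", header=False, index=False)
    else:
        df.to_csv(path, sep="\t", index=False)


def read_ssr_tsv(path: str | Path) -> list[SSRRecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        SSRRecord(
            sequence_id=str(row.sequence_id),
            start=int(row.start),
            end=int(row.end),
            motif=str(row.motif),
            length=int(row.length),
            mismatches=int(row.mismatches),
            score=int(row.score),
            perfect=bool(row.perfect),
        )
        for row in df.itertuples()
    ]
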