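"""Marker-candidate selection: flank extraction, primer design, stringent filters.

A detected SSR becomes a marker candidate only if it survives a chain of
rules modelled on stringent marker-development practice:

* MOTIF_CLASS — only tri- and tetra-nucleotide motifs (dinucleotides stutter
  during PCR and complicate peak calling);
* MIN_REPEATS — more than seven complete tandem units;
* PERFECT_ONLY — no interruptions in the repeat region;
* PRIMER_DESIGN — a primer pair exists in the 300-bp flanks (length 18-24 bp,
  Tm 58-62 degC by nearest-neighbour thermodynamics, pair dTm < 4 degC);
* MIN_3PRIME_DISTANCE — both primer 3' ends more than 10 bp from the repeat;
* SINGLE_TARGET_AMPLICON — the amplicon contains exactly one SSR (the
  target), no secondary tandem repeat of >= 4 units (motif 2-6 bp), and no
  homopolymer >= 8 bp.

Every rule decision is kept in a per-locus audit record so that failures are
independently reproducible from the stored context.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.SeqUtils import MeltingTemp as mt

from .scan import ScanParams, SSRRecord, scan_sequence

__all__ = [
    "LocusContext",
    "PrimerPair",
    "PrimerConstraints",
    "FilterAudit",
    "extract_context",
    "design_primers",
    "stringent_filter",
    "RULES",
]

RULES = (
    "PERFECT_ONLY",
    "MOTIF_CLASS",
    "MIN_REPEATS",
    "PRIMER_DESIGN",
    "MIN_3PRIME_DISTANCE",
    "SINGLE_TARGET_AMPLICON",
)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


class MissingSequenceError(KeyError):
    pass


@dataclass
class LocusContext:
    """An SSR, its repeat sequence, and flanks (target 300 bp each side)."""

    record: SSRRecord
    repeat_seq: str
    upstream_flank: str
    downstream_flank: str
    scaffold_id: str
    upstream_truncated: bool = False
    downstream_truncated: bool = False

    @property
    def full_seq(self) -> str:
        return self.upstream_flank + self.repeat_seq + self.downstream_flank


@dataclass(frozen=True)
class PrimerConstraints:
    min_len: int = 18
    max_len: int = 24
    opt_len: int = 20
    min_tm: float = 58.0
    max_tm: float = 62.0
    opt_tm: float = 60.0
    max_tm_diff: float = 4.0
    min_3prime_distance: int = 10  # bp; distance must strictly exceed this


@dataclass(frozen=True)
class PrimerPair:
    forward_seq: str
    reverse_seq: str
    forward_tm: float
    reverse_tm: float
    product_start: int  # 0-based on the context (upstream + repeat + downstream)
    product_end: int  # half-open
    product_size: int

    def badness(self, c: "PrimerConstraints") -> float:
        """Ranking penalty: |len-20| + |Tm-60| summed over both primers."""
        return (
            abs(len(self.forward_seq) - c.opt_len)
            + abs(len(self.reverse_seq) - c.opt_len)
            + abs(self.forward_tm - c.opt_tm)
            + abs(self.reverse_tm - c.opt_tm)
        )


@dataclass
class FilterAudit:
    locus_id: str
    passed: bool
    failed_rules: list[str]
    best_pair: PrimerPair | None = None

    def __post_init__(self) -> None:
        assert self.passed == (not self.failed_rules)


def extract_context(record: SSRRecord, genome: dict[str, str], flank: int = 300) -> LocusContext:
    """Cut an SSR and its flanks out of the genome.

    Flanks are truncated (never padded) at scaffold boundaries and the
    truncation is recorded on the context.
    """
    if record.sequence_id not in genome:
        raise MissingSequenceError(f"scaffold {record.sequence_id!r} not in genome")
    seq = genome[record.sequence_id].upper()
    s0, e0 = record.start - 1, record.end  # 0-based half-open
    up_start = max(0, s0 - flank)
    down_end = min(len(seq), e0 + flank)
    return LocusContext(
        record=record,
        repeat_seq=seq[s0:e0],
        upstream_flank=seq[up_start:s0],
        downstream_flank=seq[e0:down_end],
        scaffold_id=record.sequence_id,
        upstream_truncated=(s0 - up_start) < flank,
        downstream_truncated=(down_end - e0) < flank,
    )


def primer_tm(seq: str) -> float:
    """Nearest-neighbour melting temperature (degC).

    SantaLucia unified NN parameters with 50 mM monovalent salt and 0.25 uM
    primer concentration; the model is fixed package-wide so Tm windows are
    reproducible.
    """
    return float(mt.Tm_NN(seq, Na=50, dnac1=250, dnac2=0))


def _valid_windows(
    flank: str, constraints: PrimerConstraints
) -> list[tuple[int, int, str, float]]:
    """Windows meeting length/Tm constraints: (start, end, seq, tm), 0-based half-open."""
    out: list[tuple[int, int, str, float]] = []
    n = len(flank)
    for L in range(constraints.min_len, constraints.max_len + 1):
        for i in range(0, n - L + 1):
            win = flank[i : i + L]
            if "N" in win:
                continue
            tm = primer_tm(win)
            if constraints.min_tm <= tm <= constraints.max_tm:
                out.append((i, i + L, win, tm))
    return out


def design_primers(
    context: LocusContext,
    constraints: PrimerConstraints | None = None,
    max_pairs: int = 10,
    max_windows_per_side: int = 25,
) -> list[PrimerPair]:
    """Enumerate primer pairs from the flanks; best first, [] if none.

    Forward primers are windows of the upstream flank read as-is; reverse
    primers are reverse complements of downstream-flank windows. Pairs are
    ranked by |len-20| + |Tm-60| summed over both primers; a hopeless flank
    (no window in the Tm band) yields an empty list, not an error.
    """
    c = constraints or PrimerConstraints()
    fwd = _valid_windows(context.upstream_flank, c)
    rev = _valid_windows(context.downstream_flank, c)
    if not fwd or not rev:
        return []

    def window_badness(w: tuple[int, int, str, float]) -> float:
        return abs(len(w[2]) - c.opt_len) + abs(w[3] - c.opt_tm)

    fwd = sorted(fwd, key=window_badness)[:max_windows_per_side]
    rev = sorted(rev, key=window_badness)[:max_windows_per_side]
    up_len = len(context.upstream_flank)
    rep_len = context.record.length

    pairs: list[PrimerPair] = []
    for _fs, fe, f_seq, f_tm in fwd:
        for rs, _re, r_seq, r_tm in rev:
            if abs(f_tm - r_tm) >= c.max_tm_diff:
                continue
            p_start = fe - len(f_seq)
            p_end = up_len + rep_len + rs + len(r_seq)
            pairs.append(
                PrimerPair(
                    forward_seq=f_seq,
                    reverse_seq=_revcomp(r_seq),
                    forward_tm=f_tm,
                    reverse_tm=r_tm,
                    product_start=p_start,
                    product_end=p_end,
                    product_size=p_end - p_start,
                )
            )
    pairs.sort(key=lambda p: (p.badness(c), p.product_size))
    return pairs[:max_pairs]


def _max_homopolymer(seq: str) -> int:
    best = run = 0
    prev = ""
    for ch in seq:
        run = run + 1 if ch == prev else 1
        prev = ch
        best = max(best, run)
    return best


def _has_secondary_repeat(
    amplicon: str, target_start0: int, target_end0: int, min_units: int = 4
) -> bool:
    """Any tandem repeat of >= min_units complete units (motif 2-6 bp)
    extending outside [target_start0, target_end0] (0-based inclusive)?

    Mononucleotide runs are covered by the separate homopolymer rule.
    """
    n = len(amplicon)
    for k in range(2, 7):
        run = 0
        for p in range(n - k):
            if amplicon[p] != "N" and amplicon[p] == amplicon[p + k]:
                run += 1
                if run + k >= min_units * k:
                    start, end = p - run + 1, p + k  # 0-based inclusive region
                    if not (start >= target_start0 and end <= target_end0):
                        return True
            else:
                run = 0
    return False


def stringent_filter(
    contexts: list[LocusContext],
    constraints: PrimerConstraints | None = None,
    scan_params: ScanParams | None = None,
    motif_classes: tuple[int, ...] = (3, 4),
    min_repeats_exclusive: int = 7,
    secondary_min_units: int = 4,
    max_homopolymer: int = 8,
) -> list[FilterAudit]:
    """Apply the marker-candidate rules to each locus context.

    Rules are evaluated independently (no short-circuit), so the audit lists
    every violated rule. The retained best pair is the top-ranked pair that
    also satisfies the 3'-distance rule.
    """
    c = constraints or PrimerConstraints()
    sp = scan_params or ScanParams()
    audits: list[FilterAudit] = []
    for ctx in contexts:
        rec = ctx.record
        locus_id = f"{ctx.scaffold_id}:{rec.start}-{rec.end}"
        failed: set[str] = set()

        if rec.mismatches != 0:
            failed.add("PERFECT_ONLY")
        if len(rec.motif) not in motif_classes:
            failed.add("MOTIF_CLASS")
        if rec.repeats <= min_repeats_exclusive:  # repeat number must exceed it
            failed.add("MIN_REPEATS")

        pairs = design_primers(ctx, c)
        up_len = len(ctx.upstream_flank)
        rep_len = rec.length
        ok3 = [
            p
            for p in pairs
            if (up_len - (p.product_start + len(p.forward_seq))) > c.min_3prime_distance
            and ((p.product_end - len(p.reverse_seq)) - (up_len + rep_len)) > c.min_3prime_distance
        ]
        best: PrimerPair | None = None
        if not pairs:
            failed.add("PRIMER_DESIGN")
        elif not ok3:
            failed.add("MIN_3PRIME_DISTANCE")
        else:
            best = ok3[0]

        pair_for_amplicon = best if best is not None else (pairs[0] if pairs else None)
        if pair_for_amplicon is not None:
            amplicon = ctx.full_seq[pair_for_amplicon.product_start : pair_for_amplicon.product_end]
            t0 = up_len - pair_for_amplicon.product_start  # 0-based target start in amplicon
            t1 = t0 + rep_len - 1
            amp_records = scan_sequence(amplicon, "amplicon", sp)
            # the scanner may call the target a base or two wider at the
            # junctions; judge "secondary" against the called extent
            called = [r for r in amp_records if r.start - 1 <= t1 and r.end - 1 >= t0]
            if len(called) == 1:
                t0, t1 = called[0].start - 1, called[0].end - 1
            left, right = amplicon[:t0], amplicon[t1 + 1 :]
            if (
                len(amp_records) != 1
                or _has_secondary_repeat(amplicon, t0, t1, min_units=secondary_min_units)
                or max(_max_homopolymer(left), _max_homopolymer(right)) >= max_homopolymer
            ):
                failed.add("SINGLE_TARGET_AMPLICON")

        order = {r: i for i, r in enumerate(RULES)}
        failed_rules = sorted(failed, key=order.__getitem__)
        audits.append(
            FilterAudit(locus_id=locus_id, passed=not failed_rules, failed_rules=failed_rules, best_pair=best)
        )
    return audits
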