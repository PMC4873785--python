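"""Microsatellite (SSR) detection with fixed-penalty mismatch scoring.

A microsatellite is a tandem repeat of a 1-6 bp motif. The scanner finds
maximal perfect seed runs for every motif length, extends each seed in both
directions under a periodic-expectation model that tolerates isolated
mismatches, and reports maximal non-redundant loci whose score

    score = length - mismatch_penalty * mismatches

reaches a minimum threshold (defaults: minimum score 15, penalty 5). Motifs
are reported canonically: all cyclic rotations of a motif and of its reverse
complement belong to one equivalence class, represented by the
lexicographically smallest member.

A direct consequence of the default scoring is that any reported locus
shorter than ``min_score + mismatch_penalty`` bp (20 bp at defaults) is
necessarily perfect: a single mismatch would push its score below threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "ScanParams",
    "SSRRecord",
    "canonical_motif",
    "score_run",
    "scan_sequence",
    "scan_fasta_records",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_VALID_SCAN = set("ACGTN")


class InvalidAlphabetError(ValueError):
    """Raised when a sequence or motif contains characters outside A/C/G/T(/N)."""


@dataclass(frozen=True)
class ScanParams:
    """Tunable parameters of the SSR search.

    min_score: minimum score (bp units) for a locus to be reported.
    mismatch_penalty: score deducted per mismatching position.
    motif_lengths: motif sizes to search, subset of 1..6.
    min_seed_repeats: minimum tandem units in a perfect seed run.
    min_seed_length: minimum seed run length in bp.
    max_interruption_run: longest tolerated run of consecutive mismatching
        bp during extension; longer interruptions split the locus.
    """

    min_score: int = 15
    mismatch_penalty: int = 5
    motif_lengths: frozenset[int] = frozenset(range(1, 7))
    min_seed_repeats: int = 3
    min_seed_length: int = 8
    max_interruption_run: int = 3

    def __post_init__(self) -> None:
        if self.min_score <= 0:
            raise ValueError("min_score must be positive")
        if self.mismatch_penalty <= 0:
            raise ValueError("mismatch_penalty must be positive")
        lens = frozenset(self.motif_lengths)
        if not lens or not lens <= frozenset(range(1, 7)):
            raise ValueError("motif_lengths must be a non-empty subset of 1..6")
        object.__setattr__(self, "motif_lengths", lens)


@dataclass(frozen=True)
class SSRRecord:
    """One detected repeat locus (1-based inclusive coordinates)."""

    sequence_id: str
    start: int
    end: int
    motif: str
    length: int
    mismatches: int
    score: int
    perfect: bool

    @property
    def repeats(self) -> int:
        """Number of complete tandem units spanned by the locus."""
        return self.length // len(self.motif)


def _validate_motif(motif: str) -> str:
    motif = motif.upper()
    if not motif or any(c not in "ACGT" for c in motif):
        raise InvalidAlphabetError(f"motif must be non-empty over ACGT: {motif!r}")
    return motif


def primitive_period(motif: str) -> str:
    """Reduce a motif to its primitive period ('AGAG' -> 'AG')."""
    n = len(motif)
    for d in range(1, n):
        if n % d == 0 and motif == motif[:d] * (n // d):
            return motif[:d]
    return motif


def canonical_motif(motif: str) -> str:
    """Canonical representative of a motif's equivalence class.

    The class of a motif contains all cyclic rotations of the motif and all
    cyclic rotations of its reverse complement; the representative is the
    lexicographically smallest member. The motif is first reduced to its
    primitive period, so the result is idempotent and invariant under
    rotation and reverse complementation of the input.
    """
    m = primitive_period(_validate_motif(motif))
    rc = m.translate(_COMPLEMENT)[::-1]
    doubled, doubled_rc = m + m, rc + rc
    k = len(m)
    return min(
        min(doubled[i : i + k] for i in range(k)),
        min(doubled_rc[i : i + k] for i in range(k)),
    )


def score_run(length: int, mismatches: int, params: ScanParams | None = None) -> int:
    """Score of a repeat run: length minus penalty per mismatch."""
    params = params or ScanParams()
    if length < 1 or mismatches < 0:
        raise ValueError("length must be >= 1 and mismatches >= 0")
    return length - params.mismatch_penalty * mismatches


def _perfect_runs(seq: str, k: int) -> list[tuple[int, int]]:
    """Maximal 0-based [i, j] intervals where seq has exact period k, no N."""
    n = len(seq)
    runs: list[tuple[int, int]] = []
    p = 0
    while p < n - k:
        if seq[p] != "N" and seq[p] == seq[p + k]:
            q = p
            while q < n - k and seq[q + k] != "N" and seq[q] == seq[q + k]:
                q += 1
            runs.append((p, q + k - 1))
            p = q + 1
        else:
            p += 1
    return runs


def _extend(
    seq: str, seed_start: int, seed_end: int, k: int, params: ScanParams
) -> tuple[int, int, int]:
    """Extend a perfect seed in both directions under its periodic phase.

    The expected base at position p is motif[(p - seed_start) mod k] with
    motif anchored at the seed. Extension walks outward accumulating the
    running score (+1 per match, -(penalty-1) per mismatch), stops at N, at
    an interruption longer than max_interruption_run, or when the running
    score falls more than mismatch_penalty below its running maximum, and
    trims back to the maximal-score extent (earliest such point, so the
    record never ends on a mismatch).

    Returns 0-based (start, end, mismatches).
    """
    n = len(seq)
    motif = seq[seed_start : seed_start + k]
    pen = params.mismatch_penalty

    def expected(p: int) -> str:
        return motif[(p - seed_start) % k]

    # rightward
    best_end, score, best_score, mm_run, mm = seed_end, 0, 0, 0, 0
    mm_at_best_r = 0
    p = seed_end + 1
    while p < n:
        c = seq[p]
        if c == "N":
            break
        if c == expected(p):
            score += 1
            mm_run = 0
        else:
            score -= pen - 1
            mm += 1
            mm_run += 1
            if mm_run > params.max_interruption_run:
                break
        if score > best_score:
            best_score, best_end, mm_at_best_r = score, p, mm
        if score < best_score - pen:
            break
        p += 1

    # leftward
    best_start, score, best_score, mm_run, mm = seed_start, 0, 0, 0, 0
    mm_at_best_l = 0
    p = seed_start - 1
    while p >= 0:
        c = seq[p]
        if c == "N":
            break
        if c == expected(p):
            score += 1
            mm_run = 0
        else:
            score -= pen - 1
            mm += 1
            mm_run += 1
            if mm_run > params.max_interruption_run:
                break
        if score > best_score:
            best_score, best_start, mm_at_best_l = score, p, mm
        if score < best_score - pen:
            break
        p -= 1

    return best_start, best_end, mm_at_best_l + mm_at_best_r


def scan_sequence(seq: str, sequence_id: str, params: ScanParams | None = None) -> list[SSRRecord]:
    """Detect SSRs in one sequence.

    Accepts A/C/G/T/N in either case; N terminates extension and is never
    counted as match or mismatch, so no record spans an N. Overlapping calls
    with different motif lengths are resolved by highest score, ties by
    shorter motif, then leftmost start. Output is sorted by start.
    """
    params = params or ScanParams()
    seq = seq.upper()
    bad = set(seq) - _VALID_SCAN
    if bad:
        raise InvalidAlphabetError(f"invalid characters in sequence {sequence_id!r}: {sorted(bad)}")

    candidates: dict[tuple[int, int, int], SSRRecord] = {}
    for k in sorted(params.motif_lengths):
        min_seed = max(params.min_seed_repeats * k, params.min_seed_length)
        for rs, re_ in _perfect_runs(seq, k):
            if re_ - rs + 1 < min_seed:
                continue
            motif = seq[rs : rs + k]
            if len(primitive_period(motif)) != k:
                continue  # covered by the smaller motif length
            s0, e0, mm = _extend(seq, rs, re_, k, params)
            length = e0 - s0 + 1
            score = score_run(length, mm, params)
            if score < params.min_score or length < 2 * k:
                continue
            key = (s0, e0, k)
            if key not in candidates:
                candidates[key] = SSRRecord(
                    sequence_id=sequence_id,
                    start=s0 + 1,
                    end=e0 + 1,
                    motif=canonical_motif(motif),
                    length=length,
                    mismatches=mm,
                    score=score,
                    perfect=(mm == 0),
                )

    # overlap resolution: highest score, then shortest motif, then leftmost
    chosen: list[SSRRecord] = []
    occupied: list[tuple[int, int]] = []
    for rec in sorted(
        candidates.values(), key=lambda r: (-r.score, len(r.motif), r.start, r.motif)
    ):
        if any(not (rec.end < s or rec.start > e) for s, e in occupied):
            continue
        chosen.append(rec)
        occupied.append((rec.start, rec.end))
    return sorted(chosen, key=lambda r: r.start)


def scan_fasta_records(
    sequences: dict[str, str] | list[tuple[str, str]], params: ScanParams | None = None
) -> list[SSRRecord]:
    """Scan several (id, sequence) pairs; output sorted by (sequence_id, start)."""
    items = sequences.items() if isinstance(sequences, dict) else sequences
    out: list[SSRRecord] = []
    for sid, seq in items:
        out.extend(scan_sequence(seq, sid, params))
    return sorted(out, key=lambda r: (r.sequence_id, r.start))
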