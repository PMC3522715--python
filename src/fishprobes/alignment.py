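"""Local alignment of a query against a genome, with bit-score thresholding.

Hits can come from two sources: parsed 12-column tabular output of an
external aligner, or the built-in seed-and-extend aligner.  The built-in
aligner seeds on exact words on both strands and performs ungapped X-drop
extension; it is meant for desk-scale genomes (up to a few hundred kb) where
it doubles as a fully reproducible oracle.  All hit coordinates are 0-based
half-open, with subject intervals always expressed on the forward strand.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, TextIO

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

VALID_BASES = frozenset("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SequenceRecord:
    """A named DNA sequence, optionally carrying its genomic origin.

    ``origin`` is a ``(chrom, start, end)`` triple in 1-based inclusive
    coordinates, as conventionally printed (e.g. ``14:105947801-106327800``).
    """

    id: str
    seq: str
    origin: Optional[tuple[str, int, int]] = None

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"sequence {self.id!r} is empty")
        normalized = self.seq.upper()
        bad = set(normalized) - VALID_BASES
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains non-ACGTN characters: {sorted(bad)}"
            )
        object.__setattr__(self, "seq", normalized)
        if self.origin is not None:
            chrom, start, end = self.origin
            if end - start + 1 != len(normalized):
                raise ValueError(
                    f"origin {chrom}:{start}-{end} spans {end - start + 1} bp "
                    f"but sequence is {len(normalized)} bp"
                )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class ScoringScheme:
    """Ungapped local-alignment scoring with Karlin-Altschul statistics.

    Defaults mirror megablast-style scoring (+1/-2) with the published
    ungapped lambda/K for that matrix; the gap costs are bookkeeping only —
    the built-in aligner is ungapped.
    """

    match_reward: int = 1
    mismatch_penalty: int = -2
    gap_open: int = -5
    gap_extend: int = -2
    lam: float = 1.28
    k: float = 0.46
    word_size: int = 16

    def __post_init__(self) -> None:
        if self.lam <= 0 or self.k <= 0:
            raise ValueError("lambda and K must be positive")
        if not (self.mismatch_penalty < 0 <= self.match_reward):
            raise ValueError("require mismatch_penalty < 0 <= match_reward")
        if self.word_size < 8:
            raise ValueError("word_size must be >= 8")

    def min_raw_score(self, min_bits: float) -> int:
        """Smallest raw score whose bit score reaches ``min_bits``."""
        return math.ceil((min_bits * math.log(2) + math.log(self.k)) / self.lam)


@dataclass(frozen=True)
class AlignmentHit:
    """One thresholded local alignment between query and subject.

    ``raw_score`` is known only for internally generated hits; hits parsed
    from tabular output carry the bit score alone.
    """

    query_id: str
    q_start: int
    q_end: int
    subject_id: str
    s_start: int
    s_end: int
    strand: str
    bit_score: float
    identity: float
    raw_score: Optional[int] = None

    def __post_init__(self) -> None:
        if not (0 <= self.q_start < self.q_end):
            raise ValueError(f"bad query interval [{self.q_start},{self.q_end})")
        if not (0 <= self.s_start < self.s_end):
            raise ValueError(f"bad subject interval [{self.s_start},{self.s_end})")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if not (0.0 <= self.identity <= 1.0):
            raise ValueError(f"identity {self.identity} outside [0,1]")

    @property
    def q_length(self) -> int:
        return self.q_end - self.q_start

    def tabular_key(self) -> tuple:
        """Fields preserved by the 12-column tabular dialect."""
        return (
            self.query_id,
            self.q_start,
            self.q_end,
            self.subject_id,
            self.s_start,
            self.s_end,
            self.strand,
            round(self.bit_score, 1),
            round(self.identity, 4),
        )


def bit_score(raw_score: int, scheme: ScoringScheme) -> float:
    """Normalize a raw alignment score to bits: (lambda*S - ln K) / ln 2."""
    return (scheme.lam * raw_score - math.log(scheme.k)) / math.log(2)


class TabularParseError(ValueError):
    """Raised on a malformed line of 12-column tabular alignment output."""


def parse_tabular_hits(stream: Iterable[str], query_id: str) -> list[AlignmentHit]:
    """Parse BLAST-style 12-column tabular output into hits.

    Expected columns: qseqid sseqid pident length mismatch gapopen qstart
    qend sstart send evalue bitscore, with 1-based inclusive coordinates and
    sstart > send marking a minus-strand hit.  Lines whose qseqid differs
    from ``query_id`` are skipped (counted in the log); ``#`` comments and
    blank lines are ignored.
    """
    hits: list[AlignmentHit] = []
    skipped = 0
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 12:
            raise TabularParseError(
                f"line {lineno}: expected >=12 tab-separated fields, got {len(fields)}"
            )
        qseqid, sseqid = fields[0], fields[1]
        if qseqid != query_id:
            skipped += 1
            continue
        try:
            pident = float(fields[2])
            qstart, qend = int(fields[6]), int(fields[7])
            sstart, send = int(fields[8]), int(fields[9])
            bits = float(fields[11])
        except ValueError as exc:
            raise TabularParseError(f"line {lineno}: non-numeric field ({exc})") from None
        if qstart > qend:
            raise TabularParseError(f"line {lineno}: qstart > qend on query")
        if sstart <= send:
            strand, s0, s1 = "+", sstart - 1, send
        else:
            strand, s0, s1 = "-", send - 1, sstart
        hits.append(
            AlignmentHit(
                query_id=qseqid,
                q_start=qstart - 1,
                q_end=qend,
                subject_id=sseqid,
                s_start=s0,
                s_end=s1,
                strand=strand,
                bit_score=bits,
                identity=pident / 100.0,
            )
        )
    if skipped:
        log.info("parse_tabular_hits: skipped %d lines with foreign qseqid", skipped)
    return hits


def write_tabular_hits(hits: Iterable[AlignmentHit], stream: TextIO) -> None:
    """Serialize hits to the same 12-column tabular dialect (for dumps)."""
    for h in hits:
        length = h.q_end - h.q_start
        mismatch = round(length * (1.0 - h.identity))
        if h.strand == "+":
            sstart, send = h.s_start + 1, h.s_end
        else:
            sstart, send = h.s_end, h.s_start + 1
        stream.write(
            "\t".join(
                [
                    h.query_id,
                    h.subject_id,
                    f"{h.identity * 100.0:.2f}",
                    str(length),
                    str(mismatch),
                    "0",
                    str(h.q_start + 1),
                    str(h.q_end),
                    str(sstart),
                    str(send),
                    "0.0",
                    f"{h.bit_score:.1f}",
                ]
            )
            + "\n"
        )


def filter_hits(hits: list[AlignmentHit], min_bits: float) -> list[AlignmentHit]:
    """Keep hits whose bit score is >= ``min_bits`` (inclusive), order kept."""
    if min_bits < 0:
        raise ValueError("min_bits must be >= 0")
    return [h for h in hits if h.bit_score >= min_bits]


# --- built-in seed-and-extend aligner -------------------------------------


def _build_word_index(seqs: list[SequenceRecord], w: int) -> dict[str, list[tuple[int, int]]]:
    """Exact-word index {word: [(subject_index, position), ...]}; words
    containing N are never indexed."""
    index: dict[str, list[tuple[int, int]]] = {}
    for si, rec in enumerate(seqs):
        s = rec.seq
        for pos in range(len(s) - w + 1):
            word = s[pos : pos + w]
            if "N" in word:
                continue
            index.setdefault(word, []).append((si, pos))
    return index


def _extend_ungapped(
    q: str,
    s: str,
    q_pos: int,
    s_pos: int,
    w: int,
    scheme: ScoringScheme,
    xdrop: int,
) -> tuple[int, int, int, int]:
    """Extend an exact seed in both directions with X-drop termination.

    Returns ``(q_lo, q_hi, raw_score, matches)`` for the best-scoring
    ungapped extension containing the seed; coordinates half-open on q.
    """
    m, mm = scheme.match_reward, scheme.mismatch_penalty
    score = w * m
    matches = w
    # rightward from the seed end
    best, best_i, cur, cur_matches, run_matches = score, 0, score, 0, 0
    i = 0
    qi, si_ = q_pos + w, s_pos + w
    while qi + i < len(q) and si_ + i < len(s):
        if q[qi + i] == s[si_ + i] and q[qi + i] != "N":
            cur += m
            run_matches += 1
        else:
            cur += mm
        i += 1
        if cur > best:
            best, best_i, cur_matches = cur, i, run_matches
        if best - cur > xdrop:
            break
    right_ext, score, matches = best_i, best, matches + cur_matches
    # leftward from the seed start
    best, best_j, cur, cur_matches, run_matches = score, 0, score, 0, 0
    j = 0
    while q_pos - j - 1 >= 0 and s_pos - j - 1 >= 0:
        if q[q_pos - j - 1] == s[s_pos - j - 1] and q[q_pos - j - 1] != "N":
            cur += m
            run_matches += 1
        else:
            cur += mm
        j += 1
        if cur > best:
            best, best_j, cur_matches = cur, j, run_matches
        if best - cur > xdrop:
            break
    left_ext, score, matches = best_j, best, matches + cur_matches
    return q_pos - left_ext, q_pos + w + right_ext, score, matches


def align_seed_extend(
    query: SequenceRecord,
    genome: list[SequenceRecord],
    scheme: ScoringScheme = ScoringScheme(),
    xdrop: int = 20,
) -> list[AlignmentHit]:
    """Align the query to every genome sequence on both strands.

    Exact ``word_size``-mers seed ungapped X-drop extensions; hits sharing
    (subject, strand, diagonal) are de-duplicated by keeping, per diagonal,
    extensions not contained in an earlier one.  Output order is
    deterministic: (subject_id, s_start, strand, q_start).
    """
    w = scheme.word_size
    if len(query) < w:
        raise ValueError(f"query ({len(query)} bp) shorter than word size {w}")
    index = _build_word_index(genome, w)
    hits: list[AlignmentHit] = []
    n_skipped = 0
    for strand in "+-":
        q = query.seq if strand == "+" else revcomp(query.seq)
        # per (subject, diagonal): query intervals already produced, to skip
        # seeds that fall inside an existing extension
        seen: dict[tuple[int, int], list[tuple[int, int]]] = {}
        for qp in range(len(q) - w + 1):
            word = q[qp : qp + w]
            if "N" in word:
                n_skipped += 1
                continue
            for si, sp in index.get(word, ()):
                diag = sp - qp
                covered = seen.get((si, diag))
                if covered and any(lo <= qp and qp + w <= hi for lo, hi in covered):
                    continue
                q_lo, q_hi, raw, matches = _extend_ungapped(
                    q, genome[si].seq, qp, sp, w, scheme, xdrop
                )
                seen.setdefault((si, diag), []).append((q_lo, q_hi))
                s_lo, s_hi = q_lo + diag, q_hi + diag
                if strand == "+":
                    fq_lo, fq_hi = q_lo, q_hi
                else:
                    fq_lo, fq_hi = len(q) - q_hi, len(q) - q_lo
                hits.append(
                    AlignmentHit(
                        query_id=query.id,
                        q_start=fq_lo,
                        q_end=fq_hi,
                        subject_id=genome[si].id,
                        s_start=s_lo,
                        s_end=s_hi,
                        strand=strand,
                        bit_score=bit_score(raw, scheme),
                        identity=matches / (q_hi - q_lo),
                        raw_score=raw,
                    )
                )
    if n_skipped:
        log.debug("align_seed_extend: %d N-containing words not seeded", n_skipped)
    # de-duplicate identical (subject, strand, diagonal, interval) hits and
    # drop hits strictly contained in a same-diagonal longer hit
    uniq: dict[tuple, AlignmentHit] = {}
    for h in hits:
        diag = h.s_start - h.q_start if h.strand == "+" else h.s_start + h.q_end
        key = (h.subject_id, h.strand, diag, h.q_start, h.q_end)
        if key not in uniq:
            uniq[key] = h
    by_diag: dict[tuple, list[AlignmentHit]] = {}
    for (sid, strand, diag, _, _), h in uniq.items():
        by_diag.setdefault((sid, strand, diag), []).append(h)
    out: list[AlignmentHit] = []
    for group in by_diag.values():
        group.sort(key=lambda h: (h.q_start, -(h.q_end)))
        kept: list[AlignmentHit] = []
        for h in group:
            if kept and kept[-1].q_start <= h.q_start and h.q_end <= kept[-1].q_end:
                continue
            kept.append(h)
        out.extend(kept)
    out.sort(key=lambda h: (h.subject_id, h.s_start, h.strand, h.q_start))
    return out
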