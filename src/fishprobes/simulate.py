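"""Synthetic genomes with planted repeat structure, and brute-force oracles.

The generator plants three sequence classes inside and around a focal
locus: unique background, a locally repetitive family whose copies all lie
inside the locus, and a globally similar family with copies both inside and
outside.  This emulates the geometry of a repeat-rich chromosomal locus
(the immunoglobulin heavy-chain constant region being the motivating case)
while keeping per-base truth labels exact: divergence is modeled as random
substitutions only, never indels.

The module also carries the independent oracles the pipeline is validated
against: an exhaustive maximal-scoring-segment masker (Ruzzo-Tompa over
candidate diagonals), a brute-force in-silico hybridization scan, and an
exhaustive maximum-coverage selector for small candidate sets.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from fishprobes.alignment import ScoringScheme, SequenceRecord, revcomp
from fishprobes.classify import Label, SelfLocus, SimilarityMask, count_sites
from fishprobes.targets import ProbeTarget, merge_intervals, union_length

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class Segment:
    """One building block of a synthetic genome."""

    kind: str  # "unique" | "local_repeat" | "global_repeat"
    length: int
    family: int = 0
    divergence: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("unique", "local_repeat", "global_repeat"):
            raise ValueError(f"bad segment kind {self.kind!r}")
        if self.length <= 0:
            raise ValueError("segment length must be positive")
        if not 0.0 <= self.divergence <= 0.1:
            raise ValueError("divergence must lie in [0, 0.1]")


@dataclass(frozen=True)
class GenomeSpec:
    """Recipe for a synthetic genome with a focal query locus.

    ``locus`` is the inclusive span of segment indices forming the locus;
    the query is exactly the locus substring of the genome.
    """

    segments: tuple[Segment, ...]
    locus: tuple[int, int]
    gc: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.locus
        if not 0 <= lo <= hi < len(self.segments):
            raise ValueError("locus segment span out of range")
        total = sum(s.length for s in self.segments)
        if total > 200_000:
            raise ValueError(f"total genome {total} bp exceeds the 200 kb desk scale")
        for fam, kind, inside in self._family_placement():
            if kind == "local_repeat" and not all(inside):
                raise ValueError(f"local repeat family {fam} has a copy outside the locus")
            if kind == "global_repeat" and (not any(inside) or all(inside)):
                raise ValueError(
                    f"global repeat family {fam} needs copies both inside and outside"
                )

    def _family_placement(self):
        lo, hi = self.locus
        fams: dict[tuple[str, int], list[bool]] = {}
        for i, seg in enumerate(self.segments):
            if seg.kind == "unique":
                continue
            fams.setdefault((seg.kind, seg.family), []).append(lo <= i <= hi)
        return [(fam, kind, inside) for (kind, fam), inside in fams.items()]


@dataclass
class TruthAnnotation:
    """Per-base expected labels over the locus plus family membership."""

    labels: np.ndarray
    families: dict[int, list[tuple[int, int]]]
    collar: int = 16


@dataclass
class SimulatedLocus:
    genome: SequenceRecord
    query: SequenceRecord
    truth: TruthAnnotation
    locus_interval: tuple[int, int]  # genome coordinates of the locus

    @property
    def self_locus(self) -> SelfLocus:
        return SelfLocus(
            subject_id=self.genome.id,
            start=self.locus_interval[0],
            end=self.locus_interval[1],
            source="declared",
        )


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=length, p=p)


def _mutate(rng: np.random.Generator, codes: np.ndarray, divergence: float) -> np.ndarray:
    if divergence <= 0:
        return codes.copy()
    out = codes.copy()
    hit = rng.random(len(codes)) < divergence
    shifts = rng.integers(1, 4, size=int(hit.sum()))
    out[hit] = (out[hit] + shifts) % 4
    return out


def generate_genome(spec: GenomeSpec, collar: int = 16) -> SimulatedLocus:
    """Materialize a GenomeSpec deterministically.

    Every repeat family derives its copies from one master sequence, each
    copy independently substituted at the segment's divergence rate.  Truth
    labels follow the class definitions by construction: local_repeat bases
    are SIMILAR_LOCAL, global_repeat bases SIMILAR_GLOBAL, the rest UNIQUE.
    """
    rng = np.random.default_rng(spec.seed)
    masters: dict[tuple[str, int], np.ndarray] = {}
    max_len: dict[tuple[str, int], int] = {}
    for seg in spec.segments:
        if seg.kind != "unique":
            key = (seg.kind, seg.family)
            max_len[key] = max(max_len.get(key, 0), seg.length)
    for key in sorted(max_len):
        masters[key] = _random_seq(rng, max_len[key], spec.gc)
    pieces: list[np.ndarray] = []
    bounds: list[tuple[int, int]] = []
    pos = 0
    for seg in spec.segments:
        if seg.kind == "unique":
            piece = _random_seq(rng, seg.length, spec.gc)
        else:
            piece = _mutate(rng, masters[(seg.kind, seg.family)][: seg.length], seg.divergence)
        pieces.append(piece)
        bounds.append((pos, pos + seg.length))
        pos += seg.length
    genome_codes = np.concatenate(pieces)
    genome_seq = "".join(_BASES[genome_codes])
    lo, hi = spec.locus
    locus_start = bounds[lo][0]
    locus_end = bounds[hi][1]
    query_seq = genome_seq[locus_start:locus_end]
    labels = np.zeros(locus_end - locus_start, dtype=np.int8)
    families: dict[int, list[tuple[int, int]]] = {}
    for i, seg in enumerate(spec.segments):
        if not (lo <= i <= hi) or seg.kind == "unique":
            continue
        s, e = bounds[i][0] - locus_start, bounds[i][1] - locus_start
        if seg.kind == "local_repeat":
            labels[s:e] = int(Label.SIMILAR_LOCAL)
            families.setdefault(seg.family, []).append((s, e))
        else:
            labels[s:e] = int(Label.SIMILAR_GLOBAL)
    return SimulatedLocus(
        genome=SequenceRecord(id="chr1", seq=genome_seq),
        query=SequenceRecord(id="query", seq=query_seq),
        truth=TruthAnnotation(labels=labels, families=families, collar=collar),
        locus_interval=(locus_start, locus_end),
    )


def default_fixture_spec(seed: int = 0) -> GenomeSpec:
    """The default "ig-like" fixture: three long unique stretches flanking a
    three-copy local repeat family (1.5 kb copies, 2% divergence) and one
    global family (1 kb) with one copy inside and two outside the locus
    (~50 kb genome)."""
    u = lambda n: Segment("unique", n)
    loc = lambda: Segment("local_repeat", 1500, family=0, divergence=0.02)
    glo = lambda: Segment("global_repeat", 1000, family=0, divergence=0.02)
    segments = (
        u(8000), glo(), u(4000),
        u(5000), loc(), u(6000), loc(), glo(), loc(), u(8000),
        u(4000), glo(), u(8000),
    )
    return GenomeSpec(segments=segments, locus=(3, 9), seed=seed)


def random_spec(rng: np.random.Generator) -> GenomeSpec:
    """A randomized desk-scale spec exercising all three base classes.

    Repeat copies are kept well separated by unique stretches so planted
    structure stays resolvable by both the pipeline and the oracles.
    """
    local_len = int(rng.integers(800, 1600))
    global_len = int(rng.integers(600, 1200))
    div = float(rng.choice([0.0, 0.01, 0.02]))
    n_local = int(rng.integers(2, 4))
    u = lambda a, b: Segment("unique", int(rng.integers(a, b)))
    inner: list[Segment] = [u(2500, 5000)]
    for _ in range(n_local):
        inner.append(Segment("local_repeat", local_len, family=0, divergence=div))
        inner.append(u(2500, 5000))
    inner.insert(3, Segment("global_repeat", global_len, family=0, divergence=div))
    segments = (
        u(2500, 4000), Segment("global_repeat", global_len, family=0, divergence=div),
        u(2500, 4000),
        *inner,
        u(2500, 4000),
    )
    locus = (3, 3 + len(inner) - 1)
    return GenomeSpec(segments=segments, locus=locus, seed=int(rng.integers(0, 2**31 - 1)))


# --- oracle: exhaustive masking ------------------------------------------


def _ruzzo_tompa(scores: Sequence[int]) -> list[tuple[int, int, int]]:
    """All maximal scoring subsequences of an integer score sequence.

    Returns (start, end, score) triples, half-open, disjoint.
    """
    stack: list[list[int]] = []  # [start, end, Lcum, Rcum]
    cum = 0
    for i, x in enumerate(scores):
        left = cum
        cum += x
        if x <= 0:
            continue
        cur = [i, i + 1, left, cum]
        while True:
            j = None
            for idx in range(len(stack) - 1, -1, -1):
                if stack[idx][2] < cur[2]:
                    j = idx
                    break
            if j is None or stack[j][3] >= cur[3]:
                stack.append(cur)
                break
            cur = [stack[j][0], cur[1], stack[j][2], cur[3]]
            del stack[j:]
    return [(s, e, r - l) for s, e, l, r in stack]


def _candidate_diagonals(t: str, s: str, w: int) -> set[int]:
    """Diagonals (s_pos - t_pos) sharing at least one exact w-mer."""
    words: dict[str, list[int]] = {}
    for i in range(len(s) - w + 1):
        word = s[i : i + w]
        if "N" not in word:
            words.setdefault(word, []).append(i)
    diags: set[int] = set()
    for i in range(len(t) - w + 1):
        for j in words.get(t[i : i + w], ()):
            diags.add(j - i)
    return diags


def brute_force_mask(
    query: SequenceRecord,
    genome: Sequence[SequenceRecord],
    scheme: ScoringScheme,
    min_bits: float,
    self_locus: Optional[SelfLocus] = None,
) -> SimilarityMask:
    """Independent per-position multiplicity oracle for classification.

    Enumerates, on every seed-bearing diagonal of both strands, all maximal
    scoring segments (Ruzzo-Tompa) passing the bit threshold, then labels
    each query base by the number of distinct (merged) genomic sites those
    segments map it to, using the same UNIQUE / SIMILAR_LOCAL /
    SIMILAR_GLOBAL rules as the pipeline.
    """
    raw_min = scheme.min_raw_score(min_bits)
    qlen = len(query)
    # run: (q0, q1, subject, s0, s1, strand)
    runs: list[tuple[int, int, str, int, int, str]] = []
    for rec in genome:
        for strand in "+-":
            t = query.seq if strand == "+" else revcomp(query.seq)
            for d in sorted(_candidate_diagonals(t, rec.seq, scheme.word_size)):
                t0 = max(0, -d)
                t1 = min(len(t), len(rec.seq) - d)
                if t1 - t0 < scheme.word_size:
                    continue
                tA = np.frombuffer(t[t0:t1].encode(), dtype=np.uint8)
                sA = np.frombuffer(rec.seq[t0 + d : t1 + d].encode(), dtype=np.uint8)
                match = (tA == sA) & (tA != ord("N"))
                scores = np.where(match, scheme.match_reward, scheme.mismatch_penalty)
                for a, b, sc in _ruzzo_tompa(scores.tolist()):
                    if sc < raw_min:
                        continue
                    ta, tb = t0 + a, t0 + b
                    if strand == "+":
                        q0, q1 = ta, tb
                    else:
                        q0, q1 = len(t) - tb, len(t) - ta
                    runs.append((q0, q1, rec.id, ta + d, tb + d, strand))
    if self_locus is None:
        self_run = max(
            (r for r in runs if r[1] - r[0] >= 0.95 * qlen), default=None,
            key=lambda r: r[1] - r[0],
        )
        if self_run is None:
            raise ValueError("oracle could not locate the self run")
        self_locus = SelfLocus(self_run[2], self_run[3], self_run[4], "detected")
    labels = np.zeros(qlen, dtype=np.int8)
    tol = scheme.word_size
    for p in range(qlen):
        points: list[tuple[str, int]] = []
        for q0, q1, sid, s0, s1, strand in runs:
            if not (q0 <= p < q1):
                continue
            pt = s0 + (p - q0) if strand == "+" else s1 - 1 - (p - q0)
            points.append((sid, pt))
        if len(points) <= 1:
            continue
        count, all_local = count_sites(points, self_locus, tol)
        if count <= 1:
            continue
        labels[p] = int(Label.SIMILAR_LOCAL if all_local else Label.SIMILAR_GLOBAL)
    return SimilarityMask(query_id=query.id, labels=labels, min_bits=min_bits)


def collar_positions(labels_a: np.ndarray, labels_b: np.ndarray, collar: int) -> np.ndarray:
    """Boolean array marking positions within ``collar`` bases of a label
    transition in either array (excluded from oracle comparisons)."""
    n = len(labels_a)
    excl = np.zeros(n, dtype=bool)
    for arr in (labels_a, labels_b):
        trans = np.flatnonzero(np.diff(arr)) + 1
        for t in trans:
            excl[max(0, t - collar) : min(n, t + collar)] = True
    return excl


def mask_agreement(a: SimilarityMask, b: SimilarityMask, collar: int) -> float:
    """Fraction of positions outside boundary collars where two masks agree."""
    excl = collar_positions(a.labels, b.labels, collar)
    keep = ~excl
    if not keep.any():
        return 1.0
    return float(np.mean(a.labels[keep] == b.labels[keep]))


# --- oracle: in-silico hybridization --------------------------------------


def in_silico_hybridize(
    probe_seq: str,
    genome: Sequence[SequenceRecord],
    min_match_len: int = 100,
    min_identity: float = 0.85,
    seed_len: int = 12,
) -> list[tuple[str, int, int]]:
    """Predicted genomic binding loci of a probe, by brute-force scan.

    Both strands are scanned for ungapped windows of at least
    ``min_match_len`` bases at ``min_identity`` or better (the scale of the
    100-300 nt fragments a labeled probe is physically broken into);
    overlapping windows merge into loci.  Deterministic.
    """
    if len(probe_seq) < min_match_len:
        raise ValueError("probe shorter than min_match_len")
    need = math.ceil(min_identity * min_match_len)
    loci: dict[str, list[tuple[int, int]]] = {}
    for rec in genome:
        covered: list[tuple[int, int]] = []
        for strand in "+-":
            p = probe_seq.upper() if strand == "+" else revcomp(probe_seq.upper())
            for d in sorted(_candidate_diagonals(p, rec.seq, seed_len)):
                p0 = max(0, -d)
                p1 = min(len(p), len(rec.seq) - d)
                if p1 - p0 < min_match_len:
                    continue
                pA = np.frombuffer(p[p0:p1].encode(), dtype=np.uint8)
                sA = np.frombuffer(rec.seq[p0 + d : p1 + d].encode(), dtype=np.uint8)
                match = (pA == sA).astype(np.int32)
                win = np.convolve(match, np.ones(min_match_len, dtype=np.int32), "valid")
                good = np.flatnonzero(win >= need)
                for g in good:
                    covered.append((p0 + d + int(g), p0 + d + int(g) + min_match_len))
        if covered:
            loci[rec.id] = merge_intervals(covered)
    return sorted(
        (rid, s, e) for rid, ivs in loci.items() for s, e in ivs
    )


# --- oracle: exhaustive selection -----------------------------------------


def brute_force_select(candidates: Sequence[ProbeTarget]) -> list[ProbeTarget]:
    """Exhaustively optimal non-overlapping subset maximizing cumulative
    binding; refuses more than 15 candidates.  Ties break to the
    lexicographically smallest sorted interval list."""
    if len(candidates) > 15:
        raise ValueError("brute_force_select refuses > 15 candidates")
    best_val = -1
    best_sel: list[ProbeTarget] = []
    idx = list(range(len(candidates)))
    for r in range(len(idx) + 1):
        for combo in itertools.combinations(idx, r):
            sel = [candidates[i] for i in combo]
            ok = all(
                a.end <= b.start
                for a, b in itertools.combinations(sorted(sel, key=lambda t: t.start), 2)
                if a.start <= b.start
            )
            if not ok:
                continue
            val = union_length([iv for t in sel for iv in t.binding_sites])
            key = sorted(t.interval for t in sel)
            if val > best_val or (val == best_val and key < sorted(t.interval for t in best_sel)):
                best_val = val
                best_sel = sel
    return sorted(best_sel, key=lambda t: t.start)
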