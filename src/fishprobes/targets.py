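"""Probe target design: tiling, repeat-target selection, restriction screen.

Unique blocks become a tiling array of consecutive single-copy amplicons.
Similar blocks are scanned for candidate repetitive amplicons pure in
locally repetitive sequence, and a greedy maximum-coverage selection picks
the subset maximizing the cumulative length of predicted binding sites.
Every emitted amplicon is screened for forbidden restriction sites (ClaI
ATCGAT by default) so the products can later be cloned and screened by
restriction digest.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from fishprobes.alignment import AlignmentHit, revcomp
from fishprobes.classify import Label, Region, SelfLocus, SimilarityMask

log = logging.getLogger(__name__)

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass
class DesignConfig:
    """Every tunable knob of the design pipeline, flat for key=value files.

    The defaults are the working configuration: a 200-bit similarity
    threshold, unique blocks must exceed 4 kb, similar runs may be bridged
    across gaps up to 500 bp, amplicons span 1-10 kb, and amplicons must be
    free of the ClaI site ATCGAT which is also the 5' primer linker.
    """

    # similarity search
    min_bits: float = 200.0
    word_size: int = 16
    match_reward: int = 1
    mismatch_penalty: int = -2
    karlin_lambda: float = 1.28
    karlin_k: float = 0.46
    xdrop: int = 20
    # classification / blocks
    min_unique_len: int = 4000
    max_gap: int = 500
    # amplicons
    amplicon_min: int = 1000
    amplicon_max: int = 10000
    min_gain: int = 500
    forbidden_sites: tuple[str, ...] = ("ATCGAT",)
    site_mode: str = "enforce"  # "verify" | "enforce"
    # primers
    linker: str = "atcgat"
    primer_len_min: int = 18
    primer_len_opt: int = 20
    primer_len_max: int = 27
    primer_tm_min: float = 57.0
    primer_tm_opt: float = 60.0
    primer_tm_max: float = 63.0
    primer_max_tm_diff: float = 3.0
    primer_gc_min: float = 0.2
    primer_gc_max: float = 0.8
    primer_max_run: int = 4
    primer_max_self_any: int = 8
    primer_max_pair_any: int = 8
    primer_search_margin: int = 200
    primer_monovalent_mm: float = 50.0
    primer_dna_nm: float = 50.0
    # graphical output
    plot_width: float = 12.0
    plot_height: float = 2.5
    plot_dpi: int = 100

    def __post_init__(self) -> None:
        if not 0 < self.amplicon_min <= self.amplicon_max:
            raise ValueError("require 0 < amplicon_min <= amplicon_max")
        if self.min_gain < 0:
            raise ValueError("min_gain must be >= 0")
        if self.site_mode not in ("verify", "enforce"):
            raise ValueError(f"site_mode must be verify|enforce, not {self.site_mode!r}")
        for site in self.forbidden_sites:
            if not site or any(c not in IUPAC for c in site.upper()):
                raise ValueError(f"forbidden site {site!r} is not a valid IUPAC string")
        self.forbidden_sites = tuple(s.upper() for s in self.forbidden_sites)

    def scheme(self):
        from fishprobes.alignment import ScoringScheme

        return ScoringScheme(
            match_reward=self.match_reward,
            mismatch_penalty=self.mismatch_penalty,
            lam=self.karlin_lambda,
            k=self.karlin_k,
            word_size=self.word_size,
        )

    def primer_constraints(self):
        from fishprobes.primers import PrimerConstraints

        return PrimerConstraints(
            len_min=self.primer_len_min,
            len_opt=self.primer_len_opt,
            len_max=self.primer_len_max,
            tm_min=self.primer_tm_min,
            tm_opt=self.primer_tm_opt,
            tm_max=self.primer_tm_max,
            max_tm_diff=self.primer_max_tm_diff,
            gc_min=self.primer_gc_min,
            gc_max=self.primer_gc_max,
            max_run=self.primer_max_run,
            max_self_any=self.primer_max_self_any,
            max_pair_any=self.primer_max_pair_any,
            monovalent_mm=self.primer_monovalent_mm,
            dna_nm=self.primer_dna_nm,
        )


def merge_intervals(intervals: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping or touching half-open intervals."""
    out: list[list[int]] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def union_length(intervals: Sequence[tuple[int, int]]) -> int:
    return sum(e - s for s, e in merge_intervals(intervals))


@dataclass
class ProbeTarget:
    """A candidate or final amplicon with its predicted binding sites.

    ``binding_sites`` are query intervals the probe is expected to
    hybridize: just the amplicon itself for single-copy probes, plus every
    same-family local repeat copy for repetitive probes.
    """

    kind: str  # "single_copy" | "repetitive"
    start: int
    end: int
    binding_sites: list[tuple[int, int]] = field(default_factory=list)
    label: str = ""
    site_hits: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kind not in ("single_copy", "repetitive"):
            raise ValueError(f"bad target kind {self.kind!r}")
        if not self.start < self.end:
            raise ValueError(f"empty probe interval [{self.start},{self.end})")
        if not self.binding_sites:
            self.binding_sites = [(self.start, self.end)]

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def cumulative_binding(self) -> int:
        return union_length(self.binding_sites)


@dataclass(frozen=True)
class RepeatFamily:
    """Query intervals mutually connected by within-locus alignments."""

    family_id: int
    members: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("a repeat family needs >= 2 members")


def cumulative_binding(target: ProbeTarget) -> int:
    """Length of the union of a target's predicted binding sites (bp)."""
    return target.cumulative_binding


# --- repeat families ------------------------------------------------------


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def build_repeat_families(
    hits: Sequence[AlignmentHit],
    self_locus: SelfLocus,
    mask: SimilarityMask,
) -> list[RepeatFamily]:
    """Group locally repetitive intervals into families.

    Non-self hits mapping entirely inside the self locus contribute two
    query intervals each (the aligned query span and the subject span
    translated into query coordinates).  Intervals linked by a hit or by
    mutual overlap are merged transitively into one family; member
    intervals are trimmed to SIMILAR_LOCAL-labeled bases.
    """
    ls = self_locus.start
    pairs: list[tuple[tuple[int, int], tuple[int, int]]] = []
    qlen = len(mask.labels)
    for h in hits:
        if not self_locus.contains(h.subject_id, h.s_start, h.s_end):
            continue
        a = (h.q_start, h.q_end)
        b = (max(0, h.s_start - ls), min(qlen, h.s_end - ls))
        if h.strand == "+" and a == b:
            continue  # the self alignment (or a fragment on its diagonal)
        if b[0] >= b[1]:
            continue
        pairs.append((a, b))
    if not pairs:
        return []
    nodes: list[tuple[int, int]] = []
    node_id: dict[tuple[int, int], int] = {}
    for a, b in pairs:
        for iv in (a, b):
            if iv not in node_id:
                node_id[iv] = len(nodes)
                nodes.append(iv)
    uf = _UnionFind(len(nodes))
    for a, b in pairs:
        uf.union(node_id[a], node_id[b])
    order = sorted(range(len(nodes)), key=lambda i: nodes[i])
    for i, j in zip(order[:-1], order[1:]):
        if nodes[j][0] < nodes[i][1]:  # overlapping intervals share a family
            uf.union(i, j)
    comps: dict[int, list[tuple[int, int]]] = {}
    for i, iv in enumerate(nodes):
        comps.setdefault(uf.find(i), []).append(iv)
    local_runs = [
        (r.start, r.end)
        for r in _label_runs(mask.labels, int(Label.SIMILAR_LOCAL))
    ]
    families: list[RepeatFamily] = []
    for comp in comps.values():
        merged = merge_intervals(comp)
        trimmed: list[tuple[int, int]] = []
        for s, e in merged:
            for rs, re_ in local_runs:
                lo, hi = max(s, rs), min(e, re_)
                if lo < hi:
                    trimmed.append((lo, hi))
        trimmed = merge_intervals(trimmed)
        if len(trimmed) >= 2:
            families.append(RepeatFamily(family_id=0, members=tuple(trimmed)))
    families.sort(key=lambda f: f.members[0])
    return [replace(f, family_id=i) for i, f in enumerate(families)]


def _label_runs(labels: np.ndarray, value: int) -> list[Region]:
    arr = labels == value
    runs: list[Region] = []
    start = None
    for i, v in enumerate(arr):
        if v and start is None:
            start = i
        elif not v and start is not None:
            runs.append(Region(label=str(value), start=start, end=i))
            start = None
    if start is not None:
        runs.append(Region(label=str(value), start=start, end=len(arr)))
    return runs


# --- tiling of unique blocks ----------------------------------------------


def _partition_block(length: int, amin: int, amax: int) -> Optional[list[int]]:
    """Piece lengths (each in [amin, amax]) maximizing covered bases of a
    block, longest pieces first; None if the block is shorter than amin."""
    if length < amin:
        return None
    n = math.ceil(length / amax)
    if n * amin <= length:
        pieces = []
        rem = length
        for i in range(n):
            p = min(amax, rem - amin * (n - i - 1))
            pieces.append(p)
            rem -= p
        return pieces
    if n - 1 >= 1:
        return [amax] * (n - 1)  # remainder < amin stays uncovered
    return None


def tile_single_copy(blocks: Sequence[Region], cfg: DesignConfig) -> list[ProbeTarget]:
    """Partition each unique block into a left-to-right tiling array of
    single-copy amplicons; a right-edge remainder shorter than amplicon_min
    stays uncovered, and blocks below amplicon_min are skipped."""
    targets: list[ProbeTarget] = []
    for block in blocks:
        pieces = _partition_block(block.length, cfg.amplicon_min, cfg.amplicon_max)
        if pieces is None:
            log.info(
                "tile_single_copy: block [%d,%d) shorter than amplicon_min=%d, skipped",
                block.start, block.end, cfg.amplicon_min,
            )
            continue
        pos = block.start
        for p in pieces:
            targets.append(ProbeTarget(kind="single_copy", start=pos, end=pos + p))
            pos += p
    return targets


# --- repetitive targets ---------------------------------------------------


def candidate_repeat_windows(
    block: Region,
    families: Sequence[RepeatFamily],
    cfg: DesignConfig,
    mask: SimilarityMask,
) -> list[ProbeTarget]:
    """Enumerate candidate repetitive amplicons inside a similar block.

    Windows of lengths amplicon_min..amplicon_max (position and length step
    amplicon_min/2) qualify when >= 90% of their bases are SIMILAR_LOCAL and
    none is SIMILAR_GLOBAL.  A window inherits the binding sites of every
    family it overlaps by >= amplicon_min/2 bp.
    """
    step = max(1, cfg.amplicon_min // 2)
    local = np.cumsum(np.concatenate([[0], mask.labels == int(Label.SIMILAR_LOCAL)]))
    glob = np.cumsum(np.concatenate([[0], mask.labels == int(Label.SIMILAR_GLOBAL)]))
    out: list[ProbeTarget] = []
    seen: set[tuple[int, int]] = set()
    lengths = list(range(cfg.amplicon_min, min(cfg.amplicon_max, block.length) + 1, step))
    if block.length < cfg.amplicon_max and block.length >= cfg.amplicon_min:
        if block.length not in lengths:
            lengths.append(block.length)  # allow the full block as one window
    for length in lengths:
        for s in range(block.start, block.end - length + 1, step):
            e = s + length
            if (s, e) in seen:
                continue
            if glob[e] - glob[s] > 0:
                continue
            if (local[e] - local[s]) < 0.9 * length:
                continue
            seen.add((s, e))
            sites: list[tuple[int, int]] = [(s, e)]
            for fam in families:
                ov = sum(
                    max(0, min(e, me) - max(s, ms)) for ms, me in fam.members
                )
                if ov >= cfg.amplicon_min / 2:
                    sites.extend(fam.members)
            out.append(
                ProbeTarget(kind="repetitive", start=s, end=e,
                            binding_sites=merge_intervals(sites))
            )
    out.sort(key=lambda t: (t.start, t.end))
    return out


def select_repeat_targets(
    candidates: Sequence[ProbeTarget], cfg: DesignConfig
) -> list[ProbeTarget]:
    """Greedy maximum-coverage selection of repetitive targets.

    Repeatedly picks the candidate adding the most new bases to the union
    of binding sites, never letting probe intervals overlap, and stops when
    the best marginal gain drops below min_gain.  Ties break to the smaller
    start, then the shorter window — fully deterministic.
    """
    selected: list[ProbeTarget] = []
    covered: list[tuple[int, int]] = []
    remaining = list(candidates)
    while remaining:
        best = None
        best_gain = -1
        for c in remaining:
            gain = union_length(covered + c.binding_sites) - union_length(covered)
            key = (-gain, c.start, c.length)
            if best is None or key < (-best_gain, best.start, best.length):
                best, best_gain = c, gain
        if best is None or best_gain < cfg.min_gain:
            break
        selected.append(best)
        covered = merge_intervals(covered + best.binding_sites)
        remaining = [
            c
            for c in remaining
            if c is not best and (c.end <= best.start or c.start >= best.end)
        ]
    selected.sort(key=lambda t: t.start)
    return selected


# --- restriction screening ------------------------------------------------


def _iupac_regex(site: str) -> re.Pattern:
    return re.compile("(?=" + "".join(f"[{IUPAC[c]}]" for c in site.upper()) + ")")


def scan_restriction_sites(seq: str, sites: Sequence[str]) -> list[int]:
    """0-based start positions of every occurrence of each site or its
    reverse complement (palindromes like ATCGAT are reported once)."""
    seq = seq.upper()
    found: set[int] = set()
    for site in sites:
        for pat in {site.upper(), revcomp(site.upper())}:
            found.update(m.start() for m in _iupac_regex(pat).finditer(seq))
    return sorted(found)


def _window_pure(mask: SimilarityMask, s: int, e: int) -> bool:
    win = mask.labels[s:e]
    if np.any(win == int(Label.SIMILAR_GLOBAL)):
        return False
    return np.sum(win == int(Label.SIMILAR_LOCAL)) >= 0.9 * (e - s)


def _repeat_binding_sites(
    interval: tuple[int, int], families: Sequence[RepeatFamily], amin: int
) -> list[tuple[int, int]]:
    s, e = interval
    sites: list[tuple[int, int]] = [interval]
    for fam in families:
        ov = sum(max(0, min(e, me) - max(s, ms)) for ms, me in fam.members)
        if ov >= amin / 2:
            sites.extend(fam.members)
    return merge_intervals(sites)


def enforce_restriction_free(
    targets: Sequence[ProbeTarget],
    template: str,
    cfg: DesignConfig,
    blocks: Optional[Sequence[Region]] = None,
    mask: Optional[SimilarityMask] = None,
    families: Optional[Sequence[RepeatFamily]] = None,
) -> tuple[list[ProbeTarget], list[str]]:
    """Remove forbidden restriction sites from every amplicon.

    In ``verify`` mode targets pass through annotated with site positions.
    In ``enforce`` mode an amplicon containing a site is shifted within its
    block (kept inside length bounds and clear of neighboring amplicons);
    if no single placement fits, it is split at the site midpoints into
    parts of at least amplicon_min; if that fails too it is dropped.
    Returns (kept targets, log of dropped/changed items).
    """
    notes: list[str] = []
    ordered = sorted(targets, key=lambda t: t.start)
    if cfg.site_mode == "verify":
        out = []
        for t in ordered:
            hits = [p + t.start for p in
                    scan_restriction_sites(template[t.start:t.end], cfg.forbidden_sites)]
            out.append(replace(t, site_hits=hits))
        return out, notes

    site_w = {s: len(s) for s in cfg.forbidden_sites}
    kept: list[ProbeTarget] = []
    for idx, t in enumerate(ordered):
        inside = [
            p + t.start
            for p in scan_restriction_sites(template[t.start:t.end], cfg.forbidden_sites)
            if p + t.start + min(site_w.values()) <= t.end
        ]
        # occurrences fully inside the amplicon only
        occs = _full_occurrences(template, cfg.forbidden_sites, t.start, t.end)
        if not occs:
            kept.append(t)
            continue
        block = _containing_block(blocks, t) if blocks else Region("", t.start, t.end)
        lo = max(block.start, kept[-1].end if kept else block.start)
        hi = block.end
        if idx + 1 < len(ordered):
            hi = min(hi, ordered[idx + 1].start) if ordered[idx + 1].start >= t.end else hi
        placements = _site_free_placements(template, cfg, t, lo, hi, mask, families)
        if not placements:
            notes.append(
                f"dropped {t.kind} target [{t.start},{t.end}): forbidden site(s) at "
                f"{occs} and no feasible site-free placement"
            )
            continue
        if len(placements) > 1:
            notes.append(
                f"split {t.kind} target [{t.start},{t.end}) at forbidden site(s) into "
                f"{len(placements)} parts"
            )
        elif placements[0] != t.interval:
            notes.append(
                f"shifted {t.kind} target [{t.start},{t.end}) to "
                f"[{placements[0][0]},{placements[0][1]}) to exclude forbidden site"
            )
        for s, e in placements:
            if t.kind == "repetitive" and families is not None:
                sites = _repeat_binding_sites((s, e), families, cfg.amplicon_min)
            else:
                sites = [(s, e)]
            kept.append(replace(t, start=s, end=e, binding_sites=sites, site_hits=[]))
    return kept, notes


def _full_occurrences(
    template: str, sites: Sequence[str], start: int, end: int
) -> list[tuple[int, int]]:
    """Occurrence intervals (abs coords) lying fully inside [start, end)."""
    occs = []
    for site in sites:
        w = len(site)
        for p in scan_restriction_sites(template[start:end], [site]):
            if start + p + w <= end:
                occs.append((start + p, start + p + w))
    return sorted(set(occs))


def _containing_block(blocks: Sequence[Region], t: ProbeTarget) -> Region:
    for b in blocks:
        if b.start <= t.start and t.end <= b.end:
            return b
    return Region("", t.start, t.end)


def _best_in_segment(
    seg: tuple[int, int],
    want: tuple[int, int],
    length: int,
    cfg: DesignConfig,
    mask: Optional[SimilarityMask],
    families: Optional[Sequence[RepeatFamily]],
    kind: str,
) -> Optional[tuple[int, int]]:
    """Best placement of an amplicon of ``length`` inside segment ``seg``,
    maximizing overlap with ``want``; repetitive placements must stay pure."""
    s0, s1 = seg
    if s1 - s0 < length:
        return None
    lo, hi = s0, s1 - length
    pref = min(max(want[0], lo), hi)
    order = sorted(range(lo, hi + 1), key=lambda s: (abs(s - pref), s))
    for s in order:
        if kind == "repetitive" and mask is not None and not _window_pure(mask, s, s + length):
            continue
        return (s, s + length)
    return None


def _site_free_placements(
    template: str,
    cfg: DesignConfig,
    t: ProbeTarget,
    lo: int,
    hi: int,
    mask: Optional[SimilarityMask],
    families: Optional[Sequence[RepeatFamily]],
) -> list[tuple[int, int]]:
    """Placements replacing target ``t`` within free span [lo, hi).

    The span is cut at the midpoint of every full site occurrence; each cut
    segment contains no full occurrence.  If one segment admits the
    original length, the target is shifted there; otherwise one part per
    qualifying segment is emitted (split), largest legal length each.
    """
    occs = _full_occurrences(template, cfg.forbidden_sites, lo, hi)
    cuts = [lo] + [p + (pe - p) // 2 for p, pe in occs] + [hi]
    segments = [
        (a, b) for a, b in zip(cuts[:-1], cuts[1:]) if b - a >= cfg.amplicon_min
    ]
    if not segments:
        return []
    length = min(t.length, cfg.amplicon_max)
    # shift: one segment fits the whole amplicon
    fitting = [
        seg for seg in segments if seg[1] - seg[0] >= length
        and min(seg[1], t.end) > max(seg[0], t.start)  # overlaps the original
    ]
    if fitting:
        best = None
        for seg in fitting:
            cand = _best_in_segment(seg, t.interval, length, cfg, mask, families, t.kind)
            if cand is None:
                continue
            ov = max(0, min(cand[1], t.end) - max(cand[0], t.start))
            key = (-ov, cand[0])
            if best is None or key < best[0]:
                best = (key, cand)
        if best is not None:
            return [best[1]]
    # split: one part per segment overlapping the original
    parts: list[tuple[int, int]] = []
    for seg in segments:
        if min(seg[1], t.end) <= max(seg[0], t.start):
            continue
        part_len = min(cfg.amplicon_max, seg[1] - seg[0])
        cand = _best_in_segment(seg, t.interval, part_len, cfg, mask, families, t.kind)
        if cand is not None:
            parts.append(cand)
    return parts
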