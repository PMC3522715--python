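"""Per-base similarity classification of the query and region extraction.

Every query base is labeled by how many distinct genomic sites it maps to
under the thresholded hit set: exactly one site (its own) makes it UNIQUE;
two or more sites, all confined to the query's own locus, make it
SIMILAR_LOCAL (locally repetitive); any site outside the locus makes it
SIMILAR_GLOBAL.  Overlapping subject intervals are merged before counting,
so stacked hits to one place count as a single site.  Maximal runs of each
label, long unique blocks, and gap-tolerant "nearly contiguous" similar
blocks are the units downstream probe design works on.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from fishprobes.alignment import AlignmentHit, SequenceRecord


class Label(enum.IntEnum):
    UNIQUE = 0
    SIMILAR_GLOBAL = 1
    SIMILAR_LOCAL = 2


@dataclass(frozen=True)
class SelfLocus:
    """The genomic interval the query itself derives from.

    ``source`` records whether the user declared it or it was detected as
    the near-identity, near-full-length hit.
    """

    subject_id: str
    start: int
    end: int
    source: str  # "declared" | "detected"

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)

    def contains(self, subject_id: str, start: int, end: int) -> bool:
        return subject_id == self.subject_id and self.start <= start and end <= self.end


@dataclass
class SimilarityMask:
    """Per-base labels over the query plus the threshold that produced them."""

    query_id: str
    labels: np.ndarray  # int8 array of Label values
    min_bits: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int8)

    def __len__(self) -> int:
        return len(self.labels)

    def counts(self) -> dict[str, int]:
        """Base counts per label; always sums to the query length."""
        return {
            lab.name: int(np.sum(self.labels == lab.value)) for lab in Label
        }


@dataclass(frozen=True)
class Region:
    """A maximal half-open interval of one label (or a merged block)."""

    label: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"empty region [{self.start},{self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


def locate_self(
    hits: Sequence[AlignmentHit],
    query: SequenceRecord,
    declared: Optional[tuple[str, int, int]] = None,
) -> SelfLocus:
    """Identify the query's own genomic copy.

    A declaration (``(subject_id, start, end)``, 0-based half-open) wins
    outright.  Otherwise the self hit must be near-identity (>= 0.99) and
    near-full-length (>= 95% query coverage); among qualifying hits the
    highest bit score wins, ties broken by (subject_id, s_start).
    """
    if declared is not None:
        sid, start, end = declared
        return SelfLocus(subject_id=sid, start=start, end=end, source="declared")
    qlen = len(query)
    candidates = [
        h
        for h in hits
        if h.identity >= 0.99 and (h.q_end - h.q_start) >= 0.95 * qlen
    ]
    if not candidates:
        raise ValueError(
            "self locus not found: no >=99% identity hit covering >=95% of the "
            "query (is the query present in this genome build?)"
        )
    best = min(candidates, key=lambda h: (-h.bit_score, h.subject_id, h.s_start))
    return SelfLocus(
        subject_id=best.subject_id, start=best.s_start, end=best.s_end, source="detected"
    )


def count_sites(
    points: list[tuple[str, int]], locus: SelfLocus, tol: int
) -> tuple[int, bool]:
    """Cluster mapped genomic points into distinct sites.

    Points on the same subject within ``tol`` bases belong to one site
    (stacked or frayed hits to one place count once).  Returns the site
    count and whether every site lies inside the self locus.
    """
    points.sort()
    count = 0
    all_local = True
    prev_sid = None
    prev_pt = 0
    for sid, pt in points:
        if sid == prev_sid and pt - prev_pt <= tol:
            prev_pt = pt
            continue
        count += 1
        all_local &= locus.contains(sid, pt, pt + 1)
        prev_sid, prev_pt = sid, pt
    return count, all_local


def classify(
    query: SequenceRecord,
    hits: Sequence[AlignmentHit],
    self_locus: SelfLocus,
    min_bits: float = 200.0,
    site_tol: int = 16,
) -> SimilarityMask:
    """Build the UNIQUE / SIMILAR_GLOBAL / SIMILAR_LOCAL mask over the query.

    Every hit covering a base maps it to one genomic point (its diagonal
    image); points within ``site_tol`` bases of each other on the same
    subject merge into one site, so stacked hits to one place count once.
    One site (the base's own locus) means UNIQUE; several sites, all inside
    the self locus, mean SIMILAR_LOCAL; any site outside means
    SIMILAR_GLOBAL.  Bases covered by no hit at all (possible near the
    query ends when even the self hit frays) are UNIQUE.
    """
    qlen = len(query)
    for h in hits:
        if h.q_start < 0 or h.q_end > qlen:
            raise ValueError(
                f"hit query interval [{h.q_start},{h.q_end}) outside [0,{qlen})"
            )
    labels = np.zeros(qlen, dtype=np.int8)
    if not hits:
        return SimilarityMask(query_id=query.id, labels=labels, min_bits=min_bits)
    starts: dict[int, list[AlignmentHit]] = {}
    ends: dict[int, list[AlignmentHit]] = {}
    for h in hits:
        starts.setdefault(h.q_start, []).append(h)
        ends.setdefault(h.q_end, []).append(h)
    active: list[AlignmentHit] = []
    for p in range(qlen):
        if p in ends:
            gone = set(map(id, ends[p]))
            active = [h for h in active if id(h) not in gone]
        if p in starts:
            active.extend(starts[p])
        if len(active) <= 1:
            continue  # UNIQUE (zero or one site)
        points = []
        for h in active:
            if h.strand == "+":
                pt = h.s_start + (p - h.q_start)
            else:
                pt = h.s_end - 1 - (p - h.q_start)
            points.append((h.subject_id, pt))
        count, all_local = count_sites(points, self_locus, site_tol)
        if count <= 1:
            continue
        labels[p] = int(Label.SIMILAR_LOCAL if all_local else Label.SIMILAR_GLOBAL)
    return SimilarityMask(query_id=query.id, labels=labels, min_bits=min_bits)


def extract_regions(mask: SimilarityMask, label: Label) -> list[Region]:
    """Maximal runs of ``label``, sorted by start."""
    arr = mask.labels == int(label)
    if not arr.any():
        return []
    diffs = np.flatnonzero(np.diff(arr.astype(np.int8)))
    starts = [0] if arr[0] else []
    starts += [int(i) + 1 for i in diffs if arr[i + 1]]
    ends = [int(i) + 1 for i in diffs if arr[i]]
    if arr[-1]:
        ends.append(len(arr))
    return [Region(label=Label(label).name, start=s, end=e) for s, e in zip(starts, ends)]


def unique_blocks(mask: SimilarityMask, min_len: int = 4000) -> list[Region]:
    """UNIQUE regions strictly longer than ``min_len`` (default: exceeding
    4 kb), the stretches eligible for single-copy probe tiling."""
    if min_len < 0:
        raise ValueError("min_len must be >= 0")
    return [r for r in extract_regions(mask, Label.UNIQUE) if r.length > min_len]


def similar_blocks(mask: SimilarityMask, max_gap: int = 500) -> list[Region]:
    """Nearly contiguous similar blocks.

    Runs of SIMILAR_GLOBAL or SIMILAR_LOCAL separated by at most ``max_gap``
    bases of other labels are merged; block boundaries always lie on
    similar-labeled bases.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    similar = np.isin(mask.labels, (int(Label.SIMILAR_GLOBAL), int(Label.SIMILAR_LOCAL)))
    runs: list[tuple[int, int]] = []
    in_run = False
    start = 0
    for i, v in enumerate(similar):
        if v and not in_run:
            start, in_run = i, True
        elif not v and in_run:
            runs.append((start, i))
            in_run = False
    if in_run:
        runs.append((start, len(similar)))
    merged: list[list[int]] = []
    for s, e in runs:
        if merged and s - merged[-1][1] <= max_gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    return [Region(label="SIMILAR_BLOCK", start=s, end=e) for s, e in merged]
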