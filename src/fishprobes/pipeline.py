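"""End-to-end probe design: classify, tile, select, screen, design primers."""

from __future__ import annotations

import logging
import string
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

from fishprobes.alignment import (
    AlignmentHit,
    SequenceRecord,
    align_seed_extend,
    filter_hits,
)
from fishprobes.classify import (
    Region,
    SelfLocus,
    SimilarityMask,
    classify,
    locate_self,
    similar_blocks,
    unique_blocks,
)
from fishprobes.primers import PrimerDesignError, PrimerPair, design_pair, extend_five_prime
from fishprobes.targets import (
    DesignConfig,
    ProbeTarget,
    RepeatFamily,
    _repeat_binding_sites,
    build_repeat_families,
    candidate_repeat_windows,
    enforce_restriction_free,
    select_repeat_targets,
)

log = logging.getLogger(__name__)


def _letter_labels():
    """A, B, ..., Z, AA, AB, ... in coordinate order."""
    for size in range(1, 3):
        for combo in _product(string.ascii_uppercase, size):
            yield combo


def _product(alphabet, size):
    if size == 1:
        yield from alphabet
    else:
        for prefix in _product(alphabet, size - 1):
            for c in alphabet:
                yield prefix + c


def _repeat_labels():
    """x, y, z, then the rest of the lowercase alphabet, then xx, xy, ..."""
    rotated = string.ascii_lowercase[23:] + string.ascii_lowercase[:23]
    yield from rotated
    for a in rotated:
        for b in rotated:
            yield a + b


@dataclass
class PipelineResult:
    """Everything one design run produced, in query coordinates."""

    query: SequenceRecord
    config: DesignConfig
    hits: list[AlignmentHit]
    self_locus: SelfLocus
    mask: SimilarityMask
    unique_blocks: list[Region]
    similar_blocks: list[Region]
    families: list[RepeatFamily]
    targets: list[ProbeTarget]
    primer_pairs: dict[str, PrimerPair]
    dropped: list[str] = field(default_factory=list)

    def amplicon_seq(self, label: str) -> str:
        pair = self.primer_pairs[label]
        s, e = pair.product_interval
        return self.query.seq[s:e]

    @property
    def total_probe_length(self) -> int:
        return sum(t.length for t in self.targets)

    @property
    def total_binding_length(self) -> int:
        from fishprobes.targets import union_length

        return union_length([iv for t in self.targets for iv in t.binding_sites])


def run_pipeline(
    query: SequenceRecord,
    genome: Optional[Sequence[SequenceRecord]] = None,
    hits: Optional[Sequence[AlignmentHit]] = None,
    cfg: Optional[DesignConfig] = None,
    declared_locus: Optional[tuple[str, int, int]] = None,
) -> PipelineResult:
    """Run the full probe-design pipeline on one query.

    Either a genome (aligned with the built-in aligner) or a pre-computed
    hit list must be supplied.  Steps: bit-score filtering, self-locus
    identification, per-base similarity classification, single-copy tiling
    over long unique blocks, repetitive-target selection maximizing
    cumulative binding, restriction-site screening, and primer design with
    5' linker extension.  Targets whose primer design fails are dropped and
    logged in ``result.dropped``.
    """
    cfg = cfg or DesignConfig()
    if hits is None:
        if genome is None:
            raise ValueError("need a genome or a pre-computed hit list")
        hits = align_seed_extend(query, list(genome), cfg.scheme(), xdrop=cfg.xdrop)
    kept = filter_hits(list(hits), cfg.min_bits)
    if declared_locus is None and query.origin is not None:
        chrom, start, end = query.origin
        declared_locus = (chrom, start - 1, end)
    self_locus = locate_self(kept, query, declared_locus)
    mask = classify(query, kept, self_locus, min_bits=cfg.min_bits)
    ublocks = unique_blocks(mask, cfg.min_unique_len)
    sblocks = similar_blocks(mask, cfg.max_gap)
    families = build_repeat_families(kept, self_locus, mask)

    sc_targets = tile_single_copy_blocks(ublocks, cfg)
    candidates: list[ProbeTarget] = []
    for block in sblocks:
        candidates.extend(candidate_repeat_windows(block, families, cfg, mask))
    rep_targets = select_repeat_targets(candidates, cfg)

    screened, notes = enforce_restriction_free(
        sc_targets + rep_targets,
        query.seq,
        cfg,
        blocks=list(ublocks) + list(sblocks),
        mask=mask,
        families=families,
    )
    dropped = list(notes)

    singles = sorted((t for t in screened if t.kind == "single_copy"), key=lambda t: t.start)
    repeats = sorted((t for t in screened if t.kind == "repetitive"), key=lambda t: t.start)
    for t, lab in zip(singles, _letter_labels()):
        t.label = lab
    for t, lab in zip(repeats, _repeat_labels()):
        t.label = lab

    final_targets: list[ProbeTarget] = []
    primer_pairs: dict[str, PrimerPair] = {}
    constraints = cfg.primer_constraints()
    for t in sorted(singles + repeats, key=lambda t: t.start):
        try:
            pair = design_pair(query.seq, t, constraints, margin=cfg.primer_search_margin)
        except PrimerDesignError as exc:
            dropped.append(f"dropped target {t.label}: {exc}")
            continue
        pair = extend_five_prime(pair, cfg.linker)
        s, e = pair.product_interval
        if t.kind == "repetitive":
            sites = _repeat_binding_sites((s, e), families, cfg.amplicon_min)
        else:
            sites = [(s, e)]
        final_targets.append(replace(t, start=s, end=e, binding_sites=sites))
        primer_pairs[t.label] = pair

    return PipelineResult(
        query=query,
        config=cfg,
        hits=kept,
        self_locus=self_locus,
        mask=mask,
        unique_blocks=ublocks,
        similar_blocks=sblocks,
        families=families,
        targets=final_targets,
        primer_pairs=primer_pairs,
        dropped=dropped,
    )


def tile_single_copy_blocks(blocks: Sequence[Region], cfg: DesignConfig) -> list[ProbeTarget]:
    from fishprobes.targets import tile_single_copy

    return tile_single_copy(blocks, cfg)
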