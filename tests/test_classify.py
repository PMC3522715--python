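"""Similarity mask construction, self-locus detection, region extraction."""

import numpy as np
import pytest

from fishprobes.alignment import AlignmentHit, ScoringScheme, SequenceRecord, align_seed_extend, filter_hits
from fishprobes.classify import (
    Label,
    SelfLocus,
    SimilarityMask,
    classify,
    extract_regions,
    locate_self,
    similar_blocks,
    unique_blocks,
)
from fishprobes.simulate import GenomeSpec, Segment, generate_genome, mask_agreement


def _hit(q0, q1, s0, s1, bits=500.0, ident=1.0, sid="g", strand="+"):
    return AlignmentHit("q", q0, q1, sid, s0, s1, strand, bits, ident)


def _mask(labels):
    trans = {"U": Label.UNIQUE, "G": Label.SIMILAR_GLOBAL, "L": Label.SIMILAR_LOCAL}
    return SimilarityMask("q", np.array([int(trans[c]) for c in labels], dtype=np.int8), 200.0)


class TestLocateSelf:
    def test_single_full_length_candidate_wins(self):
        query = SequenceRecord("q", "ACGT" * 300)
        hits = [_hit(0, 1200, 5000, 6200)]
        locus = locate_self(hits, query)
        assert (locus.subject_id, locus.start, locus.end) == ("g", 5000, 6200)
        assert locus.source == "detected"

    def test_declaration_wins_over_hits(self):
        query = SequenceRecord("q", "ACGT" * 300)
        locus = locate_self([_hit(0, 1200, 5000, 6200)], query, declared=("chrX", 7, 1207))
        assert (locus.subject_id, locus.start, locus.end) == ("chrX", 7, 1207)
        assert locus.source == "declared"

    def test_duplicate_locus_tie_breaks(self):
        query = SequenceRecord("q", "ACGT" * 300)
        # higher bit score wins
        hits = [_hit(0, 1200, 5000, 6200, bits=900.0), _hit(0, 1200, 9000, 10200, bits=950.0)]
        assert locate_self(hits, query).start == 9000
        # equal bits: lexicographically smallest (subject_id, s_start)
        hits = [_hit(0, 1200, 9000, 10200), _hit(0, 1200, 5000, 6200)]
        assert locate_self(hits, query).start == 5000

    def test_no_candidate_errors(self):
        query = SequenceRecord("q", "ACGT" * 300)
        with pytest.raises(ValueError, match="self locus not found"):
            locate_self([_hit(0, 400, 0, 400)], query)


class TestClassify:
    def test_lone_copy_query_is_all_unique(self):
        query = SequenceRecord("q", "ACGT" * 250)
        locus = SelfLocus("g", 0, 1000, "declared")
        mask = classify(query, [_hit(0, 1000, 0, 1000)], locus)
        assert mask.counts()["UNIQUE"] == 1000

    def test_local_and_global_repeats_on_synthetic_genome(self):
        """Planted repeats, divergence 0: labels match truth-by-construction
        outside seeding collars, and adding an outside copy flips the label
        from SIMILAR_LOCAL to SIMILAR_GLOBAL."""
        local_spec = GenomeSpec(
            segments=(
                Segment("unique", 3000),
                Segment("unique", 3000), Segment("local_repeat", 500),
                Segment("unique", 3000), Segment("local_repeat", 500),
                Segment("unique", 3000),
                Segment("unique", 2000),
            ),
            locus=(1, 5),
            seed=11,
        )
        sim = generate_genome(local_spec)
        scheme = ScoringScheme()
        hits = filter_hits(align_seed_extend(sim.query, [sim.genome], scheme), 200.0)
        mask = classify(sim.query, hits, sim.self_locus)
        truth = SimilarityMask("query", sim.truth.labels, 200.0)
        assert mask_agreement(mask, truth, scheme.word_size) == 1.0
        assert mask.counts()["SIMILAR_LOCAL"] > 0

        # same geometry, but the repeat family gains a copy outside the locus
        segs = list(local_spec.segments)
        segs[2] = Segment("global_repeat", 500)
        segs[4] = Segment("global_repeat", 500)
        segs.append(Segment("global_repeat", 500))
        global_spec = GenomeSpec(segments=tuple(segs), locus=(1, 5), seed=11)
        sim2 = generate_genome(global_spec)
        hits2 = filter_hits(align_seed_extend(sim2.query, [sim2.genome], scheme), 200.0)
        mask2 = classify(sim2.query, hits2, sim2.self_locus)
        truth2 = SimilarityMask("query", sim2.truth.labels, 200.0)
        assert mask_agreement(mask2, truth2, scheme.word_size) == 1.0
        assert mask2.counts()["SIMILAR_GLOBAL"] > 0
        # outside boundary collars, nothing is called locally repetitive
        from fishprobes.simulate import collar_positions

        keep = ~collar_positions(mask2.labels, truth2.labels, scheme.word_size)
        assert not np.any(mask2.labels[keep] == int(Label.SIMILAR_LOCAL))

    def test_hit_outside_query_is_corrupt_input(self):
        query = SequenceRecord("q", "ACGT" * 100)
        locus = SelfLocus("g", 0, 400, "declared")
        with pytest.raises(ValueError, match="outside"):
            classify(query, [_hit(0, 500, 0, 500)], locus)

    def test_partition_invariant(self, result):
        counts = result.mask.counts()
        assert sum(counts.values()) == len(result.query)

    def test_raising_threshold_never_shrinks_unique(self, sim):
        scheme = ScoringScheme()
        hits = align_seed_extend(sim.query, [sim.genome], scheme)
        prev = -1
        for bits in (100.0, 200.0, 400.0):
            kept = filter_hits(hits, bits)
            mask = classify(sim.query, kept, sim.self_locus, min_bits=bits)
            n_unique = mask.counts()["UNIQUE"]
            assert n_unique >= prev
            prev = n_unique


class TestRegions:
    def test_run_length_extraction(self):
        regions = extract_regions(_mask("UUGGUU"), Label.UNIQUE)
        assert [(r.start, r.end) for r in regions] == [(0, 2), (4, 6)]

    def test_uniform_mask_single_region(self):
        regions = extract_regions(_mask("UUUU"), Label.UNIQUE)
        assert [(r.start, r.end) for r in regions] == [(0, 4)]

    def test_regions_tile_the_query(self, rng):
        labels = "".join(rng.choice(list("UGL"), 200))
        mask = _mask(labels)
        all_regions = []
        for lab in Label:
            all_regions.extend(extract_regions(mask, lab))
        all_regions.sort(key=lambda r: r.start)
        assert all_regions[0].start == 0 and all_regions[-1].end == 200
        for a, b in zip(all_regions[:-1], all_regions[1:]):
            assert a.end == b.start
        # agreement with a naive scanner
        naive = []
        start = 0
        for i in range(1, 201):
            if i == 200 or labels[i] != labels[start]:
                naive.append((start, i))
                start = i
        assert [(r.start, r.end) for r in all_regions] == naive


class TestUniqueBlocks:
    def test_exactly_4000_is_excluded_4001_included(self):
        mask = _mask("U" * 4000 + "G" * 10 + "U" * 4001)
        blocks = unique_blocks(mask)  # default: exceeding 4 kb
        assert [(b.start, b.end) for b in blocks] == [(4010, 8011)]

    def test_zero_min_len_keeps_all(self):
        mask = _mask("UUGGUU")
        assert len(unique_blocks(mask, min_len=0)) == 2


class TestSimilarBlocks:
    def test_gap_at_tolerance_merges(self):
        mask = _mask("GGUUGG")
        blocks = similar_blocks(mask, max_gap=2)
        assert [(b.start, b.end) for b in blocks] == [(0, 6)]

    def test_gap_above_tolerance_splits(self):
        mask = _mask("GGUUGG")
        blocks = similar_blocks(mask, max_gap=1)
        assert [(b.start, b.end) for b in blocks] == [(0, 2), (4, 6)]

    def test_zero_gap_equals_adjacency_merge(self, rng):
        for _ in range(20):
            labels = "".join(rng.choice(list("UGL"), 120))
            mask = _mask(labels)
            blocks = similar_blocks(mask, max_gap=0)
            naive = []
            for i, c in enumerate(labels):
                if c in "GL":
                    if naive and naive[-1][1] == i:
                        naive[-1][1] = i + 1
                    else:
                        naive.append([i, i + 1])
            assert [(b.start, b.end) for b in blocks] == [tuple(x) for x in naive]

    def test_boundaries_lie_on_similar_bases(self):
        mask = _mask("UUGGUUGGUU")
        for b in similar_blocks(mask, max_gap=2):
            assert mask.labels[b.start] != int(Label.UNIQUE)
            assert mask.labels[b.end - 1] != int(Label.UNIQUE)
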