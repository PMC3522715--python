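"""Repeat families, tiling, greedy selection, restriction screening."""

import numpy as np
import pytest

from fishprobes.alignment import AlignmentHit
from fishprobes.classify import Label, Region, SelfLocus, SimilarityMask
from fishprobes.simulate import brute_force_select
from fishprobes.targets import (
    DesignConfig,
    ProbeTarget,
    build_repeat_families,
    candidate_repeat_windows,
    cumulative_binding,
    enforce_restriction_free,
    scan_restriction_sites,
    select_repeat_targets,
    tile_single_copy,
    union_length,
    _partition_block,
)


def _hit(q0, q1, s0, s1, sid="g", strand="+"):
    return AlignmentHit("q", q0, q1, sid, s0, s1, strand, 500.0, 0.98)


def _mask_with_local(qlen, local_intervals):
    labels = np.zeros(qlen, dtype=np.int8)
    for s, e in local_intervals:
        labels[s:e] = int(Label.SIMILAR_LOCAL)
    return SimilarityMask("q", labels, 200.0)


LOCUS = SelfLocus("g", 0, 10000, "declared")


class TestRepeatFamilies:
    def test_one_linking_hit_gives_two_member_family(self):
        mask = _mask_with_local(10000, [(1000, 1500), (3000, 3500)])
        fams = build_repeat_families([_hit(1000, 1500, 3000, 3500)], LOCUS, mask)
        assert len(fams) == 1
        assert fams[0].members == ((1000, 1500), (3000, 3500))

    def test_transitive_closure_merges_chained_copies(self):
        mask = _mask_with_local(10000, [(1000, 1500), (3000, 3500), (5000, 5500)])
        hits = [
            _hit(1000, 1500, 3000, 3500),  # R1 <-> R2
            _hit(3000, 3500, 5000, 5500),  # R2 <-> R3 (no R1 <-> R3 hit)
        ]
        fams = build_repeat_families(hits, LOCUS, mask)
        assert len(fams) == 1
        assert fams[0].members == ((1000, 1500), (3000, 3500), (5000, 5500))

    def test_unrelated_repeats_form_separate_families(self):
        mask = _mask_with_local(
            10000, [(1000, 1500), (3000, 3500), (6000, 6400), (8000, 8400)]
        )
        hits = [_hit(1000, 1500, 3000, 3500), _hit(6000, 6400, 8000, 8400)]
        fams = build_repeat_families(hits, LOCUS, mask)
        assert len(fams) == 2
        assert [f.family_id for f in fams] == [0, 1]

    def test_hits_reaching_outside_the_locus_are_ignored(self):
        mask = _mask_with_local(10000, [(1000, 1500)])
        assert build_repeat_families([_hit(1000, 1500, 12000, 12500)], LOCUS, mask) == []


class TestTiling:
    CFG = DesignConfig()

    def test_block_at_max_length_is_one_amplicon(self):
        targets = tile_single_copy([Region("UNIQUE", 0, 10000)], self.CFG)
        assert [(t.start, t.end) for t in targets] == [(0, 10000)]

    def test_awkward_block_fully_covered_by_two_amplicons(self):
        targets = tile_single_copy([Region("UNIQUE", 0, 10500)], self.CFG)
        assert sum(t.length for t in targets) == 10500
        assert all(1000 <= t.length <= 10000 for t in targets)
        assert targets[0].start == 0 and targets[-1].end == 10500

    def test_block_below_minimum_is_skipped(self):
        assert tile_single_copy([Region("UNIQUE", 0, 999)], self.CFG) == []

    @pytest.mark.parametrize("amin,amax", [(1000, 10000), (1000, 1500), (700, 1200)])
    def test_partition_matches_integer_oracle(self, rng, amin, amax):
        """Covered bases equal the exhaustive optimum over piece counts."""
        for length in rng.integers(1, 30000, size=40):
            length = int(length)
            pieces = _partition_block(length, amin, amax)
            best = 0
            n = 1
            while n * amin <= length:
                best = max(best, min(n * amax, length))
                n += 1
            covered = sum(pieces) if pieces else 0
            assert covered == best
            if pieces:
                assert all(amin <= p <= amax for p in pieces)


class TestCandidateWindows:
    def test_windows_never_touch_globally_similar_bases(self, result):
        glob = result.mask.labels == int(Label.SIMILAR_GLOBAL)
        for block in result.similar_blocks:
            cands = candidate_repeat_windows(block, result.families, result.config, result.mask)
            for c in cands:
                assert not glob[c.start : c.end].any()

    def test_candidates_match_exhaustive_window_scan(self, result):
        cfg = result.config
        step = cfg.amplicon_min // 2
        for block in result.similar_blocks:
            got = {
                c.interval
                for c in candidate_repeat_windows(block, result.families, cfg, result.mask)
            }
            expected = set()
            lengths = list(range(cfg.amplicon_min, min(cfg.amplicon_max, block.length) + 1, step))
            if cfg.amplicon_min <= block.length < cfg.amplicon_max and block.length not in lengths:
                lengths.append(block.length)
            for length in lengths:
                for s in range(block.start, block.end - length + 1, step):
                    win = result.mask.labels[s : s + length]
                    if (win == int(Label.SIMILAR_GLOBAL)).any():
                        continue
                    if (win == int(Label.SIMILAR_LOCAL)).sum() < 0.9 * length:
                        continue
                    expected.add((s, s + length))
            assert got == expected

    def test_window_inside_copy_binds_all_family_members(self, result):
        fam = result.families[0]
        ms, me = fam.members[0]
        block = next(b for b in result.similar_blocks if b.start <= ms < b.end)
        cands = candidate_repeat_windows(block, result.families, result.config, result.mask)
        inside = [c for c in cands if c.start >= ms - 8 and c.end <= me + 8]
        assert inside
        for c in inside:
            for member in fam.members:
                assert any(s <= member[0] and member[1] <= e for s, e in c.binding_sites)


def _cand(s, e, extra=()):
    return ProbeTarget(kind="repetitive", start=s, end=e,
                       binding_sites=[(s, e), *extra])


class TestSelection:
    CFG = DesignConfig()

    def test_greedy_picks_disjoint_high_gain_candidates(self):
        a = _cand(0, 2000, [(10000, 18000)])       # binds 10 kb
        b = _cand(3000, 5000, [(20000, 26000)])    # 8 kb disjoint from a
        c = _cand(10500, 12500, [(10000, 17000)])  # subset of a's union
        sel = select_repeat_targets([a, b, c], self.CFG)
        assert [t.interval for t in sel] == [a.interval, b.interval]
        covered = union_length([iv for t in sel for iv in t.binding_sites])
        assert covered == 18000
        opt = brute_force_select([a, b, c])
        assert covered == union_length([iv for t in opt for iv in t.binding_sites])

    def test_single_candidate_above_min_gain_selected(self):
        sel = select_repeat_targets([_cand(0, 2000)], self.CFG)
        assert len(sel) == 1

    def test_all_gains_below_min_gain_selects_nothing(self):
        cands = [_cand(0, 1100), _cand(2000, 3100)]
        cfg = DesignConfig(min_gain=5000)
        assert select_repeat_targets(cands, cfg) == []

    def test_selected_probe_intervals_never_overlap(self, rng):
        for _ in range(20):
            cands = []
            for _ in range(10):
                s = int(rng.integers(0, 20000))
                e = s + int(rng.integers(1000, 3000))
                extra = [(int(x), int(x) + 1500) for x in rng.integers(0, 30000, 2)]
                cands.append(_cand(s, e, extra))
            sel = sorted(select_repeat_targets(cands, self.CFG), key=lambda t: t.start)
            for a, b in zip(sel[:-1], sel[1:]):
                assert a.end <= b.start

    def test_greedy_within_guarantee_of_exhaustive_optimum(self, rng):
        bound = 1 - 1 / np.e
        for _ in range(15):
            cands = []
            for _ in range(8):
                s = int(rng.integers(0, 15000))
                e = s + int(rng.integers(1000, 2500))
                extra = [(int(x), int(x) + 1200) for x in rng.integers(0, 25000, 2)]
                cands.append(_cand(s, e, extra))
            cfg = DesignConfig(min_gain=0)
            greedy = select_repeat_targets(cands, cfg)
            opt = brute_force_select(cands)
            g = union_length([iv for t in greedy for iv in t.binding_sites])
            o = union_length([iv for t in opt for iv in t.binding_sites])
            assert g >= bound * o


class TestRestrictionScan:
    def test_clai_site_position(self):
        assert scan_restriction_sites("GGATCGATGG", ["ATCGAT"]) == [2]

    def test_absent_site_empty(self):
        assert scan_restriction_sites("GGGGGGGGGG", ["ATCGAT"]) == []

    def test_overlapping_occurrences_found(self):
        assert scan_restriction_sites("ATCGATCGAT", ["ATCGAT"]) == [0, 4]

    def test_non_palindromic_site_scanned_on_both_strands(self):
        # GACGTC is palindromic; use GGTACA (revcomp TGTACC)
        seq = "AAGGTACAAATGTACCAA"
        assert scan_restriction_sites(seq, ["GGTACA"]) == [2, 10]

    def test_iupac_ambiguity_expanded(self):
        assert scan_restriction_sites("AAGAATTCAA", ["GRATTC"]) == [2]


class TestEnforcement:
    def _template(self, rng, n, site_positions):
        seq = list("".join(np.array(list("ACGT"))[rng.integers(0, 4, n)]))
        for p in site_positions:
            seq[p : p + 6] = "ATCGAT"
        s = "".join(seq)
        # keep only the planted sites
        extra = [q for q in scan_restriction_sites(s, ["ATCGAT"]) if q not in site_positions]
        for q in extra:
            seq[q] = {"A": "C"}[s[q]] if s[q] == "A" else "A"
        return "".join(seq)

    def test_verify_mode_annotates_without_moving(self, rng):
        template = self._template(rng, 4000, [500])
        t = ProbeTarget(kind="single_copy", start=0, end=2000)
        cfg = DesignConfig(site_mode="verify")
        out, notes = enforce_restriction_free([t], template, cfg)
        assert out[0].interval == (0, 2000)
        assert out[0].site_hits == [500]
        assert notes == []

    def test_site_near_edge_is_shifted_out(self, rng):
        template = self._template(rng, 4000, [50])
        t = ProbeTarget(kind="single_copy", start=0, end=2000)
        cfg = DesignConfig()
        out, notes = enforce_restriction_free(
            [t], template, cfg, blocks=[Region("UNIQUE", 0, 3000)]
        )
        assert len(out) == 1
        s, e = out[0].interval
        assert e - s == 2000  # length preserved by the shift
        assert scan_restriction_sites(template[s:e], ["ATCGAT"]) == []
        assert any("shifted" in n for n in notes)

    def test_centered_site_in_tight_block_splits(self, rng):
        template = self._template(rng, 2000, [997])
        t = ProbeTarget(kind="single_copy", start=0, end=2000)
        out, notes = enforce_restriction_free(
            [t], template, DesignConfig(), blocks=[Region("UNIQUE", 0, 2000)]
        )
        assert len(out) == 2
        for part in out:
            assert part.length >= 1000
            s, e = part.interval
            assert scan_restriction_sites(template[s:e], ["ATCGAT"]) == []
        assert out[0].end <= out[1].start
        assert any("split" in n for n in notes)

    def test_enforcement_output_always_clean(self, rng):
        """Whatever the site layout, enforce mode emits zero occurrences."""
        for trial in range(10):
            n = 8000
            pos = sorted(int(x) for x in rng.integers(10, n - 10, rng.integers(0, 4)))
            pos = [p for i, p in enumerate(pos) if i == 0 or p - pos[i - 1] > 6]
            template = self._template(rng, n, pos)
            t = ProbeTarget(kind="single_copy", start=500, end=6500)
            out, _ = enforce_restriction_free(
                [t], template, DesignConfig(), blocks=[Region("UNIQUE", 0, n)]
            )
            for part in out:
                s, e = part.interval
                assert scan_restriction_sites(template[s:e], ["ATCGAT"]) == []
                assert 1000 <= part.length <= 10000


class TestCumulativeBinding:
    def test_disjoint_and_overlapping_unions(self):
        t = ProbeTarget(kind="repetitive", start=0, end=100,
                        binding_sites=[(0, 100), (200, 350)])
        assert cumulative_binding(t) == 250
        t2 = ProbeTarget(kind="repetitive", start=0, end=100,
                         binding_sites=[(0, 100), (50, 150)])
        assert cumulative_binding(t2) == 150

    def test_union_length_matches_per_base_oracle(self, rng):
        for _ in range(20):
            ivs = []
            for _ in range(6):
                s = int(rng.integers(0, 500))
                ivs.append((s, s + int(rng.integers(1, 120))))
            arr = np.zeros(700, dtype=bool)
            for s, e in ivs:
                arr[s:e] = True
            assert union_length(ivs) == int(arr.sum())
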