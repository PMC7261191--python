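"""CpG-island caller: window composition, run detection, association rules."""

import numpy as np
import pytest

from promenh import (
    GenomicInterval,
    associate_enhancer_cgi,
    associate_promoter_cgi,
    call_cgis,
    extract_anchored,
    window_composition,
)
from promenh.cgi import CgiCall
from tests.conftest import make_anchored


def brute_force_calls(seq, window=100, min_gc=50.0, min_obs_exp=0.6, min_region=200):
    """Independent O(L*W) scanner: per-window composition from string slices,
    then the same maximal-run / span / merge rules."""
    qualifying = []
    for s in range(len(seq) - window + 1):
        win = seq[s : s + window]
        if any(ch not in "ACGT" for ch in win):
            qualifying.append(False)
            continue
        comp = window_composition(win, window)
        qualifying.append(comp.gc_percent >= min_gc and comp.cpg_obs_exp >= min_obs_exp)
    spans = []
    i = 0
    while i < len(qualifying):
        if not qualifying[i]:
            i += 1
            continue
        j = i
        while j + 1 < len(qualifying) and qualifying[j + 1]:
            j += 1
        if (j + window) - i >= min_region:
            spans.append((i, j + window))
        i = j + 1
    merged = []
    for s, e in spans:
        if merged and s < merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


class TestWindowComposition:
    def test_cg_repeat(self):
        comp = window_composition("CG" * 50)
        assert comp.gc_percent == 100.0
        assert comp.n_cpg == 50
        assert comp.cpg_obs_exp == pytest.approx(2.0)

    def test_degenerate_all_a(self):
        comp = window_composition("A" * 100)
        assert comp.gc_percent == 0.0
        assert comp.cpg_obs_exp == 0.0

    def test_shifted_phase_gc_repeat(self):
        # "GC"*50 has 49 overlapping CG dinucleotides
        comp = window_composition("GC" * 50)
        assert comp.n_cpg == 49
        assert comp.cpg_obs_exp == pytest.approx(49 * 100 / 2500)

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            window_composition("ACGT")


class TestCallCgis:
    def test_planted_block_gives_one_call(self):
        seq = "AT" * 175 + "CG" * 150 + "AT" * 175
        calls = call_cgis(seq)
        assert len(calls) == 1
        assert brute_force_calls(seq) == [(calls[0].rel_start, calls[0].rel_end)]
        # the call covers the CG block (350..650) and little more
        assert calls[0].rel_start <= 350 and calls[0].rel_end >= 650

    def test_all_at_is_empty(self):
        assert call_cgis("AT" * 500) == []

    def test_short_block_below_min_region(self):
        # 150-nt island-like block (GC 65%): windows need >= 77 island bases
        # to reach 50% GC, so the qualifying span tops out below 200 bp
        from promenh.simulate import CGI_TILE

        seq = "AT" * 200 + (CGI_TILE * 8)[:150] + "AT" * 200
        assert call_cgis(seq) == []
        assert brute_force_calls(seq) == []

    def test_n_bases_fail_windows(self):
        seq = "CG" * 100 + "N" + "CG" * 100
        mine = [(c.rel_start, c.rel_end) for c in call_cgis(seq)]
        assert mine == brute_force_calls(seq)
        # windows straddling the N never qualify, so no call crosses it
        assert all(end <= 200 or start > 200 for start, end in mine)

    def test_idempotent_on_called_region(self):
        seq = "AT" * 175 + "CG" * 150 + "AT" * 175
        (call,) = call_cgis(seq)
        inner = seq[call.rel_start : call.rel_end]
        (re_call,) = call_cgis(inner)
        assert re_call.rel_start == 0 and re_call.rel_end == len(inner)

    def test_matches_bruteforce_on_random_sequences(self, rng):
        for _ in range(150):
            gc = rng.uniform(0.45, 0.75)
            seq = "".join(
                rng.choice(list("ACGT"), size=800,
                           p=[(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
            )
            mine = [(c.rel_start, c.rel_end) for c in call_cgis(seq)]
            assert mine == brute_force_calls(seq)

    def test_threshold_monotonicity(self, rng):
        """Lowering the obs/exp threshold never removes coverage; raising
        min_region never adds a call."""
        for _ in range(30):
            seq = "".join(rng.choice(list("ACGT"), size=1200, p=[0.18, 0.32, 0.32, 0.18]))
            strict = call_cgis(seq, min_obs_exp=0.7)
            loose = call_cgis(seq, min_obs_exp=0.5)

            def covered(calls, pos):
                return any(c.contains(pos) for c in calls)

            for c in strict:
                assert all(covered(loose, p) for p in range(c.rel_start, c.rel_end))
            # raising min_region never covers new ground (calls may split, so
            # coverage, not call count, is the monotone quantity)
            small = call_cgis(seq, min_region=200)
            for c in call_cgis(seq, min_region=300):
                assert all(covered(small, p) for p in range(c.rel_start, c.rel_end))


class TestPromoterAssociation:
    def test_cg_rich_window_is_associated(self):
        anchored = make_anchored("CG" * 250, anchor_index=250)
        associated, calls = associate_promoter_cgi(anchored)
        assert associated and calls

    def test_at_rich_is_not(self):
        anchored = make_anchored("AT" * 250, anchor_index=250)
        associated, calls = associate_promoter_cgi(anchored)
        assert not associated and not calls

    def test_island_upstream_of_tss_counts(self):
        # qualifying 200-bp block entirely inside [-200, 0)
        seq = "CG" * 100 + "AT" * 150
        anchored = make_anchored(seq, anchor_index=200)
        associated, _ = associate_promoter_cgi(anchored)
        assert associated

    def test_insufficient_span_rejected(self):
        anchored = make_anchored("CG" * 100, anchor_index=100)
        with pytest.raises(ValueError):
            associate_promoter_cgi(anchored)


class TestEnhancerAssociation:
    @staticmethod
    def _genome(block_center, total=2000, block=400):
        b0 = block_center - block // 2
        seq = list("AT" * (total // 2))
        seq[b0 : b0 + block] = list("CG" * (block // 2))
        return {"chrE": "".join(seq)}

    def test_island_on_forward_tss(self):
        enh = GenomicInterval("chrE", 700, 1000)
        genome = self._genome(block_center=999)
        assert associate_enhancer_cgi(enh, genome)

    def test_island_on_reverse_tss_only(self):
        enh = GenomicInterval("chrE", 700, 1000)
        genome = self._genome(block_center=700)
        assert associate_enhancer_cgi(enh, genome)

    def test_island_far_from_both_tss(self):
        enh = GenomicInterval("chrE", 700, 1000)
        genome = self._genome(block_center=1600)
        assert not associate_enhancer_cgi(enh, genome)
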