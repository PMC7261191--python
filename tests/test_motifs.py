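"""PWM construction, scanning, dependency gating, and the overrepresentation test."""

import dataclasses
import math

import numpy as np
import pytest

from promenh import (
    MotifHit,
    load_pwms,
    overrepresentation_test,
    positional_profile,
    pwm_weights_from_frequencies,
    scan,
)
from promenh.motifs import (
    PWM,
    PositionalProfile,
    cooccurrence_table,
    elements_with_functional_hit,
    frequencies_from_iupac,
)
from tests.conftest import make_anchored


class TestWeights:
    def test_log_odds_arithmetic(self):
        w = pwm_weights_from_frequencies(np.array([[1.0, 0, 0, 0]]), pseudocount=0.01)
        expected = math.log2((1.0 + 0.01 * 0.25) / 1.01 / 0.25)
        assert w[0, 0] == pytest.approx(expected, abs=1e-9)
        assert w[0, 0] == pytest.approx(1.989, abs=1e-3)

    def test_uniform_column_is_zero(self):
        w = pwm_weights_from_frequencies(np.full((3, 4), 0.25))
        assert np.allclose(w, 0.0)

    def test_zero_frequency_without_pseudocount(self):
        with pytest.raises(ValueError):
            pwm_weights_from_frequencies(np.array([[0.5, 0.5, 0.0, 0.0]]), pseudocount=0.0)

    def test_iupac_expansion(self):
        f = frequencies_from_iupac("RN")
        assert f[0].tolist() == [0.48, 0.02, 0.48, 0.02]
        assert f[1].tolist() == [0.25, 0.25, 0.25, 0.25]
        with pytest.raises(ValueError):
            frequencies_from_iupac("Z")


class TestShippedAsset:
    def test_twelve_cpes_with_valid_cutoffs(self, pwms):
        assert len(pwms) == 12
        for pwm in pwms.values():
            assert pwm.cutoff <= pwm.max_score
            assert pwm.functional_window[1] - pwm.functional_window[0] + 1 == 5

    def test_consensus_scores_max(self, pwms):
        """The consensus oligo scores exactly the maximum achievable score."""
        for pwm in pwms.values():
            assert pwm.score(pwm.consensus_from_weights) == pytest.approx(
                pwm.max_score, abs=1e-12
            )

    def test_dpe_requires_inr(self, pwms):
        assert pwms["DPE"].requires == "Inr"


def _exact_pwm(pwm):
    """Raise the cutoff so only the consensus oligonucleotide matches."""
    return dataclasses.replace(pwm, cutoff=pwm.max_score)


class TestScan:
    def _element(self, inserts):
        """701+ nt all-A element covering [-520, +260]; inserts = {rel: oligo}."""
        seq = list("A" * 781)
        for rel, oligo in inserts.items():
            idx = 520 + rel
            seq[idx : idx + len(oligo)] = list(oligo)
        return make_anchored("".join(seq), anchor_index=520)

    def test_planted_consensus_found_once(self, pwms):
        tata = _exact_pwm(pwms["TATA"])
        element = self._element({-30: tata.consensus_from_weights})
        hits = scan(element, tata, element_id="e1")
        assert [(h.start, h.element_id) for h in hits] == [(-30, "e1")]
        assert hits[0].score == pytest.approx(tata.max_score)

    def test_unreachable_cutoff_gives_no_hits(self, pwms):
        tata = dataclasses.replace(pwms["TATA"], cutoff=pwms["TATA"].max_score)
        element = self._element({})
        assert scan(element, tata) == []

    def test_dpe_not_called_without_inr(self, pwms):
        dpe = _exact_pwm(pwms["DPE"])
        inr = pwms["Inr"]
        local = {"DPE": dpe, "Inr": _exact_pwm(inr)}
        element = self._element({28: dpe.consensus_from_weights})
        assert scan(element, dpe, pwms=local) == []
        # planting Inr in its functional window unlocks the DPE call
        element2 = self._element({28: dpe.consensus_from_weights,
                                  -2: local["Inr"].consensus_from_weights})
        hits = scan(element2, dpe, pwms=local)
        assert [h.start for h in hits] == [28]

    def test_inr_outside_functional_window_does_not_unlock(self, pwms):
        dpe = _exact_pwm(pwms["DPE"])
        local = {"DPE": dpe, "Inr": _exact_pwm(pwms["Inr"])}
        element = self._element({28: dpe.consensus_from_weights,
                                 -100: local["Inr"].consensus_from_weights})
        assert scan(element, dpe, pwms=local) == []


class TestPositionalProfile:
    def test_counts_distinct_elements(self):
        hits = [
            MotifHit("e1", "TATA", -30, 5.0),
            MotifHit("e1", "TATA", -30, 5.0),  # duplicate position, same element
            MotifHit("e2", "TATA", -30, 5.0),
            MotifHit("e1", "TATA", 0, 5.0),
        ]
        profile = positional_profile(hits, n_elements=3)
        assert profile.counts[-30 - profile.start] == 2
        assert profile.counts[0 - profile.start] == 1
        assert profile.counts.sum() == 3

    def test_out_of_range_hit_rejected(self):
        with pytest.raises(ValueError):
            positional_profile([MotifHit("e1", "TATA", 300, 1.0)], n_elements=1)


def _profile_from_positions(positions_by_element, n_elements):
    hits = [
        MotifHit(eid, "X", int(p), 1.0)
        for eid, positions in positions_by_element.items()
        for p in positions
    ]
    profile = positional_profile(hits, n_elements=n_elements)
    profile.cpe_name = "X"
    return profile


class TestOverrepresentation:
    PWM_X = PWM(name="X", weights=np.zeros((5, 4)), cutoff=0.0, expected_position=-30)

    def test_planted_fraction_is_significant(self, rng):
        n = 500
        positions = {}
        for i in range(n):
            pos = list(rng.choice(np.arange(-500, 201), size=3, replace=False))
            if i < 150:  # 30% carry the motif at the expected location
                pos.append(-30 + int(rng.integers(-2, 3)))
            positions[f"e{i}"] = pos
        res = overrepresentation_test(_profile_from_positions(positions, n), self.PWM_X)
        assert res.n_plus >= 150
        assert res.significant
        assert res.p_gaussian < 1e-3 and res.p_binomial < 1e-3

    def test_uniform_background_not_significant(self, rng):
        n = 500
        positions = {
            f"e{i}": list(rng.choice(np.arange(-500, 201), size=4, replace=False))
            for i in range(n)
        }
        res = overrepresentation_test(_profile_from_positions(positions, n), self.PWM_X)
        assert not res.significant

    def test_no_hits_anywhere(self):
        profile = PositionalProfile(cpe_name="X", counts=np.zeros(701, dtype=int),
                                    n_elements=100)
        res = overrepresentation_test(profile, self.PWM_X)
        assert res.n_plus == 0
        assert not res.significant
        assert res.degenerate  # all background windows are zero

    def test_degenerate_sigma_with_functional_excess(self):
        # hits only inside the functional window: background sd is 0
        profile = _profile_from_positions({f"e{i}": [-30] for i in range(50)}, 50)
        res = overrepresentation_test(profile, self.PWM_X)
        assert res.degenerate
        assert res.n_plus == 50
        assert res.p_gaussian == 0.0


class TestFunctionalSets:
    def test_functional_membership_and_table(self):
        pwm = PWM(name="X", weights=np.zeros((5, 4)), cutoff=0.0, expected_position=-30)
        hits = [MotifHit("e1", "X", -31, 1.0), MotifHit("e2", "X", -40, 1.0)]
        assert elements_with_functional_hit(hits, pwm) == {"e1"}
        table = cooccurrence_table({"e1"}, {"e1", "e2"}, ["e1", "e2", "e3"])
        assert (table.a, table.b, table.c, table.d) == (1, 0, 1, 1)
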