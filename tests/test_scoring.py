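"""Signature matching, indicator score, and single-vs-combination ranking."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from synsig.datatypes import DiseaseSignature, DrugZProfile, MatchTable, ScoreRecord
from synsig.diffexpr import regulation_calls
from synsig.scoring import match_genes, rank_triplet, score_all, score_treatment


def make_signature(calls: dict, disease_id="dz") -> DiseaseSignature:
    return DiseaseSignature(
        disease_id=disease_id,
        calls=pd.Series(calls, dtype=object),
        alpha_bh=0.01,
        min_fold_change=2.0,
    )


def make_profile(name, z: dict) -> DrugZProfile:
    series = pd.Series(z, dtype=float)
    return DrugZProfile(treatment_id=name, z=series,
                        regulation=regulation_calls(series))


def make_match(name, coeffs, magnitudes, disease_id="dz") -> MatchTable:
    rows = pd.DataFrame({
        "gene": [f"g{i}" for i in range(len(coeffs))],
        "disease_direction": "up",
        "drug_regulation": "down",
        "I": coeffs,
        "magnitude": magnitudes,
    })
    return MatchTable(treatment_id=name, disease_id=disease_id, rows=rows)


def record(name, score, disease_id="dz", flag="") -> ScoreRecord:
    return ScoreRecord(name, disease_id, 1, 1, score, 0.5, score, flag=flag)


class TestMatchGenes:
    SIGNATURE = {"g1": "up", "g2": "up", "g3": "down", "g4": "down"}

    def test_matching_coefficient_table(self):
        """Opposite disease/drug directions give I=+1, identical give -1,
        and 'none' regulation is excluded."""
        sig = make_signature(self.SIGNATURE)
        prof = make_profile("d", {"g1": -2.5, "g2": 2.5, "g3": 3.0, "g4": -3.0,
                                  "g5": 4.0})
        match = match_genes(prof, sig)
        by_gene = match.rows.set_index("gene")
        assert by_gene.loc["g1", "I"] == 1   # up disease, down drug
        assert by_gene.loc["g2", "I"] == -1  # up disease, up drug
        assert by_gene.loc["g3", "I"] == 1   # down disease, up drug
        assert by_gene.loc["g4", "I"] == -1  # down disease, down drug
        assert "g5" not in by_gene.index     # not in signature
        assert match.k == 4

    def test_unregulated_signature_gene_excluded(self):
        sig = make_signature(self.SIGNATURE)
        prof = make_profile("d", {"g1": -2.5, "g2": 0.5, "g3": 1.0, "g4": -1.5})
        match = match_genes(prof, sig)
        assert list(match.rows["gene"]) == ["g1"]
        assert match.k == 1

    def test_magnitude_is_absolute_z(self):
        sig = make_signature({"g1": "up"})
        prof = make_profile("d", {"g1": -3.25})
        match = match_genes(prof, sig)
        assert match.rows["magnitude"].iloc[0] == pytest.approx(3.25)


class TestScoreTreatment:
    def test_worked_example(self):
        """Two reversing matches of magnitude 2.5 and 3.0 over a
        10-gene signature score 0.55."""
        match = make_match("d", [1, 1], [2.5, 3.0])
        rec = score_treatment(match, N=10)
        assert rec.mean_signed == pytest.approx(2.75)
        assert rec.p_k == pytest.approx(stats.norm.cdf(2.75))
        assert rec.score == pytest.approx(0.55, abs=1e-12)

    def test_single_mimicking_match(self):
        rec = score_treatment(make_match("d", [-1], [2.0]), N=4)
        assert rec.score == pytest.approx(-0.5)

    def test_flipping_coefficients_negates_score_exactly(self):
        rng = np.random.default_rng(9)
        coeffs = rng.choice([-1, 1], size=20)
        mags = rng.uniform(2, 6, size=20)
        s_pos = score_treatment(make_match("d", coeffs, mags), N=50).score
        s_neg = score_treatment(make_match("d", -coeffs, mags), N=50).score
        assert s_pos == -s_neg

    def test_empty_match_is_flagged_not_zero(self):
        rec = score_treatment(make_match("d", [], []), N=10)
        assert rec.flag == "no_matched_genes"
        assert np.isnan(rec.score)
        assert not rec.rankable

    def test_empty_signature_is_flagged(self):
        rec = score_treatment(make_match("d", [1], [2.0]), N=0)
        assert rec.flag == "empty_signature"
        assert not rec.rankable

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.data())
    def test_direct_form_equals_probit_composition(self, data):
        """score = sum(I*|z|)/N equals Phi^-1(Phi(mean_signed))*k/N to
        1e-10 whenever |mean_signed| <= 6."""
        k = data.draw(st.integers(1, 30))
        coeffs = np.array(data.draw(
            st.lists(st.sampled_from([-1, 1]), min_size=k, max_size=k)))
        mags = np.array(data.draw(st.lists(
            st.floats(0.0, 6.0, allow_nan=False), min_size=k, max_size=k)))
        n_total = data.draw(st.integers(k, 100))
        rec = score_treatment(make_match("d", coeffs, mags), N=n_total)
        if abs(rec.mean_signed) <= 6:
            # evaluate the probit round trip through the numerically
            # stable tail so oracle rounding does not mask the identity
            m = rec.mean_signed
            roundtrip = (stats.norm.isf(stats.norm.sf(m)) if m >= 0
                         else stats.norm.ppf(stats.norm.cdf(m)))
            assert rec.score == pytest.approx(roundtrip * k / n_total, abs=1e-10)
        assert abs(rec.score) <= (k / n_total) * mags.max() + 1e-12

    def test_perfect_reversal_and_mimicry(self):
        """Full-coverage reversal gives a positive score; full mimicry
        with the same magnitudes gives its exact negation."""
        sig = make_signature({"g1": "up", "g2": "down", "g3": "up"})
        reverser = make_profile("r", {"g1": -3.0, "g2": 4.0, "g3": -2.5})
        mimic = make_profile("m", {"g1": 3.0, "g2": -4.0, "g3": 2.5})
        s_rev = score_treatment(match_genes(reverser, sig), sig.N)
        s_mim = score_treatment(match_genes(mimic, sig), sig.N)
        assert s_rev.k == sig.N
        assert (match_genes(reverser, sig).rows["I"] == 1).all()
        assert s_rev.score > 0
        assert s_mim.score == -s_rev.score


class TestScoreAll:
    def test_cartesian_records_in_deterministic_order(self):
        sigs = [make_signature({"g1": "up"}, disease_id=d) for d in ("dz2", "dz1")]
        profs = [make_profile(n, {"g1": -3.0}) for n in ("b", "a", "c")]
        records = score_all(profs, sigs)
        keys = [(r.disease_id, r.treatment_id) for r in records]
        assert keys == [("dz1", "a"), ("dz1", "b"), ("dz1", "c"),
                        ("dz2", "a"), ("dz2", "b"), ("dz2", "c")]
        shuffled = score_all(profs[::-1], sigs[::-1])
        assert [(r.disease_id, r.treatment_id, r.score) for r in shuffled] == \
               [(r.disease_id, r.treatment_id, r.score) for r in records]

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            score_all([], [make_signature({"g1": "up"})])


class TestRankTriplet:
    def make_ab(self, score, flag=""):
        return ScoreRecord("a+b", "dz", 1, 1, score, 0.5, score, flag=flag)

    @pytest.mark.parametrize(
        "a, b, ab, verdict",
        [
            (0.2, 0.1, 0.3, "combination_more_effective"),
            (-0.1, -0.2, -0.05, "none_effective"),
            (0.3, 0.1, 0.3, "single_A_best"),   # tie goes to the single
            (0.1, 0.3, 0.2, "single_B_best"),
            (0.0, -0.1, 0.0, "none_effective"),  # max must exceed 0
        ],
    )
    def test_verdicts(self, a, b, ab, verdict):
        res = rank_triplet(record("a", a), record("b", b), self.make_ab(ab))
        assert res.verdict == verdict

    def test_flagged_record_cannot_win(self):
        res = rank_triplet(record("a", 0.5), record("b", 0.1),
                           self.make_ab(99.0, flag="no_matched_genes"))
        assert res.verdict == "single_A_best"

    def test_all_flagged_is_none_effective(self):
        res = rank_triplet(record("a", 1.0, flag="no_matched_genes"),
                           record("b", 1.0, flag="no_matched_genes"),
                           self.make_ab(1.0, flag="no_matched_genes"))
        assert res.verdict == "none_effective"

    def test_mismatched_disease_is_error(self):
        with pytest.raises(ValueError, match="disease"):
            rank_triplet(record("a", 0.1), record("b", 0.1, disease_id="other"),
                         self.make_ab(0.2))
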