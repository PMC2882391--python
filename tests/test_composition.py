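"""Composition profiles, preference selections, and comparison measures."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dwebiclique.biclique import SupportRecord, make_pattern
from dwebiclique.composition import (
    AA3,
    PAIRS,
    BackgroundComposition,
    CompositionProfile,
    UndefinedCorrelationError,
    UndefinedProfileError,
    correlation,
    delta_f,
    frequency_ratio,
    pair_frequencies,
    pair_matrix,
    pair_ratio_and_ipRP,
    residue_frequencies,
    select_idR,
    select_idRP,
    select_ipR_antiipR,
)


def _rec(small, large, supports):
    return SupportRecord(make_pattern(small, large), dict(supports))


class TestResidueFrequencies:
    def test_single_pattern_multiset_percentages(self):
        recs = [_rec(["ALA", "ALA"], ["LEU", "LEU", "LEU"], {"obligate": 1})]
        freq = residue_frequencies(recs, "obligate")
        assert freq["ALA"] == pytest.approx(40.0)
        assert freq["LEU"] == pytest.approx(60.0)
        assert freq.sum() == pytest.approx(100.0)

    def test_support_scaling_leaves_percentages(self):
        base = [_rec(["ALA", "ALA"], ["LEU", "LEU", "LEU"], {"obligate": 1})]
        tripled = [_rec(["ALA", "ALA"], ["LEU", "LEU", "LEU"], {"obligate": 3})]
        assert residue_frequencies(base, "obligate").equals(
            residue_frequencies(tripled, "obligate"))

    def test_two_pattern_hand_count(self):
        recs = [
            _rec(["ALA", "GLY"], ["LEU", "LEU", "VAL"], {"obligate": 2}),
            _rec(["TRP", "TRP"], ["CYS", "CYS", "CYS"], {"obligate": 1}),
        ]
        freq = residue_frequencies(recs, "obligate")
        # weighted residues: 2*(ALA,GLY,LEU,LEU,VAL) + 1*(TRP,TRP,CYS,CYS,CYS)
        assert freq["LEU"] == pytest.approx(100 * 4 / 15)
        assert freq["TRP"] == pytest.approx(100 * 2 / 15)
        assert freq["CYS"] == pytest.approx(100 * 3 / 15)

    def test_per_pattern_weighting(self):
        recs = [
            _rec(["ALA", "ALA"], ["ALA", "ALA", "ALA"], {"obligate": 5}),
            _rec(["GLY", "GLY"], ["GLY", "GLY", "GLY"], {"obligate": 1}),
        ]
        freq = residue_frequencies(recs, "obligate", weighting="per_pattern")
        assert freq["ALA"] == pytest.approx(50.0)

    def test_empty_class_errors(self):
        recs = [_rec(["ALA"], ["GLY"], {"obligate": 2})]
        with pytest.raises(UndefinedProfileError):
            residue_frequencies(recs, "crystal_packing")


class TestPairFrequencies:
    def test_cross_pairs_only(self):
        recs = [_rec(["ALA", "ALA"], ["LEU"], {"obligate": 1})]
        freq = pair_frequencies(recs, "obligate")
        assert freq[("ALA", "LEU")] == pytest.approx(100.0)
        assert freq.sum() == pytest.approx(100.0)

    def test_identical_residue_pair_on_diagonal(self):
        recs = [_rec(["ALA"], ["ALA"], {"obligate": 1})]
        freq = pair_frequencies(recs, "obligate")
        assert freq[("ALA", "ALA")] == pytest.approx(100.0)

    def test_hand_enumerated_cross_products(self):
        recs = [
            _rec(["ALA", "GLY"], ["LEU", "VAL"], {"obligate": 1}),
            _rec(["CYS"], ["CYS", "TRP"], {"obligate": 2}),
        ]
        freq = pair_frequencies(recs, "obligate")
        # pattern 1: AL, AV, GL, GV once; pattern 2: CC, CW twice -> total 8
        assert freq[("ALA", "LEU")] == pytest.approx(100 / 8)
        assert freq[("CYS", "CYS")] == pytest.approx(200 / 8)
        assert freq[("CYS", "TRP")] == pytest.approx(200 / 8)

    def test_pair_matrix_symmetry(self):
        recs = [_rec(["ALA", "GLY"], ["LEU", "VAL"], {"obligate": 1})]
        mat = pair_matrix(pair_frequencies(recs, "obligate"))
        assert np.allclose(mat.values, mat.values.T)


class TestBackgroundAndRatios:
    def test_background_sums_and_pair_expectation(self):
        bg = BackgroundComposition.swissprot55()
        assert bg.percent.sum() == pytest.approx(100.0, abs=0.5)
        assert bg.pair_expectation().sum() == pytest.approx(1.0, rel=1e-9)

    def test_ratio_identity_and_scaling(self):
        bg = BackgroundComposition.swissprot55()
        ratios = frequency_ratio(bg.percent.copy(), bg)
        assert np.allclose(ratios.values, 1.0)
        doubled = bg.percent.copy()
        doubled["TRP"] *= 2
        assert frequency_ratio(doubled, bg)["TRP"] == pytest.approx(2.0)

    def test_gly_ratio_consistency_with_published_profile(self):
        """An obligate-interface Gly frequency of 6.78% over the shipped
        background gives a ratio near 0.96 (within 0.02)."""
        bg = BackgroundComposition.swissprot55()
        assert 6.78 / bg.percent["GLY"] == pytest.approx(0.96, abs=0.02)


class TestSelections:
    def test_idR_ranking_and_ties(self):
        freq = pd.Series(5.0, index=list(AA3))
        freq["LEU"] = 14.4
        freq["ALA"] = 8.2
        top = select_idR(freq, k=7)
        assert top[0] == "LEU"
        assert top[1] == "ALA"
        # remaining five tied at 5.0 resolve alphabetically
        assert top[2:] == ["ARG", "ASN", "ASP", "CYS", "GLN"]

    def test_idR_uniform_alphabetical(self):
        freq = pd.Series(5.0, index=list(AA3))
        assert select_idR(freq, k=7) == ["ALA", "ARG", "ASN", "ASP", "CYS",
                                         "GLN", "GLU"]

    def test_ipR_boundaries_strict(self):
        ratios = pd.Series(1.0, index=list(AA3))
        ratios["TYR"] = 1.87   # in
        ratios["TRP"] = 1.05   # boundary: out
        ratios["CYS"] = 0.5    # anti
        ratios["SER"] = 0.8    # boundary: out
        ipr, anti = select_ipR_antiipR(ratios)
        assert "TYR" in ipr and "TRP" not in ipr
        assert "CYS" in anti and "SER" not in anti
        assert not ipr & anti

    @settings(max_examples=40, derandomize=True)
    @given(st.floats(0.1, 1.0), st.floats(1.01, 3.0))
    def test_ipR_antiipR_always_disjoint(self, lo, hi):
        rng = np.random.default_rng(1)
        ratios = pd.Series(rng.uniform(0, 3, 20), index=list(AA3))
        ipr, anti = select_ipR_antiipR(ratios, hi=hi, lo=lo)
        assert not ipr & anti

    def test_idRP_ranking(self):
        freq = pd.Series(0.0, index=pd.MultiIndex.from_tuples(PAIRS))
        hydrophobic = [("ILE", "VAL"), ("ILE", "LEU"), ("LEU", "VAL"),
                       ("ILE", "PHE"), ("LEU", "PHE")]
        for i, p in enumerate(hydrophobic):
            key = tuple(sorted(p))
            freq[key] = 30.0 - i
        out = select_idRP(freq, k=5)
        assert set(out) == {tuple(sorted(p)) for p in hydrophobic}
        assert out[0] == ("ILE", "VAL")

    def test_ipRP_boundary_and_enrichment(self):
        bg = BackgroundComposition.swissprot55()
        expectation = bg.pair_expectation()
        # flat profile exactly at expectation: ratio 1, ln 2 < 1.05, no ipRP
        flat = 100.0 * expectation.copy()
        ratios, iprp = pair_ratio_and_ipRP(flat, bg)
        assert np.allclose(ratios.values, 1.0)
        assert iprp == set()
        # enrich one pair 3x: ln 4 > 1.05 -> sole ipRP
        enriched = flat.copy()
        enriched[("ILE", "VAL")] *= 3
        enriched *= 100.0 / enriched.sum()
        ratios, iprp = pair_ratio_and_ipRP(enriched, bg)
        assert iprp == {("ILE", "VAL")}

    def test_ipRP_threshold_strictness_around_cut(self):
        bg = BackgroundComposition.swissprot55()
        cut = math.exp(1.05) - 1.0
        flat = 100.0 * bg.pair_expectation()
        # every ratio just below the cut: nothing selected (strict >)
        _, iprp_below = pair_ratio_and_ipRP(flat * (cut * (1 - 1e-6)), bg)
        assert iprp_below == set()
        # every ratio just above: everything selected
        _, iprp_above = pair_ratio_and_ipRP(flat * (cut * (1 + 1e-6)), bg)
        assert len(iprp_above) == 210

    def test_ipRP_membership_monotone_in_threshold(self):
        recs = [_rec(["ILE", "VAL"], ["ILE", "LEU", "VAL"], {"obligate": 2}),
                _rec(["TRP"], ["TRP", "TYR"], {"obligate": 2})]
        bg = BackgroundComposition.swissprot55()
        freq = pair_frequencies(recs, "obligate")
        sets = [pair_ratio_and_ipRP(freq, bg, log_threshold=t)[1]
                for t in (0.5, 1.05, 2.0, 4.0)]
        for small, large in zip(sets[1:], sets[:-1]):
            assert small <= large


class TestComparisonMeasures:
    def test_delta_f_zero_on_equal(self):
        f = np.full(20, 5.0)
        assert delta_f(f, f) == 0.0

    def test_delta_f_single_component(self):
        f = np.full(20, 5.0)
        g = f.copy()
        g[3] += 3.0
        assert delta_f(f, g) == pytest.approx(3.0)

    def test_delta_f_hand_value_and_rms_variant(self):
        f = np.zeros(20)
        g = np.zeros(20)
        g[:4] = [3.0, 4.0, 0.0, 12.0]
        assert delta_f(f, g) == pytest.approx(13.0)  # sqrt(9+16+144)
        assert delta_f(f, g, variant="rms") == pytest.approx(13.0 / math.sqrt(20))

    @settings(max_examples=50, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_delta_f_metric_properties(self, seed):
        rng = np.random.default_rng(seed)
        f, g, h = rng.uniform(0, 10, size=(3, 20))
        assert delta_f(f, g) == pytest.approx(delta_f(g, f))
        assert delta_f(f, g) >= 0
        assert delta_f(f, h) <= delta_f(f, g) + delta_f(g, h) + 1e-9

    def test_correlation_identity_and_mirror(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0.5, 2.0, 20)
        assert correlation(x, x) == pytest.approx(1.0)
        assert correlation(x, 2 * x.mean() - x) == pytest.approx(-1.0)

    def test_correlation_affine_invariance(self):
        rng = np.random.default_rng(3)
        x, y = rng.uniform(0, 2, size=(2, 20))
        assert correlation(x, 3.0 * y + 1.0) == pytest.approx(correlation(x, y))

    def test_correlation_zero_variance_errors(self):
        with pytest.raises(UndefinedCorrelationError):
            correlation(np.ones(20), np.arange(20.0))


class TestProfile:
    def test_full_profile_construction(self):
        recs = [
            _rec(["ILE", "VAL"], ["ILE", "LEU", "VAL"], {"obligate": 3}),
            _rec(["TRP", "TYR"], ["PHE", "TRP", "TYR"], {"obligate": 2}),
        ]
        profile = CompositionProfile.from_support_records(recs, "obligate")
        assert profile.res_freq.sum() == pytest.approx(100.0)
        assert profile.pair_freq.sum() == pytest.approx(100.0)
        assert len(profile.idR) == 7
        assert profile.idR[0] in ("ILE", "VAL")
        assert "ILE" in profile.ipR  # heavily enriched over ~5.9% background
        assert "ALA" in profile.anti_ipR  # absent entirely
        data = profile.selections_json()
        assert "idRP" in data and "ipRP" in data
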