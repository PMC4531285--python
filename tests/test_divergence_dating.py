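"""NG86 site/difference counting, Jukes-Cantor Ks, peaks, clock dating."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cicerkit import divergence_dating as dd
from cicerkit.io_core import SequenceRecord
from cicerkit.synthetic_data import simulate_cds_pairs


class TestSites:
    def test_phe_codon_has_one_third_synonymous_site(self):
        # TTT: only TTT<->TTC is synonymous, at the third position
        assert dd.synonymous_sites("TTT") == pytest.approx(1 / 3)

    def test_fourfold_degenerate_third_position(self):
        # GGG (Gly): all third-position changes synonymous -> exactly 1
        assert dd.synonymous_sites("GGG") == pytest.approx(1.0)

    def test_stop_codon_is_an_error(self):
        with pytest.raises(ValueError):
            dd.synonymous_sites("TAA")

    def test_site_counts_bounded_per_codon(self):
        for codon in dd.SENSE_CODONS:
            s = dd.synonymous_sites(codon)
            assert 0.0 <= s <= 3.0


class TestPathways:
    def test_two_difference_example_averages_pathways(self):
        # TTT (Phe) vs GTA (Val): path via GTT gives 1 syn + 1 nonsyn,
        # path via TTA gives 2 nonsyn -> sd = 0.5, nd = 1.5
        sd, nd = dd.pathway_differences("TTT", "GTA")
        assert sd == pytest.approx(0.5)
        assert nd == pytest.approx(1.5)

    def test_identical_codons_have_no_differences(self):
        assert dd.pathway_differences("ATG", "ATG") == (0.0, 0.0)

    def test_single_synonymous_change(self):
        sd, nd = dd.pathway_differences("TTT", "TTC")
        assert (sd, nd) == (1.0, 0.0)

    def test_differences_sum_to_hamming_distance(self):
        rng = np.random.default_rng(0)
        codons = dd.SENSE_CODONS
        for _ in range(100):
            a, b = rng.choice(codons, 2)
            sd, nd = dd.pathway_differences(a, b)
            ham = sum(x != y for x, y in zip(a, b))
            assert sd + nd == pytest.approx(ham)


class TestKs:
    def test_identical_sequences_give_zero(self):
        a = SequenceRecord("a", "ATGGGGTTT")
        b = SequenceRecord("b", "ATGGGGTTT")
        assert dd.ks_ng86(a, b).ks == 0.0

    def test_single_synonymous_difference_closed_form(self):
        # ten Gly codons, one synonymous change: Sd = 1,
        # S = (9*S(GGG) + S(GGG) + 9*S(GGG) + S(GGA)) / 2
        s = (10 * dd.synonymous_sites("GGG")
             + 9 * dd.synonymous_sites("GGG")
             + dd.synonymous_sites("GGA")) / 2
        ps = 1 / s
        expected = -0.75 * math.log(1 - 4 / 3 * ps)
        a = SequenceRecord("a", "GGG" * 10)
        b = SequenceRecord("b", "GGG" * 9 + "GGA")
        assert dd.ks_ng86(a, b).ks == pytest.approx(expected)

    def test_saturation_raises(self):
        # a single fully synonymous codon pair saturates: pS = 1
        a = SequenceRecord("a", "TTT")
        b = SequenceRecord("b", "TTC")
        with pytest.raises(dd.KsSaturationError):
            dd.ks_ng86(a, b)

    def test_length_mismatch_and_frame_errors(self):
        with pytest.raises(ValueError):
            dd.proportion_synonymous("ATGATG", "ATG")
        with pytest.raises(ValueError, match="divisible"):
            dd.proportion_synonymous("ATGA", "ATGA")
        with pytest.raises(ValueError, match="stop"):
            dd.proportion_synonymous("ATGTAA", "ATGTAA")

    def test_generator_round_trip(self):
        pairs, truth = simulate_cds_pairs(3, 3000, [0.003], seed=2)
        for a, b in pairs:
            ks = dd.ks_ng86(a, b).ks
            assert ks == pytest.approx(0.003, rel=0.10)

    @given(st.floats(min_value=0.0, max_value=0.74, exclude_max=True))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_jc_correction_is_monotone_and_at_least_ps(self, ps):
        ks = -0.75 * math.log(1 - 4 / 3 * ps)
        assert ks >= ps - 1e-12


class TestKsPeak:
    def test_bimodal_distribution_recovers_both_modes(self):
        rng = np.random.default_rng(1)
        low = rng.normal(0.0001, 0.00002, 500).clip(0)
        high = rng.normal(0.0025, 0.0002, 500).clip(0)
        peaks = dd.ks_peak(np.concatenate([low, high]).tolist())
        assert len(peaks) >= 2
        assert any(abs(p - 0.0001) <= 0.0005 for p in peaks)
        assert any(abs(p - 0.0025) <= 0.0005 for p in peaks)

    def test_too_few_values_is_an_error(self):
        with pytest.raises(ValueError):
            dd.ks_peak([0.001] * 9)

    def test_minor_mass_below_threshold_is_ignored(self):
        values = [0.001] * 95 + [0.005] * 4  # 4% mass at the second mode
        peaks = dd.ks_peak(values, min_mass=0.05)
        assert len(peaks) == 1


class TestDating:
    def test_recent_divergence_rounds_to_eight_thousand_years(self):
        years = dd.divergence_time(0.0001)
        assert years == pytest.approx(8196.72, abs=0.01)
        assert dd.format_years_thousand(years) == 8000

    def test_older_divergences_in_million_years(self):
        assert dd.format_million_years(dd.divergence_time(0.002)) == 0.16
        assert dd.format_million_years(dd.divergence_time(0.003)) == 0.25

    def test_time_is_linear_in_ks(self):
        t1 = dd.divergence_time(0.001)
        t2 = dd.divergence_time(0.002)
        assert t2 == pytest.approx(2 * t1)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            dd.divergence_time(-0.1)
        with pytest.raises(ValueError):
            dd.DatingParams(r=0)
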