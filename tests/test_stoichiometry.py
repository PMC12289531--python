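"""Histone acetylation stoichiometry: isomer shares, weighting, round trips."""

import numpy as np
import pytest

import turnoverkit as tk
from turnoverkit.errors import ContractError, DomainError, IncompleteDenominatorError
from turnoverkit.stoichiometry import (
    H3_PEPTIDE,
    H4_PEPTIDE,
    PositionalIsomerQuant,
    quantify_histone_table,
)


class TestH3MonoShares:
    @pytest.mark.parametrize(
        "light, heavy, k18",
        [(5, 0, 1.0), (3, 3, 0.5), (2, 6, 0.25), (0, 4, 0.0)],
    )
    def test_b2_ratio(self, light, heavy, k18):
        shares = tk.h3_mono_isomer_shares(light, heavy)
        assert shares["K18"] == pytest.approx(k18)
        assert shares["K23"] == pytest.approx(1 - k18)

    def test_both_channels_zero_unquantifiable(self):
        with pytest.raises(DomainError):
            tk.h3_mono_isomer_shares(0.0, 0.0)


class TestH4MonoShares:
    def test_telescoping_attribution(self):
        shares, clamped = tk.h4_mono_isomer_shares({"y5": 0.2, "y7": 0.5, "y12": 0.8})
        assert shares == pytest.approx({"K5": 0.2, "K8": 0.3, "K12": 0.3, "K16": 0.2})
        assert not clamped

    def test_no_light_signal_attributes_k5(self):
        shares, _ = tk.h4_mono_isomer_shares({"y5": 0.0, "y7": 0.0, "y12": 0.0})
        assert shares == pytest.approx({"K5": 1.0, "K8": 0.0, "K12": 0.0, "K16": 0.0})

    def test_noise_inversion_clamped_and_renormalized(self):
        shares, clamped = tk.h4_mono_isomer_shares({"y5": 0.3, "y7": 0.2, "y12": 0.6})
        assert clamped
        assert shares["K12"] == 0.0
        assert sum(shares.values()) == pytest.approx(1.0, abs=1e-9)

    def test_out_of_range_fraction_rejected(self):
        with pytest.raises(DomainError):
            tk.h4_mono_isomer_shares({"y5": 1.2, "y7": 0.5, "y12": 0.8})


def _form(peptide, label, count, ms1, occupancy=None, shares=None):
    return PositionalIsomerQuant(
        peptide=peptide, form_label=label, acetyl_count=count, ms1_abundance=ms1,
        site_shares=shares or {}, site_occupancy=occupancy or {},
    )


class TestSiteStoichiometry:
    def test_light_equals_heavy_gives_half(self):
        forms = [
            _form(H3_PEPTIDE, "1ac", 1, 10.0, {"K18": 1.0}, {"K18": 1.0}),
            _form(H3_PEPTIDE, "0ac", 0, 10.0),
        ]
        stoich = tk.site_stoichiometry(forms)
        assert stoich["K18"] == pytest.approx(0.5)
        assert stoich["K23"] == 0.0

    def test_no_endogenous_forms_all_zero(self):
        stoich = tk.site_stoichiometry([_form(H3_PEPTIDE, "0ac", 0, 7.0)])
        assert stoich == {"K18": 0.0, "K23": 0.0}

    def test_three_form_weighted_sum(self):
        forms = [
            _form(H3_PEPTIDE, "1ac", 1, 0.2, {"K18": 1.0}, {"K18": 1.0}),
            _form(H3_PEPTIDE, "2ac", 2, 0.1, {"K18": 1.0, "K23": 1.0}, {"K18+K23": 1.0}),
            _form(H3_PEPTIDE, "0ac", 0, 0.7),
        ]
        stoich = tk.site_stoichiometry(forms)
        assert stoich["K18"] == pytest.approx(0.3)
        assert stoich["K23"] == pytest.approx(0.1)

    def test_missing_all_heavy_form_rejected(self):
        with pytest.raises(IncompleteDenominatorError):
            tk.site_stoichiometry(
                [_form(H3_PEPTIDE, "1ac", 1, 1.0, {"K18": 1.0}, {"K18": 1.0})]
            )

    def test_ms1_scale_invariance(self):
        def build(c):
            return [
                _form(H3_PEPTIDE, "1ac", 1, 0.4 * c, {"K23": 1.0}, {"K23": 1.0}),
                _form(H3_PEPTIDE, "0ac", 0, 0.6 * c),
            ]
        s1 = tk.site_stoichiometry(build(1.0))
        s2 = tk.site_stoichiometry(build(137.0))
        assert s1["K23"] == pytest.approx(s2["K23"], abs=1e-12)


class TestCombineDiacetyl:
    def test_additivity(self):
        forms = [
            _form(H4_PEPTIDE, "K5+K12", 2, 2.0),
            _form(H4_PEPTIDE, "K8+K16", 2, 3.0),
        ]
        combined = tk.combine_unresolvable_diacetyl(forms)
        assert combined.ms1_abundance == pytest.approx(5.0)
        assert set(combined.members) == {"K5+K12", "K8+K16"}

    def test_empty_subset(self):
        combined = tk.combine_unresolvable_diacetyl([])
        assert combined.ms1_abundance == 0.0
        assert combined.members == ()

    def test_mixed_acetyl_counts_rejected(self):
        forms = [
            _form(H4_PEPTIDE, "K5+K12", 2, 2.0),
            _form(H4_PEPTIDE, "1ac", 1, 3.0),
        ]
        with pytest.raises(ContractError):
            tk.combine_unresolvable_diacetyl(forms)

    def test_generator_round_trip(self):
        # combined abundance equals the sum of known isomer abundances
        rng = np.random.default_rng(4)
        weights = rng.uniform(1, 5, size=4)
        labels = ["K5+K12", "K5+K16", "K8+K12", "K8+K16"]
        forms = [_form(H4_PEPTIDE, l, 2, w) for l, w in zip(labels, weights)]
        assert tk.combine_unresolvable_diacetyl(forms).ms1_abundance == pytest.approx(
            float(weights.sum())
        )


class TestFixtureRoundTrip:
    @pytest.mark.parametrize(
        "peptide, truth",
        [
            (H3_PEPTIDE, {"K18": 0.25, "K23": 0.10}),
            (H4_PEPTIDE, {"K5": 0.05, "K8": 0.12, "K12": 0.20, "K16": 0.33}),
        ],
    )
    def test_noise_free_recovery(self, peptide, truth):
        table, gt = tk.generate_histone_fixture(peptide, truth)
        res = quantify_histone_table(table)
        got = dict(zip(res["site"], res["stoichiometry"]))
        for site, v in gt["site_stoichiometry"].items():
            assert got[site] == pytest.approx(v, abs=1e-9)

    def test_multiacetyl_mixture_recovery(self):
        mix = {
            frozenset(): 0.55,
            frozenset({"K18"}): 0.25,
            frozenset({"K18", "K23"}): 0.20,
        }
        table, gt = tk.generate_histone_fixture(H3_PEPTIDE, form_mixture=mix)
        res = quantify_histone_table(table)
        got = dict(zip(res["site"], res["stoichiometry"]))
        assert got["K18"] == pytest.approx(0.45, abs=1e-9)
        assert got["K23"] == pytest.approx(0.20, abs=1e-9)
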