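"""Isotopologue arithmetic: fractional labelling, artifact removal, net labelling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import forward_convolve
from leaftracer.isotope import (
    ArtifactModel,
    DegenerateInputError,
    LabellingResult,
    MIDVector,
    correct_m1_artifact,
    estimate_m1_artifact,
    forward_m1_artifact,
    fractional_labelling,
    mean_labelled_atoms,
    net_labelling,
)


class TestFractionalLabelling:
    @pytest.mark.parametrize(
        "values, expected",
        [
            ([100, 0], [1.0, 0.0]),
            ([80, 20], [0.8, 0.2]),
            ([50, 30, 20], [0.5, 0.3, 0.2]),
        ],
    )
    def test_quotient_formula(self, values, expected):
        res = fractional_labelling(MIDVector("proline", values))
        assert res.fractional == pytest.approx(expected)

    def test_all_zero_vector_names_sample_and_compound(self):
        with pytest.raises(DegenerateInputError, match="proline.*S1"):
            fractional_labelling(MIDVector("proline", [0, 0, 0]), sample_id="S1")

    @given(
        st.lists(st.floats(min_value=0, max_value=1e6), min_size=2, max_size=5).filter(
            lambda v: sum(v) > 1e-6
        )
    )
    @settings(max_examples=200, deadline=None)
    def test_fractions_sum_to_one(self, values):
        res = fractional_labelling(MIDVector("x", values))
        assert sum(res.fractional) == pytest.approx(1.0, abs=1e-9)


class TestArtifactEstimation:
    def test_twenty_percent_m1_in_standards(self):
        # the derivatisation artifact magnitude observed in 15N-free standards
        standards = [MIDVector("proline", [0.80, 0.20]) for _ in range(3)]
        assert estimate_m1_artifact(standards).r == pytest.approx(0.20)

    def test_clean_standard_gives_zero(self):
        assert estimate_m1_artifact([MIDVector("x", [1.0, 0.0])]).r == 0.0

    def test_mean_over_standards(self):
        standards = [MIDVector("x", [0.82, 0.18]), MIDVector("x", [0.78, 0.22])]
        assert estimate_m1_artifact(standards).r == pytest.approx(0.20)

    def test_empty_standard_set_is_configuration_error(self):
        with pytest.raises(ValueError, match="standards"):
            estimate_m1_artifact([])

    def test_negative_excess_clamped_to_zero(self):
        standards = [MIDVector("x", [0.95, 0.05])]
        assert estimate_m1_artifact(standards, baseline=0.10).r == 0.0


class TestArtifactCorrection:
    def test_pure_m0_recovered(self):
        corrected = correct_m1_artifact(
            MIDVector("x", [0.8, 0.2], is_fractional=True), ArtifactModel(0.2)
        )
        assert corrected.values == pytest.approx([1.0, 0.0], abs=1e-12)

    def test_r_zero_is_identity(self):
        mid = MIDVector("x", [0.5, 0.3, 0.2])
        assert correct_m1_artifact(mid, ArtifactModel(0.0)).values == mid.values

    def test_round_trip_against_forward_oracle(self):
        true = [0.5, 0.3, 0.2]
        observed = forward_convolve(true, 0.2)
        corrected = correct_m1_artifact(
            MIDVector("x", observed / observed.sum(), is_fractional=True),
            ArtifactModel(0.2),
        )
        assert corrected.values == pytest.approx(true, abs=1e-12)

    def test_invalid_artifact_fraction_rejected(self):
        with pytest.raises(ValueError):
            ArtifactModel(1.0)

    def test_subtract_standard_mode_moves_m1_to_m0(self):
        mid = MIDVector("x", [0.6, 0.3, 0.1], is_fractional=True)
        corrected = correct_m1_artifact(mid, ArtifactModel(0.2, mode="subtract_standard"))
        assert corrected.values == pytest.approx([0.8, 0.1, 0.1])

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=2, max_size=5).filter(
            lambda v: sum(v) > 0.01
        ),
        st.floats(min_value=0.0, max_value=0.5),
    )
    @settings(max_examples=300, deadline=None)
    def test_deconvolution_inverts_forward_model(self, raw, r):
        """correct_m1_artifact ∘ forward = identity, against the oracle."""
        true = np.asarray(raw) / sum(raw)
        observed = forward_convolve(true, r)
        observed = observed / observed.sum()
        corrected = correct_m1_artifact(
            MIDVector("x", observed, is_fractional=True), ArtifactModel(r)
        )
        np.testing.assert_allclose(corrected.values, true, atol=1e-10)

    def test_forward_helper_matches_oracle(self, rng):
        true = rng.dirichlet(np.ones(5))
        mid = forward_m1_artifact(MIDVector("x", true, is_fractional=True), ArtifactModel(0.3))
        expected = forward_convolve(true, 0.3)
        np.testing.assert_allclose(mid.values, expected / expected.sum(), atol=1e-12)


class TestNetLabelling:
    def test_self_subtraction_is_zero(self):
        res = LabellingResult("proline", (0.9, 0.1))
        net = net_labelling(res, res)
        assert net.net == pytest.approx((0.0, 0.0), abs=1e-12)

    def test_direct_subtraction(self):
        sample = LabellingResult("proline", (0.90, 0.10))
        t0 = LabellingResult("proline", (0.99, 0.01))
        net = net_labelling(sample, t0)
        assert net.net == pytest.approx((-0.09, 0.09))
        assert sum(net.net) == pytest.approx(0.0, abs=1e-12)

    def test_amino_acid_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            net_labelling(
                LabellingResult("proline", (1.0, 0.0)),
                LabellingResult("glutamate", (1.0, 0.0)),
            )

    @given(
        st.lists(st.floats(min_value=0.01, max_value=1.0), min_size=2, max_size=5),
        st.lists(st.floats(min_value=0.01, max_value=1.0), min_size=2, max_size=5),
    )
    @settings(max_examples=200, deadline=None)
    def test_net_always_sums_to_zero(self, a, b):
        n = min(len(a), len(b))
        fa = np.asarray(a[:n]) / sum(a[:n])
        fb = np.asarray(b[:n]) / sum(b[:n])
        net = net_labelling(LabellingResult("x", tuple(fa)), LabellingResult("x", tuple(fb)))
        assert sum(net.net) == pytest.approx(0.0, abs=1e-9)


class TestMeanLabelledAtoms:
    @pytest.mark.parametrize(
        "net, expected",
        [
            ([-0.10, 0.10], 0.10),
            ([0.0, 0.0], 0.0),
            ([-0.15, 0.05, 0.10], 0.25),  # 1*0.05 + 2*0.10
        ],
    )
    def test_weighted_sum(self, net, expected):
        assert mean_labelled_atoms(net) == pytest.approx(expected)

    def test_bounded_by_n_atoms_for_valid_fraction_pairs(self, rng):
        for _ in range(50):
            n_atoms = rng.integers(1, 4)
            fa = rng.dirichlet(np.ones(n_atoms + 1))
            fb = rng.dirichlet(np.ones(n_atoms + 1))
            mla = mean_labelled_atoms(fa - fb)
            assert abs(mla) <= n_atoms + 1e-12


def test_full_chain_monotone_in_enrichment():
    """Higher true per-atom enrichment => higher recovered mean labelled atoms."""
    from scipy.stats import binom

    r = 0.2
    t0_mid = binom.pmf(np.arange(3), 2, 0.003663)
    t0_obs = forward_convolve(t0_mid, r)
    t0_res = fractional_labelling(
        correct_m1_artifact(MIDVector("x", t0_obs / t0_obs.sum(), is_fractional=True), ArtifactModel(r))
    )
    recovered = []
    for p in [0.05, 0.1, 0.3, 0.6, 0.9]:
        mid = binom.pmf(np.arange(3), 2, p)
        obs = forward_convolve(mid, r)
        res = fractional_labelling(
            correct_m1_artifact(MIDVector("x", obs / obs.sum(), is_fractional=True), ArtifactModel(r))
        )
        recovered.append(net_labelling(res, t0_res).mean_labelled_atoms)
    assert np.all(np.diff(recovered) > 0)
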