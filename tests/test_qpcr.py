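"""qPCR chain: primer efficiency, relative expression, geNorm, fold changes."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from leaftracer.qpcr import (
    PrimerSpec,
    QPCRExperiment,
    fold_change_ratio,
    genorm_stability,
    primer_efficiency,
    relative_expression,
)


def series_from_slope(slope, intercept=25.0, points=(0.0, -1.0, -2.0, -3.0)):
    return [(x, intercept + slope * x) for x in points]


class TestPrimerEfficiency:
    def test_perfect_doubling(self):
        spec = primer_efficiency("g", series_from_slope(-np.log2(10) * 1))  # -3.3219
        assert spec.efficiency == pytest.approx(2.0, abs=1e-9)

    def test_closed_form_slope(self):
        spec = primer_efficiency("g", series_from_slope(-3.5))
        assert spec.efficiency == pytest.approx(10 ** (1 / 3.5), abs=1e-9)

    def test_two_points_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            primer_efficiency("g", [(0, 25), (-1, 28)])

    def test_narrow_span_rejected(self):
        with pytest.raises(ValueError, match="2 log10"):
            primer_efficiency("g", [(0, 25), (-0.5, 27), (-1.0, 28)])

    def test_inverted_series_rejected(self):
        with pytest.raises(ValueError, match="not negative"):
            primer_efficiency("g", series_from_slope(+3.3))

    def test_out_of_range_efficiency_rejected(self):
        with pytest.raises(ValueError, match="efficiency"):
            primer_efficiency("g", series_from_slope(-1.0))  # E = 10


class TestRelativeExpression:
    E2 = PrimerSpec("t", 2.0)
    REF = [(20.0, PrimerSpec("r1", 2.0)), (20.0, PrimerSpec("r2", 2.0))]

    def test_symmetric_case(self):
        assert relative_expression(20.0, self.E2, self.REF) == pytest.approx(1.0)

    def test_one_cycle_later_is_half(self):
        assert relative_expression(21.0, self.E2, self.REF) == pytest.approx(0.5)

    def test_uniform_shift_invariance(self):
        base = relative_expression(23.0, self.E2, [(20.0, PrimerSpec("r", 2.0)), (26.0, PrimerSpec("r2", 2.0))])
        shifted = relative_expression(24.0, self.E2, [(21.0, PrimerSpec("r", 2.0)), (27.0, PrimerSpec("r2", 2.0))])
        assert shifted == pytest.approx(base, rel=1e-12)

    def test_no_reference_rejected(self):
        with pytest.raises(ValueError, match="reference"):
            relative_expression(20.0, self.E2, [])

    @given(
        st.floats(min_value=10, max_value=40),
        st.floats(min_value=10, max_value=40),
        st.floats(min_value=10, max_value=40),
        st.floats(min_value=-5, max_value=5),
    )
    @settings(max_examples=100, deadline=None)
    def test_shift_invariance_property(self, cq_t, cq_r1, cq_r2, shift):
        e = PrimerSpec("x", 1.9)
        refs = lambda d: [(cq_r1 + d, e), (cq_r2 + d, e)]
        a = relative_expression(cq_t, e, refs(0.0))
        b = relative_expression(cq_t + shift, e, refs(shift))
        assert b == pytest.approx(a, rel=1e-9)


class TestGeNorm:
    def test_proportional_genes_have_zero_m(self, rng):
        base = rng.uniform(1, 10, size=6)
        expr = pd.DataFrame({"g1": base, "g2": 2 * base, "g3": 0.5 * base})
        res = genorm_stability(expr)
        assert np.allclose(res["M"], 0.0)

    def test_noisy_gene_ranks_last(self, rng):
        base = rng.uniform(1, 10, size=8)
        expr = pd.DataFrame(
            {
                "stable1": base,
                "stable2": 3 * base,
                "noisy": base * rng.lognormal(0, 0.8, size=8),
            }
        )
        res = genorm_stability(expr)
        assert res.loc[res["rank"] == res["rank"].max(), "gene"].item() == "noisy"
        assert res.loc[res["gene"] == "noisy", "exclusion_order"].item() == 1

    def test_two_genes_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            genorm_stability(pd.DataFrame({"a": [1, 2], "b": [2, 4]}))

    def test_nonpositive_expression_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            genorm_stability(pd.DataFrame({"a": [1, 0], "b": [2, 4], "c": [1, 1]}))

    def test_hand_computed_m_values(self):
        # 2 samples, 3 genes; sd(ddof=1) of log2 ratios computed by hand
        expr = pd.DataFrame({"a": [1.0, 2.0], "b": [1.0, 1.0], "c": [4.0, 4.0]})
        # log2(a/b): [0,1] sd = sqrt(1/2); log2(a/c): [-2,-1] sd = sqrt(1/2)
        # log2(b/c): [-2,-2] sd = 0
        res = genorm_stability(expr).set_index("gene")
        s = np.sqrt(0.5)
        assert res.loc["a", "M"] == pytest.approx((s + s) / 2)
        assert res.loc["b", "M"] == pytest.approx(s / 2)
        assert res.loc["c", "M"] == pytest.approx(s / 2)

    def test_invariant_to_per_sample_scaling(self, rng):
        expr = pd.DataFrame(rng.lognormal(0, 0.5, size=(6, 4)), columns=list("abcd"))
        scaled = expr.mul(rng.uniform(0.1, 10, size=6), axis=0)
        pd.testing.assert_frame_equal(
            genorm_stability(expr), genorm_stability(scaled), check_exact=False
        )

    def test_permutation_equivariance(self, rng):
        expr = pd.DataFrame(rng.lognormal(0, 0.5, size=(5, 4)), columns=list("abcd"))
        perm = expr[["c", "a", "d", "b"]]
        res1 = genorm_stability(expr).set_index("gene")["M"]
        res2 = genorm_stability(perm).set_index("gene")["M"]
        pd.testing.assert_series_equal(res1.sort_index(), res2.sort_index())


class TestFoldChangeRatio:
    def test_identical_dynamics(self):
        _, _, log2r = fold_change_ratio(3.0, 1.5, 2.0, 1.0)
        assert log2r == pytest.approx(0.0)

    @pytest.mark.parametrize(
        "fc_t, fc_c, expected",
        [((8.0, 1.0), (1.0, 1.0), 3.0), ((1.0, 1.0), (4.0, 1.0), -2.0)],
    )
    def test_log2_ratios(self, fc_t, fc_c, expected):
        _, _, log2r = fold_change_ratio(fc_t[0], fc_t[1], fc_c[0], fc_c[1])
        assert log2r == pytest.approx(expected)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            fold_change_ratio(0.0, 1.0, 1.0, 1.0)

    @given(st.floats(min_value=1e-3, max_value=1e3), st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=100, deadline=None)
    def test_no_change_property(self, a, b):
        assert fold_change_ratio(a, a, b, b)[2] == pytest.approx(0.0, abs=1e-9)


class TestQPCRExperiment:
    def _plate(self):
        primers = {
            "UBQ11": PrimerSpec("UBQ11", 2.0),
            "RibS3": PrimerSpec("RibS3", 2.0),
            "target": PrimerSpec("target", 2.0),
        }
        cq = pd.DataFrame(
            [
                ("s1", "UBQ11", 1, 20.0),
                ("s1", "UBQ11", 2, 20.2),
                ("s1", "RibS3", 1, 22.0),
                ("s1", "RibS3", 2, 21.8),
                ("s1", "target", 1, 24.0),
                ("s1", "target", 2, 24.0),
                ("s2", "UBQ11", 1, 20.0),
                ("s2", "RibS3", 1, 22.0),
                ("s2", "target", 1, np.nan),  # undetected, not Cq=40
            ],
            columns=["sample_id", "gene", "replicate", "Cq"],
        )
        return cq, primers

    def test_technical_replicates_averaged(self):
        cq, primers = self._plate()
        res = QPCRExperiment(cq, primers).fit()
        got = res.table.set_index("sample_id").loc["s1", "relative_expression"]
        # mean Cq: UBQ11 20.1, RibS3 21.9, target 24.0; geomean ref Cq -> 21.0
        assert got == pytest.approx(2.0 ** (21.0 - 24.0))

    def test_undetected_target_reported_as_missing(self):
        cq, primers = self._plate()
        res = QPCRExperiment(cq, primers).fit()
        s2 = res.table.set_index("sample_id").loc["s2"]
        assert np.isnan(s2["relative_expression"])

    def test_missing_reference_excludes_sample(self, caplog):
        cq, primers = self._plate()
        cq = cq[~((cq.sample_id == "s2") & (cq.gene == "RibS3"))]
        with caplog.at_level("WARNING"):
            res = QPCRExperiment(cq, primers).fit()
        assert "s2" not in set(res.table["sample_id"])
        assert "excluded" in caplog.text


def test_full_qpcr_chain_recovers_configured_log2_fc(config):
    """Simulated plates invert to the configured log2 FC ratios within noise."""
    from leaftracer.qpcr import primer_efficiency
    from leaftracer.simulate import simulate_qpcr_plate

    tables = simulate_qpcr_plate(config, seed=3)
    primers = {
        g: primer_efficiency(g, list(zip(grp["log10_input"], grp["Cq"])))
        for g, grp in tables["dilution_series"].groupby("gene")
    }
    exp = QPCRExperiment(tables["cq"], primers, metadata=tables["metadata"])
    fc = exp.fit().fold_change_table(t0="T0", t1="T1").set_index("gene")

    truth = {"P5CS1c": 7.0, "P5CS1a": 2.0, "ProDH1a": -2.0}
    # noise envelope: Cq noise sd 0.2 on 4 cells of duplicate wells averaged
    # over n=3 samples, plus biological jitter sd 0.05 log2 per cell, plus
    # efficiency-estimate error; 3x the propagated sd
    cell_sd = np.sqrt((0.2 / np.sqrt(2)) ** 2 + 0.05**2) / np.sqrt(config.n_replicates)
    tol = 3 * 2 * cell_sd + 0.3  # 4 cells pairwise, efficiency-slope term
    for gene, expected in truth.items():
        assert fc.loc[gene, "log2_fc_ratio"] == pytest.approx(expected, abs=tol)
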