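"""Symmetry metrics, symmetry-binned tests, GLM and motif positioning."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from meiorec.config import SimConfig
from meiorec.hotspots import (
    average_homologous_heat,
    b6_ratio,
    b6_ratio_background_corrected,
    bin_by_symmetry,
    event_motif_distance,
    glm_symmetry_vs_density,
    homologous_heat,
    initiation_fraction_less_bound,
    motif_disruption_fraction,
    observed_vs_expected,
    symmetry,
)
from meiorec.simulate import simulate_hotspots, simulate_snp_map


class TestRatios:
    @pytest.mark.parametrize(
        "b6,cast,expected", [(50, 50, 0.5), (30, 10, 0.75)]
    )
    def test_ratio_values(self, b6, cast, expected):
        assert b6_ratio(b6, cast) == pytest.approx(expected)

    def test_below_threshold_undefined(self):
        assert np.isnan(b6_ratio(9, 0))
        assert not np.isnan(b6_ratio(10, 0))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            b6_ratio(-1, 5)

    def test_background_correction_shifts_ratio(self):
        x = b6_ratio_background_corrected(60, 40, 20, 0, factor=1.0)
        assert x == pytest.approx(0.5)

    @pytest.mark.parametrize("x,expected", [(0.5, 1.0), (1.0, 0.0), (0.9, 0.36)])
    def test_symmetry_values(self, x, expected):
        assert symmetry(x) == pytest.approx(expected)

    def test_symmetry_domain(self):
        with pytest.raises(ValueError):
            symmetry(1.2)

    @settings(deadline=None, max_examples=50)
    @given(st.floats(min_value=0.0, max_value=1.0))
    def test_symmetry_label_invariance(self, x):
        assert symmetry(x) == pytest.approx(symmetry(1.0 - x))

    def test_homologous_heat_template_convention(self):
        # DSB on CAST repairs off the B6 homologue (fraction x)
        assert homologous_heat(0.8, 10.0, "CAST") == pytest.approx(8.0)
        assert homologous_heat(0.8, 10.0, "B6") == pytest.approx(2.0)
        assert homologous_heat(0.5, 10.0, "B6") == pytest.approx(5.0)

    def test_average_homologous_heat(self):
        assert average_homologous_heat(0.5, 10.0) == pytest.approx(5.0)
        assert average_homologous_heat(1.0, 10.0) == pytest.approx(0.0)
        # equals initiation-weighted mean of the two homologous heats
        x, h = 0.3, 7.0
        weighted = x * homologous_heat(x, h, "B6") + (1 - x) * homologous_heat(
            x, h, "CAST"
        )
        assert average_homologous_heat(x, h) == pytest.approx(weighted)


def _hotspot_frame(n=600, seed=0, sym_spread=True):
    rng = np.random.default_rng(seed)
    x = rng.uniform(0.02, 0.98, n) if sym_spread else np.full(n, 0.5)
    return pd.DataFrame(
        {
            "hotspot_id": np.arange(n),
            "chrom": "chr1",
            "center": np.arange(n) * 10_000 + 5_000,
            "dmc1_total": rng.poisson(100, n) + 1,
            "h3k4_total": rng.poisson(80, n) + 1,
            "x": x,
            "x_dmc1": x,
            "x_h3k4": x,
            "symmetry": 4 * x * (1 - x),
        }
    )


class TestSymmetryBinning:
    def test_equal_heats_uniform_symmetry_balanced_bins(self):
        hs = _hotspot_frame(n=900)
        hs["dmc1_total"] = 100
        binned = bin_by_symmetry(hs)
        counts = binned["sym_bin"].value_counts()
        assert counts.max() - counts.min() < 30

    def test_single_heavy_hotspot_saturates_a_bin(self):
        hs = _hotspot_frame(n=30)
        hs.loc[0, "dmc1_total"] = 10_000
        hs.loc[0, "symmetry"] = 0.01  # most asymmetric
        binned = bin_by_symmetry(hs)
        asym = binned[binned["sym_bin"] == "asymmetric"]
        assert len(asym) <= 3

    def test_degenerate_symmetry_rejected(self):
        hs = _hotspot_frame(sym_spread=False)
        hs["symmetry"] = 1.0
        with pytest.raises(ValueError, match="degenerate"):
            bin_by_symmetry(hs)


def _events_from(hs, n, rng, depletion=None):
    """Draw events proportional to enrichment, optionally depleting
    asymmetric hotspots by the given factor."""
    w = hs["dmc1_total"].to_numpy(dtype=float)
    if depletion is not None:
        w = w * np.where(hs["symmetry"] < 0.4, depletion, 1.0)
    pick = rng.choice(hs["hotspot_id"].to_numpy(), size=n, p=w / w.sum())
    return pd.DataFrame({"hotspot_id": pick, "kind": "NCO"})


class TestObservedVsExpected:
    def test_null_events_show_no_depletion(self):
        rng = np.random.default_rng(0)
        hs = bin_by_symmetry(_hotspot_frame())
        events = _events_from(hs, 900, rng)
        res = observed_vs_expected(events, hs)
        assert res.pvalue["NCO"] > 0.01
        assert res.expected_fraction.sum() == pytest.approx(1.0)
        assert res.observed_fraction["NCO"].sum() == pytest.approx(1.0)

    def test_asymmetric_depletion_detected(self):
        rng = np.random.default_rng(1)
        hs = bin_by_symmetry(_hotspot_frame())
        events = _events_from(hs, 800, rng, depletion=0.4)
        res = observed_vs_expected(events, hs)
        i = res.bin_labels.index("asymmetric")
        assert res.observed_fraction["NCO"][i] < res.expected_fraction[i]
        assert res.pvalue["NCO"] < 0.01

    def test_null_pvalues_roughly_uniform(self):
        from scipy import stats

        hs = bin_by_symmetry(_hotspot_frame())
        ps = []
        for s in range(60):
            rng = np.random.default_rng(1000 + s)
            events = _events_from(hs, 600, rng)
            ps.append(observed_vs_expected(events, hs).pvalue["NCO"])
        d = stats.kstest(ps, "uniform").statistic
        assert d < 0.15

    def test_single_bin_rejected(self):
        hs = bin_by_symmetry(_hotspot_frame(), n_bins=1)
        with pytest.raises(ValueError):
            observed_vs_expected(
                pd.DataFrame({"hotspot_id": [0], "kind": ["NCO"]}), hs
            )


class TestInitiationFraction:
    def test_symmetric_hotspots_near_half(self):
        rng = np.random.default_rng(0)
        hs = _hotspot_frame(n=200, seed=1)
        hs["x_h3k4"] = rng.uniform(0.45, 0.499, len(hs))
        hs["x_dmc1"] = hs["x_h3k4"]
        hs["sym_bin"] = "symmetric"
        ev = pd.DataFrame(
            {
                "hotspot_id": rng.choice(hs["hotspot_id"], 2000),
                "recipient": rng.choice(["B6", "CAST"], 2000),
                "kind": "NCO",
            }
        )
        out = initiation_fraction_less_bound(ev, hs, rng=rng)
        assert abs(out["observed_frac"].iloc[0] - 0.5) < 0.05
        assert abs(out["h3k4_lessbound_frac"].iloc[0] - 0.475) < 0.01

    def test_no_events_rejected(self):
        hs = _hotspot_frame(n=10)
        hs["sym_bin"] = "symmetric"
        with pytest.raises(ValueError):
            initiation_fraction_less_bound(
                pd.DataFrame(columns=["hotspot_id", "recipient", "kind"]), hs
            )


class TestMotifDisruption:
    def test_generator_disruption_recovered_in_extreme_bins(self):
        cfg = SimConfig(
            chrom_lengths=(30_000_000,), n_hotspots=2000, frac_asymmetric=0.5
        )
        rng = np.random.default_rng(4)
        sm = simulate_snp_map(cfg, rng)
        hs = simulate_hotspots(cfg, sm, rng)
        from meiorec.simulate import simulate_chip_counts

        chip = simulate_chip_counts(hs, cfg, rng)
        merged = hs.merge(chip.drop(columns=["chrom", "center"]), on="hotspot_id")
        out = motif_disruption_fraction(merged, sm)
        extreme = out.iloc[[0, -1]]["fraction_disrupted"].mean()
        middle = out.iloc[2]["fraction_disrupted"]
        assert extreme > 0.9
        assert middle < extreme

    def test_variant_inside_counted_outside_not(self):
        hs = pd.DataFrame(
            {
                "hotspot_id": [0, 1],
                "chrom": ["chr1", "chr1"],
                "motif_posterior": [1.0, 1.0],
                "dmc1_b6": [30, 30],
                "dmc1_cast": [30, 30],
                "motif_start": [100, 1000],
                "motif_end": [130, 1030],
            }
        )

        class _Map:
            chroms = ["chr1"]
            pos = {"chr1": np.array([115, 1031])}  # inside #0, 1 bp out of #1

        out = motif_disruption_fraction(hs, _Map(), bins=(0.0, 1.0))
        assert out["fraction_disrupted"].iloc[0] == pytest.approx(0.5)


class TestGlm:
    def _snp_map(self, rng, length=30_000_000):
        cfg = SimConfig(chrom_lengths=(length,), n_hotspots=100)
        return simulate_snp_map(cfg, rng)

    def _hotspots(self, rng, n=3000, length=30_000_000):
        hs = _hotspot_frame(n=n, seed=3)
        hs["center"] = np.sort(rng.integers(5_000, length - 5_000, n))
        hs["motif_center"] = hs["center"]
        return hs

    def test_symmetry_driven_events_detected(self):
        rng = np.random.default_rng(0)
        sm = self._snp_map(rng)
        hs = self._hotspots(rng)
        logit = -2.5 + 2.5 * hs["symmetry"].to_numpy()
        hs["has_event"] = rng.random(len(hs)) < 1 / (1 + np.exp(-logit))
        table, res, separated = glm_symmetry_vs_density(hs, sm)
        assert not separated
        assert table.loc["symmetry_dmc1", "pvalue"] < 0.05
        assert all(
            table.loc[f"snp_density_{w}", "pvalue"] > 0.05 for w in (100, 500)
        )

    def test_constant_response_rejected(self):
        rng = np.random.default_rng(1)
        sm = self._snp_map(rng, 5_000_000)
        hs = self._hotspots(rng, n=200, length=5_000_000)
        hs["has_event"] = True
        with pytest.raises(ValueError):
            glm_symmetry_vs_density(hs, sm)

    def test_detection_weight_resampling_runs(self):
        rng = np.random.default_rng(2)
        sm = self._snp_map(rng, 10_000_000)
        hs = self._hotspots(rng, n=800, length=10_000_000)
        hs["has_event"] = rng.random(len(hs)) < 0.3
        w = pd.Series(rng.uniform(0.5, 1.5, len(hs)), index=hs["hotspot_id"])
        table, _, _ = glm_symmetry_vs_density(
            hs, sm, detection_weights=w, rng=rng
        )
        assert "symmetry_dmc1" in table.index


class TestEventMotifDistance:
    def test_marker_inside_motif_distance_zero(self):
        hs = pd.DataFrame(
            {
                "hotspot_id": [0],
                "chrom": ["chr1"],
                "motif_center": [1000],
                "motif_start": [985],
                "motif_end": [1015],
            }
        )

        class _Ev:
            chrom = "chr1"
            positions = np.array([1010])
            midpoint = 1010.0

        class _Map:
            chroms = ["chr1"]
            pos = {"chr1": np.arange(0, 3000, 170)}

        out = event_motif_distance([_Ev()], hs, _Map())
        assert out["distance_nearest_marker"][0] == 0.0
        assert out["distance_tract_midpoint"][0] == 10.0

    def test_midpoint_variant_centered_tract(self):
        hs = pd.DataFrame(
            {
                "hotspot_id": [0],
                "chrom": ["chr1"],
                "motif_center": [1000],
                "motif_start": [990],
                "motif_end": [1010],
            }
        )

        class _Ev:
            chrom = "chr1"
            positions = np.array([980, 1020])
            midpoint = 1000.0

        class _Map:
            chroms = ["chr1"]
            pos = {"chr1": np.arange(0, 3000, 170)}

        out = event_motif_distance([_Ev()], hs, _Map())
        assert out["distance_tract_midpoint"][0] == 0.0

    def test_no_motifs_rejected(self):
        with pytest.raises(ValueError):
            event_motif_distance([], pd.DataFrame(), None)
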