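"""Involvement summaries, percent asymmetry and distance-to-margin logic."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fwetract import stats as cs
from tests.conftest import make_profile


class TestBilateralGroup:
    def test_mean_of_both_hemispheres(self):
        value, single = cs.bilateral_group(0.2, 0.4)
        assert value == pytest.approx(0.3)
        assert not single

    def test_idempotent_on_equal_values(self):
        value, _ = cs.bilateral_group(0.7, 0.7)
        assert value == pytest.approx(0.7)

    def test_single_hemisphere_flagged(self):
        value, single = cs.bilateral_group(0.1, None)
        assert value == pytest.approx(0.1)
        assert single

    def test_both_missing(self):
        value, single = cs.bilateral_group(None, float("nan"))
        assert np.isnan(value) and single


class TestSubjectInvolvement:
    def test_no_node_exceeds_threshold(self):
        profiles = {"ILF/left": make_profile(combined=np.full(100, 0.04)),
                    "ILF/right": make_profile(hemisphere="right",
                                              combined=np.full(100, 0.05))}
        (summary,) = [s for s in cs.subject_involvement(profiles, 5.0)
                      if s.compartment == "combined"]
        assert not summary.involved
        assert summary.proportion_involved == 0.0
        assert summary.n_nodes == 200

    def test_single_involved_node_of_200(self):
        left = np.zeros(100)
        left[42] = 0.06
        profiles = {"ILF/left": make_profile(combined=left),
                    "ILF/right": make_profile(hemisphere="right")}
        (summary,) = [s for s in cs.subject_involvement(profiles, 5.0)
                      if s.compartment == "combined"]
        assert summary.involved
        assert summary.proportion_involved == pytest.approx(1 / 200)

    def test_pooled_proportion_over_hemispheres(self):
        left = np.zeros(100)
        left[:10] = 0.5
        right = np.zeros(100)
        right[:30] = 0.5
        profiles = {"ILF/left": make_profile(combined=left),
                    "ILF/right": make_profile(hemisphere="right",
                                              combined=right)}
        (summary,) = [s for s in cs.subject_involvement(profiles, 5.0)
                      if s.compartment == "combined"]
        assert summary.proportion_involved == pytest.approx(40 / 200)

    def test_brute_force_recount(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            thr = float(rng.uniform(1, 15))
            fracs = {"enhancing": rng.random(100) * 0.2,
                     "necrotic": rng.random(100) * 0.2,
                     "edema": rng.random(100) * 0.2}
            fracs["combined"] = np.minimum(
                fracs["enhancing"] + fracs["necrotic"] + fracs["edema"], 1.0)
            profiles = {"X/left": make_profile("X", "left", **fracs)}
            for s in cs.subject_involvement(profiles, thr):
                arr = fracs[s.compartment]
                expected = sum(1 for v in arr if v > thr / 100)
                assert s.proportion_involved == pytest.approx(expected / 100)
                assert s.involved == (expected > 0)


class TestThresholdSweep:
    def test_stacks_one_summary_set_per_threshold(self):
        profiles = {"ILF/left": make_profile()}
        table = cs.threshold_sweep(profiles, [1, 5, 15])
        assert sorted(table["threshold"].unique()) == [1, 5, 15]
        assert (table["proportion_involved"] == 0).all()

    def test_proportions_non_increasing_in_threshold(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            c = rng.random(100) * 0.3
            profiles = {"X/left": make_profile("X", combined=c, edema=c)}
            table = cs.threshold_sweep(profiles, list(range(1, 16)))
            for _, grp in table.groupby(["tract", "compartment"]):
                props = grp.sort_values("threshold")["proportion_involved"]
                assert (np.diff(props.to_numpy()) <= 1e-12).all()

    def test_threshold_out_of_range(self):
        with pytest.raises(ValueError):
            cs.threshold_sweep({"X/left": make_profile("X")}, [150])


class TestContralateralMean:
    def test_constant_value(self):
        profiles = {"A/right": make_profile(
            "A", "right", metrics={"fw_fa": np.full(100, 0.44)})}
        assert cs.contralateral_mean(profiles, "left", "fw_fa") == \
            pytest.approx(0.44)

    def test_pooled_mean_of_two_equal_sized_tracts(self):
        profiles = {
            "A/right": make_profile("A", "right",
                                    metrics={"m": np.full(100, 2.0)}),
            "B/right": make_profile("B", "right",
                                    metrics={"m": np.full(100, 6.0)}),
            "A/left": make_profile("A", "left",
                                   metrics={"m": np.full(100, 99.0)}),
        }
        assert cs.contralateral_mean(profiles, "left", "m") == pytest.approx(4.0)

    def test_missing_nodes_excluded(self):
        vals = np.full(100, 1.0)
        vals[[3, 50, 97]] = np.nan
        other = np.full(100, 3.0)
        profiles = {"A/right": make_profile("A", "right", metrics={"m": vals}),
                    "B/right": make_profile("B", "right",
                                            metrics={"m": other})}
        pooled = np.concatenate([vals, other])
        expected = np.nansum(pooled) / np.isfinite(pooled).sum()
        assert cs.contralateral_mean(profiles, "left", "m") == \
            pytest.approx(expected)

    def test_no_contralateral_profiles(self):
        profiles = {"A/left": make_profile("A", "left",
                                           metrics={"m": np.ones(100)})}
        assert np.isnan(cs.contralateral_mean(profiles, "left", "m"))


class TestNodeAsymmetry:
    @pytest.mark.parametrize("ipsi, contra, expected", [
        (0.5, 0.5, 0.0),
        (0.6, 0.4, 40.0),
        (0.4, 0.6, -40.0),
    ])
    def test_printed_formula(self, ipsi, contra, expected):
        assert cs.node_asymmetry(ipsi, contra) == pytest.approx(expected)

    def test_zero_sum_undefined(self):
        assert np.isnan(cs.node_asymmetry(0.0, 0.0))

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(st.floats(1e-6, 1e3), st.floats(1e-6, 1e3),
           st.floats(1e-3, 1e3))
    def test_antisymmetry_scale_invariance_bounds(self, a, b, c):
        asym = cs.node_asymmetry(a, b)
        assert asym == pytest.approx(-cs.node_asymmetry(b, a))
        assert cs.node_asymmetry(c * a, c * b) == pytest.approx(asym, rel=1e-9)
        assert -200.0 <= asym <= 200.0
        assert cs.node_asymmetry(a, a) == 0.0


class TestEligibleNodePairs:
    def test_all_nodes_eligible_when_uninvolved(self):
        ipsi = make_profile(metrics={"m": np.ones(100)})
        contra = make_profile(hemisphere="right",
                              metrics={"m": np.ones(100)})
        idx = cs.eligible_node_pairs(ipsi, contra, "m", 5.0)
        np.testing.assert_array_equal(idx, np.arange(100))

    def test_exactly_at_threshold_excluded(self):
        combined = np.zeros(100)
        combined[7] = 0.05  # exactly 5 percent: strictly-below rule drops it
        ipsi = make_profile(combined=combined, metrics={"m": np.ones(100)})
        contra = make_profile(hemisphere="right",
                              metrics={"m": np.ones(100)})
        assert 7 not in cs.eligible_node_pairs(ipsi, contra, "m", 5.0)

    def test_missing_contralateral_node_excluded(self):
        vals = np.ones(100)
        vals[13] = np.nan
        ipsi = make_profile(metrics={"m": np.ones(100)})
        contra = make_profile(hemisphere="right", metrics={"m": vals})
        assert 13 not in cs.eligible_node_pairs(ipsi, contra, "m", 5.0)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            cs.eligible_node_pairs(
                make_profile(n_nodes=100, metrics={"m": np.ones(100)}),
                make_profile(hemisphere="right", n_nodes=50,
                             metrics={"m": np.ones(50)}), "m")


def _paired_subject(tract_values):
    """profiles dict with given ipsi (left) node values, contra all 1.0."""
    profiles = {}
    for tract, vals in tract_values.items():
        vals = np.asarray(vals, dtype=float)
        profiles[f"{tract}/left"] = make_profile(
            tract, "left", n_nodes=len(vals), metrics={"m": vals})
        profiles[f"{tract}/right"] = make_profile(
            tract, "right", n_nodes=len(vals),
            metrics={"m": np.ones(len(vals))})
    return profiles


class TestWholeTractAsymmetry:
    def test_symmetric_subject_is_exactly_zero(self):
        profiles = _paired_subject({"A": np.ones(100), "B": np.ones(100)})
        assert cs.whole_tract_asymmetry(profiles, "left", "m") == 0.0

    def test_opposite_tracts_cancel(self):
        # per-tract means +10 and -10 -> two-stage mean 0
        profiles = {}
        for tract, asym in (("A", 10.0), ("B", -10.0)):
            # choose ipsi so that (i - 1)/((i + 1)/2)*100 == asym
            ipsi = (200 + asym) / (200 - asym)
            profiles.update(_paired_subject({tract: np.full(100, ipsi)}))
        val = cs.whole_tract_asymmetry(profiles, "left", "m")
        assert val == pytest.approx(0.0, abs=1e-9)

    def test_two_stage_vs_pooled_counterexample(self):
        # tract A: 2 eligible nodes at +10% each; tract B: 50 at +1% each
        def ipsi_for(asym):
            return (200 + asym) / (200 - asym)

        a_vals = np.full(100, np.nan)
        a_vals[:2] = ipsi_for(10.0)
        b_vals = np.full(100, np.nan)
        b_vals[:50] = ipsi_for(1.0)
        profiles = _paired_subject({"A": a_vals, "B": b_vals})
        two_stage = cs.whole_tract_asymmetry(profiles, "left", "m")
        pooled = cs.whole_tract_asymmetry(profiles, "left", "m", pooled=True)
        assert two_stage == pytest.approx((10.0 + 1.0) / 2)
        expected_pooled = (2 * 10.0 + 50 * 1.0) / 52
        assert pooled == pytest.approx(expected_pooled)
        assert abs(two_stage - pooled) > 1.0

    def test_no_eligible_nodes_is_missing(self):
        profiles = _paired_subject({"A": np.ones(100)})
        profiles["A/left"].involvement["combined"][:] = 1.0
        assert np.isnan(cs.whole_tract_asymmetry(profiles, "left", "m"))


class TestNodeDistanceToMargin:
    def test_exhaustive_examples(self):
        combined = np.zeros(100)
        combined[39:60] = 0.5  # involved nodes 40..60 in 1-based indexing
        prof = make_profile(combined=combined)
        dist = cs.node_distance_to_margin(prof, 5.0)
        assert dist[34] == 5    # node 35 (1-based) -> distance 5
        assert dist[9] == 30    # node 10 -> distance 30
        assert (dist[39:60] == 0).all()

    def test_empty_involved_set_undefined(self):
        dist = cs.node_distance_to_margin(make_profile(), 5.0)
        assert np.isnan(dist).all()

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(77)
        for _ in range(50):
            n = int(rng.integers(5, 200))
            combined = (rng.random(n) < 0.2) * rng.uniform(0.06, 1.0)
            prof = make_profile(n_nodes=n, combined=combined,
                                metrics={})
            dist = cs.node_distance_to_margin(prof, 5.0)
            involved = [i for i in range(n) if combined[i] > 0.05]
            for i in range(n):
                if not involved:
                    assert np.isnan(dist[i])
                else:
                    assert dist[i] == min(abs(i - j) for j in involved)


class TestDistanceBinnedAsymmetry:
    def _profiles_with_margin(self, n=100):
        combined = np.zeros(n)
        combined[0] = 0.5  # margin at node 1; distance of node k = k-1
        ipsi = np.full(n, 1.5)
        profiles = _paired_subject({"A": ipsi})
        profiles["A/left"].involvement["combined"] = combined
        return profiles

    def test_bin_edges_match_printed_segments(self):
        profiles = self._profiles_with_margin()
        # make the asymmetry equal to the node's 0-based distance so each
        # bin mean identifies which distances were pooled
        dist = np.arange(100, dtype=float)
        ipsi = (200 + dist) / (200 - dist)
        profiles["A/left"].metrics["m"] = ipsi
        out = cs.distance_binned_asymmetry(profiles, "left", "m", 5.0)
        assert out["1–5"] == pytest.approx(np.mean([1, 2, 3, 4, 5]))
        assert out["6–10"] == pytest.approx(np.mean([6, 7, 8, 9, 10]))
        assert out["≥21"] == pytest.approx(np.mean(np.arange(21, 100)))

    def test_empty_segments_are_missing(self):
        profiles = self._profiles_with_margin(n=6)
        out = cs.distance_binned_asymmetry(profiles, "left", "m", 5.0)
        assert np.isfinite(out["1–5"])
        for seg in ("6–10", "11–15", "16–20", "≥21"):
            assert np.isnan(out[seg])

    def test_overlapping_bins_rejected(self):
        profiles = self._profiles_with_margin()
        with pytest.raises(ValueError):
            cs.distance_binned_asymmetry(profiles, "left", "m", 5.0,
                                         bins=((1, 5), (5, 10)))

    def test_tract_without_margin_excluded(self):
        profiles = _paired_subject({"A": np.full(100, 1.5)})
        out = cs.distance_binned_asymmetry(profiles, "left", "m", 5.0)
        assert all(np.isnan(v) for v in out.values())
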