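import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vlptools import (
    CellSet,
    QpcrMeasurement,
    SpatialProfile,
    colocalize,
    normalize_to_wildtype,
    percent_input,
    profile_bins,
    ratio_to_dapi,
    read_activity_table,
)
from oracles import coloc_brute, profile_bins_brute

META = {"BLA": ("Basolateral amygdala", "AMY"),
        "LA": ("Lateral amygdala", "AMY"),
        "PIR": ("Piriform cortex", "CTX")}


class TestReadActivityTable:
    CSV = ("animal_id,group,BLA,LA,PIR\n"
           "wt1,WT,100,200,300\n"
           "wt2,WT,110,,290\n"
           "ko1,KO,50,60,70\n"
           "ko2,KO,55,65,75\n")

    def test_parses_groups_regions_and_missing_cells(self):
        t = read_activity_table(self.CSV, META)
        assert t.regions == ["BLA", "LA", "PIR"]
        assert t.group_labels() == ["WT", "KO"]
        assert len(t.for_group("WT")) == 2
        # empty cell stays missing, never coerced to 0
        assert np.isnan(t.values.loc["wt2", "LA"])

    def test_duplicate_animal_rejected(self):
        bad = self.CSV.replace("wt2", "wt1")
        with pytest.raises(ValueError, match="duplicate"):
            read_activity_table(bad, META)

    def test_unknown_region_named_in_error(self):
        with pytest.raises(KeyError, match="PIR"):
            read_activity_table(self.CSV, {k: META[k] for k in ("BLA", "LA")})

    def test_single_animal_group_warns(self):
        csv = self.CSV.replace("ko2,KO,55,65,75\n", "")
        with pytest.warns(UserWarning, match="KO"):
            read_activity_table(csv, META)

    def test_csv_round_trip(self):
        t = read_activity_table(self.CSV, META)
        again = read_activity_table(t.to_csv(), META)
        assert again.values.equals(t.values)


class TestCountingRatios:
    @pytest.mark.parametrize("marker,dapi,expected",
                             [(50, 200, 0.25), (0, 200, 0.0), (200, 200, 1.0)])
    def test_ratio_to_dapi(self, marker, dapi, expected):
        assert ratio_to_dapi(marker, dapi) == expected

    def test_zero_dapi_rejected_and_overcount_warns(self):
        with pytest.raises(ValueError):
            ratio_to_dapi(10, 0)
        with pytest.warns(UserWarning):
            ratio_to_dapi(300, 200)

    def test_normalize_to_wildtype(self):
        assert normalize_to_wildtype([2, 4], [1, 3]).tolist() == [1.0, 2.0]
        wt = np.array([3.0, 5.0, 4.0])
        assert normalize_to_wildtype(wt, wt).mean() == pytest.approx(1.0)
        assert normalize_to_wildtype([7, 7], [7, 7]).tolist() == [1.0, 1.0]
        with pytest.raises(ValueError):
            normalize_to_wildtype([1, 2], [0, 0])


class TestColocalize:
    def test_identical_clouds_all_colocalized(self, rng):
        pts = rng.uniform(0, 100, (20, 3))
        count, pairs = colocalize(CellSet("a", pts), CellSet("b", pts))
        assert count == 20
        assert all(i == j for i, j in pairs)

    def test_threshold_is_inclusive_at_three_voxels(self):
        a = CellSet("fos", [[0, 0, 0]])
        near = CellSet("pi", [[2.9, 0, 0]])
        far = CellSet("pi", [[3.1, 0, 0]])
        assert colocalize(a, near)[0] == 1
        assert colocalize(a, far)[0] == 0
        assert colocalize(a, CellSet("pi", [[3.0, 0, 0]]))[0] == 1

    def test_matches_all_pairs_oracle(self, rng):
        a = rng.uniform(0, 1000, (100, 3))
        b = rng.uniform(0, 1000, (100, 3))
        for thr in (3.0, 30.0, 120.0):
            count, _ = colocalize(CellSet("a", a), CellSet("b", b), thr)
            assert count == coloc_brute(a, b, thr)

    def test_monotone_in_threshold(self, rng):
        a = rng.uniform(0, 50, (40, 3))
        b = rng.uniform(0, 50, (40, 3))
        counts = [colocalize(CellSet("a", a), CellSet("b", b), t)[0]
                  for t in (0.5, 1, 2, 4, 8, 16)]
        assert counts == sorted(counts)

    def test_empty_input(self):
        empty = CellSet("a", np.empty((0, 3)))
        assert colocalize(empty, CellSet("b", [[0, 0, 0]])) == (0, [])


class TestProfileBins:
    def test_constant_profile_is_uniform(self):
        out = profile_bins(SpatialProfile(np.ones(1000)), n_bins=200)
        assert out == pytest.approx(np.full(200, 0.005), abs=1e-12)

    def test_point_mass_at_midpoint_falls_in_right_bin(self):
        v = np.zeros(200)
        v[100] = 7.0  # even-length axis: midpoint sample goes to bin n/2
        out = profile_bins(SpatialProfile(v), n_bins=200)
        assert out[100] == 1.0
        assert out.sum() == pytest.approx(1.0)

    def test_linear_ramp_matches_resampling_oracle(self):
        v = np.linspace(0, 1, 1000) * 3.5
        v[0] = 0.1
        out = profile_bins(SpatialProfile(v), n_bins=200)
        assert out == pytest.approx(profile_bins_brute(v, 200), abs=1e-9)

    def test_length_not_divisible_by_bins_conserves_mass(self, rng):
        v = rng.uniform(0, 5, 73)  # 73 samples over 10 bins: boundary splits
        out = profile_bins(SpatialProfile(v), n_bins=10)
        assert out.sum() == pytest.approx(1.0, abs=1e-9)
        assert out == pytest.approx(profile_bins_brute(v, 10), abs=1e-9)

    @given(scale=st.floats(min_value=1e-3, max_value=1e6),
           seed=st.integers(0, 100))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_scale_invariance(self, scale, seed):
        v = np.random.default_rng(seed).uniform(0.1, 2.0, 50)
        base = profile_bins(SpatialProfile(v), n_bins=20)
        scaled = profile_bins(SpatialProfile(v * scale), n_bins=20)
        assert scaled == pytest.approx(base, rel=1e-9)

    def test_all_zero_profile_rejected(self):
        with pytest.raises(ValueError, match="zero total"):
            profile_bins(SpatialProfile(np.zeros(10)))


class TestPercentInput:
    def test_equal_ct_undiluted_input_gives_100(self):
        m = QpcrMeasurement("E1", ct_ip=25.0, ct_input=25.0, input_fraction=1.0)
        assert percent_input(m) == pytest.approx(100.0)

    def test_five_percent_input_dilution(self):
        # equal Ct against a 5% input aliquot recovers exactly 5% of input
        m = QpcrMeasurement("E2", ct_ip=20.0, ct_input=20.0, input_fraction=0.05)
        assert percent_input(m) == pytest.approx(5.0, abs=1e-9)

    def test_each_cycle_doubles_and_flags_over_100(self):
        base = QpcrMeasurement("E3", ct_ip=24.0, ct_input=25.0)
        with pytest.warns(UserWarning, match="exceeds 100"):
            assert percent_input(base) == pytest.approx(200.0)

    def test_monotonicity_in_both_ct_values(self):
        p = [percent_input(QpcrMeasurement("E", ct_ip=ct, ct_input=25.0))
             for ct in (25.0, 26.0, 27.0, 28.0)]
        assert p == sorted(p, reverse=True)  # strictly decreasing in ct_ip
        q = [percent_input(QpcrMeasurement("E", ct_ip=28.0, ct_input=ct))
             for ct in (24.0, 25.0, 26.0)]
        assert q == sorted(q)  # strictly increasing in ct_input

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            QpcrMeasurement("E", ct_ip=-1, ct_input=20)
        with pytest.raises(ValueError):
            QpcrMeasurement("E", ct_ip=20, ct_input=20, input_fraction=0)
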