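"""Strand-partition pipeline: unit checks and algebraic invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from strandfold import scarseq, synthgen
from strandfold.core import InitiationZone, StrandedBinTrack


def _track(F, R, units="counts", bin_width=1000):
    return StrandedBinTrack(reference="chr1", bin_width=bin_width, F=F, R=R, units=units)


class TestCpmNormalize:
    @pytest.mark.parametrize("value,total,expected", [(5.0, 1e6, 5.0), (3.0, 2e6, 1.5)])
    def test_scaling(self, value, total, expected):
        out = scarseq.cpm_normalize(_track([value], [0.0]), total)
        assert out.F[0] == pytest.approx(expected)
        assert out.units == "CPM"

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            scarseq.cpm_normalize(_track([1.0], [1.0]), 0)


def brute_force_window_mean(x, h):
    n = len(x)
    return np.array([np.mean(x[max(i - h, 0) : min(i + h + 1, n)]) for i in range(n)])


class TestUniformBlur:
    def test_constant_track_unchanged(self):
        out = scarseq.uniform_blur(_track(np.full(100, 3.0), np.full(100, 3.0)), 30)
        assert np.allclose(out.F, 3.0) and np.allclose(out.R, 3.0)

    def test_interior_impulse_spreads_over_window(self):
        F = np.zeros(201)
        F[100] = 1.0
        out = scarseq.uniform_blur(_track(F, np.zeros(201)), 30)
        assert np.allclose(out.F[70:131], 1.0 / 61.0)
        assert out.F[69] == 0.0 and out.F[131] == 0.0

    def test_halfwidth_zero_is_identity(self):
        F = np.arange(10.0)
        out = scarseq.uniform_blur(_track(F, F), 0)
        assert np.array_equal(out.F, F)

    @given(
        data=st.lists(st.floats(0, 100), min_size=1, max_size=80),
        h=st.integers(0, 40),
    )
    @settings(max_examples=60, deadline=None)
    def test_matches_brute_force_window_mean(self, data, h):
        x = np.array(data)
        out = scarseq.uniform_blur(_track(x, np.zeros_like(x)), h)
        assert np.allclose(out.F, brute_force_window_mean(x, h))


class TestInputCorrect:
    def test_subtraction_with_zero_clipping(self):
        pd = _track([2.0, 0.2], [1.0, 1.0], units="CPM")
        inp = _track([0.5, 0.5], [1.0, 1.0], units="CPM")
        out = scarseq.input_correct(pd, inp)
        assert out.F[0] == pytest.approx(1.5)
        assert out.F[1] == 0.0  # negatives set to zero
        assert np.all(out.R == 0.0)

    def test_identical_tracks_give_zero(self):
        t = _track([1.0, 2.0], [3.0, 4.0], units="CPM")
        out = scarseq.input_correct(t, t)
        assert np.all(out.F == 0.0) and np.all(out.R == 0.0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            scarseq.input_correct(_track([1.0], [1.0]), _track([1.0, 2.0], [1.0, 2.0]))


class TestCoverageFilter:
    def test_jointly_low_bins_masked_one_sided_kept(self):
        t = _track([0.1, 0.5, 0.1], [0.1, 0.1, 0.4], units="CPM")
        keep = scarseq.coverage_filter(t, 0.3)
        assert list(keep) == [False, True, True]

    def test_zero_threshold_masks_only_empty_bins(self):
        t = _track([0.0, 0.2], [0.0, 0.0], units="CPM")
        keep = scarseq.coverage_filter(t, 0.0)
        assert list(keep) == [False, True]


class TestPartitionAndRfd:
    def test_pointwise_values(self):
        t = _track([2.0, 3.0, 3.0, 0.0], [2.0, 0.0, 1.0, 0.0], units="CPM")
        p = scarseq.partition(t)
        assert p.value[0] == 0.0
        assert p.value[1] == 1.0  # forward-only bin
        assert p.value[2] == pytest.approx(0.5)
        assert not p.mask[3] and np.isnan(p.value[3])

    def test_rfd_is_exact_negation_of_partition(self):
        rng = np.random.default_rng(0)
        t = _track(rng.poisson(5, 200).astype(float), rng.poisson(5, 200).astype(float))
        p, r = scarseq.partition(t), scarseq.rfd(t)
        m = p.mask
        assert np.array_equal(m, r.mask)
        assert np.array_equal(r.value[m], -p.value[m])

    @given(st.lists(st.tuples(st.floats(0, 50), st.floats(0, 50)), min_size=1, max_size=50))
    @settings(max_examples=60, deadline=None)
    def test_antisymmetric_under_strand_swap_and_bounded(self, bins):
        F = np.array([b[0] for b in bins])
        R = np.array([b[1] for b in bins])
        p = scarseq.partition(_track(F, R))
        q = scarseq.partition(_track(R, F))
        m = p.mask
        assert np.array_equal(m, q.mask)
        assert np.allclose(p.value[m], -q.value[m])
        assert np.all(np.abs(p.value[m]) <= 1.0 + 1e-12)


class TestIzMetaprofile:
    def _ptrack(self, values):
        v = np.asarray(values, dtype=float)
        return scarseq.PartitionTrack("chr1", 1000, v, np.isfinite(v))

    def test_single_zone_returns_track_slice(self):
        vals = np.linspace(-0.5, 0.5, 21)
        prof = scarseq.iz_metaprofile(self._ptrack(vals), [InitiationZone("chr1", 10)], 5)
        assert np.allclose(prof.mean, vals[5:16])
        assert np.all(prof.n == 1)

    def test_duplicate_zones_do_not_change_mean(self):
        vals = np.linspace(-0.5, 0.5, 21)
        izs = [InitiationZone("chr1", 10), InitiationZone("chr1", 10)]
        prof = scarseq.iz_metaprofile(self._ptrack(vals), izs, 5)
        assert np.allclose(prof.mean, vals[5:16])
        assert np.all(prof.n == 2)

    def test_reverse_oriented_zone_mirrored_and_sign_flipped(self):
        vals = np.linspace(-0.5, 0.5, 21)  # odd-symmetric around bin 10
        fwd = scarseq.iz_metaprofile(self._ptrack(vals), [InitiationZone("chr1", 10, 1)], 5)
        rev = scarseq.iz_metaprofile(self._ptrack(vals), [InitiationZone("chr1", 10, -1)], 5)
        assert np.allclose(fwd.mean, rev.mean)

    def test_empty_zone_list_rejected(self):
        with pytest.raises(ValueError):
            scarseq.iz_metaprofile(self._ptrack([0.0]), [], 5)


class TestSpikeinNormalize:
    def test_reference_maps_to_one(self):
        out = scarseq.spikein_normalize({"A": (100, 10), "B": (50, 10)}, "A")
        assert out["A"] == pytest.approx(1.0)
        assert out["B"] == pytest.approx(0.5)

    def test_double_spikein_halves_abundance(self):
        out = scarseq.spikein_normalize({"A": (100, 10), "B": (100, 20)}, "A")
        assert out["B"] == pytest.approx(0.5)

    def test_zero_spikein_rejected(self):
        with pytest.raises(ValueError):
            scarseq.spikein_normalize({"A": (100, 0)}, "A")


class TestPipelineRecovery:
    def test_injected_asymmetry_recovered_at_metaprofile_extremum(self):
        truth = synthgen.ScarSimTruth(
            n_bins=6000, iz_positions=(1000, 3000, 5000), partition_amplitude=0.4,
            depth_per_bin=50, seed=21,
        )
        s = synthgen.sim_scar_samples(truth)["sample"]
        ptrack = scarseq.compute_partition(
            s.pulldown, s.input,
            pulldown_total=s.pulldown_library_total,
            input_total=s.input_library_total,
        )
        izs = [InitiationZone("chrSim", p) for p in truth.iz_positions]
        prof = scarseq.iz_metaprofile(ptrack, izs, 600)
        assert abs(abs(prof.extremum()) - 0.4) < 0.05

    def test_zero_asymmetry_profile_indistinguishable_from_zero(self):
        truth = synthgen.ScarSimTruth(
            n_bins=4000, iz_positions=(1000, 3000), partition_amplitude=0.0,
            depth_per_bin=50, seed=22,
        )
        s = synthgen.sim_scar_samples(truth)["sample"]
        ptrack = scarseq.compute_partition(
            s.pulldown, s.input,
            pulldown_total=s.pulldown_library_total,
            input_total=s.input_library_total,
        )
        izs = [InitiationZone("chrSim", p) for p in truth.iz_positions]
        prof = scarseq.iz_metaprofile(ptrack, izs, 500)
        # the 61-bin blur correlates neighbouring offsets; subsample at the
        # blur width so the SE is computed from near-independent values
        vals = prof.mean[np.isfinite(prof.mean)][::61]
        se = vals.std(ddof=1) / np.sqrt(vals.size)
        assert abs(vals.mean()) < 3 * se
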