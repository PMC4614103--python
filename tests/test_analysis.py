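"""Order parameters, contact ratios, landscapes, states and passage times."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cotrafold.analysis import (
    GAS_CONSTANT_KCAL,
    FptResult,
    OrderParameterSeries,
    StateThresholds,
    block_average,
    classify_state,
    compute_order_parameters,
    contact_ratios,
    first_passage_times,
    free_energy_landscape,
    per_residue_contact_profile,
)
from cotrafold.structures import Conformation, Trajectory, extract_native_contacts
from cotrafold.synthetic_data import make_scripted_series, perturb_native

from test_structures import brute_force_contacts


def _series(times, rmsd_global, rmsd_N=None, rmsd_C=None):
    n = len(times)
    rg = np.asarray(rmsd_global, float)
    rn = np.asarray(rmsd_N if rmsd_N is not None else rg, float)
    rc = np.asarray(rmsd_C if rmsd_C is not None else rg, float)
    return OrderParameterSeries(
        times=np.asarray(times, float),
        rmsd_global=rg,
        rmsd_N=rn,
        rmsd_C=rc,
        q_nat=np.zeros(n),
        q_non=np.zeros(n),
        state=np.full(n, "U", dtype="<U5"),
    )


# ---------------------------------------------------------------------------
# contact ratios and per-residue profile


class TestContactRatios:
    def test_native_snapshot_is_all_native_no_nonnative(self, bundle):
        assert contact_ratios(bundle.coords, bundle) == (1.0, 0.0)

    def test_no_longrange_contacts_gives_zero_zero(self, bundle):
        chain = np.column_stack(
            [np.arange(35) * 3.8, np.zeros(35), np.zeros(35)]
        )
        assert contact_ratios(chain, bundle) == (0.0, 0.0)

    def test_random_compact_snapshot_matches_exhaustive_oracle(self, bundle, rng):
        for _ in range(10):
            x = rng.normal(scale=6.0, size=(35, 3))
            snap = brute_force_contacts(x)
            s_nat = set(bundle.native_contacts)
            expect = (
                len(snap & s_nat) / len(s_nat),
                len(snap - s_nat) / len(s_nat),
            )
            assert contact_ratios(x, bundle) == pytest.approx(expect)

    def test_perturbation_degrades_q_nat_on_average(self, bundle):
        means = []
        for sd in (0.0, 1.0, 2.0, 4.0):
            qs = [
                contact_ratios(perturb_native(bundle, sd, seed=s).coords, bundle)[0]
                for s in range(50)
            ]
            means.append(np.mean(qs))
        assert all(a >= b for a, b in zip(means, means[1:]))


class TestPerResidueProfile:
    def test_native_snapshot_is_one_everywhere_defined(self, bundle):
        prof = per_residue_contact_profile(bundle.coords, bundle)
        defined = ~np.isnan(prof)
        assert np.all(prof[defined] == 1.0)

    def test_extended_snapshot_is_zero_everywhere_defined(self, bundle, extended):
        # tertiary contacts all broken; helix i,i+4 contacts survive, so
        # only loop/linker residues with purely tertiary contacts drop to 0
        prof = per_residue_contact_profile(extended.coords, bundle)
        chain = np.column_stack([np.arange(35) * 3.8, np.zeros(35), np.zeros(35)])
        prof_chain = per_residue_contact_profile(chain, bundle)
        defined = ~np.isnan(prof_chain)
        assert np.all(prof_chain[defined] == 0.0)
        assert np.nanmean(prof) < 1.0

    def test_matches_exhaustive_enumeration(self, bundle, rng):
        x = rng.normal(scale=6.0, size=(35, 3))
        snap = brute_force_contacts(x)
        formed = snap & set(bundle.native_contacts)
        for i in range(1, 36):
            mine = [c for c in bundle.native_contacts if i in c]
            if not mine:
                continue
            expect = sum(1 for c in mine if c in formed) / len(mine)
            prof = per_residue_contact_profile(x, bundle)
            assert prof[i - 1] == pytest.approx(expect)


# ---------------------------------------------------------------------------
# order parameters over trajectories


class TestComputeOrderParameters:
    def test_native_frames_are_folded_with_full_contacts(self, bundle):
        traj = Trajectory(
            np.repeat(bundle.coords[None], 3, axis=0), np.arange(3.0) + 1
        )
        s = compute_order_parameters(traj, bundle)
        assert np.all(s.rmsd_global < 1e-8)
        assert np.all(s.q_nat == 1.0) and np.all(s.q_non == 0.0)
        assert np.all(s.state == "F")

    def test_randomized_c_segment_labels_off_pathway(self, bundle, rng):
        x = bundle.coords.copy()
        lo, hi = bundle.segments["C"]
        mid = bundle.segments["N"][1]  # keep the shared helix intact
        x[mid:] = rng.normal(scale=8.0, size=x[mid:].shape) + 40.0
        s = compute_order_parameters([Conformation(x, 1.0)], bundle)
        assert s.rmsd_N[0] < 2.0 <= s.rmsd_C[0]
        assert s.state[0] == "I_off"

    def test_residue_count_mismatch_rejected(self, bundle):
        with pytest.raises(ValueError, match="residue count"):
            compute_order_parameters(
                [Conformation(np.zeros((10, 3)) + np.eye(10, 3))], bundle
            )


# ---------------------------------------------------------------------------
# free-energy landscape


class TestFreeEnergyLandscape:
    def test_single_occupied_bin_has_zero_free_energy(self):
        s = _series([1, 2, 3], [5, 5, 5], [1.02, 1.04, 1.08], [2.51, 2.55, 2.59])
        fel = free_energy_landscape([s], temperature=300.0)
        assert fel.n_total == 3
        occupied = ~fel.mask
        assert occupied.sum() == 1
        assert fel.free_energy[occupied][0] == pytest.approx(0.0)

    def test_two_bin_worked_example(self):
        """75/25 split of 100 frames at 300 K: 0.1715 and 0.8264 kcal/mol."""
        rn = np.concatenate([np.full(75, 1.05), np.full(25, 3.05)])
        rc = np.full(100, 2.05)
        s = _series(np.arange(100.0) + 1, np.full(100, 5.0), rn, rc)
        fel = free_energy_landscape([s], temperature=300.0)
        vals = np.sort(fel.free_energy[~fel.mask])
        assert vals[0] == pytest.approx(-GAS_CONSTANT_KCAL * 300 * np.log(0.75), abs=1e-6)
        assert vals[0] == pytest.approx(0.1715, abs=1e-4)
        assert vals[1] == pytest.approx(0.8264, abs=1e-4)

    def test_counts_conserved_and_minimum_at_modal_bin(self, rng):
        for _ in range(10):
            n = int(rng.integers(10, 400))
            s = _series(
                np.arange(n) + 1.0,
                np.full(n, 9.0),
                rng.uniform(0, 4, n),
                rng.uniform(0, 4, n),
            )
            fel = free_energy_landscape([s], temperature=300.0)
            assert fel.counts.sum() == n  # exact integer conservation
            i, j = fel.minimum_bin()
            assert fel.counts[i, j] == fel.counts.max()
            expect_min = -GAS_CONSTANT_KCAL * 300 * np.log(fel.counts.max() / n)
            assert np.nanmin(fel.free_energy) == pytest.approx(expect_min)

    def test_bins_are_half_open_anchored_at_zero(self):
        # a frame exactly on an edge belongs to the upper bin
        s = _series([1, 2], [5, 5], [0.1, 0.1 - 1e-9], [0.0, 0.0])
        fel = free_energy_landscape([s], temperature=300.0)
        assert fel.counts[0, 0] == 1 and fel.counts[1, 0] == 1

    def test_pooling_over_trajectories(self):
        s1 = _series([1], [5], [0.55], [0.55])
        s2 = _series([1, 2], [5, 5], [0.55, 0.55], [0.55, 0.55])
        fel = free_energy_landscape([s1, s2], temperature=300.0)
        assert fel.n_total == 3 and fel.counts[5, 5] == 3


# ---------------------------------------------------------------------------
# state classification


class TestClassifyState:
    @pytest.mark.parametrize(
        "rn,rc,rg,label",
        [
            (0.1, 0.1, 0.1, "F"),
            (6.0, 1.0, 4.0, "I_on"),   # C-segment native first: productive
            (1.0, 6.0, 4.0, "I_off"),  # N-segment formed: misfolded
            (6.0, 6.0, 8.0, "U"),
            (2.0, 2.0, 2.0, "U"),      # exact thresholds are not folded
        ],
    )
    def test_canonical_labels(self, rn, rc, rg, label):
        assert classify_state(rn, rc, rg) == label

    def test_global_criterion_dominates(self):
        assert classify_state(5.0, 5.0, 1.9) == "F"

    @given(
        rn=st.floats(0, 12),
        rc=st.floats(0, 12),
        rg=st.floats(0, 12),
        seg=st.floats(0.5, 5),
        fold=st.floats(0.5, 5),
    )
    @settings(max_examples=200, deadline=None)
    def test_exactly_one_label_for_any_thresholds(self, rn, rc, rg, seg, fold):
        label = classify_state(rn, rc, rg, StateThresholds(fold, seg))
        assert label in {"U", "I_on", "I_off", "F"}


# ---------------------------------------------------------------------------
# first passage times


class TestFirstPassageTimes:
    def test_censored_mean_worked_example(self):
        """Four folded runs (0.19, 1.41, 1.55, 2.21 us) + one censored at
        3 us average to 1.672 us."""
        res = first_passage_times([0.19, 1.41, 1.55, 2.21, 3.0], cap=3.0)
        assert res.mfpt == pytest.approx(1.672, abs=1e-9)
        assert list(res.censored) == [False, False, False, False, True]

    def test_all_censored_degenerates_to_cap(self):
        s = _series([1, 2, 3], [8, 7, 9])
        res = first_passage_times([s, s], folded_threshold=2.0, cap=3.0)
        assert res.mfpt == 3.0 and res.censored.all()

    def test_single_trajectory_folded_at_first_frame(self):
        s = _series([0.4, 1.0], [1.0, 1.0])
        res = first_passage_times([s], folded_threshold=2.0, cap=3.0)
        assert res.mfpt == pytest.approx(0.4)

    def test_crossing_time_is_first_subthreshold_frame(self):
        s = _series([1, 2, 3, 4], [5, 1.9, 5, 1.0])
        res = first_passage_times([s], folded_threshold=2.0, cap=10.0)
        assert res.fpt[0] == 2.0

    @given(caps=st.lists(st.floats(1.0, 50.0), min_size=2, max_size=2))
    @settings(max_examples=50, deadline=None)
    def test_mfpt_monotone_in_cap_and_order_invariant(self, caps):
        lo, hi = sorted(caps)
        runs = [
            _series([1, 2, 3], [5, 1.0, 1.0]),
            _series([1, 2, 3], [9, 9, 9]),
            _series([1, 2, 3], [5, 5, 1.5]),
        ]
        m_lo = first_passage_times(runs, cap=lo).mfpt
        m_hi = first_passage_times(runs, cap=hi).mfpt
        assert m_hi >= m_lo - 1e-12
        assert first_passage_times(runs[::-1], cap=lo).mfpt == pytest.approx(m_lo)

    def test_kaplan_meier_alternative_available(self):
        res = first_passage_times([0.19, 1.41, 1.55, 2.21, 3.0], cap=3.0)
        assert res.kaplan_meier_mean() == pytest.approx(res.mfpt, abs=1e-9)


# ---------------------------------------------------------------------------
# pipeline-level recovery from scripted trajectories


class TestScriptedRecovery:
    SCHEDULE = [
        ("U", 1000.0), ("I_off", 700.0), ("U", 300.0),
        ("I_on", 800.0), ("F", 1200.0),
    ]
    CENTERS = {
        "U": (6.0, 6.0, 8.0),
        "I_on": (5.0, 0.8, 4.0),
        "I_off": (0.8, 5.0, 4.0),
        "F": (0.4, 0.4, 0.6),
    }

    def test_state_occupancies_recovered_within_two_percent(self):
        series = make_scripted_series(self.SCHEDULE, self.CENTERS,
                                      noise_sd=0.2, seed=42)
        total = sum(d for _, d in self.SCHEDULE)
        relabelled = [
            classify_state(rn, rc, rg)
            for rn, rc, rg in zip(series.rmsd_N, series.rmsd_C, series.rmsd_global)
        ]
        for label in ("U", "I_on", "I_off", "F"):
            truth = sum(d for s, d in self.SCHEDULE if s == label) / total
            got = np.mean(np.array(relabelled) == label)
            assert got == pytest.approx(truth, abs=0.02)

    def test_fel_basins_at_generating_centers_within_one_bin(self):
        series = make_scripted_series(self.SCHEDULE, self.CENTERS,
                                      noise_sd=0.2, seed=42)
        fel = free_energy_landscape([series], temperature=300.0, bin_width=0.1)
        fe = np.where(fel.mask, np.inf, fel.free_energy)
        for label, (cn, cc, _) in self.CENTERS.items():
            # local minimum within +-0.5 Å of the generating centre
            i0, j0 = int(cn / 0.1), int(cc / 0.1)
            wi = slice(max(i0 - 5, 0), i0 + 6)
            wj = slice(max(j0 - 5, 0), j0 + 6)
            local = fe[wi, wj]
            di, dj = np.unravel_index(np.argmin(local), local.shape)
            ci = (wi.start + di + 0.5) * 0.1
            cj = (wj.start + dj + 0.5) * 0.1
            assert abs(ci - cn) <= 0.1 + 0.05
            assert abs(cj - cc) <= 0.1 + 0.05


def test_block_average_means_blocks():
    t = np.arange(1, 11, dtype=float)
    v = np.arange(10, dtype=float)
    bt, bv = block_average(t, v, 5.0)
    # blocks [0,5): v=0..3 -> 1.5 ; [5,10): v=4..8 -> 6.0 ; [10,15): v=9
    np.testing.assert_allclose(bv, [1.5, 6.0, 9.0])
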