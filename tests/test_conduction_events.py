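import numpy as np
import pandas as pd
import pytest

from conftest import EXTRA_Z, INTRA_Z, make_trajectory
from permeon.errors import UndefinedRatioError
from permeon.conduction_events import (
    ASSOC_EXTRA,
    ASSOC_INTRA,
    DISSOC_EXTRA,
    DISSOC_INTRA,
    INWARD,
    MECH_PULL,
    MECH_PUSH,
    MECH_UNCLASSIFIED,
    OUTWARD,
    ConductionEvent,
    boundary_events,
    classify_all,
    conductions_to_table,
    detect_conductions,
    lifetime_distribution,
    mechanism_ratio,
)
from permeon.site_model import SiteModel
from permeon.state_analysis import state_sequence
from permeon.trajectory_io import IonTrajectory

MODEL = SiteModel.default()


def seq_from_positions(frames_of_positions, frame_interval=10.0):
    rows = []
    for f, positions in enumerate(frames_of_positions):
        for ion, z in positions.items():
            rows.append((f, ion, z))
    traj = make_trajectory(rows, frame_interval=frame_interval,
                           frame_range=(0, len(frames_of_positions) - 1))
    return state_sequence(traj, MODEL)


def pipeline(seq, resting=3):
    events = boundary_events(seq)
    conductions = detect_conductions(events, t_start=seq[0].time_ps)
    classify_all(conductions, seq, resting_count=resting)
    return events, conductions


class TestBoundaryEvents:
    def test_full_traversal(self, site_centers):
        c = site_centers
        path = [INTRA_Z, c[6], c[5], c[3], c[1], c[0], EXTRA_Z]
        frames = [{"k": z} for z in path]
        events = boundary_events(seq_from_positions(frames))
        kinds = [e.kind for e in events]
        assert kinds == [ASSOC_INTRA, DISSOC_EXTRA]

    def test_oscillation_across_s0(self, site_centers):
        zs = [site_centers[0], EXTRA_Z] * 3
        frames = [{"k": z} for z in zs]
        events = boundary_events(seq_from_positions(frames))
        kinds = [e.kind for e in events]
        assert kinds == [DISSOC_EXTRA, ASSOC_EXTRA] * 2 + [DISSOC_EXTRA]

    def test_untracked_disappearance_sides(self, site_centers):
        # ion vanishing from S0 leaves extracellularly, one from S6 intracellularly
        frames = [{"hi": site_centers[0], "lo": site_centers[6]}, {}]
        events = boundary_events(seq_from_positions(frames))
        kinds = {e.ion_id: e.kind for e in events}
        assert kinds == {"hi": DISSOC_EXTRA, "lo": DISSOC_INTRA}

    def test_kmc_event_log_recovered(self, fixtures):
        case = fixtures["mixed"]
        seq = state_sequence(case.trajectory, case.site_model)
        events = boundary_events(seq)
        truth = case.ground_truth.events
        exact = truth[truth["kind"].isin(["entry", "exit"])]
        assert len(events) == len(exact)
        interval = seq.frame_interval
        for got, (_, want) in zip(events, exact.iterrows()):
            assert str(got.ion_id) == str(want["ion_id"])
            kind_map = {
                ("entry", "INTRA"): ASSOC_INTRA,
                ("entry", "EXTRA"): ASSOC_EXTRA,
                ("exit", "INTRA"): DISSOC_INTRA,
                ("exit", "EXTRA"): DISSOC_EXTRA,
            }
            side = want["from_region"] if want["kind"] == "entry" else want["to_region"]
            assert got.kind == kind_map[(want["kind"], side)]
            # frame timestamp is the first frame after the exact event
            assert 0 <= got.time_ps - want["time_ps"] <= interval


class TestDetectConductions:
    def test_outward_conduction(self, site_centers):
        c = site_centers
        frames = [{"k": z} for z in [INTRA_Z, c[6], c[3], c[0], EXTRA_Z]]
        _, conductions = pipeline(seq_from_positions(frames))
        assert len(conductions) == 1
        assert conductions[0].direction == OUTWARD
        assert not conductions[0].resident

    def test_back_running_is_not_conduction(self, site_centers):
        c = site_centers
        frames = [{"k": z} for z in [c[0], EXTRA_Z, c[0], c[1], c[0]]]
        _, conductions = pipeline(seq_from_positions(frames))
        # first exit is by a resident (counted, flagged); the re-entry +
        # staying put yields nothing further
        assert [c_.resident for c_ in conductions] == [True]
        frames = [{"k": z} for z in [INTRA_Z, c[6], c[0], EXTRA_Z, c[0], EXTRA_Z]]
        _, conductions = pipeline(seq_from_positions(frames))
        assert len(conductions) == 1  # the re-exit after EXTRA re-entry is back-running

    def test_resident_ion_counts_on_exit(self, site_centers):
        c = site_centers
        frames = [{"k": z} for z in [c[2], c[1], c[0], EXTRA_Z]]
        _, conductions = pipeline(seq_from_positions(frames))
        assert len(conductions) == 1
        assert conductions[0].resident
        assert conductions[0].t_enter_ps == 0.0

    def test_inward_conduction(self, site_centers):
        c = site_centers
        frames = [{"k": z} for z in [EXTRA_Z, c[0], c[3], c[6], INTRA_Z]]
        _, conductions = pipeline(seq_from_positions(frames))
        assert len(conductions) == 1
        assert conductions[0].direction == INWARD

    def test_kmc_counts_match_ground_truth(self, fixtures):
        for name in ("mixed", "push", "pull", "inward"):
            case = fixtures[name]
            seq = state_sequence(case.trajectory, case.site_model)
            _, conductions = pipeline(seq)
            truth = case.ground_truth.conductions()
            assert len(conductions) == len(truth), name
            for direction in (OUTWARD, INWARD):
                assert sum(1 for c in conductions if c.direction == direction) == (
                    truth["direction"] == direction
                ).sum(), name


class TestClassifyMechanism:
    def test_constructed_push(self, site_centers):
        c = site_centers
        resting = {"a": c[0], "b": c[2], "x": c[4]}
        four_ion = dict(resting, d=c[6])
        after = {"d": c[6], "b": c[2], "x": c[4], "a": EXTRA_Z}
        resting2 = {"d": c[5], "b": c[2], "x": c[4]}
        # newcomer enters 100 frames (1 ns) before the outermost leaves
        frames = [resting] * 3 + [four_ion] * 100 + [after, resting2]
        seq = seq_from_positions(frames, frame_interval=10.0)
        _, conductions = pipeline(seq)
        assert len(conductions) == 1
        assert conductions[0].mechanism == MECH_PUSH
        assert conductions[0].intermediate_lifetime_ps == pytest.approx(1000.0)

    def test_constructed_pull(self, site_centers):
        c = site_centers
        resting = {"a": c[0], "b": c[2], "x": c[4]}
        two_ion = {"b": c[2], "x": c[4], "a": EXTRA_Z}
        refill = {"b": c[2], "x": c[4], "d": c[6]}
        # 500 frames of 10 ps = 5 ns gap before the replacement enters
        frames = [resting] * 3 + [two_ion] * 500 + [refill] * 2
        seq = seq_from_positions(frames, frame_interval=10.0)
        _, conductions = pipeline(seq)
        assert len(conductions) == 1
        assert conductions[0].mechanism == MECH_PULL
        assert conductions[0].intermediate_lifetime_ps == pytest.approx(5000.0)

    def test_open_cycle_has_no_lifetime(self, site_centers):
        c = site_centers
        resting = {"a": c[0], "b": c[2], "x": c[4]}
        two_ion = {"b": c[2], "x": c[4], "a": EXTRA_Z}
        frames = [resting] * 3 + [two_ion] * 5  # run ends mid-cycle
        seq = seq_from_positions(frames)
        _, conductions = pipeline(seq)
        assert conductions[0].mechanism == MECH_PULL
        assert conductions[0].intermediate_lifetime_ps is None

    def test_kmc_labels_recovered_exactly(self, fixtures):
        for name in ("mixed", "push", "pull", "inward"):
            case = fixtures[name]
            seq = state_sequence(case.trajectory, case.site_model)
            _, conductions = pipeline(seq)
            truth = case.ground_truth.conductions()
            got = sorted((str(c.ion_id), c.direction, c.mechanism) for c in conductions)
            want = sorted(
                (str(r.ion_id), r.direction, r.mechanism) for r in truth.itertuples()
            )
            assert got == want, name

    def test_push_pull_unclassified_partition(self, fixtures):
        case = fixtures["mixed"]
        seq = state_sequence(case.trajectory, case.site_model)
        _, conductions = pipeline(seq)
        ratio = mechanism_ratio(conductions)
        assert ratio.n_push + ratio.n_pull + ratio.n_unclassified == len(conductions)

    def test_subsampling_by_two_preserves_labels(self, fixtures):
        case = fixtures["mixed"]
        seq = state_sequence(case.trajectory, case.site_model)
        _, conductions = pipeline(seq)
        truth = case.ground_truth.conductions()
        stable_ions = {
            str(r.ion_id)
            for r in truth.itertuples()
            if r.lifetime_ps is not None and r.lifetime_ps > 4 * seq.frame_interval
        }
        sub = case.trajectory.frames[case.trajectory.frames["frame"] % 2 == 0].copy()
        sub["frame"] //= 2
        traj2 = IonTrajectory.from_table(sub)
        traj2.frame_range = (0, case.trajectory.frame_range[1] // 2)
        seq2 = state_sequence(traj2, case.site_model)
        _, conductions2 = pipeline(seq2)
        mech1 = {str(c.ion_id): c.mechanism for c in conductions if str(c.ion_id) in stable_ions}
        mech2 = {str(c.ion_id): c.mechanism for c in conductions2 if str(c.ion_id) in stable_ions}
        assert mech1 == mech2

    def test_time_reversal_swaps_directions(self, fixtures):
        case = fixtures["mixed"]
        seq = state_sequence(case.trajectory, case.site_model)
        _, conductions = pipeline(seq)
        f0, f1 = case.trajectory.frame_range
        rev = case.trajectory.frames.copy()
        rev["frame"] = f1 - rev["frame"]
        rev["time_ps"] = (f1 - f0) * case.trajectory.frame_interval - rev["time_ps"]
        traj_rev = IonTrajectory.from_table(rev)
        traj_rev.frame_range = (0, f1 - f0)
        seq_rev = state_sequence(traj_rev, case.site_model)
        _, conductions_rev = pipeline(seq_rev)
        fwd_out = {str(c.ion_id) for c in conductions if c.direction == OUTWARD and not c.resident}
        rev_in = {str(c.ion_id) for c in conductions_rev if c.direction == INWARD and not c.resident}
        assert fwd_out == rev_in
        fwd_in = {str(c.ion_id) for c in conductions if c.direction == INWARD and not c.resident}
        rev_out = {str(c.ion_id) for c in conductions_rev if c.direction == OUTWARD and not c.resident}
        assert fwd_in == rev_out


class TestMechanismRatio:
    def make_events(self, n_push, n_pull, n_unclassified=0):
        events = []
        mechs = (
            [MECH_PUSH] * n_push + [MECH_PULL] * n_pull + [MECH_UNCLASSIFIED] * n_unclassified
        )
        for i, mech in enumerate(mechs):
            events.append(
                ConductionEvent(
                    ion_id=i,
                    direction=OUTWARD,
                    t_enter_ps=0.0,
                    t_exit_ps=float(i),
                    exit_frame=i,
                    mechanism=mech,
                )
            )
        return events

    def test_five_of_six(self):
        ratio = mechanism_ratio(self.make_events(5, 1))
        assert round(ratio.percent, 1) == 83.3

    def test_twelve_of_thirtythree(self):
        ratio = mechanism_ratio(self.make_events(12, 21))
        assert round(ratio.percent, 1) == 36.4

    def test_all_pull(self):
        assert mechanism_ratio(self.make_events(0, 4)).percent == 0.0

    def test_unclassified_excluded(self):
        ratio = mechanism_ratio(self.make_events(1, 1, n_unclassified=3))
        assert ratio.ratio == 0.5
        assert ratio.n_unclassified == 3

    def test_zero_classified_raises(self):
        with pytest.raises(UndefinedRatioError):
            mechanism_ratio(self.make_events(0, 0, n_unclassified=2))


class TestLifetimes:
    def make_event(self, mech, lifetime_ns):
        return ConductionEvent(
            ion_id=0,
            direction=OUTWARD,
            t_enter_ps=0.0,
            t_exit_ps=1.0,
            exit_frame=1,
            mechanism=mech,
            intermediate_lifetime_ps=lifetime_ns * 1000.0,
        )

    def test_singleton(self):
        dist = lifetime_distribution([self.make_event(MECH_PUSH, 2.0)])
        assert dist[MECH_PUSH]["mean_ns"] == pytest.approx(2.0)
        assert dist[MECH_PUSH]["n"] == 1

    def test_two_events_mean(self):
        events = [self.make_event(MECH_PULL, 1.0), self.make_event(MECH_PULL, 3.0)]
        dist = lifetime_distribution(events)
        assert dist[MECH_PULL]["mean_ns"] == pytest.approx(2.0)
        assert dist[MECH_PULL]["median_ns"] == pytest.approx(2.0)

    def test_exponential_intermediate_dwell(self, site_centers):
        # cycles whose two-ion intermediate dwell is drawn Exp(lam); the
        # measured per-event lifetimes must average 1/lam (closed form)
        lam = 0.5  # per ns
        interval = 10.0  # ps
        rng = np.random.default_rng(17)
        c = site_centers
        frames = []
        for i in range(80):
            top, nxt = f"top{i}", f"top{i+1}"
            resting = {top: c[0], "b": c[2], "x": c[4]}
            frames += [resting] * 3
            dwell_frames = max(1, int(np.ceil(rng.exponential(1.0 / lam) * 1000.0 / interval)))
            frames += [{"b": c[2], "x": c[4], top: EXTRA_Z}] * dwell_frames
            frames += [{"b": c[2], "x": c[4], nxt: c[6]}]
        frames += [{f"top{80}": c[0], "b": c[2], "x": c[4]}] * 3
        seq = seq_from_positions(frames, frame_interval=interval)
        _, conductions = pipeline(seq)
        pulls = [
            x.intermediate_lifetime_ps / 1000.0
            for x in conductions
            if x.mechanism == MECH_PULL and x.intermediate_lifetime_ps is not None
        ]
        assert len(pulls) == 80
        se = np.std(pulls, ddof=1) / np.sqrt(len(pulls))
        assert np.mean(pulls) == pytest.approx(1.0 / lam, abs=3 * se)

    def test_table_export(self):
        events = [self.make_event(MECH_PUSH, 2.0)]
        table = conductions_to_table(events)
        assert list(table.columns) == [
            "ion_id", "direction", "t_enter_ps", "t_exit_ps", "mechanism",
            "lifetime_ns", "resident",
        ]
        assert table["lifetime_ns"].iloc[0] == pytest.approx(2.0)
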