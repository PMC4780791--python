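"""Kinetic Monte Carlo generator of single-file ion-hopping trajectories.

A continuous-time Markov jump process over discrete binding sites (Gillespie
simulation): ions enter from infinite reservoirs at constant rates, hop
between adjacent sites with a voltage-bias factor, respect hard-core
exclusion (per-site capacities), and leave at the two pore mouths.  The
generator emits both a frame-sampled trajectory (site center plus Gaussian
jitter) and an exact ground-truth event log, from which conduction events
and their mechanism labels can be derived independently of the analysis
pipeline.

Sites are indexed internally by *slot*, 0 at the intracellular end to
``n - 1`` at the extracellular end; slot ``j`` corresponds to site number
``S(n - 1 - j)``.
"""

from __future__ import annotations

import dataclasses
from typing import Hashable, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .site_model import SiteModel, default_capacities
from .trajectory_io import IonTrajectory

EV_ENTRY = "entry"
EV_EXIT = "exit"
EV_HOP = "hop"


@dataclasses.dataclass
class HopModel:
    """Rates and geometry of the hopping process.

    Rates are per ns and per ion.  ``bias`` is the dimensionless work per hop
    along the field: hops toward the extracellular side are multiplied by
    ``exp(+bias/2)`` and hops back by ``exp(-bias/2)``.  ``depths`` damp the
    escape rate out of a site by ``exp(-depth)`` (deep wells hold ions).
    ``repulsion`` is a nearest-neighbor push term: a hop away from an
    occupied adjacent site (and an exit with the neighboring site occupied)
    is accelerated by ``exp(repulsion * n_neighbors)`` — the knock-on
    ingredient that lets incoming ions expel the outermost one.
    """

    site_centers: np.ndarray  # ascending z (Angstrom), slot 0 = intracellular end
    depths: np.ndarray
    k0: float = 20.0
    bias: float = 1.0
    k_in_intra: float = 2.0
    k_in_extra: float = 0.0
    k_out_intra: float = 0.2
    k_out_extra: float = 2.0
    repulsion: float = 0.0
    capacities: np.ndarray | None = None
    jitter: float = 0.25
    p_reenter_intra: float = 0.0
    p_reenter_extra: float = 0.0
    initial_slots: tuple[int, ...] = ()
    temperature: float = 300.0

    def __post_init__(self) -> None:
        self.site_centers = np.asarray(self.site_centers, dtype=float)
        self.depths = np.asarray(self.depths, dtype=float)
        n = len(self.site_centers)
        if len(self.depths) != n:
            raise ValidationError("depths must match site_centers in length")
        if n >= 2 and np.any(np.diff(self.site_centers) <= 0):
            raise ValidationError("site centers must be strictly increasing in z")
        if self.capacities is None:
            caps = np.ones(n, dtype=int)
            caps[-1] = 2  # outermost site (S0) can hold two ions
            self.capacities = caps
        else:
            self.capacities = np.asarray(self.capacities, dtype=int)
        for rate in (
            self.k0,
            self.k_in_intra,
            self.k_in_extra,
            self.k_out_intra,
            self.k_out_extra,
        ):
            if rate < 0 or not np.isfinite(rate):
                raise ValidationError("rates must be finite and non-negative")

    @property
    def n_sites(self) -> int:
        return len(self.site_centers)

    def s_number(self, slot: int) -> int:
        return self.n_sites - 1 - slot

    def min_gap(self) -> float:
        return float(np.min(np.diff(self.site_centers)))

    def site_model(self) -> SiteModel:
        """SiteModel whose thresholds are the midpoints between site centers."""
        c = self.site_centers
        mids = 0.5 * (c[:-1] + c[1:])
        lo = c[0] - (mids[0] - c[0]) if len(c) > 1 else c[0] - 1.0
        hi = c[-1] + (c[-1] - mids[-1]) if len(c) > 1 else c[-1] + 1.0
        thresholds = np.concatenate([[lo], mids, [hi]])
        caps = {self.s_number(j): int(self.capacities[j]) for j in range(self.n_sites)}
        return SiteModel(thresholds=thresholds, site_capacity=caps)

    def region_name(self, slot: int) -> str:
        return f"S{self.s_number(slot)}"


@dataclasses.dataclass
class GroundTruth:
    """Exact event log of one simulation plus derived conduction labels."""

    events: pd.DataFrame  # time_ps, ion_id, kind, from_region, to_region
    initial_ions: dict  # ion_id -> slot at t = 0
    t_end_ps: float
    resting_count: int = 3

    def conductions(self, resting_count: int | None = None) -> pd.DataFrame:
        """Replay the exact log into completed conductions with labels.

        Mechanism classification uses the same kinetic criterion as the
        pipeline — ion count just before the exit versus the resting count —
        but operates on exact event times, never on sampled frames.
        """
        resting = self.resting_count if resting_count is None else resting_count
        ev = self.events
        mask = ev["kind"].isin([EV_ENTRY, EV_EXIT])
        changes = ev.loc[mask].reset_index(drop=True)
        count = len(self.initial_ions)
        count_times = [0.0]
        count_values = [count]
        rows = []
        entry_side: dict[Hashable, str | None] = {i: None for i in self.initial_ions}
        entry_time: dict[Hashable, float] = {i: 0.0 for i in self.initial_ions}
        for _, e in changes.iterrows():
            ion = e["ion_id"]
            if e["kind"] == EV_ENTRY:
                count += 1
                entry_side[ion] = "intra" if e["from_region"] == "INTRA" else "extra"
                entry_time[ion] = e["time_ps"]
            else:
                count_before = count
                count -= 1
                exit_side = "intra" if e["to_region"] == "INTRA" else "extra"
                side_in = entry_side.get(ion)
                resident = side_in is None
                if resident or side_in != exit_side:
                    rows.append(
                        {
                            "ion_id": ion,
                            "direction": "outward" if exit_side == "extra" else "inward",
                            "t_enter_ps": entry_time.get(ion, 0.0),
                            "t_exit_ps": e["time_ps"],
                            "count_before": count_before,
                            "resident": resident,
                        }
                    )
                entry_side[ion] = None
            count_times.append(float(e["time_ps"]))
            count_values.append(count)

        ct = np.asarray(count_times)
        cv = np.asarray(count_values)
        out = []
        for row in rows:
            k = int(np.searchsorted(ct, row["t_exit_ps"], side="left"))
            # indices: cv[k] is the count right after this exit
            mech, lifetime = _mechanism_from_series(ct, cv, k, resting, self.t_end_ps)
            row["mechanism"] = mech
            row["lifetime_ps"] = lifetime
            out.append(row)
        columns = [
            "ion_id",
            "direction",
            "t_enter_ps",
            "t_exit_ps",
            "count_before",
            "resident",
            "mechanism",
            "lifetime_ps",
        ]
        return pd.DataFrame(out, columns=columns)

    def net_crossings(self) -> int:
        conds = self.conductions()
        if len(conds) == 0:
            return 0
        return int((conds["direction"] == "outward").sum() - (conds["direction"] == "inward").sum())

    def occupancy_log(self) -> pd.DataFrame:
        """(time_ps, ion count) step series from the exact log."""
        ev = self.events
        mask = ev["kind"].isin([EV_ENTRY, EV_EXIT])
        steps = ev.loc[mask, ["time_ps", "kind"]].reset_index(drop=True)
        delta = np.where(steps["kind"] == EV_ENTRY, 1, -1)
        counts = len(self.initial_ions) + np.cumsum(delta)
        return pd.DataFrame({"time_ps": steps["time_ps"], "count": counts})

    def to_csv(self, path) -> None:
        out = self.events.copy()
        out.insert(0, "time_ns", out.pop("time_ps") / 1000.0)
        out.to_csv(path, index=False)


def _mechanism_from_series(
    ct: np.ndarray, cv: np.ndarray, k: int, resting: int, t_end_ps: float
) -> tuple[str, float | None]:
    """Classify the excursion of the exact count series containing event k."""
    count_before = cv[k - 1] if k >= 1 else cv[0]
    mech = "III-IV-III" if count_before > resting else "III-II-III"
    # opening: last moment the count departed from resting at or before t_exit
    if count_before == resting:
        t_leave = ct[k]
    else:
        g = k - 1
        while g >= 0 and cv[g] != resting:
            g -= 1
        t_leave = ct[g + 1] if g >= 0 else ct[0]
    # closing: first return to resting at or after t_exit
    if cv[k] == resting:
        t_return = ct[k]
    else:
        h = k
        while h < len(cv) and cv[h] != resting:
            h += 1
        if h == len(cv):
            return mech, None  # cycle still open at the end of the run
        t_return = ct[h]
    return mech, float(t_return - t_leave)


def simulate(
    model: HopModel,
    t_end_ns: float,
    seed: int,
    frame_interval_ps: float = 10.0,
) -> tuple[IonTrajectory, GroundTruth]:
    """Gillespie simulation of the hopping model.

    Returns the frame-sampled trajectory (z = site center + Gaussian jitter)
    and the exact ground-truth log.  Sub-frame events are intentionally
    invisible in the trajectory; the log records everything.
    """
    if t_end_ns <= 0:
        raise ValidationError("t_end must be positive")
    if model.n_sites >= 2 and model.jitter >= model.min_gap() / 2:
        raise ValidationError(
            f"jitter sigma {model.jitter} too large for the minimal inter-site "
            f"gap {model.min_gap()}; site assignment would be corrupted"
        )
    rng = np.random.default_rng(seed)
    n = model.n_sites
    caps = model.capacities
    up = model.k0 * np.exp(-model.depths) * np.exp(+model.bias / 2.0)
    down = model.k0 * np.exp(-model.depths) * np.exp(-model.bias / 2.0)

    slots: list[list] = [[] for _ in range(n)]
    next_ion = 0
    for slot in model.initial_slots:
        slots[slot].append(next_ion)
        next_ion += 1
    initial_ions = {ion: slot for slot in range(n) for ion in slots[slot]}
    recently_exited = {"intra": [], "extra": []}

    log_rows: list[tuple] = []
    frame_rows: list[tuple] = []
    t_end_ps = t_end_ns * 1000.0
    n_frames = int(np.floor(t_end_ps / frame_interval_ps)) + 1

    def emit_frames(until_frame: int, first_frame: int) -> None:
        for f in range(first_frame, until_frame):
            t = f * frame_interval_ps
            for slot in range(n):
                for ion in slots[slot]:
                    z = model.site_centers[slot] + rng.normal(0.0, model.jitter)
                    frame_rows.append((f, t, ion, z))

    t_ps = 0.0
    next_frame = 0
    while True:
        # enumerate allowed moves: (rate, mover) pairs
        moves: list[tuple[float, tuple]] = []
        rep = model.repulsion
        for j in range(n):
            occ = len(slots[j])
            if occ == 0:
                continue
            if j + 1 < n and len(slots[j + 1]) < caps[j + 1]:
                push = np.exp(rep * len(slots[j - 1])) if (rep and j - 1 >= 0) else 1.0
                moves.append((occ * up[j] * push, ("hop", j, j + 1)))
            if j - 1 >= 0 and len(slots[j - 1]) < caps[j - 1]:
                push = np.exp(rep * len(slots[j + 1])) if (rep and j + 1 < n) else 1.0
                moves.append((occ * down[j] * push, ("hop", j, j - 1)))
        if model.k_in_intra > 0 and len(slots[0]) < caps[0]:
            moves.append((model.k_in_intra, ("entry", "intra")))
        if model.k_in_extra > 0 and len(slots[n - 1]) < caps[n - 1]:
            moves.append((model.k_in_extra, ("entry", "extra")))
        if model.k_out_intra > 0 and len(slots[0]) > 0:
            push = np.exp(rep * len(slots[1])) if (rep and n > 1) else 1.0
            moves.append((len(slots[0]) * model.k_out_intra * push, ("exit", "intra")))
        if model.k_out_extra > 0 and len(slots[n - 1]) > 0:
            push = np.exp(rep * len(slots[n - 2])) if (rep and n > 1) else 1.0
            moves.append(
                (len(slots[n - 1]) * model.k_out_extra * push, ("exit", "extra"))
            )

        if not moves:
            break
        rates = np.array([m[0] for m in moves])
        total = rates.sum()
        if total <= 0:
            break
        dt_ns = rng.exponential(1.0 / total)
        t_new = t_ps + dt_ns * 1000.0
        if t_new >= t_end_ps:
            break
        # sample frames crossed before this event fires
        frames_due = int(np.floor(t_new / frame_interval_ps)) + 1
        if frames_due > next_frame:
            emit_frames(min(frames_due, n_frames), next_frame)
            next_frame = min(frames_due, n_frames)
        t_ps = t_new

        choice = moves[rng.choice(len(moves), p=rates / total)][1]
        if choice[0] == "hop":
            _, src, dst = choice
            pick = rng.integers(len(slots[src]))
            ion = slots[src].pop(pick)
            slots[dst].append(ion)
            log_rows.append(
                (t_ps, ion, EV_HOP, model.region_name(src), model.region_name(dst))
            )
        elif choice[0] == "entry":
            side = choice[1]
            p_re = model.p_reenter_intra if side == "intra" else model.p_reenter_extra
            pool = recently_exited[side]
            if pool and rng.random() < p_re:
                ion = pool.pop()
            else:
                ion = next_ion
                next_ion += 1
            slot = 0 if side == "intra" else n - 1
            slots[slot].append(ion)
            log_rows.append(
                (
                    t_ps,
                    ion,
                    EV_ENTRY,
                    "INTRA" if side == "intra" else "EXTRA",
                    model.region_name(slot),
                )
            )
        else:  # exit
            side = choice[1]
            slot = 0 if side == "intra" else n - 1
            pick = rng.integers(len(slots[slot]))
            ion = slots[slot].pop(pick)
            recently_exited[side].append(ion)
            log_rows.append(
                (
                    t_ps,
                    ion,
                    EV_EXIT,
                    model.region_name(slot),
                    "INTRA" if side == "intra" else "EXTRA",
                )
            )

    emit_frames(n_frames, next_frame)

    frames = pd.DataFrame(frame_rows, columns=["frame", "time_ps", "ion_id", "z"])
    if len(frames) == 0:
        # pore empty for the whole run: keep the grid with two sentinel-free
        # frames so downstream code still sees a (trivial) trajectory
        raise ValidationError(
            "simulation produced an empty trajectory (pore never occupied); "
            "seed ions or raise entry rates"
        )
    traj = IonTrajectory.from_table(frames)
    traj.frame_range = (0, n_frames - 1)  # grid is known exactly for synthetic runs
    log = pd.DataFrame(
        log_rows, columns=["time_ps", "ion_id", "kind", "from_region", "to_region"]
    )
    truth = GroundTruth(events=log, initial_ions=initial_ions, t_end_ps=t_end_ps)
    return traj, truth


# -- canonical models -------------------------------------------------------


def baseline_model(**overrides) -> HopModel:
    """Seven-site model with deep wells at S4, S2, S0 and a K:0:2:4 resting state."""
    params = dict(
        site_centers=np.array([-9.0, 0.0, 3.0, 6.0, 9.0, 12.0, 15.0]),
        depths=np.array([0.0, 0.0, 3.5, 0.0, 3.5, 0.0, 3.5]),
        k0=20.0,
        bias=1.0,
        k_in_intra=0.4,
        k_in_extra=0.0,
        k_out_intra=0.05,
        k_out_extra=0.4,
        repulsion=2.5,
        jitter=0.25,
        initial_slots=(2, 4, 6),  # S4, S2, S0
    )
    params.update(overrides)
    return HopModel(**params)


def make_push_regime(strength: float, **overrides) -> HopModel:
    """Entry-dominated model: associations outpace dissociations.

    ``strength`` scales entry up and exit down by a factor ``1 + strength``;
    strength 0 is the baseline.
    """
    if strength < 0:
        raise ValidationError("strength must be non-negative")
    base = baseline_model(**overrides)
    base.k_in_intra *= 1.0 + strength
    return base


def make_pull_regime(strength: float, **overrides) -> HopModel:
    """Exit-dominated model: the outermost ion leaves before replacement."""
    if strength < 0:
        raise ValidationError("strength must be non-negative")
    base = baseline_model(**overrides)
    base.k_out_extra *= 1.0 + strength
    return base


def make_inward_regime(strength: float = 5.0, **overrides) -> HopModel:
    """Inward-biased model: entry from the extracellular side, exit intracellular."""
    f = 1.0 + strength
    params = dict(
        bias=-1.2,
        k_in_intra=0.1,
        k_in_extra=0.5 * f,
        k_out_intra=0.5 * f,
        k_out_extra=0.1,
    )
    params.update(overrides)
    return baseline_model(**params)


def make_backrun_model(**overrides) -> HopModel:
    """Model whose extracellular exits are re-entered by the same ion.

    With the intracellular mouth closed and an initially empty pore, every
    ion both enters and leaves on the extracellular side: pure back-running,
    zero conductions.
    """
    params = dict(
        bias=0.3,
        k_in_intra=0.0,
        k_in_extra=2.0,
        k_out_intra=0.0,
        k_out_extra=2.0,
        repulsion=0.0,
        p_reenter_extra=1.0,
        initial_slots=(),
    )
    params.update(overrides)
    return baseline_model(**params)


@dataclasses.dataclass
class FixtureCase:
    name: str
    model: HopModel
    trajectory: IonTrajectory
    ground_truth: GroundTruth
    site_model: SiteModel


def fixture_suite(seed: int = 1) -> dict[str, FixtureCase]:
    """Deterministic set of small named trajectories with ground truth.

    Cases: ``push`` and ``pull`` (strong regimes), ``mixed`` (baseline),
    ``inward`` (negative current) and ``backrun`` (same-side exit/re-entry,
    zero conductions).  Bit-identical for a given seed.
    """
    cases = {
        "push": (make_push_regime(9.0), 150.0),
        "pull": (make_pull_regime(9.0), 150.0),
        "mixed": (baseline_model(), 150.0),
        "inward": (make_inward_regime(5.0), 100.0),
        "backrun": (make_backrun_model(), 50.0),
    }
    out = {}
    for i, (name, (model, t_end)) in enumerate(cases.items()):
        traj, truth = simulate(model, t_end_ns=t_end, seed=seed + i, frame_interval_ps=10.0)
        out[name] = FixtureCase(
            name=name,
            model=model,
            trajectory=traj,
            ground_truth=truth,
            site_model=model.site_model(),
        )
    return out
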