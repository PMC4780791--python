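"""Boundary crossings, completed conductions, and mechanism classification.

A conduction is completed when an ion that entered the pore from one
reservoir leaves it to the other.  Same-side exit/re-entry ("back-running")
yields no conduction.  Mechanism classification is kinetic: it compares the
number of pore-bound ions just before the permeating ion's exit against the
resting count.  Above resting means the exit was pushed by an earlier
association (a four-ion intermediate for outward events, the III-IV-III
mechanism); at or below resting means the exit preceded the replacement
association (two-ion intermediate, III-II-III).
"""

from __future__ import annotations

import dataclasses
from typing import Hashable, Sequence

import numpy as np
import pandas as pd

from .errors import UndefinedRatioError, ValidationError
from .site_model import EXTRA, INTRA
from .state_analysis import StateSequence

ASSOC_INTRA = "assoc_intra"
DISSOC_EXTRA = "dissoc_extra"
ASSOC_EXTRA = "assoc_extra"
DISSOC_INTRA = "dissoc_intra"

MECH_PUSH = "III-IV-III"
MECH_PULL = "III-II-III"
MECH_UNCLASSIFIED = "unclassified"

OUTWARD = "outward"
INWARD = "inward"


@dataclasses.dataclass(frozen=True)
class BoundaryEvent:
    """One pore-boundary crossing, timestamped at the arrival frame."""

    time_ps: float
    frame: int
    ion_id: Hashable
    kind: str  # one of ASSOC_INTRA, DISSOC_EXTRA, ASSOC_EXTRA, DISSOC_INTRA


@dataclasses.dataclass
class ConductionEvent:
    """One completed permeation of a single ion."""

    ion_id: Hashable
    direction: str  # OUTWARD | INWARD
    t_enter_ps: float
    t_exit_ps: float
    exit_frame: int
    mechanism: str = MECH_UNCLASSIFIED
    intermediate_lifetime_ps: float | None = None
    resident: bool = False  # ion was already in the pore at the first frame


def _side_of_site(site: int, n_sites: int) -> str:
    """Nearest reservoir for a site: low numbers sit at the extracellular end."""
    return "extra" if site <= (n_sites - 1) / 2 else "intra"


def boundary_events(seq: StateSequence) -> list[BoundaryEvent]:
    """Detect all pore-boundary crossings from ion-identity bookkeeping.

    For every pair of consecutive frames, each ion's region (a site, INTRA,
    EXTRA, or untracked) is compared.  Entering or leaving the pore produces
    one event; the reservoir side is taken from the tracked bulk region when
    available and otherwise inferred from the nearest boundary of the first
    (or last) occupied site.  Bulk-to-bulk and untracked moves produce
    nothing; sub-frame round trips are invisible by design.
    """
    n = seq.n_sites
    events: list[BoundaryEvent] = []

    def regions(rec) -> dict:
        reg: dict = {}
        for s, occ in rec.occupants.items():
            for ion in occ:
                reg[ion] = s
        reg.update(rec.bulk)
        return reg

    prev = regions(seq[0]) if len(seq) else {}
    for rec in seq.records[1:]:
        cur = regions(rec)
        for ion in prev.keys() | cur.keys():
            p = prev.get(ion)
            c = cur.get(ion)
            p_pore = isinstance(p, (int, np.integer))
            c_pore = isinstance(c, (int, np.integer))
            kind = None
            if p_pore and not c_pore:
                side = (
                    "intra" if c == INTRA else "extra" if c == EXTRA else _side_of_site(p, n)
                )
                kind = DISSOC_INTRA if side == "intra" else DISSOC_EXTRA
            elif c_pore and not p_pore:
                side = (
                    "intra" if p == INTRA else "extra" if p == EXTRA else _side_of_site(c, n)
                )
                kind = ASSOC_INTRA if side == "intra" else ASSOC_EXTRA
            if kind is not None:
                events.append(
                    BoundaryEvent(time_ps=rec.time_ps, frame=rec.frame, ion_id=ion, kind=kind)
                )
        prev = cur
    events.sort(key=lambda e: (e.time_ps, str(e.ion_id)))
    return events


_ENTRY_SIDE = {ASSOC_INTRA: "intra", ASSOC_EXTRA: "extra"}
_EXIT_SIDE = {DISSOC_INTRA: "intra", DISSOC_EXTRA: "extra"}


def detect_conductions(
    events: Sequence[BoundaryEvent], t_start: float = 0.0
) -> list[ConductionEvent]:
    """Pair entries and exits per ion into completed conductions.

    Back-running (exit and re-entry on the same side) produces no event.
    Ions resident in the pore before the first frame are counted when they
    exit, with ``t_enter_ps = t_start`` and ``resident=True``.
    """
    per_ion: dict[Hashable, list[BoundaryEvent]] = {}
    for ev in events:
        per_ion.setdefault(ev.ion_id, []).append(ev)

    conductions: list[ConductionEvent] = []
    for ion, evs in per_ion.items():
        entry_side: str | None = None
        entered = False
        t_enter = t_start
        for ev in evs:
            if ev.kind in _ENTRY_SIDE:
                entry_side = _ENTRY_SIDE[ev.kind]
                entered = True
                t_enter = ev.time_ps
            else:
                exit_side = _EXIT_SIDE[ev.kind]
                if not entered:
                    conductions.append(
                        ConductionEvent(
                            ion_id=ion,
                            direction=OUTWARD if exit_side == "extra" else INWARD,
                            t_enter_ps=t_start,
                            t_exit_ps=ev.time_ps,
                            exit_frame=ev.frame,
                            resident=True,
                        )
                    )
                elif entry_side != exit_side:
                    conductions.append(
                        ConductionEvent(
                            ion_id=ion,
                            direction=OUTWARD if exit_side == "extra" else INWARD,
                            t_enter_ps=t_enter,
                            t_exit_ps=ev.time_ps,
                            exit_frame=ev.frame,
                        )
                    )
                # same-side exit+entry = back-running: nothing recorded
                entered = False
                entry_side = None
        # ion still inside at the end: no conduction
    conductions.sort(key=lambda c: (c.t_exit_ps, str(c.ion_id)))
    return conductions


def classify_mechanism(
    conduction: ConductionEvent, seq: StateSequence, resting_count: int = 3
) -> ConductionEvent:
    """Assign a mechanism and intermediate lifetime to one conduction.

    The mechanism follows from the ion count on the last frame before the
    exit: above ``resting_count`` means the replacement ion had already
    associated (push); at or below means the dissociation came first (pull).
    The intermediate is the maximal excursion of the pore ion count away from
    ``resting_count`` containing the exit: it opens when the count last left
    resting at or before the exit and closes when the count first returns to
    resting at or after it.  If the excursion is still open when the sequence
    ends (trajectory stops mid-cycle) the lifetime is undefined (None); an
    exit at the very first transition cannot be classified at all.
    """
    counts = seq.ion_counts
    times = seq.times
    f0 = seq[0].frame
    idx_exit = conduction.exit_frame - f0  # first frame with the ion outside
    f = idx_exit - 1  # last frame with the ion inside
    if f < 0 or idx_exit >= len(counts):
        conduction.mechanism = MECH_UNCLASSIFIED
        conduction.intermediate_lifetime_ps = None
        return conduction

    count_before = counts[f]
    conduction.mechanism = MECH_PUSH if count_before > resting_count else MECH_PULL

    # opening time of the excursion
    if count_before == resting_count:
        t_leave = times[idx_exit]  # the exit itself leaves the resting count
    else:
        g = f
        while g >= 0 and counts[g] != resting_count:
            g -= 1
        t_leave = times[g + 1] if g >= 0 else times[0]

    # closing time
    if counts[idx_exit] == resting_count:
        t_return = times[idx_exit]
    else:
        h = idx_exit
        while h < len(counts) and counts[h] != resting_count:
            h += 1
        if h == len(counts):
            # cycle still open at the end of the trajectory
            conduction.intermediate_lifetime_ps = None
            return conduction
        t_return = times[h]

    conduction.intermediate_lifetime_ps = float(t_return - t_leave)
    return conduction


def classify_all(
    conductions: Sequence[ConductionEvent], seq: StateSequence, resting_count: int = 3
) -> list[ConductionEvent]:
    return [classify_mechanism(c, seq, resting_count) for c in conductions]


@dataclasses.dataclass(frozen=True)
class MechanismRatio:
    n_push: int
    n_pull: int
    n_unclassified: int

    @property
    def ratio(self) -> float:
        return self.n_push / (self.n_push + self.n_pull)

    @property
    def percent(self) -> float:
        return 100.0 * self.ratio


def mechanism_ratio(conductions: Sequence[ConductionEvent]) -> MechanismRatio:
    """Fraction of push (III-IV-III) conductions among classified events."""
    n_push = sum(1 for c in conductions if c.mechanism == MECH_PUSH)
    n_pull = sum(1 for c in conductions if c.mechanism == MECH_PULL)
    n_un = sum(1 for c in conductions if c.mechanism == MECH_UNCLASSIFIED)
    if n_push + n_pull == 0:
        raise UndefinedRatioError("no classified conduction events")
    return MechanismRatio(n_push=n_push, n_pull=n_pull, n_unclassified=n_un)


def lifetime_distribution(
    conductions: Sequence[ConductionEvent], n_bins: int = 10
) -> dict[str, dict]:
    """Per-mechanism summaries of the intermediate lifetimes, in ns."""
    out: dict[str, dict] = {}
    for mech in (MECH_PUSH, MECH_PULL):
        lifetimes = np.array(
            [
                c.intermediate_lifetime_ps / 1000.0
                for c in conductions
                if c.mechanism == mech and c.intermediate_lifetime_ps is not None
            ]
        )
        if len(lifetimes) == 0:
            continue
        counts, edges = np.histogram(lifetimes, bins=n_bins)
        out[mech] = {
            "n": int(len(lifetimes)),
            "mean_ns": float(lifetimes.mean()),
            "q1_ns": float(np.percentile(lifetimes, 25)),
            "median_ns": float(np.percentile(lifetimes, 50)),
            "q3_ns": float(np.percentile(lifetimes, 75)),
            "hist_counts": counts.tolist(),
            "hist_edges_ns": edges.tolist(),
        }
    if not out:
        raise UndefinedRatioError("no classified conduction events")
    return out


def conductions_to_table(conductions: Sequence[ConductionEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "ion_id": [c.ion_id for c in conductions],
            "direction": [c.direction for c in conductions],
            "t_enter_ps": [c.t_enter_ps for c in conductions],
            "t_exit_ps": [c.t_exit_ps for c in conductions],
            "mechanism": [c.mechanism for c in conductions],
            "lifetime_ns": [
                (c.intermediate_lifetime_ps / 1000.0)
                if c.intermediate_lifetime_ps is not None
                else np.nan
                for c in conductions
            ],
            "resident": [c.resident for c in conductions],
        }
    )


def events_to_table(events: Sequence[BoundaryEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "time_ps": [e.time_ps for e in events],
            "frame": [e.frame for e in events],
            "ion_id": [e.ion_id for e in events],
            "kind": [e.kind for e in events],
        }
    )
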