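"""Per-frame ion-binding states and the state-transition graph.

A binding state is the multiset of occupied sites at one frame, written
``K:`` followed by the sorted site numbers joined with colons, with
repetition for multiply-occupied sites (``K:0:2:4``; ``K:0:0:2:4`` for two
ions in S0).  Ions in the bulk regions (INTRA/EXTRA) are excluded from the
label but remembered per frame so that boundary crossings can be attributed
to ion identities downstream.
"""

from __future__ import annotations

import dataclasses
import warnings
from collections import Counter, defaultdict
from typing import Hashable, Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import CapacityError, EmptyTrajectoryError, ValidationError
from .site_model import EXTRA, INTRA, SiteModel
from .trajectory_io import IonTrajectory

EMPTY_LABEL = "K:"

#: Edge flags on the state graph.  ``influx``/``efflux`` mark the outward
#: conduction boundaries (new ion from INTRA into the pore / ion leaving the
#: pore to EXTRA); ``entry_extra``/``exit_intra`` are the mirrored flags used
#: for inward analysis.
FLAG_INFLUX = "influx"
FLAG_EFFLUX = "efflux"
FLAG_ENTRY_EXTRA = "entry_extra"
FLAG_EXIT_INTRA = "exit_intra"
FLAG_INTERNAL = "internal"
FLAG_AMBIGUOUS = "ambiguous"


def state_label(sites: Iterable[int]) -> str:
    """Canonical label of an occupancy multiset; pure function of the multiset."""
    return "K:" + ":".join(str(s) for s in sorted(sites)) if sites else EMPTY_LABEL


@dataclasses.dataclass(frozen=True)
class FrameState:
    """Binding state of one frame plus the identity bookkeeping."""

    frame: int
    time_ps: float
    label: str
    sites: tuple[int, ...]  # sorted site numbers with multiplicity
    occupants: Mapping[int, tuple]  # site number -> ion ids at that site
    bulk: Mapping[Hashable, str]  # ion id -> INTRA | EXTRA for tracked bulk ions

    @property
    def ion_count(self) -> int:
        return len(self.sites)


@dataclasses.dataclass
class StateSequence:
    """Uniformly spaced sequence of :class:`FrameState` records."""

    records: list[FrameState]
    frame_interval: float
    n_sites: int

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]

    @property
    def times(self) -> np.ndarray:
        return np.array([r.time_ps for r in self.records])

    @property
    def labels(self) -> list[str]:
        return [r.label for r in self.records]

    @property
    def ion_counts(self) -> np.ndarray:
        return np.array([r.ion_count for r in self.records], dtype=np.int64)

    def to_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": [r.frame for r in self.records],
                "time_ps": [r.time_ps for r in self.records],
                "label": self.labels,
                "ion_count": self.ion_counts,
            }
        )


def state_sequence(
    traj: IonTrajectory, model: SiteModel, min_dwell: int = 1
) -> StateSequence:
    """Convert a trajectory into per-frame binding states.

    Frames absent from the table (empty pore) get the empty state ``K:``.
    ``min_dwell`` > 1 applies an optional debounce: any run of identical
    states shorter than ``min_dwell`` frames is merged into the preceding
    state, suppressing threshold-crossing flicker.
    """
    if len(traj.frames) == 0:
        raise EmptyTrajectoryError("cannot build states from an empty trajectory")
    df = traj.frames
    region = model.region_index(df["z"].to_numpy())
    n = model.n_sites
    site = n - region  # S-number; valid only where 1 <= region <= n

    f0, f1, t0 = traj._grid()
    interval = traj.frame_interval

    by_frame: dict[int, list[tuple[Hashable, int, int]]] = defaultdict(list)
    ions = df["ion_id"].to_numpy()
    frames_col = df["frame"].to_numpy()
    for i in range(len(df)):
        by_frame[int(frames_col[i])].append((ions[i], int(region[i]), int(site[i])))

    records: list[FrameState] = []
    for f in range(f0, f1 + 1):
        time_ps = t0 + (f - f0) * interval
        occupants: dict[int, list] = defaultdict(list)
        bulk: dict[Hashable, str] = {}
        for ion, r, s in by_frame.get(f, ()):
            if r == 0:
                bulk[ion] = INTRA
            elif r == n + 1:
                bulk[ion] = EXTRA
            else:
                occupants[s].append(ion)
        for s, occ in occupants.items():
            cap = model.site_capacity.get(s, 1)
            if len(occ) > cap:
                raise CapacityError(
                    f"site S{s} holds {len(occ)} ions (> capacity {cap}) "
                    f"at frame {f} (t = {time_ps} ps): {occ}"
                )
        sites = tuple(sorted(s for s, occ in occupants.items() for _ in occ))
        records.append(
            FrameState(
                frame=f,
                time_ps=time_ps,
                label=state_label(sites),
                sites=sites,
                occupants={s: tuple(o) for s, o in occupants.items()},
                bulk=bulk,
            )
        )

    if min_dwell > 1:
        records = _debounce(records, min_dwell)
    return StateSequence(records=records, frame_interval=interval, n_sites=n)


def _debounce(records: list[FrameState], min_dwell: int) -> list[FrameState]:
    """Merge state runs shorter than ``min_dwell`` into the preceding state."""
    out = list(records)
    i = 0
    while i < len(out):
        j = i
        while j < len(out) and out[j].label == out[i].label:
            j += 1
        if 0 < i and (j - i) < min_dwell:
            keeper = out[i - 1]
            for k in range(i, j):
                out[k] = dataclasses.replace(
                    keeper, frame=out[k].frame, time_ps=out[k].time_ps
                )
            # re-scan from the merged run's start so adjacent runs coalesce
            i = i - 1
            while i > 0 and out[i - 1].label == out[i].label:
                i -= 1
            continue
        i = j
    return out


def build_graph(seq: StateSequence) -> nx.DiGraph:
    """Aggregate a state sequence into a directed transition graph.

    Nodes carry ``occupancy`` (fraction of frames), ``ion_count`` and later a
    ``group`` tag; edges carry ``count`` and a ``flag`` (dominant) plus the
    full ``flag_counts``.  Transitions where ions cross more than one pore
    boundary within a single frame interval are ambiguous and counted as
    internal, with a warning.
    """
    if len(seq) == 0:
        raise EmptyTrajectoryError("cannot build a graph from an empty sequence")
    from .conduction_events import boundary_events  # local: avoids import cycle

    n_frames = len(seq)
    graph = nx.DiGraph()
    occ = Counter(seq.labels)
    count_of: dict[str, int] = {}
    for rec in seq:
        count_of.setdefault(rec.label, rec.ion_count)
    for label, c in occ.items():
        graph.add_node(
            label, occupancy=c / n_frames, ion_count=count_of[label], group="other"
        )

    events_by_frame: dict[int, set[str]] = defaultdict(set)
    for ev in boundary_events(seq):
        events_by_frame[ev.frame].add(ev.kind)

    kind_to_flag = {
        "assoc_intra": FLAG_INFLUX,
        "dissoc_extra": FLAG_EFFLUX,
        "assoc_extra": FLAG_ENTRY_EXTRA,
        "dissoc_intra": FLAG_EXIT_INTRA,
    }
    n_ambiguous = 0
    for prev, cur in zip(seq.records[:-1], seq.records[1:]):
        if prev.label == cur.label:
            continue
        kinds = events_by_frame.get(cur.frame, set())
        flags = {kind_to_flag[k] for k in kinds}
        if len(flags) == 0:
            flag = FLAG_INTERNAL
        elif len(flags) == 1:
            flag = next(iter(flags))
        else:
            flag = FLAG_AMBIGUOUS
            n_ambiguous += 1
        if not graph.has_edge(prev.label, cur.label):
            graph.add_edge(prev.label, cur.label, count=0, flag_counts=Counter())
        data = graph[prev.label][cur.label]
        data["count"] += 1
        data["flag_counts"][flag] += 1
    if n_ambiguous:
        warnings.warn(
            f"{n_ambiguous} transition(s) crossed two pore boundaries within one "
            "frame interval; flagged ambiguous and treated as internal",
            stacklevel=2,
        )
    for _, _, data in graph.edges(data=True):
        fc = data["flag_counts"]
        effective = Counter(
            {(FLAG_INTERNAL if f == FLAG_AMBIGUOUS else f): c for f, c in fc.items()}
        )
        data["flag"] = effective.most_common(1)[0][0]

    graph.graph["n_frames"] = n_frames
    graph.graph["frame_labels"] = list(seq.labels)
    graph.graph["frame_counts"] = seq.ion_counts
    graph.graph["frame_interval"] = seq.frame_interval
    return graph


def group_states(graph: nx.DiGraph, resting_count: int = 3) -> nx.DiGraph:
    """Tag every node with a group: II, IIIr, IIIe, IV, V or other.

    Counts relative to the resting ion count define II (one fewer), IV (one
    more) and V (two or more extra).  Resting-count states split temporally:
    frames reached right after an excursion of the ion count, before the
    modal (most occupied) resting state is regained, vote IIIe; all other
    resting-count frames vote IIIr.  Each node takes its majority vote; the
    modal state itself is always IIIr.
    """
    labels: Sequence[str] = graph.graph["frame_labels"]
    counts: np.ndarray = graph.graph["frame_counts"]

    resting_nodes = [
        node for node, d in graph.nodes(data=True) if d["ion_count"] == resting_count
    ]
    modal = None
    if resting_nodes:
        modal = max(resting_nodes, key=lambda s: graph.nodes[s]["occupancy"])

    votes: dict[str, Counter] = defaultdict(Counter)
    entrance = False
    for i, (lab, c) in enumerate(zip(labels, counts)):
        if c != resting_count:
            continue
        if i > 0 and counts[i - 1] != resting_count:
            entrance = True
        if lab == modal:
            entrance = False
        votes[lab][("IIIe" if entrance else "IIIr")] += 1

    for node, data in graph.nodes(data=True):
        c = data["ion_count"]
        if c == resting_count - 1:
            data["group"] = "II"
        elif c == resting_count + 1:
            data["group"] = "IV"
        elif c >= resting_count + 2:
            data["group"] = "V"
        elif c == resting_count:
            if node == modal:
                data["group"] = "IIIr"
            else:
                data["group"] = votes[node].most_common(1)[0][0]
        else:
            data["group"] = "other"
    return graph


def group_occupancy(graph: nx.DiGraph, group: str) -> float:
    """Total occupancy probability of all nodes tagged with ``group``."""
    return float(
        sum(d["occupancy"] for _, d in graph.nodes(data=True) if d.get("group") == group)
    )


def mean_pore_ions(seq: StateSequence) -> float:
    """Time-averaged number of ions bound in the pore."""
    if len(seq) == 0:
        raise EmptyTrajectoryError("empty state sequence")
    return float(np.mean(seq.ion_counts))


# -- export -----------------------------------------------------------------


def write_graphml(graph: nx.DiGraph, path) -> None:
    """GraphML export; composite attributes are serialized as strings."""
    out = nx.DiGraph()
    out.add_nodes_from(graph.nodes(data=True))
    for u, v, data in graph.edges(data=True):
        out.add_edge(
            u,
            v,
            count=int(data["count"]),
            flag=data["flag"],
            flag_counts=";".join(f"{k}={c}" for k, c in sorted(data["flag_counts"].items())),
        )
    nx.write_graphml(out, path)


def write_dot(graph: nx.DiGraph, path) -> None:
    """Minimal Graphviz DOT export (no external pydot dependency)."""
    lines = ["digraph states {"]
    for node, data in graph.nodes(data=True):
        lines.append(
            f'  "{node}" [occupancy={data["occupancy"]:.6g}, '
            f'ion_count={data["ion_count"]}, group="{data.get("group", "other")}"];'
        )
    for u, v, data in graph.edges(data=True):
        lines.append(f'  "{u}" -> "{v}" [count={data["count"]}, flag="{data["flag"]}"];')
    lines.append("}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
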