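"""Independent oracles used by the test suite.

These deliberately re-derive expected values by routes different from the
library code paths they check: direct linear algebra on the jump-process
generator, and a literal replay of the exact event log.
"""

from __future__ import annotations

import itertools

import numpy as np

from permeon.synthetic_data import EV_ENTRY, EV_EXIT, GroundTruth, HopModel


def enumerate_states(capacities) -> list[tuple[int, ...]]:
    """All occupancy-count vectors compatible with the per-slot capacities."""
    return list(itertools.product(*[range(c + 1) for c in capacities]))


def outgoing_rates(model: HopModel, state: tuple[int, ...]):
    """Replicate the hop-model rate rules for one occupancy state.

    Yields (next_state, rate) pairs.  Mirrors the definition of the process:
    biased nearest-neighbor hops damped by well depth, neighbor-repulsion
    acceleration, entries blocked at full mouth sites, per-ion exits.
    """
    n = model.n_sites
    caps = model.capacities
    rep = model.repulsion
    up = model.k0 * np.exp(-model.depths) * np.exp(+model.bias / 2.0)
    down = model.k0 * np.exp(-model.depths) * np.exp(-model.bias / 2.0)
    c = list(state)
    for j in range(n):
        if c[j] == 0:
            continue
        if j + 1 < n and c[j + 1] < caps[j + 1]:
            push = np.exp(rep * c[j - 1]) if j - 1 >= 0 else 1.0
            nxt = list(c)
            nxt[j] -= 1
            nxt[j + 1] += 1
            yield tuple(nxt), c[j] * up[j] * push
        if j - 1 >= 0 and c[j - 1] < caps[j - 1]:
            push = np.exp(rep * c[j + 1]) if j + 1 < n else 1.0
            nxt = list(c)
            nxt[j] -= 1
            nxt[j - 1] += 1
            yield tuple(nxt), c[j] * down[j] * push
    if model.k_in_intra > 0 and c[0] < caps[0]:
        nxt = list(c)
        nxt[0] += 1
        yield tuple(nxt), model.k_in_intra
    if model.k_in_extra > 0 and c[n - 1] < caps[n - 1]:
        nxt = list(c)
        nxt[n - 1] += 1
        yield tuple(nxt), model.k_in_extra
    if model.k_out_intra > 0 and c[0] > 0:
        push = np.exp(rep * c[1]) if n > 1 else 1.0
        nxt = list(c)
        nxt[0] -= 1
        yield tuple(nxt), c[0] * model.k_out_intra * push
    if model.k_out_extra > 0 and c[n - 1] > 0:
        push = np.exp(rep * c[n - 2]) if n > 1 else 1.0
        nxt = list(c)
        nxt[n - 1] -= 1
        yield tuple(nxt), c[n - 1] * model.k_out_extra * push


def reachable_states(model: HopModel, initial: tuple[int, ...]) -> list[tuple[int, ...]]:
    """Occupancy states reachable from ``initial`` (closed models conserve count)."""
    seen = {initial}
    stack = [initial]
    while stack:
        s = stack.pop()
        for nxt, _ in outgoing_rates(model, s):
            if nxt not in seen:
                seen.add(nxt)
                stack.append(nxt)
    return sorted(seen)


def stationary_distribution(
    model: HopModel, initial: tuple[int, ...] | None = None
) -> dict[tuple[int, ...], float]:
    """Solve pi Q = 0 over the reachable occupancy states by linear algebra."""
    if initial is None:
        counts = [0] * model.n_sites
        for slot in model.initial_slots:
            counts[slot] += 1
        initial = tuple(counts)
    states = reachable_states(model, initial)
    index = {s: i for i, s in enumerate(states)}
    m = len(states)
    q = np.zeros((m, m))
    for s in states:
        i = index[s]
        for nxt, rate in outgoing_rates(model, s):
            j = index[nxt]
            q[i, j] += rate
            q[i, i] -= rate
    # pi Q = 0 with sum(pi) = 1
    a = np.vstack([q.T, np.ones(m)])
    b = np.zeros(m + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(a, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    pi /= pi.sum()
    return {s: float(p) for s, p in zip(states, pi)}


def replay_labels(truth: GroundTruth, model: HopModel, frame_times_ps) -> list[str]:
    """State label at each frame time, replayed literally from the exact log.

    Events strictly before a frame time are applied first; the emitted label
    is the canonical occupancy label in site numbers.
    """
    slots = {}
    for ion, slot in truth.initial_ions.items():
        slots[ion] = slot
    events = truth.events
    times = events["time_ps"].to_numpy()
    kinds = events["kind"].to_numpy()
    ions = events["ion_id"].to_numpy()
    to_region = events["to_region"].to_numpy()
    labels = []
    k = 0
    n = model.n_sites
    for t in frame_times_ps:
        while k < len(times) and times[k] < t:
            ion = ions[k]
            if kinds[k] == EV_EXIT:
                slots.pop(ion, None)
            else:
                dest = to_region[k]
                slots[ion] = n - 1 - int(dest[1:])  # region name S<k> -> slot
            k += 1
        s_numbers = sorted(n - 1 - slot for slot in slots.values())
        labels.append("K:" + ":".join(str(s) for s in s_numbers))
    return labels


def chunked_se(indicator: np.ndarray, n_chunks: int = 10) -> float:
    """Standard error of a time-series mean from contiguous chunk means."""
    chunks = np.array_split(np.asarray(indicator, dtype=float), n_chunks)
    means = np.array([c.mean() for c in chunks])
    return float(means.std(ddof=1) / np.sqrt(n_chunks))
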