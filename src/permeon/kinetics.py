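"""Currents, bootstrap errors, free-energy differences, and run summaries."""

from __future__ import annotations

import math
import warnings
from typing import Sequence

import numpy as np

from . import conduction_events as ce
from . import state_analysis as sa
from .errors import InfiniteDeltaGError, UndefinedRatioError, ValidationError
from .site_model import SiteModel
from .trajectory_io import IonTrajectory

#: Elementary charge in Coulomb.
E_CHARGE = 1.602176634e-19
#: Gas constant in kJ/(mol K).
R_KJ_MOL_K = 8.31446261815324e-3


def current(n_events: float, duration_us: float) -> float:
    """Single-channel current I = N e / T in pA.

    ``n_events`` is the signed net permeation count (outward positive); the
    result is signed the same way.
    """
    if duration_us <= 0:
        raise ValidationError("duration must be positive")
    return n_events * E_CHARGE / (duration_us * 1e-6) * 1e12


def round_sig(x: float, n_digits: int) -> float:
    """Round to ``n_digits`` significant figures (paper-style reporting)."""
    if x == 0:
        return 0.0
    exponent = math.floor(math.log10(abs(x)))
    return round(x, n_digits - 1 - exponent)


def events_to_block_series(
    times_ps: Sequence[float],
    signs: Sequence[int],
    t_start_ps: float,
    t_end_ps: float,
    block_size_ps: float,
) -> np.ndarray:
    """Signed net event count per contiguous time block."""
    if t_end_ps <= t_start_ps:
        raise ValidationError("empty time span")
    n_blocks = int(np.ceil((t_end_ps - t_start_ps) / block_size_ps))
    series = np.zeros(n_blocks)
    for t, s in zip(times_ps, signs):
        b = min(int((t - t_start_ps) // block_size_ps), n_blocks - 1)
        series[b] += s
    return series


def block_bootstrap_se(
    series: np.ndarray,
    block_size_ps: float,
    n_boot: int,
    locality_window: int = 10,
    seed: int = 0,
) -> float:
    """Local block bootstrap standard error of the current, in pA.

    The per-block event series is resampled position-locally: each block
    position draws a replacement block uniformly from positions within
    ``locality_window`` of it (clipped at the edges).  The SE is the standard
    deviation of the replicate currents.  A window of at least the series
    length reduces to the ordinary i.i.d. block bootstrap.
    """
    series = np.asarray(series, dtype=float)
    n_blocks = len(series)
    if n_blocks < 2:
        raise ValidationError("need at least 2 blocks for the bootstrap")
    duration_us = n_blocks * block_size_ps * 1e-6
    rng = np.random.default_rng(seed)
    positions = np.arange(n_blocks)
    lows = np.maximum(0, positions - locality_window)
    highs = np.minimum(n_blocks - 1, positions + locality_window)
    spans = highs - lows + 1

    sums = np.empty(n_boot)
    chunk = max(1, int(5e6 // n_blocks))
    done = 0
    while done < n_boot:
        m = min(chunk, n_boot - done)
        u = rng.random((m, n_blocks))
        idx = lows + (u * spans).astype(np.int64)
        sums[done : done + m] = series[idx].sum(axis=1)
        done += m
    replicates = sums * E_CHARGE / (duration_us * 1e-6) * 1e12
    return float(replicates.std())


def ratio_bootstrap_se(
    push_flags: Sequence[bool],
    n_boot: int = 10_000,
    block_size: int = 5,
    locality_window: int = 10,
    seed: int = 0,
) -> float:
    """Bootstrap SE of the push-mechanism fraction.

    The same local block scheme as for the current is applied to the
    time-ordered sequence of per-event mechanism labels, grouped into blocks
    of ``block_size`` events.
    """
    flags = np.asarray(push_flags, dtype=float)
    if len(flags) == 0:
        raise UndefinedRatioError("no classified conduction events")
    n_blocks = max(1, len(flags) // block_size)
    blocks = [flags[i * block_size : (i + 1) * block_size] for i in range(n_blocks)]
    blocks[-1] = flags[(n_blocks - 1) * block_size :]
    rng = np.random.default_rng(seed)
    positions = np.arange(n_blocks)
    lows = np.maximum(0, positions - locality_window)
    highs = np.minimum(n_blocks - 1, positions + locality_window)
    ratios = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(lows, highs + 1)
        sample = np.concatenate([blocks[i] for i in idx])
        ratios[b] = sample.mean()
    return float(ratios.std())


def delta_g(p_a: float, p_b: float, temperature: float = 300.0) -> float:
    """Free-energy difference G_b - G_a = -RT ln(P_b / P_a) in kJ/mol.

    With a = the two-ion group and b = the four-ion group, a negative value
    means the four-ion states are the more stable ones.
    """
    if p_a <= 0 or p_b <= 0:
        raise InfiniteDeltaGError(
            "zero occupancy probability gives an infinite free-energy "
            "difference; consider applying an occupancy floor"
        )
    return -R_KJ_MOL_K * temperature * math.log(p_b / p_a)


def summarize(
    condition: str,
    traj: IonTrajectory,
    model: SiteModel,
    resting_count: int = 3,
    block_size_ps: float = 100.0,
    n_boot: int = 10_000,
    locality_window: int = 10,
    seed: int = 0,
    temperature: float = 300.0,
    voltage_mV: float | None = None,
    min_dwell: int = 1,
) -> dict:
    """Run the full analysis pipeline and assemble the per-condition summary."""
    seq = sa.state_sequence(traj, model, min_dwell=min_dwell)
    graph = sa.build_graph(seq)
    sa.group_states(graph, resting_count=resting_count)
    events = ce.boundary_events(seq)
    conductions = ce.detect_conductions(events, t_start=seq[0].time_ps)
    ce.classify_all(conductions, seq, resting_count=resting_count)

    n_outward = sum(1 for c in conductions if c.direction == ce.OUTWARD)
    n_inward = sum(1 for c in conductions if c.direction == ce.INWARD)
    duration_us = traj.duration * 1e-6
    warnings_list: list[str] = []

    i_pa = current(n_outward - n_inward, duration_us) if duration_us > 0 else 0.0
    se_pa = 0.0
    if duration_us > 0:
        series = events_to_block_series(
            [c.t_exit_ps for c in conductions],
            [1 if c.direction == ce.OUTWARD else -1 for c in conductions],
            seq[0].time_ps,
            seq[-1].time_ps,
            block_size_ps,
        )
        if len(series) >= 2:
            se_pa = block_bootstrap_se(
                series, block_size_ps, n_boot, locality_window, seed
            )

    classified = [c for c in conductions if c.mechanism != ce.MECH_UNCLASSIFIED]
    push_ratio = None
    push_ratio_se = None
    n_push = sum(1 for c in classified if c.mechanism == ce.MECH_PUSH)
    n_pull = len(classified) - n_push
    if classified:
        ratio = ce.mechanism_ratio(conductions)
        push_ratio = ratio.ratio
        push_ratio_se = ratio_bootstrap_se(
            [c.mechanism == ce.MECH_PUSH for c in classified],
            n_boot=min(n_boot, 10_000),
            locality_window=locality_window,
            seed=seed + 1,
        )
    else:
        warnings_list.append("no classified conduction events; ratio undefined")

    n_frames = len(seq)
    floor = 0.5 / n_frames
    p_ii = sa.group_occupancy(graph, "II")
    p_iv = sa.group_occupancy(graph, "IV")
    if p_ii <= 0 or p_iv <= 0:
        warnings_list.append(
            "group II and/or IV unobserved; occupancy floor of 0.5/n_frames applied"
        )
    dg = delta_g(max(p_ii, floor), max(p_iv, floor), temperature)

    def mean_lifetime(mech: str) -> float | None:
        vals = [
            c.intermediate_lifetime_ps
            for c in classified
            if c.mechanism == mech and c.intermediate_lifetime_ps is not None
        ]
        return float(np.mean(vals) / 1000.0) if vals else None

    return {
        "condition": condition,
        "voltage_mV": voltage_mV,
        "duration_us": duration_us,
        "n_outward": n_outward,
        "n_inward": n_inward,
        "current_pA": i_pa,
        "current_se_pA": se_pa,
        "n_push": n_push,
        "n_pull": n_pull,
        "n_unclassified": len(conductions) - len(classified),
        "push_ratio": push_ratio,
        "push_ratio_se": push_ratio_se,
        "deltaG_II_IV_kJmol": dg,
        "mean_pore_ions": sa.mean_pore_ions(seq),
        "mean_lifetime_push_ns": mean_lifetime(ce.MECH_PUSH),
        "mean_lifetime_pull_ns": mean_lifetime(ce.MECH_PULL),
        "seed": seed,
        "block_size_ps": block_size_ps,
        "n_boot": n_boot,
        "warnings": warnings_list,
    }
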