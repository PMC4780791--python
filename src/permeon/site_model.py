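"""Binding-site definitions along the pore axis.

Sites are numbered S0 (extracellular-most) through S(n-1) (intracellular-most,
the hydrated cavity).  A :class:`SiteModel` is an ordered list of ``n + 1``
thresholds partitioning the axis, from low to high z, into
``INTRA, S(n-1), ..., S1, S0, EXTRA`` using half-open ``[lo, hi)`` intervals
(a value equal to a threshold belongs to the higher region).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Union

import numpy as np
import yaml
from scipy.signal import find_peaks

from .errors import EmptyTrajectoryError, ThresholdEstimationError, ValidationError
from .trajectory_io import IonTrajectory

#: Default thresholds (Angstrom) for the seven-site model: the tall low-z
#: interval is the hydrated cavity (S6), then S5..S0 up to the pore exit.
#: These are package defaults, not values measured from any particular system.
DEFAULT_THRESHOLDS = (-14.0, -4.5, 1.5, 4.5, 7.5, 10.5, 13.5, 18.0)

INTRA = "INTRA"
EXTRA = "EXTRA"


def default_capacities(n_sites: int) -> dict[int, int]:
    """Capacity 1 everywhere except the outermost site S0, which holds 2."""
    caps = {s: 1 for s in range(n_sites)}
    caps[0] = 2
    return caps


@dataclasses.dataclass
class SiteModel:
    """Axial partition of the pore into binding sites.

    Attributes
    ----------
    thresholds:
        Strictly increasing array of ``n_sites + 1`` positions (Angstrom).
    site_capacity:
        Mapping site number -> maximum simultaneous ions.
    """

    thresholds: np.ndarray
    site_capacity: dict[int, int] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        thr = np.asarray(self.thresholds, dtype=float)
        if thr.ndim != 1 or len(thr) < 2:
            raise ValidationError("need at least two thresholds (one site)")
        if np.any(np.diff(thr) <= 0):
            raise ValidationError("thresholds must be strictly increasing")
        self.thresholds = thr
        if self.site_capacity is None:
            self.site_capacity = default_capacities(self.n_sites)
        else:
            self.site_capacity = {int(k): int(v) for k, v in self.site_capacity.items()}
            for s in range(self.n_sites):
                self.site_capacity.setdefault(s, 1)

    @property
    def n_sites(self) -> int:
        return len(self.thresholds) - 1

    @property
    def region_labels(self) -> list[str]:
        """Region names ordered from low to high z."""
        n = self.n_sites
        return [INTRA] + [f"S{n - 1 - j}" for j in range(n)] + [EXTRA]

    @classmethod
    def default(cls) -> "SiteModel":
        return cls(thresholds=np.array(DEFAULT_THRESHOLDS))

    # -- assignment ---------------------------------------------------------

    def region_index(self, z) -> np.ndarray:
        """Index into :attr:`region_labels`: 0 = INTRA, n_sites+1 = EXTRA."""
        return np.searchsorted(self.thresholds, np.asarray(z, dtype=float), side="right")

    def site_of(self, z) -> np.ndarray:
        """Site number for each z, or -1 for bulk (INTRA/EXTRA)."""
        r = self.region_index(z)
        n = self.n_sites
        site = n - r  # region 1 -> S(n-1), region n -> S0
        return np.where((r >= 1) & (r <= n), site, -1)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "thresholds": [float(t) for t in self.thresholds],
            "site_capacity": {int(k): int(v) for k, v in self.site_capacity.items()},
        }

    @classmethod
    def from_dict(cls, data: dict) -> "SiteModel":
        caps = data.get("site_capacity")
        if caps is not None:
            caps = {int(k): int(v) for k, v in caps.items()}
        return cls(thresholds=np.asarray(data["thresholds"], dtype=float), site_capacity=caps)

    def save(self, path: Union[str, Path]) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: Union[str, Path]) -> "SiteModel":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def assign_site(z: float, model: SiteModel) -> str:
    """Region label (INTRA, S0..S(n-1), EXTRA) for one axial coordinate."""
    return model.region_labels[int(model.region_index(z))]


@dataclasses.dataclass
class DensityProfile:
    """Histogram of axial ion positions over all (frame, ion) observations."""

    bin_edges: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if np.any(self.counts < 0):
            raise ValidationError("density counts must be non-negative")
        if len(self.bin_edges) != len(self.counts) + 1:
            raise ValidationError("bin_edges must have len(counts) + 1 entries")

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def density(self) -> np.ndarray:
        """Counts normalized so that density * bin_width sums to 1."""
        width = np.diff(self.bin_edges)
        total = self.counts.sum()
        if total == 0:
            return np.zeros_like(self.counts)
        return self.counts / (total * width)


def density_profile(
    traj: IonTrajectory, bin_width: float, z_range: tuple[float, float] | None = None
) -> DensityProfile:
    """Histogram of all z observations with a fixed bin width."""
    if bin_width <= 0:
        raise ValidationError("bin_width must be positive")
    z = traj.frames["z"].to_numpy()
    if len(z) == 0:
        raise EmptyTrajectoryError("cannot histogram an empty trajectory")
    lo, hi = z_range if z_range is not None else (z.min(), z.max())
    n_bins = max(1, int(np.ceil((hi - lo) / bin_width)))
    edges = lo + bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(z, bins=edges)
    return DensityProfile(bin_edges=edges, counts=counts)


def _smooth(counts: np.ndarray, width: int) -> np.ndarray:
    if width <= 1:
        return counts.astype(float)
    kernel = np.ones(width) / width
    return np.convolve(counts, kernel, mode="same")


def estimate_thresholds(
    profile: DensityProfile,
    n_sites: int = 7,
    smooth_bins: int = 3,
    site_capacity: dict[int, int] | None = None,
) -> SiteModel:
    """Place site thresholds at density minima between the major density modes.

    The histogram is smoothed with a ``smooth_bins``-wide moving average, the
    ``n_sites`` highest local maxima are taken as site centers, and the
    interior thresholds are put at the minimum of the smoothed density between
    consecutive selected maxima.  The outer thresholds are the edges of the
    occupied range.
    """
    smoothed = _smooth(profile.counts, smooth_bins)
    peaks, _ = find_peaks(smoothed)
    if len(peaks) < n_sites:
        raise ThresholdEstimationError(
            f"found only {len(peaks)} density modes, need {n_sites}; "
            "use a wider bin or provide thresholds explicitly"
        )
    # keep the n_sites highest modes, in axial order
    order = np.argsort(smoothed[peaks])[::-1][:n_sites]
    selected = np.sort(peaks[order])
    centers = profile.centers
    interior = []
    for left, right in zip(selected[:-1], selected[1:]):
        k = left + int(np.argmin(smoothed[left : right + 1]))
        interior.append(float(centers[k]))
    occupied = np.nonzero(profile.counts > 0)[0]
    lo = float(profile.bin_edges[occupied[0]])
    hi = float(profile.bin_edges[occupied[-1] + 1])
    thresholds = np.array([lo] + interior + [hi])
    return SiteModel(thresholds=thresholds, site_capacity=site_capacity)
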