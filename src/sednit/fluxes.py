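"""Diffusive flux budgets and redox transition zone detection on porewater
depth profiles.

Fluxes follow Fick's first law, J = −φ·Ds·dC/dz, with the gradient estimated
by a least-squares line through the samples nearest the chosen interface and
the tortuosity correction Ds = D0/(1 − ln φ²).  The sign convention is
positive downward (into the sediment at the top boundary) throughout.

A deeply oxygenated column supplied with O2 from both the overlying seawater
and an oxic basement shows a C-shaped O2 profile with two redox transitions:
an oxic-anoxic transition zone (OATZ) where O2 falls from 10 µM to the ~3 µM
detection limit, and an anoxic-oxic transition zone (AOTZ) where it rises back
through that range.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .column_model import tortuosity_factor

log = logging.getLogger(__name__)


@dataclass
class DepthProfile:
    """One quantity sampled on a strictly increasing depth grid.

    ``depth`` in m below seafloor (positive downward), ``value`` in the units
    given (µM for porewater solutes).  ``below_detection`` flags samples at or
    below the analytical detection limit.
    """

    depth: np.ndarray
    value: np.ndarray
    species: str = ""
    unit: str = "uM"
    sd: np.ndarray | None = None
    below_detection: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if self.depth.size != self.value.size:
            raise ValueError("depth and value must have equal length")
        if np.any(np.diff(self.depth) <= 0):
            raise ValueError("depths must be strictly increasing")
        if self.below_detection is None:
            self.below_detection = np.zeros(self.depth.size, dtype=bool)
        else:
            self.below_detection = np.asarray(self.below_detection, dtype=bool)


@dataclass
class RedoxZone:
    """A redox transition interval; ``kind`` is ``"OATZ"`` or ``"AOTZ"``."""

    kind: str
    top: float
    bottom: float

    def __post_init__(self) -> None:
        if self.kind not in ("OATZ", "AOTZ"):
            raise ValueError("kind must be 'OATZ' or 'AOTZ'")
        if not self.top < self.bottom:
            raise ValueError("zone top must lie above its bottom")

    @property
    def width(self) -> float:
        return self.bottom - self.top

    @property
    def center(self) -> float:
        return 0.5 * (self.top + self.bottom)


@dataclass
class FluxEstimate:
    """Diffusive flux, mmol m⁻² yr⁻¹, positive downward."""

    value: float
    interface_depth: float
    window: np.ndarray = field(default_factory=lambda: np.array([]))
    species: str = ""
    flagged: bool = False  # e.g. below-detection values entered the gradient


def fick_flux(
    profile: DepthProfile,
    interface_depth: float,
    porosity: float,
    D0: float,
    n_points: int = 3,
    side: str = "below",
    apply_tortuosity: bool = True,
    detection_limit: float | None = None,
) -> FluxEstimate:
    """Fick's-first-law flux across ``interface_depth``, mmol m⁻² yr⁻¹.

    The gradient is a least-squares slope through the ``n_points`` samples
    nearest the interface on the chosen ``side`` ("below", "above" or "both").
    Concentrations in µM and D0 in m² yr⁻¹ give mmol m⁻² yr⁻¹ directly.
    Below-detection samples enter as ``detection_limit/2`` when a limit is
    given, and flag the estimate.
    """
    if not 0.0 < porosity < 1.0:
        raise ValueError("porosity must lie in (0, 1)")
    if n_points < 2:
        raise ValueError("n_points must be at least 2")
    depth, value = profile.depth, profile.value.copy()
    flagged = False
    if profile.below_detection is not None and np.any(profile.below_detection):
        if detection_limit is not None:
            value = np.where(profile.below_detection, detection_limit / 2.0, value)
        flagged = True
    if side == "below":
        mask = depth >= interface_depth
    elif side == "above":
        mask = depth <= interface_depth
    elif side == "both":
        mask = np.ones(depth.size, dtype=bool)
    else:
        raise ValueError("side must be 'below', 'above' or 'both'")
    idx = np.flatnonzero(mask)
    if idx.size < 2:
        raise ValueError(
            f"need at least 2 samples on side '{side}' of {interface_depth} m, "
            f"found {idx.size}"
        )
    order = idx[np.argsort(np.abs(depth[idx] - interface_depth), kind="stable")]
    chosen = np.sort(order[: min(n_points, order.size)])
    slope = np.polyfit(depth[chosen], value[chosen], 1)[0]  # µM / m
    Ds = D0 / float(tortuosity_factor(porosity)) if apply_tortuosity else D0
    j = -porosity * Ds * slope
    return FluxEstimate(float(j), float(interface_depth), depth[chosen],
                        profile.species, flagged)


def _crossings(depth: np.ndarray, value: np.ndarray, level: float) -> list[tuple[float, int]]:
    """Linearly interpolated depths where the profile crosses ``level``.

    Returns (depth, direction) with direction −1 for a downward crossing
    (value decreasing through the level) and +1 for an upward crossing.
    Samples exactly at the level count as "at or below", so a profile touching
    the level from above and returning registers a down/up crossing pair.
    """
    below = value <= level
    out = []
    for i in range(depth.size - 1):
        if below[i] == below[i + 1]:
            continue
        v0, v1 = value[i], value[i + 1]
        if v0 == level or v1 == level:
            zc = depth[i] if v0 == level else depth[i + 1]
        else:
            zc = depth[i] + (level - v0) / (v1 - v0) * (depth[i + 1] - depth[i])
        out.append((float(zc), +1 if below[i] else -1))
    return out


def detect_transition_zones(
    o2: DepthProfile,
    upper_threshold: float = 10.0,
    detection_limit: float = 3.0,
    min_width: float | None = None,
) -> list[RedoxZone]:
    """Locate OATZ/AOTZ intervals on an O2 profile.

    An OATZ runs from a downward crossing of ``upper_threshold`` to the
    subsequent downward crossing of ``detection_limit``; an AOTZ from an upward
    crossing of ``detection_limit`` to the subsequent upward crossing of
    ``upper_threshold``.  Crossing depths are linearly interpolated.  Zones
    narrower than ``min_width`` (default: one median sample spacing) — an
    artifact of non-monotonic noise — are discarded with a log note.
    """
    if detection_limit >= upper_threshold:
        raise ValueError("detection_limit must be below upper_threshold")
    depth, value = o2.depth, o2.value
    if min_width is None:
        min_width = float(np.median(np.diff(depth)))
    events = [(z, "down10" if d < 0 else "up10")
              for z, d in _crossings(depth, value, upper_threshold)]
    events += [(z, "down3" if d < 0 else "up3")
               for z, d in _crossings(depth, value, detection_limit)]
    rank = {"down10": 0, "down3": 1, "up3": 2, "up10": 3}
    events.sort(key=lambda e: (e[0], rank[e[1]]))
    # state machine: an OATZ opens at a downward 10 µM crossing and closes at
    # the next 3 µM crossing, but is aborted if O2 recovers above 10 µM first
    # (and symmetrically for AOTZ)
    zones: list[RedoxZone] = []
    pending: tuple[str, float] | None = None
    for zc, ev in events:
        if ev == "down10":
            pending = ("OATZ", zc)
        elif ev == "up3":
            pending = ("AOTZ", zc)
        elif ev == "down3":
            if pending is not None and pending[0] == "OATZ":
                zones.append(RedoxZone("OATZ", pending[1], zc))
            pending = None
        elif ev == "up10":
            if pending is not None and pending[0] == "AOTZ":
                zones.append(RedoxZone("AOTZ", pending[1], zc))
            pending = None
    kept = []
    for z in zones:
        if z.width < min_width:
            log.info("discarding %s of width %.3g m (< %.3g m grid spacing)",
                     z.kind, z.width, min_width)
            continue
        kept.append(z)
    return kept


@dataclass
class ZoneConsumption:
    consumption: float  # |flux in| − |flux out|, same units as the fluxes
    fraction_of_source: float
    warning: bool = False  # negative consumption: gradient-estimation noise


def zone_consumption(
    flux_in: FluxEstimate,
    flux_out: FluxEstimate,
    source_influx: FluxEstimate | None = None,
) -> ZoneConsumption:
    """Integrated consumption within a zone as the difference between the flux
    entering and leaving it, optionally as a fraction of a source influx
    (e.g. the O2 influx from the basement for an AOTZ)."""
    consumption = abs(flux_in.value) - abs(flux_out.value)
    warning = consumption < 0
    source = abs(source_influx.value) if source_influx is not None else abs(flux_in.value)
    fraction = consumption / source if source > 0 else np.nan
    return ZoneConsumption(float(consumption), float(fraction), warning)


def efflux_partition(upward: float, downward: float) -> tuple[float, float]:
    """Split a two-sided efflux into percentages (percent_up, percent_down).

    ``downward`` is the efflux into the underlying crust, ``upward`` into the
    overlying seawater; the two percentages sum to 100 exactly.
    """
    if upward < 0 or downward < 0:
        raise ValueError("effluxes must be nonnegative")
    total = upward + downward
    if total == 0:
        raise ValueError("at least one efflux must be positive")
    percent_down = 100.0 * downward / total
    return 100.0 - percent_down, percent_down
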