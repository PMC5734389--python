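"""Wavelength windows and resampling onto a shared grid.

Every matching method compares two spectra point-by-point, so both must
first be restricted to a wavelength range they (and any user-requested
window) all cover, then resampled onto one grid. Resampling is linear
interpolation only — CD spectra are smooth and densely sampled, and
linear interpolation never overshoots the data — and extrapolation is
never performed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .spectra_io import Spectrum

#: Default matching window when the user requests none: the standard
#: far-UV region for protein CD, intersected with data availability.
DEFAULT_WINDOW_NM = (190.0, 250.0)

#: Default grid step, nm (typical deposited-data granularity).
DEFAULT_GRID_STEP_NM = 1.0

#: A pair is unmatched (not an error for the whole run) below this many
#: shared grid points: an NRMSD over a near-empty window is meaningless.
MIN_OVERLAP_POINTS = 10


class NoOverlapError(ValueError):
    """The spectra (and requested window) share no usable wavelength range."""


class RangeError(ValueError):
    """A requested window lies (partly) outside a spectrum's native range."""


@dataclass(frozen=True)
class Window:
    """A closed wavelength interval [wl_min, wl_max], nm."""

    wl_min: float
    wl_max: float

    def __post_init__(self) -> None:
        if not (
            np.isfinite(self.wl_min)
            and np.isfinite(self.wl_max)
            and 0 < self.wl_min < self.wl_max
        ):
            raise ValueError(
                f"invalid window [{self.wl_min}, {self.wl_max}]: "
                "need 0 < wl_min < wl_max, both finite"
            )

    @property
    def span(self) -> float:
        return self.wl_max - self.wl_min


def overlap_window(
    a: Spectrum, b: Spectrum, requested: Optional[Window] = None
) -> Window:
    """Intersect the native ranges of two spectra with an optional request.

    Raises :class:`NoOverlapError` when the intersection is empty. Span
    adequacy (the 10-point minimum) is judged at grid-construction time
    by :func:`grid_points`, where the step is known.
    """
    lo = max(a.wl_min, b.wl_min)
    hi = min(a.wl_max, b.wl_max)
    if requested is not None:
        lo = max(lo, requested.wl_min)
        hi = min(hi, requested.wl_max)
    if not lo < hi:
        raise NoOverlapError(
            f"no wavelength overlap between {a.id} [{a.wl_min}, {a.wl_max}] and "
            f"{b.id} [{b.wl_min}, {b.wl_max}]"
            + (f" within requested [{requested.wl_min}, {requested.wl_max}]"
               if requested is not None else "")
        )
    return Window(lo, hi)


def grid_points(window: Window, step: float) -> np.ndarray:
    """The sampling grid wl_min, wl_min+step, …, ≤ wl_max.

    Raises :class:`NoOverlapError` if fewer than ``MIN_OVERLAP_POINTS``
    points fit in the window.
    """
    if step <= 0:
        raise ValueError(f"grid step must be positive, got {step}")
    n = int(np.floor((window.wl_max - window.wl_min) / step + 1e-9)) + 1
    grid = window.wl_min + step * np.arange(n)
    if grid.size < MIN_OVERLAP_POINTS:
        raise NoOverlapError(
            f"overlap window [{window.wl_min}, {window.wl_max}] holds only "
            f"{grid.size} grid point(s) at step {step}; "
            f"minimum is {MIN_OVERLAP_POINTS}"
        )
    return grid


def resample(s: Spectrum, window: Window, step: float = DEFAULT_GRID_STEP_NM) -> Spectrum:
    """Linearly interpolate ``s`` onto the grid of ``window`` at ``step``.

    The window must lie inside the spectrum's native range; extrapolation
    is never performed.
    """
    if not s.covers(window.wl_min, window.wl_max):
        raise RangeError(
            f"{s.id}: window [{window.wl_min}, {window.wl_max}] outside native "
            f"range [{s.wl_min}, {s.wl_max}]"
        )
    grid = grid_points(window, step)
    vals = np.interp(grid, s.wavelengths, s.values)
    return replace(s, wavelengths=grid, values=vals)


def shared_grid_values(
    a: Spectrum,
    b: Spectrum,
    requested: Optional[Window] = None,
    step: float = DEFAULT_GRID_STEP_NM,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Overlap, grid and interpolated values for a spectrum pair.

    Returns ``(grid, a_values, b_values)`` on the shared grid.
    """
    window = overlap_window(a, b, requested)
    grid = grid_points(window, step)
    return (
        grid,
        np.interp(grid, a.wavelengths, a.values),
        np.interp(grid, b.wavelengths, b.values),
    )
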