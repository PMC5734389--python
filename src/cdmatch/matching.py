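"""The NRMSD statistic and the four spectral comparison methods.

All four methods score a (query, test) spectrum pair with the normalized
root-mean-square deviation

    NRMSD = sqrt( Σ(θexp − θcal)² / Σ(θexp)² )

where θexp are the query values and θcal the test values on a shared
wavelength grid. NRMSD is 0 for identical spectra and ≈1 when the test is
no better than a flat zero line. The statistic is deliberately asymmetric:
the query always supplies the denominator, so matching a reference set
against a query is not the same as the reverse.

Methods
-------
simple_fit
    Compare the spectra as-is over the shared window. For this method an
    NRMSD ≤ 0.10 is conventionally read as strong spectral similarity
    (see ``SIMPLE_FIT_STRONG_SIMILARITY``).
normalized_comparison
    First rescale the test spectrum so its largest-magnitude extremum
    within the window equals the query's, removing overall magnitude
    (e.g. concentration error) as a factor.
ratio_comparison
    Compare only the three pairwise ratios of the band values at 195,
    208 and 222 nm — the diagnostic secondary-structure bands — making
    the score invariant to any rescaling of either spectrum.
wavelength_shift
    Slide the query's wavelength axis over ±max_shift and keep the best
    NRMSD, absorbing calibration or solvent-dielectric offsets; the
    winning shift (nm) is reported.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .preprocess import (
    DEFAULT_GRID_STEP_NM,
    NoOverlapError,
    Window,
    shared_grid_values,
)
from .spectra_io import Spectrum

#: Advisory Simple Fit threshold: NRMSD at or below this value usually
#: indicates strong spectral similarity. Interpretive, not a filter.
SIMPLE_FIT_STRONG_SIMILARITY = 0.10

#: Diagnostic band wavelengths (nm) used by the ratio comparison.
RATIO_BANDS_NM = (195.0, 208.0, 222.0)

#: Default shift search bounds: CD calibration offsets are ≲2 nm, and a
#: 0.1 nm step keeps the reported shift magnitude meaningful.
DEFAULT_MAX_SHIFT_NM = 3.0
DEFAULT_SHIFT_STEP_NM = 0.1


class UndefinedStatisticError(ZeroDivisionError, ValueError):
    """NRMSD denominator Σ(θexp)² is zero (all-zero query window)."""


class DegenerateSpectrumError(ValueError):
    """A method's scaling or ratio denominator is (near) zero."""


@dataclass(frozen=True)
class MethodResult:
    """Outcome of one method on one (query, test) pair.

    ``shift_nm`` is 0 for non-shift methods; ``scale_factor`` is 1 for
    non-normalized methods.
    """

    nrmsd: float
    shift_nm: float = 0.0
    scale_factor: float = 1.0


def nrmsd(query_values: np.ndarray, test_values: np.ndarray) -> float:
    """sqrt(Σ(θexp−θcal)² / Σ(θexp)²) with the query as θexp."""
    q = np.asarray(query_values, dtype=float)
    t = np.asarray(test_values, dtype=float)
    if q.shape != t.shape or q.ndim != 1 or q.size < 1:
        raise ValueError(
            f"query and test must be equal-length 1-D sequences, "
            f"got shapes {q.shape} and {t.shape}"
        )
    denom = float(np.sum(q * q))
    if denom == 0.0:
        raise UndefinedStatisticError(
            "NRMSD undefined: query values are all zero over the window"
        )
    return float(np.sqrt(np.sum((q - t) ** 2) / denom))


def simple_fit(
    query: Spectrum,
    test: Spectrum,
    window: Optional[Window] = None,
    *,
    grid_step: float = DEFAULT_GRID_STEP_NM,
) -> MethodResult:
    """NRMSD between the unmodified spectra over their shared window."""
    _, q, t = shared_grid_values(query, test, window, grid_step)
    return MethodResult(nrmsd=nrmsd(q, t))


def _largest_extremum(values: np.ndarray, owner: str) -> float:
    """The signed value of largest absolute magnitude (the scaling peak).

    For protein CD the dominant feature is often a negative band, so the
    peak is taken by absolute magnitude with its sign preserved.
    """
    peak = float(values[np.argmax(np.abs(values))])
    if peak == 0.0:
        raise DegenerateSpectrumError(
            f"{owner}: scaling peak is zero within the matching window"
        )
    return peak


def normalized_comparison(
    query: Spectrum,
    test: Spectrum,
    window: Optional[Window] = None,
    *,
    grid_step: float = DEFAULT_GRID_STEP_NM,
) -> MethodResult:
    """Scale the test to the query at their maxima, then NRMSD.

    The scale factor is (query's largest-|value| extremum) / (test's),
    both taken within the window, signs preserved; overall spectral
    magnitude is thereby eliminated as a factor.
    """
    _, q, t = shared_grid_values(query, test, window, grid_step)
    scale = _largest_extremum(q, query.id) / _largest_extremum(t, test.id)
    return MethodResult(nrmsd=nrmsd(q, t * scale), scale_factor=scale)


def _band_ratios(s: Spectrum) -> np.ndarray:
    """(v208/v222, v195/v222, v195/v208) by linear interpolation."""
    v195, v208, v222 = (s.value_at(b) for b in RATIO_BANDS_NM)
    eps = 1e-6 * float(np.max(np.abs(s.values)))
    for band, denom in ((222.0, v222), (208.0, v208)):
        if abs(denom) < eps:
            raise DegenerateSpectrumError(
                f"{s.id}: band value at {band} nm is below the degeneracy "
                f"threshold ({eps:.3g}); ratios undefined"
            )
    return np.array([v208 / v222, v195 / v222, v195 / v208])


def ratio_comparison(query: Spectrum, test: Spectrum) -> MethodResult:
    """NRMSD between the 195/208/222 nm band-ratio vectors.

    Both spectra must cover all three bands. Scale-invariant by
    construction: any nonzero rescaling of either spectrum leaves its
    ratio vector unchanged.
    """
    for s in (query, test):
        if not s.covers(RATIO_BANDS_NM[0], RATIO_BANDS_NM[-1]):
            raise NoOverlapError(
                f"{s.id}: range [{s.wl_min}, {s.wl_max}] does not cover the "
                f"{RATIO_BANDS_NM} nm ratio bands"
            )
    return MethodResult(nrmsd=nrmsd(_band_ratios(query), _band_ratios(test)))


def shift_spectrum(s: Spectrum, delta_nm: float) -> Spectrum:
    """Displace the wavelength axis by ``delta_nm`` (values untouched)."""
    return replace(s, wavelengths=s.wavelengths + delta_nm)


def wavelength_shift(
    query: Spectrum,
    test: Spectrum,
    window: Optional[Window] = None,
    *,
    max_shift: float = DEFAULT_MAX_SHIFT_NM,
    shift_step: float = DEFAULT_SHIFT_STEP_NM,
    grid_step: float = DEFAULT_GRID_STEP_NM,
) -> MethodResult:
    """Best NRMSD over query-axis shifts δ ∈ [−max_shift, +max_shift].

    The query's wavelength axis is shifted by each candidate δ (stepped
    by ``shift_step``), the overlap window and grid are recomputed, and
    the minimum NRMSD is returned with its δ. Ties break toward smaller
    |δ|, then toward negative δ; max_shift → 0 degenerates to
    :func:`simple_fit` exactly.
    """
    if max_shift < 0 or shift_step <= 0:
        raise ValueError("need max_shift >= 0 and shift_step > 0")
    n_side = int(np.floor(max_shift / shift_step + 1e-9))
    deltas = shift_step * np.arange(-n_side, n_side + 1)
    # Tie-break order: by |δ| ascending, negative before positive.
    order = sorted(range(deltas.size), key=lambda i: (abs(deltas[i]), deltas[i]))
    best: Optional[tuple[float, float]] = None  # (nrmsd, delta)
    any_overlap = False
    for i in order:
        delta = float(deltas[i])
        try:
            _, q, t = shared_grid_values(
                shift_spectrum(query, delta), test, window, grid_step
            )
        except NoOverlapError:
            continue
        any_overlap = True
        score = nrmsd(q, t)
        if best is None or score < best[0]:
            best = (score, delta)
    if not any_overlap or best is None:
        raise NoOverlapError(
            f"no candidate shift in ±{max_shift} nm yields a usable overlap "
            f"between {query.id} and {test.id}"
        )
    return MethodResult(nrmsd=best[0], shift_nm=best[1])
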