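"""Rank a reference set of CD spectra against a query spectrum.

This reproduces the batch semantics of a spectral nearest-neighbor
search: every reference spectrum is scored against the query with the
chosen method, per-pair failures (no usable overlap, degenerate scaling
peak, ...) degrade to skipped entries rather than aborting the run, and
the survivors are filtered by the optional NRMSD cutoff, sorted
ascending by NRMSD (ties by reference id) and truncated to the requested
number of matches. A query that is itself a member of the reference set
scores NRMSD 0.0 and therefore ranks first.

Unit reconciliation goes one way: references are converted to the
query's units, because the query defines the NRMSD denominator and must
stay untouched.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Sequence, Union

from .matching import (
    DEFAULT_MAX_SHIFT_NM,
    DEFAULT_SHIFT_STEP_NM,
    DegenerateSpectrumError,
    MethodResult,
    SIMPLE_FIT_STRONG_SIMILARITY,
    UndefinedStatisticError,
    normalized_comparison,
    ratio_comparison,
    simple_fit,
    wavelength_shift,
)
from .preprocess import DEFAULT_GRID_STEP_NM, DEFAULT_WINDOW_NM, NoOverlapError, Window
from .spectra_io import (
    Spectrum,
    SpectrumDataError,
    SpectrumFormatError,
    Units,
    convert_units,
    parse_any,
)

logger = logging.getLogger("cdmatch")


class Method(Enum):
    """The four spectral comparison methods."""

    SIMPLE = "simple"
    NORMALIZED = "normalized"
    RATIO = "ratio"
    SHIFT = "shift"


@dataclass(frozen=True)
class MatchParams:
    """User-tunable search parameters.

    ``window=None`` means the default far-UV window intersected with data
    availability; ``nrmsd_cutoff=None`` reports all matches up to
    ``max_matches`` (the 0.10 strong-similarity figure for Simple Fit is
    advisory, surfaced as an annotation, never a filter).
    """

    method: Method = Method.SIMPLE
    window: Optional[Window] = None
    max_matches: int = 10
    nrmsd_cutoff: Optional[float] = None
    max_shift: float = DEFAULT_MAX_SHIFT_NM
    shift_step: float = DEFAULT_SHIFT_STEP_NM
    grid_step: float = DEFAULT_GRID_STEP_NM

    def __post_init__(self) -> None:
        if self.max_matches < 1:
            raise ValueError(f"max_matches must be >= 1, got {self.max_matches}")
        if self.nrmsd_cutoff is not None and not self.nrmsd_cutoff > 0:
            raise ValueError(f"nrmsd_cutoff must be > 0, got {self.nrmsd_cutoff}")


@dataclass(frozen=True)
class MatchResult:
    """One reference spectrum's outcome: a score or a skip reason."""

    ref_id: str
    ref_name: str = ""
    nrmsd: Optional[float] = None
    shift_nm: float = 0.0
    scale_factor: float = 1.0
    skipped_reason: Optional[str] = None

    def __post_init__(self) -> None:
        if (self.nrmsd is None) == (self.skipped_reason is None):
            raise ValueError(
                "exactly one of nrmsd and skipped_reason must be set"
            )


@dataclass(frozen=True)
class MatchReport:
    """Ordered match list plus the parameters that produced it."""

    query_id: str
    params: MatchParams
    results: tuple[MatchResult, ...]
    skipped: tuple[MatchResult, ...] = ()

    def to_tsv(self) -> str:
        """Tab-separated table: rank, ref_id, ref_name, nrmsd, shift_nm, scale_factor."""
        lines = ["rank\tref_id\tref_name\tnrmsd\tshift_nm\tscale_factor"]
        for rank, r in enumerate(self.results, start=1):
            lines.append(
                f"{rank}\t{r.ref_id}\t{r.ref_name}\t{r.nrmsd:.6f}"
                f"\t{r.shift_nm:.3f}\t{r.scale_factor:.6g}"
            )
        return "\n".join(lines) + "\n"

    def to_json(self) -> str:
        """Full report, including skips and a parameter echo."""
        def result_dict(r: MatchResult) -> dict:
            return {
                "ref_id": r.ref_id,
                "ref_name": r.ref_name,
                "nrmsd": r.nrmsd,
                "shift_nm": r.shift_nm,
                "scale_factor": r.scale_factor,
                "skipped_reason": r.skipped_reason,
            }

        payload = {
            "query_id": self.query_id,
            "params": {
                "method": self.params.method.value,
                "window": (
                    [self.params.window.wl_min, self.params.window.wl_max]
                    if self.params.window
                    else None
                ),
                "max_matches": self.params.max_matches,
                "nrmsd_cutoff": self.params.nrmsd_cutoff,
                "max_shift": self.params.max_shift,
                "shift_step": self.params.shift_step,
                "grid_step": self.params.grid_step,
            },
            "strong_similarity_nrmsd": (
                SIMPLE_FIT_STRONG_SIMILARITY
                if self.params.method is Method.SIMPLE
                else None
            ),
            "results": [result_dict(r) for r in self.results],
            "skipped": [result_dict(r) for r in self.skipped],
        }
        return json.dumps(payload, indent=2)


@dataclass
class ReferenceSet:
    """A named collection of spectra in one unit system."""

    spectra: list[Spectrum] = field(default_factory=list)
    units: Units = Units.DELTA_EPSILON
    failures: list[tuple[str, str]] = field(default_factory=list)  # (source, reason)

    def __len__(self) -> int:
        return len(self.spectra)


class EmptyReferenceError(ValueError):
    """No parseable spectrum files in the reference source."""


def load_reference_set(
    source: Union[str, os.PathLike, Iterable[Union[str, os.PathLike]]],
    *,
    units: Units = Units.DELTA_EPSILON,
    assume_units: Units = Units.DELTA_EPSILON,
) -> ReferenceSet:
    """Load every parseable spectrum file from a directory or file list.

    Each file is format-detected and parsed; all spectra are converted to
    ``units``. ``assume_units`` applies to the unit-less dialects.
    Duplicate ids get a deterministic ``~2``, ``~3``, ... suffix; parse
    failures are collected on the returned set, not raised, except that a
    source yielding zero spectra raises :class:`EmptyReferenceError`.
    """
    if isinstance(source, (str, os.PathLike)) and os.path.isdir(source):
        paths = sorted(
            os.path.join(source, f)
            for f in os.listdir(source)
            if os.path.isfile(os.path.join(source, f))
        )
    elif isinstance(source, (str, os.PathLike)):
        paths = [os.fspath(source)]
    else:
        paths = [os.fspath(p) for p in source]

    refset = ReferenceSet(units=units)
    seen: dict[str, int] = {}
    for path in paths:
        try:
            with open(path, "r", encoding="utf-8", errors="replace") as fh:
                s = parse_any(os.path.basename(path), fh.read(), units=assume_units)
        except (SpectrumFormatError, SpectrumDataError, OSError) as exc:
            logger.warning("skipping %s: %s", path, exc)
            refset.failures.append((path, str(exc)))
            continue
        s = convert_units(s, units)
        count = seen.get(s.id, 0) + 1
        seen[s.id] = count
        if count > 1:
            s = Spectrum(
                id=f"{s.id}~{count}",
                name=s.name,
                wavelengths=s.wavelengths,
                values=s.values,
                units=s.units,
            )
        refset.spectra.append(s)
    if not refset.spectra:
        raise EmptyReferenceError(
            f"no parseable spectrum files in {source!r} "
            f"({len(refset.failures)} failure(s))"
        )
    return refset


def reference_set_from_spectra(
    spectra: Sequence[Spectrum], units: Units = Units.DELTA_EPSILON
) -> ReferenceSet:
    """Build a reference set from in-memory spectra, converting units."""
    refset = ReferenceSet(units=units)
    seen: dict[str, int] = {}
    for s in spectra:
        s = convert_units(s, units)
        count = seen.get(s.id, 0) + 1
        seen[s.id] = count
        if count > 1:
            s = Spectrum(
                id=f"{s.id}~{count}", name=s.name,
                wavelengths=s.wavelengths, values=s.values, units=s.units,
            )
        refset.spectra.append(s)
    if not refset.spectra:
        raise EmptyReferenceError("empty spectrum sequence")
    return refset


def _score_pair(query: Spectrum, ref: Spectrum, params: MatchParams) -> MethodResult:
    # A search without an explicit window uses the standard far-UV region,
    # further intersected with what both spectra actually cover.
    window = params.window if params.window is not None else Window(*DEFAULT_WINDOW_NM)
    if params.method is Method.SIMPLE:
        return simple_fit(query, ref, window, grid_step=params.grid_step)
    if params.method is Method.NORMALIZED:
        return normalized_comparison(query, ref, window, grid_step=params.grid_step)
    if params.method is Method.RATIO:
        return ratio_comparison(query, ref)
    return wavelength_shift(
        query,
        ref,
        window,
        max_shift=params.max_shift,
        shift_step=params.shift_step,
        grid_step=params.grid_step,
    )


def run_match(
    query: Spectrum, refs: ReferenceSet, params: MatchParams = MatchParams()
) -> MatchReport:
    """Score every reference against the query and rank the matches.

    References are converted to the query's units first. Pairs that raise
    a no-overlap or degeneracy error become skipped entries with reasons.
    Survivors are filtered by ``nrmsd_cutoff`` (when set), sorted
    ascending by (nrmsd, ref_id) and truncated to ``max_matches``. If the
    query itself is in the reference set, its copy scores NRMSD 0.0 and
    sorts first.
    """
    scored: list[MatchResult] = []
    skipped: list[MatchResult] = []
    for ref in refs.spectra:
        ref_q = convert_units(ref, query.units)
        try:
            res = _score_pair(query, ref_q, params)
        except (NoOverlapError, DegenerateSpectrumError, UndefinedStatisticError) as exc:
            skipped.append(
                MatchResult(ref_id=ref.id, ref_name=ref.name, skipped_reason=str(exc))
            )
            continue
        scored.append(
            MatchResult(
                ref_id=ref.id,
                ref_name=ref.name,
                nrmsd=res.nrmsd,
                shift_nm=res.shift_nm,
                scale_factor=res.scale_factor,
            )
        )
    if params.nrmsd_cutoff is not None:
        scored = [r for r in scored if r.nrmsd <= params.nrmsd_cutoff]
    scored.sort(key=lambda r: (r.nrmsd, r.ref_id))
    return MatchReport(
        query_id=query.id,
        params=params,
        results=tuple(scored[: params.max_matches]),
        skipped=tuple(skipped),
    )
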