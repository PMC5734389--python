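"""Reading, writing and unit conversion of CD spectra.

Three on-disk dialects are supported:

``two_column``
    Plain ASCII, one ``wavelength value`` pair per line, whitespace- or
    comma-separated, ``#`` comments and unparseable header lines skipped.
    The universal export format of commercial CD instruments.

``gen``
    The generic multi-column format written by CDtools-style processing
    software: any number of free-text header lines followed by a numeric
    block whose first two columns are wavelength (nm) and CD value; extra
    columns (e.g. the photomultiplier HT trace) are ignored.

``pcd``
    A PCDDB flat-file entry: tagged metadata lines (``PCDDB ID``,
    ``Protein Name``, a unit-bearing tag) followed, at the end of the file,
    by the processed-spectrum data block of (wavelength, value) pairs.
    Only the fields that feed matching are extracted; everything else in
    the entry is ignored. The tag layout is parsed tolerantly ("our
    dialect"): a tag, two or more spaces or a colon, then the value.

Spectra carry one of two unit systems: delta epsilon (Δε, per-residue
molar differential extinction, M⁻¹·cm⁻¹) or mean residue ellipticity
([θ], deg·cm²·dmol⁻¹), related by the standard per-residue convention
[θ] = 3298.2 × Δε.

Wavelength grids are canonicalized to strictly ascending order on parse
(instruments scan high→low); duplicate wavelengths are averaged with a
logged warning.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, replace
from enum import Enum
from typing import Sequence, TextIO, Union

import numpy as np

logger = logging.getLogger("cdmatch")

#: [θ] = MRE_PER_DELTA_EPSILON × Δε (per-residue convention).
MRE_PER_DELTA_EPSILON = 3298.2


class Units(Enum):
    """The two CD magnitude conventions in common use."""

    DELTA_EPSILON = "delta_epsilon"
    MEAN_RESIDUE_ELLIPTICITY = "mean_residue_ellipticity"


class FileFormat(Enum):
    PCD = "pcd"
    GEN = "gen"
    TWO_COLUMN = "two_column"


class SpectrumFormatError(ValueError):
    """The stream could not be parsed in the requested dialect."""


class SpectrumDataError(ValueError):
    """The parsed numbers violate the Spectrum invariants."""


@dataclass(frozen=True)
class Spectrum:
    """One CD spectrum on a strictly ascending wavelength grid.

    Parameters
    ----------
    id
        Short identifier: filename stem or PCDDB ID such as
        ``"CD0000048000"``.
    name
        Free-text protein name; may be empty.
    wavelengths
        Strictly ascending wavelengths, nm, all finite and positive.
    values
        CD magnitudes in ``units``, same length as ``wavelengths``.
    units
        Unit system of ``values``.
    """

    id: str
    wavelengths: np.ndarray
    values: np.ndarray
    units: Units = Units.DELTA_EPSILON
    name: str = ""

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "values", vals)
        if wl.ndim != 1 or vals.ndim != 1 or wl.size != vals.size:
            raise SpectrumDataError(
                f"{self.id}: wavelengths and values must be 1-D and equal length"
            )
        if wl.size < 2:
            raise SpectrumDataError(f"{self.id}: need at least 2 points, got {wl.size}")
        if not np.all(np.isfinite(wl)) or not np.all(np.isfinite(vals)):
            raise SpectrumDataError(f"{self.id}: non-finite wavelength or value")
        if np.any(wl <= 0):
            raise SpectrumDataError(f"{self.id}: wavelengths must be positive")
        if np.any(np.diff(wl) <= 0):
            raise SpectrumDataError(f"{self.id}: wavelength grid not strictly ascending")

    @property
    def wl_min(self) -> float:
        return float(self.wavelengths[0])

    @property
    def wl_max(self) -> float:
        return float(self.wavelengths[-1])

    def value_at(self, wavelength: float) -> float:
        """Linearly interpolated CD value at ``wavelength`` (no extrapolation)."""
        if not (self.wl_min <= wavelength <= self.wl_max):
            raise SpectrumDataError(
                f"{self.id}: {wavelength} nm outside native range "
                f"[{self.wl_min}, {self.wl_max}]"
            )
        return float(np.interp(wavelength, self.wavelengths, self.values))

    def covers(self, wl_min: float, wl_max: float) -> bool:
        return self.wl_min <= wl_min and self.wl_max >= wl_max


def _canonicalize(
    wl: Sequence[float], vals: Sequence[float], spectrum_id: str
) -> tuple[np.ndarray, np.ndarray]:
    """Sort ascending; average duplicate wavelengths (order-independent)."""
    wl = np.asarray(wl, dtype=float)
    vals = np.asarray(vals, dtype=float)
    order = np.argsort(wl, kind="stable")
    wl, vals = wl[order], vals[order]
    uniq, inverse, counts = np.unique(wl, return_inverse=True, return_counts=True)
    if uniq.size != wl.size:
        logger.warning(
            "%s: %d duplicate wavelength(s) averaged", spectrum_id, wl.size - uniq.size
        )
        sums = np.zeros_like(uniq)
        np.add.at(sums, inverse, vals)
        vals = sums / counts
        wl = uniq
    return wl, vals


_NUM_RE = re.compile(r"^[+-]?(\d+\.?\d*|\.\d+)([eE][+-]?\d+)?$")


def _try_parse_row(line: str) -> list[float] | None:
    """Parse one data line into floats, or None if any field is non-numeric."""
    stripped = line.strip()
    if not stripped or stripped.startswith("#"):
        return None
    fields = re.split(r"[,\s]+", stripped)
    if len(fields) < 2:
        return None
    if not all(_NUM_RE.match(f) for f in fields):
        return None
    return [float(f) for f in fields]


def _as_stream(text: Union[str, TextIO]) -> TextIO:
    return io.StringIO(text) if isinstance(text, str) else text


def parse_two_column(
    text: Union[str, TextIO],
    *,
    id: str = "query",
    units: Units = Units.DELTA_EPSILON,
    name: str = "",
) -> Spectrum:
    """Parse plain two-column ASCII (wavelength nm, CD value).

    Comment lines (``#``), headers and otherwise unparseable lines are
    skipped with a debug log; at least two parseable data lines are
    required.
    """
    stream = _as_stream(text)
    wl: list[float] = []
    vals: list[float] = []
    first_bad: tuple[int, str] | None = None
    for lineno, line in enumerate(stream, start=1):
        row = _try_parse_row(line)
        if row is None:
            if line.strip() and not line.strip().startswith("#") and first_bad is None:
                first_bad = (lineno, line.strip())
            if line.strip():
                logger.debug("%s: skipped line %d: %r", id, lineno, line.strip())
            continue
        wl.append(row[0])
        vals.append(row[1])
    if len(wl) < 2:
        detail = (
            f" (first offending line {first_bad[0]}: {first_bad[1]!r})"
            if first_bad
            else ""
        )
        raise SpectrumFormatError(
            f"{id}: fewer than 2 parseable data lines{detail}"
        )
    wl_arr, val_arr = _canonicalize(wl, vals, id)
    return Spectrum(id=id, name=name, wavelengths=wl_arr, values=val_arr, units=units)


def parse_gen(
    text: Union[str, TextIO],
    *,
    id: str = "query",
    units: Units = Units.DELTA_EPSILON,
    name: str = "",
) -> Spectrum:
    """Parse a CDtools-style generic file: headers then a numeric block.

    Columns beyond (wavelength, CD) — typically the HT voltage — are
    discarded. A file that is already plain two-column parses identically
    to :func:`parse_two_column`.
    """
    stream = _as_stream(text)
    wl: list[float] = []
    vals: list[float] = []
    for line in stream:
        row = _try_parse_row(line)
        if row is not None:
            wl.append(row[0])
            vals.append(row[1])
    if len(wl) < 2:
        raise SpectrumFormatError(f"{id}: no numeric block found in .gen stream")
    wl_arr, val_arr = _canonicalize(wl, vals, id)
    return Spectrum(id=id, name=name, wavelengths=wl_arr, values=val_arr, units=units)


_PCD_ID_TAGS = ("pcddb id",)
_PCD_NAME_TAGS = ("protein name", "full name")
_PCD_UNIT_TAGS = ("y units", "units", "data units", "unit")

_TAG_SPLIT_RE = re.compile(r"^(?P<tag>[A-Za-z][A-Za-z0-9 ()/_.-]*?)(?:\s{2,}|\t+|:\s*)(?P<value>\S.*)$")


def _parse_units_string(raw: str) -> Units | None:
    low = raw.lower()
    if "epsilon" in low or "delta" in low or "Δε" in raw or "de" == low.strip():
        return Units.DELTA_EPSILON
    if "ellipticity" in low or "mre" in low or "theta" in low or "deg" in low:
        return Units.MEAN_RESIDUE_ELLIPTICITY
    return None


def parse_pcd(text: Union[str, TextIO], *, id: str = "") -> Spectrum:
    """Parse a PCDDB flat-file entry.

    Extracts the PCDDB ID, the protein name and the unit tag from the
    tagged metadata lines, and the final contiguous numeric block as the
    processed spectrum. Unknown tags are ignored; an unparseable or
    absent unit tag defaults to delta epsilon with a warning.
    """
    stream = _as_stream(text)
    lines = stream.read().splitlines()

    entry_id = id
    name = ""
    units: Units | None = None
    for line in lines:
        m = _TAG_SPLIT_RE.match(line.strip())
        if not m:
            continue
        tag = m.group("tag").strip().lower()
        value = m.group("value").strip()
        if tag in _PCD_ID_TAGS and value:
            entry_id = value.split()[0]
        elif tag in _PCD_NAME_TAGS and not name:
            name = value
        elif tag in _PCD_UNIT_TAGS and units is None:
            parsed = _parse_units_string(value)
            if parsed is None:
                logger.warning(
                    "%s: unparseable unit string %r; defaulting to delta epsilon",
                    entry_id or "pcd",
                    value,
                )
                units = Units.DELTA_EPSILON
            else:
                units = parsed

    # Final contiguous run of >=2-column numeric lines = processed data block.
    block: list[list[float]] = []
    best: list[list[float]] = []
    for line in lines:
        row = _try_parse_row(line)
        if row is not None:
            block.append(row)
        else:
            if len(block) >= 2:
                best = block
            block = []
    if len(block) >= 2:
        best = block
    if len(best) < 2:
        raise SpectrumFormatError(
            f"{entry_id or 'pcd'}: no processed data block found in PCDDB entry"
        )
    if units is None:
        logger.warning(
            "%s: no unit field found; defaulting to delta epsilon", entry_id or "pcd"
        )
        units = Units.DELTA_EPSILON
    wl, vals = _canonicalize([r[0] for r in best], [r[1] for r in best], entry_id or "pcd")
    return Spectrum(
        id=entry_id or "pcd", name=name, wavelengths=wl, values=vals, units=units
    )


def detect_format(filename: str, text: Union[str, TextIO]) -> FileFormat:
    """Decide the dialect of a spectrum file.

    The ``.pcd`` / ``.gen`` extensions win outright; otherwise the content
    is sniffed: tagged PCDDB metadata lines mean ``pcd``, a header plus a
    numeric block of three or more columns means ``gen``, and a plain
    numeric two-column body means ``two_column``.
    """
    lowered = filename.lower()
    if lowered.endswith(".pcd"):
        return FileFormat.PCD
    if lowered.endswith(".gen"):
        return FileFormat.GEN
    content = text if isinstance(text, str) else text.read()
    lines = content.splitlines()
    for line in lines[:60]:
        m = _TAG_SPLIT_RE.match(line.strip())
        if m and m.group("tag").strip().lower() in _PCD_ID_TAGS + _PCD_NAME_TAGS:
            return FileFormat.PCD
    rows = [_try_parse_row(line) for line in lines]
    numeric = [r for r in rows if r is not None]
    if len(numeric) >= 2:
        if any(len(r) >= 3 for r in numeric):
            return FileFormat.GEN
        return FileFormat.TWO_COLUMN
    raise SpectrumFormatError(
        f"{filename}: undecidable format (no PCDDB tags, no numeric block; "
        "tried pcd, gen, two_column)"
    )


def parse_any(
    filename: str,
    text: Union[str, TextIO],
    *,
    units: Units = Units.DELTA_EPSILON,
) -> Spectrum:
    """Detect the dialect of ``text`` and parse it.

    ``units`` applies only to the unit-less dialects (``gen``,
    ``two_column``); a ``.pcd`` entry states its own units.
    """
    content = text if isinstance(text, str) else text.read()
    fmt = detect_format(filename, content)
    stem = re.sub(r"\.[^.]*$", "", filename.rsplit("/", 1)[-1])
    if fmt is FileFormat.PCD:
        return parse_pcd(content, id=stem)
    if fmt is FileFormat.GEN:
        return parse_gen(content, id=stem, units=units)
    return parse_two_column(content, id=stem, units=units)


def convert_units(s: Spectrum, target: Units) -> Spectrum:
    """Convert a spectrum between Δε and mean residue ellipticity.

    Uses the per-residue convention [θ] = 3298.2 × Δε. Converting to the
    spectrum's own units returns it unchanged.
    """
    if s.units is target:
        return s
    if target is Units.MEAN_RESIDUE_ELLIPTICITY:
        factor = MRE_PER_DELTA_EPSILON
    else:
        factor = 1.0 / MRE_PER_DELTA_EPSILON
    return replace(s, values=s.values * factor, units=target)


def write_two_column(s: Spectrum, target: TextIO) -> None:
    """Write a spectrum as two-column ASCII, descending wavelength.

    Descending order follows instrument-scan convention; values are
    written at full float precision so a re-parse reproduces the spectrum
    bit-for-bit up to float round-trip.
    """
    for wl, val in zip(s.wavelengths[::-1], s.values[::-1]):
        target.write(f"{float(wl)!r} {float(val)!r}\n")


def dumps_two_column(s: Spectrum) -> str:
    buf = io.StringIO()
    write_two_column(s, buf)
    return buf.getvalue()
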