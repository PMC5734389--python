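"""Synthetic protein-like CD spectra for testing and demonstration.

Real far-UV protein CD spectra are, to a first approximation, linear
combinations of secondary-structure basis spectra: an α-helix signature
with a positive band near 193 nm and the twin negative bands near 208
and 222 nm, a β-sheet signature with a positive band near 195 nm and a
negative band near 218 nm, and a disordered-coil signature with a single
negative band near 198 nm. The generator models each basis as a fixed
sum of Gaussian bands (positions, widths and amplitudes are documented
constants in Δε units — test fixtures, not physics), mixes them by
secondary-structure fractions, and adds controllable magnitude scaling,
wavelength offset and Gaussian noise.

Everything is deterministic given the seed, so frozen-seed regression
tests are bit-stable. The generator can also emit fixture files in all
three supported on-disk formats to exercise the parsers.

What this emulates and what it does not: the spectra have realistic band
positions, signs and relative magnitudes, so the *relative* behavior of
the matching methods (scale invariance, shift recovery, family
discrimination) transfers; it omits aromatic side-chain contributions,
membrane-protein band shapes and wavelength-dependent instrument noise,
so absolute NRMSD scales on real data will differ.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace
from enum import Enum

import numpy as np

from .preprocess import Window
from .spectra_io import Spectrum, Units, dumps_two_column

#: Default synthesis grid: generous far-UV range at instrument-like step.
DEFAULT_GRID = Window(175.0, 260.0)
DEFAULT_GRID_STEP = 0.5


class BasisKind(Enum):
    HELIX = "helix"
    SHEET = "sheet"
    COIL = "coil"


#: Gaussian band parameters per basis: (center nm, sigma nm, amplitude Δε).
#: Amplitudes follow canonical protein CD basis shapes: helix with the
#: +193 / −208 / −222 nm triple, sheet with +195 / −218, coil with a
#: single negative band at 198 nm.
BAND_TABLE: dict[BasisKind, tuple[tuple[float, float, float], ...]] = {
    BasisKind.HELIX: ((193.0, 6.5, 11.0), (208.0, 7.5, -9.3), (222.0, 9.5, -9.8)),
    BasisKind.SHEET: ((195.0, 7.0, 5.5), (218.0, 9.0, -4.2)),
    BasisKind.COIL: ((198.0, 7.0, -6.5),),
}


@dataclass(frozen=True)
class BasisSpec:
    """Recipe for one synthetic spectrum.

    ``fractions`` are (helix, sheet, coil), summing to 1. ``noise_sd`` is
    the Gaussian noise standard deviation as a fraction of the clean
    spectrum's peak magnitude. ``wl_offset`` displaces the wavelength
    axis, emulating a calibration offset.
    """

    fractions: tuple[float, float, float] = (1.0, 0.0, 0.0)
    magnitude_scale: float = 1.0
    noise_sd: float = 0.0
    wl_offset: float = 0.0
    seed: int = 0
    grid: Window = DEFAULT_GRID
    grid_step: float = DEFAULT_GRID_STEP

    def __post_init__(self) -> None:
        f = np.asarray(self.fractions, dtype=float)
        if f.shape != (3,) or np.any(f < -1e-12) or abs(f.sum() - 1.0) > 1e-9:
            raise ValueError(
                f"fractions must be 3 nonnegative numbers summing to 1, got {self.fractions}"
            )
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.magnitude_scale <= 0:
            raise ValueError(f"magnitude_scale must be > 0, got {self.magnitude_scale}")


def basis_band(kind: BasisKind, wavelengths: np.ndarray) -> np.ndarray:
    """Evaluate one secondary-structure basis on a wavelength grid.

    The grid must lie within [170, 280] nm, where the band model is
    meaningful.
    """
    wl = np.asarray(wavelengths, dtype=float)
    if wl.size and (wl.min() < 170.0 or wl.max() > 280.0):
        raise ValueError(
            f"grid [{wl.min()}, {wl.max()}] outside the modeled range [170, 280] nm"
        )
    out = np.zeros_like(wl)
    for center, sigma, amplitude in BAND_TABLE[BasisKind(kind)]:
        out += amplitude * np.exp(-0.5 * ((wl - center) / sigma) ** 2)
    return out


def generate_spectrum(spec: BasisSpec, *, id: str | None = None) -> Spectrum:
    """Synthesize one spectrum from a :class:`BasisSpec`.

    clean = magnitude_scale × Σ fraction_k × basis_k on the recipe grid;
    the wavelength axis is then displaced by ``wl_offset`` and Gaussian
    noise of sd = noise_sd × max|clean| is added, reproducibly from the
    seed.
    """
    n = int(np.floor((spec.grid.wl_max - spec.grid.wl_min) / spec.grid_step + 1e-9)) + 1
    wl = spec.grid.wl_min + spec.grid_step * np.arange(n)
    clean = spec.magnitude_scale * sum(
        frac * basis_band(kind, wl)
        for frac, kind in zip(spec.fractions, (BasisKind.HELIX, BasisKind.SHEET, BasisKind.COIL))
        if frac != 0.0
    )
    values = np.asarray(clean, dtype=float)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        values = values + rng.normal(
            0.0, spec.noise_sd * float(np.max(np.abs(values))), size=values.shape
        )
    h, s, c = spec.fractions
    sid = id if id is not None else f"synth_h{h:.2f}s{s:.2f}c{c:.2f}_seed{spec.seed}"
    return Spectrum(
        id=sid,
        name=f"synthetic (helix {h:.2f}, sheet {s:.2f}, coil {c:.2f})",
        wavelengths=wl + spec.wl_offset,
        values=values,
        units=Units.DELTA_EPSILON,
    )


def generate_family(n: int, base: BasisSpec, jitter: float) -> list[Spectrum]:
    """``n`` structurally similar spectra around a base recipe.

    Each member's fractions are the base's perturbed by a uniform draw in
    ±jitter per component, clipped at 0 and renormalized; member seeds
    derive deterministically from ``base.seed + index``, so the family is
    reproducible.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if not 0.0 <= jitter <= 0.5:
        raise ValueError(f"jitter must be in [0, 0.5], got {jitter}")
    out: list[Spectrum] = []
    for i in range(n):
        member_seed = base.seed + i
        if jitter > 0:
            rng = np.random.default_rng(member_seed + 10_000_019)
            f = np.asarray(base.fractions) + rng.uniform(-jitter, jitter, size=3)
            f = np.clip(f, 0.0, None)
            f = f / f.sum()
            fractions = tuple(float(x) for x in f)
        else:
            fractions = base.fractions
        member = replace(base, fractions=fractions, seed=member_seed)
        out.append(generate_spectrum(member, id=f"fam{base.seed}_{i:03d}"))
    return out


def write_fixture_file(s: Spectrum, path: str | os.PathLike, fmt: str = "two_column") -> None:
    """Emit a spectrum as a parser fixture in any supported dialect.

    ``fmt`` is ``"two_column"``, ``"gen"`` (header + 3 columns including a
    synthetic HT trace) or ``"pcd"`` (minimal tagged entry).
    """
    if fmt == "two_column":
        body = "# synthetic CD spectrum\n" + dumps_two_column(s)
    elif fmt == "gen":
        lines = [f"Generic CD data file: {s.id}", "wavelength  CD  HT"]
        for wl, val in zip(s.wavelengths[::-1], s.values[::-1]):
            ht = 300.0 + max(0.0, 200.0 - float(wl))  # plausible HT ramp-up
            lines.append(f"{float(wl)!r} {float(val)!r} {ht:.2f}")
        body = "\n".join(lines) + "\n"
    elif fmt == "pcd":
        unit_str = (
            "delta epsilon"
            if s.units is Units.DELTA_EPSILON
            else "mean residue ellipticity"
        )
        lines = [
            f"PCDDB ID                                     {s.id}",
            f"Protein Name                                 {s.name or s.id}",
            f"Y Units                                      {unit_str}",
            "Data                                         processed spectrum follows",
            "",
        ]
        lines += [
            f"{float(wl)!r} {float(val)!r}"
            for wl, val in zip(s.wavelengths[::-1], s.values[::-1])
        ]
        body = "\n".join(lines) + "\n"
    else:
        raise ValueError(f"unknown fixture format {fmt!r}")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(body)
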