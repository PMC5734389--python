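import math

import numpy as np
import pytest

from cdmatch import (
    BasisSpec,
    DegenerateSpectrumError,
    Spectrum,
    UndefinedStatisticError,
    Window,
    generate_spectrum,
    normalized_comparison,
    nrmsd,
    ratio_comparison,
    shift_spectrum,
    simple_fit,
    wavelength_shift,
)
from conftest import brute_nrmsd


def brute_shift_search(query, test, window, max_shift, shift_step, grid_step):
    """Exhaustive shift oracle: plain loops, no shortcuts, same tie-break."""
    n = int(math.floor(max_shift / shift_step + 1e-9))
    candidates = sorted(
        (shift_step * k for k in range(-n, n + 1)), key=lambda d: (abs(d), d)
    )
    best = None
    for delta in candidates:
        q_wl = [w + delta for w in query.wavelengths]
        lo = max(q_wl[0], test.wl_min, window.wl_min if window else -1e30)
        hi = min(q_wl[-1], test.wl_max, window.wl_max if window else 1e30)
        if not lo < hi:
            continue
        npts = int(math.floor((hi - lo) / grid_step + 1e-9)) + 1
        if npts < 10:
            continue
        grid = [lo + grid_step * i for i in range(npts)]
        qv = np.interp(grid, q_wl, query.values)
        tv = np.interp(grid, test.wavelengths, test.values)
        score = brute_nrmsd(qv, tv)
        if best is None or score < best[0]:
            best = (score, delta)
    return best


class TestNrmsd:
    def test_identical_is_zero(self):
        assert nrmsd([1.0, -2.0, 3.0], [1.0, -2.0, 3.0]) == 0.0

    def test_zero_test_is_one(self):
        assert nrmsd([1.0, 2.0, -3.0], [0.0, 0.0, 0.0]) == pytest.approx(1.0, abs=1e-15)

    def test_hand_evaluated_case(self):
        assert nrmsd([1.0, 2.0], [1.0, 1.0]) == pytest.approx(math.sqrt(0.2), abs=1e-15)

    def test_all_zero_query_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            nrmsd([0.0, 0.0], [1.0, 2.0])

    def test_asymmetric_in_query_and_test(self):
        assert nrmsd([1.0, 2.0], [2.0, 4.0]) != nrmsd([2.0, 4.0], [1.0, 2.0])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            nrmsd([1.0, 2.0], [1.0])


class TestSimpleFit:
    def test_self_match_zero(self, helix_spectrum):
        assert simple_fit(helix_spectrum, helix_spectrum).nrmsd == 0.0

    def test_doubled_spectrum_scores_one(self, helix_spectrum):
        doubled = Spectrum(
            id="x2",
            wavelengths=helix_spectrum.wavelengths,
            values=2.0 * helix_spectrum.values,
        )
        assert simple_fit(helix_spectrum, doubled).nrmsd == pytest.approx(1.0, abs=1e-12)

    def test_small_multiplicative_noise_scores_small(self):
        base = BasisSpec(fractions=(0.8, 0.1, 0.1), seed=5)
        a = generate_spectrum(base)
        b = Spectrum(id="b", wavelengths=a.wavelengths, values=a.values * 1.05)
        assert simple_fit(a, b).nrmsd < 0.10


class TestNormalizedComparison:
    @pytest.mark.parametrize("c", [0.1, 1.0, 3.0, 10.0])
    def test_pure_rescaling_removed(self, helix_spectrum, c):
        scaled = Spectrum(
            id="sc", wavelengths=helix_spectrum.wavelengths,
            values=c * helix_spectrum.values,
        )
        res = normalized_comparison(helix_spectrum, scaled)
        assert res.nrmsd == pytest.approx(0.0, abs=1e-12)
        assert res.scale_factor == pytest.approx(1.0 / c, rel=1e-12)

    def test_beats_simple_fit_on_magnitude_error(self):
        a = generate_spectrum(BasisSpec(fractions=(0.8, 0.1, 0.1), noise_sd=0.05, seed=20))
        b0 = generate_spectrum(BasisSpec(fractions=(0.8, 0.1, 0.1), noise_sd=0.05, seed=21))
        b = Spectrum(id="b3x", wavelengths=b0.wavelengths, values=3.0 * b0.values)
        assert normalized_comparison(a, b).nrmsd < simple_fit(a, b).nrmsd

    def test_zero_peak_is_degenerate(self, helix_spectrum):
        flat = Spectrum(
            id="flat",
            wavelengths=helix_spectrum.wavelengths,
            values=np.zeros_like(helix_spectrum.values),
        )
        with pytest.raises(DegenerateSpectrumError):
            normalized_comparison(helix_spectrum, flat)


class TestRatioComparison:
    @pytest.mark.parametrize("c", [-2.0, 0.5, 7.0])
    def test_scale_invariant_both_ways(self, helix_spectrum, c):
        scaled = Spectrum(
            id="sc", wavelengths=helix_spectrum.wavelengths,
            values=c * helix_spectrum.values,
        )
        assert ratio_comparison(helix_spectrum, scaled).nrmsd == pytest.approx(0.0, abs=1e-9)
        assert ratio_comparison(scaled, helix_spectrum).nrmsd == pytest.approx(0.0, abs=1e-9)

    def test_same_shape_different_magnitude_vs_simple(self, helix_spectrum):
        scaled = Spectrum(
            id="sc", wavelengths=helix_spectrum.wavelengths,
            values=4.0 * helix_spectrum.values,
        )
        assert ratio_comparison(helix_spectrum, scaled).nrmsd < 1e-9
        assert simple_fit(helix_spectrum, scaled).nrmsd > 0.5

    def test_band_coverage_required(self, helix_spectrum):
        from cdmatch import NoOverlapError

        narrow = Spectrum(
            id="narrow", wavelengths=np.arange(200.0, 215.0), values=np.ones(15)
        )
        with pytest.raises(NoOverlapError):
            ratio_comparison(helix_spectrum, narrow)


class TestWavelengthShift:
    def test_identity_wins_at_zero_shift(self, helix_spectrum):
        res = wavelength_shift(helix_spectrum, helix_spectrum)
        assert res.nrmsd == 0.0
        assert res.shift_nm == 0.0

    def test_recovers_injected_offset(self, helix_spectrum):
        displaced = shift_spectrum(helix_spectrum, 2.0)
        res = wavelength_shift(displaced, helix_spectrum)
        assert res.shift_nm == pytest.approx(-2.0, abs=0.1)
        assert res.nrmsd < 1e-6

    def test_never_worse_than_simple_fit(self, helix_spectrum, sheet_spectrum):
        w = Window(195, 245)
        shift_res = wavelength_shift(helix_spectrum, sheet_spectrum, w)
        simple_res = simple_fit(helix_spectrum, sheet_spectrum, w)
        assert shift_res.nrmsd <= simple_res.nrmsd + 1e-12

    def test_zero_max_shift_degenerates_to_simple_fit(self, helix_spectrum, sheet_spectrum):
        res = wavelength_shift(helix_spectrum, sheet_spectrum, max_shift=0.0)
        assert res.nrmsd == simple_fit(helix_spectrum, sheet_spectrum).nrmsd
        assert res.shift_nm == 0.0


class TestOracleEquivalence:
    """Each method against an independent brute-force evaluation."""

    @staticmethod
    def _random_pair(seed):
        rng = np.random.default_rng(seed)
        fr = rng.dirichlet([2.0, 1.5, 1.0])
        fr2 = rng.dirichlet([2.0, 1.5, 1.0])
        a = generate_spectrum(
            BasisSpec(fractions=tuple(fr), noise_sd=0.03, seed=int(seed)),
            id=f"qa{seed}",
        )
        b = generate_spectrum(
            BasisSpec(
                fractions=tuple(fr2),
                magnitude_scale=float(rng.uniform(0.5, 2.0)),
                noise_sd=0.03,
                wl_offset=float(rng.uniform(-1.5, 1.5)),
                seed=int(seed) + 500,
            ),
            id=f"qb{seed}",
        )
        return a, b

    @pytest.mark.parametrize("seed", range(25))
    def test_simple_and_normalized_match_brute_force(self, seed):
        a, b = self._random_pair(seed)
        w = Window(190, 250)
        grid = np.arange(190.0, 250.0 + 1e-9, 1.0)
        # clamp to actual overlap (b may be offset)
        lo = max(a.wl_min, b.wl_min, 190.0)
        hi = min(a.wl_max, b.wl_max, 250.0)
        npts = int(math.floor(hi - lo + 1e-9)) + 1
        grid = lo + np.arange(npts) * 1.0
        qv = np.interp(grid, a.wavelengths, a.values)
        tv = np.interp(grid, b.wavelengths, b.values)
        assert simple_fit(a, b, w).nrmsd == pytest.approx(
            brute_nrmsd(qv, tv), abs=1e-9
        )
        scale = qv[np.argmax(np.abs(qv))] / tv[np.argmax(np.abs(tv))]
        assert normalized_comparison(a, b, w).nrmsd == pytest.approx(
            brute_nrmsd(qv, tv * scale), abs=1e-9
        )

    @pytest.mark.parametrize("seed", range(25))
    def test_ratio_matches_brute_force(self, seed):
        a, b = self._random_pair(seed)
        ra = [a.value_at(208) / a.value_at(222), a.value_at(195) / a.value_at(222),
              a.value_at(195) / a.value_at(208)]
        rb = [b.value_at(208) / b.value_at(222), b.value_at(195) / b.value_at(222),
              b.value_at(195) / b.value_at(208)]
        assert ratio_comparison(a, b).nrmsd == pytest.approx(
            brute_nrmsd(ra, rb), abs=1e-9
        )

    @pytest.mark.parametrize("seed", range(10))
    def test_shift_matches_exhaustive_search(self, seed):
        a, b = self._random_pair(seed)
        w = Window(190, 250)
        res = wavelength_shift(a, b, w, max_shift=2.0, shift_step=0.25)
        oracle = brute_shift_search(a, b, w, 2.0, 0.25, 1.0)
        assert res.nrmsd == pytest.approx(oracle[0], abs=1e-9)
        assert res.shift_nm == pytest.approx(oracle[1], abs=1e-12)
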