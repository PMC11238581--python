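import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vesifit.errors import ConfigurationError, InvalidInputError
from vesifit.ffe import (
    DeviceCalibration,
    Electropherogram,
    detect_peaks,
    effective_field,
    henry_factor,
    mobilities_from_series,
    mobility_from_deflections,
    mobility_from_zeta,
    zeta_from_mobility,
)
from vesifit.physchem import BufferSpec, SolventProps
from vesifit.synthetic import generate_electropherogram_series

CAL = DeviceCalibration()
BUF = BufferSpec(phosphate_total=0.020, pH=6.5)
SOLV = SolventProps()


class TestEffectiveField:
    def test_zero_voltage(self):
        assert effective_field(0.0, 0.0, CAL) == 0.0

    def test_lossless_electrodes(self):
        cal = DeviceCalibration(electrode_resistance=1e-12)
        assert effective_field(80.0, 1e-3, cal) == pytest.approx(80.0 / cal.chamber_width)

    def test_ohmic_drop(self):
        """80 V applied, 30 V lost over the electrodes, 1 mm chamber."""
        cal = DeviceCalibration(electrode_resistance=30e3, chamber_width=1e-3)
        assert effective_field(80.0, 1e-3, cal) == pytest.approx((80.0 - 30.0) / 1e-3)

    def test_inconsistent_calibration_rejected(self):
        cal = DeviceCalibration(electrode_resistance=100e3)
        with pytest.raises(InvalidInputError):
            effective_field(10.0, 1e-3, cal)  # 100 V drop > 10 V applied


class TestPeakDetection:
    def _trace(self, y):
        x = np.linspace(0, CAL.chamber_width, 256)
        return Electropherogram(x, y, applied_voltage=0.0, measured_current=0.0)

    def test_single_gaussian(self):
        x = np.linspace(0, CAL.chamber_width, 256)
        mu, sig = 0.8e-3, 50e-6
        peaks = detect_peaks(self._trace(np.exp(-0.5 * ((x - mu) / sig) ** 2)))
        assert len(peaks) == 1
        assert abs(peaks[0][0] - mu) < 0.01 * sig

    def test_two_separated_gaussians(self):
        x = np.linspace(0, CAL.chamber_width, 256)
        p = dict(zip(("mu1", "mu2", "sig"), (0.6e-3, 1.4e-3, 60e-6)))
        y = np.exp(-0.5 * ((x - p["mu1"]) / p["sig"]) ** 2) \
            + 0.7 * np.exp(-0.5 * ((x - p["mu2"]) / p["sig"]) ** 2)
        peaks = detect_peaks(self._trace(y), max_species=2)
        assert len(peaks) == 2
        assert abs(peaks[0][0] - p["mu1"]) < 0.05 * p["sig"]
        assert abs(peaks[1][0] - p["mu2"]) < 0.05 * p["sig"]

    def test_pure_noise_degenerate(self):
        rng = np.random.default_rng(0)
        peaks = detect_peaks(self._trace(np.abs(rng.normal(0, 1e-3, 256))), max_species=2)
        assert len(peaks) <= 1  # nothing above the noise floor beyond a token component

    def test_all_zero_rejected(self):
        with pytest.raises(InvalidInputError):
            detect_peaks(self._trace(np.zeros(256)))


class TestMobilityRegression:
    def test_zero_displacement(self):
        pairs = [(0.0, 0.0), (1e3, 0.0), (2e3, 0.0)]
        assert mobility_from_deflections(pairs, 2.0).mobility == 0.0

    def test_exact_linear_series(self):
        mu, t = -1.52e-8, 2.5
        fields = np.array([0.0, 1e3, 2e3, 3e3, 4e3])
        pairs = [(e, mu * e * t) for e in fields]
        res = mobility_from_deflections(pairs, t)
        assert res.mobility == pytest.approx(mu, rel=1e-3)
        assert res.stderr == pytest.approx(0.0, abs=1e-12)

    def test_singular_fields_rejected(self):
        with pytest.raises(InvalidInputError):
            mobility_from_deflections([(1e3, 1e-4), (1e3, 2e-4)], 1.0)


class TestSeriesAnalysis:
    def test_round_trip_noise_free(self):
        series = generate_electropherogram_series(
            [-1.52e-8], [1.0], [0, 20, 40, 60, 80], CAL, 0.0, seed=0
        )
        res = mobilities_from_series(series, CAL)
        assert res[0].mobility == pytest.approx(-1.52e-8, rel=1e-3)

    def test_round_trip_with_noise(self):
        """2% intensity noise: mean recovery over 20 seeds within 2%."""
        vals = []
        for seed in range(20):
            series = generate_electropherogram_series(
                [-1.52e-8], [1.0], [0, 20, 40, 60, 80], CAL, 0.02, seed=1000 + seed
            )
            vals.append(mobilities_from_series(series, CAL)[0].mobility)
        assert np.mean(vals) == pytest.approx(-1.52e-8, rel=0.02)

    def test_intensity_scale_invariance(self):
        s1 = generate_electropherogram_series(
            [-1.52e-8], [1.0], [0, 20, 40, 60, 80], CAL, 0.0, seed=0
        )
        s2 = [
            Electropherogram(e.lateral_positions, 37.5 * e.intensities,
                             e.applied_voltage, e.measured_current, e.channel)
            for e in s1
        ]
        m1 = mobilities_from_series(s1, CAL)[0].mobility
        m2 = mobilities_from_series(s2, CAL)[0].mobility
        assert m1 == pytest.approx(m2, rel=1e-9)


class TestHenryFactor:
    def test_limits(self):
        assert henry_factor(1e-9) == pytest.approx(1.0, abs=1e-6)
        assert henry_factor(1e9) == pytest.approx(1.5, abs=1e-6)

    def test_reference_value(self):
        """κa = 1: evaluate the closure formula longhand."""
        ka = 1.0
        expected = 1.0 + 0.5 * (1.0 + 2.5 / (ka * (1.0 + 2.0 * math.exp(-ka)))) ** -3
        assert henry_factor(1.0) == pytest.approx(expected, rel=1e-12)

    def test_monotone_and_bounded(self):
        grid = np.geomspace(1e-4, 1e6, 400)
        vals = np.array([henry_factor(k) for k in grid])
        assert np.all(np.diff(vals) > 0)
        assert np.all((vals >= 1.0) & (vals <= 1.5))


class TestZeta:
    def test_zero_mobility(self):
        assert zeta_from_mobility(0.0, 3.3, BUF, SOLV).zeta_mv == 0.0

    def test_sign_follows_mobility(self):
        res = zeta_from_mobility(-1.52e-8, 3.3, BUF, SOLV, model="henry")
        assert res.zeta_mv < 0
        assert res.kappa_a > 0

    def test_smoluchowski_henry_agree_at_large_kappa_a(self):
        # large particle in strong electrolyte: kappa*a ~ 1e3
        buf = BufferSpec(0.0, 7.0, added_salt=(("Na+", 1.0, 1), ("Cl-", 1.0, -1)))
        hen = zeta_from_mobility(-2e-8, 300.0, buf, SOLV, model="henry")
        smo = zeta_from_mobility(-2e-8, 300.0, buf, SOLV, model="smoluchowski")
        assert hen.kappa_a > 500
        assert hen.zeta_mv == pytest.approx(smo.zeta_mv, rel=0.01)

    @settings(max_examples=40, derandomize=True)
    @given(zeta=st.floats(-100, 100), lka=st.floats(-1, 3))
    def test_round_trip_closure(self, zeta, lka):
        """ζ→μ→ζ closes to < 0.1 mV across the physical range of κa."""
        # choose radius to realize the requested kappa_a in the test buffer
        from vesifit.physchem import debye_length, ionic_strength

        ka = 10.0**lka
        r_nm = ka * debye_length(ionic_strength(BUF), SOLV) * 1e9
        mu = mobility_from_zeta(zeta, r_nm, BUF, SOLV, model="henry")
        back = zeta_from_mobility(mu, r_nm, BUF, SOLV, model="henry")
        assert abs(back.zeta_mv - zeta) < 0.1

    def test_unknown_model_rejected(self):
        with pytest.raises(ConfigurationError):
            zeta_from_mobility(-1e-8, 3.3, BUF, SOLV, model="obrien")
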