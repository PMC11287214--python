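"""4PL dose-response fitting, EC50 confidence intervals, and preference ranking."""

import math

import numpy as np
import pytest

from corrikit.dilution import serial_dilution_series
from corrikit.doseresponse import (
    DoseResponseDataset,
    FourPLFit,
    ec50_confidence_interval,
    fit_fourpl,
    fourpl_inverse,
    fourpl_predict,
    preference_ranking,
)

SERIES = serial_dilution_series(10e-9, 12, 4.0).concentrations


def _simulate(bottom, top, hill, ec50, conc=None, noise=0.0, seed=0, reps=1):
    conc = SERIES if conc is None else np.asarray(conc)
    conc = np.repeat(conc, reps)
    y = fourpl_predict(conc, bottom, top, hill, ec50)
    if noise:
        y = np.clip(y + np.random.default_rng(seed).normal(0, noise, conc.size),
                    0, 2)
    return DoseResponseDataset("iso", "B12", conc, np.asarray(y, float))


class TestPredict:
    def test_midpoint(self):
        assert fourpl_predict(1e-12, 0.05, 0.6, 1.0, 1e-12) == pytest.approx(0.325)

    def test_asymptotes(self):
        assert fourpl_predict(1e3, 0.05, 0.6, 1.0, 1e-12) == pytest.approx(0.6, abs=1e-9)
        assert fourpl_predict(1e-30, 0.05, 0.6, 1.0, 1e-12) == pytest.approx(0.05, abs=1e-9)

    def test_example_value(self):
        # bottom 0.05, top 0.6, hill 1, ec50 1 pM, x = 3 pM -> 0.05 + 0.55 * 3/4
        assert fourpl_predict(3e-12, 0.05, 0.6, 1.0, 1e-12) == pytest.approx(0.4625)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            fourpl_predict(0.0, 0.05, 0.6, 1.0, 1e-12)
        with pytest.raises(ValueError):
            fourpl_predict(1e-12, 0.05, 0.6, 1.0, -1.0)

    def test_inverse_is_identity_within_span(self):
        params = (0.05, 0.7, 1.4, 3e-12)
        for x in np.logspace(-14, -9, 11):
            y = fourpl_predict(x, *params)
            assert fourpl_inverse(y, *params) == pytest.approx(x, rel=1e-9)


class TestFit:
    def test_noise_free_recovery(self):
        truth = dict(bottom=0.05, top=0.7, hill=1.5, ec50=1e-12)
        fit = fit_fourpl(_simulate(**truth))
        assert fit.status == "fit"
        for name, val in truth.items():
            assert getattr(fit, name) == pytest.approx(val, rel=1e-4)

    def test_scale_equivariance(self):
        truth = dict(bottom=0.05, top=0.7, hill=1.2, ec50=2e-12)
        f1 = fit_fourpl(_simulate(**truth))
        scaled = _simulate(**truth)
        f2 = fit_fourpl(DoseResponseDataset(
            "iso", "B12", scaled.concentrations * 1e3, scaled.od600))
        assert f2.ec50 == pytest.approx(f1.ec50 * 1e3, rel=1e-6)
        assert f2.bottom == pytest.approx(f1.bottom, abs=1e-8)
        assert f2.top == pytest.approx(f1.top, abs=1e-8)
        assert f2.hill == pytest.approx(f1.hill, rel=1e-6)

    def test_no_growth_status(self):
        data = DoseResponseDataset("iso", "B12", SERIES,
                                   np.full(SERIES.size, 0.02))
        assert fit_fourpl(data).status == "NG"

    def test_insufficient_concentrations_nd(self):
        data = DoseResponseDataset("iso", "B12", [1e-9, 1e-10, 1e-11],
                                   [0.7, 0.4, 0.1])
        assert fit_fourpl(data).status == "ND"

    def test_flat_above_floor_nd(self):
        data = DoseResponseDataset("iso", "B12", SERIES,
                                   np.full(SERIES.size, 0.4))
        assert fit_fourpl(data).status == "ND"


class TestConfidenceInterval:
    def test_noise_free_width_shrinks_to_zero(self):
        fit = fit_fourpl(_simulate(0.05, 0.7, 1.2, 1e-12))
        width = math.log10(fit.ec50_ci_high) - math.log10(fit.ec50_ci_low)
        assert width < 1e-3

    def test_recompute_matches_fit(self):
        data = _simulate(0.05, 0.7, 1.2, 1e-12, noise=0.02, seed=3, reps=2)
        fit = fit_fourpl(data)
        lo, hi = ec50_confidence_interval(fit, data)
        assert lo <= fit.ec50 <= hi

    def test_undetermined_lower_bound_sentinel(self):
        # ec50 below the lowest tested concentration: no low-conc decline,
        # so the lower CI bound cannot be determined within the tested range
        data = _simulate(0.05, 0.8, 1.0, 3e-15, noise=0.01, seed=7)
        fit = fit_fourpl(data)
        assert fit.status == "fit"
        assert fit.ci_low_sentinel

    def test_requires_successful_fit(self):
        with pytest.raises(ValueError):
            ec50_confidence_interval(FourPLFit(status="NG"),
                                     _simulate(0.05, 0.7, 1.0, 1e-12))

    def test_coverage_over_seeded_simulations(self):
        """Wald intervals on log10 EC50 cover truth at close to nominal rate."""
        covered = n_fit = 0
        rng = np.random.default_rng(99)
        for i in range(200):
            l10 = rng.uniform(-13.0, -10.5)
            data = _simulate(0.05, 0.8, 1.2, 10 ** l10, noise=0.02,
                             seed=1000 + i, reps=2)
            fit = fit_fourpl(data)
            if fit.status != "fit":
                continue
            n_fit += 1
            lo = math.log10(fit.ec50_ci_low)
            hi = math.log10(fit.ec50_ci_high)
            lo_ok = fit.ci_low_sentinel or lo <= l10
            hi_ok = fit.ci_high_sentinel or l10 <= hi
            covered += lo_ok and hi_ok
        assert n_fit >= 190
        assert 0.90 <= covered / n_fit <= 0.99


class TestPreference:
    def _fit(self, ec50):
        return fit_fourpl(_simulate(0.05, 0.7, 1.2, ec50))

    def test_lowest_ec50_preferred(self):
        fits = {"B12": self._fit(1e-12), "5OH": self._fit(1e-11),
                "ADE": FourPLFit(status="NG")}
        table = preference_ranking("iso", fits)
        assert table.preferred == "B12"
        assert table.ranking == ["B12", "5OH"]  # NG excluded but retained
        assert "ADE" in table.fits

    def test_all_ng_undefined(self):
        fits = {c: FourPLFit(status="NG") for c in ("B12", "5OH")}
        table = preference_ranking("iso", fits)
        assert table.preferred is None
        assert table.ranking == []

    def test_exact_tie_flagged(self):
        f = self._fit(1e-12)
        table = preference_ranking("iso", {"B12": f, "5OH": f})
        assert table.tie_flag
        assert table.preferred in ("B12", "5OH")
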