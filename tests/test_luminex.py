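"""Secretome calibration: blanks, 5PL curves, LOQ normalization, referencing."""

import numpy as np
import pandas as pd
import pytest

from rnmkit import (
    CalibrationError,
    SecretomePanel,
    StandardCurve5PL,
    aggregate_and_reference,
    calibrate_panel,
    fit_5pl,
    invert_5pl,
    make_synthetic_secretome,
    normalize_loq,
    subtract_blank,
)
from rnmkit.luminex import _five_pl
from rnmkit.synthetic import SyntheticSecretomeSpec

TRUE = dict(lower=50.0, upper=12_000.0, inflection=30.0, slope=1.4, asymmetry=1.2)


def standards_from(params, concs, rng=None, noise=0.0):
    mfi = _five_pl(np.asarray(concs), params["lower"], params["upper"],
                   params["inflection"], params["slope"], params["asymmetry"])
    if noise:
        mfi = mfi * np.exp(rng.normal(0.0, noise, size=len(concs)))
    return pd.DataFrame({"analyte": "A", "concentration": concs, "mfi": mfi})


def tiny_panel(mfis, blank=100.0):
    concs = np.geomspace(1.0, 1000.0, 8)
    std = standards_from(TRUE, concs)
    std["mfi"] += blank
    rows = [
        {"analyte": "A", "donor": f"d{i}", "condition": "control_unloaded", "day": 7, "mfi": m}
        for i, m in enumerate(mfis)
    ]
    return SecretomePanel(
        measurements=pd.DataFrame(rows),
        standards=std,
        blanks=pd.DataFrame({"analyte": ["A"], "mfi": [blank]}),
        loq=pd.DataFrame({"analyte": ["A"], "lloq": [1.0], "uloq": [1000.0]}),
    )


class TestBlankSubtraction:
    def test_net_mfi(self):
        panel = subtract_blank(tiny_panel([500.0]))
        assert panel.measurements["mfi"].iloc[0] == pytest.approx(400.0)
        assert not panel.measurements["floored"].iloc[0]

    def test_floor_flag(self):
        panel = subtract_blank(tiny_panel([60.0]))
        assert panel.measurements["mfi"].iloc[0] == 0.0
        assert bool(panel.measurements["floored"].iloc[0])

    def test_all_blank_panel(self):
        panel = subtract_blank(tiny_panel([100.0, 100.0, 100.0]))
        assert (panel.measurements["mfi"] == 0.0).all()

    def test_missing_blank_named(self):
        panel = tiny_panel([500.0])
        panel.blanks = pd.DataFrame({"analyte": ["B"], "mfi": [1.0]})
        with pytest.raises(CalibrationError, match="'A'"):
            subtract_blank(panel)


class TestFit5PL:
    def test_noiseless_parameter_recovery(self):
        """Standards generated exactly from a known curve give every
        parameter back within 1% relative error."""
        concs = np.geomspace(0.3, 3000.0, 10)
        curve = fit_5pl(standards_from(TRUE, concs))
        assert curve.converged and not curve.is_4pl_fallback
        for name, key in [("lower", "lower"), ("upper", "upper"),
                          ("inflection", "inflection"), ("slope", "slope"),
                          ("asymmetry", "asymmetry")]:
            got = getattr(curve, name)
            assert got == pytest.approx(TRUE[key], rel=0.01), name

    def test_noisy_median_inflection(self):
        """2% multiplicative MFI noise, 50 replicate fits: the median
        inflection estimate stays within 5% of truth."""
        rng = np.random.default_rng(123)
        concs = np.geomspace(0.3, 3000.0, 10)
        estimates = []
        for _ in range(50):
            curve = fit_5pl(standards_from(TRUE, concs, rng=rng, noise=0.02))
            if curve.converged:
                estimates.append(curve.inflection)
        assert len(estimates) >= 45
        med = float(np.median(estimates))
        assert abs(med - TRUE["inflection"]) / TRUE["inflection"] < 0.05

    def test_four_point_fallback_to_4pl(self):
        concs = np.geomspace(1.0, 1000.0, 4)
        curve = fit_5pl(standards_from(TRUE, concs))
        assert curve.is_4pl_fallback
        assert curve.asymmetry == 1.0

    def test_too_few_points(self):
        concs = np.geomspace(1.0, 100.0, 3)
        with pytest.raises(CalibrationError, match="4"):
            fit_5pl(standards_from(TRUE, concs))


class TestInvert5PL:
    @pytest.fixture()
    def curve(self):
        return StandardCurve5PL(**TRUE)

    @pytest.mark.parametrize("c", [1.5, 5.0, 30.0, 400.0])
    def test_round_trip(self, curve, c):
        mfi = float(curve.predict(c))
        conc, censor = invert_5pl(curve, mfi, lloq=1.0, uloq=1000.0)
        assert censor == "none"
        assert conc == pytest.approx(c, rel=1e-9)

    def test_lower_censoring(self, curve):
        conc, censor = invert_5pl(curve, TRUE["lower"], lloq=1.0, uloq=1000.0)
        assert (conc, censor) == (1.0, "lower")

    def test_upper_censoring(self, curve):
        conc, censor = invert_5pl(curve, TRUE["upper"] + 5.0, lloq=1.0, uloq=1000.0)
        assert (conc, censor) == (1000.0, "upper")

    def test_monotonicity(self, curve):
        """Increasing MFI never decreases the reported concentration."""
        mfis = np.linspace(0.0, TRUE["upper"] * 1.01, 200)
        concs = [invert_5pl(curve, m, lloq=1.0, uloq=1000.0)[0] for m in mfis]
        assert all(b >= a for a, b in zip(concs, concs[1:]))


class TestNormalizeLOQ:
    @pytest.mark.parametrize(
        "c, expected", [(10.0, 0.0), (1000.0, 1.0), (505.0, 0.5), (1.0, 0.0), (2000.0, 1.0)]
    )
    def test_anchors_and_clipping(self, c, expected):
        assert normalize_loq(c, 10.0, 1000.0) == pytest.approx(expected)

    def test_bad_limits(self):
        with pytest.raises(CalibrationError):
            normalize_loq(5.0, 10.0, 10.0)


@pytest.fixture(scope="module")
def noiseless():
    spec = SyntheticSecretomeSpec(seed=5, n_analytes=10, sigma_donor=0.0, sigma_resid=0.0)
    panel, truth = make_synthetic_secretome(spec)
    calibrated, _, excluded = calibrate_panel(panel)
    return panel, truth, calibrated, excluded


class TestAggregateAndReference:
    def test_noiseless_pipeline_recovers_planted_values(self, noiseless):
        """Blank subtraction -> 5PL -> LOQ normalization on noise-free
        input reproduces the generator's planted x exactly."""
        _, truth, calibrated, excluded = noiseless
        assert excluded == []
        merged = calibrated.merge(truth["x_true"], on=["analyte", "condition", "day"])
        assert len(merged) == len(calibrated)
        assert np.max(np.abs(merged["x"] - merged["x_true"])) < 1e-9

    def test_reference_subtraction_range_and_zero(self, noiseless):
        _, _, calibrated, excluded = noiseless
        sec = aggregate_and_reference(calibrated, excluded=excluded)
        ref_rows = sec.table[sec.table["condition"] == "control_unloaded"]
        assert (ref_rows["x_ref"] == 0.0).all()
        assert sec.table["x_ref"].between(-1.0, 1.0).all()
        assert sec.table["x"].between(0.0, 1.0).all()

    def test_planted_tnf_effect_recovered(self):
        """+0.3 planted TNF effect, σ_donor = 0.05, 5 donors: the median
        recovered effect over 20 seeds lands within ±0.05."""
        effects = []
        for seed in range(20):
            spec = SyntheticSecretomeSpec(
                seed=seed, n_analytes=6, sigma_donor=0.05, sigma_resid=0.0
            )
            panel, truth = make_synthetic_secretome(spec)
            calibrated, _, excl = calibrate_panel(panel)
            sec = aggregate_and_reference(calibrated, excluded=excl)
            effects.append(float(sec.vector("TNF_unloaded")["IL-6"]))  # tnf_up class
        assert abs(float(np.median(effects)) - 0.3) <= 0.05

    def test_missing_reference_excludes_analyte(self, noiseless):
        _, _, calibrated, _ = noiseless
        trimmed = calibrated[
            ~((calibrated["analyte"] == "IL-6") & (calibrated["condition"] == "control_unloaded"))
        ]
        with pytest.warns(UserWarning, match="IL-6"):
            sec = aggregate_and_reference(trimmed)
        assert "IL-6" not in set(sec.table["analyte"])
        assert "IL-6" in sec.excluded

    def test_per_day_mode(self, noiseless):
        _, _, calibrated, excl = noiseless
        sec = aggregate_and_reference(calibrated, per_day=True, excluded=excl)
        assert set(sec.table["day"]) == {7, 14}
        v7 = sec.vector("TNF_unloaded", day=7)
        assert len(v7) > 0

    def test_missing_reference_condition_error(self, noiseless):
        _, _, calibrated, _ = noiseless
        sub = calibrated[calibrated["condition"] != "control_unloaded"]
        with pytest.raises(CalibrationError, match="control_unloaded"):
            aggregate_and_reference(sub)


def test_panel_invariants_enforced():
    with pytest.raises(CalibrationError, match="lloq"):
        SecretomePanel(
            measurements=pd.DataFrame(columns=["analyte", "donor", "condition", "day", "mfi"]),
            standards=pd.DataFrame(
                {"analyte": ["A"] * 4, "concentration": [1, 10, 100, 1000], "mfi": [1, 2, 3, 4]}
            ),
            blanks=pd.DataFrame({"analyte": ["A"], "mfi": [0.0]}),
            loq=pd.DataFrame({"analyte": ["A"], "lloq": [10.0], "uloq": [1.0]}),
        )
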