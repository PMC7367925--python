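"""4PL fitting, BMC/PoD derivation, censoring and cytotoxicity anchoring."""

import math

import numpy as np
import pytest
from scipy.optimize import brentq

from navitro import (Curve4PL, PoDPolicy, SyntheticSpec, assemble_pod_matrix,
                     cytotox_anchor, derive_bmc, derive_pod, fit_4pl,
                     generate_plate, normalize_to_controls, reference_ec50)
from navitro.curves import NO_EFFECT, PoDResult
from navitro.errors import (BlockedStateError, ConflictError,
                            DegenerateInputError, InsufficientDataError,
                            InvalidValueError, NoEC50Error)
from navitro.platedata import MetadataBlock, PlateDataset, WellMeasurement
from navitro.synth import flat_curve

CONCS_13 = [4.0 + 0.5 * i for i in range(13)]


def _md():
    return MetadataBlock(test_method_id="TM", lab_id="lab", solvent="DMSO",
                         exposure_h=24.0)


class TestNormalizeToControls:
    def _plate(self, controls, treatments, blanks=()):
        wells = []
        names = iter(f"{r}{c}" for r in "ABCDEFGH" for c in range(1, 13))
        for v in controls:
            wells.append(WellMeasurement("P1", next(names), "solvent_control",
                                         "viability", v))
        for v in blanks:
            wells.append(WellMeasurement("P1", next(names), "blank", "viability", v))
        for v in treatments:
            wells.append(WellMeasurement("P1", next(names), "treatment", "viability",
                                         v, compound_id="x", conc_neglog_molar=5.0))
        return PlateDataset(wells, _md())

    def test_control_mean_maps_to_100(self):
        rows = normalize_to_controls(self._plate([90, 110], [100]), "viability")
        treat = [r for r in rows if r["role"] == "treatment"]
        assert treat[0]["response_percent"] == pytest.approx(100.0)

    def test_half_of_control_mean_maps_to_50(self):
        rows = normalize_to_controls(self._plate([90, 110], [50]), "viability")
        treat = [r for r in rows if r["role"] == "treatment"]
        assert treat[0]["response_percent"] == pytest.approx(50.0)

    def test_blank_subtraction_first(self):
        rows = normalize_to_controls(
            self._plate([110, 130], [70], blanks=[20, 20]), "viability")
        treat = [r for r in rows if r["role"] == "treatment"]
        assert treat[0]["response_percent"] == pytest.approx(50.0)

    def test_zero_raw_with_zero_blank_is_zero(self):
        rows = normalize_to_controls(self._plate([100], [0]), "viability")
        treat = [r for r in rows if r["role"] == "treatment"]
        assert treat[0]["response_percent"] == pytest.approx(0.0)

    def test_solvent_controls_average_100_on_every_plate(self):
        rows = normalize_to_controls(self._plate([90, 100, 110], [50]), "viability")
        ctrl = [r["response_percent"] for r in rows if r["role"] == "solvent_control"]
        assert np.mean(ctrl) == pytest.approx(100.0)

    def test_no_usable_controls(self):
        ds = self._plate([], [50])
        with pytest.raises(DegenerateInputError):
            normalize_to_controls(ds, "viability")

    def test_flagged_controls_excluded_from_reference(self):
        ds = self._plate([100, 100], [100])
        ctrl = [m for m in ds.measurements if m.role == "solvent_control"]
        ctrl[0].raw_value = 1e5
        ctrl[0].flags = frozenset({"outlier"})
        rows = normalize_to_controls(ds, "viability")
        treat = [r for r in rows if r["role"] == "treatment"]
        assert treat[0]["response_percent"] == pytest.approx(100.0)


class TestFit4PL:
    def test_noiseless_parameter_recovery(self):
        truth = Curve4PL(top=100.0, bottom=0.0, log_ec50=6.0, hill=1.0)
        resp = truth.predict(CONCS_13)
        fit = fit_4pl(CONCS_13, resp, "decline")
        assert fit.fit_ok
        assert fit.top == pytest.approx(100.0, abs=1e-6)
        assert fit.bottom == pytest.approx(0.0, abs=1e-6)
        assert fit.log_ec50 == pytest.approx(6.0, abs=1e-6)
        assert fit.hill == pytest.approx(1.0, abs=1e-6)

    def test_noiseless_induction_recovery(self):
        truth = Curve4PL(top=300.0, bottom=100.0, log_ec50=7.0, hill=1.5,
                         direction="induce")
        fit = fit_4pl(CONCS_13, truth.predict(CONCS_13), "induce")
        assert fit.fit_ok
        assert fit.log_ec50 == pytest.approx(7.0, abs=1e-5)
        assert fit.top == pytest.approx(300.0, rel=1e-5)

    def test_flat_response_is_no_effect(self):
        fit = fit_4pl(CONCS_13, [100.0] * 13, "decline")
        assert not fit.fit_ok
        assert "no effect" in fit.diagnostics.convergence_note

    def test_too_few_concentrations(self):
        with pytest.raises(InsufficientDataError):
            fit_4pl([4, 5, 6], [100, 80, 20], "decline")

    def test_ec50_stays_within_tested_range_plus_margin(self):
        truth = Curve4PL(top=100.0, bottom=0.0, log_ec50=2.0, hill=1.0)
        fit = fit_4pl(CONCS_13, truth.predict(CONCS_13), "decline")
        assert fit.log_ec50 >= CONCS_13[0] - 1.0 - 1e-9

    def test_median_ec50_error_under_noise(self):
        # 13-point series, 3 replicates, 5% multiplicative noise, 100 seeds
        errors = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            truth = Curve4PL(top=100.0, bottom=0.0, log_ec50=6.0, hill=1.5)
            c = np.repeat(CONCS_13, 3)
            sigma = math.sqrt(math.log(1 + 0.05 ** 2))
            noise = rng.lognormal(-sigma ** 2 / 2, sigma, c.size)
            fit = fit_4pl(c, truth.predict(c) * noise, "decline")
            assert fit.fit_ok
            errors.append(abs(fit.log_ec50 - 6.0))
        assert np.median(errors) < 0.2


class TestDeriveBMC:
    def test_bmr50_equals_ec50(self):
        curve = Curve4PL(top=100.0, bottom=0.0, log_ec50=6.0, hill=1.0)
        assert derive_bmc(curve, 50.0).bmc_neglog_molar == pytest.approx(6.0)

    def test_bmr25_is_ec50_over_3_for_unit_hill(self):
        curve = Curve4PL(top=100.0, bottom=0.0, log_ec50=6.0, hill=1.0)
        bmc = derive_bmc(curve, 25.0)
        assert 10 ** -bmc.bmc_neglog_molar == pytest.approx(1e-6 / 3)

    def test_closed_form_matches_root_finding_on_1000_curves(self):
        rng = np.random.default_rng(12)
        for _ in range(1000):
            curve = Curve4PL(
                top=rng.uniform(90, 110), bottom=rng.uniform(-5, 40),
                log_ec50=rng.uniform(4.5, 9.0), hill=rng.uniform(0.3, 6.0),
                direction=rng.choice(["decline", "induce"]))
            if curve.direction == "induce":
                curve.top, curve.bottom = curve.bottom + 200, curve.top
            bmr = rng.uniform(5, min(45, abs(curve.top - curve.bottom) - 1))
            if bmr <= 0:
                continue
            bmc = derive_bmc(curve, bmr)
            target = 100 - bmr if curve.direction == "decline" else 100 + bmr
            lo, hi = min(curve.top, curve.bottom), max(curve.top, curve.bottom)
            if not (lo < target < hi):
                assert bmc.censored
                continue
            root = brentq(lambda c: float(curve.predict(c)) - target, -5, 20,
                          xtol=1e-12)
            assert bmc.bmc_neglog_molar == pytest.approx(root, abs=1e-9)

    def test_weak_curve_is_censored_at_highest_tested_conc(self):
        curve = Curve4PL(top=100.0, bottom=85.0, log_ec50=6.0, hill=1.0)
        curve.diagnostics.conc_min_neglog = 4.0
        bmc = derive_bmc(curve, 25.0)
        assert bmc.censored
        assert bmc.censor_bound == 4.0

    def test_bmc_monotone_in_bmr(self):
        curve = Curve4PL(top=100.0, bottom=0.0, log_ec50=6.0, hill=2.0)
        bmcs = [derive_bmc(curve, b).bmc_neglog_molar for b in (10, 25, 50, 75)]
        assert all(a >= b for a, b in zip(bmcs, bmcs[1:]))

    @pytest.mark.parametrize("bmr", [0.0, -5.0, 100.0])
    def test_invalid_bmr(self, bmr):
        curve = Curve4PL(top=100.0, bottom=0.0, log_ec50=6.0, hill=1.0)
        with pytest.raises(InvalidValueError):
            derive_bmc(curve, bmr)


class TestDerivePoD:
    def test_bmc_1um_gives_pod_6(self):
        # a PoD of 6.0 in -log(M) means the effect threshold sits at 1 µM;
        # for unit hill the BMC25 sits log10(3) below the EC50 in -log(M)
        curve = Curve4PL(top=100.0, bottom=0.0, log_ec50=6.0 - math.log10(3), hill=1.0)
        pod = derive_pod(curve, PoDPolicy(bmr_percent=25.0))
        assert 10 ** -pod.pod_neglog_molar == pytest.approx(1e-6, rel=1e-9)

    def test_censored_pod_reads_no_effect(self):
        pod = derive_pod(flat_curve(), PoDPolicy(), compound_id="x", endpoint_id="v")
        assert pod.censored
        assert pod.label == "no effect observed"

    def test_policy_recorded_in_result(self):
        curve = Curve4PL(top=100.0, bottom=0.0, log_ec50=6.0, hill=1.0)
        pod = derive_pod(curve, PoDPolicy(bmr_percent=10.0, mode="functional_agonist"))
        assert pod.bmr_percent == 10.0
        assert pod.mode == "functional_agonist"


def _pod(value, censored=False, bound=None):
    return PoDResult(endpoint_id="e", compound_id="c", mode="viability",
                     pod_neglog_molar=value, censored=censored,
                     bmr_percent=25.0, censor_bound=bound)


class TestCytotoxAnchor:
    def test_taxol_like_profile_is_specific(self):
        # functional antagonism at 7.4, cytotoxicity at 5.6: ~63-fold apart
        res = cytotox_anchor(_pod(7.4), _pod(5.6))
        assert res.specificity_ratio == pytest.approx(10 ** 1.8, rel=1e-9)
        assert res.cls == "specific"

    def test_equal_pods_are_confounded(self):
        res = cytotox_anchor(_pod(6.0), _pod(6.0))
        assert res.specificity_ratio == pytest.approx(1.0)
        assert res.cls == "cytotoxicity_confounded"

    def test_borderline_band(self):
        assert cytotox_anchor(_pod(6.7), _pod(6.0)).cls == "borderline"

    def test_censored_functional_is_undetermined(self):
        res = cytotox_anchor(_pod(None, censored=True, bound=4.0), _pod(6.0))
        assert res.cls == "undetermined"
        assert res.specificity_ratio is None

    def test_censored_viability_gives_lower_bound(self):
        res = cytotox_anchor(_pod(7.0), _pod(None, censored=True, bound=4.0))
        assert res.cls == "specific"
        assert res.ratio_is_lower_bound
        assert res.specificity_ratio == pytest.approx(1000.0)


class TestReferenceEC50:
    def test_ec50_as_co_treatment_concentration(self):
        curve = Curve4PL(top=100.0, bottom=0.0, log_ec50=7.0, hill=1.0)
        assert reference_ec50(curve).nanomolar == pytest.approx(100.0)

    def test_identity_in_neglog(self):
        curve = Curve4PL(top=100.0, bottom=0.0, log_ec50=6.0, hill=1.0)
        assert reference_ec50(curve).neglog_molar == 6.0

    def test_flat_curve_has_no_ec50(self):
        with pytest.raises(NoEC50Error):
            reference_ec50(flat_curve())


class TestPodMatrix:
    def test_matrix_with_censored_cell(self):
        pods = [
            _mk_pod("a", "e1", 6.0), _mk_pod("a", "e2", 5.0),
            _mk_pod("b", "e1", 7.0), _mk_pod("b", "e2", None, censored=True),
        ]
        m = assemble_pod_matrix(pods)
        assert m.shape == (2, 2)
        assert m.loc["b", "e2"] == NO_EFFECT
        assert m.loc["a", "e1"] == 6.0

    def test_duplicate_entry_conflicts(self):
        with pytest.raises(ConflictError):
            assemble_pod_matrix([_mk_pod("a", "e", 6.0), _mk_pod("a", "e", 7.0)])

    def test_empty_input_gives_empty_matrix(self):
        assert assemble_pod_matrix([]).empty

    def test_pending_visual_check_is_refused(self):
        curve = Curve4PL(top=100.0, bottom=0.0, log_ec50=6.0, hill=1.0)
        assert curve.visual_check_flag == "pending"
        pod = derive_pod(curve, PoDPolicy(), compound_id="a", endpoint_id="e")
        with pytest.raises(BlockedStateError):
            assemble_pod_matrix([pod])
        curve.visual_check_flag = "passed"
        assert assemble_pod_matrix([pod]).shape == (1, 1)


def _mk_pod(comp, ep, value, censored=False):
    return PoDResult(endpoint_id=ep, compound_id=comp, mode="viability",
                     pod_neglog_molar=value, censored=censored, bmr_percent=25.0)
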