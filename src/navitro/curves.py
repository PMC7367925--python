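"""Concentration-response analysis: normalization, 4PL fits, BMC/PoD, anchoring.

The curve family is the four-parameter log-logistic (4PL) model, written in
-log10(M) units throughout.  For a declining endpoint (viability):

    resp(c) = bottom + (top - bottom) / (1 + 10^(hill * (log_ec50 - c)))

where ``c`` is the tested concentration in -log10(M): small ``c`` means high
concentration, so the response runs from ``top`` (low concentration) down to
``bottom``.  For an induced endpoint (reporter activation) the sign of the
exponent flips.  The benchmark concentration (BMC) at a benchmark response
(BMR, % change from the 100% control level) is obtained by closed-form
inversion of the fitted curve; when the fitted asymptotic effect never
reaches the BMR the result is censored ("no effect observed" up to the
highest tested concentration).  Points of departure (PoD) are BMCs under a
recorded policy, and functional PoDs are anchored against the viability PoD
of the same system to separate specific from cytotoxicity-confounded hits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .chem import ConcentrationValue
from .errors import (BlockedStateError, ConflictError, DegenerateInputError,
                     InsufficientDataError, InvalidValueError, NoEC50Error)
from .platedata import PlateDataset

CONTROL_LEVEL = 100.0  # % of solvent control


def normalize_to_controls(dataset: PlateDataset, endpoint_id: str) -> list[dict]:
    """Express raw values as % of the plate's solvent-control mean.

    Blank wells (when present and unflagged) are averaged per plate and
    subtracted from every raw value first.  Solvent controls flagged
    ``lab_error`` or ``outlier`` are excluded from the reference mean; all
    rows (including flagged ones) are returned with their flags so that
    downstream steps decide what to exclude.
    """
    rows: list[dict] = []
    for plate in dataset.plates():
        wells = dataset.wells(plate, endpoint_id)
        if not wells:
            continue
        blanks = [m.raw_value for m in wells
                  if m.role == "blank" and not m.flags and m.raw_value is not None]
        blank = float(np.mean(blanks)) if blanks else 0.0
        controls = [m.raw_value for m in wells
                    if m.role == "solvent_control" and m.raw_value is not None
                    and not ({"lab_error", "outlier"} & m.flags)]
        if not controls:
            raise DegenerateInputError(
                f"plate {plate!r} has no usable solvent controls for {endpoint_id!r}")
        ref = float(np.mean(controls)) - blank
        if ref == 0:
            raise DegenerateInputError(
                f"plate {plate!r}: blank-corrected control mean is zero")
        for m in wells:
            if m.role == "blank" or m.raw_value is None:
                continue
            rows.append({
                "plate_id": plate, "well": m.well, "role": m.role,
                "compound_id": m.compound_id,
                "conc_neglog_molar": m.conc_neglog_molar,
                "replicate": m.replicate, "flags": m.flags,
                "response_percent": 100.0 * (m.raw_value - blank) / ref,
            })
    return rows


@dataclass
class FitDiagnostics:
    residual_sd: float = float("nan")
    n_points: int = 0
    convergence_note: str = ""
    conc_min_neglog: float | None = None  # highest tested concentration
    conc_max_neglog: float | None = None  # lowest tested concentration


@dataclass
class Curve4PL:
    """A fitted (or ground-truth) 4PL curve in -log10(M) units."""

    top: float
    bottom: float
    log_ec50: float
    hill: float
    direction: str = "decline"  # or "induce"
    fit_ok: bool = True
    visual_check_flag: str = "pending"  # pending | passed | failed
    diagnostics: FitDiagnostics = field(default_factory=FitDiagnostics)

    def __post_init__(self):
        if self.direction not in ("decline", "induce"):
            raise InvalidValueError(f"direction must be decline|induce, got {self.direction!r}")
        if self.fit_ok and not self.hill > 0:
            raise InvalidValueError("hill slope must be > 0")

    def predict(self, conc_neglog) -> np.ndarray:
        c = np.asarray(conc_neglog, dtype=float)
        sign = 1.0 if self.direction == "decline" else -1.0
        return self.bottom + (self.top - self.bottom) / (
            1.0 + 10.0 ** (self.hill * sign * (self.log_ec50 - c)))


def _model(direction: str):
    sign = 1.0 if direction == "decline" else -1.0

    def f(c, top, bottom, log_ec50, hill):
        return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * sign * (log_ec50 - c)))

    return f


DEFAULT_BOUNDS = {
    "decline": {"bottom": (-10.0, 50.0), "top": (50.0, 120.0), "hill": (1e-3, 10.0)},
    "induce": {"bottom": (50.0, 120.0), "top": (100.0, 10000.0), "hill": (1e-3, 10.0)},
}


def fit_4pl(concs_neglog, responses, direction: str = "decline",
            bounds: dict | None = None, min_effect_size: float = 10.0,
            log_ec50_margin: float = 1.0) -> Curve4PL:
    """Least-squares 4PL fit with bound constraints.

    ``log_ec50`` is constrained to the tested range +/- ``log_ec50_margin``
    log units, so a derived PoD can never extrapolate far beyond the series.
    ``fit_ok`` is False when the optimizer fails or the fitted effect size
    |top - bottom| is below ``min_effect_size`` (% of control).
    """
    c = np.asarray(concs_neglog, dtype=float)
    r = np.asarray(responses, dtype=float)
    if c.shape != r.shape:
        raise InvalidValueError("concs and responses must have the same length")
    if len(np.unique(c)) < 4:
        raise InsufficientDataError(
            f"need >= 4 distinct concentrations, got {len(np.unique(c))}")
    b = {**DEFAULT_BOUNDS[direction], **(bounds or {})}
    le_lo, le_hi = c.min() - log_ec50_margin, c.max() + log_ec50_margin
    lower = [b["top"][0], b["bottom"][0], le_lo, b["hill"][0]]
    upper = [b["top"][1], b["bottom"][1], le_hi, b["hill"][1]]

    # data-driven start: plateaus from the series ends, EC50 near mid-response
    order = np.argsort(c)
    lo_conc_resp = r[order][-3:].mean()   # highest neglog = lowest concentration
    hi_conc_resp = r[order][:3].mean()
    if direction == "decline":
        top0, bottom0 = lo_conc_resp, hi_conc_resp
    else:
        top0, bottom0 = hi_conc_resp, lo_conc_resp
    mid = (top0 + bottom0) / 2.0
    le0 = float(c[np.argmin(np.abs(r - mid))])
    p0 = [float(np.clip(top0, *b["top"])), float(np.clip(bottom0, *b["bottom"])),
          float(np.clip(le0, le_lo, le_hi)), 1.0]

    diag = FitDiagnostics(n_points=int(c.size),
                          conc_min_neglog=float(c.min()), conc_max_neglog=float(c.max()))
    try:
        popt, _ = curve_fit(_model(direction), c, r, p0=p0,
                            bounds=(lower, upper), maxfev=20000)
    except (RuntimeError, ValueError) as exc:
        diag.convergence_note = f"no convergence: {exc}"
        return Curve4PL(top=float("nan"), bottom=float("nan"), log_ec50=float("nan"),
                        hill=1.0, direction=direction, fit_ok=False, diagnostics=diag)
    top, bottom, log_ec50, hill = (float(v) for v in popt)
    resid = r - _model(direction)(c, *popt)
    diag.residual_sd = float(np.std(resid, ddof=min(4, c.size - 1)))
    # effect realised inside the tested window, not the asymptotic span —
    # guards against flat data "explained" by an EC50 beyond the series
    pred = _model(direction)(np.unique(c), *popt)
    realised_effect = float(pred.max() - pred.min())
    if min(abs(top - bottom), realised_effect) < min_effect_size:
        diag.convergence_note = "no effect (response range below minimum effect size)"
        return Curve4PL(top=top, bottom=bottom, log_ec50=log_ec50, hill=hill,
                        direction=direction, fit_ok=False, diagnostics=diag)
    return Curve4PL(top=top, bottom=bottom, log_ec50=log_ec50, hill=hill,
                    direction=direction, fit_ok=True, diagnostics=diag)


@dataclass
class BMCResult:
    bmr_percent: float
    bmc_neglog_molar: float | None
    censored: bool
    censor_bound: float | None = None  # highest tested conc in -log(M), when censored


def derive_bmc(curve: Curve4PL, bmr_percent: float) -> BMCResult:
    """Closed-form inversion of the 4PL at the benchmark response.

    Target response is ``100 - bmr`` for declining endpoints and ``100 + bmr``
    for induced ones (both in % of control).  When the fitted curve never
    reaches the target, the BMC is censored at the highest tested
    concentration.
    """
    if not math.isfinite(bmr_percent) or bmr_percent <= 0:
        raise InvalidValueError(f"bmr must be > 0, got {bmr_percent!r}")
    if curve.direction == "decline":
        if bmr_percent >= CONTROL_LEVEL:
            raise InvalidValueError("bmr exceeds the dynamic range of a decline endpoint")
        target = CONTROL_LEVEL - bmr_percent
    else:
        target = CONTROL_LEVEL + bmr_percent
    if not curve.fit_ok:
        return BMCResult(bmr_percent, None, True, curve.diagnostics.conc_min_neglog)
    lo, hi = min(curve.bottom, curve.top), max(curve.bottom, curve.top)
    if not (lo < target < hi):
        return BMCResult(bmr_percent, None, True, curve.diagnostics.conc_min_neglog)
    ratio = (curve.top - target) / (target - curve.bottom)
    sign = 1.0 if curve.direction == "decline" else -1.0
    bmc = curve.log_ec50 - sign * math.log10(ratio) / curve.hill
    # benchmark response only reached beyond the highest tested concentration
    # => no effect observed within the series
    bound = curve.diagnostics.conc_min_neglog
    if bound is not None and bmc < bound:
        return BMCResult(bmr_percent, None, True, bound)
    return BMCResult(bmr_percent, float(bmc), False)


@dataclass
class PoDPolicy:
    """How a PoD is derived; recorded in every output for provenance."""

    bmr_percent: float = 25.0
    mode: str = "viability"  # viability | functional_agonist | functional_antagonist


@dataclass
class PoDResult:
    endpoint_id: str
    compound_id: str
    mode: str
    pod_neglog_molar: float | None  # None => "no effect observed"
    censored: bool
    bmr_percent: float
    censor_bound: float | None = None
    source_curve: Curve4PL | None = None

    @property
    def label(self) -> str:
        return "no effect observed" if self.censored else f"{self.pod_neglog_molar:.1f}"


def derive_pod(curve: Curve4PL, policy: PoDPolicy,
               compound_id: str = "", endpoint_id: str = "") -> PoDResult:
    """PoD = BMC at the policy's BMR; censoring propagates from the BMC."""
    bmc = derive_bmc(curve, policy.bmr_percent)
    return PoDResult(endpoint_id=endpoint_id, compound_id=compound_id,
                     mode=policy.mode, pod_neglog_molar=bmc.bmc_neglog_molar,
                     censored=bmc.censored, bmr_percent=policy.bmr_percent,
                     censor_bound=bmc.censor_bound, source_curve=curve)


@dataclass
class AnchorResult:
    specificity_ratio: float | None  # fold difference, functional vs viability
    ratio_is_lower_bound: bool
    cls: str  # specific | borderline | cytotoxicity_confounded | undetermined


def cytotox_anchor(functional_pod: PoDResult, viability_pod: PoDResult,
                   specific_fold: float = 10.0,
                   borderline_fold: float = 3.0) -> AnchorResult:
    """Classify a functional hit against the viability PoD of the same system.

    ratio = 10^(functional_pod - viability_pod): how many-fold below the
    cytotoxic concentration the functional effect appears.  >= 10-fold counts
    as specific, [3, 10) borderline, < 3 cytotoxicity-confounded.  A censored
    functional PoD is undetermined; a censored viability PoD alone yields a
    "specific" call with the ratio as a lower bound.
    """
    if functional_pod.censored:
        return AnchorResult(None, False, "undetermined")
    if viability_pod.censored:
        bound = viability_pod.censor_bound
        ratio = (10.0 ** (functional_pod.pod_neglog_molar - bound)
                 if bound is not None else None)
        return AnchorResult(ratio, True, "specific")
    ratio = 10.0 ** (functional_pod.pod_neglog_molar - viability_pod.pod_neglog_molar)
    if ratio >= specific_fold:
        cls = "specific"
    elif ratio >= borderline_fold:
        cls = "borderline"
    else:
        cls = "cytotoxicity_confounded"
    return AnchorResult(ratio, False, cls)


def reference_ec50(curve: Curve4PL) -> ConcentrationValue:
    """The fitted EC50 as a concentration, e.g. for antagonist-mode co-treatment."""
    if not curve.fit_ok or not math.isfinite(curve.log_ec50):
        raise NoEC50Error("curve has no usable EC50 (flat or failed fit)")
    return ConcentrationValue(curve.log_ec50)


NO_EFFECT = "no effect"


def assemble_pod_matrix(pod_results: list[PoDResult],
                        require_visual_check: bool = True) -> pd.DataFrame:
    """Compound x endpoint matrix of PoDs in -log10(M).

    Censored cells carry the ``"no effect"`` token.  Rows and columns are
    sorted alphabetically.  Curves still awaiting their visual check are
    refused (summary exports require the check to have happened); duplicate
    (compound, endpoint) pairs raise a conflict.
    """
    cells: dict[tuple[str, str], object] = {}
    for pod in pod_results:
        if (require_visual_check and pod.source_curve is not None
                and pod.source_curve.visual_check_flag == "pending"):
            raise BlockedStateError(
                f"curve for ({pod.compound_id}, {pod.endpoint_id}) awaits its visual check")
        key = (pod.compound_id, pod.endpoint_id)
        if key in cells:
            raise ConflictError(f"duplicate PoD for {key}")
        cells[key] = NO_EFFECT if pod.censored else pod.pod_neglog_molar
    if not cells:
        return pd.DataFrame()
    compounds = sorted({k[0] for k in cells})
    endpoints = sorted({k[1] for k in cells})
    data = [[cells.get((comp, ep), NO_EFFECT) for ep in endpoints] for comp in compounds]
    return pd.DataFrame(data, index=compounds, columns=endpoints)
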