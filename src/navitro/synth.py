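"""Deterministic synthetic plate datasets with known ground truth.

Every other module is testable without any external data: the generator lays
out plates the way the reporter-battery screens were run — a 13-point
half-log dilution series from 100 µM to 0.1 nM, triplicate wells, solvent
controls on every plate — draws raw signals from known 4PL curves under
multiplicative lognormal noise, and optionally injects flagged outliers.

Determinism: the random stream for plate ``i`` is seeded from
``(master_seed, i)``, so regenerating with more plates never reshuffles the
existing ones, and the same spec + seed yields byte-identical files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .curves import Curve4PL, PoDPolicy, derive_pod
from .errors import ConflictError, InvalidValueError
from .platedata import MetadataBlock, PlateDataset, WellMeasurement

BASE_SIGNAL = 1000.0  # instrument units of an untreated well

#: Default noise of solvent controls: multiplicative lognormal with CV 10%,
#: in line with baseline replicate variation typically staying below ~15%.
DEFAULT_NOISE_CV = 0.10


@dataclass
class SyntheticSpec:
    seed: int
    true_curves: dict[tuple[str, str], Curve4PL]  # (compound_id, endpoint_id) -> truth
    n_plates: int = 1
    n_replicates: int = 3
    series: tuple[float, float, float] = (4.0, 10.0, 0.5)  # start, end, step in -log(M)
    noise_cv: float = DEFAULT_NOISE_CV
    outlier_rate: float = 0.0
    negative_controls: list[str] = field(default_factory=list)
    n_solvent_controls: int = 6
    test_method_id: str = "SYN1"
    lab_id: str = "synthlab"

    def __post_init__(self):
        if self.noise_cv < 0:
            raise InvalidValueError("noise CV must be >= 0")
        if not (0.0 <= self.outlier_rate <= 1.0):
            raise InvalidValueError("outlier_rate must be in [0, 1]")
        if self.n_plates < 1 or self.n_replicates < 1:
            raise InvalidValueError("n_plates and n_replicates must be >= 1")

    def series_neglogs(self) -> list[float]:
        start, end, step = self.series
        n = int(math.floor((end - start) / step + 1e-9)) + 1
        return [start + i * step for i in range(n)]


def _well_names():
    for row in "ABCDEFGHIJKLMNOP":
        for col in range(1, 25):
            yield f"{row}{col}"


def _lognormal_factor(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Unit-mean multiplicative noise with the requested CV."""
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return rng.lognormal(mean=-sigma * sigma / 2.0, sigma=sigma, size=size)


def generate_plate(spec: SyntheticSpec) -> PlateDataset:
    """Generate ``spec.n_plates`` plates in one dataset.

    Raw values are ``BASE_SIGNAL x true_response(c)/100 x noise``; solvent
    controls sit at the base signal.  A declared fraction of wells receives a
    3x deviation and the ``outlier`` flag.  The metadata block declares the
    dilution series, so the output passes format validation by construction.
    """
    start, end, step = spec.series
    metadata = MetadataBlock(
        test_method_id=spec.test_method_id, test_method_version="1.0",
        lab_id=spec.lab_id, solvent="DMSO", solvent_final_percent=0.1,
        exposure_h=24.0, method_description_ref=f"tmd:{spec.test_method_id}",
        compound_batch="synthetic-batch-1", seed_or_run_id=f"seed-{spec.seed}",
        series_start_neglog=start, series_end_neglog=end, series_step_log=step,
    )
    endpoints = sorted({ep for _, ep in spec.true_curves})
    measurements: list[WellMeasurement] = []
    for plate_idx in range(spec.n_plates):
        rng = np.random.default_rng([spec.seed, plate_idx])
        plate_id = f"P{plate_idx + 1:02d}"
        wells = _well_names()
        for endpoint in endpoints:
            # solvent controls first
            noise = _lognormal_factor(rng, spec.noise_cv, spec.n_solvent_controls)
            for j in range(spec.n_solvent_controls):
                measurements.append(WellMeasurement(
                    plate_id=plate_id, well=next(wells), role="solvent_control",
                    endpoint_id=endpoint, raw_value=float(BASE_SIGNAL * noise[j]),
                    replicate=j + 1,
                ))
            for (comp, ep), truth in sorted(spec.true_curves.items()):
                if ep != endpoint:
                    continue
                role = ("negative_control_compound" if comp in spec.negative_controls
                        else "treatment")
                for conc in spec.series_neglogs():
                    resp = float(truth.predict(conc))
                    noise = _lognormal_factor(rng, spec.noise_cv, spec.n_replicates)
                    is_outlier = rng.random(spec.n_replicates) < spec.outlier_rate
                    for rep in range(spec.n_replicates):
                        raw = BASE_SIGNAL * resp / 100.0 * noise[rep]
                        flags = frozenset()
                        if is_outlier[rep]:
                            raw *= 3.0
                            flags = frozenset({"outlier"})
                        measurements.append(WellMeasurement(
                            plate_id=plate_id, well=next(wells), role=role,
                            compound_id=comp, conc_neglog_molar=conc,
                            endpoint_id=endpoint, raw_value=float(raw),
                            replicate=rep + 1, flags=flags,
                        ))
    return PlateDataset(measurements, metadata)


def flat_curve(level: float = 100.0) -> Curve4PL:
    """Ground truth for a compound with no effect (negative control)."""
    return Curve4PL(top=level, bottom=level, log_ec50=7.0, hill=1.0,
                    fit_ok=False, visual_check_flag="passed")


def generate_battery(specs: list[SyntheticSpec],
                     bmr_percent: float = 25.0) -> tuple[list[PlateDataset], pd.DataFrame]:
    """Generate one dataset per spec plus a ground-truth table.

    The truth table holds, per (method, compound, endpoint), the true curve
    parameters and the true PoD at the given BMR (censored for flat curves),
    for recovery experiments against the fitting pipeline.
    """
    ids = [s.test_method_id for s in specs]
    if len(set(ids)) != len(ids):
        raise ConflictError(f"duplicate test_method_ids: {ids}")
    datasets = []
    rows = []
    for spec in specs:
        datasets.append(generate_plate(spec))
        for (comp, ep), truth in sorted(spec.true_curves.items()):
            if truth.fit_ok and abs(truth.top - truth.bottom) > 0:
                pod = derive_pod(truth, PoDPolicy(bmr_percent=bmr_percent),
                                 compound_id=comp, endpoint_id=ep)
                pod_val, censored = pod.pod_neglog_molar, pod.censored
            else:
                pod_val, censored = None, True
            rows.append({
                "test_method_id": spec.test_method_id, "compound_id": comp,
                "endpoint_id": ep, "true_top": truth.top, "true_bottom": truth.bottom,
                "true_log_ec50": truth.log_ec50, "true_hill": truth.hill,
                "direction": truth.direction, "bmr_percent": bmr_percent,
                "true_pod_neglog": pod_val, "censored": censored,
            })
    return datasets, pd.DataFrame(rows)
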