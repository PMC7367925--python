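"""Baseline-variance QC of solvent controls and negative-control spread.

Two complementary noise measures for a plate-based test method:

* per-plate relative standard deviation (RSD, %) of the solvent-control
  technical replicates, ``RSD = SD * 100 / mean`` with replicate values also
  reported normalized to their plate average (``x_norm = x / mean``);
* the pooled spread of non-cytotoxic negative-control compounds at their two
  lowest tested concentrations, expressed in % of solvent control — in a
  well-behaved assay most of these values fall within 80-120%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateInputError, NotFoundError
from .platedata import PlateDataset


@dataclass
class BaselineStats:
    plate_id: str
    endpoint_id: str
    n_replicates: int
    mean_raw: float
    sd_raw: float
    rsd_percent: float
    normalized_values: list[float]


@dataclass
class BaselineProfile:
    per_plate: list[BaselineStats]
    average_rsd_percent: float  # unweighted mean of per-plate RSDs

    def to_json_obj(self) -> dict:
        return {
            "average_rsd_percent": self.average_rsd_percent,
            "plates": [{
                "plate_id": s.plate_id, "endpoint_id": s.endpoint_id,
                "n_replicates": s.n_replicates, "mean_raw": s.mean_raw,
                "sd_raw": s.sd_raw, "rsd_percent": s.rsd_percent,
                "normalized_values": s.normalized_values,
            } for s in self.per_plate],
        }


def normalize_replicates(values: list[float]) -> list[float]:
    """Normalize technical replicates to their average: x_norm = x / mean.

    The normalized values average to exactly 1 by construction.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise DegenerateInputError(f"need >= 2 replicates, got {arr.size}")
    mu = arr.mean()
    if mu == 0 or not math.isfinite(mu):
        raise DegenerateInputError("replicate mean is zero or non-finite")
    return (arr / mu).tolist()


def rsd(values: list[float], ddof: int = 1) -> float:
    """Relative standard deviation in percent: SD * 100 / mean.

    Uses the sample SD (n-1 denominator) by default — replicates are a small
    sample, where the choice matters; set ``ddof=0`` for the population SD.
    Scale-invariant: rsd(c*x) == rsd(x) for c > 0.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise DegenerateInputError(f"need >= 2 replicates, got {arr.size}")
    mu = arr.mean()
    if mu <= 0 or not math.isfinite(mu):
        raise DegenerateInputError("replicate mean must be > 0 for an RSD")
    return float(arr.std(ddof=ddof) * 100.0 / mu)


def plate_baseline_profile(dataset: PlateDataset, endpoint_id: str,
                           ddof: int = 1) -> BaselineProfile:
    """Per-plate solvent-control RSD plus the cross-plate unweighted average.

    Only solvent-control wells enter; rows flagged ``lab_error`` are excluded
    from the mean and SD (the flag stays in the file, exclusion happens only
    here at computation time).
    """
    if endpoint_id not in dataset.endpoints():
        raise NotFoundError(f"endpoint {endpoint_id!r} not in dataset")
    stats: list[BaselineStats] = []
    for plate in dataset.plates():
        wells = [m for m in dataset.wells(plate, endpoint_id, "solvent_control")
                 if "lab_error" not in m.flags and m.raw_value is not None]
        if len(wells) < 2:
            continue
        raws = [m.raw_value for m in wells]
        stats.append(BaselineStats(
            plate_id=plate, endpoint_id=endpoint_id, n_replicates=len(raws),
            mean_raw=float(np.mean(raws)), sd_raw=float(np.std(raws, ddof=ddof)),
            rsd_percent=rsd(raws, ddof=ddof),
            normalized_values=normalize_replicates(raws),
        ))
    if not stats:
        raise DegenerateInputError(
            f"no plate has >= 2 usable solvent controls for {endpoint_id!r}")
    return BaselineProfile(stats, float(np.mean([s.rsd_percent for s in stats])))


@dataclass
class SpreadSummary:
    endpoint_id: str
    values_percent: list[float]  # pooled, % of solvent control
    mean_percent: float
    sd_percent: float
    fraction_within_80_120: float
    warnings: list[str] = field(default_factory=list)


def negative_control_spread(dataset: PlateDataset, neg_compounds: list[str],
                            max_conc_um: dict[str, float]) -> dict[str, SpreadSummary]:
    """Pool normalized responses of negative-control compounds per endpoint.

    For each compound, the two lowest tested concentrations are taken and
    additionally required to lie below the per-compound cap (in µM); both
    conditions are applied conjunctively.  Responses are normalized per plate
    to the solvent controls (% of control).  Compounds without qualifying
    concentrations are skipped with a warning.
    """
    from .curves import normalize_to_controls  # local import to avoid a cycle

    out: dict[str, SpreadSummary] = {}
    for endpoint in dataset.endpoints():
        norm = normalize_to_controls(dataset, endpoint)
        pooled: list[float] = []
        warnings: list[str] = []
        for comp in neg_compounds:
            rows = [r for r in norm
                    if r["compound_id"] == comp and r["conc_neglog_molar"] is not None]
            if not rows:
                warnings.append(f"{comp}: not tested for endpoint {endpoint!r}")
                continue
            # two lowest concentrations = two highest -log(M) values
            neglogs = sorted({r["conc_neglog_molar"] for r in rows}, reverse=True)[:2]
            cap = max_conc_um.get(comp, math.inf)
            usable = [c for c in neglogs if 10 ** (6 - c) < cap]
            if not usable:
                warnings.append(
                    f"{comp}: lowest tested concentrations exceed the {cap} µM cap")
                continue
            pooled.extend(r["response_percent"] for r in rows
                          if r["conc_neglog_molar"] in usable)
        if not pooled:
            continue
        arr = np.asarray(pooled)
        out[endpoint] = SpreadSummary(
            endpoint_id=endpoint, values_percent=pooled,
            mean_percent=float(arr.mean()), sd_percent=float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
            fraction_within_80_120=float(np.mean((arr >= 80) & (arr <= 120))),
            warnings=warnings,
        )
    return out
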