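"""Free (unbound) compound concentration in cell culture media.

A three-compartment mass balance: a test compound distributes between the
aqueous medium, serum protein (all protein treated as albumin, MW 66.5 kDa)
and serum lipid (triacylglycerol).  With binding linear in the tested range,

    f_unbound = 1 / (1 + K_protein * C_protein + K_lipid * C_lipid)

with phase concentrations in kg/L and affinities in L/kg.  The free
concentration is simply nominal x f_unbound.  Two routes to the binding
constants are offered:

* ``ppb_scaled`` — infer the albumin affinity from the measured plasma
  protein binding, (1 - fu_plasma)/fu_plasma divided by the plasma albumin
  phase concentration (600 µM reference);
* ``kow_regression`` — predict from lipophilicity alone,
  log10 K_protein = 0.71 * logK_ow + 0.42 (serum-albumin sorption
  regression) and K_lipid = K_ow for storage lipid.

Binding to plastic and to cells is deliberately not modelled; for extremely
hydrophobic compounds plastic adsorption can claim on the order of a third
of the nominal amount, and a warning says so.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .chem import Compound, ConcentrationValue, mass_conc_to_molar, volatility_flag
from .errors import InvalidValueError, NavitroError

#: Reference composition of undiluted fetal calf serum.
FCS_ALBUMIN_UM_PER_PERCENT = 3.46     # 100% FCS = 346 µM albumin (23 mg/mL at 66.5 kDa)
FCS_LIPID_MG_L_PER_PERCENT = 60.0     # 100% FCS ~ 6000 mg/L triacylglycerol
ALBUMIN_MW_KDA = 66.5
PLASMA_ALBUMIN_UM = 600.0             # human plasma reference for PPB scaling

#: logK_ow above which plastic adsorption becomes a material loss channel.
EXTREME_HYDROPHOBICITY_LOGKOW = 5.0


class PropertyMissingError(NavitroError, ValueError):
    """A binding-constant mode needs a compound property that is absent."""


@dataclass
class MediumComposition:
    medium_id: str
    fcs_percent: float = 0.0
    albumin_conc: float = 0.0   # µM, total including any FCS contribution
    lipid_conc: float = 0.0     # mg/L TAG
    notes: str = ""

    def __post_init__(self):
        if self.albumin_conc < 0 or self.lipid_conc < 0:
            raise InvalidValueError("albumin and lipid concentrations must be >= 0")

    @property
    def serum_free(self) -> bool:
        return self.albumin_conc == 0 and self.lipid_conc == 0

    @property
    def protein_kg_per_l(self) -> float:
        # µM -> mol/L -> g/L (x MW in g/mol) -> kg/L
        return self.albumin_conc * 1e-6 * ALBUMIN_MW_KDA * 1000.0 / 1000.0

    @property
    def lipid_kg_per_l(self) -> float:
        return self.lipid_conc * 1e-6


def medium_from_fcs(medium_id: str, fcs_percent: float,
                    extra_albumin_um: float = 0.0,
                    extra_lipid_mg_l: float = 0.0,
                    notes: str = "") -> MediumComposition:
    """Build a medium from its FCS percentage by linear scaling of the 100%
    reference (346 µM albumin, 6000 mg/L lipid) plus explicit supplements.

    Charcoal-stripped serum keeps the protein but loses the lipid; pass the
    FCS percent and a negative-free override via ``extra_*`` fields or build
    the composition directly.
    """
    if not (0.0 <= fcs_percent <= 100.0):
        raise InvalidValueError(f"fcs_percent must be in [0, 100], got {fcs_percent!r}")
    return MediumComposition(
        medium_id=medium_id,
        fcs_percent=fcs_percent,
        albumin_conc=fcs_percent * FCS_ALBUMIN_UM_PER_PERCENT + extra_albumin_um,
        lipid_conc=fcs_percent * FCS_LIPID_MG_L_PER_PERCENT + extra_lipid_mg_l,
        notes=notes,
    )


def stripped_serum_medium(medium_id: str, fcs_percent: float,
                          notes: str = "charcoal-stripped serum") -> MediumComposition:
    """Charcoal/dextran-stripped serum: same protein, no additional lipid."""
    if not (0.0 <= fcs_percent <= 100.0):
        raise InvalidValueError(f"fcs_percent must be in [0, 100], got {fcs_percent!r}")
    return MediumComposition(
        medium_id=medium_id, fcs_percent=fcs_percent,
        albumin_conc=fcs_percent * FCS_ALBUMIN_UM_PER_PERCENT,
        lipid_conc=0.0, notes=notes,
    )


def example_media_panel() -> list[MediumComposition]:
    """A representative panel of culture media used across a test battery:
    serum-free, 5% and 10% FCS, and 5% charcoal-stripped serum."""
    return [
        MediumComposition("serum_free", 0.0, 0.0, 0.0, notes="defined, serum-free"),
        medium_from_fcs("fcs_5", 5.0),
        medium_from_fcs("fcs_10", 10.0),
        stripped_serum_medium("dcc_5", 5.0),
    ]


@dataclass
class BindingConstants:
    k_protein: float  # L/kg
    k_lipid: float    # L/kg
    method: str       # ppb_scaled | kow_regression
    warnings: list[str] = field(default_factory=list)


def binding_constants(compound: Compound, mode: str = "auto") -> BindingConstants:
    """Albumin and lipid affinities (L/kg) for a compound.

    ``mode="auto"`` uses ``ppb_scaled`` when a plasma-protein-binding value is
    on record, else ``kow_regression``.
    """
    if mode == "auto":
        mode = "ppb_scaled" if compound.ppb_fraction_bound is not None else "kow_regression"
    warnings: list[str] = []
    if mode == "ppb_scaled":
        if compound.ppb_fraction_bound is None:
            raise PropertyMissingError(
                f"{compound.compound_id}: ppb_scaled needs ppb_fraction_bound "
                "(fall back to kow_regression)")
        fu = 1.0 - compound.ppb_fraction_bound
        c_plasma = PLASMA_ALBUMIN_UM * 1e-6 * ALBUMIN_MW_KDA  # kg/L
        if fu == 0.0:
            raise InvalidValueError(
                f"{compound.compound_id}: PPB of exactly 1 gives an infinite affinity")
        k_protein = (compound.ppb_fraction_bound / fu) / c_plasma
        if compound.log_kow is not None:
            k_lipid = 10.0 ** compound.log_kow
        else:
            k_lipid = 0.0
            warnings.append("no logK_ow on record; lipid binding assumed zero")
        return BindingConstants(k_protein, k_lipid, "ppb_scaled", warnings)
    if mode == "kow_regression":
        if compound.log_kow is None:
            raise PropertyMissingError(
                f"{compound.compound_id}: kow_regression needs log_kow "
                "(fall back to ppb_scaled)")
        k_protein = 10.0 ** (0.71 * compound.log_kow + 0.42)
        k_lipid = 10.0 ** compound.log_kow
        return BindingConstants(k_protein, k_lipid, "kow_regression", warnings)
    raise InvalidValueError(f"unknown mode {mode!r}; use auto, ppb_scaled or kow_regression")


@dataclass
class FreeFractionResult:
    f_unbound: float
    bound_to_protein: float
    bound_to_lipid: float
    method: str
    warnings: list[str] = field(default_factory=list)

    def free_conc(self, nominal_molar: float) -> float:
        return nominal_molar * self.f_unbound


def free_fraction(compound: Compound, medium: MediumComposition,
                  mode: str = "auto") -> FreeFractionResult:
    """Predicted unbound fraction of the nominal concentration in a medium.

    The three fractions (aqueous, protein-bound, lipid-bound) sum to 1.
    Serum-free media give f_unbound = 1 exactly.  Warnings flag volatile or
    borderline-volatile compounds (air loss not modelled) and extreme
    hydrophobics (plastic adsorption not modelled, can be ~1/3 of nominal).
    """
    warnings: list[str] = []
    vflag = volatility_flag(compound)
    if vflag in ("volatile", "borderline"):
        warnings.append(f"compound is {vflag} (K_AW = {compound.k_aw}); "
                        "air-water loss is not modelled")
    if compound.log_kow is not None and compound.log_kow >= EXTREME_HYDROPHOBICITY_LOGKOW:
        warnings.append("extremely hydrophobic compound: plastic adsorption "
                        "(not modelled) can bind a substantial share, on the order of 1/3")
    warnings.append("binding to plastic and cells is not modelled (pre-adsorbed "
                    "plasticware assumed)")
    if medium.serum_free:
        return FreeFractionResult(1.0, 0.0, 0.0, "serum_free", warnings)
    k = binding_constants(compound, mode)
    warnings.extend(k.warnings)
    term_p = k.k_protein * medium.protein_kg_per_l
    term_l = k.k_lipid * medium.lipid_kg_per_l
    denom = 1.0 + term_p + term_l
    return FreeFractionResult(
        f_unbound=1.0 / denom,
        bound_to_protein=term_p / denom,
        bound_to_lipid=term_l / denom,
        method=k.method,
        warnings=warnings,
    )


def free_concentration(nominal: ConcentrationValue,
                       result: FreeFractionResult) -> ConcentrationValue:
    """Free concentration = nominal x f_unbound, in -log10(M)."""
    return ConcentrationValue.from_molar(nominal.molar * result.f_unbound)


def percent_difference_free_vs_nominal(result: FreeFractionResult) -> float:
    """100 x (1 - free/nominal): how far the free concentration falls below
    the nominal one.  0 for serum-free media."""
    return 100.0 * (1.0 - result.f_unbound)
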