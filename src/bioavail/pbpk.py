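"""PBPK integration stages: gut absorption/extraction and well-stirred liver.

The gut stage combines dissolution- and permeability-limited absorption with a
multiplicative efflux penalty (MDR-1/BCRP substrates), an active-uptake floor
for quinolones and beta-lactams, and a constant first-pass gut-wall extraction
for CYP3A4 substrates and phenols.  The liver stage is the classical
well-stirred model,

    CL_h = Q * fu_b * CL_int / (Q + fu_b * CL_int),

with biliary clearance added inside the extraction term and the total
extraction ratio clamped at 1.  Oral bioavailability composes the two escapes:
F_pred = F_int * F_liver.  All F-like quantities are fractions in [0, 1];
I/O layers convert to percent.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .chemstruct import Compound, DescriptorRangeConfig, DomainStatus, check_domain
from .qsar import ADMEProfile, TrainedModel, predict_profile


@dataclass(frozen=True)
class PBPKParams:
    """Physiological and integration parameters.

    liver_blood_flow: hepatic blood flow Q in mL/min (adult human, 1500).
    gut_extraction_cyp3a4 / gut_extraction_phenol: constant first-pass gut-wall
        extraction fractions applied to CYP3A4 substrates / phenols.
    efflux_penalty: multiplicative reduction of passive absorption for MDR-1 or
        BCRP substrates.
    active_uptake_floor: minimum permeability-limited absorption granted to
        actively transported classes (quinolones, beta-lactams).
    """

    liver_blood_flow: float = 1500.0
    gut_extraction_cyp3a4: float = 0.3
    gut_extraction_phenol: float = 0.3
    efflux_penalty: float = 0.7
    active_uptake_floor: float = 0.9

    def __post_init__(self):
        if self.liver_blood_flow <= 0:
            raise ValueError("liver_blood_flow must be > 0")
        for name in ("gut_extraction_cyp3a4", "gut_extraction_phenol", "active_uptake_floor"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0,1]")
        if not 0.0 < self.efflux_penalty <= 1.0:
            raise ValueError("efflux_penalty must be in (0,1]")


@dataclass(frozen=True)
class GutResult:
    f_abs: float
    E_gut: float
    F_int: float

    def __post_init__(self):
        if abs(self.F_int - self.f_abs * (1.0 - self.E_gut)) > 1e-12:
            raise ValueError("F_int must equal f_abs * (1 - E_gut)")


@dataclass(frozen=True)
class LiverResult:
    fu_blood: float
    CL_h: float  # mL/min
    E_total: float
    F_liver: float

    def __post_init__(self):
        if abs(self.F_liver - (1.0 - self.E_total)) > 1e-12:
            raise ValueError("F_liver must equal 1 - E_total")


@dataclass(frozen=True)
class FPrediction:
    """Final per-compound result; F fields are None for no-estimate compounds
    (parse failures, metals, quaternary amines)."""

    compound_id: str
    F_int: float | None
    F_liver: float | None
    F_pred: float | None
    domain: DomainStatus
    profile: ADMEProfile | None
    gut: GutResult | None = None
    liver: LiverResult | None = None

    @property
    def estimated(self) -> bool:
        return self.F_pred is not None


def fu_blood(f_u: float, cbl_cpl: float) -> float:
    """Unbound fraction referenced to whole blood: f_u / (C_bl/C_pl)."""
    if f_u <= 0 or f_u > 1:
        raise ValueError(f"f_u={f_u} outside (0,1]")
    if cbl_cpl <= 0:
        raise ValueError(f"cbl_cpl={cbl_cpl} must be > 0")
    return f_u / cbl_cpl


def gut_model(profile: ADMEProfile, params: PBPKParams = PBPKParams()) -> GutResult:
    """Intestinal absorption and gut-wall extraction (F_int = f_abs * (1 - E_gut))."""
    f_abs_eff = profile.f_abs_p
    if profile.mdr1 or profile.bcrp:
        f_abs_eff *= params.efflux_penalty
    if profile.alerts.quinolone or profile.alerts.beta_lactam:
        f_abs_eff = max(f_abs_eff, params.active_uptake_floor)
    f_abs = min(profile.f_diss, f_abs_eff)
    E_gut = 0.0
    if profile.cyp3a4:
        E_gut = params.gut_extraction_cyp3a4
    if profile.alerts.phenol:
        E_gut = max(E_gut, params.gut_extraction_phenol)
    return GutResult(f_abs=f_abs, E_gut=E_gut, F_int=f_abs * (1.0 - E_gut))


def liver_model(profile: ADMEProfile, params: PBPKParams = PBPKParams()) -> LiverResult:
    """Well-stirred hepatic first pass with additive biliary clearance."""
    if profile.CL_int < 0 or profile.CL_bile < 0:
        raise ValueError("clearances must be >= 0")
    q = params.liver_blood_flow
    fu_b = fu_blood(profile.f_u, profile.cbl_cpl)
    cl_h = q * fu_b * profile.CL_int / (q + fu_b * profile.CL_int)
    e_total = min(1.0, (cl_h + profile.CL_bile) / q)
    return LiverResult(fu_blood=fu_b, CL_h=cl_h, E_total=e_total, F_liver=1.0 - e_total)


def predict_F(
    compound: Compound,
    registry: Mapping[str, TrainedModel],
    params: PBPKParams = PBPKParams(),
    ranges: DescriptorRangeConfig | None = None,
    patterns: dict | None = None,
) -> FPrediction:
    """Full pipeline: domain gate -> ADME profile -> gut -> liver -> F_pred.

    Out-of-domain compounds still receive an estimate (flagged), except metals
    and quaternary amines, which are not predictable at all.
    """
    domain = check_domain(compound, ranges=ranges)
    if not domain.predictable:
        return FPrediction(
            compound_id=compound.compound_id,
            F_int=None, F_liver=None, F_pred=None,
            domain=domain, profile=None,
        )
    profile = predict_profile(registry, compound, patterns=patterns)
    gut = gut_model(profile, params)
    liver = liver_model(profile, params)
    return FPrediction(
        compound_id=compound.compound_id,
        F_int=gut.F_int,
        F_liver=liver.F_liver,
        F_pred=gut.F_int * liver.F_liver,
        domain=domain,
        profile=profile,
        gut=gut,
        liver=liver,
    )
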