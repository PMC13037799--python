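"""Protection-quantity evaluation from transport tallies.

Bone-component doses below the high-energy threshold come from the
fluence-spectrum estimator

    ED_a = M_a * sum_bins Phi_a(E) * (mu_en/rho)(E) * E        [MeV]
    D_a  = ED_a * c / M_a                                      [Gy]

(the component mass cancels, as the closed form implies).  At and above the
threshold (default 1 MeV) the total energy deposited in an anatomical bone
region is partitioned across components in proportion to their masses,
which makes the mass-specific dose identical for every component of the
region.  The MeV-to-joule constant defaults to 1.602176634e-13 J/MeV.

Whole-body marrow/endosteum doses are mass-weighted averages over the
packaged 20-region inventories.  Effective dose follows the ICRP 103
scheme: w_R = 1 for photons and electrons, remainder handled as the
arithmetic mean of the configured remainder tissues per sex, and tissue
equivalent doses sex-averaged before weighting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib.resources import files

import numpy as np

from .photon_transport import TallyResult
from .skeleton_materials import BoneInventory, COMPONENTS, mixture_mu_en


@dataclass
class DoseConstants:
    mev_to_joule: float = 1.602176634e-13  # J/MeV
    high_energy_threshold: float = 1.0     # MeV


@dataclass
class OrganDose:
    region_id: int
    dose_pGy_cm2: float
    fsd: float = 0.0

    def __post_init__(self):
        if self.dose_pGy_cm2 < 0:
            raise ValueError("dose must be non-negative")


@dataclass
class BoneDoseContext:
    """Per-bone-region spectra and masses feeding the dose equations."""
    region_spectra: dict       # region name -> fluence per bin (dimensionless)
    bin_edges: np.ndarray      # MeV
    inventory: BoneInventory
    component_materials: dict  # component -> Material
    region_edep: dict = field(default_factory=dict)   # MeV per history
    field_area_cm2: float = 1.0

    def validate(self):
        missing = set(self.inventory.regions) - set(self.region_spectra)
        if missing:
            raise ValueError(f"missing spectra for bone regions: {sorted(missing)}")


def spectrum_dose(fluence, bin_edges, mu_en_curve, constants=None):
    """Midpoint-rule dose (Gy * cm^2 per unit incident fluence... in the
    units of the supplied fluence) of a binned fluence spectrum.

    ``mu_en_curve(E)`` must return m^2/kg.  With fluence normalized per unit
    incident fluence, the result is Gy.m^2 per unit fluence; multiply by
    1e16 for pGy.cm^2.
    """
    constants = constants or DoseConstants()
    mids = 0.5 * (np.asarray(bin_edges[:-1]) + np.asarray(bin_edges[1:]))
    mu = np.asarray([mu_en_curve(e) for e in mids], float)
    return float(np.sum(np.asarray(fluence) * mu * mids)
                 * constants.mev_to_joule)


def bone_component_dose_lowE(ctx: BoneDoseContext, component,
                             constants: DoseConstants | None = None) -> dict:
    """Per-region component dose (Gy.m^2 per unit incident fluence) from the
    track-length fluence spectra (below-threshold estimator)."""
    if component not in ("active_marrow", "endosteum"):
        raise ValueError("component must be active_marrow or endosteum")
    constants = constants or DoseConstants()
    ctx.validate()
    mat = ctx.component_materials[component]
    doses = {}
    for region in ctx.inventory.regions:
        flu = ctx.region_spectra[region]
        doses[region] = spectrum_dose(
            flu, ctx.bin_edges, lambda e: mixture_mu_en(mat, e), constants)
    return doses


def bone_component_dose_highE(region_edep_mev, region_total_mass_kg,
                              constants: DoseConstants | None = None) -> float:
    """Mass-proportional partition dose (Gy): every component of the region
    receives the region's mass-specific dose."""
    constants = constants or DoseConstants()
    if region_total_mass_kg <= 0:
        raise ValueError("region mass must be positive")
    return region_edep_mev * constants.mev_to_joule / region_total_mass_kg


def partition_energy(region_edep_mev, component_masses: dict) -> dict:
    """Split deposited energy across components proportionally to mass."""
    total = sum(component_masses.values())
    if total <= 0:
        raise ValueError("region total mass must be positive")
    return {c: region_edep_mev * m / total for c, m in component_masses.items()}


def whole_body_component_dose(region_doses: dict, inventory: BoneInventory,
                              component: str) -> float:
    """Mass-weighted whole-body average over the 20-region inventory."""
    if component not in COMPONENTS:
        raise KeyError(f"unknown component {component!r}")
    num = 0.0
    den = 0.0
    for region in inventory.regions:
        m = inventory.mass(region, component)
        if m == 0.0:
            continue
        if region not in region_doses:
            raise ValueError(f"missing dose for region {region!r} "
                             f"with nonzero {component} mass")
        num += region_doses[region] * m
        den += m
    if den == 0.0:
        raise ValueError(f"inventory has zero total {component} mass")
    return num / den


def organ_absorbed_dose(tally: TallyResult, region_id, mass_kg,
                        constants: DoseConstants | None = None) -> OrganDose:
    """Absorbed dose per unit incident fluence (pGy.cm^2) for one region."""
    constants = constants or DoseConstants()
    if mass_kg <= 0:
        raise ValueError("region mass must be positive")
    idx = tally.region_index(region_id)
    edep = tally.edep_per_history[idx]           # MeV per history
    gy_per_history = edep * constants.mev_to_joule / mass_kg
    dose = gy_per_history * tally.field_area_cm2 * 1e12
    return OrganDose(int(region_id), dose, float(tally.fsd[idx]))


def equivalent_dose(dose: OrganDose, radiation: str = "photon") -> float:
    """Equivalent dose (pSv.cm^2); w_R = 1 for photons and electrons."""
    if radiation not in ("photon", "electron"):
        raise ValueError(f"unsupported radiation type {radiation!r}")
    return dose.dose_pGy_cm2


@dataclass
class TissueWeighting:
    weights: dict                 # tissue -> w_T (weighted tissues only)
    remainder: dict               # sex -> list of remainder tissue names
    remainder_key: str = "remainder"

    @classmethod
    def icrp103(cls) -> "TissueWeighting":
        text = files("phantomkit.data").joinpath("wt_icrp103.tsv").read_text()
        weights = {}
        remainder = {"male": [], "female": []}
        for line in text.splitlines():
            if not line or line.startswith("#") or line.startswith("tissue"):
                continue
            tissue, wt, role, sex = line.split("\t")
            if role == "weighted":
                weights[tissue] = float(wt)
            else:
                if sex in ("both", "male"):
                    remainder["male"].append(tissue)
                if sex in ("both", "female"):
                    remainder["female"].append(tissue)
        tw = cls(weights, remainder)
        tw.validate()
        return tw

    def validate(self):
        if abs(sum(self.weights.values()) - 1.0) > 1e-6:
            raise ValueError("tissue weighting factors must sum to 1")


#: sex-specific stand-ins for weighted tissues
_TISSUE_ALIASES = {"gonads": {"male": "testes", "female": "ovaries"}}


def _tissue_dose(doses: dict, tissue: str, sex: str, weighting: TissueWeighting):
    if tissue == weighting.remainder_key:
        members = weighting.remainder[sex]
        vals = [doses[m] for m in members if m in doses]
        if not vals:
            raise ValueError(f"no remainder tissues present in {sex} dose map")
        return float(np.mean(vals))
    names = [tissue]
    if tissue in _TISSUE_ALIASES:
        names.insert(0, _TISSUE_ALIASES[tissue][sex])
    for name in names:
        if name in doses:
            return float(doses[name])
    raise ValueError(f"missing weighted tissue {tissue!r} in {sex} dose map")


def effective_dose(male: dict, female: dict,
                   weighting: TissueWeighting | None = None) -> float:
    """Sex-averaged effective dose (same units as the input equivalent
    doses): E = sum_T w_T (H_T_male + H_T_female) / 2."""
    weighting = weighting or TissueWeighting.icrp103()
    total = 0.0
    for tissue, wt in weighting.weights.items():
        hm = _tissue_dose(male, tissue, "male", weighting)
        hf = _tissue_dose(female, tissue, "female", weighting)
        total += wt * 0.5 * (hm + hf)
    return total
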