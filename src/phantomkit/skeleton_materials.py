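"""Skeletal component inventories, bone-mixture homogenization and mixture
mass energy-absorption coefficients.

The packaged inventories ("jpm" male, "jpf" female) list, for each of the 20
anatomical bone regions, the masses of active marrow, inactive marrow, hard
bone and endosteum.  Each anatomical bone region is treated as a homogenized
mixture of its components; the endosteum composition defaults to that of
active marrow (configurable).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib.resources import files

import numpy as np
import pandas as pd

from . import xsdata
from .phantom_io import Material, default_material_library

COMPONENTS = ("active_marrow", "inactive_marrow", "hard_bone", "endosteum")

REGION_NAMES = (
    "Humeri, upper half", "Humeri, lower half", "Ulnae and radii",
    "Wrist and hand bones", "Clavicles", "Cranium", "Femora, upper half",
    "Femora, lower half", "Tibiae, fibiae, patellae", "Ankle and foot bones",
    "Mandible", "Pelvis", "Ribs", "Scapulae", "Cervical vertebrae",
    "Thoracic vertebrae", "Lumbar vertebrae", "Sacrum", "Sternum",
    "Os hyoideum",
)


def _read_fixture(name):
    text = files("phantomkit.data").joinpath(f"{name}.tsv").read_text()
    from io import StringIO
    return pd.read_csv(StringIO(text), sep="\t", comment="#")


@dataclass
class BoneInventory:
    """Per-anatomical-region component masses [kg]."""
    table: pd.DataFrame  # index: region name; columns: COMPONENTS

    @classmethod
    def load(cls, which: str) -> "BoneInventory":
        if which not in ("jpm", "jpf"):
            raise ValueError("inventory name must be 'jpm' or 'jpf'")
        df = _read_fixture(f"{which}_bone").set_index("region")
        inv = cls(df[list(COMPONENTS)].astype(float))
        inv.validate()
        return inv

    def validate(self):
        if tuple(self.table.index) != REGION_NAMES:
            raise ValueError("inventory must list the 20 anatomical bone "
                             "regions in canonical order")
        if (self.table.values < 0).any():
            raise ValueError("component masses must be non-negative")

    @property
    def regions(self):
        return list(self.table.index)

    def mass(self, region, component):
        return float(self.table.loc[region, component])

    def region_total(self, region):
        return float(self.table.loc[region].sum())


def default_component_compositions() -> dict:
    """Packaged component compositions; endosteum mirrors active marrow."""
    lib = default_material_library()
    comps = {
        "hard_bone": lib["hard_bone"],
        "active_marrow": lib["active_marrow"],
        "inactive_marrow": lib["inactive_marrow"],
    }
    am = lib["active_marrow"]
    comps["endosteum"] = Material("endosteum", dict(am.fractions), am.density)
    return comps


@dataclass
class MixtureMaterial:
    fractions: dict          # element -> mass fraction
    density: float           # g/cm^3
    component_fractions: dict  # component name -> mass fraction

    def validate(self):
        if abs(sum(self.fractions.values()) - 1.0) > 1e-6:
            raise ValueError("elemental fractions must sum to 1")
        if abs(sum(self.component_fractions.values()) - 1.0) > 1e-6:
            raise ValueError("component fractions must sum to 1")


def homogenize_region(components) -> MixtureMaterial:
    """Mass-weighted homogenization of (mass_kg, Material) pairs.

    Elemental fraction of e = sum(m_i w_ie) / sum(m_i); density is the
    volume-conserving harmonic mix sum(m_i) / sum(m_i / rho_i).
    """
    comps = list(components)
    if not comps:
        raise ValueError("at least one component required")
    masses = np.array([m for m, _ in comps], float)
    if (masses < 0).any():
        raise ValueError("component masses must be non-negative")
    total = masses.sum()
    if total <= 0:
        raise ValueError("all-zero component masses")
    fractions: dict[str, float] = {}
    inv_rho = 0.0
    for m, mat in comps:
        for el, w in mat.fractions.items():
            fractions[el] = fractions.get(el, 0.0) + m * w
        inv_rho += m / mat.density
    fractions = {el: v / total for el, v in fractions.items()}
    density = total / inv_rho
    comp_fracs = {mat.name: m / total for m, mat in comps}
    mix = MixtureMaterial(fractions, density, comp_fracs)
    mix.validate()
    return mix


def homogenize_inventory_region(inventory: BoneInventory, region,
                                compositions=None) -> MixtureMaterial:
    compositions = compositions or default_component_compositions()
    pairs = [(inventory.mass(region, c), compositions[c]) for c in COMPONENTS]
    return homogenize_region([(m, mat) for m, mat in pairs if m > 0])


def aggregate_skeleton(inventory: BoneInventory, component: str) -> float:
    """Whole-skeleton mass of one component (kg), summed over the 20 regions."""
    if component not in COMPONENTS:
        raise KeyError(f"unknown component {component!r}")
    return float(inventory.table[component].sum())


def mass_ratio(mass_kg: float, reference_kg: float, decimals: int | None = 2):
    """Ratio mass/reference; reported with half-up rounding (default 2 dp)."""
    if reference_kg <= 0:
        raise ValueError("reference mass must be positive")
    ratio = mass_kg / reference_kg
    if decimals is None:
        return ratio
    q = Decimal(repr(ratio)).quantize(Decimal(1).scaleb(-decimals),
                                      rounding=ROUND_HALF_UP)
    return float(q)


def component_mass_fraction(inventory: BoneInventory, region,
                            component: str) -> float:
    if component not in COMPONENTS:
        raise KeyError(f"unknown component {component!r}")
    total = inventory.region_total(region)
    if total <= 0:
        raise ValueError(f"region {region!r} has zero total mass")
    return inventory.mass(region, component) / total


def mixture_mu_en(material, E_mev):
    """Mass energy-absorption coefficient of a material [m^2/kg].

    ``material`` is anything with a ``fractions`` mapping (Material or
    MixtureMaterial).  Log-log interpolated on the packaged elemental grid;
    energies outside table coverage raise.
    """
    coeffs = xsdata.mixture_coefficients(material.fractions, E_mev)
    out = coeffs["mu_en"] * 0.1  # cm^2/g -> m^2/kg
    return float(out[0]) if np.isscalar(E_mev) else out
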