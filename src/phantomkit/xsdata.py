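"""Elemental photon interaction coefficients (0.001-20 MeV).

The packaged table carries, per element and energy, mass coefficients
(cm^2/g) for the photoelectric effect, incoherent (Compton) scattering and
nuclear pair production, plus the mass energy-absorption coefficient.

The numbers come from an internally consistent analytic model:

* Incoherent scattering is the exact Klein-Nishina cross section on Z free
  electrons; its energy-transfer fraction is integrated numerically.
* Photoelectric absorption uses a calibrated Z^4.4 / E^3 Born-type power
  law (no shell edges); all transferred energy is absorbed locally.
* Pair production uses the Bethe-Heitler high-energy logarithm with a cubic
  near-threshold ramp; 2 m_e c^2 is carried away by annihilation photons.
* Coherent (Rayleigh) scattering and radiative losses are omitted, so the
  energy-absorption coefficient here is an energy-transfer coefficient.

This is a self-consistent approximation suitable for verification and for
reproducing qualitative photon-energy trends; it is not a replacement for
evaluated nuclear data.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

R_E_CM = 2.8179403262e-13          # classical electron radius [cm]
SIGMA_T = 8.0 * np.pi / 3.0 * R_E_CM ** 2   # Thomson cross section [cm^2]
ALPHA = 7.2973525693e-3
MEC2 = 0.51099895                  # electron rest energy [MeV]
N_A = 6.02214076e23

# symbol -> (Z, A)
ELEMENT_DATA = {
    "H": (1, 1.008), "C": (6, 12.011), "N": (7, 14.007), "O": (8, 15.999),
    "Na": (11, 22.990), "Mg": (12, 24.305), "P": (15, 30.974),
    "S": (16, 32.06), "Cl": (17, 35.45), "K": (19, 39.098),
    "Ca": (20, 40.078), "Fe": (26, 55.845), "I": (53, 126.904),
}

E_MIN, E_MAX = 1e-3, 20.0
N_GRID = 87

# photoelectric calibration: water mu_pe/rho ~ 4.94 cm^2/g at 0.01 MeV
_PE_EXPONENT = 4.4
_PE_CONSTANT = 1.253e-31  # cm^2 per atom at eps=1 for Z=1


def energy_grid():
    return np.geomspace(E_MIN, E_MAX, N_GRID)


# ---------------------------------------------------------------------------
# Klein-Nishina
# ---------------------------------------------------------------------------

def kn_total_cross_section(E_mev):
    """Total Klein-Nishina cross section per electron [cm^2]."""
    k = np.asarray(E_mev, float) / MEC2
    t1 = (1 + k) / k ** 2 * (2 * (1 + k) / (1 + 2 * k) - np.log(1 + 2 * k) / k)
    t2 = np.log(1 + 2 * k) / (2 * k)
    t3 = (1 + 3 * k) / (1 + 2 * k) ** 2
    return 2 * np.pi * R_E_CM ** 2 * (t1 + t2 - t3)


def kn_differential(E_mev, cos_theta):
    """d(sigma)/d(cos theta) per electron [cm^2]."""
    k = E_mev / MEC2
    eps = 1.0 / (1.0 + k * (1.0 - cos_theta))
    sin2 = 1.0 - cos_theta ** 2
    return np.pi * R_E_CM ** 2 * eps ** 2 * (eps + 1.0 / eps - sin2)


def kn_transfer_fraction(E_mev, n=4001):
    """Mean fraction of photon energy given to the Compton electron."""
    mu = np.linspace(-1.0, 1.0, n)
    k = E_mev / MEC2
    eps = 1.0 / (1.0 + k * (1.0 - mu))
    w = kn_differential(E_mev, mu)
    sigma = np.trapezoid(w, mu)
    return float(np.trapezoid(w * (1.0 - eps), mu) / sigma)


# ---------------------------------------------------------------------------
# photoelectric / pair models
# ---------------------------------------------------------------------------

def pe_cross_section(Z, E_mev):
    """Approximate photoelectric cross section per atom [cm^2] (no edges)."""
    eps = np.asarray(E_mev, float) / MEC2
    return _PE_CONSTANT * Z ** _PE_EXPONENT * eps ** -3 / np.sqrt(1.0 + eps)


def pair_cross_section(Z, E_mev):
    """Approximate nuclear pair-production cross section per atom [cm^2]."""
    eps = np.asarray(E_mev, float) / MEC2
    scalar = np.isscalar(E_mev)
    eps = np.atleast_1d(eps)
    out = np.zeros_like(eps)
    eps0 = 8.0
    p_hi = 28.0 / 9.0 * np.log(2 * eps) - 218.0 / 27.0
    p0 = 28.0 / 9.0 * np.log(2 * eps0) - 218.0 / 27.0
    ramp = p0 * ((eps - 2.0) / (eps0 - 2.0)) ** 3
    out = np.where(eps >= eps0, p_hi, np.where(eps > 2.0, ramp, 0.0))
    sigma = ALPHA * R_E_CM ** 2 * Z ** 2 * out
    return float(sigma[0]) if scalar else sigma


# ---------------------------------------------------------------------------
# per-element mass coefficients
# ---------------------------------------------------------------------------

def element_coefficients(symbol, E_mev):
    """dict of mass coefficients (cm^2/g) for one element at E (array ok)."""
    Z, A = ELEMENT_DATA[symbol]
    E = np.atleast_1d(np.asarray(E_mev, float))
    atoms_per_g = N_A / A
    pe = pe_cross_section(Z, E) * atoms_per_g
    compton = kn_total_cross_section(E) * Z * atoms_per_g
    pair = pair_cross_section(Z, E) * atoms_per_g
    f_c = np.array([kn_transfer_fraction(e) for e in E])
    f_pair = np.where(E > 2 * MEC2, (E - 2 * MEC2) / np.maximum(E, 1e-30), 0.0)
    mu_en = pe * 1.0 + compton * f_c + pair * f_pair
    return {
        "pe": pe, "compton": compton, "pair": pair,
        "total": pe + compton + pair, "mu_en": mu_en,
    }


def generate_table_text():
    """Render the packaged coefficient table (TSV) from the analytic model."""
    grid = energy_grid()
    lines = [
        "# Elemental photon mass interaction coefficients [cm^2/g].",
        "# Generated by phantomkit's analytic model (see phantomkit.xsdata):",
        "# exact Klein-Nishina incoherent scattering, calibrated Z^4.4/E^3",
        "# photoelectric power law, Bethe-Heitler-style pair production.",
        "# Coherent scattering and radiative losses omitted.",
        "element\tZ\tenergy_MeV\tpe\tcompton\tpair\ttotal\tmu_en",
    ]
    for sym, (Z, _A) in ELEMENT_DATA.items():
        c = element_coefficients(sym, grid)
        for i, e in enumerate(grid):
            lines.append(
                f"{sym}\t{Z}\t{e:.10e}\t{c['pe'][i]:.10e}\t"
                f"{c['compton'][i]:.10e}\t{c['pair'][i]:.10e}\t"
                f"{c['total'][i]:.10e}\t{c['mu_en'][i]:.10e}")
    return "\n".join(lines) + "\n"


@lru_cache(maxsize=1)
def load_element_table():
    """Packaged table as {symbol: {channel: array}} plus the energy grid."""
    from importlib.resources import files
    text = files("phantomkit.data").joinpath("photon_coefficients.tsv").read_text()
    rows = [l.split("\t") for l in text.splitlines()
            if l and not l.startswith("#") and not l.startswith("element")]
    table: dict[str, dict[str, list]] = {}
    grid: list[float] = []
    first = rows[0][0]
    for sym, _z, e, pe, comp, pair, tot, muen in rows:
        d = table.setdefault(sym, {"pe": [], "compton": [], "pair": [],
                                   "total": [], "mu_en": []})
        if sym == first:
            grid.append(float(e))
        d["pe"].append(float(pe))
        d["compton"].append(float(comp))
        d["pair"].append(float(pair))
        d["total"].append(float(tot))
        d["mu_en"].append(float(muen))
    out = {sym: {ch: np.array(v) for ch, v in d.items()}
           for sym, d in table.items()}
    return np.array(grid), out


def _loglog_interp(E, grid, values):
    """Log-log interpolation, strict on range (no extrapolation)."""
    E = np.asarray(E, float)
    if np.any(E < grid[0] * (1 - 1e-12)) or np.any(E > grid[-1] * (1 + 1e-12)):
        raise ValueError(
            f"energy outside table range [{grid[0]:g}, {grid[-1]:g}] MeV")
    logv = np.log(np.maximum(values, 1e-300))
    return np.exp(np.interp(np.log(E), np.log(grid), logv))


def mixture_coefficients(fractions, E_mev):
    """Mass-fraction-weighted coefficients (cm^2/g) for a mixture at E.

    ``fractions``: {element symbol: mass fraction}.  Log-log interpolation
    on the packaged grid; raises outside table coverage.
    """
    grid, table = load_element_table()
    E = np.atleast_1d(np.asarray(E_mev, float))
    out = {ch: np.zeros_like(E) for ch in ("pe", "compton", "pair",
                                           "total", "mu_en")}
    for sym, w in fractions.items():
        if sym not in table:
            raise KeyError(f"element {sym!r} not covered by the packaged table")
        for ch in out:
            out[ch] += w * _loglog_interp(E, grid, table[sym][ch])
    return out
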