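"""Material definitions and proton stopping-power / range services.

Every downstream piece of the pipeline (condensed-history transport,
water-equivalent-thickness conversion, aperture stopping-thickness sizing)
pulls its energy-loss physics from here.  Each supported material ships with
a plain-text fixture table (energy, electronic mass stopping power, CSDA
range) generated once by ``scripts/generate_stopping_tables.py`` from the
Bethe stopping-power formula with standard composition constants; the tables
are interpolated log-log, so evaluating at a tabulated energy reproduces the
tabulated value exactly.

Units follow radiotherapy convention: energies in MeV, mass stopping powers
in MeV·cm²/g, densities in g/cm³, radiation lengths in g/cm², thicknesses
and ranges in mm.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.optimize import brentq

__all__ = [
    "Material",
    "get_material",
    "supported_materials",
    "mass_stopping_power",
    "linear_stopping_power",
    "csda_range",
    "energy_from_range",
    "relative_stopping_power",
    "wet_thickness",
    "min_stopping_thickness",
    "EnergyRangeError",
    "UnsupportedMaterialError",
]

# Validity window of the fixture tables (MeV).
E_TABLE_MIN = 1.0
E_TABLE_MAX = 250.0

# Bohr energy-straggling constant: d(sigma_E^2)/dt = BOHR_K * (Z/A) MeV^2 per g/cm^2.
BOHR_K = 0.1569

PROTON_MASS_MEV = 938.272


class UnsupportedMaterialError(KeyError):
    pass


class EnergyRangeError(ValueError):
    pass


# name -> (density g/cm3, Z/A, I eV, X0 g/cm2, mass-weighted mean A, is_metal)
# Compositions: water H2O; air (ICRU dry); polycarbonate C16H14O3 (Lexan,
# the default range-shifter plastic); brass 70/30 Cu/Zn by mass via Bragg
# additivity.  Constants are the standard PDG/ICRU reference values.
_CONSTANTS: dict[str, tuple[float, float, float, float, float, bool]] = {
    "water": (1.000, 0.55509, 75.0, 36.08, 14.32, False),
    "air": (1.205e-3, 0.49919, 85.7, 36.62, 14.40, False),
    "polycarbonate": (1.200, 0.52697, 73.1, 41.50, 12.15, False),
    "tungsten": (19.30, 0.40252, 727.0, 6.76, 183.84, True),
    "nickel": (8.902, 0.47706, 311.0, 12.68, 58.69, True),
    "lead": (11.35, 0.39575, 823.0, 6.37, 207.2, True),
    "brass": (8.520, 0.45711, 324.4, 12.73, 64.10, True),
}

# Nuclear-removal interaction length: ~120 g/cm^2 in water, scaled by the
# geometric (A^(1/3)) dependence of the per-nucleus cross-section.
_NUCLEAR_LAMBDA_WATER = 120.0

# Condensed-history step-size caps (mm); metals need finer steps to resolve
# thin-aperture slit scattering.  The transport kernel imports these, and the
# deterministic depth-dose model below evaluates its Highland log-correction
# at the same step so both share one effective scattering power.
MAX_STEP_MM_METAL = 0.2
MAX_STEP_MM_LIGHT = 1.0
HIGHLAND_LOG_FLOOR = 0.25


def max_step_mm(material: "Material") -> float:
    return MAX_STEP_MM_METAL if material.is_metal else MAX_STEP_MM_LIGHT


def highland_sigma(material: "Material", energy, step_mm, cum_t_x0=0.0):
    """Highland projected multiple-scattering angle sigma (rad) for one step.

    theta_0 = (14.1 MeV / pv) sqrt(t/X0) [1 + (1/9) log10(t/X0)], with the
    bracket floored to stay positive for very thin steps.

    When condensed-history transport subdivides a thick slab, applying the
    logarithmic correction to each thin substep systematically underscatters
    (the correction is calibrated for the full thickness).  Passing the
    radiative thickness already traversed as ``cum_t_x0`` evaluates the
    correction at cumulative + step instead — the differential form of the
    formula — so summed substeps track the full-thickness prediction.  For a
    fresh proton taking a single step the two forms coincide.
    """
    t_x0 = np.asarray(step_mm, dtype=float) / 10.0 * material.density / material.radiation_length
    t_eval = t_x0 + np.asarray(cum_t_x0, dtype=float)
    corr = np.maximum(1.0 + np.log10(np.maximum(t_eval, 1e-12)) / 9.0, HIGHLAND_LOG_FLOOR)
    return 14.1 / pv(energy) * np.sqrt(t_x0) * corr


@dataclass(frozen=True)
class Material:
    """A transport medium with its embedded stopping/range reference data."""

    name: str
    density: float  # g/cm^3
    z_over_a: float
    mean_excitation_ev: float
    radiation_length: float  # g/cm^2
    mean_a: float
    is_metal: bool
    energy_grid: np.ndarray = field(repr=False)  # MeV
    stopping_grid: np.ndarray = field(repr=False)  # MeV cm^2/g
    range_grid: np.ndarray = field(repr=False)  # g/cm^2
    # cached logs for fast log-log interpolation
    _log_e: np.ndarray = field(repr=False)
    _log_s: np.ndarray = field(repr=False)
    _log_r: np.ndarray = field(repr=False)

    @property
    def stopping_table(self) -> np.ndarray:
        """(n, 2) array of (energy MeV, mass stopping power MeV cm^2/g)."""
        return np.column_stack([self.energy_grid, self.stopping_grid])

    @property
    def relative_stopping_power(self) -> float:
        """Scalar linear stopping-power ratio to water at 100 MeV."""
        return relative_stopping_power(self, 100.0)

    @property
    def nuclear_interaction_length(self) -> float:
        """Simplified removal interaction length, g/cm^2."""
        return _NUCLEAR_LAMBDA_WATER * (self.mean_a / _CONSTANTS["water"][4]) ** (1.0 / 3.0)


def supported_materials() -> list[str]:
    return sorted(_CONSTANTS)


def _load_table(name: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    path = resources.files("ssadose.data").joinpath(f"stopping_{name}.csv")
    with path.open("rb") as fh:
        raw = np.loadtxt(fh, delimiter=",", comments="#", skiprows=2)
    return raw[:, 0], raw[:, 1], raw[:, 2]


@functools.lru_cache(maxsize=None)
def get_material(name: str) -> Material:
    """Look up a supported material by (case-insensitive) name."""
    key = name.strip().lower()
    if key not in _CONSTANTS:
        raise UnsupportedMaterialError(
            f"unsupported material {name!r}; supported: {', '.join(supported_materials())}"
        )
    density, z_over_a, i_ev, x0, mean_a, is_metal = _CONSTANTS[key]
    e, s, r = _load_table(key)
    return Material(
        name=key,
        density=density,
        z_over_a=z_over_a,
        mean_excitation_ev=i_ev,
        radiation_length=x0,
        mean_a=mean_a,
        is_metal=is_metal,
        energy_grid=e,
        stopping_grid=s,
        range_grid=r,
        _log_e=np.log(e),
        _log_s=np.log(s),
        _log_r=np.log(r),
    )


def _check_energy(energy, lo=E_TABLE_MIN, hi=E_TABLE_MAX) -> np.ndarray:
    e = np.asarray(energy, dtype=float)
    if np.any(e < lo) or np.any(e > hi):
        raise EnergyRangeError(
            f"energy {energy} MeV outside supported table range [{lo}, {hi}] MeV"
        )
    return e


def mass_stopping_power(material: Material, energy):
    """Electronic mass stopping power, MeV·cm²/g (log-log interpolated).

    Accepts scalars or arrays; energies must lie in [1, 250] MeV.
    """
    e = _check_energy(energy)
    out = np.exp(np.interp(np.log(e), material._log_e, material._log_s))
    return float(out) if np.isscalar(energy) else out


def linear_stopping_power(material: Material, energy):
    """Linear stopping power, MeV/mm."""
    return mass_stopping_power(material, energy) * material.density / 10.0


def csda_range(material: Material, energy):
    """Continuous-slowing-down range in mm of material."""
    e = _check_energy(energy)
    r_gcm2 = np.exp(np.interp(np.log(e), material._log_e, material._log_r))
    out = r_gcm2 / material.density * 10.0
    return float(out) if np.isscalar(energy) else out


def energy_from_range(material: Material, range_mm: float) -> float:
    """Energy whose CSDA range equals ``range_mm`` (inverse of :func:`csda_range`).

    Monotone root find; converges well below 0.01 MeV.
    """
    r_lo = csda_range(material, E_TABLE_MIN)
    r_hi = csda_range(material, E_TABLE_MAX)
    if not (r_lo <= range_mm <= r_hi):
        raise EnergyRangeError(
            f"range {range_mm} mm outside achievable [{r_lo:.4g}, {r_hi:.4g}] mm "
            f"for {material.name} between {E_TABLE_MIN} and {E_TABLE_MAX} MeV"
        )
    return float(
        brentq(
            lambda e: csda_range(material, e) - range_mm,
            E_TABLE_MIN,
            E_TABLE_MAX,
            xtol=1e-5,
            rtol=1e-12,
        )
    )


def relative_stopping_power(material: Material, energy) -> float:
    """Linear stopping-power ratio to water at the given energy."""
    water = get_material("water")
    return (
        mass_stopping_power(material, energy)
        * material.density
        / (mass_stopping_power(water, energy) * water.density)
    )


def wet_thickness(material: Material, physical_thickness: float, energy: float) -> float:
    """Water-equivalent thickness (mm) of a slab at the given energy."""
    if physical_thickness < 0:
        raise ValueError("physical_thickness must be non-negative")
    return physical_thickness * relative_stopping_power(material, energy)


def pv(energy):
    """Momentum times velocity, MeV (the Highland-formula kinematic factor)."""
    e = np.asarray(energy, dtype=float)
    out = e * (e + 2.0 * PROTON_MASS_MEV) / (e + PROTON_MASS_MEV)
    return float(out) if np.isscalar(energy) else out


def range_straggling_sigma(material: Material, energy: float) -> float:
    """Bohr longitudinal range-straggling sigma (mm) for a stopping proton.

    sigma_R^2 = ∫_0^E  k (Z/A) dE' / (rho^2 S_m(E')^3), integrated over the
    tabulated window (the sub-1 MeV contribution is negligible).
    """
    _check_energy(energy)
    e_grid = np.geomspace(E_TABLE_MIN, energy, 400)
    s = mass_stopping_power(material, e_grid)
    integrand = BOHR_K * material.z_over_a / (material.density**2 * s**3)
    sigma2_cm2 = np.trapezoid(integrand, e_grid)
    return float(np.sqrt(sigma2_cm2) * 10.0)


def depth_dose_csda(material: Material, energy: float, dz_mm: float = 0.02):
    """Straggling-convolved CSDA depth-dose curve in the material.

    Returns (z_mm, dose): energy deposition per unit *depth* as a function of
    depth, built by slowing a proton down along its CSDA path, projecting the
    path onto depth with the mean-cosine detour from accumulated Highland
    multiple scattering (a few percent in high-Z metals, negligible in
    water), and convolving with a Gaussian of the Bohr range-straggling
    width.  Deterministic stand-in for a depth-dose simulation, used when
    sizing aperture stopping thicknesses.
    """
    r0 = csda_range(material, energy)
    sigma = range_straggling_sigma(material, energy)
    ds = dz_mm
    s = np.arange(0.0, r0, ds)
    # residual path -> local energy via the inverse range table
    resid = np.maximum(r0 - s, csda_range(material, E_TABLE_MIN))
    e_local = np.exp(np.interp(np.log(resid * material.density / 10.0),
                               material._log_r, material._log_e))
    # accumulated space-angle variance: differential Highland form, with the
    # log-correction evaluated at the cumulative thickness traversed
    t_x0 = np.maximum(s, ds) / 10.0 * material.density / material.radiation_length
    f_corr = np.maximum(1.0 + np.log10(t_x0) / 9.0, HIGHLAND_LOG_FLOOR)
    theta2_proj = (14.1**2) * np.cumsum(ds / 10.0 * material.density
                                        / material.radiation_length / pv(e_local) ** 2)
    theta2_space = 2.0 * theta2_proj * f_corr**2
    mean_cos = np.exp(-theta2_space / 2.0)
    depth = np.cumsum(mean_cos * ds)
    # deposit dE/ds onto a uniform depth grid
    de = linear_stopping_power(material, e_local) * ds
    z = np.arange(0.0, depth[-1] + 8.0 * sigma + 1.0, dz_mm)
    dose = np.zeros_like(z)
    np.add.at(dose, np.minimum((depth / dz_mm).astype(int), z.size - 1), de / dz_mm)
    dose = gaussian_filter1d(dose, sigma / dz_mm, mode="nearest")
    return z, dose


def min_stopping_thickness(material: Material, energy: float) -> float:
    """Aperture thickness (mm) sized to stop protons of the given energy.

    Depth at which the straggling-convolved depth-dose has fallen to 0.1% of
    its Bragg-peak value, enlarged by 5% as a safety margin.
    """
    z, dose = depth_dose_csda(material, energy)
    peak = dose.max()
    if peak <= 0:
        raise EnergyRangeError("degenerate depth-dose curve")
    beyond = np.nonzero(dose >= 1e-3 * peak)[0]
    z_falloff = z[beyond[-1]]
    return 1.05 * float(z_falloff)
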