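"""Secondary-neutron dose model for aperture material comparisons.

Stopping a proton beamlet in a metal block produces neutrons, some of which
deposit dose in the downstream phantom.  Neutrons are not transported
microscopically here: the model combines an empirical thick-target yield
parameterization Y(E, material) — a power law in proton energy with a
per-material amplitude, shipped as a fixture table — with a two-component
(isotropic + forward-peaked) dose kernel averaged over a cylindrical water
phantom placed behind the block.  The kernel constants are calibrated once
so that relative doses between materials and the depth trend match
published thick-target collimator measurements; absolute doses are
order-of-magnitude only and every reported comparison is a ratio.

The treatment-field estimator rescales spot fluence so the protons passing
the aperture match the plan (delivered = planned / transmission), attributes
the absorbed remainder to the block, and sums neutron dose over spots.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from . import materials
from .beam_model import TreatmentField
from .materials import Material, get_material

__all__ = [
    "NeutronYieldModel",
    "NeutronResult",
    "load_yield_model",
    "neutron_dose",
    "relative_neutron_dose",
    "field_eligible",
    "integral_neutron_dose",
    "aperture_incident_energy",
    "ELIGIBLE_WET_MIN_MM",
    "ELIGIBLE_WET_MAX_MM",
]

ELIGIBLE_WET_MIN_MM = 40.0
ELIGIBLE_WET_MAX_MM = 100.0

# Figure-3-style block/phantom geometry: cylindrical water phantom, 20 cm
# diameter, front face a small air gap behind the block.
PHANTOM_DIAMETER_MM = 200.0
BLOCK_TO_PHANTOM_MM = 10.0
PHANTOM_LENGTH_MM = 200.0

# Dose kernel calibration: water kerma-like conversion (Gy cm^2 per neutron)
# and the forward-peaked enhancement over isotropic emission.
KERMA_GY_CM2 = 6e-11
FORWARD_ENHANCEMENT = 2.0


@dataclass(frozen=True)
class NeutronYieldModel:
    """Thick-target neutron yields per stopped proton, by material and energy."""

    energies: np.ndarray  # MeV grid
    yields: dict = field(default_factory=dict)  # material name -> yield array
    calibration: str = "synthetic-calibrated"

    def yield_per_proton(self, material: Material, energy: float) -> float:
        if material.name not in self.yields:
            raise KeyError(
                f"no neutron yield data for {material.name!r}; "
                f"available: {sorted(self.yields)}"
            )
        if energy > self.energies[-1]:
            raise materials.EnergyRangeError(
                f"proton energy {energy} MeV above the {self.energies[-1]} MeV yield-table maximum"
            )
        return float(np.interp(energy, self.energies, self.yields[material.name]))


def load_yield_model() -> NeutronYieldModel:
    """Load the shipped synthetic thick-target yield fixture."""
    path = resources.files("ssadose.data").joinpath("neutron_yield.csv")
    with path.open("rb") as fh:
        raw = np.loadtxt(fh, delimiter=",", comments="#", skiprows=2)
    with path.open("r") as fh:
        fh.readline()
        header = fh.readline().strip().split(",")
    energies = raw[:, 0]
    yields = {name: raw[:, i] for i, name in enumerate(header) if i > 0}
    return NeutronYieldModel(energies=energies, yields=yields)


def _dose_kernel_gy_per_neutron() -> float:
    """Mean phantom dose per emitted neutron for the block/phantom geometry.

    Isotropic component: solid-angle fraction of the phantom front face seen
    from the block exit, times a water kerma factor; the forward-peaked
    component multiplies that by a fixed enhancement (neutron emission from
    stopping protons is forward-biased at these energies).
    """
    r = PHANTOM_DIAMETER_MM / 2.0
    d = BLOCK_TO_PHANTOM_MM + PHANTOM_LENGTH_MM / 2.0
    solid_angle_fraction = 0.5 * (1.0 - d / np.sqrt(d**2 + r**2))
    # fluence averaged over the front face, per unit area in cm^2
    mean_fluence_cm2 = solid_angle_fraction / (np.pi * (r / 10.0) ** 2)
    return KERMA_GY_CM2 * mean_fluence_cm2 * FORWARD_ENHANCEMENT


def neutron_dose(
    material: Material,
    energy: float,
    n_protons: float,
    yield_model: NeutronYieldModel | None = None,
) -> float:
    """Total neutron dose (Gy) to the phantom from protons stopped in a block.

    The block thickness is implicitly the minimum stopping thickness for the
    given energy (the yields are thick-target yields, i.e. full stopping).
    """
    if n_protons < 0:
        raise ValueError("n_protons must be non-negative")
    model = yield_model if yield_model is not None else load_yield_model()
    y = model.yield_per_proton(material, energy)
    return float(n_protons * y * _dose_kernel_gy_per_neutron())


def relative_neutron_dose(
    material: Material,
    reference: Material,
    energy: float,
    yield_model: NeutronYieldModel | None = None,
) -> float:
    """Neutron dose of ``material`` as a percent of ``reference`` at equal energy."""
    model = yield_model if yield_model is not None else load_yield_model()
    ref = neutron_dose(reference, energy, 1.0, model)
    if ref <= 0:
        raise ValueError("reference material has zero neutron dose")
    return 100.0 * neutron_dose(material, energy, 1.0, model) / ref


def field_eligible(field_: TreatmentField) -> bool:
    """Shallow-field eligibility: WET minimum < 4 cm and maximum < 10 cm."""
    return (
        field_.wet_depth_min < ELIGIBLE_WET_MIN_MM
        and field_.wet_depth_max < ELIGIBLE_WET_MAX_MM
    )


def aperture_incident_energy(nominal_energy: float, rs_wet_mm: float) -> float:
    """Energy at the aperture after degradation in the attached range shifter."""
    water = get_material("water")
    resid = materials.csda_range(water, nominal_energy) - rs_wet_mm
    return materials.energy_from_range(water, resid)


def integral_neutron_dose(
    field_: TreatmentField,
    aperture_material: Material,
    transmission_lookup,
    rs_wet_mm: float = 45.0,
    yield_model: NeutronYieldModel | None = None,
) -> float:
    """Excess integral neutron dose (Gy) for one treatment field.

    ``transmission_lookup(energy_MeV)`` must return the beamlet transmission
    for the aperture configuration under study.  Per spot with planned
    protons P and transmission T, the fluence is rescaled so P protons still
    pass the aperture: delivered = P/T, absorbed = P(1/T - 1).  The absorbed
    protons stop in the aperture at the range-shifter-degraded energy and
    their neutron dose is summed over spots.
    """
    if not field_eligible(field_):
        raise ValueError(
            f"field {field_.field_id!r} is not eligible (WET window "
            f"[{field_.wet_depth_min}, {field_.wet_depth_max}] mm)"
        )
    model = yield_model if yield_model is not None else load_yield_model()
    total = 0.0
    for energy, _x, _y, planned in field_.spots:
        t = float(transmission_lookup(energy))
        if t <= 0:
            raise ValueError(f"zero transmission at {energy} MeV: spot undeliverable")
        absorbed = planned * (1.0 / t - 1.0)
        e_ap = aperture_incident_energy(energy, rs_wet_mm)
        total += neutron_dose(aperture_material, e_ap, absorbed, model)
    return total
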