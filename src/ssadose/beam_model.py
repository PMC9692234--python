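"""Synthetic beam model and treatment-plan generation.

The machine model emulates a modern pencil-beam-scanning proton system with
17 nominal energies from 70 to 230 MeV and in-air spot sigmas at isocenter
of about 6 mm at the lowest energy and 2 mm at the highest, interpolated
monotonically in 1/E between those anchors.  Beamlets are sampled as
parallel Gaussian bundles (zero divergence by default) at a source plane
500 mm upstream of isocenter, so the free-drift sigma at the isocenter
plane equals the configured in-air sigma.

Synthetic treatment fields stand in for clinical head-and-neck plans: each
field is a stack of energy layers with randomized elliptical cross
sections, spots on a square grid, and log-normal protons-per-spot.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import materials
from .materials import EnergyRangeError, get_material

__all__ = [
    "BeamModel",
    "ProtonBundle",
    "TreatmentField",
    "sigma_air",
    "sample_beamlet",
    "energy_for_bp_depth",
    "generate_synthetic_plan",
    "fields_to_json",
    "fields_from_json",
]

MACHINE_E_MIN = 70.0
MACHINE_E_MAX = 230.0
DEFAULT_SOURCE_UPSTREAM_MM = 500.0  # source plane upstream of isocenter


@dataclass(frozen=True)
class BeamModel:
    """Machine beam model: nominal energies and in-air spot sizes."""

    energies: np.ndarray = field(
        default_factory=lambda: np.linspace(MACHINE_E_MIN, MACHINE_E_MAX, 17)
    )
    sigma_anchor_low: float = 6.0  # mm at the lowest energy
    sigma_anchor_high: float = 2.0  # mm at the highest energy
    divergence_sigma_mrad: float = 0.0  # parallel beam by default
    source_upstream_mm: float = DEFAULT_SOURCE_UPSTREAM_MM
    # optional (energy, sigma) table overriding the 1/E interpolation
    sigma_table: np.ndarray | None = None


@dataclass
class ProtonBundle:
    """Struct-of-arrays collection of proton states (the MC transport unit).

    position (n,3) mm; direction (n,3) unit vectors; kinetic energy MeV;
    statistical weight; alive flag.
    """

    position: np.ndarray
    direction: np.ndarray
    energy: np.ndarray
    weight: np.ndarray
    alive: np.ndarray
    # cumulative radiative thickness traversed (t/X0), which the transport
    # kernel feeds back into the Highland log-correction
    t_rad: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.t_rad is None:
            self.t_rad = np.zeros(self.energy.size)

    def __len__(self) -> int:
        return self.energy.size

    def copy(self) -> "ProtonBundle":
        return ProtonBundle(
            self.position.copy(),
            self.direction.copy(),
            self.energy.copy(),
            self.weight.copy(),
            self.alive.copy(),
            self.t_rad.copy(),
        )

    def select(self, mask: np.ndarray) -> "ProtonBundle":
        return ProtonBundle(
            self.position[mask].copy(),
            self.direction[mask].copy(),
            self.energy[mask].copy(),
            self.weight[mask].copy(),
            self.alive[mask].copy(),
            self.t_rad[mask].copy(),
        )

    @staticmethod
    def empty() -> "ProtonBundle":
        return ProtonBundle(
            np.zeros((0, 3)), np.zeros((0, 3)), np.zeros(0), np.zeros(0), np.zeros(0, bool)
        )


@dataclass(frozen=True)
class TreatmentField:
    """A spot list with its water-equivalent treatment-depth window."""

    field_id: str
    wet_depth_min: float  # mm
    wet_depth_max: float  # mm
    # (n_spots, 4): energy MeV, x mm, y mm, planned protons
    spots: np.ndarray

    def __post_init__(self) -> None:
        if self.wet_depth_min > self.wet_depth_max:
            raise ValueError("wet_depth_min must not exceed wet_depth_max")
        if np.any(self.spots[:, 3] <= 0):
            raise ValueError("planned proton counts must be positive")


def sigma_air(model: BeamModel, energy: float) -> float:
    """In-air spot sigma (mm) at the isocenter plane for a nominal energy."""
    e_lo, e_hi = model.energies[0], model.energies[-1]
    if not (e_lo <= energy <= e_hi):
        raise EnergyRangeError(
            f"energy {energy} MeV outside machine range [{e_lo}, {e_hi}] MeV"
        )
    if model.sigma_table is not None:
        tab = np.asarray(model.sigma_table, dtype=float)
        return float(np.interp(energy, tab[:, 0], tab[:, 1]))
    # linear in 1/E through the two anchors
    inv = 1.0 / energy
    inv_lo, inv_hi = 1.0 / e_lo, 1.0 / e_hi
    w = (inv - inv_hi) / (inv_lo - inv_hi)
    return float(model.sigma_anchor_high + w * (model.sigma_anchor_low - model.sigma_anchor_high))


def sample_beamlet(
    model: BeamModel,
    energy: float,
    n: int,
    seed: int,
    infinitesimal: bool = False,
    isocenter_z_mm: float = 50.0,
) -> ProtonBundle:
    """Sample a beamlet phase space at the source plane, directed along +z.

    With ``infinitesimal=True`` all protons start exactly on axis with zero
    divergence (the theoretical lower-limit beamlet).  Otherwise lateral
    positions and angles are Gaussian, arranged so that the free-drift sigma
    at the isocenter plane equals ``sigma_air(model, energy)``.
    Deterministic for a fixed seed.
    """
    z0 = isocenter_z_mm - model.source_upstream_mm
    if n == 0:
        return ProtonBundle.empty()
    pos = np.zeros((n, 3))
    pos[:, 2] = z0
    dirs = np.zeros((n, 3))
    dirs[:, 2] = 1.0
    if not infinitesimal:
        rng = np.random.default_rng(seed)
        sig_iso = sigma_air(model, energy)
        theta = model.divergence_sigma_mrad * 1e-3
        drift = model.source_upstream_mm
        # source-plane sigma such that sigma^2(source) + theta^2 * L^2 = sigma_iso^2
        sig_src2 = sig_iso**2 - (theta * drift) ** 2
        if sig_src2 < 0:
            raise ValueError("divergence alone exceeds the configured isocenter sigma")
        pos[:, 0] = rng.normal(0.0, np.sqrt(sig_src2), n)
        pos[:, 1] = rng.normal(0.0, np.sqrt(sig_src2), n)
        if theta > 0:
            sx = rng.normal(0.0, theta, n)
            sy = rng.normal(0.0, theta, n)
            norm = np.sqrt(1.0 + sx**2 + sy**2)
            dirs[:, 0] = sx / norm
            dirs[:, 1] = sy / norm
            dirs[:, 2] = 1.0 / norm
    return ProtonBundle(
        position=pos,
        direction=dirs,
        energy=np.full(n, float(energy)),
        weight=np.ones(n),
        alive=np.ones(n, dtype=bool),
    )


def energy_for_bp_depth(target_depth_mm: float, geometry_wet_upstream_mm: float) -> float:
    """Nominal energy whose water range equals target depth + upstream WET.

    Shallow targets must be reached through a range shifter: energies below
    the 70 MeV machine minimum are rejected rather than extrapolated.
    """
    water = get_material("water")
    total = target_depth_mm + geometry_wet_upstream_mm
    energy = materials.energy_from_range(water, total)
    if energy < MACHINE_E_MIN - 1e-9:
        raise EnergyRangeError(
            f"required energy {energy:.2f} MeV is below the {MACHINE_E_MIN} MeV machine "
            "minimum; add upstream water-equivalent thickness (range shifter) to reach "
            f"a {target_depth_mm} mm depth"
        )
    if energy > MACHINE_E_MAX + 1e-9:
        raise EnergyRangeError(
            f"required energy {energy:.2f} MeV exceeds the {MACHINE_E_MAX} MeV machine maximum"
        )
    return float(energy)


def _layer_spot_grid(spacing: float, a: float, b: float) -> np.ndarray:
    """Square-grid points (x, y) inside an ellipse with semi-axes a, b."""
    nx = int(np.floor(a / spacing))
    ny = int(np.floor(b / spacing))
    xs = np.arange(-nx, nx + 1) * spacing
    ys = np.arange(-ny, ny + 1) * spacing
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    inside = (gx / a) ** 2 + (gy / b) ** 2 <= 1.0
    return np.column_stack([gx[inside], gy[inside]])


def generate_synthetic_plan(
    n_fields: int,
    seed: int,
    depth_profile: tuple[float, float, float, float] = (15.0, 38.0, 20.0, 55.0),
    spot_spacing: float = 5.0,
    protons_per_spot_scale: tuple[float, float] = (1e7, 0.5),
    layer_wet_spacing: float = 5.0,
    rs_wet_mm: float = 45.0,
    target_semi_axes: tuple[float, float] = (10.0, 30.0),
) -> list[TreatmentField]:
    """Generate synthetic shallow-target treatment fields.

    ``depth_profile`` = (min depth low, min depth high, extent low, extent
    high) in mm WET: each field draws its proximal depth uniformly from the
    first interval and its depth extent from the second (distal edge capped
    at 99 mm so the default profile satisfies the shallow-field eligibility
    rule).  ``protons_per_spot_scale`` = (median, log-sigma) of the
    log-normal protons-per-spot draw.  Spot energies are chosen so the Bragg
    peak sits at the layer depth behind a ``rs_wet_mm`` range shifter.
    """
    if n_fields < 1:
        raise ValueError("n_fields must be >= 1")
    if spot_spacing <= 0:
        raise ValueError("spot_spacing must be positive")
    ax_lo, ax_hi = target_semi_axes
    if ax_hi <= 0 or ax_lo <= 0:
        raise ValueError("degenerate target: semi-axes must be positive")
    rng = np.random.default_rng(seed)
    median, log_sigma = protons_per_spot_scale
    fields: list[TreatmentField] = []
    for i in range(n_fields):
        d_min = rng.uniform(depth_profile[0], depth_profile[1])
        d_max = min(d_min + rng.uniform(depth_profile[2], depth_profile[3]), 99.0)
        a0 = rng.uniform(ax_lo, ax_hi)
        b0 = rng.uniform(ax_lo, ax_hi)
        layers = np.arange(d_min, d_max + 1e-9, layer_wet_spacing)
        rows = []
        for depth in layers:
            scale = rng.uniform(0.6, 1.0)
            xy = _layer_spot_grid(spot_spacing, scale * a0, scale * b0)
            energy = energy_for_bp_depth(depth, rs_wet_mm)
            protons = rng.lognormal(np.log(median), log_sigma, len(xy))
            rows.append(
                np.column_stack([np.full(len(xy), energy), xy, protons])
            )
        spots = np.vstack(rows)
        fields.append(
            TreatmentField(
                field_id=f"synthetic-{seed}-{i:03d}",
                wet_depth_min=float(d_min),
                wet_depth_max=float(d_max),
                spots=spots,
            )
        )
    return fields


def fields_to_json(fields: list[TreatmentField], path) -> None:
    payload = [
        {
            "field_id": f.field_id,
            "wet_depth_min_mm": f.wet_depth_min,
            "wet_depth_max_mm": f.wet_depth_max,
            "spots": [
                {"energy_MeV": e, "x_mm": x, "y_mm": y, "protons": p}
                for e, x, y, p in f.spots
            ],
        }
        for f in fields
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def fields_from_json(path) -> list[TreatmentField]:
    with open(path) as fh:
        payload = json.load(fh)
    return [
        TreatmentField(
            field_id=item["field_id"],
            wet_depth_min=item["wet_depth_min_mm"],
            wet_depth_max=item["wet_depth_max_mm"],
            spots=np.array(
                [
                    [s["energy_MeV"], s["x_mm"], s["y_mm"], s["protons"]]
                    for s in item["spots"]
                ]
            ),
        )
        for item in payload
    ]
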