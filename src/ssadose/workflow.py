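"""End-to-end experiment orchestration: parameter sweeps and result tables.

Each study reproduces one of the characterization experiments: spot sizes
at the Bragg peak for aperture configurations against open-beam / extended
range shifter (ERS) / moveable range shifter comparators; dose-ratio
beamlet transmission with and without a worst-case 1 mm misalignment; the
range-shifter-to-aperture gap tradeoff; relative neutron doses per aperture
material; and per-field integral neutron dose plus delivery-time overhead
for synthetic treatment plans.

Results are plain pandas DataFrames; every study is reproducible bit-exactly
from its spec and seed.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import dosimetry, materials, neutron
from .beam_model import BeamModel, TreatmentField, energy_for_bp_depth, sample_beamlet
from .delivery_time import TimingParams, additional_time
from .materials import get_material, relative_stopping_power
from .transport import (
    Aperture,
    DEFAULT_APERTURE_THICKNESS_MM,
    GeometryStack,
    TransportResult,
    simulate_configuration,
    transport_beamlet,
)

__all__ = [
    "SweepSpec",
    "ssa_geometry",
    "ers_geometry",
    "moveable_rs_geometry",
    "open_geometry",
    "run_beamlet",
    "beamlet_sigma",
    "run_spot_size_study",
    "run_transmission_study",
    "run_gap_study",
    "run_neutron_study",
    "run_plan_study",
    "build_transmission_lookup",
]

ERS_UPSTREAM_MM = 300.0  # extended range shifter: downstream face 30 cm from isocenter


@dataclass(frozen=True)
class SweepSpec:
    """Default parameter grids for the characterization sweeps."""

    materials: tuple = ("tungsten", "nickel")
    radii_mm: tuple = (1.0, 2.0, 3.0, 4.0)
    asds_mm: tuple = (1.0, 50.0, 100.0)
    gaps_mm: tuple = tuple(np.linspace(0.0, 300.0, 7))
    bp_depths_mm: tuple = tuple(np.linspace(0.0, 100.0, 9))
    rs_wet_mm: float = 45.0
    n_histories: int = 200_000
    seed: int = 20220
    nuclear: bool = True
    comparators: tuple = ("infinitesimal", "open", "ers", "moveable_rs")
    phantom_shape: tuple = (61, 61, 120)

    def to_yaml_dict(self) -> dict:
        d = asdict(self)
        return {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}


def _child_seed(seed: int, *tags) -> int:
    h = hashlib.sha256(repr((seed,) + tags).encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31 - 1)


def _rs_physical_thickness(rs_wet_mm: float, rs_material: str = "polycarbonate") -> float:
    return rs_wet_mm / relative_stopping_power(get_material(rs_material), 100.0)


def ssa_geometry(
    material: str = "tungsten",
    radius_mm: float = 3.0,
    asd_mm: float = 50.0,
    gap_mm: float = 0.0,
    rs_wet_mm: float = 45.0,
    offset_mm: tuple[float, float] = (0.0, 0.0),
    thickness_mm: float | None = None,
    phantom_shape: tuple = (61, 61, 120),
) -> GeometryStack:
    """Aperture + attached range shifter at a given distance to the phantom."""
    mat = get_material(material)
    if thickness_mm is None:
        thickness_mm = DEFAULT_APERTURE_THICKNESS_MM[mat.name]
    ap = Aperture(mat, thickness_mm, radius_mm, lateral_offset=offset_mm,
                  z_downstream=-asd_mm)
    rs = None
    if rs_wet_mm > 0:
        poly = get_material("polycarbonate")
        rs = (poly, _rs_physical_thickness(rs_wet_mm), ap.z_upstream - gap_mm)
    return GeometryStack(range_shifter=rs, aperture=ap, phantom_shape=phantom_shape)


def ers_geometry(
    rs_wet_mm: float = 45.0,
    isocenter_depth: float = 50.0,
    phantom_shape: tuple = (61, 61, 120),
) -> GeometryStack:
    """Extended range shifter: downstream face 30 cm upstream of isocenter."""
    poly = get_material("polycarbonate")
    z1 = isocenter_depth - ERS_UPSTREAM_MM
    return GeometryStack(
        range_shifter=(poly, _rs_physical_thickness(rs_wet_mm), z1),
        phantom_shape=phantom_shape,
        isocenter_depth=isocenter_depth,
    )


def moveable_rs_geometry(
    asd_mm: float,
    rs_wet_mm: float = 45.0,
    phantom_shape: tuple = (61, 61, 120),
) -> GeometryStack:
    """Range shifter at the aperture's position, with no aperture."""
    poly = get_material("polycarbonate")
    return GeometryStack(
        range_shifter=(poly, _rs_physical_thickness(rs_wet_mm), -asd_mm),
        phantom_shape=phantom_shape,
    )


def open_geometry(phantom_shape: tuple = (61, 61, 120)) -> GeometryStack:
    return GeometryStack(phantom_shape=phantom_shape)


def run_beamlet(
    geometry: GeometryStack,
    bp_depth_mm: float,
    spec: SweepSpec,
    tag: tuple,
    model: BeamModel | None = None,
    infinitesimal: bool = False,
    n_histories: int | None = None,
) -> TransportResult:
    """Transport one beamlet aimed at a target Bragg-peak depth."""
    model = model or BeamModel()
    wet_upstream = 0.0
    if geometry.range_shifter is not None:
        mat, thick, _ = geometry.range_shifter
        wet_upstream = materials.wet_thickness(mat, thick, 100.0)
    energy = energy_for_bp_depth(bp_depth_mm, wet_upstream)
    n = n_histories if n_histories is not None else spec.n_histories
    src = sample_beamlet(model, energy, n, _child_seed(spec.seed, "src", *tag),
                         infinitesimal=infinitesimal)
    return transport_beamlet(src, geometry, _child_seed(spec.seed, "mc", *tag),
                             nuclear=spec.nuclear)


def beamlet_sigma(result: TransportResult) -> tuple[float, float]:
    """(Bragg-peak depth, spot sigma at that depth) for one run."""
    curve = dosimetry.idd(result.dose_grid)
    bp = dosimetry.bragg_peak_depth(curve)
    return bp, dosimetry.spot_sigma(result.dose_grid, bp)


def run_spot_size_study(spec: SweepSpec, model: BeamModel | None = None) -> pd.DataFrame:
    """Spot sigma at the Bragg peak for every configuration and comparator."""
    model = model or BeamModel()
    rows = []
    for depth in spec.bp_depths_mm:
        # comparators (shared across SSA configurations)
        for comp in spec.comparators:
            try:
                if comp == "infinitesimal":
                    geom, infinitesimal = open_geometry(spec.phantom_shape), True
                elif comp == "open":
                    geom, infinitesimal = open_geometry(spec.phantom_shape), False
                elif comp == "ers":
                    geom, infinitesimal = ers_geometry(spec.rs_wet_mm,
                                                       phantom_shape=spec.phantom_shape), False
                else:
                    continue  # moveable_rs depends on the ASD; handled below
                res = run_beamlet(geom, depth, spec, (comp, depth), model, infinitesimal)
                bp, sigma = beamlet_sigma(res)
            except materials.EnergyRangeError:
                continue  # depth unreachable without a range shifter
            rows.append(dict(config=comp, material="", radius_mm=np.nan, asd_mm=np.nan,
                             target_depth_mm=depth, bp_depth_mm=bp, sigma_mm=sigma))
        for asd in spec.asds_mm:
            if "moveable_rs" in spec.comparators:
                geom = moveable_rs_geometry(asd, spec.rs_wet_mm, spec.phantom_shape)
                res = run_beamlet(geom, depth, spec, ("mrs", asd, depth), model)
                bp, sigma = beamlet_sigma(res)
                rows.append(dict(config="moveable_rs", material="", radius_mm=np.nan,
                                 asd_mm=asd, target_depth_mm=depth, bp_depth_mm=bp,
                                 sigma_mm=sigma))
            for mat in spec.materials:
                for radius in spec.radii_mm:
                    geom = ssa_geometry(mat, radius, asd, rs_wet_mm=spec.rs_wet_mm,
                                        phantom_shape=spec.phantom_shape)
                    res = run_beamlet(geom, depth, spec, ("ssa", mat, radius, asd, depth),
                                      model)
                    bp, sigma = beamlet_sigma(res)
                    rows.append(dict(config="ssa", material=mat, radius_mm=radius,
                                     asd_mm=asd, target_depth_mm=depth, bp_depth_mm=bp,
                                     sigma_mm=sigma))
    return pd.DataFrame(rows)


def _paired_transmission(
    material: str,
    radius_mm: float,
    asd_mm: float,
    gap_mm: float,
    depth: float,
    spec: SweepSpec,
    offset_mm: tuple[float, float] = (0.0, 0.0),
    model: BeamModel | None = None,
    without_cache: dict | None = None,
):
    """(with-run, without-run, transmission) with the without-run cached."""
    model = model or BeamModel()
    geom = ssa_geometry(material, radius_mm, asd_mm, gap_mm, spec.rs_wet_mm,
                        offset_mm=offset_mm, phantom_shape=spec.phantom_shape)
    wet = spec.rs_wet_mm
    energy = energy_for_bp_depth(depth, wet)
    tag = ("trans", material, asd_mm, gap_mm, depth)
    src = sample_beamlet(model, energy, spec.n_histories,
                         _child_seed(spec.seed, "src", *tag))
    with_res = transport_beamlet(src, geom, _child_seed(spec.seed, "mc", *tag),
                                 nuclear=spec.nuclear)
    key = tag
    if without_cache is not None and key in without_cache:
        without_res = without_cache[key]
    else:
        open_geom = GeometryStack(
            range_shifter=geom.range_shifter, aperture=None,
            phantom_shape=geom.phantom_shape, voxel_size=geom.voxel_size,
            exit_plane_z=geom.aperture.z_downstream,
        )
        without_res = transport_beamlet(src, open_geom,
                                        _child_seed(spec.seed, "mc", *tag),
                                        nuclear=spec.nuclear)
        if without_cache is not None:
            without_cache[key] = without_res
    t = dosimetry.transmission(with_res.dose_grid, without_res.dose_grid)
    return with_res, without_res, t


def run_transmission_study(
    spec: SweepSpec,
    offset_mm: float = 1.0,
    asd_mm: float = 50.0,
    model: BeamModel | None = None,
) -> pd.DataFrame:
    """Transmission per (material, radius, depth), aligned and misaligned."""
    if offset_mm < 0:
        raise ValueError("offset must be non-negative")
    model = model or BeamModel()
    cache: dict = {}
    rows = []
    for mat in spec.materials:
        for radius in spec.radii_mm:
            for depth in spec.bp_depths_mm:
                _, _, t0 = _paired_transmission(mat, radius, asd_mm, 0.0, depth, spec,
                                                model=model, without_cache=cache)
                row = dict(material=mat, radius_mm=radius, asd_mm=asd_mm,
                           bp_depth_mm=depth, transmission=t0,
                           transmission_offset=np.nan, offset_mm=offset_mm)
                if offset_mm > 0:
                    _, _, t1 = _paired_transmission(
                        mat, radius, asd_mm, 0.0, depth, spec,
                        offset_mm=(offset_mm, 0.0), model=model, without_cache=cache)
                    row["transmission_offset"] = t1
                rows.append(row)
    return pd.DataFrame(rows)


def run_gap_study(
    spec: SweepSpec,
    material: str = "tungsten",
    radius_mm: float = 3.0,
    asd_mm: float = 50.0,
    bp_depth_mm: float = 50.0,
    model: BeamModel | None = None,
) -> pd.DataFrame:
    """Relative spot sigma and transmission vs range-shifter-aperture gap."""
    model = model or BeamModel()
    rows = []
    for gap in spec.gaps_mm:
        cache: dict = {}
        with_res, _, t = _paired_transmission(material, radius_mm, asd_mm, gap,
                                              bp_depth_mm, spec, model=model,
                                              without_cache=cache)
        bp, sigma = beamlet_sigma(with_res)
        rows.append(dict(material=material, radius_mm=radius_mm, asd_mm=asd_mm,
                         gap_mm=gap, bp_depth_mm=bp, sigma_mm=sigma, transmission=t))
    df = pd.DataFrame(rows)
    ref = df[df.gap_mm == df.gap_mm.min()].iloc[0]
    df["relative_sigma"] = df.sigma_mm / ref.sigma_mm
    df["relative_transmission"] = df.transmission / ref.transmission
    return df


def run_neutron_study(
    material_names: tuple = ("tungsten", "lead", "brass", "nickel"),
    max_depths_mm: tuple = (20.0, 40.0, 60.0, 80.0, 100.0, 150.0, 230.0, 329.0),
    n_protons: float = 1e6,
) -> pd.DataFrame:
    """Absolute and tungsten-relative neutron doses vs maximum treatment depth."""
    water = get_material("water")
    ymodel = neutron.load_yield_model()
    rows = []
    for depth in max_depths_mm:
        energy = materials.energy_from_range(water, depth)
        energy = min(energy, 230.0)
        for name in material_names:
            mat = get_material(name)
            dose = neutron.neutron_dose(mat, energy, n_protons, ymodel)
            rel = neutron.relative_neutron_dose(mat, get_material("tungsten"),
                                                energy, ymodel)
            rows.append(dict(material=name, max_depth_mm=depth, energy_MeV=energy,
                             block_thickness_mm=materials.min_stopping_thickness(mat, energy),
                             neutron_dose_Gy=dose, relative_to_tungsten_pct=rel))
    return pd.DataFrame(rows)


def build_transmission_lookup(
    material: str,
    radius_mm: float,
    spec: SweepSpec,
    energies: np.ndarray | None = None,
    asd_mm: float = 50.0,
    n_histories: int = 50_000,
    model: BeamModel | None = None,
):
    """MC-sampled transmission vs nominal energy, linearly interpolated.

    Used by the plan study; a callable (energy MeV) -> fraction.
    """
    model = model or BeamModel()
    water = get_material("water")
    if energies is None:
        energies = np.linspace(75.0, 145.0, 4)
    small = SweepSpec(n_histories=n_histories, seed=spec.seed, rs_wet_mm=spec.rs_wet_mm,
                      nuclear=spec.nuclear, phantom_shape=spec.phantom_shape)
    ts = []
    for e in energies:
        depth = materials.csda_range(water, e) - spec.rs_wet_mm
        _, _, t = _paired_transmission(material, radius_mm, asd_mm, 0.0, depth, small,
                                       model=model)
        ts.append(t)
    ts = np.asarray(ts)

    def lookup(energy: float) -> float:
        return float(np.interp(energy, energies, ts))

    return lookup


def run_plan_study(
    plans: list[TreatmentField],
    configs: tuple = (("tungsten", 3.0), ("tungsten", 4.0), ("nickel", 3.0), ("nickel", 4.0)),
    spec: SweepSpec | None = None,
    spot_spacing_mm: float = 5.0,
    motor_speed_mm_s: float = 500.0,
    transmission_lookups: dict | None = None,
    model: BeamModel | None = None,
) -> pd.DataFrame:
    """Integral neutron dose and delivery overhead per eligible field and config."""
    spec = spec or SweepSpec()
    ymodel = neutron.load_yield_model()
    eligible = [f for f in plans if neutron.field_eligible(f)]
    rows = []
    for mat_name, radius in configs:
        if transmission_lookups is not None and (mat_name, radius) in transmission_lookups:
            lookup = transmission_lookups[(mat_name, radius)]
        else:
            lookup = build_transmission_lookup(mat_name, radius, spec, model=model)
        mat = get_material(mat_name)
        for f in eligible:
            dose = neutron.integral_neutron_dose(f, mat, lookup,
                                                 rs_wet_mm=spec.rs_wet_mm,
                                                 yield_model=ymodel)
            t_add = additional_time(TimingParams(len(f.spots), spot_spacing_mm,
                                                 motor_speed_mm_s))
            rows.append(dict(field_id=f.field_id, material=mat_name, radius_mm=radius,
                             n_spots=len(f.spots),
                             integral_neutron_dose_Gy=dose, t_add_s=t_add))
    return pd.DataFrame(rows)


def log_run(record: dict, manifest_path) -> None:
    """Append one structured run record (JSON line) to a manifest file."""
    record = dict(record, timestamp=time.time())
    with open(manifest_path, "a") as fh:
        fh.write(json.dumps(record) + "\n")
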