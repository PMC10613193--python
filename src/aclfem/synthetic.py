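"""Synthetic study inputs: geometry configs, lunge profiles, random strain
fields, and the packaged printed outcome tables.

The subject's CT anatomy and dual-fluoroscopy kinematics are not
published, so every pipeline input is generated here.  The synthetic scene
is a sagittal-plane idealization in the fixed tibial CS (x medial-lateral,
y proximal, z anterior, mm):

* tibial tunnel aperture at the origin, tunnel tilted 35 deg anteriorly
  from the vertical in the sagittal plane;
* femoral tunnel aperture 26 mm proximal / 7 mm posterior (native ACL
  span length), the tunnel continuing obliquely 25 deg anterior of the
  span into an idealized 26 mm bone block (2 mm rigid cortical shell);
* the graft runs 20 mm into each tunnel with rounded aperture turns;
* the rounded-rectangle long axis lies medial-laterally (ridge-parallel,
  perpendicular to the sagittal bending plane of the killer turn);
* flexion rotates the femur about a medial-lateral axis through the
  posterior aperture lip (the functional pulley of a near-isometric
  anatomically placed graft), with small coupled anterior translation
  and internal rotation and a bounded near-isometric elongation
  schedule.

The printed outcome tables ship as CSV fixtures, checksum-pinned; they
are the published results of the original study, not pipeline output, and
serve aggregation and trend tests only.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .errors import ValidationError
from .geometry import CrossSection, make_tunnel_family
from .kinematics import LungeParams, LungeProfile, synthesize_lunge_profile
from .meshing import Mesh

__all__ = [
    "FixtureBundle",
    "make_fixture_bundle",
    "random_strain_field",
    "load_table",
    "verify_table_integrity",
    "default_config",
    "MODEL_LABELS",
    "TABLE_CHECKSUMS",
]

MODEL_LABELS = (
    "Circular",
    "Rounded rectangular 1",
    "Rounded rectangular 2",
    "Rounded rectangular 3",
    "Rounded rectangular 4",
)

TABLE_FILES = {
    "graft_stress": "table1_graft_stress.csv",
    "strain_volume": "table2_strain_volume.csv",
}
TABLE_CHECKSUMS = {
    "graft_stress":
        "cbe929e7cb2333d365269927b47a84cf7c8c459fd1f8e5c747b6b056b7abc375",
    "strain_volume":
        "ae90a48659666fbf8ba61e381ab1fce64509a77866e6aea76b7821ccd46ffec6",
}


def _table_bytes(name: str) -> bytes:
    if name not in TABLE_FILES:
        raise ValidationError(f"unknown packaged table {name!r}")
    ref = resources.files("aclfem.data") / TABLE_FILES[name]
    return ref.read_bytes()


def verify_table_integrity(name: str) -> bool:
    """True iff the packaged table matches its pinned SHA-256 digest."""
    return hashlib.sha256(_table_bytes(name)).hexdigest() == \
        TABLE_CHECKSUMS[name]


def load_table(name: str) -> pd.DataFrame:
    """Load a packaged printed table ('graft_stress' MPa or
    'strain_volume' mm^3), indexed by flexion angle; refuses to load a
    fixture that fails its checksum."""
    if not verify_table_integrity(name):
        raise ValidationError(
            f"packaged table {name!r} fails its integrity checksum"
        )
    from io import BytesIO

    df = pd.read_csv(BytesIO(_table_bytes(name)))
    return df.set_index("flexion_angle")


def default_config(scale: float = 0.5, seed: int = 0) -> dict:
    """The study conditions as one structured configuration.

    ``scale`` is the desk-scale mesh-density factor (1.0 = reference
    density); geometry, materials, loads and the lunge schedule do not
    scale.
    """
    if not 0.0 < scale <= 1.0:
        raise ValidationError("scale must lie in (0, 1]")
    c35, s35 = float(np.cos(np.radians(35.0))), float(np.sin(np.radians(35.0)))
    # Sagittal-plane scene: the intra-articular span runs ~27 mm from
    # the tibial footprint up and slightly posterior to the femoral
    # aperture (native ACL length).  The femoral tunnel continues
    # obliquely, tilted 25 deg anterior of the span, so flexion (about
    # the medial-lateral axis) steadily grows the killer-turn bend the
    # free graft carries; all bending is about the medial-lateral ridge
    # axis and the flattened sections present their short axis to it.
    Ef = [0.0, 26.0, -7.0]
    Pt = [0.0, 0.0, 0.0]
    u = np.asarray(Ef) - np.asarray(Pt)
    u /= np.linalg.norm(u)
    a = np.radians(25.0)
    Rx = np.array([[1, 0, 0],
                   [0, np.cos(a), -np.sin(a)],
                   [0, np.sin(a), np.cos(a)]])
    af_v = Rx @ u
    af_v /= np.linalg.norm(af_v)
    af = af_v.tolist()
    # The functional pulley is the posterior aperture lip the graft
    # wraps: the flexion axis passes through it (the knee's flexion axis
    # sits posterior-distal to the ACL femoral footprint), so flexion
    # grows the wrap angle without yanking the tether.  The same point
    # is the femoral reference for the elongation schedule.
    rho_rim = 2.5
    m = u - float(u @ af_v) * af_v
    m /= np.linalg.norm(m)
    pulley = (np.asarray(Ef) + (4.0 + rho_rim) * m
              + rho_rim * af_v)
    center = pulley.tolist()
    return {
        "geometry": {
            "round_diameter": 8.0,
            "L_values": [2.0, 4.0, 6.0, 8.0],
            "embedded_depth": 20.0,
            # 'auto': ridge-parallel, i.e. perpendicular to the sagittal
            # bending plane of the killer turn (the block's AP-ish axis)
            "long_axis_direction": "auto",
        },
        "scene": {
            "tibial_attachment": Pt,
            "femoral_attachment": Ef,
            "tibial_axis": [0.0, -c35, s35],
            "femoral_axis": af,
            "block_extents": [26.0, 26.0, 26.0],
            "cortical_thickness": 2.0,
            "rotation_center": center,
            # elongation schedule is referenced to the pulley point
            "isometry_point": pulley.tolist(),
        },
        "mesh": {
            "graft_size": 1.1,
            "bone_size": 1.4,
            "entrance_refined_size": 1.0,
            "refinement_radius": 6.0,
            "scale_factor": float(scale),
        },
        "materials": {
            "graft": {"C1": 1.95, "D": 0.00683, "squared_invariant": False},
            "bone": {"E": 389.0, "nu": 0.3},
        },
        "interface": {
            "tie_stiffness": 2.0e3,
            "tie_tolerance": 2.5,
            "channel_penalty": 1.0e3,
            "channel_clearance": 0.25,
            # rounding radius of the femoral aperture rim the graft
            # wraps over; identical for every tunnel shape
            "aperture_edge_radius": rho_rim,
        },
        "lunge": {
            "angles": [0.0, 30.0, 60.0, 90.0],
            "ap_translation_per_deg": 0.02,
            "ir_rotation_per_deg": 0.03,
            # an anatomically placed graft is near-isometric over the
            # lunge: small elongation in early flexion, mild slackening
            # in mid flexion, partial re-tightening in deep flexion
            "span_strain_targets": [0.0, 0.01, -0.005, 0.005],
            "distraction_bounds": [-0.2, 0.05],
            "jitter": 0.0,
        },
        "loading": {"pretension_N": 50.0},
        "window_microstrain": [1000.0, 3000.0],
        "seed": int(seed),
    }


def lunge_params_from_config(cfg: dict) -> LungeParams:
    sc, lg = cfg["scene"], cfg["lunge"]
    return LungeParams(
        angles=tuple(lg["angles"]),
        flexion_axis=(1.0, 0.0, 0.0),
        rotation_center=tuple(sc["rotation_center"]),
        ap_translation_per_deg=lg["ap_translation_per_deg"],
        ir_rotation_per_deg=lg["ir_rotation_per_deg"],
        femoral_attachment=tuple(
            sc.get("isometry_point", sc["femoral_attachment"])
        ),
        tibial_attachment=tuple(sc["tibial_attachment"]),
        span_strain_targets=tuple(lg["span_strain_targets"]),
        distraction_bounds=tuple(lg["distraction_bounds"]),
        jitter=lg["jitter"],
    )


@dataclass
class FixtureBundle:
    """Everything the pipeline and tests consume, regenerable from
    (scale, seed)."""

    scale: float
    seed: int
    sections: list               # 5-member constant-area tunnel family
    lunge_params: LungeParams
    profile: LungeProfile
    table_graft_stress: pd.DataFrame
    table_strain_volume: pd.DataFrame
    config: dict


def make_fixture_bundle(scale: float = 0.5, seed: int = 0) -> FixtureBundle:
    """Deterministic bundle of study inputs at a desk mesh scale."""
    cfg = default_config(scale, seed)
    g = cfg["geometry"]
    sections = make_tunnel_family(g["round_diameter"], g["L_values"])
    params = lunge_params_from_config(cfg)
    profile = synthesize_lunge_profile(params, seed)
    return FixtureBundle(
        scale=scale,
        seed=seed,
        sections=sections,
        lunge_params=params,
        profile=profile,
        table_graft_stress=load_table("graft_stress"),
        table_strain_volume=load_table("strain_volume"),
        config=cfg,
    )


def random_strain_field(mesh_or_n, low: float = 0.0, high: float = 5000.0,
                        seed: int = 0) -> np.ndarray:
    """Seeded uniform per-element equivalent strains (microstrain), oracle
    fodder for the strain-window volume statistic."""
    if not (np.isfinite(low) and np.isfinite(high)) or low < 0 or high < low:
        raise ValidationError("need 0 <= low <= high, finite")
    n = mesh_or_n.n_elements if isinstance(mesh_or_n, Mesh) else int(mesh_or_n)
    rng = np.random.default_rng(seed)
    return rng.uniform(low, high, size=n)
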