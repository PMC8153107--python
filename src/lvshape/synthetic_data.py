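"""Synthetic LV populations with linked clinical cohorts.

The left ventricle is idealised as a capped prolate half-ellipsoid shell:
the endocardium has semi-axes (a, a, c) with the long axis c running from
apex to base, truncated by a basal plane through the ellipsoid centre that
may be tilted (emulating valve-plane orientation) and capped flat so the
mesh is closed; the epicardium is the same shape offset outward by the wall
thickness.  Because the basal plane passes through the centre of a centrally
symmetric ellipsoid, the cavity volume is exactly (2/3) pi a^2 c at any tilt,
which gives every generated subject an analytic ground-truth volume.

Population variation is drawn on four interpretable axes — cavity sphericity
s = a/c (designed to dominate), overall size, wall thickness and basal tilt —
plus a nuisance rigid pose, so that an alignment + PCA pipeline should
recover sphericity as the leading shape mode and report variance fractions
matching the designed amplitude ratios.  The linked cohort generator ties
functional variables (EDV from the analytic cavity volume, ESV through a
drawn ejection fraction) and a binary adverse-event label (a logistic model
on standardised shape parameters) to the same geometry.

Default means are anchored to published clinical ranges for this population
(cavity volume near 76 mL, age near 60 y); variation SDs are generator
calibration choices documented in the methods note.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.spatial.transform import Rotation

from .alignment import LandmarkSet, SimilarityTransform
from .exceptions import ValidationError
from .geometry_io import SurfaceMesh


@dataclass
class LVParams:
    """Geometry of one idealised LV shell (mm / degrees)."""

    short_semi_axis: float = 25.0   # a, cavity radius at the base
    long_semi_axis: float = 58.0    # c, apex-to-base cavity length
    wall_thickness: float = 10.0    # t, endo->epi offset
    basal_tilt: float = 0.0         # degrees, tilt of the truncation plane
    pose: SimilarityTransform | None = None

    def validate(self) -> None:
        if min(self.short_semi_axis, self.long_semi_axis,
               self.wall_thickness) <= 0:
            raise ValidationError("semi-axes and wall thickness must be positive")
        if self.wall_thickness >= self.short_semi_axis:
            raise ValidationError("wall thickness must be below the short semi-axis")
        if abs(self.basal_tilt) >= 30.0:
            raise ValidationError("basal tilt must be below 30 degrees")

    @property
    def sphericity(self) -> float:
        """Short-to-long axis ratio a/c; 1 = hemisphere."""
        return self.short_semi_axis / self.long_semi_axis

    def cavity_volume_mm3(self) -> float:
        """Exact cavity volume (2/3) pi a^2 c; tilt-invariant because the
        basal plane passes through the ellipsoid centre."""
        return (2.0 / 3.0) * np.pi * self.short_semi_axis ** 2 \
            * self.long_semi_axis

    def cavity_volume_ml(self) -> float:
        return self.cavity_volume_mm3() / 1000.0


def _capped_half_ellipsoid(a: float, c: float, tilt_rad: float,
                           n_circ: int, n_long: int,
                           label: str) -> SurfaceMesh:
    """Closed, outward-oriented mesh of a half ellipsoid below a (possibly
    tilted) plane through its centre, with a flat basal cap."""
    phi = 2.0 * np.pi * np.arange(n_circ) / n_circ
    if abs(tilt_rad) < 1e-12:
        theta_rim = np.full(n_circ, np.pi / 2.0)
    else:
        # rim where the ellipsoid meets the plane with normal
        # (sin tilt, 0, cos tilt) through the origin
        theta_rim = np.arctan2(c * np.cos(tilt_rad),
                               a * np.cos(phi) * np.sin(tilt_rad))

    verts = [np.array([0.0, 0.0, -c])]  # apex
    for i in range(1, n_long + 1):
        theta = (i / n_long) * theta_rim
        ring = np.column_stack([
            a * np.sin(theta) * np.cos(phi),
            a * np.sin(theta) * np.sin(phi),
            -c * np.cos(theta),
        ])
        verts.extend(ring)
    vertices = np.vstack(verts)
    rim_start = 1 + (n_long - 1) * n_circ
    rim = vertices[rim_start:rim_start + n_circ]
    centroid_idx = len(vertices)
    vertices = np.vstack([vertices, rim.mean(axis=0)])

    faces = []
    nxt = (np.arange(n_circ) + 1) % n_circ
    ring0 = 1 + np.arange(n_circ)
    for j in range(n_circ):  # apex fan
        faces.append((0, ring0[j], ring0[nxt[j]]))
    for i in range(n_long - 1):  # lateral quads
        lo = 1 + i * n_circ + np.arange(n_circ)
        hi = lo + n_circ
        for j in range(n_circ):
            faces.append((lo[j], hi[j], hi[nxt[j]]))
            faces.append((lo[j], hi[nxt[j]], lo[nxt[j]]))
    rim_idx = rim_start + np.arange(n_circ)
    for j in range(n_circ):  # flat basal cap
        faces.append((rim_idx[j], centroid_idx, rim_idx[nxt[j]]))
    faces = np.asarray(faces, np.int64)

    mesh = SurfaceMesh(vertices, faces, label=label)
    tri = mesh.triangles()
    signed = np.einsum("ij,ij->i", tri[:, 0],
                       np.cross(tri[:, 1], tri[:, 2])).sum() / 6.0
    if signed < 0:  # enforce outward orientation
        mesh = SurfaceMesh(vertices, faces[:, [0, 2, 1]], label=label)
    return mesh


def make_lv_mesh(params: LVParams, resolution: int = 64,
                 label_prefix: str = "lv") -> tuple[SurfaceMesh, SurfaceMesh]:
    """Build the (endocardium, epicardium) shell pair for one subject.

    ``resolution`` is the number of circumferential divisions (longitudinal
    rings are half that); the epicardium uses semi-axes enlarged by the wall
    thickness.  The rigid pose nuisance, if any, is applied last to both
    surfaces.
    """
    params.validate()
    if resolution < 8:
        raise ValueError("resolution must be at least 8 circumferential divisions")
    n_long = max(8, resolution // 2)
    tilt = np.deg2rad(params.basal_tilt)
    endo = _capped_half_ellipsoid(params.short_semi_axis,
                                  params.long_semi_axis, tilt,
                                  resolution, n_long, f"{label_prefix}_endo")
    t = params.wall_thickness
    epi = _capped_half_ellipsoid(params.short_semi_axis + t,
                                 params.long_semi_axis + t, tilt,
                                 resolution, n_long, f"{label_prefix}_epi")
    if params.pose is not None:
        endo = endo.transformed(params.pose.rotation, params.pose.translation,
                                params.pose.scale)
        epi = epi.transformed(params.pose.rotation, params.pose.translation,
                              params.pose.scale)
    return endo, epi


@dataclass
class PopulationSpec:
    """Study-condition description of a synthetic LV population."""

    n_subjects: int = 30
    mean_params: LVParams = field(default_factory=LVParams)
    sd_sphericity: float = 0.05     # SD of s = a/c (mean ~0.43)
    sd_size: float = 0.04           # fractional SD of the global size factor
    sd_thickness: float = 1.2       # mm
    sd_tilt: float = 4.0            # degrees
    pose_rotation_deg: float = 20.0  # max nuisance rotation angle
    pose_translation_mm: float = 10.0
    mesh_resolution: int = 48
    sphericity_mode: str = "constant_long_axis"  # or "constant_volume"
    phases: tuple[str, ...] = ("ED", "ES")
    ef_mean: float = 63.6           # %, used to derive the ES geometry
    ef_sd: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 3:
            raise ValueError("a population needs at least 3 subjects")
        for sd in (self.sd_sphericity, self.sd_size, self.sd_thickness,
                   self.sd_tilt):
            if sd < 0:
                raise ValueError("SDs must be non-negative")
        if self.sphericity_mode not in ("constant_long_axis", "constant_volume"):
            raise ValueError("unknown sphericity_mode")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["mean_params"].pop("pose")
        d["phases"] = list(self.phases)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PopulationSpec":
        d = dict(d)
        d["mean_params"] = LVParams(**d["mean_params"])
        d["phases"] = tuple(d.get("phases", ("ED", "ES")))
        return cls(**d)


@dataclass
class CohortSpec:
    """Statistical link from generated geometry to the clinical table."""

    edv_noise_ml: float = 3.0
    ef_mean: float = 63.6
    ef_sd: float = 8.0
    age_mean: float = 60.14
    age_sd: float = 10.11
    bsa_mean: float = 2.0
    bsa_sd: float = 0.2
    heart_rate_mean: float = 73.0
    heart_rate_sd: float = 12.0
    systolic_mean: float = 133.0
    systolic_sd: float = 11.0
    diastolic_mean: float = 77.0
    diastolic_sd: float = 8.5
    event_intercept: float = 0.0
    #: logit-scale coefficients on *standardised* truth-table columns
    event_coefficients: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        for sd in (self.edv_noise_ml, self.ef_sd, self.age_sd, self.bsa_sd,
                   self.heart_rate_sd, self.systolic_sd, self.diastolic_sd):
            if sd < 0:
                raise ValueError("noise SDs must be non-negative")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        return cls(**d)


def save_spec(spec, path: str | Path) -> Path:
    """Round-trip a PopulationSpec/CohortSpec through YAML (or JSON)."""
    path = Path(path)
    payload = {"kind": type(spec).__name__, "spec": spec.to_dict()}
    if path.suffix == ".json":
        path.write_text(json.dumps(payload, indent=2))
    else:
        path.write_text(yaml.safe_dump(payload, sort_keys=False))
    return path


def load_spec(path: str | Path):
    path = Path(path)
    text = path.read_text()
    payload = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    cls = {"PopulationSpec": PopulationSpec, "CohortSpec": CohortSpec}[payload["kind"]]
    return cls.from_dict(payload["spec"])


@dataclass
class PopulationSample:
    truth: pd.DataFrame
    meshes: dict  # (subject_id, phase) -> (endo, epi)

    def endo_meshes(self, phase: str = "ED") -> list[SurfaceMesh]:
        sids = self.truth["subject_id"].tolist()
        return [self.meshes[(sid, phase)][0] for sid in sids]

    def subject_ids(self) -> list[str]:
        return self.truth["subject_id"].tolist()


def _draw_params(spec: PopulationSpec, rng: np.random.Generator,
                 ) -> tuple[LVParams, dict]:
    """One truncated-Gaussian parameter draw (without pose)."""
    base = spec.mean_params
    s0 = base.sphericity
    for attempt in range(200):
        s = rng.normal(s0, spec.sd_sphericity)
        g = rng.normal(1.0, spec.sd_size)
        t = rng.normal(base.wall_thickness, spec.sd_thickness)
        tilt = rng.normal(base.basal_tilt, spec.sd_tilt)
        if spec.sphericity_mode == "constant_long_axis":
            c = base.long_semi_axis * g
            a = s * c
        else:  # constant cavity volume at the size factor
            k = base.short_semi_axis ** 2 * base.long_semi_axis * g ** 3
            c = (k / s ** 2) ** (1.0 / 3.0)
            a = s * c
        params = LVParams(a, c, t, tilt)
        try:
            params.validate()
        except ValidationError:
            continue
        return params, {"rejected_draws": attempt, "size_factor": g}
    raise ValidationError("could not draw valid LV parameters in 200 attempts")


def _random_pose(spec: PopulationSpec,
                 rng: np.random.Generator) -> SimilarityTransform:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.deg2rad(rng.uniform(0.0, spec.pose_rotation_deg))
    R = Rotation.from_rotvec(angle * axis).as_matrix()
    t = rng.uniform(-spec.pose_translation_mm, spec.pose_translation_mm, size=3)
    return SimilarityTransform(1.0, R, t)


def sample_population(spec: PopulationSpec) -> PopulationSample:
    """Draw a population of LV shells and its ground-truth table.

    Parameters are independent truncated Gaussians around the spec means;
    each subject gets a random rigid pose nuisance shared by its phases.
    The ES geometry shrinks the short semi-axis at constant long axis so the
    analytic ES cavity volume equals EDV x (1 - EF/100) for the subject's
    drawn ejection fraction.  Per-subject RNG streams make the draw
    bit-reproducible and independent of subject ordering.
    """
    rows = []
    meshes: dict = {}
    total_rejected = 0
    for i in range(spec.n_subjects):
        rng = np.random.default_rng([spec.seed, i])
        params, info = _draw_params(spec, rng)
        total_rejected += info["rejected_draws"]
        pose = _random_pose(spec, rng) if (
            spec.pose_rotation_deg > 0 or spec.pose_translation_mm > 0
        ) else None
        ef = float(np.clip(rng.normal(spec.ef_mean, spec.ef_sd), 25.0, 85.0))
        sid = f"s{i:03d}"

        params_ed = LVParams(params.short_semi_axis, params.long_semi_axis,
                             params.wall_thickness, params.basal_tilt, pose)
        # shrink the short semi-axis at constant long axis so the analytic
        # ES cavity volume is exactly EDV x (1 - EF/100); the ES wall is
        # thinned if needed to keep the shell parameterization valid
        a_es = params.short_semi_axis * np.sqrt(1.0 - ef / 100.0)
        t_es = min(params.wall_thickness, 0.8 * a_es)
        params_es = LVParams(a_es, params.long_semi_axis,
                             t_es, params.basal_tilt, pose)

        if "ED" in spec.phases:
            meshes[(sid, "ED")] = make_lv_mesh(params_ed, spec.mesh_resolution,
                                               label_prefix=sid)
        if "ES" in spec.phases:
            meshes[(sid, "ES")] = make_lv_mesh(params_es, spec.mesh_resolution,
                                               label_prefix=sid)
        rotvec = (Rotation.from_matrix(pose.rotation).as_rotvec()
                  if pose is not None else np.zeros(3))
        rows.append({
            "subject_id": sid,
            "a_ed": params.short_semi_axis,
            "c": params.long_semi_axis,
            "thickness": params.wall_thickness,
            "tilt_deg": params.basal_tilt,
            "sphericity": params.sphericity,
            "size_factor": info["size_factor"],
            "ef_true": ef,
            "a_es": a_es,
            "cavity_ed_ml": params_ed.cavity_volume_ml(),
            "cavity_es_ml": params_es.cavity_volume_ml(),
            "pose_rotvec_x": rotvec[0], "pose_rotvec_y": rotvec[1],
            "pose_rotvec_z": rotvec[2],
            "pose_tx": pose.translation[0] if pose is not None else 0.0,
            "pose_ty": pose.translation[1] if pose is not None else 0.0,
            "pose_tz": pose.translation[2] if pose is not None else 0.0,
        })
    if total_rejected > 0.2 * spec.n_subjects:
        warnings.warn(
            f"{total_rejected} draws rejected by validity truncation "
            f"for {spec.n_subjects} subjects (> 20%)", stacklevel=2)
    return PopulationSample(pd.DataFrame(rows), meshes)


def simulate_cohort(truth: pd.DataFrame, spec: CohortSpec) -> pd.DataFrame:
    """Clinical table statistically linked to the generated geometry.

    EDV is the analytic ED cavity volume plus Gaussian measurement noise;
    ESV = EDV x (1 - EF/100) with the subject's true ejection fraction;
    demographics are drawn from the spec distributions; the event label is
    Bernoulli with logit = intercept + sum(coef x standardised shape
    parameter) over ``event_coefficients``.
    """
    rng = np.random.default_rng(spec.seed)
    n = len(truth)
    # standardised shape parameters for the event model
    logit = np.full(n, spec.event_intercept, float)
    for col, coef in spec.event_coefficients.items():
        x = truth[col].to_numpy(float)
        sd = x.std(ddof=1)
        z = (x - x.mean()) / sd if sd > 0 else np.zeros(n)
        logit = logit + coef * z
    p_event = 1.0 / (1.0 + np.exp(-logit))

    rows = []
    for i, (_, t) in enumerate(truth.iterrows()):
        ef = float(t["ef_true"]) if "ef_true" in t else float(
            np.clip(rng.normal(spec.ef_mean, spec.ef_sd), 25.0, 85.0))
        edv = esv = None
        for _ in range(100):
            cand = t["cavity_ed_ml"] + rng.normal(0.0, spec.edv_noise_ml)
            cand_esv = cand * (1.0 - ef / 100.0)
            if cand > cand_esv > 0:
                edv, esv = cand, cand_esv
                break
        if edv is None:
            raise ValidationError(
                f"could not draw EDV > ESV for subject {t['subject_id']}")
        sp = rng.normal(spec.systolic_mean, spec.systolic_sd)
        dp = rng.normal(spec.diastolic_mean, spec.diastolic_sd)
        dp = min(dp, sp - 10.0)
        rows.append({
            "subject_id": t["subject_id"],
            "age": float(np.clip(rng.normal(spec.age_mean, spec.age_sd),
                                 18.0, 95.0)),
            "sex": "M" if rng.random() < 0.5 else "F",
            "bsa": float(np.clip(rng.normal(spec.bsa_mean, spec.bsa_sd),
                                 1.2, 2.8)),
            "heart_rate": float(np.clip(
                rng.normal(spec.heart_rate_mean, spec.heart_rate_sd),
                40.0, 130.0)),
            "systolic_pressure": float(max(sp, 90.0)),
            "diastolic_pressure": float(max(dp, 40.0)),
            "edv": float(edv),
            "esv": float(esv),
            "event": int(rng.random() < p_event[i]),
            "group": "none",
        })
    return pd.DataFrame(rows)


def orthogonal_field_population(base_points: np.ndarray, sds: list[float],
                                n_subjects: int, seed: int = 0,
                                phase: str = "ED",
                                ) -> tuple[list[LandmarkSet], np.ndarray]:
    """Landmark population varying along orthonormal displacement fields.

    ``sds`` are the per-field amplitude standard deviations (mm); the
    population's designed variance fractions are sd_i^2 / sum(sd^2).  Returns
    the subjects and the (3m x q) field matrix so PCA recovery of a known
    variance structure (fractions and eigenvector directions) can be checked.
    """
    base = np.asarray(base_points, float).reshape(-1)
    rng = np.random.default_rng(seed)
    q = len(sds)
    fields = rng.normal(size=(len(base), q))
    fields, _ = np.linalg.qr(fields)  # orthonormal columns
    amps = rng.normal(size=(n_subjects, q)) * np.asarray(sds, float)
    out = []
    for i in range(n_subjects):
        vec = base + fields @ amps[i]
        out.append(LandmarkSet(vec.reshape(-1, 3),
                               subject_id=f"s{i:03d}", phase=phase))
    return out, fields
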