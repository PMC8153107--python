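"""Rigid/similarity registration and iterative mean-template construction.

The registration primitive is the closed-form least-squares similarity fit
(Umeyama), used both directly on corresponded landmark sets and inside an
iterative-closest-point (ICP) loop for unmatched point clouds.  Template
construction alternates alignment of every subject to the current mean shape
with point-wise averaging until the mean stops moving.

Correspondence across subjects is established by nearest neighbours against
the template: for each template point the closest point of the (similarity-
aligned) subject cloud is taken.  The transform actually *applied* to produce
each subject's stored landmark set is rigid only (rotation + translation), so
that natural size variation between ventricles is retained in the shape
matrix — heart size is itself a clinical indicator.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .exceptions import DegenerateGeometryError
from .geometry_io import PointCloud, SurfaceMesh


@dataclass
class SimilarityTransform:
    """x -> scale * rotation @ x + translation (mm)."""

    scale: float
    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, float)
        self.translation = np.asarray(self.translation, float)
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if not np.allclose(self.rotation.T @ self.rotation, np.eye(3), atol=1e-9):
            raise ValueError("rotation must be orthogonal")
        if not np.isclose(np.linalg.det(self.rotation), 1.0, atol=1e-9):
            raise ValueError("rotation must be proper (det = +1)")

    @classmethod
    def identity(cls) -> "SimilarityTransform":
        return cls(1.0, np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return self.scale * np.asarray(points, float) @ self.rotation.T + self.translation

    def rigid_part(self) -> "SimilarityTransform":
        """Same rotation and translation with scale discarded."""
        return SimilarityTransform(1.0, self.rotation, self.translation)


@dataclass
class LandmarkSet:
    """Ordered m x 3 point set in template-frame correspondence.

    Row i of every subject's landmark set refers to the same anatomic
    location (template point i).
    """

    points: np.ndarray
    subject_id: str = ""
    phase: str = "ED"

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("landmark points must be an (m, 3) array")
        if self.phase not in ("ED", "ES"):
            raise ValueError("phase must be 'ED' or 'ES'")

    @property
    def m(self) -> int:
        return len(self.points)

    def as_vector(self) -> np.ndarray:
        """Flattened 3m coordinate vector (x1, y1, z1, x2, ...)."""
        return self.points.reshape(-1)


@dataclass
class AlignmentReport:
    iterations: int
    rms_history: list[float] = field(default_factory=list)
    converged: bool = True


def _as_points(cloud) -> np.ndarray:
    if isinstance(cloud, PointCloud):
        return cloud.points
    if isinstance(cloud, LandmarkSet):
        return cloud.points
    return np.asarray(cloud, float)


def fit_similarity(source_points, target_points,
                   with_scale: bool = True) -> SimilarityTransform:
    """Closed-form least-squares similarity (or rigid) transform.

    Finds the scale, rotation and translation minimising
    ``sum_i || s R x_i + t - y_i ||^2`` over corresponding rows.  Reflections
    are excluded by sign-correcting the smallest singular direction, so the
    returned rotation always has determinant +1.
    """
    X = _as_points(source_points)
    Y = _as_points(target_points)
    if X.shape != Y.shape:
        raise ValueError(f"point sets differ in shape: {X.shape} vs {Y.shape}")
    m = len(X)
    if m < 3:
        raise ValueError("at least 3 corresponding points are required")
    mu_x = X.mean(axis=0)
    mu_y = Y.mean(axis=0)
    Xc = X - mu_x
    Yc = Y - mu_y
    sv = np.linalg.svd(Xc, compute_uv=False)
    if sv[1] <= 1e-10 * max(sv[0], 1e-300):
        raise DegenerateGeometryError(
            "source configuration is rank-deficient (collinear or coincident)"
        )
    cov = Yc.T @ Xc / m
    U, D, Vt = np.linalg.svd(cov)
    S = np.eye(3)
    if np.linalg.det(U) * np.linalg.det(Vt) < 0:
        S[2, 2] = -1.0
    R = U @ S @ Vt
    if with_scale:
        var_x = (Xc ** 2).sum() / m
        scale = float(np.trace(np.diag(D) @ S) / var_x)
    else:
        scale = 1.0
    t = mu_y - scale * R @ mu_x
    return SimilarityTransform(scale, R, t)


def registration_rms(source_points, target_points,
                     transform: SimilarityTransform) -> float:
    """Root-mean-square residual of a transform over corresponded rows."""
    diff = transform.apply(_as_points(source_points)) - _as_points(target_points)
    return float(np.sqrt((diff ** 2).sum(axis=1).mean()))


def icp_align(source_cloud, target_cloud, with_scale: bool = True,
              max_iter: int = 50, tol: float = 1e-5,
              ) -> tuple[SimilarityTransform, AlignmentReport]:
    """Iterative closest point: alternate nearest-neighbour matching
    (source -> target) with the closed-form similarity fit.

    Stops when the matched RMS changes by less than ``tol`` (mm) or after
    ``max_iter`` iterations.  The matched-RMS history is non-increasing.
    """
    X = _as_points(source_cloud)
    Y = _as_points(target_cloud)
    if len(X) < 4 or len(Y) < 4:
        raise ValueError("both clouds need at least 4 points")
    tree = cKDTree(Y)
    # initialise by centroid translation and radius-of-gyration scale: a
    # cold identity start can collapse the similarity fit (scale -> 0) when
    # the clouds are far apart, because all points match one corner of the
    # target
    mu_x, mu_y = X.mean(axis=0), Y.mean(axis=0)
    if with_scale:
        rg_x = np.sqrt(((X - mu_x) ** 2).sum(axis=1).mean())
        rg_y = np.sqrt(((Y - mu_y) ** 2).sum(axis=1).mean())
        s0 = rg_y / rg_x if rg_x > 0 else 1.0
    else:
        s0 = 1.0
    transform = SimilarityTransform(s0, np.eye(3), mu_y - s0 * mu_x)
    rms_history: list[float] = []
    converged = False
    for _ in range(max_iter):
        _, idx = tree.query(transform.apply(X), k=1)
        transform = fit_similarity(X, Y[idx], with_scale=with_scale)
        rms = registration_rms(X, Y[idx], transform)
        rms_history.append(rms)
        if len(rms_history) >= 2 and abs(rms_history[-2] - rms) < tol:
            converged = True
            break
    return transform, AlignmentReport(len(rms_history), rms_history, converged)


def _match_indices(template_points: np.ndarray, shape_points: np.ndarray,
                   ) -> np.ndarray:
    """Index into ``shape_points`` of the nearest neighbour of each template
    point.  cKDTree resolves exact ties to the lowest index, keeping the
    matching deterministic."""
    tree = cKDTree(shape_points)
    _, idx = tree.query(template_points, k=1)
    return idx


def correspond_to_template(template_points, shape_cloud) -> LandmarkSet:
    """Resample a shape into template correspondence.

    For each template point the nearest point of ``shape_cloud`` is taken
    (the nearest point *on the surface* when a :class:`SurfaceMesh` is
    supplied).  The shape must already be aligned to the template frame.
    """
    T = _as_points(template_points)
    subject_id = getattr(shape_cloud, "source_label", "") or ""
    if isinstance(shape_cloud, SurfaceMesh):
        import trimesh

        tm = trimesh.Trimesh(vertices=shape_cloud.vertices,
                             faces=shape_cloud.faces, process=False)
        matched, _, _ = trimesh.proximity.closest_point_naive(tm, T)
        matched = np.asarray(matched, float)
        subject_id = shape_cloud.label
    else:
        S = _as_points(shape_cloud)
        if len(S) == 0:
            raise ValueError("shape cloud is empty")
        matched = S[_match_indices(T, S)]
    return LandmarkSet(matched, subject_id=subject_id)


def _medoid_index(point_sets: list[np.ndarray], subsample: int = 120,
                  seed: int = 0) -> int:
    """Medoid shape: minimum summed pairwise post-rigid-alignment RMS.

    Pairwise distances are computed on deterministically subsampled clouds to
    keep the O(N^2) scan tractable for populations of ~100 subjects.
    """
    rng = np.random.default_rng(seed)
    subs = []
    for pts in point_sets:
        if len(pts) > subsample:
            idx = rng.choice(len(pts), size=subsample, replace=False)
            idx.sort()
            subs.append(pts[idx])
        else:
            subs.append(pts)
    n = len(subs)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            _, rep = icp_align(subs[i], subs[j], with_scale=False,
                               max_iter=15, tol=1e-4)
            d = rep.rms_history[-1]
            dist[i, j] = dist[j, i] = d
    return int(np.argmin(dist.sum(axis=1)))


def _align_one(points: np.ndarray, template: np.ndarray, with_scale: bool,
               icp_subsample: int = 2000) -> np.ndarray:
    """Correspond one raw cloud to the template and return its rigid-aligned
    landmark rows (native size retained).

    The pose is estimated by ICP on a deterministic subsample of the source
    cloud (the estimate is already dense at ~2000 points); the final
    correspondence uses the full cloud.
    """
    src = points
    if len(points) > icp_subsample:
        step = len(points) / icp_subsample
        src = points[(np.arange(icp_subsample) * step).astype(int)]
    transform, _ = icp_align(src, template, with_scale=with_scale)
    aligned = transform.apply(points)
    idx = _match_indices(template, aligned)
    native = points[idx]  # corresponded rows in the subject's own frame
    rigid = fit_similarity(native, template, with_scale=False)
    return rigid.apply(native)


def build_mean_template(shapes, reference_index: int | None = None,
                        with_scale_registration: bool = True,
                        max_rounds: int = 20, tol: float | None = None,
                        subject_ids: list[str] | None = None,
                        phase: str = "ED",
                        ) -> tuple[LandmarkSet, list[LandmarkSet], AlignmentReport]:
    """Iterative mean-template construction over a shape population.

    Round 0 aligns every shape to a reference (the medoid by default) and
    averages the corresponded landmarks point-wise; each subsequent round
    re-aligns all shapes to the current mean and re-averages, stopping when
    the mean shape moves by less than ``tol`` (RMS, mm) or at ``max_rounds``.

    Registration uses full similarity by default for matching quality, but
    the stored landmark sets are produced by the rigid part only, so subject
    size is retained.  Default ``tol`` is 1e-3 x the mean centroid size of
    the input shapes.
    """
    point_sets = [_as_points(s) for s in shapes]
    n = len(point_sets)
    if n < 2:
        raise ValueError("at least 2 shapes are required")
    if subject_ids is None:
        subject_ids = [
            getattr(s, "source_label", "") or f"subject_{i:03d}"
            for i, s in enumerate(shapes)
        ]
    if tol is None:
        sizes = [
            np.sqrt(((p - p.mean(axis=0)) ** 2).sum(axis=1).mean())
            for p in point_sets
        ]
        tol = 1e-3 * float(np.mean(sizes))
    if reference_index is None:
        reference_index = _medoid_index(point_sets)
    if not 0 <= reference_index < n:
        raise ValueError(f"reference_index {reference_index} out of range")

    template = point_sets[reference_index].copy()
    rms_history: list[float] = []
    converged = False
    aligned_pts: list[np.ndarray] = []
    for _ in range(max_rounds):
        aligned_pts = [
            _align_one(p, template, with_scale_registration) for p in point_sets
        ]
        new_template = np.mean(aligned_pts, axis=0)
        change = float(np.sqrt(((new_template - template) ** 2)
                               .sum(axis=1).mean()))
        rms_history.append(change)
        template = new_template
        if change < tol:
            converged = True
            break
        # correspondence re-jitter makes the mean-shape change plateau at a
        # small positive level; once it stops shrinking, further rounds only
        # re-shuffle matches, so stop and report non-convergence
        if len(rms_history) >= 3 and change > 0.9 * rms_history[-2]:
            break
    if not converged:
        warnings.warn(
            f"mean template did not converge in {len(rms_history)} rounds "
            f"(last RMS change {rms_history[-1]:.4g} mm, tol {tol:.4g})",
            stacklevel=2,
        )
    aligned = [
        LandmarkSet(p, subject_id=sid, phase=phase)
        for p, sid in zip(aligned_pts, subject_ids)
    ]
    report = AlignmentReport(len(rms_history), rms_history, converged)
    return LandmarkSet(template, subject_id="template", phase=phase), aligned, report


# ---------------------------------------------------------------------------
# serialization

def landmarks_to_csv(landmark_sets: list[LandmarkSet], path: str | Path) -> Path:
    """Write landmark sets as tidy CSV
    (subject_id, phase, point_index, x, y, z)."""
    frames = []
    for ls in landmark_sets:
        frames.append(pd.DataFrame({
            "subject_id": ls.subject_id,
            "phase": ls.phase,
            "point_index": np.arange(ls.m),
            "x": ls.points[:, 0],
            "y": ls.points[:, 1],
            "z": ls.points[:, 2],
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    return Path(path)


def landmarks_from_csv(path: str | Path) -> list[LandmarkSet]:
    df = pd.read_csv(path)
    out = []
    for (sid, phase), grp in df.groupby(["subject_id", "phase"], sort=False):
        grp = grp.sort_values("point_index")
        out.append(LandmarkSet(grp[["x", "y", "z"]].to_numpy(),
                               subject_id=str(sid), phase=str(phase)))
    return out


def save_landmark_matrix(landmark_sets: list[LandmarkSet], path: str | Path,
                         template: LandmarkSet | None = None) -> Path:
    """Subjects x 3m matrix container (.npz) with a JSON sidecar listing the
    subject order and template provenance."""
    path = Path(path)
    mat = np.vstack([ls.as_vector() for ls in landmark_sets])
    arrays = {"landmarks": mat}
    if template is not None:
        arrays["template"] = template.as_vector()
    np.savez(path, **arrays)
    sidecar = {
        "subjects": [ls.subject_id for ls in landmark_sets],
        "phase": landmark_sets[0].phase if landmark_sets else None,
        "m": landmark_sets[0].m if landmark_sets else 0,
        "has_template": template is not None,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return path
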