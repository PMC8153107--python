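"""Surface-mesh I/O, area-uniform sampling and enclosed-volume computation.

Meshes are triangulated anatomical surfaces (left-ventricular endocardium or
epicardium) with vertex coordinates in millimetres.  File handling is backed
by :mod:`trimesh` (STL ascii/binary, PLY ascii, OBJ); sampling and signed
volume are implemented here because the pipeline depends on their exact
determinism and error semantics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

from .exceptions import FormatError, GeometryError

SUPPORTED_FORMATS = ("stl", "ply", "obj")

#: default sampling resolution (Cartesian points per surface)
DEFAULT_N_POINTS = 15_000

MANIFEST_COLUMNS = ("subject_id", "phase", "surface", "mesh_path")


@dataclass
class SurfaceMesh:
    """Triangulated 3D surface.

    Parameters
    ----------
    vertices : (n, 3) float array
        Vertex coordinates in mm.
    faces : (k, 3) int array
        Triangles as ordered vertex-index triples.
    label : str
        Free-text identifier, e.g. ``"endo_ED"``.
    """

    vertices: np.ndarray
    faces: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise GeometryError("vertices must be an (n, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise GeometryError("faces must be a (k, 3) array of triangles")
        if len(self.faces) and (
            self.faces.min() < 0 or self.faces.max() >= len(self.vertices)
        ):
            raise GeometryError("face indices out of vertex range")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def triangles(self) -> np.ndarray:
        """(k, 3, 3) array of face corner coordinates."""
        return self.vertices[self.faces]

    def face_areas(self) -> np.ndarray:
        tri = self.triangles()
        cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        return 0.5 * np.linalg.norm(cross, axis=1)

    def boundary_edge_count(self) -> int:
        """Number of undirected edges not shared by exactly two faces."""
        edges = np.vstack(
            [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
        )
        edges = np.sort(edges, axis=1)
        _, counts = np.unique(edges, axis=0, return_counts=True)
        return int(np.sum(counts != 2))

    def is_closed(self) -> bool:
        return self.n_faces > 0 and self.boundary_edge_count() == 0

    def transformed(self, rotation: np.ndarray, translation: np.ndarray,
                    scale: float = 1.0, label: str | None = None) -> "SurfaceMesh":
        """Return a copy with ``x -> scale * R x + t`` applied to vertices."""
        v = scale * self.vertices @ np.asarray(rotation, float).T + np.asarray(
            translation, float
        )
        return SurfaceMesh(v, self.faces.copy(),
                           self.label if label is None else label)


@dataclass
class PointCloud:
    """Unordered m x 3 point set sampled from a surface (mm)."""

    points: np.ndarray
    source_label: str = ""
    seed: int = 0

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must be an (m, 3) array")
        if len(self.points) < 4:
            raise ValueError("a point cloud needs at least 4 points")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("point coordinates must be finite")

    def __len__(self) -> int:
        return len(self.points)


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    fmt = fmt.lower()
    if fmt not in SUPPORTED_FORMATS:
        raise FormatError(
            f"unsupported mesh format {fmt!r}; expected one of {SUPPORTED_FORMATS}"
        )
    return fmt


def read_mesh(path: str | Path, format: str | None = None,
              label: str | None = None) -> SurfaceMesh:
    """Read an STL/PLY/OBJ surface into a :class:`SurfaceMesh`.

    Topology is preserved as stored (no vertex merging); polygonal faces in
    OBJ/PLY are fan-triangulated on load.  Raises :class:`FormatError` for
    unknown formats or unparseable files.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    try:
        # STL stores three vertices per facet with no shared topology, so
        # coincident vertices must be merged to recover a closed surface;
        # PLY/OBJ topology is preserved exactly as stored
        mesh = trimesh.load(str(path), file_type=fmt,
                            process=(fmt == "stl"), force="mesh")
    except Exception as exc:  # trimesh raises many concrete types
        raise FormatError(f"could not parse {path} as {fmt}: {exc}") from exc
    if not isinstance(mesh, trimesh.Trimesh) or len(mesh.faces) == 0:
        raise FormatError(f"{path} did not contain a triangulated surface")
    return SurfaceMesh(
        np.asarray(mesh.vertices, float),
        np.asarray(mesh.faces, np.int64),
        label if label is not None else path.stem,
    )


def write_mesh(mesh: SurfaceMesh, path: str | Path,
               format: str | None = None) -> Path:
    """Write a mesh to STL (binary), PLY (ascii) or OBJ; re-readable by
    :func:`read_mesh` with identical topology."""
    if mesh.n_vertices == 0 or mesh.n_faces == 0:
        raise GeometryError("refusing to write an empty mesh")
    path = Path(path)
    fmt = _infer_format(path, format)
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    try:
        if fmt == "ply":
            data = trimesh.exchange.ply.export_ply(tm, encoding="ascii")
        else:
            data = tm.export(file_type=fmt)
    except Exception as exc:
        raise FormatError(f"could not export mesh as {fmt}: {exc}") from exc
    mode = "wb" if isinstance(data, bytes) else "w"
    with open(path, mode) as fh:
        fh.write(data)
    return path


def sample_surface(mesh: SurfaceMesh, n_points: int = DEFAULT_N_POINTS,
                   seed: int = 0) -> PointCloud:
    """Sample ``n_points`` area-uniformly from a surface.

    Faces are chosen with probability proportional to area and points are
    placed uniformly within each face via barycentric coordinates; the draw
    is bit-reproducible for a given ``seed``.
    """
    if n_points < 4:
        raise ValueError("n_points must be >= 4")
    areas = mesh.face_areas()
    total = areas.sum()
    if not total > 0:
        raise GeometryError("mesh has zero total surface area")
    rng = np.random.default_rng(seed)
    face_idx = rng.choice(mesh.n_faces, size=n_points, p=areas / total)
    tri = mesh.vertices[mesh.faces[face_idx]]
    u = rng.random(n_points)
    v = rng.random(n_points)
    flip = u + v > 1.0
    u[flip] = 1.0 - u[flip]
    v[flip] = 1.0 - v[flip]
    pts = (
        tri[:, 0]
        + u[:, None] * (tri[:, 1] - tri[:, 0])
        + v[:, None] * (tri[:, 2] - tri[:, 0])
    )
    return PointCloud(pts, source_label=mesh.label, seed=seed)


def mesh_volume(mesh: SurfaceMesh) -> float:
    """Enclosed volume of a closed, consistently oriented mesh, in mm^3.

    Computed by the divergence theorem as the sum of signed tetrahedron
    volumes of each face against the origin.  The positive magnitude is
    returned; a warning is emitted when the signed value is negative
    (inward-facing orientation).
    """
    if not mesh.is_closed():
        raise GeometryError(
            f"mesh {mesh.label!r} is not closed "
            f"({mesh.boundary_edge_count()} boundary/non-manifold edges)"
        )
    tri = mesh.triangles()
    signed = np.einsum("ij,ij->i", tri[:, 0], np.cross(tri[:, 1], tri[:, 2]))
    vol = signed.sum() / 6.0
    if vol < 0:
        warnings.warn(
            f"mesh {mesh.label!r} appears inward-oriented (signed volume < 0); "
            "returning magnitude",
            stacklevel=2,
        )
    return abs(float(vol))


def mesh_volume_ml(mesh: SurfaceMesh) -> float:
    """Enclosed volume in millilitres (1 mL = 1000 mm^3)."""
    return mesh_volume(mesh) / 1000.0


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read the cohort mesh manifest CSV.

    Required columns: ``subject_id``, ``phase`` (ED/ES), ``surface``
    (endo/epi), ``mesh_path``.
    """
    df = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest is missing required columns: {missing}")
    bad_phase = set(df["phase"].unique()) - {"ED", "ES"}
    if bad_phase:
        raise ValueError(f"manifest contains unknown phases: {sorted(bad_phase)}")
    bad_surface = set(df["surface"].unique()) - {"endo", "epi"}
    if bad_surface:
        raise ValueError(f"manifest contains unknown surfaces: {sorted(bad_surface)}")
    return df
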