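"""Shared fixtures: small meshes, synthetic populations and numeric oracles."""

from __future__ import annotations

import numpy as np
import pytest
import trimesh
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

import lvshape as lv


def make_unit_cube() -> lv.SurfaceMesh:
    box = trimesh.creation.box(extents=(1.0, 1.0, 1.0))
    v = np.asarray(box.vertices) + 0.5  # corner at origin
    return lv.SurfaceMesh(v, np.asarray(box.faces), label="unit_cube")


def make_icosphere(radius: float = 1.0, subdivisions: int = 3) -> lv.SurfaceMesh:
    ico = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return lv.SurfaceMesh(np.asarray(ico.vertices), np.asarray(ico.faces),
                          label=f"icosphere_r{radius}")


@pytest.fixture
def unit_cube() -> lv.SurfaceMesh:
    return make_unit_cube()


@pytest.fixture(scope="session")
def sphericity_population():
    """20 LV shells varying only in sphericity, with pose nuisance (ED)."""
    spec = lv.PopulationSpec(n_subjects=20, seed=3, sd_size=0.0,
                             sd_thickness=0.0, sd_tilt=0.0,
                             phases=("ED",), mesh_resolution=32)
    return lv.sample_population(spec)


@pytest.fixture(scope="session")
def sphericity_pipeline(sphericity_population):
    """Aligned landmarks + shape model for the sphericity population."""
    from lvshape.shape_model import build_ssm_from_meshes

    pop = sphericity_population
    template, aligned, model = build_ssm_from_meshes(
        pop.endo_meshes("ED"), n_points=2000, seed=0,
        subject_ids=pop.subject_ids())
    return pop, template, aligned, model


def random_similarity(rng: np.random.Generator,
                      with_scale: bool = True) -> lv.SimilarityTransform:
    R = Rotation.random(random_state=int(rng.integers(2 ** 31))).as_matrix()
    s = float(rng.uniform(0.5, 2.0)) if with_scale else 1.0
    t = rng.uniform(-20, 20, size=3)
    return lv.SimilarityTransform(s, R, t)


def brute_force_similarity(source: np.ndarray, target: np.ndarray,
                           with_scale: bool = True,
                           allow_reflection: bool = False,
                           n_restarts: int = 6, seed: int = 0) -> float:
    """Best residual sum of squares by direct numerical optimization over a
    rotation-vector parameterization (independent of the closed form)."""
    rng = np.random.default_rng(seed)

    def residual(params, reflect):
        rotvec, log_s, t = params[:3], params[3], params[4:]
        R = Rotation.from_rotvec(rotvec).as_matrix()
        if reflect:
            R = R @ np.diag([1.0, 1.0, -1.0])
        s = np.exp(log_s) if with_scale else 1.0
        diff = s * source @ R.T + t - target
        return float((diff ** 2).sum())

    best = np.inf
    reflections = (False, True) if allow_reflection else (False,)
    for reflect in reflections:
        for _ in range(n_restarts):
            x0 = np.concatenate([rng.uniform(-np.pi, np.pi, 3), [0.0],
                                 rng.uniform(-5, 5, 3)])
            res = minimize(residual, x0, args=(reflect,), method="Powell",
                           options={"maxiter": 5000, "xtol": 1e-12,
                                    "ftol": 1e-14})
            # polish with a simplex pass
            res = minimize(residual, res.x, args=(reflect,),
                           method="Nelder-Mead",
                           options={"maxiter": 3000, "xatol": 1e-12,
                                    "fatol": 1e-14})
            best = min(best, res.fun)
    return best


@pytest.fixture
def similarity_oracle():
    return brute_force_similarity


def mann_whitney_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Brute-force pairwise Mann-Whitney AUC oracle."""
    s1 = scores[labels == 1][:, None]
    s0 = scores[labels == 0][None, :]
    return float((np.sum(s1 > s0) + 0.5 * np.sum(s1 == s0)) / (s1.size * s0.size))


@pytest.fixture
def auc_oracle():
    return mann_whitney_auc
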