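"""Procedural femur-like cohorts for end-to-end exercise of the pipeline.

Real B-score work runs on corresponded surfaces segmented from MR and CT
knee images.  This module fabricates everything those pipelines need, at
desk scale, with known ground truth:

* a watertight genus-0 *template* vaguely shaped like a distal femur — an
  ellipsoidal shaft end with two condylar lobes (anatomical realism is
  explicitly not the goal; what matters is a shaft region, two articular
  caps and a rim);
* a small set of smooth *healthy variation modes* (overall size, shaft
  elongation, condylar spread, bend, and spread along the OA direction
  itself) giving a Gaussian healthy population;
* an *OA deformation field* that broadens the condylar region, flattens
  the articular caps and raises an osteophyte-like ridge around their
  border, applied linearly with a severity parameter ``g >= 0``;
* paired observations of each bone: an MR-like observation in the
  reference parameterization, and a CT-like observation that is an
  independent remeshing of the same surface onto a different vertex layout
  (so CT observations genuinely require re-parameterization), each with
  surface noise along vertex normals — a mix of a spatially smooth
  component (segmentation models err coherently over regions) and
  pixel-scale iid jitter;
* a pseudo-KL ordinal grade 0-4 driving the severity distribution, with a
  grade mixture matching a mixed clinical analysis population.

Severity calibration (a generator design choice): grade-wise mean
severities (0, 0.5, 1.5, 3, 5) with 20 % relative SD and the default field
amplitudes put grade 0/1 subjects in the overlapping B-score band around 0
and push grades 2-4 progressively above B = +2, qualitatively matching the
curvilinear B-score vs KL-grade pattern seen clinically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bscore_scale import define_scale
from .errors import ConfigError, InsufficientDataError
from .mesh_core import TriangleMesh, vertex_normals
from .shape_model import (
    AlignmentSpec,
    ParameterizedShape,
    build_shape_model,
    generalized_procrustes,
)

__all__ = [
    "CohortConfig",
    "SyntheticSubject",
    "make_template",
    "healthy_mode_fields",
    "oa_deformation_field",
    "radial_remesh",
    "generate_cohort",
    "build_reference_assets",
]

# --- template anatomy constants (mm / radians) ------------------------------
# The two condylar lobes are deliberately unequal (as the medial and lateral
# femoral condyles are): the asymmetry anchors the principal-axis frame so
# model-to-volume pose initialization cannot confuse a bone with its mirror.
BASE_RADIUS = 22.0  # ellipsoidal shaft end
LOBE_AMPLITUDES = (15.0, 12.0)  # condylar lobe protrusions (medial, lateral)
LOBE_WIDTH = 0.55  # angular width of each lobe (rad)
SHAFT_AMPLITUDE = 6.0  # proximal elongation of the shaft end
_LOBE_DIRS = np.array([[0.50, -0.05, -0.87], [-0.45, -0.18, -0.88]])
_LOBE_DIRS /= np.linalg.norm(_LOBE_DIRS, axis=1, keepdims=True)

# --- OA deformation field amplitudes (mm per unit severity g) ---------------
# Angular widths are kept comparable to the template's own mesh resolution
# (~0.27 rad edge length at 3 subdivisions) so every generated feature is
# resolvable by the correspondence that measures it, as real dense femoral
# correspondences resolve real osteophytes.
FLATTEN_AMPLITUDE = 1.2  # inward push on the articular caps
BROADEN_AMPLITUDE = 1.0  # outward horizontal push of the condylar region
RIDGE_AMPLITUDE = 1.5  # outward normal ridge around the cap border
_CAP_EDGE = (0.30, 0.65)  # cap weight falls from 1 to 0 over this angle band
_BROADEN_EDGE = (0.75, 1.05)
_RIDGE_CENTER, _RIDGE_WIDTH = 0.75, 0.25
_SHAFT_EDGE = (0.10, 0.30)  # field forced to exactly 0 for u_z above edge[1]

# --- healthy population modes (per-vertex RMS displacement SD, mm) ----------
# The last mode is variation along the OA deformation direction itself:
# healthy knees spread on either side of the mean in the healthy-to-OA
# direction of shape space, which is what makes the lowest radiographic
# grades overlap on the B-score axis.
HEALTHY_MODE_SDS = (1.2, 0.8, 0.5, 0.3, 0.4)


def _smoothstep(x, edge0, edge1):
    """C1 cubic smoothstep from 1 at edge0 to 0 at edge1."""
    t = np.clip((x - edge0) / (edge1 - edge0), 0.0, 1.0)
    return 1.0 - t * t * (3.0 - 2.0 * t)


def make_template(subdivisions: int = 3) -> TriangleMesh:
    """Deterministic femur-like template: a radially displaced icosphere.

    Watertight, consistently oriented, genus 0; the vertex count is a
    deterministic function of ``subdivisions`` (icosphere topology).
    """
    import trimesh

    if subdivisions < 2:
        raise ValueError("subdivisions must be >= 2")
    ico = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    u = np.asarray(ico.vertices)
    u = u / np.linalg.norm(u, axis=1, keepdims=True)
    r = np.full(len(u), BASE_RADIUS)
    for d, amp in zip(_LOBE_DIRS, LOBE_AMPLITUDES):
        ang = np.arccos(np.clip(u @ d, -1.0, 1.0))
        r = r + amp * np.exp(-((ang / LOBE_WIDTH) ** 2))
    r = r + SHAFT_AMPLITUDE * np.maximum(u[:, 2], 0.0) ** 2
    return TriangleMesh(u * r[:, None], np.asarray(ico.faces))


def parameterization_id(subdivisions: int = 3) -> str:
    return f"synthfemur-ref-s{subdivisions}"


def healthy_mode_fields(template: TriangleMesh) -> np.ndarray:
    """Smooth displacement fields spanning healthy anatomical variation.

    Returns an array of shape (5, N, 3): overall size, shaft elongation,
    condylar spread, bend, and spread along the OA deformation direction
    (healthy anatomy varies along that axis too), each normalized to 1 mm
    per-vertex RMS.
    """
    v = template.vertices
    c = v.mean(axis=0)
    x = v - c
    fields = np.zeros((5, len(v), 3))
    fields[0] = x  # isotropic size
    fields[1, :, 2] = x[:, 2]  # shaft elongation
    fields[2, :, 0] = np.tanh(x[:, 0] / 10.0)  # condylar spread
    fields[3, :, 0] = (x[:, 2] / 20.0) ** 2  # bend (x-shear quadratic in z)
    fields[4] = oa_deformation_field(template)  # healthy spread along OA axis
    for k in range(len(fields)):
        rms = np.sqrt(np.mean(np.sum(fields[k] ** 2, axis=1)))
        fields[k] /= rms
    return fields


def oa_deformation_field(template: TriangleMesh) -> np.ndarray:
    """Per-vertex displacement (mm per unit severity) emulating OA change.

    Three smoothly weighted terms: the articular caps are pushed inward
    along the normal (flattening), the condylar region is pushed outward
    horizontally (broadening), and an outward normal bump runs along the
    closed rim around each cap border (osteophytic ridge).  The field is
    exactly zero on the shaft.  Applying ``g * field`` is linear in ``g``
    by construction.
    """
    v = template.vertices
    c = v.mean(axis=0)
    u = v - c
    u = u / np.linalg.norm(u, axis=1, keepdims=True)
    n = vertex_normals(template)
    th = np.full(len(v), np.inf)
    for d in _LOBE_DIRS:
        th = np.minimum(th, np.arccos(np.clip(u @ d, -1.0, 1.0)))

    w_cap = _smoothstep(th, *_CAP_EDGE)
    w_broaden = _smoothstep(th, *_BROADEN_EDGE)
    w_ridge = np.exp(-(((th - _RIDGE_CENTER) / _RIDGE_WIDTH) ** 2))
    w_shaft = _smoothstep(u[:, 2], *_SHAFT_EDGE)

    e_h = u.copy()
    e_h[:, 2] = 0.0
    e_h_norm = np.linalg.norm(e_h, axis=1, keepdims=True)
    e_h = np.where(e_h_norm > 1e-12, e_h / np.maximum(e_h_norm, 1e-12), 0.0)

    disp = (
        -FLATTEN_AMPLITUDE * w_cap[:, None] * n
        + BROADEN_AMPLITUDE * w_broaden[:, None] * e_h
        + RIDGE_AMPLITUDE * w_ridge[:, None] * n
    )
    return disp * w_shaft[:, None]


# ---------------------------------------------------------------------------
# CT-like alien parameterization: welded UV sphere + radial raycast remesh
# ---------------------------------------------------------------------------

def _welded_uv_sphere(n_lat: int, n_lon: int):
    """Unit UV sphere with welded seam and poles (watertight by construction)."""
    verts = [np.array([0.0, 0.0, 1.0])]
    for i in range(1, n_lat):
        phi = np.pi * i / n_lat
        for j in range(n_lon):
            lam = 2 * np.pi * j / n_lon
            verts.append(
                np.array(
                    [np.sin(phi) * np.cos(lam), np.sin(phi) * np.sin(lam), np.cos(phi)]
                )
            )
    verts.append(np.array([0.0, 0.0, -1.0]))
    verts = np.array(verts)
    south = len(verts) - 1

    def ring(i, j):
        return 1 + (i - 1) * n_lon + (j % n_lon)

    faces = []
    for j in range(n_lon):
        faces.append([0, ring(1, j), ring(1, j + 1)])
    for i in range(1, n_lat - 1):
        for j in range(n_lon):
            a, b = ring(i, j), ring(i, j + 1)
            c2, d2 = ring(i + 1, j), ring(i + 1, j + 1)
            faces.append([a, c2, d2])
            faces.append([a, d2, b])
    for j in range(n_lon):
        faces.append([south, ring(n_lat - 1, j + 1), ring(n_lat - 1, j)])
    return verts, np.array(faces, dtype=np.int64)


def radial_remesh(mesh: TriangleMesh, n_lat: int = 80, n_lon: int = 160) -> TriangleMesh:
    """Resample a star-shaped surface onto an independent UV-sphere layout.

    Rays are cast from the mesh centroid along every UV-sphere vertex
    direction; the outermost triangle intersection defines the new vertex.
    The result has a vertex arrangement unrelated to the input's, which is
    exactly the situation a CT-trained segmentation model creates relative
    to the scale-defining MR model.
    """
    dirs, faces = _welded_uv_sphere(n_lat, n_lon)
    c = mesh.vertices.mean(axis=0)
    tri = mesh.vertices[mesh.faces]  # (F, 3, 3)
    v0 = tri[:, 0]
    e1 = tri[:, 1] - v0
    e2 = tri[:, 2] - v0
    t_best = np.zeros(len(dirs))
    # Moller-Trumbore, vectorized over faces, chunked over rays
    chunk = max(1, int(2_000_000 // max(len(mesh.faces), 1)))
    for start in range(0, len(dirs), chunk):
        d = dirs[start : start + chunk]  # (R, 3)
        pvec = np.cross(d[:, None, :], e2[None, :, :])  # (R, F, 3)
        det = np.einsum("fj,rfj->rf", e1, pvec)
        ok = np.abs(det) > 1e-12
        inv_det = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)
        tvec = c - v0  # (F, 3)
        uu = np.einsum("fj,rfj->rf", tvec, pvec) * inv_det
        qvec = np.cross(tvec, e1)  # (F, 3)
        vv = np.einsum("rj,fj->rf", d, qvec) * inv_det
        tt = np.einsum("fj,fj->f", e2, qvec)[None, :] * inv_det
        hit = ok & (uu >= -1e-10) & (vv >= -1e-10) & (uu + vv <= 1 + 1e-10) & (tt > 0)
        tt = np.where(hit, tt, 0.0)
        t_best[start : start + chunk] = tt.max(axis=1)
    if (t_best <= 0).any():
        raise ValueError(
            f"{int((t_best <= 0).sum())} rays missed the surface; "
            "mesh is not star-shaped about its centroid"
        )
    return TriangleMesh(c + dirs * t_best[:, None], faces)


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

#: analysis-population pseudo-KL mixture (grades 0..4), normalized
DEFAULT_GRADE_MIXTURE = np.array([19.0, 31.0, 30.0, 16.0, 3.0])
DEFAULT_GRADE_MIXTURE /= DEFAULT_GRADE_MIXTURE.sum()

DEFAULT_SEVERITY_MEANS = (0.0, 0.5, 1.5, 3.0, 5.0)


@dataclass
class CohortConfig:
    """Study conditions for a synthetic cohort.

    Noise SDs are surface displacement SDs (mm) along vertex normals; the
    defaults of 0.2 mm reflect sub-voxel segmentation surface error at
    typical knee-image resolution.
    """

    n_subjects: int = 50
    grade_mixture: np.ndarray = field(
        default_factory=lambda: DEFAULT_GRADE_MIXTURE.copy()
    )
    severity_means: tuple = DEFAULT_SEVERITY_MEANS
    severity_rel_sd: float = 0.2
    healthy_mode_sds: tuple = HEALTHY_MODE_SDS
    sigma_mr: float = 0.2
    sigma_ct: float = 0.2
    subdivisions: int = 3
    ct_n_lat: int = 80
    ct_n_lon: int = 160
    seed: int = 0

    def __post_init__(self):
        self.grade_mixture = np.asarray(self.grade_mixture, dtype=np.float64)
        if self.grade_mixture.shape != (5,):
            raise ConfigError("grade_mixture must have 5 entries (grades 0..4)")
        if abs(self.grade_mixture.sum() - 1.0) > 1e-9:
            raise ConfigError(
                f"grade_mixture must sum to 1 (got {self.grade_mixture.sum()})"
            )
        if (self.grade_mixture < 0).any():
            raise ConfigError("grade_mixture entries must be non-negative")
        if self.sigma_mr < 0 or self.sigma_ct < 0:
            raise ConfigError("noise SDs must be >= 0")
        if self.n_subjects < 1:
            raise ConfigError("n_subjects must be >= 1")


@dataclass
class SyntheticSubject:
    """One simulated bone with its paired two-parameterization observations."""

    subject_id: str
    grade: int
    severity: float
    truth_shape: ParameterizedShape  # reference parameterization, no noise
    mr_obs: ParameterizedShape | None  # reference parameterization + MR noise
    ct_obs: TriangleMesh | None  # alien parameterization + CT noise


def _truth_points(template, fields, oa_field, healthy_coeffs, g):
    disp = np.tensordot(healthy_coeffs, fields, axes=(0, 0))
    return template.vertices + disp + g * oa_field


#: variance share of the spatially smooth noise component (the rest is iid)
NOISE_SMOOTH_FRACTION = 0.7


def _surface_noise(rng, points, sigma, smooth_fraction=NOISE_SMOOTH_FRACTION):
    """Per-vertex scalar noise (mm) with unit SD scaled to ``sigma``.

    Segmentation surface error is not independent per vertex: models err
    smoothly over whole regions, with pixel-level jitter on top.  The field
    here mixes a random low-order (quadratic-in-direction) smooth component
    with iid noise, variance split ``smooth_fraction : 1-smooth_fraction``.
    """
    if sigma <= 0:
        return np.zeros(len(points))
    c = points.mean(axis=0)
    u = points - c
    u = u / np.linalg.norm(u, axis=1, keepdims=True)
    basis = np.stack(
        [
            np.ones(len(u)), u[:, 0], u[:, 1], u[:, 2],
            u[:, 0] * u[:, 1], u[:, 1] * u[:, 2], u[:, 0] * u[:, 2],
            u[:, 0] ** 2 - u[:, 2] ** 2, u[:, 1] ** 2 - u[:, 2] ** 2,
        ],
        axis=1,
    )
    basis = basis / np.sqrt(np.mean(basis**2, axis=0))
    coef = rng.standard_normal(basis.shape[1]) / np.sqrt(basis.shape[1])
    smooth = basis @ coef
    smooth = smooth / max(float(smooth.std()), 1e-12)
    iid = rng.standard_normal(len(u))
    return sigma * (
        np.sqrt(smooth_fraction) * smooth + np.sqrt(1.0 - smooth_fraction) * iid
    )


def generate_cohort(
    config: CohortConfig, with_observations: bool = True
) -> list[SyntheticSubject]:
    """Draw a fully seed-reproducible cohort of synthetic subjects.

    Per subject: a pseudo-KL grade from the mixture, a severity ``g`` from
    the grade's truncated-normal distribution (``g = 0`` for grade 0), a
    healthy-model draw, then ``truth = healthy + g * oa_field``; the MR
    observation adds normal-direction noise in the reference
    parameterization, the CT observation radially remeshes the truth onto
    the alien layout before adding its own noise.

    Each subject draws from its own spawned random stream, so the truth
    shapes are identical whether or not observations are generated
    (``with_observations=False`` is a cheap path for model training, which
    only consumes truth shapes; ``mr_obs``/``ct_obs`` are then None).
    """
    template = make_template(config.subdivisions)
    pid = parameterization_id(config.subdivisions)
    fields = healthy_mode_fields(template)
    oa_field = oa_deformation_field(template)
    sds = np.asarray(config.healthy_mode_sds, dtype=np.float64)
    streams = np.random.SeedSequence(config.seed).spawn(config.n_subjects)
    subjects = []
    for i in range(config.n_subjects):
        rng = np.random.default_rng(streams[i])
        grade = int(rng.choice(5, p=config.grade_mixture))
        if grade == 0:
            g = 0.0
        else:
            mean_g = config.severity_means[grade]
            g = max(0.0, float(rng.normal(mean_g, config.severity_rel_sd * mean_g)))
        z = np.clip(rng.standard_normal(len(sds)), -3.0, 3.0) * sds
        truth_pts = _truth_points(template, fields, oa_field, z, g)
        truth = ParameterizedShape(
            truth_pts, pid, subject_id=f"S{i:04d}", modality="truth"
        )
        mr_obs = ct_mesh = None
        if with_observations:
            truth_mesh = TriangleMesh(truth_pts, template.faces)
            eta_mr = _surface_noise(rng, truth_pts, config.sigma_mr)
            mr_pts = truth_pts + eta_mr[:, None] * vertex_normals(truth_mesh)
            mr_obs = ParameterizedShape(
                mr_pts, pid, subject_id=f"S{i:04d}", modality="MR"
            )
            ct_mesh = radial_remesh(truth_mesh, config.ct_n_lat, config.ct_n_lon)
            if config.sigma_ct > 0:
                eta_ct = _surface_noise(rng, ct_mesh.vertices, config.sigma_ct)
                ct_pts = ct_mesh.vertices + eta_ct[:, None] * vertex_normals(ct_mesh)
                ct_mesh = TriangleMesh(ct_pts, ct_mesh.faces)
        subjects.append(
            SyntheticSubject(
                subject_id=f"S{i:04d}",
                grade=grade,
                severity=g,
                truth_shape=truth,
                mr_obs=mr_obs,
                ct_obs=ct_mesh,
            )
        )
    return subjects


def build_reference_assets(
    config: CohortConfig,
    cohort: list[SyntheticSubject] | None = None,
    variance_retained: float = 0.995,
):
    """Build the scale-defining shape model and B-score scale.

    The point-distribution model is trained on all truth shapes of the
    cohort (so it spans both healthy variation and the OA direction); the
    scale splits grades {0, 1} as non-OA from grades >= 2 as OA, following
    the conventional radiographic-OA boundary.
    """
    if cohort is None:
        cohort = generate_cohort(config, with_observations=False)
    template = make_template(config.subdivisions)
    healthy = [s.truth_shape for s in cohort if s.grade <= 1]
    oa = [s.truth_shape for s in cohort if s.grade >= 2]
    if len(healthy) < 2 or len(oa) < 2:
        raise InsufficientDataError(
            f"need >= 2 shapes per group (healthy {len(healthy)}, OA {len(oa)})"
        )
    spec = AlignmentSpec()
    truths = [s.truth_shape for s in cohort]
    aligned, _, _ = generalized_procrustes(truths, spec)
    model = build_shape_model(
        aligned,
        variance_retained=variance_retained,
        template_faces=template.faces,
        alignment_spec=spec,
    )
    scale = define_scale(healthy, oa, spec)
    return model, scale
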