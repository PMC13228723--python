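"""Point-distribution models over corresponded landmark sets.

A population of bones segmented with the same template carries a one-to-one
vertex correspondence, so each bone is a point in a 3N-dimensional shape
space.  This module provides the classical machinery on that space:
generalized Procrustes alignment (GPA), PCA model building, projection and
reconstruction, sampling, and model fitting — both to corresponded point
sets and to binary volumes.  The binary-volume fit is a geometric
model-based segmentation: the model surface is attracted to the
zero-crossing of the volume's signed distance field under a regularized
pose + shape-coefficient optimization.  It plays the role that an
intensity-based active appearance model search plays on real images, while
staying fully defined by geometry.

Pose alignment defaults to rigid (rotation + translation, no scaling) and
size is *not* normalized away: disease-related surface broadening is partly
a size effect that shape statistics here must retain.  Both behaviours are
controlled by :class:`AlignmentSpec`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .errors import (
    ConvergenceError,
    CorrespondenceError,
    InsufficientDataError,
    OutOfFieldError,
    RankError,
)
from .mesh_core import BinaryVolume, TriangleMesh, signed_distance_field

__all__ = [
    "AlignmentSpec",
    "Similarity",
    "ParameterizedShape",
    "ShapeModel",
    "procrustes_align",
    "generalized_procrustes",
    "build_shape_model",
    "project",
    "reconstruct",
    "sample_shape",
    "fit_model_to_points",
    "fit_model_to_binary",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class AlignmentSpec:
    """How shapes are brought into a common frame.

    allow_scale : include an optimal isotropic scale factor in pairwise
        Procrustes fits (a "similarity" alignment).
    remove_scale : normalize every shape to unit centroid size before
        statistics, erasing size differences entirely.
    """

    allow_scale: bool = False
    remove_scale: bool = False


@dataclass
class Similarity:
    """A similarity transform ``p -> scale * R @ p + t``."""

    scale: float
    rotation: np.ndarray
    translation: np.ndarray

    @classmethod
    def identity(cls) -> "Similarity":
        return cls(1.0, np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return self.scale * points @ self.rotation.T + self.translation

    def inverse_apply(self, points: np.ndarray) -> np.ndarray:
        return (points - self.translation) @ self.rotation / self.scale


@dataclass
class ParameterizedShape:
    """An ordered, corresponded 3D landmark set for one bone.

    Shape-space arithmetic is only meaningful between shapes that share
    ``parameterization_id`` (i.e. were produced by the same template).
    """

    points: np.ndarray
    parameterization_id: str
    subject_id: str | None = None
    timepoint: str | None = None
    modality: str | None = None

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=np.float64).reshape(-1, 3)

    @property
    def n_points(self) -> int:
        return len(self.points)

    def flat(self) -> np.ndarray:
        return self.points.reshape(-1)

    def with_points(self, points: np.ndarray) -> "ParameterizedShape":
        return replace(self, points=np.asarray(points, dtype=np.float64))

    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)

    def centroid_size(self) -> float:
        c = self.points - self.centroid()
        return float(np.linalg.norm(c))


def _check_same_parameterization(shapes):
    pids = {s.parameterization_id for s in shapes}
    if len(pids) > 1:
        raise CorrespondenceError(f"mixed parameterizations: {sorted(pids)}")
    counts = {s.n_points for s in shapes}
    if len(counts) > 1:
        raise CorrespondenceError(f"mixed landmark counts: {sorted(counts)}")


@dataclass
class ShapeModel:
    """Procrustes-aligned PCA point-distribution model.

    ``modes`` has orthonormal columns (3N x k); ``mode_variances`` is
    non-increasing.  ``template_faces`` carries the triangulation of the
    parameterization so model shapes can be meshed.
    """

    mean_shape: np.ndarray  # (3N,)
    modes: np.ndarray  # (3N, k), orthonormal columns
    mode_variances: np.ndarray  # (k,), non-increasing
    parameterization_id: str
    template_faces: np.ndarray | None = None
    alignment_spec: AlignmentSpec = field(default_factory=AlignmentSpec)

    def __post_init__(self):
        self.mean_shape = np.asarray(self.mean_shape, dtype=np.float64).reshape(-1)
        self.modes = np.asarray(self.modes, dtype=np.float64)
        self.mode_variances = np.asarray(self.mode_variances, dtype=np.float64)
        gram = self.modes.T @ self.modes
        if not np.allclose(gram, np.eye(self.n_modes), atol=1e-8):
            raise ValueError("modes are not orthonormal")
        if (np.diff(self.mode_variances) > 1e-12).any():
            raise ValueError("mode variances must be non-increasing")
        if (self.mode_variances < -1e-12).any():
            raise ValueError("mode variances must be non-negative")

    @property
    def n_points(self) -> int:
        return self.mean_shape.size // 3

    @property
    def n_modes(self) -> int:
        return self.modes.shape[1]

    def mean_points(self) -> np.ndarray:
        return self.mean_shape.reshape(-1, 3)

    def mean_as_shape(self) -> ParameterizedShape:
        return ParameterizedShape(self.mean_points(), self.parameterization_id)

    def mean_as_mesh(self) -> TriangleMesh:
        if self.template_faces is None:
            raise ValueError("model has no template faces")
        return TriangleMesh(self.mean_points(), self.template_faces)


# ---------------------------------------------------------------------------
# Procrustes
# ---------------------------------------------------------------------------

def procrustes_align(
    source: np.ndarray,
    target: np.ndarray,
    allow_scale: bool = False,
    weights: np.ndarray | None = None,
) -> Similarity:
    """Least-squares similarity/rigid transform mapping ``source`` onto
    ``target`` (Kabsch/Umeyama, optionally weighted)."""
    x = np.asarray(source, dtype=np.float64).reshape(-1, 3)
    y = np.asarray(target, dtype=np.float64).reshape(-1, 3)
    if weights is None:
        w = np.ones(len(x))
    else:
        w = np.asarray(weights, dtype=np.float64)
    wsum = w.sum()
    if wsum <= 0:
        raise RankError("all alignment weights are zero")
    cx = (w[:, None] * x).sum(0) / wsum
    cy = (w[:, None] * y).sum(0) / wsum
    x0 = x - cx
    y0 = y - cy
    h = (w[:, None] * x0).T @ y0
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    if allow_scale:
        denom = (w * (x0 * x0).sum(1)).sum()
        if denom < 1e-300:
            raise RankError("degenerate source shape (all points coincident)")
        scale = float((s * np.diag(corr)).sum() / denom)
    else:
        scale = 1.0
    t = cy - scale * rot @ cx
    return Similarity(scale, rot, t)


def generalized_procrustes(
    shapes: list[ParameterizedShape],
    alignment_spec: AlignmentSpec | None = None,
    tol: float = 1e-10,
    max_iters: int = 100,
):
    """Generalized Procrustes analysis.

    Iteratively aligns every shape to the running consensus mean until the
    mean stops moving (RMS change < ``tol``).  Returns
    ``(aligned_shapes, consensus_mean, transforms)`` where each transform
    maps the raw input shape into the aligned frame.  The consensus mean
    has its centroid at the origin; with ``remove_scale`` every aligned
    shape additionally has unit centroid size.
    """
    spec = alignment_spec or AlignmentSpec()
    if len(shapes) < 2:
        raise InsufficientDataError(f"GPA needs >= 2 shapes, got {len(shapes)}")
    _check_same_parameterization(shapes)
    pts = [s.points.copy() for s in shapes]
    for i, p in enumerate(pts):
        if np.linalg.norm(p - p.mean(0)) < 1e-12:
            raise RankError(f"shape {i} is degenerate (all points coincident)")
    scales0 = np.ones(len(pts))
    if spec.remove_scale:
        for i, p in enumerate(pts):
            size = np.linalg.norm(p - p.mean(0))
            scales0[i] = 1.0 / size
            pts[i] = p * scales0[i]

    mean = pts[0] - pts[0].mean(0)
    transforms = [Similarity.identity() for _ in pts]
    for _ in range(max_iters):
        aligned = []
        for i, p in enumerate(pts):
            tr = procrustes_align(p, mean, allow_scale=spec.allow_scale)
            transforms[i] = tr
            aligned.append(tr.apply(p))
        new_mean = np.mean(aligned, axis=0)
        new_mean = new_mean - new_mean.mean(0)
        if spec.remove_scale:
            new_mean = new_mean / np.linalg.norm(new_mean)
        change = np.sqrt(np.mean((new_mean - mean) ** 2))
        if change < tol:
            # keep the mean the final transforms were computed against, so
            # re-aligning any input to the returned consensus reproduces its
            # aligned pose exactly (bit-identical), not merely within tol
            break
        mean = new_mean
    else:
        # max_iters exhausted: one last pass so transforms match `mean`
        for i, p in enumerate(pts):
            transforms[i] = procrustes_align(p, mean, allow_scale=spec.allow_scale)
    aligned_shapes = [
        s.with_points(tr.apply(p)) for s, p, tr in zip(shapes, pts, transforms)
    ]
    # fold the pre-scaling into the returned raw->aligned transforms
    full_transforms = [
        Similarity(tr.scale * s0, tr.rotation, tr.translation)
        for tr, s0 in zip(transforms, scales0)
    ]
    consensus = ParameterizedShape(mean, shapes[0].parameterization_id)
    return aligned_shapes, consensus, full_transforms


# ---------------------------------------------------------------------------
# PCA model
# ---------------------------------------------------------------------------

def build_shape_model(
    aligned_shapes: list[ParameterizedShape],
    variance_retained: float = 0.98,
    template_faces: np.ndarray | None = None,
    alignment_spec: AlignmentSpec | None = None,
) -> ShapeModel:
    """PCA point-distribution model from Procrustes-aligned shapes.

    Keeps the smallest number of modes whose cumulative variance reaches
    ``variance_retained`` of the total.  Variances use the n-1 denominator.
    """
    if len(aligned_shapes) < 3:
        raise InsufficientDataError(
            f"model building needs >= 3 shapes, got {len(aligned_shapes)}"
        )
    if not (0.0 < variance_retained <= 1.0):
        raise ValueError("variance_retained must be in (0, 1]")
    _check_same_parameterization(aligned_shapes)
    data = np.stack([s.flat() for s in aligned_shapes])  # (n, 3N)
    mean = data.mean(axis=0)
    centered = data - mean
    # SVD of the centered data; singular values -> variances with n-1
    _, svals, vt = np.linalg.svd(centered, full_matrices=False)
    variances = svals**2 / (len(data) - 1)
    nonzero = variances > max(variances[0], 1e-30) * 1e-12
    variances = variances[nonzero]
    vt = vt[nonzero]
    total = variances.sum()
    cum = np.cumsum(variances)
    k = int(np.searchsorted(cum, variance_retained * total - 1e-15) + 1)
    k = min(k, len(variances))
    return ShapeModel(
        mean_shape=mean,
        modes=vt[:k].T,
        mode_variances=variances[:k],
        parameterization_id=aligned_shapes[0].parameterization_id,
        template_faces=template_faces,
        alignment_spec=alignment_spec or AlignmentSpec(),
    )


def project(
    model: ShapeModel, shape: ParameterizedShape, align: bool = False
) -> np.ndarray:
    """Mode coefficients of a shape: ``modes.T @ (x - mean)``.

    With ``align=True`` the shape is first Procrustes-aligned onto the
    model mean per the model's alignment spec.
    """
    if shape.parameterization_id != model.parameterization_id:
        raise CorrespondenceError(
            f"shape parameterization {shape.parameterization_id!r} != "
            f"model {model.parameterization_id!r}"
        )
    pts = shape.points
    if align:
        tr = procrustes_align(
            pts, model.mean_points(), allow_scale=model.alignment_spec.allow_scale
        )
        pts = tr.apply(pts)
    return model.modes.T @ (pts.reshape(-1) - model.mean_shape)


def reconstruct(model: ShapeModel, coefficients: np.ndarray) -> ParameterizedShape:
    """Shape from mode coefficients: ``mean + modes @ c``."""
    c = np.asarray(coefficients, dtype=np.float64).reshape(-1)
    if c.size != model.n_modes:
        raise ValueError(f"expected {model.n_modes} coefficients, got {c.size}")
    flat = model.mean_shape + model.modes @ c
    return ParameterizedShape(flat.reshape(-1, 3), model.parameterization_id)


def sample_shape(
    model: ShapeModel,
    rng: np.random.Generator | int,
    sd_clip: float = 3.0,
) -> ParameterizedShape:
    """Draw a random plausible shape: independent normal coefficients with
    the model variances, truncated at ±``sd_clip`` standard deviations."""
    if sd_clip <= 0:
        raise ValueError("sd_clip must be > 0")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    sd = np.sqrt(model.mode_variances)
    z = rng.standard_normal(model.n_modes)
    z = np.clip(z, -sd_clip, sd_clip)
    return reconstruct(model, z * sd)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _clip_coefficients(c, variances, regularization_sd):
    lim = regularization_sd * np.sqrt(variances)
    return np.clip(c, -lim, lim)


def _solve_coefficients(model, y_flat, weights, regularization_sd):
    """Weighted least-squares mode coefficients of y (model frame)."""
    resid = y_flat - model.mean_shape
    if weights is None:
        c = model.modes.T @ resid
    else:
        w3 = np.repeat(weights, 3)
        a = model.modes.T @ (w3[:, None] * model.modes)
        b = model.modes.T @ (w3 * resid)
        c = np.linalg.solve(a + 1e-12 * np.eye(model.n_modes), b)
    return _clip_coefficients(c, model.mode_variances, regularization_sd)


def fit_model_to_points(
    model: ShapeModel,
    target: ParameterizedShape,
    regularization_sd: float = 3.0,
    max_iters: int = 50,
    tol: float = 1e-12,
    weights: np.ndarray | None = None,
    init_pose: Similarity | None = None,
):
    """Fit pose + mode coefficients to a corresponded target point set.

    Alternates an optimal pose step (per the model's alignment spec) and a
    clipped coefficient solve; the weighted residual RMS is non-increasing.
    Raises :class:`ConvergenceError` if the residual increases three
    iterations in a row (which indicates corrupted inputs).

    Returns ``(fitted_shape_in_target_frame, coefficients, pose)`` where
    ``pose`` maps model frame to target frame.
    """
    if target.parameterization_id != model.parameterization_id:
        raise CorrespondenceError(
            f"target parameterization {target.parameterization_id!r} != "
            f"model {model.parameterization_id!r}"
        )
    if regularization_sd <= 0:
        raise ValueError("regularization_sd must be > 0")
    y = target.points
    allow_scale = model.alignment_spec.allow_scale
    pose = init_pose or procrustes_align(
        model.mean_points(), y, allow_scale=allow_scale, weights=weights
    )
    coeffs = np.zeros(model.n_modes)
    w = None if weights is None else np.asarray(weights, dtype=np.float64)
    prev_resid = np.inf
    bad_streak = 0
    recon = model.mean_points()
    for _ in range(max_iters):
        y_model = pose.inverse_apply(y)
        coeffs = _solve_coefficients(model, y_model.reshape(-1), w, regularization_sd)
        recon = (model.mean_shape + model.modes @ coeffs).reshape(-1, 3)
        pose = procrustes_align(recon, y, allow_scale=allow_scale, weights=w)
        diff = pose.apply(recon) - y
        if w is None:
            resid = float(np.sqrt(np.mean(diff**2)))
        else:
            resid = float(np.sqrt((w * (diff**2).sum(1)).sum() / max(w.sum(), 1e-300)))
        if resid > prev_resid + 1e-12:
            bad_streak += 1
            if bad_streak >= 3:
                raise ConvergenceError(
                    f"fit diverged: residual rose 3 consecutive iterations "
                    f"(last {resid:.3e})"
                )
        else:
            bad_streak = 0
        if abs(prev_resid - resid) < tol:
            prev_resid = resid
            break
        prev_resid = resid
    fitted = ParameterizedShape(pose.apply(recon), model.parameterization_id)
    return fitted, coeffs, pose


class _SdfSampler:
    """Trilinear sampler of a signed distance field and its gradient."""

    def __init__(self, volume: BinaryVolume):
        self.volume = volume
        self.sdf = signed_distance_field(volume)
        self.grads = np.gradient(self.sdf, *volume.spacing, edge_order=1)
        self.far = float(self.sdf.max() + 10 * volume.spacing.max())

    def sample(self, points_world):
        idx = self.volume.world_to_index(points_world).T
        d = ndimage.map_coordinates(
            self.sdf, idx, order=1, mode="constant", cval=self.far
        )
        g = np.stack(
            [
                ndimage.map_coordinates(gi, idx, order=1, mode="constant", cval=0.0)
                for gi in self.grads
            ],
            axis=1,
        )
        shape = np.array(self.volume.shape)
        inside = ((idx.T >= 0) & (idx.T <= shape - 1)).all(axis=1)
        return d, g, inside


def fit_model_to_binary(
    model: ShapeModel,
    volume: BinaryVolume,
    init_pose: Similarity | None = None,
    max_iters: int = 100,
    tol: float = 0.01,
    regularization_sd: float = 3.0,
    search_distance: float = 10.0,
):
    """Segment a binary volume with the shape model.

    Iterates: (a) for every current model point, find the zero-crossing of
    the volume's signed distance field by a capped Newton step along the
    field gradient; (b) re-fit pose + clipped mode coefficients to those
    target points.  Points with no crossing within ``search_distance`` mm
    keep their position with zero weight.  Stops when the mean point motion
    drops below ``tol`` mm (converged) or after ``max_iters``.

    Raises :class:`OutOfFieldError` when more than half of the model points
    find no surface crossing — the anatomy is (partly) outside the imaged
    field of view.  Non-convergence is flagged, not raised.

    Returns ``(fitted_shape, info)`` with ``info`` holding coefficients,
    pose, ``mean_abs_surface_distance`` (mm), ``converged``, ``n_iters``
    and ``valid_fraction``.
    """
    occ = volume.occupancy
    if (
        occ[0].any() or occ[-1].any()
        or occ[:, 0].any() or occ[:, -1].any()
        or occ[:, :, 0].any() or occ[:, :, -1].any()
    ):
        raise OutOfFieldError(
            "segmentation mask touches the volume boundary: anatomy extends "
            "beyond the scan field of view"
        )
    sampler = _SdfSampler(volume)
    if init_pose is None:
        pose = _select_init_pose(
            model, volume, sampler, regularization_sd, search_distance
        )
    else:
        pose = init_pose
    coeffs = np.zeros(model.n_modes)
    current = pose.apply(model.mean_points())
    converged = False
    n_iters = 0
    valid_frac = 0.0
    for n_iters in range(1, max_iters + 1):
        d, g, inside = sampler.sample(current)
        gnorm = np.linalg.norm(g, axis=1)
        valid = inside & (np.abs(d) <= search_distance) & (gnorm > 1e-6)
        valid_frac = float(valid.mean())
        if valid_frac < 0.5:
            raise OutOfFieldError(
                f"only {valid.sum()}/{len(valid)} model points found a surface "
                f"crossing within {search_distance} mm: anatomy partially "
                "outside the volume field of view"
            )
        step = np.zeros_like(current)
        step[valid] = -(d[valid] / gnorm[valid])[:, None] * (
            g[valid] / gnorm[valid][:, None]
        )
        targets = current + step
        weights = valid.astype(np.float64)
        target_shape = ParameterizedShape(targets, model.parameterization_id)
        try:
            fitted, coeffs, pose = fit_model_to_points(
                model,
                target_shape,
                regularization_sd=regularization_sd,
                max_iters=5,
                weights=weights,
                init_pose=pose,
            )
        except ConvergenceError:
            # weighted solve + coefficient clipping can stall on hard
            # volumes; a non-converged result is flagged, not raised
            break
        motion = float(np.mean(np.linalg.norm(fitted.points - current, axis=1)))
        current = fitted.points
        if motion < tol:
            converged = True
            break
    d_final, _, inside = sampler.sample(current)
    mad = float(np.mean(np.abs(d_final[inside]))) if inside.any() else np.inf
    fitted_shape = ParameterizedShape(current, model.parameterization_id)
    info = {
        "coefficients": coeffs,
        "pose": pose,
        "mean_abs_surface_distance": mad,
        "converged": converged,
        "n_iters": n_iters,
        "valid_fraction": valid_frac,
    }
    return fitted_shape, info


def _principal_axes(points):
    c = points.mean(0)
    cov = np.cov((points - c).T)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    return c, evecs[:, order]


def _candidate_init_poses(model, volume):
    """Centroid + principal-axes initializations: identity plus the four
    proper sign combinations of the matched principal frames."""
    occ_pts = volume.voxel_centers_world()
    c_vol, ax_vol = _principal_axes(occ_pts)
    c_mod, ax_mod = _principal_axes(model.mean_points())
    rotations = [np.eye(3)]
    for s1 in (1.0, -1.0):
        for s2 in (1.0, -1.0):
            d = np.diag([s1, s2, s1 * s2])  # keeps det = +1
            rotations.append(ax_vol @ d @ ax_mod.T)
    return [Similarity(1.0, rot, c_vol - rot @ c_mod) for rot in rotations]


def _select_init_pose(model, volume, sampler, regularization_sd, search_distance):
    """Resolve the principal-axis sign ambiguity by a short trial fit per
    candidate pose, keeping the one with the lowest mean |SDF| afterwards.

    A nearly-symmetric bone can make the raw pre-fit |SDF| score prefer a
    flipped pose whose fit then converges to a wrong local optimum; a few
    fit iterations separate the candidates reliably.
    """
    best, best_score, first_error = None, np.inf, None
    for pose in _candidate_init_poses(model, volume):
        try:
            shape, info = fit_model_to_binary(
                model,
                volume,
                init_pose=pose,
                max_iters=8,
                tol=0.0,
                regularization_sd=regularization_sd,
                search_distance=search_distance,
            )
        except OutOfFieldError as exc:
            if first_error is None:
                first_error = exc
            continue
        if info["mean_abs_surface_distance"] < best_score:
            best_score = info["mean_abs_surface_distance"]
            best = info["pose"]
    if best is None:
        raise first_error
    return best


# ---------------------------------------------------------------------------
# Serialization — single .npz archive with a versioned JSON header
# ---------------------------------------------------------------------------

_FORMAT_VERSION = 1


def save_model(model: ShapeModel, path) -> None:
    """Serialize a ShapeModel to a single ``.npz`` archive."""
    meta = {
        "format_version": _FORMAT_VERSION,
        "kind": "shape_model",
        "parameterization_id": model.parameterization_id,
        "alignment_spec": {
            "allow_scale": model.alignment_spec.allow_scale,
            "remove_scale": model.alignment_spec.remove_scale,
        },
    }
    arrays = {
        "meta_json": np.frombuffer(
            json.dumps(meta).encode("utf-8"), dtype=np.uint8
        ),
        "mean_shape": model.mean_shape,
        "modes": model.modes,
        "mode_variances": model.mode_variances,
    }
    if model.template_faces is not None:
        arrays["template_faces"] = model.template_faces
    np.savez_compressed(path, **arrays)


def load_model(path) -> ShapeModel:
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta_json"]).decode("utf-8"))
        if meta.get("format_version") != _FORMAT_VERSION:
            raise ValueError(
                f"unsupported model archive version {meta.get('format_version')}"
            )
        spec = AlignmentSpec(**meta["alignment_spec"])
        faces = data["template_faces"] if "template_faces" in data else None
        return ShapeModel(
            mean_shape=data["mean_shape"],
            modes=data["modes"],
            mode_variances=data["mode_variances"],
            parameterization_id=meta["parameterization_id"],
            template_faces=faces,
            alignment_spec=spec,
        )
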