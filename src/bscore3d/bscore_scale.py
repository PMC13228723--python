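"""The B-score: a z-score along the healthy-to-OA axis in femoral shape space.

The scale is defined entirely by two training subpopulations of corresponded
shapes.  Its origin is the mean healthy shape ``mu_H``; its direction ``v``
is the unit vector from ``mu_H`` to the OA-group mean; and one unit equals
the standard deviation ``sigma_H`` of the healthy shapes' projections onto
``v``.  Any corresponded shape ``s`` then scores

    B(s) = ((s - mu_H) . v) / sigma_H

so the healthy training population has B-score mean 0 and SD 1 by
construction, and larger values mean further along the structural change
associated with osteoarthritis (surface broadening and flattening,
osteophytic ridge growth).  Typical adult values fall between about -2 and
+8; values from roughly +2 upward correspond to radiographic OA.

Projection is performed in the raw aligned 3N landmark space, not in a
truncated PCA coefficient space: when all modes are kept the two are
equivalent, and the raw space avoids committing to any particular mode
truncation.  The SD uses the n-1 denominator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    CorrespondenceError,
    DegenerateAxisError,
    DegenerateSpreadError,
    InsufficientDataError,
)
from .shape_model import (
    AlignmentSpec,
    ParameterizedShape,
    generalized_procrustes,
    procrustes_align,
)

__all__ = [
    "BScoreScale",
    "BScore",
    "define_scale",
    "compute_bscore",
    "bscore_cohort",
    "save_scale",
    "load_scale",
]

#: sanity band for adult populations; values outside trigger a warning
TYPICAL_RANGE = (-10.0, 15.0)


@dataclass
class BScoreScale:
    """Healthy-mean origin, unit healthy->OA direction and healthy SD.

    ``reference_shape`` stores the GPA consensus of the training population;
    query shapes that still carry an arbitrary pose are Procrustes-aligned
    onto it (not onto ``mu_H``) so that re-scoring a training shape
    reproduces its training-time pose, keeping the scale self-consistent.
    """

    healthy_mean: np.ndarray  # mu_H, (3N,), aligned frame
    direction: np.ndarray  # v, unit (3N,)
    sigma_h: float
    parameterization_id: str
    reference_shape: np.ndarray | None = None  # GPA consensus, (3N,)
    alignment_spec: AlignmentSpec = field(default_factory=AlignmentSpec)
    n_healthy: int = 0
    n_oa: int = 0

    def __post_init__(self):
        self.healthy_mean = np.asarray(self.healthy_mean, np.float64).reshape(-1)
        self.direction = np.asarray(self.direction, np.float64).reshape(-1)
        norm = np.linalg.norm(self.direction)
        if abs(norm - 1.0) > 1e-10:
            raise ValueError(f"direction must be unit length (got {norm})")
        if not self.sigma_h > 0:
            raise DegenerateSpreadError("sigma_h must be > 0")


@dataclass
class BScore:
    """A single dimensionless B-score with its provenance metadata."""

    value: float
    subject_id: str | None = None
    timepoint: str | None = None
    modality: str | None = None


def define_scale(
    healthy_shapes: list[ParameterizedShape],
    oa_shapes: list[ParameterizedShape],
    alignment_spec: AlignmentSpec | None = None,
) -> BScoreScale:
    """Build the B-score scale from healthy and OA training shapes.

    All shapes are first brought into a common frame by generalized
    Procrustes analysis of the pooled population; the group means, the
    healthy->OA direction and the healthy projection SD (n-1 denominator)
    are computed in that frame.
    """
    spec = alignment_spec or AlignmentSpec()
    if len(healthy_shapes) < 2 or len(oa_shapes) < 2:
        raise InsufficientDataError(
            f"need >= 2 shapes per group (got {len(healthy_shapes)} healthy, "
            f"{len(oa_shapes)} OA)"
        )
    pooled = list(healthy_shapes) + list(oa_shapes)
    aligned, consensus, _ = generalized_procrustes(pooled, spec)
    h = np.stack([s.flat() for s in aligned[: len(healthy_shapes)]])
    o = np.stack([s.flat() for s in aligned[len(healthy_shapes):]])
    mu_h = h.mean(axis=0)
    mu_o = o.mean(axis=0)
    axis = mu_o - mu_h
    norm = np.linalg.norm(axis)
    if norm < 1e-9:
        raise DegenerateAxisError(
            "healthy and OA mean shapes coincide; no axis can be defined"
        )
    v = axis / norm
    proj = (h - mu_h) @ v
    sigma = float(proj.std(ddof=1))
    if sigma <= 0:
        raise DegenerateSpreadError("healthy projections have zero spread")
    return BScoreScale(
        healthy_mean=mu_h,
        direction=v,
        sigma_h=sigma,
        parameterization_id=pooled[0].parameterization_id,
        reference_shape=consensus.flat(),
        alignment_spec=spec,
        n_healthy=len(healthy_shapes),
        n_oa=len(oa_shapes),
    )


def compute_bscore(
    shape: ParameterizedShape, scale: BScoreScale, align: bool = False
) -> BScore:
    """B-score of a corresponded shape.

    The shape is assumed to already sit in the scale's aligned frame; pass
    ``align=True`` for shapes still carrying an arbitrary pose (they are
    Procrustes-aligned onto the scale's reference consensus first).
    """
    if shape.parameterization_id != scale.parameterization_id:
        raise CorrespondenceError(
            f"shape parameterization {shape.parameterization_id!r} != "
            f"scale {scale.parameterization_id!r}"
        )
    pts = shape.points
    if align:
        ref = (
            scale.reference_shape
            if scale.reference_shape is not None
            else scale.healthy_mean
        )
        tr = procrustes_align(
            pts, ref.reshape(-1, 3), allow_scale=scale.alignment_spec.allow_scale
        )
        pts = tr.apply(pts)
    value = float((pts.reshape(-1) - scale.healthy_mean) @ scale.direction
                  / scale.sigma_h)
    if not np.isfinite(value):
        raise ValueError("non-finite B-score")
    if not (TYPICAL_RANGE[0] <= value <= TYPICAL_RANGE[1]):
        warnings.warn(
            f"B-score {value:.2f} outside the typical population band "
            f"{TYPICAL_RANGE}",
            stacklevel=2,
        )
    return BScore(
        value,
        subject_id=shape.subject_id,
        timepoint=shape.timepoint,
        modality=shape.modality,
    )


def bscore_cohort(
    shapes: list[ParameterizedShape], scale: BScoreScale, align: bool = False
) -> list[dict]:
    """Score a whole cohort, capturing per-shape failures as records.

    Returns one record per input shape: ``{"status": "ok", "bscore": ...}``
    or ``{"status": "error", "error": message}`` — failed shapes are
    excluded from analysis but never silently dropped.
    """
    records = []
    for shape in shapes:
        try:
            b = compute_bscore(shape, scale, align=align)
            records.append(
                {
                    "status": "ok",
                    "bscore": b,
                    "subject_id": shape.subject_id,
                    "timepoint": shape.timepoint,
                    "modality": shape.modality,
                }
            )
        except Exception as exc:  # per-shape isolation
            records.append(
                {
                    "status": "error",
                    "error": f"{type(exc).__name__}: {exc}",
                    "subject_id": shape.subject_id,
                    "timepoint": shape.timepoint,
                    "modality": shape.modality,
                }
            )
    return records


# ---------------------------------------------------------------------------
# Serialization (same .npz-with-JSON-header convention as ShapeModel)
# ---------------------------------------------------------------------------

import json  # noqa: E402

_FORMAT_VERSION = 1


def save_scale(scale: BScoreScale, path) -> None:
    meta = {
        "format_version": _FORMAT_VERSION,
        "kind": "bscore_scale",
        "parameterization_id": scale.parameterization_id,
        "sigma_h": scale.sigma_h,
        "n_healthy": scale.n_healthy,
        "n_oa": scale.n_oa,
        "alignment_spec": {
            "allow_scale": scale.alignment_spec.allow_scale,
            "remove_scale": scale.alignment_spec.remove_scale,
        },
    }
    arrays = {
        "meta_json": np.frombuffer(json.dumps(meta).encode("utf-8"), dtype=np.uint8),
        "healthy_mean": scale.healthy_mean,
        "direction": scale.direction,
    }
    if scale.reference_shape is not None:
        arrays["reference_shape"] = scale.reference_shape
    np.savez_compressed(path, **arrays)


def load_scale(path) -> BScoreScale:
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta_json"]).decode("utf-8"))
        if meta.get("format_version") != _FORMAT_VERSION:
            raise ValueError(
                f"unsupported scale archive version {meta.get('format_version')}"
            )
        ref = data["reference_shape"] if "reference_shape" in data else None
        return BScoreScale(
            healthy_mean=data["healthy_mean"],
            direction=data["direction"],
            sigma_h=float(meta["sigma_h"]),
            parameterization_id=meta["parameterization_id"],
            reference_shape=ref,
            alignment_spec=AlignmentSpec(**meta["alignment_spec"]),
            n_healthy=int(meta["n_healthy"]),
            n_oa=int(meta["n_oa"]),
        )
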