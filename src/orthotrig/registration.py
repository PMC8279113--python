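"""Landmark-based rigid "best fit" alignment.

The commercial workflow performs surface best-fit alignment on dense
meshes.  Here the same role is played by exact-correspondence rigid
registration (Kabsch) on the five landmarks per tooth: the final model is
brought into the initial model's space so both can be measured in the one
reference frame built on the initial model.
"""

from __future__ import annotations

import numpy as np

from .errors import DegenerateGeometryError
from .geometry import COLLINEARITY_RTOL, RigidTransform
from .model_io import ArchModel

__all__ = ["kabsch_fit", "whole_arch_align", "apply_transform"]


def kabsch_fit(source, target) -> RigidTransform:
    """Least-squares rigid transform mapping ``source`` onto ``target``.

    Minimises sum ||R s_i + t - t_i||^2 over proper rotations R and
    translations t (reflections are excluded by sign-flipping the smallest
    singular direction when needed).

    Parameters
    ----------
    source, target : (n, 3) array-like
        Corresponding point sets, n >= 3, not collinear.
    """
    src = np.asarray(source, float)
    tgt = np.asarray(target, float)
    if src.shape != tgt.shape or src.ndim != 2 or src.shape[1] != 3:
        raise DegenerateGeometryError("point lists must both be (n, 3)")
    if src.shape[0] < 3:
        raise DegenerateGeometryError("rigid fit needs at least 3 correspondences")
    sc, tc = src.mean(axis=0), tgt.mean(axis=0)
    H = (src - sc).T @ (tgt - tc)
    U, s, Vt = np.linalg.svd(H)
    if s[1] < COLLINEARITY_RTOL * max(s[0], 1e-300):
        raise DegenerateGeometryError(
            "cross-covariance is rank deficient (collinear correspondences)"
        )
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return RigidTransform(R, tc - R @ sc)


def whole_arch_align(
    initial: ArchModel,
    final: ArchModel,
    exclude: set[int] | frozenset[int] = frozenset({17, 27, 37, 47}),
) -> RigidTransform:
    """Best-fit transform carrying the final model into the initial's space.

    Runs :func:`kabsch_fit` over the concatenated five landmarks of all
    teeth shared by both models and not in ``exclude`` (default: second
    molars, mirroring the reference-plane policy).
    """
    exclude = {int(t) for t in exclude}
    shared = [
        fdi
        for fdi in initial.teeth
        if fdi in final.teeth and fdi not in exclude
    ]
    if len(shared) < 3:
        raise DegenerateGeometryError(
            f"whole-arch alignment needs >= 3 shared teeth (got {len(shared)})"
        )
    tgt = np.concatenate([initial.teeth[f].points() for f in shared])
    src = np.concatenate([final.teeth[f].points() for f in shared])
    return kabsch_fit(src, tgt)


def apply_transform(t: RigidTransform, model: ArchModel) -> ArchModel:
    """Map every landmark of ``model`` by p -> R p + t (identities kept)."""
    return model.map_points(t.apply)
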