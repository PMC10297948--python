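"""Alignment of sequential-IHC staining rounds.

Each staining round of a sequential-IHC experiment is acquired after the
slide has been destained, re-stained and re-mounted, so rounds are related
by a global rigid/affine motion plus a smooth elastic deformation (tissue
swelling during washing).  Registration proceeds in two steps, always on
the hematoxylin concentration channel (the counterstain is the only
modality shared across rounds): a global transform from intensity MSE
minimization (:func:`estimate_affine`), then a dense elastic refinement
from regularized iterative Lucas-Kanade optical flow
(:func:`elastic_refine`).

Transform convention
--------------------
A :class:`Transform` is the *sampling map* ``V`` used to pull the moving
image onto the fixed grid: ``warped(x) = moving(V(x))`` with
``V(x) = A @ [x + d(x), 1]`` — displacement field first, then affine, in
(row, col) coordinates.  Composing an estimated transform with
``warp`` therefore aligns the moving image to the fixed one, and ground
truth for a synthetic distortion is the *inverse* of the sampling map used
to distort (see :meth:`Transform.invert`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize
from skimage.registration import optical_flow_ilk, phase_cross_correlation
from skimage.transform import pyramid_gaussian

__all__ = [
    "Transform",
    "estimate_affine",
    "elastic_refine",
    "warp",
    "landmark_error",
    "random_transform",
    "register_rounds",
]


def _identity_affine() -> np.ndarray:
    return np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])


@dataclass
class Transform:
    """Sampling map: affine 2x3 plus optional dense displacement field.

    ``field`` has shape (H, W, 2) with (d_row, d_col) per fixed-grid pixel.
    """

    affine: np.ndarray = field(default_factory=_identity_affine)
    field: np.ndarray | None = None

    def __post_init__(self):
        a = np.asarray(self.affine, float)
        if a.shape != (2, 3):
            raise ValueError(f"affine must be 2x3, got {a.shape}")
        if abs(np.linalg.det(a[:, :2])) < 1e-12:
            raise ValueError("affine is singular")
        if self.field is not None and not np.all(np.isfinite(self.field)):
            raise ValueError("displacement field has non-finite values")
        self.affine = a

    @property
    def is_identity(self) -> bool:
        return self.field is None and np.allclose(self.affine, _identity_affine())

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map points (N, 2) in (row, col) through the sampling map."""
        pts = np.atleast_2d(np.asarray(points, float))
        if self.field is not None:
            d = np.stack(
                [ndimage.map_coordinates(self.field[..., k], pts.T, order=1,
                                         mode="nearest") for k in range(2)],
                axis=1)
            pts = pts + d
        return pts @ self.affine[:, :2].T + self.affine[:, 2]

    def coordinate_grid(self, shape) -> np.ndarray:
        """Evaluate the map on every pixel of ``shape``; returns (2, H, W)."""
        rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]),
                             indexing="ij")
        base = np.stack([rr, cc]).astype(float)
        if self.field is not None:
            base = base + np.moveaxis(self.field, -1, 0)
        lin, t = self.affine[:, :2], self.affine[:, 2]
        return np.einsum("ij,jhw->ihw", lin, base) + t[:, None, None]

    def compose(self, inner: "Transform", shape) -> "Transform":
        """Return the transform equivalent to applying ``self`` after
        ``inner`` as image operations: warp(warp(img, self), inner) ==
        warp(img, composed).  Represented as a pure displacement field on
        ``shape`` (exact at grid nodes, bilinear between)."""
        grid_inner = inner.coordinate_grid(shape)
        grid_self = self.coordinate_grid(shape)
        out = np.stack(
            [ndimage.map_coordinates(grid_self[k], grid_inner, order=1,
                                     mode="nearest")
             for k in range(2)])
        rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]),
                             indexing="ij")
        fld = np.moveaxis(out - np.stack([rr, cc]), 0, -1)
        return Transform(field=fld)

    def invert(self, shape, n_iter: int = 30) -> "Transform":
        """Numerically invert the sampling map on the given grid.

        Fixed-point iteration ``y <- y - (V(y) - x)``; converges for the
        smooth, moderate-magnitude deformations this pipeline produces.
        """
        rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]),
                             indexing="ij")
        x = np.stack([rr, cc]).astype(float)
        grid = self.coordinate_grid(shape)
        y = x.copy()
        for _ in range(n_iter):
            vy = np.stack(
                [ndimage.map_coordinates(grid[k], y, order=1, mode="nearest")
                 for k in range(2)])
            y = y - 0.8 * (vy - x)
        return Transform(field=np.moveaxis(y - x, 0, -1))


def warp(image: np.ndarray, transform: Transform, order: int = 1,
         background: float = 255.0) -> np.ndarray:
    """Resample ``image`` through a transform (bilinear by default).

    Out-of-bounds samples are filled with ``background`` (white, matching
    bright-field slides)."""
    image = np.asarray(image, float)
    if transform.is_identity:
        return image.copy()
    coords = transform.coordinate_grid(image.shape[:2])
    if image.ndim == 3:
        return np.stack(
            [ndimage.map_coordinates(image[..., c], coords, order=order,
                                     mode="constant", cval=background)
             for c in range(image.shape[2])], axis=-1)
    return ndimage.map_coordinates(image, coords, order=order,
                                   mode="constant", cval=background)


def landmark_error(true_transform: Transform, estimated_transform: Transform,
                   landmarks: np.ndarray) -> float:
    """Mean Euclidean distance between the two maps over the landmarks."""
    a = true_transform.apply(landmarks)
    b = estimated_transform.apply(landmarks)
    return float(np.mean(np.linalg.norm(a - b, axis=1)))


def _normalize(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, float)
    sd = img.std()
    if sd == 0:
        raise ValueError("blank image (zero variance)")
    return (img - img.mean()) / sd


def _rigid_affine(theta: float, t: np.ndarray, center: np.ndarray) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    lin = np.array([[c, -s], [s, c]])
    trans = center - lin @ center + t
    return np.hstack([lin, trans[:, None]])


def _mse_after(fixed, moving, affine):
    coords = Transform(affine=affine).coordinate_grid(fixed.shape)
    w = ndimage.map_coordinates(moving, coords, order=1, mode="constant",
                                cval=np.nan)
    valid = np.isfinite(w)
    if valid.mean() < 0.25:
        return np.inf
    return float(np.nanmean((fixed - np.where(valid, w, 0.0)) ** 2
                            * valid) / valid.mean())


def estimate_affine(fixed: np.ndarray, moving: np.ndarray,
                    mode: str = "rigid") -> Transform:
    """Estimate a global transform mapping the fixed grid into ``moving``.

    ``translation`` uses spectral cross-correlation with sub-pixel
    refinement; ``rigid`` and ``affine`` minimize mean-squared intensity
    error over a 3-level Gaussian pyramid (Powell search), seeded by the
    translation estimate.
    """
    if mode not in ("translation", "rigid", "affine"):
        raise ValueError(f"unknown mode {mode!r}")
    fixed_n = _normalize(fixed)
    moving_n = _normalize(moving)

    shift, _, _ = phase_cross_correlation(fixed_n, moving_n,
                                          upsample_factor=20,
                                          normalization=None)
    # phase_cross_correlation returns the shift of moving relative to fixed;
    # the sampling map needs the opposite sign: moving(x - shift) ~ fixed(x).
    t0 = -np.asarray(shift, float)
    if mode == "translation":
        aff = _identity_affine()
        aff[:, 2] = t0
        return Transform(affine=aff)

    center = (np.asarray(fixed.shape, float) - 1) / 2
    pyramids = list(zip(
        pyramid_gaussian(fixed_n, max_layer=2, downscale=2,
                         preserve_range=True),
        pyramid_gaussian(moving_n, max_layer=2, downscale=2,
                         preserve_range=True)))
    if mode == "rigid":
        params = np.array([0.0, *t0])
    else:
        params = np.array([0.0, 0.0, 1.0, 1.0, *t0])

    for level in range(len(pyramids) - 1, -1, -1):
        f_l, m_l = pyramids[level]
        scale = 2.0 ** level
        c_l = center / scale

        if mode == "rigid":
            def cost(p):
                aff = _rigid_affine(p[0], np.array(p[1:]) / scale, c_l)
                return _mse_after(f_l, m_l, aff)
        else:
            def cost(p):
                theta, shear, sy, sx = p[0], p[1], p[2], p[3]
                c, s = np.cos(theta), np.sin(theta)
                lin = np.array([[c, -s], [s, c]]) @ np.array(
                    [[sy, shear], [0.0, sx]])
                trans = c_l - lin @ c_l + np.array(p[4:]) / scale
                return _mse_after(f_l, m_l, np.hstack([lin, trans[:, None]]))

        res = optimize.minimize(cost, params, method="Powell",
                                options={"xtol": 1e-4, "ftol": 1e-6,
                                         "maxiter": 200})
        params = res.x

    if mode == "rigid":
        aff = _rigid_affine(params[0], np.asarray(params[1:]), center)
    else:
        theta, shear, sy, sx = params[0], params[1], params[2], params[3]
        c, s = np.cos(theta), np.sin(theta)
        lin = np.array([[c, -s], [s, c]]) @ np.array([[sy, shear], [0.0, sx]])
        trans = center - lin @ center + np.asarray(params[4:])
        aff = np.hstack([lin, trans[:, None]])
    return Transform(affine=aff)


def elastic_refine(fixed: np.ndarray, moving: np.ndarray,
                   grid_spacing: int = 16, regularization: float = 4.0,
                   prior: Transform | None = None) -> Transform:
    """Dense elastic refinement of a pre-aligned pair.

    Runs iterative Lucas-Kanade optical flow (window radius
    ``grid_spacing``) between the fixed image and the prior-warped moving
    image, Gaussian-smooths the flow (sigma ``regularization``) as an
    explicit smoothness penalty, and composes it with the prior.  If the
    refinement does not reduce MSE, the prior is returned unchanged
    (monotonicity contract).
    """
    if grid_spacing <= 0:
        raise ValueError("grid_spacing must be positive")
    fixed = np.asarray(fixed, float)
    moving = np.asarray(moving, float)
    prior = prior or Transform()
    pre = warp(moving, prior, background=float(np.median(moving)))
    mse_before = float(np.mean((fixed - pre) ** 2))

    flow = optical_flow_ilk(fixed, pre, radius=int(grid_spacing),
                            gaussian=True, prefilter=True)
    if regularization > 0:
        flow = np.stack([ndimage.gaussian_filter(flow[k], regularization)
                         for k in range(2)])
    refined = prior.compose(Transform(field=np.moveaxis(flow, 0, -1)),
                            fixed.shape) if not prior.is_identity else \
        Transform(field=np.moveaxis(flow, 0, -1))

    post = warp(moving, refined, background=float(np.median(moving)))
    if float(np.mean((fixed - post) ** 2)) > mse_before:
        return prior
    return refined


def register_rounds(fixed: np.ndarray, moving: np.ndarray,
                    mode: str = "rigid", grid_spacing: int = 16,
                    regularization: float = 4.0) -> Transform:
    """Full chain: global estimate then elastic refinement."""
    global_t = estimate_affine(fixed, moving, mode=mode)
    return elastic_refine(fixed, moving, grid_spacing=grid_spacing,
                          regularization=regularization, prior=global_t)


def random_transform(shape, rng: np.random.Generator,
                     max_shift: float = 10.0, max_rotation_deg: float = 2.0,
                     elastic_magnitude: float = 8.0,
                     elastic_smoothness: float = 40.0,
                     max_magnitude: float = 15.0) -> Transform:
    """Sample a plausible inter-round distortion (rigid + smooth elastic).

    The elastic part is Gaussian-filtered white noise rescaled so its
    maximum displacement magnitude equals ``elastic_magnitude`` (must stay
    below ``max_magnitude``, the regime the registration chain is designed
    for)."""
    if elastic_magnitude >= max_magnitude:
        raise ValueError("elastic magnitude exceeds the supported bound")
    theta = np.deg2rad(rng.uniform(-max_rotation_deg, max_rotation_deg))
    t = rng.uniform(-max_shift, max_shift, size=2)
    center = (np.asarray(shape, float) - 1) / 2
    affine = _rigid_affine(theta, t, center)
    fld = None
    if elastic_magnitude > 0:
        noise = rng.standard_normal((2,) + tuple(shape))
        sm = np.stack([ndimage.gaussian_filter(noise[k], elastic_smoothness)
                       for k in range(2)])
        mag = np.linalg.norm(sm, axis=0).max()
        if mag > 0:
            sm *= elastic_magnitude / mag
        fld = np.moveaxis(sm, 0, -1)
    return Transform(affine=affine, field=fld)
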