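"""Sigmoid margin sharpness features.

For each sampled surface voxel a line is cast along the outward surface
normal covering +/- L mm (L in {3, 5, 7}); intensity is sampled at sub-voxel
steps and fit by least squares to a logistic s(t) = a + b / (1 + exp(-(t-c)/w)).
The margin slope of a line is b/(4w), the maximum derivative of the fitted
sigmoid; per L the features are the mean and SD of the slope over fitted
lines.  Fitting is deterministic (fixed initialization, no randomness).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from radrep.features._base import FeatureValue, fail_all
from radrep.features.shape import surface_voxels

HALF_LENGTHS = (3.0, 5.0, 7.0)
STEP_MM = 0.5
#: deterministic cap on sampled surface lines; keeps large nodules tractable
MAX_LINES = 96
_MAX_ITER = 200
_FTOL = 1e-10


def margin_names(half_lengths=HALF_LENGTHS):
    return [f"margin.L{int(L)}.slope_{s}" for L in half_lengths for s in ("mean", "sd")]


def _sigmoid(t, a, b, c, w):
    return a + b / (1.0 + np.exp(np.clip(-(t - c) / w, -500, 500)))


def _lm_fit(t: np.ndarray, y: np.ndarray, p0) -> np.ndarray:
    """Damped Levenberg-Marquardt for the 4-parameter logistic.

    Self-contained with an analytic Jacobian and a fixed iteration policy so
    that identical inputs always yield bit-identical parameters.
    """
    p = np.asarray(p0, dtype=np.float64)
    resid = _sigmoid(t, *p) - y
    cost = float(resid @ resid)
    lam = 1e-3
    for _ in range(_MAX_ITER):
        a, b, c, w = p
        z = np.clip((t - c) / w, -500, 500)
        s = 1.0 / (1.0 + np.exp(-z))
        ds = s * (1.0 - s)
        J = np.column_stack([
            np.ones_like(t),
            s,
            -b * ds / w,
            -b * ds * (t - c) / (w * w),
        ])
        g = J.T @ resid
        H = J.T @ J
        stepped = False
        for _ in range(20):
            A = H + lam * np.diag(np.maximum(np.diag(H), 1e-12))
            try:
                delta = np.linalg.solve(A, -g)
            except np.linalg.LinAlgError:
                lam *= 10.0
                continue
            p_try = p + delta
            if abs(p_try[3]) < 1e-6:  # keep the width away from the pole
                p_try[3] = 1e-6 if p_try[3] >= 0 else -1e-6
            r_try = _sigmoid(t, *p_try) - y
            c_try = float(r_try @ r_try)
            if np.isfinite(c_try) and c_try <= cost:
                improved = cost - c_try
                p, resid, cost = p_try, r_try, c_try
                lam = max(lam / 3.0, 1e-12)
                stepped = True
                if improved <= _FTOL * (cost + 1e-30):
                    return p
                break
            lam *= 2.0
        if not stepped:
            return p  # damping exhausted: accept the current stationary point
    return p


def _fit_line(t: np.ndarray, y: np.ndarray, L: float) -> float | None:
    """Fit one sampling line; return the slope b/(4w), or None if degenerate.

    Deterministic initialization: a = line minimum, b = line range, c = 0
    (the surface crossing), w = 1 mm.  Fits whose inflection point leaves
    the sampled window or whose width degenerates below the sampling
    resolution are counted as non-converged.
    """
    rng_y = float(y.max() - y.min())
    if rng_y < 1e-6:
        return None
    _, b, c, w = _lm_fit(t, y, (float(y.min()), rng_y, 0.0, 1.0))
    if not np.isfinite(w) or abs(w) < 0.02 or abs(w) > 2 * L or abs(c) > L:
        return None
    # (b, w) -> (-b, -w) is the same curve, and b/(4w) is invariant to it
    return float(b / (4.0 * w))


def sigmoid_margin_features(volume: np.ndarray, mask: np.ndarray, spacing,
                            half_lengths=HALF_LENGTHS,
                            max_lines: int = MAX_LINES) -> dict[str, FeatureValue]:
    """Mean and SD of the fitted margin slope at each sampling half-length.

    Surface normals come from the gradient of the Gaussian-smoothed mask
    (sigma = 1 voxel).  If more than half the lines fail to fit (or are
    degenerate, e.g. a uniform volume), the two statistics for that length
    are FAILED(fit_nonconvergence); a single-voxel mask has no defined
    normals and fails with too_few_voxels.
    """
    names = margin_names(half_lengths)
    mask = np.asarray(mask) > 0
    if not mask.any():
        return fail_all(names, "empty_roi")
    surf = surface_voxels(mask)
    if mask.sum() < 2 or len(surf) < 2:
        return fail_all(names, "too_few_voxels")
    if len(surf) > max_lines:
        # deterministic uniform thinning in lexicographic surface order
        idx = np.linspace(0, len(surf) - 1, max_lines).round().astype(int)
        surf = surf[idx]

    spacing = np.asarray(spacing, dtype=float)
    smoothed = ndimage.gaussian_filter(mask.astype(np.float64), sigma=1.0)
    grads = np.stack(np.gradient(smoothed), axis=-1)  # index-space gradient

    out: dict[str, FeatureValue] = {}
    for L in half_lengths:
        t = np.arange(-L, L + STEP_MM / 2, STEP_MM)
        slopes = []
        n_attempted = 0
        for vox in surf:
            g = grads[tuple(vox)] / spacing  # physical-space gradient
            norm = np.linalg.norm(g)
            if norm < 1e-12:
                continue
            direction = -g / norm  # outward: against the mask gradient
            pts_mm = vox * spacing + t[:, None] * direction
            coords = (pts_mm / spacing).T
            inside = np.all((coords >= 0) & (coords <= (np.array(mask.shape) - 1)[:, None]),
                            axis=0)
            if inside.sum() < 8:
                continue
            y = ndimage.map_coordinates(volume, coords[:, inside], order=1)
            n_attempted += 1
            slope = _fit_line(t[inside], y, L)
            if slope is not None:
                slopes.append(slope)
        if n_attempted == 0 or len(slopes) <= 0.5 * n_attempted:
            out[f"margin.L{int(L)}.slope_mean"] = FeatureValue.fail("fit_nonconvergence")
            out[f"margin.L{int(L)}.slope_sd"] = FeatureValue.fail("fit_nonconvergence")
        else:
            s = np.asarray(slopes)
            out[f"margin.L{int(L)}.slope_mean"] = FeatureValue.ok(s.mean())
            out[f"margin.L{int(L)}.slope_sd"] = FeatureValue.ok(s.std())
    return out
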