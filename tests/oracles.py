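"""Independent oracles used to cross-check the implementation.

These deliberately use different algorithms from the package: superposition
via Horn's quaternion eigenproblem (the package uses SVD Kabsch), and
correlation/OLS via direct closed-form arithmetic (the package delegates to
scipy/numpy fitting routines).
"""

from __future__ import annotations

import math

import numpy as np


def quaternion_superpose(ref: np.ndarray, mov: np.ndarray) -> np.ndarray:
    """Per-residue deviations after an optimal rigid fit, by Horn's method.

    Builds the 4x4 symmetric key matrix from the coordinate correlation
    matrix; the eigenvector of the largest eigenvalue is the optimal unit
    quaternion.
    """
    ref_c = ref - ref.mean(axis=0)
    mov_c = mov - mov.mean(axis=0)
    s = mov_c.T @ ref_c
    sxx, sxy, sxz = s[0]
    syx, syy, syz = s[1]
    szx, szy, szz = s[2]
    key = np.array(
        [
            [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
            [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
            [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
            [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
        ]
    )
    eigvals, eigvecs = np.linalg.eigh(key)
    q = eigvecs[:, -1]
    w, x, y, z = q
    rot = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    fitted = mov_c @ rot.T + ref.mean(axis=0)
    return np.linalg.norm(fitted - ref, axis=1)


def pearson_direct(x, y) -> float:
    """Product-moment r by the covariance/sigma-sigma definition, plain loops."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    vx = sum((a - mx) ** 2 for a in x)
    vy = sum((b - my) ** 2 for b in y)
    return cov / math.sqrt(vx * vy)


def ols_normal_equations(x, y) -> tuple[float, float]:
    """Least-squares slope/intercept from the 2x2 normal equations."""
    n = len(x)
    sx = sum(x)
    sy = sum(y)
    sxx = sum(a * a for a in x)
    sxy = sum(a * b for a, b in zip(x, y))
    denom = n * sxx - sx * sx
    slope = (n * sxy - sx * sy) / denom
    intercept = (sy - slope * sx) / n
    return slope, intercept


def random_trace_pair(rng: np.random.Generator, n: int) -> tuple[np.ndarray, np.ndarray]:
    """A random reference and a noisy rigidly-moved copy, as coordinate arrays."""
    ref = rng.normal(scale=5.0, size=(n, 3))
    mov = ref + rng.normal(scale=0.5, size=(n, 3))
    # apply a random proper rigid motion to the moving copy
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = rng.uniform(0, 2 * math.pi)
    k = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    rot = np.eye(3) + math.sin(angle) * k + (1 - math.cos(angle)) * (k @ k)
    mov = mov @ rot.T + rng.normal(scale=10.0, size=3)
    return ref, mov
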