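"""Small shared numerics: seeding, spherical geometry, alignment helpers."""

from __future__ import annotations

import numpy as np

__all__ = [
    "rng_from",
    "spawn_rngs",
    "great_circle_distance",
    "morans_i",
    "pearson",
]


def rng_from(seed) -> np.random.Generator:
    """Accept an int seed, SeedSequence, or Generator and return a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def spawn_rngs(seed: int, names: list[str]) -> dict[str, np.random.Generator]:
    """Named independent substreams from one master seed."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def great_circle_distance(xyz_a: np.ndarray, xyz_b: np.ndarray | None = None) -> np.ndarray:
    """Pairwise great-circle distances (radians) between unit vectors."""
    a = np.asarray(xyz_a, dtype=float)
    b = a if xyz_b is None else np.asarray(xyz_b, dtype=float)
    dots = np.clip(a @ b.T, -1.0, 1.0)
    return np.arccos(dots)


def morans_i(values: np.ndarray, weights: np.ndarray) -> float:
    """Moran's I spatial autocorrelation with a given (zero-diagonal) weight matrix."""
    x = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    n = x.size
    z = x - x.mean()
    denom = (z**2).sum()
    if denom == 0:
        return 0.0
    num = z @ w @ z
    return float(n / w.sum() * num / denom)


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation; 0.0 if either input is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt((xc**2).sum())
    sy = np.sqrt((yc**2).sum())
    if sx == 0 or sy == 0:
        return 0.0
    return float(xc @ yc / (sx * sy))
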