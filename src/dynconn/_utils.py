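"""Shared helpers: edge vectorization, Fisher transform, seeding."""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np

#: cap on |Fisher z| so perfect correlations stay finite downstream
Z_CAP = 6.0


def upper_edge_index(n_regions: int) -> list[tuple[int, int]]:
    """Ordered (i, j) pairs, i < j, row-major over the upper triangle."""
    iu = np.triu_indices(n_regions, k=1)
    return list(zip(iu[0].tolist(), iu[1].tolist()))


def vec_upper(mat: np.ndarray) -> np.ndarray:
    """Row-major upper-triangle (i<j) vectorization of a square matrix."""
    iu = np.triu_indices(mat.shape[-1], k=1)
    return np.asarray(mat)[..., iu[0], iu[1]]


def unvec_upper(vec: np.ndarray, n_regions: int) -> np.ndarray:
    """Inverse of :func:`vec_upper`; diagonal set to 0."""
    out = np.zeros((n_regions, n_regions), dtype=float)
    iu = np.triu_indices(n_regions, k=1)
    out[iu] = vec
    out += out.T
    return out


def fisher_z(r: np.ndarray, z_cap: float = Z_CAP) -> np.ndarray:
    """arctanh with the argument clipped so |z| <= z_cap."""
    r_max = np.tanh(z_cap)
    return np.arctanh(np.clip(r, -r_max, r_max))


def check_random_state(seed) -> np.random.Generator:
    """Accept None, an int seed, or an existing Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def spawn_seed(rng: np.random.Generator) -> int:
    """Draw a child seed below 2**31 from an existing generator."""
    return int(rng.integers(0, 2**31 - 1))


def file_sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
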