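"""Structural connectome construction, validation and I/O.

The transport substrate is a weighted, symmetric, nonnegative adjacency
matrix over the atlas regions, built by averaging per-subject fibre-count
matrices, symmetrizing, normalizing by the maximum entry and removing weak
edges below a cutoff.  Disconnection is a hard error: the steady-state
theory requires a single connected component (single zero eigenvalue of the
graph Laplacian).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .atlas import RegionAtlas

__all__ = ["Connectome", "ConnectomeError", "build_connectome", "load_connectome"]

_SYMMETRY_RTOL = 1e-12


class ConnectomeError(ValueError):
    pass


@dataclass(frozen=True)
class Connectome:
    """Normalized symmetric structural connectivity aligned to an atlas.

    ``W[i, j]`` is the (dimensionless) fibre weight between regions i and j
    after averaging, symmetrization, division by the maximum entry and
    cutoff filtering; the diagonal is zero and the maximum entry is exactly 1.
    """

    atlas: RegionAtlas
    W: np.ndarray
    cutoff: float = 0.01

    def __post_init__(self):
        W = np.asarray(self.W, dtype=float)
        object.__setattr__(self, "W", W)
        _validate(W, self.cutoff, self.atlas)

    @property
    def n_regions(self) -> int:
        return self.W.shape[0]

    def degrees(self) -> np.ndarray:
        return self.W.sum(axis=0)


def _components(W: np.ndarray):
    n, labels = connected_components(csr_matrix(W != 0), directed=False)
    return n, labels


def _validate(W: np.ndarray, cutoff: float, atlas: RegionAtlas) -> None:
    n = atlas.n_regions
    if W.shape != (n, n):
        raise ConnectomeError(f"matrix shape {W.shape} does not match atlas ({n} regions)")
    if not np.all(np.isfinite(W)):
        raise ConnectomeError("non-finite connectivity weights")
    if np.any(W < 0):
        raise ConnectomeError("negative connectivity weights")
    if not np.allclose(W, W.T, rtol=_SYMMETRY_RTOL, atol=0.0):
        raise ConnectomeError("connectivity matrix not symmetric")
    if np.any(np.diag(W) != 0):
        raise ConnectomeError("nonzero diagonal")
    mx = W.max()
    if not np.isclose(mx, 1.0, rtol=1e-9):
        raise ConnectomeError(f"matrix not normalized (max entry {mx})")
    nz = W[W != 0]
    if nz.size and nz.min() <= cutoff:
        raise ConnectomeError(f"entries at or below cutoff {cutoff} present")
    ncomp, labels = _components(W)
    if ncomp != 1:
        names = np.asarray(atlas.region_names)
        comps = [sorted(names[labels == c]) for c in range(ncomp)]
        raise ConnectomeError(
            f"graph has {ncomp} connected components: "
            + "; ".join(str(c[:4]) + ("..." if len(c) > 4 else "") for c in comps)
        )


def build_connectome(
    matrices: Sequence[np.ndarray],
    cutoff: float = 0.01,
    atlas: RegionAtlas = None,
) -> Connectome:
    """Average, symmetrize, normalize and threshold raw adjacency matrices.

    Pipeline: element-wise average over ``matrices`` -> (M + M.T)/2 -> zero
    the diagonal -> divide by the maximum entry -> zero all entries <= cutoff.
    An entry survives only if strictly greater than ``cutoff``.
    """
    if atlas is None:
        raise ValueError("atlas is required")
    if len(matrices) == 0:
        raise ValueError("no matrices given")
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    n = atlas.n_regions
    acc = np.zeros((n, n), dtype=float)
    for M in matrices:
        M = np.asarray(M, dtype=float)
        if M.shape != (n, n):
            raise ConnectomeError(f"matrix shape {M.shape} does not match atlas ({n})")
        if np.any(M < 0) or not np.all(np.isfinite(M)):
            raise ConnectomeError("matrices must be finite and nonnegative")
        acc += M
    acc /= len(matrices)
    W = (acc + acc.T) / 2.0
    np.fill_diagonal(W, 0.0)
    mx = W.max()
    if mx == 0:
        raise ConnectomeError("all-zero connectivity after symmetrization")
    W = W / mx
    W[W <= cutoff] = 0.0
    # thresholding may have removed the (former) maximum's rivals but the
    # max itself is 1 > cutoff for any cutoff < 1, so normalization holds
    return Connectome(atlas=atlas, W=W, cutoff=cutoff)


def load_connectome(path, atlas: RegionAtlas) -> Connectome:
    """Read an already-normalized connectome CSV (region-name header row and
    first column), reordering rows/columns to atlas order."""
    df = pd.read_csv(path, index_col=0)
    names = list(atlas.region_names)
    missing = sorted(set(names) - set(df.index) | set(names) - set(df.columns))
    extra = sorted((set(df.index) | set(df.columns)) - set(names))
    if missing or extra:
        raise ConnectomeError(
            f"region names do not match atlas (missing {missing[:6]}, unknown {extra[:6]})"
        )
    df = df.loc[names, names]
    W = df.to_numpy(dtype=float)
    if not np.allclose(W, W.T, rtol=_SYMMETRY_RTOL, atol=0.0):
        raise ConnectomeError("asymmetry beyond tolerance in connectome file; "
                              "rebuild with build_connectome")
    return Connectome(atlas=atlas, W=W)


def save_connectome(conn: Connectome, path) -> None:
    names = list(conn.atlas.region_names)
    pd.DataFrame(conn.W, index=names, columns=names).to_csv(path)
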