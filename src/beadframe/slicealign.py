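"""Serial-section registration from bead tracks via a weighted sparse solve.

Consecutive slice catalogs are crossmatched by mutual nearest neighbors,
matches are chained into unique bead tracks, and tracks seen in fewer than
two physical slices are discarded (removing almost all spurious
contaminants). Every within-track observation pair (i, j) constrains the
difference of the absolute slice offsets, ``x_j - x_i = D_j - D_i + noise``,
giving an overdetermined linear system ``d = C @ Delta`` that is sparse and
solved independently for x and y by weighted least squares, with the
reference slice pinned to (0, 0). Each slice needs of order >=20 usable
beads for sub-pixel registration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse import csgraph
from scipy.spatial import cKDTree

__all__ = [
    "match_consecutive",
    "build_tracks",
    "solve_offsets",
    "apply_offsets",
    "read_offsets",
    "SliceOffsetSolution",
    "DisconnectedSlicesError",
]


class DisconnectedSlicesError(ValueError):
    def __init__(self, components):
        self.components = components
        super().__init__(
            f"slice graph is disconnected; components: {components}")


@dataclass
class SliceOffsetSolution:
    offsets: np.ndarray          # (n_slices, 2), px; reference slice == (0, 0)
    uncertainty: np.ndarray      # (n_slices, 2) formal 1-sigma, px
    residual_rms: float
    n_pairs: int
    reference_slice: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(dict(slice=np.arange(len(self.offsets)),
                                 dx=self.offsets[:, 0], dy=self.offsets[:, 1],
                                 err_x=self.uncertainty[:, 0],
                                 err_y=self.uncertainty[:, 1]))


def match_consecutive(catalog_i: pd.DataFrame, catalog_j: pd.DataFrame,
                      radius: float) -> pd.DataFrame:
    """Mutual-nearest-neighbor bead matches between two slice catalogs.

    Each bead is matched at most once; ties (two beads exactly equidistant
    from one target) are broken toward the smaller label/row id. Catalogs
    need columns ``x, y`` (px); a ``center_err`` column, if present, feeds
    the pair weights (inverse summed variance).
    """
    if len(catalog_i) == 0 or len(catalog_j) == 0:
        return pd.DataFrame(columns=["i", "j", "dx", "dy", "dist", "weight"])
    pi = catalog_i[["x", "y"]].to_numpy(float)
    pj = catalog_j[["x", "y"]].to_numpy(float)
    tree_j = cKDTree(pj)
    tree_i = cKDTree(pi)
    d_ij, nn_ij = tree_j.query(pi, k=1, distance_upper_bound=radius)
    d_ji, nn_ji = tree_i.query(pj, k=1, distance_upper_bound=radius)

    rows = []
    order = np.argsort(np.arange(len(pi)))  # ascending id = deterministic tie-break
    for a in order:
        b = nn_ij[a]
        if not np.isfinite(d_ij[a]) or b >= len(pj):
            continue
        if nn_ji[b] != a:
            continue
        ei = float(catalog_i["center_err"].iloc[a]) if "center_err" in catalog_i else 1.0
        ej = float(catalog_j["center_err"].iloc[b]) if "center_err" in catalog_j else 1.0
        rows.append(dict(i=int(a), j=int(b),
                         dx=float(pj[b, 0] - pi[a, 0]),
                         dy=float(pj[b, 1] - pi[a, 1]),
                         dist=float(d_ij[a]),
                         weight=1.0 / (ei ** 2 + ej ** 2)))
    return pd.DataFrame(rows, columns=["i", "j", "dx", "dy", "dist", "weight"])


def build_tracks(catalogs: list[pd.DataFrame], radius: float,
                 min_slices: int = 2) -> pd.DataFrame:
    """Chain consecutive-slice matches into unique bead tracks.

    Returns a long table ``(track_id, slice, x, y, weight)``; tracks
    observed in fewer than ``min_slices`` physical slices are dropped.
    """
    # union-find over (slice, row) observation nodes
    parent: dict[tuple[int, int], tuple[int, int]] = {}

    def find(n):
        while parent.setdefault(n, n) != n:
            parent[n] = parent[parent[n]]
            n = parent[n]
        return n

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    for s in range(len(catalogs) - 1):
        m = match_consecutive(catalogs[s], catalogs[s + 1], radius)
        for r in m.itertuples():
            union((s, r.i), (s + 1, r.j))

    groups: dict[tuple[int, int], list[tuple[int, int]]] = {}
    for s, cat in enumerate(catalogs):
        for row in range(len(cat)):
            groups.setdefault(find((s, row)), []).append((s, row))

    rows = []
    tid = 0
    for members in groups.values():
        slices = {s for s, _ in members}
        if len(slices) < min_slices:
            continue
        for s, r in sorted(members):
            cat = catalogs[s]
            err = float(cat["center_err"].iloc[r]) if "center_err" in cat else 1.0
            rows.append(dict(track_id=tid, slice=s,
                             x=float(cat["x"].iloc[r]), y=float(cat["y"].iloc[r]),
                             weight=1.0 / err ** 2))
        tid += 1
    return pd.DataFrame(rows, columns=["track_id", "slice", "x", "y", "weight"])


def solve_offsets(tracks: pd.DataFrame, n_slices: int,
                  reference_slice: int = 0,
                  use_sparse: bool = True) -> SliceOffsetSolution:
    """Weighted least-squares solve of ``d = C @ Delta`` for the slice offsets.

    Rows are all within-track observation pairs; the x and y systems share
    the coefficient matrix and are solved independently. The gauge is fixed
    by pinning the reference slice to (0, 0).

    Raises :class:`DisconnectedSlicesError` when the pair graph does not
    connect all slices, listing the connected groups.
    """
    rows_i, rows_j, dx, dy, wts = [], [], [], [], []
    for _, g in tracks.groupby("track_id"):
        g = g.sort_values("slice")
        s = g["slice"].to_numpy()
        xs = g["x"].to_numpy()
        ys = g["y"].to_numpy()
        w = g["weight"].to_numpy()
        for a in range(len(g)):
            for b in range(a + 1, len(g)):
                rows_i.append(s[a])
                rows_j.append(s[b])
                dx.append(xs[b] - xs[a])
                dy.append(ys[b] - ys[a])
                # pair variance = sum of the two observation variances
                wts.append(1.0 / (1.0 / w[a] + 1.0 / w[b]))
    n_pairs = len(dx)
    if n_pairs == 0:
        raise ValueError("no usable track pairs")
    rows_i = np.asarray(rows_i)
    rows_j = np.asarray(rows_j)

    # connectivity of the slice graph
    adj = sparse.coo_matrix((np.ones(n_pairs), (rows_i, rows_j)),
                            shape=(n_slices, n_slices))
    n_comp, labels = csgraph.connected_components(adj, directed=False)
    if n_comp > 1:
        comps = [list(np.nonzero(labels == c)[0]) for c in range(n_comp)]
        raise DisconnectedSlicesError(comps)

    w = np.sqrt(np.asarray(wts))
    k = np.arange(n_pairs)
    # free parameters: all slices except the pinned reference
    cols = np.delete(np.arange(n_slices), reference_slice)
    colmap = {s: c for c, s in enumerate(cols)}
    data, ri, ci = [], [], []
    for kk in range(n_pairs):
        if rows_j[kk] != reference_slice:
            data.append(w[kk]); ri.append(kk); ci.append(colmap[rows_j[kk]])
        if rows_i[kk] != reference_slice:
            data.append(-w[kk]); ri.append(kk); ci.append(colmap[rows_i[kk]])
    C = sparse.csr_matrix((data, (ri, ci)), shape=(n_pairs, n_slices - 1))
    bx = w * np.asarray(dx)
    by = w * np.asarray(dy)

    if use_sparse:
        sol_x = sparse.linalg.lsqr(C, bx, atol=1e-12, btol=1e-12)[0]
        sol_y = sparse.linalg.lsqr(C, by, atol=1e-12, btol=1e-12)[0]
    else:
        Cd = C.toarray()
        sol_x, *_ = np.linalg.lstsq(Cd, bx, rcond=None)
        sol_y, *_ = np.linalg.lstsq(Cd, by, rcond=None)

    offsets = np.zeros((n_slices, 2))
    offsets[cols, 0] = sol_x
    offsets[cols, 1] = sol_y

    rx = C @ sol_x - bx
    ry = C @ sol_y - by
    dof = max(2 * n_pairs - 2 * (n_slices - 1), 1)
    s2 = (rx @ rx + ry @ ry) / dof
    # formal errors from the diagonal of (C^T C)^{-1}
    try:
        cov = np.linalg.inv((C.T @ C).toarray())
        sig = np.sqrt(np.clip(np.diag(cov) * s2, 0, None))
    except np.linalg.LinAlgError:  # pragma: no cover - near-singular fallback
        sig = np.full(n_slices - 1, np.nan)
    unc = np.zeros((n_slices, 2))
    unc[cols, 0] = sig
    unc[cols, 1] = sig
    rms = float(np.sqrt((rx @ rx + ry @ ry) / (2 * n_pairs)))
    return SliceOffsetSolution(offsets=offsets, uncertainty=unc,
                               residual_rms=rms, n_pairs=n_pairs,
                               reference_slice=reference_slice)


def apply_offsets(store, solution: SliceOffsetSolution, n_slices: int | None = None):
    """Write per-slice translations into store metadata (pixels untouched).

    ``store`` may be a zarr group or any object with an ``attrs`` mapping.
    Readers resample on the fly using these offsets.
    """
    n = n_slices if n_slices is not None else len(solution.offsets)
    if n != len(solution.offsets):
        raise ValueError(f"solution covers {len(solution.offsets)} slices, "
                         f"store has {n}")
    store.attrs["slice_offsets"] = [[float(dx), float(dy)]
                                    for dx, dy in solution.offsets]
    store.attrs["units"] = "px"


def read_offsets(store) -> np.ndarray:
    return np.asarray(store.attrs["slice_offsets"], dtype=float)
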