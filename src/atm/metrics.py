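"""Tractography evaluation metrics: six families.

* similarity — bundle adjacency (BA) from pairwise minimum-direct-flip
  (MDF) streamline distances;
* coverage — voxel overlap, overreach and Dice against a ground-truth
  occupancy mask;
* validity — valid/invalid streamline ratios against per-bundle endpoint
  regions and masks;
* orientation — tract orientation distribution (TOD) maps in a real
  even-order spherical-harmonic basis, compared with the angular
  correlation coefficient (ACC);
* geometry — mean length, span, volume, surface area, and absolute
  percent differences;
* connectivity — parcellation connectomes, Pearson agreement, and graph
  summaries (density, characteristic path length, global efficiency,
  modularity).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import factorial

import networkx as nx
import numpy as np
from scipy.special import sph_harm_y

from atm.io import (
    StreamlineSet,
    Volume3D,
    iter_segment_voxels,
    streamline_length,
    streamlines_to_occupancy,
)

# ---------------------------------------------------------------------------
# Similarity: MDF distance and bundle adjacency


def mdf_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Minimum average direct-flip distance between two K-point streamlines."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("MDF requires equal point counts")
    direct = np.mean(np.linalg.norm(a - b, axis=1))
    flipped = np.mean(np.linalg.norm(a - b[::-1], axis=1))
    return float(min(direct, flipped))


def _pairwise_min_mdf(a_arr: np.ndarray, b_arr: np.ndarray, chunk: int = 256) -> np.ndarray:
    """For each streamline of A, its minimum MDF distance to any of B."""
    nb = len(b_arr)
    b_flip = b_arr[:, ::-1]
    mins = np.full(len(a_arr), np.inf)
    for start in range(0, len(a_arr), chunk):
        asub = a_arr[start : start + chunk]  # (m, K, 3)
        diff_d = np.linalg.norm(asub[:, None] - b_arr[None], axis=3).mean(axis=2)
        diff_f = np.linalg.norm(asub[:, None] - b_flip[None], axis=3).mean(axis=2)
        mins[start : start + len(asub)] = np.minimum(diff_d, diff_f).min(axis=1)
    return mins


def bundle_adjacency(
    a: StreamlineSet, b: StreamlineSet, threshold_mm: float = 5.0
) -> float:
    """Symmetric fraction of streamlines within an MDF threshold of the
    other bundle; 0 = no similarity, 1 = perfect match."""
    if len(a) == 0 or len(b) == 0:
        raise ValueError("bundle adjacency requires nonempty bundles")
    a_arr, b_arr = a.as_array(), b.as_array()
    if a_arr.shape[1] != b_arr.shape[1]:
        raise ValueError("bundles must share the streamline point count K")
    frac_a = float(np.mean(_pairwise_min_mdf(a_arr, b_arr) < threshold_mm))
    frac_b = float(np.mean(_pairwise_min_mdf(b_arr, a_arr) < threshold_mm))
    return 0.5 * (frac_a + frac_b)


# ---------------------------------------------------------------------------
# Coverage


def coverage_scores(
    candidate: StreamlineSet | Volume3D,
    gt_mask: Volume3D,
    grid: Volume3D | None = None,
    dice_mode: str = "standard",
) -> tuple[float, float, float]:
    """(dice, overlap, overreach) of a candidate bundle against GT voxels.

    overlap = |C∩G| / |G|; overreach = |C\\G| / |G| (can exceed 1);
    dice (standard) = 2|C∩G| / (|C| + |G|).  ``dice_mode="harmonic"``
    instead returns the harmonic mean of overlap and 1/(1+overreach).
    """
    if isinstance(candidate, Volume3D):
        c = candidate.data > 0
    else:
        ref = grid if grid is not None else gt_mask
        c = streamlines_to_occupancy(candidate, ref).data > 0
    g = gt_mask.data > 0
    n_g = int(g.sum())
    if n_g == 0:
        raise ValueError("ground-truth mask is empty")
    inter = int((c & g).sum())
    spill = int((c & ~g).sum())
    overlap = inter / n_g
    overreach = spill / n_g
    if dice_mode == "standard":
        dice = 2.0 * inter / (int(c.sum()) + n_g) if (c.sum() + n_g) else 0.0
    elif dice_mode == "harmonic":
        prec = 1.0 / (1.0 + overreach)
        dice = (
            2.0 * overlap * prec / (overlap + prec) if (overlap + prec) > 0 else 0.0
        )
    else:
        raise ValueError(f"unknown dice_mode {dice_mode!r}")
    return dice, overlap, overreach


# ---------------------------------------------------------------------------
# Validity


@dataclass
class BundleDefinition:
    """Ground-truth definition of one bundle for validity scoring."""

    mask: Volume3D
    roi_a: Volume3D
    roi_b: Volume3D


def streamline_validity(
    sset: StreamlineSet,
    gt_defs: dict[str, BundleDefinition],
    point_fraction: float = 0.9,
) -> tuple[float, float]:
    """(VS, IS): fractions of valid and invalid streamlines.

    A streamline is valid iff, for some bundle, its endpoints land one in
    each of the bundle's two endpoint regions and at least
    ``point_fraction`` of its points lie inside the bundle mask.
    VS + IS = 1 by construction.
    """
    if len(sset) == 0:
        raise ValueError("empty streamline set")
    n_valid = 0
    for line in sset:
        ends = line[[0, -1]]
        for d in gt_defs.values():
            in_a = d.roi_a.values_at(ends, outside=0)
            in_b = d.roi_b.values_at(ends, outside=0)
            paired = (in_a[0] == 1 and in_b[1] == 1) or (in_a[1] == 1 and in_b[0] == 1)
            if not paired:
                continue
            frac = float(np.mean(d.mask.values_at(line, outside=0) == 1))
            if frac >= point_fraction:
                n_valid += 1
                break
    vs = n_valid / len(sset)
    return vs, 1.0 - vs


# ---------------------------------------------------------------------------
# Orientation: TOD maps and angular correlation


def n_even_sh_coeffs(lmax: int) -> int:
    """Coefficient count of the real even-order SH basis up to lmax."""
    return (lmax + 1) * (lmax + 2) // 2


def real_even_sh_basis(directions: np.ndarray, lmax: int) -> np.ndarray:
    """Real spherical-harmonic basis (even orders only) at unit directions.

    Ordering: for l = 0, 2, ..., lmax and m = -l..l; real harmonics are
    built from the complex ones in the standard way (sqrt(2) * Im for
    m < 0, sqrt(2) * Re for m > 0).  Antipodal symmetry holds because only
    even l are included.
    """
    if lmax < 2 or lmax % 2 != 0:
        raise ValueError("lmax must be even and >= 2")
    dirs = np.atleast_2d(directions)
    theta = np.arccos(np.clip(dirs[:, 2], -1.0, 1.0))  # polar
    phi = np.arctan2(dirs[:, 1], dirs[:, 0])  # azimuth
    cols = []
    for l in range(0, lmax + 1, 2):
        for m in range(-l, l + 1):
            y = sph_harm_y(l, abs(m), theta, phi)
            if m < 0:
                cols.append(np.sqrt(2.0) * y.imag)
            elif m == 0:
                cols.append(y.real)
            else:
                cols.append(np.sqrt(2.0) * y.real)
    return np.stack(cols, axis=1)


def sh_degree_slices(lmax: int):
    """(l, slice) pairs into the even-order coefficient vector."""
    out = []
    start = 0
    for l in range(0, lmax + 1, 2):
        n = 2 * l + 1
        out.append((l, slice(start, start + n)))
        start += n
    return out


@dataclass
class TODMap:
    """Per-voxel spherical-harmonic tract orientation distribution."""

    coeffs: np.ndarray  # (X, Y, Z, n_coeffs)
    affine: np.ndarray
    lmax: int

    def nonzero_mask(self) -> np.ndarray:
        return np.any(self.coeffs != 0, axis=-1)


def tod_map(sset: StreamlineSet, grid: Volume3D, lmax: int = 8) -> TODMap:
    """Accumulate segment directions into per-voxel SH coefficients.

    Each segment contributes its in-voxel length times the SH basis at its
    (antipodally symmetrized) unit direction; directions are
    sign-normalized to the upper hemisphere.
    """
    if lmax < 2 or lmax % 2 != 0:
        raise ValueError("lmax must be even and >= 2")
    n_c = n_even_sh_coeffs(lmax)
    coeffs = np.zeros(grid.shape + (n_c,))
    entries = []  # (voxel, length, direction)
    for _, vox, length_mm, u in iter_segment_voxels(sset, grid):
        if u is None or length_mm <= 0:
            continue
        if u[2] < 0 or (u[2] == 0 and (u[1] < 0 or (u[1] == 0 and u[0] < 0))):
            u = -u
        entries.append((vox, length_mm, u))
    if entries:
        dirs = np.array([e[2] for e in entries])
        basis = real_even_sh_basis(dirs, lmax)  # (n, n_c)
        weights = np.array([e[1] for e in entries])
        vox = np.array([e[0] for e in entries])
        np.add.at(coeffs, (vox[:, 0], vox[:, 1], vox[:, 2]), basis * weights[:, None])
    return TODMap(coeffs=coeffs, affine=grid.affine.copy(), lmax=lmax)


def angular_correlation(u: TODMap, v: TODMap) -> float:
    """Mean ACC over voxels where ``v`` (the reference) is nonzero.

    Per voxel, ACC is the cosine similarity of the coefficient vectors
    restricted to orders l >= 2; voxels where either restricted vector is
    zero contribute 0.
    """
    if u.lmax != v.lmax:
        raise ValueError("TOD maps have different lmax")
    if u.coeffs.shape != v.coeffs.shape:
        raise ValueError("TOD maps live on different grids")
    mask = v.nonzero_mask()
    if not np.any(mask):
        raise ValueError("reference TOD map is empty")
    hi = slice(1, None)  # drop the single l=0 coefficient
    uu = u.coeffs[mask][:, hi]
    vv = v.coeffs[mask][:, hi]
    nu = np.linalg.norm(uu, axis=1)
    nv = np.linalg.norm(vv, axis=1)
    ok = (nu > 0) & (nv > 0)
    acc = np.zeros(len(uu))
    acc[ok] = np.sum(uu[ok] * vv[ok], axis=1) / (nu[ok] * nv[ok])
    return float(acc.mean())


def tod_peak_directions(tod: TODMap, n_dirs: int = 10_000, seed: int = 0) -> np.ndarray:
    """Per-voxel spherical maximum of the TOD by dense direction search.

    Returns (X, Y, Z, 3) unit vectors (zero where the TOD is zero).
    """
    rng = np.random.default_rng(seed)
    dirs = rng.standard_normal((n_dirs, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    basis = real_even_sh_basis(dirs, tod.lmax)  # (n_dirs, n_c)
    peaks = np.zeros(tod.coeffs.shape[:3] + (3,))
    mask = tod.nonzero_mask()
    vals = tod.coeffs[mask] @ basis.T  # (n_vox, n_dirs)
    best = dirs[np.argmax(vals, axis=1)]
    peaks[mask] = best
    return peaks


# ---------------------------------------------------------------------------
# Geometry


def geometry_summary(
    sset: StreamlineSet, grid: Volume3D
) -> tuple[float, float, float, float]:
    """(mean_length mm, span mm, volume mm^3, surface_area mm^2)."""
    if len(sset) == 0:
        raise ValueError("empty streamline set")
    lengths = [streamline_length(s) for s in sset]
    spans = [float(np.linalg.norm(s[-1] - s[0])) for s in sset]
    occ = streamlines_to_occupancy(sset, grid).data > 0
    vox_vol = grid.voxel_volume()
    volume = float(occ.sum()) * vox_vol
    # exposed faces, 6-connectivity
    faces = 0
    for ax in range(3):
        for shift in (1, -1):
            nb = np.roll(occ, shift, axis=ax)
            edge = np.zeros_like(occ)
            idx = [slice(None)] * 3
            idx[ax] = 0 if shift == 1 else -1
            edge[tuple(idx)] = True
            faces += int(np.sum(occ & (~nb | edge)))
    face_area = vox_vol ** (2.0 / 3.0)
    return float(np.mean(lengths)), float(np.mean(spans)), volume, faces * face_area


def absolute_percent_difference(measured: float, reference: float) -> float:
    """|measured - reference| / |reference| * 100."""
    if reference == 0:
        raise ValueError("reference must be nonzero")
    return abs(measured - reference) / abs(reference) * 100.0


# ---------------------------------------------------------------------------
# Connectivity


@dataclass
class Connectome:
    """Symmetric nonnegative region-by-region connection matrix."""

    matrix: np.ndarray
    labels: np.ndarray  # region ids for each row/column
    normalized: bool = False


def build_connectome(
    sset: StreamlineSet, parcellation: Volume3D, normalize: bool = False
) -> Connectome:
    """Count streamlines connecting pairs of parcellation labels.

    Endpoint labels are looked up in the parcellation; streamlines with an
    endpoint on label 0 (background) are not counted.  If ``normalize``,
    the matrix is divided by the *total* streamline count of the set.
    """
    labels = np.unique(parcellation.data)
    labels = labels[labels > 0]
    index = {int(l): i for i, l in enumerate(labels)}
    r = len(labels)
    mat = np.zeros((r, r))
    for line in sset:
        la, lb = (int(v) for v in parcellation.values_at(line[[0, -1]], outside=0))
        if la == 0 or lb == 0 or la == lb:
            continue
        i, j = index[la], index[lb]
        mat[i, j] += 1
        mat[j, i] += 1
    if normalize and len(sset) > 0:
        mat = mat / len(sset)
    return Connectome(matrix=mat, labels=labels, normalized=normalize)


def graph_metrics(c: Connectome | np.ndarray, seed: int = 0) -> dict[str, float]:
    """Density, characteristic path length, global efficiency, modularity.

    Edge lengths are reciprocal weights; CPL is the mean shortest-path
    length over connected node pairs, efficiency is the mean inverse
    shortest-path length over all distinct pairs (0 for disconnected), and
    modularity is Newman modularity of the greedy best partition.
    """
    mat = c.matrix if isinstance(c, Connectome) else np.asarray(c, dtype=float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError("connectome matrix must be square")
    if not np.allclose(mat, mat.T):
        raise ValueError("connectome matrix must be symmetric")
    r = mat.shape[0]
    g = nx.Graph()
    g.add_nodes_from(range(r))
    for i in range(r):
        for j in range(i + 1, r):
            if mat[i, j] > 0:
                g.add_edge(i, j, weight=float(mat[i, j]), length=1.0 / float(mat[i, j]))
    n_edges = g.number_of_edges()
    density = 2.0 * n_edges / (r * (r - 1)) if r > 1 else 0.0
    dist = dict(nx.all_pairs_dijkstra_path_length(g, weight="length"))
    path_lengths = []
    inv_sum = 0.0
    n_pairs = r * (r - 1) / 2 if r > 1 else 0
    for i in range(r):
        for j in range(i + 1, r):
            d = dist.get(i, {}).get(j)
            if d is not None and d > 0:
                path_lengths.append(d)
                inv_sum += 1.0 / d
    cpl = float(np.mean(path_lengths)) if path_lengths else float("inf")
    efficiency = inv_sum / n_pairs if n_pairs else 0.0
    if n_edges > 0:
        communities = nx.community.greedy_modularity_communities(g, weight="weight")
        modularity = nx.community.modularity(g, communities, weight="weight")
    else:
        modularity = 0.0
    return {
        "density": float(density),
        "cpl": float(cpl),
        "global_efficiency": float(efficiency),
        "modularity": float(modularity),
    }


def connectome_correlation(c1: Connectome | np.ndarray, c2: Connectome | np.ndarray) -> float:
    """Pearson correlation over strictly-upper-triangle entries."""
    m1 = c1.matrix if isinstance(c1, Connectome) else np.asarray(c1, dtype=float)
    m2 = c2.matrix if isinstance(c2, Connectome) else np.asarray(c2, dtype=float)
    if m1.shape != m2.shape:
        raise ValueError("connectomes have different shapes")
    iu = np.triu_indices(m1.shape[0], k=1)
    v1, v2 = m1[iu], m2[iu]
    if np.all(v1 == v1[0]) or np.all(v2 == v2[0]):
        raise ValueError("correlation undefined for constant connectome")
    return float(np.corrcoef(v1, v2)[0, 1])


# ---------------------------------------------------------------------------
# Aggregate report


@dataclass
class MetricsReport:
    """All per-bundle evaluation results, JSON-serializable via vars()."""

    ba: float
    dice: float
    overlap: float
    overreach: float
    vs: float
    is_ratio: float
    mean_acc: float
    mean_length: float
    span: float
    volume: float
    surface_area: float
    apd: dict[str, float] = field(default_factory=dict)
    connectome_r: float | None = None
    graph: dict[str, float] = field(default_factory=dict)
    graph_gt: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "ba": self.ba,
            "dice": self.dice,
            "overlap": self.overlap,
            "overreach": self.overreach,
            "vs": self.vs,
            "is": self.is_ratio,
            "mean_acc": self.mean_acc,
            "mean_length": self.mean_length,
            "span": self.span,
            "volume": self.volume,
            "surface_area": self.surface_area,
            "apd": self.apd,
            "connectome_r": self.connectome_r,
            "graph": self.graph,
            "graph_gt": self.graph_gt,
        }


def evaluate_bundle(
    pred: StreamlineSet,
    gt: StreamlineSet,
    gt_mask: Volume3D,
    grid: Volume3D,
    gt_defs: dict[str, BundleDefinition] | None = None,
    parcellation: Volume3D | None = None,
    ba_threshold_mm: float = 5.0,
    lmax: int = 8,
    validity_fraction: float = 0.9,
) -> MetricsReport:
    """Run all six metric families for one predicted bundle.

    Trimming can leave the prediction with varying point counts; the
    MDF-based adjacency needs a common K, so the prediction is resampled
    to the ground truth's K for that metric only.
    """
    k_gt = gt.n_points
    pred_ba = pred if pred.n_points == k_gt else pred.resampled(k_gt)
    ba = bundle_adjacency(pred_ba, gt, ba_threshold_mm)
    dice, overlap, overreach = coverage_scores(pred, gt_mask, grid)
    if gt_defs is not None:
        vs, is_ratio = streamline_validity(pred, gt_defs, validity_fraction)
    else:
        vs, is_ratio = float("nan"), float("nan")
    acc = angular_correlation(tod_map(pred, grid, lmax), tod_map(gt, grid, lmax))
    mean_length, span, volume, surface = geometry_summary(pred, grid)
    gl, gs, gv, ga = geometry_summary(gt, grid)
    apd = {
        "mean_length": absolute_percent_difference(mean_length, gl),
        "span": absolute_percent_difference(span, gs),
        "volume": absolute_percent_difference(volume, gv),
        "surface_area": absolute_percent_difference(surface, ga),
    }
    connectome_r = None
    graph = {}
    graph_gt = {}
    if parcellation is not None:
        c_pred = build_connectome(pred, parcellation, normalize=True)
        c_gt = build_connectome(gt, parcellation, normalize=True)
        try:
            connectome_r = connectome_correlation(c_pred, c_gt)
        except ValueError:
            connectome_r = None
        graph = graph_metrics(c_pred)
        graph_gt = graph_metrics(c_gt)
    return MetricsReport(
        ba=ba,
        dice=dice,
        overlap=overlap,
        overreach=overreach,
        vs=vs,
        is_ratio=is_ratio,
        mean_acc=acc,
        mean_length=mean_length,
        span=span,
        volume=volume,
        surface_area=surface,
        apd=apd,
        connectome_r=connectome_r,
        graph=graph,
        graph_gt=graph_gt,
    )
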