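"""Synthetic phantom subjects: paired anatomy volumes and curated bundles.

Each phantom subject emulates the structure the mapping model is trained on:
a co-registered anatomical intensity volume (three tissue levels, smoothed,
noisy, normalized to [0, 1]), one or more ground-truth streamline bundles,
their binary occupancy maps, brain and white-matter masks, a coarse integer
parcellation, and per-bundle endpoint regions.  Bundle centerlines come from
a small family of closed-form curves (straight, circular arc, U-shape,
helix); individual streamlines add a smooth low-order transverse offset so
they remain differentiable curves inside a tube of fixed radius.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial.transform import Rotation

from atm.io import StreamlineSet, Volume3D, resample_streamline, streamlines_to_occupancy

FAMILIES = ("straight", "arc", "ushape", "helix")


class PhantomConstructionError(RuntimeError):
    """Raised when a bundle does not fit inside the phantom brain."""


@dataclass
class BundleSpec:
    """Geometry of one synthetic bundle.

    ``size_mm`` is the family's primary scale: the total length of a
    straight bundle, or the centerline radius of arc / U-shape / helix
    bundles.  ``angular_extent`` (radians) applies to arc and helix;
    a U-shape is an arc fixed at extent pi.  ``jitter_sd`` controls the
    spread of the smooth transverse offsets (defaults to half the tube
    radius).
    """

    name: str = "bundle"
    family: str = "arc"
    center: tuple[float, float, float] = (16.0, 16.0, 16.0)
    size_mm: float = 10.0
    angular_extent: float = 2.8
    orientation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    tube_radius: float = 2.5
    n_streamlines: int = 200
    jitter_sd: float | None = None
    n_points: int = 128
    helix_pitch_mm: float = 8.0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown bundle family {self.family!r}")
        if self.tube_radius <= 0:
            raise ValueError("tube_radius must be positive")
        if not (0.0 < self.angular_extent < 2.0 * np.pi):
            raise ValueError("angular_extent must lie in (0, 2*pi)")
        if self.n_streamlines < 1:
            raise ValueError("n_streamlines must be >= 1")

    @property
    def offset_sd(self) -> float:
        return self.tube_radius / 2.0 if self.jitter_sd is None else self.jitter_sd


def _centerline(spec: BundleSpec, n: int = 200) -> np.ndarray:
    """Dense centerline in world mm for a spec (canonical frame, then posed)."""
    t = np.linspace(0.0, 1.0, n)
    if spec.family == "straight":
        pts = np.stack(
            [np.zeros(n), np.zeros(n), (t - 0.5) * spec.size_mm], axis=1
        )
    elif spec.family in ("arc", "ushape"):
        extent = np.pi if spec.family == "ushape" else spec.angular_extent
        phi = (t - 0.5) * extent
        r = spec.size_mm
        pts = np.stack([r * np.sin(phi), np.zeros(n), r * np.cos(phi)], axis=1)
    else:  # helix
        phi = spec.angular_extent * (t - 0.5)
        r = spec.size_mm
        z = spec.helix_pitch_mm * phi / (2.0 * np.pi)
        pts = np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)
    pts = pts - pts.mean(axis=0)
    rot = Rotation.from_euler("xyz", spec.orientation).as_matrix()
    return pts @ rot.T + np.asarray(spec.center)


# number of cosine harmonics in the smooth transverse offset basis
_N_HARMONICS = 4


def _smooth_offsets(
    rng: np.random.Generator, spec: BundleSpec, t: np.ndarray, tangents: np.ndarray
) -> np.ndarray:
    """One streamline's smooth radial offset curve, capped at the tube radius.

    Offsets are projected perpendicular to the local centerline tangent so
    they are purely radial: they widen the tube without shortening the
    streamline.
    """
    coeffs = rng.normal(
        0.0,
        [spec.offset_sd / (k + 1.0) for k in range(_N_HARMONICS)],
        size=(3, _N_HARMONICS),
    )
    basis = np.cos(np.outer(np.arange(_N_HARMONICS) * np.pi, t))  # (H, n)
    off = (coeffs @ basis).T  # (n, 3)
    off -= np.sum(off * tangents, axis=1, keepdims=True) * tangents
    max_norm = float(np.max(np.linalg.norm(off, axis=1)))
    if max_norm > spec.tube_radius:
        off *= spec.tube_radius / max_norm
    return off


def make_bundle(spec: BundleSpec, rng_seed: int) -> StreamlineSet:
    """Generate a bundle of ``spec.n_streamlines`` streamlines, K points each.

    Deterministic given ``rng_seed``.  Every point lies within
    ``tube_radius`` of the centerline curve.
    """
    rng = np.random.default_rng(rng_seed)
    n_dense = max(4 * spec.n_points, 256)
    center = _centerline(spec, n_dense)
    t = np.linspace(0.0, 1.0, n_dense)
    grad = np.gradient(center, axis=0)
    tangents = grad / np.linalg.norm(grad, axis=1, keepdims=True)
    lines = []
    for _ in range(spec.n_streamlines):
        pts = center + _smooth_offsets(rng, spec, t, tangents)
        lines.append(resample_streamline(pts, spec.n_points))
    return StreamlineSet(lines)


def _ellipsoid_mask(
    shape: Sequence[int], semi_axes: np.ndarray, exponent: float = 4.0
) -> np.ndarray:
    """Superellipsoid mask (exponent 4 = rounded box, brain-like blob)."""
    shape = tuple(shape)
    c = (np.asarray(shape) - 1) / 2.0
    grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    r = sum(
        (np.abs(g - ci) / ai) ** exponent for g, ci, ai in zip(grids, c, semi_axes)
    )
    return (r <= 1.0).astype(np.int64)


@dataclass
class PhantomSubject:
    """One synthetic subject: anatomy, bundles, masks, parcellation, ROIs."""

    name: str
    t1_like: Volume3D
    bundles: dict[str, StreamlineSet]
    gt_occupancy: dict[str, Volume3D]
    brain_mask: Volume3D
    wm_mask: Volume3D
    parcellation: Volume3D
    endpoint_rois: dict[str, tuple[Volume3D, Volume3D]]
    exception_labels: frozenset[int] = frozenset({9, 10})
    specs: list[BundleSpec] = field(default_factory=list)
    seed: int | None = None


# tissue intensity levels before smoothing/noise: background, gray-matter
# shell, white matter, bundle tube
_LEVELS = {"background": 0.0, "gm": 0.5, "wm": 0.75, "tube": 0.95}


def make_subject(
    specs: Sequence[BundleSpec],
    grid_shape: Sequence[int] = (32, 32, 32),
    rng_seed: int = 0,
    *,
    noise_sd: float = 0.02,
    smooth_sigma: float = 0.7,
    affine: np.ndarray | None = None,
    name: str = "subject",
) -> PhantomSubject:
    """Build a full phantom subject from bundle specs.

    The anatomical volume is a smoothed, noisy three-level tissue mixture
    clipped to [0, 1]; bundle tubes are brighter than surrounding white
    matter so the anatomy carries the positional cue the mapping learns.
    """
    if affine is None:
        affine = np.eye(4)
    shape = tuple(int(s) for s in grid_shape)
    rng = np.random.default_rng(rng_seed)
    grid = Volume3D(np.zeros(shape), affine=affine, kind="intensity")

    brain = _ellipsoid_mask(shape, 0.48 * np.asarray(shape))
    wm_core = _ellipsoid_mask(shape, 0.33 * np.asarray(shape))
    brain_mask = Volume3D(brain, affine=affine, kind="binary_mask")

    bundles: dict[str, StreamlineSet] = {}
    occupancies: dict[str, Volume3D] = {}
    child_seeds = rng.integers(0, 2**31 - 1, size=len(specs))
    for spec, cseed in zip(specs, child_seeds):
        sset = make_bundle(spec, int(cseed))
        sset.reference_affine = affine.copy()
        sset.reference_shape = shape
        all_pts = np.concatenate(sset.streamlines)
        inside = brain_mask.values_at(all_pts, outside=0)
        if not np.all(inside == 1):
            raise PhantomConstructionError(
                f"bundle {spec.name!r} escapes the brain mask "
                f"({int(np.sum(inside == 0))} points outside)"
            )
        bundles[spec.name] = sset
        occupancies[spec.name] = streamlines_to_occupancy(sset, grid)

    occ_union = np.zeros(shape, dtype=np.int64)
    for occ in occupancies.values():
        occ_union |= occ.data
    wm = (((wm_core | ndimage.binary_dilation(occ_union)) & brain) | occ_union).astype(
        np.int64
    )
    wm_mask = Volume3D(wm, affine=affine, kind="binary_mask")

    tissue = np.full(shape, _LEVELS["background"])
    tissue[brain == 1] = _LEVELS["gm"]
    tissue[wm == 1] = _LEVELS["wm"]
    tissue[occ_union == 1] = _LEVELS["tube"]
    t1 = ndimage.gaussian_filter(tissue, smooth_sigma)
    if noise_sd > 0:
        t1 = t1 + rng.normal(0.0, noise_sd, size=shape)
    t1 = np.clip(t1, 0.0, 1.0)
    t1_like = Volume3D(t1, affine=affine, kind="intensity")

    parcellation = _make_parcellation(shape, brain, affine)

    endpoint_rois = {
        nm: _endpoint_rois(sset, grid) for nm, sset in bundles.items()
    }

    return PhantomSubject(
        name=name,
        t1_like=t1_like,
        bundles=bundles,
        gt_occupancy=occupancies,
        brain_mask=brain_mask,
        wm_mask=wm_mask,
        parcellation=parcellation,
        endpoint_rois=endpoint_rois,
        specs=list(specs),
        seed=rng_seed,
    )


def _make_parcellation(shape, brain: np.ndarray, affine: np.ndarray) -> Volume3D:
    """Coarse block parcellation: 8 octant labels + 2 exception labels.

    Labels 1-8 are the octants of the brain mask about its center; labels 9
    and 10 carve out inferior caps standing in for brainstem and cerebellum.
    Labels tile the brain mask exactly and are disjoint.
    """
    c = (np.asarray(shape) - 1) / 2.0
    gi, gj, gk = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    octant = 1 + (gi > c[0]) * 1 + (gj > c[1]) * 2 + (gk > c[2]) * 4
    labels = np.where(brain == 1, octant, 0).astype(np.int64)
    z_cap = int(round(0.18 * shape[2]))
    inferior = (gk < z_cap) & (brain == 1)
    labels[inferior & (gi <= c[0])] = 9   # brainstem stand-in
    labels[inferior & (gi > c[0])] = 10   # cerebellum stand-in
    return Volume3D(labels, affine=affine, kind="label_map")


def _endpoint_rois(sset: StreamlineSet, grid: Volume3D) -> tuple[Volume3D, Volume3D]:
    """Two spherical label masks covering all head / tail endpoints."""
    heads = np.stack([s[0] for s in sset])
    tails = np.stack([s[-1] for s in sset])
    rois = []
    for pts in (heads, tails):
        centroid = pts.mean(axis=0)
        radius = float(np.max(np.linalg.norm(pts - centroid, axis=1))) + 1.0
        gi, gj, gk = np.meshgrid(*[np.arange(s) for s in grid.shape], indexing="ij")
        vox = np.stack([gi, gj, gk], axis=-1).reshape(-1, 3)
        world = grid.voxel_to_world(vox)
        inside = np.linalg.norm(world - centroid, axis=1) <= radius
        mask = inside.reshape(grid.shape).astype(np.int64)
        rois.append(Volume3D(mask, affine=grid.affine.copy(), kind="binary_mask"))
    return rois[0], rois[1]


def make_population(
    n_subjects: int,
    base_specs: Sequence[BundleSpec],
    variability_sd: float,
    rng_seed: int = 0,
    **subject_kwargs,
) -> list[PhantomSubject]:
    """A population of subjects with jittered bundle geometry.

    Each subject's bundle centers and primary sizes are the base specs
    perturbed by independent Gaussian jitter of sd ``variability_sd`` (mm),
    truncated at two sigma so every subject fits the shared grid; all
    subjects share the grid and parcellation topology.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    rng = np.random.default_rng(rng_seed)

    def jitter(size=None):
        return np.clip(
            rng.normal(0.0, variability_sd, size), -2 * variability_sd, 2 * variability_sd
        )

    subjects = []
    for i in range(n_subjects):
        specs_i = []
        for spec in base_specs:
            center = np.asarray(spec.center) + jitter(3)
            size = spec.size_mm + float(jitter())
            specs_i.append(
                replace(spec, center=tuple(center), size_mm=float(size))
            )
        seed_i = int(rng.integers(0, 2**31 - 1))
        subjects.append(
            make_subject(
                specs_i, rng_seed=seed_i, name=f"subject_{i:03d}", **subject_kwargs
            )
        )
    return subjects


def default_specs(n_points: int = 128) -> list[BundleSpec]:
    """Two demo bundles that fit the default 32^3 1-mm grid."""
    return [
        BundleSpec(
            name="arc_left",
            family="arc",
            center=(15.3, 16.0, 16.0),
            size_mm=8.5,
            angular_extent=3.1,
            orientation=(0.0, 0.785, 0.0),
            tube_radius=1.8,
            n_points=n_points,
        ),
        BundleSpec(
            name="straight_right",
            family="straight",
            center=(16.5, 16.5, 16.0),
            size_mm=21.0,
            orientation=(0.12, 0.0, 0.0),
            tube_radius=2.0,
            jitter_sd=None,
            n_points=n_points,
        ),
    ]
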