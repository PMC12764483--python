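"""Filtering and trimming of generated bundles.

Three rules, applied in order:

1. discard streamlines with any point outside the brain mask;
2. discard streamlines shorter than a minimum arc length (default 20 mm);
3. trim the remaining streamlines at the white-matter boundary — leading
   points are dropped until the first point inside the WM mask and trailing
   points until the last — except for streamlines that connect to an
   exception region (brainstem / cerebellum stand-ins) or whose endpoints
   lie on opposite sides of the mid-sagittal plane, which pass unchanged.

The WM "surface" is realized as a binary mask: a point is beyond the
surface iff its containing voxel is 0.  Trimming removes only terminal
excursions, never interior dips.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from atm.io import StreamlineSet, Volume3D, streamline_length


@dataclass
class FilterReport:
    """Bookkeeping of what each rule removed or changed."""

    n_input: int = 0
    n_output: int = 0
    removed: dict[str, int] = field(default_factory=dict)
    points_trimmed: int = 0
    exempted: int = 0

    def check(self) -> None:
        if self.n_input != self.n_output + sum(self.removed.values()):
            raise AssertionError("filter report counts are inconsistent")


def _require_binary(mask: Volume3D, name: str) -> None:
    vals = np.unique(mask.data)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValueError(f"{name} must be binary (contains {vals[:5]}...)")


def filter_streamlines(
    sset: StreamlineSet,
    brain_mask: Volume3D,
    min_length_mm: float = 20.0,
    *,
    outside_rule: str = "any_point",
) -> tuple[StreamlineSet, FilterReport]:
    """Remove streamlines leaving the brain or shorter than the threshold.

    ``outside_rule`` is ``"any_point"`` (default, strict) or
    ``"endpoint"`` (only endpoints are tested against the brain mask).
    Survivor order is preserved.  Points falling outside the mask's grid
    count as outside the brain.
    """
    _require_binary(brain_mask, "brain_mask")
    if outside_rule not in ("any_point", "endpoint"):
        raise ValueError(f"unknown outside_rule {outside_rule!r}")
    report = FilterReport(n_input=len(sset), removed={"outside_brain": 0, "too_short": 0})
    survivors = []
    for line in sset:
        probe = line if outside_rule == "any_point" else line[[0, -1]]
        inside = brain_mask.values_at(probe, outside=0)
        if not np.all(inside == 1):
            report.removed["outside_brain"] += 1
            continue
        if streamline_length(line) < min_length_mm:
            report.removed["too_short"] += 1
            continue
        survivors.append(line)
    report.n_output = len(survivors)
    report.check()
    out = StreamlineSet(
        survivors,
        reference_affine=sset.reference_affine,
        reference_shape=sset.reference_shape,
    )
    return out, report


def trim_streamlines(
    sset: StreamlineSet,
    wm_mask: Volume3D,
    parcellation: Volume3D | None = None,
    exception_labels=(),
    hemisphere_plane_x: float | None = None,
) -> tuple[StreamlineSet, FilterReport]:
    """Trim terminal points outside the WM mask; exempt special streamlines.

    A streamline is exempt (passes unchanged) if an endpoint lies in one of
    ``exception_labels`` of the parcellation, or its endpoints straddle the
    mid-sagittal plane ``x = hemisphere_plane_x`` (world mm).  Non-exempt
    streamlines keep the contiguous stretch from their first to their last
    point inside the WM mask; those left with fewer than 2 points are
    removed.
    """
    _require_binary(wm_mask, "wm_mask")
    exception_labels = frozenset(int(v) for v in exception_labels)
    report = FilterReport(n_input=len(sset), removed={"trimmed_away": 0})
    survivors = []
    for line in sset:
        if _is_exempt(line, parcellation, exception_labels, hemisphere_plane_x):
            report.exempted += 1
            survivors.append(line)
            continue
        inside = wm_mask.values_at(line, outside=0) == 1
        if not np.any(inside):
            report.removed["trimmed_away"] += 1
            continue
        first = int(np.argmax(inside))
        last = len(line) - 1 - int(np.argmax(inside[::-1]))
        trimmed = line[first : last + 1]
        if len(trimmed) < 2:
            report.removed["trimmed_away"] += 1
            continue
        report.points_trimmed += len(line) - len(trimmed)
        survivors.append(trimmed)
    report.n_output = len(survivors)
    report.check()
    out = StreamlineSet(
        survivors,
        reference_affine=sset.reference_affine,
        reference_shape=sset.reference_shape,
    )
    return out, report


def _is_exempt(line, parcellation, exception_labels, hemisphere_plane_x) -> bool:
    if exception_labels and parcellation is not None:
        end_labels = parcellation.values_at(line[[0, -1]], outside=0)
        if any(int(v) in exception_labels for v in end_labels):
            return True
    if hemisphere_plane_x is not None:
        x0, x1 = line[0, 0], line[-1, 0]
        if (x0 - hemisphere_plane_x) * (x1 - hemisphere_plane_x) < 0:
            return True
    return False


def postprocess_bundle(
    sset: StreamlineSet,
    brain_mask: Volume3D,
    wm_mask: Volume3D,
    parcellation: Volume3D | None = None,
    exception_labels=(),
    min_length_mm: float = 20.0,
    hemisphere_plane_x: float | None = None,
) -> tuple[StreamlineSet, dict]:
    """Full pipeline: filter (brain, length) then trim (WM surface)."""
    filtered, rep1 = filter_streamlines(sset, brain_mask, min_length_mm)
    trimmed, rep2 = trim_streamlines(
        filtered, wm_mask, parcellation, exception_labels, hemisphere_plane_x
    )
    report = {
        "n_input": rep1.n_input,
        "n_output": rep2.n_output,
        "removed": {**rep1.removed, **rep2.removed},
        "points_trimmed": rep2.points_trimmed,
        "exempted": rep2.exempted,
    }
    return trimmed, report
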