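"""Segmentation evaluation: Dice overlap, volumes, and summary statistics."""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass

import numpy as np

from .errors import GeometryError, ParameterError
from .volume import BinaryMask

__all__ = ["EvalReport", "dice", "mask_volume", "evaluate_masks", "summarize"]


@dataclass(frozen=True)
class EvalReport:
    """One automatic-vs-reference comparison (DSC, volumes, voxel counts)."""

    dsc_percent: float
    volume_mm3_auto: float
    volume_mm3_ref: float
    voxels_auto: int
    voxels_ref: int

    def to_dict(self) -> dict:
        d = asdict(self)
        d["dsc_percent"] = round(self.dsc_percent, 2)
        return d


def dice(a: BinaryMask, b: BinaryMask) -> float:
    """Dice Similarity Coefficient in percent: 100 * 2|A∩B| / (|A| + |B|).

    Symmetric; 100 for identical nonempty masks, 0 for disjoint ones.
    Two empty masks yield 0 (with a warning) rather than 0/0.
    """
    if not a.same_grid(b):
        raise GeometryError("masks are not on the same voxel grid")
    na, nb = a.n_voxels, b.n_voxels
    if na + nb == 0:
        warnings.warn("Dice of two empty masks is defined as 0", stacklevel=2)
        return 0.0
    overlap = int(np.count_nonzero(a.voxels & b.voxels))
    return 100.0 * 2.0 * overlap / (na + nb)


def mask_volume(m: BinaryMask) -> tuple[int, float]:
    """Foreground voxel count and the corresponding volume in mm^3."""
    n = m.n_voxels
    return n, n * m.voxel_volume_mm3


def evaluate_masks(auto: BinaryMask, ref: BinaryMask) -> EvalReport:
    """Full report comparing an automatic mask against a reference."""
    d = dice(auto, ref)
    na, va = mask_volume(auto)
    nr, vr = mask_volume(ref)
    return EvalReport(
        dsc_percent=d,
        volume_mm3_auto=va,
        volume_mm3_ref=vr,
        voxels_auto=na,
        voxels_ref=nr,
    )


def summarize(values_by_metric: dict) -> dict:
    """Min / max / mean / sd per metric over a set of cases.

    The standard deviation uses the sample convention (ddof = 1); a
    single case reports sd 0.  Accepts either a dict of metric-name to
    value list, or a list of :class:`EvalReport`.
    """
    if isinstance(values_by_metric, (list, tuple)):
        reports = values_by_metric
        if not reports:
            raise ParameterError("cannot summarize an empty report list")
        values_by_metric = {
            name: [getattr(r, name) for r in reports]
            for name in ("dsc_percent", "volume_mm3_auto", "volume_mm3_ref",
                         "voxels_auto", "voxels_ref")
        }
    if not values_by_metric:
        raise ParameterError("cannot summarize an empty metric dict")

    out = {}
    for name, vals in values_by_metric.items():
        arr = np.asarray(vals, dtype=np.float64)
        if arr.size == 0:
            raise ParameterError(f"metric {name!r} has no values")
        sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
        out[name] = {
            "min": float(arr.min()),
            "max": float(arr.max()),
            "mean": float(arr.mean()),
            "sd": sd,
            "n": int(arr.size),
        }
    return out
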