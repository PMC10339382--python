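"""Response surfaces of extreme von Mises stress and force-trend analysis.

For every snapshot the extreme (maximum, or a configurable percentile)
von Mises stress over a tissue region is extracted, giving a 2-D response
surface over the (Fy, Fz) grid — one surface per region of interest (root
dentin, periodontal ligament). Along each force axis the trend of the
extreme stress is summarized by its percent increase between the lowest and
highest load and classified as linear or quadratic from competing
polynomial fits.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .geometry import Mesh, Region
from .snapshots import SnapshotTensor

__all__ = [
    "ResponseSurface",
    "TrendResult",
    "extreme_vms",
    "percent_increase",
    "classify_trend",
    "region_node_mask",
]


@dataclass
class ResponseSurface:
    """Extreme stress (MPa) per grid point for one region."""

    region: str
    values: np.ndarray  # (n_fy, n_fz)
    fy_values: np.ndarray
    fz_values: np.ndarray
    statistic: str = "max"
    percentile: Optional[float] = None

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: fy, fz, region, extreme_vms."""
        fy, fz = np.meshgrid(self.fy_values, self.fz_values, indexing="ij")
        return pd.DataFrame(
            {
                "fy_N": fy.ravel(),
                "fz_N": fz.ravel(),
                "region": self.region,
                "extreme_vms_MPa": self.values.ravel(),
            }
        )


@dataclass
class TrendResult:
    """Trend of extreme stress along one force axis.

    ``classification`` is "quadratic" only when the degree-2 fit reduces the
    relative RMSE by more than ``rmse_factor`` over the degree-1 fit *and*
    the quadratic term contributes more than ``curvature_floor`` of the
    response range — otherwise noise-level curvature would be promoted.
    """

    axis: str
    percent_increase: float
    classification: str
    coeffs_deg1: list
    coeffs_deg2: list
    rel_rmse_deg1: float
    rel_rmse_deg2: float

    def to_dict(self) -> dict:
        return asdict(self)


def region_node_mask(mesh: Mesh, region: Region) -> np.ndarray:
    """Boolean node mask for one tissue region."""
    keep = np.zeros(mesh.n_nodes, dtype=bool)
    keep[np.unique(mesh.elements[mesh.region_tag == region])] = True
    return keep


def extreme_vms(
    tensor: SnapshotTensor,
    region_mask: np.ndarray,
    region_name: str = "ROOT",
    statistic: str = "max",
    percentile: float = 99.0,
) -> ResponseSurface:
    """Per-grid-point extreme stress over the masked nodes.

    ``statistic="max"`` takes the maximum (the conventional definition);
    ``"percentile"`` uses the given percentile instead, which is less
    sensitive to mesh-dependent stress concentrations.
    """
    mask = np.asarray(region_mask, dtype=bool)
    if mask.shape[0] != tensor.n_nodes or not mask.any():
        raise ValidationError("region mask must be nonempty and match the node count")
    sub = tensor.values[mask]
    if statistic == "max":
        vals = sub.max(axis=0)
    elif statistic == "percentile":
        vals = np.percentile(sub, percentile, axis=0)
    else:
        raise ValidationError(f"unknown statistic {statistic!r}")
    return ResponseSurface(
        region=region_name,
        values=vals,
        fy_values=tensor.grid.fy_values,
        fz_values=tensor.grid.fz_values,
        statistic=statistic,
        percentile=percentile if statistic == "percentile" else None,
    )


def percent_increase(values: np.ndarray) -> float:
    """100 · (last − first) / first along one traversed axis."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValidationError("need at least 2 values")
    if not v[0] > 0:
        raise ValidationError("percent increase undefined for nonpositive start value")
    return float(100.0 * (v[-1] - v[0]) / v[0])


def classify_trend(
    axis_values: np.ndarray,
    response_values: np.ndarray,
    axis: str = "fy",
    rmse_factor: float = 2.0,
    curvature_floor: float = 0.05,
) -> TrendResult:
    """Linear-vs-quadratic classification of a response along one axis.

    Degree-1 and degree-2 least-squares fits are compared through their
    RMSE relative to the response's root-mean-square. The trend is
    quadratic only if the quadratic fit improves the relative RMSE by more
    than ``rmse_factor`` and its curvature term spans more than
    ``curvature_floor`` of the response range over the axis interval.
    """
    x = np.asarray(axis_values, dtype=float)
    y = np.asarray(response_values, dtype=float)
    if x.size != y.size:
        raise ValidationError("axis and response must have equal length")
    if x.size < 3:
        raise ValidationError("quadratic classification needs at least 3 points")

    # centre/scale the axis for numerical conditioning of the fits
    x0 = x.mean()
    xs = (x - x0) / (x.max() - x.min())
    c1 = np.polyfit(xs, y, 1)
    c2 = np.polyfit(xs, y, 2)
    rms = np.sqrt(np.mean(y**2))
    if rms == 0:
        rms = 1.0
    rmse1 = float(np.sqrt(np.mean((np.polyval(c1, xs) - y) ** 2)) / rms)
    rmse2 = float(np.sqrt(np.mean((np.polyval(c2, xs) - y) ** 2)) / rms)

    y_range = float(y.max() - y.min())
    span = float(xs.max() - xs.min())
    curvature = abs(c2[0]) * (span / 2.0) ** 2
    is_quadratic = (
        rmse2 < rmse1 / rmse_factor
        and curvature > curvature_floor * max(y_range, 1e-30)
    )
    return TrendResult(
        axis=axis,
        percent_increase=percent_increase(y),
        classification="quadratic" if is_quadratic else "linear",
        coeffs_deg1=list(map(float, c1)),
        coeffs_deg2=list(map(float, c2)),
        rel_rmse_deg1=rmse1,
        rel_rmse_deg2=rmse2,
    )
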