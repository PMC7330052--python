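"""Theta-angle dose calling from two-channel fluorescence signals.

Each sample/marker point (x = A-channel, y = M-channel) is summarised by the
angle theta between the x axis and the line joining the origin to the point.
Per-marker anchors are calibrated from control samples of known genotype
(homozygous AA near the x axis, homozygous MM near the y axis, and a 1:1
heterozygous reference). The expected theta of an M-allele fraction f is
obtained by piecewise-linear interpolation through (0, theta_AA),
(1/2, theta_het), (1, theta_MM); a triploid carrying d M doses has
f = d/3, and each point is assigned the dose whose expected theta is
nearest. Points nearest to f = 1 (an impossible MMM triploid in this cross)
are flagged invalid and set missing, as are points with radial intensity
below the QC threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import DataError, DoseMatrix, MarkerDef

DOSE_FRACTIONS = (0.0, 1.0 / 3.0, 2.0 / 3.0, 1.0)  # f = d/3; f = 1 is invalid


class CallingError(ValueError):
    pass


@dataclass(frozen=True)
class ThetaAnchors:
    """Per-marker calibration: mean control thetas and an intensity floor."""

    theta_AA: float
    theta_het: float
    theta_MM: float
    min_intensity: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.theta_AA < self.theta_het < self.theta_MM <= 90.0):
            raise CallingError(
                "anchor ordering violated: need 0 <= theta_AA < theta_het "
                f"< theta_MM <= 90, got ({self.theta_AA}, {self.theta_het}, "
                f"{self.theta_MM})"
            )

    def expected_theta(self, f: float) -> float:
        """Piecewise-linear expected theta for M-allele fraction f in [0, 1]."""
        if f <= 0.5:
            return self.theta_AA + (self.theta_het - self.theta_AA) * (f / 0.5)
        return self.theta_het + (self.theta_MM - self.theta_het) * ((f - 0.5) / 0.5)


def theta(x: float, y: float) -> float:
    """Angle in degrees in [0, 90]; undefined (NaN) at the origin."""
    if not (math.isfinite(x) and math.isfinite(y)) or x < 0 or y < 0:
        raise CallingError(f"signals must be finite and non-negative, got ({x}, {y})")
    if x == 0.0 and y == 0.0:
        return float("nan")
    return math.degrees(math.atan2(y, x))


def calibrate_anchors(
    controls: pd.DataFrame,
    marker_ids: list[str],
    min_intensity_frac: float = 0.10,
) -> dict[str, ThetaAnchors]:
    """Anchor thetas per marker from control records.

    ``controls`` needs columns sample_id, marker_id, genotype (AA/AM/MM),
    x_signal, y_signal; a marker_id of "*" applies a control row to every
    marker. Each anchor is the mean theta of its class's controls. The
    intensity floor is ``min_intensity_frac`` times the median control
    radial norm of the marker.
    """
    required = {"sample_id", "marker_id", "genotype", "x_signal", "y_signal"}
    if not required.issubset(controls.columns):
        raise DataError(f"control table must have columns {sorted(required)}")
    anchors: dict[str, ThetaAnchors] = {}
    for mid in marker_ids:
        sub = controls[(controls["marker_id"] == mid) | (controls["marker_id"] == "*")]
        class_thetas: dict[str, list[float]] = {"AA": [], "AM": [], "MM": []}
        norms: list[float] = []
        for row in sub.itertuples(index=False):
            if row.genotype not in class_thetas:
                raise CallingError(f"unknown control genotype {row.genotype!r}")
            t = theta(float(row.x_signal), float(row.y_signal))
            if math.isnan(t):
                continue
            class_thetas[row.genotype].append(t)
            norms.append(math.hypot(float(row.x_signal), float(row.y_signal)))
        for cls, vals in class_thetas.items():
            if not vals:
                raise CallingError(f"marker {mid}: no control for class {cls}")
        anchors[mid] = ThetaAnchors(
            theta_AA=float(np.mean(class_thetas["AA"])),
            theta_het=float(np.mean(class_thetas["AM"])),
            theta_MM=float(np.mean(class_thetas["MM"])),
            min_intensity=min_intensity_frac * float(np.median(norms)),
        )
    return anchors


def call_dose(
    x: float, y: float, anchors: ThetaAnchors
) -> float:
    """Dose call for one point: 0/1/2, NaN for low intensity or invalid (MMM)."""
    if math.hypot(x, y) < anchors.min_intensity:
        return float("nan")
    t = theta(x, y)
    if math.isnan(t):
        return float("nan")
    expected = [anchors.expected_theta(f) for f in DOSE_FRACTIONS]
    dists = [abs(t - e) for e in expected]
    # ties (a point exactly on a cluster boundary) resolve to the lower dose
    d = int(np.flatnonzero(np.asarray(dists) <= min(dists) + 1e-9)[0])
    if d == 3:  # nearest to f=1: impossible MMM triploid in this cross
        return float("nan")
    return float(d)


def call_doses(
    signals: pd.DataFrame,
    anchors: dict[str, ThetaAnchors],
    markers: dict[str, MarkerDef],
) -> DoseMatrix:
    """Call a full signal table (sample_id, marker_id, x_signal, y_signal)."""
    required = {"sample_id", "marker_id", "x_signal", "y_signal"}
    if not required.issubset(signals.columns):
        raise DataError(f"signal table must have columns {sorted(required)}")
    marker_ids = list(dict.fromkeys(signals["marker_id"]))
    for mid in marker_ids:
        if mid not in anchors:
            raise CallingError(f"no calibrated anchors for marker {mid}")
        if mid not in markers:
            raise DataError(f"marker {mid} absent from metadata")
    sample_ids = list(dict.fromkeys(signals["sample_id"]))
    sample_index = {s: i for i, s in enumerate(sample_ids)}
    marker_index = {m: j for j, m in enumerate(marker_ids)}
    dose = np.full((len(sample_ids), len(marker_ids)), np.nan)
    for row in signals.itertuples(index=False):
        i = sample_index[row.sample_id]
        j = marker_index[row.marker_id]
        dose[i, j] = call_dose(float(row.x_signal), float(row.y_signal), anchors[row.marker_id])
    return DoseMatrix(
        samples=sample_ids, markers=[markers[m] for m in marker_ids], dose=dose
    )
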