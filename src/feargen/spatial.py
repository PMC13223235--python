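"""Spatial generalization analysis: glomerular overlap and proximity.

Two spatial mechanisms of fear generalization are quantified on ROI
centers in µm field coordinates:

* **overlap** — a CS− ROI counts as overlapping the CS+ representation when
  its center lies within 70 µm (one small-glomerulus width) of *any* CS+
  ROI center in the same animal;
* **proximity** — each ROI's Euclidean distance to the maximally responsive
  pre-drug CS+ ROI, categorized at 400 µm (about four glomerular widths).

Both cuts are boundary-inclusive ("within"), and both are computed
center-to-center.  ROI centers come from pixel coordinates times the
µm-per-pixel calibration (default 10 µm/pixel).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from ._exceptions import ValidationError

OVERLAP_RADIUS_UM = 70.0
PROXIMITY_CUT_UM = 400.0
DEFAULT_UM_PER_PIXEL = 10.0


@dataclass
class RoiGeometry:
    """An ROI's µm-calibrated center and its per-odor responsiveness."""

    roi: int
    center_um: tuple[float, float]
    responsive_odors: frozenset = field(default_factory=frozenset)

    @classmethod
    def from_pixels(cls, roi: int, center_px, um_per_pixel: float = DEFAULT_UM_PER_PIXEL,
                    responsive_odors=()) -> "RoiGeometry":
        if um_per_pixel <= 0:
            raise ValidationError("um_per_pixel must be > 0")
        return cls(roi=roi,
                   center_um=(center_px[0] * um_per_pixel, center_px[1] * um_per_pixel),
                   responsive_odors=frozenset(responsive_odors))


@dataclass
class OverlapLabel:
    roi: int
    label: str  # "overlapping" | "non_overlapping"
    distance_um: float  # to the nearest CS+ ROI


@dataclass
class ProximityLabel:
    roi: int
    distance_um: float  # to the max-ΔF/F CS+ ROI
    category: str  # "within_400" | "beyond_400"


def find_max_cs_roi(responses) -> int:
    """ROI with the maximal pre-drug mean peak for the CS+ odor.

    `responses` is a sequence of objects with ``roi`` and ``mean_peak``
    attributes (e.g. :class:`feargen.imaging.RoiResponse`) or a DataFrame
    with roi/peak columns.  Ties break toward the lowest ROI id.
    """
    if isinstance(responses, pd.DataFrame):
        if responses.empty:
            raise ValidationError("no CS+ responses")
        agg = responses.groupby("roi")["peak"].mean()
        best = agg.max()
        return int(min(agg.index[agg == best]))
    responses = list(responses)
    if not responses:
        raise ValidationError("no CS+ responses")
    pairs = sorted(((r.mean_peak, -r.roi) for r in responses))
    return int(-pairs[-1][1])


def _centers(rois) -> np.ndarray:
    return np.array([r.center_um for r in rois], dtype=float).reshape(-1, 2)


def classify_overlap(cs_minus: list[RoiGeometry], cs_plus: list[RoiGeometry],
                     radius: float = OVERLAP_RADIUS_UM) -> list[OverlapLabel]:
    """Label each CS− ROI by its minimum center distance to the CS+ set.

    Distance exactly equal to `radius` counts as overlapping.  Labels are
    independent of the ordering of either ROI list.
    """
    if not cs_plus:
        raise ValidationError("empty CS+ ROI set")
    if not cs_minus:
        return []
    d = cdist(_centers(cs_minus), _centers(cs_plus)).min(axis=1)
    return [
        OverlapLabel(roi=r.roi,
                     label="overlapping" if di <= radius else "non_overlapping",
                     distance_um=float(di))
        for r, di in zip(cs_minus, d)
    ]


def proximity_categorize(rois: list[RoiGeometry], anchor: int,
                         cut: float = PROXIMITY_CUT_UM) -> list[ProximityLabel]:
    """Euclidean distance of every ROI to the anchor ROI, two-way
    categorized at `cut` µm (boundary inclusive into within_400)."""
    by_id = {r.roi: r for r in rois}
    if anchor not in by_id:
        raise ValidationError(f"unknown anchor ROI {anchor}")
    ax, ay = by_id[anchor].center_um
    out = []
    for r in rois:
        d = float(np.hypot(r.center_um[0] - ax, r.center_um[1] - ay))
        out.append(ProximityLabel(
            roi=r.roi, distance_um=d,
            category="within_400" if d <= cut else "beyond_400"))
    return out


def group_effects_by_label(effects: pd.DataFrame, labels) -> pd.DataFrame:
    """Per-label-group n / mean / SEM of drug effects.

    `effects` needs roi and drug_effect_pct columns; `labels` is a list of
    OverlapLabel or ProximityLabel objects (their ``label``/``category``
    field defines the groups) and must cover every effect row.  Empty
    groups are reported with n=0 and NaN mean/SEM.
    """
    lab_map = {}
    group_names = set()
    for lb in labels:
        name = getattr(lb, "label", None) or getattr(lb, "category")
        lab_map[lb.roi] = name
        group_names.add(name)
    missing = sorted(set(effects["roi"]) - set(lab_map))
    if missing:
        raise ValidationError(f"effect rows without labels: ROIs {missing}")
    df = effects.copy()
    df["group"] = df["roi"].map(lab_map)
    rows = []
    for name in sorted(group_names):
        vals = df.loc[df["group"] == name, "drug_effect_pct"].to_numpy(float)
        n = len(vals)
        rows.append({
            "group": name, "n": n,
            "mean": float(vals.mean()) if n else np.nan,
            "sem": float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan,
        })
    return pd.DataFrame(rows)
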