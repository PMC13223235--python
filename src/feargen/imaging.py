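"""Odor-evoked response quantification for widefield calcium imaging.

Implements the imaging arm of the pipeline: per-ROI ΔF/F traces, peak
responses within the odor window, pre-drug -> post-drug percent change (the
main dependent variable of the drug experiments), temporal-bin profiles, and
cumulative-percentile distributions of effect sizes.

Trial structure
---------------
Each trial is a 20-s acquisition at 50 Hz: 225 pre-odor frames, 350 odor
frames, and 425 post-odor frames (1000 frames total).  ΔF/F is computed
against the mean fluorescence of the final second (50 frames) of the
pre-odor segment:

    ΔF/F_t = (F_t - B) / B,   B = mean(F over the 50 frames before onset)

ΔF/F is invariant to multiplicative rescaling of F but *not* to additive
offsets; uncorrected offsets (e.g., camera bias) must be removed upstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._exceptions import ValidationError

DEFAULT_SEGMENTS = (225, 350, 425)
DEFAULT_FRAME_RATE = 50.0
#: Baseline = final 1 s of the pre-odor period.
BASELINE_FRAMES = 50
#: Peak search extends this far past odor offset to allow for indicator lag.
PEAK_LAG_S = 0.5


@dataclass
class ImagingTrial:
    """One odor trial: a (T, H, W) frame stack plus acquisition metadata."""

    frames: np.ndarray
    odor: str
    phase: str  # "pre" (pre-drug) or "post" (post-drug)
    mock: bool = False
    block: int = 0
    trial: int = 0
    frame_rate: float = DEFAULT_FRAME_RATE
    segments: tuple[int, int, int] = DEFAULT_SEGMENTS

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValidationError("frames must be a (T, H, W) stack")
        if self.frames.shape[0] != sum(self.segments):
            raise ValidationError(
                f"frame count {self.frames.shape[0]} does not equal the sum of "
                f"segment lengths {self.segments} = {sum(self.segments)}"
            )
        if self.phase not in ("pre", "post"):
            raise ValidationError(f"phase must be 'pre' or 'post', got {self.phase!r}")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def odor_onset(self) -> int:
        """Frame index of odor onset."""
        return self.segments[0]

    @property
    def odor_offset(self) -> int:
        """Frame index one past the last odor frame."""
        return self.segments[0] + self.segments[1]


@dataclass
class RoiTrace:
    """Per-frame ΔF/F of one ROI, with the trial context needed downstream."""

    roi: int
    dff: np.ndarray
    frame_rate: float
    odor_onset: int
    odor_offset: int
    odor: str = ""
    phase: str = "pre"
    mock: bool = False
    block: int = 0
    trial: int = 0


@dataclass
class RoiResponse:
    """Per-phase response summary of one ROI: per-trial peaks and their mean."""

    roi: int
    odor: str
    phase: str
    peaks: list[float] = field(default_factory=list)
    latencies_s: list[float] = field(default_factory=list)
    mock: bool = False

    @property
    def mean_peak(self) -> float:
        if not self.peaks:
            raise ValidationError("RoiResponse has no recorded trials")
        return float(np.mean(self.peaks))

    @property
    def mean_latency_s(self) -> float:
        return float(np.mean(self.latencies_s))


@dataclass
class DrugEffect:
    """Pre-drug -> post-drug percent change of the mean peak ΔF/F of one ROI."""

    roi: int
    odor: str
    percent_change: float


def compute_dff(trial: ImagingTrial, roi_mask: np.ndarray, roi: int = 0,
                baseline_frames: int = BASELINE_FRAMES) -> RoiTrace:
    """ΔF/F trace of one ROI.

    The per-frame ROI fluorescence is the mean over the mask; the baseline B
    is the mean of the `baseline_frames` frames immediately preceding odor
    onset.  Raises on an empty mask or a non-positive baseline.
    """
    mask = np.asarray(roi_mask, dtype=bool)
    if mask.shape != trial.frames.shape[1:]:
        raise ValidationError(
            f"mask shape {mask.shape} does not match frame shape {trial.frames.shape[1:]}"
        )
    if not mask.any():
        raise ValidationError("ROI mask is empty")
    raw = trial.frames[:, mask].mean(axis=1)
    onset = trial.odor_onset
    if baseline_frames <= 0 or baseline_frames > onset:
        raise ValidationError("baseline window must fit inside the pre-odor segment")
    baseline = float(raw[onset - baseline_frames:onset].mean())
    if baseline <= 0:
        raise ValidationError(f"non-positive baseline fluorescence ({baseline})")
    dff = (raw - baseline) / baseline
    return RoiTrace(
        roi=roi, dff=dff, frame_rate=trial.frame_rate,
        odor_onset=onset, odor_offset=trial.odor_offset,
        odor=trial.odor, phase=trial.phase, mock=trial.mock,
        block=trial.block, trial=trial.trial,
    )


def peak_response(trace: RoiTrace, window: tuple[int, int] | None = None):
    """Maximum ΔF/F within the search window and its latency from odor onset.

    The default window runs from odor onset to odor offset plus a 0.5-s lag
    allowance.  Ties are broken by the earliest frame.  Returns
    ``(peak_value, latency_s)``.
    """
    if window is None:
        lag = int(round(PEAK_LAG_S * trace.frame_rate))
        window = (trace.odor_onset, min(trace.odor_offset + lag, len(trace.dff)))
    lo, hi = int(window[0]), int(window[1])
    if not (0 <= lo < hi <= len(trace.dff)):
        raise ValidationError(f"empty or out-of-range peak window {window}")
    seg = trace.dff[lo:hi]
    idx = int(np.argmax(seg))  # argmax returns the first maximum: earliest-frame tie-break
    peak = float(seg[idx])
    latency_s = (lo + idx - trace.odor_onset) / trace.frame_rate
    return peak, latency_s


def temporal_profile(trace: RoiTrace, n_intervals: int = 4,
                     interval_s: float = 2.0) -> np.ndarray:
    """Per-interval maxima of ΔF/F over consecutive 2-s intervals from odor onset.

    The four default intervals span 8 s from onset; since the odor lasts 7 s
    the final interval includes 1 s of the post-odor period.
    """
    n_per = int(round(interval_s * trace.frame_rate))
    need = trace.odor_onset + n_intervals * n_per
    if len(trace.dff) < need:
        raise ValidationError(
            f"trace too short for {n_intervals} x {interval_s}-s intervals "
            f"(need {need} frames, have {len(trace.dff)})"
        )
    out = np.empty(n_intervals)
    for i in range(n_intervals):
        lo = trace.odor_onset + i * n_per
        out[i] = trace.dff[lo:lo + n_per].max()
    return out


def drug_effect(pre: RoiResponse, post: RoiResponse) -> DrugEffect:
    """Percent change of mean peak ΔF/F from pre-drug to post-drug.

    Requires matching ROI/odor, at least one recorded trial per phase, no
    mock trials, and a positive pre-drug mean peak.
    """
    if pre.mock or post.mock:
        raise ValidationError("mock trials must be excluded before computing drug effects")
    if (pre.roi, pre.odor) != (post.roi, post.odor):
        raise ValidationError(
            f"mismatched ROI/odor: pre=({pre.roi}, {pre.odor}) post=({post.roi}, {post.odor})"
        )
    if not pre.peaks or not post.peaks:
        raise ValidationError("each phase needs at least one recorded trial")
    pre_mean = pre.mean_peak
    if pre_mean <= 0:
        raise ValidationError(f"non-positive pre-drug mean peak ({pre_mean})")
    pct = 100.0 * (post.mean_peak - pre_mean) / pre_mean
    return DrugEffect(roi=pre.roi, odor=pre.odor, percent_change=pct)


def cumulative_percentile(values, convention: str = "ecdf") -> pd.DataFrame:
    """Ordered (value, percentile) pairs of an effect-size distribution.

    ``ecdf``: percentile of x = fraction of values <= x (monotone
    non-decreasing; identical values form a step).  ``midpoint``: plotting
    positions (i - 0.5)/n over the sorted sample.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValidationError("empty value list")
    order = np.sort(v)
    if convention == "ecdf":
        pct = np.searchsorted(order, order, side="right") / v.size
    elif convention == "midpoint":
        pct = (np.arange(1, v.size + 1) - 0.5) / v.size
    else:
        raise ValidationError(f"unknown percentile convention {convention!r}")
    return pd.DataFrame({"value": order, "percentile": pct})


def behavior_physiology_pairs(effects: pd.DataFrame,
                              immobility: pd.DataFrame) -> pd.DataFrame:
    """Pair per-mouse-per-odor mean drug effects with immobility percentages.

    Both tables must carry ``mouse`` and ``odor`` key columns plus
    ``drug_effect_pct`` / ``immobility_pct`` respectively; unmatched keys on
    either side raise an error naming them.  Returns one row per mouse x odor.
    """
    for df, col in ((effects, "drug_effect_pct"), (immobility, "immobility_pct")):
        missing = {"mouse", "odor", col} - set(df.columns)
        if missing:
            raise ValidationError(f"missing columns {sorted(missing)}")
    left = effects.groupby(["mouse", "odor"], as_index=False)["drug_effect_pct"].mean()
    right = immobility[["mouse", "odor", "immobility_pct"]]
    merged = left.merge(right, on=["mouse", "odor"], how="outer", indicator=True)
    bad = merged[merged["_merge"] != "both"]
    if len(bad):
        keys = [
            f"{m}/{o} ({'imaging' if w == 'left_only' else 'behavior'} only)"
            for m, o, w in zip(bad["mouse"], bad["odor"], bad["_merge"])
        ]
        raise ValidationError(f"unmatched mouse/odor keys: {keys}")
    return merged.drop(columns="_merge")


# ---------------------------------------------------------------------------
# session-level aggregation


def summarize_trials(trials, roi_masks: dict[int, np.ndarray],
                     rois_by_odor: dict[str, set] | None = None,
                     include_mock: bool = False,
                     window: tuple[int, int] | None = None,
                     smooth_frames: int = 5) -> pd.DataFrame:
    """Per-trial peak table: one row per ROI x trial.

    `rois_by_odor` optionally restricts which ROIs are scored for each odor
    (each animal/odor combination has its own ROI set); by default every ROI
    is scored for every trial.  The ΔF/F trace is boxcar-smoothed over
    `smooth_frames` frames (default 100 ms at 50 Hz) before peak detection,
    which suppresses the upward bias of a raw max over frame noise without
    touching a noise-free plateau response; set 1 to disable.
    """
    rows = []
    for t in trials:
        if t.mock and not include_mock:
            continue
        roi_ids = roi_masks.keys()
        if rois_by_odor is not None:
            roi_ids = [r for r in roi_ids if r in rois_by_odor.get(t.odor, ())]
        frames2d = t.frames.reshape(t.n_frames, -1)
        onset = t.odor_onset
        for r in roi_ids:
            mask = np.asarray(roi_masks[r], dtype=bool).ravel()
            if not mask.any():
                raise ValidationError(f"ROI {r} mask is empty")
            raw = frames2d[:, mask].mean(axis=1)
            baseline = float(raw[onset - BASELINE_FRAMES:onset].mean())
            if baseline <= 0:
                raise ValidationError(f"non-positive baseline for ROI {r}")
            dff = (raw - baseline) / baseline
            if smooth_frames > 1:
                kern = np.ones(smooth_frames) / smooth_frames
                dff = np.convolve(dff, kern, mode="same")
            trace = RoiTrace(roi=r, dff=dff, frame_rate=t.frame_rate,
                             odor_onset=onset, odor_offset=t.odor_offset,
                             odor=t.odor, phase=t.phase, mock=t.mock,
                             block=t.block, trial=t.trial)
            peak, lat = peak_response(trace, window)
            rows.append({"roi": r, "odor": t.odor, "phase": t.phase,
                         "block": t.block, "trial": t.trial, "mock": t.mock,
                         "peak": peak, "latency_s": lat})
    return pd.DataFrame(rows)


def phase_responses(peaks: pd.DataFrame) -> dict[tuple, RoiResponse]:
    """Collapse a per-trial peak table into RoiResponse objects keyed by
    (roi, odor, phase).  Mock rows are rejected."""
    if peaks.empty:
        raise ValidationError("empty peak table")
    if peaks["mock"].any():
        raise ValidationError("mock trials present in peak table; exclude them first")
    out = {}
    for (roi, odor, phase), grp in peaks.groupby(["roi", "odor", "phase"]):
        out[(roi, odor, phase)] = RoiResponse(
            roi=roi, odor=odor, phase=phase,
            peaks=grp["peak"].tolist(), latencies_s=grp["latency_s"].tolist(),
        )
    return out


def drug_effect_table(peaks: pd.DataFrame) -> pd.DataFrame:
    """Per-ROI drug effects from a per-trial peak table.

    Averages peaks across recorded trials within each phase, then computes
    the percent change — one dependent variable per ROI x odor.
    """
    responses = phase_responses(peaks)
    rows = []
    for (roi, odor, phase), resp in responses.items():
        if phase != "pre":
            continue
        post = responses.get((roi, odor, "post"))
        if post is None:
            raise ValidationError(f"ROI {roi}/{odor} has no post-drug trials")
        eff = drug_effect(resp, post)
        rows.append({"roi": roi, "odor": odor,
                     "drug_effect_pct": eff.percent_change})
    return pd.DataFrame(rows).sort_values(["odor", "roi"]).reset_index(drop=True)


def select_responsive_rois(peaks_with_baseline_sd: pd.DataFrame,
                           k: float = 3.0) -> dict[str, set]:
    """Automated stand-in for manual ROI curation.

    Keeps, per odor, the ROIs whose trial-averaged peak ΔF/F exceeds
    ``k`` x the SD of the baseline ΔF/F.  Input needs columns
    roi/odor/peak/baseline_sd; explicit ROI lists can always be supplied to
    the downstream functions instead.
    """
    need = {"roi", "odor", "peak", "baseline_sd"}
    if need - set(peaks_with_baseline_sd.columns):
        raise ValidationError(f"need columns {sorted(need)}")
    agg = peaks_with_baseline_sd.groupby(["roi", "odor"], as_index=False).agg(
        mean_peak=("peak", "mean"), baseline_sd=("baseline_sd", "mean"))
    out: dict[str, set] = {}
    for _, row in agg.iterrows():
        if row["mean_peak"] > k * row["baseline_sd"] and row["mean_peak"] > 0:
            out.setdefault(row["odor"], set()).add(row["roi"])
    return out
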