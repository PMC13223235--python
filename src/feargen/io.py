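"""File formats, run configuration, and provenance.

Artifacts are plain, auditable formats: trajectories as CSV
(``time_s,x,y``), imaging trials as multi-frame TIFF with a JSON metadata
sidecar, ROI geometry and ground truth as JSON, run configuration as YAML.
CSV dialect is comma-separated UTF-8 with period decimals and a mandatory
header.  Every pipeline stage can stamp its outputs with a provenance
record (stage name, config hash, seed).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import arena as _arena
from ._exceptions import MissingArtifactError, ValidationError
from .behavior import Trajectory
from .imaging import DEFAULT_FRAME_RATE, DEFAULT_SEGMENTS, ImagingTrial

# ---------------------------------------------------------------------------
# trajectories


def read_trajectory_csv(path, arena=_arena.DEFAULT_ARENA,
                        corner_odors=None) -> Trajectory:
    """Read a tracked centroid path (EthoVision-style export).

    Requires a header with time_s, x, y; strictly increasing time is
    enforced and violations are reported with their row numbers (1-based,
    excluding the header).
    """
    path = Path(path)
    if not path.exists():
        raise MissingArtifactError(f"trajectory file not found: {path}")
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - report parse failures uniformly
        raise ValidationError(f"unparseable trajectory CSV {path}: {exc}") from exc
    missing = {"time_s", "x", "y"} - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    for col in ("time_s", "x", "y"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = np.nonzero(coerced.isna().to_numpy())[0]
        if bad.size:
            raise ValidationError(
                f"{path}: unparseable {col} values at rows {(bad + 1).tolist()[:20]}")
        df[col] = coerced
    t = df["time_s"].to_numpy(float)
    bad = np.nonzero(np.diff(t) <= 0)[0]
    if bad.size:
        raise ValidationError(
            f"{path}: time not strictly increasing at rows {(bad + 2).tolist()[:20]}")
    return Trajectory(t=t, x=df["x"].to_numpy(float), y=df["y"].to_numpy(float),
                      arena=arena,
                      corner_odors=dict(corner_odors or _arena.DEFAULT_CORNER_ODORS))


def write_trajectory_csv(traj: Trajectory, path) -> None:
    pd.DataFrame({"time_s": traj.t, "x": traj.x, "y": traj.y}).to_csv(
        path, index=False)


# ---------------------------------------------------------------------------
# imaging trials


def write_trial_tiff(trial: ImagingTrial, path, sidecar_path=None) -> None:
    """One multi-frame TIFF per trial plus a JSON metadata sidecar."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(trial.frames, dtype=np.float32),
                     photometric="minisblack")
    sidecar_path = Path(sidecar_path) if sidecar_path else path.with_suffix(".json")
    meta = {"odor": trial.odor, "phase": trial.phase, "mock": bool(trial.mock),
            "block": int(trial.block), "trial": int(trial.trial),
            "frame_rate": trial.frame_rate, "segments": list(trial.segments)}
    sidecar_path.write_text(json.dumps(meta, indent=1))


def read_trial_tiff(path, sidecar_path=None) -> ImagingTrial:
    """Read a trial back, validating the frame count against the sidecar's
    segment boundaries."""
    path = Path(path)
    if not path.exists():
        raise MissingArtifactError(f"trial TIFF not found: {path}")
    sidecar_path = Path(sidecar_path) if sidecar_path else path.with_suffix(".json")
    if not sidecar_path.exists():
        raise MissingArtifactError(f"trial sidecar not found: {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    frames = tifffile.imread(path)
    segments = tuple(meta.get("segments", DEFAULT_SEGMENTS))
    if frames.shape[0] != sum(segments):
        raise ValidationError(
            f"{path}: frame count {frames.shape[0]} does not match sidecar "
            f"segments {segments} (= {sum(segments)})")
    return ImagingTrial(frames=frames, odor=meta["odor"], phase=meta["phase"],
                        mock=bool(meta["mock"]), block=int(meta["block"]),
                        trial=int(meta["trial"]),
                        frame_rate=float(meta.get("frame_rate", DEFAULT_FRAME_RATE)),
                        segments=segments)


# ---------------------------------------------------------------------------
# ROI geometry


def write_rois_json(path, centers_px, um_per_pixel: float,
                    responsive_odors: dict[int, list[str]] | None = None) -> None:
    rois = []
    for i, c in enumerate(centers_px):
        rec = {"roi": i, "center_px": [float(c[0]), float(c[1])]}
        if responsive_odors and i in responsive_odors:
            rec["responsive_odors"] = sorted(responsive_odors[i])
        rois.append(rec)
    Path(path).write_text(json.dumps(
        {"um_per_pixel": um_per_pixel, "rois": rois}, indent=1))


def read_rois_json(path):
    """Returns (list of RoiGeometry, um_per_pixel)."""
    from .spatial import RoiGeometry

    path = Path(path)
    if not path.exists():
        raise MissingArtifactError(f"ROI file not found: {path}")
    data = json.loads(path.read_text())
    upp = float(data["um_per_pixel"])
    rois = [
        RoiGeometry.from_pixels(int(r["roi"]), r["center_px"], upp,
                                r.get("responsive_odors", ()))
        for r in data["rois"]
    ]
    return rois, upp


# ---------------------------------------------------------------------------
# configuration and provenance


@dataclass
class RunConfig:
    """All pipeline thresholds and labels in one round-trippable record."""

    odors: tuple[str, ...] = ("MV", "BA", "HEX")
    cs_plus: str = "MV"
    um_per_pixel: float = 10.0
    overlap_radius_um: float = 70.0
    proximity_cut_um: float = 400.0
    immobility_speed_threshold: float = 2.0
    immobility_min_still_s: float = 1.0
    exclusion_min_difference_pct: float = 5.0
    ess_interval_s: float = 5.0
    arena: tuple[float, float] = _arena.DEFAULT_ARENA
    seed: int = 0
    paths: dict = field(default_factory=dict)

    def __post_init__(self):
        for name in ("um_per_pixel", "overlap_radius_um", "proximity_cut_um",
                     "immobility_speed_threshold", "immobility_min_still_s",
                     "exclusion_min_difference_pct", "ess_interval_s"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if self.cs_plus not in self.odors:
            raise ValidationError(f"CS+ {self.cs_plus!r} not among odors {self.odors}")

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["odors"] = list(d["odors"])
        d["arena"] = list(d["arena"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise MissingArtifactError(f"config not found: {path}")
        d = yaml.safe_load(path.read_text())
        d["odors"] = tuple(d.get("odors", ("MV", "BA", "HEX")))
        d["arena"] = tuple(d.get("arena", _arena.DEFAULT_ARENA))
        return cls(**d)

    def hash(self) -> str:
        d = asdict(self)
        d["odors"] = list(d["odors"])
        d["arena"] = list(d["arena"])
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def write_provenance(path, stage: str, config: RunConfig, seed: int,
                     extra: dict | None = None) -> None:
    rec = {"stage": stage, "config_hash": config.hash(), "seed": int(seed)}
    if extra:
        rec.update(extra)
    Path(path).write_text(json.dumps(rec, indent=1, sort_keys=True))
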