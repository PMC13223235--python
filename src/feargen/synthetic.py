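"""Synthetic imaging sessions and arena trajectories with exported ground truth.

This module emulates the statistical structure of the study's two data
streams so that every downstream stage is testable without raw data:

* **Imaging**: per animal, three odors (MV = threat-predictive, BA =
  similar, HEX = dissimilar) imaged over six 8-trial blocks (three pre-drug,
  three post-drug); within each block the first four trials are mock
  presentations at 2% odor strength and the last four are recorded.  Each
  trial is 1000 frames at 50 Hz (225 pre-odor / 350 odor / 425 post-odor).
  Glomeruli are isotropic 2-D Gaussians (σ = radius/2) on a µm-calibrated
  field; odor tuning controls which glomeruli respond to which odors and how
  strongly the MV and BA representations overlap relative to MV and HEX.
  Post-infusion responses are scaled by an odor-specific drug multiplier
  times a nonspecific rundown factor (~5% decline mimicking the vehicle
  effect).

* **Behavior**: 5-min open-field trajectories in an 18 x 18 arena with MV
  and BA in adjacent corners, generated under one of four occupancy
  hypotheses (no fear / MV-specific fear / similarity gradient /
  overgeneralization).  The zone sequence is a Metropolis–Hastings random
  walk on the 3x3 zone grid whose stationary distribution is exactly the
  model's zone-probability vector, dressed with continuous within-zone
  jitter and straight-line crossings between adjacent zones.

All randomness derives from a single master seed via
``numpy.random.SeedSequence([master, counter])``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import arena as _arena
from ._exceptions import InfeasibleLayoutError, ValidationError
from .behavior import Trajectory
from .imaging import DEFAULT_FRAME_RATE, DEFAULT_SEGMENTS, ImagingTrial

ODORS = _arena.ODORS

# ---------------------------------------------------------------------------
# layout and tuning


@dataclass
class GlomerularLayout:
    """Synthetic stand-in for a dorsal-bulb glomerular map.

    centers are µm positions on a rectangular field; each glomerulus renders
    as an isotropic Gaussian with σ = radius/2.
    """

    centers: np.ndarray  # (n, 2) µm
    radii: np.ndarray  # (n,) µm
    field_size: tuple[float, float]  # µm
    um_per_pixel: float

    def __post_init__(self):
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        self.radii = np.atleast_1d(np.asarray(self.radii, dtype=float))
        if self.um_per_pixel <= 0:
            raise ValidationError("um_per_pixel must be > 0")
        w, h = self.field_size
        if ((self.centers[:, 0] < 0) | (self.centers[:, 0] > w)
                | (self.centers[:, 1] < 0) | (self.centers[:, 1] > h)).any():
            raise ValidationError("glomerulus centers outside the field")

    @property
    def n(self) -> int:
        return len(self.centers)

    @property
    def shape_px(self) -> tuple[int, int]:
        """(H, W) pixel shape of the rendered field."""
        w, h = self.field_size
        return (int(round(h / self.um_per_pixel)), int(round(w / self.um_per_pixel)))

    def roi_masks(self) -> dict[int, np.ndarray]:
        """Disc masks (one per glomerulus) in pixel coordinates."""
        H, W = self.shape_px
        yy, xx = np.mgrid[0:H, 0:W]
        masks = {}
        for g in range(self.n):
            cx, cy = self.centers[g] / self.um_per_pixel
            r_px = max(self.radii[g] / self.um_per_pixel, 1.0)
            masks[g] = (xx - cx) ** 2 + (yy - cy) ** 2 <= r_px ** 2
        return masks

    def spatial_profiles(self) -> np.ndarray:
        """(n, H, W) Gaussian footprint of each glomerulus, peak 1 at center."""
        H, W = self.shape_px
        yy, xx = np.mgrid[0:H, 0:W]
        out = np.empty((self.n, H, W))
        for g in range(self.n):
            cx, cy = self.centers[g] / self.um_per_pixel
            sigma_px = (self.radii[g] / 2.0) / self.um_per_pixel
            out[g] = np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sigma_px ** 2))
        return out


def generate_layout(n_glomeruli: int, field_size: tuple[float, float] = (640.0, 640.0),
                    min_spacing: float = 70.0, seed: int = 0,
                    radius: float = 35.0, um_per_pixel: float = 20.0,
                    max_attempts_per_glomerulus: int = 400) -> GlomerularLayout:
    """Place glomeruli by rejection sampling under a minimum-spacing rule.

    Deterministic given the seed.  Raises :class:`InfeasibleLayoutError`
    when the requested density cannot be met within the attempt budget.
    """
    if n_glomeruli < 1:
        raise ValidationError("n_glomeruli must be >= 1")
    w, h = field_size
    if min_spacing >= math.hypot(w, h):
        raise ValidationError("min_spacing must be smaller than the field diagonal")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0]))
    margin = min(radius, w / 2, h / 2)
    centers: list[np.ndarray] = []
    budget = max_attempts_per_glomerulus * n_glomeruli
    attempts = 0
    while len(centers) < n_glomeruli:
        if attempts >= budget:
            raise InfeasibleLayoutError(
                f"could not place {n_glomeruli} glomeruli with spacing "
                f"{min_spacing} µm in a {w}x{h} µm field after {budget} attempts"
            )
        attempts += 1
        cand = rng.uniform([margin, margin], [w - margin, h - margin])
        if all(np.hypot(*(cand - c)) >= min_spacing for c in centers):
            centers.append(cand)
    return GlomerularLayout(
        centers=np.array(centers), radii=np.full(n_glomeruli, radius),
        field_size=field_size, um_per_pixel=um_per_pixel,
    )


@dataclass
class OdorTuning:
    """Per-odor response amplitudes (peak ΔF/F at glomerulus center) and the
    realized joint-responder structure."""

    amplitudes: dict[str, np.ndarray]  # odor -> (n,) ΔF/F amplitudes, >= 0
    overlap_design: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self):
        for odor, a in self.amplitudes.items():
            self.amplitudes[odor] = np.asarray(a, dtype=float)
            if (self.amplitudes[odor] < 0).any():
                raise ValidationError(f"negative amplitude for odor {odor}")

    def responders(self, odor: str) -> set[int]:
        return set(np.nonzero(self.amplitudes[odor] > 0)[0].tolist())

    def joint_responders(self, a: str, b: str) -> set[int]:
        return self.responders(a) & self.responders(b)


def design_tuning(layout: GlomerularLayout, seed: int = 0,
                  n_per_odor: int = 12,
                  overlap: dict[tuple[str, str], float] | None = None,
                  amp_mean: float = 0.30) -> OdorTuning:
    """Assign odor tuning with controlled representational overlap.

    Default overlap targets make the MV–BA joint-responder fraction (1/3)
    larger than MV–HEX (1/12), mirroring the observation that the MV map is
    closer to BA than to HEX.  Amplitudes are gamma-distributed around
    `amp_mean` ΔF/F.  Amplitudes are nominal *center* values; averaging a
    Gaussian footprint over its ROI disc attenuates them by (1 − e⁻²)/2 ≈
    0.43, so the defaults put effective ROI responses in the 5–15% ΔF/F
    range typical of curated glomerular responders.  The realized
    joint-responder counts are exact for the configured fractions (rounded
    to whole glomeruli).
    """
    if overlap is None:
        overlap = {("MV", "BA"): 4 / 12, ("MV", "HEX"): 1 / 12}
    n = layout.n
    k_mvba = int(round(overlap.get(("MV", "BA"), 0.0) * n_per_odor))
    k_mvhex = int(round(overlap.get(("MV", "HEX"), 0.0) * n_per_odor))
    if n < 3 * n_per_odor - k_mvba - k_mvhex:
        raise ValidationError(
            f"layout too small: need {3 * n_per_odor - k_mvba - k_mvhex} "
            f"glomeruli, have {n}"
        )
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 1]))
    perm = rng.permutation(n)
    mv = set(perm[:n_per_odor].tolist())
    rest = [g for g in perm if g not in mv]
    mv_list = [g for g in perm if g in mv]
    ba = set(mv_list[:k_mvba]) | set(rest[: n_per_odor - k_mvba])
    rest2 = [g for g in rest if g not in ba]
    hex_ = set(mv_list[k_mvba:k_mvba + k_mvhex]) | set(rest2[: n_per_odor - k_mvhex])
    amplitudes = {}
    for odor, members in (("MV", mv), ("BA", ba), ("HEX", hex_)):
        a = np.zeros(n)
        idx = sorted(members)
        # responders emulate *curated* ROIs: the floor keeps effective
        # (disc-averaged) responses at or above ~5% ΔF/F
        a[idx] = np.maximum(rng.gamma(4.0, amp_mean / 4.0, size=len(idx)), 0.12)
        amplitudes[odor] = a
    return OdorTuning(amplitudes=amplitudes, overlap_design=dict(overlap))


@dataclass
class DrugEffectSpec:
    """Multiplicative post-infusion response model.

    Post-infusion recorded trials carry ``multiplier[odor] * rundown_factor``
    on the odor-evoked amplitude; `noise_sd` is additive per-pixel-per-frame
    Gaussian noise in fluorescence counts (baseline = 100 counts, so the
    default 1.0 is ~1% frame noise).
    """

    multipliers: dict[str, float]
    rundown_factor: float = 0.95
    noise_sd: float = 1.0

    def __post_init__(self):
        if any(m <= 0 for m in self.multipliers.values()):
            raise ValidationError("drug multipliers must be > 0")
        if not 0 < self.rundown_factor <= 1:
            raise ValidationError("rundown_factor must be in (0, 1]")

    @classmethod
    def conditioned(cls, noise_sd: float = 1.0) -> "DrugEffectSpec":
        """Fear-conditioned + GABA_B blockade: blockade effect smallest for
        the threat-predictive odor, largest for the dissimilar odor."""
        return cls({"MV": 1.10, "BA": 1.25, "HEX": 1.40}, 0.95, noise_sd)

    @classmethod
    def control(cls, noise_sd: float = 1.0) -> "DrugEffectSpec":
        """Non-conditioned + GABA_B blockade: equal effect across odors."""
        return cls({"MV": 1.40, "BA": 1.40, "HEX": 1.40}, 0.95, noise_sd)

    @classmethod
    def vehicle(cls, noise_sd: float = 1.0) -> "DrugEffectSpec":
        """Vehicle: no drug effect, rundown only (~5% decline)."""
        return cls({"MV": 1.0, "BA": 1.0, "HEX": 1.0}, 0.95, noise_sd)

    def expected_effect_pct(self, odor: str) -> float:
        """Closed-form measured drug effect: 100·(multiplier·rundown − 1)."""
        return 100.0 * (self.multipliers[odor] * self.rundown_factor - 1.0)


# ---------------------------------------------------------------------------
# imaging session


def _temporal_kernel(segments=DEFAULT_SEGMENTS, frame_rate=DEFAULT_FRAME_RATE,
                     ramp_s: float = 0.5, decay_s: float = 1.0) -> np.ndarray:
    """Odor-response kernel: ramp to plateau within `ramp_s` of onset,
    plateau 1.0 through odor offset, exponential decay after."""
    pre, odor, post = segments
    t = np.arange(pre + odor + post) / frame_rate
    onset, offset = pre / frame_rate, (pre + odor) / frame_rate
    k = np.zeros_like(t)
    rising = (t >= onset) & (t < onset + ramp_s)
    k[rising] = (t[rising] - onset) / ramp_s
    plateau = (t >= onset + ramp_s) & (t < offset)
    k[plateau] = 1.0
    tail = t >= offset
    k[tail] = np.exp(-(t[tail] - offset) / decay_s)
    return k


MOCK_STRENGTH = 0.02  # mock odor presentations at 2% strength


@dataclass
class SyntheticTrial:
    """Lazy trial record: metadata plus a recipe to render the frame stack.

    Frames are materialised on demand (deterministically from the stored
    seed entropy) so a full 144-trial session does not need to live in
    memory at once.
    """

    odor: str
    phase: str
    mock: bool
    block: int
    trial: int
    seed_entropy: tuple[int, ...]
    _session: "SyntheticSession"

    def render(self) -> ImagingTrial:
        s = self._session
        scale = 1.0
        if self.phase == "post":
            scale = s.drug_spec.multipliers[self.odor] * s.drug_spec.rundown_factor
        if self.mock:
            scale *= MOCK_STRENGTH
        kernel = s._kernel
        smap = s._odor_maps[self.odor]  # ΔF/F spatial amplitude map
        frames = s.baseline * (1.0 + np.multiply.outer(kernel, smap) * scale)
        if s.drug_spec.noise_sd > 0:
            # float32 is ample for the noisy path and halves render time
            rng = np.random.default_rng(np.random.SeedSequence(list(self.seed_entropy)))
            frames = frames.astype(np.float32)
            frames += s.drug_spec.noise_sd * rng.standard_normal(
                frames.shape, dtype=np.float32)
        return ImagingTrial(frames=frames, odor=self.odor, phase=self.phase,
                            mock=self.mock, block=self.block, trial=self.trial,
                            frame_rate=s.frame_rate, segments=s.segments)


@dataclass
class SyntheticGroundTruth:
    """Generator-side truth fully determining the dataset given the seed."""

    layout: GlomerularLayout
    tuning: OdorTuning
    drug_spec: DrugEffectSpec
    seed: int
    expected_peak_dff: dict[str, np.ndarray]  # odor -> (n_roi,) pre-drug peak ΔF/F
    occupancy: "OccupancyModelParams | None" = None

    def expected_drug_effect_pct(self, odor: str) -> float:
        return self.drug_spec.expected_effect_pct(odor)

    def responders(self, odor: str) -> set[int]:
        return self.tuning.responders(odor)

    def to_dict(self) -> dict:
        d = {
            "seed": self.seed,
            "um_per_pixel": self.layout.um_per_pixel,
            "field_size_um": list(self.layout.field_size),
            "centers_um": self.layout.centers.tolist(),
            "radii_um": self.layout.radii.tolist(),
            "amplitudes": {o: a.tolist() for o, a in self.tuning.amplitudes.items()},
            "multipliers": dict(self.drug_spec.multipliers),
            "rundown_factor": self.drug_spec.rundown_factor,
            "noise_sd": self.drug_spec.noise_sd,
            "expected_peak_dff": {o: v.tolist() for o, v in self.expected_peak_dff.items()},
            "expected_drug_effect_pct": {
                o: self.expected_drug_effect_pct(o) for o in self.tuning.amplitudes},
        }
        if self.occupancy is not None:
            d["occupancy"] = {
                "model": self.occupancy.model_name,
                "weights": dict(self.occupancy.weights),
                "zone_probs": self.occupancy.zone_probs.tolist(),
            }
        return d


class SyntheticSession:
    """A full imaging session: 6 blocks x 8 trials per odor (4 mock + 4
    recorded per block), blocks 1–3 pre-drug and 4–6 post-drug."""

    def __init__(self, layout: GlomerularLayout, tuning: OdorTuning,
                 drug_spec: DrugEffectSpec, seed: int,
                 n_blocks: int = 6, trials_per_block: int = 8, n_mock: int = 4,
                 baseline: float = 100.0,
                 segments=DEFAULT_SEGMENTS, frame_rate=DEFAULT_FRAME_RATE):
        if n_blocks % 2:
            raise ValidationError("n_blocks must be even (half pre-drug, half post-drug)")
        missing = [o for o in tuning.amplitudes if o not in drug_spec.multipliers]
        if missing:
            raise ValidationError(f"drug_spec lacks multipliers for odors {missing}")
        self.layout, self.tuning, self.drug_spec = layout, tuning, drug_spec
        self.seed = int(seed)
        self.baseline = float(baseline)
        self.segments, self.frame_rate = tuple(segments), float(frame_rate)
        self._kernel = _temporal_kernel(self.segments, self.frame_rate)
        profiles = layout.spatial_profiles()
        self._odor_maps = {
            odor: np.tensordot(amps, profiles, axes=1)
            for odor, amps in tuning.amplitudes.items()
        }
        self.trials: list[SyntheticTrial] = []
        counter = 0
        for block in range(1, n_blocks + 1):
            phase = "pre" if block <= n_blocks // 2 else "post"
            for odor in tuning.amplitudes:
                for k in range(trials_per_block):
                    self.trials.append(SyntheticTrial(
                        odor=odor, phase=phase, mock=k < n_mock,
                        block=block, trial=counter,
                        seed_entropy=(self.seed, 1000 + counter), _session=self))
                    counter += 1
        masks = layout.roi_masks()
        expected = {}
        for odor, smap in self._odor_maps.items():
            expected[odor] = np.array([float(smap[m].mean()) for m in masks.values()])
        self.roi_masks = masks
        self.truth = SyntheticGroundTruth(
            layout=layout, tuning=tuning, drug_spec=drug_spec, seed=self.seed,
            expected_peak_dff=expected)

    def imaging_trials(self, recorded_only: bool = False):
        """Yield rendered :class:`ImagingTrial` objects in acquisition order."""
        for t in self.trials:
            if recorded_only and t.mock:
                continue
            yield t.render()

    def rois_by_odor(self) -> dict[str, set]:
        """The per-odor ROI sets (ground-truth responders)."""
        return {o: self.tuning.responders(o) for o in self.tuning.amplitudes}


def generate_session(layout: GlomerularLayout, tuning: OdorTuning,
                     drug_spec: DrugEffectSpec, seed: int,
                     **kwargs) -> SyntheticSession:
    """Build a synthetic imaging session (see :class:`SyntheticSession`)."""
    return SyntheticSession(layout, tuning, drug_spec, seed, **kwargs)


# ---------------------------------------------------------------------------
# occupancy models and trajectories


@dataclass
class OccupancyModelParams:
    """A parameterized occupancy hypothesis over the 9 arena zones.

    `weights` maps odor name -> avoidance weight a >= 0; the corner zone of
    an avoided odor gets unnormalized mass exp(-a) (all other zones 1), and
    the 9-zone probability vector is the normalization.  no_fear has no
    weights and reduces to the uniform vector; overgeneralization shares one
    weight across all three odor corners.
    """

    model_name: str
    weights: dict[str, float] = field(default_factory=dict)
    corner_odors: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(_arena.DEFAULT_CORNER_ODORS))
    #: optional explicit 9-zone probability vector (overrides the weights;
    #: useful for degenerate occupancy patterns the avoidance weights
    #: cannot express)
    explicit_probs: np.ndarray | None = None

    VALID = ("no_fear", "cs_specific", "gradient", "overgeneralization")

    def __post_init__(self):
        if self.model_name not in self.VALID:
            raise ValidationError(f"unknown model {self.model_name!r}")
        if any(a < 0 for a in self.weights.values()):
            raise ValidationError("avoidance weights must be >= 0")
        if self.explicit_probs is not None:
            p = np.asarray(self.explicit_probs, dtype=float)
            if p.shape != (9,) or (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
                raise ValidationError("explicit_probs must be a 9-zone probability vector")
            self.explicit_probs = p

    @property
    def zone_probs(self) -> np.ndarray:
        if self.explicit_probs is not None:
            return self.explicit_probs
        zones = _arena.odor_corner_zones(self.corner_odors)
        u = np.ones(9)
        for odor, a in self.weights.items():
            u[zones[odor]] = math.exp(-a)
        return u / u.sum()

    @classmethod
    def make(cls, model_name: str, effect_size: float = 1.5,
             corner_odors=None) -> "OccupancyModelParams":
        """Canonical parameterization of the four a priori hypotheses at a
        given avoidance effect size (gradient: BA at half the MV weight)."""
        kw = {} if corner_odors is None else {"corner_odors": dict(corner_odors)}
        w = float(effect_size)
        weights = {
            "no_fear": {},
            "cs_specific": {"MV": w},
            "gradient": {"MV": w, "BA": w / 2.0},
            "overgeneralization": {"MV": w, "BA": w, "HEX": w},
        }[model_name]
        return cls(model_name=model_name, weights=weights, **kw)


def generate_trajectory(params: OccupancyModelParams, duration: float = 300.0,
                        rate: float = 25.0, seed: int = 0,
                        arena: tuple[float, float] = _arena.DEFAULT_ARENA,
                        hold_s: float = 2.0, speed: float = 18.0,
                        step_sd: float = 0.5) -> Trajectory:
    """Simulate a centroid path whose long-run zone dwell fractions converge
    to the model's zone probabilities.

    Zone-to-zone moves follow a Metropolis–Hastings chain on the 3x3 grid
    (uniform proposal over 4-neighbours), updated every `hold_s` seconds;
    detailed balance makes the stationary zone distribution exactly
    ``params.zone_probs``.  Between updates the mouse walks toward a random
    target point inside the current zone at `speed` units/s and jitters
    around it (per-step SD `step_sd`), so the path is continuous and zone
    crossings pass directly through the shared boundary.
    """
    if duration <= 0 or rate <= 0:
        raise ValidationError("duration and rate must be > 0")
    p = params.zone_probs
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 7]))
    n = int(round(duration * rate))
    dt = 1.0 / rate
    n_hold = max(int(round(hold_s * rate)), 1)
    inset = 0.06 * min(arena) / 3.0

    def rand_point(zone):
        x0, x1, y0, y1 = _arena.zone_bounds(zone, arena)
        return rng.uniform([x0 + inset, y0 + inset], [x1 - inset, y1 - inset])

    deg = {z: len(nb) for z, nb in _arena.ZONE_NEIGHBORS.items()}
    zone = int(rng.choice(9, p=p))
    pos = rand_point(zone)
    xs = np.empty(n)
    ys = np.empty(n)
    filled = 0
    while filled < n:
        nb = _arena.ZONE_NEIGHBORS[zone]
        j = int(nb[rng.integers(len(nb))])
        if p[zone] > 0 and rng.random() < min(
                1.0, (p[j] * deg[zone]) / (p[zone] * deg[j])):
            zone = j
        target = rand_point(zone)
        m = min(n_hold, n - filled)
        delta = target - pos
        dist = float(np.hypot(*delta))
        step = speed * dt
        n_travel = min(int(np.ceil(dist / step)) if dist > 0 else 0, m)
        block = np.empty((m, 2))
        if n_travel:
            frac = np.minimum(np.arange(1, n_travel + 1) * step, dist) / max(dist, 1e-12)
            block[:n_travel] = pos + frac[:, None] * delta
        if m > n_travel:
            jit = np.cumsum(rng.normal(0.0, step_sd, (m - n_travel, 2)), axis=0)
            x0, x1, y0, y1 = _arena.zone_bounds(zone, arena)
            pts = target + jit
            pts[:, 0] = np.clip(pts[:, 0], x0 + inset, x1 - inset)
            pts[:, 1] = np.clip(pts[:, 1], y0 + inset, y1 - inset)
            block[n_travel:] = pts
        xs[filled:filled + m] = block[:, 0]
        ys[filled:filled + m] = block[:, 1]
        pos = block[-1]
        filled += m
    t = np.arange(n) * dt
    return Trajectory(t=t, x=xs, y=ys, arena=arena,
                      corner_odors=dict(params.corner_odors))


def generate_cohort(model_name: str, effect_size: float = 1.5,
                    n_mice: int = 10, seed: int = 0,
                    **traj_kwargs):
    """Independent per-mouse trajectories under one occupancy model.

    Per-mouse seeds derive deterministically from the master seed
    (``SeedSequence([seed, mouse_index])`` via an integer counter), so two
    cohorts with the same master seed are identical.  Returns
    ``(trajectories, params)``; `params` is the generating truth label.
    """
    if n_mice < 1:
        raise ValidationError("n_mice must be >= 1")
    params = OccupancyModelParams.make(
        model_name, effect_size, corner_odors=traj_kwargs.pop("corner_odors", None))
    trajs = [
        generate_trajectory(params, seed=(int(seed) * 10007 + i) % (2 ** 31), **traj_kwargs)
        for i in range(n_mice)
    ]
    return trajs, params
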