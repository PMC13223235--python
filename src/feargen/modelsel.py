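"""AIC comparison of four a priori fear-generalization occupancy models.

The avoidance data are zone dwell times in the 9-zone open-field arena.
Four hypotheses about how fear generalizes across the odor corners are
scored against them:

==================  ==========================================  ===
model               avoidance structure                          k
==================  ==========================================  ===
no_fear             uniform occupancy over the 9 zones           0
cs_specific         one avoidance weight on the MV corner        1
gradient            MV weight >= BA weight >= 0, HEX at           2
                    baseline (similarity gradient)
overgeneralization  one shared weight on all three odor corners  1
==================  ==========================================  ===

A zone with avoidance weight ``a`` gets unnormalized mass ``exp(-a)``
(other zones 1); the model probability vector is the normalization, so
``no_fear`` reduces exactly to the uniform vector.

Likelihood
----------
Dwell times are converted to effective observation counts at one
observation per `ess_interval` seconds (default 5 s) to blunt the serial
autocorrelation of a continuous path, pooled across mice (fixed-effect
pooling), and scored with the multinomial counts kernel

    logL = sum_z c_z * ln(p_z)

with the multinomial coefficient omitted consistently across models.
AIC = 2k − 2 logL, and the relative likelihood (evidence ratio) of model a
over model b is exp((AIC_b − AIC_a)/2).

The usual statsmodels shape applies: build an
:class:`OccupancyModelComparison` from counts or trajectories, call
``fit()``, and read the :class:`ModelSelectionResults`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from . import arena as _arena
from ._exceptions import FeargenError, ValidationError
from .behavior import Trajectory, ZoneOccupancy, time_in_zones

MODEL_NAMES = ("no_fear", "cs_specific", "gradient", "overgeneralization")
DEFAULT_ESS_INTERVAL_S = 5.0


class ConvergenceError(FeargenError, RuntimeError):
    """The constrained likelihood optimization failed."""


def evidence_ratio(aic_a: float, aic_b: float) -> float:
    """Relative likelihood of model a over model b: exp((AIC_b − AIC_a)/2)."""
    if not (math.isfinite(aic_a) and math.isfinite(aic_b)):
        raise ValidationError("evidence ratio needs finite AICs")
    return math.exp((aic_b - aic_a) / 2.0)


@dataclass
class CandidateModel:
    """One occupancy hypothesis: a name, its free-parameter count, and the
    constrained mapping from parameters to a 9-zone probability vector."""

    name: str
    corner_odors: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(_arena.DEFAULT_CORNER_ODORS))

    K = {"no_fear": 0, "cs_specific": 1, "gradient": 2, "overgeneralization": 1}

    def __post_init__(self):
        if self.name not in MODEL_NAMES:
            raise ValidationError(f"unknown model {self.name!r}")
        self._zones = _arena.odor_corner_zones(self.corner_odors)

    @property
    def k(self) -> int:
        return self.K[self.name]

    def weights(self, params: np.ndarray) -> dict[str, float]:
        """Per-odor avoidance weights implied by a raw parameter vector."""
        params = np.asarray(params, dtype=float)
        if params.shape != (self.k,):
            raise ValidationError(f"{self.name} expects {self.k} parameters")
        if (params < 0).any():
            raise ValidationError("avoidance parameters must be >= 0")
        if self.name == "no_fear":
            return {}
        if self.name == "cs_specific":
            return {"MV": float(params[0])}
        if self.name == "overgeneralization":
            w = float(params[0])
            return {"MV": w, "BA": w, "HEX": w}
        # gradient: params = (b, d) with a_BA = b, a_MV = b + d, so the
        # ordering constraint a_MV >= a_BA >= 0 holds by construction
        b, d = params
        return {"MV": float(b + d), "BA": float(b)}

    def zone_probs(self, params) -> np.ndarray:
        u = np.ones(9)
        for odor, a in self.weights(params).items():
            u[self._zones[odor]] = math.exp(-a)
        return u / u.sum()


@dataclass
class OccupancyCounts:
    """Effective per-mouse dwell counts per zone.

    Each mouse's dwell times are thinned to one effective observation per
    `ess_interval` seconds using largest-remainder rounding, so the count
    total equals round(total dwell / ess_interval) exactly.
    """

    per_mouse: np.ndarray  # (n_mice, 9) integer counts
    ess_interval_s: float = DEFAULT_ESS_INTERVAL_S

    def __post_init__(self):
        self.per_mouse = np.atleast_2d(np.asarray(self.per_mouse))
        if self.per_mouse.shape[1] != 9:
            raise ValidationError("counts must have 9 zone columns")
        if (self.per_mouse < 0).any():
            raise ValidationError("counts must be >= 0")

    @property
    def pooled(self) -> np.ndarray:
        return self.per_mouse.sum(axis=0)

    @property
    def n(self) -> int:
        return int(self.pooled.sum())

    def fingerprint(self) -> tuple:
        return tuple(self.pooled.tolist()) + (self.per_mouse.shape[0],)


def _dwell_to_counts(dwell_s: np.ndarray, ess: float) -> np.ndarray:
    raw = dwell_s / ess
    total = int(round(raw.sum()))
    base = np.floor(raw).astype(int)
    deficit = total - int(base.sum())
    if deficit > 0:
        rem = raw - base
        order = np.argsort(-rem, kind="stable")  # ties -> lower zone index
        base[order[:deficit]] += 1
    return base


def occupancy_counts(trajectories, ess_interval: float = DEFAULT_ESS_INTERVAL_S,
                     ) -> OccupancyCounts:
    """Convert per-mouse trajectories (or ZoneOccupancy vectors) to
    effective dwell counts at one observation per `ess_interval` seconds."""
    if ess_interval <= 0:
        raise ValidationError("ess_interval must be > 0")
    rows = []
    for item in trajectories:
        occ = item if isinstance(item, ZoneOccupancy) else time_in_zones(item)
        rows.append(_dwell_to_counts(occ.dwell_s, ess_interval))
    return OccupancyCounts(per_mouse=np.array(rows), ess_interval_s=ess_interval)


def model_loglik(counts: OccupancyCounts, probs: np.ndarray) -> float:
    """Multinomial counts kernel sum_z c_z ln p_z (pooled over mice).

    Returns -inf explicitly when a zone with zero model probability holds
    observed counts.
    """
    c = counts.pooled.astype(float)
    p = np.asarray(probs, dtype=float)
    if p.shape != (9,) or (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
        raise ValidationError("probs must be a valid 9-zone probability vector")
    if ((p == 0) & (c > 0)).any():
        return -math.inf
    mask = c > 0
    return float((c[mask] * np.log(p[mask])).sum())


@dataclass
class ModelScore:
    """Scored fit of one candidate model."""

    model: str
    k: int
    loglik: float
    aic: float
    params: dict[str, float]
    daic: float | None = None
    evidence_ratio_vs_best: float | None = None
    _fingerprint: tuple | None = None


_GRID_MAX = 6.0  # corner probability at w=6 is ~3e-4: effectively excluded


def fit_model(counts: OccupancyCounts, model: "CandidateModel | str") -> ModelScore:
    """Maximize the constrained log-likelihood of one candidate model.

    Deterministic coarse grid over the avoidance weights followed by local
    refinement (bounded scalar minimization for 1-parameter models,
    L-BFGS-B for the 2-parameter gradient model).  AIC = 2k − 2 logL.
    """
    if isinstance(model, str):
        model = CandidateModel(model)
    if counts.n == 0:
        raise ValidationError("degenerate counts: no observations")

    def nll(params):
        return -model_loglik(counts, model.zone_probs(np.asarray(params)))

    if model.k == 0:
        ll = -nll([])
        params = np.array([])
    elif model.k == 1:
        grid = np.linspace(0.0, _GRID_MAX, 61)
        vals = [nll([w]) for w in grid]
        w0 = grid[int(np.argmin(vals))]
        step = grid[1] - grid[0]
        res = optimize.minimize_scalar(
            lambda w: nll([w]), bounds=(max(0.0, w0 - step), min(_GRID_MAX, w0 + step)),
            method="bounded", options={"xatol": 1e-8})
        if not res.success:
            raise ConvergenceError(f"{model.name}: {res.message}")
        params = np.array([res.x]) if res.fun <= nll([w0]) else np.array([w0])
        ll = -nll(params)
    else:
        grid = np.linspace(0.0, _GRID_MAX, 25)
        best, b0 = np.inf, (0.0, 0.0)
        for b in grid:
            for d in grid:
                v = nll([b, d])
                if v < best:
                    best, b0 = v, (b, d)
        res = optimize.minimize(
            nll, x0=np.array(b0), method="L-BFGS-B",
            bounds=[(0.0, 2 * _GRID_MAX), (0.0, 2 * _GRID_MAX)])
        if not res.success and res.fun > best:
            raise ConvergenceError(f"{model.name}: {res.message}")
        params = res.x if res.fun <= best else np.array(b0)
        ll = -nll(params)
    aic = 2.0 * model.k - 2.0 * ll
    return ModelScore(model=model.name, k=model.k, loglik=ll, aic=aic,
                      params=model.weights(params), _fingerprint=counts.fingerprint())


def select_model(scores: list[ModelScore]) -> pd.DataFrame:
    """Rank scored models by ascending AIC (ties broken by fewer parameters)
    and attach ΔAIC and evidence ratios versus the winner."""
    if len(scores) < 2:
        raise ValidationError("need at least two scored models")
    fps = {s._fingerprint for s in scores if s._fingerprint is not None}
    if len(fps) > 1:
        raise ValidationError("scores were computed on mismatched count data")
    ranked = sorted(scores, key=lambda s: (s.aic, s.k))
    best = ranked[0]
    rows = []
    for s in ranked:
        s.daic = s.aic - best.aic
        s.evidence_ratio_vs_best = evidence_ratio(best.aic, s.aic)
        rows.append({"model": s.model, "k": s.k, "loglik": s.loglik,
                     "aic": s.aic, "daic": s.daic,
                     "evidence_ratio": s.evidence_ratio_vs_best,
                     **{f"w_{o}": v for o, v in s.params.items()}})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# model / results objects


class OccupancyModelComparison:
    """Compare the four a priori occupancy models on avoidance data.

    Parameters
    ----------
    counts : OccupancyCounts
        Effective per-mouse zone dwell counts.
    models : sequence of str, optional
        Candidate model names (default: all four).
    corner_odors : dict, optional
        Odor-corner assignment (default: MV/BA adjacent on one side).

    Examples
    --------
    >>> comp = OccupancyModelComparison.from_trajectories(trajs)  # doctest: +SKIP
    >>> res = comp.fit()                                          # doctest: +SKIP
    >>> print(res.summary())                                      # doctest: +SKIP
    """

    def __init__(self, counts: OccupancyCounts, models=MODEL_NAMES,
                 corner_odors=None):
        self.counts = counts
        self.corner_odors = dict(corner_odors or _arena.DEFAULT_CORNER_ODORS)
        self.models = [CandidateModel(m, corner_odors=dict(self.corner_odors))
                       for m in models]

    @classmethod
    def from_trajectories(cls, trajectories,
                          ess_interval: float = DEFAULT_ESS_INTERVAL_S,
                          models=MODEL_NAMES) -> "OccupancyModelComparison":
        trajectories = list(trajectories)
        counts = occupancy_counts(trajectories, ess_interval)
        corner = trajectories[0].corner_odors if isinstance(
            trajectories[0], Trajectory) else None
        return cls(counts, models=models, corner_odors=corner)

    @classmethod
    def from_dataframe(cls, occupancy: pd.DataFrame,
                       ess_interval: float = DEFAULT_ESS_INTERVAL_S,
                       models=MODEL_NAMES) -> "OccupancyModelComparison":
        """Build from a long table with mouse / zone / dwell_s columns."""
        need = {"mouse", "zone", "dwell_s"}
        if need - set(occupancy.columns):
            raise ValidationError(f"need columns {sorted(need)}")
        rows = []
        for _, grp in occupancy.groupby("mouse"):
            dwell = np.zeros(9)
            dwell[grp["zone"].to_numpy(int)] = grp["dwell_s"].to_numpy(float)
            rows.append(_dwell_to_counts(dwell, ess_interval))
        return cls(OccupancyCounts(np.array(rows), ess_interval), models=models)

    def fit(self) -> "ModelSelectionResults":
        scores = [fit_model(self.counts, m) for m in self.models]
        table = select_model(scores)
        return ModelSelectionResults(self, scores, table)


class ModelSelectionResults:
    """Fitted model comparison: ranked AIC table, winner, evidence ratios."""

    def __init__(self, model: OccupancyModelComparison,
                 scores: list[ModelScore], table: pd.DataFrame):
        self.model = model
        self.scores = {s.model: s for s in scores}
        self.table = table

    @property
    def best_model(self) -> str:
        return str(self.table.iloc[0]["model"])

    @property
    def best_params(self) -> dict[str, float]:
        return dict(self.scores[self.best_model].params)

    def evidence_ratio(self, a: str, b: str) -> float:
        """Relative likelihood of model a over model b."""
        return evidence_ratio(self.scores[a].aic, self.scores[b].aic)

    def summary(self) -> str:
        lines = [
            "Occupancy model comparison (multinomial kernel, "
            f"ess interval {self.model.counts.ess_interval_s:g} s, "
            f"n = {self.model.counts.n} effective observations, "
            f"{self.model.counts.per_mouse.shape[0]} mice)",
            "",
            f"{'model':<20}{'k':>3}{'logL':>12}{'AIC':>10}{'dAIC':>9}{'ev.ratio':>11}",
        ]
        for _, r in self.table.iterrows():
            lines.append(
                f"{r['model']:<20}{int(r['k']):>3}{r['loglik']:>12.2f}"
                f"{r['aic']:>10.2f}{r['daic']:>9.2f}{r['evidence_ratio']:>11.3g}")
        lines.append("")
        lines.append(f"best model: {self.best_model}  params: "
                     + json.dumps(self.best_params))
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "best_model": self.best_model,
            "best_params": self.best_params,
            "ess_interval_s": self.model.counts.ess_interval_s,
            "n_effective": self.model.counts.n,
            "models": self.table.drop(
                columns=[c for c in self.table.columns if c.startswith("w_")]
            ).to_dict(orient="records"),
        }
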