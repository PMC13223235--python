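"""Simulation studies validating the pipeline end-to-end.

These routines generate synthetic data under the study conditions, run the
full analysis path, and measure how well the known generating truth is
recovered: drug-effect recovery, the odor-dependent effect gradient,
occupancy-model selection, and the calibration of the inferential tests
under the null.  They are used by the test suite and the reproduction
script alike.

Problem sizes are desk-scale by design: imaging sessions use a 640 µm
synthetic field at 20 µm/pixel with 32 glomeruli (12 responders per odor),
and behavioral cohorts use 10 mice x 5-min sessions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import modelsel, stats, synthetic
from .imaging import drug_effect_table, summarize_trials

ODORS = ("MV", "BA", "HEX")


def simulate_session_effects(seed: int, drug: str = "conditioned",
                             noise_sd: float = 1.0,
                             n_glomeruli: int = 32,
                             n_per_odor: int = 12) -> pd.DataFrame:
    """Generate one imaging session and measure per-ROI drug effects.

    Runs the actual pipeline: render recorded trials, compute ΔF/F per ROI,
    peak per trial, phase means, percent change.  Returns the
    roi/odor/drug_effect_pct table.
    """
    layout = synthetic.generate_layout(n_glomeruli, seed=seed)
    tuning = synthetic.design_tuning(layout, seed=seed, n_per_odor=n_per_odor)
    spec = {
        "conditioned": synthetic.DrugEffectSpec.conditioned,
        "control": synthetic.DrugEffectSpec.control,
        "vehicle": synthetic.DrugEffectSpec.vehicle,
    }[drug](noise_sd=noise_sd)
    session = synthetic.generate_session(layout, tuning, spec, seed)
    peaks = summarize_trials(session.imaging_trials(recorded_only=True),
                             session.roi_masks, session.rois_by_odor())
    return drug_effect_table(peaks)


def drug_effect_recovery(seed: int, noise_sd: float) -> dict[str, float]:
    """Mean measured drug effect per odor for one conditioned session."""
    eff = simulate_session_effects(seed, "conditioned", noise_sd)
    return eff.groupby("odor")["drug_effect_pct"].mean().to_dict()


def odor_gradient_study(n_sessions: int = 100, seed: int = 0,
                        alpha: float = 0.05) -> dict[str, float]:
    """Qualitative twin of the drug-effect-by-odor summary.

    Conditioned sessions should show the measured mean-effect ordering
    MV < BA < HEX; control sessions (equal multipliers) should show no
    significant odor effect beyond the test's false-positive rate.
    Returns the ordering rate over conditioned sessions and the one-way
    ANOVA rejection rate over control sessions.
    """
    ordered = 0
    rejected = 0
    for i in range(n_sessions):
        eff_c = simulate_session_effects(seed * 100003 + 2 * i)
        m = eff_c.groupby("odor")["drug_effect_pct"].mean()
        if m["MV"] < m["BA"] < m["HEX"]:
            ordered += 1
        eff_k = simulate_session_effects(seed * 100003 + 2 * i + 1, "control")
        groups = [g["drug_effect_pct"].to_numpy() for _, g in eff_k.groupby("odor")]
        if sps.f_oneway(*groups).pvalue < alpha:
            rejected += 1
    return {"ordering_rate": ordered / n_sessions,
            "control_rejection_rate": rejected / n_sessions,
            "n_sessions": n_sessions}


def model_recovery_study(n_replicates: int = 200, seed: int = 0,
                         effect_size: float = 1.5,
                         n_mice: int = 10) -> dict[str, float]:
    """Selection rate of the generating occupancy model, per model.

    For each of the four a priori models, simulates `n_replicates` cohorts
    of `n_mice` 5-min trajectories, scores all four candidates by AIC, and
    counts how often the generating model wins.  Also reports which model
    is the modal winner on the null (no_fear) cohorts.
    """
    rates: dict[str, float] = {}
    null_wins: dict[str, int] = {}
    for m_idx, model in enumerate(modelsel.MODEL_NAMES):
        hits = 0
        for rep in range(n_replicates):
            rep_seed = (seed * 1000003 + m_idx * 65537 + rep * 7919) % (2 ** 31)
            trajs, _ = synthetic.generate_cohort(model, effect_size, n_mice,
                                                 seed=rep_seed)
            res = modelsel.OccupancyModelComparison.from_trajectories(trajs).fit()
            if res.best_model == model:
                hits += 1
            if model == "no_fear":
                null_wins[res.best_model] = null_wins.get(res.best_model, 0) + 1
        rates[model] = hits / n_replicates
    rates["null_modal_winner"] = max(null_wins, key=null_wins.get)  # type: ignore[assignment]
    return rates


def null_calibration_study(n_replicates: int = 2000, seed: int = 0,
                           alpha: float = 0.05) -> dict[str, float]:
    """Type-I error rates of the inferential tests under null simulations.

    rm-ANOVA on 12 subjects x 3 conditions, mixed-ANOVA interaction on
    2 groups x 10 subjects x 3 conditions, and Pearson correlation at
    n = 20, all on iid standard-normal data.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) % (2 ** 31), 99]))
    rej = {"rm_anova": 0, "mixed_interaction": 0, "pearson": 0}
    g = np.repeat(["a", "b"], 10 * 3)
    s = np.repeat(np.arange(20), 3)
    c = np.tile(np.arange(3), 20)
    for _ in range(n_replicates):
        if stats.rm_anova_oneway(rng.standard_normal((12, 3))).p < alpha:
            rej["rm_anova"] += 1
        df = pd.DataFrame({"subject": s, "group": g, "condition": c,
                           "value": rng.standard_normal(60)})
        if stats.mixed_anova_twoway(df)["interaction"].p < alpha:
            rej["mixed_interaction"] += 1
        if stats.pearson_corr(rng.standard_normal(20),
                              rng.standard_normal(20)).p < alpha:
            rej["pearson"] += 1
    return {k: v / n_replicates for k, v in rej.items()}
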