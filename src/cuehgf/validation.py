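"""Replicated simulation experiments that validate the pipeline end to end:
parameter recovery for the HGF fit, statistical power for the injected
P3b-amplitude group effect, and type-I error control under a null forward
model.

These are the package's own calibration checks.  Replicated runs use epochs
sampled at 125 Hz (the window-averaged GLM betas are insensitive to epoch
resolution well above the component bandwidths, and this keeps one hundred
cohort replicates tractable on one core).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import cohort as cohort_mod
from . import design, erp
from .hgf import (
    FitOptions,
    PerceptualParams,
    ResponseParams,
    fit_hgf,
    simulate_agent,
)
from .stats import one_sample_t, two_sample_t

__all__ = [
    "parameter_recovery",
    "subject_window_betas",
    "p3b_belief_group_pvalue",
    "power_p3b_belief",
    "type1_error_rates",
]

#: Parameter ranges that agents are drawn from for recovery studies —
#: the prior-plausible regime of the default estimation priors.
RECOVERY_RANGES = {
    "omega2": (-5.0, -1.5),
    "omega3": (-8.0, -4.0),
    "zeta1v": (1.5, 3.0),
    "zeta2v": (0.5, 2.0),
    "zeta1i": (1.5, 3.0),
    "zeta2i": (0.5, 2.0),
}

#: Realistic trial-to-trial residual RS variability (1/s).
DEFAULT_RS_NOISE_SD = 0.35


def parameter_recovery(
    n_agents: int = 60,
    seed: int = 0,
    noise_sd: float = DEFAULT_RS_NOISE_SD,
    fit_opts: FitOptions | None = None,
) -> pd.DataFrame:
    """Simulate agents with known parameters, refit each, and tabulate
    true vs recovered values.

    Returns a long DataFrame (agent, parameter, true, recovered).  Use
    :func:`recovery_correlations` for the summary rank correlations.
    """
    sequence = design.generate_trial_sequence()
    u = sequence["validity"].to_numpy()
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_agents):
        draws = {k: rng.uniform(*v) for k, v in RECOVERY_RANGES.items()}
        pp = PerceptualParams(omega2=draws["omega2"], omega3=draws["omega3"])
        rp = ResponseParams(zeta1v=draws["zeta1v"], zeta2v=draws["zeta2v"],
                            zeta1i=draws["zeta1i"], zeta2i=draws["zeta2i"],
                            noise_var=noise_sd ** 2)
        behavior = simulate_agent(sequence, pp, rp,
                                  seed=np.random.SeedSequence(seed, spawn_key=(i,)))
        fit = fit_hgf(behavior, u, opts=fit_opts or FitOptions(seed=i))
        recovered = fit.params_dict()
        for name in ("omega2", "omega3", "zeta2v", "zeta2i"):
            rows.append({"agent": i, "parameter": name, "true": draws[name],
                         "recovered": recovered[name]})
    return pd.DataFrame(rows)


def recovery_correlations(recovery: pd.DataFrame) -> dict[str, float]:
    """Spearman rank correlation of true vs recovered, per parameter."""
    out = {}
    for name, chunk in recovery.groupby("parameter"):
        out[name] = float(sps.spearmanr(chunk["true"], chunk["recovered"]).statistic)
    return out


def _reduced_config(config_fn, n_per_group: int, master_seed: int):
    config = config_fn(n_per_group, master_seed)
    for g in config.groups:
        g.erp.srate_hz = 125.0
    return config


def subject_window_betas(
    config: cohort_mod.CohortConfig,
    windows=erp.DEFAULT_WINDOWS,
) -> pd.DataFrame:
    """Generate epochs for every cohort subject and return window-averaged
    single-trial GLM betas (regressor: the subject's generative beliefs)."""
    subjects = cohort_mod.generate_cohort(config)
    group_fwd = {g.label: g.erp for g in config.groups}
    rows = []
    for i, subject in enumerate(subjects):
        epochs = cohort_mod.generate_epochs(
            subject.behavior, subject.trajectory, group_fwd[subject.group],
            seed=cohort_mod.epoch_seed_for(config, i))
        epochs = erp.baseline_correct(epochs)
        include = ((subject.behavior["correct"].to_numpy() == 1)
                   & (subject.behavior["missed"].to_numpy() == 0))
        designm = erp.build_design_matrix(
            subject.behavior["validity"].to_numpy()[include],
            np.asarray(subject.trajectory.muhat1)[include])
        kept = cohort_mod.EpochArray(
            epochs.data[include], epochs.srate_hz, epochs.t0_ms,
            epochs.channel_names)
        per_channel = {}
        for window in windows:
            if window.channel not in per_channel:
                per_channel[window.channel] = erp.single_trial_glm(
                    kept, designm, window.channel)
            wavg = erp.window_average(per_channel[window.channel], window)
            for reg, b in wavg.items():
                rows.append({"subject": subject.subject_id,
                             "group": subject.group, "window": window.name,
                             "regressor": reg, "b": float(b)})
    return pd.DataFrame(rows)


def p3b_belief_group_pvalue(betas: pd.DataFrame) -> float:
    """p of the pooled two-sample t on the P3b-amplitude belief betas."""
    chunk = betas[(betas["window"] == "p3b_amp") & (betas["regressor"] == "belief")]
    groups = sorted(chunk["group"].unique())
    a = chunk.loc[chunk["group"] == groups[0], "b"].to_numpy()
    b = chunk.loc[chunk["group"] == groups[1], "b"].to_numpy()
    return two_sample_t(a, b).p


def power_p3b_belief(
    n_reps: int = 100, n_per_group: int = 30, seed: int = 0, alpha: float = 0.05
) -> float:
    """Fraction of replicate cohorts in which the control-vs-TS-like
    difference in P3b-amplitude belief betas is detected at ``alpha``.

    The default cohort injects a negative belief coefficient on P3b amplitude
    for control-like subjects and zero for TS-like subjects.
    """
    hits = 0
    for rep in range(n_reps):
        config = _reduced_config(cohort_mod.default_cohort_config,
                                 n_per_group, seed * 100_003 + rep)
        betas = subject_window_betas(config)
        hits += p3b_belief_group_pvalue(betas) < alpha
    return hits / n_reps


def type1_error_rates(
    n_reps: int = 100, n_per_group: int = 30, seed: int = 0, alpha: float = 0.05
) -> dict[str, float]:
    """Rejection rates under the null cohort (all ERP coefficients zero).

    Keys: ``two_sample_p3b_belief`` plus ``one_sample_<window>_<regressor>``
    for every non-intercept window beta tested across all subjects.
    """
    counts: dict[str, int] = {}
    for rep in range(n_reps):
        config = _reduced_config(cohort_mod.null_cohort_config,
                                 n_per_group, seed * 200_003 + rep)
        betas = subject_window_betas(config)
        counts["two_sample_p3b_belief"] = (
            counts.get("two_sample_p3b_belief", 0)
            + (p3b_belief_group_pvalue(betas) < alpha))
        for (window, reg), chunk in betas.groupby(["window", "regressor"]):
            if reg == "intercept":
                continue
            key = f"one_sample_{window}_{reg}"
            p = one_sample_t(chunk["b"].to_numpy()).p
            counts[key] = counts.get(key, 0) + (p < alpha)
    return {k: v / n_reps for k, v in counts.items()}
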