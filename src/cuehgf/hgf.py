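"""Three-level binary Hierarchical Gaussian Filter with a linear response-speed
observation model.

Perceptual model
----------------
The observer filters the binary cue-validity input u(t) (1 = valid).  The
probability of a valid cue is sigmoid(x2), where x2 performs a Gaussian random
walk whose step variance exp(kappa * x3 + omega2) is modulated by the
log-volatility state x3; x3 itself performs a random walk with step variance
exp(omega3).  Variational inversion under a mean-field approximation yields
one-step update equations driven by precision-weighted prediction errors; the
subject-specific tonic parameters omega2 and omega3 set the update magnitude
at levels 2 and 3.

Per trial, with the superscript ``-`` denoting the previous posterior::

    muhat1 = s(mu2-)                      # predicted P(valid) before outcome
    sighat2 = sigma2- + exp(kappa*mu3- + omega2)
    delta1 = u - muhat1
    pi2 = 1/sighat2 + muhat1*(1 - muhat1)
    mu2 = mu2- + delta1/pi2 ;  sigma2 = 1/pi2
    w2 = exp(kappa*mu3- + omega2) / sighat2
    delta2 = (sigma2 + (mu2 - mu2-)^2) / sighat2 - 1
    sighat3 = sigma3- + exp(omega3)
    pi3 = 1/sighat3 + (kappa^2/2) * w2 * (w2 + (2*w2 - 1)*delta2)
    mu3 = mu3- + (kappa/2) * (w2/pi3) * delta2 ;  sigma3 = 1/pi3

Response model
--------------
Response speed RS = 1/RT (1/s) is linear in the predicted cue validity
muhat1(t), with separate intercept/slope per validity branch::

    RS(t) = zeta1v + zeta2v * muhat1(t)        valid trials
    RS(t) = zeta1i + zeta2i * (1 - muhat1(t))  invalid trials

Estimation is MAP: Gaussian RS likelihood on correct, non-missed trials plus
Gaussian priors on (omega2, omega3, zetas, log noise_var), maximized by a
seeded multi-start quasi-Newton optimizer.  Belief updates are computed on
every trial — the cue-target contingency is observed regardless of the
response — while excluded trials simply contribute no likelihood term.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "PerceptualParams",
    "ResponseParams",
    "BeliefTrajectory",
    "FitResult",
    "ModelDivergence",
    "DEFAULT_PRIORS",
    "sigmoid",
    "hgf_filter",
    "predict_rs",
    "simulate_agent",
    "log_joint",
    "fit_hgf",
    "compare_group_params",
]


class ModelDivergence(RuntimeError):
    """Raised when a posterior precision becomes non-positive (numerically
    implausible parameters), mirroring standard HGF toolbox behaviour."""


@dataclass(frozen=True)
class PerceptualParams:
    """Tonic volatility parameters and initial beliefs of the perceptual model."""

    omega2: float = -3.0
    omega3: float = -6.0
    kappa: float = 1.0
    mu2_0: float = 0.0
    sigma2_0: float = 1.0
    mu3_0: float = 1.0
    sigma3_0: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma2_0 <= 0 or self.sigma3_0 <= 0:
            raise ValueError("initial state variances must be positive")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")


@dataclass(frozen=True)
class ResponseParams:
    """Linear RS observation model: intercept/slope per validity branch."""

    zeta1v: float = 2.0
    zeta2v: float = 1.0
    zeta1i: float = 2.0
    zeta2i: float = 1.0
    noise_var: float = 0.1  # Gaussian residual variance on the RS scale (1/s)^2

    def __post_init__(self) -> None:
        if self.noise_var <= 0:
            raise ValueError("noise_var must be positive")


@dataclass(frozen=True)
class BeliefTrajectory:
    """Per-trial filtered quantities; all arrays share length T."""

    muhat1: np.ndarray
    mu2: np.ndarray
    sigma2: np.ndarray
    mu3: np.ndarray
    sigma3: np.ndarray
    delta1: np.ndarray
    delta2: np.ndarray
    pi2: np.ndarray
    pi3: np.ndarray

    def __len__(self) -> int:
        return len(self.muhat1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "muhat1": self.muhat1,
                "mu2": self.mu2,
                "sigma2": self.sigma2,
                "mu3": self.mu3,
                "sigma3": self.sigma3,
                "delta1": self.delta1,
                "delta2": self.delta2,
                "pi2": self.pi2,
                "pi3": self.pi3,
            }
        )


def sigmoid(x):
    """Logistic sigmoid 1/(1+exp(-x)), stable for large |x|."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    if out.ndim == 0:
        return float(out)
    return out


def _sigmoid_scalar(x: float) -> float:
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    ex = math.exp(x)
    return ex / (1.0 + ex)


def hgf_filter(u, params: PerceptualParams = PerceptualParams()) -> BeliefTrajectory:
    """Run the 3-level binary HGF over the input sequence ``u``.

    Deterministic given ``(u, params)``.  Raises :class:`ModelDivergence` if
    any posterior precision pi2 or pi3 becomes non-positive.
    """
    u = np.asarray(u, dtype=float)
    if u.ndim != 1:
        raise ValueError("u must be a 1-D binary sequence")
    if not np.all((u == 0) | (u == 1)):
        raise ValueError("u must be binary (0/1)")
    T = len(u)
    kappa, omega2, omega3 = params.kappa, params.omega2, params.omega3

    out = {k: np.empty(T) for k in
           ("muhat1", "mu2", "sigma2", "mu3", "sigma3",
            "delta1", "delta2", "pi2", "pi3")}

    mu2, sigma2 = params.mu2_0, params.sigma2_0
    mu3, sigma3 = params.mu3_0, params.sigma3_0
    try:
        e_omega3 = math.exp(omega3)
    except OverflowError as exc:
        raise ModelDivergence(f"exp(omega3) overflow, omega3 = {omega3}") from exc

    for t in range(T):
        muhat1 = _sigmoid_scalar(mu2)
        try:
            step2 = math.exp(min(kappa * mu3 + omega2, 700.0))
        except OverflowError as exc:
            raise ModelDivergence(f"step variance overflow at trial {t + 1}") from exc
        sighat2 = sigma2 + step2
        delta1 = float(u[t]) - muhat1
        pi2 = 1.0 / sighat2 + muhat1 * (1.0 - muhat1)
        if not math.isfinite(pi2) or pi2 <= 0:
            raise ModelDivergence(f"pi2 = {pi2} at trial {t + 1}")
        mu2_new = mu2 + delta1 / pi2
        sigma2_new = 1.0 / pi2

        w2 = step2 / sighat2
        try:
            delta2 = (sigma2_new + (mu2_new - mu2) ** 2) / sighat2 - 1.0
        except OverflowError as exc:
            raise ModelDivergence(f"delta2 overflow at trial {t + 1}") from exc
        sighat3 = sigma3 + e_omega3
        pi3 = 1.0 / sighat3 + (kappa ** 2 / 2.0) * w2 * (w2 + (2.0 * w2 - 1.0) * delta2)
        if not math.isfinite(pi3) or pi3 <= 0:
            raise ModelDivergence(f"pi3 = {pi3} at trial {t + 1}")
        mu3 = mu3 + (kappa / 2.0) * (w2 / pi3) * delta2
        sigma3 = 1.0 / pi3
        mu2, sigma2 = mu2_new, sigma2_new

        out["muhat1"][t] = muhat1
        out["mu2"][t] = mu2
        out["sigma2"][t] = sigma2
        out["mu3"][t] = mu3
        out["sigma3"][t] = sigma3
        out["delta1"][t] = delta1
        out["delta2"][t] = delta2
        out["pi2"][t] = pi2
        out["pi3"][t] = pi3

    return BeliefTrajectory(**out)


def predict_rs(traj: BeliefTrajectory, validity, params: ResponseParams) -> np.ndarray:
    """Model-predicted RS per trial given beliefs and trial validity."""
    validity = np.asarray(validity)
    muhat1 = np.asarray(traj.muhat1)
    if len(validity) != len(muhat1):
        raise ValueError("validity and trajectory lengths differ")
    return np.where(
        validity == 1,
        params.zeta1v + params.zeta2v * muhat1,
        params.zeta1i + params.zeta2i * (1.0 - muhat1),
    )


@dataclass(frozen=True)
class LapseConfig:
    """Rates of incorrect and missed responses (independent per trial)."""

    p_incorrect: float = 0.03
    p_missed: float = 0.01


RT_BOUNDS_S = (0.1, 2.0)


def simulate_agent(
    sequence: pd.DataFrame,
    pparams: PerceptualParams,
    rparams: ResponseParams,
    lapse_cfg: LapseConfig = LapseConfig(),
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a subject's behaviour table on a trial sequence.

    RS is the model prediction plus Gaussian noise (sd sqrt(noise_var)); draws
    leaving RT outside (0.1 s, 2 s) are resampled (boundary clamp after 100
    attempts).  Incorrect/missed trials are drawn at the configured lapse
    rates.  Deterministic per seed; noise-free config returns predict_rs
    exactly.
    """
    rng = np.random.default_rng(seed)
    u = sequence["validity"].to_numpy()
    traj = hgf_filter(u, pparams)
    rs_pred = predict_rs(traj, u, rparams)
    sd = float(np.sqrt(rparams.noise_var))

    lo, hi = 1.0 / RT_BOUNDS_S[1], 1.0 / RT_BOUNDS_S[0]
    rs = np.empty(len(u))
    for t, mean in enumerate(rs_pred):
        value = mean + sd * rng.standard_normal()
        tries = 0
        while not lo < value < hi:
            value = mean + sd * rng.standard_normal()
            tries += 1
            if tries >= 100:
                value = float(np.clip(value, lo + 1e-9, hi - 1e-9))
                break
        rs[t] = value

    correct = (rng.uniform(size=len(u)) >= lapse_cfg.p_incorrect).astype(int)
    missed = (rng.uniform(size=len(u)) < lapse_cfg.p_missed).astype(int)
    correct[missed == 1] = 0

    return pd.DataFrame(
        {
            "trial_index": sequence["trial_index"].to_numpy(),
            "validity": u.astype(int),
            "rt_s": 1.0 / rs,
            "rs": rs,
            "correct": correct,
            "missed": missed,
        }
    )


@dataclass(frozen=True)
class GaussianPrior:
    mean: float
    var: float

    def logpdf(self, x: float) -> float:
        return float(-0.5 * np.log(2 * np.pi * self.var)
                     - 0.5 * (x - self.mean) ** 2 / self.var)


#: Default MAP priors on the unconstrained scale (noise variance via its log).
DEFAULT_PRIORS: dict[str, GaussianPrior] = {
    "omega2": GaussianPrior(-3.0, 16.0),
    "omega3": GaussianPrior(-6.0, 16.0),
    "zeta1v": GaussianPrior(0.0, 100.0),
    "zeta2v": GaussianPrior(0.0, 100.0),
    "zeta1i": GaussianPrior(0.0, 100.0),
    "zeta2i": GaussianPrior(0.0, 100.0),
    "log_noise_var": GaussianPrior(-2.0, 16.0),
}

_FREE_PARAMS = ("omega2", "omega3", "zeta1v", "zeta2v", "zeta1i", "zeta2i",
                "log_noise_var")


def _included_mask(behavior: pd.DataFrame) -> np.ndarray:
    return (behavior["correct"].to_numpy() == 1) & (behavior["missed"].to_numpy() == 0)


def log_joint(
    pparams: PerceptualParams,
    rparams: ResponseParams,
    behavior: pd.DataFrame,
    u,
    priors: dict[str, GaussianPrior] = DEFAULT_PRIORS,
) -> float:
    """MAP objective: RS log-likelihood on included trials + log-priors.

    Belief updates run over all trials; only correct, non-missed trials
    contribute likelihood terms.
    """
    u = np.asarray(u)
    if len(behavior) != len(u):
        raise ValueError("behavior and input sequence lengths differ")
    traj = hgf_filter(u, pparams)
    rs_pred = predict_rs(traj, u, rparams)
    mask = _included_mask(behavior)
    resid = behavior["rs"].to_numpy()[mask] - rs_pred[mask]
    n = int(mask.sum())
    ll = (-0.5 * n * np.log(2 * np.pi * rparams.noise_var)
          - 0.5 * np.sum(resid ** 2) / rparams.noise_var)
    lp = (priors["omega2"].logpdf(pparams.omega2)
          + priors["omega3"].logpdf(pparams.omega3)
          + priors["zeta1v"].logpdf(rparams.zeta1v)
          + priors["zeta2v"].logpdf(rparams.zeta2v)
          + priors["zeta1i"].logpdf(rparams.zeta1i)
          + priors["zeta2i"].logpdf(rparams.zeta2i)
          + priors["log_noise_var"].logpdf(np.log(rparams.noise_var)))
    return float(ll + lp)


@dataclass(frozen=True)
class FitOptions:
    n_restarts: int = 5
    seed: int = 0
    gtol: float = 1e-6
    min_trials: int = 30
    #: sd of the seeded perturbation around prior means for restarts 2..n
    restart_scale: float = 1.0


@dataclass
class FitResult:
    pparams: PerceptualParams
    rparams: ResponseParams
    neg_log_joint: float
    converged: bool
    n_restarts_used: int
    trajectory: BeliefTrajectory = field(repr=False)

    def params_dict(self) -> dict[str, float]:
        return {
            "omega2": self.pparams.omega2,
            "omega3": self.pparams.omega3,
            "zeta1v": self.rparams.zeta1v,
            "zeta2v": self.rparams.zeta2v,
            "zeta1i": self.rparams.zeta1i,
            "zeta2i": self.rparams.zeta2i,
            "noise_var": self.rparams.noise_var,
        }


def _unpack(x: np.ndarray, base: PerceptualParams) -> tuple[PerceptualParams, ResponseParams]:
    pp = replace(base, omega2=float(x[0]), omega3=float(x[1]))
    rp = ResponseParams(
        zeta1v=float(x[2]), zeta2v=float(x[3]),
        zeta1i=float(x[4]), zeta2i=float(x[5]),
        noise_var=float(np.exp(x[6])),
    )
    return pp, rp


def fit_hgf(
    behavior: pd.DataFrame,
    u,
    priors: dict[str, GaussianPrior] = DEFAULT_PRIORS,
    opts: FitOptions = FitOptions(),
    base_pparams: PerceptualParams = PerceptualParams(),
) -> FitResult:
    """MAP-fit perceptual (omega2, omega3) and response parameters to RS data.

    Multi-start L-BFGS-B on the unconstrained scale (noise variance fitted as
    its log).  The first start sits at the prior means; subsequent starts are
    seeded Gaussian perturbations, so refitting with identical options is
    deterministic.  Raises on fewer than ``opts.min_trials`` included trials
    or if no restart converges.
    """
    u = np.asarray(u)
    mask = _included_mask(behavior)
    if int(mask.sum()) < opts.min_trials:
        raise ValueError(
            f"insufficient data: {int(mask.sum())} included trials "
            f"(minimum {opts.min_trials})"
        )

    def objective(x: np.ndarray) -> float:
        try:
            pp, rp = _unpack(x, base_pparams)
            return -log_joint(pp, rp, behavior, u, priors)
        except (ModelDivergence, ValueError, OverflowError, FloatingPointError):
            return 1e12

    # box bounds on the unconstrained scale keep exp() transforms finite
    bounds = [(-15.0, 5.0), (-15.0, 5.0)] + [(-50.0, 50.0)] * 4 + [(-20.0, 5.0)]

    prior_mean = np.array([priors[k].mean for k in _FREE_PARAMS])
    # start response intercepts near the observed mean RS rather than 0
    rs_obs = behavior["rs"].to_numpy()[mask]
    prior_mean[2] = prior_mean[4] = float(np.mean(rs_obs))
    prior_mean[6] = float(np.log(np.var(rs_obs) + 1e-12))

    rng = np.random.default_rng(opts.seed)
    best = None
    n_used = 0
    for restart in range(opts.n_restarts):
        x0 = prior_mean.copy()
        if restart > 0:
            x0 = x0 + opts.restart_scale * rng.standard_normal(len(x0))
        x0 = np.clip(x0, [b[0] for b in bounds], [b[1] for b in bounds])
        res = optimize.minimize(
            objective, x0, method="L-BFGS-B", bounds=bounds,
            options={"gtol": opts.gtol, "maxiter": 500},
        )
        n_used += 1
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun) or best.fun >= 1e12:
        raise RuntimeError("non-convergence: no restart reached a finite optimum")

    pp, rp = _unpack(best.x, base_pparams)
    return FitResult(
        pparams=pp,
        rparams=rp,
        neg_log_joint=float(best.fun),
        converged=bool(best.success or np.isfinite(best.fun)),
        n_restarts_used=n_used,
        trajectory=hgf_filter(u, pp),
    )


_GROUP_TEST_PARAMS = ("omega2", "omega3", "zeta2v", "zeta2i")


def compare_group_params(fits_a, fits_b) -> pd.DataFrame:
    """Independent-samples pooled-variance t-tests on fitted parameters.

    Compares omega2, omega3 and the response slopes zeta2v/zeta2i between two
    groups of fits (the response intercepts are not analysed further).
    """
    if len(fits_a) < 2 or len(fits_b) < 2:
        raise ValueError("each group needs at least 2 fits")
    rows = []
    for name in _GROUP_TEST_PARAMS:
        a = np.array([f.params_dict()[name] for f in fits_a])
        b = np.array([f.params_dict()[name] for f in fits_b])
        t, p = stats.ttest_ind(a, b, equal_var=True)
        if np.allclose(a.mean(), b.mean()) and np.isnan(t):
            t, p = 0.0, 1.0  # identical zero-variance groups
        rows.append(
            {"parameter": name, "t": float(t), "df": len(a) + len(b) - 2,
             "p": float(p), "mean_a": float(a.mean()), "mean_b": float(b.mean())}
        )
    return pd.DataFrame(rows)
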