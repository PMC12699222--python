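"""Group-level inference: t-tests, 2 x 2 x 3 mixed ANOVA with
Greenhouse–Geisser correction, and Spearman correlations.

The behavioural design is one between-subject factor (group, 2 levels) and
two within-subject factors (cue validity, 2 levels; cue predictability,
50/70/90 %, 3 levels), balanced with per-subject cell means as the response.
The ANOVA decomposes sums of squares with separate error strata per within
effect; for within effects involving a factor with more than two levels the
Greenhouse–Geisser epsilon is computed from the pooled contrast-score
covariance and applied when Mauchly's test signals a sphericity violation
(or always, via a switch).

Plain t-tests and Spearman correlations delegate to scipy.stats; the
two-sample t uses the pooled-variance (Student) form, consistent with
reporting df = n1 + n2 - 2 for two groups of 30.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TTestResult",
    "rt_condition_means",
    "mixed_anova",
    "one_sample_t",
    "two_sample_t",
    "t_from_summary",
    "spearman",
    "gg_epsilon",
    "mauchly_test",
]


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    mean_diff: float
    cohen_d: float


# -- condition means --------------------------------------------------------

def rt_condition_means(behaviors, sequence: pd.DataFrame) -> pd.DataFrame:
    """Per-subject cell means of RT and accuracy by validity x predictability.

    ``behaviors`` is a mapping subject_id -> behaviour table (a single table
    is treated as one subject).  Incorrect and missed trials are excluded
    from the RT means only; accuracy is % correct over non-missed-agnostic
    all trials.  Subjects whose overall accuracy falls below the sample mean
    minus 2 SD are flagged (``low_accuracy``) but retained.  Empty cells
    yield NaN means and are reported via the ``n_rt`` column.
    """
    if isinstance(behaviors, pd.DataFrame):
        behaviors = {"s1": behaviors}
    levels = sorted(sequence["block_p_valid"].unique())
    rows = []
    overall_acc = {}
    for sid, beh in behaviors.items():
        if len(beh) != len(sequence):
            raise ValueError(f"behaviour for {sid} not aligned with sequence")
        merged = beh.reset_index(drop=True).copy()
        merged["block_p_valid"] = sequence["block_p_valid"].to_numpy()
        overall_acc[sid] = 100.0 * merged["correct"].mean()
        for v, p in itertools.product((0, 1), levels):
            cell = merged[(merged["validity"] == v) & (merged["block_p_valid"] == p)]
            ok = cell[(cell["correct"] == 1) & (cell["missed"] == 0)]
            rows.append(
                {
                    "subject": sid,
                    "validity": v,
                    "p_valid": p,
                    "mean_rt_s": float(ok["rt_s"].mean()) if len(ok) else np.nan,
                    "accuracy_pct": 100.0 * cell["correct"].mean() if len(cell) else np.nan,
                    "n_rt": int(len(ok)),
                }
            )
    table = pd.DataFrame(rows)
    acc = pd.Series(overall_acc)
    cutoff = acc.mean() - 2.0 * acc.std(ddof=1) if len(acc) > 1 else -np.inf
    table["low_accuracy"] = table["subject"].map(acc < cutoff)
    return table


# -- mixed ANOVA ------------------------------------------------------------

def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1) x k orthonormal contrast rows, each orthogonal to the unit vector."""
    helmert = np.zeros((k - 1, k))
    for i in range(k - 1):
        helmert[i, : i + 1] = 1.0
        helmert[i, i + 1] = -(i + 1)
        helmert[i] /= np.linalg.norm(helmert[i])
    return helmert


def _effect_contrast(b: int, c: int, effect: str) -> np.ndarray:
    """Orthonormal contrast matrix over the b*c within cells for one effect."""
    ones_b = np.full((1, b), 1.0 / np.sqrt(b))
    ones_c = np.full((1, c), 1.0 / np.sqrt(c))
    cb, cc = _orthonormal_contrasts(b), _orthonormal_contrasts(c)
    if effect == "B":
        return np.kron(cb, ones_c)
    if effect == "C":
        return np.kron(ones_b, cc)
    if effect == "BC":
        return np.kron(cb, cc)
    raise ValueError(effect)


def gg_epsilon(S: np.ndarray) -> float:
    """Greenhouse–Geisser epsilon from a contrast-score covariance matrix."""
    p = S.shape[0]
    if p == 1:
        return 1.0
    denom = p * np.sum(S * S.T)
    if denom <= 0:
        return 1.0  # degenerate (zero) covariance: sphericity is vacuous
    return float(np.trace(S) ** 2 / denom)


def mauchly_test(S: np.ndarray, n_error_df: int) -> tuple[float, float]:
    """Mauchly's sphericity test on a contrast-score covariance.

    Returns (W, p) via the standard chi-square approximation; W = 1, p = 1
    for a 1-D (trivially spherical) contrast space.
    """
    p = S.shape[0]
    if p == 1:
        return 1.0, 1.0
    det = np.linalg.det(S)
    mean_eig = np.trace(S) / p
    if det <= 0 or mean_eig <= 0:
        return 0.0, 0.0
    W = float(det / mean_eig ** p)
    d = 1.0 - (2.0 * p ** 2 + p + 2.0) / (6.0 * p * n_error_df)
    chi2 = -n_error_df * d * np.log(W)
    df = p * (p + 1) // 2 - 1
    return W, float(sps.chi2.sf(chi2, df))


def _cell_matrix(cells: pd.DataFrame, dv: str):
    """Pivot the long cell-mean table to subjects x (validity, p_valid) cells."""
    wide = cells.pivot_table(index="subject", columns=["validity", "p_valid"],
                             values=dv)
    if wide.isna().any().any():
        missing = wide.columns[wide.isna().any()].tolist()
        raise ValueError(f"missing cells in design: {missing}")
    wide = wide.sort_index(axis=1)
    return wide


def mixed_anova(
    cells: pd.DataFrame,
    groups: dict[str, str] | pd.Series,
    dv: str = "mean_rt_s",
    sphericity_correction: str = "auto",
    alpha_mauchly: float = 0.05,
) -> pd.DataFrame:
    """Balanced mixed ANOVA: group (between) x validity x predictability.

    ``cells`` is the long table from :func:`rt_condition_means`; ``groups``
    maps subject id -> group label.  ``sphericity_correction`` is ``"auto"``
    (apply GG when Mauchly rejects), ``"always"`` or ``"never"``.

    Returns a table with SS, df (GG-corrected where applied), MS, F, p,
    partial eta squared and the epsilon used.
    """
    wide = _cell_matrix(cells, dv)
    groups = pd.Series(groups)
    glabels = groups.loc[wide.index]
    group_levels = sorted(glabels.unique())
    a = len(group_levels)
    ns = [int((glabels == g).sum()) for g in group_levels]
    if min(ns) < 2:
        raise ValueError("need >= 2 subjects per group")
    if len(set(ns)) != 1:
        raise ValueError("unbalanced group sizes are not supported")
    n = ns[0]

    v_levels = sorted({col[0] for col in wide.columns})
    p_levels = sorted({col[1] for col in wide.columns})
    b, c = len(v_levels), len(p_levels)
    Y = wide.to_numpy().reshape(a * n, b, c)  # subjects sorted by group below
    order = np.argsort(glabels.to_numpy(), kind="stable")
    Y = Y[order]
    Yg = Y.reshape(a, n, b, c)

    M = Y.mean()
    m_g = Yg.mean(axis=(1, 2, 3))
    m_b = Y.mean(axis=(0, 2))
    m_c = Y.mean(axis=(0, 1))
    m_gb = Yg.mean(axis=(1, 3))
    m_gc = Yg.mean(axis=(1, 2))
    m_bc = Y.mean(axis=0)
    m_gbc = Yg.mean(axis=1)
    s_mean = Yg.mean(axis=(2, 3))          # a x n subject means
    s_b = Yg.mean(axis=3)                  # a x n x b
    s_c = Yg.mean(axis=2)                  # a x n x c

    ss = {}
    ss["group"] = n * b * c * np.sum((m_g - M) ** 2)
    ss["subj(group)"] = b * c * np.sum((s_mean - m_g[:, None]) ** 2)
    ss["validity"] = a * n * c * np.sum((m_b - M) ** 2)
    ss["group*validity"] = n * c * np.sum(
        (m_gb - m_g[:, None] - m_b[None, :] + M) ** 2)
    ss["validity*subj(group)"] = c * np.sum(
        (s_b - s_mean[:, :, None] - m_gb[:, None, :] + m_g[:, None, None]) ** 2)
    ss["predictability"] = a * n * b * np.sum((m_c - M) ** 2)
    ss["group*predictability"] = n * b * np.sum(
        (m_gc - m_g[:, None] - m_c[None, :] + M) ** 2)
    ss["predictability*subj(group)"] = b * np.sum(
        (s_c - s_mean[:, :, None] - m_gc[:, None, :] + m_g[:, None, None]) ** 2)
    ss["validity*predictability"] = a * n * np.sum(
        (m_bc - m_b[:, None] - m_c[None, :] + M) ** 2)
    ss["group*validity*predictability"] = n * np.sum(
        (m_gbc - m_gb[:, :, None] - m_gc[:, None, :] + m_g[:, None, None]
         - m_bc[None, :, :] + m_b[None, :, None] + m_c[None, None, :] - M) ** 2)
    resid = (Yg - s_b[:, :, :, None] - s_c[:, :, None, :] + s_mean[:, :, None, None]
             - m_gbc[:, None, :, :] + m_gb[:, None, :, None]
             + m_gc[:, None, None, :] - m_g[:, None, None, None])
    ss["validity*predictability*subj(group)"] = np.sum(resid ** 2)

    # squash floating-point residue so constant data yields exact zeros
    tol = 10.0 * np.finfo(float).eps * max(float(np.sum(Y * Y)), 1.0)
    ss = {k: (0.0 if v < tol else float(v)) for k, v in ss.items()}

    df = {
        "group": a - 1,
        "subj(group)": a * (n - 1),
        "validity": b - 1,
        "group*validity": (a - 1) * (b - 1),
        "validity*subj(group)": a * (n - 1) * (b - 1),
        "predictability": c - 1,
        "group*predictability": (a - 1) * (c - 1),
        "predictability*subj(group)": a * (n - 1) * (c - 1),
        "validity*predictability": (b - 1) * (c - 1),
        "group*validity*predictability": (a - 1) * (b - 1) * (c - 1),
        "validity*predictability*subj(group)": a * (n - 1) * (b - 1) * (c - 1),
    }
    error_of = {
        "group": "subj(group)",
        "validity": "validity*subj(group)",
        "group*validity": "validity*subj(group)",
        "predictability": "predictability*subj(group)",
        "group*predictability": "predictability*subj(group)",
        "validity*predictability": "validity*predictability*subj(group)",
        "group*validity*predictability": "validity*predictability*subj(group)",
    }
    within_space = {
        "validity": "B", "group*validity": "B",
        "predictability": "C", "group*predictability": "C",
        "validity*predictability": "BC", "group*validity*predictability": "BC",
    }

    # pooled (within-group) covariance of contrast scores per within effect
    cells_mat = Y.reshape(a, n, b * c)
    eps_of, mauchly_of = {}, {}
    for space in ("B", "C", "BC"):
        C = _effect_contrast(b, c, space)
        Z = cells_mat @ C.T  # a x n x df
        Zc = Z - Z.mean(axis=1, keepdims=True)
        S = sum(Zc[g].T @ Zc[g] for g in range(a)) / (a * (n - 1))
        eps_of[space] = gg_epsilon(S)
        mauchly_of[space] = mauchly_test(S, a * (n - 1))

    rows = []
    for effect in [e for e in df if "subj" not in e]:
        err = error_of[effect]
        ms_e, ms_err = ss[effect] / df[effect], ss[err] / df[err]
        F = ms_e / ms_err if ms_err > 0 else 0.0
        d1, d2 = float(df[effect]), float(df[err])
        eps = 1.0
        w = p_m = np.nan
        if effect in within_space:
            space = within_space[effect]
            w, p_m = mauchly_of[space]
            candidate = eps_of[space]
            apply = (sphericity_correction == "always"
                     or (sphericity_correction == "auto" and p_m < alpha_mauchly))
            if apply and candidate < 1.0:
                eps = candidate
                d1, d2 = eps * d1, eps * d2
        p = float(sps.f.sf(F, d1, d2)) if F > 0 else 1.0
        rows.append(
            {"effect": effect, "SS": float(ss[effect]), "df1": d1, "df2": d2,
             "MS": float(ms_e), "F": float(F), "p": p,
             "pes": float(ss[effect] / (ss[effect] + ss[err]))
                    if ss[effect] + ss[err] > 0 else 0.0,
             "gg_epsilon": float(eps), "mauchly_W": float(w) if w == w else np.nan,
             "mauchly_p": float(p_m) if p_m == p_m else np.nan,
             "error_SS": float(ss[err]), "error_term": err}
        )
    return pd.DataFrame(rows)


# -- t-tests and correlations ----------------------------------------------

def one_sample_t(values, popmean: float = 0.0) -> TTestResult:
    """Two-tailed one-sample t-test against ``popmean``."""
    x = np.asarray(values, dtype=float)
    if len(x) < 2:
        raise ValueError("need n >= 2")
    sd = x.std(ddof=1)
    if sd == 0:
        t = 0.0 if np.isclose(x.mean(), popmean) else np.inf * np.sign(x.mean() - popmean)
        p = 1.0 if t == 0 else float(np.nextafter(0, 1))
        return TTestResult(float(t), len(x) - 1, p, float(x.mean() - popmean),
                           float("nan"))
    res = sps.ttest_1samp(x, popmean)
    d = (x.mean() - popmean) / sd
    return TTestResult(float(res.statistic), float(len(x) - 1),
                       float(res.pvalue), float(x.mean() - popmean), float(d))


def two_sample_t(a, b) -> TTestResult:
    """Two-tailed pooled-variance (Student) two-sample t-test."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need n >= 2 per sample")
    sp2 = (((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1))
           / (len(a) + len(b) - 2))
    if sp2 == 0:
        t = 0.0 if np.isclose(a.mean(), b.mean()) else np.inf * np.sign(a.mean() - b.mean())
        p = 1.0 if t == 0 else float(np.nextafter(0, 1))
        return TTestResult(float(t), float(len(a) + len(b) - 2), p,
                           float(a.mean() - b.mean()), float("nan"))
    res = sps.ttest_ind(a, b, equal_var=True)
    d = (a.mean() - b.mean()) / np.sqrt(sp2)
    return TTestResult(float(res.statistic), float(len(a) + len(b) - 2),
                       float(res.pvalue), float(a.mean() - b.mean()), float(d))


def t_from_summary(m1: float, sd1: float, n1: int,
                   m2: float, sd2: float, n2: int) -> TTestResult:
    """Pooled-variance two-sample t computed from summary statistics alone."""
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("sds must be positive")
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per sample")
    sp2 = ((n1 - 1) * sd1 ** 2 + (n2 - 1) * sd2 ** 2) / (n1 + n2 - 2)
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    t = (m1 - m2) / se
    df = n1 + n2 - 2
    p = 2.0 * sps.t.sf(abs(t), df)
    return TTestResult(float(t), float(df), float(p), float(m1 - m2),
                       float((m1 - m2) / np.sqrt(sp2)))


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation (midranks for ties) with two-tailed p via
    the t approximation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y lengths differ")
    if len(x) < 4:
        raise ValueError("need n >= 4")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("spearman undefined for constant input")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)
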