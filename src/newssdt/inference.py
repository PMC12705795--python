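"""Inferential battery for pre/post discrimination and bias scores.

Implements the analysis battery applied to the per-participant AUC and B"D
scores: repeated-measures t-tests with the paired effect size dz and default
JZS (Cauchy-prior) Bayes factors, the 2x2 mixed ANOVA (test x counterbalancing
condition) with generalized eta-squared, Monte-Carlo g-prior Bayes factors for
the ANOVA effects, an a priori power analysis for the paired t-test via the
noncentral t distribution, and the per-category mean-ratings comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate, linalg, stats

from .exceptions import (
    ComputationError,
    ConfigurationError,
    DegenerateDataError,
    NumericalError,
)
from .io_model import FAKE_CATEGORIES, RatingsTable

#: Default Cauchy prior scale on the standardized effect size ("medium").
DEFAULT_RSCALE = float(np.sqrt(2.0) / 2.0)


@dataclass(frozen=True)
class TestResult:
    """One pre/post contrast: t statistic, df, two-tailed p, dz, and BF10."""

    t: float
    df: int
    p: float
    dz: float
    bf10: float | None
    n: int

    def to_dict(self) -> dict:
        return {
            "t": self.t, "df": self.df, "p": self.p,
            "dz": self.dz, "bf10": self.bf10, "n": self.n,
        }


def paired_t(
    pre,
    post,
    rscale: float = DEFAULT_RSCALE,
    compute_bf: bool = True,
) -> TestResult:
    """Classical paired t-test of post vs pre with dz and JZS BF10.

    ``dz = mean(diff) / SD(diff)`` (sample SD), so ``dz = t / sqrt(n)``.
    Identical samples (all differences zero) are guarded as t=0, p=1, dz=0
    with a warning; constant non-zero differences leave t undefined and raise
    :class:`DegenerateDataError`.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1:
        raise ConfigurationError("pre and post must be equal-length 1-d vectors")
    n = pre.size
    if n < 2:
        raise DegenerateDataError("paired t-test needs n >= 2 pairs")
    diff = post - pre
    sd = diff.std(ddof=1)
    if sd == 0.0:
        if np.all(diff == 0.0):
            warnings.warn(
                "identical paired samples: returning t=0, p=1, dz=0",
                RuntimeWarning,
                stacklevel=2,
            )
            t_stat, p = 0.0, 1.0
        else:
            raise DegenerateDataError(
                "zero-variance non-zero differences leave t undefined"
            )
    else:
        res = stats.ttest_rel(post, pre)
        t_stat, p = float(res.statistic), float(res.pvalue)
    dz = float(diff.mean() / sd) if sd > 0 else 0.0
    bf10 = jzs_bf_paired(t_stat, n, rscale) if compute_bf else None
    return TestResult(t=t_stat, df=n - 1, p=p, dz=dz, bf10=bf10, n=n)


def jzs_bf_paired(t: float, n: int, rscale: float = DEFAULT_RSCALE) -> float:
    """Default JZS Bayes factor BF10 for a one-sample / paired t statistic.

    Under H1 the standardized effect size delta has a Cauchy(0, rscale)
    prior; BF10 is the ratio of the marginal likelihood of ``t`` under H1
    (noncentral t with ncp = delta*sqrt(n), integrated over the prior) to its
    likelihood under the point null.  Computed by adaptive quadrature with
    relative tolerance 1e-8.
    """
    if n < 2:
        raise ConfigurationError("jzs_bf_paired needs n >= 2")
    if not np.isfinite(t):
        raise ConfigurationError("t must be finite")
    if rscale <= 0:
        raise ConfigurationError("rscale must be positive")
    df = n - 1
    root_n = np.sqrt(n)

    def integrand(delta: float) -> float:
        return stats.nct.pdf(t, df, delta * root_n) * stats.cauchy.pdf(delta, scale=rscale)

    num, err = integrate.quad(integrand, -np.inf, np.inf, epsabs=0.0, epsrel=1e-8)
    if not np.isfinite(num) or num <= 0 or err > 1e-6 * num:
        raise NumericalError(
            f"JZS quadrature did not converge (value={num!r}, abserr={err!r})"
        )
    return float(num / stats.t.pdf(t, df))


@dataclass(frozen=True)
class PowerSpec:
    """A priori power analysis for a paired t-test."""

    dz: float
    alpha: float
    power: float
    tails: int
    n_required: int
    achieved_power: float


def _paired_t_power(dz: float, n: int, alpha: float, tails: int) -> float:
    df = n - 1
    ncp = dz * np.sqrt(n)
    if tails == 2:
        tc = stats.t.isf(alpha / 2.0, df)
        return float(stats.nct.sf(tc, df, ncp) + stats.nct.cdf(-tc, df, ncp))
    tc = stats.t.isf(alpha, df)
    return float(stats.nct.sf(tc, df, ncp))


def power_paired_t(
    dz: float,
    alpha: float = 0.05,
    power: float = 0.95,
    tails: int = 2,
) -> PowerSpec:
    """Smallest n for a paired t-test to reach the target power.

    Power is evaluated exactly from the noncentral t distribution with
    noncentrality ``dz * sqrt(n)`` and df ``n - 1``; the returned n achieves
    the target while n-1 does not.
    """
    if not 0 < alpha < 1:
        raise ConfigurationError("alpha must be in (0, 1)")
    if not 0 < power < 1:
        raise ConfigurationError("power must be in (0, 1)")
    if dz <= 0:
        raise ConfigurationError("dz must be positive")
    if tails not in (1, 2):
        raise ConfigurationError("tails must be 1 or 2")
    lo, hi = 2, 4
    while _paired_t_power(dz, hi, alpha, tails) < power:
        lo, hi = hi, hi * 2
        if hi > 10**7:
            raise NumericalError("target power unreachable within n <= 1e7")
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if _paired_t_power(dz, mid, alpha, tails) >= power:
            hi = mid
        else:
            lo = mid
    return PowerSpec(
        dz=dz, alpha=alpha, power=power, tails=tails,
        n_required=hi, achieved_power=_paired_t_power(dz, hi, alpha, tails),
    )


# -- 2x2 mixed ANOVA ----------------------------------------------------------


@dataclass(frozen=True)
class AnovaResult:
    """A 2 (test: pre/post) x 2 (condition: set A/B) mixed ANOVA.

    ``table`` has one row per effect (``test``, ``condition``,
    ``interaction``) with F, df1, df2, p and generalized eta-squared; the
    component sums of squares are kept for effect-size recomputation.
    """

    table: pd.DataFrame
    ss: dict[str, float]

    def effect(self, name: str) -> pd.Series:
        return self.table.loc[name]


def _split_plot_ss(pre, post, group):
    """Sums of squares of the 2x2 split-plot design on the response scale.

    Uses the sum/difference-score decomposition: subject means carry the
    between-subject part; difference scores carry the within part.  The
    within-factor and interaction tests use unweighted (type III) cell means,
    so they remain valid for unequal group sizes.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    group = np.asarray(group)
    if not (pre.shape == post.shape == group.shape) or pre.ndim != 1:
        raise ConfigurationError("pre, post and group must be equal-length vectors")
    levels = np.unique(group)
    if len(levels) != 2:
        raise ConfigurationError(f"between factor must have 2 levels, got {list(levels)}")
    n_j = np.array([(group == g).sum() for g in levels])
    if n_j.min() < 2:
        raise DegenerateDataError("each group needs at least 2 participants")
    d = post - pre
    m = (post + pre) / 2.0
    N = pre.size
    # between-subjects part (one obs per subject on m; x2 for the y scale)
    grand = m.mean()
    m_j = np.array([m[group == g].mean() for g in levels])
    ss_cond = 2.0 * float(np.sum(n_j * (m_j - grand) ** 2))
    ss_err_b = 2.0 * float(sum(((m[group == g] - mj) ** 2).sum() for g, mj in zip(levels, m_j)))
    # within part on difference scores (unweighted cell means; /2 for y scale)
    d_j = np.array([d[group == g].mean() for g in levels])
    w = 4.0 / (1.0 / n_j[0] + 1.0 / n_j[1])
    alpha_hat = d_j.mean()          # within main effect (unweighted)
    beta_hat = (d_j[0] - d_j[1]) / 2.0  # interaction
    ss_test = w * alpha_hat**2 / 2.0
    ss_inter = w * beta_hat**2 / 2.0
    ss_err_w = float(sum(((d[group == g] - dj) ** 2).sum() for g, dj in zip(levels, d_j))) / 2.0
    return {
        "test": ss_test, "condition": ss_cond, "interaction": ss_inter,
        "error_between": ss_err_b, "error_within": ss_err_w, "n_groups": n_j, "N": N,
    }


def mixed_anova_2x2(pre, post, group) -> AnovaResult:
    """2 (test) x 2 (condition) mixed ANOVA with generalized eta-squared.

    The between factor is treated as an observed (measured) factor in the
    generalized eta-squared denominators, so every effect's denominator pools
    the condition and interaction sums of squares with both error terms.
    Degenerate data with no variance at all return F = 0, ges = 0, p = 1.
    """
    ss = _split_plot_ss(pre, post, group)
    N = ss["N"]
    df2 = N - 2

    def f_ratio(ss_eff: float, ss_err: float) -> tuple[float, float]:
        ms_err = ss_err / df2
        if ms_err == 0.0:
            return 0.0, 1.0
        f = ss_eff / ms_err
        return f, float(stats.f.sf(f, 1, df2))

    f_test, p_test = f_ratio(ss["test"], ss["error_within"])
    f_cond, p_cond = f_ratio(ss["condition"], ss["error_between"])
    f_int, p_int = f_ratio(ss["interaction"], ss["error_within"])

    observed = ss["condition"] + ss["interaction"]
    errors = ss["error_between"] + ss["error_within"]

    def ges(ss_eff: float, effect_observed: bool) -> float:
        denom = observed + errors + (0.0 if effect_observed else ss_eff)
        return ss_eff / denom if denom > 0 else 0.0

    table = pd.DataFrame(
        {
            "F": [f_test, f_cond, f_int],
            "df1": [1, 1, 1],
            "df2": [df2, df2, df2],
            "p": [p_test, p_cond, p_int],
            "ges": [
                ges(ss["test"], False),
                ges(ss["condition"], True),
                ges(ss["interaction"], True),
            ],
        },
        index=pd.Index(["test", "condition", "interaction"], name="effect"),
    )
    return AnovaResult(table=table, ss={k: v for k, v in ss.items() if np.isscalar(v)})


# -- Monte-Carlo g-prior Bayes factors for the ANOVA effects ------------------


def _orthonormal_contrasts(levels: int) -> np.ndarray:
    """(levels x levels-1) sum-to-zero contrast matrix with orthonormal columns."""
    h = np.zeros((levels, levels - 1))
    for j in range(1, levels):
        h[:j, j - 1] = 1.0
        h[j, j - 1] = -j
        h[:, j - 1] /= np.linalg.norm(h[:, j - 1])
    return h


class _GPriorModel:
    """Marginal likelihood (vs the intercept-only null) of one g-prior model.

    The design columns are grouped into blocks, each sharing one g parameter
    with an independent scaled inverse-chi-squared (InvGamma(1/2, r^2/2))
    prior.  Conditional on g the Bayes factor against the null has a closed
    form; the mixture over g is integrated by Monte Carlo.
    """

    def __init__(self, y: np.ndarray, blocks: list[tuple[np.ndarray, float]]):
        y = np.asarray(y, dtype=float)
        self.n = y.size
        yc = y - y.mean()
        self.s_yy = float(yc @ yc)
        X = np.hstack([b for b, _ in blocks])
        Xc = X - X.mean(axis=0)
        self.A = Xc.T @ Xc
        self.b = Xc.T @ yc
        self.block_sizes = [b.shape[1] for b, _ in blocks]
        self.rscales = np.array([r for _, r in blocks])

    def log_bf_given_g(self, g: np.ndarray) -> float:
        g_vec = np.repeat(g, self.block_sizes)
        M = self.A + np.diag(1.0 / g_vec)
        c, low = linalg.cho_factor(M, lower=True, check_finite=False)
        logdet = 2.0 * np.sum(np.log(np.diag(c))) + np.sum(np.log(g_vec))
        q = float(self.b @ linalg.cho_solve((c, low), self.b, check_finite=False))
        resid = max(1.0 - q / self.s_yy, np.finfo(float).tiny)
        return -0.5 * logdet - 0.5 * (self.n - 1) * np.log(resid)

    def sample_log_bf(self, iterations: int, rng: np.random.Generator) -> np.ndarray:
        # g = r^2 / chisq_1 draws an InvGamma(1/2, r^2/2) variate per block
        z = rng.standard_normal((iterations, len(self.rscales)))
        gs = (self.rscales**2) / np.clip(z**2, 1e-300, None)
        return np.array([self.log_bf_given_g(g) for g in gs])


def _mc_mean_and_se(log_bf: np.ndarray) -> tuple[float, float]:
    shift = log_bf.max()
    w = np.exp(log_bf - shift)
    mean = float(np.exp(shift) * w.mean())
    se = float(np.exp(shift) * w.std(ddof=1) / np.sqrt(len(w)))
    return mean, se


def anova_bf_approx(
    pre,
    post,
    group,
    mc_iterations: int = 10_000,
    seed: int | None = None,
    rscale_fixed: float = 0.5,
    rscale_random: float = 1.0,
) -> pd.DataFrame:
    """Monte-Carlo Bayes factors for the three 2x2 mixed-ANOVA effects.

    Each effect's BF10 compares the linear mixed model containing the effect
    against the same model without it, with participant as an additive random
    factor and default g-priors (scale 0.5 on fixed effects, 1.0 on the
    random participant factor).  Main-effect BFs compare ``participant +
    effect`` with ``participant``; the interaction BF compares the full model
    with the two-main-effect model.  Returns a DataFrame indexed by effect
    with columns ``bf10`` and ``bf_se`` (the Monte-Carlo standard error).
    """
    if mc_iterations < 1000:
        raise ConfigurationError("mc_iterations must be >= 1000")
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    group = np.asarray(group)
    N = pre.size
    if np.allclose(post - pre, (post - pre)[0]) and np.allclose(pre, pre[0]):
        raise DegenerateDataError("no variance in the responses")
    levels = np.unique(group)
    if len(levels) != 2:
        raise ConfigurationError("between factor must have 2 levels")

    y = np.concatenate([pre, post])
    subj = np.tile(np.arange(N), 2)
    phase = np.repeat([0, 1], N)
    cond = np.concatenate([(group == levels[1]).astype(int)] * 2)

    subj_contr = _orthonormal_contrasts(N)[subj]            # 2N x (N-1)
    two = _orthonormal_contrasts(2)[:, 0]                   # (+1/sqrt2, -1/sqrt2)
    phase_col = two[phase][:, None]
    cond_col = two[cond][:, None]
    inter_col = phase_col * cond_col

    rng = np.random.default_rng(seed)
    models = {
        "null": [(subj_contr, rscale_random)],
        "test": [(subj_contr, rscale_random), (phase_col, rscale_fixed)],
        "condition": [(subj_contr, rscale_random), (cond_col, rscale_fixed)],
        "mains": [
            (subj_contr, rscale_random),
            (phase_col, rscale_fixed),
            (cond_col, rscale_fixed),
        ],
        "full": [
            (subj_contr, rscale_random),
            (phase_col, rscale_fixed),
            (cond_col, rscale_fixed),
            (inter_col, rscale_fixed),
        ],
    }
    est: dict[str, tuple[float, float]] = {}
    for name, blocks in models.items():
        model = _GPriorModel(y, blocks)
        est[name] = _mc_mean_and_se(model.sample_log_bf(mc_iterations, rng))

    def ratio(num: str, den: str) -> tuple[float, float]:
        (m1, s1), (m2, s2) = est[num], est[den]
        bf = m1 / m2
        se = bf * np.sqrt((s1 / m1) ** 2 + (s2 / m2) ** 2)
        return bf, se

    rows = {
        "test": ratio("test", "null"),
        "condition": ratio("condition", "null"),
        "interaction": ratio("full", "mains"),
    }
    return pd.DataFrame(
        {"bf10": [v[0] for v in rows.values()], "bf_se": [v[1] for v in rows.values()]},
        index=pd.Index(rows.keys(), name="effect"),
    )


# -- mean-ratings comparison --------------------------------------------------


def mean_ratings_tests(
    table: RatingsTable,
    rscale: float = DEFAULT_RSCALE,
    compute_bf: bool = True,
) -> dict[str, TestResult]:
    """Four repeated-measures t-tests on per-category mean ratings.

    For each item category (Control, Conspiracy, Discrediting, Impersonation)
    the participant-level mean rating is computed per phase and compared post
    vs pre with :func:`paired_t`.  This is the mean-ratings analysis that
    conflates discrimination and response bias; it is provided for comparison
    with the ROC statistics.
    """
    df = table.data
    means = (
        df.groupby(["category", "participant_id", "phase"], observed=True)["rating"]
        .mean()
        .unstack("phase")
    )
    out: dict[str, TestResult] = {}
    for category in ("Control",) + tuple(sorted(FAKE_CATEGORIES)):
        if category not in means.index.get_level_values("category"):
            raise ComputationError(f"category {category!r} absent from the table")
        sub = means.loc[category]
        if sub.isna().any().any():
            raise ComputationError(
                f"category {category!r} missing in one phase for some participants"
            )
        out[category] = paired_t(
            sub["pre"].to_numpy(), sub["post"].to_numpy(),
            rscale=rscale, compute_bf=compute_bf,
        )
    return out
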