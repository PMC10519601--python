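"""Inferential statistics for the three analyses.

Within-user comparison: dependent t-tests over per-user (MH, non-MH) mean
scores with Bonferroni correction for the five categories and paired Cohen's
d. Two d variants are reported — d_z = mean(diff)/sd(diff) and
d_av = mean(diff)/sqrt((sd₁² + sd₂²)/2) — because published paired effect
sizes are frequently not identifiable to one variant from summary tables
alone; d_av is the variant recomputable from printed group means and SDs.

Between-user comparison: binomial logistic regression (logit link) fitted by
iteratively reweighted least squares, with Wald standard errors from the
inverse observed information, normal-approximation z/p, 1.96-SE confidence
intervals, odds ratios, AIC/BIC, a likelihood-ratio test against the nested
controls-only model, and three likelihood-based pseudo-R² summaries
(Hosmer–Lemeshow 1 − ll/ll₀, Cox–Snell, Nagelkerke). Perfect separation and
rank-deficient designs raise explicit errors rather than returning
unreliable estimates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from bdforum.lexicon import CATEGORIES

Z_95 = 1.959963984540054  # normal 97.5% quantile; 1.96 at printed precision
BONFERRONI_M = 5


class DegenerateTestError(ValueError):
    """The requested test is undefined on this input."""


class SeparationError(RuntimeError):
    """The likelihood has no finite maximiser (perfect separation)."""


class RankDeficientError(ValueError):
    """The design matrix is rank deficient."""


# ---------------------------------------------------------------------------
# Paired within-user comparison


def interpret_d(d: float) -> str:
    """Conventional magnitude label for Cohen's d."""
    a = abs(d)
    if a < 0.01:
        return "Negligible"
    if a < 0.2:
        return "Very small"
    if a < 0.5:
        return "Small"
    if a < 0.8:
        return "Medium"
    if a < 1.2:
        return "Large"
    if a < 2.0:
        return "Very large"
    return "Huge"


@dataclass(frozen=True)
class PairedComparison:
    variable: str
    n: int
    mean_mh: float
    sd_mh: float
    mean_nonmh: float
    sd_nonmh: float
    t: float
    df: int
    p: float
    p_bonf: float
    d_z: float
    d_av: float
    interpretation: str


def cohens_d_av(mean_diff: float, sd1: float, sd2: float) -> float:
    """Paired d standardised by the average of the two condition SDs."""
    denom = math.sqrt((sd1**2 + sd2**2) / 2.0)
    if denom == 0:
        raise DegenerateTestError("both condition SDs are zero")
    return mean_diff / denom


def paired_comparison(
    mh_means: Sequence[float],
    nonmh_means: Sequence[float],
    variable: str = "",
    m: int = BONFERRONI_M,
) -> PairedComparison:
    """Dependent t-test on per-user paired means, MH minus non-MH.

    ``p_bonf = min(1, m·p)``. With zero difference variance the test is
    degenerate: identical vectors give the null result (t=0, p=1, d=0);
    a nonzero constant difference raises :class:`DegenerateTestError`.
    """
    a = np.asarray(mh_means, dtype=float)
    b = np.asarray(nonmh_means, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired vectors must be one-dimensional and equal length")
    n = a.size
    if n < 2:
        raise DegenerateTestError("paired t-test requires n >= 2")
    diff = a - b
    sd_diff = float(np.std(diff, ddof=1))
    mean_diff = float(np.mean(diff))
    if sd_diff == 0.0:
        if mean_diff != 0.0:
            raise DegenerateTestError("zero difference variance with nonzero mean difference")
        t = 0.0
        p = 1.0
        d_z = 0.0
    else:
        t = mean_diff / (sd_diff / math.sqrt(n))
        p = float(2.0 * sps.t.sf(abs(t), df=n - 1))
        d_z = mean_diff / sd_diff
    sd_mh = float(np.std(a, ddof=1))
    sd_nonmh = float(np.std(b, ddof=1))
    if sd_mh == 0.0 and sd_nonmh == 0.0:
        d_av = 0.0 if mean_diff == 0.0 else math.inf
    else:
        d_av = cohens_d_av(mean_diff, sd_mh, sd_nonmh)
    return PairedComparison(
        variable=variable,
        n=n,
        mean_mh=float(np.mean(a)),
        sd_mh=sd_mh,
        mean_nonmh=float(np.mean(b)),
        sd_nonmh=sd_nonmh,
        t=float(t),
        df=n - 1,
        p=p,
        p_bonf=min(1.0, m * p),
        d_z=float(d_z),
        d_av=float(d_av),
        interpretation=interpret_d(d_av),
    )


def rq2_table(sample) -> list[PairedComparison]:
    """The five paired comparisons over an RQ2-eligible record sample."""
    out = []
    for cat in CATEGORIES:
        mh = [r.mean_mh[cat] for r in sample]
        nonmh = [r.mean_nonmh[cat] for r in sample]
        out.append(paired_comparison(mh, nonmh, variable=cat))
    return out


# ---------------------------------------------------------------------------
# Logistic regression


@dataclass(frozen=True)
class CoefficientEstimate:
    name: str
    beta: float
    se: float

    @property
    def z(self) -> float:
        return self.beta / self.se

    @property
    def p(self) -> float:
        return float(2.0 * sps.norm.sf(abs(self.z)))

    @property
    def ci(self) -> tuple[float, float]:
        return (self.beta - Z_95 * self.se, self.beta + Z_95 * self.se)

    @property
    def odds_ratio(self) -> float:
        return math.exp(self.beta)

    @property
    def or_ci(self) -> tuple[float, float]:
        lo, hi = self.ci
        return (math.exp(lo), math.exp(hi))


@dataclass(frozen=True)
class ModelFit:
    ll: float
    ll_null: float
    k: int
    n: int

    @property
    def aic(self) -> float:
        return 2 * self.k - 2 * self.ll

    @property
    def bic(self) -> float:
        return self.k * math.log(self.n) - 2 * self.ll

    @property
    def df_resid(self) -> int:
        return self.n - self.k

    @property
    def pseudo_r2(self) -> tuple[float, float, float]:
        return pseudo_r2(self.ll_null, self.ll, self.n)


def information_criteria(ll: float, k: int, n: int) -> tuple[float, float]:
    """AIC = 2k − 2ll and BIC = k·ln(n) − 2ll."""
    if k < 0 or n < 1:
        raise ValueError("require k >= 0 and n >= 1")
    return 2 * k - 2 * ll, k * math.log(n) - 2 * ll


def pseudo_r2(ll_null: float, ll: float, n: int) -> tuple[float, float, float]:
    """(Hosmer–Lemeshow, Cox–Snell, Nagelkerke) pseudo-R² triple.

    Hosmer–Lemeshow here is the likelihood-ratio index 1 − ll/ll₀ (the
    McFadden formula, under the name used in applied reporting);
    Cox–Snell = 1 − exp(2(ll₀ − ll)/n); Nagelkerke rescales Cox–Snell by its
    maximum 1 − exp(2·ll₀/n).
    """
    if ll_null == 0:
        raise DegenerateTestError("null log-likelihood of zero is degenerate")
    if ll < ll_null - 1e-8:
        raise ValueError("full-model log-likelihood below null; fits not comparable")
    hl = 1.0 - ll / ll_null
    cs = 1.0 - math.exp(2.0 * (ll_null - ll) / n)
    nk = cs / (1.0 - math.exp(2.0 * ll_null / n))
    return hl, cs, nk


def _bernoulli_ll(y: np.ndarray, p: np.ndarray) -> float:
    eps = 1e-12
    p = np.clip(p, eps, 1 - eps)
    return float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))


def _null_ll(y: np.ndarray) -> float:
    p = float(np.mean(y))
    if p in (0.0, 1.0):
        raise ValueError("outcome has a single class")
    n = y.size
    return n * (p * math.log(p) + (1 - p) * math.log(1 - p))


def _check_rank(M: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(M)
    if rank == M.shape[1]:
        return
    # name a minimal set of columns whose removal restores full rank
    bad = []
    keep: list[int] = []
    for j in range(M.shape[1]):
        trial = keep + [j]
        if np.linalg.matrix_rank(M[:, trial]) < len(trial):
            bad.append(names[j])
        else:
            keep.append(j)
    raise RankDeficientError(f"design matrix is rank deficient; collinear columns: {bad}")


def fit_logistic(
    X,
    y,
    add_intercept: bool = True,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> tuple[list[CoefficientEstimate], ModelFit]:
    """Maximum-likelihood logistic fit by iteratively reweighted least squares.

    ``X`` is a pandas DataFrame (named columns) or 2-D array; an intercept
    column is prepended by default. Convergence when the log-likelihood
    changes by less than ``tol``; standard errors come from the inverse
    observed information at the optimum. The null (intercept-only)
    log-likelihood on the same sample is carried in the returned
    :class:`ModelFit`.
    """
    try:
        names = list(X.columns)
        M = X.to_numpy(dtype=float)
    except AttributeError:
        M = np.asarray(X, dtype=float)
        if M.ndim == 1:
            M = M[:, None]
        names = [f"x{j}" for j in range(M.shape[1])]
    y = np.asarray(y, dtype=float)
    if np.any(np.isnan(M)) or np.any(np.isnan(y)):
        raise ValueError("missing values in design or outcome")
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if add_intercept:
        M = np.hstack([np.ones((M.shape[0], 1)), M])
        names = ["intercept"] + names
    n, k = M.shape
    if len({0.0, 1.0} & set(np.unique(y))) < 2:
        raise ValueError("both outcome classes must be present")
    _check_rank(M, names)

    beta = np.zeros(k)
    ll_prev = -np.inf
    converged = False
    for _ in range(max_iter):
        eta = M @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1.0 - p)
        ll = _bernoulli_ll(y, p)
        if abs(ll - ll_prev) < tol:
            converged = True
            break
        ll_prev = ll
        # a separated likelihood climbs to 0 with diverging coefficients;
        # a single extreme-but-legitimate fitted probability does not
        if np.max(np.abs(beta)) > 1e3 or ll > -1e-3:
            raise SeparationError(
                "perfect separation suspected: likelihood approaching zero / diverging coefficients"
            )
        WM = M * w[:, None]
        info = M.T @ WM
        score = M.T @ (y - p)
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:
            raise SeparationError("information matrix singular during IRLS") from exc
        beta = beta + step
    if not converged:
        raise RuntimeError(f"IRLS did not converge within {max_iter} iterations")

    eta = M @ beta
    p = 1.0 / (1.0 + np.exp(-eta))
    w = p * (1.0 - p)
    info = M.T @ (M * w[:, None])
    cov = np.linalg.inv(info)
    ses = np.sqrt(np.diag(cov))
    ll = _bernoulli_ll(y, p)
    estimates = [
        CoefficientEstimate(name=names[j], beta=float(beta[j]), se=float(ses[j]))
        for j in range(k)
    ]
    fit = ModelFit(ll=ll, ll_null=_null_ll(y), k=k, n=n)
    return estimates, fit


@dataclass(frozen=True)
class LrtResult:
    x2: float
    df: int
    p: float


def likelihood_ratio(nested: ModelFit, full: ModelFit, tol: float = 1e-6) -> LrtResult:
    """χ² likelihood-ratio test of a full fit against a nested fit."""
    if full.n != nested.n:
        raise ValueError("fits compare different samples")
    df = full.k - nested.k
    if df < 1:
        raise ValueError("full model must add at least one parameter")
    x2 = 2.0 * (full.ll - nested.ll)
    if x2 < -tol:
        raise ValueError("full-model likelihood below nested: not nested or not converged")
    x2 = max(0.0, x2)
    return LrtResult(x2=x2, df=df, p=float(sps.chi2.sf(x2, df)))


def relative_probability(
    estimates: Sequence[CoefficientEstimate],
    profile: Mapping[str, float],
    flip: str = "gender",
) -> float:
    """Percent change in predicted probability between ``flip``=0 and 1.

    Evaluates the fitted model at the covariate profile with the flip
    variable at 0 and at 1 and returns (p₀ − p₁)/p₁ × 100 — e.g. how much
    more likely the feminine-coded group is to post in MH communities at
    that profile.
    """
    coef = {e.name: e.beta for e in estimates}

    def prob(flip_value: float) -> float:
        eta = coef.get("intercept", 0.0)
        for name, b in coef.items():
            if name == "intercept":
                continue
            x = flip_value if name == flip else float(profile[name])
            eta += b * x
        return 1.0 / (1.0 + math.exp(-eta))

    p0, p1 = prob(0.0), prob(1.0)
    return (p0 - p1) / p1 * 100.0


def mean_profile(X) -> dict[str, float]:
    """Sample means of all predictors (the default evaluation profile)."""
    return {c: float(X[c].mean()) for c in X.columns}


def gender_balanced_rerun(X, y, rng: np.random.Generator):
    """Refit on outcome groups down-sampled to gender balance.

    Within each outcome group the majority gender is randomly down-sampled
    to the minority count; the model is refitted on the union. Raises if an
    outcome group contains a single gender.
    """
    import pandas as pd

    y = np.asarray(y, dtype=float)
    keep_idx: list[np.ndarray] = []
    for cls in (0.0, 1.0):
        mask = y == cls
        genders = X.loc[mask, "gender"].to_numpy()
        n0 = int(np.sum(genders == 0.0))
        n1 = int(np.sum(genders == 1.0))
        if n0 == 0 or n1 == 0:
            raise ValueError(f"outcome group {int(cls)} contains a single gender")
        m = min(n0, n1)
        idx = np.flatnonzero(mask)
        for g in (0.0, 1.0):
            g_idx = idx[genders == g]
            if g_idx.size > m:
                g_idx = rng.choice(g_idx, size=m, replace=False)
            keep_idx.append(np.sort(g_idx))
    keep = np.sort(np.concatenate(keep_idx))
    Xb = X.iloc[keep]
    yb = y[keep]
    estimates, fit = fit_logistic(Xb, yb)
    return Xb, yb, estimates, fit
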