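"""Selfing Markov models of epiallele inheritance and rate estimation.

Each region carries two epialleles; the diploid epigenotype is the number of
methylated epialleles, k in {0, 1, 2}, observed as U, I, M.  One selfing
generation is modelled as segregation followed by spontaneous epimutation:

* Segregation S: homozygous epigenotypes (k = 0, 2) breed true; a
  heterozygote (k = 1) segregates 1/4 : 1/2 : 1/4.  Under selection the
  segregation output is reweighted — ABmm penalises the unmethylated
  products (weights (1-s, 1-s/2, 1) on k = 0, 1, 2), ABuu the methylated
  ones (weights (1, 1-s/2, 1-s)) — and renormalised.
* Epimutation E: independently per epiallele, an unmethylated allele gains
  methylation with probability alpha and a methylated allele loses it with
  probability beta.

The one-generation transition matrix is T = S(s) . E(alpha, beta); ABneutral
has s = 0 and ABnull is the identity (no accumulation).  Founder regions are
assumed at the stationary distribution pi of T.  The expected divergence of
two descendants at branch lengths t_i, t_j below their common ancestor is

    E[D] = c + sum_a pi_a sum_{x,y} (T^t_i)_{a,x} (T^t_j)_{a,y} w(x, y)

with w the 0 / 0.5 / 1 divergence weights and c an intercept absorbing
measurement noise.  Rates are estimated by bounded non-linear least squares
of this curve against observed pairwise divergences, with multi-start over
log-uniform (alpha, beta) draws and residual-bootstrap standard errors;
competing models are compared by nested F-tests on residual sums of squares.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

MODEL_KINDS = ("ABneutral", "ABmm", "ABuu", "ABnull")

#: Divergence weights w(x, y) on epigenotype pairs.
_W = np.array([[0.0, 0.5, 1.0], [0.5, 0.0, 0.5], [1.0, 0.5, 0.0]])

ALPHA_BOUNDS = (1e-12, 0.1)
S_BOUNDS = (0.0, 0.99)
#: The intercept is allowed marginally below zero during optimisation: with
#: a true intercept near zero, clamping at 0 drags the rate estimates down
#: whenever noise favours a negative intercept.  Reported intercepts may
#: therefore be slightly negative; physically the intercept is noise-driven
#: and non-negative.
C_BOUNDS = (-0.05, 1.0)


def transition_matrix(
    alpha: float, beta: float, s: float = 0.0, kind: str = "ABneutral"
) -> np.ndarray:
    """One-generation 3x3 transition matrix over epigenotypes {0, 1, 2}."""
    if kind not in MODEL_KINDS:
        raise ValueError(f"unknown model kind {kind!r}")
    if not (0 <= alpha <= 1 and 0 <= beta <= 1):
        raise ValueError("alpha and beta must lie in [0, 1]")
    if not (0 <= s < 1):
        raise ValueError("s must lie in [0, 1)")
    if kind == "ABnull":
        return np.eye(3)
    if kind == "ABneutral":
        s = 0.0
    het = np.array([0.25, 0.5, 0.25])
    if kind == "ABmm":
        het = het * np.array([1 - s, 1 - s / 2, 1.0])
    elif kind == "ABuu":
        het = het * np.array([1.0, 1 - s / 2, 1 - s])
    het = het / het.sum()
    S = np.array([[1.0, 0.0, 0.0], het, [0.0, 0.0, 1.0]])
    a, b = alpha, beta
    E = np.array(
        [
            [(1 - a) ** 2, 2 * a * (1 - a), a**2],
            [(1 - a) * b, (1 - a) * (1 - b) + a * b, a * (1 - b)],
            [b**2, 2 * b * (1 - b), (1 - b) ** 2],
        ]
    )
    return S @ E


def equilibrium(T: np.ndarray) -> np.ndarray:
    """Stationary distribution pi with pi . T = pi, sum(pi) = 1.

    Requires an ergodic chain; an absorbing homozygous state (alpha = 0 or
    beta = 0) raises with the offending state named.
    """
    T = np.asarray(T, dtype=float)
    if T[0, 1] + T[0, 2] == 0.0:
        raise ValueError("chain not ergodic: state 0 (UU) is absorbing (alpha = 0)")
    if T[2, 0] + T[2, 1] == 0.0:
        raise ValueError("chain not ergodic: state 2 (MM) is absorbing (beta = 0)")
    vals, vecs = np.linalg.eig(T.T)
    k = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, k])
    pi = pi / pi.sum()
    if (pi < -1e-9).any():
        raise ValueError("no non-negative stationary distribution (non-ergodic chain)")
    return np.clip(pi, 0.0, None) / np.clip(pi, 0.0, None).sum()


def _matrix_powers(T: np.ndarray, ts: list[int]) -> dict[int, np.ndarray]:
    """T^t for each t, sharing intermediate products across the sorted ts."""
    powers: dict[int, np.ndarray] = {}
    cur = np.eye(3)
    t_cur = 0
    for t in sorted(set(int(t) for t in ts)):
        if t < 0:
            raise ValueError("branch lengths must be non-negative")
        for _ in range(t - t_cur):
            cur = cur @ T
        t_cur = t
        powers[t] = cur.copy()
    return powers


def expected_divergence(
    alpha: float,
    beta: float,
    t_i,
    t_j,
    c: float = 0.0,
    s: float = 0.0,
    kind: str = "ABneutral",
    pi: np.ndarray | None = None,
) -> np.ndarray | float:
    """Expected pairwise divergence for branch lengths (t_i, t_j).

    Accepts scalars or arrays of equal length; under ABnull the expectation
    is the intercept alone.
    """
    ti = np.atleast_1d(np.asarray(t_i, dtype=int))
    tj = np.atleast_1d(np.asarray(t_j, dtype=int))
    if (ti < 0).any() or (tj < 0).any():
        raise ValueError("branch lengths must be non-negative")
    if kind == "ABnull":
        out = np.full(ti.shape, float(c))
        return out if out.size > 1 else float(out[0])
    T = transition_matrix(alpha, beta, s, kind)
    if pi is None:
        pi = equilibrium(T)
    powers = _matrix_powers(T, list(ti) + list(tj))
    # many pairs share branch lengths; evaluate each unique combination once
    cache: dict[tuple[int, int], float] = {}
    out = np.empty(ti.shape, dtype=float)
    for n, (a, b) in enumerate(zip(ti, tj)):
        key = (int(a), int(b))
        if key not in cache:
            A = powers[key[0]]
            B = powers[key[1]]
            cache[key] = float(pi @ np.einsum("ax,xy,ay->a", A, _W, B))
        out[n] = c + cache[key]
    return out if out.size > 1 else float(out[0])


@dataclass
class RateFit:
    """Result of fitting one inheritance model to a divergence table."""

    kind: str
    alpha: float
    beta: float
    s: float
    intercept: float
    rss: float
    n_obs: int
    n_params: int
    converged: bool
    pi: np.ndarray | None = None
    se: dict = field(default_factory=dict)
    ci95: dict = field(default_factory=dict)
    ci95_percentile: dict = field(default_factory=dict)
    bootstrap_estimates: pd.DataFrame | None = None

    @property
    def beta_alpha_ratio(self) -> float:
        return self.beta / self.alpha if self.alpha > 0 else float("inf")

    def predict(self, t_i, t_j) -> np.ndarray:
        return np.atleast_1d(
            expected_divergence(
                self.alpha, self.beta, t_i, t_j, self.intercept, self.s, self.kind
            )
        )

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "alpha": self.alpha,
            "beta": self.beta,
            "s": self.s,
            "intercept": self.intercept,
            "rss": self.rss,
            "n_obs": self.n_obs,
            "n_params": self.n_params,
            "converged": self.converged,
            "se": self.se,
            "ci95": self.ci95,
        }


def _n_params(kind: str) -> int:
    return {"ABnull": 1, "ABneutral": 3, "ABmm": 4, "ABuu": 4}[kind]


def _residuals(
    theta: np.ndarray, kind: str, ti, tj, d_obs, p2_obs=None, eq_weight=1.0
) -> np.ndarray:
    if kind == "ABneutral":
        la, lb, c = theta
        s = 0.0
    else:
        la, lb, s, c = theta
    alpha, beta = 10.0**la, 10.0**lb
    T = transition_matrix(alpha, beta, s, kind)
    pi = equilibrium(T)
    pred = expected_divergence(alpha, beta, ti, tj, c, s, kind, pi=pi)
    resid = np.atleast_1d(pred) - d_obs
    if p2_obs is not None:
        # equilibrium anchor: the chain's stationary methylated fraction must
        # reproduce the observed one.  Without it the divergence curve is
        # exactly invariant under swapping alpha and beta (relabelling U and
        # M), and nearly flat along a ridge trading the two rates off.
        resid = np.concatenate([resid, [eq_weight * (pi[2] - p2_obs)]])
    return resid


def _fit_once(theta0: np.ndarray, kind: str, ti, tj, d_obs, p2_obs=None, eq_weight=1.0):
    lo_a, hi_a = np.log10(ALPHA_BOUNDS[0]), np.log10(ALPHA_BOUNDS[1])
    if kind == "ABneutral":
        lo = [lo_a, lo_a, C_BOUNDS[0]]
        hi = [hi_a, hi_a, C_BOUNDS[1]]
    else:
        lo = [lo_a, lo_a, S_BOUNDS[0], C_BOUNDS[0]]
        hi = [hi_a, hi_a, S_BOUNDS[1], C_BOUNDS[1]]
    theta0 = np.clip(theta0, lo, hi)
    return optimize.least_squares(
        _residuals,
        theta0,
        bounds=(lo, hi),
        args=(kind, ti, tj, d_obs, p2_obs, eq_weight),
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
        max_nfev=2000,
    )


def fit_model(
    records: pd.DataFrame,
    kind: str = "ABneutral",
    restarts: int = 20,
    seed: int = 0,
    n_bootstrap: int = 200,
    observed_meth_fraction: float | None = None,
    equilibrium_weight: float = 1.0,
) -> RateFit:
    """Fit one model to a divergence table by multi-start least squares.

    ``records`` needs columns t_i, t_j and divergence (as produced by
    :func:`epirate.divergence.divergence_table`).  Multi-start initial
    (alpha, beta) are drawn log-uniformly; the best-RSS solution is kept.
    Standard errors and 95% intervals come from a residual bootstrap
    (set ``n_bootstrap=0`` to skip).

    ``observed_meth_fraction`` is the observed fraction of M calls over the
    retained regions.  Supplying it adds the equilibrium anchor — the
    stationary methylated fraction of the fitted chain must reproduce the
    observed one — which is what makes alpha and beta separately
    identifiable: the expected divergence curve alone is exactly invariant
    under swapping the two rates.  The reported RSS covers the divergence
    residuals only, so nested model comparisons are unaffected.
    """
    if kind not in MODEL_KINDS:
        raise ValueError(f"unknown model kind {kind!r}")
    ti = records["t_i"].to_numpy(dtype=int)
    tj = records["t_j"].to_numpy(dtype=int)
    d_obs = records["divergence"].to_numpy(dtype=float)
    n = len(d_obs)
    if kind == "ABnull":
        c = float(d_obs.mean())
        rss = float(((d_obs - c) ** 2).sum())
        return RateFit(kind, 0.0, 0.0, 0.0, c, rss, n, 1, True)
    if n < 4 or len(set(zip(ti, tj))) < 2:
        raise ValueError("need >= 4 records with >= 2 distinct divergence times")

    p2 = observed_meth_fraction
    w = equilibrium_weight
    rng = np.random.default_rng(seed)
    best = None
    for k in range(restarts):
        la, lb = rng.uniform(-7, -2, size=2)
        c0 = rng.uniform(0, min(0.2, max(d_obs.min(), 1e-3)))
        theta0 = (
            np.array([la, lb, c0])
            if kind == "ABneutral"
            else np.array([la, lb, rng.uniform(0, 0.5), c0])
        )
        try:
            res = _fit_once(theta0, kind, ti, tj, d_obs, p2, w)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError(f"all {restarts} restarts failed for model {kind}")

    def unpack(theta):
        if kind == "ABneutral":
            la, lb, c = theta
            s = 0.0
        else:
            la, lb, s, c = theta
        return 10.0**la, 10.0**lb, s, c

    alpha, beta, s, c = unpack(best.x)
    pred = d_obs + _residuals(best.x, kind, ti, tj, d_obs)[:n]
    resid = d_obs - pred
    rss = float((resid**2).sum())
    fit = RateFit(
        kind, alpha, beta, s, c, rss, n, _n_params(kind), bool(best.success)
    )
    try:
        fit.pi = equilibrium(transition_matrix(alpha, beta, s, kind))
    except ValueError:
        fit.pi = None

    if n_bootstrap > 0:
        boot = []
        for _ in range(n_bootstrap):
            d_star = pred + rng.choice(resid, size=n, replace=True)
            try:
                res_b = _fit_once(best.x, kind, ti, tj, d_star, p2, w)
            except Exception:
                continue
            boot.append(unpack(res_b.x))
        bdf = pd.DataFrame(boot, columns=["alpha", "beta", "s", "intercept"])
        fit.bootstrap_estimates = bdf
        for col in bdf.columns:
            fit.se[col] = float(bdf[col].std(ddof=1))
            lo, hi = np.percentile(bdf[col], [2.5, 97.5])
            fit.ci95[col] = (float(lo), float(hi))
    return fit


def region_bootstrap(
    fit: RateFit,
    ti: np.ndarray,
    tj: np.ndarray,
    W: np.ndarray,
    m_frac: np.ndarray,
    n_bootstrap: int = 100,
    seed: int = 0,
    equilibrium_weight: float = 1.0,
) -> RateFit:
    """Region-level (case) bootstrap standard errors and 95% intervals.

    Regions are the independent sampling units: the pairwise divergences
    share regions and lineages, so resampling *residuals* across pairs
    ignores most of the estimator's variance.  Here regions are resampled
    with replacement (via multinomial weights), every pairwise divergence
    and the equilibrium anchor are recomputed from the resampled set, and
    the model is refitted from the point estimate.  Updates ``fit.se`` /
    ``fit.ci95`` in place and returns the fit.
    """
    if fit.kind == "ABnull":
        raise ValueError("region bootstrap is defined for accumulation models")
    n = W.shape[0]
    rng = np.random.default_rng(seed)
    if fit.kind == "ABneutral":
        x0 = np.array([np.log10(fit.alpha), np.log10(fit.beta), fit.intercept])
    else:
        x0 = np.array(
            [np.log10(fit.alpha), np.log10(fit.beta), fit.s, fit.intercept]
        )
    boot = []
    for _ in range(n_bootstrap):
        counts = rng.multinomial(n, np.full(n, 1.0 / n))
        d_star = (counts @ W) / n
        p2_star = float(counts @ m_frac) / n
        try:
            res = _fit_once(x0, fit.kind, ti, tj, d_star, p2_star, equilibrium_weight)
        except Exception:
            continue
        if fit.kind == "ABneutral":
            la, lb, c = res.x
            s = 0.0
        else:
            la, lb, s, c = res.x
        boot.append((10.0**la, 10.0**lb, s, c))
    bdf = pd.DataFrame(boot, columns=["alpha", "beta", "s", "intercept"])
    fit.bootstrap_estimates = bdf
    point = {"alpha": fit.alpha, "beta": fit.beta, "s": fit.s, "intercept": fit.intercept}
    for col in bdf.columns:
        fit.se[col] = float(bdf[col].std(ddof=1))
        lo, hi = np.percentile(bdf[col], [2.5, 97.5])
        # basic (reflected) interval: corrects the median bias induced by
        # the intercept's lower bound at zero, which drags percentile
        # intervals below the truth when the true intercept is small
        fit.ci95[col] = (max(0.0, float(2 * point[col] - hi)), float(2 * point[col] - lo))
        fit.ci95_percentile[col] = (float(lo), float(hi))
    return fit


def fit_all_models(
    records: pd.DataFrame,
    restarts: int = 20,
    seed: int = 0,
    n_bootstrap: int = 200,
    kinds: tuple[str, ...] = MODEL_KINDS,
    observed_meth_fraction: float | None = None,
) -> dict[str, RateFit]:
    """Fit every model kind on the same record set."""
    return {
        k: fit_model(
            records,
            k,
            restarts=restarts,
            seed=seed,
            n_bootstrap=n_bootstrap,
            observed_meth_fraction=observed_meth_fraction,
        )
        for k in kinds
    }


def _f_test(small: RateFit, big: RateFit) -> dict:
    if small.n_obs != big.n_obs:
        raise ValueError("nested F-test requires identical record sets")
    dp = big.n_params - small.n_params
    if dp < 1:
        raise ValueError("models must differ by at least one parameter")
    df2 = big.n_obs - big.n_params
    if df2 <= 0 or big.rss <= 0:
        return {"F": float("inf"), "p": 0.0, "df1": dp, "df2": max(df2, 1)}
    F = ((small.rss - big.rss) / dp) / (big.rss / df2)
    F = max(F, 0.0)
    p = float(stats.f.sf(F, dp, df2))
    return {"F": float(F), "p": p, "df1": dp, "df2": df2}


def compare_models(fits: dict[str, RateFit], alpha_level: float = 0.05) -> dict:
    """Nested F-test comparison of the four inheritance models.

    ABnull vs ABneutral asks whether divergence accumulates at all;
    ABneutral vs ABmm / ABuu asks whether selection on a methylation state
    improves the fit.  ABneutral is retained unless a selection model is
    significant; ABnull is chosen when accumulation itself is not.
    """
    for k in MODEL_KINDS:
        if k not in fits:
            raise ValueError(f"missing fit for {k}")
    tests = {
        "ABnull_vs_ABneutral": _f_test(fits["ABnull"], fits["ABneutral"]),
        "ABneutral_vs_ABmm": _f_test(fits["ABneutral"], fits["ABmm"]),
        "ABneutral_vs_ABuu": _f_test(fits["ABneutral"], fits["ABuu"]),
    }
    if tests["ABnull_vs_ABneutral"]["p"] >= alpha_level:
        selected = "ABnull"
    else:
        p_mm = tests["ABneutral_vs_ABmm"]["p"]
        p_uu = tests["ABneutral_vs_ABuu"]["p"]
        if min(p_mm, p_uu) < alpha_level:
            selected = "ABmm" if p_mm <= p_uu else "ABuu"
        else:
            selected = "ABneutral"
    return {"tests": tests, "selected": selected}
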