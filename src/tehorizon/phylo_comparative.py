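"""Phylogenetic signal, comparative model fitting, ancestral TE loads.

All methods operate on a :class:`TraitTree`: an ultrametric timetree plus
one numeric trait value per tip (here, TE load as percent of genome). The
trait is modelled as multivariate normal with mean ``z0 * 1`` and a
covariance determined by the evolutionary model:

* BM (Brownian motion): ``sigma2 * C`` with ``C`` the shared-path-length
  matrix;
* lambda (Pagel): off-diagonals of ``C`` scaled by ``lambda``;
* OU (Ornstein–Uhlenbeck, single optimum, ultrametric tree):
  ``V_ij = sigma2/(2 alpha) * exp(-2 alpha d_ij) * (1 - exp(-2 alpha t_ij))``
  with ``t_ij`` the shared time and ``d_ij`` the time since the MRCA;
* EB (Early Burst): the rate decays as ``sigma2 * exp(a s)`` along time
  ``s`` from the root (``a <= 0``), giving
  ``V_ij = sigma2 * (exp(a t_ij) - 1)/a``;
* WN (white noise): ``sigma2 * I``.

``sigma2`` and ``z0`` are always profiled analytically (GLS); only the
one shape parameter (lambda, alpha or a) is optimised numerically, with a
fixed multi-start for determinism. Model selection uses AICc.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import optimize, stats

from .timetree import TimeTree

__all__ = [
    "TraitTree", "SignalResult", "ModelFit", "AncestralStates",
    "CorrelationResult", "pearson_correlation", "pagel_lambda",
    "blomberg_k", "fit_continuous", "ancestral_ml", "MODELS",
]

MODELS = ("BM", "OU", "EB", "WN")

_EPS = 1e-10


class TraitTree:
    """Species timetree plus a per-tip numeric trait.

    Trait keys must coincide with the tree's tip labels. The trait vector
    and phylogenetic covariance are exposed in the tree's tip order.
    """

    def __init__(self, tree: TimeTree, trait: Mapping[str, float]):
        if set(trait) != set(tree.taxa):
            missing = set(tree.taxa) ^ set(trait)
            raise ValueError(f"trait keys do not match tips: {sorted(missing)}")
        self.tree = tree
        self.trait = {t: float(trait[t]) for t in tree.taxa}
        self.z = np.array([self.trait[t] for t in tree.taxa])
        self.C = tree.vcv()

    @property
    def n(self) -> int:
        return self.tree.n_tips


@dataclass(frozen=True)
class SignalResult:
    statistic: str             # "lambda" | "K"
    estimate: float
    log_likelihood: float | None = None
    log_likelihood_null: float | None = None
    p_value: float | None = None
    n_permutations: int | None = None
    degenerate: bool = False


@dataclass(frozen=True)
class ModelFit:
    model: str
    parameters: dict
    log_likelihood: float
    k_params: int
    aicc: float
    n: int


@dataclass(frozen=True)
class AncestralStates:
    """ML states at internal nodes plus per-branch direction calls."""

    states: dict[str, float]                 # node id -> value
    clades: dict[str, tuple[str, ...]]       # node id -> tip labels
    directions: list[tuple[str, str, str]]   # (parent, child, direction)


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_value: float
    n: int


def pearson_correlation(x, y) -> CorrelationResult:
    """Product-moment correlation with the two-sided t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("x and y must be equal-length 1-d arrays, n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite input")
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(r=float(r), p_value=float(p), n=len(x))


# ----------------------------------------------------------------------
# MVN likelihood machinery
# ----------------------------------------------------------------------

def _profiled_loglik(z: np.ndarray, V0: np.ndarray
                     ) -> tuple[float, float, float]:
    """ML log-likelihood with mean z0*1 and covariance sigma2*V0, both
    profiled analytically. Returns (logL, sigma2_hat, z0_hat)."""
    n = len(z)
    try:
        L = np.linalg.cholesky(V0)
    except np.linalg.LinAlgError:
        # singular covariance (e.g. lambda at its upper bound): a very
        # low but finite likelihood keeps bounded optimisers stable
        return -1e10, math.nan, math.nan
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    ones = np.ones(n)
    zi = np.linalg.solve(L, z)
    oi = np.linalg.solve(L, ones)
    z0 = float(oi @ zi) / float(oi @ oi)
    ri = zi - z0 * oi
    sigma2 = float(ri @ ri) / n
    if sigma2 <= 0:
        sigma2 = _EPS
    logL = -0.5 * (n * math.log(2 * math.pi) + n * math.log(sigma2)
                   + logdet + n)
    return logL, sigma2, z0


def _multistart_minimize(f, lo: float, hi: float, n_starts: int = 5,
                         tol: float = 1e-8):
    """Deterministic multi-start bounded 1-d minimisation."""
    best = None
    starts = np.linspace(lo, hi, n_starts + 2)[1:-1]
    for x0 in starts:
        res = optimize.minimize(f, x0=[x0], bounds=[(lo, hi)],
                                method="L-BFGS-B",
                                options={"ftol": tol, "gtol": 1e-10})
        if not res.success and not math.isfinite(res.fun):
            raise RuntimeError(f"optimizer failed: {res.message}")
        if best is None or res.fun < best.fun:
            best = res
    # also probe the bounds themselves
    for xb in (lo, hi):
        fb = f([xb])
        if fb < best.fun:
            class _R:
                pass
            r = _R()
            r.x, r.fun = np.array([xb]), fb
            best = r
    return float(best.x[0]), float(best.fun)


# ----------------------------------------------------------------------
# Pagel's lambda
# ----------------------------------------------------------------------

def _lambda_cov(C: np.ndarray, lam: float) -> np.ndarray:
    V = lam * C
    np.fill_diagonal(V, np.diag(C))
    return V


def pagel_lambda(tt: TraitTree) -> SignalResult:
    """ML estimate of Pagel's lambda with a likelihood-ratio p-value.

    lambda scales the off-diagonal (shared-history) covariances; the
    search is bounded above by ``lambda_max = height / deepest internal
    node depth``, the largest value keeping the transformed matrix a
    valid tree covariance, so the estimate may exceed 1.
    """
    if tt.n < 4:
        raise ValueError("need >= 4 tips")
    C = tt.C
    off = C[~np.eye(tt.n, dtype=bool)]
    max_off = off.max() if off.size else 0.0
    if max_off <= _EPS * tt.tree.height:
        # star tree: lambda has no effect on the likelihood
        logL, _, _ = _profiled_loglik(tt.z, np.diag(np.diag(C)))
        return SignalResult(statistic="lambda", estimate=0.0,
                            log_likelihood=logL, log_likelihood_null=logL,
                            p_value=1.0, degenerate=True)
    lam_max = tt.tree.height / max_off

    def nll(x):
        return -_profiled_loglik(tt.z, _lambda_cov(C, float(x[0])))[0]

    lam_hat, nll_hat = _multistart_minimize(nll, 0.0, lam_max)
    logL = -nll_hat
    logL0 = _profiled_loglik(tt.z, np.diag(np.diag(C)))[0]
    lr = max(0.0, 2.0 * (logL - logL0))
    p = float(stats.chi2.sf(lr, df=1))
    return SignalResult(statistic="lambda", estimate=lam_hat,
                        log_likelihood=logL, log_likelihood_null=logL0,
                        p_value=p)


# ----------------------------------------------------------------------
# Blomberg's K
# ----------------------------------------------------------------------

def _k_ratio(z: np.ndarray, Cinv: np.ndarray, ones: np.ndarray) -> float:
    denom = float(ones @ Cinv @ ones)
    abar = float(ones @ Cinv @ z) / denom
    r = z - abar
    mse0 = float(r @ r)
    mse = float(r @ Cinv @ r)
    return mse0 / mse


def blomberg_k(tt: TraitTree, n_perm: int = 1000,
               seed: int | None = None) -> SignalResult:
    """Blomberg's K with an optional tip-permutation significance test.

    K is the observed MSE0/MSE ratio (phylogenetically corrected mean)
    relative to its Brownian-motion expectation
    ``[tr(C) - n / (1' C^-1 1)] / (n - 1)``; K ≈ 1 under BM. The p-value
    is the fraction of tip permutations with a ratio at least as large as
    observed (observed permutation included).
    """
    if tt.n < 4:
        raise ValueError("need >= 4 tips")
    n = tt.n
    C = tt.C
    Cinv = np.linalg.inv(C)
    ones = np.ones(n)
    obs_ratio = _k_ratio(tt.z, Cinv, ones)
    expected = (np.trace(C) - n / float(ones @ Cinv @ ones)) / (n - 1)
    K = obs_ratio / expected
    if n_perm <= 0:
        return SignalResult(statistic="K", estimate=K, n_permutations=0)
    rng = np.random.default_rng(seed)
    hits = 1  # count the observed ordering
    for _ in range(n_perm):
        zp = rng.permutation(tt.z)
        if _k_ratio(zp, Cinv, ones) >= obs_ratio:
            hits += 1
    p = hits / (n_perm + 1)
    return SignalResult(statistic="K", estimate=K, p_value=p,
                        n_permutations=n_perm)


# ----------------------------------------------------------------------
# Model fitting (BM / OU / EB / WN) and AICc
# ----------------------------------------------------------------------

def _aicc(logL: float, k: int, n: int) -> float:
    if n - k - 1 <= 0:
        return math.nan   # small-sample correction undefined
    return -2.0 * logL + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def eb_cov(C: np.ndarray, a: float) -> np.ndarray:
    """Early-Burst covariance: integral of the decaying rate over shared
    time, ``(exp(a t) - 1)/a`` elementwise (BM in the a -> 0 limit)."""
    if abs(a) < 1e-12:
        return C.copy()
    return (np.exp(a * C) - 1.0) / a


def _ou_cov(C: np.ndarray, alpha: float) -> np.ndarray:
    T = np.diag(C)
    H = 0.5 * (T[:, None] + T[None, :])   # ultrametric: tip depth
    d = H - C                              # time since MRCA
    return np.exp(-2.0 * alpha * d) * (1.0 - np.exp(-2.0 * alpha * C)) \
        / (2.0 * alpha)


def fit_continuous(tt: TraitTree, model: str) -> ModelFit:
    """ML fit of one comparative model; returns parameters, logL, AICc.

    BM and WN have closed-form profiles (k = 2 parameters); OU and EB add
    one numerically optimised shape parameter (k = 3).
    """
    if model not in MODELS:
        raise ValueError(f"model must be one of {MODELS}")
    z, C, n = tt.z, tt.C, tt.n
    height = tt.tree.height

    if model == "BM":
        logL, s2, z0 = _profiled_loglik(z, C)
        params = {"sigma2": s2, "z0": z0}
        k = 2
    elif model == "WN":
        logL, s2, z0 = _profiled_loglik(z, np.eye(n))
        params = {"sigma2": s2, "z0": z0}
        k = 2
    elif model == "EB":
        lo, hi = -10.0 / height, -1e-8

        def nll(x):
            return -_profiled_loglik(z, eb_cov(C, float(x[0])))[0]

        a_hat, nll_hat = _multistart_minimize(nll, lo, hi)
        logL = -nll_hat
        _, s2, z0 = _profiled_loglik(z, eb_cov(C, a_hat))
        params = {"sigma2": s2, "z0": z0, "a": a_hat}
        k = 3
    else:  # OU
        lo, hi = 1e-8 / height, 50.0 / height

        def nll(x):
            return -_profiled_loglik(z, _ou_cov(C, float(x[0])))[0]

        alpha_hat, nll_hat = _multistart_minimize(nll, lo, hi)
        logL = -nll_hat
        _, s2raw, z0 = _profiled_loglik(z, _ou_cov(C, alpha_hat))
        params = {"sigma2": s2raw, "z0": z0, "alpha": alpha_hat}
        k = 3

    return ModelFit(model=model, parameters=params, log_likelihood=logL,
                    k_params=k, aicc=_aicc(logL, k, n), n=n)


# ----------------------------------------------------------------------
# Ancestral states
# ----------------------------------------------------------------------

def ancestral_ml(tt: TraitTree, model_fit: ModelFit,
                 tol: float = 1e-12) -> AncestralStates:
    """ML (GLS) ancestral states under BM on the (EB-rescaled) tree.

    For an EB fit the shared-time matrices are first transformed by the
    fitted exponent; the ancestral state at each internal node is then the
    BM conditional mean given the tips, with the root state at its GLS
    estimate. Branch directions compare child to parent state
    ("expansion", "reduction", or "no_change" at equality within *tol*
    relative to the trait range).
    """
    if model_fit.model not in ("BM", "EB"):
        raise ValueError("ancestral reconstruction supports BM or EB fits")
    a = model_fit.parameters.get("a", 0.0)
    C = eb_cov(tt.C, a)
    node_ids, M = tt.tree.node_tip_shared_depths()
    Mt = eb_cov(M, a) if abs(a) >= 1e-12 else M

    n = tt.n
    ones = np.ones(n)
    Cinv = np.linalg.inv(C)
    z0 = float(ones @ Cinv @ tt.z) / float(ones @ Cinv @ ones)
    cond = z0 + Mt @ Cinv @ (tt.z - z0 * ones)

    states = {nid: float(v) for nid, v in zip(node_ids, cond)}
    clades = {nid: tips for nid, tips, _age in tt.tree.internal_nodes()}

    value = dict(states)
    value.update(tt.trait)
    span = max(1.0, float(np.ptp(tt.z)))
    directions = []
    for parent, child in tt.tree.edges():
        delta = value[child] - value[parent]
        if abs(delta) <= tol * span:
            direction = "no_change"
        elif delta > 0:
            direction = "expansion"
        else:
            direction = "reduction"
        directions.append((parent, child, direction))
    return AncestralStates(states=states, clades=clades,
                           directions=directions)
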