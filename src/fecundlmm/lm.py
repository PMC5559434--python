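"""Two-state latent Markov model with covariates in the measurement model.

The latent chain U(1..T) is a homogeneous first-order Markov chain on
{1, 2} (state 2 = conception-prone); the observed conception indicator
Y(t) given U(t) = u and covariates x is Bernoulli with

    logit P(Y = 1 | u, x) = mu + alpha_u + x'beta,   alpha_1 = 0.

Estimation is by the EM algorithm with scaled forward-backward recursions,
a full Newton M-step for the measurement logit, deterministic plus random
multi-start initialization, observed-information standard errors, and
local (marginal-posterior) decoding.  Unequal sequence lengths are handled
by evaluating each couple's likelihood over its own T_i; drop-out is
treated as ignorable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LMParameters",
    "PanelData",
    "PosteriorSet",
    "FitResult",
    "emission_probability",
    "forward_backward",
    "complete_data_loglik",
    "e_step",
    "m_step",
    "fit_em",
    "standard_errors",
    "decode_states",
]

_EPS = 1e-300
_PCLIP = 1e-12


@dataclass
class LMParameters:
    """Parameters of the two-state model.

    ``pi`` are the initial state probabilities, ``Pi`` the transition
    matrix (rows = state at t-1), ``mu`` the measurement cut-point,
    ``alpha2`` the state-2 support point (alpha1 = 0 by the
    identifiability constraint; alpha2 >= 0 labels state 2 as the
    conception-prone state), and ``beta`` the covariate coefficients.
    """

    pi: np.ndarray
    Pi: np.ndarray
    mu: float
    alpha2: float
    beta: np.ndarray
    covariate_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        self.Pi = np.asarray(self.Pi, dtype=float)
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))

    def validate(self, tol: float = 1e-6) -> None:
        if self.pi.shape != (2,) or self.Pi.shape != (2, 2):
            raise ValueError("pi must be (2,) and Pi must be (2,2)")
        if np.any(self.pi < -tol) or abs(self.pi.sum() - 1.0) > tol:
            raise ValueError("pi must be a probability vector")
        if np.any(self.Pi < -tol) or np.any(np.abs(self.Pi.sum(axis=1) - 1.0) > tol):
            raise ValueError("transition rows must sum to 1")

    def alpha(self, u: int) -> float:
        """Support point of state ``u`` (1-based)."""
        return 0.0 if u == 1 else self.alpha2

    def relabeled(self) -> "LMParameters":
        """Swap state labels so that alpha2 >= 0 (state 2 conception-prone)."""
        if self.alpha2 >= 0:
            return self
        return LMParameters(
            pi=self.pi[::-1].copy(),
            Pi=self.Pi[::-1, ::-1].copy(),
            mu=self.mu + self.alpha2,
            alpha2=-self.alpha2,
            beta=self.beta.copy(),
            covariate_names=self.covariate_names,
        )

    def to_dict(self) -> dict:
        return {
            "pi": self.pi.tolist(),
            "Pi": self.Pi.tolist(),
            "mu": float(self.mu),
            "alpha2": float(self.alpha2),
            "beta": self.beta.tolist(),
            "covariate_names": self.covariate_names,
        }


@dataclass
class PanelData:
    """Stacked panel of conception sequences and couple covariates.

    ``X`` is (n, p) for time-fixed covariates or (n, T_max, p) for
    time-varying ones; ``Y`` is (n, T_max) float with NaN padding beyond
    each couple's ``lengths``.
    """

    X: np.ndarray
    Y: np.ndarray
    lengths: np.ndarray
    covariate_names: list[str] | None = None
    couple_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.Y = np.asarray(self.Y, dtype=float)
        self.lengths = np.asarray(self.lengths, dtype=int)
        if self.Y.ndim != 2:
            raise ValueError("Y must be (n, T_max)")
        if np.any(self.lengths < 1) or np.any(self.lengths > self.Y.shape[1]):
            raise ValueError("lengths must be in 1..T_max")

    @property
    def n(self) -> int:
        return int(self.Y.shape[0])

    @property
    def T_max(self) -> int:
        return int(self.Y.shape[1])

    @property
    def p(self) -> int:
        return int(self.X.shape[-1])

    def time_varying(self) -> bool:
        return self.X.ndim == 3

    def xmat(self, t: int) -> np.ndarray:
        """Covariate matrix at occasion t (0-based), shape (n, p)."""
        return self.X[:, t, :] if self.time_varying() else self.X

    def mask(self) -> np.ndarray:
        """(n, T_max) bool, True where an observation exists."""
        return np.arange(self.T_max)[None, :] < self.lengths[:, None]

    def truncated(self, T: int) -> "PanelData":
        """Panel restricted to the first ``T`` fertile windows."""
        T = int(min(T, self.T_max))
        X = self.X[:, :T, :] if self.time_varying() else self.X
        return PanelData(X=X, Y=self.Y[:, :T].copy(),
                         lengths=np.minimum(self.lengths, T),
                         covariate_names=self.covariate_names,
                         couple_ids=self.couple_ids)

    @classmethod
    def from_simulated(cls, panel) -> "PanelData":
        """Build from a :class:`~fecundlmm.simulate.SimulatedPanel`."""
        Y = np.where(panel.y < 0, np.nan, panel.y).astype(float)
        return cls(X=panel.X, Y=Y, lengths=panel.lengths,
                   covariate_names=panel.covariate_names,
                   couple_ids=panel.couple_ids)

    @classmethod
    def from_frames(cls, panel_df: pd.DataFrame, covariates: pd.DataFrame,
                    covariate_names: Sequence[str]) -> "PanelData":
        """Assemble from tidy ``panel.csv`` / ``covariates.csv`` frames.

        Couples present in both tables are kept; window indices are
        renumbered consecutively per couple in their original order.
        """
        ids = [c for c in covariates["couple_id"] if c in set(panel_df["couple_id"])]
        cov = covariates.set_index("couple_id").loc[ids]
        X = cov.loc[:, list(covariate_names)].to_numpy(dtype=float)
        grouped = panel_df.sort_values(["couple_id", "window_index"]) \
                          .groupby("couple_id")["y"].apply(list).to_dict()
        seqs = [grouped[c] for c in ids]
        T_max = max(len(s) for s in seqs)
        Y = np.full((len(ids), T_max), np.nan)
        lengths = np.zeros(len(ids), dtype=int)
        for i, s in enumerate(seqs):
            Y[i, : len(s)] = s
            lengths[i] = len(s)
        return cls(X=X, Y=Y, lengths=lengths,
                   covariate_names=list(covariate_names),
                   couple_ids=np.asarray(ids, dtype=object))


@dataclass
class PosteriorSet:
    """Forward-backward output: state posteriors gamma (n, T, 2), joint
    transition posteriors xi (n, T-1, 2, 2) and the incomplete-data
    log-likelihood (with per-couple contributions)."""

    gamma: np.ndarray
    xi: np.ndarray
    loglik: float
    loglik_i: np.ndarray


@dataclass
class FitResult:
    params: LMParameters
    loglik: float
    loglik_trace: np.ndarray
    start_logliks: list[float]
    n_starts: int
    converged: bool
    n_iter: int
    seed: int | None
    standard_errors: dict | None = None
    degenerate: bool = False
    start_traces: list | None = None

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "loglik": float(self.loglik),
            "loglik_trace": np.asarray(self.loglik_trace).tolist(),
            "start_logliks": [float(v) for v in self.start_logliks],
            "n_starts": self.n_starts,
            "converged": bool(self.converged),
            "n_iter": int(self.n_iter),
            "seed": self.seed,
            "standard_errors": self.standard_errors,
            "degenerate": bool(self.degenerate),
        }


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def emission_probability(x: np.ndarray, u: int, params: LMParameters) -> np.ndarray:
    """P(Y = 1 | U = u, x): the generalized-logit success probability."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[-1] != params.beta.size:
        raise ValueError("covariate dimension does not match beta")
    z = params.mu + params.alpha(u) + x @ params.beta
    out = _sigmoid(z)
    return out[0] if out.size == 1 else out


def _emission_matrix(panel: PanelData, params: LMParameters) -> np.ndarray:
    """B[i, t, u] = P(y_it | U = u+1, x_it); 1.0 beyond each couple's T_i."""
    n, T = panel.n, panel.T_max
    B = np.ones((n, T, 2))
    mask = panel.mask()
    alphas = np.array([0.0, params.alpha2])
    if panel.time_varying():
        for t in range(T):
            xb = panel.xmat(t) @ params.beta
            p1 = _sigmoid(params.mu + alphas[None, :] + xb[:, None])
            y = panel.Y[:, t]
            obs = mask[:, t]
            B[obs, t, :] = np.where(y[obs, None] == 1.0, p1[obs], 1.0 - p1[obs])
    else:
        xb = panel.X @ params.beta
        p1 = _sigmoid(params.mu + alphas[None, :] + xb[:, None])  # (n, 2)
        for t in range(T):
            y = panel.Y[:, t]
            obs = mask[:, t]
            B[obs, t, :] = np.where(y[obs, None] == 1.0, p1[obs], 1.0 - p1[obs])
    return np.clip(B, _PCLIP, 1.0)


def forward_backward(panel: PanelData, params: LMParameters) -> PosteriorSet:
    """Scaled forward-backward recursions for unequal-length panels.

    Returns exact smoothed posteriors gamma, joint posteriors xi, and the
    incomplete-data log-likelihood.  A couple whose sequence has zero
    probability contributes -inf to the log-likelihood instead of raising.
    """
    params.validate()
    n, T = panel.n, panel.T_max
    B = _emission_matrix(panel, params)
    mask = panel.mask()

    a = np.zeros((n, T, 2))  # scaled forward
    c = np.ones((n, T))  # scaling constants
    f = params.pi[None, :] * B[:, 0, :]
    c[:, 0] = f.sum(axis=1)
    a[:, 0, :] = f / np.maximum(c[:, 0], _EPS)[:, None]
    for t in range(1, T):
        f = (a[:, t - 1, :] @ params.Pi) * B[:, t, :]
        ct = f.sum(axis=1)
        obs = mask[:, t]
        c[obs, t] = ct[obs]
        with np.errstate(invalid="ignore"):
            a[:, t, :] = np.where(obs[:, None],
                                  f / np.maximum(ct, _EPS)[:, None],
                                  a[:, t - 1, :])

    b = np.zeros((n, T, 2))
    b[:, T - 1, :] = 1.0
    for t in range(T - 2, -1, -1):
        nxt = B[:, t + 1, :] * b[:, t + 1, :]
        obs_next = mask[:, t + 1]
        bt = (nxt @ params.Pi.T) / np.maximum(c[:, t + 1], _EPS)[:, None]
        b[:, t, :] = np.where(obs_next[:, None], bt, 1.0)

    gamma = a * b
    gamma_sum = gamma.sum(axis=2, keepdims=True)
    gamma = gamma / np.maximum(gamma_sum, _EPS)

    xi = np.zeros((n, max(T - 1, 0), 2, 2))
    for t in range(T - 1):
        obs_next = mask[:, t + 1]
        num = (a[:, t, :, None] * params.Pi[None, :, :]
               * (B[:, t + 1, None, :] * b[:, t + 1, None, :]))
        num = num / np.maximum(c[:, t + 1], _EPS)[:, None, None]
        xi[:, t, :, :] = np.where(obs_next[:, None, None], num, 0.0)

    with np.errstate(divide="ignore"):
        logc = np.where(mask, np.log(np.maximum(c, 0.0)), 0.0)
    loglik_i = logc.sum(axis=1)
    loglik_i = np.where(np.any(mask & (c <= 0.0), axis=1), -np.inf, loglik_i)
    return PosteriorSet(gamma=gamma, xi=xi,
                        loglik=float(loglik_i.sum()), loglik_i=loglik_i)


def complete_data_loglik(panel: PanelData, states: np.ndarray,
                         params: LMParameters) -> float:
    """Log-likelihood of (y, u) jointly: measurement terms plus log-initial
    and log-transition terms.  ``states`` is (n, T_max) with values 1/2
    (padding beyond T_i ignored)."""
    params.validate()
    states = np.asarray(states, dtype=int)
    mask = panel.mask()
    B = _emission_matrix(panel, params)
    n = panel.n
    s0 = states[:, 0] - 1
    with np.errstate(divide="ignore"):
        total = np.log(np.maximum(params.pi[s0], 0.0)).sum()
        idx = np.arange(n)
        total += np.log(B[idx, 0, s0]).sum()
        for t in range(1, panel.T_max):
            obs = mask[:, t]
            st, sp = states[:, t] - 1, states[:, t - 1] - 1
            total += np.log(np.maximum(params.Pi[sp[obs], st[obs]], 0.0)).sum()
            total += np.log(B[idx[obs], t, st[obs]]).sum()
    return float(total)


def e_step(panel: PanelData, params: LMParameters) -> PosteriorSet:
    """E-step: expected indicator frequencies given current parameters.

    The smoothed posteriors gamma are the expectations of the per-occasion
    state indicators (and, paired with (y, x), of the measurement counts);
    xi are the expected transition indicators.
    """
    return forward_backward(panel, params)


def _measurement_design(panel: PanelData):
    """Design matrix rows for the weighted-logit M-step.

    One row per (observation, state): columns [1, 1{u=2}, x]; cached on
    the panel instance since it never changes across EM iterations.
    """
    cached = getattr(panel, "_mdesign", None)
    if cached is not None:
        return cached
    mask = panel.mask()
    ii, tt = np.nonzero(mask)
    y = panel.Y[ii, tt]
    if panel.time_varying():
        x = panel.X[ii, tt, :]
    else:
        x = panel.X[ii, :]
    m = ii.size
    Z = np.empty((2 * m, 2 + panel.p))
    Z[:, 0] = 1.0
    Z[:m, 1] = 0.0
    Z[m:, 1] = 1.0
    Z[:m, 2:] = x
    Z[m:, 2:] = x
    yy = np.concatenate([y, y])
    panel._mdesign = (Z, yy, ii, tt, m)
    return panel._mdesign


def _weighted_logit(Z: np.ndarray, y: np.ndarray, w: np.ndarray,
                    theta0: np.ndarray, free: np.ndarray,
                    tol: float = 1e-10, max_iter: int = 100) -> np.ndarray:
    """Newton-Raphson for the weighted Bernoulli log-likelihood.

    ``free`` masks the coefficients being updated (fixed ones keep their
    ``theta0`` value).  Runs to its own tolerance: a full M-step.
    """
    theta = theta0.copy()
    Zf = Z[:, free]
    for _ in range(max_iter):
        p = _sigmoid(Z @ theta)
        g = Zf.T @ (w * (y - p))
        if np.max(np.abs(g)) < tol:
            break
        wpq = w * p * (1.0 - p)
        H = (Zf * wpq[:, None]).T @ Zf
        H[np.diag_indices_from(H)] += 1e-10
        step = np.linalg.solve(H, g)
        # step-halving guard (the problem is concave; rarely triggers)
        ll0 = np.sum(w * (y * np.log(np.clip(p, _PCLIP, 1)) +
                          (1 - y) * np.log(np.clip(1 - p, _PCLIP, 1))))
        scale = 1.0
        for _ in range(30):
            trial = theta.copy()
            trial[free] = theta[free] + scale * step
            pt = _sigmoid(Z @ trial)
            ll = np.sum(w * (y * np.log(np.clip(pt, _PCLIP, 1)) +
                             (1 - y) * np.log(np.clip(1 - pt, _PCLIP, 1))))
            if ll >= ll0 - 1e-12:
                theta = trial
                break
            scale *= 0.5
        else:
            break
    return theta


def m_step(post: PosteriorSet, panel: PanelData, current: LMParameters,
           fix_alpha2: float | None = None) -> LMParameters:
    """M-step: closed-form updates for pi and the transition matrix,
    Newton-to-convergence weighted logistic regression (with a state-2
    indicator column) for (mu, alpha2, beta)."""
    n = panel.n
    pi = post.gamma[:, 0, :].sum(axis=0) / n
    pi = np.clip(pi, 0.0, 1.0)
    pi = pi / pi.sum()

    trans = post.xi.sum(axis=(0, 1))  # (2, 2)
    row = trans.sum(axis=1, keepdims=True)
    Pi = np.where(row > 0, trans / np.maximum(row, _EPS), current.Pi)

    Z, yy, ii, tt, m = _measurement_design(panel)
    w = np.concatenate([post.gamma[ii, tt, 0], post.gamma[ii, tt, 1]])
    degenerate = bool(min(post.gamma[ii, tt, 0].sum(),
                          post.gamma[ii, tt, 1].sum()) < 1e-8)

    theta0 = np.concatenate([[current.mu, current.alpha2], current.beta])
    free = np.ones(theta0.size, dtype=bool)
    if fix_alpha2 is not None:
        theta0[1] = fix_alpha2
        free[1] = False
    theta = _weighted_logit(Z, yy, w, theta0, free)

    out = LMParameters(pi=pi, Pi=Pi, mu=float(theta[0]),
                       alpha2=float(theta[1]), beta=theta[2:].copy(),
                       covariate_names=current.covariate_names)
    out._degenerate = degenerate
    return out


def _pooled_logit(panel: PanelData) -> tuple[float, np.ndarray]:
    """Ordinary pooled logistic fit ignoring the latent states."""
    Z, yy, ii, tt, m = _measurement_design(panel)
    # use only the state-1 copy of each row, no state column
    Zp = np.delete(Z[:m], 1, axis=1)
    theta = _weighted_logit(Zp, yy[:m], np.ones(m),
                            np.zeros(Zp.shape[1]),
                            np.ones(Zp.shape[1], dtype=bool))
    return float(theta[0]), theta[1:].copy()


def _standardize(panel: PanelData):
    """Internally standardized copy of the panel (for optimization)."""
    if panel.time_varying():
        mask = panel.mask()
        flat = panel.X[mask]
    else:
        flat = panel.X
    mean = flat.mean(axis=0)
    sd = flat.std(axis=0)
    sd = np.where(sd < 1e-12, 1.0, sd)
    Xs = (panel.X - mean) / sd
    ps = PanelData(X=Xs, Y=panel.Y, lengths=panel.lengths,
                   covariate_names=panel.covariate_names,
                   couple_ids=panel.couple_ids)
    return ps, mean, sd


def _destandardize(params: LMParameters, mean: np.ndarray,
                   sd: np.ndarray) -> LMParameters:
    beta = params.beta / sd
    mu = params.mu - float(np.sum(params.beta * mean / sd))
    return replace(params, mu=mu, beta=beta)


def _em_run(panel: PanelData, start: LMParameters, tol: float, max_iter: int,
            fix_alpha2: float | None):
    """One EM run; returns (params, trace, converged, degenerate)."""
    params = start
    trace = []
    degenerate = False
    post = e_step(panel, params)
    trace.append(post.loglik)
    converged = False
    for it in range(max_iter):
        params = m_step(post, panel, params, fix_alpha2=fix_alpha2)
        degenerate = degenerate or getattr(params, "_degenerate", False)
        post = e_step(panel, params)
        trace.append(post.loglik)
        prev, cur = trace[-2], trace[-1]
        if np.isfinite(cur) and abs(cur - prev) < tol * (abs(cur) + 1e-10):
            converged = True
            break
    return params, np.asarray(trace), converged, degenerate


def _random_start(det: LMParameters, rng: np.random.Generator) -> LMParameters:
    """Multiplicative perturbation of the deterministic start."""
    pi = det.pi * rng.uniform(0.2, 1.8, size=2)
    pi = pi / pi.sum()
    Pi = det.Pi * rng.uniform(0.2, 1.8, size=(2, 2))
    Pi = Pi / Pi.sum(axis=1, keepdims=True)
    mu = det.mu * rng.uniform(0.5, 1.5) + rng.normal(0.0, 0.2)
    alpha2 = abs(det.alpha2) * rng.uniform(0.25, 2.5)
    beta = det.beta * rng.uniform(0.5, 1.5, size=det.beta.size) \
        + rng.normal(0.0, 0.1, size=det.beta.size)
    return LMParameters(pi=pi, Pi=Pi, mu=mu, alpha2=alpha2, beta=beta,
                        covariate_names=det.covariate_names)


def fit_em(panel: PanelData, n_random_starts: int = 20,
           seed: int | None = None, tol: float = 1e-8, max_iter: int = 5000,
           fix_alpha2: float | None = None, screen_iter: int = 100,
           compute_se: bool = False) -> FitResult:
    """Maximum-likelihood fit by multi-start EM.

    One deterministic start (uniform pi, 0.8/0.2 diagonal-heavy
    transitions, measurement initialized from a pooled logistic fit with
    alpha2 = +1) plus ``n_random_starts`` multiplicative perturbations.
    Every start runs up to ``screen_iter`` EM iterations; the best by
    log-likelihood is then polished to the full tolerance (relative
    log-likelihood change below ``tol``).  States are relabeled at the end
    so alpha2 >= 0 (state 2 = conception-prone).
    """
    if panel.n == 0:
        raise ValueError("panel must be non-empty")
    ps, mean, sd = _standardize(panel)
    mu0, beta0 = _pooled_logit(ps)
    det = LMParameters(pi=np.array([0.5, 0.5]),
                       Pi=np.array([[0.8, 0.2], [0.2, 0.8]]),
                       mu=mu0, alpha2=1.0 if fix_alpha2 is None else fix_alpha2,
                       beta=beta0, covariate_names=panel.covariate_names)
    rng = np.random.default_rng(seed)
    starts = [det] + [_random_start(det, rng) for _ in range(n_random_starts)]

    screened = []
    for s in starts:
        res = _em_run(ps, s, tol=tol, max_iter=screen_iter,
                      fix_alpha2=fix_alpha2)
        screened.append(res)
    start_logliks = [float(r[1][-1]) for r in screened]
    best_idx = int(np.argmax(start_logliks))
    params, trace0, conv0, degen0 = screened[best_idx]
    if conv0:
        params_f, trace, converged, degen = params, trace0, True, degen0
    else:
        params_f, trace1, converged, degen1 = _em_run(
            ps, params, tol=tol, max_iter=max_iter, fix_alpha2=fix_alpha2)
        trace = np.concatenate([trace0, trace1[1:]])
        degen = degen0 or degen1

    params_f = _destandardize(params_f, mean, sd)
    if fix_alpha2 is None:
        params_f = params_f.relabeled()
    result = FitResult(params=params_f, loglik=float(trace[-1]),
                       loglik_trace=trace, start_logliks=start_logliks,
                       n_starts=len(starts), converged=converged,
                       n_iter=int(trace.size - 1), seed=seed,
                       degenerate=degen,
                       start_traces=[np.asarray(r[1]) for r in screened])
    if compute_se:
        result.standard_errors = standard_errors(panel, params_f)
    return result


def _logit(p: float) -> float:
    p = min(max(p, 1e-12), 1 - 1e-12)
    return float(np.log(p / (1 - p)))


def _params_from_free(phi: np.ndarray, names) -> LMParameters:
    pi2 = 1.0 / (1.0 + np.exp(-phi[0]))
    p12 = 1.0 / (1.0 + np.exp(-phi[1]))
    p21 = 1.0 / (1.0 + np.exp(-phi[2]))
    return LMParameters(pi=np.array([1 - pi2, pi2]),
                        Pi=np.array([[1 - p12, p12], [p21, 1 - p21]]),
                        mu=float(phi[3]), alpha2=float(phi[4]),
                        beta=phi[5:].copy(), covariate_names=names)


def standard_errors(panel: PanelData, params: LMParameters) -> dict:
    """Observed-information standard errors.

    The Hessian of the incomplete-data log-likelihood is computed by
    central finite differences in an unconstrained parameterization
    (logits of pi_2 and of the off-diagonal transition probabilities; raw
    measurement coefficients) and mapped back to the probability scale by
    the delta method.  Parameters whose information is not positive get
    NaN with a warning.
    """
    import warnings

    phi = np.concatenate([
        [_logit(params.pi[1]), _logit(params.Pi[0, 1]), _logit(params.Pi[1, 0]),
         params.mu, params.alpha2], params.beta])
    k = phi.size

    def nll(v: np.ndarray) -> float:
        return -forward_backward(panel, _params_from_free(v, params.covariate_names)).loglik

    h = 1e-4 * np.maximum(1.0, np.abs(phi))
    H = np.zeros((k, k))
    f0 = nll(phi)
    for a in range(k):
        for b in range(a, k):
            if a == b:
                va, vb = phi.copy(), phi.copy()
                va[a] += h[a]
                vb[a] -= h[a]
                H[a, a] = (nll(va) - 2 * f0 + nll(vb)) / h[a] ** 2
            else:
                vpp, vpm, vmp, vmm = (phi.copy() for _ in range(4))
                vpp[[a, b]] += [h[a], h[b]]
                vpm[a] += h[a]
                vpm[b] -= h[b]
                vmp[a] -= h[a]
                vmp[b] += h[b]
                vmm[[a, b]] -= [h[a], h[b]]
                H[a, b] = H[b, a] = (nll(vpp) - nll(vpm) - nll(vmp) + nll(vmm)) \
                    / (4 * h[a] * h[b])

    eig = np.linalg.eigvalsh(H)
    if eig.min() <= 0:
        warnings.warn("observed information is not positive definite; "
                      "standard errors may be unreliable")
    cov = np.linalg.pinv(H)
    var = np.diag(cov).copy()
    bad = var <= 0
    if bad.any():
        warnings.warn("non-positive variance for some parameters; reported as NaN")
        var[bad] = np.nan
    se_phi = np.sqrt(var)

    # delta method back to the probability scale: d expit / d phi = p (1 - p)
    pi2, p12, p21 = params.pi[1], params.Pi[0, 1], params.Pi[1, 0]
    out = {
        "pi_2": float(se_phi[0] * pi2 * (1 - pi2)),
        "Pi_1to2": float(se_phi[1] * p12 * (1 - p12)),
        "Pi_2to1": float(se_phi[2] * p21 * (1 - p21)),
        "mu": float(se_phi[3]),
        "alpha2": float(se_phi[4]),
    }
    names = params.covariate_names or [f"x{j + 1}" for j in range(params.beta.size)]
    for j, name in enumerate(names):
        out[f"beta_{name}"] = float(se_phi[5 + j])
    return out


def decode_states(panel: PanelData, params: LMParameters) -> np.ndarray:
    """Local decoding: per-occasion argmax of the marginal posterior.

    Returns an (n, T_max) int array with states 1/2 (0 beyond T_i); ties
    break toward state 1.
    """
    post = forward_backward(panel, params)
    states = np.where(post.gamma[:, :, 1] > post.gamma[:, :, 0], 2, 1)
    return np.where(panel.mask(), states, 0)
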