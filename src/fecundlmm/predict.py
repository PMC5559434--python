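"""Predicted conception-state probabilities.

Two deliverables: the cohort-level decline curve (average posterior
probability of the conception-prone state at the final fertile window of
models refit with an increasing number of windows) and per-couple
filtered/smoothed trajectories with a one-step-ahead forecast.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .lm import LMParameters, PanelData, fit_em, forward_backward

logger = logging.getLogger(__name__)

__all__ = ["DeclineCurve", "decline_curve", "predict_couple"]


@dataclass
class DeclineCurve:
    """Average predicted probability of the conception state by number of
    fertile windows included in the fit."""

    T_values: list[int]
    avg_prob: list[float]  # smoothed posterior at window T, couples present at T
    avg_prob_all_windows: list[float]  # variant: averaged over all windows
    n_couples: list[int]
    logliks: list[float] = field(default_factory=list)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "T": self.T_values,
                "avg_prob_state2": self.avg_prob,
                "avg_prob_state2_all_windows": self.avg_prob_all_windows,
                "n_couples": self.n_couples,
                "loglik": self.logliks,
            }
        )


def decline_curve(panel: PanelData, T_list, refit: bool = False,
                  **fit_kwargs) -> DeclineCurve:
    """Average smoothed posterior probability of the conception state as
    the number of fertile windows grows.

    By default one model is estimated (full multi-start EM on the largest
    requested T) and its posteriors are evaluated on each nested sub-panel
    of windows 1..T, which keeps the per-T averages comparable.  With
    ``refit=True`` the model is independently refit for every T; under
    weakly separated states those refits can land on different points of a
    flat likelihood ridge, so the resulting curve is noisier.

    The headline series averages the posterior at window T over the
    couples still observed at window T; the all-window variant averages
    over every observed window.  T values exceeding the available data are
    skipped with a warning.
    """
    T_valid = []
    for T in T_list:
        if T < 1 or T > panel.T_max:
            logger.warning("T=%s outside available windows (1..%d); skipped",
                           T, panel.T_max)
            continue
        T_valid.append(int(T))
    T_vals, avg, avg_all, ns, lls = [], [], [], [], []
    anchor = None
    if T_valid and not refit:
        anchor = fit_em(panel.truncated(max(T_valid)), **fit_kwargs).params
    for T in T_valid:
        sub = panel.truncated(T)
        params = fit_em(sub, **fit_kwargs).params if refit else anchor
        post = forward_backward(sub, params)
        at_T = sub.lengths >= T
        if not at_T.any():
            logger.warning("no couples observed at window T=%d; skipped", T)
            continue
        mask = sub.mask()
        T_vals.append(int(T))
        avg.append(float(post.gamma[at_T, T - 1, 1].mean()))
        avg_all.append(float(post.gamma[:, :, 1][mask].mean()))
        ns.append(int(at_T.sum()))
        lls.append(float(post.loglik))
    return DeclineCurve(T_values=T_vals, avg_prob=avg,
                        avg_prob_all_windows=avg_all, n_couples=ns,
                        logliks=lls)


def predict_couple(params: LMParameters, x, y_observed, n_ahead: int = 1) -> dict:
    """State-2 probability trajectory for a single couple.

    Returns filtered and smoothed probabilities for the observed windows
    plus an ``n_ahead``-window forecast obtained by propagating the final
    filtered posterior through the transition matrix (Chapman-Kolmogorov).
    With no observations the forecast is the prior sequence
    pi, pi*Pi, pi*Pi^2, ...
    """
    params.validate()
    x = np.atleast_1d(np.asarray(x, dtype=float))
    if x.size != params.beta.size:
        raise ValueError("covariate dimension does not match beta")
    y = np.atleast_1d(np.asarray(y_observed, dtype=float)) if y_observed is not None \
        else np.empty(0)
    T = int(y.size)

    if T == 0:
        probs = []
        dist = params.pi.copy()
        for _ in range(max(n_ahead, 1)):
            probs.append(float(dist[1]))
            dist = dist @ params.Pi
        return {"filtered": np.empty(0), "smoothed": np.empty(0),
                "forecast": np.asarray(probs)}

    panel = PanelData(X=x[None, :], Y=y[None, :], lengths=np.array([T]),
                      covariate_names=params.covariate_names)
    post = forward_backward(panel, params)
    # filtered posteriors: forward pass only
    from .lm import _emission_matrix

    B = _emission_matrix(panel, params)[0]
    f = params.pi * B[0]
    f = f / f.sum()
    filtered = [float(f[1])]
    for t in range(1, T):
        f = (f @ params.Pi) * B[t]
        f = f / f.sum()
        filtered.append(float(f[1]))

    forecast = []
    dist = f.copy()
    for _ in range(n_ahead):
        dist = dist @ params.Pi
        forecast.append(float(dist[1]))
    return {
        "filtered": np.asarray(filtered),
        "smoothed": post.gamma[0, :T, 1].copy(),
        "forecast": np.asarray(forecast),
    }
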