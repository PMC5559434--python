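"""Published reference estimates for the two-state fecundability model.

These are the point estimates reported for the motivating European
prospective NFP cohort (673 couples, first four fertile windows): the
initial probability of the conception-prone state, the 2x2 transition
matrix of the latent chain, the measurement-model cut-point, and the
covariate coefficients of the generalized logit.  They parameterize the
simulate-and-refit recovery experiments shipped with this package.

The state-2 support point ``alpha2`` was not published; the value 2.0 used
here is a synthetic stand-in chosen so that the two states are separated
on the logit scale, and must not be read as a cohort estimate.
"""

from __future__ import annotations

import numpy as np

# order matters: this is the covariate order of the coefficient vector
MODEL_COVARIATES = [
    "woman_age",
    "man_age",
    "fertile_len",
    "intercourse_freq",
    "prev_pregnancy",
    "no_contraception",
]

REFERENCE_BETA = {
    "woman_age": -0.0415,
    "man_age": -0.0212,
    "fertile_len": -0.0653,
    "intercourse_freq": 0.2058,
    "prev_pregnancy": 0.3869,
    "no_contraception": 0.0299,
}

REFERENCE_BETA_SE = {
    "woman_age": 0.0229,
    "man_age": 0.0195,
    "fertile_len": 0.0210,
    "intercourse_freq": 0.0377,
    "prev_pregnancy": 0.1333,
    "no_contraception": 0.1340,
}

#: initial probability of state 2 (conception-prone) at the first window
REFERENCE_PI2 = 0.373

#: transition matrix, rows = state at t-1, cols = state at t
REFERENCE_TRANSITION = np.array([[0.8771, 0.1229], [0.2066, 0.7934]])

#: measurement cut-point (state-1 baseline log-odds once alpha1 = 0)
REFERENCE_MU = -0.079

#: synthetic stand-in for the unpublished state-2 support point
REFERENCE_ALPHA2 = 2.0


def reference_parameters():
    """Return the reference model as an :class:`~fecundlmm.lm.LMParameters`."""
    from .lm import LMParameters

    beta = np.array([REFERENCE_BETA[c] for c in MODEL_COVARIATES])
    return LMParameters(
        pi=np.array([1.0 - REFERENCE_PI2, REFERENCE_PI2]),
        Pi=REFERENCE_TRANSITION.copy(),
        mu=REFERENCE_MU,
        alpha2=REFERENCE_ALPHA2,
        beta=beta,
        covariate_names=list(MODEL_COVARIATES),
    )
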