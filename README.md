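# fecundlmm

Symptothermal fertile-window delimitation and a two-state latent Markov
model of fecundability with covariates.

## What this package is for

Couples using natural family planning chart daily fertility signs — basal
body temperature (BBT) and cervical mucus symptoms (CMS) — and time
intercourse by the fertile window those signs delimit. This package is
for biostatisticians studying fecundability from such charts. It
implements the full two-stage analysis:

1. **Rule engine** — read daily symptothermal charts, score mucus on the
   0–4 scale, detect the thermal shift by the *three-over-six rule* (the
   first three consecutive recorded temperatures each strictly above the
   maximum of the previous six), locate the mucus peak, and delimit the
   fertile window from the first day of felt or detected mucus to the
   third high-temperature day after the peak; then apply the cycle
   exclusion cascade and build per-couple covariates.
2. **Latent Markov model** — for the binary conception indicator
   Y(t) ∈ {0, 1} in fertile window t, a hidden first-order Markov chain
   U(t) ∈ {1 = infecund, 2 = conception-prone} with initial probabilities
   π_u, transition matrix π_{u|ū}, and measurement model

       logit P(Y(t) = 1 | U(t) = u, x) = μ + α_u + x′β ,   α₁ = 0 ,

   estimated by multi-start EM with forward–backward recursions,
   observed-information standard errors, local decoding of the latent
   states, and the predicted decline curve of the conception probability
   across fertile windows.

The motivating cohort (a 1990s European prospective NFP study of ~673
couples) is not publicly available, so a first-class synthetic-data
module reproduces its covariate distributions, chart structure and
outcome model; all tests and the acceptance script run on synthetic
cohorts. See `docs/methods.md` for the model, its assumptions, and what
the synthetic cohort does and does not emulate.

## Worked example

The `analysis/` scripts run the pipeline on a synthetic 800-couple cohort
(seed 7): `01_simulate.py` → `02_fertile_windows.py` → `03_fit_model.py`
→ `04_decline_curve.py`, writing tables under `results/cohort/`.

`02_fertile_windows.py` prints the filter cascade:

```
2156 cycles -> removed 0 with protected intercourse, 125 without a
delimitable window, 216 without intercourse in the window -> 1815 cycles
from 766 women retained
chart-derived aggregates: mean window length 11.9 days, mean intercourse
acts 3.6 per window
```

i.e. of 2,156 simulated cycles, 125 lacked the BBT/CMS information to
delimit a window and 216 had no intercourse inside it; the surviving
cycles average a 11.9-day fertile window. `03_fit_model.py` then fits the
model to the retained panel:

```
log-likelihood -1109.1 over 11 starts (converged: True)
initial P(conception state) = 0.188 (SE 0.045)
transitions: stay infecund 0.833, infecund->conception 0.167, conception->infecund 0.997
cut-point mu = 1.266, support point alpha2 = 6.86
  beta[woman_age] = -0.0785  (SE 0.0523)
  ...
  beta[intercourse_freq] = +0.4738  (SE 0.1640)
  beta[prev_pregnancy] = +0.8468  (SE 0.3674)
```

Intercourse frequency in the window and previous pregnancies raise the
conception odds; ages lower them slightly. (At this demonstration size
the *latent* parameters sit on a flat likelihood ridge — see
`docs/methods.md` — so π₂ and α₂ should not be read as recovered truth.)
`04_decline_curve.py` reports the average predicted probability of the
conception state falling from 0.189 at the first fertile window to 0.156
at the fourth: with conception absorbing, couples still observed later
are increasingly the infecund ones.

The same pipeline is scriptable: `fecundlmm simulate | windows | fit |
predict | run`, with every generator and rule parameter exposed as a
flag and full runs reproducible byte-for-byte from one seed.

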