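# frphylo

Functional-response analysis of herbivore feeding trials, with split-plot
mixed-model and phylogenetic GLS inference.

## The problem

When a generalist herbivore (here modelled on the invasive golden apple
snail, *Pomacea canaliculata*) is offered plants it shares an evolutionary
history with ("familiar", same biogeographic origin) versus plants it has
never met ("novel"), does its per capita feeding efficiency differ — and
does warming change that? Feeding efficiency is quantified not by a
snapshot feeding rate but by the parameters of a Type II functional
response fitted to trials across a biomass gradient: the attack (cropping)
rate *a*, the handling (chewing and digestion) time *h*, and the maximum
feeding rate 1/*h*.

Because each 60 h trial depletes the plant material it consumes, the right
model is Rogers' random-predator equation,

    Ne = N (1 − exp(a (Ne h − T))),

implicit in the consumed biomass *Ne*; the package evaluates its explicit
solution via the Lambert W function,

    Ne = N − W(a h N e^{−a(T − hN)}) / (a h),

fits (*a*, *h*) per species × temperature by nonlinear least squares,
bootstraps 95% confidence bands around group-mean curves, and feeds the
log-parameters into two comparative frameworks: split-plot linear mixed
models (temperature is a whole-plot/tank factor; species and biomass are
subplot factors; tank is a random effect) and phylogenetic GLS under
Brownian motion, using each familiar species' mean cophenetic distance to
the novel group as a relatedness covariate. A seeded synthetic-data
generator emulates the full 3-block × 5-temperature × 10-species ×
7-biomass-level experiment (1,050 units) plus its 210-unit no-herbivore
control, so the entire chain is testable end to end. See
`docs/methods.md` for the model, assumptions, and numerical choices.

## Layout

- `src/frphylo/` — the library: `design` (experimental design, CSV I/O,
  control correction), `synthetic` (data generator), `frfit` (Rogers
  solver, NLS fitting, bootstrap bands), `phylo` (Newick, cophenetic and
  Brownian matrices), `models` (split-plot LMM, PGLS), `pipeline` + `cli`
  (orchestration).
- `analysis/01…05_*.py` — the narrative analysis: simulate → fit →
  bootstrap bands → split-plot models → PGLS, writing tables under
  `results/`.
- `frphylo` console script: `simulate`, `fit`, `band`, `models`, `run`
  verbs (e.g. `frphylo run --seed 7 --out results/run`); configs in YAML
  or JSON mirroring `frphylo.pipeline.paper_like_config()`.

## Worked example

```
$ python analysis/01_simulate.py
trials: 1050 records (25 clamped by the [0, N] net-consumption bound)
controls: 210 records

$ python analysis/02_fit_functional_responses.py
fitted 50 cells; 50 converged
group-mean handling time (hr/g) by temperature:
group          familiar  novel
temperature_C
26.0              34.28   6.76
28.0              24.16   6.63
30.0              20.58   6.92
32.0              15.20   7.06
34.0              11.75   6.73
```

Familiar plants take far longer to handle than novel ones, and warming
compresses that gap from ~5× at 26 °C to ~1.7× at 34 °C — the generator's
truth surface, recovered by the fitter. The split-plot models quantify it:

```
$ python analysis/04_split_plot_models.py
temp × origin F tests (df_den: Temp 3, Origin/interaction 43):
temp_origin  log_h  Temp         1  3  12.904  0.037
temp_origin  log_h  Origin       1 43   9.001  0.004
temp_origin  log_h  Temp:Origin  1 43   6.679  0.013
...
temp_origin  log_h  Familiar: Temp  -0.165  -3.592  0.001
temp_origin  log_h  Novel: Temp      0.003   0.063  0.950
```

The familiar-group temperature slope on log handling time (−0.165 in this
run; truth −0.129) is significant while the novel group is flat, and the
denominator degrees of freedom (3 for the whole-plot temperature test, 43
for subplot terms, 18 in the familiar-only phylogeny model) follow from
the split-plot design shape alone. `analysis/03_bootstrap_bands.py`
reports that the familiar and novel 95% bands overlap nowhere on the
biomass grid at any temperature, and `analysis/05_pgls.py` repeats the
origin contrast with Brownian-motion error covariance, one observation per
species per temperature.

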