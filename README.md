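# sedshift

Critical-transition analysis of dated sediment-core microbial community
time series.

Lake sediments archive the DNA of past microbial communities in dated
layers, so a single core yields a centuries-long community time series.
`sedshift` takes a taxon-by-sample count table plus a calibrated chronology
and asks the tipping-point questions paleolimnologists ask of such records:

* Did the community occupy **two alternative states**, separated by an
  abrupt shift?  (Bray–Curtis ordination, stratigraphically constrained
  zonation, ANOSIM/PERMANOVA, kernel-density bimodality of the NMDS1 state
  axis, structural-change breakpoints on alpha diversity, ARIMA
  forecast-deviation between states.)
* Was the shift preceded by **critical slowing down**?  (Sliding-window
  variance and lag-1 autocorrelation of NMDS1 with Kendall trend tests.)
* How did **stability and species interactions** change through the shift?
  (Per-stage generalized Lotka–Volterra inference with local stability
  analysis.)

## The model at the core

Community dynamics are modeled with the generalized Lotka–Volterra (gLV)
system

```
dN_i/dt = N_i ( r_i − Σ_j a_ij N_j ),    i = 1 … S,
```

where `N_i` is the relative abundance of taxon *i*, `r_i` its intrinsic
growth rate (per year) and `a_ij` the strength with which taxon *j*
inhibits taxon *i*.  A forward difference over consecutive dated samples
turns this into one linear regression per taxon,

```
Δ ln N_i(t_k) / Δt_k = r_i − Σ_j a_ij N_j(t_k),
```

solved with Tikhonov (ridge) regularization of the interaction
coefficients, the ridge weight chosen by k-fold cross-validation over
contiguous blocks of equations.  The record is split into overlapping
stages (window 10 samples, step 5); per stage, the interior equilibrium
`N*` solves `A N* = r`, the Jacobian there is `−diag(N*) A`, and the stage
is locally stable when every eigenvalue has negative real part.  The mean
of the eigenvalues' real parts (the spectral "centroid") serves as a graded
stability level, and each taxon pair is typed from the signs of the growth
effects `e_ij = −a_ij` as mutualism (+/+), antagonism (−/−) or exploitation
(+/−).

A synthetic-data module generates ground-truth gLV communities — including
a dated two-regime scenario in which a slow environmental driver pushes a
bistable community core past its invasion threshold — so every stage of the
pipeline is testable without sequencing data.

## Worked example

Simulate a 35-sample, 12-class sediment core spanning 1200–2010 CE and run
the full pipeline:

```sh
sedshift --seed 7 --outdir fixture simulate
sedshift --seed 7 --outdir results run \
    --table fixture/taxon_table.tsv --chronology fixture/chronology.tsv
```

which prints:

```
samples: 35, taxa: 13
states: 2 (boundary at sample index 12)
ANOSIM R = 1.000, p = 0.001; PERMANOVA F = 765.85, p = 0.001
NMDS stress = 0.0002; NMDS1 KDE modes = 2
breakpoints[richness]: m = 1 at 1581
breakpoints[shannon]: m = 2 at 1367, 1486
breakpoints[simpson]: m = 2 at 1367, 1486
EWS (window 5): tau_var = 0.286 (p = 0.399), tau_ac = 0.429 (p = 0.179)
ARIMA forecast deviation: 100% of state-2 observations outside the 95% band
stages analyzed: 7 (7 with stability estimates)
  stage 1: centroid = -0.0076 (unstable)
  stage 2: centroid = +0.0310 (unstable)
  stage 3: centroid = +0.0110 (unstable)
  stage 4: centroid = -0.0296 (stable)
  stage 5: centroid = -0.0176 (stable)
  stage 6: centroid = -0.0390 (stable)
  stage 7: centroid = -0.0350 (stable)
```

Reading this output: the zonation and permutation tests find two cleanly
separated community states (ANOSIM R = 1 with the minimal attainable
p-value at 999 permutations), the NMDS1 state axis is bimodal, and the
Shannon/Simpson breakpoint at 1367 CE dates the regime shift.  An ARIMA
(1,1,0) model fitted to state 1 fails to forecast state 2 — every state-2
observation falls outside the 95% prediction band, the signature of a
bifurcation rather than smooth drift.  The per-stage gLV analysis shows the
eigenvalue centroid rising above zero exactly in the stages that straddle
the simulated transition (stages 2–3) and returning to stable values
afterwards: the community is most unstable at the tipping point.  In this
synthetic record the true stability-loss threshold is at 1320 CE and the
regime crossover at 1460 CE (written to `fixture/ground_truth.json`), both
inside the unstable stages.  The per-window early-warning trends are
positive but not individually significant at this record length — with
only twelve pre-transition samples the Kendall test has little power,
which is exactly why the test suite validates the EWS machinery on longer
fold-approach simulations.

Each subcommand (`diversity`, `ordination`, `transition`, `glv`) can also
be run on its own, and every output TSV carries a provenance header with
the package version, command and master seed.

## Layout

```
src/sedshift/tables_io.py   count tables, chronologies, rarefaction, collapsing
src/sedshift/diversity.py   alpha diversity + Kruskal–Wallis state tests
src/sedshift/ordination.py  Bray–Curtis, NMDS, ANOSIM/PERMANOVA, zonation, KDE
src/sedshift/transition.py  breakpoint DP, sliding-window EWS, ARIMA deviation
src/sedshift/glv.py         stage windows, ridge gLV fits, stability, interactions
src/sedshift/synthetic.py   ground-truth simulators and the two-regime scenario
src/sedshift/pipeline.py    end-to-end orchestration
src/sedshift/cli.py         `sedshift` command-line interface
docs/methods.md             model, assumptions, parameter choices, limitations
```
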