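# supercoilfret

Simulation and analysis of single-molecule FRET (smTIRF) experiments that
probe how DNA supercoiling modulates protein–DNA kinetics. The package
covers two experiment archetypes on surface-tethered plasmid DNA:

* **Enzyme-driven DNA unwinding snapshots** — a donor/acceptor pair spans
  the target site; unwinding (R-loop formation) shifts molecules from a
  high-FRET to a low-FRET population. Short movies taken at a series of
  timepoints yield FRET histograms from which the fraction of unwound
  molecules, *f*<sub>unwound</sub>, is extracted and fitted over time.
* **Protein binding / sliding-clamp movies** — the acceptor sits on the DNA
  next to a mismatch and the donor on the protein. Binding appears as a
  high-FRET event out of darkness; conversion to a mobile sliding clamp as
  a high→low FRET transition. Dwell-time statistics give the kinetic rates.

## Models and statistics

**Population classification.** Pooled FRET histograms are fitted with a sum
of three Gaussians (donor-only artifact, unwound, wound populations); the
intersection points of adjacent components define the classification window
(*lower*, *upper*). A molecule counts as unwound iff *lower* < *E* < *upper*
and enters the total iff *E* > *lower*, so

f<sub>unwound</sub> = N(lower < E < upper) / N(E > lower).

**Unwinding time course.** f<sub>unwound</sub>(t) follows one-phase
association, y = y0 + (plateau − y0)(1 − e^(−k t)), fitted by nonlinear
least squares (t in minutes, k in 1/min).

**Dwell-time kinetics.** Trajectories are idealized either by a per-trace
maximum-likelihood two-state Gaussian HMM (EM + Viterbi) or by deterministic
intensity/FRET-threshold segmentation of binding events. Dwell times are
summarized as an empirical survival curve (1 − CDF; Kaplan–Meier when
right-censored sojourns are included) and fitted with
y = y0 + A1·e^(−k t). When the bound state exits through two competing
channels, the composite rate k = k₋₁ + k₂ is split exactly by the branch
counts N₂ (clamp formations) and N₋₁ (dissociations):
k₂ = k·N₂/(N₂+N₋₁), k₋₁ = k·N₋₁/(N₂+N₋₁). The association side is reported
as the event frequency k₁ (events per molecule per second) and the
pseudo-first-order rate k′_on fitted from the waiting times.

**Synthetic data.** A seeded generator produces both archetypes with the
statistical structure the analysis assumes: Gillespie continuous-time Markov
paths, Gaussian state emissions, channel noise, photobleaching, inactive
acceptors, and the standard excitation schedules (donor-excitation frames
for FRET, direct acceptor-excitation frames for the acceptor-presence
filter). Identical configuration (including seed) reproduces a bit-identical
dataset.

## Worked example

Simulate the no-clamp binding archetype at a generative dissociation rate of
0.204 /s, then re-estimate the rates through the full pipeline
(acceptor-presence filter → event segmentation → survival curve →
exponential fit):

```python
from supercoilfret import workflows

r = workflows.recover_adp_koff(seed=11, k_dissoc=0.204, n_molecules=800)
print(f"generative k_off : {r['generative_k_off']:.3f} /s")
print(f"recovered  k_off : {r['recovered_k_off']:.3f} /s")
print(f"recovered  k'_on : {r['recovered_k_on_pseudo']:.4f} /s")
print(f"events analysed  : {r['n_uncensored_events']}")
```

prints

```
generative k_off : 0.204 /s
recovered  k_off : 0.194 /s
recovered  k'_on : 0.0206 /s
events analysed  : 2589
```

i.e. the dissociation rate is recovered within ~5% from one seed (the
spread over seeds is ~3%), and the waiting-time analysis returns the
configured arrival rate of 0.02 /s. The unwinding time course works the
same way:

```python
r = workflows.recover_timecourse(seed=7, plateau=0.79)
print(f"plateau  : generative 0.790, recovered {r['recovered']['plateau']:.3f}")
print(f"k (1/min): generative 0.300, recovered {r['recovered']['k_assoc']:.3f}")
```

```
plateau  : generative 0.790, recovered 0.792
k (1/min): generative 0.300, recovered 0.280
```

A config-driven CLI wraps the same pipelines
(`supercoilfret --config run.yaml --out results/ --seed 1`) with modes
`simulate`, `analyze-cas9-timecourse`, `analyze-cas9-equilibrium`,
`analyze-muts-adp`, `analyze-muts-atp` and `recover`; traces are exchanged
as HDF5, event tables as CSV, fitted parameters as JSON next to a
provenance record.

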