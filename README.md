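# rnmkit

Semi-quantitative regulatory-network simulation and model–experiment
concordance for chondrocyte-like cells.

## The problem

Cartilage-resident cells (articular chondrocytes, cartilaginous endplate
cells) integrate inflammatory cues such as TNF and mechanical cues sensed by
integrins (α5β1, αvβ3) and the TRPV4 channel into a phenotype decision:
a matrix-building **pro-anabolic** program (high aggrecan, ACAN) or a
matrix-degrading **pro-catabolic** one.  A practical way to reason about
this is a *regulatory network model* (RNM): a signed, weighted interaction
graph whose node activations live on [0, 1] and evolve under continuous-logic
dynamics to attractors representing cell states.  Experimental conditions —
TNF stimulation, unloaded vs dynamically compressed culture — are imposed as
**clamps**: nodes held at fixed activation (0 = knock-down, 0.5 = basal,
1 = full activation) for the whole simulation.

`rnmkit` implements this in-silico arm end to end:

1. **Dynamics** — each unclamped node follows
   `dx_i/dt = f(ω_i) − γ·x_i`, where
   `ω_i = (Σ w_a x_a / Σ w_a)·(1 − Σ w_b x_b / Σ w_b)` aggregates
   activators and inhibitors, and `f` is a normalized sigmoid calibrated so
   that ω = 0, 0.5, 1 map to targets 0, 0.5, 1.  Each condition is simulated
   as an ensemble of 100 attractor searches from random initial states;
   steady states are classified pro-anabolic (ACAN ≥ 0.5) or pro-catabolic.
   A bisection scan locates critical clamp levels (e.g. the IL-4 activation
   at which the phenotype flips).
2. **Secretome calibration** — raw multiplex-immunoassay (Luminex) MFI
   readings are blank-subtracted, calibrated through per-analyte
   5-parameter-logistic standard curves, normalized linearly between each
   analyte's lower/upper limits of quantification to x ∈ [0, 1], median
   aggregated over donors, and referenced to the control-unloaded condition
   (x′ ∈ [−1, 1]).
3. **Concordance** — predicted activations y′ (ensemble means, referenced the
   same way) are aligned with measured x′ through an alias table and compared
   with `NMAD = Σ|x_n − y_n|/N` (reported in %) and per-protein
   `NRSE_n = RSE_n / MAX.RSE`, so the most discordant protein scores 1.
4. **Synthetic data** — generators produce benchmark networks with planted
   attractor structure (forced catabolic switch under TNF, an exactly planted
   IL-4-type flip value, a bistable toggle with an analytic basin) and
   Luminex-style secretome tables with planted effect classes, donor noise
   and LOQ censoring — so the whole pipeline is testable without any
   external data.

## Worked example

```python
import rnmkit as rk
from rnmkit.luminex import calibrate_panel, aggregate_and_reference

net, truth = rk.make_benchmark_network()
for name in ("lit_control_unloaded", "lit_control_dynamic", "lit_TNF_unloaded"):
    ens = rk.run_ensemble(net, rk.get_preset(name), n=100, seed=7)
    print(f"{name}: {ens.pct_anabolic:.0f}% pro-anabolic, "
          f"mean ACAN = {ens.mean_activation['ACAN']:.3f}, "
          f"{ens.attractor_count} attractor(s)")

c = rk.find_critical_clamp(net, "IL4", truth["flip_base_clamps"], tol=1e-3, seed=7)
print(f"critical IL4 clamp: {c:.4f} (planted {truth['flip_value']})")

fx = rk.make_paired_fixture(seed=11, deviation=("VEGF", 0.2))
calibrated, _, excluded = calibrate_panel(fx.panel)
secretome = aggregate_and_reference(calibrated, excluded=excluded)
report = rk.concordance_report(fx.condition_means, secretome, aliases=fx.aliases)
for cond in ("control_dynamic", "TNF_unloaded", "TNF_dynamic"):
    block = report["conditions"][cond]
    print(f"{cond}: NMAD = {block['nmad_pct']:.2f}% over N = {block['n_aligned']}; "
          f"worst protein: {block['error_ranking'][0]}")
```

prints

```
lit_control_unloaded: 0% pro-anabolic, mean ACAN = 0.154, 1 attractor(s)
lit_control_dynamic: 100% pro-anabolic, mean ACAN = 0.846, 1 attractor(s)
lit_TNF_unloaded: 0% pro-anabolic, mean ACAN = 0.000, 1 attractor(s)
critical IL4 clamp: 0.2583 (planted 0.2585)
control_dynamic: NMAD = 2.00% over N = 10; worst protein: VEGF
TNF_unloaded: NMAD = 2.00% over N = 10; worst protein: VEGF
TNF_dynamic: NMAD = 2.00% over N = 10; worst protein: VEGF
```

Reading this: on the benchmark network, basal mechanoreceptor activation
(clamps at 0.5) leaves the readout below threshold, full dynamic-compression
activation (clamps at 1) drives every run anabolic, and TNF = 1 forces the
catabolic attractor.  The bisection recovers the planted IL-4 flip level to
the requested 10⁻³.  In the paired fixture a single planted deviation of
0.2 on one of the ten shared analytes produces exactly
NMAD = 100·0.2/10 = 2% and puts that analyte at the top of the NRSE error
ranking.

The same steps are available from a shell: `rnmkit synth network`,
`rnmkit synth secretome`, `rnmkit simulate`, `rnmkit calibrate`,
`rnmkit concord` (see `rnmkit --help`).

To run a *real* network, supply its signed weighted edge list as CSV
(`source,target,sign,weight`, optional `node,role` metadata, SIF also
accepted) and any of the ten built-in condition presets; preset clamps
reference nodes named α5β1, αvβ3, TRPV4, Actin, TNF, IL4, so a network
lacking one of these raises a configuration error naming it.

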