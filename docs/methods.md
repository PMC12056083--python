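# Methods

## Network model and dynamics

A regulatory network is a signed, weighted directed graph.  Node roles
distinguish *pure external inputs* (mechanoreceptors, cytokines with no
incoming edges: they decay to 0 unless clamped) from *generic* internal
nodes (a generic node with no regulators self-sustains — its input equals
its own activation, which at high gain makes an isolated memory element),
and mark the phenotype *readout* (ACAN by default; a network without a
readout is rejected at load).

Unclamped nodes follow the continuous-logic ODE family

    dx_i/dt = f(ω_i) − γ x_i ,

discretized by explicit Euler with step dt.  The aggregated input is

    ω_i = (Σ_a w_a x_a / Σ_a w_a) · (1 − Σ_b w_b x_b / Σ_b w_b)

over activators a and inhibitors b; a node with inhibitors but no
activators gets activator factor 1 (full basal drive).  The sigmoid is the
*normalized* logistic

    f(ω) = (s(ω) − s(0)) / (s(1) − s(0)),   s(ω) = 1/(1 + e^{−h(ω−0.5)}),

pinned so that ω = 0, 0.5, 1 map to targets exactly 0, 0.5 and 1.  This
calibration is what makes clamp semantics compositional: a regulator held
at 0.5 ("basal") drives a single downstream target to 0.5, and the
knock-down/full-activation extremes propagate exactly.  Clamped nodes are
overwritten with their clamp value at every step; all states are clipped
to [0, 1] (the flow cannot leave the box, clipping only guards float
round-off).

**Defaults and units.**  gain h = 10 (dimensionless; large enough for
bistability through positive feedback, small enough for smooth basins),
decay γ = 1 (per unit time; sets the activation scale so the fixed point
of an isolated regulated node is f(ω)), step dt = 0.1 (stable for γ = 1
explicit Euler with wide margin), max 10 000 iterations.

**Convergence** is declared on the flow residual max_i |f(ω_i) − γx_i| <
tol (default 10⁻⁶), i.e. step-change < tol·dt, rather than on the raw
step-change.  The residual bounds the distance to the fixed point
independently of the step size, which keeps the documented oracle
guarantee — steady states agree with exhaustively scanned fixed points of
the update map within 10·tol — meaningful.  Hitting the iteration cap
(e.g. on an oscillatory attractor) flags the run as non-converged; such
runs are excluded from ensemble summaries and counted, never raised.

**Attractor bookkeeping.**  Two converged states are the same attractor
when their max node-wise difference is below 10⁻³ (well above solver
noise ~tol, well below the separation of distinct logic states).
Ensemble fractions (% pro-anabolic / pro-catabolic) are computed over
*runs*, not deduplicated attractors; the attractor count is reported
separately.  An ensemble whose runs all fail to converge reports `None`
fractions and an empty mean-activation map rather than NaN.

## Condition presets and classification

Ten built-in presets encode the experimental conditions as clamp sets:
literature-derived mechanoreceptor activation (α5β1 = αvβ3 = TRPV4 = 0.5
basal / free swelling; = 1 under dynamic compression; TNF = 1 for
stimulation) and experiment-derived activation (α5β1 = 0.5, Actin = 0 for
deficient cytoskeletal coupling in agarose, IL4 = 0.2585 at its critical
level, TRPV4 = 1 / 0.5 / 0.25 for day 0 / control / TNF, dynamic presets
identical to unloaded).  Values are preserved exactly through YAML/JSON
round trips (0.2585 stays 0.2585).  Day-0 presets are simulated like any
other and excluded from concordance by default.

A steady state is pro-anabolic when the readout is **at or above** the
threshold (default 0.5) — the boundary is inclusive on the anabolic side
— else pro-catabolic.

`find_critical_clamp` bisects the clamp value of one node for the level
at which the *majority* label of a seed-deterministic probe ensemble
(n = 25 per probe; majority is robust to multistability) flips, erroring
explicitly when both interval endpoints agree (no switch).  Per-probe
seeds derive from `SeedSequence([seed, probe_index])`, so repeated calls
agree exactly.

## Secretome calibration

Pipeline: (1) net MFI = raw − per-analyte blank, floored at 0 and
flagged; (2) per-analyte 5PL standard curve
`MFI(c) = L + (U − L)/(1 + (C/c)^B)^G` fitted by least squares with
**constant-CV weights** (residuals scaled by 1/MFI) — the standard
immunoassay weighting, and the correctly specified estimator for the
multiplicative errors these assays show; unweighted fitting leaves the
inflection C poorly identified against the asymmetry G.  Fewer than five
distinct standard concentrations drop to a 4PL (G ≡ 1), flagged; an
optimizer failure flags the curve and excludes the analyte downstream
with a warning.  (3) closed-form inversion to concentration, censored at
the LOQ limits: readings at/below the lower asymptote *or* inverting
below the lower LOQ report the lower LOQ with a `lower` flag
(symmetrically above), which makes the reported concentration
non-decreasing in MFI.  (4) linear normalization
x = (c − LLOQ)/(ULOQ − LLOQ), clipped to [0, 1]; a log-concentration
option exists but is off by default — the LOQ anchors are
concentration-scale and linear is the minimal reading.  (5) median across
donors, then median pooling of day 7 and day 14 into one value per
condition (the network model carries no time axis; per-day output is an
option), then subtraction of the control-unloaded reference, giving
x′ ∈ [−1, 1] with the reference itself exactly 0.  Undetectable analytes
surface as lower-censored, x = 0.

Concentration (not MFI) is the quantity normalized against the LOQ
limits, since LOQs are concentration-scale quantities.

## Concordance statistics

Model values are ensemble means per condition, referenced against the
control-unloaded ensemble means.  Alignment is the intersection of model
nodes and panel analytes through an explicit alias table (panel spellings
like "IL-6" map to node "IL6"); unmatched names on both sides are
reported, proteins present on only one side are excluded from N, and an
empty intersection is an error listing near-miss names.

* NMAD = Σ|x_n − y_n| / N, reported ×100 as a percentage (raw fraction
  also emitted).
* NRSE_n = RSE_n / MAX.RSE with MAX.RSE the per-condition maximum
  (a global-across-conditions option exists).  Two RSE conventions are
  implemented: `difference` |x_n − y_n| (default) and `as-printed`
  |x_n + y_n|.  The summed form vanishes when model and experiment agree
  in magnitude with opposite signs — unusable as an error measure on
  referenced data, where disagreement *is* an opposite-signed response —
  so the difference form is the default while the summed form remains
  selectable.  Error ranking sorts by NRSE descending with alphabetical
  tie-break.

Reports carry a provenance block (mode, alias map, exclusions, seeds)
sufficient to regenerate them byte-identically.

## Synthetic generators

The real chondrocyte network and measured secretome are external, so the
generators produce stand-ins whose ground truth is known by construction.

**Benchmark network** (16 nodes): integrins → actin; TNF → IL6 / IL8 /
IL17, TNF ⊣ CCL2; IL6 → LIF / RETN; TRPV4 → TGFB / NGF; actin → VEGF;
ACAN activated by IL4, actin, TRPV4 and inhibited by IL6.  Consequences
used as oracles: TNF = 1 forces IL6 = 1 hence ω_ACAN = 0 — the catabolic
attractor from *every* initial state; under base clamps
{α5β1 = 0.5, αvβ3 = 0.5, TRPV4 = 1 − c} the readout's input is
(IL4 + 0.5 + (1 − c))/3, crossing the 0.5 threshold exactly at IL4 = c —
an analytically planted flip point for the bisection.  The **toggle**
(two mutually inhibiting nodes) is exactly symmetric, so its anabolic
basin has uniform measure 1/2 with the diagonal as separatrix — an
analytic basin oracle.

**Synthetic secretome** (defaults: 73 analytes, 5 donors, 4 conditions ×
days 7/14): per-analyte assay truth (LLOQ ~ 1–10, ULOQ/LLOQ ~ 10²–10³,
5PL curves with slope 1–2 and asymmetry 0.8–1.5, blanks 10–40 MFI,
10 noiseless log-spaced standards); planted effect classes on the
normalized scale — TNF-up +0.3, TNF-down −0.3, time-decay ×0.5 at day 14,
detected-only-under-TNF (below LLOQ in controls), null — with canonical
assignments (IL-6/IL-8/IL-17 up, CCL2 down, VEGF/NGF/RETN decaying,
IL-4/DEFB1 TNF-only) and the rest assigned by seed.  Noise is
multiplicative log-normal on concentration: donor effect σ_d = 0.2 and
residual σ_r = 0.1 on the log scale, standard for immunoassay
concentrations.  Every generator is fully seed-deterministic and its
output passes the corresponding loader's validators.

**Paired fixture**: the benchmark network's four condition ensembles
(n = 100) are run first and the secretome truth for ten shared analytes
is set equal to the ensemble means, noise-free — so the full
calibrate-align-compare chain yields NMAD = 0 by construction, a planted
deviation δ on one analyte yields exactly 100·δ/N, and planted
incongruent analytes (graded magnitudes, largest first) occupy the top of
the error ranking.

**What passing these tests does not show.**  The generators emulate the
*structure* of the real inputs, not their content: the benchmark topology
is a deliberately simple feed-forward caricature (no feedback loops
except the toggle, no cross-talk between mechanical and inflammatory
arms), donor variation is exchangeable log-normal (no day-to-day assay
drift, plate effects, or heteroscedastic low-end noise), and the paired
fixture guarantees agreement by construction.  Green tests certify the
machinery — dynamics, calibration, statistics, bookkeeping — not any
biological claim about real endplate cells; conclusions about a real
system require the externally published network and measured secretome,
supplied as ordinary input files.

## Problem sizes

Ensembles default to n = 100 attractor searches per condition (the
protocol's ensemble size); acceptance-style checks use 100-run ensembles,
2 000 runs for the toggle basin estimate, 50 replicate fits for the noisy
5PL study, and 50 random networks for the determinism/conservation sweep
— desk-scale sizes a laptop handles in seconds.

## Known limitations

* The dynamics formalism (normalized-sigmoid continuous logic, explicit
  Euler) is a documented choice; other published RNMs use different
  update rules, so numerical agreement with any particular prior model is
  not claimed — only the qualitative clamp/attractor semantics.
* Oscillatory attractors are flagged and excluded, not characterized.
* The 5PL inversion ignores measurement uncertainty (no confidence
  interval on concentration); censoring is a hard flag.
* Alias matching is exact-name after the alias table; no fuzzy matching
  beyond the near-miss diagnostics in error messages.
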