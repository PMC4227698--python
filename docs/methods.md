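# Methods

## Kinetic model

Gating and block are modelled as an aggregated continuous-time Markov chain
whose states are observed only through two conductance classes (open /
closed).  The canonical scheme couples an agonist-dependent C⇌O gate to
three desensitized states D1–D3 and one or two blocked states entered from
O.  All transition rates follow `rate = base · [ligand] · exp(s·V_m)`:
first-order mass action for the ligand-dependent steps (opening in ACh,
blocking in blocker; µM⁻¹s⁻¹), and an optional exponential voltage factor
(per mV, with V_m = V_rest − V_hold in the cell-attached convention).  By
default only the blocking rate is a candidate for voltage sensitivity, and
its default slope is zero; voltage enters only where a scheme explicitly
flags it.

The desensitized states are attached to O in a star topology.  Their exact
interconnection is not identifiable from the aggregated data used here and
is a nuisance for blockade estimation: what matters is that they produce
long non-conducting dwells that terminate activation clusters.  Any other
topology can be expressed through the generic `KineticScheme` container.

Units are seconds and µM internally; dwell files use ms (the DWT
convention).

### Default rate constants (the synthetic study conditions)

| rate | value | meaning |
|---|---|---|
| opening | 2.0 µM⁻¹s⁻¹ | ×100 µM ACh → 200 s⁻¹; intra-cluster closed dwells ≈ 5 ms |
| closing | 150 s⁻¹ | with desensitization entries, α_total = 184.5 s⁻¹ → τ_app ≈ 5.4 ms |
| d1_on / d1_off | 25 / 50 s⁻¹ | desensitized lifetime 20 ms |
| d2_on / d2_off | 8 / 12.5 s⁻¹ | lifetime 80 ms |
| d3_on / d3_off | 1.5 / 1.0 s⁻¹ | lifetime 1 s (slowest, ranks D1<D2<D3) |
| kb_on | 15 µM⁻¹s⁻¹ | reference blocker k₊B |
| kb_off | 2 s⁻¹ | reference blocker k₋B → blocked dwells ≈ 0.5 s |

The blockade constants are the published single-channel values for the
strongest PEG-QA blocker; the gating constants are chosen once to give
AChR-like cluster structure (clusters of a handful of ms-long openings
separated by desensitized dwells 20 ms–1 s) with every dwell scale at least
an order of magnitude above the 0.2 ms dead time, so that the remaining
missed-event effects are within reach of the first-order correction
(below).  The two-mode table (k₋B 60 and 3 s⁻¹) represents the
fast/slow-dissociation regime seen with the smaller quaternary ammonium
head groups.

## Synthetic recordings

Dwell sequences come from exact Gillespie simulation of the generator
matrix (initial state drawn from the stationary distribution).  Traces are
rendered at 10 kHz by sampling the piecewise-constant two-level current
(0 pA closed, 7 pA open, openings upward), convolving with a Gaussian
low-pass kernel, and adding i.i.d. Gaussian noise (1 pA SD) at the samples.
The Gaussian kernel stands in for the recording chain's Bessel filter —
standard for simulated single-channel data and analytically tractable
(σ_t = 0.1325/f_c for a −3 dB cutoff f_c).

The sampling theorem constraint `sample_rate > 2·cutoff` forces a choice at
10 kHz sampling: the default cutoff is 4 kHz.  All dwell scales of interest
(≥ 2 ms) are ~50× the filter rise time (~83 µs), so the analysis results do
not depend on this choice.

Per-dataset seeds derive from `(master_seed, cell, dose, V)` via
`numpy.random.SeedSequence`, so datasets are reproducible byte-for-byte and
adding a condition never perturbs the others.  One active channel per patch
is simulated by default; a multi-channel mode (k independent copies, summed
current) exists only to exercise the NPo activity metrics.

What the generator does **not** emulate: baseline drift, 50/60 Hz
interference, seal breakdown, channel rundown, or multi-conductance
substates.  Passing tests therefore demonstrate correctness of the
estimators under the model's assumptions, not robustness to every artifact
of real patches.

## Idealization (SKM)

The SKM variant alternates (i) Viterbi decoding under a discrete HMM with
Gaussian emissions — per-class means, one pooled variance (filtered noise
is class-independent to first order) — and (ii) re-estimation of the means,
pooled variance, and transition probabilities from the segmentation,
stopping when the segmentation is unchanged (flagged non-converged at the
iteration cap; a class left empty is re-initialized once).  Classes are
reported ranked by amplitude, so "open = more positive" regardless of
initialization.  No amplitude constraints or drift tracking are modelled.

A dead time td (default 0.2 ms = 2 samples at 10 kHz) is then imposed:
events shorter than td are deleted and absorbed into their flanking events,
which merge, iterating until no short event remains.  The operation
conserves total duration exactly and is idempotent.  Cluster segmentation
cuts at closed dwells longer than τ_crit; the default τ_crit solves the
equal-misclassification criterion between the slowest intra-cluster closed
component and the fastest desensitized component, and is insensitive in
practice because those time scales are well separated.

## Interval likelihood and missed events

The dwell-sequence likelihood is the standard aggregated-Markov interval
product (entry at the equilibrium entry vector; the final interval
contributes only its survivor function), evaluated in log space.  With a
single open-class state — true of every scheme fitted here — the product
factorizes exactly into per-interval scalars and is evaluated in one
vectorized pass using an eigendecomposition of the closed-class block; a
general scaled forward pass covers arbitrary aggregates and doubles as an
internal cross-check.

Dead-time-imposed data are fitted with the first-order missed-event
correction: undetected excursions shorter than td into the other class are
folded into effective within-class blocks
`Q'_aa = Q_aa + Q_ab (∫₀^td e^{Q_bb s} ds) Q_ba`, apparent durations enter
as `exp(Q'_aa (t − td))`, and each detected transition carries the survival
factor `Q_ab e^{Q_bb td}`.  At td = 0 this reduces exactly to the ideal
likelihood.  The correction matters: with the reference blockade constants
at 20 µM, ~9% of open dwells fall below td, and ignoring them biases k₊B
and k₋B several percent low (each missed opening merges two blocked/closed
dwells).  The correction is first order — accurate while dwell scales are
several times td, which the default conditions guarantee — not the exact
missed-event likelihood.

`fit_mil` maximizes the summed log-likelihood over named free base rates
(shared across datasets; each dataset's conditions provide ligand and
voltage scaling) with L-BFGS-B in log-rate space, box bounds 10⁻³–10⁶ s⁻¹,
and a fixed-seed multi-start (default 4–5 jittered starts).  Standard
errors come from a central-difference Hessian of the negative
log-likelihood in log-rate space (delta-method transformed); a rate whose
curvature is below 10⁻⁶ — e.g. a blocking rate fitted to blocker-free
data — is flagged non-identifiable instead of being given a meaningless SE.

## The dose-series pipeline

Per cell, the blocker-free control recording determines the eight gating
rates by MIL (starting values from the open-dwell mean and an
exponential-mixture decomposition of the closed dwells).  Because C and the
D states are topologically symmetric around O at a single agonist
concentration, the gating fit is identified only up to relabelling; the
fitted generator — not the labels — is what the next stage needs.  Per
(cell, dose > 0), the blocking and unblocking rates are then fitted with
the gating fixed at that cell's control estimates.

Aggregation follows the source analysis exactly: the blocking rate
(k̂₊B·c) is averaged over cells per dose; the least-squares line of those
means against dose gives k₊B with the slope's standard error (the intercept
is fitted and reported, and the through-origin slope is also reported);
k₋B is the unweighted mean of all per-cell, per-dose unblocking rates
± SEM; K_d = k₋B/k₊B with first-order (delta-method) error propagation —
the published ± for K_d is not described, so the delta method is this
package's documented choice.  With two blockade modes, per-fit modes are
labelled fast/slow by unblocking rate (matched across doses by lifetime
ordering), and per-dose rows can be flagged `excluded` to drop them from
aggregation.  Apparent open times are pooled within cells, then averaged
± SEM across cells.

Closed-time histograms are decomposed by EM exponential-mixture fitting in
linear time with deterministic quantile-of-log-duration initialization;
the component count is fixed by the caller or chosen by BIC (scan 1–6);
components with area < 1/n are dropped and the mixture refitted, with the
drop counted.  Display histograms use log₁₀-spaced bins with a square-root
ordinate.

NPo uses the standard definition Σᵢ i·P_o,i over simultaneously-open
levels (the figure defining it in the source is image-only; this is the
conventional reading), with mean open time taken from single-open-level
sojourns.

## Molecular complexity

The Bertz index C(η) + C(E) is computed from the molecular graph with
implicit hydrogens.  Connections are two-edge paths counted on the
bond-order multigraph (a bond of order m is m parallel edges; aromatic
order 1.5), partitioned into equivalence classes by canonical
graph-symmetry atom ranks; C(η) = 2η log₂ η − Σ nᵢ log₂ nᵢ.  C(E) is the
information content of the heavy-atom element distribution
(N log₂ N − Σ n_e log₂ n_e; zero for a pure carbon skeleton).  Published
"Bertz index" values differ between software variants, so cross-compound
comparisons are reported as ratios, which damp those differences; the
test suite cross-checks the scores against an independent implementation
(rdkit's `BertzCT`) without ever substituting it for this one.

The bundled compound table is a reconstruction, and says so: the PQ0–PQ5
structures are assembled from their described composition (octa(ethylene
glycol) backbone, two quaternary ammonium end groups; the middle members of
the series use a plausible homologous QA progression), the tubocurarine
entry is a formula-correct bisbenzylisoquinoline macrocycle, and the
comparator dissociation constants are approximate literature values used
only to place compounds on the affinity axis.

## Problem sizes and numerical choices

The reference end-to-end run uses 3 cells × 4 doses × 3000 events with
full 10 kHz trace rendering (~10⁷ samples per cell) and completes in about
a minute on one CPU; the test suite runs the same pipeline once plus
dwell-level property checks (KS agreement of simulated dwells with the
phase-type distributions, closed-form MLE and ODE-integration likelihood
oracles, two-mode identifiability over 20 replicates, etc.).  Matrix
exponentials in the likelihood use eigendecompositions of the small
within-class blocks, falling back to the scaled forward pass if a density
evaluates non-positive; equilibrium distributions come from the null space
of Qᵀ; EM and all simulations are seeded and deterministic.

## Known limitations

* The missed-event correction is first order; at dead times comparable to
  the fastest dwell scale an exact correction would be needed (the hook is
  `Dataset.dead_time`).
* The gating stage assumes the control condition identifies the gating
  rates; strongly overlapping closed components make those estimates a
  near-equivalent reparametrization rather than the generating values,
  which is sufficient for (and tested against) blockade estimation only.
* No detailed-balance or loop constraints (the canonical schemes are
  trees), no multi-conductance idealization, no baseline tracking, and no
  claim of numerical equality with any particular QuB configuration.
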