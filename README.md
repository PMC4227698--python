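# pegblock

Single-channel kinetics of open-channel block of the muscle nicotinic
acetylcholine receptor (AChR), built around the analysis used to
characterize PEG-based bis-quaternary-ammonium blockers: simulation of
cell-attached patch recordings under an aggregated Markov
gating + sequential-blockade scheme, segmented-k-means (SKM) hidden-Markov
idealization, maximum-interval-likelihood (MIL) estimation of rate
constants, dose- and voltage-dependence analysis, and Bertz
molecular-complexity scoring of the blockers themselves.

It is aimed at ion-channel biophysicists who want a tested, scriptable
version of the QuB-style dwell-time workflow — and a synthetic-data
generator with known ground truth to validate it against.

## The model

Channel gating is a continuous-time Markov chain observed only through
conductance classes.  The canonical scheme is

```
            D1  D2  D3          (desensitized, non-conducting)
             \  |  /
    C  <-->   O   <-->  B       (B: blocker-occluded, non-conducting)
```

with agonist-dependent opening (C→O first order in [ACh]) and sequential
open-channel block: a blocker binds the *open* pore with the bimolecular
rate constant k₊B (µM⁻¹s⁻¹) and leaves it with the unimolecular rate k₋B
(s⁻¹).  Two diagnostics identify this mechanism in dwell-time data: the
apparent mean open time τ_app = 1/(α_total + k₊B·c) falls with blocker
concentration c, and a new closed-time component appears whose *area* grows
with c while its lifetime τ_B = 1/k₋B does not.  The observable dwell
distributions are phase-type (mixtures of exponentials given by the
within-class blocks of the generator matrix Q), and the dwell-sequence
likelihood is

    L = π_e^T · Π_i [ exp(Q_{a_i a_i} t_i) · Q_{a_i a_{i+1}} ] · 1

evaluated with a first-order missed-event (dead-time) correction.  Rate
constants are aggregated across conditions as in the source analysis:
k₊B is the slope of the least-squares line of blocking rate vs. dose, k₋B
the mean unblocking rate over all doses and cells, and K_d = k₋B/k₊B.

## Worked example

```python
from pegblock.pipeline import PipelineConfig, run_pipeline

config = PipelineConfig(doses_uM=[0.0, 5.0, 10.0, 20.0], master_seed=1)
result = run_pipeline(config, "results/02_pq5_run")
mode = result["summary"].modes["single"]
print(f"k+B = {mode.k_plus_B:.2f} ± {mode.k_plus_B_se:.2f} µM⁻¹s⁻¹")
print(f"k-B = {mode.k_minus_B:.3f} ± {mode.k_minus_B_sem:.3f} s⁻¹")
print(f"Kd  = {mode.Kd_uM:.3f} ± {mode.Kd_se:.3f} µM")
```

This simulates three cells × four blocker doses (3000 events each) with the
generating constants k₊B = 15 µM⁻¹s⁻¹ and k₋B = 2 s⁻¹, renders 10 kHz
traces, idealizes them, fits every recording by MIL, and prints

```
k+B = 15.88 ± 0.02 µM⁻¹s⁻¹
k-B = 2.020 ± 0.040 s⁻¹
Kd  = 0.127 ± 0.003 µM
```

i.e. the full pipeline returns the generating constants to within a few
percent (the k₊B uncertainty shown is the residual slope error of the
three-dose line; sampling scatter across seeds is a few percent as well).
The numbered scripts under `analysis/` run the individual study analyses —
synthetic recordings, blockade kinetics, voltage dependence, NPo agonist
activity, and the complexity comparison — each printing what it found and
writing tables under `results/`.

A `pegblock` command-line tool exposes the same stages
(`simulate`, `idealize`, `fit`, `analyze`, `complexity`, `demo`).

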