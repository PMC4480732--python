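# Methods

`pimnet` re-implements, as a tested library, the in-silico analysis chain of a
pan-PIM-kinase inhibitor study design: Bayesian evidence integration for
protein–protein interaction (PPI) prediction around seed kinases, SAM and
k-TSP differential miRNA analysis on a minimal two-class microarray design,
consensus miRNA-target voting with pathway assembly, and the quantitative
readout formulas of MD post-processing and cell/animal assays. Every stage is
exercisable on synthetic data with known ground truth.

## Naive Bayes PPI integration

Each evidence channel `E_i` (interolog mapping, co-expression, domain–domain
interaction, smallest-shared-biological-process similarity) is calibrated
against a positive reference set (PRS) of known interacting pairs and a
negative reference set (NRS):

    TPR = |E_i ⊂ PRS| / |PRS|,   FPR = |E_i ⊂ NRS| / |NRS|,   LR(E_i) = TPR / FPR

Under conditional independence, channel LRs multiply into a composite score
and `O_posterior = O_prior × LR`. A pair is predicted to interact when its
composite LR exceeds a cutoff chosen from the TP/FP-ratio curve.

Choices the underlying method description leaves open, fixed here:

- **Smoothing.** Additive pseudocount `α` (default 0.5) on hit counts and
  `2α` on denominators. Keeps every LR finite and positive; `α = 0`
  reproduces the raw rate ratio but raises on zero NRS hits rather than
  emitting an infinite LR silently.
- **Missing evidence** contributes a neutral factor 1 (consistent with
  conditional independence of unobserved channels).
- **Prior odds** default to `|PRS| / (|universe| − |PRS|)`, the standard
  gold-standard prior; configurable.
- **Strict inequality** at the cutoff ("above" read literally); the edge set
  is therefore antitone in the cutoff.
- **NRS variants.** `Loc`-style negatives pair proteins with differing
  (synthetic) compartment labels, `Ran`-style negatives are uniform
  non-positive pairs. All downstream code is variant-agnostic.
- Binned channels are supported with user-supplied bin indices; the default
  channels are binary because no bin edges are specified for any source.

The ROC AUC is computed by our own trapezoid over (FPR, TPR) with
(0,0)/(1,1) endpoints; tests cross-check it against scikit-learn's
independent ROC routine. An `FP = 0` cutoff yields an explicit `+inf`
TP/FP marker, never a crash; cutoff selection accepts it as qualifying.

## SAM on a 2v2 design

The moderated difference statistic is

    d_i = r_i / (s_i + s0)

with `r_i` the treated-minus-normal mean difference, `s_i` the pooled
standard error, and `s0` a fudge constant chosen by minimising the
coefficient of variation of |d| across windows of the `s` distribution over
the percentile grid {0, 5, …, 100} (a fixed value can be supplied instead).
Features are ordered by `d`; the null expectation at each rank averages the
rank-sorted permuted `d` over all distinct class assignments — enumerated
exactly whenever that number is ≤ 1000, which for a 2v2 design means all 6
assignments. A feature is called when `|d_(i) − expected_d_(i)| > delta`,
up/down by the sign of the difference. The FDR estimate is the median
permutation false-call count (the observed assignment excluded from that
median) over the observed call count, capped at 1 and reported as 0 when
nothing is called; with only 5 informative permutations the estimate is
coarse, and the granularity is printed in the summary rather than hidden.

**Known limitation (measured, not hidden).** With 35 of 70 features
up-spiked and 2 down-spiked at effect 4×SD — the spike-in configuration the
synthetic generator emulates — the complement label assignment mirrors the
dominant up-signal into the negative tail of the permutation null: the
expected order statistic at the most-negative ranks is itself ≈ −1.1 while
the observed down-spike `d` is ≈ −0.9. The two down-regulated features are
therefore structurally masked at any `delta`, capping truth agreement at the
delta matched to the spike count near 35/37 ≈ 94.6 % (measured over 100
seeds; stable across every `s0` policy and for the monotone threshold-
crossing variant of the calling rule). This is a genuine property of a
6-assignment permutation null under strongly asymmetric differential signal,
and it is what passing or failing the spike-recovery check shows; real
designs with more than two samples per class do not share this ceiling.

## Hierarchical clustering and k-TSP

Called features are clustered by average linkage (cluster distance = mean
pairwise distance), with 1 − Pearson correlation as the default metric (the
convention of the classic expression-clustering tools) and Euclidean
available. The agglomeration is delegated to `scipy.cluster.hierarchy`; a
brute-force agglomeration oracle in the tests verifies merge heights. A
constant feature has no defined correlation distance and raises an error
naming the feature. Trees export to Newick.

k-TSP scores every feature pair by

    Δ_ij = | P(X_i < X_j | treated) − P(X_i < X_j | normal) |

estimated by within-sample comparison frequencies; ties contribute to
neither probability. Δ-ties are broken by the average within-sample
rank-difference score, then lexicographically; the top `k` feature-disjoint
pairs are selected greedily. Because only within-sample orderings enter, the
scores are invariant under any strictly increasing transform of the matrix.

## Consensus targets and pathway triples

A miRNA→target edge is retained when at least `min_sources` of the (up to)
nine prediction sources agree; the "high conforming" threshold is nowhere
standardised, so the default is 5 — a simple majority of 9 — and fully
configurable. Conforming miRNA→kinase edges are crossed with the kinase's
predicted partners carrying a chosen annotation (default `apoptosis`),
yielding deduplicated, deterministically ordered
(miRNA, kinase, downstream) triples. Direction consistency between miRNA and
target expression changes is *not* required for a triple; the join is purely
structural.

## Readout formulas

- MM/GBSA bookkeeping: `ΔG_sol = ΔG_sol,ele + ΔG_sol,nopol`,
  `ΔG_ele = ΔE_int,ele + ΔG_sol,ele`,
  `ΔG_bind = ΔE_int,ele + ΔE_int,vdw + ΔG_sol,nopol + ΔG_sol,ele + (−TΔS)`.
  The package ships the published component table for the PI003–PIM1/2/3
  complexes; the aggregation report prints recomputed totals next to printed
  ones. For PIM2 the component sum reproduces the printed −38.81 kcal/mol
  exactly; for PIM1 and PIM3 the sums (−43.47, −41.90) differ from the
  printed totals (−43.69, −42.12) by 0.22 kcal/mol each — likely a rounding
  or entropy-term inconsistency in the source table. The discrepancy is
  reported, never silenced or "corrected".
- Snapshot schedule: `floor(span_ps / interval_ps)`, start-exclusive /
  end-inclusive — the unique convention under which a 1–10 ns window at
  20 ps yields 450 snapshots.
- Hydrogen-bond occupancy: percent of frames with distance ≤ 3.5 Å AND angle
  ≤ 30° (both configurable; geometric criteria are a field convention, not
  printed anywhere authoritative for this system); means are over qualifying
  frames only.
- RMSD equilibration: the earliest time `t` (leaving at least one `window`
  of trajectory) from which every value deviates from the tail mean by less
  than `tol` (default 0.5 Å, matching the stability the narrative states for
  the equilibrated phase; window default 100 ps). A centred rolling-mean
  criterion was rejected: a slow ramp tracks its own local mean and would be
  declared equilibrated from frame 0.
- MTT inhibitory ratio
  `(OD_control − OD_sample) / (OD_control − OD_blank) × 100` (affine
  invariant in the three ODs) and tumor volume `V = L × W² / 2` (dimensions
  swapped into order when given reversed).

## Synthetic data generator

The generator emulates the statistical structure each stage assumes; its
defaults are the study conditions:

- **Reference sets & channels**: 200-protein universe, 500/500 PRS/NRS (up
  to 5000/5000 for calibration checks), 4 binary channels at target LRs
  8/3/5/2 with PRS coverages 0.4–0.6 — a channel fires on PRS pairs with
  probability `coverage` and on NRS/unknown pairs with `coverage/LR`, so the
  empirical LR converges to the target (±15 % verified at 5000/5000).
- **Expression**: 70 miRNA features × (2 treated + 2 normal) samples,
  background N(0, 0.5²) log2 units, 35 up- and 2 down-spikes at effect 2.0
  log2 units (4×SD).
- **Target table**: 9 sources; a tier map assigns each miRNA an exact
  source-support count.
- **Readouts**: 1000 frames at 10 ps; hydrogen-bond geometry satisfying the
  criteria in exactly `round(occ% × n_frames)` frames (default 99.6 %);
  RMSD ramping to a 1.2 Å plateau at 1 ns, with pre-equilibration
  fluctuation SD 0.6 Å (chosen above the 0.5 Å stability criterion so that
  "unequilibrated" is a detectable state) and equilibrated SD 0.1 Å; an
  energy bundle that satisfies the component identity exactly.

Determinism: each generator op draws from its own RNG stream derived from
the master seed by a fixed op offset; identical configs give byte-identical
serialized outputs. Ground truth travels alongside the data and is read only
in test assertions.

What the synthetic data does **not** emulate — and hence what passing tests
do not show: real interaction-database biases and overlap structure,
microarray normalisation artefacts and probe-level noise, correlated
evidence channels (the generator's channels are conditionally independent by
construction, so the naive Bayes assumption holds exactly), sequence-driven
miRNA target-site structure, and genuine MD force-field behaviour. Results on
real data depend on how far those assumptions hold.

## Problem sizes

Default test and acceptance runs use a 200-protein universe (≤ 19 900 candidate
pairs), 5000/5000 reference pairs for calibration recovery, 70 × 4 expression
matrices over 100 seeds for spike recovery, 200 null matrices for FDR
control, and 1000-frame readout series — sizes at which the exact
enumeration and brute-force oracles in the test-suite remain exact.
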