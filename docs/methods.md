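# Methods

## Model and assumptions

The simulator operates on a signed directed graph `G(V, E)` with edge
weights `w ∈ {+1, −1}` (activation / inhibition) and treats each node as
a three-state random variable: activated, inhibited, unchanged. The
state distribution under an input `I` (a direction `v ∈ {+1, −1}` per
deregulated node) is estimated empirically by a `T`-repetition
Monte-Carlo loop; within each repetition the network response is linear
and instantaneous (a steady state, not a time course). The model
assumes interactions are adequately summarised by a sign, that a node
divides its influence evenly among its outgoing interactions, and that
input deregulations are statistically independent across nodes unless
explicitly grouped (see *Dependent inputs*).

## Synthetic log-fold-changes

Input magnitudes are drawn per step from a rectified Gaussian
`max(0, sd·rN + mean)` for up-regulation and `min(0, sd·rN − mean)` for
down-regulation, `rN` a standard normal. Defaults `mean = 5`,
`sd = 2` (log2 units) reflect the empirical spread of tumour-vs-normal
fold changes; both are exposed (`LogFCParams`, CLI `--logfc-mean/--logfc-sd`).
The wrong-signed Gaussian tail is mapped to exactly 0 (a *rectified*,
not a resampled-truncated, normal), so an up-regulated node draws a
zero LogFC with probability `Φ(−mean/sd) ≈ 0.6%` and then tallies as
"unchanged" — the zero is propagated as-is and classified by the sign
function like any other value.

Standard normals come from the Marsaglia polar method. The stream is
buffered in generation order, so scalar and vectorised consumption give
identical sequences; one seedable stream serves a whole run, consumed
in a documented order (input nodes sorted by id, within steps in
sequence), which makes every run bit-reproducible from its seed.

## Propagation

Perturbation is the fixed point of
`P(i) = ΔE(i) + Σ_{u∈U(i)} w(u,i)/W(u) · P(u)` with
`W(u) = Σ_{d∈D(u)} |w(u,d)|`. Two normalisation choices deserve note:

* the denominator is the **upstream** node's total outgoing weight (the
  sender splits its signal), the convention of topology-based pathway
  perturbation analysis; normalising by the receiver's downstream set
  has no propagation semantics;
* the denominator uses absolute weights: with ±1 weights a signed sum
  could vanish for a node with balanced out-edges and divide by zero —
  the denominator measures interaction bandwidth, the sign belongs in
  the numerator.

The solver is a Jacobi iteration from `P = ΔE` (simultaneous update,
hence order-independent and reproducible), stopping when the max-norm
step change drops below `tol` (default 1e−6, cap 2000 sweeps). On an
acyclic graph this terminates exactly after longest-path-many sweeps.
Cycles can push the operator's spectral radius to 1 or above (e.g. a
two-node feedback loop with unit out-degrees), where no iterative
steady state exists; the solver then falls back to the minimum-norm
least-squares solution of `(I − M)P = ΔE` and flags the result
`converged = False`. `propagate_exact` exposes that direct solve as an
independent oracle. Within `run_simulation`, steps that needed the
fallback are counted; if more than 10% of steps diverge the run aborts
with a diagnostic rather than returning tallies dominated by flagged
values. Non-finite ΔE entries are rejected.

## Scores

Per node, states are tallied by `sign(P)` with **exact zero** as the
unchanged state — no epsilon, since propagation is exact arithmetic on
the inputs and an epsilon would silently reclassify small real effects.
Probabilities are counts over `T`; the Activity Score is the signed
log2-odds of the majority state, 0 when "unchanged" wins or no state
exceeds ½. When the majority count is exactly `T`, the odds are
continuity-corrected (`T → T − ½`), capping |score| at
`log2((T − ½)/½)` — finite, still ranked, and growing with `T` as
confidence should. Default `T = 1000`.

Pathway records apply the identical tally → probability → score
pipeline to a per-step pathway perturbation, by default the **sum** of
member-node perturbations (linear, superposition-respecting; `mean`
available). The aggregation rule is a declared design choice — no
canonical definition exists for pathway-level aggregation here — so it
is configurable and recorded in every output header.

## Significance

`R` random inputs (default 1000) preserve the direction multiset and
draw node identities uniformly without replacement from the non-virtual
nodes of the *already-reduced* graph, keeping the non-expressed
constraints of the observed run; each is simulated with `T_inner = 100`
(default) steps. The p-value is the exceedance fraction of random
scores over the observed score. Two comparisons are exposed:

* `abs` (default): `|A_random| > |A_observed|` — two-sided semantics,
  so strong inhibition is as significant as strong activation;
* `raw`: the literal one-sided `A_random > A_observed`, under which a
  strongly inhibited node would always look null.

No add-one smoothing is applied (`p = r/R`, so `p = 0` is attainable).
q-values follow Storey's procedure with `π0` estimated at a single
`λ = 0.5` (`π0 = min(1, #{p > λ}/((1−λ)m))`) — stable at the small `m`
of desk-scale graphs, and forcible (e.g. `π0 = 1` recovers
Benjamini–Hochberg). Correction is applied jointly across nodes and
pathways, matching the single output table.

### Null calibration

The suite verifies that when the "observed" input is itself a random
draw, the p-value of a scored node is uniform (KS test, 200
repetitions, `R = 50`, `T_inner = 20`). Two points make this test
meaningful. First, it uses the `raw` comparison: under the symmetric
null the score distribution is sign-symmetric and the one-sided
exceedance is its natural rank statistic, while the `abs` comparison
folds the distribution and concentrates ties (measured mass ≈ 0.1 at
`p = 0`, failing KS at any fixture we tried — an intrinsic property of
magnitude exceedance on heavily tied discrete scores, not a defect of
the implementation). Second, the fixture is built for score spread: a
star of activating sources feeding a scored hub, half directly (path
coefficient 1) and half also leaking to a side node (coefficient ½),
with input multiset `{+1, −1}`. Every candidate pair then produces a
genuinely stochastic per-step sign at the hub, so null scores spread
over many tally values instead of piling at the capped extremes.

## Dependent inputs

A dependency group `{(V_k, v_k)}` is modelled by inserting a virtual
node `V*` with one edge `V* → V_k` of weight `v_k` per member and
replacing the members' directions by `V* = +1`. One LogFC draw per step
then drives the whole group coherently. Virtual nodes are excluded from
randomization draws. A group needs ≥ 2 members (a singleton is
equivalent to a plain input and is rejected as likely user error; the
equivalence itself is asserted in the suite).

## Non-expressed genes

Nodes declared non-expressed are **deleted** with their incident edges
before simulation, rather than clamped to zero: deletion also shrinks
the out-degree denominator of their upstream neighbours, which clamping
would not, and matches the intent of removing the node from the
computation entirely. The evaluation module supplies the detection
rules (sequencing: mean count < 10; microarray: mean below the
10th-percentile mean, linear-interpolation percentile).

## Benchmark arithmetic

Observed log-fold-changes are ternarized at `|LogFC| ≥ 0.6` (boundary
inclusive — only values strictly *lower* than the threshold are
non-altered); predictions take the sign of the Activity Score. The
altered-class table counts the four sign-pair cells (TP: up/up, TN:
down/down, FP: up/down, FN: down/up); genes predicted unaltered but
observed altered fit none of them and are reported separately as
`missed_altered`. The non-altered class counts predicted-quiet (TP)
vs predicted-altered (FN). Rates use the standard formulas
(PPV = TP/(TP+FP), Sensitivity = TP/(TP+FN), Specificity = TN/(TN+FP),
FNR = FN/(FN+TP)); an empty denominator yields NA, never 0, so averages
across datasets are not biased by degenerate tables. Accuracy is
fraction-correct over all scored genes.

## Synthetic data

`random_network` draws Erdős–Rényi-style signed digraphs (independent
edge probability, optional acyclicity by index ordering, inhibition
fraction per edge) with pathways as BFS-grown connected subsets, so
pathway aggregation sees overlapping membership. `toy_cascade` is a
branching activating tree whose steady state is `x / branching^depth`
in closed form, used as an exact oracle. `synth_observed_logfc`
produces pseudo-observed tables (one propagated draw plus additive
Gaussian noise). These generators exercise every code path but do not
emulate real pathway topology — no hubs/degree heavy tails, no motif
structure, no correlated noise — so green tests demonstrate
correctness of the algorithms, not predictive accuracy on real
networks or expression data.

## Problem sizes and defaults

Library defaults follow the method's standard operating point
(`T = 1000`, `R = 1000`, `T_inner = 100`, `tol = 1e−6`,
`max_iter = 2000`, LogFC (±5, 2), threshold 0.6). The test and
acceptance workloads are desk-scale by design: graphs of 2–50 nodes,
`T` up to 1000, randomization passes with `R ≤ 200`, and 10⁶-draw
moment checks — sizes chosen so the full suite characterises the
implementation in seconds while exercising the same code paths as a
full-scale run.

## Known limitations

* Linear propagation with even splitting ignores kinetics, saturation
  and combinatorial logic (AND/OR regulation).
* Networks whose feedback structure is non-contractive get
  least-squares values flagged `converged = False`; interpretation of
  those magnitudes is up to the user.
* The pathway aggregation rule (sum) is a convention; pathway scores
  are comparable within a run, not across aggregation choices.
* p-values are discrete multiples of `1/R`; at small `R` the magnitude
  comparison concentrates mass at `p = 0` for tied scores.
* Identifier handling is opaque and case-sensitive; no cross-species or
  cross-database id mapping is attempted.
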