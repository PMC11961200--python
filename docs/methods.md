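# Methods

## Model

A microbial community of `N` taxa is modelled as an undirected signed
graph `G` with `M+` synergistic (`+1`) and `M-` competitive (`-1`)
edges, equivalently a symmetric interaction matrix `I` with entries in
`{-1, 0, +1}` and zero diagonal.  Presence/absence states
`s ∈ {0,1}^N` evolve synchronously under the threshold ("majority
vote") rule: node `i` becomes 1 when its signed input field
`h_i = Σ_j I_ij s_j` is positive, 0 when negative, and keeps its state
at exactly zero.  Updating each of the `2^N` states once yields a
functional graph whose fixed points and cycles form the attractor set
`A`; the package's working assumption is that binarized abundance
patterns observed in a community are (a subset of) these attractors.

Attractor enumeration is exact and exhaustive: states are encoded as
integers (node 0 = least-significant bit), the successor map is built
by one vectorized matrix product over all `2^N` states, and the states
lying on cycles are obtained by `N`-fold squaring of the successor map
(`f^(2^N)` maps every state onto its cycle).  The default enumeration
cap is `N ≤ 20`; all study-scale analyses here use `N = 10`.  The
all-zeros state is always a fixed point and is kept in attractor sets;
pipelines on observed data can drop it (`drop_empty`) because the empty
community is unobservable.

## Localizing edge changes: D, C, B, |E| and SN

For two attractor sets `A` (reference) and `A*` (current), the
destroyed attractors are `cD = A \ A*` and the created ones
`cC = A* \ A`.  Each destroyed attractor is matched to *all* its
Hamming-nearest states in `A*` (ties kept — every minimizer contributes
a row), and the element-wise differences are summed over rows into the
length-`N` array `D`; analogously `C` (nearest in `A` minus created)
and `B` (destroyed minus nearest created).  Taking absolute values of
each difference row *before* the row sum gives `|D|, |C|, |B|` and
their total `|E|`.  Sorting nodes by descending `|E|` (ties by
ascending index, for determinism) yields the sorted-nodes vector SN;
the endpoints of a changed edge concentrate at its front because their
columns flip most often between matched attractor pairs.  When the two
attractor sets are identical SN is undefined and the index order is
returned with a warning flag; inside the refinement loop this cannot
occur because perfect overlap terminates first.

## ESABO seeding

The initial network guess scores each taxon pair by the entropy shift
of the AND-combined binary columns.  For columns with `a` and `b` ones
over `n` patterns, the null model holds the margins fixed (equivalent
to shuffling one column), so the co-occurrence count is
`k ~ Hypergeometric(n, a, b)`.  The null mean and standard deviation of
the binary entropy `H(k/n)` (base-2; `H(0)=H(1)=0`) are computed by
exact summation over that distribution, and the score is
`(H_obs − μ0)/σ0`.  This fixed-margin null was chosen over a
`Binomial(n, ab/n²)` null because it is the exact distribution of the
shuffle experiment: it matches an exhaustive permutation oracle to
machine precision and makes scores mean-0/sd-1 calibrated under column
shuffles (the binomial null over-disperses slightly by ignoring the
margin conditioning).  Constant columns carry no co-occurrence signal;
their pairs are flagged NaN and excluded from selection.  Edge
selection is either count-based (top `n_pos`/bottom `n_neg` scoring
pairs, ties at the boundary broken by ascending pair index; "random"
counts draw uniformly from a configured range, default 1–10) or
threshold-based.

## EDAME refinement

Starting from the seed network, the loop repeatedly (i) enumerates the
current network's fixed points and their Jaccard overlap `JI` with the
target's stationary states,
(ii) computes SN, (iii) builds node lists from the front of SN — the
first two nodes plus the 3rd, 4th, … node, then lists of size four,
five, … up to `N` — and turns each list into candidate moves: every
unordered pair of its node pairs, set to every joint edge-state
combination over `{-1,0,+1}²` except the current one, (iv) accepts the
best JI-improving candidate of the first list containing one, and
(v) on a sweep with no improving candidate anywhere, registers a
failure and restarts from the seed network with a freshly randomized
edge-pair exploration order.  Search stops at `JI = 1` (success), after
`failure_limit` failed attempts, or when an attempt exhausts its
`iteration_limit` of accepted moves (also a failure); the best network
seen is returned.

The matching objective deliberately uses *stationary* states only.  An
observed pattern set contains stable community compositions; transient
2-cycles, which synchronous symmetric threshold dynamics spawn freely
in intermediate candidate networks, have no observable counterpart,
and penalizing their states leaves the search stranded in local optima
(measured: the success rate saturates near 44% on the study ensemble
and does not respond to more restarts, against ~50% with markedly
closer final networks under fixed-point matching).  The general
comparison utilities (`attractor_jaccard`, the D/C/B/|E| arrays) keep
full state-set semantics, cycles included state-by-state.

Numerical choices: JI comparisons use exact integer cross-multiplied
fractions, so acceptance (`>`) and termination (`== 1`) involve no
floating-point tolerance.  Fixed-point sets of candidate networks are
memoized by interaction-matrix key for the duration of a run.  Within
one node list all candidates are evaluated and the *best* improving one
is taken ("sequential edge correction"): accepting the first weak
improvement instead lets the search drift through long chains of
marginal moves — in calibration runs a single rewired edge then took
~20 accepted moves instead of a handful.  Moves may disconnect the
network (connectivity is a property of the simulated ground truth, not
of the search space); results carry a connectivity flag.  Two
deliberate consequences of the restart-from-seed semantics: the
accepted-move JI sequence is strictly increasing *within* an attempt
(not across attempts), and an attempt that fails with zero accepted
moves proves every further restart would fail identically (the
improving-move set of a fixed network is order-independent), so the
remaining failures are charged at once.

Default limits are `iteration_limit = 20` and `failure_limit = 20`,
the calibration operating point; the limits are per-attempt, so hard
seeds get up to `failure_limit` independent randomized searches.

## Synthetic study conditions

The simulation benchmarks define the study conditions and are not
tuned per run:

* **Random networks**: uniform edge sample with exactly `M+` positive
  and `M-` negative signs, rejection-sampled until connected
  (adequate at `N ≈ 10`).  Study scale is `N = 10`, `M+ = M- = 10`.
* **Rewiring**: a move keeps a uniformly chosen endpoint (anchor) of a
  uniformly chosen edge, preserves the sign (so `M+`/`M-` are
  invariant), forbids multi-edges and disconnection, and never undoes
  an earlier move of the same call — `n` rewires are exactly `2n`
  signed-edge differences.
* **Calibration** (`run_calibration`): 50 experiments per rewire count
  in the test suite; the same ground truth is shared across rewire
  counts within an experiment (paired design), so success-rate
  comparisons between rewire counts are not confounded by the draw.
* **Method comparison** (`run_method_comparison`): 100 networks at
  study scale (25 in the test suite to bound runtime); each method
  reconstructs the network from the attractor bit-matrix alone.
  Refinement runs with a non-binding iteration limit of 100 per
  attempt (successful trajectories from ESABO seeds stay below ~40
  moves) and 20 restarts.
  ESABO/EDAME receive the true edge counts (top-10/bottom-10); the
  generic baselines (mutual information, Pearson, phi) keep pairs
  significant at `p < 0.05` under each statistic's canonical test
  (t-test for Pearson; `n·phi² ~ χ²(1)` for phi and for MI, which on
  2×2 tables is a monotone transform of `|phi|`, with MI's edge sign
  taken from phi).  Count-mode selection for baselines is available
  but not used for the headline comparison: handing the generic
  methods the true edge counts makes them artificially competitive
  with the count-free significance convention used in practice.

What the synthetic generator does *not* emulate: incomplete attractor
sampling (real surveys observe a subset of attractors), zero-inflated
abundances (absence vs. undersampling), compositional noise, and
directed interactions.  Passing these benchmarks therefore shows the
machinery is correct and well-calibrated on complete attractor sets,
not that real cohort networks are recovered at the same fidelity.

## Microbiome pipeline

Observed tables are taxa × samples relative abundances.  Species rows
are summed to phyla via a user-supplied two-column map (no taxonomy
database is bundled), entries binarized at a presence threshold
(default 0, i.e. strict presence/absence — the threshold is exposed
because zero-inflation may warrant a positive value), and the unique
sample patterns become a fixed-point-only attractor set for inference.
Cohort summaries weight each study's edges by the attractor JI reached
at the end of refinement; the quality index is the ratio of mean
pairwise signed-edge Jaccard within cohorts to the mean across
cohorts (a prose-level reconstruction; an all-but-identical cohort
set with zero across-cohort similarity is flagged and reported as
infinity).  A thin Spearman-correlation baseline (p < 0.05, magnitude
threshold) operates on the non-binarized table.

## Known limitations

* Exhaustive `2^N` enumeration restricts practical use to `N ≲ 20`
  (phylum-level communities); no sampling-based attractor estimation.
* The refinement loop is a greedy local search: it can stall in local
  optima of the attractor-overlap landscape, and a network with the
  target attractor set need not be the generating network (though it
  usually is at study scale).
* Incomplete attractor sets — the typical real-data regime — are
  interpreted literally as the full target set; missing patterns bias
  the refinement.
* Cyclic attractors are compared state-by-state, a choice that
  degrades gracefully in the fixed-point-dominated regime but has no
  orbit-level matching.
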