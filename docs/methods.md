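# Methods

## Problem and pipeline

Pre-miRNA identification is posed as binary classification of ~60–130 nt
hairpin sequences: true precursors vs pseudo-hairpins that match them in
length and composition. The pipeline is

1. feature extraction — 87 profile + 24 structure-graph + 480
   Hilbert–Huang features, 591 in all;
2. mRMR ranking and incremental feature selection (IFS);
3. an RBF-kernel SVM evaluated by the jackknife (leave-one-out) test.

## Profile features

The input PSSM is an L×5 integer score matrix over (A, C, G, U, −); scores
are 10·ln(observed/background frequency) rounded to integers, produced by
an external iterative profile search (running that search is out of scope;
the matrix is an input, or a synthetic stand-in). Each score is mapped
through `2^(0.1 s)` — positive for any integer score — and rows are
normalised to the frequency matrix. Because a constant additive shift of
all scores multiplies each exponentiated row by a constant that the
normalisation removes, every profile feature is shift-invariant (property-
tested).

The consensus sequence is the per-position argmax over the four nucleotide
columns only; the gap column can never win. Argmax ties break to the
lowest alphabet index (A < C < G < U) for determinism. The consensus
composition entropy (ECS) is computed over the four nucleotides with the
0·ln 0 := 0 convention, so ECS ∈ [0, ln 4]; the profile entropy (EFM)
averages the five-column row entropies, EFM ∈ [0, ln 5]. Both use natural
logarithms. Consensus k-mers (k = 2, 3) are relative frequencies over the
L−1 and L−2 windows rather than raw counts, so features are comparable
across the length range.

If a sequence has no PSSM, a one-hot pseudo-profile (+5 match / −5
elsewhere) is synthesised and the event logged; its consensus is the
sequence itself. This keeps extraction total rather than partial.

PSSM files are read in two dialects, sniffed from the first non-blank
line: the standard ASCII layout of profile-search tools, and a headered
TSV used by the synthetic generator. A 4-column file (no gap column) is
accepted; the gap column is filled with the row minimum so it cannot
dominate normalisation.

## Structure-graph features

The dot-bracket structure becomes a simple undirected graph: nodes 1..L,
backbone edges {i, i+1}, one edge per base pair. The 24 descriptors (the
`net.*` block) are computed with igraph, with these conventions:

* variances are population variances (ddof = 0);
* cocitation and bibliographic coupling are means over ordered node pairs
  i ≠ j — on an undirected graph the two are identical by construction,
  and both are kept so the block names the two classical coupling
  measures;
* local transitivity of degree-<2 nodes is 0, not NaN;
* girth of an acyclic graph is encoded as 0 to keep features finite;
* modularity is the greedy agglomerative (fast-greedy) maximisation,
  which is deterministic;
* the hub score is computed as eigenvector centrality — the unique Perron
  vector of the adjacency matrix — via a dense symmetric eigensolver. On
  undirected graphs the hub-score concept reduces to exactly this; the
  A·Aᵀ formulation is degenerate on bipartite graphs (any unpaired
  sequence gives a path graph), and iterative solvers are not
  bit-reproducible.

All descriptors are cross-checked in the test suite against brute-force,
first-principles computations (explicit shortest-path enumeration for
betweenness, explicit subset enumeration for motif counts, explicit
peeling for coreness, a dense eigensolver for hub scores, vertex-removal
connectivity for articulation points) on graphs of up to 12 nodes.

When no structure is supplied, a fallback folder predicts one by base-pair
maximisation (Nussinov dynamic programming) over Watson–Crick and GU
wobble pairs with a minimum hairpin loop of 3 unpaired bases and a
deterministic traceback. This is a combinatorial fold, not a
thermodynamic minimum-free-energy fold: it tends to over-pair random
sequence. Users with a thermodynamic folder supply its dot-bracket output
instead (`--structures`). Pseudoknots (extra bracket levels) are rejected.

## Hilbert–Huang features

Fifteen dinucleotide property maps — enthalpy, entropy and free energy in
two variants each (two nearest-neighbour parameter sets), hydrophilicity
in two variants, and the base-step geometry/stacking parameters rise,
roll, shift, slide, stacking energy, tilt, twist — are shipped as a
versioned TSV (`stemloop/data/dinucleotide_properties.tsv`), curated from
the standard RNA nearest-neighbour thermodynamic literature and
dinucleotide property compilations. A width-2, step-1 window turns a
length-L sequence into 15 series of length L−1. The table can be
overridden (`--property-table`).

Empirical mode decomposition uses cubic-spline envelopes through the local
maxima and minima, with 2 extrema mirrored past each boundary; sifting
stops at the Cauchy criterion SD < 0.2 or after 50 sifts; decomposition
stops when the residual is monotonic or lacks two maxima/minima, or at 10
IMFs. These are the standard defaults of the EMD literature. The residual
is defined by subtraction, so reconstruction is exact to floating point
(tested < 1e-8 relative on all fixtures). Constant series (homopolymers)
short-circuit to zero IMFs, making all 480 features zero — a documented
degenerate case.

Per series, the first 8 IMFs (a cap motivated by the ~6 IMFs typical for
these series lengths; absent IMFs contribute zeros) each yield 4
statistics from the analytic signal (discrete Hilbert transform): mean and
variance of instantaneous amplitude with 5 samples trimmed per edge
(end-effect suppression), mean instantaneous frequency from the one-sided
unwrapped-phase difference in cycles/step with the endpoint samples
excluded, and the IMF's fraction of the input series' energy. A planted
pure tone's frequency is recovered within 2% (tested). The exact
32-statistic scheme is this package's frozen reconstruction of the
"32 features per series" design; it is documented so downstream numbers
are self-consistent, but equivalence with any other implementation's
per-series feature set cannot be asserted.

Energy fractions are only approximately a partition of unity: EMD is not
exactly orthogonal. Measured leakage is ~2% on a two-tone fixture and can
reach tens of percent on series dominated by a DC offset, consistent with
orthogonality indices reported for sifting EMD; the tests assert the
two-tone partition to within 10% rather than to machine precision. The
completeness (reconstruction) invariant, by contrast, is exact.

## Feature selection

Relevance and redundancy are plug-in mutual information values in nats
between 3-bin discretised features (edges at mean ± one standard
deviation, the canonical mRMR discretisation) and the class labels.
Ranking is the greedy difference scheme: step 1 maximises I(f, y); each
later step maximises I(f, y) − mean_{g∈F} I(f, g) over the not-yet-chosen
features, with ties broken by the frozen column order. The full pairwise
MI matrix is computed once via indicator-matrix products (591² pairs in
about a second); the tests verify entry-level equality with a per-pair
reference and the whole greedy ordering against an independent
brute-force oracle.

IFS evaluates nested prefixes S_k of the ranking by jackknife accuracy
and keeps the best prefix (smallest k on ties). The exhaustive sweep is
quadratic in cost; `--ifs-step s` evaluates every s-th prefix (the full
set and k = 1 are always included) for desk-scale runs. The optimal k is
data-dependent by design.

## Classifier and evaluation

The SVM uses the RBF kernel exp(−γ‖x−x′‖²). Features are z-score
standardised per column, fit on training rows only — including inside
every jackknife round, so no statistics leak from the held-out sample.
Standardisation is on by default (`--no-scale` disables): the 591 features
mix entropies, counts and energies whose scales differ by orders of
magnitude, and the RBF distance is scale-sensitive.

The default kernel width is the `scale` heuristic γ = 1/(d·Var(X)). A
fixed small-dimension optimum (such as the recorded presets in
`classify.PRESETS`) applied to hundreds of standardised features drives
γ‖x−x′‖² into the tens, the kernel underflows to zero, and leave-one-out
evaluation degenerates into an anti-majority vote — an instructive failure
mode the test suite pins down. For real use, (C, γ) should come from
`grid_search`, which sweeps the standard coarse grid C ∈ 2^{−5..15},
γ ∈ 2^{−15..3} by seeded stratified 5-fold inner cross-validation with
ties resolved to the smallest C then smallest γ.

Metrics come from the pooled jackknife confusion matrix: Sn = TP/(TP+FN),
Sp = TN/(TN+FP), Acc, and Mcc with the convention Mcc := 0 when a
denominator factor is zero. No class rebalancing is applied by default;
the synthetic corpus is balanced by construction.

## Synthetic benchmark

`SynthConfig` defaults describe the corpus the tests and the acceptance
script use: 50 positives + 50 negatives, lengths uniform in 60–130 nt, a
planted stem of 25 bp (typical of precursor stems) with a 4–8 nt loop and
random flanks, profile noise as Dirichlet perturbation (concentration
0.05) around one-hot rows converted to integer log-odds against a uniform
background (truncated toward zero). Positives carry the planted
dot-bracket; negatives are Altschul–Erickson dinucleotide shuffles of the
positives — identical length and dinucleotide multiset — folded by the
Nussinov fallback. All randomness flows from the single seed.

What this emulates: the hard-negative design where composition and length
carry no signal, so classification must exploit structure and sequence
order. What it does not emulate: real evolutionary conservation (the
PSSMs are noise around the sequence itself, not alignments), thermodynamic
folding, miRNA family structure, or class imbalance. Passing the
end-to-end test therefore shows the pipeline recovers a planted
structural signal under matched composition — not that it attains any
particular accuracy on biological benchmarks, which depend on external
databases.

On this corpus (seed 0), the full protocol — grid-searched (C, γ), mRMR,
IFS with step 10 — gives a full-591-feature jackknife accuracy of 0.89 and
a post-selection accuracy of 0.99 at k = 10; the selected prefix is
dominated by structure-graph descriptors. Shuffling labels collapses
accuracy to chance (0.50–0.54, inside the n = 100 binomial 95% null band).
These are the numbers the acceptance script recomputes.

## Numerical and design choices

* 0·ln 0 := 0 everywhere an entropy is computed.
* The consensus-composition entropy is summed over the four nucleotides;
  a fifth (gap) term would be vacuous since the gap never wins the argmax.
* Coordinates are 0-based internally; file formats and reports are
  1-based.
* The 24-descriptor list is a frozen reconstruction: the descriptor
  families (degree, path lengths, betweenness, coreness, constraint, hub
  score, coupling counts, transitivity, density, modularity, motifs,
  articulation points, girth, eccentricity) with A-/V-/Var-/N- summary
  prefixes. It is versioned with the package so results are
  self-consistent.
* Model archives are JSON: schema, scaler parameters, support vectors,
  dual coefficients, intercept and the resolved numeric γ; prediction
  evaluates the dual decision function directly, so archives do not
  depend on solver internals.
* Problem sizes in tests and the acceptance script (50+50 corpus, IFS
  step 10, ≤12-node oracle graphs, 256-sample signal fixtures) were chosen
  to keep a full run at interactive desk scale on a single CPU.

## Known limitations

* The fallback folder maximises pair count, not free energy; its folds
  over-pair random sequence relative to a thermodynamic model.
* Plug-in MI with 3-bin discretisation is biased at small n; relevance
  values near zero are estimator noise (tested against the analytic bias
  scale).
* Modularity depends on the chosen greedy algorithm; other community
  algorithms give different (also valid) values.
* The dinucleotide property table is a curated literature compilation;
  other compilations will shift the `hht.*` block numerically.
* Jackknife on n rows refits the SVM n times; cost grows quickly past a
  few hundred rows. Use `--ifs-step` for the selection sweep.
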