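# Methods

## Model and procedure

`idscore` scores every (family, column) pair of a classified superfamily
alignment for *differential conservation*: conservation within the family of
interest (FOI) that is absent, or different, in other families.  The
procedure is a pairwise tournament.  For each FOI, each alignment column is
compared with the corresponding column of all `F` families (the nFOIs,
including the FOI itself); each comparison produces one binary decision per
measure; the per-measure score of a column is the fraction of the `F`
decisions that came out positive; and the integrated ID_score is a fixed
linear combination of the per-measure scores.  Because the self-comparison
is included in the denominator and is structurally zero (a profile can never
be differentially conserved relative to itself), scores live in
`[0, (F−1)/F]`.

Pairwise comparison, rather than FOI-versus-rest pooling, is what lets a
site shared with a few close relatives still register as family-specific in
the majority of comparisons, while globally conserved sites register in
none.

### Column profiles and the low-frequency filter

All measures consume per-family column profiles over a fixed 22-symbol
alphabet (20 amino acids, `X`, gap).  Before any measure is computed,
symbols whose within-family frequency at the column is strictly below
`min_freq` (default 0.085) are disregarded — a correction for alignment
inaccuracy.  Choices that the original formulation leaves open, made here
and exposed as configuration:

* The filter applies to *every* symbol, gaps and `X` included, with the
  full family size as denominator.
* Frequencies of the retained symbols are renormalized to sum to 1 before
  entropies are computed; without renormalization, entropies would not be
  comparable across families of different sizes or filter losses.
* The pooled FOI+nFOI category is the sum of the two *post-filter* count
  multisets, not re-filtered after merging.
* Comparison with the threshold is strict: frequency < 8.5% is removed,
  exactly 8.5% retained (the comparison carries a 1e-9 absolute tolerance so
  that exact-ratio cases such as 17/200 are not lost to float rounding).

An *empty* post-filter profile (possible when every symbol is rare) is
treated as uninformative: every decision involving one is 0 under the
default `empty_profile_policy="zero"`.  The `"literal"` policy instead takes
empty profiles at face value (vacuously 10 conserved properties, entropy 0),
which makes an empty FOI profile look maximally conserved — kept available
because it is what the decision rules state when read literally, but not the
default.  Similarly, a gap-only FOI profile literally conserves all ten
properties (gaps carry none); `mask_gap_columns=True` zeroes such columns'
decisions, off by default to preserve the literal rules.

### The three measures and thresholds

* `pc` (integer 0–10): number of the ten physicochemical property classes
  uniformly present or uniformly absent across the retained distinct
  symbols.  Default threshold `t_p = 4` conserved properties.
* `ent` (nats, 0 to ln 22 ≈ 3.09): Shannon entropy of the renormalized
  retained frequencies, each of the 22 symbols counted individually.
  Default threshold `t_e = 1.375` nats (about the entropy of four
  equiprobable residues).
* `prob` (probability): multivariate-hypergeometric point mass of the FOI
  multiset under without-replacement draws from the nFOI pool; `C(n,k) = 0`
  when `k > n`, so any FOI symbol exceeding its nFOI count gives probability
  exactly 0.  Default threshold `t_s = 0.0`, i.e. only impossible draws are
  flagged.  A with-replacement multinomial variant is provided for
  comparison.  The scalar implementation uses exact integer binomials; the
  vectorized engine uses log-gamma arithmetic, with impossibility handled
  exactly so the `t_s = 0` decision never depends on floating-point
  underflow.

The defaults (`t_p=4`, `t_e=1.375`, `t_s=0.0`, weights `0.615/0.385/0.0`)
are the discriminability-optimal values for a large curated
kinase-superfamily alignment; on other data they should be re-derived with
the sweep functions.

### Discriminability objective

A candidate threshold (or weight triple) is evaluated by conformity scoring:
every sequence is scored against every FOI as the sum of the FOI's score
vector over columns where the sequence's symbol belongs to the FOI's
retained repertoire (post-filter distinct set by default; a pre-filter
option exists).  Pooling all (sequence, FOI) pairs, entries where the
sequence belongs to the FOI are positives; the pooled ROC AUC is the
objective.  AUC is computed as the midrank Mann–Whitney statistic, which is
threshold-free, handles the heavy ties that conformity scores produce, and
equals the trapezoidal area under the empirical ROC curve exactly (asserted
to 1e-12 in tests).  Sweep grids default to `t_p ∈ {0..10}`,
`t_e ∈ {0, 0.125, …, 2.5}`, `t_s ∈ {0, 0.02, …, 0.9}`.  The weight search
runs on the unit simplex `pc_wt + ent_wt + prob_wt = 1` at step 0.005: AUC
is invariant under positive scaling of the weights, so the simplex loses
nothing (asserted in tests); an explicit grid can be passed for independent
per-axis designs.  Argmax ties are broken toward the smallest threshold /
lexicographically smallest triple, for determinism — on easy data where
whole AUC plateaus sit at 1.0, the reported "best" value is therefore the
smallest of the tied ones, not a unique optimum.

### Conformity is linear in the scores

The weight sweep exploits that the conformity score is linear in the score
vector: per-measure conformity components are computed once and recombined
per weight triple, so the 20 301-triple default grid costs one ranking pass
per triple rather than a rescoring of the alignment.

### Downstream analytics

* **Hotspots**: columns with ID_score ≥ 0.1 in at least 10% of families,
  the count read as `ceil(0.10·F)` ("at least 10%" taken strictly; a floor
  variant is available for sensitivity analysis).
* **Controls**: the equally many columns with fewest gaps, ties broken
  toward lower column index (stable argsort).
* **Trees** arrive as Newick (inference is out of scope).  Midpoint rooting
  finds the diameter path by double traversal and roots at its half-way
  point (placed exactly on a node when the arithmetic says so).
  Ultrametrization extends terminal branches to the maximum root-to-leaf
  distance; polytomies are resolved in input order into ladders of
  zero-length edges — cluster purity is invariant to the resolution order.
  Cutting at depth `d` yields one cluster per edge crossing `d`; `d = 0`
  gives one cluster, `d = height` gives singletons on trees with positive
  terminal branches.
* **Purity** of a clustering is the average dominant-family fraction,
  `(1/n) Σ_i max_j |c_i ∩ f_j|`; it is non-decreasing under refinement and
  along increasing cut depths on ultrametric trees (both property-tested).

## Synthetic data generator

The generator emulates the statistical structure the scorer assumes:
globally conserved columns (one residue shared by all families), planted
family-specific columns (the owning family conserved on a private residue
that no other family carries; all other families draw background), and
neutral columns (every sequence draws independently from a background
distribution), plus independent gap insertion.  All draws come from one
seeded stream in a fixed order, so outputs are byte-identical per seed.

Default study conditions, chosen once: 6 families × 100 sequences × 150
columns, 3 specific columns per family, 15 global columns, 5%
within-family substitution noise at conserved cells, 2% gap rate.  Family
size 100 is mid-range of the 5–200 family sizes in a curated kinase
superfamily dataset and deep enough that the 8.5% filter (retention cutoff:
count ≥ 9) counts background columns reliably; 6 families × 150 columns is a
scaled-down analogue of the 107 × 1094 full problem, sized so the entire
pipeline — sweeps included — runs in seconds.

The background is uniform over the six residues `A E H P R V`.  This is the
one genuinely delicate design choice: with a 20-way-uniform background every
residue sits below the 8.5% cutoff at realistic family sizes, so "neutral"
columns collapse under the filter into small spuriously conserved retained
sets — an artifact of sampling depth, not of the method.  The six-residue
support was selected by exhaustive enumeration so that no subset of four or
more of its residues conserves four or more of the ten property classes;
retained background sets of typical size therefore can neither pass the
physicochemical gate (`pc ≥ 4`) nor the entropy gate (their renormalized
entropy stays above 1.375 nats), and planted columns separate strictly from
neutral ones in the noise-free limit.

Substitution noise replaces a conserved cell with a uniform draw from the 19
other residues.  A consequence worth knowing: each substitute residue's
expected frequency is `noise/19 < 8.5%` for any noise level, so the
low-frequency filter absorbs uniform substitution noise almost entirely, and
planted-column recovery stays at recall 1.0 until the *conserved* residue's
own frequency approaches the cutoff (noise ≈ 0.9).  Monotone-degradation
tests therefore probe noise at {0, 0.9, 1.0}.  This robustness is the
filter working as designed, not an artifact.

What the generator does **not** emulate: phylogenetic correlation within and
between families (sequences are exchangeable draws), realistic residue
substitution matrices, alignment errors other than the iid gap process, and
sub-family structure.  Passing tests on synthetic data therefore demonstrate
the pipeline's correctness and its behavior under the stated statistical
structure — not performance on real superfamilies, where alignment quality
and classification errors dominate.

## Problem sizes and verification

* Unit and property tests run at desk scale (≤ 6 families, ≤ 600 sequences,
  ≤ 150 columns); the whole suite completes in a few seconds.
* The vectorized engine is asserted bit-identical to a naive
  per-(FOI, nFOI, column) recomputation built from the scalar API on random
  5-family fixtures, including gaps and `X`.
* The without-replacement probability is asserted equal (|error| < 1e-12) to
  an exhaustive enumeration oracle over all draws for pools of up to 8
  residues, 1000 random compositions.
* `scripts/acceptance.py` runs the full study (all sweeps at their default
  grids, weight simplex at step 0.005, scoring, hotspot/control selection,
  recovery, purity) in well under a minute on one CPU.
* The cluster-purity demonstration builds trees by average-linkage (UPGMA)
  over Hamming distances restricted to the selected positions — a stand-in
  for an externally inferred phylogeny, post-processed by the package's own
  rooting/ultrametrization/cutting operations.
* One acceptance test reproduces the published kinase-superfamily numbers
  (pooled AUCs 0.9904 / 0.9895 / 0.9743 / 0.992, 194 of 1094 hotspot
  positions, with-replacement peak 0.970 at t_s = 0.02) when the curated
  5488-sequence master alignment and family map are placed under
  `data/kinase/`; the dataset is too large to ship with the package, so the
  test reports its absence otherwise.  Rank-based tie handling in the AUC
  may shift third decimals relative to printed values; the comparison is at
  two decimals.

## Known limitations

* Threshold and weight optimization is in-sample (all families pooled), as
  in the original formulation; no held-out or cross-validated AUC.
* The ID_score treats columns independently; covariation between positions
  is not modeled (correlated sites are still scored individually).
* Decisions are binary per comparison, so score resolution is 1/F; small
  datasets quantize coarsely.
* Empty-profile and gap-column conventions are policy choices (documented
  above) in regimes the original rules leave unspecified.
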