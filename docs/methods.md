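# Methods

This note documents the models, parameter choices, numerical conventions
and known limitations of `mdiva`. It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Mass-difference network construction

The network is defined over features with exact neutral monoisotopic
masses. For every ordered pair (i, j) with `m_j > m_i` (strict) and every
entry *e* of the mass-difference list K, an edge (i, j, e) exists iff
`|m_j − m_i − Δ_e| ≤ tol`. Conventions:

- **Tolerance** is absolute, default **0.001 Da**. FT-ICR-class mass
  accuracy motivates a sub-mDa default; it is a parameter everywhere.
- **Direction** is always low → high mass with strictly positive deltas,
  which removes sign ambiguity. Equal masses are kept as distinct nodes
  and never self-edge (deltas are positive, so a zero gap cannot match).
- **Parallel edges** are created when several deltas match one pair within
  tolerance; each carries its own annotations. Deduplicating or summing
  parallel annotations would conflate chemically distinct transformations.
- Construction is a sorted-mass binary search, O(n·k·log n); its output is
  asserted equal, edge for edge, to an independent O(n²k) triple loop on
  randomized instances (test suite). Edge order is canonicalized by
  endpoint masses and ids, so the network is invariant to input row order.

## Formula propagation

Seed features carry trusted formulas (validated against their measured
mass within tolerance; inconsistent seeds are an error). Candidates move
along edges as `formula(source) + Δformula` (subtraction against the edge
direction); candidates with a negative element count or a mass deviating
from the target's measured mass beyond tolerance are rejected; edges whose
delta formula is unknown are skipped. The implementation computes the
**closure of all reachable candidates before classifying features** —
exactly one surviving candidate ⇒ assigned, several ⇒ conflict (left
unassigned), none ⇒ unassigned. A naive first-wins breadth-first search
would make conflict detection depend on traversal order; the closure makes
it provably order-invariant (tested under shuffled inputs). Seeds are
authoritative anchors: incoming candidates never revise them.

Monoisotopic element masses (C, H, N, O, P, S, Cl) are hard-coded to six
decimals so results do not depend on an external lookup.

## Edge projection

`U_rs = √(x_is · x_js)`. A zero at either endpoint gives `U_rs = 0` and
the edge is **retained**, keeping the row set of U constant across samples
so walks are comparable. On the log scale the projection is the midpoint
of the endpoint log-intensities.

## Enrichment walks

Per sample, edges are ranked by `|U|^τ` descending with deterministic
tie-breaks (delta mass ascending, then edge id). The walk is the weighted
in-set cumulative fraction minus the unweighted complement cumulative
fraction; both sums reach 1, so every walk terminates at 0 and |values|
≤ 1. The enrichment score is the signed value at the maximum absolute
deviation.

- **τ defaults to 1** (the GSVA-family heritage choice); τ = 0 with binary
  counts reduces the ES exactly to the signed two-sample KS statistic,
  which the tests verify against an independent ECDF implementation to
  1e−12.
- The annotation count `C_r` uses **set semantics** per mass difference:
  an enzyme listed twice on one MD counts once.
- Sets with zero in-set weight or an empty complement are degenerate and
  raise (or are skipped with a log entry at the pipeline level).
- Ranking is per sample, independently; multiplying a sample's entire U
  column by any positive constant leaves its walks unchanged.
- Walk percentiles across sets use mean-rank ties mapped to (rank − ½)/n ×
  100, a deterministic, symmetric convention.

## Residual walks and quadrants

Group walks are position-wise arithmetic means over member samples;
the residual is bloom minus pre-bloom. The quadrant label is read at the
peak of the **dominant** group's walk — the group whose mean walk deviates
farther from zero — with the first axis expressed from the bloom
perspective (a dominant pre-bloom peak enters with flipped sign) and the
second axis the residual at that position: (+,+) → quadrant 1 (dominant in
the bloom), (+,−) → 2, (−,−) → 3 (depleted in the bloom), (−,+) → 4; any
zero gives no label. When the bloom walk dominates — the canonical
situation the analysis targets — this is literally "signs of the bloom
walk and of the residual at the bloom walk's maximum deviation". Anchoring
the position at the dominant group makes the label exactly antisymmetric
under group swap (1 ↔ 3, 2 ↔ 4), a property the tests assert; reading it
at the bloom walk's own peak unconditionally would break that symmetry
whenever the reference group's baseline walk dominates.

## Maximum-deviation p-values

- **Permutation (default):** the annotation count vector is permuted over
  edge positions, `n_perm = 999` by default (199 in the heavier test
  loops), with add-one correction `p = (1 + #{perm ≥ obs})/(n_perm + 1)`.
  One shared permutation is applied across samples, since C is a property
  of the master network's edges. An alternative blocked scheme that
  permutes annotation labels over whole mass differences (edges of one MD
  keep a shared count under the null) is available via `blocks=`; on
  independent synthetic null instances both schemes are calibrated within
  the nominal band, the positional scheme being mildly conservative on
  MD-blocked count vectors and more powerful against concentrated planted
  effects.
- **Analytic:** the Kolmogorov asymptotic tail at effective size
  `n₁n₂/(n₁+n₂)` from in-set/complement position counts (multiplied by the
  harmonic group-size factor for residuals). This is an approximation kept
  because permutation resolution is bounded by 1/(n_perm+1); outputs are
  labelled with the method used.
- Benjamini–Hochberg adjusted p-values are reported alongside raw ones
  across gene sets.

Null calibration is checked on **independent** synthetic instances (one
p-value per instance). Drawing many sets from one dataset leaves each
p-value marginally calibrated but correlates them through the shared U
matrix and annotation structure, which distorts aggregate uniformity
diagnostics — a property of the diagnostic, not of the test.

## Gene-level GSVA

The identical walk machinery on a TPM matrix: genes ranked per sample by
`TPM^τ` descending (ties by gene id), counts = overlap of the gene's
pathway annotations with the set (gene ids themselves when no annotation
map is given). Group ES differences are mean(bloom) − mean(pre-bloom);
swapping labels negates them exactly.

## Expression statistics

- `TPM^0.25` variance-stabilising transform; z-scores with the n−1
  standard deviation (constant vectors return zeros with a warning).
- Per-gene OLS against one environmental parameter; stations with missing
  values dropped pairwise, never imputed; two-sided p for slope = 0; sign
  classified at **α = 0.05 on the raw p** (BH-adjusted values are emitted
  alongside). Regressions default to transform-then-z; both orders are
  possible by composing the public functions.
- Coexpression: euclidean distance on the transformed, unscaled matrix,
  cutoff 1.0, clusters capped at the **1000 nearest** genes, seed
  excluded, deterministic tie-breaks by gene id.
- Fold enrichment `(x/k)/(m/N)` with a hypergeometric upper tail
  P(X ≥ x | N, m, k) and BH adjustment across pathways per cluster. The
  universe N is the set of pathway-annotated genes in the dataset, and
  cluster members outside the universe do not enter the counts (k is the
  annotated cluster size), keeping the 2×2 margins consistent; the
  low-level `fold_and_pvalue(x, k, m, N)` accepts arbitrary counts.

## Synthetic-data generator

The generator emulates the study design the pipeline targets: two station
groups (pre-bloom, bloom) in triplicate by default, a feature table of 200
features (two orders of magnitude below a real FT-ICR-MS survey, for test
speed; sizes are parameters), a mass-difference list derived from actual
substrate→product formula pairs of a random CHNOPS(Cl) universe
(H ≤ 2C+2, heteroatoms ≤ C), annotation ids partitioned with overlap into
pathways and folded into broader classes.

- **Intensities are log-normal** (log10 base, feature-level mean ~N(6,
  0.5), per-observation noise σ = 0.2 log10 units) with a per-sample
  multiplicative depth factor uniform in [0.8, 1.25]. The intensity
  distribution of the emulated instrument class is not publicly
  characterized; log-normal is a documented stand-in that mimics
  multiplicative MS dispersion without modelling isotopes.
- **Planted effects act on feature intensities** (node level) and reach U
  through the geometric-mean projection — the causal direction of the real
  assay. With effect `log2fc`, a fraction `frac_affected` of the features
  incident to a planted pathway's annotated edges is multiplied by
  `2^±log2fc` in every bloom sample. Planting targets the eligible
  pathways with the **most annotated edges** (deterministically): an
  "affected pathway" backed by a handful of edges is a degenerate study
  design, not a harder instance of the same one.
- **Decoy features** (default 30%) get masses whose gap to every other
  feature matches no listed delta, exercising non-edges.
- Expression: TPM columns normalised to exactly 10⁶; planted genes are
  generated on the fourth-root scale as `ρ·z(env) + √(1−ρ²)·ε` against a
  designated covariate (defaults emulate N:P ratio, salinity, longitude,
  silicate station covariates).
- Everything is deterministic given the seed (byte-identical files on
  rerun); named substreams derive from the master seed via SeedSequence.

What passing tests on this generator do **not** show: robustness to
isotopologues, adducts, ionization suppression, chromatographic artefacts,
heteroscedastic noise floors, or compositionality of real TPM data — none
of which are modelled.

## Problem sizes and numerical conventions

Test and acceptance runs use 120–300 features, 12–40 mass differences,
8–70 gene sets, 6–12 samples, 199 permutations, and 200–500 Monte-Carlo
replicates — sizes chosen so the statistical checks (oracle equality,
null uniformity, ≥90 % planted recovery) are sharp while the whole suite
stays interactive. Tabular outputs are UTF-8 TSV with floats at six
significant digits and a `# config_hash=…` provenance header; logs go to
standard error only. Permutation p-values are never 0 by construction
(add-one correction); analytic p-values are clipped to (0, 1].

## Known limitations

- The analytic p-value is asymptotic and heuristic for residual walks;
  use permutation where its resolution suffices.
- Quadrant labels at an exact tie of the two groups' maximum deviations
  fall back to the bloom branch; antisymmetry can break on that
  measure-zero boundary.
- Formula propagation reports conflicts but does not attempt resolution
  (no scoring of candidates); at wide tolerances near-isobaric element
  substitutions (e.g. C₃ vs SH₄, 3.4 mDa) conflict quickly.
- The coexpression step follows the euclidean/no-scaling/cutoff-1
  convention of the gene-finder tools it mirrors; with very different
  expression scales a cutoff re-appraisal is the user's responsibility.
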