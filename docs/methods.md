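# Methods

This note documents the models, algorithms and design choices behind
`ms1match`, and what the test suite does and does not establish.

## Run representation and normalization

A run is a bag of MS1 features, each a tuple (m/z in Thomson, intensity in
arbitrary units, integer charge ≥ 1, retention time in seconds). Before
scoring, a run is reduced to its *N* most intense features (default
N = 4000; intensity ties broken by ascending (m/z, RT, charge) so the
selection is independent of input row order) and normalized **over the
post-top-N set**:

* `rt_norm = (rt − min rt) / (max rt − min rt)`, 0 everywhere if the range is
  degenerate;
* `intensity_norm = intensity / max intensity`, 0 everywhere if the maximum
  is 0.

Min-max RT scaling makes every downstream quantity invariant under positive
affine transforms of the time axis — the dominant between-experiment
distortion (gradient length, dead volume). Max intensity scaling gives
invariance to uniform scaling (injection amount, gain). These invariances
are asserted exactly in the test suite. Whether a log-transform of
intensity would serve M2 better is an open modeling question; the linear
max-scaling keeps M2 in [0, 1] per edge and is the documented choice.

## Graph construction

Edges connect features of equal charge whose m/z values differ by at most
δ₁ ppm **of the mean of the two values**, boundary inclusive (default
δ₁ = 4 ppm, a typical precursor tolerance). No deconvolution to neutral
mass is attempted; matching on recorded m/z at equal charge is equivalent
for the same analyte and avoids cross-charge false matches. Degree
constraints are not applied to E — a feature may support many candidate
edges.

Edges are stored in a canonical order: sort by the *unordered* pair of
endpoint keys, each key = (m/z, RT, intensity, charge) of the feature. This
order is invariant under swapping the two runs, and every edge attribute
used downstream is either symmetric (ppm distance, mean intensity) or
antisymmetric under swap inside an absolute value (RT shift), so the final
score — including greedy tie-breaks — is *bitwise* symmetric in its two run
arguments. The test suite asserts exact equality, not approximate.

A `max_edges` cap (default 20 000) guards the O(|E|²) pairwise term on
pathological inputs by keeping the lowest-ppm edges, with a logged warning;
the truncation uses the symmetric ppm values and canonical order, so
symmetry survives capping.

## Objective

For an edge set A the four terms are

| term | entry | type | favors |
|------|-------|------|--------|
| M1 | 1 per edge | modular | many matches |
| M2 | mean of the two normalized intensities | modular | intense matches |
| M3 | exp(−α·abs(Δt)) per edge | modular | small normalized-RT shifts |
| M4 | exp(−β·abs(Δt₁−Δt₂))·exp(−γ·(abs(tᵤ₁−tᵤ₂)+abs(tᵥ₁−tᵥ₂))/2) per *ordered pair* of edges, 1 on the diagonal | supermodular | coherent shift patterns |

Δt is the signed difference of normalized RTs across an edge; tᵤ, tᵥ are the
normalized RTs of the two endpoints. M4 sums over all ordered pairs
including the diagonal, so |A| ≤ M4(A) ≤ |A|². All entries lie in [0, 1].
The exponential-kernel forms encode the two coherence requirements — similar
shifts, and nearby elution within each run — as separable multiplicative
decays; α, β, γ are free hyperparameters covered by the random search
(defaults α = 1, β = γ = 10, i.e. e-folding over a tenth of the gradient for
the pairwise kernels).

Each term is normalized by its value on the full edge set E, making the λ
weights comparable across run pairs; the final score un-normalizes by the
pair constant Σⱼ λⱼ Mⱼ(E):

S = (Σⱼ λⱼ Mⱼ(E)) · maxₐ Σᵢ λᵢ Mᵢ(A)/Mᵢ(E).

Degenerate normalizers (Mᵢ(E) = 0, possible for M2 with all-zero intensities
or for empty E) contribute 0 to both factors (0/0 := 0). Empty E gives
S = 0 exactly.

## Greedy matching

The matching constraint — every feature in at most one selected edge — is
the intersection of two partition matroids. Because all matrix entries are
nonnegative and M4 is supermodular, the greedy algorithm applies: repeatedly
add the feasible edge maximizing the marginal gain

Δ(e|A) = Σ_{i≤3} λᵢ mᵢ(e)/Mᵢ(E) + λ₄ (1 + 2 Σ_{e′∈A} m4(e, e′)) / M4(E),

until no feasible edge remains (every gain is nonnegative, so early stopping
can never help). Gains are maintained incrementally — each candidate carries
its running Σ m4 against the selected set, updated in O(|E|) per step — for
O(|E|·|A|) total work. Ties take the lowest canonical edge index, which is
what makes symmetry exact under ties.

A brute-force enumerator over all feasible matchings (guarded to |E| ≤ 20)
provides the exact optimum for testing. On 200 random enumerable instances
the exact value always dominates greedy, and in the purely modular case
(λ₄ = 0) greedy achieves at least ½ of the optimum — the classical bound for
greedy weighted matching, witnessed tightly (ratio 0.6) by a hand-built
3-edge instance where greedy's first pick blocks the two-edge optimum. For
λ₄ > 0 the greedy/optimal ratio is measured and reported but no bound is
asserted.

## Baselines

Binned baselines drop features into (⌊m/z / w⌋, RT bin, charge) cells
(default w = 0.01 Da; RT binning on `rt_norm` with the right boundary
clamped; n_rt_bins = 1 ignores RT) and aggregate per-cell **counts** with
indicator / product / min / max rules. Counts rather than intensities are
the documented choice, matching the "number of bins in common" reading of
these baselines. Charge is part of the bin key for consistency with the
edge definition. The `max` aggregator is implemented but excluded from
default reports (poor retrieval performance). Hard bin edges make these
scores degrade under systematic RT shifts — the indicator score with
n_rt_bins = 2 can only be ≤ its n = 1 value when each m/z cell holds one
feature per run, an edge-effect the matching score avoids by construction.

The continuous baseline replaces bins with Gaussian kernels,
Σ exp(−ppm²/2σ²) (optionally × a kernel on Δrt_norm) over same-charge pairs
within 3σ ppm.

## Retrieval metrics

Average precision follows the step definition Σₖ Pₖ(Rₖ − Rₖ₋₁); it agrees
with scikit-learn's implementation on *all* 0/1 sequences up to length 8
(exhaustive test). QAP averages per-query APs over leave-one-out rankings;
AAP computes one AP over the globally sorted upper triangle. Ranking ties
break by ascending run identifier; queries whose label is unique are skipped
with a warning (AP is undefined without relevant items). Both metrics
depend only on the ranking and are invariant under strictly monotone score
transforms and joint row/column-and-label permutations.

The random search draws the λ vector uniformly on the simplex (four
uniforms normalized, with the last coordinate closed exactly), N uniformly
as an integer in [100, 5000], and δ₁, α, β, γ log-uniformly (δ₁ in 1–20 ppm,
decays in 0.01–100) — ranges bracketing the default configuration by an
order of magnitude each way, chosen here because no canonical ranges exist.
The search is reproducible from its seed, which is recorded in the report
header.

## Synthetic data generator

The generator emulates a labeled multi-species repository. Each species
owns a pool of analytes (m/z uniform in 300–1500 Th, rejection-sampled so
within-pool separations exceed 3·δ₁; charge ∈ {2, 3}; canonical RT uniform
in [0, 1]; base intensity log-uniform over 10⁵–10⁸, a realistic LC-MS
dynamic range). A run observes each analyte with probability
`detection_prob`, applies multiplicative m/z noise of `ppm_sigma` ppm, an
affine per-run RT warp plus Gaussian jitter (mapped to seconds via a nominal
one-hour gradient), log-normal intensity noise, and adds `n_contaminants`
features drawn from a global contaminant pool shared by all species
(chemical background, and the only source of cross-species edges when pools
are disjoint). With `shared_fraction > 0`, consecutive species pairs share
that fraction of their pools as identical analytes.

The benchmark conditions — 3 species × 5 runs, pool 500, disjoint pools,
detection 0.8, 1 ppm mass noise, per-run warp slopes uniform in [0.8, 1.2]
and intercepts in [0, 0.2], jitter 0.01, 25 contaminants — are the
generator defaults and the dataset used by the retrieval tests and the
acceptance script. The affine warp is exactly the distortion min-max
normalization absorbs, so the generator probes the mechanism the M3/M4
kernels rely on.

What the generator does **not** emulate: isotope envelopes and detector
peak shapes, co-elution and ionization suppression, nonlinear (non-affine)
RT distortions, charge-state correlation between analytes, and missing
high-mass ranges. Passing the synthetic retrieval tests therefore shows the
pipeline is correct and discriminative under controlled noise; it does not
by itself establish performance on real repository data, where nonlinear RT
warps and denser m/z neighborhoods make matching harder.

## Numerical choices and limitations

* The λ simplex is validated to 1e−9; degenerate-term contributions use
  0/0 := 0.
* The pairwise kernel is evaluated as exp(−(β·d₁ + γ·d₂)) in 2048-row
  blocks; M4 totals are exact (no truncation), so the only approximation in
  the pipeline is the greedy matching itself.
* Feature tables are plain TSV; floats are written with `repr` for lossless
  round-trips and byte-identical reproducibility.
* Scale: scoring a pair costs O(|E|²) for M4(E) plus O(|E|·|A|) for greedy.
  With the default N = 4000 and dense edge sets the `max_edges` cap bounds
  the quadratic term; at the benchmark sizes (≈ 425 features/run) a full
  15-run matrix computes in seconds.
* Greedy offers no certified bound for λ₄ > 0 here; the oracle tests bound
  its behaviour empirically on enumerable instances only.
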