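# Methods

## The tissue model

The synthetic generator (`skinmap.synthgen`) emulates a biopsy of layered
inflamed skin as seen by three assays: droplet scRNA-seq, spot-based
spatial capture, and sub-cellular pixel capture.

**Counts.** Every observation is negative-binomial in the mean–dispersion
parameterization, variance $\mu + \mu^2/\theta$, with $\theta$ shared
across genes (default 10, a typical droplet-data value; $\theta \to
\infty$ gives the Poisson limit). A cell of type $t$ with depth $d$
(expected transcripts, default 5,000) has
$\mu_{g} = d\,(1 - s)\,\rho_{g} m_{gt}$, where $\rho$ is a baseline
relative-expression profile drawn once per dataset from a lognormal
(σ = 1), $m_{gt}$ collects the planted effects, and $s$ is the cell's
mitochondrial share, Beta-distributed (default mean 5 %) with an outlier
component so the QC filter has something to catch. Mitochondrial genes
carry the `MT-` prefix. Expected depth is nominal up to the planted
multipliers (a few percent per type); spot profiles are renormalized to a
simplex so a spot's expected total equals `spot_depth` exactly.

**Planted structure.**

- *Cell types* (default 8: three keratinocyte layers, fibroblast, T cell,
  myeloid, endothelial, melanocyte) each own a disjoint block of marker
  genes upregulated fold 5 — strong enough that clustering and marker DE
  are solvable, weak enough that QC/normalization errors would show.
- *Conditions* NS/PN/PP are drawn per cell; each type has three
  sub-clusters whose occupancy is condition-skewed (one NS-leaning, one
  mixed, one PP-leaning), producing the > 70 % condition-specific
  sub-clusters the interaction analysis relies on.
- *Pseudotime* for keratinocytes is linear in layer index with uniform
  jitter, $t = (\text{layer} + U)/3$; non-epidermal cells get uniform
  values. This is a stand-in for a differentiation trajectory, not a
  mechanistic simulation.
- *Cytokine-response programs* are gene blocks whose expression is
  multiplied by a per-layer effect, linearly interpolated in $t$ between
  layer centers, so a monotone effect triple (e.g. 1, 2, 4 for an
  IL-17-like program peaking supraspinously) rises continuously along
  differentiation.
- *Ligand–receptor genes* live in a dedicated "signaling" block held near
  the detection floor (≈ 2–3 % of cells) with a tight lognormal spread
  (σ = 0.25), emulating baseline cytokine/receptor transcripts in resting
  tissue. A planted interaction multiplies the ligand in the source type
  and the receptor in the target type (restricted to one condition) by
  fold 50 — the order of induction seen for inflammatory mediators in
  lesional skin — lifting detection to ≈ 50–70 %. The tight baseline
  spread matters: with transcriptome-wide variance, a tail of null
  signaling genes crosses the 10 % expression threshold and the planted
  benchmark's false-discovery rate becomes unstable.
- *Spots* lie on a 16 × 30 lattice (square rook/queen or Visium-style
  odd-r hexagonal) whose rows are banded into supraspinous / spinous /
  basal / dermis strata; each spot's true type fractions are Dirichlet
  jitter (concentration 60) around its stratum mixture, and its expected
  expression is `spot_depth` × (fractions · type profiles).
- *Pixels* are uniform in a rectangular µm field banded like the lattice;
  each pixel's gene is drawn from its band's mixture profile.

Determinism: one master seed is split with `numpy.random.SeedSequence`
into fixed-order per-stage streams (base profile, assignments, mito,
cells, spots, pixels), so adding a stage never changes earlier draws and
identical configs reproduce identical bytes.

**What the generator does not emulate** — and therefore what green tests
do not certify on real data: doublets, ambient RNA (a known contaminant
of real spot data), batch/chemistry effects, per-gene dispersion
variation, gene–gene correlation beyond the planted programs, irregular
tissue geometry, and segmentation errors in pixel data. Results on real
tissue additionally depend on reference-atlas fidelity, which the
benchmark sidesteps by building signatures from the same generator.

## Analysis choices

**QC boundaries.** "Fewer than 500 transcripts or 100 genes" is read
literally: removal when transcripts < 500 OR genes < 100; mitochondrial
removal only when strictly above 10 %. The filter is idempotent and
reports per-cell metrics alongside the decision.

**HVG selection** is vst-style on the CP10K scale reconstructed by
expm1: lowess of log10 variance on log10 mean, standardization by the
trend, clipping at $\sqrt{n}$, ranking by clipped variance. A constant
matrix returns stored order with a warning.

**Clustering** is PCA (20 components on z-scored, ±10-clipped HVGs) →
symmetrized 15-NN graph → Leiden (RB configuration) at resolution 0.5,
labels relabeled by decreasing size. The contract is the partition;
the community-detection backend (igraph/leidenalg) is replaceable.

**Wilcoxon DE** uses the tie-corrected normal approximation with
continuity correction; when $n_A n_B \le 400$ and a gene has no ties the
exact null distribution of U replaces it (the exact method assumes
continuity, so tied genes keep the approximation). Fully constant genes
get p = 1. Log fold-changes use pseudocount 1e-9 on mean expm1 values.

**Module scores** use 24 expression bins and 100 controls per target by
default (the conventional values for the binned-control score). Controls
are drawn per target gene from its bin, without replacement when the bin
allows, and pooled with multiplicity. Caveat observed on synthetic data:
when cell populations differ in their expression *composition* (marker
or program blocks consume different depth shares), CP10K places a small
population-dependent offset on every gene; bin-matched controls cancel
most but not all of it, so random-set scores are exactly centered only
over exchangeable cells. The null-distribution tests therefore run on a
single-type, flat-program configuration; structured configurations are
covered by planted-effect recovery tests instead.

**Deconvolution** works on the linear CP10K scale, where mixtures of
cell-type profiles are additive. An earlier log-space formulation was
discarded because its Jensen-type model mismatch varies with spot depth
and recovery error was not monotone in depth. Genes are weighted by
$1/\sqrt{m + m^2/\theta + 10^{-3}}$ (m = signature row mean, θ = 10), the
NB noise scale, so a handful of highly expressed genes cannot dominate
the fit; NNLS coefficients are renormalized to a simplex, zero-count
spots are flagged NaN. The signature is the per-type mean CP10K over a
marker ∪ HVG panel (per-type top-50 rank-sum markers by default);
`scale="lognorm"` provides the mean-log signature for display. Measured
on the default benchmark: per-type mean absolute fraction error 0.02–0.03
at depth 10,000, monotone 0.059 → 0.042 → 0.039 across depths 1k/10k/100k.

**Adjacency** counts each unordered lattice edge once; for an edge
(s, s′) every ordered membership pair (a ∈ s, b ∈ s′) contributes one
count, and the matrix is symmetrized with the diagonal kept as-is, so the
diagonal counts unordered same-type adjacencies once. Membership defaults
to fraction ≥ τ = 0.1 (the slices visible in a scatter-pie display), with
a dominant-type rule available. Hexagonal neighborhoods use odd-r row
parity offsets and are unit-tested against a cube-coordinate distance.

**Grid binning** uses half-open cells $[ig, (i+1)g)$ so each pixel maps
to exactly one grid; the 30-distinct-gene filter runs after aggregation.

**Interaction scoring** re-implements the published cluster-mean
statistic: complex units take the minimum over members for means and
require every member detected in > 10 % of the cluster's cells;
unexpressed combinations score 0 with p = 1; the permutation p uses the
+1 correction, p = (1 + #{perm ≥ obs})/(1 + n_perm), hence
p ≥ 1/(n_perm+1) and exactness under exchangeability. Permuted scores are
computed from jointly shuffled labels without re-applying the expression
filter. Merging sub-cluster records to cell types takes the maximum score
and keeps the winning sub-cluster pair as provenance (order-independent,
preserves the strongest signal); the differential network keeps
(pair, src, dst) with score strictly higher in PP, treating NS absence as
0 (`require_both` flips that convention). Condition specificity is
computed over NS + PP cells only, matching runs that exclude PN.

Calibration caveat: true type labels are not a null for the permutation
test even for genes with identical expected counts, because marker blocks
shift per-type CP10K totals and with ~250 cells per cluster the induced
mean differences are resolvable (measured rejection 0.12 at nominal
0.05). The calibration benchmark therefore assigns labels at random, and
scores pairs in 8 chunks with independent labelings and permutation
streams so the per-pair p-values behave as replicated independent nulls
(across 12 master seeds: mean rejection 0.051, range 0.037–0.067 at
nominal 0.05, n_perm = 200).

**Enrichment** is the upper-tail hypergeometric probability
$P(X \ge k)$ with population = detected genes, BH-adjusted across
regulators. Regulator–pseudotime association is Pearson correlation of
the regulator's module score with the supplied pseudotime (Spearman via
flag); pseudotime construction itself is out of scope and consumed as
input (the generator's layer-graded truth serves in benchmarks).

## Problem sizes and defaults

Benchmarks run at desk scale, chosen to make the measured statistics
stable without being expensive: 2,000-cell atlases for
clustering/DE/deconvolution references, 1,000 cells for the QC benchmark,
1,500 cells × 520 pairs × 200 permutations for null calibration,
2,400 cells × 200 pairs (20 planted) for interaction recovery, 512 spots
at depth 10,000 for deconvolution, ≤ 100 spots for brute-force adjacency
cross-checks, and a 120 × 120 µm pixel field at 1.5 pixels/µm². The
pipeline CLI and `scripts/acceptance.py` use these same conditions.

## Known limitations

- The NNLS signature assumes reference and spots share a depth-normalized
  expression scale; platform effects between scRNA-seq and spatial
  chemistry are not modeled or corrected.
- Permutation p-values are exchangeability-based; condition or donor
  structure inside a cluster is not a null the test accounts for.
- The interaction score is expression-level only — no downstream
  signaling activity, directionality beyond ligand→receptor, or spatial
  constraint enters the statistic.
- k-means domains assume roughly isotropic composition clusters; elongated
  or nested tissue domains may split or merge.
- The Wilcoxon exact branch silently falls back to the asymptotic test in
  the presence of ties, which is the common case for sparse counts.
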