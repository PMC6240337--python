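# Methods

`molshape` quantifies the *shape* of molecular surface silhouettes —
here, scorpion-venom ICK (inhibitor cystine knot) peptides rendered in
frontal and lateral view — and asks how that shape, together with simple
biochemical traits, evolved on a dated phylogeny.  This note documents the
models, the numerical choices, and what the synthetic data generator does
and does not emulate.

## Outline extraction

A silhouette arrives as a binary mask.  The traced outline is the boundary
of the largest 4-connected foreground component, taken as the exact
pixel-edge polygon at the 0.5-pixel level (pixel centers at integer
coordinates, image rows flipped to mathematical y-up), with collinear
vertex runs merged.  Smaller components are treated as rendering speckle:
the largest is kept and a warning logged.  Holes are ignored.

A raw pixel-edge boundary of a rasterized *smooth* shape is a 1-px
staircase whose polygonal perimeter overestimates the true boundary length
by up to ~27% (the Manhattan limit).  When more than half of the boundary
edges are staircase steps (length ≤ 1.5 px), the vertex chain is therefore
resampled at 0.25-px spacing and smoothed with a periodic Gaussian filter
(σ = 1.5 px of arc length, clipped to perimeter/16 for very small shapes).
On a rasterized disk of radius 20 px this brings perimeter and enclosed
area within a fraction of a percent of the analytic values, while
rectilinear masks (few or no staircase edges) are returned exactly —
a 3×3 pixel block yields precisely its 4 corners.  The tracing is
deterministic and translation-equivariant (vertex order is canonicalized
at the lexicographically smallest vertex).

Outlines are resampled to equal arc-length spacing (default 300 points,
more than 10× the highest harmonic used, avoiding aliasing) before Fourier
analysis.

## Elliptic Fourier analysis

A closed outline traversed at constant speed defines periodic functions
x(t), y(t) with period T (the perimeter).  Harmonic n carries the
quadruple (a_n, b_n, c_n, d_n):

    x(t) = A0 + Σ_n a_n cos(2πnt/T) + b_n sin(2πnt/T)
    y(t) = C0 + Σ_n c_n cos(2πnt/T) + d_n sin(2πnt/T)

Coefficients are computed with the classical closed-polygon formulas
(exact for piecewise-linear outlines); the DC terms are the exact mean of
the parameterized curve.  Per-harmonic power is P_n =
(a_n²+b_n²+c_n²+d_n²)/2, including the first harmonic by default
(exclusion available via flag), and the harmonic-count criterion returns
the smallest N whose cumulative power fraction reaches a threshold
(conventionally 0.99; for the silhouettes this analysis targets, 20
harmonics suffice).

Note that the constant-speed parameterization is intrinsic to the curve:
for a 2:1 axis-aligned ellipse the first harmonic is (a_1 ≈ 1.83,
d_1 ≈ 1.02), not the semi-axes themselves, although the descriptor
reconstructs the ellipse exactly at full rank.

Normalization against the first-harmonic ellipse (size a_1 = 1, rotation
and start point standardized, b_1 = c_1 = 0) is available but **off by
default**: the intended inputs are silhouettes pre-aligned on landmark
residues, where normalization would discard real orientation information.
The 180° start-point ambiguity is resolved deterministically by choosing
the candidate with the lexicographically larger flattened coefficient
vector (rounded at 1e-9), which is invariant to the input's rotation,
scale, and start point.  The normalization state is recorded in all
serialized output.

Mean shapes are per-coefficient arithmetic means (DC included) over
families sharing one harmonic count and normalization state.

## Morphospace and deformation

Shapes enter PCA as rows of flattened harmonic coefficients, DC terms
excluded (location is an alignment artifact).  PCA is column-centered with
**no** column scaling — EFA coefficients share units, so the covariance
eigendecomposition is appropriate — computed by SVD with a deterministic
sign convention (each component's largest-magnitude loading is positive).
Group separation along a component is tested with a two-sample location
test of the scores (Welch by default; pooled available); a group with a
single member yields a low-power-flagged result, not an error.  The
published analysis attaches p-values to PC variance percentages without
stating the method; this package reports the group test alongside the
variance fraction and does not claim it is the original procedure.

Mean shapes of two groups (reconstructed at a common point count, so point
indices correspond) are compared with an exact-interpolation thin-plate
spline: kernel U(r) = r² log r (U(0) = 0), affine part plus kernel weights
solved from the standard augmented linear system.  The deformation heatmap
is the displacement magnitude |f(x) − x| on a 60×60 lattice (default)
covering the source bounding box padded 10%; direction is not rendered.
Degenerate (collinear/duplicated) control points raise an error rather
than returning a least-squares fit.

## Phylogenetic comparative layer

The dated ultrametric tree is an input (Newick with branch lengths in
Myr); tree inference and dating are upstream.  Edges are indexed by the
postorder position of their child node, fixed at parse time, so shift
configurations are stable across runs.  Pruning preserves retained
patristic distances exactly (unary nodes suppressed, lengths summed).
When silhouette data exist at the genus level only, one tip per genus is
retained — the lexicographically smallest label, a deterministic choice
that is inconsequential when intrageneric sequences are near-identical
(the situation this rule is designed for).

Ancestral states for visualization use Brownian motion regardless of the
trait model fitted downstream, mirroring standard phylomorphospace
practice: internal nodes sit at the GLS/ML estimates (root =
(1ᵀV⁻¹1)⁻¹1ᵀV⁻¹y with V the shared-time covariance; internal nodes at the
conditional means, which coincide with the joint-ML states).
Phylomorphospace places nodes at two traits' values/estimates;
phenograms at (node age, trait).

## OU regime-shift detection

Traits follow an Ornstein–Uhlenbeck process with selection strength α
(1/Myr), diffusion σ², and an optimum θ that may jump at the start of
selected edges.  With the root held at the base optimum, tip expectations
are linear in the shift effects:

    E[y_i] = θ0 + Σ_{e : i below e} β_e (1 − e^{−α τ_ie}),

with τ_ie the time from the start of edge e to tip i, and tip covariance
(per unit σ²) V_ij = e^{−α d_ij}(1 − e^{−2α t_ij})/(2α) (patristic
distance d, shared time t; the α = 0 limit is Brownian, V_ij = t_ij).

**Candidate search.**  For each α on a grid, traits are whitened by the
Cholesky factor of V(α), the (unpenalized, whitened) intercept is
projected out, and all m traits are regressed jointly on the edge design
with a multi-task lasso — an ℓ1 penalty on per-edge effect-row norms, so
an edge either shifts all traits or none.  Distinct supports along a
25-point geometric λ path from λ_max down to 10⁻³λ_max, with at most
`max_shifts` edges (default min(15, n/4)), are candidates; the empty
support always is.  All edges are candidate shift positions (two shifts on
the root's child edges are jointly confounded with the intercept; the rank
check below discards such configurations).  Convergent regimes are not
merged.  The solver is scikit-learn's coordinate-descent `MultiTaskLasso`
(warm-started along the path, tol 1e-8, iteration cap 1e5).

**Selection.**  Each candidate support is refit by maximum likelihood —
GLS for θ0 and β per trait, closed-form σ̂²_j per trait, α shared across
traits and profiled on a 32-point log grid spanning (tree depth)⁻¹ ×
[10⁻³, 10³] (candidate search uses every 4th grid point; refits use the
full grid) — and scored with a conservative phylogenetic BIC:

    pBIC(S) = −2 log L + (1 + 2m + |S|m) log n
              + 2 log C(2n−3, |S|) − m log det R_S

The first penalty is a plain BIC over all parameters (one α, m diffusions,
m intercepts, |S|·m effects).  The combinatorial term prices the *choice*
of shift positions uniformly among the ~2n−3 edges; the last term, with
R_S the correlation matrix of the whitened intercept-projected selected
columns, penalizes near-collinear (poorly identified) placements and
vanishes for the empty and orthogonal supports.  The named criterion has
published variants; this package's exact formula is the one above, a plain
BIC (κ = 1 + 2m + |S|m) is always reported alongside, and every output
records which criterion selected it.  Ties break toward fewer shifts, then
lower edge indices.  Because the empty support is always scored, the
selected configuration never has a worse pBIC than the no-shift model.

**Preprocessing.**  The trait columns (PC scores, charge, mass, volume)
are z-scored before joint fitting — they are on incommensurate scales and
the group penalty compares effect norms across traits — with a raw-scale
option retained; the output records which was used.  Constant traits floor
σ² at 1e-12 and return only the no-shift model.

**Bootstrap support.**  Parametric: trait tables are simulated from the
fitted model (same tree, α̂, σ̂², optima, effects; replicate r uses the
derived seed SeedSequence(seed, spawn_key=(r,))), the full candidate
search + selection reruns on each (without re-standardizing — replicates
are generated on the model scale), and an edge's support is the fraction
of replicates whose selected configuration contains it.  100 replicates by
default.

## Biochemical traits

Computed from the mature peptide sequence alone.  Net charge at pH is a
Henderson–Hasselbalch sum: basics (N-terminus, K, R, H) contribute
1/(1+10^(pH−pKa)), acidics (C-terminus, D, E, Y, free C) subtract
1/(1+10^(pKa−pH)).  The shipped pKa table is Lehninger-style free-residue
values with a provenance tag; online calculators use differing tables, so
second-decimal disagreement with any particular one is expected.  For ICK
peptides the six bridge-forming cysteines do not ionize; `bridged_cys=6`
excludes them (clipped per sequence in table mode).  Molecular weight is
the sum of average residue masses plus one water (Biopython's table).
Molecular volume is a sum of Zamyatnin-style mean residue volumes — an
acknowledged sequence-level approximation (no packing or solvent effects);
outputs carry a method tag, and volume comparisons against
structure-derived values should be read as comparable-but-not-identical.

## Synthetic data: what it emulates, and what it does not

The generator supplies every input at the statistical structure the
analysis assumes, with study-scale defaults:

- **Trees**: Yule (pure birth) topologies conditioned on the tip count,
  rescaled so all tips sit at a 430-Myr depth (the crown-age scale of the
  group studied).  Default demo size 48 tips, split by the root into two
  basal clades playing the calcin/LKTx roles.
- **Shapes**: per clade, coefficients = shared base blob + clade offset +
  iid Gaussian coefficient noise (default sd 0.02, small against the
  first-harmonic scale of ~2); one clade gains apex-like second/third
  harmonic content, the other becomes more globular.  Outlines are the
  inverse transforms; validity requires first-harmonic dominance.
- **Traits**: per-trait OU simulation sharing one shift configuration
  (the multivariate assumption), 7 columns by default.
- **Peptides**: random 33–36-mers with exactly six cysteines; clade-biased
  residue composition (K/R-rich vs D/E-leaning) produces a real net-charge
  contrast between clades.

Not emulated: actual 3-D structure, rendering and landmark alignment
(shapes are generated directly in coefficient space, so outline extraction
is tested separately on geometric masks); sequence evolution along the
tree (peptides are iid within clade, so peptide traits carry a clade
signal but no within-clade phylogenetic autocorrelation); measurement
error; non-ultrametric trees.  Passing tests therefore demonstrate the
correctness of the operations and the recovery behavior of the detector
under its own model, not the biological fidelity of any particular
published dataset.

All randomness flows from one root seed through documented
`SeedSequence(entropy=seed, spawn_key=(k,))` streams; the demo pipeline is
byte-identical across reruns with the same seed.

## Problem sizes and numerical choices

Recovery and conservatism of the shift detector are evaluated on 64-tip
Yule trees with 7 traits: a single planted shift of 10 stationary SDs
(σ√(1/2α)) on a long internal edge must be recovered exactly in ≥90% of 50
seeded replicates, no-shift data must select the empty configuration in
≥90% of 50 replicates, and parametric bootstrap support of the true edge
(100 replicates) must be ≥0.9.  OU/BM simulator calibration uses 10,000
replicate columns on 2-tip trees.  EFA roundtrip accuracy is assessed at
2048 points / 1024 harmonics.  These sizes were chosen as the smallest at
which the distributional claims are stable.

Other numerics: lasso support threshold 1e-10 on effect-row norms;
σ² floor 1e-12; Cholesky-based whitening (V(α) is symmetric positive
definite on trees with positive branch lengths); rank-deficient candidate
designs (e.g. an edge pair spanning all tips together with the intercept)
are discarded during refit; ultrametricity is checked at 1e-6 relative
tolerance.

## Known limitations

- The shift model assumes an ultrametric tree and places shifts at the
  start of edges; within-edge shift positions are not estimated.
- α is shared across traits (per-trait α is a straightforward extension
  but not implemented); σ² is per-trait diagonal — no trait covariance.
- The selection criterion is this package's documented pBIC variant, not
  a transcription of any specific published implementation.
- Outline tracing assumes the silhouette is a single dominant component;
  interior holes are deliberately ignored.
- The exact Kendall p-value is used only for n ≤ 10 without ties; larger
  samples use the asymptotic tau-b approximation.
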