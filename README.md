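# molshape

Molecular morphometrics for venom-peptide evolution: quantify the shape of
toxin surface silhouettes with elliptic Fourier analysis (EFA), embed them
in a PCA morphospace, compare group mean shapes with thin-plate-spline
deformation heatmaps, place shape and biochemical traits on a dated
phylogeny (phylomorphospaces and phenograms), and detect shifts in
evolutionary trait optima with a multivariate Ornstein–Uhlenbeck (OU)
lasso scored by a conservative phylogenetic BIC (pBIC).

The package is aimed at comparative biologists studying structurally
conserved peptide families — the motivating system is the scorpion ICK
(inhibitor cystine knot) toxins, where the two basal clades carry
homologous peptides (calcins vs LKTx) whose *molecular shape* carries
phylogenetic signal that sequences alone understate.

## The models in brief

**Shape.** A closed outline traversed at constant speed defines periodic
coordinates expanded per harmonic n as (a_n, b_n, c_n, d_n):

```
x(t) = A0 + Σ a_n cos(2πnt/T) + b_n sin(2πnt/T)
y(t) = C0 + Σ c_n cos(2πnt/T) + d_n sin(2πnt/T)
```

Harmonic power P_n = (a_n²+b_n²+c_n²+d_n²)/2 sets the harmonic count
(smallest N reaching 99% cumulative power); flattened coefficients enter a
covariance PCA (the morphospace).

**Evolution.** Traits follow an OU process dX = α(θ − X)dt + σ dB whose
optimum θ may jump at the start of tree edges.  On an ultrametric tree the
tip means are linear in the shift effects, E[y_i] = θ0 + Σ_e β_e(1 −
e^{−ατ_ie}), so shift detection is a group-sparse regression on the edge
design after whitening by the OU covariance V_ij = e^{−αd_ij}(1 −
e^{−2αt_ij})/(2α).  Candidate configurations from the lasso path are refit
by maximum likelihood and scored with

```
pBIC(S) = −2 log L + (1 + 2m + |S|m) log n + 2 log C(2n−3, |S|) − m log det R_S
```

(m traits, n tips, |S| shifts); per-edge support comes from a parametric
bootstrap (100 replicates by default).  See `docs/methods.md` for every
definition and default.

## Worked example

The bundled synthetic pipeline generates a 48-tip dated tree with two
basal clades, clade-structured silhouette outlines in two views,
cysteine-rich peptides with a clade charge contrast, runs the full
analysis, and writes all artifacts:

```python
import molshape as ms

results = ms.run_demo(seed=17, out_dir="demo", n_tips=48, n_boot=25)
print(100 * results["pc_variance_fractions"]["frontal"][0])  # 49.70
print(results["t_tests"]["net_charge"])
# {'t': 6.527, 'p': 3.03e-05, 'df': 11.82, 'variant': 'welch'}
print(results["shift_configuration"]["shifts"])
# [{'edge_id': 16, 'clade_tips': [... 9 tips ...], 'support': 1.0, ...}]
```

Reading the numbers: PC1 of the frontal morphospace explains 49.7% of the
shape variation and separates the two clades (group test p ≈ 9e-19); net
charge differs between clades (Welch t = 6.53, p = 3.0e-05) while
molecular weight does not (t = 1.68, p = 0.11); the OU search selects one
optimum shift, on the stem edge of the 9-tip second clade (edge 16), with
bootstrap support 1.0 — i.e. the detector finds exactly the planted
clade structure and nothing else.

The same pipeline is exposed on the command line, along with each stage
separately:

```bash
molshape demo --seed 17 --out demo/            # tree, outlines, coeffs,
                                               # traits, results.json
molshape outline --in masks/ --n 300 --out outlines.csv
molshape efa --outlines outlines.csv --harmonics 20 --out coeffs.csv
molshape pca --coeffs coeffs.csv --groups groups.csv --out-prefix morpho
molshape deform --coeffs coeffs.csv --groups groups.csv \
    --group-a calcin --group-b lktx --out deform.csv
molshape props --fasta mature.fa --ph 7 --bridged-cys 6 --out props.csv
molshape shifts --tree tree.nwk --traits traits.csv --bootstrap 100 \
    --seed 17 --out shifts.json
```

Running `molshape demo` twice with the same seed produces byte-identical
`results.json`.

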