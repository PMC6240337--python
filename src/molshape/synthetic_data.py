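"""Synthetic inputs with the statistical structure the pipeline assumes.

The study's raw inputs (rendered silhouette images of toxin surface models
and a dated phylogenomic tree) are not machine-readable deliverables, so
every stage is exercised on generated stand-ins: Yule trees rescaled to the
crown-age scale of scorpions (~430 Myr), clade-structured outline families
(shared base shape + clade-specific harmonic offsets + coefficient noise),
OU trait matrices with known shift configurations, and short cysteine-rich
peptides emulating the ICK scaffold (six cysteines, three bridges).

Every generator is exactly reproducible from (parameters, seed); the demo
pipeline derives all of its stream seeds from one root seed via
``numpy.random.SeedSequence(entropy=seed, spawn_key=(k,))``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import efa as _efa
from . import morphospace as _morpho
from . import peptide_props as _props
from . import regime_shifts as _shifts
from . import stats as _stats
from .errors import BadParameter, DegenerateShape
from .outlines import Outline, write_outlines_csv
from .phylo import Phylogeny, simulate_ou, write_newick

#: default crown age (Myr) for generated trees, matching the inferred
#: diversification age scale of crown scorpions
DEFAULT_TREE_AGE = 430.0


@dataclass
class SyntheticTruth:
    """Ground truth of one generated dataset; sufficient to recompute every
    expected value used in recovery tests."""

    seed: int | None = None
    tree_newick: str = ""
    clades: dict = field(default_factory=dict)
    shift_edges: list = field(default_factory=list)
    effect_sizes: list = field(default_factory=list)
    alpha: float | None = None
    sigma2: float | None = None
    theta0: float = 0.0
    extra: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True, indent=2)


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

def make_yule_tree(n_tips: int, birth_rate: float = 1.0, seed=None,
                   age: float = DEFAULT_TREE_AGE) -> Phylogeny:
    """Pure-birth (Yule) tree conditioned on ``n_tips``, rescaled so every
    tip sits at depth ``age``; ultrametric by construction."""
    if n_tips < 2:
        raise BadParameter("need at least 2 tips")
    if birth_rate <= 0 or age <= 0:
        raise BadParameter("birth_rate and age must be positive")
    rng = np.random.default_rng(seed)
    # node bookkeeping: parent id, birth time, death time (None while active)
    parent = [-1, 0, 0]
    birth = [0.0, 0.0, 0.0]
    death: list[float | None] = [0.0, None, None]
    active = [1, 2]
    t = 0.0
    for k in range(2, n_tips):
        t += rng.exponential(1.0 / (birth_rate * k))
        i = active.pop(rng.integers(len(active)))
        death[i] = t
        for _ in range(2):
            parent.append(i)
            birth.append(t)
            death.append(None)
            active.append(len(parent) - 1)
    t += rng.exponential(1.0 / (birth_rate * n_tips))
    for i in active:
        death[i] = t

    scale = age / t
    is_tip = [death[i] is not None and not any(p == i for p in parent)
              for i in range(len(parent))]
    tip_old = [i for i, x in enumerate(is_tip) if x]
    internal_old = [i for i, x in enumerate(is_tip) if not x]
    new_id = {old: k for k, old in enumerate(tip_old)}
    new_id.update({old: len(tip_old) + k for k, old in enumerate(internal_old)})
    n = len(parent)
    new_parent = np.full(n, -1, dtype=int)
    new_len = np.zeros(n)
    for old in range(n):
        i = new_id[old]
        if parent[old] >= 0:
            new_parent[i] = new_id[parent[old]]
            new_len[i] = (death[old] - birth[old]) * scale
    labels = [f"t{k + 1:02d}" for k in range(len(tip_old))]
    return Phylogeny(new_parent, new_len, labels)


def two_clade_labels(tree: Phylogeny,
                     names: tuple[str, str] = ("calcin", "lktx")) -> pd.Series:
    """Label tips by the two basal clades (the root's child subtrees); the
    subtree holding the lowest tip id gets ``names[0]``."""
    kids = sorted(tree.children[tree.root],
                  key=lambda c: int(tree.descendant_tips(c).min()))
    out = {}
    for name, child in zip(names, kids):
        for tip in tree.descendant_tips(child):
            out[tree.tip_labels[tip]] = name
    return pd.Series(out).reindex(tree.tip_labels)


# ---------------------------------------------------------------------------
# Shape families
# ---------------------------------------------------------------------------

def default_base_shape(n_harmonics: int = 20) -> _efa.EFACoefficients:
    """A smooth asymmetric blob with dominant first harmonic (an ellipse with
    mild higher-harmonic content), the common scaffold of both clades."""
    a = np.zeros(n_harmonics)
    b = np.zeros(n_harmonics)
    c = np.zeros(n_harmonics)
    d = np.zeros(n_harmonics)
    a[0], d[0] = 2.0, 1.2
    a[2], c[1], d[2] = 0.10, 0.08, 0.05
    return _efa.EFACoefficients(a, b, c, d, label="base")


def default_clade_offsets(n_harmonics: int = 20,
                          names: tuple[str, str] = ("calcin", "lktx"),
                          ) -> dict[str, np.ndarray]:
    """Per-clade coefficient deltas (4 x N arrays, rows a/b/c/d): the first
    clade gains apex-like second/third-harmonic content (slender, tipped),
    the second becomes more globular (closer first-harmonic axes)."""
    apex = np.zeros((4, n_harmonics))
    apex[0, 1], apex[3, 2], apex[2, 2] = 0.18, 0.12, 0.06
    globular = np.zeros((4, n_harmonics))
    globular[3, 0], globular[0, 1] = 0.35, -0.05
    return {names[0]: apex, names[1]: globular}


def make_shape_family(base: _efa.EFACoefficients,
                      clade_offsets: dict[str, np.ndarray],
                      noise_sd: float = 0.02,
                      n_per_clade: int | dict[str, int] = 20,
                      seed=None, n_points: int = 300,
                      labels: dict[str, list[str]] | None = None,
                      ):
    """Generate outline families: per shape, coefficients = base + clade
    offset + iid Gaussian noise on every harmonic coefficient; outlines are
    the inverse transforms.  Returns (outlines, coefficients, groups, truth).

    ``labels`` optionally names the members of each clade (e.g. tip labels);
    otherwise ``{clade}_{i:02d}`` is used.  Raises :class:`DegenerateShape`
    if offsets or noise destroy first-harmonic dominance (the closed-curve
    validity of the family).
    """
    if noise_sd < 0:
        raise BadParameter("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    outlines: list[Outline] = []
    coeffs: list[_efa.EFACoefficients] = []
    groups: dict[str, str] = {}
    for clade in sorted(clade_offsets):
        off = np.asarray(clade_offsets[clade], dtype=float)
        if off.shape != (4, base.n_harmonics):
            raise BadParameter("each clade offset must be a 4 x N array")
        if labels is not None:
            member_names = labels[clade]
        else:
            count = (n_per_clade if isinstance(n_per_clade, int)
                     else n_per_clade[clade])
            member_names = [f"{clade}_{i:02d}" for i in range(count)]
        for name in member_names:
            noise = noise_sd * rng.standard_normal((4, base.n_harmonics))
            mat = np.stack([base.a, base.b, base.c, base.d]) + off + noise
            cf = _efa.EFACoefficients(*mat, dc=base.dc, label=name)
            power = 0.5 * (mat ** 2).sum(axis=0)
            if power[0] < 0.5 * power.sum():
                raise DegenerateShape(
                    f"shape {name!r}: first harmonic no longer dominant")
            coeffs.append(cf)
            outlines.append(_efa.efa_inverse(cf, n_points))
            groups[name] = clade
    truth = SyntheticTruth(
        seed=None, clades=groups,
        extra={"noise_sd": noise_sd,
               "base": base.flattened(include_dc=True).tolist(),
               "offsets": {k: np.asarray(v).tolist()
                           for k, v in clade_offsets.items()}})
    return outlines, coeffs, pd.Series(groups), truth


# ---------------------------------------------------------------------------
# Trait matrices with known shift configurations
# ---------------------------------------------------------------------------

DEFAULT_TRAIT_NAMES = ("pc1_frontal", "pc2_frontal", "pc1_lateral",
                       "pc2_lateral", "net_charge", "mol_volume",
                       "mol_weight")


def make_trait_dataset(tree: Phylogeny, shift_edges=(), effect_sizes=(),
                       alpha: float = 0.01, sigma2: float = 1.0,
                       n_traits: int = 7, seed: int = 0,
                       trait_names=None) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Multivariate OU tip data with a shared shift configuration.

    ``effect_sizes`` is (n_shifts, n_traits)-broadcastable: the optimum of
    every trait jumps by its effect at the start of the corresponding shift
    edge (the multivariate assumption of the shift analysis).  Each trait
    column is simulated independently given the shared configuration, with
    per-trait seeds derived from ``seed``.
    """
    shift_edges = [int(e) for e in np.atleast_1d(shift_edges)] \
        if len(np.atleast_1d(shift_edges)) else []
    eff = np.broadcast_to(np.asarray(effect_sizes, dtype=float).reshape(
        len(shift_edges), -1) if len(shift_edges) else
        np.zeros((0, n_traits)), (len(shift_edges), n_traits)).copy()
    if trait_names is None:
        trait_names = (list(DEFAULT_TRAIT_NAMES) if n_traits == 7
                       else [f"trait{j + 1}" for j in range(n_traits)])
    cols = {}
    for j in range(n_traits):
        theta = np.concatenate([[0.0], eff[:, j]])
        rng_seed = np.random.SeedSequence(entropy=seed, spawn_key=(j,))
        col = simulate_ou(tree, alpha, sigma2, theta_by_regime=theta,
                          shift_edges=shift_edges, seed=rng_seed, n_cols=1)
        cols[trait_names[j]] = col.iloc[:, 0]
    traits = pd.DataFrame(cols)
    truth = SyntheticTruth(seed=seed, tree_newick=write_newick(tree),
                           shift_edges=shift_edges,
                           effect_sizes=eff.tolist(), alpha=alpha,
                           sigma2=sigma2)
    return traits, truth


# ---------------------------------------------------------------------------
# Peptides
# ---------------------------------------------------------------------------

def make_peptides(n: int, length_range: tuple[int, int] = (33, 36),
                  n_cysteines: int = 6, seed=None, composition=None,
                  ids=None, clade: str = "") -> list[_props.PeptideRecord]:
    """Random cysteine-rich peptides: exactly ``n_cysteines`` C residues at
    random positions, the rest drawn from ``composition`` (weights over the
    19 non-C residues; uniform by default)."""
    lo, hi = length_range
    if lo < n_cysteines:
        raise BadParameter("length_range shorter than the cysteine count")
    if n < 1:
        raise BadParameter("n must be positive")
    rng = np.random.default_rng(seed)
    residues = sorted(_props.STANDARD_RESIDUES - {"C"})
    w = np.array([1.0 if composition is None else
                  float(composition.get(r, 1.0)) for r in residues])
    w = w / w.sum()
    records = []
    for i in range(n):
        length = int(rng.integers(lo, hi + 1))
        seq = rng.choice(residues, size=length, p=w)
        pos = rng.choice(length, size=n_cysteines, replace=False)
        seq[pos] = "C"
        name = ids[i] if ids is not None else f"pep{i + 1:03d}"
        records.append(_props.PeptideRecord(name, "".join(seq), clade=clade))
    return records


def write_fasta(records: list[_props.PeptideRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.sequence}\n")


# ---------------------------------------------------------------------------
# End-to-end demo pipeline
# ---------------------------------------------------------------------------

#: residue-composition biases emulating the clades' charge contrast
#: (calcins are lysine/arginine-rich; the LKTx-like clade leans acidic)
CLADE_COMPOSITIONS = {
    "calcin": {"K": 4.0, "R": 3.0},
    "lktx": {"D": 3.0, "E": 2.0},
}


def run_demo(seed: int = 17, out_dir=None, n_tips: int = 48,
             n_boot: int = 100, n_harmonics: int = 20,
             noise_sd: float = 0.02) -> dict:
    """Full synthetic analysis: tree -> clade-structured shapes (two views)
    -> EFA -> PCA morphospace -> biochemical traits -> t tests / Kendall
    correlations -> OU shift detection with bootstrap support.

    Deterministic given ``seed``; when ``out_dir`` is given, writes tree.nwk,
    outlines.csv, coeffs.csv, traits.csv, peptides.fa, truth.json and
    results.json there and returns the results dict.
    """
    def subseed(k: int) -> np.random.SeedSequence:
        return np.random.SeedSequence(entropy=seed, spawn_key=(k,))

    tree = make_yule_tree(n_tips, seed=subseed(0))
    clades = two_clade_labels(tree)
    base = default_base_shape(n_harmonics)
    offsets = default_clade_offsets(n_harmonics)
    tip_by_clade = {c: [t for t in tree.tip_labels if clades[t] == c]
                    for c in ("calcin", "lktx")}

    views, view_scores, all_outlines, all_coeffs = {}, {}, [], []
    for k, view in enumerate(("frontal", "lateral")):
        # the lateral view carries the clade contrast too, expressed in the
        # opposite direction (swapped offsets, slightly amplified)
        off = offsets if view == "frontal" else {
            "calcin": 1.2 * offsets["lktx"], "lktx": 1.2 * offsets["calcin"]}
        outlines, coeffs, groups, _ = make_shape_family(
            base, off, noise_sd=noise_sd, seed=subseed(1 + k),
            labels=tip_by_clade)
        for o, c in zip(outlines, coeffs):
            o.label = c.label = f"{o.label}_{view}"
        all_outlines.extend(outlines)
        all_coeffs.extend(coeffs)
        mat = _morpho.build_shape_matrix(
            coeffs, groups=[clades[lbl.rsplit("_", 1)[0]]
                            for lbl in (c.label for c in coeffs)], view=view)
        res = _morpho.pca(mat)
        res.scores.index = [lbl.rsplit("_", 1)[0] for lbl in res.scores.index]
        views[view] = (mat, res)
        view_scores[view] = res.scores[["PC1", "PC2"]]

    peptides = []
    for k, clade in enumerate(("calcin", "lktx")):
        peptides.extend(make_peptides(
            len(tip_by_clade[clade]), seed=subseed(3 + k),
            composition=CLADE_COMPOSITIONS[clade], ids=tip_by_clade[clade],
            clade=clade))
    props = _props.properties_table(peptides,
                                    bridged_cys=_props.ICK_BRIDGED_CYS)

    traits = pd.DataFrame({
        "pc1_frontal": view_scores["frontal"]["PC1"],
        "pc2_frontal": view_scores["frontal"]["PC2"],
        "pc1_lateral": view_scores["lateral"]["PC1"],
        "pc2_lateral": view_scores["lateral"]["PC2"],
        "net_charge": props["net_charge_pH7"],
        "mol_volume": props["volume_a3"],
        "mol_weight": props["mw_da"],
    }).reindex(tree.tip_labels)

    t_tests = {}
    for col in ("net_charge", "mol_weight", "mol_volume"):
        x = traits.loc[clades == "calcin", col]
        y = traits.loc[clades == "lktx", col]
        r = _stats.two_sample_t(x, y, variant="welch")
        t_tests[col] = {"t": r.statistic, "p": r.p_value, "df": r.df,
                        "variant": r.variant}
    corr = _stats.correlation_matrix(traits)

    pc_tests = {}
    for view, (mat, res) in views.items():
        for pc in ("PC1", "PC2"):
            r = _morpho.pc_group_test(res.scores[pc],
                                      clades.loc[res.scores.index])
            pc_tests[f"{pc.lower()}_{view}"] = {
                "statistic": r.statistic, "p": r.p_value}

    config = _shifts.fit_regime_shifts(tree, traits)
    support = {}
    if n_boot > 0 and config.edges:
        sup = _shifts.bootstrap_support(tree, traits, config, n_reps=n_boot,
                                        seed=int(subseed(5).entropy))
        support = {str(int(e)): float(v) for e, v in sup.items()}

    min_h99 = max(_efa.min_harmonics_for_power(c, 0.99) for c in all_coeffs)

    results = {
        "seed": seed,
        "n_tips": n_tips,
        "clade_sizes": {c: len(v) for c, v in tip_by_clade.items()},
        "pc_variance_fractions": {
            view: [float(f) for f in res.variance_fractions[:4]]
            for view, (mat, res) in views.items()},
        "pc_group_tests": pc_tests,
        "t_tests": t_tests,
        "kendall_tau": {
            "pc1_frontal_vs_net_charge":
                float(corr.tau.loc["pc1_frontal", "net_charge"]),
            "pc1_lateral_vs_net_charge":
                float(corr.tau.loc["pc1_lateral", "net_charge"]),
        },
        "min_harmonics_for_99pct_power": int(min_h99),
        "shift_configuration": config.to_dict(tree),
        "bootstrap_support": support,
        "bootstrap_replicates": n_boot,
    }

    truth = SyntheticTruth(
        seed=seed, tree_newick=write_newick(tree),
        clades=clades.to_dict(),
        extra={"noise_sd": noise_sd, "n_harmonics": n_harmonics,
               "compositions": CLADE_COMPOSITIONS})

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "tree.nwk").write_text(write_newick(tree) + "\n")
        write_outlines_csv(all_outlines, out / "outlines.csv")
        _efa.write_coeffs_csv(all_coeffs, out / "coeffs.csv")
        traits.rename_axis("tip_label").to_csv(out / "traits.csv")
        write_fasta(peptides, out / "peptides.fa")
        (out / "truth.json").write_text(truth.to_json() + "\n")
        (out / "results.json").write_text(
            json.dumps(results, sort_keys=True, indent=2) + "\n")
    return results
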