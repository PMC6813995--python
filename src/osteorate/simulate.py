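"""Synthetic-data generators for every input the pipeline consumes.

All generators are pure functions of (config, seed): a fixed seed yields
identical trees, trait tables, branch rates and images across runs.  Each
generator also returns its ground truth (habitat clade, coupled gene ids,
generating image parameters) so recovery can be tested closed-loop.

What is emulated
----------------
* an ultrametric pure-birth tree (depth normalized to 1) standing in for a
  time-calibrated mammal phylogeny (default 27 tips);
* Brownian-motion bone traits with tunable Pagel's lambda, a habitat
  contrast painted either on one clade (the realistic, phylogenetically
  clustered case) or at random, and a body-size proxy MD correlated with
  S, Cc and Cp;
* per-gene branch-wise dN and dS in which a chosen subset of genes has its
  branch omega linearly coupled to the trait value at the branch midpoint
  (ancestral states are taken from the simulation itself, so no
  reconstruction step is involved), plus multiplicative lognormal noise on
  both dS and dN — the dN noise is what gives uncoupled genes non-degenerate
  root-to-tip values, as real estimation error would;
* binary annular bone sections whose radial occupancy follows the sigmoid
  compactness model with known S, P, Min, Max.
"""

from __future__ import annotations

import random as _random
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .bone_image import BoneSection, sigmoid
from .errors import InvalidInputError
from .phylo import PhyloTree, normalize_label
from .rates import BranchRate, BranchRates

__all__ = [
    "SimulationConfig",
    "gen_tree",
    "gen_traits",
    "gen_branch_rates",
    "gen_bone_section",
    "codeml_freeratio_text",
]


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the scale of a mammal-wide comparative design: 27
    species, 348 candidate genes, tree depth 1, unit Brownian rate.  The
    rate-coupling ``effect_size`` is calibrated so a coupled gene is
    detected with roughly 90% power at n_tips = 27 and alpha = 0.05.
    """

    seed: int
    n_tips: int = 27
    lambda_true: float = 1.0
    sigma2: float = 1.0
    habitat_assignment: str = "clustered"  # or "random"
    habitat_effect: float = 3.0  # offset in units of the BM tip s.d.
    size_correlation: float = 0.5  # trait-vs-size-proxy correlation
    n_genes: int = 348
    n_coupled: int = 35
    focal_variable: str = "Cc"
    effect_size: float = 0.05  # branch omega per unit (z-scale) trait
    omega_baseline: float = 0.2
    dS_rate: float = 0.2  # synonymous subs per unit branch length
    ds_noise_sd: float = 0.2  # lognormal sigma on branch dS
    dn_noise_sd: float = 0.2  # lognormal sigma on branch dN
    # bone-section image parameters
    image_size: int = 512
    S_true: float = 0.05
    P_true: float = 0.4
    Min_true: float = 0.1
    Max_true: float = 0.95

    def __post_init__(self):
        if self.seed is None:
            raise InvalidInputError("seed is mandatory")
        if self.n_coupled > self.n_genes:
            raise InvalidInputError("n_coupled must be <= n_genes")
        for name in ("sigma2", "dS_rate", "omega_baseline"):
            if getattr(self, name) <= 0:
                raise InvalidInputError(f"{name} must be positive")


# ---------------------------------------------------------------------------
# tree
# ---------------------------------------------------------------------------


def gen_tree(n_tips: int = 27, seed: int = 0) -> PhyloTree:
    """Pure-birth (Yule, unit birth rate) ultrametric tree, depth normalized
    to 1.

    The process starts from the root split (two lineages), waits an
    Exponential(k) time while k lineages are extant, splits a uniformly
    chosen lineage, and — once n lineages exist — runs one final
    Exponential(n) stretch to the present, so terminal branches are never
    zero-length.  Tips are labelled sp01..spNN; internal nodes n1, n2, ...
    so branch records in long-format CSVs can name them.
    """
    if n_tips < 4:
        raise InvalidInputError("n_tips must be >= 4")
    rng = np.random.default_rng(int(seed))

    tree = dendropy.Tree()
    root = tree.seed_node
    t = 0.0
    birth_time = {root: 0.0}
    active = []
    for _ in range(2):
        child = root.new_child()
        birth_time[child] = 0.0
        active.append(child)
    while len(active) < n_tips:
        t += rng.exponential(1.0 / len(active))
        node = active.pop(rng.integers(len(active)))
        node.edge.length = t - birth_time[node]
        for _ in range(2):
            child = node.new_child()
            birth_time[child] = t
            active.append(child)
    t_end = t + rng.exponential(1.0 / len(active))
    for node in active:
        node.edge.length = t_end - birth_time[node]

    ns = dendropy.TaxonNamespace()
    tree.taxon_namespace = ns
    width = len(str(n_tips))
    for i, leaf in enumerate(tree.leaf_node_iter(), 1):
        leaf.taxon = ns.new_taxon(f"sp{i:0{width}d}")
    j = 0
    for node in tree.preorder_node_iter():
        if node.edge.length is not None:
            node.edge.length /= t_end
        if not node.is_leaf():
            j += 1
            node.label = f"n{j}"
    tree.seed_node.edge.length = None
    return PhyloTree(tree)


# ---------------------------------------------------------------------------
# traits
# ---------------------------------------------------------------------------


def _bm_node_states(tree: PhyloTree, sigma2: float, rng) -> dict:
    """Brownian node states (root = 0), keyed by dendropy node."""
    states = {}
    for node in tree.tree.preorder_node_iter():
        if node.parent_node is None:
            states[node] = 0.0
        else:
            length = node.edge.length or 0.0
            states[node] = states[node.parent_node] + rng.normal(
                0.0, np.sqrt(sigma2 * length)
            )
    return states


def _pick_habitat_clade(tree: PhyloTree, target_frac: float = 1.0 / 3.0):
    """Deterministically pick the internal node whose clade is closest in
    size to target_frac of the tips (ties: larger clade, then first in
    preorder)."""
    n = tree.n_tips
    target = max(3, round(target_frac * n))
    best = None
    for node in tree.tree.preorder_internal_node_iter():
        if node.parent_node is None:
            continue
        size = sum(1 for _ in node.leaf_iter())
        if size > n - 2:  # must leave >= 2 species outside
            continue
        key = (abs(size - target), -size)
        if best is None or key < best[0]:
            best = (key, node)
    return best[1]


# natural-scale affine maps for the rib variable set: (centre, per-z slope,
# clip range, habitat direction, correlated-with-size flag)
_VARIABLE_MAPS = {
    "S": (0.25, 0.06, (0.01, 1.0), +1, True),
    "P": (0.5, 0.10, (0.0, 1.0), 0, False),
    "Cc": (0.5, 0.08, (0.0, 1.0), +1, True),
    "Cp": (0.8, 0.05, (0.0, 1.0), -1, True),
    "Cg": (0.6, 0.08, (0.0, 1.0), 0, False),
}


@dataclass
class SimulatedTraits:
    """Trait table plus the ground truth behind it."""

    table: pd.DataFrame
    habitat: pd.Series
    aquatic_tips: frozenset
    focal_z: pd.Series  # z-scale focal trait at the tips
    branch_midpoint_z: dict  # child-clade frozenset -> focal z at branch midpoint


def gen_traits(tree: PhyloTree, config: SimulationConfig) -> SimulatedTraits:
    """Habitat-structured Brownian bone traits with a body-size proxy.

    Each variable is an affine map of a z-scale process
    ``z = rho * z_size + sqrt(1 - rho^2) * BM + dir * habitat_effect`` (the
    habitat offset applies inside the aquatic clade; S and Cc shift up, Cp
    down, mimicking the aquatic bone-microstructure contrast).  With
    ``lambda_true < 1`` tips receive an extra independent normal component so
    the tip covariance is the lambda-scaled Brownian matrix.  MD is lognormal
    in its own Brownian process.
    """
    rng = np.random.default_rng(config.seed)
    tips = tree.tip_labels
    sd_tip = float(np.sqrt(config.sigma2 * tree.depth))

    if config.habitat_assignment == "clustered":
        clade = _pick_habitat_clade(tree)
        aquatic = frozenset(
            normalize_label(l.taxon.label) for l in clade.leaf_iter()
        )
        aquatic_nodes = set(clade.preorder_iter())
    elif config.habitat_assignment == "random":
        k = max(3, round(len(tips) / 3))
        aquatic = frozenset(rng.choice(tips, size=k, replace=False))
        aquatic_nodes = {
            l for l in tree.tree.leaf_node_iter()
            if normalize_label(l.taxon.label) in aquatic
        }
    else:
        raise InvalidInputError("habitat_assignment must be clustered or random")
    habitat = pd.Series(
        {t: ("aquatic" if t in aquatic else "terrestrial") for t in tips}
    )

    def tip_values(states) -> pd.Series:
        vals = {
            normalize_label(l.taxon.label): states[l]
            for l in tree.tree.leaf_node_iter()
        }
        s = pd.Series(vals).loc[tips]
        if config.lambda_true < 1.0:
            lam = config.lambda_true
            depths = pd.Series(tree.tip_depths()).loc[tips]
            extra = rng.normal(0.0, 1.0, len(tips)) * np.sqrt(
                (1.0 - lam) * config.sigma2 * depths.to_numpy()
            )
            s = np.sqrt(lam) * s + extra
        return s

    z_size = tip_values(_bm_node_states(tree, config.sigma2, rng))

    def offset_of(node) -> float:
        return config.habitat_effect * sd_tip if node in aquatic_nodes else 0.0

    table = pd.DataFrame(index=tips)
    focal_states = None
    for var, (centre, slope, clip, direction, sized) in _VARIABLE_MAPS.items():
        states = _bm_node_states(tree, config.sigma2, rng)
        rho = config.size_correlation if sized else 0.0
        z = rho * z_size + np.sqrt(1.0 - rho**2) * tip_values(states)
        z = z + direction * config.habitat_effect * sd_tip * habitat.eq(
            "aquatic"
        ).astype(float)
        table[var] = np.clip(centre + slope * (z / max(sd_tip, 1e-12)), *clip)
        if var == config.focal_variable:
            focal_states, focal_rho, focal_dir = states, rho, direction
    if focal_states is None:
        raise InvalidInputError(
            f"focal_variable {config.focal_variable!r} not in variable set"
        )
    table["MD"] = np.exp(2.0 + 0.5 * z_size / max(sd_tip, 1e-12))
    table["habitat"] = habitat

    # z-scale focal trait at tips and at branch midpoints (size component is
    # tip-only, so midpoints use the focal BM process plus the habitat step)
    focal_z = pd.Series(index=tips, dtype=float)
    for l in tree.tree.leaf_node_iter():
        t = normalize_label(l.taxon.label)
        focal_z[t] = (
            focal_rho * z_size[t]
            + np.sqrt(1.0 - focal_rho**2) * focal_states[l]
            + focal_dir * config.habitat_effect * sd_tip * (t in aquatic)
        )
    midpoints = {}
    for clade_set, node in tree.clade_tipsets().items():
        parent = node.parent_node
        off = 0.5 * (offset_of(node) * focal_dir + offset_of(parent) * focal_dir)
        midpoints[clade_set] = (
            np.sqrt(1.0 - focal_rho**2)
            * 0.5
            * (focal_states[node] + focal_states[parent])
            + off
        )
    return SimulatedTraits(
        table=table,
        habitat=habitat,
        aquatic_tips=aquatic,
        focal_z=focal_z,
        branch_midpoint_z=midpoints,
    )


# ---------------------------------------------------------------------------
# branch rates
# ---------------------------------------------------------------------------


@dataclass
class SimulatedRates:
    rates: dict  # gene_id -> BranchRates
    coupled_genes: list


def gen_branch_rates(
    tree: PhyloTree,
    traits: SimulatedTraits,
    config: SimulationConfig,
    degenerate: bool = False,
) -> SimulatedRates:
    """Per-gene branch dN/dS with trait coupling for a known gene subset.

    For every branch: ``dS = dS_rate * length * LogNormal(ds_noise_sd)``;
    ``omega = omega_baseline (+ effect_size * focal z at the branch
    midpoint, for coupled genes)``, floored at 0.01; ``dN = omega * dS *
    LogNormal(dn_noise_sd)``.  ``degenerate=True`` zeroes dS on one branch of
    every gene to exercise the downstream division guards.
    """
    rng = np.random.default_rng(config.seed + 1)
    width = len(str(config.n_genes))
    genes = [f"g{i + 1:0{width}d}" for i in range(config.n_genes)]
    coupled = sorted(
        rng.choice(genes, size=config.n_coupled, replace=False).tolist()
    )
    coupled_set = set(coupled)
    branches = list(tree.clade_tipsets().items())
    lengths = {cl: (node.edge.length or 0.0) for cl, node in branches}

    out = {}
    for gene in genes:
        rec = BranchRates(gene_id=gene)
        kill = rng.integers(len(branches)) if degenerate else -1
        for b, (cl, _node) in enumerate(branches):
            ds = config.dS_rate * max(lengths[cl], 1e-6) * rng.lognormal(
                0.0, config.ds_noise_sd
            )
            omega = config.omega_baseline
            if gene in coupled_set:
                omega = max(
                    0.01,
                    omega + config.effect_size * traits.branch_midpoint_z[cl],
                )
            dn = omega * ds * rng.lognormal(0.0, config.dn_noise_sd)
            if b == kill:
                ds, dn = 0.0, 0.0
            rec.add(
                BranchRate(
                    clade=cl, dn=dn, ds=ds,
                    omega=(dn / ds if ds > 1e-6 else float("nan")),
                )
            )
        out[gene] = rec
    return SimulatedRates(rates=out, coupled_genes=coupled)


def rates_to_csv_frame(sim: SimulatedRates, tree: PhyloTree) -> pd.DataFrame:
    """Long-format frame (gene, child, dN, dS, omega) round-trippable through
    :func:`osteorate.rates.read_rates_csv`."""
    tipsets = tree.clade_tipsets()
    rows = []
    for gene, rec in sim.rates.items():
        for cl, r in rec.records.items():
            node = tipsets[cl]
            child = (
                normalize_label(node.taxon.label)
                if node.is_leaf()
                else (node.label or "|".join(sorted(cl)))
            )
            rows.append(
                dict(gene=gene, child=child, dN=r.dn, dS=r.ds, omega=r.omega)
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# bone sections
# ---------------------------------------------------------------------------


def gen_bone_section(
    size: int = 512,
    S: float = 0.05,
    P: float = 0.4,
    cmin: float = 0.1,
    cmax: float = 0.95,
    boundary: str = "circle",
    axis_ratio: float = 0.7,
    seed: int = 0,
    species_id: str = "",
    bone_type: str = "rib",
) -> BoneSection:
    """Binary section whose radial occupancy follows the sigmoid model.

    Pixels inside the (circular or elliptical) boundary are foreground with
    probability ``sigmoid(r; S, P, cmin, cmax)`` at normalized radius r.
    """
    if size < 128:
        raise InvalidInputError("image size must be >= 128")
    rng = np.random.default_rng(seed)
    c = (size - 1) / 2.0
    a = 0.45 * size
    b = a * axis_ratio if boundary == "ellipse" else a
    yy, xx = np.mgrid[0:size, 0:size]
    r = np.sqrt(((xx - c) / a) ** 2 + ((yy - c) / b) ** 2)
    inside = r <= 1.0
    p = sigmoid(r, S, P, cmin, cmax)
    mask = inside & (rng.random((size, size)) < p)
    return BoneSection(mask, species_id=species_id, bone_type=bone_type)


# ---------------------------------------------------------------------------
# codeml-style free-ratio text (for parser fixtures and round-trip tests)
# ---------------------------------------------------------------------------


def codeml_freeratio_text(rec: BranchRates, tree: PhyloTree) -> str:
    """Render branch rates as a minimal codeml free-ratio main-output file.

    Reproduces the pieces the parser relies on: the ``TREE #`` numeric
    topology, the taxon-name tree in the same tip order, and the
    ``dN & dS for each branch`` table with codeml's node numbering (tips
    1..n in order of appearance, internal nodes n+1.. in preorder).
    """
    numbers: dict = {}
    names: list[str] = []
    for leaf in tree.tree.leaf_node_iter():
        numbers[leaf] = len(numbers) + 1
        names.append(normalize_label(leaf.taxon.label))
    n = len(names)
    k = n
    for node in tree.tree.preorder_internal_node_iter():
        k += 1
        numbers[node] = k

    def render(node, with_names: bool) -> str:
        if node.is_leaf():
            return names[numbers[node] - 1] if with_names else str(numbers[node])
        return "(" + ", ".join(render(c, with_names) for c in node.child_nodes()) + ")"

    lines = [
        f"TREE #  1:  {render(tree.tree.seed_node, False)};   MP score: -1",
        "",
        f"{render(tree.tree.seed_node, True)};",
        "",
        "dN & dS for each branch",
        "",
        " branch          t       N       S   dN/dS      dN      dS  N*dN  S*dS",
        "",
    ]
    tipsets = tree.clade_tipsets()
    for cl, node in tipsets.items():
        r = rec.records[cl]
        t = node.edge.length or 0.0
        omega = r.omega if np.isfinite(r.omega) else 0.0
        lines.append(
            f"  {numbers[node.parent_node]}..{numbers[node]}"
            f"   {t:7.4f}  900.0  300.0  {omega:7.4f} {r.dn:7.4f} {r.ds:7.4f}"
            f"  {r.dn * 900:5.1f} {r.ds * 300:5.1f}"
        )
    lines.append("")
    return "\n".join(lines)
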