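"""Synthetic comparative-genomics datasets with planted convergent gene loss.

The generator emulates the statistical shape of a family-wide bacterial
strain panel undergoing reductive genome evolution:

* a Yule (pure-birth) ultrametric phylogeny over ``n_strains`` leaves;
* a polyphyletic focal group: ``n_focal`` strains drawn from
  ``n_focal_clades`` disjoint clades on opposite sides of the root;
* loss-only evolution of ``n_families`` metabolic gene families from an
  all-present ancestor, with class-specific loss rates (carbohydrate
  class G losing fastest) and lognormal per-branch rate multipliers that
  create lineage-wide genome reduction;
* a *planted* marker signal: ``n_planted_missing`` families that suffer
  convergent extra loss inside the focal clades, and
  ``n_planted_specific`` families that suffer extra loss everywhere
  *except* the focal lineages;
* genome sizes linearly coupled to total gene counts (metabolic families
  plus a class-structured non-metabolic padding complement) with Gaussian
  measurement noise.

Everything is deterministic given the single integer seed; each stage
draws from its own named substream, so changing one stage's draw count
never perturbs another stage.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd

from .errors import ValidationError
from .io_formats import ClassCountTable, GenomeRecord, PresenceMatrix

__all__ = [
    "COG_CLASSES",
    "SimulationConfig",
    "PlantedTruth",
    "SyntheticBundle",
    "simulate_tree",
    "select_focal_clades",
    "evolve_gene_content",
    "couple_genome_sizes",
    "simulate_dataset",
]

#: The 21 single-letter COG functional classes used for bacterial panels.
COG_CLASSES = (
    "C", "D", "E", "F", "G", "H", "I", "J", "K", "L", "M",
    "N", "O", "P", "Q", "R", "S", "T", "U", "V", "Z",
)


def _substream(seed: int, name: str) -> np.random.Generator:
    """Independent, reproducible generator for one named stage."""
    return np.random.default_rng(
        [int(seed) % (2**31), zlib.crc32(name.encode()) % (2**31)]
    )


def default_class_weights() -> np.ndarray:
    """Ancestral class composition: G 9%, E 6%, the rest uniform."""
    w = np.full(len(COG_CLASSES), (1.0 - 0.09 - 0.06) / (len(COG_CLASSES) - 2))
    w[COG_CLASSES.index("G")] = 0.09
    w[COG_CLASSES.index("E")] = 0.06
    return w


def default_class_loss_scale() -> np.ndarray:
    """Relative loss-rate multipliers: G 3x, E 2x, others 1x."""
    s = np.ones(len(COG_CLASSES))
    s[COG_CLASSES.index("G")] = 3.0
    s[COG_CLASSES.index("E")] = 2.0
    return s


@dataclass
class SimulationConfig:
    """All tunables of the generator; defaults are the study conditions.

    ``base_loss_prob`` is the per-branch loss probability of an ordinary
    family on a branch of mean length; ``class_loss_scale`` multiplies it
    per class.  Convergent loss is modelled through a *niche-dispensable*
    family set shared by all focal clades: a fraction
    ``dispensable_frac`` of families (sampled with class bias
    ``dispensable_class_bias``, i.e. mostly carbohydrate genes) receives
    a susceptibility in [``dispensable_min_susceptibility``, 1], and on
    branches inside focal clades each family suffers the extra hazard
    ``focal_extra_loss`` (per mean-length branch) scaled by its
    susceptibility.  The planted-missing families are the fully
    susceptible extreme; planted-specific families instead suffer the
    extra hazard on all branches with no focal descendant.  Setting
    ``focal_extra_loss = 0`` switches the whole convergence mechanism
    off and is the clean control.  ``branch_rate_sigma`` is the log-sd
    of per-branch loss-rate multipliers and controls how widely genome
    sizes spread across the panel; ``n_padding`` is the ancestral count
    of non-metabolic genes carried per genome in addition to the
    ``n_families`` metabolic families.  ``planted_rate_scale`` keeps the
    planted families core-like (well conserved) outside the
    planted-loss regime.  ``min_clade_depth`` makes the focal clades old,
    genus-like lineages so that lineage-specific loss has branch length
    to act on.
    """

    n_strains: int = 174
    n_focal: int = 10
    n_focal_clades: int = 2
    n_families: int = 2340
    n_classes: int = 21
    class_weights: np.ndarray = field(default_factory=default_class_weights)
    base_loss_prob: float = 0.02
    class_loss_scale: np.ndarray = field(default_factory=default_class_loss_scale)
    n_planted_missing: int = 16
    n_planted_specific: int = 1
    focal_extra_loss: float = 0.5
    kb_per_gene: float = 1.0
    size_noise_sd_mbp: float = 0.05
    seed: int = 0
    # generator-model choices beyond the headline parameters
    branch_rate_sigma: float = 1.0
    branch_rate_cap: float = 8.0
    focal_core_scale: float = 0.25
    dispensable_frac: float = 0.3
    dispensable_min_susceptibility: float = 0.6
    dispensable_class_bias: dict = field(
        default_factory=lambda: {"G": 8.0, "E": 3.0}
    )
    kill_exponent: float = 8.0
    planted_rate_scale: float = 0.05
    n_padding: int = 1160
    n_groups: int = 20
    min_clade_depth: float = 0.3

    def __post_init__(self) -> None:
        self.class_weights = np.asarray(self.class_weights, dtype=float)
        self.class_loss_scale = np.asarray(self.class_loss_scale, dtype=float)
        if self.n_classes != len(COG_CLASSES):
            raise ValidationError("n_classes must equal the 21 COG classes")
        if self.class_weights.shape != (self.n_classes,):
            raise ValidationError("class_weights must have one entry per class")
        if abs(float(self.class_weights.sum()) - 1.0) > 1e-12:
            raise ValidationError("class_weights must sum to 1")
        if (self.class_weights < 0).any():
            raise ValidationError("class_weights must be non-negative")
        for name in ("base_loss_prob", "focal_extra_loss"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")
        if self.n_focal > self.n_strains:
            raise ValidationError("n_focal must not exceed n_strains")
        if self.n_focal > 0 and self.n_focal_clades > self.n_focal:
            raise ValidationError("n_focal_clades must not exceed n_focal")
        if self.n_planted_missing + self.n_planted_specific > self.n_families:
            raise ValidationError("planted families exceed n_families")
        if self.n_strains < 2:
            raise ValidationError("n_strains must be >= 2")


@dataclass
class PlantedTruth:
    """Ground truth recorded alongside a simulated dataset."""

    planted_missing: list[str]
    planted_specific: list[str]
    focal_strains: list[str]
    class_slopes: dict[str, float]


@dataclass
class SyntheticBundle:
    """One simulated dataset plus its ground truth.

    ``class_counts`` is what an annotation pipeline would report: present
    metabolic families per class plus the strain's non-metabolic padding
    genes per class (``padding`` keeps the two parts separable).
    """

    tree: dendropy.Tree
    metadata: list[GenomeRecord]
    class_counts: ClassCountTable
    presence: PresenceMatrix
    family_classes: pd.Series
    padding: pd.DataFrame
    truth: PlantedTruth


# ---------------------------------------------------------------------------
# tree simulation
# ---------------------------------------------------------------------------


def simulate_tree(n_strains: int, seed: int) -> dendropy.Tree:
    """Yule (pure-birth) ultrametric tree scaled to root depth 1.

    Exponential waiting times between splits, uniform choice of the
    splitting lineage, a final exponential wait before the present, then
    a global rescaling so every root-to-tip path length equals 1.  Leaves
    are labelled ``S1 .. Sn`` in traversal order.
    """
    if n_strains < 2:
        raise ValidationError("n_strains must be >= 2")
    rng = _substream(seed, "tree")
    tree = dendropy.Tree()
    root = tree.seed_node
    root.birth_time = 0.0
    active: list[dendropy.Node] = []
    for _ in range(2):
        child = dendropy.Node()
        child.birth_time = 0.0
        root.add_child(child)
        active.append(child)
    t = 0.0
    while len(active) < n_strains:
        t += rng.exponential(1.0 / len(active))
        idx = int(rng.integers(len(active)))
        node = active.pop(idx)
        node.split_time = t
        for _ in range(2):
            child = dendropy.Node()
            child.birth_time = t
            node.add_child(child)
            active.append(child)
    t_final = t + rng.exponential(1.0 / n_strains)
    scale = 1.0 / t_final
    for node in tree.preorder_node_iter():
        if node is root:
            node.edge.length = 0.0
            continue
        end = getattr(node, "split_time", t_final)
        node.edge.length = (end - node.birth_time) * scale
    ns = dendropy.TaxonNamespace()
    tree.taxon_namespace = ns
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon = ns.new_taxon(f"S{i}")
    return tree


def _leafsets(tree: dendropy.Tree) -> dict[dendropy.Node, frozenset[str]]:
    """Leaf-label set under every node (postorder fill)."""
    out: dict[dendropy.Node, frozenset[str]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            out[node] = frozenset({node.taxon.label})
        else:
            s: set[str] = set()
            for c in node.child_nodes():
                s |= out[c]
            out[node] = frozenset(s)
    return out


def _node_depths(tree: dendropy.Tree) -> dict[dendropy.Node, float]:
    """Root-to-node path length for every node."""
    depths: dict[dendropy.Node, float] = {tree.seed_node: 0.0}
    for nd in tree.preorder_node_iter():
        if nd.parent_node is not None:
            depths[nd] = depths[nd.parent_node] + nd.edge.length
    return depths


def select_focal_clades(
    tree: dendropy.Tree,
    n_focal: int,
    n_focal_clades: int,
    seed: int,
    min_clade_depth: float = 0.5,
    max_tries: int = 500,
) -> set[str]:
    """Pick ``n_focal`` leaves from disjoint clades spanning the root.

    Clade sizes are split as evenly as possible.  For two or more clades
    the chosen clades are required to sit in at least two different
    root-child subtrees, which makes the focal set polyphyletic with the
    union's MRCA at the root.  Candidates are restricted to clades whose
    stem attaches at least ``min_clade_depth`` (as a fraction of the tree
    depth) above the tips, mimicking old genus-level lineages with enough
    branch length for lineage-specific evolution to act on; the
    constraint is relaxed stepwise if no arrangement exists, and the
    candidate pool is resampled up to ``max_tries`` times per level
    before giving up.
    """
    leaves = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    n = len(leaves)
    if not 1 <= n_focal_clades <= n_focal <= n:
        raise ValidationError("need 1 <= n_focal_clades <= n_focal <= n_strains")
    if n_focal == n:
        return set(leaves)
    rng = _substream(seed, "focal")

    def draw_sizes(min_part: int) -> list[int]:
        # random composition of n_focal into n_focal_clades parts >= min_part
        free = n_focal - min_part * n_focal_clades
        if free == 0:
            return [min_part] * n_focal_clades
        cuts = np.sort(rng.integers(0, free + 1, size=n_focal_clades - 1))
        parts = np.diff(np.concatenate(([0], cuts, [free])))
        return [int(p) + min_part for p in parts]

    leafsets = _leafsets(tree)
    depths = _node_depths(tree)
    root = tree.seed_node
    side_of: dict[dendropy.Node, int] = {}
    for i, rc in enumerate(root.child_nodes()):
        for node in rc.preorder_iter():
            side_of[node] = i

    min_parts = [2, 1] if n_focal >= 2 * n_focal_clades else [1]
    depth_reqs = [min_clade_depth * f for f in (1.0, 0.8, 0.6, 0.4, 0.2, 0.0)]
    for min_part in min_parts:
        for depth_req in depth_reqs:
            by_size: dict[int, list[dendropy.Node]] = {}
            for node, ls in leafsets.items():
                if node is root:
                    continue
                # clade evolutionary depth: stem start to tips
                if 1.0 - depths[node] + node.edge.length < depth_req:
                    continue
                by_size.setdefault(len(ls), []).append(node)
            for cand in by_size.values():  # stable order for reproducibility
                cand.sort(key=lambda nd: min(leafsets[nd]))
            for _ in range(max_tries):
                sizes = draw_sizes(min_part)
                chosen: list[dendropy.Node] = []
                taken: set[str] = set()
                ok = True
                for s in sizes:
                    cands = [
                        nd
                        for nd in by_size.get(s, [])
                        if leafsets[nd].isdisjoint(taken)
                    ]
                    if not cands:
                        ok = False
                        break
                    nd = cands[int(rng.integers(len(cands)))]
                    chosen.append(nd)
                    taken |= leafsets[nd]
                if not ok:
                    continue
                if n_focal_clades >= 2 and len({side_of[nd] for nd in chosen}) < 2:
                    continue
                return set(taken)
    raise ValidationError(
        f"could not place {n_focal_clades} disjoint focal clades totalling "
        f"{n_focal} leaves after {max_tries} attempts"
    )


# ---------------------------------------------------------------------------
# gene-content evolution
# ---------------------------------------------------------------------------


def _hazard(prob_at_mean_branch: float, mean_branch: float) -> float:
    """Per-unit-length hazard whose mean-branch loss probability is given."""
    if prob_at_mean_branch >= 1.0:
        return math.inf
    return -math.log1p(-prob_at_mean_branch) / mean_branch


def evolve_gene_content(
    tree: dendropy.Tree,
    config: SimulationConfig,
    focal: set[str] | None = None,
) -> tuple[PresenceMatrix, pd.Series, dict]:
    """Loss-only evolution of gene families down the tree.

    Every family is present at the root.  On a branch of length ``b``
    with rate multiplier ``m``, a family of class ``c`` survives with
    probability ``exp(-lambda_c * m * b)`` where ``lambda_c`` is the
    class hazard, calibrated so the loss probability on a mean-length
    branch is ``base_loss_prob * class_loss_scale[c]``.  On branches
    inside the focal clades every family additionally faces a
    convergent-loss hazard scaled by its niche susceptibility: 1 for
    planted-missing families, a shared random value in (0, 1] for the
    niche-dispensable set, 0 otherwise.  The hazard is normalized to the
    clade's depth so that a fully susceptible family survives a whole
    stem-to-tip path with probability
    ``(1 - focal_extra_loss) ** kill_exponent`` whatever the clade's
    age; ``kill_exponent`` plays the role of the number of
    mean-branch-length steps on such a path.  Planted-*specific*
    families face the analogous extra hazard (normalized to the tree
    depth) on all branches with no focal descendant instead.  Lost
    families are never regained.

    Loss draws use one uniform per (branch, family) in a fixed preorder,
    so runs with the same seed are coupled: raising any loss probability
    can only shrink presence (common-random-numbers monotonicity).

    Returns the leaf presence matrix, the per-family class labels and a
    truth dict with planted ids and per-(class, strain) survival
    accounting used for the analytic slope calculation.
    """
    cfg = config
    rng_classes = _substream(cfg.seed, "classes")
    rng_plant = _substream(cfg.seed, "planting")
    rng_rates = _substream(cfg.seed, "rates")
    rng_loss = _substream(cfg.seed, "loss")

    nf = cfg.n_families
    family_ids = [f"K{i:05d}" for i in range(1, nf + 1)]
    class_idx = rng_classes.choice(cfg.n_classes, size=nf, p=cfg.class_weights)

    n_planted = cfg.n_planted_missing + cfg.n_planted_specific
    planted = rng_plant.choice(nf, size=n_planted, replace=False)
    planted_missing = np.sort(planted[: cfg.n_planted_missing])
    planted_specific = np.sort(planted[cfg.n_planted_missing :])
    g_idx = COG_CLASSES.index("G")
    class_idx[planted] = g_idx  # planted markers are carbohydrate genes
    is_pm = np.zeros(nf, dtype=bool)
    is_pm[planted_missing] = True
    is_ps = np.zeros(nf, dtype=bool)
    is_ps[planted_specific] = True

    edges = [nd for nd in tree.preorder_node_iter() if nd.parent_node is not None]
    blens = np.array([nd.edge.length for nd in edges])
    mean_b = float(blens.mean())
    lam_class = np.array(
        [
            _hazard(min(cfg.base_loss_prob * s, 1.0), mean_b)
            for s in cfg.class_loss_scale
        ]
    )
    lam_planted = _hazard(min(cfg.base_loss_prob * cfg.planted_rate_scale, 1.0), mean_b)
    # whole-path hazard budget of the convergent loss (inf when certain)
    kill = (
        math.inf
        if cfg.focal_extra_loss >= 1.0
        else -cfg.kill_exponent * math.log1p(-cfg.focal_extra_loss)
    )

    # per-family background hazard (planted families are core-like)
    lam_family = lam_class[class_idx].copy()
    lam_family[is_pm | is_ps] = lam_planted
    # inside the convergence regime the surviving (non-dispensable) core
    # is stabilized: streamlined genomes conserve what they keep; the
    # damping scales with focal_extra_loss and saturates at 0.5 so the
    # zero-convergence control is untouched
    core_scale = 1.0 - (1.0 - cfg.focal_core_scale) * min(
        cfg.focal_extra_loss / 0.5, 1.0
    )

    # niche susceptibility: which families the fructose-like niche makes
    # dispensable, shared across all focal clades (this is what makes the
    # focal loss convergent rather than independent)
    rng_disp = _substream(cfg.seed, "dispensable")
    suscept = np.zeros(nf)
    suscept[is_pm] = 1.0
    n_disp = int(round(cfg.dispensable_frac * nf))
    pool = np.flatnonzero(~(is_pm | is_ps))
    if n_disp > 0 and pool.size > 0:
        n_disp = min(n_disp, pool.size)
        bias = np.ones(pool.size)
        for code, w in (cfg.dispensable_class_bias or {}).items():
            bias[class_idx[pool] == COG_CLASSES.index(code)] = w
        dispensable = rng_disp.choice(
            pool, size=n_disp, replace=False, p=bias / bias.sum()
        )
        suscept[dispensable] = rng_disp.uniform(
            cfg.dispensable_min_susceptibility, 1.0, size=n_disp
        )

    focal = set(focal or ())
    leafsets = _leafsets(tree)
    depths = _node_depths(tree)
    tree_depth = max(depths[leaf] for leaf in tree.leaf_node_iter())
    # depth (stem top to tips) of the focal clade each in-focal edge sits in
    clade_depth_of: dict[dendropy.Node, float] = {}
    for nd in edges:
        if focal and leafsets[nd] <= focal:
            parent = nd.parent_node
            if parent in clade_depth_of:
                clade_depth_of[nd] = clade_depth_of[parent]
            else:  # clade root: its stem starts the convergent regime
                clade_depth_of[nd] = tree_depth - (depths[nd] - nd.edge.length)
    sigma = cfg.branch_rate_sigma
    multipliers = {}
    for nd in edges:
        # lognormal with mean 1: mu = -sigma^2/2; capped to avoid
        # single-branch catastrophes that empty whole genomes
        multipliers[nd] = min(
            float(rng_rates.lognormal(mean=-0.5 * sigma**2, sigma=sigma)),
            cfg.branch_rate_cap,
        )

    present: dict[dendropy.Node, np.ndarray] = {tree.seed_node: np.ones(nf, bool)}
    surv: dict[dendropy.Node, np.ndarray] = {tree.seed_node: np.ones(nf)}
    cls_surv: dict[dendropy.Node, np.ndarray] = {
        tree.seed_node: np.ones(cfg.n_classes)
    }
    for nd in edges:
        b = nd.edge.length
        m = multipliers[nd]
        ls = leafsets[nd]
        in_focal = bool(focal) and ls <= focal
        no_focal_below = bool(focal) and ls.isdisjoint(focal)
        log_s = -lam_family * m * b
        if in_focal:
            log_s = log_s * core_scale
            # kill may be inf (certain loss); keep 0 * inf out of the mask
            rate = kill * b / clade_depth_of[nd]
            with np.errstate(invalid="ignore"):
                extra = np.where(suscept > 0, rate * suscept, 0.0)
            log_s = log_s - extra
        if no_focal_below:
            extra = np.where(is_ps, kill * b / tree_depth, 0.0)
            log_s = log_s - extra
        s_edge = np.exp(log_s)  # exp(-inf) -> 0 handles certain loss
        u = rng_loss.random(nf)
        parent = nd.parent_node
        present[nd] = present[parent] & (u < s_edge)
        surv[nd] = surv[parent] * s_edge
        cls_surv[nd] = cls_surv[parent] * np.exp(
            -lam_class * m * b * (core_scale if in_focal else 1.0)
        )

    leaves = [leaf for leaf in tree.leaf_node_iter()]
    leaf_labels = [leaf.taxon.label for leaf in leaves]
    mat = np.stack([present[leaf] for leaf in leaves], axis=1).astype(np.int8)
    presence = PresenceMatrix(
        pd.DataFrame(mat, index=pd.Index(family_ids, name="family_id"),
                     columns=leaf_labels)
    )
    family_classes = pd.Series(
        [COG_CLASSES[i] for i in class_idx], index=family_ids, name="class"
    )
    truth = {
        "planted_missing": [family_ids[i] for i in planted_missing],
        "planted_specific": [family_ids[i] for i in planted_specific],
        "survival": np.stack([surv[leaf] for leaf in leaves], axis=1),
        "class_survival": np.stack([cls_surv[leaf] for leaf in leaves], axis=1),
        "class_idx": class_idx,
        "strains": leaf_labels,
    }
    return presence, family_classes, truth


def couple_genome_sizes(
    class_counts: ClassCountTable,
    kb_per_gene: float = 1.0,
    size_noise_sd_mbp: float = 0.05,
    seed: int = 0,
) -> np.ndarray:
    """Genome sizes linearly coupled to total gene counts.

    ``size = total_genes * kb_per_gene / 1000 + N(0, sd)``, floored at
    0.5 Mbp.  With zero noise the coupling is exact and every class
    regression on the noiseless data has r^2 = 1 against its own planted
    relation.
    """
    rng = _substream(seed, "sizes")
    totals = class_counts.total_genes().to_numpy(dtype=float)
    sizes = totals * kb_per_gene / 1000.0
    noise = rng.normal(0.0, 1.0, size=len(sizes))  # drawn even when sd == 0
    sizes = sizes + size_noise_sd_mbp * noise
    return np.maximum(sizes, 0.5)


def _assign_groups(tree: dendropy.Tree, n_groups: int) -> dict[str, str]:
    """Taxon-like group labels from the oldest splits of the tree."""
    internal = [
        nd
        for nd in tree.preorder_node_iter()
        if not nd.is_leaf() and nd.parent_node is not None
    ]
    root = tree.seed_node
    # cut the tree right below the n_groups-1 oldest internal splits
    internal.sort(key=lambda nd: getattr(nd, "birth_time", 0.0))
    cut_nodes = set(internal[: max(n_groups - 2, 0)]) | {root}
    group_roots: list[dendropy.Node] = []
    for nd in tree.preorder_node_iter():
        if nd.parent_node is not None and nd.parent_node in cut_nodes and nd not in cut_nodes:
            group_roots.append(nd)
    labels: dict[str, str] = {}
    for gi, gr in enumerate(group_roots, start=1):
        name = f"G{gi:02d}"
        for leaf in gr.leaf_iter():
            labels[leaf.taxon.label] = name
    for leaf in tree.leaf_node_iter():  # leaves hanging directly off cut nodes
        labels.setdefault(leaf.taxon.label, "G00")
    return labels


def _analytic_class_slopes(
    cfg: SimulationConfig,
    truth: dict,
    padding_ancestral: np.ndarray,
) -> dict[str, float]:
    """Population OLS slope of class count on genome size, per class.

    Computed from the model's per-(family, strain) survival probabilities
    rather than from the realized counts: the slope of the best linear
    predictor given between-strain variation in expected counts, the
    within-strain binomial variance, and the Gaussian size noise.
    """
    surv = truth["survival"]  # families x strains
    cls_surv = truth["class_survival"]  # classes x strains
    class_idx = truth["class_idx"]
    n_classes = cfg.n_classes
    mu = np.zeros((n_classes, surv.shape[1]))
    var = np.zeros_like(mu)
    for c in range(n_classes):
        rows = class_idx == c
        mu[c] = surv[rows].sum(axis=0)
        var[c] = (surv[rows] * (1.0 - surv[rows])).sum(axis=0)
    mu += padding_ancestral[:, None] * cls_surv
    var += padding_ancestral[:, None] * cls_surv * (1.0 - cls_surv)
    g2m = cfg.kb_per_gene / 1000.0  # Mbp per gene
    mu_t = mu.sum(axis=0)
    var_t = var.sum(axis=0)
    denom = (np.var(mu_t) + var_t.mean()) * g2m**2 + cfg.size_noise_sd_mbp**2
    slopes = {}
    for c in range(n_classes):
        cov = np.cov(mu[c], mu_t, bias=True)[0, 1] + var[c].mean()
        slopes[COG_CLASSES[c]] = float(cov * g2m / denom)
    return slopes


def simulate_dataset(config: SimulationConfig) -> SyntheticBundle:
    """Compose tree, focal clades, gene content, padding and sizes.

    Pure function of the config (writes nothing); the same config yields
    an identical bundle every time.
    """
    cfg = config
    tree = simulate_tree(cfg.n_strains, cfg.seed)
    if cfg.n_focal > 0:
        focal = select_focal_clades(
            tree,
            cfg.n_focal,
            cfg.n_focal_clades,
            cfg.seed,
            min_clade_depth=cfg.min_clade_depth,
        )
    else:
        focal = set()
    presence, family_classes, truth = evolve_gene_content(tree, cfg, focal)
    strains = truth["strains"]

    # metabolic class counts from the presence matrix
    mat = presence.values.to_numpy()
    class_idx = truth["class_idx"]
    met_counts = np.zeros((len(strains), cfg.n_classes), dtype=np.int64)
    for c in range(cfg.n_classes):
        met_counts[:, c] = mat[class_idx == c].sum(axis=0)

    # non-metabolic padding: class-structured complement with the same
    # class survival probabilities, drawn independently per strain
    pad_ancestral = np.floor(cfg.n_padding * cfg.class_weights).astype(np.int64)
    pad_ancestral[0] += cfg.n_padding - int(pad_ancestral.sum())
    rng_pad = _substream(cfg.seed, "padding")
    cls_surv = truth["class_survival"]  # classes x strains
    pad_counts = rng_pad.binomial(
        pad_ancestral[:, None], cls_surv
    ).T  # strains x classes
    padding = pd.DataFrame(pad_counts, index=strains, columns=list(COG_CLASSES))

    counts = pd.DataFrame(
        met_counts + pad_counts, index=pd.Index(strains, name="strain_id"),
        columns=list(COG_CLASSES),
    )
    class_counts = ClassCountTable(counts)

    sizes = couple_genome_sizes(
        class_counts, cfg.kb_per_gene, cfg.size_noise_sd_mbp, cfg.seed
    )
    groups = _assign_groups(tree, cfg.n_groups)
    metadata = [
        GenomeRecord(
            strain_id=s,
            genome_size_mbp=float(sz),
            group=groups.get(s, "G00"),
            is_focal=s in focal,
        )
        for s, sz in zip(strains, sizes)
    ]
    slopes = _analytic_class_slopes(cfg, truth, pad_ancestral)
    planted_truth = PlantedTruth(
        planted_missing=truth["planted_missing"],
        planted_specific=truth["planted_specific"],
        focal_strains=sorted(focal, key=strains.index),
        class_slopes=slopes,
    )
    return SyntheticBundle(
        tree=tree,
        metadata=metadata,
        class_counts=class_counts,
        presence=presence,
        family_classes=family_classes,
        padding=padding,
        truth=planted_truth,
    )
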