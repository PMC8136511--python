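"""Forward simulation of amino-acid loci and long-branch-attraction scenarios.

The generator emulates the statistical structure of an ordinal-level
phylogenomic data set built around a long-branch attraction (LBA)
problem: a focal clade whose basally branching subgroups are
short-branched while a derived subgroup is fast-evolving, a
short-branch true sister clade, an unrelated fast-evolving "attractor"
clade, hundreds of loci with across-locus rate variation drawn from a
gamma law, and per-locus taxon dropout that produces realistic gene
occupancy.  Long branches are created purely by multiplying branch
lengths — the substitution process itself is homogeneous — so the only
confounding mechanism in play is rate, the classic Felsenstein-zone
setting.

Sequence evolution: root states are drawn from the model's stationary
frequencies and evolved down each branch with the model's transition
matrices; per-site discrete-gamma categories are drawn with equal
weights.  No indels are simulated; gaps arise only from dropout
masking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .phylo_core.models import AMINO_ACIDS, SubstitutionModel, poisson
from .phylo_core.tree import Node, Phylogeny
from .study_design import PruningStep, TaxonRecord
from .supermatrix import LocusAlignment

_AA = np.array(list(AMINO_ACIDS))


def simulate_alignment(
    tree: Phylogeny,
    model: SubstitutionModel,
    n_sites: int,
    seed: int,
    rate_multiplier: float = 1.0,
    locus_id: str = "locus",
) -> LocusAlignment:
    """Evolve *n_sites* columns down *tree* under *model*."""
    if n_sites < 1:
        raise ValueError("need at least one site")
    rng = np.random.default_rng(seed)
    rates = model.category_rates
    cats = rng.integers(0, len(rates), size=n_sites)
    pi = model.frequencies
    states: dict[int, np.ndarray] = {}
    rows: dict[str, str] = {}
    for node in tree.preorder():
        if node.parent is None:
            states[id(node)] = rng.choice(20, size=n_sites, p=pi)
        else:
            parent_states = states[id(node.parent)]
            t = (node.length or 0.0) * rate_multiplier
            child = parent_states.copy()
            for c, rate in enumerate(rates):
                mask = cats == c
                if not mask.any():
                    continue
                P = model.transition_matrix(t * rate)
                cum = P.cumsum(axis=1)
                u = rng.random(int(mask.sum()))
                child[mask] = (u[:, None] > cum[parent_states[mask]]).sum(axis=1)
            states[id(node)] = child
        if node.is_leaf:
            rows[node.name] = "".join(_AA[states[id(node)]])
    return LocusAlignment(id=locus_id, rows=rows)


# ---- scenario configuration ----------------------------------------

@dataclass
class SubgroupSpec:
    name: str
    n_tips: int
    multiplier: float = 1.0  # applied to the subgroup tips
    stem_multiplier: float | None = None  # defaults to the tip multiplier


@dataclass
class CladeSpec:
    name: str
    subgroups: list[SubgroupSpec]
    role: str = "ingroup"

    @property
    def n_tips(self) -> int:
        return sum(s.n_tips for s in self.subgroups)


@dataclass
class ScenarioConfig:
    """Everything needed to simulate one locus set."""

    clades: list[CladeSpec]
    tree: Phylogeny
    n_loci: int = 300
    sites_min: int = 150
    sites_max: int = 400
    rate_shape: float = 1.0  # across-locus gamma (mean 1)
    dropout: float = 0.25  # per-locus, per-taxon removal probability
    model: SubstitutionModel = field(default_factory=poisson)
    seed: int = 42

    def __post_init__(self):
        if not (0.0 <= self.dropout <= 1.0):
            raise ValueError("dropout must be a probability")
        if self.rate_shape <= 0:
            raise ValueError("rate gamma shape must be positive")
        for clade in self.clades:
            for sub in clade.subgroups:
                if sub.multiplier <= 0:
                    raise ValueError("branch-length multipliers must be positive")

    def registry(self) -> list[TaxonRecord]:
        out = []
        for clade in self.clades:
            for sub in clade.subgroups:
                for i in range(sub.n_tips):
                    out.append(
                        TaxonRecord(
                            name=f"{sub.name}_{i + 1}",
                            group=clade.name,
                            subgroup=sub.name if sub.name != clade.name else "",
                            role=clade.role,
                        )
                    )
        return out


def simulate_locus_set(config: ScenarioConfig):
    """Simulate ``config.n_loci`` loci on ``config.tree``.

    Returns ``(loci, truth)`` where *truth* is a table of per-locus
    rate multipliers, lengths and dropped taxa.  Dropout removes rows
    from loci, never leaves from the truth tree.
    """
    rng = np.random.default_rng(config.seed)
    taxa = config.tree.leaf_names()
    expected = (1.0 - config.dropout) * len(taxa)
    if expected < 4:
        import warnings

        warnings.warn(
            f"expected taxa per locus ({expected:.1f}) is below 4; most loci will be untreeable",
            RuntimeWarning,
            stacklevel=2,
        )
    loci, records = [], []
    for i in range(config.n_loci):
        mult = rng.gamma(shape=config.rate_shape, scale=1.0 / config.rate_shape)
        n_sites = int(rng.integers(config.sites_min, config.sites_max + 1))
        locus_seed = int(rng.integers(0, 2**31 - 1))
        locus = simulate_alignment(
            config.tree,
            config.model,
            n_sites,
            seed=locus_seed,
            rate_multiplier=mult,
            locus_id=f"locus{i + 1:04d}",
        )
        drop = [t for t in taxa if rng.random() < config.dropout]
        if len(taxa) - len(drop) >= 1:
            locus.rows = {t: s for t, s in locus.rows.items() if t not in drop}
        else:
            drop = []
        loci.append(locus)
        records.append(
            {
                "locus": locus.id,
                "rate_multiplier": mult,
                "n_sites": n_sites,
                "dropped": ",".join(drop),
            }
        )
    return loci, pd.DataFrame(records)


# ---- the LBA scenario ----------------------------------------------

@dataclass
class LbaScenario:
    config: ScenarioConfig
    true_tree: Phylogeny
    pruned_trees: dict[str, Phylogeny]  # T-label -> tree
    pruning_steps: list[PruningStep]
    focal_group: str
    sister_group: str
    attractor_group: str
    outgroup: str


def _clade_node(subgroups, tip_len, inner_len, name_prefix=None) -> Node:
    """A ladderized clade of subgroups, each subgroup a cherry/fan of tips."""
    sub_nodes = []
    for sub in subgroups:
        node = Node()
        stem_mult = sub.multiplier if sub.stem_multiplier is None else sub.stem_multiplier
        node.length = inner_len * stem_mult
        for i in range(sub.n_tips):
            tip = Node(f"{sub.name}_{i + 1}", tip_len * sub.multiplier)
            node.add(tip)
        if sub.n_tips == 1:
            only = node.children[0]
            only.length += node.length
            node = only
        sub_nodes.append(node)
    while len(sub_nodes) > 1:
        right = sub_nodes.pop()
        left = sub_nodes.pop()
        joint = Node()
        joint.length = inner_len
        joint.add(left)
        joint.add(right)
        sub_nodes.append(joint)
    return sub_nodes[0]


def lba_scenario(
    n_basal_subgroups: int = 3,
    tips_per_basal: int = 2,
    n_derived_tips: int = 2,
    n_sister_tips: int = 4,
    n_attractor_tips: int = 4,
    n_other_tips: int = 4,
    n_outgroup_tips: int = 4,
    long_multiplier: float = 6.0,
    tip_length: float = 0.02,
    internal_length: float = 0.12,
    backbone_length: float = 0.03,
    n_loci: int = 300,
    sites_min: int = 150,
    sites_max: int = 400,
    rate_shape: float = 1.0,
    dropout: float = 0.25,
    model: SubstitutionModel | None = None,
    seed: int = 42,
) -> LbaScenario:
    """Build the default chelicerate-like LBA scenario.

    The focal clade has *n_basal_subgroups* short-branch basal
    subgroups and one fast-evolving derived subgroup; its true sister
    is a short-branch clade; an unrelated fast-evolving attractor
    clade sits outside both, separated by short internal branches.
    Sequential removal of the basal focal subgroups gives the pruned
    tree series (T0, T-1, ...), whose endpoint leaves the focal clade
    represented only by its long-branch tips — the quartet reduction of
    that endpoint is a Felsenstein-zone configuration.
    """
    if n_basal_subgroups < 1:
        raise ValueError("need at least one basal subgroup")
    basal = [
        SubgroupSpec(f"FocalBasal{i + 1}", tips_per_basal) for i in range(n_basal_subgroups)
    ]
    # long tips on the derived subgroup, but a short stem: the long
    # unbroken pendant edge only comes into existence when the basal
    # subgroups that subdivide the path to it are pruned away
    derived = SubgroupSpec(
        "FocalDerived", n_derived_tips, multiplier=long_multiplier, stem_multiplier=1.0
    )
    focal = CladeSpec("Focal", basal + [derived])
    sister = CladeSpec("Sister", [SubgroupSpec("Sister", n_sister_tips)])
    attractor = CladeSpec(
        "Attractor", [SubgroupSpec("Attractor", n_attractor_tips, multiplier=long_multiplier)]
    )
    other = CladeSpec("Other", [SubgroupSpec("Other", n_other_tips)])
    outgroup = CladeSpec("Outgroup", [SubgroupSpec("Outgroup", n_outgroup_tips)], role="outgroup")

    tip, inner, backbone = tip_length, internal_length, backbone_length
    # ladderized focal clade: the first subgroup is the basal-most split,
    # so the pruning series removes basal subgroups in order
    focal_node = _clade_node(basal + [derived], tip, inner)
    sister_node = _clade_node(sister.subgroups, tip, inner)
    attractor_node = _clade_node(attractor.subgroups, tip, inner)
    other_node = _clade_node(other.subgroups, tip, inner)
    out_node = _clade_node(outgroup.subgroups, tip, inner)

    # short backbone internodes: the deep radiation whose resolution the
    # analysis is about
    focal_node.length = backbone
    pair = Node()
    pair.length = backbone
    pair.add(sister_node)
    pair.add(focal_node)
    ingroup1 = Node()
    ingroup1.length = backbone
    ingroup1.add(other_node)
    ingroup1.add(pair)
    ingroup = Node()
    ingroup.length = backbone
    ingroup.add(attractor_node)
    ingroup.add(ingroup1)
    root = Node()
    out_node.length = backbone
    root.add(out_node)
    root.add(ingroup)
    true_tree = Phylogeny(root)

    config = ScenarioConfig(
        clades=[outgroup, attractor, other, sister, focal],
        tree=true_tree,
        n_loci=n_loci,
        sites_min=sites_min,
        sites_max=sites_max,
        rate_shape=rate_shape,
        dropout=dropout,
        model=model if model is not None else poisson(),
        seed=seed,
    )
    steps = [
        PruningStep(index=i + 1, removed_subgroups=[b.name], removed_count=b.n_tips)
        for i, b in enumerate(basal)
    ]
    pruned = {"T0": true_tree}
    removed: set[str] = set()
    for i, b in enumerate(basal):
        removed.update(f"{b.name}_{j + 1}" for j in range(b.n_tips))
        keep = [t for t in true_tree.leaf_names() if t not in removed]
        pruned[f"T-{i + 1}"] = true_tree.prune_to(keep)
    return LbaScenario(
        config=config,
        true_tree=true_tree,
        pruned_trees=pruned,
        pruning_steps=steps,
        focal_group="Focal",
        sister_group="Sister",
        attractor_group="Attractor",
        outgroup="Outgroup",
    )


def attractor_alternative(scenario: LbaScenario, subset: str = "T0") -> Phylogeny:
    """The competing hypothesis topology: the focal clade regrafted as
    sister of the attractor clade (the placement an LBA artifact
    produces), on the requested taxon subset's tree."""
    tree = scenario.pruned_trees[subset].copy()
    focal = frozenset(
        n for n in tree.leaf_names()
        if any(n.startswith(f"{s}_") for s in _focal_subgroup_names(scenario))
    )
    attractor = frozenset(
        n for n in tree.leaf_names() if n.startswith(f"{scenario.attractor_group}")
    )
    focal_node = tree.find_clade(focal)
    if focal_node is None or focal_node.parent is None:
        raise ValueError("focal clade not available on this subset")
    parent = focal_node.parent
    parent.children.remove(focal_node)
    focal_node.parent = None
    if len(parent.children) == 1 and parent.parent is not None:
        only = parent.children[0]
        only.length = (only.length or 0.0) + (parent.length or 0.0)
        gp = parent.parent
        gp.children[gp.children.index(parent)] = only
        only.parent = gp
    att_node = tree.find_clade(attractor)
    half = (att_node.length or 0.02) / 2.0
    joint = Node()
    joint.length = half
    att_parent = att_node.parent
    att_parent.children[att_parent.children.index(att_node)] = joint
    joint.parent = att_parent
    att_node.length = half
    joint.add(att_node)
    joint.add(focal_node)
    return Phylogeny(tree.root)


def _focal_subgroup_names(scenario: LbaScenario) -> list[str]:
    focal_clades = [c for c in scenario.config.clades if c.name == scenario.focal_group]
    return [s.name for c in focal_clades for s in c.subgroups]


def felsenstein_zone_quartet(
    p_long: float,
    p_short: float,
    internal: float,
    n_sites: int,
    seed: int,
    model: SubstitutionModel | None = None,
):
    """Classic two-long-branches-separated quartet ((A,C),(B,D)).

    A and B are short, C and D long; the true unrooted topology groups
    A with C and B with D.  Returns ``(alignment, true_tree)``.
    """
    for v in (p_long, p_short, internal):
        if v <= 0:
            raise ValueError("branch lengths must be positive")
    from .phylo_core.tree import read_newick

    tree = read_newick(
        f"((A:{p_short},C:{p_long}):{internal / 2.0},(B:{p_short},D:{p_long}):{internal / 2.0});"
    )
    aln = simulate_alignment(
        tree, model if model is not None else poisson(), n_sites, seed, locus_id="quartet"
    )
    return aln, tree
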