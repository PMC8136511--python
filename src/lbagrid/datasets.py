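"""Bundled study-design constants and small fixtures.

The chelicerate registry reproduces the ordinal composition of the
phylogenomic data set the package's grid accounting is built around:
117 chelicerate ingroup terminals (40 pseudoscorpions spanning all
superfamilies, 12 scorpions, 17 spiders, 4 Pedipalpi, 13 harvestmen,
5 Ricinulei, 3 horseshoe crabs, 2 Solifugae, 9 Parasitiformes,
10 Acariformes, 2 sea spiders) plus 15 outgroups (3 Onychophora,
4 Myriapoda, 8 Pancrustacea).  Terminal names are synthetic
(``<Group>_<i>``); only the counts and group structure matter for
design accounting.

The ancestral-state fixture is an order-level chelicerate tree with
binary characters for the *promenade à deux* courtship dance,
maternal brood care, and book lungs.  Pseudoscorpiones is coded
present for the promenade (retention in Cheliferoidea); the
sub-ordinal loss/regain story is below the tip granularity of the
fixture.  The ohnolog fixture is a schematic gene tree of a
twice-retained appendage-patterning gene (dachshund-style) whose two
ohnolog clusters each contain spider, scorpion and pseudoscorpion
copies, with a single-copy mite ortholog outside.
"""

from __future__ import annotations

from .phylo_core.tree import Phylogeny, read_newick
from .rgc import CharacterMatrix
from .study_design import OccupancyFamily, PruningStep, TaxonRecord, occupancy_families

# ---- chelicerate study design ---------------------------------------

INGROUP_ORDERS = {
    "Pseudoscorpiones": 40,
    "Scorpiones": 12,
    "Araneae": 17,
    "Pedipalpi": 4,
    "Opiliones": 13,
    "Ricinulei": 5,
    "Xiphosura": 3,
    "Solifugae": 2,
    "Parasitiformes": 9,
    "Acariformes": 10,
    "Pycnogonida": 2,
}

OUTGROUP_ORDERS = {
    "Onychophora": 3,
    "Myriapoda": 4,
    "Pancrustacea": 8,
}

#: pseudoscorpion superfamilies with terminal counts; ordered basally
#: branching first (the order of the sequential pruning series)
PSEUDOSCORPION_SUBGROUPS = {
    "Chthonioidea": 6,
    "Feaelloidea": 2,
    "Neobisioidea": 10,
    "Garypoidea": 5,
    "Garypinoidea": 3,
    "Cheridoidea": 1,
    "Sternophoroidea": 1,
    "Cheliferoidea": 12,
}

OCCUPANCY_THRESHOLDS = [0.55, 0.60, 0.65, 0.70, 0.75, 0.80]


def chelicerate_registry() -> list[TaxonRecord]:
    records = []
    for group, n in INGROUP_ORDERS.items():
        if group == "Pseudoscorpiones":
            for subgroup, k in PSEUDOSCORPION_SUBGROUPS.items():
                for i in range(k):
                    records.append(
                        TaxonRecord(
                            name=f"{subgroup}_{i + 1}",
                            group=group,
                            subgroup=subgroup,
                        )
                    )
        else:
            for i in range(n):
                records.append(TaxonRecord(name=f"{group}_{i + 1}", group=group))
    for group, n in OUTGROUP_ORDERS.items():
        for i in range(n):
            records.append(
                TaxonRecord(name=f"{group}_{i + 1}", group=group, role="outgroup")
            )
    return records


def chelicerate_pruning_steps() -> list[PruningStep]:
    """Sequential removal of basally branching pseudoscorpion
    superfamilies until only Cheliferoidea remains; the two smallest
    superfamilies are removed as one step."""
    return [
        PruningStep(1, ["Chthonioidea"], removed_count=6),
        PruningStep(2, ["Feaelloidea"], removed_count=2),
        PruningStep(3, ["Neobisioidea"], removed_count=10),
        PruningStep(4, ["Garypoidea"], removed_count=5),
        PruningStep(5, ["Garypinoidea"], removed_count=3),
        PruningStep(6, ["Cheridoidea", "Sternophoroidea"], removed_count=2),
    ]


def chelicerate_families() -> list[OccupancyFamily]:
    return occupancy_families(OCCUPANCY_THRESHOLDS)


def chelicerate_plan_spec() -> list[dict]:
    """The full analysis plan: partitioned ML and summary-coalescent
    runs on the 6x7 grid, site-heterogeneous reruns of the densest and
    largest families, and rate-tertile runs of the two
    intermediate-occupancy families."""
    families = [f.label for f in chelicerate_families()]
    subsets = [f"T-{i}" if i else "T0" for i in range(7)]
    tertiles = ["slow", "intermediate", "fast"]
    return [
        {"method": "partitioned_ml", "families": families, "subsets": subsets,
         "note": "concatenated ML, partitioned models"},
        {"method": "astral", "families": families, "subsets": subsets,
         "note": "summary-coalescent species trees from per-locus gene trees"},
        {"method": "pmsf_c20", "families": ["G1", "G6"], "subsets": subsets,
         "note": "site-heterogeneous mixture rerun of densest and largest families"},
        {"method": "pmsf_c60", "families": ["G1"], "subsets": subsets,
         "note": "richer mixture rerun of the densest family"},
        {"method": "rate_tertile_ml", "families": ["G2", "G3"], "subsets": subsets,
         "tertiles": tertiles, "note": "ML on rate tertiles (MPSI binning)"},
        {"method": "rate_tertile_astral", "families": ["G2", "G3"], "subsets": subsets,
         "tertiles": tertiles, "note": "summary-coalescent on rate tertiles"},
    ]


# ---- ancestral-state fixture ---------------------------------------

RECONSTRUCTION_TREE_NEWICK = (
    "(Onychophora,(Pycnogonida,(Xiphosura,(Ricinulei,(Solifugae,(Opiliones,"
    "(Acariformes,(Parasitiformes,((Scorpiones,Pseudoscorpiones)Panscorpiones,"
    "(Araneae,(Amblypygi,(Uropygi,Schizomida)Thelyphonida)Pedipalpi)"
    "Tetrapulmonata)Arachnopulmonata))))))));"
)


def reconstruction_fixture() -> tuple[Phylogeny, dict[str, CharacterMatrix]]:
    """Order-level tree plus binary behavior/morphology characters.

    All absences are coded 0 explicitly; the outgroup for root-state
    resolution is Onychophora.
    """
    tree = read_newick(RECONSTRUCTION_TREE_NEWICK)
    tips = tree.leaf_names()

    def character(name: str, present: set[str]) -> CharacterMatrix:
        return CharacterMatrix(
            name=name, states={t: (1 if t in present else 0) for t in tips}
        )

    promenade = character(
        "promenade_a_deux",
        {"Pseudoscorpiones", "Scorpiones", "Amblypygi", "Uropygi", "Schizomida"},
    )
    brood_care = character(
        "maternal_brood_care",
        {"Pseudoscorpiones", "Scorpiones", "Amblypygi", "Uropygi", "Schizomida"},
    )
    book_lungs = character(
        "book_lungs",
        {"Scorpiones", "Araneae", "Amblypygi", "Uropygi", "Schizomida"},
    )
    return tree, {c.name: c for c in (promenade, brood_care, book_lungs)}


# ---- ohnolog fixture ------------------------------------------------

OHNOLOG_SPECIES_TREE_NEWICK = "(mite,(spider,(scorpion,pseudoscorpion)));"

OHNOLOG_GENE_TREE_NEWICK = (
    "(mite_dac,((spider_dac1,(scorpion_dac1,pseudoscorpion_dac1)),"
    "(spider_dac2,(scorpion_dac2,pseudoscorpion_dac2))));"
)


def ohnolog_fixture() -> tuple[Phylogeny, Phylogeny, dict[str, str]]:
    """Schematic twice-retained ohnolog gene tree, its species tree and
    the gene-leaf-to-species map."""
    gene = read_newick(OHNOLOG_GENE_TREE_NEWICK)
    species = read_newick(OHNOLOG_SPECIES_TREE_NEWICK)
    leaf_map = {leaf: leaf.split("_")[0] for leaf in gene.leaf_names()}
    return gene, species, leaf_map
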