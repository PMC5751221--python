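"""Synthetic multi-gene systems with planted selection and coevolution.

Generates what the pipeline needs for end-to-end testing without any
database access: an ultrametric species tree, a set of coding-gene
alignments sharing that tree but differing in conservation level (per-gene
branch-length scalers), a small fraction of codons under episodic positive
selection (each with its own branch subset), and planted inter-gene pairs
of coevolving nucleotide positions, spliced into third codon positions so
the two planted signal types stay separable.  A JSON-serialisable truth
ledger records every planted effect.

Background codons evolve under the codon model with dN/dS drawn from
{omega_purifying, 1} at the configured proportions, mirroring the published
gene-level composition of the melanocortin system (about 2.6% of codons
positively selected, 6.7% neutral, the rest purifying).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm

from .coevolution import CoevProfile, coev_rate_matrix
from .seq_io import GeneAlignment
from .selection import simulate_codon_alignment
from .trees import Tree


class ScenarioError(ValueError):
    pass


def generate_tree(n_taxa: int, birth_rate: float = 1.0, seed: int = 0,
                  height: float = 0.5) -> Tree:
    """Ultrametric pure-birth (Yule) tree scaled to a target root-to-tip
    height (in expected substitutions per site)."""
    if n_taxa < 3:
        raise ScenarioError("need at least 3 taxa")
    rng = np.random.default_rng(seed)
    t = 0.0
    root = {"children": None, "start": 0.0}
    active = [root]
    while len(active) < n_taxa:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        k = rng.integers(0, len(active))
        node = active.pop(k)
        node["split"] = t
        a = {"children": None, "start": t}
        b = {"children": None, "start": t}
        node["children"] = [a, b]
        active.extend([a, b])
    T = t + rng.exponential(1.0 / (birth_rate * n_taxa))
    names = iter(f"t{i}" for i in range(n_taxa))

    def newick(node: dict) -> str:
        if node["children"] is None:
            return f"{next(names)}:{T - node['start']:.10g}"
        inner = ",".join(newick(c) for c in node["children"])
        return f"({inner}):{node['split'] - node['start']:.10g}"

    tree = Tree.from_newick(newick(root) + ";")
    depth = tree.root_to_tip_depths()[0]  # ultrametric by construction
    return tree.scaled(height / depth)


def simulate_coev_pair(tree: Tree, profile: CoevProfile, s: float, d: float,
                       rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Simulate one coevolving site pair (two nucleotide columns) under the
    16-state chain; root uniform over dinucleotides."""
    Q = coev_rate_matrix(profile, s, d)
    P = {int(v): expm(Q * tree.blen[v]) for v in tree.branches}
    states = np.empty(tree.n_nodes, dtype=np.int64)
    states[tree.root] = rng.integers(0, 16)
    for v in tree.preorder():
        p = tree.parent[v]
        if p < 0:
            continue
        states[v] = rng.choice(16, p=P[v][states[p]] / P[v][states[p]].sum())
    leaf_states = states[: tree.n_leaves]
    nucs = np.array(list("ACGT"))
    return nucs[leaf_states // 4], nucs[leaf_states % 4]


@dataclass
class GeneSpec:
    name: str
    n_codons: int
    branch_scale: float = 1.0


@dataclass
class PlantedPair:
    gene_a: str
    codon_a: int
    gene_b: str
    codon_b: int
    s: float
    d: float
    profile: tuple[str, str] = ("AA", "CC")

    @property
    def col_a(self) -> int:
        return 3 * self.codon_a + 2

    @property
    def col_b(self) -> int:
        return 3 * self.codon_b + 2


@dataclass
class SyntheticScenario:
    """Study-condition description for one synthetic system."""

    seed: int
    n_taxa: int = 30
    tree_height: float = 0.5
    genes: list[GeneSpec] = field(default_factory=list)
    frac_positive: float = 0.026
    frac_neutral: float = 0.067
    omega_purifying: float = 0.1
    omega_plus: float = 5.0
    episode_branch_fraction: float = 0.3
    kappa: float = 2.0
    planted_pairs: list[PlantedPair] = field(default_factory=list)
    tree_newick: str | None = None

    def validate(self) -> None:
        names = {g.name: g for g in self.genes}
        if len(names) != len(self.genes):
            raise ScenarioError("duplicate gene names")
        for pp in self.planted_pairs:
            if pp.gene_a == pp.gene_b:
                raise ScenarioError("planted pairs must be inter-molecular")
            for gene, codon in ((pp.gene_a, pp.codon_a), (pp.gene_b, pp.codon_b)):
                if gene not in names:
                    raise ScenarioError(f"unknown gene {gene} in planted pair")
                if not 0 <= codon < names[gene].n_codons:
                    raise ScenarioError(
                        f"planted codon {codon} out of range for {gene}")


def generate_system(scenario: SyntheticScenario
                    ) -> tuple[dict[str, GeneAlignment], dict, Tree]:
    """Simulate all gene alignments of a scenario plus the truth ledger."""
    scenario.validate()
    rng = np.random.default_rng(scenario.seed)
    if scenario.tree_newick:
        tree = Tree.from_newick(scenario.tree_newick)
    else:
        tree = generate_tree(scenario.n_taxa, seed=scenario.seed,
                             height=scenario.tree_height)
    branches = tree.branches
    n_episode = max(1, round(scenario.episode_branch_fraction * len(branches)))
    truth: dict = {"seed": scenario.seed, "tree": tree.to_newick(),
                   "genes": {}, "coev_pairs": []}
    alignments: dict[str, GeneAlignment] = {}
    planted_sel: dict[str, set[int]] = {}
    # codons hosting a planted coevolving column evolve neutrally so the
    # planted pair cannot be dropped by conserved-codon trimming or confounded
    # with a planted selection episode
    coev_hosts: dict[str, set[int]] = {g.name: set() for g in scenario.genes}
    for pp in scenario.planted_pairs:
        coev_hosts[pp.gene_a].add(pp.codon_a)
        coev_hosts[pp.gene_b].add(pp.codon_b)
    for gi, gene in enumerate(scenario.genes):
        gtree = tree.scaled(gene.branch_scale)
        n = gene.n_codons
        u = rng.random(n)
        category = np.where(u < scenario.frac_positive, "positive",
                            np.where(u < scenario.frac_positive + scenario.frac_neutral,
                                     "neutral", "purifying"))
        for c in coev_hosts[gene.name]:
            category[c] = "neutral"
        omega_bg = {"purifying": scenario.omega_purifying, "neutral": 1.0,
                    "positive": scenario.omega_purifying}
        site_omegas = np.empty((n, tree.n_nodes))
        gene_truth = {"n_codons": n, "branch_scale": gene.branch_scale,
                      "categories": category.tolist(), "selected_codons": {}}
        for c in range(n):
            site_omegas[c] = omega_bg[category[c]]
            if category[c] == "positive":
                sub = rng.choice(branches, size=n_episode, replace=False)
                site_omegas[c, sub] = scenario.omega_plus
                gene_truth["selected_codons"][str(c)] = {
                    "omega_plus": scenario.omega_plus,
                    "branches": sorted(int(b) for b in sub)}
        cols = simulate_codon_alignment(gtree, site_omegas, scenario.kappa,
                                        seed=int(rng.integers(2**31)))
        matrix = np.array([list("".join(col[i] for col in cols))
                           for i in range(tree.n_leaves)], dtype="<U1")
        alignments[gene.name] = GeneAlignment(
            gene_name=gene.name, species=list(tree.leaf_names),
            sequences=matrix)
        planted_sel[gene.name] = {int(c) for c in range(n)
                                  if category[c] == "positive"}
        truth["genes"][gene.name] = gene_truth
    for pp in scenario.planted_pairs:
        profile = CoevProfile(*sorted(pp.profile))
        col_a, col_b = simulate_coev_pair(tree, profile, pp.s, pp.d, rng)
        alignments[pp.gene_a].sequences[:, pp.col_a] = col_a
        alignments[pp.gene_b].sequences[:, pp.col_b] = col_b
        truth["coev_pairs"].append({
            "gene_a": pp.gene_a, "col_a": pp.col_a, "codon_a": pp.codon_a,
            "gene_b": pp.gene_b, "col_b": pp.col_b, "codon_b": pp.codon_b,
            "profile": [profile.state1, profile.state2],
            "s": pp.s, "d": pp.d,
            "overlaps_selected": bool(pp.codon_a in planted_sel[pp.gene_a]
                                      or pp.codon_b in planted_sel[pp.gene_b]),
        })
    return alignments, truth, tree


def save_truth(truth: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)


def load_truth(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


# gene lengths (nt, trimmed) of the ten melanocortin-system genes
MELANOCORTIN_LENGTHS = {
    "ASIP": 396, "AGRP": 396, "POMC": 801, "PCSK1": 2256, "PCSK2": 1914,
    "MC1R": 951, "MC2R": 891, "MC3R": 969, "MC4R": 996, "MC5R": 972,
}


def melanocortin_fixture(n_taxa: int = 30, seed: int = 2618,
                         n_planted_pairs: int = 12,
                         coev_s: float = 10.0, coev_d: float = 1.0,
                         ) -> SyntheticScenario:
    """Deterministic 10-gene scenario shaped like the melanocortin system.

    Gene names and (trimmed) lengths follow the study system; conservation
    differences are emulated with per-gene branch scalers (ligand/convertase
    genes slowest, antagonists fastest).  Desk scale defaults to 30 taxa; use
    ``n_taxa=138`` for a study-sized system.
    """
    scales = {"POMC": 0.6, "PCSK1": 0.7, "PCSK2": 0.7, "MC1R": 1.2,
              "MC2R": 1.0, "MC3R": 1.0, "MC4R": 0.9, "MC5R": 1.0,
              "ASIP": 1.4, "AGRP": 1.3}
    genes = [GeneSpec(name, length // 3, scales[name])
             for name, length in MELANOCORTIN_LENGTHS.items()]
    rng = np.random.default_rng(seed)
    names = list(MELANOCORTIN_LENGTHS)
    planted = []
    used: dict[str, set[int]] = {n: set() for n in names}
    while len(planted) < n_planted_pairs:
        ga, gb = rng.choice(names, size=2, replace=False)
        ca = int(rng.integers(0, MELANOCORTIN_LENGTHS[ga] // 3))
        cb = int(rng.integers(0, MELANOCORTIN_LENGTHS[gb] // 3))
        if ca in used[ga] or cb in used[gb]:
            continue
        used[ga].add(ca)
        used[gb].add(cb)
        planted.append(PlantedPair(ga, ca, gb, cb, s=coev_s, d=coev_d,
                                   profile=("AT", "GC")))
    return SyntheticScenario(seed=seed, n_taxa=n_taxa, genes=genes,
                             planted_pairs=planted)
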