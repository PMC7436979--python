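"""Seeded synthetic inputs with planted structure for every pipeline stage.

The generator emulates the statistical shape the screening procedure
assumes: a heavy-tailed (preferential-attachment) interaction graph,
compound and disease target sets sharing a planted hub core, a gene-set
collection containing one planted over-represented set, and a docking
table in which designated compound-target pairs score above the ligand
baseline. Every artifact is a pure function of (config, seed); the truth
record makes the planted structure recoverable in tests.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .model import (
    CompoundTargetMap,
    DiseaseTargetSet,
    DockingTable,
    GeneSet,
    GeneSetCollection,
    PPIEdge,
)
from . import io as npio

__all__ = [
    "SyntheticConfig",
    "SyntheticDataset",
    "generate_ppi",
    "generate_targets",
    "generate_genesets",
    "generate_docking",
    "generate_dataset",
    "write_dataset",
    "PLANTED_SET_NAME",
]

PLANTED_SET_NAME = "PLANTED_PATHWAY"


@dataclass(frozen=True)
class SyntheticConfig:
    n_genes: int = 500
    attach_m: int = 2
    n_compounds: int = 16
    targets_per_compound: int = 20
    n_disease_targets: int = 60
    n_planted_hubs: int = 6
    hub_inclusion_prob: float = 0.9
    n_genesets: int = 20
    geneset_size_range: Tuple[int, int] = (10, 40)
    planted_set_overlap: float = 1.0
    n_dock_targets: int = 13
    strong_pair_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_genes": self.n_genes,
            "attach_m": self.attach_m,
            "n_compounds": self.n_compounds,
            "targets_per_compound": self.targets_per_compound,
            "n_disease_targets": self.n_disease_targets,
            "n_planted_hubs": self.n_planted_hubs,
            "n_genesets": self.n_genesets,
            "n_dock_targets": self.n_dock_targets,
        }
        for name, value in counts.items():
            if value <= 0:
                raise ValueError(f"{name} must be positive, got {value}")
        for name in ("hub_inclusion_prob", "planted_set_overlap", "strong_pair_fraction"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.n_planted_hubs >= self.n_genes:
            raise ValueError("n_planted_hubs must be smaller than n_genes")
        lo, hi = self.geneset_size_range
        if not (0 < lo <= hi):
            raise ValueError(f"bad geneset_size_range {self.geneset_size_range}")


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    ppi_edges: List[PPIEdge]
    compound_targets: CompoundTargetMap
    disease_targets: DiseaseTargetSet
    genesets: GeneSetCollection
    disease_pathways: List[str]
    docking: DockingTable
    truth: Dict = field(default_factory=dict)


def _gene_name(i: int) -> str:
    return f"G{i:04d}"


def generate_ppi(n: int, m: int, seed: int) -> List[PPIEdge]:
    """Preferential-attachment interaction graph with m(n-m) edges.

    The seed graph is a star on m+1 nodes; each subsequent node attaches
    to m distinct existing nodes with probability proportional to their
    current degree. Edge confidence scores are Uniform(0.41, 1.0), so all
    edges pass a strict 0.4 filter.
    """
    if n <= m or m < 1:
        raise ValueError(f"need n > m >= 1, got n={n}, m={m}")
    rng = np.random.default_rng(seed)
    degree = np.zeros(n, dtype=float)
    pairs: List[Tuple[int, int]] = []
    # star seed: node 0 is the center
    for leaf in range(1, m + 1):
        pairs.append((0, leaf))
    degree[0] = m
    degree[1 : m + 1] = 1.0

    for new in range(m + 1, n):
        chosen: List[int] = []
        weights = degree[:new].copy()
        for _ in range(m):
            p = weights / weights.sum()
            pick = int(rng.choice(new, p=p))
            chosen.append(pick)
            weights[pick] = 0.0  # enforce distinct attachment points
        for pick in chosen:
            pairs.append((pick, new))
            degree[pick] += 1
        degree[new] = m

    scores = rng.uniform(0.41, 1.0, size=len(pairs))
    return [
        PPIEdge(_gene_name(a), _gene_name(b), float(s))
        for (a, b), s in zip(pairs, scores)
    ]


def _ppi_degrees(ppi_edges: Sequence[PPIEdge]) -> Dict[str, int]:
    degree: Dict[str, int] = {}
    for e in ppi_edges:
        degree[e.a] = degree.get(e.a, 0) + 1
        degree[e.b] = degree.get(e.b, 0) + 1
    return degree


def planted_hubs(ppi_edges: Sequence[PPIEdge], n_hubs: int) -> List[str]:
    """The n_hubs highest-degree genes, ties broken by gene id."""
    degree = _ppi_degrees(ppi_edges)
    ranked = sorted(degree, key=lambda g: (-degree[g], g))
    return ranked[:n_hubs]


def generate_targets(
    ppi_edges: Sequence[PPIEdge], config: SyntheticConfig, seed: int
) -> Tuple[CompoundTargetMap, DiseaseTargetSet, Dict]:
    """Compound and disease target sets sharing a planted hub core.

    Each set includes every planted hub independently with
    ``hub_inclusion_prob`` and is filled to its nominal size with uniform
    random non-hub genes. truth['common'] lists the hubs present in both
    the compound-target union and the disease set.
    """
    if config.targets_per_compound > config.n_genes:
        raise ValueError("targets_per_compound exceeds the gene pool")
    if config.n_disease_targets > config.n_genes:
        raise ValueError("n_disease_targets exceeds the gene pool")
    rng = np.random.default_rng(seed)
    genes = [_gene_name(i) for i in range(config.n_genes)]
    hubs = planted_hubs(ppi_edges, config.n_planted_hubs)
    non_hubs = np.array([g for g in genes if g not in set(hubs)])

    def _target_set(size: int) -> Set[str]:
        chosen = {
            h for h in hubs if rng.random() < config.hub_inclusion_prob
        }
        n_fill = max(size - len(chosen), 0)
        fill = rng.choice(non_hubs, size=n_fill, replace=False)
        return chosen | set(fill.tolist())

    ct = CompoundTargetMap()
    for c in range(config.n_compounds):
        compound = f"CMP{c + 1:02d}"
        for gene in sorted(_target_set(config.targets_per_compound)):
            ct.add(compound, gene, source="synthetic")
    dt = DiseaseTargetSet()
    for gene in sorted(_target_set(config.n_disease_targets)):
        dt.add(gene, source="synthetic")

    truth = {
        "planted_hubs": hubs,
        "common": sorted(set(hubs) & ct.all_targets() & dt.genes),
    }
    return ct, dt, truth


def generate_genesets(
    genes: Sequence[str],
    planted_members: Sequence[str],
    config: SyntheticConfig,
    seed: int,
) -> Tuple[GeneSetCollection, List[str]]:
    """Collection with one planted over-represented set, plus the
    disease-pathway list naming it.

    The planted set holds ``planted_set_overlap`` of the planted members
    topped up with uniform fillers; the remaining sets are uniform random
    within the configured size range.
    """
    rng = np.random.default_rng(seed)
    genes = sorted(genes)
    lo, hi = config.geneset_size_range
    if hi > len(genes):
        raise ValueError("gene-set size range exceeds the gene pool")
    n_core = int(round(config.planted_set_overlap * len(planted_members)))
    core = list(planted_members[:n_core])
    if len(core) > hi:
        raise ValueError("planted core larger than the maximum set size")

    sets: Dict[str, GeneSet] = {}
    planted_size = int(rng.integers(max(lo, len(core)), hi + 1))
    pool = [g for g in genes if g not in set(core)]
    fillers = rng.choice(pool, size=planted_size - len(core), replace=False)
    sets[PLANTED_SET_NAME] = GeneSet(
        name=PLANTED_SET_NAME,
        description="planted over-represented set",
        members=frozenset(core) | frozenset(fillers.tolist()),
    )
    for i in range(config.n_genesets - 1):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(genes, size=size, replace=False)
        name = f"RANDOM_SET_{i + 1:03d}"
        sets[name] = GeneSet(
            name=name, description="random filler set",
            members=frozenset(members.tolist()),
        )
    # a couple of decoy disease pathways that exist in the collection
    decoys = [name for name in sets if name != PLANTED_SET_NAME][:2]
    disease_pathways = [PLANTED_SET_NAME, *decoys]
    return GeneSetCollection(sets), disease_pathways


def generate_docking(
    compounds: Sequence[str],
    targets: Sequence[str],
    config: SyntheticConfig,
    seed: int,
) -> Tuple[DockingTable, Dict]:
    """Docking table with a per-target ligand baseline and planted strong pairs.

    Ligand baselines are Uniform(80, 140); strong pairs score baseline x
    Uniform(1.0, 1.2) and all other present cells baseline x
    Uniform(0.5, 0.9). 5% of the non-strong compound cells are MISSING
    (strong pairs stay present so the planted truth remains recoverable).
    """
    rng = np.random.default_rng(seed)
    compounds = list(compounds)
    targets = list(targets)
    cells = [(c, t) for c in compounds for t in targets]
    n_strong = int(round(config.strong_pair_fraction * len(cells)))
    strong_idx = rng.choice(len(cells), size=n_strong, replace=False)
    strong = {cells[i] for i in strong_idx}

    records: Dict[Tuple[str, str], Optional[float]] = {}
    ligands: Dict[str, str] = {}
    for t in targets:
        ligand = f"LIG_{t}"
        baseline = float(rng.uniform(80.0, 140.0))
        ligands[t] = ligand
        records[(ligand, t)] = baseline
        for c in compounds:
            if (c, t) in strong:
                records[(c, t)] = baseline * float(rng.uniform(1.0, 1.2))
            elif rng.random() < 0.05:
                records[(c, t)] = None
            else:
                records[(c, t)] = baseline * float(rng.uniform(0.5, 0.9))
    truth = {"strong_pairs": sorted(strong)}
    return DockingTable(records, ligands), truth


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Generate every pipeline input from one config + seed.

    Per-artifact random streams are spawned deterministically from the
    config seed, so regenerating any artifact alone is reproducible.
    """
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0]) for s in ss.spawn(5)]

    ppi = generate_ppi(config.n_genes, config.attach_m, seeds[0])
    ct, dt, target_truth = generate_targets(ppi, config, seeds[1])
    genes = [_gene_name(i) for i in range(config.n_genes)]
    genesets, disease_pathways = generate_genesets(
        genes, target_truth["planted_hubs"], config, seeds[2]
    )
    dock_targets = list(target_truth["planted_hubs"])
    extra_pool = [g for g in genes if g not in set(dock_targets)]
    rng = np.random.default_rng(seeds[3])
    n_extra = max(config.n_dock_targets - len(dock_targets), 0)
    dock_targets += rng.choice(extra_pool, size=n_extra, replace=False).tolist()
    dock_targets = dock_targets[: config.n_dock_targets]
    docking, dock_truth = generate_docking(
        sorted(ct.compounds()), dock_targets, config, seeds[4]
    )

    truth = {
        **target_truth,
        **dock_truth,
        "planted_set_name": PLANTED_SET_NAME,
        "dock_targets": dock_targets,
    }
    dataset = SyntheticDataset(
        config=config,
        ppi_edges=ppi,
        compound_targets=ct,
        disease_targets=dt,
        genesets=genesets,
        disease_pathways=disease_pathways,
        docking=docking,
        truth=truth,
    )
    _check_truth(dataset)
    return dataset


def _check_truth(ds: SyntheticDataset) -> None:
    """Generation-time consistency checks of the truth record."""
    hubs = set(ds.truth["planted_hubs"])
    assert set(ds.truth["common"]) == hubs & ds.compound_targets.all_targets() & ds.disease_targets.genes
    planted = ds.genesets[PLANTED_SET_NAME].members
    n_core = int(round(ds.config.planted_set_overlap * len(hubs)))
    assert len(planted & hubs) >= min(n_core, len(hubs))
    for (c, t) in ds.truth["strong_pairs"]:
        score = ds.docking.score(c, t)
        assert score is not None and score >= ds.docking.ligand_score(t)


def write_dataset(ds: SyntheticDataset, outdir) -> Dict[str, str]:
    """Write the dataset in the exact dialects the readers consume.

    Returns a name -> path mapping of the files written.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "ppi": outdir / "ppi_edges.tsv",
        "compound_targets": outdir / "compound_targets.tsv",
        "disease_targets": outdir / "disease_targets.tsv",
        "genesets": outdir / "genesets.gmt",
        "disease_pathways": outdir / "disease_pathways.txt",
        "docking": outdir / "docking.csv",
        "truth": outdir / "truth.json",
    }
    with paths["ppi"].open("w") as fh:
        fh.write("node1\tnode2\tcombined_score\n")
        for e in ds.ppi_edges:
            fh.write(f"{e.a}\t{e.b}\t{e.score:.6f}\n")
    with paths["compound_targets"].open("w") as fh:
        fh.write("compound\tgene\tsource\n")
        for compound in sorted(ds.compound_targets.entries):
            for gene in sorted(ds.compound_targets.entries[compound]):
                fh.write(f"{compound}\t{gene}\tsynthetic\n")
    with paths["disease_targets"].open("w") as fh:
        fh.write("gene\tsource\n")
        for gene in sorted(ds.disease_targets.genes):
            fh.write(f"{gene}\tsynthetic\n")
    npio.write_gmt(ds.genesets, paths["genesets"])
    npio.write_gene_list(ds.disease_pathways, paths["disease_pathways"])
    npio.write_docking_table(ds.docking, paths["docking"])
    payload = {"config": asdict(ds.config), "truth": ds.truth}
    paths["truth"].write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return {k: str(v) for k, v in paths.items()}
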