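"""Seeded synthetic CF-MS datasets with planted complex structure.

The generator emulates the statistical skeleton the pipeline assumes:
members of a complex co-elute (a Gaussian elution peak with a shared apex,
jittered per member), background proteins elute independently, intensities
carry additive noise and random missingness, complex members share a
sequence motif, each complex maps to one GO leaf term and one subcellular
compartment.  Everything derives from a single integer seed, so equal
configurations produce byte-identical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .elution import ElutionMatrix
from .metrics import GoDag

__all__ = [
    "SimConfig",
    "SyntheticDataset",
    "simulate_dataset",
    "make_toy_godag",
    "write_dataset",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
COMPARTMENTS = (
    "nucleus",
    "cytosol",
    "mitochondrion",
    "endoplasmic_reticulum",
    "golgi",
    "plasma_membrane",
    "peroxisome",
    "vacuole",
)


@dataclass
class SimConfig:
    """Study conditions for one synthetic dataset.

    Defaults mirror a small CF-MS experiment: 200 proteins over 40
    fractions, 20 planted complexes of 3-8 members, narrow elution peaks
    (sd 1.5 fractions) with sub-fraction apex jitter, 5% relative noise and
    5% missing cells, sequences of 80-300 residues with an 8-mer complex
    motif carried by 80% of members.
    """

    n_proteins: int = 200
    n_fractions: int = 40
    n_complexes: int = 20
    complex_size_range: tuple[int, int] = (3, 8)
    peak_sd: float = 1.5
    apex_jitter: float = 0.5
    noise_sd: float = 0.05
    missing_rate: float = 0.05
    seq_len_range: tuple[int, int] = (80, 300)
    motif_share: float = 0.8
    motif_len: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_proteins", "n_fractions", "n_complexes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("missing_rate", "motif_share"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability in [0, 1]")
        for name in ("complex_size_range", "seq_len_range"):
            lo, hi = getattr(self, name)
            if lo <= 0 or lo > hi:
                raise ValueError(f"{name} must satisfy 0 < min <= max")
        if self.peak_sd <= 0 or self.noise_sd < 0 or self.apex_jitter < 0:
            raise ValueError("peak_sd must be > 0; jitter and noise >= 0")


@dataclass
class SyntheticDataset:
    """One simulated study: elution, sequences, truth and annotations."""

    elution: ElutionMatrix
    sequences: dict[str, str]
    catalog: "ComplexCatalog"
    godag: GoDag
    localizations: dict[str, str]
    config: SimConfig
    complex_terms: dict[str, str] = field(default_factory=dict)

    @property
    def protein_ids(self) -> list[str]:
        return self.elution.protein_ids

    def truth_pairs(self):
        """Ground-truth pair labels from the planted catalog.

        Applies the same labeling rules as the gold-standard module to the
        preprocessed (imputed, normalized) elution matrix, so generator and
        labeler stay consistent by construction.
        """
        from .elution import preprocess
        from .labels import derive_pair_labels

        E = self.elution if self.elution.normalized else preprocess(self.elution)
        return derive_pair_labels(self.catalog, E)


def make_toy_godag(
    n_levels: int, branching: int, seed: int = 0, part_of_rate: float = 0.3
) -> GoDag:
    """Small rooted typed DAG for exercising the semantic-similarity code.

    A complete ``branching``-ary tree of depth ``n_levels - 1`` whose edges
    are is_a or (with probability ``part_of_rate``) part_of, plus sparse
    seeded cross-links between levels so the graph is a genuine DAG rather
    than a tree.  Terms are named T<level>_<index>; the root is T0_0.
    """
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    rng = np.random.default_rng(seed)
    graph = nx.DiGraph()
    levels = [["T0_0"]]
    graph.add_node("T0_0")
    for level in range(1, n_levels):
        nodes = []
        for i, parent in enumerate(levels[-1]):
            for b in range(branching):
                node = f"T{level}_{i * branching + b}"
                etype = "part_of" if rng.random() < part_of_rate else "is_a"
                graph.add_edge(node, parent, type=etype)
                nodes.append(node)
        levels.append(nodes)
    # sparse extra child->grandparent links (DAG, not tree)
    for level in range(2, n_levels):
        for node in levels[level]:
            if rng.random() < 0.1:
                gp = levels[level - 2][rng.integers(len(levels[level - 2]))]
                if not nx.has_path(graph, gp, node):
                    graph.add_edge(node, gp, type="is_a")
    dag = GoDag(graph)
    dag.levels = levels  # leaf terms = levels[-1]
    return dag


def _elution_profile(
    rng: np.random.Generator, n_fractions: int, apex: float, peak_sd: float
) -> np.ndarray:
    amplitude = rng.uniform(0.5, 2.0)
    fractions = np.arange(n_fractions, dtype=float)
    return amplitude * np.exp(-((fractions - apex) ** 2) / (2.0 * peak_sd**2))


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def simulate_dataset(cfg: SimConfig) -> "SyntheticDataset":
    """Generate one seeded synthetic dataset under the given conditions."""
    from .labels import ComplexCatalog  # local import avoids cycle at module load

    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.complex_size_range
    sizes = rng.integers(lo, hi + 1, size=cfg.n_complexes)
    if sizes.sum() > cfg.n_proteins:
        raise ValueError(
            f"complex sizes total {int(sizes.sum())} but only "
            f"{cfg.n_proteins} proteins are available"
        )
    protein_ids = [f"P{i + 1:04d}" for i in range(cfg.n_proteins)]
    order = rng.permutation(cfg.n_proteins)
    complexes: dict[str, frozenset[str]] = {}
    cursor = 0
    member_of: dict[str, str] = {}
    for c, size in enumerate(sizes):
        cid = f"CPX{c + 1:03d}"
        members = [protein_ids[i] for i in order[cursor: cursor + size]]
        cursor += int(size)
        complexes[cid] = frozenset(members)
        for p in members:
            member_of[p] = cid

    # ---- elution: shared apex per complex, independent for background
    apexes = {}
    margin = 3.0 * cfg.peak_sd
    lo_apex, hi_apex = margin, max(margin + 1.0, cfg.n_fractions - 1 - margin)
    for cid in complexes:
        apexes[cid] = rng.uniform(lo_apex, hi_apex)
    values = np.empty((cfg.n_proteins, cfg.n_fractions))
    for i, pid in enumerate(protein_ids):
        if pid in member_of:
            apex = apexes[member_of[pid]] + rng.normal(0.0, cfg.apex_jitter)
        else:
            apex = rng.uniform(lo_apex, hi_apex)
        values[i] = _elution_profile(rng, cfg.n_fractions, apex, cfg.peak_sd)
    if cfg.noise_sd > 0:
        values = values + rng.normal(0.0, cfg.noise_sd, size=values.shape)
        values = np.clip(values, 0.0, None)
    if cfg.missing_rate > 0:
        mask = rng.random(values.shape) < cfg.missing_rate
        values[mask] = np.nan
    elution = ElutionMatrix(protein_ids, values, original_fractions=cfg.n_fractions)

    # ---- sequences: uniform residues; one fixed 8-mer motif per complex
    motifs = {
        cid: _random_sequence(rng, cfg.motif_len) for cid in complexes
    }
    sequences = {}
    for pid in protein_ids:
        length = int(rng.integers(cfg.seq_len_range[0], cfg.seq_len_range[1] + 1))
        seq = _random_sequence(rng, length)
        cid = member_of.get(pid)
        if cid is not None and rng.random() < cfg.motif_share:
            pos = int(rng.integers(0, length - cfg.motif_len + 1))
            seq = seq[:pos] + motifs[cid] + seq[pos + cfg.motif_len:]
        sequences[pid] = seq

    # ---- GO: one leaf term per complex, plus random noise terms
    n_leaves_needed = cfg.n_complexes + 5
    branching = 3
    n_levels = 2
    while branching ** (n_levels - 1) < n_leaves_needed:
        n_levels += 1
    godag = make_toy_godag(n_levels, branching, seed=cfg.seed + 1)
    leaves = godag.levels[-1]
    leaf_order = rng.permutation(len(leaves))
    complex_terms = {
        cid: leaves[leaf_order[i]] for i, cid in enumerate(complexes)
    }
    noise_leaves = [leaves[i] for i in leaf_order[cfg.n_complexes:]]
    annotations: dict[str, dict[str, set[str]]] = {}
    for pid in protein_ids:
        terms: set[str] = set()
        cid = member_of.get(pid)
        if cid is not None:
            terms.add(complex_terms[cid])
        if not terms or rng.random() < 0.3:
            terms.add(noise_leaves[rng.integers(len(noise_leaves))])
        annotations[pid] = {"BP": terms}
    godag.annotations = annotations

    # ---- localizations: one compartment per complex
    comp_of_complex = {
        cid: COMPARTMENTS[rng.integers(len(COMPARTMENTS))] for cid in complexes
    }
    localizations = {}
    for pid in protein_ids:
        cid = member_of.get(pid)
        if cid is not None:
            localizations[pid] = comp_of_complex[cid]
        else:
            localizations[pid] = COMPARTMENTS[rng.integers(len(COMPARTMENTS))]

    return SyntheticDataset(
        elution=elution,
        sequences=sequences,
        catalog=ComplexCatalog(complexes),
        godag=godag,
        localizations=localizations,
        config=cfg,
        complex_terms=complex_terms,
    )


# ---------------------------------------------------------------------------
# writers

def _write_obo(dag: GoDag, path) -> None:
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\nontology: toy\n\n")
        for term in sorted(dag.graph.nodes):
            fh.write(f"[Term]\nid: {term}\nname: {term}\n")
            for _, parent, data in sorted(dag.graph.out_edges(term, data=True)):
                if data["type"] == "is_a":
                    fh.write(f"is_a: {parent} ! {parent}\n")
                else:
                    fh.write(f"relationship: part_of {parent} ! {parent}\n")
            fh.write("\n")


def write_dataset(ds: SyntheticDataset, outdir) -> dict[str, str]:
    """Write the dataset in its on-disk exchange formats.

    elution TSV, sequences FASTA, complexes GMT-like TSV, GO OBO subset,
    annotations 3-column TSV, localizations 2-column TSV.  Returns the
    mapping of artifact name to path.
    """
    from pathlib import Path

    from .elution import write_elution
    from .labels import write_complexes

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {name: outdir / fname for name, fname in [
        ("elution", "elution.tsv"),
        ("sequences", "sequences.fasta"),
        ("complexes", "complexes.gmt"),
        ("obo", "ontology.obo"),
        ("annotations", "annotations.tsv"),
        ("localizations", "localizations.tsv"),
    ]}
    write_elution(ds.elution, paths["elution"])
    with open(paths["sequences"], "w") as fh:
        for pid, seq in ds.sequences.items():
            fh.write(f">{pid}\n{seq}\n")
    write_complexes(ds.catalog, paths["complexes"])
    _write_obo(ds.godag, paths["obo"])
    with open(paths["annotations"], "w") as fh:
        for gene in sorted(ds.godag.annotations):
            for ns, terms in ds.godag.annotations[gene].items():
                for term in sorted(terms):
                    fh.write(f"{gene}\t{term}\t{ns}\n")
    with open(paths["localizations"], "w") as fh:
        for pid in ds.protein_ids:
            fh.write(f"{pid}\t{ds.localizations[pid]}\n")
    return {k: str(v) for k, v in paths.items()}
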