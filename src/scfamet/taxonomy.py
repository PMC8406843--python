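"""Taxonomic assignment of genes: significant-hit retention + LCA.

For each gene, alignment hits within 10x the best (smallest) e-value are
retained and the gene is placed at the lowest common ancestor of the retained
taxa.  Species-level assignments are then joined with enzyme annotations to
produce species x enzyme "harboring" tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "Taxonomy",
    "read_taxonomy",
    "retain_significant",
    "lca",
    "assign_gene_taxa",
    "harboring_species",
    "HarboringResult",
]


class Taxonomy:
    """Rooted taxonomy from a (taxon_id, parent_id, rank, name) table.

    The root is the single node whose parent is itself or null.  Cycles and
    dangling parent references are rejected at construction.
    """

    def __init__(self, table: pd.DataFrame):
        for col in ("taxon_id", "parent_id", "rank", "name"):
            if col not in table.columns:
                raise ValueError(f"taxonomy missing column {col!r}")
        self.table = table.reset_index(drop=True)
        self.parent: dict = {}
        self.rank: dict = {}
        self.name: dict = {}
        roots = []
        for row in self.table.itertuples(index=False):
            tid, pid = row.taxon_id, row.parent_id
            if pd.isna(pid) or pid == tid:
                roots.append(tid)
                pid = None
            self.parent[tid] = pid
            self.rank[tid] = row.rank
            self.name[tid] = row.name
        if len(roots) != 1:
            raise ValueError(f"taxonomy must have exactly one root, found {len(roots)}")
        self.root = roots[0]
        missing = {p for p in self.parent.values() if p is not None} - set(self.parent)
        if missing:
            raise ValueError(f"parent taxa absent from table: {sorted(missing)}")
        self.depth = self._compute_depths()

    def _compute_depths(self) -> dict:
        depth: dict = {self.root: 0}
        for tid in self.parent:
            chain = []
            node = tid
            while node not in depth:
                chain.append(node)
                node = self.parent[node]
                if node in chain or len(chain) > len(self.parent):
                    raise ValueError(f"cycle in taxonomy at {tid}")
            d = depth[node]
            for n in reversed(chain):
                d += 1
                depth[n] = d
        return depth

    def __contains__(self, taxon_id) -> bool:
        return taxon_id in self.parent

    def leaves(self) -> list:
        parents = {p for p in self.parent.values() if p is not None}
        return [t for t in self.parent if t not in parents]


def read_taxonomy(path) -> Taxonomy:
    return Taxonomy(pd.read_csv(path, sep="\t"))


def retain_significant(hits_for_gene: pd.DataFrame, factor: float = 10.0) -> pd.DataFrame:
    """Keep hits with e-value <= factor * min(e-value); idempotent."""
    if hits_for_gene.empty:
        raise ValueError("gene has no hits")
    e = hits_for_gene["e_value"].to_numpy(float)
    if (e <= 0).any():
        raise ValueError("e-values must be positive")
    return hits_for_gene[e <= factor * e.min()]


def lca(taxa, taxonomy: Taxonomy):
    """Lowest common ancestor of a set of taxa.

    Implemented as pairwise depth-aligned walks to the root, folded over the
    input set.
    """
    taxa = list(taxa)
    if not taxa:
        raise ValueError("taxa must be non-empty")
    for t in taxa:
        if t not in taxonomy:
            raise ValueError(f"unknown taxon: {t}")
    node = taxa[0]
    for other in taxa[1:]:
        node = _lca_pair(node, other, taxonomy)
    return node


def _lca_pair(a, b, taxonomy: Taxonomy):
    da, db = taxonomy.depth[a], taxonomy.depth[b]
    while da > db:
        a = taxonomy.parent[a]
        da -= 1
    while db > da:
        b = taxonomy.parent[b]
        db -= 1
    while a != b:
        a = taxonomy.parent[a]
        b = taxonomy.parent[b]
    return a


def assign_gene_taxa(
    hits: pd.DataFrame, taxonomy: Taxonomy, factor: float = 10.0
) -> dict:
    """Per-gene taxon: LCA over retained significant hits."""
    for col in ("gene_id", "taxon_id", "e_value"):
        if col not in hits.columns:
            raise ValueError(f"hit table missing column {col!r}")
    out = {}
    for gene, sub in hits.groupby("gene_id", sort=True):
        kept = retain_significant(sub, factor=factor)
        out[gene] = lca(set(kept["taxon_id"]), taxonomy)
    return out


@dataclass
class HarboringResult:
    """Species x enzyme abundance matrix plus per-enzyme species counts."""

    matrix: pd.DataFrame          # index: species taxon_id, columns: enzyme
    species_counts: pd.Series     # enzyme -> number of harboring species
    excluded_genes: pd.DataFrame  # genes whose LCA is above species rank


def harboring_species(
    gene2enzyme: dict,
    gene2taxon: dict,
    abundance,
    taxonomy: Taxonomy,
    species_rank: str = "species",
) -> HarboringResult:
    """Join gene->enzyme and gene->taxon maps into a harboring table.

    ``abundance`` is a per-gene abundance Series, or a samples x genes
    DataFrame whose per-gene mean is used.  Genes whose assigned taxon is not
    at ``species_rank`` are excluded from the matrix and reported.
    """
    if isinstance(abundance, pd.DataFrame):
        abundance = abundance.mean(axis=0)
    abundance = pd.Series(abundance)

    cells: dict[tuple, float] = {}
    harborers: dict[str, set] = {}
    excluded = []
    for gene, enzyme in gene2enzyme.items():
        if gene not in gene2taxon:
            continue
        taxon = gene2taxon[gene]
        if taxonomy.rank.get(taxon) != species_rank:
            excluded.append(
                {"gene_id": gene, "enzyme": enzyme, "taxon_id": taxon,
                 "rank": taxonomy.rank.get(taxon)}
            )
            continue
        mass = float(abundance.get(gene, 0.0))
        cells[(taxon, enzyme)] = cells.get((taxon, enzyme), 0.0) + mass
        harborers.setdefault(enzyme, set()).add(taxon)

    if cells:
        ser = pd.Series(cells)
        matrix = ser.unstack(fill_value=0.0)
        matrix.index.name = "taxon_id"
    else:
        matrix = pd.DataFrame()
    counts = pd.Series({e: len(s) for e, s in sorted(harborers.items())}, dtype=int)
    counts.index.name = "enzyme"
    excluded_df = pd.DataFrame(
        excluded, columns=["gene_id", "enzyme", "taxon_id", "rank"]
    )
    return HarboringResult(matrix=matrix, species_counts=counts, excluded_genes=excluded_df)
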