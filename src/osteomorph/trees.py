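"""Species phylogeny handling (Newick, dendropy-backed).

Trees are pruned to the species present in the design table; polytomies
are kept as true multifurcations, which matters downstream when the
phylogenetic covariance is assembled (shared path length at the
polytomy node is used as-is, a conservative treatment of unresolved
relationships).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable

import dendropy
import numpy as np

__all__ = ["read_tree", "phylo_covariance", "simulate_brownian"]

log = logging.getLogger(__name__)


def read_tree(path: str | Path, species: Iterable[str] | None = None) -> dendropy.Tree:
    """Read a Newick tree with branch lengths, optionally pruning it.

    Parameters
    ----------
    path : Newick file.
    species : iterable of tip labels, optional
        If given, the tree is pruned to exactly these tips; tips absent
        from the list are removed (and logged), species absent from the
        tree raise.
    """
    tree = dendropy.Tree.get(path=str(path), schema="newick",
                             preserve_underscores=True)
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise ValueError(f"negative branch length on edge to {edge.head_node}")
    if species is not None:
        wanted = set(species)
        tips = {t.label for t in tree.taxon_namespace}
        missing = wanted - tips
        if missing:
            raise ValueError(f"species missing from tree: {sorted(missing)}")
        extra = tips - wanted
        if extra:
            log.info("pruning %d tip(s) absent from design: %s",
                     len(extra), sorted(extra))
        tree.retain_taxa_with_labels(sorted(wanted))
        tree.purge_taxon_namespace()
    return tree


def phylo_covariance(tree: dendropy.Tree, taxa: list[str] | None = None) -> tuple[np.ndarray, list[str]]:
    """Brownian-motion covariance matrix from shared root-to-MRCA paths.

    ``C[i, j]`` is the path length from the root to the most recent
    common ancestor of tips i and j; diagonals are tip depths.
    Multifurcations contribute their (possibly zero) shared path
    directly.  Unit branch lengths are assumed where lengths are absent.
    """
    tree = tree.clone(depth=1)
    tree.is_rooted = True
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    labels = [t.label for t in tree.taxon_namespace]
    if taxa is None:
        taxa = sorted(labels)
    pdm = {}
    leaf_of = {}
    for leaf in tree.leaf_node_iter():
        leaf_of[leaf.taxon.label] = leaf
    n = len(taxa)
    C = np.zeros((n, n))
    for i, a in enumerate(taxa):
        C[i, i] = leaf_of[a].root_distance
        for j in range(i + 1, n):
            b = taxa[j]
            mrca = dendropy.Tree.mrca(tree, taxa=[leaf_of[a].taxon, leaf_of[b].taxon])
            C[i, j] = C[j, i] = mrca.root_distance if mrca.root_distance else 0.0
    return C, list(taxa)


def simulate_brownian(
    tree: dendropy.Tree,
    rate: float,
    lam: float,
    rng: np.random.Generator,
    n_traits: int = 1,
) -> tuple[np.ndarray, list[str]]:
    """Draw tip values of a Brownian trait with Pagel-λ structure.

    Tips are jointly normal with covariance ``rate * C_λ`` where
    ``C_λ`` is the shared-path matrix with off-diagonals multiplied by
    ``lam``.  λ=1 is plain Brownian motion, λ=0 independent tips with
    depth-proportional variances.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must lie in [0, 1]")
    C, taxa = phylo_covariance(tree)
    Cl = lam * C
    np.fill_diagonal(Cl, np.diag(C))
    L = np.linalg.cholesky(rate * Cl + 1e-12 * np.eye(len(taxa)))
    z = rng.standard_normal((len(taxa), n_traits))
    return L @ z, taxa
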