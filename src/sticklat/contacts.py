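"""Shared lattice contact census used by the analysis modules.

All contact definitions use the 26-site neighborhood (within sqrt(3)
lattice units under minimum image), matching the energy function.
"""

from __future__ import annotations

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .mc import OFFSETS26, N_HALF, LatticeConfiguration


def contact_pairs(config: LatticeConfiguration) -> tuple[np.ndarray, np.ndarray]:
    """All unordered bead pairs on neighboring sites (bonded included).

    Returns two index arrays (i, j); each unordered pair appears once.
    """
    occ = config.occupancy()
    i_list, j_list = [], []
    for k in range(N_HALF):
        o = OFFSETS26[k]
        rolled = np.roll(occ, shift=(-o[0], -o[1], -o[2]), axis=(0, 1, 2))
        mask = (occ > 0) & (rolled > 0)
        if mask.any():
            i_list.append(occ[mask] - 1)
            j_list.append(rolled[mask] - 1)
    if not i_list:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    return np.concatenate(i_list), np.concatenate(j_list)


def nonbonded_pairs(config: LatticeConfiguration) -> tuple[np.ndarray, np.ndarray]:
    """Contact pairs with bonded (consecutive same-chain) pairs removed."""
    i, j = contact_pairs(config)
    bonded = (config.chain_of[i] == config.chain_of[j]) & (np.abs(i - j) == 1)
    return i[~bonded], j[~bonded]


def neighbor_census(config: LatticeConfiguration) -> tuple[np.ndarray, np.ndarray]:
    """Per-bead counts of same-chain and other-chain occupied neighbors.

    Every occupied neighbor site counts (bonded partners included), so
    same + other + empty = 26 for each bead.
    """
    i, j = contact_pairs(config)
    same = np.zeros(config.n_beads, dtype=np.int64)
    other = np.zeros(config.n_beads, dtype=np.int64)
    same_mask = config.chain_of[i] == config.chain_of[j]
    for arr, mask in ((same, same_mask), (other, ~same_mask)):
        np.add.at(arr, i[mask], 1)
        np.add.at(arr, j[mask], 1)
    return same, other


def chain_adjacency_pairs(config: LatticeConfiguration,
                          sticker_only: bool = False) -> np.ndarray:
    """Unordered chain pairs in contact (optionally sticker-sticker only)."""
    i, j = contact_pairs(config)
    inter = config.chain_of[i] != config.chain_of[j]
    i, j = i[inter], j[inter]
    if sticker_only:
        st = config.sticker_mask
        keep = st[i] & st[j]
        i, j = i[keep], j[keep]
    ci, cj = config.chain_of[i], config.chain_of[j]
    if len(ci) == 0:
        return np.empty((0, 2), dtype=np.int64)
    pairs = np.stack([np.minimum(ci, cj), np.maximum(ci, cj)], axis=1)
    return np.unique(pairs, axis=0)


def chain_cluster_labels(config: LatticeConfiguration) -> np.ndarray:
    """Connected-component label per chain under any-bead contact."""
    pairs = chain_adjacency_pairs(config)
    n = config.n_chains
    if len(pairs) == 0:
        return np.arange(n)
    m = coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
    )
    _, labels = connected_components(m, directed=False)
    return labels
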