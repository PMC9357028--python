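"""Neural-dissociation statistics over contributing-edge sets.

Two factor-model components have dissociated neural substrates when the
edges that drive their connectome-based predictions barely overlap.  Overlap
is quantified by the Dice coefficient with a random-subset permutation null;
anatomy is summarized by ranking nodes on contributing-edge degree and by
network-pair enrichment folds around an anchor node.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


def n_edges(n_nodes: int) -> int:
    """Number of canonical i<j edges in an n_nodes graph."""
    return n_nodes * (n_nodes - 1) // 2


def edge_endpoints(n_nodes: int) -> tuple[np.ndarray, np.ndarray]:
    """Node endpoints (i, j), i<j, of every canonical edge in index order."""
    return np.triu_indices(n_nodes, k=1)


def dice_coefficient(mask_x: np.ndarray, mask_y: np.ndarray) -> float:
    """Dice(X, Y) = 2|X ∩ Y| / (|X| + |Y|); 0 when both sets are empty."""
    x = np.asarray(mask_x)
    y = np.asarray(mask_y)
    if x.shape != y.shape:
        raise ValueError("edge masks must share the same universe")
    nx, ny = int(x.sum()), int(y.sum())
    if nx + ny == 0:
        return 0.0
    return 2.0 * int((x & y).sum()) / (nx + ny)


def dice_null_mean(size_x: int, size_y: int, universe: int) -> float:
    """Closed-form E[Dice] for independent uniform subsets.

    E|X ∩ Y| = |X||Y|/N, hence E[Dice] = 2|X||Y| / (N (|X|+|Y|)).
    """
    if universe <= 0:
        raise ValueError("universe must be positive")
    if size_x + size_y == 0:
        return 0.0
    return 2.0 * size_x * size_y / (universe * (size_x + size_y))


@dataclass
class DiceResult:
    observed: float
    null_samples: np.ndarray
    p_value: float


def dice_permutation_test(
    size_x: int,
    size_y: int,
    universe: int,
    observed: float,
    n_perm: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> DiceResult:
    """Permutation p for an observed Dice coefficient.

    Each permutation draws independent uniform random subsets of the two
    observed sizes from the edge universe and recomputes Dice; the one-sided
    p uses the +1 small-sample correction.
    """
    if universe <= 0:
        raise ValueError("universe must be positive")
    if size_x > universe or size_y > universe:
        raise ValueError("subset sizes cannot exceed the universe")
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    # hypergeometric draw of the intersection size is equivalent to drawing
    # both subsets explicitly, and much cheaper
    inter = rng.hypergeometric(size_x, universe - size_x, size_y, size=n_perm)
    null = 2.0 * inter / max(size_x + size_y, 1)
    p = (1.0 + np.sum(null >= observed)) / (1.0 + n_perm)
    return DiceResult(observed=float(observed), null_samples=null, p_value=float(p))


def rank_nodes(mask: np.ndarray, parcellation: pd.DataFrame, top_k: int | None = None) -> pd.DataFrame:
    """Rank nodes by the number of contributing edges incident to them.

    Descending count, ties broken by node id.  `parcellation` must carry one
    row per node with at least a `network` column (plus optional `name`).
    """
    n_nodes = len(parcellation)
    ii, jj = edge_endpoints(n_nodes)
    sel = np.asarray(mask, dtype=bool)
    counts = np.bincount(ii[sel], minlength=n_nodes) + np.bincount(jj[sel], minlength=n_nodes)
    df = parcellation.copy()
    df["node"] = np.arange(n_nodes)
    df["n_contributing"] = counts
    df = df.sort_values(["n_contributing", "node"], ascending=[False, True], kind="stable")
    df = df.reset_index(drop=True)
    if top_k is not None:
        df = df.head(top_k)
    return df


def network_enrichment(mask: np.ndarray, anchor_node: int, parcellation: pd.DataFrame) -> pd.DataFrame:
    """Network-pair enrichment folds for contributing edges at one node.

    For each network l of the anchor's potential partners: A_l = observed
    selected edges from the anchor into l; E_l = (#partner nodes in l) * k /
    (n_nodes - 1) where k is the anchor's selected-edge count, i.e. the count
    expected if the k edges spread uniformly over the 263 possible partners.
    fold = A_l / E_l.  All folds are emitted; display conventions may filter
    to fold >= 1.
    """
    n_nodes = len(parcellation)
    if not 0 <= anchor_node < n_nodes:
        raise ValueError("anchor node outside parcellation")
    ii, jj = edge_endpoints(n_nodes)
    sel = np.asarray(mask, dtype=bool)
    at_anchor = sel & ((ii == anchor_node) | (jj == anchor_node))
    partners = np.where(ii[at_anchor] == anchor_node, jj[at_anchor], ii[at_anchor])
    k = len(partners)
    networks = parcellation["network"].to_numpy()
    anchor_net = networks[anchor_node]
    rows = []
    all_nodes = np.arange(n_nodes)
    for net in pd.unique(networks):
        possible = int(np.sum((networks == net) & (all_nodes != anchor_node)))
        a_l = int(np.sum(networks[partners] == net))
        e_l = possible * k / (n_nodes - 1)
        fold = a_l / e_l if e_l > 0 else np.nan
        rows.append(
            {
                "anchor_node": anchor_node,
                "network_pair": f"{anchor_net}-{net}",
                "partner_network": net,
                "possible_partners": possible,
                "observed": a_l,
                "expected": e_l,
                "fold": fold,
            }
        )
    return pd.DataFrame(rows)
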