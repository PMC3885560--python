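"""Chemical-similarity network of OGTT-responsive metabolites.

Vertices are metabolites carrying the signed LV1 loading of the OGTT
time-course PLS model (size = |loading|, direction = sign); edges join
pairs whose binary-fingerprint Tanimoto similarity is strictly above the
threshold (default 0.7).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import networkx as nx

from ogttmet.io_tables import Fingerprint, direction_of


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """|A intersect B| / |A union B| over set bits; two empty sets -> 0."""
    if a.n_bits != b.n_bits:
        raise ValueError(f"tanimoto: fingerprint lengths differ ({a.n_bits} vs {b.n_bits})")
    inter = int(np.count_nonzero(a.bits & b.bits))
    union = int(np.count_nonzero(a.bits | b.bits))
    if union == 0:
        warnings.warn("tanimoto: both fingerprints empty; similarity defined as 0")
        return 0.0
    return inter / union


def pairwise_tanimoto(fps: list[Fingerprint]) -> np.ndarray:
    """Dense pairwise similarity matrix (vectorized bit counting)."""
    if not fps:
        return np.zeros((0, 0))
    lengths = {fp.n_bits for fp in fps}
    if len(lengths) > 1:
        raise ValueError(f"pairwise_tanimoto: mixed fingerprint lengths {sorted(lengths)}")
    B = np.stack([fp.bits for fp in fps]).astype(np.int64)
    inter = B @ B.T
    ones = B.sum(axis=1)
    union = ones[:, None] + ones[None, :] - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        sim = np.where(union > 0, inter / np.maximum(union, 1), 0.0)
    return sim


def build_network(fps: list[Fingerprint], loadings, threshold: float = 0.7,
                  eps: float = 0.0) -> nx.Graph:
    """Similarity network with LV1-loading vertex attributes.

    ``loadings`` maps metabolite_id -> signed LV1 loading (dict or
    Series); metabolites without a loading get direction "unclear".  An
    edge joins every unordered pair with tanimoto strictly > threshold.
    """
    loadings = dict(loadings) if loadings is not None else {}
    g = nx.Graph()
    for fp in fps:
        loading = float(loadings.get(fp.metabolite_id, float("nan")))
        g.add_node(fp.metabolite_id,
                   loading_lv1=loading,
                   size=abs(loading) if np.isfinite(loading) else 0.0,
                   direction=direction_of(loading, eps=eps))
    sim = pairwise_tanimoto(fps)
    n = len(fps)
    for i in range(n):
        for j in range(i + 1, n):
            if sim[i, j] > threshold:
                g.add_edge(fps[i].metabolite_id, fps[j].metabolite_id,
                           tanimoto=float(sim[i, j]))
    return g


def component_summary(g: nx.Graph) -> pd.DataFrame:
    """One row per connected component: size, edges, dominant direction."""
    rows = []
    for k, comp in enumerate(sorted(nx.connected_components(g), key=len, reverse=True)):
        sub = g.subgraph(comp)
        dirs = pd.Series([d.get("direction", "unclear") for _, d in sub.nodes(data=True)])
        rows.append({"component": k, "n_nodes": sub.number_of_nodes(),
                     "n_edges": sub.number_of_edges(),
                     "dominant_direction": dirs.mode().iloc[0],
                     "members": ";".join(sorted(comp))})
    return pd.DataFrame(rows)
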