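"""Network-level summaries of edge components.

Regions are assigned to one of 8 canonical large-scale networks (7 cortical
systems — visual, somatomotor, dorsal attention, ventral attention, limbic,
frontoparietal control, default mode — plus one subcortical network).
Given a significant edge component, this module computes the proportion of
affected edges within/between each network pair, per-region (optionally
|t|-weighted) abnormal degrees, component intersections, and seed-region
connection profiles.

The package ships a schematic 432-region atlas table
(``data/synthetic_atlas_432.csv``) with the standard schema
(region_id, label, network, x, y, z); substitute any table with the same
schema to use a real parcellation.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "CANONICAL_NETWORKS",
    "load_atlas",
    "load_default_atlas",
    "NetworkPairMatrix",
    "edge_fraction_matrix",
    "node_abnormal_degree",
    "component_intersection",
    "seed_region_profile",
]

CANONICAL_NETWORKS = ("Vis", "SomMot", "DorsAttn", "SalVentAttn", "Limbic",
                      "Cont", "Default", "Subcortical")


def load_atlas(path) -> pd.DataFrame:
    """Read an atlas table (region_id, label, network[, x, y, z])."""
    atlas = pd.read_csv(path)
    for col in ("region_id", "label", "network"):
        if col not in atlas.columns:
            raise ValueError(f"atlas table lacks column {col!r}")
    if atlas["region_id"].duplicated().any():
        raise ValueError("duplicate region_id in atlas table")
    return atlas


def load_default_atlas() -> pd.DataFrame:
    """The packaged schematic 432-region table (400 cortical parcels across
    7 systems + 32 subcortical regions)."""
    with resources.files("dynconn.data").joinpath(
            "synthetic_atlas_432.csv").open() as f:
        return load_atlas(f)


def _network_of(atlas: pd.DataFrame) -> dict[int, str]:
    return dict(zip(atlas["region_id"].astype(int), atlas["network"]))


@dataclass
class NetworkPairMatrix:
    networks: list[str]
    proportion: np.ndarray      # 8 x 8, symmetric, in [0, 1]
    counts: np.ndarray          # significant edges per pair
    denominator: np.ndarray     # total possible edges per pair

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.proportion, index=self.networks,
                            columns=self.networks)


def edge_fraction_matrix(component, atlas: pd.DataFrame,
                         networks=None) -> NetworkPairMatrix:
    """Proportion of component edges among all possible edges within or
    between each network pair."""
    net_of = _network_of(atlas)
    nets = list(networks) if networks is not None else \
        [n for n in CANONICAL_NETWORKS if n in set(atlas["network"])] or \
        sorted(set(atlas["network"]))
    idx = {n: k for k, n in enumerate(nets)}
    sizes = np.array([(atlas["network"] == n).sum() for n in nets], dtype=float)
    K = len(nets)
    denom = np.outer(sizes, sizes)
    np.fill_diagonal(denom, sizes * (sizes - 1) / 2.0)
    counts = np.zeros((K, K))
    for (i, j) in component:
        if i not in net_of or j not in net_of:
            raise ValueError(f"edge ({i},{j}) references a region not in the atlas")
        a, b = idx[net_of[i]], idx[net_of[j]]
        counts[a, b] += 1
        if a != b:
            counts[b, a] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        prop = np.where(denom > 0, counts / denom, 0.0)
    return NetworkPairMatrix(networks=nets, proportion=prop, counts=counts,
                             denominator=denom)


def node_abnormal_degree(component, atlas: pd.DataFrame,
                         weights=None) -> pd.Series:
    """Degree of each atlas region in the component graph.

    ``weights`` (e.g. per-edge |t|, aligned with ``component``) switches to
    the weighted count: the sum of |weight| over incident edges.
    """
    deg = pd.Series(0.0, index=atlas["region_id"].astype(int))
    component = list(component)
    if weights is None:
        weights = np.ones(len(component))
    for (i, j), w in zip(component, np.abs(np.asarray(weights, dtype=float))):
        deg[i] += w
        deg[j] += w
    return deg


def _norm(edge) -> tuple[int, int]:
    i, j = edge
    return (i, j) if i < j else (j, i)


def component_intersection(a, b) -> set[tuple[int, int]]:
    """Edges present in both components (order-insensitive endpoints)."""
    return {_norm(e) for e in a} & {_norm(e) for e in b}


def seed_region_profile(component, atlas: pd.DataFrame,
                        seed_label: str) -> pd.DataFrame:
    """Edges incident to any region whose label contains ``seed_label``
    (case-insensitive substring), grouped by partner region and sorted by
    incident edge count."""
    labels = atlas.set_index(atlas["region_id"].astype(int))["label"]
    seed_ids = set(labels.index[
        labels.str.contains(seed_label, case=False, regex=False)])
    if not seed_ids:
        available = sorted(atlas["label"].unique())
        raise ValueError(
            f"no atlas label contains {seed_label!r}; available labels "
            f"include e.g. {available[:10]}")
    rows: dict[int, int] = {}
    for e in component:
        i, j = _norm(e)
        for seed, partner in ((i, j), (j, i)):
            if seed in seed_ids and partner not in seed_ids:
                rows[partner] = rows.get(partner, 0) + 1
    prof = pd.DataFrame({
        "partner_region": list(rows.keys()),
        "n_edges": list(rows.values()),
    })
    if len(prof):
        prof["partner_label"] = prof["partner_region"].map(labels)
        prof["partner_network"] = prof["partner_region"].map(
            atlas.set_index(atlas["region_id"].astype(int))["network"])
        prof = prof.sort_values("n_edges", ascending=False,
                                ignore_index=True)
    return prof
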