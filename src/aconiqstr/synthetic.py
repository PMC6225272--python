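"""Seeded synthetic-data generators and the bundled reference tables.

Each generator emulates the statistical structure one pipeline stage
assumes — a latent-factor descriptor/activity dataset for the PLS stage,
random point-atom molecules for the field engine, a hub-rich
preferential-attachment interaction network for the screening stage, and
relevance/ordering tables at a controlled Kendall distance for the NDCG
stage. All draws come from ``numpy.random.default_rng(seed)``, so identical
parameters give bit-identical output.

The bundled reference tables (33-compound activity set with the 7-compound
external test flags, the experimental/docking rank table for receptors
2V7O and 2VZ6, and the 12-protein literature-frequency list) are shipped as
CSV and verified by content hash at load time.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources

import networkx as nx
import numpy as np
import pandas as pd

from .fields import FieldBlock
from .molecules import COMSIA_PROPERTIES, AlignedMolecule
from .params import VDW_PARAMS
from .pls import QSTRDataset, split_3to1
from .ranking import RankingTable

_FIXTURE_HASHES = {
    "activity_table.csv": "d16eb6c1995c563a4109ebddf6d27a4b083b090bc92945296a7175e927743112",
    "ranking_table.csv": "0c220a58188f8f7f7ddc20eb23cb7c824b00a07d46e3ea37314a18d3d1cdcbf4",
    "protein_table.csv": "833924515ea3c106dd7047be15bf652f065427a25a350b2c85687732d00c58e4",
}


def gen_latent_qstr(n_mol: int = 32, n_cols: int = 120, n_comp: int = 3,
                    noise_sd: float = 0.1, seed: int = 0,
                    x_noise_sd: float = 0.05) -> QSTRDataset:
    """Latent-factor QSTR dataset: X = T P' + E, y = T q + f.

    T is standard normal (n_mol x n_comp), P has orthonormal columns,
    ||q|| = 1 so the noiseless activity has unit variance and ``noise_sd``
    is directly the noise-to-signal scale (noise_sd = 0.5 gives population
    R^2 = 0.8). The planted truth (T, P, q) is stored in
    ``dataset.block.to_frame().attrs`` -> available via ``dataset.truth``.
    A seeded 3:1 activity-stratified train/test split is flagged.
    """
    if n_mol <= n_comp + 2:
        raise ValueError("need n_mol > n_comp + 2")
    if n_cols < n_comp:
        raise ValueError("need n_cols >= n_comp")
    rng = np.random.default_rng(seed)
    T = rng.standard_normal((n_mol, n_comp))
    P, _ = np.linalg.qr(rng.standard_normal((n_cols, n_comp)))
    q = rng.standard_normal(n_comp)
    q /= np.linalg.norm(q)
    X = T @ P.T + x_noise_sd * rng.standard_normal((n_mol, n_cols))
    y = T @ q + noise_sd * rng.standard_normal(n_mol)
    block = FieldBlock(X, [(j, "latent") for j in range(n_cols)],
                       [f"mol{i + 1}" for i in range(n_mol)])
    ds = QSTRDataset(block, y, split_3to1(y, seed=seed))
    ds.truth = {"T": T, "P": P, "q": q, "coefficients": P @ q, "n_comp": n_comp}
    return ds


def gen_point_molecules(n_mol: int = 5, n_atoms: int = 8, box: float = 6.0,
                        seed: int = 0) -> list[AlignedMolecule]:
    """Random point-atom molecules in a shared frame: uniform coordinates in
    [-box/2, box/2]^3, element palette H/C/N/O, charges summing to zero,
    random similarity-property weights in [0, 1]."""
    if n_atoms < 3:
        raise ValueError("need at least 3 atoms")
    rng = np.random.default_rng(seed)
    palette = ["H", "C", "N", "O"]
    out = []
    for i in range(n_mol):
        elements = tuple(rng.choice(palette, size=n_atoms))
        charges = rng.normal(0, 0.2, size=n_atoms)
        charges -= charges.mean()  # neutral molecule
        radius = np.array([VDW_PARAMS[e][0] for e in elements])
        eps = np.array([VDW_PARAMS[e][1] for e in elements])
        props = {p: rng.uniform(0, 1, size=n_atoms) for p in COMSIA_PROPERTIES}
        out.append(AlignedMolecule(
            id=f"synth{i + 1}", elements=elements,
            coords=rng.uniform(-box / 2, box / 2, size=(n_atoms, 3)),
            charges=charges, vdw_radius=radius, vdw_epsilon=eps, props=props,
        ))
    return out


def gen_ba_network(n_nodes: int = 100, n_hubs: int = 5, seed: int = 0,
                   hub_fraction: float = 0.30) -> nx.Graph:
    """Hub-rich interaction network: preferential-attachment background with
    ``n_hubs`` planted nodes each wired to at least ``hub_fraction`` of the
    graph. Planted hub ids are recorded in ``graph.graph['hubs']``.

    The planted truth is kept separable from the background's own
    scale-free core: hubs are picked outside the top-degree decile of the
    background and their extra edges go to a uniform sample of the
    remaining (mostly peripheral) nodes, emulating essential proteins whose
    interactions span the whole network rather than piggy-backing on an
    existing module.
    """
    if n_nodes <= 3 * n_hubs:
        raise ValueError("need n_nodes > 3 * n_hubs")
    rng = np.random.default_rng(seed)
    g = nx.barabasi_albert_graph(n_nodes, m=1, seed=int(rng.integers(2**31)))
    deg = dict(g.degree())
    core = set(sorted(deg, key=deg.get, reverse=True)[:max(1, n_nodes // 10)])
    pool = [v for v in g.nodes() if v not in core]
    hubs = list(rng.choice(pool, size=n_hubs, replace=False))
    k = max(1, int(np.ceil(hub_fraction * n_nodes)))
    for hub in hubs:
        targets = rng.choice([v for v in pool if v != hub], size=k, replace=False)
        g.add_edges_from((hub, int(t)) for t in targets)
    g = nx.relabel_nodes(g, {v: f"P{v:03d}" for v in g.nodes()})
    g.graph["hubs"] = [f"P{h:03d}" for h in hubs]
    return g


def max_kendall_distance(n_items: int) -> int:
    return n_items * (n_items - 1) // 2


def gen_ranking(n_items: int = 12, kendall_distance: int = 0, seed: int = 0) -> RankingTable:
    """Relevance/ordering table at an exact Kendall (adjacent-swap) distance
    from the ideal descending-relevance ordering.

    Relevance values are positive, distinct, drawn uniformly; the predicted
    ordering starts from the ideal permutation and applies random adjacent
    transpositions that each increase the inversion count by one.
    """
    if not 0 <= kendall_distance <= max_kendall_distance(n_items):
        raise ValueError(
            f"kendall_distance must be in [0, {max_kendall_distance(n_items)}]"
        )
    rng = np.random.default_rng(seed)
    relevance = np.sort(rng.uniform(0.5, 5.0, size=n_items))[::-1]  # item i: rank i+1 ideal
    relevance += np.arange(n_items, 0, -1) * 1e-6  # enforce distinct values
    order = list(range(n_items))  # predicted order, positions hold item ids
    applied = 0
    while applied < kendall_distance:
        j = int(rng.integers(0, n_items - 1))
        if order[j] < order[j + 1]:  # swap increases inversions w.r.t. ideal
            order[j], order[j + 1] = order[j + 1], order[j]
            applied += 1
    ranks = np.empty(n_items, dtype=int)
    for pos, item in enumerate(order):
        ranks[item] = pos + 1
    items = [f"cmpd{i + 1}" for i in range(n_items)]
    return RankingTable(items, relevance, {"predicted": ranks})


@dataclass(frozen=True)
class Fixtures:
    activities: pd.DataFrame   # id-indexed: cas, substituents, pld50, is_test
    ranking: RankingTable      # relevance = experimental pLD50
    ranking_frame: pd.DataFrame
    proteins: pd.DataFrame     # name-indexed: classification, frequency


def _read_fixture(name: str) -> pd.DataFrame:
    path = resources.files("aconiqstr.data").joinpath(name)
    raw = path.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _FIXTURE_HASHES[name]:
        raise ValueError(f"fixture {name} is corrupted (sha256 {digest})")
    from io import BytesIO

    return pd.read_csv(BytesIO(raw), comment="#")


def load_fixtures() -> Fixtures:
    """Load the bundled 33-compound activity table, the experimental/docking
    rank table and the 12-protein frequency list, verifying content hashes."""
    act = _read_fixture("activity_table.csv").set_index("id")
    rank = _read_fixture("ranking_table.csv")
    prot = _read_fixture("protein_table.csv").set_index("name")
    merged = rank.merge(act[["pld50"]], left_on="id", right_index=True, how="left")
    table = RankingTable(
        [str(i) for i in merged["id"]],
        merged["pld50"].to_numpy(float),
        {"fit_2V7O": merged["fit_2V7O"].to_numpy(int),
         "fit_2VZ6": merged["fit_2VZ6"].to_numpy(int),
         "experimental": merged["exp_rank"].to_numpy(int)},
    )
    return Fixtures(act, table, rank, prot)
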