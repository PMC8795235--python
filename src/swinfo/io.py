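"""Serialization, deterministic seed management and tiny test fixtures.

Formats are plain text throughout: networks as a tab-separated edge list
(two 0-based node indices per line) plus a node table (index, x, y), with an
optional GraphML export carrying coordinates as node attributes; ensembles as
a directory of such files plus a one-row-per-network CSV manifest; stimuli as
a 0/1 string with a JSON sidecar.
"""

from __future__ import annotations

import json
import hashlib
from pathlib import Path

import numpy as np
import pandas as pd

from .netgen import Network
from .stimulus import BitSequence, StimulusSpec

__all__ = [
    "derive_seed",
    "write_network",
    "read_network",
    "write_graphml",
    "write_ensemble",
    "read_ensemble",
    "write_stimulus",
    "read_stimulus",
    "make_fixtures",
]


def derive_seed(master_seed: int, *key) -> int:
    """Stable sub-seed below 2**31, derived by hashing (master, key...)."""
    text = json.dumps([int(master_seed), *map(str, key)])
    digest = hashlib.sha256(text.encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def write_network(net: Network, path: str | Path) -> None:
    """Write ``<stem>.edges`` (i<TAB>j per line) and ``<stem>.nodes`` (i, x, y)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path.with_suffix(".edges"), "w") as fh:
        for i, j in net.edge_list():
            fh.write(f"{i}\t{j}\n")
    with open(path.with_suffix(".nodes"), "w") as fh:
        fh.write("index\tx\ty\n")
        for i, (x, y) in enumerate(net.coords):
            fh.write(f"{i}\t{float(x)!r}\t{float(y)!r}\n")


def read_network(path: str | Path) -> Network:
    path = Path(path)
    nodes = pd.read_csv(path.with_suffix(".nodes"), sep="\t")
    n = len(nodes)
    adj = np.zeros((n, n), dtype=bool)
    edge_file = path.with_suffix(".edges")
    if not edge_file.exists():
        raise FileNotFoundError(edge_file)
    for line in edge_file.read_text().splitlines():
        if not line.strip():
            continue
        i, j = map(int, line.split("\t"))
        adj[i, j] = adj[j, i] = True
    return Network(coords=nodes[["x", "y"]].to_numpy(), adjacency=adj)


def write_graphml(net: Network, path: str | Path) -> None:
    import networkx as nx

    nx.write_graphml(net.to_networkx(), str(path))


def write_ensemble(nets: list[Network], out_dir: str | Path) -> pd.DataFrame:
    """Write per-network edge lists plus a ``manifest.csv`` of provenance rows."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, net in enumerate(nets):
        write_network(net, out_dir / f"net_{i:04d}")
        rows.append(
            dict(
                network_id=i,
                n=net.n_nodes,
                m=net.n_edges,
                **{k: v for k, v in net.provenance.items() if np.isscalar(v)},
            )
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def read_ensemble(out_dir: str | Path) -> list[Network]:
    out_dir = Path(out_dir)
    manifest = pd.read_csv(out_dir / "manifest.csv")
    nets = []
    for row in manifest.itertuples():
        net = read_network(out_dir / f"net_{int(row.network_id):04d}")
        net.provenance = {
            k: getattr(row, k)
            for k in manifest.columns
            if k not in ("network_id", "n", "m")
        }
        nets.append(net)
    return nets


def write_stimulus(
    bits: BitSequence, spec: StimulusSpec, path: str | Path, seed: int | None = None
) -> None:
    """Plain 0/1 string plus a JSON sidecar with (N, p, delta_t, J/C_m, seed)."""
    path = Path(path)
    path.write_text("".join(map(str, bits.bits.tolist())) + "\n")
    sidecar = dict(
        n_words=spec.n_words,
        p=spec.p,
        delta_t_letter=spec.delta_t_letter,
        J_over_Cm=spec.J_over_Cm,
        seed=seed,
    )
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_stimulus(path: str | Path) -> tuple[BitSequence, dict]:
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    bits = np.array([int(c) for c in path.read_text().strip()], dtype=np.uint8)
    return BitSequence(bits=bits, delta_t_letter=meta["delta_t_letter"]), meta


def _complete(n: int) -> np.ndarray:
    adj = np.ones((n, n), dtype=bool)
    np.fill_diagonal(adj, False)
    return adj


def _ring_lattice(n: int, k: int) -> np.ndarray:
    """Ring of n nodes, each linked to its k/2 nearest neighbours per side."""
    adj = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for step in range(1, k // 2 + 1):
            j = (i + step) % n
            adj[i, j] = adj[j, i] = True
    return adj


def make_fixtures() -> dict:
    """Deterministic tiny test assets with analytically known structure."""
    circle = lambda n, r: np.column_stack(
        [r * np.cos(2 * np.pi * np.arange(n) / n), r * np.sin(2 * np.pi * np.arange(n) / n)]
    )
    fixtures: dict = {}
    fixtures["k3"] = Network(coords=circle(3, 1.0), adjacency=_complete(3))
    fixtures["k4"] = Network(coords=circle(4, 1.0), adjacency=_complete(4))
    star = np.zeros((5, 5), dtype=bool)
    star[0, 1:] = star[1:, 0] = True
    fixtures["star4"] = Network(
        coords=np.vstack([[0.0, 0.0], circle(4, 1.0)]), adjacency=star
    )
    path_adj = np.zeros((3, 3), dtype=bool)
    path_adj[0, 1] = path_adj[1, 0] = path_adj[1, 2] = path_adj[2, 1] = True
    fixtures["path3"] = Network(
        coords=np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]]), adjacency=path_adj
    )
    fixtures["ring30"] = Network(coords=circle(30, 3.0), adjacency=_ring_lattice(30, 4))
    pair = np.zeros((2, 2), dtype=bool)
    pair[0, 1] = pair[1, 0] = True
    fixtures["pair"] = Network(
        coords=np.array([[0.0, 0.0], [1.0, 0.0]]), adjacency=pair
    )
    fixtures["bits_alternating"] = BitSequence(
        bits=np.tile([1, 0], 12).astype(np.uint8), delta_t_letter=3.0
    )
    fixtures["bits_zero"] = BitSequence(bits=np.zeros(24, dtype=np.uint8), delta_t_letter=3.0)
    # canned sweep with known analytic structure: eta peaks at sw = 5.1
    # (off-center within its bin, so the binned argmax is unambiguous)
    sw = np.repeat(np.arange(0.25, 10.0, 0.5), 2)
    eta = 1.0 + 4.0 * np.exp(-((sw - 5.1) ** 2) / 4.0)
    fixtures["sweep_records"] = pd.DataFrame(
        dict(
            network_id=np.arange(len(sw)),
            sw=sw,
            n_words=3,
            p=0.4,
            delta_t=72.0,
            f=400 / 3,
            AN=(10 * eta).round().astype(int),
            I_grid=eta * 3.0,
            I_peak=eta,
            I_input=1.0,
            eta_nodes=eta,
            eta_grid=eta,
            eta_peak=eta,
        )
    )
    return fixtures
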