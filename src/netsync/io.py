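"""Plain-text persistence for networks, phase records and coherence
matrices.

Formats (all LF-terminated TSV):

* edge list — two tab-separated 0-based node ids per line, smaller id
  first, no header, one line per undirected edge;
* phase record — ``#`` header lines carrying n_nodes/dt_eff/t0/seed, then
  one row of node phases per time sample;
* coherence matrix — dense symmetric matrix, one row per line;
* weighted edge list — ``i<TAB>j<TAB>w`` for all pairs or the top-L pairs.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import numpy as np

from .coherence import CoherenceMatrix
from .dynamics import PhaseRecord, wrap_phase

__all__ = [
    "write_edgelist",
    "read_edgelist",
    "write_record",
    "read_record",
    "write_matrix",
    "read_matrix",
    "write_weighted_edgelist",
]


def write_edgelist(net: nx.Graph, path: str | Path) -> None:
    lines = sorted((min(u, v), max(u, v)) for u, v in net.edges)
    with open(path, "w", newline="\n") as fh:
        for u, v in lines:
            fh.write(f"{u}\t{v}\n")


def read_edgelist(path: str | Path, n_nodes: int | None = None) -> nx.Graph:
    """Read an edge list; node count defaults to max id + 1."""
    g = nx.Graph()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            u, v = map(int, line.split("\t"))
            g.add_edge(u, v)
    n = n_nodes if n_nodes is not None else (max(g.nodes) + 1 if g.nodes else 0)
    g.add_nodes_from(range(n))
    return g


def write_record(rec: PhaseRecord, path: str | Path) -> None:
    p = rec.provenance
    with open(path, "w", newline="\n") as fh:
        fh.write(f"# n_nodes={rec.n_nodes}\n")
        dt_eff = rec.times[1] - rec.times[0] if rec.n_samples > 1 else 0.0
        fh.write(f"# t0={rec.times[0]:.10g} dt_eff={dt_eff:.10g}\n")
        fh.write(f"# seed={p.get('rng_seed', '')}\n")
        np.savetxt(fh, rec.phases, fmt="%.10g", delimiter="\t")


def read_record(path: str | Path) -> PhaseRecord:
    meta: dict = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            for tok in line[1:].split():
                if "=" in tok:
                    k, v = tok.split("=", 1)
                    meta[k] = v
    phases = np.loadtxt(path, delimiter="\t", comments="#", ndmin=2)
    t0 = float(meta.get("t0", 0.0))
    dt_eff = float(meta.get("dt_eff", 1.0)) or 1.0
    times = t0 + dt_eff * np.arange(phases.shape[0])
    prov = {"source": str(path)}
    if meta.get("seed"):
        prov["rng_seed"] = int(meta["seed"])
    return PhaseRecord(
        times=times, phases=wrap_phase(phases), unwrapped=phases, provenance=prov
    )


def write_matrix(wns: CoherenceMatrix, path: str | Path) -> None:
    with open(path, "w", newline="\n") as fh:
        np.savetxt(fh, wns.weights, fmt="%.10g", delimiter="\t")


def read_matrix(path: str | Path) -> CoherenceMatrix:
    w = np.loadtxt(path, delimiter="\t", ndmin=2)
    return CoherenceMatrix(weights=w, provenance=(str(path),))


def write_weighted_edgelist(
    wns: CoherenceMatrix, path: str | Path, top_l: int | None = None
) -> None:
    n = wns.n_nodes
    iu, ju = np.triu_indices(n, k=1)
    w = wns.weights[iu, ju]
    order = np.lexsort((iu * n + ju, -w))
    if top_l is not None:
        order = order[:top_l]
    with open(path, "w", newline="\n") as fh:
        for idx in order:
            fh.write(f"{iu[idx]}\t{ju[idx]}\t{w[idx]:.10g}\n")
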