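"""Full-order partial-correlation trait network with marker association edges.

Trait-trait edges carry the partial correlation (conditioning on all other
traits); marker-trait edges carry -log10 of the multiplicity-adjusted
association p-value.  Networks are exported as Pajek ``.net`` files and as
TSV edge lists.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import networkx as nx
from scipy import stats

from .assoc import AssocScanResult
from .simdata import PhenotypeTable

__all__ = [
    "PartialCorrResult",
    "partial_correlation",
    "build_network",
    "write_pajek",
    "read_pajek",
    "write_edgelist",
    "write_vertex_table",
]


@dataclass
class PartialCorrResult:
    matrix: np.ndarray  # traits x traits, unit diagonal
    p: np.ndarray
    n: int
    trait_names: list[str]
    method: str = "inverse"
    shrinkage: float = 0.0


def _shrinkage_intensity(Z: np.ndarray) -> float:
    """Schaefer-Strimmer analytic intensity toward the identity correlation."""
    n, t = Z.shape
    R = (Z.T @ Z) / n
    W = Z[:, :, None] * Z[:, None, :]  # n x t x t products
    var_r = W.var(axis=0, ddof=1) * n / (n - 1) ** 2
    off = ~np.eye(t, dtype=bool)
    denom = float((R[off] ** 2).sum())
    if denom <= 0:
        return 1.0
    return float(np.clip(var_r[off].sum() / denom, 0.0, 1.0))


def partial_correlation(pheno: PhenotypeTable, method: str = "inverse"
                        ) -> PartialCorrResult:
    """Full-order partial correlations between traits.

    Scales the inverse correlation matrix: rho_ij.rest = -W_ij/sqrt(W_ii W_jj).
    Two-sided p-values use the t transform with df = n - 2 - (T - 2), the
    number of conditioned traits being T - 2.  ``method="shrinkage"`` shrinks
    the correlation matrix toward the identity with analytic intensity first
    (needed when n is close to the trait count).
    """
    Y = pheno.values
    n, t = Y.shape
    if t < 2:
        raise ValueError("need at least 2 traits")
    if method == "inverse" and n <= t + 2:
        raise ValueError("n too small for plain inversion; use method='shrinkage'")
    Z = (Y - Y.mean(axis=0)) / Y.std(axis=0, ddof=0)
    R = np.corrcoef(Y.T)
    lam = 0.0
    if method == "shrinkage":
        lam = _shrinkage_intensity(Z)
        R = (1.0 - lam) * R + lam * np.eye(t)
    cond = np.linalg.cond(R)
    if method == "inverse" and cond > 1e10:
        raise ValueError(
            f"correlation matrix is near-singular (cond={cond:.2e}); "
            "use method='shrinkage'")
    Om = np.linalg.inv(R)
    d = np.sqrt(np.diag(Om))
    P = -Om / np.outer(d, d)
    np.fill_diagonal(P, 1.0)
    P = np.clip((P + P.T) / 2.0, -1.0, 1.0)

    df = n - 2 - (t - 2)
    if df < 1:
        raise ValueError("insufficient df for partial-correlation test")
    r = np.clip(P, -0.9999999999, 0.9999999999)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = r * np.sqrt(df / (1.0 - r ** 2))
    pv = 2.0 * stats.t.sf(np.abs(tstat), df)
    np.fill_diagonal(pv, 0.0)
    pv = (pv + pv.T) / 2.0
    return PartialCorrResult(matrix=P, p=pv, n=n,
                             trait_names=list(pheno.trait_names),
                             method=method, shrinkage=lam)


def build_network(pcorr: PartialCorrResult,
                  scans: Iterable[AssocScanResult] = (),
                  alpha: float = 0.05) -> nx.Graph:
    """Assemble the trait/marker network.

    Trait-trait edges where the partial-correlation p <= alpha, weighted by
    |rho|; marker-trait edges for markers significant after adjustment,
    weighted by -log10(p_adj).  Trait vertices are always retained; marker
    vertices appear only with at least one edge.
    """
    G = nx.Graph()
    for name in pcorr.trait_names:
        G.add_node(name, role="trait")
    t = len(pcorr.trait_names)
    for i in range(t):
        for j in range(i + 1, t):
            if pcorr.p[i, j] <= alpha:
                G.add_edge(pcorr.trait_names[i], pcorr.trait_names[j],
                           weight=float(abs(pcorr.matrix[i, j])),
                           rho=float(pcorr.matrix[i, j]), kind="trait-trait")
    for scan in sorted(scans, key=lambda s: s.trait):
        p = scan.p_adj if scan.p_adj is not None else scan.p_raw
        for name, pv in zip(scan.marker_names, p):
            if np.isfinite(pv) and pv <= alpha:
                w = float(-np.log10(max(pv, np.finfo(float).tiny)))
                if name not in G:
                    G.add_node(name, role="marker")
                G.add_edge(name, scan.trait, weight=w, kind="marker-trait")
    return G


def write_pajek(G: nx.Graph, path: str | Path) -> None:
    """Write the Pajek ``.net`` dialect: ``*Vertices n`` with quoted labels
    (1-based ids), then ``*Edges`` lines "u v weight"."""
    path = Path(path)
    nodes = list(G.nodes())
    index = {name: i + 1 for i, name in enumerate(nodes)}
    with open(path, "w") as fh:
        fh.write(f"*Vertices {len(nodes)}\n")
        for name in nodes:
            fh.write(f'{index[name]} "{name}"\n')
        fh.write("*Edges\n")
        for u, v, data in G.edges(data=True):
            w = data.get("weight", 1.0)
            fh.write(f"{index[u]} {index[v]} {w:.12g}\n")


def read_pajek(path: str | Path) -> nx.Graph:
    """Parse the dialect written by :func:`write_pajek`."""
    G = nx.Graph()
    names: dict[int, str] = {}
    section = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.lower().startswith("*vertices"):
                section = "v"
                continue
            if line.lower().startswith("*edges"):
                section = "e"
                continue
            if section == "v":
                idx, rest = line.split(" ", 1)
                name = rest.strip()
                if name.startswith('"') and name.endswith('"'):
                    name = name[1:-1]
                names[int(idx)] = name
                G.add_node(name)
            elif section == "e":
                a, b, w = line.split()
                G.add_edge(names[int(a)], names[int(b)], weight=float(w))
    return G


def write_edgelist(G: nx.Graph, path: str | Path) -> None:
    rows = [{"u": u, "v": v, "kind": d.get("kind", ""),
             "weight": d.get("weight", 1.0)}
            for u, v, d in G.edges(data=True)]
    pd.DataFrame(rows, columns=["u", "v", "kind", "weight"]).to_csv(
        path, sep="\t", index=False)


def write_vertex_table(G: nx.Graph, path: str | Path) -> None:
    rows = [{"name": n, "role": d.get("role", "")} for n, d in G.nodes(data=True)]
    pd.DataFrame(rows, columns=["name", "role"]).to_csv(path, sep="\t", index=False)
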