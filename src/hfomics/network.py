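"""Regulatory-network construction and feed-forward-loop enumeration.

Builds three networks over differentially expressed molecules, using
correlation across HF samples only:

* miRNA-mRNA: consensus target evidence (>= 2 prediction tools, or an
  experimentally validated interaction) plus a *negative* Spearman
  correlation (p < 0.05) — miRNAs repress their targets.
* lncRNA-mRNA: co-expression edges at Spearman p < 0.05, either sign.
* co-regulatory: the union of both, plus miRNA-lncRNA edges at
  Spearman p < 0.05.

A feed-forward loop (FFL) is a triple (miRNA m, lncRNA l, mRNA g) whose
three pairwise edges m-g, l-g and m-l are all present in the co-regulatory
network.  By default the only sign requirement is the miRNA-target
negativity inherited from the miRNA-mRNA network; a strict mode restricts
to the competing-endogenous-RNA pattern (m-g negative, m-l negative,
l-g positive).
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path

import networkx as nx
import pandas as pd

from .matrix import ExpressionMatrix
from .stats import spearman

NODE_TYPES = ("miRNA", "lncRNA", "mRNA")


@dataclasses.dataclass
class Network:
    """Typed undirected regulatory network.

    Nodes carry a ``type`` attribute; edges carry ``rho``, ``p``, ``sign``
    and an ``evidence`` string.  No self-loops; one edge per node pair.
    """

    graph: nx.Graph
    provenance: str  # mir_mrna | lnc_mrna | co_regulatory

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def nodes_of_type(self, node_type: str) -> list[str]:
        return sorted(n for n, d in self.graph.nodes(data=True)
                      if d.get("type") == node_type)

    def edge_table(self) -> pd.DataFrame:
        rows = [{"regulator": u, "target": v, **d}
                for u, v, d in sorted(self.graph.edges(data=True))]
        cols = ["regulator", "target", "rho", "p", "sign", "evidence"]
        return pd.DataFrame(rows, columns=cols)

    def to_sif(self, path) -> None:
        lines = [f"{u}\t{d['sign']}\t{v}"
                 for u, v, d in sorted(self.graph.edges(data=True))]
        Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))

    def to_graphml(self, path) -> None:
        nx.write_graphml(self.graph, path)


@dataclasses.dataclass(frozen=True)
class FFL:
    """A miRNA-lncRNA-mRNA feed-forward triple."""

    mirna: str
    lncrna: str
    mrna: str


def integrate_targets(predicted: dict[str, pd.DataFrame],
                      validated: pd.DataFrame | None = None) -> pd.DataFrame:
    """Consensus miRNA-target interactions.

    Keeps pairs predicted by at least two tools, united with all
    experimentally validated pairs.  Returns a DataFrame with columns
    ``mirna_id``, ``gene_id``, ``sources`` (comma-joined tool names) and
    ``validated``.
    """
    if len(set(predicted)) != len(predicted):
        raise ValueError("tool names must be distinct")
    support: dict[tuple[str, str], set[str]] = {}
    for tool, df in predicted.items():
        for m, g in zip(df["mirna_id"].astype(str), df["gene_id"].astype(str)):
            if not m or not g:
                raise ValueError("malformed interaction id")
            support.setdefault((m, g), set()).add(tool)
    validated_pairs = set()
    if validated is not None and len(validated):
        validated_pairs = set(zip(validated["mirna_id"].astype(str),
                                  validated["gene_id"].astype(str)))
    keep = {pair for pair, tools in support.items() if len(tools) >= 2}
    keep |= validated_pairs
    rows = [(m, g, ",".join(sorted(support.get((m, g), ()))),
             (m, g) in validated_pairs)
            for m, g in sorted(keep)]
    return pd.DataFrame(rows, columns=["mirna_id", "gene_id", "sources",
                                       "validated"])


def _hf_values(mat: ExpressionMatrix, gene: str):
    hf = mat.samples_where("HF")
    return mat.values.loc[gene, hf].to_numpy(dtype=float)


def _corr_edge(x, y, alpha: float):
    """Spearman edge candidate: (rho, p, sign) or None if not significant."""
    try:
        rho, p = spearman(x, y)
    except ValueError:
        return None
    if p >= alpha:
        return None
    return rho, p, ("negative" if rho < 0 else "positive")


def _add_edge(g: nx.Graph, u, utype, v, vtype, rho, p, sign, evidence):
    g.add_node(u, type=utype)
    g.add_node(v, type=vtype)
    g.add_edge(u, v, rho=float(rho), p=float(p), sign=sign, evidence=evidence)


def build_mir_mrna_network(demirs, degs, targets: pd.DataFrame,
                           mir_mat: ExpressionMatrix,
                           mrna_mat: ExpressionMatrix,
                           alpha: float = 0.05,
                           two_hop: bool = False) -> Network:
    """miRNA-mRNA repression network over HF samples.

    An edge (m, g) requires m in ``demirs``, g in ``degs``, consensus
    target evidence, Spearman rho < 0 and p < ``alpha`` across HF samples.
    With ``two_hop`` enabled, a DE miRNA may additionally connect to a DEG
    that is significantly *positively* correlated with one of its direct
    DE targets (an indirect-regulation edge, off by default).
    """
    demirs, degs = set(demirs), set(degs)
    g = nx.Graph()
    direct: list[tuple[str, str]] = []
    for m, tg, sources, val in targets[["mirna_id", "gene_id", "sources",
                                        "validated"]].itertuples(index=False):
        if m not in demirs or tg not in degs:
            continue
        if m not in mir_mat.values.index or tg not in mrna_mat.values.index:
            warnings.warn(f"no expression for DE pair ({m}, {tg}); skipped")
            continue
        cand = _corr_edge(_hf_values(mir_mat, m), _hf_values(mrna_mat, tg), alpha)
        if cand is None or cand[2] != "negative":
            continue
        evidence = sources + (",validated" if val else "")
        _add_edge(g, m, "miRNA", tg, "mRNA", *cand, evidence.strip(","))
        direct.append((m, tg))
    if two_hop:
        for m, tg in direct:
            for other in sorted(degs - {tg}):
                if g.has_edge(m, other) or other not in mrna_mat.values.index:
                    continue
                cand = _corr_edge(_hf_values(mrna_mat, tg),
                                  _hf_values(mrna_mat, other), alpha)
                if cand is not None and cand[2] == "positive":
                    mg = _corr_edge(_hf_values(mir_mat, m),
                                    _hf_values(mrna_mat, other), alpha)
                    if mg is not None and mg[2] == "negative":
                        _add_edge(g, m, "miRNA", other, "mRNA", *mg,
                                  f"two_hop:{tg}")
    return Network(g, "mir_mrna")


def build_lnc_mrna_network(delncs, degs, lnc_mat: ExpressionMatrix,
                           mrna_mat: ExpressionMatrix,
                           alpha: float = 0.05) -> Network:
    """lncRNA-mRNA co-expression network (Spearman p < alpha, either sign)."""
    g = nx.Graph()
    for l in sorted(set(delncs)):
        if l not in lnc_mat.values.index:
            warnings.warn(f"no expression for DE lncRNA {l}; skipped")
            continue
        xl = _hf_values(lnc_mat, l)
        for tg in sorted(set(degs)):
            if tg not in mrna_mat.values.index:
                warnings.warn(f"no expression for DEG {tg}; skipped")
                continue
            cand = _corr_edge(xl, _hf_values(mrna_mat, tg), alpha)
            if cand is not None:
                _add_edge(g, l, "lncRNA", tg, "mRNA", *cand, "coexpression")
    return Network(g, "lnc_mrna")


def build_coregulatory_network(mir_net: Network, lnc_net: Network,
                               mir_mat: ExpressionMatrix,
                               lnc_mat: ExpressionMatrix,
                               alpha: float = 0.05) -> Network:
    """Union of both networks plus significant miRNA-lncRNA edges."""
    hf_mir = mir_mat.samples_where("HF")
    hf_lnc = lnc_mat.samples_where("HF")
    if list(hf_mir) != list(hf_lnc):
        raise ValueError("miRNA and lncRNA matrices cover different HF samples")
    g = nx.Graph()
    for net in (mir_net, lnc_net):
        for node, d in net.graph.nodes(data=True):
            g.add_node(node, **d)
        for u, v, d in net.graph.edges(data=True):
            g.add_edge(u, v, **d)
    for m in mir_net.nodes_of_type("miRNA"):
        if m not in mir_mat.values.index:
            continue
        xm = _hf_values(mir_mat, m)
        for l in lnc_net.nodes_of_type("lncRNA"):
            if l not in lnc_mat.values.index:
                continue
            cand = _corr_edge(xm, _hf_values(lnc_mat, l), alpha)
            if cand is not None:
                _add_edge(g, m, "miRNA", l, "lncRNA", *cand, "coexpression")
    return Network(g, "co_regulatory")


def find_ffls(net: Network, strict: bool = False) -> list[FFL]:
    """All miRNA-lncRNA-mRNA triples whose three edges are present.

    Default sign requirement: the miRNA-mRNA edge must be negative (it
    always is when the edge came from the repression network).  Strict
    mode additionally requires a negative miRNA-lncRNA edge and a positive
    lncRNA-mRNA edge.  Output is sorted lexicographically.
    """
    g = net.graph

    def sign(u, v):
        return g.edges[u, v]["sign"]

    ffls = []
    for m, l in sorted(g.edges()):
        tm = g.nodes[m].get("type")
        tl = g.nodes[l].get("type")
        if {tm, tl} != {"miRNA", "lncRNA"}:
            continue
        if tm == "lncRNA":
            m, l = l, m
        for tg in sorted(set(g.neighbors(m)) & set(g.neighbors(l))):
            if g.nodes[tg].get("type") != "mRNA":
                continue
            if sign(m, tg) != "negative":
                continue
            if strict and (sign(m, l) != "negative" or sign(l, tg) != "positive"):
                continue
            ffls.append(FFL(m, l, tg))
    return sorted(ffls, key=lambda f: (f.mirna, f.lncrna, f.mrna))


def node_degree_report(net: Network) -> pd.DataFrame:
    """Per-node degree table, sorted by degree descending then node id."""
    rows = [(n, d.get("type", ""), net.graph.degree(n))
            for n, d in net.graph.nodes(data=True)]
    df = pd.DataFrame(rows, columns=["node", "type", "degree"])
    return df.sort_values(["degree", "node"], ascending=[False, True],
                          ignore_index=True)
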