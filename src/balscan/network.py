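"""Median-joining haplotype network, outgroup rooting, rho TMRCA dating.

The network algorithm follows the median-joining construction: keep all
links of the epsilon-relaxed minimum-spanning network, add
majority-consensus median (Steiner) vectors of connectable triples when
they reduce the total spanning cost, delete obsolete medians, iterate to
convergence.  With homoplasy-free data the result is the unique
most-parsimonious tree.

Dating uses the rho statistic: the frequency-weighted mean mutational
distance from the root to every sampled chromosome, converted to years
with a per-locus mutation rate calibrated on fixed differences to an
outgroup (rate = fixed_differences / (2 * divergence_time)).
"""

from __future__ import annotations


from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import minimum_spanning_tree


@dataclass
class MJNetwork:
    graph: nx.Graph  # nodes = haplotype strings; attrs: sampled, counts
    epsilon: int = 0
    site_ids: list = field(default_factory=list)
    root: str | None = None

    @property
    def sampled_nodes(self) -> list[str]:
        return [v for v, d in self.graph.nodes(data=True) if d.get("sampled")]

    @property
    def median_nodes(self) -> list[str]:
        return [v for v, d in self.graph.nodes(data=True) if not d.get("sampled")]

    def total_sampled(self) -> int:
        return sum(
            sum(d.get("counts", {}).values()) for _, d in self.graph.nodes(data=True)
        )


@dataclass(frozen=True)
class CalibrationInfo:
    fixed_differences: int
    divergence_time_years: float = 6e6
    locus_length: int | None = None

    def __post_init__(self):
        if self.fixed_differences <= 0 or self.divergence_time_years <= 0:
            raise ValueError("calibration quantities must be positive")

    @property
    def rate_per_year(self) -> float:
        """Per-lineage per-locus mutation rate per year."""
        return self.fixed_differences / (2.0 * self.divergence_time_years)


@dataclass
class TmrcaEstimate:
    rho: float
    sigma_rho: float
    tmrca_years: float
    ci_years: tuple


# ---------------------------------------------------------------------------
# condensing chromosomes to distinct haplotypes


def condense(H, panel=None) -> dict[str, dict[str, int]]:
    """Distinct haplotype strings with per-group chromosome counts.

    ``panel`` maps samples to clusters; without it all chromosomes count
    under group "all".
    """
    out: dict[str, dict[str, int]] = {}
    for j in range(H.n_chromosomes):
        s = "".join(str(int(x)) for x in H.data[:, j])
        group = panel.cluster[H.sample_ids[j]] if panel is not None else "all"
        out.setdefault(s, {})
        out[s][group] = out[s].get(group, 0) + 1
    return out


# ---------------------------------------------------------------------------
# construction


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _dist_matrix(nodes: list[str]) -> np.ndarray:
    arr = np.frombuffer("".join(nodes).encode(), dtype=np.uint8).reshape(len(nodes), -1)
    return (arr[:, None, :] != arr[None, :, :]).sum(axis=2)


def _mst_weight(D: np.ndarray) -> float:
    return float(minimum_spanning_tree(D).sum())


def _minimax_distances(D: np.ndarray) -> np.ndarray:
    """Max edge on the MST path between every pair (connection level)."""
    V = D.shape[0]
    T = minimum_spanning_tree(D).toarray()
    adj = [[] for _ in range(V)]
    for i in range(V):
        for j in range(V):
            if T[i, j] > 0:
                adj[i].append((j, T[i, j]))
                adj[j].append((i, T[i, j]))
    mm = np.zeros((V, V))
    for src in range(V):
        stack = [(src, -1, 0.0)]
        while stack:
            v, parent, best = stack.pop()
            mm[src, v] = best
            for w, wt in adj[v]:
                if w != parent:
                    stack.append((w, v, max(best, wt)))
    return mm


def _msn_edges(nodes: list[str], epsilon: int) -> list[tuple[int, int, int]]:
    """epsilon-relaxed minimum-spanning-network links.

    A pair is linked when its distance is within epsilon of its
    connection level (the minimax path distance), which for epsilon = 0
    keeps exactly the union of all minimum spanning trees.
    """
    D = _dist_matrix(nodes)
    mm = _minimax_distances(D)
    edges = []
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            if D[i, j] <= mm[i, j] + epsilon:
                edges.append((i, j, int(D[i, j])))
    return edges


def _majority_median(u: str, v: str, w: str) -> str:
    return "".join(
        "1" if (a == "1") + (b == "1") + (c == "1") >= 2 else "0"
        for a, b, c in zip(u, v, w)
    )


def build_mj_network(
    haplotypes: dict[str, dict[str, int]] | list[str],
    epsilon: int = 0,
    site_ids: list | None = None,
    max_rounds: int = 50,
) -> MJNetwork:
    """Median-joining network of the given haplotypes.

    ``haplotypes`` is either condense() output or a plain list of binary
    strings (each counted once under group "all").
    """
    if isinstance(haplotypes, dict):
        counts = haplotypes
    else:
        counts = {h: {"all": 1} for h in haplotypes}
    sampled = sorted(counts)
    if len(sampled) < 2:
        raise ValueError("need at least 2 distinct haplotypes")
    L = len(sampled[0])
    for h in sampled:
        if len(h) != L or set(h) - {"0", "1"}:
            raise ValueError(f"haplotype {h!r} is not binary of length {L}")

    nodes = list(sampled)
    for _ in range(max_rounds):
        changed = False
        # greedy median additions while they reduce the spanning cost
        while True:
            D = _dist_matrix(nodes)
            base_w = _mst_weight(D)
            links = {(i, j) for i, j, _ in _msn_edges(nodes, epsilon)}
            neighbors: dict[int, set] = {i: set() for i in range(len(nodes))}
            for i, j in links:
                neighbors[i].add(j)
                neighbors[j].add(i)
            candidates = set()
            for i, j in links:
                for k in neighbors[i] | neighbors[j]:
                    if k in (i, j):
                        continue
                    m = _majority_median(nodes[i], nodes[j], nodes[k])
                    if m not in nodes:
                        candidates.add(m)
            best = None
            for m in candidates:
                w = _mst_weight(_dist_matrix(nodes + [m]))
                if w < base_w - 1e-9 and (best is None or w < best[0]):
                    best = (w, m)
            if best is None:
                break
            nodes.append(best[1])
            changed = True
        # obsolete-median cleanup: unsampled nodes whose removal keeps cost
        removed = True
        while removed:
            removed = False
            D = _dist_matrix(nodes)
            base_w = _mst_weight(D)
            deg = {i: 0 for i in range(len(nodes))}
            for i, j, _ in _msn_edges(nodes, epsilon):
                deg[i] += 1
                deg[j] += 1
            for i in sorted(deg, key=lambda x: deg[x]):
                if nodes[i] in counts or deg[i] > 2:
                    continue
                rest = nodes[:i] + nodes[i + 1 :]
                if len(rest) >= 2 and _mst_weight(_dist_matrix(rest)) <= base_w + 1e-9:
                    nodes = rest
                    removed = changed = True
                    break
        if not changed:
            break

    G = nx.Graph()
    for h in nodes:
        G.add_node(h, sampled=h in counts, counts=dict(counts.get(h, {})))
    sid = site_ids or list(range(L))
    for i, j, d in _msn_edges(nodes, epsilon):
        u, v = nodes[i], nodes[j]
        muts = [sid[k] for k in range(L) if u[k] != v[k]]
        G.add_edge(u, v, weight=d, sites=muts)
    return MJNetwork(graph=G, epsilon=epsilon, site_ids=list(sid))


# ---------------------------------------------------------------------------
# rooting and dating


def root_by_outgroup(net: MJNetwork, outgroup_haplotype: str) -> MJNetwork:
    """Root at the node closest to the outgroup string.

    Ties break by highest sampled count, then lexicographically smallest
    haplotype string.
    """
    if not net.graph.number_of_nodes():
        raise ValueError("empty network")
    best = min(
        net.graph.nodes(data=True),
        key=lambda nd: (
            _hamming(nd[0], outgroup_haplotype),
            -sum(nd[1].get("counts", {}).values()),
            nd[0],
        ),
    )
    net.root = best[0]
    return net


def rho_tmrca(net: MJNetwork, calib: CalibrationInfo) -> TmrcaEstimate:
    """rho-statistic TMRCA of the rooted network.

    rho is the count-weighted mean shortest mutational path from the
    root to each sampled chromosome; its standard error is the square
    root of the count-weighted sum of squared path lengths divided by
    n^2.  Years follow as rho / rate.
    """
    if net.root is None:
        raise ValueError("network must be rooted first (root_by_outgroup)")
    dist = nx.single_source_dijkstra_path_length(net.graph, net.root, weight="weight")
    total = 0
    s1 = s2 = 0.0
    for v, d in net.graph.nodes(data=True):
        c = sum(d.get("counts", {}).values())
        if not c:
            continue
        if v not in dist:
            raise ValueError(f"sampled node {v} disconnected from root")
        total += c
        s1 += c * dist[v]
        s2 += c * dist[v] ** 2
    rho = s1 / total
    sigma = np.sqrt(s2) / total
    rate = calib.rate_per_year
    return TmrcaEstimate(
        rho=rho,
        sigma_rho=sigma,
        tmrca_years=rho / rate,
        ci_years=(max(0.0, rho - 1.96 * sigma) / rate, (rho + 1.96 * sigma) / rate),
    )


def clade_partition(net: MJNetwork) -> tuple[set, set]:
    """Split the network in two by cutting its heaviest link (the deep
    inter-clade edge in a balanced-polymorphism locus)."""
    u, v, _ = max(net.graph.edges(data="weight"), key=lambda e: e[2])
    cut = net.graph.copy()
    cut.remove_edge(u, v)
    comps = list(nx.connected_components(cut))
    if len(comps) == 1:  # heaviest edge was in a cycle; fall back to MST cut
        T = nx.minimum_spanning_tree(net.graph, weight="weight")
        u, v, _ = max(T.edges(data="weight"), key=lambda e: e[2])
        T.remove_edge(u, v)
        comps = list(nx.connected_components(T))
    side = min(comps, key=len)
    return set(side), set(net.graph.nodes) - set(side)


# ---------------------------------------------------------------------------
# serialization


def _encode_counts(counts: dict) -> str:
    return ";".join(f"{g}:{c}" for g, c in sorted(counts.items()))


def _decode_counts(s: str) -> dict:
    if not s:
        return {}
    return {g: int(c) for g, c in (part.split(":") for part in s.split(";"))}


def write_gml(net: MJNetwork, path) -> None:
    G = nx.Graph()
    for v, d in net.graph.nodes(data=True):
        G.add_node(
            v, sampled=int(bool(d.get("sampled"))), counts=_encode_counts(d.get("counts", {}))
        )
    for u, v, d in net.graph.edges(data=True):
        G.add_edge(u, v, weight=int(d["weight"]), sites=",".join(map(str, d["sites"])))
    G.graph["epsilon"] = net.epsilon
    G.graph["root"] = net.root or ""
    G.graph["site_ids"] = ",".join(map(str, net.site_ids))
    nx.write_gml(G, str(path))


def read_gml(path) -> MJNetwork:
    G = nx.read_gml(str(path), label="label")
    H = nx.Graph()
    for v, d in G.nodes(data=True):
        H.add_node(v, sampled=bool(d.get("sampled")), counts=_decode_counts(d.get("counts", "")))
    for u, v, d in G.edges(data=True):
        sites = d.get("sites", "")
        H.add_edge(u, v, weight=int(d["weight"]), sites=sites.split(",") if sites else [])
    sid = G.graph.get("site_ids", "")
    return MJNetwork(
        graph=H,
        epsilon=int(G.graph.get("epsilon", 0)),
        site_ids=sid.split(",") if sid else [],
        root=G.graph.get("root") or None,
    )


def write_edge_tsv(net: MJNetwork, path) -> None:
    with open(path, "w") as fh:
        fh.write("# nodes\n")
        fh.write("haplotype\tsampled\tcounts\n")
        for v, d in sorted(net.graph.nodes(data=True)):
            fh.write(f"{v}\t{int(bool(d.get('sampled')))}\t{_encode_counts(d.get('counts', {}))}\n")
        fh.write("# edges\n")
        fh.write("node_a\tnode_b\tn_mutations\tsites\n")
        for u, v, d in sorted(net.graph.edges(data=True)):
            fh.write(f"{u}\t{v}\t{d['weight']}\t{','.join(map(str, d['sites']))}\n")
        fh.write(f"# epsilon={net.epsilon} root={net.root or ''}\n")


def read_edge_tsv(path) -> MJNetwork:
    G = nx.Graph()
    epsilon, root = 0, None
    mode = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("# nodes"):
                mode = "nodes"
                continue
            if line.startswith("# edges"):
                mode = "edges"
                continue
            if line.startswith("# epsilon"):
                parts = line[2:].split()
                epsilon = int(parts[0].split("=")[1])
                r = parts[1].split("=", 1)[1] if len(parts) > 1 else ""
                root = r or None
                continue
            if not line or line.startswith(("haplotype\t", "node_a\t")):
                continue
            cells = line.split("\t")
            if mode == "nodes":
                G.add_node(cells[0], sampled=bool(int(cells[1])), counts=_decode_counts(cells[2]))
            elif mode == "edges":
                sites = cells[3].split(",") if len(cells) > 3 and cells[3] else []
                G.add_edge(cells[0], cells[1], weight=int(cells[2]), sites=sites)
    return MJNetwork(graph=G, epsilon=epsilon, root=root)
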