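"""Statistical-parsimony haplotype networks and temporal congruence tests.

A haplotype network connects unique sequences by single-mutation steps;
under concerted evolution the dominant haplotype sits at the centre of a
star of rare minor haplotypes whose monthly read profiles track its own
seasonality.  Two ingredients are implemented here:

* **network construction** in the statistical-parsimony (TCS) style:
  pairs of haplotypes are processed in ascending Hamming distance and an
  edge is added whenever it joins haplotypes not yet connected by
  strictly shorter steps, up to a *connection limit*.  With tied
  distances all cross-component edges of that length enter, so the
  sampled-haplotype edge set equals the union of all minimum spanning
  trees (the minimum spanning network).  Links of d > 1 steps are
  expanded with d-1 unsampled intermediate nodes.  The default limit is
  the number of steps that can be accepted as unambiguous single-site
  changes with 95% confidence given the sequence length (see
  :func:`parsimony_connection_limit`).

* a **Kolmogorov-Smirnov test with Monte-Carlo permutations** comparing
  the monthly read profile of a node against the dominant node's,
  treating months as ordered categories; the permutation null reassigns
  pooled reads to the two nodes preserving their totals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .haplotypes import HaplotypeTable
from .simulate import decode_matrix, encode_sequences

logger = logging.getLogger(__name__)


def parsimony_connection_limit(seq_len: int, confidence: float = 0.95) -> int:
    """Maximum number of steps accepted as parsimonious at a confidence
    level, from sequence length alone.

    j substitutions scattered uniformly over ``seq_len`` sites are an
    unambiguous parsimonious path only if they hit j distinct sites; the
    probability of that is prod_{i=1}^{j-1} (1 - i/seq_len).  The limit
    is the largest j for which this probability is still at least
    ``confidence`` (395 bp -> 6 steps, for example).  This reproduces the
    statistical-parsimony criterion semantically; exact agreement with
    any particular software implementation is not promised, and the
    limit can always be overridden explicitly.
    """
    if seq_len < 1:
        raise ValueError("sequence length must be positive")
    prob, j = 1.0, 1
    while True:
        nxt = prob * (1.0 - j / seq_len)
        if nxt < confidence:
            return j
        prob = nxt
        j += 1


@dataclass
class ParsimonyNetwork:
    """Forest of haplotype networks.

    ``graph`` holds sampled haplotype nodes (attributes: ``sequence``,
    ``sampled=True``) and inferred intermediates (``sampled=False``);
    every edge is one mutational step.  ``sampled_edges`` records the
    pre-expansion links between sampled haplotypes with their step
    counts.
    """

    graph: nx.Graph
    sampled_edges: list[tuple[str, str, int]]
    connection_limit: int
    dominant_id: str

    @property
    def sampled_nodes(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d["sampled"]]

    def component_of(self, node: str) -> set[str]:
        return nx.node_connected_component(self.graph, node)


@dataclass(frozen=True)
class MonthlyProfile:
    counts: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts, dtype=np.int64)
        if arr.ndim != 1 or (arr < 0).any():
            raise ValueError("monthly counts must be a non-negative vector")
        object.__setattr__(self, "counts", arr)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def n_months(self) -> int:
        return int(self.counts.size)


@dataclass(frozen=True)
class TemporalKSResult:
    node_id: str
    D: float
    p_mc: float
    n_perm: int
    congruent: bool  # p_mc > alpha: same temporal distribution as dominant


class _DisjointSet:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, x: int, y: int) -> None:
        self.parent[self.find(x)] = self.find(y)


def build_network(table: HaplotypeTable,
                  limit: int | str = "auto") -> ParsimonyNetwork:
    """Build the statistical-parsimony network of a haplotype table.

    Pairwise Hamming distances are processed level by level in ascending
    order; at each level every pair in different components (with respect
    to all strictly shorter links) is connected, provided the distance
    does not exceed the connection limit.  Haplotypes further apart than
    the limit from every network stay singletons, so the result may be a
    forest.  Multi-step links are expanded with inferred intermediate
    nodes (ids ``medN``), placed by mutating the first sequence towards
    the second at the differing sites in positional order.
    """
    ids = list(table.counts.index)
    seqs = [table.sequences[h] for h in ids]
    mat = encode_sequences(seqs)  # validates equal length
    n, length = mat.shape
    if limit == "auto":
        limit_steps = parsimony_connection_limit(length)
    else:
        limit_steps = int(limit)
        if limit_steps < 1:
            raise ValueError("connection limit must be >= 1")

    dist = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        dist[i, i + 1:] = (mat[i + 1:] != mat[i][None, :]).sum(axis=1)
    dist = dist + dist.T

    # order ids lexicographically by sequence for deterministic tie output
    seq_rank = np.argsort(np.argsort(np.array(seqs)))
    pairs: dict[int, list[tuple[int, int]]] = {}
    for i in range(n):
        for j in range(i + 1, n):
            d = int(dist[i, j])
            if 1 <= d <= limit_steps:
                a, b = sorted((i, j), key=lambda x: seq_rank[x])
                pairs.setdefault(d, []).append((a, b))

    dsu = _DisjointSet(n)
    edges: list[tuple[str, str, int]] = []
    for d in sorted(pairs):
        level = [(i, j) for i, j in sorted(
            pairs[d], key=lambda ij: (seq_rank[ij[0]], seq_rank[ij[1]]))
            if dsu.find(i) != dsu.find(j)]
        for i, j in level:
            edges.append((ids[i], ids[j], d))
        for i, j in level:
            dsu.union(i, j)

    graph = nx.Graph()
    for hap_id, seq in zip(ids, seqs):
        graph.add_node(hap_id, sequence=seq, sampled=True)
    med = 0
    for u, v, d in edges:
        if d == 1:
            graph.add_edge(u, v)
            continue
        a = encode_sequences([table.sequences[u]])[0].copy()
        b = encode_sequences([table.sequences[v]])[0]
        prev = u
        for site in np.flatnonzero(a != b)[:-1]:
            a[site] = b[site]
            med += 1
            mid = f"med{med}"
            graph.add_node(mid, sequence=decode_matrix(a[None, :])[0],
                           sampled=False)
            graph.add_edge(prev, mid)
            prev = mid
        graph.add_edge(prev, v)

    dominant_id = ids[0]  # table rows are in rank order
    logger.info("network: %d haplotypes, %d links (limit %d steps), "
                "%d components", n, len(edges), limit_steps,
                nx.number_connected_components(graph))
    return ParsimonyNetwork(graph=graph, sampled_edges=edges,
                            connection_limit=limit_steps,
                            dominant_id=dominant_id)


def monthly_profile(node_id: str, table: HaplotypeTable,
                    n_months: int | None = None) -> MonthlyProfile:
    """Reads of one haplotype pooled by month.

    Inferred intermediate nodes carry no reads and yield an all-zero
    profile.
    """
    if table.sample_dates is None:
        raise ValueError("haplotype table carries no sample dates")
    if n_months is None:
        n_months = max(table.sample_dates.values())
    counts = np.zeros(n_months, dtype=np.int64)
    if node_id in table.counts.index:
        row = table.counts.loc[node_id]
        for sample, n in row.items():
            counts[table.sample_dates[sample] - 1] += int(n)
    return MonthlyProfile(counts)


def ks_temporal_test(node_profile: MonthlyProfile,
                     dominant_profile: MonthlyProfile,
                     n_perm: int = 1000,
                     seed: int = 0,
                     alpha: float = 0.05) -> TemporalKSResult:
    """Two-sample KS test on monthly profiles with a Monte-Carlo null.

    D is the maximum absolute difference between the two empirical CDFs
    over months in calendar order.  The permutation null pools all reads
    and redraws the node's month counts by sampling without replacement
    (a multivariate hypergeometric draw, equivalent to permuting read
    labels while preserving group sizes); the p-value uses the add-one
    estimator p = (1 + #{D* >= D}) / (1 + n_perm), so p is never 0.
    """
    if node_profile.n_months != dominant_profile.n_months:
        raise ValueError("profiles cover different numbers of months")
    n1, n2 = node_profile.total, dominant_profile.total
    if n1 < 1 or n2 < 1:
        raise ValueError("both profiles need at least one read")
    c1 = node_profile.counts
    c2 = dominant_profile.counts
    D = float(np.max(np.abs(np.cumsum(c1) / n1 - np.cumsum(c2) / n2)))
    rng = np.random.default_rng(seed)
    pooled = c1 + c2
    draws = rng.multivariate_hypergeometric(pooled, n1, size=n_perm)
    ecdf1 = np.cumsum(draws, axis=1) / n1
    ecdf2 = np.cumsum(pooled[None, :] - draws, axis=1) / n2
    d_star = np.max(np.abs(ecdf1 - ecdf2), axis=1)
    p = (1.0 + int((d_star >= D - 1e-12).sum())) / (1.0 + n_perm)
    return TemporalKSResult(node_id="", D=D, p_mc=p, n_perm=n_perm,
                            congruent=p > alpha)


def classify_nodes(network: ParsimonyNetwork,
                   table: HaplotypeTable,
                   n_perm: int = 1000,
                   seed: int = 0,
                   alpha: float = 0.05,
                   nodes: list[str] | None = None) -> dict[str, list]:
    """Label each sampled non-dominant node congruent (*) or divergent (#).

    A node is *congruent* when its monthly read distribution does not
    deviate from the dominant node's (p > alpha), *divergent* otherwise.
    By default all sampled non-dominant nodes are tested; ``nodes``
    restricts the test to a selection.  Returns ``{"congruent": [...],
    "divergent": [...], "results": [TemporalKSResult, ...]}``.
    """
    if nodes is None:
        nodes = [x for x in network.sampled_nodes if x != network.dominant_id]
    n_months = (max(table.sample_dates.values())
                if table.sample_dates else 0)
    dom = monthly_profile(network.dominant_id, table, n_months)
    congruent: list[str] = []
    divergent: list[str] = []
    results: list[TemporalKSResult] = []
    ss = np.random.SeedSequence(seed)
    for node, child in zip(nodes, ss.spawn(len(nodes))):
        prof = monthly_profile(node, table, n_months)
        if prof.total == 0:
            continue
        res = ks_temporal_test(prof, dom, n_perm=n_perm,
                               seed=int(child.generate_state(1)[0] % 2**31),
                               alpha=alpha)
        res = TemporalKSResult(node_id=node, D=res.D, p_mc=res.p_mc,
                               n_perm=res.n_perm, congruent=res.congruent)
        results.append(res)
        (congruent if res.congruent else divergent).append(node)
    return {"congruent": congruent, "divergent": divergent, "results": results}


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------


def write_ks_report(results: list[TemporalKSResult], path) -> None:
    with open(path, "w") as fh:
        fh.write("node\tD\tp_mc\tn_perm\tcongruent\n")
        for res in results:
            fh.write(f"{res.node_id}\t{res.D:.6f}\t{res.p_mc:.6f}\t"
                     f"{res.n_perm}\t{res.congruent}\n")


def write_edge_list(network: ParsimonyNetwork, path) -> None:
    """Tab-separated edges of the expanded network (one step per edge)."""
    with open(path, "w") as fh:
        fh.write("node1\tnode2\n")
        for u, v in network.graph.edges():
            fh.write(f"{u}\t{v}\n")


def write_gml(network: ParsimonyNetwork, path) -> None:
    nx.write_gml(network.graph, str(path))


def write_nexus(network: ParsimonyNetwork, table: HaplotypeTable, path,
                n_months: int | None = None) -> None:
    """PopART-compatible NEXUS: TAXA, CHARACTERS, monthly TRAITS and the
    network edges as a NETWORK block."""
    if table.sample_dates is not None and n_months is None:
        n_months = max(table.sample_dates.values())
    sampled = network.sampled_nodes
    nchar = len(table.sequences[sampled[0]])
    with open(path, "w") as fh:
        fh.write("#NEXUS\n\nBEGIN TAXA;\n")
        fh.write(f"DIMENSIONS NTAX={len(sampled)};\nTAXLABELS\n")
        for node in sampled:
            fh.write(f"{node}\n")
        fh.write(";\nEND;\n\nBEGIN CHARACTERS;\n")
        fh.write(f"DIMENSIONS NCHAR={nchar};\n"
                 "FORMAT DATATYPE=DNA MISSING=? GAP=-;\nMATRIX\n")
        for node in sampled:
            fh.write(f"{node} {table.sequences[node]}\n")
        fh.write(";\nEND;\n\nBEGIN TRAITS;\n")
        if n_months:
            labels = ",".join(f"month{m}" for m in range(1, n_months + 1))
            fh.write(f"Dimensions NTRAITS={n_months};\n"
                     "Format labels=yes missing=? separator=Comma;\n"
                     f"TraitLabels {labels.replace(',', ' ')};\nMatrix\n")
            for node in sampled:
                prof = monthly_profile(node, table, n_months)
                fh.write(f"{node} {','.join(str(int(c)) for c in prof.counts)}\n")
            fh.write(";\n")
        fh.write("END;\n\nBEGIN NETWORK;\n")
        fh.write(f"[connection limit: {network.connection_limit} steps]\n")
        fh.write("EDGES\n")
        for i, (u, v) in enumerate(network.graph.edges(), start=1):
            fh.write(f"{i} {u} {v},\n")
        fh.write(";\nEND;\n")


def read_nexus_network(path) -> tuple[list[str], dict[str, str],
                                      dict[str, list[int]],
                                      list[tuple[str, str]]]:
    """Read back the NEXUS written by :func:`write_nexus`.

    Returns (taxa, sequences, monthly traits, edges); used to verify the
    export round-trips losslessly.
    """
    taxa: list[str] = []
    seqs: dict[str, str] = {}
    traits: dict[str, list[int]] = {}
    edges: list[tuple[str, str]] = []
    section = None
    in_matrix = False
    for raw in open(path):
        line = raw.strip()
        if line.startswith("BEGIN "):
            section = line.split()[1].rstrip(";")
            in_matrix = False
            continue
        if line == "END;":
            section = None
            continue
        if section == "TAXA":
            if line.startswith("TAXLABELS"):
                in_matrix = True
            elif line == ";":
                in_matrix = False
            elif in_matrix and not line.startswith("DIMENSIONS"):
                taxa.append(line)
        elif section in ("CHARACTERS", "TRAITS"):
            if line.startswith(("MATRIX", "Matrix")):
                in_matrix = True
            elif line == ";":
                in_matrix = False
            elif in_matrix:
                name, payload = line.split(None, 1)
                if section == "CHARACTERS":
                    seqs[name] = payload
                else:
                    traits[name] = [int(x) for x in payload.split(",")]
        elif section == "NETWORK":
            if line.startswith("EDGES"):
                in_matrix = True
            elif line == ";":
                in_matrix = False
            elif in_matrix and not line.startswith("["):
                _, u, v = line.rstrip(",").split()
                edges.append((u, v))
    return taxa, seqs, traits, edges
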