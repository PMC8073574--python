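"""Body-bar rigidity analysis: constraint graph, (6,6) pebble game, clusters.

Atoms are 6-degree-of-freedom rigid bodies joined by bars: a rotatable
covalent bond contributes 5 bars (removing all relative freedom except the
spin about the bond), the partial-double peptide bond and the C=O double
bond contribute 6 (locked), a backbone hydrogen bond 5, and a hydrophobic
contact 2.  The (6,6) pebble game determines which bars are independent
constraints; two bodies belong to the same rigid cluster exactly when no
seventh pebble can be gathered on the pair once every bar has been played.

The analysis runs on the same coarse-grained model as the search (backbone
plus C-beta, no hydrogens).  This is deliberately coarser than an all-atom
rigidity analysis: it reproduces the qualitative hinge-versus-domain
decomposition, not any particular all-atom cluster set.  A user-supplied
flexible-residue list can override the analysis entirely.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import networkx as nx
from scipy.spatial.distance import cdist

from .constants import ATOM_ORDER, HYDROPHOBIC_RESIDUES
from .kinematics import Conformation

__all__ = [
    "ConstraintGraph",
    "RigidityReport",
    "build_constraint_graph",
    "pebble_game",
    "derive_flexible_residues",
    "analyze_conformation",
    "parse_flexible_list",
    "report_to_tsv",
]

DOF_PER_BODY = 6


@dataclass
class ConstraintGraph:
    """Undirected multigraph of atom bodies joined by bars.

    ``edges`` holds ``(i, j, bars, tag)`` tuples with ``i < j``; the bar
    multiplicity is capped at 6 (more cannot be independent in 3D).
    """

    n_bodies: int
    edges: list = field(default_factory=list)

    def add_edge(self, i: int, j: int, bars: int, tag: str) -> None:
        if i == j:
            raise ValueError("self-edges are not allowed")
        if not 1 <= bars <= DOF_PER_BODY:
            raise ValueError(f"bar multiplicity must be in [1, 6], got {bars}")
        self.edges.append((min(i, j), max(i, j), int(bars), tag))

    def edges_with_tag(self, tag: str) -> list:
        return [e for e in self.edges if e[3] == tag]

    def to_networkx(self) -> nx.MultiGraph:
        g = nx.MultiGraph()
        g.add_nodes_from(range(self.n_bodies))
        for i, j, bars, tag in self.edges:
            g.add_edge(i, j, bars=bars, tag=tag)
        return g


@dataclass
class RigidityReport:
    """Retained rigid clusters and the derived flexible-residue set."""

    clusters: list            # list of frozenset of atom indices, size >= threshold
    min_cluster_atoms: int
    flexible_residues: frozenset  # 0-based residue indices


def build_constraint_graph(
    conformation: Conformation,
    hb_dist_max: float = 3.5,
    hb_angle_min: float = 90.0,
    hb_min_seq_sep: int = 3,
    hydrophobic_dist_max: float = 6.0,
    hydrophobic_min_seq_sep: int = 2,
) -> ConstraintGraph:
    """Build the molecular constraint graph for one conformation.

    Covalent backbone bonds: rotatable single bonds (N-CA, CA-C, CA-CB)
    contribute 5 bars; the peptide C-N bond and the C=O double bond are
    locked at 6.  Hydrogen bonds are detected geometrically on backbone
    O(i)...N(j) pairs (distance and CA-O...N angle criteria) and contribute
    5 bars; hydrophobic contacts are CB-CB pairs of hydrophobic residues
    within a distance cutoff, contributing 2 bars.
    """
    structure = conformation.structure
    idx = structure._atom_index
    gap = structure.gap_after
    m = structure.n_residues
    coords = structure.coords
    graph = ConstraintGraph(n_bodies=structure.n_atoms)

    def a(r, name):
        return int(idx[r, ATOM_ORDER[name]])

    for r in range(m):
        graph.add_edge(a(r, "N"), a(r, "CA"), 5, "covalent_rotatable")
        graph.add_edge(a(r, "CA"), a(r, "C"), 5, "covalent_rotatable")
        graph.add_edge(a(r, "C"), a(r, "O"), 6, "covalent_locked")
        if a(r, "CB") >= 0:
            graph.add_edge(a(r, "CA"), a(r, "CB"), 5, "covalent_rotatable")
        if r + 1 < m and not gap[r]:
            graph.add_edge(a(r, "C"), a(r + 1, "N"), 6, "covalent_locked")

    # hydrogen bonds: O(i)...N(j), |i-j| >= 3, distance < cutoff, CA-O...N > angle cutoff
    o_idx = idx[:, ATOM_ORDER["O"]]
    n_idx = idx[:, ATOM_ORDER["N"]]
    ca_idx = idx[:, ATOM_ORDER["CA"]]
    d_on = cdist(coords[o_idx], coords[n_idx])
    sep = np.abs(np.subtract.outer(np.arange(m), np.arange(m)))
    cand = np.nonzero((d_on < hb_dist_max) & (sep >= hb_min_seq_sep))
    for oi, nj in zip(*cand):
        v1 = coords[ca_idx[oi]] - coords[o_idx[oi]]
        v2 = coords[n_idx[nj]] - coords[o_idx[oi]]
        cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
        if np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))) > hb_angle_min:
            graph.add_edge(int(o_idx[oi]), int(n_idx[nj]), 5, "hbond")

    # hydrophobic contacts: CB-CB of hydrophobic residues, |i-j| >= 2
    hydro = [
        r
        for r in range(m)
        if str(structure.residue_names[r]) in HYDROPHOBIC_RESIDUES and a(r, "CB") >= 0
    ]
    if hydro:
        cb = np.array([a(r, "CB") for r in hydro])
        d_cb = cdist(coords[cb], coords[cb])
        for u in range(len(hydro)):
            for v in range(u + 1, len(hydro)):
                if (
                    abs(hydro[u] - hydro[v]) >= hydrophobic_min_seq_sep
                    and d_cb[u, v] < hydrophobic_dist_max
                ):
                    graph.add_edge(int(cb[u]), int(cb[v]), 2, "hydrophobic")
    return graph


class _PebbleGame:
    """(6,6) body-bar pebble game with component detection.

    Every body starts with 6 pebbles.  A bar between u and v is independent
    iff 7 pebbles can be gathered on {u, v}; accepting it pays one pebble
    from u and orients the bar u->v.  After all bars are played, two bodies
    are mutually rigid iff a seventh pebble can no longer be gathered on
    the pair.
    """

    def __init__(self, n: int):
        self.n = n
        self.pebbles = np.full(n, DOF_PER_BODY, dtype=int)
        self.adj: list[list[int]] = [[] for _ in range(n)]
        self._visit_mark = np.full(n, -1, dtype=int)
        self._epoch = 0

    def _find_pebble(self, root: int, exclude: int) -> bool:
        """Move one free pebble to ``root`` along a reversed directed path,
        never taking pebbles from ``exclude``.  Depth-first search."""
        self._epoch += 1
        mark = self._visit_mark
        mark[root] = self._epoch
        mark[exclude] = self._epoch
        # iterative DFS storing the tree to reverse the path on success
        parent = {root: -1}
        stack = [root]
        while stack:
            u = stack.pop()
            for v in self.adj[u]:
                if mark[v] == self._epoch:
                    continue
                mark[v] = self._epoch
                parent[v] = u
                if self.pebbles[v] > 0:
                    # reverse edges along root -> ... -> v
                    self.pebbles[v] -= 1
                    node = v
                    while parent[node] != -1:
                        prev = parent[node]
                        self.adj[prev].remove(node)
                        self.adj[node].append(prev)
                        node = prev
                    self.pebbles[root] += 1
                    return True
                stack.append(v)
        return False

    def can_gather(self, u: int, v: int, target: int) -> bool:
        while self.pebbles[u] + self.pebbles[v] < target:
            if self._find_pebble(u, v):
                continue
            if self._find_pebble(v, u):
                continue
            return False
        return True

    def insert_bar(self, u: int, v: int) -> bool:
        if not self.can_gather(u, v, DOF_PER_BODY + 1):
            return False  # redundant bar
        if self.pebbles[u] == 0:
            u, v = v, u
        self.pebbles[u] -= 1
        self.adj[u].append(v)
        return True


def pebble_game(graph: ConstraintGraph) -> list:
    """Run the (6,6) body-bar pebble game and return the rigid cluster
    decomposition as a list of frozensets of atom indices (singletons
    included; every body is in exactly one cluster)."""
    game = _PebbleGame(graph.n_bodies)
    for i, j, bars, _tag in graph.edges:
        for _ in range(bars):
            game.insert_bar(i, j)

    # mutual rigidity is an equivalence; testing the pairs that share an
    # edge suffices because rigid clusters are connected in the graph
    parent = list(range(graph.n_bodies))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    seen_pairs = set()
    for i, j, _bars, _tag in graph.edges:
        if (i, j) in seen_pairs:
            continue
        seen_pairs.add((i, j))
        if find(i) == find(j):
            continue
        if not game.can_gather(i, j, DOF_PER_BODY + 1):
            parent[find(i)] = find(j)

    clusters: dict[int, set] = {}
    for x in range(graph.n_bodies):
        clusters.setdefault(find(x), set()).add(x)
    return [frozenset(c) for c in sorted(clusters.values(), key=lambda c: (-len(c), min(c)))]


def derive_flexible_residues(
    clusters: list, conformation: Conformation, min_cluster_atoms: int
) -> RigidityReport:
    """Discard clusters below the size threshold and mark as flexible every
    residue with at least one atom outside all retained clusters."""
    if min_cluster_atoms < 1:
        raise ValueError("min_cluster_atoms must be >= 1")
    retained = [c for c in clusters if len(c) >= min_cluster_atoms]
    in_cluster = np.zeros(conformation.structure.n_atoms, dtype=bool)
    for c in retained:
        in_cluster[list(c)] = True
    res_of_atom = conformation.structure.atom_residue_index
    flexible = frozenset(int(r) for r in np.unique(res_of_atom[~in_cluster]))
    return RigidityReport(
        clusters=retained,
        min_cluster_atoms=min_cluster_atoms,
        flexible_residues=flexible,
    )


def analyze_conformation(
    conformation: Conformation, min_cluster_atoms: int = 6, **graph_kwargs
) -> RigidityReport:
    """Constraint graph -> pebble game -> flexible residues, in one call."""
    graph = build_constraint_graph(conformation, **graph_kwargs)
    clusters = pebble_game(graph)
    return derive_flexible_residues(clusters, conformation, min_cluster_atoms)


def parse_flexible_list(text: str, structure) -> frozenset:
    """Parse a flexible-residue override file: one PDB residue number per
    line, ``#`` comments.  Returns 0-based residue indices; numbers absent
    from the structure are ignored."""
    wanted = set()
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        wanted.add(int(line))
    return frozenset(
        i for i, num in enumerate(structure.residue_numbers) if int(num) in wanted
    )


def report_to_tsv(report: RigidityReport, structure) -> str:
    """Tab-separated cluster table plus the flexible-residue list."""
    lines = ["cluster_id\tsize\tatom_serials"]
    for k, cluster in enumerate(report.clusters, start=1):
        serials = sorted(int(structure.serials[a]) for a in cluster)
        lines.append(f"{k}\t{len(cluster)}\t{','.join(map(str, serials))}")
    flex_numbers = sorted(int(structure.residue_numbers[r]) for r in report.flexible_residues)
    lines.append("# flexible_residues\t" + ",".join(map(str, flex_numbers)))
    return "\n".join(lines) + "\n"
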