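"""Independent reference implementations used as test oracles.

Everything here is deliberately brute-force and structurally unrelated to
the package's own implementations: plain loops, dense linear algebra and
random search, at sizes where being slow does not matter.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize as scipy_minimize
from scipy.spatial.transform import Rotation


def rigidity_matrix_clusters(n_bodies: int, edges, rng: np.random.Generator):
    """Rigid-cluster decomposition from the rank of a generic body-bar
    rigidity matrix.

    Bodies move with 6 velocities (v, omega); a bar with generic endpoints
    a_u, a_v adds the row of the constraint (va_u - va_v) . (a_u - a_v) = 0.
    Two bodies are mutually rigid iff appending one extra generic bar
    between them does not raise the matrix rank.
    """
    pos = rng.uniform(-1.0, 1.0, size=(n_bodies, 3))

    def bar_row(u: int, v: int) -> np.ndarray:
        a_u = pos[u] + rng.uniform(-0.3, 0.3, 3)
        a_v = pos[v] + rng.uniform(-0.3, 0.3, 3)
        d = a_u - a_v
        row = np.zeros(6 * n_bodies)
        row[6 * u:6 * u + 3] = d
        row[6 * u + 3:6 * u + 6] = np.cross(a_u, d)
        row[6 * v:6 * v + 3] = -d
        row[6 * v + 3:6 * v + 6] = -np.cross(a_v, d)
        return row

    rows = []
    for u, v, bars, _tag in edges:
        for _ in range(bars):
            rows.append(bar_row(u, v))
    matrix = np.array(rows) if rows else np.zeros((0, 6 * n_bodies))
    base_rank = np.linalg.matrix_rank(matrix, tol=1e-8)

    parent = list(range(n_bodies))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for u in range(n_bodies):
        for v in range(u + 1, n_bodies):
            trial = np.vstack([matrix, bar_row(u, v)]) if len(matrix) else bar_row(u, v)[None]
            if np.linalg.matrix_rank(trial, tol=1e-8) == base_rank:
                parent[find(u)] = find(v)

    clusters: dict[int, set] = {}
    for x in range(n_bodies):
        clusters.setdefault(find(x), set()).add(x)
    return sorted((frozenset(c) for c in clusters.values()), key=lambda c: (-len(c), min(c)))


def grid_search_rmsd(coords_a: np.ndarray, coords_b: np.ndarray, rng: np.random.Generator) -> float:
    """Minimum superposition RMSD by random rotation search plus local
    refinement over rotation vectors (independent of the Kabsch/SVD path)."""
    a = coords_a - coords_a.mean(axis=0)
    b = coords_b - coords_b.mean(axis=0)
    n = len(a)

    def rmsd_for(rotvec: np.ndarray) -> float:
        rot = Rotation.from_rotvec(rotvec).as_matrix()
        d = a - b @ rot.T
        return float(np.sqrt(np.sum(d * d) / n))

    candidates = Rotation.random(4000, random_state=rng.integers(2**31)).as_rotvec()
    best = min(candidates, key=rmsd_for)
    res = scipy_minimize(rmsd_for, best, method="Nelder-Mead", options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 4000})
    return float(res.fun)


def brute_force_vdw(structure, params) -> float:
    """Plain O(n^2) loop over all atom pairs, recomputing bond separations
    by breadth-first search, reproducing the soft-LJ sum."""
    from pathweaver.energy import get_topology

    topo = get_topology(structure)
    n = structure.n_atoms
    neighbors = [[] for _ in range(n)]
    for i, j in topo.bonds:
        neighbors[i].append(j)
        neighbors[j].append(i)

    def bond_sep(i: int, j: int) -> int:
        seen = {i: 0}
        frontier = [i]
        while frontier:
            nxt = []
            for u in frontier:
                for v in neighbors[u]:
                    if v not in seen:
                        seen[v] = seen[u] + 1
                        if v == j:
                            return seen[v]
                        if seen[v] < 4:
                            nxt.append(v)
            frontier = nxt
        return 99

    total = 0.0
    coords = structure.coords
    for i in range(n):
        for j in range(i + 1, n):
            sep = bond_sep(i, j)
            if sep < 3:
                continue
            r = float(np.linalg.norm(coords[i] - coords[j]))
            if r > params.vdw_cutoff:
                continue
            sig = 0.5 * (
                params.lj_sigma[str(structure.atom_names[i])]
                + params.lj_sigma[str(structure.atom_names[j])]
            )
            eps = np.sqrt(
                params.lj_epsilon[str(structure.atom_names[i])]
                * params.lj_epsilon[str(structure.atom_names[j])]
            )
            if sep == 3:
                sig *= params.lj_14_sigma_scale
                eps *= params.lj_14_epsilon_scale
            r_eff = max(r, params.vdw_softening * sig)
            x6 = (sig / r_eff) ** 6
            total += 4.0 * eps * (x6 * x6 - x6)
    return total


def recompute_tree_costs(result_nodes, g_mode: str) -> dict[int, float]:
    """Recompute every node's accumulated cost along its parent chain."""
    out = {}

    def g_of(node):
        if node.parent is None:
            return 0.0
        if node.index in out:
            return out[node.index]
        if g_mode == "literal":
            inc = node.lrmsd_to_start
        else:
            from pathweaver.geometry import rmsd_to_many
            inc = float(rmsd_to_many(node.centered_ca, node.parent.centered_ca[None])[0])
        g = g_of(node.parent) + inc
        out[node.index] = g
        return g

    for node in result_nodes:
        g_of(node)
    out[0] = 0.0
    return out
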