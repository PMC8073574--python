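"""RRT*/Monte-Carlo search for conformational transition pathways.

The tree grows from the start conformation toward the goal.  Each iteration
selects a node (biased toward the k best by goal-lRMSD), perturbs phi/psi
torsions of eligible residues (those still differing from the goal, and —
when rigidity guidance is on — flexible ones), relaxes the result with a few
steps of steepest descent, gates it on total energy, applies a Monte-Carlo
acceptance on the goal-lRMSD, and then inserts it RRT*-style: least-cost
parent among the near neighbours, followed by rewiring.  The node pool is
pruned of redundant members on a geometric schedule.  In adaptive mode the
rigidity analysis is recomputed whenever the best conformation has drifted
by more than a threshold since the last run.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .energy import EnergyParams, energy_gate, minimize, total_energy
from .geometry import circular_difference
from .kinematics import Conformation, lrmsd, lrmsd_to_many, paired_ca_coords, set_dihedral
from .rigidity import RigidityReport, analyze_conformation
from .structure import ResiduePairing, pair_residues

logger = logging.getLogger(__name__)

__all__ = [
    "SearchConfig",
    "TreeNode",
    "SearchTree",
    "PathResult",
    "NoEligibleAngles",
    "select_node",
    "perturb",
    "near_neighbors",
    "node_cost",
    "choose_parent",
    "rewire",
    "mc_accept",
    "prune",
    "should_recompute_rigidity",
    "run_search",
]


class NoEligibleAngles(Exception):
    """Raised when no torsion is eligible for perturbation."""


GOAL_THRESHOLD_BAND = (1.7, 3.65)


@dataclass(frozen=True)
class SearchConfig:
    """Run configuration; defaults follow the published study conditions."""

    bias_fraction: float = 1.0 / 3.0
    k_best: int = 20
    angle_diff_min: float = 5.0          # degrees
    neighbor_radius: float = 1.0         # Angstrom
    minimize_steps: int = 10
    energy_k: float = 5.0                # gate: E_total < energy_k * n_residues
    mc_a: float = 0.01
    stall_limit: int = 500               # M iterations without improvement
    goal_threshold: float | None = None  # None: 0.25*initial lRMSD clamped to the band
    prune_start_size: int | None = None  # None: n_residues
    prune_growth: int = 3
    rigidity_mode: str = "adaptive"      # off | once | adaptive
    rigidity_recompute_drift: float = 2.0  # Angstrom
    min_cluster_atoms: int = 6
    max_iterations: int = 20000
    perturb_max_angles: int | None = None  # None: max(2, ceil(0.05*n_residues))
    perturb_step_max: float = 10.0       # degrees
    rng_seed: int = 0
    g_mode: str = "literal"              # literal | edge
    energy_params: EnergyParams = field(default_factory=EnergyParams)

    def __post_init__(self):
        if not 0.0 < self.bias_fraction < 1.0:
            raise ValueError("bias_fraction must be in (0, 1)")
        if self.rigidity_mode not in ("off", "once", "adaptive"):
            raise ValueError(f"unknown rigidity_mode {self.rigidity_mode!r}")
        if self.g_mode not in ("literal", "edge"):
            raise ValueError(f"unknown g_mode {self.g_mode!r}")
        for name in (
            "neighbor_radius", "perturb_step_max", "rigidity_recompute_drift",
            "angle_diff_min", "mc_a",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def resolve_goal_threshold(self, initial_lrmsd: float) -> float:
        if self.goal_threshold is not None:
            return self.goal_threshold
        lo, hi = GOAL_THRESHOLD_BAND
        return min(hi, max(lo, 0.25 * initial_lrmsd))

    def resolve_perturb_max_angles(self, n_residues: int) -> int:
        if self.perturb_max_angles is not None:
            return self.perturb_max_angles
        return max(2, math.ceil(0.05 * n_residues))


@dataclass
class TreeNode:
    """One sampled conformation in the RRT* tree."""

    conformation: Conformation
    parent: "TreeNode | None"
    g: float                    # accumulated cost, Angstrom-sum
    h: float                    # lRMSD to the goal
    lrmsd_to_start: float
    in_pool: bool = True
    rigidity_epoch: int = 0
    index: int = 0
    children: list = field(default_factory=list)
    centered_ca: np.ndarray | None = None

    @property
    def cost(self) -> float:
        return self.g + self.h


@dataclass
class PathResult:
    """Extracted path and run diagnostics."""

    path: list                  # Conformations, start -> best
    best_lrmsd: float
    iterations_used: int
    tree_size: int
    lrmsd_trace: np.ndarray     # per-iteration best (pool-minimum) lRMSD
    size_trace: np.ndarray      # per-iteration (tree_size, pool_size, rigidity_epoch)
    rigidity_runs: int
    goal_threshold: float
    initial_lrmsd: float
    seed: int
    config: SearchConfig
    stop_reason: str = ""
    tree: "SearchTree | None" = None


class SearchTree:
    """RRT* tree with a centered-CA coordinate cache for fast batched lRMSD."""

    def __init__(self, root: TreeNode, pairing: ResiduePairing):
        self.nodes: list[TreeNode] = []
        self.pairing = pairing
        self._ca_stack: list[np.ndarray] = []
        self.add(root)

    def add(self, node: TreeNode) -> None:
        node.index = len(self.nodes)
        self.nodes.append(node)
        if node.centered_ca is None:
            node.centered_ca = self.centered_ca(node.conformation)
        self._ca_stack.append(node.centered_ca)
        if node.parent is not None:
            node.parent.children.append(node)

    def centered_ca(self, conformation: Conformation) -> np.ndarray:
        s = conformation.structure
        ca = s.coords[s.ca_indices[self.pairing.start_indices]]
        return ca - ca.mean(axis=0)

    @property
    def size(self) -> int:
        return len(self.nodes)

    def pool_nodes(self) -> list[TreeNode]:
        return [n for n in self.nodes if n.in_pool]

    def lrmsd_to_nodes(self, centered_ca: np.ndarray, nodes: list[TreeNode]) -> np.ndarray:
        if not nodes:
            return np.empty(0)
        stack = np.stack([n.centered_ca for n in nodes])
        return lrmsd_to_many(centered_ca, stack)


def select_node(tree: SearchTree, rng: np.random.Generator, config: SearchConfig) -> TreeNode:
    """Biased node selection: with probability ``bias_fraction`` draw
    uniformly from the k pool members closest to the goal, otherwise
    uniformly from the whole pool."""
    pool = tree.pool_nodes()
    if not pool:
        raise RuntimeError("empty selection pool")
    if rng.uniform() < config.bias_fraction:
        ranked = sorted(pool, key=lambda n: (n.h, n.index))
        pool = ranked[: config.k_best]
    return pool[int(rng.integers(len(pool)))]


def _eligible_angles(
    conformation: Conformation,
    goal: Conformation,
    pairing: ResiduePairing,
    angle_diff_min: float,
    flexible: RigidityReport | frozenset | None,
) -> list[tuple[int, str]]:
    flex_set = None
    if flexible is not None:
        flex_set = flexible.flexible_residues if isinstance(flexible, RigidityReport) else flexible
    out = []
    d_node = conformation.dihedrals
    d_goal = goal.dihedrals
    for si, gi in pairing.pairs:
        if flex_set is not None and si not in flex_set:
            continue
        for kind in ("phi", "psi"):
            a = (d_node.phi if kind == "phi" else d_node.psi)[si]
            b = (d_goal.phi if kind == "phi" else d_goal.psi)[gi]
            if not (np.isfinite(a) and np.isfinite(b)):
                continue
            if circular_difference(a, b) > angle_diff_min:
                out.append((si, kind))
    return out


def perturb(
    node: TreeNode,
    flexible: RigidityReport | frozenset | None,
    goal: Conformation,
    pairing: ResiduePairing,
    rng: np.random.Generator,
    config: SearchConfig,
) -> Conformation:
    """Perturb randomly chosen eligible torsions of the node's conformation.

    Eligible torsions are the defined phi/psi of paired residues whose
    circular difference from the goal counterpart exceeds
    ``angle_diff_min``, intersected with the flexible residues when
    rigidity guidance is active.  Raises :class:`NoEligibleAngles` when the
    set is empty.
    """
    eligible = _eligible_angles(
        node.conformation, goal, pairing, config.angle_diff_min, flexible
    )
    if not eligible:
        raise NoEligibleAngles
    max_angles = config.resolve_perturb_max_angles(node.conformation.n_residues)
    m = int(rng.integers(1, max_angles + 1))
    m = min(m, len(eligible))
    chosen = rng.choice(len(eligible), size=m, replace=False)
    conf = node.conformation
    for k in chosen:
        res_i, kind = eligible[int(k)]
        current = (conf.dihedrals.phi if kind == "phi" else conf.dihedrals.psi)[res_i]
        step = rng.uniform(-config.perturb_step_max, config.perturb_step_max)
        conf = set_dihedral(conf, res_i, kind, current + step)
    return conf


def near_neighbors(
    tree: SearchTree, conf: Conformation, config: SearchConfig | None = None,
    centered_ca: np.ndarray | None = None,
) -> list[TreeNode]:
    """Pool nodes within ``neighbor_radius`` lRMSD of ``conf`` (inclusive);
    if none, the single nearest pool node."""
    config = config or SearchConfig()
    pool = tree.pool_nodes()
    if centered_ca is None:
        centered_ca = tree.centered_ca(conf)
    d = tree.lrmsd_to_nodes(centered_ca, pool)
    within = [n for n, di in zip(pool, d) if di <= config.neighbor_radius]
    if within:
        return within
    return [pool[int(np.argmin(d))]]


def node_cost(node: TreeNode) -> float:
    """A*-style cost(n) = g(n) + h(n)."""
    return node.g + node.h


def _g_increment(config: SearchConfig, lrmsd_to_start: float, lrmsd_to_parent: float) -> float:
    if config.g_mode == "literal":
        # as stated: g(n) = g(parent) + lRMSD(n, start)
        return lrmsd_to_start
    return lrmsd_to_parent


def choose_parent(
    neighbors: list[TreeNode],
    conf_h: float,
    conf_lrmsd_to_start: float,
    lrmsd_to_neighbors: np.ndarray,
    config: SearchConfig,
) -> TreeNode:
    """Least prospective-cost neighbour; ties broken by smaller lRMSD to the
    new conformation, then insertion order."""
    if not neighbors:
        raise ValueError("choose_parent requires at least one neighbor")
    best = None
    best_key = None
    for n, d in zip(neighbors, lrmsd_to_neighbors):
        cost = n.g + _g_increment(config, conf_lrmsd_to_start, float(d)) + conf_h
        key = (cost, float(d), n.index)
        if best_key is None or key < best_key:
            best, best_key = n, key
    return best


def _update_subtree_g(node: TreeNode, delta: float) -> None:
    stack = [node]
    while stack:
        n = stack.pop()
        n.g += delta
        stack.extend(n.children)


def rewire(
    tree: SearchTree,
    new_node: TreeNode,
    neighbors: list[TreeNode],
    lrmsd_to_neighbors: np.ndarray,
    config: SearchConfig,
) -> int:
    """Reparent any neighbour whose accumulated cost would strictly drop by
    routing through the new node; subtree costs are updated and cycles are
    impossible because the new node's ancestors are excluded."""
    ancestors = set()
    a = new_node
    while a is not None:
        ancestors.add(id(a))
        a = a.parent
    count = 0
    for n, d in zip(neighbors, lrmsd_to_neighbors):
        if id(n) in ancestors or n is new_node:
            continue
        g_via = new_node.g + _g_increment(config, n.lrmsd_to_start, float(d))
        if g_via < n.g - 1e-12:
            old_parent = n.parent
            if old_parent is not None:
                old_parent.children.remove(n)
            n.parent = new_node
            new_node.children.append(n)
            _update_subtree_g(n, g_via - n.g)
            count += 1
    return count


def mc_accept(
    lrmsd_new: float,
    lrmsd_parent: float,
    a: float,
    rng: np.random.Generator,
) -> bool:
    """Monte-Carlo acceptance on the goal-lRMSD score.

    Improvements are always accepted; a worsening is accepted with
    probability exp(-(new - parent) / (new * a)), which lets the search
    climb out of local minima with small probability.
    """
    if lrmsd_new < lrmsd_parent:
        return True
    if lrmsd_new == 0.0:
        return True
    bound = math.exp(-(lrmsd_new - lrmsd_parent) / (lrmsd_new * a))
    return rng.uniform() < bound


def prune(tree: SearchTree, config: SearchConfig | None = None) -> int:
    """Remove redundant nodes from the selection pool.

    For every pool pair whose mutual lRMSD is at most 10% of the smaller
    goal-lRMSD of the two, the node farther from the goal leaves the pool.
    Tree edges are never severed, so extracted paths stay intact.  Returns
    the number of nodes removed."""
    pool = sorted(tree.pool_nodes(), key=lambda n: (n.h, n.index))
    removed = 0
    active = np.ones(len(pool), dtype=bool)
    for i, keeper in enumerate(pool):
        if not active[i]:
            continue
        rest = [j for j in range(i + 1, len(pool)) if active[j]]
        if not rest:
            break
        d = tree.lrmsd_to_nodes(keeper.centered_ca, [pool[j] for j in rest])
        for j, dj in zip(rest, d):
            # h(keeper) <= h(pool[j]) by the sort order
            if dj <= 0.10 * keeper.h:
                pool[j].in_pool = False
                active[j] = False
                removed += 1
    return removed


def should_recompute_rigidity(
    current: Conformation,
    last_rigidity_conf: Conformation,
    pairing: ResiduePairing,
    drift_threshold: float = 2.0,
) -> bool:
    """True iff the conformation drifted strictly more than the threshold
    (lRMSD) since rigidity was last analysed."""
    identity = ResiduePairing(pairs=[(s, s) for s, _ in pairing.pairs])
    return lrmsd(current, last_rigidity_conf, identity) > drift_threshold


def run_search(
    start: Conformation,
    goal: Conformation,
    config: SearchConfig | None = None,
    flexible_override: frozenset | None = None,
) -> PathResult:
    """Grow the tree from ``start`` toward ``goal`` and extract the path.

    Stops when the best goal-lRMSD falls to the goal threshold, when it has
    not improved for ``stall_limit`` consecutive iterations, or at
    ``max_iterations``.  The returned path is the parent chain from the
    start conformation to the best node.
    """
    config = config or SearchConfig()
    rng = np.random.default_rng(config.rng_seed)
    pairing = pair_residues(start.structure, goal.structure)
    n_residues = start.n_residues

    initial = lrmsd(start, goal, pairing)
    threshold = config.resolve_goal_threshold(initial)

    flexible: RigidityReport | frozenset | None = None
    rigidity_runs = 0
    last_rigidity_conf = start
    if flexible_override is not None:
        flexible = flexible_override
    elif config.rigidity_mode != "off":
        flexible = analyze_conformation(start, config.min_cluster_atoms)
        rigidity_runs = 1
        logger.info(
            "rigidity: %d flexible residues of %d",
            len(flexible.flexible_residues), n_residues,
        )

    root = TreeNode(
        conformation=start, parent=None, g=0.0, h=initial, lrmsd_to_start=0.0
    )
    tree = SearchTree(root, pairing)
    best = root
    trace = []
    size_trace = []
    stall = 0
    prune_trigger = config.prune_start_size or n_residues
    epoch = 0
    stop_reason = "max_iterations"
    iterations = 0

    if best.h <= threshold:
        stop_reason = "goal_threshold"

    while best.h > threshold and iterations < config.max_iterations:
        iterations += 1
        improved = False
        accepted_node = None
        node = select_node(tree, rng, config)
        try:
            candidate = perturb(node, flexible, goal, pairing, rng, config)
        except NoEligibleAngles:
            candidate = None
        if candidate is not None:
            if config.minimize_steps > 0:
                candidate = minimize(
                    candidate, config.energy_params, max_steps=config.minimize_steps
                )
            breakdown = total_energy(candidate, config.energy_params)
            if energy_gate(breakdown, n_residues, config.energy_k):
                centered = tree.centered_ca(candidate)
                h_new = float(lrmsd_to_many(centered, _goal_ca(tree, goal)[None])[0])
                if mc_accept(h_new, node.h, config.mc_a, rng):
                    pool = tree.pool_nodes()
                    d_pool = tree.lrmsd_to_nodes(centered, pool)
                    within = d_pool <= config.neighbor_radius
                    if np.any(within):
                        neighbors = [n for n, w in zip(pool, within) if w]
                        d_nb = d_pool[within]
                    else:
                        k = int(np.argmin(d_pool))
                        neighbors = [pool[k]]
                        d_nb = d_pool[[k]]
                    lrmsd_start = float(
                        tree.lrmsd_to_nodes(centered, [root])[0]
                    )
                    parent = choose_parent(neighbors, h_new, lrmsd_start, d_nb, config)
                    d_parent = float(d_nb[neighbors.index(parent)])
                    g_new = parent.g + _g_increment(config, lrmsd_start, d_parent)
                    accepted_node = TreeNode(
                        conformation=candidate,
                        parent=parent,
                        g=g_new,
                        h=h_new,
                        lrmsd_to_start=lrmsd_start,
                        rigidity_epoch=epoch,
                        centered_ca=centered,
                    )
                    tree.add(accepted_node)
                    rewire(tree, accepted_node, neighbors, d_nb, config)
                    if h_new < best.h - 1e-12:
                        best = accepted_node
                        improved = True

        if improved:
            stall = 0
        else:
            stall += 1
        trace.append(best.h)
        size_trace.append(
            (tree.size, sum(1 for n in tree.nodes if n.in_pool), epoch)
        )

        pool_size = sum(1 for n in tree.nodes if n.in_pool)
        if pool_size >= prune_trigger:
            prune(tree, config)
            prune_trigger *= config.prune_growth
            if not best.in_pool:
                # the best node can never be pruned (it minimises h), but be safe
                best.in_pool = True

        if (
            accepted_node is not None
            and flexible_override is None
            and config.rigidity_mode == "adaptive"
            and should_recompute_rigidity(
                best.conformation, last_rigidity_conf, pairing,
                config.rigidity_recompute_drift,
            )
        ):
            flexible = analyze_conformation(best.conformation, config.min_cluster_atoms)
            last_rigidity_conf = best.conformation
            rigidity_runs += 1
            epoch += 1

        if best.h <= threshold:
            stop_reason = "goal_threshold"
            break
        if stall >= config.stall_limit:
            stop_reason = "stalled"
            break
    else:
        if best.h <= threshold:
            stop_reason = "goal_threshold"

    path_nodes = []
    n = best
    while n is not None:
        path_nodes.append(n)
        n = n.parent
    path_nodes.reverse()

    return PathResult(
        path=[n.conformation for n in path_nodes],
        best_lrmsd=best.h,
        iterations_used=iterations,
        tree_size=tree.size,
        lrmsd_trace=np.array(trace),
        size_trace=np.array(size_trace, dtype=int).reshape(-1, 3),
        rigidity_runs=rigidity_runs,
        goal_threshold=threshold,
        initial_lrmsd=initial,
        seed=config.rng_seed,
        config=config,
        stop_reason=stop_reason,
        tree=tree,
    )


def _goal_ca(tree: SearchTree, goal: Conformation) -> np.ndarray:
    cached = getattr(tree, "_goal_ca", None)
    if cached is None:
        s = goal.structure
        ca = s.coords[s.ca_indices[tree.pairing.goal_indices]]
        cached = ca - ca.mean(axis=0)
        tree._goal_ca = cached
    return cached
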