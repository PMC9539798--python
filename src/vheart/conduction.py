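"""His-Purkinje system and atrio-ventricular node.

The HPS is a surface-constrained stochastic fractal tree: from each
fascicular root site, binary branching with mean cable length 6 mm (sd
1 mm, truncated), sibling repulsion of at least 45 degrees, collision
avoidance (2 mm), growth confined to the subendocardial surface except
for the RV moderator-band fascicle which crosses the cavity to the free
wall.  Cables conduct at 2.0 m/s; the last cable before each fascicular
root site is re-tuned (Euclidean length over residual delay) so root
arrival times match prescribed fascicular delays.  Terminal leaves couple
to the myocardium through PMJs with 8 ms antegrade / 3 ms retrograde
delays.  A 1-D AV-node cable joins the basal right atrium to the His
bundle; its conduction velocity is tuned to a physiological PR interval.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import cKDTree

from .anatomy import HeartModel
from .mesh import Tissue

# branch side / kind codes
SIDE_NONE, SIDE_LEFT, SIDE_RIGHT = 0, 1, 2
KIND_TRUNK, KIND_FASCICLE, KIND_AVN = 0, 1, 2

PMJ_ANTEGRADE_MS = 8.0
PMJ_RETROGRADE_MS = 3.0
HPS_CV_M_PER_S = 2.0
SEGMENT_LENGTH_MM = 0.5


@dataclass(frozen=True)
class FascicleSpec:
    """One fascicular branch: root site and desired post-His delay."""

    name: str
    side: int                      # SIDE_LEFT or SIDE_RIGHT
    root_point: tuple              # heart-frame point near the root site
    delay_ms: float                # desired activation delay at the root
    surface: str                   # 'lv_endo' | 'rv_septal' | 'rv_freewall'


def default_fascicles() -> list:
    """Five-fascicle layout (LV anterior/septal/posterior, RV septal,
    RV moderator band) with delays calibrated for a sinus QRS near 85 ms.
    """
    return [
        FascicleSpec("lv_septal", SIDE_LEFT, (-22.0, 3.0, -30.0), 16.0, "lv_endo"),
        FascicleSpec("lv_anterior", SIDE_LEFT, (-3.0, 22.0, -32.0), 22.0, "lv_endo"),
        FascicleSpec("lv_posterior", SIDE_LEFT, (-3.0, -22.0, -32.0), 24.0, "lv_endo"),
        FascicleSpec("rv_septal", SIDE_RIGHT, (-30.0, 3.0, -30.0), 18.0, "rv_septal"),
        FascicleSpec("rv_moderator", SIDE_RIGHT, (-55.0, 5.0, -25.0), 24.0,
                     "rv_freewall"),
    ]


@dataclass(frozen=True)
class BranchConfig:
    """Fractal growth parameters of the Purkinje network."""

    mean_cable_mm: float = 6.0
    sd_cable_mm: float = 1.0
    min_cable_mm: float = 3.0
    max_cable_mm: float = 9.0
    repulsion_deg: float = 45.0
    repulsion_jitter_deg: float = 10.0
    collision_radius_mm: float = 2.0
    max_generations: int = 20
    step_mm: float = 1.0
    n_initial_branches: int = 6


@dataclass
class PurkinjeTree:
    """Geometric cable graph of the His-Purkinje system.

    Nodes in torso-frame mm; per-edge Euclidean length (mm), conduction
    velocity (m/s = mm/ms), side and kind codes.  ``his_node`` is node 0.
    PMJs couple leaf nodes to myocardial mesh nodes with asymmetric
    antegrade/retrograde delays.
    """

    nodes: np.ndarray
    edge_nodes: np.ndarray          # (E, 2) int
    edge_length: np.ndarray         # (E,) mm
    edge_cv: np.ndarray             # (E,) m/s
    edge_side: np.ndarray           # (E,) int8
    edge_kind: np.ndarray           # (E,) int8
    his_node: int = 0
    pmj_tree_nodes: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    pmj_mesh_nodes: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    pmj_sides: np.ndarray = field(default_factory=lambda: np.empty(0, np.int8))
    pmj_antegrade_ms: float = PMJ_ANTEGRADE_MS
    pmj_retrograde_ms: float = PMJ_RETROGRADE_MS
    #: pre-discretization cable lengths drawn by the generator (the 6 mm
    #: truncated-normal statistic); realized cables are shorter where
    #: growth stopped at a boundary or collision
    cable_lengths_mm: list = field(default_factory=list)
    realized_cable_lengths_mm: list = field(default_factory=list)
    fascicle_roots: dict = field(default_factory=dict)   # name -> node index
    fascicle_delays: dict = field(default_factory=dict)  # name -> desired ms
    terminal_edges: dict = field(default_factory=dict)   # name -> edge idx array
    blocked_side: int = SIDE_NONE
    segment_length_mm: float = SEGMENT_LENGTH_MM
    seed: int | None = None

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def conducting_edges(self) -> np.ndarray:
        """Edge mask excluding the blocked bundle-branch trunk."""
        mask = np.ones(len(self.edge_nodes), dtype=bool)
        if self.blocked_side != SIDE_NONE:
            mask &= ~((self.edge_side == self.blocked_side)
                      & (self.edge_kind == KIND_TRUNK))
        return mask

    def solve_times(self, sources) -> np.ndarray:
        """Multi-source shortest arrival times on the cable graph (ms)."""
        mask = self.conducting_edges()
        en = self.edge_nodes[mask]
        w = self.edge_length[mask] / self.edge_cv[mask]
        n = self.n_nodes
        virt = n
        src_i = np.array([int(s[0]) for s in sources], dtype=int)
        src_t = np.array([float(s[1]) for s in sources], dtype=float)
        rows = np.concatenate([en[:, 0], np.full(len(src_i), virt)])
        cols = np.concatenate([en[:, 1], src_i])
        vals = np.concatenate([w, src_t])
        A = coo_matrix((vals, (rows, cols)), shape=(n + 1, n + 1)).tocsr()
        t = dijkstra(A, directed=False, indices=virt)
        return t[:n]

    def to_json(self, path) -> None:
        obj = {
            "nodes": self.nodes.tolist(),
            "edges": [
                {"n": [int(a), int(b)], "length_mm": float(l),
                 "cv_m_per_s": float(c), "side": int(s), "kind": int(k)}
                for (a, b), l, c, s, k in zip(
                    self.edge_nodes, self.edge_length, self.edge_cv,
                    self.edge_side, self.edge_kind)
            ],
            "his_node": int(self.his_node),
            "pmjs": [
                {"tree_node": int(t), "mesh_node": int(m), "side": int(s),
                 "antegrade_ms": self.pmj_antegrade_ms,
                 "retrograde_ms": self.pmj_retrograde_ms}
                for t, m, s in zip(self.pmj_tree_nodes, self.pmj_mesh_nodes,
                                   self.pmj_sides)
            ],
            "fascicle_roots": {k: int(v) for k, v in self.fascicle_roots.items()},
            "fascicle_delays": self.fascicle_delays,
            "seed": self.seed,
        }
        with open(path, "w") as f:
            json.dump(obj, f)


# --------------------------------------------------------------------------
# growth
# --------------------------------------------------------------------------

class _TreeBuilder:
    def __init__(self):
        self.nodes = []
        self.edges = []  # (a, b, side, kind)
        self.cable_lengths = []      # drawn (nominal) cable lengths
        self.realized_lengths = []   # geometric lengths actually laid down
        self._hash = {}
        self._cell = 2.0

    def add_node(self, p) -> int:
        idx = len(self.nodes)
        self.nodes.append(np.asarray(p, float))
        key = tuple((np.asarray(p) // self._cell).astype(int))
        self._hash.setdefault(key, []).append(idx)
        return idx

    def add_edge(self, a, b, side, kind):
        self.edges.append((a, b, side, kind))

    def near(self, p, radius, newer_than=-1):
        """Any existing node within radius, ignoring indices > newer_than
        cut-off (own cable and immediate parent)."""
        c = (np.asarray(p) // self._cell).astype(int)
        r = int(np.ceil(radius / self._cell))
        for dx in range(-r, r + 1):
            for dy in range(-r, r + 1):
                for dz in range(-r, r + 1):
                    for idx in self._hash.get((c[0] + dx, c[1] + dy, c[2] + dz), ()):
                        if idx >= newer_than:
                            continue
                        if np.linalg.norm(self.nodes[idx] - p) < radius:
                            return True
        return False


def _surface_frame(geom, surface):
    project = {"lv_endo": geom.project_lv_endo,
               "rv_septal": geom.project_rv_septal,
               "rv_freewall": geom.project_rv_freewall}[surface]
    pred = {"lv_endo": geom.on_lv_endo,
            "rv_septal": geom.on_rv_septal,
            "rv_freewall": geom.on_rv_freewall}[surface]
    return project, pred


def _rotate_about(v, axis, angle):
    axis = axis / np.linalg.norm(axis)
    return (v * np.cos(angle) + np.cross(axis, v) * np.sin(angle)
            + axis * (axis @ v) * (1 - np.cos(angle)))


def _surface_normal(geom, surface, p):
    if surface == "lv_endo":
        center, axes = np.zeros(3), np.asarray(geom.config.lv_endo)
    elif surface == "rv_septal":
        center, axes = np.zeros(3), np.asarray(geom.config.lv_epi)
    else:
        center, axes = np.asarray(geom.config.rv_center), np.asarray(
            geom.config.rv_endo)
    n = (p - center) / axes ** 2
    return n / np.linalg.norm(n)


def _seed_fascicle(builder: _TreeBuilder, geom, surface, root_idx, root_pos,
                   cfg: BranchConfig, side, chamber, rng):
    """Initial branch directions fanning out of a fascicular root site."""
    n0 = _surface_normal(geom, surface, root_pos)
    seed_dir = np.array([0.0, 0.0, -1.0])
    seed_dir = seed_dir - (seed_dir @ n0) * n0
    if np.linalg.norm(seed_dir) < 1e-6:
        seed_dir = np.array([1.0, 0.0, 0.0]) - n0[0] * n0
    seed_dir /= np.linalg.norm(seed_dir)
    entries = []
    excl_from = len(builder.nodes)
    for k in range(cfg.n_initial_branches):
        ang = 2 * np.pi * k / cfg.n_initial_branches + rng.uniform(0, np.pi / 4)
        entries.append((root_idx, _rotate_about(seed_dir, n0, ang), 0,
                        surface, side, chamber, excl_from))
    return entries


def _grow_network(builder: _TreeBuilder, geom, queue, cfg: BranchConfig, rng):
    """Breadth-first fractal growth; all fascicles expand concurrently.

    Queue entries are (start_idx, direction, generation, surface, side,
    chamber); returns leaves as (node_idx, side, chamber).
    """
    from collections import deque

    leaves = []
    queue = deque(queue)
    while queue:
        (start_idx, direction, gen, surface, side, chamber,
         excl_from) = queue.popleft()
        project, pred = _surface_frame(geom, surface)
        pos = builder.nodes[start_idx].copy()
        length = float(np.clip(rng.normal(cfg.mean_cable_mm, cfg.sd_cable_mm),
                               cfg.min_cable_mm, cfg.max_cable_mm))
        cable_start_count = len(builder.nodes)
        prev = start_idx
        travelled = 0.0
        terminated = False
        while travelled < length:
            step = min(cfg.step_mm, length - travelled)
            nxt = project(pos + step * direction)[0]
            if not pred(nxt[None, :])[0]:
                terminated = True
                break
            # siblings diverge from the shared branch point: collision
            # checks begin only once the cable has cleared that zone; the
            # own and parent cables are excluded (excl_from cut-off)
            if (travelled + step > cfg.collision_radius_mm + 1.0
                ) and builder.near(nxt, cfg.collision_radius_mm,
                                   newer_than=excl_from):
                # steer away before giving up: try deflected headings
                blocked = True
                nrm = _surface_normal(geom, surface, pos)
                for ang in (30.0, -30.0, 60.0, -60.0, 90.0, -90.0,
                            120.0, -120.0):
                    cand_dir = _rotate_about(direction, nrm, np.deg2rad(ang))
                    cand = project(pos + step * cand_dir)[0]
                    if (pred(cand[None, :])[0]
                            and not builder.near(cand, cfg.collision_radius_mm,
                                                 newer_than=excl_from)):
                        nxt = cand
                        blocked = False
                        break
                if blocked:
                    terminated = True
                    break
            d = nxt - pos
            nd = np.linalg.norm(d)
            if nd < 0.2 * step:   # projection stall (surface pole)
                terminated = True
                break
            direction = d / nd
            idx = builder.add_node(nxt)
            builder.add_edge(prev, idx, side, KIND_FASCICLE)
            prev = idx
            pos = nxt
            travelled += nd
        if travelled > 0:
            # nominal drawn length is the generator statistic; realized
            # length is shorter when the cable hits a boundary/collision
            builder.cable_lengths.append(length)
            builder.realized_lengths.append(travelled)
        if terminated or gen + 1 >= cfg.max_generations:
            if prev != start_idx:
                leaves.append((prev, side, chamber))
            continue
        # branch: two children repelled by >= repulsion angle
        n = _surface_normal(geom, surface, pos)
        tang = direction - (direction @ n) * n
        if np.linalg.norm(tang) < 1e-6:
            leaves.append((prev, side, chamber))
            continue
        tang /= np.linalg.norm(tang)
        half = 0.5 * (cfg.repulsion_deg
                      + abs(rng.normal(0, cfg.repulsion_jitter_deg)))
        half = np.deg2rad(half)
        queue.append((prev, _rotate_about(tang, n, +half), gen + 1,
                      surface, side, chamber, cable_start_count))
        queue.append((prev, _rotate_about(tang, n, -half), gen + 1,
                      surface, side, chamber, cable_start_count))
    return leaves


def _trunk_path(builder: _TreeBuilder, geom, surface, start_idx, target_pos,
                cfg: BranchConfig, side):
    """Cable path from an existing node to a root site along a surface.

    The chord is sampled and projected onto the surface; the final cable
    (the last <= mean_cable_mm before the root) is returned separately as
    the tunable terminal cable.
    """
    project, _ = _surface_frame(geom, surface)
    p0 = builder.nodes[start_idx]
    target = project(target_pos)[0]
    chord = np.linalg.norm(target - p0)
    n_samp = max(int(np.ceil(chord / cfg.step_mm)), 2)
    ts = np.linspace(0, 1, n_samp + 1)[1:]
    pts = project(p0 + ts[:, None] * (target - p0))
    prev = start_idx
    edge_ids = []
    for p in pts:
        idx = builder.add_node(p)
        edge_ids.append(len(builder.edges))
        builder.add_edge(prev, idx, side, KIND_TRUNK)
        prev = idx
    # terminal cable: trailing edges covering ~ the last mean cable length
    lengths = [np.linalg.norm(builder.nodes[builder.edges[e][1]]
                              - builder.nodes[builder.edges[e][0]])
               for e in edge_ids]
    acc, term = 0.0, []
    for e, l in zip(reversed(edge_ids), reversed(lengths)):
        term.append(e)
        acc += l
        if acc >= cfg.mean_cable_mm:
            break
    n_cables = max(int(round(sum(lengths) / cfg.mean_cable_mm)), 1)
    builder.cable_lengths.extend([sum(lengths) / n_cables] * n_cables)
    builder.realized_lengths.extend([sum(lengths) / n_cables] * n_cables)
    return prev, sorted(term)


def grow_tree(heart: HeartModel, fascicles=None,
              branch_config: BranchConfig | None = None,
              seed: int = 0) -> PurkinjeTree:
    """Generate the full His-Purkinje tree with PMJ couplings.

    Seeded and deterministic for a given (heart, config, seed).  Leaves
    become PMJs mapped to the nearest endocardial myocardial node of the
    correct chamber; cables are discretized to <= 500 um segments.
    """
    fascicles = fascicles if fascicles is not None else default_fascicles()
    cfg = branch_config or BranchConfig()
    geom = heart.geom
    rng = np.random.default_rng(seed)

    builder = _TreeBuilder()
    his_idx = builder.add_node(geom.his_point)

    roots, delays, terminal = {}, {}, {}
    seeds = []
    rb_entry = None
    for spec in fascicles:
        root_pos = _surface_frame(geom, spec.surface)[0](
            np.asarray(spec.root_point, float))[0]
        if spec.surface == "lv_endo":
            start = his_idx
            prev, term = _trunk_path(builder, geom, spec.surface, start,
                                     root_pos, cfg, spec.side)
        else:
            if rb_entry is None:
                # His penetrates the septal crest to the RV septal surface
                entry_pos = geom.project_rv_septal(geom.his_point)[0]
                rb_entry = builder.add_node(entry_pos)
                builder.add_edge(his_idx, rb_entry, SIDE_RIGHT, KIND_TRUNK)
            if spec.surface == "rv_freewall":
                # moderator band: along the septum, then across the cavity
                mid_pos = geom.project_rv_septal(
                    np.array([-32.0, 6.0, -28.0]))[0]
                mid, _ = _trunk_path(builder, geom, "rv_septal", rb_entry,
                                     mid_pos, cfg, spec.side)
                idx = builder.add_node(root_pos)
                term = [len(builder.edges)]
                builder.add_edge(mid, idx, spec.side, KIND_TRUNK)
                mb_len = float(np.linalg.norm(root_pos - builder.nodes[mid]))
                builder.cable_lengths.append(mb_len)
                builder.realized_lengths.append(mb_len)
                prev = idx
            else:
                prev, term = _trunk_path(builder, geom, spec.surface, rb_entry,
                                         root_pos, cfg, spec.side)
        roots[spec.name] = prev
        delays[spec.name] = spec.delay_ms
        terminal[spec.name] = np.asarray(term, int)
        chamber = Tissue.LV if spec.side == SIDE_LEFT else Tissue.RV
        seeds.extend(_seed_fascicle(builder, geom, spec.surface, prev,
                                    builder.nodes[prev], cfg, spec.side,
                                    chamber, rng))

    leaf_info = _grow_network(builder, geom, seeds, cfg, rng)
    for spec in fascicles:
        if not any(li[1] == spec.side for li in leaf_info):
            raise ValueError(f"surface too small: fascicle {spec.name} "
                             "produced no cables")

    nodes_h = np.asarray(builder.nodes)
    edges = np.asarray([(a, b) for a, b, _, _ in builder.edges], int)
    side_arr = np.asarray([s for _, _, s, _ in builder.edges], np.int8)
    kind_arr = np.asarray([k for _, _, _, k in builder.edges], np.int8)

    # PMJ mapping: nearest endocardial tissue node of the right chamber
    nodes_t = geom.config.to_torso(nodes_h)
    pmj_tree, pmj_mesh, pmj_side = [], [], []
    mesh = heart.mesh
    for chamber in (Tissue.LV, Tissue.RV):
        cand = np.where((heart.coords.chamber == chamber)
                        & (heart.coords.t <= 0.35))[0]
        tree_kd = cKDTree(mesh.nodes[cand])
        for leaf, s, ch in leaf_info:
            if ch != chamber:
                continue
            _, j = tree_kd.query(nodes_t[leaf])
            pmj_tree.append(leaf)
            pmj_mesh.append(int(cand[j]))
            pmj_side.append(s)

    lengths = np.linalg.norm(nodes_h[edges[:, 1]] - nodes_h[edges[:, 0]],
                             axis=1)
    tree = PurkinjeTree(
        nodes=nodes_t,
        edge_nodes=edges,
        edge_length=lengths,
        edge_cv=np.full(len(edges), HPS_CV_M_PER_S),
        edge_side=side_arr,
        edge_kind=kind_arr,
        his_node=his_idx,
        pmj_tree_nodes=np.asarray(pmj_tree, int),
        pmj_mesh_nodes=np.asarray(pmj_mesh, int),
        pmj_sides=np.asarray(pmj_side, np.int8),
        cable_lengths_mm=list(builder.cable_lengths),
        realized_cable_lengths_mm=list(builder.realized_lengths),
        fascicle_roots=roots,
        fascicle_delays=delays,
        terminal_edges=terminal,
        seed=seed,
    )
    return _discretize(tree)


def _discretize(tree: PurkinjeTree) -> PurkinjeTree:
    """Split every edge into segments <= the prescribed 500 um."""
    seg = tree.segment_length_mm
    new_nodes = list(tree.nodes)
    en, el, ecv = [], [], []
    es, ek = [], []
    edge_map = {}  # old edge index -> new edge indices
    for e, ((a, b), l, cv, s, k) in enumerate(zip(
            tree.edge_nodes, tree.edge_length, tree.edge_cv,
            tree.edge_side, tree.edge_kind)):
        nseg = max(int(np.ceil(l / seg - 1e-9)), 1)
        pa, pb = tree.nodes[a], tree.nodes[b]
        prev = a
        ids = []
        for i in range(1, nseg + 1):
            if i == nseg:
                nxt = b
            else:
                nxt = len(new_nodes)
                new_nodes.append(pa + (pb - pa) * i / nseg)
            ids.append(len(en))
            en.append((prev, nxt))
            el.append(l / nseg)
            ecv.append(cv)
            es.append(s)
            ek.append(k)
            prev = nxt
        edge_map[e] = ids
    return replace(
        tree,
        nodes=np.asarray(new_nodes),
        edge_nodes=np.asarray(en, int),
        edge_length=np.asarray(el),
        edge_cv=np.asarray(ecv),
        edge_side=np.asarray(es, np.int8),
        edge_kind=np.asarray(ek, np.int8),
        terminal_edges={name: np.concatenate([edge_map[e] for e in idxs])
                        for name, idxs in tree.terminal_edges.items()},
    )


# --------------------------------------------------------------------------
# tuning and AV node
# --------------------------------------------------------------------------

def tune_terminal_cvs(tree: PurkinjeTree, base_cv: float = HPS_CV_M_PER_S,
                      tol_ms: float = 0.1) -> PurkinjeTree:
    """Tune the terminal cable preceding each fascicular root site.

    With all cables at ``base_cv``, the His-rooted activation map of the
    tree determines each root's untuned arrival; the terminal cable CV is
    then the cable's Euclidean length over the residual desired delay.
    Raises if a desired delay is not reachable (arrival at the cable head
    already exceeds it).
    """
    tree = replace(tree, edge_cv=np.full(len(tree.edge_nodes), base_cv))
    t0 = tree.solve_times([(tree.his_node, 0.0)])
    cv = tree.edge_cv.copy()
    for name, root in tree.fascicle_roots.items():
        want = tree.fascicle_delays[name]
        eids = tree.terminal_edges[name]
        cable_len = tree.edge_length[eids].sum()
        heads = set(tree.edge_nodes[eids].ravel())
        # cable head: the node of the terminal cable closest to the His
        head = min(heads, key=lambda n: t0[n])
        residual = want - t0[head]
        if residual <= 0:
            raise ValueError(
                f"fascicle {name}: desired delay {want} ms <= upstream "
                f"arrival {t0[head]:.2f} ms (infeasible tuning)")
        cv[eids] = cable_len / residual
    tuned = replace(tree, edge_cv=cv)
    t1 = tuned.solve_times([(tuned.his_node, 0.0)])
    for name, root in tuned.fascicle_roots.items():
        err = abs(t1[root] - tuned.fascicle_delays[name])
        if err > tol_ms:
            raise RuntimeError(f"fascicle {name} tuning residual {err:.3f} ms")
    return tuned


def inhibit_branch(tree: PurkinjeTree, side: str) -> PurkinjeTree:
    """Complete block of the proximal left/right bundle branch.

    Trunk edges of the named side become non-conducting in both
    directions; the distal fascicular network remains excitable
    retrogradely through its PMJs.  ``side='none'`` returns the tree
    unchanged.
    """
    code = {"none": SIDE_NONE, "left": SIDE_LEFT, "right": SIDE_RIGHT}[side]
    return replace(tree, blocked_side=code)


@dataclass
class AVNode:
    """Topologically simple 1-D AV-node cable (atrial anchor to His)."""

    length_mm: float = 8.0
    cv_m_per_s: float = 0.07
    attach_mesh_node: int = -1

    @property
    def transit_ms(self) -> float:
        return self.length_mm / self.cv_m_per_s


@dataclass
class ConductionSystem:
    """Purkinje tree + AV node, coupled to a myocardial mesh.

    Provides the two half-steps of the bidirectional fixed-point coupling
    used by :func:`vheart.activation.solve_coupled`.
    """

    tree: PurkinjeTree
    avn: AVNode

    def solve_tree(self, myocardial_at: np.ndarray) -> np.ndarray:
        """Tree arrival times given current myocardial activation."""
        sources = []
        a_at = myocardial_at[self.avn.attach_mesh_node]
        if np.isfinite(a_at):
            sources.append((self.tree.his_node, a_at + self.avn.transit_ms))
        retro = myocardial_at[self.tree.pmj_mesh_nodes]
        fin = np.isfinite(retro)
        for leaf, t in zip(self.tree.pmj_tree_nodes[fin], retro[fin]):
            sources.append((int(leaf), float(t + self.tree.pmj_retrograde_ms)))
        if not sources:
            return np.full(self.tree.n_nodes, np.inf)
        return self.tree.solve_times(sources)

    def myocardial_sources(self, tree_at: np.ndarray) -> list:
        """Antegrade PMJ sources plus retrograde AVN exit into the atria."""
        out = []
        t_leaf = tree_at[self.tree.pmj_tree_nodes]
        fin = np.isfinite(t_leaf)
        for m, t in zip(self.tree.pmj_mesh_nodes[fin], t_leaf[fin]):
            out.append((int(m), float(t + self.tree.pmj_antegrade_ms)))
        t_his = tree_at[self.tree.his_node]
        if np.isfinite(t_his) and self.avn.attach_mesh_node >= 0:
            out.append((int(self.avn.attach_mesh_node),
                        float(t_his + self.avn.transit_ms)))
        return out

    def with_avn_cv(self, cv: float) -> "ConductionSystem":
        return ConductionSystem(tree=self.tree,
                                avn=replace(self.avn, cv_m_per_s=cv))

    def with_block(self, side: str) -> "ConductionSystem":
        return ConductionSystem(tree=inhibit_branch(self.tree, side),
                                avn=self.avn)


def attach_avn(tree: PurkinjeTree, heart: HeartModel,
               length_mm: float = 8.0,
               cv_m_per_s: float = 0.07) -> ConductionSystem:
    """Couple the tree to the basal RA through the AV-node cable."""
    avn = AVNode(length_mm=length_mm, cv_m_per_s=cv_m_per_s,
                 attach_mesh_node=heart.avn_attach_node)
    return ConductionSystem(tree=tree, avn=avn)


def tune_avn_cv(evaluate_pr, avn_length_mm: float, target_pr_ms: float,
                bracket=(0.01, 1.0), tol_ms: float = 1.0,
                initial_cv: float = 0.07, max_iter: int = 60):
    """Tune the AV-node CV so the simulated PR interval hits the target.

    ``evaluate_pr(cv)`` must run the sinus simulation and return the
    measured PR in ms.  Because the AVN is a 1-D cable, changing its CV
    rigidly shifts every ventricular event by ``L/cv - L/cv0``; bisection
    therefore runs on the exact shift identity anchored at one measured
    PR, followed by measured-PR secant corrections until |PR - target| <=
    ``tol_ms``.  Raises if the target lies outside the achievable range.

    Returns (cv, achieved_pr_ms).
    """
    lo, hi = bracket
    pr0 = evaluate_pr(initial_cv)

    def predict(cv):
        return pr0 + avn_length_mm / cv - avn_length_mm / initial_cv

    pr_min, pr_max = predict(hi), predict(lo)
    if not (pr_min - tol_ms <= target_pr_ms <= pr_max + tol_ms):
        raise ValueError(
            f"target PR {target_pr_ms} ms unreachable: achievable range "
            f"[{pr_min:.1f}, {pr_max:.1f}] ms for cv in [{hi}, {lo}] m/s")

    a, b = lo, hi
    for _ in range(max_iter):
        mid = 0.5 * (a + b)
        if predict(mid) > target_pr_ms:
            a = mid
        else:
            b = mid
        if abs(predict(mid) - target_pr_ms) < 0.25 * tol_ms:
            break
    cv = 0.5 * (a + b)

    pr = evaluate_pr(cv)
    for _ in range(8):
        if abs(pr - target_pr_ms) <= tol_ms:
            return cv, pr
        # exact cable identity correction on the measured PR
        inv = 1.0 / cv + (target_pr_ms - pr) / avn_length_mm
        if inv <= 0:
            raise ValueError("target PR unreachable during correction")
        cv = 1.0 / inv
        if not (bracket[0] <= cv <= bracket[1]):
            raise ValueError(
                f"target PR {target_pr_ms} ms drives AVN CV outside "
                f"bracket {bracket}")
        pr = evaluate_pr(cv)
    raise RuntimeError(f"AVN tuning did not converge (PR={pr:.2f} ms)")
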