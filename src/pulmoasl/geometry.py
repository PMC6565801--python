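"""Synthetic pulmonary vascular network generation and I/O.

A right-lung-like half-ellipsoid domain is filled with paired arterial and
venous trees grown by volume-filling branching: uniformly sampled terminal
seed points are recursively bisected through their centre of mass and a
branch is extended from the parent tip toward each sub-cloud centroid.  Each
arterial terminal is coupled to the spatially nearest venous terminal via an
arteriole -> capillary-sheet -> venule unit.  Large conduit vessels are
thereby concentrated near the hilum on the medial face, and capillary units
fill the periphery -- the spatial pattern that makes medial image slices
conduit-dominated and lateral slices perfusion-dominated.

Coordinate frame (right-handed, mm):
    x: lateral (-) -> medial (+); the flat medial face of the half-ellipsoid
       is the plane x = 0, so the domain occupies x in [-a, 0].
    y: dorsal (-) -> ventral (+).
    z: caudal (-) -> cranial (+).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

ELEMENT_TYPES = ("artery", "arteriole", "capillary", "venule", "vein")

#: allowed downstream successor types along an inlet->outlet path
_TYPE_SUCCESSORS = {
    "artery": {"artery", "arteriole"},
    "arteriole": {"capillary"},
    "capillary": {"venule"},
    "venule": {"vein"},
    "vein": {"vein"},
}

AXIS_LABELS = {"x": "lateral(-)->medial(+)", "y": "dorsal(-)->ventral(+)", "z": "caudal(-)->cranial(+)"}


class NetworkValidationError(ValueError):
    """Raised when a network table violates a structural invariant."""


@dataclass(frozen=True)
class DomainShape:
    """Half-ellipsoid right-lung-like domain.

    Parameters
    ----------
    semi_axes : (a, b, c) in mm.  The domain is the set of points with
        (x/a)^2 + (y/b)^2 + (z/c)^2 <= 1 and x <= 0; the flat medial face
        sits at x = 0.
    hilum : entry/exit point of the pulmonary trunk and veins; must lie on
        the medial face.  The default is displaced dorsally, mirroring the
        posterior position of the lung root in the chest -- this structural
        dorsal advantage is what makes supine perfusion more heterogeneous
        than prone.
    """

    semi_axes: tuple[float, float, float] = (75.0, 75.0, 110.0)
    hilum: tuple[float, float, float] = (0.0, -22.5, 0.0)

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.semi_axes):
            raise ValueError(f"semi-axes must be positive, got {self.semi_axes}")
        hx, hy, hz = self.hilum
        _, b, c = self.semi_axes
        if abs(hx) > 1e-9:
            raise ValueError("hilum must lie on the medial face x = 0")
        if (hy / b) ** 2 + (hz / c) ** 2 > 1.0 + 1e-9:
            raise ValueError("hilum lies outside the medial face of the domain")

    def contains(self, points: np.ndarray, tol: float = 1e-9) -> np.ndarray:
        """Boolean mask of points inside or on the domain boundary."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        a, b, c = self.semi_axes
        q = (pts[:, 0] / a) ** 2 + (pts[:, 1] / b) ** 2 + (pts[:, 2] / c) ** 2
        return (q <= 1.0 + tol) & (pts[:, 0] <= tol)

    @property
    def lateral_extent(self) -> tuple[float, float]:
        """(x_min, x_max) of the domain along the lateral-medial axis."""
        return (-self.semi_axes[0], 0.0)


@dataclass(frozen=True)
class GeometryConfig:
    """Parameters of the volume-filling tree generator."""

    n_terminals: int = 1000
    seed: int = 0
    murray_exponent: float = 3.0
    terminal_radius_mm: float = 0.1
    trunk_radius_mm: float | None = 15.0
    length_fraction: float = 0.4
    min_branch_length_mm: float = 2.0
    capillary_radius_mm: float = 0.05
    coupling_offset_mm: float = 1.0
    # gravity-independent structural preference for the dorsal lung:
    # terminal-unit density rises linearly toward the dorsal face, as in
    # real lungs where dorsal tissue and vascular density are higher.
    # This is what flattens prone perfusion instead of mirroring supine.
    dorsal_density_bias: float = 0.35

    def __post_init__(self) -> None:
        if self.n_terminals < 1:
            raise ValueError("n_terminals must be >= 1")
        if self.murray_exponent <= 0:
            raise ValueError("Murray exponent must be > 0")
        if self.terminal_radius_mm <= 0 or self.min_branch_length_mm <= 0:
            raise ValueError("radii and lengths must be positive")


@dataclass
class VascularNetwork:
    """Typed node/element graph with geometry.

    ``nodes``:    columns (id, x_mm, y_mm, z_mm), id unique.
    ``elements``: columns (id, node_in, node_out, type, radius0_mm,
                  length_mm), directed in the direction of flow.
    """

    nodes: pd.DataFrame
    elements: pd.DataFrame
    inlet_element: int
    outlet_element: int
    n_terminals: int
    domain: DomainShape | None = None

    # -- convenience accessors -------------------------------------------
    def node_positions(self) -> pd.DataFrame:
        return self.nodes.set_index("id")[["x_mm", "y_mm", "z_mm"]]

    def elements_of_type(self, *types: str) -> pd.DataFrame:
        return self.elements[self.elements["type"].isin(types)]

    def validate(self) -> None:
        """Check all structural invariants; raise NetworkValidationError."""
        nodes, els = self.nodes, self.elements
        if nodes["id"].duplicated().any():
            dup = nodes.loc[nodes["id"].duplicated(), "id"].iloc[0]
            raise NetworkValidationError(f"duplicated node id {dup}")
        if els["id"].duplicated().any():
            dup = els.loc[els["id"].duplicated(), "id"].iloc[0]
            raise NetworkValidationError(f"duplicated element id {dup}")
        bad_type = ~els["type"].isin(ELEMENT_TYPES)
        if bad_type.any():
            row = els[bad_type].iloc[0]
            raise NetworkValidationError(
                f"element id {row['id']}: unknown type {row['type']!r}"
            )
        node_ids = set(nodes["id"])
        for col in ("node_in", "node_out"):
            missing = ~els[col].isin(node_ids)
            if missing.any():
                row = els[missing].iloc[0]
                raise NetworkValidationError(
                    f"element id {row['id']}: {col}={row[col]} is not a node"
                )
        if (els["length_mm"] <= 0).any() or (els["radius0_mm"] <= 0).any():
            row = els[(els["length_mm"] <= 0) | (els["radius0_mm"] <= 0)].iloc[0]
            raise NetworkValidationError(
                f"element id {row['id']}: non-positive length or radius"
            )
        if self.inlet_element not in set(els["id"]):
            raise NetworkValidationError("inlet element id not in element table")
        if self.outlet_element not in set(els["id"]):
            raise NetworkValidationError("outlet element id not in element table")

        # type transitions along flow direction
        etype = dict(zip(els["id"], els["type"]))
        out_of = {}
        for eid, nin in zip(els["id"], els["node_in"]):
            out_of.setdefault(nin, []).append(eid)
        for eid, nout, t in zip(els["id"], els["node_out"], els["type"]):
            for succ in out_of.get(nout, []):
                if etype[succ] not in _TYPE_SUCCESSORS[t]:
                    raise NetworkValidationError(
                        f"element {eid} ({t}) feeds element {succ} "
                        f"({etype[succ]}): illegal type transition"
                    )
        # capillary elements: exactly one arteriole parent, one venule child
        in_of = {}
        for eid, nout in zip(els["id"], els["node_out"]):
            in_of.setdefault(nout, []).append(eid)
        for eid, nin, nout in zip(els["id"], els["node_in"], els["node_out"]):
            if etype[eid] != "capillary":
                continue
            parents = in_of.get(nin, [])
            children = out_of.get(nout, [])
            if len(parents) != 1 or etype[parents[0]] != "arteriole":
                raise NetworkValidationError(
                    f"capillary element {eid} must have exactly one arteriole parent"
                )
            if len(children) != 1 or etype[children[0]] != "venule":
                raise NetworkValidationError(
                    f"capillary element {eid} must have exactly one venule child"
                )
        # connectivity (undirected)
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(nodes["id"])
        g.add_edges_from(zip(els["node_in"], els["node_out"]))
        if nodes.shape[0] and nx.number_connected_components(g) != 1:
            raise NetworkValidationError("network graph is not connected")
        # arterial / venous subgraphs acyclic
        for types, label in ((("artery", "arteriole"), "arterial"),
                             (("vein", "venule"), "venous")):
            sub = els[els["type"].isin(types)]
            sg = nx.DiGraph()
            sg.add_edges_from(zip(sub["node_in"], sub["node_out"]))
            if not nx.is_directed_acyclic_graph(sg):
                raise NetworkValidationError(f"{label} subgraph contains a cycle")

    def equals(self, other: "VascularNetwork") -> bool:
        return (
            self.nodes.reset_index(drop=True).equals(other.nodes.reset_index(drop=True))
            and self.elements.reset_index(drop=True).equals(
                other.elements.reset_index(drop=True)
            )
            and self.inlet_element == other.inlet_element
            and self.outlet_element == other.outlet_element
        )


# ---------------------------------------------------------------------------
# volume-filling branching
# ---------------------------------------------------------------------------

def _sample_points(domain: DomainShape, n: int, rng: np.random.Generator,
                   dorsal_bias: float = 0.0) -> np.ndarray:
    """Points inside the half-ellipsoid by rejection sampling; density rises
    linearly toward the dorsal (-y) face by ``dorsal_bias``."""
    a, b, c = domain.semi_axes
    pts = np.empty((0, 3))
    while pts.shape[0] < n:
        cand = rng.uniform([-a, -b, -c], [0.0, b, c], size=(4 * n, 3))
        keep = domain.contains(cand)
        if dorsal_bias > 0:
            w = (1.0 - dorsal_bias * cand[:, 1] / b) / (1.0 + dorsal_bias)
            keep &= rng.uniform(size=cand.shape[0]) < w
        pts = np.vstack([pts, cand[keep]])
    return pts[:n]


def _clamp_into_domain(tip: np.ndarray, target: np.ndarray, domain: DomainShape) -> np.ndarray:
    """Shrink the step tip->target so the endpoint stays inside the domain."""
    if domain.contains(target[None])[0]:
        return target
    lo, hi = 0.0, 1.0
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if domain.contains((tip + mid * (target - tip))[None])[0]:
            lo = mid
        else:
            hi = mid
    return tip + lo * (target - tip)


def _bisect_cloud(points: np.ndarray, idxs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split a point cloud in two by the plane through its centre of mass
    perpendicular to its principal axis.  Points exactly on the plane go to
    the negative side; ties in degenerate clouds are broken by lowest point
    index (stable sort)."""
    pts = points[idxs]
    centred = pts - pts.mean(axis=0)
    cov = centred.T @ centred
    w, v = np.linalg.eigh(cov)
    axis = v[:, -1]
    nz = np.flatnonzero(np.abs(axis) > 1e-12)
    if nz.size and axis[nz[0]] < 0:  # deterministic sign
        axis = -axis
    proj = centred @ axis
    neg = idxs[proj <= 0]
    pos = idxs[proj > 0]
    if neg.size == 0 or pos.size == 0:
        order = idxs[np.argsort(proj, kind="stable")]
        half = order.size // 2
        neg, pos = order[:half], order[half:]
    return neg, pos


class _TreeBuilder:
    def __init__(self, domain: DomainShape, cfg: GeometryConfig):
        self.domain = domain
        self.cfg = cfg
        self.node_xyz: list[np.ndarray] = []
        self.edges: list[tuple[int, int]] = []  # (node_in, node_out)
        self.terminal_nodes: dict[int, int] = {}  # point index -> node id

    def add_node(self, xyz: np.ndarray) -> int:
        self.node_xyz.append(np.asarray(xyz, dtype=float))
        return len(self.node_xyz) - 1

    def grow(self, root_xyz: np.ndarray, points: np.ndarray) -> int:
        """Grow the tree; returns the root node index."""
        root = self.add_node(root_xyz)
        all_idx = np.arange(points.shape[0])
        if all_idx.size == 1:
            self._terminal_branch(root, points, all_idx[0])
            return root
        # trunk toward the full-cloud centroid
        tip = self._branch_toward(root, points[all_idx].mean(axis=0))
        self._recurse(tip, points, all_idx)
        return root

    def _branch_toward(self, parent: int, target: np.ndarray) -> int:
        tip = self.node_xyz[parent]
        d = target - tip
        dist = float(np.linalg.norm(d))
        if dist < 1e-12:
            end = tip + np.array([0.0, 0.0, self.cfg.min_branch_length_mm])
        else:
            length = max(self.cfg.length_fraction * dist, self.cfg.min_branch_length_mm)
            end = tip + (length / dist) * d
        end = _clamp_into_domain(tip, end, self.domain)
        node = self.add_node(end)
        self.edges.append((parent, node))
        return node

    def _terminal_branch(self, parent: int, points: np.ndarray, pidx: int) -> None:
        node = self.add_node(points[pidx])
        self.edges.append((parent, node))
        self.terminal_nodes[int(pidx)] = node

    def _recurse(self, parent: int, points: np.ndarray, idxs: np.ndarray) -> None:
        stack = [(parent, idxs)]
        while stack:
            par, cloud = stack.pop()
            neg, pos = _bisect_cloud(points, cloud)
            for sub in (neg, pos):
                if sub.size == 1:
                    self._terminal_branch(par, points, sub[0])
                else:
                    tip = self._branch_toward(par, points[sub].mean(axis=0))
                    stack.append((tip, sub))


def generate_network(
    domain: DomainShape, config: GeometryConfig, seed: int | None = None
) -> VascularNetwork:
    """Generate a paired arterial/venous network by volume-filling branching.

    ``seed`` overrides ``config.seed`` when given; all randomness (the
    terminal seed-point sample) is fixed by it.  The returned network
    satisfies every structural invariant checked by
    :meth:`VascularNetwork.validate` and has radii already assigned via
    :func:`assign_radii`.
    """
    if seed is None:
        seed = config.seed
    if any(s <= config.min_branch_length_mm for s in domain.semi_axes):
        raise ValueError(
            f"degenerate domain: semi-axes {domain.semi_axes} must all exceed "
            f"the minimum branch length {config.min_branch_length_mm} mm"
        )
    rng = np.random.default_rng(seed)
    points = _sample_points(domain, config.n_terminals, rng,
                            config.dorsal_density_bias)
    hilum = np.asarray(domain.hilum, dtype=float)

    art = _TreeBuilder(domain, config)
    art.grow(hilum, points)
    ven = _TreeBuilder(domain, config)
    # venous root offset slightly ventral of the arterial root on the face
    ven_root = _clamp_into_domain(hilum, hilum + np.array([0.0, 4.0, 0.0]), domain)
    ven_root[0] = 0.0
    ven.grow(ven_root, points)

    # nearest-terminal coupling (arterial terminal k -> closest venous terminal)
    ven_term_pidx = sorted(ven.terminal_nodes)
    ven_term_xyz = np.array([ven.node_xyz[ven.terminal_nodes[i]] for i in ven_term_pidx])
    tree = cKDTree(ven_term_xyz)

    node_rows: list[tuple[int, float, float, float]] = []
    el_rows: list[tuple[int, int, int, str, float, float]] = []
    next_node = 0
    next_el = 0

    def emit_nodes(builder: _TreeBuilder) -> dict[int, int]:
        nonlocal next_node
        remap = {}
        for i, xyz in enumerate(builder.node_xyz):
            remap[i] = next_node
            node_rows.append((next_node, float(xyz[0]), float(xyz[1]), float(xyz[2])))
            next_node += 1
        return remap

    art_map = emit_nodes(art)
    ven_map = emit_nodes(ven)

    def emit_edges(builder: _TreeBuilder, remap: dict[int, int], etype: str,
                   reverse: bool) -> list[int]:
        nonlocal next_el
        ids = []
        for a, b in builder.edges:
            n_in, n_out = (remap[b], remap[a]) if reverse else (remap[a], remap[b])
            pa, pb = builder.node_xyz[a], builder.node_xyz[b]
            length = max(float(np.linalg.norm(pb - pa)), 1e-6)
            el_rows.append((next_el, n_in, n_out, etype, 1.0, length))
            ids.append(next_el)
            next_el += 1
        return ids

    art_ids = emit_edges(art, art_map, "artery", reverse=False)
    # venous tree: flow runs terminal -> root, so reverse edge direction
    ven_ids = emit_edges(ven, ven_map, "vein", reverse=True)
    inlet_element = art_ids[0]
    outlet_element = ven_ids[0]

    # terminal coupling units
    off = config.coupling_offset_mm
    for pidx in sorted(art.terminal_nodes):
        a_node = art_map[art.terminal_nodes[pidx]]
        p = points[pidx]
        _, j = tree.query(p)
        v_node = ven_map[ven.terminal_nodes[ven_term_pidx[int(j)]]]
        u = hilum - p
        nu = float(np.linalg.norm(u))
        u = u / nu if nu > 1e-9 else np.array([0.0, 0.0, 1.0])
        c1 = p + off * u
        c2 = p + 2.0 * off * u
        n1 = next_node
        node_rows.append((n1, float(c1[0]), float(c1[1]), float(c1[2])))
        n2 = next_node + 1
        node_rows.append((n2, float(c2[0]), float(c2[1]), float(c2[2])))
        next_node += 2
        for n_in, n_out, etype, length in (
            (a_node, n1, "arteriole", off),
            (n1, n2, "capillary", off),
            (n2, v_node, "venule", off),
        ):
            el_rows.append((next_el, n_in, n_out, etype, 1.0, float(length)))
            next_el += 1

    nodes = pd.DataFrame(node_rows, columns=["id", "x_mm", "y_mm", "z_mm"])
    elements = pd.DataFrame(
        el_rows, columns=["id", "node_in", "node_out", "type", "radius0_mm", "length_mm"]
    )
    net = VascularNetwork(
        nodes=nodes,
        elements=elements,
        inlet_element=inlet_element,
        outlet_element=outlet_element,
        n_terminals=config.n_terminals,
        domain=domain,
    )
    net = assign_radii(net, config)
    net.validate()
    return net


# ---------------------------------------------------------------------------
# radii
# ---------------------------------------------------------------------------

def assign_radii(network: VascularNetwork, config: GeometryConfig) -> VascularNetwork:
    """Assign radii: terminal arterioles/venules get the configured terminal
    radius, conduit radii follow Murray's law r_parent^k = sum r_child^k
    propagated root-ward, capillaries get a nominal sheet radius, and the
    trunk (inlet element) radius is optionally overridden."""
    els = network.elements.copy()
    k = config.murray_exponent
    etype = els["type"].to_numpy()
    radius = np.ones(len(els))
    radius[np.isin(etype, ["arteriole", "venule"])] = config.terminal_radius_mm
    radius[etype == "capillary"] = config.capillary_radius_mm

    ids = els["id"].to_numpy()
    node_in = els["node_in"].to_numpy()
    node_out = els["node_out"].to_numpy()
    idx_of = {int(e): i for i, e in enumerate(ids)}

    for conduit, feeder_terminal in (("artery", "arteriole"), ("vein", "venule")):
        # Murray "children" of a conduit element are the peripheral elements
        # it feeds (arterial side: leave its downstream node) or that feed
        # it (venous side: tributaries entering its upstream node).
        key_node: dict[int, list[int]] = {}
        for i in range(len(els)):
            if etype[i] in (conduit, feeder_terminal):
                key = int(node_in[i]) if conduit == "artery" else int(node_out[i])
                key_node.setdefault(key, []).append(i)
        sel = np.flatnonzero(etype == conduit)
        if conduit == "artery":
            children = {int(i): key_node.get(int(node_out[i]), []) for i in sel}
            central_nodes = {int(node_out[i]) for i in sel}
            roots = [int(i) for i in sel if int(node_in[i]) not in central_nodes]
        else:
            children = {int(i): key_node.get(int(node_in[i]), []) for i in sel}
            central_nodes = {int(node_in[i]) for i in sel}
            roots = [int(i) for i in sel if int(node_out[i]) not in central_nodes]
        # process leaf-ward elements first via iterative postorder
        order: list[int] = []
        visited: set[int] = set()
        # simple iterative postorder
        stack = [(int(i), False) for i in roots]
        while stack:
            i, done = stack.pop()
            if done:
                order.append(i)
                continue
            if i in visited:
                continue
            visited.add(i)
            stack.append((i, True))
            for j in children.get(i, []):
                if etype[j] == conduit:
                    stack.append((int(j), False))
        for i in order:
            kids = children.get(i, [])
            if kids:
                radius[i] = float(np.sum(radius[kids] ** k) ** (1.0 / k))

    if config.trunk_radius_mm is not None:
        i = idx_of[int(network.inlet_element)]
        radius[i] = max(radius[i], config.trunk_radius_mm)
        j = idx_of[int(network.outlet_element)]
        radius[j] = max(radius[j], config.trunk_radius_mm)

    els["radius0_mm"] = radius
    return replace_elements(network, els)


def replace_elements(network: VascularNetwork, elements: pd.DataFrame) -> VascularNetwork:
    return VascularNetwork(
        nodes=network.nodes,
        elements=elements,
        inlet_element=network.inlet_element,
        outlet_element=network.outlet_element,
        n_terminals=network.n_terminals,
        domain=network.domain,
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_network(network: VascularNetwork, path: str | Path) -> None:
    """Write nodes.csv, elements.csv and header.json to a directory."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    # %.17g guarantees float64 round-trip through the text format
    network.nodes.to_csv(path / "nodes.csv", index=False, float_format="%.17g")
    network.elements.to_csv(path / "elements.csv", index=False, float_format="%.17g")
    header = {
        "inlet_element": int(network.inlet_element),
        "outlet_element": int(network.outlet_element),
        "n_terminals": int(network.n_terminals),
        "axes": AXIS_LABELS,
        "units": "mm",
    }
    if network.domain is not None:
        header["domain"] = {
            "semi_axes_mm": list(network.domain.semi_axes),
            "hilum_mm": list(network.domain.hilum),
        }
    (path / "header.json").write_text(json.dumps(header, indent=2))


def read_network(path: str | Path) -> VascularNetwork:
    """Read a network directory written by :func:`write_network`.

    Malformed tables are rejected with row-level diagnostics.
    """
    path = Path(path)
    for fname in ("nodes.csv", "elements.csv", "header.json"):
        if not (path / fname).exists():
            raise FileNotFoundError(f"missing network file: {path / fname}")
    nodes = pd.read_csv(path / "nodes.csv", float_precision="round_trip")
    elements = pd.read_csv(path / "elements.csv", float_precision="round_trip")
    header = json.loads((path / "header.json").read_text())
    domain = None
    if "domain" in header:
        domain = DomainShape(
            semi_axes=tuple(header["domain"]["semi_axes_mm"]),
            hilum=tuple(header["domain"]["hilum_mm"]),
        )
    net = VascularNetwork(
        nodes=nodes,
        elements=elements,
        inlet_element=int(header["inlet_element"]),
        outlet_element=int(header["outlet_element"]),
        n_terminals=int(header.get("n_terminals", 0)),
        domain=domain,
    )
    net.validate()
    return net
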