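"""Neuronal morphologies: SWC I/O, synthetic generation and discretization.

A :class:`Morphology` is the raw point-and-diameter tree read from (or written
to) a standard 7-column SWC file.  A :class:`SegmentedCell` is its
compartmentalized counterpart: an ordered list of cylindrical compartments with
membrane areas and soma-centered path distances, the substrate every simulation
in this package runs on.

The synthetic generator produces branched PVI-like (fast-spiking interneuron)
and GC-like (granule cell) trees whose dendritic diameters are calibrated so
that, under the default passive parameter sets, the somatic input resistance
matches the in vitro targets (PVI ~101.5 MOhm, GC ~308.7 MOhm).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import IntEnum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Structure",
    "SwcNode",
    "Morphology",
    "SWCParseError",
    "MorphologyError",
    "CalibrationError",
    "GeometryParams",
    "read_swc",
    "write_swc",
    "path_distance",
    "generate_synthetic_morphology",
    "discretize",
    "MaxSegLength",
    "LambdaRule",
    "SegmentedCell",
]


class Structure(IntEnum):
    """SWC structure identifiers (types 3 and 4 both map to DENDRITE)."""

    SOMA = 1
    AXON = 2
    DENDRITE = 3


_SWC_TYPE_MAP = {1: Structure.SOMA, 2: Structure.AXON,
                 3: Structure.DENDRITE, 4: Structure.DENDRITE}


class SWCParseError(ValueError):
    """Malformed SWC content; carries the 1-based line number."""


class MorphologyError(ValueError):
    """Structural invariant violation (cycles, orphans, bad radii...)."""


class CalibrationError(RuntimeError):
    """Input-resistance calibration did not converge."""

    def __init__(self, message: str, achieved_rin_mohm: float):
        super().__init__(f"{message} (achieved R_in = {achieved_rin_mohm:.1f} MOhm)")
        self.achieved_rin_mohm = achieved_rin_mohm


@dataclass(frozen=True)
class SwcNode:
    """One SWC sample point.  Coordinates and radius in micrometres."""

    id: int
    structure: Structure
    x: float
    y: float
    z: float
    radius: float
    parent_id: int | None


class Morphology:
    """A validated neuronal tree of SWC sample points.

    Nodes are stored in topological order (root first, every parent before its
    children) regardless of the order they were supplied in.  Invariants
    enforced at construction: exactly one root, tree topology (no cycles,
    every parent exists), all radii > 0, at least one dendrite node.
    """

    def __init__(self, nodes: Iterable[SwcNode]):
        nodes = list(nodes)
        if not nodes:
            raise MorphologyError("empty morphology")
        by_id: dict[int, SwcNode] = {}
        for nd in nodes:
            if nd.id in by_id:
                raise MorphologyError(f"duplicate node id {nd.id}")
            if not nd.radius > 0:
                raise MorphologyError(f"node {nd.id} has non-positive radius")
            by_id[nd.id] = nd
        roots = [nd for nd in nodes if nd.parent_id is None]
        if len(roots) != 1:
            raise MorphologyError(f"expected exactly one root, found {len(roots)}")
        children: dict[int, list[int]] = {nd.id: [] for nd in nodes}
        for nd in nodes:
            if nd.parent_id is not None:
                if nd.parent_id not in by_id:
                    raise MorphologyError(
                        f"node {nd.id} references missing parent {nd.parent_id}")
                children[nd.parent_id].append(nd.id)
        # topological order by iterative DFS; anything unreached sits on a cycle
        order: list[SwcNode] = []
        stack = [roots[0].id]
        seen: set[int] = set()
        while stack:
            nid = stack.pop()
            if nid in seen:  # pragma: no cover - defensive, cycles caught below
                raise MorphologyError(f"cycle through node {nid}")
            seen.add(nid)
            order.append(by_id[nid])
            stack.extend(reversed(children[nid]))
        if len(order) != len(nodes):
            raise MorphologyError("graph is not a tree (cycle or disconnected nodes)")
        if not any(nd.structure == Structure.DENDRITE for nd in nodes):
            raise MorphologyError("morphology has no dendrite nodes")
        self._nodes = order
        self._by_id = by_id
        self._children = children
        self._pathdist: dict[int, float] = {}
        for nd in order:
            if nd.parent_id is None:
                self._pathdist[nd.id] = 0.0
            else:
                self._pathdist[nd.id] = (
                    self._pathdist[nd.parent_id] + self.edge_length(nd.id))

    @property
    def nodes(self) -> list[SwcNode]:
        return list(self._nodes)

    @property
    def root(self) -> SwcNode:
        return self._nodes[0]

    @property
    def n_nodes(self) -> int:
        return len(self._nodes)

    def node(self, node_id: int) -> SwcNode:
        try:
            return self._by_id[node_id]
        except KeyError:
            raise KeyError(f"unknown node id {node_id}") from None

    def children(self, node_id: int) -> list[SwcNode]:
        return [self._by_id[c] for c in self._children[node_id]]

    def edge_length(self, node_id: int) -> float:
        """Euclidean distance from ``node_id`` to its parent (um)."""
        nd = self.node(node_id)
        if nd.parent_id is None:
            return 0.0
        p = self._by_id[nd.parent_id]
        return math.dist((nd.x, nd.y, nd.z), (p.x, p.y, p.z))

    def path_distance(self, node_id: int) -> float:
        """Summed Euclidean inter-node distance to the root (um)."""
        if node_id not in self._by_id:
            raise KeyError(f"unknown node id {node_id}")
        return self._pathdist[node_id]

    def max_path_distance(self, structure: Structure | None = Structure.DENDRITE) -> float:
        vals = [self._pathdist[nd.id] for nd in self._nodes
                if structure is None or nd.structure == structure]
        return max(vals) if vals else 0.0

    def with_scaled_dendrite_radii(self, scale: float) -> "Morphology":
        return Morphology(
            replace(nd, radius=nd.radius * scale)
            if nd.structure == Structure.DENDRITE else nd
            for nd in self._nodes)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Morphology):
            return NotImplemented
        return self._nodes == other._nodes

    def __repr__(self) -> str:
        return f"<Morphology: {self.n_nodes} nodes, max path {self.max_path_distance():.0f} um>"


def path_distance(m: Morphology, node_id: int) -> float:
    """Path distance (um) from ``node_id`` to the root along the tree."""
    return m.path_distance(node_id)


# ---------------------------------------------------------------------------
# SWC I/O
# ---------------------------------------------------------------------------

def read_swc(path: str | Path) -> Morphology:
    """Read a standard 7-column SWC file.

    Columns: id, type, x, y, z, radius, parent (-1 for the root).  ``#``
    comment lines and blank lines are skipped.  Node order in the file is
    irrelevant: parents may appear after their children; topology is resolved
    after reading.
    """
    entries: list[SwcNode] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 7:
                raise SWCParseError(
                    f"{path}:{lineno}: expected 7 columns, got {len(parts)}")
            try:
                nid = int(parts[0])
                stype = int(parts[1])
                x, y, z, radius = (float(v) for v in parts[2:6])
                parent = int(parts[6])
            except ValueError as exc:
                raise SWCParseError(f"{path}:{lineno}: {exc}") from None
            if stype not in _SWC_TYPE_MAP:
                raise SWCParseError(
                    f"{path}:{lineno}: unsupported SWC type {stype}")
            entries.append(SwcNode(nid, _SWC_TYPE_MAP[stype], x, y, z, radius,
                                   None if parent < 0 else parent))
    try:
        return Morphology(entries)
    except MorphologyError as exc:
        raise MorphologyError(f"{path}: {exc}") from None


def write_swc(m: Morphology, path: str | Path) -> None:
    """Write the same 7-column SWC dialect :func:`read_swc` consumes."""
    with open(path, "w") as fh:
        fh.write("# id type x y z radius parent\n")
        for nd in m.nodes:
            parent = -1 if nd.parent_id is None else nd.parent_id
            fh.write(f"{nd.id} {int(nd.structure)} {nd.x:.4f} {nd.y:.4f} "
                     f"{nd.z:.4f} {nd.radius:.4f} {parent}\n")


# ---------------------------------------------------------------------------
# Synthetic morphologies
# ---------------------------------------------------------------------------

@dataclass
class GeometryParams:
    """Geometry of a synthetic branched morphology.

    ``branch_distances`` are path distances (um) at which every growing branch
    bifurcates; PVI-like trees branch once (~150 um), GC-like trees branch
    early (~40 um) and again at ~150 um.  ``base_radius``/``tip_radius`` set a
    linear taper over path distance; the generator's calibration loop rescales
    dendritic radii uniformly to hit ``target_rin_mohm``.
    """

    n_apical: int = 8
    branch_distances: tuple[float, ...] = (150.0,)
    max_path_um: float = 320.0
    node_spacing_um: float = 10.0
    soma_radius_um: float = 7.5
    base_radius_um: float = 1.4
    tip_radius_um: float = 0.65
    axon_length_um: float = 60.0
    axon_radius_um: float = 0.5
    jitter: float = 0.07
    branch_angle_deg: float = 25.0
    taper_power: float = 1.0
    target_rin_mohm: float = 101.5

    @staticmethod
    def for_cell_type(cell_type: str) -> "GeometryParams":
        ct = cell_type.upper()
        if ct == "PVI":
            return GeometryParams()
        if ct == "GC":
            return GeometryParams(
                n_apical=5, branch_distances=(40.0, 150.0), soma_radius_um=6.0,
                base_radius_um=2.5, tip_radius_um=0.15, axon_length_um=30.0,
                taper_power=0.4, target_rin_mohm=308.7)
        raise ValueError(f"unknown cell type {cell_type!r}")


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _rotated_pair(direction: np.ndarray, angle_deg: float,
                  rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Two daughter directions deviating by ~angle from the parent direction."""
    a = math.radians(angle_deg)
    # random orthonormal frame around `direction`
    ref = np.array([1.0, 0.0, 0.0])
    if abs(direction @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = _unit(np.cross(direction, ref))
    w = np.cross(direction, u)
    phi = rng.uniform(0, 2 * math.pi)
    side = math.sin(a) * (math.cos(phi) * u + math.sin(phi) * w)
    d1 = _unit(math.cos(a) * direction + side)
    d2 = _unit(math.cos(a) * direction - side)
    return d1, d2


def _grow_tree(params: GeometryParams, rng: np.random.Generator) -> list[SwcNode]:
    nodes: list[SwcNode] = [
        SwcNode(1, Structure.SOMA, 0.0, 0.0, 0.0, params.soma_radius_um, None)]
    next_id = 2

    def radius_at(d: float) -> float:
        f = min(d / params.max_path_um, 1.0) ** params.taper_power
        return params.base_radius_um + (params.tip_radius_um - params.base_radius_um) * f

    def add_chain(parent_id: int, start: np.ndarray, direction: np.ndarray,
                  start_path: float, stop_path: float, structure: Structure,
                  radius_fn) -> tuple[int, np.ndarray, float]:
        nonlocal next_id
        pos = start.copy()
        d = start_path
        pid = parent_id
        while d < stop_path - 1e-9:
            step = min(params.node_spacing_um, stop_path - d)
            pos = pos + direction * step
            d += step
            nodes.append(SwcNode(next_id, structure, *pos, radius_fn(d), pid))
            pid = next_id
            next_id += 1
        return pid, pos, d

    # axon: straight chain "downward"
    if params.axon_length_um > 0:
        add_chain(1, np.zeros(3), np.array([0.0, -1.0, 0.0]), 0.0,
                  params.axon_length_um, Structure.AXON,
                  lambda d: params.axon_radius_um)

    # apical dendrites: grow into the upper hemisphere, branching at the
    # prescribed (jittered) path distances
    for k in range(params.n_apical):
        theta = rng.uniform(0, 2 * math.pi)
        elev = rng.uniform(math.radians(25), math.radians(80))
        direction = np.array([math.cos(theta) * math.cos(elev),
                              math.sin(elev),
                              math.sin(theta) * math.cos(elev)])

        def jittered(x: float) -> float:
            return x * (1.0 + params.jitter * rng.standard_normal())

        def grow(parent_id: int, start: np.ndarray, drn: np.ndarray,
                 start_path: float, level: int) -> None:
            branches = params.branch_distances
            if level < len(branches):
                stop = max(start_path + params.node_spacing_um,
                           jittered(branches[level]))
                pid, pos, d = add_chain(parent_id, start, drn, start_path, stop,
                                        Structure.DENDRITE, radius_at)
                d1, d2 = _rotated_pair(drn, params.branch_angle_deg, rng)
                grow(pid, pos, d1, d, level + 1)
                grow(pid, pos, d2, d, level + 1)
            else:
                stop = max(start_path + params.node_spacing_um,
                           jittered(params.max_path_um))
                add_chain(parent_id, start, drn, start_path, stop,
                          Structure.DENDRITE, radius_at)

        grow(1, np.zeros(3), direction, 0.0, 0)

    return nodes


def generate_synthetic_morphology(
        cell_type: str,
        geometry_params: GeometryParams | None = None,
        seed: int = 0,
        calibrate: bool = True,
        rin_tolerance: float = 0.02,
        max_iter: int = 50) -> Morphology:
    """Generate a reproducible branched morphology for a PVI- or GC-like cell.

    When ``calibrate`` is set (the default) an internal loop uniformly rescales
    dendritic radii until the passive somatic input resistance of the tree —
    evaluated with the default passive parameter set for ``cell_type`` — lands
    within ``rin_tolerance`` (relative) of the geometry's target.  The final
    morphology is therefore guaranteed to sit well inside the +/-15% band
    around the in vitro input-resistance values.

    Raises :class:`CalibrationError` (reporting the achieved R_in) if the loop
    does not converge within ``max_iter`` iterations.
    """
    params = geometry_params or GeometryParams.for_cell_type(cell_type)
    rng = np.random.default_rng(seed)
    base = Morphology(_grow_tree(params, rng))
    if not calibrate:
        return base

    # deferred import: calibration needs the passive presets and the linear
    # steady-state solver
    from .model import preset_cell_model
    from .engine import steady_state_input_resistance

    target = params.target_rin_mohm
    scale = 1.0
    achieved = math.nan
    for _ in range(max_iter):
        m = base.with_scaled_dendrite_radii(scale)
        cell = preset_cell_model(discretize(m), cell_type, passive_only=True)
        achieved = steady_state_input_resistance(cell)
        rel = achieved / target - 1.0
        if abs(rel) < rin_tolerance:
            return m
        # R_in scales roughly as scale^-3/2 for cables (R_inf ~ d^-3/2)
        scale *= (achieved / target) ** (1.0 / 1.5)
    raise CalibrationError(
        f"R_in calibration for {cell_type} did not converge in {max_iter} iterations",
        achieved)


# ---------------------------------------------------------------------------
# Discretization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MaxSegLength:
    """Fixed upper bound on compartment length (um).  Default 5 um is finer
    than 0.1 lambda everywhere for the parameter sets used here."""

    value_um: float = 5.0

    def max_length(self, diameter_um: float) -> float:
        if self.value_um <= 0:
            raise ValueError("max segment length must be positive")
        return self.value_um


@dataclass(frozen=True)
class LambdaRule:
    """Bound compartment length by a fraction of the local space constant.

    DC space constant lambda = sqrt(R_m * d / (4 * R_a)); when ``frequency_hz``
    is positive the AC length constant 0.5 * sqrt(d / (pi f R_a C_m)) is used
    instead (the convention of compartmental simulators).  Thinner cables get
    finer compartments.
    """

    lambda_fraction: float = 0.1
    frequency_hz: float = 0.0
    r_m_kohm_cm2: float = 10.0
    r_a_ohm_cm: float = 170.0
    c_m_uf_cm2: float = 1.0

    def max_length(self, diameter_um: float) -> float:
        if self.lambda_fraction <= 0:
            raise ValueError("lambda fraction must be positive")
        d_cm = diameter_um * 1e-4
        if self.frequency_hz > 0:
            lam_cm = 0.5 * math.sqrt(
                d_cm / (math.pi * self.frequency_hz * self.r_a_ohm_cm
                        * self.c_m_uf_cm2 * 1e-6))
        else:
            lam_cm = math.sqrt(self.r_m_kohm_cm2 * 1000.0 * d_cm
                               / (4.0 * self.r_a_ohm_cm))
        return self.lambda_fraction * lam_cm * 1e4


class SegmentedCell:
    """Compartmentalized morphology: ordered cylinders on a tree.

    ``parent_index[i] < i`` for every non-root compartment, the ordering the
    implicit cable solver's one-pass tree elimination relies on.  Areas are
    lateral cylinder areas pi*d*L (um^2); ``path_distance`` is measured
    center-to-center from the soma center (root at 0).
    """

    def __init__(self, parent_index, length_um, diameter_um, path_distance_um,
                 structure, section, primary):
        self.parent_index = np.asarray(parent_index, dtype=np.int64)
        self.length_um = np.asarray(length_um, dtype=float)
        self.diameter_um = np.asarray(diameter_um, dtype=float)
        self.path_distance_um = np.asarray(path_distance_um, dtype=float)
        self.structure = np.asarray(structure, dtype=np.int64)
        self.section = np.asarray(section, dtype=np.int64)
        self.primary = np.asarray(primary, dtype=np.int64)
        self.membrane_area_um2 = math.pi * self.diameter_um * self.length_um
        n = self.n
        if n < 1 or self.parent_index[0] != -1:
            raise MorphologyError("segmented cell must have a root compartment")
        if np.any(self.parent_index[1:] >= np.arange(1, n)):
            raise MorphologyError("parent_index must precede child index")

    @property
    def n(self) -> int:
        return int(self.parent_index.shape[0])

    @property
    def soma_index(self) -> int:
        return 0

    def is_dendrite(self) -> np.ndarray:
        return self.structure == int(Structure.DENDRITE)

    def max_dendrite_path_um(self) -> float:
        d = self.path_distance_um[self.is_dendrite()]
        return float(d.max()) if d.size else 0.0

    def total_area_um2(self) -> float:
        return float(self.membrane_area_um2.sum())

    def locate(self, distance_um: float, primary: int | None = None,
               section: int | None = None) -> int:
        """Index of the dendritic compartment whose center is nearest to
        ``distance_um`` along the requested primary dendrite (or section).
        Ties break toward the soma (smaller path distance, then smaller
        index)."""
        mask = self.is_dendrite()
        if primary is not None:
            mask &= self.primary == primary
        if section is not None:
            mask &= self.section == section
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            raise LookupError(
                f"no dendritic compartments on primary={primary} section={section}")
        pd = self.path_distance_um[idx]
        err = np.abs(pd - distance_um)
        best = np.lexsort((idx, pd, err))[0]
        i = int(idx[best])
        if err[best] > 25.0:
            raise LookupError(
                f"no compartment within 25 um of requested distance {distance_um} um")
        return i

    def sections_in_band(self, lo_um: float, hi_um: float) -> list[int]:
        """Distinct unbranched dendritic sections with at least one compartment
        center inside [lo, hi] um path distance, ordered by section id."""
        mask = (self.is_dendrite()
                & (self.path_distance_um >= lo_um)
                & (self.path_distance_um <= hi_um))
        return sorted(set(int(s) for s in self.section[mask]))

    def path_to_root(self, index: int) -> list[int]:
        """Compartment indices from ``index`` up to and including the root."""
        out = [int(index)]
        while self.parent_index[out[-1]] >= 0:
            out.append(int(self.parent_index[out[-1]]))
        return out


def discretize(m: Morphology,
               rule: MaxSegLength | LambdaRule | float = MaxSegLength()) -> SegmentedCell:
    """Split every inter-node cylinder into compartments bounded by ``rule``.

    Each SWC edge is treated as a linearly tapering cylinder between the
    parent and child diameters; splitting uses mid-point diameters, which
    conserves total lateral membrane area exactly for linear taper.  A
    single-point soma becomes one cylinder with length = 2*radius; consecutive
    soma points form a cylinder stack.
    """
    if isinstance(rule, (int, float)):
        rule = MaxSegLength(float(rule))

    nodes = m.nodes
    parent_idx: list[int] = []
    lengths: list[float] = []
    diams: list[float] = []
    pdist: list[float] = []
    structs: list[int] = []
    sections: list[int] = []
    primaries: list[int] = []

    # root soma compartment
    root = m.root
    if root.structure != Structure.SOMA:
        raise MorphologyError("root node must be a soma point")
    parent_idx.append(-1)
    lengths.append(2.0 * root.radius)
    diams.append(2.0 * root.radius)
    pdist.append(0.0)
    structs.append(int(Structure.SOMA))
    sections.append(0)
    primaries.append(-1)

    last_comp: dict[int, int] = {root.id: 0}
    node_section: dict[int, int] = {root.id: 0}
    node_primary: dict[int, int] = {root.id: -1}
    next_section = 1
    next_primary = 0

    for nd in nodes[1:]:
        p = m.node(nd.parent_id)
        # section bookkeeping: new unbranched section starts at branch points,
        # at structure changes and at the soma
        if (len(m.children(p.id)) > 1 or p.structure != nd.structure
                or p.structure == Structure.SOMA):
            sec = next_section
            next_section += 1
        else:
            sec = node_section[p.id]
        node_section[nd.id] = sec
        if p.structure == Structure.SOMA and nd.structure == Structure.DENDRITE:
            prim = next_primary
            next_primary += 1
        else:
            prim = node_primary[p.id] if p.structure == nd.structure else -1
        node_primary[nd.id] = prim

        L = m.edge_length(nd.id)
        if L < 1e-9:
            last_comp[nd.id] = last_comp[p.id]
            continue
        d0 = 2.0 * p.radius
        d1 = 2.0 * nd.radius
        dmin = min(d0, d1)
        nseg = max(1, math.ceil(L / rule.max_length(dmin)))
        seg_len = L / nseg
        base_pd = m.path_distance(p.id)
        parent_comp = last_comp[p.id]
        for j in range(nseg):
            frac_mid = (j + 0.5) / nseg
            parent_idx.append(parent_comp)
            lengths.append(seg_len)
            diams.append(d0 + (d1 - d0) * frac_mid)
            pdist.append(base_pd + frac_mid * L)
            structs.append(int(nd.structure))
            sections.append(sec)
            primaries.append(prim)
            parent_comp = len(parent_idx) - 1
        last_comp[nd.id] = parent_comp

    return SegmentedCell(parent_idx, lengths, diams, pdist, structs,
                         sections, primaries)
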