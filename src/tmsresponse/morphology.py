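"""Neuron morphologies: SWC I/O, synthetic generators, myelination, discretization.

A :class:`Morphology` is a rooted tree of :class:`Section` objects (polylines
with per-point diameters, coordinates in µm).  The soma sits at the origin and
the axon extends toward negative z, so the local z-axis coincides with the
somato-dendritic axis used to parameterize the external electric field.

Myelinated axons are represented explicitly: alternating nodes of Ranvier
(1 µm wide by default) and myelin internodes with a length-to-diameter ratio
of 100, ending distally in myelinated terminal sections with L/D = 70.
Discretization chops every section into compartments of at most 20 µm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

from .errors import ConfigurationError, GeometryError, SWCParseError, TopologyError

__all__ = [
    "SectionKind",
    "MembraneRole",
    "Section",
    "Morphology",
    "MyelinationParams",
    "Compartment",
    "CompartmentModel",
    "load_swc",
    "save_swc",
    "generate_ball_and_stick",
    "generate_synthetic_population",
    "myelinate_axon",
    "apply_scaling",
    "discretize",
    "SWC_TYPE_CODES",
]


class SectionKind(str, Enum):
    SOMA = "soma"
    AXON_UNMYELINATED = "axon_unmyelinated"
    MYELIN_INTERNODE = "myelin_internode"
    NODE_OF_RANVIER = "node_of_ranvier"
    AXON_TERMINAL = "axon_terminal"
    DENDRITE = "dendrite"


AXONAL_KINDS = frozenset(
    {
        SectionKind.AXON_UNMYELINATED,
        SectionKind.MYELIN_INTERNODE,
        SectionKind.NODE_OF_RANVIER,
        SectionKind.AXON_TERMINAL,
    }
)


class MembraneRole(str, Enum):
    ACTIVE_NODE = "active_node"
    PASSIVE_MYELIN = "passive_myelin"
    PASSIVE_SOMA_DENDRITE = "passive_soma_dendrite"


# SWC has no vocabulary for myelin, so we extend the standard type codes
# (1 soma, 2 axon, 3 basal dendrite, 4 apical dendrite) with custom ones.
SWC_TYPE_CODES = {
    SectionKind.SOMA: 1,
    SectionKind.AXON_UNMYELINATED: 2,
    SectionKind.DENDRITE: 3,
    SectionKind.MYELIN_INTERNODE: 7,
    SectionKind.NODE_OF_RANVIER: 8,
    SectionKind.AXON_TERMINAL: 9,
}
_KIND_FROM_CODE = {v: k for k, v in SWC_TYPE_CODES.items()}
_KIND_FROM_CODE[4] = SectionKind.DENDRITE  # apical dendrites collapse to 'dendrite'


@dataclass
class Section:
    """A polyline piece of neurite (or the soma sphere, a single point)."""

    kind: SectionKind
    points: np.ndarray  # (n, 3) µm
    diameters: np.ndarray  # (n,) µm
    parent: int | None  # index into Morphology.sections

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.diameters = np.asarray(self.diameters, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise GeometryError("section points must be an (n, 3) array")
        if self.diameters.shape != (self.points.shape[0],):
            raise GeometryError("one diameter per point required")

    @property
    def arc_length(self) -> float:
        if len(self.points) < 2:
            return 0.0
        return float(np.sum(np.linalg.norm(np.diff(self.points, axis=0), axis=1)))

    def validate(self) -> None:
        if not np.all(np.isfinite(self.points)):
            raise GeometryError("non-finite section coordinates")
        if np.any(self.diameters <= 0):
            raise GeometryError("diameters must be strictly positive")
        if self.kind is not SectionKind.SOMA:
            if len(self.points) < 2:
                raise GeometryError("non-soma sections need at least 2 points")
            if self.arc_length <= 0:
                raise GeometryError("section arc length must be positive")


@dataclass
class Morphology:
    sections: list[Section]
    soma_position: np.ndarray = field(default_factory=lambda: np.zeros(3))
    identifier: str = "cell"

    def __post_init__(self) -> None:
        self.soma_position = np.asarray(self.soma_position, dtype=float)

    @property
    def root_index(self) -> int:
        roots = [i for i, s in enumerate(self.sections) if s.parent is None]
        if len(roots) != 1:
            raise TopologyError(f"expected exactly one root section, found {len(roots)}")
        return roots[0]

    def children(self, index: int) -> list[int]:
        return [i for i, s in enumerate(self.sections) if s.parent == index]

    def validate(self) -> None:
        root = self.root_index
        seen: set[int] = set()
        stack = [root]
        while stack:
            i = stack.pop()
            if i in seen:
                raise TopologyError("cycle in section graph")
            seen.add(i)
            stack.extend(self.children(i))
        if len(seen) != len(self.sections):
            raise TopologyError("disconnected sections present")
        for s in self.sections:
            if s.parent is not None and not (0 <= s.parent < len(self.sections)):
                raise TopologyError("parent index out of range")
            s.validate()

    def sections_of_kind(self, *kinds: SectionKind) -> list[int]:
        return [i for i, s in enumerate(self.sections) if s.kind in kinds]

    def bounding_extent(self) -> tuple[float, float]:
        """(height along z, max radial extent from the soma axis), µm."""
        pts = np.vstack([s.points for s in self.sections])
        height = float(pts[:, 2].max() - pts[:, 2].min())
        radial = float(np.max(np.hypot(pts[:, 0] - self.soma_position[0],
                                       pts[:, 1] - self.soma_position[1])))
        return height, radial


@dataclass(frozen=True)
class MyelinationParams:
    """Myelination geometry: 1 µm nodes, internode L/D = 100, terminal L/D = 70."""

    node_width: float = 1.0  # µm
    internode_LD: float = 100.0
    terminal_LD: float = 70.0

    def __post_init__(self) -> None:
        if self.node_width <= 0 or self.internode_LD <= 0 or self.terminal_LD <= 0:
            raise ConfigurationError("myelination parameters must be strictly positive")


# ---------------------------------------------------------------------------
# SWC I/O
# ---------------------------------------------------------------------------

def load_swc(path) -> Morphology:
    """Read a 7-column SWC file into a Morphology.

    Records must be topologically sorted (each parent id precedes its child).
    Consecutive single-child records of equal type are merged into one section;
    sections split at branch points and at type changes.  If a child record
    does not duplicate its parent's coordinate, the parent point is prepended
    to the section so arc lengths include the connecting segment.
    """
    records: dict[int, tuple[int, np.ndarray, float, int]] = {}
    order: list[int] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 7:
                raise SWCParseError(f"line {lineno}: expected 7 columns, got {len(parts)}")
            try:
                rid = int(parts[0])
                code = int(parts[1])
                xyz = np.array([float(parts[2]), float(parts[3]), float(parts[4])])
                radius = float(parts[5])
                parent = int(parts[6])
            except ValueError as exc:
                raise SWCParseError(f"line {lineno}: {exc}") from None
            if code not in _KIND_FROM_CODE:
                raise SWCParseError(f"line {lineno}: unknown SWC type code {code}")
            if parent != -1 and parent not in records:
                raise TopologyError(
                    f"line {lineno}: record {rid} references undefined parent {parent}"
                )
            if rid in records:
                raise SWCParseError(f"line {lineno}: duplicate record id {rid}")
            records[rid] = (code, xyz, radius, parent)
            order.append(rid)

    if not order:
        raise SWCParseError("empty SWC file")

    children: dict[int, list[int]] = {rid: [] for rid in order}
    for rid in order:
        parent = records[rid][3]
        if parent != -1:
            children[parent].append(rid)

    roots = [rid for rid in order if records[rid][3] == -1]
    if len(roots) != 1:
        raise TopologyError(f"expected one root record, found {len(roots)}")
    root = roots[0]

    sections: list[Section] = []
    section_of_record: dict[int, int] = {}

    def is_section_start(rid: int) -> bool:
        parent = records[rid][3]
        if parent == -1:
            return True
        pcode = records[parent][0]
        return (
            pcode != records[rid][0]
            or len(children[parent]) > 1
            or pcode == SWC_TYPE_CODES[SectionKind.SOMA]
        )

    for rid in order:
        code, xyz, radius, parent = records[rid]
        if not is_section_start(rid):
            continue
        chain = [rid]
        tip = rid
        while len(children[tip]) == 1:
            nxt = children[tip][0]
            if is_section_start(nxt):
                break
            chain.append(nxt)
            tip = nxt
        pts = [records[c][1] for c in chain]
        dia = [2.0 * records[c][2] for c in chain]
        kind = _KIND_FROM_CODE[code]
        if parent != -1 and kind is not SectionKind.SOMA:
            ppos = records[parent][1]
            if not np.allclose(ppos, pts[0], atol=0.0):
                pts.insert(0, ppos)
                dia.insert(0, dia[0])
        parent_section = section_of_record[parent] if parent != -1 else None
        sections.append(Section(kind, np.array(pts), np.array(dia), parent_section))
        idx = len(sections) - 1
        for c in chain:
            section_of_record[c] = idx

    soma_sections = [s for s in sections if s.kind is SectionKind.SOMA]
    soma_position = soma_sections[0].points[0] if soma_sections else records[root][1]
    m = Morphology(sections, soma_position=soma_position, identifier=str(path))
    m.validate()
    return m


def save_swc(m: Morphology, path) -> None:
    """Write a Morphology as SWC, one record per section point.

    The first point of a non-root section duplicates its parent's last point;
    it is written as a record of its own (with the section's type code) so
    that save∘load is the identity on generator output.
    """
    m.validate()
    lines = ["# SWC written by tmsresponse; type codes: "
             + ", ".join(f"{k.value}={v}" for k, v in SWC_TYPE_CODES.items())]
    next_id = 1
    last_id_of_section: dict[int, int] = {}

    ordered = _topological_section_order(m)
    for si in ordered:
        s = m.sections[si]
        code = SWC_TYPE_CODES[s.kind]
        parent_record = -1 if s.parent is None else last_id_of_section[s.parent]
        start = 0
        if s.parent is not None and s.kind is not SectionKind.SOMA:
            psec = m.sections[s.parent]
            if np.allclose(psec.points[-1], s.points[0], atol=0.0):
                start = 1  # junction point already on file via the parent record
        if start == 1 and len(s.points) == 1:
            start = 0
        for j in range(start, len(s.points)):
            x, y, z = s.points[j]
            r = s.diameters[j] / 2.0
            lines.append(f"{next_id} {code} {x:.9g} {y:.9g} {z:.9g} {r:.9g} {parent_record}")
            parent_record = next_id
            next_id += 1
        last_id_of_section[si] = next_id - 1

    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _topological_section_order(m: Morphology) -> list[int]:
    order: list[int] = []
    stack = [m.root_index]
    while stack:
        i = stack.pop()
        order.append(i)
        stack.extend(sorted(m.children(i), reverse=True))
    return order


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def _partition_myelin(
    length: float, diameter: float, p: MyelinationParams, with_terminal: bool
) -> list[tuple[SectionKind, float]]:
    """Split an axonal cable of given length into node/internode(/terminal) pieces.

    Pattern from the proximal end: node, internode, node, internode, ...;
    distal terminal of length terminal_LD*D (truncated when the cable is
    shorter).  Boundary remainders extend the last internode instead of
    creating sub-node-width stubs.
    """
    node = p.node_width
    if length <= node:
        raise GeometryError(
            f"axonal cable of {length} µm cannot hold a node ({node} µm) plus terminal"
        )
    segs: list[tuple[SectionKind, float]] = []
    if with_terminal:
        term = min(p.terminal_LD * diameter, length - node)
        remaining = length - term
    else:
        term = 0.0
        remaining = length
    segs.append((SectionKind.NODE_OF_RANVIER, node))
    left = remaining - node
    internode = p.internode_LD * diameter
    pair = internode + node
    while left >= pair:
        segs.append((SectionKind.MYELIN_INTERNODE, internode))
        segs.append((SectionKind.NODE_OF_RANVIER, node))
        left -= pair
    if left > 1e-9:
        idx = [i for i, (k, _) in enumerate(segs) if k is SectionKind.MYELIN_INTERNODE]
        if idx:
            k, length_i = segs[idx[-1]]
            segs[idx[-1]] = (k, length_i + left)
        else:
            segs.append((SectionKind.MYELIN_INTERNODE, left))
    if with_terminal:
        segs.append((SectionKind.AXON_TERMINAL, term))
    return segs


def generate_ball_and_stick(
    axon_length: float,
    axon_diameter: float,
    myelin: MyelinationParams | None = None,
    soma_diameter: float = 20.0,
) -> Morphology:
    """Soma sphere at the origin plus a straight myelinated axon along −z.

    This is the TMS adaptation of the classic ball-and-stick cell: the passive
    dendrite is replaced by a straight axon, because under TMS-like fields the
    dendritic thresholds are an order of magnitude above the axonal ones.
    """
    if axon_length <= 0 or axon_diameter <= 0 or soma_diameter <= 0:
        raise GeometryError("ball-and-stick lengths and diameters must be positive")
    myelin = myelin or MyelinationParams()
    segs = _partition_myelin(axon_length, axon_diameter, myelin, with_terminal=True)

    sections = [Section(SectionKind.SOMA, np.zeros((1, 3)), np.array([soma_diameter]), None)]
    z = 0.0
    parent = 0
    for kind, length in segs:
        pts = np.array([[0.0, 0.0, z], [0.0, 0.0, z - length]])
        sections.append(Section(kind, pts, np.full(2, axon_diameter), parent))
        parent = len(sections) - 1
        z -= length
    m = Morphology(sections, soma_position=np.zeros(3),
                   identifier=f"ball_and_stick_l{axon_length:g}_d{axon_diameter:g}")
    m.validate()
    return m


@dataclass(frozen=True)
class PopulationParams:
    """Geometry ranges for the synthetic stand-in populations.

    The two archetypes mimic the gross anatomy that matters for field
    coupling: pyramidal-like cells are tall (long descending main axon,
    apical-like dendrite) with obliquely spreading collaterals, basket-like
    cells are compact and near-isotropic.  All sizes in µm.
    """

    main_axon_length: tuple[float, float] = (800.0, 1000.0)
    main_axon_diameter: float = 4.0
    n_collaterals: tuple[int, int] = (4, 7)
    collateral_length: tuple[float, float] = (150.0, 350.0)
    collateral_diameter: float = 2.0
    dendrite_length: float = 400.0
    dendrite_diameter: float = 3.0
    soma_diameter: float = 20.0
    collateral_polar_deg: tuple[float, float] = (55.0, 125.0)
    initial_segment: float = 0.0  # unmyelinated proximal axon, µm
    myelin: MyelinationParams = MyelinationParams()


_BASKET_PARAMS = PopulationParams(
    main_axon_length=(250.0, 350.0),
    n_collaterals=(7, 11),
    collateral_length=(200.0, 400.0),
    dendrite_length=120.0,
    collateral_polar_deg=(30.0, 150.0),
)


def generate_synthetic_population(
    n_cells: int,
    archetype: str,
    seed: int,
    params: PopulationParams | None = None,
) -> list[Morphology]:
    """Seeded stand-in cells with a descending main axon and myelinated collaterals.

    ``archetype`` is ``pyramidal_like`` (taller than wide) or ``basket_like``
    (near-isotropic).  Deterministic for a fixed seed.
    """
    if n_cells < 1:
        raise ConfigurationError("n_cells must be >= 1")
    if archetype not in ("pyramidal_like", "basket_like"):
        raise ConfigurationError(f"unknown archetype {archetype!r}")
    if params is None:
        params = PopulationParams() if archetype == "pyramidal_like" else _BASKET_PARAMS

    rng = np.random.default_rng(seed)
    cells = []
    for c in range(n_cells):
        cells.append(_generate_cell(rng, archetype, params, f"{archetype}_{seed}_{c}"))
    return cells


def _generate_cell(rng, archetype: str, p: PopulationParams, name: str) -> Morphology:
    sections = [Section(SectionKind.SOMA, np.zeros((1, 3)),
                        np.array([p.soma_diameter]), None)]

    axon_len = rng.uniform(*p.main_axon_length)
    n_coll = int(rng.integers(p.n_collaterals[0], p.n_collaterals[1] + 1))
    # branch points along the main axon, away from both ends
    branch_s = np.sort(rng.uniform(0.15, 0.85, size=n_coll)) * axon_len

    # main axon runs down -z with small lateral jitter
    def axon_point(s: float) -> np.ndarray:
        amp = 0.02 * s
        return np.array([amp * math.sin(s / 180.0), amp * math.cos(s / 150.0), -s])

    axon_section_at_branch: list[int] = []
    parent = 0
    s_prev = 0.0
    start = np.zeros(3)
    cuts = list(branch_s) + [axon_len]
    for s_cut in cuts:
        n_pts = max(2, int(math.ceil((s_cut - s_prev) / 100.0)) + 1)
        svals = np.linspace(s_prev, s_cut, n_pts)
        pts = np.vstack([start] + [axon_point(s) for s in svals[1:]])
        sections.append(Section(SectionKind.AXON_UNMYELINATED, pts,
                                np.full(len(pts), p.main_axon_diameter), parent))
        parent = len(sections) - 1
        axon_section_at_branch.append(parent)
        start = pts[-1]
        s_prev = s_cut

    for bi, s_b in enumerate(branch_s):
        base = axon_point(s_b)
        pol = math.radians(rng.uniform(*p.collateral_polar_deg))
        azi = rng.uniform(0.0, 2.0 * math.pi)
        direction = np.array([math.sin(pol) * math.cos(azi),
                              math.sin(pol) * math.sin(azi),
                              -math.cos(pol)])
        length = rng.uniform(*p.collateral_length)
        pts = np.vstack([base, base + direction * length])
        sections.append(Section(SectionKind.AXON_UNMYELINATED, pts,
                                np.full(2, p.collateral_diameter),
                                axon_section_at_branch[bi]))

    # apical-like dendrite straight up +z (passive; geometry only)
    dpts = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, p.dendrite_length]])
    sections.append(Section(SectionKind.DENDRITE, dpts,
                            np.full(2, p.dendrite_diameter), 0))

    m = Morphology(sections, soma_position=np.zeros(3), identifier=name)
    return myelinate_axon(m, p.myelin, initial_segment=p.initial_segment)


# ---------------------------------------------------------------------------
# Myelination of existing morphologies
# ---------------------------------------------------------------------------

def _split_polyline(points: np.ndarray, diameters: np.ndarray,
                    seg_lengths: Sequence[float]):
    """Cut a polyline into consecutive pieces of the given arc lengths."""
    deltas = np.linalg.norm(np.diff(points, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(deltas)])
    total = cum[-1]

    def point_at(s: float) -> tuple[np.ndarray, float]:
        s = min(max(s, 0.0), total)
        j = int(np.searchsorted(cum, s, side="right")) - 1
        j = min(j, len(deltas) - 1)
        f = 0.0 if deltas[j] == 0 else (s - cum[j]) / deltas[j]
        pt = points[j] + f * (points[j + 1] - points[j])
        dia = diameters[j] + f * (diameters[j + 1] - diameters[j])
        return pt, dia

    pieces = []
    s0 = 0.0
    for L in seg_lengths:
        s1 = s0 + L
        inner = [(points[j], diameters[j]) for j in range(len(points))
                 if s0 < cum[j] < s1 - 1e-12]
        p0, d0 = point_at(s0)
        p1, d1 = point_at(s1)
        pts = np.vstack([p0] + [p for p, _ in inner] + [p1])
        dias = np.array([d0] + [d for _, d in inner] + [d1])
        pieces.append((pts, dias))
        s0 = s1
    return pieces


def myelinate_axon(
    m: Morphology, p: MyelinationParams | None = None, initial_segment: float = 0.0
) -> Morphology:
    """Replace unmyelinated axonal sections by node/internode/terminal chains.

    Sections without axonal children end in a myelinated terminal of length
    terminal_LD × D (truncated on short cables); branch sections carry only
    the node/internode alternation.  The proximal ``initial_segment`` µm of
    root-attached axon stay unmyelinated (no consensus default; 0 disables).
    Total axonal arc length is conserved.
    """
    import warnings

    p = p or MyelinationParams()
    axon_ids = m.sections_of_kind(SectionKind.AXON_UNMYELINATED)
    if not axon_ids:
        warnings.warn("morphology has no unmyelinated axon; returning it unchanged",
                      stacklevel=2)
        return m

    new_sections: list[Section] = []
    index_map: dict[int, int] = {}  # old section -> new index of its distal end

    has_axonal_child = {
        i: any(m.sections[c].kind in AXONAL_KINDS for c in m.children(i))
        for i in range(len(m.sections))
    }
    attached_to_soma = {
        i: m.sections[i].parent is not None
        and m.sections[m.sections[i].parent].kind is SectionKind.SOMA
        for i in range(len(m.sections))
    }

    for old_i in _topological_section_order(m):
        s = m.sections[old_i]
        new_parent = None if s.parent is None else index_map[s.parent]
        if s.kind is not SectionKind.AXON_UNMYELINATED:
            new_sections.append(replace(s, parent=new_parent))
            index_map[old_i] = len(new_sections) - 1
            continue

        length = s.arc_length
        mean_d = float(np.mean(s.diameters))
        ais = min(initial_segment, length) if attached_to_soma[old_i] else 0.0
        segs: list[tuple[SectionKind, float]] = []
        if ais > 0:
            segs.append((SectionKind.AXON_UNMYELINATED, ais))
        myelinatable = length - ais
        if myelinatable > p.node_width:
            segs.extend(
                _partition_myelin(myelinatable, mean_d, p,
                                  with_terminal=not has_axonal_child[old_i])
            )
        elif myelinatable > 0:
            segs.append((SectionKind.AXON_UNMYELINATED, myelinatable))

        pieces = _split_polyline(s.points, s.diameters, [L for _, L in segs])
        parent = new_parent
        for (kind, _), (pts, dias) in zip(segs, pieces):
            new_sections.append(Section(kind, pts, dias, parent))
            parent = len(new_sections) - 1
        index_map[old_i] = parent

    out = Morphology(new_sections, soma_position=m.soma_position.copy(),
                     identifier=m.identifier)
    out.validate()
    total_before = sum(m.sections[i].arc_length for i in axon_ids)
    total_after = sum(sec.arc_length for sec in new_sections if sec.kind in AXONAL_KINDS)
    if total_before > 0 and abs(total_after - total_before) / total_before > 1e-3:
        raise GeometryError("myelination failed to conserve axonal arc length")
    return out


# ---------------------------------------------------------------------------
# Scaling
# ---------------------------------------------------------------------------

_PART_OF_KIND = {
    SectionKind.SOMA: "soma",
    SectionKind.DENDRITE: "dendrite",
    SectionKind.AXON_UNMYELINATED: "axon",
    SectionKind.MYELIN_INTERNODE: "axon",
    SectionKind.NODE_OF_RANVIER: "axon",
    SectionKind.AXON_TERMINAL: "axon",
}

_VALID_SCALE_KEYS = {
    f"{part}_{what}" for part in ("soma", "axon", "dendrite")
    for what in ("length", "diameter")
}


def apply_scaling(m: Morphology, factors: dict[str, float] | None) -> Morphology:
    """Scale lengths/diameters per morphological part; identity by default.

    ``factors`` maps keys like ``axon_diameter`` or ``dendrite_length`` to
    positive multipliers.  Species-scaling values are deliberately not built
    in (they belong to external calibrations); the defaults are the identity.
    """
    factors = dict(factors or {})
    for key, val in factors.items():
        if key not in _VALID_SCALE_KEYS:
            raise ConfigurationError(f"unknown scaling key {key!r}")
        if not (val > 0):
            raise ConfigurationError(f"scaling factor {key}={val} must be positive")

    new_sections: list[Section] = [None] * len(m.sections)  # type: ignore[list-item]
    new_end: dict[int, np.ndarray] = {}
    for i in _topological_section_order(m):
        s = m.sections[i]
        part = _PART_OF_KIND[s.kind]
        lf = factors.get(f"{part}_length", 1.0)
        df = factors.get(f"{part}_diameter", 1.0)
        if s.parent is None:
            anchor = s.points[0].copy()
        else:
            anchor = new_end[s.parent]
        pts = anchor + (s.points - s.points[0]) * lf
        new_sections[i] = Section(s.kind, pts, s.diameters * df, s.parent)
        new_end[i] = pts[-1]
    out = Morphology(new_sections, soma_position=m.soma_position.copy(),
                     identifier=m.identifier)
    out.validate()
    return out


# ---------------------------------------------------------------------------
# Discretization
# ---------------------------------------------------------------------------

@dataclass
class Compartment:
    center: np.ndarray  # µm
    endpoints: tuple[np.ndarray, np.ndarray]
    length: float  # µm
    diameter: float  # µm
    kind: SectionKind
    membrane_role: MembraneRole


_ROLE_OF_KIND = {
    SectionKind.SOMA: MembraneRole.PASSIVE_SOMA_DENDRITE,
    SectionKind.DENDRITE: MembraneRole.PASSIVE_SOMA_DENDRITE,
    SectionKind.MYELIN_INTERNODE: MembraneRole.PASSIVE_MYELIN,
    SectionKind.NODE_OF_RANVIER: MembraneRole.ACTIVE_NODE,
    SectionKind.AXON_TERMINAL: MembraneRole.ACTIVE_NODE,
    SectionKind.AXON_UNMYELINATED: MembraneRole.ACTIVE_NODE,
}


@dataclass
class CompartmentModel:
    compartments: list[Compartment]
    adjacency: np.ndarray  # parent index per compartment; -1 at root
    cell_id: str
    section_of_compartment: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.compartments)

    @property
    def centers(self) -> np.ndarray:
        return np.array([c.center for c in self.compartments])

    @property
    def lengths(self) -> np.ndarray:
        return np.array([c.length for c in self.compartments])

    @property
    def diameters(self) -> np.ndarray:
        return np.array([c.diameter for c in self.compartments])

    @property
    def roles(self) -> list[MembraneRole]:
        return [c.membrane_role for c in self.compartments]

    def validate(self, max_len: float | None = None) -> None:
        n = len(self.compartments)
        if self.adjacency.shape != (n,):
            raise TopologyError("adjacency must hold one parent index per compartment")
        if n and self.adjacency[0] != -1:
            raise TopologyError("first compartment must be the root")
        for i in range(1, n):
            if not (0 <= self.adjacency[i] < i):
                raise TopologyError("compartment parents must precede their children")
        for c in self.compartments:
            if c.length <= 0 or c.diameter <= 0:
                raise GeometryError("compartment length and diameter must be positive")
            if max_len is not None and c.length > max_len * (1 + 1e-9):
                raise GeometryError("compartment exceeds the discretization limit")


def discretize(m: Morphology, max_len: float = 20.0) -> CompartmentModel:
    """Chop every section into compartments no longer than ``max_len`` µm.

    Each non-soma section of arc length L becomes ceil(L/max_len) equal-length
    compartments; the soma is a single spherical compartment.  Nodes of
    Ranvier, terminals and unmyelinated axon map to active membrane,
    internodes to passive myelin, soma/dendrites to passive leaky membrane.
    """
    if max_len <= 0:
        raise ConfigurationError("max_len must be positive")
    m.validate()

    compartments: list[Compartment] = []
    adjacency: list[int] = []
    section_ids: list[int] = []
    last_comp_of_section: dict[int, int] = {}

    for si in _topological_section_order(m):
        s = m.sections[si]
        parent_comp = -1 if s.parent is None else last_comp_of_section[s.parent]
        if s.kind is SectionKind.SOMA:
            d = float(s.diameters[0])
            center = s.points[0].astype(float)
            half = np.array([0.0, 0.0, d / 2.0])
            compartments.append(Compartment(center, (center - half, center + half),
                                            d, d, s.kind, _ROLE_OF_KIND[s.kind]))
            adjacency.append(parent_comp)
            section_ids.append(si)
            last_comp_of_section[si] = len(compartments) - 1
            continue

        arc = s.arc_length
        n = max(1, int(math.ceil(arc / max_len - 1e-12)))
        pieces = _split_polyline(s.points, s.diameters, [arc / n] * n)
        for pts, dias in pieces:
            deltas = np.linalg.norm(np.diff(pts, axis=0), axis=1)
            cum = np.concatenate([[0.0], np.cumsum(deltas)])
            total = cum[-1]
            # midpoint along arc
            sm = total / 2.0
            j = min(int(np.searchsorted(cum, sm, side="right")) - 1, len(deltas) - 1)
            f = 0.0 if deltas[j] == 0 else (sm - cum[j]) / deltas[j]
            center = pts[j] + f * (pts[j + 1] - pts[j])
            dia = float(dias[j] + f * (dias[j + 1] - dias[j]))
            compartments.append(
                Compartment(center, (pts[0].copy(), pts[-1].copy()), arc / n, dia,
                            s.kind, _ROLE_OF_KIND[s.kind])
            )
            adjacency.append(parent_comp)
            section_ids.append(si)
            parent_comp = len(compartments) - 1
        last_comp_of_section[si] = parent_comp

    cm = CompartmentModel(compartments, np.array(adjacency, dtype=np.int64),
                          m.identifier, np.array(section_ids, dtype=np.int64))
    cm.validate(max_len=max_len)
    return cm
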