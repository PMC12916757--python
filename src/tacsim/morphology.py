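"""Reduced neuron morphologies: segment trees, builders and SWC I/O.

The five circuit cells are reduced stand-ins for morphologically detailed
cortical models: pyramidal-like cells (L2/3, L5, L6) get an elongated apical
trunk aligned with the cortical-depth (field) axis plus oblique basal
dendrites and a short axon initial segment; interneuron-like cells (L1
neurogliaform, L4 large basket) get a compact, radially near-symmetric
dendritic tree.  The elongation asymmetry is what makes pyramidal somata
polarize more per unit field than interneurons.

Coordinates are micrometres; +z points toward the pial surface (layer 1).
Every child segment starts at its parent's end point, so the tree is exactly
representable as SWC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dfield
from pathlib import Path
from typing import List, Optional

import numpy as np

from .errors import ConfigError, InvalidArgument

KINDS = ("soma", "axon", "basal", "apical")
_SWC_TYPE = {"soma": 1, "axon": 2, "basal": 3, "apical": 4}
_SWC_KIND = {v: k for k, v in _SWC_TYPE.items()}

LAYER_LABELS = ("L1_NGC", "L23_PC", "L4_LBC", "L5_PC", "L6_PC")
PYRAMIDAL = ("L23_PC", "L5_PC", "L6_PC")
INTERNEURON = ("L1_NGC", "L4_LBC")


@dataclass
class Segment:
    """A cylindrical segment of a neuron, one compartment of the solver."""

    id: int
    start_xyz: np.ndarray
    end_xyz: np.ndarray
    diameter_um: float
    kind: str
    parent: Optional[int]

    def __post_init__(self) -> None:
        self.start_xyz = np.asarray(self.start_xyz, dtype=float)
        self.end_xyz = np.asarray(self.end_xyz, dtype=float)
        if self.kind not in KINDS:
            raise InvalidArgument(f"kind must be one of {KINDS}")
        if self.diameter_um <= 0:
            raise InvalidArgument("diameter must be positive")
        if self.length_um == 0 and self.kind != "soma":
            raise InvalidArgument("only the soma may be a zero-length sphere stand-in")

    @property
    def length_um(self) -> float:
        return float(np.linalg.norm(self.end_xyz - self.start_xyz))

    @property
    def midpoint_um(self) -> np.ndarray:
        return 0.5 * (self.start_xyz + self.end_xyz)

    @property
    def area_um2(self) -> float:
        """Lateral (membrane) area of the cylinder."""
        return math.pi * self.diameter_um * max(self.length_um, self.diameter_um)


@dataclass
class Morphology:
    """A connected acyclic tree of segments; the root is the soma."""

    cell_id: str
    layer_label: str
    segments: List[Segment] = dfield(default_factory=list)

    def __post_init__(self) -> None:
        if self.layer_label not in LAYER_LABELS:
            raise InvalidArgument(f"layer_label must be one of {LAYER_LABELS}")
        self.validate()

    def validate(self) -> None:
        ids = [s.id for s in self.segments]
        if len(set(ids)) != len(ids):
            raise ConfigError("duplicate segment ids")
        by_id = {s.id: s for s in self.segments}
        roots = [s for s in self.segments if s.parent is None]
        if len(roots) != 1:
            raise ConfigError("exactly one parentless (root/soma) segment required")
        if roots[0].kind != "soma":
            raise ConfigError("the root segment must be the soma")
        # connectivity + acyclicity: walk each segment to the root
        for s in self.segments:
            seen = set()
            cur = s
            while cur.parent is not None:
                if cur.id in seen:
                    raise ConfigError("cycle in segment tree")
                seen.add(cur.id)
                if cur.parent not in by_id:
                    raise ConfigError(f"segment {cur.id} has dangling parent")
                cur = by_id[cur.parent]

    def __len__(self) -> int:
        return len(self.segments)

    @property
    def root(self) -> Segment:
        return next(s for s in self.segments if s.parent is None)

    def by_kind(self, kind: str) -> List[Segment]:
        return [s for s in self.segments if s.kind == kind]

    def extent_along(self, axis) -> float:
        """Spatial extent of the cell projected on a (unit) axis, um."""
        a = np.asarray(axis, dtype=float)
        a = a / np.linalg.norm(a)
        proj = [p @ a for s in self.segments for p in (s.start_xyz, s.end_xyz)]
        return float(max(proj) - min(proj))

    def translate(self, offset_um) -> "Morphology":
        off = np.asarray(offset_um, dtype=float)
        segs = [
            Segment(s.id, s.start_xyz + off, s.end_xyz + off, s.diameter_um,
                    s.kind, s.parent)
            for s in self.segments
        ]
        return Morphology(self.cell_id, self.layer_label, segs)


# ---------------------------------------------------------------------------
# Builders
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeometryParams:
    """Tunable dimensions of a reduced morphology (micrometres)."""

    soma_length_um: float = 20.0
    soma_diameter_um: float = 20.0
    apical_length_um: float = 600.0
    apical_diameter_um: float = 3.5
    apical_seg_um: float = 40.0
    n_basal: int = 4
    basal_length_um: float = 150.0
    basal_diameter_um: float = 1.5
    basal_seg_um: float = 50.0
    axon_length_um: float = 40.0
    axon_diameter_um: float = 1.5
    dend_length_um: float = 120.0  # interneuron dendrites
    dend_diameter_um: float = 1.2
    n_dend: int = 6

    def __post_init__(self) -> None:
        for name in (
            "soma_length_um", "soma_diameter_um", "apical_length_um",
            "apical_diameter_um", "basal_length_um", "basal_diameter_um",
            "axon_length_um", "axon_diameter_um", "dend_length_um",
            "dend_diameter_um",
        ):
            if getattr(self, name) <= 0:
                raise InvalidArgument(f"{name} must be positive")


#: Per-layer default geometry; pyramidal trunks lengthen with depth.
DEFAULT_GEOMETRY = {
    "L1_NGC": GeometryParams(soma_length_um=15, soma_diameter_um=15,
                             dend_length_um=120, n_dend=6),
    "L23_PC": GeometryParams(apical_length_um=450, apical_diameter_um=5.0,
                             basal_length_um=80.0, basal_seg_um=40.0),
    "L4_LBC": GeometryParams(soma_length_um=15, soma_diameter_um=15,
                             dend_length_um=140, n_dend=6),
    "L5_PC": GeometryParams(apical_length_um=1000),
    "L6_PC": GeometryParams(apical_length_um=750),
}

# Oblique basal directions (unit vectors, pointing down/outward).
_BASAL_DIRS = np.array([
    [0.60, 0.60, -0.53], [-0.60, 0.60, -0.53],
    [0.60, -0.60, -0.53], [-0.60, -0.60, -0.53],
    [0.80, 0.0, -0.60], [-0.80, 0.0, -0.60],
])
_BASAL_DIRS /= np.linalg.norm(_BASAL_DIRS, axis=1)[:, None]

# Radially near-symmetric interneuron dendrite directions.
_DEND_DIRS = np.array([
    [1.0, 0.0, 0.05], [-1.0, 0.0, -0.05],
    [0.0, 1.0, 0.05], [0.0, -1.0, -0.05],
    [0.55, 0.55, 0.62], [-0.55, -0.55, -0.62],
    [0.55, -0.55, 0.62], [-0.55, 0.55, -0.62],
])
_DEND_DIRS /= np.linalg.norm(_DEND_DIRS, axis=1)[:, None]


def _chain(segs, start, direction, total_len, seg_len, diameter, kind, parent_id):
    """Append a straight chain of segments; returns ids of the chain."""
    n = max(1, int(math.ceil(total_len / seg_len)))
    step = total_len / n
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    ids = []
    pos = np.asarray(start, dtype=float)
    parent = parent_id
    for _ in range(n):
        nxt = pos + d * step
        sid = len(segs)
        segs.append(Segment(sid, pos.copy(), nxt.copy(), diameter, kind, parent))
        ids.append(sid)
        parent = sid
        pos = nxt
    return ids


def build_reduced_morphology(
    layer_label: str, geometry: Optional[GeometryParams] = None
) -> Morphology:
    """Deterministic reduced morphology for one of the five cell types.

    Pyramidal-like cells: soma, apical trunk climbing several hundred um
    along +z, oblique basal dendrites, short descending axon initial
    segment.  Interneuron-like cells: soma plus short radially symmetric
    dendrites — much smaller extent along the field axis.
    """
    if layer_label not in LAYER_LABELS:
        raise InvalidArgument(f"unknown layer label {layer_label!r}")
    g = geometry or DEFAULT_GEOMETRY[layer_label]
    segs: List[Segment] = []
    half = g.soma_length_um / 2.0
    soma = Segment(0, np.array([0.0, 0.0, -half]), np.array([0.0, 0.0, half]),
                   g.soma_diameter_um, "soma", None)
    segs.append(soma)
    top = soma.end_xyz

    if layer_label in PYRAMIDAL:
        _chain(segs, top, [0, 0, 1], g.apical_length_um, g.apical_seg_um,
               g.apical_diameter_um, "apical", 0)
        for k in range(g.n_basal):
            _chain(segs, top, _BASAL_DIRS[k % len(_BASAL_DIRS)],
                   g.basal_length_um, g.basal_seg_um,
                   g.basal_diameter_um, "basal", 0)
        _chain(segs, top, [0, 0, -1], g.axon_length_um, g.axon_length_um / 2.0,
               g.axon_diameter_um, "axon", 0)
    else:
        for k in range(g.n_dend):
            _chain(segs, top, _DEND_DIRS[k % len(_DEND_DIRS)],
                   g.dend_length_um, g.basal_seg_um,
                   g.dend_diameter_um, "basal", 0)
        _chain(segs, top, [0, 0, -1], g.axon_length_um, g.axon_length_um / 2.0,
               g.axon_diameter_um, "axon", 0)

    return Morphology(cell_id=layer_label, layer_label=layer_label, segments=segs)


# ---------------------------------------------------------------------------
# SWC I/O
# ---------------------------------------------------------------------------

def write_swc(morph: Morphology, path) -> None:
    """Write the morphology as SWC (one sample per segment end point).

    Node 1 is the root segment's start; node i+2 is segment i's end point
    with its parent segment's node as SWC parent.
    """
    lines = ["# SWC export; columns: n T x y z R parent"]
    root = morph.root
    x, y, z = root.start_xyz
    lines.append(f"1 1 {x:.4f} {y:.4f} {z:.4f} {root.diameter_um / 2:.4f} -1")
    node_of = {}
    for n, s in enumerate(morph.segments, start=2):
        node_of[s.id] = n
    for s in morph.segments:
        parent_node = 1 if s.parent is None else node_of[s.parent]
        x, y, z = s.end_xyz
        lines.append(
            f"{node_of[s.id]} {_SWC_TYPE[s.kind]} {x:.4f} {y:.4f} {z:.4f} "
            f"{s.diameter_um / 2:.4f} {parent_node}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_swc(path, cell_id: str = "", layer_label: str = "L5_PC") -> Morphology:
    """Read an SWC file written by :func:`write_swc` back into a Morphology."""
    nodes = {}
    order = []
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        f = line.split()
        n = int(f[0])
        nodes[n] = (int(f[1]), np.array([float(f[2]), float(f[3]), float(f[4])]),
                    2.0 * float(f[5]), int(f[6]))
        order.append(n)
    segs = []
    seg_of_node = {}
    for n in order:
        t, xyz, diam, parent = nodes[n]
        if parent == -1:
            continue  # the root start point; consumed by its child
        p_t, p_xyz, _, _ = nodes[parent]
        sid = len(segs)
        parent_seg = seg_of_node.get(parent)  # None for the soma segment
        segs.append(Segment(sid, p_xyz.copy(), xyz.copy(), diam,
                            _SWC_KIND.get(t, "basal"), parent_seg))
        seg_of_node[n] = sid
    return Morphology(cell_id or Path(path).stem, layer_label, segs)
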