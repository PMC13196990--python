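"""Neuron morphologies as trees of cylindrical segments.

A :class:`Morphology` is an ordered list of :class:`Segment` objects
forming a single connected tree with exactly one soma.  The soma is
encoded as a zero-length segment whose ``radius`` is the sphere radius;
its center is the origin used for rotations.

Coordinates are micrometers throughout.  The sensor plane is z = 0 and
cells live at z > 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from neurofields.errors import FormatError, InvalidParameterError

_SWC_LABELS = {1: "soma", 2: "axon", 3: "dendrite"}
_SWC_CODES = {"soma": 1, "axon": 2, "dendrite": 3}

#: tolerance for the child-start == parent-end invariant (um)
CONNECT_TOL = 1e-6


@dataclass(frozen=True)
class Segment:
    """One cylindrical compartment.

    ``start``/``end`` are 3-vectors (um); ``radius`` > 0 (um).  A soma
    may have ``start == end`` (sphere of radius ``radius``).  ``parent``
    is the index of the parent segment in the owning morphology, or
    ``None`` for the root.
    """

    start: np.ndarray
    end: np.ndarray
    radius: float
    parent: Optional[int]
    label: str = "axon"

    def __post_init__(self):
        object.__setattr__(self, "start", np.asarray(self.start, dtype=float))
        object.__setattr__(self, "end", np.asarray(self.end, dtype=float))
        if self.radius <= 0:
            raise InvalidParameterError("segment radius must be > 0")
        if self.label not in ("soma", "axon", "dendrite"):
            raise InvalidParameterError(f"unknown segment label {self.label!r}")
        if self.label != "soma" and np.allclose(self.start, self.end):
            raise InvalidParameterError("zero-length segment only allowed for soma")

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.end - self.start))

    @property
    def midpoint(self) -> np.ndarray:
        return 0.5 * (self.start + self.end)

    @property
    def direction(self) -> np.ndarray:
        """Direction vector with magnitude equal to the segment length."""
        return self.end - self.start


@dataclass
class Morphology:
    """A connected tree of segments with exactly one soma."""

    segments: list[Segment] = field(default_factory=list)
    soma_position: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.soma_position = np.asarray(self.soma_position, dtype=float)
        self._validate()

    def _validate(self) -> None:
        somas = [s for s in self.segments if s.label == "soma"]
        if len(somas) != 1:
            raise InvalidParameterError(
                f"morphology must contain exactly one soma, got {len(somas)}"
            )
        roots = [i for i, s in enumerate(self.segments) if s.parent is None]
        if len(roots) != 1:
            raise InvalidParameterError(f"expected exactly one root, got {len(roots)}")
        for i, s in enumerate(self.segments):
            if s.parent is not None:
                if not (0 <= s.parent < len(self.segments)) or s.parent == i:
                    raise InvalidParameterError(f"segment {i} has invalid parent")
                p = self.segments[s.parent]
                if np.max(np.abs(s.start - p.end)) > CONNECT_TOL:
                    raise InvalidParameterError(
                        f"segment {i} start does not coincide with parent end"
                    )
            if not np.all(np.isfinite(s.start)) or not np.all(np.isfinite(s.end)):
                raise InvalidParameterError(f"segment {i} has non-finite coordinates")
        # connectivity: every segment must reach the root
        for i, s in enumerate(self.segments):
            seen = set()
            j = i
            while self.segments[j].parent is not None:
                if j in seen:
                    raise InvalidParameterError("cyclic parent reference")
                seen.add(j)
                j = self.segments[j].parent

    def __len__(self) -> int:
        return len(self.segments)

    # -- cached geometry arrays -------------------------------------------
    @property
    def starts(self) -> np.ndarray:
        return np.array([s.start for s in self.segments])

    @property
    def ends(self) -> np.ndarray:
        return np.array([s.end for s in self.segments])

    @property
    def radii(self) -> np.ndarray:
        return np.array([s.radius for s in self.segments])

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.starts + self.ends)

    @property
    def lengths(self) -> np.ndarray:
        return np.linalg.norm(self.ends - self.starts, axis=1)

    @property
    def parents(self) -> np.ndarray:
        return np.array(
            [-1 if s.parent is None else s.parent for s in self.segments], dtype=int
        )

    @property
    def soma_index(self) -> int:
        return next(i for i, s in enumerate(self.segments) if s.label == "soma")

    def leaf_count(self) -> int:
        """Number of leaf tips (segments that are nobody's parent)."""
        parents = {s.parent for s in self.segments if s.parent is not None}
        return sum(1 for i in range(len(self.segments)) if i not in parents)


def make_ball_stick(
    axon_length: float,
    axon_diameter: float,
    soma_diameter: float,
    segment_length: float,
) -> Morphology:
    """Soma sphere at the origin plus a straight axon along +x.

    The axon is divided into ``ceil(axon_length / segment_length)`` equal
    compartments of radius ``axon_diameter / 2``.
    """
    for name, v in (
        ("axon_length", axon_length),
        ("axon_diameter", axon_diameter),
        ("soma_diameter", soma_diameter),
        ("segment_length", segment_length),
    ):
        if v <= 0:
            raise InvalidParameterError(f"{name} must be > 0, got {v}")
    if segment_length > axon_length:
        raise InvalidParameterError("segment_length must be <= axon_length")

    n = math.ceil(axon_length / segment_length)
    dx = axon_length / n
    origin = np.zeros(3)
    segments = [Segment(origin, origin, soma_diameter / 2.0, None, "soma")]
    r = axon_diameter / 2.0
    for i in range(n):
        start = np.array([i * dx, 0.0, 0.0])
        end = np.array([(i + 1) * dx, 0.0, 0.0])
        segments.append(Segment(start, end, r, i, "axon"))
    return Morphology(segments, origin)


def make_branched_cell(
    trunk_length: float,
    n_minor_branches: int,
    branch_length: float,
    seed: int,
    trunk_diameter: float = 2.0,
    branch_diameter: float = 1.0,
    soma_diameter: float = 20.0,
    segment_length: float = 10.0,
) -> Morphology:
    """A dominant +x trunk plus minor branches at randomized angles.

    Synthetic stand-in for an elongated pyramidal-like geometry: one long
    process from the soma and ``n_minor_branches`` shorter processes, at
    least one of which points opposite the trunk (the geometry that makes
    the near-soma polarity inversion appear).  Deterministic given
    ``seed``.
    """
    if trunk_length <= 0:
        raise InvalidParameterError("trunk_length must be > 0")
    if n_minor_branches < 0:
        raise InvalidParameterError("n_minor_branches must be >= 0")
    if n_minor_branches > 0 and branch_length <= 0:
        raise InvalidParameterError("branch_length must be > 0")

    rng = np.random.default_rng(seed)
    n_trunk = max(1, math.ceil(trunk_length / segment_length))
    dx = trunk_length / n_trunk
    origin = np.zeros(3)
    segments = [Segment(origin, origin, soma_diameter / 2.0, None, "soma")]
    rt = trunk_diameter / 2.0
    for i in range(n_trunk):
        segments.append(
            Segment(
                np.array([i * dx, 0.0, 0.0]),
                np.array([(i + 1) * dx, 0.0, 0.0]),
                rt,
                i,
                "axon",
            )
        )

    rb = branch_diameter / 2.0
    for b in range(n_minor_branches):
        if b == 0:
            # guaranteed opposing process (negative x-component), placed
            # obliquely so its inverted near-soma field overlaps the
            # trunk's — the failure mode the second-pass boundary
            # estimator corrects
            sign = 1.0 if rng.random() < 0.5 else -1.0
            angle = sign * (2.0 * math.pi / 3.0 + rng.uniform(-0.15, 0.15))
        else:
            angle = rng.uniform(0.25 * math.pi, 1.75 * math.pi)
        u = np.array([math.cos(angle), math.sin(angle), 0.0])
        n_seg = max(1, math.ceil(branch_length / segment_length))
        db = branch_length / n_seg
        parent = 0  # attach at the soma
        for i in range(n_seg):
            start = origin + i * db * u
            end = origin + (i + 1) * db * u
            segments.append(Segment(start, end, rb, parent, "dendrite"))
            parent = len(segments) - 1
    return Morphology(segments, origin)


def flatten_morphology(m: Morphology, z_min: float, z_max: float) -> Morphology:
    """Affine min-max rescale of all z-coordinates into [z_min, z_max].

    x and y are untouched.  A degenerate input range (all z equal) maps to
    the interval midpoint.  Idempotent for already-flattened input.
    """
    if z_min >= z_max:
        raise InvalidParameterError("z_min must be < z_max")
    zs = np.concatenate([m.starts[:, 2], m.ends[:, 2]])
    lo, hi = float(zs.min()), float(zs.max())

    if hi - lo < 1e-12:
        def remap(z):
            return 0.5 * (z_min + z_max)
    else:
        scale = (z_max - z_min) / (hi - lo)

        def remap(z):
            return z_min + (z - lo) * scale

    def move(p):
        return np.array([p[0], p[1], remap(p[2])])

    segments = [
        replace(s, start=move(s.start), end=move(s.end)) for s in m.segments
    ]
    return Morphology(segments, move(m.soma_position))


def transform_morphology(
    m: Morphology, theta: float, delta: Sequence[float]
) -> Morphology:
    """Rotate about the z-axis through the soma, then translate in-plane.

    ``theta`` is in degrees, counterclockwise viewed from +z.  ``delta``
    is an (x, y) displacement in um.  Rigid: all pairwise distances are
    preserved.
    """
    th = math.radians(theta)
    c, s = math.cos(th), math.sin(th)
    rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    shift = np.array([delta[0], delta[1], 0.0])
    pivot = m.soma_position

    def move(p):
        return rot @ (p - pivot) + pivot + shift

    segments = [
        replace(s_, start=move(s_.start), end=move(s_.end)) for s_ in m.segments
    ]
    return Morphology(segments, move(m.soma_position))


# ---------------------------------------------------------------------------
# SWC input/output (standard 7-column dialect, 1-based ids)
# ---------------------------------------------------------------------------

def read_swc(path) -> Morphology:
    """Read a morphology from a standard SWC file.

    Each non-root node becomes one segment from its parent's coordinates
    to its own, carrying the node's radius and type code.  The root must
    be a soma node; it becomes the zero-length soma segment.
    """
    nodes = {}  # id -> (type, xyz, radius, parent_id)
    order = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 7:
                raise FormatError(f"line {lineno}: expected 7 columns, got {len(parts)}")
            try:
                nid = int(parts[0])
                ntype = int(parts[1])
                xyz = np.array([float(parts[2]), float(parts[3]), float(parts[4])])
                radius = float(parts[5])
                parent = int(parts[6])
            except ValueError as exc:
                raise FormatError(f"line {lineno}: {exc}") from None
            if nid in nodes:
                raise FormatError(f"line {lineno}: duplicate node id {nid}")
            nodes[nid] = (ntype, xyz, radius, parent, lineno)
            order.append(nid)

    roots = [nid for nid in order if nodes[nid][3] == -1]
    if len(roots) == 0:
        raise FormatError("no root node (parent -1) found")
    if len(roots) > 1:
        lines = ", ".join(str(nodes[r][4]) for r in roots)
        raise FormatError(f"multiple roots at lines {lines}")

    # cycle check by walking each node to the root
    for nid in order:
        seen = set()
        cur = nid
        while cur != -1:
            if cur in seen:
                raise FormatError(
                    f"line {nodes[nid][4]}: cyclic parent reference at node {nid}"
                )
            seen.add(cur)
            if cur not in nodes:
                raise FormatError(f"node {nid} references unknown parent {cur}")
            cur = nodes[cur][3]

    root = roots[0]
    rtype, rxyz, rradius, _, rline = nodes[root]
    if _SWC_LABELS.get(rtype, "dendrite") != "soma":
        raise FormatError(f"line {rline}: root node must be a soma (type 1)")

    segments = [Segment(rxyz, rxyz, rradius, None, "soma")]
    seg_of_node = {root: 0}
    for nid in order:
        if nid == root:
            continue
        ntype, xyz, radius, parent, lineno = nodes[nid]
        if parent not in seg_of_node:
            # parents must precede children in file order for this dialect;
            # fall back to a second pass if needed
            raise FormatError(f"line {lineno}: parent {parent} appears after child")
        pseg = segments[seg_of_node[parent]]
        label = _SWC_LABELS.get(ntype, "dendrite")
        segments.append(Segment(pseg.end, xyz, radius, seg_of_node[parent], label))
        seg_of_node[nid] = len(segments) - 1
    return Morphology(segments, rxyz)


def write_swc(m: Morphology, path) -> None:
    """Write a morphology as standard SWC (inverse of :func:`read_swc`)."""
    soma_i = m.soma_index
    node_of_seg = {soma_i: 1}
    lines = []
    soma = m.segments[soma_i]
    lines.append(
        f"1 1 {soma.end[0]:.9g} {soma.end[1]:.9g} {soma.end[2]:.9g} "
        f"{soma.radius:.9g} -1"
    )
    next_id = 2
    for i, s in enumerate(m.segments):
        if i == soma_i:
            continue
        parent_node = node_of_seg[s.parent]
        code = _SWC_CODES.get(s.label, 3)
        lines.append(
            f"{next_id} {code} {s.end[0]:.9g} {s.end[1]:.9g} {s.end[2]:.9g} "
            f"{s.radius:.9g} {parent_node}"
        )
        node_of_seg[i] = next_id
        next_id += 1
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
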