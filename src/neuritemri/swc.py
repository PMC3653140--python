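"""Reading, writing, and geometric preprocessing of SWC neuron reconstructions.

SWC is the standard 7-column plain-text format for neuron morphologies
(node id, structure-type code, x, y, z, radius, parent id).  This module
parses SWC text into a validated :class:`NeuronTree`, resamples edges at a
fixed spatial step, and decomposes the (soma-free) arbor into unbranched
coordinate paths — the preprocessing chain that feeds the orientation
morphometry.

Coordinates and radii are micrometres throughout (NeuroMorpho convention);
no unit inference is attempted.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SWCError",
    "NeuronTree",
    "UnbranchedPath",
    "parse_swc",
    "read_swc",
    "write_swc",
    "interpolate",
    "decompose_paths",
    "SOMA",
    "AXON",
    "BASAL_DENDRITE",
    "APICAL_DENDRITE",
]

# Canonical SWC structure-type codes.
SOMA = 1
AXON = 2
BASAL_DENDRITE = 3
APICAL_DENDRITE = 4

#: structure codes treated as neurite (contributing to paths) by default
DEFAULT_NEURITE_TYPES = frozenset({AXON, BASAL_DENDRITE, APICAL_DENDRITE})


class SWCError(ValueError):
    """Raised for malformed SWC content; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


@dataclass
class NeuronTree:
    """A rooted forest of 3-D nodes with radii, as stored in an SWC file.

    Parameters
    ----------
    ids : (N,) int array of node identifiers (unique).
    type_codes : (N,) int array of SWC structure codes.
    xyz : (N, 3) float array of coordinates in μm.
    radii : (N,) float array of radii in μm (all > 0).
    parent_ids : (N,) int array; -1 marks a root.  Every parent must appear
        earlier in the node order, so the parent relation is a forest.
    name : free-text label.
    """

    ids: np.ndarray
    type_codes: np.ndarray
    xyz: np.ndarray
    radii: np.ndarray
    parent_ids: np.ndarray
    name: str = ""
    _index: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        self.ids = np.asarray(self.ids, dtype=np.int64)
        self.type_codes = np.asarray(self.type_codes, dtype=np.int64)
        self.xyz = np.asarray(self.xyz, dtype=float).reshape(-1, 3)
        self.radii = np.asarray(self.radii, dtype=float)
        self.parent_ids = np.asarray(self.parent_ids, dtype=np.int64)
        self._validate()
        self._index = {int(i): k for k, i in enumerate(self.ids)}

    def _validate(self):
        n = len(self.ids)
        if not (len(self.type_codes) == len(self.radii) == len(self.parent_ids) == self.xyz.shape[0] == n):
            raise SWCError("inconsistent array lengths")
        if len(np.unique(self.ids)) != n:
            raise SWCError("duplicate node ids")
        if not np.all(np.isfinite(self.xyz)):
            raise SWCError("non-finite coordinates")
        if np.any(self.radii <= 0) or not np.all(np.isfinite(self.radii)):
            raise SWCError("radii must be positive and finite")
        seen = set()
        for k in range(n):
            pid = int(self.parent_ids[k])
            if pid != -1 and pid not in seen:
                raise SWCError(
                    f"node {int(self.ids[k])} references parent {pid} "
                    "which does not appear earlier (forward reference, "
                    "unknown id, or cycle)"
                )
            seen.add(int(self.ids[k]))

    # -- convenience accessors -------------------------------------------

    def __len__(self) -> int:
        return len(self.ids)

    def index_of(self, node_id: int) -> int:
        return self._index[int(node_id)]

    def children(self) -> list[list[int]]:
        """Child row-indices per row, in ascending node-id (= file) order."""
        kids: list[list[int]] = [[] for _ in range(len(self))]
        for k in range(len(self)):
            pid = int(self.parent_ids[k])
            if pid != -1:
                kids[self.index_of(pid)].append(k)
        return kids

    def edges(self) -> np.ndarray:
        """(E, 2) array of (parent_row, child_row) pairs."""
        mask = self.parent_ids != -1
        child_rows = np.nonzero(mask)[0]
        parent_rows = np.array([self.index_of(p) for p in self.parent_ids[mask]], dtype=np.int64)
        return np.column_stack([parent_rows, child_rows])

    def total_length(self) -> float:
        """Summed Euclidean edge length (μm)."""
        e = self.edges()
        if len(e) == 0:
            return 0.0
        d = self.xyz[e[:, 1]] - self.xyz[e[:, 0]]
        return float(np.linalg.norm(d, axis=1).sum())

    def n_termini(self, type_codes=DEFAULT_NEURITE_TYPES) -> int:
        """Number of leaf nodes among the given structure types."""
        kids = self.children()
        keep = np.isin(self.type_codes, list(type_codes))
        return int(sum(1 for k in range(len(self)) if keep[k] and not kids[k]))


@dataclass
class UnbranchedPath:
    """A maximal run of consecutive coordinates with no interior branching."""

    coords: np.ndarray  # (P, 3) μm
    radii: np.ndarray  # (P,) μm

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        self.radii = np.asarray(self.radii, dtype=float)
        if self.coords.shape[0] < 2:
            raise ValueError("a path needs at least 2 points")
        if self.coords.shape[0] != len(self.radii):
            raise ValueError("coords/radii length mismatch")
        steps = np.linalg.norm(np.diff(self.coords, axis=0), axis=1)
        if np.any(steps == 0):
            raise ValueError("consecutive path points must be distinct")

    def __len__(self) -> int:
        return self.coords.shape[0]

    @property
    def length(self) -> float:
        return float(np.linalg.norm(np.diff(self.coords, axis=0), axis=1).sum())


# ---------------------------------------------------------------------------
# I/O


def parse_swc(text: str, name: str = "") -> NeuronTree:
    """Parse SWC-format text into a :class:`NeuronTree`.

    Lines starting with '#' and blank lines are skipped.  Exactly seven
    whitespace-separated numeric fields are required per data line; any
    malformation is reported with its 1-based line number.
    """
    ids, types, xyz, radii, parents = [], [], [], [], []
    seen: set[int] = set()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) != 7:
            raise SWCError(f"expected 7 fields, got {len(fields)}", lineno)
        try:
            nid = int(fields[0])
            tcode = int(fields[1])
            x, y, z, r = (float(v) for v in fields[2:6])
            pid = int(fields[6])
        except ValueError as exc:
            raise SWCError(f"non-numeric field: {exc}", lineno) from None
        if nid in seen:
            raise SWCError(f"duplicate node id {nid}", lineno)
        if r <= 0 or not math.isfinite(r):
            raise SWCError(f"nonpositive radius {r} for node {nid}", lineno)
        if not all(math.isfinite(v) for v in (x, y, z)):
            raise SWCError(f"non-finite coordinate for node {nid}", lineno)
        if pid != -1 and pid not in seen:
            raise SWCError(f"node {nid} references unknown parent {pid}", lineno)
        seen.add(nid)
        ids.append(nid)
        types.append(tcode)
        xyz.append((x, y, z))
        radii.append(r)
        parents.append(pid)
    if not ids:
        raise SWCError("no data lines found")
    return NeuronTree(
        ids=np.array(ids),
        type_codes=np.array(types),
        xyz=np.array(xyz),
        radii=np.array(radii),
        parent_ids=np.array(parents),
        name=name,
    )


def read_swc(path) -> NeuronTree:
    with open(path) as fh:
        return parse_swc(fh.read(), name=str(path))


def write_swc(tree: NeuronTree, path=None, header: str | None = None) -> str:
    """Serialize a tree to SWC text; returns the text, optionally writing it.

    A '#' header records provenance (package name plus any caller-supplied
    comment lines).
    """
    buf = io.StringIO()
    buf.write("# written by neuritemri\n")
    if tree.name:
        buf.write(f"# name: {tree.name}\n")
    if header:
        for line in header.splitlines():
            buf.write(f"# {line}\n")
    buf.write("# id type x y z radius parent\n")
    for k in range(len(tree)):
        x, y, z = tree.xyz[k]
        buf.write(
            f"{int(tree.ids[k])} {int(tree.type_codes[k])} "
            f"{x:.17g} {y:.17g} {z:.17g} {tree.radii[k]:.17g} {int(tree.parent_ids[k])}\n"
        )
    text = buf.getvalue()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


# ---------------------------------------------------------------------------
# Geometry


def interpolate(tree: NeuronTree, step: float = 1.0) -> NeuronTree:
    """Resample every edge into equal sub-edges of length ≤ ``step`` μm.

    Each parent→child edge of length L is split into ceil(L/step) equal
    pieces; inserted nodes interpolate coordinates and radii linearly and
    inherit the child's structure code.  Topology, total cable length and
    termini are preserved.  Nodes are renumbered consecutively.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    new_type, new_xyz, new_r, new_parent = [], [], [], []
    # maps old row -> new id of that node
    new_id_of: dict[int, int] = {}
    next_id = 1

    for k in range(len(tree)):
        pid = int(tree.parent_ids[k])
        if pid == -1:
            new_id_of[k] = next_id
            new_type.append(int(tree.type_codes[k]))
            new_xyz.append(tree.xyz[k])
            new_r.append(tree.radii[k])
            new_parent.append(-1)
            next_id += 1
            continue
        prow = tree.index_of(pid)
        p0, p1 = tree.xyz[prow], tree.xyz[k]
        r0, r1 = tree.radii[prow], tree.radii[k]
        L = float(np.linalg.norm(p1 - p0))
        npieces = max(1, int(math.ceil(L / step - 1e-12))) if L > 0 else 1
        prev_new = new_id_of[prow]
        for j in range(1, npieces + 1):
            t = j / npieces
            new_type.append(int(tree.type_codes[k]))
            new_xyz.append((1 - t) * p0 + t * p1)
            new_r.append((1 - t) * r0 + t * r1)
            new_parent.append(prev_new)
            prev_new = next_id
            next_id += 1
        new_id_of[k] = prev_new

    n = len(new_type)
    return NeuronTree(
        ids=np.arange(1, n + 1),
        type_codes=np.array(new_type),
        xyz=np.array(new_xyz),
        radii=np.array(new_r),
        parent_ids=np.array(new_parent),
        name=tree.name,
    )


def decompose_paths(
    tree: NeuronTree,
    neurite_types=DEFAULT_NEURITE_TYPES,
    soma_attachment: str = "centroid",
) -> list[UnbranchedPath]:
    """Decompose the neuritic arbor into unbranched coordinate paths.

    Soma nodes (type 1) never contribute their own edges; a neurite stem
    whose parent is a soma node starts its path at the soma coordinate
    (``soma_attachment='centroid'``) or at the point on the soma sphere
    toward the stem (``'surface'``).  Descent is depth-first; at a branch
    point the current path continues into the lowest-id unused child and
    each remaining child starts a new path from the branch coordinate, so
    every non-soma edge belongs to exactly one path and the number of
    paths equals the number of termini.
    """
    if soma_attachment not in ("centroid", "surface"):
        raise ValueError("soma_attachment must be 'centroid' or 'surface'")
    keep = np.isin(tree.type_codes, list(neurite_types))
    kids = tree.children()

    def kept_children(row):
        return [c for c in kids[row] if keep[c]]

    # Stems: kept nodes whose parent is absent, or is not itself kept.
    stems = []
    for k in range(len(tree)):
        if not keep[k]:
            continue
        pid = int(tree.parent_ids[k])
        if pid == -1 or not keep[tree.index_of(pid)]:
            stems.append(k)

    paths: list[UnbranchedPath] = []

    def start_coords(stem_row):
        """Initial (coords, radii) prefix for a stem path."""
        pid = int(tree.parent_ids[stem_row])
        if pid == -1:
            return [], []
        prow = tree.index_of(pid)
        if int(tree.type_codes[prow]) == SOMA:
            c = tree.xyz[prow].copy()
            if soma_attachment == "surface":
                d = tree.xyz[stem_row] - c
                nrm = np.linalg.norm(d)
                if nrm > 0:
                    c = c + d / nrm * min(tree.radii[prow], nrm)
            return [c], [tree.radii[prow]]
        return [tree.xyz[prow].copy()], [tree.radii[prow]]

    for stem in stems:
        # stack of (prefix_coords, prefix_radii, node_row) path starters
        stack = [(start_coords(stem), stem)]
        while stack:
            (pc, pr), row = stack.pop()
            coords = list(pc)
            radii = list(pr)
            while True:
                coords.append(tree.xyz[row].copy())
                radii.append(float(tree.radii[row]))
                ch = kept_children(row)
                if not ch:
                    break
                if len(ch) > 1:
                    # siblings start fresh paths at this branch coordinate;
                    # pushed in reverse so lower ids are traversed first
                    for sib in reversed(ch[1:]):
                        stack.append((([tree.xyz[row].copy()], [float(tree.radii[row])]), sib))
                row = ch[0]
            # drop zero-length leading steps (e.g. stem coincident with soma)
            coords_a = np.asarray(coords)
            dedup = [0]
            for i in range(1, len(coords_a)):
                if np.linalg.norm(coords_a[i] - coords_a[dedup[-1]]) > 0:
                    dedup.append(i)
            if len(dedup) >= 2:
                paths.append(UnbranchedPath(coords_a[dedup], np.asarray(radii)[dedup]))
    return paths
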