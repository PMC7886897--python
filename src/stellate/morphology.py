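"""Stellate-cell morphologies: SWC I/O, a statistical generator, and the
five-class electrotonic reduction.

A morphology is a tree of *segments* (unbranched runs of 3D points with
per-point diameters) labelled ``soma``, ``dendrite``, ``ais`` or ``axon``.
For simulation the tree is reduced to five electrotonic compartment
classes -- soma, proximal dendrite, distal dendrite, AIS and axon -- with
proximal/distal dendrites separated at a diameter cut-off (0.6 um by
default).

The generator emulates the morphometrics of reconstructed mouse stellate
cells: soma surface 42.4 +/- 9.3 um^2, total dendritic length
845.2 +/- 121.2 um, ~11 proximal and ~63.5 distal dendritic segments,
a 28-um axon initial segment continuing into a ~578-um branched axon.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "Segment",
    "Morphology",
    "MorphometricTargets",
    "read_swc",
    "write_swc",
    "generate_sc_morphology",
    "classify_compartments",
    "morphometrics",
    "DENDRITE_DIAMETER_CUTOFF_UM",
]

#: diameter separating proximal (>=) from distal (<) dendritic segments, um
DENDRITE_DIAMETER_CUTOFF_UM = 0.6

SECTION_LABELS = ("soma", "dendrite", "ais", "axon")
COMPARTMENT_CLASSES = ("soma", "proximal_dendrite", "distal_dendrite", "ais", "axon")

# SWC type codes.  SWC has no AIS code: on write the AIS is emitted as
# axon (code 2); on read the first axonal path of ``ais_length`` um from
# the soma is relabelled ``ais``.
_LABEL_TO_SWC = {"soma": 1, "axon": 2, "ais": 2, "dendrite": 3}
_SWC_TO_LABEL = {1: "soma", 2: "axon", 3: "dendrite", 4: "dendrite"}


class SWCError(ValueError):
    """Malformed SWC content (carries the offending line number)."""


@dataclass
class Segment:
    """Unbranched run of points between two branch points (or a tip)."""

    id: int
    parent: int  # -1 for the root segment
    label: str
    points: np.ndarray  # (n, 3) xyz in um
    diameters: np.ndarray  # (n,) in um

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        self.diameters = np.asarray(self.diameters, dtype=float).ravel()
        if len(self.points) != len(self.diameters):
            raise ValueError("points/diameters length mismatch")
        if self.label not in SECTION_LABELS:
            raise ValueError(f"unknown section label {self.label!r}")
        if np.any(self.diameters <= 0):
            raise ValueError("diameters must be positive")

    @property
    def length(self) -> float:
        """Path length, um (sum of inter-point distances)."""
        if len(self.points) < 2:
            return 0.0
        return float(np.sum(np.linalg.norm(np.diff(self.points, axis=0), axis=1)))

    @property
    def mean_diameter(self) -> float:
        return float(np.mean(self.diameters))

    def surface(self) -> float:
        """Lateral (cylindrical frustum) surface area, um^2."""
        if len(self.points) < 2:
            return 0.0
        dl = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        dmid = 0.5 * (self.diameters[:-1] + self.diameters[1:])
        return float(np.sum(math.pi * dmid * dl))


@dataclass
class Morphology:
    """Single connected tree of labelled segments rooted at the soma."""

    segments: list[Segment]
    cell_id: str = "cell"
    units: str = "um"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        ids = {s.id for s in self.segments}
        roots = [s for s in self.segments if s.parent == -1]
        if len(roots) != 1:
            raise ValueError(f"morphology must have exactly one root, got {len(roots)}")
        if roots[0].label != "soma":
            raise ValueError("root segment must be the soma")
        for s in self.segments:
            if s.parent != -1 and s.parent not in ids:
                raise ValueError(f"segment {s.id} has unknown parent {s.parent}")

    def by_label(self, label: str) -> list[Segment]:
        return [s for s in self.segments if s.label == label]

    def children(self, seg_id: int) -> list[Segment]:
        return [s for s in self.segments if s.parent == seg_id]

    @property
    def root(self) -> Segment:
        return next(s for s in self.segments if s.parent == -1)


@dataclass
class MorphometricTargets:
    """Summary statistics the generator reproduces (mean, sd pairs)."""

    soma_surface_um2: tuple[float, float] = (42.4, 9.3)
    total_dendritic_length_um: tuple[float, float] = (845.2, 121.2)
    proximal_segment_count: tuple[float, float] = (11.0, 3.0)
    distal_segment_count: tuple[float, float] = (63.5, 14.0)
    ais_length_um: tuple[float, float] = (28.0, 6.7)
    axon_length_um: tuple[float, float] = (577.9, 225.0)
    dendrite_diameter_cutoff_um: float = DENDRITE_DIAMETER_CUTOFF_UM
    n_dendritic_trees: tuple[int, int] = (3, 4)

    def validate(self) -> None:
        for name in (
            "soma_surface_um2",
            "total_dendritic_length_um",
            "proximal_segment_count",
            "distal_segment_count",
            "ais_length_um",
            "axon_length_um",
        ):
            mean, sd = getattr(self, name)
            if mean <= 0 or sd < 0:
                raise ValueError(f"invalid target {name}: mean {mean}, sd {sd}")
        if not (0 < self.dendrite_diameter_cutoff_um):
            raise ValueError("cutoff must be positive")


# ---------------------------------------------------------------------------
# SWC I/O


def read_swc(path, ais_length_um: float = 28.0) -> Morphology:
    """Read a 7-column SWC file into a :class:`Morphology`.

    SWC type codes map 1 -> soma, 2 -> axon, 3/4 -> dendrite.  The first
    axonal path of ``ais_length_um`` (measured from its soma attachment)
    is relabelled ``ais``, since SWC has no AIS code.
    """
    nodes: dict[int, tuple[int, float, float, float, float, int]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 7:
                raise SWCError(f"line {lineno}: expected 7 columns, got {len(parts)}")
            try:
                nid = int(parts[0])
                typ = int(parts[1])
                x, y, z, r = (float(v) for v in parts[2:6])
                parent = int(parts[6])
            except ValueError as exc:
                raise SWCError(f"line {lineno}: {exc}") from None
            if typ not in _SWC_TO_LABEL:
                raise SWCError(f"line {lineno}: unknown SWC type {typ}")
            if r <= 0:
                raise SWCError(f"line {lineno}: non-positive radius")
            if nid in nodes:
                raise SWCError(f"line {lineno}: duplicate node id {nid}")
            nodes[nid] = (typ, x, y, z, r, parent)

    roots = [nid for nid, rec in nodes.items() if rec[5] == -1]
    if len(roots) != 1:
        raise SWCError(f"expected a single root node, found {len(roots)}")

    children: dict[int, list[int]] = {nid: [] for nid in nodes}
    for nid, rec in nodes.items():
        if rec[5] != -1:
            if rec[5] not in nodes:
                raise SWCError(f"node {nid} references missing parent {rec[5]}")
            children[rec[5]].append(nid)

    # walk the node tree splitting it into unbranched, single-label segments
    segments: list[Segment] = []
    seg_of_node: dict[int, int] = {}
    next_id = [0]

    def emit(start: int, parent_seg: int) -> None:
        typ = nodes[start][1 - 1]
        chain = [start]
        cur = start
        while True:
            kids = children[cur]
            if len(kids) == 1 and nodes[kids[0]][0] == typ:
                cur = kids[0]
                chain.append(cur)
            else:
                break
        pts = np.array([[nodes[n][1], nodes[n][2], nodes[n][3]] for n in chain])
        dia = np.array([2.0 * nodes[n][4] for n in chain])
        # prepend the attachment point so the segment is spatially connected
        if parent_seg >= 0:
            attach = nodes[start][5]
            pts = np.vstack([[nodes[attach][1], nodes[attach][2], nodes[attach][3]], pts])
            dia = np.concatenate([[dia[0]], dia])
        sid = next_id[0]
        next_id[0] += 1
        segments.append(
            Segment(sid, parent_seg, _SWC_TO_LABEL[typ], pts, dia)
        )
        for n in chain:
            seg_of_node[n] = sid
        for kid in children[cur]:
            emit(kid, sid)

    emit(roots[0], -1)
    _relabel_ais(segments, ais_length_um)
    return Morphology(segments=segments, cell_id=str(path))


def _relabel_ais(segments: list[Segment], ais_length_um: float) -> None:
    """Mark the first ``ais_length_um`` of axon leaving the soma as AIS."""
    by_id = {s.id: s for s in segments}
    for seg in segments:
        if seg.label != "axon":
            continue
        parent = by_id.get(seg.parent)
        if parent is None or parent.label != "soma":
            continue
        if seg.length <= ais_length_um * 1.25 or len(seg.points) < 3:
            seg.label = "ais"
        else:
            # split the leading run off as the AIS at the node closest to
            # the nominal AIS length (splitting at an existing node keeps
            # write -> read round trips exact)
            cum = np.concatenate(
                [[0.0], np.cumsum(np.linalg.norm(np.diff(seg.points, axis=0), axis=1))]
            )
            k = int(np.argmin(np.abs(cum - ais_length_um)))
            k = max(1, min(k, len(seg.points) - 2))
            new_id = max(s.id for s in segments) + 1
            tail = Segment(new_id, seg.id, "axon", seg.points[k:], seg.diameters[k:])
            for s in segments:
                if s.parent == seg.id and s is not tail:
                    s.parent = new_id
            seg.points = seg.points[: k + 1]
            seg.diameters = seg.diameters[: k + 1]
            seg.label = "ais"
            segments.append(tail)
        break


def write_swc(morph: Morphology, path) -> None:
    """Write a morphology as standard 7-column SWC (AIS emitted as axon)."""
    lines = ["# SWC export", "# columns: id type x y z radius parent"]
    node_id = [0]
    last_node_of_seg: dict[int, int] = {}

    def emit(seg: Segment, parent_seg: int) -> None:
        try:
            typ = _LABEL_TO_SWC[seg.label]
        except KeyError:
            raise ValueError(f"section label {seg.label!r} has no SWC mapping") from None
        start = 1 if parent_seg >= 0 else 0  # attachment point belongs to the parent
        prev = last_node_of_seg[parent_seg] if parent_seg >= 0 else -1
        for i in range(start, len(seg.points)):
            node_id[0] += 1
            x, y, z = seg.points[i]
            lines.append(
                f"{node_id[0]} {typ} {x:.6f} {y:.6f} {z:.6f} "
                f"{seg.diameters[i] / 2.0:.6f} {prev}"
            )
            prev = node_id[0]
        last_node_of_seg[seg.id] = prev
        for child in sorted(morph.children(seg.id), key=lambda s: s.id):
            emit(child, seg.id)

    emit(morph.root, -1)
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Generator


class GenerationError(RuntimeError):
    pass


def generate_sc_morphology(
    targets: Optional[MorphometricTargets] = None,
    seed: int = 0,
    max_attempts: int = 40,
) -> Morphology:
    """Grow a random stellate-cell morphology matching the target
    morphometrics within one sd.

    The soma is a single cylinder matched to the target surface.  3-4
    dendritic trunks branch recursively; diameters taper from ~1.0 um at
    the trunk to ~0.3 um at the tips so the 0.6-um cut-off splits each
    tree into proximal and distal portions.  An AIS and a branched axon
    are appended.  Coordinates are in um with the soma at the origin;
    orientation carries no semantics.
    """
    targets = targets or MorphometricTargets()
    targets.validate()
    rng = np.random.default_rng(seed)
    last_err: Optional[str] = None
    for _ in range(max_attempts):
        try:
            morph = _grow_once(targets, rng)
        except GenerationError as exc:
            last_err = str(exc)
            continue
        mm = morphometrics(morph)
        ok = (
            _within(mm["total_dendritic_length_um"], targets.total_dendritic_length_um)
            and _within(mm["proximal_segment_count"], targets.proximal_segment_count)
            and _within(mm["distal_segment_count"], targets.distal_segment_count)
        )
        if ok:
            return morph
        last_err = f"morphometrics off target: {mm}"
    raise GenerationError(f"could not reach targets in {max_attempts} attempts: {last_err}")


def _within(value: float, mean_sd: tuple[float, float]) -> bool:
    mean, sd = mean_sd
    return abs(value - mean) <= max(sd, 1e-9)


def _sample(rng, mean_sd, lo=None) -> float:
    mean, sd = mean_sd
    v = rng.normal(mean, 0.5 * sd)
    v = float(np.clip(v, mean - sd, mean + sd))
    if lo is not None:
        v = max(v, lo)
    return v


def _grow_once(targets: MorphometricTargets, rng) -> Morphology:
    cutoff = targets.dendrite_diameter_cutoff_um
    segs: list[Segment] = []
    next_id = [0]

    def add(parent, label, pts, dias) -> Segment:
        s = Segment(next_id[0], parent, label, pts, dias)
        next_id[0] += 1
        segs.append(s)
        return s

    # soma: cylinder with lateral surface == target (pi*d*L, L = d)
    surf = _sample(rng, targets.soma_surface_um2, lo=5.0)
    d_soma = math.sqrt(surf / math.pi)
    soma = add(
        -1,
        "soma",
        [[0.0, -d_soma / 2, 0.0], [0.0, d_soma / 2, 0.0]],
        [d_soma, d_soma],
    )

    # dendrites: build the branching topology first (every expansion adds
    # two daughters, so the tree has no single-child runs and survives
    # SWC round trips), then assign lengths/diameters, then geometry.
    n_trees = int(
        rng.integers(targets.n_dendritic_trees[0], targets.n_dendritic_trees[1] + 1)
    )
    total_len = _sample(rng, targets.total_dendritic_length_um, lo=100.0)
    n_prox = max(n_trees, int(round(_sample(rng, targets.proximal_segment_count, lo=1))))
    n_dist = max(2, int(round(_sample(rng, targets.distal_segment_count, lo=2))))
    n_total = n_prox + n_dist
    if (n_total - n_trees) % 2 == 1:
        n_dist += 1
        n_total += 1
    if cutoff <= 0.3 or cutoff >= 1.0:
        raise GenerationError("cut-off outside the generator's taper range")

    parent_of: dict[int, int] = {}  # local dendrite index -> parent (-1 = soma)
    level_of: dict[int, int] = {}
    children: dict[int, list[int]] = {}
    tips: list[int] = []
    for i in range(n_trees):
        parent_of[i] = -1
        level_of[i] = 0
        children[i] = []
        tips.append(i)
    nxt = n_trees
    while nxt < n_total:
        k = int(rng.integers(len(tips)))
        tip = tips.pop(k)
        for _ in range(2):
            parent_of[nxt] = tip
            level_of[nxt] = level_of[tip] + 1
            children[nxt] = []
            children[tip].append(nxt)
            tips.append(nxt)
            nxt += 1

    # shallowest n_prox segments become proximal (>= cutoff), the rest
    # distal; diameters taper with rank inside each group
    order = sorted(range(n_total), key=lambda i: (level_of[i], rng.random()))
    diam: dict[int, float] = {}
    for rank, idx in enumerate(order):
        if rank < n_prox:
            f = rank / max(n_prox - 1, 1)
            diam[idx] = 1.05 - f * (1.05 - (cutoff + 0.05))
        else:
            f = (rank - n_prox) / max(n_dist - 1, 1)
            diam[idx] = (cutoff - 0.05) - f * ((cutoff - 0.05) - 0.30)

    # lengths: jittered equal shares rescaled to the exact total
    lengths = rng.uniform(0.85, 1.15, size=n_total)
    lengths *= total_len / lengths.sum()

    # geometry: place trees radially in the sagittal plane
    seg_of: dict[int, Segment] = {}
    end_pt: dict[int, np.ndarray] = {}
    direction: dict[int, np.ndarray] = {}
    soma_tip = np.asarray(soma.points[-1], dtype=float)
    for i in sorted(parent_of, key=lambda i: level_of[i]):
        p = parent_of[i]
        if p == -1:
            theta = 2 * math.pi * i / n_trees + rng.uniform(-0.3, 0.3)
            u = np.array([math.cos(theta), math.sin(theta), 0.2 * (i % 2)])
            u /= np.linalg.norm(u)
            origin = soma_tip
            par_seg = soma
        else:
            u = _jitter(direction[p], rng, 0.7)
            origin = end_pt[p]
            par_seg = seg_of[p]
        end = origin + u * lengths[i]
        seg = add(par_seg.id, "dendrite", [origin, end], [diam[i], diam[i]])
        seg_of[i] = seg
        end_pt[i] = end
        direction[i] = u

    # AIS: straight cable off the soma
    ais_len = _sample(rng, targets.ais_length_um, lo=5.0)
    u = np.array([0.0, -1.0, 0.3])
    u /= np.linalg.norm(u)
    p0 = soma_tip
    ais = add(soma.id, "ais", [p0, p0 + u * ais_len], [0.7, 0.5])

    # axon: a main section continuing the AIS plus 2-3 collaterals
    # branching from the main section's endpoint
    axon_len = _sample(rng, targets.axon_length_um, lo=50.0)
    n_coll = int(rng.integers(2, 4))
    start = ais.points[-1].copy()
    main_len = axon_len * 0.5
    main = add(ais.id, "axon", [start, start + u * main_len], [0.4, 0.3])
    branch_pt = main.points[-1].copy()
    rest = axon_len - main_len
    for _ in range(n_coll):
        length = rest / n_coll
        v = _jitter(u, rng, 1.0)
        add(main.id, "axon", [branch_pt, branch_pt + v * length], [0.3, 0.25])

    return Morphology(segments=segs, cell_id="sc-generated")


def _jitter(direction: np.ndarray, rng, scale: float) -> np.ndarray:
    v = direction + rng.normal(0.0, scale, size=3) * np.array([1.0, 1.0, 0.25])
    n = np.linalg.norm(v)
    if n < 1e-9:
        return direction
    return v / n


# ---------------------------------------------------------------------------
# Classification & morphometrics


def classify_compartments(
    morph: Morphology, cutoff_um: float = DENDRITE_DIAMETER_CUTOFF_UM
) -> dict[int, str]:
    """Map every segment id to one of the five electrotonic classes.

    Dendritic segments are proximal when their mean diameter is at or
    above the cut-off, distal below it.
    """
    if not morph.by_label("soma"):
        raise ValueError("morphology has no soma")
    out: dict[int, str] = {}
    for seg in morph.segments:
        if seg.label == "soma":
            out[seg.id] = "soma"
        elif seg.label == "ais":
            out[seg.id] = "ais"
        elif seg.label == "axon":
            out[seg.id] = "axon"
        else:
            out[seg.id] = (
                "proximal_dendrite" if seg.mean_diameter >= cutoff_um else "distal_dendrite"
            )
    return out


def morphometrics(morph: Morphology, cutoff_um: float = DENDRITE_DIAMETER_CUTOFF_UM) -> dict:
    """Summary morphometrics (soma surface, dendritic length, counts...)."""
    cls = classify_compartments(morph, cutoff_um)
    dend = morph.by_label("dendrite")
    return {
        "soma_surface_um2": sum(s.surface() for s in morph.by_label("soma")),
        "total_dendritic_length_um": sum(s.length for s in dend),
        "proximal_segment_count": sum(1 for s in dend if cls[s.id] == "proximal_dendrite"),
        "distal_segment_count": sum(1 for s in dend if cls[s.id] == "distal_dendrite"),
        "ais_length_um": sum(s.length for s in morph.by_label("ais")),
        "axon_length_um": sum(s.length for s in morph.by_label("axon")),
        "n_segments": len(morph.segments),
    }
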