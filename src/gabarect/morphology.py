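"""Neuronal morphologies: single-branch cables, a synthetic CA1-like tree, SWC I/O.

Sections are unbranched pieces of cable addressed by integer id; positions on a
section use the arc-length fraction ``x`` in [0, 1].  All distances reported by
:func:`path_distance` are path distances along the tree measured from the soma
root, with the soma itself treated as the zero point (a branch attached to the
soma starts at distance 0).

The synthetic CA1-like morphology is a parameterized stand-in, not a
reconstruction: it reproduces the layer structure (SO/SP/SR/SLM), the apical
trunk/oblique/tuft organisation, and declared synapse capacities per layer, but
its detailed geometry is generic.  Every synthetic morphology is labelled as
such in its ``comment`` field.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Section",
    "Location",
    "Morphology",
    "SynthCA1Params",
    "MorphologyError",
    "SWCParseError",
    "build_single_branch",
    "generate_synthetic_ca1",
    "read_swc",
    "write_swc",
    "path_distance",
]

TYPE_LABELS = ("soma", "basal", "apical_trunk", "apical_oblique", "tuft")
LAYER_TAGS = ("SO", "SP", "SR", "SLM")

#: Default layer tag for each section type.  The tuft => SLM mapping is a hard
#: invariant; the others are conventions of the CA1 layout.
TYPE_TO_LAYER = {
    "soma": "SP",
    "basal": "SO",
    "apical_trunk": "SR",
    "apical_oblique": "SR",
    "tuft": "SLM",
}

# SWC structure identifiers.  1/3/4 are standard; 5 and 6 are the conventional
# "custom" range, used here for obliques and tuft branches.
_TYPE_TO_SWC = {"soma": 1, "basal": 3, "apical_trunk": 4, "apical_oblique": 5, "tuft": 6}
_SWC_TO_TYPE = {v: k for k, v in _TYPE_TO_SWC.items()}


class MorphologyError(ValueError):
    """Invalid morphology geometry or topology."""


class SWCParseError(ValueError):
    """Malformed SWC content; carries the offending line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


@dataclass
class Section:
    id: int
    parent_id: int | None
    type_label: str
    layer_tag: str
    length_um: float
    diam_um: float
    #: arc-length fraction on the parent where this section attaches
    attach: float = 1.0
    #: optional 3D samples, shape (n, 4): x, y, z, radius (um)
    points: np.ndarray | None = None
    #: preferred compartment count for discretization (odd); None = use rule
    nseg: int | None = None

    def area_um2(self) -> float:
        """Lateral membrane area of the cylindrical section."""
        return math.pi * self.diam_um * self.length_um


@dataclass(frozen=True)
class Location:
    section_id: int
    x: float

    def __post_init__(self):
        if not 0.0 <= self.x <= 1.0:
            raise MorphologyError(f"location fraction {self.x} outside [0, 1]")


@dataclass
class Morphology:
    sections: dict[int, Section] = field(default_factory=dict)
    #: synapse placement slots: (layer_tag, kind) -> list of Location
    slots: dict[tuple[str, str], list[Location]] = field(default_factory=dict)
    comment: str = ""

    def __post_init__(self):
        self.validate()

    # -- structure ---------------------------------------------------------
    def validate(self) -> None:
        roots = [s for s in self.sections.values() if s.parent_id is None]
        if len(roots) != 1:
            raise MorphologyError(f"expected exactly one root, found {len(roots)}")
        if roots[0].type_label != "soma":
            raise MorphologyError("root section must be the soma")
        for s in self.sections.values():
            if s.length_um <= 0 or s.diam_um <= 0:
                raise MorphologyError(f"section {s.id}: non-positive geometry")
            if s.type_label not in TYPE_LABELS:
                raise MorphologyError(f"section {s.id}: unknown type {s.type_label!r}")
            if s.layer_tag not in LAYER_TAGS:
                raise MorphologyError(f"section {s.id}: unknown layer {s.layer_tag!r}")
            if s.type_label == "tuft" and s.layer_tag != "SLM":
                raise MorphologyError(f"section {s.id}: tuft sections must be tagged SLM")
            if s.parent_id is not None:
                if s.parent_id not in self.sections:
                    raise MorphologyError(f"section {s.id}: dangling parent {s.parent_id}")
                if not 0.0 <= s.attach <= 1.0:
                    raise MorphologyError(f"section {s.id}: attach fraction outside [0, 1]")

    @property
    def root(self) -> Section:
        return next(s for s in self.sections.values() if s.parent_id is None)

    def children(self, section_id: int) -> list[Section]:
        return [s for s in self.sections.values() if s.parent_id == section_id]

    def total_area_um2(self) -> float:
        return sum(s.area_um2() for s in self.sections.values())

    def total_length_um(self) -> float:
        return sum(s.length_um for s in self.sections.values())

    def capacity(self, layer: str, kind: str) -> int:
        return len(self.slots.get((layer, kind), ()))

    def sections_in_layer(self, layer: str) -> list[Section]:
        return [s for s in self.sections.values() if s.layer_tag == layer]


def path_distance(morph: Morphology, loc: Location) -> float:
    """Arc length (um) from the soma root to ``loc`` along the tree.

    The soma is the distance origin: every location on the soma section maps to
    0, and children measure from their attachment point.
    """
    if loc.section_id not in morph.sections:
        raise MorphologyError(f"unknown section {loc.section_id}")
    sec = morph.sections[loc.section_id]
    if sec.parent_id is None:
        return 0.0
    d = loc.x * sec.length_um
    while sec.parent_id is not None:
        parent = morph.sections[sec.parent_id]
        if parent.parent_id is not None:  # soma contributes zero
            d += sec.attach * parent.length_um
        sec = parent
    return d


# ---------------------------------------------------------------------------
# Constructors
# ---------------------------------------------------------------------------

def build_single_branch(length_um: float, diam_um: float, n_compartments: int = 1) -> Morphology:
    """A soma-attached unbranched passive cable, discretized into an odd number
    of compartments so that x = 0.5 falls on a compartment center."""
    if length_um <= 0 or diam_um <= 0:
        raise MorphologyError("length and diameter must be positive")
    if n_compartments < 1 or n_compartments % 2 == 0:
        raise MorphologyError("n_compartments must be a positive odd integer")
    soma = Section(0, None, "soma", "SP", length_um=1e-3, diam_um=1e-3, nseg=1)
    branch = Section(1, 0, "basal", "SO", length_um=length_um, diam_um=diam_um,
                     attach=1.0, nseg=n_compartments)
    return Morphology({0: soma, 1: branch}, comment="single branch")


@dataclass
class SynthCA1Params:
    """Geometry and capacity targets for the synthetic CA1-like stand-in."""

    soma_length_um: float = 20.0
    soma_diam_um: float = 20.0
    n_basal: int = 4
    basal_length_um: float = 150.0
    basal_diam_um: float = 1.0
    trunk_length_um: float = 400.0
    trunk_diam_um: float = 2.5
    n_obliques: int = 20
    oblique_length_um: float = 100.0
    oblique_diam_um: float = 0.8
    #: attachment distances of obliques on the trunk (start, end), um
    oblique_span_um: tuple[float, float] = (50.0, 290.0)
    #: branching pattern of the tuft: children per level, each level 100 um long
    tuft_fanout: tuple[int, ...] = (2, 3, 2)
    tuft_level_length_um: float = 100.0
    tuft_diams_um: tuple[float, ...] = (1.0, 0.7, 0.5)
    #: relative geometry jitter applied to oblique/tuft lengths (seeded)
    jitter: float = 0.05
    # synapse capacity targets
    sr_glut: int = 6000
    slm_glut: int = 1464
    slm_gaba: int = 280
    sr_gaba: int = 147


def _allocate(total: int, weights: np.ndarray) -> np.ndarray:
    """Largest-remainder allocation of ``total`` slots proportional to weights."""
    raw = total * weights / weights.sum()
    counts = np.floor(raw).astype(int)
    rem = total - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:rem]] += 1
    return counts


def generate_synthetic_ca1(seed: int = 0, params: SynthCA1Params | None = None) -> Morphology:
    """Seeded, parameterized CA1-like tree with declared synapse capacities.

    The tuft subtree starts at the distal end of the trunk, so every tuft
    location lies at a larger path distance than any oblique (SR) location.
    """
    p = params or SynthCA1Params()
    if p.n_obliques < 1 and p.sr_glut > 0:
        raise MorphologyError("cannot place SR synapses without oblique branches")
    if not p.tuft_fanout and (p.slm_glut > 0 or p.slm_gaba > 0):
        raise MorphologyError("cannot place SLM synapses without tuft branches")
    if len(p.tuft_fanout) != len(p.tuft_diams_um):
        raise MorphologyError("tuft_fanout and tuft_diams_um must have equal length")
    if p.oblique_span_um[1] + p.oblique_length_um * (1 + p.jitter) >= p.trunk_length_um:
        raise MorphologyError("oblique span reaches past the trunk end; tuft/SR ordering lost")

    rng = np.random.default_rng(seed)
    sections: dict[int, Section] = {}
    nid = 0

    def add(parent, tlabel, layer, L, d, attach=1.0):
        nonlocal nid
        sections[nid] = Section(nid, parent, tlabel, layer, L, d, attach)
        nid += 1
        return nid - 1

    soma = add(None, "soma", "SP", p.soma_length_um, p.soma_diam_um)
    for _ in range(p.n_basal):
        add(soma, "basal", "SO", p.basal_length_um, p.basal_diam_um)
    trunk = add(soma, "apical_trunk", "SR", p.trunk_length_um, p.trunk_diam_um)

    obliques = []
    for i in range(p.n_obliques):
        lo, hi = p.oblique_span_um
        dist = lo if p.n_obliques == 1 else lo + i * (hi - lo) / (p.n_obliques - 1)
        L = p.oblique_length_um * (1 + p.jitter * rng.uniform(-1, 1))
        obliques.append(add(trunk, "apical_oblique", "SR", L, p.oblique_diam_um,
                            attach=dist / p.trunk_length_um))

    tuft: list[int] = []
    frontier = [trunk]
    for level, (fan, diam) in enumerate(zip(p.tuft_fanout, p.tuft_diams_um)):
        nxt = []
        for parent in frontier:
            for _ in range(fan):
                L = p.tuft_level_length_um * (1 + p.jitter * rng.uniform(-1, 1))
                sid = add(parent, "tuft", "SLM", L, diam, attach=1.0)
                nxt.append(sid)
                tuft.append(sid)
        frontier = nxt

    morph = Morphology(sections, comment=f"synthetic CA1-like stand-in (seed={seed})")

    def make_slots(section_ids: list[int], total: int) -> list[Location]:
        lengths = np.array([sections[i].length_um for i in section_ids])
        counts = _allocate(total, lengths)
        locs = []
        for sid, n in zip(section_ids, counts):
            for k in range(n):
                locs.append(Location(sid, (k + 0.5) / n))
        return locs

    morph.slots[("SR", "glut")] = make_slots(obliques, p.sr_glut)
    morph.slots[("SR", "gaba")] = make_slots(obliques, p.sr_gaba)
    morph.slots[("SLM", "glut")] = make_slots(tuft, p.slm_glut)
    morph.slots[("SLM", "gaba")] = make_slots(tuft, p.slm_gaba)
    return morph


# ---------------------------------------------------------------------------
# SWC I/O
# ---------------------------------------------------------------------------

def _section_points(morph: Morphology) -> dict[int, np.ndarray]:
    """3D sample runs per section; synthesized deterministically when absent."""
    out = {}
    # lay sections out radially: direction keyed by section id, origin at the
    # distal end of the attachment point on the parent
    origin: dict[int, np.ndarray] = {}
    ends: dict[int, tuple[np.ndarray, np.ndarray]] = {}

    def direction(sec: Section) -> np.ndarray:
        ang = (sec.id * 2.399963) % (2 * math.pi)  # golden-angle spread
        if sec.type_label in ("apical_trunk", "tuft", "apical_oblique"):
            base = np.array([0.25 * math.cos(ang), 1.0, 0.25 * math.sin(ang)])
        elif sec.type_label == "basal":
            base = np.array([math.cos(ang), -1.0, math.sin(ang)])
        else:
            base = np.array([0.0, 1.0, 0.0])
        return base / np.linalg.norm(base)

    def visit(sec: Section, start: np.ndarray, axis_start: np.ndarray, axis_end: np.ndarray):
        if sec.points is not None:
            pts = sec.points.copy()
        else:
            d = direction(sec)
            n = max(2, int(math.ceil(sec.length_um / 25.0)) + 1)
            ts = np.linspace(0.0, sec.length_um, n)
            pts = np.column_stack([start[None, :] + ts[:, None] * d[None, :],
                                   np.full(n, sec.diam_um / 2.0)])
        out[sec.id] = pts
        ends[sec.id] = (pts[0, :3], pts[-1, :3])
        # children start exactly at the parent sample nearest their attachment
        # point, so the SWC parent link carries no cable length of its own
        seglen = np.linalg.norm(np.diff(pts[:, :3], axis=0), axis=1)
        arc = np.concatenate([[0.0], np.cumsum(seglen)])
        for ch in morph.children(sec.id):
            idx = int(np.argmin(np.abs(arc - ch.attach * arc[-1])))
            at = pts[idx, :3].copy()
            visit(ch, at, at, at)

    root = morph.root
    visit(root, np.zeros(3), np.zeros(3), np.zeros(3))
    return out


def write_swc(morph: Morphology, stream) -> None:
    """Serialize to standard 7-column SWC (one sample run per section)."""
    pts = _section_points(morph)
    lines = []
    sample_id = 0
    # sample index of the point nearest a given fraction of each section
    sec_sample: dict[int, tuple[int, np.ndarray]] = {}

    def nearest_sample(sec_id: int, frac: float) -> int:
        first, arr = sec_sample[sec_id]
        seglen = np.linalg.norm(np.diff(arr[:, :3], axis=0), axis=1)
        arc = np.concatenate([[0.0], np.cumsum(seglen)])
        idx = int(np.argmin(np.abs(arc - frac * arc[-1])))
        return first + idx

    def visit(sec: Section):
        nonlocal sample_id
        arr = pts[sec.id]
        swc_type = _TYPE_TO_SWC[sec.type_label]
        if sec.parent_id is None:
            parent_sample = -1
        else:
            parent_sample = nearest_sample(sec.parent_id, sec.attach) + 1
        first = sample_id
        for i, row in enumerate(arr):
            pid = parent_sample if i == 0 else sample_id  # previous sample
            lines.append(f"{sample_id + 1} {swc_type} "
                         f"{row[0]:.6f} {row[1]:.6f} {row[2]:.6f} {row[3]:.6f} {pid}")
            sample_id += 1
        sec_sample[sec.id] = (first, arr)
        for ch in morph.children(sec.id):
            visit(ch)

    lines.insert(0, f"# {morph.comment}" if morph.comment else "#")
    visit(morph.root)
    stream.write("\n".join(lines) + "\n")


def read_swc(stream) -> Morphology:
    """Parse standard 7-column SWC into a section-based morphology.

    Sample chains are split into sections at branch points and at structure-id
    changes; section length is the summed Euclidean distance of its samples.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    samples: dict[int, tuple[int, np.ndarray, float, int]] = {}  # id -> (type, xyz, r, parent)
    order: list[int] = []
    for ln, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        cols = line.split()
        if len(cols) != 7:
            raise SWCParseError(f"expected 7 columns, got {len(cols)}", ln)
        try:
            sid = int(cols[0]); styp = int(cols[1])
            xyz = np.array([float(c) for c in cols[2:5]])
            r = float(cols[5]); par = int(cols[6])
        except ValueError as e:
            raise SWCParseError(f"non-numeric field ({e})", ln) from None
        if par != -1 and par not in samples:
            raise SWCParseError(f"sample {sid} references missing parent {par}", ln)
        samples[sid] = (styp, xyz, r, par)
        order.append(sid)
    if not samples:
        raise SWCParseError("empty SWC", 0)

    children: dict[int, list[int]] = {}
    roots = []
    for sid in order:
        par = samples[sid][3]
        if par == -1:
            roots.append(sid)
        else:
            children.setdefault(par, []).append(sid)
    if len(roots) != 1:
        raise SWCParseError(f"expected one root sample, found {len(roots)}", 0)

    sections: dict[int, Section] = {}
    sec_of_sample: dict[int, tuple[int, float]] = {}  # sample -> (section, arc fraction)
    next_id = [0]

    def chain_from(start: int, parent_sec: int | None, attach: float):
        """Collect a non-branching run of same-type samples into one section."""
        run = [start]
        while True:
            kids = children.get(run[-1], [])
            if len(kids) == 1 and samples[kids[0]][0] == samples[run[-1]][0]:
                # peek: a child that itself is a branch point still ends the run
                run.append(kids[0])
                if len(children.get(kids[0], [])) > 1:
                    break
            else:
                break
        styp = samples[run[0]][0]
        # The cable segment from the parent sample to the first sample of the
        # run belongs to this section (standard convention), except across the
        # soma boundary where the link is a point attachment.  Writers produced
        # by this module place child samples exactly on a parent sample, so
        # the prepended segment has zero length for round-tripped files.
        par_sample = samples[run[0]][3]
        pts = []
        offset = 0
        if par_sample != -1 and samples[par_sample][0] != 1:
            pts.append(np.append(samples[par_sample][1], samples[par_sample][2]))
            offset = 1
        pts.extend(np.append(samples[sid][1], samples[sid][2]) for sid in run)
        arr = np.array(pts)
        seglen = np.linalg.norm(np.diff(arr[:, :3], axis=0), axis=1)
        length = float(seglen.sum())
        if length <= 0:
            length = 1e-3
        tlabel = _SWC_TO_TYPE.get(styp, "basal")
        sec_id = next_id[0]; next_id[0] += 1
        sections[sec_id] = Section(sec_id, parent_sec, tlabel, TYPE_TO_LAYER[tlabel],
                                   length_um=length,
                                   diam_um=float(2 * arr[offset:, 3].mean()),
                                   attach=attach, points=arr)
        arc = np.concatenate([[0.0], np.cumsum(seglen)])
        for i, sid in enumerate(run):
            frac = arc[i + offset] / arc[-1] if arc[-1] > 0 else 0.0
            sec_of_sample[sid] = (sec_id, frac)
        tail = run[-1]
        for kid in children.get(tail, []):
            if kid in sec_of_sample:
                continue
            chain_from(kid, sec_id, 1.0)
        # branch points mid-run cannot occur (run stops at them); children of
        # interior samples only arise off the root/soma chain
        for i, sid in enumerate(run[:-1]):
            for kid in children.get(sid, []):
                if kid not in sec_of_sample and kid not in run:
                    chain_from(kid, sec_id, sec_of_sample[sid][1])

    root = roots[0]
    # the soma chain: all contiguous type-1 samples
    chain_from(root, None, 0.5)
    # ensure root is soma-typed
    if sections[0].type_label != "soma":
        sections[0] = replace(sections[0], type_label="soma", layer_tag="SP")
    return Morphology(sections, comment="read from SWC")
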