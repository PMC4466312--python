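"""Template-guided alignment of 2D structures.

The aligner needs only (i) one or more "templates" — 3D structures already
posed in a shared frame — and (ii) candidate structures described by 2D
connectivity alone.  For every pairing of an anchor bond in the candidate
with an anchor bond in a template, a breadth-first simultaneous walk grows
the largest injective, connectivity-consistent atom mapping rooted at that
bond pair.  The best mapping wins (most matched atoms, then most
element-identical atoms, then deterministic index tie-breaks); template
coordinates are copied verbatim onto the matched candidate atoms; the
remaining atoms are placed by a canonical, purely rule-based "topomer"
procedure so that identical substituents at equivalent roots always
receive identical local geometry.

Atom compatibility during matching is topology-only: any heavy element may
match any heavy element.  Lenient matching is deliberate — predictive
field models tolerate (and benefit from) alignments that maximize the
number of coordinate-invariant atoms even when the element pairing looks
chemically odd.

Also here: the template-perturbation utilities (rigid separation of
templates, randomized conformation/pose) used as stress protocols, and
rigid-body RMS comparison of two alignments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdMolTransforms
from rdkit.Geometry import Point3D

from . import chem_io
from .chem_io import EmbedError

logger = logging.getLogger(__name__)

# covalent radii (Å) for standard bond-length construction during topomer
# placement; pairs not listed fall back to the periodic-table values
_PT = Chem.GetPeriodicTable()


def _bond_length(z1: int, z2: int) -> float:
    return _PT.GetRcovalent(z1) + _PT.GetRcovalent(z2)


def _canonical_ranks(mol: Chem.Mol) -> list[int]:
    return list(Chem.CanonicalRankAtoms(mol, breakTies=True))


def heavy_indices(mol: Chem.Mol) -> list[int]:
    return [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() > 1]


# ---------------------------------------------------------------------------
# anchor bonds and chain matching


def enumerate_anchor_bonds(mol: Chem.Mol) -> list[tuple[int, int]]:
    """Oriented anchor bonds of a molecule, in deterministic order.

    Suitable anchors are acyclic single bonds between heavy atoms, taken in
    both orientations.  A molecule with no such bond (a bare ring system)
    falls back to its ring bonds so that rigid structures remain alignable.
    """
    if len(heavy_indices(mol)) < 2:
        return []
    acyclic, ring = [], []
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if bond.GetBeginAtom().GetAtomicNum() <= 1 or bond.GetEndAtom().GetAtomicNum() <= 1:
            continue
        if bond.IsInRing():
            ring.append((i, j))
        elif bond.GetBondType() == Chem.BondType.SINGLE:
            acyclic.append((i, j))
    chosen = acyclic if acyclic else ring
    oriented = [(i, j) for i, j in chosen] + [(j, i) for i, j in chosen]
    oriented.sort()
    return oriented


@dataclass
class AtomMatch:
    """An anchor-rooted injective mapping candidate-atom -> template-atom."""

    template_index: int
    template_anchor: tuple[int, int]
    candidate_anchor: tuple[int, int]
    mapping: dict[int, int] = field(default_factory=dict)

    @property
    def matched_count(self) -> int:
        return len(self.mapping)

    def element_identical_count(self, candidate: Chem.Mol, template: Chem.Mol) -> int:
        return sum(
            1
            for c, t in self.mapping.items()
            if candidate.GetAtomWithIdx(c).GetAtomicNum()
            == template.GetAtomWithIdx(t).GetAtomicNum()
        )


def match_chains(
    candidate: Chem.Mol,
    template: Chem.Mol,
    cand_anchor: tuple[int, int],
    tmpl_anchor: tuple[int, int],
    template_index: int = 0,
) -> AtomMatch:
    """Grow the anchor-rooted atom-chain match by simultaneous BFS.

    Starting from the superimposed anchor pair, each dequeued matched pair
    tries to extend the mapping across its still-unmapped heavy neighbors.
    Neighbor pairing is deterministic: candidate neighbors are visited in
    canonical-rank order and each takes, preferentially, an element-identical
    template neighbor (again in canonical-rank order), else the first
    available one.  The result is maximal under these growth rules; the
    minimum mapping is the two anchor endpoints.
    """
    cr = _canonical_ranks(candidate)
    tr = _canonical_ranks(template)
    k, l = cand_anchor
    i, j = tmpl_anchor
    mapping = {k: i, l: j}
    used_t = {i, j}
    queue = [(k, i), (l, j)]
    while queue:
        c, t = queue.pop(0)
        c_nb = sorted(
            (
                n.GetIdx()
                for n in candidate.GetAtomWithIdx(c).GetNeighbors()
                if n.GetAtomicNum() > 1 and n.GetIdx() not in mapping
            ),
            key=lambda idx: cr[idx],
        )
        t_nb = sorted(
            (
                n.GetIdx()
                for n in template.GetAtomWithIdx(t).GetNeighbors()
                if n.GetAtomicNum() > 1 and n.GetIdx() not in used_t
            ),
            key=lambda idx: tr[idx],
        )
        for cn in c_nb:
            if not t_nb:
                break
            zc = candidate.GetAtomWithIdx(cn).GetAtomicNum()
            same = [tn for tn in t_nb if template.GetAtomWithIdx(tn).GetAtomicNum() == zc]
            tn = same[0] if same else t_nb[0]
            t_nb.remove(tn)
            mapping[cn] = tn
            used_t.add(tn)
            queue.append((cn, tn))
    return AtomMatch(template_index, tmpl_anchor, cand_anchor, mapping)


# ---------------------------------------------------------------------------
# topomer completion


def _ring_systems(mol: Chem.Mol) -> list[set[int]]:
    """Fused ring systems as disjoint atom-index sets."""
    systems: list[set[int]] = []
    for ring in mol.GetRingInfo().AtomRings():
        ring = set(ring)
        merged = [s for s in systems if s & ring]
        for s in merged:
            systems.remove(s)
            ring |= s
        systems.append(ring)
    return systems


def _rotation_about_axis(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    c, s = np.cos(angle), np.sin(angle)
    x, y, z = axis
    K = np.array([[0, -z, y], [z, 0, -x], [-y, x, 0]])
    return c * np.eye(3) + s * K + (1 - c) * np.outer(axis, axis)


def _place_by_zmatrix(
    pos_c: np.ndarray,
    pos_b: np.ndarray | None,
    pos_a: np.ndarray | None,
    length: float,
    angle_deg: float,
    torsion_deg: float,
) -> np.ndarray:
    """Position a new atom d bonded to c with internal coordinates
    (length d–c, angle d–c–b, torsion d–c–b–a).  Missing references fall
    back to fixed global directions so the construction stays total."""
    if pos_b is None:
        pos_b = pos_c + np.array([1.0, 0.0, 0.0])
    if pos_a is None:
        u = pos_c - pos_b
        ref = np.array([0.0, 0.0, 1.0])
        if np.linalg.norm(np.cross(u, ref)) < 1e-8:
            ref = np.array([0.0, 1.0, 0.0])
        pos_a = pos_b + ref
    bc = pos_c - pos_b
    bc /= np.linalg.norm(bc)
    ab = pos_b - pos_a
    n = np.cross(ab, bc)
    if np.linalg.norm(n) < 1e-8:
        ref = np.array([0.0, 0.0, 1.0])
        if abs(np.dot(bc, ref)) > 0.99:
            ref = np.array([0.0, 1.0, 0.0])
        n = np.cross(ref, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    ang = np.deg2rad(angle_deg)
    tor = np.deg2rad(torsion_deg)
    d_local = length * np.array(
        [-np.cos(ang), np.sin(ang) * np.cos(tor), np.sin(ang) * np.sin(tor)]
    )
    frame = np.column_stack([bc, m, n])
    return pos_c + frame @ d_local


_ANGLE_BY_HYB = {
    Chem.HybridizationType.SP: 180.0,
    Chem.HybridizationType.SP2: 120.0,
    Chem.HybridizationType.SP3: 109.471,
}

# canonical torsion sequence: first branch anti-periplanar, later branches
# staggered in a fixed order
_TORSION_SEQUENCE = [180.0, 60.0, -60.0, 0.0, 120.0, -120.0]


def topomer_place(
    mol: Chem.Mol,
    placed: set[int],
    ref_mol: Chem.Mol | None = None,
) -> tuple[Chem.Mol, list[int]]:
    """Complete the heavy-atom geometry of ``mol`` from a placed subset.

    Unplaced atoms are positioned by canonical rules only — standard bond
    lengths, hybridization-standard angles, every acyclic torsion
    anti-periplanar (later branches staggered in a fixed sequence), branch
    order by canonical atom rank — so the result depends only on the graph,
    the placed set and the frame of the placed atoms, never on input
    coordinates of unplaced atoms.  Ring systems are attached rigidly in
    their reference local geometry (``ref_mol``, a 3D embedding of the same
    graph), oriented by the same anti-periplanar attachment rule; a ring
    system with three or more already-placed atoms is completed by
    least-squares superposition of the reference geometry instead.

    Returns the molecule with a full heavy-atom conformer and the list of
    atoms that were topomer-placed.
    """
    mol = Chem.Mol(mol)
    heavy = set(heavy_indices(mol))
    if not placed <= set(range(mol.GetNumAtoms())):
        raise ValueError("placed set contains invalid atom indices")
    unplaced = heavy - placed
    if not unplaced:
        return mol, []
    remainder_ok = all(
        any(n.GetIdx() in heavy for n in mol.GetAtomWithIdx(a).GetNeighbors())
        for a in unplaced
    )
    if not remainder_ok:
        raise ValueError("disconnected remainder: isolated unplaced atom")
    if ref_mol is None:
        ref_mol = chem_io.embed_3d(mol, seed=0)
    ref_xyz = chem_io.coordinates(ref_mol)

    conf = mol.GetConformer()
    ranks = _canonical_ranks(mol)
    systems = _ring_systems(mol)
    ring_of = {}
    for s in systems:
        for a in s:
            ring_of[a] = frozenset(s)
    pos = {a: np.array(conf.GetAtomPosition(a)) for a in placed}
    # per-root count of already-attached branches drives the staggered
    # torsion sequence
    branch_count: dict[int, int] = {}
    placed_order: list[int] = []

    def frontier() -> list[tuple[int, int]]:
        edges = []
        for c in pos:
            for nb in mol.GetAtomWithIdx(c).GetNeighbors():
                d = nb.GetIdx()
                if d in heavy and d not in pos:
                    edges.append((c, d))
        edges.sort(key=lambda e: (ranks[e[0]], ranks[e[1]]))
        return edges

    def references(c: int, exclude: int) -> tuple[np.ndarray | None, np.ndarray | None]:
        nbs = sorted(
            (n.GetIdx() for n in mol.GetAtomWithIdx(c).GetNeighbors()
             if n.GetIdx() in pos and n.GetIdx() != exclude),
            key=lambda idx: ranks[idx],
        )
        if not nbs:
            return None, None
        b = nbs[0]
        nbs2 = sorted(
            (n.GetIdx() for n in mol.GetAtomWithIdx(b).GetNeighbors()
             if n.GetIdx() in pos and n.GetIdx() != c),
            key=lambda idx: ranks[idx],
        )
        return pos[b], (pos[nbs2[0]] if nbs2 else None)

    def target_position(c: int, d: int) -> np.ndarray:
        zc = mol.GetAtomWithIdx(c).GetAtomicNum()
        zd = mol.GetAtomWithIdx(d).GetAtomicNum()
        hyb = mol.GetAtomWithIdx(c).GetHybridization()
        angle = _ANGLE_BY_HYB.get(hyb, 109.471)
        k = branch_count.get(c, 0)
        torsion = _TORSION_SEQUENCE[k % len(_TORSION_SEQUENCE)]
        branch_count[c] = k + 1
        pb, pa = references(c, exclude=d)
        return _place_by_zmatrix(pos[c], pb, pa, _bond_length(zc, zd), angle, torsion)

    def place_ring_system(c: int, d: int, system: frozenset[int]) -> None:
        already = sorted(system & set(pos))
        missing = sorted(a for a in system if a not in pos)
        if len(already) >= 3:
            A = ref_xyz[already]
            B = np.array([pos[a] for a in already])
            R, t = _kabsch(A, B)
            for a in missing:
                pos[a] = R @ ref_xyz[a] + t
                placed_order.append(a)
            return
        # rigid attach through the entry bond c-d
        target_d = target_position(c, d)
        u_ref = ref_xyz[d] - ref_xyz[c]
        u_tgt = target_d - pos[c]
        R1 = _align_vectors(u_ref, u_tgt)
        # spin about the entry bond: highest-priority ring neighbor of d
        # goes anti-periplanar to the reference atom behind c
        ring_nbs = sorted(
            (n.GetIdx() for n in mol.GetAtomWithIdx(d).GetNeighbors()
             if n.GetIdx() in system),
            key=lambda idx: ranks[idx],
        )
        pb, _ = references(c, exclude=d)
        xyz0 = {a: R1 @ (ref_xyz[a] - ref_xyz[d]) + target_d for a in system}
        if ring_nbs and pb is not None:
            e = ring_nbs[0]
            axis = target_d - pos[c]
            cur = _torsion(pb, pos[c], target_d, xyz0[e])
            spin = _rotation_about_axis(axis, np.deg2rad(180.0) - cur)
            xyz0 = {a: spin @ (p - target_d) + target_d for a, p in xyz0.items()}
        for a in sorted(system, key=lambda idx: ranks[idx]):
            if a not in pos:
                pos[a] = xyz0[a]
                placed_order.append(a)

    while True:
        edges = frontier()
        if not edges:
            break
        c, d = edges[0]
        if d in ring_of:
            place_ring_system(c, d, ring_of[d])
        else:
            pos[d] = target_position(c, d)
            placed_order.append(d)

    if set(pos) != heavy | (placed & set(range(mol.GetNumAtoms()))):
        missing = heavy - set(pos)
        if missing:
            raise ValueError(f"could not place atoms {sorted(missing)}")
    for a, p in pos.items():
        conf.SetAtomPosition(a, Point3D(*p))
    return mol, placed_order


def _torsion(p0, p1, p2, p3) -> float:
    b0, b1, b2 = p1 - p0, p2 - p1, p3 - p2
    n0, n1 = np.cross(b0, b1), np.cross(b1, b2)
    m = np.cross(n0, b1 / np.linalg.norm(b1))
    return float(np.arctan2(np.dot(m, n1), np.dot(n0, n1)))


def _align_vectors(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Minimal rotation taking direction u onto direction v."""
    u = u / np.linalg.norm(u)
    v = v / np.linalg.norm(v)
    axis = np.cross(u, v)
    s = np.linalg.norm(axis)
    c = float(np.dot(u, v))
    if s < 1e-12:
        if c > 0:
            return np.eye(3)
        ref = np.array([1.0, 0.0, 0.0])
        if abs(u[0]) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        axis = np.cross(u, ref)
        return _rotation_about_axis(axis, np.pi)
    return _rotation_about_axis(axis / s, float(np.arctan2(s, c)))


# ---------------------------------------------------------------------------
# full alignment


@dataclass
class AlignmentResult:
    """Outcome of aligning one candidate against a template set."""

    mol: Chem.Mol | None
    status: str  # "aligned" | "failed"
    template_id: str | None = None
    matched_atoms: list[int] = field(default_factory=list)
    topomer_atoms: list[int] = field(default_factory=list)
    reason: str | None = None

    @property
    def ok(self) -> bool:
        return self.status == "aligned"


class TemplateAligner:
    """Aligns 2D candidates to a fixed set of pre-posed 3D templates.

    Parameters
    ----------
    templates : sequence of rdkit Mol
        3D structures in one shared frame; every template must carry a
        conformer.
    """

    def __init__(self, templates):
        templates = list(templates)
        if not templates:
            raise ValueError("at least one template is required")
        for t in templates:
            if t.GetNumConformers() == 0:
                raise ValueError("templates must have 3D coordinates")
        self.templates = templates
        self._anchor_cache = [enumerate_anchor_bonds(t) for t in templates]

    def best_match(self, candidate: Chem.Mol) -> AtomMatch | None:
        """Best anchor-rooted match of the candidate over all templates.

        Ranking: (1) most matched atoms, (2) most element-identical matched
        atoms, (3) lowest template index, (4) lowest oriented candidate
        anchor, (5) lowest oriented template anchor.
        """
        cand_anchors = enumerate_anchor_bonds(candidate)
        if not cand_anchors:
            return None
        best: AtomMatch | None = None
        best_key: tuple | None = None
        for t_idx, (template, t_anchors) in enumerate(
            zip(self.templates, self._anchor_cache)
        ):
            for ca_idx, ca in enumerate(cand_anchors):
                for ta_idx, ta in enumerate(t_anchors):
                    m = match_chains(candidate, template, ca, ta, t_idx)
                    key = (
                        m.matched_count,
                        m.element_identical_count(candidate, template),
                        -t_idx,
                        -ca_idx,
                        -ta_idx,
                    )
                    if best_key is None or key > best_key:
                        best, best_key = m, key
        return best

    def align(self, candidate: Chem.Mol, seed: int = 0) -> AlignmentResult:
        """Align one 2D candidate: embed, match, copy, topomer-complete.

        The matched candidate atoms receive their template partners'
        coordinates verbatim (even where that distorts candidate valence
        geometry); the remaining heavy atoms are topomer-placed; hydrogens
        are added by standard geometry last.
        """
        cand = Chem.RemoveHs(Chem.Mol(candidate))
        if len(heavy_indices(cand)) < 2:
            return AlignmentResult(None, "failed", reason="fewer than 2 heavy atoms")
        try:
            embedded = chem_io.embed_3d(cand, seed=seed)
        except EmbedError as exc:
            return AlignmentResult(None, "failed", reason=str(exc))
        match = self.best_match(cand)
        if match is None:
            return AlignmentResult(None, "failed", reason="no anchor bonds")
        template = self.templates[match.template_index]
        t_conf = template.GetConformer()
        work = Chem.RemoveHs(Chem.Mol(embedded))
        conf = work.GetConformer()
        for c_idx, t_idx in match.mapping.items():
            conf.SetAtomPosition(c_idx, t_conf.GetAtomPosition(t_idx))
        try:
            placed_mol, topo_atoms = topomer_place(
                work, set(match.mapping), ref_mol=embedded
            )
        except ValueError as exc:
            return AlignmentResult(None, "failed", reason=str(exc))
        out = Chem.AddHs(placed_mol, addCoords=True)
        if candidate.HasProp("_Name"):
            out.SetProp("_Name", candidate.GetProp("_Name"))
        out.SetProp("template_id", chem_io.mol_id(template) or str(match.template_index))
        out.SetProp("matched_atoms", ",".join(map(str, sorted(match.mapping))))
        return AlignmentResult(
            out,
            "aligned",
            template_id=chem_io.mol_id(template) or str(match.template_index),
            matched_atoms=sorted(match.mapping),
            topomer_atoms=topo_atoms,
        )


def align_to_templates(candidate: Chem.Mol, templates, seed: int = 0) -> AlignmentResult:
    """Functional wrapper over :class:`TemplateAligner` for one candidate."""
    return TemplateAligner(templates).align(candidate, seed=seed)


# ---------------------------------------------------------------------------
# template perturbation protocols


def separate_templates(templates, min_gap: float = 3.0) -> list[Chem.Mol]:
    """Rigidly translate templates apart until every inter-template
    heavy-atom distance is at least ``min_gap`` Å.

    Templates are strung out along x: each is shifted so its bounding box
    starts ``min_gap`` beyond the previous template's box.  Intramolecular
    geometry is untouched.
    """
    out: list[Chem.Mol] = []
    prev_max_x = None
    for t in templates:
        t = Chem.Mol(t)
        xyz = chem_io.coordinates(t)
        if prev_max_x is not None:
            shift = prev_max_x + min_gap - xyz[:, 0].min()
            conf = t.GetConformer()
            for i in range(t.GetNumAtoms()):
                p = conf.GetAtomPosition(i)
                conf.SetAtomPosition(i, Point3D(p.x + shift, p.y, p.z))
            xyz = chem_io.coordinates(t)
        prev_max_x = xyz[:, 0].max()
        out.append(t)
    return out


def _rotatable_torsions(mol: Chem.Mol) -> list[tuple[int, int, int, int]]:
    ranks = _canonical_ranks(mol)
    torsions = []
    for bond in mol.GetBonds():
        if bond.IsInRing() or bond.GetBondType() != Chem.BondType.SINGLE:
            continue
        b, c = bond.GetBeginAtom(), bond.GetEndAtom()
        if b.GetAtomicNum() <= 1 or c.GetAtomicNum() <= 1:
            continue
        b_nb = sorted(
            (n.GetIdx() for n in b.GetNeighbors()
             if n.GetIdx() != c.GetIdx() and n.GetAtomicNum() > 1),
            key=lambda i: ranks[i],
        )
        c_nb = sorted(
            (n.GetIdx() for n in c.GetNeighbors()
             if n.GetIdx() != b.GetIdx() and n.GetAtomicNum() > 1),
            key=lambda i: ranks[i],
        )
        if b_nb and c_nb:
            torsions.append((b_nb[0], b.GetIdx(), c.GetIdx(), c_nb[0]))
    return torsions


def randomize_pose(mol: Chem.Mol, seed: int) -> Chem.Mol:
    """Scramble conformation and pose, deterministically per seed.

    All adjustable (acyclic single-bond) torsions are set to random values;
    then three randomly chosen heavy atoms are posed successively at the
    origin, along the +x axis, and into the x–y plane; finally the
    heavy-atom centroid is moved to the origin.  All moves are rigid or
    torsional, so bond lengths and angles are preserved.
    """
    mol = Chem.Mol(mol)
    if mol.GetNumConformers() == 0:
        raise ValueError("randomize_pose needs coordinates")
    rng = np.random.default_rng(seed)
    conf = mol.GetConformer()
    for a, b, c, d in _rotatable_torsions(mol):
        rdMolTransforms.SetDihedralDeg(conf, a, b, c, d, float(rng.uniform(0.0, 360.0)))
    heavies = heavy_indices(mol)
    xyz = np.asarray(conf.GetPositions(), dtype=float)
    if len(heavies) >= 3:
        p1, p2, p3 = (int(i) for i in rng.choice(heavies, size=3, replace=False))
        xyz = xyz - xyz[p1]
        R1 = _align_vectors(xyz[p2], np.array([1.0, 0.0, 0.0]))
        xyz = xyz @ R1.T
        v = xyz[p3].copy()
        v[0] = 0.0
        if np.linalg.norm(v) > 1e-9:
            ang = np.arctan2(v[2], v[1])
            R2 = _rotation_about_axis(np.array([1.0, 0.0, 0.0]), -ang)
            xyz = xyz @ R2.T
    xyz = xyz - xyz[heavies].mean(axis=0)
    for i in range(mol.GetNumAtoms()):
        conf.SetAtomPosition(i, Point3D(*xyz[i]))
    return mol


# ---------------------------------------------------------------------------
# alignment comparison


def _kabsch(A: np.ndarray, B: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Proper rotation R and translation t minimizing ||R A + t − B||²."""
    ca, cb = A.mean(axis=0), B.mean(axis=0)
    H = (A - ca).T @ (B - cb)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    return R, cb - R @ ca


def rigid_fit_rms(
    a: np.ndarray, b: np.ndarray, correspondence=None
) -> float:
    """RMS of distances between corresponding atoms after a least-squares
    rigid-body fit (rotation + translation, no reflection).

    ``correspondence`` maps rows of ``a`` to rows of ``b``; identity when
    omitted.  At least 3 correspondences are required.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if correspondence is not None:
        pairs = list(correspondence)
        a = a[[p[0] for p in pairs]]
        b = b[[p[1] for p in pairs]]
    if a.shape != b.shape or a.shape[0] < 3:
        raise ValueError("rigid fit needs >= 3 corresponding points")
    R, t = _kabsch(a, b)
    d = (a @ R.T + t) - b
    return float(np.sqrt(np.mean(np.sum(d**2, axis=1))))
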