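"""Molecular graph I/O and preparation.

Molecules are plain :class:`rdkit.Chem.Mol` objects carrying an ``_Name``
property as their identifier.  This module covers everything upstream of
alignment: reading/writing SDF (V2000) and SMILES tables, protomer
neutralization, Gasteiger partial charges, a deterministic 3D embedder,
and the "reduced skeleton" diversity key (the generic ring-and-linker
graph left after erasing atom/bond types and pruning terminal atoms).
"""

from __future__ import annotations

import csv
import logging
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem, Descriptors

logger = logging.getLogger(__name__)


class EmbedError(RuntimeError):
    """Raised when no 3D geometry can be generated for a molecule."""


def mol_id(mol: Chem.Mol) -> str:
    """Identifier of a molecule (the SDF title line / ``_Name`` property)."""
    return mol.GetProp("_Name") if mol.HasProp("_Name") else ""


def set_mol_id(mol: Chem.Mol, mid: str) -> Chem.Mol:
    mol.SetProp("_Name", str(mid))
    return mol


def largest_fragment(mol: Chem.Mol) -> Chem.Mol:
    """Strip salts/counter-ions: keep the fragment with most heavy atoms."""
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) <= 1:
        return mol
    best = max(frags, key=lambda f: f.GetNumHeavyAtoms())
    logger.warning("multi-fragment record %r reduced to largest fragment", mol_id(mol))
    if mol.HasProp("_Name"):
        best.SetProp("_Name", mol.GetProp("_Name"))
    return best


def read_structures(path: str, fmt: str | None = None) -> list[Chem.Mol]:
    """Read molecules from an SDF (``sdf``) or a SMILES CSV (``smiles-csv``).

    The CSV dialect expects a ``smiles`` column and, if present, a
    ``compound_id`` column used as the molecule id.  Unparseable records are
    skipped with a logged warning carrying the record index; input order is
    otherwise preserved.  Multi-fragment records are reduced to their
    largest fragment.
    """
    if fmt is None:
        fmt = "smiles-csv" if path.lower().endswith((".csv", ".smi")) else "sdf"
    mols: list[Chem.Mol] = []
    if fmt == "sdf":
        import os

        if os.path.getsize(path) == 0:
            return []
        supplier = Chem.SDMolSupplier(path, removeHs=False, sanitize=True)
        for i, mol in enumerate(supplier):
            if mol is None:
                logger.warning("unparseable SDF record %d in %s: skipped", i, path)
                continue
            Chem.RemoveStereochemistry(mol)  # 2D connectivity drives everything
            mols.append(largest_fragment(mol))
    elif fmt == "smiles-csv":
        with open(path, newline="") as fh:
            for i, row in enumerate(csv.DictReader(fh)):
                mol = Chem.MolFromSmiles(row["smiles"])
                if mol is None:
                    logger.warning("unparseable SMILES record %d in %s: skipped", i, path)
                    continue
                set_mol_id(mol, row.get("compound_id", str(i)))
                mols.append(largest_fragment(mol))
    else:
        raise ValueError(f"unknown format: {fmt!r}")
    return mols


def write_sdf(mols: Iterable[Chem.Mol], path: str) -> None:
    """Write molecules as SDF V2000 (coordinates in Å when present)."""
    writer = Chem.SDWriter(path)
    writer.SetForceV3000(False)
    for mol in mols:
        writer.write(mol)
    writer.close()


def neutralize(mol: Chem.Mol) -> Chem.Mol:
    """Return the neutral protomer: formal charges zeroed where a proton
    can be added or removed.  Permanent charges (e.g. quaternary nitrogen,
    which carries no proton to surrender) are untouched; the heavy-atom
    graph is otherwise unchanged.  Idempotent.
    """
    out = Chem.RWMol(mol)
    for atom in out.GetAtoms():
        fc = atom.GetFormalCharge()
        if fc == 0:
            continue
        h = atom.GetTotalNumHs()
        if fc > 0:
            if h >= fc:  # protonated site: remove fc protons
                atom.SetFormalCharge(0)
                atom.SetNumExplicitHs(h - fc)
                atom.SetNoImplicit(True)
            # else permanent cation (quaternary N etc.): leave alone
        else:  # deprotonated site: add |fc| protons
            atom.SetFormalCharge(0)
            atom.SetNumExplicitHs(h - fc)
            atom.SetNoImplicit(True)
    result = out.GetMol()
    try:
        Chem.SanitizeMol(result)
    except Exception:  # chemically impossible adjustment: fall back to input
        return Chem.Mol(mol)
    if mol.HasProp("_Name"):
        result.SetProp("_Name", mol.GetProp("_Name"))
    return result


def assign_charges(mol: Chem.Mol) -> Chem.Mol:
    """Assign Gasteiger–Marsili partial charges (property ``_GasteigerCharge``).

    Charges are computed on the molecule as given (call :func:`neutralize`
    first if neutral protomers are wanted) and sum to the total formal
    charge to within numerical tolerance.
    """
    mol = Chem.Mol(mol)
    AllChem.ComputeGasteigerCharges(mol)
    return mol


def partial_charges(mol: Chem.Mol) -> np.ndarray:
    """Per-atom Gasteiger charges in e, in atom-index order."""
    return np.array(
        [float(a.GetProp("_GasteigerCharge")) for a in mol.GetAtoms()], dtype=float
    )


def _canonical_order(mol: Chem.Mol) -> list[int]:
    ranks = list(Chem.CanonicalRankAtoms(mol, breakTies=True))
    order = [0] * len(ranks)
    for idx, rank in enumerate(ranks):
        order[rank] = idx
    return order


def embed_3d(mol: Chem.Mol, seed: int = 0, optimize: bool = True) -> Chem.Mol:
    """Deterministic 3D embedding (distance geometry + MMFF94 relaxation).

    The conformer is a pure function of the molecular graph and the seed:
    the molecule is renumbered into canonical atom order before embedding,
    so two differently-ordered inputs of the same graph receive identical
    geometries (mapped back to the input order).  Heavy atoms keep their
    input indices; explicit hydrogens are appended after them.

    Raises :class:`EmbedError` when no valence-consistent geometry can be
    produced.
    """
    heavy = Chem.RemoveHs(Chem.Mol(mol))
    n = heavy.GetNumAtoms()
    # rebuild from canonical SMILES: atom AND bond order become pure
    # functions of the graph, so the embedding is too
    smi = Chem.MolToSmiles(heavy)
    out_order = [
        int(tok)
        for tok in heavy.GetProp("_smilesAtomOutputOrder").strip("[]").split(",")
        if tok.strip()
    ]
    canon = Chem.MolFromSmiles(smi)
    if canon is None or canon.GetNumAtoms() != n:
        raise EmbedError(f"cannot canonicalize {mol_id(mol)!r}")
    order = out_order  # canon atom i corresponds to heavy atom order[i]
    canon_h = Chem.AddHs(canon)
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed) % (2**31 - 1)
    params.useRandomCoords = False
    if AllChem.EmbedMolecule(canon_h, params) != 0:
        params.useRandomCoords = True
        if AllChem.EmbedMolecule(canon_h, params) != 0:
            raise EmbedError(f"embedding failed for {mol_id(mol)!r}")
    if optimize:
        try:
            AllChem.MMFFOptimizeMolecule(canon_h, maxIters=500)
        except Exception:
            pass  # unparameterized atom types: keep DG geometry
    # undo the canonical renumbering for the heavy block; hydrogens stay last
    inverse = [0] * canon_h.GetNumAtoms()
    for new_idx, old_idx in enumerate(order):
        inverse[old_idx] = new_idx
    for h_idx in range(n, canon_h.GetNumAtoms()):
        inverse[h_idx] = h_idx
    out = Chem.RenumberAtoms(canon_h, inverse)
    Chem.SanitizeMol(out)
    if mol.HasProp("_Name"):
        out.SetProp("_Name", mol.GetProp("_Name"))
    return out


def coordinates(mol: Chem.Mol, heavy_only: bool = False) -> np.ndarray:
    """Conformer coordinates as an (n, 3) array in Å."""
    if mol.GetNumConformers() == 0:
        raise ValueError("molecule has no conformer")
    xyz = np.asarray(mol.GetConformer().GetPositions(), dtype=float)
    if heavy_only:
        keep = [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() > 1]
        xyz = xyz[keep]
    return xyz


def reduced_skeleton(mol: Chem.Mol) -> str | None:
    """Canonical key of the molecule's reduced skeleton, or None if acyclic.

    The skeleton is obtained by removing hydrogens, erasing all atom and
    bond types to a generic type, and iteratively deleting terminal atoms
    until none remain — leaving only the connected ring systems and the
    chains linking them.  The key is the canonical serialization of that
    generic graph, invariant under atom reordering of the input.
    """
    em = Chem.RWMol(Chem.RemoveHs(Chem.Mol(mol)))
    while True:
        terminal = [a.GetIdx() for a in em.GetAtoms() if a.GetDegree() <= 1]
        if not terminal:
            break
        for idx in sorted(terminal, reverse=True):
            em.RemoveAtom(idx)
    if em.GetNumAtoms() == 0:
        return None
    for atom in em.GetAtoms():
        atom.SetAtomicNum(6)
        atom.SetFormalCharge(0)
        atom.SetIsAromatic(False)
        atom.SetNoImplicit(True)
        atom.SetNumExplicitHs(0)
    for bond in em.GetBonds():
        bond.SetBondType(Chem.BondType.SINGLE)
        bond.SetIsAromatic(False)
    generic = em.GetMol()
    Chem.SanitizeMol(generic, Chem.SanitizeFlags.SANITIZE_SYMMRINGS)
    return Chem.MolToSmiles(generic)


def count_reduced_skeletons(mols: Sequence[Chem.Mol]) -> int:
    """Number of distinct reduced skeletons in a molecule collection."""
    return len({k for k in (reduced_skeleton(m) for m in mols) if k is not None})


def molecular_weight(mol: Chem.Mol) -> float:
    """Average molecular weight in g/mol (hydrogens included)."""
    return float(Descriptors.MolWt(mol))
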