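"""CoMFA lattice regions and molecular interaction fields.

A "region" is a Cartesian lattice enclosing all training structures with a
margin (default 2 Å beyond the union extents, 2 Å spacing).  At every
lattice point a probe atom (sp3 carbon, +1 e charge by default) feels a
steric 6-12 Lennard-Jones potential and a Coulomb electrostatic potential
with distance-dependent dielectric ε(r) = r, both in kcal/mol:

    E_steric(p) = Σ_a ε_ap [ (R_ap / r)^12 − 2 (R_ap / r)^6 ],  capped above
    E_elec(p)   = 332.0637 Σ_a q_a q_probe / r²,                clipped

with R_ap = R*_a + R*_probe and ε_ap = sqrt(ε_a ε_probe).  The steric sum
is capped at the steric cutoff (default 30 kcal/mol); where the cap is hit
the point lies inside the molecular envelope and the electrostatic value
is flagged for column-mean imputation during pretreatment (the classic
convention).  Note the attractive well makes small negative steric values
legitimate.

Pretreatment (imputation, minimum-sigma column drop, centering, optional
block-variance "CoMFA standard" scaling) is fit on the training table and
applied unchanged to prediction rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from rdkit import Chem

from . import chem_io

COULOMB_KCAL = 332.0637  # kcal·Å/(mol·e²)

#: Tripos-style van der Waals parameters per element: (R* Å, ε kcal/mol)
VDW_PARAMS: dict[str, tuple[float, float]] = {
    "H": (1.50, 0.042),
    "C": (1.70, 0.107),
    "N": (1.55, 0.095),
    "O": (1.52, 0.116),
    "F": (1.47, 0.109),
    "P": (1.80, 0.314),
    "S": (1.80, 0.314),
    "Cl": (1.75, 0.344),
    "Br": (1.85, 0.434),
    "I": (1.98, 0.623),
}
_DEFAULT_VDW = (1.70, 0.107)


@dataclass(frozen=True)
class Probe:
    """The probe atom placed at every lattice point (sp3 carbon, +1 e)."""

    r_star: float = 1.70
    epsilon: float = 0.107
    charge: float = 1.0


@dataclass
class Region:
    """Axis-aligned lattice: point (a,b,c) sits at origin + (a,b,c)·spacing."""

    origin: np.ndarray
    spacing: float
    counts: tuple[int, int, int]
    mask: np.ndarray = field(default=None)  # retained-point mask, flat C-order

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float)
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if any(c < 1 for c in self.counts):
            raise ValueError("counts must be >= 1")
        if self.mask is None:
            self.mask = np.ones(self.n_total, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool).reshape(self.n_total)

    @property
    def n_total(self) -> int:
        nx, ny, nz = self.counts
        return nx * ny * nz

    @property
    def n_retained(self) -> int:
        return int(self.mask.sum())

    def all_points(self) -> np.ndarray:
        """All lattice points, flat C-order (x slowest), shape (n_total, 3)."""
        nx, ny, nz = self.counts
        ia, ib, ic = np.meshgrid(
            np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
        )
        idx = np.stack([ia.ravel(), ib.ravel(), ic.ravel()], axis=1)
        return self.origin + idx * self.spacing

    def points(self) -> np.ndarray:
        """Retained lattice points, shape (n_retained, 3)."""
        return self.all_points()[self.mask]

    def to_dict(self) -> dict:
        return {
            "origin": self.origin.tolist(),
            "spacing": self.spacing,
            "counts": list(self.counts),
            "mask": self.mask.astype(int).tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Region":
        return cls(
            np.array(d["origin"]), float(d["spacing"]), tuple(d["counts"]),
            np.array(d["mask"], dtype=bool),
        )


def build_region(
    mols, margin: float = 2.0, spacing: float = 2.0, snap: bool = True
) -> Region:
    """Lattice enclosing a parallelepiped ``margin`` Å beyond the x, y and z
    extents of every structure, at ``spacing`` Å intervals; the outermost
    points sit at or beyond the box faces.

    With ``snap`` the origin is rounded down to a multiple of the spacing,
    so regions built from different molecule subsets share one global
    lattice (points of a sub-region coincide with points of a super-region).
    """
    mols = list(mols)
    if not mols:
        raise ValueError("build_region needs at least one molecule")
    coords = np.vstack([chem_io.coordinates(m) for m in mols])
    lo = coords.min(axis=0) - margin
    hi = coords.max(axis=0) + margin
    if snap:
        lo = np.floor(lo / spacing) * spacing
    counts = tuple(int(np.ceil((h - l) / spacing - 1e-9)) + 1 for l, h in zip(lo, hi))
    return Region(lo, spacing, counts)


def trim_region(
    region: Region, keep_lo=None, keep_hi=None, max_points: int | None = None
) -> Region:
    """Restrict the retained-point mask to a sub-box (and/or deterministically
    to at most ``max_points`` points, kept nearest the region centroid)."""
    pts = region.all_points()
    mask = region.mask.copy()
    if keep_lo is not None:
        mask &= np.all(pts >= np.asarray(keep_lo, dtype=float) - 1e-9, axis=1)
    if keep_hi is not None:
        mask &= np.all(pts <= np.asarray(keep_hi, dtype=float) + 1e-9, axis=1)
    if max_points is not None and mask.sum() > max_points:
        center = pts[mask].mean(axis=0)
        d = np.linalg.norm(pts - center, axis=1)
        d[~mask] = np.inf
        keep_idx = np.argsort(d, kind="stable")[:max_points]
        mask = np.zeros_like(mask)
        mask[keep_idx] = True
    if not mask.any():
        raise ValueError("trim removed every lattice point")
    return replace(region, mask=mask)


def _vdw_table(mol: Chem.Mol) -> tuple[np.ndarray, np.ndarray]:
    r, e = [], []
    for atom in mol.GetAtoms():
        rs, es = VDW_PARAMS.get(atom.GetSymbol(), _DEFAULT_VDW)
        r.append(rs)
        e.append(es)
    return np.array(r), np.array(e)


def compute_fields(
    mol: Chem.Mol,
    region: Region,
    probe: Probe = Probe(),
    steric_cutoff: float = 30.0,
    elec_cutoff: float = 30.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Field row of one aligned, charged molecule.

    Returns (steric, electrostatic) over retained lattice points, kcal/mol.
    Electrostatic values at points where the steric sum hit the cutoff
    (inside the envelope) are NaN — flagged for column-mean imputation.
    """
    if mol.GetNumConformers() == 0:
        raise ValueError("compute_fields needs 3D coordinates")
    try:
        charges = chem_io.partial_charges(mol)
    except KeyError as exc:
        raise ValueError("compute_fields needs partial charges") from exc
    if not np.all(np.isfinite(charges)):
        raise ValueError("non-finite partial charges")
    xyz = chem_io.coordinates(mol)
    pts = region.points()
    r = np.linalg.norm(pts[None, :, :] - xyz[:, None, :], axis=2)
    r = np.maximum(r, 1e-6)
    r_star, eps = _vdw_table(mol)
    rij = r_star[:, None] + probe.r_star
    eij = np.sqrt(eps[:, None] * probe.epsilon)
    ratio6 = (rij / r) ** 6
    steric = np.sum(eij * (ratio6**2 - 2.0 * ratio6), axis=0)
    inside = steric >= steric_cutoff
    steric = np.minimum(steric, steric_cutoff)
    with np.errstate(over="ignore"):
        elec = COULOMB_KCAL * probe.charge * np.sum(charges[:, None] / r**2, axis=0)
    elec = np.clip(elec, -elec_cutoff, elec_cutoff)
    elec[inside] = np.nan
    return steric, elec


@dataclass
class FieldTable:
    """Rows = aligned molecules; columns = steric block then electrostatic
    block, one column per retained lattice point per block."""

    X: np.ndarray  # (n_mols, 2 * n_retained); NaN marks flagged cells
    region: Region
    ids: list[str]

    @property
    def n_points(self) -> int:
        return self.X.shape[1] // 2

    @property
    def blocks(self) -> np.ndarray:
        """Per-column block label: 's' (steric) or 'e' (electrostatic)."""
        return np.array(["s"] * self.n_points + ["e"] * self.n_points)

    @property
    def point_index(self) -> np.ndarray:
        """Per-column index into the region's retained points."""
        return np.concatenate([np.arange(self.n_points)] * 2)

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{b}{i}" for b, i in zip(self.blocks, self.point_index)]
        return pd.DataFrame(self.X, index=self.ids, columns=cols)


def field_table(mols, region: Region, probe: Probe = Probe(), **kw) -> FieldTable:
    """Stack field rows for a set of aligned molecules into one table."""
    rows, ids = [], []
    for m in mols:
        s, e = compute_fields(m, region, probe, **kw)
        rows.append(np.concatenate([s, e]))
        ids.append(chem_io.mol_id(m))
    return FieldTable(np.array(rows, dtype=float), region, ids)


class FieldPretreater:
    """Column pretreatment fitted on the training table, reapplied verbatim
    to prediction rows (scikit-learn transformer conventions).

    Steps: impute flagged (NaN) electrostatic cells with the training
    column mean; drop columns with SD below ``min_sigma`` (kcal/mol);
    center; with ``scaling='comfa-std'`` rescale each block so the steric
    and electrostatic blocks carry equal total variance.

    Fitted attributes: ``impute_means_``, ``keep_``, ``center_``,
    ``scale_`` (per retained column), ``blocks_``, ``point_index_``.
    """

    def __init__(self, min_sigma: float = 2.0, scaling: str = "comfa-std"):
        if scaling not in ("comfa-std", "none"):
            raise ValueError("scaling must be 'comfa-std' or 'none'")
        self.min_sigma = min_sigma
        self.scaling = scaling

    def fit(self, table: FieldTable) -> "FieldPretreater":
        X = np.asarray(table.X, dtype=float)
        if X.shape[0] < 2:
            raise ValueError("pretreatment needs >= 2 rows")
        all_nan = np.isnan(X).all(axis=0)
        means = np.zeros(X.shape[1])
        cols = ~all_nan  # all-flagged columns impute to 0 (then get dropped)
        means[cols] = np.nanmean(X[:, cols], axis=0)
        Xi = np.where(np.isnan(X), means[None, :], X)
        sd = Xi.std(axis=0, ddof=1)
        keep = sd >= self.min_sigma
        if not keep.any():
            raise ValueError("pretreatment dropped every column")
        self.impute_means_ = means
        self.keep_ = keep
        self.center_ = Xi[:, keep].mean(axis=0)
        blocks = table.blocks[keep]
        scale = np.ones(keep.sum())
        if self.scaling == "comfa-std":
            for b in ("s", "e"):
                sel = blocks == b
                if sel.any():
                    total_var = Xi[:, keep][:, sel].var(axis=0, ddof=1).sum()
                    if total_var > 0:
                        scale[sel] = 1.0 / np.sqrt(total_var)
        self.scale_ = scale
        self.blocks_ = blocks
        self.point_index_ = table.point_index[keep]
        self.n_points_ = table.n_points
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        Xi = np.where(np.isnan(X), self.impute_means_[None, :], X)
        return (Xi[:, self.keep_] - self.center_) * self.scale_

    def fit_transform(self, table: FieldTable) -> np.ndarray:
        return self.fit(table).transform(table.X)

    def column_sd(self, X: np.ndarray) -> np.ndarray:
        """SD of the pretreated columns of ``X`` (for stdev*coeff grids)."""
        return self.transform(X).std(axis=0, ddof=1)


def pretreat(
    table: FieldTable, min_sigma: float = 2.0, scaling: str = "comfa-std"
) -> tuple[np.ndarray, FieldPretreater]:
    """Functional wrapper: fit a pretreater on a table, return the
    pretreated matrix and the fitted pretreater."""
    pt = FieldPretreater(min_sigma=min_sigma, scaling=scaling)
    return pt.fit_transform(table), pt
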