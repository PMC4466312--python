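"""End-to-end template CoMFA modelling.

:class:`TemplateCoMFA` is the full workflow as one scikit-learn style
estimator: align 2D structures to the templates (or, for the no-template
control protocols, just embed and optionally randomize them), sample
steric/electrostatic fields on a lattice built over the training set,
pretreat the columns, pick the component count by leave-one-out SDEP and
fit the final PLS model.  ``predict`` pushes new 2D structures through the
identical alignment and the *training* region/pretreatment.

Protocols (template provenance / perturbation):

===  ==========================================================
A–D  templates taken as given (pre-aligned 3D input files)
E    no alignment: deterministic 3D embedding poses only
F    as A–D after rigidly separating the templates by >= min_gap
G    as E, then conformation and pose randomized per structure
===  ==========================================================

Also here: the active/inactive/uncertain classification thresholds,
contingency tabulation, OR/AND combination with a second classifier, and
the "stdev*coeff" contour grids with Gaussian-cube export.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field

import numpy as np
from rdkit import Chem
from sklearn.base import BaseEstimator, RegressorMixin

from . import chem_io, curation, fields
from .alignment import TemplateAligner, randomize_pose, separate_templates
from .chem_io import EmbedError
from .fields import FieldPretreater, Probe, Region, build_region, field_table
from .pls import LOOResult, PLSRegressionNIPALS, loo_crossvalidate

NO_TEMPLATE_PROTOCOLS = ("E", "G")


def _per_mol_seed(seed: int, index: int) -> int:
    return (int(seed) * 1000003 + 7919 * index) % (2**31 - 1)


class TemplateCoMFA(BaseEstimator, RegressorMixin):
    """Template CoMFA 3D-QSAR model.

    Parameters
    ----------
    templates : list of 3D rdkit Mol, or None
        Pre-aligned templates in one shared frame (protocols A–D, F);
        ignored for the no-template controls E and G.
    protocol : str
        One of A–G (see module docstring).
    seed : int
        Drives 3D embedding and protocol-G randomization.
    spacing, margin : float
        Lattice geometry in Å.
    min_sigma : float
        Column-drop threshold in kcal/mol.
    scaling : str
        'comfa-std' (equal block variance) or 'none'.
    max_components : int
        Upper bound for leave-one-out component selection.
    min_gap : float
        Protocol-F inter-template separation in Å.
    trim : (lo, hi) or None
        Optional sub-box to which the region is trimmed.

    Fitted attributes: ``aligner_``, ``region_``, ``pretreater_``,
    ``pls_``, ``loo_``, ``q2_``, ``sdep_``, ``n_components_``, ``r2_``,
    ``s_``, ``train_results_``, ``train_failed_``.
    """

    def __init__(
        self,
        templates=None,
        protocol: str = "B",
        seed: int = 0,
        spacing: float = 2.0,
        margin: float = 2.0,
        min_sigma: float = 2.0,
        scaling: str = "comfa-std",
        max_components: int = 20,
        min_gap: float = 3.0,
        trim=None,
        probe: Probe = Probe(),
    ):
        self.templates = templates
        self.protocol = protocol
        self.seed = seed
        self.spacing = spacing
        self.margin = margin
        self.min_sigma = min_sigma
        self.scaling = scaling
        self.max_components = max_components
        self.min_gap = min_gap
        self.trim = trim
        self.probe = probe

    # -- alignment ---------------------------------------------------------

    def _make_aligner(self):
        if self.protocol in NO_TEMPLATE_PROTOCOLS:
            return None
        if not self.templates:
            raise ValueError(f"protocol {self.protocol} requires templates")
        templates = list(self.templates)
        if self.protocol == "F":
            templates = separate_templates(templates, min_gap=self.min_gap)
        return TemplateAligner(templates)

    def _pose(self, mols):
        """Aligned (or embedded/randomized) 3D structures, with Gasteiger
        charges; failures are recorded, not raised."""
        posed, ok_index, failed = [], [], []
        for i, mol in enumerate(mols):
            mol = chem_io.neutralize(mol)
            if self.aligner_ is not None:
                res = self.aligner_.align(mol, seed=self.seed)
                if not res.ok:
                    failed.append((i, res.reason))
                    continue
                m3 = res.mol
            else:
                try:
                    m3 = chem_io.embed_3d(mol, seed=self.seed)
                except EmbedError as exc:
                    failed.append((i, str(exc)))
                    continue
                if self.protocol == "G":
                    m3 = randomize_pose(m3, seed=_per_mol_seed(self.seed, i))
            posed.append(chem_io.assign_charges(m3))
            ok_index.append(i)
        return posed, ok_index, failed

    # -- estimator surface -------------------------------------------------

    def fit(self, mols, y):
        mols = list(mols)
        y = np.asarray(y, dtype=float).ravel()
        if y.size != len(mols):
            raise ValueError("molecule and value counts differ")
        self.aligner_ = self._make_aligner()
        posed, ok, failed = self._pose(mols)
        self.train_failed_ = failed
        if len(posed) < 3:
            raise ValueError("fewer than 3 structures aligned successfully")
        y_ok = y[ok]
        region = build_region(posed, margin=self.margin, spacing=self.spacing)
        if self.trim is not None:
            region = fields.trim_region(region, *self.trim)
        self.region_ = region
        table = field_table(posed, region, probe=self.probe)
        self.pretreater_ = FieldPretreater(self.min_sigma, self.scaling)
        X = self.pretreater_.fit_transform(table)
        self.train_table_ = table
        self.loo_: LOOResult = loo_crossvalidate(X, y_ok, max_comp=self.max_components)
        self.n_components_ = self.loo_.n_components
        self.q2_ = self.loo_.q2_chosen
        self.sdep_ = self.loo_.sdep_chosen
        self.pls_ = PLSRegressionNIPALS(self.n_components_).fit(X, y_ok)
        self.r2_ = self.pls_.r2_
        self.s_ = self.pls_.s_
        self.train_results_ = posed
        self.train_index_ = ok
        self.y_train_ = y_ok
        return self

    def predict(self, mols) -> np.ndarray:
        """Predicted pAffinities; NaN where alignment/embedding failed.

        Prediction rows are evaluated on the training region and pretreated
        with the training means, masks and scales.
        """
        mols = list(mols)
        posed, ok, failed = self._pose(mols)
        self.predict_failed_ = failed
        out = np.full(len(mols), np.nan)
        if posed:
            table = field_table(posed, self.region_, probe=self.probe)
            X = self.pretreater_.transform(table.X)
            out[np.array(ok)] = self.pls_.predict(X)
        return out

    # -- model archive -----------------------------------------------------

    def to_archive(self) -> dict:
        """JSON-serializable snapshot of the fitted model (region,
        pretreatment bookkeeping, PLS vectors, metrics)."""
        pt = self.pretreater_
        return {
            "protocol": self.protocol,
            "seed": self.seed,
            "region": self.region_.to_dict(),
            "pretreat": {
                "impute_means": pt.impute_means_.tolist(),
                "keep": pt.keep_.astype(int).tolist(),
                "center": pt.center_.tolist(),
                "scale": pt.scale_.tolist(),
                "min_sigma": pt.min_sigma,
                "scaling": pt.scaling,
            },
            "pls": {
                "coef": self.pls_.coef_.tolist(),
                "x_mean": self.pls_.x_mean_.tolist(),
                "y_mean": self.pls_.y_mean_,
            },
            "metrics": {
                "q2": self.q2_,
                "SDEP": self.sdep_,
                "n_components": self.n_components_,
                "r2": self.r2_,
                "s": self.s_,
            },
        }

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_archive(), fh, sort_keys=True, indent=1)


# ---------------------------------------------------------------------------
# evaluation report


@dataclass
class EvaluationReport:
    """Model-quality summary mirroring the standard reporting columns."""

    null_sd: float
    q2: float
    sdep: float
    n_components: int
    r2: float
    s: float
    se_prospective: float | None = None
    mw_s: float | None = None
    n_train: int = 0
    n_predict: int = 0
    n_failed_train: int = 0
    n_failed_predict: int = 0

    @property
    def uncertainty_reduction(self) -> float:
        """Null SD minus LOO SDEP: how much the model shrinks the error of
        the predict-the-mean null hypothesis."""
        return self.null_sd - self.sdep

    def to_dict(self) -> dict:
        d = {
            "null_sd": self.null_sd,
            "q2": self.q2,
            "SDEP": self.sdep,
            "n_components": self.n_components,
            "r2": self.r2,
            "s": self.s,
            "SE_predictions": self.se_prospective,
            "uncertainty_reduction": self.uncertainty_reduction,
            "s_MW": self.mw_s,
            "n_train": self.n_train,
            "n_predict": self.n_predict,
            "n_failed_train": self.n_failed_train,
            "n_failed_predict": self.n_failed_predict,
        }
        return d


def prospective_se(predicted: np.ndarray, actual: np.ndarray) -> float:
    """SE of prospective predictions: sample SD of the signed errors,
    over structures that received a prediction."""
    err = np.asarray(predicted, dtype=float) - np.asarray(actual, dtype=float)
    err = err[np.isfinite(err)]
    if err.size < 2:
        raise ValueError("SE needs >= 2 successful predictions")
    return float(np.std(err, ddof=1))


def run_protocol(
    train_mols,
    train_values,
    protocol: str = "B",
    templates=None,
    predict_mols=None,
    predict_values=None,
    seed: int = 0,
    **model_kw,
) -> tuple[TemplateCoMFA, EvaluationReport]:
    """Fit one protocol end to end and evaluate it.

    Returns the fitted model and a report containing the null SD, the
    leave-one-out metrics, the MW negative-control s, and — when a
    prediction set is given — the SE of prospective predictions.
    """
    model = TemplateCoMFA(
        templates=templates, protocol=protocol, seed=seed, **model_kw
    ).fit(train_mols, train_values)
    y = np.asarray(train_values, dtype=float)
    try:
        mw_s, _, _ = curation.mw_baseline(y, train_mols)
    except ValueError:
        mw_s = None
    se = None
    n_pred = 0
    n_failed_pred = 0
    if predict_mols is not None:
        preds = model.predict(predict_mols)
        n_failed_pred = int(np.sum(~np.isfinite(preds)))
        n_pred = len(preds) - n_failed_pred
        if predict_values is not None:
            se = prospective_se(preds, predict_values)
    report = EvaluationReport(
        null_sd=curation.null_sd(y),
        q2=model.q2_,
        sdep=model.sdep_,
        n_components=model.n_components_,
        r2=model.r2_,
        s=model.s_,
        se_prospective=se,
        mw_s=mw_s,
        n_train=len(model.train_results_),
        n_predict=n_pred,
        n_failed_train=len(model.train_failed_),
        n_failed_predict=n_failed_pred,
    )
    return model, report


# ---------------------------------------------------------------------------
# classification and method combination


ACTIVE_THRESHOLD = 4.5
INACTIVE_THRESHOLD = 3.5


def classify(
    value: float,
    active_gt: float = ACTIVE_THRESHOLD,
    inactive_lt: float = INACTIVE_THRESHOLD,
) -> str:
    """Three-way call on a pAffinity: > 4.5 active, < 3.5 inactive,
    the band between is 'uncertain' (no prediction is attempted)."""
    if not np.isfinite(value):
        return "uncertain"
    if value > active_gt:
        return "active"
    if value < inactive_lt:
        return "inactive"
    return "uncertain"


def contingency(predicted, actual) -> dict:
    """Correct-prediction rates per actual class.

    For each actual class ('inactive', 'active'): n attempted and the
    fraction predicted correctly.  Structures whose *actual* class is
    uncertain are excluded; uncertain *predictions* count as attempted and
    wrong.  Empty classes report n=0 and fraction None.
    """
    predicted = list(predicted)
    actual = list(actual)
    if len(predicted) != len(actual):
        raise ValueError("class lists differ in length")
    out = {}
    for cls in ("inactive", "active"):
        hits = [p == cls for p, a in zip(predicted, actual) if a == cls]
        out[cls] = {
            "n": len(hits),
            "fraction_true": (sum(hits) / len(hits)) if hits else None,
        }
    return out


def combine_predictions(tc_classes, nn_classes, mode: str, actual) -> dict:
    """Combine two classifiers' calls.

    mode='OR': count actual actives called active by the field model but
    inactive by the neighbor model ('n+'), and that count as a percentage
    of the neighbor model's true actives.  mode='AND': the contingency
    table restricted to structures where the two classifiers agree.
    """
    tc = list(tc_classes)
    nn = list(nn_classes)
    act = list(actual)
    if not (len(tc) == len(nn) == len(act)):
        raise ValueError("class lists differ in length")
    if mode == "OR":
        n_plus = sum(
            1 for t, n, a in zip(tc, nn, act)
            if a == "active" and t == "active" and n == "inactive"
        )
        nn_true_actives = sum(
            1 for n, a in zip(nn, act) if a == "active" and n == "active"
        )
        pct = 100.0 * n_plus / nn_true_actives if nn_true_actives else None
        return {"n_plus": n_plus, "pct_of_nn_true_actives": pct}
    if mode == "AND":
        agree = [(t, a) for t, n, a in zip(tc, nn, act) if t == n]
        return contingency([t for t, _ in agree], [a for _, a in agree])
    raise ValueError("mode must be 'OR' or 'AND'")


# ---------------------------------------------------------------------------
# contour grids


def stdev_coeff_grid(model: TemplateCoMFA) -> tuple[np.ndarray, np.ndarray]:
    """Conventional 'stdev*coeff' contour fields of a fitted model.

    Per retained lattice point and block: (training column SD) × (PLS
    coefficient), mapped back onto the full region lattice; dropped points
    carry 0.  Returns (steric grid, electrostatic grid) shaped like the
    region counts.
    """
    pt = model.pretreater_
    sd = pt.column_sd(model.train_table_.X)
    contrib = sd * model.pls_.coef_
    region = model.region_
    retained_to_full = np.flatnonzero(region.mask)
    grids = []
    for b in ("s", "e"):
        g = np.zeros(region.n_total)
        sel = pt.blocks_ == b
        g[retained_to_full[pt.point_index_[sel]]] = contrib[sel]
        grids.append(g.reshape(region.counts))
    return grids[0], grids[1]


_BOHR = 0.52917721092


def write_cube(grid: np.ndarray, region: Region, path: str, comment: str = "") -> None:
    """Export one scalar lattice as a Gaussian cube file (voxel-exact)."""
    nx, ny, nz = region.counts
    step = region.spacing / _BOHR
    org = region.origin / _BOHR
    with open(path, "w") as fh:
        fh.write(f"tcomfa field grid {comment}\n")
        fh.write("stdev*coeff lattice\n")
        fh.write(f"{1:5d}{org[0]:12.6f}{org[1]:12.6f}{org[2]:12.6f}\n")
        fh.write(f"{nx:5d}{step:12.6f}{0.0:12.6f}{0.0:12.6f}\n")
        fh.write(f"{ny:5d}{0.0:12.6f}{step:12.6f}{0.0:12.6f}\n")
        fh.write(f"{nz:5d}{0.0:12.6f}{0.0:12.6f}{step:12.6f}\n")
        fh.write(f"{6:5d}{0.0:12.6f}{0.0:12.6f}{0.0:12.6f}{0.0:12.6f}\n")
        flat = np.asarray(grid, dtype=float).reshape(nx, ny, nz)
        for ix in range(nx):
            for iy in range(ny):
                row = flat[ix, iy]
                for k in range(0, nz, 6):
                    fh.write("".join(f"{v:13.5E}" for v in row[k : k + 6]) + "\n")


def read_cube(path: str) -> tuple[np.ndarray, Region]:
    """Read back a cube file written by :func:`write_cube`."""
    with open(path) as fh:
        fh.readline()
        fh.readline()
        parts = fh.readline().split()
        origin = np.array([float(x) for x in parts[1:4]]) * _BOHR
        axes = []
        counts = []
        for _ in range(3):
            parts = fh.readline().split()
            counts.append(int(parts[0]))
            axes.append(float(parts[1]) * _BOHR)
        fh.readline()  # single placeholder atom
        data = np.array(fh.read().split(), dtype=float)
    region = Region(origin, axes[0], tuple(counts))
    return data.reshape(tuple(counts)), region
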