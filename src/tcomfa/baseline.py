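"""Tanimoto nearest-neighbor affinity baseline.

The dominant off-target prediction approach: predict an unknown affinity
to be that of the most structurally similar training compound, similarity
being the Tanimoto coefficient over 2D fragment fingerprints.  The
fingerprint is a hashed linear-path fingerprint over heavy atoms (paths of
2–7 bonds folded into 2048 bits) — a behavioral, not bit-level, surrogate
for proprietary path fingerprints.
"""

from __future__ import annotations

import numpy as np
from rdkit import Chem
from sklearn.base import BaseEstimator, RegressorMixin

from . import chem_io


def fingerprint(
    mol: Chem.Mol, n_bits: int = 2048, min_path: int = 2, max_path: int = 7
) -> np.ndarray:
    """Hashed linear-path fingerprint as a boolean vector.

    Deterministic and invariant under atom reordering (isomorphic graphs
    give identical bits); computed on the heavy-atom graph.
    """
    mol = Chem.RemoveHs(Chem.Mol(mol))
    fp = Chem.RDKFingerprint(
        mol, minPath=min_path, maxPath=max_path, fpSize=n_bits, branchedPaths=False
    )
    arr = np.zeros(n_bits, dtype=bool)
    arr[list(fp.GetOnBits())] = True
    return arr


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """|a ∧ b| / |a ∨ b|; 0 when both vectors are empty."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("fingerprint length mismatch")
    union = int(np.count_nonzero(a | b))
    if union == 0:
        return 0.0
    return int(np.count_nonzero(a & b)) / union


class TanimotoNNRegressor(BaseEstimator, RegressorMixin):
    """1-nearest-neighbor affinity predictor under Tanimoto similarity.

    Ties in similarity break toward the lowest training index.
    ``exclude_self`` skips exact self-matches (same fingerprint AND same
    id) for leave-one-out style evaluation; off by default, matching plain
    train/predict usage.
    """

    def __init__(
        self,
        n_bits: int = 2048,
        min_path: int = 2,
        max_path: int = 7,
        exclude_self: bool = False,
    ):
        self.n_bits = n_bits
        self.min_path = min_path
        self.max_path = max_path
        self.exclude_self = exclude_self

    def _fp(self, mol) -> np.ndarray:
        return fingerprint(mol, self.n_bits, self.min_path, self.max_path)

    def fit(self, mols, y):
        mols = list(mols)
        y = np.asarray(y, dtype=float).ravel()
        if len(mols) == 0:
            raise ValueError("empty training set")
        if y.size != len(mols):
            raise ValueError("molecule and value counts differ")
        self.fingerprints_ = np.array([self._fp(m) for m in mols])
        self.y_ = y
        self.ids_ = [chem_io.mol_id(m) for m in mols]
        return self

    def kneighbors(self, mols) -> list[tuple[float, int, float]]:
        """Per query: (predicted value, training index of neighbor,
        Tanimoto similarity)."""
        out = []
        train = self.fingerprints_
        union_base = train.sum(axis=1)
        for k, mol in enumerate(mols):
            q = self._fp(mol)
            inter = (train & q).sum(axis=1)
            union = union_base + int(q.sum()) - inter
            with np.errstate(invalid="ignore", divide="ignore"):
                sim = np.where(union > 0, inter / np.maximum(union, 1), 0.0)
            if self.exclude_self:
                qid = chem_io.mol_id(mol)
                for i, tid in enumerate(self.ids_):
                    if tid == qid and np.array_equal(train[i], q):
                        sim[i] = -1.0
            best = int(np.argmax(sim))  # argmax takes first max: lowest index
            out.append((float(self.y_[best]), best, float(sim[best])))
        return out

    def predict(self, mols) -> np.ndarray:
        return np.array([v for v, _, _ in self.kneighbors(mols)])


def nn_predict(train_mols, train_values, query: Chem.Mol) -> tuple[float, int, float]:
    """Functional wrapper: nearest-neighbor prediction for one query.

    Returns (predicted pAffinity, neighbor training index, similarity).
    """
    model = TanimotoNNRegressor().fit(train_mols, train_values)
    return model.kneighbors([query])[0]
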