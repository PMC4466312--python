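"""Bioactivity-table curation.

Affinity compilations aggregated from the literature report the same
compound in several nominally equivalent assays, and cross-laboratory
discrepancies of two or more log units are common.  The curation step
tabulates every duplicate measurement pair, sorts by affinity difference,
and drops every record of any assay repeatedly implicated in large
discrepancies.  The module also provides the deterministic odd/even
train/prediction split, per-compound value resolution, and the two
baselines every model is judged against: the null-hypothesis SD (predict
the mean) and a molecular-weight regression.

Tables are pandas DataFrames with columns
``compound_id, smiles, assay_id, assay_type, value, target_id``
(value = pAffinity, −log10 molar).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import chem_io

logger = logging.getLogger(__name__)

COLUMNS = ["compound_id", "smiles", "assay_id", "assay_type", "value", "target_id"]


def read_biodata(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"compound_id": str, "assay_id": str})
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"biodata table missing columns: {missing}")
    out_of_range = df["value"].notna() & ~df["value"].between(0, 14)
    if out_of_range.any():
        logger.warning("%d pAffinity values outside [0, 14]", int(out_of_range.sum()))
    return df


def write_biodata(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, index=False)


@dataclass(frozen=True)
class DuplicatePair:
    """One unordered pair of measurements of the same compound."""

    compound_id: str
    assay_a: str
    assay_b: str
    value_a: float
    value_b: float

    @property
    def abs_diff(self) -> float:
        return abs(self.value_a - self.value_b)


def pair_duplicates(records: pd.DataFrame) -> list[DuplicatePair]:
    """Tabulate duplicate measurements by pairs, sorted by affinity difference.

    One pair per unordered pair of valued records sharing a compound id,
    sorted descending by absolute difference; ties are ordered by
    (compound id, assay id pair) for a stable listing.
    """
    valued = records[records["value"].notna()]
    pairs: list[DuplicatePair] = []
    for cid, grp in valued.groupby("compound_id", sort=True):
        rows = list(grp.itertuples())
        for r1, r2 in itertools.combinations(rows, 2):
            a, b = sorted(
                [(str(r1.assay_id), float(r1.value)), (str(r2.assay_id), float(r2.value))]
            )
            pairs.append(DuplicatePair(str(cid), a[0], b[0], a[1], b[1]))
    pairs.sort(key=lambda p: (-p.abs_diff, p.compound_id, p.assay_a, p.assay_b))
    return pairs


def filter_discordant(
    records: pd.DataFrame,
    delta: float = 2.0,
    min_repeats: int = 2,
    key: str = "assay_id",
) -> tuple[pd.DataFrame, set[str]]:
    """Drop records from assays repeatedly implicated in large discrepancies.

    An assay is dropped iff it participates in at least ``min_repeats``
    duplicate pairs whose absolute affinity difference exceeds ``delta``;
    all records bearing a dropped assay — anywhere in the table — are
    removed, as are records lacking a value.  ``key`` selects whether the
    rule is keyed on ``assay_id`` or on ``assay_type``.

    Returns (kept records, dropped key set).
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    if min_repeats < 1:
        raise ValueError("min_repeats must be >= 1")
    if key not in ("assay_id", "assay_type"):
        raise ValueError("key must be 'assay_id' or 'assay_type'")
    valued = records[records["value"].notna()].copy()
    if key == "assay_type":
        id_to_key = dict(zip(valued["assay_id"].astype(str), valued["assay_type"].astype(str)))
    counts: dict[str, int] = {}
    for pair in pair_duplicates(valued):
        if pair.abs_diff > delta:
            for assay in {pair.assay_a, pair.assay_b}:
                k = id_to_key.get(assay, assay) if key == "assay_type" else assay
                counts[k] = counts.get(k, 0) + 1
    dropped = {k for k, n in counts.items() if n >= min_repeats}
    keep_mask = ~valued[key].astype(str).isin(dropped)
    return valued[keep_mask], dropped


def split_odd_even(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Deterministic training/prediction split by 1-based table position:
    odd-numbered records train, even-numbered records are predicted."""
    idx = np.arange(len(records))
    return records.iloc[idx % 2 == 0], records.iloc[idx % 2 == 1]


def resolve_per_compound(records: pd.DataFrame, mode: str = "median") -> pd.DataFrame:
    """Collapse a filtered table to one record per compound.

    The surviving duplicate values are aggregated (median by default,
    robust to residual cross-source scatter); assay fields are set to the
    sentinel ``resolved``.  First-appearance order of compounds is kept.
    """
    if mode not in ("median", "mean"):
        raise ValueError("mode must be 'median' or 'mean'")
    valued = records[records["value"].notna()]
    rows = []
    for cid in valued["compound_id"].drop_duplicates():
        grp = valued[valued["compound_id"] == cid]
        agg = grp["value"].median() if mode == "median" else grp["value"].mean()
        first = grp.iloc[0]
        rows.append(
            {
                "compound_id": cid,
                "smiles": first["smiles"],
                "assay_id": "resolved",
                "assay_type": "resolved",
                "value": float(agg),
                "target_id": first["target_id"],
            }
        )
    return pd.DataFrame(rows, columns=COLUMNS)


def null_sd(values) -> float:
    """Null-hypothesis prediction error: the sample SD (n−1) of the known
    affinities, i.e. the error of always predicting their mean."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("null SD needs at least 2 values")
    return float(np.std(v, ddof=1))


def mw_baseline(values, mols) -> tuple[float, float, float]:
    """Molecular-weight negative control: OLS of affinity on MW.

    Returns (s, slope, intercept) where s is the residual standard error
    sqrt(SS_res / (n − 2)).  Affinity often correlates weakly with size;
    a model is only interesting where it beats this trivial regression.
    """
    y = np.asarray(values, dtype=float)
    mw = np.array([chem_io.molecular_weight(m) for m in mols], dtype=float)
    if y.size < 3:
        raise ValueError("MW baseline needs at least 3 records")
    if np.ptp(mw) < 1e-12:
        raise ValueError("degenerate MW baseline: constant molecular weight")
    slope, intercept = np.polyfit(mw, y, 1)
    resid = y - (slope * mw + intercept)
    s = float(np.sqrt(np.sum(resid**2) / (y.size - 2)))
    return s, float(slope), float(intercept)
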