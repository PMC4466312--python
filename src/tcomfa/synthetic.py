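"""Seeded synthetic fixtures: molecule series, planted activities, assay
tables, decoy mixes.

The generator emulates the data regime the template CoMFA workflow is
aimed at: congeneric-plus-diverse small-molecule series (a few ring
scaffolds, a substituent vocabulary), pAffinity values that are *linear in
the lattice fields of the template-aligned structures* (the structural
assumption of the field model — planting on aligned fields keeps the
alignment step on the causal path), active-biased value distributions
around pAffinity ≈ 5.5, duplicate measurements spread over assays with
designated discordant assays shifted by more than 2 log units, and
decoy mixes at a 10:1 inactive:active ratio with decoys assigned
pAffinity 2.5.

Defaults: 200 molecules, planted signal SD 1.2 (the scale of affinity
spread in curated bioactivity sets), measurement noise SD 0.3 (the usual
within-laboratory repeat SD), 3 templates, 10:1 decoy ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from itertools import product

import numpy as np
import pandas as pd
from rdkit import Chem

from . import chem_io
from .alignment import TemplateAligner
from .fields import Region, field_table

SCAFFOLDS = [
    "c1ccc({r1})cc1{r2}",          # benzene
    "c1ccc2cc({r1})ccc2c1{r2}",    # naphthalene
    "C1CCC({r1})CC1{r2}",          # cyclohexane
]
DECOY_SCAFFOLDS = [
    "c1ccnc({r1})c1{r2}",          # pyridine
    "c1oc({r1})cc1{r2}",           # furan (wrong-family decoys)
    "C1CCCCC1C({r1}){r2}",         # homologated cyclohexane
]
SUBSTITUENTS = [
    "", "C", "CC", "CCC", "C(C)C", "F", "Cl", "Br",
    "O", "OC", "N", "C#N", "CO", "C(=O)C", "OCC", "NC",
]


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic dataset."""

    n_molecules: int = 200
    seed: int = 0
    scaffolds: list = dc_field(default_factory=lambda: list(SCAFFOLDS))
    substituents: list = dc_field(default_factory=lambda: list(SUBSTITUENTS))
    signal_sd: float = 1.2       # pAffinity spread of the planted signal
    noise_sd: float = 0.3        # measurement noise, pAffinity
    intercept: float = 5.5       # active-biased center, like curated tables
    coefficient_length_scale: float = 3.0  # Å, smoothness of the planted field
    n_assays: int = 6
    duplicate_fraction: float = 0.25
    n_discordant_assays: int = 0
    n_discordant_duplicates: int = 4  # replicates each discordant assay plants
    discordance_shift: float = 2.5  # > 2.0, so the curation filter fires
    decoy_ratio: int = 10
    n_decoy_templates: int = 30
    decoy_value: float = 2.5


def _substitute(scaffold: str, r1: str, r2: str) -> str | None:
    smi = scaffold.replace("({r1})", f"({r1})" if r1 else "")
    smi = smi.replace("{r2}", r2)
    smi = smi.replace("{r1}", r1)
    return smi if Chem.MolFromSmiles(smi) is not None else None


def _enumerate_smiles(scaffolds, substituents) -> list[str]:
    seen, out = set(), []
    for scaf, r1, r2 in product(scaffolds, substituents, substituents):
        smi = _substitute(scaf, r1, r2)
        if smi is None:
            continue
        canon = Chem.MolToSmiles(Chem.MolFromSmiles(smi))
        if canon not in seen:
            seen.add(canon)
            out.append(canon)
    return out


def make_series(spec: SyntheticSpec, prefix: str = "SYN"):
    """Scaffold+substituent series with three templates in a shared frame.

    Molecules are enumerated as SMILES, shuffled by the seeded RNG, and the
    first ``n_molecules`` kept.  One representative of each scaffold family
    becomes a template: the first is embedded to define the frame, the
    others are aligned onto it by the template aligner, so all templates
    share one frame.

    Returns (templates, molecules) — templates as 3D Mols, molecules 2D.
    """
    pool = _enumerate_smiles(spec.scaffolds, spec.substituents)
    if len(pool) < spec.n_molecules:
        raise ValueError(
            f"vocabulary yields only {len(pool)} molecules < {spec.n_molecules}"
        )
    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(len(pool))
    chosen = [pool[i] for i in order[: spec.n_molecules]]
    mols = []
    for i, smi in enumerate(chosen):
        m = Chem.MolFromSmiles(smi)
        chem_io.set_mol_id(m, f"{prefix}{i:04d}")
        mols.append(m)
    # templates: lightly substituted representative of each scaffold family
    tmpl_smis = []
    for scaf in spec.scaffolds:
        smi = _substitute(scaf, "C", "CC") or _substitute(scaf, "C", "C")
        tmpl_smis.append(smi)
    t0 = chem_io.embed_3d(
        chem_io.set_mol_id(Chem.MolFromSmiles(tmpl_smis[0]), f"{prefix}-T0"),
        seed=spec.seed,
    )
    templates = [t0]
    aligner = TemplateAligner([t0])
    for k, smi in enumerate(tmpl_smis[1:], start=1):
        cand = chem_io.set_mol_id(Chem.MolFromSmiles(smi), f"{prefix}-T{k}")
        res = aligner.align(cand, seed=spec.seed)
        if not res.ok:
            raise RuntimeError(f"template {k} failed to align: {res.reason}")
        templates.append(res.mol)
    return templates, mols


def random_coefficient_grid(
    region: Region, n_columns: int, rng, length_scale: float = 3.0
) -> np.ndarray:
    """Spatially smooth random coefficient field over both blocks.

    A binding-site contribution is a smooth function of space, so the
    planted coefficients are a Gaussian random field (squared-exponential
    kernel, ``length_scale`` Å) over the retained lattice points, drawn
    independently for the steric and electrostatic block.
    """
    pts = region.points()
    half = n_columns // 2
    if pts.shape[0] != half:
        raise ValueError("coefficient grid dims do not match the region")
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
    K = np.exp(-d2 / (2.0 * length_scale**2))
    coef = np.zeros(n_columns)
    for b0 in (0, half):
        coef[b0 : b0 + half] = K @ rng.normal(size=half)
    return coef


def plant_activities(
    aligned_mols,
    region: Region,
    coefficient_grid: np.ndarray | None = None,
    noise_sd: float | None = None,
    seed: int | None = None,
    spec: SyntheticSpec | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Plant field-linear activities on template-aligned structures.

    value_i = intercept + grid · fields_i + Normal(0, noise SD).  When no
    grid is given, a sparse random one is drawn (seeded) and rescaled so
    the noise-free signal has SD ``spec.signal_sd`` across the set; an
    explicitly supplied grid is used as-is.  Flagged (inside-envelope)
    electrostatic cells contribute 0 to the planted signal.

    Returns (values, coefficient grid).
    """
    spec = spec or SyntheticSpec()
    noise_sd = spec.noise_sd if noise_sd is None else noise_sd
    seed = spec.seed if seed is None else seed
    if noise_sd < 0:
        raise ValueError("noise SD must be >= 0")
    rng = np.random.default_rng(seed)
    table = field_table(aligned_mols, region)
    X = np.nan_to_num(table.X, nan=0.0)
    offset = 0.0
    if coefficient_grid is None:
        coef = random_coefficient_grid(
            region, X.shape[1], rng, spec.coefficient_length_scale
        )
        g = X @ coef
        g_sd = np.std(g, ddof=1)
        if g_sd > 0:
            coef = coef * (spec.signal_sd / g_sd)
        # center the signal so the series stays active-biased around the
        # intercept regardless of the drawn field
        offset = -float(np.mean(X @ coef))
    else:
        coef = np.asarray(coefficient_grid, dtype=float)
        if coef.size != X.shape[1]:
            raise ValueError("coefficient grid does not match the region")
    values = (
        spec.intercept + offset + X @ coef + rng.normal(0.0, noise_sd, size=X.shape[0])
    )
    return values, coef


def make_biodata_table(
    spec: SyntheticSpec, mols, values
) -> pd.DataFrame:
    """Assay table with duplicate measurements and planted discordance.

    Every compound gets one base record, with base assays assigned
    round-robin over the non-discordant assays (so no clean assay is
    repeatedly implicated in large differences).  A seeded fraction of
    compounds receive a concordant replicate in the next clean assay
    (shift ~ N(0, 0.1)).  Each of the first ``n_discordant_assays`` assay
    ids additionally replicates ``n_discordant_duplicates`` distinct
    compounds shifted by ``discordance_shift`` (> 2 log units), so the
    curation filter drops exactly the discordant assays and the post-filter
    record count is computable from the spec.
    """
    rng = np.random.default_rng(spec.seed + 1)
    discordant = [f"A{k}" for k in range(spec.n_discordant_assays)]
    clean = [f"A{k}" for k in range(spec.n_discordant_assays, spec.n_assays)]
    if not clean:
        raise ValueError("need at least one non-discordant assay")
    rows = []
    mols = list(mols)
    for i, (mol, val) in enumerate(zip(mols, values)):
        cid = chem_io.mol_id(mol)
        smi = Chem.MolToSmiles(Chem.RemoveHs(Chem.Mol(mol)))
        base = clean[i % len(clean)]
        rows.append((cid, smi, base, "B", float(val), "SYNT"))
        if rng.random() < spec.duplicate_fraction:
            dup = clean[(i + 1) % len(clean)]
            rows.append((cid, smi, dup, "B", float(val + rng.normal(0, 0.1)), "SYNT"))
    for k, assay in enumerate(discordant):
        start = k * spec.n_discordant_duplicates
        for i in range(start, start + spec.n_discordant_duplicates):
            mol, val = mols[i % len(mols)], values[i % len(mols)]
            cid = chem_io.mol_id(mol)
            smi = Chem.MolToSmiles(Chem.RemoveHs(Chem.Mol(mol)))
            rows.append(
                (cid, smi, assay, "B", float(val + spec.discordance_shift), "SYNT")
            )
    return pd.DataFrame(
        rows,
        columns=["compound_id", "smiles", "assay_id", "assay_type", "value", "target_id"],
    )


def make_decoy_mix(spec: SyntheticSpec, actives, active_values):
    """Mix actives with presumed-inactive decoys at ``decoy_ratio``:1.

    Decoys come from a distinct scaffold family and carry pAffinity
    ``decoy_value`` (2.5: weaker than millimolar).  The template set is the
    active-series triplet extended with ``n_decoy_templates`` decoy
    templates aligned into the same frame.  Returns a dict with keys
    ``templates``, ``train``/``train_values`` and ``predict``/
    ``predict_values`` (odd/even split of the interleaved mix).
    """
    actives = list(actives)
    n_decoys = spec.decoy_ratio * len(actives)
    decoy_spec = SyntheticSpec(
        n_molecules=n_decoys + spec.n_decoy_templates,
        seed=spec.seed + 17,
        scaffolds=list(DECOY_SCAFFOLDS),
        substituents=spec.substituents,
    )
    pool = _enumerate_smiles(decoy_spec.scaffolds, decoy_spec.substituents)
    if len(pool) < decoy_spec.n_molecules:
        raise ValueError(
            f"decoy vocabulary yields {len(pool)} < {decoy_spec.n_molecules} structures"
        )
    templates, _ = make_series(spec)
    rng = np.random.default_rng(decoy_spec.seed)
    order = rng.permutation(len(pool))
    decoy_smis = [pool[i] for i in order[: decoy_spec.n_molecules]]
    decoys = []
    for i, smi in enumerate(decoy_smis[: n_decoys]):
        decoys.append(chem_io.set_mol_id(Chem.MolFromSmiles(smi), f"DEC{i:04d}"))
    aligner = TemplateAligner(templates)
    for i, smi in enumerate(decoy_smis[n_decoys:]):
        cand = chem_io.set_mol_id(Chem.MolFromSmiles(smi), f"DECT{i:02d}")
        res = aligner.align(cand, seed=spec.seed)
        if res.ok:
            templates.append(res.mol)
    # interleave actives among decoys deterministically, then odd/even split
    mix = list(zip(decoys, [spec.decoy_value] * len(decoys)))
    step = max(len(mix) // max(len(actives), 1), 1)
    for k, (m, v) in enumerate(zip(actives, active_values)):
        mix.insert(k * (step + 1) % (len(mix) + 1), (m, float(v)))
    train = [(m, v) for i, (m, v) in enumerate(mix) if i % 2 == 0]
    predict = [(m, v) for i, (m, v) in enumerate(mix) if i % 2 == 1]
    return {
        "templates": templates,
        "train": [m for m, _ in train],
        "train_values": np.array([v for _, v in train]),
        "predict": [m for m, _ in predict],
        "predict_values": np.array([v for _, v in predict]),
    }


def make_dataset(spec: SyntheticSpec):
    """One-call fixture: series, alignment, region, planted values.

    Returns a dict with templates, 2D molecules, aligned 3D molecules,
    the region, planted values and the coefficient grid.
    """
    templates, mols = make_series(spec)
    aligner = TemplateAligner(templates)
    aligned, kept = [], []
    for m in mols:
        res = aligner.align(m, seed=spec.seed)
        if res.ok:
            aligned.append(chem_io.assign_charges(res.mol))
            kept.append(m)
    from .fields import build_region

    region = build_region(aligned)
    values, coef = plant_activities(aligned, region, spec=spec, seed=spec.seed)
    return {
        "templates": templates,
        "molecules": kept,
        "aligned": aligned,
        "region": region,
        "values": values,
        "coefficients": coef,
    }
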