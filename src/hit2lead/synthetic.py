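"""Seeded generators for every pipeline input, with planted ground truth.

Each generator is a pure function of (seed, parameters) and emits its
ground truth alongside the data so downstream fits can be checked in a
closed loop.  Random streams are split by a fixed rule: generator ``name``
draws from ``numpy.random.default_rng([seed, STREAM[name]])``, so adding
parameters to one generator never perturbs another's draws.

Scenarios
---------
* ``gen_library`` — a screening library with planted analogs of a
  reference scaffold (substituents grafted onto aromatic CH positions, so
  every scaffold path survives and 2D-fingerprint containment is
  guaranteed) among scaffold-free decoys built from a small fragment
  grammar.
* ``gen_qsar`` — a 3D-QSAR training set: pseudo-compounds sharing a planar
  aromatic scaffold with 0-4 randomly placed chain heteroatoms, activities
  linear in the field descriptors plus Gaussian noise (optionally
  calibrated to a target true R^2).
* ``gen_dose_response`` — exact 4PL responses on a dose ladder with
  multiplicative Gaussian noise.
* ``gen_mst`` — a 16-point 1:2 serial dilution titration (10,000 nM down
  to 0.305 nM) of F_norm values from the quadratic mass-action isotherm at
  fixed labeled-target concentration.
* ``gen_gene_table`` — gene tables drawn into (direction x STAT3 prior x
  STAT1 prior) cells at given proportions, fold changes past threshold and
  fdr below it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from rdkit import Chem

from .chem_io import Compound
from .pharm import DoseResponse, fraction_bound, four_pl
from .qsar import GridSpec, compute_fields, descriptor_matrix

__all__ = [
    "DEFAULT_REFERENCE_SMILES",
    "gen_library",
    "gen_pharm_library",
    "gen_qsar",
    "QSARDataset",
    "gen_dose_response",
    "gen_mst",
    "gen_gene_table",
    "TABLE3_PROPORTIONS",
]

# Stream ids for the seed-splitting rule.
STREAM = {"library": 1, "qsar": 2, "dose": 3, "mst": 4, "genes": 5, "pharm": 6}

# N-(naphth-1-yl)benzenesulfonamide, the scaffold class of the screening
# reference.
DEFAULT_REFERENCE_SMILES = "O=S(=O)(Nc1cccc2ccccc12)c1ccccc1"

_SUBSTITUENTS = ["C", "CC", "CCC", "CO", "CCO", "CN", "CCN", "OC", "C(C)C", "CCCO"]

_DECOY_FRAGMENTS = [
    "CCO", "CCN", "CCCC", "COC", "CC(C)O", "CCOC", "C1CCCCC1", "C1CCOC1",
    "CC(=O)O", "CCS", "OCCO", "NCCN", "CC(C)N", "CCCCO", "C1CCNC1",
]


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), STREAM[stream]])


def _graft(scaffold: Chem.Mol, position: int, substituent: str) -> str:
    """Attach a chain at an aromatic CH position; returns the new SMILES."""
    frag = Chem.MolFromSmiles(substituent)
    combined = Chem.RWMol(Chem.CombineMols(scaffold, frag))
    combined.AddBond(position, scaffold.GetNumAtoms(), Chem.BondType.SINGLE)
    mol = combined.GetMol()
    Chem.SanitizeMol(mol)
    return Chem.MolToSmiles(mol)


def gen_library(
    seed: int,
    n_decoys: int = 100,
    n_analogs: int = 5,
    reference_smiles: str = DEFAULT_REFERENCE_SMILES,
) -> tuple[list[Compound], pd.DataFrame]:
    """Screening library of decoys plus planted scaffold analogs.

    Returns (compounds, truth) where truth has columns (compound_id,
    is_analog).  Analogs are the reference scaffold with a substituent
    grafted onto a seeded choice of aromatic CH position, which preserves
    every scaffold path (fingerprint containment holds by construction).
    """
    if n_decoys < 0 or n_analogs < 0:
        raise ValueError("counts must be >= 0")
    scaffold = Chem.MolFromSmiles(reference_smiles)
    if scaffold is None:
        raise ValueError(f"invalid reference SMILES: {reference_smiles!r}")
    rng = _rng(seed, "library")
    ch_positions = [
        a.GetIdx()
        for a in scaffold.GetAtoms()
        if a.GetIsAromatic() and a.GetSymbol() == "C" and a.GetTotalNumHs() == 1
    ]
    compounds: list[Compound] = []
    truth_rows = []
    made: set[str] = set()
    i = 0
    while len([r for r in truth_rows if r[1]]) < n_analogs:
        pos = int(rng.choice(ch_positions))
        sub = _SUBSTITUENTS[int(rng.integers(len(_SUBSTITUENTS)))]
        smi = _graft(scaffold, pos, sub)
        if smi in made:
            continue
        made.add(smi)
        cid = f"analog{i:03d}"
        compounds.append(Compound(id=cid, smiles=smi))
        truth_rows.append((cid, True))
        i += 1
    for j in range(n_decoys):
        n_frag = int(rng.integers(1, 3))
        parts = [_DECOY_FRAGMENTS[int(rng.integers(len(_DECOY_FRAGMENTS)))] for _ in range(n_frag)]
        smi = "".join(p if k == 0 else p.replace("1", "2") for k, p in enumerate(parts))
        if Chem.MolFromSmiles(smi) is None:  # grammar collision; fall back to first part
            smi = parts[0]
        cid = f"decoy{j:03d}"
        compounds.append(Compound(id=cid, smiles=smi))
        truth_rows.append((cid, False))
    truth = pd.DataFrame(truth_rows, columns=["compound_id", "is_analog"])
    return compounds, truth


@dataclass
class QSARDataset:
    """A generated QSAR training set with its planted linear truth."""

    compounds: list[Compound]
    grid: GridSpec
    X: np.ndarray
    y: np.ndarray
    y_clean: np.ndarray
    beta: np.ndarray
    noise_sd: float


_HEX_R = 1.39  # aromatic C-C ring radius, Angstrom

# Fixed substituent attachment sites (A) around the shared scaffold — the
# aligned R-group positions a congeneric SAR series decorates.
_SITES = np.array(
    [[2.9, 0.0, 0.3], [4.4, 0.4, 0.0], [-1.5, 2.5, 0.2], [1.5, -2.6, -0.2]]
)


def _pseudo_compound(
    rng: np.random.Generator, cid: str, jitter: float, site_prob: float
) -> Compound:
    """Planar aromatic scaffold decorated at fixed sites with jittered atoms.

    Each of the four sites is independently occupied with probability
    ``site_prob`` by a C/C/O/N atom placed at the site template plus
    isotropic Gaussian jitter — a congeneric series sharing an alignment
    frame, which is what makes the field descriptors learnable from a
    40-compound training set.
    """
    ring_xyz = [
        (_HEX_R * np.cos(k * np.pi / 3), _HEX_R * np.sin(k * np.pi / 3), 0.0) for k in range(6)
    ]
    conformer = [("C", *map(float, p)) for p in ring_xyz]
    symbols = []
    for site in _SITES:
        if rng.random() < site_prob:
            sym = str(rng.choice(["C", "C", "O", "N"]))
            pos = site + rng.normal(scale=jitter, size=3)
            conformer.append((sym, *map(float, pos)))
            symbols.append(sym)
    smiles = "c1ccccc1" + "".join(symbols)
    return Compound(id=cid, smiles=smiles, conformer=conformer)


def gen_qsar(
    seed: int,
    n_compounds: int = 40,
    spacing: float = 2.0,
    margin: float = 3.0,
    alpha: float = 0.5,
    signal_channel: str = "hydrophobic",
    noise_sd: float | None = None,
    target_r2: float | None = None,
    jitter: float = 0.3,
    site_prob: float = 0.6,
) -> QSARDataset:
    """QSAR training set with activities linear in the field descriptors.

    The planted coefficient vector ``beta`` is structured: a single
    standard-normal weight applied uniformly over one field channel
    (default ``hydrophobic``, mirroring a SAR dominated by hydrophobic
    bulk), zero elsewhere; y = X beta + N(0, noise_sd).  If ``target_r2``
    is given instead of ``noise_sd``, the noise is calibrated so the true
    (population) R^2 of the generating model equals it:
    noise_sd = sd(X beta) * sqrt((1 - R^2) / R^2).
    """
    from .qsar import CHANNELS  # local import to avoid cycle at module load

    rng = _rng(seed, "qsar")
    compounds = [
        _pseudo_compound(rng, f"cmpd{i:03d}", jitter, site_prob) for i in range(n_compounds)
    ]
    grid = GridSpec.enclosing(compounds, spacing=spacing, margin=margin)
    fields = compute_fields(compounds, grid=grid, alpha=alpha)
    X = descriptor_matrix(fields)
    if signal_channel not in CHANNELS:
        raise ValueError(f"unknown channel {signal_channel!r}")
    G = grid.n_points
    ci = CHANNELS.index(signal_channel)
    beta = np.zeros(X.shape[1])
    beta[ci * G : (ci + 1) * G] = rng.normal()
    y_clean = X @ beta
    if noise_sd is None:
        if target_r2 is not None:
            if not 0 < target_r2 < 1:
                raise ValueError("target_r2 must be in (0, 1)")
            noise_sd = float(np.std(y_clean) * np.sqrt((1 - target_r2) / target_r2))
        else:
            noise_sd = 0.0
    y = y_clean + rng.normal(scale=noise_sd, size=n_compounds) if noise_sd > 0 else y_clean.copy()
    return QSARDataset(
        compounds=compounds, grid=grid, X=X, y=y, y_clean=y_clean,
        beta=beta, noise_sd=float(noise_sd),
    )


def gen_pharm_library(
    seed: int,
    reference: Compound,
    n_match: int = 10,
    n_decoys: int = 90,
    jitter: float = 0.05,
) -> tuple[list[Compound], pd.DataFrame]:
    """3D library where planted analogs share the reference feature geometry.

    Each match is the reference molecule under a random rigid motion plus
    per-atom jitter far smaller than a distance bin, so its pharmacophore
    fingerprint equals the reference's; decoys are embedded short alkanes
    whose feature sets share essentially nothing with a polyfunctional
    reference.  The reference must carry a conformer.  Returns (compounds,
    truth) with truth columns (compound_id, is_match).
    """
    from scipy.spatial.transform import Rotation

    from .pharmacophore import embed_compound

    if reference.conformer is None:
        raise ValueError("reference must have a conformer")
    rng = _rng(seed, "pharm")
    xyz = np.array([[x, y, z] for _e, x, y, z in reference.conformer])
    elements = [e for e, *_ in reference.conformer]
    compounds: list[Compound] = []
    rows = []
    for i in range(n_match):
        R = Rotation.random(random_state=int(rng.integers(2**31))).as_matrix()
        t = rng.uniform(-5, 5, size=3)
        new = xyz @ R.T + t + rng.normal(scale=jitter, size=xyz.shape)
        conf = [(el, *map(float, p)) for el, p in zip(elements, new)]
        cid = f"match{i:03d}"
        compounds.append(Compound(id=cid, smiles=reference.smiles, conformer=conf))
        rows.append((cid, True))
    decoy_smiles = ["CCCC", "CCCCC", "CCCCCC", "CC(C)CC", "CCC(C)C"]
    for j in range(n_decoys):
        smi = decoy_smiles[int(rng.integers(len(decoy_smiles)))]
        cid = f"decoy{j:03d}"
        comp = embed_compound(Compound(id=cid, smiles=smi), seed=int(rng.integers(2**31)))
        compounds.append(comp)
        rows.append((cid, False))
    return compounds, pd.DataFrame(rows, columns=["compound_id", "is_match"])


DEFAULT_DOSE_LADDER_M = (0.1e-6, 0.3e-6, 1e-6, 3e-6, 10e-6, 100e-6)


def gen_dose_response(
    seed: int,
    ic50: float,
    hill: float = 1.0,
    top: float = 100.0,
    bottom: float = 0.0,
    dose_ladder=DEFAULT_DOSE_LADDER_M,
    noise_frac: float = 0.0,
) -> tuple[DoseResponse, dict]:
    """Exact 4PL responses on a dose ladder, with multiplicative noise.

    response_i = 4PL(dose_i) * (1 + noise_frac * eps_i), eps ~ N(0, 1).
    """
    rng = _rng(seed, "dose")
    doses = np.asarray(dose_ladder, dtype=float)
    clean = four_pl(doses, ic50, hill, top, bottom)
    eps = rng.normal(size=len(doses)) if noise_frac > 0 else np.zeros(len(doses))
    responses = clean * (1.0 + noise_frac * eps)
    truth = {"ic50": ic50, "hill": hill, "top": top, "bottom": bottom,
             "noise_frac": noise_frac}
    return DoseResponse(doses=doses, responses=responses), truth


def gen_mst(
    seed: int,
    kd: float,
    target_conc: float = 80e-9,
    top_conc: float = 1e-5,
    n_points: int = 16,
    dilution: float = 2.0,
    noise_frac: float = 0.0,
    baseline: float = 1.0,
    amplitude: float = -0.2,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Mass-action F_norm titration on a serial-dilution ladder.

    L_i = top_conc / dilution^i for i = 0..n_points-1 (the default 16-point
    1:2 ladder from 10,000 nM ends at 0.305 nM); F_norm_i = baseline +
    amplitude * FB(L_i) + noise_frac * |amplitude| * eps_i.  Noise is
    quoted relative to the transition amplitude: F_norm is a ratio with an
    arbitrary offset near 1, so scaling noise by the baseline would tie
    the benchmark's difficulty to a nuisance parameter that carries no
    binding information.  Returns (titrant concentrations, fnorms, truth).
    """
    rng = _rng(seed, "mst")
    L = top_conc / dilution ** np.arange(n_points)
    clean = baseline + amplitude * fraction_bound(L, target_conc, kd)
    eps = rng.normal(size=n_points) if noise_frac > 0 else np.zeros(n_points)
    fnorms = clean + noise_frac * abs(amplitude) * eps
    truth = {"kd": kd, "target_conc": target_conc, "baseline": baseline,
             "amplitude": amplitude, "noise_frac": noise_frac}
    return L, fnorms, truth


# Cell counts of the packaged curated gene table: (direction, stat3, stat1)
# -> count; proportions for gene-table generation default to these.
TABLE3_PROPORTIONS: dict[tuple[str, str, str], int] = {
    ("down", "Pos", "None"): 8,
    ("down", "Pos", "Pos"): 16,
    ("down", "Neg", "Pos"): 14,
    ("down", "None", "Pos"): 10,
    ("up", "Neg", "None"): 36,
    ("up", "Neg", "Neg"): 1,
    ("up", "Pos", "None"): 1,
    ("up", "None", "Pos"): 4,
}


def gen_gene_table(
    seed: int,
    cell_counts: dict[tuple[str, str, str], int] | None = None,
    fc_min: float = 1.5,
    fdr_max: float = 0.01,
) -> tuple[pd.DataFrame, dict]:
    """Gene table with known (direction x STAT3 x STAT1) cell occupancies.

    Fold changes are drawn past the magnitude threshold (|fc| = fc_min +
    Exp(mean 0.5), signed by direction) and fdr uniformly below the
    significance threshold, so every generated gene survives the filter
    and the cross-tab recovers the planted counts exactly.
    """
    cells = TABLE3_PROPORTIONS if cell_counts is None else cell_counts
    rng = _rng(seed, "genes")
    rows = []
    g = 0
    for (direction, s3, s1), count in sorted(cells.items()):
        for _ in range(count):
            mag = fc_min + rng.exponential(0.5)
            fc = -mag if direction == "down" else mag
            fdr = float(rng.uniform(0.0, fdr_max * 0.9))
            rows.append((f"G{g:04d}", f"NM_{900000 + g}", round(fc, 3), fdr, s3, s1))
            g += 1
    df = pd.DataFrame(
        rows, columns=["gene", "refseq", "fold_change", "fdr", "stat3_prior", "stat1_prior"]
    )
    truth = {"cell_counts": {"|".join(k): v for k, v in sorted(cells.items())}}
    return df, truth
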