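"""3D pharmacophore features, distance-bin fingerprints, and 0-100 ranking.

Features are perceived from SMARTS rules over six classes — H-bond donor
(D), acceptor (A), hydrophobe (H), aromatic ring (R), negative ionizable
(N), positive ionizable (P) — each placed at the centroid of its matched
atoms (so a ring feature sits at the ring centroid).  Every unordered
feature pair contributes one count at the key (sorted type pair, distance
bin); the similarity of two such count maps is the count-vector Tanimoto
100 * sum(min) / sum(max), so identical maps score 100 and disjoint maps
score 0.  Candidates scoring strictly above the selection threshold
(default 70) are retained.

Default distance bins are 2-Angstrom-wide from 0 to 12 A with an overflow
bin; bins and feature rules are configurable (rules also loadable from
YAML: ``{type: [SMARTS, ...]}``).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from rdkit import Chem
from rdkit.Chem import AllChem
from sklearn.base import BaseEstimator, TransformerMixin

from .chem_io import Compound

__all__ = [
    "PharmFeature",
    "PharmFingerprint",
    "DEFAULT_FEATURE_RULES",
    "DEFAULT_BIN_EDGES",
    "load_feature_rules",
    "perceive_features",
    "embed_compound",
    "pharm_fingerprint",
    "pharm_similarity",
    "rank_and_select",
    "PharmacophoreRanker",
    "MissingConformerError",
]

FEATURE_TYPES = ("D", "A", "H", "R", "N", "P")

# One SMARTS list per feature class; a feature is the centroid of a match,
# deduplicated by (class, matched-atom set).
DEFAULT_FEATURE_RULES: dict[str, list[str]] = {
    "D": ["[#7;!H0]", "[#8;!H0]", "[#16;!H0]"],
    "A": ["[N;X1,X2,X3;!+]", "[O;X1,X2;!+]"],
    "H": ["[C;H1,H2,H3;!$([C]~[#7,#8,#9,#15,#16,#17,#35,#53])]"],
    "R": ["a1aaaaa1", "a1aaaa1"],
    "N": [
        "[CX3](=O)[OX1H0-,OX2H1]",
        "[SX4](=O)(=O)[OX1H0-,OX2H1]",
        "[PX4](=O)([OX1H0-,OX2H1])[OX1H0-,OX2H1]",
    ],
    "P": ["[NX3;H2,H3;+0;!$(NC=O)]", "[N+]"],
}

DEFAULT_BIN_EDGES: tuple[float, ...] = (0.0, 2.0, 4.0, 6.0, 8.0, 10.0, 12.0)

DEFAULT_EMBED_SEED = 20160325


class MissingConformerError(ValueError):
    """A 3D operation was requested on a compound without coordinates."""


@dataclass(frozen=True)
class PharmFeature:
    ftype: str
    centroid: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.ftype not in FEATURE_TYPES:
            raise ValueError(f"unknown feature type {self.ftype!r}")
        if not np.all(np.isfinite(self.centroid)):
            raise ValueError("non-finite centroid")


@dataclass(frozen=True)
class PharmFingerprint:
    """Count map over (sorted feature-type pair, distance-bin index) keys."""

    counts: dict[tuple[str, str, int], int]
    bin_edges: tuple[float, ...]

    def total(self) -> int:
        return sum(self.counts.values())


def load_feature_rules(path: str | Path) -> dict[str, list[str]]:
    """Load feature rules from a YAML file mapping type -> list of SMARTS."""
    rules = yaml.safe_load(Path(path).read_text())
    unknown = set(rules) - set(FEATURE_TYPES)
    if unknown:
        raise ValueError(f"unknown feature types in rules file: {sorted(unknown)}")
    return {k: list(v) for k, v in rules.items()}


def embed_compound(compound: Compound, seed: int = DEFAULT_EMBED_SEED) -> Compound:
    """Deterministic 3D embedding (seeded ETKDG); returns a new Compound.

    Hydrogens are used during embedding but only heavy-atom coordinates are
    stored, in graph order.
    """
    mol = Chem.AddHs(compound.to_mol())
    params = AllChem.ETKDGv3()
    params.randomSeed = seed
    if AllChem.EmbedMolecule(mol, params) != 0:
        params.useRandomCoords = True
        if AllChem.EmbedMolecule(mol, params) != 0:
            raise ValueError(f"3D embedding failed for compound {compound.id!r}")
    mol = Chem.RemoveHs(mol)
    conf = mol.GetConformer()
    conformer = [
        (atom.GetSymbol(), *map(float, conf.GetAtomPosition(atom.GetIdx())))
        for atom in mol.GetAtoms()
    ]
    return Compound(
        id=compound.id, smiles=compound.smiles, conformer=conformer, props=dict(compound.props)
    )


def perceive_features(
    compound: Compound, rules: dict[str, list[str]] | None = None
) -> list[PharmFeature]:
    """Perceive pharmacophore features from SMARTS rules on a 3D compound.

    Raises :class:`MissingConformerError` if the compound has no conformer.
    """
    if compound.conformer is None:
        raise MissingConformerError(f"compound {compound.id!r} has no conformer")
    rules = DEFAULT_FEATURE_RULES if rules is None else rules
    mol = compound.to_mol(with_coords=True)
    coords = mol.GetConformer().GetPositions()
    features: list[PharmFeature] = []
    seen: set[tuple[str, frozenset[int]]] = set()
    for ftype in FEATURE_TYPES:
        for smarts in rules.get(ftype, []):
            patt = Chem.MolFromSmarts(smarts)
            if patt is None:
                raise ValueError(f"invalid SMARTS for type {ftype}: {smarts!r}")
            for match in mol.GetSubstructMatches(patt):
                key = (ftype, frozenset(match))
                if key in seen:
                    continue
                seen.add(key)
                centroid = coords[list(match)].mean(axis=0)
                features.append(PharmFeature(ftype, tuple(map(float, centroid))))
    return features


def pharm_fingerprint(
    features: list[PharmFeature], bin_edges: tuple[float, ...] = DEFAULT_BIN_EDGES
) -> PharmFingerprint:
    """Distance-bin count fingerprint over all unordered feature pairs.

    A pair at distance d falls in bin b where edges[b] <= d < edges[b+1];
    d beyond the last edge falls in the overflow bin.
    """
    edges = tuple(float(e) for e in bin_edges)
    if len(edges) < 2 or edges[0] != 0.0:
        raise ValueError("bin_edges must start at 0 and contain >= 2 values")
    if any(lo >= hi for lo, hi in zip(edges, edges[1:])):
        raise ValueError("bin_edges must be strictly increasing")
    counts: dict[tuple[str, str, int], int] = {}
    pts = np.array([f.centroid for f in features]) if features else np.empty((0, 3))
    for i in range(len(features)):
        for j in range(i + 1, len(features)):
            d = float(np.linalg.norm(pts[i] - pts[j]))
            b = int(np.searchsorted(edges, d, side="right") - 1)
            b = min(b, len(edges) - 1)  # overflow bin for d >= last edge
            t1, t2 = sorted((features[i].ftype, features[j].ftype))
            key = (t1, t2, b)
            counts[key] = counts.get(key, 0) + 1
    return PharmFingerprint(counts=counts, bin_edges=edges)


def pharm_similarity(a: PharmFingerprint, b: PharmFingerprint) -> float:
    """Count-vector Tanimoto scaled to [0, 100].

    100 * sum_k min(a_k, b_k) / sum_k max(a_k, b_k) over the union of keys;
    both empty -> 100, exactly one empty -> 0.
    """
    if a.bin_edges != b.bin_edges:
        raise ValueError("fingerprints use different bin edges")
    keys = set(a.counts) | set(b.counts)
    if not keys:
        return 100.0
    num = sum(min(a.counts.get(k, 0), b.counts.get(k, 0)) for k in keys)
    den = sum(max(a.counts.get(k, 0), b.counts.get(k, 0)) for k in keys)
    return 100.0 * num / den


class PharmacophoreRanker(BaseEstimator, TransformerMixin):
    """Rank a library by pharmacophore similarity to a reference.

    Parameters
    ----------
    threshold : float
        Selection threshold; compounds scoring strictly above it are
        selected (default 70).
    bin_edges : tuple of float
        Distance-bin edges in Angstrom.
    rules : dict or None
        Feature SMARTS rules; None uses :data:`DEFAULT_FEATURE_RULES`.
    embed : bool
        Whether to embed compounds lacking a conformer (seeded ETKDG).
    embed_seed : int
        Seed for the deterministic embedding.

    Attributes
    ----------
    reference_fp_ : PharmFingerprint
        Fingerprint of the reference (or pooled references) set by fit.
    """

    def __init__(
        self,
        threshold: float = 70.0,
        bin_edges: tuple[float, ...] = DEFAULT_BIN_EDGES,
        rules: dict[str, list[str]] | None = None,
        embed: bool = True,
        embed_seed: int = DEFAULT_EMBED_SEED,
    ):
        self.threshold = threshold
        self.bin_edges = bin_edges
        self.rules = rules
        self.embed = embed
        self.embed_seed = embed_seed

    def _fingerprint(self, compound: Compound) -> PharmFingerprint:
        if compound.conformer is None:
            if not self.embed:
                raise MissingConformerError(
                    f"compound {compound.id!r} has no conformer and embedding is disabled"
                )
            compound = embed_compound(compound, seed=self.embed_seed)
        feats = perceive_features(compound, rules=self.rules)
        return pharm_fingerprint(feats, bin_edges=self.bin_edges)

    def fit(self, reference: Compound | list[Compound], y=None) -> "PharmacophoreRanker":
        """Fit on a single reference, or pool several (elementwise count max)."""
        if isinstance(reference, Compound):
            self.reference_fp_ = self._fingerprint(reference)
            return self
        fps = [self._fingerprint(c) for c in reference]
        if not fps:
            raise ValueError("empty reference set")
        pooled: dict[tuple[str, str, int], int] = {}
        for fp in fps:
            for k, v in fp.counts.items():
                pooled[k] = max(pooled.get(k, 0), v)
        self.reference_fp_ = PharmFingerprint(pooled, fps[0].bin_edges)
        return self

    def transform(self, library: list[Compound]) -> pd.DataFrame:
        """Score the library; columns (compound_id, score, selected).

        Sorted by descending score, ties broken by compound id; ``selected``
        is score strictly greater than ``threshold``.
        """
        if not hasattr(self, "reference_fp_"):
            raise RuntimeError("ranker is not fitted; call fit(reference) first")
        rows = []
        for comp in library:
            score = pharm_similarity(self.reference_fp_, self._fingerprint(comp))
            rows.append((comp.id, score, score > self.threshold))
        df = pd.DataFrame(rows, columns=["compound_id", "score", "selected"])
        return df.sort_values(
            ["score", "compound_id"], ascending=[False, True], ignore_index=True
        )


def rank_and_select(
    library: list[Compound],
    reference: Compound,
    threshold: float = 70.0,
    bin_edges: tuple[float, ...] = DEFAULT_BIN_EDGES,
    rules: dict[str, list[str]] | None = None,
    embed: bool = True,
    embed_seed: int = DEFAULT_EMBED_SEED,
) -> tuple[pd.DataFrame, list[str]]:
    """Rank a library and return (ranked table, selected compound ids)."""
    ranker = PharmacophoreRanker(
        threshold=threshold, bin_edges=bin_edges, rules=rules, embed=embed, embed_seed=embed_seed
    )
    ranked = ranker.fit(reference).transform(library)
    selected = ranked.loc[ranked["selected"], "compound_id"].tolist()
    return ranked, selected
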