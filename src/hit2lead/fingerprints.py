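"""2D hashed linear-path fingerprints and Tanimoto library screening.

The fingerprint enumerates every simple (non-self-intersecting, unbranched)
bond path of 1..``max_path_bonds`` bonds over the heavy-atom graph.  Atoms
are typed by (element, aromaticity, formal charge) and bonds by order; the
canonical token string of each path (the lexicographic minimum of the two
read directions) is hashed with 32-bit FNV-1a onto one of ``nbits`` bits.
Elaborating a scaffold only adds paths, so the bit set of an analog contains
the bit set of its scaffold — this is the containment semantics used to
screen for analogs of a reference structure ("100 percent similarity"
against a scaffold).  A plain Tanimoto cutoff mode is also available.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from rdkit import Chem
from sklearn.base import BaseEstimator, TransformerMixin

from .chem_io import Compound, EmptyLibraryError

__all__ = [
    "Fingerprint2D",
    "fingerprint2d",
    "tanimoto",
    "screen_library",
    "TanimotoScreener",
]

_FNV_OFFSET = 2166136261
_FNV_PRIME = 16777619


def _fnv1a32(data: bytes) -> int:
    h = _FNV_OFFSET
    for b in data:
        h ^= b
        h = (h * _FNV_PRIME) & 0xFFFFFFFF
    return h


@dataclass(frozen=True)
class Fingerprint2D:
    """A hashed path fingerprint: a set of on-bits out of ``nbits``."""

    nbits: int
    bits: frozenset[int]

    def __post_init__(self) -> None:
        if self.bits and max(self.bits) >= self.nbits:
            raise ValueError("bit index out of range")


def _atom_token(atom: Chem.Atom) -> str:
    return f"{atom.GetSymbol()}{'a' if atom.GetIsAromatic() else ''}{atom.GetFormalCharge():+d}"


def _bond_token(bond: Chem.Bond) -> str:
    if bond.GetIsAromatic():
        return "~"
    return {Chem.BondType.SINGLE: "-", Chem.BondType.DOUBLE: "=", Chem.BondType.TRIPLE: "#"}.get(
        bond.GetBondType(), str(bond.GetBondTypeAsDouble())
    )


def _enumerate_path_tokens(mol: Chem.Mol, max_path_bonds: int) -> set[str]:
    """Canonical token strings for all simple linear paths of 1..n bonds."""
    atok = [_atom_token(a) for a in mol.GetAtoms()]
    neighbors: list[list[tuple[int, str]]] = [[] for _ in range(mol.GetNumAtoms())]
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        btok = _bond_token(bond)
        neighbors[i].append((j, btok))
        neighbors[j].append((i, btok))

    tokens: set[str] = set()

    def dfs(path: list[int], toks: list[str]) -> None:
        if len(path) > 1:
            fwd = "".join(toks)
            rev = "".join(reversed(toks))
            tokens.add(min(fwd, rev))
        if len(path) - 1 == max_path_bonds:
            return
        last = path[-1]
        for nxt, btok in neighbors[last]:
            if nxt in path:
                continue
            dfs(path + [nxt], toks + [btok, atok[nxt]])

    for start in range(mol.GetNumAtoms()):
        dfs([start], [atok[start]])
    return tokens


def fingerprint2d(
    compound: Compound | str, max_path_bonds: int = 7, nbits: int = 2048
) -> Fingerprint2D:
    """Hashed linear-path fingerprint of a compound.

    Deterministic and invariant to atom ordering (paths are canonicalized by
    direction and enumerated exhaustively).  A molecule with no bonds (e.g.
    methane over heavy atoms) yields an empty bit set.
    """
    smiles = compound.smiles if isinstance(compound, Compound) else compound
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    tokens = _enumerate_path_tokens(mol, max_path_bonds)
    bits = frozenset(_fnv1a32(t.encode()) % nbits for t in tokens)
    return Fingerprint2D(nbits=nbits, bits=bits)


def tanimoto(a: Fingerprint2D, b: Fingerprint2D) -> float:
    """|a∩b| / |a∪b| over the on-bits; two empty fingerprints → 1.0."""
    if a.nbits != b.nbits:
        raise ValueError(f"fingerprint lengths differ: {a.nbits} vs {b.nbits}")
    union = len(a.bits | b.bits)
    if union == 0:
        return 1.0
    return len(a.bits & b.bits) / union


class TanimotoScreener(BaseEstimator, TransformerMixin):
    """Screen a library against a reference compound.

    Parameters
    ----------
    mode : {"containment", "tanimoto"}
        ``containment`` flags a hit when every reference bit is present in
        the candidate (scaffold-analog semantics, the default); ``tanimoto``
        flags a hit when the Tanimoto coefficient is >= ``cutoff``.
    cutoff : float in [0, 1]
        Tanimoto-mode hit threshold (ignored for containment).
    max_path_bonds, nbits : int
        Fingerprint parameters.

    Attributes
    ----------
    reference_fp_ : Fingerprint2D
        Fingerprint of the reference set by :meth:`fit`.
    """

    def __init__(
        self,
        mode: str = "containment",
        cutoff: float = 1.0,
        max_path_bonds: int = 7,
        nbits: int = 2048,
    ):
        self.mode = mode
        self.cutoff = cutoff
        self.max_path_bonds = max_path_bonds
        self.nbits = nbits

    def fit(self, reference: Compound | str, y=None) -> "TanimotoScreener":
        if self.mode not in ("containment", "tanimoto"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not 0.0 <= self.cutoff <= 1.0:
            raise ValueError(f"cutoff must be in [0, 1], got {self.cutoff}")
        self.reference_fp_ = fingerprint2d(reference, self.max_path_bonds, self.nbits)
        return self

    def transform(self, library: list[Compound]) -> pd.DataFrame:
        """Rank the library; returns columns (compound_id, tanimoto, passes).

        Sorted by descending Tanimoto, ties broken by compound id.
        """
        if not hasattr(self, "reference_fp_"):
            raise RuntimeError("screener is not fitted; call fit(reference) first")
        if not library:
            raise EmptyLibraryError("empty library")
        ref = self.reference_fp_
        rows = []
        for comp in library:
            fp = fingerprint2d(comp, self.max_path_bonds, self.nbits)
            t = tanimoto(ref, fp)
            if self.mode == "containment":
                passes = ref.bits <= fp.bits
            else:
                passes = t >= self.cutoff
            rows.append((comp.id, t, passes))
        df = pd.DataFrame(rows, columns=["compound_id", "tanimoto", "passes"])
        return df.sort_values(
            ["tanimoto", "compound_id"], ascending=[False, True], ignore_index=True
        )


def screen_library(
    library: list[Compound],
    reference: Compound | str,
    mode: str = "containment",
    cutoff: float = 1.0,
    max_path_bonds: int = 7,
    nbits: int = 2048,
) -> pd.DataFrame:
    """Functional wrapper over :class:`TanimotoScreener`."""
    screener = TanimotoScreener(
        mode=mode, cutoff=cutoff, max_path_bonds=max_path_bonds, nbits=nbits
    )
    return screener.fit(reference).transform(library)
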