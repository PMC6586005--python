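"""Feature computation: built-in physchem descriptors, hashed circular
fingerprints, pluggable external providers, and the missing/zero-variance
feature filter.

The physchem block is a compact, interpretable subset — molecular weight,
Wildman-Crippen logP, topological polar surface area (all-heteroatom and
N/O-only variants), hydrogen-bond donor/acceptor counts, acidic/basic group
counts, rotatable bonds, ring statistics — computed via RDKit.  The circular
fingerprint (extended-connectivity, diameter 4, folded to 4,096 bits by
default) is implemented here from first principles: invariant atom
initialization, iterative neighbourhood hashing, duplicate-environment
collapse by bond set, and modulo folding, with a platform-stable hash.

External descriptor providers (anything returning a named numeric matrix for
a list of structures) can be plugged in to extend the feature space.
"""

from __future__ import annotations

import hashlib
import struct
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski, rdMolDescriptors

__all__ = [
    "FingerprintConfig",
    "DescriptorMatrix",
    "PHYSCHEM_NAMES",
    "compute_physchem",
    "circular_fingerprint",
    "build_matrix",
    "filter_features",
    "ro5_profile",
]

_ACID_SMARTS = [
    Chem.MolFromSmarts(s)
    for s in (
        "[CX3](=O)[OX2H1]",          # carboxylic acid
        "[SX4](=O)(=O)[OX2H1]",      # sulfonic acid
        "[PX4](=O)([OX2H1])",        # phosphonic/phosphoric acid
        "c1ccc(cc1)[OX2H1]",         # phenol (weakly acidic) excluded: keep strict
    )[:3]
]
_BASE_SMARTS = [
    Chem.MolFromSmarts(s)
    for s in ("[NX3;H2;!$(NC=O)]", "[NX3;H1;!$(NC=O)](C)C", "[NX3;H0;!$(NC=O)](C)(C)C")
]


@dataclass(frozen=True)
class FingerprintConfig:
    """Circular-fingerprint settings: environment diameter and folded width."""

    diameter: int = 4
    nbits: int = 4096

    def __post_init__(self) -> None:
        if self.diameter < 0 or self.diameter % 2:
            raise ValueError(f"diameter must be an even nonnegative integer, got {self.diameter}")
        if self.nbits < 1 or (self.nbits & (self.nbits - 1)):
            raise ValueError(f"nbits must be a power of two, got {self.nbits}")

    @property
    def radius(self) -> int:
        return self.diameter // 2


@dataclass
class DescriptorMatrix:
    """Compounds x features with per-feature provenance.

    values is a dense float matrix; fingerprint bits live in {0,1}.
    """

    compound_ids: list[str]
    feature_names: list[str]
    values: np.ndarray
    provenance: list[str]  # physchem | fingerprint | external, per feature

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.compound_ids), len(self.feature_names)):
            raise ValueError("values shape does not match ids x features")
        if len(self.provenance) != len(self.feature_names):
            raise ValueError("one provenance tag per feature required")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.compound_ids, columns=self.feature_names)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, provenance: Sequence[str]) -> "DescriptorMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float), list(provenance))


PHYSCHEM_NAMES = [
    "MW",
    "SLogP",
    "TopoPSA",
    "TopoPSA_NO",
    "HBA",
    "HBD",
    "nAcid",
    "nBase",
    "nRot",
    "nAromRing",
    "nRing",
    "nHeavy",
    "FracCSP3",
    "nHetero",
    "nF",
    "nCl",
    "MR",
]


def compute_physchem(mol: Chem.Mol) -> dict[str, float]:
    """Named physchem descriptor vector for one parsed structure.

    A descriptor that fails on an exotic structure is reported as NaN and
    later removed by :func:`filter_features`.
    """
    out: dict[str, float] = {}

    def safe(name: str, fn: Callable[[], float]) -> None:
        try:
            out[name] = float(fn())
        except Exception:
            out[name] = float("nan")

    safe("MW", lambda: Descriptors.MolWt(mol))
    safe("SLogP", lambda: Crippen.MolLogP(mol))
    safe("TopoPSA", lambda: rdMolDescriptors.CalcTPSA(mol, includeSandP=True))
    safe("TopoPSA_NO", lambda: rdMolDescriptors.CalcTPSA(mol))
    safe("HBA", lambda: Lipinski.NumHAcceptors(mol))
    safe("HBD", lambda: Lipinski.NumHDonors(mol))
    safe("nAcid", lambda: sum(len(mol.GetSubstructMatches(p)) for p in _ACID_SMARTS))
    safe("nBase", lambda: sum(len(mol.GetSubstructMatches(p)) for p in _BASE_SMARTS))
    safe("nRot", lambda: Lipinski.NumRotatableBonds(mol))
    safe("nAromRing", lambda: rdMolDescriptors.CalcNumAromaticRings(mol))
    safe("nRing", lambda: rdMolDescriptors.CalcNumRings(mol))
    safe("nHeavy", lambda: mol.GetNumHeavyAtoms())
    safe("FracCSP3", lambda: rdMolDescriptors.CalcFractionCSP3(mol))
    safe("nHetero", lambda: rdMolDescriptors.CalcNumHeteroatoms(mol))
    safe("nF", lambda: sum(1 for a in mol.GetAtoms() if a.GetSymbol() == "F"))
    safe("nCl", lambda: sum(1 for a in mol.GetAtoms() if a.GetSymbol() == "Cl"))
    safe("MR", lambda: Crippen.MolMR(mol))
    return out


def _hash64(*ints: int) -> int:
    """Platform-stable 64-bit hash of a tuple of integers."""
    packed = struct.pack(f"<{len(ints)}Q", *(v & 0xFFFFFFFFFFFFFFFF for v in ints))
    return int.from_bytes(hashlib.blake2b(packed, digest_size=8).digest(), "little")


def circular_fingerprint(mol: Chem.Mol, config: FingerprintConfig = FingerprintConfig()) -> np.ndarray:
    """Extended-connectivity fingerprint folded to ``config.nbits`` bits.

    Atom identifiers start from an invariant tuple (atomic number, heavy
    degree, total H count, formal charge, ring membership) and are refined
    ``diameter/2`` times by hashing each atom's identifier with its sorted
    (bond order, neighbour identifier) pairs.  An environment is emitted only
    if its bond set has not been produced before (identical environments
    collapse — e.g. methane sets exactly one bit); emitted identifiers fold
    into the bit vector modulo ``nbits``.
    """
    bits = np.zeros(config.nbits, dtype=np.uint8)
    n = mol.GetNumAtoms()
    if n == 0:
        return bits

    ids: list[int] = []
    for atom in mol.GetAtoms():
        ids.append(
            _hash64(
                atom.GetAtomicNum(),
                atom.GetDegree(),
                atom.GetTotalNumHs(),
                atom.GetFormalCharge(),
                int(atom.IsInRing()),
            )
        )

    seen_envs: set[frozenset[int]] = set()
    # radius-0 environments: empty bond set, shared by every atom — emit the
    # distinct identifiers (duplicates fold to the same bit anyway)
    env_bonds: list[frozenset[int]] = [frozenset() for _ in range(n)]
    emitted: list[int] = []
    for i in range(n):
        emitted.append(ids[i])
    seen_envs.add(frozenset())

    bond_order = {
        Chem.BondType.SINGLE: 1,
        Chem.BondType.DOUBLE: 2,
        Chem.BondType.TRIPLE: 3,
        Chem.BondType.AROMATIC: 4,
    }

    for _ in range(config.radius):
        new_ids = list(ids)
        new_envs = list(env_bonds)
        # deterministic atom order; growth then dedup by environment bond set
        for i, atom in enumerate(mol.GetAtoms()):
            nbrs = []
            env = set(env_bonds[i])
            for bond in atom.GetBonds():
                j = bond.GetOtherAtomIdx(i)
                nbrs.append((bond_order.get(bond.GetBondType(), 5), ids[j]))
                env.add(bond.GetIdx())
                env.update(env_bonds[j])
            nbrs.sort()
            flat = [ids[i]]
            for o, nid in nbrs:
                flat.extend((o, nid))
            new_ids[i] = _hash64(*flat)
            new_envs[i] = frozenset(env)
        ids = new_ids
        env_bonds = new_envs
        # collapse identical environments: one identifier per new bond set,
        # the smallest, so the result is independent of atom input order
        fresh: dict[frozenset[int], int] = {}
        for i in range(n):
            env = env_bonds[i]
            if env in seen_envs:
                continue
            if env not in fresh or ids[i] < fresh[env]:
                fresh[env] = ids[i]
        for env, ident in fresh.items():
            seen_envs.add(env)
            emitted.append(ident)

    for ident in emitted:
        bits[ident % config.nbits] = 1
    return bits


def build_matrix(
    structures: dict[str, str],
    fingerprint: FingerprintConfig | None = FingerprintConfig(),
    physchem: bool = True,
    external_provider: Callable[[dict[str, str]], pd.DataFrame] | None = None,
) -> DescriptorMatrix:
    """Assemble the full descriptor matrix for ``{compound_id: smiles}``.

    Column blocks: physchem, fingerprint bits (``FP0000``...), then any
    external provider output.  Unparseable structures raise — parse failures
    should have been screened out upstream by io_chem.
    """
    ids = list(structures)
    mols = []
    for cid in ids:
        mol = Chem.MolFromSmiles(structures[cid])
        if mol is None:
            raise ValueError(f"unparseable SMILES for compound {cid}: {structures[cid]!r}")
        mols.append(mol)

    blocks: list[np.ndarray] = []
    names: list[str] = []
    prov: list[str] = []

    if physchem:
        rows = [compute_physchem(m) for m in mols]
        names.extend(PHYSCHEM_NAMES)
        prov.extend(["physchem"] * len(PHYSCHEM_NAMES))
        blocks.append(np.array([[r[n] for n in PHYSCHEM_NAMES] for r in rows], dtype=float))

    if fingerprint is not None:
        width = len(str(fingerprint.nbits - 1))
        names.extend(f"FP{i:0{width}d}" for i in range(fingerprint.nbits))
        prov.extend(["fingerprint"] * fingerprint.nbits)
        blocks.append(
            np.array([circular_fingerprint(m, fingerprint) for m in mols], dtype=float)
        )

    if external_provider is not None:
        ext = external_provider(structures)
        ext = ext.loc[ids]
        names.extend(str(c) for c in ext.columns)
        prov.extend(["external"] * ext.shape[1])
        blocks.append(ext.to_numpy(dtype=float))

    values = np.hstack(blocks) if blocks else np.zeros((len(ids), 0))
    return DescriptorMatrix(ids, names, values, prov)


def filter_features(matrix: DescriptorMatrix) -> tuple[DescriptorMatrix, pd.DataFrame]:
    """Drop features with any missing value or zero variance.

    Zero variance is exact equality of every entry in the raw column, not a
    variance-epsilon test.  Returns the reduced matrix and a report listing
    each removal with its reason.  Idempotent; raises if nothing survives.
    """
    X = matrix.values
    removed: list[tuple[str, str]] = []
    keep: list[int] = []
    for j, name in enumerate(matrix.feature_names):
        col = X[:, j]
        if np.isnan(col).any():
            removed.append((name, "missing"))
        elif np.all(col == col[0]):
            removed.append((name, "zero_variance"))
        else:
            keep.append(j)
    if not keep:
        raise ValueError("feature filtering removed every column")
    reduced = DescriptorMatrix(
        list(matrix.compound_ids),
        [matrix.feature_names[j] for j in keep],
        X[:, keep].copy(),
        [matrix.provenance[j] for j in keep],
    )
    report = pd.DataFrame(removed, columns=["feature_name", "reason"])
    return reduced, report


def ro5_profile(mol: Chem.Mol) -> dict[str, object]:
    """Lipinski rule-of-five profile: values plus strict pass/fail flags.

    Criteria (strict inequalities): MW < 500, logP < 5, HBA < 10, HBD < 5.
    """
    mw = Descriptors.MolWt(mol)
    logp = Crippen.MolLogP(mol)
    hba = Lipinski.NumHAcceptors(mol)
    hbd = Lipinski.NumHDonors(mol)
    return {
        "MW": mw,
        "logP": logp,
        "HBA": hba,
        "HBD": hbd,
        "MW_ok": mw < 500.0,
        "logP_ok": logp < 5.0,
        "HBA_ok": hba < 10,
        "HBD_ok": hbd < 5,
    }
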