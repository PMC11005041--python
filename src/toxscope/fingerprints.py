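"""SMILES standardization, fingerprint computation and bit-to-atom maps.

Three fingerprint families are supported:

* ``MORGAN`` -- circular (ECFP-like) environments of radius 2 hashed to 1024
  bits; each on-bit retro-maps to the atoms of the hashed environment(s).
* ``PATH_TOPOLOGICAL`` -- RDKit's Daylight-inspired topological fingerprint
  over bond subgraphs of 1-7 bonds, hashed to 2048 bits; each on-bit
  retro-maps to the atoms of the hashed subgraph(s).
* ``PUBCHEM`` -- an 881-bit substructure key (see :mod:`toxscope._pubchem`);
  each on-bit retro-maps to the atoms matched by the bit's definition, one
  atom set per occurrence.

The bit-to-atom maps are what later allows Shapley feature attributions to be
re-painted onto the molecular structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from functools import lru_cache
from typing import Iterable

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import rdFingerprintGenerator
from rdkit.Chem.MolStandardize import rdMolStandardize

from . import _pubchem

RDLogger.DisableLog("rdApp.error")
RDLogger.DisableLog("rdApp.warning")


class SMILESError(ValueError):
    """Raised when a SMILES string cannot be parsed or standardized."""


class Family(str, Enum):
    MORGAN = "MORGAN"
    PATH_TOPOLOGICAL = "PATH_TOPOLOGICAL"
    PUBCHEM = "PUBCHEM"


@dataclass(frozen=True)
class FingerprintConfig:
    """Fixed per-experiment fingerprint settings.

    Morgan radius 2 / 1024 bits and the 881-bit substructure key are fixed by
    the method; the topological family's length and path-size range are free
    parameters, defaulting to 2048 bits over 1-7 bond paths.
    """

    morgan_radius: int = 2
    morgan_n_bits: int = 1024
    path_n_bits: int = 2048
    path_min_bonds: int = 1
    path_max_bonds: int = 7


DEFAULT_CONFIG = FingerprintConfig()


def family_length(family: Family, config: FingerprintConfig = DEFAULT_CONFIG) -> int:
    if family == Family.MORGAN:
        return config.morgan_n_bits
    if family == Family.PATH_TOPOLOGICAL:
        return config.path_n_bits
    if family == Family.PUBCHEM:
        return _pubchem.N_BITS
    raise ValueError(f"unknown family: {family!r}")


@dataclass(frozen=True)
class MoleculeRecord:
    """A parsed, standardized molecule with stable heavy-atom indexing.

    ``mol`` is re-parsed from the canonical SMILES, so atom indices in every
    downstream bit-atom map refer to the canonical atom order.
    """

    raw_smiles: str
    canonical_smiles: str
    n_atoms: int
    mol: Chem.Mol = field(repr=False, compare=False)

    @property
    def atom_indices(self) -> tuple[int, ...]:
        return tuple(range(self.n_atoms))


@dataclass(frozen=True)
class BitVector:
    family: Family
    length: int
    bits: frozenset[int]

    def to_array(self) -> np.ndarray:
        arr = np.zeros(self.length, dtype=np.uint8)
        arr[list(self.bits)] = 1
        return arr


@dataclass(frozen=True)
class BitAtomMap:
    """On-bit -> occurrence list (one atom-index tuple per occurrence).

    ``unmappable`` records on-bits for which no atom correspondence could be
    derived; they contribute nothing to atom weights.
    """

    family: Family
    entries: dict[int, list[tuple[int, ...]]]
    unmappable: frozenset[int] = frozenset()

    def n_occ(self, bit: int) -> int:
        return len(self.entries[bit])


_FRAGMENT_CHOOSER = rdMolStandardize.LargestFragmentChooser()


def standardize_smiles(raw: str) -> MoleculeRecord:
    """Parse a SMILES string into a standardized :class:`MoleculeRecord`.

    Standardization keeps the largest covalent fragment (salt/solvate
    stripping), sanitizes, and writes the RDKit canonical SMILES;
    stereochemistry present in the input is retained.  Identical structures
    written differently yield identical ``canonical_smiles``.
    """
    if not isinstance(raw, str) or not raw.strip():
        raise SMILESError(f"empty or non-text SMILES input: {raw!r}")
    mol = Chem.MolFromSmiles(raw.strip())
    if mol is None:
        raise SMILESError(f"unparsable SMILES: {raw.strip()!r}")
    mol = _FRAGMENT_CHOOSER.choose(mol)
    canonical = Chem.MolToSmiles(mol)
    mol = Chem.MolFromSmiles(canonical)
    if mol is None or mol.GetNumAtoms() < 1:  # pragma: no cover - defensive
        raise SMILESError(f"standardization failed for {raw.strip()!r}")
    return MoleculeRecord(raw_smiles=raw, canonical_smiles=canonical,
                          n_atoms=mol.GetNumAtoms(), mol=mol)


def standardize_many(smiles: Iterable[str]) -> tuple[list[MoleculeRecord], list[tuple[str, str]]]:
    """Standardize a batch; failures are collected, not raised."""
    records, failures = [], []
    for s in smiles:
        try:
            records.append(standardize_smiles(s))
        except SMILESError as exc:
            failures.append((s, str(exc)))
    return records, failures


@lru_cache(maxsize=8)
def _morgan_generator(radius: int, n_bits: int):
    return rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)


@lru_cache(maxsize=8)
def _path_generator(min_bonds: int, max_bonds: int, n_bits: int):
    return rdFingerprintGenerator.GetRDKitFPGenerator(
        minPath=min_bonds, maxPath=max_bonds, fpSize=n_bits)


def compute_fingerprint(mol: MoleculeRecord, family: Family,
                        config: FingerprintConfig = DEFAULT_CONFIG) -> BitVector:
    """Compute the binary fingerprint of ``mol`` for one family."""
    family = Family(family)
    length = family_length(family, config)
    if family == Family.MORGAN:
        fp = _morgan_generator(config.morgan_radius, config.morgan_n_bits) \
            .GetFingerprint(mol.mol)
        bits = frozenset(fp.GetOnBits())
    elif family == Family.PATH_TOPOLOGICAL:
        fp = _path_generator(config.path_min_bonds, config.path_max_bonds,
                             config.path_n_bits).GetFingerprint(mol.mol)
        bits = frozenset(fp.GetOnBits())
    else:
        bits = frozenset(_pubchem.match_bits(mol.mol))
    return BitVector(family=family, length=length, bits=bits)


def _morgan_env_atoms(mol: Chem.Mol, atom: int, radius: int) -> tuple[int, ...]:
    if radius == 0:
        return (atom,)
    bond_ids = Chem.FindAtomEnvironmentOfRadiusN(mol, radius, atom)
    atoms = {atom}
    for b in bond_ids:
        bond = mol.GetBondWithIdx(b)
        atoms.add(bond.GetBeginAtomIdx())
        atoms.add(bond.GetEndAtomIdx())
    return tuple(sorted(atoms))


def _path_atoms(mol: Chem.Mol, bond_path: tuple[int, ...]) -> tuple[int, ...]:
    atoms = set()
    for b in bond_path:
        bond = mol.GetBondWithIdx(b)
        atoms.add(bond.GetBeginAtomIdx())
        atoms.add(bond.GetEndAtomIdx())
    return tuple(sorted(atoms))


def map_bits_to_atoms(mol: MoleculeRecord, family: Family, fp: BitVector,
                      config: FingerprintConfig = DEFAULT_CONFIG) -> BitAtomMap:
    """Trace every on-bit of ``fp`` back to the atoms that set it.

    Hash collisions (several substructures setting one bit) are retained as
    separate occurrences of that bit.
    """
    family = Family(family)
    if fp.family != family:
        raise ValueError(f"fingerprint family {fp.family} does not match {family}")
    if fp.length != family_length(family, config):
        raise ValueError("fingerprint length does not match configuration")

    entries: dict[int, list[tuple[int, ...]]] = {}
    if family == Family.MORGAN:
        ao = rdFingerprintGenerator.AdditionalOutput()
        ao.AllocateBitInfoMap()
        _morgan_generator(config.morgan_radius, config.morgan_n_bits) \
            .GetFingerprint(mol.mol, additionalOutput=ao)
        for bit, envs in ao.GetBitInfoMap().items():
            entries[bit] = [_morgan_env_atoms(mol.mol, a, r) for a, r in envs]
    elif family == Family.PATH_TOPOLOGICAL:
        ao = rdFingerprintGenerator.AdditionalOutput()
        ao.AllocateBitPaths()
        _path_generator(config.path_min_bonds, config.path_max_bonds,
                        config.path_n_bits).GetFingerprint(mol.mol, additionalOutput=ao)
        for bit, paths in ao.GetBitPaths().items():
            entries[bit] = [_path_atoms(mol.mol, p) for p in paths]
    else:
        entries = _pubchem.match_bits(mol.mol)

    unmappable = frozenset(fp.bits - set(entries))
    entries = {b: occ for b, occ in entries.items() if b in fp.bits}
    for bit, occs in entries.items():
        for occ in occs:
            for a in occ:
                if a >= mol.n_atoms:  # pragma: no cover - defensive
                    raise ValueError(f"atom index {a} out of range for bit {bit}")
    return BitAtomMap(family=family, entries=entries, unmappable=unmappable)


def fingerprint_matrix(records: list[MoleculeRecord], family: Family,
                       config: FingerprintConfig = DEFAULT_CONFIG) -> np.ndarray:
    """Stack fingerprints into an (n_molecules, n_bits) uint8 matrix."""
    length = family_length(family, config)
    X = np.zeros((len(records), length), dtype=np.uint8)
    for i, rec in enumerate(records):
        X[i, list(compute_fingerprint(rec, family, config).bits)] = 1
    return X
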