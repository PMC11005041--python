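"""Reading and writing the toolkit's plain-text formats.

SMILES come in as ``.smi`` files (one record per line, ``SMILES[ id]`` or
``SMILES,id``) or CSV with ``smiles``/``label`` columns (header optional).
Outputs are UTF-8 CSV/JSON: labeled datasets, fingerprint matrices and the
bit-atom map dialect ``{bit: [[atom, ...], ...]}`` with 0-based atom indices.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import pandas as pd

from .curation import LabeledCompound
from .fingerprints import (BitAtomMap, Family, FingerprintConfig,
                           DEFAULT_CONFIG, MoleculeRecord,
                           compute_fingerprint, family_length,
                           standardize_smiles)


def read_smiles_file(path) -> list[tuple[str, str]]:
    """Read a .smi file into (smiles, id) pairs; ids default to row numbers."""
    out = []
    for i, line in enumerate(Path(path).read_text().splitlines()):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = [p for p in line.replace(",", " ").split() if p]
        out.append((parts[0], parts[1] if len(parts) > 1 else f"mol{i}"))
    return out


def _find_column(df: pd.DataFrame, name: str) -> str | None:
    for c in df.columns:
        if str(c).strip().lower() == name:
            return c
    return None


def read_labeled_csv(path) -> pd.DataFrame:
    """Read a smiles,label CSV (header tolerant) into a tidy DataFrame."""
    df = pd.read_csv(path)
    smiles_col = _find_column(df, "smiles")
    if smiles_col is None:
        df = pd.read_csv(path, header=None)
        if df.shape[1] < 2:
            raise ValueError(f"{path}: expected smiles,label columns")
        df.columns = ["smiles", "label"] + [f"extra{i}" for i in
                                            range(df.shape[1] - 2)]
        smiles_col = "smiles"
    label_col = _find_column(df, "label")
    if label_col is None:
        raise ValueError(f"{path}: no label column found")
    out = df.rename(columns={smiles_col: "smiles", label_col: "label"})
    out["label"] = out["label"].astype(int)
    return out[["smiles", "label"]]


def dataset_from_frame(df: pd.DataFrame) -> tuple[list[LabeledCompound], list[tuple[str, str]]]:
    """Standardize a smiles,label frame; per-row failures are collected."""
    records, failures = [], []
    for smiles, label in zip(df["smiles"], df["label"]):
        try:
            rec = standardize_smiles(str(smiles))
        except ValueError as exc:
            failures.append((str(smiles), str(exc)))
            continue
        records.append(LabeledCompound(mol=rec, label=int(label)))
    return records, failures


def load_labeled_dataset(path) -> list[LabeledCompound]:
    records, failures = dataset_from_frame(read_labeled_csv(path))
    if failures:
        bad = ", ".join(s for s, _ in failures[:5])
        raise ValueError(f"{path}: {len(failures)} unparsable SMILES ({bad} ...)")
    return records


def write_labeled_csv(records: list[LabeledCompound], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["smiles", "label"])
        for r in records:
            w.writerow([r.mol.canonical_smiles, r.label])


def write_fingerprint_csv(records: list[MoleculeRecord], family: Family,
                          path, config: FingerprintConfig = DEFAULT_CONFIG) -> None:
    """One row per compound, one 0/1 column per bit."""
    length = family_length(family, config)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["smiles"] + [f"bit{i}" for i in range(length)])
        for rec in records:
            row = [0] * length
            for b in compute_fingerprint(rec, family, config).bits:
                row[b] = 1
            w.writerow([rec.canonical_smiles] + row)


def write_bit_atom_json(bam: BitAtomMap, path) -> None:
    payload = {str(bit): [list(occ) for occ in occs]
               for bit, occs in sorted(bam.entries.items())}
    with open(path, "w") as fh:
        json.dump({"family": bam.family.value, "entries": payload,
                   "unmappable": sorted(bam.unmappable)}, fh)
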