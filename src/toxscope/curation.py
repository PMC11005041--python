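"""Endpoint labeling rules, dataset refinement, and the 80/20 random split.

The labeling functions encode the toxic/nontoxic classification rules used to
curate the per-endpoint datasets: androgen-receptor assay logic, the GHS
erythema/edema score threshold for skin irritation, single-dose ocular damage
for eye irritation, and the 2000 mg/kg LD50 cut-off for acute oral toxicity.
They are pure functions applied to already-extracted evidence tables; no
database clients are provided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fingerprints import MoleculeRecord

ENDPOINTS = (
    "ANDROGENICITY", "SKIN_IRRITATION", "EYE_IRRITATION", "ORAL_TOXICITY",
    "MUTAGENICITY", "CARCINOGENICITY", "HEPATOTOXICITY", "ESTROGENICITY",
)

TOXIC, NONTOXIC = 1, 0

#: GHS average erythema/edema score above which a compound is irritant
SKIN_SCORE_THRESHOLD = 2.3
#: LD50 (mg/kg) below which a compound is acutely orally toxic
ORAL_LD50_THRESHOLD = 2000.0


@dataclass(frozen=True)
class LabeledCompound:
    mol: MoleculeRecord
    label: int
    endpoint: str | None = None

    def __post_init__(self):
        if self.label not in (TOXIC, NONTOXIC):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")


@dataclass(frozen=True)
class DatasetSplit:
    train: list[LabeledCompound]
    test: list[LabeledCompound]
    seed: int
    train_fraction: float


def label_androgenicity(binding_positive: bool, any_reporter_positive: bool,
                        all_assays_negative: bool) -> int | None:
    """Androgenicity rule from competitive-binding and reporter-gene assays.

    Toxic when binding activity was seen in at least one competitive binding
    assay AND activity was detected in at least one reporter gene assay;
    nontoxic when the binding assay and all reporter gene assays were
    negative.  Any other evidence pattern is indeterminate (``None``) and the
    compound is excluded from the dataset.
    """
    if binding_positive is None and any_reporter_positive is None \
            and all_assays_negative is None:
        raise ValueError("no assay evidence provided")
    if all_assays_negative and (binding_positive or any_reporter_positive):
        raise ValueError("inconsistent assay evidence: negatives flagged "
                         "together with positive assay results")
    if binding_positive and any_reporter_positive:
        return TOXIC
    if all_assays_negative:
        return NONTOXIC
    return None


def label_skin(avg_erythema_edema_score: float,
               irreversible_corrosion: bool = False) -> int:
    """Skin irritation/corrosion rule (GHS).

    Toxic when the average erythema/edema score is strictly higher than 2.3,
    or when irreversible skin irritation and corrosion effects were reported.
    """
    if avg_erythema_edema_score < 0:
        raise ValueError(f"negative erythema/edema score: {avg_erythema_edema_score}")
    if irreversible_corrosion or avg_erythema_edema_score > SKIN_SCORE_THRESHOLD:
        return TOXIC
    return NONTOXIC


def label_eye(conjunctiva_damage: bool, cornea_damage: bool,
              iris_damage: bool) -> int:
    """Eye irritation rule: damage observed after a single dose.

    Damage to any of conjunctiva, cornea or iris classifies the compound as
    toxic (the GHS-style ANY reading of the tissue list).
    """
    if conjunctiva_damage or cornea_damage or iris_damage:
        return TOXIC
    return NONTOXIC


def label_oral(ld50: float) -> int:
    """Acute oral toxicity rule: toxic iff LD50 strictly below 2000 mg/kg."""
    if ld50 <= 0:
        raise ValueError(f"LD50 must be positive, got {ld50}")
    return TOXIC if ld50 < ORAL_LD50_THRESHOLD else NONTOXIC


def refine_dataset(records: list[LabeledCompound]) -> tuple[list[LabeledCompound], dict]:
    """Remove duplicate and label-inconsistent instances.

    One record is kept per canonical structure; structures carrying both
    labels are dropped entirely (no adjudication).  Returns the refined list,
    preserving first-seen order, together with a removal report.
    """
    by_smiles: dict[str, list[LabeledCompound]] = {}
    order: list[str] = []
    for rec in records:
        key = rec.mol.canonical_smiles
        if key not in by_smiles:
            order.append(key)
        by_smiles.setdefault(key, []).append(rec)

    refined, conflicts, duplicates = [], [], 0
    for key in order:
        group = by_smiles[key]
        labels = {r.label for r in group}
        if len(labels) > 1:
            conflicts.append(key)
        else:
            duplicates += len(group) - 1
            refined.append(group[0])
    report = {
        "n_input": len(records),
        "n_retained": len(refined),
        "duplicates_removed": duplicates,
        "conflicting_structures_removed": conflicts,
    }
    return refined, report


def random_split(records: list[LabeledCompound], train_fraction: float = 0.8,
                 seed: int = 0) -> DatasetSplit:
    """Random, non-stratified split into disjoint train/test sets.

    Reproducible for a given seed; requires at least 5 records.  The split is
    by record, and records are assumed deduplicated by canonical structure
    (see :func:`refine_dataset`), which makes the partition disjoint by
    structure as well.
    """
    if len(records) < 5:
        raise ValueError(f"need at least 5 records to split, got {len(records)}")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError(f"train_fraction must be in (0, 1), got {train_fraction}")
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(records))
    n_train = int(round(train_fraction * len(records)))
    n_train = min(max(n_train, 1), len(records) - 1)
    train = [records[i] for i in sorted(idx[:n_train])]
    test = [records[i] for i in sorted(idx[n_train:])]
    return DatasetSplit(train=train, test=test, seed=seed,
                        train_fraction=train_fraction)
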