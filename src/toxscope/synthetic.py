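"""Seeded synthetic datasets with a planted toxicophore.

The generator assembles chemically valid small molecules from a fixed grammar
of drug-like scaffolds and substituents and labels each molecule by the
presence of a planted toxicophore substructure (default: an aromatic nitro
group), optionally flipping labels with a configurable noise probability.
Because the label is a deterministic function of a substructure that all
three fingerprint families encode, noise-free datasets are separable and are
used to exercise the whole train / consensus / explain pipeline without any
external data.  The grammar makes no attempt to mimic the chemistry of real
toxicity endpoints; it tests mechanics, not toxicology.

Class balance defaults to 70% nontoxic / 30% toxic, mirroring the imbalance
of typical curated endpoint tables.

Four literature compounds with known toxicophores (aflatoxin B1,
6-ketoestrone, trimethylolpropane triacrylate, ethyl-parathion) are bundled
for qualitative demonstration runs of the explanation pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem

from .curation import LabeledCompound
from .fingerprints import MoleculeRecord, standardize_smiles

#: aromatic nitro group, the default planted toxicophore
NITROAROMATIC_SMARTS = "c[N+](=O)[O-]"

# aromatic scaffolds: {r1} is always substituted (ring position), a second
# fragment may be appended after the final ring-closure atom
_AROMATIC_SCAFFOLDS = [
    "c1ccc({r1})cc1",
    "Cc1ccc({r1})cc1",
    "COc1ccc({r1})cc1",
    "Clc1ccc({r1})cc1",
    "Fc1ccc({r1})cc1",
    "c1ccc({r1})nc1",
    "c1ccc2cc({r1})ccc2c1",
    "c1ccc(-c2ccc({r1})cc2)cc1",
    "Cc1cc({r1})ccc1C",
    "c1ccc({r1})cc1C",
    "CC(C)c1ccc({r1})cc1",
    "c1cc({r1})ccc1O",
    "c1ccc({r1})s1",
    "c1ccc({r1})o1",
    "CCc1ccc({r1})cc1",
    "CCOc1ccc({r1})cc1",
    "Cc1ccc({r1})c(C)c1",
    "c1ccc(Cc2ccc({r1})cc2)cc1",
]

# aliphatic / saturated-heterocycle scaffolds (never carry the aromatic
# toxicophore even if a nitro group were attached)
_ALIPHATIC_SCAFFOLDS = [
    "C1CCC({r1})CC1",
    "C1CCN({r1})CC1",
    "C1CCC({r1})OC1",
    "O1CCC({r1})CC1",
    "C1CC({r1})CN1C",
    "CC1CCC({r1})CC1",
    "C1CCC({r1})C1",
    "CC(C)C({r1})CC",
]

# substituent fragments, valid inside parentheses after a ring atom
_SUBSTITUENTS = [
    "C", "CC", "CCC", "C(C)C", "CCCC", "C(C)(C)C",
    "O", "OC", "OCC", "N", "NC", "N(C)C",
    "F", "Cl", "Br", "C#N", "C(F)(F)F",
    "C=C", "C(=O)C", "C(=O)OC", "C(=O)N", "C(=O)NC",
    "S(=O)(=O)N", "S(=O)(=O)C", "SC", "CO", "CCO", "CN",
    "CC(=O)N", "OC(=O)C", "C(=O)O", "CCl", "CF", "CCN",
    "N1CCOCC1", "N1CCCC1",
]

#: fragment appended at the second attachment point ("" = hydrogen)
_SECONDARY = ["", "C", "CC", "O", "OC", "N", "F", "Cl", "C#N", "C(=O)OC"]

_NITRO_FRAGMENT = "[N+](=O)[O-]"


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic dataset.

    ``class_balance`` is the target nontoxic fraction; ``label_noise`` is the
    probability of flipping each substructure-derived label.
    """

    n_compounds: int = 300
    toxicophore: str = NITROAROMATIC_SMARTS
    label_noise: float = 0.0
    class_balance: float = 0.70
    seed: int = 0

    def __post_init__(self):
        if self.n_compounds < 20:
            raise ValueError("n_compounds must be at least 20")
        if not 0.0 <= self.label_noise < 0.5:
            raise ValueError("label_noise must be in [0, 0.5)")
        if not 0.05 <= self.class_balance <= 0.95:
            raise ValueError("class_balance must be in [0.05, 0.95]")


def _assemble(template: str, r1: str, tail: str) -> str | None:
    smiles = template.format(r1=r1) + tail
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    return Chem.MolToSmiles(mol)


def _candidate_pools(pattern: Chem.Mol) -> tuple[list[str], list[str]]:
    """Enumerate the grammar; partition by toxicophore presence."""
    toxic, clean = [], []
    seen: set[str] = set()

    def add(canonical: str | None):
        if canonical is None or canonical in seen:
            return
        seen.add(canonical)
        mol = Chem.MolFromSmiles(canonical)
        if mol.HasSubstructMatch(pattern):
            toxic.append(canonical)
        else:
            clean.append(canonical)

    # toxicophore-bearing candidates: nitro at an aromatic position
    for tmpl in _AROMATIC_SCAFFOLDS:
        for tail in sorted(set(_SECONDARY + _SUBSTITUENTS)):
            add(_assemble(tmpl, _NITRO_FRAGMENT, tail))
        for sub in _SUBSTITUENTS:
            add(_assemble(tmpl, sub, _NITRO_FRAGMENT))
    # nitro-free candidates over the whole grammar
    for tmpl in _AROMATIC_SCAFFOLDS + _ALIPHATIC_SCAFFOLDS:
        for sub in _SUBSTITUENTS:
            for tail in _SECONDARY:
                add(_assemble(tmpl, sub, tail))
    return toxic, clean


def generate_dataset(spec: FixtureSpec) -> list[LabeledCompound]:
    """Generate a labeled dataset; a pure, seeded function of ``spec``.

    Labels equal toxicophore presence XOR a seeded noise flip.  Raises if the
    toxicophore pattern is invalid or cannot be produced by the grammar, or
    if the grammar cannot supply enough unique structures.
    """
    pattern = Chem.MolFromSmarts(spec.toxicophore)
    if pattern is None:
        raise ValueError(f"invalid toxicophore SMARTS: {spec.toxicophore!r}")
    toxic_pool, clean_pool = _candidate_pools(pattern)
    if not toxic_pool:
        raise ValueError(
            f"toxicophore {spec.toxicophore!r} is not producible by the "
            f"molecule grammar")

    rng = np.random.default_rng(spec.seed)
    n_clean = int(round(spec.class_balance * spec.n_compounds))
    n_toxic = spec.n_compounds - n_clean
    if n_toxic < 1 or n_clean < 1:
        raise ValueError("requested composition leaves a class empty")
    if n_toxic > len(toxic_pool) or n_clean > len(clean_pool):
        raise ValueError(
            f"grammar provides {len(toxic_pool)} toxicophore-bearing and "
            f"{len(clean_pool)} clean structures; requested {n_toxic}/{n_clean}")

    chosen = list(rng.choice(toxic_pool, size=n_toxic, replace=False)) + \
        list(rng.choice(clean_pool, size=n_clean, replace=False))
    order = rng.permutation(len(chosen))

    records: list[LabeledCompound] = []
    flips = rng.random(len(chosen)) < spec.label_noise
    for pos, i in enumerate(order):
        rec = standardize_smiles(chosen[i])
        label = int(rec.mol.HasSubstructMatch(pattern))
        if flips[pos]:
            label = 1 - label
        records.append(LabeledCompound(mol=rec, label=label, endpoint=None))
    labels = {r.label for r in records}
    if len(labels) < 2:  # pragma: no cover - only at extreme noise settings
        raise ValueError("generated dataset is single-class; adjust spec")
    return records


#: demonstration compounds with literature-known toxicophores
WORKED_EXAMPLES = {
    "aflatoxin B1": "COc1cc2c(c3oc(=O)c4c(c13)CCC4=O)C1C=COC1O2",
    "6-ketoestrone": "CC12CCC3c4ccc(O)cc4C(=O)CC3C1CCC2=O",
    "trimethylolpropane triacrylate":
        "CCC(COC(=O)C=C)(COC(=O)C=C)COC(=O)C=C",
    "ethyl-parathion": "CCOP(=S)(OCC)Oc1ccc(cc1)[N+](=O)[O-]",
}


def worked_examples() -> list[MoleculeRecord]:
    """The four bundled demonstration molecules, standardized."""
    return [standardize_smiles(s) for s in WORKED_EXAMPLES.values()]
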