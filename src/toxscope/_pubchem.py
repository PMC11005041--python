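"""881-bit PubChem-style substructure fingerprint.

The bit layout follows the section structure of the public CACTVS/PubChem
substructure key: hierarchic element counts (bits 0-114), a ring-system block
encoding ring size / count / saturation-aromaticity flavors (bits 115-262),
simple atom pairs, atom nearest-neighbor patterns, bond-specific pairs, and
SMARTS substructure patterns with occurrence thresholds (bits 263-880).  The
per-bit catalogue itself is this package's own deterministic curation: every
bit has an explicit definition, so each on-bit can be retro-mapped to the atom
sets (occurrences) that set it.

Ring-block bits (115-262) have no single SMARTS query; they are matched at the
ring-system level and grouped into clusters of bits that describe the same
ring flavor and differ only in the occurrence count, which the explainability
layer uses to de-duplicate attributions.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from rdkit import Chem

N_BITS = 881

# section boundaries (inclusive start, exclusive end)
ELEMENT_SECTION = (0, 115)
RING_SECTION = (115, 263)
PAIR_SECTION = (263, 327)
NEIGHBOR_SECTION = (327, 416)
BONDED_PAIR_SECTION = (416, 460)
PATTERN_SECTION = (460, 713)
COMPLEX_SECTION = (713, 881)


@dataclass(frozen=True)
class BitDef:
    """Definition of one fingerprint bit.

    kind is one of "element", "hydrogen", "ring", "aromatic_ring", "smarts".
    The bit is on when the molecule contains at least ``min_count``
    occurrences of the defined feature.
    """

    kind: str
    min_count: int = 1
    smarts: str | None = None
    anum: int | None = None
    ring_size: int | None = None
    ring_flavor: int | None = None
    hetero_aromatic: bool | None = None


# ---------------------------------------------------------------------------
# section 1: element counts (115 bits)
# ---------------------------------------------------------------------------

# multi-threshold elements (symbol -> atomic number, thresholds)
_ELEMENT_THRESHOLDS = [
    (1, (4, 8, 16, 32)),     # H
    (3, (1, 2)),             # Li
    (5, (1, 2, 4)),          # B
    (6, (2, 4, 8, 16, 32)),  # C
    (7, (1, 2, 4, 8)),       # N
    (8, (1, 2, 4, 8, 16)),   # O
    (9, (1, 2, 4)),          # F
    (11, (1, 2)),            # Na
    (14, (1, 2)),            # Si
    (15, (1, 2, 4)),         # P
    (16, (1, 2, 4, 8)),      # S
    (17, (1, 2, 4, 8)),      # Cl
    (19, (1, 2)),            # K
    (35, (1, 2, 4)),         # Br
    (53, (1, 2, 4)),         # I
]

# single-threshold (>=1) elements, 66 of them
_SINGLE_ELEMENTS = [
    2, 4, 10, 12, 13, 18, 20, 21, 22, 23, 24, 25, 26, 27, 28, 29, 30, 31,
    32, 33, 34, 36, 37, 38, 39, 40, 41, 42, 43, 44, 45, 46, 47, 48, 49, 50,
    51, 52, 54, 55, 56, 57, 58, 59, 60, 62, 63, 64, 65, 66, 67, 68, 70, 71,
    72, 73, 74, 75, 76, 77, 78, 79, 80, 81, 82, 83,
]

# ---------------------------------------------------------------------------
# section 2: ring block (148 bits)
# ---------------------------------------------------------------------------

# count levels per ring size (number of ">= c rings of size s" thresholds)
_RING_COUNT_LEVELS = {3: (1, 2), 4: (1, 2), 5: (1, 2, 3, 4, 5),
                      6: (1, 2, 3, 4, 5), 7: (1, 2), 8: (1, 2),
                      9: (1,), 10: (1,)}

# ring flavors, applied per ring of a given size:
#   0 any ring
#   1 saturated or aromatic, carbon-only
#   2 saturated or aromatic, nitrogen-containing
#   3 saturated or aromatic, heteroatom-containing
#   4 unsaturated non-aromatic, carbon-only
#   5 unsaturated non-aromatic, nitrogen-containing
#   6 unsaturated non-aromatic, heteroatom-containing
_N_RING_FLAVORS = 7

# trailing aromatic-ring bits: (hetero_aromatic, min_count)
_AROMATIC_BITS = [(False, 1), (True, 1), (False, 2), (True, 2),
                  (False, 3), (True, 3), (False, 4), (True, 4)]

# ---------------------------------------------------------------------------
# sections 3-7: SMARTS-backed bits
# ---------------------------------------------------------------------------

_PAIR_ELEMENTS = (6, 7, 8, 16, 15, 9, 17, 35, 53, 14, 5)
_NEIGHBOR_CENTERS = (6, 7, 8, 15, 16)
_NEIGHBOR_ELEMS = (6, 7, 8, 9, 15, 16, 17, 35, 53)
_BONDED_PAIRS = [(6, 6), (6, 7), (6, 8), (6, 16), (6, 15), (7, 7), (7, 8),
                 (7, 16), (8, 8), (8, 15), (8, 16), (15, 16)]
_BOND_SYMBOLS = ("-", "=", "#", ":")

# functional-group patterns; each contributes bits at thresholds >=1 and >=2
_FUNCTIONAL_GROUPS = [
    "[CX3](=O)[OX2H1]",          # carboxylic acid
    "[CX3](=O)[OX1-]",           # carboxylate
    "[CX3](=O)[OX2][#6]",        # ester
    "[CX3](=O)[NX3]",            # amide
    "[CX3H1]=O",                 # aldehyde
    "[#6][CX3](=O)[#6]",         # ketone
    "[OX2H][#6;!$([CX3]=O)]",    # alcohol / phenol
    "[OX2H]c",                   # phenol
    "[OX2]([#6])[#6]",           # ether
    "[NX3;H2][#6]",              # primary amine
    "[NX3;H1]([#6])[#6]",        # secondary amine
    "[NX3]([#6])([#6])[#6]",     # tertiary amine
    "[N+](=O)[O-]",              # nitro
    "c[N+](=O)[O-]",             # aromatic nitro
    "[NX2]=O",                   # nitroso
    "N=N",                       # azo
    "C#N",                       # nitrile
    "[NX3][NX3]",                # hydrazine
    "[NX2]=[CX3]",               # imine
    "N=[N+]=[N-]",               # azide
    "[SX2H]",                    # thiol
    "[SX2]([#6])[#6]",           # thioether
    "[SX3]=[OX1]",               # sulfoxide
    "[SX4](=O)(=O)",             # sulfonyl
    "[SX4](=O)(=O)[NX3]",        # sulfonamide
    "[SX4](=O)(=O)[OX2H]",       # sulfonic acid
    "[#6]=[#16]",                # thiocarbonyl
    "SC#N",                      # thiocyanate
    "P=O",                       # phosphoryl
    "P=S",                       # thiophosphoryl
    "[PX4]",                     # tetracoordinate P
    "[#6]F",
    "[#6]Cl",
    "[#6]Br",
    "[#6]I",
    "C(F)(F)F",                  # trifluoromethyl
    "cF", "cCl", "cBr", "cI",    # aryl halides
    "[OX2;r3]",                  # epoxide
    "C=C",
    "C#C",
    "C=C[CX3]=O",                # Michael acceptor
    "C=C[CX3](=O)[OX2]",         # acrylate
    "[CX3](=O)Cl",               # acid chloride
    "[CX3](=O)O[CX3](=O)",       # anhydride
    "[OX1]=[CX3]([NX3])[NX3]",   # urea
    "[NX3][CX3](=[OX1])[OX2]",   # carbamate
    "[OX2][OX2]",                # peroxide
    "[NX3][OX2H]",               # hydroxylamine
]

# ring systems / substituted aromatics for the complex section (presence bits)
_COMPLEX_PATTERNS = [
    "c1ccccc1",                      # benzene
    "c1ccc2ccccc2c1",                # naphthalene
    "c1ccc(-c2ccccc2)cc1",           # biphenyl
    "Nc1ccccc1",                     # aniline
    "Oc1ccccc1",                     # phenol
    "COc1ccccc1",                    # anisole
    "Cc1ccccc1",                     # toluene
    "OC(=O)c1ccccc1",                # benzoic acid
    "O=[N+]([O-])c1ccccc1",          # nitrobenzene
    "C=Cc1ccccc1",                   # styrene
    "O=Cc1ccccc1",                   # benzaldehyde
    "CC(=O)c1ccccc1",                # acetophenone
    "NC(=O)c1ccccc1",                # benzamide
    "c1ccncc1",                      # pyridine
    "c1cncnc1",                      # pyrimidine
    "c1cc[nH]c1",                    # pyrrole
    "c1ccoc1",                       # furan
    "c1ccsc1",                       # thiophene
    "c1c[nH]cn1",                    # imidazole
    "c1cnc[nH]1",                    # imidazole tautomer query
    "c1cocn1",                       # oxazole
    "c1cscn1",                       # thiazole
    "c1ccc2[nH]ccc2c1",              # indole
    "c1ccc2ncccc2c1",                # quinoline
    "c1ccc2cnccc2c1",                # isoquinoline
    "C1CCNCC1",                      # piperidine
    "C1CNCCN1",                      # piperazine
    "C1COCCN1",                      # morpholine
    "C1CCOC1",                       # tetrahydrofuran
    "C1CCNC1",                       # pyrrolidine
    "C1CCCCC1",                      # cyclohexane
    "C1CCCC1",                       # cyclopentane
    "C1CCC1",                        # cyclobutane
    "C1CC1",                         # cyclopropane
    "C1OCCO1",                       # dioxolane
    "O=C1CCCCN1",                    # lactam
    "O=C1CCCCO1",                    # lactone
    "Clc1ccccc1",                    # chlorobenzene
    "Fc1ccccc1",                     # fluorobenzene
    "Nc1ccc(N)cc1",                  # phenylenediamine
]


def _chain_smarts(elems: tuple[int, ...]) -> str:
    return "~".join(f"[#{a}]" for a in elems)


def _generate_pairs() -> list[str]:
    out = []
    n = len(_PAIR_ELEMENTS)
    for i in range(n):
        for j in range(i, n):
            out.append(f"[#{_PAIR_ELEMENTS[i]}]~[#{_PAIR_ELEMENTS[j]}]")
    return out


def _generate_neighbors() -> list[str]:
    out = []
    for c in _NEIGHBOR_CENTERS:
        n = len(_NEIGHBOR_ELEMS)
        for i in range(n):
            for j in range(i, n):
                a, b = _NEIGHBOR_ELEMS[i], _NEIGHBOR_ELEMS[j]
                out.append(f"[#{c}](~[#{a}])~[#{b}]")
    return out


def _generate_bonded_pairs() -> list[str]:
    out = []
    for a, b in _BONDED_PAIRS:
        for bond in _BOND_SYMBOLS:
            out.append(f"[#{a}]{bond}[#{b}]")
    return out


def _generate_triples() -> list[str]:
    elems = (6, 7, 8, 9, 15, 16, 17)
    out = []
    for b in elems:
        for i, a in enumerate(elems):
            for c in elems[i:]:
                out.append(_chain_smarts((a, b, c)))
    return out


def _generate_quads() -> list[str]:
    elems = (6, 7, 8, 16)
    out = []
    seen = set()
    for a in elems:
        for b in elems:
            for c in elems:
                for d in elems:
                    key = min((a, b, c, d), (d, c, b, a))
                    if key in seen:
                        continue
                    seen.add(key)
                    out.append(_chain_smarts((a, b, c, d)))
    return out


@lru_cache(maxsize=1)
def bit_definitions() -> tuple[BitDef, ...]:
    """The full, ordered catalogue of 881 bit definitions."""
    defs: list[BitDef] = []
    # element counts
    for anum, thresholds in _ELEMENT_THRESHOLDS:
        for t in thresholds:
            if anum == 1:
                defs.append(BitDef("hydrogen", min_count=t))
            else:
                defs.append(BitDef("element", min_count=t, anum=anum,
                                   smarts=f"[#{anum}]"))
    for anum in _SINGLE_ELEMENTS:
        defs.append(BitDef("element", min_count=1, anum=anum,
                           smarts=f"[#{anum}]"))
    assert len(defs) == ELEMENT_SECTION[1]

    # ring block
    for size in range(3, 11):
        for count in _RING_COUNT_LEVELS[size]:
            for flavor in range(_N_RING_FLAVORS):
                defs.append(BitDef("ring", min_count=count, ring_size=size,
                                   ring_flavor=flavor))
    for hetero, count in _AROMATIC_BITS:
        defs.append(BitDef("aromatic_ring", min_count=count,
                           hetero_aromatic=hetero))
    assert len(defs) == RING_SECTION[1]

    # simple atom pairs
    for smarts in _generate_pairs()[:PAIR_SECTION[1] - PAIR_SECTION[0]]:
        defs.append(BitDef("smarts", smarts=smarts))
    assert len(defs) == PAIR_SECTION[1]

    # nearest-neighbor patterns
    need = NEIGHBOR_SECTION[1] - NEIGHBOR_SECTION[0]
    for smarts in _generate_neighbors()[:need]:
        defs.append(BitDef("smarts", smarts=smarts))
    assert len(defs) == NEIGHBOR_SECTION[1]

    # bond-order-specific pairs
    need = BONDED_PAIR_SECTION[1] - BONDED_PAIR_SECTION[0]
    for smarts in _generate_bonded_pairs()[:need]:
        defs.append(BitDef("smarts", smarts=smarts))
    assert len(defs) == BONDED_PAIR_SECTION[1]

    # functional groups at thresholds 1 and 2, then 3-atom chains
    for smarts in _FUNCTIONAL_GROUPS:
        defs.append(BitDef("smarts", smarts=smarts, min_count=1))
        defs.append(BitDef("smarts", smarts=smarts, min_count=2))
    need = PATTERN_SECTION[1] - len(defs)
    for smarts in _generate_triples()[:need]:
        defs.append(BitDef("smarts", smarts=smarts))
    assert len(defs) == PATTERN_SECTION[1]

    # complex patterns, then 4-atom chains
    for smarts in _COMPLEX_PATTERNS:
        defs.append(BitDef("smarts", smarts=smarts))
    need = COMPLEX_SECTION[1] - len(defs)
    for smarts in _generate_quads()[:need]:
        defs.append(BitDef("smarts", smarts=smarts))
    assert len(defs) == N_BITS, len(defs)
    return tuple(defs)


@lru_cache(maxsize=1)
def _compiled_smarts() -> dict[int, Chem.Mol]:
    out = {}
    for i, d in enumerate(bit_definitions()):
        if d.smarts is not None:
            pat = Chem.MolFromSmarts(d.smarts)
            assert pat is not None, d.smarts
            out[i] = pat
    return out


@lru_cache(maxsize=1)
def ring_bit_clusters() -> dict[str, tuple[int, ...]]:
    """Disjoint clusters over the ring block (bits 115-262).

    Bits describing the same ring size and flavor, differing only in the
    occurrence-count threshold, form one cluster; the eight trailing
    aromatic-ring bits form two clusters (carbo- and hetero-aromatic).
    """
    clusters: dict[str, list[int]] = {}
    for i, d in enumerate(bit_definitions()):
        if d.kind == "ring":
            key = f"ring_s{d.ring_size}_f{d.ring_flavor}"
        elif d.kind == "aromatic_ring":
            key = "hetero_aromatic" if d.hetero_aromatic else "aromatic"
        else:
            continue
        clusters.setdefault(key, []).append(i)
    out = {k: tuple(sorted(v)) for k, v in clusters.items()}
    covered = sorted(i for bits in out.values() for i in bits)
    assert covered == list(range(*RING_SECTION))
    return out


def _ring_flags(mol: Chem.Mol, ring: tuple[int, ...]) -> dict[str, bool]:
    atoms = [mol.GetAtomWithIdx(i) for i in ring]
    bonds = []
    for i in range(len(ring)):
        bonds.append(mol.GetBondBetweenAtoms(ring[i], ring[(i + 1) % len(ring)]))
    aromatic = all(b.GetIsAromatic() for b in bonds)
    saturated = all(b.GetBondType() == Chem.BondType.SINGLE for b in bonds)
    carbon_only = all(a.GetAtomicNum() == 6 for a in atoms)
    has_n = any(a.GetAtomicNum() == 7 for a in atoms)
    return {"aromatic": aromatic, "saturated": saturated,
            "carbon_only": carbon_only, "has_nitrogen": has_n,
            "has_hetero": not carbon_only}


def _ring_matches_flavor(flags: dict[str, bool], flavor: int) -> bool:
    sat_or_arom = flags["saturated"] or flags["aromatic"]
    unsat = not sat_or_arom
    return (
        flavor == 0
        or (flavor == 1 and sat_or_arom and flags["carbon_only"])
        or (flavor == 2 and sat_or_arom and flags["has_nitrogen"])
        or (flavor == 3 and sat_or_arom and flags["has_hetero"])
        or (flavor == 4 and unsat and flags["carbon_only"])
        or (flavor == 5 and unsat and flags["has_nitrogen"])
        or (flavor == 6 and unsat and flags["has_hetero"])
    )


def match_bits(mol: Chem.Mol) -> dict[int, list[tuple[int, ...]]]:
    """Evaluate all 881 bits on ``mol``.

    Returns only on-bits, each mapped to its occurrence list: one atom-index
    tuple per occurrence of the feature.  A bit with threshold ``min_count``
    is on when the number of occurrences reaches the threshold; all
    occurrences are reported (the retro-mapping formula normalises by the
    occurrence count).
    """
    defs = bit_definitions()
    patterns = _compiled_smarts()
    rings = [tuple(r) for r in mol.GetRingInfo().AtomRings()]
    ring_flags = [_ring_flags(mol, r) for r in rings]
    smarts_cache: dict[str, tuple[tuple[int, ...], ...]] = {}

    out: dict[int, list[tuple[int, ...]]] = {}
    for i, d in enumerate(defs):
        if d.kind == "hydrogen":
            occ = [(a.GetIdx(),) for a in mol.GetAtoms() if a.GetTotalNumHs() > 0]
            n_h = sum(a.GetTotalNumHs() for a in mol.GetAtoms())
            if n_h >= d.min_count and occ:
                out[i] = occ
        elif d.kind == "ring":
            occ = [rings[j] for j, fl in enumerate(ring_flags)
                   if len(rings[j]) == d.ring_size
                   and _ring_matches_flavor(fl, d.ring_flavor)]
            if len(occ) >= d.min_count:
                out[i] = occ
        elif d.kind == "aromatic_ring":
            occ = [rings[j] for j, fl in enumerate(ring_flags)
                   if fl["aromatic"]
                   and (fl["has_hetero"] if d.hetero_aromatic else True)]
            if len(occ) >= d.min_count:
                out[i] = occ
        else:  # element or smarts: substructure matches
            matches = smarts_cache.get(d.smarts)
            if matches is None:
                matches = mol.GetSubstructMatches(patterns[i])
                smarts_cache[d.smarts] = matches
            if len(matches) >= d.min_count:
                out[i] = [tuple(m) for m in matches]
    return out
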