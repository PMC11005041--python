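"""Shapley feature attribution and atom-level retro-mapping.

For each member of the best consensus combination, per-bit Shapley values are
estimated with the Kernel SHAP scheme: the model is evaluated on coalitions
of fingerprint bits (absent bits imputed from a background sample of training
compounds) and a weighted linear regression under the Shapley kernel recovers
one signed score per bit.  Positive scores push the prediction toward
toxicity, negative toward nontoxicity, and the scores plus the background
expectation reproduce the model's PS (local accuracy).  When the number of
varying bits is small the full coalition space is enumerated, which makes the
estimate exact.

Scores are then retro-mapped onto atoms through the fingerprint bit-atom
maps: a feature f with score s_f, n_Atoms atoms per occurrence and n_occ
occurrences contributes s_f / (n_Atoms * n_occ) to each atom of each
occurrence, and an atom's weight fw is the sum over the features containing
it.  For the 881-bit substructure key, the redundant ring-count block (bits
115-262) is first collapsed: within each cluster of bits describing the same
ring flavor only the highest score is retained.  The final atom weights are
averaged over the consensus members and can be rendered on the structure.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, replace as dc_replace
from typing import Callable, Sequence

import numpy as np

from . import _pubchem
from .fingerprints import (DEFAULT_CONFIG, BitAtomMap, Family,
                           MoleculeRecord, compute_fingerprint,
                           fingerprint_matrix, map_bits_to_atoms)
from .training import TrainedClassifier

#: default number of background compounds subsampled from the training set
DEFAULT_BACKGROUND_SIZE = 50
#: feature counts up to this bound are explained by exact coalition enumeration
MAX_EXACT_FEATURES = 13
#: rows per model-evaluation chunk (memory bound)
_EVAL_CHUNK = 65536


@dataclass(frozen=True)
class FeatureScoreVector:
    """Signed per-bit scores for one (model, compound) explanation."""

    model_id: str
    family: Family
    scores: np.ndarray
    base: float
    ps: float

    @property
    def local_accuracy_residual(self) -> float:
        return float(self.ps - self.base - self.scores.sum())


@dataclass(frozen=True)
class AtomWeightMap:
    """Signed per-atom contribution weights fw for one compound."""

    canonical_smiles: str
    weights: np.ndarray
    provenance: dict[int, tuple[int, ...]]
    n_models: int = 1

    def top_atom(self) -> int:
        return int(np.argmax(self.weights))


# ---------------------------------------------------------------------------
# Kernel SHAP
# ---------------------------------------------------------------------------

def _kernel_weight(m: int, s: int) -> float:
    return (m - 1) / (math.comb(m, s) * s * (m - s))


def _masked_values(f: Callable[[np.ndarray], np.ndarray], x: np.ndarray,
                   background: np.ndarray, masks: np.ndarray,
                   varying: np.ndarray) -> np.ndarray:
    """v(z) = E_b f(x_z, b_!z) for each coalition mask z over the varying bits."""
    nb, d = background.shape
    n = masks.shape[0]
    out = np.empty(n, dtype=float)
    per_chunk = max(1, _EVAL_CHUNK // nb)
    xa = x[varying]
    bga = background[:, varying]
    for start in range(0, n, per_chunk):
        chunk = masks[start:start + per_chunk]
        c = chunk.shape[0]
        rows = np.broadcast_to(background, (c, nb, d)).copy()
        rows[:, :, varying] = np.where(chunk[:, None, :], xa[None, None, :],
                                       bga[None, :, :])
        preds = f(rows.reshape(c * nb, d))
        out[start:start + c] = preds.reshape(c, nb).mean(axis=1)
    return out


def kernel_shap(f: Callable[[np.ndarray], np.ndarray], x: np.ndarray,
                background: np.ndarray, seed: int = 0,
                n_samples: int | str = "auto",
                max_exact_features: int = MAX_EXACT_FEATURES,
                ) -> tuple[np.ndarray, float, float]:
    """Shapley values of ``f`` at ``x`` against a background sample.

    ``f`` maps an (n, d) matrix to n probabilities.  Returns
    ``(phi, base, fx)`` with ``phi`` of length d; features identical in ``x``
    and every background row receive 0.  The coalition game is
    v(S) = E_b[f(x_S, b_!S)]; with full enumeration (up to
    ``max_exact_features`` varying features) the result is exact, otherwise
    coalitions are sampled size-stratified under the Shapley kernel and the
    regression solved by weighted least squares with the local-accuracy
    constraint enforced.
    """
    x = np.asarray(x, dtype=float).ravel()
    background = np.atleast_2d(np.asarray(background, dtype=float))
    if background.shape[1] != x.size:
        raise ValueError("background feature dimension does not match x")
    base = float(np.mean(f(background)))
    fx = float(f(x[None, :])[0])
    phi = np.zeros(x.size, dtype=float)

    varying = np.flatnonzero(np.any(background != x[None, :], axis=0))
    m = varying.size
    if m == 0:
        return phi, base, fx
    if m == 1:
        phi[varying[0]] = fx - base
        return phi, base, fx

    rng = np.random.default_rng(seed)
    if n_samples == "auto":
        n_samples = 2 * m + 2048

    if m <= max_exact_features:
        masks = []
        for s in range(1, m):
            for combo in itertools.combinations(range(m), s):
                z = np.zeros(m, dtype=bool)
                z[list(combo)] = True
                masks.append(z)
        masks = np.array(masks)
        sizes = masks.sum(axis=1)
        weights = np.array([_kernel_weight(m, int(s)) for s in sizes])
    else:
        masks, weights = _sample_coalitions(m, int(n_samples), rng)

    v = _masked_values(f, x, background, masks, varying)

    # weighted regression with sum(phi) = fx - base enforced by eliminating
    # the last varying feature
    ey = v - base
    ey_adj = ey - masks[:, -1] * (fx - base)
    zt = masks[:, :-1].astype(float) - masks[:, -1:].astype(float)
    sw = np.sqrt(weights)
    coef, *_ = np.linalg.lstsq(zt * sw[:, None], ey_adj * sw, rcond=None)
    phi_v = np.empty(m)
    phi_v[:-1] = coef
    phi_v[-1] = (fx - base) - coef.sum()
    phi[varying] = phi_v
    return phi, base, fx


def _sample_coalitions(m: int, budget: int,
                       rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Size-stratified coalition sampling under the Shapley kernel.

    Complete size levels are enumerated from the extremes inward while the
    budget allows (their kernel weights are used exactly); the remaining
    budget is spent on random masks drawn from the leftover sizes in
    proportion to their total kernel weight.
    """
    # total kernel weight of one size level: kernel(m,s) * C(m,s), with the
    # binomial factor cancelling analytically (avoids huge-int overflow)
    size_weight = {s: (m - 1) / (s * (m - s)) for s in range(1, m)}
    order = []
    for s in range(1, m // 2 + 1):
        order.append(s)
        if s != m - s:
            order.append(m - s)

    masks: list[np.ndarray] = []
    weights: list[float] = []
    enumerated: set[int] = set()
    remaining = budget
    for s in order:
        count = math.comb(m, s)
        if count <= remaining * (size_weight[s] /
                                 sum(size_weight[t] for t in order
                                     if t not in enumerated)):
            for combo in itertools.combinations(range(m), s):
                z = np.zeros(m, dtype=bool)
                z[list(combo)] = True
                masks.append(z)
                weights.append(_kernel_weight(m, s))
            enumerated.add(s)
            remaining -= count
        else:
            break

    leftover = [s for s in order if s not in enumerated]
    if leftover and remaining > 0:
        probs = np.array([size_weight[s] for s in leftover])
        probs /= probs.sum()
        total_leftover_weight = sum(size_weight[s] for s in leftover)
        picks = rng.choice(len(leftover), size=remaining, p=probs)
        for idx in picks:
            s = leftover[idx]
            z = np.zeros(m, dtype=bool)
            z[rng.choice(m, size=s, replace=False)] = True
            masks.append(z)
            weights.append(total_leftover_weight / remaining)
    return np.array(masks), np.array(weights)


# ---------------------------------------------------------------------------
# model-level API
# ---------------------------------------------------------------------------

def compute_feature_scores(model: TrainedClassifier, mol: MoleculeRecord,
                           background: Sequence[MoleculeRecord],
                           seed: int = 0, n_samples: int | str = "auto",
                           max_background: int = DEFAULT_BACKGROUND_SIZE,
                           ) -> FeatureScoreVector:
    """Per-bit Shapley scores of one model's prediction for one compound.

    ``background`` is a reference sample drawn from the model's training
    compounds; at most ``max_background`` of them are used (seeded
    subsample).  Scores are signed: positive toward toxicity.
    """
    if not background:
        raise ValueError("background compound set must be non-empty")
    rng = np.random.default_rng(seed)
    bg = list(background)
    if len(bg) > max_background:
        bg = [bg[i] for i in rng.choice(len(bg), size=max_background,
                                        replace=False)]
    fp_config = model.config.fp_config
    X_bg = fingerprint_matrix([b for b in bg], model.family, fp_config)
    x = fingerprint_matrix([mol], model.family, fp_config)[0]
    phi, base, fx = kernel_shap(model.predict_ps_matrix, x, X_bg,
                                seed=seed, n_samples=n_samples)
    return FeatureScoreVector(model_id=model.model_id, family=model.family,
                              scores=phi, base=base, ps=fx)


def cluster_ring_bits(scores: FeatureScoreVector,
                      clusters: dict[str, tuple[int, ...]] | None = None,
                      ) -> FeatureScoreVector:
    """Collapse the 881-bit key's ring-count block (bits 115-262).

    Within each cluster of bits encoding the same ring flavor (differing only
    in occurrence count) only the highest score is retained; the other member
    scores are zeroed.  Ties keep the lowest bit index.  Families other than
    the substructure key pass through unchanged.
    """
    if scores.family != Family.PUBCHEM:
        return scores
    if clusters is None:
        clusters = _pubchem.ring_bit_clusters()
    new = scores.scores.copy()
    for bits in clusters.values():
        bits = list(bits)
        vals = scores.scores[bits]
        if not np.any(vals != 0):
            continue
        keep = bits[int(np.argmax(vals))]
        for b in bits:
            if b != keep:
                new[b] = 0.0
    return dc_replace(scores, scores=new)


def atom_weights(mol: MoleculeRecord, bit_atom_map: BitAtomMap,
                 scores: FeatureScoreVector) -> AtomWeightMap:
    """Retro-map feature scores to atoms.

    fw(atom) = sum over features f containing the atom of
    s_f / (n_Atoms_f * n_occ_f), evaluated per occurrence.  Bits without an
    atom correspondence (off-bits and unmappable bits) contribute nothing.
    """
    if bit_atom_map.family != scores.family:
        raise ValueError("bit-atom map and scores are from different families")
    weights = np.zeros(mol.n_atoms, dtype=float)
    provenance: dict[int, list[int]] = {}
    for bit, occurrences in bit_atom_map.entries.items():
        s = float(scores.scores[bit])
        if s == 0.0:
            continue
        n_occ = len(occurrences)
        for occ in occurrences:
            share = s / (len(occ) * n_occ)
            for a in occ:
                if a >= mol.n_atoms:
                    raise ValueError(f"atom index {a} out of range")
                weights[a] += share
                provenance.setdefault(a, []).append(bit)
    prov = {a: tuple(sorted(set(b))) for a, b in provenance.items()}
    return AtomWeightMap(canonical_smiles=mol.canonical_smiles,
                         weights=weights, provenance=prov, n_models=1)


def aggregate_over_models(per_model_maps: Sequence[AtomWeightMap]) -> AtomWeightMap:
    """Average atom weights over the consensus members."""
    if not per_model_maps:
        raise ValueError("no atom-weight maps to aggregate")
    smiles = {m.canonical_smiles for m in per_model_maps}
    if len(smiles) > 1:
        raise ValueError("atom-weight maps describe different molecules")
    stacked = np.vstack([m.weights for m in per_model_maps])
    provenance: dict[int, set[int]] = {}
    for m in per_model_maps:
        for a, bits in m.provenance.items():
            provenance.setdefault(a, set()).update(bits)
    return AtomWeightMap(canonical_smiles=per_model_maps[0].canonical_smiles,
                         weights=stacked.mean(axis=0),
                         provenance={a: tuple(sorted(b))
                                     for a, b in provenance.items()},
                         n_models=len(per_model_maps))


def explain_compound(models: Sequence[TrainedClassifier], mol: MoleculeRecord,
                     background: Sequence[MoleculeRecord], seed: int = 0,
                     n_samples: int | str = "auto",
                     max_background: int = DEFAULT_BACKGROUND_SIZE,
                     ) -> tuple[AtomWeightMap, list[FeatureScoreVector]]:
    """Full explanation pipeline for one compound over consensus members.

    Computes Kernel SHAP scores per member on that member's own fingerprint
    family, collapses the substructure key's ring block, retro-maps to atoms
    and averages the per-model maps (the molecule's atoms are the common
    denominator across the mixed-family consensus).
    """
    maps, fsvs = [], []
    for model in models:
        fsv = compute_feature_scores(model, mol, background, seed=seed,
                                     n_samples=n_samples,
                                     max_background=max_background)
        fsv = cluster_ring_bits(fsv)
        fp = compute_fingerprint(mol, model.family, model.config.fp_config)
        bam = map_bits_to_atoms(mol, model.family, fp, model.config.fp_config)
        maps.append(atom_weights(mol, bam, fsv))
        fsvs.append(fsv)
    return aggregate_over_models(maps), fsvs


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def render_atom_weights(mol: MoleculeRecord, weight_map: AtomWeightMap,
                        path=None, fmt: str = "svg",
                        size: tuple[int, int] = (420, 420)) -> str | bytes:
    """Draw the structure with atoms colored by signed weight.

    Toxicity-directed (positive) weights are shaded red, nontoxicity-directed
    (negative) weights blue; intensity scales with |fw| relative to the
    largest magnitude.  Returns the SVG text (or PNG bytes) and optionally
    writes it to ``path``.
    """
    from rdkit.Chem.Draw import rdMolDraw2D

    if not np.all(np.isfinite(weight_map.weights)):
        raise ValueError("atom weights must be finite")
    if fmt == "svg":
        drawer = rdMolDraw2D.MolDraw2DSVG(*size)
    elif fmt == "png":
        drawer = rdMolDraw2D.MolDraw2DCairo(*size)
    else:
        raise ValueError(f"unsupported format: {fmt!r}")

    w = weight_map.weights
    peak = float(np.abs(w).max())
    highlight, colors = [], {}
    if peak > 0:
        for a, value in enumerate(w):
            t = abs(value) / peak
            if t < 1e-9:
                continue
            highlight.append(a)
            if value > 0:
                colors[a] = (1.0, 1.0 - 0.8 * t, 1.0 - 0.8 * t)
            else:
                colors[a] = (1.0 - 0.8 * t, 1.0 - 0.8 * t, 1.0)
    rdMolDraw2D.PrepareAndDrawMolecule(
        drawer, mol.mol, highlightAtoms=highlight, highlightAtomColors=colors)
    drawer.FinishDrawing()
    doc = drawer.GetDrawingText()
    if path is not None:
        mode = "w" if isinstance(doc, str) else "wb"
        with open(path, mode) as fh:
            fh.write(doc)
    return doc


def write_atom_weight_json(weight_map: AtomWeightMap, path) -> None:
    """Machine-readable sidecar: {atom_index: weight}."""
    with open(path, "w") as fh:
        json.dump({"canonical_smiles": weight_map.canonical_smiles,
                   "n_models": weight_map.n_models,
                   "weights": {str(i): float(v)
                               for i, v in enumerate(weight_map.weights)}},
                  fh, indent=2)
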