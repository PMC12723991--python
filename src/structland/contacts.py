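"""Residue contact maps from PDB structures and DI-based contact evaluation.

A contact is a residue pair whose representative atoms (Cβ, or Cα for
glycine) lie within an inclusive distance cutoff — 8 Å by default — and
whose sequence separation exceeds ``min_separation`` (|i−j| > 4 by default,
the long-range convention).  Predicted pairs are DI-ranked; performance is
a true-positive-rate curve over the top 0.1L … 3L pairs.

Residue/column mapping: by default structure residue k corresponds to MSA
column k (1-based) after removing columns that are gaps in every row; an
explicit two-column mapping overrides this.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .msa_io import EncodedMsa
from .potts import DiMatrix, compute_weights, direct_information, mean_field_fit, site_statistics

logger = logging.getLogger(__name__)

DEFAULT_CUTOFF = 8.0
DEFAULT_MIN_SEPARATION = 4
DEFAULT_FRACTIONS = tuple(np.round(np.arange(0.1, 3.01, 0.1), 10))


@dataclass
class ContactMap:
    """Unordered residue pairs (1-based, i < j) within the distance cutoff."""

    L: int
    pairs: set
    cutoff: float = DEFAULT_CUTOFF
    min_separation: int = DEFAULT_MIN_SEPARATION
    atom_rule: str = "CB-else-CA-for-GLY"

    def __post_init__(self):
        for (i, j) in self.pairs:
            if not 1 <= i < j <= self.L:
                raise ValueError(f"contact pair {(i, j)} outside [1, L={self.L}]")
            if j - i <= self.min_separation:
                raise ValueError(f"pair {(i, j)} violates min_separation={self.min_separation}")


@dataclass
class TprCurve:
    fractions: list
    tpr: list
    n_pairs: list

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"fraction": self.fractions, "tpr": self.tpr, "n_pairs": self.n_pairs})


def _representative_atoms(chain):
    """(positions, coords): Cβ per residue, Cα for glycine; else skip.

    Positions are the PDB residue numbers (resseq), assumed to match the
    1-based MSA/model coordinate system.
    """
    coords, positions = [], []
    for residue in chain:
        if residue.id[0] != " ":  # skip heteroatoms/waters
            continue
        pos = residue.id[1]
        name = "CA" if residue.get_resname() == "GLY" else "CB"
        if name in residue:
            atom = residue[name]
        elif "CA" in residue:
            logger.warning("residue %s %d lacks %s; falling back to CA",
                           residue.get_resname(), pos, name)
            atom = residue["CA"]
        else:
            logger.warning("residue %s %d lacks CB and CA; skipped", residue.get_resname(), pos)
            continue
        positions.append(pos)
        coords.append(atom.coord)
    return positions, np.array(coords, dtype=float)


def pdb_contact_map(
    path,
    cutoff: float = DEFAULT_CUTOFF,
    min_separation: int = DEFAULT_MIN_SEPARATION,
    chain_id: str = None,
    model_index: int = 0,
) -> ContactMap:
    """Extract the contact map of one chain of a PDB file.

    Pair (i, j) is a contact iff the representative-atom distance is
    ≤ cutoff (inclusive) and j − i > min_separation.  First model, first
    chain by default.
    """
    from Bio.PDB import PDBParser

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = PDBParser(QUIET=True).get_structure("s", path)
    models = list(structure)
    if not models:
        raise ValueError(f"{path}: empty structure")
    chains = list(models[model_index])
    if not chains:
        raise ValueError(f"{path}: no chains in model {model_index}")
    if chain_id is None:
        chain = chains[0]
    else:
        chain = models[model_index][chain_id]

    positions, coords = _representative_atoms(chain)
    if len(positions) == 0:
        raise ValueError(f"{path}: no usable residues in chain {chain.id}")
    L = positions[-1]
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
    pairs = set()
    for a in range(len(positions)):
        for b in range(a + 1, len(positions)):
            i, j = positions[a], positions[b]
            if j - i > min_separation and d[a, b] <= cutoff:
                pairs.add((i, j))
    return ContactMap(L=L, pairs=pairs, cutoff=cutoff, min_separation=min_separation)


def rank_pairs(di: DiMatrix, min_separation: int = DEFAULT_MIN_SEPARATION) -> list:
    """Long-range pairs (j − i > min_separation) by descending DI.

    Ties break lexicographically ascending on (i, j) for determinism.
    Returned pairs are 1-based.
    """
    L = di.L
    entries = [
        (-di.di[i, j], i + 1, j + 1)
        for i in range(L)
        for j in range(i + 1, L)
        if j - i > min_separation
    ]
    entries.sort()
    return [(i, j) for _, i, j in entries]


def tpr_curve(ranked: list, truth: ContactMap, fractions=DEFAULT_FRACTIONS) -> TprCurve:
    """True-positive rate of the top round(x·L) ranked pairs for each x."""
    fractions = list(fractions)
    if any(f <= 0 for f in fractions) or any(
        b <= a for a, b in zip(fractions, fractions[1:])
    ):
        raise ValueError("fractions must be positive and strictly increasing")
    L = truth.L
    tpr, n_pairs = [], []
    for x in fractions:
        n = min(int(round(x * L)), len(ranked))
        taken = ranked[:n]
        hits = sum(1 for p in taken if p in truth.pairs)
        tpr.append(hits / n if n else float("nan"))
        n_pairs.append(n)
    return TprCurve(fractions=fractions, tpr=tpr, n_pairs=n_pairs)


def subsample_evaluation(
    encoded: EncodedMsa,
    sizes,
    truth: ContactMap,
    replicates: int = 1,
    seed: int = 0,
    fractions=DEFAULT_FRACTIONS,
    theta: float = 0.8,
    lam: float = 0.5,
    min_separation: int = DEFAULT_MIN_SEPARATION,
) -> pd.DataFrame:
    """Contact-prediction performance as a function of MSA depth.

    For each size and replicate, sequences are drawn without replacement
    (seeded), the full mfDCA pipeline is re-run, and the DI ranking is
    scored against ``truth``.  Returns a tidy table with columns
    (size, replicate, fraction, tpr, n_pairs).
    """
    N = encoded.N
    rows = []
    rng = np.random.default_rng(seed)
    for size in sizes:
        if size > N:
            raise ValueError(f"subsample size {size} exceeds N={N}")
        if size < 10:
            logger.warning("subsample size %d < 10: statistics unreliable", size)
        for rep in range(replicates):
            idx = rng.choice(N, size=size, replace=False)
            sub = EncodedMsa(states=encoded.states[idx], alphabet=encoded.alphabet)
            w = compute_weights(sub, theta=theta)
            stats = site_statistics(sub, w, lam=lam)
            model = mean_field_fit(stats)
            di = direct_information(model, stats)
            curve = tpr_curve(rank_pairs(di, min_separation), truth, fractions)
            for x, t, n in zip(curve.fractions, curve.tpr, curve.n_pairs):
                rows.append({"size": size, "replicate": rep, "fraction": x,
                             "tpr": t, "n_pairs": n})
    return pd.DataFrame(rows)
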