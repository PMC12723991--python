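"""Synthetic fixtures: planted Potts families, Gibbs-sampled MSAs, toy PDBs.

Everything downstream (DCA inference, VAE training, landscape construction,
contact evaluation) can be exercised against these generators, whose ground
truth — planted coupled pairs, cluster labels, contact geometry — is known
exactly.  The fixtures are statistical objects, not biophysical ones: no
attempt is made to mimic real 3Di state statistics or real fold geometry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .alphabets import reduced_alphabet
from .contacts import ContactMap
from .msa_io import EncodedMsa, Msa, decode
from .potts import PottsModel, to_zero_sum_gauge

MIN_SEPARATION = 4  # planted pairs always pass the |i-j| > 4 long-range filter


@dataclass
class PlantedFamily:
    """A Potts model with known sparse coupling topology."""

    model: PottsModel
    planted_pairs: set  # of (i, j) 0-based, i < j
    seed: int
    cluster_labels: np.ndarray = None


def make_planted_model(
    L: int,
    q: int,
    n_pairs: int,
    coupling_strength: float = 1.0,
    field_scale: float = 0.3,
    seed: int = 0,
) -> PlantedFamily:
    """A sparse Potts model whose couplings live only on n_pairs planted pairs.

    Fields are zero-mean Gaussian draws scaled by ``field_scale``.  Each
    planted pair (i, j), chosen among long-range pairs with j - i > 4, gets
    a q x q coupling block of magnitude ``coupling_strength`` favoring one
    random preferred state pair.  The model is returned in zero-sum gauge,
    so couplings remain exactly zero outside the planted pairs.
    """
    rng = np.random.default_rng(seed)
    admissible = [(i, j) for i in range(L) for j in range(i + 1, L) if j - i > MIN_SEPARATION]
    if n_pairs > len(admissible):
        raise ValueError(f"n_pairs={n_pairs} exceeds {len(admissible)} admissible long-range pairs")
    chosen = [admissible[k] for k in rng.choice(len(admissible), size=n_pairs, replace=False)]

    h = field_scale * rng.standard_normal((L, q))
    e = np.zeros((L, L, q, q))
    for (i, j) in chosen:
        a_star, b_star = rng.integers(0, q, size=2)
        block = np.zeros((q, q))
        block[a_star, b_star] = coupling_strength
        e[i, j] = block
        e[j, i] = block.T
    model = to_zero_sum_gauge(PottsModel(h=h, e=e))
    return PlantedFamily(model=model, planted_pairs=set(chosen), seed=seed)


@njit(cache=True)
def _gibbs_kernel(h, e, n_sequences, n_sweeps, seed):  # pragma: no cover - jitted
    L, q = h.shape
    out = np.empty((n_sequences, L), dtype=np.int64)
    np.random.seed(seed)
    logits = np.empty(q)
    for n in range(n_sequences):
        s = np.empty(L, dtype=np.int64)
        for i in range(L):
            s[i] = np.random.randint(0, q)
        for _ in range(n_sweeps):
            for i in range(L):
                for a in range(q):
                    v = h[i, a]
                    for j in range(L):
                        if j != i:
                            v += e[i, j, a, s[j]]
                    logits[a] = v
                mx = logits[0]
                for a in range(1, q):
                    if logits[a] > mx:
                        mx = logits[a]
                tot = 0.0
                for a in range(q):
                    logits[a] = np.exp(logits[a] - mx)
                    tot += logits[a]
                u = np.random.random() * tot
                acc = 0.0
                pick = q - 1
                for a in range(q):
                    acc += logits[a]
                    if u < acc:
                        pick = a
                        break
                s[i] = pick
        out[n] = s
    return out


def gibbs_sample(
    model: PottsModel,
    n_sequences: int,
    burn_in: int = 500,
    thinning: int = 1,
    seed: int = 0,
    as_msa: bool = True,
    id_prefix: str = "sample",
):
    """Draw sequences from the Potts distribution by single-site Gibbs sampling.

    One independent chain per output sequence: each chain starts from a
    uniform random sequence and runs ``burn_in`` full sweeps (fixed site
    order) of single-site updates with exact full-conditional probabilities
    P(s_i = a | rest) ∝ exp(h_i(a) + sum_{j≠i} e_ij(a, s_j)); the final
    state is the sample.  ``thinning`` is accepted for interface
    compatibility but has no effect across independent chains.
    """
    if burn_in < 0 or thinning < 1:
        raise ValueError("burn_in >= 0 and thinning >= 1 required")
    states = _gibbs_kernel(
        np.ascontiguousarray(model.h),
        np.ascontiguousarray(model.e),
        n_sequences,
        burn_in,
        int(seed) % 2**31,
    )
    encoded = EncodedMsa(
        states=states,
        alphabet=reduced_alphabet(model.q),
        ids=[f"{id_prefix}_{n:05d}" for n in range(n_sequences)],
    )
    return decode(encoded) if as_msa else encoded


def make_clustered_family(
    k_clusters: int,
    L: int,
    q: int,
    per_cluster_n: int,
    divergence: float,
    seed: int = 0,
    n_pairs: int = 10,
    coupling_strength: float = 1.0,
    burn_in: int = 200,
):
    """A mixture-of-Potts MSA: shared coupling topology, displaced fields.

    Each of the k clusters keeps the same planted couplings but has its
    field vector displaced by an independent Gaussian of scale
    ``divergence``, yielding distinguishable sequence populations.  Returns
    (Msa, labels, [PlantedFamily per cluster]).
    """
    if k_clusters < 2:
        raise ValueError("k_clusters >= 2 required")
    rng = np.random.default_rng(seed)
    base = make_planted_model(
        L, q, n_pairs, coupling_strength=coupling_strength, seed=int(rng.integers(2**31))
    )
    families, all_states, labels = [], [], []
    for k in range(k_clusters):
        h_k = base.model.h + divergence * rng.standard_normal((L, q))
        model_k = to_zero_sum_gauge(PottsModel(h=h_k, e=base.model.e))
        fam = PlantedFamily(model=model_k, planted_pairs=set(base.planted_pairs), seed=seed)
        families.append(fam)
        enc = gibbs_sample(
            model_k,
            per_cluster_n,
            burn_in=burn_in,
            seed=int(rng.integers(2**31)),
            as_msa=False,
            id_prefix=f"c{k}",
        )
        all_states.append(enc.states)
        labels.extend([k] * per_cluster_n)
    states = np.vstack(all_states)
    ids = [f"cluster{k}_seq{n:04d}" for k in range(k_clusters) for n in range(per_cluster_n)]
    msa = decode(EncodedMsa(states=states, alphabet=reduced_alphabet(q), ids=ids))
    return msa, np.array(labels), families


# ---------------------------------------------------------------------------
# toy structures
# ---------------------------------------------------------------------------

_BOND = 3.8  # Å, consecutive CA-CA
_CONTACT_TARGET = 6.0  # Å, target CB distance for requested contacts
_REPULSION = 9.5  # Å, minimum CA distance for non-requested long-range pairs


def _relax_coordinates(L, contact_pairs, rng, n_steps=4000, lr=0.02):
    """Gradient relaxation of CA coordinates: bonds at 3.8 Å, requested
    contacts pulled to ~6 Å, other long-range pairs pushed beyond 9.5 Å."""
    xyz = np.column_stack(
        [np.arange(L) * _BOND, np.zeros(L), np.zeros(L)]
    ) + 0.1 * rng.standard_normal((L, 3))
    contact_pairs = list(contact_pairs)
    others = [
        (i, j)
        for i in range(L)
        for j in range(i + 1, L)
        if j - i > MIN_SEPARATION and (i, j) not in set(contact_pairs)
    ]
    for _ in range(n_steps):
        grad = np.zeros_like(xyz)

        def spring(i, j, target, one_sided):
            d = xyz[i] - xyz[j]
            r = np.linalg.norm(d) + 1e-9
            if one_sided == "min" and r >= target:
                return
            if one_sided == "max" and r <= target:
                return
            g = 2.0 * (r - target) * d / r
            grad[i] += g
            grad[j] -= g

        for i in range(L - 1):
            spring(i, i + 1, _BOND, "")
        for (i, j) in contact_pairs:
            spring(i, j, _CONTACT_TARGET, "max")
        for (i, j) in others:
            spring(i, j, _REPULSION, "min")
        xyz -= lr * grad
    return xyz


def _cb_positions(ca: np.ndarray) -> np.ndarray:
    """Place CB 1.53 Å from CA, directed away from the local chain axis."""
    L = ca.shape[0]
    cb = np.empty_like(ca)
    for i in range(L):
        lo, hi = max(i - 1, 0), min(i + 1, L - 1)
        axis = ca[hi] - ca[lo]
        n = np.linalg.norm(axis)
        axis = axis / n if n > 0 else np.array([1.0, 0.0, 0.0])
        ref = np.array([0.0, 0.0, 1.0])
        if abs(axis @ ref) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        perp = ref - (ref @ axis) * axis
        perp /= np.linalg.norm(perp)
        cb[i] = ca[i] + 1.53 * perp
    return cb


def make_toy_structure(
    L: int,
    contact_pairs=(),
    seed: int = 0,
    path=None,
    glycine_positions=(),
    cutoff: float = 8.0,
    min_separation: int = MIN_SEPARATION,
):
    """Emit a minimal single-chain PDB whose contact map is known.

    The chain is relaxed from an extended conformation so that requested
    long-range pairs come within the contact cutoff and all other
    long-range pairs stay outside it.  Residues at ``glycine_positions``
    (0-based) are written as GLY without a CB atom, exercising the
    CA-fallback contact rule.  Returns (pdb_text_or_path, ContactMap); the
    returned map is the brute-force distance scan of the emitted
    coordinates, which must contain every requested pair or a ValueError
    lists the unrealizable ones.
    """
    contact_pairs = sorted(tuple(sorted(p)) for p in contact_pairs)
    for (i, j) in contact_pairs:
        if not (0 <= i < j < L) or j - i <= min_separation:
            raise ValueError(f"requested pair {(i, j)} is not long-range admissible")
    rng = np.random.default_rng(seed)
    ca = _relax_coordinates(L, contact_pairs, rng)
    cb = _cb_positions(ca)
    gly = set(glycine_positions)

    rep = np.array([ca[i] if i in gly else cb[i] for i in range(L)])
    dists = np.linalg.norm(rep[:, None, :] - rep[None, :, :], axis=2)
    pairs = {
        (i + 1, j + 1)
        for i in range(L)
        for j in range(i + 1, L)
        if j - i > min_separation and dists[i, j] <= cutoff
    }
    missing = [p for p in contact_pairs if (p[0] + 1, p[1] + 1) not in pairs]
    if missing:
        raise ValueError(f"geometry could not realize requested contacts: {missing}")

    lines = []
    serial = 1
    for i in range(L):
        resname = "GLY" if i in gly else "ALA"
        for atom, coord in (("CA", ca[i]),) + ((("CB", cb[i]),) if i not in gly else ()):
            lines.append(
                f"ATOM  {serial:5d}  {atom:<3s}{resname:>4s} A{i + 1:4d}    "
                f"{coord[0]:8.3f}{coord[1]:8.3f}{coord[2]:8.3f}  1.00  0.00"
                f"          {atom[0]:>2s}"
            )
            serial += 1
    lines.append("TER")
    lines.append("END")
    text = "\n".join(lines) + "\n"
    cmap = ContactMap(
        L=L, pairs=pairs, cutoff=cutoff, min_separation=min_separation
    )
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
        return path, cmap
    return text, cmap
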