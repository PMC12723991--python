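"""Latent generative landscapes: Hamiltonian and entropy surfaces over a grid.

A regular grid is laid over the VAE's 2-D latent space.  At each node the
decoder's per-position softmax distribution is computed; the
maximum-probability sequence S* (per-position argmax, ties to the lowest
state index) is extracted and scored by the Potts Hamiltonian H(S*), and
the node's uncertainty is the average per-position Shannon entropy of the
decoder distribution,

    Ĥ(z) = -(1/L) Σ_i Σ_a P(a|z)_i ln P(a|z)_i,

with natural log, summed over all q states (gap included), so
0 ≤ Ĥ ≤ ln q.  Low-Hamiltonian regions mark sequences plausible under the
family's coevolutionary constraints and are favored when generating.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import vae as vae_mod
from .msa_io import EncodedMsa
from .potts import PottsModel, hamiltonian_batch


@dataclass
class LandscapeGrid:
    """Axes, decoded sequences, and the H and entropy surfaces."""

    z0: np.ndarray  # (R0,) grid coordinates, first latent dim
    z1: np.ndarray  # (R1,)
    sequences: np.ndarray  # (R0, R1, L) decoded argmax states
    hamiltonian: np.ndarray  # (R0, R1)
    entropy: np.ndarray  # (R0, R1)

    @property
    def shape(self):
        return self.hamiltonian.shape

    def nearest_cell(self, point) -> tuple:
        return (
            int(np.argmin(np.abs(self.z0 - point[0]))),
            int(np.argmin(np.abs(self.z1 - point[1]))),
        )


@dataclass
class CorrelationProfile:
    """Pearson R between input and decoded-at-mu Hamiltonians vs exclusion radius."""

    radii: np.ndarray
    r_values: np.ndarray  # NaN where undefined (fewer than 3 retained points)
    n_retained: np.ndarray


def make_grid(embedding: np.ndarray, resolution: int = 100, margin: float = 0.1):
    """Uniform axes covering the embedded points plus a fractional margin.

    Returns (z0_axis, z1_axis).  A degenerate (zero-range) dimension falls
    back to a unit box around the point, with a warning.
    """
    if resolution < 2:
        raise ValueError("resolution must be >= 2")
    pts = np.atleast_2d(np.asarray(embedding, dtype=float))
    if pts.shape[0] < 1:
        raise ValueError("need at least one embedded point")
    axes = []
    for d in range(2):
        lo, hi = pts[:, d].min(), pts[:, d].max()
        rng = hi - lo
        if rng == 0:
            warnings.warn(f"degenerate embedding range in dimension {d}; using unit box")
            lo, hi = lo - 0.5, hi + 0.5
        else:
            lo, hi = lo - margin * rng, hi + margin * rng
        axes.append(np.linspace(lo, hi, resolution))
    return axes[0], axes[1]


def build_landscape(
    model: "vae_mod.VaeModel",
    potts: PottsModel,
    axes,
    decoder=None,
) -> LandscapeGrid:
    """Decode and score every grid node.

    ``decoder`` overrides the VAE decoder with any callable mapping a batch
    of latent points (B, 2) to probability arrays (B, q, L) — used for
    stubbed landscapes in validation.
    """
    z0, z1 = axes
    if potts is not None and model is not None and (model.L, model.q) != (potts.L, potts.q):
        raise ValueError("VAE and Potts model dimensions differ")
    Z0, Z1 = np.meshgrid(z0, z1, indexing="ij")
    zs = np.column_stack([Z0.ravel(), Z1.ravel()])
    probs = decoder(zs) if decoder is not None else model.decode_probabilities(zs)
    seqs = np.argmax(probs, axis=1)  # (B, L)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(probs > 0, probs * np.log(probs), 0.0)
    ent = -plogp.sum(axis=1).mean(axis=1)  # (B,)
    H = hamiltonian_batch(potts, seqs)
    R0, R1 = len(z0), len(z1)
    L = seqs.shape[1]
    return LandscapeGrid(
        z0=np.asarray(z0),
        z1=np.asarray(z1),
        sequences=seqs.reshape(R0, R1, L),
        hamiltonian=H.reshape(R0, R1),
        entropy=ent.reshape(R0, R1),
    )


def embed_msa(
    encoded: EncodedMsa,
    model: "vae_mod.VaeModel",
    potts: PottsModel,
    decoder=None,
) -> pd.DataFrame:
    """Per-sequence table: μ, σ, input H, decoded-at-μ H, local entropy.

    Every sequence is encoded to its posterior mean μ; the decoder's
    distribution at μ yields the decoded maximum-probability sequence and
    its Hamiltonian, directly comparable to the input sequence's own
    Hamiltonian.
    """
    mu, sigma = vae_mod.encode_msa(model, encoded)
    probs = decoder(mu) if decoder is not None else model.decode_probabilities(mu)
    dec_seqs = np.argmax(probs, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(probs > 0, probs * np.log(probs), 0.0)
    ent = -plogp.sum(axis=1).mean(axis=1)
    return pd.DataFrame(
        {
            "id": encoded.ids,
            "mu0": mu[:, 0],
            "mu1": mu[:, 1],
            "sigma0": sigma[:, 0],
            "sigma1": sigma[:, 1],
            "hamiltonian_input": hamiltonian_batch(potts, encoded.states),
            "hamiltonian_decoded": hamiltonian_batch(potts, dec_seqs),
            "entropy": ent,
        }
    )


def correlation_profile(
    encoded: EncodedMsa,
    model: "vae_mod.VaeModel",
    potts: PottsModel,
    radii,
    center=(0.0, 0.0),
    decoder=None,
    table: pd.DataFrame = None,
) -> CorrelationProfile:
    """Input-vs-decoded Hamiltonian correlation under radial exclusion.

    Sequences whose μ lies within radius r of ``center`` — by default the
    latent origin, where decoder entropy peaks — are excluded and Pearson R
    is computed on the remainder.  R is NaN where fewer than 3 sequences
    remain.
    """
    radii = np.asarray(list(radii), dtype=float)
    if radii.size and np.any(np.diff(radii) <= 0):
        raise ValueError("radii must be strictly increasing")
    if table is None:
        table = embed_msa(encoded, model, potts, decoder=decoder)
    mu = table[["mu0", "mu1"]].to_numpy()
    dist = np.linalg.norm(mu - np.asarray(center, dtype=float), axis=1)
    h_in = table["hamiltonian_input"].to_numpy()
    h_dec = table["hamiltonian_decoded"].to_numpy()
    r_values, n_ret = [], []
    for r in radii:
        keep = dist > r
        n = int(keep.sum())
        n_ret.append(n)
        if n < 3 or np.std(h_in[keep]) == 0 or np.std(h_dec[keep]) == 0:
            r_values.append(np.nan)
        else:
            r_values.append(sps.pearsonr(h_in[keep], h_dec[keep]).statistic)
    return CorrelationProfile(
        radii=radii, r_values=np.array(r_values), n_retained=np.array(n_ret)
    )


def select_low_energy(grid: LandscapeGrid, quantile: float) -> list:
    """Grid cells in the lowest Hamiltonian quantile, ascending by H.

    Returns [(z, S*), ...] with z the cell's latent coordinates and S* its
    decoded state sequence; ``quantile`` = 1 returns every cell, and the
    limit quantile -> 0+ returns the single minimal-H cell.
    """
    if not 0 < quantile <= 1:
        raise ValueError("quantile must be in (0, 1]")
    H = grid.hamiltonian
    n_cells = H.size
    k = max(1, int(np.ceil(quantile * n_cells)))
    flat_order = np.argsort(H, axis=None, kind="stable")[:k]
    out = []
    for f in flat_order:
        i, j = np.unravel_index(f, H.shape)
        out.append(((float(grid.z0[i]), float(grid.z1[j])), grid.sequences[i, j].copy()))
    return out


def path_cells(grid: LandscapeGrid, start, end, n_points: int = 25, inner_fraction: float = 1 / 3):
    """Unique grid cells along the straight latent segment from start to end.

    Only the central ``inner_fraction`` of the segment is kept, which
    isolates the inter-cluster barrier region from the cluster cores.
    """
    start, end = np.asarray(start, float), np.asarray(end, float)
    t0 = 0.5 - inner_fraction / 2
    ts = np.linspace(t0, 1 - t0, n_points)
    cells = {grid.nearest_cell(start + t * (end - start)) for t in ts}
    return sorted(cells)


def save_landscape(grid: LandscapeGrid, path):
    import h5py

    with h5py.File(path, "w") as f:
        for name in ("z0", "z1", "sequences", "hamiltonian", "entropy"):
            f.create_dataset(name, data=getattr(grid, name))
    return path


def load_landscape(path) -> LandscapeGrid:
    import h5py

    with h5py.File(path, "r") as f:
        return LandscapeGrid(**{k: f[k][...] for k in ("z0", "z1", "sequences", "hamiltonian", "entropy")})


def plot_landscape(grid: LandscapeGrid, embedding: np.ndarray = None, path=None, surface="hamiltonian"):
    """Heatmap of the H or entropy surface with an optional μ scatter overlay."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    M = getattr(grid, surface)
    im = ax.pcolormesh(grid.z0, grid.z1, M.T, shading="nearest", cmap="viridis")
    fig.colorbar(im, ax=ax, label=surface)
    if embedding is not None:
        ax.scatter(embedding[:, 0], embedding[:, 1], s=6, c="white", edgecolors="k", linewidths=0.2)
    ax.set_xlabel("z0")
    ax.set_ylabel("z1")
    if path:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
        return path
    return fig
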