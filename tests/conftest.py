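"""Shared fixtures: planted Potts families, clustered MSAs, trained VAEs.

Heavy fixtures (Gibbs-sampled MSAs, trained models) are session-scoped so
the property tests and the acceptance tests share one computation.
"""

import numpy as np
import pytest

from structland import landscape, msa_io, potts, synthetic, vae
from structland.alphabets import reduced_alphabet


@pytest.fixture(scope="session")
def planted():
    """Planted sparse family at the standard fixture scale (L=30, q=4)."""
    fam = synthetic.make_planted_model(
        L=30, q=4, n_pairs=10, coupling_strength=1.0, seed=7
    )
    enc = synthetic.gibbs_sample(fam.model, 2000, burn_in=500, seed=7, as_msa=False)
    return fam, enc


@pytest.fixture(scope="session")
def planted_fit(planted):
    fam, enc = planted
    model, stats, weights = potts.fit_msa(enc)
    di = potts.direct_information(model, stats)
    return fam, enc, model, stats, di


@pytest.fixture(scope="session")
def two_cluster():
    """Two-cluster mixture-of-Potts family with strongly displaced fields."""
    msa, labels, fams = synthetic.make_clustered_family(
        k_clusters=2, L=30, q=4, per_cluster_n=150, divergence=2.0, seed=7
    )
    return msa_io.encode(msa), labels, fams


@pytest.fixture(scope="session")
def two_cluster_vae(two_cluster):
    enc, labels, _ = two_cluster
    cfg = vae.VaeConfig(learning_rate=1e-3, patience=50, max_epochs=600, seed=7)
    model, report = vae.train(enc, cfg)
    return model, report


@pytest.fixture(scope="session")
def two_cluster_landscape(two_cluster, two_cluster_vae):
    enc, labels, _ = two_cluster
    model, _ = two_cluster_vae
    pm, stats, _ = potts.fit_msa(enc)
    mu, _ = vae.encode_msa(model, enc)
    axes = landscape.make_grid(mu, resolution=50)
    grid = landscape.build_landscape(model, pm, axes)
    return grid, mu, pm


@pytest.fixture
def tiny_aa_msa():
    from structland.alphabets import AA

    return msa_io.Msa(
        ids=["s1", "s2", "s3"],
        rows=["AC-D", "AAGD", "GC-D"],
        alphabet=AA,
    )


def random_model(L, q, rng, scale=1.0):
    """A random symmetric Potts model with zero diagonal couplings."""
    h = scale * rng.standard_normal((L, q))
    e = scale * rng.standard_normal((L, L, q, q))
    e = 0.5 * (e + e.transpose(1, 0, 3, 2))
    idx = np.arange(L)
    e[idx, idx] = 0.0
    return potts.PottsModel(h=h, e=e)


def brute_force_hamiltonian(model, seq):
    """Independent double-loop evaluation of H(S)."""
    total = 0.0
    L = model.L
    for i in range(L):
        total -= model.h[i, seq[i]]
        for j in range(i + 1, L):
            total -= model.e[i, j, seq[i], seq[j]]
    return total
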