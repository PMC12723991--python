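"""Mean-field direct coupling analysis (mfDCA) and Potts Hamiltonian scoring.

The model is the standard Potts distribution over aligned sequences,

    P(S) = (1/Z) exp( sum_{i<j} e_ij(a_i, a_j) + sum_i h_i(a_i) ),

with Hamiltonian H(S) = -sum_{i<j} e_ij(a_i,a_j) - sum_i h_i(a_i), so lower
H means higher probability.  Inference is the mean-field inversion of the
connected-correlation matrix computed from reweighted, pseudocounted MSA
statistics; contacts are ranked by direct information (DI).

The gap is an ordinary 21st state throughout; the gap state (last alphabet
index) is the excluded reference in the (q-1)-state inversion.
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np

from .msa_io import EncodedMsa

DEFAULT_THETA = 0.8
DEFAULT_LAMBDA = 0.5


class DcaError(RuntimeError):
    pass


@dataclass
class SequenceWeights:
    """Identity-based reweighting: w[n] = 1 / (# sequences >= theta identical)."""

    w: np.ndarray
    theta: float

    @property
    def Meff(self) -> float:
        return float(self.w.sum())


@dataclass
class SiteStatistics:
    """Pseudocounted single-site and pair frequencies of a weighted MSA."""

    f_i: np.ndarray  # (L, q)
    f_ij: np.ndarray  # (L, L, q, q)
    lam: float
    q: int

    @property
    def L(self) -> int:
        return self.f_i.shape[0]


@dataclass
class PottsModel:
    """Fields h_i(a) and couplings e_ij(a,b); e_ij(a,b) = e_ji(b,a), e_ii = 0."""

    h: np.ndarray  # (L, q)
    e: np.ndarray  # (L, L, q, q)
    gauge: str = "mean-field-raw"

    @property
    def L(self) -> int:
        return self.h.shape[0]

    @property
    def q(self) -> int:
        return self.h.shape[1]


@dataclass
class DiMatrix:
    """Symmetric nonnegative direct-information matrix with zero diagonal."""

    di: np.ndarray  # (L, L)

    @property
    def L(self) -> int:
        return self.di.shape[0]


def compute_weights(encoded: EncodedMsa, theta: float = DEFAULT_THETA) -> SequenceWeights:
    """Down-weight redundant sequences at fractional-identity threshold theta.

    w[n] = 1 / |{m : identity(n, m) >= theta}| (the count includes n itself),
    so 0 < w[n] <= 1 and 1 <= Meff <= N.
    """
    if not 0 < theta <= 1:
        raise ValueError("theta must be in (0, 1]")
    S = encoded.states
    N, L = S.shape
    counts = np.zeros(N, dtype=np.int64)
    # chunked pairwise identity to bound memory at ~chunk*N*L bytes
    chunk = max(1, int(2e8 // (N * L + 1)))
    for start in range(0, N, chunk):
        block = S[start : start + chunk]  # (c, L)
        ident = (block[:, None, :] == S[None, :, :]).mean(axis=2)  # (c, N)
        counts[start : start + chunk] = (ident >= theta).sum(axis=1)
    return SequenceWeights(w=1.0 / counts, theta=theta)


def site_statistics(
    encoded: EncodedMsa,
    weights: SequenceWeights = None,
    lam: float = DEFAULT_LAMBDA,
) -> SiteStatistics:
    """Weighted single-site and pair frequencies with uniform pseudocount lam.

    f_i(a)      = lam/q   + (1-lam) * weighted count of a at i / Meff
    f_ij(a,b)   = lam/q^2 + (1-lam) * weighted pair count / Meff   (i != j)
    f_ii(a,b)   = f_i(a) * [a == b]
    """
    if not 0 <= lam < 1:
        raise ValueError("lambda must be in [0, 1)")
    S = encoded.states
    N, L = S.shape
    q = encoded.q
    w = np.ones(N) if weights is None else weights.w
    Meff = w.sum()

    X = np.zeros((N, L, q))
    X[np.arange(N)[:, None], np.arange(L)[None, :], S] = 1.0
    Xw = X * w[:, None, None]

    fi_obs = Xw.sum(axis=0) / Meff  # (L, q)
    Xf = Xw.reshape(N, L * q)
    fij_obs = (X.reshape(N, L * q).T @ Xf).reshape(L, q, L, q).transpose(0, 2, 1, 3) / Meff

    f_i = lam / q + (1 - lam) * fi_obs
    f_ij = lam / q**2 + (1 - lam) * fij_obs
    # diagonal blocks carry single-site frequencies only
    for i in range(L):
        f_ij[i, i] = np.diag(f_i[i])
    return SiteStatistics(f_i=f_i, f_ij=f_ij, lam=lam, q=q)


def mean_field_fit(stats: SiteStatistics) -> PottsModel:
    """Infer a Potts model by mean-field inversion of connected correlations.

    C_ij(a,b) = f_ij(a,b) - f_i(a) f_j(b) over the q-1 non-reference states
    per site is inverted; e_ij(a,b) = -(C^-1)_ij(a,b), zero-padded on the
    reference (gap) state.  Fields are set self-consistently from the
    single-site frequencies.  The model is returned in zero-sum gauge.
    """
    if stats.lam <= 0:
        raise ValueError("mean-field inversion requires lambda > 0")
    L, q = stats.L, stats.q
    r = q - 1  # reduced states; last (gap) state is the reference
    C = (
        stats.f_ij[:, :, :r, :r]
        - stats.f_i[:, None, :r, None] * stats.f_i[None, :, None, :r]
    )
    Cm = C.transpose(0, 2, 1, 3).reshape(L * r, L * r)
    try:
        Jm = -np.linalg.inv(Cm)
    except np.linalg.LinAlgError as exc:
        raise DcaError(
            "connected-correlation matrix is singular; increase the pseudocount lambda"
        ) from exc

    e = np.zeros((L, L, q, q))
    e[:, :, :r, :r] = Jm.reshape(L, r, L, r).transpose(0, 2, 1, 3)
    idx = np.arange(L)
    e[idx, idx] = 0.0
    e = 0.5 * (e + e.transpose(1, 0, 3, 2))  # enforce e_ij(a,b) = e_ji(b,a)

    # mean-field self-consistent fields: h_i(a) = ln f_i(a)/f_i(ref)
    #                                            - sum_j e_ij(a, :) . f_j
    h = np.log(stats.f_i / stats.f_i[:, -1:])
    h -= np.einsum("ijab,jb->ia", e, stats.f_i)
    model = PottsModel(h=h, e=e, gauge="mean-field-raw")
    return to_zero_sum_gauge(model)


def hamiltonian(model: PottsModel, sequence: np.ndarray) -> float:
    """H(S) = -sum_{i<j} e_ij(a_i,a_j) - sum_i h_i(a_i)."""
    s = np.asarray(sequence, dtype=np.int64)
    if s.shape != (model.L,):
        raise ValueError(f"sequence length {s.shape} does not match model L={model.L}")
    field = model.h[np.arange(model.L), s].sum()
    pair = 0.0
    iu, ju = np.triu_indices(model.L, k=1)
    pair = model.e[iu, ju, s[iu], s[ju]].sum()
    return float(-pair - field)


def hamiltonian_batch(model: PottsModel, sequences: np.ndarray) -> np.ndarray:
    """Vectorized Hamiltonian for an (N, L) array of state sequences."""
    S = np.asarray(sequences, dtype=np.int64)
    if S.ndim == 1:
        S = S[None, :]
    L = model.L
    field = model.h[np.arange(L)[None, :], S].sum(axis=1)
    iu, ju = np.triu_indices(L, k=1)
    pair = model.e[iu[None, :], ju[None, :], S[:, iu], S[:, ju]].sum(axis=1)
    return -pair - field


def to_zero_sum_gauge(model: PottsModel) -> PottsModel:
    """Re-express the model with zero-sum couplings and zero-mean fields.

    Hamiltonian differences H(S1) - H(S2) are invariant under this change;
    only a sequence-independent constant shifts.
    """
    e = model.e.copy()
    row = e.mean(axis=3, keepdims=True)  # (L, L, q, 1)
    col = e.mean(axis=2, keepdims=True)  # (L, L, 1, q)
    tot = e.mean(axis=(2, 3), keepdims=True)
    e_zs = e - row - col + tot
    # absorb the removed coupling parts into the fields
    h = model.h + (row.squeeze(3) - tot.squeeze((2, 3))[:, :, None]).sum(axis=1)
    h = h - h.mean(axis=1, keepdims=True)
    idx = np.arange(model.L)
    e_zs[idx, idx] = 0.0
    return PottsModel(h=h, e=e_zs, gauge="zero-sum")


def direct_information(
    model: PottsModel,
    stats: SiteStatistics,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> DiMatrix:
    """Direct information of every position pair.

    For each i<j the two-site direct distribution
    P_dir(a,b) ∝ exp(e_ij(a,b)) · ĥ_i(a) · ĥ_j(b) is built with auxiliary
    fields ĥ chosen by fixed-point iteration so its marginals match f_i and
    f_j; DI[i,j] is the KL divergence of P_dir from the product of its
    marginals (the mutual information of the direct distribution).
    """
    L, q = model.L, model.q
    if stats.L != L or stats.q != q:
        raise ValueError("model and statistics dimensions differ")
    di = np.zeros((L, L))
    f = stats.f_i
    for i in range(L):
        for j in range(i + 1, L):
            W = np.exp(model.e[i, j])
            mi = np.full(q, 1.0 / q)
            mj = np.full(q, 1.0 / q)
            for _ in range(max_iter):
                mi_new = f[i] / (W @ mj)
                mi_new /= mi_new.sum()
                mj_new = f[j] / (W.T @ mi_new)
                mj_new /= mj_new.sum()
                P = W * np.outer(mi_new, mj_new)
                P /= P.sum()
                err = max(
                    np.abs(P.sum(axis=1) - f[i]).max(),
                    np.abs(P.sum(axis=0) - f[j]).max(),
                )
                mi, mj = mi_new, mj_new
                if err < tol:
                    break
            else:
                raise DcaError(f"DI fixed point did not converge for pair ({i}, {j})")
            pi = P.sum(axis=1)
            pj = P.sum(axis=0)
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(P > 0, P / np.outer(pi, pj), 1.0)
                val = float((P * np.log(ratio)).sum())
            di[i, j] = di[j, i] = max(val, 0.0)
    return DiMatrix(di=di)


def fit_msa(
    encoded: EncodedMsa,
    theta: float = DEFAULT_THETA,
    lam: float = DEFAULT_LAMBDA,
):
    """Convenience pipeline: weights -> statistics -> mean-field model."""
    weights = compute_weights(encoded, theta=theta)
    stats = site_statistics(encoded, weights, lam=lam)
    model = mean_field_fit(stats)
    return model, stats, weights


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def save_model(model: PottsModel, path, alphabet_name: str = "", meta: dict = None):
    """Write h, e, gauge and provenance metadata to an HDF5 container."""
    with h5py.File(path, "w") as f:
        f.create_dataset("h", data=model.h)
        f.create_dataset("e", data=model.e)
        f.attrs["gauge"] = model.gauge
        f.attrs["alphabet"] = alphabet_name
        for k, v in (meta or {}).items():
            f.attrs[k] = v
    return path


def load_model(path) -> PottsModel:
    with h5py.File(path, "r") as f:
        return PottsModel(h=f["h"][...], e=f["e"][...], gauge=f.attrs.get("gauge", ""))
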