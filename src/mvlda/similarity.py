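"""Profile-based similarity matrices and their weighted fusion.

lncRNA similarity LS and disease similarity DS are each a convex
combination of the Gaussian interaction profile (GIP) kernel and cosine
similarity computed from the binary association profiles (LD rows for
lncRNAs, LD columns for diseases).  A precomputed disease semantic
similarity matrix can replace the cosine term on the disease side.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from sklearn.metrics.pairwise import cosine_similarity as _sk_cosine

from .datasets import AssociationDataset, Config

__all__ = [
    "SimilarityBundle",
    "gip_kernel",
    "cosine_similarity",
    "fuse_similarities",
    "build_similarity_bundle",
]


@dataclasses.dataclass(frozen=True)
class SimilarityBundle:
    LS: np.ndarray  # nl x nl fused lncRNA similarity
    DS: np.ndarray  # nd x nd fused disease similarity


def gip_kernel(profiles: np.ndarray, bandwidth_factor: float = 1.0) -> np.ndarray:
    """Gaussian interaction profile kernel between binary profiles.

    K(i,j) = exp(-gamma * ||p_i - p_j||^2) with the bandwidth normalized by
    the mean squared profile norm: gamma = bandwidth_factor / mean_i ||p_i||^2.
    Symmetric with unit diagonal.
    """
    profiles = np.asarray(profiles, dtype=float)
    mean_sq = np.mean(np.sum(profiles**2, axis=1))
    if mean_sq == 0:
        raise ValueError("all profiles are zero: GIP bandwidth undefined")
    gamma = bandwidth_factor / mean_sq
    sq = np.sum(profiles**2, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * profiles @ profiles.T
    np.maximum(d2, 0.0, out=d2)
    K = np.exp(-gamma * d2)
    # exact symmetry / unit diagonal against float round-off
    K = 0.5 * (K + K.T)
    np.fill_diagonal(K, 1.0)
    return K


def cosine_similarity(profiles: np.ndarray) -> np.ndarray:
    """Cosine similarity between profile rows; zero-norm rows map to 0
    everywhere, including their own diagonal."""
    profiles = np.asarray(profiles, dtype=float)
    C = _sk_cosine(profiles)  # handles zero rows by returning 0
    C = 0.5 * (C + C.T)
    nonzero = np.linalg.norm(profiles, axis=1) > 0
    np.fill_diagonal(C, nonzero.astype(float))
    return np.clip(C, -1.0, 1.0)


def fuse_similarities(K: np.ndarray, C: np.ndarray,
                      w_gip: float, w_cos: float) -> np.ndarray:
    """Weighted sum w_gip*K + w_cos*C, clipped into [0, 1]."""
    K = np.asarray(K, dtype=float)
    C = np.asarray(C, dtype=float)
    if K.shape != C.shape:
        raise ValueError(f"shape mismatch: {K.shape} vs {C.shape}")
    return np.clip(w_gip * K + w_cos * C, 0.0, 1.0)


def build_similarity_bundle(dataset: AssociationDataset, config: Config,
                            semantic_DS: np.ndarray | None = None,
                            LD: np.ndarray | None = None) -> SimilarityBundle:
    """Fused LS and DS for a dataset.

    ``LD`` overrides the dataset's association matrix; cross-validation
    passes the training-fold matrix (test edges zeroed) here so that
    similarities never see held-out associations.  When ``semantic_DS`` is
    given it stands in for the cosine term of the disease fusion.
    """
    A = dataset.LD if LD is None else np.asarray(LD, dtype=float)
    LS = fuse_similarities(
        gip_kernel(A, config.gamma_l_prime),
        cosine_similarity(A),
        config.alpha1, config.alpha2)
    if semantic_DS is not None:
        semantic_DS = np.asarray(semantic_DS, dtype=float)
        if semantic_DS.shape != (dataset.nd, dataset.nd):
            raise ValueError(
                f"semantic similarity shape {semantic_DS.shape} does not "
                f"match disease count {dataset.nd}")
        dcos = semantic_DS
    else:
        dcos = cosine_similarity(A.T)
    DS = fuse_similarities(gip_kernel(A.T, config.gamma_d), dcos,
                           config.beta1, config.beta2)
    return SimilarityBundle(LS=LS, DS=DS)


def check_bundle(bundle: SimilarityBundle, atol: float = 1e-10) -> None:
    """Assert symmetry and [0,1] range; used by tests and debug dumps."""
    for name, S in (("LS", bundle.LS), ("DS", bundle.DS)):
        if not np.allclose(S, S.T, atol=atol):
            raise AssertionError(f"{name} is not symmetric")
        if S.min() < -atol or S.max() > 1 + atol:
            raise AssertionError(f"{name} entries outside [0,1]")
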