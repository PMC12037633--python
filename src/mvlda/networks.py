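"""Construction of the two graph views and their propagation matrices.

The association view (net2) stacks similarities and associations into one
symmetric block matrix over lncRNA and disease nodes; the same matrix
doubles as the initial feature matrix, so features(l_i) = [LS row i ; LD
row i] and features(d_j) = [LD^T row j ; DS row j].  The heterogeneous view
(net1) adds a miRNA layer between lncRNAs and diseases.  Both are
symmetrically normalized with self-loops before spectral convolution.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .similarity import SimilarityBundle

__all__ = [
    "ViewGraphs",
    "build_association_view",
    "build_heterogeneous_view",
    "normalize_adjacency",
    "build_views",
]


@dataclasses.dataclass(frozen=True)
class ViewGraphs:
    """Adjacency, feature and normalized propagation matrices of both views.

    net1 matrices (A1/X1/Ahat1) are ``None`` when the heterogeneous view is
    not built (association-view-only ablation).
    """

    A2: np.ndarray
    F1: np.ndarray
    Ahat2: np.ndarray
    A1: np.ndarray | None
    X1: np.ndarray | None
    Ahat1: np.ndarray | None
    nl: int
    nm: int
    nd: int


def build_association_view(bundle: SimilarityBundle, LD: np.ndarray):
    """Block matrix [[LS, LD], [LD^T, DS]]; returned twice as (A2, F1)
    because the adjacency doubles as the initial feature matrix."""
    LS, DS = bundle.LS, bundle.DS
    LD = np.asarray(LD, dtype=float)
    nl, nd = LD.shape
    if LS.shape != (nl, nl) or DS.shape != (nd, nd):
        raise ValueError(
            f"block shapes inconsistent: LS {LS.shape}, DS {DS.shape}, "
            f"LD {LD.shape}")
    A2 = np.block([[LS, LD], [LD.T, DS]])
    return A2, A2.copy()


def build_heterogeneous_view(bundle: SimilarityBundle, LD: np.ndarray,
                             LM: np.ndarray):
    """Three-layer lncRNA-miRNA-disease adjacency, nodes ordered
    (lncRNAs, miRNAs, diseases):

        [[LS,   LM, LD],
         [LM^T, I,  0 ],
         [LD^T, 0,  DS]]

    miRNA-disease edges are absent and miRNAs carry self-loops only.  The
    feature matrix X1 equals A1, extending the features-equal-adjacency
    convention of the association view.
    """
    LS, DS = bundle.LS, bundle.DS
    LD = np.asarray(LD, dtype=float)
    LM = np.asarray(LM, dtype=float)
    nl, nd = LD.shape
    nm = LM.shape[1]
    if LM.shape[0] != nl:
        raise ValueError(f"LM has {LM.shape[0]} rows, expected {nl}")
    if LS.shape != (nl, nl) or DS.shape != (nd, nd):
        raise ValueError("similarity block shapes inconsistent with LD")
    A1 = np.block([
        [LS, LM, LD],
        [LM.T, np.eye(nm), np.zeros((nm, nd))],
        [LD.T, np.zeros((nd, nm)), DS],
    ])
    return A1, A1.copy()


def normalize_adjacency(A: np.ndarray) -> np.ndarray:
    """Symmetric normalization with self-loops:
    Ahat = Dt^{-1/2} (A + I) Dt^{-1/2}, Dt_ii = sum_j (A + I)_ij.

    Self-loops keep every degree positive, and the result's spectrum lies
    in [-1, 1] with Dt^{1/2}·1 an eigenvector at eigenvalue 1.
    """
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError(f"adjacency must be square, got {A.shape}")
    if (A < 0).any():
        raise ValueError("adjacency entries must be nonnegative")
    At = A + np.eye(A.shape[0])
    dinv_sqrt = 1.0 / np.sqrt(At.sum(axis=1))
    return dinv_sqrt[:, None] * At * dinv_sqrt[None, :]


def build_views(bundle: SimilarityBundle, LD: np.ndarray, LM: np.ndarray,
                view: str = "both") -> ViewGraphs:
    """Assemble every matrix the encoder needs for the requested view(s).

    ``view='net2'`` skips the heterogeneous view entirely; ``view='net1'``
    still builds the association view because it supplies nothing to the
    encoder in that mode (its matrices are cheap and keep the contract
    uniform), but training will only consume A1/X1.
    """
    LD = np.asarray(LD, dtype=float)
    nl, nd = LD.shape
    nm = LM.shape[1]
    A2, F1 = build_association_view(bundle, LD)
    Ahat2 = normalize_adjacency(A2)
    if view == "net2":
        A1 = X1 = Ahat1 = None
    else:
        A1, X1 = build_heterogeneous_view(bundle, LD, LM)
        Ahat1 = normalize_adjacency(A1)
    return ViewGraphs(A2=A2, F1=F1, Ahat2=Ahat2, A1=A1, X1=X1, Ahat1=Ahat1,
                      nl=nl, nm=nm, nd=nd)
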