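"""Per-view GCN -> GAT -> GCN encoder and the bilinear decoder.

Each view's encoder is a spectral graph convolution (propagation with the
symmetrically normalized adjacency, a linear map and a ReLU), a graph
attention layer whose scores are computed from node features only and
normalized over each node's neighborhood, and a second graph convolution
down to the view's latent width.  The two latent matrices are concatenated
column-wise, split into lncRNA and disease blocks, and decoded bilinearly
into an association score for every pair.

The public functions accept plain numpy arrays and return numpy arrays;
training drives the same ``*_t`` tensor implementations through the
autodiff engine, so there is exactly one code path for the mathematics.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .datasets import Config
from .networks import ViewGraphs

__all__ = [
    "ModelParams",
    "init_params",
    "gcn_layer",
    "gat_scores",
    "gat_layer",
    "encode_view",
    "concat_embeddings",
    "bilinear_decode",
    "forward_scores",
]


@dataclasses.dataclass
class ModelParams:
    """All trainable tensors.

    ``net1``/``net2`` each hold the per-view encoder parameters
    (Wc1, B1 first convolution; Wt, bt attention; Wc2, B2 second
    convolution); ``Wl``/``Wd`` are the decoder projections.  A view dict is
    ``None`` when that view is disabled by the ablation mode.
    """

    net1: dict | None
    net2: dict | None
    Wl: Tensor
    Wd: Tensor

    def trainable(self) -> list[Tensor]:
        out = []
        for view in (self.net1, self.net2):
            if view is not None:
                out.extend(view.values())
        out.extend([self.Wl, self.Wd])
        return out

    def regularized(self) -> list[Tensor]:
        """Parameters entering the norm penalty: Wc, Wt, B and offsets of
        every view, plus the decoder map Wd (Wl is not penalized)."""
        out = []
        for view in (self.net1, self.net2):
            if view is not None:
                out.extend(view.values())
        out.append(self.Wd)
        return out


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def _view_params(rng: np.random.Generator, in_dim: int, hidden: int,
                 latent: int) -> dict:
    return {
        "Wc1": ad.parameter(_glorot(rng, in_dim, hidden)),
        "B1": ad.parameter(np.zeros((1, hidden))),
        "Wt": ad.parameter(_glorot(rng, hidden, hidden)),
        "bt": ad.parameter(np.zeros((1, hidden))),
        "Wc2": ad.parameter(_glorot(rng, hidden, latent)),
        "B2": ad.parameter(np.zeros((1, latent))),
    }


def init_params(config: Config, in_dim1: int | None, in_dim2: int | None,
                rng: np.random.Generator) -> ModelParams:
    """Glorot-uniform weights, zero offsets, fully seeded.

    ``in_dim1``/``in_dim2`` are the feature widths of the heterogeneous and
    association views (``None`` disables a view).  The decoder input width
    is the sum of the active latent widths.
    """
    net1 = net2 = None
    dec_in = 0
    if in_dim1 is not None:
        net1 = _view_params(rng, in_dim1, config.hidden, config.l1)
        dec_in += config.l1
    if in_dim2 is not None:
        net2 = _view_params(rng, in_dim2, config.hidden, config.l2)
        dec_in += config.l2
    if dec_in == 0:
        raise ValueError("at least one view must be enabled")
    Wl = ad.parameter(_glorot(rng, dec_in, config.r))
    Wd = ad.parameter(_glorot(rng, dec_in, config.r))
    return ModelParams(net1=net1, net2=net2, Wl=Wl, Wd=Wd)


# -- tensor-path layers ----------------------------------------------------

def gcn_layer_t(Ahat: Tensor, X: Tensor, Wc: Tensor, B: Tensor) -> Tensor:
    """relu(Ahat @ X @ Wc + B); B broadcasts one offset per output feature."""
    return ad.relu(ad.matmul(ad.matmul(Ahat, X), Wc) + B)


def gat_scores_t(H: Tensor, Wt: Tensor, bt: Tensor,
                 neighbor_mask: np.ndarray) -> Tensor:
    """Attention weights alpha_ij = softmax_j(e_ij) over j in N(i).

    e_ij = (Wt h_j)^T tanh(Wt h_i + b): with U = H Wt^T and
    V = tanh(U + b), the score matrix is E = V U^T.
    """
    U = ad.matmul(H, Wt.T)
    V = ad.tanh(U + bt)
    E = ad.matmul(V, U.T)
    return ad.masked_softmax(E, neighbor_mask)


def gat_layer_t(H: Tensor, attention: Tensor) -> Tensor:
    """h'_i = relu(sum_j alpha_ij h_j) — convex neighbor mixing + ReLU."""
    return ad.relu(ad.matmul(attention, H))


def encode_view_t(Ahat: Tensor, X0: Tensor, vp: dict,
                  neighbor_mask: np.ndarray,
                  keep: tuple | None = None) -> Tensor:
    """GCN -> GAT -> GCN for one view.

    ``keep`` = ((l_start, l_stop), (d_start, d_stop)) restricts the output to
    the lncRNA and disease rows; the heterogeneous view uses it to drop its
    miRNA rows so both views emit (nl + nd) embeddings.
    """
    H1 = gcn_layer_t(Ahat, X0, vp["Wc1"], vp["B1"])
    att = gat_scores_t(H1, vp["Wt"], vp["bt"], neighbor_mask)
    H2 = gat_layer_t(H1, att)
    H3 = gcn_layer_t(Ahat, H2, vp["Wc2"], vp["B2"])
    if keep is not None:
        (ls, le), (ds, de) = keep
        H3 = ad.concat_rows(ad.slice_rows(H3, ls, le),
                            ad.slice_rows(H3, ds, de))
    return H3


def bilinear_decode_t(Yl: Tensor, Yd: Tensor, Wl: Tensor, Wd: Tensor) -> Tensor:
    return ad.matmul(ad.matmul(Yl, Wl), ad.matmul(Yd, Wd).T)


def forward_scores(views: ViewGraphs, params: ModelParams) -> Tensor:
    """Full encoder/decoder pass; returns the nl x nd score tensor."""
    nl, nm, nd = views.nl, views.nm, views.nd
    embeddings = []
    if params.net1 is not None:
        mask1 = (views.A1 + np.eye(views.A1.shape[0])) > 0
        H3n1 = encode_view_t(ad.constant(views.Ahat1), ad.constant(views.X1),
                             params.net1, mask1,
                             keep=((0, nl), (nl + nm, nl + nm + nd)))
        embeddings.append(H3n1)
    if params.net2 is not None:
        mask2 = (views.A2 + np.eye(views.A2.shape[0])) > 0
        H3n2 = encode_view_t(ad.constant(views.Ahat2), ad.constant(views.F1),
                             params.net2, mask2)
        embeddings.append(H3n2)
    Y = embeddings[0] if len(embeddings) == 1 else ad.concat_cols(*embeddings)
    Yl = ad.slice_rows(Y, 0, nl)
    Yd = ad.slice_rows(Y, nl, nl + nd)
    return bilinear_decode_t(Yl, Yd, params.Wl, params.Wd)


# -- numpy convenience wrappers (same code path, constant tensors) ---------

def gcn_layer(Ahat, X, Wc, B) -> np.ndarray:
    for arr in (Ahat, X, Wc, B):
        if not np.all(np.isfinite(arr)):
            raise ValueError("non-finite input to gcn_layer")
    return gcn_layer_t(ad.constant(Ahat), ad.constant(X), ad.constant(Wc),
                       ad.constant(B)).value


def gat_scores(H, Wt, bt, neighbor_mask) -> np.ndarray:
    return gat_scores_t(ad.constant(H), ad.constant(Wt), ad.constant(bt),
                        np.asarray(neighbor_mask)).value


def gat_layer(H, attention) -> np.ndarray:
    return gat_layer_t(ad.constant(H), ad.constant(attention)).value


def encode_view(Ahat, X0, vp_arrays: dict, neighbor_mask,
                keep: tuple | None = None) -> np.ndarray:
    vp = {k: ad.constant(v) for k, v in vp_arrays.items()}
    return encode_view_t(ad.constant(Ahat), ad.constant(X0), vp,
                         np.asarray(neighbor_mask), keep=keep).value


def concat_embeddings(H3_net1: np.ndarray, H3_net2: np.ndarray, nl: int):
    """Column-wise concatenation split into (Y, Yl, Yd)."""
    if H3_net1.shape[0] != H3_net2.shape[0]:
        raise ValueError(
            f"row mismatch: {H3_net1.shape[0]} vs {H3_net2.shape[0]}")
    Y = np.concatenate([H3_net1, H3_net2], axis=1)
    return Y, Y[:nl], Y[nl:]


def bilinear_decode(Yl, Yd, Wl, Wd) -> np.ndarray:
    Yl, Yd, Wl, Wd = map(np.asarray, (Yl, Yd, Wl, Wd))
    if Yl.shape[1] != Wl.shape[0] or Yd.shape[1] != Wd.shape[0]:
        raise ValueError("embedding width does not match decoder map")
    return bilinear_decode_t(ad.constant(Yl), ad.constant(Yd),
                             ad.constant(Wl), ad.constant(Wd)).value
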