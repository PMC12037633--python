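"""Association tables, configuration, and dataset assembly.

The package consumes two binary association tables: lncRNA-disease (LD,
nl x nd) and lncRNA-miRNA (LM, nl x nm).  Edge lists are two-column TSV
files; dense matrices are labeled CSV.  Identifiers are sorted
lexicographically at load time so every downstream matrix index is
deterministic regardless of file row order.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "AssociationDataset",
    "Config",
    "load_edge_list",
    "load_dense_csv",
    "save_dense_csv",
    "save_edge_list",
    "assemble_dataset",
    "count_candidates",
]


@dataclasses.dataclass(frozen=True)
class AssociationDataset:
    """Validated binary association data over named entities.

    ``LD`` is the lncRNA-disease matrix (nl x nd), ``LM`` the lncRNA-miRNA
    matrix (nl x nm; nm may be 0 when no miRNA layer is available, in which
    case the heterogeneous view degenerates to the association view's node
    set).
    """

    lncrna_ids: tuple
    disease_ids: tuple
    mirna_ids: tuple
    LD: np.ndarray
    LM: np.ndarray

    @property
    def nl(self) -> int:
        return len(self.lncrna_ids)

    @property
    def nd(self) -> int:
        return len(self.disease_ids)

    @property
    def nm(self) -> int:
        return len(self.mirna_ids)


@dataclasses.dataclass
class Config:
    """Hyperparameters for similarity fusion, the encoder, and training.

    Similarity weights (alpha1, alpha2 for lncRNAs; beta1, beta2 for
    diseases) mix the Gaussian interaction profile kernel with cosine
    similarity and default to the published setting 0.1/0.9 and 0.2/0.8.
    ``delta`` is the semantic decay factor of DAG-based disease semantics;
    it is carried for use with a precomputed semantic matrix and unused by
    the default cosine path.
    """

    delta: float = 0.5
    gamma_d: float = 1.0
    gamma_l_prime: float = 1.0
    alpha1: float = 0.1
    alpha2: float = 0.9
    beta1: float = 0.2
    beta2: float = 0.8
    hidden: int = 128          # width of the first GCN layer (and the GAT)
    l1: int = 64               # latent width of the heterogeneous view
    l2: int = 64               # latent width of the association view
    r: int = 32                # decoder projection width
    gamma_reg: float = 1e-4    # weight of the parameter-norm penalty
    learning_rate: float = 0.005
    epochs: int = 400
    seed: int = 0
    classification_threshold: float | None = None  # None -> F1-maximizing
    alpha_mode: str = "complement"  # positive-class weight: "complement" or "prevalence"
    view: str = "both"         # "both", "net1" or "net2"

    def __post_init__(self):
        if abs(self.alpha1 + self.alpha2 - 1.0) > 1e-9:
            warnings.warn("lncRNA similarity fusion weights do not sum to 1",
                          stacklevel=2)
        if abs(self.beta1 + self.beta2 - 1.0) > 1e-9:
            warnings.warn("disease similarity fusion weights do not sum to 1",
                          stacklevel=2)
        for name in ("hidden", "l1", "l2", "r", "epochs"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v > 0):
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        if self.gamma_reg < 0:
            raise ValueError("gamma_reg must be nonnegative")
        if self.alpha_mode not in ("prevalence", "complement"):
            raise ValueError("alpha_mode must be 'prevalence' or 'complement'")
        if self.view not in ("both", "net1", "net2"):
            raise ValueError("view must be 'both', 'net1' or 'net2'")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "Config":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def load_edge_list(path: str | Path):
    """Read a two-column TSV edge list into a binary matrix.

    Returns ``(matrix, row_ids, col_ids)`` with identifiers sorted
    lexicographically; an entry is 1 iff the pair occurs at least once
    (duplicate lines are idempotent).
    """
    path = Path(path)
    edges = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not parts[0].strip() or not parts[1].strip():
                raise ValueError(
                    f"{path}:{lineno}: expected two tab-separated ids, "
                    f"got {line!r}")
            edges.append((parts[0].strip(), parts[1].strip()))
    if not edges:
        raise ValueError(f"{path}: empty edge list")
    row_ids = sorted({r for r, _ in edges})
    col_ids = sorted({c for _, c in edges})
    ri = {r: i for i, r in enumerate(row_ids)}
    ci = {c: i for i, c in enumerate(col_ids)}
    mat = np.zeros((len(row_ids), len(col_ids)))
    for r, c in edges:
        mat[ri[r], ci[c]] = 1.0
    return mat, row_ids, col_ids


def save_edge_list(path: str | Path, matrix: np.ndarray, row_ids, col_ids) -> None:
    with open(path, "w") as fh:
        for i, r in enumerate(row_ids):
            for j, c in enumerate(col_ids):
                if matrix[i, j]:
                    fh.write(f"{r}\t{c}\n")


def load_dense_csv(path: str | Path):
    """Read a labeled dense CSV matrix; returns (values, row_ids, col_ids)."""
    df = pd.read_csv(path, index_col=0)
    return df.to_numpy(dtype=float), list(map(str, df.index)), list(map(str, df.columns))


def save_dense_csv(path: str | Path, matrix: np.ndarray, row_ids, col_ids) -> None:
    pd.DataFrame(matrix, index=list(row_ids), columns=list(col_ids)).to_csv(path)


def _check_binary(mat: np.ndarray, name: str) -> np.ndarray:
    mat = np.asarray(mat, dtype=float)
    bad = ~np.isin(mat, (0.0, 1.0))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(f"{name}[{i},{j}] = {mat[i, j]} is not binary")
    return mat


def assemble_dataset(LD, LM, lncrna_ids, disease_ids, mirna_ids=()) -> AssociationDataset:
    """Validate shapes, identifiers and binarity and build the dataset.

    LD and LM must share the same lncRNA row ordering.
    """
    LD = _check_binary(LD, "LD")
    LM = _check_binary(LM, "LM") if len(mirna_ids) else np.zeros((LD.shape[0], 0))
    for ids, axis_name, n in (
        (lncrna_ids, "lncRNA", LD.shape[0]),
        (disease_ids, "disease", LD.shape[1]),
        (mirna_ids, "miRNA", LM.shape[1]),
    ):
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate {axis_name} identifiers")
        if len(ids) != n:
            raise ValueError(
                f"{axis_name} axis: {len(ids)} identifiers vs matrix size {n}")
    if LM.shape[0] != LD.shape[0]:
        raise ValueError(
            f"lncRNA axis: LD has {LD.shape[0]} rows but LM has {LM.shape[0]}")
    return AssociationDataset(
        lncrna_ids=tuple(lncrna_ids),
        disease_ids=tuple(disease_ids),
        mirna_ids=tuple(mirna_ids),
        LD=LD,
        LM=LM,
    )


def count_candidates(dataset: AssociationDataset) -> int:
    """Number of unknown lncRNA-disease pairs: nl*nd minus known positives."""
    return int(dataset.nl * dataset.nd - dataset.LD.sum())
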