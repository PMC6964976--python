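"""Drug-target interaction datasets.

Reads the Yamanishi gold-standard dialect (tab-delimited matrices with
identifier headers), generates synthetic graph-consistent DTI data, and
reports dataset statistics.

The on-disk interaction files store targets as rows and drugs as columns;
everywhere in memory the convention is rows = drugs, columns = targets,
so the interaction matrix is transposed on load and on write.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "DTIDataset",
    "SyntheticSpec",
    "SyntheticResult",
    "load_yamanishi",
    "write_yamanishi",
    "generate_synthetic",
    "dataset_stats",
]

_SYM_TOL = 1e-10


class DatasetError(ValueError):
    """Raised when input files violate the DTI dataset contract."""


def _check_similarity(S: np.ndarray, k: int, name: str) -> np.ndarray:
    S = np.asarray(S, dtype=float)
    if S.shape != (k, k):
        raise DatasetError(
            f"{name} has shape {S.shape}, expected ({k}, {k}) to match the "
            f"interaction matrix"
        )
    if not np.allclose(S, S.T, atol=_SYM_TOL, rtol=0):
        raise DatasetError(f"{name} is not symmetric (tolerance {_SYM_TOL})")
    if not np.allclose(np.diag(S), 1.0, atol=_SYM_TOL):
        raise DatasetError(f"{name} does not have a unit diagonal")
    return S


@dataclass(frozen=True)
class DTIDataset:
    """A drug-target interaction dataset.

    Attributes
    ----------
    drug_ids, target_ids
        Identifiers, preserved verbatim from the source files.
    interactions
        n_drugs x n_targets binary matrix; 1 marks a known interaction.
    chem_similarity
        n_drugs x n_drugs chemical-structure similarity (e.g. SIMCOMP),
        symmetric with unit diagonal, values in [0, 1].
    seq_similarity
        n_targets x n_targets sequence similarity (e.g. normalized
        Smith-Waterman), symmetric with unit diagonal, values in [0, 1].
    """

    drug_ids: list[str]
    target_ids: list[str]
    interactions: np.ndarray
    chem_similarity: np.ndarray
    seq_similarity: np.ndarray

    def __post_init__(self) -> None:
        n, m = len(self.drug_ids), len(self.target_ids)
        X = np.asarray(self.interactions, dtype=float)
        if X.shape != (n, m):
            raise DatasetError(
                f"interaction matrix has shape {X.shape}, expected ({n}, {m}) "
                f"from the identifier lists"
            )
        if not np.isin(X, (0.0, 1.0)).all():
            bad = X[~np.isin(X, (0.0, 1.0))].flat[0]
            raise DatasetError(f"interaction matrix contains non-binary entry {bad!r}")
        object.__setattr__(self, "interactions", X)
        object.__setattr__(
            self, "chem_similarity",
            _check_similarity(self.chem_similarity, n, "drug similarity matrix"),
        )
        object.__setattr__(
            self, "seq_similarity",
            _check_similarity(self.seq_similarity, m, "target similarity matrix"),
        )

    @property
    def n_drugs(self) -> int:
        return len(self.drug_ids)

    @property
    def n_targets(self) -> int:
        return len(self.target_ids)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic DTI generator.

    The generator draws clustered nonnegative latent factors for drugs and
    targets, forms interaction propensities from their inner products, and
    thresholds at the quantile matching ``interaction_density``.  Side
    similarities are a monotone transform of latent-factor cosine
    similarity, so the similarity graphs genuinely reflect the low-rank
    signal the completion method exploits.
    """

    n_drugs: int = 60
    n_targets: int = 30
    latent_rank: int = 3
    n_drug_clusters: int = 4
    n_target_clusters: int = 3
    interaction_density: float = 0.15
    label_flip_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_drugs, self.n_targets, self.latent_rank,
               self.n_drug_clusters, self.n_target_clusters) < 1:
            raise ValueError("counts must be positive")
        if self.latent_rank > min(self.n_drugs, self.n_targets):
            raise ValueError("latent_rank must not exceed min(n_drugs, n_targets)")
        if not 0.0 < self.interaction_density < 1.0:
            raise ValueError("interaction_density must lie in (0, 1)")
        if not 0.0 <= self.label_flip_rate < 0.5:
            raise ValueError("label_flip_rate must lie in [0, 0.5)")


@dataclass(frozen=True)
class SyntheticResult:
    """Synthetic dataset together with its generating ground truth."""

    dataset: DTIDataset
    probabilities: np.ndarray      # noiseless propensity matrix, rank <= latent_rank
    drug_factors: np.ndarray       # n_drugs x latent_rank
    target_factors: np.ndarray     # n_targets x latent_rank
    diagnostics: dict = field(default_factory=dict)


def _read_matrix(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    df.index = df.index.map(str)
    df.columns = df.columns.map(str)
    return df


def load_yamanishi(
    interaction_path: str | Path,
    drug_sim_path: str | Path,
    target_sim_path: str | Path,
) -> DTIDataset:
    """Load a DTI dataset from Yamanishi-dialect tab-delimited files.

    The interaction file stores targets as rows and drugs as columns; it is
    transposed so rows = drugs internally.  Rows and columns are aligned to
    the similarity files by identifier, not by position; an unmatched
    identifier is an error.
    """
    inter = _read_matrix(interaction_path)
    dsim = _read_matrix(drug_sim_path)
    tsim = _read_matrix(target_sim_path)

    drug_ids = [str(i) for i in dsim.index]
    target_ids = [str(i) for i in tsim.index]
    if list(dsim.columns) != drug_ids:
        raise DatasetError("drug similarity file row/column identifiers disagree")
    if list(tsim.columns) != target_ids:
        raise DatasetError("target similarity file row/column identifiers disagree")

    # distributed orientation: rows = targets, columns = drugs
    missing_d = set(drug_ids) - set(inter.columns)
    missing_t = set(target_ids) - set(inter.index)
    if missing_d or missing_t:
        raise DatasetError(
            f"interaction file is missing drug ids {sorted(missing_d)} / "
            f"target ids {sorted(missing_t)}"
        )
    if inter.shape != (len(target_ids), len(drug_ids)):
        raise DatasetError(
            f"interaction matrix shape {inter.shape} does not match "
            f"{len(target_ids)} targets x {len(drug_ids)} drugs"
        )
    X = inter.loc[target_ids, drug_ids].to_numpy(dtype=float).T
    return DTIDataset(
        drug_ids=drug_ids,
        target_ids=target_ids,
        interactions=X,
        chem_similarity=dsim.to_numpy(dtype=float),
        seq_similarity=tsim.to_numpy(dtype=float),
    )


def _format_matrix(values: np.ndarray, rows: list[str], cols: list[str]) -> str:
    lines = ["\t" + "\t".join(cols)]
    for rid, row in zip(rows, values):
        lines.append(rid + "\t" + "\t".join(format(v, ".17g") for v in row))
    return "\n".join(lines) + "\n"


def write_yamanishi(
    ds: DTIDataset,
    interaction_path: str | Path,
    drug_sim_path: str | Path,
    target_sim_path: str | Path,
) -> None:
    """Write a dataset in the same tab-delimited dialect ``load_yamanishi`` reads.

    The interaction matrix is written targets-as-rows, matching the
    distributed files, so load(write(ds)) round-trips exactly.
    """
    Path(interaction_path).write_text(
        _format_matrix(ds.interactions.T, ds.target_ids, ds.drug_ids)
    )
    Path(drug_sim_path).write_text(
        _format_matrix(ds.chem_similarity, ds.drug_ids, ds.drug_ids)
    )
    Path(target_sim_path).write_text(
        _format_matrix(ds.seq_similarity, ds.target_ids, ds.target_ids)
    )


def _cosine_similarity_matrix(F: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(F, axis=1)
    norms[norms == 0] = 1.0
    S = (F / norms[:, None]) @ (F / norms[:, None]).T
    S = np.clip((S + S.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(S, 1.0)
    return S


def generate_synthetic(spec: SyntheticSpec) -> SyntheticResult:
    """Generate a synthetic graph-consistent DTI dataset.

    Procedure: draw nonnegative cluster centroids, assign drugs/targets to
    clusters, draw latent factors around the centroids, form the propensity
    matrix P = U V^T / max(U V^T) (a positive monotone squashing that keeps
    rank(P) <= latent_rank), set to 1 exactly the round(density * n * m)
    largest entries of P, then flip each label independently with
    ``label_flip_rate``.  Side similarities are latent-factor cosine
    similarities, hence consistent with the low-rank signal.
    """
    rng = np.random.default_rng(spec.seed)
    n, m, r = spec.n_drugs, spec.n_targets, spec.latent_rank

    # nonnegative centroids with distinct magnitudes per cluster
    cd = rng.gamma(shape=2.0, scale=1.0, size=(spec.n_drug_clusters, r))
    ct = rng.gamma(shape=2.0, scale=1.0, size=(spec.n_target_clusters, r))
    drug_cluster = rng.integers(spec.n_drug_clusters, size=n)
    target_cluster = rng.integers(spec.n_target_clusters, size=m)

    # factors: centroid plus within-cluster jitter, clipped to stay nonnegative
    U = np.maximum(cd[drug_cluster] + 0.25 * rng.standard_normal((n, r)), 0.0)
    V = np.maximum(ct[target_cluster] + 0.25 * rng.standard_normal((m, r)), 0.0)

    raw = U @ V.T
    peak = raw.max()
    P = raw / peak if peak > 0 else raw

    k = int(round(spec.interaction_density * n * m))
    order = np.argsort(P, axis=None, kind="stable")[::-1]
    X = np.zeros(n * m)
    X[order[:k]] = 1.0
    X = X.reshape(n, m)

    if spec.label_flip_rate > 0:
        flips = rng.random((n, m)) < spec.label_flip_rate
        X = np.where(flips, 1.0 - X, X)

    ds = DTIDataset(
        drug_ids=[f"D{i:05d}" for i in range(n)],
        target_ids=[f"hsa{j:04d}" for j in range(m)],
        interactions=X,
        chem_similarity=_cosine_similarity_matrix(U),
        seq_similarity=_cosine_similarity_matrix(V),
    )
    diagnostics = {
        "empty_drug_rows": [int(i) for i in np.flatnonzero(X.sum(axis=1) == 0)],
        "empty_target_columns": [int(j) for j in np.flatnonzero(X.sum(axis=0) == 0)],
        "n_ones": int(X.sum()),
    }
    return SyntheticResult(
        dataset=ds,
        probabilities=P,
        drug_factors=U,
        target_factors=V,
        diagnostics=diagnostics,
    )


def dataset_stats(ds: DTIDataset) -> dict:
    """Summary statistics: counts of drugs, targets, interactions, and sparsity."""
    n_ones = int(ds.interactions.sum())
    total = ds.interactions.size
    return {
        "n_drugs": ds.n_drugs,
        "n_targets": ds.n_targets,
        "n_interactions": n_ones,
        "sparsity": n_ones / total if total else 0.0,
    }
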