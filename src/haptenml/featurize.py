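"""Molecular descriptors and sensitivity-analysis feature selection.

Descriptors are computed through a pluggable provider so the pipeline can
run either from chemistry (the RDKit 2D descriptor set) or from a
precomputed matrix on disk.  Feature selection mirrors the classic WEKA
attribute evaluators: absolute Pearson correlation with the class,
information gain / gain ratio after equal-frequency discretization, and
correlation-based feature subset selection (CFS) by greedy best-first
forward search on the merit

    Merit(S) = k * r_cf / sqrt(k + k (k - 1) * r_ff)

where ``r_cf`` is the mean absolute feature–class correlation over the
subset S of size k and ``r_ff`` the mean absolute pairwise feature–feature
correlation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Protocol, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "DescriptorMatrix",
    "FeatureRanking",
    "DescriptorProvider",
    "RDKit2DProvider",
    "FileProvider",
    "compute_descriptors",
    "rank_correlation",
    "rank_info_gain",
    "select_cfs",
    "cfs_merit",
    "make_input_vector",
    "impute_median",
]


@dataclass
class DescriptorMatrix:
    """Haptens × named numeric descriptors.

    Missing values are ``NaN``; everything else must be finite.
    """

    row_ids: List[str]
    descriptor_names: List[str]
    values: np.ndarray
    provider_id: str = "unknown"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if self.values.shape != (len(self.row_ids), len(self.descriptor_names)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.row_ids)} rows x {len(self.descriptor_names)} descriptors"
            )
        if len(set(self.row_ids)) != len(self.row_ids):
            raise ValueError("duplicate row ids")
        if len(set(self.descriptor_names)) != len(self.descriptor_names):
            raise ValueError("duplicate descriptor names")
        with np.errstate(invalid="ignore"):
            if np.isinf(self.values).any():
                raise ValueError("non-finite (inf) descriptor values")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.row_ids, columns=self.descriptor_names
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, provider_id: str = "frame") -> "DescriptorMatrix":
        return cls(
            row_ids=[str(i) for i in frame.index],
            descriptor_names=[str(c) for c in frame.columns],
            values=frame.to_numpy(dtype=float),
            provider_id=provider_id,
        )

    def to_csv(self, path: Union[str, Path]) -> None:
        self.to_frame().to_csv(path, index_label="row_id")

    @classmethod
    def from_csv(cls, path: Union[str, Path], provider_id: Optional[str] = None) -> "DescriptorMatrix":
        frame = pd.read_csv(path, index_col=0)
        return cls.from_frame(frame, provider_id=provider_id or f"csv:{Path(path).name}")


@dataclass
class FeatureRanking:
    """Descriptors ordered by a selection score (descending).

    Ties are broken lexicographically by descriptor name so rankings are
    reproducible across runs and platforms.
    """

    method: str
    scores: Dict[str, float]
    order: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.order:
            self.order = sorted(self.scores, key=lambda n: (-self.scores[n], n))

    def top(self, k: int) -> List[str]:
        return self.order[:k]


class DescriptorProvider(Protocol):
    """Anything that turns SMILES into a fixed-length descriptor vector."""

    provider_id: str
    descriptor_names: List[str]

    def compute(self, smiles: str) -> np.ndarray: ...


class RDKit2DProvider:
    """2D physicochemical/topological descriptors from RDKit.

    Covers constitutional, topological, electrotopological and
    surface-area descriptors (~210 columns).  Values are deterministic
    for a fixed RDKit version, which is recorded in ``provider_id``.
    """

    def __init__(self) -> None:
        import rdkit
        from rdkit.Chem import Descriptors

        self._descriptors = list(Descriptors.CalcMolDescriptors.__globals__["_descList"])
        self.descriptor_names = [name for name, _ in self._descriptors]
        self.provider_id = f"rdkit2d:{rdkit.__version__}"

    def compute(self, smiles: str) -> np.ndarray:
        from rdkit import Chem

        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise ValueError(f"unparseable SMILES: {smiles!r}")
        out = np.empty(len(self._descriptors), dtype=float)
        for i, (_, fn) in enumerate(self._descriptors):
            try:
                out[i] = float(fn(mol))
            except Exception:  # a few descriptors fail on exotic atoms
                out[i] = np.nan
        return out


class FileProvider:
    """Serve descriptor rows from a precomputed matrix, keyed by row id.

    Enables bit-exact, chemistry-free tests and reuse of externally
    computed descriptor tables.
    """

    def __init__(self, matrix: DescriptorMatrix):
        self._matrix = matrix
        self._index = {rid: i for i, rid in enumerate(matrix.row_ids)}
        self.descriptor_names = list(matrix.descriptor_names)
        self.provider_id = f"file:{matrix.provider_id}"

    def compute(self, key: str) -> np.ndarray:
        if key not in self._index:
            raise ValueError(
                f"row {key!r} not in the precomputed matrix; recompute the "
                "fixture or switch to a chemistry provider"
            )
        return self._matrix.values[self._index[key]].copy()


def compute_descriptors(
    smiles_list: Sequence[str],
    provider: DescriptorProvider,
    row_ids: Optional[Sequence[str]] = None,
) -> DescriptorMatrix:
    """One descriptor row per input structure.

    ``row_ids`` default to the SMILES strings themselves; pass hapten
    names to get a matrix the dataset module can align by name.
    """
    if row_ids is None:
        row_ids = list(smiles_list)
    if len(row_ids) != len(smiles_list):
        raise ValueError("row_ids length does not match smiles_list")
    rows = [provider.compute(s) for s in smiles_list]
    values = np.vstack(rows) if rows else np.empty((0, len(provider.descriptor_names)))
    return DescriptorMatrix(
        row_ids=list(row_ids),
        descriptor_names=list(provider.descriptor_names),
        values=values,
        provider_id=provider.provider_id,
    )


def _check_ranking_input(values: np.ndarray, labels: np.ndarray) -> None:
    if values.shape[0] < 3:
        raise ValueError("need at least 3 rows to rank descriptors")
    if len(np.unique(labels)) < 2:
        raise ValueError("labels are constant; ranking is undefined")


def _abs_pearson(col: np.ndarray, y: np.ndarray) -> float:
    sx = col.std()
    sy = y.std()
    if sx == 0 or sy == 0:
        return 0.0
    r = float(np.corrcoef(col, y)[0, 1])
    return abs(r) if math.isfinite(r) else 0.0


def rank_correlation(matrix: DescriptorMatrix, labels: Sequence[int]) -> FeatureRanking:
    """Score each descriptor by |Pearson r| with the 0/1 class.

    Constant columns score 0.
    """
    y = np.asarray(labels, dtype=float)
    _check_ranking_input(matrix.values, y)
    scores = {
        name: _abs_pearson(matrix.values[:, j], y)
        for j, name in enumerate(matrix.descriptor_names)
    }
    return FeatureRanking(method="correlation", scores=scores)


def _entropy_bits(counts: np.ndarray) -> float:
    total = counts.sum()
    if total == 0:
        return 0.0
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def equal_frequency_bins(col: np.ndarray, n_bins: int) -> np.ndarray:
    """Assign each value to an equal-frequency bin (ties share a bin)."""
    qs = np.quantile(col, np.linspace(0, 1, n_bins + 1)[1:-1])
    return np.searchsorted(qs, col, side="left")


def rank_info_gain(
    matrix: DescriptorMatrix,
    labels: Sequence[int],
    n_bins: int = 10,
    gain_ratio: bool = False,
) -> FeatureRanking:
    """Information gain (bits) of each descriptor after discretization.

    Columns are cut into ``n_bins`` equal-frequency bins and scored by
    ``IG = H(Y) − H(Y | bin)``.  With ``gain_ratio=True`` the score is
    divided by the bin entropy ``H(bin)`` (defined as 0 when the column
    lands in a single bin).
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    y = np.asarray(labels, dtype=int)
    _check_ranking_input(matrix.values, y)
    classes = np.unique(y)
    h_y = _entropy_bits(np.array([(y == c).sum() for c in classes]))

    scores: Dict[str, float] = {}
    for j, name in enumerate(matrix.descriptor_names):
        bins = equal_frequency_bins(matrix.values[:, j], n_bins)
        uniq = np.unique(bins)
        n = len(y)
        h_cond = 0.0
        bin_counts = []
        for b in uniq:
            mask = bins == b
            bin_counts.append(mask.sum())
            h_cond += (mask.sum() / n) * _entropy_bits(
                np.array([(y[mask] == c).sum() for c in classes])
            )
        ig = h_y - h_cond
        if gain_ratio:
            h_bin = _entropy_bits(np.array(bin_counts))
            ig = ig / h_bin if h_bin > 0 else 0.0
        scores[name] = max(ig, 0.0)
    return FeatureRanking(method="gain_ratio" if gain_ratio else "info_gain", scores=scores)


def cfs_merit(
    subset: Sequence[int], corr_cf: np.ndarray, corr_ff: np.ndarray
) -> float:
    """CFS merit of a feature subset given precomputed |correlations|."""
    k = len(subset)
    if k == 0:
        return 0.0
    idx = list(subset)
    r_cf = float(corr_cf[idx].mean())
    if k == 1:
        r_ff = 0.0
    else:
        sub = corr_ff[np.ix_(idx, idx)]
        r_ff = float((sub.sum() - np.trace(sub)) / (k * (k - 1)))
    denom = math.sqrt(k + k * (k - 1) * r_ff)
    return k * r_cf / denom if denom > 0 else 0.0


def select_cfs(
    matrix: DescriptorMatrix,
    labels: Sequence[int],
    max_evals: int = 10_000,
    patience: int = 5,
) -> List[str]:
    """Correlation-based feature subset selection (best-first forward).

    Starting from the empty set, the search keeps a frontier of scored
    subsets, always expands the most meritorious one by each single
    feature addition, and remembers the best subset seen anywhere.  The
    search stops after ``patience`` consecutive expansions that fail to
    improve the best merit, or after ``max_evals`` merit evaluations.
    On small feature spaces the frontier covers the subset lattice, so
    the result coincides with exhaustive merit maximization.
    """
    y = np.asarray(labels, dtype=float)
    names = matrix.descriptor_names
    d = len(names)
    if d < 2:
        raise ValueError("need at least 2 candidate descriptors")
    X = matrix.values
    corr_cf = np.array([_abs_pearson(X[:, j], y) for j in range(d)])
    corr_ff = np.zeros((d, d))
    for a in range(d):
        for b in range(a + 1, d):
            # constant columns contribute zero correlation
            if X[:, a].std() > 0 and X[:, b].std() > 0:
                r = abs(float(np.corrcoef(X[:, a], X[:, b])[0, 1]))
            else:
                r = 0.0
            corr_ff[a, b] = corr_ff[b, a] = r

    import heapq

    best_subset: tuple = ()
    best_merit = 0.0
    evals = 0
    stale = 0
    frontier = [(-0.0, ())]  # (-merit, sorted index tuple)
    scored = {()}
    expanded = set()
    while frontier and stale < patience and evals < max_evals:
        _, subset = heapq.heappop(frontier)
        if subset in expanded:
            continue
        expanded.add(subset)
        improved = False
        for j in range(d):
            if j in subset:
                continue
            child = tuple(sorted(subset + (j,)))
            if child in scored:
                continue
            scored.add(child)
            merit = cfs_merit(list(child), corr_cf, corr_ff)
            evals += 1
            heapq.heappush(frontier, (-merit, child))
            if merit > best_merit + 1e-12:
                best_merit = merit
                best_subset = child
                improved = True
        stale = 0 if improved else stale + 1
    return [names[j] for j in sorted(best_subset, key=lambda j: (-corr_cf[j], names[j]))]


def make_input_vector(
    ranking: Union[FeatureRanking, Sequence[str]], size: int
) -> List[str]:
    """Top-``size`` descriptor names from a ranking, order preserved.

    A plain name list (e.g. a CFS subset, optionally padded upstream) is
    accepted in place of a ranking.
    """
    order = ranking.order if isinstance(ranking, FeatureRanking) else list(ranking)
    if size <= 0:
        raise ValueError("input vector size must be positive")
    if size > len(order):
        raise ValueError(f"requested {size} descriptors, only {len(order)} ranked")
    return order[:size]


def impute_median(
    train: np.ndarray, test: Optional[np.ndarray] = None
) -> tuple:
    """Column-median imputation fitted on the training partition only.

    Returns the imputed train matrix and, if given, the test matrix
    imputed with the *training* medians (no leakage across CV folds).
    """
    train = np.array(train, dtype=float, copy=True)
    with np.errstate(all="ignore"):
        med = np.nanmedian(train, axis=0)
    med = np.where(np.isnan(med), 0.0, med)
    idx = np.where(np.isnan(train))
    train[idx] = med[idx[1]]
    if test is None:
        return train, None
    test = np.array(test, dtype=float, copy=True)
    idx = np.where(np.isnan(test))
    test[idx] = med[idx[1]]
    return train, test
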