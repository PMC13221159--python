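"""Block orthogonalization and fusion.

The acoustic block is residualized on the linguistic block: a least-squares
map from centered linguistic columns to centered acoustic columns is fitted
on training rows only, and the acoustic block is replaced by its residual —
the component orthogonal to the linguistic column space.  Held-out rows are
transformed with the training-fitted coefficients (no refit), so exact
orthogonality is guaranteed on training rows only.  The two blocks are then
concatenated for classification.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .blocks import BlockSet, FeatureBlock
from .linguistic import KeywordLexicon, PCAReducer, TermMatrix, apply_pca, fit_pca, screen_keywords

logger = logging.getLogger(__name__)

__all__ = [
    "Orthogonalizer",
    "fit_orthogonalizer",
    "apply_orthogonalizer",
    "fuse",
    "Standardizer",
    "FeaturePipeline",
    "FittedPipeline",
    "SETTINGS",
]

SETTINGS = ("combined_ortho", "combined_raw", "linguistic", "acoustic")


@dataclass
class Orthogonalizer:
    """Training-set projection of the acoustic block off the linguistic block.

    ``coefficients[j, k]`` predicts centered acoustic column ``k`` from
    centered linguistic column ``j``; the solve uses a rank-tolerant
    pseudo-inverse with singular-value cutoff ``tolerance`` relative to
    the largest singular value, since a wide linguistic basis on few
    training rows can be near-collinear.
    """

    basis_means: np.ndarray
    acoustic_means: np.ndarray
    coefficients: np.ndarray
    tolerance: float = 1e-10


def fit_orthogonalizer(
    L_train: FeatureBlock, A_train: FeatureBlock, tolerance: float = 1e-10
) -> Orthogonalizer:
    """Fit the least-squares map from linguistic to acoustic columns."""
    if L_train.n_participants != A_train.n_participants:
        raise ValueError("linguistic and acoustic training blocks differ in rows")
    if L_train.n_participants == 0:
        raise ValueError("zero training rows")
    l_means = L_train.values.mean(axis=0)
    a_means = A_train.values.mean(axis=0)
    Lc = L_train.values - l_means
    Ac = A_train.values - a_means
    coef, *_ = np.linalg.lstsq(Lc, Ac, rcond=tolerance)
    return Orthogonalizer(l_means, a_means, coef, tolerance)


def apply_orthogonalizer(
    ortho: Orthogonalizer, A: FeatureBlock, L: FeatureBlock
) -> FeatureBlock:
    """Residualize: centered A minus the linguistic prediction.

    Idempotent; on the training pair every returned column has zero inner
    product with every centered linguistic column.
    """
    if L.n_features != ortho.basis_means.size:
        raise ValueError("linguistic block does not match fitted basis dimension")
    if A.n_features != ortho.acoustic_means.size:
        raise ValueError("acoustic block does not match fitted dimension")
    if A.n_participants != L.n_participants:
        raise ValueError("blocks differ in rows")
    residual = (A.values - ortho.acoustic_means) - (L.values - ortho.basis_means) @ ortho.coefficients
    return FeatureBlock(residual, list(A.feature_names), list(A.participant_ids), "acoustic")


def fuse(L: FeatureBlock, A_perp: FeatureBlock) -> FeatureBlock:
    """Column-wise concatenation with block-tag-prefixed names."""
    if L.participant_ids != A_perp.participant_ids:
        raise ValueError("cannot fuse blocks with misaligned participant ids")
    names = [f"{L.block_tag}__{n}" for n in L.feature_names]
    names += [f"{A_perp.block_tag}__{n}" for n in A_perp.feature_names]
    values = np.hstack([L.values, A_perp.values]) if A_perp.n_features else L.values.copy()
    return FeatureBlock(values, names, list(L.participant_ids), "fused")


@dataclass
class Standardizer:
    """Per-column training mean/SD scaling; zero-SD columns pass through."""

    means: np.ndarray
    sds: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "Standardizer":
        means = X.mean(axis=0)
        sds = X.std(axis=0)
        sds = np.where(sds < 1e-12, 1.0, sds)
        return cls(means, sds)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.means) / self.sds


# ---------------------------------------------------------------------------
# Fold-level preprocessing pipeline


@dataclass
class FittedPipeline:
    """Preprocessing state fitted on one training fold."""

    setting: str
    kept_terms: list[str] | None
    kept_indices: np.ndarray | None
    reducer: PCAReducer | None
    orthogonalizer: Orthogonalizer | None
    standardizer: Standardizer | None
    feature_names: list[str]
    ortho_basis: str = "pca"

    def transform(self, blocks: BlockSet, rows: np.ndarray | None = None) -> np.ndarray:
        """Build the design matrix for the given rows with training-fold state."""
        L = blocks.linguistic if rows is None else blocks.linguistic.take_rows(rows)
        A = None
        if blocks.acoustic is not None:
            A = blocks.acoustic if rows is None else blocks.acoustic.take_rows(rows)

        parts = []
        L_scores = None
        if self.setting != "acoustic":
            if self.kept_indices is not None:
                L = FeatureBlock(
                    L.values[:, self.kept_indices],
                    [L.feature_names[j] for j in self.kept_indices],
                    list(L.participant_ids),
                    "linguistic",
                )
            L_scores = apply_pca(self.reducer, L) if self.reducer is not None else L
            if self.setting in ("linguistic", "combined_ortho", "combined_raw"):
                parts.append(L_scores.values)
        if self.setting in ("acoustic", "combined_ortho", "combined_raw"):
            if A is None:
                raise ValueError(f"setting {self.setting!r} needs an acoustic block")
            if self.setting == "combined_ortho":
                basis = L_scores if self.ortho_basis == "pca" else L
                A = apply_orthogonalizer(self.orthogonalizer, A, basis)
            parts.append(A.values)
        X = np.hstack(parts)
        return self.standardizer.transform(X) if self.standardizer is not None else X


@dataclass
class FeaturePipeline:
    """Declarative description of the per-fold preprocessing.

    ``setting`` selects which blocks feed the classifier: ``linguistic``,
    ``acoustic``, ``combined_raw`` (fusion without orthogonalization) or
    ``combined_ortho`` (acoustic residualized on the PCA-reduced
    linguistic scores before fusion).  Screening, PCA, the orthogonalizer
    and the standardizer are all fitted on training rows only.

    ``screen`` controls keyword screening scope: ``"fold"`` re-screens on
    each training fold, ``"fixed"`` expects the caller to have screened
    the corpus once upstream, ``"off"`` disables screening.  ``ortho_basis``
    chooses whether residualization uses the PCA scores (default, a
    well-conditioned basis) or the raw screened counts.
    """

    setting: str = "combined_ortho"
    variance_fraction: float = 0.95
    standardize: bool = True
    lexicon: KeywordLexicon | None = None
    screen: str = "fold"
    min_total: int = 2
    ortho_basis: str = "pca"
    tolerance: float = 1e-10

    def __post_init__(self) -> None:
        if self.setting not in SETTINGS:
            raise ValueError(f"unknown setting {self.setting!r}; choose from {SETTINGS}")
        if self.screen not in ("fold", "fixed", "off"):
            raise ValueError("screen must be 'fold', 'fixed' or 'off'")
        if self.ortho_basis not in ("pca", "raw"):
            raise ValueError("ortho_basis must be 'pca' or 'raw'")

    def fit(self, blocks: BlockSet, train_rows: np.ndarray) -> FittedPipeline:
        train_rows = np.asarray(train_rows, dtype=int)
        L_train = blocks.linguistic.take_rows(train_rows)
        A_train = blocks.acoustic.take_rows(train_rows) if blocks.acoustic is not None else None

        kept_terms = kept_idx = None
        reducer = None
        ortho = None
        L_scores_train = None

        if self.setting != "acoustic":
            if self.screen == "fold" and self.lexicon is not None:
                tm = TermMatrix(
                    L_train.values.astype(int), list(L_train.feature_names), list(L_train.participant_ids)
                )
                kept_terms = screen_keywords(tm, self.lexicon, self.min_total)
                if not kept_terms:
                    raise ValueError("screening removed every keyword in this training fold")
                index = {t: j for j, t in enumerate(L_train.feature_names)}
                kept_idx = np.array([index[t] for t in kept_terms], dtype=int)
                L_train = FeatureBlock(
                    L_train.values[:, kept_idx], kept_terms, list(L_train.participant_ids), "linguistic"
                )
            reducer = fit_pca(L_train, self.variance_fraction)
            L_scores_train = apply_pca(reducer, L_train)

        if self.setting == "combined_ortho":
            basis = L_scores_train if self.ortho_basis == "pca" else L_train
            ortho = fit_orthogonalizer(basis, A_train, self.tolerance)
            A_train = apply_orthogonalizer(ortho, A_train, basis)

        parts, names = [], []
        if self.setting in ("linguistic", "combined_ortho", "combined_raw"):
            parts.append(L_scores_train.values)
            names += [f"linguistic__{n}" for n in L_scores_train.feature_names]
        if self.setting in ("acoustic", "combined_ortho", "combined_raw"):
            parts.append(A_train.values)
            names += [f"acoustic__{n}" for n in A_train.feature_names]
        X_train = np.hstack(parts)
        standardizer = Standardizer.fit(X_train) if self.standardize else None

        return FittedPipeline(
            setting=self.setting,
            kept_terms=kept_terms,
            kept_indices=kept_idx,
            reducer=reducer,
            orthogonalizer=ortho,
            standardizer=standardizer,
            feature_names=names,
            ortho_basis=self.ortho_basis,
        )


def write_fused(block: FeatureBlock, fitted: FittedPipeline, directory) -> None:
    """Persist a fused block with a JSON sidecar for exact reapplication."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    block.write_csv(d / "fused.csv")
    sidecar = {
        "setting": fitted.setting,
        "kept_terms": fitted.kept_terms,
        "tolerance": fitted.orthogonalizer.tolerance if fitted.orthogonalizer else None,
        "basis_means": fitted.orthogonalizer.basis_means.tolist() if fitted.orthogonalizer else None,
        "n_linguistic_components": fitted.reducer.retained if fitted.reducer else None,
    }
    (d / "fused.json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))
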