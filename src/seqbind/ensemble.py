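"""Hybrid regressor: embedding network -> PCA condensation -> RF + XGBoost.

The trained embedding network maps every complex to a 256-d vector; PCA
condenses those embeddings (default 32 components), and the condensed
embedding is concatenated with the raw ligand descriptor and protein feature
catalogs.  A Random Forest and an XGBoost regressor are fit on that matrix
and their predictions are averaged for the final pK estimate.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict

import joblib
import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold
from sklearn.utils.validation import check_is_fitted
from xgboost import XGBRegressor

from . import tpe
from .featurization import (EncodedDataset, LIGAND_SCHEMA, PROTEIN_SCHEMA,
                            GRAPH_FEATURE_NAMES, DESCRIPTOR_SCHEMA)
from .network import EmbeddingNetwork, NetworkConfig


@dataclass(frozen=True)
class HyperparameterSpace:
    """Closed search intervals for the tree heads (TPE objective = CV PCC)."""
    rf_n_estimators: tuple[int, int] = (50, 500)
    rf_max_depth: tuple[int, int] = (5, 50)
    xgb_n_estimators: tuple[int, int] = (50, 500)
    xgb_max_depth: tuple[int, int] = (3, 15)
    xgb_learning_rate: tuple[float, float] = (0.01, 0.2)  # log-scaled
    xgb_subsample: tuple[float, float] = (0.6, 1.0)
    max_evals: int = 10

    def dimensions(self) -> list[tpe.Dimension]:
        return [
            tpe.Dimension("rf_n_estimators", *self.rf_n_estimators, is_int=True),
            tpe.Dimension("rf_max_depth", *self.rf_max_depth, is_int=True),
            tpe.Dimension("xgb_n_estimators", *self.xgb_n_estimators, is_int=True),
            tpe.Dimension("xgb_max_depth", *self.xgb_max_depth, is_int=True),
            tpe.Dimension("xgb_learning_rate", *self.xgb_learning_rate, log=True),
            tpe.Dimension("xgb_subsample", *self.xgb_subsample),
        ]

    def midpoints(self) -> dict:
        """Defaults used when tuning is skipped: interval midpoints
        (geometric for the log-scaled learning rate)."""
        return {
            "rf_n_estimators": sum(self.rf_n_estimators) // 2,
            "rf_max_depth": sum(self.rf_max_depth) // 2,
            "xgb_n_estimators": sum(self.xgb_n_estimators) // 2,
            "xgb_max_depth": sum(self.xgb_max_depth) // 2,
            "xgb_learning_rate": float(np.sqrt(np.prod(self.xgb_learning_rate))),
            "xgb_subsample": float(np.mean(self.xgb_subsample)),
        }


class TreeEnsembleRegressor(BaseEstimator, RegressorMixin):
    """RF + XGBoost pair whose predictions are averaged.

    A plain sklearn estimator over a 2-D feature matrix; used both as the
    head of :class:`AffinityModel` and as the objective model during tuning.
    """

    def __init__(self, rf_n_estimators=275, rf_max_depth=27, xgb_n_estimators=275,
                 xgb_max_depth=9, xgb_learning_rate=0.0447, xgb_subsample=0.8,
                 random_state=0):
        self.rf_n_estimators = rf_n_estimators
        self.rf_max_depth = rf_max_depth
        self.xgb_n_estimators = xgb_n_estimators
        self.xgb_max_depth = xgb_max_depth
        self.xgb_learning_rate = xgb_learning_rate
        self.xgb_subsample = xgb_subsample
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        self.rf_ = RandomForestRegressor(
            n_estimators=int(self.rf_n_estimators), max_depth=int(self.rf_max_depth),
            random_state=self.random_state, n_jobs=1).fit(X, y)
        self.xgb_ = XGBRegressor(
            n_estimators=int(self.xgb_n_estimators), max_depth=int(self.xgb_max_depth),
            learning_rate=float(self.xgb_learning_rate),
            subsample=float(self.xgb_subsample),
            random_state=self.random_state, n_jobs=1, verbosity=0).fit(X, y)
        self.n_features_in_ = X.shape[1]
        return self

    def predict_components(self, X) -> tuple[np.ndarray, np.ndarray]:
        check_is_fitted(self, "rf_")
        X = np.asarray(X, dtype=float)
        return self.rf_.predict(X), self.xgb_.predict(X)

    def predict(self, X) -> np.ndarray:
        rf_pred, xgb_pred = self.predict_components(X)
        return 0.5 * (rf_pred + xgb_pred)


class AffinityModel(BaseEstimator, RegressorMixin):
    """Full trained ensemble over encoded complexes (network + PCA + trees).

    Fitted attributes: ``network_`` (trained embedding stack), ``embed_pca_``,
    ``trees_``, the structural standardization stats ``lig_stats_`` /
    ``prot_stats_`` and a ``schema_hash_`` that ``predict`` verifies.
    """

    MIN_TRAIN_ROWS = 20

    def __init__(self, network_config: NetworkConfig | None = None,
                 tree_params: dict | None = None, condensed_dim: int | None = None,
                 random_state: int = 0):
        self.network_config = network_config
        self.tree_params = tree_params
        self.condensed_dim = condensed_dim
        self.random_state = random_state

    def _schema_hash(self) -> str:
        payload = json.dumps([GRAPH_FEATURE_NAMES, DESCRIPTOR_SCHEMA,
                              PROTEIN_SCHEMA]).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def fit(self, dataset: EncodedDataset, y) -> "AffinityModel":
        y = np.asarray(y, dtype=float)
        if len(dataset) < self.MIN_TRAIN_ROWS:
            raise ValueError(f"need at least {self.MIN_TRAIN_ROWS} training rows, "
                             f"got {len(dataset)}")
        cfg = self.network_config or NetworkConfig(seed=self.random_state)
        n_condensed = self.condensed_dim or cfg.condensed_dim
        n_condensed = min(n_condensed, len(dataset), cfg.fc_dim)

        # per-channel standardization of the structural vectors (train stats)
        self.lig_stats_ = (dataset.ligand_struct.mean(axis=0),
                           dataset.ligand_struct.std(axis=0))
        self.prot_stats_ = (dataset.protein_struct.mean(axis=0),
                            dataset.protein_struct.std(axis=0))
        std_ds = self._standardize(dataset)

        self.network_ = EmbeddingNetwork(cfg).fit(std_ds, y)
        embeddings = self.network_.embed(std_ds)
        self.embed_pca_ = PCA(n_components=n_condensed, svd_solver="full",
                              random_state=self.random_state).fit(embeddings)
        features = self._tree_features(std_ds, embeddings)
        params = dict(self.tree_params or HyperparameterSpace().midpoints())
        self.trees_ = TreeEnsembleRegressor(random_state=self.random_state,
                                            **params).fit(features, y)
        self.schema_hash_ = self._schema_hash()
        self.n_train_ = len(dataset)
        return self

    def _standardize(self, dataset: EncodedDataset) -> EncodedDataset:
        lig_mean, lig_std = self.lig_stats_
        prot_mean, prot_std = self.prot_stats_
        return EncodedDataset(
            complex_ids=dataset.complex_ids,
            ligand_onehot=dataset.ligand_onehot,
            protein_onehot=dataset.protein_onehot,
            ligand_struct=(dataset.ligand_struct - lig_mean)
            / np.where(lig_std > 0, lig_std, 1.0),
            protein_struct=(dataset.protein_struct - prot_mean)
            / np.where(prot_std > 0, prot_std, 1.0),
            n_tokens=dataset.n_tokens,
            n_residues=dataset.n_residues,
        )

    def _tree_features(self, std_ds: EncodedDataset, embeddings: np.ndarray) -> np.ndarray:
        condensed = self.embed_pca_.transform(embeddings)
        lig_catalog = std_ds.ligand_struct[:, :len(LIGAND_SCHEMA)]
        prot_catalog = std_ds.protein_struct[:, :len(PROTEIN_SCHEMA)]
        return np.hstack([condensed, lig_catalog, prot_catalog])

    def predict(self, dataset: EncodedDataset) -> np.ndarray:
        check_is_fitted(self, "trees_")
        if self._schema_hash() != self.schema_hash_:
            raise ValueError("feature schema hash mismatch: model was fit under a "
                             "different schema")
        std_ds = self._standardize(dataset)
        embeddings = self.network_.embed(std_ds)
        return self.trees_.predict(self._tree_features(std_ds, embeddings))

    def predict_components(self, dataset: EncodedDataset) -> tuple[np.ndarray, np.ndarray]:
        check_is_fitted(self, "trees_")
        std_ds = self._standardize(dataset)
        embeddings = self.network_.embed(std_ds)
        return self.trees_.predict_components(self._tree_features(std_ds, embeddings))

    # -- persistence --------------------------------------------------------
    def save(self, path) -> None:
        check_is_fitted(self, "trees_")
        artifact = {
            "network_state": self.network_.state_dict(),
            "embed_pca": self.embed_pca_,
            "trees": self.trees_,
            "lig_stats": self.lig_stats_,
            "prot_stats": self.prot_stats_,
            "schema_hash": self.schema_hash_,
            "params": self.get_params(deep=False),
            "n_train": self.n_train_,
        }
        manifest = {k: hashlib.sha256(repr(v).encode()).hexdigest()[:12]
                    for k, v in artifact.items()}
        joblib.dump({"artifact": artifact, "manifest": manifest}, path)

    @classmethod
    def load(cls, path) -> "AffinityModel":
        payload = joblib.load(path)
        artifact = payload["artifact"]
        model = cls(**artifact["params"])
        model.network_ = EmbeddingNetwork.from_state_dict(artifact["network_state"])
        model.embed_pca_ = artifact["embed_pca"]
        model.trees_ = artifact["trees"]
        model.lig_stats_ = artifact["lig_stats"]
        model.prot_stats_ = artifact["prot_stats"]
        model.schema_hash_ = artifact["schema_hash"]
        model.n_train_ = artifact["n_train"]
        return model


def train(dataset: EncodedDataset, y, network_config: NetworkConfig | None = None,
          tree_params: dict | None = None, random_state: int = 0) -> AffinityModel:
    """Functional wrapper around :meth:`AffinityModel.fit`."""
    return AffinityModel(network_config=network_config, tree_params=tree_params,
                         random_state=random_state).fit(dataset, y)


def tune(X, y, space: HyperparameterSpace | None = None, k: int = 10,
         seed: int = 0) -> tuple[dict, list[tpe.Trial]]:
    """TPE search over the tree-head hyperparameters.

    The objective is the mean k-fold cross-validated Pearson correlation of
    the averaged RF/XGBoost prediction on the supplied feature matrix (the
    condensed embeddings plus catalogs produced by :class:`AffinityModel`),
    maximized; at most ``space.max_evals`` trials are run and a crashed trial
    scores worst without stopping the search.
    """
    from scipy.stats import pearsonr

    space = space or HyperparameterSpace()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(y) < k:
        raise ValueError(f"dataset of {len(y)} rows does not admit {k}-fold splitting")
    splits = list(KFold(n_splits=k, shuffle=True, random_state=seed).split(X))

    def objective(params):
        pccs = []
        for train_idx, test_idx in splits:
            model = TreeEnsembleRegressor(random_state=seed, **params)
            model.fit(X[train_idx], y[train_idx])
            pred = model.predict(X[test_idx])
            if pred.std() == 0 or y[test_idx].std() == 0:
                continue
            pccs.append(pearsonr(y[test_idx], pred).statistic)
        if not pccs:
            return float("inf")
        return -float(np.mean(pccs))  # TPE minimizes

    best, trials = tpe.minimize(objective, space.dimensions(),
                                max_evals=space.max_evals, seed=seed)
    return best, trials
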