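"""End-to-end orchestration over complex records.

``AffinityPipeline`` ties the stages together: featurize every complex into
the fixed-shape encoding, project the numeric catalog onto its first two
principal components, drop training rows whose affinity deviates more than
3 residual standard deviations from the PC trendline, and fit the hybrid
network + RF/XGBoost ensemble on what remains.  Outlier filtering only ever
touches training data; prediction paths are unfiltered.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from . import evaluation
from .ensemble import AffinityModel, HyperparameterSpace
from .featurization import EncodedDataset, encode_complex, feature_matrix, stack_encoded
from .network import NetworkConfig
from .preprocessing import OutlierReport, ResidualOutlierFilter, StandardizedPCA


class AffinityPipeline(BaseEstimator):
    """featurize -> PCA/outlier filter -> train ensemble, over complex records.

    Parameters mirror the stage knobs; ``seed`` drives every source of
    randomness (network init and shuffling, tree seeds).
    """

    def __init__(self, network_config: NetworkConfig | None = None,
                 tree_params: dict | None = None, z_threshold: float = 3.0,
                 pca_components: int = 2, filter_outliers: bool = True,
                 seed: int = 0):
        self.network_config = network_config
        self.tree_params = tree_params
        self.z_threshold = z_threshold
        self.pca_components = pca_components
        self.filter_outliers = filter_outliers
        self.seed = seed

    # records may be ComplexRecord lists or a pre-encoded dataset
    @staticmethod
    def _encode(records) -> EncodedDataset:
        if isinstance(records, EncodedDataset):
            return records
        return stack_encoded([encode_complex(r) for r in records])

    def fit(self, records, y=None) -> "AffinityPipeline":
        dataset = self._encode(records)
        if y is None:
            y = np.array([r.affinity.pK for r in records])
        y = np.asarray(y, dtype=float)

        if self.filter_outliers:
            X, _ = feature_matrix(dataset)
            self.pca_ = StandardizedPCA(n_components=self.pca_components).fit(X)
            filt = ResidualOutlierFilter(z_threshold=self.z_threshold).fit(
                self.pca_.transform(X), y, ids=dataset.complex_ids)
            kept = filt.kept_indices()
            self.outlier_report_ = filt.report_
        else:
            kept = np.arange(len(dataset))
            self.outlier_report_ = None

        cfg = self.network_config or NetworkConfig(seed=self.seed)
        self.model_ = AffinityModel(network_config=cfg, tree_params=self.tree_params,
                                    random_state=self.seed).fit(dataset.subset(kept),
                                                                y[kept])
        return self

    def predict(self, records) -> np.ndarray:
        return self.model_.predict(self._encode(records))

    def save(self, path) -> None:
        self.model_.save(path)


def crossval(records, y=None, k: int = 10, seed: int = 0, repeats: int = 1,
             **pipeline_kwargs):
    """k-fold cross-validation of the full pipeline (filtering on train folds only)."""
    dataset = AffinityPipeline._encode(records)
    if y is None:
        y = np.array([r.affinity.pK for r in records])

    def factory(fold_seed):
        kwargs = dict(pipeline_kwargs)
        cfg = kwargs.pop("network_config", None)
        if cfg is not None:
            cfg = NetworkConfig(**{**cfg.__dict__, "seed": fold_seed})
        return AffinityPipeline(network_config=cfg, seed=fold_seed, **kwargs)

    return evaluation.kfold_cv(dataset, y, factory, k=k, seed=seed, repeats=repeats)


def screen(pipeline: AffinityPipeline, groups: dict
           ) -> tuple[list[evaluation.DecoyAnalysis], list[dict]]:
    """Per-receptor active/decoy screening statistics and per-pair predictions.

    ``groups`` maps receptor id -> {"actives": records, "decoys": records};
    groups with fewer than 2 ligands on either side are skipped with a
    warning.  The per-pair table carries every receptor-ligand prediction in
    both pK and micromolar units.
    """
    import warnings

    analyses, pairs = [], []
    for receptor, sets in groups.items():
        actives, decoys = sets["actives"], sets["decoys"]
        if len(actives) < 2 or len(decoys) < 2:
            warnings.warn(f"receptor {receptor}: group with < 2 ligands, skipped")
            continue
        preds = {}
        for group, records in (("active", actives), ("decoy", decoys)):
            preds[group] = pipeline.predict(records)
            for rec, p in zip(records, preds[group]):
                pairs.append({"receptor": receptor, "ligand": rec.complex_id,
                              "group": group, "pred_pK": float(p),
                              "pred_uM": evaluation.convert_affinity(
                                  float(p), "pK", "uM")})
        analyses.append(evaluation.active_decoy_analysis(
            preds["active"], preds["decoy"], receptor=receptor))
    return analyses, pairs
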