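"""Comparator models: subtypes-only and stages-only ablations.

The subtypes-only model is a Gaussian mixture over the biomarker vectors
(diagonal covariance by default): phenotypic clusters with no notion of
disease stage.  The stages-only model is the single-sequence special case
of the full model (C = 1): one progression pattern with no phenotypic
heterogeneity.  Together they isolate what modelling stage and subtype
jointly adds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import BiomarkerDataset, NoiseModel, ZScoreEventSet
from .fitting import FitResult, fit_single_cluster
from .selection import make_folds, select_n_subtypes

__all__ = ["SubtypesOnlyModel", "fit_subtypes_only", "fit_stages_only",
           "subtypes_only_assignments_frame"]


@dataclass
class SubtypesOnlyModel:
    """Gaussian-mixture clustering result with CVIC-based model selection."""

    means: np.ndarray                  # (C, I)
    variances: np.ndarray              # (C, I) diagonal covariances
    weights: np.ndarray                # (C,)
    selected_c: int
    cvic: np.ndarray                   # per candidate C
    test_log_likelihoods: np.ndarray   # (n_folds, c_max)
    meta: dict = field(default_factory=dict)
    _gmm: object = None

    @property
    def n_subtypes(self) -> int:
        return len(self.weights)

    def predict_proba(self, data: BiomarkerDataset) -> np.ndarray:
        """Per-subject cluster posteriors (rows sum to 1)."""
        return self._gmm.predict_proba(np.asarray(data.values, float))


def _make_gmm(c: int, covariance_type: str, seed: int | None):
    from sklearn.mixture import GaussianMixture

    return GaussianMixture(n_components=c, covariance_type=covariance_type,
                           n_init=5, random_state=seed, reg_covar=1e-6)


def fit_subtypes_only(data: BiomarkerDataset, c_max: int = 3,
                      n_folds: int = 10, seed: int | None = None,
                      covariance_type: str = "diag") -> SubtypesOnlyModel:
    """Fit Gaussian mixtures for C = 1..c_max and select C by CVIC.

    The cluster count is chosen with the same criterion as the full model:
    CVIC = -2 x summed out-of-sample log-likelihood over the folds, with
    the smallest C within 6 of the minimum preferred.
    """
    X = np.asarray(data.values, float)
    if not np.isfinite(X).all():
        raise ValueError("subtypes-only model requires complete data")
    if c_max > data.n_subjects:
        raise ValueError("more clusters than subjects requested")
    folds = make_folds(data.n_subjects, n_folds, seed)
    test_ll = np.zeros((len(folds), c_max))
    for f, (train, test) in enumerate(folds):
        for ci in range(c_max):
            gmm = _make_gmm(ci + 1, covariance_type, seed)
            gmm.fit(X[train])
            test_ll[f, ci] = gmm.score_samples(X[test]).sum()
    cvic = -2.0 * test_ll.sum(axis=0)
    selected = select_n_subtypes(cvic)
    final = _make_gmm(selected, covariance_type, seed)
    final.fit(X)
    if covariance_type == "diag":
        variances = final.covariances_
    else:
        variances = np.stack([np.diag(S) for S in final.covariances_])
    return SubtypesOnlyModel(final.means_, variances, final.weights_,
                             selected, cvic, test_ll,
                             meta={"covariance_type": covariance_type,
                                   "seed": seed, "n_folds": n_folds},
                             _gmm=final)


def subtypes_only_assignments_frame(model: SubtypesOnlyModel,
                                    data: BiomarkerDataset):
    """Cluster assignments in the shared assignments-CSV schema.

    Stage-related fields are empty: the subtypes-only model has no notion
    of disease stage.
    """
    import pandas as pd

    post = model.predict_proba(data)
    rows = []
    for j in range(data.n_subjects):
        row = {"subject_id": data.subject_ids[j],
               "ml_subtype": int(np.argmax(post[j])),
               "ml_stage": np.nan, "expected_stage": np.nan,
               "strength": np.nan, "strongly_assigned": np.nan}
        for c in range(model.n_subtypes):
            row[f"p_subtype{c}"] = post[j, c]
        rows.append(row)
    return pd.DataFrame(rows)


def fit_stages_only(data: BiomarkerDataset, event_set: ZScoreEventSet,
                    noise: NoiseModel | None = None, n_restarts: int = 25,
                    seed: int | None = None,
                    quadrature_points: int = 10) -> FitResult:
    """Single-sequence progression model: the C = 1 special case."""
    return fit_single_cluster(data, event_set, noise, n_restarts, seed,
                              quadrature_points)
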