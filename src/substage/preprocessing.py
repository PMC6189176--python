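"""Control-referenced z-scoring and z-score event selection.

Raw biomarker values are referenced to a control population: covariates
(age, sex, education, genotype dose, ...) whose effect on a biomarker is
significant in controls are regressed out, the residuals are standardised
so controls have mean 0 and SD 1, and biomarkers that *decrease* with
disease (e.g. regional brain volumes) are sign-flipped so that abnormality
always increases.  Candidate z-score events (z = 1, 2, 3 by default) are
then kept only where enough patients actually exceed the threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import BiomarkerDataset, ZScoreEventSet

__all__ = [
    "ControlAdjustment",
    "fit_control_adjustment",
    "to_zscores",
    "select_events",
    "log_asymmetry",
    "save_adjustment",
    "load_adjustment",
]


@dataclass
class ControlAdjustment:
    """Per-biomarker covariate correction and control-referenced scaling."""

    biomarker_names: list[str]
    covariate_names: list[str]
    # per biomarker: names of covariates retained by the significance screen
    retained_covariates: dict[str, list[str]] = field(default_factory=dict)
    # per biomarker: coefficient per retained covariate
    coefficients: dict[str, dict[str, float]] = field(default_factory=dict)
    control_mean: dict[str, float] = field(default_factory=dict)
    control_sd: dict[str, float] = field(default_factory=dict)
    flip_sign: dict[str, bool] = field(default_factory=dict)
    unusable: list[str] = field(default_factory=list)
    alpha: float = 0.05


def fit_control_adjustment(raw: pd.DataFrame, control_mask: np.ndarray,
                           biomarker_names: list[str],
                           covariate_names: list[str] | None = None,
                           alpha: float = 0.05,
                           decline_direction: bool | dict[str, bool] = False,
                           ) -> ControlAdjustment:
    """Estimate covariate effects and control statistics per biomarker.

    A per-biomarker ordinary least squares model with intercept is fitted on
    the controls; covariates are retained only when their t-test p-value is
    below ``alpha`` (no multiple-testing correction), and the model is
    refitted with the retained set.  The residual mean and SD on controls
    define the z-scoring.  ``decline_direction`` marks biomarkers whose raw
    value falls with disease, so their z-scores are negated downstream.
    """
    import statsmodels.api as sm

    covariate_names = list(covariate_names or [])
    control_mask = np.asarray(control_mask, bool)
    if control_mask.sum() < 10:
        raise ValueError("need at least 10 controls to fit the adjustment")
    controls = raw.loc[control_mask]
    if covariate_names and controls[covariate_names].isna().any().any():
        raise ValueError("covariates must be complete for controls")
    adj = ControlAdjustment(list(biomarker_names), covariate_names,
                            alpha=alpha)
    for name in biomarker_names:
        y = controls[name].to_numpy(float)
        ok = np.isfinite(y)
        if y[ok].std(ddof=1) == 0 or ok.sum() < 3:
            warnings.warn(f"biomarker {name} has no variance in controls; "
                          "flagged unusable")
            adj.unusable.append(name)
            continue
        retained = []
        if covariate_names:
            X = sm.add_constant(controls.loc[ok, covariate_names].to_numpy(float))
            fit = sm.OLS(y[ok], X).fit()
            pvals = fit.pvalues[1:]
            retained = [cv for cv, p in zip(covariate_names, pvals)
                        if p < alpha]
        coefs: dict[str, float] = {}
        resid = y.copy()
        if retained:
            Xr = sm.add_constant(controls.loc[ok, retained].to_numpy(float))
            refit = sm.OLS(y[ok], Xr).fit()
            for cv, b in zip(retained, refit.params[1:]):
                coefs[cv] = float(b)
            resid[ok] = y[ok] - Xr[:, 1:] @ refit.params[1:]
        adj.retained_covariates[name] = retained
        adj.coefficients[name] = coefs
        adj.control_mean[name] = float(np.nanmean(resid[ok]))
        adj.control_sd[name] = float(np.nanstd(resid[ok], ddof=1))
        if isinstance(decline_direction, dict):
            adj.flip_sign[name] = bool(decline_direction.get(name, False))
        else:
            adj.flip_sign[name] = bool(decline_direction)
    if not adj.control_mean:
        raise ValueError("no usable biomarkers after the control screen")
    return adj


def to_zscores(raw: pd.DataFrame, adjustment: ControlAdjustment,
               subject_id_col: str | None = None,
               label_col: str | None = None) -> BiomarkerDataset:
    """Apply a fitted control adjustment to a raw table.

    Covariate effects are subtracted, values are standardised by the control
    residual mean/SD, and decline-direction biomarkers are negated so that
    abnormality is non-negative increasing.  The transform is affine per
    biomarker, so subject rank order within a biomarker is preserved.
    """
    if isinstance(raw, BiomarkerDataset):
        raise TypeError("data is already z-scored; the control-referenced "
                        "transform must not be applied twice")
    usable = [n for n in adjustment.biomarker_names
              if n not in adjustment.unusable]
    missing_cols = [n for n in usable if n not in raw.columns]
    if missing_cols:
        raise KeyError(f"biomarker columns missing from input: {missing_cols}")
    J = len(raw)
    out = np.empty((J, len(usable)))
    for k, name in enumerate(usable):
        y = raw[name].to_numpy(float).copy()
        for cv, b in adjustment.coefficients[name].items():
            y = y - b * raw[cv].to_numpy(float)
        z = (y - adjustment.control_mean[name]) / adjustment.control_sd[name]
        if adjustment.flip_sign[name]:
            z = -z
        out[:, k] = z
    ids = (raw[subject_id_col].astype(str).tolist() if subject_id_col
           else [str(i) for i in raw.index])
    labels = raw[label_col].to_numpy() if label_col else None
    return BiomarkerDataset(out, usable, ids, labels)


def select_events(data: BiomarkerDataset, patient_mask: np.ndarray,
                  candidate_z: tuple[float, ...] = (1.0, 2.0, 3.0),
                  min_count: int = 10) -> ZScoreEventSet:
    """Retain z-score events supported by enough patients.

    A threshold z is kept for a biomarker when at least ``min_count``
    patients exceed it; because exceedance sets are nested, the retained
    set is always a prefix of the candidates.  The trajectory cap z_max is
    2, 3 or 5 according to whether the largest retained z is 1, 2 or 3.
    Biomarkers retaining no event are dropped with a warning.
    """
    patient_mask = np.asarray(patient_mask, bool)
    if not patient_mask.any():
        raise ValueError("patient mask selects no subjects")
    zmax_map = {1.0: 2.0, 2.0: 3.0, 3.0: 5.0}
    names, z_lists, z_maxes = [], [], []
    for i, name in enumerate(data.biomarker_names):
        x = data.values[patient_mask, i]
        kept = [z for z in candidate_z
                if np.sum(x[np.isfinite(x)] > z) >= min_count]
        if not kept:
            warnings.warn(f"biomarker {name} dropped: fewer than "
                          f"{min_count} patients exceed any candidate z")
            continue
        top = kept[-1]
        z_cap = zmax_map.get(float(top), float(top) + 2.0)
        names.append(name)
        z_lists.append(np.asarray(kept, float))
        z_maxes.append(z_cap)
    if not names:
        raise ValueError("all biomarkers dropped by the event selection rule")
    return ZScoreEventSet(names, z_lists, np.asarray(z_maxes))


def save_adjustment(adjustment: ControlAdjustment, path) -> None:
    """Serialise a fitted control adjustment to JSON for reuse."""
    import json
    from dataclasses import asdict
    from pathlib import Path

    Path(path).write_text(json.dumps(asdict(adjustment), indent=2,
                                     sort_keys=True) + "\n")


def load_adjustment(path) -> ControlAdjustment:
    import json
    from pathlib import Path

    return ControlAdjustment(**json.loads(Path(path).read_text()))


def log_asymmetry(left: np.ndarray, right: np.ndarray,
                  eps: float = 1e-12) -> np.ndarray:
    """Log-transformed hemispheric asymmetry index.

    |L - R| / (L + R), log-transformed to improve normality; a derived
    feature computed on raw volumes before z-scoring.
    """
    left = np.asarray(left, float)
    right = np.asarray(right, float)
    return np.log(np.abs(left - right) / (left + right) + eps)
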