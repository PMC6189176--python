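"""File formats: dataset CSV, model JSON, sample and positional tables.

Models serialise to JSON (event table, sequences as event-index lists,
fractions, noise, metadata); MCMC samples export to a compressed CSV with
one row per sample; positional distributions export to a long-format CSV
(subtype, event, position, probability).  Every artefact embeds the seed
and software version so runs are reproducible.
"""

from __future__ import annotations

import gzip
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    BiomarkerDataset,
    NoiseModel,
    SubtypeMixtureModel,
    SubtypeSequence,
    ZScoreEventSet,
)
from .mcmc import MCMCSamples, PositionalDistribution

__all__ = [
    "read_dataset_csv",
    "write_dataset_csv",
    "model_to_dict",
    "model_from_dict",
    "save_model",
    "load_model",
    "save_samples",
    "load_samples",
    "positional_to_frame",
    "config_hash",
]


def read_dataset_csv(path: str | Path, subject_id_col: str | None = None,
                     label_col: str | None = None) -> BiomarkerDataset:
    """Read a subjects x biomarkers CSV.

    The header row names the biomarkers; optional leading columns carry the
    subject id and a categorical label.  Empty cells and "NA" are missing.
    """
    df = pd.read_csv(path, na_values=["NA"])
    ids = None
    labels = None
    if subject_id_col is not None:
        if subject_id_col not in df.columns:
            raise KeyError(f"subject id column {subject_id_col!r} not found")
        ids = df[subject_id_col].astype(str).tolist()
        df = df.drop(columns=[subject_id_col])
    if label_col is not None:
        if label_col not in df.columns:
            raise KeyError(f"label column {label_col!r} not found")
        labels = df[label_col].to_numpy()
        df = df.drop(columns=[label_col])
    return BiomarkerDataset(df.to_numpy(float), list(df.columns), ids, labels)


def write_dataset_csv(data: BiomarkerDataset, path: str | Path) -> None:
    df = pd.DataFrame(data.values, columns=data.biomarker_names)
    df.insert(0, "subject_id", data.subject_ids)
    if data.labels is not None:
        df.insert(1, "label", data.labels)
    df.to_csv(path, index=False)


def model_to_dict(model: SubtypeMixtureModel, seed: int | None = None,
                  extra_meta: dict | None = None) -> dict:
    from . import __version__

    es = model.event_set
    return {
        "events": [
            {"biomarker": es.biomarker_names[i],
             "z_scores": es.z_scores[i].tolist(),
             "z_max": float(es.z_max[i])}
            for i in range(es.n_biomarkers)
        ],
        "sequences": [s.order.tolist() for s in model.sequences],
        "fractions": model.fractions.tolist(),
        "sigma": model.noise.sigma.tolist(),
        "metadata": {"seed": seed, "version": __version__,
                     **(extra_meta or {})},
    }


def model_from_dict(d: dict) -> SubtypeMixtureModel:
    es = ZScoreEventSet(
        [e["biomarker"] for e in d["events"]],
        [np.asarray(e["z_scores"], float) for e in d["events"]],
        np.asarray([e["z_max"] for e in d["events"]], float),
    )
    sequences = [SubtypeSequence(np.asarray(o, int)) for o in d["sequences"]]
    return SubtypeMixtureModel(es, sequences, np.asarray(d["fractions"]),
                               NoiseModel(np.asarray(d["sigma"])))


def save_model(model: SubtypeMixtureModel, path: str | Path,
               seed: int | None = None, extra_meta: dict | None = None) -> None:
    Path(path).write_text(
        json.dumps(model_to_dict(model, seed, extra_meta), indent=2,
                   sort_keys=True) + "\n")


def load_model(path: str | Path) -> SubtypeMixtureModel:
    return model_from_dict(json.loads(Path(path).read_text()))


def save_samples(samples: MCMCSamples, path: str | Path) -> None:
    """One row per sample: per-subtype sequences, fractions, log-likelihood."""
    C, N = samples.n_subtypes, samples.n_events
    cols: dict[str, np.ndarray] = {}
    for c in range(C):
        for k in range(N):
            cols[f"seq{c}_pos{k}"] = samples.sequences[:, c, k]
    for c in range(C):
        cols[f"f{c}"] = samples.fractions[:, c]
    cols["log_likelihood"] = samples.log_likelihoods
    df = pd.DataFrame(cols)
    path = str(path)
    if path.endswith(".gz"):
        with gzip.open(path, "wt") as fh:
            df.to_csv(fh, index=False)
    else:
        df.to_csv(path, index=False)


def load_samples(path: str | Path, n_subtypes: int,
                 acceptance_rate: float = np.nan,
                 seed: int | None = None) -> MCMCSamples:
    df = pd.read_csv(path)
    seq_cols = [c for c in df.columns if c.startswith("seq")]
    N = len(seq_cols) // n_subtypes
    S = len(df)
    seqs = np.empty((S, n_subtypes, N), dtype=np.int16)
    for c in range(n_subtypes):
        for k in range(N):
            seqs[:, c, k] = df[f"seq{c}_pos{k}"]
    fracs = np.stack([df[f"f{c}"].to_numpy() for c in range(n_subtypes)], axis=1)
    return MCMCSamples(seqs, fracs, df["log_likelihood"].to_numpy(),
                       acceptance_rate, seed)


def positional_to_frame(pos: PositionalDistribution) -> pd.DataFrame:
    """Long-format table: subtype, event, position, probability."""
    rows = []
    for c in range(pos.n_subtypes):
        mat = pos.subtype(c)
        for e in range(pos.n_events):
            for p in range(pos.n_events):
                rows.append((c, e, p, mat[e, p]))
    return pd.DataFrame(rows, columns=["subtype", "event", "position",
                                       "probability"])


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping."""
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]
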