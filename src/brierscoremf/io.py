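"""Delimited-text I/O for spectra tables, labels, models and datasets.

Spectra travel as TSV with sample identifiers in the first column and
one header row carrying the wavenumber axis (or abstract channel names
for synthetic data).  Labels are a two-column CSV with the ordered class
registry in a small JSON sidecar.  A trained model serializes to a
single JSON bundle whose threshold vector round-trips bit-exactly
(Python float repr is shortest-round-trip).
"""

from __future__ import annotations

import hashlib
import json
import re
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .preprocess import ReplicateGroup
from .simulate import SyntheticDataset
from .types import FactorModel, SignalMatrix, SpectraMatrix, ThresholdVector

__all__ = [
    "read_spectra",
    "write_spectra",
    "read_labels",
    "write_labels",
    "save_model",
    "load_model",
    "group_replicates",
    "write_dataset",
]

_REPLICATE_SUFFIX = re.compile(r"^(?P<sample>.+)__rep\d+$")


def write_spectra(X: SpectraMatrix, path: str | Path, sep: str = "\t") -> None:
    """Write a spectra table: first column sample_id, header = wavenumbers."""
    if X.wavenumbers is not None:
        columns = [repr(float(w)) for w in X.wavenumbers]
    else:
        columns = [f"f{j}" for j in range(X.n_channels)]
    df = pd.DataFrame(X.values, index=pd.Index(X.sample_ids, name="sample_id"), columns=columns)
    df.to_csv(path, sep=sep)


def read_spectra(path: str | Path, sep: str = "\t") -> SpectraMatrix:
    """Read a spectra table written by :func:`write_spectra`.

    Header fields that all parse as numbers are interpreted as the
    wavenumber axis; otherwise channels are treated as anonymous.
    """
    df = pd.read_csv(path, sep=sep, index_col=0)
    try:
        wavenumbers = np.asarray([float(c) for c in df.columns])
    except ValueError:
        wavenumbers = None
    return SpectraMatrix(
        df.to_numpy(dtype=float),
        sample_ids=[str(s) for s in df.index],
        wavenumbers=wavenumbers,
    )


def write_labels(
    sample_ids: Sequence[str],
    labels: Sequence[str],
    path: str | Path,
    class_names: Sequence[str] | None = None,
) -> None:
    """Write sample_id,label CSV plus a JSON sidecar with the class registry."""
    path = Path(path)
    if class_names is None:
        class_names = sorted(set(labels))
    pd.DataFrame({"sample_id": list(sample_ids), "label": list(labels)}).to_csv(
        path, index=False
    )
    sidecar = path.with_suffix(path.suffix + ".classes.json")
    sidecar.write_text(json.dumps({"class_names": list(class_names)}, indent=1))


def read_labels(path: str | Path) -> tuple[list[str], list[str], list[str]]:
    """Read labels; returns (sample_ids, labels, class_names)."""
    path = Path(path)
    df = pd.read_csv(path)
    sidecar = path.with_suffix(path.suffix + ".classes.json")
    if sidecar.exists():
        class_names = json.loads(sidecar.read_text())["class_names"]
    else:
        class_names = sorted(set(df["label"].astype(str)))
    return (
        [str(s) for s in df["sample_id"]],
        [str(l) for l in df["label"]],
        [str(c) for c in class_names],
    )


def save_model(model: FactorModel, path: str | Path) -> None:
    """Serialize a trained model to one JSON bundle."""
    payload = {
        "format": "brierscoremf-model",
        "version": 1,
        "class_names": model.class_names,
        "thresholds": [float(v) for v in model.b],
        "signals": [[float(v) for v in row] for row in model.S],
        "meta": model.meta,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_model(path: str | Path) -> FactorModel:
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != "brierscoremf-model":
        raise ValueError(f"{path} is not a factor-model bundle")
    class_names = list(payload["class_names"])
    return FactorModel(
        thresholds=ThresholdVector(np.array(payload["thresholds"], dtype=float), class_names),
        signals=SignalMatrix(np.array(payload["signals"], dtype=float)),
        class_names=class_names,
        meta=payload.get("meta", {}),
    )


def group_replicates(X: SpectraMatrix) -> list[ReplicateGroup]:
    """Group rows of a spectra table by the ``<sample>__rep<i>`` convention.

    Rows without the suffix form singleton names and are rejected (QC
    needs at least two replicates per sample).
    """
    buckets: dict[str, list[int]] = {}
    for i, sid in enumerate(X.sample_ids):
        m = _REPLICATE_SUFFIX.match(sid)
        name = m.group("sample") if m else sid
        buckets.setdefault(name, []).append(i)
    groups = []
    for name, rows in buckets.items():
        if len(rows) < 2:
            raise ValueError(
                f"sample {name!r} has only one spectrum; replicate QC needs >= 2 "
                "(use the '<sample>__rep<i>' naming convention)"
            )
        groups.append(
            ReplicateGroup(
                sample_id=name,
                spectra=X.values[rows],
                wavenumbers=X.wavenumbers,
            )
        )
    return groups


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_dataset(ds: SyntheticDataset, out_dir: str | Path) -> Path:
    """Write a synthetic dataset as delimited tables plus a JSON manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_spectra(ds.X, out / "X.tsv")
    write_labels(list(ds.X.sample_ids), ds.labels, out / "labels.csv", ds.class_names)
    np.savetxt(out / "A_true.tsv", ds.A_true.values, delimiter="\t")
    np.savetxt(out / "S_true.tsv", ds.S_true.values, delimiter="\t")
    np.savetxt(out / "b_true.tsv", ds.b_true.b, delimiter="\t")
    files = ["X.tsv", "labels.csv", "A_true.tsv", "S_true.tsv", "b_true.tsv"]
    manifest = {
        "config": {
            "seed": ds.config.seed,
            "n": ds.config.n,
            "k": ds.config.k,
            "m": ds.config.m,
            "order_range": list(ds.config.order_range),
        },
        "order": ds.order,
        "class_names": ds.class_names,
        "checksums": {f: _sha256(out / f) for f in files},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out
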