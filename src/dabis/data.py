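"""Dataset manifests and per-sample data access.

A manifest is a table of patient-level records — sample id, patient id,
site id, class label — each pointing at (or inlining) one sample: a 2-D
single/multi-channel image, a multi-channel 1-D signal (channels x
timesteps), a small 3-D volume, or a plain-text document.

On disk a manifest is a CSV with columns ``sample_id, patient_id,
site_id, label, path`` plus a declared modality; sample files are PNG
images, plain numeric CSV grids, or UTF-8 text files.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

MODALITIES = ("image2d", "signal1d", "volume3d", "text")

MANIFEST_COLUMNS = ("sample_id", "patient_id", "site_id", "label", "path")

#: character vocabulary for the text model; index 0 is the out-of-vocab /
#: padding channel
TEXT_VOCAB = "\0abcdefghijklmnopqrstuvwxyz0123456789 .,;:!?-'\""


@dataclasses.dataclass
class LabeledSample:
    """One patient-level record: data (or a path to it), label, ids."""

    sample_id: str
    patient_id: str
    label: str
    site_id: str = ""
    data: object = None          # np.ndarray, str (text), or None if on disk
    path: Optional[str] = None
    provenance: Optional[str] = None


@dataclasses.dataclass
class DatasetManifest:
    """A named collection of labeled samples of one modality."""

    records: List[LabeledSample]
    modality: str
    class_names: tuple
    name: str = "dataset"

    def __post_init__(self):
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}; "
                             f"expected one of {MODALITIES}")
        self.class_names = tuple(self.class_names)
        seen = set()
        for rec in self.records:
            if rec.sample_id in seen:
                raise ValueError(f"duplicate sample_id {rec.sample_id!r}")
            seen.add(rec.sample_id)
            if not rec.patient_id:
                raise ValueError(f"sample {rec.sample_id!r} has no patient_id")
            if rec.label not in self.class_names:
                raise ValueError(
                    f"sample {rec.sample_id!r} has label {rec.label!r} "
                    f"not in class_names {self.class_names}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def sample_ids(self) -> list:
        return [r.sample_id for r in self.records]

    @property
    def patient_ids(self) -> list:
        return [r.patient_id for r in self.records]

    def label_indices(self) -> np.ndarray:
        lut = {name: i for i, name in enumerate(self.class_names)}
        return np.array([lut[r.label] for r in self.records], dtype=int)

    def load_data(self) -> list:
        """Materialise every sample (arrays or text documents)."""
        out = []
        for rec in self.records:
            if rec.data is not None:
                out.append(rec.data)
            elif rec.path is not None:
                out.append(load_sample_file(rec.path, self.modality))
            else:
                raise ValueError(f"sample {rec.sample_id!r} has neither "
                                 "inline data nor a path")
        return out

    def subset(self, indices: Sequence[int], name: Optional[str] = None
               ) -> "DatasetManifest":
        return DatasetManifest([self.records[i] for i in indices],
                               self.modality, self.class_names,
                               name or self.name)


def load_sample_file(path: str, modality: str):
    """Load one sample file, normalising layout to channels-first."""
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"sample file does not exist: {path}")
    if modality == "text":
        return p.read_text(encoding="utf-8")
    if p.suffix.lower() == ".png":
        from PIL import Image, UnidentifiedImageError
        try:
            with Image.open(p) as img:
                arr = np.asarray(img, dtype=float)
        except (UnidentifiedImageError, OSError) as exc:
            raise ValueError(f"cannot parse image file {path}: {exc}") from exc
        if arr.ndim == 2:
            arr = arr[None]
        else:                      # H x W x C -> C x H x W
            arr = np.moveaxis(arr, -1, 0)
        return arr / 255.0
    # plain numeric CSV grid: rows are channels (1-D) or image rows (2-D)
    try:
        arr = np.loadtxt(p, delimiter=",", dtype=float, ndmin=2)
    except ValueError as exc:
        raise ValueError(f"cannot parse numeric grid {path}: {exc}") from exc
    if modality == "image2d":
        return arr[None]
    return arr


def save_sample_file(data, path: str, modality: str) -> None:
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    if modality == "text":
        p.write_text(data, encoding="utf-8")
    elif p.suffix.lower() == ".png":
        from PIL import Image
        arr = np.asarray(data, dtype=float)
        if arr.ndim == 3 and arr.shape[0] == 1:
            arr = arr[0]
        lo, hi = arr.min(), arr.max()
        scaled = np.zeros_like(arr) if hi == lo else (arr - lo) / (hi - lo)
        Image.fromarray((scaled * 255).astype(np.uint8)).save(p)
    else:
        arr = np.asarray(data, dtype=float)
        if arr.ndim == 3 and arr.shape[0] == 1:
            arr = arr[0]
        np.savetxt(p, np.atleast_2d(arr), delimiter=",")


def read_manifest(path, modality: str, class_names: Optional[Sequence[str]] = None,
                  name: Optional[str] = None, validate_files: bool = True
                  ) -> DatasetManifest:
    """Read and validate a manifest CSV.

    Every referenced sample file must exist and parse; missing columns,
    dangling paths and duplicate sample ids raise specific errors.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    for col in MANIFEST_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"manifest {path} is missing required column {col!r}")
    records = []
    for _, row in df.iterrows():
        sample_path = row["path"]
        if not (isinstance(sample_path, str) and sample_path):
            raise ValueError(f"sample {row['sample_id']!r} has an empty path")
        resolved = str((path.parent / sample_path))
        records.append(LabeledSample(
            sample_id=str(row["sample_id"]), patient_id=str(row["patient_id"]),
            site_id=str(row["site_id"]) if pd.notna(row["site_id"]) else "",
            label=str(row["label"]), path=resolved,
            provenance=str(row["provenance"]) if "provenance" in df.columns
            and pd.notna(row.get("provenance")) else None))
    if class_names is None:
        class_names = tuple(sorted({r.label for r in records}))
    manifest = DatasetManifest(records, modality, tuple(class_names),
                               name or path.stem)
    if validate_files:
        manifest.load_data()
    return manifest


def write_manifest(manifest: DatasetManifest, csv_path, data_dir=None) -> None:
    """Write a manifest CSV; inline data is materialised under ``data_dir``."""
    csv_path = Path(csv_path)
    csv_path.parent.mkdir(parents=True, exist_ok=True)
    rows = []
    ext = {"image2d": ".png", "signal1d": ".csv", "volume3d": ".csv",
           "text": ".txt"}[manifest.modality]
    for rec in manifest.records:
        rel = rec.path
        if rec.data is not None:
            if data_dir is None:
                raise ValueError("data_dir required to materialise inline data")
            rel = str(Path(data_dir) / f"{rec.sample_id}{ext}")
            target = rel if Path(rel).is_absolute() else csv_path.parent / rel
            if manifest.modality == "volume3d":
                save_sample_file(np.asarray(rec.data).reshape(
                    np.asarray(rec.data).shape[0], -1), str(target),
                    "signal1d")
            else:
                save_sample_file(rec.data, str(target), manifest.modality)
        rows.append({"sample_id": rec.sample_id, "patient_id": rec.patient_id,
                     "site_id": rec.site_id, "label": rec.label, "path": rel,
                     "provenance": rec.provenance})
    pd.DataFrame(rows).to_csv(csv_path, index=False)


def encode_text(document: str, max_len: int = 256,
                vocab: str = TEXT_VOCAB) -> np.ndarray:
    """One-hot character encoding, channels x positions.

    Lower-cases the document, truncates/pads to ``max_len``; characters
    outside the vocabulary map to the 0 channel.
    """
    lut = {ch: i for i, ch in enumerate(vocab)}
    arr = np.zeros((len(vocab), max_len))
    for pos, ch in enumerate(document.lower()[:max_len]):
        arr[lut.get(ch, 0), pos] = 1.0
    return arr
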