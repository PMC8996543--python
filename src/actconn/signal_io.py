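"""Containers and delimited-text I/O for ROI-by-time signal matrices.

A :class:`SignalMatrix` holds one subject's extracted time series: rows are
ROIs (individual neurons for calcium imaging, brain regions for BOLD fMRI),
columns are time samples at a fixed sampling interval ``dt``.  Every
downstream stage of the pipeline (activity, connectivity, level
classification, null models) consumes this container and nothing else.

On-disk format is UTF-8 delimited text (comma for ``.csv``, tab for
``.tsv``): a header row of time indices and a first column of ROI ids, or a
headerless pure-numeric matrix when ``headerless=True``.  Cohorts are
described by a :class:`CohortManifest` (YAML or JSON) listing one file per
subject.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

logger = logging.getLogger(__name__)

#: Documented modality strings.  Simulated data may use prefixed variants
#: such as ``"simulated-calcium"``; the container accepts any non-empty tag.
MODALITIES = ("calcium", "bold")


class SignalFormatError(ValueError):
    """Structural problem in a signal file (e.g. ragged rows)."""


class SignalParseError(ValueError):
    """A cell could not be parsed as a number; message carries coordinates."""


@dataclass
class SignalMatrix:
    """One subject's ROI x time signal values.

    Parameters
    ----------
    subject_id : str
        Unique subject identifier.
    modality : str
        ``"calcium"`` (dF/F traces), ``"bold"`` or a simulated variant.
    dt : float
        Seconds per sample (0.5 s for ~2 Hz calcium volumes, 2.0 s BOLD TR).
    roi_ids : list of str
        Ordered, unique ROI identifiers; length R.
    values : numpy.ndarray
        Real matrix of shape (R, T), row i holding signal s_i.
    labels : list of str, optional
        Per-ROI anatomical labels.
    meta : dict
        Free-form provenance (imputation flags, null-model tags, ...).
    """

    subject_id: str
    modality: str
    dt: float
    roi_ids: list[str]
    values: np.ndarray
    labels: list[str] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D ROI x time matrix")
        r, t = self.values.shape
        if r < 2 or t < 2:
            raise ValueError(f"need at least 2 ROIs and 2 samples, got {r} x {t}")
        if len(self.roi_ids) != r:
            raise ValueError(f"{len(self.roi_ids)} roi_ids for {r} rows")
        if len(set(self.roi_ids)) != len(self.roi_ids):
            raise ValueError("roi_ids must be unique")
        if self.labels is not None and len(self.labels) != r:
            raise ValueError("labels length must match ROI count")
        if not self.dt > 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if not self.modality:
            raise ValueError("modality must be a non-empty string")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values contain NaN/inf; load with impute=True "
                             "or clean the input")

    # ------------------------------------------------------------------
    @property
    def n_rois(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def with_values(self, values: np.ndarray, **meta) -> "SignalMatrix":
        """Copy carrying new values (same ids/dt/modality), merging meta."""
        new_meta = {**self.meta, **meta}
        return replace(self, values=np.asarray(values, dtype=float),
                       meta=new_meta)


# ----------------------------------------------------------------------
# Reading / writing
# ----------------------------------------------------------------------

def _delimiter_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def read_signal_matrix(path, subject_id: str | None = None,
                       modality: str = "calcium", dt: float = 1.0,
                       headerless: bool = False,
                       impute: bool = False) -> SignalMatrix:
    """Read a delimited-text signal matrix.

    With a header (default), the first row holds time indices and the first
    column ROI ids.  With ``headerless=True`` the file is a pure numeric
    matrix and ids ``roi_0001, roi_0002, ...`` are generated.

    Missing/blank cells are rejected unless ``impute=True``, in which case
    they are replaced by the row mean of the present values and the affected
    ROIs are recorded in ``meta["imputed_rois"]``.
    """
    path = Path(path)
    if subject_id is None:
        subject_id = path.stem
    delim = _delimiter_for(path)
    with open(path, newline="", encoding="utf-8") as fh:
        rows = list(csv.reader(fh, delimiter=delim))
    rows = [r for r in rows if r and any(c.strip() for c in r)]
    if not rows:
        raise SignalFormatError(f"{path}: empty file")

    if headerless:
        data_rows = rows
        roi_ids = [f"roi_{i + 1:04d}" for i in range(len(rows))]
        first_data_col = 0
        row_offset = 1  # 1-based file line of first data row
    else:
        data_rows = rows[1:]
        roi_ids = [r[0].strip() for r in data_rows]
        first_data_col = 1
        row_offset = 2

    if len(data_rows) < 1:
        raise SignalFormatError(f"{path}: no data rows")
    width = len(data_rows[0])
    for i, r in enumerate(data_rows):
        if len(r) != width:
            raise SignalFormatError(
                f"{path}: ragged row {i + row_offset} "
                f"({len(r)} cells, expected {width})")
    dupes = {rid for rid in roi_ids if roi_ids.count(rid) > 1}
    if dupes:
        raise ValueError(f"{path}: duplicate roi_id(s): {sorted(dupes)}")

    n_t = width - first_data_col
    values = np.empty((len(data_rows), n_t), dtype=float)
    missing: list[tuple[int, int]] = []
    for i, r in enumerate(data_rows):
        for j, cell in enumerate(r[first_data_col:]):
            s = cell.strip()
            if s == "" or s.lower() == "nan":
                missing.append((i, j))
                values[i, j] = np.nan
                continue
            try:
                values[i, j] = float(s)
            except ValueError as exc:
                raise SignalParseError(
                    f"{path}: non-numeric cell {cell!r} at data row "
                    f"{i + row_offset}, column {j + first_data_col + 1}"
                ) from exc

    meta: dict = {}
    if missing:
        if not impute:
            i, j = missing[0]
            raise SignalParseError(
                f"{path}: missing value at data row {i + row_offset}, "
                f"column {j + first_data_col + 1} "
                f"({len(missing)} missing total); pass impute=True to "
                "row-mean impute")
        imputed_rois = sorted({roi_ids[i] for i, _ in missing})
        for i in {i for i, _ in missing}:
            row = values[i]
            row[np.isnan(row)] = np.nanmean(row)
        meta["imputed_rois"] = imputed_rois
        logger.info("imputed %d missing cells in %d ROIs of %s",
                    len(missing), len(imputed_rois), path)

    return SignalMatrix(subject_id=subject_id, modality=modality, dt=dt,
                        roi_ids=roi_ids, values=values, meta=meta)


def write_signal_matrix(m: SignalMatrix, path) -> Path:
    """Write a SignalMatrix as delimited text; round-trips exactly.

    Floats are printed with 17 significant digits so that
    ``read_signal_matrix(write_signal_matrix(m))`` reproduces the values
    bit-for-bit.
    """
    path = Path(path)
    delim = _delimiter_for(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter=delim, lineterminator="\n")
        w.writerow(["roi_id"] + [str(k) for k in range(m.n_samples)])
        for rid, row in zip(m.roi_ids, m.values):
            w.writerow([rid] + [f"{v:.17g}" for v in row])
    return path


# ----------------------------------------------------------------------
# Normalization
# ----------------------------------------------------------------------

def znormalize(m: SignalMatrix) -> SignalMatrix:
    """Standardize each ROI's series to mean 0, population variance 1.

    Zero-variance rows cannot be standardized; they are set to all-zeros and
    their ids recorded in ``meta["zero_variance_rois"]`` (no exception).
    """
    mu = m.values.mean(axis=1, keepdims=True)
    sd = m.values.std(axis=1, keepdims=True)  # population (divide by T)
    flat = (sd[:, 0] == 0)
    safe_sd = np.where(sd == 0, 1.0, sd)
    out = (m.values - mu) / safe_sd
    out[flat, :] = 0.0
    meta: dict = {}
    if flat.any():
        meta["zero_variance_rois"] = [rid for rid, f in zip(m.roi_ids, flat)
                                      if f]
        logger.warning("znormalize: %d zero-variance ROI(s) set to zeros",
                       int(flat.sum()))
    return m.with_values(out, **meta)


# ----------------------------------------------------------------------
# Cohort manifests
# ----------------------------------------------------------------------

@dataclass
class ManifestEntry:
    path: str
    subject_id: str
    modality: str
    dt: float


@dataclass
class CohortManifest:
    """List of subjects in a cohort; each entry points at a signal file."""

    entries: list[ManifestEntry]

    def __post_init__(self) -> None:
        if len(self.entries) < 1:
            raise ValueError("manifest needs at least one entry")
        ids = [e.subject_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("subject_id must be unique within a manifest")

    @property
    def subject_ids(self) -> list[str]:
        return [e.subject_id for e in self.entries]

    def load_subjects(self, base_dir=None) -> list[SignalMatrix]:
        """Read every subject's matrix (paths resolved against base_dir)."""
        base = Path(base_dir) if base_dir is not None else None
        out = []
        for e in self.entries:
            p = Path(e.path)
            if base is not None and not p.is_absolute():
                p = base / p
            out.append(read_signal_matrix(p, subject_id=e.subject_id,
                                          modality=e.modality, dt=e.dt))
        return out


def save_manifest(manifest: CohortManifest, path) -> Path:
    path = Path(path)
    doc = {"subjects": [vars(e) for e in manifest.entries]}
    with open(path, "w", encoding="utf-8") as fh:
        if path.suffix.lower() == ".json":
            json.dump(doc, fh, indent=2, sort_keys=True)
            fh.write("\n")
        else:
            yaml.safe_dump(doc, fh, sort_keys=True)
    return path


def load_manifest(path) -> CohortManifest:
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh) if path.suffix.lower() == ".json" \
            else yaml.safe_load(fh)
    entries = [ManifestEntry(path=str(e["path"]),
                             subject_id=str(e["subject_id"]),
                             modality=str(e["modality"]), dt=float(e["dt"]))
               for e in doc["subjects"]]
    return CohortManifest(entries=entries)
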