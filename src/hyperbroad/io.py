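"""Readers/writers for ROI time series, subject manifests and model archives.

Time-series tables are plain delimited text: rows are time points, columns
are ROIs (regions of interest).  Three dialects are understood:

``abide_1d``
    Whitespace-separated, the dialect of the ABIDE C-PAC ROI exports.
    Lines starting with ``#`` are comments; a first data line whose tokens
    are not all numeric is taken as the ROI-label header.
``csv`` / ``tsv``
    Comma / tab separated, optional single header row of ROI labels.

A transposed table (more columns than rows, i.e. apparently more ROIs than
time points) is rejected unless ``transpose=True`` is passed explicitly —
silent auto-transposition would corrupt every downstream correlation.

Model archives are single-file numpy ``.npz`` bundles keyed by named arrays.
Key schema::

    __meta__            JSON string (config, class codes, shapes)
    scaler/mean, scaler/std
    ae/enc_W_{i}, ae/enc_b_{i}, ae/dec_W_{i}, ae/dec_b_{i}
    bls/map_W_{i}, bls/map_b_{i}, bls/enh_W_{i}, bls/enh_b_{i}, bls/W_out
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ParseError, ValidationError

__all__ = [
    "RoiTimeSeries",
    "ManifestEntry",
    "SubjectManifest",
    "read_timeseries",
    "write_timeseries",
    "read_manifest",
    "write_manifest",
    "save_archive",
    "load_archive",
]

#: label tokens accepted in manifests, normalised to {positive, control}
LABEL_TOKENS = {
    "asd": "positive",
    "positive": "positive",
    "case": "positive",
    "patient": "positive",
    "1": "positive",
    "nc": "control",
    "control": "control",
    "tc": "control",
    "hc": "control",
    "0": "control",
}

_DIALECT_SEP = {"csv": ",", "tsv": "\t", "abide_1d": None}


@dataclass
class RoiTimeSeries:
    """One subject's T x M BOLD table: T time points, M ROIs."""

    subject_id: str
    values: np.ndarray
    roi_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValidationError("time series must be a 2-D table")
        t, m = self.values.shape
        if t < 3:
            raise ValidationError(
                f"subject {self.subject_id!r}: need at least 3 time points, got {t}"
            )
        if m < 2:
            raise ValidationError(
                f"subject {self.subject_id!r}: need at least 2 ROIs, got {m}"
            )
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValidationError(
                f"subject {self.subject_id!r}: non-finite value at "
                f"row {bad[0] + 1}, column {bad[1] + 1}"
            )
        if self.roi_labels is not None and len(self.roi_labels) != m:
            raise ValidationError(
                f"subject {self.subject_id!r}: {len(self.roi_labels)} ROI labels "
                f"for {m} columns"
            )

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_rois(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class ManifestEntry:
    subject_id: str
    path: Path
    label: str  # "positive" | "control"
    site: str | None = None


@dataclass
class SubjectManifest:
    """Ordered list of subjects; order is the file order of the manifest."""

    entries: list[ManifestEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [e.subject_id for e in self.entries]
        dupes = {s for s in ids if ids.count(s) > 1}
        if dupes:
            raise ValidationError(f"duplicate subject ids in manifest: {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def labels(self) -> list[str]:
        return [e.label for e in self.entries]


def _infer_dialect(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".csv":
        return "csv"
    if suffix in (".tsv", ".txt"):
        return "tsv"
    return "abide_1d"  # .1D and anything else whitespace-separated


def read_timeseries(
    path: str | Path,
    dialect: str = "auto",
    subject_id: str | None = None,
    transpose: bool = False,
) -> RoiTimeSeries:
    """Load one subject's ROI table from delimited text.

    Parameters
    ----------
    path : file path
    dialect : {"auto", "abide_1d", "csv", "tsv"}
        ``auto`` infers from the file suffix (.csv, .tsv/.txt, else .1D style).
    subject_id : defaults to the file stem.
    transpose : transpose after reading (for files stored ROIs-by-time).
    """
    path = Path(path)
    if dialect == "auto":
        dialect = _infer_dialect(path)
    if dialect not in _DIALECT_SEP:
        raise ValidationError(
            f"unknown dialect {dialect!r}; expected abide_1d, csv, tsv or auto"
        )
    sep = _DIALECT_SEP[dialect]

    rows: list[list[float]] = []
    labels: list[str] | None = None
    ncol: int | None = None
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        tokens = [t for t in line.split(sep)] if sep else line.split()
        tokens = [t.strip() for t in tokens]
        if not rows and labels is None:
            # first content line: header iff any token is non-numeric
            try:
                first = [float(t) for t in tokens]
            except ValueError:
                labels = tokens
                ncol = len(tokens)
                continue
            rows.append(first)
            ncol = len(first)
            continue
        if ncol is not None and len(tokens) != ncol:
            raise ParseError(
                f"{path}: line {lineno} has {len(tokens)} columns, expected {ncol}"
            )
        try:
            rows.append([float(t) for t in tokens])
        except ValueError as exc:
            raise ParseError(f"{path}: non-numeric cell on line {lineno}: {exc}") from None

    if not rows:
        raise ParseError(f"{path}: no data rows")
    values = np.asarray(rows, dtype=np.float64)
    if transpose:
        values = values.T
    t, m = values.shape
    if m > t and not transpose:
        raise ValidationError(
            f"{path}: {m} columns > {t} rows — more ROIs than time points suggests "
            "a transposed table; pass transpose=True (CLI: --transpose) if so"
        )
    return RoiTimeSeries(
        subject_id=subject_id or path.stem,
        values=values,
        roi_labels=labels if not transpose else None,
    )


def write_timeseries(ts: RoiTimeSeries, path: str | Path, dialect: str = "auto") -> Path:
    """Write a time series in the given dialect (17 significant digits)."""
    path = Path(path)
    if dialect == "auto":
        dialect = _infer_dialect(path)
    sep = _DIALECT_SEP[dialect]
    join = sep if sep is not None else " "
    lines = []
    if dialect == "abide_1d":
        lines.append(f"# subject {ts.subject_id}")
    if ts.roi_labels is not None:
        labels = ts.roi_labels
        if sep is None and any(" " in lab for lab in labels):
            raise ValidationError("abide_1d ROI labels must not contain spaces")
        lines.append(join.join(labels))
    for row in ts.values:
        lines.append(join.join(f"{v:.17g}" for v in row))
    path.write_text("\n".join(lines) + "\n")
    return path


def normalize_label(token: str) -> str:
    key = str(token).strip().lower()
    if key not in LABEL_TOKENS:
        accepted = sorted(set(LABEL_TOKENS))
        raise ValidationError(
            f"unknown label {token!r}; accepted tokens (case-insensitive): {accepted}"
        )
    return LABEL_TOKENS[key]


def read_manifest(path: str | Path) -> SubjectManifest:
    """Read a CSV manifest with columns subject_id, path, label[, site].

    Labels are normalised to ``positive``/``control``; relative paths are
    resolved against the manifest's own directory. Row order is preserved.
    """
    path = Path(path)
    frame = pd.read_csv(path, dtype=str)
    required = {"subject_id", "path", "label"}
    missing = required - set(frame.columns)
    if missing:
        raise ValidationError(f"{path}: manifest missing columns {sorted(missing)}")
    entries = []
    base = path.parent
    for rec in frame.to_dict("records"):
        p = Path(str(rec["path"]))
        if not p.is_absolute():
            p = base / p
        site = rec.get("site")
        entries.append(
            ManifestEntry(
                subject_id=str(rec["subject_id"]),
                path=p,
                label=normalize_label(str(rec["label"])),
                site=None if site is None or pd.isna(site) else str(site),
            )
        )
    return SubjectManifest(entries=entries)


def write_manifest(manifest: SubjectManifest, path: str | Path) -> Path:
    path = Path(path)
    frame = pd.DataFrame(
        {
            "subject_id": [e.subject_id for e in manifest],
            "path": [str(e.path) for e in manifest],
            "label": [e.label for e in manifest],
            "site": [e.site if e.site is not None else "" for e in manifest],
        }
    )
    frame.to_csv(path, index=False)
    return path


def save_archive(path: str | Path, arrays: dict[str, np.ndarray], meta: dict) -> Path:
    """Persist named arrays plus a JSON metadata blob to a single .npz file."""
    path = Path(path)
    payload = {k.replace("/", "__"): np.asarray(v) for k, v in arrays.items()}
    payload["__meta__"] = np.frombuffer(
        json.dumps(meta, sort_keys=True).encode(), dtype=np.uint8
    )
    np.savez(path, **payload)
    return path


def load_archive(path: str | Path) -> tuple[dict[str, np.ndarray], dict]:
    with np.load(Path(path)) as npz:
        meta = json.loads(bytes(npz["__meta__"]).decode())
        arrays = {
            k.replace("__", "/"): npz[k] for k in npz.files if k != "__meta__"
        }
    return arrays, meta
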