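"""Synthetic two-class ROI time-series datasets with block correlation structure.

Each class is defined by a block-structured M x M correlation matrix: ROIs
are partitioned into modules; within-module pairs share one correlation,
cross-module pairs another. The two classes differ only in the
between-module coupling, so a classifier is rewarded exactly for detecting
multi-region (module-level) interaction structure — the signal the
hypergraph high-order network is designed to capture.

Per subject, T time points are drawn i.i.d. from N(0, C_class) and
independent Gaussian observation noise (sd ``noise_sd``) is added, which
attenuates all correlations by 1/(1 + noise_sd^2). Everything is
reproducible from the spec seed, including the bytes of the written files.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .exceptions import ValidationError
from .io import ManifestEntry, RoiTimeSeries, SubjectManifest, write_manifest, write_timeseries

__all__ = ["SyntheticSpec", "block_correlation", "generate_subjects", "generate_dataset"]


@dataclass
class SyntheticSpec:
    """Study conditions for a generated dataset.

    Defaults are the desk-scale conditions used throughout the tests:
    120 subjects (60 per class), 40 ROIs in 4 modules, 150 time points,
    within-module correlation 0.6, between-module correlation 0.1 for
    controls vs 0.5 for cases, observation noise sd 0.2.
    """

    n_per_class: int = 60
    n_rois: int = 40
    n_timepoints: int = 150
    n_modules: int = 4
    within_module_corr: float = 0.6
    between_module_corr_control: float = 0.1
    between_module_corr_case: float = 0.5
    noise_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 1 or self.n_rois < 2 or self.n_timepoints < 3:
            raise ValidationError("need n_per_class >= 1, n_rois >= 2, n_timepoints >= 3")
        if not 1 <= self.n_modules <= self.n_rois:
            raise ValidationError("n_modules must be in [1, n_rois]")
        if not 0 <= self.within_module_corr < 1:
            raise ValidationError("within_module_corr must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        # both class correlation matrices must be positive definite
        for name, c in (
            ("control", self.correlation_matrix("control")),
            ("case", self.correlation_matrix("case")),
        ):
            lam_min = float(np.linalg.eigvalsh(c)[0])
            if lam_min <= 0:
                raise ValidationError(
                    f"{name} correlation matrix is not positive definite "
                    f"(smallest eigenvalue {lam_min:.3e})"
                )

    def module_assignment(self) -> np.ndarray:
        """Near-equal partition of ROIs into modules."""
        return np.array_split(np.arange(self.n_rois), self.n_modules)

    def correlation_matrix(self, which: str) -> np.ndarray:
        between = (
            self.between_module_corr_case
            if which == "case"
            else self.between_module_corr_control
        )
        return block_correlation(
            self.n_rois, self.n_modules, self.within_module_corr, between
        )


def block_correlation(
    n_rois: int, n_modules: int, within: float, between: float
) -> np.ndarray:
    """Block-structured correlation matrix: ``within`` inside modules,
    ``between`` across, unit diagonal."""
    c = np.full((n_rois, n_rois), float(between))
    for block in np.array_split(np.arange(n_rois), n_modules):
        c[np.ix_(block, block)] = within
    np.fill_diagonal(c, 1.0)
    return c


def _draw_subject(
    rng: np.random.Generator, chol: np.ndarray, t: int, noise_sd: float
) -> np.ndarray:
    z = rng.standard_normal((t, chol.shape[0]))
    x = z @ chol.T
    if noise_sd > 0:
        x = x + noise_sd * rng.standard_normal(x.shape)
    return x


def generate_subjects(spec: SyntheticSpec) -> tuple[list[RoiTimeSeries], list[str]]:
    """Draw all subjects in memory; labels are 'positive' (case) / 'control'.

    Subjects are ordered case_000..case_{n-1}, control_000..; the single
    generator stream seeded by ``spec.seed`` makes the draw reproducible.
    """
    rng = np.random.default_rng(spec.seed)
    chol_case = np.linalg.cholesky(spec.correlation_matrix("case"))
    chol_ctrl = np.linalg.cholesky(spec.correlation_matrix("control"))
    subjects: list[RoiTimeSeries] = []
    labels: list[str] = []
    for which, chol, label in (
        ("case", chol_case, "positive"),
        ("control", chol_ctrl, "control"),
    ):
        for i in range(spec.n_per_class):
            values = _draw_subject(rng, chol, spec.n_timepoints, spec.noise_sd)
            subjects.append(
                RoiTimeSeries(subject_id=f"sub-{which}-{i:03d}", values=values)
            )
            labels.append(label)
    return subjects, labels


def generate_dataset(spec: SyntheticSpec, out_dir: str | Path) -> SubjectManifest:
    """Write one .1D file per subject plus a manifest.csv into ``out_dir``.

    Manifest labels use the field tokens ASD/NC (normalised on read).
    Byte-identical across runs with the same spec.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    subjects, labels = generate_subjects(spec)
    entries = []
    for ts, label in zip(subjects, labels):
        fname = f"{ts.subject_id}.1D"
        write_timeseries(ts, out_dir / fname, dialect="abide_1d")
        entries.append(
            ManifestEntry(
                subject_id=ts.subject_id,
                path=out_dir / fname,
                label="positive" if label == "positive" else "control",
            )
        )
    manifest = SubjectManifest(entries=entries)
    # manifest on disk carries the raw field tokens
    raw = SubjectManifest(
        entries=[
            replace(e, label="ASD" if e.label == "positive" else "NC")
            for e in entries
        ]
    )
    write_manifest(raw, out_dir / "manifest.csv")
    return manifest


def null_spec(spec: SyntheticSpec) -> SyntheticSpec:
    """Matched null: case coupling set equal to control coupling."""
    return replace(spec, between_module_corr_case=spec.between_module_corr_control)
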