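"""End-to-end classification under repeated stratified k-fold cross-validation.

Per subject: low-order Pearson FCN -> kNN hypergraph over ROIs -> high-order
association matrix S -> strict-upper-triangle feature vector. Per training
fold: z-score with training statistics, train the stacked autoencoder,
encode, z-score the codes, train the BLS; held-out subjects are pushed
through the frozen fold transforms. Metrics are accuracy, sensitivity,
specificity and precision with the 'positive' class as the positive.

The model/results interface mirrors the fit-then-summarize idiom:

    model = DeepBroadModel.from_manifest("manifest.csv", config)
    results = model.fit()
    print(results.summary())
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import autoencoder as ae
from . import bls as bls_mod
from .connectivity import pearson_fcn, vectorize_upper
from .exceptions import FitError, ValidationError
from .hypergraph import build_knn_hypergraph, ho_features, hypergraph_laplacian
from .io import RoiTimeSeries, SubjectManifest, read_manifest, read_timeseries, save_archive, load_archive

__all__ = [
    "HypergraphConfig",
    "AutoencoderConfig",
    "CvConfig",
    "PipelineConfig",
    "CvResults",
    "DeepBroadModel",
    "run_pipeline",
    "compute_metrics",
    "stratified_folds",
    "extract_subject_features",
]

logger = logging.getLogger(__name__)

METRIC_NAMES = ("accuracy", "sensitivity", "specificity", "precision")


# --------------------------------------------------------------------------- config


@dataclass
class HypergraphConfig:
    k: int = 5
    feature_space: str = "fcn_rows"  # or "timeseries"
    matrix: str = "assoc"  # or "laplacian_norm" | "incidence"


@dataclass
class AutoencoderConfig:
    n_layers: int = 3
    bottleneck: int = 512
    epochs: int = 200
    batch_size: int = 32
    learning_rate: float = 1e-3


@dataclass
class CvConfig:
    n_folds: int = 10
    n_repeats: int = 10
    seed: int = 0


@dataclass
class PipelineConfig:
    hypergraph: HypergraphConfig = field(default_factory=HypergraphConfig)
    autoencoder: AutoencoderConfig = field(default_factory=AutoencoderConfig)
    bls: bls_mod.BlsConfig = field(default_factory=bls_mod.BlsConfig)
    cv: CvConfig = field(default_factory=CvConfig)

    def __post_init__(self) -> None:
        if self.cv.n_folds < 2:
            raise ValidationError("cv.n_folds must be >= 2")
        if self.cv.n_repeats < 1:
            raise ValidationError("cv.n_repeats must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(
            hypergraph=HypergraphConfig(**raw.get("hypergraph", {})),
            autoencoder=AutoencoderConfig(**raw.get("autoencoder", {})),
            bls=bls_mod.BlsConfig(**raw.get("bls", {})),
            cv=CvConfig(**raw.get("cv", {})),
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


# ------------------------------------------------------------------- feature stage


def extract_subject_features(
    ts: RoiTimeSeries, cfg: HypergraphConfig | None = None
) -> np.ndarray:
    """One subject's high-order feature vector.

    ``feature_space`` picks the ROI representation for the kNN distances:
    connectivity profiles (rows of the low-order FCN, default) or the raw
    time-series columns. ``matrix`` picks what is vectorized: the
    association matrix S (default), the normalized Laplacian, or the raw
    incidence matrix H (flattened, as H is not symmetric).
    """
    cfg = cfg or HypergraphConfig()
    fcn = pearson_fcn(ts)
    if cfg.feature_space == "fcn_rows":
        feats = fcn.values
    elif cfg.feature_space == "timeseries":
        feats = ts.values.T  # row per ROI
    else:
        raise ValidationError(f"unknown feature_space {cfg.feature_space!r}")
    hg = build_knn_hypergraph(feats, cfg.k)
    ho = hypergraph_laplacian(hg)
    if cfg.matrix == "assoc":
        return ho_features(ho).values
    if cfg.matrix == "laplacian_norm":
        return vectorize_upper(ho.laplacian_norm).values
    if cfg.matrix == "incidence":
        return hg.incidence.ravel()
    raise ValidationError(f"unknown matrix choice {cfg.matrix!r}")


# ------------------------------------------------------------------------ CV plumbing


def stratified_folds(labels, n_folds: int, seed: int) -> np.ndarray:
    """Deterministic class-stratified fold assignment.

    Returns an integer fold id per subject. Per-class counts across folds
    differ by at most 1; supports n_folds up to N (leave-one-out). Warns
    when n_folds exceeds the smallest class count (some folds then miss a
    class and per-fold metrics can be undefined).
    """
    labels = np.asarray(labels)
    n = len(labels)
    if n_folds < 2:
        raise ValidationError("n_folds must be >= 2")
    if n_folds > n:
        raise ValidationError(f"n_folds={n_folds} exceeds {n} subjects")
    classes, counts = np.unique(labels, return_counts=True)
    if n_folds > counts.min():
        warnings.warn(
            f"n_folds={n_folds} exceeds smallest class count {counts.min()}; "
            "some folds will miss a class",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    fold = np.empty(n, dtype=np.int64)
    start = 0
    for cls in classes:
        idx = np.flatnonzero(labels == cls)
        idx = idx[rng.permutation(len(idx))]
        for j, i in enumerate(idx):
            fold[i] = (start + j) % n_folds
        start = (start + len(idx)) % n_folds
    return fold


def compute_metrics(tp: int, fp: int, tn: int, fn: int) -> dict[str, float]:
    """ACC/SEN/SPE/precision from confusion counts.

    A zero denominator yields NaN (undefined, not 0) with a logged reason.
    """
    if min(tp, fp, tn, fn) < 0 or tp + fp + tn + fn == 0:
        raise ValidationError("confusion counts must be non-negative with positive sum")
    out = {"accuracy": (tp + tn) / (tp + fp + tn + fn)}
    for name, num, den, reason in (
        ("sensitivity", tp, tp + fn, "no actual positives"),
        ("specificity", tn, tn + fp, "no actual controls"),
        ("precision", tp, tp + fp, "no predicted positives"),
    ):
        if den == 0:
            logger.info("metric %s undefined: %s", name, reason)
            out[name] = float("nan")
        else:
            out[name] = num / den
    return out


@dataclass
class FoldModel:
    """Frozen per-fold transforms: scaler -> autoencoder -> scaler -> BLS."""

    feat_mean: np.ndarray
    feat_std: np.ndarray
    ae_model: ae.AutoencoderModel
    code_mean: np.ndarray
    code_std: np.ndarray
    bls_model: bls_mod.BlsModel

    def transform(self, X: np.ndarray) -> np.ndarray:
        z = (X - self.feat_mean) / self.feat_std
        codes = ae.encode(self.ae_model, z)
        return (codes - self.code_mean) / self.code_std

    def predict(self, X: np.ndarray) -> np.ndarray:
        labels, _ = bls_mod.predict_bls(self.bls_model, self.transform(X))
        return labels

    def save(self, path: str | Path) -> Path:
        arrays = {"scaler/mean": self.feat_mean, "scaler/std": self.feat_std,
                  "scaler/code_mean": self.code_mean, "scaler/code_std": self.code_std,
                  "bls/W_out": self.bls_model.W_out}
        for i, (w, b) in enumerate(zip(self.ae_model.enc_W, self.ae_model.enc_b)):
            arrays[f"ae/enc_W_{i}"], arrays[f"ae/enc_b_{i}"] = w, b
        for i, (w, b) in enumerate(zip(self.ae_model.dec_W, self.ae_model.dec_b)):
            arrays[f"ae/dec_W_{i}"], arrays[f"ae/dec_b_{i}"] = w, b
        for i, (w, b) in enumerate(self.bls_model.map_params):
            arrays[f"bls/map_W_{i}"], arrays[f"bls/map_b_{i}"] = w, b
        for i, (w, b) in enumerate(self.bls_model.enh_params):
            arrays[f"bls/enh_W_{i}"], arrays[f"bls/enh_b_{i}"] = w, b
        meta = {
            "layer_dims": self.ae_model.layer_dims,
            "class_codes": self.bls_model.class_codes,
            "ae_seed": self.ae_model.seed,
            "bls_seed": self.bls_model.seed,
            "bls_config": asdict(self.bls_model.config),
        }
        return save_archive(path, arrays, meta)

    @classmethod
    def load(cls, path: str | Path) -> "FoldModel":
        arrays, meta = load_archive(path)
        model = ae.AutoencoderModel(layer_dims=meta["layer_dims"], seed=meta["ae_seed"])
        i = 0
        while f"ae/enc_W_{i}" in arrays:
            model.enc_W.append(arrays[f"ae/enc_W_{i}"])
            model.enc_b.append(arrays[f"ae/enc_b_{i}"])
            i += 1
        i = 0
        while f"ae/dec_W_{i}" in arrays:
            model.dec_W.append(arrays[f"ae/dec_W_{i}"])
            model.dec_b.append(arrays[f"ae/dec_b_{i}"])
            i += 1
        blsm = bls_mod.BlsModel(
            config=bls_mod.BlsConfig(**meta["bls_config"]),
            seed=meta["bls_seed"],
            input_dim=model.bottleneck_dim,
            class_codes=meta["class_codes"],
            W_out=arrays["bls/W_out"],
        )
        i = 0
        while f"bls/map_W_{i}" in arrays:
            blsm.map_params.append((arrays[f"bls/map_W_{i}"], arrays[f"bls/map_b_{i}"]))
            i += 1
        i = 0
        while f"bls/enh_W_{i}" in arrays:
            blsm.enh_params.append((arrays[f"bls/enh_W_{i}"], arrays[f"bls/enh_b_{i}"]))
            i += 1
        return cls(
            feat_mean=arrays["scaler/mean"],
            feat_std=arrays["scaler/std"],
            ae_model=model,
            code_mean=arrays["scaler/code_mean"],
            code_std=arrays["scaler/code_std"],
            bls_model=blsm,
        )


def _safe_std(x: np.ndarray) -> np.ndarray:
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0  # constant feature: leave centered at 0
    return sd


def _derived_seeds(base: int, repeat: int, fold: int) -> tuple[int, int]:
    ss = np.random.SeedSequence([int(base), int(repeat), int(fold)])
    s = ss.generate_state(2)
    return int(s[0] % 2**31), int(s[1] % 2**31)


def train_fold(
    X_train: np.ndarray, y_train: np.ndarray, cfg: PipelineConfig, ae_seed: int, bls_seed: int
) -> FoldModel:
    """Fit scaler, autoencoder and BLS on training subjects only."""
    y_train = np.asarray(y_train)
    if len(np.unique(y_train)) < 2:
        raise FitError(
            "training split contains a single class; re-stratify or change cv.seed"
        )
    mean = X_train.mean(axis=0)
    std = _safe_std(X_train)
    z = (X_train - mean) / std
    dims = ae.geometric_dims(
        z.shape[1], cfg.autoencoder.bottleneck, cfg.autoencoder.n_layers
    )
    model, history = ae.fit_autoencoder(
        z,
        dims,
        ae.TrainConfig(
            epochs=cfg.autoencoder.epochs,
            batch_size=cfg.autoencoder.batch_size,
            learning_rate=cfg.autoencoder.learning_rate,
            seed=ae_seed,
        ),
    )
    logger.info(
        "fold autoencoder dims=%s loss %0.4f -> %0.4f",
        dims,
        history[0],
        history[-1],
    )
    codes = ae.encode(model, z)
    code_mean = codes.mean(axis=0)
    code_std = _safe_std(codes)
    codes = (codes - code_mean) / code_std
    blsm = bls_mod.fit_bls(codes, y_train, cfg.bls, seed=bls_seed)
    return FoldModel(
        feat_mean=mean,
        feat_std=std,
        ae_model=model,
        code_mean=code_mean,
        code_std=code_std,
        bls_model=blsm,
    )


# ----------------------------------------------------------------------- results


@dataclass
class CvResults:
    """Cross-validation outcome: per-fold confusion counts and metrics.

    ``frame`` has one row per repeat x fold with columns
    repeat, fold, n_test, tp, fp, tn, fn, accuracy, sensitivity,
    specificity, precision. Aggregates are means/sds over all cells
    (NaN-aware: undefined per-fold metrics are excluded).
    """

    frame: pd.DataFrame
    config: PipelineConfig
    n_subjects: int
    class_counts: dict[str, int]
    n_features: int
    predictions: pd.DataFrame | None = None
    fold_models: dict[tuple[int, int], FoldModel] | None = None

    @property
    def mean_metrics(self) -> dict[str, float]:
        return {m: float(np.nanmean(self.frame[m])) for m in METRIC_NAMES}

    @property
    def sd_metrics(self) -> dict[str, float]:
        return {m: float(np.nanstd(self.frame[m], ddof=1)) for m in METRIC_NAMES}

    def pooled_metrics(self) -> pd.DataFrame:
        """Metrics from confusion counts pooled within each repeat (the
        robust aggregation when folds are tiny, e.g. leave-one-out)."""
        rows = []
        for rep, grp in self.frame.groupby("repeat"):
            counts = {c: int(grp[c].sum()) for c in ("tp", "fp", "tn", "fn")}
            rows.append({"repeat": rep, **counts, **compute_metrics(**counts)})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        mean, sd = self.mean_metrics, self.sd_metrics
        cls = ", ".join(f"{k}: {v}" for k, v in sorted(self.class_counts.items()))
        lines = [
            "Deep-broad brain-network classification — cross-validation summary",
            "=" * 66,
            f"subjects: {self.n_subjects} ({cls})",
            f"high-order features per subject: {self.n_features}",
            f"folds: {self.config.cv.n_folds}  repeats: {self.config.cv.n_repeats}"
            f"  seed: {self.config.cv.seed}",
            f"hypergraph k: {self.config.hypergraph.k}"
            f"  AE layers: {self.config.autoencoder.n_layers}"
            f"  BLS nodes: {self.config.bls.n_map_groups}x"
            f"{self.config.bls.nodes_per_group}+"
            f"{self.config.bls.n_enh_groups}x{self.config.bls.enh_nodes_per_group}",
            "-" * 66,
            f"{'metric':<14}{'mean %':>10}{'sd %':>10}",
        ]
        for m in METRIC_NAMES:
            lines.append(f"{m:<14}{100 * mean[m]:>10.1f}{100 * sd[m]:>10.1f}")
        return "\n".join(lines)

    def plot_fold_accuracy(self, ax=None):
        """Diagnostic strip plot of per-fold accuracy by repeat."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(self.frame["repeat"], self.frame["accuracy"], alpha=0.6)
        ax.set_xlabel("repeat")
        ax.set_ylabel("fold accuracy")
        ax.set_ylim(0, 1)
        return ax


# -------------------------------------------------------------------------- model


class DeepBroadModel:
    """Deep-broad classifier over high-order brain connectivity features.

    Built from per-subject feature vectors (or raw time series / a
    manifest via the constructors); ``fit()`` runs repeated stratified
    k-fold cross-validation and returns :class:`CvResults`.
    """

    def __init__(
        self,
        features: np.ndarray,
        labels,
        config: PipelineConfig | None = None,
        subject_ids: list[str] | None = None,
    ) -> None:
        self.config = config or PipelineConfig()
        self.features = np.asarray(features, dtype=np.float64)
        self.labels = np.asarray(labels)
        if self.features.ndim != 2:
            raise ValidationError("features must be N x D")
        if len(self.labels) != self.features.shape[0]:
            raise ValidationError("labels length must match feature rows")
        classes, counts = np.unique(self.labels, return_counts=True)
        if len(classes) < 2 or counts.min() < 2:
            raise FitError("need at least 2 subjects in each of 2 classes")
        self.subject_ids = subject_ids or [
            f"sub-{i:04d}" for i in range(self.features.shape[0])
        ]

    @classmethod
    def from_timeseries(
        cls,
        subjects: list[RoiTimeSeries],
        labels,
        config: PipelineConfig | None = None,
    ) -> "DeepBroadModel":
        config = config or PipelineConfig()
        sizes = {ts.n_rois for ts in subjects}
        if len(sizes) > 1:
            offenders = [
                f"{ts.subject_id}({ts.n_rois})" for ts in subjects
            ]
            raise ValidationError(
                f"inconsistent ROI counts across subjects: {offenders}"
            )
        feats = np.vstack(
            [extract_subject_features(ts, config.hypergraph) for ts in subjects]
        )
        return cls(
            feats,
            labels,
            config,
            subject_ids=[ts.subject_id for ts in subjects],
        )

    @classmethod
    def from_manifest(
        cls, manifest: SubjectManifest | str | Path, config: PipelineConfig | None = None
    ) -> "DeepBroadModel":
        if not isinstance(manifest, SubjectManifest):
            manifest = read_manifest(manifest)
        subjects = [
            read_timeseries(e.path, subject_id=e.subject_id) for e in manifest
        ]
        return cls.from_timeseries(subjects, manifest.labels, config)

    def fit(self, keep_models: bool = False) -> CvResults:
        """Repeated stratified k-fold CV; no test-fold information reaches
        any fitted transform."""
        cfg = self.config
        y = self.labels
        rows = []
        preds = []
        models: dict[tuple[int, int], FoldModel] = {}
        for rep in range(cfg.cv.n_repeats):
            fold_seed = int(
                np.random.SeedSequence([cfg.cv.seed, rep]).generate_state(1)[0] % 2**31
            )
            fold_of = stratified_folds(y, cfg.cv.n_folds, fold_seed)
            for f in range(cfg.cv.n_folds):
                test = fold_of == f
                train = ~test
                ae_seed, bls_seed = _derived_seeds(cfg.cv.seed, rep, f)
                fm = train_fold(self.features[train], y[train], cfg, ae_seed, bls_seed)
                pred = fm.predict(self.features[test])
                truth = y[test]
                tp = int(np.sum((pred == "positive") & (truth == "positive")))
                fp = int(np.sum((pred == "positive") & (truth == "control")))
                tn = int(np.sum((pred == "control") & (truth == "control")))
                fn = int(np.sum((pred == "control") & (truth == "positive")))
                rows.append(
                    {
                        "repeat": rep,
                        "fold": f,
                        "n_test": int(test.sum()),
                        "tp": tp,
                        "fp": fp,
                        "tn": tn,
                        "fn": fn,
                        **compute_metrics(tp, fp, tn, fn),
                    }
                )
                for sid, t, p in zip(
                    np.asarray(self.subject_ids, dtype=object)[test], truth, pred
                ):
                    preds.append(
                        {
                            "repeat": rep,
                            "fold": f,
                            "subject_id": sid,
                            "true": t,
                            "predicted": p,
                        }
                    )
                if keep_models:
                    models[(rep, f)] = fm
                logger.info(
                    "repeat %d fold %d: n_test=%d acc=%.3f",
                    rep,
                    f,
                    int(test.sum()),
                    rows[-1]["accuracy"],
                )
        classes, counts = np.unique(y, return_counts=True)
        return CvResults(
            frame=pd.DataFrame(rows),
            config=cfg,
            n_subjects=len(y),
            class_counts={str(c): int(n) for c, n in zip(classes, counts)},
            n_features=self.features.shape[1],
            predictions=pd.DataFrame(preds),
            fold_models=models if keep_models else None,
        )


def run_pipeline(
    manifest: SubjectManifest | str | Path,
    config: PipelineConfig | None = None,
    keep_models: bool = False,
) -> CvResults:
    """Functional wrapper: manifest in, cross-validated results out."""
    return DeepBroadModel.from_manifest(manifest, config).fit(keep_models=keep_models)


def metrics_from_predictions(predictions: pd.DataFrame) -> pd.DataFrame:
    """Recompute the per-fold metric table from saved per-subject predictions."""
    rows = []
    for (rep, f), grp in predictions.groupby(["repeat", "fold"]):
        tp = int(np.sum((grp["predicted"] == "positive") & (grp["true"] == "positive")))
        fp = int(np.sum((grp["predicted"] == "positive") & (grp["true"] == "control")))
        tn = int(np.sum((grp["predicted"] == "control") & (grp["true"] == "control")))
        fn = int(np.sum((grp["predicted"] == "control") & (grp["true"] == "positive")))
        rows.append(
            {
                "repeat": rep,
                "fold": f,
                "n_test": len(grp),
                "tp": tp,
                "fp": fp,
                "tn": tn,
                "fn": fn,
                **compute_metrics(tp, fp, tn, fn),
            }
        )
    return pd.DataFrame(rows)
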