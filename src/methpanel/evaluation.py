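"""ROC/AUC evaluation, PCA QC projection, and end-to-end orchestration.

The classifier is judged by receiver-operating-characteristic analysis on
the held-out test partition only: sweep a threshold over the distinct
predicted scores, trace (false-positive rate, true-positive rate) points,
and integrate the curve with the trapezoidal rule to get the AUC.

A two-component PCA projection of the continuous beta values serves as a
QC visualization (do cancer and normal samples separate? are there swapped
or aberrant samples?); it uses training + validation samples only, since
the test partition is excluded from all visualization.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio
from . import network, preprocessing, selection
from .core import CANCER, BinaryMatrix, CpGPanel, LabeledBetaMatrix, PipelineError
from .synthetic import CohortConfig, simulate_cohort

logger = logging.getLogger("methpanel")


@dataclass
class ROCResult:
    """ROC points over all score thresholds plus the trapezoidal AUC."""

    points: pd.DataFrame  # columns: threshold, fpr, tpr
    auc: float

    def __post_init__(self) -> None:
        fpr = self.points["fpr"].to_numpy()
        tpr = self.points["tpr"].to_numpy()
        if (np.diff(fpr) < -1e-12).any() or (np.diff(tpr) < -1e-12).any():
            raise PipelineError("ROC points must be monotone non-decreasing")


def roc_curve(scores, labels) -> ROCResult:
    """ROC curve from continuous scores and Cancer/Normal labels.

    Thresholds sweep the distinct score values in descending order (ties
    grouped, one point per distinct score), with anchor points (0, 0) and
    (1, 1); positive = Cancer.  AUC is the trapezoidal integral over the
    curve.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(pd.Series(labels) == CANCER, dtype=bool)
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise PipelineError("ROC analysis needs both classes present")

    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_y = y[order]
    tp = np.cumsum(sorted_y)
    fp = np.cumsum(~sorted_y)
    distinct = np.flatnonzero(np.r_[np.diff(sorted_scores) != 0, True])
    points = pd.DataFrame(
        {
            "threshold": np.r_[np.inf, sorted_scores[distinct]],
            "fpr": np.r_[0.0, fp[distinct] / n_neg],
            "tpr": np.r_[0.0, tp[distinct] / n_pos],
        }
    )
    auc = float(np.trapezoid(points["tpr"], points["fpr"]))
    return ROCResult(points=points, auc=auc)


def pca_project(matrix: LabeledBetaMatrix, k: int = 2):
    """Mean-centered projection of samples onto the top-k principal axes.

    Returns ``(coordinates, explained_variance)``: an n x k DataFrame of
    sample scores (columns PC1..PCk) and the per-component variances in
    non-increasing order.  Sign convention: each axis is flipped so its
    largest-magnitude loading is positive.
    """
    if matrix.values.isna().any().any():
        raise PipelineError("PCA requires a complete matrix; impute first")
    X = matrix.values.to_numpy(dtype=float)
    n, p = X.shape
    if n < 2:
        raise PipelineError("PCA needs at least 2 samples")
    if k > min(n, p):
        raise PipelineError(f"k={k} exceeds min(n, p)={min(n, p)}")
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    for i in range(k):
        j = int(np.argmax(np.abs(Vt[i])))
        if Vt[i, j] < 0:
            Vt[i] *= -1
            U[:, i] *= -1
    coords = pd.DataFrame(
        U[:, :k] * s[:k],
        index=matrix.values.index,
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    explained = (s[:k] ** 2) / (n - 1)
    return coords, explained


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Everything one run needs: data source, stage parameters, seeds."""

    cohort: CohortConfig | None = None  # simulate when set...
    manifest: str | None = None  # ...or read files listed in this manifest
    site_na_thresh: float = preprocessing.DEFAULT_NA_THRESHOLD
    patient_na_thresh: float = preprocessing.DEFAULT_NA_THRESHOLD
    cutoff: float = preprocessing.DEFAULT_CUTOFF
    fractions: tuple[float, float, float] = preprocessing.DEFAULT_FRACTIONS
    min_panel: int = 10
    max_runs: int = 50
    #: fit the selection trees on training samples only (default) or on
    #: pooled training + validation samples
    select_on_validation: bool = False
    architecture: str = "A"
    train_config: network.TrainConfig = field(default_factory=network.TrainConfig)
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if (self.cohort is None) == (self.manifest is None):
            raise PipelineError(
                "configure exactly one data source: cohort (simulate) or manifest"
            )

    @property
    def split_seed(self) -> int:
        return (self.seed + 1) % 2**31

    @property
    def net_seed(self) -> int:
        return (self.seed + 2) % 2**31


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute ingest -> preprocess -> select -> train -> evaluate.

    Returns a JSON-serializable report holding the panel, counts dropped at
    each stage, QC moments, PCA coordinates, the validation and test AUCs
    and every seed used.  The quarantined test partition is touched exactly
    once, in the final ROC step.  When ``config.out_dir`` is set the panel
    TSV, model JSON, ROC points TSV and the report itself are written
    there.
    """
    stage = "ingest"
    try:
        if config.cohort is not None:
            matrix = simulate_cohort(config.cohort)
        else:
            matrix = mio.read_cohort(config.manifest)

        stage = "preprocess"
        matrix = preprocessing.drop_unmapped_sites(matrix)
        matrix, filter_report = preprocessing.filter_missing(
            matrix, config.site_na_thresh, config.patient_na_thresh
        )
        matrix = preprocessing.impute_site_mean(matrix)
        split = preprocessing.split_dataset(
            matrix, fractions=config.fractions, seed=config.split_seed
        )
        train_val = split.train_validation()
        moments = preprocessing.group_moments(train_val)
        pca_coords, pca_var = pca_project(train_val, k=2)

        stage = "select"
        select_input = train_val if config.select_on_validation else split.train
        binary_select = preprocessing.binarize(select_input, cutoff=config.cutoff)
        raw_panel = selection.iterative_select(
            binary_select, min_panel=config.min_panel, max_runs=config.max_runs
        )
        panel = selection.refine_panel(raw_panel, train_val, cutoff=config.cutoff)
        if len(panel) == 0:
            logger.warning(
                "run_pipeline: separation-score filter removed every selected "
                "site; falling back to the unrefined panel (no informative "
                "signal in this cohort?)"
            )
            panel = CpGPanel(table=raw_panel.table.copy(), excluded=panel.excluded)

        stage = "train"
        arch = network.MLPArchitecture.preset(config.architecture)
        binary_train = preprocessing.binarize(split.train, cutoff=config.cutoff)
        features_train = binary_train.select_sites(panel.site_ids)
        model = network.init_network(
            arch, n_inputs=len(panel), seed=config.net_seed,
            feature_names=panel.site_ids,
        )
        model, history = network.train(model, features_train, config.train_config)

        stage = "evaluate"
        binary_val = preprocessing.binarize(split.validation, cutoff=config.cutoff)
        val_scores = network.predict_scores(model, binary_val.select_sites(panel.site_ids))
        val_roc = roc_curve(val_scores, split.validation.labels)

        # the single permitted touch of the quarantined test partition
        binary_test = preprocessing.binarize(split.test, cutoff=config.cutoff)
        test_scores = network.predict_scores(model, binary_test.select_sites(panel.site_ids))
        test_roc = roc_curve(test_scores, split.test.labels)
    except PipelineError as exc:
        raise PipelineError(f"[stage {stage}] {exc}") from exc

    report = {
        "tissue": matrix.tissue,
        "counts": {
            "samples": matrix.n_samples,
            "sites": matrix.n_sites,
            **filter_report,
            "split_sizes": list(split.sizes),
            "panel_selected": len(raw_panel),
            "panel_retained": len(panel),
            "panel_excluded": len(panel.excluded),
            "epochs_run": len(history),
        },
        "seeds": {
            "pipeline": config.seed,
            "cohort": None if config.cohort is None else config.cohort.seed,
            "split": config.split_seed,
            "network": config.net_seed,
        },
        "panel": panel.table.to_dict(orient="records"),
        "panel_excluded": panel.excluded.to_dict(orient="records"),
        "qc": {
            "group_moments": moments.round(6).to_dict(orient="index"),
            "pca_explained_variance": [float(v) for v in pca_var],
        },
        "validation_auc": val_roc.auc,
        "test_auc": test_roc.auc,
        "final_train_loss": history[-1] if history else None,
        "test_partition_reads": 1,
    }

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        mio.write_panel(panel, out / "panel.tsv", include_excluded=True)
        model.to_json(out / "model.json")
        test_roc.points.to_csv(out / "roc_test.tsv", sep="\t", index=False)
        pca_coords.assign(label=train_val.labels).to_csv(
            out / "pca_train_validation.tsv", sep="\t", index_label="sample_id"
        )
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report


def plot_roc(roc: ROCResult, path) -> None:
    """Save a single-panel ROC plot with the AUC in the legend."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(roc.points["fpr"], roc.points["tpr"], label=f"AUC = {roc.auc:.3f}")
    ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_pca(coords: pd.DataFrame, labels: pd.Series, path) -> None:
    """Scatter of the 2-PC projection colored by Cancer/Normal label."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 4))
    for label, color in ((CANCER, "tab:red"), ("Normal", "tab:blue")):
        mask = (labels == label).to_numpy()
        ax.scatter(coords.iloc[mask, 0], coords.iloc[mask, 1], s=8, c=color, label=label)
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
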