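"""Cleaning, imputation, binarization, splitting and distribution QC.

The stages run in a fixed order that matters scientifically:

1. drop probes with genomic position ``"*"`` (non-existent on the build);
2. discard CpG sites with more than 15% NA, THEN patients with more than
   15% NA — sites first because the array has far more sites than
   patients, so dropping a site loses less information;
3. impute remaining NAs with the site's arithmetic mean across the
   cohort (computed before splitting; this is deliberate fidelity to the
   published procedure and is flagged as mild train/test leakage — a
   split-first mode is available);
4. binarize at the 0.3 cutoff (beta >= 0.3 is methylated);
5. randomly split 70/20/10 into train/validation/test, the test partition
   quarantined from all fitting and visualization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    UNMAPPED_POSITION,
    BinaryMatrix,
    LabeledBetaMatrix,
    PipelineError,
)

logger = logging.getLogger("methpanel")

DEFAULT_NA_THRESHOLD = 0.15
DEFAULT_CUTOFF = 0.3
DEFAULT_FRACTIONS = (0.70, 0.20, 0.10)


def drop_unmapped_sites(matrix: LabeledBetaMatrix) -> LabeledBetaMatrix:
    """Remove all sites whose position is the ``"*"`` sentinel."""
    mapped = matrix.positions["position"] != UNMAPPED_POSITION
    n_dropped = int((~mapped).sum())
    if mapped.sum() == 0:
        raise PipelineError("all sites are unmapped ('*'); nothing left to analyze")
    if n_dropped:
        logger.info("drop_unmapped_sites: removed %d '*' sites", n_dropped)
    return matrix.select_sites(matrix.positions.index[mapped])


def filter_missing(
    matrix: LabeledBetaMatrix,
    site_thresh: float = DEFAULT_NA_THRESHOLD,
    patient_thresh: float = DEFAULT_NA_THRESHOLD,
) -> tuple[LabeledBetaMatrix, dict]:
    """Two sequential NA-fraction filters: sites first, then patients.

    A site (column) is dropped when its NA fraction is strictly greater
    than ``site_thresh``; patients (rows) are then filtered the same way
    against ``patient_thresh`` on the reduced matrix.  The order is not
    commutable: dropping a bad site changes every patient's NA fraction.

    Returns the filtered matrix and a ``{"sites_dropped": ..,
    "patients_dropped": ..}`` report.
    """
    for name, thr in (("site_thresh", site_thresh), ("patient_thresh", patient_thresh)):
        if not 0.0 < thr < 1.0:
            raise PipelineError(f"{name} must lie in (0, 1), got {thr}")
    na = matrix.values.isna()
    site_frac = na.mean(axis=0)
    keep_sites = site_frac <= site_thresh  # "more than 15%" is strict
    reduced = matrix.select_sites(matrix.values.columns[keep_sites])

    patient_frac = reduced.values.isna().mean(axis=1)
    keep_patients = patient_frac <= patient_thresh
    result = reduced.select_samples(reduced.values.index[keep_patients])

    report = {
        "sites_dropped": int((~keep_sites).sum()),
        "patients_dropped": int((~keep_patients).sum()),
    }
    if result.n_samples == 0 or result.n_sites == 0:
        raise PipelineError("missingness filter removed all samples or sites")
    logger.info(
        "filter_missing: dropped %(sites_dropped)d sites then %(patients_dropped)d patients",
        report,
    )
    return result, report


def impute_site_mean(matrix: LabeledBetaMatrix) -> LabeledBetaMatrix:
    """Replace each NA with the arithmetic mean of its site's observed values.

    The mean pools all retained samples of the cohort (the per-tissue
    matrix), cancer and normal alike, and is computed before the
    train/validation/test split.
    """
    values = matrix.values
    if not values.isna().any().any():
        return matrix
    site_means = values.mean(axis=0, skipna=True)
    if site_means.isna().any():
        bad = site_means.index[site_means.isna()].tolist()[:5]
        raise PipelineError(f"sites with no observed values cannot be imputed: {bad}")
    return replace(matrix, values=values.fillna(site_means))


def binarize(matrix: LabeledBetaMatrix, cutoff: float = DEFAULT_CUTOFF) -> BinaryMatrix:
    """Methylation call per entry: 1 iff beta >= cutoff, else 0."""
    if matrix.values.isna().any().any():
        raise PipelineError("matrix contains missing values; impute before binarizing")
    calls = (matrix.values >= cutoff).astype(np.int8)
    return BinaryMatrix(
        values=calls,
        labels=matrix.labels.copy(),
        positions=matrix.positions.copy(),
        cutoff=cutoff,
        tissue=matrix.tissue,
        is_test=matrix.is_test,
    )


@dataclass
class SplitDataset:
    """Disjoint train/validation/test partitions of one cohort."""

    train: LabeledBetaMatrix
    validation: LabeledBetaMatrix
    test: LabeledBetaMatrix
    fractions: tuple[float, float, float]
    seed: int

    @property
    def sizes(self) -> tuple[int, int, int]:
        return (self.train.n_samples, self.validation.n_samples, self.test.n_samples)

    def train_validation(self) -> LabeledBetaMatrix:
        """Concatenated train + validation samples (panel statistics, QC)."""
        values = pd.concat([self.train.values, self.validation.values])
        labels = pd.concat([self.train.labels, self.validation.labels])
        return replace(self.train, values=values, labels=labels)


def split_sizes(n: int, fractions=DEFAULT_FRACTIONS) -> tuple[int, int, int]:
    """Partition sizes: round train and validation to nearest, remainder to test.

    This is the rule that reproduces the published 70/20/10 counts for all
    three tissue cohorts (439 -> 307/88/44, 484 -> 339/97/48,
    542 -> 379/108/55).
    """
    f_train, f_val, f_test = fractions
    if abs(f_train + f_val + f_test - 1.0) > 1e-9:
        raise PipelineError(f"fractions must sum to 1, got {fractions}")
    n_train = int(np.floor(f_train * n + 0.5))
    n_val = int(np.floor(f_val * n + 0.5))
    n_test = n - n_train - n_val
    if min(n_train, n_val, n_test) < 1:
        raise PipelineError(f"n={n} too small to split into three non-empty sets")
    return n_train, n_val, n_test


def split_dataset(
    matrix: LabeledBetaMatrix,
    fractions=DEFAULT_FRACTIONS,
    seed: int = 0,
    stratify: bool = False,
) -> SplitDataset:
    """Randomly partition samples 70/20/10 under ``seed``.

    The split is unstratified by default; ``stratify=True`` applies the
    size rule within each label group instead.  The test partition is
    flagged so downstream fitting refuses it.
    """
    n = matrix.n_samples
    n_train, n_val, n_test = split_sizes(n, fractions)
    rng = np.random.default_rng(seed)
    ids = np.array(matrix.sample_ids)

    if stratify:
        train_ids, val_ids, test_ids = [], [], []
        for label in sorted(matrix.labels.unique()):
            group = ids[matrix.label_mask(label)]
            g_train, g_val, _ = split_sizes(len(group), fractions)
            perm = rng.permutation(group)
            train_ids.extend(perm[:g_train])
            val_ids.extend(perm[g_train : g_train + g_val])
            test_ids.extend(perm[g_train + g_val :])
    else:
        perm = rng.permutation(ids)
        train_ids = perm[:n_train]
        val_ids = perm[n_train : n_train + n_val]
        test_ids = perm[n_train + n_val :]

    return SplitDataset(
        train=matrix.select_samples(train_ids, is_test=False),
        validation=matrix.select_samples(val_ids, is_test=False),
        test=matrix.select_samples(test_ids, is_test=True),
        fractions=tuple(fractions),
        seed=seed,
    )


def group_moments(matrix: LabeledBetaMatrix) -> pd.DataFrame:
    """First four moments of the pooled beta values per label group.

    Conventions: population variance (ddof=0), standardized skewness and
    excess kurtosis.  For a constant group, skewness and kurtosis are
    undefined and reported as NaN.  Used as a QC check that the cancer and
    normal value distributions are comparable.
    """
    if matrix.values.isna().all().all():
        raise PipelineError("no observed values for moment computation")
    rows = {}
    for label in sorted(matrix.labels.unique()):
        pooled = matrix.values.loc[matrix.label_mask(label)].to_numpy().ravel()
        pooled = pooled[~np.isnan(pooled)]
        if pooled.size == 0:
            raise PipelineError(f"group {label!r} has no observed values")
        var = float(np.var(pooled))
        if var == 0.0:
            skew = kurt = float("nan")
        else:
            skew = float(stats.skew(pooled, bias=True))
            kurt = float(stats.kurtosis(pooled, fisher=True, bias=True))
        rows[label] = {
            "mean": float(np.mean(pooled)),
            "variance": var,
            "skewness": skew,
            "kurtosis": kurt,
        }
    return pd.DataFrame(rows).T
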