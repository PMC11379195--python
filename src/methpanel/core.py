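"""Shared containers for the methylation classification pipeline.

The central object is :class:`LabeledBetaMatrix`: a samples x CpG-sites
matrix of beta values (methylation fractions in [0, 1], possibly missing)
together with per-sample Cancer/Normal labels and per-site genomic
coordinates.  :class:`BinaryMatrix` is its methylated/unmethylated
counterpart after thresholding, and :class:`CpGPanel` holds the selected
marker sites with their group statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Sentinel chromosome position used by GDC-style files for probes that do
#: not map to the genome build ("non-existent" probes).
UNMAPPED_POSITION = "*"

#: Class labels, fixed throughout the pipeline.
CANCER = "Cancer"
NORMAL = "Normal"

PANEL_COLUMNS = [
    "probe_id",
    "chromosome",
    "position",
    "cancer_median",
    "normal_median",
    "cancer_sd",
    "normal_sd",
    "separation_score",
    "selection_order",
]


class PipelineError(Exception):
    """Base error for all pipeline failures."""


class ConfigError(PipelineError):
    """Invalid configuration value; the message names the offending field."""


class ParseError(PipelineError):
    """Malformed input file; the message carries the line number."""


def _check_unique(ids, what: str) -> None:
    ids = pd.Index(ids)
    if ids.has_duplicates:
        dupes = ids[ids.duplicated()].unique().tolist()[:5]
        raise ValueError(f"duplicate {what}: {dupes}")


@dataclass
class LabeledBetaMatrix:
    """Samples x sites matrix of beta values with labels and coordinates.

    Parameters
    ----------
    values
        DataFrame indexed by sample id, columns are CpG probe ids.  Entries
        are beta values in [0, 1]; missing measurements are NaN.
    labels
        Series mapping sample id -> "Cancer" or "Normal", aligned to
        ``values.index``.
    positions
        DataFrame indexed by probe id with columns ``chromosome`` and
        ``position`` (kept verbatim as strings; ``"*"`` marks unmapped
        probes).
    tissue
        Free-text tissue tag (e.g. "bladder").
    is_test
        True when this matrix is the quarantined test partition; model
        fitting refuses such matrices.
    """

    values: pd.DataFrame
    labels: pd.Series
    positions: pd.DataFrame
    tissue: str = ""
    is_test: bool = False

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "sample ids")
        _check_unique(self.values.columns, "site ids")
        if len(self.labels) != self.values.shape[0]:
            raise ValueError(
                f"labels length {len(self.labels)} != sample count "
                f"{self.values.shape[0]}"
            )
        self.labels = self.labels.reindex(self.values.index)
        if self.labels.isna().any():
            missing = self.labels.index[self.labels.isna()].tolist()[:5]
            raise ValueError(f"samples missing labels: {missing}")
        bad = set(self.labels.unique()) - {CANCER, NORMAL}
        if bad:
            raise ValueError(f"labels must be Cancer/Normal, got {sorted(bad)}")
        self.positions = self.positions.reindex(self.values.columns)
        vals = self.values.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            out_of_range = np.nanmin(vals, initial=0.0) < 0.0 or np.nanmax(
                vals, initial=1.0
            ) > 1.0
        if out_of_range:
            raise ValueError("beta values must lie in [0, 1]")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_sites(self) -> int:
        return self.values.shape[1]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def site_ids(self) -> list[str]:
        return list(self.values.columns)

    def select_sites(self, site_ids) -> "LabeledBetaMatrix":
        """Return a copy restricted to ``site_ids`` (order preserved)."""
        missing = [s for s in site_ids if s not in self.values.columns]
        if missing:
            raise KeyError(f"sites not in matrix: {missing[:5]}")
        return replace(
            self,
            values=self.values.loc[:, list(site_ids)].copy(),
            positions=self.positions.loc[list(site_ids)].copy(),
        )

    def select_samples(self, sample_ids, *, is_test: bool | None = None) -> "LabeledBetaMatrix":
        """Return a copy restricted to ``sample_ids`` (order preserved)."""
        sub = replace(
            self,
            values=self.values.loc[list(sample_ids)].copy(),
            labels=self.labels.loc[list(sample_ids)].copy(),
        )
        if is_test is not None:
            sub.is_test = is_test
        return sub

    def label_mask(self, label: str) -> np.ndarray:
        return (self.labels == label).to_numpy()


@dataclass
class BinaryMatrix:
    """Methylation-call matrix: 1 = methylated (beta >= cutoff), 0 = not.

    Mirrors :class:`LabeledBetaMatrix` but with integer {0, 1} entries and
    no missing values; ``cutoff`` records the threshold used.
    """

    values: pd.DataFrame
    labels: pd.Series
    positions: pd.DataFrame
    cutoff: float = 0.3
    tissue: str = ""
    is_test: bool = False

    def __post_init__(self) -> None:
        vals = self.values.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("binary matrix entries must be 0 or 1")
        self.labels = self.labels.reindex(self.values.index)
        if self.labels.isna().any():
            raise ValueError("samples missing labels")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_sites(self) -> int:
        return self.values.shape[1]

    @property
    def site_ids(self) -> list[str]:
        return list(self.values.columns)

    def label_vector(self) -> np.ndarray:
        """Labels as integers: Cancer -> 1, Normal -> 0."""
        return (self.labels == CANCER).to_numpy(dtype=int)

    def select_sites(self, site_ids) -> "BinaryMatrix":
        missing = [s for s in site_ids if s not in self.values.columns]
        if missing:
            raise KeyError(f"sites not in matrix: {missing[:5]}")
        return replace(
            self,
            values=self.values.loc[:, list(site_ids)].copy(),
            positions=self.positions.reindex(list(site_ids)).copy(),
        )

    def select_samples(self, sample_ids, *, is_test: bool | None = None) -> "BinaryMatrix":
        sub = replace(
            self,
            values=self.values.loc[list(sample_ids)].copy(),
            labels=self.labels.loc[list(sample_ids)].copy(),
        )
        if is_test is not None:
            sub.is_test = is_test
        return sub


@dataclass
class CpGPanel:
    """Ordered list of selected CpG sites with per-site group statistics.

    ``table`` has one row per retained site in selection order, with the
    columns of :data:`PANEL_COLUMNS` (selection_order is 1-based).  Before
    refinement the statistic columns are NaN.  ``excluded`` records sites
    removed by the separation-score filter together with the score that
    excluded them.
    """

    table: pd.DataFrame
    excluded: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=PANEL_COLUMNS)
    )

    def __post_init__(self) -> None:
        for df in (self.table, self.excluded):
            missing = [c for c in PANEL_COLUMNS if c not in df.columns]
            if missing:
                raise ValueError(f"panel table missing columns {missing}")
        _check_unique(self.table["probe_id"], "panel probe ids")

    @property
    def site_ids(self) -> list[str]:
        return list(self.table["probe_id"])

    def __len__(self) -> int:
        return len(self.table)
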