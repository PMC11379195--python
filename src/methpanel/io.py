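"""Reading and writing GDC-style methylation files, manifests and panels.

File dialects
-------------
Per-sample file: tab-separated, four columns — probe id, chromosome,
position, beta value — one probe per row, header optional.  Missing betas
are the literal ``NA`` (an empty field is also accepted); probes that do
not exist on the genome build carry position ``*``.

Manifest: tab-separated with columns ``file``, ``sample_id``, ``tissue``,
``label``.

Panel table: tab-separated with one row per selected CpG (probe id,
coordinates, group medians and SDs, separation score, selection order),
modeled on the per-tissue marker tables of 450k classification studies.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    PANEL_COLUMNS,
    UNMAPPED_POSITION,
    CpGPanel,
    LabeledBetaMatrix,
    ParseError,
    PipelineError,
)

logger = logging.getLogger("methpanel")

SAMPLE_FILE_COLUMNS = ["probe_id", "chromosome", "position", "beta"]
MANIFEST_COLUMNS = ["file", "sample_id", "tissue", "label"]
NA_LITERAL = "NA"


@dataclass
class SampleRecord:
    """One sample's per-probe methylation rows."""

    sample_id: str
    table: pd.DataFrame  # columns: probe_id, chromosome, position, beta

    @property
    def probe_ids(self) -> pd.Index:
        return pd.Index(self.table["probe_id"])

    @property
    def unmapped(self) -> pd.Series:
        """Boolean mask of position-``*`` (non-existent) probes."""
        return self.table["position"] == UNMAPPED_POSITION


def read_sample_file(path, sample_id: str | None = None) -> SampleRecord:
    """Parse one per-sample methylation TSV.

    Betas are validated to [0, 1]; a value outside that range or a row with
    the wrong number of columns raises :class:`ParseError` naming the line.
    """
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ParseError(
                    f"{path.name}:{lineno}: expected 4 tab-separated fields, "
                    f"got {len(fields)}"
                )
            if lineno == 1 and _looks_like_header(fields):
                continue
            probe, chrom, pos, beta_str = fields
            beta_str = beta_str.strip()
            if beta_str in ("", NA_LITERAL):
                beta = math.nan
            else:
                try:
                    beta = float(beta_str)
                except ValueError as exc:
                    raise ParseError(
                        f"{path.name}:{lineno}: unparseable beta {beta_str!r}"
                    ) from exc
                if not 0.0 <= beta <= 1.0:
                    raise ParseError(
                        f"{path.name}:{lineno}: beta {beta} outside [0, 1]"
                    )
            rows.append((probe, chrom, pos, beta))
    table = pd.DataFrame(rows, columns=SAMPLE_FILE_COLUMNS)
    if table["probe_id"].duplicated().any():
        dupes = table.loc[table["probe_id"].duplicated(), "probe_id"].tolist()[:5]
        raise ParseError(f"{path.name}: duplicate probe ids {dupes}")
    return SampleRecord(sample_id=sample_id or path.stem.split(".")[0], table=table)


def _looks_like_header(fields: list[str]) -> bool:
    last = fields[3].strip()
    if last in ("", NA_LITERAL):
        return False
    try:
        float(last)
        return False
    except ValueError:
        return True


def write_sample_file(record: SampleRecord, path) -> None:
    table = record.table.copy()
    table["beta"] = table["beta"].map(
        lambda v: NA_LITERAL if pd.isna(v) else format(float(v), ".17g")
    )
    table.to_csv(path, sep="\t", index=False, header=False)


def assemble_matrix(records: list[SampleRecord], manifest: pd.DataFrame) -> LabeledBetaMatrix:
    """Stack sample records into a labeled matrix.

    Uses the intersection of the records' probe universes (logging how many
    probes were dropped), orders columns lexicographically by probe id, and
    joins labels and tissue from the manifest.  A record whose sample id is
    absent from the manifest is an error.
    """
    if not records:
        raise PipelineError("no sample records to assemble")
    manifest = manifest.set_index("sample_id", drop=False)
    missing = [r.sample_id for r in records if r.sample_id not in manifest.index]
    if missing:
        raise PipelineError(f"samples absent from manifest: {missing}")

    common = records[0].probe_ids
    universe = set(common)
    for rec in records[1:]:
        common = common.intersection(rec.probe_ids)
        universe |= set(rec.probe_ids)
    common = common.sort_values()
    dropped = len(universe) - len(common)
    if dropped:
        logger.info("assemble_matrix: dropped %d probes outside the shared universe", dropped)
    if common.empty:
        raise PipelineError("records share no probes")

    sample_ids = [r.sample_id for r in records]
    values = np.empty((len(records), len(common)))
    for i, rec in enumerate(records):
        values[i] = (
            rec.table.set_index("probe_id")["beta"].reindex(common).to_numpy()
        )
    first = records[0].table.set_index("probe_id").loc[common]
    positions = first[["chromosome", "position"]].copy()

    tissues = manifest.loc[sample_ids, "tissue"].unique()
    return LabeledBetaMatrix(
        values=pd.DataFrame(values, index=sample_ids, columns=list(common)),
        labels=manifest.loc[sample_ids, "label"].copy(),
        positions=positions,
        tissue=",".join(map(str, tissues)),
    )


# ---------------------------------------------------------------------------
# cohort round trip
# ---------------------------------------------------------------------------

def write_cohort(matrix: LabeledBetaMatrix, out_dir) -> Path:
    """Write one per-sample TSV per row plus a manifest; returns manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest_rows = []
    for sample_id in matrix.sample_ids:
        fname = f"{sample_id}.methylation.tsv"
        record = SampleRecord(
            sample_id=sample_id,
            table=pd.DataFrame(
                {
                    "probe_id": matrix.site_ids,
                    "chromosome": matrix.positions["chromosome"].to_numpy(),
                    "position": matrix.positions["position"].to_numpy(),
                    "beta": matrix.values.loc[sample_id].to_numpy(),
                }
            ),
        )
        write_sample_file(record, out_dir / fname)
        manifest_rows.append(
            (fname, sample_id, matrix.tissue, matrix.labels.loc[sample_id])
        )
    manifest = pd.DataFrame(manifest_rows, columns=MANIFEST_COLUMNS)
    manifest_path = out_dir / "manifest.tsv"
    manifest.to_csv(manifest_path, sep="\t", index=False)
    return manifest_path


def read_manifest(path) -> pd.DataFrame:
    manifest = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise ParseError(f"manifest missing columns {missing}")
    return manifest


def read_cohort(manifest_path) -> LabeledBetaMatrix:
    """Read a manifest and all the per-sample files it lists."""
    manifest_path = Path(manifest_path)
    manifest = read_manifest(manifest_path)
    records = [
        read_sample_file(manifest_path.parent / row.file, sample_id=row.sample_id)
        for row in manifest.itertuples()
    ]
    return assemble_matrix(records, manifest)


# ---------------------------------------------------------------------------
# matrix and panel tables
# ---------------------------------------------------------------------------

def write_matrix(matrix: LabeledBetaMatrix, path) -> None:
    """Samples x probes TSV with a leading ``sample_id`` and ``label`` column."""
    out = matrix.values.copy()
    out.insert(0, "label", matrix.labels)
    out.to_csv(path, sep="\t", index_label="sample_id", na_rep=NA_LITERAL)


def write_panel(panel: CpGPanel, path, include_excluded: bool = False) -> None:
    """Write a panel table as TSV.

    Retained panels are positive-score only; attempting to write a panel
    whose retained rows carry non-positive separation scores raises unless
    ``include_excluded`` is set, in which case excluded rows are appended
    and marked in a ``retained`` column.
    """
    table = panel.table.copy()
    scores = table["separation_score"]
    if not include_excluded and (scores.notna() & (scores <= 0)).any():
        raise PipelineError(
            "panel contains non-positive separation scores; retained panels "
            "are positive-score only (write with include_excluded=True to "
            "keep them)"
        )
    if include_excluded:
        table["retained"] = True
        excl = panel.excluded.copy()
        excl["retained"] = False
        table = pd.concat([table, excl], ignore_index=True)
    table.to_csv(path, sep="\t", index=False, float_format="%.6f", na_rep=NA_LITERAL)


def read_panel(path) -> CpGPanel:
    table = pd.read_csv(path, sep="\t", na_values=[NA_LITERAL], dtype={"position": str})
    missing = [c for c in PANEL_COLUMNS if c not in table.columns]
    if missing:
        raise ParseError(f"panel table missing columns {missing}")
    if table["probe_id"].duplicated().any():
        raise ParseError("panel table has duplicate probe ids")
    if "retained" in table.columns:
        retained = table["retained"].astype(bool)
        excluded = table.loc[~retained, PANEL_COLUMNS].reset_index(drop=True)
        table = table.loc[retained, PANEL_COLUMNS].reset_index(drop=True)
        return CpGPanel(table=table, excluded=excluded)
    return CpGPanel(table=table[PANEL_COLUMNS])
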