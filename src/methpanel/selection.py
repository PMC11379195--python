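"""CpG panel selection: masked depth-2 entropy trees + separation score.

The selector looks for two kinds of marker CpGs: *primary* separating
sites, on which a single methylated/unmethylated split already divides
cancer from normal samples well, and *secondary* sites that correct the
primary split's mistakes.  A depth-2 decision tree grown by information
gain yields exactly one primary (the root) and up to two secondary sites
(the children's splits) per run.  Running the tree repeatedly while
masking every previously selected site forces each run onto fresh
locations; the loop stops at the end of the first run that brings the
accumulated list to at least ``min_panel`` sites (typically 10-12 when
each run contributes up to three).

The panel is then refined on the *continuous* beta values: for each site
the cancer and normal medians and SDs are computed and combined into a
separation score

    score = -((median_C - cutoff) / SD_C) * ((median_N - cutoff) / SD_N)

which is positive exactly when the two group medians fall on opposite
sides of the cutoff; sites with non-positive scores are removed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    CANCER,
    NORMAL,
    PANEL_COLUMNS,
    BinaryMatrix,
    CpGPanel,
    LabeledBetaMatrix,
    PipelineError,
)

logger = logging.getLogger("methpanel")

DEFAULT_CUTOFF = 0.3
_GAIN_EPS = 1e-12


class NoInformativeSplit(PipelineError):
    """No unmasked site yields positive information gain at the root."""


@dataclass
class NodeStats:
    """Class composition of one tree node."""

    normal_fraction: float
    cancer_fraction: float
    n_samples: int

    def __post_init__(self) -> None:
        if self.n_samples > 0 and not np.isclose(
            self.normal_fraction + self.cancer_fraction, 1.0
        ):
            raise PipelineError(
                "normal_fraction + cancer_fraction must equal 1, got "
                f"{self.normal_fraction} + {self.cancer_fraction}"
            )


def node_entropy(stats: NodeStats) -> float:
    """Binary entropy of a node's class mix, in bits.

    Base-2 logarithms so the value is 0 for a pure node and exactly 1 for
    an evenly mixed one; 0*log(0) is defined as 0.
    """
    return float(_entropy_from_fractions(stats.normal_fraction, stats.cancer_fraction))


def _entropy_from_fractions(p: float, q: float) -> float:
    h = 0.0
    for f in (p, q):
        if f > 0.0:
            h -= f * np.log2(f)
    return h


def _entropy_from_counts(n_pos: np.ndarray, n_tot: np.ndarray) -> np.ndarray:
    """Vectorized binary entropy from positive counts; empty nodes get 0."""
    n_pos = np.asarray(n_pos, dtype=float)
    n_tot = np.asarray(n_tot, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n_tot > 0, n_pos / np.maximum(n_tot, 1), 0.0)
        h = -np.where(p > 0, p * np.log2(p), 0.0) - np.where(
            (1 - p) > 0, (1 - p) * np.log2(1 - p), 0.0
        )
    return np.where(n_tot > 0, h, 0.0)


@dataclass
class TreeNode:
    stats: NodeStats
    entropy: float
    prediction: str  # majority label; ties go to Cancer
    site: str | None = None  # split site; None for a leaf
    left: "TreeNode | None" = None  # branch with call 0 (unmethylated)
    right: "TreeNode | None" = None  # branch with call 1 (methylated)

    @property
    def is_leaf(self) -> bool:
        return self.site is None


@dataclass
class DecisionTree:
    """Depth-<=2 tree over binary methylation calls."""

    root: TreeNode
    excluded: frozenset = field(default_factory=frozenset)

    def split_sites(self) -> list[str]:
        """Split sites root-first, then second level left-to-right."""
        sites = []
        if self.root.site is not None:
            sites.append(self.root.site)
        for child in (self.root.left, self.root.right):
            if child is not None and child.site is not None:
                sites.append(child.site)
        return sites

    def predict(self, binary: BinaryMatrix) -> pd.Series:
        calls = binary.values
        out = []
        for i in range(binary.n_samples):
            node = self.root
            while not node.is_leaf:
                child = node.right if calls.iloc[i][node.site] == 1 else node.left
                if child is None:  # pragma: no cover - children always built
                    break
                node = child
            out.append(node.prediction)
        return pd.Series(out, index=calls.index, name="prediction")


def _make_stats(y: np.ndarray) -> tuple[NodeStats, float, str]:
    n = len(y)
    n_cancer = int(y.sum())
    if n == 0:
        return NodeStats(0.0, 0.0, 0), 0.0, CANCER
    p_c = n_cancer / n
    stats = NodeStats(normal_fraction=1 - p_c, cancer_fraction=p_c, n_samples=n)
    prediction = CANCER if n_cancer * 2 >= n else NORMAL
    return stats, _entropy_from_fractions(1 - p_c, p_c), prediction


def _best_split(X: np.ndarray, y: np.ndarray, allowed: np.ndarray):
    """(column index, gain) of the highest-information-gain split.

    Ties break to the lowest column index.  Returns ``(None, 0.0)`` when no
    allowed column has positive gain.
    """
    n = len(y)
    parent_h = _entropy_from_counts(np.array([y.sum()]), np.array([n]))[0]
    n_right = X.sum(axis=0)
    c_right = (X * y[:, None]).sum(axis=0)
    n_left = n - n_right
    c_left = y.sum() - c_right
    child_h = (
        n_left * _entropy_from_counts(c_left, n_left)
        + n_right * _entropy_from_counts(c_right, n_right)
    ) / n
    gain = parent_h - child_h
    gain[~allowed] = -np.inf
    best = gain.max()
    if best <= _GAIN_EPS:
        return None, 0.0
    # ties (within float noise of the max) break to the lowest column index
    j = int(np.argmax(gain >= best - _GAIN_EPS))
    return j, float(gain[j])


def fit_depth2_tree(
    binary: BinaryMatrix, excluded: set | frozenset = frozenset()
) -> DecisionTree:
    """Grow a depth-<=2 tree by information gain over non-excluded sites.

    The root split is the site that best separates cancer from normal
    samples; each impure child is split once more by the site best able to
    correct the root's mistakes.  Pure or unimprovable children become
    leaves predicting their majority class.  Raises
    :class:`NoInformativeSplit` when no unmasked site has positive gain at
    the root.
    """
    site_ids = np.array(binary.site_ids)
    excluded = frozenset(excluded)
    allowed = ~np.isin(site_ids, list(excluded))
    if not allowed.any():
        raise NoInformativeSplit("all sites are excluded")
    X = binary.values.to_numpy(dtype=np.int8)
    y = binary.label_vector()

    stats, h, pred = _make_stats(y)
    root = TreeNode(stats=stats, entropy=h, prediction=pred)
    j_root, _ = _best_split(X, y, allowed)
    if j_root is None:
        raise NoInformativeSplit("no site with positive information gain at the root")
    root.site = str(site_ids[j_root])
    allowed_children = allowed.copy()
    allowed_children[j_root] = False

    for side, mask in (("left", X[:, j_root] == 0), ("right", X[:, j_root] == 1)):
        y_child = y[mask]
        c_stats, c_h, c_pred = _make_stats(y_child)
        child = TreeNode(stats=c_stats, entropy=c_h, prediction=c_pred)
        if c_h > 0.0:
            j_child, _ = _best_split(X[mask], y_child, allowed_children)
            if j_child is not None:
                child.site = str(site_ids[j_child])
                for g_side, g_mask in (
                    ("left", X[mask][:, j_child] == 0),
                    ("right", X[mask][:, j_child] == 1),
                ):
                    g_stats, g_h, g_pred = _make_stats(y_child[g_mask])
                    setattr(
                        child,
                        g_side,
                        TreeNode(stats=g_stats, entropy=g_h, prediction=g_pred),
                    )
        setattr(root, side, child)
    return DecisionTree(root=root, excluded=excluded)


def tree_accuracy(tree: DecisionTree, binary: BinaryMatrix) -> float:
    """Fraction of samples whose leaf-majority label matches their label."""
    predictions = tree.predict(binary)
    return float((predictions == binary.labels).mean())


def iterative_select(
    binary: BinaryMatrix,
    min_panel: int = 10,
    max_runs: int = 50,
) -> CpGPanel:
    """Accumulate split sites over repeated masked depth-2 tree runs.

    Each run fits a fresh tree that may not split on any previously
    selected site; the run's sites (root first, then second-level children
    left to right) are appended to the panel.  The loop stops at the end of
    the first run reaching ``min_panel`` sites — the panel can overshoot by
    up to two — or early, with a logged warning, when no informative split
    remains or ``max_runs`` is hit.  Group statistics are filled in later
    by :func:`refine_panel`.
    """
    if binary.n_samples == 0 or binary.n_sites == 0:
        raise PipelineError("cannot select from an empty matrix")
    if binary.is_test:
        raise PipelineError("refusing to select sites on the quarantined test partition")
    selected: list[str] = []
    runs: list[int] = []
    mask: set[str] = set()
    for run in range(1, max_runs + 1):
        try:
            tree = fit_depth2_tree(binary, excluded=mask)
        except NoInformativeSplit:
            logger.warning(
                "iterative_select: no informative split left after %d sites "
                "(run %d); stopping early",
                len(selected),
                run,
            )
            break
        new_sites = [s for s in tree.split_sites() if s not in mask]
        selected.extend(new_sites)
        runs.extend([run] * len(new_sites))
        mask.update(new_sites)
        if len(selected) >= min_panel:
            break
    else:
        logger.warning(
            "iterative_select: reached max_runs=%d with %d sites", max_runs, len(selected)
        )
    table = pd.DataFrame(
        {
            "probe_id": selected,
            "chromosome": binary.positions.loc[selected, "chromosome"].to_numpy()
            if selected
            else [],
            "position": binary.positions.loc[selected, "position"].to_numpy()
            if selected
            else [],
            "cancer_median": np.nan,
            "normal_median": np.nan,
            "cancer_sd": np.nan,
            "normal_sd": np.nan,
            "separation_score": np.nan,
            "selection_order": np.arange(1, len(selected) + 1),
            "run": runs,
        },
        columns=PANEL_COLUMNS + ["run"],
    )
    return CpGPanel(table=table)


@dataclass
class SiteGroupStats:
    """Per-site continuous-value statistics of the two label groups."""

    cancer_median: float
    normal_median: float
    cancer_sd: float
    normal_sd: float
    cutoff: float = DEFAULT_CUTOFF

    def __post_init__(self) -> None:
        if self.cancer_sd < 0 or self.normal_sd < 0:
            raise PipelineError("standard deviations must be >= 0")


def separation_score(stats: SiteGroupStats) -> float:
    """Cutoff-standardized median product; positive iff medians straddle.

    score = -((median_C - cutoff)/SD_C) * ((median_N - cutoff)/SD_N).
    Negative when both group medians sit on the same side of the cutoff;
    zero when a median lies exactly on it.  Undefined (error) when either
    SD is zero.
    """
    if stats.cancer_sd == 0 or stats.normal_sd == 0:
        raise PipelineError("separation score undefined for zero-SD group")
    return float(
        -((stats.cancer_median - stats.cutoff) / stats.cancer_sd)
        * ((stats.normal_median - stats.cutoff) / stats.normal_sd)
    )


def site_group_stats(
    continuous: LabeledBetaMatrix, site: str, cutoff: float = DEFAULT_CUTOFF
) -> SiteGroupStats:
    """Medians and sample SDs (ddof=1) of one site's values per group."""
    col = continuous.values[site]
    cancer = col[continuous.label_mask(CANCER)].to_numpy(dtype=float)
    normal = col[~continuous.label_mask(CANCER)].to_numpy(dtype=float)
    return SiteGroupStats(
        cancer_median=float(np.median(cancer)),
        normal_median=float(np.median(normal)),
        cancer_sd=float(np.std(cancer, ddof=1)) if len(cancer) > 1 else 0.0,
        normal_sd=float(np.std(normal, ddof=1)) if len(normal) > 1 else 0.0,
        cutoff=cutoff,
    )


def refine_panel(
    panel: CpGPanel,
    continuous: LabeledBetaMatrix,
    cutoff: float = DEFAULT_CUTOFF,
) -> CpGPanel:
    """Fill in group statistics and drop non-positive-score sites.

    Statistics are computed on the continuous (pre-binarization) values of
    the supplied matrix — by convention the pooled training + validation
    samples.  Sites whose score is not strictly positive (both medians on
    one side of the cutoff, a median exactly on it, or a zero-SD group)
    are moved to ``panel.excluded`` with their scores recorded.
    """
    missing = [s for s in panel.site_ids if s not in continuous.values.columns]
    if missing:
        raise PipelineError(f"panel sites absent from matrix: {missing[:5]}")
    table = panel.table.copy()
    scores = []
    for site in table["probe_id"]:
        st = site_group_stats(continuous, site, cutoff=cutoff)
        if st.cancer_sd == 0 or st.normal_sd == 0:
            logger.warning("refine_panel: %s has a zero-SD group; excluded", site)
            score = np.nan
        else:
            score = separation_score(st)
        scores.append((st.cancer_median, st.normal_median, st.cancer_sd, st.normal_sd, score))
    table[["cancer_median", "normal_median", "cancer_sd", "normal_sd", "separation_score"]] = scores

    keep = table["separation_score"] > 0  # strict; NaN fails too
    retained = table.loc[keep].reset_index(drop=True)
    excluded = table.loc[~keep].reset_index(drop=True)
    n_excl = len(excluded)
    if n_excl:
        logger.info("refine_panel: removed %d non-positive-score sites", n_excl)
    return CpGPanel(table=retained, excluded=excluded)
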