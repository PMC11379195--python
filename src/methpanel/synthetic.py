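"""Synthetic tumor/normal methylation cohort generator.

Emulates the structure of GDC-style 450k beta-value cohorts so the whole
pipeline is testable without external downloads:

* bimodal background methylome — uninformative sites drawn from a
  two-component beta mixture (a mostly-unmethylated and a mostly-methylated
  component);
* planted informative sites whose cancer and normal generating
  distributions have medians on opposite sides of the 0.3 methylation
  cutoff (hyper- or hypomethylated in cancer, per site);
* class imbalance (more cancer than normal samples, as in public tumor
  repositories);
* structured missingness: a base rate of scattered NAs plus designated
  "bad" sites and patients whose NA fraction exceeds the 15% filter
  threshold, and fully-NA unmapped probes (genomic position ``"*"``).

All randomness flows from a single integer seed; identical configs give
byte-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import CANCER, NORMAL, UNMAPPED_POSITION, ConfigError, LabeledBetaMatrix

HYPER = "hyper_in_cancer"
HYPO = "hypo_in_cancer"

#: Strongly separated per-site defaults: cancer Beta(8, 2) vs normal
#: Beta(2, 8) for hypermethylated-in-cancer sites (medians ~0.820 / ~0.180),
#: swapped for hypomethylated-in-cancer sites.
DEFAULT_HYPER_PARAMS = ((8.0, 2.0), (2.0, 8.0))  # (cancer, normal)

# rng stream tags so generation and NA injection are independent but both
# reproducible from the one config seed
_VALUES_STREAM = 0
_NA_STREAM = 1


@dataclass
class CohortConfig:
    """Stated world for one simulated tissue cohort.

    Defaults describe a desk-scale cohort: 200 cancer vs 120 normal samples
    over 2000 sites, 15 of them planted discriminative sites with group
    medians straddling the 0.3 cutoff.
    """

    n_cancer: int = 200
    n_normal: int = 120
    n_sites: int = 2000
    n_informative: int = 15
    #: per informative site, or a single tag broadcast to all
    informative_direction: str | tuple[str, ...] = HYPO
    #: (alpha, beta) per informative site, or one pair broadcast; None uses
    #: the direction-specific defaults
    cancer_beta_params: tuple | None = None
    normal_beta_params: tuple | None = None
    #: ((a1, b1), (a2, b2), weight of component 1)
    background_mixture: tuple = ((1.5, 8.0), (8.0, 1.5), 0.5)
    na_rate_base: float = 0.01
    n_bad_sites: int = 20
    n_bad_patients: int = 5
    na_rate_bad: float = 0.30
    n_unmapped: int = 25
    tissue: str = "simulated"
    seed: int = 0

    # -- normalized per-site parameter arrays (filled by validate) --
    _directions: tuple = field(default=(), repr=False, compare=False)
    _cancer_params: tuple = field(default=(), repr=False, compare=False)
    _normal_params: tuple = field(default=(), repr=False, compare=False)

    def __post_init__(self) -> None:
        self.validate()

    @property
    def n_samples(self) -> int:
        return self.n_cancer + self.n_normal

    def validate(self) -> None:
        for name in ("n_cancer", "n_normal", "n_sites"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        for name in ("n_informative", "n_bad_sites", "n_bad_patients", "n_unmapped"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.n_informative + self.n_unmapped > self.n_sites:
            raise ConfigError("n_informative + n_unmapped exceeds n_sites")
        for name in ("na_rate_base", "na_rate_bad"):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1]")
        a1b1, a2b2, w = self.background_mixture
        if not 0.0 <= w <= 1.0:
            raise ConfigError("background_mixture weight must lie in [0, 1]")
        for pair in (a1b1, a2b2):
            if min(pair) <= 0:
                raise ConfigError("background_mixture shape parameters must be > 0")

        self._directions = _broadcast(
            self.informative_direction, self.n_informative, "informative_direction"
        )
        for d in self._directions:
            if d not in (HYPER, HYPO):
                raise ConfigError(
                    f"informative_direction must be {HYPER!r} or {HYPO!r}, got {d!r}"
                )
        cancer, normal = [], []
        for i, d in enumerate(self._directions):
            c_def, n_def = (
                DEFAULT_HYPER_PARAMS if d == HYPER else DEFAULT_HYPER_PARAMS[::-1]
            )
            c = _pick(self.cancer_beta_params, i, c_def)
            n = _pick(self.normal_beta_params, i, n_def)
            for name, pair in (("cancer_beta_params", c), ("normal_beta_params", n)):
                if min(pair) <= 0:
                    raise ConfigError(f"{name}[{i}] shape parameters must be > 0")
            c_med = float(stats.beta.median(*c))
            n_med = float(stats.beta.median(*n))
            if (c_med - 0.3) * (n_med - 0.3) >= 0:
                raise ConfigError(
                    f"informative site {i}: generating medians {c_med:.3f} and "
                    f"{n_med:.3f} do not straddle the 0.3 cutoff"
                )
            cancer.append(tuple(map(float, c)))
            normal.append(tuple(map(float, n)))
        self._cancer_params = tuple(cancer)
        self._normal_params = tuple(normal)


def _broadcast(value, n: int, name: str) -> tuple:
    if isinstance(value, str):
        return (value,) * n
    value = tuple(value)
    if len(value) != n:
        raise ConfigError(f"{name} must have length {n}, got {len(value)}")
    return value


def _pick(params, i: int, default: tuple) -> tuple:
    if params is None:
        return default
    params = tuple(params)
    if params and np.isscalar(params[0]):  # a single (a, b) pair, broadcast
        return params
    return tuple(params[i])


def _site_layout(config: CohortConfig):
    """Probe ids, coordinates and the planted/unmapped index sets.

    Consumes the first draws of the values stream so that
    :func:`planted_site_ids` stays consistent with :func:`generate_cohort`.
    """
    rng = np.random.default_rng([config.seed, _VALUES_STREAM])
    numbers = _unique_integers(rng, config.n_sites, 10**8)
    site_ids = np.array([f"cg{n:08d}" for n in numbers])
    chrom = np.array([f"chr{c}" for c in rng.integers(1, 23, size=config.n_sites)])
    pos = rng.integers(10_000, 200_000_000, size=config.n_sites).astype(object)
    special = rng.choice(
        config.n_sites, size=config.n_informative + config.n_unmapped, replace=False
    )
    informative = np.sort(special[: config.n_informative])
    unmapped = np.sort(special[config.n_informative :])
    pos[unmapped] = UNMAPPED_POSITION
    return rng, site_ids, chrom, pos, informative, unmapped


def _unique_integers(rng: np.random.Generator, n: int, high: int) -> np.ndarray:
    seen: set[int] = set()
    out: list[int] = []
    while len(out) < n:
        for x in rng.integers(0, high, size=n - len(out)).tolist():
            if x not in seen:
                seen.add(x)
                out.append(x)
    return np.array(out)


def planted_site_ids(config: CohortConfig) -> list[str]:
    """Probe ids of the planted informative sites for this config/seed."""
    _, site_ids, _, _, informative, _ = _site_layout(config)
    return list(site_ids[informative])


def unmapped_site_ids(config: CohortConfig) -> list[str]:
    """Probe ids of the position-``"*"`` probes for this config/seed."""
    _, site_ids, _, _, _, unmapped = _site_layout(config)
    return list(site_ids[unmapped])


def generate_cohort(config: CohortConfig) -> LabeledBetaMatrix:
    """Draw a complete (no-NA) labeled beta-value cohort.

    Cancer samples come first, then normal samples.  Informative sites are
    drawn from their class-specific beta distributions; all remaining
    mapped sites are background, each assigned one component of the
    bimodal mixture (shared by both classes, so background sites carry no
    label signal).  Missingness is added separately by
    :func:`inject_missingness`.
    """
    config.validate()
    rng, site_ids, chrom, pos, informative, _ = _site_layout(config)
    n, p = config.n_samples, config.n_sites

    # per-site mixture component for the background methylome
    (a1, b1), (a2, b2), w = config.background_mixture
    comp = rng.random(p) < w
    alpha = np.where(comp, a1, a2)
    beta_ = np.where(comp, b1, b2)
    values = rng.beta(alpha[None, :], beta_[None, :], size=(n, p))

    cancer_rows = np.arange(config.n_cancer)
    normal_rows = np.arange(config.n_cancer, n)
    for k, j in enumerate(informative):
        ca, cb = config._cancer_params[k]
        na_, nb = config._normal_params[k]
        values[cancer_rows, j] = rng.beta(ca, cb, size=config.n_cancer)
        values[normal_rows, j] = rng.beta(na_, nb, size=config.n_normal)

    sample_ids = [f"S{i:04d}" for i in range(n)]
    labels = pd.Series(
        [CANCER] * config.n_cancer + [NORMAL] * config.n_normal,
        index=sample_ids,
        name="label",
    )
    positions = pd.DataFrame(
        {"chromosome": chrom, "position": pos}, index=site_ids
    )
    return LabeledBetaMatrix(
        values=pd.DataFrame(values, index=sample_ids, columns=site_ids),
        labels=labels,
        positions=positions,
        tissue=config.tissue,
    )


def inject_missingness(
    matrix: LabeledBetaMatrix, config: CohortConfig
) -> LabeledBetaMatrix:
    """Overlay the cohort's NA structure on a complete matrix.

    Three layers, in order: (1) unmapped (position ``"*"``) probes become
    all-NA, as in GDC files where most NAs sit at non-existent probes;
    (2) designated bad sites and bad patients receive enough NAs that
    their NA fraction strictly exceeds 0.15, giving the downstream 15%
    filters work to do (bad sites are drawn from mapped background columns
    so the planted signal survives filtering); (3) a base rate of NAs
    scattered uniformly over all cells.
    """
    config.validate()
    n, p = matrix.values.shape
    if config.n_bad_sites > p:
        raise ConfigError("n_bad_sites exceeds number of sites")
    if config.n_bad_patients > n:
        raise ConfigError("n_bad_patients exceeds number of samples")

    rng = np.random.default_rng([config.seed, _NA_STREAM])
    values = matrix.values.to_numpy(dtype=float).copy()

    unmapped_mask = (matrix.positions["position"] == UNMAPPED_POSITION).to_numpy()
    values[:, unmapped_mask] = np.nan

    planted = set(planted_site_ids(config)) & set(matrix.site_ids)
    col_index = {s: j for j, s in enumerate(matrix.site_ids)}
    protected = {col_index[s] for s in planted}
    eligible_cols = np.array(
        [
            j
            for j in range(p)
            if j not in protected and not unmapped_mask[j]
        ]
    )
    if config.n_bad_sites > len(eligible_cols):
        raise ConfigError("n_bad_sites exceeds number of eligible background sites")
    bad_cols = rng.choice(eligible_cols, size=config.n_bad_sites, replace=False)
    # exact NA count guaranteeing a fraction strictly above the 0.15 filter
    n_na_site = max(int(np.ceil(config.na_rate_bad * n)), int(0.15 * n) + 1)
    for j in bad_cols:
        rows = rng.choice(n, size=n_na_site, replace=False)
        values[rows, j] = np.nan

    bad_rows = rng.choice(n, size=config.n_bad_patients, replace=False)
    n_na_patient = max(int(np.ceil(config.na_rate_bad * p)), int(0.15 * p) + 1)
    for i in bad_rows:
        cols = rng.choice(p, size=n_na_patient, replace=False)
        values[i, cols] = np.nan

    if config.na_rate_base > 0:
        base = rng.random((n, p)) < config.na_rate_base
        values[base] = np.nan

    out = matrix.select_samples(matrix.sample_ids)  # deep copy
    out.values = pd.DataFrame(
        values, index=matrix.values.index, columns=matrix.values.columns
    )
    return out


def simulate_cohort(config: CohortConfig) -> LabeledBetaMatrix:
    """Convenience: :func:`generate_cohort` + :func:`inject_missingness`."""
    return inject_missingness(generate_cohort(config), config)
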