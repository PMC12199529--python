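"""Count-table filtering, zero replacement, CLR and alpha-diversity summaries.

The filtering scheme keeps samples with adequate sequencing depth first, then
keeps genera that are both non-negligibly abundant on average and observed in
a minimum fraction of samples.  Zero replacement is Bayesian-multiplicative:
zeros are imputed by the Dirichlet-posterior expected fraction under a weak
prior and the non-zero fractions are rescaled multiplicatively so each sample
remains a composition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from skbio.diversity import alpha as skbio_alpha

__all__ = [
    "CountTable",
    "FilterConfig",
    "FilterReport",
    "CompositionTable",
    "filter_counts",
    "zero_replace",
    "clr",
    "alpha_diversity",
    "compare_diversity",
]


@dataclass
class CountTable:
    """Genus x sample integer count matrix with optional group labels."""

    counts: pd.DataFrame
    group_of: pd.Series | None = None

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.has_duplicates or c.columns.has_duplicates:
            raise ValueError("duplicate genus or sample IDs")
        arr = c.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("counts must be integral")
            self.counts = c.astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if self.group_of is not None:
            self.group_of = self.group_of.reindex(self.counts.columns)
            if self.group_of.isna().any():
                missing = list(self.group_of.index[self.group_of.isna()])
                raise ValueError(f"samples missing a group label: {missing[:5]}")

    @property
    def genus_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def subset_group(self, label: str) -> "CountTable":
        if self.group_of is None:
            raise ValueError("table has no group labels")
        cols = self.group_of.index[self.group_of == label]
        if len(cols) == 0:
            raise ValueError(f"no samples in group {label!r}")
        return CountTable(self.counts[cols].copy(), self.group_of[cols].copy())


@dataclass(frozen=True)
class FilterConfig:
    """Taxon/sample retention thresholds.

    ``min_mean_rel_abundance`` is interpreted as the mean over retained
    samples of each genus's per-sample relative abundance (scale-free).  The
    literal alternative -- mean raw reads per sample relative to the grand
    total -- is available via ``abundance_rule="grand_total"``.
    """

    min_mean_rel_abundance: float = 1e-5
    min_prevalence: float = 0.01
    min_sample_depth: int = 10_000
    abundance_rule: str = "mean_relative"  # or "grand_total"

    def __post_init__(self) -> None:
        if min(self.min_mean_rel_abundance, self.min_prevalence, self.min_sample_depth) < 0:
            raise ValueError("filter thresholds must be non-negative")
        if self.min_prevalence > 1:
            raise ValueError("min_prevalence is a fraction in [0, 1]")
        if self.abundance_rule not in ("mean_relative", "grand_total"):
            raise ValueError(f"unknown abundance_rule {self.abundance_rule!r}")


@dataclass
class FilterReport:
    n_samples_before: int
    n_samples_after: int
    n_genera_before: int
    n_genera_after_abundance: int
    n_genera_after_prevalence: int
    dropped_samples: list[str] = field(default_factory=list)
    dropped_genera: list[str] = field(default_factory=list)


@dataclass
class CompositionTable:
    """Strictly positive genus x sample fractions; columns sum to one."""

    fractions: pd.DataFrame

    def __post_init__(self) -> None:
        arr = self.fractions.to_numpy()
        if (arr <= 0).any():
            raise ValueError("composition entries must be strictly positive")
        if not np.allclose(arr.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError("composition columns must sum to 1")


def filter_counts(table: CountTable, config: FilterConfig = FilterConfig()) -> tuple[CountTable, FilterReport]:
    """Drop shallow samples, then rare genera.

    Samples below ``min_sample_depth`` total reads are removed first; genera
    are then kept only if the abundance rule *and* the prevalence rule hold on
    the retained samples.  Filtering is a single pass (not iterated).
    """
    if table.counts.empty:
        raise ValueError("empty count table")
    counts = table.counts
    depths = counts.sum(axis=0)
    keep_samples = depths >= config.min_sample_depth
    if not keep_samples.any():
        raise ValueError("all samples fall below the depth threshold")
    kept = counts.loc[:, keep_samples]

    rel = kept / kept.sum(axis=0)
    if config.abundance_rule == "mean_relative":
        abundance_ok = rel.mean(axis=1) >= config.min_mean_rel_abundance
    else:
        abundance_ok = kept.mean(axis=1) >= config.min_mean_rel_abundance * kept.to_numpy().sum()
    prevalence_ok = (kept > 0).mean(axis=1) >= config.min_prevalence
    keep_genera = abundance_ok & prevalence_ok
    if not keep_genera.any():
        raise ValueError("all genera removed by the taxon filters")

    out = kept.loc[keep_genera]
    group = table.group_of[out.columns] if table.group_of is not None else None
    report = FilterReport(
        n_samples_before=counts.shape[1],
        n_samples_after=out.shape[1],
        n_genera_before=counts.shape[0],
        n_genera_after_abundance=int(abundance_ok.sum()),
        n_genera_after_prevalence=int(keep_genera.sum()),
        dropped_samples=list(counts.columns[~keep_samples]),
        dropped_genera=list(counts.index[~keep_genera]),
    )
    return CountTable(out.copy(), group), report


def bayes_multiplicative_replace(counts: np.ndarray, prior_strength: float | None = None) -> np.ndarray:
    """Numpy core of :func:`zero_replace` (genus x sample counts -> fractions)."""
    counts = np.asarray(counts, dtype=float)
    D, n = counts.shape
    depths = counts.sum(axis=0)
    if (depths == 0).any():
        raise ValueError("all-zero samples cannot form compositions")
    s = np.sqrt(depths) if prior_strength is None else np.full(n, float(prior_strength))
    imputed = (1.0 / D) * s / (depths + s)          # posterior mean for a zero part
    frac = counts / depths
    zero = counts == 0
    zero_mass = (zero * imputed[None, :]).sum(axis=0)
    return np.where(zero, imputed[None, :], frac * (1.0 - zero_mass)[None, :])


def zero_replace(table: CountTable, prior_strength: float | None = None) -> CompositionTable:
    """Bayesian-multiplicative zero replacement.

    Under a symmetric Dirichlet prior with total strength ``s`` (default
    ``sqrt(depth)``, a weak square-root prior) and uniform base measure
    ``t_i = 1/D``, a zero count is imputed by its posterior expected fraction
    ``t_i * s / (depth + s)``; the non-zero fractions are then rescaled
    multiplicatively so the column still sums to one.  Samples without zeros
    pass through as plain relative abundances.
    """
    counts = table.counts.to_numpy(dtype=float)
    depths = counts.sum(axis=0)
    if (depths == 0).any():
        bad = list(table.counts.columns[depths == 0])
        raise ValueError(f"all-zero samples cannot form compositions: {bad}")
    out = bayes_multiplicative_replace(counts, prior_strength)
    return CompositionTable(pd.DataFrame(out, index=table.counts.index, columns=table.counts.columns))


def clr(comp: CompositionTable) -> pd.DataFrame:
    """Centered log-ratio transform per sample; output columns sum to zero."""
    arr = comp.fractions.to_numpy()
    if (arr <= 0).any():
        raise ValueError("CLR requires strictly positive input")
    logs = np.log(arr)
    out = logs - logs.mean(axis=0, keepdims=True)
    return pd.DataFrame(out, index=comp.fractions.index, columns=comp.fractions.columns)


def alpha_diversity(table: CountTable, chao1_bias_corrected: bool = True) -> pd.DataFrame:
    """Shannon entropy (natural log) and Chao1 richness per sample.

    Chao1 uses the bias-corrected form ``S_obs + F1(F1-1)/(2(F2+1))`` by
    default so it stays defined without doubletons; the classic
    ``S_obs + F1^2/(2 F2)`` form is available via the flag.
    """
    counts = table.counts.to_numpy()
    if (counts.sum(axis=0) == 0).any():
        raise ValueError("zero-depth sample")
    rows = []
    for j in range(counts.shape[1]):
        col = counts[:, j]
        rows.append(
            {
                "shannon": float(skbio_alpha.shannon(col, base=np.e)),
                "chao1": float(skbio_alpha.chao1(col, bias_corrected=chao1_bias_corrected)),
            }
        )
    return pd.DataFrame(rows, index=table.counts.columns)


def compare_diversity(diversity: pd.DataFrame, group_of: pd.Series) -> pd.Series:
    """Two-sided Mann-Whitney p-value per diversity index between two groups."""
    groups = group_of.reindex(diversity.index)
    labels = [g for g in pd.unique(groups.dropna())]
    if len(labels) != 2:
        raise ValueError(f"need exactly two groups, got {labels}")
    a = diversity.loc[groups == labels[0]]
    b = diversity.loc[groups == labels[1]]
    if min(len(a), len(b)) < 2:
        raise ValueError("each group needs at least two samples")
    pvals = {}
    for col in diversity.columns:
        _, p = stats.mannwhitneyu(a[col], b[col], alternative="two-sided")
        pvals[col] = float(p)
    return pd.Series(pvals, name="p_value")
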