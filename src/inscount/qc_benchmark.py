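"""Sensitivity and precision benchmarking.

Covers the assay-QC analyses run on every code set: spike-in standard
curves (log10 count vs log10 fmol), replicate coefficient-of-variation
summaries, RNA input-mass titration tables (average counts per probe
class per mass, fold-scaling between masses), biological-replicate group
averaging, and cross-platform concordance of group-averaged profiles.

Conventions: log10 throughout; zero or negative values are excluded
pairwise from log-scale correlations (recorded in the result, never
pseudocounted); CV uses the sample SD (n-1); concordance is Pearson by
default on the flattened gene x group pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .codeset_io import CodeSet, CountMatrix, ProbeClass
from .errors import AlignmentError, FitError, ValidationError

__all__ = [
    "StandardCurveFit",
    "CVSummary",
    "TitrationSummary",
    "ConcordanceResult",
    "fit_standard_curve",
    "replicate_cv",
    "titration_summary",
    "group_average",
    "platform_concordance",
]


@dataclass(frozen=True)
class StandardCurveFit:
    """OLS fit of log10(count) on log10(fmol)."""

    slope: float
    intercept: float  # log10 counts at 1 fmol
    r_squared: float
    n_points: int
    slope_se: float = float("nan")

    def predict(self, fmol) -> np.ndarray:
        """Predicted counts at the given spike amounts."""
        return 10.0 ** (self.intercept + self.slope * np.log10(np.asarray(fmol, dtype=float)))


def fit_standard_curve(counts, amounts) -> StandardCurveFit:
    """Fit the positive-control standard curve.

    ``counts`` and ``amounts`` are matched per-probe count and spike
    (fmol) vectors.  Points with nonpositive counts are dropped (they
    carry no log-scale information); at least two usable points with
    distinct amounts are required.
    """
    counts = np.asarray(counts, dtype=float)
    amounts = np.asarray(amounts, dtype=float)
    if counts.shape != amounts.shape:
        raise FitError("counts and amounts must have matching shapes")
    if (amounts <= 0).any():
        raise FitError("spike amounts must be positive")
    usable = counts > 0
    counts, amounts = counts[usable], amounts[usable]
    if counts.size < 2:
        raise FitError("standard curve needs at least 2 points with positive counts")
    if np.unique(amounts).size < 2:
        raise FitError("standard curve needs at least 2 distinct spike amounts")
    fit = stats.linregress(np.log10(amounts), np.log10(counts))
    return StandardCurveFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
        n_points=int(counts.size),
        slope_se=float(fit.stderr),
    )


@dataclass(frozen=True)
class CVSummary:
    """Per-gene, per-group replicate CV (%) with group medians.

    Genes with zero replicate mean have no defined CV; they appear as
    NaN in ``per_gene_cv``, are excluded from the medians and are listed
    in ``undefined``.
    """

    per_gene_cv: pd.DataFrame
    median_cv: pd.Series
    group_sizes: pd.Series
    undefined: dict[str, list[str]] = field(default_factory=dict)


def _resolve_groups(
    counts: CountMatrix, groups: str | Mapping[str, Sequence[str]]
) -> dict[str, list[str]]:
    """Groups are either a metadata column name or an explicit mapping
    of group label -> sample ids."""
    if isinstance(groups, str):
        meta = counts.meta
        if groups not in meta.columns:
            raise ValidationError(f"unknown metadata column {groups!r}")
        out: dict[str, list[str]] = {}
        for sid, label in meta[groups].items():
            out.setdefault(str(label), []).append(sid)
        return out
    resolved = {str(k): list(v) for k, v in groups.items()}
    seen: set[str] = set()
    known = set(counts.sample_ids)
    for label, ids in resolved.items():
        bad = [s for s in ids if s not in known]
        if bad:
            raise ValidationError(f"group {label!r}: unknown sample(s) {bad}")
        if seen & set(ids):
            raise ValidationError("groups must not share samples")
        seen |= set(ids)
    return resolved


def replicate_cv(
    counts: CountMatrix,
    groups: str | Mapping[str, Sequence[str]] = "condition",
    probe_filter: ProbeClass | str | None = ProbeClass.TARGET,
) -> CVSummary:
    """Per-gene replicate CV% = 100 * sample SD / mean within each group.

    Every group needs >= 2 samples.  The median per group is taken over
    probes passing ``probe_filter`` (default: targets only) whose mean
    is nonzero.
    """
    resolved = _resolve_groups(counts, groups)
    small = [g for g, ids in resolved.items() if len(ids) < 2]
    if small:
        raise ValidationError(f"group(s) with fewer than 2 replicates: {', '.join(small)}")
    genes = counts.codeset.gene_ids if probe_filter is None else counts.codeset.by_class(probe_filter)
    cv = {}
    undefined: dict[str, list[str]] = {}
    for label, ids in resolved.items():
        sub = counts.counts.loc[genes, ids]
        mean = sub.mean(axis=1)
        sd = sub.std(axis=1, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            col = 100.0 * sd / mean
        col[mean == 0] = np.nan
        zeros = mean.index[mean == 0].tolist()
        if zeros:
            undefined[label] = zeros
        cv[label] = col
    per_gene = pd.DataFrame(cv)
    return CVSummary(
        per_gene_cv=per_gene,
        median_cv=per_gene.median(axis=0, skipna=True),
        group_sizes=pd.Series({g: len(ids) for g, ids in resolved.items()}),
        undefined=undefined,
    )


@dataclass(frozen=True)
class TitrationSummary:
    """Per-mass class averages and fold-ratios from an input-mass titration.

    ``table`` rows: average positive-control / negative-control / target
    count and the grand summed counts; columns: RNA mass (ug), ascending.
    """

    table: pd.DataFrame
    n_replicates: pd.Series

    @property
    def masses(self) -> list[float]:
        return list(self.table.columns)

    def fold_ratio(self, numerator_mass: float, denominator_mass: float, row: str = "average_targets") -> float:
        """Ratio of a class-average row between two mass levels."""
        return float(self.table.loc[row, numerator_mass] / self.table.loc[row, denominator_mass])


def titration_summary(counts: CountMatrix, by: str = "rna_mass") -> TitrationSummary:
    """Class-average counts per RNA-mass level.

    Requires positive-normalized counts and >= 2 mass levels.  Averages
    are over probes x replicates within each class; the grand sum is the
    per-sample total summed counts averaged over replicates.
    """
    meta = counts.meta
    if by not in meta.columns:
        raise ValidationError(f"unknown metadata column {by!r}")
    masses = sorted(meta[by].unique())
    if len(masses) < 2:
        raise ValidationError("titration requires at least 2 mass levels")
    cols = {}
    n_reps = {}
    for m in masses:
        ids = meta.index[meta[by] == m].tolist()
        n_reps[m] = len(ids)
        cols[m] = {
            "average_positives": counts.class_counts(ProbeClass.POSITIVE)[ids].to_numpy().mean(),
            "average_negatives": counts.class_counts(ProbeClass.NEGATIVE)[ids].to_numpy().mean(),
            "average_targets": counts.class_counts(ProbeClass.TARGET)[ids].to_numpy().mean(),
            "sum_counts": counts.counts[ids].sum(axis=0).mean(),
        }
    table = pd.DataFrame(cols)[masses]
    return TitrationSummary(table=table, n_replicates=pd.Series(n_reps))


def group_average(
    counts: CountMatrix, groups: str | Mapping[str, Sequence[str]] = "condition"
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Per-gene mean and sample SD over each biological-replicate group.

    Returns (means, sds, group sizes); genes x groups.  A singleton
    group has mean equal to its single value and undefined (NaN) SD.
    """
    resolved = _resolve_groups(counts, groups)
    empty = [g for g, ids in resolved.items() if not ids]
    if empty:
        raise ValidationError(f"empty group(s): {', '.join(empty)}")
    means = {}
    sds = {}
    for label, ids in resolved.items():
        sub = counts.counts[ids]
        means[label] = sub.mean(axis=1)
        sds[label] = sub.std(axis=1, ddof=1)
    return pd.DataFrame(means), pd.DataFrame(sds), pd.Series({g: len(v) for g, v in resolved.items()})


@dataclass(frozen=True)
class ConcordanceResult:
    """Cross-platform concordance of two group-averaged profiles."""

    r: float
    n_pairs: int
    n_dropped: int
    scale: str
    method: str
    table: pd.DataFrame  # paired long-format values actually correlated


def platform_concordance(
    profile_a: pd.DataFrame,
    profile_b: pd.DataFrame,
    exclude: Sequence[str] = (),
    scale: str = "log10",
    method: str = "pearson",
) -> ConcordanceResult:
    """Correlate two genes x groups averaged profiles.

    Pairs are the flattened gene x group cells shared by both profiles
    after dropping ``exclude`` genes.  On the log10 scale, pairs where
    either value is <= 0 are excluded pairwise (with a warning) rather
    than pseudocounted.  Requires >= 3 usable pairs.
    """
    if scale not in ("log10", "linear"):
        raise ValueError(f"unknown scale {scale!r}")
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")
    genes = [g for g in profile_a.index if g in set(profile_b.index) and g not in set(exclude)]
    groups = [c for c in profile_a.columns if c in set(profile_b.columns)]
    if not groups:
        raise AlignmentError("profiles share no group labels")
    if len(genes) < 3:
        raise AlignmentError("fewer than 3 shared genes after exclusions")
    a = profile_a.loc[genes, groups].stack()
    b = profile_b.loc[genes, groups].stack()
    table = pd.DataFrame({"a": a, "b": b}).dropna()
    n_total = len(table)
    if scale == "log10":
        ok = (table["a"] > 0) & (table["b"] > 0)
        dropped = int((~ok).sum())
        if dropped:
            warnings.warn(f"excluding {dropped} nonpositive pair(s) from log-scale correlation")
        table = table[ok]
        values = np.log10(table)
    else:
        dropped = n_total - len(table)
        values = table
    if len(table) < 3:
        raise AlignmentError("fewer than 3 usable pairs for correlation")
    if method == "pearson":
        r = float(stats.pearsonr(values["a"], values["b"]).statistic)
    else:
        r = float(stats.spearmanr(values["a"], values["b"]).statistic)
    out = table.copy()
    out.index = out.index.set_names(["gene_id", "group"])
    return ConcordanceResult(
        r=r, n_pairs=len(table), n_dropped=dropped, scale=scale, method=method, table=out.reset_index()
    )
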