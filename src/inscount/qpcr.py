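"""qPCR cross-validation: standard curves, Ct-to-copies conversion,
reference-gene normalization and per-gene profile comparison.

A genomic-DNA dilution series gives, per primer pair, an OLS fit of Ct
on log10(copies).  A valid curve has negative slope; the amplification
efficiency is E = 10^(-1/slope), E = 2 for perfect doubling (slope
-3.3219 cycles per decade).  Sample Cts convert to absolute copy
numbers through the curve; copies are per reaction (the assay loads a
fixed RNA-equivalent per reaction), and between-preparation differences
are removed by dividing by the geometric mean of reference-gene copies
in each sample.

Cross-platform comparison of stage profiles scales each platform's
profile to its own mean first — counts and copy numbers are in
incommensurate units, so only the profile *shape* is comparable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import FitError, NormalizationError, ValidationError

__all__ = [
    "QpcrCurve",
    "fit_qpcr_curve",
    "ct_to_copies",
    "predict_ct",
    "reference_normalize",
    "platform_profile_compare",
]

LOG10_2 = math.log10(2.0)


@dataclass(frozen=True)
class QpcrCurve:
    """Per-primer-pair standard curve: Ct = intercept + slope*log10(copies)."""

    slope: float  # Ct per log10 copies; < 0 for a valid curve
    intercept: float  # Ct at 1 copy
    r_squared: float
    n_points: int = 0
    ct_range: tuple[float, float] | None = None

    @property
    def efficiency(self) -> float:
        """Amplification factor per cycle, E = 10^(-1/slope)."""
        return 10.0 ** (-1.0 / self.slope)

    @property
    def efficiency_in_range(self) -> bool:
        """Flag check: plausible efficiencies lie in (1, 2.2]."""
        return 1.0 < self.efficiency <= 2.2


def fit_qpcr_curve(cts, copies) -> QpcrCurve:
    """OLS of Ct on log10(copies) over a dilution series.

    Requires >= 3 points spanning >= 2 decades of template copies and a
    negative fitted slope.
    """
    cts = np.asarray(cts, dtype=float)
    copies = np.asarray(copies, dtype=float)
    if cts.shape != copies.shape:
        raise FitError("cts and copies must have matching shapes")
    if cts.size < 3:
        raise FitError("standard curve needs at least 3 dilution points")
    if (copies <= 0).any():
        raise FitError("template copies must be positive")
    logc = np.log10(copies)
    if logc.max() - logc.min() < 2.0:
        raise FitError("dilution series must span at least 2 log10 of template")
    fit = stats.linregress(logc, cts)
    if fit.slope >= 0:
        raise FitError(f"nonnegative slope ({fit.slope:.3g}); not a valid amplification curve")
    return QpcrCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
        n_points=int(cts.size),
        ct_range=(float(cts.min()), float(cts.max())),
    )


def predict_ct(curve: QpcrCurve, copies) -> np.ndarray:
    """Expected Ct at the given template copies (inverse of ct_to_copies)."""
    return curve.intercept + curve.slope * np.log10(np.asarray(copies, dtype=float))


def ct_to_copies(ct, curve: QpcrCurve, warn_extrapolation: bool = False):
    """copies = 10^((ct - intercept) / slope).

    Always defined; values outside the fitted Ct range are extrapolations
    (optionally raised as a warning, never an error).
    """
    ct_arr = np.asarray(ct, dtype=float)
    copies = 10.0 ** ((ct_arr - curve.intercept) / curve.slope)
    if warn_extrapolation and curve.ct_range is not None:
        lo, hi = curve.ct_range
        if ((ct_arr < lo) | (ct_arr > hi)).any():
            import warnings

            warnings.warn("Ct outside the fitted standard-curve range; copies are extrapolated")
    return float(copies) if np.isscalar(ct) else copies


def reference_normalize(
    measurements: pd.DataFrame, reference_genes: Sequence[str]
) -> pd.DataFrame:
    """Normalize copy numbers between RNA/cDNA preparations.

    ``measurements`` is long-format with columns gene_id, sample_id,
    copies.  Each sample's copies are divided by that sample's reference
    factor: the geometric mean of its reference-gene copies, rescaled so
    the across-sample mean factor is 1 (which makes the normalization an
    identity when the references are constant).  Per-sample global
    scaling cancels exactly.
    """
    for col in ("gene_id", "sample_id", "copies"):
        if col not in measurements.columns:
            raise ValidationError(f"measurements lack column {col!r}")
    refs = list(reference_genes)
    if not refs:
        raise NormalizationError("at least one reference gene is required")
    # geometric mean of reference copies per sample (replicates averaged first)
    ref_rows = measurements[measurements["gene_id"].isin(refs)]
    per_sample = ref_rows.groupby(["sample_id", "gene_id"])["copies"].mean().unstack("gene_id")
    missing = per_sample.reindex(columns=refs).isna()
    samples = set(measurements["sample_id"])
    absent = (samples - set(per_sample.index)) | set(per_sample.index[missing.any(axis=1)])
    if absent:
        raise NormalizationError(
            f"sample(s) missing reference-gene copies: {', '.join(sorted(map(str, absent)))}"
        )
    per_sample = per_sample[refs]
    if (per_sample <= 0).to_numpy().any():
        raise NormalizationError("reference-gene copies must be > 0 in every sample")
    geo = np.exp(np.log(per_sample).mean(axis=1))
    factors = geo / geo.mean()
    out = measurements.copy()
    out["normalized_abundance"] = out["copies"] / out["sample_id"].map(factors).to_numpy()
    return out


def platform_profile_compare(
    qpcr_profile: pd.DataFrame,
    count_profile: pd.DataFrame,
    genes: Sequence[str] | None = None,
    fold_flag: float = 2.0,
    fold_quiet: float = 1.3,
) -> pd.DataFrame:
    """Per-gene concordance of stage profiles measured on two platforms.

    Inputs are genes x stages mean-abundance tables (any units).  For
    each gene the two profiles are scaled to their own across-stage mean
    and correlated (Pearson, log10 scale) over the >= 3 shared stages.
    Stages where one platform moves >= ``fold_flag``-fold from its gene
    mean while the other moves < ``fold_quiet``-fold are flagged as
    platform-discordant.  A flat profile on either platform yields an
    undefined correlation, reported as NaN with a flag rather than 0.
    """
    shared_stages = [s for s in qpcr_profile.columns if s in set(count_profile.columns)]
    if len(shared_stages) < 3:
        raise ValidationError("profiles share fewer than 3 stages")
    if genes is None:
        genes = [g for g in qpcr_profile.index if g in set(count_profile.index)]
    records = []
    for gene in genes:
        a = qpcr_profile.loc[gene, shared_stages].astype(float)
        b = count_profile.loc[gene, shared_stages].astype(float)
        ok = (a > 0) & (b > 0)
        a, b = a[ok], b[ok]
        if len(a) < 3:
            records.append((gene, np.nan, len(a), "insufficient_positive_stages"))
            continue
        a_rel, b_rel = a / a.mean(), b / b.mean()
        if a_rel.nunique() == 1 or b_rel.nunique() == 1:
            records.append((gene, np.nan, len(a), "flat_profile"))
            continue
        r = float(stats.pearsonr(np.log10(a_rel), np.log10(b_rel)).statistic)
        discord = [
            s
            for s in a_rel.index
            if (max(a_rel[s], 1 / a_rel[s]) >= fold_flag and max(b_rel[s], 1 / b_rel[s]) < fold_quiet)
            or (max(b_rel[s], 1 / b_rel[s]) >= fold_flag and max(a_rel[s], 1 / a_rel[s]) < fold_quiet)
        ]
        records.append((gene, r, len(a), ";".join(discord)))
    return pd.DataFrame(records, columns=["gene_id", "r", "n_stages", "flags"]).set_index("gene_id")
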