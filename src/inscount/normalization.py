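"""Two-step between-sample normalization.

Step 1 (always): scale every sample so that its positive-control sum
equals the across-sample mean of positive-control sums.  Spike-in
amounts are identical in every hybridization, so any between-sample
difference in the positive-control sum reflects assay efficiency, not
biology; dividing it out puts all samples on a common scale.

Step 2 (per-experiment, used for validation and life-cycle analysis but
not for the mass titration): further rescale only the *target* rows so
per-sample target sums are equal, a total-content normalization that
compensates for differing mRNA fraction per mass of total RNA.  Control
rows are untouched.

Reference value = mean of per-sample sums.  Any positive constant gives
identical relative results downstream; the mean keeps the normalized
table on the scale of the raw data.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .codeset_io import CountMatrix, NormState, ProbeClass
from .errors import NormalizationError

__all__ = ["NormalizationResult", "normalize_positive_controls", "normalize_target_sum"]


@dataclass(frozen=True)
class NormalizationResult:
    """Per-sample scale factors plus the common post-scaling reference sum."""

    factors: pd.Series
    reference_value: float
    method: str  # "positive_controls" | "target_sum"

    def __post_init__(self) -> None:
        if (self.factors <= 0).any():
            raise NormalizationError("all normalization factors must be > 0")


def _factors_from_sums(sums: pd.Series, method: str) -> NormalizationResult:
    zero = sums.index[sums <= 0].tolist()
    if zero:
        raise NormalizationError(
            f"{method}: sample(s) with nonpositive control sum: {', '.join(map(str, zero))}"
        )
    reference = float(sums.mean())
    return NormalizationResult(factors=reference / sums, reference_value=reference, method=method)


def normalize_positive_controls(counts: CountMatrix) -> tuple[CountMatrix, NormalizationResult]:
    """Scale each sample by reference / (its positive-control sum).

    Requires raw counts; afterwards every sample's positive-control sum
    equals the across-sample mean of the raw sums.
    """
    if counts.norm_state is not NormState.RAW:
        raise NormalizationError(
            f"positive-control normalization requires raw counts, got {counts.norm_state.value}"
        )
    pos_sums = counts.class_counts(ProbeClass.POSITIVE).sum(axis=0)
    result = _factors_from_sums(pos_sums, "positive_controls")
    scaled = counts.counts.mul(result.factors, axis=1)
    return counts.with_counts(scaled, NormState.POSITIVE_NORMALIZED), result


def normalize_target_sum(counts: CountMatrix) -> tuple[CountMatrix, NormalizationResult]:
    """Rescale target rows so per-sample target sums equal their mean.

    Must follow positive-control normalization (the norm-state machine
    rejects any other order).  Positive- and negative-control rows pass
    through bit-identical.
    """
    if counts.norm_state is not NormState.POSITIVE_NORMALIZED:
        raise NormalizationError(
            "target-sum normalization requires positive-normalized counts, "
            f"got {counts.norm_state.value}"
        )
    targets = counts.codeset.targets
    target_sums = counts.counts.loc[targets].sum(axis=0)
    result = _factors_from_sums(target_sums, "target_sum")
    scaled = counts.counts.copy()
    scaled.loc[targets] = scaled.loc[targets].mul(result.factors, axis=1)
    return counts.with_counts(scaled, NormState.TARGET_SUM_NORMALIZED), result


def normalize_housekeeping(counts: CountMatrix, genes) -> tuple[CountMatrix, NormalizationResult]:
    """Housekeeping-gene normalization. Not implemented: this code set
    contains no invariant internal-control genes."""
    raise NotImplementedError(
        "housekeeping normalization requires invariant control genes, "
        "which this code set does not include"
    )
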