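"""Background threshold estimation and detection calling.

Two ways of putting a floor under "detected":

* **Negative-control model** — threshold = mean + k*SD of the
  negative-control counts within a sample group (default k = 3).  The
  SD pools all negative-control values in the group (probes x samples),
  with the n-1 denominator: with 8 negative probes and 3 replicates,
  per-probe SDs are too unstable to use, and one cutoff per condition is
  what the assay needs.

* **Deletion-calibrated model** — residual counts for probes whose
  target gene has been deleted measure real cross-hybridization, which
  exceeds what foreign-sequence negative controls can see.  The
  threshold is the largest deletion-strain residual mean plus k times
  that gene's SD (default k = 4), optionally rounded up to a round
  number of counts for a conservative operating cutoff.

Detection uses strict inequality ("detected *above* background"):
counts exactly at the threshold are not detected.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .codeset_io import CodeSet, CountMatrix, NormState, ProbeClass
from .errors import BackgroundModelError

__all__ = [
    "BackgroundModel",
    "DeletionSummary",
    "DetectionCalls",
    "Rounding",
    "negative_control_threshold",
    "deletion_threshold",
    "call_detection",
    "detection_summary",
]


class Rounding(str, enum.Enum):
    NONE = "none"
    CEIL_TO_50 = "ceil_to_50"
    CEIL_TO_100 = "ceil_to_100"

    def apply(self, value: float) -> float:
        if self is Rounding.NONE:
            return value
        step = 50 if self is Rounding.CEIL_TO_50 else 100
        return float(math.ceil(value / step) * step)


@dataclass(frozen=True)
class BackgroundModel:
    """A detection threshold with its provenance."""

    threshold: float
    method: str  # "negctrl_mean_sd" | "deletion_calibrated" | "fixed"
    k: float = 0.0
    scope: str = ""
    mean: float | None = None
    sd: float | None = None

    def __post_init__(self) -> None:
        if self.threshold < 0:
            raise BackgroundModelError("threshold must be >= 0")


@dataclass(frozen=True)
class DeletionSummary:
    """Replicate summary for one probe in wild type vs its deletion strain."""

    gene_id: str
    wildtype_mean: float
    deletion_mean: float
    deletion_sd: float
    n_replicates: int = 3

    def __post_init__(self) -> None:
        if self.deletion_sd < 0:
            raise BackgroundModelError("deletion_sd must be >= 0")
        if self.n_replicates < 2:
            raise BackgroundModelError("n_replicates must be >= 2 for the SD to be defined")


@dataclass(frozen=True)
class DetectionCalls:
    """Boolean probes x scopes call matrix plus the model used per scope."""

    calls: pd.DataFrame
    models: Mapping[str, BackgroundModel]

    def detected(self, scope: str) -> list[str]:
        return self.calls.index[self.calls[scope]].tolist()


def _resolve_scope(counts: CountMatrix, scope: str | Sequence[str] | None) -> tuple[str, list[str]]:
    """A scope is either a condition label from the sample metadata or an
    explicit list of sample ids."""
    if scope is None:
        return "all", counts.sample_ids
    if isinstance(scope, str):
        ids = counts.samples_where(condition=scope)
        if not ids:
            raise BackgroundModelError(f"scope {scope!r} matches no samples")
        return scope, ids
    ids = list(scope)
    missing = [s for s in ids if s not in set(counts.sample_ids)]
    if missing:
        raise BackgroundModelError(f"scope samples not in matrix: {', '.join(missing)}")
    return ",".join(ids), ids


def negative_control_threshold(
    counts: CountMatrix, scope: str | Sequence[str] | None = None, k: float = 3.0
) -> BackgroundModel:
    """Threshold = mean + k*SD of the pooled negative-control counts in scope.

    The pool is all negative-control values (probes x samples) within
    the scope; SD uses the n-1 denominator.  Requires
    positive-normalized counts so that between-sample scale differences
    do not inflate the spread.
    """
    if counts.norm_state is NormState.RAW:
        raise BackgroundModelError("negative-control threshold requires positive-normalized counts")
    label, sample_ids = _resolve_scope(counts, scope)
    neg = counts.class_counts(ProbeClass.NEGATIVE)[sample_ids]
    values = neg.to_numpy().ravel()
    if values.size == 0:
        raise BackgroundModelError("code set has no negative controls")
    if values.size < 2:
        raise BackgroundModelError("a single negative-control value leaves the SD undefined")
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    return BackgroundModel(
        threshold=mean + k * sd, method="negctrl_mean_sd", k=k, scope=label, mean=mean, sd=sd
    )


def deletion_threshold(
    summaries: Iterable[DeletionSummary],
    k: float = 4.0,
    rounding: Rounding | str = Rounding.NONE,
) -> BackgroundModel:
    """Threshold from deletion-strain residual counts.

    Takes the summary with the largest residual (deletion-strain) mean
    and returns that mean plus k times *its* SD, optionally rounded up.
    """
    summaries = list(summaries)
    if not summaries:
        raise BackgroundModelError("deletion_threshold requires at least one summary")
    rounding = Rounding(rounding)
    top = max(summaries, key=lambda s: s.deletion_mean)
    raw = top.deletion_mean + k * top.deletion_sd
    return BackgroundModel(
        threshold=rounding.apply(raw),
        method="deletion_calibrated",
        k=k,
        scope=top.gene_id,
        mean=top.deletion_mean,
        sd=top.deletion_sd,
    )


def call_detection(
    counts: CountMatrix,
    models: BackgroundModel | Mapping[str, BackgroundModel],
    statistic: str = "group_mean",
) -> DetectionCalls:
    """Call each probe detected in each scope.

    ``models`` maps scope label (a condition in the sample metadata) to
    its threshold; a single model is applied to its own scope (or all
    samples if its scope is empty).  With ``statistic="group_mean"`` a
    probe is detected when its replicate-mean count strictly exceeds the
    threshold; with ``"per_sample"`` every sample in the scope must
    exceed it.
    """
    if statistic not in ("group_mean", "per_sample"):
        raise ValueError(f"unknown statistic {statistic!r}")
    if isinstance(models, BackgroundModel):
        models = {models.scope or "all": models}
    calls = {}
    for label, model in models.items():
        scope = None if label == "all" else label
        _, sample_ids = _resolve_scope(counts, scope)
        sub = counts.counts[sample_ids]
        if statistic == "group_mean":
            stat = sub.mean(axis=1)
            calls[label] = stat > model.threshold
        else:
            calls[label] = (sub > model.threshold).all(axis=1)
    return DetectionCalls(calls=pd.DataFrame(calls), models=dict(models))


def detection_summary(calls: DetectionCalls, codeset: CodeSet) -> pd.DataFrame:
    """Detected-probe counts per class per scope.

    Rows are probe classes (positive, negative, target) with the class
    size annotated; columns are scopes; cells count probes called
    detected.
    """
    classes = codeset.classes()
    rows = {}
    for pc in (ProbeClass.POSITIVE, ProbeClass.NEGATIVE, ProbeClass.TARGET):
        genes = codeset.by_class(pc)
        rows[f"{pc.value} (n={len(genes)})"] = calls.calls.loc[genes].sum(axis=0).astype(int)
    out = pd.DataFrame(rows).T
    out.index.name = "probe_class"
    return out
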