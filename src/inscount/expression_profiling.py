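"""Life-cycle expression profiles, fold-changes and pattern classification.

A stage profile holds, per gene and developmental stage, the replicate
mean and sample SD of fully normalized counts.  The canonical stage
order is embryo, L1 arrest, then 12/24/36/48/60 h of post-embryonic
development, then dauer arrest; "developing larvae" means the 12-48 h
stages (the 60 h point includes adults and their early embryos, so it
is excluded from the larval reference).

Pattern classification formalizes the qualitative vocabulary used to
describe stage profiles (embryo-specific, arrest-enriched, ...) into
explicit rules on stage means against a background threshold T and a
minimum fold F_min, applied in a fixed precedence order.  Borderline
genes can legitimately land in a different class than a human reader
would assign; the supporting statistics (peak stage, peak fold) are
emitted so such calls are auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .codeset_io import CountMatrix, NormState
from .errors import ValidationError

__all__ = [
    "STAGE_ORDER",
    "LARVAL_STAGES",
    "ARREST_STAGES",
    "PATTERN_LABELS",
    "ExpressionProfile",
    "stage_profile",
    "fold_change",
    "classify_patterns",
]

STAGE_ORDER = ("embryo", "L1 arrest", "12h", "24h", "36h", "48h", "60h", "dauer")
LARVAL_STAGES = ("12h", "24h", "36h", "48h")
ARREST_STAGES = ("L1 arrest", "dauer")

PATTERN_LABELS = (
    "below_background",
    "embryo_specific",
    "adult_enriched",
    "arrest_enriched",
    "larval_peaking",
    "broadly_expressed",
)


@dataclass
class ExpressionProfile:
    """Genes x stages replicate mean / SD / n, with an optional detection
    threshold attached for interpretation."""

    means: pd.DataFrame
    sds: pd.DataFrame
    ns: pd.DataFrame
    stage_order: tuple[str, ...] = STAGE_ORDER
    threshold: float | None = None

    def __post_init__(self) -> None:
        stages = list(self.means.columns)
        if len(set(stages)) != len(stages):
            raise ValidationError("stage labels must be unique")
        for name, df in (("sds", self.sds), ("ns", self.ns)):
            if list(df.columns) != stages or list(df.index) != list(self.means.index):
                raise ValidationError(f"{name} does not align with means")
        if (self.sds.to_numpy() < 0).any():
            raise ValidationError("SDs must be >= 0")
        if (self.ns.to_numpy() < 1).any():
            raise ValidationError("each cell needs n >= 1")

    @property
    def genes(self) -> list[str]:
        return list(self.means.index)

    @property
    def stages(self) -> list[str]:
        return list(self.means.columns)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (gene, stage, mean, sd, n) for serialization."""
        rows = []
        for g in self.genes:
            for s in self.stages:
                rows.append((g, s, self.means.at[g, s], self.sds.at[g, s], int(self.ns.at[g, s])))
        return pd.DataFrame(rows, columns=["gene_id", "stage", "mean", "sd", "n"]).set_index("gene_id")


def _order_stages(stages: Sequence[str]) -> list[str]:
    known = [s for s in STAGE_ORDER if s in set(stages)]
    extra = [s for s in stages if s not in set(STAGE_ORDER)]
    return known + sorted(extra)


def stage_profile(
    counts: CountMatrix,
    stage_grouping: str | Mapping[str, Sequence[str]] = "condition",
    require_normalized: bool = True,
    threshold: float | None = None,
) -> ExpressionProfile:
    """Replicate mean/SD/n per gene x stage.

    ``stage_grouping`` is a metadata column whose values are stage
    labels, or an explicit stage -> sample-ids mapping.  By default the
    counts must be fully normalized (both steps); pass
    ``require_normalized=False`` for already-averaged or externally
    normalized data.
    """
    if require_normalized and counts.norm_state is not NormState.TARGET_SUM_NORMALIZED:
        raise ValidationError(
            f"stage_profile requires fully normalized counts, got {counts.norm_state.value}"
        )
    if isinstance(stage_grouping, str):
        meta = counts.meta
        if stage_grouping not in meta.columns:
            raise ValidationError(f"unknown metadata column {stage_grouping!r}")
        mapping: dict[str, list[str]] = {}
        for sid, label in meta[stage_grouping].items():
            mapping.setdefault(str(label), []).append(sid)
    else:
        mapping = {str(k): list(v) for k, v in stage_grouping.items()}
        known = set(counts.sample_ids)
        for stage, ids in mapping.items():
            bad = [s for s in ids if s not in known]
            if bad:
                raise ValidationError(f"stage {stage!r}: unknown sample(s) {bad}")
    empty = [s for s, ids in mapping.items() if not ids]
    if empty:
        raise ValidationError(f"stage(s) with no replicates: {', '.join(empty)}")
    stages = _order_stages(list(mapping))
    means, sds, ns = {}, {}, {}
    for stage in stages:
        sub = counts.counts[mapping[stage]]
        means[stage] = sub.mean(axis=1)
        sds[stage] = sub.std(axis=1, ddof=1).fillna(0.0) if sub.shape[1] > 1 else pd.Series(0.0, index=sub.index)
        ns[stage] = pd.Series(sub.shape[1], index=sub.index)
    return ExpressionProfile(
        means=pd.DataFrame(means)[stages],
        sds=pd.DataFrame(sds)[stages],
        ns=pd.DataFrame(ns)[stages],
        threshold=threshold,
    )


def fold_change(
    profile: ExpressionProfile,
    gene: str,
    numerator: str | Sequence[str],
    denominator: str | Sequence[str],
) -> float:
    """F = mean of stage means over numerator stages / same over denominator.

    Ratio of means (not mean of ratios): stage means are the plotted and
    interpreted quantity, so their averages are what fold-changes relate.
    """
    num = [numerator] if isinstance(numerator, str) else list(numerator)
    den = [denominator] if isinstance(denominator, str) else list(denominator)
    for s in num + den:
        if s not in profile.stages:
            raise ValidationError(f"unknown stage {s!r}")
    if gene not in profile.means.index:
        raise ValidationError(f"unknown gene {gene!r}")
    den_mean = float(profile.means.loc[gene, den].mean())
    if den_mean <= 0:
        raise ValidationError(f"{gene}: denominator stage mean is 0, fold undefined")
    return float(profile.means.loc[gene, num].mean()) / den_mean


def classify_patterns(
    profile: ExpressionProfile,
    background: float | None = None,
    min_fold: float = 3.0,
    specificity_flags: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Assign one pattern label per gene.

    Rules, applied in precedence order on the stage means (T =
    ``background``, F = ``min_fold``):

    1. below_background — no stage mean exceeds T.
    2. embryo_specific — embryo mean > T and >= F x every other stage.
    3. adult_enriched — 60h mean > T and >= F x every other stage.
    4. arrest_enriched — mean over {L1 arrest, dauer} > T and >= F x
       the mean over developing larvae (12-48h).
    5. larval_peaking — max stage mean is at 12-48h, > T, and >= F x
       both the embryo and 60h means.
    6. broadly_expressed — everything else.

    Returns a table with label, peak stage (earliest stage attaining the
    max), peak fold (max mean / T) and any propagated specificity flag.
    Labels are invariant under rescaling all counts and T by the same
    positive constant.
    """
    T = profile.threshold if background is None else background
    if T is None:
        raise ValidationError("a background threshold is required (argument or profile attribute)")
    if T < 0:
        raise ValidationError("background threshold must be >= 0")
    means = profile.means
    stages = profile.stages
    larval = [s for s in LARVAL_STAGES if s in stages]
    required = {"embryo", "60h", *ARREST_STAGES}
    missing = required - set(stages)
    if missing or not larval:
        raise ValidationError(f"profile lacks stages needed for classification: {sorted(missing)}")

    records = []
    for gene in profile.genes:
        m = means.loc[gene]
        peak_stage = min((s for s in stages if m[s] == m.max()), key=stages.index)
        peak_fold = float(m.max() / T) if T > 0 else float("inf") if m.max() > 0 else 0.0
        others_than = lambda s: [x for x in stages if x != s]

        if not (m > T).any():
            label = "below_background"
        elif m["embryo"] > T and (m["embryo"] >= min_fold * m[others_than("embryo")]).all():
            label = "embryo_specific"
        elif m["60h"] > T and (m["60h"] >= min_fold * m[others_than("60h")]).all():
            label = "adult_enriched"
        elif (
            m[list(ARREST_STAGES)].mean() > T
            and m[list(ARREST_STAGES)].mean() >= min_fold * m[larval].mean()
        ):
            label = "arrest_enriched"
        elif (
            peak_stage in larval
            and m[peak_stage] > T
            and m[peak_stage] >= min_fold * m["embryo"]
            and m[peak_stage] >= min_fold * m["60h"]
        ):
            label = "larval_peaking"
        else:
            label = "broadly_expressed"
        flag = (specificity_flags or {}).get(gene, "")
        records.append((gene, label, peak_stage, peak_fold, flag))
    out = pd.DataFrame(
        records, columns=["gene_id", "label", "peak_stage", "peak_fold", "specificity_flag"]
    ).set_index("gene_id")
    return out
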