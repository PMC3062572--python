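"""Data model and I/O for code sets, count matrices and sample metadata.

An nCounter-style code set is a fixed panel of probes, each either a
*target* (a gene of the organism under study), a *positive* control (a
synthetic transcript spiked into the hybridization at a known fmol
amount) or a *negative* control (a probe against foreign sequence with
no spiked transcript, measuring nonspecific background).  Counts are
nonnegative integers per probe per sample; normalized counts are reals.

Files are plain delimited text (comma or tab, auto-detected), probes as
rows and samples as columns, matching the usual expression-matrix
convention.  An optional spreadsheet reader handles three-sheet
workbooks (raw / replicate means / replicate SDs).
"""

from __future__ import annotations

import csv
import enum
import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

__all__ = [
    "ProbeClass",
    "NormState",
    "ProbeDef",
    "CodeSet",
    "SampleMeta",
    "CountMatrix",
    "read_codeset",
    "write_codeset",
    "read_counts",
    "read_sample_meta",
    "write_table",
    "read_workbook",
]


class ProbeClass(str, enum.Enum):
    TARGET = "target"
    POSITIVE = "positive"
    NEGATIVE = "negative"

    @classmethod
    def parse(cls, value: str) -> "ProbeClass":
        v = str(value).strip().lower()
        aliases = {
            "target": cls.TARGET,
            "endogenous": cls.TARGET,
            "positive": cls.POSITIVE,
            "pos": cls.POSITIVE,
            "negative": cls.NEGATIVE,
            "neg": cls.NEGATIVE,
        }
        try:
            return aliases[v]
        except KeyError:
            raise ValidationError(f"unknown probe class {value!r}") from None


class NormState(str, enum.Enum):
    """Normalization state machine: raw -> positive_normalized -> target_sum_normalized."""

    RAW = "raw"
    POSITIVE_NORMALIZED = "positive_normalized"
    TARGET_SUM_NORMALIZED = "target_sum_normalized"


@dataclass(frozen=True)
class ProbeDef:
    """One probe of the code set.

    ``spike_fmol`` is required (and must be positive) exactly for
    positive controls: it is the known amount of synthetic transcript
    spiked into every hybridization.  ``specificity_flag`` carries known
    cross-hybridization caveats (e.g. a probe that actually reports a
    different, overlapping gene) into all downstream outputs.
    """

    gene_id: str
    probe_class: ProbeClass
    target_region: str = ""
    spike_fmol: float | None = None
    specificity_flag: str | None = None

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValidationError("gene_id must be nonempty")
        if self.probe_class is ProbeClass.POSITIVE:
            if self.spike_fmol is None or not self.spike_fmol > 0:
                raise ValidationError(
                    f"positive control {self.gene_id!r} requires spike_fmol > 0"
                )
        elif self.spike_fmol is not None:
            raise ValidationError(
                f"{self.gene_id!r}: spike_fmol only allowed for positive controls"
            )


@dataclass(frozen=True)
class CodeSet:
    """Ordered collection of probes with unique gene ids."""

    probes: tuple[ProbeDef, ...]

    def __post_init__(self) -> None:
        ids = [p.gene_id for p in self.probes]
        dupes = sorted({g for g in ids if ids.count(g) > 1})
        if dupes:
            raise ValidationError(f"duplicate gene_id(s): {', '.join(dupes)}")

    def __len__(self) -> int:
        return len(self.probes)

    def __iter__(self):
        return iter(self.probes)

    @property
    def gene_ids(self) -> list[str]:
        return [p.gene_id for p in self.probes]

    def by_class(self, probe_class: ProbeClass | str) -> list[str]:
        pc = probe_class if isinstance(probe_class, ProbeClass) else ProbeClass.parse(probe_class)
        return [p.gene_id for p in self.probes if p.probe_class is pc]

    @property
    def targets(self) -> list[str]:
        return self.by_class(ProbeClass.TARGET)

    @property
    def positives(self) -> list[str]:
        return self.by_class(ProbeClass.POSITIVE)

    @property
    def negatives(self) -> list[str]:
        return self.by_class(ProbeClass.NEGATIVE)

    @property
    def spike_fmols(self) -> pd.Series:
        """Spike amounts (fmol) indexed by positive-control gene id."""
        return pd.Series(
            {p.gene_id: float(p.spike_fmol) for p in self.probes if p.probe_class is ProbeClass.POSITIVE},
            name="spike_fmol",
        )

    def class_counts(self) -> dict[str, int]:
        return {
            "target": len(self.targets),
            "positive": len(self.positives),
            "negative": len(self.negatives),
        }

    def classes(self) -> pd.Series:
        """Probe class per gene, in code-set order."""
        return pd.Series(
            {p.gene_id: p.probe_class.value for p in self.probes}, name="probe_class"
        ).reindex(self.gene_ids)

    def probe(self, gene_id: str) -> ProbeDef:
        for p in self.probes:
            if p.gene_id == gene_id:
                return p
        raise KeyError(gene_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": [p.gene_id for p in self.probes],
                "probe_class": [p.probe_class.value for p in self.probes],
                "target_region": [p.target_region for p in self.probes],
                "spike_fmol": [p.spike_fmol for p in self.probes],
                "specificity_flag": [p.specificity_flag or "" for p in self.probes],
            }
        )


@dataclass(frozen=True)
class SampleMeta:
    """Per-sample annotation: input RNA mass (ug), condition label,
    replicate number and strain."""

    sample_id: str
    rna_mass: float = float("nan")
    condition: str = ""
    replicate: int = 1
    strain: str = ""

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValidationError("sample_id must be nonempty")
        if self.rna_mass == self.rna_mass and self.rna_mass < 0:  # NaN allowed
            raise ValidationError(f"{self.sample_id}: rna_mass must be >= 0")
        if self.replicate < 1:
            raise ValidationError(f"{self.sample_id}: replicate must be >= 1")


@dataclass
class CountMatrix:
    """Probes x samples count matrix with metadata and normalization state.

    ``counts`` rows are indexed by gene_id in code-set order; columns are
    sample ids in metadata order.  Raw counts are nonnegative integers;
    normalized counts are nonnegative reals.
    """

    counts: pd.DataFrame
    codeset: CodeSet
    samples: tuple[SampleMeta, ...]
    norm_state: NormState = NormState.RAW

    def __post_init__(self) -> None:
        self.samples = tuple(self.samples)
        sample_ids = [s.sample_id for s in self.samples]
        if len(set(sample_ids)) != len(sample_ids):
            raise ValidationError("duplicate sample_id in metadata")
        if list(self.counts.columns) != sample_ids:
            raise ValidationError("count columns do not match sample metadata order")
        if list(self.counts.index) != self.codeset.gene_ids:
            raise ValidationError("count rows do not match code-set probes")
        if (self.counts.to_numpy() < 0).any():
            raise ValidationError("counts must be nonnegative")
        if self.counts.isna().to_numpy().any():
            raise ValidationError("counts must not contain missing values")

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def meta(self) -> pd.DataFrame:
        """Sample metadata as a DataFrame indexed by sample_id."""
        return pd.DataFrame(
            {
                "rna_mass": [s.rna_mass for s in self.samples],
                "condition": [s.condition for s in self.samples],
                "replicate": [s.replicate for s in self.samples],
                "strain": [s.strain for s in self.samples],
            },
            index=pd.Index(self.sample_ids, name="sample_id"),
        )

    def samples_where(self, **criteria) -> list[str]:
        """Sample ids whose metadata match all keyword criteria."""
        out = []
        for s in self.samples:
            if all(getattr(s, k) == v for k, v in criteria.items()):
                out.append(s.sample_id)
        return out

    def class_counts(self, probe_class: ProbeClass | str) -> pd.DataFrame:
        """Sub-matrix restricted to one probe class."""
        return self.counts.loc[self.codeset.by_class(probe_class)]

    def with_counts(self, counts: pd.DataFrame, norm_state: NormState) -> "CountMatrix":
        return CountMatrix(counts=counts, codeset=self.codeset, samples=self.samples, norm_state=norm_state)

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        keep = [s for s in self.samples if s.sample_id in set(sample_ids)]
        return CountMatrix(
            counts=self.counts[[s.sample_id for s in keep]],
            codeset=self.codeset,
            samples=tuple(keep),
            norm_state=self.norm_state,
        )

    def copy(self) -> "CountMatrix":
        return CountMatrix(self.counts.copy(), self.codeset, self.samples, self.norm_state)


# ---------------------------------------------------------------------------
# delimited-text I/O

_FLOAT_FMT = "%.12g"  # round-trips doubles for this data's dynamic range


def _sniff_delimiter(path: Path) -> str:
    with open(path, "r", newline="") as fh:
        header = fh.readline()
    if "\t" in header:
        return "\t"
    if "," in header:
        return ","
    try:
        return csv.Sniffer().sniff(header).delimiter
    except csv.Error:
        return ","


def _require_columns(df: pd.DataFrame, required: Iterable[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")


def read_codeset(path: str | Path, dialect: str | None = None) -> CodeSet:
    """Read a code-set definition table.

    Required columns: ``gene_id``, ``probe_class``; optional:
    ``target_region``, ``spike_fmol``, ``specificity_flag``.  Probe
    classes are parsed case-insensitively.  Rows violating probe
    invariants are reported together in one :class:`ValidationError`.
    """
    path = Path(path)
    sep = dialect or _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, dtype=str)
    _require_columns(df, ["gene_id", "probe_class"], path)
    probes: list[ProbeDef] = []
    problems: list[str] = []
    for i, row in df.iterrows():
        try:
            fmol_raw = row.get("spike_fmol")
            fmol = None
            if fmol_raw is not None and str(fmol_raw).strip() not in ("", "nan"):
                fmol = float(fmol_raw)
            flag = row.get("specificity_flag")
            flag = None if flag is None or str(flag).strip() in ("", "nan") else str(flag)
            probes.append(
                ProbeDef(
                    gene_id=str(row["gene_id"]).strip(),
                    probe_class=ProbeClass.parse(row["probe_class"]),
                    target_region=str(row.get("target_region") or "") if str(row.get("target_region")) != "nan" else "",
                    spike_fmol=fmol,
                    specificity_flag=flag,
                )
            )
        except (ValidationError, ValueError) as exc:
            problems.append(f"row {i + 2}: {exc}")
    if problems:
        raise ValidationError(f"{path}: invalid probe rows:\n" + "\n".join(problems))
    return CodeSet(probes=tuple(probes))


def write_codeset(codeset: CodeSet, path: str | Path, sep: str = ",") -> None:
    codeset.to_frame().to_csv(path, sep=sep, index=False)


def read_sample_meta(path: str | Path, dialect: str | None = None) -> tuple[SampleMeta, ...]:
    """Read per-sample metadata (sample_id, rna_mass, condition, replicate, strain)."""
    path = Path(path)
    sep = dialect or _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep)
    _require_columns(df, ["sample_id"], path)
    metas = []
    for _, row in df.iterrows():
        metas.append(
            SampleMeta(
                sample_id=str(row["sample_id"]),
                rna_mass=float(row["rna_mass"]) if "rna_mass" in df.columns else float("nan"),
                condition=str(row.get("condition", "") or ""),
                replicate=int(row["replicate"]) if "replicate" in df.columns else 1,
                strain=str(row.get("strain", "") or ""),
            )
        )
    return tuple(metas)


def read_counts(
    path: str | Path,
    codeset: CodeSet,
    samples: Sequence[SampleMeta] | None = None,
    dialect: str | None = None,
    allow_missing: bool = False,
    norm_state: NormState = NormState.RAW,
) -> CountMatrix:
    """Read a probes x samples count table against a code set.

    The first column holds probe ids; remaining columns are samples.
    Probes present in the code set but absent from the file raise unless
    ``allow_missing`` is set (missing rows are then dropped from the
    returned matrix's code set).  Negative or non-numeric cells raise a
    :class:`FormatError` with row/column coordinates.
    """
    path = Path(path)
    sep = dialect or _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)

    unknown = [g for g in df.index if g not in set(codeset.gene_ids)]
    if unknown:
        raise ValidationError(f"{path}: unknown probe id(s): {', '.join(map(str, unknown))}")
    absent = [g for g in codeset.gene_ids if g not in set(df.index)]
    cs = codeset
    if absent:
        if not allow_missing:
            raise ValidationError(
                f"{path}: probes in code set but absent from file: {', '.join(absent)}"
            )
        cs = CodeSet(tuple(p for p in codeset.probes if p.gene_id not in set(absent)))

    for col in df.columns:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if bad.any():
            probe = df.index[bad.argmax()]
            raise FormatError(f"{path}: non-numeric count at probe {probe!r}, sample {col!r}")
        if df[col].isna().any():
            probe = df.index[df[col].isna().argmax()]
            raise FormatError(f"{path}: missing count at probe {probe!r}, sample {col!r}")
        neg = numeric < 0
        if neg.any():
            pos = int(neg.argmax())
            raise FormatError(
                f"{path}: negative count ({numeric.iloc[pos]}) at probe {df.index[pos]!r}, sample {col!r}"
            )
        df[col] = numeric.astype(float)

    df = df.reindex(cs.gene_ids)
    if samples is None:
        samples = tuple(SampleMeta(sample_id=str(c)) for c in df.columns)
    else:
        samples = tuple(samples)
        want = [s.sample_id for s in samples]
        missing_cols = [s for s in want if s not in df.columns]
        if missing_cols:
            raise ValidationError(f"{path}: samples missing from file: {', '.join(missing_cols)}")
        df = df[want]
    return CountMatrix(counts=df, codeset=cs, samples=samples, norm_state=norm_state)


def write_table(obj, path: str | Path, sep: str = ",") -> None:
    """Write a CountMatrix, ExpressionProfile or plain DataFrame as
    delimited text with a header.  Numeric cells round-trip to at least
    12 significant digits."""
    path = Path(path)
    if isinstance(obj, CountMatrix):
        df = obj.counts.copy()
        df.index.name = "gene_id"
        df.to_csv(path, sep=sep, float_format=_FLOAT_FMT)
    elif hasattr(obj, "to_frame") and not isinstance(obj, pd.Series):
        obj.to_frame().to_csv(path, sep=sep, float_format=_FLOAT_FMT)
    elif isinstance(obj, (pd.DataFrame, pd.Series)):
        obj.to_csv(path, sep=sep, float_format=_FLOAT_FMT)
    else:
        raise TypeError(f"cannot serialize {type(obj).__name__}")


def read_workbook(path: str | Path, codeset: CodeSet | None = None) -> dict[str, pd.DataFrame]:
    """Read a three-sheet workbook (raw counts / replicate means /
    replicate SDs), returning sheets verbatim keyed ``raw``, ``mean``,
    ``sd``.  The caller declares the normalization state of the raw
    sheet; sheets beyond the third are ignored."""
    sheets = pd.read_excel(Path(path), sheet_name=None, index_col=0)
    names = list(sheets)
    if len(names) < 3:
        raise FormatError(f"{path}: expected 3 sheets (raw, mean, sd), found {len(names)}")
    out = {"raw": sheets[names[0]], "mean": sheets[names[1]], "sd": sheets[names[2]]}
    if codeset is not None:
        known = set(codeset.gene_ids)
        for key, df in out.items():
            unknown = [g for g in df.index if str(g) not in known]
            if unknown:
                raise ValidationError(f"{path} sheet {key!r}: unknown probe id(s): {unknown}")
    return out
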