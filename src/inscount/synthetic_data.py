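"""Synthetic digital barcode-count data with known ground truth.

The generator reproduces the statistical structure of a solution-phase
hybridization counting assay run on an insulin-like-gene code set:

* expected target counts are linear in input RNA mass m (counts =
  a_g * m above background, with per-gene abundance a_g in counts/ug);
* positive-control spike-ins are added to the hybridization at fixed
  fmol amounts, so their expected counts are independent of m;
* every probe carries nonspecific background b(m) that is flat up to
  1 ug and doubles log-linearly by 10 ug, with a fixed per-probe
  propensity multiplier (some probe sequences stick more than others);
* observed counts are Poisson around the expected value, with a
  lognormal per-replicate technical factor on the specific target
  signal, plus an independent per-gene lognormal factor for biological
  replicates;
* a deletion strain retains a fraction rho of the deleted gene's own
  specific signal (cross-hybridization of family members scales with
  the gene's wild-type expression).

Default rates are calibrated so that a simulated mass titration
reproduces the magnitudes of a real 43-target insulin-like code set:
positive-control average ~5600 counts, negative controls ~24 counts up
to 1 ug doubling at 10 ug, mean target count ~230 at 0.1 ug scaling
~10x per decade of RNA, technical CV floor ~1.5% and median technical
CV ~8% at 0.1 ug.

Everything is deterministic given (config, seed): gene-level parameters
(abundances, background propensities) are drawn from a dedicated stream
of the config seed, and each simulation call takes or derives its own
:class:`numpy.random.Generator`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .codeset_io import CodeSet, CountMatrix, NormState, ProbeClass, ProbeDef, SampleMeta
from .errors import ValidationError
from .expression_profiling import ARREST_STAGES, LARVAL_STAGES, STAGE_ORDER

__all__ = [
    "SyntheticConfig",
    "simulate_codeset",
    "ground_truth",
    "simulate_hybridization",
    "simulate_titration",
    "simulate_deletion_strain",
    "default_stage_profiles",
    "simulate_life_cycle",
    "simulate_qpcr",
]

REFERENCE_GENES = ("rpl-12", "rpl-19")


def _default_spike_fmols() -> tuple[float, ...]:
    # 2-fold ladder from 0.1 fmol (the lowest spike is near the detection limit)
    return tuple(0.1 * 2.0**k for k in range(10))


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator parameters (the study conditions).

    ``abundance_median`` / ``abundance_sigma`` set the lognormal spread
    of per-gene target abundances (counts per ug of total RNA at
    reference efficiency).  ``background_rate`` is the baseline
    nonspecific count level b0; b(m) = b0 for m <= 1 ug and rises
    log-linearly to 2*b0 at 10 ug.  ``replicate_noise_cv`` is the
    technical (same RNA prep) lognormal CV on specific signal;
    ``biological_noise_cv`` is the additional per-gene CV between
    biological replicates.  ``residual_crosshyb`` is the fraction of a
    deleted gene's own specific signal that survives as
    cross-hybridization in its deletion strain.
    """

    n_targets: int = 43
    n_positives: int = 10
    n_negatives: int = 8
    abundance_median: float = 1400.0  # counts/ug, median over genes
    abundance_sigma: float = 1.0  # lognormal sigma of gene abundances
    target_abundances: Mapping[str, float] | None = None  # explicit override, counts/ug
    spike_fmols: tuple[float, ...] = field(default_factory=_default_spike_fmols)
    spike_count_per_fmol: float = 550.0
    background_rate: float = 24.0  # b0, counts
    probe_background_cv: float = 0.25  # probe-to-probe spread of background propensity
    replicate_noise_cv: float = 0.015  # technical lognormal CV (tau)
    biological_noise_cv: float = 0.20  # extra per-gene CV for biological replicates
    residual_crosshyb: float = 0.05  # rho
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_targets, self.n_positives, self.n_negatives) < 1:
            raise ValidationError("probe class sizes must be >= 1")
        if len(self.spike_fmols) != self.n_positives:
            raise ValidationError("spike_fmols must have one entry per positive control")
        if min(self.spike_fmols) <= 0 or self.spike_count_per_fmol <= 0:
            raise ValidationError("spike amounts and counts/fmol must be positive")
        if self.background_rate <= 0 or self.abundance_median <= 0:
            raise ValidationError("rates must be positive")
        if not 0 <= self.residual_crosshyb < 1:
            raise ValidationError("residual_crosshyb must lie in [0, 1)")
        if self.replicate_noise_cv < 0 or self.biological_noise_cv < 0:
            raise ValidationError("noise CVs must be >= 0")

    def background(self, mass: float) -> float:
        """Expected baseline background b(m) in counts."""
        if mass < 0:
            raise ValidationError("mass must be >= 0")
        if mass <= 1.0:
            return self.background_rate
        # doubles per decade above 1 ug: b(10) = 2*b0 exactly
        return self.background_rate * 2.0 ** math.log10(mass)


# canonical insulin-like panel: 39 ins genes + daf-28 = 40 peptides,
# plus the receptor (daf-2), its effector (daf-16) and a readout (sod-3)
def _target_names(n: int) -> list[str]:
    canonical = [f"ins-{i}" for i in range(1, 40)] + ["daf-28", "daf-2", "daf-16", "sod-3"]
    if n <= len(canonical):
        return canonical[:n]
    return canonical + [f"gene-{i}" for i in range(1, n - len(canonical) + 1)]


def simulate_codeset(config: SyntheticConfig) -> CodeSet:
    """Build the synthetic code set: targets, spike-in positives, negatives."""
    probes = [
        ProbeDef(
            gene_id=g,
            probe_class=ProbeClass.TARGET,
            specificity_flag="reports acdh-2" if g == "ins-13" else None,
        )
        for g in _target_names(config.n_targets)
    ]
    for j, fmol in enumerate(config.spike_fmols):
        probes.append(ProbeDef(gene_id=f"POS_{chr(65 + j)}", probe_class=ProbeClass.POSITIVE, spike_fmol=fmol))
    for j in range(config.n_negatives):
        probes.append(ProbeDef(gene_id=f"NEG_{chr(65 + j)}", probe_class=ProbeClass.NEGATIVE))
    return CodeSet(tuple(probes))


def _lognormal_unit_mean(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Lognormal draws with mean exactly 1 and the requested CV."""
    if cv == 0:
        return np.ones(size)
    sigma2 = math.log1p(cv * cv)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=math.sqrt(sigma2), size=size)


@dataclass(frozen=True)
class GroundTruth:
    """Gene-level parameters drawn once per (config, seed)."""

    codeset: CodeSet
    abundances: pd.Series  # counts per ug, index = target gene ids
    background_mult: pd.Series  # per-probe background propensity, all probes


def ground_truth(config: SyntheticConfig) -> GroundTruth:
    """Deterministic gene-level truth for a config (dedicated seed stream)."""
    codeset = simulate_codeset(config)
    rng = np.random.default_rng([config.seed, 9001])
    targets = codeset.targets
    if config.target_abundances is not None:
        abund = pd.Series(config.target_abundances, dtype=float).reindex(targets)
        if abund.isna().any():
            raise ValidationError("target_abundances must cover every target gene")
    else:
        abund = pd.Series(
            config.abundance_median
            * np.exp(rng.normal(0.0, config.abundance_sigma, size=len(targets))),
            index=targets,
        )
    mult = pd.Series(
        _lognormal_unit_mean(rng, config.probe_background_cv, len(codeset)),
        index=codeset.gene_ids,
    )
    return GroundTruth(codeset=codeset, abundances=abund, background_mult=mult)


def _expected_counts(
    config: SyntheticConfig,
    truth: GroundTruth,
    mass: float,
    abundances: pd.Series,
) -> pd.Series:
    """Noise-free expected count per probe at the given mass."""
    cs = truth.codeset
    bg = config.background(mass) * truth.background_mult
    lam = bg.copy()
    lam.loc[abundances.index] += abundances * mass
    fmols = cs.spike_fmols
    lam.loc[fmols.index] += config.spike_count_per_fmol * fmols
    return lam


def _draw_counts(
    config: SyntheticConfig,
    truth: GroundTruth,
    mass: float,
    n_replicates: int,
    rng: np.random.Generator,
    abundances: pd.Series | None = None,
    biological: bool = False,
) -> pd.DataFrame:
    """Poisson counts (probes x replicates) around the noisy expected value."""
    cs = truth.codeset
    abund = truth.abundances if abundances is None else abundances
    bg = (config.background(mass) * truth.background_mult).to_numpy()[:, None]
    specific = np.zeros((len(cs), n_replicates))
    idx = pd.Index(cs.gene_ids)
    t_pos = idx.get_indexer(abund.index)
    u = _lognormal_unit_mean(rng, config.replicate_noise_cv, n_replicates)  # technical, per replicate
    sig = abund.to_numpy()[:, None] * mass * u[None, :]
    if biological:
        sig = sig * _lognormal_unit_mean(rng, config.biological_noise_cv, sig.shape)
    specific[t_pos, :] = sig
    fmols = cs.spike_fmols
    p_pos = idx.get_indexer(fmols.index)
    specific[p_pos, :] += (config.spike_count_per_fmol * fmols.to_numpy())[:, None]
    lam = bg + specific
    counts = rng.poisson(lam).astype(float)
    return pd.DataFrame(counts, index=cs.gene_ids)


def _assemble(
    truth: GroundTruth,
    blocks: Sequence[tuple[pd.DataFrame, list[SampleMeta]]],
) -> CountMatrix:
    frames, metas = [], []
    for df, meta in blocks:
        df = df.copy()
        df.columns = [m.sample_id for m in meta]
        frames.append(df)
        metas.extend(meta)
    return CountMatrix(
        counts=pd.concat(frames, axis=1),
        codeset=truth.codeset,
        samples=tuple(metas),
        norm_state=NormState.RAW,
    )


def simulate_hybridization(
    config: SyntheticConfig,
    mass: float,
    n_replicates: int = 3,
    condition: str | None = None,
    strain: str = "N2",
    biological: bool = False,
    rng: np.random.Generator | None = None,
) -> CountMatrix:
    """Simulate one hybridization condition: ``n_replicates`` samples at
    RNA mass ``mass`` (ug).  ``mass=0`` is the no-RNA control: targets
    then carry only probe-level background, like negative controls."""
    if mass < 0:
        raise ValidationError("mass must be >= 0")
    truth = ground_truth(config)
    if rng is None:
        rng = np.random.default_rng([config.seed, 1, int(round(mass * 1000))])
    cond = condition if condition is not None else f"{mass:g}ug"
    counts = _draw_counts(config, truth, mass, n_replicates, rng, biological=biological)
    meta = [
        SampleMeta(sample_id=f"{cond}_r{r + 1}", rna_mass=mass, condition=cond, replicate=r + 1, strain=strain)
        for r in range(n_replicates)
    ]
    return _assemble(truth, [(counts, meta)])


def simulate_titration(
    config: SyntheticConfig,
    masses: Sequence[float] = (0.0, 0.1, 1.0, 10.0),
    n_replicates: int = 3,
) -> CountMatrix:
    """The input-mass titration experiment: technical replicates of one
    RNA preparation hybridized at each mass (plus a no-RNA control)."""
    truth = ground_truth(config)
    rng = np.random.default_rng([config.seed, 2])
    blocks = []
    for m in masses:
        cond = f"{m:g}ug"
        counts = _draw_counts(config, truth, m, n_replicates, rng)
        meta = [
            SampleMeta(sample_id=f"{cond}_r{r + 1}", rna_mass=m, condition=cond, replicate=r + 1)
            for r in range(n_replicates)
        ]
        blocks.append((counts, meta))
    return _assemble(truth, blocks)


def simulate_deletion_strain(
    config: SyntheticConfig,
    gene: str,
    mass: float = 3.0,
    n_replicates: int = 3,
    rng: np.random.Generator | None = None,
) -> CountMatrix:
    """Simulate a strain in which ``gene`` is deleted: its specific
    signal drops to the residual cross-hybridization fraction rho, all
    other probes are unchanged."""
    truth = ground_truth(config)
    if gene not in truth.abundances.index:
        raise ValidationError(f"{gene!r} is not a target gene")
    if rng is None:
        rng = np.random.default_rng([config.seed, 3, abs(hash(gene)) % (2**31)])
    abund = truth.abundances.copy()
    abund[gene] = abund[gene] * config.residual_crosshyb
    strain = f"{gene}(del)"
    counts = _draw_counts(config, truth, mass, n_replicates, rng, abundances=abund, biological=True)
    meta = [
        SampleMeta(sample_id=f"{strain}_r{r + 1}", rna_mass=mass, condition="L1 arrest",
                   replicate=r + 1, strain=strain)
        for r in range(n_replicates)
    ]
    return _assemble(truth, [(counts, meta)])


# ---------------------------------------------------------------------------
# life-cycle experiment

# planted stage-specific abundance levels, counts/ug of total RNA
_EMBRYO_GENES = ("ins-2", "ins-34")
_ADULT_GENES = ("ins-19",)
_ARREST_GENES = ("ins-18", "ins-10", "ins-15", "ins-16", "ins-17", "ins-20", "ins-24")
_LOW_GENES = ("ins-8", "ins-21", "ins-25", "ins-32", "ins-36", "ins-39")


def default_stage_profiles(config: SyntheticConfig) -> tuple[pd.DataFrame, pd.Series]:
    """Planted gene x stage abundances (counts/ug) and their pattern labels.

    The panel plants every pattern class the classifier knows: two
    embryo-specific genes, one adult-enriched, seven arrest-enriched, a
    sod-3-like gene 10x up in L1 arrest and 30x up in dauer relative to
    developing larvae, two larval-peaking genes (one peaking at 12 h, one
    at 36 h), six genes below background, and the remainder broadly
    expressed.  Broad-gene levels are adjusted per stage so that the
    total target abundance is identical in every stage (whole-organism
    mRNA composition is roughly mass-invariant), which makes target-sum
    normalization exact rather than distorting.
    """
    genes = _target_names(config.n_targets)
    stages = list(STAGE_ORDER)
    prof = pd.DataFrame(0.0, index=genes, columns=stages)
    labels = pd.Series("broadly_expressed", index=pd.Index(genes, name="gene_id"), name="label")

    def set_profile(gene, values, label):
        if gene in prof.index:
            prof.loc[gene] = [values[s] for s in stages]
            labels[gene] = label

    base_off = 100.0
    for g in _EMBRYO_GENES:
        set_profile(g, {s: 2000.0 if s == "embryo" else base_off for s in stages}, "embryo_specific")
    for g in _ADULT_GENES:
        set_profile(g, {s: 2000.0 if s == "60h" else base_off for s in stages}, "adult_enriched")
    for g in _ARREST_GENES:
        set_profile(
            g, {s: 800.0 if s in ARREST_STAGES else base_off for s in stages}, "arrest_enriched"
        )
    # sod-3-like: 10x in L1 arrest and 30x in dauer vs developing larvae
    sod3_larval = 120.0
    set_profile(
        "sod-3",
        {
            "embryo": sod3_larval,
            "L1 arrest": 10.0 * sod3_larval,
            "12h": sod3_larval,
            "24h": sod3_larval,
            "36h": sod3_larval,
            "48h": sod3_larval,
            "60h": sod3_larval,
            "dauer": 30.0 * sod3_larval,
        },
        "arrest_enriched",
    )
    set_profile(
        "ins-33",
        {"embryo": 60, "L1 arrest": 60, "12h": 200, "24h": 600, "36h": 1200, "48h": 800, "60h": 150, "dauer": 60},
        "larval_peaking",
    )
    set_profile(
        "daf-28",
        {"embryo": 80, "L1 arrest": 100, "12h": 1500, "24h": 500, "36h": 300, "48h": 300, "60h": 200, "dauer": 80},
        "larval_peaking",
    )
    for g in _LOW_GENES:
        set_profile(g, {s: 10.0 for s in stages}, "below_background")

    broad = [g for g in genes if labels[g] == "broadly_expressed"]
    levels = [300.0, 500.0, 800.0, 1200.0]
    for i, g in enumerate(broad):
        prof.loc[g] = levels[i % len(levels)]
    # equalize stage totals through the broad genes (composition invariance)
    if broad:
        nonbroad_total = prof.drop(index=broad).sum(axis=0)
        broad_total = prof.loc[broad].sum(axis=0)
        common = float((nonbroad_total + broad_total).max())
        factors = (common - nonbroad_total) / broad_total
        prof.loc[broad] = prof.loc[broad].mul(factors, axis=1)
    return prof, labels


def simulate_life_cycle(
    config: SyntheticConfig,
    stage_profiles: pd.DataFrame | None = None,
    labels: pd.Series | None = None,
    n_replicates: int = 3,
    mass: float = 3.0,
    rng: np.random.Generator | None = None,
) -> tuple[CountMatrix, pd.Series, pd.DataFrame]:
    """Simulate the life-cycle experiment: biological replicates at a
    fixed hybridization mass for each stage, with planted stage x gene
    abundances.  Returns (raw counts, ground-truth labels, planted
    abundances)."""
    if stage_profiles is None:
        stage_profiles, labels = default_stage_profiles(config)
    elif labels is None:
        labels = pd.Series("unknown", index=stage_profiles.index, name="label")
    if (stage_profiles.to_numpy() < 0).any():
        raise ValidationError("stage abundances must be >= 0")
    truth = ground_truth(config)
    missing = [g for g in stage_profiles.index if g not in set(truth.codeset.targets)]
    if missing:
        raise ValidationError(f"stage profile genes not in code set: {missing}")
    if rng is None:
        rng = np.random.default_rng([config.seed, 4])
    blocks = []
    for stage in stage_profiles.columns:
        abund = stage_profiles[stage].astype(float)
        counts = _draw_counts(config, truth, mass, n_replicates, rng, abundances=abund, biological=True)
        meta = [
            SampleMeta(
                sample_id=f"{stage}_r{r + 1}".replace(" ", "_"),
                rna_mass=mass,
                condition=stage,
                replicate=r + 1,
            )
            for r in range(n_replicates)
        ]
        blocks.append((counts, meta))
    return _assemble(truth, blocks), labels, stage_profiles


def simulate_qpcr(
    config: SyntheticConfig,
    genes: Sequence[str] | None = None,
    stage_profiles: pd.DataFrame | None = None,
    n_replicates: int = 3,
    efficiency: float = 2.0,
    intercept: float = 38.0,
    ct_noise_sd: float = 0.15,
    copies_per_abundance: float = 0.5,
    reference_copies: float = 2.0e4,
    dilution_copies: Sequence[float] = (1e2, 1e3, 1e4, 1e5, 1e6),
    rng: np.random.Generator | None = None,
) -> dict[str, pd.DataFrame]:
    """Simulate qPCR cross-validation of a stage experiment.

    Emits a genomic-DNA dilution series per gene (for standard-curve
    fitting) and per-stage replicate Ct measurements whose underlying
    copy numbers are proportional to the same stage abundances used for
    count simulation, plus two constant reference genes.  Ct values
    follow Ct = intercept + slope*log10(copies) + N(0, ct_noise_sd) with
    slope = -1/log10(efficiency).
    """
    if not 1.0 < efficiency <= 2.2:
        raise ValidationError("efficiency must lie in (1, 2.2]")
    if stage_profiles is None:
        stage_profiles, _ = default_stage_profiles(config)
    if genes is None:
        genes = list(stage_profiles.index)
    if rng is None:
        rng = np.random.default_rng([config.seed, 5])
    slope = -1.0 / math.log10(efficiency)

    def ct_of(copies, size=None):
        mu = intercept + slope * np.log10(copies)
        return mu + rng.normal(0.0, ct_noise_sd, size=np.shape(mu) if size is None else size)

    dil_rows = []
    all_genes = list(genes) + list(REFERENCE_GENES)
    for g in all_genes:
        for c in dilution_copies:
            dil_rows.append((g, float(c), float(ct_of(float(c), size=()))))
    dilutions = pd.DataFrame(dil_rows, columns=["gene_id", "copies", "ct"])

    meas_rows = []
    truth_rows = []
    for stage in stage_profiles.columns:
        for r in range(1, n_replicates + 1):
            sample = f"{stage}_r{r}".replace(" ", "_")
            prep = float(_lognormal_unit_mean(rng, 0.2, ()))  # per-prep yield, cancels on normalization
            for g in all_genes:
                base = reference_copies if g in REFERENCE_GENES else (
                    float(stage_profiles.at[g, stage]) * copies_per_abundance
                )
                noisy = base * prep * float(_lognormal_unit_mean(rng, config.biological_noise_cv, ()))
                if noisy <= 0:
                    continue
                meas_rows.append((g, sample, stage, r, float(ct_of(noisy, size=()))))
                truth_rows.append((g, sample, stage, r, base))
    cols = ["gene_id", "sample_id", "stage", "replicate"]
    measurements = pd.DataFrame(meas_rows, columns=cols + ["ct"])
    truth = pd.DataFrame(truth_rows, columns=cols + ["copies"])
    return {"dilutions": dilutions, "measurements": measurements, "truth_copies": truth}
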