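"""Synthetic qPCR Ct matrices and miRNA count matrices with known ground truth.

The generators emulate the two-cohort plasma-EV biomarker study design the
pipeline is built for: per cohort, 10 cases vs 10 controls assayed on a panel
of 34 target miRNAs, a handful of stable reference-candidate assays, and
constant spike-in controls.  Eight of the targets carry cohort-specific true
fold changes (the published fingerprint effects); every other target is null
(FC = 1).

Generative model for a Ct value (cycles; lower Ct = more template):

    Ct(assay i, sample j) = base_i + shift_j - log2(FC_i) * [j is case] + eps

where ``base_i`` is an assay-level baseline, ``shift_j`` a per-sample loading
shift common to all non-spike-in assays (what reference-gene normalization
must remove), and ``eps`` additive Gaussian noise on the Ct (log2) scale.
Spike-ins are independent of the sample loading.  Haemolysis contamination is
modelled as a Ct drop on miR-451a (red-cell enriched) in a random subset of
samples, leaving miR-23a-3p untouched.

Counts are drawn gene-wise from a negative binomial with common dispersion
``phi`` (variance mu + phi*mu^2; Poisson when phi = 0), with log-normal gene
abundances scaled by per-sample library size.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import CASE, CONTROL, CtMatrix, CountMatrix, SampleSheet

HEMOLYSIS_ASSAY = "miR-451a"
HEMOLYSIS_STABLE_ASSAY = "miR-23a-3p"

#: published per-cohort fold regulations of the eight fingerprint miRNAs
#: (fold regulation = FC if FC >= 1 else -1/FC; sign encodes direction)
FINGERPRINT_FOLD_REGULATION: dict[str, dict[str, float]] = {
    "miR-146a-5p": {"1": 1.2, "2": 1.4},
    "miR-199a-3p": {"1": 1.4, "2": 2.7},
    "miR-4454": {"1": -1.7, "2": -1.8},
    "miR-10b-5p": {"1": -2.1, "2": -7.0},
    "miR-29b-3p": {"1": -1.7, "2": -1.7},
    "miR-151a-3p": {"1": 1.5, "2": 2.2},
    "miR-151a-5p": {"1": 1.4, "2": 3.2},
    "miR-199a-5p": {"1": 1.9, "2": 4.2},
}

#: panel targets that are truly null in the simulation (FC = 1 in both cohorts)
NULL_TARGETS: tuple[str, ...] = (
    "let-7b-5p", "let-7d-3p", "let-7d-5p", "miR-126-3p", "miR-126-5p",
    "miR-133a-3p", "miR-1-3p", "miR-143-3p", "miR-146a-3p", "miR-194-3p",
    "miR-23a-3p", "miR-330-3p", "miR-338-3p", "miR-339-3p", "miR-339-5p",
    "miR-451a", "miR-517a-3p", "miR-584-5p", "miR-625-3p", "miR-708-5p",
    "miR-744-5p",
    # padding to the 34-assay panel size
    "miR-24-3p", "miR-150-3p", "miR-16-5p", "miR-320a", "miR-486-5p",
)

DEFAULT_REFERENCE_ASSAYS: tuple[str, ...] = (
    "miR-103a-3p", "miR-30c-5p", "miR-191-5p", "miR-142-3p",
)

SPIKEIN_ASSAYS: tuple[str, ...] = ("UniSp3", "UniSp6")


def fold_regulation_to_fold_change(fr: float) -> float:
    """Invert the sign-symmetric fold-regulation convention back to linear FC."""
    if fr == 0:
        raise ValueError("fold regulation cannot be 0")
    return fr if fr >= 1 else -1.0 / fr


def default_assay_effects() -> dict[str, dict[str, float]]:
    """True linear fold changes per (assay, cohort) for the default panel."""
    effects: dict[str, dict[str, float]] = {}
    for assay, per_cohort in FINGERPRINT_FOLD_REGULATION.items():
        effects[assay] = {
            cohort: fold_regulation_to_fold_change(fr)
            for cohort, fr in per_cohort.items()
        }
    for assay in NULL_TARGETS:
        effects[assay] = {"1": 1.0, "2": 1.0}
    return effects


@dataclass
class SimulationSpec:
    """Parameters of the qPCR cohort simulator.

    ``assay_effects`` maps every target assay to its per-cohort linear fold
    change (case vs control); FC = 1 means null.  All noise parameters are in
    cycles (Ct / log2 units).
    """

    cohorts: tuple[str, ...] = ("1", "2")
    n_case: int = 10
    n_control: int = 10
    assay_effects: Mapping[str, Mapping[str, float]] = field(
        default_factory=default_assay_effects
    )
    n_reference_genes: int = 4
    reference_noise_sd: float = 0.1
    target_noise_sd: float = 0.25
    load_shift_sd: float = 1.0
    base_ct_range: tuple[float, float] = (18.0, 28.0)
    hemolysis_fraction: float = 0.05
    hemolysis_ct_drop: float = 5.0
    spikein_ct: float = 20.0
    spikein_sd: float = 0.15
    seed: int = 0
    # assay-level baselines pinned so the haemolysis statistic has a stable
    # noise-free value (H = 22 - 19 = 3 cycles) instead of a random one
    fixed_base_ct: Mapping[str, float] = field(
        default_factory=lambda: {HEMOLYSIS_STABLE_ASSAY: 22.0, HEMOLYSIS_ASSAY: 19.0}
    )

    def __post_init__(self) -> None:
        for name in ("reference_noise_sd", "target_noise_sd", "load_shift_sd", "spikein_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.hemolysis_fraction <= 1.0:
            raise ValueError("hemolysis_fraction must be in [0, 1]")
        if self.n_case < 2 or self.n_control < 2:
            raise ValueError("need at least 2 samples per group")
        if self.n_reference_genes < 0:
            raise ValueError("n_reference_genes must be >= 0")
        for assay, per_cohort in self.assay_effects.items():
            for cohort, fc in per_cohort.items():
                if fc <= 0:
                    raise ValueError(f"fold change must be > 0 ({assay}, cohort {cohort})")

    @property
    def reference_assays(self) -> tuple[str, ...]:
        k = self.n_reference_genes
        names = list(DEFAULT_REFERENCE_ASSAYS[:k])
        names += [f"ref-{i + 1}" for i in range(len(names), k)]
        return tuple(names)

    def with_effects(self, effects: Mapping[str, Mapping[str, float]]) -> "SimulationSpec":
        return replace(self, assay_effects=effects)


@dataclass
class GroundTruth:
    """Generative truth recorded alongside a simulated cohort."""

    true_fold_change: dict[tuple[str, str], float]
    hemolysed_samples: set[str]
    sample_load_shift: dict[str, float]


@dataclass
class CountSimSpec:
    """Parameters of the NGS count simulator (common-dispersion NB model)."""

    n_genes: int = 350
    n_de: int = 100
    de_fold_change: float = 2.0
    dispersion: float = 0.2
    library_sizes: Sequence[float] = ()
    abundance_log_mean: float = 4.0
    abundance_log_sd: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_de > self.n_genes:
            raise ValueError("n_de cannot exceed n_genes")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.de_fold_change <= 0:
            raise ValueError("de_fold_change must be > 0")
        if len(self.library_sizes) and any(n <= 0 for n in self.library_sizes):
            raise ValueError("library sizes must be > 0")


@dataclass
class CountGroundTruth:
    """True DE gene set and fold change of a simulated count matrix."""

    de_genes: set[str]
    fold_change: float


def _cohort_rng(seed: int, cohort_id: str) -> np.random.Generator:
    # one independent stream per cohort derived from (seed, cohort id)
    return np.random.default_rng([int(seed), zlib.crc32(str(cohort_id).encode())])


def simulate_qpcr_cohort(
    spec: SimulationSpec, cohort_id: str, seed: int | None = None
) -> tuple[CtMatrix, SampleSheet, GroundTruth]:
    """Simulate one cohort's Ct matrix, sample sheet and ground truth.

    Deterministic given ``(spec, cohort_id, seed)``; ``seed`` defaults to
    ``spec.seed``.  Case samples have their target Ct lowered by log2(FC)
    (more template = earlier amplification) relative to controls.
    """
    cohort_id = str(cohort_id)
    rng = _cohort_rng(spec.seed if seed is None else seed, cohort_id)

    targets = list(spec.assay_effects)
    references = list(spec.reference_assays)
    overlap = set(targets) & set(references)
    if overlap:
        raise ValueError(f"assays cannot be both target and reference: {sorted(overlap)}")
    if spec.hemolysis_fraction > 0:
        panel = set(targets) | set(references)
        for required in (HEMOLYSIS_ASSAY, HEMOLYSIS_STABLE_ASSAY):
            if required not in panel:
                raise ValueError(
                    f"hemolysis_fraction > 0 requires assay {required!r} on the panel"
                )

    cases = [f"{cohort_id}-case-{k + 1:02d}" for k in range(spec.n_case)]
    controls = [f"{cohort_id}-ctrl-{k + 1:02d}" for k in range(spec.n_control)]
    samples = cases + controls
    is_case = np.array([1.0] * spec.n_case + [0.0] * spec.n_control)

    shifted_assays = targets + references
    low, high = spec.base_ct_range
    base = rng.uniform(low, high, size=len(shifted_assays))
    for i, assay in enumerate(shifted_assays):
        if assay in spec.fixed_base_ct:
            base[i] = spec.fixed_base_ct[assay]
    shift = rng.normal(0.0, spec.load_shift_sd, size=len(samples))

    rows = {}
    truth_fc: dict[tuple[str, str], float] = {}
    for i, assay in enumerate(targets):
        fc = float(spec.assay_effects[assay].get(cohort_id, 1.0))
        truth_fc[(assay, cohort_id)] = fc
        eps = rng.normal(0.0, spec.target_noise_sd, size=len(samples))
        rows[assay] = base[i] + shift - np.log2(fc) * is_case + eps
    for k, assay in enumerate(references):
        truth_fc[(assay, cohort_id)] = 1.0
        eps = rng.normal(0.0, spec.reference_noise_sd, size=len(samples))
        rows[assay] = base[len(targets) + k] + shift + eps
    for assay in SPIKEIN_ASSAYS:
        rows[assay] = spec.spikein_ct + rng.normal(0.0, spec.spikein_sd, size=len(samples))

    n_hem = int(round(spec.hemolysis_fraction * len(samples)))
    hemolysed: set[str] = set()
    if n_hem > 0:
        picked = rng.choice(len(samples), size=n_hem, replace=False)
        hemolysed = {samples[int(k)] for k in picked}
        mask = np.array([s in hemolysed for s in samples])
        rows[HEMOLYSIS_ASSAY] = rows[HEMOLYSIS_ASSAY] - spec.hemolysis_ct_drop * mask

    ct = pd.DataFrame(rows, index=samples).T
    roles = pd.Series("target", index=ct.index)
    roles.loc[references] = "reference-candidate"
    roles.loc[list(SPIKEIN_ASSAYS)] = "spike-in"

    sheet = SampleSheet.from_records(
        [(s, CASE, cohort_id) for s in cases] + [(s, CONTROL, cohort_id) for s in controls]
    )
    truth = GroundTruth(
        true_fold_change=truth_fc,
        hemolysed_samples=hemolysed,
        sample_load_shift={s: float(shift[j]) for j, s in enumerate(samples)},
    )
    return CtMatrix(ct, roles), sheet, truth


def simulate_study(
    spec: SimulationSpec, seed: int | None = None
) -> tuple[dict[str, CtMatrix], SampleSheet, dict[str, GroundTruth]]:
    """Simulate every cohort in the spec; cohorts are independent replicates."""
    matrices: dict[str, CtMatrix] = {}
    truths: dict[str, GroundTruth] = {}
    sheets = []
    for cohort in spec.cohorts:
        ct, sheet, truth = simulate_qpcr_cohort(spec, cohort, seed)
        matrices[str(cohort)] = ct
        truths[str(cohort)] = truth
        sheets.append(sheet.table)
    return matrices, SampleSheet(pd.concat(sheets)), truths


def simulate_counts(
    spec: CountSimSpec, groups: Sequence[str], seed: int | None = None
) -> tuple[CountMatrix, CountGroundTruth]:
    """Simulate an NGS count matrix with ``n_de`` genes at the given fold change.

    Gene relative abundances are log-normal; expected counts scale with
    per-sample library size; DE genes are multiplied by ``de_fold_change`` in
    case samples.  Counts are NB with common dispersion (Poisson at phi = 0).
    """
    groups = list(groups)
    bad = set(groups) - {CASE, CONTROL}
    if bad:
        raise ValueError(f"unknown group labels {sorted(bad)}")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n_samples = len(groups)
    lib = np.asarray(
        spec.library_sizes if len(spec.library_sizes) else [1e5] * n_samples, dtype=float
    )
    if lib.shape[0] != n_samples:
        raise ValueError("library_sizes length must match number of samples")

    genes = [f"gene-{i + 1:04d}" for i in range(spec.n_genes)]
    lam = rng.lognormal(spec.abundance_log_mean, spec.abundance_log_sd, size=spec.n_genes)
    rel = lam / lam.sum()
    de_idx = rng.choice(spec.n_genes, size=spec.n_de, replace=False) if spec.n_de else np.array([], dtype=int)
    fc_per_gene = np.ones(spec.n_genes)
    fc_per_gene[de_idx] = spec.de_fold_change

    is_case = np.array([g == CASE for g in groups])
    mean = rel[:, None] * lib[None, :]
    mean = mean * np.where(is_case[None, :], fc_per_gene[:, None], 1.0)

    if spec.dispersion == 0:
        counts = rng.poisson(mean)
    else:
        r = 1.0 / spec.dispersion
        p = r / (r + mean)
        counts = rng.negative_binomial(r, p)

    cols = [f"{'case' if is_case[j] else 'ctrl'}-{j + 1:02d}" for j in range(n_samples)]
    cm = CountMatrix(pd.DataFrame(counts, index=genes, columns=cols))
    truth = CountGroundTruth(
        de_genes={genes[int(i)] for i in de_idx}, fold_change=spec.de_fold_change
    )
    return cm, truth
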