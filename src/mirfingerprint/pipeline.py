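"""End-to-end orchestration: screen -> qc -> references -> quantify -> test -> fingerprint."""

from __future__ import annotations

import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import io as mio
from .containers import CtMatrix, CountMatrix, SampleSheet
from .fingerprint import FingerprintReport, render_report, replicate_intersection
from .qc import hemolysis_stat, negative_control_check, qc_report, spikein_qc
from .quant import RelQuantTable, quantify, summarize_groups
from .references import normfinder_stability, select_reference_genes
from .screen import run_screen
from .stats import test_all

log = logging.getLogger("mirfingerprint")

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]


@dataclass
class RunConfig:
    """Every tunable of the pipeline, with its default.

    Unknown keys in a config file are rejected; the effective (fully
    resolved) configuration is echoed into every output table's header.
    """

    seed: int = 0
    # stage-1 NGS screen
    tpm_threshold: float = 1.0
    abundance_rule: str = "mean"
    screen_alpha: float = 0.05
    trim_m: float = 0.30
    trim_a: float = 0.05
    # qPCR QC
    hemolysis_threshold: float = 7.0
    spike_max_dev: float = 1.5
    ntc_min_separation: float = 5.0
    exclude_flagged: bool = False
    # reference selection
    v_threshold: float = 0.05
    start_n: int = 3
    # relative quantification + testing
    calibrator: str = "control-mean"
    fc_basis: str = "mean-ratio"
    mwu_mode: str = "auto"
    alpha: float = 0.05

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, object]) -> "RunConfig":
        valid = set(cls.__dataclass_fields__)
        unknown = set(mapping) - valid
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**mapping)  # type: ignore[arg-type]

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        if not isinstance(doc, dict):
            raise ValueError(f"{path}: config must be a flat key-value mapping")
        return cls.from_mapping(doc)

    def to_dict(self) -> dict[str, object]:
        return asdict(self)


@dataclass
class PipelineResult:
    """All intermediate and final tables of one pipeline run."""

    qc: dict[str, pd.DataFrame] = field(default_factory=dict)
    stability: dict[str, pd.DataFrame] = field(default_factory=dict)
    selected_references: dict[str, list[str]] = field(default_factory=dict)
    quant: dict[str, RelQuantTable] = field(default_factory=dict)
    summaries: dict[str, pd.DataFrame] = field(default_factory=dict)
    diff: dict[str, pd.DataFrame] = field(default_factory=dict)
    screen: pd.DataFrame | None = None
    candidates: list[str] | None = None
    report: FingerprintReport | None = None
    rendered: pd.DataFrame | None = None


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
            log.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
            return out
        return inner
    return wrap


def run_pipeline(
    ct_by_cohort: Mapping[str, CtMatrix],
    sheet: SampleSheet,
    config: RunConfig | None = None,
    counts: CountMatrix | None = None,
    count_groups: Sequence[str] | None = None,
    whitelist: Sequence[str] = (),
    ntc_samples: Sequence[str] = (),
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Run every stage on the given cohorts; persist tables if ``out_dir`` set.

    The NGS screen runs only when ``counts`` is provided (with group labels
    per count column).  Each cohort is processed independently: QC,
    reference selection, ddCt quantification and Mann-Whitney testing; the
    replication gate then intersects the per-cohort results.
    """
    config = config or RunConfig()
    result = PipelineResult()
    meta = config.to_dict()
    out = Path(out_dir) if out_dir is not None else None

    if counts is not None:
        if count_groups is None:
            count_groups = list(sheet.groups_for(counts.samples))
        result.screen, result.candidates = _stage("screen")(run_screen)(
            counts, count_groups,
            tpm_threshold=config.tpm_threshold, abundance_rule=config.abundance_rule,
            alpha=config.screen_alpha, whitelist=whitelist,
            trim_m=config.trim_m, trim_a=config.trim_a,
        )
        log.info("screen: %d candidates", len(result.candidates))
        if out is not None:
            mio.write_table(result.screen, out / "screen.tsv", meta, index=False)

    for cohort, ct in ct_by_cohort.items():
        cohort = str(cohort)
        samples = [s for s in ct.samples if s in set(sheet.cohort_samples(cohort))]
        groups = sheet.groups_for(samples)

        hemo = _stage("qc")(hemolysis_stat)(ct, threshold=config.hemolysis_threshold)
        spike = spikein_qc(ct, max_dev=config.spike_max_dev) if ct.spikeins else None
        qc_tab = qc_report(hemo, spike)
        if ntc_samples:
            ntc = negative_control_check(ct, ntc_samples, config.ntc_min_separation)
            qc_tab["ntc_any_fail"] = bool((~ntc).any())
        result.qc[cohort] = qc_tab
        flagged = list(qc_tab.index[qc_tab["hemolysis_flag"] | qc_tab["spikein_flag"]])
        if flagged:
            log.info("cohort %s: QC-flagged samples %s", cohort, flagged)

        cand = ct.subset(ct.reference_candidates)
        stability = _stage("references")(normfinder_stability)(
            cand.ct.loc[:, samples], list(groups)
        )
        refs = select_reference_genes(
            stability, cand.ct.loc[:, samples],
            v_threshold=config.v_threshold, start_n=config.start_n,
        )
        result.stability[cohort] = stability.table
        result.selected_references[cohort] = refs
        log.info("cohort %s: selected references %s", cohort, refs)

        exclude = flagged if config.exclude_flagged else []
        rq = _stage("quantify")(quantify)(
            ct, refs, sheet.table["group"], calibrator=config.calibrator,
            exclude_samples=exclude,
        )
        result.quant[cohort] = rq
        result.summaries[cohort] = summarize_groups(rq, config.fc_basis).table
        result.diff[cohort] = _stage("test")(test_all)(
            rq, alpha=config.alpha, fc_basis=config.fc_basis, mode=config.mwu_mode
        )

        if out is not None:
            mio.write_table(result.qc[cohort], out / f"qc_cohort{cohort}.tsv", meta)
            mio.write_table(result.stability[cohort], out / f"stability_cohort{cohort}.tsv", meta)
            mio.write_table(rq.table, out / f"quant_cohort{cohort}.tsv", meta, index=False)
            mio.write_table(result.diff[cohort], out / f"diff_cohort{cohort}.tsv", meta)

    if len(result.diff) >= 2:
        result.report = _stage("fingerprint")(replicate_intersection)(
            result.diff, alpha=config.alpha
        )
        result.rendered = render_report(result.report, result.diff)
        log.info("fingerprint members: %s", result.report.member_targets)
        if out is not None:
            mio.write_table(result.rendered, out / "fingerprint.tsv", meta, index=False)
            mio.write_table(result.report.excluded, out / "excluded.tsv", meta, index=False)
    return result
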