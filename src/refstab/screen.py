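"""Microarray fold-change screening cascade for candidate reference genes.

A discovery study (control, day 1 and day 5 after nerve transection)
nominates probes whose expression barely moves: fold changes fc_1/0,
fc_5/0 and fc_5/1 must all sit inside a tight window around 1 (default
[0.99, 1.01], boundaries inclusive), every condition-group mean must
clear a minimum fluorescence (default 100, so the gene is genuinely
expressed), and a gene must be supported by at least two surviving
probes.  Candidates are then confirmed against an independent study
(fc_7/0): for every gated contrast, the mean and sample SD of the fold
change across *all* of the gene's probes — including probes that failed
the earlier per-probe stages — must satisfy mean ∈ [0.98, 1.02] and
SD ≤ 0.05, and genes with known pseudogenes are removed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError
from .io import ExpressionMatrix, GeneAnnotation

logger = logging.getLogger(__name__)

#: The three within-discovery contrasts gated probe-by-probe, in gate order.
DISCOVERY_CONTRASTS = ("fc_1/0", "fc_5/0", "fc_5/1")


def contrast_label(numerator: float, denominator: float) -> str:
    def fmt(t: float) -> str:
        return str(int(t)) if float(t).is_integer() else str(t)
    return f"fc_{fmt(numerator)}/{fmt(denominator)}"


@dataclass
class ScreenConfig:
    """Thresholds of the cascade; defaults follow the published screen."""

    probe_fc_window: tuple[float, float] = (0.99, 1.01)
    min_signal: float = 100.0
    min_probes_per_gene: int = 2
    gene_fc_window: tuple[float, float] = (0.98, 1.02)
    max_gene_sd: float = 0.05
    exclude_pseudogenes: bool = True
    #: gate the descriptive extra study's contrasts with the same
    #: mean/SD rule instead of only reporting them
    gate_extra_study: bool = False
    #: with exclude_pseudogenes, also exclude genes absent from the
    #: gene annotation (pseudogene status unknown)
    strict_annotation: bool = False

    def __post_init__(self) -> None:
        for lo, hi in (self.probe_fc_window, self.gene_fc_window):
            if not lo < hi:
                raise InputError(f"fc window lower bound must be < upper: ({lo}, {hi})")
        if self.min_signal < 0:
            raise InputError("min_signal must be >= 0")
        if self.min_probes_per_gene < 1:
            raise InputError("min_probes_per_gene must be >= 1")


@dataclass
class FoldChangeTable:
    """Per-probe condition-group means and fold changes for one study.

    ``fc`` holds one column per contrast (label ``fc_<a>/<b>``); an
    undefined ratio (zero denominator mean) is NaN and flagged in
    ``undefined``.
    """

    group_means: pd.DataFrame      # probes × time points
    fc: pd.DataFrame               # probes × contrast labels
    undefined: pd.DataFrame        # probes × contrast labels, bool
    probe2gene: pd.Series

    @property
    def probe_ids(self) -> list[str]:
        return list(self.fc.index)


@dataclass
class StageResult:
    name: str
    n_probes: int
    n_genes: int
    n_discarded: int
    probe_ids: tuple[str, ...]


@dataclass
class CascadeReport:
    """Stage-by-stage survivors plus, after confirmation, the final candidates."""

    stages: list[StageResult]
    probe2gene: pd.Series
    candidates: pd.DataFrame | None = None          # per-gene means/SDs and gate flags
    missing_from_confirmation: list[str] = field(default_factory=list)
    unannotated_genes: list[str] = field(default_factory=list)

    @property
    def counts(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s.name, s.n_probes, s.n_genes, s.n_discarded) for s in self.stages],
            columns=["stage", "n_probes", "n_genes", "n_discarded"],
        )

    def surviving_probes(self) -> tuple[str, ...]:
        return self.stages[-1].probe_ids

    def surviving_genes(self) -> list[str]:
        genes = self.probe2gene.loc[list(self.stages[-1].probe_ids)]
        return sorted(set(genes))

    def candidate_genes(self) -> list[str]:
        if self.candidates is None:
            raise InputError("confirmation has not been run on this report")
        return sorted(self.candidates.index[self.candidates["kept"]])


# ---------------------------------------------------------------------------
# Fold changes
# ---------------------------------------------------------------------------

def compute_fold_changes(
    matrix: ExpressionMatrix,
    contrasts: list[tuple[float, float]],
) -> FoldChangeTable:
    """Average replicates per time point, then form fold-change ratios.

    Each contrast ``(a, b)`` produces ``fc_a/b`` = (mean fluorescence at
    day a) / (mean at day b) per probe.  A zero denominator mean leaves
    that fc undefined (NaN) and flags the probe/contrast pair.
    """
    if matrix.condition_meta is None:
        raise InputError("expression matrix lacks condition metadata (time points)")
    tps = matrix.condition_meta["time_point"]
    groups: dict[float, list[str]] = {}
    for cid in matrix.condition_ids:
        groups.setdefault(float(tps[cid]), []).append(cid)
    for num, den in contrasts:
        for t in (num, den):
            if float(t) not in groups:
                raise InputError(f"contrast references absent time point: {t}")
    gm = pd.DataFrame(
        {tp: matrix.fluorescence[cols].mean(axis=1) for tp, cols in sorted(groups.items())}
    )
    fc_cols, und_cols = {}, {}
    for num, den in contrasts:
        label = contrast_label(num, den)
        denom = gm[float(den)]
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = gm[float(num)] / denom
        undefined = denom == 0
        ratio = ratio.where(~undefined)
        fc_cols[label] = ratio
        und_cols[label] = undefined
    return FoldChangeTable(
        group_means=gm,
        fc=pd.DataFrame(fc_cols),
        undefined=pd.DataFrame(und_cols),
        probe2gene=matrix.probe2gene,
    )


# ---------------------------------------------------------------------------
# Probe-level cascade
# ---------------------------------------------------------------------------

def _stage(name: str, probes: pd.Index, prev_n: int, probe2gene: pd.Series) -> StageResult:
    genes = set(probe2gene.loc[list(probes)]) if len(probes) else set()
    return StageResult(
        name=name,
        n_probes=len(probes),
        n_genes=len(genes),
        n_discarded=prev_n - len(probes),
        probe_ids=tuple(probes),
    )


def filter_probes(
    fold_changes: FoldChangeTable,
    config: ScreenConfig | None = None,
    discovery_contrasts: tuple[str, str, str] = DISCOVERY_CONTRASTS,
) -> CascadeReport:
    """Run the probe-level stages of the cascade on the discovery study.

    Stages, in order: the three fold-change windows (boundaries
    inclusive; an undefined fc fails), the minimum-signal rule (every
    condition-group mean must be >= ``min_signal``), and the
    multiple-probe rule (keep genes with >= ``min_probes_per_gene``
    surviving probes).
    """
    config = config or ScreenConfig()
    if len(fold_changes.fc.index) == 0:
        raise InputError("empty fold-change table")
    missing = [c for c in discovery_contrasts if c not in fold_changes.fc.columns]
    if missing:
        raise InputError(f"fold-change table lacks discovery contrast(s): {missing}")
    p2g = fold_changes.probe2gene
    lo, hi = config.probe_fc_window
    probes = fold_changes.fc.index
    stages = [_stage("input", probes, len(probes), p2g)]
    for label in discovery_contrasts:
        vals = fold_changes.fc.loc[probes, label]
        probes = probes[((vals >= lo) & (vals <= hi)).fillna(False).to_numpy()]
        stages.append(_stage(f"{label} in [{lo}, {hi}]", probes, stages[-1].n_probes, p2g))
    means = fold_changes.group_means.loc[probes]
    probes = probes[(means >= config.min_signal).all(axis=1).to_numpy()]
    stages.append(_stage(f"all group means >= {config.min_signal}", probes,
                         stages[-1].n_probes, p2g))
    counts = p2g.loc[list(probes)].value_counts()
    good_genes = set(counts.index[counts >= config.min_probes_per_gene])
    probes = probes[[p2g[p] in good_genes for p in probes]]
    stages.append(_stage(f">= {config.min_probes_per_gene} probes per gene", probes,
                         stages[-1].n_probes, p2g))
    return CascadeReport(stages=stages, probe2gene=p2g)


# ---------------------------------------------------------------------------
# Gene-level confirmation
# ---------------------------------------------------------------------------

def _gene_mean_sd(fct: FoldChangeTable, gene: str, label: str) -> tuple[float, float]:
    probes = fct.probe2gene.index[fct.probe2gene == gene]
    vals = fct.fc.loc[probes.intersection(fct.fc.index), label].to_numpy(dtype=float)
    if vals.size == 0:
        return np.nan, np.nan
    mean = float(vals.mean())
    sd = 0.0 if vals.size == 1 else float(vals.std(ddof=1))
    return mean, sd


def aggregate_and_confirm(
    discovery_report: CascadeReport,
    discovery_fc: FoldChangeTable,
    confirmation_fc: FoldChangeTable,
    annotation: GeneAnnotation | None = None,
    config: ScreenConfig | None = None,
    extra_fc: FoldChangeTable | None = None,
    discovery_contrasts: tuple[str, str, str] = DISCOVERY_CONTRASTS,
) -> CascadeReport:
    """Gene-level mean/SD confirmation of the cascade survivors.

    For every surviving gene and every gated contrast, the fold change is
    averaged over *all* of that gene's probes in the relevant study (the
    sample SD of a single probe is 0).  A gene is kept iff every gated
    mean lies in ``gene_fc_window``, every gated SD is <= ``max_gene_sd``
    and, when pseudogene exclusion is on, the annotation marks it
    pseudogene-free.  Genes absent from the confirmation study are
    reported separately, never silently passed.  An optional extra study
    is tabulated descriptively (gated only with ``gate_extra_study``).
    """
    config = config or ScreenConfig()
    annotation = annotation or GeneAnnotation()
    genes = discovery_report.surviving_genes()
    gated: list[tuple[FoldChangeTable, str]] = [
        (discovery_fc, c) for c in discovery_contrasts
    ]
    conf_labels = list(confirmation_fc.fc.columns)
    gated += [(confirmation_fc, c) for c in conf_labels]
    descriptive: list[tuple[FoldChangeTable, str]] = []
    if extra_fc is not None:
        pairs = [(extra_fc, c) for c in extra_fc.fc.columns]
        (gated if config.gate_extra_study else descriptive).extend(pairs)

    conf_genes = set(confirmation_fc.probe2gene)
    missing_conf = [g for g in genes if g not in conf_genes]
    unannotated: list[str] = []
    rows: dict[str, dict[str, float | bool]] = {}
    for gene in genes:
        row: dict[str, float | bool] = {}
        ok = True
        for fct, label in gated:
            mean, sd = _gene_mean_sd(fct, gene, label)
            row[f"mean_{label}"] = mean
            row[f"sd_{label}"] = sd
            lo, hi = config.gene_fc_window
            if not (np.isfinite(mean) and lo <= mean <= hi and sd <= config.max_gene_sd):
                ok = False
        for fct, label in descriptive:
            mean, sd = _gene_mean_sd(fct, gene, label)
            row[f"mean_{label}"] = mean
            row[f"sd_{label}"] = sd
        if gene in missing_conf:
            ok = False
        pseudo = annotation.has_pseudogene(gene)
        if pseudo is None and gene not in annotation:
            unannotated.append(gene)
            if config.exclude_pseudogenes and config.strict_annotation:
                ok = False
        elif config.exclude_pseudogenes and pseudo:
            ok = False
        row["has_pseudogene"] = bool(pseudo) if pseudo is not None else False
        row["kept"] = ok
        rows[gene] = row
    if unannotated:
        logger.warning("genes absent from annotation (pseudogene status unknown): %s",
                       unannotated)
    candidates = pd.DataFrame.from_dict(rows, orient="index")
    kept = candidates.index[candidates["kept"]] if len(candidates) else pd.Index([])
    kept_probes = tuple(
        p for p in discovery_report.surviving_probes()
        if discovery_report.probe2gene[p] in set(kept)
    )
    stages = discovery_report.stages + [
        _stage("gene mean/SD + pseudogene confirmation", pd.Index(kept_probes),
               discovery_report.stages[-1].n_probes, discovery_report.probe2gene)
    ]
    return CascadeReport(
        stages=stages,
        probe2gene=discovery_report.probe2gene,
        candidates=candidates,
        missing_from_confirmation=missing_conf,
        unannotated_genes=unannotated,
    )


def run_screen(
    discovery: ExpressionMatrix,
    confirmation: ExpressionMatrix,
    annotation: GeneAnnotation | None = None,
    config: ScreenConfig | None = None,
    extra: ExpressionMatrix | None = None,
    discovery_contrast_days: tuple[tuple[float, float], ...] = ((1, 0), (5, 0), (5, 1)),
    confirmation_contrast_days: tuple[tuple[float, float], ...] = ((7, 0),),
) -> CascadeReport:
    """Convenience wrapper: fold changes → probe cascade → confirmation."""
    config = config or ScreenConfig()
    disc_fc = compute_fold_changes(discovery, list(discovery_contrast_days))
    conf_fc = compute_fold_changes(confirmation, list(confirmation_contrast_days))
    extra_fc = None
    if extra is not None:
        extra_tps = sorted(set(extra.condition_meta["time_point"]))
        base = min(extra_tps)
        extra_fc = compute_fold_changes(extra, [(t, base) for t in extra_tps if t != base])
    labels = tuple(contrast_label(a, b) for a, b in discovery_contrast_days)
    report = filter_probes(disc_fc, config, labels)
    return aggregate_and_confirm(report, disc_fc, conf_fc, annotation, config,
                                 extra_fc, labels)
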