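"""Synthetic qPCR CT tables and microarray matrices with planted truth.

The generator emulates the structure of an injury time-course experiment:
samples at days 0 (uninjured control), 1, 7 and 28 after nerve lesion, in
biological triplicate.  *Stable* genes keep a constant expected CT;
*regulated* genes get a per-time-point log2 effect subtracted from their
baseline CT (one PCR cycle = one log2 expression unit, lower CT = higher
expression).  CT noise is additive Gaussian on the cycle (log) scale;
microarray fluorescence noise is multiplicative log-normal, matching each
platform's conventional error structure.

Every draw is governed by the design's seed: the same design yields
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InputError
from .io import CtTable, ExpressionMatrix, GeneAnnotation

#: Decaying base pattern rotated/flipped to build distinct regulation shapes.
_BASE_PATTERN = (1.0, 0.5, 0.25)


@dataclass
class SimulationDesign:
    """Knobs of the simulated experiment; defaults mirror the validation design.

    ``noise_sd`` (CT cycles == log2 units) may be a scalar or one value
    per gene (stable genes first, then regulated).  ``regulation_profiles``
    maps each regulated gene index to {time_point: log2 effect}; if None,
    distinct deterministic profiles are built from a rotated/sign-flipped
    decaying pattern with amplitudes 1.5, 1.75, 2.0, ...
    """

    time_points: tuple[float, ...] = (0, 1, 7, 28)
    replicates: int = 3
    n_stable_genes: int = 2
    n_regulated_genes: int = 4
    regulation_profiles: Mapping[int, Mapping[float, float]] | None = None
    ct_baseline_range: tuple[float, float] = (10.0, 32.0)
    noise_sd: float | Sequence[float] = 0.15
    probes_per_gene: int = 2
    signal_baseline_range: tuple[float, float] = (1000.0, 8000.0)
    low_signal_fraction: float = 0.0
    single_probe_fraction: float = 0.0
    fluor_noise_sd: float = 0.002       # log2 units, multiplicative
    probe_affinity_sd: float = 0.5      # log2 spread of probe brightness
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_stable_genes < 0 or self.n_regulated_genes < 0:
            raise InputError("gene counts must be >= 0")
        if self.n_stable_genes + self.n_regulated_genes < 2:
            raise InputError("need at least 2 genes in total")
        if self.replicates < 1:
            raise InputError("need at least 1 replicate per time point")
        sds = np.atleast_1d(np.asarray(self.noise_sd, dtype=float))
        if (sds < 0).any():
            raise InputError("noise SD must be >= 0")
        if sds.size not in (1, self.n_genes):
            raise InputError("noise_sd must be scalar or one value per gene")
        if self.probes_per_gene < 1:
            raise InputError("probes_per_gene must be >= 1")

    @property
    def n_genes(self) -> int:
        return self.n_stable_genes + self.n_regulated_genes

    @property
    def gene_ids(self) -> list[str]:
        return [f"STAB{i + 1}" for i in range(self.n_stable_genes)] + [
            f"REG{i + 1}" for i in range(self.n_regulated_genes)
        ]

    def per_gene_noise_sd(self) -> np.ndarray:
        sds = np.atleast_1d(np.asarray(self.noise_sd, dtype=float))
        return np.full(self.n_genes, sds[0]) if sds.size == 1 else sds

    def resolved_profiles(self) -> dict[str, dict[float, float]]:
        """Log2 effect per time point for every regulated gene.

        The control time point (the smallest) always has effect 0.
        Auto-generated profiles rotate a decaying pattern, alternate sign
        and step the amplitude, so no two genes share a profile.
        """
        control = min(self.time_points)
        nonzero = [t for t in self.time_points if t != control]
        out: dict[str, dict[float, float]] = {}
        for j in range(self.n_regulated_genes):
            name = f"REG{j + 1}"
            if self.regulation_profiles is not None and j in self.regulation_profiles:
                prof = {float(t): float(e) for t, e in self.regulation_profiles[j].items()}
            else:
                amp = (1.5 + 0.25 * j) * (1 if j % 2 == 0 else -1)
                prof = {
                    t: amp * _BASE_PATTERN[(i + j) % len(_BASE_PATTERN)]
                    for i, t in enumerate(nonzero)
                }
            prof.setdefault(control, 0.0)
            out[name] = prof
        return out


def _sample_frame(design: SimulationDesign) -> pd.DataFrame:
    rows = []
    for tp in design.time_points:
        for rep in range(1, design.replicates + 1):
            model = "control" if tp == min(design.time_points) else "crush"
            rows.append((f"d{tp:g}_r{rep}", float(tp), model, rep))
    return pd.DataFrame(rows, columns=["sample_id", "time_point", "model",
                                       "replicate"]).set_index("sample_id")


def simulate_ct_table(design: SimulationDesign) -> tuple[CtTable, pd.Series]:
    """Simulate a CT table; returns the table and per-gene truth labels.

    Stable genes: ``CT = baseline + noise``.  Regulated genes:
    ``CT = baseline - effect(time point) + noise`` (a positive effect is
    up-regulation, hence a lower CT).
    """
    meta = _sample_frame(design)
    rng = np.random.default_rng(design.seed)
    lo, hi = design.ct_baseline_range
    baselines = rng.uniform(lo, hi, size=design.n_genes)
    profiles = design.resolved_profiles()
    sds = design.per_gene_noise_sd()
    tp_per_sample = meta["time_point"].to_numpy()
    ct = np.empty((design.n_genes, len(meta)))
    for g, gene in enumerate(design.gene_ids):
        effect = np.array([profiles.get(gene, {}).get(t, 0.0) for t in tp_per_sample])
        ct[g] = baselines[g] - effect + rng.normal(0.0, sds[g], size=len(meta))
    table = CtTable(pd.DataFrame(ct, index=design.gene_ids, columns=meta.index), meta)
    truth = pd.Series(
        ["stable"] * design.n_stable_genes + ["regulated"] * design.n_regulated_genes,
        index=design.gene_ids, name="status",
    )
    return table, truth


def simulate_expression_matrix(
    design: SimulationDesign,
    probe_effects: Mapping[tuple[str, int], Mapping[float, float]] | None = None,
) -> tuple[ExpressionMatrix, pd.Series]:
    """Simulate a probes × conditions fluorescence matrix with planted truth.

    Per probe: ``fluorescence = gene condition mean × probe affinity ×
    2**N(0, fluor_noise_sd)``.  A leading fraction of the stable genes is
    planted below the usual signal threshold (baseline drawn in [20, 80])
    and a further fraction gets exactly one probe, so the signal and
    multiple-probe stages of the screen both see planted negatives.
    ``probe_effects`` adds probe-specific log2 shifts at given time
    points, for planting probe-discordant genes.
    """
    meta = _sample_frame(design)
    rng = np.random.default_rng(design.seed)
    lo, hi = design.signal_baseline_range
    baselines = rng.uniform(lo, hi, size=design.n_genes)
    n_low = int(round(design.low_signal_fraction * design.n_stable_genes))
    baselines[:n_low] = rng.uniform(10.0, 30.0, size=n_low)
    n_single = int(round(design.single_probe_fraction * design.n_stable_genes))
    profiles = design.resolved_profiles()
    tp_per_sample = meta["time_point"].to_numpy()
    truth_labels = []
    probe_rows, probe_ids, probe_genes = [], [], []
    for g, gene in enumerate(design.gene_ids):
        if gene.startswith("STAB"):
            if g < n_low:
                truth_labels.append("low_signal")
            elif g < n_low + n_single:
                truth_labels.append("single_probe")
            else:
                truth_labels.append("stable")
        else:
            truth_labels.append("regulated")
        n_probes = 1 if truth_labels[-1] == "single_probe" else design.probes_per_gene
        effect = np.array([profiles.get(gene, {}).get(t, 0.0) for t in tp_per_sample])
        gene_mean_log2 = np.log2(baselines[g]) + effect
        for p in range(n_probes):
            # affinity clamped to +-3 sigma so planted signal levels cannot
            # cross the detection threshold by an extreme draw
            affinity = float(np.clip(rng.normal(0.0, design.probe_affinity_sd),
                                     -3 * design.probe_affinity_sd,
                                     3 * design.probe_affinity_sd))
            shift = np.zeros(len(meta))
            if probe_effects and (gene, p) in probe_effects:
                pe = {float(t): float(v) for t, v in probe_effects[(gene, p)].items()}
                shift = np.array([pe.get(t, 0.0) for t in tp_per_sample])
            noise = rng.normal(0.0, design.fluor_noise_sd, size=len(meta))
            probe_rows.append(2.0 ** (gene_mean_log2 + affinity + shift + noise))
            probe_ids.append(f"{gene}_p{p + 1}")
            probe_genes.append(gene)
    matrix = ExpressionMatrix(
        pd.DataFrame(probe_rows, index=probe_ids, columns=meta.index),
        pd.Series(probe_genes, index=probe_ids, name="gene_symbol"),
        meta,
    )
    truth = pd.Series(truth_labels, index=design.gene_ids, name="status")
    return matrix, truth


# ---------------------------------------------------------------------------
# Full screen bundle: one plant per cascade stage
# ---------------------------------------------------------------------------

@dataclass
class ScreenBundle:
    """Discovery + confirmation (+ extra) studies sharing one gene set.

    ``truth`` labels each gene with the cascade stage meant to remove it
    (or ``clean``); ``expected_candidates`` is the planted-clean set.
    """

    discovery: ExpressionMatrix
    confirmation: ExpressionMatrix
    extra: ExpressionMatrix
    annotation: GeneAnnotation
    truth: pd.Series
    expected_candidates: list[str]


def simulate_screen_bundle(
    seed: int = 0,
    n_clean: int = 3,
    n_regulated: int = 2,
    fluor_noise_sd: float = 0.002,
    probes_per_gene: int = 2,
) -> ScreenBundle:
    """Three coupled studies with a planted violation for every stage.

    Plants, besides ``n_clean`` clean stable genes and ``n_regulated``
    discovery-regulated genes: one low-signal gene, one single-probe
    gene, one gene whose probes disagree in the confirmation study
    (fc_7/0 of 2**±0.1, mean in window but SD ≈ 0.098 > 0.05), one gene
    uniformly shifted in the confirmation study (fc_7/0 ≈ 1.03, outside
    the mean window) and one clean gene carrying a pseudogene flag.
    """
    rng = np.random.default_rng(seed)
    sub = lambda: int(rng.integers(0, 2**31 - 1))  # noqa: E731

    n_special = 4  # discordant, shifted, pseudogene; +1 low-signal handled via fraction
    n_stable = n_clean + n_special + 1  # + single-probe
    base = SimulationDesign(
        n_stable_genes=n_stable,
        n_regulated_genes=n_regulated,
        probes_per_gene=probes_per_gene,
        fluor_noise_sd=fluor_noise_sd,
        low_signal_fraction=1.0 / n_stable,
        single_probe_fraction=1.0 / n_stable,
    )
    # stable gene layout: STAB1 low-signal, STAB2 single-probe, STAB3 discordant,
    # STAB4 shifted, STAB5 pseudogene, STAB6.. clean
    discord, shifted, pseudo = "STAB3", "STAB4", "STAB5"
    clean = [f"STAB{i}" for i in range(6, 6 + n_clean)]

    disc_design = replace(base, time_points=(0, 1, 5), seed=sub())
    discovery, truth = simulate_expression_matrix(disc_design)

    conf_effects = {
        (discord, 0): {7.0: +0.1},
        (discord, 1): {7.0: -0.1},
    }
    conf_design = replace(base, time_points=(0, 7), n_regulated_genes=n_regulated,
                          seed=sub())
    shift_profiles = {  # uniform +0.0428 log2 at day 7 => fc_7/0 ~ 1.030
        (shifted, p): {7.0: 0.0428} for p in range(probes_per_gene)
    }
    conf_effects.update(shift_profiles)
    confirmation, _ = simulate_expression_matrix(conf_design, conf_effects)

    extra_design = replace(base, time_points=(0, 3, 7, 14), seed=sub())
    extra, _ = simulate_expression_matrix(extra_design)

    ann = GeneAnnotation(pd.DataFrame(
        {
            "accession": [f"NM_{i:06d}" for i in range(base.n_genes)],
            "has_pseudogene": [g == pseudo for g in base.gene_ids],
            "intron_spanning": True,
        },
        index=pd.Index(base.gene_ids, name="symbol"),
    ))
    truth = truth.copy()
    truth[discord] = "confirm_discordant"
    truth[shifted] = "confirm_shifted"
    truth[pseudo] = "pseudogene"
    return ScreenBundle(
        discovery=discovery,
        confirmation=confirmation,
        extra=extra,
        annotation=ann,
        truth=truth,
        expected_candidates=sorted(clean),
    )
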