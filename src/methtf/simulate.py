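"""Synthetic data with planted, recoverable structure for every stage of
the pipeline.

The generator emulates the study design this package targets: a paired
two-condition methylation array experiment (three donors, each measured
before and after differentiation), a probe geography over CpG-island
relation categories with the characteristic bimodal beta distribution
(island probes mostly unmethylated, open-sea probes mostly methylated),
a 15-state chromatin segmentation, a TF binding-site catalog in which
decoy TFs cover CpGs at a uniform background rate while planted TFs
preferentially cover one CpG class, expression negatively coupled to
5'UTR methylation, and RNAPII-interaction regions enriched for
hypo-methylated CpGs.

Randomness: one seed; each output component draws from its own child
generator derived by a fixed spawn key, so adding a component never
perturbs the others.  Noise is added on the M (logit) scale and
back-transformed, keeping beta in range without truncation artifacts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .diff import beta_to_m, m_to_beta
from .context import ChromatinSegmentation
from .formats import (
    GenomicInterval,
    ProbeManifest,
    SampleSheet,
    ISLAND_CATEGORIES,
)

logger = logging.getLogger(__name__)

STATE_NAMES = (
    "ActivePromoter",
    "WeakPromoter",
    "PoisedPromoter",
    "StrongEnhancer",
    "StrongEnhancer2",
    "WeakEnhancer",
    "WeakEnhancer2",
    "Insulator",
    "TxnTransition",
    "TxnElongation",
    "WeakTxn",
    "PolycombRepressed",
    "Heterochromatin",
    "Repetitive",
    "Repetitive2",
)

#: island-relation category proportions, roughly those of a 450K-style array
CATEGORY_PROPS = {
    "Island": 0.31,
    "N_Shore": 0.12,
    "S_Shore": 0.11,
    "N_Shelf": 0.05,
    "S_Shelf": 0.05,
    "OpenSea": 0.36,
}

#: Beta-distribution parameters for baseline methylation per category:
#: islands largely unmethylated, open sea largely methylated, the
#: intermediate zones in between
CATEGORY_BETA_PARAMS = {
    "Island": (2.0, 10.0),
    "N_Shore": (3.0, 7.0),
    "S_Shore": (3.0, 7.0),
    "N_Shelf": (6.0, 4.0),
    "S_Shelf": (6.0, 4.0),
    "OpenSea": (10.0, 2.0),
}


@dataclass
class SimulationConfig:
    seed: int = 0
    n_chrom: int = 2
    chrom_length: int = 1_000_000
    n_probes: int = 10_000
    category_props: dict = field(default_factory=lambda: dict(CATEGORY_PROPS))
    n_states: int = 15
    mean_segment_length: int = 5_000
    n_samples_per_condition: int = 3
    paired: bool = True
    n_planted_diff: int = 200
    planted_hyper_fraction: float = 0.5
    delta_beta: float = 0.3
    beta_noise_sd: float = 0.03  # per-sample noise on the M (logit) scale
    donor_sd: float = 0.1  # donor effect on the M scale, shared within pairs
    tf_specs: list = field(
        default_factory=lambda: default_tf_specs()
    )  # (label, hypo_cov, hyper_cov, background_cov)
    peak_halfwidth: int = 20
    n_genes: int = 1_000
    gene_tag_fraction: float = 0.8
    utr5_fraction: float = 0.2
    expr_intercept: float = 10.0
    expr_slope: float = 1.5  # expression = intercept - slope * mean M + noise
    expr_noise_sd: float = 1.0
    rnapii_hypo_cov: float = 0.5
    rnapii_hyper_cov: float = 0.2
    rnapii_background_cov: float = 0.05
    rnapii_halfwidth: int = 1_000
    state_shifts: dict = field(default_factory=dict)  # state -> delta beta in treatment

    def validate(self) -> None:
        if self.n_planted_diff > self.n_probes:
            raise ValueError("n_planted_diff exceeds n_probes")
        if self.n_probes > self.n_chrom * self.chrom_length // 2:
            raise ValueError("too many probes for the genome size")
        probs = [p for spec in self.tf_specs for p in spec[1:]] + [
            self.rnapii_hypo_cov,
            self.rnapii_hyper_cov,
            self.rnapii_background_cov,
            self.planted_hyper_fraction,
            self.gene_tag_fraction,
            self.utr5_fraction,
        ]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("coverage probabilities must lie in [0, 1]")
        if abs(sum(self.category_props.values()) - 1.0) > 1e-9:
            raise ValueError("category proportions must sum to 1")
        if self.n_samples_per_condition < 2:
            raise ValueError("need >= 2 samples per condition")
        if self.n_states > len(STATE_NAMES):
            raise ValueError(f"at most {len(STATE_NAMES)} states supported")


def default_tf_specs(n_decoys: int = 20, background: float = 0.15):
    """One planted hyper-biased TF (covers hyper CpGs at 0.6 vs 0.15)
    among uniform-background decoys."""
    specs = [("TF_PLANTED_HYPER", background, 0.6, background)]
    for i in range(1, n_decoys + 1):
        specs.append((f"TF_DECOY_{i:02d}", background, background, background))
    return specs


@dataclass
class GroundTruth:
    planted_hypo: list
    planted_hyper: list
    tf_coverage: dict  # label -> (hypo_cov, hyper_cov, background_cov)
    expr_coupled_genes: list
    expr_intercept: float
    expr_slope: float
    rnapii_coverage: tuple
    state_shifts: dict

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)


@dataclass
class SimulatedData:
    config: SimulationConfig
    manifest: ProbeManifest
    segmentation: ChromatinSegmentation
    beta: pd.DataFrame
    sheet: SampleSheet
    tf_peaks: list  # (tf_label, cell_type, [GenomicInterval])
    expression: pd.DataFrame
    rnapii: list
    truth: GroundTruth


def _rng(seed: int, component: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(component,)))


def simulate_all(config: SimulationConfig) -> SimulatedData:
    """Generate every input the pipeline consumes, plus ground truth.

    Deterministic for a fixed config (including seed).
    """
    config.validate()
    seed = config.seed

    # --- probe geography -------------------------------------------------
    rng = _rng(seed, 0)
    chroms = [f"chr{i + 1}" for i in range(config.n_chrom)]
    per_chrom = np.full(config.n_chrom, config.n_probes // config.n_chrom)
    per_chrom[: config.n_probes % config.n_chrom] += 1
    chrom_col, pos_col = [], []
    for chrom, k in zip(chroms, per_chrom):
        pos = np.sort(rng.choice(config.chrom_length, size=int(k), replace=False))
        chrom_col.extend([chrom] * int(k))
        pos_col.extend(pos.tolist())
    probe_ids = [f"cg{i:06d}" for i in range(config.n_probes)]
    cat_names = list(config.category_props)
    categories = rng.choice(
        cat_names, size=config.n_probes, p=[config.category_props[c] for c in cat_names]
    )

    # --- baseline methylation and planted differences --------------------
    rng = _rng(seed, 1)
    beta0 = np.empty(config.n_probes)
    for cat in cat_names:
        a, b = CATEGORY_BETA_PARAMS[cat]
        mask = categories == cat
        beta0[mask] = rng.beta(a, b, size=int(mask.sum()))
    beta0 = np.clip(beta0, 0.01, 0.99)

    rng = _rng(seed, 2)
    planted = rng.choice(config.n_probes, size=config.n_planted_diff, replace=False)
    n_hyper = int(round(config.n_planted_diff * config.planted_hyper_fraction))
    planted_hyper = np.sort(planted[:n_hyper])
    planted_hypo = np.sort(planted[n_hyper:])
    beta_trt = beta0.copy()
    beta_trt[planted_hyper] = np.clip(beta_trt[planted_hyper] + config.delta_beta, 0.01, 0.99)
    beta_trt[planted_hypo] = np.clip(beta_trt[planted_hypo] - config.delta_beta, 0.01, 0.99)

    # --- chromatin segmentation ------------------------------------------
    rng = _rng(seed, 3)
    states = STATE_NAMES[: config.n_states]
    seg_intervals = []
    for chrom in chroms:
        n_seg = max(2, config.chrom_length // config.mean_segment_length)
        cuts = np.sort(rng.choice(config.chrom_length - 1, size=n_seg - 1, replace=False)) + 1
        bounds = np.concatenate([[0], cuts, [config.chrom_length]])
        labels = rng.choice(states, size=n_seg)
        for s, e, lab in zip(bounds[:-1], bounds[1:], labels):
            seg_intervals.append(GenomicInterval(chrom, int(s), int(e), str(lab)))
    segmentation = ChromatinSegmentation(seg_intervals)

    # optional per-state beta shifts in the treatment condition
    if config.state_shifts:
        probe_states = segmentation.states_at(list(zip(chrom_col, pos_col)))
        for state, shift in config.state_shifts.items():
            mask = np.array([s == state for s in probe_states])
            beta_trt[mask] = np.clip(beta_trt[mask] + shift, 0.01, 0.99)

    # --- per-sample beta values (paired design) ---------------------------
    rng = _rng(seed, 4)
    n_d = config.n_samples_per_condition
    donors = [f"d{j + 1}" for j in range(n_d)]
    m_ref0 = beta_to_m(beta0)
    m_trt0 = beta_to_m(beta_trt)
    donor_eff = rng.normal(0.0, config.donor_sd, size=(config.n_probes, n_d))
    cols, data = [], []
    for cond, m0 in (("reference", m_ref0), ("treatment", m_trt0)):
        for j, donor in enumerate(donors):
            noise = rng.normal(0.0, config.beta_noise_sd, size=config.n_probes)
            m_sample = m0 + donor_eff[:, j] + noise
            data.append(m_to_beta(m_sample))
            cols.append(("ref" if cond == "reference" else "trt") + f"_{donor}")
    beta_df = pd.DataFrame(np.column_stack(data), index=probe_ids, columns=cols)
    beta_df.index.name = "probe_id"
    sheet = SampleSheet(
        pd.DataFrame(
            {
                "condition": ["reference"] * n_d + ["treatment"] * n_d,
                "donor": donors + donors,
            },
            index=pd.Index(cols, name="sample_id"),
        )
    )

    # --- TF binding-site peaks -------------------------------------------
    rng = _rng(seed, 5)
    hypo_mask = np.zeros(config.n_probes, bool)
    hypo_mask[planted_hypo] = True
    hyper_mask = np.zeros(config.n_probes, bool)
    hyper_mask[planted_hyper] = True
    tf_peaks = []
    pos_arr = np.asarray(pos_col)
    chrom_arr = np.asarray(chrom_col)
    for label, p_hypo, p_hyper, p_bg in config.tf_specs:
        p_cover = np.full(config.n_probes, p_bg)
        p_cover[hypo_mask] = p_hypo
        p_cover[hyper_mask] = p_hyper
        covered = rng.random(config.n_probes) < p_cover
        ivs = [
            GenomicInterval(
                str(c),
                max(0, int(p) - config.peak_halfwidth),
                min(config.chrom_length, int(p) + config.peak_halfwidth + 1),
                label,
            )
            for c, p in zip(chrom_arr[covered], pos_arr[covered])
        ]
        tf_peaks.append((label, "synthCell", ivs))

    # --- gene model and expression ---------------------------------------
    rng = _rng(seed, 6)
    genes = [f"g{j + 1:05d}" for j in range(config.n_genes)]
    tagged = rng.random(config.n_probes) < config.gene_tag_fraction
    gene_of = np.where(tagged, rng.integers(0, config.n_genes, size=config.n_probes), -1)
    utr5 = tagged & (rng.random(config.n_probes) < config.utr5_fraction)
    other_flags = rng.choice(["Body", "TSS1500", "TSS200", "ThreeUTR"], size=config.n_probes)

    gene_symbols = [
        (genes[g],) if g >= 0 else () for g in gene_of
    ]
    region_flags = [
        frozenset({"FiveUTR"}) if u else (frozenset({f}) if t else frozenset())
        for u, t, f in zip(utr5, tagged, other_flags)
    ]

    # genes whose 5'UTR carries a planted CpG get expression coupled
    # (negatively) to that CpG's M-value in each condition
    coupled: dict[int, int] = {}
    for i in np.concatenate([planted_hypo, planted_hyper]):
        if utr5[i] and gene_of[i] >= 0 and gene_of[i] not in coupled:
            coupled[int(gene_of[i])] = int(i)
    base_expr = rng.uniform(2.0, 12.0, size=config.n_genes)
    expr_cols = []
    for cond, m0 in (("reference", m_ref0), ("treatment", m_trt0)):
        mean = base_expr.copy()
        for g, i in coupled.items():
            mean[g] = config.expr_intercept - config.expr_slope * m0[i]
        for j in range(n_d):
            noise = rng.normal(0.0, config.expr_noise_sd, size=config.n_genes)
            expr_cols.append(np.clip(mean + noise, 0.0, None))
    expr_df = pd.DataFrame(
        np.column_stack(expr_cols), index=pd.Index(genes, name="gene"), columns=cols
    )

    # --- RNAPII-interaction regions ---------------------------------------
    rng = _rng(seed, 7)
    p_cover = np.full(config.n_probes, config.rnapii_background_cov)
    p_cover[hypo_mask] = config.rnapii_hypo_cov
    p_cover[hyper_mask] = config.rnapii_hyper_cov
    covered = rng.random(config.n_probes) < p_cover
    rnapii = [
        GenomicInterval(
            str(c),
            max(0, int(p) - config.rnapii_halfwidth),
            min(config.chrom_length, int(p) + config.rnapii_halfwidth + 1),
            "RNAPII",
        )
        for c, p in zip(chrom_arr[covered], pos_arr[covered])
    ]

    manifest = ProbeManifest(
        pd.DataFrame(
            {
                "chrom": chrom_col,
                "pos": pos_col,
                "island_relation": categories,
                "gene_symbols": gene_symbols,
                "region_flags": region_flags,
            },
            index=pd.Index(probe_ids, name="probe_id"),
        )
    )
    truth = GroundTruth(
        planted_hypo=[probe_ids[i] for i in planted_hypo],
        planted_hyper=[probe_ids[i] for i in planted_hyper],
        tf_coverage={s[0]: tuple(s[1:]) for s in config.tf_specs},
        expr_coupled_genes=[genes[g] for g in sorted(coupled)],
        expr_intercept=config.expr_intercept,
        expr_slope=config.expr_slope,
        rnapii_coverage=(
            config.rnapii_hypo_cov,
            config.rnapii_hyper_cov,
            config.rnapii_background_cov,
        ),
        state_shifts=dict(config.state_shifts),
    )
    logger.info(
        "simulate_all: %d probes, %d planted (%d hypo / %d hyper), %d TFs",
        config.n_probes, config.n_planted_diff, len(planted_hypo),
        len(planted_hyper), len(config.tf_specs),
    )
    return SimulatedData(
        config, manifest, segmentation, beta_df, sheet, tf_peaks, expr_df, rnapii, truth
    )


PRESETS = {
    "tiny": dict(
        n_chrom=1,
        chrom_length=200_000,
        n_probes=400,
        n_planted_diff=40,
        n_genes=60,
        mean_segment_length=2_000,
        tf_specs=default_tf_specs(n_decoys=4),
    ),
    "default": dict(),
    "null": dict(
        n_probes=5_000,
        n_planted_diff=0,
        delta_beta=0.0,
        expr_slope=0.0,
    ),
}


def make_config(preset: str, seed: int, **overrides) -> SimulationConfig:
    if preset not in PRESETS:
        raise ValueError(
            f"unknown preset '{preset}'; available: {sorted(PRESETS)}"
        )
    kwargs = dict(PRESETS[preset])
    kwargs.update(overrides)
    return SimulationConfig(seed=seed, **kwargs)


def _write_bed(path: Path, intervals) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            label = iv.label if iv.label is not None else "."
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{label}\n")


def emit_fixture(
    preset: str, outdir: str | Path, seed: int, **overrides
) -> dict[str, Path]:
    """Write a complete synthetic input set (all formats the readers
    consume) plus ground-truth JSON to ``outdir``; returns the paths.

    Byte-identical across runs with the same preset/seed/overrides.
    """
    config = make_config(preset, seed, **overrides)
    data = simulate_all(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    mt = data.manifest.table
    manifest_out = pd.DataFrame(
        {
            "probe_id": mt.index,
            "chrom": mt["chrom"].to_numpy(),
            "pos": mt["pos"].to_numpy() + 1,  # external manifests are 1-based
            "island_relation": mt["island_relation"].to_numpy(),
            "gene_symbols": [";".join(g) for g in mt["gene_symbols"]],
            "region_flags": [";".join(sorted(f)) for f in mt["region_flags"]],
        }
    )
    paths["manifest"] = outdir / "manifest.tsv"
    manifest_out.to_csv(paths["manifest"], sep="\t", index=False)

    paths["segmentation"] = outdir / "states.bed"
    _write_bed(paths["segmentation"], data.segmentation.intervals)

    paths["beta"] = outdir / "beta.tsv"
    data.beta.to_csv(paths["beta"], sep="\t", float_format="%.6f")

    paths["samples"] = outdir / "samples.tsv"
    data.sheet.table.to_csv(paths["samples"], sep="\t")

    paths["expression"] = outdir / "expression.tsv"
    data.expression.to_csv(paths["expression"], sep="\t", float_format="%.6f")

    paths["rnapii"] = outdir / "rnapii.bed"
    _write_bed(paths["rnapii"], data.rnapii)

    peak_dir = outdir / "peaks"
    peak_dir.mkdir(exist_ok=True)
    peak_rows = []
    for label, cell_type, ivs in data.tf_peaks:
        p = peak_dir / f"{label}_{cell_type}.bed"
        _write_bed(p, ivs)
        # store paths relative to outdir so fixtures are relocatable and
        # byte-identical across runs in different directories
        peak_rows.append(
            {"tf_label": label, "cell_type": cell_type,
             "path": str(p.relative_to(outdir))}
        )
    paths["peaks_manifest"] = outdir / "peaks_manifest.tsv"
    pd.DataFrame(peak_rows).to_csv(paths["peaks_manifest"], sep="\t", index=False)

    paths["truth"] = outdir / "truth.json"
    paths["truth"].write_text(data.truth.to_json() + "\n")
    logger.info("emit_fixture('%s', seed=%d) -> %s", preset, seed, outdir)
    return paths
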