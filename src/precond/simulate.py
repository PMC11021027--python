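"""Synthetic screen data with the statistical structure the pipeline assumes.

The generator emulates a DGRP-style stress-preconditioning screen: ~177
fully inbred strains (homozygous 0/1 dosages), biallelic SNPs with target
MAF above 0.05 plus sub-threshold and multi-allelic sites to exercise the
variant filters, block-structured relatedness, a small set of causal
variants whose summed effects set each strain's true preconditioning
log hazard ratio, and two 100-fly arms per strain whose death times are
observed on a 2-hour monitoring grid during an 8 AM–8 PM window with an
overnight gap.  It also fabricates gene annotations and gene sets around
the simulated variant positions (guaranteeing every structural corner case
the annotation stage must handle), negative-binomial count matrices with an
optional planted outlier sample, and qPCR Ct tables with known fold
changes.

Everything is a pure function of the config's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gwas import GenotypePanel

CHROM_ARMS = ("2L", "2R", "3L", "3R", "X")

QPCR_TIMEPOINTS = (
    "no_treatment",
    "heat_shock",
    "post_recovery",
    "er_stress",
    "preconditioned_er_stress",
)
QPCR_GENES = ("Set1", "Hsp70", "Hsp26", "Hsp83", "GstD2")


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic screen.

    Defaults mirror the screen design: 177 strains, 100 flies per arm,
    deaths checked every 2 h between clock hours 8 and 20 (assay clock
    starts at the first morning check window), exponential baseline hazard
    of 0.02 deaths/h (mean time to death ~50 h on stress food) and a
    right-censoring horizon of one week.
    """

    n_strains: int = 177
    n_variants: int = 2000
    maf_range: tuple = (0.05, 0.5)
    frac_subthreshold: float = 0.10
    frac_multiallelic: float = 0.05
    n_blocks: int = 8
    block_share: float = 0.6
    n_causal: int = 8
    effect_sizes: tuple | None = None  # per-causal log-HR effects
    strain_log_hr_noise_sd: float = 0.0
    baseline_hazard: float = 0.02  # deaths per hour
    weibull_shape: float = 1.0  # 1.0 = exponential baseline
    flies_per_arm: int = 100
    monitor_interval_h: float = 2.0
    monitor_window: tuple = (8, 20)  # daily clock hours under observation
    censor_horizon_h: float = 168.0
    missing_rate: float = 0.0
    # expression / qPCR block
    rnaseq_n_genes: int = 500
    rnaseq_samples_per_group: int = 5
    rnaseq_dispersion: float = 0.1
    rnaseq_outlier_shift: float = 0.0  # fold applied to a fraction of genes
    rnaseq_outlier_frac: float = 0.3
    qpcr_noise_sd: float = 0.1
    qpcr_replicates: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.n_causal > self.n_variants:
            raise ValueError("n_causal cannot exceed n_variants")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if self.flies_per_arm <= 0:
            raise ValueError("flies_per_arm must be positive")
        if self.monitor_interval_h <= 0:
            raise ValueError("monitor_interval_h must be positive")
        if self.effect_sizes is not None and len(self.effect_sizes) != self.n_causal:
            raise ValueError("effect_sizes length must equal n_causal")

    def resolved_effects(self) -> np.ndarray:
        if self.effect_sizes is not None:
            return np.asarray(self.effect_sizes, dtype=float)
        # alternating beneficial/detrimental effects of moderate size
        signs = np.where(np.arange(self.n_causal) % 2 == 0, 1.0, -1.0)
        return 0.5 * signs


@dataclass
class GroundTruth:
    """What the generator planted, for recovery testing downstream."""

    causal_variant_ids: list
    effect_sizes: np.ndarray
    per_strain_true_log_hr: pd.Series
    block_membership: dict


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def simulate_panel(config: SimulationConfig) -> tuple[GenotypePanel, GroundTruth]:
    """Genotype panel with block relatedness plus the planted ground truth.

    Each variant has a target minor-allele frequency (a stated fraction
    below the 0.05 filter); strains inherit the variant's block-level allele
    with probability ``block_share`` and draw independently otherwise, which
    induces block-structured relatedness without coalescent machinery.
    """
    rng = _rng(config, 0)
    n, p = config.n_strains, config.n_variants

    strains = [f"RAL{i + 101}" for i in range(n)]
    blocks = np.repeat(np.arange(config.n_blocks), int(np.ceil(n / config.n_blocks)))[:n]

    # positions: variants split across chromosome arms, spacing 400-700 bp
    per_chrom = np.array_split(np.arange(p), len(CHROM_ARMS))
    chrom = np.empty(p, dtype=object)
    pos = np.empty(p, dtype=int)
    for arm, idx in zip(CHROM_ARMS, per_chrom):
        chrom[idx] = arm
        pos[idx] = 10_000 + np.cumsum(rng.integers(400, 701, size=idx.size))

    n_sub = int(round(config.frac_subthreshold * p))
    target_maf = rng.uniform(*config.maf_range, size=p)
    sub_idx = rng.choice(p, size=n_sub, replace=False)
    target_maf[sub_idx] = rng.uniform(0.005, 0.045, size=n_sub)

    block_alleles = rng.random((config.n_blocks, p)) < target_maf
    indiv = rng.random((n, p)) < target_maf
    use_block = rng.random((n, p)) < config.block_share
    dosage = np.where(use_block, block_alleles[blocks, :], indiv).astype(float)

    n_multi = int(round(config.frac_multiallelic * p))
    multi_idx = rng.choice(np.setdiff1d(np.arange(p), sub_idx), size=n_multi,
                           replace=False)
    n_alleles = np.full(p, 2, dtype=int)
    n_alleles[multi_idx] = 3

    if config.missing_rate > 0:
        miss = rng.random((n, p)) < config.missing_rate
        dosage[miss] = np.nan

    variants = pd.DataFrame(
        {
            "variant_id": [f"{c}_{q}" for c, q in zip(chrom, pos)],
            "chrom": chrom,
            "pos": pos,
            "ref": "A",
            "alt": "T",
            "n_alleles": n_alleles,
            "target_maf": target_maf,
        }
    )
    panel = GenotypePanel(strains=strains, variants=variants, dosage=dosage)
    realized = panel.maf()
    panel.variants["maf"] = realized

    # causal variants: common, biallelic, so their effects are identifiable
    eligible = np.where((n_alleles == 2) & (realized >= 0.15))[0]
    if eligible.size < config.n_causal:
        eligible = np.where((n_alleles == 2) & (realized > 0))[0]
    if eligible.size < config.n_causal:  # degenerate tiny panels
        eligible = np.where(n_alleles == 2)[0]
    causal_idx = np.sort(rng.choice(eligible, size=config.n_causal, replace=False))
    effects = config.resolved_effects()

    X_causal = panel.imputed_dosage()[:, causal_idx]
    true_log_hr = X_causal @ effects
    if config.strain_log_hr_noise_sd > 0:
        true_log_hr = true_log_hr + rng.normal(
            0.0, config.strain_log_hr_noise_sd, size=n
        )
    truth = GroundTruth(
        causal_variant_ids=list(variants["variant_id"].iloc[causal_idx]),
        effect_sizes=effects,
        per_strain_true_log_hr=pd.Series(true_log_hr, index=strains),
        block_membership=dict(zip(strains, blocks.tolist())),
    )
    return panel, truth


def monitoring_grid_points(config: SimulationConfig, horizon: float) -> np.ndarray:
    """Check times (hours since the first morning of the assay) up to horizon."""
    win_len = config.monitor_window[1] - config.monitor_window[0]
    n_checks = int(np.floor(win_len / config.monitor_interval_h))
    days = int(np.ceil(horizon / 24.0)) + 1
    pts = [
        24.0 * d + j * config.monitor_interval_h
        for d in range(days)
        for j in range(1, n_checks + 1)
    ]
    return np.asarray(pts)


def discretize_to_grid(times: np.ndarray, config: SimulationConfig) -> np.ndarray:
    """Round death times up to the next monitoring check.

    The assay clock starts at the first morning observation (clock hour 8);
    checks run every ``monitor_interval_h`` until clock hour 20.  A death
    after the last evening check is recorded at the next morning's first
    check — the overnight-gap convention.
    """
    t = np.asarray(times, dtype=float)
    win_len = config.monitor_window[1] - config.monitor_window[0]
    n_checks = int(np.floor(win_len / config.monitor_interval_h))
    last_check = n_checks * config.monitor_interval_h
    day = np.floor(t / 24.0)
    within = t - 24.0 * day
    j = np.ceil(within / config.monitor_interval_h)
    j = np.maximum(j, 1)
    overnight = within > last_check
    out = np.where(
        overnight,
        24.0 * (day + 1) + config.monitor_interval_h,
        24.0 * day + j * config.monitor_interval_h,
    )
    return out


def simulate_survival(
    panel: GenotypePanel, truth: GroundTruth, config: SimulationConfig
) -> pd.DataFrame:
    """Two-arm fly-level survival records for every strain.

    Control-arm deaths follow the baseline hazard (exponential by default;
    Weibull when ``weibull_shape`` != 1); the preconditioned arm's hazard is
    multiplied by exp(true log-HR).  Raw times are discretized up to the
    monitoring grid and right-censored at the horizon.
    """
    if config.baseline_hazard <= 0:
        raise ValueError("baseline_hazard must be positive")
    missing = set(truth.per_strain_true_log_hr.index) - set(panel.strains)
    if missing:
        raise ValueError(f"strains in truth absent from panel: {sorted(missing)[:5]}")
    rng = _rng(config, 1)
    m = config.flies_per_arm
    k = config.weibull_shape
    frames = []
    for strain in panel.strains:
        log_hr = float(truth.per_strain_true_log_hr.loc[strain])
        for arm, rate in (
            ("control", config.baseline_hazard),
            ("preconditioned", config.baseline_hazard * np.exp(log_hr)),
        ):
            e = rng.exponential(1.0, size=m)
            raw = (e / rate) ** (1.0 / k)  # PH Weibull; k=1 is exponential
            t = discretize_to_grid(raw, config)
            event = (t <= config.censor_horizon_h).astype(int)
            t = np.where(event == 1, t, config.censor_horizon_h)
            frames.append(
                pd.DataFrame(
                    {"strain": strain, "arm": arm, "time_h": t, "event": event}
                )
            )
    return pd.concat(frames, ignore_index=True)


def _build_gene(gene_id, chrom, positions, types, start=None, end=None):
    """Feature rows for one gene whose i-th sub-interval contains the i-th
    position; internal boundaries fall midway between adjacent positions."""
    positions = list(positions)
    start = int(positions[0] - 50) if start is None else int(start)
    end = int(positions[-1] + 50) if end is None else int(end)
    bounds = [start]
    for a, b in zip(positions[:-1], positions[1:]):
        bounds.append(int((a + b) // 2))
    bounds.append(end)
    rows = [
        {"gene_id": gene_id, "chrom": chrom, "feature": "gene",
         "start": start, "end": end}
    ]
    for i, typ in enumerate(types):
        lo = bounds[i] + 1 if i > 0 else start
        hi = bounds[i + 1]
        rows.append(
            {"gene_id": gene_id, "chrom": chrom, "feature": typ,
             "start": lo, "end": hi}
        )
    return rows


def simulate_annotation(
    panel: GenotypePanel,
    config: SimulationConfig,
    truth: GroundTruth | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Gene annotation tiled over the panel's variant positions, plus GMT-style
    gene sets.

    Per chromosome the tiling guarantees, by construction: variants inside
    exons, UTRs and introns; a variant in one gene's exon that is also
    within 1 kb upstream of the next gene; a variant inside two overlapping
    genes; flank variants within 1 kb of a gene; and a 5-variant intergenic
    gap whose middle variants are more than 1 kb from every gene.  Causal
    variants falling inside a gene are forced into exon sub-intervals; any
    causal variant left intergenic gets a small rescue gene so that every
    causal effect maps to a gene.

    Returns (annotation table, gene sets).  Gene sets always include
    ``enriched_set`` (causal-variant genes padded with random genes) and
    ``random_set``.
    """
    rng = _rng(config, 2)
    causal_ids = set(truth.causal_variant_ids) if truth is not None else set()
    variants = panel.variants
    rows: list[dict] = []
    gene_counter = 0

    def next_gene_id():
        nonlocal gene_counter
        gene_counter += 1
        return f"SG{gene_counter:04d}"

    base_types = ["UTR", "exon", "intron", "exon", "UTR"]
    for arm in CHROM_ARMS:
        sub = variants[variants["chrom"] == arm]
        pos = sub["pos"].to_numpy()
        ids = sub["variant_id"].to_numpy()
        n = pos.size
        i = 0

        def types_for(chunk_ids, base):
            # causal variants must land in an exon sub-interval
            return [
                "exon" if vid in causal_ids else t
                for vid, t in zip(chunk_ids, base)
            ]

        structured = n >= 30
        if structured:
            # gene 1 (plain), then a >1 kb intergenic gap
            rows += _build_gene(next_gene_id(), arm, pos[0:5],
                                types_for(ids[0:5], base_types))
            # variants 5-9 intergenic; spacing >= 400 bp keeps the middle
            # ones > 1 kb from both neighbours
            # gene 2 ends on an exon; gene 3 starts < 1 kb after it
            g2_types = types_for(ids[10:15], ["UTR", "exon", "intron", "exon", "exon"])
            rows += _build_gene(next_gene_id(), arm, pos[10:15], g2_types)
            g3_start = int(pos[14] + 300)
            g3_types = types_for(ids[15:20], ["exon", "intron", "intron", "exon", "UTR"])
            rows += _build_gene(next_gene_id(), arm, pos[15:20], g3_types,
                                start=g3_start)
            # gene 4 overlaps gene 3's tail: pos[19] sits in gene 3's UTR and
            # gene 4's leading exon
            g4_types = types_for(ids[19:24], ["exon", "intron", "exon", "UTR", "exon"])
            rows += _build_gene(next_gene_id(), arm, pos[19:24], g4_types,
                                start=int(pos[19] - 50))
            i = 29  # variants 24-28 form the second intergenic gap
        # regular tiling: 5-variant genes separated by 3-variant gaps
        while i + 5 <= n:
            chunk = slice(i, i + 5)
            rows += _build_gene(next_gene_id(), arm, pos[chunk],
                                types_for(ids[chunk], base_types))
            i += 8

    annot = pd.DataFrame(rows)

    # rescue genes so every causal variant maps to a gene
    if causal_ids:
        from .annotation import assign_variants, load_annotation

        index = load_annotation(annot)
        causal_rows = variants[variants["variant_id"].isin(causal_ids)]
        assigned = assign_variants(causal_rows, index)
        orphan = assigned[assigned["gene_id"].isna()]["variant_id"]
        extra = []
        for vid in orphan:
            row = variants[variants["variant_id"] == vid].iloc[0]
            gid = next_gene_id()
            extra += [
                {"gene_id": gid, "chrom": row["chrom"], "feature": "gene",
                 "start": int(row["pos"] - 200), "end": int(row["pos"] + 200)},
                {"gene_id": gid, "chrom": row["chrom"], "feature": "exon",
                 "start": int(row["pos"] - 200), "end": int(row["pos"] + 200)},
            ]
        if extra:
            annot = pd.concat([annot, pd.DataFrame(extra)], ignore_index=True)

    # gene sets
    from .annotation import assign_variants, load_annotation

    index = load_annotation(annot)
    all_genes = sorted(index.genes)
    gene_sets: dict[str, list] = {}
    if causal_ids:
        causal_rows = variants[variants["variant_id"].isin(causal_ids)]
        assigned = assign_variants(causal_rows, index)
        causal_genes = sorted(set(assigned["gene_id"].dropna()))
    else:
        causal_genes = []
    pool = [g for g in all_genes if g not in causal_genes]
    pad = max(0, 10 - len(causal_genes))
    padding = list(rng.choice(pool, size=pad, replace=False)) if pad else []
    gene_sets["enriched_set"] = causal_genes + padding
    remaining = [g for g in pool if g not in padding]
    gene_sets["random_set"] = sorted(
        rng.choice(remaining, size=min(10, len(remaining)), replace=False)
    )
    return annot, gene_sets


def simulate_orthologs(gene_ids, config: SimulationConfig) -> pd.DataFrame:
    """Ortholog score table (source_gene, target_gene, score) with 0-2
    candidate targets per gene and integer confidence scores 1-15, so both
    sides of the >= 5 reporting threshold occur."""
    rng = _rng(config, 4)
    rows = []
    for gene in gene_ids:
        for k in range(rng.integers(0, 3)):
            rows.append(
                {
                    "source_gene": gene,
                    "target_gene": f"HS_{gene}_{k}",
                    "score": int(rng.integers(1, 16)),
                }
            )
    return pd.DataFrame(rows, columns=["source_gene", "target_gene", "score"])


@dataclass
class ExpressionSim:
    counts: pd.DataFrame          # genes x samples
    sample_groups: pd.Series      # sample -> beneficial/detrimental
    outlier_sample: str | None
    ct: pd.DataFrame              # tidy Ct table
    true_folds: dict              # (genotype, timepoint, gene) -> fold


def default_true_folds() -> dict:
    """Planted qPCR fold changes: stress-response genes induced on heat
    shock and ER stress, Set1 knocked down in the knockdown genotype."""
    folds = {}
    for genotype in ("control", "knockdown"):
        for tp in QPCR_TIMEPOINTS:
            for gene in QPCR_GENES:
                fold = 1.0
                if gene.startswith("Hsp") and tp in (
                    "heat_shock", "preconditioned_er_stress"
                ):
                    fold = 8.0 if tp == "heat_shock" else 3.0
                if gene == "GstD2" and tp in ("er_stress", "preconditioned_er_stress"):
                    fold = 4.0
                if gene == "Set1" and genotype == "knockdown":
                    fold = 0.3
                folds[(genotype, tp, gene)] = fold
    return folds


def simulate_counts_and_ct(
    config: SimulationConfig, true_folds: dict | None = None
) -> ExpressionSim:
    """Negative-binomial count matrix (optional planted outlier sample) and a
    qPCR Ct table with known fold changes.

    The outlier, when ``rnaseq_outlier_shift`` > 1, is the last sample of
    the beneficial group with a ``rnaseq_outlier_frac`` fraction of its gene
    means multiplied by the shift.  Ct values derive from a housekeeping
    gene at ~18 cycles, per-gene baseline dCt of 5 cycles, and
    -log2(true fold) displacement plus replicate noise.
    """
    rng = _rng(config, 3)
    G = config.rnaseq_n_genes
    reps = config.rnaseq_samples_per_group
    samples = [f"beneficial_{i+1}" for i in range(reps)] + [
        f"detrimental_{i+1}" for i in range(reps)
    ]
    groups = pd.Series(
        ["beneficial"] * reps + ["detrimental"] * reps, index=samples
    )
    base_mean = np.exp(rng.normal(np.log(100.0), 1.0, size=G))
    # mild group structure: 10% of genes differ twofold between groups
    de = rng.random(G) < 0.10
    fold = np.where(de, 2.0, 1.0)
    mean = np.tile(base_mean[:, None], (1, 2 * reps))
    mean[:, reps:] *= fold[:, None]

    outlier_sample = None
    if config.rnaseq_outlier_shift > 1.0:
        outlier_sample = samples[reps - 1]
        shifted = rng.random(G) < config.rnaseq_outlier_frac
        mean[shifted, reps - 1] *= config.rnaseq_outlier_shift

    disp = config.rnaseq_dispersion
    # NB with mean m and dispersion a: var = m + a m^2
    r = 1.0 / disp
    counts = rng.negative_binomial(r, r / (r + mean))
    counts_df = pd.DataFrame(
        counts, index=[f"gene_{g+1}" for g in range(G)], columns=samples
    )

    if true_folds is None:
        true_folds = default_true_folds()
    rows = []
    for genotype in ("control", "knockdown"):
        for tp in QPCR_TIMEPOINTS:
            for rep in range(1, config.qpcr_replicates + 1):
                sample = f"{genotype}_{tp}_r{rep}"
                hk_ct = 18.0 + rng.normal(0.0, config.qpcr_noise_sd)
                rows.append(
                    {"sample": sample, "genotype": genotype, "timepoint": tp,
                     "gene": "RpL19", "ct": hk_ct, "replicate": rep}
                )
                for gene in QPCR_GENES:
                    f = true_folds[(genotype, tp, gene)]
                    ct = (
                        hk_ct + 5.0 - np.log2(f)
                        + rng.normal(0.0, config.qpcr_noise_sd)
                    )
                    rows.append(
                        {"sample": sample, "genotype": genotype, "timepoint": tp,
                         "gene": gene, "ct": ct, "replicate": rep}
                    )
    ct_df = pd.DataFrame(rows)
    return ExpressionSim(
        counts=counts_df,
        sample_groups=groups,
        outlier_sample=outlier_sample,
        ct=ct_df,
        true_folds=true_folds,
    )
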