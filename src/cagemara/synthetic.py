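"""Synthetic CAGE time-course generator with known ground truth.

The generator inverts the analysis model: it plants motif sites in random
promoter sequences, draws per-interval motif activities from a small number
of smooth archetype curves, and accumulates gene expression multiplicatively
from the implied log2 changes

    delta*_{g,t} = c_t + sum_m Ntilde_{g,m} A*_{m,t} + eps_{g,t},

where Ntilde is the column-standardized affinity matrix of the planted
sequences.  Replicates add independent log2 noise.  Every random draw flows
from one integer seed, so a configuration maps to a byte-identical bundle.

Defaults emulate a developmental CAGE design: 12 timepoints (daily embryonic
E11-E18, then P0/P3/P6/P9) x 3 replicates, 400 bp regions, baseline
abundances log-uniform over 10-1000 TPM, interval noise 0.3 and replicate
noise 0.15 log2 units.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .affinity import BASES, MotifMatrix, affinity_matrix, write_jaspar
from .activity import standardize_design
from .expression import ExpressionTable, TimepointDesign, default_design


@dataclass(frozen=True)
class SimulationConfig:
    """Everything the generator needs; one seed drives all randomness."""

    n_genes: int = 1000
    n_motifs: int = 20
    motif_width: int = 8
    n_timepoints: int = 12
    n_replicates: int = 3
    region_length: int = 400
    interval_noise_sd: float = 0.3  # sigma, log2 units per gene-interval
    replicate_noise_sd: float = 0.15  # tau, log2 units per measurement
    pseudocount: float = 1.0  # delta, expression units
    n_archetypes: int = 5
    informativeness: float = 0.9
    sites_per_region_rate: float = 2.0
    amplitude: float = 1.0
    intercept_sd: float = 0.0
    n_enhancers: int = 0
    library_size: float = 5e6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < self.n_motifs + 2:
            raise ValueError("need n_genes >= n_motifs + 2")
        if self.n_timepoints < 3:
            raise ValueError("need at least 3 timepoints")
        if self.motif_width < 4:
            raise ValueError("motif_width must be >= 4")
        if self.region_length < self.motif_width:
            raise ValueError("region_length must be >= motif_width")
        for name in ("interval_noise_sd", "replicate_noise_sd", "intercept_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")

    @property
    def design(self) -> TimepointDesign:
        return default_design(self.n_timepoints, self.n_replicates)


@dataclass(frozen=True)
class PlantedSite:
    region_id: str
    motif_id: str
    offset: int
    strand: str


@dataclass
class SyntheticTruth:
    """Ground truth for one simulated bundle."""

    activities: pd.DataFrame  # motifs x (T-1)
    intercepts: np.ndarray  # per interval
    archetype_labels: dict[str, int]
    planted_sites: list[PlantedSite]
    interval_noise: np.ndarray  # G x (T-1), the eps draws
    baselines: np.ndarray  # per-gene starting abundance (TPM)
    seed_motifs: list[str]
    novel_motifs: list[str]
    config: SimulationConfig
    baselines_raised: int = 0


def simulate_motifs(
    n_motifs: int,
    width: int,
    informativeness: float = 0.9,
    seed: int = 0,
    path: str | Path | None = None,
) -> list[MotifMatrix]:
    """Motifs with pairwise-distinct random consensi; each column puts
    ``informativeness`` probability on the consensus base and spreads the rest
    evenly.  Optionally written as a JASPAR PFM file."""
    if not 0 < informativeness <= 1:
        raise ValueError("informativeness must be in (0, 1]")
    if n_motifs > 4**width:
        raise ValueError(
            f"cannot build {n_motifs} distinct consensi of width {width}"
        )
    rng = np.random.default_rng(seed)
    consensi: list[tuple[int, ...]] = []
    seen: set[tuple[int, ...]] = set()
    while len(consensi) < n_motifs:
        cand = tuple(int(b) for b in rng.integers(0, 4, size=width))
        if cand not in seen:
            seen.add(cand)
            consensi.append(cand)
    off = (1.0 - informativeness) / 3.0
    motifs = []
    for k, consensus in enumerate(consensi, start=1):
        mat = np.full((4, width), off)
        mat[consensus, np.arange(width)] = informativeness
        motifs.append(
            MotifMatrix(f"M{k:03d}", f"TF{k:03d}", mat / mat.sum(axis=0, keepdims=True))
        )
    if path is not None:
        write_jaspar(motifs, path)
    return motifs


def _sample_site(motif: MotifMatrix, rng: np.random.Generator) -> np.ndarray:
    return np.array(
        [rng.choice(4, p=motif.probabilities[:, j]) for j in range(motif.width)],
        dtype=np.int8,
    )


def simulate_regions_and_sequences(
    n_regions: int,
    region_length: int,
    motifs: Sequence[MotifMatrix],
    sites_per_region_rate: float = 2.0,
    background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    seed: int = 0,
    region_prefix: str = "prom",
    ensure_every_motif: bool = True,
) -> tuple[dict[str, str], pd.DataFrame, list[PlantedSite]]:
    """Random background sequences with Poisson-many motif sites planted at
    uniform offsets on either strand.

    Returns (region_id -> sequence, BED table of 0-based half-open intervals,
    planted-site records).  With ``ensure_every_motif`` each motif receives at
    least one site somewhere (one extra deterministic plant if the Poisson
    draw missed it).
    """
    bg = np.asarray(background, dtype=float)
    if not np.isclose(bg.sum(), 1.0):
        raise ValueError("background base frequencies must sum to 1")
    rng = np.random.default_rng(seed)
    ids = [f"{region_prefix}_{i:05d}" for i in range(1, n_regions + 1)]
    seqs = {
        rid: rng.choice(4, size=region_length, p=bg).astype(np.int8) for rid in ids
    }
    sites: list[PlantedSite] = []

    def plant(rid: str, motif: MotifMatrix) -> None:
        w = motif.width
        offset = int(rng.integers(0, region_length - w + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        site = _sample_site(motif, rng)
        if strand == "-":
            site = (3 - site)[::-1]
        seqs[rid][offset : offset + w] = site
        sites.append(PlantedSite(rid, motif.motif_id, offset, strand))

    if sites_per_region_rate > 0 and motifs:
        for rid in ids:
            for _ in range(int(rng.poisson(sites_per_region_rate))):
                plant(rid, motifs[int(rng.integers(len(motifs)))])
    if ensure_every_motif and motifs and sites_per_region_rate > 0:
        planted_motifs = {s.motif_id for s in sites}
        for motif in motifs:
            if motif.motif_id not in planted_motifs:
                plant(ids[int(rng.integers(n_regions))], motif)

    sequences = {rid: "".join(BASES[b] for b in arr) for rid, arr in seqs.items()}
    bed = pd.DataFrame(
        {
            "chrom": ids,
            "start": 0,
            "end": region_length,
            "name": ids,
            "score": 0,
            "strand": "+",
        }
    )
    return sequences, bed, sites


def _archetype_curves(
    n_archetypes: int,
    n_intervals: int,
    amplitude: float,
    rng: np.random.Generator,
    max_abs_corr: float = 0.3,
    max_tries: int = 5000,
) -> np.ndarray:
    """Smooth curves (moving-average of white noise) scaled to peak
    |amplitude|, accepted only if pairwise |Pearson r| < max_abs_corr."""
    curves: list[np.ndarray] = []
    for _ in range(max_tries):
        if len(curves) == n_archetypes:
            break
        raw = rng.normal(size=n_intervals + 2)
        smooth = np.convolve(raw, np.ones(3) / 3.0, mode="valid")
        if np.allclose(smooth, smooth[0]):
            continue
        peak = np.abs(smooth).max()
        cand = smooth / peak * amplitude if peak > 0 else smooth
        if amplitude == 0:
            cand = smooth / max(np.abs(smooth).max(), 1e-12)
        ok = all(
            abs(np.corrcoef(cand, c)[0, 1]) < max_abs_corr for c in curves
        )
        if ok:
            curves.append(cand)
    if len(curves) < n_archetypes:
        raise RuntimeError(
            f"could not draw {n_archetypes} decorrelated archetype curves"
        )
    if amplitude == 0:
        return np.zeros((n_archetypes, n_intervals))
    return np.vstack(curves)


def simulate_activities(
    n_motifs: int,
    n_timepoints: int,
    n_archetypes: int = 5,
    amplitude: float = 1.0,
    seed: int = 0,
    interval_labels: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Ground-truth activity profiles: each motif follows one of
    ``n_archetypes`` smooth archetype curves times a per-motif gain
    (U[0.8, 1.2]) plus small jitter (SD 0.05 x amplitude).

    Returns (motifs x (T-1) activity table, motif -> archetype labels).
    """
    if n_archetypes > n_motifs:
        raise ValueError("n_archetypes cannot exceed n_motifs")
    if n_archetypes < 2:
        warnings.warn(
            "fewer than 2 archetypes: k-selection on this truth is impossible",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    n_int = n_timepoints - 1
    curves = _archetype_curves(max(n_archetypes, 1), n_int, amplitude, rng)
    motif_ids = [f"M{k:03d}" for k in range(1, n_motifs + 1)]
    labels = {mid: k % max(n_archetypes, 1) for k, mid in enumerate(motif_ids)}
    gains = rng.uniform(0.8, 1.2, size=n_motifs)
    jitter = rng.normal(0.0, 0.05 * amplitude, size=(n_motifs, n_int))
    profiles = curves[[labels[m] for m in motif_ids]] * gains[:, None] + jitter
    if interval_labels is None:
        interval_labels = [f"i{t:02d}" for t in range(1, n_int + 1)]
    table = pd.DataFrame(profiles, index=motif_ids, columns=list(interval_labels))
    return table, labels


def simulate_expression(
    true_affinities: pd.DataFrame,
    true_activities: pd.DataFrame,
    config: SimulationConfig,
) -> tuple[ExpressionTable, ExpressionTable, dict]:
    """Expression tables (exact TPM variant, rounded counts variant) generated
    from planted affinities and activities.

    Log2 changes per consecutive interval are ``c_t + Ntilde A* + eps``;
    abundances accumulate multiplicatively from a log-uniform baseline in
    pseudocounted space, so that the analysis-side fold-change transform
    inverts the generative one exactly when sigma = tau = 0.  Baselines are
    raised where necessary to keep every abundance non-negative (recorded in
    the returned draw record).
    """
    cfg = config
    G, K = true_affinities.shape
    if G != cfg.n_genes:
        raise ValueError("true_affinities rows must equal n_genes")
    if list(true_affinities.columns) != list(true_activities.index):
        raise ValueError("affinity columns and activity rows must match")
    n_int = cfg.n_timepoints - 1
    if true_activities.shape[1] != n_int:
        raise ValueError("activities must have T-1 columns")

    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2076]))
    design = cfg.design
    z, _ = standardize_design(true_affinities)
    A = true_activities.loc[z.columns].to_numpy()

    intercepts = (
        rng.normal(0.0, cfg.intercept_sd, size=n_int)
        if cfg.intercept_sd > 0
        else np.zeros(n_int)
    )
    eps = (
        rng.normal(0.0, cfg.interval_noise_sd, size=(G, n_int))
        if cfg.interval_noise_sd > 0
        else np.zeros((G, n_int))
    )
    delta = intercepts[None, :] + z.to_numpy() @ A + eps

    baselines = 10.0 ** rng.uniform(1.0, 3.0, size=G)  # 10..1000 TPM
    cum = np.concatenate([np.zeros((G, 1)), np.cumsum(delta, axis=1)], axis=1)
    # positivity guard: keep pseudocounted abundance >= pseudocount everywhere
    min_cum = cum.min(axis=1)
    floor = cfg.pseudocount * 2.0 ** (-min_cum)
    m0 = np.maximum(baselines + cfg.pseudocount, floor)
    raised = int((m0 > baselines + cfg.pseudocount).sum())
    M = m0[:, None] * 2.0**cum  # pseudocounted abundance, G x T
    levels = M - cfg.pseudocount  # exact TPM-scale abundance, >= 0

    R = cfg.n_replicates
    rep_noise = (
        rng.normal(0.0, cfg.replicate_noise_sd, size=(G, cfg.n_timepoints, R))
        if cfg.replicate_noise_sd > 0
        else np.zeros((G, cfg.n_timepoints, R))
    )
    M_rep = M[:, :, None] * 2.0**rep_noise
    values = np.maximum(M_rep - cfg.pseudocount, 0.0).reshape(G, cfg.n_timepoints * R)

    gene_ids = list(true_affinities.index)
    symbols = pd.Series(
        [rid.replace("prom_", "g", 1) for rid in gene_ids], index=gene_ids
    )
    tpm = ExpressionTable(
        pd.DataFrame(values, index=gene_ids, columns=design.sample_ids),
        symbols,
        design,
    )
    col_sums = tpm.values.sum(axis=0)
    counts_df = (tpm.values / col_sums * cfg.library_size).round()
    counts = ExpressionTable(counts_df, symbols, design)
    record = {
        "intercepts": intercepts,
        "interval_noise": eps,
        "baselines": levels[:, 0],
        "baselines_raised": raised,
        "replicate_noise": rep_noise,
    }
    return tpm, counts, record


@dataclass
class SyntheticBundle:
    """A complete simulated study: inputs for every pipeline stage + truth."""

    config: SimulationConfig
    motifs: list[MotifMatrix]
    sequences: dict[str, str]
    bed: pd.DataFrame
    true_affinities: pd.DataFrame
    expression: ExpressionTable  # exact TPM variant
    counts: ExpressionTable
    annotations: pd.DataFrame  # TF symbol-indexed flags
    seeds: pd.DataFrame  # seed TF symbols + motif ids
    truth: SyntheticTruth
    enhancer_sequences: dict[str, str] = field(default_factory=dict)
    enhancer_links: dict[str, str] = field(default_factory=dict)


def simulate_bundle(config: SimulationConfig) -> SyntheticBundle:
    """Generate the full study: motifs, planted sequences, activities,
    expression, and the seed/novel designation used for candidate discovery.

    The first ``n_motifs`` genes are the TF genes themselves (symbol TFxxx),
    so the expression filter and the motif analysis talk about the same
    entities.  One motif per archetype (among the first two archetypes) is
    flagged as a known "seed" regulator; other motifs sharing those
    archetypes are the planted novel candidates.
    """
    cfg = config
    ss = np.random.SeedSequence(cfg.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4)]

    motifs = simulate_motifs(
        cfg.n_motifs, cfg.motif_width, cfg.informativeness, seed=seeds[0]
    )
    sequences, bed, sites = simulate_regions_and_sequences(
        cfg.n_genes,
        cfg.region_length,
        motifs,
        cfg.sites_per_region_rate,
        seed=seeds[1],
    )
    activities, labels = simulate_activities(
        cfg.n_motifs,
        cfg.n_timepoints,
        cfg.n_archetypes,
        cfg.amplitude,
        seed=seeds[2],
        interval_labels=cfg.design.interval_labels,
    )
    N_true = affinity_matrix(sequences, motifs)
    tpm, counts, record = simulate_expression(N_true, activities, cfg)

    # rename the first K genes to be the TF genes
    tf_symbols = {m.motif_id: m.tf_name for m in motifs}
    gene_ids = list(tpm.values.index)
    symbols = tpm.gene_symbols.copy()
    for k, m in enumerate(motifs):
        symbols.iloc[k] = m.tf_name
    tpm = ExpressionTable(tpm.values, symbols, cfg.design)
    counts = ExpressionTable(counts.values, symbols, cfg.design)

    seed_archetypes = sorted(set(labels.values()))[: min(2, cfg.n_archetypes)]
    seed_motifs: list[str] = []
    for a in seed_archetypes:
        seed_motifs.append(min(m for m, lab in labels.items() if lab == a))
    novel_motifs = [
        m
        for m, lab in labels.items()
        if lab in seed_archetypes and m not in seed_motifs
    ]
    annotations = pd.DataFrame(
        {
            "is_known_cerebellar": [
                tf_symbols[m.motif_id] in {tf_symbols[s] for s in seed_motifs}
                for m in motifs
            ],
            "ko_status": "no_ko",
            "eurexpress": False,
            "allen": True,
        },
        index=pd.Index([m.tf_name for m in motifs], name="symbol"),
    )
    seeds_df = pd.DataFrame(
        {
            "symbol": [tf_symbols[m] for m in seed_motifs],
            "motif_id": seed_motifs,
            "role": "planted known regulator",
        }
    )
    truth = SyntheticTruth(
        activities=activities,
        intercepts=record["intercepts"],
        archetype_labels=labels,
        planted_sites=sites,
        interval_noise=record["interval_noise"],
        baselines=record["baselines"],
        seed_motifs=seed_motifs,
        novel_motifs=novel_motifs,
        config=cfg,
        baselines_raised=record["baselines_raised"],
    )

    enh_seqs: dict[str, str] = {}
    enh_links: dict[str, str] = {}
    if cfg.n_enhancers > 0:
        enh_seqs, _, _ = simulate_regions_and_sequences(
            cfg.n_enhancers,
            cfg.region_length,
            motifs,
            sites_per_region_rate=0.0,
            seed=seeds[3],
            region_prefix="enh",
        )
        enh_links = {
            eid: gene_ids[i % cfg.n_genes] for i, eid in enumerate(enh_seqs)
        }
    return SyntheticBundle(
        config=cfg,
        motifs=motifs,
        sequences=sequences,
        bed=bed,
        true_affinities=N_true,
        expression=tpm,
        counts=counts,
        annotations=annotations,
        seeds=seeds_df,
        truth=truth,
        enhancer_sequences=enh_seqs,
        enhancer_links=enh_links,
    )


def write_bundle(bundle: SyntheticBundle, outdir: str | Path) -> dict[str, Path]:
    """Write the bundle as plain-text fixtures: regions.fa, regions.bed,
    motifs.jaspar, expression.tsv, counts.tsv, annotation.tsv, seeds.tsv,
    truth.json.  Byte-identical across reruns of the same configuration."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    fa_lines = []
    for rid, seq in {**bundle.sequences, **bundle.enhancer_sequences}.items():
        fa_lines.append(f">{rid}")
        for i in range(0, len(seq), 70):
            fa_lines.append(seq[i : i + 70])
    paths["fasta"] = out / "regions.fa"
    paths["fasta"].write_text("\n".join(fa_lines) + "\n")

    paths["bed"] = out / "regions.bed"
    bundle.bed.to_csv(paths["bed"], sep="\t", header=False, index=False)

    paths["motifs"] = out / "motifs.jaspar"
    write_jaspar(bundle.motifs, paths["motifs"])

    paths["expression"] = out / "expression.tsv"
    expr = bundle.expression.values.copy()
    expr.insert(0, "gene_symbol", bundle.expression.gene_symbols)
    expr.to_csv(paths["expression"], sep="\t", index_label="promoter_id",
                float_format="%.10g")

    paths["counts"] = out / "counts.tsv"
    cnt = bundle.counts.values.copy()
    cnt.insert(0, "gene_symbol", bundle.counts.gene_symbols)
    cnt.to_csv(paths["counts"], sep="\t", index_label="promoter_id",
               float_format="%.10g")

    paths["annotation"] = out / "annotation.tsv"
    bundle.annotations.to_csv(paths["annotation"], sep="\t")

    paths["seeds"] = out / "seeds.tsv"
    bundle.seeds.to_csv(paths["seeds"], sep="\t", index=False)

    truth = bundle.truth
    payload = {
        "config": asdict(truth.config),
        "activities": {
            m: [float(x) for x in truth.activities.loc[m]]
            for m in truth.activities.index
        },
        "interval_labels": list(truth.activities.columns),
        "intercepts": [float(x) for x in truth.intercepts],
        "archetype_labels": truth.archetype_labels,
        "planted_sites": [asdict(s) for s in truth.planted_sites],
        "seed_motifs": truth.seed_motifs,
        "novel_motifs": truth.novel_motifs,
        "baselines_raised": truth.baselines_raised,
    }
    paths["truth"] = out / "truth.json"
    paths["truth"].write_text(json.dumps(payload, indent=1, sort_keys=True))
    return paths
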