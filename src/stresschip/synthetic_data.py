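"""Synthetic genomes, tiling arrays, ChIP tracks, expression time courses
and growth curves with known ground truth.

The generator emulates the study design the analysis assumes: a fission-yeast
-like genome tiled with 50-mer probes every 17 bp on alternating strands,
peak-shaped enrichment at planted motif-bearing promoter sites over Gaussian
log-ratio noise, H2O2 expression time courses at 0/10/30/60/120 min with
induced/repressed/unresponsive genes carrying factor-dependency structure,
and logistic mini-culture growth curves with a stress-induced lag.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import Gene, GeneAnnotation, SiteRecord, write_bed, write_fasta
from .chip_signal import ProbeTrack, write_probe_table
from .expression_response import ExpressionTimeCourse
from .growth_fitness import GrowthCurve, write_growth_csv
from .motif_scan import BASES, PSSM

# An ATF/CREB-class (M26-like) heptamer used as the default planted motif.
_DEFAULT_MOTIF_CONSENSUS = "TGACGTA"


def default_true_pssm(dominant: float = 0.85) -> PSSM:
    w = len(_DEFAULT_MOTIF_CONSENSUS)
    probs = np.full((4, w), (1 - dominant) / 3)
    for j, b in enumerate(_DEFAULT_MOTIF_CONSENSUS):
        probs[BASES.index(b), j] = dominant
    return PSSM(probs)


@dataclass
class SimConfig:
    """Study conditions for the synthetic dataset (see docs/methods.md)."""

    genome_length: int = 170_000          # bp per chromosome
    n_chromosomes: int = 3
    n_genes: int = 240
    frac_divergent: float = 0.4
    frac_noncoding: float = 0.05
    probe_length: int = 50
    probe_step: int = 17
    peak_width: int = 250                 # enrichment-kernel half-width, bp
    n_planted_sites: int = 50
    site_enrichment_log2: float = 2.5
    noise_sd: float = 0.3
    true_pssm: PSSM = field(default_factory=default_true_pssm)
    time_points: tuple[int, ...] = (0, 10, 30, 60, 120)
    n_replicates: int = 3
    induced_fraction: float = 0.15
    repressed_fraction: float = 0.10
    dep_both_fraction: float = 0.5        # of induced genes
    dep_atf1_fraction: float = 0.15
    dep_pcr1_fraction: float = 0.05
    expression_noise_sd: float = 0.25
    min_fold_change: float = 2.5
    growth_K: float = 1.0
    growth_r: float = 0.05                # per minute
    lag_optimal: float = 300.0            # logistic midpoint, min
    lag_stress: float = 120.0             # added midpoint delay under stress
    sensitive_lag_multiplier: float = 3.0
    growth_noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.probe_step >= self.probe_length:
            raise ValueError("probe_step must be smaller than probe_length")
        fr = (self.induced_fraction, self.repressed_fraction)
        if any(not 0 <= f <= 1 for f in fr) or sum(fr) > 1:
            raise ValueError("response fractions must lie in [0,1] and sum <= 1")
        dep = (self.dep_both_fraction, self.dep_atf1_fraction, self.dep_pcr1_fraction)
        if any(not 0 <= f <= 1 for f in dep) or sum(dep) > 1:
            raise ValueError("dependency fractions must lie in [0,1] and sum <= 1")
        if not np.allclose(self.true_pssm.probs.sum(axis=0), 1.0):
            raise ValueError("true_pssm columns must sum to 1")


@dataclass
class PlantedSite:
    chromosome: str
    apex: int
    motif: str
    target_genes: tuple[str, ...]
    arrangement: str            # tandem | divergent
    height: float = 0.0

    def to_record(self, name: str) -> SiteRecord:
        return SiteRecord(self.chromosome, self.apex, self.apex + len(self.motif),
                          name, self.height, ".")


# ------------------------------------------------------------------- genome


def make_genome_annotation(
    config: SimConfig,
) -> tuple[dict[str, str], GeneAnnotation, list[PlantedSite]]:
    """Random genome + non-overlapping gene layout + planted promoter sites.

    Genes are laid out left to right with intergenic gaps; a fraction of
    adjacent pairs is arranged head-to-head (divergent).  Each planted site
    carries one motif instance sampled from ``true_pssm``, sits in the
    intergenic promoter window of its target gene, and records every gene
    the promoter rules should assign it to.
    """
    rng = np.random.default_rng(config.seed)
    n_chrom = config.n_chromosomes
    genes_per_chrom = _split_counts(config.n_genes, n_chrom)

    genome: dict[str, str] = {}
    genes: list[Gene] = []
    gene_layout: list[tuple[Gene, int, int]] = []  # gene, gap_start, gap_end

    gene_counter = 0
    for ci in range(n_chrom):
        chrom = f"chr{ci + 1}"
        seq = rng.choice(list("ACGT"), size=config.genome_length)
        pos = int(rng.integers(300, 800))
        placed = 0
        pending_divergent = False
        while placed < genes_per_chrom[ci]:
            length = int(rng.integers(600, 1400))
            if pos + length + 300 > config.genome_length:
                break
            if pending_divergent:
                strand = "+"
                pending_divergent = False
            elif placed + 1 < genes_per_chrom[ci] and rng.random() < config.frac_divergent:
                strand = "-"
                pending_divergent = True
            else:
                strand = "+" if rng.random() < 0.5 else "-"
            coding = rng.random() >= config.frac_noncoding
            gene_counter += 1
            atg = pos if strand == "+" else pos + length
            tss_off = int(rng.integers(20, 120))
            tss = atg - tss_off if strand == "+" else atg + tss_off
            g = Gene(f"gene{gene_counter:04d}", chrom, pos, pos + length,
                     strand, tss=tss, coding=coding)
            genes.append(g)
            placed += 1
            gap = int(rng.integers(450, 1100))
            gene_layout.append((g, pos + length, pos + length + gap))
            pos = pos + length + gap
        if placed < genes_per_chrom[ci]:
            raise ValueError(
                f"genome_length {config.genome_length} too short for "
                f"{genes_per_chrom[ci]} genes on {chrom}"
            )
        genome[chrom] = "".join(seq)

    annotation = GeneAnnotation(genes)

    # plant sites in the upstream intergenic promoter window of target genes
    sites: list[PlantedSite] = []
    if config.n_planted_sites and config.n_genes:
        candidates = [g for g in genes if g.coding]
        if not candidates:
            raise ValueError("no coding genes to plant sites at")
        rng.shuffle(candidates)
        by_chrom = {c: annotation.on_chromosome(c) for c in annotation.chromosomes()}
        for g in candidates:
            if len(sites) >= config.n_planted_sites:
                break
            site = _plant_site_for(g, by_chrom[g.chromosome], config, rng)
            if site is not None:
                sites.append(site)
        if len(sites) < config.n_planted_sites:
            raise ValueError(
                "could not place the requested number of planted sites; "
                "increase genome_length or n_genes"
            )
        # splice motif sequences into the genome
        for s in sites:
            seq = genome[s.chromosome]
            genome[s.chromosome] = (
                seq[: s.apex] + s.motif + seq[s.apex + len(s.motif):]
            )
    return genome, annotation, sites


def _split_counts(total: int, parts: int) -> list[int]:
    base = total // parts
    out = [base] * parts
    for i in range(total - base * parts):
        out[i] += 1
    return out


def _plant_site_for(
    gene: Gene, chrom_genes: list[Gene], config: SimConfig, rng: np.random.Generator
) -> PlantedSite | None:
    """Place a motif in ``gene``'s upstream intergenic region, 150-600 bp
    from the ATG, and record every promoter-rule target."""
    w = config.true_pssm.width
    offset = int(rng.integers(150, 600))
    if gene.strand == "+":
        apex = gene.atg - offset
        lo_limit = max(
            [g.end for g in chrom_genes if g is not gene and g.end <= gene.atg],
            default=0,
        )
        if apex - lo_limit < 10 or apex < w:
            return None
    else:
        apex = gene.atg + offset
        hi_limit = min(
            [g.start for g in chrom_genes if g is not gene and g.start >= gene.atg],
            default=config.genome_length,
        )
        if hi_limit - apex < 10 + w or apex + w >= config.genome_length:
            return None
    # other genes whose start-codon promoter window contains the apex
    targets = [gene.gene_id]
    arrangement = "tandem"
    for g in chrom_genes:
        if g is gene or not g.coding:
            continue
        if g.strand == "+" and g.atg - 1000 <= apex <= g.atg + 200:
            lo = max([o.end for o in chrom_genes if o is not g and o.end <= g.atg],
                     default=0)
            if apex >= lo:
                targets.append(g.gene_id)
                arrangement = "divergent" if g.strand != gene.strand else arrangement
        elif g.strand == "-" and g.atg - 200 <= apex <= g.atg + 1000:
            hi = min([o.start for o in chrom_genes if o is not g and o.start >= g.atg],
                     default=config.genome_length)
            if apex <= hi:
                targets.append(g.gene_id)
                arrangement = "divergent" if g.strand != gene.strand else arrangement
    motif = "".join(
        rng.choice(list(BASES), p=config.true_pssm.probs[:, j])
        for j in range(w)
    )
    return PlantedSite(gene.chromosome, apex, motif, tuple(sorted(set(targets))),
                       arrangement)


# -------------------------------------------------------------------- arrays


def make_array_design(
    genome: dict[str, str], probe_length: int = 50, probe_step: int = 17
) -> list[ProbeTrack]:
    """Probe skeleton: starts on a ``probe_step`` grid, strands alternating
    probe to probe, values zeroed."""
    if not genome:
        raise ValueError("empty genome")
    tracks = []
    for chrom in sorted(genome):
        clen = len(genome[chrom])
        if probe_length > clen:
            raise ValueError(f"probe_length {probe_length} exceeds {chrom} length")
        starts = np.arange(0, clen - probe_length + 1, probe_step, dtype=np.int64)
        strands = np.where(np.arange(starts.size) % 2 == 0, "+", "-")
        tracks.append(
            ProbeTrack(chrom, starts, np.zeros(starts.size), strands, probe_length)
        )
    return tracks


def simulate_chip_track(
    design: list[ProbeTrack],
    sites: list[PlantedSite],
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> list[ProbeTrack]:
    """Log2-ratio tracks: Gaussian noise plus a triangular kernel of
    half-width ``peak_width`` and height ~N(site_enrichment_log2, 0.2x) at
    each planted site.  Site heights are recorded on the inputs."""
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    out = []
    by_chrom: dict[str, list[PlantedSite]] = {}
    for s in sites:
        by_chrom.setdefault(s.chromosome, []).append(s)
    for track in design:
        clen = int(track.positions[-1]) + track.probe_length
        values = rng.normal(0.0, config.noise_sd, size=len(track))
        centres = track.positions + track.probe_length // 2
        for s in by_chrom.get(track.chromosome, []):
            if not 0 <= s.apex <= clen:
                raise ValueError(f"site apex {s.apex} outside {track.chromosome}")
            if s.height == 0.0:
                s.height = float(
                    max(1.0, rng.normal(config.site_enrichment_log2,
                                        0.2 * config.site_enrichment_log2))
                ) if config.site_enrichment_log2 > 0 else 0.0
            if s.height:
                d = np.abs(centres - s.apex)
                kernel = np.clip(1.0 - d / config.peak_width, 0.0, None)
                values = values + s.height * kernel
        out.append(track.with_values(values))
    return out


# ---------------------------------------------------------------- expression


@dataclass
class ExpressionTruth:
    status: pd.Series               # induced | repressed | unresponsive
    dependency: pd.Series           # both | atf1_only | pcr1_only | independent | NA
    delayed: set[str]               # induced genes with the delayed (indirect) profile
    max_log2_fc: pd.Series


_FAST_SHAPE = {0: 0.0, 10: 0.75, 30: 1.0, 60: 1.0, 120: 0.85}
_DELAYED_SHAPE = {0: 0.0, 10: 0.25, 30: 0.85, 60: 1.0, 120: 0.9}
_ATTENUATION = 0.15   # residual response fraction in a dependent mutant


def simulate_expression(
    annotation: GeneAnnotation,
    config: SimConfig,
    bound_genes: set[str] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, ExpressionTimeCourse], ExpressionTruth]:
    """Time courses for wt, atf1d and pcr1d with planted response structure.

    Induced genes rise to a log-normal maximal fold change (floored at
    ``min_fold_change``) sustained over the 30/60 min points; genes bound by
    the factors (``bound_genes``, defaulting to a random subset) respond
    with the fast profile, unbound induced genes with the delayed one.
    Dependency labels attenuate the response in the matching deletion
    strains.  Replicate noise is Gaussian on the log2 ratios.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 2)
    gene_ids = [g.gene_id for g in annotation if g.coding]
    n = len(gene_ids)
    n_ind = int(round(config.induced_fraction * n))
    n_rep = int(round(config.repressed_fraction * n))
    order = rng.permutation(n)
    induced = [gene_ids[i] for i in order[:n_ind]]
    repressed = [gene_ids[i] for i in order[n_ind : n_ind + n_rep]]
    status = pd.Series("unresponsive", index=pd.Index(gene_ids, name="gene"))
    status.loc[induced] = "induced"
    status.loc[repressed] = "repressed"

    if bound_genes is None:
        bound_genes = set(rng.choice(induced, size=max(1, len(induced) // 2),
                                     replace=False)) if induced else set()
    delayed = {g for g in induced if g not in bound_genes}

    dependency = pd.Series("NA", index=status.index, dtype=object)
    responsive = induced + repressed
    labels = []
    for _ in responsive:
        u = rng.random()
        if u < config.dep_both_fraction:
            labels.append("both")
        elif u < config.dep_both_fraction + config.dep_atf1_fraction:
            labels.append("atf1_only")
        elif u < (config.dep_both_fraction + config.dep_atf1_fraction
                  + config.dep_pcr1_fraction):
            labels.append("pcr1_only")
        else:
            labels.append("independent")
    dependency.loc[responsive] = labels

    fc = np.maximum(config.min_fold_change,
                    np.exp(rng.normal(np.log(6.0), 0.4, size=len(responsive))))
    max_lfc = pd.Series(0.0, index=status.index)
    max_lfc.loc[responsive] = np.log2(fc)
    max_lfc.loc[repressed] *= -1.0

    strains = {"wt": ("none",), "atf1d": ("both", "atf1_only"),
               "pcr1d": ("both", "pcr1_only")}
    courses = {}
    times = tuple(sorted(config.time_points))
    for strain, broken in strains.items():
        cols = {}
        for t in times:
            for r in range(config.n_replicates):
                signal = np.zeros(n)
                for gi, g in enumerate(status.index):
                    if status[g] == "unresponsive" or t == 0:
                        continue
                    shape = _DELAYED_SHAPE if g in delayed else _FAST_SHAPE
                    level = max_lfc[g] * shape.get(t, 1.0)
                    if dependency[g] in broken:
                        level *= _ATTENUATION
                    signal[gi] = level
                noise = rng.normal(0.0, config.expression_noise_sd, size=n)
                cols[(t, r)] = signal + noise
        df = pd.DataFrame(cols, index=status.index)
        df.columns = pd.MultiIndex.from_tuples(df.columns,
                                               names=["time_min", "replicate"])
        courses[strain] = ExpressionTimeCourse(df, strain)
    truth = ExpressionTruth(status, dependency, delayed, max_lfc)
    return courses, truth


# -------------------------------------------------------------------- growth


def simulate_growth_curves(
    strains: dict[str, bool],
    config: SimConfig,
    rng: np.random.Generator | None = None,
    t_max: float = 900.0,
    t_step: float = 15.0,
) -> list[GrowthCurve]:
    """Logistic OD(t) = K/(1+exp(-r(t-t0))) per strain/condition/replicate.

    ``strains`` maps strain id -> sensitive flag; stress shifts the
    midpoint by ``lag_stress`` (times ``sensitive_lag_multiplier`` for
    sensitive strains) and Gaussian measurement noise is added.
    """
    if config.n_replicates < 3:
        raise ValueError("need >= 3 replicates")
    rng = rng if rng is not None else np.random.default_rng(config.seed + 3)
    t = np.arange(0.0, t_max + t_step, t_step)
    curves = []
    for strain, sensitive in sorted(strains.items()):
        lag = config.lag_stress * (config.sensitive_lag_multiplier if sensitive else 1.0)
        for condition, t0 in (("optimal", config.lag_optimal),
                              ("stress", config.lag_optimal + lag)):
            for r in range(config.n_replicates):
                od = config.growth_K / (1.0 + np.exp(-config.growth_r * (t - t0)))
                od = np.clip(od + rng.normal(0, config.growth_noise_sd, t.size), 0, None)
                curves.append(GrowthCurve(strain, condition, r, t.copy(), od))
    return curves


# ------------------------------------------------------------------- bundle


@dataclass
class SyntheticDataset:
    config: SimConfig
    genome: dict[str, str]
    annotation: GeneAnnotation
    planted_sites: list[PlantedSite]
    chip_tracks: list[ProbeTrack]
    expression: dict[str, ExpressionTimeCourse]
    expression_truth: ExpressionTruth
    growth_curves: list[GrowthCurve]
    sensitive_strains: set[str]


def simulate_all(config: SimConfig) -> SyntheticDataset:
    """Run every generator with seeds derived from ``config.seed``."""
    genome, annotation, sites = make_genome_annotation(config)
    design = make_array_design(genome, config.probe_length, config.probe_step)
    tracks = simulate_chip_track(design, sites, config)
    bound = {g for s in sites for g in s.target_genes}
    expr, truth = simulate_expression(annotation, config, bound_genes=bound or None)
    rng = np.random.default_rng(config.seed + 3)
    induced = [g for g in truth.status.index if truth.status[g] == "induced"]
    n_sens = min(3, len(induced))
    sensitive = set(induced[:n_sens])
    strain_map = {"wt": False}
    for g in induced[: 6]:
        strain_map[f"{g}d"] = g in sensitive
    growth = simulate_growth_curves(strain_map, config, rng)
    return SyntheticDataset(config, genome, annotation, sites, tracks, expr,
                            truth, growth, {f"{g}d" for g in sensitive})


def write_dataset(ds: SyntheticDataset, outdir: str) -> dict[str, str]:
    """Write the full dataset as plain-text files; returns {name: path}."""
    os.makedirs(outdir, exist_ok=True)
    paths = {}
    p = os.path.join(outdir, "genome.fasta")
    write_fasta(ds.genome, p)
    paths["genome"] = p
    p = os.path.join(outdir, "annotation.gff3")
    ds.annotation.to_gff3(p)
    paths["annotation"] = p
    p = os.path.join(outdir, "planted_sites.bed")
    write_bed([s.to_record(f"site{i:03d}") for i, s in enumerate(ds.planted_sites)], p)
    paths["planted_sites"] = p
    p = os.path.join(outdir, "chip_track.tsv")
    write_probe_table(ds.chip_tracks, p)
    paths["chip_track"] = p
    for strain, course in ds.expression.items():
        p = os.path.join(outdir, f"expression_{strain}.tsv")
        course.to_table(p)
        paths[f"expression_{strain}"] = p
    p = os.path.join(outdir, "growth_curves.csv")
    write_growth_csv(ds.growth_curves, p)
    paths["growth"] = p
    return paths
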