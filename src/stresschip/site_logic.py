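"""Binding-site comparison, major/minor classification and promoter assignment.

Two binding sites overlap when their apexes lie within 200 bp on the same
chromosome.  A *major* site is one recovered in both of two compared
experiments (before/after stress for the transcription factors, two repeats
for the kinase); everything else is *minor*.  Sites are mapped to the genes
they probably regulate through two promoter definitions: up to 1 kb of
upstream intergenic sequence through 200 bp downstream of the start codon,
or 150 bp either side of the transcription start site.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .annotation import Gene, GeneAnnotation
from .chip_signal import Occupancy


@dataclass
class SiteComparisonParams:
    max_overlap_distance: int = 200
    overlap_strict: bool = False        # True: "< 200 bp", False: "<= 200 bp"
    promoter_upstream_orf: int = 1000
    promoter_downstream_orf: int = 200
    promoter_upstream_tss: int = 150
    promoter_downstream_tss: int = 150

    def __post_init__(self) -> None:
        for name in ("max_overlap_distance", "promoter_upstream_orf",
                     "promoter_downstream_orf", "promoter_upstream_tss",
                     "promoter_downstream_tss"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    def _within(self, d: int) -> bool:
        return d < self.max_overlap_distance if self.overlap_strict \
            else d <= self.max_overlap_distance


@dataclass
class ClassifiedSite:
    site: Occupancy
    site_class: str                     # "major" | "minor"
    factors: tuple[str, ...] = ()
    genes: tuple[str, ...] = ()
    intergenic_class: str = ""          # "tandem" | "divergent" | "intragenic"
    partner_level: float | None = None  # matched site's level, if major

    @property
    def mean_level(self) -> float:
        if self.partner_level is None:
            return self.site.level
        return 0.5 * (self.site.level + self.partner_level)


def overlap_sites(
    list_a: list[Occupancy],
    list_b: list[Occupancy],
    params: SiteComparisonParams = SiteComparisonParams(),
) -> tuple[list[tuple[Occupancy, Occupancy]], list[Occupancy], list[Occupancy]]:
    """Greedy nearest-apex matching of two site lists.

    Candidate pairs on the same chromosome within the overlap distance are
    matched in order of increasing apex distance (leftmost pair on ties);
    each site participates in at most one pair.  Returns (pairs,
    unmatched_a, unmatched_b); swapping the inputs mirrors the pairing.
    """
    candidates = []
    for i, a in enumerate(list_a):
        for j, b in enumerate(list_b):
            if a.chromosome != b.chromosome:
                continue
            d = abs(a.apex - b.apex)
            if params._within(d):
                candidates.append((d, min(a.apex, b.apex), i, j))
    candidates.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs = []
    for _, _, i, j in candidates:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pairs.append((list_a[i], list_b[j]))
    unmatched_a = [a for i, a in enumerate(list_a) if i not in used_a]
    unmatched_b = [b for j, b in enumerate(list_b) if j not in used_b]
    return pairs, unmatched_a, unmatched_b


def classify_major(
    sites_pre: list[Occupancy],
    sites_post: list[Occupancy],
    params: SiteComparisonParams = SiteComparisonParams(),
) -> tuple[list[ClassifiedSite], list[ClassifiedSite], dict]:
    """Label sites found in both conditions as major, the rest minor.

    Returns (classified_pre, classified_post, summary) where the summary
    carries the per-class median enrichment levels.
    """
    pairs, un_pre, un_post = overlap_sites(sites_pre, sites_post, params)
    cls_pre = [ClassifiedSite(a, "major", partner_level=b.level) for a, b in pairs]
    cls_pre += [ClassifiedSite(a, "minor") for a in un_pre]
    cls_post = [ClassifiedSite(b, "major", partner_level=a.level) for a, b in pairs]
    cls_post += [ClassifiedSite(b, "minor") for b in un_post]
    major_levels = [c.site.level for c in cls_pre + cls_post if c.site_class == "major"]
    minor_levels = [c.site.level for c in cls_pre + cls_post if c.site_class == "minor"]
    summary = {
        "n_major_pairs": len(pairs),
        "median_major_level": float(np.median(major_levels)) if major_levels else float("nan"),
        "median_minor_level": float(np.median(minor_levels)) if minor_levels else float("nan"),
    }
    return cls_pre, cls_post, summary


def common_major_sites(
    major_a: list[ClassifiedSite],
    major_b: list[ClassifiedSite],
    params: SiteComparisonParams = SiteComparisonParams(),
    factor_a: str = "factor_a",
    factor_b: str = "factor_b",
) -> list[ClassifiedSite]:
    """Merge two factors' major site lists into common sites.

    Overlapping major:major pairs are fused to a single site at the apex
    midpoint, carrying each factor's level and their mean.
    """
    occ_a = [c.site for c in major_a]
    occ_b = [c.site for c in major_b]
    pairs, _, _ = overlap_sites(occ_a, occ_b, params)
    merged = []
    for a, b in pairs:
        mid = (a.apex + b.apex) // 2
        site = Occupancy(
            chromosome=a.chromosome,
            start_index=min(a.start_index, b.start_index),
            end_index=max(a.end_index, b.end_index),
            start_bp=min(a.start_bp, b.start_bp),
            end_bp=max(a.end_bp, b.end_bp),
            apex=mid,
            level=0.5 * (a.level + b.level),
            n_probes=max(a.n_probes, b.n_probes),
            label=f"{factor_a}:{factor_b}",
        )
        merged.append(
            ClassifiedSite(site, "major", factors=(factor_a, factor_b),
                           partner_level=None)
        )
    return merged


# --------------------------------------------------------------- gene mapping


def _promoter_window_orf(gene: Gene, neighbours: list[Gene],
                         params: SiteComparisonParams) -> tuple[int, int] | None:
    """[ATG - upstream, ATG + downstream] in reading orientation, with the
    upstream arm truncated where it leaves the intergenic region."""
    up = params.promoter_upstream_orf
    down = params.promoter_downstream_orf
    if gene.strand == "+":
        lo = gene.atg - up
        for g in neighbours:
            if g is gene:
                continue
            if g.end <= gene.atg:
                lo = max(lo, g.end)
        return lo, gene.atg + down
    lo = gene.atg
    hi = gene.atg + up
    for g in neighbours:
        if g is gene:
            continue
        if g.start >= gene.atg:
            hi = min(hi, g.start)
    return lo - down, hi


def _promoter_window_tss(gene: Gene, params: SiteComparisonParams) -> tuple[int, int] | None:
    if gene.tss is None:
        return None
    if gene.strand == "+":
        return gene.tss - params.promoter_upstream_tss, gene.tss + params.promoter_downstream_tss
    return gene.tss - params.promoter_downstream_tss, gene.tss + params.promoter_upstream_tss


def assign_promoters(
    sites: list[Occupancy],
    annotation: GeneAnnotation,
    params: SiteComparisonParams = SiteComparisonParams(),
    rule: str = "orf",
) -> dict[int, list[str]]:
    """Map each site (by list index) to the coding gene(s) whose promoter
    contains its apex.

    ``rule``: "orf" uses the start-codon window, "tss" the TSS window and
    "either" their union.  A site between two divergent genes may map to
    both; non-coding genes are never targets but truncate their neighbours'
    upstream intergenic span.
    """
    if rule not in ("orf", "tss", "either"):
        raise ValueError(f"unknown rule {rule!r}")
    assignments: dict[int, list[str]] = {}
    for idx, site in enumerate(sites):
        genes = annotation.on_chromosome(site.chromosome)
        hits = []
        for g in genes:
            if not g.coding:
                continue
            windows = []
            if rule in ("orf", "either"):
                w = _promoter_window_orf(g, genes, params)
                if w:
                    windows.append(w)
            if rule in ("tss", "either"):
                w = _promoter_window_tss(g, params)
                if w:
                    windows.append(w)
            if any(lo <= site.apex <= hi for lo, hi in windows):
                hits.append(g.gene_id)
        assignments[idx] = hits
    return assignments


def classify_intergenic(site: Occupancy, annotation: GeneAnnotation) -> str:
    """Classify a site as intragenic, divergent-intergenic or tandem.

    Divergent means the flanking genes transcribe away from the site on both
    sides (head-to-head promoters face it); co-oriented and tail-to-tail
    neighbourhoods are folded into tandem.
    """
    genes = annotation.on_chromosome(site.chromosome)
    for g in genes:
        if g.start <= site.apex < g.end:
            return "intragenic"
    left = [g for g in genes if g.end <= site.apex]
    right = [g for g in genes if g.start > site.apex]
    left_g = max(left, key=lambda g: g.end) if left else None
    right_g = min(right, key=lambda g: g.start) if right else None
    if left_g is None or right_g is None:
        import warnings
        warnings.warn("site beyond the outermost gene; classified by one flank")
        single = left_g or right_g
        if single is None:
            return "tandem"
        # a lone '+' right / '-' left gene points away on that side only
        return "tandem"
    if left_g.strand == "-" and right_g.strand == "+":
        return "divergent"
    return "tandem"
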