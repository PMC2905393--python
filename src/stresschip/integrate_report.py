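"""Integration of the binding, expression and fitness layers.

Cross-tabulates bound vs responsive gene sets with hypergeometric
enrichment statistics, ranks genes by mean factor enrichment, computes the
kinase-recruitment dependency ratio, and writes the final report tables.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import SiteRecord, write_bed


def rank_by_mean_enrichment(levels: pd.DataFrame) -> pd.Series:
    """Dense descending ranks of the row-mean enrichment level.

    Ties share a rank and the next distinct value takes the previous rank
    plus one (so duplicated rank 9 is followed by 10, not 11).
    """
    means = levels.mean(axis=1)
    if not np.all(np.isfinite(means)):
        raise ValueError("non-finite enrichment levels")
    ranks = means.rank(method="dense", ascending=False).astype(int)
    ranks.name = "rank"
    return ranks


@dataclass
class GeneSetCrossTable:
    k: int          # genes in both sets
    K: int          # size of set A (the group tested for enrichment)
    n: int          # size of set B (e.g. all bound genes)
    N: int          # gene universe
    observed: float
    expected: float
    fold: float
    p_value: float

    def __post_init__(self) -> None:
        if self.k > min(self.K, self.n) or self.N < max(self.K, self.n):
            raise ValueError("inconsistent cross-table counts")


def fold_enrichment(
    k: int, K: int, n: int, N: int, alternative: str = "two-sided"
) -> GeneSetCrossTable:
    """Observed fraction k/K against the chance level n/N, with an exact
    hypergeometric p-value.

    Two-sided p sums all outcomes whose probability does not exceed the
    observed outcome's (minimum-likelihood convention); "greater"/"less"
    give the one-sided tails.
    """
    if k > min(K, n) or N < max(K, n) or min(k, K, n, N) < 0:
        raise ValueError("inconsistent counts")
    if n == 0 or N == 0 or K == 0:
        raise ValueError("expected fraction undefined (empty set)")
    observed = k / K
    expected = n / N
    rv = stats.hypergeom(N, n, K)
    if alternative == "greater":
        p = float(rv.sf(k - 1))
    elif alternative == "less":
        p = float(rv.cdf(k))
    elif alternative == "two-sided":
        support = np.arange(max(0, K + n - N), min(K, n) + 1)
        pmf = rv.pmf(support)
        p = float(pmf[pmf <= rv.pmf(k) * (1 + 1e-7)].sum())
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return GeneSetCrossTable(k, K, n, N, observed, expected,
                             observed / expected, min(p, 1.0))


@dataclass
class DependencyRatioRecord:
    gene: str
    wt_level_log2: float
    mutant_levels_log2: tuple[float, ...]
    ratio: float
    dependent: bool


def sty1_dependency_ratio(
    wt_levels_log2: np.ndarray,
    mutant_levels_log2: np.ndarray,
    gene: str = "",
    cutoff: float = 0.6,
) -> DependencyRatioRecord:
    """Mutant-to-wild-type ratio of kinase recruitment on the linear scale.

    Levels are stored in log2; both the wild-type repeats and the per-mutant
    averages are de-logged before averaging, because the published ratios
    are linear-scale quotients.  Dependent iff ratio < cutoff (strict).
    """
    wt = np.asarray(wt_levels_log2, dtype=float)
    mut = np.asarray(mutant_levels_log2, dtype=float)
    wt_mean = float(np.mean(2.0 ** wt))
    if wt_mean <= 0:
        raise ValueError("wild-type mean level must be positive")
    mut_mean = float(np.mean(2.0 ** mut))
    ratio = mut_mean / wt_mean
    return DependencyRatioRecord(
        gene, float(np.mean(wt)), tuple(mut.tolist()), ratio, ratio < cutoff
    )


def cross_classify(
    bound_major: set[str],
    bound_minor: set[str],
    responsive: pd.Series,
    sensitive: dict[str, bool] | None = None,
) -> pd.DataFrame:
    """Per-gene report rows: binding class x response status x sensitivity.

    ``responsive`` (index = the full gene universe) supplies the status
    column; every universe gene appears exactly once and the marginal counts
    reproduce the inputs.
    """
    universe = set(responsive.index)
    strays = (bound_major | bound_minor) - universe
    if strays:
        raise ValueError(f"bound genes outside the universe: {sorted(strays)[:5]}")
    rows = []
    for g in responsive.index:
        if g in bound_major:
            binding = "bound_major"
        elif g in bound_minor:
            binding = "bound_minor"
        else:
            binding = "unbound"
        rows.append(
            {"gene": g, "binding": binding, "status": responsive[g],
             "sensitive": bool(sensitive.get(g, False)) if sensitive else False}
        )
    return pd.DataFrame(rows).set_index("gene")


def cross_table_counts(report: pd.DataFrame) -> pd.DataFrame:
    return pd.crosstab(report["binding"], report["status"])


def build_report(
    outdir: str,
    sites: list[SiteRecord] | None = None,
    gene_report: pd.DataFrame | None = None,
    fitness: pd.DataFrame | None = None,
    ranking: pd.Series | None = None,
    extra_tables: dict[str, pd.DataFrame] | None = None,
) -> dict[str, str]:
    """Write the deterministic report file set; returns {name: path}.

    Raises when a required stage output is missing.
    """
    missing = [name for name, obj in
               [("sites", sites), ("gene_report", gene_report)] if obj is None]
    if missing:
        raise ValueError(f"stage missing: {', '.join(missing)}")
    os.makedirs(outdir, exist_ok=True)
    paths: dict[str, str] = {}

    bed = os.path.join(outdir, "binding_sites.bed")
    write_bed(sites, bed)
    paths["sites_bed"] = bed

    genes_tsv = os.path.join(outdir, "gene_report.tsv")
    gene_report.sort_index().to_csv(genes_tsv, sep="\t")
    paths["gene_report"] = genes_tsv

    if fitness is not None:
        p = os.path.join(outdir, "fitness.tsv")
        fitness.sort_index().to_csv(p, sep="\t")
        paths["fitness"] = p
    if ranking is not None:
        p = os.path.join(outdir, "ranking.tsv")
        ranking.sort_index().to_csv(p, sep="\t")
        paths["ranking"] = p
    for name, df in (extra_tables or {}).items():
        p = os.path.join(outdir, f"{name}.tsv")
        df.to_csv(p, sep="\t")
        paths[name] = p

    counts = cross_table_counts(gene_report)
    summary = os.path.join(outdir, "summary.txt")
    with open(summary, "w") as fh:
        fh.write(f"binding sites\t{len(sites)}\n")
        fh.write(f"genes\t{len(gene_report)}\n")
        for binding in counts.index:
            for status in counts.columns:
                fh.write(f"{binding}:{status}\t{int(counts.loc[binding, status])}\n")
        if "sensitive" in gene_report:
            fh.write(f"sensitive genes\t{int(gene_report['sensitive'].sum())}\n")
    paths["summary"] = summary
    return paths
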