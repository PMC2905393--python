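"""Stress-response expression classification.

Genes are called H2O2-responsive when their transcript level changes more
than 2-fold at a permutation FDR below threshold in at least two consecutive
post-treatment time points, using a SAM-style moderated statistic per time
point (treated replicates vs the t=0 reference replicates).  Dependency on a
transcription factor is the same rule applied to the mutant-vs-wild-type
contrast of 0-min-normalised levels.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class ResponseParams:
    fold_change_min: float = 2.0
    fdr_max: float = 0.05
    min_consecutive_timepoints: int = 2
    post_treatment_timepoints: tuple[int, ...] = (10, 30, 60, 120)
    n_permutations: int = 100
    seed: int = 0
    s0_percentile: float = 50.0

    def __post_init__(self) -> None:
        if self.fold_change_min <= 1:
            raise ValueError("fold_change_min must exceed 1")
        if not 0 < self.fdr_max < 1:
            raise ValueError("fdr_max must lie in (0,1)")
        if self.min_consecutive_timepoints < 1:
            raise ValueError("min_consecutive_timepoints must be >= 1")


class ExpressionTimeCourse:
    """Per-gene log2 ratios vs t=0 over time points x replicates, one strain.

    Wraps a DataFrame indexed by gene with MultiIndex columns
    (time_min, replicate).
    """

    def __init__(self, data: pd.DataFrame, strain: str = "wt"):
        if not isinstance(data.columns, pd.MultiIndex):
            raise ValueError("columns must be a (time_min, replicate) MultiIndex")
        self.data = data.sort_index(axis=1)
        self.strain = strain

    @property
    def genes(self) -> pd.Index:
        return self.data.index

    @property
    def timepoints(self) -> list[int]:
        return sorted({int(t) for t in self.data.columns.get_level_values(0)})

    def replicates_at(self, time: int) -> np.ndarray:
        """Gene x replicate matrix at one time point."""
        return self.data[time].to_numpy()

    def mean_profile(self, genes=None) -> pd.Series:
        """Replicate-mean log2 ratio per time point, averaged over ``genes``."""
        df = self.data if genes is None else self.data.loc[genes]
        by_time = df.T.groupby(level=0).mean().T  # replicate mean per timepoint
        return by_time.mean(axis=0)

    def to_table(self, path: str) -> None:
        out = self.data.copy()
        out.columns = [f"{self.strain}:t{t}:r{r}" for t, r in out.columns]
        out.to_csv(path, sep="\t", index_label="gene")

    @classmethod
    def from_table(cls, path: str, strain: str) -> "ExpressionTimeCourse":
        df = pd.read_csv(path, sep="\t", index_col="gene")
        cols = []
        for c in df.columns:
            s, t, r = c.split(":")
            cols.append((int(t[1:]), int(r[1:])))
        df.columns = pd.MultiIndex.from_tuples(cols, names=["time_min", "replicate"])
        return cls(df, strain)


@dataclass
class ResponseCall:
    gene: str
    status: str                    # induced | repressed | unresponsive
    dependency: str = "NA"         # both | atf1_specific | pcr1_specific | independent | NA
    rank: int | None = None
    mean_induction: float = float("nan")


# ------------------------------------------------------------- SAM machinery


def pooled_se(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pooled standard error of the mean difference, per row (gene)."""
    na, nb = a.shape[1], b.shape[1]
    va = a.var(axis=1, ddof=1)
    vb = b.var(axis=1, ddof=1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    return np.sqrt(sp2 * (1.0 / na + 1.0 / nb))


def sam_s0(s: np.ndarray, percentile: float = 50.0) -> float:
    """The exchangeability (fudge) constant: a percentile of the per-gene SE."""
    return float(np.percentile(s, percentile))


def sam_d(a: np.ndarray, b: np.ndarray, s0: float) -> np.ndarray:
    """Moderated difference statistic d = (mean_a - mean_b) / (s + s0)."""
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("need >= 2 replicates per group")
    diff = a.mean(axis=1) - b.mean(axis=1)
    denom = pooled_se(a, b) + s0
    # a zero denominator only arises for exactly constant data; call it null
    return np.divide(diff, denom, out=np.zeros_like(diff), where=denom > 0)


def _label_permutations(na: int, nb: int, n_max: int, rng: np.random.Generator):
    """Distinct relabelings of the pooled columns into groups of size na/nb.

    All of them when few exist, otherwise a seeded sample.
    """
    cols = list(range(na + nb))
    all_combos = list(itertools.combinations(cols, na))
    if len(all_combos) <= n_max:
        return all_combos
    pick = rng.choice(len(all_combos), size=n_max, replace=False)
    return [all_combos[i] for i in pick]


def permuted_d_matrix(
    a: np.ndarray, b: np.ndarray, s0: float, n_permutations: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """d statistics under group-label permutation; shape (n_perm, n_genes)."""
    pooled = np.hstack([a, b])
    na = a.shape[1]
    combos = _label_permutations(na, b.shape[1], n_permutations, rng)
    rows = []
    for combo in combos:
        mask = np.zeros(pooled.shape[1], dtype=bool)
        mask[list(combo)] = True
        rows.append(sam_d(pooled[:, mask], pooled[:, ~mask], s0))
    return np.vstack(rows)


def permutation_fdr(d: np.ndarray, d_perm: np.ndarray) -> np.ndarray:
    """Per-gene q-values from the permutation null.

    FDR(t) = median over permutations of #{|d*| >= t} / #{|d| >= t},
    evaluated at t = |d_gene|, clipped to [0,1] and made monotone (q
    nonincreasing in |d|) by a running minimum taken from the smallest |d|
    upward, as in the step-up convention.  An empty numerator and
    denominator (t above max|d|) is FDR 0 by convention.
    """
    absd = np.abs(np.asarray(d, dtype=float))
    absperm = np.abs(d_perm)
    order = np.argsort(absd, kind="stable")  # ascending |d|
    q = np.empty_like(absd)
    running = np.inf
    for gi in order:
        t = absd[gi]
        observed = int(np.sum(absd >= t))
        if observed == 0:
            fdr = 0.0
        else:
            null = float(np.median(np.sum(absperm >= t, axis=1)))
            fdr = min(null / observed, 1.0)
        running = min(running, fdr)
        q[gi] = running
    return q


# ------------------------------------------------------------------- calling


def _consecutive_hit(flags: np.ndarray, k: int) -> bool:
    run = 0
    for f in flags:
        run = run + 1 if f else 0
        if run >= k:
            return True
    return False


def _per_timepoint_significance(
    course_a: ExpressionTimeCourse,
    course_b: ExpressionTimeCourse,
    params: ResponseParams,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene mean log2 difference and q-value at each post time point,
    contrasting strain/time a against b at the same time points."""
    rng = np.random.default_rng(params.seed)
    diffs, qs = {}, {}
    for t in params.post_treatment_timepoints:
        a = course_a.replicates_at(t)
        b = course_b.replicates_at(t)
        s = pooled_se(a, b)
        s0 = sam_s0(s, params.s0_percentile)
        d = sam_d(a, b, s0)
        d_perm = permuted_d_matrix(a, b, s0, params.n_permutations, rng)
        qs[t] = permutation_fdr(d, d_perm)
        diffs[t] = a.mean(axis=1) - b.mean(axis=1)
    idx = course_a.genes
    return (pd.DataFrame(diffs, index=idx), pd.DataFrame(qs, index=idx))


def call_responsive(
    wt: ExpressionTimeCourse, params: ResponseParams = ResponseParams()
) -> pd.Series:
    """Induced / repressed / unresponsive per gene.

    A gene is induced (repressed) when >= ``min_consecutive_timepoints``
    consecutive post-treatment time points each show fold change above
    ``fold_change_min`` (below its reciprocal) at q < ``fdr_max``, in a
    consistent direction.  Values are log2 ratios vs t=0, so the treated
    replicates are contrasted against the t=0 replicates.
    """
    missing = [t for t in params.post_treatment_timepoints if t not in wt.timepoints]
    if 0 not in wt.timepoints:
        missing = [0] + missing
    if missing:
        raise ValueError(f"missing time points: {missing}")
    ref = _reference_course(wt, params)
    diffs, qs = _per_timepoint_significance(wt, ref, params)
    lfc_min = np.log2(params.fold_change_min)
    up = (diffs.to_numpy() > lfc_min) & (qs.to_numpy() < params.fdr_max)
    down = (diffs.to_numpy() < -lfc_min) & (qs.to_numpy() < params.fdr_max)
    k = params.min_consecutive_timepoints
    status = []
    for i in range(len(wt.genes)):
        if _consecutive_hit(up[i], k):
            status.append("induced")
        elif _consecutive_hit(down[i], k):
            status.append("repressed")
        else:
            status.append("unresponsive")
    return pd.Series(status, index=wt.genes, name="status")


def _reference_course(
    course: ExpressionTimeCourse, params: ResponseParams
) -> ExpressionTimeCourse:
    """The t=0 replicates replicated across the post-treatment grid."""
    zero = course.data[0]
    blocks = {}
    for t in params.post_treatment_timepoints:
        for r in zero.columns:
            blocks[(t, r)] = zero[r]
    df = pd.DataFrame(blocks)
    df.columns = pd.MultiIndex.from_tuples(df.columns, names=["time_min", "replicate"])
    return ExpressionTimeCourse(df, strain=course.strain + ":t0")


def call_dependent(
    mutant: ExpressionTimeCourse,
    wt: ExpressionTimeCourse,
    params: ResponseParams = ResponseParams(),
) -> set[str]:
    """Genes whose 0-min-normalised response differs from wild type under
    the same fold-change / FDR / consecutive-timepoint rule."""
    if not mutant.genes.equals(wt.genes):
        raise ValueError("mutant and wild-type matrices must share genes")
    if mutant.timepoints != wt.timepoints:
        raise ValueError("mutant and wild-type matrices must share time points")
    diffs, qs = _per_timepoint_significance(mutant, wt, params)
    lfc_min = np.log2(params.fold_change_min)
    hit = (np.abs(diffs.to_numpy()) > lfc_min) & (qs.to_numpy() < params.fdr_max)
    k = params.min_consecutive_timepoints
    return {
        g for i, g in enumerate(wt.genes) if _consecutive_hit(hit[i], k)
    }


def classify_dependency(
    atf1_set: set[str], pcr1_set: set[str], responsive: list[str] | pd.Index
) -> pd.Series:
    """both / atf1_specific / pcr1_specific / independent per responsive gene."""
    labels = {}
    for g in responsive:
        in_a, in_p = g in atf1_set, g in pcr1_set
        if in_a and in_p:
            labels[g] = "both"
        elif in_a:
            labels[g] = "atf1_specific"
        elif in_p:
            labels[g] = "pcr1_specific"
        else:
            labels[g] = "independent"
    return pd.Series(labels, name="dependency", dtype=object)


def time_to_fold(
    profile: pd.Series | dict[int, float], fold: float = 4.0
) -> float:
    """First time (minutes) the mean log2 profile crosses log2(fold), by
    linear interpolation between sampled time points; inf if never."""
    if isinstance(profile, dict):
        profile = pd.Series(profile)
    profile = profile.sort_index()
    target = np.log2(fold)
    times = profile.index.to_numpy(dtype=float)
    vals = profile.to_numpy(dtype=float)
    for i in range(len(vals)):
        if vals[i] >= target:
            if i == 0:
                return float(times[0])
            t0, t1 = times[i - 1], times[i]
            v0, v1 = vals[i - 1], vals[i]
            return float(t0 + (target - v0) * (t1 - t0) / (v1 - v0))
    return float("inf")


def response_rank(
    responsive_genes: list[str],
    wt: ExpressionTimeCourse,
    rank_timepoints: tuple[int, ...] = (30, 60, 120),
) -> pd.Series:
    """Dense descending ranks of the mean induction level over the late
    time points across replicates; ties share a rank."""
    for t in rank_timepoints:
        if t not in wt.timepoints:
            raise ValueError(f"time point {t} absent from matrix")
    sub = wt.data.loc[list(responsive_genes), list(rank_timepoints)]
    means = sub.mean(axis=1)
    ranks = means.rank(method="dense", ascending=False).astype(int)
    ranks.name = "response_rank"
    return ranks
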