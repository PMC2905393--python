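"""End-to-end synthetic run: generate, analyse, and score recovery.

Ties the generator to every analysis stage and measures how well each
stage recovers the planted ground truth; this is the package's built-in
validation experiment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import chip_signal, expression_response, growth_fitness, motif_scan, site_logic
from .annotation import SiteRecord
from .chip_signal import SERParams
from .expression_response import ResponseParams
from .integrate_report import build_report, cross_classify
from .motif_scan import MotifParams
from .site_logic import SiteComparisonParams
from .synthetic_data import SimConfig, SyntheticDataset, simulate_all


@dataclass
class PipelineResult:
    dataset: SyntheticDataset
    called_sites: list
    metrics: dict[str, float] = field(default_factory=dict)
    gene_report: pd.DataFrame | None = None


def match_to_truth(called, planted, max_distance: int = 100):
    """Pair called sites with planted sites by apex distance."""
    pairs = []
    used = set()
    for p_idx, p in enumerate(planted):
        best = None
        for c_idx, c in enumerate(called):
            if c_idx in used or c.chromosome != p.chromosome:
                continue
            d = abs(c.apex - p.apex)
            if d <= max_distance and (best is None or d < best[0]):
                best = (d, c_idx)
        if best is not None:
            used.add(best[1])
            pairs.append((p_idx, best[1], best[0]))
    return pairs


def run_synthetic_analysis(
    config: SimConfig | None = None,
    ser_params: SERParams = SERParams(),
    site_params: SiteComparisonParams = SiteComparisonParams(),
    response_params: ResponseParams | None = None,
    motif_params: MotifParams | None = None,
    n_fdr_permutations: int = 50,
    outdir: str | None = None,
) -> PipelineResult:
    config = config or SimConfig()
    response_params = response_params or ResponseParams(seed=config.seed + 11)
    motif_params = motif_params or MotifParams(seed=config.seed + 12)
    ds = simulate_all(config)
    metrics: dict[str, float] = {}

    # ---- occupancy calling and recovery against the planted truth
    called = chip_signal.call_sers_genome(ds.chip_tracks, ser_params)
    pairs = match_to_truth(called, ds.planted_sites, max_distance=100)
    n_planted = len(ds.planted_sites)
    metrics["n_called_sites"] = float(len(called))
    metrics["site_recovery_fraction"] = len(pairs) / n_planted if n_planted else float("nan")
    metrics["apex_mean_abs_error_bp"] = (
        float(np.mean([d for _, _, d in pairs])) if pairs else float("nan")
    )
    metrics["chip_fdr"] = chip_signal.estimate_fdr(
        ds.chip_tracks, ser_params, n_perm=n_fdr_permutations, seed=config.seed + 13
    )

    # ---- promoter assignment accuracy on recovered sites
    assignments = site_logic.assign_promoters(called, ds.annotation, site_params, "orf")
    correct = 0
    for p_idx, c_idx, _ in pairs:
        truth_targets = set(ds.planted_sites[p_idx].target_genes)
        if truth_targets & set(assignments.get(c_idx, [])):
            correct += 1
    metrics["promoter_assignment_fraction"] = correct / len(pairs) if pairs else float("nan")

    # ---- motif recovery from apex-centred sequences of the called sites
    ranked = sorted(called, key=lambda c: -c.level)
    seqs = motif_scan.extract_apex_sequences(ranked, ds.genome, motif_params.apex_window)
    n_seed = min(motif_params.n_seed_sequences, len(seqs))
    pssm = motif_scan.discover_pssm(
        seqs[:n_seed], seqs[n_seed : n_seed + motif_params.n_refine_sequences],
        motif_params,
    )
    metrics["motif_mean_column_tv"] = mean_column_tv(pssm, config.true_pssm)

    bound_scores = np.array([motif_scan.pssm_score(pssm, s) for s in seqs])
    bound_gene_set = {g for s in ds.planted_sites for g in s.target_genes}
    # size-matched to the apex window so score maxima are comparable
    promoters = motif_scan.promoter_sequences(
        ds.annotation, ds.genome, upstream=motif_params.apex_window
    )
    unbound = [v for k, v in promoters.items() if k not in bound_gene_set]
    rng = np.random.default_rng(config.seed + 14)
    if len(unbound) > len(seqs):
        idx = rng.choice(len(unbound), size=len(seqs), replace=False)
        unbound = [unbound[i] for i in idx]
    unbound_scores = np.array([motif_scan.pssm_score(pssm, s) for s in unbound])
    _, _, auc = motif_scan.roc_auc(bound_scores, unbound_scores)
    metrics["motif_roc_auc"] = auc

    # ---- expression responsiveness / dependency recovery
    wt = ds.expression["wt"]
    status = expression_response.call_responsive(wt, response_params)
    truth_status = ds.expression_truth.status
    resp_true = truth_status != "unresponsive"
    resp_called = status != "unresponsive"
    tp = int((resp_true & resp_called).sum())
    metrics["responsive_sensitivity"] = tp / int(resp_true.sum()) if resp_true.any() else float("nan")
    tn = int((~resp_true & ~resp_called).sum())
    metrics["responsive_specificity"] = (
        tn / int((~resp_true).sum()) if (~resp_true).any() else float("nan")
    )

    atf1_set = expression_response.call_dependent(ds.expression["atf1d"], wt, response_params)
    pcr1_set = expression_response.call_dependent(ds.expression["pcr1d"], wt, response_params)
    responsive_genes = list(status.index[resp_called])
    dep = expression_response.classify_dependency(atf1_set, pcr1_set, responsive_genes)
    metrics["dependency_balanced_accuracy"] = dependency_balanced_accuracy(
        dep, ds.expression_truth.dependency
    )

    # ---- response-timing contrast: direct (bound) vs delayed (unbound) genes
    bound_induced = [g for g in truth_status.index
                     if truth_status[g] == "induced" and g not in ds.expression_truth.delayed]
    delayed_induced = sorted(ds.expression_truth.delayed)
    if bound_induced and delayed_induced:
        t_bound = expression_response.time_to_fold(wt.mean_profile(bound_induced))
        t_delayed = expression_response.time_to_fold(wt.mean_profile(delayed_induced))
        metrics["time_to_4fold_bound_min"] = t_bound
        metrics["time_to_4fold_unbound_min"] = t_delayed

    # ---- growth phenotyping recovery
    fitness = growth_fitness.score_strains(ds.growth_curves, wildtype="wt")
    called_sensitive = set(fitness.index[fitness["sensitive"]]) - {"wt"}
    truth_sensitive = ds.sensitive_strains
    metrics["sensitive_true_positives"] = float(len(called_sensitive & truth_sensitive))
    metrics["sensitive_false_positives"] = float(len(called_sensitive - truth_sensitive))
    metrics["sensitive_false_negatives"] = float(len(truth_sensitive - called_sensitive))
    metrics["wt_deficient_score"] = float(fitness.loc["wt", "deficient_score"])

    # ---- integrated gene report
    bound_called = set()
    for c_idx, genes in assignments.items():
        bound_called.update(genes)
    sensitive_map = {
        s[:-1]: bool(fitness.loc[s, "sensitive"]) for s in fitness.index if s != "wt"
    }
    report = cross_classify(
        bound_major=bound_called, bound_minor=set(),
        responsive=status, sensitive=sensitive_map,
    )
    result = PipelineResult(ds, called, metrics, report)
    if outdir is not None:
        records = [
            SiteRecord(c.chromosome, c.start_bp, c.end_bp, f"ser{i:03d}", c.level)
            for i, c in enumerate(called)
        ]
        confusion = pd.DataFrame(
            {"planted": [n_planted], "recovered": [len(pairs)],
             "called": [len(called)]}
        )
        build_report(outdir, sites=records, gene_report=report, fitness=fitness,
                     extra_tables={"recovery": confusion})
    return result


def mean_column_tv(a, b) -> float:
    """Mean per-column total-variation distance between two PSSMs, taking
    the better of the forward and reverse-complement alignments (a motif is
    recoverable on either strand) over all offsets of the narrower matrix."""
    import numpy as np

    def tv(p, q):
        return float(np.mean(0.5 * np.abs(p - q).sum(axis=0)))

    p, q = a.probs, b.probs
    if p.shape[1] < q.shape[1]:
        p, q = q, p
    # q slides along p
    best = np.inf
    q_rc = q[::-1, ::-1]
    for off in range(p.shape[1] - q.shape[1] + 1):
        window = p[:, off : off + q.shape[1]]
        best = min(best, tv(window, q), tv(window, q_rc))
    return best


def dependency_balanced_accuracy(called: pd.Series, truth: pd.Series) -> float:
    """Balanced accuracy of the dependency labels over responsive genes.

    Truth labels use the generator vocabulary (atf1_only/pcr1_only); the
    caller's (atf1_specific/pcr1_specific) are mapped onto it.
    """
    mapping = {"atf1_specific": "atf1_only", "pcr1_specific": "pcr1_only"}
    common = called.index.intersection(truth.index[truth != "NA"])
    if len(common) == 0:
        return float("nan")
    pred = called.loc[common].replace(mapping)
    true = truth.loc[common]
    accs = []
    for label in sorted(true.unique()):
        mask = true == label
        accs.append(float((pred[mask] == label).mean()))
    return float(np.mean(accs))
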