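"""Motif discovery at binding-site apexes, PSSM scoring and ROC evaluation.

Discovery follows the word-enumeration strategy of MDscan: w-mers from the
top-ranked apex sequences seed candidate alignments (all w-mers within one
mismatch, both strands), candidates are scored by information content, the
best few are refined against the next block of ranked sequences, and the
highest-information-content matrix wins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .annotation import GeneAnnotation
from .chip_signal import Occupancy

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMP = {0: 3, 1: 2, 2: 1, 3: 0}


def encode(seq: str) -> np.ndarray:
    """A,C,G,T -> 0..3; any ambiguity code -> 4."""
    return np.array([_BASE_INDEX.get(b, 4) for b in seq.upper()], dtype=np.int8)


def revcomp(seq: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    return "".join(comp.get(b, "N") for b in reversed(seq.upper()))


@dataclass
class PSSM:
    """Per-position base probabilities with a background model.

    ``probs`` has shape (4, w) in A,C,G,T row order; columns sum to 1.
    """

    probs: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = 0.5

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.shape[0] != 4:
            raise ValueError("probs must have 4 rows (A,C,G,T)")
        if not np.allclose(self.probs.sum(axis=0), 1.0, atol=1e-6):
            raise ValueError("PSSM columns must each sum to 1")
        if not np.isclose(self.background.sum(), 1.0):
            raise ValueError("background must sum to 1")

    @property
    def width(self) -> int:
        return self.probs.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in np.argmax(self.probs, axis=0))

    @classmethod
    def from_sequences(
        cls,
        words: list[str],
        background: np.ndarray | None = None,
        pseudocount: float = 0.5,
    ) -> "PSSM":
        if not words:
            raise ValueError("no words to build a PSSM from")
        w = len(words[0])
        counts = np.full((4, w), pseudocount)
        for word in words:
            enc = encode(word)
            for j, b in enumerate(enc):
                if b < 4:
                    counts[b, j] += 1
        probs = counts / counts.sum(axis=0, keepdims=True)
        bg = background if background is not None else np.full(4, 0.25)
        return cls(probs, bg, pseudocount)


def information_content(pssm: PSSM) -> float:
    """Relative entropy to the background, in bits, summed over columns."""
    p = pssm.probs
    q = pssm.background[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(p / q), 0.0)
    return float(terms.sum())


def pssm_score(pssm: PSSM, sequence: str) -> float:
    """Best summed log-odds over all offsets and both strands.

    Ambiguous bases contribute 0 (scored at background).
    """
    w = pssm.width
    if len(sequence) < w:
        raise ValueError("sequence shorter than motif width")
    logodds = np.zeros((5, w))
    logodds[:4] = np.log2(pssm.probs / pssm.background[:, None])
    best = -np.inf
    for seq in (sequence, revcomp(sequence)):
        enc = encode(seq)
        n = enc.size - w + 1
        # windows matrix: n x w indices into logodds rows
        idx = np.lib.stride_tricks.sliding_window_view(enc, w)
        scores = logodds[idx, np.arange(w)].sum(axis=1)
        best = max(best, float(scores.max()))
    return best


def background_from_sequences(seqs: list[str]) -> np.ndarray:
    counts = np.full(4, 1.0)
    for s in seqs:
        enc = encode(s)
        for b in range(4):
            counts[b] += int(np.sum(enc == b))
    return counts / counts.sum()


# ------------------------------------------------------------------ discovery


def extract_apex_sequences(
    sites: list[Occupancy] | list,
    genome: dict[str, str],
    window: int = 150,
) -> list[str]:
    """Window of ``window`` bp centred on each apex, clipped at chromosome
    ends.  The input order is preserved: callers pass sites ranked by
    descending enrichment."""
    out = []
    for site in sites:
        occ = site.site if hasattr(site, "site") else site
        chrom = genome.get(occ.chromosome)
        if chrom is None or not 0 <= occ.apex < len(chrom):
            raise ValueError(f"apex {occ.apex} outside genome ({occ.chromosome})")
        half = window // 2
        lo = max(0, occ.apex - half)
        hi = min(len(chrom), lo + window)
        lo = max(0, hi - window)
        out.append(chrom[lo:hi].upper())
    return out


@dataclass
class MotifParams:
    apex_window: int = 150
    n_seed_sequences: int = 30
    n_refine_sequences: int = 30
    widths: tuple[int, ...] = (7, 8)
    max_mismatches: int = 1
    n_top_candidates: int = 10
    max_seed_sequences_for_seeding: int = 5
    min_seed_fraction: float = 0.5
    random_promoter_count: int | None = None
    seed: int = 0


def _wmers(enc: np.ndarray, w: int) -> np.ndarray:
    """All ungapped w-mers (rows) of an encoded sequence; drops ambiguous."""
    if enc.size < w:
        return np.empty((0, w), dtype=np.int8)
    win = np.lib.stride_tricks.sliding_window_view(enc, w)
    return win[~np.any(win == 4, axis=1)]


def _collect_words(seqs_enc: list[np.ndarray], w: int) -> tuple[np.ndarray, np.ndarray]:
    """Stack of all w-mers on both strands with their source-sequence ids."""
    mats, ids = [], []
    for i, enc in enumerate(seqs_enc):
        fwd = _wmers(enc, w)
        rc = np.array([_COMP[int(b)] for b in enc[::-1] if b < 4], dtype=np.int8)
        rev = _wmers(rc, w)
        for m in (fwd, rev):
            if m.size:
                mats.append(m)
                ids.append(np.full(m.shape[0], i))
    if not mats:
        return np.empty((0, w), dtype=np.int8), np.empty(0, dtype=int)
    return np.vstack(mats), np.concatenate(ids)


def _candidate_from_seed(
    seed_word: np.ndarray,
    words: np.ndarray,
    word_seq_ids: np.ndarray,
    d: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Matrix of words within d mismatches of the seed + their sequence ids.

    At most one (best) match is kept per source sequence, as in MDscan's
    seed-alignment step."""
    mism = np.sum(words != seed_word[None, :], axis=1)
    keep = mism <= d
    matched, ids, dist = words[keep], word_seq_ids[keep], mism[keep]
    best_rows = []
    for sid in np.unique(ids):
        rows = np.flatnonzero(ids == sid)
        best_rows.append(rows[np.argmin(dist[rows])])
    best_rows = np.array(best_rows, dtype=int)
    return matched[best_rows], ids[best_rows]


def _pssm_from_matrix(mat: np.ndarray, background: np.ndarray, alpha: float) -> PSSM:
    w = mat.shape[1]
    counts = np.full((4, w), alpha)
    for b in range(4):
        counts[b] += np.sum(mat == b, axis=0)
    return PSSM(counts / counts.sum(axis=0, keepdims=True), background, alpha)


def discover_pssm(
    seed_seqs: list[str],
    refine_seqs: list[str],
    params: MotifParams = MotifParams(),
) -> PSSM:
    """MDscan-style discovery: seed on w-mers of the top sequences, score by
    information content, refine the best candidates on the next block of
    sequences, return the highest-IC matrix."""
    usable = [s for s in seed_seqs if len(s) >= min(params.widths)]
    if not usable:
        raise ValueError("no seed sequence reaches the motif width")
    background = background_from_sequences(list(seed_seqs) + list(refine_seqs))
    seqs_enc = [encode(s) for s in usable]
    best: tuple[float, PSSM] | None = None
    for w in params.widths:
        words, word_ids = _collect_words(seqs_enc, w)
        if words.shape[0] == 0:
            continue
        n_seed_src = min(params.max_seed_sequences_for_seeding, len(seqs_enc))
        seed_mask = word_ids < n_seed_src
        seed_words = np.unique(words[seed_mask], axis=0)
        candidates: list[tuple[float, PSSM]] = []
        for seed_word in seed_words:
            mat, ids = _candidate_from_seed(
                seed_word, words, word_ids, params.max_mismatches
            )
            if np.unique(ids).size < params.min_seed_fraction * len(seqs_enc):
                continue
            pssm = _pssm_from_matrix(mat, background, 0.5)
            candidates.append((information_content(pssm), pssm))
        candidates.sort(key=lambda t: -t[0])
        for ic, pssm in candidates[: params.n_top_candidates]:
            refined = _refine(pssm, refine_seqs, background)
            # per-column IC makes candidates of different widths commensurable
            ric = information_content(refined) / refined.width
            if best is None or ric > best[0]:
                best = (ric, refined)
    if best is None:
        raise ValueError("no motif candidate reached the sequence-support floor")
    return best[1]


def _refine(pssm: PSSM, refine_seqs: list[str], background: np.ndarray) -> PSSM:
    """Add each refinement sequence's best positive-scoring site and
    re-estimate the matrix."""
    w = pssm.width
    words = [pssm.consensus]  # anchor so refinement cannot empty the model
    logodds = np.zeros((5, w))
    logodds[:4] = np.log2(pssm.probs / pssm.background[:, None])
    for s in refine_seqs:
        if len(s) < w:
            continue
        best_word, best_score = None, 0.0
        for seq in (s, revcomp(s)):
            enc = encode(seq)
            idx = np.lib.stride_tricks.sliding_window_view(enc, w)
            scores = logodds[idx, np.arange(w)].sum(axis=1)
            k = int(np.argmax(scores))
            if scores[k] > best_score:
                best_score = float(scores[k])
                best_word = seq[k : k + w]
        if best_word is not None:
            words.append(best_word)
    return PSSM.from_sequences(words, background, pssm.pseudocount)


# ------------------------------------------------------------------------ ROC


def roc_auc(
    bound_scores: np.ndarray, unbound_scores: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC curve (FPR, TPR) by threshold sweep and trapezoidal AUC.

    Equals the Mann-Whitney U statistic divided by n1*n2.
    """
    pos = np.asarray(bound_scores, dtype=float)
    neg = np.asarray(unbound_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score sets must be nonempty")
    thresholds = np.unique(np.concatenate([pos, neg]))[::-1]
    tpr = [0.0]
    fpr = [0.0]
    for t in thresholds:
        tpr.append(float(np.mean(pos >= t)))
        fpr.append(float(np.mean(neg >= t)))
    tpr.append(1.0)
    fpr.append(1.0)
    fpr_a, tpr_a = np.array(fpr), np.array(tpr)
    auc = float(np.trapezoid(tpr_a, fpr_a))
    return fpr_a, tpr_a, auc


def promoter_sequences(
    annotation: GeneAnnotation,
    genome: dict[str, str],
    upstream: int = 500,
    gene_ids: list[str] | None = None,
) -> dict[str, str]:
    """Upstream promoter slices per coding gene (for the unbound ROC set)."""
    out = {}
    wanted = set(gene_ids) if gene_ids is not None else None
    for g in annotation:
        if not g.coding or (wanted is not None and g.gene_id not in wanted):
            continue
        chrom = genome[g.chromosome]
        if g.strand == "+":
            lo, hi = max(0, g.atg - upstream), g.atg
        else:
            lo, hi = g.atg, min(len(chrom), g.atg + upstream)
        if hi - lo >= 20:
            out[g.gene_id] = chrom[lo:hi].upper()
    return out
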