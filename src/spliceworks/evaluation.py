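"""Model-quality metrics and in-silico mutagenesis (ISM).

Top-k accuracy: for a class with n_true annotated sites, the fraction of
the k * n_true highest-scoring positions that are annotated sites of that
class.  Threshold metrics are standard one-vs-rest accuracy / precision /
recall / F1 plus AUPRC via step-wise average precision.

ISM importance at a position: S_ref - (S_A + S_C + S_G + S_T) / 4, where
S_b is the site score after substituting base b at that position (the
reference base's "substitution" scores S_ref itself).  Negative values --
mutations that increase the site score -- are preserved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genomics_io import one_hot_encode
from .inference import predict_ensemble, _check_ensemble
from .model import SpliceModel

__all__ = [
    "topk_accuracy",
    "confusion_metrics",
    "ISMProfile",
    "ism_importance",
    "motif_matrix",
    "profile_correlation",
]

_BASES = "ACGT"
_CLASS_CHANNEL = {"acceptor": 1, "donor": 2}


def topk_accuracy(
    scores: np.ndarray,
    true_sites: dict[str, np.ndarray],
    k: float = 1,
    ties: str = "include",
) -> dict[str, float | None]:
    """Pooled top-k accuracy per class.

    scores: (N, 3) per-position class probabilities.  true_sites maps
    "acceptor"/"donor" to arrays of 0-based positions.  A class with no
    true sites is undefined and reported as None.  ties="include" admits
    every position tied with the cutoff score (the fraction is clipped to
    1); ties="truncate" keeps exactly k*n_true by stable sort order.
    """
    if ties not in ("include", "truncate"):
        raise ValueError("ties must be 'include' or 'truncate'")
    scores = np.asarray(scores)
    out: dict[str, float | None] = {}
    for cls, channel in _CLASS_CHANNEL.items():
        truth = np.asarray(true_sites.get(cls, []), dtype=np.int64)
        n_true = len(truth)
        if n_true == 0:
            out[cls] = None
            continue
        n_top = int(round(k * n_true))
        col = scores[:, channel]
        order = np.argsort(-col, kind="stable")
        if ties == "include":
            cutoff = col[order[n_top - 1]]
            selected = np.flatnonzero(col >= cutoff)
        else:
            selected = order[:n_top]
        hits = np.intersect1d(selected, truth).size
        out[cls] = min(hits / n_top, 1.0)
    return out


def _average_precision(y_true: np.ndarray, y_score: np.ndarray) -> float:
    from sklearn.metrics import average_precision_score

    return float(average_precision_score(y_true, y_score))


def confusion_metrics(
    scores: np.ndarray,
    labels: np.ndarray,
    threshold: float = 0.5,
) -> dict[str, dict[str, float | None]]:
    """One-vs-rest metrics per class at a score threshold, plus AUPRC.

    labels: int classes (0 none, 1 acceptor, 2 donor).  Precision is None
    ("missing") when nothing is predicted positive; AUPRC is None for a
    class without positives.
    """
    scores = np.asarray(scores)
    labels = np.asarray(labels).astype(np.int64)
    out: dict[str, dict[str, float | None]] = {}
    for cls, channel in (("none", 0), ("acceptor", 1), ("donor", 2)):
        y_true = (labels == channel).astype(np.int64)
        y_pred = (scores[:, channel] > threshold).astype(np.int64)
        tp = int(((y_pred == 1) & (y_true == 1)).sum())
        fp = int(((y_pred == 1) & (y_true == 0)).sum())
        fn = int(((y_pred == 0) & (y_true == 1)).sum())
        tn = int(((y_pred == 0) & (y_true == 0)).sum())
        precision = tp / (tp + fp) if (tp + fp) else None
        recall = tp / (tp + fn) if (tp + fn) else None
        if precision and recall:
            f1 = 2 * precision * recall / (precision + recall)
        elif precision is not None and recall is not None:
            f1 = 0.0
        else:
            f1 = None
        auprc = _average_precision(y_true, scores[:, channel]) if y_true.any() else None
        out[cls] = {
            "accuracy": (tp + tn) / len(y_true),
            "precision": precision,
            "recall": recall,
            "f1": f1,
            "auprc": auprc,
            "tp": tp, "fp": fp, "fn": fn, "tn": tn,
        }
    return out


@dataclass
class ISMProfile:
    center: int
    site_class: str
    window: int
    s_ref: float
    scores: np.ndarray  # (2*window+1, 4): site score after each substitution
    importance: np.ndarray  # (2*window+1,)

    @property
    def drops(self) -> np.ndarray:
        """Raw score decrease per (position, substituted base)."""
        return self.s_ref - self.scores

    @property
    def positions(self) -> np.ndarray:
        return np.arange(-self.window, self.window + 1) + self.center


def _site_scores_batch(
    models: list[SpliceModel],
    seqs: np.ndarray,
    site_index: int,
    channel: int,
    batch_size: int = 64,
) -> np.ndarray:
    """Score one position (channel) for a batch of one-hot sequences."""
    probs = predict_ensemble(models, seqs, batch_size=batch_size)
    return probs[:, site_index, channel]


def ism_importance(
    models: list[SpliceModel] | SpliceModel,
    seq: str,
    site: int,
    site_class: str,
    window: int = 40,
    batch_size: int = 64,
) -> ISMProfile:
    """Saturation mutagenesis around one splice site.

    Every position within +-window of the site is substituted with each of
    the four bases and the site's (ensemble-averaged) score re-computed.
    The sequence must provide real flanking context: the extraction window
    is site +- (window + flank/2).
    """
    if isinstance(models, SpliceModel):
        models = [models]
    flank = _check_ensemble(models)
    if site_class not in _CLASS_CHANNEL:
        raise ValueError("site_class must be 'acceptor' or 'donor'")
    channel = _CLASS_CHANNEL[site_class]
    half = flank // 2
    ctx = window + half
    start, end = site - ctx, site + ctx + 1
    if start < 0 or end > len(seq):
        raise ValueError(
            f"ISM window [{start}, {end}) exceeds the sequence bounds "
            f"[0, {len(seq)})"
        )
    segment = seq[start:end]
    base_onehot = one_hot_encode(segment)
    site_in_segment = ctx  # position of the splice site inside the segment
    scored_index = site_in_segment - half

    n_pos = 2 * window + 1
    batch = np.repeat(base_onehot[None, :, :], n_pos * 4 + 1, axis=0)
    eye = np.eye(4, dtype=np.float32)
    row = 0
    for p in range(n_pos):
        seg_pos = half + p  # mutated position inside the segment
        for b in range(4):
            batch[row, seg_pos, :] = eye[b]
            row += 1
    # final row: untouched reference
    site_scores = _site_scores_batch(
        models, batch, scored_index, channel, batch_size
    )
    s_ref = float(site_scores[-1])
    scores = site_scores[:-1].reshape(n_pos, 4)
    # the reference base's substitution is the reference sequence itself
    ref_rows = base_onehot[half : half + n_pos]
    for p in range(n_pos):
        nz = np.flatnonzero(ref_rows[p])
        if nz.size:
            scores[p, nz[0]] = s_ref
    importance = s_ref - scores.mean(axis=1)
    return ISMProfile(
        center=site,
        site_class=site_class,
        window=window,
        s_ref=s_ref,
        scores=scores,
        importance=importance,
    )


def motif_matrix(
    models: list[SpliceModel] | SpliceModel,
    sites: list[tuple[str, int, str]],
    seq_len: int = 400,
    shown_window: int = 80,
    batch_size: int = 64,
) -> np.ndarray:
    """Mean raw score decrease per (position, substituted base) across
    sites, center-aligned; rows cover the central `shown_window` positions.

    sites: (sequence, site position within it, "donor"/"acceptor")
    triples; each sequence is recentred to `seq_len` around its site.
    The returned (shown_window, 4) matrix feeds sequence-logo rendering.
    """
    if isinstance(models, SpliceModel):
        models = [models]
    if not sites:
        raise ValueError("at least one site is required")
    half_shown = shown_window // 2
    mats = []
    for seq, pos, cls in sites:
        prof = ism_importance(
            models, seq, pos, cls, window=half_shown, batch_size=batch_size
        )
        mats.append(prof.drops[: 2 * half_shown])
    return np.mean(mats, axis=0)


def profile_correlation(a: ISMProfile, b: ISMProfile) -> float:
    """Pearson correlation of two paired importance profiles."""
    x, y = a.importance, b.importance
    if len(x) != len(y):
        raise ValueError("profiles must have equal window lengths")
    return float(np.corrcoef(x, y)[0, 1])
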