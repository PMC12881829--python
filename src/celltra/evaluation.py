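"""Evaluation metrics for seen/unseen cell-type annotation.

Micro-F1 and support-weighted macro-F1 (class imbalance is the norm in
cell atlases), computed separately on the cells whose TRUE type is seen
versus unseen, combined into a mixed score by harmonic mean; per-type
accuracy; and the entropy-bin curve relating prediction entropy to the
proportion of seen-type cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import f1_score

__all__ = ["EvaluationReport", "f1_scores", "split_scores", "mixed_f1",
           "entropy_bin_curve", "per_type_accuracy", "evaluate"]


def f1_scores(predicted: list[str], truth: list[str],
              average: str = "micro") -> float:
    """Micro or support-weighted macro F1.

    Micro-F1 aggregates TP/FP/FN globally (equal to accuracy for
    single-label multi-class); weighted macro averages per-class F1 with
    truth-side support weights, so classes never appearing in the truth
    contribute nothing.
    """
    if len(predicted) != len(truth):
        raise ValueError("label lists must be the same length")
    if not truth:
        raise ValueError("empty label lists")
    if average not in ("micro", "weighted_macro"):
        raise ValueError(f"unknown average {average!r}")
    sk_avg = "micro" if average == "micro" else "weighted"
    # prediction-only classes must still count as false positives (micro)
    # while carrying zero truth-side support weight (weighted macro)
    labels = sorted(set(truth) | set(predicted))
    return float(f1_score(truth, predicted, labels=labels, average=sk_avg,
                          zero_division=0))


def split_scores(predicted: list[str], truth: list[str],
                 seen_set) -> dict[str, float | None]:
    """Micro and weighted-macro F1 on the seen-truth and unseen-truth
    partitions, plus their harmonic-mean mixed scores.

    Partitioning is by the TRUE label: a seen-type cell predicted as an
    unseen name still counts in the seen partition. An empty partition
    yields None for that side and for the mixed score.
    """
    seen_set = set(seen_set)
    seen_idx = [i for i, t in enumerate(truth) if t in seen_set]
    unseen_idx = [i for i, t in enumerate(truth) if t not in seen_set]

    def _side(idx):
        if not idx:
            return None, None
        p = [predicted[i] for i in idx]
        t = [truth[i] for i in idx]
        return f1_scores(p, t, "micro"), f1_scores(p, t, "weighted_macro")

    seen_micro, seen_macro = _side(seen_idx)
    unseen_micro, unseen_macro = _side(unseen_idx)
    return {
        "seen_micro_f1": seen_micro,
        "seen_macro_f1": seen_macro,
        "unseen_micro_f1": unseen_micro,
        "unseen_macro_f1": unseen_macro,
        "mixed_micro_f1": mixed_f1(seen_micro, unseen_micro)
        if seen_micro is not None and unseen_micro is not None else None,
        "mixed_macro_f1": mixed_f1(seen_macro, unseen_macro)
        if seen_macro is not None and unseen_macro is not None else None,
    }


def mixed_f1(seen_f1: float, unseen_f1: float) -> float:
    """Harmonic mean 2ab/(a+b); 0 when either side is 0."""
    if seen_f1 < 0 or unseen_f1 < 0:
        raise ValueError("F1 scores must be non-negative")
    if seen_f1 + unseen_f1 == 0:
        return 0.0
    return 2.0 * seen_f1 * unseen_f1 / (seen_f1 + unseen_f1)


def entropy_bin_curve(entropies, truth_seen_flags, n_bins: int = 100) -> np.ndarray:
    """Seen-type proportion per entropy bin.

    Cells are sorted ascending by entropy (ties keep input order) and cut
    into ``n_bins`` contiguous bins whose sizes differ by at most one (the
    first ``n mod n_bins`` bins take the extra cell); each bin reports the
    fraction of cells whose true type is seen.
    """
    entropies = np.asarray(list(entropies), dtype=np.float64)
    flags = np.asarray(list(truth_seen_flags), dtype=bool)
    n = entropies.size
    if n < n_bins:
        raise ValueError(f"{n} cells cannot fill {n_bins} bins")
    order = np.argsort(entropies, kind="stable")
    sorted_flags = flags[order]
    base, extra = divmod(n, n_bins)
    out = np.empty(n_bins)
    start = 0
    for b in range(n_bins):
        size = base + (1 if b < extra else 0)
        out[b] = sorted_flags[start:start + size].mean()
        start += size
    return out


def per_type_accuracy(predicted: list[str], truth: list[str]) -> dict[str, float]:
    """Per true type, the fraction of its cells predicted correctly."""
    if not truth:
        raise ValueError("empty label lists")
    out: dict[str, list[int]] = {}
    for p, t in zip(predicted, truth):
        hit_total = out.setdefault(t, [0, 0])
        hit_total[0] += int(p == t)
        hit_total[1] += 1
    return {t: hits / total for t, (hits, total) in out.items()}


@dataclass
class EvaluationReport:
    micro_f1: float
    weighted_macro_f1: float
    seen_micro_f1: float | None
    seen_macro_f1: float | None
    unseen_micro_f1: float | None
    unseen_macro_f1: float | None
    mixed_micro_f1: float | None
    mixed_macro_f1: float | None
    per_type_accuracy: dict[str, float]
    entropy_bins: np.ndarray | None

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "entropy_bins"}
        d["entropy_bins"] = (None if self.entropy_bins is None
                             else [float(x) for x in self.entropy_bins])
        return d


def evaluate(predicted: list[str], truth: list[str], seen_set,
             entropies=None, n_bins: int = 100) -> EvaluationReport:
    """Full report over a mixed seen/unseen test set."""
    split = split_scores(predicted, truth, seen_set)
    bins = None
    if entropies is not None and len(truth) >= n_bins:
        seen_flags = [t in set(seen_set) for t in truth]
        bins = entropy_bin_curve(entropies, seen_flags, n_bins=n_bins)
    return EvaluationReport(
        micro_f1=f1_scores(predicted, truth, "micro"),
        weighted_macro_f1=f1_scores(predicted, truth, "weighted_macro"),
        per_type_accuracy=per_type_accuracy(predicted, truth),
        entropy_bins=bins,
        **split,
    )
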