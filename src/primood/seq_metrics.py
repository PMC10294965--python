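"""Levenshtein edit-operation evaluation of predicted primitive sequences.

A predicted sequence is compared against ground truth by a minimal-cost
unit-cost alignment.  Operations are counted from the model's perspective:

* deletion     — remove a predicted token the model incorrectly added;
* insertion    — add a ground-truth token the model missed;
* substitution — swap a misclassified token for the correct one.

From pooled counts: FDR = (deletions + substitutions) / n_predicted,
TPR = 1 - (insertions + substitutions) / n_ground_truth (floored at 0),
and F1 = harmonic mean of TPR and (1 - FDR).  Per-subject metrics pool
(micro-average) edit counts over all windows before applying the formulas.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["EditCounts", "edit_counts", "fdr", "tpr", "f1", "aggregate_counts"]


@dataclass(frozen=True)
class EditCounts:
    deletions: int
    insertions: int
    substitutions: int
    n_pred: int
    n_gt: int

    def __post_init__(self):
        assert self.deletions <= self.n_pred and self.insertions <= self.n_gt
        # matched-token conservation
        assert self.n_pred - self.deletions == self.n_gt - self.insertions

    @property
    def distance(self) -> int:
        return self.deletions + self.insertions + self.substitutions


def edit_counts(pred, gt) -> EditCounts:
    """Count edit operations of one minimal alignment transforming pred -> gt.

    When several minimal alignments exist, the one maximizing aligned
    (match/substitution) pairs is chosen, with the backtrace preferring
    substitution over deletion over insertion.  This makes the counts
    deterministic and symmetric: deletions(a, b) == insertions(b, a).
    """
    pred, gt = list(pred), list(gt)
    if not pred or not gt:
        raise ValueError("sequences must be non-empty")
    n, m = len(pred), len(gt)
    # lexicographic DP: minimize distance, then maximize diagonal steps
    # (substitutions/matches).  The greedy local preference is not enough:
    # maximizing diagonal steps globally is what makes the counts
    # deterministic and symmetric under swapping the sequences.
    INF = n + m + 1
    dist = [[0] * (m + 1) for _ in range(n + 1)]
    diag = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        dist[i][0] = i
    for j in range(1, m + 1):
        dist[0][j] = j
    for i in range(1, n + 1):
        d_row, g_row = dist[i], diag[i]
        d_prev, g_prev = dist[i - 1], diag[i - 1]
        pi = pred[i - 1]
        for j in range(1, m + 1):
            cost = 0 if pi == gt[j - 1] else 1
            best, most = d_prev[j - 1] + cost, g_prev[j - 1] + 1
            cand = d_prev[j] + 1
            if cand < best or (cand == best and g_prev[j] > most):
                best, most = cand, g_prev[j]
            cand = d_row[j - 1] + 1
            if cand < best or (cand == best and g_row[j - 1] > most):
                best, most = cand, g_row[j - 1]
            d_row[j], g_row[j] = best, most
    dels = ins = subs = 0
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0:
            cost = 0 if pred[i - 1] == gt[j - 1] else 1
            if dist[i][j] == dist[i - 1][j - 1] + cost \
                    and diag[i][j] == diag[i - 1][j - 1] + 1:
                subs += cost
                i, j = i - 1, j - 1
                continue
        if i > 0 and dist[i][j] == dist[i - 1][j] + 1 \
                and diag[i][j] == diag[i - 1][j]:
            dels += 1
            i -= 1
            continue
        ins += 1
        j -= 1
    return EditCounts(dels, ins, subs, n, m)


def fdr(c: EditCounts) -> float:
    if c.n_pred < 1:
        raise ValueError("n_pred must be >= 1")
    return (c.deletions + c.substitutions) / c.n_pred


def tpr(c: EditCounts) -> float:
    if c.n_gt < 1:
        raise ValueError("n_gt must be >= 1")
    return max(0.0, 1.0 - (c.insertions + c.substitutions) / c.n_gt)


def f1(tpr_value: float, fdr_value: float) -> float:
    precision = 1.0 - fdr_value
    denom = tpr_value + precision
    if denom == 0.0:
        return 0.0
    return 2.0 * tpr_value * precision / denom


def aggregate_counts(counts) -> EditCounts:
    """Pool edit counts (micro-averaging) before applying the rate formulas."""
    counts = list(counts)
    if not counts:
        raise ValueError("nothing to aggregate")
    return EditCounts(
        sum(c.deletions for c in counts),
        sum(c.insertions for c in counts),
        sum(c.substitutions for c in counts),
        sum(c.n_pred for c in counts),
        sum(c.n_gt for c in counts),
    )
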