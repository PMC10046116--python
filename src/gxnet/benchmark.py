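"""Gold-standard evaluation in the DREAM5 style.

Predicted links are restricted to the experimentally tested TF x gene
universe (untested pairs are neither rewarded nor penalized), tested pairs
the method did not predict are appended with score zero so the ranking
covers the whole universe, and the completed labeled ranking is scored by
AUROC (ties count one half) and AUPR (average-precision convention).
Scores are unsigned: the gold standard does not distinguish activation
from repression, so |coefficient| is the natural edge score.
"""

from __future__ import annotations

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from .io import GoldStandard


def restrict_to_tested(
    links: list[tuple[str, str, float]], gold: GoldStandard
) -> list[tuple[float, int]]:
    """Label predicted links against the tested universe.

    ``links`` are (tf, target, score >= 0) with duplicates and self-loops
    disallowed.  Links outside the tested universe are discarded; tested
    pairs absent from the prediction enter with score 0.  With a dense gold
    standard the universe is all non-self pairs in tested_tfs x
    tested_genes; otherwise only explicitly listed rows are used.
    """
    if not gold.true_links:
        raise ValueError("gold standard has no positive links; AUPR is undefined")
    seen: set[tuple[str, str]] = set()
    scored: dict[tuple[str, str], float] = {}
    for tf, tg, score in links:
        if (tf, tg) in seen:
            raise ValueError(f"duplicate predicted link ({tf},{tg})")
        seen.add((tf, tg))
        if tf == tg:
            raise ValueError(f"predicted self-loop ({tf},{tg})")
        if score < 0:
            raise ValueError("scores must be non-negative")
        scored[(tf, tg)] = float(score)

    if gold.dense:
        universe = list(gold.universe())
    else:
        universe = sorted(gold.true_links | gold.negative_links)

    labeled = [
        (scored.get(pair, 0.0), 1 if pair in gold.true_links else 0) for pair in universe
    ]
    labeled.sort(key=lambda t: -t[0])
    return labeled


def auroc(labeled: list[tuple[float, int]]) -> float:
    """Probability-of-correct-ranking AUROC (Mann-Whitney; ties give 1/2)."""
    scores = np.array([s for s, _ in labeled], dtype=float)
    labels = np.array([l for _, l in labeled], dtype=int)
    if labels.min() == labels.max():
        raise ValueError("AUROC needs both classes present")
    return float(roc_auc_score(labels, scores))


def aupr(labeled: list[tuple[float, int]]) -> float:
    """Area under precision-recall: sum of precision * delta-recall at each
    positive (the average-precision convention)."""
    scores = np.array([s for s, _ in labeled], dtype=float)
    labels = np.array([l for _, l in labeled], dtype=int)
    if labels.sum() == 0:
        raise ValueError("AUPR needs at least one positive")
    return float(average_precision_score(labels, scores))


def class_imbalance(gold: GoldStandard) -> float:
    """Fraction of true links in the tested universe |Egold| / |Egoldfull|."""
    full = gold.universe_size if gold.dense else len(gold.true_links | gold.negative_links)
    if full == 0:
        raise ValueError("empty tested universe")
    return len(gold.true_links) / full


def evaluate_ranking(
    links: list[tuple[str, str, float]], gold: GoldStandard
) -> dict[str, float]:
    """Convenience wrapper: restrict, then AUROC/AUPR plus counts."""
    labeled = restrict_to_tested(links, gold)
    return {
        "auroc": auroc(labeled),
        "aupr": aupr(labeled),
        "n_pos": float(sum(l for _, l in labeled)),
        "n_tested": float(len(labeled)),
    }
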