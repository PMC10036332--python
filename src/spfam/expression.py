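"""Differential-expression thresholding and common-regulation set logic.

The pipeline consumes precomputed per-gene statistics (log2 ratio and
q-value per ordered condition pair) and applies the family's standard
filter: a gene is significantly up in A vs B when log2(ratio) >= 1 with
q < 0.05, down when log2(ratio) <= -1 with q < 0.05, otherwise not
significant.  On top of the per-pair verdicts it builds the pairwise
up/down count matrix and Venn-style "commonly regulated" gene sets.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import pandas as pd

from .io_formats import ExpressionRecord

LOG2_THRESHOLD = 1.0
Q_THRESHOLD = 0.05


def de_classify(log2_ratio: float, q_value: float) -> str:
    """up / down / ns verdict for one gene in one comparison.

    The fold-change bound is inclusive (log2 = 1 with q < 0.05 is up); the
    q-value bound is strict (q = 0.05 is ns).
    """
    if not 0.0 <= q_value <= 1.0:
        raise ValueError(f"q-value {q_value} outside [0, 1]")
    if q_value < Q_THRESHOLD:
        if log2_ratio >= LOG2_THRESHOLD:
            return "up"
        if log2_ratio <= -LOG2_THRESHOLD:
            return "down"
    return "ns"


def classify_records(records: Iterable[ExpressionRecord]) -> dict[tuple[str, tuple[str, str]], str]:
    """Verdict per (gene, ordered comparison); duplicates are an error."""
    verdicts: dict[tuple[str, tuple[str, str]], str] = {}
    for rec in records:
        key = (rec.gene, rec.comparison)
        if key in verdicts:
            raise ValueError(f"duplicate record for gene {rec.gene} in {rec.comparison}")
        verdicts[key] = de_classify(rec.log2_ratio, rec.q_value)
    return verdicts


def pairwise_matrix(
    records: Sequence[ExpressionRecord],
    conditions: Sequence[str] | None = None,
) -> dict[tuple[str, str], tuple[int, int]]:
    """(n_up, n_down) per ordered condition pair.

    Orientation is row-vs-column: an "up" verdict for (A, B) counts a gene
    upregulated in A relative to B.  ``conditions`` fixes which pairs are
    reported (all ordered pairs present in the data when omitted).
    """
    verdicts = classify_records(records)
    counts: dict[tuple[str, str], list[int]] = {}
    if conditions is not None:
        for a in conditions:
            for b in conditions:
                if a != b:
                    counts[(a, b)] = [0, 0]
    for (gene, pair), verdict in verdicts.items():
        if pair not in counts:
            if conditions is not None:
                continue
            counts[pair] = [0, 0]
        if verdict == "up":
            counts[pair][0] += 1
        elif verdict == "down":
            counts[pair][1] += 1
    return {pair: (up, down) for pair, (up, down) in counts.items()}


def matrix_to_frame(matrix: dict[tuple[str, str], tuple[int, int]]) -> pd.DataFrame:
    """Long-format DataFrame (condition_a, condition_b, n_up, n_down)."""
    rows = [(a, b, up, down) for (a, b), (up, down) in sorted(matrix.items())]
    return pd.DataFrame(rows, columns=["condition_a", "condition_b", "n_up", "n_down"])


def common_regulated(
    records: Sequence[ExpressionRecord],
    focal_condition: str,
    others: Sequence[str],
    direction: str,
    min_others: int | None = None,
) -> set[str]:
    """Genes with the given verdict in focal-vs-other comparisons.

    A record stored with the opposite orientation (other, focal) is used
    with its log2 ratio negated.  ``min_others`` defaults to len(others),
    i.e. the intersection ("commonly regulated") semantics.
    """
    if direction not in {"up", "down"}:
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    if min_others is None:
        min_others = len(others)
    hits: dict[str, int] = {}
    wanted = set(others)
    seen: set[tuple[str, str]] = set()
    for rec in records:
        a, b = rec.comparison
        if a == focal_condition and b in wanted:
            log2, other = rec.log2_ratio, b
        elif b == focal_condition and a in wanted:
            log2, other = -rec.log2_ratio, a
        else:
            continue
        key = (rec.gene, other)
        if key in seen:
            raise ValueError(
                f"duplicate focal comparison for gene {rec.gene} vs {other}"
            )
        seen.add(key)
        if de_classify(log2, rec.q_value) == direction:
            hits[rec.gene] = hits.get(rec.gene, 0) + 1
    return {gene for gene, n in hits.items() if n >= min_others}


def common_regulation_report(
    records: Sequence[ExpressionRecord],
    conditions: Sequence[str],
    min_others: int | None = None,
) -> dict[str, dict[str, list[str]]]:
    """Per condition, the commonly up- and downregulated gene lists."""
    report: dict[str, dict[str, list[str]]] = {}
    for focal in conditions:
        others = [c for c in conditions if c != focal]
        report[focal] = {
            "common_up": sorted(
                common_regulated(records, focal, others, "up", min_others)
            ),
            "common_down": sorted(
                common_regulated(records, focal, others, "down", min_others)
            ),
        }
    return report
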