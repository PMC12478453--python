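"""Signed significance metric for ranking proteins before set enrichment.

For each protein the metric is ``-log10(p) * sign(log2 FC)``, where p is
the pooled-variance two-sided t-test p-value between the complete- and
poor-responder groups and FC is the ratio of group means
(complete / poor).  A positive metric means the protein is up in
complete responders.  Differential expression is called when the
absolute metric exceeds the alpha = 0.05 line, |metric| > 1.3010
(printed as 1.30 at two decimals); the comparison is strict, so
p = 0.05 exactly is not differential.

Set-level enrichment itself (KEGG/Reactome walks, NES, permutation
p-values) is deliberately out of scope: the module emits a ``.rnk``-style
rank file consumable by external enrichment tools.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from seraman.exceptions import DegenerateDataError, DuplicateRecordError, ParameterError
from seraman.stats import ttest_homoscedastic

#: alpha = 0.05 significance line on the -log10 scale, at 4 decimals.
DEFAULT_CUTOFF = round(-np.log10(0.05), 4)  # 1.3010


def rank_metric(p_value: float, fold_change: float) -> float:
    """``-log10(p) * sign(log2 FC)``; the sign of log2(1) is defined as 0."""
    if not (0 < p_value <= 1):
        raise ParameterError(f"p-value must be in (0, 1], got {p_value}")
    if fold_change <= 0:
        raise ParameterError(f"fold change must be > 0, got {fold_change}")
    return float(-np.log10(p_value) * np.sign(np.log2(fold_change)))


def call_differential(
    proteins: Iterable[tuple[str, float, float]],
    cutoff: float = DEFAULT_CUTOFF,
) -> pd.DataFrame:
    """Compute the metric per protein and call differential expression.

    ``proteins`` yields ``(protein_id, p_value, fold_change)``.  The call
    is strict on the metric rounded to 4 decimals: differential iff
    ``round(|metric|, 4) > cutoff``.  Output is sorted by descending
    metric (most up-in-complete first).
    """
    rows = []
    seen = set()
    for pid, p, fc in proteins:
        if pid in seen:
            raise DuplicateRecordError(f"duplicate protein id {pid!r}")
        seen.add(pid)
        m = rank_metric(p, fc)
        rows.append((pid, p, fc, m, round(abs(m), 4) > cutoff))
    out = pd.DataFrame(
        rows,
        columns=["protein", "p_value", "fold_change", "rank_metric", "differential"],
    )
    return out.sort_values(
        "rank_metric", ascending=False, kind="mergesort"
    ).reset_index(drop=True)


def metrics_from_groups(
    panel: pd.DataFrame,
    labels: pd.Series,
    case: str = "complete",
    reference: str = "poor",
    cutoff: float = DEFAULT_CUTOFF,
) -> pd.DataFrame:
    """Rank metrics for every analyte of a protein panel.

    ``panel`` is samples x analytes; ``labels`` assigns each sample to a
    responder class.  FC = mean(case) / mean(reference).
    """
    labels = labels.reindex(panel.index)
    for g in (case, reference):
        if (labels == g).sum() < 2:
            raise DegenerateDataError(f"group {g!r} has < 2 samples")
    A = panel.loc[labels == case]
    B = panel.loc[labels == reference]
    triples = []
    for col in panel.columns:
        mb = B[col].mean()
        if mb == 0:
            raise DegenerateDataError(
                f"{col}: zero mean in reference group, fold change undefined"
            )
        _, p = ttest_homoscedastic(A[col], B[col])
        triples.append((col, p, A[col].mean() / mb))
    return call_differential(triples, cutoff=cutoff)


def write_rnk(calls: pd.DataFrame, path: str | Path) -> None:
    """Two-column tab-separated rank file (protein, metric), no header."""
    calls[["protein", "rank_metric"]].to_csv(
        path, sep="\t", header=False, index=False
    )
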