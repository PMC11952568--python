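"""Hypoxia scoring from a normalized expression matrix.

Each tumor receives +1 per scored gene expressed strictly above the cohort
median for that gene and -1 when strictly below; exact ties score 0.  With
K scored genes the total ranges from -K (most normoxic) to +K (most
hypoxic).
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import pandas as pd


def assemble_hypoxia_genes(
    source_lists: Iterable[Iterable[str]],
    removal_set: Iterable[str] = (),
) -> list[str]:
    """Union of source marker lists, deduplicated, minus a removal set.

    Mirrors building a master hypoxia list from several published signatures
    and dropping genes filtered by the expression pipeline.  Order follows
    first appearance.  An empty result raises.
    """
    seen: dict[str, None] = {}
    for lst in source_lists:
        for gene in lst:
            seen.setdefault(gene, None)
    removal = set(removal_set)
    out = [g for g in seen if g not in removal]
    if not out:
        raise ValueError("hypoxia gene list is empty after removal")
    return out


def hypoxia_score(
    expression: pd.DataFrame, gene_list: Sequence[str]
) -> pd.DataFrame:
    """Median-dichotomization hypoxia score per tumor.

    ``expression`` is genes x samples (tumors only — medians are computed
    across these columns).  Genes missing from the matrix are dropped with a
    warning, reducing K.  Returns a DataFrame with sample_id, score and K.
    """
    if expression.shape[1] < 2:
        raise ValueError("need >= 2 samples to define per-gene medians")
    present = [g for g in gene_list if g in expression.index]
    missing = set(gene_list) - set(present)
    if missing:
        warnings.warn(f"{len(missing)} hypoxia genes absent from matrix; dropped")
    if not present:
        raise ValueError("no hypoxia genes present in the expression matrix")
    sub = expression.loc[present]
    med = sub.median(axis=1)
    above = sub.gt(med, axis=0).sum(axis=0)
    below = sub.lt(med, axis=0).sum(axis=0)
    scores = (above - below).astype(int)
    return pd.DataFrame({
        "sample_id": sub.columns,
        "score": scores.to_numpy(),
        "k": len(present),
    })
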