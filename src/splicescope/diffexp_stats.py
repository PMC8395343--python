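"""Two-group comparison statistics: Welch tests, log2 fold-changes,
row-scaled heatmap matrices, and gene-list intersections."""

from __future__ import annotations

import logging
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_io import ExpressionMatrix

logger = logging.getLogger(__name__)


def welch_test(values_g1: Sequence[float], values_g2: Sequence[float]) -> tuple[float, float]:
    """Welch's unequal-variance t-test (two-sided).

    Degenerate inputs follow the usual conventions: zero variance in both
    groups with equal means gives (0, 1); zero variance with different
    means gives (+/-inf, 0) and a logged flag.
    """
    a = np.asarray(values_g1, dtype=float)
    b = np.asarray(values_g2, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two values per group")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("non-finite values in input")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        logger.warning("welch_test: zero variance with different means")
        return (math.inf if a.mean() > b.mean() else -math.inf), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def log2fc(mean_g1: float, mean_g2: float, pseudocount: float = 1.0) -> float:
    """log2((m1 + pc) / (m2 + pc)); the pseudocount keeps zeros finite."""
    if mean_g1 < 0 or mean_g2 < 0:
        raise ValueError("means must be non-negative")
    return math.log2((mean_g1 + pseudocount) / (mean_g2 + pseudocount))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    return multipletests(p_values, method="fdr_bh")[1]


def differential_expression(
    expr: ExpressionMatrix, alpha: float = 0.05, pseudocount: float = 1.0
) -> pd.DataFrame:
    """Per-feature Welch test on log2(x + pc), group 1 vs group 2."""
    g1, g2 = expr.group_names
    rows = []
    for feature in expr.values.index:
        v1 = expr.group_values(feature, g1)
        v2 = expr.group_values(feature, g2)
        t, p = welch_test(np.log2(v1 + pseudocount), np.log2(v2 + pseudocount))
        rows.append(
            {
                "feature": feature,
                "log2fc": log2fc(float(v1.mean()), float(v2.mean()), pseudocount),
                "t": t,
                "p": p,
            }
        )
    df = pd.DataFrame(rows, columns=["feature", "log2fc", "t", "p"])
    if len(df):
        df["p_adj"] = bh_adjust(df["p"])
        df["significant"] = df["p_adj"] < alpha
    else:
        df["p_adj"] = pd.Series(dtype=float)
        df["significant"] = pd.Series(dtype=bool)
    return df


def scale_heatmap_matrix(expr: ExpressionMatrix, features: Sequence[str]) -> pd.DataFrame:
    """Row-scaled matrix for heatmap display: log2(x + 1) per cell, then
    each row centred to mean 0 and scaled to unit variance (sample sd).
    Constant rows become all-zero and are logged."""
    if not len(features):
        raise ValueError("feature subset must be non-empty")
    unknown = [f for f in features if f not in expr.values.index]
    if unknown:
        raise KeyError(f"unknown feature ids: {unknown}")
    sub = np.log2(expr.values.loc[list(features)].astype(float) + 1.0)
    centred = sub.sub(sub.mean(axis=1), axis=0)
    sd = sub.std(axis=1, ddof=1)
    constant = sd == 0
    if constant.any():
        logger.info("scale_heatmap_matrix: %d constant rows set to zero", int(constant.sum()))
    sd_safe = sd.mask(constant, 1.0)
    scaled = centred.div(sd_safe, axis=0)
    scaled.loc[constant] = 0.0
    return scaled


def intersect_gene_lists(
    spliced_genes: Sequence[str],
    external_genes: Sequence[str],
    ortholog_map: Mapping[str, Sequence[str]],
) -> pd.DataFrame:
    """Map external (e.g. human GWAS) symbols through an ortholog map and
    intersect with the spliced-gene set, case-insensitively.

    Returns one row per (external symbol, native gene) match with an
    ``ambiguous`` flag for external symbols mapping to several native
    genes.  An empty map yields an empty intersection with a warning.
    """
    if not ortholog_map:
        logger.warning("intersect_gene_lists: empty ortholog map")
    spliced_by_lower = {}
    for g in spliced_genes:
        spliced_by_lower.setdefault(g.lower(), g)
    map_by_lower: dict[str, list[str]] = {}
    for ext, natives in ortholog_map.items():
        map_by_lower.setdefault(ext.lower(), []).extend(natives)

    rows = []
    seen: set[tuple[str, str]] = set()
    for ext in external_genes:
        natives = map_by_lower.get(ext.lower(), [])
        ambiguous = len(natives) > 1
        for native in natives:
            match = spliced_by_lower.get(native.lower())
            if match is None:
                continue
            key = (ext.lower(), match.lower())
            if key in seen:
                continue
            seen.add(key)
            rows.append(
                {"external_symbol": ext, "gene": match, "ambiguous": ambiguous}
            )
    return pd.DataFrame(rows, columns=["external_symbol", "gene", "ambiguous"])
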