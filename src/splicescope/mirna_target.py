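"""miRNA differential expression and canonical seed-match target prediction.

Seed sites in a 3'UTR are classified by the canonical hierarchy: the 6mer
core is the reverse complement of miRNA positions 2-7; adding a match to
position 8 gives a 7mer-m8; an adenosine opposite position 1 gives a
7mer-A1; both together give an 8mer.  Differential miRNAs are called with a
Welch t-test on log2(x + 1) values and BH adjustment; candidate regulators
of a gene are the miRNAs significant in the required direction that carry
at least one site of the minimum class (default 7mer) in the gene's 3'UTR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .core_io import ExpressionMatrix, reverse_complement, complement_base
from .diffexp_stats import welch_test, log2fc

logger = logging.getLogger(__name__)

SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1", "6mer")
SITE_PRIORITY = {"8mer": 3, "7mer-m8": 2, "7mer-A1": 1, "6mer": 0}


@dataclass(frozen=True)
class SeedSite:
    mirna: str
    offset: int  # 0-based offset of the site's 5' end in the UTR
    site_type: str


def _normalize(seq: str) -> str:
    return seq.upper().replace("U", "T")


def find_seed_sites(
    mirna_sequence: str, utr_sequence: str, mirna_id: str = "miRNA"
) -> list[SeedSite]:
    """Canonical seed sites of one miRNA in one UTR (highest-priority type
    per locus).  RNA and DNA alphabets are equivalent (U == T)."""
    m = _normalize(mirna_sequence)
    utr = _normalize(utr_sequence)
    if len(m) < 8:
        raise ValueError("miRNA must be at least 8 nt")
    seed = m[1:8]  # positions 2-8, 0-based slice
    if set(seed) - set("ACGT"):
        raise ValueError(f"ambiguous bases in miRNA seed {seed!r}")
    core = reverse_complement(m[1:7])  # 6mer core: positions 2-7
    m8_comp = complement_base(m[7])

    sites: list[SeedSite] = []
    for i in range(len(utr) - len(core) + 1):
        if utr[i : i + 6] != core:
            continue
        has_m8 = i > 0 and utr[i - 1] == m8_comp
        has_a1 = i + 6 < len(utr) and utr[i + 6] == "A"
        if has_m8 and has_a1:
            site_type, start = "8mer", i - 1
        elif has_m8:
            site_type, start = "7mer-m8", i - 1
        elif has_a1:
            site_type, start = "7mer-A1", i
        else:
            site_type, start = "6mer", i
        sites.append(SeedSite(mirna_id, start, site_type))
    return sites


def best_site(sites: Sequence[SeedSite]) -> SeedSite | None:
    if not sites:
        return None
    return max(sites, key=lambda s: (SITE_PRIORITY[s.site_type], -s.offset))


def differential_mirnas(
    mirnas: ExpressionMatrix,
    alpha: float = 0.05,
    pseudocount: float = 1.0,
    full: bool = False,
) -> pd.DataFrame:
    """Welch t-test on log2(x + pc) per miRNA, group 1 vs group 2, with BH
    adjustment.  Returns the significant rows (or all rows if ``full``)."""
    g1, g2 = mirnas.group_names
    rows = []
    for mirna in mirnas.values.index:
        v1 = mirnas.group_values(mirna, g1)
        v2 = mirnas.group_values(mirna, g2)
        if (v1 == 0).all() and (v2 == 0).all():
            logger.info("differential_mirnas: %s all-zero, skipped", mirna)
            continue
        t, p = welch_test(np.log2(v1 + pseudocount), np.log2(v2 + pseudocount))
        lfc = log2fc(float(v1.mean()), float(v2.mean()), pseudocount)
        rows.append(
            {
                "mirna": mirna,
                "log2fc": lfc,
                "t": t,
                "p": p,
                "direction": 1 if lfc >= 0 else -1,
            }
        )
    df = pd.DataFrame(rows, columns=["mirna", "log2fc", "t", "p", "direction"])
    if len(df):
        df["p_adj"] = multipletests(df["p"], method="fdr_bh")[1]
        df["significant"] = df["p_adj"] < alpha
    else:
        df["p_adj"] = pd.Series(dtype=float)
        df["significant"] = pd.Series(dtype=bool)
    if full:
        return df
    return df[df["significant"]].reset_index(drop=True)


def candidate_regulators(
    diff_mirnas: pd.DataFrame,
    mirna_sequences: Mapping[str, str],
    utr_sequence: str,
    required_direction: int = 1,
    min_site: str = "7mer-m8",
) -> pd.DataFrame:
    """miRNAs significant in ``required_direction`` with >= 1 seed site of
    class ``min_site`` or better in the UTR, ranked by (site class, p)."""
    min_priority = SITE_PRIORITY[min_site]
    rows = []
    for _, row in diff_mirnas.iterrows():
        if row["direction"] != required_direction:
            continue
        seq = mirna_sequences.get(row["mirna"])
        if seq is None:
            logger.warning("candidate_regulators: no sequence for %s", row["mirna"])
            continue
        site = best_site(find_seed_sites(seq, utr_sequence, row["mirna"]))
        if site is None or SITE_PRIORITY[site.site_type] < min_priority:
            continue
        rows.append(
            {
                "mirna": row["mirna"],
                "site_type": site.site_type,
                "offset": site.offset,
                "log2fc": row["log2fc"],
                "p_adj": row["p_adj"],
            }
        )
    df = pd.DataFrame(rows, columns=["mirna", "site_type", "offset", "log2fc", "p_adj"])
    if len(df):
        df["_prio"] = df["site_type"].map(SITE_PRIORITY)
        df = (
            df.sort_values(["_prio", "p_adj"], ascending=[False, True])
            .drop(columns="_prio")
            .reset_index(drop=True)
        )
    return df
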