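"""Trait identification for significant trans-eQTLs with sFDR control.

Conditional on a SNP passing the global test, the traits it regulates are
discovered by Benjamini-Hochberg applied to that SNP's trans-trait p-values
at the reduced level α·m/M (m significant SNPs out of M tested), which
controls the selected-SNP false discovery rate at α.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = ["SFDRConfig", "bh_discoveries", "identify_traits"]


@dataclass
class SFDRConfig:
    alpha: float = 0.05
    m_total: int = 1
    m_sig: int = 0

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 <= self.m_sig <= self.m_total:
            raise ValueError("need 0 <= m_sig <= M")

    @property
    def per_snp_level(self) -> float:
        return self.alpha * self.m_sig / self.m_total


def bh_discoveries(pvalues: np.ndarray, level: float) -> np.ndarray:
    """Benjamini-Hochberg step-up: indices of discovered hypotheses."""
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    p = np.asarray(pvalues, dtype=float)
    reject, *_ = multipletests(p, alpha=level, method="fdr_bh")
    return np.flatnonzero(reject)


def identify_traits(
    scan_results: pd.DataFrame,
    per_snp_pvalues: dict[str, tuple[list[str], np.ndarray]],
    config: SFDRConfig,
    global_cutoff: float,
) -> pd.DataFrame:
    """For each SNP with global p-value ≤ cutoff, discover its traits by BH
    at level α·m_sig/M.

    ``per_snp_pvalues`` maps snp_id -> (trait_ids, p-values) over the SNP's
    trans traits.  Returns a table (snp_id, trait_id, pvalue, rank, level).
    """
    sig = scan_results.loc[scan_results["pvalue"] <= global_cutoff, "snp_id"]
    m_sig = len(sig)
    cfg = SFDRConfig(alpha=config.alpha, m_total=config.m_total, m_sig=m_sig)
    rows = []
    if m_sig == 0:
        return pd.DataFrame(columns=["snp_id", "trait_id", "pvalue", "rank", "level"])
    level = cfg.per_snp_level
    for snp in sig:
        trait_ids, pvals = per_snp_pvalues[snp]
        pvals = np.asarray(pvals, dtype=float)
        disc = bh_discoveries(pvals, level)
        order = np.argsort(pvals)
        rank_of = np.empty_like(order)
        rank_of[order] = np.arange(1, len(pvals) + 1)
        for i in disc:
            rows.append((snp, trait_ids[i], float(pvals[i]),
                         int(rank_of[i]), level))
    return pd.DataFrame(rows, columns=["snp_id", "trait_id", "pvalue",
                                       "rank", "level"])
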