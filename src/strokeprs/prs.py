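"""Weighted polygenic risk score (PRS) and quintile-based genetic risk groups.

The score for participant *i* is the weighted allele count

.. math:: \\mathrm{PRS}_i = \\sum_j g_{ij} w_j

where ``g_ij`` in {0, 1, 2} counts risk alleles at SNP *j* and ``w_j`` is the
externally derived per-allele weight.  Participants are grouped into *low*
(bottom quintile), *intermediate* (quintiles 2-4) and *high* (top quintile)
genetic risk by the empirical 20th/80th percentiles of the score.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

GENETIC_GROUPS = ["low", "intermediate", "high"]


class MissingSnpError(KeyError):
    """A panel SNP is absent from the genotype matrix."""


class MissingGenotypeError(ValueError):
    """Genotype calls contain missing values (no silent imputation)."""


def compute_prs(genotypes: pd.DataFrame, panel: pd.DataFrame) -> pd.DataFrame:
    """Compute the raw and standardized PRS for every participant.

    Parameters
    ----------
    genotypes
        One row per participant (index = participant id), one column per
        SNP id, values in {0, 1, 2}.
    panel
        SNP weight table with columns ``snp_id`` and ``weight`` (risk-allele
        orientation is assumed to match the genotype coding).

    Returns
    -------
    DataFrame indexed like ``genotypes`` with columns ``prs_raw`` and
    ``prs_std`` (z-scored on the scoring sample).
    """
    snp_ids = list(panel["snp_id"])
    if len(set(snp_ids)) != len(snp_ids):
        raise ValueError("duplicate snp_id in panel")
    missing = [s for s in snp_ids if s not in genotypes.columns]
    if missing:
        raise MissingSnpError(
            f"{len(missing)} panel SNPs absent from genotype matrix: "
            f"{missing[:10]}{'...' if len(missing) > 10 else ''}"
        )
    g = genotypes[snp_ids].to_numpy(dtype=float)
    if np.isnan(g).any():
        raise MissingGenotypeError("missing genotype calls; refusing to impute")
    w = panel["weight"].to_numpy(dtype=float)
    raw = g @ w
    sd = raw.std(ddof=0)
    std = (raw - raw.mean()) / sd if sd > 0 else np.zeros_like(raw)
    return pd.DataFrame({"prs_raw": raw, "prs_std": std}, index=genotypes.index)


def assign_genetic_groups(prs: np.ndarray | pd.Series) -> pd.Categorical:
    """Assign low / intermediate / high genetic risk by PRS quintiles.

    Boundaries are the empirical 20th and 80th percentiles (``method="lower"``,
    i.e. the lower order statistic at ties).  Values at a boundary fall in the
    lower-risk group: low is ``prs <= q20``, high is ``prs > q80``.
    """
    x = np.asarray(prs, dtype=float)
    if np.unique(x).size < 5:
        raise ValueError("quintile groups undefined: fewer than 5 distinct PRS values")
    q20, q80 = np.quantile(x, [0.2, 0.8], method="lower")
    codes = np.where(x <= q20, 0, np.where(x > q80, 2, 1))
    return pd.Categorical.from_codes(codes, categories=GENETIC_GROUPS, ordered=True)
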