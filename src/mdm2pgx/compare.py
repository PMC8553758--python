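"""COMPARE-style profile correlation.

The COMPARE strategy infers a query compound's mechanism of action by
rank-correlating its per-cell-line potency profile (Abs IC50) against a
library of reference compound profiles: mechanistically related compounds
show high positive Spearman rho over the shared lines.  Censored IC50s
participate at their clamped values, as they do in the source profiles.
"""

from __future__ import annotations

import logging

import pandas as pd

from .panel import AnalysisConfig
from .stats import bh_adjust, spearman

logger = logging.getLogger("mdm2pgx")

COMPARE_COLUMNS = ["reference_drug_id", "n_overlap", "rho", "p", "adj_p"]


def compare_profile(
    query: pd.DataFrame,
    reference: pd.DataFrame,
    config: AnalysisConfig,
) -> tuple[pd.DataFrame, list[str]]:
    """Correlate one drug's Abs IC50 profile against a reference matrix.

    ``query`` is a long-format sensitivity table for a single drug
    (columns cl_id, abs_ic50_uM); ``reference`` is a drug x cell-line Abs
    IC50 matrix.  Each reference drug with at least
    ``config.min_compare_overlap`` shared cell lines is scored with
    Spearman rho (average ranks, two-sided t-approximation p) over the
    shared pairs; BH adjustment runs across all scored drugs.  Returns
    the result table sorted by rho descending, plus the list of reference
    drugs skipped for insufficient overlap.
    """
    if query["drug_id"].nunique() > 1:
        raise ValueError("query must contain a single drug")
    profile = query.set_index("cl_id")["abs_ic50_uM"].astype(float)
    profile = profile[profile.index.isin(reference.columns)]

    rows, skipped = [], []
    for drug_id, ref_row in reference.iterrows():
        ref = ref_row.dropna()
        shared = profile.index.intersection(ref.index)
        if len(shared) < config.min_compare_overlap:
            skipped.append(str(drug_id))
            continue
        res = spearman(profile.loc[shared].to_numpy(), ref.loc[shared].to_numpy())
        rows.append(
            {
                "reference_drug_id": str(drug_id),
                "n_overlap": len(shared),
                "rho": res.statistic,
                "p": res.p,
            }
        )
    if not rows:
        logger.warning("compare_profile: no reference drug meets the overlap floor")
        return pd.DataFrame(columns=COMPARE_COLUMNS), skipped
    table = pd.DataFrame(rows)
    table["adj_p"] = bh_adjust(table["p"].to_numpy())
    table = table.sort_values("rho", ascending=False, kind="stable").reset_index(drop=True)
    return table[COMPARE_COLUMNS], skipped
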