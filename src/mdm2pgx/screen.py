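"""Genome-wide association screens for drug sensitivity.

Two arms share the machinery:

* the *genomic* arm binarizes alterations (mutation, amplification at
  copy number >= 8, homozygous deletion at 0) and tests each gene's
  altered-vs-unaltered Abs IC50 split with the Wilcoxon rank-sum test;
* the *expression* arm runs a triple test per feature — Welch t between
  the sensitive and resistant dichotomy groups, the empirical-Bayes
  moderated t, and Spearman correlation against Abs IC50 — and calls a
  feature significant only when its BH-adjusted p clears the threshold in
  all three, a deliberately stringent intersection rule.

Probe-level hits are collapsed to one probe per gene by annotation
quality score, filtered on |log2 fold difference| > 0.5, clustered
(correlation distance, Ward linkage), and tested for gene-set
over-representation.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .panel import AlterationData, AnalysisConfig, ExpressionMatrix
from .stats import (
    TestResult,
    bh_adjust,
    hypergeom_enrichment,
    moderated_t,
    proportion_test,
    wilcoxon_rank_sum,
)

logger = logging.getLogger("mdm2pgx")


# ---------------------------------------------------------------------------
# Genomic arm
# ---------------------------------------------------------------------------

def binarize_alterations(
    alterations: AlterationData, config: AnalysisConfig
) -> pd.DataFrame:
    """Collapse mutation and copy-number matrices to one binary matrix.

    A (gene, line) entry is 1 iff the gene is mutated, amplified
    (SCNA >= config.scna_amp_threshold) or homozygously deleted
    (SCNA == config.scna_del_value) in that line.  Gene sets of the two
    matrices are unioned with zero-fill.
    """
    mut = alterations.mutation_matrix
    scna = alterations.scna_matrix
    cl_ids = mut.columns.union(scna.columns, sort=False)
    genes = mut.index.union(scna.index, sort=False)
    if not mut.index.equals(scna.index):
        logger.info(
            "binarize_alterations: mutation and SCNA gene sets differ; "
            "taking the union with zero-fill (%d genes)", len(genes),
        )
    mut_full = mut.reindex(index=genes, columns=cl_ids).fillna(0).astype(int)
    scna_full = scna.reindex(index=genes, columns=cl_ids)
    amp = (scna_full >= config.scna_amp_threshold).fillna(False)
    dele = (scna_full == config.scna_del_value).fillna(False)
    return ((mut_full == 1) | amp | dele).astype(int)


def genomic_screen(
    binary: pd.DataFrame, abs_ic50: pd.Series, config: AnalysisConfig
) -> pd.DataFrame:
    """Per-gene Wilcoxon association of alteration status with Abs IC50.

    Genes altered in fewer than two lines (or altered in all lines) are
    excluded.  Direction is ``resistance_associated`` when the altered
    group's median Abs IC50 is higher, ``sensitivity_associated`` when
    lower.  BH adjustment runs across the tested genes.
    """
    shared = [c for c in binary.columns if c in abs_ic50.index]
    binary = binary[shared]
    ic50 = abs_ic50.loc[shared].to_numpy(dtype=float)
    rows = []
    for gene, row in binary.iterrows():
        altered = row.to_numpy() == 1
        if altered.sum() < 2 or (~altered).sum() < 1:
            continue
        res = wilcoxon_rank_sum(ic50[altered], ic50[~altered])
        diff = float(np.median(ic50[altered]) - np.median(ic50[~altered]))
        rows.append(
            {
                "feature_id": gene,
                "n_altered": int(altered.sum()),
                "statistic": res.statistic,
                "p": res.p,
                "median_diff_uM": diff,
                "direction": (
                    "resistance_associated" if diff > 0
                    else "sensitivity_associated" if diff < 0 else "unset"
                ),
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["feature_id", "n_altered", "statistic", "p", "adj_p",
                     "median_diff_uM", "direction"]
        )
    table = pd.DataFrame(rows)
    table["adj_p"] = bh_adjust(table["p"].to_numpy())
    return table.sort_values("p", kind="stable").reset_index(drop=True)[
        ["feature_id", "n_altered", "statistic", "p", "adj_p",
         "median_diff_uM", "direction"]
    ]


# ---------------------------------------------------------------------------
# Expression arm
# ---------------------------------------------------------------------------

def filter_probes(matrix: ExpressionMatrix, config: AnalysisConfig) -> ExpressionMatrix:
    """Drop probes lacking consistent expression.

    A probe is removed only when *all* its sample values fall below the
    floor (default log2 intensity 5); one value at or above the floor is
    enough to retain it.
    """
    if matrix.values.empty:
        raise ValueError("empty expression matrix")
    keep = (matrix.values >= config.probe_floor).any(axis=1)
    if not keep.any():
        raise ValueError("probe floor removed every probe")
    return ExpressionMatrix(matrix.values.loc[keep], matrix.level)


def _vectorized_spearman(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Spearman rho of X against y with t-approximation p.

    Average ranks for ties; algebraically identical to calling
    :func:`mdm2pgx.stats.spearman` per row (asserted in the tests).
    """
    n = X.shape[1]
    rx = sps.rankdata(X, axis=1)
    ry = sps.rankdata(y)
    rx = rx - rx.mean(axis=1, keepdims=True)
    ry = ry - ry.mean()
    denom = np.sqrt((rx**2).sum(axis=1) * (ry**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (rx @ ry) / denom
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * sps.t.sf(np.abs(t), n - 2)
    p = np.where(np.isnan(rho), 1.0, np.where(np.abs(rho) >= 1.0, 0.0, p))
    return rho, np.clip(p, np.finfo(float).tiny, 1.0)


def expression_screen(
    matrix: ExpressionMatrix,
    abs_ic50: pd.Series,
    labels: pd.Series,
    config: AnalysisConfig,
) -> pd.DataFrame:
    """Triple-test association of each feature's expression with response.

    Per feature: Welch t (sensitive vs resistant dichotomy groups),
    moderated t on the same split, and Spearman of expression vs Abs
    IC50.  BH adjustment within each test; ``significant`` requires
    adjusted p < config.adj_p_threshold in all three.  The log2 fold
    difference is the sensitive-group mean minus the resistant-group
    mean, so positive values mark sensitivity-associated expression.
    """
    cl_ids = [c for c in matrix.cl_ids if c in labels.index and c in abs_ic50.index]
    X = matrix.values[cl_ids].to_numpy(dtype=float)
    lab = labels.loc[cl_ids].to_numpy()
    y = abs_ic50.loc[cl_ids].to_numpy(dtype=float)
    sens = lab == "sensitive"
    res = lab == "resistant"
    if sens.sum() < 2 or res.sum() < 2:
        raise ValueError("each dichotomy group needs at least 2 lines")

    # Welch t, vectorised (identical to stats.two_sample_t per feature).
    t_stat, t_p = sps.ttest_ind(X[:, sens], X[:, res], axis=1, equal_var=False)
    degen = np.isnan(t_stat)
    t_stat = np.where(degen, 0.0, t_stat)
    t_p = np.where(degen, 1.0, t_p)

    mod_results, d0, s0_2 = moderated_t(X, sens.astype(int))
    mod_p = np.array([r.p for r in mod_results])
    mod_t = np.array([r.statistic for r in mod_results])

    rho, sp_p = _vectorized_spearman(X, y)

    fold = X[:, sens].mean(axis=1) - X[:, res].mean(axis=1)
    table = pd.DataFrame(
        {
            "feature_id": matrix.feature_ids,
            "t_stat": t_stat,
            "t_p": t_p,
            "t_adj_p": bh_adjust(t_p),
            "moderated_t": mod_t,
            "moderated_p": mod_p,
            "moderated_adj_p": bh_adjust(mod_p),
            "spearman_rho": rho,
            "spearman_p": sp_p,
            "spearman_adj_p": bh_adjust(sp_p),
            "log2_fold_diff": fold,
        }
    )
    table["significant"] = (
        (table["t_adj_p"] < config.adj_p_threshold)
        & (table["moderated_adj_p"] < config.adj_p_threshold)
        & (table["spearman_adj_p"] < config.adj_p_threshold)
    )
    table["direction"] = np.where(
        table["log2_fold_diff"] > 0, "sensitivity_associated",
        np.where(table["log2_fold_diff"] < 0, "resistance_associated", "unset"),
    )
    table.attrs["moderated_d0"] = d0
    table.attrs["moderated_s0_2"] = s0_2
    return table


def select_gene_probes(
    table: pd.DataFrame, annotation: pd.DataFrame
) -> pd.DataFrame:
    """Collapse a probe-level table to one representative probe per gene.

    Keeps the probe with the highest annotation quality score per gene
    (ties broken by lexicographically smallest probe_id); probes without
    a gene mapping are dropped.  Falls back to the probe with the
    highest mean expression rank when quality scores are missing.
    """
    ann = annotation.copy()
    if ann["quality_score"].isna().all():
        logger.warning(
            "select_gene_probes: no quality scores; falling back to per-probe "
            "mean expression order"
        )
        order = {pid: i for i, pid in enumerate(table["feature_id"])}
        ann["quality_score"] = [-order.get(p, np.inf) for p in ann["probe_id"]]
    merged = table.merge(
        ann[["probe_id", "gene_symbol", "quality_score"]],
        left_on="feature_id", right_on="probe_id", how="inner",
    )
    merged = merged[merged["gene_symbol"].notna()]
    merged = merged.sort_values(
        ["gene_symbol", "quality_score", "probe_id"],
        ascending=[True, False, True], kind="stable",
    )
    best = merged.groupby("gene_symbol", sort=True).head(1).copy()
    best["probe_id"] = best["feature_id"]
    best["feature_id"] = best["gene_symbol"]
    return best.drop(columns=["gene_symbol"]).reset_index(drop=True)


def fold_difference_filter(table: pd.DataFrame, config: AnalysisConfig) -> pd.DataFrame:
    """Keep features with |log2 fold difference| strictly above the threshold."""
    mask = table["log2_fold_diff"].abs() > config.fold_diff_threshold
    return table[mask].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Clustering and enrichment
# ---------------------------------------------------------------------------

def cluster_panel(
    matrix: ExpressionMatrix,
    labels: pd.Series,
    k: int,
) -> tuple[pd.Series, pd.DataFrame, TestResult | None]:
    """Agglomerative clustering of cell lines on selected genes.

    Distance = 1 - Pearson correlation between line expression profiles,
    Ward linkage, cut at ``k`` clusters.  Returns (cluster label per
    line, per-cluster response-rate table, proportion-test result across
    clusters; the test is skipped for k = 1).
    """
    X = matrix.values.to_numpy(dtype=float).T  # lines x genes
    n = X.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if n < k:
        raise ValueError("fewer lines than clusters")
    cl_index = pd.Index(matrix.cl_ids, name="cl_id")
    if k == 1:
        assignment = pd.Series(1, index=cl_index, name="cluster")
    else:
        corr = np.corrcoef(X)
        if np.isnan(corr).any():
            raise ValueError("zero-variance profiles: correlation distance undefined")
        dist = 1.0 - corr
        np.fill_diagonal(dist, 0.0)
        if dist.max() <= 1e-12:
            raise ValueError("all profiles identical; cannot cut into clusters")
        Z = linkage(squareform(dist, checks=False), method="ward")
        assignment = pd.Series(
            fcluster(Z, t=k, criterion="maxclust"), index=cl_index, name="cluster"
        )
        if assignment.nunique() < k:
            raise ValueError("could not separate the requested number of clusters")

    lab = labels.loc[cl_index]
    rates = pd.DataFrame(
        {
            "n": assignment.groupby(assignment).size(),
            "n_sensitive": (lab == "sensitive").groupby(assignment.values).sum().values,
        }
    )
    rates["response_rate"] = rates["n_sensitive"] / rates["n"]
    rates.index.name = "cluster"
    test = None
    if k > 1:
        test = proportion_test(
            rates["n_sensitive"].to_numpy(), rates["n"].to_numpy()
        )
    return assignment, rates, test


def enrich(
    selected: list[str],
    collection: dict[str, list[str]],
    universe: list[str],
) -> pd.DataFrame:
    """Hypergeometric over-representation of each gene set in a selection.

    ``universe`` should be the genes actually tested (surviving the probe
    floor and probe-to-gene selection).  Sets disjoint from the universe
    are skipped with a warning; BH adjustment runs across scored sets,
    sorted by ascending adjusted p.
    """
    if not collection:
        raise ValueError("empty gene-set collection")
    uni = set(universe)
    sel = set(selected) & uni
    rows = []
    if not sel:
        return pd.DataFrame(
            columns=["set_name", "n_set", "n_overlap", "p", "adj_p"]
        )
    for name, genes in collection.items():
        in_universe = set(genes) & uni
        if not in_universe:
            logger.warning("enrich: gene set %r disjoint from universe; skipped", name)
            continue
        res = hypergeom_enrichment(in_universe, uni, sel)
        rows.append(
            {
                "set_name": name,
                "n_set": len(in_universe),
                "n_overlap": int(res.statistic),
                "p": res.p,
            }
        )
    table = pd.DataFrame(rows)
    if table.empty:
        return pd.DataFrame(columns=["set_name", "n_set", "n_overlap", "p", "adj_p"])
    table["adj_p"] = bh_adjust(table["p"].to_numpy())
    return table.sort_values(["adj_p", "p"], kind="stable").reset_index(drop=True)


def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT gene-set file: name <tab> description <tab> genes..."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets
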