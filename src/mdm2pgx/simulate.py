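"""Synthetic cell-line panel generator.

Emulates the statistical structure of a ~237-line MDM2-inhibitor screening
panel: ~69% TP53-mutant lines, log-normal within-group IC50s whose medians
separate wild-type (~1.4 µM) from mutant (~15.1 µM) lines by an order of
magnitude, discordant subgroups (wild-type-resistant, mutant-sensitive),
and an 11-gene p53-pathway expression signature coupled to sensitivity on
a gcrma-like log2 scale.

A single latent binary *pathway activity* per line drives both the IC50
group and the signature expression, which is what produces the negative
score–IC50 correlation downstream.  Everything is deterministic given the
spec's seed; sub-streams are spawned from one ``numpy`` SeedSequence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dose_response import DEFAULT_CONCENTRATION_GRID_UM, DoseResponseCurve, four_pl
from .panel import (
    SCORE_GENES,
    AlterationData,
    AnalysisConfig,
    ExpressionMatrix,
    PanelBundle,
)

# Panel composition used for the cosmetic tumour-type labels: counts per
# (sub)type in a 274-line reference panel spanning digestive, urogenital,
# respiratory, breast, sarcoma, head & neck, melanoma, CNS, skin and
# haematologic malignancies.
TUMOUR_TYPE_COUNTS = {
    "CRC": 16, "stomach": 16, "pancreas": 15, "liver_hep": 11,
    "liver_chol": 5, "oesophagus": 5, "kidney": 14, "ovary": 11,
    "bladder": 8, "prostate": 5, "uterus": 11, "NSCLC": 28, "SCLC": 10,
    "mesothelioma": 5, "breast": 15, "sarcoma": 13, "HNSC": 12,
    "melanoma": 12, "CNS_GBM": 9, "skin": 1, "leukaemia": 27, "lymphoma": 25,
}
HAEMATOLOGIC_TYPES = frozenset({"leukaemia", "lymphoma"})


@dataclass
class SimulationSpec:
    """Generating conditions for one synthetic panel.

    ``ic50_log_sd`` (log10 scale) is calibrated so that ~91% of mutant
    lines land at Abs IC50 >= 10 µM, which simultaneously puts the
    panel-wide 30th percentile near 10.7 µM.  ``signature_effect_log2`` is
    the expression shift of the 11 signature genes between low- and
    high-activity lines, centred on the 7.5 score cutoff.
    """

    n_cl: int = 237
    frac_tp53_mut: float = 0.69
    wt_median_ic50_uM: float = 1.4
    mut_median_ic50_uM: float = 15.1
    ic50_log_sd: float = 0.07
    frac_wt_resistant: float = 21 / 74
    frac_mut_sensitive: float = 14 / 163
    n_background_genes: int = 2000
    n_background_mut_genes: int = 300
    signature_effect_log2: float = 1.0
    probes_per_gene: tuple[int, int] = (1, 3)
    noise_sd_expression: float = 0.5
    tc_noise_sd: float = 3.0
    concentration_grid: tuple[float, ...] = DEFAULT_CONCENTRATION_GRID_UM
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_tp53_mut", "frac_wt_resistant", "frac_mut_sensitive"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.wt_median_ic50_uM <= 0 or self.mut_median_ic50_uM <= 0:
            raise ValueError("group median IC50s must be positive")
        grid = np.asarray(self.concentration_grid, dtype=float)
        if np.any(np.diff(grid) <= 0):
            raise ValueError("concentration grid must be strictly increasing")
        if self.n_cl < 10:
            raise ValueError("n_cl < 10: too small for the percentile machinery")


@dataclass
class GroundTruth:
    """Latent generator state, for testing planted-signal recovery."""

    activity: pd.Series            # 1 = high pathway activity (sensitive side)
    true_ic50_uM: pd.Series
    signature_genes: tuple[str, ...]
    true_class: pd.Series

    def __post_init__(self) -> None:
        if tuple(self.signature_genes) != SCORE_GENES:
            raise ValueError("signature gene list must equal the 11 score genes")


def _classify(ic50: float, config: AnalysisConfig) -> str:
    lo, hi = config.class_cutoffs_uM
    if ic50 < lo:
        return "highly_sensitive"
    return "intermediate" if ic50 < hi else "resistant"


def generate_panel(
    spec: SimulationSpec, config: AnalysisConfig | None = None
) -> tuple[PanelBundle, GroundTruth]:
    """Draw one fully annotated synthetic panel plus its ground truth.

    TP53 status is Bernoulli(frac_tp53_mut) per line.  Activity is high
    for wild-type lines except a frac_wt_resistant subset, and for a
    frac_mut_sensitive subset of mutant lines.  log10 IC50 is normal
    around the activity-group median (high -> wt median, low -> mutant
    median), truncated to the concentration grid with censoring flags.
    The 11 signature genes sit at ``7.5 - effect/2 + effect * activity``
    plus noise so high-activity lines average above the 7.5 score cutoff
    and low-activity lines below it; background genes are signal-free.
    Each gene expands into 1–3 probes; the best-quality probe per gene
    carries no offset (it is the faithful measurement), extra probes get
    random offsets.
    """
    config = config or AnalysisConfig()
    ss = np.random.SeedSequence(spec.seed)
    (r_status, r_activity, r_ic50, r_expr, r_probe, r_alt, r_type) = (
        np.random.default_rng(child) for child in ss.spawn(7)
    )
    n = spec.n_cl
    cl_ids = [f"CL{i:04d}" for i in range(n)]

    mutated = r_status.random(n) < spec.frac_tp53_mut
    high = np.where(
        mutated,
        r_activity.random(n) < spec.frac_mut_sensitive,
        r_activity.random(n) >= spec.frac_wt_resistant,
    )

    log_median = np.where(
        high, np.log10(spec.wt_median_ic50_uM), np.log10(spec.mut_median_ic50_uM)
    )
    true_ic50 = 10.0 ** (log_median + spec.ic50_log_sd * r_ic50.standard_normal(n))
    grid = np.asarray(spec.concentration_grid, dtype=float)
    clipped = np.clip(true_ic50, grid.min(), grid.max())
    censor = np.where(
        true_ic50 > grid.max(), "at_highest",
        np.where(true_ic50 < grid.min(), "at_lowest", "none"),
    )

    # Cosmetic tumour-type labels from the fixed composition table.
    types = list(TUMOUR_TYPE_COUNTS)
    probs = np.array(list(TUMOUR_TYPE_COUNTS.values()), dtype=float)
    probs /= probs.sum()
    tumour_type = r_type.choice(types, size=n, p=probs)

    cell_lines = pd.DataFrame(
        {
            "tumour_type": tumour_type,
            "histology_subtype": tumour_type,
            "lineage": [
                "haematologic" if t in HAEMATOLOGIC_TYPES else "solid"
                for t in tumour_type
            ],
            "tp53_status": np.where(mutated, "mutated", "wild_type"),
        },
        index=pd.Index(cl_ids, name="cl_id"),
    )

    sensitivity = pd.DataFrame(
        {
            "cl_id": cl_ids,
            "drug_id": "MI-773",
            "abs_ic50_uM": clipped,
            "rel_ic50_uM": clipped,
            "censor": censor,
            "response_class": [_classify(v, config) for v in clipped],
        }
    )

    # Gene-level signal: signature genes follow activity, background is noise.
    baseline_sig = 7.5 - spec.signature_effect_log2 / 2.0
    signature = np.tile(
        baseline_sig + spec.signature_effect_log2 * high.astype(float), (11, 1)
    )
    bg_genes = [f"BG{i:04d}" for i in range(spec.n_background_genes)]
    bg_baseline = np.clip(r_expr.normal(7.0, 2.0, size=spec.n_background_genes), 2.0, 14.0)
    background = np.tile(bg_baseline[:, None], (1, n))
    gene_values = np.vstack([signature, background])
    gene_values = gene_values + spec.noise_sd_expression * r_expr.standard_normal(
        gene_values.shape
    )
    gene_ids = list(SCORE_GENES) + bg_genes

    # Probe expansion with per-probe offsets and quality scores.
    lo_p, hi_p = spec.probes_per_gene
    probe_rows, probe_ids, ann_rows = [], [], []
    for gi, gene in enumerate(gene_ids):
        k = int(r_probe.integers(lo_p, hi_p + 1))
        qualities = r_probe.uniform(0.0, 1.0, size=k)
        best = int(np.argmax(qualities))
        for j in range(k):
            offset = 0.0 if j == best else float(r_probe.normal(0.0, 0.5))
            pid = f"{gene}_p{j}"
            probe_ids.append(pid)
            probe_rows.append(gene_values[gi] + offset)
            ann_rows.append(
                {"probe_id": pid, "gene_symbol": gene, "quality_score": float(qualities[j])}
            )
    expression = ExpressionMatrix(
        pd.DataFrame(
            np.asarray(probe_rows),
            index=pd.Index(probe_ids, name="probe_id"),
            columns=cl_ids,
        ),
        level="probe",
    )
    probe_annotation = pd.DataFrame(ann_rows)

    # Alterations: TP53 mutations mirror the status; background mutation
    # genes and copy-number events are independent of response.
    mut_rows = {"TP53": mutated.astype(int)}
    freqs = r_alt.uniform(0.02, 0.25, size=spec.n_background_mut_genes)
    for i, f in enumerate(freqs):
        mut_rows[f"MUTG{i:04d}"] = (r_alt.random(n) < f).astype(int)
    mutation_matrix = pd.DataFrame(mut_rows, index=cl_ids).T
    mutation_matrix.index.name = "gene"

    scna_genes = ["MDM2"] + [f"CNG{i:04d}" for i in range(100)]
    scna = np.full((len(scna_genes), n), 2, dtype=int)
    scna += r_alt.integers(0, 3, size=scna.shape)  # moderate 2-4 background
    events = r_alt.random(scna.shape)
    scna[events < 0.01] = 0                         # rare homozygous deletion
    scna[(events >= 0.01) & (events < 0.02)] = 9    # rare amplification
    scna[0, :] = np.clip(scna[0, :], 2, 4)          # MDM2: moderate only
    scna_matrix = pd.DataFrame(
        scna, index=pd.Index(scna_genes, name="gene"), columns=cl_ids
    )

    bundle = PanelBundle(
        cell_lines=cell_lines,
        sensitivity=sensitivity,
        expression=expression,
        probe_annotation=probe_annotation,
        alterations=AlterationData(mutation_matrix, scna_matrix),
    )
    truth = GroundTruth(
        activity=pd.Series(high.astype(int), index=cl_ids, name="activity"),
        true_ic50_uM=pd.Series(true_ic50, index=cl_ids, name="true_ic50_uM"),
        signature_genes=SCORE_GENES,
        true_class=pd.Series(
            [_classify(v, config) for v in clipped], index=cl_ids, name="true_class"
        ),
    )
    return bundle, truth


def generate_curves(
    spec: SimulationSpec, truth: GroundTruth
) -> list[DoseResponseCurve]:
    """T/C% concentration series for every line.

    Each curve is the 4PL (top=100, bottom=0, hill=1, ec50=true IC50)
    evaluated on the spec's grid plus Gaussian noise (sd ``tc_noise_sd``
    T/C points), floored at 0.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(8)[-1])
    grid = np.asarray(spec.concentration_grid, dtype=float)
    curves = []
    for cl_id, ic50 in truth.true_ic50_uM.items():
        tc = four_pl(grid, 100.0, 0.0, 1.0, float(ic50))
        tc = np.maximum(tc + spec.tc_noise_sd * rng.standard_normal(len(grid)), 0.0)
        curves.append(DoseResponseCurve(cl_id, "MI-773", grid.copy(), tc))
    return curves


def generate_reference_drug_matrix(
    spec: SimulationSpec,
    n_drugs: int,
    n_correlated: int,
    truth: GroundTruth | None = None,
) -> pd.DataFrame:
    """Reference drug x cell-line Abs IC50 matrix for COMPARE testing.

    The first ``n_correlated`` drugs share the panel's latent activity
    (same group-median construction as the query drug, fresh noise), so
    their profiles have a known positive rank correlation with the query;
    the remaining drugs are log-normal noise with no relation to activity.
    """
    if n_correlated > n_drugs:
        raise ValueError("n_correlated must not exceed n_drugs")
    if truth is None:
        _, truth = generate_panel(spec)
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(9)[-1])
    high = truth.activity.to_numpy() == 1
    n = len(high)
    log_median = np.where(
        high, np.log10(spec.wt_median_ic50_uM), np.log10(spec.mut_median_ic50_uM)
    )
    rows = {}
    for d in range(n_drugs):
        if d < n_correlated:
            vals = 10.0 ** (
                log_median + 4.0 * spec.ic50_log_sd * rng.standard_normal(n)
            )
        else:
            vals = 10.0 ** rng.normal(1.0, 0.5, size=n)
        rows[f"REF{d:03d}"] = vals
    return pd.DataFrame(rows, index=truth.activity.index).T.rename_axis("drug_id")
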