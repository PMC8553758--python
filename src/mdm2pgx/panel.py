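"""Domain types, analysis configuration, and tabular I/O for cell-line panels.

A *panel bundle* collects everything the downstream analyses need about a
cell-line (CL) panel: per-line annotations (tumour type, lineage, TP53
status), per-(line, drug) sensitivity records (absolute/relative IC50 in
micromolar with censoring flags), a log2 expression matrix at probe or gene
level with probe annotations, and genomic alteration matrices (binary
mutations plus PICNIC-style integer copy-number calls in 0–14).

All tables are tab-separated UTF-8 with a single header row; matrices are
stored features-as-rows with cell lines as columns.  Missing values are
empty fields and read back as missing (never as zero — zero is a meaningful
copy-number value).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("mdm2pgx")

# ---------------------------------------------------------------------------
# Controlled vocabularies
# ---------------------------------------------------------------------------

LINEAGES = frozenset({"haematologic", "solid"})
TP53_STATUSES = frozenset({"wild_type", "mutated", "unknown"})
CENSOR_FLAGS = frozenset({"none", "at_lowest", "at_highest"})
RESPONSE_CLASSES = frozenset({"highly_sensitive", "intermediate", "resistant"})

#: The 11 p53-pathway genes whose mean log2 expression forms the predictive
#: score: direct TP53 interactors (MDM2, MDM4, PPM1D), cell cycle (CDKN1A,
#: ZMAT3, CCNG1, RRM2B), apoptosis (BAX, BCL2), DNA repair (DDB2) and
#: antioxidant defence (SESN1).
SCORE_GENES = (
    "MDM2", "MDM4", "PPM1D", "CDKN1A", "ZMAT3", "CCNG1",
    "RRM2B", "BAX", "BCL2", "DDB2", "SESN1",
)


class PanelFormatError(ValueError):
    """A file does not match the documented TSV dialect."""


class PanelIntegrityError(ValueError):
    """A bundle violates a structural invariant (e.g. duplicated cl_id)."""


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class AnalysisConfig:
    """Analysis constants.

    Defaults encode the study conventions: response classes split at 1 and
    10 µM; the sensitive/resistant dichotomy at the panel's 30th Abs-IC50
    percentile; the 11-gene predictive score with its 7.5 cutoff on the
    gcrma-like log2 scale (the cutoff is scale-bound and only meaningful on
    that scale); copy-number amplification at PICNIC >= 8 and homozygous
    deletion at 0; the probe expression floor at 5; the log2
    fold-difference filter at |fd| > 0.5; BH-adjusted significance at 0.05.
    """

    class_cutoffs_uM: tuple[float, float] = (1.0, 10.0)
    dichotomy_percentile: float = 30.0
    score_genes: tuple[str, ...] = SCORE_GENES
    score_cutoff: float = 7.5
    scna_amp_threshold: int = 8
    scna_del_value: int = 0
    scna_moderate_threshold: int = 2
    probe_floor: float = 5.0
    fold_diff_threshold: float = 0.5
    adj_p_threshold: float = 0.05
    min_compare_overlap: int = 10
    rng_seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.class_cutoffs_uM
        if not lo < hi:
            raise ValueError("class_cutoffs_uM must be strictly increasing")
        if len(self.score_genes) != 11:
            raise ValueError("score_genes must contain exactly 11 symbols")
        if not 0 < self.dichotomy_percentile < 100:
            raise ValueError("dichotomy_percentile must be in (0, 100)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PanelFormatError(f"unknown config keys: {sorted(unknown)}")
        for key in ("class_cutoffs_uM", "score_genes"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["class_cutoffs_uM"] = list(self.class_cutoffs_uM)
        data["score_genes"] = list(self.score_genes)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Features x cell-lines matrix of log2 intensities.

    ``level`` distinguishes probe-set rows (many-to-one onto genes) from
    gene-symbol rows.  Values are expected on the log2 scale (typical
    gcrma range roughly 2–15); this is a documented contract, not enforced.
    """

    values: pd.DataFrame  # index = feature ids, columns = cl_ids
    level: str  # "probe" or "gene"

    def __post_init__(self) -> None:
        if self.level not in ("probe", "gene"):
            raise ValueError(f"level must be 'probe' or 'gene', got {self.level!r}")
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].tolist()
            raise PanelIntegrityError(f"duplicated feature ids: {dupes[:5]}")
        if self.values.columns.duplicated().any():
            raise PanelIntegrityError("duplicated cl_id columns in expression matrix")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def cl_ids(self) -> list[str]:
        return list(self.values.columns)

    def restrict(self, cl_ids: list[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[:, list(cl_ids)], self.level)


@dataclass
class AlterationData:
    """Binary mutation matrix and integer SCNA matrix, genes x cell lines."""

    mutation_matrix: pd.DataFrame
    scna_matrix: pd.DataFrame

    def __post_init__(self) -> None:
        mut = self.mutation_matrix
        if not mut.isin([0, 1]).all().all():
            raise PanelIntegrityError("mutation matrix entries must be 0 or 1")
        scna = self.scna_matrix
        vals = scna.to_numpy()
        finite = vals[~pd.isna(vals)]
        if len(finite) and (
            (finite < 0).any() or (finite > 14).any()
            or not np.allclose(finite, np.round(finite))
        ):
            raise PanelIntegrityError("SCNA entries must be integers in [0, 14]")

    def restrict(self, cl_ids: list[str]) -> "AlterationData":
        ids = list(cl_ids)
        return AlterationData(
            self.mutation_matrix.loc[:, [c for c in ids if c in self.mutation_matrix.columns]],
            self.scna_matrix.loc[:, [c for c in ids if c in self.scna_matrix.columns]],
        )


SENSITIVITY_COLUMNS = [
    "cl_id", "drug_id", "abs_ic50_uM", "rel_ic50_uM", "censor", "response_class",
]
CELL_LINE_COLUMNS = [
    "cl_id", "tumour_type", "histology_subtype", "lineage", "tp53_status",
]
PROBE_ANNOTATION_COLUMNS = ["probe_id", "gene_symbol", "quality_score"]


@dataclass
class PanelBundle:
    """A consistent, validated snapshot of one annotated cell-line panel."""

    cell_lines: pd.DataFrame          # indexed by cl_id
    sensitivity: pd.DataFrame         # long format, SENSITIVITY_COLUMNS
    expression: ExpressionMatrix | None = None
    probe_annotation: pd.DataFrame | None = None
    alterations: AlterationData | None = None

    def __post_init__(self) -> None:
        cl = self.cell_lines
        if cl.index.name != "cl_id":
            raise PanelIntegrityError("cell_lines must be indexed by cl_id")
        if cl.index.duplicated().any():
            dupes = cl.index[cl.index.duplicated()].tolist()
            raise PanelIntegrityError(f"duplicated cl_id: {dupes[:5]}")
        bad_lineage = set(cl["lineage"]) - LINEAGES
        if bad_lineage:
            raise PanelIntegrityError(f"unknown lineage values: {sorted(bad_lineage)}")
        bad_status = set(cl["tp53_status"]) - TP53_STATUSES
        if bad_status:
            raise PanelIntegrityError(f"unknown tp53_status values: {sorted(bad_status)}")
        sens = self.sensitivity
        missing = set(SENSITIVITY_COLUMNS) - set(sens.columns)
        if missing:
            raise PanelFormatError(f"sensitivity table missing columns: {sorted(missing)}")
        ic50 = sens["abs_ic50_uM"].to_numpy(dtype=float)
        if len(ic50) and (not np.isfinite(ic50).all() or (ic50 <= 0).any()):
            raise PanelIntegrityError("abs_ic50_uM must be finite and positive")
        bad_censor = set(sens["censor"]) - CENSOR_FLAGS
        if bad_censor:
            raise PanelIntegrityError(f"unknown censor flags: {sorted(bad_censor)}")
        if self.probe_annotation is not None:
            ann = self.probe_annotation
            if ann["probe_id"].duplicated().any():
                raise PanelIntegrityError("probe_annotation maps a probe to several genes")

    @property
    def cl_ids(self) -> list[str]:
        return list(self.cell_lines.index)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

_FILES = {
    "cell_lines": "cell_lines.tsv",
    "sensitivity": "sensitivity.tsv",
    "expression": "expression.tsv",
    "probe_annotation": "probe_annotation.tsv",
    "mutations": "mutations.tsv",
    "scna": "scna.tsv",
}


def _read_tsv(path: Path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={c: str for c in ("cl_id", "drug_id", "probe_id")})
    missing = set(required) - set(df.columns)
    if missing:
        raise PanelFormatError(f"{path.name}: missing required column(s) {sorted(missing)}")
    return df


def _read_matrix(path: Path, index_name: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = index_name
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def read_panel(in_dir: str | Path, config: AnalysisConfig | None = None) -> PanelBundle:
    """Read a panel bundle from a directory of TSV files.

    The returned bundle is restricted to the cell lines present in the
    annotation table *and* in every optional layer that was supplied;
    dropped lines are logged.  Only ``cell_lines.tsv`` and
    ``sensitivity.tsv`` are mandatory.
    """
    in_dir = Path(in_dir)
    cl = _read_tsv(in_dir / _FILES["cell_lines"], CELL_LINE_COLUMNS)
    if cl["cl_id"].duplicated().any():
        dupes = cl.loc[cl["cl_id"].duplicated(), "cl_id"].tolist()
        raise PanelIntegrityError(f"{_FILES['cell_lines']}: duplicated cl_id {dupes[:5]}")
    cl = cl.set_index("cl_id")

    sens = _read_tsv(in_dir / _FILES["sensitivity"], SENSITIVITY_COLUMNS)
    sens["censor"] = sens["censor"].fillna("none")
    sens["response_class"] = sens["response_class"].where(sens["response_class"].notna(), None)

    expression = None
    if (in_dir / _FILES["expression"]).exists():
        with open(in_dir / _FILES["expression"]) as fh:
            level = "probe" if fh.readline().split("\t")[0] == "probe_id" else "gene"
        expression = ExpressionMatrix(
            _read_matrix(in_dir / _FILES["expression"], "probe_id" if level == "probe" else "gene_symbol"),
            level,
        )

    probe_annotation = None
    if (in_dir / _FILES["probe_annotation"]).exists():
        probe_annotation = _read_tsv(in_dir / _FILES["probe_annotation"], PROBE_ANNOTATION_COLUMNS)

    alterations = None
    if (in_dir / _FILES["mutations"]).exists():
        mut = _read_matrix(in_dir / _FILES["mutations"], "gene")
        scna = _read_matrix(in_dir / _FILES["scna"], "gene")
        alterations = AlterationData(mut, scna)

    # Restrict to the intersection of cell lines across the supplied layers.
    keep = set(cl.index)
    for name, ids in (
        ("expression", None if expression is None else expression.cl_ids),
        ("mutations", None if alterations is None else list(alterations.mutation_matrix.columns)),
        ("scna", None if alterations is None else list(alterations.scna_matrix.columns)),
    ):
        if ids is not None:
            dropped = keep - set(ids)
            if dropped:
                logger.warning(
                    "read_panel: dropping %d line(s) absent from %s: %s",
                    len(dropped), name, sorted(dropped)[:5],
                )
            keep &= set(ids)
    kept = [c for c in cl.index if c in keep]
    cl = cl.loc[kept]
    sens = sens[sens["cl_id"].isin(keep)].reset_index(drop=True)
    if expression is not None:
        expression = expression.restrict(kept)
    if alterations is not None:
        alterations = alterations.restrict(kept)

    return PanelBundle(cl, sens, expression, probe_annotation, alterations)


def write_panel(bundle: PanelBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write a bundle as TSV files with deterministic row/column order.

    Rows are sorted by cl_id (and drug_id for the sensitivity table),
    matrix columns by cl_id, matrix rows by feature id; writing the same
    bundle twice yields byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    cl = bundle.cell_lines.sort_index().reset_index()[CELL_LINE_COLUMNS]
    paths["cell_lines"] = out_dir / _FILES["cell_lines"]
    cl.to_csv(paths["cell_lines"], sep="\t", index=False)

    sens = bundle.sensitivity.sort_values(["cl_id", "drug_id"]).reset_index(drop=True)
    paths["sensitivity"] = out_dir / _FILES["sensitivity"]
    sens[SENSITIVITY_COLUMNS].to_csv(paths["sensitivity"], sep="\t", index=False)

    if bundle.expression is not None:
        mat = bundle.expression.values.sort_index()
        mat = mat[sorted(mat.columns)]
        mat.index.name = "probe_id" if bundle.expression.level == "probe" else "gene_symbol"
        paths["expression"] = out_dir / _FILES["expression"]
        mat.to_csv(paths["expression"], sep="\t", float_format="%.10g")
    if bundle.probe_annotation is not None:
        ann = bundle.probe_annotation.sort_values("probe_id").reset_index(drop=True)
        paths["probe_annotation"] = out_dir / _FILES["probe_annotation"]
        ann[PROBE_ANNOTATION_COLUMNS].to_csv(paths["probe_annotation"], sep="\t", index=False)
    if bundle.alterations is not None:
        for key, mat in (
            ("mutations", bundle.alterations.mutation_matrix),
            ("scna", bundle.alterations.scna_matrix),
        ):
            mat = mat.sort_index()
            mat = mat[sorted(mat.columns)]
            mat.index.name = "gene"
            paths[key] = out_dir / _FILES[key]
            mat.to_csv(paths[key], sep="\t")
    return paths
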