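"""Reporter metadata: category summaries, expression concordance, cell-type PCA.

Each transcription-factor promoter reporter carries five non-exclusive
expression-category flags assigned by visual inspection of gemma images
(``no_signal``, ``dim``, ``ubiquitous``, ``notch``, ``specialized``) plus a
set of cell-type flags.  This module summarizes the catalog, checks that the
image-based categories are concordant with independent RNA-seq abundance
(asinh-transformed TPM and expressing-cell counts), and projects cell types
into a principal-component space based on which reporters mark them.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CATEGORIES",
    "CELL_TYPES",
    "ReporterRecord",
    "summarize_classes",
    "expression_concordance",
    "celltype_matrix",
    "matrix_to_records",
    "celltype_pca",
    "records_to_csv",
    "records_from_csv",
]

CATEGORIES = ("no_signal", "dim", "ubiquitous", "notch", "specialized")
CELL_TYPES = (
    "rhizoid",
    "oil_body",
    "mucilage_papilla",
    "border",
    "attachment",
    "SCZ",
    "DDCZ",
    "TZ",
    "PZ",
    "CZ",
    "air_pore",
    "gemma_cup",
)

_GENE_ID_RE = re.compile(r"^Mp[1-8UV]g\d{5}$")


@dataclass
class ReporterRecord:
    """One promoter reporter: gene identity, TF family, category and cell-type flags."""

    gene_id: str
    gene_name: str = ""
    tf_family: str = ""
    categories: frozenset = frozenset()
    cell_types: frozenset = frozenset()

    def __post_init__(self) -> None:
        self.categories = frozenset(self.categories)
        self.cell_types = frozenset(self.cell_types)
        unknown = self.categories - set(CATEGORIES)
        if unknown:
            raise ValueError(f"unknown categories: {sorted(unknown)}")
        unknown_ct = self.cell_types - set(CELL_TYPES)
        if unknown_ct:
            raise ValueError(f"unknown cell types: {sorted(unknown_ct)}")
        if not self.categories:
            raise ValueError("at least one category flag must be set")
        if self.gene_id and not _GENE_ID_RE.match(self.gene_id):
            raise ValueError(f"gene id {self.gene_id!r} does not match Mp[1-8UV]gNNNNN")


def summarize_classes(records: list[ReporterRecord]) -> pd.DataFrame:
    """Per-category reporter count and percentage of the catalog.

    Categories are non-exclusive, so the percentages (rounded to the nearest
    integer) need not sum to 100.
    """
    if not records:
        raise ValueError("empty record list")
    total = len(records)
    counts = {c: sum(c in r.categories for r in records) for c in CATEGORIES}
    return pd.DataFrame(
        {
            "count": pd.Series(counts),
            "percent": pd.Series(
                {c: int(round(100.0 * n / total)) for c, n in counts.items()}
            ),
        }
    )


def expression_concordance(
    records: list[ReporterRecord], table: pd.DataFrame
) -> dict:
    """Concordance of image categories with RNA-seq abundance.

    ``table`` has columns ``gene_id``, ``tpm`` and optionally ``n_cells``.
    For each category the asinh(TPM) (and asinh cell-count) values of the
    matched genes are collected, with a Gaussian KDE summary where there are
    enough points, and the category means are checked for the expected
    ordering ubiquitous >= {specialized, notch} >= dim >= no_signal.
    """
    table = table.set_index("gene_id") if "gene_id" in table.columns else table
    matched = [r for r in records if r.gene_id in table.index]
    if not matched:
        raise ValueError("no gene-id overlap between records and expression table")
    out: dict = {"categories": {}, "ordering": {}}
    means: dict[str, float] = {}
    for cat in CATEGORIES:
        genes = [r.gene_id for r in matched if cat in r.categories]
        if not genes:
            continue
        tpm = np.arcsinh(table.loc[genes, "tpm"].to_numpy(dtype=float))
        entry = {"n": len(genes), "asinh_tpm": tpm, "mean_asinh_tpm": float(tpm.mean())}
        if "n_cells" in table.columns:
            cells = np.arcsinh(table.loc[genes, "n_cells"].to_numpy(dtype=float))
            entry["asinh_cells"] = cells
            entry["mean_asinh_cells"] = float(cells.mean())
        if len(genes) >= 3 and tpm.std() > 0:
            entry["kde"] = stats.gaussian_kde(tpm)
        out["categories"][cat] = entry
        means[cat] = entry["mean_asinh_tpm"]
    ordering = {}
    if {"ubiquitous", "dim", "no_signal"} <= means.keys():
        for mid in ("specialized", "notch"):
            if mid in means:
                ordering[f"ubiquitous>={mid}"] = means["ubiquitous"] >= means[mid]
                ordering[f"{mid}>=dim"] = means[mid] >= means["dim"]
        ordering["dim>=no_signal"] = means["dim"] >= means["no_signal"]
    out["ordering"] = ordering
    out["ordering_holds"] = bool(ordering) and all(ordering.values())
    return out


def celltype_matrix(records: list[ReporterRecord]) -> pd.DataFrame:
    """Binary cell-type x reporter incidence matrix.

    Entry (t, g) is 1 iff reporter g carries cell-type flag t; row sums are
    the reporter counts per cell type.
    """
    if not any(r.cell_types for r in records):
        raise ValueError("no cell-type flags set in the catalog")
    data = np.zeros((len(CELL_TYPES), len(records)), dtype=int)
    for j, r in enumerate(records):
        for ct in r.cell_types:
            data[CELL_TYPES.index(ct), j] = 1
    return pd.DataFrame(data, index=list(CELL_TYPES), columns=[r.gene_id for r in records])


def matrix_to_records(matrix: pd.DataFrame) -> list[ReporterRecord]:
    """Rebuild minimal records (cell-type flags only) from an incidence matrix."""
    records = []
    for gene in matrix.columns:
        flags = frozenset(ct for ct in matrix.index if matrix.loc[ct, gene])
        records.append(
            ReporterRecord(gene, categories=frozenset({"specialized"}), cell_types=flags)
        )
    return records


def celltype_pca(matrix: pd.DataFrame, n_components: int | None = None) -> dict:
    """Centered (unscaled) PCA of cell types over their reporter flags.

    Cell types are the samples, reporters the features.  Signs are fixed so
    the largest-magnitude loading of each component is positive.  Returns
    scores, loadings and per-component variances; the variances sum to the
    total variance of the centered matrix.
    """
    X = matrix.to_numpy(dtype=float)
    n, p = X.shape
    if n < 2 or p < 2:
        raise ValueError("need at least 2 cell types and 2 reporters")
    Xc = X - X.mean(axis=0, keepdims=True)
    if np.allclose(Xc, 0):
        raise ValueError("zero-variance matrix")
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    k = min(n_components or len(s), len(s))
    for i in range(k):
        j = int(np.argmax(np.abs(vt[i])))
        if vt[i, j] < 0:
            vt[i] = -vt[i]
            u[:, i] = -u[:, i]
    scores = u[:, :k] * s[:k]
    variances = (s**2) / (n - 1)
    return {
        "scores": pd.DataFrame(
            scores, index=matrix.index, columns=[f"PC{i+1}" for i in range(k)]
        ),
        "loadings": pd.DataFrame(
            vt[:k].T, index=matrix.columns, columns=[f"PC{i+1}" for i in range(k)]
        ),
        "explained_variance": variances[:k],
        "total_variance": float(Xc.var(axis=0, ddof=1).sum()),
    }


def records_to_csv(records: list[ReporterRecord], path) -> None:
    rows = []
    for r in records:
        row = {"gene_id": r.gene_id, "gene_name": r.gene_name, "tf_family": r.tf_family}
        row.update({c: int(c in r.categories) for c in CATEGORIES})
        row.update({ct: int(ct in r.cell_types) for ct in CELL_TYPES})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def records_from_csv(path) -> list[ReporterRecord]:
    df = pd.read_csv(path).fillna("")
    records = []
    for _, row in df.iterrows():
        cats = frozenset(c for c in CATEGORIES if c in df.columns and row[c])
        cts = frozenset(ct for ct in CELL_TYPES if ct in df.columns and row[ct])
        records.append(
            ReporterRecord(
                str(row["gene_id"]),
                str(row.get("gene_name", "")),
                str(row.get("tf_family", "")),
                cats,
                cts,
            )
        )
    return records
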