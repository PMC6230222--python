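"""Gene-level expression aggregation and the swapped BP matrix (scBP).

Isoform TPMs are summed to the gene level over transcripts starting within
2 kb of the gene's most 5' TSS.  For each BP the gene with the larger total
single-cell expression (Sum) becomes the H gene (ties to Watson), and the
scBP matrix stores, per BP row, the L gene's expression in all N cells
followed by the H gene's in the same cell order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import BidirectionalPromoter, GeneModel, qualifying_transcripts


def gene_expression(
    isoform_tpm: pd.DataFrame,
    genes: list[GeneModel],
    window: int = 2000,
    strict: bool = False,
) -> pd.DataFrame:
    """Sum isoform TPMs to genes over the 2 kb TSS qualification window.

    Parameters
    ----------
    isoform_tpm : DataFrame, transcript_id x cell_id
    genes : gene models whose transcripts resolve the isoform ids
    window : downstream window from the anchor TSS within which a
        transcript's TSS must fall for its isoforms to count
    strict : raise on isoform ids that resolve to no known transcript
        (default: warn with a count and skip)

    Returns a gene_id x cell_id TPM DataFrame.
    """
    known: set[str] = {t.transcript_id for g in genes for t in g.transcripts}
    unresolved = [t for t in isoform_tpm.index if t not in known]
    if unresolved:
        msg = f"{len(unresolved)} isoform ids not resolvable to any transcript"
        if strict:
            raise KeyError(msg)
        warnings.warn(msg + "; skipped")
    rows = {}
    for g in genes:
        qual = [t.transcript_id for t in qualifying_transcripts(g, window)
                if t.transcript_id in isoform_tpm.index]
        if qual:
            rows[g.gene_id] = isoform_tpm.loc[qual].sum(axis=0)
        else:
            rows[g.gene_id] = pd.Series(0.0, index=isoform_tpm.columns)
    out = pd.DataFrame(rows).T
    out.index.name = "gene_id"
    if (out.to_numpy() < 0).any():
        raise ValueError("negative TPM values in expression matrix")
    return out


def assign_high_low(bp: BidirectionalPromoter, matrix: pd.DataFrame) -> tuple[str, str]:
    """Decide the (H, L) gene ids of a BP by total expression over cells.

    The Watson gene is H when its Sum is greater than *or equal to* the
    Crick gene's, so exact ties resolve to Watson.
    """
    w, c = bp.gene_watson.gene_id, bp.gene_crick.gene_id
    for gid in (w, c):
        if gid not in matrix.index:
            raise KeyError(f"gene {gid} of {bp.bp_id} absent from expression matrix")
    if matrix.loc[w].sum() >= matrix.loc[c].sum():
        return w, c
    return c, w


@dataclass
class SwappedBPMatrix:
    """M x 2N swapped matrix: L-gene half then H-gene half, same cell order."""

    bp_ids: list[str]
    cell_ids: list[str]
    values: np.ndarray  # M x 2N
    l_gene_ids: list[str]
    h_gene_ids: list[str]

    def __post_init__(self) -> None:
        m, n2 = self.values.shape
        if m != len(self.bp_ids) or n2 != 2 * len(self.cell_ids):
            raise ValueError("scBP dimensions inconsistent")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def l_half(self) -> np.ndarray:
        return self.values[:, : self.n_cells]

    @property
    def h_half(self) -> np.ndarray:
        return self.values[:, self.n_cells:]

    def row(self, bp_id: str) -> tuple[np.ndarray, np.ndarray]:
        i = self.bp_ids.index(bp_id)
        return self.l_half[i], self.h_half[i]

    def to_frame(self) -> pd.DataFrame:
        cols = ([f"{c}_L" for c in self.cell_ids] + [f"{c}_H" for c in self.cell_ids])
        df = pd.DataFrame(self.values, index=pd.Index(self.bp_ids, name="bp_id"), columns=cols)
        df.insert(0, "l_gene", self.l_gene_ids)
        df.insert(1, "h_gene", self.h_gene_ids)
        return df

    def to_tsv(self, path) -> None:
        self.to_frame().round(6).to_csv(path, sep="\t")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SwappedBPMatrix":
        l_gene = df["l_gene"].tolist()
        h_gene = df["h_gene"].tolist()
        vals = df.drop(columns=["l_gene", "h_gene"])
        n = vals.shape[1] // 2
        cells = [c[:-2] for c in vals.columns[:n]]
        return cls(list(df.index), cells, vals.to_numpy(dtype=float), l_gene, h_gene)

    @classmethod
    def from_tsv(cls, path) -> "SwappedBPMatrix":
        return cls.from_frame(pd.read_csv(path, sep="\t", index_col="bp_id"))


def build_scbp(bps: list[BidirectionalPromoter], matrix: pd.DataFrame) -> SwappedBPMatrix:
    """Assemble the swapped BP matrix from the catalog and a gene x cell matrix."""
    missing = [bp.bp_id for bp in bps
               if bp.gene_watson.gene_id not in matrix.index
               or bp.gene_crick.gene_id not in matrix.index]
    if missing:
        raise KeyError(f"BPs with genes absent from expression matrix: {missing}")
    rows, l_ids, h_ids = [], [], []
    for bp in bps:
        h, l = assign_high_low(bp, matrix)
        rows.append(np.concatenate([matrix.loc[l].to_numpy(), matrix.loc[h].to_numpy()]))
        l_ids.append(l)
        h_ids.append(h)
    return SwappedBPMatrix(
        [bp.bp_id for bp in bps], list(matrix.columns), np.array(rows), l_ids, h_ids
    )


def unswap(scbp: SwappedBPMatrix) -> pd.DataFrame:
    """Invert the swap: recover the original gene x cell matrix rows."""
    rows = {}
    for i, bp_id in enumerate(scbp.bp_ids):
        rows[scbp.l_gene_ids[i]] = scbp.l_half[i]
        rows[scbp.h_gene_ids[i]] = scbp.h_half[i]
    out = pd.DataFrame(rows, index=scbp.cell_ids).T
    out.index.name = "gene_id"
    return out


def impute_hook(
    matrix: pd.DataFrame,
    imputed_path=None,
    method: str = "none",
    params: dict | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Dropout-imputation hook: pass-through or externally imputed matrix.

    Imputation itself is delegated to external tools; when ``imputed_path``
    is given, that matrix (same genes/cells) replaces the raw one.  The
    returned provenance dict records what was (or was not) done.
    """
    provenance = {"imputation_method": method, "imputation_params": params or {}}
    if imputed_path is None:
        return matrix, provenance
    imp = pd.read_csv(imputed_path, sep="\t", index_col=0)
    imp.index.name = matrix.index.name
    missing = set(matrix.index) - set(imp.index)
    if missing:
        raise KeyError(f"imputed matrix missing {len(missing)} genes")
    provenance["imputed_file"] = str(imputed_path)
    return imp.loc[matrix.index, matrix.columns], provenance
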