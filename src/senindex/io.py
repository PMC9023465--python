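"""Expression containers and standard-format I/O.

The pipeline works on two aligned layers: raw integer counts
(:class:`CountMatrix`) and a library-size-normalized, log1p-transformed
layer (:class:`NormalizedMatrix`). Both are cells x genes, backed by CSR
sparse storage; all contracts are stated on the logical dense values.

On-disk formats: 10x-style Matrix Market triplets (matrix.mtx +
features.tsv + barcodes.tsv, gzip-transparent), GMT gene-set files, and a
gene-annotation TSV (symbol, biotype, is_mito).
"""

from __future__ import annotations

import gzip
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "CountMatrix",
    "NormalizedMatrix",
    "GeneSet",
    "SignatureRegistry",
    "FormatError",
    "read_10x_triplet",
    "write_10x_triplet",
    "read_gmt",
    "write_gmt",
    "read_gene_annotation",
    "builtin_signatures",
    "normalize",
]


class FormatError(ValueError):
    """A file violates its declared format."""


@dataclass
class GeneSet:
    """A named list of gene symbols."""

    name: str
    genes: list[str]
    source: str = "paper"

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"gene set {self.name!r} contains duplicate symbols")

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.genes

    def intersect(self, panel: pd.Index, case_sensitive: bool = True) -> "GeneSet":
        """Restrict to symbols present in *panel*, warning about the missing ones."""
        if case_sensitive:
            present = [g for g in self.genes if g in panel]
        else:
            lower = {str(p).lower(): p for p in panel}
            present = [lower[g.lower()] for g in self.genes if g.lower() in lower]
        missing = sorted(set(self.genes) - set(present))
        if missing and len(present) > 0:
            logger.warning(
                "gene set %s: %d/%d symbols absent from panel: %s",
                self.name, len(missing), len(self.genes), ", ".join(missing[:10]),
            )
        if not present:
            raise ValueError(
                f"gene set {self.name!r}: none of its {len(self.genes)} symbols "
                "are present in the expression panel"
            )
        return GeneSet(self.name, present, self.source)


SignatureRegistry = dict[str, GeneSet]


def _positional(mask) -> np.ndarray:
    """Boolean mask or integer positions -> integer positions."""
    mask = np.asarray(mask)
    return np.flatnonzero(mask) if mask.dtype == bool else mask


def _as_int_csr(x) -> sp.csr_matrix:
    m = sp.csr_matrix(x)
    if m.nnz:
        data = m.data
        if not np.all(np.isfinite(data)):
            raise FormatError("counts contain non-finite entries")
        if np.any(data < 0):
            raise FormatError("counts contain negative entries")
        if not np.allclose(data, np.round(data)):
            raise FormatError("counts contain non-integer entries")
    m = m.astype(np.int64)
    m.eliminate_zeros()
    return m


@dataclass
class CountMatrix:
    """Raw UMI counts, cells x genes, with gene and cell metadata.

    ``genes`` is indexed by unique symbol with columns ``biotype`` (str) and
    ``is_mito`` (bool); ``cells`` is indexed by unique barcode and may carry
    ``sample`` and ``treatment`` columns.
    """

    X: sp.csr_matrix
    genes: pd.DataFrame
    cells: pd.DataFrame

    def __post_init__(self) -> None:
        self.X = _as_int_csr(self.X)
        if self.X.shape != (len(self.cells), len(self.genes)):
            raise ValueError(
                f"matrix shape {self.X.shape} does not match metadata "
                f"({len(self.cells)} cells x {len(self.genes)} genes)"
            )
        if self.genes.index.has_duplicates:
            raise ValueError("duplicate gene symbols")
        if self.cells.index.has_duplicates:
            raise ValueError("duplicate cell barcodes")
        if "biotype" not in self.genes.columns:
            self.genes = self.genes.assign(biotype="protein_coding")
        if "is_mito" not in self.genes.columns:
            # fall back to symbol prefix when no explicit annotation is given
            idx = self.genes.index.astype(str)
            self.genes = self.genes.assign(
                is_mito=idx.str.startswith("mt-") | idx.str.startswith("MT-")
            )
        self.genes["is_mito"] = self.genes["is_mito"].astype(bool)

    @property
    def n_cells(self) -> int:
        return self.X.shape[0]

    @property
    def n_genes(self) -> int:
        return self.X.shape[1]

    @property
    def gene_ids(self) -> pd.Index:
        return self.genes.index

    @property
    def cell_ids(self) -> pd.Index:
        return self.cells.index

    def subset_cells(self, mask: np.ndarray) -> "CountMatrix":
        idx = _positional(mask)
        return CountMatrix(self.X[idx], self.genes.copy(), self.cells.iloc[idx].copy())

    def subset_genes(self, mask: np.ndarray) -> "CountMatrix":
        idx = _positional(mask)
        return CountMatrix(self.X[:, idx], self.genes.iloc[idx].copy(), self.cells.copy())

    def dense(self) -> np.ndarray:
        return np.asarray(self.X.todense())


@dataclass
class NormalizedMatrix:
    """ln(1 + count / cell_total * scale_factor), aligned to its parent counts."""

    X: sp.csr_matrix
    genes: pd.DataFrame
    cells: pd.DataFrame
    scale_factor: float = 1e4
    log_base: str = field(default="natural", repr=False)

    def __post_init__(self) -> None:
        self.X = sp.csr_matrix(self.X).astype(np.float64)
        if self.X.shape != (len(self.cells), len(self.genes)):
            raise ValueError("matrix shape does not match metadata")

    @property
    def n_cells(self) -> int:
        return self.X.shape[0]

    @property
    def n_genes(self) -> int:
        return self.X.shape[1]

    @property
    def gene_ids(self) -> pd.Index:
        return self.genes.index

    @property
    def cell_ids(self) -> pd.Index:
        return self.cells.index

    def subset_cells(self, mask: np.ndarray) -> "NormalizedMatrix":
        idx = _positional(mask)
        return NormalizedMatrix(
            self.X[idx], self.genes.copy(), self.cells.iloc[idx].copy(), self.scale_factor
        )

    def gene_vector(self, symbol: str) -> np.ndarray:
        """Dense expression of one gene across cells."""
        if symbol not in self.genes.index:
            raise KeyError(f"gene {symbol!r} not in panel")
        j = self.genes.index.get_loc(symbol)
        return np.asarray(self.X[:, j].todense()).ravel()

    def dense(self) -> np.ndarray:
        return np.asarray(self.X.todense())


def _open_maybe_gz(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _find_file(dir_path: Path, stems: list[str]) -> Path:
    for stem in stems:
        for cand in (dir_path / stem, dir_path / f"{stem}.gz"):
            if cand.exists():
                return cand
    raise FileNotFoundError(
        f"none of {stems} (optionally .gz) found in {dir_path}"
    )


def read_10x_triplet(dir_path: str | Path) -> CountMatrix:
    """Read a 10x-style triplet directory into a cells x genes CountMatrix.

    Accepts matrix.mtx(.gz) with features.tsv/genes.tsv(.gz) and
    barcodes.tsv(.gz). The on-disk orientation (genes x cells, the 10x
    convention, or cells x genes) is resolved against the TSV line counts;
    output is always cells x genes.
    """
    dir_path = Path(dir_path)
    mtx_path = _find_file(dir_path, ["matrix.mtx"])
    feat_path = _find_file(dir_path, ["features.tsv", "genes.tsv"])
    bc_path = _find_file(dir_path, ["barcodes.tsv"])

    with _open_maybe_gz(mtx_path) as fh:
        try:
            mat = scipy.io.mmread(fh)
        except ValueError as exc:
            raise FormatError(f"{mtx_path}: {exc}") from exc
    mat = sp.coo_matrix(mat)
    if mat.nnz and (np.any(mat.data < 0) or not np.allclose(mat.data, np.round(mat.data))):
        raise FormatError(f"{mtx_path}: negative or non-integer count entry")

    with _open_maybe_gz(feat_path) as fh:
        feats = [line.rstrip("\n").split("\t") for line in fh if line.strip()]
    with _open_maybe_gz(bc_path) as fh:
        barcodes = [line.strip() for line in fh if line.strip()]

    n_feat, n_bc = len(feats), len(barcodes)
    if mat.shape == (n_feat, n_bc):
        mat = mat.T  # genes x cells on disk (10x convention)
    elif mat.shape != (n_bc, n_feat):
        raise FormatError(
            f"{mtx_path}: matrix shape {mat.shape} matches neither "
            f"(genes={n_feat} x cells={n_bc}) nor its transpose"
        )

    symbols = [f[1] if len(f) > 1 else f[0] for f in feats]
    genes = pd.DataFrame(index=pd.Index(symbols, name="symbol"))
    if any(len(f) > 2 for f in feats):
        genes["feature_type"] = [f[2] if len(f) > 2 else "" for f in feats]
    cells = pd.DataFrame(index=pd.Index(barcodes, name="barcode"))
    return CountMatrix(sp.csr_matrix(mat), genes, cells)


def write_10x_triplet(cm: CountMatrix, dir_path: str | Path) -> None:
    """Write counts as matrix.mtx (genes x cells) + features.tsv + barcodes.tsv."""
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(
        str(dir_path / "matrix.mtx"), sp.coo_matrix(cm.X.T), field="integer"
    )
    with open(dir_path / "features.tsv", "w") as fh:
        for sym in cm.gene_ids:
            fh.write(f"{sym}\t{sym}\tGene Expression\n")
    with open(dir_path / "barcodes.tsv", "w") as fh:
        for bc in cm.cell_ids:
            fh.write(f"{bc}\n")


def read_gene_annotation(path: str | Path) -> pd.DataFrame:
    """Read a gene-annotation TSV with columns symbol, biotype, is_mito."""
    df = pd.read_csv(path, sep="\t", dtype={"symbol": str, "biotype": str})
    for col in ("symbol", "biotype", "is_mito"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    df = df.set_index("symbol")
    df["is_mito"] = df["is_mito"].astype(bool)
    return df


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Parse a GMT file: one set per line, name TAB description TAB genes..."""
    sets: list[GeneSet] = []
    with _open_maybe_gz(Path(path)) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: expected >=3 tab-separated fields, got {len(fields)}"
                )
            name = fields[0]
            genes: list[str] = []
            seen = set()
            dups = []
            for g in fields[2:]:
                if not g:
                    continue
                if g in seen:
                    dups.append(g)
                    continue
                seen.add(g)
                genes.append(g)
            if dups:
                logger.warning(
                    "%s:%d: set %s has duplicate symbols %s (deduplicated)",
                    path, lineno, name, sorted(set(dups)),
                )
            sets.append(GeneSet(name=name, genes=genes, source=str(path)))
    return sets


def write_gmt(sets: list[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, gs.source or "na", *gs.genes]) + "\n")


# Printed gene lists. p16^INK4a and p19^Arf are distinct Cdkn2a protein
# products; at the gene-count level the locus appears once, so the core
# senescence signature carries Cdkn2a a single time.
_SIGNATURES: dict[str, list[str]] = {
    "anti_apoptosis": [
        "Bcl2", "Bcl2l1", "Mcl1", "Bcl2l12", "Bcl2a1a",
        "Cflar", "Gadd45a", "Traf1", "Ptpn13", "Birc3",
    ],
    "pro_apoptosis": [
        "Bbc3", "Bcl2l11", "Pmaip1", "Bak1", "Bax",
        "Pidd1", "Bid", "Apaf1", "Fas", "Tnfrsf10b",
    ],
    "ferroptosis": [
        "Map1lc3a", "Atg5", "Atg7", "Ncoa4", "Alox15", "Lpcat3", "Acsl4",
        "Vdac2", "Vdac3", "Cybb", "Gpx4", "Gss", "Gclc",
    ],
    "necroptosis": ["Mlkl", "Trpm7", "Ripk1", "Ripk3"],
    "parthanatos": ["Aifm1", "Rnf146", "Parp1", "Parg"],
    "pyroptosis": ["Gsdmd", "Nlrp3", "Nlrc4", "Aim2", "Casp1", "Pycard", "Mefv"],
    "sasp": [
        "Cxcl1", "Cxcl2", "Hc", "Csf3", "Csf2", "Csf1", "Il10", "Il13", "Il6",
        "Cxcl13", "Cxcl10", "Icam1", "Ccl2", "Cxcl15", "Ccl20", "Vegfc",
        "Vegfa", "Inhba", "Il1a", "Il1b", "Bmp2", "Gdf15", "Tgfb1", "Tgfb2",
        "Tgfb3", "Bmp6", "Ogg1",
    ],
    "senescence_core": ["Cdkn2a", "Cdkn2b", "Cdkn1a", "Cdkn1b", "Serpine1"],
    "luminal": ["Cd24a", "Krt8", "Krt18"],
    "basal": ["Trp63", "Krt5", "Krt14"],
    "seminal_vesicle": ["Pax2", "Pate4", "Calml3"],
}


def builtin_signatures() -> SignatureRegistry:
    """The built-in murine signature registry (death pathways, SASP,
    senescence core markers, prostate epithelial compartment markers)."""
    return {
        name: GeneSet(name=name, genes=list(genes), source="builtin")
        for name, genes in _SIGNATURES.items()
    }


def normalize(cm: CountMatrix, scale_factor: float = 1e4) -> NormalizedMatrix:
    """Library-size normalization: ln(1 + count / cell_total * scale_factor).

    Every cell must have nonzero total counts; run cell QC first.
    """
    if scale_factor <= 0:
        raise ValueError("scale_factor must be positive")
    totals = np.asarray(cm.X.sum(axis=1)).ravel().astype(np.float64)
    if np.any(totals == 0):
        bad = int((totals == 0).sum())
        raise ValueError(
            f"{bad} cell(s) have zero total counts; apply cell QC before normalizing"
        )
    x = cm.X.tocoo().astype(np.float64)
    x.data = np.log1p(x.data / totals[x.row] * scale_factor)
    return NormalizedMatrix(
        sp.csr_matrix(x), cm.genes.copy(), cm.cells.copy(), scale_factor
    )
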