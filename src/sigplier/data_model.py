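"""Expression matrices, signature atlases and the binary prior-knowledge matrix.

The decomposition consumes a genes × samples expression matrix (TPM or
log2(TPM+0.5) scale) together with a collection of gene signatures.  The
signatures are encoded as a binary genes × signatures membership matrix C
that anchors latent variables to prior knowledge.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TPM = "tpm"
LOG2_TPM_HALF = "log2_tpm_half"

#: value a TPM of exactly zero maps to under log2(x + 0.5)
LOG_ZERO = -1.0

_METADATA_FIELDS = ("author", "species", "clinical_condition", "cell_type")
NON_ASSOCIATED = "Non associated"


class DataError(ValueError):
    """Raised for malformed or inconsistent input data."""


@dataclass
class ExpressionMatrix:
    """A genes × samples numeric expression matrix with an explicit scale."""

    genes: pd.Index
    samples: pd.Index
    values: np.ndarray
    scale: str = TPM

    def __post_init__(self) -> None:
        self.genes = pd.Index(self.genes)
        self.samples = pd.Index(self.samples)
        self.values = np.asarray(self.values, dtype=float)
        if self.genes.has_duplicates:
            raise DataError("duplicate gene identifiers")
        if self.samples.has_duplicates:
            raise DataError("duplicate sample identifiers")
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise DataError(
                f"value matrix shape {self.values.shape} inconsistent with "
                f"{len(self.genes)} genes × {len(self.samples)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            raise DataError("expression values must be finite")
        if self.scale not in (TPM, LOG2_TPM_HALF):
            raise DataError(f"unknown scale {self.scale!r}")
        if self.scale == LOG2_TPM_HALF and self.values.min(initial=0.0) < LOG_ZERO - 1e-12:
            raise DataError("log2(TPM+0.5) values cannot fall below -1")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.samples)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, scale: str = TPM) -> "ExpressionMatrix":
        return cls(df.index, df.columns, df.to_numpy(dtype=float), scale)

    def subset_genes(self, genes) -> "ExpressionMatrix":
        idx = self.genes.get_indexer(genes)
        if (idx < 0).any():
            raise DataError("requested genes missing from matrix")
        return ExpressionMatrix(pd.Index(genes), self.samples, self.values[idx], self.scale)


@dataclass
class Signature:
    """A named gene set with optional provenance metadata."""

    name: str
    genes: tuple
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        # preserve order, drop duplicates
        seen = dict.fromkeys(self.genes)
        self.genes = tuple(seen)
        if not self.genes:
            raise DataError(f"signature {self.name!r} has no genes")
        meta = {k: NON_ASSOCIATED if k == "cell_type" else "" for k in _METADATA_FIELDS}
        meta.update(self.metadata or {})
        self.metadata = meta

    @property
    def cell_type(self) -> str:
        return self.metadata["cell_type"]


@dataclass
class SignatureAtlas:
    """An ordered collection of uniquely named signatures."""

    signatures: list

    def __post_init__(self) -> None:
        if not self.signatures:
            raise DataError("atlas must contain at least one signature")
        names = [s.name for s in self.signatures]
        if len(set(names)) != len(names):
            raise DataError("duplicate signature names in atlas")
        self._by_name = {s.name: s for s in self.signatures}

    def __len__(self) -> int:
        return len(self.signatures)

    def __iter__(self):
        return iter(self.signatures)

    def __getitem__(self, name: str) -> Signature:
        return self._by_name[name]

    @property
    def names(self) -> list:
        return [s.name for s in self.signatures]

    def gene_union(self) -> set:
        out: set = set()
        for s in self.signatures:
            out.update(s.genes)
        return out


@dataclass
class PriorMatrix:
    """Binary genes × signatures membership matrix C."""

    genes: pd.Index
    signature_names: pd.Index
    values: np.ndarray

    def __post_init__(self) -> None:
        self.genes = pd.Index(self.genes)
        self.signature_names = pd.Index(self.signature_names)
        self.values = np.asarray(self.values, dtype=float)
        if not np.isin(self.values, (0.0, 1.0)).all():
            raise DataError("prior matrix entries must be 0 or 1")
        if (self.values.sum(axis=0) < 1).any():
            raise DataError("every prior-matrix column needs at least one member gene")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.signature_names)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PriorMatrix":
        return cls(df.index, df.columns, df.to_numpy(dtype=float))


# ---------------------------------------------------------------------------
# I/O


def _sep_for(path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_expression(path, scale_hint: str = TPM) -> ExpressionMatrix:
    """Read a genes-in-rows expression table (TSV or CSV, header row of samples)."""
    try:
        df = pd.read_csv(
            path, sep=_sep_for(path), index_col=0, float_precision="round_trip"
        )
    except pd.errors.EmptyDataError as exc:
        raise DataError(f"empty expression table: {path}") from exc
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise DataError(f"expression table has no data: {path}")
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise DataError(f"duplicate gene identifiers: {dups[:5]}")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise DataError(f"non-numeric expression values in {path}") from exc
    return ExpressionMatrix(df.index.astype(str), df.columns.astype(str), values, scale_hint)


def write_expression(em: ExpressionMatrix, path) -> None:
    # %.17g keeps the text round-trip value-exact for doubles
    em.to_frame().to_csv(path, sep=_sep_for(path), float_format="%.17g")


def read_gmt(path, metadata_path=None) -> SignatureAtlas:
    """Read a GMT gene-set file, optionally joining a metadata TSV by signature name.

    Each GMT line is ``name<TAB>description<TAB>gene1<TAB>gene2...``.  Metadata
    columns: name, author, species, clinical_condition, cell_type; signatures
    without a metadata row get cell_type "Non associated".
    """
    meta: dict = {}
    if metadata_path is not None:
        mdf = pd.read_csv(metadata_path, sep="\t", dtype=str).fillna("")
        if "name" not in mdf.columns:
            raise DataError("metadata table needs a 'name' column")
        meta = {
            row["name"]: {k: row.get(k, "") for k in _METADATA_FIELDS}
            for _, row in mdf.iterrows()
        }

    signatures = []
    seen = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3 or not any(f.strip() for f in fields[2:]):
                raise DataError(f"GMT line {lineno}: signature with no genes")
            name = fields[0]
            if name in seen:
                raise DataError(f"GMT line {lineno}: duplicate signature name {name!r}")
            seen.add(name)
            genes = tuple(g for g in fields[2:] if g.strip())
            signatures.append(Signature(name, genes, meta.get(name, {})))
    if not signatures:
        raise DataError(f"empty GMT file: {path}")

    unknown = set(meta) - seen
    if unknown:
        warnings.warn(
            f"{len(unknown)} metadata rows match no signature and were ignored",
            stacklevel=2,
        )
    return SignatureAtlas(signatures)


def write_gmt(atlas: SignatureAtlas, path, metadata_path=None) -> None:
    with open(path, "w") as fh:
        for sig in atlas:
            fh.write("\t".join([sig.name, "na", *sig.genes]) + "\n")
    if metadata_path is not None:
        rows = [{"name": s.name, **s.metadata} for s in atlas]
        pd.DataFrame(rows, columns=["name", *_METADATA_FIELDS]).to_csv(
            metadata_path, sep="\t", index=False
        )


# ---------------------------------------------------------------------------
# preprocessing


def log_transform(em: ExpressionMatrix) -> ExpressionMatrix:
    """log2(TPM + 0.5); a TPM of 0 maps to −1."""
    if em.scale != TPM:
        raise DataError("log_transform expects a TPM-scale matrix")
    if em.values.min(initial=0.0) < 0:
        raise DataError("negative TPM values")
    return ExpressionMatrix(em.genes, em.samples, np.log2(em.values + 0.5), LOG2_TPM_HALF)


def _zero_mask(em: ExpressionMatrix) -> np.ndarray:
    zero_value = 0.0 if em.scale == TPM else LOG_ZERO
    return np.isclose(em.values, zero_value)


def filter_genes(
    em: ExpressionMatrix, atlas: SignatureAtlas, zero_frac_max: float = 0.95
) -> ExpressionMatrix:
    """Drop null-variance genes, genes with more than ``zero_frac_max`` zeros,
    and genes absent from every atlas signature.  Gene order is preserved;
    the rule on the zero fraction is strict (exactly 95% zeros is retained).
    """
    variance = em.values.var(axis=1)
    zero_frac = _zero_mask(em).mean(axis=1)
    in_atlas = em.genes.isin(atlas.gene_union())
    keep = (variance > 0) & (zero_frac <= zero_frac_max) & in_atlas
    if not keep.any():
        raise DataError("gene filtering removed every gene")
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("filter_genes dropped %d of %d genes", n_dropped, em.n_genes)
    return ExpressionMatrix(em.genes[keep], em.samples, em.values[keep], em.scale)


def build_prior_matrix(atlas: SignatureAtlas, gene_universe) -> PriorMatrix:
    """Binary membership matrix C over ``gene_universe``: C[i,s]=1 iff gene i
    belongs to signature s.  Signature genes outside the universe are dropped
    with a warning; columns emptied by the intersection are dropped entirely.
    """
    universe = pd.Index(gene_universe)
    if len(universe) == 0:
        raise DataError("empty gene universe")
    pos = {g: i for i, g in enumerate(universe)}

    cols, kept_names, dropped = [], [], []
    n_outside = 0
    for sig in atlas:
        col = np.zeros(len(universe))
        inside = [g for g in sig.genes if g in pos]
        n_outside += len(sig.genes) - len(inside)
        if not inside:
            dropped.append(sig.name)
            continue
        col[[pos[g] for g in inside]] = 1.0
        cols.append(col)
        kept_names.append(sig.name)
    if n_outside:
        logger.warning("%d signature genes fall outside the gene universe", n_outside)
    if dropped:
        warnings.warn(
            f"{len(dropped)} signatures have no genes in the universe and were "
            f"dropped: {dropped[:5]}",
            stacklevel=2,
        )
    if not cols:
        raise DataError("no signature overlaps the gene universe")
    return PriorMatrix(universe, pd.Index(kept_names), np.column_stack(cols))
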