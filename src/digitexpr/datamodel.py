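"""Shared data types and tabular I/O for the digit-transcriptomics pipeline.

The central containers are :class:`CountMatrix` (gene x sample integer read
counts with per-sample design metadata), :class:`ExpressionMatrix` (TPM and
its normalized descendants, with an explicit transform state), gene lists,
transcript-length tables, cross-species ortholog maps, and sample dendrograms
(:class:`ClusterTree`).

All file formats are plain text: TSV matrices with a header row of sample
IDs, TSV metadata/ortholog tables, one-ID-per-line gene lists, and Newick
trees with internal-node support labels. Validation is total — a malformed
file raises a diagnostic error naming the offending cell/sample rather than
silently coercing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

METADATA_COLUMNS = ("species", "limb", "digit", "stage", "replicate")

#: transform states of an ExpressionMatrix, in the only order they may advance
TRANSFORM_STATES = ("tpm", "sqrt_tpm", "centered_sqrt_tpm")


class ValidationError(ValueError):
    """An input file or in-memory object violates a structural invariant."""


# ---------------------------------------------------------------------------
# CountMatrix
# ---------------------------------------------------------------------------


@dataclass
class CountMatrix:
    """Gene x sample integer read counts plus per-sample design metadata.

    Parameters
    ----------
    counts
        DataFrame of non-negative integers, genes in rows (unique index),
        samples in columns (unique).
    metadata
        DataFrame indexed by sample ID with columns
        ``species, limb, digit, stage, replicate``. ``digit`` is a 1-based
        ordinal, anterior (D1) to posterior.
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        c = self.counts
        if not c.index.is_unique:
            dups = c.index[c.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene IDs: {dups[:5]}")
        if not c.columns.is_unique:
            raise ValidationError("duplicate sample IDs in counts")
        arr = c.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            # accept float storage only if every value is integral
            bad = ~np.isclose(arr, np.round(arr)) | ~np.isfinite(arr)
            if bad.any():
                g, s = np.argwhere(bad)[0]
                raise ValidationError(
                    f"non-integer count at gene {c.index[g]!r}, "
                    f"sample {c.columns[s]!r}: {arr[g, s]!r}"
                )
            self.counts = c = c.round().astype(np.int64)
            arr = c.to_numpy()
        if (arr < 0).any():
            g, s = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative count at gene {c.index[g]!r}, sample {c.columns[s]!r}"
            )
        missing_cols = [k for k in METADATA_COLUMNS if k not in self.metadata.columns]
        if missing_cols:
            raise ValidationError(f"metadata lacks columns {missing_cols}")
        meta_set, count_set = set(self.metadata.index), set(c.columns)
        if meta_set != count_set:
            raise ValidationError(
                f"metadata/counts sample mismatch: only in counts "
                f"{sorted(count_set - meta_set)}, only in metadata "
                f"{sorted(meta_set - count_set)}"
            )
        if self.metadata[list(METADATA_COLUMNS)].isna().any().any():
            bad = self.metadata.index[
                self.metadata[list(METADATA_COLUMNS)].isna().any(axis=1)
            ].tolist()
            raise ValidationError(f"incomplete metadata for samples {bad}")
        # align metadata rows to the counts column order
        self.metadata = self.metadata.loc[c.columns]

    # -- convenience ------------------------------------------------------
    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def subset_samples(self, sample_ids) -> "CountMatrix":
        sample_ids = list(sample_ids)
        return CountMatrix(self.counts[sample_ids], self.metadata.loc[sample_ids])

    def subset_genes(self, gene_ids) -> "CountMatrix":
        gene_ids = [g for g in gene_ids if g in self.counts.index]
        return CountMatrix(self.counts.loc[gene_ids], self.metadata)

    def groups(self, keys=("species", "limb", "digit", "stage")):
        """Iterate (key tuple, sample-ID list) over design cells."""
        for key, sub in self.metadata.groupby(list(keys), sort=True):
            yield key, list(sub.index)


def read_count_matrix(counts_path, metadata_path) -> CountMatrix:
    """Read a genes x samples TSV plus a sample-metadata TSV.

    The counts file has a header row of sample IDs and gene IDs in the first
    column; the metadata file has one row per sample with a ``sample_id``
    column. Sample order is taken from the counts header.
    """
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    meta = pd.read_csv(metadata_path, sep="\t")
    if "sample_id" not in meta.columns:
        raise ValidationError("metadata must have a 'sample_id' column")
    meta = meta.set_index("sample_id")
    return CountMatrix(counts, meta)


def write_count_matrix(cm: CountMatrix, counts_path, metadata_path) -> None:
    cm.counts.to_csv(counts_path, sep="\t", index_label="gene_id")
    cm.metadata.to_csv(metadata_path, sep="\t", index_label="sample_id")


def read_count_matrix_mtx(mtx_path, genes_path, samples_path, metadata_path) -> CountMatrix:
    """Optional MTX triplet reader producing the same CountMatrix."""
    from scipy.io import mmread

    mat = mmread(mtx_path).toarray()
    genes = [line.strip() for line in open(genes_path) if line.strip()]
    samples = [line.strip() for line in open(samples_path) if line.strip()]
    counts = pd.DataFrame(mat, index=genes, columns=samples)
    meta = pd.read_csv(metadata_path, sep="\t").set_index("sample_id")
    return CountMatrix(counts, meta)


# ---------------------------------------------------------------------------
# TranscriptLengthTable
# ---------------------------------------------------------------------------


@dataclass
class TranscriptLengthTable:
    """Median transcript length (bp) per gene, used only for TPM."""

    lengths: pd.Series  # gene_id -> length in bp

    def __post_init__(self) -> None:
        if (self.lengths <= 0).any() or self.lengths.isna().any():
            bad = self.lengths.index[~(self.lengths > 0)].tolist()
            raise ValidationError(f"non-positive transcript lengths for {bad[:5]}")

    def for_genes(self, gene_ids) -> np.ndarray:
        missing = [g for g in gene_ids if g not in self.lengths.index]
        if missing:
            raise ValidationError(f"missing transcript lengths for genes {missing[:5]}")
        return self.lengths.loc[list(gene_ids)].to_numpy(dtype=float)


def read_length_table(path) -> TranscriptLengthTable:
    tab = pd.read_csv(path, sep="\t", index_col=0)
    return TranscriptLengthTable(tab.iloc[:, 0].astype(float))


def write_length_table(t: TranscriptLengthTable, path) -> None:
    t.lengths.rename("median_transcript_length_bp").to_csv(
        path, sep="\t", index_label="gene_id"
    )


# ---------------------------------------------------------------------------
# GeneList
# ---------------------------------------------------------------------------


@dataclass
class GeneList:
    name: str
    members: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.members = frozenset(self.members)
        if not self.members:
            raise ValidationError(f"gene list {self.name!r} is empty")

    def __contains__(self, gene_id) -> bool:
        return gene_id in self.members

    def __len__(self) -> int:
        return len(self.members)


def read_gene_list(path, name: str | None = None) -> GeneList:
    """One gene ID per line; '#' lines are comments; duplicates collapse."""
    ids = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                ids.append(line)
    if not ids:
        raise ValidationError(f"gene list file {path} contains no identifiers")
    if len(set(ids)) < len(ids):
        logger.warning("gene list %s: %d duplicate IDs collapsed", path, len(ids) - len(set(ids)))
    return GeneList(name or str(path), frozenset(ids))


def write_gene_list(gl: GeneList, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {gl.name}\n")
        for g in sorted(gl.members):
            fh.write(g + "\n")


# ---------------------------------------------------------------------------
# OrthologMap
# ---------------------------------------------------------------------------


@dataclass
class OrthologMap:
    """Ortholog groups: one row per group, one column per species.

    Blank / NaN cells mean the species lacks a member. The ``one_to_one``
    flag marks rows in which every species of ``species_set`` appears exactly
    once and no gene is shared between one-to-one rows of the same species.
    """

    table: pd.DataFrame  # index group_id, columns species
    species_set: tuple
    one_to_one: pd.Series = None  # bool per group, set in __post_init__

    def __post_init__(self) -> None:
        missing = [s for s in self.species_set if s not in self.table.columns]
        if missing:
            raise ValidationError(f"species missing from ortholog map: {missing}")
        sub = self.table[list(self.species_set)]
        flag = sub.notna().all(axis=1)
        for sp in self.species_set:
            genes = sub.loc[flag, sp]
            if genes.duplicated().any():
                dup = genes[genes.duplicated()].iloc[0]
                raise ValidationError(
                    f"gene {dup!r} of species {sp!r} appears in multiple "
                    "one-to-one ortholog rows"
                )
        self.one_to_one = flag

    def one_to_one_table(self) -> pd.DataFrame:
        """Rows that are one-to-one across the species set, species columns only."""
        return self.table.loc[self.one_to_one, list(self.species_set)]

    def genes_of(self, species: str) -> pd.Series:
        """group_id -> gene_id for one species, over one-to-one rows."""
        return self.one_to_one_table()[species]

    @property
    def n_one_to_one(self) -> int:
        return int(self.one_to_one.sum())


def read_ortholog_map(path, species_set) -> OrthologMap:
    tab = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    tab = tab.replace("", np.nan)
    return OrthologMap(tab, tuple(species_set))


def write_ortholog_map(om: OrthologMap, path) -> None:
    om.table.to_csv(path, sep="\t", index_label="group_id")


# ---------------------------------------------------------------------------
# ExpressionMatrix
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Relative-abundance matrix with an explicit, monotone transform state.

    States advance only as tpm -> sqrt_tpm -> centered_sqrt_tpm; each stage
    of the pipeline checks the state of its input so that, e.g., PCA is never
    run on raw TPM by accident.
    """

    values: pd.DataFrame  # genes x samples, float
    transform_state: str = "tpm"
    bulk_assignment: dict | None = None  # sample -> bulk label, set on centering
    universe: str = "full"  # which gene universe the TPM denominator used

    def __post_init__(self) -> None:
        if self.transform_state not in TRANSFORM_STATES:
            raise ValidationError(f"unknown transform state {self.transform_state!r}")
        if self.transform_state != "centered_sqrt_tpm" and (self.values.to_numpy() < 0).any():
            raise ValidationError("negative values in un-centered expression matrix")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def require_state(self, state: str) -> None:
        if self.transform_state != state:
            raise ValidationError(
                f"expected expression state {state!r}, got {self.transform_state!r}"
            )

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        gene_ids = [g for g in gene_ids if g in self.values.index]
        return ExpressionMatrix(
            self.values.loc[gene_ids], self.transform_state, self.bulk_assignment, self.universe
        )


def write_expression_matrix(em: ExpressionMatrix, path, sidecar_path=None) -> None:
    em.values.to_csv(path, sep="\t", index_label="gene_id")
    if sidecar_path is not None:
        import json

        with open(sidecar_path, "w") as fh:
            json.dump(
                {
                    "transform_state": em.transform_state,
                    "universe": em.universe,
                    "bulk_assignment": em.bulk_assignment,
                },
                fh,
                indent=1,
            )


def read_expression_matrix(path, sidecar_path=None) -> ExpressionMatrix:
    values = pd.read_csv(path, sep="\t", index_col=0)
    state, universe, bulks = "tpm", "full", None
    if sidecar_path is not None:
        import json

        with open(sidecar_path) as fh:
            side = json.load(fh)
        state = side.get("transform_state", "tpm")
        universe = side.get("universe", "full")
        bulks = side.get("bulk_assignment")
    return ExpressionMatrix(values, state, bulks, universe)


# ---------------------------------------------------------------------------
# ClusterTree
# ---------------------------------------------------------------------------


@dataclass
class TreeNode:
    """Node of a sample dendrogram.

    Leaves carry a ``label``; internal nodes carry the merge ``height`` (in
    dissimilarity units), exactly two children, and optional bootstrap
    support ``bp`` (and ``au``) in [0, 100].
    """

    label: str | None = None
    height: float = 0.0
    children: tuple = ()
    bp: float | None = None
    au: float | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list:
        if self.is_leaf:
            return [self.label]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out


@dataclass
class ClusterTree:
    """Binary dendrogram over samples with optional per-node bootstrap support."""

    root: TreeNode
    n_boot: int = 0

    @property
    def leaf_names(self) -> list:
        return self.root.leaves()

    def internal_nodes(self) -> list:
        out = []

        def rec(node):
            if not node.is_leaf:
                out.append(node)
                for c in node.children:
                    rec(c)

        rec(self.root)
        return out

    def clusters(self) -> set:
        """Frozensets of leaf labels under each internal node."""
        return {frozenset(n.leaves()) for n in self.internal_nodes()}

    def support_of(self, leaf_set) -> float | None:
        """BP support of the internal node whose leaf set equals ``leaf_set``."""
        target = frozenset(leaf_set)
        for n in self.internal_nodes():
            if frozenset(n.leaves()) == target:
                return n.bp
        return None


def _newick_rec(node: TreeNode, parent_height: float) -> str:
    blen = parent_height - node.height
    if node.is_leaf:
        return f"{node.label}:{blen:.10g}"
    inner = ",".join(_newick_rec(c, node.height) for c in node.children)
    label = "" if node.bp is None else f"{node.bp:.6g}"
    return f"({inner}){label}:{blen:.10g}"


def tree_to_newick(tree: ClusterTree) -> str:
    """Newick with branch lengths = merge-height differences and internal
    labels = bootstrap support (BP, percent)."""
    root = tree.root
    inner = ",".join(_newick_rec(c, root.height) for c in root.children)
    label = "" if root.bp is None else f"{root.bp:.6g}"
    return f"({inner}){label};"


def write_tree_newick(tree: ClusterTree, path) -> None:
    for n in tree.internal_nodes():
        if n.bp is not None and not (0 <= n.bp <= 100):
            raise ValidationError(f"bootstrap support {n.bp} outside [0, 100]")
    with open(path, "w") as fh:
        fh.write(tree_to_newick(tree) + "\n")
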