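"""Readers and writers for the study's plain-text formats.

Counts, metadata, relatedness and distance matrices travel as TSV; trees
as newick (parsed with scikit-bio). Readers validate and reject malformed
input rather than coercing it; every writer/reader pair round-trips.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import skbio

from .core import (
    StudyMetadata,
    ValidationError,
    ValidationReport,
    validate_relatedness,
)

logger = logging.getLogger("dyadome")

__all__ = [
    "read_count_table",
    "write_count_table",
    "read_tree",
    "write_tree",
    "read_metadata",
    "write_metadata",
    "read_relatedness",
    "write_relatedness",
    "read_distance_matrix",
    "write_distance_matrix",
    "validate_study",
]


def read_count_table(path, metadata: StudyMetadata | None = None) -> pd.DataFrame:
    """Read an ASV count table (TSV, ASVs as rows, samples as columns).

    Cells must be non-negative integers; row and column ids must be
    unique. If ``metadata`` is supplied and the *row* labels are
    recognized as sample ids while the columns are not, the table is
    transposed (and the decision logged), so tables written samples-as-rows
    are accepted too.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if raw.index.has_duplicates:
        dup = raw.index[raw.index.duplicated()][0]
        raise ValidationError(f"{path}: duplicate row id {dup!r}")
    if raw.columns.has_duplicates:
        dup = raw.columns[raw.columns.duplicated()][0]
        raise ValidationError(f"{path}: duplicate column id {dup!r}")
    values = np.empty(raw.shape, dtype=np.int64)
    for j, col in enumerate(raw.columns):
        for i, cell in enumerate(raw[col]):
            try:
                as_float = float(cell)
            except (TypeError, ValueError):
                raise ValidationError(
                    f"{path}: non-numeric count {cell!r} at row "
                    f"{raw.index[i]!r}, column {col!r}"
                ) from None
            if as_float != int(as_float):
                raise ValidationError(
                    f"{path}: non-integer count {cell!r} at row "
                    f"{raw.index[i]!r}, column {col!r}"
                )
            if as_float < 0:
                raise ValidationError(
                    f"{path}: negative count {cell!r} at row "
                    f"{raw.index[i]!r}, column {col!r}"
                )
            values[i, j] = int(as_float)
    counts = pd.DataFrame(values, index=raw.index, columns=raw.columns)
    counts.index.name = "asv_id"
    if counts.empty:
        raise ValidationError(f"{path}: empty count table")
    if metadata is not None:
        known = set(metadata.sample_ids)
        rows_are_samples = set(counts.index) <= known
        cols_are_samples = set(counts.columns) <= known
        if rows_are_samples and not cols_are_samples:
            logger.info("count table %s detected samples-as-rows; transposing", path)
            counts = counts.T
            counts.index.name = "asv_id"
    return counts


def write_count_table(counts: pd.DataFrame, path) -> None:
    out = counts.copy()
    out.index.name = "asv_id"
    out.to_csv(path, sep="\t")


def read_tree(path) -> skbio.TreeNode:
    """Read a rooted newick tree; validate tip labels and branch lengths.

    Unlabelled or duplicate tips and malformed newick raise
    :class:`ValidationError`. A missing root branch length is treated
    as 0; missing lengths on any other edge are rejected.
    """
    try:
        tree = skbio.TreeNode.read(str(path), format="newick")
    except Exception as exc:  # skbio raises several parse error types
        raise ValidationError(f"{path}: cannot parse newick: {exc}") from exc
    return _validate_tree(tree, where=str(path))


def _validate_tree(tree: skbio.TreeNode, where: str = "tree") -> skbio.TreeNode:
    names = [t.name for t in tree.tips()]
    if any(n is None or n == "" for n in names):
        raise ValidationError(f"{where}: unlabelled tip")
    if len(set(names)) != len(names):
        seen, dup = set(), None
        for n in names:
            if n in seen:
                dup = n
                break
            seen.add(n)
        raise ValidationError(f"{where}: duplicate tip label {dup!r}")
    if tree.length is None:
        tree.length = 0.0
    for node in tree.traverse(include_self=False):
        if node.length is None:
            raise ValidationError(
                f"{where}: missing branch length on edge above "
                f"{node.name or 'an internal node'}"
            )
        if node.length < 0:
            raise ValidationError(f"{where}: negative branch length {node.length}")
    return tree


def write_tree(tree: skbio.TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def read_metadata(
    samples_path, individuals_path, dyads_path=None, season_order=None
) -> StudyMetadata:
    samples = pd.read_csv(samples_path, sep="\t", index_col=0, dtype=str)
    individuals = pd.read_csv(individuals_path, sep="\t", index_col=0)
    for col in ("age", "fgcm", "leaf_intake"):
        if col in individuals.columns:
            individuals[col] = pd.to_numeric(individuals[col])
    dyads = None
    if dyads_path is not None:
        dyads = pd.read_csv(dyads_path, sep="\t")
    kwargs = {}
    if season_order is not None:
        kwargs["season_order"] = tuple(season_order)
    else:
        observed = list(dict.fromkeys(samples["season_id"]))
        from .core import DEFAULT_SEASON_ORDER

        if not set(observed) <= set(DEFAULT_SEASON_ORDER):
            kwargs["season_order"] = tuple(sorted(set(observed)))
    return StudyMetadata(samples=samples, individuals=individuals, dyads=dyads, **kwargs)


def write_metadata(meta: StudyMetadata, samples_path, individuals_path, dyads_path=None):
    samples = meta.samples.copy()
    samples.index.name = "sample_id"
    samples.to_csv(samples_path, sep="\t")
    individuals = meta.individuals.copy()
    individuals.index.name = "individual_id"
    individuals.to_csv(individuals_path, sep="\t")
    if dyads_path is not None and meta.dyads is not None:
        meta.dyads.to_csv(dyads_path, sep="\t", index=False)


def read_relatedness(path) -> pd.DataFrame:
    matrix = pd.read_csv(path, sep="\t", index_col=0)
    matrix.columns = matrix.columns.astype(str)
    matrix.index = matrix.index.astype(str)
    return validate_relatedness(matrix)


def write_relatedness(relatedness: pd.DataFrame, path) -> None:
    out = relatedness.copy()
    out.index.name = "individual_id"
    out.to_csv(path, sep="\t")


def read_distance_matrix(path) -> skbio.DistanceMatrix:
    """Read a square labelled TSV distance matrix."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    if list(frame.index) != list(frame.columns):
        raise ValidationError(f"{path}: distance matrix labels not square")
    try:
        return skbio.DistanceMatrix(frame.to_numpy(dtype=float), ids=list(frame.index))
    except Exception as exc:
        raise ValidationError(f"{path}: invalid distance matrix: {exc}") from exc


def write_distance_matrix(d: skbio.DistanceMatrix, path) -> None:
    frame = pd.DataFrame(d.data, index=list(d.ids), columns=list(d.ids))
    frame.index.name = "id"
    frame.to_csv(path, sep="\t")


def validate_study(
    counts: pd.DataFrame, tree: skbio.TreeNode, meta: StudyMetadata
) -> ValidationReport:
    """Cross-check counts, tree, and metadata.

    Fatal: a counted sample without metadata (downstream group/season
    assignment is impossible). Warnings: ASVs absent from the tree, tree
    tips never counted, metadata samples without counts, and groups with
    fewer than two individuals (no within-group dyads).
    """
    report = ValidationReport()
    sample_ids = set(counts.columns)
    meta_ids = set(meta.sample_ids)
    for sid in sorted(sample_ids - meta_ids):
        report.add("fatal", "sample-without-metadata", f"sample {sid!r} has no metadata")
    for sid in sorted(meta_ids - sample_ids):
        report.add("warning", "metadata-without-sample", f"sample {sid!r} has no counts")
    tips = {t.name for t in tree.tips()}
    asvs = set(counts.index)
    missing_tips = sorted(asvs - tips)
    if missing_tips:
        report.add(
            "warning",
            "asv-not-in-tree",
            f"{len(missing_tips)} ASVs absent from tree (e.g. {missing_tips[0]!r})",
        )
    unused_tips = sorted(tips - asvs)
    if unused_tips:
        report.add(
            "warning",
            "tip-not-in-counts",
            f"{len(unused_tips)} tree tips never counted (e.g. {unused_tips[0]!r})",
        )
    sizes = meta.individuals_per_group()
    for group, size in sizes.items():
        if size < 2:
            report.add(
                "warning",
                "small-group",
                f"group {group!r} has {size} individual(s); no within-group dyads",
            )
    return report
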