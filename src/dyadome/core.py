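"""Shared data model: study metadata, relatedness matrices, validation.

The pipeline's in-memory containers are deliberately plain:

* ASV count tables are :class:`pandas.DataFrame` objects indexed by
  ``asv_id`` (rows) with ``sample_id`` columns, non-negative integers.
* Phylogenetic trees are :class:`skbio.TreeNode` objects (rooted, branch
  lengths on non-root edges).
* Distance matrices are :class:`skbio.DistanceMatrix` objects.

This module adds the study-specific layers on top: the sample -> individual
-> group -> season mapping that defines the exchangeability blocks of the
permutation tests, the maternal-relatedness matrix, and a validation report
that separates fatal inconsistencies (a sample without metadata) from
benign ones (a tree tip never observed in the counts).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AGE_CLASSES",
    "RANK_CATEGORIES",
    "REPRODUCTIVE_STATES",
    "RC_VALUES",
    "DEFAULT_SEASON_ORDER",
    "DyadomeError",
    "ValidationError",
    "UndefinedValueError",
    "StudyMetadata",
    "ValidationReport",
    "validate_relatedness",
]

#: Closed category sets for individual covariates.
AGE_CLASSES = ("adult", "juvenile", "infant")
RANK_CATEGORIES = ("dominant-male", "subordinate-male", "adult-female")
REPRODUCTIVE_STATES = ("reproducing", "not-reproducing")

#: Admissible maternal relatedness coefficients: 0.5 mother-offspring and
#: full siblings, 0.25 half-siblings / grandmother-grandchild / avuncular,
#: 0.375 for sibling pairs that cannot be resolved to full or half.
RC_VALUES = (0.0, 0.25, 0.375, 0.5)

#: Four field seasons: early/late dry season in two consecutive years.
DEFAULT_SEASON_ORDER = (
    "early-dry-2016",
    "late-dry-2016",
    "early-dry-2017",
    "late-dry-2017",
)


class DyadomeError(Exception):
    """Base class for errors raised by this package."""


class ValidationError(DyadomeError):
    """Malformed or internally inconsistent input."""


class UndefinedValueError(DyadomeError):
    """A quantity is mathematically undefined for the given input."""


_SAMPLE_COLUMNS = ("individual_id", "group_id", "season_id")
_INDIVIDUAL_COLUMNS = ("group_id", "sex", "age_class")


@dataclass
class StudyMetadata:
    """Sample-to-individual-to-group mapping plus individual covariates.

    Parameters
    ----------
    samples : pandas.DataFrame
        Indexed by ``sample_id``; columns ``individual_id``, ``group_id``,
        ``season_id`` (optionally ``collection_date``).
    individuals : pandas.DataFrame
        Indexed by ``individual_id``; columns ``group_id``, ``sex``,
        ``age_class`` and optionally ``rank_category``,
        ``reproductive_state``, ``age``, ``fgcm``, ``leaf_intake``.
    dyads : pandas.DataFrame, optional
        One row per unordered individual pair with dyadic covariates
        (``individual_a``, ``individual_b``, ``affiliation_minutes``,
        ``residence_years``). ``individual_a < individual_b`` lexically.
    season_order : tuple of str
        Chronological order of the field seasons.
    """

    samples: pd.DataFrame
    individuals: pd.DataFrame
    dyads: pd.DataFrame | None = None
    season_order: tuple = DEFAULT_SEASON_ORDER

    def __post_init__(self):
        for col in _SAMPLE_COLUMNS:
            if col not in self.samples.columns:
                raise ValidationError(f"samples table lacks column {col!r}")
        for col in _INDIVIDUAL_COLUMNS:
            if col not in self.individuals.columns:
                raise ValidationError(f"individuals table lacks column {col!r}")
        if self.samples.index.has_duplicates:
            dup = self.samples.index[self.samples.index.duplicated()][0]
            raise ValidationError(f"duplicate sample id {dup!r}")
        if self.individuals.index.has_duplicates:
            dup = self.individuals.index[self.individuals.index.duplicated()][0]
            raise ValidationError(f"duplicate individual id {dup!r}")
        missing = set(self.samples["individual_id"]) - set(self.individuals.index)
        if missing:
            raise ValidationError(
                f"samples reference unknown individuals: {sorted(missing)}"
            )
        self._check_categories("age_class", AGE_CLASSES, self.individuals)
        self._check_categories("rank_category", RANK_CATEGORIES, self.individuals)
        self._check_categories(
            "reproductive_state", REPRODUCTIVE_STATES, self.individuals
        )
        unknown_seasons = set(self.samples["season_id"]) - set(self.season_order)
        if unknown_seasons:
            raise ValidationError(
                f"samples use seasons not in season_order: {sorted(unknown_seasons)}"
            )

    @staticmethod
    def _check_categories(col, allowed, frame):
        if col not in frame.columns:
            return
        values = frame[col].dropna()
        bad = set(values) - set(allowed)
        if bad:
            raise ValidationError(f"invalid {col} values: {sorted(bad)}")

    # -- convenience lookups -------------------------------------------------

    @property
    def sample_ids(self) -> list:
        return list(self.samples.index)

    @property
    def individual_ids(self) -> list:
        return list(self.individuals.index)

    @property
    def group_ids(self) -> list:
        return sorted(self.individuals["group_id"].unique())

    @property
    def seasons(self) -> list:
        present = set(self.samples["season_id"])
        return [s for s in self.season_order if s in present]

    def individuals_per_group(self) -> pd.Series:
        return self.individuals.groupby("group_id").size()

    def sample_individuals(self, sample_ids) -> np.ndarray:
        """Individual id for each sample id, in order."""
        return self.samples.loc[list(sample_ids), "individual_id"].to_numpy()

    def sample_groups(self, sample_ids) -> np.ndarray:
        return self.samples.loc[list(sample_ids), "group_id"].to_numpy()

    def sample_seasons(self, sample_ids) -> np.ndarray:
        return self.samples.loc[list(sample_ids), "season_id"].to_numpy()

    def subset_samples(self, sample_ids) -> "StudyMetadata":
        """Metadata restricted to the given samples (individuals retained)."""
        return StudyMetadata(
            samples=self.samples.loc[list(sample_ids)].copy(),
            individuals=self.individuals.copy(),
            dyads=None if self.dyads is None else self.dyads.copy(),
            season_order=self.season_order,
        )


@dataclass
class ValidationReport:
    """Outcome of cross-checking counts, tree, and metadata.

    ``entries`` is a list of ``(severity, code, message)`` triples with
    severity ``"fatal"`` or ``"warning"``. The pipeline refuses to run when
    any fatal entry is present.
    """

    entries: list = field(default_factory=list)

    def add(self, severity: str, code: str, message: str) -> None:
        if severity not in ("fatal", "warning"):
            raise ValueError(f"unknown severity {severity!r}")
        self.entries.append((severity, code, message))

    @property
    def fatal(self) -> list:
        return [e for e in self.entries if e[0] == "fatal"]

    @property
    def warnings(self) -> list:
        return [e for e in self.entries if e[0] == "warning"]

    @property
    def ok(self) -> bool:
        return not self.fatal

    def __str__(self) -> str:
        if not self.entries:
            return "validation: clean"
        lines = [f"[{sev}] {code}: {msg}" for sev, code, msg in self.entries]
        return "\n".join(lines)


def validate_relatedness(
    relatedness: pd.DataFrame, individuals=None, atol: float = 1e-12
) -> pd.DataFrame:
    """Check a maternal relatedness matrix and return it.

    Requires a square, symmetric matrix whose off-diagonal entries are in
    the closed RC set {0, 0.25, 0.375, 0.5}; the diagonal is unused and
    ignored. When ``individuals`` is given, every one of them must be
    present in the matrix labels.
    """
    if list(relatedness.index) != list(relatedness.columns):
        raise ValidationError("relatedness matrix index and columns differ")
    values = relatedness.to_numpy(dtype=float)
    if not np.allclose(values, values.T, atol=atol):
        raise ValidationError("relatedness matrix is not symmetric")
    off = values[~np.eye(len(values), dtype=bool)]
    allowed = np.isclose(off[:, None], np.array(RC_VALUES)[None, :], atol=atol).any(
        axis=1
    )
    if not allowed.all():
        bad = sorted(set(np.round(off[~allowed], 6)))
        raise ValidationError(f"relatedness values outside {RC_VALUES}: {bad}")
    if individuals is not None:
        missing = set(individuals) - set(relatedness.index)
        if missing:
            raise ValidationError(
                f"individuals missing from relatedness matrix: {sorted(missing)}"
            )
    return relatedness
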