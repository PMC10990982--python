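"""Long-format longitudinal data, missing-data patterns and dropout summaries.

A longitudinal design plans measurements of a response at a fixed set of
occasions (weeks).  A missing response is encoded by the *absence* of a row,
the long-format mixed-model convention, so the observation mask of a subject
over the key occasions is exactly the set of rows present.  From the masks we
derive the catalogue of missing-data patterns (complete, monotone dropout,
intermittent, mixed), a subject-level dropout indicator, the last-observed
week and its log (the proxy for dropout time used by the joint dropout-time
models), and a pattern-by-group contingency table with a Monte-Carlo exact
test of independence.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import random_table

logger = logging.getLogger("patternmix")

DEFAULT_PLANNED_WEEKS = (0, 1, 2, 3, 4, 5, 6)
DEFAULT_KEY_WEEKS = (0, 1, 3, 6)

PATTERN_CLASSES = ("complete", "monotone_dropout", "intermittent", "mixed")


class ConfigurationError(ValueError):
    """A requested column/option is missing or inconsistent."""


class DataError(ValueError):
    """The data violate a structural invariant (e.g. duplicated rows)."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class LongitudinalDataset:
    """Long-format records plus subject-level covariates.

    Parameters
    ----------
    records
        DataFrame with columns ``subject``, ``week``, ``y``; one row per
        observed response.  A missing response has no row.
    covariates
        Subject-level table indexed by subject id (e.g. a binary ``drug``
        column).  Its index order defines the canonical subject order.
    planned_weeks
        Occasions the design intends.
    key_weeks
        Ordered subset of ``planned_weeks`` used to define missing-data
        patterns.  Occasions outside this set (e.g. the rarely assessed
        mid-weeks) are used as data when present but do not enter the
        pattern definition.
    """

    records: pd.DataFrame
    covariates: pd.DataFrame
    planned_weeks: tuple = DEFAULT_PLANNED_WEEKS
    key_weeks: tuple = DEFAULT_KEY_WEEKS

    def __post_init__(self) -> None:
        self.records = pd.DataFrame(self.records).reset_index(drop=True)
        self.covariates = pd.DataFrame(self.covariates)
        self.planned_weeks = tuple(self.planned_weeks)
        self.key_weeks = tuple(self.key_weeks)
        self.validate()

    def validate(self) -> None:
        req = {"subject", "week", "y"}
        missing = req - set(self.records.columns)
        if missing:
            raise ConfigurationError(f"records missing columns: {sorted(missing)}")
        if not set(self.key_weeks) <= set(self.planned_weeks):
            raise ConfigurationError("key_weeks must be a subset of planned_weeks")
        dup = self.records.duplicated(subset=["subject", "week"])
        if dup.any():
            offenders = self.records.loc[dup, ["subject", "week"]].to_records(index=False)
            raise DataError(f"duplicate (subject, week) rows: {list(offenders)[:10]}")
        bad_weeks = set(self.records["week"]) - set(self.planned_weeks)
        if bad_weeks:
            raise DataError(f"weeks outside the planned design: {sorted(bad_weeks)}")
        rec_subjects = set(self.records["subject"])
        cov_subjects = set(self.covariates.index)
        if rec_subjects - cov_subjects:
            raise DataError(
                f"subjects in records without covariates: {sorted(rec_subjects - cov_subjects)[:10]}"
            )
        if cov_subjects - rec_subjects:
            raise DataError(
                f"subjects in covariates without records: {sorted(cov_subjects - rec_subjects)[:10]}"
            )
        if self.covariates.index.duplicated().any():
            raise DataError("duplicated subject ids in covariates")

    # -- convenience ------------------------------------------------------

    @property
    def subjects(self) -> pd.Index:
        return self.covariates.index

    @property
    def n_subjects(self) -> int:
        return len(self.covariates)

    def with_covariates(self, extra: pd.DataFrame) -> "LongitudinalDataset":
        """Return a copy with additional subject-level columns."""
        cov = self.covariates.join(extra, how="left")
        return replace(self, covariates=cov)

    def to_csv(self, path, delimiter: str = ",") -> None:
        """Write the dataset as one long-format CSV (round-trips with
        :func:`read_long_csv`)."""
        wide = self.records.merge(
            self.covariates, left_on="subject", right_index=True, how="left"
        )
        wide = wide.rename(columns={"subject": "id"})
        wide.to_csv(path, sep=delimiter, index=False)


@dataclass
class PatternAssignment:
    """Per-subject observation masks over the key weeks and their catalogue.

    ``masks`` maps each subject to a bit-string over ``key_weeks``
    ('1' = observed).  Pattern ids are 1-based, ordered by descending
    frequency with ties broken by ascending mask value, which reproduces the
    conventional presentation (complete data first).
    """

    masks: pd.Series
    pattern_id: pd.Series
    pattern_class: pd.Series          # per subject
    frequencies: pd.Series            # pattern_id -> count
    mask_of_pattern: Mapping[int, str]
    key_weeks: tuple

    def class_of_pattern(self, pid: int) -> str:
        return classify_mask(self.mask_of_pattern[pid])


@dataclass
class DropoutSummary:
    """Subject-level dropout indicator and last-observed-week variables.

    ``drop`` is 1 when the final key week is unobserved.  ``max_week`` is the
    last week with any observed record.  ``ln_max_week`` is
    ``log(max_week + week_offset)``; with the default offset of 1 the weeks
    are effectively renumbered 1..7 so the log is defined for subjects
    observed only at baseline.
    """

    drop: pd.Series
    max_week: pd.Series
    ln_max_week: pd.Series
    drop_proportion: float
    week_offset: float = 1.0


@dataclass
class PatternCrosstab:
    """Observed and expected pattern-by-group counts."""

    observed: pd.DataFrame
    expected: pd.DataFrame
    row_totals: pd.Series
    col_totals: pd.Series

    @property
    def grand_total(self) -> int:
        return int(self.row_totals.sum())


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def read_long_csv(
    path,
    column_map: Mapping[str, str] | None = None,
    delimiter: str = ",",
    planned_weeks: Sequence = DEFAULT_PLANNED_WEEKS,
    key_weeks: Sequence = DEFAULT_KEY_WEEKS,
) -> LongitudinalDataset:
    """Read a long-format CSV into a :class:`LongitudinalDataset`.

    ``column_map`` maps the logical names ``id``, ``week``, ``y`` to file
    column names (defaults to identity).  All remaining columns are treated
    as subject-level covariates and must be constant within subject.  Rows
    with a missing response are dropped: absence of a row is what encodes
    missingness downstream.
    """
    cmap = {"id": "id", "week": "week", "y": "y"}
    cmap.update(column_map or {})
    raw = pd.read_csv(path, sep=delimiter)
    for logical, col in cmap.items():
        if col not in raw.columns:
            raise ConfigurationError(
                f"column {col!r} (mapped from {logical!r}) not found in {path}"
            )
    rec = raw.rename(
        columns={cmap["id"]: "subject", cmap["week"]: "week", cmap["y"]: "y"}
    )
    rec["y"] = pd.to_numeric(rec["y"], errors="coerce")
    rec["week"] = pd.to_numeric(rec["week"])
    observed = rec.dropna(subset=["y"]).reset_index(drop=True)

    cov_cols = [c for c in rec.columns if c not in ("subject", "week", "y")]
    # subject-level covariates come from all rows (a fully missing response
    # row still carries covariate information, but such subjects cannot stay
    # in the dataset without any record)
    cov = rec.loc[rec["subject"].isin(observed["subject"]), ["subject"] + cov_cols]
    grouped = cov.groupby("subject", sort=False)
    for c in cov_cols:
        if grouped[c].nunique(dropna=False).gt(1).any():
            raise DataError(f"covariate {c!r} varies within subject; "
                            "time-varying covariates are not supported")
    covariates = grouped.first()

    return LongitudinalDataset(
        records=observed[["subject", "week", "y"]],
        covariates=covariates,
        planned_weeks=tuple(planned_weeks),
        key_weeks=tuple(key_weeks),
    )


# ---------------------------------------------------------------------------
# patterns
# ---------------------------------------------------------------------------

def classify_mask(mask: str) -> str:
    """Classify one observation mask over the key weeks.

    complete: all observed.  monotone_dropout: a (possibly empty) prefix of
    1s followed only by 0s.  intermittent: interior gaps but the final key
    week observed.  mixed: interior gaps plus trailing missingness.
    """
    bits = [int(b) for b in mask]
    if all(bits):
        return "complete"
    first_zero = mask.find("0")
    if "1" not in mask[first_zero:]:
        return "monotone_dropout"
    if bits[-1] == 1:
        return "intermittent"
    return "mixed"


def classify_patterns(ds: LongitudinalDataset) -> PatternAssignment:
    """Assign each subject its observation mask over the key weeks and
    catalogue the distinct patterns."""
    if not ds.key_weeks:
        raise ConfigurationError("key_weeks must be nonempty")
    key = list(ds.key_weeks)
    present = set(zip(ds.records["subject"], ds.records["week"]))
    masks = pd.Series(
        {
            s: "".join("1" if (s, w) in present else "0" for w in key)
            for s in ds.subjects
        },
        name="mask",
    ).reindex(ds.subjects)

    zero = masks == "0" * len(key)
    if zero.any():
        logger.warning(
            "%d subject(s) observed at no key week; assigned the all-zero mask",
            int(zero.sum()),
        )

    counts = masks.value_counts()
    ordered = sorted(counts.index, key=lambda m: (-counts[m], m))
    mask_of_pattern = {i + 1: m for i, m in enumerate(ordered)}
    id_of_mask = {m: i for i, m in mask_of_pattern.items()}
    pattern_id = masks.map(id_of_mask).rename("pattern_id")
    pattern_class = masks.map(classify_mask).rename("pattern_class")
    frequencies = pd.Series(
        {pid: int(counts[m]) for pid, m in mask_of_pattern.items()},
        name="count",
    ).sort_index()
    return PatternAssignment(
        masks=masks,
        pattern_id=pattern_id,
        pattern_class=pattern_class,
        frequencies=frequencies,
        mask_of_pattern=mask_of_pattern,
        key_weeks=tuple(key),
    )


def dropout_summary(
    ds: LongitudinalDataset,
    pa: PatternAssignment,
    week_offset: float = 1.0,
) -> DropoutSummary:
    """Derive the dropout indicator and the last-observed-week variables.

    ``drop`` is 1 exactly when the final key week is unobserved (on the
    reference illness-severity data this is the union of the monotone-dropout
    patterns and the single mixed pattern).  ``max_week`` uses every observed
    record, including non-key weeks.  The log transform renumbers weeks
    starting at ``week_offset`` (default 1) so it is finite for baseline-only
    subjects; this renumbering reproduces the published dropout-time
    regression intercepts exactly.
    """
    drop = pa.masks.str[-1].eq("0").astype(int).rename("drop")
    max_week = ds.records.groupby("subject")["week"].max().reindex(ds.subjects)
    max_week = max_week.rename("max_week")
    if max_week.isna().any():
        raise DataError("subjects with no observed record at all")
    ln_max_week = np.log(max_week.astype(float) + week_offset).rename("ln_max_week")
    if not np.isfinite(ln_max_week).all():
        raise DataError("non-finite ln_max_week; check week_offset")
    return DropoutSummary(
        drop=drop,
        max_week=max_week,
        ln_max_week=ln_max_week,
        drop_proportion=float(drop.mean()),
        week_offset=week_offset,
    )


# ---------------------------------------------------------------------------
# contingency table and exact test
# ---------------------------------------------------------------------------

def pattern_crosstab(pa: PatternAssignment, group: pd.Series) -> PatternCrosstab:
    """Observed and expected pattern-by-group counts.

    ``expected[i, j] = row_total[i] * col_total[j] / grand_total`` — the
    usual independence expectation.  Rounding happens only at display time.
    """
    group = pd.Series(group).reindex(pa.pattern_id.index)
    if group.isna().any():
        raise DataError("group undefined for some subjects")
    observed = (
        pd.crosstab(pa.pattern_id, group)
        .reindex(index=pa.frequencies.index, fill_value=0)
        .sort_index()
    )
    observed.index.name = "pattern_id"
    if observed.shape[1] == 1:
        logger.warning("group has a single level; expected counts equal observed")
    row = observed.sum(axis=1)
    col = observed.sum(axis=0)
    grand = row.sum()
    expected = pd.DataFrame(
        np.outer(row.to_numpy(), col.to_numpy()) / grand,
        index=observed.index,
        columns=observed.columns,
    )
    return PatternCrosstab(
        observed=observed, expected=expected, row_totals=row, col_totals=col
    )


def _log_table_prob(tables: np.ndarray, row: np.ndarray, col: np.ndarray) -> np.ndarray:
    """Log-probability of r x c tables under the fixed-margins
    (multivariate hypergeometric) null."""
    n = row.sum()
    const = gammaln(row + 1).sum() + gammaln(col + 1).sum() - gammaln(n + 1)
    return const - gammaln(np.asarray(tables, dtype=float) + 1).sum(axis=(-2, -1))


def mc_exact_independence_test(
    ct: PatternCrosstab, reps: int = 100_000, seed: int = 0
) -> float:
    """Monte-Carlo exact (Fisher-type) test of row/column independence.

    Samples ``reps`` tables with the observed margins from the hypergeometric
    null and returns the proportion whose null probability is at most that of
    the observed table, with the (s+1)/(reps+1) continuity correction.  The
    estimate is reproducible given ``seed``.
    """
    if reps < 1000:
        raise ConfigurationError("reps must be at least 1000")
    obs = ct.observed.to_numpy()
    row = ct.row_totals.to_numpy()
    col = ct.col_totals.to_numpy()
    if (row <= 0).any():
        bad = ct.row_totals.index[row <= 0].tolist()
        raise DataError(f"empty row(s) in the contingency table: {bad}")
    if (col <= 0).any():
        bad = ct.col_totals.index[col <= 0].tolist()
        raise DataError(f"empty column(s) in the contingency table: {bad}")
    rng = np.random.default_rng(seed)
    lp_obs = _log_table_prob(obs, row, col)
    hits = 0
    chunk = 20_000
    done = 0
    while done < reps:
        k = min(chunk, reps - done)
        tables = random_table(row, col).rvs(k, random_state=rng)
        lp = _log_table_prob(tables, row, col)
        hits += int((lp <= lp_obs + 1e-9).sum())
        done += k
    return (hits + 1) / (reps + 1)


def write_pattern_table(
    ds: LongitudinalDataset,
    pa: PatternAssignment,
    ct: PatternCrosstab,
    path,
) -> pd.DataFrame:
    """Pattern catalogue (mask, class, per-group observed and expected
    counts) as a CSV table; returns the DataFrame written."""
    out = pd.DataFrame(
        {
            "pattern_id": pa.frequencies.index,
            "mask": [pa.mask_of_pattern[p] for p in pa.frequencies.index],
            "class": [classify_mask(pa.mask_of_pattern[p]) for p in pa.frequencies.index],
            "count": pa.frequencies.to_numpy(),
        }
    ).set_index("pattern_id")
    for g in ct.observed.columns:
        out[f"observed_{g}"] = ct.observed[g]
        out[f"expected_{g}"] = ct.expected[g].round(1)
    if path is not None:
        out.to_csv(path)
    return out
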