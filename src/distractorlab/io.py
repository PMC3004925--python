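"""Reading, writing and validation of exam data files.

All on-disk formats are UTF-8 comma-separated CSV:

* responses — long format with columns ``candidate_id,item_id,choice`` or
  wide format with ``candidate_id`` plus one column per item;
* answer key — ``item_id,correct,options`` with options given as a string
  such as ``"ABCDE"``;
* expert ratings — ``expert_id,item_id,option,rank`` with an optional
  ``block`` column;
* report tables — plain CSV with a fixed column order.

Omitted answers are represented by the reserved label ``OMIT``.  They are
scored as incorrect and are never counted as a distractor selection, but
the candidate stays in every denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

#: Reserved label for an omitted answer.
OMIT = "OMIT"

#: Default ordered option set for five-option one-best-answer items.
DEFAULT_OPTIONS = ("A", "B", "C", "D", "E")

LONG_COLUMNS = ("candidate_id", "item_id", "choice")


class DataFormatError(ValueError):
    """Raised when an input file violates a structural invariant."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class ResponseMatrix:
    """Candidate x item matrix of chosen option labels.

    ``table`` is indexed by candidate id with one column per item; every
    cell holds an option label or :data:`OMIT`.  Invariants (checked by
    :meth:`validate`): the matrix is complete, labels come from the allowed
    option set, and there are at least 2 candidates and 2 items.
    """

    table: pd.DataFrame
    options: tuple[str, ...] = DEFAULT_OPTIONS

    def __post_init__(self) -> None:
        self.table.index = self.table.index.astype(str)
        self.table.columns = self.table.columns.astype(str)
        self.validate()

    # -- accessors ---------------------------------------------------------
    @property
    def candidate_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def item_ids(self) -> list[str]:
        return list(self.table.columns)

    @property
    def n_candidates(self) -> int:
        return len(self.table.index)

    @property
    def n_items(self) -> int:
        return len(self.table.columns)

    def choice(self, candidate: str, item: str) -> str:
        return self.table.at[candidate, item]

    def copy(self) -> "ResponseMatrix":
        return ResponseMatrix(self.table.copy(), self.options)

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        if self.n_candidates < 2 or self.n_items < 2:
            raise DataFormatError(
                f"need at least 2 candidates and 2 items, got "
                f"{self.n_candidates} x {self.n_items}"
            )
        if self.table.index.duplicated().any():
            dup = self.table.index[self.table.index.duplicated()][0]
            raise DataFormatError(f"duplicate candidate id {dup!r}")
        if self.table.columns.duplicated().any():
            dup = self.table.columns[self.table.columns.duplicated()][0]
            raise DataFormatError(f"duplicate item id {dup!r}")
        if self.table.isna().any().any():
            cand = self.table.index[self.table.isna().any(axis=1)][0]
            raise DataFormatError(f"candidate {cand!r} is missing an entry")
        allowed = set(self.options) | {OMIT}
        bad = set(self.table.to_numpy().ravel()) - allowed
        if bad:
            raise DataFormatError(
                f"option labels outside the declared set: {sorted(bad)}"
            )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ResponseMatrix):
            return NotImplemented
        return self.options == other.options and self.table.equals(other.table)


@dataclass
class AnswerKey:
    """Correct option and ordered option set per item."""

    correct: dict[str, str]
    options: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for item, ans in self.correct.items():
            opts = self.options.setdefault(item, DEFAULT_OPTIONS)
            if ans not in opts:
                raise DataFormatError(
                    f"item {item!r}: correct option {ans!r} not in option "
                    f"set {''.join(opts)}"
                )

    @property
    def item_ids(self) -> list[str]:
        return list(self.correct)

    def distractors(self, item: str) -> tuple[str, ...]:
        ans = self.correct[item]
        return tuple(o for o in self.options[item] if o != ans)


@dataclass
class ExpertRatings:
    """Per-expert least-plausibility marks.

    ``frame`` has columns ``expert_id, item_id, option, rank`` (rank 1 or 2)
    and optionally ``block``.  Per expert and item the marks are either one
    rank-1 plus one rank-2, or two rank-1 marks (a tie); never more than two
    marks and never the keyed correct answer.
    """

    frame: pd.DataFrame
    key: AnswerKey | None = None

    def __post_init__(self) -> None:
        missing = {"expert_id", "item_id", "option", "rank"} - set(self.frame.columns)
        if missing:
            raise DataFormatError(f"ratings missing columns {sorted(missing)}")
        self.frame = self.frame.astype(
            {"expert_id": str, "item_id": str, "option": str, "rank": int}
        )
        self.validate()

    def validate(self) -> None:
        if not self.frame["rank"].isin((1, 2)).all():
            raise DataFormatError("rating ranks must be 1 or 2")
        for (expert, item), grp in self.frame.groupby(
            ["expert_id", "item_id"], sort=False
        ):
            ranks = sorted(grp["rank"])
            if len(grp) > 2:
                raise DataFormatError(
                    f"expert {expert!r} marked {len(grp)} options on item "
                    f"{item!r}; at most two are allowed"
                )
            if ranks not in ([1, 2], [1, 1], [1], [2]):
                raise DataFormatError(
                    f"expert {expert!r}, item {item!r}: marks must be one "
                    f"rank-1 and one rank-2, or a rank-1 tie (got {ranks})"
                )
            if grp["option"].duplicated().any():
                raise DataFormatError(
                    f"expert {expert!r} marked the same option twice on "
                    f"item {item!r}"
                )
        if self.key is not None:
            for item, grp in self.frame.groupby("item_id", sort=False):
                if item not in self.key.correct:
                    continue
                ans = self.key.correct[item]
                if (grp["option"] == ans).any():
                    raise DataFormatError(
                        f"item {item!r}: an expert marked the keyed answer "
                        f"{ans!r} as implausible"
                    )

    @property
    def expert_ids(self) -> list[str]:
        return sorted(self.frame["expert_id"].unique())

    @property
    def item_ids(self) -> list[str]:
        return sorted(self.frame["item_id"].unique())

    def marks(self, expert: str, item: str) -> dict[str, int]:
        """Mapping option -> rank for one expert on one item."""
        sel = self.frame[
            (self.frame["expert_id"] == expert) & (self.frame["item_id"] == item)
        ]
        return dict(zip(sel["option"], sel["rank"]))


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_responses(
    path,
    fmt: str = "auto",
    options: tuple[str, ...] = DEFAULT_OPTIONS,
) -> ResponseMatrix:
    """Read a response matrix from CSV (long or wide format).

    ``fmt`` is ``"long"``, ``"wide"`` or ``"auto"`` (detected from the
    header: the long format has exactly the columns
    ``candidate_id,item_id,choice``).  Duplicate (candidate, item) cells and
    incomplete matrices are rejected.
    """
    df = pd.read_csv(path, dtype=str)
    if fmt == "auto":
        fmt = "long" if list(df.columns) == list(LONG_COLUMNS) else "wide"
    if fmt == "long":
        if list(df.columns) != list(LONG_COLUMNS):
            raise DataFormatError(
                f"long-format responses need columns {LONG_COLUMNS}, got "
                f"{list(df.columns)}"
            )
        dup = df.duplicated(subset=["candidate_id", "item_id"])
        if dup.any():
            row = df[dup].iloc[0]
            raise DataFormatError(
                f"duplicate cell for candidate {row['candidate_id']!r}, "
                f"item {row['item_id']!r}"
            )
        wide = df.pivot(index="candidate_id", columns="item_id", values="choice")
        wide = wide.rename_axis(index=None, columns=None)
        # preserve first-appearance order of candidates and items
        wide = wide.reindex(
            index=df["candidate_id"].unique(), columns=df["item_id"].unique()
        )
    else:
        if df.columns[0] != "candidate_id":
            raise DataFormatError(
                "wide-format responses must start with a candidate_id column"
            )
        if df["candidate_id"].duplicated().any():
            dup_id = df["candidate_id"][df["candidate_id"].duplicated()].iloc[0]
            raise DataFormatError(f"duplicate candidate id {dup_id!r}")
        wide = df.set_index("candidate_id")
        wide.index.name = None
    return ResponseMatrix(wide, options=options)


def read_key(path) -> AnswerKey:
    """Read an answer key CSV with columns ``item_id,correct[,options]``."""
    df = pd.read_csv(path, dtype=str)
    if not {"item_id", "correct"}.issubset(df.columns):
        raise DataFormatError("key needs columns item_id,correct[,options]")
    if df["item_id"].duplicated().any():
        dup = df["item_id"][df["item_id"].duplicated()].iloc[0]
        raise DataFormatError(f"duplicate key entry for item {dup!r}")
    correct = dict(zip(df["item_id"], df["correct"]))
    options: dict[str, tuple[str, ...]] = {}
    if "options" in df.columns:
        options = {
            item: tuple(opts)
            for item, opts in zip(df["item_id"], df["options"])
            if isinstance(opts, str)
        }
    return AnswerKey(correct=correct, options=options)


def read_expert_ratings(path, key: AnswerKey | None = None) -> ExpertRatings:
    """Read expert ratings; with ``key`` also reject marks on keyed answers."""
    df = pd.read_csv(path, dtype=str)
    return ExpertRatings(df, key=key)


def read_table(path) -> pd.DataFrame:
    """Read back a report table written by :func:`write_table`."""
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_responses(responses: ResponseMatrix, path, fmt: str = "long") -> None:
    if fmt == "wide":
        out = responses.table.rename_axis("candidate_id").reset_index()
        out.to_csv(path, index=False)
        return
    long = (
        responses.table.rename_axis("candidate_id")
        .reset_index()
        .melt(id_vars="candidate_id", var_name="item_id", value_name="choice")
        .sort_values(["candidate_id", "item_id"], kind="stable")
    )
    long.to_csv(path, index=False)


def write_key(key: AnswerKey, path) -> None:
    rows = [
        {"item_id": item, "correct": key.correct[item],
         "options": "".join(key.options[item])}
        for item in key.item_ids
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_expert_ratings(ratings: ExpertRatings, path) -> None:
    ratings.frame.to_csv(path, index=False)


def write_table(report: pd.DataFrame, path, decimals: int | None = None) -> None:
    """Write a report table bit-stably.

    The column order of ``report`` is preserved.  With ``decimals`` set,
    float columns are rounded to that many decimal places before writing
    (report CSVs use 2, matching the convention of printing percentages and
    reliabilities to two decimals); otherwise values round-trip exactly.
    """
    out = report.copy()
    if decimals is not None:
        for col in out.columns:
            if pd.api.types.is_float_dtype(out[col]):
                out[col] = out[col].round(decimals)
    out.to_csv(path, index=False)
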