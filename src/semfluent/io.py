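"""Fluency-table, lexicon and edge-list I/O, plus list cleaning.

The observed data are ordered category-fluency lists (here: animal naming),
several per participant.  Before network estimation two kinds of responses
are removed: *intrusions* (items outside the category lexicon, e.g. "house")
and *perseverations* (repetitions of an item within the same list).  Cleaning
is lexicon-driven and deterministic: normalization is lower-casing and
whitespace canonicalization only, with no spell correction.

File formats
------------
- Fluency table: CSV with header ``id,listnum,position,item`` (UTF-8).
- Lexicon: plain text, one canonical item per line, ``#`` comments allowed.
- Network: 2-column TSV edge list, one undirected edge per row.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

REQUIRED_COLUMNS = ("id", "listnum", "position", "item")

_WS = re.compile(r"\s+")


class FluencyParseError(ValueError):
    """Raised when a fluency table violates its format contract."""


@dataclass(frozen=True)
class FluencyList:
    """One participant's ordered responses for a single list administration."""

    participant_id: str
    list_index: int
    items: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.items)


@dataclass(frozen=True)
class CleaningReport:
    """Totals of removed responses over a whole fluency table."""

    n_responses_total: int
    n_intrusions: int
    n_perseverations: int
    empty_lists: tuple[tuple[str, int], ...] = field(default_factory=tuple)

    @property
    def intrusion_rate(self) -> float:
        if self.n_responses_total == 0:
            return 0.0
        return self.n_intrusions / self.n_responses_total


def normalize_item(raw: str) -> str:
    """Canonicalize a response: lower-case, trim, collapse internal whitespace."""
    return _WS.sub(" ", str(raw).strip()).lower()


def read_fluency_table(path) -> pd.DataFrame:
    """Read a fluency CSV, validating structure but preserving item strings.

    Raises :class:`FluencyParseError` naming the offending row (1-based data
    row, excluding the header) on missing columns, non-integer positions,
    duplicate ``(id, listnum, position)`` keys, or positions that are not
    consecutive from 0 within a list.
    """
    df = pd.read_csv(path, dtype={"item": str}, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FluencyParseError(f"missing column(s) {missing} in {path}")
    for col in ("listnum", "position"):
        try:
            df[col] = df[col].astype(int)
        except (ValueError, TypeError):
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()].index[0]
            raise FluencyParseError(
                f"non-integer {col!r} in data row {bad + 1} of {path}"
            ) from None
    df["id"] = df["id"].astype(str)
    dup = df.duplicated(subset=["id", "listnum", "position"])
    if dup.any():
        row = int(dup.idxmax())
        key = tuple(df.loc[row, ["id", "listnum", "position"]])
        raise FluencyParseError(
            f"duplicate (id, listnum, position) = {key} at data row {row + 1}"
        )
    for (pid, ln), grp in df.groupby(["id", "listnum"], sort=False):
        pos = sorted(grp["position"])
        if pos != list(range(len(pos))):
            raise FluencyParseError(
                f"positions for participant {pid!r} list {ln} are not "
                f"consecutive from 0: {pos}"
            )
    return df[list(REQUIRED_COLUMNS)]


def write_fluency_table(table: pd.DataFrame, path) -> None:
    table[list(REQUIRED_COLUMNS)].to_csv(path, index=False)


def read_lexicon(path) -> frozenset[str]:
    """Read a one-item-per-line lexicon; '#' starts a comment."""
    members = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            entry = line.split("#", 1)[0].strip()
            if entry:
                members.add(normalize_item(entry))
    if not members:
        raise ValueError(f"lexicon {path} is empty")
    return frozenset(members)


def bundled_lexicon() -> frozenset[str]:
    """The packaged toy animal lexicon (70 items)."""
    ref = resources.files("semfluent.data") / "animal_lexicon.txt"
    with resources.as_file(ref) as path:
        return read_lexicon(path)


def clean_lists(
    table: pd.DataFrame, lexicon: Iterable[str]
) -> tuple[list[FluencyList], CleaningReport]:
    """Normalize items and remove intrusions and perseverations.

    Per list, in order of position: items are normalized; items absent from
    the lexicon are dropped and counted as intrusions; repeats of an item
    already produced in the same list are dropped and counted as
    perseverations.  Order is otherwise preserved.  Lists left empty after
    cleaning are retained (with zero items) and flagged in the report.
    """
    lex = frozenset(lexicon)
    if not lex:
        raise ValueError("lexicon must be nonempty")
    n_total = 0
    n_intr = 0
    n_pers = 0
    out: list[FluencyList] = []
    empty: list[tuple[str, int]] = []
    for (pid, ln), grp in table.groupby(["id", "listnum"], sort=True):
        items: list[str] = []
        seen: set[str] = set()
        for raw in grp.sort_values("position")["item"]:
            n_total += 1
            item = normalize_item(raw)
            if item not in lex:
                n_intr += 1
            elif item in seen:
                n_pers += 1
            else:
                seen.add(item)
                items.append(item)
        if not items:
            empty.append((str(pid), int(ln)))
        out.append(FluencyList(str(pid), int(ln), tuple(items)))
    report = CleaningReport(n_total, n_intr, n_pers, tuple(empty))
    return out, report


def fluency_counts(lists: Sequence[FluencyList]) -> pd.DataFrame:
    """Per-participant cleaned-list lengths and their mean.

    Returns a frame indexed by participant id with columns ``n_lists`` and
    ``mean_items``.
    """
    if not lists:
        raise ValueError("no fluency lists given")
    rows: dict[str, list[int]] = {}
    for fl in lists:
        rows.setdefault(fl.participant_id, []).append(len(fl))
    data = {
        pid: (len(lengths), sum(lengths) / len(lengths))
        for pid, lengths in rows.items()
    }
    df = pd.DataFrame.from_dict(data, orient="index", columns=["n_lists", "mean_items"])
    df.index.name = "id"
    return df.sort_index()


def read_edge_list(path) -> nx.Graph:
    """Read a 2-column TSV edge list into an undirected, unweighted graph.

    Duplicate edges collapse; a self-loop row is an error naming the row.
    """
    g = nx.Graph()
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"row {i} of {path}: expected 2 columns, got {len(parts)}")
            a, b = parts[0].strip(), parts[1].strip()
            if a == b:
                raise ValueError(f"row {i} of {path}: self-loop edge ({a!r}, {b!r})")
            g.add_edge(a, b)
    return g


def write_edge_list(network: nx.Graph, path) -> None:
    """Write edges as a sorted 2-column TSV; round-trip stable with the reader."""
    # isolated nodes are not expressible in a 2-column edge list and are
    # dropped on round-trip; callers needing them must track nodes separately
    with open(path, "w", encoding="utf-8") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in network.edges):
            fh.write(f"{a}\t{b}\n")


def bundled_reference_network() -> nx.Graph:
    """The packaged toy reference association network over the toy lexicon."""
    ref = resources.files("semfluent.data") / "reference_network.tsv"
    with resources.as_file(ref) as path:
        return read_edge_list(path)


def read_score_table(path) -> pd.DataFrame:
    """Read the per-participant score table: id, group, creativity, intelligence."""
    df = pd.read_csv(path, dtype={"id": str})
    needed = {"id", "group", "creativity", "intelligence"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"score table {path} missing column(s) {sorted(missing)}")
    return df.set_index("id")


def write_score_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=True)
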