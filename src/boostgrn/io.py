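"""Readers and writers for the tabular formats the tool touches.

Supported formats:

* time-series expression tables (DREAM4-style TSV: header row names the
  genes, first column is time, replicate experiments concatenated with
  resetting clocks, repeated headers or blank separator lines);
* knockout expression matrices (knocked-out gene x measured gene TSV with
  row and column labels);
* candidate-regulator (transcription factor) lists, one identifier per line;
* directed edge lists, both scored predictions ("regulator<TAB>target<TAB>
  score") and binary gold standards ("regulator<TAB>target<TAB>{0,1}").

Gene identifiers are opaque, case-sensitive strings throughout; missing
values are a hard parse error (the inference method has no imputation step).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import FormatError, ParseError, ValidationError

logger = logging.getLogger(__name__)

_TIME_HEADER_TOKENS = {"time", '"time"'}


@dataclass
class ExpressionSeries:
    """One replicate time course: ordered time points x genes.

    Attributes
    ----------
    gene_ids
        Unique gene identifiers, in column order.
    times
        Strictly increasing time values (arbitrary units).
    values
        Array of shape ``(len(times), len(gene_ids))`` of nonnegative
        expression levels.
    """

    gene_ids: list[str]
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("duplicate gene identifiers in series")
        if self.times.ndim != 1 or len(self.times) < 2:
            raise ValidationError(
                f"a series needs at least 2 time points, got {len(self.times)}"
            )
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError("time values must be strictly increasing within a series")
        if self.values.shape != (len(self.times), len(self.gene_ids)):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"({len(self.times)}, {len(self.gene_ids)})"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("non-finite expression value in series")
        if np.any(self.values < 0):
            raise ValidationError("negative expression value in series")

    @property
    def n_timepoints(self) -> int:
        return len(self.times)


@dataclass
class ExpressionDataset:
    """Replicate time courses over a shared gene panel.

    ``regulator_ids`` designates the candidate regulators (all genes by
    default, or a transcription-factor subset).
    """

    series: list[ExpressionSeries]
    regulator_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.series:
            raise ValidationError("dataset needs at least one series")
        ref = self.series[0].gene_ids
        for idx, s in enumerate(self.series):
            if s.gene_ids != ref:
                raise ValidationError(
                    f"series {idx} gene ids disagree with series 0"
                )
        if not self.regulator_ids:
            self.regulator_ids = list(ref)
        unknown = [r for r in self.regulator_ids if r not in set(ref)]
        if unknown:
            raise ValidationError(f"regulator ids not in gene panel: {unknown}")

    @property
    def gene_ids(self) -> list[str]:
        return self.series[0].gene_ids

    def with_regulators(self, regulator_ids: Sequence[str]) -> "ExpressionDataset":
        """Return a copy restricted to the given candidate regulators."""
        return ExpressionDataset(series=self.series, regulator_ids=list(regulator_ids))


@dataclass
class KnockoutMatrix:
    """Steady-state expression after single-gene knockouts.

    Row *i* holds the expression of every measured gene after deleting
    ``knocked_gene_ids[i]``.
    """

    knocked_gene_ids: list[str]
    measured_gene_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.knocked_gene_ids)) != len(self.knocked_gene_ids):
            raise ValidationError("duplicate knocked-out gene labels")
        if len(set(self.measured_gene_ids)) != len(self.measured_gene_ids):
            raise ValidationError("duplicate measured gene labels")
        if self.values.shape != (len(self.knocked_gene_ids), len(self.measured_gene_ids)):
            raise ValidationError(
                f"knockout values shape {self.values.shape} does not match labels"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("non-finite knockout expression value")


@dataclass(frozen=True)
class GoldStandard:
    """True directed edges plus the universe of scoreable ordered pairs."""

    edges: frozenset
    universe: frozenset

    def __post_init__(self) -> None:
        if any(r == t for r, t in self.universe):
            raise ValidationError("gold-standard universe contains a self-pair")
        if not self.edges <= self.universe:
            raise ValidationError("gold-standard edges not contained in universe")

    @staticmethod
    def from_pairs(
        edges: Iterable[tuple[str, str]],
        regulator_ids: Sequence[str],
        target_ids: Sequence[str],
    ) -> "GoldStandard":
        """Build a gold standard whose universe is all regulator x target
        ordered pairs excluding self-pairs."""
        universe = frozenset(
            (r, t) for r in regulator_ids for t in target_ids if r != t
        )
        return GoldStandard(edges=frozenset(edges), universe=universe)


def _split_fields(line: str) -> list[str]:
    # DREAM4 files are tab-separated; tolerate space-separated variants
    return line.rstrip("\n").split("\t") if "\t" in line else line.split()


def read_timeseries(path: str | Path, dialect: str = "dream4") -> ExpressionDataset:
    """Read a (possibly multi-replicate) time-series expression table.

    A new replicate series starts whenever the time value is <= the previous
    row's time, or on a blank line or repeated header line.  With
    ``dialect="dream4"`` the first header field must be "Time" (any case);
    ``dialect="plain"`` accepts any first-column name.
    """
    if dialect not in ("dream4", "plain"):
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    header: list[str] | None = None
    gene_ids: list[str] = []
    blocks: list[list[tuple[float, list[float]]]] = []
    current: list[tuple[float, list[float]]] = []

    def flush() -> None:
        nonlocal current
        if current:
            blocks.append(current)
            current = []

    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            if not raw.strip():
                flush()
                continue
            fields = _split_fields(raw)
            if header is None:
                if dialect == "dream4" and fields[0].strip().lower() not in _TIME_HEADER_TOKENS:
                    raise FormatError(
                        f"line {lineno}: expected a 'Time' header column, got {fields[0]!r}"
                    )
                if len(fields) < 2:
                    raise FormatError(f"line {lineno}: header names no genes")
                header = fields
                gene_ids = [f.strip().strip('"') for f in fields[1:]]
                if len(set(gene_ids)) != len(gene_ids):
                    raise FormatError(f"line {lineno}: duplicate gene name in header")
                continue
            if fields == header:
                flush()
                continue
            if len(fields) != len(header):
                raise FormatError(
                    f"line {lineno}: expected {len(header)} fields, got {len(fields)}"
                )
            try:
                row = [float(f) for f in fields]
            except ValueError as exc:
                raise ParseError(f"line {lineno}: non-numeric cell ({exc})") from None
            t = row[0]
            if current and t <= current[-1][0]:
                flush()
            current.append((t, row[1:]))
    flush()

    if header is None or not blocks:
        raise FormatError(f"{path}: no data rows found")
    series = []
    for bidx, block in enumerate(blocks):
        if len(block) < 2:
            raise ValidationError(
                f"{path}: replicate block {bidx} has fewer than 2 time points"
            )
        times = np.array([t for t, _ in block])
        values = np.array([v for _, v in block])
        series.append(ExpressionSeries(gene_ids=list(gene_ids), times=times, values=values))
    return ExpressionDataset(series=series)


def write_timeseries(data: ExpressionDataset, path: str | Path) -> None:
    """Write a dataset as a DREAM4-style TSV with resetting clocks."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("Time\t" + "\t".join(data.gene_ids) + "\n")
        for s in data.series:
            for t, row in zip(s.times, s.values):
                fh.write(_fmt(t) + "\t" + "\t".join(_fmt(v) for v in row) + "\n")


def read_knockout(path: str | Path) -> KnockoutMatrix:
    """Read a labeled knockout expression table (rows: knocked-out gene;
    columns: measured gene)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", index_col=0)
    knocked = [str(i) for i in df.index]
    measured = [str(c) for c in df.columns]
    if len(set(knocked)) != len(knocked):
        raise ValidationError(f"{path}: duplicated knocked-out gene label")
    missing = [g for g in knocked if g not in set(measured)]
    if missing:
        logger.warning(
            "%s: %d knocked-out genes absent from measured columns (partial knockouts)",
            path, len(missing),
        )
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric knockout cell ({exc})") from None
    return KnockoutMatrix(knocked_gene_ids=knocked, measured_gene_ids=measured, values=values)


def write_knockout(ko: KnockoutMatrix, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("knockout\t" + "\t".join(ko.measured_gene_ids) + "\n")
        for gid, row in zip(ko.knocked_gene_ids, ko.values):
            fh.write(gid + "\t" + "\t".join(_fmt(v) for v in row) + "\n")


def read_tf_list(path: str | Path) -> list[str]:
    """Read a candidate-regulator list, one identifier per line."""
    ids = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    if len(set(ids)) != len(ids):
        raise ValidationError(f"{path}: duplicate identifier in regulator list")
    return ids


def read_gold_standard(
    path: str | Path,
    regulator_ids: Sequence[str] | None = None,
    target_ids: Sequence[str] | None = None,
) -> GoldStandard:
    """Read a binary edge list ("regulator<TAB>target<TAB>{0,1}").

    If regulator/target panels are given, the universe is every ordered
    regulator x target pair (no self-pairs); otherwise it is the set of
    pairs listed in the file.
    """
    edges = set()
    listed = set()
    with Path(path).open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            if not raw.strip() or raw.startswith("#"):
                continue
            fields = _split_fields(raw)
            if len(fields) != 3:
                raise FormatError(f"line {lineno}: expected 3 fields, got {len(fields)}")
            reg, tgt, label = fields[0], fields[1], fields[2]
            if label not in ("0", "1"):
                raise ParseError(f"line {lineno}: gold-standard label must be 0 or 1")
            if reg == tgt:
                continue
            listed.add((reg, tgt))
            if label == "1":
                edges.add((reg, tgt))
    if regulator_ids is not None and target_ids is not None:
        return GoldStandard.from_pairs(edges, regulator_ids, target_ids)
    return GoldStandard(edges=frozenset(edges), universe=frozenset(listed))


def write_gold_standard(gold: GoldStandard, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for reg, tgt in sorted(gold.universe):
            fh.write(f"{reg}\t{tgt}\t{1 if (reg, tgt) in gold.edges else 0}\n")


def write_edge_list(ranked, path: str | Path, top_n: int | None = None,
                    header_lines: Sequence[str] = ()) -> None:
    """Write ranked edges as "regulator<TAB>target<TAB>score" lines in
    descending score order, 12 significant digits, optional # comments."""
    entries = ranked.entries if top_n is None else ranked.entries[:top_n]
    for _, _, score in entries:
        if not math.isfinite(score):
            raise ValidationError("edge score is not finite")
    path = Path(path)
    with path.open("w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        for reg, tgt, score in entries:
            fh.write(f"{reg}\t{tgt}\t{score:.12g}\n")


def read_edge_list(path: str | Path):
    """Read a scored edge list written by :func:`write_edge_list`."""
    from .assembly import RankedEdgeList

    entries = []
    with Path(path).open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            if not raw.strip() or raw.startswith("#"):
                continue
            fields = _split_fields(raw)
            if len(fields) != 3:
                raise FormatError(f"line {lineno}: expected 3 fields, got {len(fields)}")
            try:
                score = float(fields[2])
            except ValueError:
                raise ParseError(f"line {lineno}: non-numeric score") from None
            entries.append((fields[0], fields[1], score))
    return RankedEdgeList(entries=entries)


def _fmt(v: float) -> str:
    # 17 significant digits: lossless text round-trip for doubles
    return f"{v:.17g}"
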