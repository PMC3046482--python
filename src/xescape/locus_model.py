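"""Domain types, validation and tabular I/O for scored-nucleus RNA-FISH data.

The data model starts downstream of the microscope: each record is one
interphase nucleus scored for the number of nascent-transcript signals of an
X-borne test probe (0, 1 or 2) and of an autosomal control probe. Female
nuclei with two test signals are "2X-active" (the locus escapes inactivation
on the inactive X in that nucleus); one signal is "1X-active". The autosomal
control restricts analysis to diploid, probe-accessible nuclei.

Packaged fixtures encode the published male-efficiency, female-escape,
Y-paralogue and two-locus concordance tables plus a locus map of the 25
probes (synthetic coordinates preserving the published order).
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Sex",
    "YParalogue",
    "LocusMeta",
    "NucleusScore",
    "PairNucleusScore",
    "CountSummary",
    "TableFormatError",
    "TableValidationError",
    "NoDataError",
    "read_nucleus_table",
    "write_nucleus_table",
    "read_pair_table",
    "write_pair_table",
    "read_locus_meta",
    "write_locus_meta",
    "filter_diploid",
    "summarize_counts",
    "percentages_to_counts",
    "load_fixture",
    "load_locus_map",
    "table1_male_summaries",
    "table2_female_summaries",
    "fixture_checksums",
    "FIXTURE_FILES",
]


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"


class YParalogue(str, Enum):
    """Expression status of a locus's Y-chromosome paralogue in fibroblasts."""

    NONE = "none"
    EXPRESSED = "expressed"
    SILENT = "silent"


class TableFormatError(ValueError):
    """A delimited input file lacks required columns or is unreadable."""


class TableValidationError(ValueError):
    """One or more rows violate domain invariants; offending rows are named."""


class NoDataError(ValueError):
    """A requested locus has no scored nuclei."""


_VALID_SIGNALS = (0, 1, 2)


@dataclass(frozen=True)
class LocusMeta:
    """One probe (BAC/fosmid) on the X: constituent genes and map position.

    ``x_position`` is the integer midpoint of the clone in bp (BED-like
    0-based half-open inputs are converted on read); ``None`` when unmapped.
    """

    locus_id: str
    genes: tuple[str, ...]
    clone_id: str = ""
    x_position: int | None = None
    y_paralogue: YParalogue = YParalogue.NONE
    human_band: str | None = None

    def __post_init__(self) -> None:
        if not self.locus_id:
            raise ValueError("locus_id must be non-empty")
        if len(self.genes) == 0:
            raise ValueError(f"{self.locus_id}: genes must be non-empty")
        if self.x_position is not None and self.x_position <= 0:
            raise ValueError(
                f"{self.locus_id}: x_position must be a positive integer, "
                f"got {self.x_position}"
            )


@dataclass(frozen=True)
class NucleusScore:
    """Signal counts for one nucleus at one locus (single-probe experiment)."""

    nucleus_id: int
    individual_id: str
    sex: Sex
    locus_id: str
    test_signals: int
    control_signals: int

    def __post_init__(self) -> None:
        for name in ("test_signals", "control_signals"):
            v = getattr(self, name)
            if v not in _VALID_SIGNALS:
                raise ValueError(
                    f"nucleus {self.nucleus_id}: {name}={v} outside {{0,1,2}}"
                )


@dataclass(frozen=True)
class PairNucleusScore:
    """Signal counts for one nucleus in a two-locus, two-color experiment."""

    nucleus_id: int
    individual_id: str
    sex: Sex
    locus_a_signals: int
    locus_b_signals: int

    def __post_init__(self) -> None:
        for name in ("locus_a_signals", "locus_b_signals"):
            v = getattr(self, name)
            if v not in _VALID_SIGNALS:
                raise ValueError(
                    f"nucleus {self.nucleus_id}: {name}={v} outside {{0,1,2}}"
                )


@dataclass(frozen=True)
class CountSummary:
    """Per-locus tally of nuclei with 2/1/0 test signals among those scored."""

    locus_id: str
    n_scored: int
    n2: int
    n1: int
    n0: int

    def __post_init__(self) -> None:
        if min(self.n2, self.n1, self.n0) < 0:
            raise ValueError(f"{self.locus_id}: negative count")
        if self.n2 + self.n1 + self.n0 != self.n_scored:
            raise ValueError(
                f"{self.locus_id}: n2+n1+n0 = {self.n2 + self.n1 + self.n0} "
                f"!= n_scored = {self.n_scored}"
            )

    @property
    def fractions(self) -> tuple[float, float, float]:
        """(f2, f1, f0) as fractions of ``n_scored``."""
        if self.n_scored == 0:
            raise NoDataError(f"{self.locus_id}: no scored nuclei")
        n = self.n_scored
        return self.n2 / n, self.n1 / n, self.n0 / n


# ---------------------------------------------------------------------------
# Tabular I/O

NUCLEUS_COLUMNS = [
    "nucleus_id",
    "individual_id",
    "sex",
    "locus_id",
    "test_signals",
    "control_signals",
]

LOCUS_COLUMNS = [
    "locus_id",
    "genes",
    "clone_id",
    "chrom",
    "start",
    "end",
    "y_paralogue",
    "human_band",
]


def read_nucleus_table(
    path: str | Path, permissive: bool = False
) -> list[NucleusScore]:
    """Read a tab-separated scored-nucleus table.

    Every row is validated against the domain invariants. Invalid rows abort
    with a :class:`TableValidationError` naming the offending row numbers
    (1-based, excluding the header); with ``permissive=True`` they are
    dropped with a warning instead.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in NUCLEUS_COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing column(s) {missing}")
    records: list[NucleusScore] = []
    bad: list[tuple[int, str]] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            records.append(
                NucleusScore(
                    nucleus_id=int(row.nucleus_id),
                    individual_id=str(row.individual_id),
                    sex=Sex(str(row.sex)),
                    locus_id=str(row.locus_id),
                    test_signals=int(row.test_signals),
                    control_signals=int(row.control_signals),
                )
            )
        except (ValueError, TypeError) as exc:
            bad.append((i, str(exc)))
    if bad:
        msg = "; ".join(f"row {i}: {m}" for i, m in bad[:10])
        if permissive:
            warnings.warn(
                f"{path}: dropped {len(bad)} invalid row(s) ({msg})",
                stacklevel=2,
            )
        else:
            raise TableValidationError(
                f"{path}: {len(bad)} invalid row(s): {msg}"
            )
    return records


def write_nucleus_table(records: Iterable[NucleusScore], path: str | Path) -> None:
    """Write scored nuclei as the canonical tab-separated table."""
    df = pd.DataFrame(
        [
            (r.nucleus_id, r.individual_id, r.sex.value, r.locus_id,
             r.test_signals, r.control_signals)
            for r in records
        ],
        columns=NUCLEUS_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


PAIR_COLUMNS = [
    "nucleus_id",
    "individual_id",
    "sex",
    "locus_a_signals",
    "locus_b_signals",
]


def read_pair_table(path: str | Path, permissive: bool = False) -> list[PairNucleusScore]:
    """Read a tab-separated two-locus scored-nucleus table."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in PAIR_COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing column(s) {missing}")
    records: list[PairNucleusScore] = []
    bad: list[tuple[int, str]] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            records.append(
                PairNucleusScore(
                    nucleus_id=int(row.nucleus_id),
                    individual_id=str(row.individual_id),
                    sex=Sex(str(row.sex)),
                    locus_a_signals=int(row.locus_a_signals),
                    locus_b_signals=int(row.locus_b_signals),
                )
            )
        except (ValueError, TypeError) as exc:
            bad.append((i, str(exc)))
    if bad:
        msg = "; ".join(f"row {i}: {m}" for i, m in bad[:10])
        if permissive:
            warnings.warn(
                f"{path}: dropped {len(bad)} invalid row(s) ({msg})", stacklevel=2
            )
        else:
            raise TableValidationError(f"{path}: {len(bad)} invalid row(s): {msg}")
    return records


def write_pair_table(records: Iterable[PairNucleusScore], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            (r.nucleus_id, r.individual_id, r.sex.value,
             r.locus_a_signals, r.locus_b_signals)
            for r in records
        ],
        columns=PAIR_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def _parse_locus_df(df: pd.DataFrame, origin: str) -> list[LocusMeta]:
    missing = [c for c in LOCUS_COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(f"{origin}: missing column(s) {missing}")
    metas: list[LocusMeta] = []
    seen: set[str] = set()
    for row in df.itertuples(index=False):
        locus_id = str(row.locus_id)
        if locus_id in seen:
            raise TableValidationError(f"{origin}: duplicate locus_id {locus_id}")
        seen.add(locus_id)
        if pd.isna(row.start) or pd.isna(row.end):
            midpoint = None
        else:
            # BED convention: 0-based half-open [start, end)
            midpoint = int((int(row.start) + int(row.end)) // 2)
        band = None if (pd.isna(row.human_band) or row.human_band == ".") else str(row.human_band)
        metas.append(
            LocusMeta(
                locus_id=locus_id,
                genes=tuple(str(row.genes).split(",")),
                clone_id=str(row.clone_id),
                x_position=midpoint,
                y_paralogue=YParalogue(str(row.y_paralogue)),
                human_band=band,
            )
        )
    return metas


def read_locus_meta(path: str | Path) -> list[LocusMeta]:
    """Read BED-like locus metadata (tab-separated, 0-based half-open)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    return _parse_locus_df(df, str(path))


def write_locus_meta(metas: Iterable[LocusMeta], path: str | Path) -> None:
    rows = []
    for m in metas:
        if m.x_position is None:
            start = end = ""
        else:
            # invert the midpoint convention with a nominal 1 bp interval
            start, end = m.x_position, m.x_position + 1
        rows.append(
            (m.locus_id, ",".join(m.genes), m.clone_id, "X", start, end,
             m.y_paralogue.value, m.human_band if m.human_band else ".")
        )
    pd.DataFrame(rows, columns=LOCUS_COLUMNS).to_csv(
        path, sep="\t", index=False, lineterminator="\n"
    )


# ---------------------------------------------------------------------------
# Filtering and summaries


def filter_diploid(scores: Sequence[NucleusScore]) -> list[NucleusScore]:
    """Keep nuclei with both autosomal control alleles detected.

    Restricting to nuclei showing two control signals excludes polyploid
    nuclei and nuclei the probe could not access ("shielding"). Idempotent.
    """
    kept = [s for s in scores if s.control_signals == 2]
    removed = len(scores) - len(kept)
    if removed:
        logger.info("filter_diploid: removed %d of %d nuclei", removed, len(scores))
    # males carry a single X: two test signals in a diploid male nucleus
    # indicate polyploidy or cross-hybridization; flag, never drop silently
    n_male2 = sum(
        1 for s in kept if s.sex is Sex.MALE and s.test_signals == 2
    )
    if n_male2:
        warnings.warn(
            f"{n_male2} diploid male nucleus(ei) with two test signals "
            "(possible polyploidy or cross-hybridization)",
            stacklevel=2,
        )
    return kept


def summarize_counts(
    scores: Sequence[NucleusScore], locus_id: str
) -> CountSummary:
    """Tally 2/1/0-signal nuclei for one locus (input already diploid-filtered)."""
    sub = [s for s in scores if s.locus_id == locus_id]
    if not sub:
        raise NoDataError(f"no scored nuclei for locus {locus_id!r}")
    counts = [0, 0, 0]
    for s in sub:
        counts[s.test_signals] += 1
    n0, n1, n2 = counts
    return CountSummary(locus_id=locus_id, n_scored=len(sub), n2=n2, n1=n1, n0=n0)


def percentages_to_counts(
    percentages: Sequence[float], n: int = 100
) -> tuple[int, ...]:
    """Apportion printed percentages into integer counts summing to ``n``.

    Largest-remainder (Hamilton) apportionment; ties broken by larger
    remainder first, then by earlier position. Used to reconstruct per-nucleus
    counts from published percentage tables scored at "at least 100" nuclei.
    """
    quotas = [p * n / 100.0 for p in percentages]
    floors = [int(np.floor(q)) for q in quotas]
    shortfall = n - sum(floors)
    if shortfall < 0:
        raise ValueError(f"percentages sum above 100: {percentages}")
    order = sorted(
        range(len(quotas)), key=lambda i: (-(quotas[i] - floors[i]), i)
    )
    counts = floors[:]
    for i in order[:shortfall]:
        counts[i] += 1
    return tuple(counts)


# ---------------------------------------------------------------------------
# Packaged fixtures

FIXTURE_FILES = {
    "table1": "table1_male_efficiency.tsv",
    "table2": "table2_female_counts.tsv",
    "table3": "table3_y_paralogues.tsv",
    "table4": "table4_pair_counts.tsv",
    "locus_map": "locus_map.tsv",
}


def _fixture_path(name: str):
    if name not in FIXTURE_FILES:
        raise KeyError(
            f"unknown fixture {name!r}; choose from {sorted(FIXTURE_FILES)}"
        )
    return resources.files("xescape.fixtures").joinpath(FIXTURE_FILES[name])


def load_fixture(name: str) -> pd.DataFrame:
    """Load a packaged fixture table by name.

    Names: ``table1`` (male one-signal percentages, 25 probes), ``table2``
    (female 2/1/0-signal percentages, 23 probes), ``table3`` (Y-paralogue
    expression vs escape band), ``table4`` (two-locus concordance counts),
    ``locus_map`` (probe metadata with synthetic coordinates).
    """
    with resources.as_file(_fixture_path(name)) as p:
        return pd.read_csv(p, sep="\t", comment="#")


def fixture_checksums() -> dict[str, str]:
    """SHA-256 of each packaged fixture file (integrity check for replays)."""
    out = {}
    for name in FIXTURE_FILES:
        out[name] = hashlib.sha256(_fixture_path(name).read_bytes()).hexdigest()
    return out


def load_locus_map() -> list[LocusMeta]:
    """The 25-probe locus map as typed metadata."""
    return _parse_locus_df(load_fixture("locus_map"), "locus_map")


def table1_male_summaries(n: int = 100) -> list[CountSummary]:
    """Male one-signal percentages reconstructed as counts at nominal ``n``."""
    df = load_fixture("table1")
    out = []
    for row in df.itertuples(index=False):
        n1 = int(round(row.pct_one_signal * n / 100.0))
        out.append(
            CountSummary(
                locus_id=str(row.locus_id), n_scored=n, n2=0, n1=n1, n0=n - n1
            )
        )
    return out


def table2_female_summaries(n: int = 100) -> list[CountSummary]:
    """Female 2/1/0-signal percentages reconstructed as counts at nominal ``n``."""
    df = load_fixture("table2")
    out = []
    for row in df.itertuples(index=False):
        n2, n1, n0 = percentages_to_counts(
            (row.pct_2_signals, row.pct_1_signal, row.pct_0_signals), n=n
        )
        out.append(
            CountSummary(locus_id=str(row.locus_id), n_scored=n, n2=n2, n1=n1, n0=n0)
        )
    return out
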