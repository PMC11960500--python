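"""2x2 drug-event contingency tables and reconstruction from published stats.

Disproportionality analysis compares how often an adverse-event term is
reported with the focal drug against its frequency in the rest of the
database, through the 2x2 table

    =============  ============  ===========
                   target event  other events
    focal drug     a (n11)       b (n10)
    other drugs    c (n01)       d (n00)
    =============  ============  ===========

Two counting units are supported: ``event`` (margins are drug-event pairs;
one case can contribute several events) and ``report`` (margins are cases;
a case contributes at most once per term).  Published analyses mix the two
— PT-level tables here follow the event unit, SOC-level case counts the
report unit — so the unit is always explicit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .errors import ConfigurationError, ReconstructionError, ValidationError

logger = logging.getLogger(__name__)

UNMAPPED_SOC = "unmapped"


@dataclass(frozen=True)
class ContingencyTable:
    """Counts (a, b, c, d) for one drug-event pair."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValidationError(f"cell {name} must be a non-negative "
                                      f"integer, got {v!r}")
            object.__setattr__(self, name, int(v))
        if self.n == 0:
            raise ValidationError("contingency table is all zeros")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def drug_margin(self) -> int:
        return self.a + self.b

    @property
    def event_margin(self) -> int:
        return self.a + self.c

    @property
    def expected(self) -> float:
        """E = (a+b)(a+c)/N, the count expected under independence."""
        return self.drug_margin * self.event_margin / self.n

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)


def build_tables(reactions: pd.DataFrame, focal_case_ids: Iterable,
                 level: str = "PT",
                 pt_soc_map: Mapping[str, str] | None = None,
                 unit: str = "event") -> list[tuple[str, ContingencyTable]]:
    """One contingency table per distinct term.

    ``reactions`` needs columns ``case_id`` and ``pt``.  At SOC level each
    PT is mapped through ``pt_soc_map`` (case-insensitive keys); PTs missing
    from the map are pooled under the ``"unmapped"`` pseudo-SOC with a
    warning.  Tables are returned sorted by descending ``a`` then term.
    """
    level = level.upper()
    if level not in ("PT", "SOC"):
        raise ConfigurationError(f"level must be PT or SOC, got {level!r}")
    if unit not in ("event", "report"):
        raise ConfigurationError(f"unit must be event or report, got {unit!r}")
    if reactions.empty:
        return []
    frame = reactions[["case_id", "pt"]].copy()
    frame["case_id"] = frame["case_id"].astype(str)
    if level == "SOC":
        mapping = {str(k).lower(): str(v) for k, v in (pt_soc_map or {}).items()}
        terms = frame["pt"].astype("string").str.lower().map(mapping)
        n_unmapped = int(terms.isna().sum())
        if n_unmapped:
            logger.warning("%d reaction rows with PTs absent from the PT->SOC"
                           " map recorded under %r", n_unmapped, UNMAPPED_SOC)
        frame["term"] = terms.fillna(UNMAPPED_SOC)
    else:
        frame["term"] = frame["pt"].astype("string")
    focal = set(str(c) for c in focal_case_ids)
    frame["is_focal"] = frame["case_id"].isin(focal)

    if unit == "report":
        frame = frame.drop_duplicates(["case_id", "term"])
        focal_total = frame.loc[frame["is_focal"], "case_id"].nunique()
        other_total = frame.loc[~frame["is_focal"], "case_id"].nunique()
    else:
        focal_total = int(frame["is_focal"].sum())
        other_total = int(len(frame) - focal_total)

    counts = frame.groupby(["term", "is_focal"], observed=True).size()
    tables = []
    for term in sorted(frame["term"].unique()):
        a = int(counts.get((term, True), 0))
        c = int(counts.get((term, False), 0))
        tables.append((str(term), ContingencyTable(a=a, b=focal_total - a,
                                                   c=c, d=other_total - c)))
    tables.sort(key=lambda item: (-item[1].a, item[0]))
    return tables


def reconstruct_from_published(a: int, ror: float, drug_total: int,
                               grand_total: int,
                               tol: float = 0.01) -> ContingencyTable:
    """Rebuild the 2x2 table implied by a printed (count, ROR) pair.

    Given the focal-drug event total and the database grand total, the only
    free cell is c; inverting ROR = (a*d)/(b*c) with d = S - c gives
    c = a*S / (ror*b + a), rounded to the nearest integer (counts are
    integers and published RORs carry enough significant figures for
    nearest-integer recovery).  The reconstruction is rejected if the
    recomputed ROR drifts more than ``tol`` (relative) from the input.
    """
    if a < 1:
        raise ReconstructionError("a must be >= 1")
    if ror <= 0:
        raise ReconstructionError("ror must be positive")
    if drug_total < a:
        raise ReconstructionError("drug_total must be >= a")
    if grand_total <= drug_total:
        raise ReconstructionError("grand_total must exceed drug_total")
    b = drug_total - a
    s = grand_total - drug_total
    c = round(a * s / (ror * b + a)) if b > 0 else 0
    if c <= 0:
        raise ReconstructionError(
            f"reconstruction infeasible: implied c rounds to {c}")
    d = s - c
    table = ContingencyTable(a=a, b=b, c=c, d=d)
    implied_ror = (table.a * table.d) / (table.b * table.c)
    if abs(implied_ror / ror - 1.0) > tol:
        raise ReconstructionError(
            f"reconstructed ROR {implied_ror:.6g} deviates more than "
            f"{tol:.0%} from input {ror:.6g}")
    return table


def tables_to_frame(tables: Iterable[tuple[str, ContingencyTable]],
                    level: str = "PT") -> pd.DataFrame:
    """Export tables as a tidy frame (term, level, a, b, c, d)."""
    rows = [(term, level, t.a, t.b, t.c, t.d) for term, t in tables]
    return pd.DataFrame(rows, columns=["term", "level", "a", "b", "c", "d"])
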