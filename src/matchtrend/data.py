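"""Data model and I/O for matched and unmatched bi-allelic genotype data.

Genotypes are coded as the number of copies of a declared candidate allele
``D`` carried by a subject: 0 (``dd``), 1 (``Dd``) or 2 (``DD``).  A matched
study is a collection of matched sets, each holding one case and a fixed
number ``m`` of confounder-matched controls, grouped into strata defined by
the matching factors.

Two plain-text formats are supported:

* subject records — a TSV with columns ``set_id  stratum  status  genotype``;
* per-stratum pair tables — blocks of 3x3 case-genotype x control-genotype
  counts, the natural summary of a 1:1 pair-matched study.

The bundled ACCESS sarcoidosis pair-matched study (KM(1,3) marker, three
strata: Caucasian, Female/African-American, Male/African-American) ships in
the pair-table format and is loaded with :func:`load_access`.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "MatchedSet",
    "MatchedStudy",
    "StratumCounts",
    "UnmatchedTable",
    "read_matched_study",
    "write_matched_study",
    "from_pair_tables",
    "read_pair_tables",
    "write_pair_tables",
    "stratum_summaries",
    "load_access",
    "ACCESS_CODING",
]

_VALID_CODES = (0, 1, 2)


class DataError(ValueError):
    """Raised for structurally invalid genotype data."""


def _check_code(g: int) -> int:
    g = int(g)
    if g not in _VALID_CODES:
        raise DataError(f"genotype code must be 0, 1 or 2, got {g!r}")
    return g


@dataclass(frozen=True)
class MatchedSet:
    """One case and its ``m`` matched controls within a stratum."""

    stratum: str
    case: int
    controls: tuple[int, ...]

    def __post_init__(self) -> None:
        _check_code(self.case)
        if len(self.controls) == 0:
            raise DataError("a matched set needs at least one control")
        object.__setattr__(self, "controls", tuple(_check_code(g) for g in self.controls))

    def flipped(self) -> "MatchedSet":
        return MatchedSet(self.stratum, 2 - self.case, tuple(2 - g for g in self.controls))


@dataclass(frozen=True)
class MatchedStudy:
    """A 1:m matched case-control study over ``L`` strata.

    Every set must have the same number of controls ``m``; the conditional
    score statistics implemented in :mod:`matchtrend.matched` assume it.
    """

    sets: tuple[MatchedSet, ...]

    def __post_init__(self) -> None:
        if len(self.sets) == 0:
            raise DataError("study has no matched sets")
        ms = {len(s.controls) for s in self.sets}
        if len(ms) != 1:
            raise DataError(f"all sets must share one controls-per-case count m, found {sorted(ms)}")

    @property
    def m(self) -> int:
        return len(self.sets[0].controls)

    @property
    def strata(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for s in self.sets:
            seen.setdefault(s.stratum, None)
        return tuple(seen)

    @property
    def n_cases(self) -> int:
        return len(self.sets)

    @property
    def n_controls(self) -> int:
        return self.m * len(self.sets)

    def flipped(self) -> "MatchedStudy":
        """Recode genotypes g -> 2 - g (swap the candidate allele)."""
        return MatchedStudy(tuple(s.flipped() for s in self.sets))

    def by_stratum(self) -> dict[str, list[MatchedSet]]:
        out: dict[str, list[MatchedSet]] = {lab: [] for lab in self.strata}
        for s in self.sets:
            out[s.stratum].append(s)
        return out

    # array views used by the statistics modules
    def stratum_arrays(self) -> list[tuple[str, np.ndarray, np.ndarray]]:
        """Per stratum: (label, case genotype vector, controls matrix r_l x m)."""
        out = []
        for lab, sets in self.by_stratum().items():
            cases = np.array([s.case for s in sets], dtype=np.int64)
            ctrls = np.array([s.controls for s in sets], dtype=np.int64)
            out.append((lab, cases, ctrls))
        return out


@dataclass(frozen=True)
class StratumCounts:
    """Genotype counts (G0, G1, G2) for cases and controls in one stratum."""

    stratum: str
    r0: int
    r1: int
    r2: int
    s0: int
    s1: int
    s2: int
    m: int

    def __post_init__(self) -> None:
        for v in (self.r0, self.r1, self.r2, self.s0, self.s1, self.s2):
            if v < 0:
                raise DataError("negative genotype count")
        if self.r_l == 0:
            raise DataError(f"stratum {self.stratum!r} has no cases")
        if self.s_l != self.m * self.r_l:
            raise DataError(f"stratum {self.stratum!r}: control total {self.s_l} != m*r_l = {self.m * self.r_l}")

    @property
    def r_l(self) -> int:
        return self.r0 + self.r1 + self.r2

    @property
    def s_l(self) -> int:
        return self.s0 + self.s1 + self.s2

    @property
    def case_counts(self) -> np.ndarray:
        return np.array([self.r0, self.r1, self.r2], dtype=float)

    @property
    def control_counts(self) -> np.ndarray:
        return np.array([self.s0, self.s1, self.s2], dtype=float)

    @property
    def case_freqs(self) -> np.ndarray:
        """p-hat_il = r_il / r_l."""
        return self.case_counts / self.r_l

    @property
    def control_freqs(self) -> np.ndarray:
        """q-hat_il = s_il / (m r_l)."""
        return self.control_counts / (self.m * self.r_l)

    @property
    def pooled_genotype_freqs(self) -> np.ndarray:
        """p-hat_il = (r_il + s_il) / ((m + 1) r_l), cases and controls pooled."""
        return (self.case_counts + self.control_counts) / ((self.m + 1) * self.r_l)

    @property
    def pooled_allele_freq(self) -> float:
        """p-hat_l = [2(r_2l + s_2l) + (r_1l + s_1l)] / [2(m+1) r_l]."""
        num = 2.0 * (self.r2 + self.s2) + (self.r1 + self.s1)
        return num / (2.0 * (self.m + 1) * self.r_l)


@dataclass(frozen=True)
class UnmatchedTable:
    """A 2x3 genotype count table for an unmatched case-control study."""

    r0: int
    r1: int
    r2: int
    s0: int
    s1: int
    s2: int

    def __post_init__(self) -> None:
        for v in (self.r0, self.r1, self.r2, self.s0, self.s1, self.s2):
            if v < 0:
                raise DataError("negative genotype count")
        if self.r == 0 or self.s == 0:
            raise DataError("both arms of an unmatched table must be non-empty")

    @property
    def r(self) -> int:
        return self.r0 + self.r1 + self.r2

    @property
    def s(self) -> int:
        return self.s0 + self.s1 + self.s2

    @property
    def n(self) -> int:
        return self.r + self.s

    @property
    def case_counts(self) -> np.ndarray:
        return np.array([self.r0, self.r1, self.r2], dtype=float)

    @property
    def control_counts(self) -> np.ndarray:
        return np.array([self.s0, self.s1, self.s2], dtype=float)

    @property
    def pooled_allele_freq(self) -> float:
        return (2.0 * (self.r2 + self.s2) + (self.r1 + self.s1)) / (2.0 * self.n)

    def flipped(self) -> "UnmatchedTable":
        return UnmatchedTable(self.r2, self.r1, self.r0, self.s2, self.s1, self.s0)


def stratum_summaries(study: MatchedStudy) -> list[StratumCounts]:
    """Per-stratum genotype count summaries, in first-appearance order."""
    out = []
    for lab, cases, ctrls in study.stratum_arrays():
        rc = np.bincount(cases, minlength=3)
        sc = np.bincount(ctrls.ravel(), minlength=3)
        out.append(StratumCounts(lab, *map(int, rc), *map(int, sc), m=study.m))
    return out


# ---------------------------------------------------------------------------
# subject-record TSV format

_HEADER = ("set_id", "stratum", "status", "genotype")


def _parse_genotype(tok: str, risk_allele: str | None, lineno: int) -> int:
    tok = tok.strip()
    if tok in {"0", "1", "2"}:
        return int(tok)
    if "/" in tok:
        if risk_allele is None:
            raise DataError(
                f"line {lineno}: allele-pair genotype {tok!r} needs a declared risk allele"
            )
        alleles = tok.split("/")
        if len(alleles) != 2 or any(not a for a in alleles):
            raise DataError(f"line {lineno}: malformed genotype {tok!r}")
        return sum(a == risk_allele for a in alleles)
    raise DataError(f"line {lineno}: invalid genotype symbol {tok!r}")


def read_matched_study(source, risk_allele: str | None = None) -> MatchedStudy:
    """Read subject records (TSV: set_id, stratum, status, genotype).

    ``status`` must be ``case`` or ``control``; genotypes are 0/1/2 codes or
    allele pairs like ``"1/3"`` resolved against ``risk_allele``.  Each set
    must contain exactly one case; the controls-per-case count ``m`` is
    inferred and checked to be constant.
    """
    if isinstance(source, (str, os.PathLike)):
        with open(source, "rt") as fh:
            return read_matched_study(fh, risk_allele)
    rows: list[tuple[str, str, str, int]] = []
    for lineno, line in enumerate(source, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if lineno == 1 and tuple(p.strip() for p in parts) == _HEADER:
            continue
        if len(parts) != 4:
            raise DataError(f"line {lineno}: expected 4 tab-separated fields, got {len(parts)}")
        set_id, stratum, status, gtok = (p.strip() for p in parts)
        if status not in {"case", "control"}:
            raise DataError(f"line {lineno}: status must be 'case' or 'control', got {status!r}")
        rows.append((set_id, stratum, status, _parse_genotype(gtok, risk_allele, lineno)))
    if not rows:
        raise DataError("no subject records found")

    order: dict[str, None] = {}
    groups: dict[str, list[tuple[str, str, int]]] = {}
    for set_id, stratum, status, g in rows:
        order.setdefault(set_id, None)
        groups.setdefault(set_id, []).append((stratum, status, g))

    sets = []
    for set_id in order:
        members = groups[set_id]
        cases = [(st, g) for st, stat, g in members if stat == "case"]
        ctrls = [g for _, stat, g in members if stat == "control"]
        if len(cases) != 1:
            raise DataError(f"set {set_id!r} has {len(cases)} cases; exactly one is required")
        strata = {st for st, _, _ in members}
        if len(strata) != 1:
            raise DataError(f"set {set_id!r} spans multiple strata {sorted(strata)}")
        sets.append(MatchedSet(cases[0][0], cases[0][1], tuple(ctrls)))
    return MatchedStudy(tuple(sets))


def write_matched_study(study: MatchedStudy, dest) -> None:
    """Write subject records in the TSV format read by :func:`read_matched_study`."""
    if isinstance(dest, (str, os.PathLike)):
        with open(dest, "wt") as fh:
            write_matched_study(study, fh)
            return
    dest.write("\t".join(_HEADER) + "\n")
    for i, s in enumerate(study.sets, start=1):
        sid = f"set{i}"
        dest.write(f"{sid}\t{s.stratum}\tcase\t{s.case}\n")
        for g in s.controls:
            dest.write(f"{sid}\t{s.stratum}\tcontrol\t{g}\n")


# ---------------------------------------------------------------------------
# pair-table format (1:1 matching only)


def from_pair_tables(tables: Mapping[str, np.ndarray] | Sequence[tuple[str, np.ndarray]]) -> MatchedStudy:
    """Expand per-stratum 3x3 pair tables into a 1:1 matched study.

    ``tables[stratum][i, j]`` is the number of pairs with case genotype code
    ``i`` and control genotype code ``j`` (codes 0, 1, 2).
    """
    items = tables.items() if isinstance(tables, Mapping) else tables
    sets: list[MatchedSet] = []
    for stratum, mat in items:
        mat = np.asarray(mat)
        if mat.shape != (3, 3):
            raise DataError(f"stratum {stratum!r}: pair table must be 3x3, got {mat.shape}")
        if np.any(mat < 0) or not np.all(mat == np.round(mat)):
            raise DataError(f"stratum {stratum!r}: pair table must hold non-negative integers")
        for i in range(3):
            for j in range(3):
                sets.extend(MatchedSet(stratum, i, (j,)) for _ in range(int(mat[i, j])))
    if not sets:
        raise DataError("pair tables are all zero")
    return MatchedStudy(tuple(sets))


def pair_tables(study: MatchedStudy) -> dict[str, np.ndarray]:
    """Summarize a 1:1 matched study back into per-stratum pair tables."""
    if study.m != 1:
        raise DataError("pair tables are defined for 1:1 matching only")
    out: dict[str, np.ndarray] = {}
    for lab, cases, ctrls in study.stratum_arrays():
        mat = np.zeros((3, 3), dtype=int)
        np.add.at(mat, (cases, ctrls[:, 0]), 1)
        out[lab] = mat
    return out


def read_pair_tables(source, coding: Mapping[str, int]) -> dict[str, np.ndarray]:
    """Read pair-table blocks; ``coding`` maps genotype labels to codes 0/1/2.

    Block format (tab-separated)::

        stratum <TAB> <label>
        .       <TAB> g1 <TAB> g2 <TAB> g3      (column labels = control genotype)
        g1      <TAB> c  <TAB> c  <TAB> c       (row label = case genotype)
        ...

    Blocks are separated by blank lines.
    """
    if isinstance(source, (str, os.PathLike)):
        with open(source, "rt") as fh:
            return read_pair_tables(fh, coding)
    text = source.read()
    out: dict[str, np.ndarray] = {}
    for block in [b for b in text.split("\n\n") if b.strip()]:
        lines = [ln for ln in block.splitlines() if ln.strip() and not ln.startswith("#")]
        head = lines[0].split("\t")
        if head[0] != "stratum" or len(head) != 2:
            raise DataError(f"bad pair-table block header: {lines[0]!r}")
        stratum = head[1].strip()
        col_labels = [t.strip() for t in lines[1].split("\t")[1:]]
        cols = [coding[lab] for lab in col_labels]
        mat = np.zeros((3, 3), dtype=int)
        for ln in lines[2:]:
            toks = [t.strip() for t in ln.split("\t")]
            i = coding[toks[0]]
            for j, tok in zip(cols, toks[1:]):
                mat[i, j] = int(tok)
        out[stratum] = mat
    if not out:
        raise DataError("no pair-table blocks found")
    return out


def write_pair_tables(tables: Mapping[str, np.ndarray], dest, labels: Mapping[int, str] | None = None) -> None:
    if isinstance(dest, (str, os.PathLike)):
        with open(dest, "wt") as fh:
            write_pair_tables(tables, fh, labels)
            return
    labels = labels or {0: "0", 1: "1", 2: "2"}
    blocks = []
    for stratum, mat in tables.items():
        mat = np.asarray(mat, dtype=int)
        lines = [f"stratum\t{stratum}", ".\t" + "\t".join(labels[j] for j in range(3))]
        for i in range(3):
            lines.append(labels[i] + "\t" + "\t".join(str(mat[i, j]) for j in range(3)))
        blocks.append("\n".join(lines))
    dest.write("\n\n".join(blocks) + "\n")


# ---------------------------------------------------------------------------
# bundled ACCESS sarcoidosis fixture

#: KM(1,3) marker coded by copies of allele '3': '33' -> 2, '13' -> 1,
#: '11' -> 0.  This coding reproduces the published per-score trend-test
#: p-values; the robust tests are invariant under swapping the counted
#: allele, and the risk-allele direction is inferred from the data (the
#: additive trend statistic is negative, pointing at allele '1').
ACCESS_CODING: dict[str, int] = {"11": 0, "13": 1, "33": 2}


def load_access(combined: bool = False):
    """Load the ACCESS sarcoidosis pair-matched study bundled with the package.

    Returns the three-stratum :class:`MatchedStudy` (497 pairs) or, with
    ``combined=True``, the per-stratum pair tables as a dict of 3x3 arrays.
    """
    ref = resources.files("matchtrend") / "fixtures" / "access_pairs.tsv"
    tables = read_pair_tables(io.StringIO(ref.read_text()), ACCESS_CODING)
    if combined:
        return tables
    return from_pair_tables(tables)
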