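"""Pedigree table parsing, validation and transformation.

The on-disk format is the ten-column family table: one row per individual
with columns PedigreeID, ID, Sex, MotherID, FatherID, isProband, CurAge,
isAff, Age, Geno (header match is case-insensitive; missing values are
empty or NA).  Sex is coded 0/F/female = female, 1/M/male = male; isAff is
1 = diagnosed, 0 = unaffected, NA = unknown; Geno is 1 = carrier,
0 = noncarrier, NA = unknown; CurAge is the censoring age (current age if
alive, age at death otherwise); Age is the age at diagnosis.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .model import DEFAULT_MAX_AGE, FEMALE, MALE, UNKNOWN_SEX

SCHEMA_COLUMNS = [
    "PedigreeID",
    "ID",
    "Sex",
    "MotherID",
    "FatherID",
    "isProband",
    "CurAge",
    "isAff",
    "Age",
    "Geno",
]

_SEX_CODES = {
    "0": FEMALE,
    "f": FEMALE,
    "female": FEMALE,
    "1": MALE,
    "m": MALE,
    "male": MALE,
}


class PedigreeSchemaError(ValueError):
    """Raised for structurally unreadable input (missing columns, bad codes)."""


class PedigreeValidationError(ValueError):
    """Raised when a pedigree violates a hard constraint during parsing."""


@dataclass
class IndividualRecord:
    """One family member: identity, parental links, phenotype and genotype."""

    id: str
    sex: str = UNKNOWN_SEX  # 'F', 'M' or 'U'
    mother_id: str | None = None
    father_id: str | None = None
    is_proband: bool = False
    cur_age: int | None = None
    is_aff: int | None = None  # 1 affected, 0 unaffected, None unknown
    onset_age: int | None = None
    geno: int | None = None  # 1 carrier, 0 noncarrier, None unknown

    @property
    def is_founder(self) -> bool:
        return self.mother_id is None and self.father_id is None


@dataclass
class Pedigree:
    """A single family: ordered members plus derived parent-child structure."""

    family_id: str
    members: list[IndividualRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._by_id = {m.id: m for m in self.members}
        if len(self._by_id) != len(self.members):
            seen: set[str] = set()
            dups = [m.id for m in self.members if m.id in seen or seen.add(m.id)]
            raise PedigreeValidationError(
                f"family {self.family_id}: duplicate member id(s) {sorted(set(dups))}"
            )

    def __len__(self) -> int:
        return len(self.members)

    def __getitem__(self, ind_id: str) -> IndividualRecord:
        return self._by_id[ind_id]

    def __contains__(self, ind_id: str) -> bool:
        return ind_id in self._by_id

    @property
    def proband_ids(self) -> list[str]:
        return [m.id for m in self.members if m.is_proband]

    @property
    def founders(self) -> list[IndividualRecord]:
        return [m for m in self.members if m.is_founder]

    def parent_graph(self) -> nx.DiGraph:
        """Directed graph with edges parent -> child."""
        g = nx.DiGraph()
        g.add_nodes_from(m.id for m in self.members)
        for m in self.members:
            for pid in (m.mother_id, m.father_id):
                if pid is not None and pid in self._by_id:
                    g.add_edge(pid, m.id)
        return g

    def nuclear_families(self) -> dict[tuple[str, str], list[str]]:
        """Map (mother_id, father_id) -> list of child ids, in member order."""
        fams: dict[tuple[str, str], list[str]] = {}
        for m in self.members:
            if m.mother_id is not None and m.father_id is not None:
                fams.setdefault((m.mother_id, m.father_id), []).append(m.id)
        return fams


@dataclass
class ValidationReport:
    """Outcome of validation: every violation found, plus headline counts."""

    errors: list[tuple[str, str, str]] = field(default_factory=list)
    warnings: list[tuple[str, str, str]] = field(default_factory=list)
    counts: dict[str, float] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.errors

    def to_json(self) -> str:
        return json.dumps(
            {
                "ok": self.ok,
                "errors": [list(e) for e in self.errors],
                "warnings": [list(w) for w in self.warnings],
                "counts": self.counts,
            },
            indent=2,
        )


def _parse_int(value, what: str, family: str, ind: str) -> int | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    s = str(value).strip()
    if s == "" or s.upper() == "NA":
        return None
    f = float(s)
    if not f.is_integer():
        raise PedigreeSchemaError(
            f"family {family}, individual {ind}: {what} must be an integer year, got {value!r}"
        )
    return int(f)


def _parse_id(value) -> str | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    s = str(value).strip()
    if s == "" or s.upper() == "NA":
        return None
    # integral floats from pandas ("3.0") normalize to "3"
    try:
        f = float(s)
        if f.is_integer():
            return str(int(f))
    except ValueError:
        pass
    return s


def _parse_sex(value, family: str, ind: str) -> str:
    s = _parse_id(value)
    if s is None:
        return UNKNOWN_SEX
    code = _SEX_CODES.get(s.lower())
    if code is None:
        raise PedigreeSchemaError(
            f"family {family}, individual {ind}: unrecognized Sex code {value!r}"
        )
    return code


def _parse_flag(value, what: str, family: str, ind: str) -> int | None:
    v = _parse_int(value, what, family, ind)
    if v is None:
        return None
    if v not in (0, 1):
        raise PedigreeSchemaError(
            f"family {family}, individual {ind}: {what} must be 0/1/NA, got {value!r}"
        )
    return v


def parse_pedigrees(source) -> list[Pedigree]:
    """Parse a delimited pedigree table (path, file-like, or DataFrame).

    Returns one :class:`Pedigree` per distinct PedigreeID, preserving row
    order.  Raises :class:`PedigreeSchemaError` for missing columns and
    :class:`PedigreeValidationError` for duplicate ids or dangling parent
    references.
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.read_csv(source, sep=None, engine="python", dtype=str, keep_default_na=False)

    colmap = {c.lower(): c for c in df.columns}
    missing = [c for c in SCHEMA_COLUMNS if c.lower() not in colmap]
    if missing:
        raise PedigreeSchemaError(f"missing mandatory column(s): {', '.join(missing)}")

    def col(name):
        return df[colmap[name.lower()]]

    peds: list[Pedigree] = []
    order: list[str] = []
    groups: dict[str, list[IndividualRecord]] = {}
    for i in range(len(df)):
        fam = _parse_id(col("PedigreeID").iloc[i])
        ind = _parse_id(col("ID").iloc[i])
        if fam is None or ind is None:
            raise PedigreeSchemaError(f"row {i}: PedigreeID and ID are mandatory")
        rec = IndividualRecord(
            id=ind,
            sex=_parse_sex(col("Sex").iloc[i], fam, ind),
            mother_id=_parse_id(col("MotherID").iloc[i]),
            father_id=_parse_id(col("FatherID").iloc[i]),
            is_proband=bool(_parse_flag(col("isProband").iloc[i], "isProband", fam, ind) or 0),
            cur_age=_parse_int(col("CurAge").iloc[i], "CurAge", fam, ind),
            is_aff=_parse_flag(col("isAff").iloc[i], "isAff", fam, ind),
            onset_age=_parse_int(col("Age").iloc[i], "Age", fam, ind),
            geno=_parse_flag(col("Geno").iloc[i], "Geno", fam, ind),
        )
        if fam not in groups:
            groups[fam] = []
            order.append(fam)
        groups[fam].append(rec)

    for fam in order:
        ped = Pedigree(family_id=fam, members=groups[fam])
        for m in ped.members:
            for which, pid in (("MotherID", m.mother_id), ("FatherID", m.father_id)):
                if pid is not None and pid not in ped:
                    raise PedigreeValidationError(
                        f"family {fam}: {which} {pid!r} of individual {m.id} "
                        f"does not reference a member of the family"
                    )
        peds.append(ped)
    return peds


def write_pedigrees(peds: Iterable[Pedigree], path, sep: str = ",") -> None:
    """Serialize pedigrees back to the ten-column table (NA for missing)."""
    rows = []
    for p in peds:
        for m in p.members:
            rows.append(
                {
                    "PedigreeID": p.family_id,
                    "ID": m.id,
                    "Sex": {FEMALE: "0", MALE: "1", UNKNOWN_SEX: "NA"}[m.sex],
                    "MotherID": m.mother_id if m.mother_id is not None else "NA",
                    "FatherID": m.father_id if m.father_id is not None else "NA",
                    "isProband": int(m.is_proband),
                    "CurAge": m.cur_age if m.cur_age is not None else "NA",
                    "isAff": m.is_aff if m.is_aff is not None else "NA",
                    "Age": m.onset_age if m.onset_age is not None else "NA",
                    "Geno": m.geno if m.geno is not None else "NA",
                }
            )
    pd.DataFrame(rows, columns=SCHEMA_COLUMNS).to_csv(path, sep=sep, index=False)


def validate_pedigree(p: Pedigree, max_age: int = DEFAULT_MAX_AGE) -> ValidationReport:
    """Check every record and structural invariant; collect all violations."""
    rep = ValidationReport()
    err = rep.errors.append

    for m in p.members:
        if m.onset_age is not None and m.is_aff != 1:
            err((p.family_id, m.id, "onset age present but not recorded as affected"))
        if m.onset_age is not None and m.cur_age is not None and m.onset_age > m.cur_age:
            err((p.family_id, m.id, "onset after censoring"))
        if (m.mother_id is None) != (m.father_id is None):
            err((p.family_id, m.id, "exactly one parent reference present"))
        for what, age in (("CurAge", m.cur_age), ("Age", m.onset_age)):
            if age is not None and not (1 <= age <= max_age):
                err((p.family_id, m.id, f"{what} {age} outside [1, {max_age}]"))
        for which, pid in (("mother", m.mother_id), ("father", m.father_id)):
            if pid is not None and pid not in p:
                err((p.family_id, m.id, f"{which} id {pid} not in family"))
        if m.mother_id is not None and m.mother_id in p and p[m.mother_id].sex == MALE:
            rep.warnings.append((p.family_id, m.id, "mother recorded as male"))
        if m.father_id is not None and m.father_id in p and p[m.father_id].sex == FEMALE:
            rep.warnings.append((p.family_id, m.id, "father recorded as female"))

    g = p.parent_graph()
    if not nx.is_directed_acyclic_graph(g):
        cyc = nx.find_cycle(g)
        err((p.family_id, cyc[0][0], "individual is its own ancestor (parent cycle)"))

    n_aff = sum(1 for m in p.members if m.is_aff == 1)
    rep.counts = {
        "families": 1,
        "individuals": len(p),
        "affected": n_aff,
        "carriers_observed": sum(1 for m in p.members if m.geno == 1),
    }
    return rep


def cohort_summary(peds: Sequence[Pedigree]) -> dict[str, float]:
    """Headline bookkeeping over a pedigree collection.

    Includes family count, individual count, mean family size, affected
    counts overall and by sex, and observed carrier counts.
    """
    n_fam = len(peds)
    n_ind = sum(len(p) for p in peds)
    aff_f = sum(1 for p in peds for m in p.members if m.is_aff == 1 and m.sex == FEMALE)
    aff_m = sum(1 for p in peds for m in p.members if m.is_aff == 1 and m.sex == MALE)
    aff_u = sum(1 for p in peds for m in p.members if m.is_aff == 1 and m.sex == UNKNOWN_SEX)
    return {
        "families": n_fam,
        "individuals": n_ind,
        "mean_family_size": (n_ind / n_fam) if n_fam else float("nan"),
        "affected_total": aff_f + aff_m + aff_u,
        "affected_female": aff_f,
        "affected_male": aff_m,
        "carriers_observed": sum(1 for p in peds for m in p.members if m.geno == 1),
        "probands": sum(len(p.proband_ids) for p in peds),
    }


def _membership_graph(p: Pedigree) -> nx.Graph:
    """Bipartite graph: individual nodes <-> nuclear-family nodes."""
    g = nx.Graph()
    g.add_nodes_from(("ind", m.id) for m in p.members)
    for k, (couple, children) in enumerate(p.nuclear_families().items()):
        fnode = ("fam", k)
        g.add_node(fnode, couple=couple)
        mother, father = couple
        g.add_edge(fnode, ("ind", mother))
        g.add_edge(fnode, ("ind", father))
        for c in children:
            g.add_edge(fnode, ("ind", c))
    return g


def detect_loops(p: Pedigree) -> list[list[str]]:
    """Find marriage/inbreeding loops.

    A pedigree is loop-free exactly when the bipartite graph linking
    individuals to the nuclear families they belong to is acyclic.  Each
    reported loop lists the individual ids on one independent cycle.
    """
    g = _membership_graph(p)
    loops = []
    for cycle in nx.cycle_basis(g):
        loops.append([node_id for kind, node_id in cycle if kind == "ind"])
    return loops


def apply_proband_removal(p: Pedigree, enabled: bool = True) -> Pedigree | None:
    """Ascertainment correction by masking the proband's phenotype.

    The proband's is_aff and onset_age are set to unknown; the genotype
    observation is kept.  Families consisting only of the proband carry no
    age-specific risk information once masked and are excluded (returns
    ``None``).  With ``enabled=False`` the pedigree is returned unchanged.
    """
    if not enabled:
        return p
    if not p.proband_ids:
        raise PedigreeValidationError(f"family {p.family_id}: no proband to remove")
    if len(p) == 1:
        return None
    members = [
        replace(m, is_aff=None, onset_age=None) if m.is_proband else replace(m)
        for m in p.members
    ]
    return Pedigree(family_id=p.family_id, members=members)


def prepare_analysis_set(
    peds: Sequence[Pedigree], remove_proband: bool = False
) -> tuple[list[Pedigree], list[str]]:
    """Apply proband removal across a collection; report excluded family ids."""
    kept, excluded = [], []
    for p in peds:
        q = apply_proband_removal(p, enabled=remove_proband)
        if q is None:
            excluded.append(p.family_id)
        else:
            kept.append(q)
    return kept, excluded
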