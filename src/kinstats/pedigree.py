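"""Multi-generation family structures and the additive relationship matrix.

A pedigree is a directed acyclic graph of individuals with father/mother
links.  This module reads the common pedigree file dialects (PLINK ``.fam``,
LINKAGE pre-makeped, generic CSV), partitions individuals into families
(connected components), classifies relative pairs (parent-offspring,
full-sibling, spouse), and computes the additive genetic relationship
matrix A by the tabular method: processing individuals so that parents
precede offspring,

    a_ij = (a_{j,father(i)} + a_{j,mother(i)}) / 2        (j processed before i)
    a_ii = 1 + a_{father(i),mother(i)} / 2

with missing parents contributing zero.  The diagonal is 1 + F_i where F_i
is the inbreeding coefficient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "Individual",
    "Pedigree",
    "PedigreeError",
    "RelationshipMatrix",
    "read_pedigree",
    "families",
    "classify_pairs",
    "relationship_matrix",
]

MALE, FEMALE, UNKNOWN = "male", "female", "unknown"

_MISSING_PARENT = {"0", "", "na", "nan", "none", "-9"}


class PedigreeError(ValueError):
    """Structural problem in a pedigree (cycle, duplicate id, sex conflict)."""


@dataclass(frozen=True)
class Individual:
    """One pedigree member.

    Parameters
    ----------
    iid : str
        Unique identifier.
    father, mother : str or None
        Parent identifiers; ``None`` encodes an unknown parent.
    sex : {'male', 'female', 'unknown'}
    """

    iid: str
    father: str | None = None
    mother: str | None = None
    sex: str = UNKNOWN

    def __post_init__(self):
        if self.iid in (self.father, self.mother):
            raise PedigreeError(f"individual {self.iid!r} is its own parent")
        if self.sex not in (MALE, FEMALE, UNKNOWN):
            raise PedigreeError(f"invalid sex {self.sex!r} for {self.iid!r}")

    @property
    def is_founder(self) -> bool:
        return self.father is None and self.mother is None


class Pedigree:
    """Validated directed acyclic family graph.

    Parents referenced but never listed as individuals are materialized as
    founders of unknown sex (with a warning).  Generation index is the
    longest-path depth from founders, so parents always precede offspring
    in generation order.  Families are connected components of the
    undirected parent-link (plus declared partner-link) graph.

    Parameters
    ----------
    individuals : iterable of Individual
    partners : iterable of (id, id) pairs, optional
        Declared partner links for childless couples (some dialects carry
        them); spouse classification also infers couples from common
        children.
    """

    def __init__(
        self,
        individuals: Iterable[Individual],
        partners: Iterable[tuple[str, str]] = (),
    ):
        members: dict[str, Individual] = {}
        for ind in individuals:
            if ind.iid in members:
                raise PedigreeError(f"duplicate individual id {ind.iid!r}")
            members[ind.iid] = ind

        # materialize referenced-but-absent parents as founders
        ghosts = []
        for ind in list(members.values()):
            for parent in (ind.father, ind.mother):
                if parent is not None and parent not in members:
                    ghosts.append(parent)
                    members[parent] = Individual(parent)
        if ghosts:
            warnings.warn(
                f"{len(ghosts)} parent(s) not listed as individuals were added "
                f"as founders: {sorted(set(ghosts))[:10]}",
                stacklevel=2,
            )

        self._check_sex(members)
        self._members = members
        self.partners = frozenset(frozenset(p) for p in partners if p[0] != p[1])

        dag = nx.DiGraph()
        dag.add_nodes_from(members)
        for ind in members.values():
            for parent in (ind.father, ind.mother):
                if parent is not None:
                    dag.add_edge(parent, ind.iid)
        if not nx.is_directed_acyclic_graph(dag):
            cycle = nx.find_cycle(dag)
            raise PedigreeError(f"pedigree contains a cycle: {cycle}")
        self._dag = dag

        self.generation: dict[str, int] = {}
        for iid in nx.topological_sort(dag):
            ind = members[iid]
            parent_gens = [
                self.generation[p] for p in (ind.father, ind.mother) if p is not None
            ]
            self.generation[iid] = 1 + max(parent_gens) if parent_gens else 0

        self.family_of = self._assign_families()

    @staticmethod
    def _check_sex(members: Mapping[str, Individual]) -> None:
        bad = []
        for ind in members.values():
            f = members.get(ind.father) if ind.father else None
            m = members.get(ind.mother) if ind.mother else None
            if f is not None and f.sex == FEMALE:
                bad.append((ind.iid, "father", f.iid))
            if m is not None and m.sex == MALE:
                bad.append((ind.iid, "mother", m.iid))
        if bad:
            raise PedigreeError(f"parent sex inconsistencies (child, role, parent): {bad}")

    def _assign_families(self) -> dict[str, str]:
        ug = self._dag.to_undirected(as_view=False)
        for pair in self.partners:
            a, b = tuple(pair)
            ug.add_edge(a, b)
        fam = {}
        for comp in nx.connected_components(ug):
            label = f"F{min(comp)}"
            for iid in comp:
                fam[iid] = label
        return fam

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._members)

    def __contains__(self, iid: str) -> bool:
        return iid in self._members

    def __getitem__(self, iid: str) -> Individual:
        return self._members[iid]

    def __iter__(self):
        return iter(self._members.values())

    @property
    def ids(self) -> list[str]:
        return list(self._members)

    @property
    def founders(self) -> list[str]:
        return [i.iid for i in self if i.is_founder]

    def children_of(self, iid: str) -> list[str]:
        return sorted(self._dag.successors(iid))

    def ancestors(self, iid: str) -> set[str]:
        return nx.ancestors(self._dag, iid)

    def to_frame(self) -> pd.DataFrame:
        """Tabular view: iid, father, mother, sex, family, generation."""
        rows = [
            (i.iid, i.father, i.mother, i.sex, self.family_of[i.iid], self.generation[i.iid])
            for i in self
        ]
        return pd.DataFrame(
            rows, columns=["iid", "father", "mother", "sex", "family", "generation"]
        )

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        id_col: str = "iid",
        father_col: str = "father",
        mother_col: str = "mother",
        sex_col: str | None = "sex",
        partner_col: str | None = None,
    ) -> "Pedigree":
        """Build a pedigree from a DataFrame with configurable column names."""

        def norm_parent(v) -> str | None:
            if pd.isna(v) or str(v).strip().lower() in _MISSING_PARENT:
                return None
            return str(v).strip()

        inds = []
        for _, row in df.iterrows():
            sex = _norm_sex(row[sex_col]) if sex_col and sex_col in df else UNKNOWN
            inds.append(
                Individual(
                    str(row[id_col]).strip(),
                    norm_parent(row[father_col]),
                    norm_parent(row[mother_col]),
                    sex,
                )
            )
        partners = []
        if partner_col and partner_col in df:
            for _, row in df.iterrows():
                p = norm_parent(row[partner_col])
                if p is not None:
                    partners.append((str(row[id_col]).strip(), p))
        return cls(inds, partners)


def _norm_sex(v) -> str:
    if pd.isna(v):
        return UNKNOWN
    s = str(v).strip().lower()
    if s in {"1", "m", "male"}:
        return MALE
    if s in {"2", "f", "female"}:
        return FEMALE
    return UNKNOWN


def read_pedigree(path: str | Path, dialect: str = "plink_fam", **csv_cols) -> Pedigree:
    """Read a pedigree file.

    Parameters
    ----------
    path : path
    dialect : {'plink_fam', 'linkage_ped', 'csv'}
        ``plink_fam``: 6 whitespace-separated columns
        (FID IID father mother sex phenotype), missing parent "0",
        sex 1=male / 2=female / 0=unknown.  ``linkage_ped``: same core
        columns, trailing phenotype/marker columns ignored.  ``csv``:
        header row; column names via ``id_col``, ``father_col``,
        ``mother_col``, ``sex_col`` (and optionally ``partner_col``).

    Returns
    -------
    Pedigree
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect in ("plink_fam", "linkage_ped"):
        df = pd.read_csv(path, sep=r"\s+", header=None, dtype=str, comment="#")
        if df.shape[1] < 5:
            raise PedigreeError(f"{dialect} file needs >=5 columns, got {df.shape[1]}")
        df = df.iloc[:, :5]
        df.columns = ["fid", "iid", "father", "mother", "sex"]
        if df["iid"].duplicated().any():
            # PLINK scopes IID within FID; disambiguate deterministically
            df["iid"] = df["fid"] + ":" + df["iid"]
            df["father"] = np.where(
                df["father"].isin(_MISSING_PARENT), df["father"], df["fid"] + ":" + df["father"]
            )
            df["mother"] = np.where(
                df["mother"].isin(_MISSING_PARENT), df["mother"], df["fid"] + ":" + df["mother"]
            )
        return Pedigree.from_frame(df, "iid", "father", "mother", "sex")
    if dialect == "csv":
        df = pd.read_csv(path, dtype=str)
        return Pedigree.from_frame(
            df,
            csv_cols.get("id_col", "iid"),
            csv_cols.get("father_col", "father"),
            csv_cols.get("mother_col", "mother"),
            csv_cols.get("sex_col", "sex"),
            csv_cols.get("partner_col"),
        )
    raise ValueError(f"unknown dialect {dialect!r}")


def write_fam(ped: Pedigree, path: str | Path) -> None:
    """Write a pedigree as PLINK ``.fam`` (phenotype column set to -9)."""
    sex_code = {MALE: "1", FEMALE: "2", UNKNOWN: "0"}
    with open(path, "w") as fh:
        for ind in ped:
            fh.write(
                " ".join(
                    [
                        ped.family_of[ind.iid],
                        ind.iid,
                        ind.father or "0",
                        ind.mother or "0",
                        sex_code[ind.sex],
                        "-9",
                    ]
                )
                + "\n"
            )


def families(ped: Pedigree) -> dict[str, list[str]]:
    """Partition ids into family components (family label -> member ids)."""
    out: dict[str, list[str]] = {}
    for iid, fam in ped.family_of.items():
        out.setdefault(fam, []).append(iid)
    for members in out.values():
        members.sort()
    return out


# ---------------------------------------------------------------------------
# relative-pair classification
# ---------------------------------------------------------------------------

PARENT_OFFSPRING = "parent-offspring"
FULL_SIBLING = "full-sibling"
SPOUSE = "spouse"
OTHER = "other"
FIRST_DEGREE = (PARENT_OFFSPRING, FULL_SIBLING)


def classify_pairs(ped: Pedigree) -> pd.DataFrame:
    """Enumerate parent-offspring, full-sibling and spouse pairs.

    Spouses are two individuals with at least one common child, or declared
    partner links when the source dialect provides them.  A spouse pair
    whose members share a pedigree ancestor (or are first-degree relatives
    of each other) is flagged ``consanguineous`` so it can be excluded from
    spouse analyses.  Half-siblings and more distant relatives are not
    enumerated (they are "other" by definition of first-degree).

    Returns
    -------
    DataFrame with columns id_a, id_b (canonically ordered id_a < id_b),
    relation, consanguineous (bool, spouse rows only).
    """
    rows: dict[tuple[str, str], tuple[str, bool]] = {}

    def canon(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a < b else (b, a)

    for ind in ped:
        for parent in (ind.father, ind.mother):
            if parent is not None:
                rows[canon(ind.iid, parent)] = (PARENT_OFFSPRING, False)

    by_parents: dict[tuple[str, str], list[str]] = {}
    for ind in ped:
        if ind.father is not None and ind.mother is not None:
            by_parents.setdefault((ind.father, ind.mother), []).append(ind.iid)
    for sibs in by_parents.values():
        for i, a in enumerate(sibs):
            for b in sibs[i + 1 :]:
                rows[canon(a, b)] = (FULL_SIBLING, False)

    couples = {canon(f, m) for f, m in by_parents}
    couples |= {canon(*sorted(p)) for p in ped.partners}
    for a, b in couples:
        if (a, b) in rows:  # couple already first-degree related: flag, keep relation
            rel, _ = rows[(a, b)]
            rows[(a, b)] = (rel, True)
            continue
        # any shared ancestor (or one being the other's ancestor) => consanguineous
        consang = bool((ped.ancestors(a) | {a}) & (ped.ancestors(b) | {b}))
        rows[(a, b)] = (SPOUSE, consang)

    df = pd.DataFrame(
        [(a, b, rel, cons) for (a, b), (rel, cons) in rows.items()],
        columns=["id_a", "id_b", "relation", "consanguineous"],
    )
    return df.sort_values(["id_a", "id_b"], ignore_index=True)


# ---------------------------------------------------------------------------
# additive relationship matrix
# ---------------------------------------------------------------------------


@dataclass
class RelationshipMatrix:
    """Additive genetic relationship matrix over an ordered id list.

    ``A`` is dense (ndarray) for small pedigrees and sparse CSR above
    ``SPARSE_THRESHOLD`` individuals; values are identical either way.
    Diagonal entries equal ``1 + F_i`` (inbreeding coefficient F).
    """

    ids: list[str]
    A: np.ndarray | sp.csr_matrix
    index: dict[str, int] = field(init=False)

    def __post_init__(self):
        self.index = {iid: k for k, iid in enumerate(self.ids)}

    def coeff(self, a: str, b: str) -> float:
        i, j = self.index[a], self.index[b]
        return float(self.A[i, j])

    def dense(self) -> np.ndarray:
        return self.A.toarray() if sp.issparse(self.A) else np.asarray(self.A)

    def restrict(self, ids: Sequence[str]) -> "RelationshipMatrix":
        idx = [self.index[i] for i in ids]
        A = self.dense()[np.ix_(idx, idx)]
        return RelationshipMatrix(list(ids), A)


SPARSE_THRESHOLD = 2000


def _component_matrix(ped: Pedigree, members: list[str]) -> tuple[list[str], np.ndarray]:
    """Tabular-method A for one connected component, generation order."""
    order = sorted(members, key=lambda i: (ped.generation[i], i))
    pos = {iid: k for k, iid in enumerate(order)}
    n = len(order)
    A = np.zeros((n, n))
    for i, iid in enumerate(order):
        ind = ped[iid]
        fi = pos.get(ind.father) if ind.father else None
        mi = pos.get(ind.mother) if ind.mother else None
        # rows for previously processed individuals
        if fi is None and mi is None:
            pass  # founder: off-diagonals with earlier members stay 0
        else:
            af = A[fi, :i] if fi is not None else 0.0
            am = A[mi, :i] if mi is not None else 0.0
            A[i, :i] = 0.5 * (af + am)
            A[:i, i] = A[i, :i]
        A[i, i] = 1.0 + (0.5 * A[fi, mi] if fi is not None and mi is not None else 0.0)
    return order, A


def relationship_matrix(
    ped: Pedigree,
    subset: Sequence[str] | None = None,
    sparse: bool | None = None,
) -> RelationshipMatrix:
    """Compute the additive relationship matrix A.

    Computed per family component over the *full* pedigree, then restricted
    to ``subset`` if given, so unphenotyped connecting ancestors still
    contribute relatedness.  Individuals in different families have a = 0.

    Parameters
    ----------
    ped : Pedigree
    subset : ids to retain (order preserved), optional
    sparse : force sparse/dense output; default picks sparse above
        ``SPARSE_THRESHOLD`` retained individuals.
    """
    if subset is not None:
        missing = [i for i in subset if i not in ped]
        if missing:
            raise KeyError(f"subset ids not in pedigree: {missing[:10]}")

    keep = set(subset) if subset is not None else None
    blocks: list[tuple[list[str], np.ndarray]] = []
    for members in sorted(families(ped).values(), key=lambda m: m[0]):
        order, A = _component_matrix(ped, members)
        if keep is not None:
            idx = [k for k, iid in enumerate(order) if iid in keep]
            if not idx:
                continue
            order = [order[k] for k in idx]
            A = A[np.ix_(idx, idx)]
        blocks.append((order, A))

    all_ids = [iid for order, _ in blocks for iid in order]
    n = len(all_ids)
    use_sparse = sparse if sparse is not None else n > SPARSE_THRESHOLD
    if use_sparse:
        M = sp.block_diag([A for _, A in blocks], format="csr")
    else:
        M = np.zeros((n, n))
        off = 0
        for order, A in blocks:
            k = len(order)
            M[off : off + k, off : off + k] = A
            off += k
    rm = RelationshipMatrix(all_ids, M)
    if subset is not None:
        # restore requested order
        rm = rm.restrict(list(subset)) if list(subset) != all_ids else rm
    return rm


def family_blocks(
    ped: Pedigree, subset: Sequence[str] | None = None
) -> list[tuple[list[str], np.ndarray]]:
    """Per-family (ids, dense A block) pairs; subset handled as in
    :func:`relationship_matrix`.  Used by the variance-component fitter."""
    keep = set(subset) if subset is not None else None
    out = []
    for members in sorted(families(ped).values(), key=lambda m: m[0]):
        order, A = _component_matrix(ped, members)
        if keep is not None:
            idx = [k for k, iid in enumerate(order) if iid in keep]
            if not idx:
                continue
            order = [order[k] for k in idx]
            A = A[np.ix_(idx, idx)]
        out.append((order, A))
    return out
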