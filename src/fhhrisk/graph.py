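"""Expansion of relationship-coded pedigrees into explicit parent-linked graphs.

Relation codes name individuals relative to the proband; the Mendelian
likelihood needs explicit mother/father links.  Expansion resolves each
code into links and inserts *placeholder* founders wherever a relationship
implies a connector the participant did not enter (an aunt implies a
grandparent couple; a niece implies a sibling and their partner).
Placeholders carry no phenotype information (history unknown) and so only
contribute transmission structure to the likelihood.

Conventions:

- every individual has either both parents in the graph or neither
  (a lone entered parent is completed with a placeholder partner);
- each cousin, niece/nephew and grandchild gets its own connector couple —
  which entered relative they descend through is not recorded in the
  interchange format, so no guess is made;
- half-siblings share one parent with the proband and get a distinct
  placeholder for the other;
- generation indices follow the relation codes (proband 1, parents 2,
  grandparents 3, children 0, grandchildren -1).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional

import networkx as nx

from .pedigree import (
    Pedigree,
    PedigreeError,
    RelativeRecord,
    Sex,
    generation_index,
)


class ExpansionError(PedigreeError):
    """Pedigree structure cannot be resolved into a consistent graph."""


@dataclass
class Individual:
    """A node of the expanded pedigree graph."""

    id: str
    sex: Sex
    mother: Optional[str] = None
    father: Optional[str] = None
    generation: int = 1
    placeholder: bool = False
    relation_code: Optional[str] = None
    censoring_age: Optional[float] = None
    history_known: bool = True
    # condition_code -> onset age (None if onset unknown)
    affected: dict[str, Optional[float]] = field(default_factory=dict)

    @property
    def is_founder(self) -> bool:
        return self.mother is None and self.father is None


@dataclass
class PedigreeGraph:
    """Explicit parent-linked pedigree with the proband as counselee."""

    individuals: dict[str, Individual]
    proband_id: str = "self"
    family_id: str = "FAM1"

    def __post_init__(self) -> None:
        self._check()

    def _check(self) -> None:
        for ind in self.individuals.values():
            for pid, want in ((ind.mother, Sex.FEMALE), (ind.father, Sex.MALE)):
                if pid is None:
                    continue
                if pid not in self.individuals:
                    raise ExpansionError(f"{ind.id}: parent {pid} not in graph")
                parent = self.individuals[pid]
                if parent.sex != want and parent.sex != Sex.UNKNOWN:
                    raise ExpansionError(
                        f"{ind.id}: parent {pid} has sex {parent.sex.value}, expected {want.value}"
                    )
            if (ind.mother is None) != (ind.father is None):
                raise ExpansionError(f"{ind.id}: has exactly one parent link")
        dg = self.digraph()
        if not nx.is_directed_acyclic_graph(dg):
            raise ExpansionError("pedigree graph contains a cycle")

    def digraph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.individuals)
        for ind in self.individuals.values():
            for pid in (ind.mother, ind.father):
                if pid is not None:
                    g.add_edge(pid, ind.id)
        return g

    def founders(self) -> list[Individual]:
        return [i for i in self.individuals.values() if i.is_founder]

    def children_of(self, mother_id: str, father_id: str) -> list[Individual]:
        return [
            i
            for i in self.individuals.values()
            if i.mother == mother_id and i.father == father_id
        ]

    def nuclear_families(self) -> list[tuple[str, str, list[str]]]:
        """(mother, father, children) triples for every mated couple."""
        fams: dict[tuple[str, str], list[str]] = {}
        for ind in self.individuals.values():
            if ind.mother is not None:
                fams.setdefault((ind.mother, ind.father), []).append(ind.id)
        return [(m, f, sorted(kids)) for (m, f), kids in sorted(fams.items())]

    def generations(self) -> set[int]:
        return {i.generation for i in self.individuals.values()}

    @property
    def n_placeholders(self) -> int:
        return sum(1 for i in self.individuals.values() if i.placeholder)

    def has_loops(self) -> bool:
        """True if the marriage graph is not a tree (inbreeding loops etc.)."""
        g = nx.Graph()
        g.add_nodes_from(self.individuals)
        edges = 0
        for m, f, kids in self.nuclear_families():
            fam = f"fam:{m}+{f}"
            g.add_edge(fam, m)
            g.add_edge(fam, f)
            edges += 2
            for k in kids:
                g.add_edge(fam, k)
                edges += 1
        return edges > g.number_of_nodes() - nx.number_connected_components(g)


def _from_record(rec: RelativeRecord, id_: str) -> Individual:
    return Individual(
        id=id_,
        sex=rec.sex,
        generation=generation_index(rec.relation_code),
        relation_code=rec.relation_code,
        censoring_age=rec.censoring_age,
        history_known=rec.history_known,
        affected={c.condition_code: c.age_of_onset for c in rec.conditions},
    )


class _Builder:
    def __init__(self) -> None:
        self.nodes: dict[str, Individual] = {}
        self._n = itertools.count(1)

    def add(self, ind: Individual) -> Individual:
        if ind.id in self.nodes:
            raise ExpansionError(f"duplicate individual id {ind.id}")
        self.nodes[ind.id] = ind
        return ind

    def placeholder(self, role: str, sex: Sex, generation: int) -> Individual:
        ind = Individual(
            id=f"ph.{role}.{next(self._n)}",
            sex=sex,
            generation=generation,
            placeholder=True,
            history_known=False,
        )
        return self.add(ind)

    def get_or_placeholder(self, id_: str, role: str, sex: Sex, generation: int) -> Individual:
        if id_ in self.nodes:
            return self.nodes[id_]
        ind = Individual(
            id=id_,
            sex=sex,
            generation=generation,
            placeholder=True,
            history_known=False,
        )
        return self.add(ind)


def entered_ids(p: Pedigree) -> list[tuple[str, RelativeRecord]]:
    """Deterministic graph ids for entered individuals.

    Singleton slots keep their relation code (spaces to underscores);
    repeated codes get a 1-based counter suffix in entry order.
    """
    counters: dict[str, int] = {}
    out: list[tuple[str, RelativeRecord]] = [("self", p.proband)]
    for rec in p.relatives:
        code = rec.relation_code
        n = counters.get(code, 0) + 1
        counters[code] = n
        id_ = code.replace(" ", "_")
        if n > 1 or not _singleton(code):
            id_ = f"{id_}.{n}"
        out.append((id_, rec))
    return out


def expand_to_graph(p: Pedigree) -> PedigreeGraph:
    """Resolve relation codes into an explicit parent-linked graph.

    Entered individuals are never dropped; placeholder founders are inserted
    for every implied-but-unentered connector.
    """
    b = _Builder()
    entered = entered_ids(p)
    for id_, rec in entered:
        b.add(_from_record(rec, id_))

    codes = {rec.relation_code for _, rec in entered}

    def present(code: str) -> Optional[str]:
        cid = code.replace(" ", "_")
        return cid if cid in b.nodes else None

    need_parents = bool(
        codes
        & {
            "mother",
            "father",
            "sister",
            "brother",
            "niece",
            "nephew",
            "maternal half-sister",
            "maternal half-brother",
            "paternal half-sister",
            "paternal half-brother",
        }
        or any(c.startswith(("maternal", "paternal")) for c in codes)
    )
    mother = father = None
    if need_parents:
        mother = b.get_or_placeholder("mother", "mother", Sex.FEMALE, 2)
        father = b.get_or_placeholder("father", "father", Sex.MALE, 2)
        b.nodes["self"].mother = mother.id
        b.nodes["self"].father = father.id

    maternal_side = any(c.startswith("maternal") for c in codes)
    paternal_side = any(c.startswith("paternal") for c in codes)
    m_gps = p_gps = None
    if maternal_side and codes & {
        "maternal grandmother",
        "maternal grandfather",
        "maternal aunt",
        "maternal uncle",
        "maternal cousin",
    }:
        gm = b.get_or_placeholder("maternal_grandmother", "mgm", Sex.FEMALE, 3)
        gf = b.get_or_placeholder("maternal_grandfather", "mgf", Sex.MALE, 3)
        mother.mother, mother.father = gm.id, gf.id
        m_gps = (gm, gf)
    if paternal_side and codes & {
        "paternal grandmother",
        "paternal grandfather",
        "paternal aunt",
        "paternal uncle",
        "paternal cousin",
    }:
        gm = b.get_or_placeholder("paternal_grandmother", "pgm", Sex.FEMALE, 3)
        gf = b.get_or_placeholder("paternal_grandfather", "pgf", Sex.MALE, 3)
        father.mother, father.father = gm.id, gf.id
        p_gps = (gm, gf)

    partner: Optional[Individual] = None  # proband's co-parent for children

    def proband_partner() -> Individual:
        nonlocal partner
        if partner is None:
            sex = Sex.MALE if p.proband.sex == Sex.FEMALE else Sex.FEMALE
            partner = b.placeholder("partner", sex, 1)
        return partner

    for id_, rec in entered:
        code = rec.relation_code
        node = b.nodes[id_]
        if code in ("sister", "brother"):
            node.mother, node.father = mother.id, father.id
        elif code in ("maternal half-sister", "maternal half-brother"):
            other = b.placeholder("halfsib_father", Sex.MALE, 2)
            node.mother, node.father = mother.id, other.id
        elif code in ("paternal half-sister", "paternal half-brother"):
            other = b.placeholder("halfsib_mother", Sex.FEMALE, 2)
            node.mother, node.father = other.id, father.id
        elif code in ("maternal aunt", "maternal uncle"):
            node.mother, node.father = m_gps[0].id, m_gps[1].id
        elif code in ("paternal aunt", "paternal uncle"):
            node.mother, node.father = p_gps[0].id, p_gps[1].id
        elif code in ("daughter", "son"):
            pp = proband_partner()
            if p.proband.sex == Sex.FEMALE:
                node.mother, node.father = "self", pp.id
            else:
                node.mother, node.father = pp.id, "self"
        elif code in ("niece", "nephew"):
            sib = b.placeholder("sibling", Sex.UNKNOWN, 1)
            sib.mother, sib.father = mother.id, father.id
            spouse = b.placeholder("sibling_partner", Sex.UNKNOWN, 1)
            node.mother, node.father = sib.id, spouse.id
            _fix_couple_sexes(sib, spouse, node)
        elif code in ("granddaughter", "grandson"):
            pp = proband_partner()
            child = b.placeholder("child", Sex.UNKNOWN, 0)
            if p.proband.sex == Sex.FEMALE:
                child.mother, child.father = "self", pp.id
            else:
                child.mother, child.father = pp.id, "self"
            spouse = b.placeholder("child_partner", Sex.UNKNOWN, 0)
            node.mother, node.father = child.id, spouse.id
            _fix_couple_sexes(child, spouse, node)
        elif code in ("maternal cousin", "paternal cousin"):
            gps = m_gps if code == "maternal cousin" else p_gps
            conn = b.placeholder("auntuncle", Sex.UNKNOWN, 2)
            conn.mother, conn.father = gps[0].id, gps[1].id
            spouse = b.placeholder("auntuncle_partner", Sex.UNKNOWN, 2)
            node.mother, node.father = conn.id, spouse.id
            _fix_couple_sexes(conn, spouse, node)
    return PedigreeGraph(individuals=b.nodes)


def _fix_couple_sexes(a: Individual, spouse: Individual, child: Individual) -> None:
    """Assign mother/father roles within a placeholder couple."""
    a.sex = Sex.FEMALE
    spouse.sex = Sex.MALE
    child.mother, child.father = a.id, spouse.id


def _singleton(code: str) -> bool:
    from .pedigree import _VOCAB

    return _VOCAB[code][3]


_SEX_CODE = {Sex.MALE: 1, Sex.FEMALE: 2, Sex.UNKNOWN: 0}


def write_ped(g: PedigreeGraph, condition_code: Optional[str] = None) -> str:
    """Serialise to LINKAGE/PED text.

    Columns: family id, individual id, father id, mother id, sex (1=male,
    2=female, 0=unknown), affection status for *condition_code* (1=unaffected,
    2=affected, 0=unknown).  Missing parents are coded 0.
    """
    rows = []
    for ind in sorted(g.individuals.values(), key=lambda i: (-i.generation, i.id)):
        if not ind.history_known or condition_code is None:
            aff = 0
        else:
            aff = 2 if condition_code in ind.affected else 1
        rows.append(
            f"{g.family_id} {ind.id} {ind.father or 0} {ind.mother or 0} "
            f"{_SEX_CODE[ind.sex]} {aff}"
        )
    return "\n".join(rows) + "\n"
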