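"""Genogram construction: a multigenerational family-structure graph built
from the 12 structured intake answers, exportable as DOT or JSON.

The genogram is a therapist-facing diagram: the index person, their unions
(with status married / divorced / remarried / partnered), children per
union, parents, siblings and grandparents, with deceased flags and
relational annotations.  No patient-facing recommendation is produced from
it; interpretation stays with the professional.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any, Mapping

import networkx as nx

UNION_STATUSES = ("married", "divorced", "remarried", "partnered")
SEXES = ("female", "male", "unspecified")
ROLES = ("index", "partner", "ex_partner", "child", "parent", "sibling", "grandparent", "other")


class GenogramError(ValueError):
    """Raised when intake records or a genogram violate structural invariants."""


@dataclass
class Person:
    id: str
    role: str = "other"
    sex: str = "unspecified"
    alive: bool = True
    annotations: set[str] = field(default_factory=set)


@dataclass
class Union:
    id: str
    partners: tuple[str, str]
    status: str = "partnered"


@dataclass
class Genogram:
    persons: dict[str, Person] = field(default_factory=dict)
    unions: dict[str, Union] = field(default_factory=dict)
    # union id -> list of child person ids
    offspring: dict[str, list[str]] = field(default_factory=dict)
    index_id: str = "index"

    def add_person(self, person: Person) -> Person:
        if person.id in self.persons:
            raise GenogramError(f"duplicate person id: {person.id}")
        self.persons[person.id] = person
        return person

    def add_union(self, union: Union) -> Union:
        if union.id in self.unions:
            raise GenogramError(f"duplicate union id: {union.id}")
        self.unions[union.id] = union
        return union

    def add_child(self, union_id: str, child_id: str) -> None:
        self.offspring.setdefault(union_id, []).append(child_id)

    def parents_of(self, child_id: str) -> list[str]:
        parents: list[str] = []
        for uid, children in self.offspring.items():
            if child_id in children:
                parents.extend(self.unions[uid].partners)
        return parents

    def validate(self) -> None:
        """Raise GenogramError on any structural invariant violation."""
        if self.index_id not in self.persons:
            raise GenogramError(f"index person {self.index_id!r} missing")
        for union in self.unions.values():
            for pid in union.partners:
                if pid not in self.persons:
                    raise GenogramError(f"union {union.id} references unknown person {pid!r}")
            if union.status not in UNION_STATUSES:
                raise GenogramError(f"union {union.id}: unknown status {union.status!r}")
        child_unions: dict[str, list[str]] = {}
        for uid, children in self.offspring.items():
            if uid not in self.unions:
                raise GenogramError(f"offspring link references unknown union {uid!r}")
            for child in children:
                if child not in self.persons:
                    raise GenogramError(f"offspring link references unknown person {child!r}")
                child_unions.setdefault(child, []).append(uid)
        for child, uids in child_unions.items():
            if len(uids) > 1:
                raise GenogramError(
                    f"person {child} has parent links from {len(uids)} unions (> 2 parents)"
                )
        # Parentage must be acyclic: parent -> child edges form a DAG.
        dag = nx.DiGraph()
        dag.add_nodes_from(self.persons)
        for uid, children in self.offspring.items():
            for parent in self.unions[uid].partners:
                for child in children:
                    dag.add_edge(parent, child)
        if not nx.is_directed_acyclic_graph(dag):
            cycle = nx.find_cycle(dag)
            raise GenogramError(f"cyclic parentage: {cycle}")


# ---------------------------------------------------------------------------
# intake -> genogram

def _person_record(rec: Mapping[str, Any] | None, pid: str, role: str) -> Person:
    rec = rec or {}
    return Person(
        id=pid,
        role=role,
        sex=str(rec.get("sex", "unspecified")),
        alive=bool(rec.get("alive", True)),
        annotations=set(rec.get("annotations", [])),
    )


def build_genogram(intake: Mapping[str, Any]) -> Genogram:
    """Build a three-generation genogram from the structured intake answers.

    ``intake`` maps the 12 genogram question ids to structured records; see
    the reference bank question texts for the semantics of each.  The
    returned genogram is validated (acyclic parentage, <= 2 parents per
    child, no dangling references).
    """
    g = Genogram()
    index_rec = intake.get("gen_index_profile", {})
    index = _person_record(index_rec, "index", "index")
    g.add_person(index)

    # Partners and the unions of the index person.
    for i, rec in enumerate(intake.get("gen_partners", []) or [], start=1):
        pid = str(rec.get("id", f"partner_{i}"))
        role = "ex_partner" if rec.get("status") == "divorced" else "partner"
        g.add_person(_person_record(rec, pid, role))
        status = str(rec.get("status", "partnered"))
        if status not in UNION_STATUSES:
            raise GenogramError(f"partner {pid}: unknown union status {status!r}")
        g.add_union(Union(id=f"u_index_{i}", partners=("index", pid), status=status))

    # Children, each attached to one of the index unions (or a lone-parent
    # union with an unspecified other parent).
    lone_union: str | None = None
    for i, rec in enumerate(intake.get("gen_children", []) or [], start=1):
        cid = str(rec.get("id", f"child_{i}"))
        g.add_person(_person_record(rec, cid, "child"))
        partner_index = rec.get("partner_index")
        if partner_index is not None:
            uid = f"u_index_{int(partner_index) + 1}"
            if uid not in g.unions:
                raise GenogramError(f"child {cid}: partner_index {partner_index} has no union")
        else:
            if lone_union is None:
                other = g.add_person(Person(id="unspecified_coparent", role="other"))
                lone_union = g.add_union(
                    Union(id="u_index_lone", partners=("index", other.id), status="partnered")
                ).id
            uid = lone_union
        g.add_child(uid, cid)

    # Parents of the index person and their union.
    parents = intake.get("gen_parents", {}) or {}
    have_parents = False
    if parents:
        mother = _person_record(parents.get("mother"), "mother", "parent")
        mother.sex = "female"
        father = _person_record(parents.get("father"), "father", "parent")
        father.sex = "male"
        g.add_person(mother)
        g.add_person(father)
        status = str((intake.get("gen_parent_union", {}) or {}).get("status", "married"))
        g.add_union(Union(id="u_parents", partners=("mother", "father"), status=status))
        g.add_child("u_parents", "index")
        have_parents = True

    for i, rec in enumerate(intake.get("gen_siblings", []) or [], start=1):
        sid = str(rec.get("id", f"sibling_{i}"))
        g.add_person(_person_record(rec, sid, "sibling"))
        if have_parents:
            g.add_child("u_parents", sid)

    for side, parent_id in (("maternal", "mother"), ("paternal", "father")):
        rec = intake.get(f"gen_grandparents_{side}", {}) or {}
        if not rec or not have_parents:
            continue
        gm = _person_record(rec.get("grandmother"), f"{side}_grandmother", "grandparent")
        gm.sex = "female"
        gf = _person_record(rec.get("grandfather"), f"{side}_grandfather", "grandparent")
        gf.sex = "male"
        g.add_person(gm)
        g.add_person(gf)
        g.add_union(Union(id=f"u_{side}", partners=(gm.id, gf.id), status="married"))
        g.add_child(f"u_{side}", parent_id)

    for tag in intake.get("gen_family_tags", []) or []:
        index.annotations.add(str(tag))
    for rec in intake.get("gen_deceased", []) or []:
        pid = str(rec.get("id", ""))
        if pid in g.persons:
            g.persons[pid].alive = False

    g.validate()
    return g


# ---------------------------------------------------------------------------
# export

def _dot_node(person: Person) -> str:
    shape = {"male": "box", "female": "circle"}.get(person.sex, "ellipse")
    label = person.id.replace("_", " ")
    if not person.alive:
        label += " ×"  # deceased mark
    attrs = [f'shape={shape}', f'label="{label}"']
    if person.role == "index":
        attrs.append("penwidth=2")
    if person.annotations:
        attrs.append(f'tooltip="{",".join(sorted(person.annotations))}"')
    return f'  "{person.id}" [{", ".join(attrs)}];'


def genogram_to_dot(g: Genogram) -> str:
    """Render the genogram as GraphViz DOT text.

    Genogram drawing convention approximated in DOT attributes: square =
    male, circle = female, x = deceased; union edges carry their status;
    offspring edges descend from a point node per union.
    """
    lines = ["graph genogram {", "  rankdir=TB;"]
    for pid in sorted(g.persons):
        lines.append(_dot_node(g.persons[pid]))
    for uid in sorted(g.unions):
        union = g.unions[uid]
        a, b = union.partners
        lines.append(f'  "{uid}" [shape=point, width=0.05];')
        lines.append(f'  "{a}" -- "{uid}" [label="{union.status}"];')
        lines.append(f'  "{uid}" -- "{b}";')
        for child in g.offspring.get(uid, []):
            lines.append(f'  "{uid}" -- "{child}" [style=solid];')
    lines.append("}")
    return "\n".join(lines) + "\n"


def genogram_to_json_dict(g: Genogram) -> dict[str, Any]:
    return {
        "index_id": g.index_id,
        "persons": [
            {
                "id": p.id,
                "role": p.role,
                "sex": p.sex,
                "alive": p.alive,
                "annotations": sorted(p.annotations),
            }
            for p in (g.persons[pid] for pid in sorted(g.persons))
        ],
        "unions": [
            {"id": u.id, "partners": list(u.partners), "status": u.status}
            for u in (g.unions[uid] for uid in sorted(g.unions))
        ],
        "offspring": {uid: list(children) for uid, children in sorted(g.offspring.items())},
    }


def genogram_from_json_dict(doc: Mapping[str, Any]) -> Genogram:
    g = Genogram(index_id=str(doc.get("index_id", "index")))
    for rec in doc["persons"]:
        g.add_person(
            Person(
                id=str(rec["id"]),
                role=str(rec.get("role", "other")),
                sex=str(rec.get("sex", "unspecified")),
                alive=bool(rec.get("alive", True)),
                annotations=set(rec.get("annotations", [])),
            )
        )
    for rec in doc["unions"]:
        g.add_union(
            Union(
                id=str(rec["id"]),
                partners=(str(rec["partners"][0]), str(rec["partners"][1])),
                status=str(rec.get("status", "partnered")),
            )
        )
    for uid, children in doc.get("offspring", {}).items():
        for child in children:
            g.add_child(str(uid), str(child))
    g.validate()
    return g


def genogram_export(g: Genogram, format: str) -> str:
    """Export the genogram as 'dot' or 'json' text."""
    if format == "dot":
        return genogram_to_dot(g)
    if format == "json":
        return json.dumps(genogram_to_json_dict(g), indent=2, sort_keys=True)
    raise ValueError(f"unknown genogram export format {format!r}")
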