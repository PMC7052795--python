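"""Hierarchical assembly planning and end-to-end simulation.

A design is a tree: leaves are L0 part names, internal nodes carry a level
(1-4), a kit, and a receiver position.  Odd levels assemble with BsaI into
kanamycin receivers, even levels with SapI into spectinomycin or
chloramphenicol receivers; the planner enforces the alternation, requires
full four-child chains above level 1, simulates every node bottom-up with
the one-pot engine, counts part composition, and prices out bench recipes.
"""

from __future__ import annotations

import dataclasses
import json
from collections import Counter

from .seqio import DnaMolecule, Feature
from .typeiis import (
    BSAI,
    SAPI,
    ChainAssemblyError,
    digest,
    enumerate_ligations,
    fragment_has_site,
    one_pot_assemble,
)
from .schema import OverhangTable, PartL0, Receiver, validate_part_chain

__all__ = [
    "DesignNode",
    "Design",
    "Library",
    "Plan",
    "Recipe",
    "CompositionCount",
    "PlanError",
    "plan_design",
    "simulate_plan",
    "count_composition",
    "make_recipe",
    "NG_PER_FMOL_BP",
]

# Average molar mass of a base pair; fmol * bp * 650 / 1e6 = nanograms.
NG_PER_FMOL_BP = 650e-6

PART_FMOL = 15.0
RECEIVER_FMOL = 7.5
DNA_MIX_UL = 5.0

MASTER_MIX = {
    "odd": {
        "dH2O": 3.0,
        "T4 DNA ligase buffer 10x": 1.0,
        "BSA 1 mg/ml": 0.5,
        "T4 DNA ligase 400 U/ul": 0.25,
        "BsaI 10 U/ul": 0.25,
    },
    "even": {
        "dH2O": 3.5,
        "T4 DNA ligase buffer 10x": 0.5,
        "CutSmart buffer 10x": 0.5,
        "T4 DNA ligase 400 U/ul": 0.25,
        "SapI 10 U/ul": 0.25,
    },
}

REGULAR_CYCLE = {"denature": (37.0, 3.0), "ligate": (16.0, 4.0)}
SHORT_CYCLE = {"denature": (37.0, 1.0), "ligate": (16.0, 1.5)}


class PlanError(ValueError):
    pass


@dataclasses.dataclass
class DesignNode:
    """One assembly reaction in the tree."""

    level: int
    position: int
    children: list  # part-name strings (level 1) or DesignNode (level >= 2)
    kit: str = "pCA"
    receiver_free: bool = False
    node_id: str = ""

    @property
    def parity(self) -> str:
        return "odd" if self.level % 2 else "even"

    def signature(self) -> str:
        child_sigs = [
            c if isinstance(c, str) else c.signature() for c in self.children
        ]
        return json.dumps(
            {
                "level": self.level,
                "position": self.position,
                "kit": self.kit,
                "receiver_free": self.receiver_free,
                "children": child_sigs,
            },
            sort_keys=True,
        )

    @classmethod
    def from_dict(cls, data: dict) -> "DesignNode":
        children = [
            c if isinstance(c, str) else cls.from_dict(c)
            for c in data["children"]
        ]
        return cls(
            level=int(data["level"]),
            position=int(data.get("position", 1)),
            children=children,
            kit=data.get("kit", "pCA"),
            receiver_free=bool(data.get("receiver_free", False)),
            node_id=data.get("id", ""),
        )

    def to_dict(self) -> dict:
        return {
            "id": self.node_id,
            "level": self.level,
            "position": self.position,
            "kit": self.kit,
            "receiver_free": self.receiver_free,
            "children": [
                c if isinstance(c, str) else c.to_dict() for c in self.children
            ],
        }


@dataclasses.dataclass
class Design:
    root: DesignNode
    name: str = ""

    @classmethod
    def from_json(cls, path) -> "Design":
        with open(path) as fh:
            data = json.load(fh)
        return cls(root=DesignNode.from_dict(data["root"]), name=data.get("name", ""))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"name": self.name, "root": self.root.to_dict()}, fh, indent=2)


@dataclasses.dataclass
class Library:
    """Resolvable collections backing a plan."""

    parts: dict  # name -> PartL0
    receivers: dict  # (kit, parity, position) -> Receiver
    table: OverhangTable

    def part(self, name: str) -> PartL0:
        try:
            return self.parts[name]
        except KeyError:
            raise PlanError(f"unknown part {name!r}") from None

    def receiver(self, kit: str, parity: str, position: int) -> Receiver:
        try:
            return self.receivers[(kit, parity, position)]
        except KeyError:
            raise PlanError(f"no receiver for ({kit}, {parity}, {position})") from None


@dataclasses.dataclass
class Plan:
    design: Design
    library: Library
    nodes: list  # (path, DesignNode, Receiver | None) in leaf-to-root order


def _walk(node: DesignNode, path: str, out: list) -> None:
    for i, child in enumerate(node.children):
        if isinstance(child, DesignNode):
            _walk(child, f"{path}/{child.node_id or f'child{i}'}", out)
    out.append((path, node))


def plan_design(design: Design, library: Library) -> Plan:
    """Validate level alternation, positions, markers, and every chain."""
    ordered: list = []
    _walk(design.root, design.root.node_id or "root", ordered)
    planned = []
    for path, node in ordered:
        if not 1 <= node.level <= 4:
            raise PlanError(f"{path}: level must be 1..4, got {node.level}")
        if node.receiver_free and node.level != 4:
            raise PlanError(f"{path}: only level-4 nodes may be receiver-free")
        receiver = None
        if not node.receiver_free:
            receiver = library.receiver(node.kit, node.parity, node.position)
        if node.level == 1:
            parts = []
            for child in node.children:
                if not isinstance(child, str):
                    raise PlanError(f"{path}: level-1 children must be L0 part names")
                parts.append(library.part(child))
            try:
                validate_part_chain(parts, "A", "F")
            except ChainAssemblyError as exc:
                raise PlanError(f"{path}: {exc}") from exc
        else:
            if len(node.children) != 4:
                raise PlanError(
                    f"{path}: level-{node.level} nodes require a full chain of "
                    f"4 children, got {len(node.children)}"
                )
            for i, child in enumerate(node.children, start=1):
                if not isinstance(child, DesignNode):
                    raise PlanError(f"{path}: level-{node.level} children must be nodes")
                if child.level != node.level - 1:
                    raise PlanError(
                        f"{path}: child level {child.level} does not feed "
                        f"level {node.level} (expected {node.level - 1})"
                    )
                if child.position != i:
                    raise PlanError(
                        f"{path}: child {i} sits at receiver position "
                        f"{child.position}, expected {i}"
                    )
                if receiver is not None:
                    child_receiver = library.receiver(
                        child.kit, child.parity, child.position
                    )
                    if child_receiver.marker == receiver.marker:
                        raise PlanError(
                            f"{path}: marker does not alternate between levels "
                            f"({receiver.marker})"
                        )
        planned.append((path, node, receiver))
    return Plan(design=design, library=library, nodes=planned)


def _annotate_tu(product: DnaMolecule, cargo_span: tuple) -> None:
    product.add_feature(
        Feature("other", "TU", cargo_span[0], cargo_span[1], qualifiers={"unit": "TU"})
    )


def _receiver_free_assemble(products: list[DnaMolecule], enzyme):
    """SapI-style assembly without a receiver: returns the annotated
    full-length linear product and the concatemer ladder."""
    pool = []
    for mol in products:
        stable = [f for f in digest(mol, enzyme) if not fragment_has_site(f, enzyme)]
        if len(stable) != 1:
            raise PlanError(
                f"{mol.id}: expected one stable release fragment, got {len(stable)}"
            )
        pool.append(stable[0])
    ladder = enumerate_ligations(pool, mode="include_linear", max_copies=1)
    # Chain the pool deterministically: the unique start fragment is the one
    # whose left overhang is produced by no other fragment's right end.
    rights = {f.right_overhang for f in pool}
    starts = [f for f in pool if f.left_overhang not in rights]
    if len(starts) != 1:
        raise PlanError("receiver-free pool does not form a single linear chain")
    chain = [starts[0]]
    remaining = [f for f in pool if f is not starts[0]]
    while remaining:
        nxt = [f for f in remaining if f.left_overhang == chain[-1].right_overhang]
        if len(nxt) != 1:
            raise PlanError("receiver-free pool does not form a single linear chain")
        chain.append(nxt[0])
        remaining.remove(nxt[0])
    seq = "".join(f.core for f in chain) + chain[-1].right_overhang
    features = []
    offset = 0
    for f in chain:
        features.extend(feat.shifted(offset) for feat in f.features)
        offset += len(f.core)
    full = DnaMolecule(
        id="+".join(m.id for m in products),
        sequence=seq,
        topology="linear",
        features=features,
        provenance=f"receiver-free {enzyme.name} assembly",
    )
    return full, ladder


def simulate_plan(plan: Plan, warn=None) -> dict:
    """Run every node's one-pot reaction bottom-up.

    Returns ``{"products": {path: DnaMolecule}, "root": DnaMolecule,
    "ladder": [...]}`` (the ladder only for a receiver-free root).  Repeated
    subtrees are simulated once via structural memoisation.
    """
    library = plan.library
    memo: dict[str, DnaMolecule] = {}
    products: dict[str, DnaMolecule] = {}
    ladder = None
    root_path = plan.nodes[-1][0]

    def product_of(node: DesignNode, path: str) -> DnaMolecule:
        nonlocal ladder
        sig = node.signature()
        if sig in memo:
            products[path] = memo[sig]
            return memo[sig]
        if node.level == 1:
            inserts = [library.part(c).molecule for c in node.children]
        else:
            inserts = [
                product_of(c, f"{path}/{c.node_id or f'child{i}'}")
                for i, c in enumerate(node.children)
            ]
        enzyme = BSAI if node.parity == "odd" else SAPI
        if node.receiver_free:
            mol, ladder = _receiver_free_assemble(inserts, enzyme)
        else:
            receiver = library.receiver(node.kit, node.parity, node.position)
            # Different children may memoise to the same product; a one-pot
            # pool needs distinct molecules, so alias duplicates.
            seen: dict[str, int] = {}
            pool = []
            for mol_in in inserts:
                n = seen.get(mol_in.id, 0)
                seen[mol_in.id] = n + 1
                if n:
                    mol_in = dataclasses.replace(mol_in, id=f"{mol_in.id}.{n + 1}")
                pool.append(mol_in)
            try:
                report = one_pot_assemble(
                    receiver.molecule,
                    pool,
                    enzyme,
                    code_names=library.table.code_names(),
                )
            except ChainAssemblyError as exc:
                raise PlanError(f"{path}: {exc}") from exc
            if report.n_intended != 1:
                raise PlanError(f"{path}: reaction yields no unique intended product")
            mol = report.intended
            mol.id = node.node_id or mol.id
            if node.level == 1:
                _annotate_tu(mol, report.cargo_span)
        memo[sig] = mol
        products[path] = mol
        return mol

    root = product_of(plan.nodes[-1][1], root_path)
    out = {"products": products, "root": root}
    if ladder is not None:
        out["ladder"] = ladder
    return out


@dataclasses.dataclass
class CompositionCount:
    """Multiset of leaf-level part labels plus the transcription-unit count."""

    tus: int
    parts: Counter

    def __add__(self, other: "CompositionCount") -> "CompositionCount":
        return CompositionCount(self.tus + other.tus, self.parts + other.parts)


_COUNTED_KINDS = ("promoter", "CDS", "tag", "terminator", "RBS")


def count_composition(target, library: Library | None = None, warn=None) -> CompositionCount:
    """Exact composition census of a design tree or a simulated product.

    Plan-level counting (over the tree) and feature-level counting (over
    the product's annotations) agree by construction; parts without a kind
    label are tallied under ``other`` with a warning.
    """
    if isinstance(target, Design):
        target = target.root
    if isinstance(target, DesignNode):
        if library is None:
            raise PlanError("counting a design requires the part library")
        if target.level == 1:
            parts: Counter = Counter()
            for name in target.children:
                part = library.part(name)
                if part.kind in _COUNTED_KINDS:
                    parts[part.census_label] += 1
                else:
                    if warn is not None:
                        warn(f"part {part.name} has no counted kind; tallied as other")
                    parts["other"] += 1
            return CompositionCount(tus=1, parts=parts)
        total = CompositionCount(0, Counter())
        for child in target.children:
            total = total + count_composition(child, library, warn)
        return total
    if isinstance(target, DnaMolecule):
        parts = Counter(
            f.label for f in target.features if f.kind in _COUNTED_KINDS
        )
        tus = sum(1 for f in target.features if f.label == "TU")
        return CompositionCount(tus=tus, parts=parts)
    raise PlanError(f"cannot count composition of {type(target).__name__}")


@dataclasses.dataclass
class Recipe:
    """Bench recipe for one assembly node: 5 ul DNA mix + 5 ul master mix."""

    node: str
    parity: str
    dna_mix: list  # dicts: id, fmol, length_bp, ng, conc_ng_ul, volume_ul
    water_ul: float
    master_mix: dict
    cycles: int
    cycling: dict
    options: dict

    @property
    def dna_mix_total_ul(self) -> float:
        return sum(row["volume_ul"] for row in self.dna_mix) + self.water_ul

    @property
    def master_mix_total_ul(self) -> float:
        return sum(self.master_mix.values())

    @property
    def total_ul(self) -> float:
        return self.dna_mix_total_ul + self.master_mix_total_ul

    def format(self) -> str:
        lines = [f"# Assembly recipe for {self.node} ({self.parity} level)", "", "DNA mix:"]
        for row in self.dna_mix:
            lines.append(
                f"  {row['id']}: {row['volume_ul']:.3f} ul "
                f"({row['fmol']} fmol, {row['length_bp']} bp at "
                f"{row['conc_ng_ul']} ng/ul)"
            )
        lines.append(f"  dH2O: {self.water_ul:.3f} ul (to {DNA_MIX_UL:.1f} ul)")
        lines.append("")
        lines.append("Master mix:")
        for component, vol in self.master_mix.items():
            lines.append(f"  {component}: {vol:.2f} ul")
        den = self.cycling["denature"]
        lig = self.cycling["ligate"]
        lines.append("")
        lines.append(
            f"Cycling: {self.cycles}x ({den[1]:g} min at {den[0]:g} C / "
            f"{lig[1]:g} min at {lig[0]:g} C)"
        )
        lines.append(f"Total reaction volume: {self.total_ul:.1f} ul")
        return "\n".join(lines)


def make_recipe(
    node_label: str,
    parity: str,
    inputs: list,
    concentrations: dict,
    short_cycle: bool = False,
    double_enzyme: bool = False,
    cycles: int = 25,
    ng_per_fmol_bp: float = NG_PER_FMOL_BP,
) -> Recipe:
    """Compute dispense volumes for one reaction.

    ``inputs`` is a list of ``(id, length_bp, role)`` with role ``receiver``
    (7.5 fmol) or ``part`` (15 fmol); ``concentrations`` maps id to ng/ul.
    Volume per input is ``fmol * bp * 650 / 1e6 / conc``; water fills the
    DNA mix to 5 ul and the parity-specific master mix adds 5 more.
    """
    if parity not in MASTER_MIX:
        raise PlanError("parity must be 'odd' or 'even'")
    if cycles not in (25, 50):
        raise PlanError("cycle count options are 25 or 50")
    rows = []
    for mol_id, length_bp, role in inputs:
        if role not in ("receiver", "part"):
            raise PlanError(f"unknown input role {role!r}")
        conc = concentrations.get(mol_id)
        if conc is None or conc <= 0:
            raise PlanError(f"missing or non-positive concentration for {mol_id!r}")
        fmol = RECEIVER_FMOL if role == "receiver" else PART_FMOL
        ng = fmol * length_bp * ng_per_fmol_bp
        rows.append(
            {
                "id": mol_id,
                "role": role,
                "fmol": fmol,
                "length_bp": length_bp,
                "ng": round(ng, 4),
                "conc_ng_ul": conc,
                "volume_ul": ng / conc,
            }
        )
    dna_volume = sum(r["volume_ul"] for r in rows)
    if dna_volume > DNA_MIX_UL:
        needed = ", ".join(
            f"{r['id']} >= {r['ng'] * len(rows) / DNA_MIX_UL:.1f} ng/ul" for r in rows
        )
        raise PlanError(
            f"DNA volumes total {dna_volume:.2f} ul > {DNA_MIX_UL} ul; "
            f"concentrate inputs (sufficient: {needed})"
        )
    master = dict(MASTER_MIX[parity])
    if double_enzyme:
        enzyme_key = next(k for k in master if k.startswith(("BsaI", "SapI")))
        master["dH2O"] = round(master["dH2O"] - master[enzyme_key], 4)
        master[enzyme_key] = round(master[enzyme_key] * 2, 4)
    return Recipe(
        node=node_label,
        parity=parity,
        dna_mix=rows,
        water_ul=DNA_MIX_UL - dna_volume,
        master_mix=master,
        cycles=cycles,
        cycling=SHORT_CYCLE if short_cycle else REGULAR_CYCLE,
        options={
            "short_cycle": short_cycle,
            "double_enzyme": double_enzyme,
            "cycles": cycles,
        },
    )


def recipe_for_node(
    plan: Plan, path_or_id: str, concentrations: dict, **options
) -> Recipe:
    """Recipe for one node of a validated plan."""
    for path, node, receiver in plan.nodes:
        if path_or_id in (path, node.node_id):
            inputs = []
            if receiver is not None:
                inputs.append(
                    (receiver.molecule.id, len(receiver.molecule), "receiver")
                )
            if node.level == 1:
                for name in node.children:
                    part = plan.library.part(name)
                    inputs.append((part.name, len(part.molecule), "part"))
            else:
                sim = simulate_plan(plan)
                for i, child in enumerate(node.children):
                    child_path = f"{path}/{child.node_id or f'child{i}'}"
                    mol = sim["products"][child_path]
                    inputs.append((mol.id, len(mol), "part"))
            return make_recipe(
                node.node_id or path, node.parity, inputs, concentrations, **options
            )
    raise PlanError(f"no node {path_or_id!r} in plan")
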