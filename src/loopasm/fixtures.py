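"""Deterministic synthetic kits, part libraries, and test designs.

Everything is generated from a single integer seed so the whole system is
testable offline; regeneration with the same seed is byte-identical.
Synthetic sizes put level-1 products around 3-4 kb and level-3 products in
the tens of kilobases, but exact sizes are not contracts.  Constructions
that can fail by chance (a recognition site arising across a junction) are
rejection-sampled, so any seed yields a valid library.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .seqio import DnaMolecule, Feature
from .schema import (
    KITS,
    OverhangTable,
    PartL0,
    build_entry_vector,
    build_l0_entry,
    build_receiver,
    domesticate,
)
from .planner import Design, DesignNode, Library

__all__ = [
    "FixtureSpec",
    "generate_kit",
    "generate_part_library",
    "generate_library",
    "paper_test_designs",
    "DESIGN_IDS",
]

DESIGN_IDS = (
    "L1-4_sfGFP",
    "L2-allx4",
    "L2-4_sfGFP",
    "L3-allx4",
    "L3-4_sfGFP",
    "L4",
)

_BASES = np.array(list("ACGT"))
_NON_STOP_CODONS = sorted(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
)
_MAX_TRIES = 50


@dataclasses.dataclass
class FixtureSpec:
    seed: int = 42
    kits: tuple = KITS
    backbone_bp: tuple = (2000, 4000)


def _random_dna(rng, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _clean_random_dna(rng, length: int) -> str:
    seq, _ = domesticate(_random_dna(rng, length))
    return seq


def _random_cds_body(rng, n_codons: int) -> str:
    idx = rng.integers(0, len(_NON_STOP_CODONS), size=n_codons)
    return "".join(_NON_STOP_CODONS[i] for i in idx)


def generate_kit(seed: int = 42, table: OverhangTable | None = None, kits=KITS):
    """Receivers for every (kit, parity, position) plus the entry vector.

    Each kit gets one random recognition-free backbone (2-4 kb) shared by
    its eight receivers, named ``<kit>o-1..4`` / ``<kit>e-1..4``.
    """
    table = table or OverhangTable.default()
    rng = np.random.default_rng(seed)
    receivers: dict = {}
    for kit in kits:
        for _ in range(_MAX_TRIES):
            length = int(rng.integers(2000, 4001))
            backbone = DnaMolecule(
                id=f"{kit}-backbone",
                sequence=_clean_random_dna(rng, length),
                topology="linear",
                provenance="synthetic minimized backbone",
            )
            try:
                built = {
                    (kit, parity, position): build_receiver(
                        kit, parity, position, backbone, table
                    )
                    for parity in ("odd", "even")
                    for position in range(1, 5)
                }
                break
            except ValueError:
                continue  # junction recreated a site; draw a new backbone
        else:
            raise RuntimeError(f"could not build a clean {kit} backbone")
        receivers.update(built)
    for _ in range(_MAX_TRIES):
        entry_backbone = DnaMolecule(
            id="entry-backbone",
            sequence=_clean_random_dna(rng, int(rng.integers(1800, 2600))),
            topology="linear",
        )
        try:
            entry_vector = build_entry_vector(entry_backbone, table)
            break
        except ValueError:
            continue
    else:
        raise RuntimeError("could not build a clean entry vector")
    return receivers, entry_vector


# (name, kind, label, spec); CDS lengths in codons, others in nt.
_PART_DEFS = (
    ("AB_J23101", "promoter", "J23101", {"nt": 60}),
    ("BC_B0034m", "RBS", "B0034m", {"nt": 24}),
    ("CE_sfGFP", "CDS", "sfGFP", {"codons": 238, "stop": True}),
    ("EF_B0015", "terminator", "B0015", {"nt": 129}),
    ("AC_35S", "promoter", "CaMV35S", {"nt": 700}),
    ("CE_mRuby3", "CDS", "mRuby3", {"codons": 236, "stop": True}),
    ("CD_mTurquoise2", "CDS", "mTurquoise2", {"codons": 238, "stop": False}),
    ("CD_Venus", "CDS", "Venus", {"codons": 238, "stop": False}),
    ("DE_N7", "tag", "N7", {"codons": 80, "stop": True}),
    ("EF_nos", "terminator", "nos", {"nt": 253}),
)


def _part_insert(rng, kind: str, spec: dict) -> str:
    """A domesticated insert body.

    CDS bodies omit the start codon (the C code's embedded ATG supplies
    it); stopless bodies end on GC so the D junction completes Ala-Gly.
    """
    if "codons" in spec:
        body = _random_cds_body(rng, spec["codons"])
        insert = body + ("TAA" if spec["stop"] else "GC")
        insert, _ = domesticate(insert, cds_intervals=[(0, (len(insert) // 3) * 3)])
        return insert
    insert, _ = domesticate(_random_dna(rng, spec["nt"]))
    return insert


def generate_part_library(
    seed: int = 42,
    entry_vector: DnaMolecule | None = None,
    table: OverhangTable | None = None,
) -> dict:
    """The named L0 catalog used by the test designs."""
    table = table or OverhangTable.default()
    if entry_vector is None:
        _, entry_vector = generate_kit(seed, table, kits=("pCA",))
    rng = np.random.default_rng(seed + 1)
    parts: dict[str, PartL0] = {}
    for name, kind, label, spec in _PART_DEFS:
        five, three = name[0], name[1]
        name_label = name.split("_", 1)[1]
        for _ in range(_MAX_TRIES):
            insert = _part_insert(rng, kind, spec)
            try:
                part = build_l0_entry(
                    insert, five, three, entry_vector, table, name_label, kind=kind
                )
                part.payload_label = label
                break
            except ValueError:
                continue  # flank junction recreated a site; redraw
        else:
            raise RuntimeError(f"could not build part {name}")
        start, end = part.insert_span
        if kind == "CDS":
            # Span from the C code's embedded ATG; stopless CDSs borrow the
            # first base of the D code to close the final Ala codon.
            f0 = start - 3
            f1 = end if spec["stop"] else end + 1
        else:
            f0, f1 = start, end
        quals = {"partial": True} if kind == "CDS" and (f1 - f0) % 3 else {}
        part.molecule.add_feature(Feature(kind, label, f0, f1, qualifiers=quals))
        parts[name] = part
    return parts


_TU_PARTS = {
    "sfGFP": ["AB_J23101", "BC_B0034m", "CE_sfGFP", "EF_B0015"],
    "35SmR3": ["AC_35S", "CE_mRuby3", "EF_nos"],
    "35SmT2": ["AC_35S", "CD_mTurquoise2", "DE_N7", "EF_nos"],
    "35SVe": ["AC_35S", "CD_Venus", "DE_N7", "EF_nos"],
}


def _l1(tu: str, position: int, kit: str, node_id: str | None = None) -> DesignNode:
    return DesignNode(
        level=1,
        position=position,
        children=list(_TU_PARTS[tu]),
        kit=kit,
        node_id=node_id or f"pL1-{position}_{tu}",
    )


def paper_test_designs(kit: str = "pCA") -> dict:
    """The published test-assembly trees, encoded with fixture parts."""

    def l2_allx4(position: int) -> DesignNode:
        return DesignNode(
            level=2,
            position=position,
            kit=kit,
            node_id=f"L2-{position}_allx4",
            children=[
                _l1("35SmR3", 1, kit),
                _l1("35SmT2", 2, kit),
                _l1("35SVe", 3, kit),
                _l1("35SmR3", 4, kit),
            ],
        )

    def l2_sfgfp() -> DesignNode:
        return DesignNode(
            level=2,
            position=4,
            kit=kit,
            node_id="L2-4_sfGFP",
            children=[
                _l1("35SmR3", 1, kit),
                _l1("35SmT2", 2, kit),
                _l1("35SVe", 3, kit),
                _l1("sfGFP", 4, kit, node_id="L1-4_sfGFP"),
            ],
        )

    def l3_allx4(position: int) -> DesignNode:
        return DesignNode(
            level=3,
            position=position,
            kit=kit,
            node_id=f"L3-{position}_allx4",
            children=[l2_allx4(i) for i in range(1, 5)],
        )

    l3_sfgfp = DesignNode(
        level=3,
        position=4,
        kit=kit,
        node_id="L3-4_sfGFP",
        children=[l2_allx4(1), l2_allx4(2), l2_allx4(3), l2_sfgfp()],
    )

    l4 = DesignNode(
        level=4,
        position=1,
        kit=kit,
        receiver_free=True,
        node_id="L4",
        children=[l3_allx4(1), l3_allx4(2), l3_allx4(3), l3_sfgfp],
    )

    return {
        "L1-4_sfGFP": Design(_l1("sfGFP", 4, kit, node_id="L1-4_sfGFP"), name="L1-4_sfGFP"),
        "L2-allx4": Design(l2_allx4(4), name="L2-allx4"),
        "L2-4_sfGFP": Design(l2_sfgfp(), name="L2-4_sfGFP"),
        "L3-allx4": Design(l3_allx4(4), name="L3-allx4"),
        "L3-4_sfGFP": Design(l3_sfgfp, name="L3-4_sfGFP"),
        "L4": Design(l4, name="L4"),
    }


def generate_library(seed: int = 42, kits=("pCA",), table: OverhangTable | None = None) -> Library:
    """One-call fixture: receivers + entry vector + part catalog."""
    table = table or OverhangTable.default()
    receivers, entry_vector = generate_kit(seed, table, kits=kits)
    parts = generate_part_library(seed, entry_vector, table)
    return Library(parts=parts, receivers=receivers, table=table)
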