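"""Recursive odd/even assembly grammar: overhang alphabets, nomenclature,
receiver construction, L0 entry, and domestication.

The 3-nt even-level (SapI) overhang alphabet ships with its published
values.  The 4-nt odd-level (BsaI) alphabet follows the community fusion
site convention but is configuration, not contract: every consumer should
derive expectations from the active :class:`OverhangTable` rather than from
literal sequences.  Likewise the UNS verification flanks and the entry
overhangs are replaceable defaults.
"""

from __future__ import annotations

import configparser
import dataclasses
import re

from Bio.Data.CodonTable import standard_dna_table

from .seqio import DnaMolecule, Feature, reverse_complement, translate_cds
from .typeiis import (
    BSAI,
    SAPI,
    ChainAssemblyError,
    Enzyme,
    digest,
    fidelity_check,
    scan_sites,
)

__all__ = [
    "OverhangTable",
    "PartL0",
    "Receiver",
    "KITS",
    "MARKERS",
    "validate_part_chain",
    "build_receiver",
    "domesticate",
    "build_l0_entry",
    "compose_name",
    "parse_name",
    "part_syntax_warnings",
    "DomesticationError",
    "NameError_",
]

KITS = ("pCA", "pCO", "pSB", "pAN")

# Odd levels always select with kanamycin; even levels alternate by kit.
MARKERS = {
    ("pCA", "odd"): "kanamycin",
    ("pCO", "odd"): "kanamycin",
    ("pSB", "odd"): "kanamycin",
    ("pAN", "odd"): "kanamycin",
    ("pCA", "even"): "spectinomycin",
    ("pCO", "even"): "spectinomycin",
    ("pSB", "even"): "chloramphenicol",
    ("pAN", "even"): "chloramphenicol",
}

_ODD_DEFAULTS = {
    "A": "GGAG",
    "B": "TACT",
    "C": "AATG",
    "D": "CGGT",
    "E": "GGTA",
    "F": "CGCT",
}
_EVEN_DEFAULTS = {
    "alpha": "ATG",
    "beta": "GCA",
    "gamma": "TAC",
    "epsilon": "CAG",
    "omega": "GGT",
}
_GREEK = {"α": "alpha", "β": "beta", "γ": "gamma", "ε": "epsilon", "ω": "omega"}

UNS1_DEFAULT = "CATTACTCGCATCCATTCTC"
UNSX_DEFAULT = "GCTAACGAGTGCCTTAAACG"


class DomesticationError(ValueError):
    pass


class NameError_(ValueError):
    """Malformed part name."""


@dataclasses.dataclass
class OverhangTable:
    """The two alternating overhang alphabets plus auxiliary flank config.

    ``odd_release_chain`` lists the five odd codes that chain four
    even-level composites into an odd receiver (first term A, last term F);
    its interior terms reuse odd codes already consumed as scars at the
    previous odd level, which is safe because scars carry no recognition
    sites.
    """

    odd_codes: dict = dataclasses.field(default_factory=lambda: dict(_ODD_DEFAULTS))
    even_codes: dict = dataclasses.field(default_factory=lambda: dict(_EVEN_DEFAULTS))
    odd_release_chain: tuple = ("A", "B", "C", "E", "F")
    even_chain: tuple = ("alpha", "beta", "gamma", "epsilon", "omega")
    entry_overhangs: tuple = ("CTA", "TCC")
    uns1: str = UNS1_DEFAULT
    unsx: str = UNSX_DEFAULT

    def __post_init__(self) -> None:
        for code, seq in self.odd_codes.items():
            if len(seq) != BSAI.overhang_len:
                raise ValueError(f"odd code {code}: length must be {BSAI.overhang_len}")
        for code, seq in self.even_codes.items():
            if len(seq) != SAPI.overhang_len:
                raise ValueError(f"even code {code}: length must be {SAPI.overhang_len}")
        for alphabet in (self.odd_codes, self.even_codes):
            report = fidelity_check(list(alphabet.values()))
            if not report["clean"]:
                raise ValueError(f"overhang alphabet fails fidelity check: {report}")
        if self.odd_release_chain[0] != "A" or self.odd_release_chain[-1] != "F":
            raise ValueError("odd release chain must run A..F")
        if len(self.odd_release_chain) != 5 or len(self.even_chain) != 5:
            raise ValueError("release chains must have five terms")

    # -- lookups ----------------------------------------------------------
    def odd(self, code: str) -> str:
        return self.odd_codes[code]

    def even(self, code: str) -> str:
        return self.even_codes[_GREEK.get(code, code)]

    def code_names(self) -> dict:
        """Map overhang sequence -> code letter, for diagnostics."""
        names = {seq: code for code, seq in self.odd_codes.items()}
        names.update({seq: code for code, seq in self.even_codes.items()})
        return names

    @classmethod
    def default(cls) -> "OverhangTable":
        return cls()

    @classmethod
    def from_config(cls, path) -> "OverhangTable":
        """Read a ``key = sequence`` config file (sections [odd], [even])."""
        parser = configparser.ConfigParser()
        parser.optionxform = str  # preserve code-letter case
        with open(path) as fh:
            parser.read_file(fh)
        kwargs = {}
        if parser.has_section("odd"):
            kwargs["odd_codes"] = {k: v.upper() for k, v in parser.items("odd")}
        if parser.has_section("even"):
            kwargs["even_codes"] = {k: v.upper() for k, v in parser.items("even")}
        if parser.has_section("flanks"):
            flanks = dict(parser.items("flanks"))
            kwargs["uns1"] = flanks.get("UNS1", UNS1_DEFAULT).upper()
            kwargs["unsx"] = flanks.get("UNSX", UNSX_DEFAULT).upper()
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# Nomenclature

_NAME_RE = re.compile(r"^([A-F])([A-F])_(.+)$")


def compose_name(five_code: str, three_code: str, label: str) -> str:
    for code in (five_code, three_code):
        if code not in _ODD_DEFAULTS:
            raise NameError_(f"unknown odd-alphabet code {code!r}")
    if not label or "_" in label[:0]:
        raise NameError_("empty label")
    return f"{five_code}{three_code}_{label}"


def parse_name(name: str) -> tuple[str, str, str]:
    m = _NAME_RE.match(name)
    if not m:
        raise NameError_(
            f"malformed part name {name!r}: expected <five><three>_<label> "
            "with codes in A-F"
        )
    return m.group(1), m.group(2), m.group(3)


# ---------------------------------------------------------------------------
# Part and receiver records


@dataclasses.dataclass
class PartL0:
    """A basic part held in an entry-vector plasmid."""

    molecule: DnaMolecule
    five_code: str
    three_code: str
    label: str
    kind: str = "other"
    insert_span: tuple = (0, 0)
    payload_label: str | None = None  # census label when it differs from the name

    @property
    def name(self) -> str:
        return compose_name(self.five_code, self.three_code, self.label)

    @property
    def census_label(self) -> str:
        return self.payload_label or self.label


@dataclasses.dataclass
class Receiver:
    """A destination plasmid of one parity, kit, and chain position."""

    kit: str
    parity: str
    position: int
    marker: str
    accept_left: str
    accept_right: str
    release_left: str
    release_right: str
    molecule: DnaMolecule

    @property
    def assembly_enzyme(self) -> Enzyme:
        return BSAI if self.parity == "odd" else SAPI

    @property
    def release_enzyme(self) -> Enzyme:
        return SAPI if self.parity == "odd" else BSAI


# Constrained position syntax, enforced as warnings only.  The paper's own
# library uses C-E for untagged CDSs (e.g. the sfGFP part), so both C-D and
# C-E are accepted silently for CDS parts.
_SYNTAX = {
    "promoter": {("A", "C"), ("A", "B")},
    "RBS": {("B", "C")},
    "tag": {("B", "C"), ("D", "E")},
    "CDS": {("C", "D"), ("C", "E")},
    "terminator": {("E", "F")},
}


def part_syntax_warnings(part: PartL0) -> list[str]:
    allowed = _SYNTAX.get(part.kind)
    if allowed is None:
        return []
    if (part.five_code, part.three_code) in allowed:
        return []
    return [
        f"part {part.name}: {part.kind} parts conventionally use "
        f"{sorted(allowed)}, not ({part.five_code}, {part.three_code})"
    ]


# ---------------------------------------------------------------------------
# Chain validation


def validate_part_chain(parts: list, accept_left: str, accept_right: str) -> list:
    """Order elements declaring (five_code, three_code) into the unique
    junction path accept_left -> ... -> accept_right.

    Input order is irrelevant; every junction code must be used exactly
    once.  A gap names the missing junction; two elements sharing a
    five_code name the collision.
    """
    by_five: dict[str, list] = {}
    for p in parts:
        by_five.setdefault(p.five_code, []).append(p)
    for code, ps in by_five.items():
        if len(ps) > 1:
            names = [getattr(p, "name", repr(p)) for p in ps]
            raise ChainAssemblyError(
                f"chain branch: parts {names} share five_code {code}"
            )
    chain = []
    current = accept_left
    used = set()
    while current != accept_right or len(used) < len(parts):
        nxt = by_five.get(current)
        if nxt is None:
            unplaced = sorted(p.five_code for p in parts if id(p) not in used)
            raise ChainAssemblyError(
                f"chain gap: no part starts at code {current}; unplaced parts "
                f"start at {unplaced or ['<none>']}"
            )
        part = nxt[0]
        if id(part) in used:
            raise ChainAssemblyError(
                f"chain loop detected at code {current}"
            )
        chain.append(part)
        used.add(id(part))
        current = part.three_code
    if current != accept_right:
        raise ChainAssemblyError(
            f"chain ends at code {current}, receiver closes at {accept_right}"
        )
    return chain


# ---------------------------------------------------------------------------
# Domestication

_SPACER = "A"
_TRANSITION = str.maketrans("ACGT", "GTAC")

_SYNONYMS: dict[str, list[str]] = {}


def _codon_synonyms() -> dict[str, list[str]]:
    if not _SYNONYMS:
        aa_of = dict(standard_dna_table.forward_table)
        for stop in standard_dna_table.stop_codons:
            aa_of[stop] = "*"
        by_aa: dict[str, list[str]] = {}
        for codon, aa in aa_of.items():
            by_aa.setdefault(aa, []).append(codon)
        for codon, aa in aa_of.items():
            _SYNONYMS[codon] = sorted(c for c in by_aa[aa] if c != codon)
    return _SYNONYMS


def _site_matches(seq: str, enzymes) -> list[tuple[int, int, int]]:
    """(start, end, strand) spans of recognition matches on both strands."""
    out = []
    for enz in enzymes:
        for pattern, strand in ((enz.recognition, 1), (reverse_complement(enz.recognition), -1)):
            i = seq.find(pattern)
            while i != -1:
                out.append((i, i + len(pattern), strand))
                i = seq.find(pattern, i + 1)
    return sorted(out)


def _synonymous_edit(seq, match, cds, synonyms):
    """One-substitution synonymous edit destroying the match, or None."""
    m_start, m_end, _ = match
    cds_start, cds_end = cds
    first = cds_start + ((max(m_start, cds_start) - cds_start) // 3) * 3
    for codon_start in range(first, min(m_end, cds_end), 3):
        codon = seq[codon_start : codon_start + 3]
        if len(codon) < 3:
            break
        for alt in synonyms.get(codon, []):
            diffs = [i for i in range(3) if codon[i] != alt[i]]
            if len(diffs) != 1:
                continue
            pos = codon_start + diffs[0]
            if not (m_start <= pos < m_end):
                continue
            return pos, alt[diffs[0]], codon
    return None


def domesticate(
    seq: str,
    cds_intervals: list[tuple[int, int]] = (),
    enzymes: tuple = (BSAI, SAPI),
    max_iterations: int = 10,
) -> tuple[str, list[dict]]:
    """Destroy every recognition site with one substitution per site.

    Inside a declared CDS interval the substitution is synonymous (the
    translation of every interval is unchanged); elsewhere the final
    recognition base is switched to its transition partner.  Edits are
    rescanned to a fixpoint because a substitution can in principle create
    a new site.
    """
    seq = seq.upper()
    synonyms = _codon_synonyms()
    edits: list[dict] = []
    for _ in range(max_iterations):
        matches = _site_matches(seq, enzymes)
        if not matches:
            return seq, edits
        edited_spans: list[tuple[int, int]] = []
        for match in matches:
            m_start, m_end, strand = match
            if any(m_start < e and s < m_end for s, e in edited_spans):
                continue  # an earlier edit this round may already kill it
            cds = next(
                (c for c in cds_intervals if m_start < c[1] and c[0] < m_end),
                None,
            )
            if cds is not None:
                hit = _synonymous_edit(seq, match, cds, synonyms)
                if hit is None:
                    codon_idx = (max(m_start, cds[0]) - cds[0]) // 3
                    codon_start = cds[0] + codon_idx * 3
                    raise DomesticationError(
                        "no single-substitution synonymous escape for codon "
                        f"{seq[codon_start:codon_start + 3]} at {codon_start}"
                    )
                pos, base, codon = hit
                reason = f"synonymous within codon {codon}"
            else:
                pos = m_end - 1 if strand == 1 else m_start
                base = seq[pos].translate(_TRANSITION)
                reason = "transition at terminal recognition base"
            edits.append(
                {
                    "position": pos,
                    "old": seq[pos],
                    "new": base,
                    "site": seq[m_start:m_end],
                    "strand": strand,
                    "reason": reason,
                }
            )
            seq = seq[:pos] + base + seq[pos + 1 :]
            edited_spans.append((m_start, m_end))
    if _site_matches(seq, enzymes):
        raise DomesticationError(
            f"domestication did not reach a fixpoint in {max_iterations} iterations"
        )
    return seq, edits


# ---------------------------------------------------------------------------
# Receiver and L0 entry construction


def _cassette_odd(table: OverhangTable, position: int, dropout_seq: str):
    chain = table.even_chain
    rl, rr = chain[position - 1], chain[position]
    left = (
        SAPI.recognition
        + _SPACER
        + table.even(rl)
        + table.odd("A")
        + _SPACER
        + reverse_complement(BSAI.recognition)
    )
    right = (
        BSAI.recognition
        + _SPACER
        + table.odd("F")
        + table.even(rr)
        + _SPACER
        + reverse_complement(SAPI.recognition)
    )
    return left, right, ("A", "F"), (rl, rr)


def _cassette_even(table: OverhangTable, position: int, dropout_seq: str):
    chain = table.odd_release_chain
    rl, rr = chain[position - 1], chain[position]
    left = (
        BSAI.recognition
        + _SPACER
        + table.odd(rl)
        + table.even("alpha")
        + _SPACER
        + reverse_complement(SAPI.recognition)
    )
    right = (
        SAPI.recognition
        + _SPACER
        + table.even("omega")
        + table.odd(rr)
        + _SPACER
        + reverse_complement(BSAI.recognition)
    )
    return left, right, ("alpha", "omega"), (rl, rr)


def build_receiver(
    kit: str,
    parity: str,
    position: int,
    backbone: DnaMolecule,
    table: OverhangTable,
    dropout_seq: str = "",
    name: str | None = None,
) -> Receiver:
    """Insert the grammar cassette and parity marker into a clean backbone.

    The cassette reads
    ``UNS1 [release site, inward] [accept-left code] [assembly site, inward
    from the dropout side] lacZ-dropout [assembly site] [accept-right code]
    [release site] UNSX`` so that digestion with the assembly enzyme drops
    the recognition-carrying stuffer and exposes the accept codes, while
    the release enzyme excises the finished composite flanked by the
    position's release codes.
    """
    if kit not in KITS:
        raise ValueError(f"unknown kit {kit!r}")
    if parity not in ("odd", "even"):
        raise ValueError("parity must be 'odd' or 'even'")
    if not 1 <= position <= 4:
        raise ValueError("position must be 1..4")
    for enz in (BSAI, SAPI):
        hits = scan_sites(backbone, enz)
        if hits:
            raise ValueError(
                f"backbone {backbone.id!r} carries {enz.name} sites at "
                f"{[h.recognition_start for h in hits]}; domesticate first"
            )
    if not dropout_seq:
        dropout_seq = "ATGACCATGATTACGGATTCACTGGCCGTCGTTTTACAACGTCGTGACTGG"
    builder = _cassette_odd if parity == "odd" else _cassette_even
    left, right, accept, release = builder(table, position, dropout_seq)

    marker = MARKERS[(kit, parity)]
    name = name or f"{kit}{parity[0]}-{position}"

    segments = [
        ("UNS", "UNS1", table.uns1),
        (None, None, left),
        ("dropout", "lacZ", dropout_seq),
        (None, None, right),
        ("UNS", "UNSX", table.unsx),
        (None, None, backbone.sequence),
    ]
    seq_parts: list[str] = []
    features: list[Feature] = []
    offset = 0
    for kind, label, segment in segments:
        if kind is not None:
            features.append(Feature(kind, label, offset, offset + len(segment)))
        seq_parts.append(segment)
        offset += len(segment)
    backbone_offset = offset - len(backbone.sequence)
    features.extend(f.shifted(backbone_offset) for f in backbone.features)
    marker_start = backbone_offset + min(100, len(backbone.sequence) // 4)
    features.append(Feature("marker", marker, marker_start, marker_start + 60))

    mol = DnaMolecule(
        id=name,
        sequence="".join(seq_parts),
        topology="circular",
        features=features,
        provenance=f"{kit} {parity} receiver, position {position}",
    )
    for enz in (BSAI, SAPI):
        n = len(scan_sites(mol, enz))
        if n != 2:
            raise ValueError(
                f"receiver {name}: expected exactly 2 {enz.name} sites, found {n} "
                "(dropout or code sequence recreates a site)"
            )
    return Receiver(
        kit=kit,
        parity=parity,
        position=position,
        marker=marker,
        accept_left=accept[0],
        accept_right=accept[1],
        release_left=release[0],
        release_right=release[1],
        molecule=mol,
    )


def build_entry_vector(backbone: DnaMolecule, table: OverhangTable, name: str = "pL0R-lacZ") -> DnaMolecule:
    """Entry vector whose lacZ dropout is excised by SapI, exposing the
    fixed entry overhangs."""
    for enz in (BSAI, SAPI):
        if scan_sites(backbone, enz):
            raise ValueError(f"entry backbone carries {enz.name} sites")
    tau_l, tau_r = table.entry_overhangs
    dropout = "ATGACCATGATTACGGATTCACTGGCCGTCGTTTTACAACGTCGTGACTGG"
    cassette_left = tau_l + _SPACER + reverse_complement(SAPI.recognition)
    cassette_right = SAPI.recognition + _SPACER + tau_r
    seq = (
        table.uns1
        + cassette_left
        + dropout
        + cassette_right
        + table.unsx
        + backbone.sequence
    )
    d_start = len(table.uns1) + len(cassette_left)
    features = [
        Feature("UNS", "UNS1", 0, len(table.uns1)),
        Feature("dropout", "lacZ", d_start, d_start + len(dropout)),
        Feature(
            "UNS",
            "UNSX",
            d_start + len(dropout) + len(cassette_right),
            d_start + len(dropout) + len(cassette_right) + len(table.unsx),
        ),
    ]
    mol = DnaMolecule(
        id=name,
        sequence=seq,
        topology="circular",
        features=features,
        provenance="SapI entry vector",
    )
    if len(scan_sites(mol, SAPI)) != 2 or scan_sites(mol, BSAI):
        raise ValueError("entry vector cassette failed site audit")
    return mol


def _check_d_rule(insert: str, kind: str, table: OverhangTable) -> None:
    """A CDS closed by the D code must have lost its stop and end in-frame
    so that the junction's GC dinucleotide completes Ala and opens Gly."""
    if kind != "CDS":
        return
    body = "ATG" + insert  # the C code supplies the start codon
    if len(body) % 3 != 2 or not body.endswith("GC"):
        raise ValueError(
            "CDS part with three_code D must end in-frame on GC "
            "(stop removed; junction completes Ala-Gly)"
        )
    protein = translate_cds(body[:-2])
    if "*" in protein:
        raise ValueError("CDS part with three_code D must carry no stop codon")


def build_l0_entry(
    insert: str,
    five_code: str,
    three_code: str,
    entry_vector: DnaMolecule,
    table: OverhangTable,
    label: str,
    kind: str = "other",
    payload_feature: Feature | None = None,
) -> PartL0:
    """Simulate SapI-mediated entry of a domesticated insert.

    The resulting plasmid releases the insert with the declared
    odd-alphabet codes when cut with BsaI and carries no SapI site.
    """
    insert = insert.upper()
    probe = DnaMolecule(id="_insert", sequence=insert, topology="linear")
    sites = [
        (enz.name, h.recognition_start)
        for enz in (BSAI, SAPI)
        for h in scan_sites(probe, enz)
    ]
    if sites:
        raise DomesticationError(
            f"insert for {label!r} is not domesticated; internal sites at {sites}"
        )
    if three_code == "D":
        _check_d_rule(insert, kind, table)

    tau_l, tau_r = table.entry_overhangs
    backbone_frag = next(
        f
        for f in digest(entry_vector, SAPI)
        if SAPI.recognition not in f.footprint
        and reverse_complement(SAPI.recognition) not in f.footprint
    )
    donor_core = (
        tau_l
        + BSAI.recognition
        + _SPACER
        + table.odd(five_code)
        + insert
        + table.odd(three_code)
        + _SPACER
        + reverse_complement(BSAI.recognition)
    )
    # Ligate donor after the backbone fragment; junction overhangs must agree.
    if backbone_frag.right_overhang != tau_l or backbone_frag.left_overhang != tau_r:
        raise ValueError("entry vector overhangs do not match the configured pair")
    seq = backbone_frag.core + donor_core
    name = compose_name(five_code, three_code, label)
    insert_start = len(backbone_frag.core) + len(tau_l) + len(BSAI.recognition) + 1 + len(
        table.odd(five_code)
    )
    features = [f.shifted(0) for f in backbone_frag.features]
    if payload_feature is not None:
        features.append(payload_feature.shifted(insert_start))
    mol = DnaMolecule(
        id=name,
        sequence=seq,
        topology="circular",
        features=features,
        provenance=f"L0 entry of {label}",
    )
    if scan_sites(mol, SAPI):
        raise ValueError("L0 entry left SapI sites behind")
    if len(scan_sites(mol, BSAI)) != 2:
        raise ValueError("L0 plasmid must carry exactly the two release BsaI sites")
    return PartL0(
        molecule=mol,
        five_code=five_code,
        three_code=three_code,
        label=label,
        kind=kind,
        insert_span=(insert_start, insert_start + len(insert)),
    )
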