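"""Enzyme-agnostic Type IIS digestion and sticky-end ligation engine.

The engine models the end state of a thermocycled one-pot digestion-ligation
(Golden Gate) reaction rather than its kinetics: fragments that still carry
an intact recognition site of the reaction enzyme are treated as recuttable
and therefore unstable, and only recognition-site-free circular products are
reported as stable end products.

Overhang convention: every sticky end is a 5' single-stranded extension.
Both ends of a fragment are expressed as *top-strand* sequence, so two
fragments ligate X->Y exactly when ``X.right_overhang == Y.left_overhang``.
A fragment's ``core`` includes its left overhang bases and excludes its
right overhang bases; the sum of core lengths over a circular digest
therefore equals the parent length exactly.
"""

from __future__ import annotations

import dataclasses
from collections import Counter

from .seqio import (
    DnaMolecule,
    Feature,
    canonical_rotation,
    reverse_complement,
)

__all__ = [
    "Enzyme",
    "BSAI",
    "SAPI",
    "SiteHit",
    "StickyFragment",
    "LigationProduct",
    "AssemblyReport",
    "scan_sites",
    "digest",
    "cut_junctions",
    "enumerate_ligations",
    "one_pot_assemble",
    "fidelity_check",
    "UncutCircularError",
    "ChainAssemblyError",
    "LigationExplosionError",
]


class UncutCircularError(ValueError):
    """Circular molecule with no recognition site for the digestion enzyme."""


class ChainAssemblyError(ValueError):
    """The overhang path from receiver left code to right code is broken."""


class LigationExplosionError(RuntimeError):
    """Ligation enumeration exceeded the configured candidate cap."""


@dataclasses.dataclass(frozen=True)
class Enzyme:
    """A Type IIS enzyme leaving 5' overhangs downstream of its site.

    ``spacer`` is the number of nucleotides between the 3' end of the
    recognition sequence and the top-strand cut; the bottom-strand cut lies
    ``overhang_len`` further downstream.
    """

    name: str
    recognition: str
    spacer: int
    overhang_len: int

    def __post_init__(self) -> None:
        if self.recognition == reverse_complement(self.recognition):
            raise ValueError("recognition sequence must be non-palindromic")


BSAI = Enzyme("BsaI", "GGTCTC", spacer=1, overhang_len=4)
SAPI = Enzyme("SapI", "GCTCTTC", spacer=1, overhang_len=3)


@dataclasses.dataclass(frozen=True)
class SiteHit:
    """One recognition-site occurrence with its derived cut positions.

    ``cut_top``/``cut_bottom`` are top-strand coordinates of the top- and
    bottom-strand cuts; for a 5' overhang-generating enzyme
    ``cut_bottom - cut_top == overhang_len`` on either strand (positions
    wrap modulo the length on circular molecules).
    """

    enzyme: Enzyme
    strand: int
    recognition_start: int
    cut_top: int
    cut_bottom: int


def _find_all(haystack: str, needle: str) -> list[int]:
    out = []
    i = haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def scan_sites(mol: DnaMolecule, enzyme: Enzyme) -> list[SiteHit]:
    """All recognition occurrences on both strands, wrap-aware on circles.

    Any ``N`` in the molecule is a non-match by construction (the shipped
    recognition sequences contain no ambiguity codes).  On linear molecules
    sites whose cuts would fall outside the molecule are dropped.
    """
    seq = mol.sequence
    L = len(seq)
    rec = enzyme.recognition
    rec_rc = reverse_complement(rec)
    reach = len(rec) + enzyme.spacer + enzyme.overhang_len
    circular = mol.topology == "circular"
    search = seq + seq[: reach - 1] if circular else seq

    hits: list[SiteHit] = []
    for start in _find_all(search, rec):
        if start >= L:
            continue
        ct = start + len(rec) + enzyme.spacer
        cb = ct + enzyme.overhang_len
        if not circular and cb > L:
            continue
        if circular:
            ct, cb = ct % L, ct % L + enzyme.overhang_len
        hits.append(SiteHit(enzyme, 1, start, ct, cb))
    for start in _find_all(search, rec_rc):
        if start >= L:
            continue
        ct = start - enzyme.spacer - enzyme.overhang_len
        cb = start - enzyme.spacer
        if not circular and ct < 0:
            continue
        if circular:
            ct, cb = ct % L, ct % L + enzyme.overhang_len
        hits.append(SiteHit(enzyme, -1, start, ct, cb))
    hits.sort(key=lambda h: (h.recognition_start, -h.strand))
    return hits


@dataclasses.dataclass
class StickyFragment:
    """Double-stranded fragment with 5' overhangs at each end.

    ``core`` is the top strand from this fragment's left top-strand cut to
    the next fragment's left top-strand cut (includes the left overhang,
    excludes the right).  ``footprint`` (= core + right_overhang) is the
    full top-strand reading of the duplex region the fragment occupies.
    Blunt ends (linear molecule termini) have empty overhangs.
    Features are re-based to footprint coordinates.
    """

    core: str
    left_overhang: str
    right_overhang: str
    parent_id: str
    source_span: tuple = (0, 0)
    features: list = dataclasses.field(default_factory=list)
    frag_id: str = ""

    @property
    def footprint(self) -> str:
        return self.core + self.right_overhang

    def __len__(self) -> int:
        return len(self.core)

    def flipped(self) -> "StickyFragment":
        """The same physical fragment read from the other strand."""
        fp = reverse_complement(self.footprint)
        n = len(self.footprint)
        new_ro = reverse_complement(self.left_overhang)
        feats = [
            dataclasses.replace(
                f, start=n - f.end, end=n - f.start, strand=-f.strand
            )
            for f in reversed(self.features)
        ]
        return StickyFragment(
            core=fp[: len(fp) - len(new_ro)] if new_ro else fp,
            left_overhang=reverse_complement(self.right_overhang),
            right_overhang=new_ro,
            parent_id=self.parent_id,
            source_span=self.source_span,
            features=feats,
            frag_id=self.frag_id + "'",
        )


def cut_junctions(mol: DnaMolecule, enzymes) -> list[tuple[int, str]]:
    """Deduplicated, sorted (cut_top, overhang_seq) pairs for all enzymes."""
    if isinstance(enzymes, Enzyme):
        enzymes = [enzymes]
    junctions: dict[int, str] = {}
    for enz in enzymes:
        for hit in scan_sites(mol, enz):
            ov = mol.region(hit.cut_top, hit.cut_bottom)
            junctions.setdefault(hit.cut_top, ov)
    return sorted(junctions.items())


def _features_in(mol: DnaMolecule, start: int, span_len: int) -> list[Feature]:
    """Features wholly contained in the wrap-aware window [start, start+span_len)."""
    L = len(mol.sequence)
    out = []
    for f in mol.features:
        if f.length > span_len:
            continue
        rel = (f.start - start) % L if mol.topology == "circular" else f.start - start
        if 0 <= rel and rel + f.length <= span_len:
            out.append(dataclasses.replace(f, start=rel, end=rel + f.length))
    return out


def digest(mol: DnaMolecule, enzymes) -> list[StickyFragment]:
    """Cut a molecule with one or several Type IIS enzymes.

    Returns fragments between successive top-strand cuts.  An uncut
    circular molecule raises :class:`UncutCircularError`; an uncut linear
    molecule returns itself as a single blunt-ended fragment.
    """
    junctions = cut_junctions(mol, enzymes)
    L = len(mol.sequence)
    frags: list[StickyFragment] = []
    if mol.topology == "circular":
        if not junctions:
            raise UncutCircularError(
                f"uncut circular: no recognition site in {mol.id!r}"
            )
        n = len(junctions)
        for i, (ct, ov) in enumerate(junctions):
            nct, nov = junctions[(i + 1) % n]
            span = (nct - ct) % L or L
            footprint_len = span + len(nov)
            frags.append(
                StickyFragment(
                    core=mol.region(ct, ct + span),
                    left_overhang=ov,
                    right_overhang=nov,
                    parent_id=mol.id,
                    source_span=(ct, ct + footprint_len),
                    features=_features_in(mol, ct, footprint_len),
                    frag_id=f"{mol.id}/{i}",
                )
            )
    else:
        if not junctions:
            return [
                StickyFragment(
                    core=mol.sequence,
                    left_overhang="",
                    right_overhang="",
                    parent_id=mol.id,
                    source_span=(0, L),
                    features=list(mol.features),
                    frag_id=f"{mol.id}/0",
                )
            ]
        bounds = [(0, "")] + junctions + [(L, "")]
        for i in range(len(bounds) - 1):
            ct, ov = bounds[i]
            nct, nov = bounds[i + 1]
            footprint_len = nct - ct + len(nov)
            frags.append(
                StickyFragment(
                    core=mol.sequence[ct:nct],
                    left_overhang=ov,
                    right_overhang=nov,
                    parent_id=mol.id,
                    source_span=(ct, ct + footprint_len),
                    features=_features_in(mol, ct, footprint_len),
                    frag_id=f"{mol.id}/{i}",
                )
            )
    return frags


def fragment_has_site(frag: StickyFragment, enzyme: Enzyme) -> bool:
    """True if the fragment's duplex region carries an intact recognition site."""
    fp = frag.footprint
    return enzyme.recognition in fp or reverse_complement(enzyme.recognition) in fp


@dataclasses.dataclass
class LigationProduct:
    """A distinct circular or linear ligation outcome."""

    topology: str
    parts: list  # list of (StickyFragment, orientation) in chain order
    junctions: list  # overhang sequences at successive joints
    sequence: str  # canonical form (rotation/reflection-invariant)
    length: int

    @property
    def fragment_ids(self) -> list[str]:
        return [f.frag_id.rstrip("'") for f, _ in self.parts]


def _chain_sequences(chain: list[StickyFragment], circular: bool) -> tuple[str, int]:
    if circular:
        seq = "".join(f.core for f in chain)
        return canonical_rotation(seq), len(seq)
    fp = "".join(f.core for f in chain) + chain[-1].right_overhang
    return min(fp, reverse_complement(fp)), len(fp)


def enumerate_ligations(
    pool: list[StickyFragment],
    mode: str = "circular_only",
    max_copies: int = 1,
    cap: int = 100_000,
) -> list[LigationProduct]:
    """Every distinct ligation product reachable from the fragment pool.

    Products are deduplicated up to rotation and reflection (circular) or
    reversal (linear) via canonical sequences, and returned sorted by
    (length, canonical sequence).  Blunt-blunt joining is excluded: a
    junction requires identical non-empty top-strand overhangs.  If the
    search expands more than ``cap`` chain states a
    :class:`LigationExplosionError` is raised with a diagnostic of the
    duplicated overhangs driving the blow-up.
    """
    if not pool:
        raise ValueError("empty fragment pool")
    if max_copies < 1:
        raise ValueError("max_copies must be >= 1")
    if mode not in ("circular_only", "include_linear"):
        raise ValueError(f"unknown mode {mode!r}")

    oriented = [(i, frag, frag.flipped()) for i, frag in enumerate(pool)]
    products: dict[tuple[str, str], LigationProduct] = {}
    counts = [0] * len(pool)
    chain: list[tuple[int, StickyFragment, int]] = []
    expansions = 0

    def duplicated_overhangs() -> list[str]:
        ends = Counter()
        for f in pool:
            for ov in (f.left_overhang, f.right_overhang):
                if ov:
                    ends[ov] += 1
        return sorted(ov for ov, n in ends.items() if n > 2)

    def record(circular: bool) -> None:
        frags = [f for _, f, _ in chain]
        seq, length = _chain_sequences(frags, circular)
        key = ("circular" if circular else "linear", seq)
        if key in products:
            return
        products[key] = LigationProduct(
            topology="circular" if circular else "linear",
            parts=[(f, o) for _, f, o in chain],
            junctions=[f.right_overhang for f in frags[:-1]]
            + ([frags[-1].right_overhang] if circular else []),
            sequence=seq,
            length=length,
        )

    def extend() -> None:
        nonlocal expansions
        if mode == "include_linear":
            record(circular=False)
        first = chain[0][1]
        last = chain[-1][1]
        if first.left_overhang and last.right_overhang == first.left_overhang:
            record(circular=True)
        for i, fwd, rev in oriented:
            if counts[i] >= max_copies:
                continue
            for orient, frag in ((1, fwd), (-1, rev)):
                if not frag.left_overhang or frag.left_overhang != last.right_overhang:
                    continue
                expansions += 1
                if expansions > cap:
                    raise LigationExplosionError(
                        "ligation enumeration exceeded cap "
                        f"({cap}); overhangs present on >2 fragment ends: "
                        f"{duplicated_overhangs()}"
                    )
                counts[i] += 1
                chain.append((i, frag, orient))
                extend()
                chain.pop()
                counts[i] -= 1

    for i, fwd, rev in oriented:
        for orient, frag in ((1, fwd), (-1, rev)):
            counts[i] += 1
            chain.append((i, frag, orient))
            extend()
            chain.pop()
            counts[i] -= 1

    return sorted(products.values(), key=lambda p: (p.length, p.sequence))


def fidelity_check(overhangs: list[str]) -> dict:
    """Flag duplicate, self-complementary, and mutually complementary overhangs."""
    lens = {len(o) for o in overhangs}
    if len(lens) > 1:
        raise ValueError(f"overhangs must share a length, got lengths {sorted(lens)}")
    dup = sorted(ov for ov, n in Counter(overhangs).items() if n > 1)
    pal = sorted({ov for ov in overhangs if ov == reverse_complement(ov)})
    seen = set(overhangs)
    collisions = sorted(
        {
            tuple(sorted((ov, reverse_complement(ov))))
            for ov in overhangs
            if ov != reverse_complement(ov) and reverse_complement(ov) in seen
        }
    )
    return {
        "duplicates": dup,
        "palindromes": pal,
        "complement_collisions": [list(c) for c in collisions],
        "clean": not (dup or pal or collisions),
    }


@dataclasses.dataclass
class AssemblyReport:
    """Classified outcome of a one-pot Golden Gate reaction."""

    enzyme: Enzyme
    intended: DnaMolecule | None
    chain: list  # ordered fragment ids backbone-first
    junction_overhangs: list
    misassemblies: list  # LigationProducts other than the intended one
    parental: list  # input plasmid ids whose re-ligation restores the input
    cargo_span: tuple = (0, 0)

    @property
    def n_intended(self) -> int:
        return 0 if self.intended is None else 1


def _overhang_name(ov: str, code_names: dict | None) -> str:
    if code_names and ov in code_names:
        return f"{code_names[ov]} ({ov})"
    return ov


def one_pot_assemble(
    receiver: DnaMolecule,
    inserts: list[DnaMolecule],
    enzyme: Enzyme,
    code_names: dict | None = None,
    max_copies: int = 2,
    enumerate_misassemblies: bool = True,
) -> AssemblyReport:
    """Simulate a one-pot digestion-ligation into a receiver plasmid.

    All inputs are digested; fragments still carrying a recognition site of
    the reaction enzyme (the receiver dropout and the insert donor
    backbones) are recuttable and excluded from stable products.  The
    intended product is the unique circular chain
    ``backbone -> insert_1 -> ... -> insert_n -> backbone``; a gap,
    duplication, or ambiguity in that overhang path raises
    :class:`ChainAssemblyError`.  ``code_names`` optionally maps overhang
    sequences to grammar code letters for readable diagnostics.
    """
    for mol in [receiver] + inserts:
        if mol.topology != "circular":
            raise ValueError(f"one-pot input {mol.id!r} must be circular")
    ids = [m.id for m in [receiver] + inserts]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate input ids in one-pot reaction")

    stable: list[StickyFragment] = []
    backbone: StickyFragment | None = None
    for mol in [receiver] + inserts:
        mol_stable = [
            f for f in digest(mol, enzyme) if not fragment_has_site(f, enzyme)
        ]
        if not mol_stable:
            raise ChainAssemblyError(
                f"input {mol.id!r} yields no stable (recognition-free) fragment"
            )
        if mol is receiver:
            if len(mol_stable) != 1:
                raise ChainAssemblyError(
                    f"receiver {mol.id!r} yields {len(mol_stable)} stable "
                    "fragments; expected exactly one backbone"
                )
            backbone = mol_stable[0]
        stable.extend(mol_stable)

    assert backbone is not None
    insert_frags = [f for f in stable if f is not backbone]

    # Walk the overhang path from the backbone's exposed right code to its
    # exposed left code, consuming every insert fragment exactly once.
    chain: list[StickyFragment] = []
    remaining = list(insert_frags)
    current = backbone.right_overhang
    while True:
        matches = []
        for f in remaining:
            if f.left_overhang == current:
                matches.append(f)
            elif f.flipped().left_overhang == current:
                matches.append(f.flipped())
        if len(matches) > 1:
            raise ChainAssemblyError(
                "chain branch: multiple fragments start at overhang "
                f"{_overhang_name(current, code_names)}: "
                f"{[m.frag_id for m in matches]}"
            )
        if not matches:
            if current == backbone.left_overhang and not remaining:
                break
            starts = sorted(
                {
                    _overhang_name(f.left_overhang, code_names)
                    for f in remaining
                }
            )
            raise ChainAssemblyError(
                "chain gap: no fragment starts at overhang "
                f"{_overhang_name(current, code_names)}; unplaced fragments "
                f"start at {starts or ['<none>']} and the backbone closes at "
                f"{_overhang_name(backbone.left_overhang, code_names)}"
            )
        frag = matches[0]
        chain.append(frag)
        remaining = [
            f for f in remaining if f.frag_id != frag.frag_id.rstrip("'")
        ]
        current = frag.right_overhang
        if current == backbone.left_overhang and not remaining:
            break

    # Stitch the intended product, backbone core first.
    ordered = [backbone] + chain
    seq = "".join(f.core for f in ordered)
    features = []
    offset = 0
    for f in ordered:
        features.extend(feat.shifted(offset) for feat in f.features)
        offset += len(f.core)
    product = DnaMolecule(
        id=f"{receiver.id}+{'+'.join(m.id for m in inserts)}",
        sequence=seq,
        topology="circular",
        features=features,
        provenance=f"one-pot {enzyme.name} assembly into {receiver.id}",
    )
    if scan_sites(product, enzyme):
        raise AssertionError(
            "intended product unexpectedly retains recognition sites "
            f"of {enzyme.name}"
        )

    misassemblies: list[LigationProduct] = []
    if enumerate_misassemblies:
        intended_canonical = canonical_rotation(product)
        for prod in enumerate_ligations(
            stable, mode="circular_only", max_copies=max_copies
        ):
            if prod.sequence != intended_canonical:
                misassemblies.append(prod)

    return AssemblyReport(
        enzyme=enzyme,
        intended=product,
        chain=[backbone.frag_id] + [f.frag_id for f in chain],
        junction_overhangs=[backbone.right_overhang]
        + [f.right_overhang for f in chain],
        misassemblies=misassemblies,
        parental=[m.id for m in [receiver] + inserts],
        cargo_span=(len(backbone.core), len(seq)),
    )
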