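"""In-silico verification readouts and bench metric calculators.

Digest profiles are compared in base pairs against a user tolerance
(default 100 bp); gel mobility is not modeled.  PCR matching is exact by
default because the verification primers are exact by design.
"""

from __future__ import annotations

import dataclasses
from itertools import permutations

from .seqio import DnaMolecule, reverse_complement
from .typeiis import StickyFragment, cut_junctions, enumerate_ligations

__all__ = [
    "DigestProfile",
    "ProfileMatch",
    "Amplicon",
    "digest_profile",
    "compare_profile",
    "insilico_pcr",
    "efficiency_metrics",
    "concatemer_ladder",
]

DEFAULT_TOLERANCE_BP = 100


@dataclasses.dataclass
class DigestProfile:
    source_id: str
    enzymes: list
    lengths: list  # bp, sorted descending
    uncut: bool = False


def digest_profile(mol: DnaMolecule, enzymes) -> DigestProfile:
    """Band lengths of a combined digestion, sorted descending.

    For circular sources the bands sum exactly to the molecule length; an
    uncut circular molecule reports a single full-length band flagged
    ``uncut``.
    """
    junctions = cut_junctions(mol, enzymes)
    names = [e.name for e in (enzymes if isinstance(enzymes, list) else [enzymes])]
    L = len(mol.sequence)
    if mol.topology == "circular":
        if not junctions:
            return DigestProfile(mol.id, names, [L], uncut=True)
        cuts = [ct for ct, _ in junctions]
        lengths = [
            (cuts[(i + 1) % len(cuts)] - cuts[i]) % L or L for i in range(len(cuts))
        ]
    else:
        cuts = [0] + [ct for ct, _ in junctions] + [L]
        lengths = [cuts[i + 1] - cuts[i] for i in range(len(cuts) - 1)]
        lengths = [x for x in lengths if x > 0]
    return DigestProfile(mol.id, names, sorted(lengths, reverse=True))


@dataclasses.dataclass
class ProfileMatch:
    observed: list
    expected: list
    tolerance_bp: int
    verdict: bool
    pairing: list  # (observed, expected) pairs when the verdict is true


def compare_profile(observed, expected, tolerance_bp: int = DEFAULT_TOLERANCE_BP) -> ProfileMatch:
    """One-to-one band matching within a symmetric tolerance.

    The verdict is true iff a perfect pairing exists with every
    ``|obs - exp| <= tolerance``; for sorted lists of equal-tolerance bands
    the sorted pairing is optimal, and an exhaustive search confirms it for
    up to 12 bands.
    """
    if tolerance_bp < 0:
        raise ValueError("tolerance must be >= 0")
    obs = sorted(observed)
    exp = sorted(expected)
    if len(obs) != len(exp):
        return ProfileMatch(obs, exp, tolerance_bp, False, [])
    ok = all(abs(o - e) <= tolerance_bp for o, e in zip(obs, exp))
    if not ok and len(obs) <= 12:
        for perm in permutations(exp):
            if all(abs(o - e) <= tolerance_bp for o, e in zip(obs, perm)):
                ok = True
                exp = list(perm)
                break
    pairing = list(zip(obs, exp)) if ok else []
    return ProfileMatch(obs, sorted(exp), tolerance_bp, ok, pairing)


@dataclasses.dataclass
class Amplicon:
    sequence: str
    start: int
    end: int
    length: int


def insilico_pcr(
    mol: DnaMolecule,
    fwd: str,
    rev: str,
    max_mismatches: int = 0,
) -> dict:
    """Exact-match PCR: amplicons from a + strand forward primer site to a
    - strand reverse primer site, wrap-aware on circular templates.

    Returns ``{"amplicons": [...], "ambiguous": bool}``; more than one
    binding site for either primer flags the result ambiguous.
    """
    fwd = fwd.upper()
    rev = rev.upper()
    if len(fwd) < 12 or len(rev) < 12:
        raise ValueError("primers must be >= 12 nt")
    if max_mismatches != 0:
        raise NotImplementedError("only exact primer matching is supported")
    seq = mol.sequence
    L = len(seq)
    circular = mol.topology == "circular"
    search = seq + seq[: max(len(fwd), len(rev)) - 1] if circular else seq
    rev_rc = reverse_complement(rev)

    def binding_sites(primer: str) -> list[int]:
        out = []
        i = search.find(primer)
        while i != -1:
            if i < L:
                out.append(i)
            i = search.find(primer, i + 1)
        return out

    fwd_sites = binding_sites(fwd)
    rev_sites = binding_sites(rev_rc)  # site start of the rev primer's template
    amplicons = []
    for fs in fwd_sites:
        for rs in rev_sites:
            end = rs + len(rev)
            if circular:
                length = (end - fs) % L or L
                amplicons.append(Amplicon(mol.region(fs, fs + length), fs, fs + length, length))
            elif end > fs:
                amplicons.append(Amplicon(seq[fs:end], fs, end, end - fs))
    amplicons.sort(key=lambda a: (a.start, a.length))
    return {
        "amplicons": amplicons,
        "ambiguous": len(fwd_sites) > 1 or len(rev_sites) > 1,
    }


def efficiency_metrics(counts: dict, plated_fraction_factor: int = 30) -> dict:
    """Colony-count calculators for assembly efficiency and productivity.

    Efficiency is the percentage of fluorescent colonies among all colonies
    not expressing the dropout marker (blue colonies are excluded from both
    metrics); productivity scales the non-blue colony count by the plated
    fraction factor (default 30: 10 ul plated of a 300 ul recovery).
    """
    sfgfp = counts.get("sfgfp", 0)
    white = counts.get("white_nonfluorescent", 0)
    blue = counts.get("blue", 0)
    if min(sfgfp, white, blue) < 0:
        raise ValueError("colony counts must be >= 0")
    denominator = sfgfp + white
    efficiency = 100.0 * sfgfp / denominator if denominator else None
    return {
        "efficiency_percent": efficiency,
        "productivity": denominator * plated_fraction_factor,
        "excluded_blue": blue,
    }


def concatemer_ladder(pool: list) -> dict:
    """Lengths of every contiguous sub-chain of a linear chain grammar.

    Returns ``{n: [lengths...]}`` for n = 1..len(pool) plus the full-length
    chain under ``"full_length"``.  The pool must order into a single
    linear chain (checked via the ligation enumerator).
    """
    if not pool:
        raise ValueError("empty pool")
    products = enumerate_ligations(pool, mode="include_linear", max_copies=1)
    linear = [p for p in products if p.topology == "linear"]
    by_n: dict[int, list] = {}
    for p in linear:
        by_n.setdefault(len(p.parts), []).append(p.length)
    expected_counts = {n: len(pool) - n + 1 for n in range(1, len(pool) + 1)}
    for n, count in expected_counts.items():
        if len(by_n.get(n, [])) != count:
            raise ValueError(
                f"pool is not a simple chain: {len(by_n.get(n, []))} distinct "
                f"{n}-mers, expected {count}"
            )
    full = max(by_n[len(pool)])
    return {
        "ladder": {n: sorted(v) for n, v in sorted(by_n.items())},
        "full_length": full,
    }
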