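from itertools import product as iproduct

import pytest

from loopasm.seqio import DnaMolecule, reverse_complement
from loopasm.typeiis import (
    BSAI,
    SAPI,
    ChainAssemblyError,
    Enzyme,
    LigationExplosionError,
    StickyFragment,
    UncutCircularError,
    digest,
    enumerate_ligations,
    fidelity_check,
    one_pot_assemble,
    scan_sites,
)

# ---------------------------------------------------------------------------
# Oracles


def brute_force_site_starts(seq: str, recognition: str, circular: bool):
    """Independent site finder: substring search on seq and its revcomp."""
    search = seq + seq[: len(recognition) - 1] if circular else seq
    fwd = [
        i
        for i in range(len(seq))
        if search[i : i + len(recognition)] == recognition
    ]
    rc = reverse_complement(recognition)
    rev = [i for i in range(len(seq)) if search[i : i + len(rc)] == rc]
    return sorted(fwd), sorted(rev)


def _canon_circular(seq: str) -> str:
    cands = []
    for s in (seq, reverse_complement(seq)):
        cands.extend(s[i:] + s[:i] for i in range(len(s)))
    return min(cands)


def brute_force_ligations(pool, mode, max_copies):
    """Exhaustive enumeration over all orderings x orientations."""
    n = len(pool)
    results = set()
    for r in range(1, n * max_copies + 1):
        for idxs in iproduct(range(n), repeat=r):
            if any(idxs.count(i) > max_copies for i in set(idxs)):
                continue
            for orients in iproduct((1, -1), repeat=r):
                frags = [
                    pool[i] if o == 1 else pool[i].flipped()
                    for i, o in zip(idxs, orients)
                ]
                if any(
                    not frags[k].right_overhang
                    or frags[k].right_overhang != frags[k + 1].left_overhang
                    for k in range(r - 1)
                ):
                    continue
                if mode == "include_linear":
                    footprint = "".join(f.core for f in frags) + frags[-1].right_overhang
                    results.add(
                        ("linear", min(footprint, reverse_complement(footprint)))
                    )
                if (
                    frags[0].left_overhang
                    and frags[-1].right_overhang == frags[0].left_overhang
                ):
                    circle = "".join(f.core for f in frags)
                    results.add(("circular", _canon_circular(circle)))
    return results


def frag(core, lo, ro, fid="f"):
    return StickyFragment(
        core=core, left_overhang=lo, right_overhang=ro, parent_id=fid, frag_id=fid
    )


# ---------------------------------------------------------------------------
# Site scanning


class TestScanSites:
    def test_single_plus_site_geometry(self):
        # BsaI: cut_top = recognition_end + spacer, overhang 4
        mol = DnaMolecule(id="m", sequence="AAAGGTCTCATTTTCCCCGGGG")
        hits = scan_sites(mol, BSAI)
        assert len(hits) == 1
        (hit,) = hits
        assert hit.strand == 1
        assert hit.recognition_start == 3
        assert hit.cut_top == 3 + 6 + 1
        assert hit.cut_bottom == hit.cut_top + 4

    def test_no_sites(self):
        mol = DnaMolecule(id="m", sequence="ACATACATACATACAT")
        assert scan_sites(mol, BSAI) == []
        assert scan_sites(mol, SAPI) == []

    def test_convergent_sites_vs_brute_force(self, library):
        receiver = library.receiver("pCA", "odd", 1).molecule
        hits = scan_sites(receiver, BSAI)
        assert len(hits) == 2
        assert sorted(h.strand for h in hits) == [-1, 1]
        fwd, rev = brute_force_site_starts(receiver.sequence, BSAI.recognition, True)
        assert sorted(h.recognition_start for h in hits if h.strand == 1) == fwd
        assert sorted(h.recognition_start for h in hits if h.strand == -1) == rev

    def test_wraparound_match_on_circle(self):
        seq = "TCTCA" + "T" * 40 + "GG"  # GGTCTC spans the origin
        mol = DnaMolecule(id="m", sequence=seq, topology="circular")
        hits = scan_sites(mol, BSAI)
        assert len(hits) == 1
        assert hits[0].recognition_start == 45

    def test_linear_edge_site_uncuttable(self):
        # + site too close to the end: cut would fall outside the molecule
        mol = DnaMolecule(id="m", sequence="AAAGGTCTCAT")
        assert scan_sites(mol, BSAI) == []

    def test_n_in_site_is_nonmatch(self):
        mol = DnaMolecule(id="m", sequence="AAAGGTCNCATTTTCCCC")
        assert scan_sites(mol, BSAI) == []

    def test_toy_enzyme(self):
        toy = Enzyme("Toy", "GACT", spacer=2, overhang_len=3)
        mol = DnaMolecule(id="m", sequence="TTGACTNNAAACCCGGG".replace("N", "T"))
        (hit,) = scan_sites(mol, toy)
        assert hit.cut_top == 2 + 4 + 2
        assert hit.cut_bottom == hit.cut_top + 3


class TestDigest:
    def test_circular_conservation_two_sapi_sites(self, library):
        entry = None
        # any even receiver has exactly two SapI sites
        entry = library.receiver("pCA", "even", 2).molecule
        frags = digest(entry, SAPI)
        assert len(frags) == 2
        assert sum(len(f.core) for f in frags) == len(entry)
        for f in frags:
            assert len(f.left_overhang) == 3
            assert len(f.right_overhang) == 3

    def test_linear_one_site_blunt_ends(self):
        mol = DnaMolecule(id="m", sequence="AAAGGTCTCATTTTCCCCGGGGAAA")
        frags = digest(mol, BSAI)
        assert len(frags) == 2
        assert frags[0].left_overhang == ""
        assert frags[1].right_overhang == ""
        assert frags[0].right_overhang == frags[1].left_overhang == "TTTT"
        assert sum(len(f.core) for f in frags) == len(mol)

    def test_uncut_circular_raises(self):
        mol = DnaMolecule(id="m", sequence="ACATACAT" * 10, topology="circular")
        with pytest.raises(UncutCircularError):
            digest(mol, BSAI)

    def test_uncut_linear_returns_whole(self):
        mol = DnaMolecule(id="m", sequence="ACATACAT" * 10)
        frags = digest(mol, BSAI)
        assert len(frags) == 1
        assert frags[0].core == mol.sequence
        assert frags[0].left_overhang == frags[0].right_overhang == ""

    def test_l0_release_overhangs_match_codes(self, library, table):
        part = library.part("CE_sfGFP")
        frags = digest(part.molecule, BSAI)
        release = [
            f for f in frags if BSAI.recognition not in f.footprint
            and reverse_complement(BSAI.recognition) not in f.footprint
        ]
        assert len(release) == 1
        assert release[0].left_overhang == table.odd("C")
        assert release[0].right_overhang == table.odd("E")

    def test_flip_involution(self, library):
        part = library.part("AB_J23101")
        for f in digest(part.molecule, BSAI):
            back = f.flipped().flipped()
            assert back.core == f.core
            assert back.left_overhang == f.left_overhang
            assert back.right_overhang == f.right_overhang


# ---------------------------------------------------------------------------
# Ligation enumeration


class TestEnumerateLigations:
    def test_two_fragments_one_circular_dimer(self):
        pool = [frag("ATTTCCC", "ATTT", "GGGG", "f1"), frag("GGGGAACT", "GGGG", "ATTT", "f2")]
        products = enumerate_ligations(pool, mode="circular_only", max_copies=1)
        assert len(products) == 1
        assert products[0].topology == "circular"
        assert products[0].length == len(pool[0].core) + len(pool[1].core)

    def test_four_chain_ladder(self):
        # alpha -> beta -> gamma -> epsilon -> omega style linear chain
        ovs = ["ATG", "GCA", "TAC", "CAG", "GGT"]
        pool = [
            frag(ovs[i] + "TTTTT", ovs[i], ovs[i + 1], f"c{i}") for i in range(4)
        ]
        products = enumerate_ligations(pool, mode="include_linear", max_copies=1)
        linear = [p for p in products if p.topology == "linear"]
        sizes = sorted(len(p.parts) for p in linear)
        assert sizes == [1, 1, 1, 1, 2, 2, 2, 3, 3, 4]
        assert len([p for p in linear if len(p.parts) == 4]) == 1

    def test_oracle_equivalence_chain(self):
        ovs = ["ATG", "GCA", "TAC", "CAG", "GGT"]
        pool = [
            frag(ovs[i] + "CTTAG", ovs[i], ovs[i + 1], f"c{i}") for i in range(4)
        ]
        self._assert_oracle(pool, "include_linear", 1)
        self._assert_oracle(pool, "circular_only", 2)

    def test_oracle_equivalence_with_duplicate_overhangs(self):
        pool = [
            frag("AATTCGCG", "AATT", "GGCC", "a"),
            frag("AATTTTTT", "AATT", "GGCC", "b"),  # shares both ends with a
            frag("GGCCAAAA", "GGCC", "AATT", "c"),
        ]
        self._assert_oracle(pool, "circular_only", 1)
        self._assert_oracle(pool, "include_linear", 2)

    def test_oracle_equivalence_six_random_fragments(self):
        import random

        rng = random.Random(0)
        bases = "ACGT"
        ovs = ["AGGT", "CCAT", "GTTG", "TACA", "AGCA", "CTTC", "GATC"]
        pool = []
        for i in range(6):
            lo, ro = rng.sample(ovs, 2)
            core = lo + "".join(rng.choice(bases) for _ in range(6))
            pool.append(frag(core, lo, ro, f"r{i}"))
        self._assert_oracle(pool, "include_linear", 1)

    def _assert_oracle(self, pool, mode, max_copies):
        expected = brute_force_ligations(pool, mode, max_copies)
        got = {
            (p.topology, p.sequence)
            for p in enumerate_ligations(pool, mode=mode, max_copies=max_copies)
        }
        assert got == expected

    def test_misassembly_from_shared_left_overhang_flagged(self):
        pool = [
            frag("AGTTCGCGAT", "AGTT", "GGCA", "a"),
            frag("AGTTTTTTAT", "AGTT", "GGCA", "b"),
            frag("GGCAAAAACC", "GGCA", "AGTT", "c"),
        ]
        products = enumerate_ligations(pool, mode="circular_only", max_copies=1)
        # both a+c and b+c circles form: ambiguity is visible as >1 product
        assert len(products) == 2

    def test_blunt_blunt_excluded(self):
        pool = [frag("AAAA", "", "", "a"), frag("TTTT", "", "", "b")]
        products = enumerate_ligations(pool, mode="include_linear", max_copies=1)
        assert all(len(p.parts) == 1 for p in products)

    def test_explosion_guard(self):
        pool = [frag("AATTGG", "AATT", "AATT", f"x{i}") for i in range(8)]
        with pytest.raises(LigationExplosionError) as err:
            enumerate_ligations(pool, mode="include_linear", max_copies=8, cap=500)
        assert "AATT" in str(err.value)

    def test_empty_pool(self):
        with pytest.raises(ValueError):
            enumerate_ligations([], mode="circular_only")


# ---------------------------------------------------------------------------
# Fidelity


class TestFidelityCheck:
    def test_printed_even_alphabet_clean(self):
        report = fidelity_check(["ATG", "GCA", "TAC", "CAG", "GGT"])
        assert report["clean"]
        assert report["duplicates"] == []
        assert report["palindromes"] == []
        assert report["complement_collisions"] == []

    def test_palindrome(self):
        assert fidelity_check(["AATT"])["palindromes"] == ["AATT"]

    def test_duplicate(self):
        assert fidelity_check(["ATG", "ATG"])["duplicates"] == ["ATG"]

    def test_complement_collision(self):
        report = fidelity_check(["ATGC", "GCAT"])
        assert report["complement_collisions"] == [["ATGC", "GCAT"]]

    def test_mixed_lengths_rejected(self):
        with pytest.raises(ValueError):
            fidelity_check(["ATG", "ATGC"])


# ---------------------------------------------------------------------------
# One-pot assembly


class TestOnePot:
    def test_l1_assembly_intended_and_scar_free(self, library):
        receiver = library.receiver("pCA", "odd", 4)
        parts = [
            library.part(n).molecule
            for n in ("AB_J23101", "BC_B0034m", "CE_sfGFP", "EF_B0015")
        ]
        report = one_pot_assemble(receiver.molecule, parts, BSAI)
        assert report.n_intended == 1
        product = report.intended
        assert scan_sites(product, BSAI) == []
        with pytest.raises(UncutCircularError):
            digest(product, BSAI)

    def test_input_order_irrelevant(self, library):
        receiver = library.receiver("pCA", "odd", 4)
        names = ["EF_B0015", "CE_sfGFP", "AB_J23101", "BC_B0034m"]
        report = one_pot_assemble(
            receiver.molecule, [library.part(n).molecule for n in names], BSAI
        )
        assert report.n_intended == 1

    def test_length_conservation(self, library):
        receiver = library.receiver("pCA", "odd", 4)
        parts = [
            library.part(n).molecule
            for n in ("AB_J23101", "BC_B0034m", "CE_sfGFP", "EF_B0015")
        ]
        report = one_pot_assemble(receiver.molecule, parts, BSAI)
        # independent expectation: backbone core + sum of release-fragment cores
        def stable_core(mol):
            return sum(
                len(f.core)
                for f in digest(mol, BSAI)
                if BSAI.recognition not in f.footprint
                and reverse_complement(BSAI.recognition) not in f.footprint
            )

        expected = stable_core(receiver.molecule) + sum(stable_core(p) for p in parts)
        assert len(report.intended) == expected

    def test_chain_gap_names_codes(self, library):
        receiver = library.receiver("pCA", "odd", 4)
        parts = [
            library.part(n).molecule for n in ("AB_J23101", "CE_sfGFP", "EF_B0015")
        ]
        with pytest.raises(ChainAssemblyError) as err:
            one_pot_assemble(
                receiver.molecule, parts, BSAI, code_names=library.table.code_names()
            )
        msg = str(err.value)
        assert "B" in msg and "C" in msg

    def test_release_with_opposite_enzyme(self, library, table):
        receiver = library.receiver("pCA", "odd", 2)
        parts = [
            library.part(n).molecule
            for n in ("AB_J23101", "BC_B0034m", "CE_sfGFP", "EF_B0015")
        ]
        product = one_pot_assemble(receiver.molecule, parts, BSAI).intended
        frags = digest(product, SAPI)
        release = [
            f for f in frags if SAPI.recognition not in f.footprint
            and reverse_complement(SAPI.recognition) not in f.footprint
        ]
        assert len(release) == 1
        assert release[0].left_overhang == table.even("beta")
        assert release[0].right_overhang == table.even("gamma")

    def test_linear_input_rejected(self, library):
        receiver = library.receiver("pCA", "odd", 4)
        lin = DnaMolecule(id="lin", sequence="ACGT" * 100)
        with pytest.raises(ValueError):
            one_pot_assemble(receiver.molecule, [lin], BSAI)

    def test_parental_lists_inputs(self, library):
        receiver = library.receiver("pCA", "odd", 4)
        parts = [
            library.part(n).molecule
            for n in ("AB_J23101", "BC_B0034m", "CE_sfGFP", "EF_B0015")
        ]
        report = one_pot_assemble(receiver.molecule, parts, BSAI)
        assert receiver.molecule.id in report.parental
        assert len(report.parental) == 5
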