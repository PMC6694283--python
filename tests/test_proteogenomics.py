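"""Variant database construction, tryptic digestion and peptide uniqueness."""

import numpy as np
import pytest
from pyteomics import parser as pyt_parser

import ribothrough as rt
from ribothrough.proteogenomics import AMINO_ACIDS, InvalidResidue, cleavage_sites

#: simple trypsin rule as a regex for the pyteomics cross-check
TRYPSIN_NO_P = r"[KR](?=[^P])"


def enumerate_digest_oracle(protein, max_missed, proline_rule=True):
    """Independent digest oracle: test every substring for cleavage consistency."""

    def cut_after(i):  # cut between i and i+1
        return protein[i] in "KR" and not (
            proline_rule and i + 1 < len(protein) and protein[i + 1] == "P"
        )

    out = set()
    for a in range(len(protein)):
        for b in range(a + 1, len(protein) + 1):
            left_ok = a == 0 or cut_after(a - 1)
            right_ok = b == len(protein) or cut_after(b - 1)
            internal = sum(cut_after(i) for i in range(a, b - 1))
            if left_ok and right_ok and internal <= max_missed:
                out.add((a, protein[a:b], internal))
    return out


class TestBuildReadthroughDb:
    def test_twenty_variants_differ_only_at_stop_position(self):
        db = rt.build_readthrough_db("MK", "AA")
        assert len(db.variants) == 20
        assert {len(v) for v in db.variants.values()} == {5}
        assert {v[:2] for v in db.variants.values()} == {"MK"}
        assert {v[3:] for v in db.variants.values()} == {"AA"}
        assert sorted(v[2] for v in db.variants.values()) == sorted(AMINO_ACIDS)

    def test_empty_extension_adds_single_residue(self):
        db = rt.build_readthrough_db("MKV", "")
        assert all(len(v) == 4 for v in db.variants.values())

    def test_variant_length_matches_isr_translation(self):
        ann = rt.make_transcript(rt.SimSpec(isr_len=99, n_reads=0, seed=31))
        extension = rt.translate_extension(ann)[1:]  # strip the X placeholder
        db = rt.build_readthrough_db("M" + "A" * 858, extension)
        assert all(len(v) == 859 + 34 for v in db.variants.values())

    def test_invalid_residue_rejected(self):
        with pytest.raises(InvalidResidue):
            rt.build_readthrough_db("MKB", "AA")
        with pytest.raises(InvalidResidue):
            rt.build_readthrough_db("MK", "A*")


class TestTrypticDigest:
    def test_antibody_peptide_zero_missed(self):
        peps = rt.tryptic_digest("RQNAVTSLDRRKLSKP", max_missed=0)
        assert [(p.peptide, p.start) for p in peps] == [
            ("R", 0), ("QNAVTSLDR", 1), ("R", 10), ("K", 11), ("LSKP", 12)
        ]
        assert all(p.missed_cleavages == 0 for p in peps)

    def test_no_cleavage_sites_yields_whole_protein(self):
        peps = rt.tryptic_digest("MAGICSEQENCE", max_missed=3)
        assert [(p.peptide, p.start, p.missed_cleavages) for p in peps] == [
            ("MAGICSEQENCE", 0, 0)
        ]

    def test_one_missed_cleavage_enumeration(self):
        got = {(p.peptide, p.missed_cleavages) for p in rt.tryptic_digest("AKCKD", max_missed=1)}
        assert got == {("AK", 0), ("CK", 0), ("D", 0), ("AKCK", 1), ("CKD", 1)}

    def test_proline_suppresses_cleavage_unless_disabled(self):
        assert cleavage_sites("AKPD") == []
        assert cleavage_sites("AKPD", proline_rule=False) == [2]
        peps = {p.peptide for p in rt.tryptic_digest("AKPD", 0, proline_rule=False)}
        assert peps == {"AK", "PD"}

    def test_zero_missed_products_concatenate_to_protein(self):
        rng = np.random.default_rng(41)
        for _ in range(20):
            protein = "".join(rng.choice(list(AMINO_ACIDS), size=50))
            peps = [p for p in rt.tryptic_digest(protein, 0)]
            assert "".join(p.peptide for p in sorted(peps, key=lambda p: p.start)) == protein

    @pytest.mark.parametrize("max_missed", [0, 1, 2, 5])
    def test_matches_enumeration_oracle_on_random_proteins(self, max_missed):
        rng = np.random.default_rng(43)
        for _ in range(25):
            protein = "".join(rng.choice(list(AMINO_ACIDS), size=50))
            got = {
                (p.start, p.peptide, p.missed_cleavages)
                for p in rt.tryptic_digest(protein, max_missed)
            }
            assert got == enumerate_digest_oracle(protein, max_missed)

    @pytest.mark.parametrize("max_missed", [0, 2, 5])
    def test_peptide_sets_match_pyteomics(self, max_missed):
        rng = np.random.default_rng(47)
        for _ in range(10):
            protein = "".join(rng.choice(list(AMINO_ACIDS), size=60))
            ours = {p.peptide for p in rt.tryptic_digest(protein, max_missed)}
            ref = pyt_parser.cleave(
                protein, TRYPSIN_NO_P, missed_cleavages=max_missed, min_length=1
            )
            assert ours == set(ref)


class TestExtensionSpecificPeptides:
    BASE = "MSTAGKVDELQR"        # canonical protein
    EXT = "NAVTSLDKWQPE"         # ISR-encoded extension

    def proteome(self):
        # one entry shares a canonical tryptic peptide, one shares an extension peptide
        return {
            "prot1": "GGGVDELQRGGG",
            "prot2": "HHHWQPEHHH",
        }

    def matches(self, **kw):
        db = rt.build_readthrough_db(self.BASE, self.EXT)
        return db, rt.find_extension_specific_peptides(
            db, self.proteome(), max_missed=2, min_len=1, max_len=None, **kw
        )

    def test_canonical_peptides_never_flagged(self):
        _, matches = self.matches()
        for m in matches:
            if m.end <= len(self.BASE):
                assert not m.overlaps_extension and not m.unique_to_extension

    def test_unique_implies_overlap(self):
        _, matches = self.matches()
        assert any(m.unique_to_extension for m in matches)
        for m in matches:
            if m.unique_to_extension:
                assert m.overlaps_extension

    def test_extension_peptide_in_proteome_not_unique(self):
        # WQPE terminates every variant and also occurs in prot2
        _, matches = self.matches()
        wqpe = [m for m in matches if m.peptide == "WQPE"]
        assert wqpe and all(m.overlaps_extension and not m.unique_to_extension for m in wqpe)

    def test_spanning_peptide_is_unique_evidence(self):
        # VDELQR + readthrough residue + extension start spans the stop position
        _, matches = self.matches()
        spanning = [m for m in matches if m.peptide.startswith("VDELQR") and len(m.peptide) > 6]
        assert spanning and all(m.unique_to_extension for m in spanning)

    def test_all_variants_share_non_spanning_peptides(self):
        # trypsin/p rule: cleavage at the base/extension junction cannot
        # depend on the substituted residue (a proline would suppress it)
        db, matches = self.matches(proline_rule=False)
        per_variant = {}
        for m in matches:
            if m.end <= db.extension_start:
                per_variant.setdefault(m.parent, set()).add((m.start, m.peptide))
        shared = set.intersection(*per_variant.values())
        assert all(v == shared for v in per_variant.values())

    def test_il_equivalence_demotes_leucine_isoleucine_twins(self):
        # an extension peptide whose I/L-folded form exists in the proteome
        db = rt.build_readthrough_db("MKGGGR", "AILDE")
        proteome = {"decoy": "XXALLDEXX".replace("X", "G")}
        strict = rt.find_extension_specific_peptides(
            db, proteome, max_missed=2, min_len=1, max_len=None
        )
        folded = rt.find_extension_specific_peptides(
            db, proteome, max_missed=2, min_len=1, max_len=None, il_equivalent=True
        )
        pick = lambda ms: {m.peptide for m in ms if m.unique_to_extension}
        assert "AILDE" in pick(strict)
        assert "AILDE" not in pick(folded)

    def test_unique_extension_peptides_helper(self):
        _, matches = self.matches()
        uniq = rt.unique_extension_peptides(matches)
        assert uniq == {m.peptide for m in matches if m.unique_to_extension}
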