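"""Inversion PCR, snap-back fragments, microhomology, spacer bookkeeping."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gapseq import (
    GenomicInterval,
    PalindromeLocus,
    Primer,
    build_palindrome_sequence,
    compute_microhomology,
    predict_inversion_pcr,
    predict_snapback_fragments,
    spacer_length,
)

C = 50_000  # canonical center used by most loci below


def left_locus(arm_len=10_000, spacer_len=400):
    spacer = (
        GenomicInterval("c", C, C + spacer_len) if spacer_len else None
    )
    return PalindromeLocus("c", GenomicInterval("c", C - arm_len, C), spacer, "left")


class TestInversionPcr:
    def test_single_arm_primer_product(self):
        locus = left_locus(spacer_len=400)
        primers = [Primer("P1", C - 1_000, 20)]
        products, notes = predict_inversion_pcr(locus, primers)
        assert notes["P1"] == "arm"
        (p,) = products
        assert (p.forward_primer, p.reverse_primer) == ("P1", "P1")
        assert p.product_len == 2 * 1_000 + 400

    def test_spacer_arm_pair_product(self):
        locus = left_locus(spacer_len=400)
        primers = [Primer("arm", C - 1_000, 20), Primer("sp", C + 100, 20)]
        products, notes = predict_inversion_pcr(locus, primers)
        assert notes["sp"] == "spacer"
        lens = {(p.forward_primer, p.reverse_primer): p.product_len for p in products}
        assert lens[("sp", "arm")] == (400 - 100) + 1_000
        assert lens[("arm", "arm")] == 2_400

    def test_distant_primer_yields_nothing(self):
        locus = left_locus()
        products, notes = predict_inversion_pcr(locus, [Primer("far", C + 10_000, 20)])
        assert products == []
        assert "no product" in notes["far"]

    def test_center_straddling_primer_unusable(self):
        locus = left_locus(spacer_len=400)
        products, notes = predict_inversion_pcr(locus, [Primer("bad", C - 10, 20)])
        assert products == []
        assert "unusable" in notes["bad"]

    def test_right_arm_locus_mirrors_left(self):
        """Reflected locus + primers give identical product lengths."""
        spacer = 300
        left = PalindromeLocus(
            "c", GenomicInterval("c", C - 8_000, C),
            GenomicInterval("c", C, C + spacer), "left",
        )
        right = PalindromeLocus(
            "c", GenomicInterval("c", C, C + 8_000),
            GenomicInterval("c", C - spacer, C), "right",
        )
        lp = [Primer("a", C - 2_000, 20), Primer("s", C + 50, 20)]
        # mirror image through the center: [p, p+L) -> [2C - p - L, 2C - p)
        rp = [Primer(p.name, 2 * C - p.start - p.length, p.length) for p in lp]
        pl, _ = predict_inversion_pcr(left, lp)
        pr, _ = predict_inversion_pcr(right, rp)
        assert [(p.forward_primer, p.reverse_primer, p.product_len) for p in pl] == [
            (p.forward_primer, p.reverse_primer, p.product_len) for p in pr
        ]

    def test_every_product_contains_the_junction(self, rng):
        """Product arithmetic agrees with exhaustive string-level search."""
        arm_len, spacer_len = 3_000, 400
        for trial in range(5):
            arm = "".join(rng.choice(list("ACGT"), arm_len))
            spacer = "".join(rng.choice(list("ACGT"), spacer_len))
            molecule = build_palindrome_sequence(arm, spacer)
            locus = PalindromeLocus(
                "c",
                GenomicInterval("c", C - arm_len, C),
                GenomicInterval("c", C, C + spacer_len),
                "left",
            )
            # primers are substrings of the reference (arm + spacer)
            offs = rng.integers(0, arm_len - 25, 3)
            primers = [
                Primer(f"a{i}", C - arm_len + int(o), 20)
                for i, o in enumerate(offs)
            ]
            sp_off = int(rng.integers(0, spacer_len - 25))
            primers.append(Primer("sp", C + sp_off, 20))
            seqs = {
                p.name: (arm + spacer)[p.start - (C - arm_len) :][: p.length]
                for p in primers
            }
            predicted, _ = predict_inversion_pcr(locus, primers)

            oracle = set()
            comp = str.maketrans("ACGT", "TGCA")
            for pa in primers:
                fa = seqs[pa.name]
                fwd_hits = _find_all(molecule, fa)
                for pb in primers:
                    rc = seqs[pb.name].translate(comp)[::-1]
                    for r in _find_all(molecule, rc):
                        for f in fwd_hits:
                            if f <= r and (r + pb.length) - f <= 10_000:
                                oracle.add(
                                    (frozenset((pa.name, pb.name)), r + pb.length - f)
                                )
            got = {
                (frozenset((p.forward_primer, p.reverse_primer)), p.product_len)
                for p in predicted
            }
            assert got == oracle
            # every predicted amplicon spans the novel junction, the
            # boundary between the spacer and the inverted arm copy
            junction = arm_len + spacer_len
            for p in predicted:
                f = _find_all(molecule, seqs[p.forward_primer])[0]
                assert f <= junction <= f + p.product_len


def _find_all(s, sub):
    out, i = [], s.find(sub)
    while i != -1:
        out.append(i)
        i = s.find(sub, i + 1)
    return out


class TestSnapbackFragments:
    def test_symmetric_sites_no_spacer_halves_exactly(self):
        locus = left_locus(spacer_len=0)
        frag = predict_snapback_fragments(locus, [C - 4_000, C + 4_000])
        assert frag.native == 8_000
        assert frag.snapback == 4_000

    def test_spacer_adds_to_both_fragments(self):
        locus = left_locus(spacer_len=400)
        frag = predict_snapback_fragments(locus, [C - 4_000])
        assert frag.native == 8_400
        assert frag.snapback == 4_200

    def test_nearest_arm_side_site_used(self):
        locus = left_locus(spacer_len=0)
        frag = predict_snapback_fragments(locus, [C - 9_000, C - 2_500])
        assert frag.arm_site_distance == 2_500

    def test_distal_only_sites_raise(self):
        locus = left_locus(spacer_len=400)
        with pytest.raises(ValueError, match="arm side"):
            predict_snapback_fragments(locus, [C + 1_000, C + 5_000])

    def test_right_arm_locus(self):
        locus = PalindromeLocus(
            "c", GenomicInterval("c", C, C + 10_000),
            GenomicInterval("c", C - 200, C), "right",
        )
        frag = predict_snapback_fragments(locus, [C + 3_000])
        assert frag.native == 6_200
        assert frag.snapback == 3_100


class TestMicrohomology:
    @pytest.mark.parametrize(
        "left,right,expected",
        [
            ("TTCATG", "GGCATG", 4),
            ("AAAT", "CCCG", 0),
            ("GATCCGA", "GATCCGA", 7),  # junctions show 0-7 bp in practice
            ("catg", "CATG", 4),  # case-insensitive
            ("AN", "AN", 0),  # N earns no credit
        ],
    )
    def test_examples(self, left, right, expected):
        assert compute_microhomology(left, right) == expected

    def test_invalid_alphabet_raises(self):
        with pytest.raises(ValueError):
            compute_microhomology("ACGX", "ACGT")

    @given(
        st.text(alphabet="ACGTN", min_size=0, max_size=30),
        st.text(alphabet="ACGTN", min_size=0, max_size=30),
    )
    def test_matches_brute_force(self, a, b):
        def brute(x, y):
            for k in range(min(len(x), len(y)), 0, -1):
                if x[-k:] == y[-k:] and "N" not in x[-k:]:
                    return k
            return 0

        assert compute_microhomology(a, b) == brute(a.upper(), b.upper())


class TestSpacerLength:
    @pytest.mark.parametrize(
        "bounds,expected",
        [
            ((196_630_725, 196_632_280), 1_555),  # Chr1q31.3 candidate
            ((52_346_284, 52_346_941), 657),  # Chr15q21.3 candidate
            ((100, 100), 0),
        ],
    )
    def test_boundary_subtraction(self, bounds, expected):
        assert spacer_length(bounds) == expected

    def test_indel_adjustments(self):
        assert spacer_length((0, 276), insertion_len=185) == 461
        assert spacer_length((0, 1_000), deletion_len=400) == 600

    def test_negative_size_raises(self):
        with pytest.raises(ValueError):
            spacer_length((0, 100), deletion_len=200)

    def test_accepts_interval_objects(self):
        assert spacer_length(GenomicInterval("c", 10, 30)) == 20
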