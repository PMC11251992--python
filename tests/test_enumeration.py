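import string

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neoscreen.enumeration import (
    NeoantigenVariant,
    build_manifest,
    build_window,
    enumerate_candidates,
)
from neoscreen.errors import ReferenceMismatchError

PROTEIN = (
    "MTEYKLVVVGAGGVGKSALTIQLIQNHFVDEYDPTIEDSYRKQVVIDGETCLLDILDTAGQEEYSAMRDQ"
    "YMRTGEGFLCVFAINNTKSFEDIHHYREQIKRVKDSEDVPMVLVGNKCDLPSRTVDTKQAQDLARSYGIP"
    "FIETSAKTRQGVDDAFYTLVREIRQYRLKKISKEEKTPGCVKIKKCIIM"
)


def brute_force_candidates(window: str, mutation_offset: int, lengths) -> set:
    """Oracle: every substring of each length whose span covers the mutated index."""
    out = set()
    for k in lengths:
        for start in range(1, len(window) - k + 2):
            if start <= mutation_offset <= start + k - 1:
                out.add((k, start, window[start - 1 : start + k - 1]))
    return out


class TestBuildWindow:
    def test_interior_mutation_gives_25mer_centered(self):
        v = build_window(PROTEIN, 100, PROTEIN[99], "W", flank=12)
        assert len(v.window_seq) == 25
        assert v.mutation_offset == 13
        assert v.window_seq[12] == "W"

    def test_nterminal_truncation(self):
        v = build_window(PROTEIN, 5, PROTEIN[4], "W", flank=12)
        assert len(v.window_seq) == 17
        assert v.mutation_offset == 5

    def test_flanks_keep_native_context(self):
        v = build_window(PROTEIN, 100, PROTEIN[99], "W", flank=12)
        assert v.window_seq[:12] == PROTEIN[87:99]
        assert v.window_seq[13:] == PROTEIN[100:112]

    def test_reference_mismatch_raises_with_details(self):
        wrong = "A" if PROTEIN[99] != "A" else "G"
        with pytest.raises(ReferenceMismatchError) as err:
            build_window(PROTEIN, 100, wrong, "W", protein_id="KRAS")
        assert "KRAS" in str(err.value) and "100" in str(err.value)

    def test_indels_rejected(self):
        with pytest.raises(ValueError):
            build_window(PROTEIN, 100, PROTEIN[99], "WW")


class TestEnumerateCandidates:
    @pytest.mark.parametrize(
        "position,expected_total",
        [(100, 38), (1, 4), (5, 20)],  # interior / N-terminus / 5 residues in
    )
    def test_counts_match_brute_force(self, position, expected_total):
        ref = PROTEIN[position - 1]
        alt = "W" if ref != "W" else "Y"
        v = build_window(PROTEIN, position, ref, alt)
        cands = enumerate_candidates(v)
        oracle = brute_force_candidates(v.window_seq, v.mutation_offset, (8, 9, 10, 11))
        assert len(cands) == expected_total
        assert {(len(c.sequence), c.start_in_window, c.sequence) for c in cands} == oracle

    def test_interior_count_per_length_is_k(self):
        v = build_window(PROTEIN, 100, PROTEIN[99], "W")
        by_len = {}
        for c in enumerate_candidates(v):
            by_len[len(c.sequence)] = by_len.get(len(c.sequence), 0) + 1
        assert by_len == {8: 8, 9: 9, 10: 10, 11: 11}

    def test_every_candidate_carries_the_mutation(self):
        v = build_window(PROTEIN, 100, PROTEIN[99], "W")
        for c in enumerate_candidates(v):
            assert c.sequence[c.mutation_pos_in_peptide - 1] == "W"

    def test_ordering_by_length_then_start(self):
        v = build_window(PROTEIN, 100, PROTEIN[99], "W")
        keys = [(len(c.sequence), c.start_in_window) for c in enumerate_candidates(v)]
        assert keys == sorted(keys)

    @given(
        window_len=st.integers(1, 25),
        offset_frac=st.floats(0, 1),
        data=st.data(),
    )
    @settings(max_examples=200, derandomize=True)
    def test_matches_oracle_on_random_windows(self, window_len, offset_frac, data):
        offset = 1 + round(offset_frac * (window_len - 1))
        letters = data.draw(
            st.lists(
                st.sampled_from("ACDEFGHIKLMNPQRSTVWY"),
                min_size=window_len,
                max_size=window_len,
            )
        )
        window = "".join(letters)
        v = NeoantigenVariant(
            variant_id="v",
            protein_id="p",
            protein_position=offset,
            ref_residue="?",
            alt_residue=window[offset - 1],
            window_seq=window,
            mutation_offset=offset,
        )
        got = {(len(c.sequence), c.start_in_window, c.sequence)
               for c in enumerate_candidates(v)}
        assert got == brute_force_candidates(window, offset, (8, 9, 10, 11))


def _interior_variants(n):
    out = []
    for i in range(n):
        # distinct windows: rotate the protein so sequences differ
        seq = PROTEIN[i:] + PROTEIN[:i]
        out.append(
            build_window(
                seq, 100, seq[99], "W" if seq[99] != "W" else "Y",
                variant_id=f"v{i}", protein_id=f"p{i}",
            )
        )
    return out


class TestBuildManifest:
    def test_full_cartesian_product_without_collisions(self):
        variants = _interior_variants(50)
        alleles = [f"A*{i:02d}:01" for i in range(15)]
        manifest = build_manifest(variants, alleles)
        assert len(manifest) == 50 * 38 * 15
        assert manifest.n_sequence_collisions == 0

    def test_overlapping_variants_merge_with_provenance(self):
        # same substitution described twice -> identical candidate sequences
        a = build_window(PROTEIN, 100, PROTEIN[99], "W", variant_id="va")
        b = build_window(PROTEIN, 100, PROTEIN[99], "W", variant_id="vb")
        manifest = build_manifest([a, b], ["A*02:01"])
        assert len(manifest) == 38  # counted once per (sequence, allele)
        assert all(ids == ("va", "vb") for ids in manifest.table["variant_ids"])

    def test_excluding_all_alleles_gives_empty_manifest(self):
        variants = _interior_variants(2)
        manifest = build_manifest(variants, ["A*02:01"], excluded_alleles=["A*02:01"])
        assert len(manifest) == 0

    def test_empty_variant_list_gives_empty_manifest(self):
        assert len(build_manifest([], ["A*02:01"])) == 0

    def test_pairs_unique(self):
        manifest = build_manifest(_interior_variants(3), ["A*02:01", "B*07:02"])
        assert len(manifest.pairs) == len(manifest)
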