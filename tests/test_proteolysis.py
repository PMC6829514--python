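import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from peptikit import (CleavageRule, Enzyme, ProteinRecord, cleavage_sites,
                      default_registry, digest, digest_sequential,
                      parse_enzyme_config)

from oracles import brute_force_missed, brute_force_sites

ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
sequences = st.text(alphabet=ALPHABET, min_size=1, max_size=200)

BUNDLED = sorted(default_registry())


def make_protein(seq: str) -> ProteinRecord:
    return ProteinRecord("H1", "", seq)


TOYASE = Enzyme("toyase", rules=(CleavageRule(p1_allow=frozenset("K")),))


class TestCleavageRule:
    def test_overlapping_allow_block_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            CleavageRule(p1_allow=frozenset("K"), p1_block=frozenset("K"))

    def test_non_canonical_residue_rejected(self):
        with pytest.raises(ValueError, match="non-canonical"):
            CleavageRule(p1_allow=frozenset("X"))

    def test_p2_trigger_requires_existing_p2(self):
        # papain-style rule: P2 = F triggers cleavage one bond downstream
        rule = CleavageRule(p2_allow=frozenset("F"))
        assert rule.fires("A", "G", "F")
        assert not rule.fires("A", "G", None)
        assert not rule.fires("A", "G", "A")


class TestCleavageSites:
    def test_pepsin_hand_enumeration(self, pepsin):
        # A F A V A L A E A: F at 2, L at 6, E at 8 are pepsin P1 residues
        assert cleavage_sites(make_protein("AFAVALAEA"), pepsin) == [2, 6, 8]

    def test_enzyme_with_no_triggers_finds_no_sites(self):
        inert = Enzyme("inert", rules=(CleavageRule(),))
        assert cleavage_sites(make_protein("AFKLRWY"), inert) == []

    def test_trypsin_proline_exception(self, trypsin):
        # standard Keil exception: no cleavage of K-P bonds
        assert cleavage_sites(make_protein("AKPA"), trypsin) == []
        assert cleavage_sites(make_protein("AKAA"), trypsin) == [2]

    @pytest.mark.parametrize("enzyme_name", BUNDLED)
    @given(seq=sequences)
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_sites_match_per_bond_oracle(self, registry, enzyme_name, seq):
        enzyme = registry[enzyme_name]
        assert (cleavage_sites(make_protein(seq), enzyme)
                == brute_force_sites(seq, enzyme))


class TestDigest:
    def test_pepsin_fragments(self, pepsin):
        frags = digest(make_protein("AFAVALAEA"), pepsin)
        assert [(f.sequence, f.start, f.end) for f in frags] == [
            ("AF", 1, 2), ("AVAL", 3, 6), ("AE", 7, 8), ("A", 9, 9)]
        assert all(f.n_missed == 0 for f in frags)

    def test_no_sites_gives_whole_protein(self, trypsin):
        frags = digest(make_protein("AAAA"), trypsin)
        assert [f.sequence for f in frags] == ["AAAA"]

    def test_missed_cleavage_enumeration(self):
        frags = digest(make_protein("AKAKA"), TOYASE, max_missed=1)
        got = [(f.sequence, f.start, f.end, f.n_missed) for f in frags]
        assert got == [("AK", 1, 2, 0), ("AKAK", 1, 4, 1),
                       ("AK", 3, 4, 0), ("AKA", 3, 5, 1), ("A", 5, 5, 0)]

    @pytest.mark.parametrize("enzyme_name", BUNDLED)
    @given(seq=sequences, max_missed=st.integers(0, 3))
    @settings(max_examples=40, derandomize=True, deadline=None)
    def test_digest_matches_brute_force(self, registry, enzyme_name, seq,
                                        max_missed):
        enzyme = registry[enzyme_name]
        frags = digest(make_protein(seq), enzyme, max_missed=max_missed)
        assert ([(f.start, f.end, f.sequence, f.n_missed) for f in frags]
                == brute_force_missed(seq, enzyme, max_missed))

    @pytest.mark.parametrize("enzyme_name", BUNDLED)
    @given(seq=sequences)
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_zero_missed_fragments_partition_parent(self, registry,
                                                    enzyme_name, seq):
        frags = digest(make_protein(seq), registry[enzyme_name])
        assert "".join(f.sequence for f in frags) == seq
        assert sum(len(f) for f in frags) == len(seq)
        assert all(len(f) > 0 for f in frags)

    @given(seq=st.text(alphabet=ALPHABET, min_size=1, max_size=40))
    @settings(max_examples=40, derandomize=True, deadline=None)
    def test_missed_count_tally_matches_site_count(self, seq):
        """With k sites, exactly k+1-j fragments carry n_missed=j."""
        protein = make_protein(seq)
        k = len(cleavage_sites(protein, TOYASE))
        frags = digest(protein, TOYASE, max_missed=8)
        for j in range(0, min(k, 8) + 1):
            assert sum(f.n_missed == j for f in frags) == k + 1 - j

    def test_negative_missed_rejected(self, trypsin):
        with pytest.raises(ValueError):
            digest(make_protein("AK"), trypsin, max_missed=-1)


class TestSequentialDigestion:
    def test_lysc_then_trypsin_equals_trypsin_when_sites_nest(self, registry):
        protein = make_protein("AKARA")
        frags = digest_sequential(protein, [registry["lys_c"],
                                            registry["trypsin"]])
        assert [f.sequence for f in frags] == ["AK", "AR", "A"]

    def test_single_enzyme_reduces_to_plain_digest(self, pepsin):
        protein = make_protein("AFAVALAEA")
        assert digest_sequential(protein, [pepsin]) == digest(protein, pepsin)

    @given(seq=sequences)
    @settings(max_examples=40, derandomize=True, deadline=None)
    def test_union_site_monotonicity(self, registry, seq):
        protein = make_protein(seq)
        e1, e2 = registry["lys_c"], registry["pepsin_ph_gt2"]
        union_cuts = {f.end for f in digest_sequential(protein, [e1, e2])}
        for enzyme in (e1, e2):
            assert set(cleavage_sites(protein, enzyme)) <= union_cuts

    def test_requires_an_enzyme(self):
        with pytest.raises(ValueError):
            digest_sequential(make_protein("AK"), [])


class TestEnzymeConfig:
    def test_bundled_registry_contents(self, registry):
        expected = {"pepsin_ph_gt2": "3.4.23.1", "bromelain_stem": "3.4.22.32",
                    "papain": "3.4.22.2", "trypsin": "3.4.21.4",
                    "chymotrypsin_a": "3.4.21.1", "lys_c": "3.4.21.50"}
        for name, ec in expected.items():
            assert registry[name].ec_number == ec

    def test_user_enzyme_added_and_digests(self, tmp_path):
        cfg = tmp_path / "enzymes.yaml"
        cfg.write_text("enzymes:\n  toyase:\n    p1_allow: K\n")
        registry = parse_enzyme_config(cfg)
        assert "toyase" in registry
        frags = digest(make_protein("AKAKA"), registry["toyase"])
        assert [f.sequence for f in frags] == ["AK", "AK", "A"]

    def test_user_override_replaces_bundled(self, tmp_path):
        cfg = tmp_path / "enzymes.yaml"
        cfg.write_text("enzymes:\n  trypsin:\n    ec: 3.4.21.4\n"
                       "    p1_allow: K\n")
        registry = parse_enzyme_config(cfg)
        assert registry["trypsin"].rules[0].p1_allow == frozenset("K")

    def test_empty_config_keeps_defaults(self, tmp_path):
        cfg = tmp_path / "enzymes.yaml"
        cfg.write_text("")
        assert sorted(parse_enzyme_config(cfg)) == BUNDLED

    def test_conflicting_rule_rejected(self, tmp_path):
        cfg = tmp_path / "enzymes.yaml"
        cfg.write_text("enzymes:\n  bad:\n    p1_allow: K\n    p1_block: K\n")
        with pytest.raises(ValueError, match="overlap"):
            parse_enzyme_config(cfg)

    def test_unknown_key_rejected(self, tmp_path):
        cfg = tmp_path / "enzymes.yaml"
        cfg.write_text("enzymes:\n  bad:\n    p9_allow: K\n")
        with pytest.raises(ValueError, match="unknown"):
            parse_enzyme_config(cfg)

    def test_unknown_enzyme_error_lists_registry(self, registry):
        with pytest.raises(KeyError, match="pepsin_ph_gt2"):
            registry.get_enzyme("nope")
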