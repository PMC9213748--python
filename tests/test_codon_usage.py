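"""Codon counting, RSCU identities, profiles and the depth-group t-test."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitocompare.codon_usage import (
    AA_CLASSES,
    AMINO_ACIDS,
    AminoAcidProfile,
    GeneticCode,
    amino_acid_profile,
    audit_start_stop,
    compare_depth_groups,
    compute_rscu,
    count_codons,
)
from mitocompare.mito_io import GeneFeature, MitoGenome

CODE4 = GeneticCode.from_table_id(4)


class TestGeneticCode:
    def test_table4_stop_set_and_tga_trp(self):
        assert CODE4.is_stop("TAA") and CODE4.is_stop("TAG")
        assert not CODE4.is_stop("TGA")
        assert CODE4.translate_codon("TGA") == "W"

    def test_families_cover_62_sense_codons(self):
        fams = CODE4.synonymous_families()
        assert sum(len(v) for v in fams.values()) == 62
        assert len(fams) == 20


class TestAudit:
    def test_typical_and_flagged_codons(self):
        g = MitoGenome(
            "g", "ATGGTTTAA" + "GTGGTTTAG",
            features=[GeneFeature("cox1", "CDS", 0, 9, 1), GeneFeature("ND3", "CDS", 9, 18, 1)],
        )
        df = audit_start_stop(g, CODE4).set_index("gene")
        assert df.loc["cox1", "start_codon"] == "ATG"
        assert df.loc["cox1", "stop_codon"] == "TAA"
        assert bool(df.loc["cox1", "start_is_atg"])
        assert df.loc["ND3", "start_codon"] == "GTG"
        assert not bool(df.loc["ND3", "start_is_atg"])
        assert df.loc["ND3", "stop_codon"] == "TAG"
        assert bool(df.loc["ND3", "stop_is_stop"])

    def test_synthetic_default_is_atg_taa_except_nd3(self, default_ancestor):
        g, _ = default_ancestor
        df = audit_start_stop(g, CODE4).set_index("gene")
        assert df.start_codon.eq("ATG").all()
        assert df.loc["ND3", "stop_codon"] == "TAG"
        assert df.drop("ND3").stop_codon.eq("TAA").all()


class TestCountCodons:
    def test_stop_tallied_separately(self):
        t = count_codons(["ATGTAA"], CODE4)
        assert t.counts == {"ATG": 1}
        assert t.stop_counts == {"TAA": 1}
        assert t.total_codons == 1 and t.total_with_stops == 2

    def test_pooling(self):
        t = count_codons(["ATGGTTTAA", "ATGGTTTAA"], CODE4)
        assert t.counts["ATG"] == 2 and t.counts["GTT"] == 2

    def test_codons_with_n_skipped_and_logged(self):
        t = count_codons(["ATGANTTAA"], CODE4)
        assert t.skipped_codons == 1
        assert t.counts == {"ATG": 1}

    @given(st.lists(st.text("ACGT", min_size=3, max_size=30), max_size=5))
    @settings(max_examples=50, deadline=None)
    def test_additive_over_sequence_lists(self, seqs):
        seqs = [s[: len(s) - len(s) % 3] for s in seqs]
        whole = count_codons(seqs, CODE4)
        parts = count_codons(seqs[: len(seqs) // 2], CODE4)
        rest = count_codons(seqs[len(seqs) // 2:], CODE4)
        merged = {
            c: parts.counts.get(c, 0) + rest.counts.get(c, 0)
            for c in set(parts.counts) | set(rest.counts)
        }
        assert whole.counts == merged


counts_tables = st.dictionaries(
    st.sampled_from([c for c in CODE4.codon_map if not CODE4.is_stop(c)]),
    st.integers(0, 50),
    max_size=40,
)


class TestRscu:
    def test_uniform_family_usage_gives_rscu_1(self):
        fams = CODE4.synonymous_families()
        t = count_codons([], CODE4)
        for family in fams.values():
            for c in family:
                t.counts[c] = 5
        compute_rscu(t)
        assert all(v == pytest.approx(1.0) for v in t.rscu.values())

    def test_two_codon_family_3_to_1(self):
        t = count_codons([], CODE4)
        t.counts["GAA"] = 3  # Glu family: GAA/GAG
        t.counts["GAG"] = 1
        compute_rscu(t)
        assert t.rscu["GAA"] == pytest.approx(1.5)
        assert t.rscu["GAG"] == pytest.approx(0.5)

    def test_unexpressed_family_is_nan_not_zero(self):
        t = count_codons(["ATGTAA"], CODE4)
        compute_rscu(t)
        assert np.isnan(t.rscu["GAA"])

    @given(counts_tables)
    @settings(max_examples=80, deadline=None)
    def test_family_mean_1_and_sum_equals_degeneracy(self, counts):
        t = count_codons([], CODE4)
        t.counts.update(counts)
        compute_rscu(t)
        for aa, family in CODE4.synonymous_families().items():
            total = sum(t.counts.get(c, 0) for c in family)
            if total == 0:
                continue
            vals = [t.rscu[c] for c in family]
            assert np.mean(vals) == pytest.approx(1.0, abs=1e-9)
            assert np.sum(vals) == pytest.approx(len(family), abs=1e-9)


class TestProfiles:
    def test_met_only_table(self):
        t = count_codons(["ATGATGATG"], CODE4)
        p = amino_acid_profile(t, "g")
        assert p.aa_percent["M"] == pytest.approx(100.0)
        assert p.class_percent["nonpolar"] == pytest.approx(100.0)

    @given(counts_tables)
    @settings(max_examples=60, deadline=None)
    def test_percentages_sum_to_100(self, counts):
        if sum(counts.values()) == 0:
            return
        t = count_codons([], CODE4)
        t.counts.update(counts)
        p = amino_acid_profile(t, "g")
        assert sum(p.aa_percent.values()) == pytest.approx(100.0, abs=1e-9)
        assert sum(p.class_percent.values()) == pytest.approx(100.0, abs=1e-9)

    def test_class_table_partitions_the_20_amino_acids(self):
        union = set().union(*AA_CLASSES.values())
        assert union == set(AMINO_ACIDS)
        assert sum(len(v) for v in AA_CLASSES.values()) == 20


def _profile(gid, valine, rng):
    # the 19 non-valine percentages are drawn identically in both groups;
    # sums are left un-normalized so those draws stay group-independent
    pct = {aa: max(0.01, 100.0 / 20 + rng.normal(0, 0.3)) for aa in AMINO_ACIDS}
    pct["V"] = valine
    cls = {c: sum(pct[a] for a in members) for c, members in AA_CLASSES.items()}
    return AminoAcidProfile(gid, pct, cls)


class TestDepthGroups:
    def test_identical_groups_t0_p1(self):
        pct = {aa: 5.0 for aa in AMINO_ACIDS}
        cls = {c: sum(pct[a] for a in m) for c, m in AA_CLASSES.items()}
        profiles = [AminoAcidProfile(f"g{i}", pct, cls) for i in range(6)]
        grouping = {f"g{i}": ("deep" if i < 3 else "shallow") for i in range(6)}
        df = compare_depth_groups(profiles, grouping)
        assert (df.t == 0).all() and (df.p == 1).all()

    def test_elevated_valine_is_the_only_significant_amino_acid(self):
        """Deep group valine ~8.5 +/- 0.04 vs shallow ~7.5 +/- 0.3 (19 other
        amino acids drawn identically) flags only valine at p < 0.01."""
        rng = np.random.default_rng(3)
        profiles = [
            _profile(f"d{i}", rng.normal(8.5, 0.04), rng) for i in range(2)
        ] + [
            _profile(f"s{i}", rng.normal(7.5, 0.3), rng) for i in range(12)
        ]
        grouping = {p.genome_id: ("deep" if p.genome_id.startswith("d") else "shallow")
                    for p in profiles}
        with pytest.warns(UserWarning, match="fewer than 3"):
            df = compare_depth_groups(profiles, grouping)
        aa = df[df.label.isin(AMINO_ACIDS)].set_index("label")
        assert aa.loc["V", "p"] < 0.01
        assert (aa.drop("V").p > 0.05).all()
        assert (aa.flag == "small_group").all()

    def test_symmetric_up_to_sign_under_relabeling(self):
        rng = np.random.default_rng(5)
        profiles = [_profile(f"g{i}", rng.normal(8, 0.3), rng) for i in range(8)]
        g1 = {f"g{i}": ("deep" if i < 4 else "shallow") for i in range(8)}
        g2 = {k: ("shallow" if v == "deep" else "deep") for k, v in g1.items()}
        d1 = compare_depth_groups(profiles, g1)
        d2 = compare_depth_groups(profiles, g2)
        assert np.allclose(d1.t.values, -d2.t.values, equal_nan=True)
        assert np.allclose(d1.p.values, d2.p.values, equal_nan=True)

    def test_undersized_group_flagged_untestable(self):
        rng = np.random.default_rng(1)
        profiles = [_profile(f"g{i}", 8.0, rng) for i in range(3)]
        grouping = {"g0": "deep", "g1": "shallow", "g2": "shallow"}
        with pytest.warns(UserWarning):
            df = compare_depth_groups(profiles, grouping)
        assert (df.flag == "untestable_group_size").all()
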