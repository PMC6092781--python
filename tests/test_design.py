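import pytest

from exonskip.design import design_guides, enumerate_guides, guides_to_dataframe, targetability_summary
from exonskip.editors import IUPAC, BaseEditor, EfficiencyProfile
from exonskip.genome import Genome, acceptor_of, exon_refs, inner_exons, revcomp
from exonskip.simulate import FixtureSpec, PlantedGuide, make_toy_genome

from oracles import brute_force_guides, mirror_transcripts


def fixture_acceptors(fx):
    return [acceptor_of(r, fx.genome) for r in inner_exons(fx.transcripts)]


class TestEnumerateGuides:
    def test_matches_manifest_exactly(self, planted_fixture, be3):
        fx = planted_fixture
        guides = design_guides(fixture_acceptors(fx), fx.genome, [be3])
        got = {(g.contig, g.start, g.end, g.strand, g.target_c_position) for g in guides}
        want = {
            (m["contig"], m["start"], m["end"], m["strand"], m["target_c_position"])
            for m in fx.manifest["guides"]
        }
        assert got == want
        by_locus = {(g.contig, g.start): g for g in guides}
        for m in fx.manifest["guides"]:
            assert by_locus[(m["contig"], m["start"])].protospacer == m["protospacer"]

    def test_matches_brute_force_oracle(self, planted_fixture, be3):
        fx = planted_fixture
        for acc in fixture_acceptors(fx):
            got = {
                (g.start, g.end, g.strand, g.target_c_position)
                for g in enumerate_guides(acc, fx.genome, be3)
            }
            assert got == brute_force_guides(acc, fx.genome, be3, IUPAC)

    def test_no_planted_pams_yields_nothing(self, be3):
        fx = make_toy_genome(FixtureSpec(seed=23, n_transcripts=2))
        assert design_guides(fixture_acceptors(fx), fx.genome, [be3]) == []

    def test_mutated_pam_kills_candidate(self, planted_fixture, be3):
        fx = planted_fixture
        m = fx.manifest["guides"][0]
        seq = fx.genome.sequences[m["contig"]]
        # break the planted PAM: overwrite the NGG's GG with TT
        k = 3
        if m["strand"] == "-":
            lo = m["start"] - k
            broken = seq[:lo] + revcomp("NTT").replace("N", seq[lo + 2]) + seq[lo + k:]
        else:
            lo = m["end"]
            broken = seq[:lo] + seq[lo] + "TT" + seq[lo + k:]
        genome = Genome({**fx.genome.sequences, m["contig"]: broken})
        acc = [a for a in fixture_acceptors(fx) if a.position == m["acceptor_position"]][0]
        assert enumerate_guides(acc, genome, be3) == []

    def test_target_c_invariant_and_pam_match(self, planted_fixture, editors):
        fx = planted_fixture
        for editor in editors.values():
            for g in design_guides(fixture_acceptors(fx), fx.genome, [editor]):
                assert g.protospacer[g.target_c_position - 1] == "C"
                assert editor.pam_matcher.matches(g.pam_observed)
                assert g.predicted_efficiency == editor.profile[g.target_c_position]

    def test_be3_guides_place_c_12_to_17_bp_from_pam(self, planted_fixture, be3):
        fx = planted_fixture
        guides = design_guides(fixture_acceptors(fx), fx.genome, [be3])
        assert guides and all(12 <= g.c_to_pam_distance <= 17 for g in guides)

    def test_sorted_by_efficiency(self, planted_fixture, be3):
        fx = planted_fixture
        for acc in fixture_acceptors(fx):
            effs = [g.predicted_efficiency for g in enumerate_guides(acc, fx.genome, be3)]
            assert effs == sorted(effs, reverse=True)

    def test_reverse_complement_equivariance(self, planted_fixture, be3):
        fx = planted_fixture
        rc_genome = fx.genome.reverse_complemented()
        mirrored = mirror_transcripts(fx.transcripts, fx.genome)
        fwd = design_guides(fixture_acceptors(fx), fx.genome, [be3])
        rev = design_guides(
            [acceptor_of(r, rc_genome) for r in inner_exons(mirrored)], rc_genome, [be3]
        )
        flip = {"+": "-", "-": "+"}
        total = {c: len(s) for c, s in fx.genome.sequences.items()}
        want = {
            (g.contig, total[g.contig] - g.end, total[g.contig] - g.start,
             flip[g.strand], g.protospacer, g.target_c_position)
            for g in fwd
        }
        got = {(g.contig, g.start, g.end, g.strand, g.protospacer, g.target_c_position) for g in rev}
        assert got == want


class TestBystander:
    def _acceptor_genome(self, first_exon_base: str):
        # intron ...AG | exon starts with `first_exon_base`; NGG PAM planted
        # deep in the intron so the target C sits at protospacer position 6
        intron = "T" * 30 + "CCTTTTTTTTTTTTTTAG"  # CC -> GG PAM on the antisense strand
        exon = first_exon_base + "CAAACCCAAACCCAAA"
        seq = intron + exon + "GTTTTTTTTTTTTTTTTTTTTTAGCCCAAACCCAAACCCAAA"
        genome = Genome({"c": seq})
        from exonskip.genome import ExonRef

        start = len(intron)
        ref = ExonRef("t", 1, "c", start, start + len(exon), "+", 3)
        return acceptor_of(ref, genome), genome

    @pytest.mark.parametrize("base,expected", [("A", False), ("G", True), ("C", False)])
    def test_first_exonic_base_rule(self, base, expected, be3):
        acc, genome = self._acceptor_genome(base)
        guides = [g for g in enumerate_guides(acc, genome, be3) if g.target_c_position == 6]
        assert guides, "fixture must yield the position-6 guide"
        assert guides[0].bystander is expected

    def test_exonic_g_outside_window_not_flagged(self, be3):
        # at target position 4 the exonic base falls at position 3, where the
        # editing window reports zero efficiency -> no bystander flag
        acc, genome = self._acceptor_genome("G")
        tiny = BaseEditor(
            name="pos4-only", pam="NGG", protospacer_length=20,
            profile=EfficiencyProfile({4: 0.3}),
        )
        guides = enumerate_guides(acc, genome, tiny)
        if guides:  # PAM geometry may or may not admit position 4 here
            assert all(not g.bystander for g in guides)


class TestTargetability:
    def test_counts_and_monotonicity(self, be3):
        spec = FixtureSpec(
            seed=31,
            n_transcripts=4,
            planted_guides=(
                PlantedGuide(0, 1, "SpCas9-BE3", 6),
                PlantedGuide(1, 1, "SpCas9-BE3", 5),
                PlantedGuide(2, 1, "SpCas9-BE3", 9),
            ),
        )
        fx = make_toy_genome(spec)
        accs = fixture_acceptors(fx)
        thresholds = [0.0, 0.2, 0.4, 1.0]
        cutoffs = [0.0, 10.0, float("inf")]
        table = targetability_summary(accs, fx.genome, [be3], thresholds, cutoffs)
        at = lambda t, c: int(
            table[(table.efficiency_threshold == t) & (table.offtarget_cutoff == c)].n_targetable.iloc[0]
        )
        # 3 of the acceptors were given valid PAMs; unique guides pass any cutoff
        assert at(0.0, float("inf")) == 3
        assert at(1.1 if 1.1 in thresholds else 1.0, float("inf")) == 0  # above max profile value
        for c in cutoffs:
            counts = [at(t, c) for t in thresholds]
            assert counts == sorted(counts, reverse=True)  # tighter efficiency never adds exons
        for t in thresholds:
            counts = [at(t, c) for c in reversed(cutoffs)]
            assert counts == sorted(counts, reverse=True)  # tighter cutoff never adds exons


def test_dataframe_round_trip(planted_fixture, be3):
    fx = planted_fixture
    guides = design_guides(fixture_acceptors(fx), fx.genome, [be3])
    df = guides_to_dataframe(guides)
    assert len(df) == len(guides)
    assert set(df.columns) >= {"guide_id", "protospacer", "pam", "predicted_efficiency", "bystander"}
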