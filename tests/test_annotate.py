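"""Tiled-tag annotation, break detection and novel-allele inference."""

import pytest

import tcrweave as tw
from tcrweave.annotate import reverse_complement


def _alt(seq, pos):
    """First substitution at 1-based pos that keeps the codon stop-free."""
    idx = pos - 1
    for base in "ACGT":
        if base == seq[idx]:
            continue
        start = idx - idx % 3
        codon = seq[start:idx] + base + seq[idx + 1 : start + 3]
        if codon not in ("TAA", "TAG", "TGA"):
            return base
    raise AssertionError


class TestBuildTagIndex:
    def test_grid_offsets_for_length_60(self, ref):
        info = tw.build_tag_index(ref).alleles["TRBJ1-1*01"]
        assert info.grid == [0, 10, 20, 30, 40]

    def test_terminal_tag_added_off_grid(self):
        rec = tw.SegmentRecord(tw.GeneIdentifier("TRBVX", "01"),
                               tw.SegmentType.VARIABLE, "F",
                               "TGT" + "ACGATTGCCA" * 6 + "TG")  # 65 nt
        index = tw.TagIndex()
        index.add_allele(rec)
        assert index.alleles["TRBVX*01"].grid == [0, 10, 20, 30, 40, 45]

    def test_shared_tags_map_to_all_source_alleles(self, ref, tag_index):
        # *01 and *02 differ by a single base; distal tags are shared
        v01 = ref.get("TRBV2-1", "01", tw.SegmentType.VARIABLE).sequence
        hits = tag_index.tags[v01[:20]]
        assert {a for a, _ in hits} >= {"TRBV2-1*01", "TRBV2-1*02"}

    def test_short_allele_skipped(self, caplog):
        import logging
        rec = tw.SegmentRecord(tw.GeneIdentifier("TRBVY", "01"),
                               tw.SegmentType.VARIABLE, "F", "TGTACGATTGC")
        index = tw.TagIndex()
        with caplog.at_level(logging.WARNING, logger="tcrweave.annotate"):
            index.add_allele(rec)
        assert "TRBVY*01" not in index.alleles


class TestAnnotateRead:
    def test_error_free_read_gets_exact_allele_calls(self, tag_index, sims):
        for read in tw.reads_for_annotation(sims[:50]):
            a = tw.annotate_read(read.sequence, tag_index, read.read_id)
            assert a.v_calls == [str(read.sim.v_allele)]
            assert a.j_calls == [str(read.sim.j_allele)]
            assert a.v_jump == 0 and not a.ambiguous

    def test_truncated_read_has_positive_v_jump(self, tag_index, sims):
        for read in tw.reads_for_annotation(sims[:10], truncate_offset=25):
            a = tw.annotate_read(read.sequence, tag_index)
            assert a.v_jump is not None and a.v_jump > 0

    def test_random_sequence_yields_no_calls(self, tag_index):
        import numpy as np
        rng = np.random.default_rng(99)
        read = "".join(np.array(list("ACGT"))[rng.integers(4, size=400)])
        a = tw.annotate_read(read, tag_index)
        assert a.v_calls == [] and a.j_calls == []

    def test_reverse_complement_recovered_and_flagged(self, tag_index, sims):
        read = tw.reads_for_annotation(sims[:1])[0]
        a = tw.annotate_read(reverse_complement(read.sequence), tag_index)
        assert a.v_calls == [str(read.sim.v_allele)]
        assert a.reversed

    def test_snv_read_still_called_unambiguously(self, ref, tag_index, sims):
        read = next(r for r in tw.reads_for_annotation(sims)
                    if r.sim.v_allele.gene_name == "TRBV3-1")
        seq = read.sequence
        mutated = seq[:100] + _alt(seq, 101) + seq[101:]
        a = tw.annotate_read(mutated[:len(seq)], tag_index)
        assert a.v_calls == [str(read.sim.v_allele)]


class TestExtractJunction:
    def test_matches_ground_truth(self, tag_index, sims):
        for read in tw.reads_for_annotation(sims[:50]):
            a = tw.annotate_read(read.sequence, tag_index, read.read_id)
            assert a.junction_nt == read.sim.junction_nt
            assert a.junction_aa == read.sim.junction_aa

    def test_read_truncated_before_j_anchor_has_no_junction(
            self, tag_index, sims):
        read = tw.reads_for_annotation(sims[:1])[0]
        sim = read.sim
        cut = sim.junction_end - sim.leader_len - 5  # before the J anchor end
        a = tw.annotate_read(read.sequence[:cut], tag_index)
        assert a.junction_nt is None

    def test_junction_reflects_read_not_germline(self, tag_index, sims):
        read = tw.reads_for_annotation(sims[:1])[0]
        sim = read.sim
        js = sim.junction_start - sim.leader_len
        pos = js + 4  # inside the junction, 0-based
        alt = _alt(read.sequence, pos + 1)
        seq = read.sequence[:pos] + alt + read.sequence[pos + 1 :]
        a = tw.annotate_read(seq, tag_index)
        if a.junction_nt is not None:
            assert a.junction_nt[4] == alt


class TestFindTagBreaks:
    def test_interior_snv_gives_exactly_one_two_tag_break(
            self, ref, tag_index, sims):
        read = next(r for r in tw.reads_for_annotation(sims)
                    if r.sim.v_allele.gene_name == "TRBV4-1")
        pos = 101  # interior: >= tag_length from both allele ends
        seq = read.sequence
        mutated = seq[:pos - 1] + _alt(seq, pos) + seq[pos:]
        a = tw.annotate_read(mutated, tag_index)
        breaks = tw.find_tag_breaks(mutated, a, tag_index)
        assert len(breaks) == 1
        o1, o2 = breaks[0].offsets
        assert o1 <= pos - 1 < o2 + 20
        assert o2 - o1 == 10

    def test_error_free_read_has_no_breaks(self, tag_index, sims):
        read = tw.reads_for_annotation(sims[:1])[0]
        a = tw.annotate_read(read.sequence, tag_index)
        assert tw.find_tag_breaks(read.sequence, a, tag_index) == []

    def test_detectability_window_by_exhaustive_scan(self, ref, tag_index,
                                                     sims):
        """Every substitution >= 20 nt from both allele ends knocks out
        exactly two consecutive grid tags (verified against brute-force
        window arithmetic across positions)."""
        read = next(r for r in tw.reads_for_annotation(sims)
                    if r.sim.v_allele.gene_name == "TRBV5-1"
                    and r.sim.v_trim == 0)
        seq = read.sequence
        allele_len = 300
        for pos in range(21, 100, 7):  # sample of interior 1-based positions
            mutated = seq[:pos - 1] + _alt(seq, pos) + seq[pos:]
            a = tw.annotate_read(mutated, tag_index)
            breaks = tw.find_tag_breaks(mutated, a, tag_index)
            # oracle: grid tags covering pos-1
            covering = [o for o in range(0, allele_len - 19, 10)
                        if o <= pos - 1 < o + 20]
            assert len(covering) == 2
            assert len(breaks) == 1 and list(breaks[0].offsets) == covering

    def test_near_start_snv_is_single_tag_failure_not_break(
            self, tag_index, sims):
        read = next(r for r in tw.reads_for_annotation(sims)
                    if r.sim.v_allele.gene_name == "TRBV6-1")
        seq = read.sequence
        mutated = seq[:5] + _alt(seq, 6) + seq[6:]
        a = tw.annotate_read(mutated, tag_index)
        assert tw.find_tag_breaks(mutated, a, tag_index) == []


def _donor(ref, gene, n, carrier_fraction, seed, position=101,
           reads_per_sim=1, carrier_reads_per_sim=None):
    """Build one donor's reads with an injected SNV on ``gene``."""
    beta_js = ["TRBJ1-1*01", "TRBJ1-2*01", "TRBJ2-1*01", "TRBJ2-2*01"]
    sims = tw.simulate_repertoire(ref, tw.SimParams(
        n=n, seed=seed, v_alleles=[f"{gene}*01"], j_alleles=beta_js))
    v_seq = ref.get(gene, "01", tw.SegmentType.VARIABLE).sequence
    alt = _alt(v_seq, position)
    reads = tw.inject_snv_reads(
        sims, ref, gene, position, alt, carrier_fraction, seed=seed + 1,
        reads_per_sim=reads_per_sim,
        carrier_reads_per_sim=carrier_reads_per_sim)
    return reads, alt


def _infer(ref, tag_index, reads):
    annotated = tw.annotate_reads([(r.read_id, r.sequence) for r in reads],
                                  tag_index)
    return tw.infer_novel_alleles(annotated, ref, tag_index)


class TestInferNovelAlleles:
    def test_passing_donor_yields_one_named_candidate(self, ref, tag_index):
        reads, alt = _donor(ref, "TRBV1-1", n=20, carrier_fraction=0.2,
                            seed=40)
        cands = _infer(ref, tag_index, reads)
        assert len(cands) == 1
        cand = cands[0]
        ref_base = ref.get("TRBV1-1", "01",
                           tw.SegmentType.VARIABLE).sequence[100]
        assert cand.identifier == f"TRBV1-1*01_{ref_base}101{alt}"
        assert cand.position == 101
        assert cand.supporting_recombinations >= 3

    def test_too_few_gene_recombinations_fails(self, ref, tag_index):
        # 9 distinct recombinations < 10 although every other criterion holds
        reads, _ = _donor(ref, "TRBV1-1", n=9, carrier_fraction=0.34,
                          seed=41)
        assert _infer(ref, tag_index, reads) == []

    def test_low_read_fraction_fails(self, ref, tag_index):
        # ~4% of gene reads < 5%; 3 unique recombinations keeps iii passing
        reads, _ = _donor(ref, "TRBV1-1", n=75, carrier_fraction=0.04,
                          seed=42)
        carriers = sum(r.carrier for r in reads)
        assert carriers / len(reads) < 0.05 and carriers >= 3
        assert _infer(ref, tag_index, reads) == []

    def test_too_few_unique_recombinations_fails(self, ref, tag_index):
        # 2 carrier recombinations over-sampled to pass the read fraction
        reads, _ = _donor(ref, "TRBV1-1", n=40, carrier_fraction=0.05,
                          seed=43, carrier_reads_per_sim=2)
        carriers = sum(r.carrier for r in reads)
        assert carriers / len(reads) >= 0.05
        assert len({r.sim.name for r in reads if r.carrier}) == 2
        assert _infer(ref, tag_index, reads) == []

    def test_low_break_fraction_fails(self, ref, tag_index):
        # noise SNVs at scattered positions dilute the break-read pool so
        # the variant is < 10% of break reads while >= 5% of gene reads
        reads, _ = _donor(ref, "TRBV1-1", n=100, carrier_fraction=0.06,
                          seed=44)
        noisy = []
        n_noise = 0
        for read in reads:
            if not read.carrier and n_noise < 70:
                pos = 131 + n_noise  # one distinct error position per read
                noisy.append(tw.apply_snv(read, pos, _alt(read.sequence, pos)))
                n_noise += 1
            else:
                noisy.append(read)
        cands = _infer(ref, tag_index, noisy)
        assert cands == []

    def test_two_variants_in_top_two_both_recovered(self, ref, tag_index):
        beta_js = ["TRBJ1-1*01", "TRBJ1-2*01", "TRBJ2-1*01", "TRBJ2-2*01"]
        sims = tw.simulate_repertoire(ref, tw.SimParams(
            n=30, seed=45, v_alleles=["TRBV6-1*01"], j_alleles=beta_js))
        v_seq = ref.get("TRBV6-1", "01", tw.SegmentType.VARIABLE).sequence
        reads = []
        for i, sim in enumerate(sims):
            base = tw.SimRead(read_id=f"{sim.name}/r",
                              sequence=sim.full_nt[sim.leader_len:], sim=sim)
            if i < 6:
                reads.append(tw.apply_snv(base, 101, _alt(v_seq, 101)))
            elif i < 12:
                reads.append(tw.apply_snv(base, 151, _alt(v_seq, 151)))
            else:
                reads.append(base)
        cands = _infer(ref, tag_index, reads)
        assert {c.position for c in cands} == {101, 151}


class TestAugmentReference:
    def test_round_trip_annotation_calls_novel_allele(self, ref, tag_index):
        reads, alt = _donor(ref, "TRBV2-1", n=20, carrier_fraction=0.25,
                            seed=50)
        cands = _infer(ref, tag_index, reads)
        assert len(cands) == 1
        augmented = tw.augment_reference(ref, cands)
        rec, _ = tw.resolve_segment(augmented, cands[0].identifier,
                                    tw.SegmentType.VARIABLE)
        assert rec.sequence[cands[0].position - 1] == cands[0].alt_base
        new_index = tw.build_tag_index(augmented)
        carrier = next(r for r in reads if r.carrier)
        a = tw.annotate_read(carrier.sequence, new_index)
        assert a.v_calls == [cands[0].identifier]

    def test_stitching_with_novel_allele_carries_variant_base(
            self, ref, tag_index):
        reads, alt = _donor(ref, "TRBV2-1", n=20, carrier_fraction=0.25,
                            seed=50)
        cands = _infer(ref, tag_index, reads)
        augmented = tw.augment_reference(ref, cands)
        carrier = next(r for r in reads if r.carrier)
        sim = carrier.sim
        req = tw.StitchRequest(cands[0].identifier, str(sim.j_allele),
                               sim.junction_aa, mode="AA")
        result = tw.stitch(req, augmented)
        a, _ = result.offsets["v_germline"]
        assert result.sequence[a + cands[0].position - 1] == cands[0].alt_base
        # the inferred allele has no leader of its own: *01 fallback fires
        assert any(w.code == "leader_fallback" for w in result.warnings)

    def test_empty_candidate_list_leaves_reference_unchanged(self, ref):
        augmented = tw.augment_reference(ref, [])
        assert augmented.checksum() == ref.checksum()

    def test_identifier_collision_errors(self, ref, tag_index):
        reads, _ = _donor(ref, "TRBV2-1", n=20, carrier_fraction=0.25,
                          seed=50)
        cands = _infer(ref, tag_index, reads)
        with pytest.raises(tw.AnnotationError, match="duplicate"):
            tw.augment_reference(ref, cands + cands)
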