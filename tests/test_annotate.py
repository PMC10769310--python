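"""Homology hits, defragmentation, classification, structural detection."""

import numpy as np
import pytest

from retrotrace.annotate import (
    LTRParams,
    classify_elements,
    defragment_hits,
    detect_ltr_candidates,
    extract_fle_internal,
    find_repeat_hits,
    select_best_calls,
)
from retrotrace.models import mutate_sequence, ltr_protected_sites, random_dna, random_te_model, revcomp


@pytest.fixture(scope="module")
def te():
    return random_te_model("Ty4", np.random.default_rng(1))


@pytest.fixture(scope="module")
def rng():
    return np.random.default_rng(2)


class TestFindRepeatHits:
    def test_exact_internal_copy_found_at_full_identity(self, te, rng):
        genome = {"c": random_dna(3000, rng) + te.internal_seq + random_dna(3000, rng)}
        hits = [h for h in find_repeat_hits(genome, [te]) if h.region == "internal"]
        assert len(hits) == 1
        h = hits[0]
        assert h.percent_identity == 100.0
        assert (h.qstart, h.qend) == (0, te.internal_length)
        assert h.strand == "+"

    def test_five_percent_divergence_measured(self, te, rng):
        copy = mutate_sequence(te.internal_seq, 0.052, rng)  # ~5% observed
        genome = {"c": random_dna(2000, rng) + copy + random_dna(2000, rng)}
        hits = [h for h in find_repeat_hits(genome, [te]) if h.region == "internal"]
        assert len(hits) == 1
        assert hits[0].percent_identity == pytest.approx(95.0, abs=1.5)

    def test_reverse_complement_copy_on_minus_strand(self, te, rng):
        left = random_dna(2500, rng)
        genome = {"c": left + revcomp(te.internal_seq) + random_dna(2500, rng)}
        hits = [h for h in find_repeat_hits(genome, [te]) if h.region == "internal"]
        assert len(hits) == 1
        h = hits[0]
        assert h.strand == "-"
        assert (h.start, h.end) == (2500, 2500 + te.internal_length)

    def test_empty_genome_rejected(self, te):
        with pytest.raises(ValueError):
            find_repeat_hits({}, [te])


class TestDefragment:
    def test_adjacent_ltr_internal_ltr_one_chain(self, te, rng):
        genome = {"c": random_dna(1000, rng) + te.full_sequence + random_dna(1000, rng)}
        hits = find_repeat_hits(genome, [te])
        chains = defragment_hits(hits, {"Ty4": te})
        assert len(chains) == 1
        assert [h.region for h in chains[0].hits] == ["LTR", "internal", "LTR"]

    def test_distant_hits_not_chained(self, te, rng):
        genome = {
            "c": random_dna(1000, rng)
            + te.internal_seq[:1000]
            + random_dna(10_000, rng)
            + te.internal_seq[3000:4000]
            + random_dna(1000, rng)
        }
        hits = find_repeat_hits(genome, [te])
        chains = defragment_hits(hits, {"Ty4": te})
        assert len(chains) == 2

    def test_non_monotone_query_order_not_merged(self, te, rng):
        # 3' fragment placed before 5' fragment: co-linearity is violated
        genome = {
            "c": random_dna(1000, rng)
            + te.internal_seq[3000:4000]
            + random_dna(100, rng)
            + te.internal_seq[:1000]
            + random_dna(1000, rng)
        }
        hits = find_repeat_hits(genome, [te])
        chains = defragment_hits(hits, {"Ty4": te})
        assert len(chains) == 2


class TestClassify:
    def _calls(self, genome, te):
        hits = find_repeat_hits(genome, [te])
        chains = defragment_hits(hits, {"Ty4": te})
        return classify_elements(chains, {"Ty4": te})

    def test_full_planted_element_is_fle(self, te, rng):
        genome = {"c": random_dna(800, rng) + te.full_sequence + random_dna(800, rng)}
        calls = self._calls(genome, te)
        assert [c.clazz for c in calls] == ["FLE"]
        assert calls[0].fraction_of_canonical == pytest.approx(1.0, abs=0.02)

    def test_lone_ltr_is_solo(self, te, rng):
        genome = {"c": random_dna(800, rng) + te.ltr_seq + random_dna(800, rng)}
        calls = self._calls(genome, te)
        assert [c.clazz for c in calls] == ["soloLTR"]

    def test_internal_fragment_is_truncated(self, te, rng):
        genome = {"c": random_dna(800, rng) + te.internal_seq[1000:3000] + random_dna(800, rng)}
        calls = self._calls(genome, te)
        assert [c.clazz for c in calls] == ["truncated"]

    def test_classification_matches_truth_on_simulated_world(self, annotation_world):
        truth, genomes = annotation_world["truth"], annotation_world["genomes"]
        te_models = truth.te_models
        for strain in truth.strains:
            g = genomes[strain]
            hits = find_repeat_hits({strain: g.sequence}, list(te_models.values()))
            chains = defragment_hits(hits, te_models)
            calls = classify_elements(chains, te_models)
            expected = sorted((int(p.start), p.element.clazz) for p in g.placements)
            got = sorted((c.start, c.clazz) for c in calls)
            assert len(got) == len(expected)
            for (es, ec), (gs_, gc) in zip(expected, got):
                assert gc == ec and abs(gs_ - es) < 100


class TestStructuralDetection:
    def test_planted_identical_pair_with_tsd_and_motif(self, rng):
        ltr = "TG" + random_dna(296, rng) + "CA"
        tsd = "ACGTG"
        genome = {
            "c": random_dna(3000, rng) + tsd + ltr + random_dna(4700, rng) + ltr + tsd
            + random_dna(3000, rng)
        }
        cands = detect_ltr_candidates(genome)
        assert len(cands) == 1
        c = cands[0]
        assert c.similarity == 100.0
        assert c.tsd == (tsd, tsd)
        assert c.ltr3[0] - c.ltr5[0] == 5000

    def test_pair_below_min_distance_rejected(self, rng):
        ltr = "TG" + random_dna(296, rng) + "CA"
        tsd = "ACGTG"
        genome = {"c": random_dna(3000, rng) + tsd + ltr + random_dna(700, rng) + ltr + tsd
                  + random_dna(3000, rng)}
        assert detect_ltr_candidates(genome) == []

    def test_pair_below_similarity_rejected(self, rng):
        ltr = "TG" + random_dna(296, rng) + "CA"
        diverged = mutate_sequence(ltr, 0.30, rng, ltr_protected_sites(300))
        tsd = "ACGTG"
        genome = {"c": random_dna(3000, rng) + tsd + ltr + random_dna(4700, rng) + diverged
                  + tsd + random_dna(3000, rng)}
        assert detect_ltr_candidates(genome) == []

    def test_recall_on_simulated_flrs_and_clean_background(self, annotation_world):
        truth, genomes = annotation_world["truth"], annotation_world["genomes"]
        n = hit = 0
        for strain in truth.strains:
            g = genomes[strain]
            cands = detect_ltr_candidates({strain: g.sequence})
            for p in g.placements:
                if p.element.clazz != "FLE":
                    continue
                ltr5, ltr3 = p.element.parts[0].seq, p.element.parts[-1].seq
                div = sum(a != b for a, b in zip(ltr5, ltr3)) / len(ltr5)
                if div > 0.10:
                    continue
                n += 1
                hit += any(
                    abs(c.span[0] - p.start) < 100 and abs(c.span[1] - p.end) < 100
                    for c in cands
                )
        assert n > 0 and hit / n >= 0.95


class TestExtraction:
    def test_planted_fle_internal_recovered_exactly(self, te, rng):
        evolved_int = mutate_sequence(te.internal_seq, 0.05, rng)
        element = te.ltr_seq + evolved_int + te.ltr_seq
        genome = {"c": random_dna(900, rng) + element + random_dna(900, rng)}
        hits = find_repeat_hits(genome, [te])
        calls = classify_elements(defragment_hits(hits, {"Ty4": te}), {"Ty4": te})
        out = extract_fle_internal(calls, genome, {"Ty4": te})
        assert list(out.values()) == [evolved_int]

    def test_minus_strand_output_is_reverse_complemented(self, te, rng):
        evolved_int = mutate_sequence(te.internal_seq, 0.05, rng)
        element = revcomp(te.ltr_seq + evolved_int + te.ltr_seq)
        genome = {"c": random_dna(900, rng) + element + random_dna(900, rng)}
        hits = find_repeat_hits(genome, [te])
        calls = classify_elements(defragment_hits(hits, {"Ty4": te}), {"Ty4": te})
        assert [c.strand for c in calls] == ["-"]
        out = extract_fle_internal(calls, genome, {"Ty4": te})
        assert list(out.values()) == [evolved_int]

    def test_solo_ltr_yields_no_output(self, te, rng):
        genome = {"c": random_dna(900, rng) + te.ltr_seq + random_dna(900, rng)}
        hits = find_repeat_hits(genome, [te])
        calls = classify_elements(defragment_hits(hits, {"Ty4": te}), {"Ty4": te})
        assert extract_fle_internal(calls, genome, {"Ty4": te}) == {}


def test_sister_subfamily_competition_resolved(rng):
    from retrotrace.models import diverged_te_model

    base = random_te_model("Ty4", np.random.default_rng(9))
    sister = diverged_te_model(base, "Tsu4", 0.12, np.random.default_rng(10))
    genome = {"c": random_dna(1000, rng) + sister.full_sequence + random_dna(1000, rng)}
    te_models = {"Ty4": base, "Tsu4": sister}
    hits = find_repeat_hits(genome, list(te_models.values()))
    calls = classify_elements(defragment_hits(hits, te_models), te_models)
    best = select_best_calls(calls)
    assert len(best) == 1
    assert best[0].subfamily == "Tsu4"
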