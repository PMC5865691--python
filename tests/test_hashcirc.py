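import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from circkit.hashcirc import (
    HashCircParams,
    KmerIndex,
    count_reads,
    exhaustive_counts,
    generate_kmers,
    hashcirc_run,
    quantify_sample,
    select_reads,
    smith_waterman,
)
from circkit.junction import JunctionParams, build_all
from circkit.model import revcomp
from circkit.simulate import simulate_reads, write_fastq

from _oracles import gotoh_local_score, naive_kmers, naive_shared_count

DNA = st.text(alphabet="ACGT", min_size=0, max_size=60)


class TestGenerateKmers:
    def test_worked_example(self):
        assert generate_kmers("ATCCCGTC", 3) == ["ATC", "TCC", "CCC", "CCG", "CGT", "GTC"]

    def test_shorter_than_k_is_empty(self):
        assert generate_kmers("ACG", 5) == []

    def test_repeats_preserved_positionally(self):
        assert generate_kmers("AAAA", 2) == ["AA", "AA", "AA"]

    @settings(derandomize=True, max_examples=50)
    @given(seq=DNA, k=st.integers(1, 8))
    def test_sliding_window_properties(self, seq, k):
        kmers = generate_kmers(seq, k)
        assert kmers == naive_kmers(seq, k)
        assert len(kmers) == max(0, len(seq) - k + 1)
        assert all(seq[i : i + k] == m for i, m in enumerate(kmers))


class TestKmerIndex:
    def test_worked_example_membership(self):
        params = HashCircParams(k=3, stranded=True, n_min=0, m_min=0)
        idx = KmerIndex.build({"r": "ATCCCGTC"}, params)
        assert idx.is_present("CCC")
        assert not idx.is_present("GGG")

    def test_unstranded_index_contains_reverse_complements(self):
        params = HashCircParams(k=3, n_min=0, m_min=0)
        idx = KmerIndex.build({"r": "ATCCCGTC"}, params)
        assert idx.is_present(revcomp("ATC"))

    def test_union_of_two_references_equals_brute_force(self):
        rng = np.random.default_rng(0)
        a = "".join(rng.choice(list("ACGT"), 50))
        b = "".join(rng.choice(list("ACGT"), 50))
        params = HashCircParams(k=6, stranded=True, n_min=0, m_min=0)
        idx = KmerIndex.build({"a": a, "b": b}, params)
        union = set(naive_kmers(a, 6)) | set(naive_kmers(b, 6))
        probe = {"".join(rng.choice(list("ACGT"), 6)) for _ in range(500)} | union
        for m in probe:
            assert idx.is_present(m) == (m in union)

    def test_kmers_containing_n_never_indexed(self):
        params = HashCircParams(k=3, stranded=True, n_min=0, m_min=0)
        idx = KmerIndex.build({"r": "ANCGT"}, params)
        assert not idx.is_present("ANC")
        assert idx.is_present("CGT")

    def test_all_references_shorter_than_k_error(self):
        with pytest.raises(ValueError, match="shorter than k"):
            KmerIndex.build({"r": "ACG"}, HashCircParams(k=10, n_min=0, m_min=0))

    def test_empty_reference_set_error(self):
        with pytest.raises(ValueError, match="empty"):
            KmerIndex.build({}, HashCircParams())


class TestSelectReads:
    def test_substring_read_selected_with_brute_force_count(self):
        rng = np.random.default_rng(1)
        ref = "".join(rng.choice(list("ACGT"), 120))
        read = ref[30:70]  # 40-nt exact substring
        params = HashCircParams(k=21, n_min=17, m_min=0, stranded=True)
        idx = KmerIndex.build({"r": ref}, params)
        shared = naive_shared_count(read, set(naive_kmers(ref, 21)), 21)
        assert shared == 20
        assert list(select_reads([("q", read)], idx, params)) == [("q", read)]

    def test_unrelated_read_not_selected(self):
        params = HashCircParams(k=5, n_min=1, m_min=0, stranded=True)
        idx = KmerIndex.build({"r": "ACACACACACACAC"}, params)
        read = "GGGGGTTTTTGGGGGTTTTT"
        assert naive_shared_count(read, set(naive_kmers("ACACACACACACAC", 5)), 5) == 0
        assert list(select_reads([("q", read)], idx, params)) == []

    def test_zero_threshold_selects_every_long_enough_read(self):
        params = HashCircParams(k=5, n_min=0, m_min=0, stranded=True)
        idx = KmerIndex.build({"r": "ACGTACGTAC"}, params)
        reads = [("a", "TTTTTTTT"), ("b", "ACG")]  # b shorter than k
        assert [n for n, _ in select_reads(reads, idx, params)] == ["a"]

    def test_strict_gt_flag_shifts_threshold_by_one(self):
        rng = np.random.default_rng(2)
        ref = "".join(rng.choice(list("ACGT"), 60))
        read = ref[10:36]  # 26 nt -> 6 shared 21-mers
        base = dict(k=21, m_min=0, stranded=True)
        idx = KmerIndex.build({"r": ref}, HashCircParams(n_min=6, **base))
        assert list(select_reads([("q", read)], idx, HashCircParams(n_min=6, **base)))
        strict = HashCircParams(n_min=6, strict_gt=True, **base)
        assert not list(select_reads([("q", read)], idx, strict))

    def test_selection_is_order_preserving(self):
        params = HashCircParams(k=3, n_min=1, m_min=0, stranded=True)
        idx = KmerIndex.build({"r": "AAACCC"}, params)
        reads = [("r1", "AAAT"), ("r2", "GGGG"), ("r3", "TCCC")]
        assert [n for n, _ in select_reads(reads, idx, params)] == ["r1", "r3"]


class TestSmithWaterman:
    def test_identical_strings_score_twice_length(self):
        s = "ACGTACGTACGTACGTACGT"
        assert smith_waterman(s, s) == 40

    def test_disjoint_alphabets_score_zero(self):
        assert smith_waterman("AAAA", "CCCC") == 0

    def test_single_mismatch_matches_dp_oracle(self):
        rng = np.random.default_rng(3)
        a = "".join(rng.choice(list("ACGT"), 30))
        b = a[:14] + ("A" if a[14] != "A" else "C") + a[15:]
        assert smith_waterman(a, b) == gotoh_local_score(a, b)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(a=st.text(alphabet="ACGT", min_size=1, max_size=30),
           b=st.text(alphabet="ACGT", min_size=1, max_size=30))
    def test_agrees_with_gotoh_oracle(self, a, b):
        assert smith_waterman(a, b) == gotoh_local_score(a, b)

    def test_gap_convention_open_covers_first_base(self):
        # b is a with one base deleted: 15 matches (30) minus a length-1 gap (3)
        a = "AACCGGTTAACCGGTT"
        b = "AACCGGTTACCGGTT"
        assert smith_waterman(a, b) == 27 == gotoh_local_score(a, b)


def _junction_fixture(reference, planted, n=10, L=35):
    circs, truth = planted
    multi = [c for c in circs
             if truth.set_index("circ_id").loc[c.circ_id, "category"] == "multiexonic"]
    js = build_all(multi[:n], reference.genome, JunctionParams(L))
    return {j.circ_id: j.sequence for j in js}, [j for j in js]


class TestCountReads:
    def test_exact_window_reads_count_one_each(self, toy_reference, planted):
        refs, js = _junction_fixture(toy_reference, planted)
        reads = [
            (f"q{j.circ_id}", j.sequence[10:60]) for j in js  # 50 nt centered windows
        ]
        params = HashCircParams(k=21, n_min=17, m_min=40)
        counts, stats = count_reads(reads, refs, params)
        assert all(counts[j.circ_id] == 1 for j in js)
        assert stats["counted"] == len(js)

    def test_tie_between_duplicate_references_goes_to_smaller_id(self):
        seq = "ACGT" * 20
        refs = {"b_dup": seq, "a_dup": seq}
        params = HashCircParams(k=21, n_min=0, m_min=10)
        counts, _ = count_reads([("q", seq[10:60])], refs, params)
        assert counts == {"a_dup": 1, "b_dup": 0}

    def test_linear_reads_uncounted_at_specificity_threshold(self, toy_reference, planted):
        """Reads from the linear transcript never cross a back-splice; with
        M >= L+5 matched bases a full one-flank match (35) cannot count."""
        from circkit.simulate import spliced_sequence

        refs, js = _junction_fixture(toy_reference, planted)
        circs, truth = planted
        rng = np.random.default_rng(4)
        reads = []
        for t in toy_reference.transcripts:
            s = spliced_sequence(toy_reference, t)
            for i in range(20):
                pos = int(rng.integers(0, len(s) - 50))
                reads.append((f"{t.transcript_id}:{i}", s[pos : pos + 50]))
        params = HashCircParams(k=21, n_min=0, m_min=40)  # n_min=0: alignment-only
        counts, _ = count_reads(reads, refs, params)
        assert sum(counts.values()) == 0

    def test_reverse_complement_invariance_unstranded(self, toy_reference, planted):
        refs, js = _junction_fixture(toy_reference, planted, n=5)
        reads = [(f"q{i}", j.sequence[5:55]) for i, j in enumerate(js[:5])]
        params = HashCircParams(k=21, n_min=17, m_min=30)
        fwd, _ = count_reads(reads, refs, params)
        rc, _ = count_reads([(n, revcomp(s)) for n, s in reads], refs, params)
        assert fwd == rc

    def test_monotonicity_in_n_and_m(self, toy_reference, planted, toy_spec):
        refs, js = _junction_fixture(toy_reference, planted, n=5)
        circs, truth = planted
        multi = [c for c in circs if c.circ_id in refs]
        reads_by_sample, _ = simulate_reads(
            toy_reference, multi, toy_spec, host_gene_ids=[]
        )
        reads = reads_by_sample["sample1"][:400]
        base = None
        for n_min, m_min in [(0, 0), (6, 20), (17, 40), (25, 50)]:
            params = HashCircParams(k=21, n_min=n_min, m_min=m_min)
            counts, stats = quantify_sample(iter(reads), refs, params)
            total = sum(counts.values())
            assert stats["counted"] <= stats["selected"] <= stats["scanned"]
            if base is not None:
                assert all(counts[k] <= base[k] for k in refs)
            base = counts


class TestRun:
    def test_two_samples_recover_truth_exactly(self, toy_reference, planted, toy_spec):
        import dataclasses

        circs, truth = planted
        multi = [c for c in circs
                 if truth.set_index("circ_id").loc[c.circ_id, "category"] == "multiexonic"]
        spec = dataclasses.replace(
            toy_spec, bs_depth=5, linear_reads=50, background_reads=20, error_rate=0.0,
            circs_per_category={"multiexonic": len(multi)}, linear_source="nonhost",
        )
        reads, truth_counts = simulate_reads(
            toy_reference, multi, spec, samples=("s1", "s2"),
            host_gene_ids=truth.attrs.get("host_gene_ids", []),
        )
        js = build_all(multi, toy_reference.genome, JunctionParams(35))
        refs = {j.circ_id: j.sequence for j in js}
        params = HashCircParams(k=21, n_min=17, m_min=30)
        table = hashcirc_run(reads, refs, params)
        assert (table.counts.loc[truth_counts.index] == truth_counts).all().all()

    def test_empty_fastq_gives_zero_column(self, toy_reference, planted, tmp_path):
        refs, _ = _junction_fixture(toy_reference, planted, n=3)
        empty = tmp_path / "empty.fq"
        empty.write_text("")
        table = hashcirc_run({"e": str(empty)}, refs, HashCircParams())
        assert (table.counts["e"] == 0).all()

    def test_deterministic_tsv_output(self, toy_reference, planted, toy_spec, tmp_path):
        refs, js = _junction_fixture(toy_reference, planted, n=4)
        circs, truth = planted
        multi = [c for c in circs if c.circ_id in refs]
        reads, _ = simulate_reads(toy_reference, multi, toy_spec, host_gene_ids=[])
        sample = reads["sample1"][:200]
        fq = tmp_path / "s.fq"
        write_fastq(sample, fq)
        params = HashCircParams(k=15, n_min=6, m_min=40)
        outs = []
        for name in ("a.tsv", "b.tsv"):
            table = hashcirc_run({"s": str(fq)}, refs, params)
            table.write_tsv(tmp_path / name)
            outs.append((tmp_path / name).read_bytes())
        assert outs[0] == outs[1]

    def test_unreadable_sample_continues_and_flags_failure(self, toy_reference, planted, tmp_path):
        refs, js = _junction_fixture(toy_reference, planted, n=3)
        good = tmp_path / "good.fq"
        write_fastq([("q1", js[0].sequence[10:60])], good)
        table = hashcirc_run(
            {"good": str(good), "bad": str(tmp_path / "missing.fq")},
            refs,
            HashCircParams(k=21, n_min=17, m_min=20),
            on_error="continue",
        )
        assert "good" in table.counts.columns
        assert "bad" not in table.counts.columns
        assert "bad" in table.stats["_failures"]

    def test_filtered_pipeline_matches_exhaustive_on_clean_reads(
        self, toy_reference, planted
    ):
        refs, js = _junction_fixture(toy_reference, planted, n=8)
        reads = [(f"q{i}", j.sequence[8:58]) for i, j in enumerate(js[:8])]
        reads += [("bg1", ("ACGTTGCA" * 7)[:50])]
        params = HashCircParams(k=21, n_min=17, m_min=30)
        counts, _ = quantify_sample(iter(reads), refs, params)
        assert counts == exhaustive_counts(reads, refs, params)
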