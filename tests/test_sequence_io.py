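"""Read parsing, demultiplexing, reference matching and allele tabulation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from aeiscope import sequence_io as sio
from aeiscope import synthetic_data as synth
from aeiscope.sequence_io import (
    AmpliconReference,
    Demultiplexer,
    ReferenceLibrary,
    SampleIndex,
    revcomp,
)


class TestSampleIndex:
    @pytest.mark.parametrize(
        "seq",
        ["ACGT", "ACGTAA", "ACGTX", "ACGTT", "acgta"],
        ids=["short", "long", "non-dna", "redundancy-broken", "lowercase"],
    )
    def test_invalid_indices_rejected(self, seq):
        with pytest.raises(ValueError):
            SampleIndex("S1", seq)

    def test_valid_index(self):
        assert SampleIndex("S1", "ACGTA").index_seq == "ACGTA"


class TestDemultiplex:
    def test_exact_match_assigns(self):
        idx = [SampleIndex("S1", "ACGTA"), SampleIndex("S2", "TGCAT")]
        assert sio.demultiplex("ACGTA" + "AAAA", idx) == "S1"

    def test_one_mismatch_unassigned_in_exact_mode(self):
        idx = [SampleIndex("S1", "ACGTA")]
        assert sio.demultiplex("ACGTT" + "AAAA", idx, mode="exact") is None

    def test_redundant_position_error_corrected(self):
        # the 5th base disagrees but positions 1/5 are redundant, so a single
        # mismatch there is exactly what the redundancy is designed to absorb
        idx = [SampleIndex("S1", "ACGTA")]
        assert sio.demultiplex("ACGTT" + "AAAA", idx, mode="correct") == "S1"

    def test_interior_mismatch_requires_intact_redundancy(self):
        idx = [SampleIndex("S1", "ACGTA")]
        # interior error with matching 1st/5th read bases: trusted
        assert sio.demultiplex("AAGTA" + "AAAA", idx, mode="correct") == "S1"
        # interior error AND broken read redundancy: two errors, untrusted
        assert sio.demultiplex("AAGTC" + "AAAA", idx, mode="correct") is None

    def test_tie_never_assigned_arbitrarily(self):
        idx = [SampleIndex("S1", "AAATA"), SampleIndex("S2", "AATAA")]
        # equidistant (1 mismatch each) from this prefix
        assert sio.demultiplex("AAAAA" + "CCCC", idx, mode="correct") is None

    def test_duplicate_indices_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            Demultiplexer([SampleIndex("S1", "ACGTA"), SampleIndex("S2", "ACGTA")])

    def test_every_single_substitution_recovered_or_dropped(self):
        """Exhaustive oracle: any 1-error index prefix is either corrected to
        the planted sample or left unassigned — never cross-assigned."""
        indices = synth.generate_indices(12, seed=3, min_distance=3)
        demux = Demultiplexer(indices, mode="correct")
        n_recovered = n_total = 0
        for idx in indices:
            for pos in range(5):
                for base in "ACGT":
                    if base == idx.index_seq[pos]:
                        continue
                    prefix = idx.index_seq[:pos] + base + idx.index_seq[pos + 1 :]
                    hit = demux.assign(prefix + "ACGTACGT")
                    assert hit in (idx.sample_id, None)
                    n_total += 1
                    n_recovered += hit == idx.sample_id
        # at pairwise distance >= 3, every single error is actually corrected
        assert n_recovered == n_total

    def test_planted_indices_with_substitution_errors(self, rng):
        """1% per-base errors: >=99% of reads recovered; cross-assignment
        requires a coordinated >=2-error hit and stays at the ~1e-4 level."""
        indices = synth.generate_indices(12, seed=3, min_distance=3)
        demux = Demultiplexer(indices, mode="correct")
        n = 10_000
        planted = rng.choice(len(indices), size=n)
        assigned = cross = 0
        for i in planted:
            prefix = list(indices[i].index_seq)
            err = np.flatnonzero(rng.random(5) < 0.01)
            for p in err:
                prefix[p] = str(rng.choice([b for b in "ACGT" if b != prefix[p]]))
            hit = demux.assign("".join(prefix) + "ACGTACGT")
            if hit is not None:
                assigned += 1
                if hit != indices[i].sample_id:
                    cross += 1
                    assert len(err) >= 2  # single errors can never cross-assign
        assert assigned / n >= 0.99
        assert cross <= 3


class TestParseFastq:
    def test_roundtrip(self, tmp_path):
        p = tmp_path / "x.fastq"
        p.write_text("@r1\nACGTACGT\n+\nIIIIIIII\n@r2 extra\nACGT\n+\nIIII\n")
        recs = list(sio.parse_fastq(p))
        assert recs == [("r1", "ACGTACGT", "IIIIIIII"), ("r2", "ACGT", "IIII")]

    def test_empty_file(self, tmp_path):
        p = tmp_path / "e.fastq"
        p.write_text("")
        assert list(sio.parse_fastq(p)) == []

    def test_malformed_record_names_line(self, tmp_path):
        p = tmp_path / "bad.fastq"
        p.write_text("@r1\nACGT\n+\nIIII\n@r2\nACGT\n+\n")
        with pytest.raises(ValueError, match="line 5"):
            list(sio.parse_fastq(p))


class TestMatchRead:
    def test_identity_and_orientation(self, small_refs):
        lib = ReferenceLibrary.from_references(small_refs)
        r = small_refs[2]
        assert lib.match(r.amplicon_seq) == (r.gene, "forward")
        assert lib.match(revcomp(r.amplicon_seq)) == (r.gene, "reverse")

    def test_short_and_garbage_reads_rejected(self, small_refs):
        lib = ReferenceLibrary.from_references(small_refs)
        assert lib.match("ACGT") is None
        assert lib.match("AC" * 40) is None  # low identity to everything

    def test_library_cardinality(self):
        assert ReferenceLibrary.cardinality(52, 74) == 7696

    def test_agrees_with_exhaustive_hamming_search(self, rng):
        """5,000 noisy reads from 10 equal-length genes vs a brute-force oracle."""
        refs = synth.generate_reference(10, seed=4, length_range=(80, 80))
        lib = ReferenceLibrary.from_references(refs)
        entries = [(r.gene, "forward", r.amplicon_seq) for r in refs] + [
            (r.gene, "reverse", revcomp(r.amplicon_seq)) for r in refs
        ]

        def oracle(seq):
            dists = []
            for gene, orient, ref in entries:
                d = sum(a != b for a, b in zip(seq, ref))
                dists.append((d, gene, orient))
            dists.sort(key=lambda t: t[0])
            best = dists[0][0]
            hits = [t for t in dists if t[0] == best]
            if best > round(0.1 * 80):
                return None
            if len({g for _, g, _ in hits}) > 1:
                return None
            orients = [o for _, _, o in hits]
            return (hits[0][1], "forward" if "forward" in orients else orients[0])

        for _ in range(5000):
            r = refs[rng.integers(10)]
            seq = list(r.amplicon_seq if rng.random() < 0.5 else revcomp(r.amplicon_seq))
            for p in np.flatnonzero(rng.random(80) < 0.005):
                seq[p] = str(rng.choice([b for b in "ACGT" if b != seq[p]]))
            seq = "".join(seq)
            assert lib.match(seq) == oracle(seq)


class TestExtractAllele:
    @pytest.fixture
    def ref(self):
        seq = "ACGTACGTAC" * 8  # 80 bp
        return AmpliconReference(
            gene="G1", amplicon_seq=seq, msnp_offset=40,
            allele_M=seq[40], allele_m="C" if seq[40] != "C" else "G",
            numerator_allele="M",
        )

    def test_planted_alleles(self, ref):
        assert sio.extract_allele(ref.amplicon_seq, ref, "forward") == "M"
        s = list(ref.amplicon_seq)
        s[40] = ref.allele_m
        assert sio.extract_allele("".join(s), ref, "forward") == "m"
        s[40] = [b for b in "ACGT" if b not in (ref.allele_M, ref.allele_m)][0]
        assert sio.extract_allele("".join(s), ref, "forward") == "neither"

    def test_truncated_before_msnp_is_missing(self, ref):
        assert sio.extract_allele(ref.amplicon_seq[:40], ref, "forward") == "missing"

    def test_reverse_complement_invariance(self, ref, rng):
        for _ in range(50):
            L = int(rng.integers(46, 81))
            read = ref.amplicon_seq[:L]
            fwd = sio.extract_allele(read, ref, "forward")
            rev = sio.extract_allele(revcomp(read), ref, "reverse")
            assert fwd == rev

    def test_noisy_flank_vetoes_call(self, ref):
        s = list(ref.amplicon_seq)
        for i in (30, 33, 36):  # 3 mismatches in the upstream flank
            s[i] = [b for b in "ACGT" if b != s[i]][0]
        assert sio.extract_allele("".join(s), ref, "forward") == "neither"
        assert (
            sio.extract_allele("".join(s), ref, "forward", max_flank_mismatch=3) == "M"
        )

    def test_planted_mixture_counted_exactly(self, ref):
        reads = []
        s = list(ref.amplicon_seq)
        for i in range(2000):
            s[40] = ref.allele_M if i < 1200 else ref.allele_m
            reads.append("".join(s))
        calls = [sio.extract_allele(r, ref, "forward") for r in reads]
        assert calls.count("M") == 1200 and calls.count("m") == 800


class TestCountReads:
    def _mk_reads(self, indices, refs, per=10):
        reads = []
        for i, idx in enumerate(indices):
            for r in refs:
                for j in range(per):
                    s = list(r.amplicon_seq)
                    s[r.msnp_offset] = r.allele_M if j % 2 == 0 else r.allele_m
                    reads.append((f"x{i}{j}", idx.index_seq + "".join(s), "I"))
        return reads

    def test_count_conservation(self, indices6, small_refs):
        reads = self._mk_reads(indices6, small_refs)
        res = sio.count_reads(reads, indices6, small_refs, template="cDNA")
        assert (res.counts["count_M"] + res.counts["count_m"]).sum() == res.triage.usable
        res.triage.validate()

    def test_genotype_filter_and_exclusions(self, indices6, small_refs):
        reads = self._mk_reads(indices6[:2], small_refs[:1], per=6)
        geno = pd.DataFrame(
            {
                "sample_id": [indices6[0].sample_id],
                "gene": [small_refs[0].gene],
                "genotype": ["Mm"],
            }
        )
        res = sio.count_reads(reads, indices6, small_refs, template="cDNA",
                              genotypes=geno)
        assert len(res.counts) == 1
        assert res.counts.iloc[0]["sample_id"] == indices6[0].sample_id
        reasons = {e["reason"] for e in res.exclusions}
        assert "sample_not_genotyped" in reasons

    def test_single_allele_flagged_for_heterozygote(self, indices6, small_refs):
        r = small_refs[0]
        idx = indices6[0]
        reads = [("a", idx.index_seq + r.amplicon_seq.replace(
            r.amplicon_seq[r.msnp_offset], r.allele_M), "I")]
        # all reads carry one allele although the sample is recorded Mm
        s = list(r.amplicon_seq)
        s[r.msnp_offset] = r.allele_M
        reads = [(f"a{i}", idx.index_seq + "".join(s), "I") for i in range(5)]
        geno = pd.DataFrame(
            {"sample_id": [idx.sample_id], "gene": [r.gene], "genotype": ["Mm"]}
        )
        res = sio.count_reads(reads, indices6, small_refs, template="cDNA",
                              genotypes=geno)
        assert bool(res.counts.iloc[0]["single_allele_only"])
        assert res.triage.single_allele_only == 5


class TestTabulateCounts:
    def test_simple_tabulation(self):
        assigned = [("S1", "G1", "M")] * 100 + [("S1", "G1", "m")] * 50
        res = sio.tabulate_counts(assigned)
        row = res.counts.iloc[0]
        assert (row["count_M"], row["count_m"]) == (100, 50)

    def test_triage_classes(self):
        assigned = (
            [("S1", "G1", "M")] * 3
            + [(None, None, None)] * 2
            + [("S1", "G1", "missing")]
        )
        res = sio.tabulate_counts(assigned)
        assert res.triage.failed_match == 2
        assert res.triage.missing_msnp_base == 1
        assert res.triage.usable == 3


@given(st.text(alphabet="ACGT", min_size=1, max_size=120))
def test_revcomp_is_involution(seq):
    assert revcomp(revcomp(seq)) == seq
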