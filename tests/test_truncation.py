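"""Truncation/transition extraction and candidate detection."""

import numpy as np
import pysam
import pytest

from m6akit.io import GenomicSite
from m6akit.truncation import TruncationTrack, detect_candidates, extract_tracks


def _md_tag(ref, read):
    out, run = [], 0
    for r, q in zip(ref, read):
        if r == q:
            run += 1
        else:
            out.append(str(run)); out.append(r); run = 0
    out.append(str(run))
    return "".join(out)


def _sam(tmp_path, contigs, reads, name="reads.sam"):
    """Write a SAM file; reads are (flag, chrom, start0, read_seq, ref_seq)."""
    lines = ["@HD\tVN:1.6"]
    for chrom, length in contigs.items():
        lines.append(f"@SQ\tSN:{chrom}\tLN:{length}")
    for i, (flag, chrom, start, read, ref) in enumerate(reads):
        md = _md_tag(ref, read)
        nm = sum(a != b for a, b in zip(ref, read))
        lines.append(
            f"r{i}\t{flag}\t{chrom}\t{start + 1}\t255\t{len(read)}M\t*\t0\t0\t{read}"
            f"\t{'I' * len(read)}\tNM:i:{nm}\tMD:Z:{md}"
        )
    path = tmp_path / name
    path.write_text("\n".join(lines) + "\n")
    return str(path)


REF30 = "ACGTACGTACGTACGTACGTACGTACGTAC"


class TestExtractTracks:
    def test_plus_strand_shift_one_upstream(self, tmp_path):
        path = _sam(tmp_path, {"chr1": 1000}, [(0, "chr1", 100, REF30, REF30)])
        track = extract_tracks(path)
        assert track.truncations[("chr1", "+")] == {99: 1}

    def test_minus_strand_shift(self, tmp_path):
        path = _sam(tmp_path, {"chr1": 1000}, [(16, "chr1", 200, REF30, REF30)])
        track = extract_tracks(path)
        # aligned [200,230): 5' end at 229, crosslink one nt upstream = 230
        assert track.truncations[("chr1", "-")] == {230: 1}

    def test_ct_read_goes_to_transition_channel_only(self, tmp_path):
        ref = "AACCGGTTAA"
        read = "AACTGGTTAA"  # C->T at offset 3 -> genomic 150+3
        path = _sam(tmp_path, {"chr1": 1000}, [(0, "chr1", 150, read, ref)])
        track = extract_tracks(path)
        assert track.transitions[("chr1", "+")] == {153: 1}
        assert not track.truncations
        assert track.n_transition_reads == 1 and track.n_truncation_reads == 0

    def test_minus_strand_ct_is_g_to_a(self, tmp_path):
        ref = "AAGGGGTTAA"
        read = "AAGAGGTTAA"  # ref G read A on a minus-strand read = C->T in read space
        path = _sam(tmp_path, {"chr1": 1000}, [(16, "chr1", 150, read, ref)])
        track = extract_tracks(path)
        assert track.transitions[("chr1", "-")] == {153: 1}
        # the same mismatch on a plus-strand read is NOT C->T in read space
        path2 = _sam(tmp_path, {"chr1": 1000}, [(0, "chr1", 150, read, ref)], name="b.sam")
        track2 = extract_tracks(path2)
        assert not track2.transitions and track2.n_truncation_reads == 1

    def test_channel_conservation(self, tmp_path, small_dataset):
        from m6akit.synthetic import emit_sam

        path = tmp_path / "sim.sam"
        emit_sam(small_dataset.reference, small_dataset.truth.true_sites[:40], str(path),
                 reads_per_site=8, ctot_fraction=0.3, seed=3)
        track = extract_tracks(str(path))
        n_records = sum(1 for line in open(path) if not line.startswith("@"))
        assert track.n_reads + track.n_skipped == n_records
        assert track.n_truncation_reads + track.n_transition_reads == track.n_reads
        assert track.total_truncations == track.n_truncation_reads

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_naive_per_read_rescan(self, tmp_path, seed):
        """Track extraction equals an independent per-read rescan that walks
        reference/query strings directly."""
        rng = np.random.default_rng(seed)
        contig = "".join(rng.choice(list("ACGT"), size=400))
        reads = []
        for _ in range(50):
            start = int(rng.integers(1, 350))
            length = int(rng.integers(20, 40))
            ref = contig[start : start + length]
            read = list(ref)
            for _ in range(rng.integers(0, 3)):  # random substitutions
                j = int(rng.integers(0, length))
                read[j] = str(rng.choice(list("ACGT")))
            flag = 16 if rng.random() < 0.5 else 0
            reads.append((flag, "chr1", start, "".join(read), ref))
        path = _sam(tmp_path, {"chr1": 400}, reads)
        track = extract_tracks(path)

        # independent oracle: classify each read from raw strings
        trunc, trans = {}, {}
        for flag, chrom, start, read, ref in reads:
            strand = "-" if flag & 16 else "+"
            ct = [
                start + i
                for i, (r, q) in enumerate(zip(ref, read))
                if (strand == "+" and r == "C" and q == "T")
                or (strand == "-" and r == "G" and q == "A")
            ]
            if ct:
                for p in ct:
                    trans[(strand, p)] = trans.get((strand, p), 0) + 1
            else:
                p = start - 1 if strand == "+" else start + len(read)
                trunc[(strand, p)] = trunc.get((strand, p), 0) + 1

        got_trunc = {
            (st, p): c
            for (chrom, st), m in track.truncations.items()
            for p, c in m.items()
        }
        got_trans = {
            (st, p): c
            for (chrom, st), m in track.transitions.items()
            for p, c in m.items()
        }
        assert got_trunc == trunc
        assert got_trans == trans

    def test_strand_reflection_symmetry(self, tmp_path):
        """Reverse-complementing the contig and flipping read strands leaves
        counts identical under coordinate reflection."""
        rng = np.random.default_rng(11)
        L = 300
        contig = "".join(rng.choice(list("ACGT"), size=L))
        comp = str.maketrans("ACGT", "TGCA")
        rc = contig.translate(comp)[::-1]
        reads_fwd, reads_rev = [], []
        for _ in range(30):
            start = int(rng.integers(1, 250))
            rl = 25
            ref = contig[start : start + rl]
            reads_fwd.append((0, "chr1", start, ref, ref))
            # the same molecule on the reflected genome: minus-strand read
            start2 = L - (start + rl)
            ref2 = rc[start2 : start2 + rl]
            reads_rev.append((16, "chr1", start2, ref2, ref2))
        t1 = extract_tracks(_sam(tmp_path, {"chr1": L}, reads_fwd, "f.sam"))
        t2 = extract_tracks(_sam(tmp_path, {"chr1": L}, reads_rev, "r.sam"))
        fwd = t1.truncations[("chr1", "+")]
        rev = t2.truncations[("chr1", "-")]
        assert {L - 1 - p: c for p, c in fwd.items()} == dict(rev)

    def test_skips_secondary_and_unmapped(self, tmp_path):
        path = _sam(tmp_path, {"chr1": 1000}, [
            (0, "chr1", 100, REF30, REF30),
            (256, "chr1", 100, REF30, REF30),  # secondary
            (4, "chr1", 100, REF30, REF30),  # unmapped
        ])
        track = extract_tracks(path)
        assert track.n_reads == 1 and track.n_skipped == 2


class TestDetectCandidates:
    def _track(self, counts):
        t = TruncationTrack(sample_id="t")
        for pos, c in counts.items():
            t.add_truncation("chr1", "+", pos, c)
        return t

    def test_isolated_spike_detected(self):
        sites = detect_candidates(self._track({500: 50}), min_count=5, local_window=10)
        assert [s.pos for s in sites] == [500]

    def test_uniform_track_yields_nothing(self):
        track = self._track({p: 5 for p in range(100, 200)})
        assert detect_candidates(track, min_count=1, local_window=10, min_enrichment=2.0) == []

    def test_tie_breaks_to_five_prime(self):
        track = self._track({100: 10, 103: 10})
        sites = detect_candidates(track, min_count=5, local_window=10, min_enrichment=0.0)
        assert [s.pos for s in sites] == [100]
        # on the minus strand the 5'-most position is the larger coordinate
        t = TruncationTrack(sample_id="m")
        t.add_truncation("chr1", "-", 100, 10)
        t.add_truncation("chr1", "-", 103, 10)
        sites = detect_candidates(t, min_count=5, local_window=10, min_enrichment=0.0)
        assert [s.pos for s in sites] == [103]

    def test_recovers_planted_spikes_over_background(self):
        rng = np.random.default_rng(5)
        track = TruncationTrack(sample_id="s")
        for pos in range(0, 5000):
            track.add_truncation("chr1", "+", pos, int(rng.integers(0, 3)) or 1)
        planted = list(range(100, 5000, 97))
        for pos in planted:
            track.add_truncation("chr1", "+", pos, 40)
        found = {s.pos for s in detect_candidates(track, min_count=10, local_window=15)}
        recovered = len(found & set(planted)) / len(planted)
        assert recovered >= 0.95
        # flat background alone yields no calls
        flat = self._track({p: 4 for p in range(1000)})
        assert detect_candidates(flat, min_count=2, local_window=15) == []

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            detect_candidates(self._track({}), min_count=0)
        with pytest.raises(ValueError):
            detect_candidates(self._track({}), local_window=2)
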