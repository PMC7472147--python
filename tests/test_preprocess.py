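"""Preprocessing contracts, each checked against an independent oracle where
one exists: all-pairs dedup, hand-applied trimming rules, and exhaustive
sliding-window subtraction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_read, random_dna
from viroseek import preprocess as pre
from viroseek import synthetic_data as sd
from viroseek._sequtils import encode, revcomp
from viroseek.records import Read

PP = pre.PreprocessParams()


class TestDedup:
    def test_divergent_tails_still_collapse(self):
        core = random_dna(np.random.default_rng(0), 55)
        a = make_read("a", core + "AAAAA")
        b = make_read("b", core + "TTTTT")
        survivors, removed = pre.dedup([a, b], PP)
        assert len(survivors) == 1 and removed == 1

    def test_single_read_passes(self):
        r = make_read("x", random_dna(np.random.default_rng(1), 100))
        assert pre.dedup([r], PP) == ([r], 0)

    def test_short_reads_key_on_full_sequence(self):
        a = make_read("a", "ACGTACGT")
        b = make_read("b", "ACGTACGT")
        c = make_read("c", "ACGTACGA")
        survivors, removed = pre.dedup([a, b, c], PP)
        assert {r.id for r in survivors} == {"a", "c"}

    def test_against_all_pairs_oracle(self):
        """1,000 reads with 100 planted duplicate pairs: survivor set equals
        brute-force all-pairs key comparison."""
        rng = np.random.default_rng(42)
        reads = [make_read(f"r{i:04d}", random_dna(rng, 120)) for i in range(900)]
        originals = rng.choice(900, 100, replace=False)
        for j, oi in enumerate(originals):
            tail = random_dna(rng, 65)
            dup = reads[oi].bases[:55] + tail
            reads.append(make_read(f"d{j:04d}", dup))
        order = rng.permutation(len(reads))
        reads = [reads[i] for i in order]

        survivors, removed = pre.dedup(reads, PP)
        assert len(survivors) == 900 and removed == 100

        # O(n^2) oracle: first read of every equal-key group survives
        keys = [r.bases[4:55] for r in reads]
        keep = []
        for i, k in enumerate(keys):
            if all(keys[j] != k for j in range(i)):
                keep.append(reads[i].id)
        assert [r.id for r in survivors] == keep

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.lists(st.text(alphabet="ACGT", min_size=10, max_size=80), max_size=30))
    def test_idempotent(self, seqs):
        reads = [make_read(f"r{i}", s) for i, s in enumerate(seqs)]
        once, _ = pre.dedup(reads, PP)
        twice, removed = pre.dedup(once, PP)
        assert removed == 0 and [r.id for r in twice] == [r.id for r in once]

    def test_random_survivor_mode_is_seeded(self):
        core = random_dna(np.random.default_rng(5), 60)
        reads = [make_read(f"r{i}", core) for i in range(10)]
        a, _ = pre.dedup(reads, PP, seed=3, random_survivor=True)
        b, _ = pre.dedup(reads, PP, seed=3, random_survivor=True)
        assert [r.id for r in a] == [r.id for r in b]


class TestTrimQuality:
    @pytest.mark.parametrize(
        "quals,expected_len",
        [
            ([30, 30, 30], 3),          # all good: unchanged
            ([30, 30, 30, 10, 10], 3),  # contiguous low tail removed
            ([10, 30, 10], 2),          # internal low base retained
            ([10, 10, 10], 0),          # fully low: trimmed to nothing
        ],
    )
    def test_stated_rule(self, quals, expected_len):
        r = Read("q", "A" * len(quals), np.array(quals, dtype=np.uint8))
        out = pre.trim_quality(r, 20)
        assert len(out) == expected_len
        assert out.bases == r.bases[:expected_len]

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.integers(min_value=0, max_value=41), min_size=1, max_size=60))
    def test_tail_only_invariant(self, quals):
        r = Read("q", "C" * len(quals), np.array(quals, dtype=np.uint8))
        out = pre.trim_quality(r, 20)
        # everything removed was < 20, and the new last base (if any) is >= 20
        assert all(q < 20 for q in quals[len(out):])
        if len(out):
            assert out.quals[-1] >= 20


class TestTrimAdaptor:
    ADAPTOR = "CTGTCTCTTATACACATCTCCGAGCCCACGAGA"  # 33 bases

    def test_full_adaptor_suffix_removed(self):
        rng = np.random.default_rng(8)
        insert = random_dna(rng, 80)
        r = make_read("r", insert + self.ADAPTOR)
        out = pre.trim_adaptor(r, [self.ADAPTOR])
        assert out.bases == insert

    def test_no_adaptor_unchanged(self):
        rng = np.random.default_rng(9)
        bases = random_dna(rng, 120).replace(self.ADAPTOR[:8], "AAAAAAAA")
        r = make_read("r", bases)
        assert pre.trim_adaptor(r, [self.ADAPTOR]).bases == bases

    def test_seven_base_prefix_is_below_evidence(self):
        rng = np.random.default_rng(10)
        bases = random_dna(rng, 60)
        bases = bases[: 60 - 7] + self.ADAPTOR[:7]
        r = make_read("r", bases)
        assert pre.trim_adaptor(r, [self.ADAPTOR]).bases == bases

    def test_eight_base_prefix_at_end_clipped(self):
        rng = np.random.default_rng(11)
        head = random_dna(rng, 50)
        r = make_read("r", head + self.ADAPTOR[:8])
        assert pre.trim_adaptor(r, [self.ADAPTOR]).bases == head

    def test_internal_full_adaptor_with_one_mismatch_clipped(self):
        rng = np.random.default_rng(12)
        head, junk = random_dna(rng, 40), random_dna(rng, 30)
        ad = list(self.ADAPTOR)
        ad[20] = {"A": "C"}.get(ad[20], "A")  # one mismatch
        r = make_read("r", head + "".join(ad) + junk)
        assert pre.trim_adaptor(r, [self.ADAPTOR]).bases == head


@pytest.fixture(scope="module")
def reference():
    rng = np.random.default_rng(77)
    return random_dna(rng, 5000)


@pytest.fixture(scope="module")
def index(reference):
    return pre.SubtractionIndex([("ref", reference)], pre.SubtractionParams())


class TestSubtraction:
    @staticmethod
    def oracle(read_bases, references, params):
        """Exhaustive check over every 60-base window at every offset of
        every strand (reference padded so partial diagonals are covered)."""
        w = params.min_aligned_length
        r = encode(read_bases).astype(np.int16)
        if r.shape[0] < w:
            return False
        pad = np.full(r.shape[0] - w, 9, dtype=np.int16)
        for _, ref in references:
            for strand_seq in (ref, revcomp(ref)):
                t = np.concatenate([pad, encode(strand_seq).astype(np.int16), pad])
                n_off = t.shape[0] - r.shape[0] + 1
                if n_off <= 0:
                    continue
                win = np.lib.stride_tricks.sliding_window_view(t, r.shape[0])[:n_off]
                mism = (win != r[None, :]) | (win == 9) | (r[None, :] == 4)
                c = np.cumsum(mism, axis=1)
                counts = np.concatenate([c[:, w - 1 : w], c[:, w:] - c[:, :-w]], axis=1)
                if (counts <= params.max_mismatches).any():
                    return True
        return False

    def test_verbatim_copy_is_background(self, reference, index):
        r = make_read("r", reference[1000:1250])
        assert pre.is_background(r, index)[0]

    def test_reverse_strand_copy_is_background(self, reference, index):
        r = make_read("r", revcomp(reference[2000:2250]))
        assert pre.is_background(r, index)[0]

    def test_dense_mismatches_escape(self, reference, index):
        """Every 60-base window carries >= 3 mismatches: retained."""
        frag = list(reference[3000:3250])
        for i in range(0, 250, 18):  # a mismatch every 18 bases
            frag[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[frag[i]]
        r = make_read("r", "".join(frag))
        params = index.params
        assert not self.oracle(r.bases, [("ref", reference)], params)
        assert not pre.is_background(r, index)[0]

    def test_random_read_not_background(self, reference, index):
        r = make_read("r", random_dna(np.random.default_rng(123), 250))
        assert not pre.is_background(r, index)[0]

    def test_short_read_is_never_background(self, reference, index):
        r = make_read("r", reference[100:150])
        assert not pre.is_background(r, index)[0]

    def test_against_exhaustive_window_oracle(self, reference, index):
        """500 simulated reads at mixed divergence: seed-and-extend equals
        the exhaustive sliding-window mismatch count everywhere."""
        rng = np.random.default_rng(2024)
        params = index.params
        sub = {"A": "CGT", "C": "AGT", "G": "ACT", "T": "ACG"}
        disagreements = []
        for i in range(500):
            kind = i % 5
            if kind == 4:
                bases = random_dna(rng, 250)
            else:
                start = int(rng.integers(0, len(reference) - 250))
                frag = list(reference[start : start + 250])
                rate = (0.0, 0.005, 0.02, 0.06)[kind]
                for j in range(250):
                    if rng.random() < rate:
                        frag[j] = sub[frag[j]][rng.integers(0, 3)]
                bases = "".join(frag)
                if rng.random() < 0.5:
                    bases = revcomp(bases)
            got = pre.is_background(make_read(f"r{i}", bases), index)[0]
            want = self.oracle(bases, [("ref", reference)], params)
            if got != want:
                disagreements.append((i, got, want))
        assert not disagreements

    def test_subtract_preserves_order(self, reference, index):
        rng = np.random.default_rng(5)
        reads = [
            make_read("keep1", random_dna(rng, 250)),
            make_read("drop", reference[0:250]),
            make_read("keep2", random_dna(rng, 250)),
        ]
        retained, removed = pre.subtract(reads, index)
        assert [r.id for r in retained] == ["keep1", "keep2"] and removed == 1


def test_pipeline_counts_conserve_reads(small_community):
    params = sd.ReadSimParams(n_pairs=800, seed=2)
    r1, r2, _ = sd.simulate_reads(small_community, params)
    refs = [(m.genome.label, m.genome.seq) for m in small_community.members
            if m.kind != "viral"]
    idx = pre.SubtractionIndex(refs, pre.SubtractionParams())
    pp = pre.PreprocessParams(adaptors=[sd.DEFAULT_ADAPTOR])
    reads, counts = pre.preprocess_pairs(r1, r2, pp, idx, seed=2)
    assert counts["input_reads"] == (
        counts["retained_reads"] + counts["dedup_removed_reads"]
        + counts["trim_discarded_reads"] + counts["subtracted_reads"]
    )
    assert counts["retained_reads"] == len(reads)
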