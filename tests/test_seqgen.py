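"""Sequence database construction: composition models, random generation,
alignment identity and the greedy redundancy screen."""

import numpy as np
import pytest

from nullprot.alphabet import AA_ORDER
from nullprot.seqgen import (
    CompositionModel,
    ProteinSequence,
    SequenceDataset,
    generate_random_dataset,
    generate_screened_dataset,
    load_background_frequencies,
    pairwise_identity,
    read_fasta,
    redundancy_filter,
    uniform_frequencies,
    write_fasta,
)

AA = list(AA_ORDER)


def random_protein(rng, length, ident):
    return ProteinSequence(ident, "".join(rng.choice(AA, size=length)))


class TestCompositionModels:
    def test_background_frequencies_sum_to_one(self):
        model = load_background_frequencies()
        assert model.kind == "background"
        assert abs(sum(model.frequencies) - 1.0) < 1e-9

    def test_background_frequencies_all_positive(self):
        assert all(f > 0 for f in load_background_frequencies().frequencies)

    def test_background_spot_values(self):
        # published BLOSUM62 marginals: L is the most common residue, W rarest
        model = dict(zip(AA_ORDER, load_background_frequencies().frequencies))
        assert model["L"] == pytest.approx(0.099)
        assert model["W"] == pytest.approx(0.013)
        assert max(model, key=model.get) == "L"
        assert min(model, key=model.get) == "W"

    def test_uniform_model(self):
        model = uniform_frequencies()
        assert all(f == 0.05 for f in model.frequencies)

    def test_invalid_model_rejected_with_sum(self):
        freqs = [0.05] * 19 + [0.06]
        with pytest.raises(ValueError, match="sum to 1"):
            CompositionModel(kind="uniform", frequencies=tuple(freqs))


class TestGeneration:
    def test_empty_dataset(self):
        ds = generate_random_dataset(uniform_frequencies(), 0, 60, seed=1)
        assert len(ds) == 0

    def test_shape_and_ids(self):
        ds = generate_random_dataset(uniform_frequencies(), 25, 60, seed=1)
        assert len(ds) == 25
        assert all(len(s) == 60 for s in ds)
        assert ds[3].id.endswith("00003")
        assert len({s.id for s in ds}) == 25

    def test_background_composition_within_4_se(self):
        model = load_background_frequencies()
        ds = generate_random_dataset(model, 5000, 60, seed=7)
        total = 5000 * 60
        residues = ds.all_residues()
        for aa, p in zip(AA_ORDER, model.frequencies):
            se = np.sqrt(p * (1 - p) / total)
            assert abs(residues.count(aa) / total - p) < 4 * se, aa

    def test_determinism_byte_identical_fasta(self, tmp_path):
        paths = []
        for i in (1, 2):
            ds = generate_random_dataset(uniform_frequencies(), 50, 60, seed=42)
            p = tmp_path / f"out{i}.fasta"
            write_fasta(ds, p)
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_fasta_round_trip(self, tmp_path):
        ds = generate_random_dataset(uniform_frequencies(), 10, 60, seed=3)
        p = tmp_path / "x.fasta"
        write_fasta(ds, p)
        back = read_fasta(p)
        assert [(s.id, s.residues) for s in back] == [
            (s.id, s.residues) for s in ds
        ]
        # headers are bare ids
        assert p.read_text().splitlines()[0] == f">{ds[0].id}"


class TestPairwiseIdentity:
    def test_self_identity(self):
        rng = np.random.default_rng(0)
        s = random_protein(rng, 60, "s")
        assert pairwise_identity(s, s) == 1.0

    def test_disjoint_alphabets(self):
        assert pairwise_identity(
            ProteinSequence("a", "AAAA"), ProteinSequence("b", "WWWW")
        ) == 0.0

    def test_single_mismatch(self):
        # global alignment of AAAA/AAAC has no gaps: 3 matches over 4 columns
        assert pairwise_identity(
            ProteinSequence("a", "AAAA"), ProteinSequence("b", "AAAC")
        ) == 0.75

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            ProteinSequence("x", "")

    def test_symmetry_random_pairs(self):
        rng = np.random.default_rng(1)
        for i in range(40):
            a = random_protein(rng, 60, "a")
            b = random_protein(rng, 60, "b")
            assert pairwise_identity(a, b) == pairwise_identity(b, a)

    def test_symmetry_unequal_lengths(self):
        rng = np.random.default_rng(2)
        a = random_protein(rng, 45, "a")
        b = random_protein(rng, 70, "b")
        assert pairwise_identity(a, b) == pairwise_identity(b, a)

    def test_against_biopython_aligner(self):
        """Score must agree exactly with Biopython's global aligner; the
        match count must equal the maximum identity count over all optimal
        alignments Biopython enumerates."""
        from Bio import Align
        from Bio.Align import substitution_matrices

        from nullprot._align import alignment_stats
        from nullprot.alphabet import encode

        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -11
        aligner.extend_gap_score = -1

        rng = np.random.default_rng(3)
        for i in range(25):
            a = random_protein(rng, 40, "a")
            b = random_protein(rng, 40, "b")
            score, matches, diag = alignment_stats(encode(a.residues), encode(b.residues))
            assert score == aligner.score(a.residues, b.residues)
            best = 0
            n_opt = 0
            for aln in aligner.align(a.residues, b.residues):
                best = max(best, aln.counts().identities)
                n_opt += 1
                if n_opt > 5000:
                    break
            if n_opt <= 5000:
                assert matches == best


class TestRedundancyFilter:
    def test_exact_duplicate_removed(self):
        rng = np.random.default_rng(4)
        s = random_protein(rng, 60, "s1")
        dup = ProteinSequence("s2", s.residues)
        other = random_protein(rng, 60, "s3")
        ds = SequenceDataset("d", [s, dup, other])
        out = redundancy_filter(ds, 0.3)
        assert [x.id for x in out] == ["s1", "s3"]

    def test_unrelated_random_sequences_unchanged(self):
        rng = np.random.default_rng(5)
        seqs = [random_protein(rng, 60, f"s{i}") for i in range(30)]
        ds = SequenceDataset("d", seqs)
        out = redundancy_filter(ds, 0.3)
        # brute-force oracle: verify all pairs are below the cutoff
        for i in range(len(seqs)):
            for j in range(i + 1, len(seqs)):
                assert pairwise_identity(seqs[i], seqs[j]) < 0.3
        assert [x.id for x in out] == [x.id for x in seqs]

    def test_singleton_unchanged(self):
        rng = np.random.default_rng(6)
        ds = SequenceDataset("d", [random_protein(rng, 60, "only")])
        assert len(redundancy_filter(ds, 0.3)) == 1

    def test_matches_pure_python_greedy(self):
        """Blocked-kernel screen equals a greedy screen driven solely by
        pairwise_identity, on a set with planted near-duplicates."""
        rng = np.random.default_rng(7)
        base = [random_protein(rng, 60, f"b{i}") for i in range(12)]
        seqs = list(base)
        for i, s in enumerate(base[:8]):  # mutate ~25% of positions
            res = list(s.residues)
            for pos in rng.choice(60, size=15, replace=False):
                res[pos] = AA[rng.integers(20)]
            seqs.append(ProteinSequence(f"m{i}", "".join(res)))
        cutoff = 0.5
        out = redundancy_filter(SequenceDataset("d", seqs), cutoff)
        expected = []
        for s in seqs:
            if all(pairwise_identity(s, k) < cutoff for k in expected):
                expected.append(s)
        assert [x.id for x in out] == [x.id for x in expected]
        assert len(out) < len(seqs)  # the mutants actually collided

    def test_retained_pairs_below_cutoff(self):
        rng = np.random.default_rng(8)
        base = random_protein(rng, 60, "b")
        seqs = [base]
        for i in range(20):
            res = list(base.residues)
            for pos in rng.choice(60, size=rng.integers(5, 40), replace=False):
                res[pos] = AA[rng.integers(20)]
            seqs.append(ProteinSequence(f"v{i}", "".join(res)))
        out = redundancy_filter(SequenceDataset("d", seqs), 0.4)
        kept = out.sequences
        for i in range(len(kept)):
            for j in range(i + 1, len(kept)):
                assert pairwise_identity(kept[i], kept[j]) < 0.4


class TestScreenedGeneration:
    def test_reaches_requested_size(self):
        ds = generate_screened_dataset(uniform_frequencies(), 200, 60, seed=9, cutoff=0.3)
        assert len(ds) == 200
        assert all(len(s) == 60 for s in ds)
        assert ds.identity_cutoff == 0.3

    def test_screened_output_nonredundant(self):
        ds = generate_screened_dataset(
            load_background_frequencies(), 60, 60, seed=10, cutoff=0.3
        )
        for i in range(len(ds)):
            for j in range(i + 1, len(ds)):
                assert pairwise_identity(ds[i], ds[j]) < 0.3
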