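"""Estimator correctness: examples, properties, and cross-implementation checks."""

import math
import shutil
import subprocess

import numpy as np
import pytest

from mitogeodiv import (
    Alignment,
    between_group_p_distance,
    distance_matrix,
    haplotype_diversity,
    nucleotide_diversity,
    p_distance_matrix,
    pairwise_distance,
    pairwise_p_distance,
    watterson_theta,
)
from mitogeodiv.errors import (
    InsufficientSampleError,
    SaturationError,
    UndefinedDistanceError,
)
from mitogeodiv.seqio_align import write_fasta

from conftest import random_alignment


class TestPDistance:
    def test_identity(self):
        assert pairwise_p_distance("ACGT", "ACGT") == 0.0

    def test_one_difference(self):
        assert pairwise_p_distance("ACGT", "ACGA") == 0.25

    def test_pairwise_deletion_of_missing(self):
        # N removes one site; 3 comparable sites, 1 difference
        assert pairwise_p_distance("ACGN", "ACTA") == pytest.approx(1 / 3)

    def test_gap_also_deleted(self):
        assert pairwise_p_distance("AC-T", "ACTT") == 0.0

    def test_no_comparable_sites(self):
        with pytest.raises(UndefinedDistanceError):
            pairwise_p_distance("NNNN", "ACGT")

    def test_matrix_matches_scalar(self, rng):
        for _ in range(20):
            rows = random_alignment(rng, 6, 40, missing_frac=0.1, gap_frac=0.05)
            try:
                mat = p_distance_matrix(rows)
            except UndefinedDistanceError:
                continue
            for i in range(6):
                for j in range(6):
                    expect = 0.0 if i == j else pairwise_p_distance(rows[i], rows[j])
                    assert mat[i, j] == pytest.approx(expect, abs=1e-15)


class TestNucleotideDiversity:
    def test_no_variation(self):
        assert nucleotide_diversity(["ACGT"] * 5) == 0.0

    def test_three_rows(self):
        # pairs: (a,b)=0.25, (a,c)=0.50, (b,c)=0.25
        assert nucleotide_diversity(["ACGT", "ACGA", "ACCA"]) == pytest.approx(1 / 3)

    def test_duplicated_pair(self):
        # {x,x,y,y}: 4 cross pairs at p, 2 at 0 -> 2p/3
        x, y = "ACGT", "ACGA"
        p = pairwise_p_distance(x, y)
        assert nucleotide_diversity([x, x, y, y]) == pytest.approx(2 * p / 3)

    def test_insufficient_sample(self):
        with pytest.raises(InsufficientSampleError):
            nucleotide_diversity(["ACGT"])

    def test_row_order_invariance(self, rng):
        rows = random_alignment(rng, 7, 30)
        perm = list(rng.permutation(7))
        assert nucleotide_diversity(rows) == pytest.approx(
            nucleotide_diversity([rows[i] for i in perm]), abs=1e-15
        )


class TestWattersonTheta:
    def test_identical_rows(self):
        assert watterson_theta(["ACGT", "ACGT"]) == 0.0

    def test_two_rows_one_difference(self):
        # n=2: S=1, a_2=1, L=4
        assert watterson_theta(["ACGT", "ACGA"]) == 0.25

    def test_three_rows(self):
        # S=2, a_3=1.5, L=4
        assert watterson_theta(["ACGT", "ACGA", "ACCA"]) == pytest.approx(1 / 3)

    def test_complete_deletion(self):
        # column with N dropped entirely: S=1, L=3, a_2=1
        assert watterson_theta(["NCGT", "ACGA"]) == pytest.approx(1 / 3)


class TestHaplotypeDiversity:
    def test_monomorphic(self):
        assert haplotype_diversity(["ACGT"] * 4) == 0.0

    def test_two_singletons(self):
        assert haplotype_diversity(["ACGT", "ACGA"]) == 1.0

    def test_two_classes_of_two(self):
        assert haplotype_diversity(["ACGT", "ACGT", "ACGA", "ACGA"]) == pytest.approx(
            (4 / 3) * 0.5
        )


class TestBetweenGroup:
    def test_identical_singletons(self):
        assert between_group_p_distance(["ACGT"], ["ACGT"]) == 0.0

    def test_cross_pairs_mean(self):
        # cross pairs: 0.25 and 0.50
        assert between_group_p_distance(["ACGT"], ["ACGA", "ACCA"]) == 0.375

    def test_symmetric_in_groups(self, rng):
        a = random_alignment(rng, 3, 25)
        b = random_alignment(rng, 4, 25)
        assert between_group_p_distance(a, b) == pytest.approx(
            between_group_p_distance(b, a), abs=1e-15
        )

    def test_empty_group(self):
        with pytest.raises(InsufficientSampleError):
            between_group_p_distance([], ["ACGT"])


class TestModelDistances:
    def test_jc69_closed_form(self):
        # p = 0.25 -> -(3/4) ln(1 - 1/3)
        d = pairwise_distance("AAAA", "AAAC", model="jc69")
        assert d == pytest.approx(-0.75 * math.log(1 - 1 / 3))
        assert d == pytest.approx(0.3041, abs=5e-5)

    def test_jc69_saturation(self):
        with pytest.raises(SaturationError):
            pairwise_distance("AAAA", "CCCC", model="jc69")

    def test_jc69_dominates_p(self, rng):
        for _ in range(50):
            a, b = random_alignment(rng, 2, 60)
            p = pairwise_p_distance(a, b)
            if 0 < p < 0.75:
                assert pairwise_distance(a, b, "jc69") >= p

    def test_identical_rows_zero_under_all_models(self):
        aln = Alignment(("a", "b"), ("ACGTACGT", "ACGTACGT"))
        for model in ("p", "jc69", "k80"):
            assert distance_matrix(aln, model).values.max() == 0.0

    def test_k80_transition_transversion_split(self):
        # 1 transition (A<->G) and 1 transversion (A<->C) over 8 sites
        a, b = "AAGGCCTT", "GAGGACTT"
        P, Q = 1 / 8, 1 / 8
        expect = -0.5 * math.log(1 - 2 * P - Q) - 0.25 * math.log(1 - 2 * Q)
        assert pairwise_distance(a, b, "k80") == pytest.approx(expect)


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript not on PATH")
def test_distance_models_match_ape(tmp_path, rng):
    """p, JC69 and K80 matrices agree with ape::dist.dna to 1e-10."""
    from mitogeodiv import SimConfig, simulate_dataset

    # moderately diverged sequences keep both corrections well-defined
    cfg = SimConfig(
        seed=11, n_samples=6, n_groups=2, seq_length=200,
        within_theta=0.05, between_group_div=0.2, basin_effect=0.0,
    )
    aln, _ = simulate_dataset(cfg)
    fasta = tmp_path / "aln.fasta"
    write_fasta(aln, fasta)
    script = tmp_path / "oracle.R"
    script.write_text(
        'suppressMessages(library(ape))\n'
        'args <- commandArgs(TRUE)\n'
        'a <- read.dna(args[1], format="fasta")\n'
        'for (m in c("raw", "JC69", "K80")) {\n'
        '  d <- as.matrix(dist.dna(a, model=m, pairwise.deletion=TRUE))\n'
        '  write.table(format(d, digits=17), file.path(args[2], paste0(m, ".tsv")),\n'
        '              row.names=FALSE, col.names=FALSE, quote=FALSE)\n'
        '}\n'
    )
    subprocess.run(
        ["Rscript", str(script), str(fasta), str(tmp_path)], check=True
    )
    for model, rname in (("p", "raw"), ("jc69", "JC69"), ("k80", "K80")):
        ours = distance_matrix(aln, model).values
        theirs = np.loadtxt(tmp_path / f"{rname}.tsv")
        assert np.abs(ours - theirs).max() < 1e-10


try:
    from hypothesis import given, settings, strategies as st

    _rows_strategy = st.integers(2, 6).flatmap(
        lambda length: st.lists(
            st.text(alphabet="ACGTN-", min_size=length, max_size=length),
            min_size=2,
            max_size=5,
        )
    )

    @settings(max_examples=60, derandomize=True)
    @given(_rows_strategy)
    def test_p_distance_bounded_and_symmetric(rows):
        """For every comparable pair: 0 <= p <= 1 and d(a,b) = d(b,a)."""
        for i, a in enumerate(rows):
            for b in rows[i + 1 :]:
                try:
                    d = pairwise_p_distance(a, b)
                except UndefinedDistanceError:
                    continue
                assert 0.0 <= d <= 1.0
                assert d == pairwise_p_distance(b, a)

except ImportError:  # hypothesis is an optional test dependency
    pass


def test_pi_and_theta_agree_under_neutral_coalescent():
    """π and θ_W estimate the same parameter under neutral equilibrium.

    Sequences are simulated with msprime (haploid coalescent, JC69
    mutations); over 200 replicates the two estimators' means differ by
    less than 10%.
    """
    msprime = pytest.importorskip("msprime")
    pis, thetas = [], []
    for rep in range(200):
        ts = msprime.sim_ancestry(
            samples=8,
            ploidy=1,
            sequence_length=1000,
            population_size=1000,
            random_seed=1000 + rep,
        )
        mts = msprime.sim_mutations(
            ts, rate=5e-7, random_seed=5000 + rep, model=msprime.JC69()
        )
        cols = ["".join(v.alleles[g] for g in v.genotypes) for v in mts.variants()]
        pad = "A" * (int(mts.sequence_length) - len(cols))
        rows = [
            "".join(site[i] for site in cols) + pad for i in range(mts.num_samples)
        ]
        pis.append(nucleotide_diversity(rows))
        thetas.append(watterson_theta(rows))
    mean_pi, mean_theta = np.mean(pis), np.mean(thetas)
    assert abs(mean_pi - mean_theta) / mean_theta < 0.10
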