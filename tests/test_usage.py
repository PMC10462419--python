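"""Codon usage tables, RSCU, and effective number of codons."""

import math
from collections import Counter

import numpy as np
import pytest

from lepcodon.genetics import standard_code
from lepcodon.simulate import compositional_gene
from lepcodon.usage import (
    CodonUsageTable,
    ENCConfig,
    codon_frequencies,
    enc_diff,
    enc_exp,
    enc_obs,
    pooled_usage,
    rscu,
)


def table_from_counts(counts):
    code = standard_code()
    full = {c: counts.get(c, 0) for c in code.sense_codons}
    return CodonUsageTable(scope="t", counts=full, total=sum(full.values()))


def uniform_table(per_codon=50):
    return table_from_counts({c: per_codon for c in standard_code().sense_codons})


def one_codon_per_aa_table(per_codon=50):
    code = standard_code()
    return table_from_counts({fam[0]: per_codon for fam in code.families.values()})


class TestFrequencies:
    def test_single_codon_gene(self):
        t = codon_frequencies("ATG" * 100)
        assert t.per_1000["ATG"] == 1000.0
        assert t.total == 100

    def test_uniform_per_1000(self):
        t = codon_frequencies(["".join(standard_code().sense_codons)])
        assert t.per_1000["GGG"] == pytest.approx(1000 / 61)

    def test_hand_tally_oracle(self, rng):
        """Counts equal an independent brute-force triplet tally."""
        code = standard_code()
        seq = "".join(code.sense_codons[i] for i in rng.integers(0, 61, size=200))
        t = codon_frequencies(seq)
        oracle = Counter(seq[i:i + 3] for i in range(0, len(seq), 3))
        for codon in code.sense_codons:
            assert t.counts[codon] == oracle.get(codon, 0)

    def test_stop_codons_excluded(self):
        t = codon_frequencies("ATGTAAATG")
        assert t.total == 2


class TestRSCU:
    def test_two_codon_family_ratio(self):
        vals = rscu(table_from_counts({"GAA": 30, "GAG": 10}))
        assert vals["GAA"] == pytest.approx(1.5)
        assert vals["GAG"] == pytest.approx(0.5)

    def test_equal_usage_gives_one_everywhere(self):
        vals = rscu(uniform_table())
        code = standard_code()
        for codon, v in vals.items():
            assert v == pytest.approx(1.0), codon

    def test_single_codon_monopoly(self):
        vals = rscu(table_from_counts({"GGG": 40}))
        assert vals["GGG"] == pytest.approx(4.0)
        assert vals["GGA"] == 0.0

    def test_family_mean_is_one_and_sum_is_family_size(self, rng):
        code = standard_code()
        counts = {c: int(rng.integers(1, 50)) for c in code.sense_codons}
        vals = rscu(table_from_counts(counts))
        for aa, fam in code.families.items():
            assert sum(vals[c] for c in fam) == pytest.approx(len(fam))

    def test_unused_family_flagged_nan(self):
        vals = rscu(table_from_counts({"ATG": 5}))
        assert math.isnan(vals["GGG"])


class TestENCObserved:
    def test_uniform_usage_hits_upper_bound(self):
        assert enc_obs(uniform_table()) == pytest.approx(61.0)

    def test_one_codon_per_amino_acid_hits_lower_bound(self):
        assert enc_obs(one_codon_per_aa_table()) == pytest.approx(20.0)

    def test_single_family_homozygosity_hand_value(self):
        """Counts (3,1) in a 2-fold family: F = (4*(0.5625+0.0625)-1)/3 = 0.5."""
        from lepcodon.usage import _family_homozygosity

        assert _family_homozygosity([3, 1]) == pytest.approx(0.5)

    def test_scale_invariance(self, rng):
        code = standard_code()
        counts = {c: int(rng.integers(200, 600)) for c in code.sense_codons}
        e1 = enc_obs(table_from_counts(counts))
        e2 = enc_obs(table_from_counts({c: 10 * v for c, v in counts.items()}))
        assert abs(e1 - e2) < 0.1

    def test_concentration_decreases_enc(self):
        """Shifting family usage toward one codon monotonically lowers ENC."""
        code = standard_code()
        encs = []
        for w in (0.25, 0.5, 0.75, 1.0):
            counts = {}
            for fam in code.families.values():
                k = len(fam)
                if k == 1:
                    counts[fam[0]] = 400
                    continue
                major = int(400 * (w + (1 - w) / k))
                minor = int(400 * (1 - w) / k)
                counts[fam[0]] = major
                for c in fam[1:]:
                    counts[c] = minor
            encs.append(enc_obs(table_from_counts(counts)))
        assert all(a >= b for a, b in zip(encs, encs[1:]))
        assert encs[-1] == pytest.approx(20.0)


class TestENCExpected:
    def test_default_constants_at_gc3_zero(self):
        # a + b/c^2 = 6 + 34/1.050625
        assert enc_exp(0.0) == pytest.approx(6 + 34 / 1.050625, abs=1e-9)

    def test_clamped_at_curve_peak(self):
        assert enc_exp(0.5) == 61.0

    def test_wright_classic_constants(self):
        # direct evaluation: 2 + 0.5 + 29/(0.5^2 + (1-0.5)^2) = 60.5
        val = enc_exp(0.5, ENCConfig.wright_classic())
        assert val == pytest.approx(60.5, rel=1e-9)

    def test_out_of_range_gc3_rejected(self):
        with pytest.raises(ValueError):
            enc_exp(1.2)


class TestENCDiff:
    @pytest.mark.parametrize("exp,obs,expected", [(50.0, 50.0, 0.0), (50.0, 45.0, 0.1), (50.0, 55.0, -0.1)])
    def test_arithmetic(self, exp, obs, expected):
        assert enc_diff(exp, obs) == pytest.approx(expected)

    def test_composition_only_genes_center_on_zero(self, rng):
        """Genes with purely compositional codon choice have mean ENC_diff ~ 0.

        Uses Wright's classic null curve, which estimates the
        composition-only expectation the generator realizes.
        """
        from lepcodon.genetics import gc_by_position
        from lepcodon.usage import codon_frequencies as cf

        cfg = ENCConfig.wright_classic()
        diffs = []
        for i in range(40):
            seq = compositional_gene(rng, 800, gc3=0.35)
            obs = enc_obs(cf(seq))
            exp = enc_exp(gc_by_position(seq).gc3, cfg)
            diffs.append(enc_diff(exp, obs))
        assert abs(np.mean(diffs)) < 0.04


def test_pooled_usage_from_counts_not_frequency_means():
    t1 = codon_frequencies("GAA" * 90 + "GAG" * 10)
    t2 = codon_frequencies("GAA" * 10 + "GAG" * 90)
    pooled = pooled_usage([t1, t2], scope="lineage")
    assert pooled.per_1000["GAA"] == pytest.approx(500.0)
    assert pooled.counts["GAA"] == 100
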