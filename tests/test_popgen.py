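"""Polarization, class spectra, the equilibrium-model expected SFS, and
parameter recovery of the gBGC fit."""

import numpy as np
import pytest
from scipy import integrate, special

from lepcodon.popgen import (
    PolarizedSite,
    bootstrap_fit,
    build_sfs,
    classify_site,
    expected_sfs,
    extract_polarized_sites,
    fit_gbgc,
    monomorphic_class_counts,
    polarize,
    sfs_shape,
)
from lepcodon.simulate import (
    PopgenSimConfig,
    simulate_polymorphism,
    simulate_polymorphism_fixtures,
)


class TestPolarize:
    def test_concordant_outgroups(self):
        assert polarize({"A": 19, "G": 1}, "A", "A") == ("A", "G", 1)

    def test_discordant_outgroups_unpolarized(self):
        assert polarize({"A": 19, "G": 1}, "A", "G") is None

    def test_outgroups_match_minor_allele(self):
        assert polarize({"A": 12, "G": 8}, "G", "G") == ("G", "A", 12)

    def test_outgroup_matches_neither_allele(self):
        assert polarize({"A": 10, "G": 10}, "T", "T") is None

    def test_single_outgroup_relaxed_vs_strict(self):
        assert polarize({"A": 15, "C": 5}, "A", None, relaxed=True) == ("A", "C", 5)
        assert polarize({"A": 15, "C": 5}, "A", None, relaxed=False) is None

    def test_order_invariance(self):
        a = polarize({"A": 3, "G": 17}, "A", "A")
        b = polarize({"G": 17, "A": 3}, "A", "A")
        assert a == b


class TestClassifySite:
    @pytest.mark.parametrize(
        "codon,pos,anc,der,deg,mclass",
        [
            ("GGA", 3, "A", "G", 4, "WS"),
            ("GGA", 1, "G", "A", 0, "SW"),
            ("GGA", 3, "A", "T", 4, "conservative"),
        ],
    )
    def test_classified(self, codon, pos, anc, der, deg, mclass):
        assert classify_site(codon, pos, anc, der) == (deg, mclass)

    def test_twofold_excluded(self):
        deg, _ = classify_site("GAA", 3, "A", "G")
        assert deg is None


class TestBuildSFS:
    def test_hand_binning(self):
        sites = [
            PolarizedSite(f"s{k}", "GGA", 3, 4, "A", "G", i, 4, "WS")
            for k, i in enumerate([1, 1, 2])
        ]
        sfs = build_sfs(sites, 4)
        assert np.array_equal(sfs[("WS", 4)].counts, [2, 1, 0])

    def test_empty_input(self):
        assert build_sfs([], 10) == {}

    def test_monomorphic_census(self):
        # GGA: pos3 4-fold W, pos1 0-fold S; GGC: pos3 4-fold S, pos1 0-fold S
        mono = monomorphic_class_counts("GGAGGC")
        assert mono[4] == {"W": 1, "S": 1}
        assert mono[0]["S"] >= 2


class TestExpectedSFS:
    def test_neutral_limit_closed_form(self):
        """B=0 equals theta/i to 1e-6 relative for n up to 50."""
        for n in (2, 10, 20, 50):
            e = expected_sfs(2.5, 0.0, n)
            assert np.allclose(e, 2.5 / np.arange(1, n), rtol=1e-6)

    def test_continuity_at_zero(self):
        e = expected_sfs(1.0, 1e-6, 20)
        assert np.all(np.abs(e - 1.0 / np.arange(1, 20)) < 1e-5)

    def test_riemann_sum_oracle(self):
        """B=2, n=10 matches a fine-grid midpoint-rule oracle to 1e-6 relative."""
        n, B, theta = 10, 2.0, 1.0
        x = (np.arange(2_000_000) + 0.5) / 2_000_000
        h = np.expm1(-B * (1 - x)) / np.expm1(-B)
        got = expected_sfs(theta, B, n)
        for i in range(1, n):
            f = special.comb(n, i) * x ** (i - 1) * (1 - x) ** (n - i - 1) * h
            oracle = f.mean()
            assert got[i - 1] == pytest.approx(oracle, rel=1e-6)

    def test_sign_symmetry(self):
        """E_i(-B) equals the frequency-reversed E_{n-i}(+B) scaled consistently.

        The diffusion identity: phi_{-B}(x) = phi_{+B}(1-x) * e^{-B}... the
        directly testable form is that the fast grid path agrees with
        quadrature for both signs.
        """
        for B in (-3.0, -0.5, 0.5, 3.0):
            assert np.allclose(expected_sfs(1.0, B, 20), sfs_shape(B, 20), rtol=1e-9)

    def test_positive_b_shifts_mass_to_high_frequencies(self):
        e_pos = expected_sfs(1.0, 2.0, 20)
        e_neu = expected_sfs(1.0, 0.0, 20)
        p_pos, p_neu = e_pos / e_pos.sum(), e_neu / e_neu.sum()
        assert p_pos[-1] > p_neu[-1]      # more high-frequency derived alleles
        assert p_pos[0] < p_neu[0]        # fewer singletons, proportionally

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            expected_sfs(-1.0, 0.0, 10)
        with pytest.raises(ValueError):
            expected_sfs(1.0, 0.0, 1)


class TestFit:
    def test_null_recovery(self):
        cfg = PopgenSimConfig(B=0.0, L_W=2e5, L_S=1.6e5)
        spectra, _ = simulate_polymorphism(cfg, np.random.default_rng(11))
        fit = fit_gbgc(spectra["WS"], spectra["SW"], spectra["conservative"], cfg.L_W, cfg.L_S)
        assert abs(fit.B) < 0.08

    def test_recovery_at_study_point_estimates(self):
        cfg = PopgenSimConfig()  # B=0.46, lambda=2.96, 1e6 sites
        spectra, _ = simulate_polymorphism(cfg, np.random.default_rng(5))
        fit = fit_gbgc(spectra["WS"], spectra["SW"], spectra["conservative"], cfg.L_W, cfg.L_S)
        assert fit.converged
        assert fit.B == pytest.approx(cfg.B, abs=0.1)
        assert fit.lam == pytest.approx(cfg.lam, abs=0.2)

    def test_noise_free_recovery_is_exact(self):
        from lepcodon.simulate import expected_class_spectra

        cfg = PopgenSimConfig()
        exp = expected_class_spectra(cfg)
        fit = fit_gbgc(exp["WS"], exp["SW"], exp["conservative"], cfg.L_W, cfg.L_S)
        assert fit.B == pytest.approx(cfg.B, abs=1e-3)
        assert fit.lam == pytest.approx(cfg.lam, abs=1e-3)

    def test_scale_equivariance(self):
        cfg = PopgenSimConfig(L_W=2e5, L_S=1.6e5)
        spectra, _ = simulate_polymorphism(cfg, np.random.default_rng(3))
        f1 = fit_gbgc(spectra["WS"], spectra["SW"], spectra["conservative"], cfg.L_W, cfg.L_S)
        f2 = fit_gbgc(2 * spectra["WS"], 2 * spectra["SW"], 2 * spectra["conservative"], cfg.L_W, cfg.L_S)
        assert f2.theta_WS == pytest.approx(2 * f1.theta_WS, rel=0.02)
        assert f2.B == pytest.approx(f1.B, abs=0.03)
        assert f2.lam == pytest.approx(f1.lam, rel=0.03)

    def test_distortion_absorbed_by_r(self):
        """Shared bin distortions leave B and lambda recoverable."""
        rng = np.random.default_rng(17)
        r = np.exp(rng.normal(0, 0.25, size=19))
        r = r / r.mean()
        cfg = PopgenSimConfig(distortion=r)
        spectra, _ = simulate_polymorphism(cfg, rng)
        fit = fit_gbgc(spectra["WS"], spectra["SW"], spectra["conservative"], cfg.L_W, cfg.L_S)
        assert fit.B == pytest.approx(cfg.B, abs=0.12)
        assert fit.lam == pytest.approx(cfg.lam, abs=0.2)

    def test_polarization_error_fit(self):
        cfg = PopgenSimConfig(polarization_error=0.08)
        spectra, _ = simulate_polymorphism(cfg, np.random.default_rng(23))
        fit = fit_gbgc(spectra["WS"], spectra["SW"], spectra["conservative"],
                       cfg.L_W, cfg.L_S, fit_error=True)
        assert fit.e == pytest.approx(0.08, abs=0.04)
        assert fit.B == pytest.approx(cfg.B, abs=0.15)

    def test_empty_spectra_rejected(self):
        z = np.zeros(19)
        with pytest.raises(ValueError):
            fit_gbgc(z, z, z, 1e5, 1e5)


class TestBootstrap:
    def test_determinism_and_ci_shape(self):
        cfg = PopgenSimConfig(L_W=1e5, L_S=0.8e5)
        spectra, _ = simulate_polymorphism(cfg, np.random.default_rng(2))
        args = (spectra["WS"], spectra["SW"], spectra["conservative"], cfg.L_W, cfg.L_S)
        f1 = bootstrap_fit(*args, n_boot=40, seed=9)
        f2 = bootstrap_fit(*args, n_boot=40, seed=9)
        assert f1.bootstrap["B_ci"] == f2.bootstrap["B_ci"]
        lo, hi = f1.bootstrap["B_ci"]
        assert lo <= f1.B <= hi

    def test_ci_width_shrinks_with_site_count(self):
        widths = []
        for factor in (1.0, 4.0):
            cfg = PopgenSimConfig(L_W=0.5e5 * factor, L_S=0.4e5 * factor)
            spectra, _ = simulate_polymorphism(cfg, np.random.default_rng(4))
            f = bootstrap_fit(spectra["WS"], spectra["SW"], spectra["conservative"],
                              cfg.L_W, cfg.L_S, n_boot=60, seed=1)
            lo, hi = f.bootstrap["B_ci"]
            widths.append(hi - lo)
        # 4x sites ~ half the CI width
        assert widths[1] < 0.75 * widths[0]


class TestFixturesRoundTrip:
    def test_vcf_gff_fasta_reparse_matches_truth(self, tmp_path, rng):
        """Emitted fixtures re-parse into the identical polarized site table."""
        cfg = PopgenSimConfig(L_W=5.5e5, L_S=4.5e5, mu_site=0.01)
        paths, truth = simulate_polymorphism_fixtures(
            cfg, tmp_path, rng, n_genes=12, gene_length_codons=90
        )
        sites, mono, excluded = extract_polarized_sites(
            paths["vcf"], paths["fasta"], paths["gff"], paths["outgroups"], n=cfg.n
        )
        got = {
            s.site_id: (s.degeneracy, s.mutation_class, s.derived_count, s.ancestral, s.derived)
            for s in sites
        }
        want = {
            s.site_id: (s.degeneracy, s.mutation_class, s.derived_count, s.ancestral, s.derived)
            for s in truth
        }
        assert got == want
        assert excluded["unpolarized"] == 0

    def test_polarization_error_flips_sites(self, tmp_path, rng):
        cfg = PopgenSimConfig(L_W=5.5e5, L_S=4.5e5, polarization_error=1.0)
        paths, truth = simulate_polymorphism_fixtures(
            cfg, tmp_path, rng, n_genes=6, gene_length_codons=60
        )
        sites, _, _ = extract_polarized_sites(
            paths["vcf"], paths["fasta"], paths["gff"], paths["outgroups"], n=cfg.n
        )
        got = {s.site_id: s.derived_count for s in sites}
        want = {s.site_id: s.n - s.derived_count for s in truth}  # fully inverted
        assert got == want
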