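"""Network enrichment of GWAS summary statistics: SNP annotation, the
spike-and-slab prior, variational fits against exact enumeration, and
Bayes factors."""
import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from retgnet.enrichment import (
    EffectSizePrior,
    annotate_snps,
    bayes_factor,
    default_grid,
    exact_bf_oracle,
    exact_grid_logml,
    exact_log_marginal,
    fit_grid,
    make_grid,
    model_mask,
    prior_at,
)
from retgnet.intervals import GenomicInterval, RegulatoryElement, ValidationError
from retgnet.network import RETGNetwork
from retgnet.simulate import GwasConfig, SimConfig, ar1_block_ld, gen_sumstats


def snp_frame(positions, chrom="chr1"):
    return pd.DataFrame({"chrom": chrom, "pos": positions})


def re_network(start=1_000_000, end=1_001_000):
    net = RETGNetwork()
    e = RegulatoryElement(
        GenomicInterval("chr1", start, end), "loop_anchor", "open"
    )
    net.elements[e.re_id] = e
    net.genes = {"g"}
    net.gene_category = {"g": "NoLoop"}
    return net


class TestAnnotateSnps:
    def test_window_boundaries_closed(self):
        net = re_network(1_000_000, 1_001_000)
        snps = snp_frame([
            1_000_000 - 49_999,  # inside the window
            1_000_000 - 50_000,  # exactly at the boundary: closed -> in
            1_000_000 - 50_001,  # outside
        ])
        a = annotate_snps(snps, network=net)
        assert list(a) == [1, 1, 0]

    def test_empty_network_all_zero(self):
        net = RETGNetwork()
        a = annotate_snps(snp_frame([1, 2, 3]), network=net)
        assert list(a) == [0, 0, 0]

    def test_unknown_chromosome_warns_and_zeroes(self):
        net = re_network()
        snps = pd.DataFrame({"chrom": ["chrX"], "pos": [1_000_000]})
        with pytest.warns(UserWarning, match="chrX"):
            a = annotate_snps(snps, network=net)
        assert list(a) == [0]

    def test_near_gene_mode(self):
        genes = pd.DataFrame(
            {"gene": ["g"], "chrom": ["chr1"], "start": [500_000],
             "end": [520_000], "strand": ["+"], "tss": [500_000]}
        )
        a = annotate_snps(
            snp_frame([450_001, 400_000]), genes=genes, mode="near_gene"
        )
        assert list(a) == [1, 0]

    def test_target_gene_bodies_annotated(self, default_study):
        """In network mode, SNPs inside a loop-linked gene's body count."""
        net = default_study.network
        genes = default_study.landscape.genes
        looped = [g for g in net.genes if net.gene_category[g] != "NoLoop"]
        row = genes[genes["gene"] == looped[0]].iloc[0]
        snps = snp_frame([int((row.start + row.end) // 2)])
        a = annotate_snps(snps, network=net, genes=genes)
        assert a[0] == 1


class TestPrior:
    def test_shift_arithmetic(self):
        prior = EffectSizePrior(0.1, 0.2, 1e-3, 5e-4)
        assert prior_at(prior, 1) == (pytest.approx(0.3), pytest.approx(1.5e-3))
        assert prior_at(prior, 0) == (pytest.approx(0.1), pytest.approx(1e-3))

    def test_m0_collapse_identical(self):
        prior = EffectSizePrior(0.05, 0.0, 1e-3, 0.0)
        assert prior_at(prior, 0) == prior_at(prior, 1)

    def test_invalid_pi_rejected(self):
        with pytest.raises(ValidationError):
            prior_at(EffectSizePrior(0.9, 0.2, 1e-3, 0.0), 1)

    def test_default_grid_respects_pi_bounds(self):
        grid = default_grid(n=10_000)
        assert ((grid["theta0"] + grid["theta"]) < 1).all()
        assert model_mask(grid, "M0").any()
        assert model_mask(grid, "M11").any()
        assert model_mask(grid, "M12").any()


class TestVariationalFit:
    def test_single_snp_matches_closed_form(self):
        """Mean-field VI is exact for one SNP: ELBO equals the two-component
        Gaussian mixture log marginal."""
        bh, se, pi, s2 = 0.8, 0.5, 0.3, 0.2
        exact = np.log(
            pi * norm.pdf(bh, 0, np.sqrt(s2 + se**2))
            + (1 - pi) * norm.pdf(bh, 0, se)
        )
        stats = pd.DataFrame({"betahat": [bh], "se": [se]})
        grid = pd.DataFrame(
            {"theta0": [pi], "theta": [0.0], "sigma0sq": [s2], "sigmasq": [0.0]}
        )
        fit = fit_grid(stats, np.eye(1), np.array([0]), grid)
        assert fit.grid["logml"][0] == pytest.approx(exact, abs=1e-6)

    def test_degenerate_slab_equals_null_loglik(self):
        rng = np.random.default_rng(0)
        p = 5
        se = np.full(p, 0.1)
        bh = rng.normal(0, 0.1, p)
        stats = pd.DataFrame({"betahat": bh, "se": se})
        grid = pd.DataFrame(
            {"theta0": [0.1], "theta": [0.0], "sigma0sq": [0.0], "sigmasq": [0.0]}
        )
        fit = fit_grid(stats, np.eye(p), np.zeros(p, int), grid)
        null = norm.logpdf(bh, 0, se).sum()
        assert fit.grid["logml"][0] == pytest.approx(null, abs=1e-9)

    @pytest.mark.parametrize("rho", [0.0, 0.4])
    def test_p8_matches_enumeration_oracle(self, rho):
        cfg = SimConfig(seed=3, gwas=GwasConfig(
            n=5000, p_snps=8, ld_block=4, ld_rho=rho,
            theta0=0.05, theta=0.2, sigma0sq=2e-3))
        a = np.array([0, 1, 0, 1, 1, 0, 1, 0], dtype=np.int8)
        stats, R, _ = gen_sumstats(cfg, a)
        grid = make_grid([0.05, 0.1], [0.0, 0.2], [2e-3], [0.0, 1.0])
        fit = fit_grid(stats, R, a, grid)
        exact = exact_grid_logml(stats, R, a, grid)
        diff = fit.grid["logml"].to_numpy() - exact
        assert np.abs(diff).max() < 0.1
        assert np.all(diff <= 1e-9)  # ELBO is a lower bound

    def test_p3_identity_ld_factorizes(self):
        """With identity LD the exact marginal is the product of per-SNP
        mixtures."""
        bh = np.array([0.3, -0.5, 0.1])
        se = np.array([0.2, 0.25, 0.3])
        pi = np.array([0.2, 0.4, 0.2])
        s2 = np.array([0.05, 0.05, 0.08])
        joint = exact_log_marginal(bh, se, np.eye(3), pi, s2)
        per_snp = sum(
            np.log(
                pi[j] * norm.pdf(bh[j], 0, np.sqrt(s2[j] + se[j] ** 2))
                + (1 - pi[j]) * norm.pdf(bh[j], 0, se[j])
            )
            for j in range(3)
        )
        assert joint == pytest.approx(per_snp, abs=1e-10)

    def test_elbo_histories_nondecreasing(self):
        cfg = SimConfig(seed=5, gwas=GwasConfig(n=5000, p_snps=40, ld_rho=0.5))
        rng = np.random.default_rng(1)
        a = (rng.uniform(size=40) < 0.5).astype(np.int8)
        stats, R, _ = gen_sumstats(cfg, a)
        grid = make_grid([0.01], [0.0, 0.05], [3e-3], [0.0, 1.0])
        fit = fit_grid(stats, R, a, grid)
        for hist in fit.elbo_histories:
            assert np.all(np.diff(hist) >= -1e-8 * np.maximum(1, np.abs(hist[:-1])))

    def test_oracle_refuses_large_p(self):
        stats = pd.DataFrame({"betahat": np.zeros(13), "se": np.ones(13)})
        grid = pd.DataFrame(
            {"theta0": [0.1], "theta": [0.0], "sigma0sq": [1e-3], "sigmasq": [0.0]}
        )
        with pytest.raises(ValidationError):
            exact_bf_oracle(stats, np.eye(13), np.zeros(13, int), grid, "M0")


class TestBayesFactor:
    def _fit(self, seed=0, p=60, theta=0.0):
        cfg = SimConfig(seed=seed, gwas=GwasConfig(n=10_000, p_snps=p, theta=theta))
        rng = np.random.default_rng(seed + 1000)
        a = (rng.uniform(size=p) < 0.5).astype(np.int8)
        stats, R, _ = gen_sumstats(cfg, a)
        n = 10_000
        grid = make_grid([0.004, 0.02], [0.0, 0.05], [30 / n], [0.0])
        return fit_grid(stats, R, a, grid), a, stats, R, grid

    def test_model_equals_baseline_is_one(self):
        fit, *_ = self._fit()
        assert bayes_factor(fit, "M0", "M0") == pytest.approx(1.0)

    def test_flat_likelihood_gives_unit_bf(self):
        """With a degenerate slab everywhere the likelihood is the same at
        every grid point, so every model BF is 1."""
        stats = pd.DataFrame({"betahat": [0.1, 0.2], "se": [0.1, 0.1]})
        grid = make_grid([0.01, 0.05], [0.0, 0.1], [0.0], [0.0])
        fit = fit_grid(stats, np.eye(2), np.array([0, 1]), grid)
        for model in ("M1", "M11"):
            assert bayes_factor(fit, model) == pytest.approx(1.0)

    def test_oracle_identity_for_baseline(self):
        _, a, stats, R, grid = self._fit()
        assert exact_bf_oracle(
            stats.iloc[:8], R[:8, :8], a[:8], grid, "M0"
        ) == pytest.approx(1.0)

    def test_scale_invariance_with_rescaled_variance_grid(self):
        """Scaling betahat and se by c, and slab variances by c^2, leaves
        every Bayes factor unchanged."""
        fit, a, stats, R, grid = self._fit(seed=2, theta=0.05)
        c = 3.7
        scaled = stats.copy()
        scaled["betahat"] *= c
        scaled["se"] *= c
        grid2 = grid.copy()
        grid2["sigma0sq"] *= c**2
        grid2["sigmasq"] *= c**2
        fit2 = fit_grid(scaled, R, a, grid2)
        for model in ("M1", "M11"):
            assert bayes_factor(fit2, model) == pytest.approx(
                bayes_factor(fit, model), rel=1e-5
            )

    def test_permutation_null_log_bf_centered(self):
        """No planted enrichment: log10 BF(M11:M0) has |median| < 0.5
        across seeds."""
        logs = []
        for seed in range(20):
            fit, *_ = self._fit(seed=seed, p=60, theta=0.0)
            logs.append(np.log10(bayes_factor(fit, "M11")))
        assert abs(np.median(logs)) < 0.5

    def test_parameter_recovery_at_generating_point(self):
        """Data generated at a grid point puts that point's logml within
        2 nats of the grid maximum (n=20,000, p=500)."""
        n = 20_000
        cfg = SimConfig(seed=42, gwas=GwasConfig(n=n, p_snps=500))
        rng = np.random.default_rng(4242)
        a = (rng.uniform(size=500) < 0.4).astype(np.int8)
        stats, R, _ = gen_sumstats(cfg, a)
        grid = make_grid(
            [0.001, 0.004, 0.02], [0.0, 0.01, 0.05], [10 / n, 30 / n, 100 / n],
            [0.0],
        )
        fit = fit_grid(stats, R, a, grid)
        g = fit.grid
        true_mask = (
            (g["theta0"] == 0.004) & (g["theta"] == 0.05)
            & np.isclose(g["sigma0sq"], 30 / n) & (g["sigmasq"] == 0.0)
        )
        assert true_mask.sum() == 1
        gap = g["logml"].max() - float(g.loc[true_mask, "logml"].iloc[0])
        assert gap <= 2.0
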