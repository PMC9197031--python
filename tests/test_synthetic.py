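"""Generator contracts: marginals, copula, niches, missingness, determinism."""

import numpy as np
import pytest
from scipy import stats

from phytoranges import (
    GradientSpec,
    NicheSpec,
    apply_missingness,
    default_gradient_spec,
    fit_positive_distribution,
    generate_occurrences,
    generate_sites,
    make_survey_bundle,
)
from phytoranges.data_io import CONTINUOUS_VARIABLES, ValidationError
from phytoranges.synthetic import _substrate_weights


class TestQuantileFit:
    def test_median_matched_exactly(self):
        fit = fit_positive_distribution(2.0, 8.0, 82.0)
        assert fit.achieved[1] == pytest.approx(8.0)
        assert np.exp(fit.mu) == pytest.approx(8.0)

    def test_log_symmetric_targets_fit_all_three_points(self):
        fit = fit_positive_distribution(1.0, 10.0, 100.0)
        assert fit.achieved == pytest.approx((1.0, 10.0, 100.0), rel=1e-9)

    def test_monte_carlo_quantiles_match_fit(self, rng):
        fit = fit_positive_distribution(0.1, 0.4, 1.5)
        draws = fit.rvs(100_000, rng)
        for q, target in zip((0.05, 0.5, 0.95), fit.achieved):
            assert np.quantile(draws, q) == pytest.approx(target, rel=0.05)

    def test_non_monotone_targets_rejected(self):
        with pytest.raises(ValidationError):
            fit_positive_distribution(5.0, 2.0, 10.0)


class TestGenerateSites:
    def test_identity_correlation_gives_near_zero_rank_correlations(self):
        spec = default_gradient_spec()
        spec.correlation.loc[:, :] = np.eye(6)
        sites = generate_sites(spec, 200, seed=1)
        vals = sites.data[list(CONTINUOUS_VARIABLES)].to_numpy()
        rho = stats.spearmanr(vals).statistic
        off = rho[~np.eye(6, dtype=bool)]
        assert np.abs(off).max() < 0.15

    def test_copula_correlation_realised_in_ranks(self):
        spec = default_gradient_spec()  # width-depth latent correlation 0.7
        sites = generate_sites(spec, 2000, seed=2)
        r = stats.spearmanr(sites.data["width"], sites.data["depth"]).statistic
        assert r == pytest.approx(0.7, abs=0.1)

    def test_marginal_quantiles_converge_to_targets(self):
        spec = default_gradient_spec()
        sites = generate_sites(spec, 20_000, seed=3)
        for var, (q5, q50, q95) in spec.quantiles.items():
            fit = fit_positive_distribution(q5, q50, q95)
            assert np.median(sites.data[var]) == pytest.approx(fit.achieved[1], rel=0.05)
            assert np.quantile(sites.data[var], 0.95) == pytest.approx(
                fit.achieved[2], rel=0.1
            )

    def test_substrate_follows_river_size(self):
        # wider/deeper rivers carry finer sediment on average
        sites = generate_sites(default_gradient_spec(), 4000, seed=4)
        from phytoranges.synthetic import SUBSTRATE_COARSE_TO_FINE

        fineness = {c: i for i, c in enumerate(SUBSTRATE_COARSE_TO_FINE)}
        f = sites.data["substrate"].map(fineness)
        r = stats.spearmanr(np.log(sites.data["width"] * sites.data["depth"]), f).statistic
        assert r > 0.3

    def test_determinism(self):
        spec = default_gradient_spec()
        a = generate_sites(spec, 50, seed=9)
        b = generate_sites(spec, 50, seed=9)
        assert a.data.equals(b.data)

    def test_invalid_correlation_matrix_rejected(self):
        spec = default_gradient_spec()
        with pytest.raises(ValidationError, match="positive-definite"):
            bad = spec.correlation.copy()
            bad.iloc[0, 1] = bad.iloc[1, 0] = 1.2
            GradientSpec(correlation=bad)


class TestGenerateOccurrences:
    def test_step_niche_is_a_hard_limit(self):
        sites = generate_sites(default_gradient_spec(), 400, seed=5)
        step = NicheSpec(1, {"total_phosphorus": ("below", 130.0, 0.0)}, baseline=0.9)
        occ, truth = generate_occurrences(sites, [step, NicheSpec(2, {}, baseline=0.7)], 8, seed=6)
        tp = sites.data["total_phosphorus"]
        g1_species = {s for s, g in truth.group_of.items() if g == 1}
        recs = occ.records
        g1_sites = recs.loc[recs["species_id"].isin(g1_species), "site_id"]
        assert (tp.loc[g1_sites] <= 130.0).all()

    def test_total_records_near_analytic_expectation(self):
        sites = generate_sites(default_gradient_spec(), 400, seed=7)
        niches = [NicheSpec(g, {}, baseline=0.7) for g in (1, 2)]
        occ, _ = generate_occurrences(
            sites, niches, 24, seed=8, abundance_multipliers=(1.0,)
        )
        expected = 24 * niches[0].occupancy(sites).sum()
        sd = np.sqrt(24 * (niches[0].occupancy(sites) * (1 - niches[0].occupancy(sites))).sum())
        assert abs(occ.n_records - expected) < 3 * sd

    def test_error_when_expected_occurrences_below_one(self):
        sites = generate_sites(default_gradient_spec(), 12, seed=9)
        tiny = NicheSpec(1, {"width": ("above", 5000.0, 0.0)}, baseline=0.1)
        with pytest.raises(ValidationError, match="increase baseline"):
            generate_occurrences(sites, [tiny, tiny], 4, seed=10)

    def test_truth_bundle_covers_every_species(self):
        b = make_survey_bundle(3, n_sites=100, n_species=8)
        assert len(b.truth.group_of) == 8
        assert set(b.occurrences.records["species_id"].unique()) <= set(b.truth.group_of)
        assert all(g in {1, 2, 3, 4} for g in b.truth.group_of.values())
        assert b.truth.n_groups() == 4


class TestMissingness:
    def test_zero_fractions_leave_table_unchanged(self, bundle):
        out = apply_missingness(bundle.sites_complete, {v: 0.0 for v in CONTINUOUS_VARIABLES}, 1)
        assert out.data.equals(bundle.sites_complete.data)

    def test_masked_count_is_binomial(self):
        sites = generate_sites(default_gradient_spec(), 1000, seed=11)
        out = apply_missingness(sites, {"alkalinity": 0.52}, seed=12)
        masked = int(out.data["alkalinity"].isna().sum())
        assert abs(masked - 520) < 3 * np.sqrt(1000 * 0.52 * 0.48)

    def test_masking_is_value_independent(self):
        # MCAR: masked and unmasked cells share the same mean
        sites = generate_sites(default_gradient_spec(), 4000, seed=13)
        out = apply_missingness(sites, {"alkalinity": 0.5}, seed=14)
        truth = sites.data["alkalinity"]
        miss = out.data["alkalinity"].isna()
        a, b = truth[miss], truth[~miss]
        se = np.sqrt(a.var() / len(a) + b.var() / len(b))
        assert abs(a.mean() - b.mean()) < 3 * se

    def test_substrate_maskable(self):
        sites = generate_sites(default_gradient_spec(), 500, seed=15)
        out = apply_missingness(sites, {"substrate": 0.5}, seed=16)
        assert 0.3 < out.data["substrate"].isna().mean() < 0.7


def test_bundle_determinism_byte_for_byte(tmp_path):
    from phytoranges.data_io import write_occurrences, write_site_table

    paths = []
    for tag in ("a", "b"):
        b = make_survey_bundle(21, n_sites=120, n_species=8)
        sp, op = tmp_path / f"sites_{tag}.csv", tmp_path / f"occ_{tag}.csv"
        write_site_table(b.sites, sp)
        write_occurrences(b.occurrences, op)
        (tmp_path / f"truth_{tag}.json").write_text(b.truth.to_json())
        paths.append((sp, op, tmp_path / f"truth_{tag}.json"))
    for fa, fb in zip(*paths):
        assert fa.read_bytes() == fb.read_bytes()


def test_substrate_weight_helper_normalises():
    w = _substrate_weights({"Sand": 3.0})
    assert w.sum() == pytest.approx(1.0)
    assert w.max() == w[1]  # Sand is the second category
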