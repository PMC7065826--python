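import numpy as np
import pytest

from mfqtl import (
    ChainConfig,
    IntervalGrid,
    Priors,
    call_qtls,
    permutation_threshold,
    qtl_contribution,
    qtl_intensity,
    run_mcmc,
    threshold_from_maxima,
)
from mfqtl import QTLSpec, adjust_for_environment, impute_interval_genotypes
from mfqtl.simulate import simulate_dataset

from conftest import three_family_config


def _field(p, grid=None, effect=None, seg=None, var_y=1.0, u_var=None):
    from mfqtl.bayes import PosteriorField

    p = np.asarray(p, dtype=float)
    m = len(p)
    if grid is None:
        grid = IntervalGrid.from_lengths([("1", float(m))])
    if effect is None:
        effect = np.ones(m)
    if seg is None:
        seg = np.ones((2, m))
    return PosteriorField(
        grid=grid,
        p=p,
        effect_mean=np.asarray(effect, dtype=float),
        seg_freq=np.asarray(seg, dtype=float),
        family_labels=["F1", "F2"],
        family_sizes=np.array([10, 10]),
        n_samples=100,
        mean_n=float(p.sum()),
        mu_mean=np.zeros(2),
        sigma2_mean=1.0,
        var_y=var_y,
        u_var=np.ones(m) if u_var is None else np.asarray(u_var, dtype=float),
    )


def test_intensity_is_sum_of_probabilities():
    f = _field([0.2, 0.3, 0.5, 0.0])
    assert qtl_intensity(f, "1") == pytest.approx(1.0)
    f0 = _field(np.zeros(5))
    assert qtl_intensity(f0, "1") == 0.0


def test_intensities_sum_to_mean_qtl_number(single_qtl_field):
    # bookkeeping identity: sum over chromosomes of intensity equals the
    # posterior mean number of QTLs
    total = sum(single_qtl_field.intensities().values())
    assert total == pytest.approx(single_qtl_field.mean_n, abs=1e-10)


def test_threshold_from_maxima():
    assert threshold_from_maxima(np.arange(1.0, 101.0), level=0.05) == 96.0
    assert threshold_from_maxima(np.full(40, 3.3), level=0.05) == 3.3
    # n=2 at 5%: ceil(0.1) = 1 -> the largest maximum
    assert threshold_from_maxima([1.0, 2.0], level=0.05) == 2.0
    with pytest.raises(ValueError):
        threshold_from_maxima([1.0, 2.0], level=0.0)


def test_call_qtls_below_threshold_silent():
    f = _field(np.full(30, 0.01))  # intensity 0.3
    assert call_qtls(f, threshold=0.4) == []
    with pytest.raises(ValueError):
        call_qtls(f, threshold=0.0)


def test_call_qtls_single_region_weighted_position():
    p = np.zeros(30)
    p[10], p[11], p[12] = 0.2, 0.4, 0.2
    f = _field(p)
    reports = call_qtls(f, threshold=0.5)
    assert len(reports) == 1
    rep = reports[0]
    assert rep.intensity == pytest.approx(0.8)
    # posterior-weighted midpoint: (0.2*10.5 + 0.4*11.5 + 0.2*12.5)/0.8
    assert rep.position_cm == pytest.approx(11.5)
    assert rep.effect == pytest.approx(1.0)
    assert rep.seg_prob["F1"] == pytest.approx(1.0)


def test_call_qtls_splits_bimodal_chromosome():
    p = np.zeros(40)
    p[5:8] = 0.25   # mode at ~6.5 cM, mass 0.75
    p[30:33] = 0.25  # mode at ~31.5 cM, mass 0.75
    f = _field(p)
    reports = call_qtls(f, threshold=0.5)
    assert len(reports) == 2
    assert reports[0].position_cm == pytest.approx(6.5)
    assert reports[1].position_cm == pytest.approx(31.5)
    # the split trough is excluded from both regions
    assert reports[0].end_cm <= 30.0 and reports[1].start_cm >= 8.0


def test_call_qtls_no_valid_split_warns():
    # all mass in one tight peak: intensity > 2x threshold yet unsplittable
    p = np.zeros(20)
    p[10] = 1.1
    f = _field(p)
    with pytest.warns(UserWarning, match="no valid split"):
        reports = call_qtls(f, threshold=0.5)
    assert len(reports) == 1


def test_contribution_definition():
    # p * sbar * a^2 * var_u / var_y summed over the region
    p = np.array([0.5, 0.3, 0.0])
    eff = np.array([2.0, 1.0, 5.0])
    seg = np.array([[1.0, 0.5, 1.0], [0.0, 0.5, 1.0]])
    f = _field(p, effect=eff, seg=seg, var_y=4.0, u_var=np.array([1.0, 0.8, 1.0]))
    expected = (0.5 * 0.5 * 4.0 * 1.0 + 0.3 * 0.5 * 1.0 * 0.8) / 4.0
    assert qtl_contribution(f, [0, 1, 2]) == pytest.approx(expected)
    assert qtl_contribution(_field(np.zeros(3)), [0, 1, 2]) == 0.0


def test_zero_variance_contribution_raises():
    with pytest.raises(ValueError):
        qtl_contribution(_field([0.1], var_y=0.0), [0])


def test_scan_recovers_single_qtl(single_qtl_data, single_qtl_field):
    field = single_qtl_field
    truth = single_qtl_data["truth"]["config"].qtls[0]
    # the QTL chromosome dominates
    intens = field.intensities()
    assert intens[truth.chromosome] == max(intens.values())
    assert intens[truth.chromosome] > 0.9
    peak = int(np.argmax(field.p))
    mid = field.grid.midpoints()[peak]
    assert field.grid.chrom_of()[peak] == truth.chromosome
    assert abs(mid - truth.position_cm) <= 5.0
    # sign and rough size of the effect at the peak
    assert field.effect_mean[peak] == pytest.approx(truth.effect, abs=0.25)
    # segregation detected in all three families
    assert np.all(field.seg_freq[:, peak] > 0.9)


def test_scan_called_region_contribution(single_qtl_data, single_qtl_field):
    # the contribution of the QTL chromosome should match the true share of
    # adjusted-phenotype variance explained by the genetic values (the
    # denominator includes genuine between-family mean differences)
    reports = call_qtls(single_qtl_field, threshold=0.45)
    best = max(reports, key=lambda r: r.contribution)
    assert best.chromosome == "2"
    gv = single_qtl_data["truth"]["genetic_values"]
    y = single_qtl_data["adjusted"]["value"].to_numpy(float)
    true_share = float(np.var(gv) / np.var(y))
    total = sum(r.contribution for r in reports if r.chromosome == "2")
    assert total == pytest.approx(true_share, abs=0.15)


def test_scan_seeds_agree_on_position(single_qtl_data):
    positions = []
    for seed in (11, 12, 13):
        fld = run_mcmc(
            single_qtl_data["adjusted"],
            single_qtl_data["ivgen"],
            chain=ChainConfig(iterations=1500, burn_in=400, thin=4, seed=seed),
        )
        peak = int(np.argmax(fld.p))
        assert fld.grid.chrom_of()[peak] == "2"
        positions.append(fld.grid.midpoints()[peak])
    assert np.ptp(positions) <= 6.0


def test_scan_family_specific_segregation():
    cfg = three_family_config(
        qtls=[QTLSpec("2", 50.0, 1.0, (1, 0, 0))],
        seed=31,
    )
    observed, plots, truth = simulate_dataset(cfg)
    adjusted = adjust_for_environment(plots, cfg.trait)
    grid = IntervalGrid.from_map(truth["map"])
    ivgen = impute_interval_genotypes(observed, grid)
    fld = run_mcmc(adjusted, ivgen, chain=ChainConfig(4000, 1000, 5, seed=2))
    peak = int(np.argmax(fld.p))
    assert fld.grid.chrom_of()[peak] == "2"
    seg = fld.seg_freq[:, peak]
    labels = list(fld.family_labels)
    assert seg[labels.index("F1")] > 0.9
    assert seg[labels.index("F2")] < 0.5
    assert seg[labels.index("F3")] < 0.5


def test_null_scan_stays_quiet():
    cfg = three_family_config(qtls=[], lines_per_family=60, seed=99)
    observed, plots, truth = simulate_dataset(cfg)
    adjusted = adjust_for_environment(plots, cfg.trait)
    grid = IntervalGrid.from_map(truth["map"])
    ivgen = impute_interval_genotypes(observed, grid)
    fld = run_mcmc(adjusted, ivgen, chain=ChainConfig(2000, 500, 5, seed=5))
    # with no signal the posterior QTL count stays below the prior mean
    assert fld.mean_n < Priors().n_qtl_mean
    perm = permutation_threshold(
        adjusted, ivgen, n_perm=20, level=0.10,
        chain=ChainConfig(2000, 500, 5, seed=5), seed=17,
    )
    assert perm.shortened_chain
    assert call_qtls(fld, perm.threshold) == []


def test_permutation_threshold_separates_signal(single_qtl_data, single_qtl_field):
    perm = permutation_threshold(
        single_qtl_data["adjusted"],
        single_qtl_data["ivgen"],
        n_perm=20,
        level=0.10,
        chain=ChainConfig(2000, 500, 5, seed=3),
        seed=8,
    )
    assert perm.threshold > 0
    assert single_qtl_field.intensity("2") > perm.threshold


def test_fix_s_matches_least_squares_single_family(single_qtl_data):
    # single-family scan with s pinned at 1: the effect at the true interval
    # should match the OLS regression slope within 2 SE
    ivgen = single_qtl_data["ivgen"]
    fam1 = np.flatnonzero(ivgen.families == "F1")
    sub = ivgen.subset_lines(fam1)
    adj = single_qtl_data["adjusted"]
    y = adj.set_index("line_id").loc[sub.line_ids, "value"].to_numpy(float)
    fld = run_mcmc(
        y, sub, chain=ChainConfig(3000, 800, 5, seed=6), fix_s=True
    )
    peak = int(np.argmax(fld.p))
    u = sub.hard[:, peak].astype(float)
    x = u - u.mean()
    slope = float(x @ (y - y.mean())) / float(x @ x)
    se = np.sqrt(np.var(y - y.mean() - slope * x) / float(x @ x))
    assert abs(fld.effect_mean[peak] - slope) < 2 * se + 0.05
    assert np.all(fld.seg_freq[:, peak] == 1.0)


def test_run_mcmc_input_validation(single_qtl_data):
    ivgen = single_qtl_data["ivgen"]
    with pytest.raises(ValueError, match="non-finite"):
        run_mcmc(np.full(ivgen.n_lines, np.nan), ivgen,
                 chain=ChainConfig(100, 10, 1, seed=0))
    with pytest.raises(ValueError, match="length"):
        run_mcmc(np.zeros(3), ivgen, chain=ChainConfig(100, 10, 1, seed=0))
    with pytest.raises(ValueError):
        ChainConfig(iterations=100, burn_in=100)
    with pytest.raises(ValueError, match="n_perm"):
        permutation_threshold(
            np.zeros(ivgen.n_lines), ivgen, n_perm=5,
            chain=ChainConfig(100, 10, 1, seed=0),
        )
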