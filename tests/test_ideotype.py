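import numpy as np
import pandas as pd
import pytest

from mfqtl import (
    IntervalGrid,
    PredictionModel,
    build_ideotypes,
    define_regions,
    generate_genotypes,
    predict_ideotype_phenotypes,
    regions_from_table,
)
from mfqtl.ideotype import IdeotypeSpec, QtlRegion
from mfqtl.refdata import load_ideotype_regions, load_multifamily_qtls
from mfqtl.simulate import default_wheat_chromosomes


def _grid(length=20.0):
    return IntervalGrid.from_lengths([("1", length)])


def test_define_regions_absorbs_short_gap():
    # (0, .02, .005, .03, 0): the sub-floor interval is flanked by
    # qualifying ones, so a single region spans intervals 1..3
    p = np.array([0.0, 0.02, 0.005, 0.03, 0.0])
    regions = define_regions(p, _grid(5.0))
    assert len(regions) == 1
    r = regions[0]
    np.testing.assert_array_equal(r.interval_indices, [1, 2, 3])
    assert (r.start_cm, r.end_cm) == (1.0, 4.0)
    assert r.posterior_mass == pytest.approx(0.055)


def test_define_regions_keeps_long_gaps_separate():
    p = np.zeros(10)
    p[1] = p[2] = 0.05
    p[6] = 0.05  # gap of 3 sub-floor intervals: not absorbed
    regions = define_regions(p, _grid(10.0))
    assert len(regions) == 2
    np.testing.assert_array_equal(regions[0].interval_indices, [1, 2])
    np.testing.assert_array_equal(regions[1].interval_indices, [6])


def test_define_regions_edge_gaps_not_absorbed():
    # a sub-floor run touching the chromosome end has only one flank
    p = np.array([0.02, 0.0, 0.0, 0.0, 0.0])
    regions = define_regions(p, _grid(5.0))
    assert len(regions) == 1
    np.testing.assert_array_equal(regions[0].interval_indices, [0])


def test_define_regions_empty_when_all_subfloor():
    assert define_regions(np.full(8, 0.005), _grid(8.0)) == []


def test_define_regions_partition_property(rng):
    p = rng.uniform(0, 0.05, 60)
    grid = IntervalGrid.from_lengths([("1", 30.0), ("2", 30.0)])
    regions = define_regions(p, grid)
    covered = np.concatenate([r.interval_indices for r in regions])
    assert len(covered) == len(set(covered))
    # every above-floor interval is covered by exactly one region
    above = set(np.flatnonzero(p > 0.01))
    assert above <= set(covered)
    for r in regions:
        assert len(set(grid.chrom_of()[r.interval_indices])) == 1


@pytest.fixture(scope="module")
def reference_setup():
    grid = IntervalGrid.from_lengths(default_wheat_chromosomes())
    region_table = load_ideotype_regions()
    qtl_table = load_multifamily_qtls()
    regions = regions_from_table(region_table, qtl_table, grid)
    return grid, region_table, qtl_table, regions


def test_regions_from_table_annotation(reference_setup):
    grid, region_table, qtl_table, regions = reference_setup
    assert len(regions) == len(region_table) == 21
    for region, (_, row) in zip(regions, region_table.iterrows()):
        assert region.chromosome == str(row["chromosome"])
        assert region.favorable in (-1, 1)
        idx = region.interval_indices
        assert len(idx) >= 1
        assert np.all(np.diff(idx) == 1)
        sub = grid.df.iloc[idx]
        assert float(sub["start_cm"].iloc[0]) <= row["start_cm"]
        assert float(sub["end_cm"].iloc[-1]) >= min(
            row["end_cm"], grid.df.iloc[grid.chrom_slice(region.chromosome)]["end_cm"].max()
        ) - 1.0


def test_ideotypes_reproduce_reference_pattern(reference_setup):
    """The released/fixed pattern of the ten ideotypes must match the
    bundled reference table exactly (A/B = fixed allele, '-' = released)."""
    grid, region_table, qtl_table, regions = reference_setup
    specs = build_ideotypes(regions, n_ideotypes=10)
    assert [s.label for s in specs] == list(range(1, 11))
    for k, spec in enumerate(specs, start=1):
        fixed = {id(r): allele for r, allele in spec.fixed}
        for region, (_, row) in zip(regions, region_table.iterrows()):
            published = str(row[f"ideo{k}"])
            if published == "-":
                assert id(region) not in fixed, (k, row["region"])
            else:
                allele = fixed.get(id(region))
                assert allele is not None, (k, row["region"])
                # B = common-parent allele (+1), A = donor allele (-1)
                assert allele == (1 if published == "B" else -1), (k, row["region"])


def test_build_ideotypes_too_many_raises(reference_setup):
    _, _, _, regions = reference_setup
    with pytest.raises(ValueError, match="at most"):
        build_ideotypes(regions, n_ideotypes=30)


def _region(grid, lo, hi, allele=1, chrom="1"):
    sub = grid.df.iloc[lo: hi + 1]
    return QtlRegion(
        chromosome=chrom,
        start_cm=float(sub["start_cm"].iloc[0]),
        end_cm=float(sub["end_cm"].iloc[-1]),
        interval_indices=np.arange(lo, hi + 1),
        favorable=allele,
    )


def test_overlapping_fixed_regions_rejected():
    grid = _grid(10.0)
    with pytest.raises(ValueError, match="overlap"):
        IdeotypeSpec(label=1, fixed=[
            (_region(grid, 2, 5), 1), (_region(grid, 4, 7), 1),
        ])


def test_generated_genotypes_honor_fixed_blocks():
    grid = IntervalGrid.from_lengths([("1", 40.0), ("2", 40.0)])
    r1 = _region(grid, 5, 8, chrom="1")
    r2 = _region(grid, 25, 27, chrom="1")
    r3 = _region(grid, 50, 52, chrom="2")
    spec = IdeotypeSpec(label=1, fixed=[(r1, 1), (r2, -1), (r3, 1)])
    g = generate_genotypes(spec, grid, n=400, seed=2)
    assert g.shape == (400, grid.m)
    assert set(np.unique(g)) <= {-1, 1}
    assert np.all(g[:, 5:9] == 1)
    assert np.all(g[:, 25:28] == -1)
    assert np.all(g[:, 50:53] == 1)
    # reproducible
    g2 = generate_genotypes(spec, grid, n=400, seed=2)
    np.testing.assert_array_equal(g, g2)


def test_free_chromosome_allele_frequency():
    grid = IntervalGrid.from_lengths([("1", 30.0)])
    spec = IdeotypeSpec(label=1, fixed=[])
    g = generate_genotypes(spec, grid, n=20000, seed=5)
    freq = (g == 1).mean(axis=0)
    se = 0.5 / np.sqrt(20000)
    assert np.all(np.abs(freq - 0.5) < 4 * se)


def test_far_intervals_decorrelate_from_fixed_block():
    grid = IntervalGrid.from_lengths([("1", 300.0)])
    spec = IdeotypeSpec(label=1, fixed=[(_region(grid, 0, 0), 1)])
    g = generate_genotypes(spec, grid, n=20000, seed=6)
    # ~300 cM away: essentially unlinked, frequency back to 1/2
    freq_far = (g[:, -1] == 1).mean()
    assert abs(freq_far - 0.5) < 0.02
    # adjacent interval stays nearly fixed
    assert (g[:, 1] == 1).mean() > 0.95


def test_zero_recombination_chromosome_inherits_block():
    # a grid whose midpoints coincide: rf = 0, the whole chromosome must
    # carry the fixed allele
    df = pd.DataFrame(
        {
            "chromosome": ["1"] * 4,
            "start_cm": [0.0] * 4,
            "end_cm": [0.0] * 4,
            "midpoint": [0.0] * 4,
        }
    )
    grid = IntervalGrid(df=df)
    spec = IdeotypeSpec(
        label=1,
        fixed=[(QtlRegion("1", 0.0, 0.0, interval_indices=np.array([1])), 1)],
    )
    g = generate_genotypes(spec, grid, n=200, seed=1)
    assert np.all(g == 1)


def test_infeasible_opposite_blocks_at_zero_distance():
    df = pd.DataFrame(
        {
            "chromosome": ["1"] * 4,
            "start_cm": [0.0] * 4,
            "end_cm": [0.0] * 4,
            "midpoint": [0.0] * 4,
        }
    )
    grid = IntervalGrid(df=df)
    spec = IdeotypeSpec(
        label=1,
        fixed=[
            (QtlRegion("1", 0.0, 0.0, interval_indices=np.array([0])), 1),
            (QtlRegion("1", 0.0, 0.0, interval_indices=np.array([3])), -1),
        ],
    )
    with pytest.raises(ValueError, match="infeasible|no .*recombination"):
        generate_genotypes(spec, grid, n=10, seed=1)


def test_bridge_switch_point_uniform():
    """Between opposite fixed alleles 11 intervals apart with equal step
    rfs, conditioning on the (dominant) single-switch path makes the switch
    position essentially uniform over the 12 gaps."""
    grid = IntervalGrid.from_lengths([("1", 12.0)])
    spec = IdeotypeSpec(
        label=1,
        fixed=[(_region(grid, 0, 0, 1), 1), (_region(grid, 11, 11, -1), -1)],
    )
    n = 12000
    g = generate_genotypes(spec, grid, n=n, seed=7)
    assert np.all(g[:, 0] == 1) and np.all(g[:, 11] == -1)
    # switch gap = first position where the sign drops
    switches = np.argmax(g <= 0, axis=1)  # in 1..11
    counts = np.bincount(switches, minlength=12)[1:12]
    # multi-switch paths are rare (~rf^2); allow 4 SE around uniform
    expected = n / 11
    se = np.sqrt(n * (1 / 11) * (10 / 11))
    assert np.all(np.abs(counts - expected) < 4 * se + 0.02 * expected)


def test_predict_ideotype_phenotypes_table():
    grid = _grid(10.0)
    w = np.zeros(grid.m)
    w[3] = 0.5
    models = {
        "FlYd": PredictionModel(m=grid.m, weights=w, mu_grand=70.0, mu_by_family={}),
        "Fla": PredictionModel(m=grid.m, weights=-w, mu_grand=2.0, mu_by_family={}),
    }
    sets = {
        1: np.ones((4, grid.m), dtype=np.int8),
        2: -np.ones((3, grid.m), dtype=np.int8),
    }
    table = predict_ideotype_phenotypes(sets, models)
    assert len(table) == (4 + 3) * 2 + 2  # plus the common-parent reference
    ref = table[table["ideotype"] == "common_parent"].set_index("trait")["value"]
    assert ref["FlYd"] == pytest.approx(70.5)
    assert ref["Fla"] == pytest.approx(1.5)
    ideo1 = table[(table["ideotype"] == 1) & (table["trait"] == "FlYd")]["value"]
    np.testing.assert_allclose(ideo1, 70.5)
    ideo2 = table[(table["ideotype"] == 2) & (table["trait"] == "FlYd")]["value"]
    np.testing.assert_allclose(ideo2, 69.5)


def test_released_region_mean_shift_matches_weights():
    # fixing a region at +1 vs leaving it free shifts the predicted mean by
    # the summed weights over that region (free intervals average ~0)
    grid = _grid(40.0)
    w = np.zeros(grid.m)
    w[10:14] = 0.3
    model = PredictionModel(m=grid.m, weights=w, mu_grand=0.0, mu_by_family={})
    fixed = IdeotypeSpec(label=1, fixed=[(_region(grid, 10, 13, 1), 1)])
    free = IdeotypeSpec(label=2, fixed=[])
    g_fixed = generate_genotypes(fixed, grid, n=8000, seed=3)
    g_free = generate_genotypes(free, grid, n=8000, seed=4)
    from mfqtl import predict

    shift = predict(model, g_fixed).mean() - predict(model, g_free).mean()
    assert shift == pytest.approx(w.sum(), abs=0.08)
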