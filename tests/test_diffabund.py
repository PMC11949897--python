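"""Size factors, dispersion, NB Wald test and the composed pipeline."""

import numpy as np
import pandas as pd
import pytest

from mycohub.diffabund import (
    DISPERSION_FLOOR,
    bh_adjust,
    differential_abundance,
    estimate_dispersion,
    nb_wald_test,
    size_factors_median_ratios,
)
from mycohub.io import AsvCountTable, SampleMetadata


def _table(rows, index=None, columns=None):
    rows = np.asarray(rows)
    index = index or [f"s{i}" for i in range(rows.shape[0])]
    columns = columns or [f"a{j}" for j in range(rows.shape[1])]
    return AsvCountTable(pd.DataFrame(rows, index=index, columns=columns))


def _meta(n_per_group, species=("X", "Y")):
    idx = [f"s{i}" for i in range(2 * n_per_group)]
    return SampleMetadata(pd.DataFrame({
        "species": [species[0]] * n_per_group + [species[1]] * n_per_group,
        "tissue": "leaf",
        "replicate": list(range(n_per_group)) * 2,
    }, index=idx)), idx


def test_size_factors_doubled_sample():
    tab = _table([[10, 20, 30], [20, 40, 60]])
    sf = size_factors_median_ratios(tab)
    assert sf.to_numpy() == pytest.approx([2 ** -0.5, 2 ** 0.5])


def test_size_factors_identical_samples():
    tab = _table([[5, 7], [5, 7], [5, 7]])
    assert size_factors_median_ratios(tab).to_numpy() == pytest.approx([1, 1, 1])


def test_size_factors_scale_equivariance():
    rng = np.random.default_rng(0)
    counts = rng.poisson(50, size=(4, 10)) + 1
    tab = _table(counts)
    sf = size_factors_median_ratios(tab)
    scaled = counts.copy()
    scaled[2] *= 3
    sf2 = size_factors_median_ratios(_table(scaled))
    # scaling a sample rescales the geometric reference too, so factors are
    # equivariant only up to one common constant: normalized counts agree
    norm1 = counts / sf.to_numpy()[:, None]
    norm2 = scaled / sf2.to_numpy()[:, None]
    ratio = norm2 / norm1
    assert ratio.std() == pytest.approx(0.0, abs=1e-9)


def test_size_factors_error_without_common_asv():
    tab = _table([[5, 0], [0, 5]])
    with pytest.raises(ValueError, match="pseudo_reference"):
        size_factors_median_ratios(tab)
    # the presence-restricted fallback still sizes the samples
    sf = size_factors_median_ratios(tab, pseudo_reference=True)
    assert (sf > 0).all()


def test_dispersion_constant_counts_at_floor():
    tab = _table([[10, 10]] * 6)
    meta, idx = _meta(3)
    sf = pd.Series(1.0, index=idx)
    disp = estimate_dispersion(tab, sf, meta.table["species"])
    assert np.allclose(disp.to_numpy(), DISPERSION_FLOOR)


def test_dispersion_poisson_near_floor():
    rng = np.random.default_rng(1)
    meta, idx = _meta(20)
    tab = _table(rng.poisson(rng.uniform(20, 300, 60), size=(40, 60)), index=idx)
    sf = size_factors_median_ratios(tab)
    disp = estimate_dispersion(tab, sf, meta.table["species"])
    assert np.median(disp) <= 0.01


def test_dispersion_recovers_nb_alpha():
    rng = np.random.default_rng(2)
    meta, idx = _meta(20)
    mu = rng.uniform(50, 400, 80)
    lam = rng.gamma(1 / 0.5, 0.5 * mu, size=(40, 80))
    tab = _table(rng.poisson(lam), index=idx)
    sf = size_factors_median_ratios(tab)
    disp = estimate_dispersion(tab, sf, meta.table["species"])
    assert 0.3 <= np.median(disp) <= 0.7


def test_wald_swapping_groups_negates_log2fc():
    rng = np.random.default_rng(3)
    meta, idx = _meta(6)
    counts = rng.poisson(100, size=(12, 10))
    counts[6:, 0] *= 4
    tab = _table(counts, index=idx)
    sf = size_factors_median_ratios(tab)
    disp = estimate_dispersion(tab, sf, meta.table["species"])
    fwd = nb_wald_test(tab, meta.table["species"], sf, disp, ("X", "Y"))
    rev = nb_wald_test(tab, meta.table["species"], sf, disp, ("Y", "X"))
    assert fwd["log2fc"].to_numpy() == pytest.approx(
        -rev["log2fc"].to_numpy(), abs=1e-8)


def test_wald_zero_group_pseudo_flag():
    meta, idx = _meta(3)
    counts = np.full((6, 3), 50)
    counts[:3, 0] = 0  # ASV absent from group X
    tab = _table(counts, index=idx)
    sf = pd.Series(1.0, index=idx)
    disp = pd.Series(0.1, index=tab.counts.columns)
    res = nb_wald_test(tab, meta.table["species"], sf, disp, ("X", "Y"))
    assert bool(res.iloc[0]["pseudo"])
    assert np.isnan(res.iloc[0]["p"])
    assert res.iloc[0]["log2fc"] > 0  # more abundant in the second group


def test_bh_adjust_textbook():
    out = bh_adjust([0.01, 0.02, 0.03, 0.04])
    assert out == pytest.approx([0.04, 0.04, 0.04, 0.04])
    assert bh_adjust([0.37]) == pytest.approx([0.37])


def test_bh_adjust_nan_tolerant():
    out = bh_adjust([0.01, np.nan, 0.02])
    assert np.isnan(out[1])
    assert out[0] == pytest.approx(0.02)


def test_planted_fold_change_detected():
    rng = np.random.default_rng(4)
    meta, idx = _meta(6)
    counts = rng.poisson(100, size=(12, 30))
    counts[6:, :3] = rng.poisson(800, size=(6, 3))  # log2fc = 3 planted
    tab = _table(counts, index=idx)
    res = differential_abundance(tab, meta, ("X", "Y"))
    sig = res.significant()
    assert {"a0", "a1", "a2"} <= set(sig.index)
    assert (sig["log2fc"] > 2).all()
    directions = res.direction_counts()
    assert directions["up_in_Y"] >= 3
    assert directions["up_in_X"] == 0


def test_threshold_monotonicity():
    rng = np.random.default_rng(5)
    meta, idx = _meta(6)
    counts = rng.poisson(100, size=(12, 20))
    counts[6:, :2] *= 6
    tab = _table(counts, index=idx)
    strict = differential_abundance(tab, meta, ("X", "Y"),
                                    padj_max=0.01, lfc_min=2.0)
    loose = differential_abundance(tab, meta, ("X", "Y"),
                                   padj_max=0.05, lfc_min=1.0)
    assert set(strict.significant().index) <= set(loose.significant().index)


def test_sample_reordering_invariance():
    rng = np.random.default_rng(6)
    meta, idx = _meta(5)
    counts = rng.poisson(80, size=(10, 15))
    tab = _table(counts, index=idx)
    res1 = differential_abundance(tab, meta, ("X", "Y"))
    shuffled = tab.counts.sample(frac=1.0, random_state=1)
    res2 = differential_abundance(AsvCountTable(shuffled), meta, ("X", "Y"))
    assert res1.table["log2fc"].to_numpy() == pytest.approx(
        res2.table["log2fc"].to_numpy(), abs=1e-8)


def test_contrast_selecting_nothing_errors(tiny_table, tiny_meta):
    with pytest.raises(ValueError, match="no samples"):
        differential_abundance(tiny_table, tiny_meta, ("A", "B"))
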