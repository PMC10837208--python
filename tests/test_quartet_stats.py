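"""ABBA-BABA D, windowed fd, jackknife calibration and the outlier rule."""

import math

import numpy as np
import pytest

from ricebarrier import (
    SiteFrequencies,
    WindowSpec,
    fd_window,
    jackknife_z,
    outlier_windows,
    patterson_d,
    scan_windows,
    simulate_admixed_windows,
    site_terms,
)


def sf(p1, p2, p3, p4, pos=1, chrom="chr1", **kw):
    return SiteFrequencies(p1, p2, p3, p4, pos=pos, chrom=chrom, **kw)


# ---------------------------------------------------------------------------
# Site terms and D
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "freqs,expected",
    [
        ((0, 1, 1, 0), (1.0, 0.0)),
        ((1, 0, 1, 0), (0.0, 1.0)),
        ((0.2, 0.8, 0.6, 0.0), (0.384, 0.024)),
    ],
)
def test_site_terms_patterns(freqs, expected):
    assert site_terms(sf(*freqs)) == pytest.approx(expected)


def test_patterson_d_fixed_patterns_and_symmetry():
    assert patterson_d([sf(0, 1, 1, 0)]).D == 1.0
    assert patterson_d([sf(0, 1, 1, 0, pos=1), sf(1, 0, 1, 0, pos=2)]).D == 0.0
    assert patterson_d([sf(0.2, 0.8, 0.6, 0.0)]).D == pytest.approx(0.36 / 0.408)


def test_patterson_d_sign_flips_when_p1_p2_swapped():
    sites = [sf(0.1, 0.7, 0.5, 0.05, pos=i + 1) for i in range(20)]
    swapped = [sf(s.p2, s.p1, s.p3, s.p4, pos=s.pos) for s in sites]
    assert patterson_d(sites).D == pytest.approx(-patterson_d(swapped).D)


def test_patterson_d_bounded():
    rng = np.random.default_rng(5)
    sites = [
        sf(*rng.uniform(0, 1, size=4), pos=i + 1) for i in range(200)
    ]
    assert abs(patterson_d(sites).D) <= 1.0


def test_patterson_d_undefined_without_informative_sites():
    with pytest.raises(ValueError):
        patterson_d([sf(0, 0, 0, 0)])


# ---------------------------------------------------------------------------
# Jackknife
# ---------------------------------------------------------------------------

def test_jackknife_degenerate_identical_blocks():
    sites = [sf(0, 1, 1, 0, pos=1 + i * 1_000_000) for i in range(12)]
    res = jackknife_z(sites, block_size=1_000_000)
    assert math.isinf(res.Z) and res.Z > 0


def test_jackknife_requires_ten_blocks():
    sites = [sf(0, 1, 1, 0, pos=1 + i * 1_000_000) for i in range(5)]
    with pytest.raises(ValueError):
        jackknife_z(sites, block_size=1_000_000)


def test_jackknife_null_calibration():
    hits = 0
    n_runs = 30
    for seed in range(n_runs):
        sites, _ = simulate_admixed_windows(
            n_windows=60, sites_per_window=150, introgressed_fraction=0.0, seed=seed
        )
        z = jackknife_z(sites, block_size=300_000).Z
        hits += abs(z) < 3
    assert hits / n_runs >= 0.9


def test_jackknife_power_under_admixture():
    zs = []
    for seed in range(10):
        sites, _ = simulate_admixed_windows(
            n_windows=60, sites_per_window=150,
            introgressed_fraction=1.0, f_admix=0.2, seed=seed,
        )
        zs.append(jackknife_z(sites, block_size=300_000).Z)
    assert np.median(zs) > 3


# ---------------------------------------------------------------------------
# fd
# ---------------------------------------------------------------------------

def test_fd_window_worked_example():
    w = fd_window([sf(0, 0.4, 0.8, 0)], min_sites=1)
    assert w.fd == pytest.approx(0.5)
    assert w.passed_filters


def test_fd_equals_one_when_p2_matches_donor():
    sites = [sf(0.1, 0.6, 0.6, 0.0, pos=i + 1) for i in range(5)]
    w = fd_window(sites, min_sites=1)
    assert w.fd == pytest.approx(1.0)


def test_fd_missing_for_negative_numerator():
    w = fd_window([sf(0.9, 0.1, 0.8, 0.0)], min_sites=1)
    assert w.fd is None
    assert w.D < 0


def test_fd_filters_genotyped_fraction_and_min_sites():
    thin = [sf(0, 0.4, 0.8, 0, genotyped_fraction=0.1)]
    w = fd_window(thin, min_sites=1)
    assert w.n_good_sites == 0 and not w.passed_filters and w.fd is None
    # threshold boundary: 99 good sites fails a 100-site filter
    sites = [sf(0, 0.4, 0.8, 0, pos=i + 1) for i in range(99)]
    assert not fd_window(sites, min_sites=100).passed_filters


def test_fd_invariant_to_site_order():
    rng = np.random.default_rng(9)
    sites = [sf(*rng.uniform(0, 1, 4), pos=i + 1) for i in range(50)]
    fwd = fd_window(sites, min_sites=1)
    rev = fd_window(sites[::-1], min_sites=1)
    assert fwd.fd == pytest.approx(rev.fd, rel=1e-12)
    assert fwd.n_good_sites == rev.n_good_sites


# ---------------------------------------------------------------------------
# Window scan
# ---------------------------------------------------------------------------

def test_scan_windows_tiling_two_chromosomes():
    sites = [sf(0.1, 0.5, 0.5, 0.0, pos=p, chrom=c)
             for c in ("chr1", "chr2")
             for p in range(1, 3_000_001, 10_000)]
    wins = scan_windows(sites, WindowSpec(300_000), min_sites=10)
    assert len(wins) == 20
    for w in wins:
        assert w.end - w.start == 300_000
    starts = [w.start for w in wins if w.chrom == "chr1"]
    assert starts == sorted(starts)
    assert len({(w.chrom, w.start) for w in wins}) == 20


def test_scan_windows_rejects_unsorted_input():
    sites = [sf(0.1, 0.5, 0.5, 0.0, pos=100), sf(0.1, 0.5, 0.5, 0.0, pos=50)]
    with pytest.raises(ValueError):
        scan_windows(sites)


def test_admixed_windows_rank_above_null_windows():
    sites, truth = simulate_admixed_windows(
        n_windows=200, sites_per_window=200, introgressed_fraction=0.05,
        f_admix=0.2, seed=4,
    )
    wins = scan_windows(sites, WindowSpec(300_000), min_sites=100)
    intro = set(truth.truth["introgressed_windows"])
    fd_intro = [w.fd for i, w in enumerate(wins) if i in intro and w.fd is not None]
    fd_null = [w.fd for i, w in enumerate(wins) if i not in intro and w.fd is not None]
    assert np.mean(fd_intro) > np.mean(fd_null)


# ---------------------------------------------------------------------------
# Outlier rule
# ---------------------------------------------------------------------------

def test_outlier_windows_planted_construction():
    rng = np.random.default_rng(2)
    values = list(rng.uniform(0.0, 0.05, size=1000))
    planted = [13, 200, 456, 789, 999]
    for i in planted:
        values[i] = 0.5
    assert sorted(outlier_windows(values)) == planted


def test_outlier_windows_below_minimum_returns_empty():
    assert outlier_windows(list(np.linspace(0, 1, 100))) == []


def test_outlier_windows_all_tied_capped():
    out = outlier_windows([0.3] * 400)
    assert len(out) == 2  # floor(400 * 0.005)
    assert out == [0, 1]


def test_outlier_windows_ignores_missing():
    values = [None] * 300 + list(np.linspace(0, 1, 300))
    out = outlier_windows(values)
    assert all(i >= 300 for i in out)
    assert len(out) >= 1
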