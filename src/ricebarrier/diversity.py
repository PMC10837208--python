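"""Sliding-window nucleotide diversity, pairwise LD and allelic association.

Per-site diversity uses the unbiased pairwise heterozygosity
``2 k (n - k) / (n (n - 1))`` for a derived-allele count ``k`` among ``n``
called alleles; window values divide the site sum by the *full* window
length (monomorphic and uncalled positions contribute zero), matching the
convention of the common VCF window-π tools.  LD r² treats each sample's
two haploid calls as independent observations (unphased approximation).
The case/control test is the standard one-degree-of-freedom allelic
chi-square on the 2x2 allele-count table.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .io_core import VariantSite, _MISSING

DEFAULT_PI_WINDOW = 5_000


@dataclass(frozen=True)
class PiWindow:
    chrom: str
    start: int  # 0-based half-open
    end: int
    n_variants: int
    sum_site_pi: float
    pi_per_base: float


@dataclass(frozen=True)
class AssocResult:
    """Allelic 2x2 test: rows case/control, columns alt/ref allele counts."""

    case_alt: int
    case_ref: int
    ctrl_alt: int
    ctrl_ref: int
    chi2: float
    df: int
    p: float


@dataclass(frozen=True)
class LdPair:
    chrom_a: str
    pos_a: int
    chrom_b: str
    pos_b: int
    r2: float | None  # None when either site is monomorphic among joint calls
    n_haplotypes: int


# ---------------------------------------------------------------------------
# Nucleotide diversity
# ---------------------------------------------------------------------------

def site_pi(k: int, n: int) -> float:
    """Unbiased per-site pairwise diversity 2k(n-k) / (n(n-1))."""
    if n < 2:
        raise ValueError(f"site_pi requires >= 2 called alleles, got {n}")
    if not 0 <= k <= n:
        raise ValueError(f"derived count {k} outside [0, {n}]")
    return 2.0 * k * (n - k) / (n * (n - 1.0))


def window_pi(
    sites: Sequence[VariantSite],
    window: int = DEFAULT_PI_WINDOW,
    step: int | None = None,
    region_end: int | None = None,
) -> list[PiWindow]:
    """Per-window π over sorted variant sites.

    Windows are 0-based half-open of ``window`` bases (stride ``step``,
    default non-overlapping), anchored at 0 and tiled per chromosome up to
    the last variant (or ``region_end``).  Sites with fewer than 2 called
    alleles contribute nothing; empty windows report π = 0.
    """
    if window <= 0:
        raise ValueError("window size must be > 0")
    stride = step if step is not None else window
    by_chrom: dict[str, list[VariantSite]] = {}
    prev: tuple[str, int] | None = None
    seen: set[str] = set()
    for s in sites:
        if prev is not None and s.chrom == prev[0] and s.pos < prev[1]:
            raise ValueError(f"sites not sorted at {s.chrom}:{s.pos}")
        if s.chrom not in by_chrom and s.chrom in seen:
            raise ValueError("sites not sorted: chromosome blocks not contiguous")
        seen.add(s.chrom)
        by_chrom.setdefault(s.chrom, []).append(s)
        prev = (s.chrom, s.pos)
    out: list[PiWindow] = []
    for chrom, csites in by_chrom.items():
        positions = [s.pos for s in csites]
        limit = region_end if region_end is not None else csites[-1].pos
        start = 0
        while start < limit:
            end = start + window
            total = 0.0
            count = 0
            lo = bisect.bisect_right(positions, start)
            hi = bisect.bisect_right(positions, end)
            for s in csites[lo:hi]:
                k, n = s.allele_counts()
                if n >= 2:
                    total += site_pi(k, n)
                    count += 1
            out.append(PiWindow(chrom, start, end, count, total, total / window))
            start += stride
    return out


# ---------------------------------------------------------------------------
# Association
# ---------------------------------------------------------------------------

def allelic_chisq(case_alt: int, case_ref: int, ctrl_alt: int, ctrl_ref: int) -> AssocResult:
    """One-degree-of-freedom allelic chi-square on a 2x2 allele-count table.

    Pearson statistic without continuity correction,
    ``n (ad - bc)^2 / (r1 r2 c1 c2)``; p is the upper tail at df = 1.
    """
    a, b, c, d = case_alt, case_ref, ctrl_alt, ctrl_ref
    for x in (a, b, c, d):
        if x < 0:
            raise ValueError("allele counts must be non-negative")
    n = a + b + c + d
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if n == 0 or 0 in (r1, r2, c1, c2):
        raise ValueError("degenerate margin: allelic chi-square undefined")
    chi2 = n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)
    return AssocResult(a, b, c, d, float(chi2), 1, float(stats.chi2.sf(chi2, 1)))


def assoc_scan(
    sites: Sequence[VariantSite],
    case_idx: Sequence[int],
    ctrl_idx: Sequence[int],
) -> list[tuple[VariantSite, AssocResult | None]]:
    """Per-SNP allelic association between case and control sample indices.

    Sites with a degenerate margin (monomorphic among called alleles or a
    group with no calls) report ``None``.
    """
    rows: list[tuple[VariantSite, AssocResult | None]] = []
    for s in sites:
        counts = []
        for idx in (case_idx, ctrl_idx):
            alt = ref = 0
            for i in idx:
                for h in s.calls[i]:
                    if h == 1:
                        alt += 1
                    elif h == 0:
                        ref += 1
            counts += [alt, ref]
        try:
            rows.append((s, allelic_chisq(*counts)))
        except ValueError:
            rows.append((s, None))
    return rows


# ---------------------------------------------------------------------------
# Linkage disequilibrium
# ---------------------------------------------------------------------------

def ld_r2(site_a: VariantSite, site_b: VariantSite) -> LdPair:
    """Squared allelic correlation between two sites.

    Haplotypes are paired by position within each sample's call pair (the
    unphased haploid-expansion approximation); only haplotypes called at
    both sites enter.  Returns r² = (p_AB - p_A p_B)² / (p_A q_A p_B q_B),
    undefined (None) when either site is monomorphic among joint calls.
    """
    if len(site_a.calls) != len(site_b.calls):
        raise ValueError("sites have different sample counts")
    a_obs, b_obs = [], []
    for (a1, a2), (b1, b2) in zip(site_a.calls, site_b.calls):
        for ha, hb in ((a1, b1), (a2, b2)):
            if ha != _MISSING and hb != _MISSING:
                a_obs.append(ha)
                b_obs.append(hb)
    n = len(a_obs)
    if n < 2:
        raise ValueError("ld_r2 requires >= 2 jointly called haplotypes")
    pa = sum(a_obs) / n
    pb = sum(b_obs) / n
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        return LdPair(site_a.chrom, site_a.pos, site_b.chrom, site_b.pos, None, n)
    pab = sum(x * y for x, y in zip(a_obs, b_obs)) / n
    r2 = (pab - pa * pb) ** 2 / (pa * (1 - pa) * pb * (1 - pb))
    return LdPair(site_a.chrom, site_a.pos, site_b.chrom, site_b.pos, float(r2), n)


def ld_matrix(sites: Sequence[VariantSite]) -> np.ndarray:
    """Pairwise r² over a list of sites (NaN where undefined)."""
    m = len(sites)
    out = np.full((m, m), np.nan)
    for i in range(m):
        out[i, i] = 1.0
        for j in range(i + 1, m):
            pair = ld_r2(sites[i], sites[j])
            if pair.r2 is not None:
                out[i, j] = out[j, i] = pair.r2
    return out
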