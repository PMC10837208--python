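"""Patterson's D and the windowed fd introgression scan.

Four populations (P1, P2, P3, outgroup O) are compared through per-site
derived-allele frequencies.  In the frequency form the discordant-pattern
terms at a site are::

    abba = (1 - p1) * p2 * p3 * (1 - p4)
    baba = p1 * (1 - p2) * p3 * (1 - p4)

D sums (abba - baba) over (abba + baba); significance comes from a
delete-one block jackknife.  fd rescales the window numerator by its
maximal value with a per-site donor ``pD = max(p2, p3)`` substituted for
both P2 and P3, localizing introgressed regions; windows in the top 0.5% of
the genome-wide fd distribution are flagged as introgressed.

Default window parameters follow the scan this module reproduces: 300-kb
windows, at least 100 good sites per window, and a per-site genotyped
fraction of at least 0.2.
"""

from __future__ import annotations

import bisect
import logging
import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .io_core import PopulationMap, VariantSite

logger = logging.getLogger("ricebarrier")

DEFAULT_WINDOW_SIZE = 300_000
DEFAULT_MIN_SITES = 100
DEFAULT_MIN_GENOTYPED = 0.2
OUTLIER_QUANTILE = 0.995


@dataclass(frozen=True)
class SiteFrequencies:
    """Per-site derived-allele frequencies and call counts in P1, P2, P3, O."""

    p1: float
    p2: float
    p3: float
    p4: float
    n1: int = 1
    n2: int = 1
    n3: int = 1
    n4: int = 1
    genotyped_fraction: float = 1.0
    chrom: str = "chr"
    pos: int = 1

    @property
    def defined(self) -> bool:
        """True when every population has at least one called allele."""
        return min(self.n1, self.n2, self.n3, self.n4) > 0

    def is_good(self, min_genotyped: float = DEFAULT_MIN_GENOTYPED) -> bool:
        """Usable for D/fd: frequencies defined, genotyped enough, not monomorphic."""
        if not self.defined:
            return False
        if self.genotyped_fraction < min_genotyped:
            return False
        ps = (self.p1, self.p2, self.p3, self.p4)
        return not (all(p == 0.0 for p in ps) or all(p == 1.0 for p in ps))


@dataclass(frozen=True)
class WindowSpec:
    """Genomic window grid: 0-based half-open windows of ``size``, stride ``step``."""

    size: int = DEFAULT_WINDOW_SIZE
    step: int | None = None  # None = non-overlapping (step = size)

    def __post_init__(self) -> None:
        if self.size <= 0:
            raise ValueError("window size must be > 0")
        if self.step is not None and self.step <= 0:
            raise ValueError("window step must be > 0")

    @property
    def stride(self) -> int:
        return self.step if self.step is not None else self.size


@dataclass(frozen=True)
class DStat:
    D: float
    numerator: float
    denominator: float
    n_sites: int
    Z: float | None = None


@dataclass(frozen=True)
class FdStat:
    fd: float | None
    chrom: str
    start: int  # 0-based half-open
    end: int
    n_good_sites: int
    passed_filters: bool
    D: float | None = None


# ---------------------------------------------------------------------------
# Site terms and D
# ---------------------------------------------------------------------------

def site_terms(s: SiteFrequencies) -> tuple[float, float]:
    """(abba, baba) pattern weights at one site, frequency form."""
    abba = (1.0 - s.p1) * s.p2 * s.p3 * (1.0 - s.p4)
    baba = s.p1 * (1.0 - s.p2) * s.p3 * (1.0 - s.p4)
    return abba, baba


def patterson_d(sites: Sequence[SiteFrequencies]) -> DStat:
    """Genome- or window-level D = sum(abba - baba) / sum(abba + baba)."""
    num = den = 0.0
    n = 0
    for s in sites:
        abba, baba = site_terms(s)
        num += abba - baba
        den += abba + baba
        n += 1
    if n == 0 or den == 0.0:
        raise ValueError("D undefined: no informative sites (zero denominator)")
    return DStat(num / den, num, den, n)


def jackknife_z(sites: Sequence[SiteFrequencies], block_size: int = 1_000_000) -> DStat:
    """D with a delete-one block-jackknife z-score.

    Blocks are ``block_size``-base bins per chromosome; at least 10
    non-empty blocks are required.  A zero jackknife SE yields an infinite
    Z with the sign of D.
    """
    num = den = 0.0
    bnum: dict[tuple[str, int], float] = {}
    bden: dict[tuple[str, int], float] = {}
    for s in sites:
        abba, baba = site_terms(s)
        num += abba - baba
        den += abba + baba
        key = (s.chrom, (s.pos - 1) // block_size)
        bnum[key] = bnum.get(key, 0.0) + abba - baba
        bden[key] = bden.get(key, 0.0) + abba + baba
    if den == 0.0:
        raise ValueError("D undefined: zero denominator")
    keys = sorted(bnum)
    if len(keys) < 10:
        raise ValueError(f"jackknife requires >= 10 non-empty blocks, got {len(keys)}")
    d_full = num / den
    pseudo = []
    for key in keys:
        den_i = den - bden[key]
        if den_i == 0.0:
            continue
        pseudo.append((num - bnum[key]) / den_i)
    b = len(pseudo)
    mean = sum(pseudo) / b
    var = (b - 1) / b * sum((x - mean) ** 2 for x in pseudo)
    se = math.sqrt(var)
    if se == 0.0:
        z = math.copysign(math.inf, d_full) if d_full != 0.0 else 0.0
    else:
        z = d_full / se
    return DStat(d_full, num, den, len(sites), Z=z)


# ---------------------------------------------------------------------------
# fd and windows
# ---------------------------------------------------------------------------

def fd_window(
    sites: Sequence[SiteFrequencies],
    chrom: str = "chr",
    start: int = 0,
    end: int = DEFAULT_WINDOW_SIZE,
    min_sites: int = DEFAULT_MIN_SITES,
    min_genotyped: float = DEFAULT_MIN_GENOTYPED,
) -> FdStat:
    """fd for one window of sites.

    Good sites (defined frequencies, genotyped fraction >= ``min_genotyped``,
    polymorphic somewhere) enter both sums.  The denominator recomputes the
    numerator with both p2 and p3 replaced by the per-site donor
    ``pD = max(p2, p3)``.  fd is missing when the numerator is <= 0 or the
    window fails the ``min_sites`` filter.
    """
    good = [s for s in sites if s.is_good(min_genotyped)]
    n_good = len(good)
    passed = n_good >= min_sites
    num = den = dden = 0.0
    for s in good:
        abba, baba = site_terms(s)
        num += abba - baba
        dden += abba + baba
        pd_ = max(s.p2, s.p3)
        donor = replace(s, p2=pd_, p3=pd_)
        abba_d, baba_d = site_terms(donor)
        den += abba_d - baba_d
    d_value = num / dden if dden > 0.0 else None
    if not passed or num <= 0.0 or den <= 0.0:
        return FdStat(None, chrom, start, end, n_good, passed, D=d_value)
    return FdStat(num / den, chrom, start, end, n_good, passed, D=d_value)


def scan_windows(
    sites: Sequence[SiteFrequencies],
    spec: WindowSpec = WindowSpec(),
    min_sites: int = DEFAULT_MIN_SITES,
    min_genotyped: float = DEFAULT_MIN_GENOTYPED,
) -> list[FdStat]:
    """Tile the genome into windows and compute D/fd per window.

    ``sites`` must be sorted by (chrom, pos) with 1-based positions; windows
    are 0-based half-open, anchored at 0, spanning each chromosome's
    observed sites.
    """
    _check_sorted(sites)
    by_chrom: dict[str, list[SiteFrequencies]] = {}
    for s in sites:
        by_chrom.setdefault(s.chrom, []).append(s)
    results: list[FdStat] = []
    for chrom, csites in by_chrom.items():
        positions = [s.pos for s in csites]
        max_pos = positions[-1]
        start = 0
        while start < max_pos:
            end = start + spec.size
            lo = bisect.bisect_right(positions, start)
            hi = bisect.bisect_right(positions, end)
            results.append(
                fd_window(csites[lo:hi], chrom, start, end, min_sites, min_genotyped)
            )
            start += spec.stride
    return results


def _check_sorted(sites: Sequence[SiteFrequencies]) -> None:
    seen: set[str] = set()
    prev_chrom = None
    prev_pos = -1
    for s in sites:
        if s.chrom != prev_chrom:
            if s.chrom in seen:
                raise ValueError("sites not sorted: chromosome blocks not contiguous")
            seen.add(s.chrom)
            prev_chrom, prev_pos = s.chrom, s.pos
        elif s.pos < prev_pos:
            raise ValueError(f"sites not sorted at {s.chrom}:{s.pos}")
        else:
            prev_pos = s.pos


def outlier_windows(fd_values: Sequence[float | None]) -> list[int]:
    """Indices of windows in the top 0.5% of the fd distribution.

    Missing values are excluded from both the quantile and the candidates.
    Fewer than 200 non-missing values yield an empty set (the top 0.5% is
    empty by construction).  If ties at the threshold inflate the set beyond
    0.5% of the non-missing windows, the lexicographically first indices are
    kept and the tie is logged.
    """
    present = [(i, v) for i, v in enumerate(fd_values) if v is not None and math.isfinite(v)]
    if len(present) < 200:
        return []
    values = np.array([v for _, v in present])
    threshold = float(np.quantile(values, OUTLIER_QUANTILE))
    candidates = [i for i, v in present if v >= threshold]
    cap = max(1, math.floor(len(present) * (1.0 - OUTLIER_QUANTILE)))
    if len(candidates) > cap:
        logger.info(
            "outlier_windows: %d windows tie at the 99.5%% threshold; keeping first %d",
            len(candidates), cap,
        )
        candidates = sorted(candidates)[:cap]
    return candidates


# ---------------------------------------------------------------------------
# From genotypes to site frequencies
# ---------------------------------------------------------------------------

def site_frequencies(
    sites: Iterable[VariantSite], popmap: PopulationMap
) -> list[SiteFrequencies]:
    """Per-site alt-allele frequencies in the four quartet populations.

    The alt allele is treated as derived; the outgroup enters through
    (1 - p4), so polarization only needs to be consistent across sites.
    """
    popmap.require_quartet()
    roles = ("P1", "P2", "P3", "O")
    out: list[SiteFrequencies] = []
    for site in sites:
        sample_names = _sample_order(popmap, site)
        ps: list[float] = []
        ns: list[int] = []
        ok = True
        for role in roles:
            idx = [sample_names.index(s) for s in popmap.samples(role)]
            k = n = 0
            for i in idx:
                for h in site.calls[i]:
                    if h >= 0:
                        n += 1
                        k += h
            ns.append(n)
            ps.append(k / n if n else float("nan"))
            if n == 0:
                ok = False
        freq = SiteFrequencies(
            p1=ps[0], p2=ps[1], p3=ps[2], p4=ps[3],
            n1=ns[0], n2=ns[1], n3=ns[2], n4=ns[3],
            genotyped_fraction=site.genotyped_fraction,
            chrom=site.chrom, pos=site.pos,
        )
        out.append(freq)
    return out


def _sample_order(popmap: PopulationMap, site: VariantSite) -> list[str]:
    names = list(popmap.labels)
    if len(names) != len(site.calls):
        raise ValueError(
            f"population map has {len(names)} samples but site has {len(site.calls)} call pairs"
        )
    return names
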