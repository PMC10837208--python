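"""Pairwise synonymous/nonsynonymous divergence and Ks-based dating.

Implements the Nei-Gojobori (1986) counting method on in-frame codon
alignments: synonymous/nonsynonymous site counts per codon, difference
counts averaged over substitution pathways, Jukes-Cantor multiple-hit
correction, a kernel-density peak for Ks distributions, and the molecular
clock ``T = Ks / (2 * lambda)`` with the grass substitution rate
``lambda = 6.5e-9`` per site per year as default.

Single-base changes that would create a stop codon are excluded from the
per-position site denominator, and substitution pathways passing through a
stop codon are skipped; both follow common NG86 practice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import permutations

import numpy as np
from Bio.Data import CodonTable
from scipy import stats

logger = logging.getLogger("ricebarrier")

#: Substitutions per site per year; average rate for grasses.
DEFAULT_RATE = 6.5e-9

_BASES = "ACGT"

_table = CodonTable.unambiguous_dna_by_id[1]  # universal code
GENETIC_CODE: dict[str, str] = dict(_table.forward_table)
for _stop in _table.stop_codons:
    GENETIC_CODE[_stop] = "*"
STOP_CODONS = frozenset(_table.stop_codons)
SENSE_CODONS = tuple(sorted(c for c in GENETIC_CODE if GENETIC_CODE[c] != "*"))


class SaturationError(ValueError):
    """Divergence too high for the Jukes-Cantor correction (p >= 3/4)."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CodonPair:
    """Two aligned coding sequences, equal length divisible by 3, no gaps.

    Use :func:`make_codon_pair` to build one from raw aligned sequences with
    gap/N-containing codon columns dropped pairwise.
    """

    seq_a: str
    seq_b: str

    def __post_init__(self) -> None:
        if len(self.seq_a) != len(self.seq_b):
            raise ValueError("aligned sequences must have equal length")
        if len(self.seq_a) % 3:
            raise ValueError("alignment length must be divisible by 3")
        for seq in (self.seq_a, self.seq_b):
            if set(seq) - set(_BASES):
                raise ValueError("codon pair may contain only A, C, G, T")
            for i in range(0, len(seq), 3):
                if seq[i : i + 3] in STOP_CODONS:
                    raise ValueError(f"internal stop codon at position {i + 1}")

    @property
    def n_codons(self) -> int:
        return len(self.seq_a) // 3

    def codons(self):
        for i in range(0, len(self.seq_a), 3):
            yield self.seq_a[i : i + 3], self.seq_b[i : i + 3]


def make_codon_pair(seq_a: str, seq_b: str) -> CodonPair:
    """Build a :class:`CodonPair`, dropping gap- or N-containing codon columns.

    A trailing stop codon pair is trimmed; the number of dropped codon
    columns is logged.
    """
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    if len(seq_a) != len(seq_b):
        raise ValueError("aligned sequences must have equal length")
    length = len(seq_a) - len(seq_a) % 3
    kept_a, kept_b, dropped = [], [], 0
    for i in range(0, length, 3):
        ca, cb = seq_a[i : i + 3], seq_b[i : i + 3]
        if set(ca + cb) - set(_BASES):
            dropped += 1
            continue
        kept_a.append(ca)
        kept_b.append(cb)
    if kept_a and kept_a[-1] in STOP_CODONS and kept_b[-1] in STOP_CODONS:
        kept_a.pop()
        kept_b.pop()
    if dropped:
        logger.info("make_codon_pair: dropped %d gap/ambiguous codon columns", dropped)
    return CodonPair("".join(kept_a), "".join(kept_b))


@dataclass(frozen=True)
class KsResult:
    """NG86 site and difference counts with Jukes-Cantor-corrected distances.

    S + N = 3 * n_codons; dS (= Ks) and dN (= Ka) are the corrected
    synonymous and nonsynonymous distances.
    """

    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    dS: float
    dN: float


@dataclass(frozen=True)
class DatingParams:
    """Molecular-clock rate (substitutions/site/year)."""

    rate: float = DEFAULT_RATE

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError("substitution rate must be > 0")


@dataclass(frozen=True)
class KsDistribution:
    values: tuple[float, ...]
    peak: float


# ---------------------------------------------------------------------------
# NG86 counting
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def codon_site_counts(codon: str) -> tuple[float, float]:
    """Synonymous and nonsynonymous site counts (s, n) for one sense codon.

    At each position, the synonymous fraction is the number of synonymous
    single-base changes divided by the number of changes not creating a stop
    codon; s sums the three fractions and n = 3 - s.
    """
    codon = codon.upper()
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon} has no site counts")
    if codon not in GENETIC_CODE:
        raise ValueError(f"not a codon: {codon!r}")
    aa = GENETIC_CODE[codon]
    s = 0.0
    for pos in range(3):
        syn = valid = 0
        for base in _BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if mutant in STOP_CODONS:
                continue
            valid += 1
            if GENETIC_CODE[mutant] == aa:
                syn += 1
        if valid:
            s += syn / valid
    return s, 3.0 - s


@lru_cache(maxsize=None)
def _codon_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) difference counts between two sense codons.

    Averages over all orderings of the differing positions, excluding
    pathways that pass through a stop codon; if every pathway is blocked,
    all pathways are used.
    """
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return 0.0, 0.0

    def walk(order: tuple[int, ...], allow_stops: bool) -> tuple[float, float] | None:
        syn = non = 0.0
        current = codon_a
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if nxt in STOP_CODONS and not allow_stops:
                return None
            if GENETIC_CODE[current] == GENETIC_CODE[nxt]:
                syn += 1
            else:
                non += 1
            current = nxt
        return syn, non

    orders = list(permutations(diff_pos))
    results = [w for o in orders if (w := walk(o, allow_stops=False)) is not None]
    if not results:
        results = [walk(o, allow_stops=True) for o in orders]
    syn = sum(rx[0] for rx in results) / len(results)
    non = sum(rx[1] for rx in results) / len(results)
    return syn, non


def _jc_correct(p: float, label: str) -> float:
    if p >= 0.75:
        raise SaturationError(f"{label} proportion {p:.4f} >= 3/4: correction undefined")
    return -0.75 * np.log1p(-4.0 * p / 3.0)


def ng86_pair(pair: CodonPair) -> KsResult:
    """Nei-Gojobori synonymous/nonsynonymous divergence for one codon pair.

    Site counts are averaged over the two sequences; differences are averaged
    over substitution pathways per codon.  pS = Sd/S, pN = Nd/N;
    dS = -3/4 * ln(1 - 4/3 * pS), likewise dN.  Symmetric in the two
    sequences.
    """
    S = N = Sd = Nd = 0.0
    for ca, cb in pair.codons():
        sa, _ = codon_site_counts(ca)
        sb, _ = codon_site_counts(cb)
        S += (sa + sb) / 2.0
        if ca != cb:
            # difference counts are symmetric: average both directions
            s_ab, n_ab = _codon_differences(ca, cb)
            s_ba, n_ba = _codon_differences(cb, ca)
            Sd += (s_ab + s_ba) / 2.0
            Nd += (n_ab + n_ba) / 2.0
    N = 3.0 * pair.n_codons - S
    if S <= 0:
        raise ValueError("no synonymous sites: dS undefined")
    pS = Sd / S
    pN = Nd / N if N > 0 else 0.0
    dS = _jc_correct(pS, "synonymous")
    dN = _jc_correct(pN, "nonsynonymous")
    return KsResult(S=S, N=N, Sd=Sd, Nd=Nd, pS=pS, pN=pN, dS=float(dS), dN=float(dN))


# ---------------------------------------------------------------------------
# Dating
# ---------------------------------------------------------------------------

def divergence_time(ks: float, params: DatingParams = DatingParams()) -> float:
    """Divergence time in years from a synonymous distance: T = Ks / (2 * rate)."""
    if ks < 0:
        raise ValueError(f"ks must be >= 0, got {ks}")
    return ks / (2.0 * params.rate)


def ks_peak(values) -> KsDistribution:
    """Modal Ks of a distribution of synonymous distances.

    The peak is the argmax of a Gaussian kernel density (Silverman
    bandwidth) on a 512-point grid spanning [min, max].  Requires at least
    10 finite values.
    """
    arr = np.asarray(list(values), dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size < 10:
        raise ValueError(f"ks_peak requires >= 10 finite values, got {arr.size}")
    lo, hi = float(arr.min()), float(arr.max())
    if hi - lo < 1e-12:
        return KsDistribution(tuple(arr), lo)
    grid = np.linspace(lo, hi, 512)
    density = stats.gaussian_kde(arr, bw_method="silverman")(grid)
    return KsDistribution(tuple(arr), float(grid[int(np.argmax(density))]))
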