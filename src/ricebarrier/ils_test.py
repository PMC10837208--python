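"""Quartet topology calling and the ILS-vs-introgression decision rule.

Discordance between a gene tree and the species tree can arise from
incomplete lineage sorting (ILS) or from introgression.  The two are
separated by time: under ILS the discordant alleles coalesce *before* the
species split (an older time), whereas introgressed alleles coalesce after
it (younger).  This module calls the sister pair of a four-taxon tree from
pairwise distances via the four-point condition, and classifies a gene's
coalescence time against the species divergence time with a relative
tolerance band.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Literal, Sequence

from .codon_evolution import CodonPair, DatingParams, SaturationError, divergence_time, ks_peak, ng86_pair
from .io_core import quartet_newick

Call = Literal["ILS", "introgression", "ambiguous"]

YEARS_PER_MY = 1e6


@dataclass(frozen=True)
class QuartetDistances:
    """Pairwise distances among four taxa with a designated outgroup."""

    taxa: tuple[str, str, str, str]
    distances: dict[frozenset, float]
    outgroup: str

    def __post_init__(self) -> None:
        if self.outgroup not in self.taxa:
            raise ValueError(f"outgroup {self.outgroup!r} not among taxa {self.taxa}")
        if len(set(self.taxa)) != 4:
            raise ValueError("four distinct taxon labels required")
        for pair in combinations(self.taxa, 2):
            key = frozenset(pair)
            if key not in self.distances:
                raise ValueError(f"missing distance for pair {tuple(pair)}")
            if self.distances[key] < 0:
                raise ValueError("distances must be >= 0")

    def d(self, a: str, b: str) -> float:
        return self.distances[frozenset((a, b))]

    @classmethod
    def from_matrix(cls, labels: Sequence[str], matrix, outgroup: str) -> "QuartetDistances":
        dist = {}
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                if i < j:
                    dist[frozenset((a, b))] = float(matrix[i][j])
        return cls(tuple(labels), dist, outgroup)


@dataclass(frozen=True)
class TopologyCall:
    """The inferred sister pair among the ingroup, with its support margin."""

    sister: tuple[str, str]
    margin: float
    newick: str


@dataclass(frozen=True)
class TimeComparison:
    """Gene coalescence time vs species split time, both in years."""

    t_gene: float
    t_split: float
    rel_tol: float
    call: Call
    label: str = ""
    flagged: str = ""


def quartet_topology(d: QuartetDistances) -> TopologyCall:
    """Sister-pair call by the four-point condition.

    For each pairing (x, y) of ingroup taxa with remaining ingroup taxon z,
    the sum d(x, y) + d(z, O) is minimal for the true sister pair under
    additive distances.  Margin = second-smallest minus smallest sum; ties
    (margin 0) resolve to the lexicographically first pair.
    """
    ingroup = sorted(t for t in d.taxa if t != d.outgroup)
    scored = []
    for x, y in combinations(ingroup, 2):
        (z,) = [t for t in ingroup if t not in (x, y)]
        scored.append((d.d(x, y) + d.d(z, d.outgroup), (x, y), z))
    scored.sort(key=lambda t: (t[0], t[1]))
    best, second = scored[0], scored[1]
    margin = second[0] - best[0]
    sister, other = best[1], best[2]
    return TopologyCall(sister, float(margin), quartet_newick(sister, other, d.outgroup))


def classify_discordance(t_gene: float, t_split: float, rel_tol: float = 0.1) -> TimeComparison:
    """ILS/introgression call from a gene vs species time comparison.

    "Earlier" means older, i.e. a larger time value: ILS when
    ``t_gene > t_split * (1 + rel_tol)``, introgression when
    ``t_gene < t_split * (1 - rel_tol)``, ambiguous within the band.
    Scale-invariant: both times may be in years or MY as long as they agree.
    """
    if t_gene < 0 or t_split < 0:
        raise ValueError("times must be >= 0")
    if rel_tol < 0:
        raise ValueError("rel_tol must be >= 0")
    if t_gene > t_split * (1.0 + rel_tol):
        call: Call = "ILS"
    elif t_gene < t_split * (1.0 - rel_tol):
        call = "introgression"
    else:
        call = "ambiguous"
    return TimeComparison(t_gene, t_split, rel_tol, call)


def ils_scan(
    gene_pairs: Sequence[tuple[str, CodonPair]],
    species_ks: Sequence[float],
    params: DatingParams = DatingParams(),
    rel_tol: float = 0.1,
) -> list[TimeComparison]:
    """Per-gene ILS/introgression calls against a species-wide Ks baseline.

    The species split time is dated from the modal Ks of single-copy
    ortholog pairs; each gene's coalescence time from its own pairwise dS.
    Saturated gene pairs are flagged, not dropped.
    """
    if len(species_ks) == 0:
        raise ValueError("species_ks must be non-empty")
    t_split = divergence_time(ks_peak(species_ks).peak, params)
    rows: list[TimeComparison] = []
    for label, pair in gene_pairs:
        try:
            t_gene = divergence_time(ng86_pair(pair).dS, params)
        except SaturationError as exc:
            rows.append(
                TimeComparison(float("nan"), t_split, rel_tol, "ambiguous", label, f"saturated: {exc}")
            )
            continue
        cmp = classify_discordance(t_gene, t_split, rel_tol)
        rows.append(TimeComparison(t_gene, t_split, rel_tol, cmp.call, label))
    return rows
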