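"""Seeded generators producing inputs with the statistical structure each
pipeline stage assumes.

Every generator derives its random stream by stable hashing of
``(seed, generator name)``, is reproducible bit-for-bit, and returns a
:class:`SimTruth` record of its parameters and per-item truth labels next
to the data.  Sequence evolution is Jukes-Cantor throughout, matching the
assumptions of the estimators the data feed (p-distance, NG86 with JC
correction), so recovery tests are exact in expectation.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io_core import (
    JOINT_CLASSES,
    MARGINAL1_CLASSES,
    MARGINAL2_CLASSES,
    CountsTable,
    SequenceRecord,
    VariantSite,
)
from .codon_evolution import (
    GENETIC_CODE,
    SENSE_CODONS,
    STOP_CODONS,
    CodonPair,
    codon_site_counts,
)
from .quartet_stats import SiteFrequencies
from .seg_model import TransmissionModel, expected_class_freqs

_BASES = "ACGT"


@dataclass(frozen=True)
class SimTruth:
    """Provenance sidecar: generator name, seed, parameters and truth labels."""

    generator: str
    seed: int
    params: dict
    truth: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {"generator": self.generator, "seed": self.seed,
             "params": self.params, "truth": self.truth},
            indent=2, sort_keys=True, default=_jsonable,
        )


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON-serializable: {type(x)}")


def derive_rng(seed: int, name: str) -> np.random.Generator:
    """Independent generator stream from a global seed and a stream name."""
    digest = hashlib.sha256(f"{seed}:{name}".encode()).digest()
    return np.random.default_rng(int.from_bytes(digest[:4], "big"))


# ---------------------------------------------------------------------------
# F2 genotype counts
# ---------------------------------------------------------------------------

def simulate_f2_counts(
    n: int,
    model: TransmissionModel,
    joint: bool = False,
    seed: int = 0,
    locus: int = 2,
) -> tuple[CountsTable, SimTruth]:
    """Multinomial F2 genotype counts under the gamete-elimination model.

    Draws ``n`` plants from the joint 9-class distribution; reports either
    the joint table or the 3-class marginal at ``locus`` (default 2,
    matching the reference cross's scored marker).
    """
    if n < 1:
        raise ValueError("population size must be >= 1")
    rng = derive_rng(seed, "simulate_f2_counts")
    probs = expected_class_freqs(model, JOINT_CLASSES)
    draw = rng.multinomial(n, probs)
    if joint:
        table = CountsTable(JOINT_CLASSES, tuple(int(x) for x in draw))
    else:
        classes = MARGINAL1_CLASSES if locus == 1 else MARGINAL2_CLASSES
        agg = {c: 0 for c in classes}
        for name, count in zip(JOINT_CLASSES, draw):
            part = name.split("_")[0] if locus == 1 else name.split("_")[1]
            agg[part] += int(count)
        table = CountsTable(classes, tuple(agg[c] for c in classes))
    truth = SimTruth(
        "simulate_f2_counts", seed,
        {"n": n, "tau_m": model.tau_m, "tau_f": model.tau_f, "v": model.v,
         "r": model.r, "joint": joint, "locus": locus},
        {"joint_probs": dict(zip(JOINT_CLASSES, probs.tolist()))},
    )
    return table, truth


# ---------------------------------------------------------------------------
# Quartet sequence alignments
# ---------------------------------------------------------------------------

def _jc_evolve(seq: np.ndarray, t: float, rng: np.random.Generator) -> np.ndarray:
    """Evolve an integer-coded sequence along a branch of length t (subs/site)."""
    if t < 0:
        raise ValueError("branch lengths must be >= 0")
    p_change = 0.75 * (1.0 - np.exp(-4.0 * t / 3.0))
    out = seq.copy()
    hit = rng.random(seq.size) < p_change
    # a changed site takes one of the three other bases uniformly
    shift = rng.integers(1, 4, size=int(hit.sum()))
    out[hit] = (out[hit] + shift) % 4
    return out


def simulate_quartet_alignment(
    sister: tuple[str, str] = ("A", "B"),
    labels: Sequence[str] = ("A", "B", "C", "O"),
    tip_length: float = 0.01,
    internal_length: float = 0.05,
    outgroup_length: float = 0.05,
    n_sites: int = 10_000,
    seed: int = 0,
) -> tuple[list[SequenceRecord], SimTruth]:
    """Four sequences evolved under Jukes-Cantor down a quartet tree.

    The last label is the outgroup; ``sister`` names the two ingroup taxa
    joined by the internal branch of ``internal_length``.  Tips evolve for
    ``tip_length`` (outgroup for ``outgroup_length``) expected
    substitutions/site from a uniform-random root sequence.
    """
    labels = tuple(labels)
    outgroup = labels[-1]
    ingroup = labels[:-1]
    if len(set(sister)) != 2 or not set(sister) <= set(ingroup):
        raise ValueError(f"sister pair {sister} must be two distinct ingroup taxa {ingroup}")
    (other,) = [t for t in ingroup if t not in sister]
    rng = derive_rng(seed, "simulate_quartet_alignment")
    root = rng.integers(0, 4, size=n_sites)
    # Root placed at the ingroup ancestor; outgroup hangs off it directly.
    anc_sister = _jc_evolve(root, internal_length, rng)
    seqs = {
        sister[0]: _jc_evolve(anc_sister, tip_length, rng),
        sister[1]: _jc_evolve(anc_sister, tip_length, rng),
        other: _jc_evolve(root, tip_length, rng),
        outgroup: _jc_evolve(root, outgroup_length, rng),
    }
    records = [
        SequenceRecord(lab, "".join(_BASES[b] for b in seqs[lab])) for lab in labels
    ]
    truth = SimTruth(
        "simulate_quartet_alignment", seed,
        {"labels": list(labels), "sister": list(sister), "tip_length": tip_length,
         "internal_length": internal_length, "outgroup_length": outgroup_length,
         "n_sites": n_sites},
        {"sister": sorted(sister)},
    )
    return records, truth


def p_distance(a: SequenceRecord, b: SequenceRecord) -> float:
    """Proportion of differing sites between two equal-length sequences."""
    if len(a.sequence) != len(b.sequence):
        raise ValueError("sequences must have equal length")
    arr_a = np.frombuffer(a.sequence.encode(), dtype="S1")
    arr_b = np.frombuffer(b.sequence.encode(), dtype="S1")
    return float((arr_a != arr_b).mean())


# ---------------------------------------------------------------------------
# Admixed windows for D/fd
# ---------------------------------------------------------------------------

def simulate_admixed_windows(
    n_windows: int = 1000,
    sites_per_window: int = 400,
    introgressed_fraction: float = 0.005,
    f_admix: float = 0.2,
    seed: int = 0,
    window_size: int = 300_000,
    freq_noise: float = 0.05,
) -> tuple[list[SiteFrequencies], SimTruth]:
    """Per-window site frequencies with a known set of introgressed windows.

    Null windows: a shared ancestral frequency drives P1 and P2 (adding
    independent Gaussian noise of sd ``freq_noise``, so P1 and P2 are
    exchangeable and D is centred on zero); P3 draws independently from the
    same marginal; the outgroup frequency is near zero.  Introgressed
    windows replace P2 with ``(1 - f) * p2 + f * p3`` site-wise.  Windows
    tile one chromosome contiguously; truth records the introgressed
    indices.
    """
    if not 0.0 <= f_admix <= 1.0:
        raise ValueError("f_admix must be in [0, 1]")
    rng = derive_rng(seed, "simulate_admixed_windows")
    n_intro = int(round(n_windows * introgressed_fraction))
    intro_idx = sorted(rng.choice(n_windows, size=n_intro, replace=False).tolist())
    intro_set = set(intro_idx)
    sites: list[SiteFrequencies] = []
    for w in range(n_windows):
        anc = rng.uniform(0.05, 0.95, size=sites_per_window)
        p1 = np.clip(anc + rng.normal(0.0, freq_noise, sites_per_window), 0.0, 1.0)
        p2 = np.clip(anc + rng.normal(0.0, freq_noise, sites_per_window), 0.0, 1.0)
        p3 = rng.uniform(0.05, 0.95, size=sites_per_window)
        p4 = rng.beta(1.0, 19.0, size=sites_per_window)
        if w in intro_set:
            p2 = (1.0 - f_admix) * p2 + f_admix * p3
        pos = np.sort(rng.choice(window_size, size=sites_per_window, replace=False))
        for j in range(sites_per_window):
            sites.append(
                SiteFrequencies(
                    p1=float(p1[j]), p2=float(p2[j]), p3=float(p3[j]), p4=float(p4[j]),
                    n1=20, n2=20, n3=20, n4=20, genotyped_fraction=1.0,
                    chrom="chr1", pos=int(w * window_size + pos[j] + 1),
                )
            )
    truth = SimTruth(
        "simulate_admixed_windows", seed,
        {"n_windows": n_windows, "sites_per_window": sites_per_window,
         "introgressed_fraction": introgressed_fraction, "f_admix": f_admix,
         "window_size": window_size, "freq_noise": freq_noise},
        {"introgressed_windows": intro_idx},
    )
    return sites, truth


# ---------------------------------------------------------------------------
# Codon pairs with known divergence
# ---------------------------------------------------------------------------

def _implied_p(d: float) -> float:
    return 0.75 * (1.0 - np.exp(-4.0 * d / 3.0))


def simulate_codon_pair(
    n_codons: int,
    ds_true: float,
    dn_true: float = 0.0,
    seed: int = 0,
):
    """A codon-alignment pair with known synonymous/nonsynonymous divergence.

    Ancestor codons draw uniformly from the 61 sense codons; each lineage
    receives Poisson((d/2) * sites) synonymous and nonsynonymous single-base
    events, placed uniformly over the eligible changes of the current
    sequence and rejecting stop-creating changes.  Raises for divergences
    implying a difference proportion >= 0.5 (saturation bound).

    Returns ``(CodonPair, SimTruth)``.
    """
    for name, d in (("ds_true", ds_true), ("dn_true", dn_true)):
        if d < 0:
            raise ValueError(f"{name} must be >= 0")
        if _implied_p(d) >= 0.5:
            raise ValueError(f"{name}={d} implies difference proportion >= 0.5 (saturation)")
    rng = derive_rng(seed, "simulate_codon_pair")
    ancestor = [SENSE_CODONS[i] for i in rng.integers(0, len(SENSE_CODONS), n_codons)]
    S = sum(codon_site_counts(c)[0] for c in ancestor)
    N = 3.0 * n_codons - S

    realized = {"syn": [0, 0], "non": [0, 0]}

    def evolve(lineage: int) -> list[str]:
        seq = list(ancestor)
        n_syn = rng.poisson(ds_true / 2.0 * S)
        n_non = rng.poisson(dn_true / 2.0 * N)
        for kind, n_events in (("syn", n_syn), ("non", n_non)):
            applied = 0
            attempts = 0
            limit = 1000 * (n_events + 1)
            while applied < n_events and attempts < limit:
                attempts += 1
                ci = int(rng.integers(0, n_codons))
                pos = int(rng.integers(0, 3))
                base = _BASES[int(rng.integers(0, 4))]
                codon = seq[ci]
                if base == codon[pos]:
                    continue
                mutant = codon[:pos] + base + codon[pos + 1 :]
                if mutant in STOP_CODONS:
                    continue
                synonymous = GENETIC_CODE[mutant] == GENETIC_CODE[codon]
                if (kind == "syn") != synonymous:
                    continue
                seq[ci] = mutant
                applied += 1
            realized[kind][lineage] = applied
        return seq

    seq_a = evolve(0)
    seq_b = evolve(1)
    pair = CodonPair("".join(seq_a), "".join(seq_b))
    truth = SimTruth(
        "simulate_codon_pair", seed,
        {"n_codons": n_codons, "ds_true": ds_true, "dn_true": dn_true},
        {"S_ancestor": S, "N_ancestor": N,
         "syn_events": realized["syn"], "non_events": realized["non"]},
    )
    return pair, truth


# ---------------------------------------------------------------------------
# Neutral SNP regions
# ---------------------------------------------------------------------------

def simulate_snp_region(
    length_bases: int = 100_000,
    n_haplotypes: int = 20,
    theta_per_site: float = 0.01,
    seed: int = 0,
    chrom: str = "chr1",
) -> tuple[list[VariantSite], SimTruth]:
    """Segregating sites with a neutral (1/k) frequency spectrum.

    The number of sites is Poisson(theta * L * a_n) with
    ``a_n = sum_{k=1}^{n-1} 1/k``, so the expected per-site diversity is
    ``theta``.  Haplotypes are paired into diploid samples (n must be even).
    """
    if theta_per_site < 0 or theta_per_site >= 0.1:
        raise ValueError("theta_per_site must be in [0, 0.1)")
    if n_haplotypes < 2 or n_haplotypes % 2:
        raise ValueError("n_haplotypes must be an even number >= 2")
    rng = derive_rng(seed, "simulate_snp_region")
    n = n_haplotypes
    a_n = sum(1.0 / k for k in range(1, n))
    n_sites = int(rng.poisson(theta_per_site * length_bases * a_n))
    n_sites = min(n_sites, length_bases)
    positions = np.sort(rng.choice(length_bases, size=n_sites, replace=False)) + 1
    k_weights = np.array([1.0 / k for k in range(1, n)])
    k_weights /= k_weights.sum()
    sites: list[VariantSite] = []
    truth_k: list[int] = []
    for pos in positions:
        k = int(rng.choice(np.arange(1, n), p=k_weights))
        carriers = rng.choice(n, size=k, replace=False)
        hap = np.zeros(n, dtype=int)
        hap[carriers] = 1
        ref, alt = rng.choice(list("ACGT"), size=2, replace=False)
        calls = tuple((int(hap[2 * i]), int(hap[2 * i + 1])) for i in range(n // 2))
        sites.append(VariantSite(chrom, int(pos), str(ref), str(alt), calls))
        truth_k.append(k)
    truth = SimTruth(
        "simulate_snp_region", seed,
        {"length_bases": length_bases, "n_haplotypes": n_haplotypes,
         "theta_per_site": theta_per_site, "chrom": chrom},
        {"n_sites": n_sites, "derived_counts": truth_k},
    )
    return sites, truth
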