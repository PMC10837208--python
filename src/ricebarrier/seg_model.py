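"""Two-locus duplicate-gene-loss gamete-elimination model.

A pair of redundant loci (each with a functional and a loss-of-function
allele) segregates in an F2 from a doubly heterozygous F1.  Gametes null at
*both* loci pass through pollen with viability ``tau_m`` and through ovules
with ``tau_f``; zygotes homozygous null at both loci survive with viability
``v``.  With full viabilities the model reduces to a Mendelian dihybrid.
The module computes expected F2 genotype frequencies, tests observed counts
against arbitrary ratios, fits the transmission parameters by maximum
likelihood, and predicts cross compatibility from parental allele classes.

Genotype classes are indexed internally by the count of functional alleles
per locus, ordered (2, 1, 0) = (homozygous functional, heterozygous,
homozygous null).  The reference cross displays locus-1 genotypes in
parental orientation, in which the recurrent-parent allele is the *null*
one at locus 1; ``locus_marginal(..., orientation="parental")`` reproduces
that display.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import optimize, stats

from .io_core import (
    JOINT_CLASSES,
    MARGINAL1_CLASSES,
    MARGINAL2_CLASSES,
    CountsTable,
)

Sex = Literal["male", "female"]
Phase = Literal["repulsion", "coupling"]

#: Haplotype order over (locus1, locus2) functionality:
#: F1F2, F1n2, n1F2, n1n2 — the last is the doubly-null (lethal-prone) class.
HAPLOTYPES = ((1, 1), (1, 0), (0, 1), (0, 0))


@dataclass(frozen=True)
class TransmissionModel:
    """Sex-specific gamete and zygote viabilities plus the recombination fraction.

    tau_m, tau_f : viability in [0, 1] of the doubly-null gamete through
        pollen and ovules respectively.
    v : viability in [0, 1] of the doubly-homozygous-null zygote.
    r : recombination fraction in [0, 0.5] between the two loci
        (0.5 = unlinked, the default for loci on different chromosomes).
    """

    tau_m: float = 1.0
    tau_f: float = 1.0
    v: float = 1.0
    r: float = 0.5

    def __post_init__(self) -> None:
        for name in ("tau_m", "tau_f", "v"):
            x = getattr(self, name)
            if not 0.0 <= x <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {x}")
        if not 0.0 <= self.r <= 0.5:
            raise ValueError(f"r must be in [0, 0.5], got {self.r}")


@dataclass(frozen=True)
class GameteDist:
    """Post-selection frequencies of the four haplotypes, in HAPLOTYPES order."""

    freqs: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        if any(f < -1e-12 for f in self.freqs):
            raise ValueError("gamete frequencies must be non-negative")
        if abs(sum(self.freqs) - 1.0) > 1e-9:
            raise ValueError("gamete frequencies must sum to 1")


@dataclass(frozen=True)
class JointGenotypeFreqs:
    """3x3 F2 genotype frequencies, locus 1 on rows, locus 2 on columns.

    Index order per locus: 0 = homozygous functional, 1 = heterozygous,
    2 = homozygous null.
    """

    matrix: tuple[tuple[float, ...], ...]

    def as_array(self) -> np.ndarray:
        return np.asarray(self.matrix, dtype=float)


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p: float


@dataclass(frozen=True)
class AlleleClass:
    """Functionality of a pure line at the two loci.

    Class I = (True, True), Class II = (True, False), Class III = (False, True).
    The all-False combination is not viable as a pure line.
    """

    locus1_functional: bool
    locus2_functional: bool

    @property
    def viable(self) -> bool:
        return self.locus1_functional or self.locus2_functional


CLASS_I = AlleleClass(True, True)
CLASS_II = AlleleClass(True, False)
CLASS_III = AlleleClass(False, True)


@dataclass(frozen=True)
class FitResult:
    model: TransmissionModel
    log_likelihood: float
    converged: bool
    free: tuple[str, ...]


# ---------------------------------------------------------------------------
# Gamete and zygote frequencies
# ---------------------------------------------------------------------------

def _gamete_freqs(tau: np.ndarray | float, r: float, phase: Phase) -> np.ndarray:
    """Post-selection gamete frequencies, vectorized over ``tau``.

    Returns shape (..., 4) in HAPLOTYPES order.
    """
    tau = np.asarray(tau, dtype=float)
    parental, recomb = (1.0 - r) / 2.0, r / 2.0
    if phase == "repulsion":
        base = np.array([recomb, parental, parental, recomb])
    elif phase == "coupling":
        base = np.array([parental, recomb, recomb, parental])
    else:
        raise ValueError(f"phase must be 'repulsion' or 'coupling', got {phase!r}")
    out = np.broadcast_to(base, tau.shape + (4,)).copy()
    out[..., 3] = out[..., 3] * tau
    total = out.sum(axis=-1, keepdims=True)
    if np.any(total <= 0):
        raise ValueError("all gametes eliminated: no viable haplotype remains")
    return out / total


def gamete_distribution(
    model: TransmissionModel, sex: Sex, phase: Phase = "repulsion"
) -> GameteDist:
    """Gamete frequencies produced by the doubly heterozygous F1 through one sex."""
    if sex == "male":
        tau = model.tau_m
    elif sex == "female":
        tau = model.tau_f
    else:
        raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")
    freqs = _gamete_freqs(tau, model.r, phase)
    return GameteDist(tuple(float(x) for x in freqs))


def _joint_freqs_array(
    tau_m, tau_f, v, r: float, phase: Phase = "repulsion"
) -> np.ndarray:
    """Vectorized 3x3 F2 genotype frequencies; broadcasts over parameters.

    Returns shape (..., 3, 3) with per-locus index 0/1/2 = 2/1/0 functional
    alleles.
    """
    tau_m, tau_f, v = np.broadcast_arrays(
        np.asarray(tau_m, float), np.asarray(tau_f, float), np.asarray(v, float)
    )
    gm = _gamete_freqs(tau_m, r, phase)
    gf = _gamete_freqs(tau_f, r, phase)
    joint = np.zeros(tau_m.shape + (3, 3))
    for i, (a1, a2) in enumerate(HAPLOTYPES):
        for j, (b1, b2) in enumerate(HAPLOTYPES):
            row = 2 - (a1 + b1)  # 0 = two functional alleles at locus 1
            col = 2 - (a2 + b2)
            joint[..., row, col] += gm[..., i] * gf[..., j]
    joint[..., 2, 2] *= v
    joint /= joint.sum(axis=(-2, -1), keepdims=True)
    return joint


def f2_genotype_freqs(model: TransmissionModel, phase: Phase = "repulsion") -> JointGenotypeFreqs:
    """Expected F2 joint genotype frequencies under the transmission model.

    Sums the products of sex-specific gamete frequencies over all 16
    male x female gamete combinations, applies zygote selection ``v`` to the
    doubly-homozygous-null class, and renormalizes.
    """
    joint = _joint_freqs_array(model.tau_m, model.tau_f, model.v, model.r, phase)
    return JointGenotypeFreqs(tuple(tuple(float(x) for x in row) for row in joint))


def locus_marginal(
    joint: JointGenotypeFreqs,
    locus: int,
    orientation: Literal["functional", "parental"] = "functional",
    phase: Phase = "repulsion",
) -> tuple[float, float, float]:
    """Marginal genotype frequencies at one locus.

    ``orientation="functional"`` orders classes (hom functional, het, hom
    null).  ``orientation="parental"`` orders (recurrent-parent hom, het,
    donor hom) as displayed for the reference cross; under repulsion the
    recurrent-parent allele is null at locus 1 and functional at locus 2, so
    the locus-1 marginal is reversed relative to functional order.
    """
    if locus not in (1, 2):
        raise ValueError(f"locus must be 1 or 2, got {locus}")
    m = joint.as_array()
    vec = m.sum(axis=1) if locus == 1 else m.sum(axis=0)
    if orientation == "parental" and _parent_allele_is_null(locus, phase):
        vec = vec[::-1]
    elif orientation not in ("functional", "parental"):
        raise ValueError(f"unknown orientation {orientation!r}")
    return tuple(float(x) for x in vec)


def _parent_allele_is_null(locus: int, phase: Phase) -> bool:
    # Repulsion: recurrent parent haplotype is (null at locus 1, functional at
    # locus 2); coupling: functional at both.
    return phase == "repulsion" and locus == 1


# ---------------------------------------------------------------------------
# Goodness of fit
# ---------------------------------------------------------------------------

def chisq_gof(counts: CountsTable | Sequence[int], expected_ratio: Sequence[float]) -> ChiSquareResult:
    """Pearson chi-square goodness of fit of counts against an expected ratio.

    ``expected_ratio`` need not be normalized; expected counts are
    ``total * ratio / sum(ratio)``.  df = classes - 1; p is the upper tail.
    """
    obs = np.asarray(counts.counts if isinstance(counts, CountsTable) else counts, float)
    ratio = np.asarray(expected_ratio, float)
    if obs.shape != ratio.shape:
        raise ValueError("counts and expected_ratio must have equal length")
    if np.any(ratio <= 0):
        raise ValueError("expected_ratio entries must be > 0")
    if obs.sum() <= 0:
        raise ValueError("total count must be > 0")
    exp = obs.sum() * ratio / ratio.sum()
    statistic = float(((obs - exp) ** 2 / exp).sum())
    df = len(obs) - 1
    p = float(stats.chi2.sf(statistic, df))
    return ChiSquareResult(statistic, df, p)


# ---------------------------------------------------------------------------
# Maximum-likelihood fitting
# ---------------------------------------------------------------------------

_FREE_PARAMS = ("tau", "tau_m", "tau_f", "v")


def _class_probs(
    classes: Sequence[str], params: dict[str, np.ndarray | float], r: float, phase: Phase
) -> np.ndarray:
    """Model probabilities for the named genotype classes; broadcasts over params."""
    joint = _joint_freqs_array(params["tau_m"], params["tau_f"], params["v"], r, phase)
    m1 = joint.sum(axis=-1)  # locus-1 marginal, functional order
    m2 = joint.sum(axis=-2)
    cols = []
    for name in classes:
        if name in MARGINAL1_CLASSES:
            idx = MARGINAL1_CLASSES.index(name)  # parental order
            fidx = 2 - idx if _parent_allele_is_null(1, phase) else idx
            cols.append(m1[..., fidx])
        elif name in MARGINAL2_CLASSES:
            idx = MARGINAL2_CLASSES.index(name)
            fidx = 2 - idx if _parent_allele_is_null(2, phase) else idx
            cols.append(m2[..., fidx])
        else:
            n1, n2 = name.split("_")
            i = MARGINAL1_CLASSES.index(n1)
            j = MARGINAL2_CLASSES.index(n2)
            fi = 2 - i if _parent_allele_is_null(1, phase) else i
            fj = 2 - j if _parent_allele_is_null(2, phase) else j
            cols.append(joint[..., fi, fj])
    return np.stack(cols, axis=-1)


def expected_class_freqs(
    model: TransmissionModel, classes: Sequence[str], phase: Phase = "repulsion"
) -> np.ndarray:
    """Expected frequencies of the named genotype classes under ``model``."""
    params = {"tau_m": model.tau_m, "tau_f": model.tau_f, "v": model.v}
    return _class_probs(classes, params, model.r, phase)


def fit_transmission(
    counts: CountsTable,
    free: Sequence[str] = ("tau", "v"),
    r: float = 0.5,
    phase: Phase = "repulsion",
    grid_step: float = 0.01,
) -> FitResult:
    """Maximum-likelihood transmission parameters from F2 genotype counts.

    ``free`` names the parameters to estimate, drawn from ``tau`` (ties
    tau_m = tau_f), ``tau_m``, ``tau_f`` and ``v``; the rest are fixed at 1.
    A coarse grid (step ``grid_step``) is scanned first, then the best point
    is refined with Nelder-Mead.  The search is fully deterministic; grid
    ties break toward smaller parameter values.

    Marginal 3-class counts carry 2 degrees of freedom, so at most 2 free
    parameters are allowed for marginal data.
    """
    free = tuple(free)
    for f in free:
        if f not in _FREE_PARAMS:
            raise ValueError(f"unknown free parameter {f!r}; choose from {_FREE_PARAMS}")
    if "tau" in free and ("tau_m" in free or "tau_f" in free):
        raise ValueError("'tau' (tied) cannot be combined with 'tau_m'/'tau_f'")
    if counts.kind != "joint" and len(free) > 2:
        raise ValueError("marginal 3-class data identify at most 2 free parameters")

    obs = np.asarray(counts.counts, float)

    def expand(theta: np.ndarray) -> dict[str, np.ndarray]:
        params = {"tau_m": 1.0, "tau_f": 1.0, "v": 1.0}
        for name, val in zip(free, theta):
            if name == "tau":
                params["tau_m"] = params["tau_f"] = val
            else:
                params[name] = val
        return params

    def negloglik(theta: np.ndarray) -> float:
        theta = np.clip(theta, 0.0, 1.0)
        probs = _class_probs(counts.classes, expand(theta), r, phase)
        probs = np.maximum(probs, 1e-300)
        return -float(obs @ np.log(probs))

    # Coarse grid, vectorized over all grid points at once.
    axis = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
    grids = np.meshgrid(*[axis] * len(free), indexing="ij")
    flat = np.stack([g.ravel() for g in grids], axis=-1)  # (G, k)
    params = expand(tuple(flat[:, i] for i in range(len(free))))
    probs = _class_probs(counts.classes, params, r, phase)
    ll = (np.log(np.maximum(probs, 1e-300)) * obs).sum(axis=-1)
    best = int(np.argmax(ll))  # argmax returns the first (smallest-parameter) tie
    theta0 = flat[best]

    res = optimize.minimize(
        negloglik, theta0, method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 2000},
    )
    cand = np.clip(res.x, 0.0, 1.0)
    # Keep the grid optimum if refinement did not improve (boundary effects).
    if -res.fun < ll[best] - 1e-9:
        cand, final_ll = theta0, float(ll[best])
    else:
        final_ll = -float(res.fun)
    p = expand(cand)
    model = TransmissionModel(float(p["tau_m"]), float(p["tau_f"]), float(p["v"]), r)
    return FitResult(model, final_ll, bool(res.success), free)


# ---------------------------------------------------------------------------
# Cross compatibility
# ---------------------------------------------------------------------------

def classify_cross(parent_a: AlleleClass, parent_b: AlleleClass) -> str:
    """Predict F2 compatibility of a cross between two pure lines.

    Returns ``"incompatible"`` when the F1 is heterozygous for a
    loss-of-function allele at both loci — i.e. one parent is null at locus 1
    and the other at locus 2 — so a doubly-null gamete or zygote can arise;
    ``"compatible"`` otherwise.  Symmetric in its arguments.
    """
    for p in (parent_a, parent_b):
        if not p.viable:
            raise ValueError("doubly-null parent is not viable as a pure line")
    differs_1 = parent_a.locus1_functional != parent_b.locus1_functional
    differs_2 = parent_a.locus2_functional != parent_b.locus2_functional
    return "incompatible" if (differs_1 and differs_2) else "compatible"
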