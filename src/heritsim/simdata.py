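"""Simulators for genotypes, polygenic traits, and pedigree gene drop.

This module produces the study conditions used throughout the package:

* biallelic marker genotypes (0/1/2 allele counts) for unrelated individuals
  under five population LD structures (independent, first-order
  autocorrelation, equally sized blocks, exchangeable, and exact repeats of a
  subset of markers);
* polygenic phenotypes ``y = Gamma_C beta + eps`` with a fixed target
  heritability, where ``Gamma_C`` is the column-standardized causal genotype
  matrix;
* cousinship samples obtained by dropping founder alleles through explicit
  pedigrees with Haldane (Poisson, no-interference) recombination on a single
  chromosome.

Two genotype backends are provided.  The ``gaussian`` backend returns
already-standardized continuous genotypes whose columns have exactly the
requested population correlation matrix in expectation; the bias algebra of
:mod:`heritsim.theory` is exact on this scale, so it is the backend of choice
for theory checks.  The ``binomial_threshold`` backend builds each individual
from two latent-Gaussian-threshold haplotypes and returns integer allele
counts; the correlation parameter ``rho`` is defined on the latent scale, so
the realized genotype correlation is mildly attenuated relative to ``rho``.
Exact repeat columns are byte-identical copies under both backends.

All generators are driven by :class:`numpy.random.Generator` streams spawned
from explicit seeds and record their seed provenance, so every data set is
bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "LD_KINDS",
    "COUSIN_DEGREES",
    "FREQ_LOW",
    "FREQ_HIGH",
    "AlleleFrequencySet",
    "LDStructureSpec",
    "GenotypeData",
    "TraitRealization",
    "Individual",
    "Pedigree",
    "draw_allele_freqs",
    "build_true_ld",
    "assign_causal",
    "sim_genotypes",
    "sim_phenotype",
    "build_pedigree",
    "gene_drop",
]

LD_KINDS = ("independent", "autocorrelation", "block", "exchangeable", "repeat")
COUSIN_DEGREES = ("first", "second", "third", "unrelated")

#: allele-frequency filter bounds applied to every simulated frequency set
FREQ_LOW = 0.05
FREQ_HIGH = 0.95

# expected genotypic correlation (twice the kinship coefficient) between
# j-th cousins: 2 * (1/4)**(j+1)
COUSIN_PHI = {"first": 0.125, "second": 0.03125, "third": 0.0078125, "unrelated": 0.0}


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class AlleleFrequencySet:
    """Reference-allele population frequencies, one per marker.

    Frequencies are constrained to the open interval (0.05, 0.95), emulating
    a common-variant frequency filter.
    """

    freqs: np.ndarray

    def __post_init__(self):
        freqs = np.asarray(self.freqs, dtype=float)
        object.__setattr__(self, "freqs", freqs)
        if freqs.ndim != 1 or freqs.size < 1:
            raise ValueError("freqs must be a non-empty 1-D array")
        if np.any(freqs <= FREQ_LOW) or np.any(freqs >= FREQ_HIGH):
            raise ValueError(
                f"allele frequencies must lie strictly in ({FREQ_LOW}, {FREQ_HIGH})"
            )

    def __len__(self) -> int:
        return int(self.freqs.size)


@dataclass(frozen=True)
class LDStructureSpec:
    """Parameters of a population LD structure.

    Parameters
    ----------
    kind:
        One of ``independent``, ``autocorrelation``, ``block``,
        ``exchangeable``, ``repeat``.
    m:
        Number of causal markers.
    rho:
        Correlation parameter in ``[0, 1)``.  For ``exchangeable`` this is
        the common off-diagonal correlation; ignored for ``independent`` and
        ``repeat``.
    block_size:
        Markers per block (``block`` kind only); must divide the total
        marker count.
    repeat_count:
        Number of additional exact copies ``r`` of each duplicated marker
        (``repeat`` kind only).
    repeat_fraction:
        Fraction ``g`` of causal markers that are duplicated; the number of
        duplicated originals is ``d = round(g * m)``.

    Notes
    -----
    For the four correlation-based kinds the total marker count is
    ``M = 2 m`` (half the markers causal, alternating); for ``repeat`` it is
    ``M = m + r d`` with the duplicates appended after the causal block.
    """

    kind: str
    m: int
    rho: float = 0.0
    block_size: int = 10
    repeat_count: int = 0
    repeat_fraction: float = 0.0

    def __post_init__(self):
        if self.kind not in LD_KINDS:
            raise ValueError(f"unknown LD kind {self.kind!r}; expected one of {LD_KINDS}")
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if not (0.0 <= self.rho < 1.0):
            raise ValueError("rho must lie in [0, 1)")
        if self.kind == "repeat":
            if self.repeat_count < 0:
                raise ValueError("repeat_count must be >= 0")
            if not (0.0 <= self.repeat_fraction <= 1.0):
                raise ValueError("repeat_fraction must lie in [0, 1]")
            if self.d > self.m:
                raise ValueError("number of duplicated markers exceeds m")
        elif self.kind == "block":
            if self.block_size < 1 or self.M % self.block_size:
                raise ValueError("block_size must be >= 1 and divide M")

    @property
    def d(self) -> int:
        """Number of distinct causal markers that get duplicated."""
        return int(round(self.repeat_fraction * self.m))

    @property
    def M(self) -> int:
        """Total marker count implied by the structure."""
        if self.kind == "repeat":
            return self.m + self.repeat_count * self.d
        return 2 * self.m

    @property
    def n_base(self) -> int:
        """Markers simulated before any duplication (== M except for repeat)."""
        return self.m if self.kind == "repeat" else self.M


@dataclass
class GenotypeData:
    """A simulated genotype data set.

    ``G`` holds allele counts in {0, 1, 2} for the ``binomial_threshold`` and
    ``gene_drop`` backends, or standardized continuous values for the
    ``gaussian`` backend.  ``true_ld`` is the population marker correlation
    matrix when the structure implies one; ``true_kinship`` is the expected
    genotypic correlation between individuals (unit diagonal, no inbreeding
    for any pedigree built here).
    """

    G: np.ndarray
    freqs: Optional[AlleleFrequencySet]
    causal_mask: np.ndarray
    true_ld: Optional[np.ndarray] = None
    true_kinship: Optional[np.ndarray] = None
    backend: str = "binomial_threshold"
    seed_record: dict = field(default_factory=dict)

    def __post_init__(self):
        self.causal_mask = np.asarray(self.causal_mask, dtype=bool)
        if self.causal_mask.size != self.G.shape[1]:
            raise ValueError("causal_mask length must equal the marker count")

    @property
    def n(self) -> int:
        return self.G.shape[0]

    @property
    def M(self) -> int:
        return self.G.shape[1]

    @property
    def m(self) -> int:
        return int(self.causal_mask.sum())


@dataclass
class TraitRealization:
    """One draw of the polygenic trait model.

    ``y = Gamma_C beta + eps`` with ``beta_j ~ N(0, h2/m)`` and
    ``eps_i ~ N(0, 1 - h2)``, so the model variance components are
    ``sigma_g2 = h2`` and ``sigma_e2 = 1 - h2`` and ``var(y) = 1``.
    ``genetic_values`` stores the realized ``Gamma_C beta`` for the
    gold-standard oracle.
    """

    y: np.ndarray
    beta: np.ndarray
    h2: float
    genetic_values: np.ndarray
    seed_record: dict = field(default_factory=dict)

    @property
    def sigma_g2(self) -> float:
        return self.h2

    @property
    def sigma_e2(self) -> float:
        return 1.0 - self.h2


def draw_allele_freqs(M: int, seed=None) -> AlleleFrequencySet:
    """Draw ``M`` allele frequencies uniformly on (0.05, 0.95).

    The frequency set stands in for a common-variant frequency spectrum and
    is meant to be drawn once per experiment and held fixed across replicate
    data sets.
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    rng = _rng(seed)
    return AlleleFrequencySet(rng.uniform(FREQ_LOW, FREQ_HIGH, size=M))


def build_true_ld(spec: LDStructureSpec) -> np.ndarray:
    """Population marker correlation matrix Sigma* implied by ``spec``."""
    M = spec.M
    if spec.kind == "independent":
        return np.eye(M)
    if spec.kind == "autocorrelation":
        idx = np.arange(M)
        return spec.rho ** np.abs(idx[:, None] - idx[None, :])
    if spec.kind == "block":
        nb = M // spec.block_size
        block = np.full((spec.block_size, spec.block_size), spec.rho)
        np.fill_diagonal(block, 1.0)
        return np.kron(np.eye(nb), block)
    if spec.kind == "exchangeable":
        out = np.full((M, M), spec.rho)
        np.fill_diagonal(out, 1.0)
        return out
    # repeat: identity on the m originals; each duplicate perfectly
    # correlated with its source and with its sibling copies
    out = np.eye(M)
    m, d, r = spec.m, spec.d, spec.repeat_count
    if d and r:
        src = np.arange(d)
        copies = [src] + [m + t * d + src for t in range(r)]
        for a in copies:
            for b in copies:
                out[a, b] = 1.0
    return out


def assign_causal(spec: LDStructureSpec) -> np.ndarray:
    """Boolean causal mask: alternating (odd 1-based positions) for the
    correlation structures, first ``m`` markers for ``repeat``."""
    mask = np.zeros(spec.M, dtype=bool)
    if spec.kind == "repeat":
        mask[: spec.m] = True
    else:
        mask[0::2] = True
    return mask


def _latent_base(n: int, spec: LDStructureSpec, rng: np.random.Generator) -> np.ndarray:
    """n x n_base standard-normal matrix whose columns carry the structure's
    correlation (identity for repeat/independent bases)."""
    mb = spec.n_base
    z = rng.standard_normal((n, mb))
    if spec.kind in ("independent", "repeat") or spec.rho == 0.0:
        return z
    rho = spec.rho
    if spec.kind == "autocorrelation":
        x = np.empty_like(z)
        x[:, 0] = z[:, 0]
        c = math.sqrt(1.0 - rho * rho)
        for j in range(1, mb):
            x[:, j] = rho * x[:, j - 1] + c * z[:, j]
        return x
    if spec.kind == "block":
        nb = mb // spec.block_size
        u = rng.standard_normal((n, nb))
        shared = np.repeat(u, spec.block_size, axis=1)
        return math.sqrt(rho) * shared + math.sqrt(1.0 - rho) * z
    # exchangeable: one factor shared by every marker
    u = rng.standard_normal((n, 1))
    return math.sqrt(rho) * u + math.sqrt(1.0 - rho) * z


def _duplicate_columns(X: np.ndarray, spec: LDStructureSpec) -> np.ndarray:
    """Append r byte-identical copies of the first d columns (repeat kind)."""
    d, r = spec.d, spec.repeat_count
    if spec.kind != "repeat" or d == 0 or r == 0:
        return X
    copies = np.tile(X[:, :d], (1, r))
    return np.concatenate([X, copies], axis=1)


def sim_genotypes(
    n: int,
    spec: LDStructureSpec,
    freqs: AlleleFrequencySet,
    backend: str = "binomial_threshold",
    seed=None,
) -> GenotypeData:
    """Simulate genotypes for ``n`` unrelated individuals under ``spec``.

    ``freqs`` must cover the non-duplicated marker count (``m`` for the
    repeat kind, ``M`` otherwise); duplicate columns inherit the frequency of
    their source marker.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if len(freqs) != spec.n_base:
        raise ValueError(
            f"freqs has length {len(freqs)}; expected {spec.n_base} for this structure"
        )
    if backend not in ("gaussian", "binomial_threshold"):
        raise ValueError(f"unknown backend {backend!r}")
    rng = _rng(seed)
    record = {"backend": backend, "kind": spec.kind}

    if backend == "gaussian":
        X = _latent_base(n, spec, rng)
        G = _duplicate_columns(X, spec)
        full_freqs = None
    else:
        # two latent-threshold haplotypes per individual; allele present when
        # the latent Gaussian falls below the p-quantile, so E(G_j) = 2 p_j
        from scipy.stats import norm

        thresh = norm.ppf(freqs.freqs)
        h1 = (_latent_base(n, spec, rng) < thresh).astype(np.int8)
        h2 = (_latent_base(n, spec, rng) < thresh).astype(np.int8)
        G = _duplicate_columns(h1 + h2, spec)
        full_freqs = freqs
        if spec.kind == "repeat" and spec.d and spec.repeat_count:
            dup = np.tile(freqs.freqs[: spec.d], spec.repeat_count)
            full_freqs = AlleleFrequencySet(np.concatenate([freqs.freqs, dup]))

    return GenotypeData(
        G=G,
        freqs=full_freqs,
        causal_mask=assign_causal(spec),
        true_ld=build_true_ld(spec),
        backend=backend,
        seed_record=record,
    )


def _standardized_columns(data: GenotypeData) -> np.ndarray:
    """Column-standardized genotypes used inside the trait model.

    Count backends use the allele-count standardization with empirical
    frequencies; the gaussian backend centers and scales by the sample
    standard deviation.  Zero-variance columns are mapped to zero.
    """
    X = np.asarray(data.G, dtype=float)
    if data.backend == "gaussian":
        X = X - X.mean(axis=0)
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = np.inf
        return X / sd
    p = X.mean(axis=0) / 2.0
    v = 2.0 * p * (1.0 - p)
    v[v == 0] = np.inf
    return (X - 2.0 * p) / np.sqrt(v)


def sim_phenotype(data: GenotypeData, h2: float, seed=None) -> TraitRealization:
    """Draw a polygenic trait ``y = Gamma_C beta + eps`` for ``data``.

    ``beta_j ~ N(0, h2/m)`` over the causal markers and
    ``eps_i ~ N(0, 1-h2)``, so the total model variance is 1.
    """
    if not (0.0 < h2 < 1.0):
        raise ValueError("h2 must lie strictly in (0, 1)")
    m = data.m
    if m == 0:
        raise ValueError("no causal markers in data")
    rng = _rng(seed)
    beta = rng.normal(0.0, math.sqrt(h2 / m), size=m)
    eps = rng.normal(0.0, math.sqrt(1.0 - h2), size=data.n)
    gamma_c = _standardized_columns(data)[:, data.causal_mask]
    genetic = gamma_c @ beta
    return TraitRealization(
        y=genetic + eps,
        beta=beta,
        h2=h2,
        genetic_values=genetic,
        seed_record={"h2": h2},
    )


# ---------------------------------------------------------------------------
# pedigrees and gene drop
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Individual:
    """A pedigree member; founders have no parent references."""

    id: int
    father: Optional[int] = None
    mother: Optional[int] = None

    @property
    def is_founder(self) -> bool:
        return self.father is None


@dataclass
class Pedigree:
    """A collection of mutually unrelated cousin groups.

    ``members`` are topologically ordered (parents precede children).
    ``expected_kinship`` is the matrix of expected genotypic correlations
    phi among the sampled individuals: ``2 * (1/4)**(j+1)`` for j-th cousins
    within a group, 0 across groups, 1 on the diagonal (no inbreeding).
    """

    members: list
    sampled_ids: list
    expected_kinship: np.ndarray
    degree: str
    group_of: np.ndarray  # group index per sampled individual


def build_pedigree(degree: str, k: int = 40, n_groups: int = 10) -> Pedigree:
    """Build ``n_groups`` disjoint k-ships of cousins of the given degree.

    Each group descends from a single ancestral couple: the couple's ``k``
    children are full sibs, and each branch then extends through founder
    mates for one (first cousins), two (second), or three (third)
    generations, with one sampled individual per branch.  ``unrelated``
    returns independent founders.
    """
    if degree not in COUSIN_DEGREES:
        raise ValueError(f"unknown degree {degree!r}; expected one of {COUSIN_DEGREES}")
    if degree != "unrelated" and k < 2:
        raise ValueError("k must be >= 2 for cousin groups")

    members: list[Individual] = []
    sampled: list[int] = []
    group_of: list[int] = []
    counter = 0

    def new(father=None, mother=None) -> int:
        nonlocal counter
        members.append(Individual(counter, father, mother))
        counter += 1
        return counter - 1

    gens = {"first": 1, "second": 2, "third": 3}
    for g in range(n_groups):
        if degree == "unrelated":
            for _ in range(k):
                sampled.append(new())
                group_of.append(g)
            continue
        top_a, top_b = new(), new()
        for _ in range(k):
            lineage = new(top_a, top_b)  # generation-1 full sib
            for _ in range(gens[degree] - 1):
                lineage = new(lineage, new())
            sampled.append(new(lineage, new()))
            group_of.append(g)

    n = len(sampled)
    phi = COUSIN_PHI[degree]
    group_arr = np.asarray(group_of)
    kin = np.where(group_arr[:, None] == group_arr[None, :], phi, 0.0)
    np.fill_diagonal(kin, 1.0)
    return Pedigree(
        members=members,
        sampled_ids=sampled,
        expected_kinship=kin,
        degree=degree,
        group_of=group_arr,
    )


def _meiosis(
    parent_haps: np.ndarray,
    positions: np.ndarray,
    map_length: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Transmit one recombinant haplotype from a parent.

    Crossovers follow a Poisson process at 1 per 100 cM (Haldane, no
    interference) over the single chromosome of length ``map_length`` cM.
    """
    n_x = rng.poisson(map_length / 100.0)
    start = rng.integers(2)
    if n_x == 0:
        return parent_haps[start]
    cross = np.sort(rng.uniform(0.0, map_length, size=n_x))
    source = (start + np.searchsorted(cross, positions, side="right")) % 2
    return parent_haps[source, np.arange(positions.size)]


def gene_drop(
    ped: Pedigree,
    M: int,
    freqs: AlleleFrequencySet,
    map_length_cM: float = 3000.0,
    seed=None,
) -> GenotypeData:
    """Drop founder alleles through ``ped`` and return sampled genotypes.

    Markers are equally spaced on a single chromosome of ``map_length_cM``;
    founder haplotypes are independent Bernoulli(p_j) draws per marker, and
    every meiosis recombines under the Haldane model.  Realized IBD induces
    genotype correlation with expectation equal to ``ped.expected_kinship``.
    All markers are treated as causal, matching the cousinship study design.
    """
    if not ped.members:
        raise ValueError("empty pedigree")
    if M < 1:
        raise ValueError("M must be >= 1")
    if len(freqs) != M:
        raise ValueError("freqs length must equal M")
    if map_length_cM <= 0:
        raise ValueError("map_length_cM must be positive")
    rng = _rng(seed)
    positions = np.linspace(0.0, map_length_cM, M)
    p = freqs.freqs

    haps: dict[int, np.ndarray] = {}
    for ind in ped.members:
        if ind.is_founder:
            haps[ind.id] = (rng.random((2, M)) < p).astype(np.int8)
        else:
            haps[ind.id] = np.stack(
                [
                    _meiosis(haps[ind.father], positions, map_length_cM, rng),
                    _meiosis(haps[ind.mother], positions, map_length_cM, rng),
                ]
            )

    G = np.stack([haps[i].sum(axis=0) for i in ped.sampled_ids])
    return GenotypeData(
        G=G,
        freqs=freqs,
        causal_mask=np.ones(M, dtype=bool),
        true_kinship=ped.expected_kinship,
        backend="gene_drop",
        seed_record={"degree": ped.degree, "map_length_cM": map_length_cM},
    )
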