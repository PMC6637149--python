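"""Degenerate-codon site-saturation library algebra and coverage statistics.

Covers the standard accounting for NNS-style saturation mutagenesis:
enumeration of the codon/protein variant space with per-outcome degeneracies,
the Poisson oversampling approximation P(no variant missed) = exp(−λ) with
λ = n·(1 − 1/n)^m for n unique variants and m sampled clones, the top-k
hit probability 1 − (1 − q)^L, and the plate-count confidence interval
(n ± z·√n)·N used to scale counted colonies to total transformants.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.Data.IUPACData import ambiguous_dna_values

__all__ = [
    "DegenerateCodon",
    "LibrarySpec",
    "VariantSpace",
    "CountingExperiment",
    "expand_degenerate_codon",
    "translate_codon_set",
    "variant_space",
    "uniform_variant_space",
    "coverage_lambda",
    "p_full_coverage",
    "exact_p_full_coverage",
    "required_sample_size",
    "prob_contains_top_k",
    "cfu_confidence_interval",
]

_IUPAC = {sym: "".join(sorted(bases)) for sym, bases in ambiguous_dna_values.items()}
_CODE = unambiguous_dna_by_id[1]  # standard genetic code; stop = '*'


@dataclass(frozen=True)
class DegenerateCodon:
    """An IUPAC nucleotide triplet, e.g. NNS (N = A/C/G/T, S = C/G)."""

    symbols: str

    def __post_init__(self) -> None:
        if len(self.symbols) != 3:
            raise ValueError("degenerate codon must have exactly 3 symbols")
        for sym in self.symbols:
            if sym.upper() not in _IUPAC:
                raise ValueError(f"invalid IUPAC nucleotide symbol: {sym!r}")
        object.__setattr__(self, "symbols", self.symbols.upper())


@dataclass(frozen=True)
class LibrarySpec:
    """Randomized sites and the degenerate codon used at each."""

    codons: tuple[DegenerateCodon, ...]

    def __post_init__(self) -> None:
        if not self.codons:
            raise ValueError("library must randomize at least 1 site")

    @classmethod
    def uniform(cls, n_sites: int, codon: str = "NNS") -> "LibrarySpec":
        if n_sites < 1:
            raise ValueError("library must randomize at least 1 site")
        return cls(codons=tuple(DegenerateCodon(codon) for _ in range(n_sites)))

    @property
    def n_sites(self) -> int:
        return len(self.codons)


@dataclass
class VariantSpace:
    """Enumerated outcome space of a library.

    ``outcomes`` maps each protein outcome (amino acids, '*' for stop) to
    the number of codon combinations encoding it; the degeneracies sum to
    ``codon_combinations``.
    """

    codon_combinations: int
    outcomes: dict[str, int]

    def __post_init__(self) -> None:
        if sum(self.outcomes.values()) != self.codon_combinations:
            raise ValueError("outcome degeneracies must sum to the codon-combination count")

    @property
    def n_outcomes(self) -> int:
        """Distinct protein outcomes, stop-containing included."""
        return len(self.outcomes)

    @property
    def n_stop_free(self) -> int:
        return sum(1 for o in self.outcomes if "*" not in o)

    def top_outcomes(self, k: int) -> list[str]:
        """The k outcomes of highest codon degeneracy (ties by outcome string)."""
        if not 0 < k <= self.n_outcomes:
            raise ValueError(f"k={k} outside 1..{self.n_outcomes}")
        return sorted(self.outcomes, key=lambda o: (-self.outcomes[o], o))[:k]


@dataclass(frozen=True)
class CountingExperiment:
    """A plate count: n colonies, z-quantile, and sampling scale factor N."""

    colonies: int
    z: float = 1.96
    scale: float = 1.0

    def __post_init__(self) -> None:
        if self.colonies < 0:
            raise ValueError("colony count must be non-negative")
        if self.scale < 1:
            raise ValueError("sampling scale factor must be >= 1")


def expand_degenerate_codon(codon: DegenerateCodon | str) -> list[str]:
    """All explicit ACGT codons a degenerate codon encodes, in lexicographic order."""
    if isinstance(codon, str):
        codon = DegenerateCodon(codon)
    sets = [_IUPAC[sym] for sym in codon.symbols]
    return ["".join(tpl) for tpl in itertools.product(*sets)]


def translate_codon_set(codons: Sequence[str]) -> dict[str, int]:
    """Degeneracy map: amino-acid (or '*') -> number of encoding codons."""
    out: dict[str, int] = {}
    for codon in codons:
        if len(codon) != 3 or any(b not in "ACGT" for b in codon):
            raise ValueError(f"not an explicit ACGT codon: {codon!r}")
        aa = "*" if codon in _CODE.stop_codons else _CODE.forward_table[codon]
        out[aa] = out.get(aa, 0) + 1
    return out


def variant_space(spec: LibrarySpec) -> VariantSpace:
    """Enumerate the protein-outcome space of a multi-site library."""
    per_site = [translate_codon_set(expand_degenerate_codon(c)) for c in spec.codons]
    combos = 1
    for codon in spec.codons:
        combos *= len(expand_degenerate_codon(codon))
    outcomes: dict[str, int] = {}
    for tpl in itertools.product(*(sorted(m) for m in per_site)):
        deg = 1
        for site, aa in enumerate(tpl):
            deg *= per_site[site][aa]
        outcomes["".join(tpl)] = deg
    return VariantSpace(codon_combinations=combos, outcomes=outcomes)


def uniform_variant_space(n: int) -> VariantSpace:
    """A synthetic space of n equiprobable outcomes (for oracles and simulation)."""
    if n < 1:
        raise ValueError("need at least one outcome")
    width = len(str(n - 1))
    return VariantSpace(
        codon_combinations=n,
        outcomes={f"v{i:0{width}d}": 1 for i in range(n)},
    )


def coverage_lambda(n: int, m: int) -> float:
    """Expected number of unseen variants after m uniform draws from n."""
    if n < 1:
        raise ValueError("need at least one unique variant")
    if m < 0:
        raise ValueError("sample size must be non-negative")
    if n == 1:
        return 0.0 if m >= 1 else 1.0
    return n * math.exp(m * math.log1p(-1.0 / n))


def p_full_coverage(n: int, m: int) -> float:
    """Poisson approximation of the coupon-collector coverage probability."""
    return math.exp(-coverage_lambda(n, m))


def exact_p_full_coverage(n: int, m: int) -> float:
    """Exact coverage probability by inclusion–exclusion (feasible for n <= 20).

    Cross-check oracle for the exp(−λ) approximation.
    """
    if n > 20:
        raise ValueError("exact evaluator limited to n <= 20")
    if n < 1:
        raise ValueError("need at least one unique variant")
    if m < n:
        return 0.0
    return float(
        sum((-1) ** j * math.comb(n, j) * (1 - j / n) ** m for j in range(n + 1))
    )


def required_sample_size(n: int, p: float) -> int:
    """Smallest m with p_full_coverage(n, m) >= p."""
    if not 0.0 < p < 1.0:
        raise ValueError("target probability must be in (0, 1)")
    if n < 1:
        raise ValueError("need at least one unique variant")
    if n == 1:
        return 1
    # analytic guess, then settle the boundary exactly
    target = -math.log(p)
    guess = max(0, math.ceil(math.log(target / n) / math.log1p(-1.0 / n)))
    m = guess
    while m > 0 and p_full_coverage(n, m - 1) >= p:
        m -= 1
    while p_full_coverage(n, m) < p:
        m += 1
    return m


def prob_contains_top_k(
    L: int,
    k: int,
    space: VariantSpace,
    model: Literal["equal-outcome", "codon-weighted"] = "equal-outcome",
    top_outcomes: Optional[Sequence[str]] = None,
) -> float:
    """Probability a library of L clones contains at least one of k designated
    best variants.

    Under "equal-outcome" every distinct protein outcome is equiprobable
    (q = k / n_outcomes); under "codon-weighted" outcomes are drawn with
    their codon degeneracies (q = Σ degeneracy of the designated outcomes /
    codon combinations). If ``top_outcomes`` is not given the k outcomes of
    highest degeneracy are designated.
    """
    if L < 0:
        raise ValueError("library size must be non-negative")
    if not 0 < k <= space.n_outcomes:
        raise ValueError(f"k={k} exceeds outcome count {space.n_outcomes}")
    if model == "equal-outcome":
        q = k / space.n_outcomes
    elif model == "codon-weighted":
        chosen = list(top_outcomes) if top_outcomes is not None else space.top_outcomes(k)
        if len(chosen) != k:
            raise ValueError("number of designated outcomes must equal k")
        q = sum(space.outcomes[o] for o in chosen) / space.codon_combinations
    else:
        raise ValueError(f"unknown model {model!r}")
    if q >= 1.0:
        return 1.0 if L >= 1 else 0.0
    return 1.0 - math.exp(L * math.log1p(-q))


def cfu_confidence_interval(exp: CountingExperiment) -> tuple[float, float]:
    """(n ± z·√n)·N colony-count interval, lower bound clipped at zero."""
    n, z, N = exp.colonies, exp.z, exp.scale
    half = z * math.sqrt(n)
    return (max(0.0, (n - half)) * N, (n + half) * N)
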