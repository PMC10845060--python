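"""Exact match probabilities for a pair of imputed STR profiles.

Genotype imputation emits, for every individual and locus, two allele
probability vectors A1 and A2 — one per haplotype — over the N_l alleles of
the locus.  Treating the ordered genotype i|j as having probability
A1_i * A2_j, the probability that two individuals match fully (both alleles),
partially (exactly one allele) or not at all at a locus is an exact double sum
over their genotype distributions.  Assuming independence across loci
(linkage equilibrium), per-locus probabilities combine into the bivariate
distribution of the numbers of fully and partially matching loci by a simple
dynamic program, from which expected match counts follow.

Three interchangeable per-locus implementations are provided:

* :func:`locus_match_probabilities` — the literal case-by-case double sums;
* :func:`locus_match_probabilities_fast` — an algebraically equivalent
  inner-product form, O(N_l) instead of O(N_l^2), used by the all-pairs
  search engine;
* :func:`enumerate_locus_matches` — a brute-force enumeration over all
  N_l^2 x N_l^2 ordered genotype pairs, kept as an independent test oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .profiles import Locus

__all__ = [
    "LocusAlleleProbabilities",
    "AlleleProbabilityProfile",
    "LocusMatchProbabilities",
    "MatchCountDistribution",
    "ExpectedMatches",
    "locus_match_probabilities",
    "locus_match_probabilities_fast",
    "enumerate_locus_matches",
    "match_count_distribution",
    "expected_matches",
]

#: Input vectors whose sum deviates from 1 by more than this are rejected;
#: smaller deviations (format round-off) are silently renormalized.
NORMALIZATION_TOL = 1e-6


def _normalized(vec, tol: float, what: str) -> np.ndarray:
    v = np.asarray(vec, dtype=float)
    if v.ndim != 1 or v.shape[0] < 1:
        raise ValueError(f"{what}: probability vector must be 1-D and nonempty")
    if np.any(v < -tol):
        raise ValueError(f"{what}: negative probability {v.min()}")
    v = np.clip(v, 0.0, None)
    s = v.sum()
    if abs(s - 1.0) > tol:
        raise ValueError(f"{what}: probabilities sum to {s}, expected 1")
    return v / s


@dataclass
class LocusAlleleProbabilities:
    """Imputation posterior for one individual at one locus.

    ``a1`` and ``a2`` are the allele probability vectors of the two
    haplotypes, each of length N_l.  Vectors are validated and renormalized on
    construction: sums within :data:`NORMALIZATION_TOL` of 1 are rescaled to
    sum to 1 exactly (to within floating-point round-off), larger deviations
    raise.
    """

    locus_id: str
    a1: np.ndarray
    a2: np.ndarray

    def __post_init__(self) -> None:
        self.a1 = _normalized(self.a1, NORMALIZATION_TOL,
                              f"locus {self.locus_id!r} haplotype 1")
        self.a2 = _normalized(self.a2, NORMALIZATION_TOL,
                              f"locus {self.locus_id!r} haplotype 2")
        if self.a1.shape != self.a2.shape:
            raise ValueError(
                f"locus {self.locus_id!r}: haplotype vectors have different "
                f"lengths {self.a1.shape[0]} and {self.a2.shape[0]}"
            )

    @property
    def num_alleles(self) -> int:
        return int(self.a1.shape[0])


@dataclass
class AlleleProbabilityProfile:
    """Per-locus allele probabilities for one individual, in panel locus order."""

    individual_id: str
    loci_probs: list[LocusAlleleProbabilities]

    def __len__(self) -> int:
        return len(self.loci_probs)

    def __iter__(self):
        return iter(self.loci_probs)

    def __getitem__(self, i):
        return self.loci_probs[i]

    def validate(self, loci: Sequence[Locus]) -> None:
        if len(self.loci_probs) != len(loci):
            raise ValueError(
                f"profile {self.individual_id!r} has {len(self.loci_probs)} "
                f"loci, panel has {len(loci)}"
            )
        for lp, locus in zip(self.loci_probs, loci):
            if lp.num_alleles != locus.num_alleles:
                raise ValueError(
                    f"profile {self.individual_id!r}: vector length "
                    f"{lp.num_alleles} does not match locus {locus.id!r} "
                    f"({locus.num_alleles} alleles)"
                )


@dataclass(frozen=True)
class LocusMatchProbabilities:
    """(P_full, P_partial, P_none) for one locus and one pair of individuals."""

    p_full: float
    p_partial: float
    p_none: float

    def __post_init__(self) -> None:
        for name, v in (("p_full", self.p_full), ("p_partial", self.p_partial),
                        ("p_none", self.p_none)):
            if not -1e-10 <= v <= 1 + 1e-10:
                raise ValueError(f"{name}={v} outside [0, 1]")
        total = self.p_full + self.p_partial + self.p_none
        if abs(total - 1.0) > 1e-10:
            raise ValueError(f"match probabilities sum to {total}, expected 1")


@dataclass
class MatchCountDistribution:
    """Bivariate distribution pi[m, p] of fully and partially matching loci.

    ``pi`` is a dense (L+1, L+1) array; entries with m + p > L are exactly 0
    and the whole triangle sums to 1.
    """

    L: int
    pi: np.ndarray

    def __post_init__(self) -> None:
        pi = np.asarray(self.pi, dtype=float)
        if pi.shape != (self.L + 1, self.L + 1):
            raise ValueError(f"pi must have shape ({self.L + 1}, {self.L + 1})")
        if np.any(pi < -1e-12):
            raise ValueError("negative probability in match-count distribution")
        m_idx, p_idx = np.indices(pi.shape)
        if np.any(pi[m_idx + p_idx > self.L] != 0.0):
            raise ValueError("nonzero probability at m + p > L")
        total = pi.sum()
        if abs(total - 1.0) > 1e-10:
            raise ValueError(f"match-count distribution sums to {total}")
        self.pi = pi


@dataclass(frozen=True)
class ExpectedMatches:
    """Expected matching alleles and fully/partially matching loci for a pair."""

    e_alleles: float
    e_full: float
    e_partial: float

    def __post_init__(self) -> None:
        if abs(self.e_alleles - (2 * self.e_full + self.e_partial)) > 1e-9:
            raise ValueError("e_alleles must equal 2*e_full + e_partial")


def _check_pair(a: LocusAlleleProbabilities, b: LocusAlleleProbabilities) -> None:
    if a.num_alleles != b.num_alleles:
        raise ValueError(
            f"dimension mismatch between loci {a.locus_id!r} ({a.num_alleles}) "
            f"and {b.locus_id!r} ({b.num_alleles})"
        )


def locus_match_probabilities(a: LocusAlleleProbabilities,
                              b: LocusAlleleProbabilities) -> LocusMatchProbabilities:
    """Full/partial/non-match probabilities at one locus, by the literal sums.

    Works case-by-case over A's ordered genotype i|j, separating i == j from
    i != j, exactly as the closed-form derivation is written.  Retained as a
    readable reference; the all-pairs engine uses
    :func:`locus_match_probabilities_fast`.
    """
    _check_pair(a, b)
    A1, A2, B1, B2 = a.a1, a.a2, b.a1, b.a2
    n = a.num_alleles
    W = np.outer(A1, A2)  # W[i, j] = P(A's ordered genotype is i|j)
    off = ~np.eye(n, dtype=bool)

    # Full match: A:i|j with B:i|j or B:j|i (i != j), or both i|i.
    full_off = np.outer(B1, B2) + np.outer(B2, B1)
    p_full = float((W * full_off)[off].sum() + (A1 * A2 * B1 * B2).sum())

    # Partial match, i != j: B is i|k, j|k, k|i or k|j with k distinct from
    # both, i.e. B1_i(1-B2_j) + B1_j(1-B2_i) + (1-B1_i-B1_j)(B2_i+B2_j).
    part_off = (
        np.outer(B1, 1.0 - B2)
        + np.outer(1.0 - B2, B1)
        + (1.0 - np.add.outer(B1, B1)) * np.add.outer(B2, B2)
    )
    part_diag = A1 * A2 * (B1 * (1.0 - B2) + (1.0 - B1) * B2)
    p_partial = float((W * part_off)[off].sum() + part_diag.sum())

    # Non-match: B carries neither of A's alleles on either haplotype.
    none_off = (1.0 - np.add.outer(B1, B1)) * (1.0 - np.add.outer(B2, B2))
    none_diag = A1 * A2 * (1.0 - B1) * (1.0 - B2)
    p_none = float((W * none_off)[off].sum() + none_diag.sum())

    return LocusMatchProbabilities(p_full=p_full, p_partial=p_partial, p_none=p_none)


def locus_match_probabilities_fast(a: LocusAlleleProbabilities,
                                   b: LocusAlleleProbabilities) -> LocusMatchProbabilities:
    """O(N_l) inner-product form of :func:`locus_match_probabilities`.

    Expanding the double sums and collecting terms gives, with
    s_gh = sum_i A_g,i B_h,i, w = sum_i A1_i A2_i B1_i B2_i,
    u1 = sum_i A1_i B1_i B2_i, u2 = sum_i A2_i B1_i B2_i,
    v1 = sum_i A1_i A2_i B1_i and v2 = sum_i A1_i A2_i B2_i:

        P_full = s11*s22 + s12*s21 - w
        P_none = 1 - s11 - s12 - s21 - s22 + s11*s22 + s12*s21
                 + u1 + u2 + v1 + v2 - 3w

    and P_partial = 1 - P_full - P_none.
    """
    _check_pair(a, b)
    A1, A2, B1, B2 = a.a1, a.a2, b.a1, b.a2
    bb = B1 * B2
    aa = A1 * A2
    s11 = float(A1 @ B1)
    s12 = float(A1 @ B2)
    s21 = float(A2 @ B1)
    s22 = float(A2 @ B2)
    w = float(aa @ bb)
    u1 = float(A1 @ bb)
    u2 = float(A2 @ bb)
    v1 = float(aa @ B1)
    v2 = float(aa @ B2)
    p_full = s11 * s22 + s12 * s21 - w
    p_none = (1.0 - s11 - s12 - s21 - s22 + s11 * s22 + s12 * s21
              + u1 + u2 + v1 + v2 - 3.0 * w)
    # Clip tiny negative round-off so the invariant checks stay exact.
    p_full = min(max(p_full, 0.0), 1.0)
    p_none = min(max(p_none, 0.0), 1.0)
    p_partial = 1.0 - p_full - p_none
    if p_partial < 0.0:
        p_partial = 0.0
    return LocusMatchProbabilities(p_full=p_full, p_partial=p_partial, p_none=p_none)


def enumerate_locus_matches(a: LocusAlleleProbabilities,
                            b: LocusAlleleProbabilities,
                            max_alleles: int = 64) -> LocusMatchProbabilities:
    """Brute-force oracle: enumerate all ordered genotype pairs at one locus.

    Every ordered pair (A:i|j, B:k|l) is weighted by A1_i A2_j B1_k B2_l and
    classified by the multiset-intersection cardinality of {i, j} and {k, l}.
    Quartic in N_l, so guarded; intended for tests only.
    """
    _check_pair(a, b)
    n = a.num_alleles
    if n > max_alleles:
        raise ValueError(f"enumeration guard: N_l = {n} exceeds {max_alleles}")
    i = np.arange(n)[:, None, None, None]
    j = np.arange(n)[None, :, None, None]
    k = np.arange(n)[None, None, :, None]
    l = np.arange(n)[None, None, None, :]
    shared = np.maximum(
        (i == k).astype(np.int8) + (j == l),
        (i == l).astype(np.int8) + (j == k),
    )
    w = (a.a1[:, None, None, None] * a.a2[None, :, None, None]
         * b.a1[None, None, :, None] * b.a2[None, None, None, :])
    p_full = float(w[shared == 2].sum())
    p_partial = float(w[shared == 1].sum())
    p_none = float(w[shared == 0].sum())
    total = p_full + p_partial + p_none
    return LocusMatchProbabilities(p_full=p_full / total, p_partial=p_partial / total,
                                   p_none=p_none / total)


def match_count_distribution(
    per_locus: Sequence[LocusMatchProbabilities],
) -> MatchCountDistribution:
    """Distribution of (fully, partially) matching locus counts over L loci.

    Builds pi[m, p] by the standard recursion for sums of independent
    trinomial locus outcomes: appending locus l+1 either leaves the counts
    (non-match), increments p (partial match) or increments m (full match),

        pi[m, p] <- P_none * pi[m, p] + P_partial * pi[m, p-1]
                    + P_full * pi[m-1, p],

    starting from pi[0, 0] = 1 before any locus is considered.  Assumes
    independence of match outcomes across loci (linkage equilibrium).
    """
    per_locus = list(per_locus)
    if not per_locus:
        raise ValueError("match_count_distribution requires at least one locus")
    L = len(per_locus)
    cur = np.zeros((L + 1, L + 1))
    cur[0, 0] = 1.0
    for lp in per_locus:
        new = lp.p_none * cur
        new[:, 1:] += lp.p_partial * cur[:, :-1]
        new[1:, :] += lp.p_full * cur[:-1, :]
        cur = new
    return MatchCountDistribution(L=L, pi=cur)


def expected_matches(dist: MatchCountDistribution) -> ExpectedMatches:
    """Expected numbers of matching alleles and fully/partially matching loci."""
    m_idx, p_idx = np.indices(dist.pi.shape)
    e_full = float((m_idx * dist.pi).sum())
    e_partial = float((p_idx * dist.pi).sum())
    return ExpectedMatches(
        e_alleles=2.0 * e_full + e_partial,
        e_full=e_full,
        e_partial=e_partial,
    )
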