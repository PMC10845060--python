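"""Data model for STR loci and diploid profiles, and genotype-level match counting.

An Arizona search scans all pairs of profiles in a forensic STR database and
tabulates, for each pair, the number of matching alleles, the number of loci
matching at both alleles ("fully matching") and the number of loci matching at
exactly one allele ("partially matching").  This module provides the locus and
profile containers, the per-locus and per-profile match counting used both for
searches on true genotypes and for Scheme-1 searches on genotypes called from
imputation posteriors, and the most-probable-allele genotype caller itself.

Matching is defined on unordered genotypes: the shared-allele count at a locus
is the cardinality of the multiset intersection of the two allele pairs, so a
full match contributes 2, a partial match 1, and a non-match 0.  Phase is
recorded in profiles but never affects matching.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "Locus",
    "GenotypeProfile",
    "PairMatchCounts",
    "locus_allele_matches",
    "shared_allele_counts",
    "profile_match_counts",
    "call_genotypes",
]


@dataclass(frozen=True)
class Locus:
    """A single STR locus: a name plus its ordered list of distinct allele labels.

    Allele labels (typically repeat lengths) are metadata only; every
    computation in the package works with 0-based allele indices into
    ``alleles``.
    """

    id: str
    alleles: tuple

    def __post_init__(self) -> None:
        object.__setattr__(self, "alleles", tuple(self.alleles))
        if len(self.alleles) < 1:
            raise ValueError(f"locus {self.id!r} must have at least one allele")
        if len(set(self.alleles)) != len(self.alleles):
            raise ValueError(f"locus {self.id!r} has duplicate allele labels")

    @property
    def num_alleles(self) -> int:
        return len(self.alleles)


@dataclass
class GenotypeProfile:
    """Diploid genotype of one individual over an ordered locus list.

    ``genotypes`` has shape (L, 2) and holds 0-based allele indices; the two
    columns are the two phased haplotypes.
    """

    individual_id: str
    genotypes: np.ndarray

    def __post_init__(self) -> None:
        g = np.asarray(self.genotypes, dtype=np.int64)
        if g.ndim != 2 or g.shape[1] != 2:
            raise ValueError(
                f"profile {self.individual_id!r}: genotypes must have shape (L, 2), "
                f"got {g.shape}"
            )
        self.genotypes = g

    @property
    def n_loci(self) -> int:
        return int(self.genotypes.shape[0])

    def validate(self, loci: Sequence[Locus]) -> None:
        """Check that the profile covers every locus with in-range allele indices."""
        if self.n_loci != len(loci):
            raise ValueError(
                f"profile {self.individual_id!r} covers {self.n_loci} loci, "
                f"panel has {len(loci)}"
            )
        for l, locus in enumerate(loci):
            g = self.genotypes[l]
            if g.min() < 0 or g.max() >= locus.num_alleles:
                raise ValueError(
                    f"profile {self.individual_id!r}: allele index out of range "
                    f"at locus {locus.id!r} (got {tuple(g)}, "
                    f"{locus.num_alleles} alleles)"
                )


@dataclass(frozen=True)
class PairMatchCounts:
    """Match counts for one pair of individuals over a whole panel.

    ``k`` matching alleles, ``m`` fully matching loci, ``p`` partially matching
    loci; for integer genotype comparisons k = 2m + p.
    """

    id_a: str
    id_b: str
    k: int
    m: int
    p: int


def locus_allele_matches(g_a: Sequence[int], g_b: Sequence[int],
                         num_alleles: int | None = None) -> int:
    """Shared-allele count between two unordered diploid genotypes at one locus.

    Returns the multiset-intersection cardinality of the two allele pairs, an
    integer in {0, 1, 2}: 2 is a full match, 1 a partial match, 0 a non-match.
    The result does not depend on allele order within either genotype.
    """
    a0, a1 = int(g_a[0]), int(g_a[1])
    b0, b1 = int(g_b[0]), int(g_b[1])
    if num_alleles is not None:
        for x in (a0, a1, b0, b1):
            if not 0 <= x < num_alleles:
                raise ValueError(
                    f"allele index {x} out of range for locus with "
                    f"{num_alleles} alleles"
                )
    # Multiset intersection of two size-2 multisets equals the better of the
    # two one-to-one haplotype pairings.
    return max(
        (a0 == b0) + (a1 == b1),
        (a0 == b1) + (a1 == b0),
    )


def shared_allele_counts(ga: np.ndarray, gb: np.ndarray) -> np.ndarray:
    """Vectorized per-locus shared-allele counts for two (L, 2) genotype arrays."""
    s1 = (ga[:, 0] == gb[:, 0]).astype(np.int64) + (ga[:, 1] == gb[:, 1])
    s2 = (ga[:, 0] == gb[:, 1]).astype(np.int64) + (ga[:, 1] == gb[:, 0])
    return np.maximum(s1, s2)


def profile_match_counts(profile_a: GenotypeProfile, profile_b: GenotypeProfile,
                         loci: Sequence[Locus] | None = None) -> PairMatchCounts:
    """Count matching alleles and fully/partially matching loci for one pair.

    Both profiles must be defined over the same ordered locus list.  When
    ``loci`` is given the profiles are validated against it first.
    """
    if profile_a.n_loci != profile_b.n_loci:
        raise ValueError(
            f"locus-list mismatch: {profile_a.individual_id!r} has "
            f"{profile_a.n_loci} loci, {profile_b.individual_id!r} has "
            f"{profile_b.n_loci}"
        )
    if loci is not None:
        profile_a.validate(loci)
        profile_b.validate(loci)
    shared = shared_allele_counts(profile_a.genotypes, profile_b.genotypes)
    m = int(np.count_nonzero(shared == 2))
    p = int(np.count_nonzero(shared == 1))
    return PairMatchCounts(
        id_a=profile_a.individual_id,
        id_b=profile_b.individual_id,
        k=2 * m + p,
        m=m,
        p=p,
    )


def call_genotypes(prob_profile, individual_id: str,
                   loci: Sequence[Locus] | None = None,
                   tol: float = 1e-6) -> GenotypeProfile:
    """Call a genotype profile from per-haplotype allele-probability vectors.

    For each locus and each haplotype independently the called allele is the
    index with the highest posterior probability, mirroring how imputation
    software assigns called genotypes from its allele-probability output.
    Argmax ties are broken toward the smallest allele index so that calling is
    deterministic.

    Parameters
    ----------
    prob_profile:
        Per-locus objects exposing ``a1`` and ``a2`` probability vectors
        (see :class:`azsearch.matchprob.LocusAlleleProbabilities`), in panel
        locus order.
    individual_id:
        Identifier for the returned profile.
    loci:
        Optional locus list to validate vector lengths against.
    tol:
        Maximum allowed deviation of each vector's sum from 1.
    """
    if loci is not None and len(prob_profile) != len(loci):
        raise ValueError(
            f"profile {individual_id!r} has {len(prob_profile)} loci, "
            f"panel has {len(loci)}"
        )
    calls = np.empty((len(prob_profile), 2), dtype=np.int64)
    for l, lp in enumerate(prob_profile):
        for h, vec in enumerate((lp.a1, lp.a2)):
            v = np.asarray(vec, dtype=float)
            if loci is not None and v.shape[0] != loci[l].num_alleles:
                raise ValueError(
                    f"profile {individual_id!r}: vector length {v.shape[0]} "
                    f"does not match locus {loci[l].id!r} "
                    f"({loci[l].num_alleles} alleles)"
                )
            s = v.sum()
            if abs(s - 1.0) > tol:
                raise ValueError(
                    f"profile {individual_id!r}, locus index {l}: haplotype "
                    f"{h + 1} probabilities sum to {s}, expected 1"
                )
            # np.argmax returns the first (smallest) index on ties.
            calls[l, h] = int(np.argmax(v))
    return GenotypeProfile(individual_id=individual_id, genotypes=calls)
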