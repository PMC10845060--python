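"""All-pairs Arizona searches over a profile database, with replicate splits.

The search compares every unordered pair of individuals in a database and
records, per pair, the numbers of matching alleles (k), fully matching loci
(m) and partially matching loci (p).  Three schemes are supported:

* ``"true"`` — integer counts on the true genotype profiles;
* ``"called"`` — integer counts on genotypes called from imputation
  posteriors by per-haplotype argmax (Scheme 1);
* ``"expected"`` — exact expected counts computed from the per-haplotype
  allele-probability vectors themselves (Scheme 2).

A study run splits the full panel into a reference fraction (which stands in
for the imputation reference panel and takes no part in the search) and a
database set, repeats the split over replicates with deterministic child
seeds, runs the requested schemes on each database, and pools the per-pair
records for summary statistics.  The same splits are reused across schemes so
that pair-level records can be aligned for concordance analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .matchprob import (
    AlleleProbabilityProfile,
    MatchCountDistribution,
    expected_matches,
    locus_match_probabilities_fast,
    match_count_distribution,
)
from .profiles import GenotypeProfile, Locus, call_genotypes

__all__ = [
    "SCHEMES",
    "VARIABLES",
    "SearchResult",
    "ReplicateStudy",
    "split_reference_database",
    "run_search",
    "tabulate_distribution",
    "summarize",
    "run_replicates",
]

SCHEMES = ("true", "called", "expected")

#: Map from variable name to the per-pair record field holding it.
VARIABLES = {"alleles": "k", "full": "m", "partial": "p"}

#: Pair count above which the per-pair full DP distribution is refused.
_FULL_DIST_PAIR_CAP = 50_000


@dataclass
class SearchResult:
    """Per-pair match records for one database, one scheme, one replicate.

    Pairs are in canonical order: lexicographic by (index of a, index of b)
    with a < b, over the database individual list.  ``k``, ``m`` and ``p``
    are integer arrays for the true/called schemes and float arrays of
    expectations for the expected scheme.
    """

    scheme: str
    replicate_index: int
    individual_ids: tuple
    id_a: np.ndarray
    id_b: np.ndarray
    k: np.ndarray
    m: np.ndarray
    p: np.ndarray
    distributions: list[MatchCountDistribution] | None = None

    @property
    def n_pairs(self) -> int:
        return int(self.k.shape[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "replicate": np.full(self.n_pairs, self.replicate_index,
                                     dtype=np.int64),
                "id_a": self.id_a,
                "id_b": self.id_b,
                "scheme": self.scheme,
                "k": self.k,
                "m": self.m,
                "p": self.p,
            }
        )


def split_reference_database(n_total: int, reference_fraction: float,
                             seed: int, replicate_index: int = 0
                             ) -> tuple[np.ndarray, np.ndarray]:
    """Random split of ``n_total`` individuals into reference and database sets.

    The reference set has size floor(reference_fraction * n_total); the
    database is the complement.  The partition is a uniform random one,
    determined entirely by ``(seed, replicate_index)``: replicate r draws from
    an independent child stream of the base seed, so replicates are
    independent yet reproducible.  Both index sets are returned sorted.
    """
    if not 0.0 < reference_fraction < 1.0:
        raise ValueError(f"reference_fraction must be in (0, 1), got {reference_fraction}")
    if n_total < 2:
        raise ValueError(f"need at least 2 individuals, got {n_total}")
    n_ref = math.floor(reference_fraction * n_total)
    n_db = n_total - n_ref
    if n_db < 2:
        raise ValueError(
            f"database would have {n_db} individuals; at least 2 are required"
        )
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(int(replicate_index),))
    )
    perm = rng.permutation(n_total)
    ref = np.sort(perm[:n_ref])
    db = np.sort(perm[n_ref:])
    return ref, db


def _genotype_matrix(profiles: Sequence[GenotypeProfile]) -> np.ndarray:
    return np.stack([pr.genotypes for pr in profiles])  # (n, L, 2)


def _all_pairs_integer(G: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized all-pairs (k, m, p) for an (n, L, 2) genotype index array."""
    a0 = G[:, :, 0]
    a1 = G[:, :, 1]
    s1 = ((a0[:, None, :] == a0[None, :, :]).astype(np.int8)
          + (a1[:, None, :] == a1[None, :, :]))
    s2 = ((a0[:, None, :] == a1[None, :, :]).astype(np.int8)
          + (a1[:, None, :] == a0[None, :, :]))
    shared = np.maximum(s1, s2)  # (n, n, L)
    m_mat = (shared == 2).sum(axis=2, dtype=np.int64)
    p_mat = (shared == 1).sum(axis=2, dtype=np.int64)
    iu = np.triu_indices(G.shape[0], k=1)
    m = m_mat[iu]
    p = p_mat[iu]
    return 2 * m + p, m, p


def _probability_matrices(
    prob_profiles: Sequence[AlleleProbabilityProfile], n_loci: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stack per-individual haplotype vectors into per-locus (n, N_l) matrices."""
    out = []
    for l in range(n_loci):
        X1 = np.stack([pp[l].a1 for pp in prob_profiles])
        X2 = np.stack([pp[l].a2 for pp in prob_profiles])
        out.append((X1, X2))
    return out


def _all_pairs_expected(
    prob_profiles: Sequence[AlleleProbabilityProfile], n_loci: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All-pairs expected (k, m, p) via the per-locus inner-product form.

    For each locus the pairwise P_full and P_partial matrices are computed
    with a handful of n x n matrix products (the matrix form of
    :func:`azsearch.matchprob.locus_match_probabilities_fast`); expectations
    sum over loci by linearity.
    """
    n = len(prob_profiles)
    e_full = np.zeros((n, n))
    e_partial = np.zeros((n, n))
    for X1, X2 in _probability_matrices(prob_profiles, n_loci):
        Z = X1 * X2
        s11 = X1 @ X1.T
        s12 = X1 @ X2.T
        s22 = X2 @ X2.T
        s21 = s12.T
        w = Z @ Z.T
        u1 = X1 @ Z.T  # u1[a, b] = sum_i A1_i B1_i B2_i
        u2 = X2 @ Z.T
        prod = s11 * s22 + s12 * s21
        p_full = prod - w
        p_none = (1.0 - s11 - s12 - s21 - s22 + prod
                  + u1 + u2 + u1.T + u2.T - 3.0 * w)
        np.clip(p_full, 0.0, 1.0, out=p_full)
        np.clip(p_none, 0.0, 1.0, out=p_none)
        p_partial = np.clip(1.0 - p_full - p_none, 0.0, 1.0)
        e_full += p_full
        e_partial += p_partial
    iu = np.triu_indices(n, k=1)
    m = e_full[iu]
    p = e_partial[iu]
    return 2.0 * m + p, m, p


def run_search(scheme: str, *,
               genotype_profiles: Sequence[GenotypeProfile] | None = None,
               probability_profiles: Sequence[AlleleProbabilityProfile] | None = None,
               loci: Sequence[Locus] | None = None,
               replicate_index: int = 0,
               full_distribution: bool = False) -> SearchResult:
    """Run one all-pairs Arizona search on a database.

    ``scheme`` selects the input and arithmetic: ``"true"`` counts matches on
    ``genotype_profiles``; ``"called"`` first calls genotypes from
    ``probability_profiles`` by per-haplotype argmax, then counts; and
    ``"expected"`` computes exact expected counts from the probability
    vectors.  With ``full_distribution=True`` (expected scheme only) the full
    bivariate match-count distribution of every pair is also computed by the
    dynamic program and attached to the result.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")
    if scheme == "true":
        if genotype_profiles is None:
            raise ValueError("scheme 'true' requires genotype profiles")
        profiles = list(genotype_profiles)
        ids = tuple(pr.individual_id for pr in profiles)
    else:
        if probability_profiles is None:
            raise ValueError(f"scheme {scheme!r} requires probability profiles")
        prob_profiles = list(probability_profiles)
        ids = tuple(pp.individual_id for pp in prob_profiles)
    if len(ids) < 2:
        raise ValueError("a search requires at least 2 individuals")
    if loci is not None:
        if scheme == "true":
            for pr in profiles:
                pr.validate(loci)
        else:
            for pp in prob_profiles:
                pp.validate(loci)

    if scheme == "called":
        profiles = [call_genotypes(pp.loci_probs, pp.individual_id, loci=loci)
                    for pp in prob_profiles]

    n = len(ids)
    iu = np.triu_indices(n, k=1)
    ids_arr = np.asarray(ids, dtype=object)
    distributions = None

    if scheme in ("true", "called"):
        k, m, p = _all_pairs_integer(_genotype_matrix(profiles))
    else:
        n_loci = len(prob_profiles[0])
        for pp in prob_profiles:
            if len(pp) != n_loci:
                raise ValueError(
                    f"profile {pp.individual_id!r} has {len(pp)} loci, "
                    f"expected {n_loci}"
                )
        k, m, p = _all_pairs_expected(prob_profiles, n_loci)
        if full_distribution:
            n_pairs = n * (n - 1) // 2
            if n_pairs > _FULL_DIST_PAIR_CAP:
                raise ValueError(
                    f"full_distribution refused for {n_pairs} pairs "
                    f"(cap {_FULL_DIST_PAIR_CAP})"
                )
            distributions = []
            for ia, ib in zip(*iu):
                per_locus = [
                    locus_match_probabilities_fast(prob_profiles[ia][l],
                                                   prob_profiles[ib][l])
                    for l in range(n_loci)
                ]
                distributions.append(match_count_distribution(per_locus))

    return SearchResult(
        scheme=scheme,
        replicate_index=replicate_index,
        individual_ids=ids,
        id_a=ids_arr[iu[0]],
        id_b=ids_arr[iu[1]],
        k=k,
        m=m,
        p=p,
        distributions=distributions,
    )


def _pooled(results: Sequence[SearchResult], variable: str) -> np.ndarray:
    field_name = VARIABLES[variable]
    return np.concatenate([getattr(r, field_name) for r in results])


def tabulate_distribution(results: SearchResult | Sequence[SearchResult],
                          variable: str):
    """Pool per-pair values of one variable across replicate results.

    For the integer schemes returns a normalized frequency table (a pandas
    Series indexed by count); for the expected scheme returns the pooled raw
    values, leaving any binning or density estimation to the caller.
    """
    if isinstance(results, SearchResult):
        results = [results]
    results = list(results)
    if not results:
        raise ValueError("no results to tabulate")
    schemes = {r.scheme for r in results}
    if len(schemes) > 1:
        raise ValueError(f"cannot pool mixed schemes {sorted(schemes)}")
    if variable not in VARIABLES:
        raise ValueError(f"unknown variable {variable!r}")
    values = _pooled(results, variable)
    if results[0].scheme == "expected":
        return values
    counts = pd.Series(values).value_counts().sort_index()
    return counts / counts.sum()


def summarize(results_by_scheme: Mapping[str, Sequence[SearchResult]]) -> pd.DataFrame:
    """Median and maximum of each match variable per scheme, pooled over replicates.

    Statistics are computed on the concatenation of all replicates' per-pair
    records (no per-replicate averaging); the median of an even-length pooled
    vector is the mean of the two central order statistics.
    """
    rows = []
    for stat in ("median", "maximum"):
        for variable in VARIABLES:
            row = {"statistic": stat, "variable": variable}
            for scheme, results in results_by_scheme.items():
                results = list(results)
                if not results:
                    raise ValueError(f"scheme {scheme!r} has no results")
                values = _pooled(results, variable)
                row[scheme] = float(np.median(values)) if stat == "median" \
                    else float(values.max())
            rows.append(row)
    return pd.DataFrame(rows).set_index(["statistic", "variable"])


@dataclass
class ReplicateStudy:
    """Results of an Arizona-search study over replicate reference/database splits."""

    loci: tuple
    reference_fraction: float
    base_seed: int
    schemes: tuple
    results: dict = field(default_factory=dict)  # scheme -> list[SearchResult]
    splits: list = field(default_factory=list)   # (reference, database) index arrays

    def pooled_frame(self, scheme: str) -> pd.DataFrame:
        frames = [r.to_frame() for r in self.results[scheme]]
        return pd.concat(frames, ignore_index=True)

    def summary(self) -> pd.DataFrame:
        return summarize(self.results)


def run_replicates(*,
                   loci: Sequence[Locus],
                   genotype_profiles: Sequence[GenotypeProfile] | None = None,
                   probability_profiles: Sequence[AlleleProbabilityProfile] | None = None,
                   n_replicates: int,
                   reference_fraction: float = 0.6,
                   base_seed: int = 0,
                   schemes: Sequence[str] = SCHEMES) -> ReplicateStudy:
    """Repeat the reference/database split and run every scheme on each database.

    Replicate ``r`` uses the child seed stream ``(base_seed, r)``, and the
    same split is shared by all schemes within a replicate, so per-pair
    records align across schemes for concordance analysis.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    schemes = tuple(schemes)
    for s in schemes:
        if s not in SCHEMES:
            raise ValueError(f"unknown scheme {s!r}")
    if "true" in schemes and genotype_profiles is None:
        raise ValueError("scheme 'true' requires genotype profiles")
    if any(s in schemes for s in ("called", "expected")) and probability_profiles is None:
        raise ValueError("schemes 'called'/'expected' require probability profiles")

    if genotype_profiles is not None:
        n_total = len(genotype_profiles)
        if probability_profiles is not None and len(probability_profiles) != n_total:
            raise ValueError("genotype and probability panels differ in size")
    else:
        n_total = len(probability_profiles)

    study = ReplicateStudy(
        loci=tuple(loci),
        reference_fraction=reference_fraction,
        base_seed=base_seed,
        schemes=schemes,
        results={s: [] for s in schemes},
    )
    for r in range(n_replicates):
        ref, db = split_reference_database(n_total, reference_fraction,
                                           base_seed, replicate_index=r)
        study.splits.append((ref, db))
        db_genotypes = ([genotype_profiles[i] for i in db]
                        if genotype_profiles is not None else None)
        db_probs = ([probability_profiles[i] for i in db]
                    if probability_profiles is not None else None)
        for scheme in schemes:
            study.results[scheme].append(
                run_search(scheme,
                           genotype_profiles=db_genotypes,
                           probability_profiles=db_probs,
                           loci=loci,
                           replicate_index=r)
            )
    return study
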