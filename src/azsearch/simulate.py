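"""Synthetic forensic STR panels with tunable imputation posteriors.

The generator produces every input the search pipeline consumes, with the
statistical structure the analysis assumes: per-locus allele-frequency
vectors (symmetric Dirichlet draws), diploid genotypes under Hardy-Weinberg
equilibrium at each locus and linkage equilibrium across loci, and
per-haplotype imputation posteriors whose fidelity is governed by a single
accuracy dial.

The posterior model for a haplotype with true allele ``t`` at a locus with
frequency vector ``f`` is

    posterior = lam * delta_t + (1 - lam) * q,    q ~ Dirichlet(c * f),

so ``lam = 1`` gives an exact point mass on the truth (a perfect imputation)
and ``lam = 0`` gives posteriors independent of the truth that fluctuate
around the population frequencies — mimicking an imputation engine falling
back toward reference-panel frequencies when the flanking-marker signal is
weak.  ``c`` (the posterior concentration) sets how tightly the noise
component hugs the frequencies.

The generator emulates imputation *output* only; it does not simulate SNP
haplotypes, recombination, population structure, relatives, or the
imputation algorithm itself.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .matchprob import AlleleProbabilityProfile, LocusAlleleProbabilities
from .profiles import GenotypeProfile, Locus

__all__ = [
    "SyntheticPanelConfig",
    "FrequencyPanel",
    "generate_frequencies",
    "generate_true_profiles",
    "generate_posteriors",
    "generate_panel",
]

#: Smallest Dirichlet parameter substituted for exact zeros so the noise
#: component is well defined at degenerate frequency vectors.
_ALPHA_FLOOR = 1e-9


@dataclass(frozen=True)
class SyntheticPanelConfig:
    """Study conditions for a synthetic panel.

    Defaults mirror the real-data study this pipeline is designed around:
    2,504 individuals typed at 18 STR loci, with a high-accuracy imputation
    (``accuracy=0.9``).  ``alleles_per_locus`` may be a single int or an
    inclusive (low, high) range sampled per locus; the 6-14 default spans the
    allele counts typical of forensic STR marker sets.
    """

    n_individuals: int = 2504
    n_loci: int = 18
    alleles_per_locus: int | tuple = (6, 14)
    frequency_concentration: float = 1.0
    accuracy: float = 0.9
    posterior_concentration: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 2:
            raise ValueError("n_individuals must be >= 2")
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        lo, hi = self.allele_range
        if lo < 2:
            raise ValueError("alleles_per_locus must be >= 2")
        if hi < lo:
            raise ValueError("alleles_per_locus range must have low <= high")
        if not 0.0 <= self.accuracy <= 1.0:
            raise ValueError("accuracy must be in [0, 1]")
        if self.frequency_concentration <= 0 or self.posterior_concentration <= 0:
            raise ValueError("concentrations must be positive")

    @property
    def allele_range(self) -> tuple[int, int]:
        if isinstance(self.alleles_per_locus, int):
            return self.alleles_per_locus, self.alleles_per_locus
        lo, hi = self.alleles_per_locus
        return int(lo), int(hi)


@dataclass
class FrequencyPanel:
    """Locus definitions plus one allele-frequency vector per locus."""

    loci: list[Locus]
    freqs: list[np.ndarray]

    def __post_init__(self) -> None:
        if len(self.loci) != len(self.freqs):
            raise ValueError("loci and freqs differ in length")
        for locus, f in zip(self.loci, self.freqs):
            f = np.asarray(f, dtype=float)
            if f.shape[0] != locus.num_alleles:
                raise ValueError(f"frequency vector length mismatch at {locus.id!r}")
            if np.any(f < 0) or abs(f.sum() - 1.0) > 1e-12:
                raise ValueError(f"invalid frequency vector at {locus.id!r}")

    @property
    def n_loci(self) -> int:
        return len(self.loci)


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed),
                                                        spawn_key=tuple(key)))


def generate_frequencies(config: SyntheticPanelConfig) -> FrequencyPanel:
    """Draw per-locus allele frequencies from a symmetric Dirichlet.

    Allele labels are synthetic consecutive repeat lengths starting at 5,
    carried as metadata only.
    """
    rng = _rng(config.seed, 0)
    lo, hi = config.allele_range
    loci = []
    freqs = []
    for l in range(config.n_loci):
        n_alleles = int(rng.integers(lo, hi + 1))
        f = rng.dirichlet(np.full(n_alleles, config.frequency_concentration))
        f = f / f.sum()
        loci.append(Locus(id=f"STR{l + 1:02d}",
                          alleles=tuple(range(5, 5 + n_alleles))))
        freqs.append(f)
    return FrequencyPanel(loci=loci, freqs=freqs)


def generate_true_profiles(panel: FrequencyPanel, n_individuals: int,
                           seed: int) -> list[GenotypeProfile]:
    """Sample diploid genotypes under Hardy-Weinberg and linkage equilibrium.

    Each haplotype allele is drawn independently from its locus frequency
    vector; loci are independent.
    """
    if n_individuals < 2:
        raise ValueError("n_individuals must be >= 2")
    rng = _rng(seed, 1)
    width = len(str(n_individuals))
    G = np.empty((n_individuals, panel.n_loci, 2), dtype=np.int64)
    for l, f in enumerate(panel.freqs):
        G[:, l, :] = rng.choice(f.shape[0], size=(n_individuals, 2), p=f)
    return [
        GenotypeProfile(individual_id=f"ind{i + 1:0{width}d}", genotypes=G[i])
        for i in range(n_individuals)
    ]


def generate_posteriors(true_profiles: Sequence[GenotypeProfile],
                        panel: FrequencyPanel,
                        accuracy: float,
                        posterior_concentration: float,
                        seed: int) -> list[AlleleProbabilityProfile]:
    """Synthesize imputation posteriors around the true genotypes.

    For every individual, locus and haplotype the posterior is
    ``accuracy * pointmass(true allele) + (1 - accuracy) * q`` with
    ``q ~ Dirichlet(posterior_concentration * f)`` centered on the locus
    frequencies.  ``accuracy=1`` reproduces the truth exactly; ``accuracy=0``
    yields posteriors carrying no information about the truth.
    """
    if not 0.0 <= accuracy <= 1.0:
        raise ValueError("accuracy must be in [0, 1]")
    if posterior_concentration <= 0:
        raise ValueError("posterior_concentration must be positive")
    rng = _rng(seed, 2)
    out = []
    alphas = [np.clip(posterior_concentration * f, _ALPHA_FLOOR, None)
              for f in panel.freqs]
    for pr in true_profiles:
        loci_probs = []
        for l, locus in enumerate(panel.loci):
            n_alleles = locus.num_alleles
            vecs = []
            for h in range(2):
                t = pr.genotypes[l, h]
                if accuracy == 1.0:
                    v = np.zeros(n_alleles)
                    v[t] = 1.0
                else:
                    q = rng.dirichlet(alphas[l])
                    v = (1.0 - accuracy) * q
                    v[t] += accuracy
                    v = v / v.sum()
                vecs.append(v)
            loci_probs.append(
                LocusAlleleProbabilities(locus_id=locus.id,
                                         a1=vecs[0], a2=vecs[1])
            )
        out.append(AlleleProbabilityProfile(individual_id=pr.individual_id,
                                            loci_probs=loci_probs))
    return out


def generate_panel(config: SyntheticPanelConfig):
    """Generate frequencies, true profiles and posteriors in one call.

    Returns ``(panel, true_profiles, posterior_profiles)``, all determined by
    ``config.seed``.
    """
    panel = generate_frequencies(config)
    profiles = generate_true_profiles(panel, config.n_individuals, config.seed)
    posteriors = generate_posteriors(profiles, panel, config.accuracy,
                                     config.posterior_concentration, config.seed)
    return panel, profiles, posteriors
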