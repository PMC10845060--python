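"""Readers and writers for the formats the pipeline touches.

Two VCF dialects are supported:

* phased genotype VCF — per-sample ``GT`` fields; REF plus ALT alleles define
  each locus's allele list and allele indices are the GT indices (REF = 0);
* allele-probability VCF — per-sample ``AP1``/``AP2`` FORMAT fields holding
  the probability of each ALT allele on haplotypes 1 and 2 (the dialect an
  imputation engine emits with allele-probability output enabled); the REF
  probability is the complement ``1 - sum(AP)``.

STR alleles appear in VCF as distinct ALT sequences.  The package keys
alleles by GT index, never by sequence content; the original allele labels
are carried through a custom ``ALLELES`` INFO key when files are written by
this package.  A simple tabular profile format (one row per individual, one
column per locus, cells ``a1|a2`` in allele labels) and the TSV outputs of
the search pipeline are also handled here.

Reading uses cyvcf2; writing emits uncompressed VCF text.  Parsers are
strict: a missing genotype or a malformed probability vector raises with the
sample and locus named, rather than being silently skipped.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .matchprob import AlleleProbabilityProfile, LocusAlleleProbabilities
from .profiles import GenotypeProfile, Locus
from .search import SearchResult

__all__ = [
    "read_vcf_genotypes",
    "write_vcf_genotypes",
    "read_vcf_allele_probabilities",
    "write_vcf_allele_probabilities",
    "read_profiles_table",
    "write_profiles_table",
    "write_pair_table",
    "write_summary",
    "write_concordance",
]

#: Tolerance on AP round-off: negative REF remainders no worse than this are
#: clamped to zero and the vector renormalized; larger violations raise.
AP_TOL = 1e-6

_PAIR_COLUMNS = ["replicate", "id_a", "id_b", "scheme", "k", "m", "p"]


def _allele_sequence(index: int) -> str:
    # Synthetic placeholder sequences: distinct, valid bases, keyed by index.
    return "A" + "T" * index


def _vcf_header(loci_count: int, sample_ids: Sequence[str], ap: bool) -> str:
    lines = [
        "##fileformat=VCFv4.2",
        "##source=azsearch",
        "##contig=<ID=1>",
        '##INFO=<ID=ALLELES,Number=.,Type=String,Description="Allele labels in REF+ALT order">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    if ap:
        lines += [
            '##FORMAT=<ID=AP1,Number=A,Type=Float,Description="ALT allele probabilities on haplotype 1">',
            '##FORMAT=<ID=AP2,Number=A,Type=Float,Description="ALT allele probabilities on haplotype 2">',
        ]
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(sample_ids))
    return "\n".join(lines) + "\n"


def _record_fixed(l: int, locus: Locus) -> list[str]:
    n = locus.num_alleles
    ref = _allele_sequence(0)
    alt = ",".join(_allele_sequence(i) for i in range(1, n)) if n > 1 else "."
    info = "ALLELES=" + ",".join(str(a) for a in locus.alleles)
    return ["1", str(1000 * (l + 1)), locus.id, ref, alt, ".", ".", info]


def write_vcf_genotypes(path, loci: Sequence[Locus],
                        profiles: Sequence[GenotypeProfile]) -> None:
    """Write phased genotype profiles as an uncompressed VCF (one record per locus)."""
    path = Path(path)
    sample_ids = [pr.individual_id for pr in profiles]
    with path.open("w") as fh:
        fh.write(_vcf_header(len(loci), sample_ids, ap=False))
        for l, locus in enumerate(loci):
            fields = _record_fixed(l, locus) + ["GT"]
            for pr in profiles:
                a, b = pr.genotypes[l]
                fields.append(f"{a}|{b}")
            fh.write("\t".join(fields) + "\n")


def read_vcf_genotypes(path, strict_phase: bool = True
                       ) -> tuple[list[Locus], list[GenotypeProfile]]:
    """Read phased genotype profiles from a VCF.

    Each record's REF+ALT alleles define the locus allele list (labels from
    the ``ALLELES`` INFO key when present, otherwise the sequences
    themselves); genotype values are the GT indices.  A missing call raises.
    Unphased calls raise when ``strict_phase`` is true and warn otherwise —
    matching itself ignores phase.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    loci: list[Locus] = []
    columns: list[np.ndarray] = []
    for variant in vcf:
        alleles = [variant.REF] + list(variant.ALT)
        labels = variant.INFO.get("ALLELES")
        if labels is not None:
            labels = tuple(str(labels).split(","))
            if len(labels) != len(alleles):
                raise ValueError(
                    f"record {variant.ID}: ALLELES has {len(labels)} labels "
                    f"for {len(alleles)} alleles"
                )
        else:
            labels = tuple(alleles)
        locus = Locus(id=variant.ID or f"{variant.CHROM}:{variant.POS}",
                      alleles=labels)
        gts = variant.genotypes  # per sample: [a, b, phased]
        col = np.empty((len(samples), 2), dtype=np.int64)
        for s, gt in enumerate(gts):
            a, b = int(gt[0]), int(gt[1])
            if a < 0 or b < 0:
                raise ValueError(
                    f"missing genotype for sample {samples[s]!r} at locus "
                    f"{locus.id!r}"
                )
            if not gt[2]:
                msg = (f"unphased genotype for sample {samples[s]!r} at locus "
                       f"{locus.id!r}")
                if strict_phase:
                    raise ValueError(msg)
                warnings.warn(msg + " (matching ignores phase)")
            if max(a, b) >= locus.num_alleles:
                raise ValueError(
                    f"allele index out of range for sample {samples[s]!r} at "
                    f"locus {locus.id!r}"
                )
            col[s] = (a, b)
        loci.append(locus)
        columns.append(col)
    if not loci:
        raise ValueError(f"no records in {path}")
    G = np.stack(columns, axis=1)  # (n_samples, L, 2)
    profiles = [GenotypeProfile(individual_id=sid, genotypes=G[s])
                for s, sid in enumerate(samples)]
    return loci, profiles


def _format_ap(vec: np.ndarray) -> tuple[str, str]:
    """Render one haplotype vector as (GT allele index, AP string).

    ALT probabilities are written in integer micro-units (6 decimals).  If
    rounding pushes the ALT sum above 1, the excess is removed from the
    largest entry so the implied REF remainder can never go below zero by
    more than genuine input error.
    """
    units = np.rint(vec[1:] * 1_000_000).astype(np.int64)
    excess = units.sum() - 1_000_000
    if excess > 0:
        units[np.argmax(units)] -= excess
    ap = ",".join(f"{u / 1_000_000:.6f}" for u in units) if units.size else "."
    return str(int(np.argmax(vec))), ap


def write_vcf_allele_probabilities(
        path, loci: Sequence[Locus],
        prob_profiles: Sequence[AlleleProbabilityProfile]) -> None:
    """Write per-haplotype allele probabilities as a VCF with AP1/AP2 fields.

    The GT field holds the argmax-called genotype, as imputation engines
    emit alongside their allele probabilities.
    """
    path = Path(path)
    sample_ids = [pp.individual_id for pp in prob_profiles]
    with path.open("w") as fh:
        fh.write(_vcf_header(len(loci), sample_ids, ap=True))
        for l, locus in enumerate(loci):
            fields = _record_fixed(l, locus) + ["GT:AP1:AP2"]
            for pp in prob_profiles:
                lp = pp[l]
                g1, ap1 = _format_ap(lp.a1)
                g2, ap2 = _format_ap(lp.a2)
                fields.append(f"{g1}|{g2}:{ap1}:{ap2}")
            fh.write("\t".join(fields) + "\n")


def read_vcf_allele_probabilities(path, tol: float = AP_TOL
                                  ) -> tuple[list[Locus],
                                             list[AlleleProbabilityProfile]]:
    """Read per-haplotype allele-probability vectors from AP1/AP2 FORMAT fields.

    Each haplotype vector is reconstructed as ``[1 - sum(AP), AP_1, ...,
    AP_{N-1}]`` over REF+ALT alleles.  Negative REF remainders within ``tol``
    (format round-off) are clamped to zero and the vector renormalized;
    larger violations raise.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    loci: list[Locus] = []
    per_locus_vectors: list[list[tuple[np.ndarray, np.ndarray]]] = []
    for variant in vcf:
        alleles = [variant.REF] + list(variant.ALT)
        n_alleles = len(alleles)
        labels = variant.INFO.get("ALLELES")
        labels = (tuple(str(labels).split(",")) if labels is not None
                  else tuple(alleles))
        locus = Locus(id=variant.ID or f"{variant.CHROM}:{variant.POS}",
                      alleles=labels)
        haps = []
        for key in ("AP1", "AP2"):
            ap = variant.format(key)
            if ap is None:
                raise ValueError(f"record {locus.id!r} lacks FORMAT field {key}")
            ap = np.asarray(ap, dtype=np.float64)
            if ap.shape != (len(samples), n_alleles - 1):
                raise ValueError(
                    f"record {locus.id!r}: {key} has shape {ap.shape}, "
                    f"expected ({len(samples)}, {n_alleles - 1})"
                )
            haps.append(ap)
        locus_vectors = []
        for s, sid in enumerate(samples):
            pair = []
            for h, ap in enumerate(haps):
                v = ap[s]
                if np.any(np.isnan(v)):
                    raise ValueError(
                        f"missing AP{h + 1} for sample {sid!r} at locus "
                        f"{locus.id!r}"
                    )
                if np.any(v < -tol) or np.any(v > 1.0 + tol):
                    raise ValueError(
                        f"AP{h + 1} probability outside [0, 1] for sample "
                        f"{sid!r} at locus {locus.id!r}"
                    )
                ref = 1.0 - v.sum()
                if ref < -tol:
                    raise ValueError(
                        f"AP{h + 1} probabilities sum to {v.sum()} > 1 for "
                        f"sample {sid!r} at locus {locus.id!r}"
                    )
                full = np.concatenate(([max(ref, 0.0)], np.clip(v, 0.0, None)))
                full = full / full.sum()
                pair.append(full)
            locus_vectors.append((pair[0], pair[1]))
        loci.append(locus)
        per_locus_vectors.append(locus_vectors)
    if not loci:
        raise ValueError(f"no records in {path}")
    profiles = []
    for s, sid in enumerate(samples):
        loci_probs = [
            LocusAlleleProbabilities(locus_id=loci[l].id,
                                     a1=per_locus_vectors[l][s][0],
                                     a2=per_locus_vectors[l][s][1])
            for l in range(len(loci))
        ]
        profiles.append(AlleleProbabilityProfile(individual_id=sid,
                                                 loci_probs=loci_probs))
    return loci, profiles


def write_profiles_table(path, loci: Sequence[Locus],
                         profiles: Sequence[GenotypeProfile]) -> None:
    """Write profiles in the tabular format: rows = individuals, cells = ``a1|a2`` labels."""
    data = {}
    for l, locus in enumerate(loci):
        data[locus.id] = [
            f"{locus.alleles[pr.genotypes[l, 0]]}|{locus.alleles[pr.genotypes[l, 1]]}"
            for pr in profiles
        ]
    df = pd.DataFrame(data, index=[pr.individual_id for pr in profiles])
    df.index.name = "individual_id"
    df.to_csv(path, sep="\t")


def read_profiles_table(path, loci: Sequence[Locus] | None = None
                        ) -> tuple[list[Locus], list[GenotypeProfile]]:
    """Read the tabular profile format back into loci and profiles.

    When ``loci`` is given, cell labels are mapped against it (string
    comparison on labels); otherwise locus definitions are inferred with
    alleles sorted by label.
    """
    df = pd.read_csv(path, sep="\t", index_col="individual_id", dtype=str)
    if loci is None:
        loci = []
        for col in df.columns:
            labels = set()
            for cell in df[col]:
                a, b = str(cell).split("|")
                labels.update((a, b))
            try:
                ordered = tuple(sorted(labels, key=float))
            except ValueError:
                ordered = tuple(sorted(labels))
            loci.append(Locus(id=col, alleles=ordered))
    else:
        loci = list(loci)
        if list(df.columns) != [lc.id for lc in loci]:
            raise ValueError("table columns do not match the panel locus list")
    index_of = [
        {str(label): i for i, label in enumerate(locus.alleles)}
        for locus in loci
    ]
    profiles = []
    for sid, row in df.iterrows():
        g = np.empty((len(loci), 2), dtype=np.int64)
        for l, locus in enumerate(loci):
            a, b = str(row[locus.id]).split("|")
            try:
                g[l] = (index_of[l][a], index_of[l][b])
            except KeyError as err:
                raise ValueError(
                    f"unknown allele label {err.args[0]!r} for sample "
                    f"{sid!r} at locus {locus.id!r}"
                ) from None
        profiles.append(GenotypeProfile(individual_id=str(sid), genotypes=g))
    return loci, profiles


def write_pair_table(results: Sequence[SearchResult], path) -> None:
    """Write per-pair records as TSV in canonical pair order.

    Expected-scheme values are rendered with fixed 6-decimal formatting so
    files are byte-stable across re-runs.
    """
    results = list(results)
    if not results:
        pd.DataFrame(columns=_PAIR_COLUMNS).to_csv(path, sep="\t", index=False)
        return
    df = pd.concat([r.to_frame() for r in results], ignore_index=True)
    df = df[_PAIR_COLUMNS]
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_pair_table(path) -> pd.DataFrame:
    """Read a per-pair TSV back into a DataFrame."""
    return pd.read_csv(path, sep="\t")


def write_summary(summary: pd.DataFrame, path) -> None:
    """Write the pooled median/maximum summary table as TSV."""
    summary.to_csv(path, sep="\t", float_format="%.6f")


def write_concordance(table: pd.DataFrame, path) -> None:
    """Write a concordance (or per-replicate HL) table as TSV."""
    table.to_csv(path, sep="\t", index=False, float_format="%.6f")
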