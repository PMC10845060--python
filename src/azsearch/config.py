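"""Run configuration for the end-to-end pipeline.

Configs are TOML.  Every run writes a resolved copy of its configuration
(JSON, deterministic key order) next to its outputs for provenance.  A
``[provenance]`` table is carried through untouched — it is the place to
archive upstream tool settings (e.g. the imputation engine's parameters)
that this package documents but never executes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from .search import SCHEMES

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Resolved settings for one end-to-end run."""

    # data
    source: str = "synthetic"            # "synthetic" or "vcf"
    genotypes_path: str | None = None    # required when source == "vcf"
    posteriors_path: str | None = None
    # synthetic panel
    n_individuals: int = 2504
    n_loci: int = 18
    alleles_min: int = 6
    alleles_max: int = 14
    frequency_concentration: float = 1.0
    accuracy: float = 0.9
    posterior_concentration: float = 20.0
    # search
    reference_fraction: float = 0.6
    n_replicates: int = 100
    base_seed: int = 0
    schemes: tuple = SCHEMES
    # Hodges-Lehmann strategy
    hl_max_exact_pairs: int = 50_000_000
    hl_n_subsample: int = 10_000_000
    # output
    output_dir: str = "results"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.source not in ("synthetic", "vcf"):
            raise ValueError(f"unknown data source {self.source!r}")
        if self.source == "vcf" and self.genotypes_path is None \
                and self.posteriors_path is None:
            raise ValueError("source 'vcf' requires genotypes and/or posteriors paths")
        self.schemes = tuple(self.schemes)
        for s in self.schemes:
            if s not in SCHEMES:
                raise ValueError(f"unknown scheme {s!r}")
        if not 0.0 < self.reference_fraction < 1.0:
            raise ValueError("reference_fraction must be in (0, 1)")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        data = raw.get("data", {})
        sim = raw.get("simulate", {})
        search = raw.get("search", {})
        hl = raw.get("hl", {})
        output = raw.get("output", {})
        kwargs = {}
        for key, src, name in [
            ("source", data, "source"),
            ("genotypes_path", data, "genotypes"),
            ("posteriors_path", data, "posteriors"),
            ("n_individuals", sim, "n_individuals"),
            ("n_loci", sim, "n_loci"),
            ("alleles_min", sim, "alleles_min"),
            ("alleles_max", sim, "alleles_max"),
            ("frequency_concentration", sim, "frequency_concentration"),
            ("accuracy", sim, "accuracy"),
            ("posterior_concentration", sim, "posterior_concentration"),
            ("reference_fraction", search, "reference_fraction"),
            ("n_replicates", search, "n_replicates"),
            ("base_seed", search, "base_seed"),
            ("schemes", search, "schemes"),
            ("hl_max_exact_pairs", hl, "max_exact_pairs"),
            ("hl_n_subsample", hl, "n_subsample"),
            ("output_dir", output, "directory"),
        ]:
            if name in src:
                kwargs[key] = src[name]
        kwargs["provenance"] = raw.get("provenance", {})
        return cls(**kwargs)

    def resolved(self) -> dict:
        d = dataclasses.asdict(self)
        d["schemes"] = list(self.schemes)
        return d

    def digest(self) -> str:
        """Short stable hash of the resolved configuration, for logging."""
        blob = json.dumps(self.resolved(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def write_resolved(self, path) -> None:
        Path(path).write_text(
            json.dumps(self.resolved(), sort_keys=True, indent=2) + "\n"
        )
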