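"""Simulation and pipeline configuration objects."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any

import numpy as np


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic cohort generator.

    Defaults emulate the discovery-cohort conditions: 12 tumors split
    evenly into two immunologic subtypes, a 35-marker panel with 15 gated
    phenotypes, a strongly separated microenvironment (``activation_shift``
    in within-phenotype SD units), a shared missense-mutation catalog with
    partial mass-spectrometric detection, a planted 137-gene dual-level
    signature, and survival linked to subtype with hazard ratio 1.74.
    """

    n_samples: int = 12
    subtype_fraction: float = 0.5
    n_phenotypes: int = 15
    n_markers: int = 35
    cells_per_sample: int = 600
    dirichlet_concentration: float = 5.0
    activation_shift: float = 3.0
    n_genes: int = 2000
    n_signature_genes: int = 137
    signature_effect: float = 3.0
    mrna_protein_corr: float = 0.6
    n_mutations_per_patient: int = 40
    detect_prob: float = 0.5
    abundance_shift: float = 2.0
    hazard_ratio: float = 1.74
    response_prob_good: float = 0.8
    response_prob_bad: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_samples": self.n_samples,
            "n_phenotypes": self.n_phenotypes,
            "n_markers": self.n_markers,
            "cells_per_sample": self.cells_per_sample,
            "n_genes": self.n_genes,
            "n_signature_genes": self.n_signature_genes,
            "n_mutations_per_patient": self.n_mutations_per_patient,
        }
        for name, value in counts.items():
            if int(value) != value or value < 1:
                raise ValueError(f"{name} must be an integer >= 1, got {value!r}")
        probs = {
            "subtype_fraction": self.subtype_fraction,
            "detect_prob": self.detect_prob,
            "response_prob_good": self.response_prob_good,
            "response_prob_bad": self.response_prob_bad,
        }
        for name, value in probs.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value!r}")
        if self.dirichlet_concentration <= 0:
            raise ValueError("dirichlet_concentration must be positive")
        if self.hazard_ratio <= 0:
            raise ValueError("hazard_ratio must be positive")
        if not -1.0 <= self.mrna_protein_corr <= 1.0:
            raise ValueError("mrna_protein_corr must lie in [-1, 1]")
        if self.n_signature_genes >= self.n_genes:
            raise ValueError("n_signature_genes must be < n_genes")
        if int(self.seed) != self.seed:
            raise ValueError("seed must be an integer")

    def rng(self, *stream: Any) -> np.random.Generator:
        """Independent generator for a named substream of this config's seed.

        The substream key is hashed content-wise, so the draw for one
        sample/stage never depends on the order other streams are consumed.
        """
        entropy = [self.seed] + [
            int.from_bytes(str(part).encode(), "little") % (2**63) for part in stream
        ]
        return np.random.default_rng(np.random.SeedSequence(entropy))

    def replace(self, **kwargs: Any) -> "SimConfig":
        params = asdict(self)
        params.update(kwargs)
        return SimConfig(**params)

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)


@dataclass
class PipelineConfig:
    """End-to-end pipeline configuration (stage toggles and parameters)."""

    out_dir: str = "timeatlas_run"
    sim: SimConfig = field(default_factory=SimConfig)
    stages: tuple[str, ...] = (
        "simulate", "subtype", "neoantigen", "signature", "outcomes",
    )
    k_clusters: int = 50
    cofactor: float = 5.0
    downsample_fraction: float = 0.5
    tier_mode: str = "potential"
    p_threshold: float = 0.05
    screen_p: float = 0.2
    z_cutoff: float = 1.96

    VALID_STAGES = ("simulate", "subtype", "neoantigen", "signature", "outcomes")

    def __post_init__(self) -> None:
        if isinstance(self.sim, dict):
            self.sim = SimConfig(**self.sim)
        bad = [s for s in self.stages if s not in self.VALID_STAGES]
        if bad:
            raise ValueError(f"unknown stages {bad}; valid: {self.VALID_STAGES}")
        if self.tier_mode not in ("potential", "high"):
            raise ValueError("tier_mode must be 'potential' or 'high'")
        if self.cofactor <= 0:
            raise ValueError("cofactor must be positive")
        if self.k_clusters < 2:
            raise ValueError("k_clusters must be >= 2")

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "PipelineConfig":
        data = dict(data)
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        return cls(**data)

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["stages"] = list(self.stages)
        return d
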