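"""Pluggable MHC binding percentile-rank predictors.

A predictor maps (peptide, allele) to an IEDB-style percentile rank in
(0, 100], lower meaning stronger predicted binding.  Real predictors (e.g.
IEDB consensus or NetMHCpan) plug in behind this interface; the built-in
:class:`HashRankPredictor` is a deterministic stand-in for fully
reproducible, network-free runs.
"""

from __future__ import annotations

import hashlib
from typing import Mapping, Protocol, runtime_checkable


@runtime_checkable
class RankPredictor(Protocol):
    def rank(self, peptide: str, allele: str) -> float:
        """Percentile rank in (0, 100] for a peptide-allele pair."""
        ...


class PredictorError(RuntimeError):
    """Raised when a predictor fails on a peptide; names the peptide."""


def _hash_unit(peptide: str, allele: str) -> float:
    digest = hashlib.sha256(f"{peptide}|{allele}".encode()).digest()
    return int.from_bytes(digest[:8], "big") / 2**64


class HashRankPredictor:
    """Deterministic toy percentile-rank predictor.

    Background pairs hash to a rank in (10.2, 100] — above every binder
    threshold, so unplanted pairs never register as binders.  Known true
    binders are served from an override table (rank <= 1 for class I
    binders, <= 5 for class II, as planted by the synthetic generator).
    """

    #: Lower edge of the background rank window; strictly above the most
    #: permissive (class II potential-binder, 10%) threshold.
    BACKGROUND_FLOOR = 10.2

    def __init__(self, planted: Mapping[tuple[str, str], float] | None = None) -> None:
        self.planted = dict(planted or {})
        for (pep, allele), rank in self.planted.items():
            if not 0.0 < rank <= 100.0:
                raise ValueError(
                    f"planted rank for ({pep}, {allele}) must lie in (0, 100]"
                )

    def rank(self, peptide: str, allele: str) -> float:
        if not peptide:
            raise PredictorError("empty peptide")
        key = (peptide, allele)
        if key in self.planted:
            return self.planted[key]
        u = _hash_unit(peptide, allele)
        return self.BACKGROUND_FLOOR + (100.0 - self.BACKGROUND_FLOOR) * u + 1e-12


class TableRankPredictor:
    """Predictor backed by a precomputed (peptide, allele) -> rank table."""

    def __init__(self, table: Mapping[tuple[str, str], float]) -> None:
        self.table = dict(table)

    def rank(self, peptide: str, allele: str) -> float:
        try:
            return self.table[(peptide, allele)]
        except KeyError:
            raise PredictorError(
                f"no rank available for peptide {peptide!r} on allele {allele!r}"
            ) from None
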