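"""Mass-spectrometry neoantigen identification and quantification.

Builds a missense-mutation reference database, derives 29-residue mutant
peptide windows, enumerates MHC-I (8-14mer) and MHC-II (15mer) candidate
peptides containing the mutated residue, tiers them against a patient's
typed HLA alleles by the nested mutant-vs-wild-type percentile-rank rules
(class I: potential iff mutant <= 2% and WT > 2%, high iff additionally
mutant <= 1% and WT > 1%; class II: 10%/5%), quantifies detected peptide
peaks by chromatographic AUC with fraction-of-total (iFOT) normalization,
and relates neoantigen abundance to the expression of the corresponding
MHC proteins.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .predictors import PredictorError, RankPredictor

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Candidate peptide lengths by MHC class.
CLASS_I_LENGTHS = tuple(range(8, 15))
CLASS_II_LENGTHS = (15,)

#: Percentile-rank thresholds (potential, high) by MHC class.
TIER_THRESHOLDS = {"I": (2.0, 1.0), "II": (10.0, 5.0)}

CLASS_I_LOCI = ("HLA-A", "HLA-B", "HLA-C")
CLASS_II_LOCI = (
    "HLA-DRB1", "HLA-DRB3", "HLA-DRB4", "HLA-DRB5",
    "HLA-DQA1", "HLA-DQB1", "HLA-DPA1", "HLA-DPB1",
)

TIERS = ("non_binder", "intermediate", "high")
TIER_ORDER = {t: i for i, t in enumerate(TIERS)}

#: Default half-window so the point mutation sits at the middle of a
#: 29-residue sequence.
WINDOW_FLANK = 14

IFOT_SCALE = 1e5

_CHANGE_RE = re.compile(r"^p\.([A-Z])(\d+)([A-Z])$")
_ALLELE_RE = re.compile(r"^(HLA-[A-Z]+\d*)\*\d{2,3}:\d{2,3}$")


@dataclass(frozen=True)
class MutationRecord:
    """One missense mutation site: gene, protein accession, 1-based residue
    position, and the wild-type -> mutant substitution."""

    gene: str
    accession: str
    position: int
    wt_aa: str
    mut_aa: str
    sources: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("position must be >= 1")
        if self.wt_aa == self.mut_aa:
            raise ValueError("synonymous change is not a missense mutation")
        for aa in (self.wt_aa, self.mut_aa):
            if aa not in AMINO_ACIDS:
                raise ValueError(f"{aa!r} is not a standard amino acid")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.accession, self.position, self.wt_aa, self.mut_aa)

    @property
    def label(self) -> str:
        return f"{self.gene}_{self.wt_aa}{self.position}{self.mut_aa}"


@dataclass(frozen=True)
class PeptideWindow:
    """Mutant peptide window (<= 29 residues) around one mutation."""

    sequence: str
    mutation_offset: int  # 1-based index of the mutated residue in sequence
    mutation: MutationRecord

    def __post_init__(self) -> None:
        if not 1 <= self.mutation_offset <= len(self.sequence):
            raise ValueError("mutation_offset outside window")
        if self.sequence[self.mutation_offset - 1] != self.mutation.mut_aa:
            raise ValueError("window sequence does not carry the mutant residue")
        if len(self.sequence) > 2 * WINDOW_FLANK + 1:
            raise ValueError("window longer than 29 residues")


@dataclass(frozen=True)
class CandidatePeptide:
    """A candidate neoepitope: a mutation-containing sub-peptide."""

    sequence: str
    mhc_class: str
    mutation_index: int  # 1-based position of the mutated residue

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class HlaType:
    """A patient's typed HLA alleles across the 11 loci."""

    patient_id: str
    alleles: tuple[str, ...]

    def __post_init__(self) -> None:
        per_locus: dict[str, int] = {}
        for allele in self.alleles:
            locus = allele_locus(allele)
            per_locus[locus] = per_locus.get(locus, 0) + 1
            if per_locus[locus] > 2:
                raise ValueError(f"more than 2 alleles typed at {locus}")

    def class_alleles(self, mhc_class: str) -> tuple[str, ...]:
        loci = CLASS_I_LOCI if mhc_class == "I" else CLASS_II_LOCI
        return tuple(a for a in self.alleles if allele_locus(a) in loci)


def allele_locus(allele: str) -> str:
    """Locus of a 2-field HLA allele name, e.g. HLA-B*18:01 -> HLA-B."""
    m = _ALLELE_RE.match(allele)
    if not m:
        raise ValueError(f"allele {allele!r} is not in 2-field HLA nomenclature")
    return m.group(1)


def parse_protein_change(change: str) -> tuple[str, int, str]:
    """Parse a protein-change string like ``p.N645K`` into (wt, pos, mut)."""
    m = _CHANGE_RE.match(change.strip())
    if not m:
        raise ValueError(f"malformed protein change {change!r}")
    wt, pos, mut = m.group(1), int(m.group(2)), m.group(3)
    if wt not in AMINO_ACIDS or mut not in AMINO_ACIDS:
        raise ValueError(f"non-standard residue in {change!r}")
    return wt, pos, mut


def build_mutation_db(sources: Iterable[pd.DataFrame]) -> list[MutationRecord]:
    """Union missense-mutation catalogs into a deduplicated reference DB.

    Each source table needs columns ``gene, accession, protein_change,
    source``.  Rows with the same (accession, position, substitution)
    collapse into one record keeping all source tags; synonymous or
    malformed protein-change rows are dropped and counted in the log.
    """
    merged: dict[tuple, MutationRecord] = {}
    dropped = 0
    for table in sources:
        for row in table.itertuples(index=False):
            try:
                wt, pos, mut = parse_protein_change(str(row.protein_change))
                rec = MutationRecord(
                    gene=str(row.gene), accession=str(row.accession),
                    position=pos, wt_aa=wt, mut_aa=mut,
                    sources=(str(row.source),),
                )
            except ValueError as exc:
                dropped += 1
                logger.debug("dropped mutation row %r: %s", tuple(row), exc)
                continue
            if rec.key in merged:
                old = merged[rec.key]
                tags = tuple(dict.fromkeys(old.sources + rec.sources))
                merged[rec.key] = MutationRecord(
                    gene=old.gene, accession=old.accession, position=old.position,
                    wt_aa=old.wt_aa, mut_aa=old.mut_aa, sources=tags,
                )
            else:
                merged[rec.key] = rec
    if dropped:
        logger.info("build_mutation_db: dropped %d non-missense/malformed rows", dropped)
    return list(merged.values())


def make_peptide_window(
    protein: str, mutation: MutationRecord, flank: int = WINDOW_FLANK
) -> PeptideWindow:
    """Mutant window of up to 2*flank+1 residues centered on the mutation,
    truncated at protein termini.  Raises on reference mismatch."""
    pos = mutation.position
    if pos > len(protein):
        raise ValueError(
            f"reference inconsistency: position {pos} beyond protein of "
            f"length {len(protein)}"
        )
    if protein[pos - 1] != mutation.wt_aa:
        raise ValueError(
            f"reference inconsistency: {mutation.accession} position {pos} is "
            f"{protein[pos - 1]}, expected {mutation.wt_aa}"
        )
    start = max(1, pos - flank)
    end = min(len(protein), pos + flank)
    segment = protein[start - 1 : end]
    offset = pos - start + 1
    mutant = segment[: offset - 1] + mutation.mut_aa + segment[offset:]
    return PeptideWindow(sequence=mutant, mutation_offset=offset, mutation=mutation)


def candidate_lengths(mhc_class: str) -> tuple[int, ...]:
    if mhc_class == "I":
        return CLASS_I_LENGTHS
    if mhc_class == "II":
        return CLASS_II_LENGTHS
    raise ValueError("mhc_class must be 'I' or 'II'")


def enumerate_candidates(
    window: PeptideWindow | None = None,
    mhc_class: str = "I",
    *,
    sequence: str | None = None,
    mutation_offset: int | None = None,
) -> list[CandidatePeptide]:
    """All allowed-length sub-peptides containing the mutated residue.

    Class I enumerates 8- to 14-mers, class II 15-mers.  Each distinct
    sequence is emitted once.  A window shorter than the minimum length
    yields an empty list with a warning.
    """
    if window is not None:
        sequence, mutation_offset = window.sequence, window.mutation_offset
    if sequence is None or mutation_offset is None:
        raise ValueError("provide a window or sequence + mutation_offset")
    lengths = candidate_lengths(mhc_class)
    if len(sequence) < min(lengths):
        warnings.warn(
            f"window of length {len(sequence)} shorter than the minimum "
            f"{min(lengths)}-mer; no candidates",
            stacklevel=2,
        )
        return []
    seen: dict[str, CandidatePeptide] = {}
    for length in lengths:
        if length > len(sequence):
            continue
        lo = max(1, mutation_offset - length + 1)
        hi = min(len(sequence) - length + 1, mutation_offset)
        for start in range(lo, hi + 1):
            pep = sequence[start - 1 : start - 1 + length]
            if pep not in seen:
                seen[pep] = CandidatePeptide(
                    sequence=pep, mhc_class=mhc_class,
                    mutation_index=mutation_offset - start + 1,
                )
    return list(seen.values())


def wildtype_peptide(candidate: CandidatePeptide, wt_aa: str) -> str:
    """Revert the mutated residue to obtain the WT counterpart peptide."""
    i = candidate.mutation_index - 1
    wt = candidate.sequence[:i] + wt_aa + candidate.sequence[i + 1 :]
    if wt == candidate.sequence:
        raise ValueError("WT counterpart equals the mutant peptide")
    return wt


def predict_ranks(
    candidates: Sequence[CandidatePeptide],
    wt_aa: str,
    alleles: Sequence[str],
    predictor: RankPredictor,
) -> pd.DataFrame:
    """Mutant and WT percentile ranks for every candidate x allele pair."""
    rows = []
    for cand in candidates:
        wt_pep = wildtype_peptide(cand, wt_aa)
        for allele in alleles:
            try:
                mut_rank = float(predictor.rank(cand.sequence, allele))
                wt_rank = float(predictor.rank(wt_pep, allele))
            except Exception as exc:  # noqa: BLE001 - surface the peptide
                raise PredictorError(
                    f"predictor failed on peptide {cand.sequence!r} "
                    f"(allele {allele!r}): {exc}"
                ) from exc
            for name, rank in (("mutant", mut_rank), ("WT", wt_rank)):
                if not 0.0 < rank <= 100.0:
                    raise ValueError(
                        f"{name} rank {rank} for {cand.sequence!r} outside (0, 100]"
                    )
            rows.append(
                {
                    "peptide": cand.sequence,
                    "wt_peptide": wt_pep,
                    "mhc_class": cand.mhc_class,
                    "mutation_index": cand.mutation_index,
                    "allele": allele,
                    "mut_rank": mut_rank,
                    "wt_rank": wt_rank,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "peptide", "wt_peptide", "mhc_class", "mutation_index",
            "allele", "mut_rank", "wt_rank",
        ],
    )


def classify_binder(mut_rank: float, wt_rank: float, mhc_class: str) -> str:
    """Tier a mutant/WT rank pair by the nested binder rules.

    Potential binder iff the mutant rank is at or below the class threshold
    (2% for MHC-I, 10% for MHC-II) while the WT counterpart stays above it;
    within potential binders, high affinity iff the mutant rank is at or
    below the stricter threshold (1% / 5%) with the WT above it; the rest
    are intermediate.  Boundary values follow the <= / > semantics exactly.
    """
    if mhc_class not in TIER_THRESHOLDS:
        raise ValueError("mhc_class must be 'I' or 'II'")
    potential_thr, high_thr = TIER_THRESHOLDS[mhc_class]
    for name, rank in (("mut_rank", mut_rank), ("wt_rank", wt_rank)):
        if not 0.0 < rank <= 100.0:
            raise ValueError(f"{name} {rank} outside (0, 100]")
    if mut_rank <= potential_thr and wt_rank > potential_thr:
        if mut_rank <= high_thr and wt_rank > high_thr:
            return "high"
        return "intermediate"
    return "non_binder"


def quantify_abundance(
    times: Sequence[float], intensities: Sequence[float]
) -> float:
    """Trapezoidal AUC of an extracted-ion chromatogram peak."""
    t = np.asarray(times, dtype=float)
    y = np.asarray(intensities, dtype=float)
    if len(t) < 2:
        raise ValueError("need at least 2 chromatogram points")
    if (y < 0).any():
        raise ValueError("negative intensity in chromatogram")
    if np.any(np.diff(t) < 0):
        warnings.warn("unsorted chromatogram times; sorting", stacklevel=2)
        order = np.argsort(t)
        t, y = t[order], y[order]
    return float(np.trapezoid(y, t))


def ifot_normalize(aucs: pd.Series, scale: float = IFOT_SCALE) -> pd.Series:
    """Fraction-of-total normalization within one sample: auc / sum * 1e5."""
    total = aucs.sum()
    if total <= 0:
        raise ValueError("cannot iFOT-normalize: total AUC is not positive")
    return aucs / total * scale


@dataclass
class NeoantigenCall:
    """A detected mutated peptide tiered as a binder for one patient."""

    mutation: MutationRecord
    peptide: str
    sample_id: str
    mhc_class: str
    tier: str
    alleles: tuple[str, ...]
    auc: float

    def __post_init__(self) -> None:
        if self.tier == "non_binder":
            raise ValueError("a retained call cannot be a non-binder")
        if self.auc < 0:
            raise ValueError("auc must be nonnegative")


def _match_windows(peptide: str, windows: Sequence[PeptideWindow]) -> list[tuple[PeptideWindow, int]]:
    """Windows containing the detected peptide across the mutated residue;
    returns (window, offset of the mutation inside the peptide, 1-based)."""
    hits = []
    for w in windows:
        start = w.sequence.find(peptide)
        while start != -1:
            inner = w.mutation_offset - start  # 1-based within peptide
            if 1 <= inner <= len(peptide):
                hits.append((w, inner))
                break
            start = w.sequence.find(peptide, start + 1)
    return hits


def call_neoantigens(
    patient: HlaType,
    windows: Sequence[PeptideWindow],
    peaks: pd.DataFrame,
    predictor: RankPredictor,
    tier_mode: str = "potential",
    classes: Sequence[str] = ("I", "II"),
) -> list[NeoantigenCall]:
    """Tier each detected mutated peptide against the patient's HLA type.

    ``peaks`` needs columns ``peptide, sample_id, auc`` with sample ids
    equal to the patient id.  A detected peptide becomes a neoantigen call
    for a class iff at least one legal-length sub-peptide containing the
    mutated residue is tiered intermediate or high ("potential" mode; "high"
    mode requires a high tier) on at least one typed allele of that class.
    One call per (mutation, class, sample); if several detected peptides map
    to the same mutation their AUCs are summed so abundance is attributed
    once per mutation.
    """
    if tier_mode not in ("potential", "high"):
        raise ValueError("tier_mode must be 'potential' or 'high'")
    mine = peaks[peaks["sample_id"] == patient.patient_id]
    best: dict[tuple, NeoantigenCall] = {}
    for row in mine.itertuples(index=False):
        matches = _match_windows(str(row.peptide), windows)
        if not matches:
            logger.info(
                "peak %r in sample %s matches no mutation window (unassigned)",
                row.peptide, patient.patient_id,
            )
            continue
        for window, inner in matches:
            mut = window.mutation
            for mhc_class in classes:
                alleles = patient.class_alleles(mhc_class)
                if not alleles:
                    continue
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")  # short peptides are routine here
                    cands = enumerate_candidates(
                        sequence=str(row.peptide), mutation_offset=inner,
                        mhc_class=mhc_class,
                    )
                if not cands:
                    continue
                ranks = predict_ranks(cands, mut.wt_aa, alleles, predictor)
                ranks["tier"] = [
                    classify_binder(r.mut_rank, r.wt_rank, mhc_class)
                    for r in ranks.itertuples(index=False)
                ]
                tiered = ranks[ranks["tier"] != "non_binder"]
                if tiered.empty:
                    continue
                top = max(tiered["tier"], key=TIER_ORDER.get)
                if tier_mode == "high" and top != "high":
                    continue
                support = tuple(sorted(tiered.loc[tiered["tier"] == top, "allele"].unique()))
                key = (mut.key, mhc_class, patient.patient_id)
                if key in best:
                    old = best[key]
                    merged_tier = top if TIER_ORDER[top] > TIER_ORDER[old.tier] else old.tier
                    merged_support = support if merged_tier == top else old.alleles
                    if TIER_ORDER[top] == TIER_ORDER[old.tier]:
                        merged_support = tuple(sorted(set(old.alleles) | set(support)))
                    best[key] = NeoantigenCall(
                        mutation=mut, peptide=old.peptide, sample_id=old.sample_id,
                        mhc_class=mhc_class, tier=merged_tier,
                        alleles=merged_support, auc=old.auc + float(row.auc),
                    )
                else:
                    best[key] = NeoantigenCall(
                        mutation=mut, peptide=str(row.peptide),
                        sample_id=patient.patient_id, mhc_class=mhc_class,
                        tier=top, alleles=support, auc=float(row.auc),
                    )
    return list(best.values())


def calls_to_frame(calls: Sequence[NeoantigenCall]) -> pd.DataFrame:
    rows = [
        {
            "sample_id": c.sample_id,
            "gene": c.mutation.gene,
            "accession": c.mutation.accession,
            "position": c.mutation.position,
            "mutation": c.mutation.label,
            "peptide": c.peptide,
            "mhc_class": c.mhc_class,
            "tier": c.tier,
            "alleles": ";".join(c.alleles),
            "auc": c.auc,
        }
        for c in calls
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id", "gene", "accession", "position", "mutation",
            "peptide", "mhc_class", "tier", "alleles", "auc",
        ],
    )


def average_neoantigen_abundance(calls: pd.DataFrame) -> pd.DataFrame:
    """Per-sample, per-class average neoantigen abundance: the sum of call
    AUCs divided by the number of calls.  Samples with zero calls for a
    class are reported as missing (with a warning)."""
    if calls.empty:
        warnings.warn("no neoantigen calls; average abundance undefined", stacklevel=2)
        return pd.DataFrame(columns=["sample_id", "mhc_class", "n_calls", "mean_auc"])
    out = (
        calls.groupby(["sample_id", "mhc_class"])["auc"]
        .agg(n_calls="count", mean_auc="mean")
        .reset_index()
    )
    return out


def mhc_protein_expression(
    quant: pd.DataFrame, value_col: str = "ifot"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-locus MHC protein expression and per-class totals.

    ``quant`` needs columns ``sample_id, locus`` plus the value column.
    Unknown locus symbols are ignored (logged); absent sample x locus rows
    count as 0.  Class totals sum HLA-A/B/C (MHC-I) and the eight class II
    loci (MHC-II).
    """
    known = set(CLASS_I_LOCI) | set(CLASS_II_LOCI)
    unknown = sorted(set(quant["locus"]) - known)
    if unknown:
        logger.info("ignoring unknown MHC locus symbols: %s", unknown)
    q = quant[quant["locus"].isin(known)]
    wide = (
        q.pivot_table(index="sample_id", columns="locus", values=value_col,
                      aggfunc="sum", fill_value=0.0)
        .reindex(columns=list(CLASS_I_LOCI) + list(CLASS_II_LOCI), fill_value=0.0)
    )
    totals = pd.DataFrame(
        {
            "MHC_I": wide[list(CLASS_I_LOCI)].sum(axis=1),
            "MHC_II": wide[list(CLASS_II_LOCI)].sum(axis=1),
        }
    )
    return wide, totals


@dataclass
class ConcordanceResult:
    """Quadrant analysis of neoantigen abundance vs MHC expression."""

    table: pd.DataFrame  # subtypes x (high_high, other)
    chi2: float
    p: float
    pairs: pd.DataFrame = field(repr=False, default=None)

    @property
    def high_high_proportion(self) -> pd.Series:
        return self.table["high_high"] / self.table.sum(axis=1)


def concordance_analysis(
    calls: pd.DataFrame,
    locus_expression: pd.DataFrame,
    subtypes: pd.Series,
    quantile: float = 0.5,
) -> ConcordanceResult:
    """Relate each call's abundance to its supporting MHC protein level.

    Every (call, supporting locus) pair is classified high/low abundance
    (cohort ``quantile`` split of call AUCs) and high/low MHC expression
    (per-locus cohort split across samples); the 2x2 table of high/high
    pairs versus others between the two subtypes is tested with a Pearson
    chi-square (no continuity correction).
    """
    if calls.empty:
        raise ValueError("no calls to analyze")
    counts = subtypes.value_counts()
    if len(counts) < 2 or (counts < 2).any():
        raise ValueError("concordance analysis needs >= 2 samples per subtype")
    pairs = calls.copy()
    pairs["alleles"] = pairs["alleles"].str.split(";")
    pairs = pairs.explode("alleles").rename(columns={"alleles": "allele"})
    pairs["locus"] = pairs["allele"].map(allele_locus)
    pairs = pairs.drop_duplicates(subset=["sample_id", "mutation", "mhc_class", "locus"])

    abundance_cut = pairs["auc"].quantile(quantile)
    locus_cuts = locus_expression.quantile(quantile, axis=0)
    expr = pairs.apply(
        lambda r: locus_expression.at[r["sample_id"], r["locus"]]
        if r["locus"] in locus_expression.columns and r["sample_id"] in locus_expression.index
        else 0.0,
        axis=1,
    )
    pairs["high_abundance"] = pairs["auc"] > abundance_cut
    pairs["high_expression"] = expr.to_numpy() > pairs["locus"].map(locus_cuts).to_numpy()
    pairs["high_high"] = pairs["high_abundance"] & pairs["high_expression"]
    pairs["subtype"] = pairs["sample_id"].map(subtypes)

    table = (
        pairs.groupby("subtype")["high_high"]
        .agg(high_high="sum", total="count")
        .assign(other=lambda d: d["total"] - d["high_high"])
        [["high_high", "other"]]
    )
    if table.shape[0] < 2:
        raise ValueError("calls cover only one subtype")
    chi2, p, _, _ = stats.chi2_contingency(table.to_numpy(), correction=False)
    return ConcordanceResult(table=table, chi2=float(chi2), p=float(p), pairs=pairs)
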