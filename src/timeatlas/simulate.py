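"""Synthetic cohort generator with planted ground truth.

Generates every input the pipeline consumes — single-cell marker-intensity
tables, a missense-mutation catalog with protein sequences, detected
neopeptide peaks with planted binder ranks, HLA types, paired mRNA/protein
expression with a planted dual-level signature, and clinical outcomes tied
to subtype — so each stage can be scored against known truth.  Two latent
subtypes drive (1) Dirichlet phenotype mixtures with activation-marker
shifts, (2) log-normal neopeptide abundances with a subtype mean shift,
(3) a planted signature differential at both molecular levels, and (4)
proportional-hazards survival plus Bernoulli response.

All distributions here are modeling stand-ins chosen for plausibility at
desk scale; see docs/methods.md for what they do and do not emulate.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import SimConfig
from .cytof import SAMPLE_COL, CellEventTable
from .neoantigen import (
    HlaType,
    MutationRecord,
    PeptideWindow,
    AMINO_ACIDS,
    make_peptide_window,
)
from .phenotypes import (
    ALL_MARKERS,
    DEFAULT_PHENOTYPES,
    LINEAGE_MARKERS,
    SUBTYPE_I_ACTIVATION_PROGRAM,
    SUBTYPE_II_ACTIVATION_PROGRAM,
    SUBTYPE_TILT,
)
from .predictors import HashRankPredictor
from .signature import ExpressionMatrix

#: Template intensity (arcsinh scale) for gated-high / gated-low markers,
#: within-phenotype noise SD, and the mixture-weight tilt per unit of
#: activation shift.
TEMPLATE_HI = 3.5
TEMPLATE_LO = 0.3
ACTIVATION_BASELINE = 1.0
NOISE_SD = 0.4
TILT_SCALE = 0.4

#: Log-normal neopeptide abundance baseline (log scale) and SD.
ABUNDANCE_LOG_MEAN = 9.0
ABUNDANCE_LOG_SD = 1.0

#: Baseline exponential survival: median 24 months in the good subtype;
#: censoring uniform on [0, 72] months.
BASELINE_MEDIAN_MONTHS = 24.0
CENSOR_MAX_MONTHS = 72.0

#: mRECIST split within responders (CR:PR = 3:1) and non-responders
#: (PD:SD = 4:1).
CR_GIVEN_RESPONDER = 0.75
PD_GIVEN_NONRESPONDER = 0.8

_ALLELE_POOLS: dict[str, tuple[str, ...]] = {
    "HLA-A": ("HLA-A*01:01", "HLA-A*02:01", "HLA-A*03:01"),
    "HLA-B": ("HLA-B*18:01", "HLA-B*07:02", "HLA-B*44:02"),
    "HLA-C": ("HLA-C*07:01", "HLA-C*04:01", "HLA-C*05:01"),
    "HLA-DRB1": ("HLA-DRB1*08:01", "HLA-DRB1*13:01", "HLA-DRB1*03:01"),
    "HLA-DQA1": ("HLA-DQA1*01:02", "HLA-DQA1*05:01"),
    "HLA-DQB1": ("HLA-DQB1*06:02", "HLA-DQB1*02:01"),
    "HLA-DPA1": ("HLA-DPA1*01:03", "HLA-DPA1*02:01"),
    "HLA-DPB1": ("HLA-DPB1*04:01", "HLA-DPB1*02:01"),
}
#: Alleles every synthetic patient carries; planted binders target these so
#: ground-truth calls are patient-independent.
_UNIVERSAL_I = "HLA-A*01:01"
_UNIVERSAL_II = "HLA-DRB1*08:01"

PROTEIN_LENGTH = 120

#: Baseline log-iFOT of MHC locus expression; HLA-A/-B and HLA-DRB1 are the
#: predominantly expressed class I / class II proteins.
_MHC_BASELINE_LOG = {
    "HLA-A": 4.0, "HLA-B": 4.0, "HLA-C": 3.0,
    "HLA-DRB1": 4.0, "HLA-DRB3": 2.5, "HLA-DRB4": 2.5, "HLA-DRB5": 2.5,
    "HLA-DQA1": 2.5, "HLA-DQB1": 2.5, "HLA-DPA1": 2.5, "HLA-DPB1": 2.5,
}
_MHC_LOG_SD = 0.5


def sample_ids(config: SimConfig) -> list[str]:
    return [f"MPM{1 + i:03d}" for i in range(config.n_samples)]


def generate_truth_labels(config: SimConfig) -> pd.Series:
    """Latent subtype per sample: round(n * fraction) samples are subtype I,
    assigned in a seed-determined random order."""
    ids = sample_ids(config)
    n_good = int(round(config.n_samples * config.subtype_fraction))
    rng = config.rng("labels")
    order = rng.permutation(config.n_samples)
    labels = np.array(["II"] * config.n_samples, dtype=object)
    labels[order[:n_good]] = "I"
    return pd.Series(labels, index=ids, name="subtype")


def generate_cell_events(
    config: SimConfig, truth_labels: pd.Series | None = None
) -> tuple[CellEventTable, pd.Series]:
    """Per-sample cells drawn from a mixture of phenotype templates.

    Each of the gated phenotypes has a hi/lo marker archetype on the
    arcsinh scale with Gaussian noise.  Subtype tilts the Dirichlet mixture
    weights (immunogenic phenotypes up in subtype I, suppressive ones up in
    subtype II) and shifts subtype-specific activation-marker means by
    ``activation_shift`` noise-SD units.  Values are already on the arcsinh
    scale (``transformed=True``).
    """
    if config.cells_per_sample < config.n_phenotypes:
        raise ValueError("insufficient cells: cells_per_sample < n_phenotypes")
    if config.n_phenotypes > len(DEFAULT_PHENOTYPES):
        raise ValueError(f"at most {len(DEFAULT_PHENOTYPES)} phenotypes are defined")
    markers = list(ALL_MARKERS[: config.n_markers])
    needed = set(LINEAGE_MARKERS)
    if not needed <= set(markers):
        raise ValueError("n_markers too small to cover the lineage panel")
    if truth_labels is None:
        truth_labels = generate_truth_labels(config)

    defs = DEFAULT_PHENOTYPES[: config.n_phenotypes]
    template = np.full((len(defs), len(markers)), TEMPLATE_LO)
    midx = {m: j for j, m in enumerate(markers)}
    for j, m in enumerate(markers):
        if m not in LINEAGE_MARKERS:
            template[:, j] = ACTIVATION_BASELINE
    for i, d in enumerate(defs):
        for m in d.positive:
            template[i, midx[m]] = TEMPLATE_HI
        for m in d.negative:
            template[i, midx[m]] = TEMPLATE_LO

    tilt = np.array([SUBTYPE_TILT.get(d.name, 0) for d in defs], dtype=float)
    frames = []
    for sample in truth_labels.index:
        s = 1.0 if truth_labels[sample] == "I" else -1.0
        rng = config.rng("cells", sample)
        alpha = config.dirichlet_concentration * np.exp(
            TILT_SCALE * config.activation_shift * s * tilt
        )
        weights = rng.dirichlet(alpha)
        counts = rng.multinomial(config.cells_per_sample, weights)
        program = SUBTYPE_I_ACTIVATION_PROGRAM if s > 0 else SUBTYPE_II_ACTIVATION_PROGRAM
        blocks = []
        for i, n_i in enumerate(counts):
            if n_i == 0:
                continue
            mean = template[i].copy()
            for m in program.get(defs[i].name, ()):
                if m in midx:
                    mean[midx[m]] += config.activation_shift * NOISE_SD
            blocks.append(mean + rng.normal(0.0, NOISE_SD, size=(n_i, len(markers))))
        cells = np.vstack(blocks)
        frame = pd.DataFrame(cells, columns=markers)
        frame.insert(0, SAMPLE_COL, sample)
        frames.append(frame)
    data = pd.concat(frames, ignore_index=True)
    table = CellEventTable(data=data, markers=tuple(markers), transformed=True)
    return table, truth_labels


@dataclass
class Peptidome:
    """Mutation catalog, proteins, detected peaks, HLA types, and planted
    binder truth for one synthetic cohort."""

    proteins: dict[str, str]
    mutations: list[MutationRecord]
    windows: list[PeptideWindow]
    peaks: pd.DataFrame              # peptide, sample_id, auc
    hla_types: list[HlaType]
    planted_ranks: dict[tuple[str, str], float]
    truth_calls: pd.DataFrame        # accession, position, sample_id, mhc_class, peptide, auc
    mhc_expression: pd.DataFrame = field(default=None)  # samples x loci iFOT
    rank_table: pd.DataFrame = field(repr=False, default=None)

    def predictor(self) -> HashRankPredictor:
        return HashRankPredictor(planted=self.planted_ranks)


def generate_peptidome(
    config: SimConfig, truth_labels: pd.Series
) -> Peptidome:
    """Random proteome, missense catalog, and detected neopeptide peaks.

    One tryptic-style detected peptide (15-20 residues, covering the
    mutated site) is fixed per mutation; per sample it is detected with
    probability ``detect_prob`` and its abundance is log-normal with the
    log-mean raised by ``abundance_shift`` in subtype-I samples.  For every
    mutation one class-I 9-mer (rank drawn <= 1) and one class-II 15-mer
    (rank drawn <= 5) are planted as true binders on alleles carried by all
    patients, so ground-truth calls are exactly enumerable.
    """
    rng = config.rng("peptidome")
    n_mut = config.n_mutations_per_patient
    n_prot = max(1, (n_mut + 1) // 2)
    aa = np.array(list(AMINO_ACIDS))
    proteins = {
        f"SYNP{1 + i:04d}": "".join(rng.choice(aa, size=PROTEIN_LENGTH))
        for i in range(n_prot)
    }
    accessions = list(proteins)

    mutations: list[MutationRecord] = []
    windows: list[PeptideWindow] = []
    used: set[tuple[str, int]] = set()
    while len(mutations) < n_mut:
        acc = accessions[int(rng.integers(len(accessions)))]
        pos = int(rng.integers(1, PROTEIN_LENGTH + 1))
        if (acc, pos) in used:
            continue
        used.add((acc, pos))
        wt = proteins[acc][pos - 1]
        mut = str(rng.choice([a for a in AMINO_ACIDS if a != wt]))
        rec = MutationRecord(
            gene=f"SYNG{len(mutations) + 1:04d}", accession=acc, position=pos,
            wt_aa=wt, mut_aa=mut, sources=("synthetic",),
        )
        mutations.append(rec)
        windows.append(make_peptide_window(proteins[acc], rec))

    hla_types = []
    for sample in truth_labels.index:
        prng = config.rng("hla", sample)
        alleles: list[str] = []
        for locus, pool in _ALLELE_POOLS.items():
            if locus == "HLA-A":
                pair = [_UNIVERSAL_I, str(prng.choice(pool[1:]))]
            elif locus == "HLA-DRB1":
                pair = [_UNIVERSAL_II, str(prng.choice(pool[1:]))]
            else:
                pair = list(prng.choice(pool, size=2, replace=False))
            alleles.extend(pair)
        hla_types.append(HlaType(patient_id=str(sample), alleles=tuple(alleles)))

    planted: dict[tuple[str, str], float] = {}
    detected_peptides: list[tuple[MutationRecord, str, dict[str, str]]] = []
    for rec, window in zip(mutations, windows):
        length = int(rng.integers(15, 21))
        length = min(length, len(window.sequence))
        lo = max(1, window.mutation_offset - length + 1)
        hi = min(len(window.sequence) - length + 1, window.mutation_offset)
        start = int(rng.integers(lo, hi + 1))
        peptide = window.sequence[start - 1 : start - 1 + length]
        inner = window.mutation_offset - start + 1  # 1-based in peptide
        binders: dict[str, str] = {}

        if length >= 9:
            lo9 = max(1, inner - 8)
            hi9 = min(length - 8, inner)
            s9 = int(rng.integers(lo9, hi9 + 1))
            pep9 = peptide[s9 - 1 : s9 + 8]
            planted[(pep9, _UNIVERSAL_I)] = float(rng.uniform(0.2, 1.0))
            binders["I"] = pep9
        if length >= 15:
            lo15 = max(1, inner - 14)
            hi15 = min(length - 14, inner)
            s15 = int(rng.integers(lo15, hi15 + 1))
            pep15 = peptide[s15 - 1 : s15 + 14]
            planted[(pep15, _UNIVERSAL_II)] = float(rng.uniform(1.0, 5.0))
            binders["II"] = pep15
        detected_peptides.append((rec, peptide, binders))

    peak_rows, truth_rows = [], []
    for sample in truth_labels.index:
        srng = config.rng("peaks", sample)
        shift = config.abundance_shift if truth_labels[sample] == "I" else 0.0
        for rec, peptide, binders in detected_peptides:
            if srng.random() >= config.detect_prob:
                continue
            auc = float(np.exp(srng.normal(ABUNDANCE_LOG_MEAN + shift, ABUNDANCE_LOG_SD)))
            peak_rows.append({"peptide": peptide, "sample_id": sample, "auc": auc})
            for mhc_class, binder_pep in binders.items():
                truth_rows.append(
                    {
                        "accession": rec.accession, "position": rec.position,
                        "gene": rec.gene, "sample_id": sample,
                        "mhc_class": mhc_class, "peptide": peptide,
                        "binder_peptide": binder_pep, "auc": auc,
                    }
                )
    peaks = pd.DataFrame(peak_rows, columns=["peptide", "sample_id", "auc"])
    truth_calls = pd.DataFrame(
        truth_rows,
        columns=[
            "accession", "position", "gene", "sample_id", "mhc_class",
            "peptide", "binder_peptide", "auc",
        ],
    )
    rank_table = pd.DataFrame(
        [
            {"peptide": pep, "allele": allele, "mut_rank": rank}
            for (pep, allele), rank in planted.items()
        ],
        columns=["peptide", "allele", "mut_rank"],
    )
    # MHC protein expression per sample x locus: log-normal with the log
    # mean raised by half the abundance shift in subtype-I samples (elevated
    # class I and II protein levels in the good microenvironment).
    loci = list(_MHC_BASELINE_LOG)
    expr_rows = {}
    for sample in truth_labels.index:
        erng = config.rng("mhc_expression", sample)
        bump = 0.5 * config.abundance_shift if truth_labels[sample] == "I" else 0.0
        expr_rows[sample] = [
            float(np.exp(erng.normal(_MHC_BASELINE_LOG[locus] + bump, _MHC_LOG_SD)))
            for locus in loci
        ]
    mhc_expression = pd.DataFrame.from_dict(expr_rows, orient="index", columns=loci)
    mhc_expression.index.name = "sample_id"

    return Peptidome(
        proteins=proteins, mutations=mutations, windows=windows, peaks=peaks,
        hla_types=hla_types, planted_ranks=planted, truth_calls=truth_calls,
        mhc_expression=mhc_expression, rank_table=rank_table,
    )


def generate_expression_cohort(
    config: SimConfig, truth_labels: pd.Series
) -> tuple[ExpressionMatrix, ExpressionMatrix, tuple[str, ...]]:
    """Paired mRNA/protein matrices with a planted dual-level signature.

    Planted genes separate the subtypes by ``signature_effect`` noise-SD
    units at both levels (random direction per gene); per-gene mRNA and
    protein noise are coupled with correlation ``mrna_protein_corr``;
    non-signature genes are null at both levels.
    """
    rng = config.rng("expression")
    genes = [f"SYNG{1 + i:05d}" for i in range(config.n_genes)]
    planted_idx = rng.choice(config.n_genes, size=config.n_signature_genes, replace=False)
    planted = tuple(genes[i] for i in sorted(planted_idx))
    direction = np.zeros(config.n_genes)
    direction[sorted(planted_idx)] = rng.choice([-1.0, 1.0], size=config.n_signature_genes)

    s = np.array([1.0 if truth_labels[c] == "I" else -1.0 for c in truth_labels.index])
    mu = 0.5 * config.signature_effect * np.outer(direction, s)
    rho = config.mrna_protein_corr
    e_m = rng.normal(size=mu.shape)
    e_p = rho * e_m + np.sqrt(max(0.0, 1.0 - rho**2)) * rng.normal(size=mu.shape)
    gene_index = pd.Index(genes, name="gene")
    mrna = pd.DataFrame(mu + e_m, index=gene_index, columns=truth_labels.index)
    prot = pd.DataFrame(mu + e_p, index=gene_index, columns=truth_labels.index)
    return (
        ExpressionMatrix(values=mrna, level="mRNA", platform="synthetic-array"),
        ExpressionMatrix(values=prot, level="protein", platform="synthetic-ms"),
        planted,
    )


def generate_outcomes(config: SimConfig, truth_labels: pd.Series) -> pd.DataFrame:
    """Clinical table: exponential survival (hazard multiplied by
    ``hazard_ratio`` for subtype II), independent uniform censoring on
    [0, 72] months, covariates, and mRECIST response by subtype."""
    rng = config.rng("outcomes")
    lam0 = np.log(2.0) / BASELINE_MEDIAN_MONTHS
    rows = []
    for sample in truth_labels.index:
        good = truth_labels[sample] == "I"
        lam = lam0 * (1.0 if good else config.hazard_ratio)
        t_event = rng.exponential(1.0 / lam)
        t_censor = rng.uniform(0.0, CENSOR_MAX_MONTHS)
        time = max(min(t_event, t_censor), 1e-3)
        p_resp = config.response_prob_good if good else config.response_prob_bad
        responder = rng.random() < p_resp
        if responder:
            response = "CR" if rng.random() < CR_GIVEN_RESPONDER else "PR"
        else:
            response = "PD" if rng.random() < PD_GIVEN_NONRESPONDER else "SD"
        rows.append(
            {
                "patient_id": sample,
                "time_months": time,
                "event": int(t_event <= t_censor),
                "age": float(np.round(rng.normal(63.0, 8.0), 1)),
                "asbestos": int(rng.random() < 0.7),
                "histology_epithelial": int(rng.random() < 0.7),
                "stage": int(rng.choice([1, 2, 3, 4], p=[0.15, 0.25, 0.4, 0.2])),
                "response": response,
                "subtype": truth_labels[sample],
            }
        )
    return pd.DataFrame(rows)


@dataclass
class SyntheticCohort:
    """Every pipeline input for one simulated cohort, plus ground truth."""

    config: SimConfig
    truth_labels: pd.Series
    cell_events: CellEventTable
    peptidome: Peptidome
    mrna: ExpressionMatrix
    protein: ExpressionMatrix
    planted_signature: tuple[str, ...]
    clinical: pd.DataFrame

    def content_hash(self) -> str:
        """SHA-256 over all generated tables; identical configs (including
        seed) must produce identical hashes."""
        h = hashlib.sha256()
        parts = [
            self.truth_labels.to_frame(),
            self.cell_events.data.round(10),
            self.peptidome.peaks.round(10),
            self.peptidome.truth_calls.round(10),
            self.peptidome.rank_table.round(12),
            self.peptidome.mhc_expression.round(10).reset_index(),
            self.mrna.values.round(10).reset_index(),
            self.protein.values.round(10).reset_index(),
            pd.DataFrame({"gene": list(self.planted_signature)}),
            self.clinical.round(10),
            pd.DataFrame(
                [
                    {"patient": t.patient_id, "alleles": ";".join(t.alleles)}
                    for t in self.peptidome.hla_types
                ]
            ),
            pd.DataFrame(
                [{"accession": a, "sequence": s} for a, s in self.peptidome.proteins.items()]
            ),
        ]
        for part in parts:
            h.update(part.to_csv(index=False).encode())
        return h.hexdigest()


def generate_cohort(config: SimConfig) -> SyntheticCohort:
    """Generate a complete synthetic cohort (all stages, shared labels)."""
    truth = generate_truth_labels(config)
    cells, _ = generate_cell_events(config, truth)
    peptidome = generate_peptidome(config, truth)
    mrna, protein, planted = generate_expression_cohort(config, truth)
    clinical = generate_outcomes(config, truth)
    return SyntheticCohort(
        config=config, truth_labels=truth, cell_events=cells,
        peptidome=peptidome, mrna=mrna, protein=protein,
        planted_signature=planted, clinical=clinical,
    )
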