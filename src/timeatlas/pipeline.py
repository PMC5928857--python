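"""End-to-end orchestration: simulate -> subtype -> neoantigen ->
signature -> outcomes, with a hashed run manifest and cached-stage resume.

Every artifact is reproducible from the configuration plus its seed; the
manifest records the configuration hash and a SHA-256 per output file so a
rerun with identical configuration is hash-stable and partial reruns can
skip completed stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import cytof, io, neoantigen, outcomes as outcomes_mod, signature as signature_mod
from .config import PipelineConfig
from .simulate import SyntheticCohort, generate_cohort

logger = logging.getLogger(__name__)


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(config.to_dict(), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()


def _write_json(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=float))


class PipelineError(RuntimeError):
    pass


def run_pipeline(config: PipelineConfig, resume: bool = True) -> dict:
    """Run the configured stages in dependency order and write a manifest.

    Returns the manifest dict (inputs and outputs hashed, per-stage files).
    With ``resume=True`` a stage whose outputs already exist under an
    identical configuration hash is skipped and its cached outputs reused.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = _config_hash(config)
    manifest_path = out / "manifest.json"
    previous = {}
    if resume and manifest_path.exists():
        try:
            previous = json.loads(manifest_path.read_text())
        except json.JSONDecodeError:
            previous = {}
        if previous.get("config_hash") != cfg_hash:
            previous = {}

    manifest: dict = {
        "config": config.to_dict(),
        "config_hash": cfg_hash,
        "seed": config.sim.seed,
        "stages": {},
    }

    def _cached(stage: str) -> bool:
        entry = previous.get("stages", {}).get(stage)
        if not entry:
            return False
        files = entry.get("files", {})
        ok = all(
            (out / name).exists() and _file_hash(out / name) == digest
            for name, digest in files.items()
        )
        if ok:
            manifest["stages"][stage] = entry
        return ok

    def _record(stage: str, names: list[str]) -> None:
        manifest["stages"][stage] = {
            "files": {name: _file_hash(out / name) for name in names}
        }

    # The synthetic cohort is the deterministic source for every stage and
    # is regenerated in memory even when the simulate stage is cached.
    cohort = generate_cohort(config.sim)

    try:
        if "simulate" in config.stages and not _cached("simulate"):
            _stage_simulate(cohort, out)
            _record("simulate", _SIM_FILES)

        subtypes = None
        if "subtype" in config.stages:
            if _cached("subtype"):
                subtypes = pd.read_csv(out / "subtypes.csv", index_col=0)["subtype"]
            else:
                subtypes = _stage_subtype(cohort, config, out)
                _record("subtype", _SUBTYPE_FILES)
        groups = subtypes if subtypes is not None else cohort.truth_labels

        if "neoantigen" in config.stages and not _cached("neoantigen"):
            _stage_neoantigen(cohort, config, groups, out)
            _record("neoantigen", _NEO_FILES)

        labels = None
        if "signature" in config.stages:
            if _cached("signature"):
                calls = pd.read_csv(out / "signature_calls.csv")
                labels = calls.set_index("sample_id")["label"]
            else:
                labels = _stage_signature(cohort, config, groups, out)
                _record("signature", _SIG_FILES)

        if "outcomes" in config.stages and not _cached("outcomes"):
            _stage_outcomes(cohort, config, groups, labels, out)
            _record("outcomes", _OUT_FILES)
    except (ValueError, KeyError) as exc:
        manifest["failed"] = str(exc)
        _write_json(manifest_path, manifest)
        raise PipelineError(str(exc)) from exc

    _write_json(manifest_path, manifest)
    return manifest


_SIM_FILES = [
    "inputs/cells.csv", "inputs/proteins.fasta", "inputs/mutations.csv",
    "inputs/peaks.csv", "inputs/hla.csv", "inputs/planted_ranks.csv",
    "inputs/mhc_expression.csv", "inputs/mrna.tsv", "inputs/protein.tsv",
    "inputs/clinical.csv", "inputs/truth_labels.csv",
]
_SUBTYPE_FILES = [
    "subtypes.csv", "node_medians.csv", "node_fractions.csv",
    "node_phenotypes.csv", "node_compare.csv", "zratio.csv", "scaffold.json",
]
_NEO_FILES = [
    "neoantigen_calls.csv", "neoantigen_abundance.csv", "concordance.json",
]
_SIG_FILES = ["signature.json", "signature_calls.csv", "differential_mrna.csv",
              "differential_protein.csv"]
_OUT_FILES = ["survival.json", "cox.json", "response_fisher.json"]


def _stage_simulate(cohort: SyntheticCohort, out: Path) -> None:
    inputs = out / "inputs"
    inputs.mkdir(exist_ok=True)
    io.write_cell_events(cohort.cell_events, inputs / "cells.csv")
    io.write_fasta(cohort.peptidome.proteins, inputs / "proteins.fasta")
    io.write_mutations(cohort.peptidome.mutations, inputs / "mutations.csv")
    io.write_peaks(cohort.peptidome.peaks, inputs / "peaks.csv")
    io.write_hla(cohort.peptidome.hla_types, inputs / "hla.csv")
    cohort.peptidome.rank_table.to_csv(inputs / "planted_ranks.csv", index=False)
    cohort.peptidome.mhc_expression.to_csv(inputs / "mhc_expression.csv")
    io.write_expression(cohort.mrna, inputs / "mrna.tsv")
    io.write_expression(cohort.protein, inputs / "protein.tsv")
    cohort.clinical.to_csv(inputs / "clinical.csv", index=False)
    cohort.truth_labels.to_frame().to_csv(inputs / "truth_labels.csv")


def _stage_subtype(cohort: SyntheticCohort, config: PipelineConfig, out: Path) -> pd.Series:
    events = cohort.cell_events
    down = cytof.density_downsample(
        events, target_fraction=config.downsample_fraction, seed=config.sim.seed
    )
    k = min(config.k_clusters, len(down.data))
    nodes = cytof.cluster_events(down, all_events=events, k=k, seed=config.sim.seed)
    nodes = cytof.assign_phenotypes(nodes, _phenotype_defs(config))
    graph = cytof.build_scaffold_graph(nodes)
    orientation = cytof.exhausted_cd8_score(nodes)
    subtypes = cytof.subtype_samples(nodes.fractions, orientation_score=orientation)

    group_a = subtypes.index[subtypes == "I"]
    group_b = subtypes.index[subtypes == "II"]
    frac_a = nodes.fractions.loc[group_a].mean(axis=0)
    frac_b = nodes.fractions.loc[group_b].mean(axis=0)
    compare = cytof.compare_nodes(frac_a, frac_b, nodes.phenotypes)

    summary = cytof.activation_summary(events, nodes)
    zr = cytof.z_ratio(summary, list(group_a), list(group_b), cutoff=config.z_cutoff)

    subtypes.rename_axis("sample_id").to_frame().to_csv(out / "subtypes.csv")
    nodes.medians.to_csv(out / "node_medians.csv")
    nodes.fractions.to_csv(out / "node_fractions.csv")
    pd.DataFrame(
        {"phenotype": nodes.phenotypes, "landmark": nodes.landmarks}
    ).to_csv(out / "node_phenotypes.csv")
    compare.to_csv(out / "node_compare.csv")
    zr.to_csv(out / "zratio.csv")
    io.write_graph(graph, out / "scaffold.json", retention_quantile=0.9)
    return subtypes


def _phenotype_defs(config: PipelineConfig):
    from .phenotypes import DEFAULT_PHENOTYPES

    return DEFAULT_PHENOTYPES[: config.sim.n_phenotypes]


def _stage_neoantigen(
    cohort: SyntheticCohort, config: PipelineConfig, groups: pd.Series, out: Path
) -> None:
    predictor = cohort.peptidome.predictor()
    all_calls = []
    for hla in cohort.peptidome.hla_types:
        all_calls.extend(
            neoantigen.call_neoantigens(
                hla, cohort.peptidome.windows, cohort.peptidome.peaks,
                predictor, tier_mode=config.tier_mode,
            )
        )
    calls = neoantigen.calls_to_frame(all_calls)
    calls.to_csv(out / "neoantigen_calls.csv", index=False)
    neoantigen.average_neoantigen_abundance(calls).to_csv(
        out / "neoantigen_abundance.csv", index=False
    )
    try:
        conc = neoantigen.concordance_analysis(
            calls, cohort.peptidome.mhc_expression, groups
        )
        payload = {
            "table": {
                str(k): {"high_high": int(v["high_high"]), "other": int(v["other"])}
                for k, v in conc.table.iterrows()
            },
            "chi2": conc.chi2,
            "p": conc.p,
        }
    except ValueError as exc:
        payload = {"skipped": str(exc)}
    _write_json(out / "concordance.json", payload)


def _stage_signature(
    cohort: SyntheticCohort, config: PipelineConfig, groups: pd.Series, out: Path
) -> pd.Series:
    diff_m = signature_mod.differential_features(cohort.mrna, groups)
    diff_p = signature_mod.differential_features(cohort.protein, groups)
    sig = signature_mod.derive_signature(
        diff_m, diff_p, cohort.mrna, groups, p_threshold=config.p_threshold
    )
    calls = signature_mod.classify_samples(sig, cohort.mrna)
    frame = signature_mod.calls_to_frame(calls)

    diff_m.to_csv(out / "differential_mrna.csv")
    diff_p.to_csv(out / "differential_protein.csv")
    io.write_signature(sig, out / "signature.json")
    frame.to_csv(out / "signature_calls.csv", index=False)
    return frame.set_index("sample_id")["label"]


def _stage_outcomes(
    cohort: SyntheticCohort,
    config: PipelineConfig,
    groups: pd.Series,
    labels: pd.Series | None,
    out: Path,
) -> None:
    clinical = cohort.clinical
    if labels is None:
        labels = groups.map({"I": "good_TiME", "II": "bad_TiME"})
    surv = outcomes_mod.survival_compare(clinical, labels)
    _write_json(
        out / "survival.json",
        {
            "logrank_statistic": surv.statistic,
            "p": surv.p,
            "group_sizes": surv.group_sizes,
            "curves": {
                str(g): c.to_dict(orient="list") for g, c in surv.curves.items()
            },
        },
    )

    data = clinical.copy()
    data["bad_signature"] = (
        data["patient_id"].map(labels).eq("bad_TiME").astype(int)
    )
    variables = ["bad_signature", "age", "asbestos", "histology_epithelial", "stage"]
    try:
        cox = outcomes_mod.cox_model(data, variables, screen_p=config.screen_p)
        payload = {
            "univariable": cox.univariable.to_dict(orient="index"),
            "screened_in": list(cox.screened_in),
            "multivariable": (
                cox.multivariable.to_dict(orient="index")
                if cox.multivariable is not None else None
            ),
        }
    except (RuntimeError, ValueError) as exc:
        payload = {"skipped": str(exc)}
    _write_json(out / "cox.json", payload)

    fisher = outcomes_mod.fisher_response(labels, clinical)
    _write_json(
        out / "response_fisher.json",
        {
            "table": {
                str(k): {"responder": int(v["responder"]),
                         "non_responder": int(v["non_responder"])}
                for k, v in fisher.table.iterrows()
            },
            "odds_ratio": fisher.odds_ratio,
            "p": fisher.p,
            "defined": fisher.defined,
        },
    )
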