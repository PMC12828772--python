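"""End-to-end orchestration: simulate/load -> deconvolve -> subtype -> report.

A single :class:`PipelineConfig` (YAML-serializable) drives the full
analysis. Every stage writes its artifacts as TSV/JSON into the output
directory and registers them in a manifest with SHA-256 checksums, so a
rerun with the same config and seed is byte-identical and auditable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as tio
from .association import CAF_MARKERS, crosstab_subtype, marker_comparison
from .classifier import predict_lda, save_model, train_lda
from .containers import ClinicalTable, ExpressionMatrix, SampleMap, SubtypeLabeling
from .deconvolution import deconvolve_cohort
from .heterogeneity import compare_pair_groups, pair_similarities, subtype_concordance
from .simulate import SimulationConfig, simulate_cohort, generate_reference
from .subtyping import assign_subtype_names, consensus_cluster, select_k, zscore
from .survival import cox_fit, km_estimate, model_comparison, ph_test

logger = logging.getLogger(__name__)

#: below this many events the pipeline's survival stage is skipped
MIN_EVENTS_FOR_SURVIVAL = 10

DEFAULT_MODEL_COMPARISON: dict[str, list[str]] = {
    "gleason": ["gleason"],
    "gleason_pt": ["gleason", "pt"],
    "gleason_subtype": ["gleason", "subtype"],
    "gleason_pt_subtype": ["gleason", "pt", "subtype"],
}


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and cause."""


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run.

    Exactly one of ``simulation`` (generate a synthetic cohort) or
    ``inputs`` (paths to expression/reference/clinical/sample-map TSVs)
    must be given.
    """

    simulation: SimulationConfig | None = None
    inputs: dict[str, str] | None = None
    expression_unit: str = "tpm"
    overlap_threshold: float = 0.8
    k_range: tuple[int, int] = (2, 6)
    n_resamples: int = 250
    subsample_fraction: float = 0.8
    k_policy: str = "delta-area"
    fixed_k: int = 3
    covariate_sets: dict[str, list[str]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_MODEL_COMPARISON.items()}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.simulation is None) == (self.inputs is None):
            raise ValueError("exactly one of simulation / inputs must be configured")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if raw.get("simulation") is not None:
            sim = raw["simulation"]
            for key in ("foci_per_patient", "samples_per_focus", "subtype_prior"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            for key in ("dirichlet_alpha", "gleason_probs", "pt_probs"):
                if key in sim:
                    sim[key] = {k: tuple(v) for k, v in sim[key].items()}
            raw["simulation"] = SimulationConfig(**sim)
        if "k_range" in raw:
            raw["k_range"] = tuple(raw["k_range"])
        return cls(**raw)


def patient_labels(labels: SubtypeLabeling, sample_map: SampleMap) -> SubtypeLabeling:
    """Patient-level subtype by majority vote over the patient's samples.

    Ties break by subtype name order, deterministically.
    """
    df = sample_map.data.copy()
    df["subtype"] = labels.labels.reindex(df.index)
    voted = (
        df.groupby("patient_id")["subtype"]
        .agg(lambda s: s.value_counts().sort_index().idxmax())
        .rename("subtype")
    )
    return SubtypeLabeling(voted)


class _Manifest:
    def __init__(self, out_dir: Path):
        self.out_dir = out_dir
        self.entries: list[dict[str, str]] = []

    def add(self, path: Path, stage: str) -> None:
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        self.entries.append({"file": path.name, "stage": stage, "sha256": digest})

    def write(self) -> Path:
        path = self.out_dir / "manifest.json"
        path.write_text(json.dumps({"artifacts": self.entries}, indent=1))
        return path


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute all stages and return the artifact manifest as a dict."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(out)

    def _stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    # -- acquire ------------------------------------------------------------
    def acquire():
        if cfg.simulation is not None:
            sim = cfg.simulation
            ref = generate_reference(
                sim.n_signature_genes_per_type, sim.n_background_genes, seed=sim.seed
            )
            expr, sample_map, clinical, truth = simulate_cohort(sim, ref)
            tio.write_expression(expr, out / "expression.tsv")
            tio.write_reference(ref, out / "reference.tsv")
            tio.write_sample_map(sample_map, out / "sample_map.tsv")
            tio.write_clinical(clinical, out / "clinical.tsv")
            truth.sample_proportions.assign(subtype=truth.sample_subtype).rename_axis(
                "sample_id"
            ).to_csv(out / "truth.tsv", sep="\t")
            for name in ("expression", "reference", "sample_map", "clinical", "truth"):
                manifest.add(out / f"{name}.tsv", "simulate")
            return expr, ref, sample_map, clinical
        paths = cfg.inputs
        expr = tio.load_expression(paths["expression"], unit=cfg.expression_unit)
        if expr.unit != "tpm":
            expr = tio.renormalize_tpm(expr)
        ref = tio.load_reference(paths["reference"])
        clinical = tio.load_clinical(paths["clinical"]) if "clinical" in paths else None
        if "sample_map" in paths:
            sample_map = tio.load_sample_map(paths["sample_map"])
        else:  # single-sample cohort: each sample is its own patient/focus
            sample_map = SampleMap(
                pd.DataFrame(
                    {"patient_id": expr.sample_ids, "focus_id": "F1"},
                    index=pd.Index(expr.sample_ids, name="sample_id"),
                )
            )
        return expr, ref, sample_map, clinical

    expr, ref, sample_map, clinical = _stage("acquire", acquire)

    # -- deconvolution ------------------------------------------------------
    def deconvolve():
        comp = deconvolve_cohort(expr, ref, overlap_threshold=cfg.overlap_threshold)
        tio.write_composition(comp, out / "composition.tsv")
        manifest.add(out / "composition.tsv", "deconvolve")
        return comp

    comp = _stage("deconvolve", deconvolve)

    # -- clustering + naming ------------------------------------------------
    def cluster():
        z = zscore(comp)
        res = consensus_cluster(
            z,
            k_range=cfg.k_range,
            n_resamples=cfg.n_resamples,
            subsample_fraction=cfg.subsample_fraction,
            seed=cfg.seed,
        )
        for k in res.k_values:
            pd.DataFrame(res.consensus[k], index=res.sample_ids, columns=res.sample_ids).rename_axis(
                "sample_id"
            ).to_csv(out / f"consensus_k{k}.tsv", sep="\t")
            manifest.add(out / f"consensus_k{k}.tsv", "cluster")
        if cfg.k_policy == "fixed":
            k = select_k(res, policy="fixed", fixed_k=cfg.fixed_k)
        else:
            k = select_k(res, policy="delta-area")
        labels_df = pd.DataFrame(
            {f"cluster_k{kk}": res.labels[kk] for kk in res.k_values}, index=res.sample_ids
        )
        labels_df["chosen_k"] = k
        labels_df.rename_axis("sample_id").to_csv(out / "labels.tsv", sep="\t")
        manifest.add(out / "labels.tsv", "cluster")
        if k != 3:
            logger.warning("chosen k = %d != 3; using k = 3 partition for subtype naming", k)
        naming = assign_subtype_names(res.labels[3], z)
        tio.write_labels(naming, out / "subtypes.tsv")
        manifest.add(out / "subtypes.tsv", "cluster")
        return z, res, k, naming

    z, res, chosen_k, naming = _stage("cluster", cluster)

    # -- classifier ---------------------------------------------------------
    def classify():
        model = train_lda(comp, naming)
        save_model(model, out / "model.json")
        manifest.add(out / "model.json", "train")
        predicted, posteriors = predict_lda(model, comp)
        pred_df = posteriors.copy()
        pred_df.insert(0, "subtype", predicted.labels)
        pred_df.rename_axis("sample_id").to_csv(out / "predicted.tsv", sep="\t")
        manifest.add(out / "predicted.tsv", "predict")
        return model, predicted

    model, predicted = _stage("classify", classify)

    # -- heterogeneity (multisample cohorts only) ---------------------------
    multisample = sample_map.data["patient_id"].duplicated().any()
    if multisample:
        def heterogeneity():
            pairs = pair_similarities(z, sample_map)
            pairs.to_csv(out / "pairs.tsv", sep="\t", index=False)
            manifest.add(out / "pairs.tsv", "heterogeneity")
            tests = compare_pair_groups(pairs)
            rows = [
                {
                    "comparison": key,
                    "U": r.statistic,
                    "p": r.p_value,
                    "median_a": r.median_a,
                    "median_b": r.median_b,
                    "n_a": r.n_a,
                    "n_b": r.n_b,
                }
                for key, r in tests.items()
            ]
            pd.DataFrame(rows).to_csv(out / "tests.tsv", sep="\t", index=False)
            manifest.add(out / "tests.tsv", "heterogeneity")
            per_patient, per_focus, summary = subtype_concordance(naming, sample_map)
            per_patient.rename_axis("patient_id").to_csv(out / "concordance_patients.tsv", sep="\t")
            manifest.add(out / "concordance_patients.tsv", "heterogeneity")
            (out / "concordance_summary.json").write_text(json.dumps(summary, indent=1))
            manifest.add(out / "concordance_summary.json", "heterogeneity")

        _stage("heterogeneity", heterogeneity)

    # -- survival + association (needs clinical data) -----------------------
    if clinical is not None:
        pat_labels = patient_labels(naming, sample_map)
        n_events = int(clinical.data["bcr_event"].sum())
        # small multifocal cohorts rarely carry enough relapses for Cox
        # models; survival analysis is then skipped, as validation cohorts
        # with scarce events are in the published analysis
        run_survival = n_events >= MIN_EVENTS_FOR_SURVIVAL
        if not run_survival:
            logger.warning(
                "only %d BCR events; skipping the survival stage (needs >= %d)",
                n_events,
                MIN_EVENTS_FOR_SURVIVAL,
            )

        def survival():
            curves, logrank = km_estimate(clinical, pat_labels)
            rows = []
            for curve in curves.values():
                for t, ar, ev, s, tr in zip(
                    curve.times, curve.at_risk, curve.events, curve.survival, curve.truncated
                ):
                    rows.append(
                        {
                            "group": curve.group,
                            "time": t,
                            "at_risk": ar,
                            "events": ev,
                            "survival": s,
                            "truncated": tr,
                        }
                    )
            pd.DataFrame(rows).to_csv(out / "km_curves.tsv", sep="\t", index=False)
            manifest.add(out / "km_curves.tsv", "survival")
            (out / "logrank.json").write_text(
                json.dumps(
                    {"statistic": logrank.statistic, "df": logrank.df, "p": logrank.p_value},
                    indent=1,
                )
            )
            manifest.add(out / "logrank.json", "survival")

            uni_rows = []
            for cov in ("subtype", "gleason", "pt"):
                fit = cox_fit(clinical, [cov], subtypes=pat_labels)
                t = fit.terms.copy()
                t.insert(0, "covariate", cov)
                uni_rows.append(t)
            pd.concat(uni_rows).rename_axis("term").to_csv(out / "cox_univariable.tsv", sep="\t")
            manifest.add(out / "cox_univariable.tsv", "survival")

            multi = cox_fit(clinical, ["subtype", "gleason", "pt"], subtypes=pat_labels)
            multi.terms.rename_axis("term").to_csv(out / "cox_multivariable.tsv", sep="\t")
            manifest.add(out / "cox_multivariable.tsv", "survival")

            per_term, global_p = ph_test(multi)
            per_term.assign(global_p=global_p).rename_axis("term").to_csv(
                out / "ph_test.tsv", sep="\t"
            )
            manifest.add(out / "ph_test.tsv", "survival")

            comparison = model_comparison(clinical, cfg.covariate_sets, subtypes=pat_labels)
            comparison.to_csv(out / "concordance.tsv", sep="\t")
            manifest.add(out / "concordance.tsv", "survival")

        if run_survival:
            _stage("survival", survival)

        def associate():
            for fieldname, colname in (("gleason", "gleason_category"), ("pt", "pt_category")):
                result = crosstab_subtype(pat_labels, clinical.data[colname])
                table = result.counts.copy()
                table["chi2"] = result.chi2
                table["df"] = result.df
                table["p"] = result.p_value
                table["low_expected"] = result.low_expected_counts
                table.rename_axis("subtype").to_csv(out / f"crosstab_{fieldname}.tsv", sep="\t")
                manifest.add(out / f"crosstab_{fieldname}.tsv", "associate")
            markers = [m for m in CAF_MARKERS if m in expr.data.index]
            if not markers:
                # synthetic cohorts carry the CAF signature block under SIG_CAFs_* ids
                markers = [g for g in expr.gene_ids if g.startswith("SIG_CAFs_")][:9]
            if markers:
                mc = marker_comparison(expr, naming, markers=tuple(markers))
                mc.table.to_csv(out / "markers.tsv", sep="\t", index=False)
                manifest.add(out / "markers.tsv", "associate")
            else:
                logger.info("no CAF marker genes found; skipping marker comparison")

        _stage("associate", associate)

    path = manifest.write()
    logger.info("pipeline complete: %d artifacts in %s", len(manifest.entries), out)
    return json.loads(path.read_text())
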