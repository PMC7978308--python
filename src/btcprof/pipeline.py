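"""End-to-end cohort analysis and the headline summary report.

Stages run in dependency order: mutation burden -> signature extraction and
aristolochic-acid attribution -> driver association tests -> DDR
classification -> actionability -> therapy outcomes.  The report is a JSON
document of counts, explicit denominators and half-up one-decimal percents,
plus a human-readable text block; identical inputs and seed give a
byte-identical report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .actionability import annotate_patient, load_knowledge_base, summarize_pat_prevalence
from .association import mutation_indicator_matrix, pairwise_gene_tests
from .burden import cohort_tmb
from .cohort import Cohort, NONSYNONYMOUS_CLASSES, germline_genes
from .ddr import classify_cohort_ddr, load_ddr_map, summarize_ddr
from .outcomes import classify_response_and_orr, evaluate_benefit, km_estimate
from .signatures import (
    SignatureSet,
    attribute_signature,
    build_context_matrix,
    cosine_match,
    load_reference_catalog,
    nmf_decompose,
    select_rank,
)

logger = logging.getLogger(__name__)

# per-stage seed offsets from the master seed, so stages are independently
# reproducible
_SEED_OFFSETS = {"nmf": 101, "rank": 211, "attribution": 307}


def percent(numerator: int, denominator: int) -> float:
    """Half-up one-decimal percent (96/803 -> 12.0, 12/46 -> 26.1)."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    frac = Decimal(numerator) * 100 / Decimal(denominator)
    return float(frac.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def format_percent(value: float, paper_style: bool = False) -> str:
    """Format a one-decimal percent; paper style drops a trailing '.0'."""
    if paper_style and value == int(value):
        return f"{int(value)}%"
    return f"{value:.1f}%"


def summarize_counts(counts: dict[str, tuple[int, int]], paper_style: bool = False) -> dict:
    """Turn named (numerator, denominator) pairs into percents.

    Returns ``{name: {"n": num, "denominator": den, "percent": float,
    "display": str}}``.
    """
    out = {}
    for name, (num, den) in counts.items():
        pct = percent(num, den)
        out[name] = {
            "n": int(num),
            "denominator": int(den),
            "percent": pct,
            "display": format_percent(pct, paper_style=paper_style),
        }
    return out


@dataclass
class PipelineConfig:
    seed: int
    wes_region_mb: float = 38.0
    tps_region_mb: float = 1.5
    tmb_counting_rule: str = "nonsynonymous"
    min_vaf: float | None = None
    n_signatures: int | str = 3  # an integer k, or "auto" for rank selection
    rank_range: tuple = (2, 3, 4)
    nmf_restarts: int = 20
    nmf_max_iter: int = 400
    aa_reference_name: str = "SBS22"
    # per-sample attribution re-fits onto "matched_reference" profiles (the
    # reference signatures the de-novo profiles matched), which keeps the
    # per-sample test free of extraction noise; "fitted" uses the de-novo
    # profiles directly
    attribution_profiles: str = "matched_reference"
    attribution_n_null: int = 200
    attribution_fdr: float = 0.05
    association_genes: list[str] | None = None
    association_min_freq: float = 0.05
    pat_kb_path: str | None = None
    ddr_map_path: str | None = None
    reference_catalog_path: str | None = None
    count_censored_in_ratio: bool = False
    paper_style_percents: bool = False


@dataclass
class PipelineResult:
    summary: dict
    tmb_table: pd.DataFrame
    signature_set: object | None
    attribution: pd.DataFrame | None
    pairwise: pd.DataFrame | None
    ddr_summary: dict
    pat_summary: dict
    outcome_summary: dict
    artifacts: dict = field(default_factory=dict)


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc

        return inner

    return wrap


def run_pipeline(
    cohort: Cohort, config: PipelineConfig, out_dir: str | Path | None = None
) -> PipelineResult:
    """Run all stages on a validated cohort and assemble the summary report."""
    cohort.validate()
    if cohort.n_samples == 0:
        raise ValueError("no samples in cohort")
    clin = cohort.clinical
    n_total = cohort.n_samples

    # --- mutation burden -------------------------------------------------
    tmb_table = _stage("burden")(cohort_tmb)(
        cohort.variants,
        clin,
        wes_region_mb=config.wes_region_mb,
        tps_region_mb=config.tps_region_mb,
        counting_rule=config.tmb_counting_rule,
        min_vaf=config.min_vaf,
    )
    hyper_samples = set(tmb_table.loc[tmb_table["hypermutated"], "sample_id"])
    wes_tmb = tmb_table.loc[tmb_table["platform"] == "WES", "tmb"]

    # --- mutational signatures + AA attribution --------------------------
    is_eligible = (
        (clin["platform"] == "WES")
        & (clin["subtype"] == "ICC")
        & ~clin["sample_id"].isin(hyper_samples)
    )
    eligible_ids = list(clin.loc[is_eligible, "sample_id"])
    signature_set = attribution = None
    aa_counts = (0, max(len(eligible_ids), 1))
    selected_k = None
    if eligible_ids:
        catalog = _stage("signatures")(build_context_matrix)(
            cohort.variants[cohort.variants["sample_id"].isin(eligible_ids)],
            samples=eligible_ids,
        )
        if catalog.counts.sum() > 0:
            if config.n_signatures == "auto":
                sel = _stage("signatures")(select_rank)(
                    catalog,
                    config.rank_range,
                    n_restarts=max(5, config.nmf_restarts // 2),
                    seed=config.seed + _SEED_OFFSETS["rank"],
                )
                k = sel.k
            else:
                k = int(config.n_signatures)
            selected_k = k
            signature_set = _stage("signatures")(nmf_decompose)(
                catalog,
                k,
                seed=config.seed + _SEED_OFFSETS["nmf"],
                max_iter=config.nmf_max_iter,
                n_restarts=config.nmf_restarts,
            )
            reference = load_reference_catalog(config.reference_catalog_path)
            signature_set.matches = cosine_match(signature_set.profiles, reference)
            if config.attribution_profiles == "matched_reference":
                names: list[str] = []
                for name, _ in signature_set.matches:
                    if name not in names:
                        names.append(name)
                if config.aa_reference_name not in names:
                    names.append(config.aa_reference_name)
                att_set = SignatureSet(
                    profiles=reference[names].to_numpy(),
                    exposures=np.zeros((len(names), catalog.n_samples)),
                    k=len(names),
                    reconstruction_error=float("nan"),
                    sample_ids=list(catalog.sample_ids),
                )
                target_idx = names.index(config.aa_reference_name)
            else:
                att_set = signature_set
                target_idx = _pick_target_index(
                    signature_set.matches, config.aa_reference_name
                )
            attribution = _stage("attribution")(attribute_signature)(
                catalog,
                att_set,
                target_idx,
                n_null=config.attribution_n_null,
                seed=config.seed + _SEED_OFFSETS["attribution"],
                fdr=config.attribution_fdr,
            )
            aa_counts = (int(attribution["positive"].sum()), len(attribution))

    # --- driver association ----------------------------------------------
    pairwise = None
    genes = config.association_genes
    nonsyn = cohort.variants[cohort.variants["variant_class"].isin(NONSYNONYMOUS_CLASSES)]
    if genes is None:
        freq = nonsyn.groupby("gene")["sample_id"].nunique()
        genes = sorted(freq[freq / n_total >= config.association_min_freq].index)
    if len(genes) >= 2:
        matrix = mutation_indicator_matrix(
            nonsyn, cohort.sample_ids, genes=genes, classes=NONSYNONYMOUS_CLASSES
        )
        pairwise = _stage("association")(pairwise_gene_tests)(matrix, genes)

    # --- DDR classification ----------------------------------------------
    ddr_map = load_ddr_map(config.ddr_map_path)
    statuses = _stage("ddr")(classify_cohort_ddr)(
        cohort.variants, cohort.sample_ids, ddr_map
    )
    ddr_summary = summarize_ddr(statuses)

    # --- actionability ----------------------------------------------------
    kb = load_knowledge_base(config.pat_kb_path)
    var_by_sample = dict(tuple(cohort.variants.groupby("sample_id"))) if len(cohort.variants) else {}
    cna_by_sample = dict(tuple(cohort.cnas.groupby("sample_id"))) if len(cohort.cnas) else {}
    fus_by_sample = dict(tuple(cohort.fusions.groupby("sample_id"))) if len(cohort.fusions) else {}
    empty_v, empty_c, empty_f = cohort.variants.iloc[0:0], cohort.cnas.iloc[0:0], cohort.fusions.iloc[0:0]
    calls_by_patient = {}
    for _, rec in clin.iterrows():
        sid = rec["sample_id"]
        calls_by_patient[sid] = _stage("actionability")(annotate_patient)(
            sid,
            kb,
            variants=var_by_sample.get(sid, empty_v),
            cnas=cna_by_sample.get(sid, empty_c),
            fusions=fus_by_sample.get(sid, empty_f),
            msi_high=bool(rec["msi_high"]),
        )
    pat_summary = summarize_pat_prevalence(
        calls_by_patient, subtypes=dict(zip(clin["sample_id"], clin["subtype"]))
    )

    # --- therapy outcomes --------------------------------------------------
    outcome_summary = {"n_treated": 0}
    km_median = None
    if len(cohort.outcomes):
        orr = _stage("outcomes")(classify_response_and_orr)(cohort.outcomes["best_response"])
        benefit = _stage("outcomes")(evaluate_benefit)(
            cohort.outcomes, count_censored=config.count_censored_in_ratio
        )
        events = cohort.outcomes["pfs2_event"].fillna(True).astype(bool)
        curve = _stage("outcomes")(km_estimate)(cohort.outcomes["pfs2_months"], events)
        km_median = curve.median
        outcome_summary = {**orr, **benefit, "median_pfs2_km": km_median,
                           "median_pfs2_ci": curve.median_ci}

    # --- report ------------------------------------------------------------
    n_msi = int(clin["msi_high"].fillna(False).astype(bool).sum())
    n_germline = int(sum(bool(germline_genes(v)) for v in clin["germline_pathogenic_genes"]))
    panel_ids = set(clin.loc[clin["platform"] == "TPS", "sample_id"])
    fgfr = cohort.fusions[
        (cohort.fusions["gene_5p"].isin(["FGFR2", "FGFR3"]) | cohort.fusions["gene_3p"].isin(["FGFR2", "FGFR3"]))
        & cohort.fusions["sample_id"].isin(panel_ids)
    ]
    n_fgfr = int(fgfr["sample_id"].nunique())
    counts = {
        "hypermutated": (len(hyper_samples), n_total),
        "germline_pathogenic": (n_germline, n_total),
        "ddr_mutant": (ddr_summary["n_ddr_mutant"], n_total),
        "msi_high": (n_msi, n_total),
        "ge1_pat": (pat_summary["n_ge1_pat"], n_total),
    }
    if panel_ids:
        counts["fgfr_fusion"] = (n_fgfr, len(panel_ids))
    if aa_counts[1] > 0 and eligible_ids:
        counts["aa_signature_positive"] = aa_counts
    report_counts = summarize_counts(counts, paper_style=config.paper_style_percents)
    summary = {
        "version": __version__,
        "seed": config.seed,
        "n_total": n_total,
        "counts": report_counts,
        "n_non_tp53_ddr": ddr_summary["n_non_tp53"],
        "n_tp53_attributed_ddr": ddr_summary["n_tp53_attributed"],
        "median_wes_tmb": float(wes_tmb.median()) if len(wes_tmb) else None,
        "selected_n_signatures": selected_k,
        "signature_matches": (
            [(name, round(c, 3)) for name, c in signature_set.matches]
            if signature_set is not None else None
        ),
        "n_ge2_pat": pat_summary["n_ge2_pat"],
        "outcomes": outcome_summary,
    }

    result = PipelineResult(
        summary=summary,
        tmb_table=tmb_table,
        signature_set=signature_set,
        attribution=attribution,
        pairwise=pairwise,
        ddr_summary=ddr_summary,
        pat_summary=pat_summary,
        outcome_summary=outcome_summary,
    )
    if out_dir is not None:
        _write_artifacts(result, Path(out_dir))
    return result


def _pick_target_index(matches: list[tuple[str, float]], reference_name: str) -> int:
    """Index of the fitted signature matching the target reference name; if
    none matched by name, the best-cosine candidate against that name would
    already have surfaced in matches, so fall back to the highest-cosine
    profile."""
    for j, (name, _) in enumerate(matches):
        if name == reference_name:
            return j
    logger.warning("no fitted profile matched %s; using best-cosine profile", reference_name)
    return int(np.argmax([c for _, c in matches]))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def render_text_summary(summary: dict) -> str:
    """Human-readable block mirroring the report's headline sentences."""
    lines = [f"Cohort summary (n = {summary['n_total']})"]
    for name, c in summary["counts"].items():
        lines.append(
            f"  {name.replace('_', ' ')}: {c['n']} of {c['denominator']} ({c['display']})"
        )
    lines.append(
        f"  non-TP53 DDR mutants: {summary['n_non_tp53_ddr']} "
        f"(TP53-attributed: {summary['n_tp53_attributed_ddr']})"
    )
    if summary.get("median_wes_tmb") is not None:
        lines.append(f"  median WES TMB: {summary['median_wes_tmb']:.2f} Mut/Mb")
    out = summary.get("outcomes", {})
    if out.get("n_treated"):
        lines.append(
            f"  ORR: {out['n_responders']} of {out['n_treated']} ({out['orr_percent']}%)"
        )
        if out.get("benefit_percent") is not None:
            lines.append(
                f"  PFS2/PFS1 >= 1.3: {out['n_benefit']} of {out['n_ratio_defined']} "
                f"({out['benefit_percent']}%)"
            )
    return "\n".join(lines) + "\n"


def _write_artifacts(result: PipelineResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    result.tmb_table.to_csv(out_dir / "tmb.tsv", sep="\t", index=False)
    paths["tmb"] = "tmb.tsv"
    if result.signature_set is not None:
        ss = result.signature_set
        prof = pd.DataFrame(
            ss.profiles,
            index=pd.Index(["channel_%d" % i for i in range(96)]),
            columns=[f"signature_{j}" for j in range(ss.k)],
        )
        from .channels import SBS96_LABELS

        prof.index = pd.Index(list(SBS96_LABELS), name="channel")
        prof.to_csv(out_dir / "profiles.tsv", sep="\t")
        pd.DataFrame(
            ss.exposures, index=[f"signature_{j}" for j in range(ss.k)], columns=ss.sample_ids
        ).to_csv(out_dir / "exposures.tsv", sep="\t")
        paths["profiles"] = "profiles.tsv"
        paths["exposures"] = "exposures.tsv"
    if result.attribution is not None:
        result.attribution.to_csv(out_dir / "attribution.tsv", sep="\t", index=False)
        paths["attribution"] = "attribution.tsv"
    if result.pairwise is not None:
        result.pairwise.to_csv(out_dir / "pairwise_tests.tsv", sep="\t", index=False)
        paths["pairwise"] = "pairwise_tests.tsv"
    result.artifacts = paths
    summary = {**result.summary, "artifacts": paths}
    (out_dir / "summary.json").write_text(
        json.dumps(_jsonable(summary), indent=2, sort_keys=True) + "\n"
    )
    (out_dir / "summary.txt").write_text(render_text_summary(result.summary))
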