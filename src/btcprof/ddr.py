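"""DNA-damage-repair (DDR) mutation-status classification.

Samples are classified against a versioned gene -> pathway map covering
TP53 plus eight non-TP53 functional families (checkpoint factors, Fanconi
anemia, mismatch repair, homologous recombination, nucleotide excision
repair, base excision repair, non-homologous end joining, other DDR
factors); 47 genes in total in the shipped map.  A sample is DDR-mutant iff
it carries at least one qualifying (by default: non-synonymous) variant in a
mapped gene.  The four-way status distinguishes TP53-only involvement from
non-TP53 involvement; cohort summaries pool "both"-hit samples with the
non-TP53 group, so that TP53-attributed + non-TP53 = all DDR mutants.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from .cohort import NONSYNONYMOUS_CLASSES

EXPECTED_N_GENES = 47
EXPECTED_N_NON_TP53_PATHWAYS = 8

STATUSES = ("wild_type", "tp53_only", "non_tp53", "both")


@dataclass(frozen=True)
class DdrStatus:
    sample_id: str
    status: str
    pathways_hit: frozenset[str]


def load_ddr_map(path: str | Path | None = None, strict: bool = True) -> dict[str, str]:
    """Load the gene -> pathway map (default: the shipped 47-gene map).

    ``strict`` enforces the expected shape: 47 genes, TP53 in its own
    pathway, exactly 8 non-TP53 families.
    """
    if path is None:
        ref = resources.files("btcprof.data") / "ddr_genes.yaml"
        with resources.as_file(ref) as p:
            mapping = yaml.safe_load(p.read_text())
    else:
        mapping = yaml.safe_load(Path(path).read_text())
    if not isinstance(mapping, dict) or not all(
        isinstance(k, str) and isinstance(v, str) for k, v in mapping.items()
    ):
        raise ValueError("DDR map must be a flat gene: pathway mapping")
    if strict:
        if len(mapping) != EXPECTED_N_GENES:
            raise ValueError(f"DDR map must hold {EXPECTED_N_GENES} genes, got {len(mapping)}")
        if mapping.get("TP53") != "TP53":
            raise ValueError("DDR map must map TP53 to its own pathway")
        families = set(mapping.values()) - {"TP53"}
        if len(families) != EXPECTED_N_NON_TP53_PATHWAYS:
            raise ValueError(
                f"expected {EXPECTED_N_NON_TP53_PATHWAYS} non-TP53 pathways, got {len(families)}"
            )
    return dict(mapping)


def classify_ddr(
    sample_id: str,
    variants: pd.DataFrame,
    ddr_map: dict[str, str],
    classes: frozenset = NONSYNONYMOUS_CLASSES,
) -> DdrStatus:
    """Classify one sample from its variant rows (unmapped genes ignored)."""
    hit = variants[
        variants["variant_class"].isin(classes) & variants["gene"].isin(ddr_map)
    ]
    pathways = frozenset(ddr_map[g] for g in hit["gene"])
    tp53 = "TP53" in pathways
    non_tp53 = bool(pathways - {"TP53"})
    if tp53 and non_tp53:
        status = "both"
    elif tp53:
        status = "tp53_only"
    elif non_tp53:
        status = "non_tp53"
    else:
        status = "wild_type"
    return DdrStatus(sample_id=sample_id, status=status, pathways_hit=pathways)


def classify_cohort_ddr(
    variants: pd.DataFrame,
    sample_ids: list[str],
    ddr_map: dict[str, str],
    classes: frozenset = NONSYNONYMOUS_CLASSES,
) -> list[DdrStatus]:
    by_sample = dict(tuple(variants.groupby("sample_id"))) if len(variants) else {}
    empty = variants.iloc[0:0]
    return [
        classify_ddr(sid, by_sample.get(sid, empty), ddr_map, classes=classes)
        for sid in sample_ids
    ]


def summarize_ddr(statuses: list[DdrStatus]) -> dict:
    """Cohort DDR summary.

    ``n_tp53_attributed`` counts TP53-only samples; ``n_non_tp53`` counts
    samples with any non-TP53 pathway hit ("both" pooled here), so the two
    add up to ``n_ddr_mutant``.
    """
    if not statuses:
        raise ValueError("statuses must be non-empty")
    counts = {s: 0 for s in STATUSES}
    pathway_counts: dict[str, int] = {}
    for st in statuses:
        counts[st.status] += 1
        for pw in st.pathways_hit:
            pathway_counts[pw] = pathway_counts.get(pw, 0) + 1
    n = len(statuses)
    n_mutant = n - counts["wild_type"]
    summary = {
        "n_samples": n,
        "status_counts": counts,
        "n_ddr_mutant": n_mutant,
        "n_tp53_attributed": counts["tp53_only"],
        "n_non_tp53": counts["non_tp53"] + counts["both"],
        "pathway_counts": dict(sorted(pathway_counts.items())),
    }
    assert summary["n_tp53_attributed"] + summary["n_non_tp53"] == n_mutant
    return summary
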