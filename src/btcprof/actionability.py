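"""Rule-based precision-oncology actionability engine.

Patient alterations (somatic variants, copy-number calls, fusions, MSI-H
status) are matched against an editable knowledge base of targets graded on
two evidence scales, OncoKB levels and ESCAT tiers.  An alteration is a
potentially actionable target (PAT) when its evidence reaches OncoKB level
<= 3A or ESCAT tier <= II-B.  Because the two scales are incommensurate, a
single merged rank interleaves them (default order
``IA < L1 < IB < IC < L2 < IIA < IIB < L3A < L3B < IIIA < ...``), calibrated
so that ESCAT I-C (e.g. MSI-H / pembrolizumab) outranks OncoKB level-2
(e.g. ERBB2 amplification) — the tumor-board convention this engine encodes.

Molecular-tumor-board prioritization:

I.   PAT calls outrank everything else;
II.  among PATs, the best merged rank (i.e. the optimal evidence between the
     two scales) wins;
III. an EGFR call is suppressed unless the patient shows EGFR IHC 2+/3+
     overexpression.

Ties break alphabetically by target, so the ordering is total and
deterministic.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

logger = logging.getLogger(__name__)

ONCOKB_LEVELS = ("L1", "L2", "L3A", "L3B", "L4", "none")
ESCAT_TIERS = ("IA", "IB", "IC", "IIA", "IIB", "IIIA", "IIIB", "IV", "V", "none")
ALTERATION_CLASSES = (
    "activating_mutation",
    "truncating_mutation",
    "amplification",
    "deletion",
    "fusion",
    "msi_high",
)

PAT_ONCOKB = frozenset({"L1", "L2", "L3A"})
PAT_ESCAT = frozenset({"IA", "IB", "IC", "IIA", "IIB"})

DEFAULT_TIER_ORDER = [
    "IA", "L1", "IB", "IC", "L2", "IIA", "IIB", "L3A", "L3B", "IIIA", "IIIB",
    "L4", "IV", "V",
]

#: Variant classes mapped onto knowledge-base alteration classes.  Missense
#: and in-frame changes are treated as potentially activating; nonsense,
#: frameshift and splice changes as truncating.
VARIANT_CLASS_TO_ALTERATION = {
    "missense": "activating_mutation",
    "inframe_indel": "activating_mutation",
    "nonsense": "truncating_mutation",
    "frameshift_indel": "truncating_mutation",
    "splice": "truncating_mutation",
}


@dataclass(frozen=True)
class KnowledgeBaseEntry:
    target: str
    alteration_class: str
    oncokb_level: str = "none"
    escat_tier: str = "none"
    drug_hint: str = ""
    printed_label: str = ""
    allowed_loci: dict | None = None

    @property
    def is_pat(self) -> bool:
        return self.oncokb_level in PAT_ONCOKB or self.escat_tier in PAT_ESCAT


@dataclass
class KnowledgeBase:
    entries: list[KnowledgeBaseEntry]
    tier_order: list[str] = field(default_factory=lambda: list(DEFAULT_TIER_ORDER))

    def __post_init__(self) -> None:
        self._rank = {t: i for i, t in enumerate(self.tier_order)}
        self._index: dict[tuple[str, str], KnowledgeBaseEntry] = {}
        for e in self.entries:
            key = (e.target, e.alteration_class)
            if key in self._index:
                raise ValueError(f"duplicate knowledge-base entry for {key}")
            self._index[key] = e

    def lookup(self, target: str, alteration_class: str) -> KnowledgeBaseEntry | None:
        return self._index.get((target, alteration_class))

    def merged_rank(self, oncokb_level: str, escat_tier: str) -> int:
        """Best (lowest) position of the two evidence labels on the merged scale."""
        ranks = [self._rank[t] for t in (oncokb_level, escat_tier) if t != "none"]
        if not ranks:
            raise ValueError("both evidence labels are 'none'")
        return min(ranks)

    @property
    def pat_genes(self) -> list[str]:
        return sorted({e.target for e in self.entries if e.is_pat and e.target != "MSI-H"})


def load_knowledge_base(path: str | Path | None = None) -> KnowledgeBase:
    """Load and validate a knowledge-base YAML (default: the shipped base).

    The shipped default carries 19 PAT genes plus the MSI-H biomarker; the
    loaded PAT gene count is logged for auditability.
    """
    if path is None:
        ref = resources.files("btcprof.data") / "pat_kb.yaml"
        raw = yaml.safe_load(ref.read_text())
    else:
        raw = yaml.safe_load(Path(path).read_text())
    if not raw:
        warnings.warn("empty knowledge base", stacklevel=2)
        return KnowledgeBase(entries=[])
    tier_order = raw.get("tier_order", list(DEFAULT_TIER_ORDER))
    entries = []
    for item in raw.get("entries", []):
        onco = str(item.get("oncokb_level", "none"))
        escat = str(item.get("escat_tier", "none"))
        alt = str(item["alteration_class"])
        if onco not in ONCOKB_LEVELS:
            raise ValueError(f"unknown OncoKB level {onco!r} for {item['target']}")
        if escat not in ESCAT_TIERS:
            raise ValueError(f"unknown ESCAT tier {escat!r} for {item['target']}")
        if alt not in ALTERATION_CLASSES:
            raise ValueError(f"unknown alteration class {alt!r} for {item['target']}")
        if onco == "none" and escat == "none":
            raise ValueError(
                f"entry {item['target']}/{alt} must carry at least one evidence label"
            )
        entries.append(
            KnowledgeBaseEntry(
                target=str(item["target"]),
                alteration_class=alt,
                oncokb_level=onco,
                escat_tier=escat,
                drug_hint=str(item.get("drug_hint", "")),
                printed_label=str(item.get("printed_label", "")),
                allowed_loci=item.get("allowed_loci"),
            )
        )
    kb = KnowledgeBase(entries=entries, tier_order=tier_order)
    logger.info("knowledge base: %d entries, %d PAT genes", len(entries), len(kb.pat_genes))
    return kb


@dataclass(frozen=True)
class ActionabilityCall:
    patient_id: str
    target: str
    alteration_class: str
    oncokb_level: str
    escat_tier: str
    merged_rank: int
    is_pat: bool
    drug_hint: str = ""


def _locus_allowed(entry: KnowledgeBaseEntry, chrom: str, pos: int) -> bool:
    loci = entry.allowed_loci
    if not loci:
        return True
    if "chrom" in loci and str(chrom) != str(loci["chrom"]):
        return False
    return loci.get("min_pos", 0) <= pos <= loci.get("max_pos", 2**62)


def annotate_patient(
    patient_id: str,
    kb: KnowledgeBase,
    variants: pd.DataFrame | None = None,
    cnas: pd.DataFrame | None = None,
    fusions: pd.DataFrame | None = None,
    msi_high: bool = False,
) -> list[ActionabilityCall]:
    """All knowledge-base matches for one patient's alterations.

    One call per (alteration, matching entry); duplicates of the same
    (target, alteration class) collapse to one call.  No match yields an
    empty list.
    """
    seen: set[tuple[str, str]] = set()
    calls: list[ActionabilityCall] = []

    def emit(entry: KnowledgeBaseEntry) -> None:
        key = (entry.target, entry.alteration_class)
        if key in seen:
            return
        seen.add(key)
        calls.append(
            ActionabilityCall(
                patient_id=patient_id,
                target=entry.target,
                alteration_class=entry.alteration_class,
                oncokb_level=entry.oncokb_level,
                escat_tier=entry.escat_tier,
                merged_rank=kb.merged_rank(entry.oncokb_level, entry.escat_tier),
                is_pat=entry.is_pat,
                drug_hint=entry.drug_hint,
            )
        )

    if variants is not None:
        for _, row in variants.iterrows():
            alt_class = VARIANT_CLASS_TO_ALTERATION.get(row["variant_class"])
            if alt_class is None:
                continue
            entry = kb.lookup(row["gene"], alt_class)
            if entry is not None and _locus_allowed(entry, row["chrom"], int(row["pos"])):
                emit(entry)
    if cnas is not None:
        for _, row in cnas.iterrows():
            entry = kb.lookup(row["gene"], row["cna_type"])
            if entry is not None:
                emit(entry)
    if fusions is not None:
        for _, row in fusions.iterrows():
            for gene in (row["gene_5p"], row["gene_3p"]):
                entry = kb.lookup(gene, "fusion")
                if entry is not None:
                    emit(entry)
    if msi_high:
        entry = kb.lookup("MSI-H", "msi_high")
        if entry is not None:
            emit(entry)
    return calls


@dataclass
class Recommendation:
    patient_id: str
    ordered_calls: list[ActionabilityCall]
    top: ActionabilityCall | None


def prioritize(
    calls: list[ActionabilityCall],
    egfr_ihc_2plus: bool | None = None,
    include_off_pat: bool = False,
) -> Recommendation:
    """Order calls by the tumor-board rules and pick the top recommendation.

    Rule I: PAT calls outrank non-PAT; rule II: within each group the best
    merged rank wins; rule III: EGFR calls require IHC 2+/3+ overexpression
    and are dropped otherwise.  Non-PAT (off-PAT) calls are surfaced only
    with ``include_off_pat``.
    """
    patient_id = calls[0].patient_id if calls else ""
    kept = []
    for c in calls:
        if c.target == "EGFR" and not egfr_ihc_2plus:
            continue  # rule III
        if not c.is_pat and not include_off_pat:
            continue
        kept.append(c)
    ordered = sorted(kept, key=lambda c: (not c.is_pat, c.merged_rank, c.target))
    return Recommendation(
        patient_id=patient_id, ordered_calls=ordered, top=ordered[0] if ordered else None
    )


def summarize_pat_prevalence(
    calls_by_patient: dict[str, list[ActionabilityCall]],
    subtypes: dict[str, str] | None = None,
) -> dict:
    """Patient-level PAT prevalence: >=1 PAT, >=2 PATs, per-subtype and
    per-target fractions (over patients, not calls)."""
    from .pipeline import percent

    n = len(calls_by_patient)
    n_pats = {
        pid: len({(c.target, c.alteration_class) for c in calls if c.is_pat})
        for pid, calls in calls_by_patient.items()
    }
    n_ge1 = sum(1 for v in n_pats.values() if v >= 1)
    n_ge2 = sum(1 for v in n_pats.values() if v >= 2)
    per_target: dict[str, int] = {}
    for calls in calls_by_patient.values():
        for target in {c.target for c in calls if c.is_pat}:
            per_target[target] = per_target.get(target, 0) + 1
    summary = {
        "n_patients": n,
        "n_ge1_pat": n_ge1,
        "n_ge2_pat": n_ge2,
        "pct_ge1_pat": percent(n_ge1, n) if n else 0.0,
        "per_target_counts": dict(sorted(per_target.items())),
        "per_target_fractions": {
            t: (c / n if n else 0.0) for t, c in sorted(per_target.items())
        },
    }
    if subtypes is not None:  # per-subtype carrier fractions
        by_subtype: dict[str, list[int]] = {}
        for pid, npat in n_pats.items():
            by_subtype.setdefault(subtypes.get(pid, "unknown"), []).append(npat)
        summary["per_subtype_pct_ge1"] = {
            st: percent(sum(1 for v in vals if v >= 1), len(vals))
            for st, vals in sorted(by_subtype.items())
        }
    return summary
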