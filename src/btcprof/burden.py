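"""Tumor mutation burden (TMB) and hypermutation calling.

TMB is the number of counted somatic mutations divided by the size in Mb of
the sequenced target region.  Hypermutation is called against
platform-specific thresholds (whole-exome sequencing: >= 9.36 Mut/Mb;
targeted panel sequencing: >= 16.1 Mut/Mb, boundaries inclusive).  The
default counting rule includes nonsynonymous SNVs and indels and excludes
synonymous and noncoding classes; the rule is configurable because different
platforms count differently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import NONSYNONYMOUS_CLASSES

#: Platform-specific hypermutation thresholds in Mut/Mb (inclusive).
HYPERMUTATION_THRESHOLDS = {"WES": 9.36, "TPS": 16.1}

#: Named counting rules: which variant_class values contribute to TMB.
COUNTING_RULES = {
    "nonsynonymous": NONSYNONYMOUS_CLASSES,
    "all": None,  # every variant row counts
}


@dataclass(frozen=True)
class TmbRecord:
    sample_id: str
    n_counted_mutations: int
    region_size_mb: float
    tmb: float
    platform: str
    hypermutated: bool | None = None


def count_mutations(
    variants: pd.DataFrame,
    counting_rule: str = "nonsynonymous",
    min_vaf: float | None = None,
) -> int:
    """Count variant rows passing the counting rule (and optional VAF floor)."""
    if counting_rule not in COUNTING_RULES:
        raise ValueError(f"unknown counting rule: {counting_rule!r}")
    keep = pd.Series(True, index=variants.index)
    allowed = COUNTING_RULES[counting_rule]
    if allowed is not None:
        keep &= variants["variant_class"].isin(allowed)
    if min_vaf is not None:
        vaf = pd.to_numeric(variants["vaf"], errors="coerce")
        keep &= vaf >= min_vaf
    return int(keep.sum())


def compute_tmb(
    sample_id: str,
    variants: pd.DataFrame,
    region_size_mb: float,
    platform: str,
    counting_rule: str = "nonsynonymous",
    min_vaf: float | None = None,
) -> TmbRecord:
    """Per-sample TMB in Mut/Mb (hypermutation flag left unset).

    ``variants`` holds this sample's rows only; ``region_size_mb`` must be
    positive (it is mandatory — neither platform has a universal region size).
    """
    if region_size_mb <= 0:
        raise ValueError(f"region_size_mb must be > 0, got {region_size_mb}")
    n = count_mutations(variants, counting_rule=counting_rule, min_vaf=min_vaf)
    return TmbRecord(
        sample_id=sample_id,
        n_counted_mutations=n,
        region_size_mb=float(region_size_mb),
        tmb=n / region_size_mb,
        platform=platform,
    )


def call_hypermutation(tmb: float, platform: str) -> bool:
    """True when ``tmb`` reaches the platform's hypermutation threshold."""
    if tmb < 0:
        raise ValueError("tmb must be >= 0")
    try:
        threshold = HYPERMUTATION_THRESHOLDS[platform]
    except KeyError:
        raise ValueError(f"unknown platform: {platform!r}") from None
    return tmb >= threshold


def cohort_tmb(
    cohort_variants: pd.DataFrame,
    clinical: pd.DataFrame,
    wes_region_mb: float,
    tps_region_mb: float,
    counting_rule: str = "nonsynonymous",
    min_vaf: float | None = None,
) -> pd.DataFrame:
    """TMB + hypermutation call for every sample in ``clinical``.

    Samples without variant rows get TMB 0.  Returns one row per sample with
    columns sample_id, platform, n_counted_mutations, region_size_mb, tmb,
    hypermutated.
    """
    region = {"WES": wes_region_mb, "TPS": tps_region_mb}
    for plat, mb in region.items():
        if mb <= 0:
            raise ValueError(f"{plat} region size must be > 0, got {mb}")
    by_sample = dict(tuple(cohort_variants.groupby("sample_id"))) if len(cohort_variants) else {}
    empty = cohort_variants.iloc[0:0]
    rows = []
    for _, rec in clinical.iterrows():
        sid, plat = rec["sample_id"], rec["platform"]
        r = compute_tmb(
            sid,
            by_sample.get(sid, empty),
            region[plat],
            plat,
            counting_rule=counting_rule,
            min_vaf=min_vaf,
        )
        rows.append(
            {
                "sample_id": sid,
                "platform": plat,
                "n_counted_mutations": r.n_counted_mutations,
                "region_size_mb": r.region_size_mb,
                "tmb": r.tmb,
                "hypermutated": call_hypermutation(r.tmb, plat),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id",
            "platform",
            "n_counted_mutations",
            "region_size_mb",
            "tmb",
            "hypermutated",
        ],
    )


def platform_concordance(paired_values: list[tuple[float, float]] | np.ndarray) -> float:
    """Squared Pearson correlation (R^2) between paired TMB measurements.

    Used for WES-vs-panel concordance on samples sequenced by both platforms.
    """
    arr = np.asarray(paired_values, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValueError("need at least 2 (x, y) pairs")
    x, y = arr[:, 0], arr[:, 1]
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("zero variance in paired measurements")
    r = stats.pearsonr(x, y).statistic
    return float(r * r)
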