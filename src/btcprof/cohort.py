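"""Tabular cohort data model and TSV round-trip IO.

A cohort is five tab-separated UTF-8 tables sharing ``sample_id`` as the
foreign key into the clinical table:

* ``variants.tsv``   — somatic small variants (minimal MAF dialect, 1-based
  inclusive coordinates)
* ``cnas.tsv``       — gene-level copy-number calls
* ``fusions.tsv``    — fusion events (5' / 3' partner genes)
* ``clinical.tsv``   — one row per patient: subtype, stage, hepatitis status,
  sequencing platform, MSI status, EGFR IHC flag, germline pathogenic genes
* ``outcomes.tsv``   — therapy outcomes for the treated subset (RECIST best
  response, PFS1/PFS2)

Missing values are empty strings, booleans are ``true``/``false`` literals,
and every table has a deterministic column order and row sort so that written
cohorts are diffable and round-trip exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

VARIANT_CLASSES = frozenset(
    {
        "missense",
        "nonsense",
        "frameshift_indel",
        "inframe_indel",
        "splice",
        "synonymous",
        "TERT_promoter",
        "other_noncoding",
    }
)
#: Classes counted as protein-altering by default TMB / DDR / driver rules.
NONSYNONYMOUS_CLASSES = frozenset(
    {"missense", "nonsense", "frameshift_indel", "inframe_indel", "splice"}
)
CNA_TYPES = frozenset({"amplification", "deletion"})
SUBTYPES = frozenset({"ICC", "ECC", "GBC"})
STAGES = frozenset({"I", "II", "III_IV", "unknown"})
HEPATITIS = frozenset({"positive", "negative", "unknown"})
PLATFORMS = frozenset({"WES", "TPS"})
BEST_RESPONSES = frozenset({"CR", "PR", "SD", "PD"})

VARIANT_COLUMNS = [
    "sample_id",
    "gene",
    "chrom",
    "pos",
    "ref",
    "alt",
    "variant_class",
    "vaf",
    "context_channel",
]
CNA_COLUMNS = ["sample_id", "gene", "cna_type", "cytoband"]
FUSION_COLUMNS = ["sample_id", "gene_5p", "gene_3p"]
CLINICAL_COLUMNS = [
    "sample_id",
    "subtype",
    "stage",
    "hepatitis",
    "platform",
    "msi_high",
    "egfr_ihc_2plus",
    "germline_pathogenic_genes",
]
OUTCOME_COLUMNS = [
    "patient_id",
    "matched_target",
    "best_response",
    "pfs2_months",
    "pfs2_event",
    "pfs1_months",
]

TABLE_FILES = {
    "variants": "variants.tsv",
    "cnas": "cnas.tsv",
    "fusions": "fusions.tsv",
    "clinical": "clinical.tsv",
    "outcomes": "outcomes.tsv",
}
_TABLE_COLUMNS = {
    "variants": VARIANT_COLUMNS,
    "cnas": CNA_COLUMNS,
    "fusions": FUSION_COLUMNS,
    "clinical": CLINICAL_COLUMNS,
    "outcomes": OUTCOME_COLUMNS,
}
#: Recorded in each variants.tsv header so the convention travels with the file.
_COORDINATE_COMMENT = "# coordinates: 1-based inclusive (MAF convention)"


class CohortSchemaError(ValueError):
    """A table is missing a required column or carries an invalid value."""


class CohortReferentialError(ValueError):
    """A child table references a sample_id absent from the clinical table."""


def _empty_table(name: str) -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=object) for c in _TABLE_COLUMNS[name]})


@dataclass
class Cohort:
    """In-memory cohort: five cross-validated pandas tables."""

    variants: pd.DataFrame = field(default_factory=lambda: _empty_table("variants"))
    cnas: pd.DataFrame = field(default_factory=lambda: _empty_table("cnas"))
    fusions: pd.DataFrame = field(default_factory=lambda: _empty_table("fusions"))
    clinical: pd.DataFrame = field(default_factory=lambda: _empty_table("clinical"))
    outcomes: pd.DataFrame = field(default_factory=lambda: _empty_table("outcomes"))

    @property
    def n_samples(self) -> int:
        return len(self.clinical)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.clinical["sample_id"])

    def table(self, name: str) -> pd.DataFrame:
        return getattr(self, name)

    def validate(self) -> None:
        validate_cohort(self)


def _require_columns(df: pd.DataFrame, name: str) -> None:
    missing = [c for c in _TABLE_COLUMNS[name] if c not in df.columns]
    if missing:
        raise CohortSchemaError(f"{name} table is missing column(s): {', '.join(missing)}")


def _check_enum(series: pd.Series, allowed: frozenset, what: str, allow_missing=False) -> None:
    values = series.dropna()
    if allow_missing:
        values = values[values != ""]
    bad = sorted(set(values) - allowed)
    if bad:
        raise CohortSchemaError(f"invalid {what} value(s): {bad}")


def validate_cohort(cohort: Cohort) -> None:
    """Check schemas, enum domains, row-level invariants and referential integrity.

    Raises on the first violated invariant; never silently drops rows.
    """
    for name in TABLE_FILES:
        _require_columns(cohort.table(name), name)

    clin = cohort.clinical
    if clin["sample_id"].duplicated().any():
        dups = sorted(clin.loc[clin["sample_id"].duplicated(), "sample_id"])
        raise CohortSchemaError(f"duplicate sample_id in clinical table: {dups}")
    _check_enum(clin["subtype"], SUBTYPES, "subtype")
    _check_enum(clin["stage"], STAGES, "stage")
    _check_enum(clin["hepatitis"], HEPATITIS, "hepatitis")
    _check_enum(clin["platform"], PLATFORMS, "platform")

    var = cohort.variants
    if len(var):
        _check_enum(var["variant_class"], VARIANT_CLASSES, "variant_class")
        pos = pd.to_numeric(var["pos"])
        if (pos < 1).any():
            raise CohortSchemaError("variant pos must be >= 1 (1-based coordinates)")
        if (var["ref"] == var["alt"]).any():
            raise CohortSchemaError("variant with ref == alt")
        vaf = pd.to_numeric(var["vaf"], errors="coerce")
        present = var["vaf"].notna() & (var["vaf"].astype(str) != "")
        if ((vaf[present] < 0) | (vaf[present] > 1)).any():
            raise CohortSchemaError("vaf outside [0, 1]")
        is_snv = (var["ref"].str.len() == 1) & (var["alt"].str.len() == 1)
        has_channel = var["context_channel"].notna() & (
            var["context_channel"].astype(str) != ""
        )
        if (has_channel & ~is_snv).any():
            raise CohortSchemaError("context_channel set on a non-SNV row")
        chan = pd.to_numeric(var.loc[has_channel, "context_channel"], errors="raise")
        if len(chan) and ((chan < 0) | (chan > 95)).any():
            raise CohortSchemaError("context_channel outside 0-95")

    if len(cohort.cnas):
        _check_enum(cohort.cnas["cna_type"], CNA_TYPES, "cna_type")
    fus = cohort.fusions
    if len(fus) and (fus["gene_5p"] == fus["gene_3p"]).any():
        genes = sorted(set(fus.loc[fus["gene_5p"] == fus["gene_3p"], "gene_5p"]))
        warnings.warn(
            f"intragenic rearrangement(s) with gene_5p == gene_3p: {genes}",
            stacklevel=2,
        )
    if len(cohort.outcomes):
        _check_enum(cohort.outcomes["best_response"], BEST_RESPONSES, "best_response")

    known = set(clin["sample_id"])
    for name, key in (
        ("variants", "sample_id"),
        ("cnas", "sample_id"),
        ("fusions", "sample_id"),
        ("outcomes", "patient_id"),
    ):
        df = cohort.table(name)
        if not len(df):
            continue
        orphans = sorted(set(df[key]) - known)
        if orphans:
            raise CohortReferentialError(
                f"{name} table references unknown sample_id(s): {orphans}"
            )


_SORT_KEYS = {
    "variants": ["sample_id", "chrom", "pos", "gene", "alt"],
    "cnas": ["sample_id", "gene", "cna_type"],
    "fusions": ["sample_id", "gene_5p", "gene_3p"],
    "clinical": ["sample_id"],
    "outcomes": ["patient_id"],
}


def _format_value(v) -> str:
    if v is None or (isinstance(v, float) and pd.isna(v)):
        return ""
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, float) and v == int(v) and abs(v) < 1e15:
        return repr(v)
    return str(v)


def write_cohort(cohort: Cohort, directory: str | Path) -> dict[str, Path]:
    """Write the five tables under ``directory`` with deterministic order.

    Returns the mapping table name -> written path.  The cohort is validated
    first; an empty cohort yields five header-only files.
    """
    validate_cohort(cohort)
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for name, fname in TABLE_FILES.items():
        df = cohort.table(name)[_TABLE_COLUMNS[name]].copy()
        if len(df):
            sort_cols = _SORT_KEYS[name]
            if name == "variants":
                df["pos"] = pd.to_numeric(df["pos"]).astype(int)
            df = df.sort_values(sort_cols, kind="mergesort").reset_index(drop=True)
        out = df.map(_format_value)
        path = directory / fname
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            if name == "variants":
                fh.write(_COORDINATE_COMMENT + "\n")
            out.to_csv(fh, sep="\t", index=False)
        written[name] = path
    return written


def _parse_bool(s: str):
    if s == "" or s is None:
        return None
    if s not in ("true", "false"):
        raise CohortSchemaError(f"boolean column carries {s!r}, expected true/false")
    return s == "true"


def _read_table(path: Path, name: str) -> pd.DataFrame:
    if not path.exists():
        raise FileNotFoundError(f"missing cohort table: {path}")
    df = pd.read_csv(
        path, sep="\t", dtype=str, comment="#", keep_default_na=False, na_values=[]
    )
    _require_columns(df, name)
    df = df[_TABLE_COLUMNS[name]]
    if name == "variants" and len(df):
        df["pos"] = pd.to_numeric(df["pos"]).astype(int)
        df["vaf"] = pd.to_numeric(df["vaf"].replace("", None))
        df["context_channel"] = pd.to_numeric(df["context_channel"].replace("", None))
    if name == "clinical" and len(df):
        df["msi_high"] = df["msi_high"].map(_parse_bool)
        df["egfr_ihc_2plus"] = df["egfr_ihc_2plus"].map(_parse_bool)
    if name == "outcomes" and len(df):
        df["pfs2_months"] = pd.to_numeric(df["pfs2_months"].replace("", None))
        df["pfs1_months"] = pd.to_numeric(df["pfs1_months"].replace("", None))
        df["pfs2_event"] = df["pfs2_event"].map(_parse_bool)
    return df


def read_cohort(directory: str | Path) -> Cohort:
    """Read and cross-validate a cohort directory written by :func:`write_cohort`."""
    directory = Path(directory)
    tables = {
        name: _read_table(directory / fname, name) for name, fname in TABLE_FILES.items()
    }
    cohort = Cohort(**tables)
    validate_cohort(cohort)
    return cohort


#: default column mapping for importing standard MAF files; override any
#: entry to match a local dialect
MAF_COLUMN_MAP = {
    "Tumor_Sample_Barcode": "sample_id",
    "Hugo_Symbol": "gene",
    "Chromosome": "chrom",
    "Start_Position": "pos",
    "Reference_Allele": "ref",
    "Tumor_Seq_Allele2": "alt",
    "Variant_Classification": "variant_class",
}

#: MAF Variant_Classification values folded onto the internal class enum
MAF_CLASS_MAP = {
    "Missense_Mutation": "missense",
    "Nonsense_Mutation": "nonsense",
    "Frame_Shift_Del": "frameshift_indel",
    "Frame_Shift_Ins": "frameshift_indel",
    "In_Frame_Del": "inframe_indel",
    "In_Frame_Ins": "inframe_indel",
    "Splice_Site": "splice",
    "Silent": "synonymous",
    "5'Flank": "other_noncoding",
    "3'UTR": "other_noncoding",
    "5'UTR": "other_noncoding",
    "Intron": "other_noncoding",
    "IGR": "other_noncoding",
    "Nonstop_Mutation": "missense",
    "Translation_Start_Site": "other_noncoding",
}


def import_maf(
    path: str | Path,
    column_map: dict[str, str] | None = None,
    class_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Import a standard MAF file into the internal variant table.

    Column and class mappings default to the common MAF dialect and are
    fully overridable.  All classes are kept — downstream stages apply
    their own counting rules.  VAF and context_channel are left missing
    (most MAFs do not carry a trinucleotide context).
    """
    cmap = {**MAF_COLUMN_MAP, **(column_map or {})}
    kmap = {**MAF_CLASS_MAP, **(class_map or {})}
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, low_memory=False)
    missing = [c for c in cmap if c not in df.columns]
    if missing:
        raise CohortSchemaError(f"MAF is missing column(s): {', '.join(missing)}")
    out = df[list(cmap)].rename(columns=cmap)
    unknown = sorted(set(out["variant_class"]) - set(kmap))
    if unknown:
        raise CohortSchemaError(
            f"unmapped Variant_Classification value(s): {unknown}; extend class_map"
        )
    out["variant_class"] = out["variant_class"].map(kmap)
    out["pos"] = pd.to_numeric(out["pos"]).astype(int)
    out["vaf"] = None
    out["context_channel"] = None
    return out[VARIANT_COLUMNS]


def germline_genes(record_value: str | None) -> list[str]:
    """Split the comma-separated germline gene list field ('' -> [])."""
    if record_value is None or record_value == "" or pd.isna(record_value):
        return []
    return [g for g in str(record_value).split(",") if g]
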