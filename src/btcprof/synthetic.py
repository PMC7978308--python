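"""Synthetic cohort generator with planted ground truth.

Every downstream stage of the pipeline is testable against cohorts drawn
from a generative model whose defaults encode the published cohort facts:
subtype and platform composition, a log-normal TMB distribution (median
1.23 Mut/Mb, IQR 0.7-2.34) with a separate hypermutated tail component at
4.1%, driver-gene frequencies (TP53 53%, KRAS 26%, ARID1A 18%, ...) with
pairwise co-occurrence/exclusivity planted through odds-ratio-tilted
Bernoulli pairs (marginals preserved exactly via the Plackett construction),
trinucleotide channels drawn from planted signature mixtures including an
SBS22-like aristolochic-acid profile, actionable alterations at printed
prevalences, 12% germline pathogenic carriers, 1.2% MSI-H, and exponential
progression-free survival with censoring.

``generate_cohort`` returns the cohort together with a ``truth`` mapping of
every planted quantity, so recovery tests never have to re-derive the
ground truth from the data.

Design notes:

* Non-hypermutated background TMB is truncated below 80% of the platform
  calling threshold and the hypermutated component starts 10% above it, so
  planted hypermutation labels are identifiable rather than ambiguous at
  the boundary.
* Mutation counts are TMB x platform region size with stochastic rounding;
  driver mutations are added on top (negligible for the 38 Mb exome, and
  panel TMB is never used for distribution-recovery checks).
* Per-sample signature exposures: aristolochic-acid-negative samples mix
  the background profiles with Dirichlet weights; positive samples draw the
  target exposure uniformly from ``aa_exposure_range`` and split the rest
  with the same Dirichlet.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .burden import HYPERMUTATION_THRESHOLDS
from .cohort import Cohort
from .channels import SBS96_LABELS
from .signatures import load_reference_catalog

# log-normal matching the printed WES TMB distribution:
# median 1.23 -> mu = ln 1.23; IQR 0.7-2.34 -> sigma = ln(2.34/0.7) / (2 * 0.6745)
TMB_LOG_MEAN = math.log(1.23)
TMB_LOG_SD = math.log(2.34 / 0.7) / (2 * 0.674489750196082)

DEFAULT_GENE_FREQS = {
    "TP53": 0.53,
    "KRAS": 0.26,
    "ARID1A": 0.18,
    "LRP1B": 0.14,
    "CDKN2A": 0.14,
    "SMAD4": 0.10,
    "ATM": 0.09,
    "BRCA2": 0.07,
    "PRKDC": 0.06,
    "IDH1": 0.05,
    "ATR": 0.05,
    "POLE": 0.04,
    "BRCA1": 0.03,
    "PIK3CA": 0.02,
    "MLH1": 0.02,
    "EGFR": 0.015,
}
#: log-odds of co-mutation for disjoint gene pairs (Plackett-tilted Bernoullis)
DEFAULT_PAIR_EFFECTS = {("TP53", "KRAS"): 0.9, ("IDH1", "ARID1A"): -1.5}

#: genes whose planted mutations are truncating with this probability
#: (the rest are missense); unlisted driver genes are always missense
TRUNCATING_PROB = {"BRCA1": 0.3, "BRCA2": 0.3, "ARID1A": 0.5, "SMAD4": 0.3}

#: copy-number / fusion actionable alterations: target -> (class, frequency);
#: fusions are planted only in panel (TPS) samples, mirroring a fusion-capable
#: panel assay
DEFAULT_PAT_SPEC = {
    "ERBB2": ("amplification", 0.05),
    "MET": ("amplification", 0.05),
    "CDK4": ("amplification", 0.02),
    "FGFR2": ("fusion", 0.033),
    "FGFR3": ("fusion", 0.007),
    "NTRK1": ("fusion", 0.004),
}

DEFAULT_GERMLINE_SPEC = {
    "PRSS1": 0.0300,
    "BRCA2": 0.0125,
    "MUTYH": 0.0112,
    "BRCA1": 0.0100,
    "SPINK1": 0.0100,
    "ATM": 0.0080,
    "CHEK2": 0.0080,
    "MSH2": 0.0060,
    "PALB2": 0.0060,
    "FANCA": 0.0050,
    "RAD51C": 0.0050,
    "TP53": 0.0040,
    "MLH1": 0.0040,
    "BRIP1": 0.0040,
    "NBN": 0.0040,
}

#: EGFR window used for planted activating mutations (inside the shipped
#: knowledge-base locus constraint)
_EGFR_LOCUS = ("7", 55241614, 55279321)


@dataclass
class OutcomeSpec:
    """Therapy-outcome generative settings.

    ``median_pfs1_months`` defaults to the value that makes the planted
    benefit probability P(PFS2/PFS1 >= 1.3) equal ``benefit_frac`` under the
    exponential model with censoring (see docs).
    """

    median_pfs2_months: float = 5.0
    responder_frac: float = 12 / 46
    pfs1_missing_frac: float = 9 / 46
    benefit_frac: float = 21 / 37
    censor_ratio: float = 4.0  # censoring median / event median for PFS2
    treated_frac: float = 46 / 204  # treated among PAT carriers
    median_pfs1_months: float | None = None

    def derived_median_pfs1(self) -> float:
        if self.median_pfs1_months is not None:
            return self.median_pfs1_months
        b = self.benefit_frac
        # observed (event) PFS2 is Exp with rate inflated by censoring
        inflation = 1.0 + 1.0 / self.censor_ratio
        return self.median_pfs2_months * (1 - b) / (1.3 * b * inflation)


@dataclass
class CohortConfig:
    """All knobs of the generator; defaults are the study-like conditions."""

    n_samples: int
    seed: int
    subtype_props: dict = field(
        default_factory=lambda: {"ICC": 475 / 803, "ECC": 164 / 803, "GBC": 164 / 803}
    )
    platform_props: dict = field(
        default_factory=lambda: {"WES": 160 / 803, "TPS": 643 / 803}
    )
    tmb_log_mean: float = TMB_LOG_MEAN
    tmb_log_sd: float = TMB_LOG_SD
    hypermutated_frac: float = 33 / 803
    wes_region_mb: float = 38.0
    tps_region_mb: float = 1.5
    gene_freqs: dict = field(default_factory=lambda: dict(DEFAULT_GENE_FREQS))
    pair_effects: dict = field(default_factory=lambda: dict(DEFAULT_PAIR_EFFECTS))
    signature_names: tuple = ("SBS1", "SBS22", "SBS40")
    aa_signature_index: int = 1
    signature_profiles: np.ndarray | None = None  # 96 x k; default from toy catalog
    exposure_dirichlet: tuple = (2.0, 2.0)  # over the non-target signatures
    aa_positive_frac: float = 53 / 148
    aa_exposure_range: tuple = (0.35, 0.75)
    snv_frac: float = 0.85  # counted mutations that are SNVs (rest indels)
    synonymous_extra_frac: float = 0.3  # extra synonymous rows per counted SNV
    pat_spec: dict = field(default_factory=lambda: dict(DEFAULT_PAT_SPEC))
    msi_frac: float = 10 / 803
    germline_spec: dict = field(default_factory=lambda: dict(DEFAULT_GERMLINE_SPEC))
    outcome_spec: OutcomeSpec = field(default_factory=OutcomeSpec)

    def resolved_profiles(self) -> np.ndarray:
        if self.signature_profiles is not None:
            P = np.asarray(self.signature_profiles, dtype=float)
        else:
            ref = load_reference_catalog()
            P = ref[list(self.signature_names)].to_numpy()
        if P.shape[0] != 96:
            raise ValueError("signature profiles must live on the 96-channel axis")
        if (P < 0).any():
            raise ValueError("signature profile with negative entry")
        if not np.allclose(P.sum(axis=0), 1.0, atol=1e-6):
            raise ValueError("signature profiles must each sum to 1")
        return P

    def validate(self) -> None:
        if self.n_samples < 0:
            raise ValueError("n_samples must be >= 0")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name, props in (("subtype_props", self.subtype_props), ("platform_props", self.platform_props)):
            total = sum(props.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1, got {total}")
            if any(p < 0 for p in props.values()):
                raise ValueError(f"{name} has a negative entry")
        for name, frac in (
            ("hypermutated_frac", self.hypermutated_frac),
            ("aa_positive_frac", self.aa_positive_frac),
            ("msi_frac", self.msi_frac),
            ("snv_frac", self.snv_frac),
        ):
            if not 0 <= frac <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        for gene, freq in self.gene_freqs.items():
            if not 0 <= freq <= 1:
                raise ValueError(f"gene_freqs[{gene}] must lie in [0, 1]")
        seen: set[str] = set()
        for pair in self.pair_effects:
            a, b = pair
            if a not in self.gene_freqs or b not in self.gene_freqs:
                raise ValueError(f"pair effect references unplanted gene: {pair}")
            if a in seen or b in seen:
                raise ValueError("pair_effects must involve disjoint gene pairs")
            seen.update(pair)
        self.resolved_profiles()


def _stochastic_round(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    lo = np.floor(x)
    return (lo + (rng.random(x.shape) < (x - lo))).astype(int)


def _truncated_lognormal_below(
    rng: np.random.Generator, mu: float, sd: float, upper: np.ndarray, size: int
) -> np.ndarray:
    """Log-normal draws conditioned on X < upper (element-wise), via inverse CDF."""
    from scipy.stats import norm

    z_up = (np.log(upper) - mu) / sd
    u = rng.random(size) * norm.cdf(z_up)
    return np.exp(mu + sd * norm.ppf(np.maximum(u, 1e-12)))


def _plackett_joint(p_a: float, p_b: float, log_odds: float) -> np.ndarray:
    """2x2 joint with given marginals and odds ratio exp(log_odds).

    Returns probabilities [p11, p10, p01, p00].
    """
    psi = math.exp(log_odds)
    if abs(psi - 1.0) < 1e-12:
        p11 = p_a * p_b
    else:
        s = 1.0 + (p_a + p_b) * (psi - 1.0)
        disc = s * s - 4.0 * psi * (psi - 1.0) * p_a * p_b
        p11 = (s - math.sqrt(max(disc, 0.0))) / (2.0 * (psi - 1.0))
    p11 = min(max(p11, 0.0), min(p_a, p_b))
    return np.array([p11, p_a - p11, p_b - p11, 1.0 - p_a - p_b + p11])


def sample_mutation_channels(
    signature_profiles: np.ndarray,
    exposure: np.ndarray,
    n_mut: int,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Draw ``n_mut`` channel indices from the mixture sum_j exposure_j * profile_j."""
    P = np.asarray(signature_profiles, dtype=float)
    e = np.asarray(exposure, dtype=float)
    if (P < 0).any():
        raise ValueError("signature profile with negative entry")
    if n_mut < 0:
        raise ValueError("n_mut must be >= 0")
    if abs(e.sum() - 1.0) > 1e-6:
        raise ValueError("exposure must sum to 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mixture = P @ e
    mixture = np.maximum(mixture, 0)
    mixture /= mixture.sum()
    if n_mut == 0:
        return np.empty(0, dtype=int)
    return rng.choice(96, size=n_mut, p=mixture)


def _channel_ref_alt(channel: int) -> tuple[str, str]:
    label = SBS96_LABELS[channel]
    return label[2], label[4]  # X and Y of "F[X>Y]T"


def simulate_outcomes(
    patient_ids: list[str],
    spec: OutcomeSpec,
    seed: int | np.random.Generator,
    matched_targets: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Therapy outcome rows for the given (treated) patients.

    PFS2 is exponential with the configured median, administratively
    censored by an independent exponential; PFS1 is exponential with the
    (derived) PFS1 median and missing with probability
    ``pfs1_missing_frac``; best response is CR/PR with probability
    ``responder_frac`` (CR for ~15% of responders).
    """
    if not 0 <= spec.responder_frac <= 1 or not 0 <= spec.pfs1_missing_frac <= 1:
        raise ValueError("responder_frac and pfs1_missing_frac must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    scale2 = spec.median_pfs2_months / math.log(2)
    scale1 = spec.derived_median_pfs1() / math.log(2)
    rows = []
    for pid in patient_ids:
        event_t = rng.exponential(scale2)
        censor_t = rng.exponential(scale2 * spec.censor_ratio)
        pfs2 = max(min(event_t, censor_t), 1e-3)
        event = bool(event_t <= censor_t)
        if rng.random() < spec.pfs1_missing_frac:
            pfs1 = None
        else:
            pfs1 = max(rng.exponential(scale1), 1e-3)
        if rng.random() < spec.responder_frac:
            best = "CR" if rng.random() < 0.15 else "PR"
        else:
            best = "SD" if rng.random() < 0.5 else "PD"
        rows.append(
            {
                "patient_id": pid,
                "matched_target": (matched_targets or {}).get(pid, ""),
                "best_response": best,
                "pfs2_months": round(pfs2, 4),
                "pfs2_event": event,
                "pfs1_months": None if pfs1 is None else round(pfs1, 4),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id",
            "matched_target",
            "best_response",
            "pfs2_months",
            "pfs2_event",
            "pfs1_months",
        ],
    )


def _sample_gene_statuses(
    config: CohortConfig, n: int, rng: np.random.Generator
) -> pd.DataFrame:
    """Genes x samples boolean matrix honoring marginals and pair effects."""
    genes = list(config.gene_freqs)
    status = pd.DataFrame(False, index=genes, columns=range(n))
    paired = {g for pair in config.pair_effects for g in pair}
    for (ga, gb), lam in config.pair_effects.items():
        joint = _plackett_joint(config.gene_freqs[ga], config.gene_freqs[gb], lam)
        draw = rng.choice(4, size=n, p=joint)
        status.loc[ga] = np.isin(draw, (0, 1))
        status.loc[gb] = np.isin(draw, (0, 2))
    for g in genes:
        if g not in paired:
            status.loc[g] = rng.random(n) < config.gene_freqs[g]
    return status


def generate_cohort(config: CohortConfig) -> tuple[Cohort, dict]:
    """Draw a full synthetic cohort plus its planted truth.

    Reproducible given the config seed; ``n_samples = 0`` yields an empty
    cohort and empty truths.
    """
    config.validate()
    n = config.n_samples
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    profiles = config.resolved_profiles()
    k = profiles.shape[1]
    t_idx = config.aa_signature_index
    if not 0 <= t_idx < k:
        raise ValueError("aa_signature_index out of range")
    sample_ids = [f"S{i:05d}" for i in range(n)]

    subtype_names = list(config.subtype_props)
    subtypes = rng.choice(subtype_names, size=n, p=list(config.subtype_props.values()))
    platform_names = list(config.platform_props)
    platforms = rng.choice(platform_names, size=n, p=list(config.platform_props.values()))
    region = np.where(platforms == "WES", config.wes_region_mb, config.tps_region_mb)
    thresholds = np.array([HYPERMUTATION_THRESHOLDS[p] for p in platforms])

    hyper = rng.random(n) < config.hypermutated_frac
    if config.hypermutated_frac > 0.5 and np.exp(config.tmb_log_mean) < thresholds.min():
        import warnings

        warnings.warn(
            "hypermutated_frac is high relative to the background TMB scale; "
            "the two components may be hard to distinguish", stacklevel=2,
        )
    tmb = np.empty(n)
    n_bg = int((~hyper).sum())
    if n_bg:
        tmb[~hyper] = _truncated_lognormal_below(
            rng, config.tmb_log_mean, config.tmb_log_sd, 0.8 * thresholds[~hyper], n_bg
        )
    n_hyper = int(hyper.sum())
    if n_hyper:
        tmb[hyper] = thresholds[hyper] * (1.1 + rng.exponential(0.8, size=n_hyper))

    n_counted = _stochastic_round(tmb * region, rng)
    gene_status = _sample_gene_statuses(config, n, rng)
    msi = rng.random(n) < config.msi_frac

    # aristolochic-acid positivity planted among attribution-eligible samples
    eligible = (platforms == "WES") & (subtypes == "ICC") & ~hyper
    aa_pos = eligible & (rng.random(n) < config.aa_positive_frac)
    conc = np.asarray(config.exposure_dirichlet, dtype=float)
    if conc.shape != (k - 1,):
        raise ValueError("exposure_dirichlet must cover the non-target signatures")
    exposures = np.zeros((k, n))
    non_target = [j for j in range(k) if j != t_idx]
    bg_weights = rng.dirichlet(conc, size=n)
    aa_frac = np.where(
        aa_pos, rng.uniform(*config.aa_exposure_range, size=n), 0.0
    )
    exposures[t_idx] = aa_frac
    for i, j in enumerate(non_target):
        exposures[j] = (1 - aa_frac) * bg_weights[:, i]

    germline_genes_per_sample: list[list[str]] = []
    for i in range(n):
        carried = [g for g, f in config.germline_spec.items() if rng.random() < f]
        germline_genes_per_sample.append(carried)

    egfr_mut = gene_status.loc["EGFR"].to_numpy() if "EGFR" in gene_status.index else np.zeros(n, bool)
    egfr_ihc = np.where(egfr_mut, rng.random(n) < 0.5, False)

    variant_rows: list[dict] = []
    pos_counter = 1000

    def next_pos() -> int:
        nonlocal pos_counter
        pos_counter += rng.integers(1, 50)
        return int(pos_counter)

    def bg_gene() -> str:
        return f"BG{rng.integers(0, 5000):04d}"

    for i, sid in enumerate(sample_ids):
        mixture_exposure = exposures[:, i]
        drivers = [g for g in gene_status.index if gene_status.at[g, i]]
        n_total = max(n_counted[i], len(drivers))
        n_background = n_total - len(drivers)
        n_bg_snv = int(round(n_background * config.snv_frac))
        n_bg_indel = n_background - n_bg_snv
        # driver rows
        for g in drivers:
            truncating = rng.random() < TRUNCATING_PROB.get(g, 0.0)
            if truncating:
                variant_rows.append(
                    {
                        "sample_id": sid, "gene": g, "chrom": "1", "pos": next_pos(),
                        "ref": "C", "alt": "T", "variant_class": "nonsense",
                        "vaf": round(float(rng.beta(2.5, 3.5)), 4),
                        "context_channel": int(sample_mutation_channels(profiles, mixture_exposure, 1, rng)[0]),
                    }
                )
            else:
                chan = int(sample_mutation_channels(profiles, mixture_exposure, 1, rng)[0])
                ref, alt = _channel_ref_alt(chan)
                if g == "EGFR":
                    chrom = _EGFR_LOCUS[0]
                    pos = int(rng.integers(_EGFR_LOCUS[1], _EGFR_LOCUS[2] + 1))
                else:
                    chrom, pos = "1", next_pos()
                variant_rows.append(
                    {
                        "sample_id": sid, "gene": g, "chrom": chrom, "pos": pos,
                        "ref": ref, "alt": alt, "variant_class": "missense",
                        "vaf": round(float(rng.beta(2.5, 3.5)), 4),
                        "context_channel": chan,
                    }
                )
        # background SNVs from the planted signature mixture
        channels = sample_mutation_channels(profiles, mixture_exposure, n_bg_snv, rng)
        for chan in channels:
            ref, alt = _channel_ref_alt(int(chan))
            variant_rows.append(
                {
                    "sample_id": sid, "gene": bg_gene(),
                    "chrom": "2", "pos": next_pos(), "ref": ref, "alt": alt,
                    "variant_class": "missense",
                    "vaf": round(float(rng.beta(2.5, 3.5)), 4),
                    "context_channel": int(chan),
                }
            )
        # background indels (counted, no channel)
        for _ in range(n_bg_indel):
            variant_rows.append(
                {
                    "sample_id": sid, "gene": bg_gene(),
                    "chrom": "2", "pos": next_pos(), "ref": "A", "alt": "AT",
                    "variant_class": "frameshift_indel",
                    "vaf": round(float(rng.beta(2.5, 3.5)), 4),
                    "context_channel": None,
                }
            )
        # synonymous extras (not counted by the default TMB rule)
        n_syn = int(rng.binomial(max(n_bg_snv, 1), config.synonymous_extra_frac))
        for _ in range(n_syn):
            variant_rows.append(
                {
                    "sample_id": sid, "gene": bg_gene(),
                    "chrom": "3", "pos": next_pos(), "ref": "G", "alt": "A",
                    "variant_class": "synonymous",
                    "vaf": round(float(rng.beta(2.5, 3.5)), 4),
                    "context_channel": None,
                }
            )

    # copy-number and fusion actionable alterations
    cna_rows, fusion_rows = [], []
    pat_truth = {t: np.zeros(n, dtype=bool) for t in config.pat_spec}
    fusion_partners = ["BICC1", "TACC3", "AHCYL1", "ETV6"]
    for target, (alt_class, freq) in config.pat_spec.items():
        if alt_class in ("amplification", "deletion"):
            carried = rng.random(n) < freq
            for i in np.flatnonzero(carried):
                cna_rows.append(
                    {
                        "sample_id": sample_ids[i], "gene": target,
                        "cna_type": alt_class, "cytoband": "",
                    }
                )
            pat_truth[target] = carried
        elif alt_class == "fusion":
            carried = (platforms == "TPS") & (rng.random(n) < freq)
            for i in np.flatnonzero(carried):
                fusion_rows.append(
                    {
                        "sample_id": sample_ids[i], "gene_5p": target,
                        "gene_3p": fusion_partners[int(rng.integers(len(fusion_partners)))],
                    }
                )
            pat_truth[target] = carried
        else:
            raise ValueError(f"unsupported pat_spec class {alt_class!r} for {target}")

    clinical = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "subtype": subtypes,
            "stage": rng.choice(["I", "II", "III_IV", "unknown"], size=n, p=[0.25, 0.3, 0.4, 0.05]),
            "hepatitis": rng.choice(["positive", "negative", "unknown"], size=n, p=[0.35, 0.6, 0.05]),
            "platform": platforms,
            "msi_high": msi.tolist(),
            "egfr_ihc_2plus": egfr_ihc.tolist(),
            "germline_pathogenic_genes": [",".join(sorted(g)) for g in germline_genes_per_sample],
        }
    )

    # treated subset: carriers of any planted actionable alteration
    kb_snv_pat = {"IDH1", "BRCA1", "BRCA2", "EGFR", "PIK3CA"}
    variants_df = pd.DataFrame(
        variant_rows,
        columns=["sample_id", "gene", "chrom", "pos", "ref", "alt", "variant_class", "vaf", "context_channel"],
    )
    carrier = msi.copy()
    for target, flags in pat_truth.items():
        carrier |= flags
    snv_pat_hits = variants_df[
        variants_df["gene"].isin(kb_snv_pat)
        & variants_df["variant_class"].isin(["missense", "nonsense", "frameshift_indel", "splice", "inframe_indel"])
    ]["sample_id"].unique()
    carrier |= np.isin(sample_ids, snv_pat_hits)
    treated_mask = carrier & (rng.random(n) < config.outcome_spec.treated_frac)
    treated_ids = [sid for sid, t in zip(sample_ids, treated_mask) if t]
    outcomes_df = simulate_outcomes(treated_ids, config.outcome_spec, rng)

    cohort = Cohort(
        variants=variants_df,
        cnas=pd.DataFrame(cna_rows, columns=["sample_id", "gene", "cna_type", "cytoband"]),
        fusions=pd.DataFrame(fusion_rows, columns=["sample_id", "gene_5p", "gene_3p"]),
        clinical=clinical,
        outcomes=outcomes_df,
    )

    truth = {
        "sample_ids": sample_ids,
        "subtype": dict(zip(sample_ids, subtypes)),
        "platform": dict(zip(sample_ids, platforms)),
        "tmb": dict(zip(sample_ids, tmb.round(6))),
        "hypermutated": dict(zip(sample_ids, hyper.tolist())),
        "aa_positive": dict(zip(sample_ids, aa_pos.tolist())),
        "aa_eligible": dict(zip(sample_ids, eligible.tolist())),
        "exposures": pd.DataFrame(exposures, index=list(config.signature_names), columns=sample_ids),
        "gene_status": gene_status.set_axis(sample_ids, axis=1),
        "pat_alterations": {t: [sample_ids[i] for i in np.flatnonzero(f)] for t, f in pat_truth.items()},
        "msi_high": dict(zip(sample_ids, msi.tolist())),
        "germline": dict(zip(sample_ids, germline_genes_per_sample)),
        "treated": treated_ids,
        "expected": {
            "hypermutated_frac": config.hypermutated_frac,
            "aa_positive_frac": config.aa_positive_frac,
            "msi_frac": config.msi_frac,
            "gene_freqs": dict(config.gene_freqs),
            "pat_freqs": {t: f for t, (_, f) in config.pat_spec.items()},
            "germline_any_frac": 1.0 - float(np.prod([1 - f for f in config.germline_spec.values()])),
            "responder_frac": config.outcome_spec.responder_frac,
            "benefit_frac": config.outcome_spec.benefit_frac,
            "median_pfs2_months": config.outcome_spec.median_pfs2_months,
        },
        "config": {**{k: v for k, v in asdict(config).items() if k != "signature_profiles"}},
    }
    return cohort, truth
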