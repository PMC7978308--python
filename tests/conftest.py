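import numpy as np
import pandas as pd
import pytest

from btcprof.signatures import MutationCatalog, load_reference_catalog
from btcprof.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def toy_reference():
    return load_reference_catalog()


@pytest.fixture(scope="session")
def small_cohort():
    """60-sample study-like cohort with its planted truth (fixed seed)."""
    return generate_cohort(CohortConfig(n_samples=60, seed=42))


@pytest.fixture(scope="session")
def planted_catalog(toy_reference):
    """3-signature planted catalog: 150 samples, >= 50 SBS each.

    Returns (catalog, true_profiles 96x3, true_exposures 3x150).
    """
    rng = np.random.default_rng(20240915)
    P = toy_reference[["SBS1", "SBS22", "SBS40"]].to_numpy()
    n = 150
    exposures = rng.dirichlet([1.5, 1.5, 1.5], size=n).T
    counts = np.zeros((96, n), dtype=int)
    for j in range(n):
        n_mut = 50 + rng.poisson(30)
        mix = P @ exposures[:, j]
        counts[:, j] = rng.multinomial(n_mut, mix / mix.sum())
    catalog = MutationCatalog(counts, [f"P{j:03d}" for j in range(n)])
    return catalog, P, exposures


def make_variants(rows):
    """Variant table from (sample, gene, class) triples or full dicts."""
    full = []
    for i, r in enumerate(rows):
        if isinstance(r, tuple):
            r = {"sample_id": r[0], "gene": r[1], "variant_class": r[2]}
        full.append(
            {
                "sample_id": r["sample_id"],
                "gene": r.get("gene", "GENE"),
                "chrom": r.get("chrom", "1"),
                "pos": r.get("pos", 1000 + i),
                "ref": r.get("ref", "C"),
                "alt": r.get("alt", "T"),
                "variant_class": r.get("variant_class", "missense"),
                "vaf": r.get("vaf", 0.4),
                "context_channel": r.get("context_channel"),
            }
        )
    return pd.DataFrame(
        full,
        columns=["sample_id", "gene", "chrom", "pos", "ref", "alt", "variant_class", "vaf", "context_channel"],
    )
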