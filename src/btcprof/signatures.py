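"""De-novo mutational-signature extraction and per-sample attribution.

The catalog is a 96 x S matrix of single-base-substitution counts on the
fixed pyrimidine-centered channel axis (see :mod:`btcprof.channels`).  It is
factorized de novo as ``V ~ W H`` with non-negative ``W`` (96 x k signature
profiles) and ``H`` (k x S exposures) by multiplicative updates minimizing
the generalized Kullback-Leibler divergence

    D(V || WH) = sum_ij V_ij log(V_ij / (WH)_ij) - V_ij + (WH)_ij,

the classical Lee-Seung scheme, with many random restarts and the
best-objective run kept.  After fitting, profiles are column-normalized and
the scale moved into the exposures.  Fitted profiles are matched to a named
reference catalog by cosine similarity.

Per-sample attribution of a target signature (here: the aristolochic-acid,
SBS22-like signature) tests whether a sample's counts carry more of the
target than expected under a null in which the target is absent: the
sample's exposures are re-fit with profiles fixed, the target component is
removed and the remainder renormalized into a null channel mixture, and the
observed target exposure fraction is compared against re-fits of multinomial
resamples from that null.  Benjamini-Hochberg control across samples at
FDR < 0.05 yields the positive calls.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .association import bh_adjust
from .channels import SBS96_LABELS

logger = logging.getLogger(__name__)

_EPS = 1e-12


# ---------------------------------------------------------------------------
# catalogs


@dataclass
class MutationCatalog:
    """96 x S matrix of SBS counts over the fixed channel axis."""

    counts: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (96, len(self.sample_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"96 x {len(self.sample_ids)} samples"
            )
        if (self.counts < 0).any():
            raise ValueError("catalog counts must be non-negative")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, index=list(SBS96_LABELS), columns=self.sample_ids)
        df.index.name = "channel"
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MutationCatalog":
        if list(df.index) != list(SBS96_LABELS):
            raise ValueError("catalog rows must be the 96 channels in COSMIC order")
        return cls(df.to_numpy(), list(df.columns))


def build_context_matrix(
    variants: pd.DataFrame,
    samples: list[str] | None = None,
    exclude_samples: set[str] | frozenset[str] | None = None,
) -> MutationCatalog:
    """Tally per-sample SBS counts over the 96 channels.

    ``samples`` fixes the column set and order (default: samples observed in
    the variant table, sorted); ``exclude_samples`` drops columns (used to
    exclude hypermutated samples from extraction).  Rows without a
    ``context_channel`` (indels, noncoding without context) are skipped and
    the skip count logged.
    """
    exclude = set(exclude_samples or ())
    has_channel = variants["context_channel"].notna()
    skipped = int((~has_channel).sum())
    if skipped:
        logger.info("build_context_matrix: skipped %d variant(s) without context_channel", skipped)
    eligible = variants[has_channel]
    if samples is None:
        samples = sorted(set(eligible["sample_id"]) - exclude)
    else:
        samples = [s for s in samples if s not in exclude]
    counts = np.zeros((96, len(samples)), dtype=int)
    col = {s: j for j, s in enumerate(samples)}
    for sid, chan in zip(eligible["sample_id"], eligible["context_channel"]):
        j = col.get(sid)
        if j is not None:
            counts[int(chan), j] += 1
    if counts.sum() == 0:
        warnings.warn("empty mutation catalog: no eligible SBS variants", stacklevel=2)
    return MutationCatalog(counts, samples)


def load_reference_catalog(path: str | Path | None = None) -> pd.DataFrame:
    """Load a named reference signature catalog (96 rows x named columns).

    Default: the 5-signature toy catalog shipped with the package (SBS1-,
    SBS2-, SBS5-, SBS22- and SBS40-like profiles); pass a TSV path to use a
    full catalog such as COSMIC.
    """
    if path is None:
        ref = resources.files("btcprof.data") / "reference_signatures.tsv"
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t", index_col="channel")
    else:
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index.name = "channel"
    if list(df.index) != list(SBS96_LABELS):
        raise ValueError("reference catalog rows must be the 96 channels in COSMIC order")
    if (df.to_numpy() < 0).any():
        raise ValueError("reference catalog entries must be non-negative")
    return df


# ---------------------------------------------------------------------------
# NMF


@dataclass
class SignatureSet:
    """Fitted factorization: column-stochastic profiles plus exposures."""

    profiles: np.ndarray  # 96 x k, columns sum to 1
    exposures: np.ndarray  # k x S, non-negative
    k: int
    reconstruction_error: float
    sample_ids: list[str]
    matches: list[tuple[str, float]] | None = None


def _kl_divergence(V: np.ndarray, WH: np.ndarray) -> float:
    WH = np.maximum(WH, _EPS)
    mask = V > 0
    d = float((V[mask] * np.log(V[mask] / WH[mask])).sum() - V.sum() + WH.sum())
    return d


def _nmf_kl_single(
    V: np.ndarray, k: int, rng: np.random.Generator, max_iter: int, tol: float
) -> tuple[np.ndarray, np.ndarray, float]:
    """One multiplicative-update KL run from a random non-negative start.

    The generalized KL objective is checked every 10 iterations and must be
    non-increasing (up to numerical slack) — a violated check indicates an
    implementation defect, hence the assertion.
    """
    n, m = V.shape
    scale = np.sqrt(V.mean() / k)
    W = rng.uniform(0.1, 1.0, size=(n, k)) * scale
    H = rng.uniform(0.1, 1.0, size=(k, m)) * scale
    prev_obj = _kl_divergence(V, W @ H)
    last_checked = prev_obj
    for it in range(1, max_iter + 1):
        WH = np.maximum(W @ H, _EPS)
        H *= (W.T @ (V / WH)) / np.maximum(W.sum(axis=0)[:, None], _EPS)
        WH = np.maximum(W @ H, _EPS)
        W *= ((V / WH) @ H.T) / np.maximum(H.sum(axis=1)[None, :], _EPS)
        if it % 10 == 0 or it == max_iter:
            obj = _kl_divergence(V, W @ H)
            assert obj <= last_checked + 1e-6 * max(1.0, abs(last_checked)), (
                "KL objective increased during multiplicative updates"
            )
            if last_checked - obj <= tol * max(1.0, abs(last_checked)):
                last_checked = obj
                break
            last_checked = obj
    return W, H, _kl_divergence(V, W @ H)


def _normalize_factorization(W: np.ndarray, H: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column-normalize profiles, moving scale into exposures; sort columns
    by total exposure (descending) for a deterministic presentation."""
    col = W.sum(axis=0)
    col = np.where(col < _EPS, 1.0, col)
    Wn = W / col
    Hn = H * col[:, None]
    order = np.argsort(-Hn.sum(axis=1), kind="stable")
    return Wn[:, order], Hn[order, :]


def nmf_decompose(
    catalog: MutationCatalog,
    k: int,
    seed: int,
    max_iter: int = 500,
    tol: float = 1e-6,
    n_restarts: int = 50,
) -> SignatureSet:
    """Factorize the catalog into ``k`` signatures.

    Runs ``n_restarts`` random initializations and keeps the best-objective
    run; deterministic given ``seed``.
    """
    V = catalog.counts.astype(float)
    if not 1 <= k <= min(96, catalog.n_samples):
        raise ValueError(f"k must be in [1, min(96, S)], got {k}")
    if V.sum() == 0:
        raise ValueError("cannot factorize an all-zero catalog")
    ss = np.random.SeedSequence(seed)
    best: tuple[np.ndarray, np.ndarray, float] | None = None
    for child in ss.spawn(n_restarts):
        rng = np.random.default_rng(child)
        W, H, obj = _nmf_kl_single(V, k, rng, max_iter, tol)
        if best is None or obj < best[2]:
            best = (W, H, obj)
    W, H = _normalize_factorization(best[0], best[1])
    return SignatureSet(
        profiles=W,
        exposures=H,
        k=k,
        reconstruction_error=best[2],
        sample_ids=list(catalog.sample_ids),
    )


# ---------------------------------------------------------------------------
# rank selection


@dataclass
class RankSelection:
    k: int
    diagnostics: pd.DataFrame = field(repr=False)


def select_rank(
    catalog: MutationCatalog,
    k_range: list[int] | range,
    n_restarts: int = 10,
    seed: int = 0,
    improvement_tol: float = 0.05,
    stability_threshold: float = 0.9,
    max_iter: int = 300,
) -> RankSelection:
    """Choose the number of signatures from restart stability + fit improvement.

    For each candidate ``k``, ``n_restarts`` factorizations are run; restart
    stability is scored as the mean silhouette (cosine metric) of the pooled
    profiles clustered into ``k`` groups, and fit quality as the best KL
    objective.  Candidate ranks are accepted while each step improves the
    best objective by at least ``improvement_tol`` (relative); among the
    accepted ranks the largest one whose silhouette reaches
    ``stability_threshold`` is returned (falling back to the
    silhouette-maximizing accepted rank when none is stable) — the usual
    consensus-clustering convention: grow the rank while the factorization
    both fits better and stays reproducible.  The full diagnostic table
    ships with the result.
    """
    from sklearn.cluster import KMeans
    from sklearn.metrics import silhouette_score

    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ValueError("k_range must be non-empty")
    V = catalog.counts.astype(float)
    if V.sum() == 0 or catalog.n_samples == 0:
        warnings.warn("degenerate catalog; returning min(k_range)", stacklevel=2)
        return RankSelection(ks[0], pd.DataFrame())
    ss = np.random.SeedSequence(seed)
    rows = []
    for k in ks:
        profiles, objs = [], []
        for child in ss.spawn(n_restarts):
            rng = np.random.default_rng(child)
            W, H, obj = _nmf_kl_single(V, k, rng, max_iter, tol=1e-5)
            Wn, _ = _normalize_factorization(W, H)
            profiles.append(Wn)
            objs.append(obj)
        pooled = np.hstack(profiles).T  # (k * n_restarts) x 96
        if k == 1 or len(pooled) <= k:
            sil = np.nan
        else:
            km = KMeans(n_clusters=k, n_init=10, random_state=int(ss.generate_state(1)[0] % 2**31))
            labels = km.fit_predict(pooled)
            if len(set(labels)) < 2:
                sil = np.nan
            else:
                sil = float(silhouette_score(pooled, labels, metric="cosine"))
        rows.append({"k": k, "best_kl": float(min(objs)), "mean_silhouette": sil})
    diag = pd.DataFrame(rows)

    accepted = [ks[0]]
    for i in range(1, len(ks)):
        prev_err = diag.loc[i - 1, "best_kl"]
        if prev_err <= 1e-6 * max(1.0, V.sum()):
            break  # already an essentially exact fit
        rel_gain = (prev_err - diag.loc[i, "best_kl"]) / max(prev_err, _EPS)
        if rel_gain >= improvement_tol:
            accepted.append(ks[i])
        else:
            break
    if len(accepted) == 1:
        chosen = accepted[0]
    else:
        cands = diag[diag["k"].isin(accepted) & diag["mean_silhouette"].notna()]
        if not len(cands):
            chosen = accepted[-1]
        else:
            stable = cands[cands["mean_silhouette"] >= stability_threshold]
            if len(stable):
                chosen = int(stable["k"].max())
            else:
                chosen = int(cands.loc[cands["mean_silhouette"].idxmax(), "k"])
    diag["accepted"] = diag["k"].isin(accepted)
    diag["selected"] = diag["k"] == chosen
    return RankSelection(int(chosen), diag)


# ---------------------------------------------------------------------------
# cosine matching


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine similarity of two non-negative vectors, in [0, 1]."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine similarity undefined for zero-norm vector")
    return float(np.clip(u @ v / (nu * nv), 0.0, 1.0))


def cosine_match(
    profiles: np.ndarray, reference: pd.DataFrame
) -> list[tuple[str, float]]:
    """Best-matching reference signature (by cosine) for each fitted profile."""
    matches = []
    for j in range(profiles.shape[1]):
        sims = {name: cosine_similarity(profiles[:, j], reference[name]) for name in reference.columns}
        name = max(sims, key=sims.get)
        matches.append((name, sims[name]))
    return matches


# ---------------------------------------------------------------------------
# attribution


def refit_exposures(
    profiles: np.ndarray, counts: np.ndarray, max_iter: int = 300, tol: float = 1e-7
) -> np.ndarray:
    """Non-negative KL re-fit of exposures with profiles held fixed.

    ``counts`` may be a vector (one sample) or a 96 x m matrix; returns the
    k (x m) exposure array.
    """
    V = np.atleast_2d(np.asarray(counts, dtype=float).T).T
    if V.shape[0] != profiles.shape[0]:
        raise ValueError("counts do not match the profile channel axis")
    k, m = profiles.shape[1], V.shape[1]
    H = np.full((k, m), max(V.mean(), _EPS))
    wsum = np.maximum(profiles.sum(axis=0)[:, None], _EPS)
    prev = np.inf
    for it in range(max_iter):
        WH = np.maximum(profiles @ H, _EPS)
        H *= (profiles.T @ (V / WH)) / wsum
        if it % 20 == 19:
            obj = _kl_divergence(V, profiles @ H)
            if prev - obj <= tol * max(1.0, abs(prev)):
                break
            prev = obj
    return H[:, 0] if np.asarray(counts).ndim == 1 else H


def attribute_signature(
    catalog: MutationCatalog,
    signature_set: SignatureSet,
    target_signature_index: int,
    n_null: int = 200,
    seed: int = 0,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Per-sample attribution of one signature with an FDR-controlled call.

    For each sample: re-fit exposures onto the fixed profiles; the observed
    statistic is the target's exposure fraction.  The null removes the target
    component, renormalizes the remaining mixture into channel probabilities,
    resamples ``n_null`` catalogs of the same total count and re-fits each;
    the p-value is the fraction of null target fractions at or above the
    observed one (add-one corrected).  Benjamini-Hochberg across samples;
    positive iff q < ``fdr``.
    """
    if n_null <= 0:
        raise ValueError("n_null must be positive")
    if n_null < 100:
        warnings.warn(f"n_null={n_null} < 100 gives unstable p-values", stacklevel=2)
    W = signature_set.profiles
    k = signature_set.k
    if not 0 <= target_signature_index < k:
        raise ValueError("target_signature_index out of range")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    t = target_signature_index
    non_target = [j for j in range(k) if j != t]
    rows = []
    for j, sid in enumerate(catalog.sample_ids):
        v = catalog.counts[:, j].astype(float)
        total = int(v.sum())
        if total == 0:
            rows.append((sid, 0.0, 1.0))
            continue
        e = refit_exposures(W, v)
        obs_frac = float(e[t] / max(e.sum(), _EPS))
        e_null = e.copy()
        e_null[t] = 0.0
        if e_null.sum() <= _EPS:
            # sample fit entirely by the target; null falls back to an even
            # mixture of the remaining signatures
            mixture = W[:, non_target].mean(axis=1)
        else:
            mixture = W @ (e_null / e_null.sum())
        mixture = np.maximum(mixture, 0)
        mixture /= mixture.sum()
        null_counts = rng.multinomial(total, mixture, size=n_null).T  # 96 x n_null
        H0 = refit_exposures(W, null_counts)
        null_frac = H0[t] / np.maximum(H0.sum(axis=0), _EPS)
        p = (1.0 + float((null_frac >= obs_frac).sum())) / (n_null + 1.0)
        rows.append((sid, obs_frac, p))
    df = pd.DataFrame(rows, columns=["sample_id", "exposure_fraction", "p_value"])
    df["q_value"] = bh_adjust(df["p_value"].to_numpy())
    df["positive"] = df["q_value"] < fdr
    return df
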