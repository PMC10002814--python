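"""Pseudo-labeling of biomarker-positive cognitively normal cases.

The selected peptide panel is embedded into two dimensions with t-SNE
jointly for all subjects (controls, AD and the AsymAD queries; an
out-of-sample embedding is not defined for this method), and each query is
assigned the majority label of its k=5 nearest *reference* subjects in the
embedding — AsymAD cases never vote. Because t-SNE geometry depends on its
initialization, the embed+vote step is repeated (default 100 times) with
seeds derived from a master seed; the fraction of repeats voting "AD-like"
is the assignment probability, and a final label is issued only outside an
explicit uncertainty band (default 0.4-0.6).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.manifold import TSNE

from ._utils import spawn_seeds
from .selection import _standardizer
from .stats import TestResult, fisher_exact_rx2
from .synthetic import SUBGROUP_AD_LIKE, SUBGROUP_CONTROL_LIKE

logger = logging.getLogger(__name__)

LABEL_UNCERTAIN = "uncertain"

GENOTYPES = ("e2/e2", "e2/e3", "e2/e4", "e3/e3", "e3/e4", "e4/e4")


@dataclass
class EmbeddingRun:
    seed: int
    coords: np.ndarray  # (n_subjects, 2)
    perplexity: float
    max_iter: int


def embed_2d(panel_matrix, perplexity: float = 30.0, seed: int = 0,
             max_iter: int = 1000) -> EmbeddingRun:
    """Joint 2-D t-SNE embedding of standardized panel features.

    Perplexity is capped at (n-1)/3; the run is deterministic given the
    seed (random initialization, so different seeds explore different
    layouts — the point of the stability analysis).
    """
    X = np.asarray(panel_matrix, dtype=float)
    n = X.shape[0]
    perp = min(perplexity, (n - 1) / 3.0)
    if perp < 2:
        raise ValueError(f"too few subjects ({n}) for a t-SNE embedding")
    ts = TSNE(n_components=2, perplexity=perp, random_state=seed,
              init="random", learning_rate="auto", max_iter=max_iter)
    coords = ts.fit_transform(X)
    if not np.all(np.isfinite(coords)):
        raise RuntimeError("t-SNE produced non-finite coordinates")
    return EmbeddingRun(seed=seed, coords=coords, perplexity=perp, max_iter=max_iter)


def knn_assign(coords: np.ndarray, reference_idx, reference_labels, query_idx,
               k: int = 5) -> pd.DataFrame:
    """Majority vote of the k nearest reference subjects per query.

    Distances are Euclidean in the embedding; distance ties break toward
    the earlier reference subject (stable sort), and k must be odd so the
    vote itself cannot tie. Returns a frame with vote counts and the label.
    """
    if k % 2 == 0:
        raise ValueError("k must be odd")
    ref = np.asarray(reference_idx, dtype=int)
    qry = np.asarray(query_idx, dtype=int)
    labels = np.asarray(reference_labels)
    if labels.size != ref.size:
        raise ValueError("reference labels must align with reference indices")
    if k >= ref.size:
        raise ValueError("k must be smaller than the number of reference subjects")
    is_ad = labels == "AD"
    out = []
    for q in qry:
        d = np.linalg.norm(coords[ref] - coords[q], axis=1)
        nearest = np.argsort(d, kind="stable")[:k]
        ad_votes = int(is_ad[nearest].sum())
        out.append({"query": q, "votes_ad": ad_votes, "votes_control": k - ad_votes,
                    "label": SUBGROUP_AD_LIKE if ad_votes > k / 2 else SUBGROUP_CONTROL_LIKE})
    return pd.DataFrame(out).set_index("query")


@dataclass
class StratificationResult:
    """Per-query assignment probabilities over embedding repeats."""

    table: pd.DataFrame  # index query idx; p_ad_like, n_repeats, final_label
    assignments: pd.DataFrame  # repeats x queries, label per repeat
    repeats: int
    k: int
    band: tuple[float, float]


def stability_stratify(
    panel_matrix,
    reference_idx,
    reference_labels,
    query_idx,
    repeats: int = 100,
    k: int = 5,
    band: tuple[float, float] = (0.4, 0.6),
    perplexity: float = 30.0,
    seed: int = 0,
) -> StratificationResult:
    """Repeat embed+vote with derived seeds; label by repeat probability.

    Probability of "AD-like" is the fraction of repeats voting AD-like.
    Final label: AD-like above the band, Control-like below it, otherwise
    "uncertain". ``repeats=1`` recovers the single-run assignment.
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    X = np.asarray(panel_matrix, dtype=float)
    mean, sd = _standardizer(X)
    Z = (X - mean) / sd
    seeds = spawn_seeds(seed, repeats)
    qry = np.asarray(query_idx, dtype=int)
    rows = np.zeros((repeats, qry.size), dtype=object)
    for r, s in enumerate(seeds):
        run = embed_2d(Z, perplexity=perplexity, seed=s)
        votes = knn_assign(run.coords, reference_idx, reference_labels, qry, k=k)
        rows[r] = votes["label"].to_numpy()
    assignments = pd.DataFrame(rows, columns=qry)
    p_ad = (assignments == SUBGROUP_AD_LIKE).mean(axis=0)
    lo, hi = band
    final = np.where(p_ad > hi, SUBGROUP_AD_LIKE,
                     np.where(p_ad < lo, SUBGROUP_CONTROL_LIKE, LABEL_UNCERTAIN))
    table = pd.DataFrame({"p_ad_like": p_ad, "n_repeats": repeats, "final_label": final})
    table.index.name = "query"
    return StratificationResult(table=table, assignments=assignments,
                                repeats=repeats, k=k, band=band)


def apoe_enrichment(genotypes, subgroups) -> tuple[TestResult, pd.DataFrame, pd.DataFrame]:
    """Fisher exact test of APOE genotype profiles between two subgroups.

    Builds the genotype x subgroup contingency table over the fixed
    epsilon-allele genotype categories, computes the exact (or, for huge
    tables, seeded Monte Carlo) two-sided p, and reports allele frequencies
    per subgroup alongside.
    """
    g = pd.Series(genotypes).astype(str).reset_index(drop=True)
    s = pd.Series(subgroups).astype(str).reset_index(drop=True)
    groups = sorted(s.unique())
    if len(groups) != 2:
        raise ValueError("need exactly two subgroups")
    if (s.value_counts() == 0).any():
        raise ValueError("empty subgroup")
    table = pd.DataFrame(0, index=list(GENOTYPES), columns=groups)
    for geno, sub in zip(g, s):
        if geno not in table.index:
            raise ValueError(f"unknown genotype {geno!r}")
        table.loc[geno, sub] += 1
    result = fisher_exact_rx2(table.to_numpy())

    def allele_freqs(mask):
        alleles = "/".join(g[mask]).split("/") if mask.any() else []
        counts = pd.Series(alleles).value_counts()
        total = max(len(alleles), 1)
        return {a: counts.get(a, 0) / total for a in ("e2", "e3", "e4")}

    freqs = pd.DataFrame({grp: allele_freqs(s == grp) for grp in groups}).T
    return result, table, freqs
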