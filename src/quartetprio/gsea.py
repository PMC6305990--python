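"""Preranked gene-set enrichment analysis.

Genes are ranked by log2 fold change between two conditions; for each gene
set a weighted Kolmogorov-Smirnov-like running sum gives the enrichment
score (ES), and a gene-label permutation null provides the normalized ES,
nominal p-value and an NES-ratio FDR q. The null permutes gene labels (the
only option for a preranked list, where sample labels are unavailable).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .genesets import GeneSetCollection

logger = logging.getLogger(__name__)


class GseaError(ValueError):
    pass


@dataclass
class RankedGeneList:
    """(gene, score) pairs in descending score order, ties broken by symbol."""

    genes: list[str]
    scores: np.ndarray

    def __post_init__(self) -> None:
        if len(self.genes) != len(self.scores):
            raise GseaError("genes and scores differ in length")
        if len(set(self.genes)) != len(self.genes):
            raise GseaError("gene symbols must be unique in a ranked list")

    def __len__(self) -> int:
        return len(self.genes)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"gene": self.genes, "score": self.scores})


@dataclass
class GseaResult:
    name: str
    es: float
    nes: float
    p_nominal: float
    fdr_q: float
    leading_edge: list[str]
    n_hits: int


def rank_genes(
    expr_case: pd.DataFrame, expr_control: pd.DataFrame, eps: float = 1.0
) -> RankedGeneList:
    """Rank shared genes by log2 fold change of group means.

    score(g) = log2(mean_case + eps) - log2(mean_control + eps); the
    pseudo-count eps guards zero expression. Genes with all-missing values
    in either group are dropped with a warning. Descending score, ties by
    symbol.
    """
    shared = expr_case.index.intersection(expr_control.index)
    if shared.empty:
        raise GseaError("no shared genes between the two expression groups")
    case_mean = expr_case.loc[shared].mean(axis=1)
    ctrl_mean = expr_control.loc[shared].mean(axis=1)
    bad = case_mean.isna() | ctrl_mean.isna()
    if bad.any():
        logger.warning("dropping %d genes with all-missing expression", int(bad.sum()))
    case_mean, ctrl_mean = case_mean[~bad], ctrl_mean[~bad]
    score = np.log2(case_mean + eps) - np.log2(ctrl_mean + eps)
    df = pd.DataFrame({"gene": [str(g).upper() for g in score.index], "score": score.values})
    df = df.sort_values(["score", "gene"], ascending=[False, True], kind="mergesort")
    return RankedGeneList(genes=df["gene"].tolist(), scores=df["score"].to_numpy(float))


def enrichment_score(
    ranked: RankedGeneList, gene_set: Sequence[str], exponent: float = 1.0
) -> tuple[float, np.ndarray, np.ndarray]:
    """Weighted running-sum enrichment score of one gene set.

    At each hit the sum increments by |score|^exponent / sum over hits of the
    same; at each miss it decrements by 1/(N - N_hits). ES is the signed
    maximum deviation from zero of the running sum. Returns (es,
    running_sum over all N positions, hit index array).
    """
    members = {g.upper() for g in gene_set}
    hits = np.array([g in members for g in ranked.genes], dtype=bool)
    n_hits = int(hits.sum())
    n = len(ranked)
    if n_hits == 0:
        raise GseaError("gene set shares no genes with the ranked list")
    if n_hits == n:
        raise GseaError("gene set covers the entire ranked list; miss penalty undefined")
    weights = np.abs(ranked.scores) ** exponent
    hit_w = np.where(hits, weights, 0.0)
    total = hit_w.sum()
    if total == 0:
        # all hit scores are exactly zero; fall back to equal weights
        hit_w = hits.astype(float)
        total = hit_w.sum()
    step_hit = hit_w / total
    step_miss = np.where(hits, 0.0, 1.0 / (n - n_hits))
    running = np.cumsum(step_hit - step_miss)
    es = _signed_max_deviation(float(running.max()), float(running.min()))
    return es, running, np.flatnonzero(hits)


def _signed_max_deviation(hi: float, lo: float) -> float:
    """Pick the extremum farther from zero; exact ties (to within float
    accumulation error) resolve to the positive peak."""
    if hi >= -lo or abs(hi + lo) < 1e-9:
        return hi
    return lo


def _es_only(scores_abs_exp: np.ndarray, hit_idx: np.ndarray, n: int) -> float:
    """ES from sorted hit positions only (O(k) given precomputed weights);
    equivalent to the full running sum, used for the permutation null."""
    k = len(hit_idx)
    w = scores_abs_exp[hit_idx]
    total = w.sum()
    if total == 0:
        w = np.ones(k)
        total = float(k)
    cum_hit = np.cumsum(w) / total
    miss = 1.0 / (n - k)
    i = np.arange(k)
    # value right after each hit, and right before each hit
    at_hit = cum_hit - (hit_idx - i) * miss
    before_hit = np.concatenate(([0.0], cum_hit[:-1])) - (hit_idx - i) * miss
    return _signed_max_deviation(float(at_hit.max()), float(before_hit.min()))


def leading_edge(
    ranked: RankedGeneList, gene_set: Sequence[str], es_info: tuple[float, np.ndarray, np.ndarray]
) -> list[str]:
    """Set members driving the enrichment: hits at/before the running-sum
    peak for positive ES, at/after the trough for negative ES."""
    es, running, hit_idx = es_info
    if es >= 0:
        peak = int(np.argmax(running))
        return [ranked.genes[i] for i in hit_idx if i <= peak]
    trough = int(np.argmin(running))
    return [ranked.genes[i] for i in hit_idx if i >= trough]


def permutation_stats(
    ranked: RankedGeneList,
    sets: GeneSetCollection,
    n_perm: int = 1000,
    seed: int = 0,
    exponent: float = 1.0,
) -> list[GseaResult]:
    """Permutation statistics for every gene set sharing genes with the list.

    The null for a set of k list genes is the ES of k genes drawn uniformly
    without replacement. p_nominal uses a pseudo-count so it is never 0:
    (1 + #{same-sign null ES at least as extreme}) / (1 + #same-sign null).
    NES = ES / mean(|null ES| of the same sign); FDR q is the NES-ratio
    estimator (fraction of pooled null NES at least as extreme over fraction
    of observed NES at least as extreme), clipped to [0, 1].
    """
    if n_perm < 100:
        raise GseaError("n_perm must be >= 100 for stable tail estimates")
    rng = np.random.default_rng(seed)
    n = len(ranked)
    weights = np.abs(ranked.scores) ** exponent
    gene_index = {g: i for i, g in enumerate(ranked.genes)}

    observed: list[tuple[str, float, tuple, int, np.ndarray]] = []
    for name, genes in sets.items():
        members = [g for g in genes if g.upper() in gene_index]
        if not members:
            logger.warning("gene set %s shares no genes with the ranked list; skipped", name)
            continue
        if len(members) == n:
            raise GseaError(f"gene set {name} covers the entire ranked list")
        es, running, hit_idx = enrichment_score(ranked, members, exponent)
        null = np.empty(n_perm)
        k = len(members)
        for b in range(n_perm):
            idx = np.sort(rng.choice(n, size=k, replace=False))
            null[b] = _es_only(weights, idx, n)
        observed.append((name, es, (es, running, hit_idx), k, null))

    results: list[GseaResult] = []
    nes_obs: list[float] = []
    nes_null_pool: list[np.ndarray] = []
    for name, es, es_info, k, null in observed:
        same_sign = null[null >= 0] if es >= 0 else null[null < 0]
        extreme = int((same_sign >= es).sum()) if es >= 0 else int((same_sign <= es).sum())
        p = (1 + extreme) / (1 + len(same_sign))
        pos_mean = null[null >= 0].mean() if (null >= 0).any() else np.nan
        neg_mean = np.abs(null[null < 0]).mean() if (null < 0).any() else np.nan
        denom = pos_mean if es >= 0 else neg_mean
        nes = float(es / denom) if denom and np.isfinite(denom) and denom > 0 else 0.0
        null_nes = np.where(null >= 0, null / pos_mean, null / neg_mean)
        null_nes = null_nes[np.isfinite(null_nes)]
        nes_obs.append(nes)
        nes_null_pool.append(null_nes)
        results.append(
            GseaResult(
                name=name,
                es=float(es),
                nes=nes,
                p_nominal=float(p),
                fdr_q=0.0,
                leading_edge=leading_edge(ranked, sets[name], es_info),
                n_hits=k,
            )
        )

    if results:
        pool = np.concatenate(nes_null_pool)
        obs = np.asarray(nes_obs)
        for r in results:
            if r.nes >= 0:
                d = (pool >= r.nes).mean() / max((pool >= 0).mean(), 1e-12)
                b = (obs >= r.nes).sum() / max((obs >= 0).sum(), 1)
            else:
                d = (pool <= r.nes).mean() / max((pool < 0).mean(), 1e-12)
                b = (obs <= r.nes).sum() / max((obs < 0).sum(), 1)
            r.fdr_q = float(np.clip(d / b if b > 0 else 1.0, 0.0, 1.0))
    results.sort(key=lambda r: -r.nes)
    return results


def results_frame(results: Sequence[GseaResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "name": r.name,
                "size": r.n_hits,
                "es": r.es,
                "nes": r.nes,
                "p_nominal": r.p_nominal,
                "fdr_q": r.fdr_q,
                "leading_edge": ";".join(r.leading_edge),
            }
            for r in results
        ]
    )


def read_expression_tsv(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a genes x samples TSV whose second header line assigns each
    sample to a condition ("case" / "control"); returns (case, control)."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        cond_line = fh.readline().rstrip("\n").split("\t")
        df = pd.read_csv(fh, sep="\t", header=None, names=header, index_col=0)
    conditions = dict(zip(header[1:], cond_line[1:]))
    case_cols = [s for s, c in conditions.items() if c == "case"]
    ctrl_cols = [s for s, c in conditions.items() if c == "control"]
    if not case_cols or not ctrl_cols:
        raise GseaError(f"{path}: condition header must assign both 'case' and 'control'")
    return df[case_cols], df[ctrl_cols]


def write_expression_tsv(expr: pd.DataFrame, conditions: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\t" + "\t".join(expr.columns) + "\n")
        fh.write("condition\t" + "\t".join(conditions[c] for c in expr.columns) + "\n")
        expr.to_csv(fh, sep="\t", header=False)
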