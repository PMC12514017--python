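"""Preranked gene-set enrichment with permutation NES/FDR.

Genes ranked by a signed score (here: PLS bootstrap ratios) are tested for
enrichment of gene sets with the weighted Kolmogorov-Smirnov running-sum
statistic: walking down the ranked list, set members ("hits") increment the
running sum proportionally to |score| and non-members decrement it by a
constant. The enrichment score (ES) is the extremum of that walk; it is
normalized against sign-matched permutation nulls to give an NES, an
add-one permutation p-value, and a Benjamini-Hochberg FDR within each sign
stratum. A greedy weighted set cover reduces redundant significant terms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .biostats import bh_fdr


@dataclass(frozen=True)
class GeneSet:
    term_id: str
    name: str
    genes: tuple[str, ...]

    def __post_init__(self):
        if len(self.genes) == 0:
            raise ValueError(f"gene set {self.term_id!r} is empty")


class GeneSetCollection:
    """Ordered collection of named gene sets (GMT-compatible)."""

    def __init__(self, sets: list[GeneSet]):
        ids = [s.term_id for s in sets]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate term ids in collection")
        self.sets = list(sets)
        self._by_id = {s.term_id: s for s in sets}

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, term_id: str) -> GeneSet:
        return self._by_id[term_id]

    def __contains__(self, term_id: str) -> bool:
        return term_id in self._by_id


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file (term <tab> description <tab> gene...).

    Duplicate genes within a term are dropped with a warning; a line with
    fewer than three fields is a parse error reported with its line number.
    """
    sets = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line {lineno}: expected >= 3 "
                                 f"tab-separated fields, got {len(fields)}")
            term, desc, genes = fields[0], fields[1], fields[2:]
            uniq = list(dict.fromkeys(genes))
            if len(uniq) != len(genes):
                warnings.warn(f"term {term!r}: duplicate member genes deduplicated")
            sets.append(GeneSet(term_id=term, name=desc, genes=tuple(uniq)))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for s in collection:
            fh.write("\t".join([s.term_id, s.name, *s.genes]) + "\n")


# ---------------------------------------------------------------------------
# ranking and enrichment score
# ---------------------------------------------------------------------------

def rank_genes(scores: pd.Series) -> pd.Series:
    """Sort scores descending; ties broken by gene id for determinism."""
    if scores.index.duplicated().any():
        raise ValueError("duplicate gene ids in score vector")
    df = scores.rename("score").rename_axis("gene").reset_index()
    df = df.sort_values(["score", "gene"], ascending=[False, True], kind="mergesort")
    return pd.Series(df["score"].to_numpy(), index=df["gene"].to_numpy())


def _es_from_positions(pos: np.ndarray, weights: np.ndarray, n_total: int):
    """ES of hits at (sorted) ranked-list positions, |score|-weighted (p=1).

    Returns (es, hit_index_of_extremum, is_positive). The running sum only
    changes direction at hit positions, so it suffices to evaluate the walk
    just before and just after each hit.
    """
    n_set = pos.size
    if n_set == 0 or n_set >= n_total:
        raise ValueError("hit set must be a non-empty strict subset of the list")
    hw = weights[pos]
    wsum = hw.sum()
    if wsum == 0:
        raise ValueError("all hit scores are zero; enrichment score undefined")
    miss = (pos - np.arange(n_set)) / (n_total - n_set)
    after = np.cumsum(hw) / wsum - miss
    before = after - hw / wsum
    i_max = int(np.argmax(after))
    i_min = int(np.argmin(before))
    if after[i_max] >= -before[i_min]:
        return float(after[i_max]), i_max, True
    return float(before[i_min]), i_min, False


def enrichment_score(ranked: pd.Series, members) -> tuple[float, list[str]]:
    """Weighted running-sum ES of a gene set in a ranked list.

    Returns the ES and the leading-edge genes: for positive ES the member
    genes at or before the running-sum maximum, for negative ES the members
    at or after the minimum.
    """
    genes = np.asarray(ranked.index)
    scores = ranked.to_numpy(dtype=float)
    hit = np.isin(genes, list(members))
    if not hit.any():
        raise ValueError("gene set has empty intersection with the ranked list")
    pos = np.flatnonzero(hit)
    es, i_ext, positive = _es_from_positions(pos, np.abs(scores), genes.size)
    if positive:
        leading = genes[pos[: i_ext + 1]]
    else:
        leading = genes[pos[i_ext:]]
    return es, list(leading)


def _null_es(n_set: int, weights: np.ndarray, n_total: int, n_perm: int,
             rng: np.random.Generator) -> np.ndarray:
    """Null ES distribution: random hit positions of the same set size.

    Equivalent in law to permuting gene labels of the score vector for a
    single term. Vectorized over permutations.
    """
    u = rng.random((n_perm, n_total))
    pos = np.argpartition(u, n_set - 1, axis=1)[:, :n_set]
    pos.sort(axis=1)
    hw = weights[pos]
    wsum = hw.sum(axis=1, keepdims=True)
    # a null draw with all-zero weights can only happen with degenerate scores
    wsum[wsum == 0] = np.nan
    miss = (pos - np.arange(n_set)[None, :]) / (n_total - n_set)
    after = np.cumsum(hw, axis=1) / wsum - miss
    before = after - hw / wsum
    hi = after.max(axis=1)
    lo = before.min(axis=1)
    return np.where(hi >= -lo, hi, lo)


def gsea_preranked(ranked: pd.Series, collection: GeneSetCollection,
                   min_size: int = 5, max_size: int = 2000,
                   n_perm: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Preranked GSEA over a collection, with permutation NES, p, and FDR q.

    Set sizes are evaluated after intersecting each term with the ranked
    universe; terms outside [min_size, max_size] are excluded. NES divides
    ES by the mean |null ES| of matching sign; p is the add-one sign-matched
    permutation tail; q is Benjamini-Hochberg within each sign stratum.
    """
    if len(ranked) < 50:
        raise ValueError("ranked list too short (< 50 genes)")
    ranked = rank_genes(ranked)
    universe = set(ranked.index)
    weights = np.abs(ranked.to_numpy(dtype=float))
    n_total = len(ranked)
    rng = np.random.default_rng(seed)

    rows = []
    for s in collection:
        members = [g for g in s.genes if g in universe]
        if not members:
            warnings.warn(f"term {s.term_id!r}: no members in ranked universe; skipped")
            continue
        size = len(members)
        if size < min_size or size > max_size:
            continue
        es, leading = enrichment_score(ranked, members)
        null = _null_es(size, weights, n_total, n_perm, rng)
        same_sign = null >= 0 if es >= 0 else null <= 0
        mean_mag = np.abs(null[same_sign]).mean() if same_sign.any() else np.nan
        nes = es / mean_mag if mean_mag and np.isfinite(mean_mag) else np.nan
        # tail within the sign-matched null stratum (two-sided calibration)
        matched = null[same_sign]
        extreme = (matched >= es) if es >= 0 else (matched <= es)
        p = (1 + int(extreme.sum())) / (1 + matched.size)
        rows.append({"term_id": s.term_id, "name": s.name, "size": size,
                     "es": es, "nes": nes, "p": p,
                     "n_leading_edge": len(leading),
                     "leading_edge": ",".join(leading)})
    if not rows:
        warnings.warn("all terms filtered out; empty enrichment result")
        return pd.DataFrame(columns=["term_id", "name", "size", "es", "nes",
                                     "p", "q", "n_leading_edge", "leading_edge"])
    out = pd.DataFrame(rows).set_index("term_id")
    out["q"] = np.nan
    for stratum in (out["nes"] >= 0, out["nes"] < 0):
        if stratum.any():
            out.loc[stratum, "q"] = bh_fdr(out.loc[stratum, "p"].to_numpy())
    out = out.sort_values("nes", ascending=False)
    return out[["name", "size", "n_leading_edge", "es", "nes", "p", "q",
                "leading_edge"]]


def weighted_set_cover(results: pd.DataFrame, k: int = 10) -> list[str]:
    """Greedy redundancy reduction over significant terms.

    Each term is weighted by -log10(p); the greedy step picks the term with
    the largest weight * (number of not-yet-covered leading-edge genes),
    breaking ties by larger marginal coverage then lexical term id. Stops
    after k terms or when no term adds coverage.
    """
    if results.empty:
        return []
    weights = -np.log10(np.maximum(results["p"].to_numpy(dtype=float), 1e-300))
    leading = {t: set(str(le).split(",")) if le else set()
               for t, le in results["leading_edge"].items()}
    wmap = dict(zip(results.index, weights))
    covered: set[str] = set()
    chosen: list[str] = []
    remaining = list(results.index)
    while remaining and len(chosen) < k:
        scored = [(len(leading[t] - covered), t) for t in remaining]
        new, t = min(scored, key=lambda s: (-wmap[s[1]] * s[0], -s[0], s[1]))
        if new == 0:
            break
        chosen.append(t)
        covered |= leading[t]
        remaining.remove(t)
    return chosen
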