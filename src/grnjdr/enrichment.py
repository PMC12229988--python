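"""Interpretation of survival-associated factors.

Back-mapped gene (indegree) weights are interpreted with preranked gene set
enrichment: genes are ranked by their factor weight and a weighted
Kolmogorov-Smirnov running sum scores each gene set, with a gene-label
permutation null. Back-mapped TF (outdegree) weights are interpreted by
taking the top TFs per survival-associated factor and testing the overlap
between two datasets' top-TF sets with a one-sided Fisher exact test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .factor import FeatureWeights
from .survival import adjust_bh

__all__ = [
    "GeneSetCollection",
    "read_gmt",
    "gsea_preranked",
    "top_tfs",
    "overlap_fisher",
    "TfOverlapResult",
]


@dataclass
class GeneSetCollection:
    """Named, non-empty gene sets (e.g. hallmark pathways)."""

    sets: dict[str, set[str]]
    source: str = ""

    def __post_init__(self) -> None:
        empty = [n for n, s in self.sets.items() if not s]
        if empty:
            raise ValueError(f"empty gene sets: {empty[:5]}")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a tab-separated GMT file: set name, description, member genes.

    Duplicate genes within a set are stored once; a line with fewer than
    three fields is malformed and reported with its line number.
    """
    path = Path(path)
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name = fields[0]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = {g for g in fields[2:] if g}
    if not sets:
        warnings.warn(f"{path}: empty GMT file", stacklevel=2)
    return GeneSetCollection(sets=sets, source=str(path))


def _es_from_hits(absr: np.ndarray, hit: np.ndarray) -> tuple[float, int]:
    """ES (signed extreme deviation) and its peak index for one hit mask.

    ``absr`` is |statistic| in ranked order; hits increment proportionally
    to |statistic| (exponent 1), misses decrement uniformly.
    """
    n = absr.size
    s = int(hit.sum())
    hit_w = absr * hit
    denom_hit = hit_w.sum()
    if denom_hit == 0:
        raise ValueError("gene set hits carry zero total weight")
    p_hit = np.cumsum(hit_w) / denom_hit
    if n == s:
        dev = p_hit
    else:
        p_miss = np.cumsum(~hit) / (n - s)
        dev = p_hit - p_miss
    peak = int(np.abs(dev).argmax())
    return float(dev[peak]), peak


def _null_es(absr: np.ndarray, size: int, n_perm: int, rng: np.random.Generator) -> np.ndarray:
    """Gene-label permutation null: ES of ``n_perm`` random size-``size`` sets."""
    n = absr.size
    keys = rng.random((n_perm, n))
    idx = np.argpartition(keys, size - 1, axis=1)[:, :size]
    hits = np.zeros((n_perm, n), dtype=bool)
    np.put_along_axis(hits, idx, True, axis=1)
    hit_w = absr[None, :] * hits
    p_hit = np.cumsum(hit_w, axis=1) / hit_w.sum(axis=1, keepdims=True)
    if n == size:
        dev = p_hit
    else:
        p_miss = np.cumsum(~hits, axis=1) / (n - size)
        dev = p_hit - p_miss
    peaks = np.abs(dev).argmax(axis=1)
    return dev[np.arange(n_perm), peaks]


def gsea_preranked(
    weights: pd.Series,
    sets: GeneSetCollection,
    n_perm: int = 1000,
    min_size: int = 15,
    max_size: int = 500,
    seed: int = 13,
) -> pd.DataFrame:
    """Preranked gene set enrichment on a per-gene ranking statistic.

    Genes are sorted by decreasing statistic; the running sum increments by
    |statistic| on set members and decrements uniformly otherwise, and the
    enrichment score is the extreme deviation. The null distribution comes
    from random same-size gene sets; p = (b + 1) / (m + 1) where b counts
    null scores at least as extreme among the m null scores of matching
    sign, so permutation p-values are never zero. NES divides ES by the
    mean |null ES| of matching sign. Sets outside [min_size, max_size]
    after intersection with the ranked universe are skipped, as are sets
    with no overlap.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    r = weights.dropna()
    if r.nunique() <= 1:
        raise ValueError("ranking statistic is constant; ranking undefined")
    order = np.argsort(-r.to_numpy(dtype=float), kind="stable")
    genes = np.asarray(r.index)[order]
    absr = np.abs(r.to_numpy(dtype=float)[order])
    pos = {g: i for i, g in enumerate(genes)}
    rng = np.random.default_rng(seed)

    null_cache: dict[int, np.ndarray] = {}
    rows = []
    for name, members in sets.sets.items():
        inside = sorted(members & set(genes))
        size = len(inside)
        if size == 0:
            warnings.warn(f"set {name!r} has no overlap with the ranking; skipped",
                          stacklevel=2)
            continue
        if not min_size <= size <= max_size:
            continue
        hit = np.zeros(genes.size, dtype=bool)
        hit[[pos[g] for g in inside]] = True
        es, peak = _es_from_hits(absr, hit)
        if size not in null_cache:
            null_cache[size] = _null_es(absr, size, n_perm, rng)
        null = null_cache[size]
        same_sign = null * np.sign(es) > 0 if es != 0 else np.ones_like(null, bool)
        b = int((same_sign & (np.abs(null) >= abs(es))).sum())
        # compare against the same-signed part of the null, as in standard
        # preranked GSEA; +1 keeps permutation p-values strictly positive
        p = (b + 1) / (int(same_sign.sum()) + 1)
        mean_null = float(np.abs(null[same_sign]).mean()) if same_sign.any() else np.nan
        nes = es / mean_null if mean_null and np.isfinite(mean_null) else np.nan
        if es >= 0:
            leading = [g for g in genes[: peak + 1] if g in members]
        else:
            leading = [g for g in genes[peak:] if g in members]
        rows.append(
            {"set": name, "size": size, "es": es, "nes": nes, "p": p,
             "leading_edge": ",".join(leading)}
        )
    out = pd.DataFrame(rows)
    if not out.empty:
        out["fdr"] = adjust_bh(out["p"].to_numpy())
        out = out.set_index("set")
    return out


def top_tfs(
    outdegree_weights: FeatureWeights,
    saf_ids: list[str],
    n_top: int = 20,
) -> tuple[set[str], dict[str, list[str]]]:
    """Top-|weight| TFs per survival-associated factor, and their union.

    Ties at the selection boundary are broken by TF identifier order so the
    output is deterministic.
    """
    if not saf_ids:
        raise ValueError("no survival-associated factors supplied")
    w = outdegree_weights.weights
    if n_top > w.shape[0]:
        raise ValueError(f"n_top={n_top} exceeds the {w.shape[0]} available TFs")
    per_saf: dict[str, list[str]] = {}
    for f in saf_ids:
        if f not in w.columns:
            raise KeyError(f"unknown factor {f!r}")
        ranked = sorted(w.index, key=lambda t: (-abs(w.at[t, f]), t))
        per_saf[f] = ranked[:n_top]
    union = set().union(*per_saf.values())
    return union, per_saf


@dataclass
class TfOverlapResult:
    """Fisher exact test of the overlap between two TF sets."""

    a: int  # |A ∩ B|
    b: int  # |A \ B|
    c: int  # |B \ A|
    d: int  # |U| - a - b - c
    odds_ratio: float
    p_greater: float
    p_two_sided: float

    @property
    def universe_size(self) -> int:
        return self.a + self.b + self.c + self.d


def overlap_fisher(
    set_a: set[str], set_b: set[str], universe: set[str]
) -> TfOverlapResult:
    """One-sided (greater) Fisher exact test of two sets' overlap.

    The p-value is the exact hypergeometric upper tail of the observed
    intersection size given the universe; the odds ratio is the sample
    odds ratio a*d / (b*c), infinite when b*c = 0 and a*d > 0.
    """
    stray = sorted((set_a | set_b) - universe)
    if stray:
        raise ValueError(f"sets not contained in universe: {stray[:10]}")
    a = len(set_a & set_b)
    b = len(set_a - set_b)
    c = len(set_b - set_a)
    d = len(universe) - a - b - c
    if b * c == 0:
        odds = float("inf") if a * d > 0 else (0.0 if a == 0 else float("nan"))
    else:
        odds = a * d / (b * c)
    # upper tail: P(overlap >= a) when drawing |B| from a universe with |A| marked
    p_greater = float(stats.hypergeom.sf(a - 1, len(universe), len(set_a), len(set_b)))
    _, p_two = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return TfOverlapResult(
        a=a, b=b, c=c, d=d, odds_ratio=odds,
        p_greater=min(p_greater, 1.0), p_two_sided=float(p_two),
    )
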