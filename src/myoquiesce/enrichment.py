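"""Gene-set enrichment: signal-to-noise ranking, weighted KS enrichment score,
phenotype-permutation null, and overlap-coefficient edges for enrichment-map
summaries.

The enrichment score of a set is the signed extremum of a weighted
Kolmogorov-Smirnov running sum over the ranked gene list: member hits
increment by |metric|^p / sum(|metric|^p over members) and misses decrement by
1/(N - m). Nominal p-values come from phenotype-label permutations that
regenerate the ranking each time, with the add-one rule so p is never exactly
zero; NES and FDR use the sign-stratified normalization.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io import GeneSetCollection, canonical_symbol

logger = logging.getLogger(__name__)

SD_FLOOR_FRAC = 0.2  # sd floored at 0.2 * |mean| (desktop GSEA convention)
_EPS = 1e-8


def signal_to_noise(expr: np.ndarray, is_a: np.ndarray, floor_frac: float = SD_FLOOR_FRAC) -> np.ndarray:
    """(mu_A - mu_B) / (sigma_A + sigma_B) per gene, each group sd floored at
    max(sigma, floor_frac * |mu|, eps). ``expr`` is genes x samples."""
    a = expr[:, is_a]
    b = expr[:, ~is_a]
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("each group needs >= 2 samples for signal-to-noise ranking")
    mu_a, mu_b = a.mean(axis=1), b.mean(axis=1)
    sd_a = np.maximum.reduce([a.std(axis=1, ddof=1), floor_frac * np.abs(mu_a),
                              np.full_like(mu_a, _EPS)])
    sd_b = np.maximum.reduce([b.std(axis=1, ddof=1), floor_frac * np.abs(mu_b),
                              np.full_like(mu_b, _EPS)])
    return (mu_a - mu_b) / (sd_a + sd_b)


def rank_signal_to_noise(expr: pd.DataFrame, labels, group_a: str | None = None,
                         floor_frac: float = SD_FLOOR_FRAC) -> pd.DataFrame:
    """Rank genes by signal-to-noise between two phenotype groups.

    ``expr`` is a genes x samples log-expression frame. Ties are broken
    deterministically (metric descending, then gene symbol ascending).
    """
    labels = np.asarray(labels)
    levels = pd.unique(labels)
    if len(levels) != 2:
        raise ValueError(f"expected exactly 2 label levels, got {list(levels)}")
    if group_a is None:
        group_a = levels[0]
    # alphabetical presort makes the stable metric sort break ties by symbol
    frame = expr.sort_index()
    metric = signal_to_noise(frame.to_numpy(dtype=float), labels == group_a, floor_frac)
    order = np.argsort(-metric, kind="stable")
    return pd.DataFrame({"gene": frame.index.to_numpy()[order], "metric": metric[order]})


def rank_signed_fdr(de: pd.DataFrame, q_floor: float = 1e-300) -> pd.DataFrame:
    """Rank genes by sign(log2fc) * -log10(q) from a DE result table."""
    q = np.maximum(de["q"].to_numpy(dtype=float), q_floor)
    metric = np.sign(de["log2fc"].to_numpy(dtype=float)) * (-np.log10(q))
    frame = pd.DataFrame({"gene": de.index, "metric": metric}).sort_values("gene")
    frame = frame.sort_values("metric", ascending=False, kind="stable")
    return frame.reset_index(drop=True)


def _es_from_positions(pos: np.ndarray, w: np.ndarray, n_universe: int) -> np.ndarray:
    """Vectorized ES. pos: (..., m) sorted member positions; w: matching
    |metric|^p weights; returns ES with shape (...)."""
    m = pos.shape[-1]
    W = w.sum(axis=-1, keepdims=True)
    # degenerate all-zero weights: fall back to equal increments
    w = np.where(W > 0, w, 1.0)
    W = np.where(W > 0, W, float(m))
    cumw = np.cumsum(w, axis=-1)
    idx = np.arange(m)
    if m == n_universe:
        # no misses: compare the hit CDF with the positional CDF
        v = cumw / W - (pos + 1) / n_universe
        u = (cumw - w) / W - pos / n_universe
    else:
        d = 1.0 / (n_universe - m)
        miss_before = (pos - idx) * d
        v = cumw / W - miss_before
        u = (cumw - w) / W - miss_before
    vmax = v.max(axis=-1)
    umin = u.min(axis=-1)
    return np.where(vmax >= -umin, vmax, umin)


def enrichment_score(ranked: pd.DataFrame, gene_set, p: float = 1.0) -> tuple[float, np.ndarray]:
    """Weighted KS enrichment score of ``gene_set`` against a ranked list.

    ``ranked`` has columns gene, metric (ordered). Returns (ES, running sum
    over all N positions). Raises if the set lies fully outside the universe.
    """
    genes = ranked["gene"].to_numpy()
    metric = ranked["metric"].to_numpy(dtype=float)
    members = {canonical_symbol(g) for g in gene_set}
    hit = np.fromiter((canonical_symbol(g) in members for g in genes),
                      dtype=bool, count=len(genes))
    m = int(hit.sum())
    if m == 0:
        raise ValueError("gene set has no members in the ranked universe")
    n = len(genes)
    w = np.where(hit, np.abs(metric) ** p, 0.0)
    total = w[hit].sum()
    if total <= 0:
        w = hit.astype(float)
        total = float(m)
    inc = w / total
    if m < n:
        inc = inc - (~hit) / (n - m)
        running = np.cumsum(inc)
    else:
        running = np.cumsum(inc) - (np.arange(n) + 1) / n
    pos = np.flatnonzero(hit)
    es = float(_es_from_positions(pos[None, :], w[pos][None, :], n)[0])
    return es, running


def gsea(
    expr: pd.DataFrame,
    labels,
    sets: GeneSetCollection,
    nperm: int = 1000,
    weight: float = 1.0,
    size_min: int = 15,
    size_max: int = 500,
    seed: int | None = None,
    group_a: str | None = None,
    permute: str = "phenotype",
) -> pd.DataFrame:
    """GSEA with phenotype-label permutations.

    ``expr`` is genes x samples log expression; ``labels`` the two-group
    phenotype vector. Sets are intersected with the expressed universe and
    gated to [size_min, size_max]. Nominal p uses the add-one rule on
    same-sign permutation scores; NES and FDR use the sign-stratified
    normalization. ``permute="gene_set"`` draws random same-size sets instead
    (recommended for very small sample groups).
    """
    if nperm < 1:
        raise ValueError("nperm must be >= 1")
    if permute not in {"phenotype", "gene_set"}:
        raise ValueError("permute must be 'phenotype' or 'gene_set'")
    labels = np.asarray(labels)
    levels = pd.unique(labels)
    if len(levels) != 2:
        raise ValueError(f"expected exactly 2 label levels, got {list(levels)}")
    if group_a is None:
        group_a = levels[0]
    if min((labels == levels[0]).sum(), (labels == levels[1]).sum()) < 7 \
            and permute == "phenotype":
        logger.warning(
            "fewer than 7 samples per group: phenotype permutations are coarse; "
            "consider permute='gene_set'"
        )

    frame = expr.sort_index()  # alphabetical; stable sort then breaks ties by symbol
    genes = frame.index.to_numpy()
    mat = frame.to_numpy(dtype=float)
    n_genes = len(genes)
    row_of = {g: i for i, g in enumerate(genes)}

    kept: list[tuple[str, np.ndarray]] = []
    for name, members in sets.items():
        rows = np.array(sorted(row_of[g] for g in members if g in row_of), dtype=np.int64)
        if not size_min <= len(rows) <= size_max:
            logger.info("skipping gene set %r: size %d outside [%d, %d] after "
                        "intersection", name, len(rows), size_min, size_max)
            continue
        kept.append((name, rows))
    if not kept:
        return pd.DataFrame(columns=["set", "size", "es", "nes", "p", "q", "leading_edge"])

    rng = np.random.default_rng(seed)
    is_a_obs = labels == group_a

    by_size: dict[int, list[int]] = {}
    for i, (_, rows) in enumerate(kept):
        by_size.setdefault(len(rows), []).append(i)

    def es_all(metric: np.ndarray, member_rows: dict[int, np.ndarray]) -> np.ndarray:
        """ES for every kept set given a metric vector."""
        order = np.argsort(-metric, kind="stable")
        posmap = np.empty(n_genes, dtype=np.int64)
        posmap[order] = np.arange(n_genes)
        out = np.empty(len(kept))
        for size, idxs in by_size.items():
            rows_mat = member_rows[size]  # (S, m) gene-row indices
            pos = posmap[rows_mat]
            srt = np.argsort(pos, axis=1)
            pos_sorted = np.take_along_axis(pos, srt, axis=1)
            w = np.abs(metric[rows_mat]) ** weight
            w_sorted = np.take_along_axis(w, srt, axis=1)
            out[idxs] = _es_from_positions(pos_sorted, w_sorted, n_genes)
        return out

    member_rows = {size: np.stack([kept[i][1] for i in idxs])
                   for size, idxs in by_size.items()}

    metric_obs = signal_to_noise(mat, is_a_obs)
    es_obs = es_all(metric_obs, member_rows)

    es_perm = np.empty((nperm, len(kept)))
    for b in range(nperm):
        if permute == "phenotype":
            perm_is_a = rng.permutation(is_a_obs)
            metric_b = signal_to_noise(mat, perm_is_a)
            es_perm[b] = es_all(metric_b, member_rows)
        else:
            rand_rows = {
                size: np.stack([rng.choice(n_genes, size=size, replace=False)
                                for _ in range(stack.shape[0])])
                for size, stack in member_rows.items()
            }
            es_perm[b] = es_all(metric_obs, rand_rows)

    # nominal p: add-one rule within the same-sign permutation stratum
    pvals = np.empty(len(kept))
    for s, obs in enumerate(es_obs):
        if obs > 0:
            same = es_perm[:, s] > 0
            pvals[s] = (1 + np.sum(es_perm[same, s] >= obs)) / (1 + same.sum())
        elif obs < 0:
            same = es_perm[:, s] < 0
            pvals[s] = (1 + np.sum(es_perm[same, s] <= obs)) / (1 + same.sum())
        else:
            pvals[s] = 1.0

    # sign-stratified normalization
    pos_mean = np.array([
        es_perm[:, s][es_perm[:, s] > 0].mean() if (es_perm[:, s] > 0).any() else np.nan
        for s in range(len(kept))
    ])
    neg_mean = np.array([
        np.abs(es_perm[:, s][es_perm[:, s] < 0]).mean() if (es_perm[:, s] < 0).any() else np.nan
        for s in range(len(kept))
    ])

    def normalize(es_vals: np.ndarray) -> np.ndarray:
        out = np.where(es_vals > 0, es_vals / pos_mean, es_vals / neg_mean)
        return np.where(es_vals == 0, 0.0, out)

    nes_obs = normalize(es_obs)
    nes_perm = np.vstack([normalize(es_perm[b]) for b in range(nperm)])

    qvals = np.empty(len(kept))
    perm_flat = nes_perm.ravel()
    perm_pos = perm_flat[perm_flat > 0]
    perm_neg = perm_flat[perm_flat < 0]
    obs_pos = nes_obs[nes_obs > 0]
    obs_neg = nes_obs[nes_obs < 0]
    for s, nes in enumerate(nes_obs):
        if np.isnan(nes):
            qvals[s] = np.nan
        elif nes > 0:
            num = np.mean(perm_pos >= nes) if len(perm_pos) else 0.0
            den = np.mean(obs_pos >= nes)
            qvals[s] = min(num / den, 1.0) if den > 0 else np.nan
        elif nes < 0:
            num = np.mean(perm_neg <= nes) if len(perm_neg) else 0.0
            den = np.mean(obs_neg <= nes)
            qvals[s] = min(num / den, 1.0) if den > 0 else np.nan
        else:
            qvals[s] = 1.0

    # leading edges from the observed ranking
    order = np.argsort(-metric_obs, kind="stable")
    posmap = np.empty(n_genes, dtype=np.int64)
    posmap[order] = np.arange(n_genes)
    ranked_genes = genes[order]
    leading = []
    for (name, rows), obs in zip(kept, es_obs):
        pos = np.sort(posmap[rows])
        w = np.abs(metric_obs[rows]) ** weight
        w = w[np.argsort(posmap[rows])]
        total = w.sum() if w.sum() > 0 else float(len(rows))
        w = w if w.sum() > 0 else np.ones(len(rows))
        cumw = np.cumsum(w) / total
        if len(rows) < n_genes:
            vals = cumw - (pos - np.arange(len(rows))) / (n_genes - len(rows))
        else:
            vals = cumw - (pos + 1) / n_genes
        if obs >= 0:
            cut = int(np.argmax(vals))
            edge = [g for g in ranked_genes[: pos[cut] + 1] if g in set(genes[rows])]
        else:
            before = vals - w / total
            cut = int(np.argmin(before))
            edge = [g for g in ranked_genes[pos[cut]:] if g in set(genes[rows])]
        leading.append(",".join(edge))

    return pd.DataFrame({
        "set": [name for name, _ in kept],
        "size": [len(rows) for _, rows in kept],
        "es": es_obs,
        "nes": nes_obs,
        "p": pvals,
        "q": qvals,
        "leading_edge": leading,
    })


def overlap_coefficient(set_a, set_b) -> float:
    """|A intersect B| / min(|A|, |B|)."""
    a = {canonical_symbol(g) for g in set_a}
    b = {canonical_symbol(g) for g in set_b}
    if not a or not b:
        raise ValueError("overlap coefficient is undefined for empty sets")
    return len(a & b) / min(len(a), len(b))


def enrichment_edges(
    results: pd.DataFrame,
    sets: GeneSetCollection,
    oc_min: float = 0.1,
    p_max: float = 0.005,
    fdr_max: float = 0.1,
) -> pd.DataFrame:
    """Overlap-coefficient edge list between enriched sets passing the gates."""
    passing = results[(results["p"] < p_max) & (results["q"] < fdr_max)]["set"].tolist()
    rows = []
    for i, a in enumerate(passing):
        for b in passing[i + 1:]:
            oc = overlap_coefficient(sets[a], sets[b])
            if oc >= oc_min:
                rows.append({"set_a": a, "set_b": b, "overlap_coefficient": oc})
    return pd.DataFrame(rows, columns=["set_a", "set_b", "overlap_coefficient"])
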