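"""The 39-statistic summary of a microsatellite dataset.

Per population and locus: number of alleles *K*, unbiased expected
heterozygosity *H* = n/(n-1) * (1 - sum p_i^2), and the modified
Garza-Williamson statistic *NGW* = K / (range + 1) where the range is in
repeat units (low NGW signals a bottleneck).  Per-population locus means
and locus SDs are averaged within four regional groups (AFR, ENA, CAS,
EAS).  Differentiation is measured by the microsatellite-specific R_ST: an
AMOVA variance decomposition of repeat counts, numerators and denominators
summed over loci; negative per-locus among-population components are
truncated at zero (the usual convention for variance-component
estimators).  Finally, per-population mean heterozygosity is regressed on
least-cost distance from the expansion origin under two routings, giving
the ``slope`` (with short sea crossings enabled) and ``slope_levant``
(land route through the Levant only) statistics.

Names are the join keys of the ABC layer; see :data:`SUMMARY_NAMES`.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from .landscape import GROUPS, Landscape, least_cost_distance

GROUP_PAIRS = tuple(itertools.combinations(GROUPS, 2))

SUMMARY_NAMES: tuple[str, ...] = tuple(
    f"{stat}{suffix}_{g}" for g in GROUPS for stat in ("K", "H", "NGW") for suffix in ("", "_sd")
) + tuple(f"{stat}_sd_pooled" for stat in ("K", "H", "NGW")) + tuple(
    f"FST_{g}" for g in GROUPS
) + tuple(f"FST_{a}-{b}" for a, b in GROUP_PAIRS) + ("slope", "slope_levant")

assert len(SUMMARY_NAMES) == 39


class SummaryError(ValueError):
    """A dataset/design combination on which a statistic is undefined."""


# ---------------------------------------------------------------------------
# per-locus statistics
# ---------------------------------------------------------------------------


def _gene_matrix(dataset, pop):
    """(2n, L) repeat counts with missing as MISSING sentinel."""
    g = dataset.genotypes[pop]
    n, L, _ = g.shape
    return g.transpose(0, 2, 1).reshape(2 * n, L)


def locus_stats(dataset, population: str) -> pd.DataFrame:
    """Per-locus K, H, NGW for one population.

    Loci with fewer than two typed genes in this population are excluded
    (index reflects the retained loci).
    """
    from .coalescent import MISSING

    gm = _gene_matrix(dataset, population)
    rows = []
    kept = []
    for j, locus in enumerate(dataset.locus_names):
        genes = gm[:, j]
        genes = genes[genes != MISSING]
        n = len(genes)
        if n < 2:
            continue
        vals, counts = np.unique(genes, return_counts=True)
        p = counts / n
        k = len(vals)
        h = (n / (n - 1)) * (1.0 - float(np.sum(p**2)))
        ngw = k / (float(vals.max() - vals.min()) + 1.0)
        rows.append((k, h, ngw))
        kept.append(locus)
    return pd.DataFrame(rows, columns=["K", "H", "NGW"], index=kept)


def _pooled_stats(dataset) -> pd.DataFrame:
    """K, H, NGW per locus on the pooled all-individuals sample."""
    from .coalescent import MISSING

    mats = [_gene_matrix(dataset, p) for p in dataset.populations]
    gm = np.vstack(mats)
    rows, kept = [], []
    for j, locus in enumerate(dataset.locus_names):
        genes = gm[:, j]
        genes = genes[genes != MISSING]
        n = len(genes)
        if n < 2:
            continue
        vals, counts = np.unique(genes, return_counts=True)
        p = counts / n
        k = len(vals)
        h = (n / (n - 1)) * (1.0 - float(np.sum(p**2)))
        ngw = k / (float(vals.max() - vals.min()) + 1.0)
        rows.append((k, h, ngw))
        kept.append(locus)
    return pd.DataFrame(rows, columns=["K", "H", "NGW"], index=kept)


# ---------------------------------------------------------------------------
# R_ST
# ---------------------------------------------------------------------------


def _moments(dataset, pop):
    """Per-locus (n, mean, within-SS) of repeat counts, missing excluded."""
    from .coalescent import MISSING

    gm = _gene_matrix(dataset, pop).astype(float)
    mask = gm != MISSING
    n = mask.sum(axis=0).astype(float)
    s = np.where(mask, gm, 0.0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = s / n
    ss = np.where(mask, (gm - mean) ** 2, 0.0).sum(axis=0)
    return n, mean, ss


def rst_components(dataset, pop_a: str, pop_b: str):
    """Per-locus among/within variance components (sigma2_a, sigma2_w).

    Standard two-level weighted ANOVA on repeat counts; loci without at
    least two typed genes in each population are dropped.  Negative
    among-population components are truncated at zero.
    """
    na, ma, sa = _moments(dataset, pop_a)
    nb, mb, sb = _moments(dataset, pop_b)
    ok = (na >= 2) & (nb >= 2)
    if not ok.any():
        raise SummaryError(f"populations {pop_a!r} and {pop_b!r} share no typed locus")
    na, ma, sa = na[ok], ma[ok], sa[ok]
    nb, mb, sb = nb[ok], mb[ok], sb[ok]
    N = na + nb
    grand = (na * ma + nb * mb) / N
    ss_w = sa + sb
    ms_w = ss_w / (N - 2)
    ss_a = na * (ma - grand) ** 2 + nb * (mb - grand) ** 2
    ms_a = ss_a  # df_a = 1 for two populations
    n0 = (N - (na**2 + nb**2) / N) / 1.0
    sig_a = np.maximum((ms_a - ms_w) / n0, 0.0)
    return sig_a, ms_w


def pairwise_rst(dataset, pop_a: str, pop_b: str) -> float:
    """Multilocus R_ST between two populations (sum components over loci,
    then divide)."""
    sig_a, sig_w = rst_components(dataset, pop_a, pop_b)
    denom = float(np.sum(sig_a + sig_w))
    if denom <= 0:  # every locus monomorphic across both samples
        return 0.0
    return float(np.sum(sig_a) / denom)


# ---------------------------------------------------------------------------
# heterozygosity-distance slope
# ---------------------------------------------------------------------------


def _slope(h_by_pop: dict[str, float], distances: dict[str, float]) -> float:
    pops = [p for p in h_by_pop if p in distances]
    if len(pops) < 3:
        raise SummaryError("need at least three populations for the slope")
    h = np.array([h_by_pop[p] for p in pops])
    d = np.array([distances[p] for p in pops], dtype=float)
    if np.allclose(d.var(), 0.0):
        raise SummaryError("distance variance is zero; slope undefined")
    return float(np.polyfit(d, h, 1)[0])


def het_distance_slope(dataset, distances: dict[str, float], origin_label: str | None = None) -> float:
    """OLS slope (per km) of per-population mean heterozygosity on
    least-cost distance from the expansion origin."""
    h_mean = {p: float(locus_stats(dataset, p)["H"].mean()) for p in dataset.populations}
    return _slope(h_mean, distances)


# ---------------------------------------------------------------------------
# the 39-statistic vector
# ---------------------------------------------------------------------------


def summarize(
    dataset,
    landscape: Landscape | None = None,
    distances: dict[str, dict[str, float]] | None = None,
) -> pd.Series:
    """Compute the named 39-statistic summary vector of a dataset.

    Distances may be supplied directly as ``{"levant_only": {...},
    "levant_horn_gibraltar": {...}}`` (per-population km) to avoid
    recomputing least-cost paths per dataset; otherwise they are derived
    from the landscape.
    """
    groups: dict[str, list[str]] = {g: [] for g in GROUPS}
    for p in dataset.populations:
        g = dataset.groups.get(p)
        if g not in groups:
            raise SummaryError(f"population {p!r} has no valid group assignment")
        groups[g].append(p)
    for g, pops in groups.items():
        if len(pops) < 2:
            raise SummaryError(f"group {g} has {len(pops)} population(s); need >= 2")

    per_pop = {p: locus_stats(dataset, p) for p in dataset.populations}
    out = {}
    for g in GROUPS:
        pops = groups[g]
        for stat in ("K", "H", "NGW"):
            means = [per_pop[p][stat].mean() for p in pops]
            sds = [per_pop[p][stat].std(ddof=1) for p in pops]
            out[f"{stat}_{g}"] = float(np.mean(means))
            out[f"{stat}_sd_{g}"] = float(np.mean(sds))

    pooled = _pooled_stats(dataset)
    for stat in ("K", "H", "NGW"):
        out[f"{stat}_sd_pooled"] = float(pooled[stat].std(ddof=1))

    rst_cache: dict[tuple[str, str], float] = {}

    def rst(a, b):
        key = (a, b) if a < b else (b, a)
        if key not in rst_cache:
            rst_cache[key] = pairwise_rst(dataset, *key)
        return rst_cache[key]

    for g in GROUPS:
        pairs = list(itertools.combinations(groups[g], 2))
        out[f"FST_{g}"] = float(np.mean([rst(a, b) for a, b in pairs]))
    for ga, gb in GROUP_PAIRS:
        vals = [rst(a, b) for a in groups[ga] for b in groups[gb]]
        out[f"FST_{ga}-{gb}"] = float(np.mean(vals))

    if distances is None:
        if landscape is None:
            raise SummaryError("need a landscape or precomputed distances for the slopes")
        distances = {
            r: least_cost_distance(landscape, routing=r)
            for r in ("levant_only", "levant_horn_gibraltar")
        }
    h_mean = {p: float(per_pop[p]["H"].mean()) for p in dataset.populations}
    out["slope"] = _slope(h_mean, distances["levant_horn_gibraltar"])
    out["slope_levant"] = _slope(h_mean, distances["levant_only"])

    return pd.Series([out[n] for n in SUMMARY_NAMES], index=list(SUMMARY_NAMES), dtype=float)


def summary_frame(vectors: list[pd.Series], sim_ids=None, models=None) -> pd.DataFrame:
    """Stack summary vectors into the ABC exchange table."""
    df = pd.DataFrame([v.values for v in vectors], columns=list(SUMMARY_NAMES))
    if sim_ids is not None:
        df.insert(0, "sim_id", sim_ids)
    if models is not None:
        df.insert(1 if sim_ids is not None else 0, "model", models)
    return df
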