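"""Adaptive differential-abundance and enrichment statistics for label-free
proteomes of lymph nodes from two drainage sites (mandibular = mucosa-draining,
subiliac = skin-draining) and two ages.

The abundance container is a pandas DataFrame of log2 abundances (proteins x
samples); the sample design is a DataFrame indexed by sample id with columns
``site`` (mandibular/subiliac), ``age`` (young/old) and ``mouse_id``.

Per-protein testing is adaptive: Shapiro-Wilk normality in every group of the
contrast gates an unpaired Welch t-test versus a Wilcoxon rank-sum test;
p-values are Benjamini-Hochberg adjusted to q-values. Proteins that rise with
age in *both* node types can be removed from the site contrast to isolate
age-independent regional differences. Enrichment runs on user-supplied gene
sets only: single-sample GSEA (rank-weighted running sum per sample) and
pre-ranked GSEA on per-protein t-statistics with a permutation null.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .morphometry import compare_groups

__all__ = [
    "CONTRASTS",
    "simulate_abundances",
    "total_sum_normalize",
    "filter_missing",
    "group_log2fc",
    "adaptive_test",
    "bh_adjust",
    "age_independent_filter",
    "volcano_table",
    "ssgsea_scores",
    "preranked_gsea",
    "group_test_scores",
    "overrepresentation",
    "read_gmt",
    "write_gmt",
]

SITES = ("mandibular", "subiliac")
AGES = ("young", "old")

#: contrast name -> (numerator selector, denominator selector); selectors are
#: (site, age) with None meaning "both levels, averaged as group means"
CONTRASTS: dict[str, tuple] = {
    "mand_vs_sub_mean": (("mandibular", None), ("subiliac", None)),
    "mand_vs_sub_young": (("mandibular", "young"), ("subiliac", "young")),
    "mand_vs_sub_old": (("mandibular", "old"), ("subiliac", "old")),
    "sub_vs_mand_mean": (("subiliac", None), ("mandibular", None)),
    "sub_vs_mand_young": (("subiliac", "young"), ("mandibular", "young")),
    "sub_vs_mand_old": (("subiliac", "old"), ("mandibular", "old")),
    "old_vs_young_mand": (("mandibular", "old"), ("mandibular", "young")),
    "old_vs_young_sub": (("subiliac", "old"), ("subiliac", "young")),
}


def _samples(design: pd.DataFrame, site=None, age=None) -> list[str]:
    sel = pd.Series(True, index=design.index)
    if site is not None:
        sel &= design["site"] == site
    if age is not None:
        sel &= design["age"] == age
    return design.index[sel].tolist()


# ---------------------------------------------------------------------------
# synthetic data


def simulate_abundances(n_proteins: int, n_per_group: int,
                        effects: dict | None = None, seed: int = 0,
                        baseline_mean: tuple[float, float] = (25.0, 2.0),
                        sigma_range: tuple[float, float] = (0.25, 0.6),
                        ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate a log2 abundance matrix over the 2x2 site/age design.

    ``effects`` maps effect kinds to {protein_id: delta_log2}:
    ``site`` (added to mandibular samples), ``age_both`` (added to old samples
    of both sites), ``age_mand`` / ``age_sub`` (single-site age effects).
    Each sample pair (two LNs per animal) shares a mouse id. The returned
    truth table records per-protein effect membership.
    """
    if n_per_group < 2:
        raise ValueError("need at least 2 samples per group")
    if n_proteins < 1:
        raise ValueError("need at least one protein")
    effects = effects or {}
    rng = np.random.default_rng(seed)
    proteins = [f"P{i:05d}" for i in range(n_proteins)]
    rows = []
    for site in SITES:
        for age in AGES:
            for i in range(n_per_group):
                sid = f"{site[:4]}_{age}_{i:02d}"
                rows.append((sid, site, age, f"{age}_m{i // 2:02d}"))
    design = pd.DataFrame(rows, columns=["sample_id", "site", "age", "mouse_id"]
                          ).set_index("sample_id")

    mu = rng.normal(baseline_mean[0], baseline_mean[1], size=n_proteins)
    sigma = rng.uniform(*sigma_range, size=n_proteins)
    values = rng.normal(mu[:, None], sigma[:, None],
                        size=(n_proteins, len(design)))
    mat = pd.DataFrame(values, index=proteins, columns=design.index)

    idx = {p: i for i, p in enumerate(proteins)}
    is_mand = (design["site"] == "mandibular").to_numpy()
    is_old = (design["age"] == "old").to_numpy()
    masks = {
        "site": is_mand,
        "age_both": is_old,
        "age_mand": is_old & is_mand,
        "age_sub": is_old & ~is_mand,
    }
    truth = pd.DataFrame(
        {k: 0.0 for k in ("site", "age_both", "age_mand", "age_sub")},
        index=proteins,
    )
    for kind, table in effects.items():
        if kind not in masks:
            raise KeyError(f"unknown effect kind {kind!r}")
        for pid, delta in table.items():
            mat.iloc[idx[pid], masks[kind]] += delta
            truth.loc[pid, kind] = delta
    truth["is_null"] = (truth[["site", "age_both", "age_mand", "age_sub"]]
                        .eq(0).all(axis=1))
    return mat, design, truth


def total_sum_normalize(raw: pd.DataFrame) -> pd.DataFrame:
    """Per-sample total-protein normalisation of linear abundances followed by
    log2 (the usual 'normalised to total protein amount' convention)."""
    totals = raw.sum(axis=0)
    scaled = raw * (totals.mean() / totals)
    return np.log2(scaled)


def filter_missing(mat: pd.DataFrame, design: pd.DataFrame,
                   min_frac: float = 0.6) -> pd.DataFrame:
    """Drop proteins quantified (finite) in fewer than ``min_frac`` of the
    samples of any site x age group."""
    keep = pd.Series(True, index=mat.index)
    for site in SITES:
        for age in AGES:
            cols = _samples(design, site, age)
            if not cols:
                continue
            frac = np.isfinite(mat[cols]).sum(axis=1) / len(cols)
            keep &= frac >= min_frac
    return mat.loc[keep]


# ---------------------------------------------------------------------------
# differential abundance


def group_log2fc(mat: pd.DataFrame, design: pd.DataFrame,
                 contrast: str) -> pd.Series:
    """Difference of group means of log2 abundances for one named contrast.

    For "mean" contrasts the two age-group means are computed per site and
    averaged before differencing, so unbalanced groups cannot tilt the mean.
    """
    if contrast not in CONTRASTS:
        raise KeyError(f"unknown contrast {contrast!r}")
    (site_a, age_a), (site_b, age_b) = CONTRASTS[contrast]

    def side_mean(site, age):
        if age is None:
            parts = [mat[_samples(design, site, ag)].mean(axis=1) for ag in AGES]
            return sum(parts) / len(parts)
        return mat[_samples(design, site, age)].mean(axis=1)

    return side_mean(site_a, age_a) - side_mean(site_b, age_b)


def adaptive_test(mat: pd.DataFrame, design: pd.DataFrame, contrast: str,
                  alpha_norm: float = 0.05) -> pd.DataFrame:
    """Shapiro-Wilk-gated per-protein testing for one contrast.

    Normality in *all* groups of the contrast (p > alpha_norm) routes the
    protein to Welch's unpaired t-test, anything else (including zero-variance
    groups) to the Wilcoxon rank-sum test. Returns a DataFrame with columns
    log2fc, p, q, test_used, normal_all_groups.
    """
    if contrast not in CONTRASTS:
        raise KeyError(f"unknown contrast {contrast!r}")
    (site_a, age_a), (site_b, age_b) = CONTRASTS[contrast]
    cols_a = _samples(design, site_a, age_a)
    cols_b = _samples(design, site_b, age_b)
    if len(cols_a) < 3 or len(cols_b) < 3:
        raise ValueError("each contrast group needs n >= 3 for Shapiro-Wilk")
    A = mat[cols_a].to_numpy(dtype=float)
    B = mat[cols_b].to_numpy(dtype=float)
    lfc = group_log2fc(mat, design, contrast)
    out = []
    for i in range(len(mat)):
        a, b = A[i], B[i]
        a, b = a[np.isfinite(a)], b[np.isfinite(b)]
        if len(a) < 3 or len(b) < 3:
            out.append((np.nan, "wilcoxon", False))
            continue
        normal = True
        for g in (a, b):
            if np.ptp(g) == 0:
                normal = False
                break
            if stats.shapiro(g).pvalue <= alpha_norm:
                normal = False
                break
        if normal:
            p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
            test = "t"
        else:
            p = compare_groups(a, b)[1]
            test = "wilcoxon"
        out.append((p, test, normal))
    res = pd.DataFrame(out, index=mat.index,
                       columns=["p", "test_used", "normal_all_groups"])
    res.insert(0, "log2fc", lfc)
    finite = np.isfinite(res["p"].to_numpy(dtype=float))
    q = np.full(len(res), np.nan)
    if finite.any():
        q[finite] = bh_adjust(res["p"].to_numpy(dtype=float)[finite])
    res["q"] = q
    return res[["log2fc", "p", "q", "test_used", "normal_all_groups"]]


def contrast_tstats(mat: pd.DataFrame, design: pd.DataFrame,
                    contrast: str) -> pd.Series:
    """Per-protein Welch t-statistics for one contrast (the pre-ranked GSEA
    input)."""
    if contrast not in CONTRASTS:
        raise KeyError(f"unknown contrast {contrast!r}")
    (site_a, age_a), (site_b, age_b) = CONTRASTS[contrast]
    A = mat[_samples(design, site_a, age_a)].to_numpy(dtype=float)
    B = mat[_samples(design, site_b, age_b)].to_numpy(dtype=float)
    t = stats.ttest_ind(A, B, axis=1, equal_var=False).statistic
    return pd.Series(t, index=mat.index)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values; invariant to input order."""
    p = np.asarray(p, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def age_independent_filter(site_rows: pd.DataFrame, age_rows_mand: pd.DataFrame,
                           age_rows_sub: pd.DataFrame, fc_min: float = 0.0,
                           q_max: float = 0.05
                           ) -> tuple[pd.DataFrame, list[str]]:
    """Remove proteins upregulated with age in both node types from a site
    contrast. Returns (filtered rows, removed protein ids)."""
    if not (site_rows.index.equals(age_rows_mand.index)
            and site_rows.index.equals(age_rows_sub.index)):
        raise ValueError("row sets must share one protein universe")
    up_mand = (age_rows_mand["log2fc"] > fc_min) & (age_rows_mand["q"] <= q_max)
    up_sub = (age_rows_sub["log2fc"] > fc_min) & (age_rows_sub["q"] <= q_max)
    removed = site_rows.index[(up_mand & up_sub).fillna(False)].tolist()
    return site_rows.drop(index=removed), removed


def volcano_table(rows: pd.DataFrame, q_max: float = 0.05) -> pd.DataFrame:
    """Volcano categories: 'strong' (fold >= 2, significant), 'moderate'
    (1.5 <= fold < 2, significant), else 'none'; fold = 2**|log2fc|."""
    fold = 2.0 ** rows["log2fc"].abs()
    sig = rows["q"] <= q_max
    category = np.where(sig & (fold >= 2.0), "strong",
                        np.where(sig & (fold >= 1.5), "moderate", "none"))
    with np.errstate(divide="ignore"):
        neg_log_q = -np.log10(rows["q"].to_numpy(dtype=float))
    return pd.DataFrame(
        {"log2fc": rows["log2fc"], "fold": fold, "neg_log10_q": neg_log_q,
         "category": category},
        index=rows.index,
    )


# ---------------------------------------------------------------------------
# gene-set enrichment


def read_gmt(path) -> dict[str, list[str]]:
    """Read gene sets in GMT format (name, description, members...)."""
    from gseapy.parser import read_gmt as _read
    return {k: list(v) for k, v in _read(str(path)).items()}


def write_gmt(sets: dict[str, list[str]], path) -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, "na", *members]) + "\n")


def _restrict_sets(sets: dict[str, list[str]], universe) -> dict[str, list[str]]:
    uni = set(universe)
    out = {name: [g for g in members if g in uni]
           for name, members in sets.items()}
    out = {k: v for k, v in out.items() if v}
    if not out:
        raise ValueError("no gene set overlaps the measured proteins")
    return out


def ssgsea_scores(mat: pd.DataFrame, sets: dict[str, list[str]],
                  weight_alpha: float = 0.25
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Single-sample GSEA on log2 abundances.

    Per sample, proteins are ranked by abundance (average ranks on ties,
    highest abundance = highest rank); the enrichment score is the summed
    difference between the rank-weighted in-set ECDF (weight = rank**alpha)
    and the uniform out-of-set ECDF, walked from the top of the ranking.
    Returns (scores, row-z-scored scores), sets x samples.
    """
    sets = _restrict_sets(sets, mat.index)
    n = len(mat)
    members = {name: mat.index.isin(m) for name, m in sets.items()}
    scores = pd.DataFrame(index=list(sets), columns=mat.columns, dtype=float)
    for col in mat.columns:
        vals = mat[col].to_numpy(dtype=float)
        ranks = stats.rankdata(vals, method="average")
        order = np.argsort(-vals, kind="stable")
        w = ranks[order] ** weight_alpha
        for name, in_set in members.items():
            s = in_set[order]
            m = int(s.sum())
            if m == n:
                scores.loc[name, col] = 0.0
                continue
            win = np.where(s, w, 0.0)
            p_in = np.cumsum(win) / win.sum()
            p_out = np.cumsum(~s) / (n - m)
            scores.loc[name, col] = float(np.sum(p_in - p_out))
    mean = scores.mean(axis=1)
    sd = scores.std(axis=1, ddof=1)
    z = scores.sub(mean, axis=0).div(sd.replace(0.0, np.nan), axis=0)
    return scores, z


def _ks_es(stat_sorted: np.ndarray, in_set_sorted: np.ndarray) -> float:
    """Classic weighted Kolmogorov-Smirnov enrichment score (weight = |t|)."""
    n = len(stat_sorted)
    m = int(in_set_sorted.sum())
    if m == 0 or m == n:
        return 0.0
    w = np.abs(stat_sorted) * in_set_sorted
    tot = w.sum()
    p_hit = np.cumsum(w) / tot if tot > 0 else np.cumsum(in_set_sorted) / m
    p_miss = np.cumsum(~in_set_sorted) / (n - m)
    dev = p_hit - p_miss
    return float(dev[np.argmax(np.abs(dev))])


def preranked_gsea(tstats: pd.Series, sets: dict[str, list[str]],
                   nperm: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Pre-ranked GSEA on per-protein t-statistics.

    The null is built from ``nperm`` random same-size gene sets; NES is the
    ES divided by the mean magnitude of same-sign null scores, and the
    p-value carries the +1 permutation correction. Deterministic given seed.
    """
    if nperm < 100:
        raise ValueError("nperm must be >= 100")
    if tstats.index.has_duplicates:
        raise ValueError("duplicate protein ids in ranking")
    n = len(tstats)
    order = np.argsort(-tstats.to_numpy(dtype=float), kind="stable")
    stat_sorted = tstats.to_numpy(dtype=float)[order]
    ids_sorted = tstats.index.to_numpy()[order]
    rng = np.random.default_rng(seed)
    rows = []
    for name, raw_members in sets.items():
        members = set(raw_members) & set(tstats.index)
        if len(raw_members) > n:
            raise ValueError(f"gene set {name!r} larger than the universe")
        if not members:
            continue
        in_set = np.isin(ids_sorted, list(members))
        es = _ks_es(stat_sorted, in_set)
        m = int(in_set.sum())
        null = np.empty(nperm)
        for i in range(nperm):
            perm = np.zeros(n, dtype=bool)
            perm[rng.choice(n, size=m, replace=False)] = True
            null[i] = _ks_es(stat_sorted, perm)
        same_sign = null[null > 0] if es >= 0 else null[null < 0]
        denom = np.abs(same_sign).mean() if len(same_sign) else np.nan
        nes = es / denom if denom and np.isfinite(denom) else np.nan
        p = (1 + int(np.sum(np.abs(null) >= abs(es)))) / (1 + nperm)
        rows.append((name, m, es, nes, p))
    return pd.DataFrame(rows, columns=["set", "size", "ES", "NES", "p"]
                        ).set_index("set")


def group_test_scores(scores: pd.DataFrame, design: pd.DataFrame,
                      factor: str) -> pd.DataFrame:
    """Wilcoxon rank-sum of per-sample enrichment scores between the two
    levels of ``factor`` (site or age), BH-adjusted across sets."""
    levels = design[factor].unique().tolist()
    if len(levels) != 2:
        raise ValueError(f"factor {factor!r} must have exactly two levels")
    ga = design.index[design[factor] == levels[0]]
    gb = design.index[design[factor] == levels[1]]
    if len(ga) < 2 or len(gb) < 2:
        raise ValueError("need at least 2 samples per level")
    ps = []
    for name in scores.index:
        ps.append(compare_groups(scores.loc[name, ga], scores.loc[name, gb])[1])
    return pd.DataFrame({"p": ps, "q": bh_adjust(ps)}, index=scores.index)


def overrepresentation(hits, universe, sets: dict[str, list[str]]
                       ) -> pd.DataFrame:
    """Hypergeometric over-representation of ``hits`` within each gene set,
    relative to ``universe``; BH-adjusted across sets."""
    hits = set(hits)
    uni = set(universe)
    if not hits <= uni:
        raise ValueError("hits must be a subset of the universe")
    rows = []
    for name, members in _restrict_sets(sets, uni).items():
        k = len(hits & set(members))
        p = stats.hypergeom.sf(k - 1, len(uni), len(members), len(hits))
        rows.append((name, len(members), k, float(p)))
    df = pd.DataFrame(rows, columns=["set", "size", "overlap", "p"]
                      ).set_index("set")
    df["q"] = bh_adjust(df["p"])
    return df
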