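"""Atlas-table statistics: hemisphere combination, asymmetry screening,
per-region AUC ranking with Bonferroni correction, and the derived
discriminative composite score.

The central statistic is the per-region area under the ROC curve (AUC) for
separating a positive clinical group from a negative one.  It is computed as
the Mann–Whitney U statistic divided by ``n_pos · n_neg`` (ties counted ½),
oriented so that higher uptake in the positive group gives AUC > 0.5.
Regions exceeding an AUC threshold with a Bonferroni-corrected Mann–Whitney
p below alpha are pooled into a composite whose per-subject score is the
median SUVR over the member regions.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .atlas import LEFT_SUFFIX, RIGHT_SUFFIX

ID_COLUMNS = ("subject_id", "group")

#: Exact Mann–Whitney enumeration is used at or below this many pairs.
EXACT_PAIR_LIMIT = 400


def region_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in ID_COLUMNS and c != "low_uptake_outlier"]


def _split_lateral(table: pd.DataFrame) -> list[str]:
    names = []
    cols = set(table.columns)
    for c in region_columns(table):
        if c.endswith(LEFT_SUFFIX):
            base = c[: -len(LEFT_SUFFIX)]
            if base + RIGHT_SUFFIX in cols:
                names.append(base)
    return names


# --------------------------------------------------------------------------
# Hemisphere combination and asymmetry
# --------------------------------------------------------------------------
def combine_left_right(table: pd.DataFrame, method: str = "mean") -> pd.DataFrame:
    """Collapse ``<region>_L``/``<region>_R`` column pairs into one combined
    column per region (default: arithmetic mean; ``max`` for sensitivity
    analysis).  A missing side falls back to the available side; both sides
    missing yields a missing combined value."""
    if method not in ("mean", "max"):
        raise ValueError("method must be 'mean' or 'max'")
    names = _split_lateral(table)
    if not names:
        raise ValueError("no left/right column pairs found (expected *_L / *_R)")
    out = table[list(ID_COLUMNS)].copy()
    for base in names:
        left = table[base + LEFT_SUFFIX]
        right = table[base + RIGHT_SUFFIX]
        both = pd.concat([left, right], axis=1)
        out[base] = both.mean(axis=1) if method == "mean" else both.max(axis=1)
    return out


def asymmetry_screen(table: pd.DataFrame, alpha: float = 0.001,
                     min_subjects: int = 5) -> tuple[pd.DataFrame, str]:
    """Left-minus-right screen per region and group.

    Reports mean and SD of the per-subject left−right difference and a
    two-sided Wilcoxon signed-rank p (all-zero differences give p=1), flags a
    group×region when its Bonferroni-corrected p falls below ``alpha``, and
    returns a global verdict: ``"no asymmetry detected"`` licenses collapsing
    hemispheres.  The Bonferroni multiplier is the number of tests performed
    (regions × groups)."""
    names = _split_lateral(table)
    if not names:
        raise ValueError("no left/right column pairs found")
    groups = list(dict.fromkeys(table["group"]))
    for g in groups:
        if (table["group"] == g).sum() < min_subjects:
            raise ValueError(f"group {g!r} has fewer than {min_subjects} subjects")
    n_tests = len(names) * len(groups)
    rows = []
    for g in groups:
        sub = table[table["group"] == g]
        for base in names:
            d = (sub[base + LEFT_SUFFIX] - sub[base + RIGHT_SUFFIX]).dropna().to_numpy()
            if d.size == 0 or np.all(d == 0):
                p = 1.0
            else:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    p = float(stats.wilcoxon(d, alternative="two-sided",
                                             zero_method="wilcox").pvalue)
            p_bonf = min(1.0, p * n_tests)
            rows.append({"group": g, "region": base,
                         "mean_diff": float(np.mean(d)) if d.size else np.nan,
                         "sd_diff": float(np.std(d, ddof=1)) if d.size > 1 else np.nan,
                         "p_raw": p, "p_bonferroni": p_bonf,
                         "asymmetric": p_bonf < alpha})
    report = pd.DataFrame(rows)
    verdict = ("no asymmetry detected" if not report["asymmetric"].any()
               else "asymmetry detected")
    return report, verdict


# --------------------------------------------------------------------------
# AUC ranking
# --------------------------------------------------------------------------
def mann_whitney_auc(positive: np.ndarray, negative: np.ndarray) -> float:
    """AUC = U/(n_pos·n_neg) with ties counted ½ via midranks."""
    pos = np.asarray(positive, dtype=float)
    neg = np.asarray(negative, dtype=float)
    combined = np.concatenate([pos, neg])
    ranks = stats.rankdata(combined)
    u_pos = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u_pos / (pos.size * neg.size))


def _mann_whitney_p(positive: np.ndarray, negative: np.ndarray) -> float:
    """Two-sided Mann–Whitney p: exact enumeration for small tie-free
    problems, else normal approximation with continuity and tie correction."""
    n_pairs = positive.size * negative.size
    has_ties = np.unique(np.concatenate([positive, negative])).size < positive.size + negative.size
    method = "exact" if (n_pairs <= EXACT_PAIR_LIMIT and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(positive, negative, alternative="two-sided",
                             method=method, use_continuity=True)
    return float(res.pvalue)


def rank_regions(table: pd.DataFrame, positive_group: str = "PCA",
                 negative_group: str = "DLB") -> pd.DataFrame:
    """Per-region AUC for positive vs negative group, ranked descending.

    Missing values are dropped pairwise per region; regions leaving fewer
    than two usable values in either group are excluded (with a warning) and
    the Bonferroni multiplier is the number of regions actually tested.
    Ties in AUC are broken by region name so the ranking is deterministic.
    """
    for g in (positive_group, negative_group):
        if (table["group"] == g).sum() < 2:
            raise ValueError(f"group {g!r} needs at least 2 subjects")
    pos_tab = table[table["group"] == positive_group]
    neg_tab = table[table["group"] == negative_group]
    rows = []
    for region in region_columns(table):
        pos = pos_tab[region].dropna().to_numpy()
        neg = neg_tab[region].dropna().to_numpy()
        if pos.size < 2 or neg.size < 2:
            warnings.warn(f"region {region!r} excluded: fewer than 2 non-missing "
                          "values in a group", stacklevel=2)
            continue
        rows.append({"region": region,
                     "auc": mann_whitney_auc(pos, neg),
                     "p_raw": _mann_whitney_p(pos, neg),
                     "n_pos": pos.size, "n_neg": neg.size})
    if not rows:
        raise ValueError("no region had enough data to rank")
    ranking = pd.DataFrame(rows)
    n_tested = len(ranking)
    ranking["p_bonferroni"] = np.minimum(1.0, ranking["p_raw"] * n_tested)
    ranking = ranking.sort_values(["auc", "region"], ascending=[False, True],
                                  kind="mergesort").reset_index(drop=True)
    ranking["rank"] = np.arange(1, n_tested + 1)
    return ranking[["region", "auc", "p_raw", "p_bonferroni", "rank", "n_pos", "n_neg"]]


# --------------------------------------------------------------------------
# Composite definition and scoring
# --------------------------------------------------------------------------
@dataclass(frozen=True)
class CompositeDefinition:
    """An ordered set of regions pooled by per-subject median SUVR."""

    regions: tuple[str, ...]
    auc_threshold: float
    alpha: float
    aggregation: str = "median"
    provenance: tuple[dict, ...] = field(default_factory=tuple)

    def to_json(self, path) -> None:
        payload = {"regions": list(self.regions),
                   "auc_threshold": self.auc_threshold, "alpha": self.alpha,
                   "aggregation": self.aggregation,
                   "provenance": list(self.provenance)}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "CompositeDefinition":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(tuple(raw["regions"]), raw["auc_threshold"], raw["alpha"],
                   raw.get("aggregation", "median"),
                   tuple(raw.get("provenance", ())))


def select_composite(ranking: pd.DataFrame, auc_threshold: float = 0.97,
                     alpha: float = 0.001) -> CompositeDefinition:
    """Regions with ``auc > auc_threshold`` (strict) and Bonferroni-corrected
    ``p < alpha`` (strict), kept in rank order.  An empty selection is valid
    and flagged by a warning."""
    if ranking.empty:
        raise ValueError("ranking is empty")
    sel = ranking[(ranking["auc"] > auc_threshold) & (ranking["p_bonferroni"] < alpha)]
    if sel.empty:
        warnings.warn(f"no region exceeded AUC {auc_threshold} at Bonferroni "
                      f"p < {alpha}; composite is empty", stacklevel=2)
    provenance = tuple(ranking.round(12).to_dict("records"))
    return CompositeDefinition(tuple(sel["region"]), auc_threshold, alpha,
                               provenance=provenance)


def composite_score(table: pd.DataFrame, composite: CompositeDefinition) -> pd.Series:
    """Per-subject median SUVR over the composite's member regions.

    Subjects missing some member regions are scored on the remaining support
    (with a warning); subjects missing all members get a missing score.
    """
    if not composite.regions:
        raise ValueError("composite has no member regions")
    missing_cols = [r for r in composite.regions if r not in table.columns]
    if missing_cols:
        raise ValueError(f"table lacks composite region(s) {missing_cols}")
    block = table[list(composite.regions)]
    incomplete = int((block.isna().any(axis=1) & block.notna().any(axis=1)).sum())
    if incomplete:
        warnings.warn(f"{incomplete} subject(s) scored on a reduced composite "
                      "(missing member regions)", stacklevel=2)
    scores = block.median(axis=1, skipna=True)
    scores.name = "composite_score"
    return scores
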